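# Methods

## Coordinate and binning contract

Pixel indices are 0-based `(row, column) = (y, x)`. AP positions are % egg
length (%EL), 0 at the anterior pole, 100 at the posterior; bin *i* of an
*N*-bin profile covers `[i·100/N, (i+1)·100/N)` %EL. Distances from a pole
are measured toward the embryo center, in %EL or μm. Anterior is the pole
listed first in the geometry annotation — orientation is a mounting
convention supplied by the user or the generator, never inferred from
pixel content. Invalid pixels (vitelline ring, yolk, pole cells, outside
the embryo) are NaN; every mean ignores them, and a region with no valid
pixel yields NaN (surfaced as an error where a scalar is required), never
a silent 0. Undefined profile bins are empty CSV cells.

## Synthetic scenes

The generator is the package's ground-truth instrument, not a fixture: it
renders the imaging regimes the operators must handle and stores the
analytic truth next to the pixels.

**Geometry.** An ellipse of length 500 μm and width 180 μm (defaults) at
1 μm/px, with a 20 μm margin. Two views stand in for the acquisition
modes used on real embryos: a `surface` view (the analogue of a maximum
z-projection of the cortex: membrane lattice + nuclei) and a `sagittal`
view (mid-plane: cortical membrane as a 1-3 px perimeter band). Rendering
is 2D; the z dimension of real stacks is represented by providing both
views directly, which keeps runs desk-scale and the truth exact.

**Gradients.** Membrane recruitment at distance *d* from a pole follows a
plateau plus single-exponential,

    g(d) = peak                       d ≤ plateau
    g(d) = peak · exp(−(d−plateau)/λ) d > plateau

per pole and per nuclear cycle. No functional form is established for the
real gradients; this one is chosen because its half-max boundary is
analytic (`plateau + λ·ln 2`), which gives every width measurement an
exact oracle. The full-axis truth profile is the superposition of the two
poles' gradients. Defaults per stage (free parameters, fixed once):
plateau/λ = 30/30, 25/25, 20/20, 15/15 μm and peak 200, 150, 60, 20 AU
for NC11-14 — a domain that narrows and an amplitude that collapses to
10% of its NC11 value; cytosolic background 60, 75, 95, 130 AU (a
monotone ~2.2× rise); downstream (ERK-like) λ = 92 μm with sustained
peak, rendered as a cytoplasmic stain. Alternatively `blur_mode` derives
the downstream profile by convolving the receptor profile with a
normalized Gaussian (reflecting ends, integral-preserving) — the
diffusion reading of how a narrow receptor domain yields a longer-range
gradient; direct parameterization is the default for determinism.

**Membrane lattice.** Cortical compartments are the Voronoi cells of a
hexagonal grid (8 μm spacing, rotated 15° to the AP axis so the lattice
period does not beat against the 5 μm profile bins); recruitment is
painted on the ~1 px cell edges and blurred by a 0.5 μm Gaussian PSF.
Bin means over a 40 px band therefore scale the true gradient by the
lattice coverage fraction — a uniform factor that cancels in widths and
amplitude ratios, exactly as membrane-localized signal behaves in real
line scans.

**Clutter and noise.** A bright ring just outside the embryo boundary
models the autofluorescent vitelline membrane; seeded disks model yolk
granules; both masks are part of the truth so the exclusion step of the
pipeline can be exercised. Noise is Poisson on signal plus Gaussian read
noise, both off by default: the benchmark scenes are noise-free so every
deviation is attributable to the operators, not the draw.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical z-blur and pole curvature (the reason
the extreme 1-2 %EL of real embryos are excluded is only represented by
the `imaged_fraction` metadata, default 0.98/end), nuclear-cycle
dynamics within a scene, camera-specific noise, photobleaching during
acquisition, and real segmentation error (ground-truth label masks are
perfect; Cellpose-style segmentation is consumed, not reproduced — a
threshold fallback exists for demos only).

## Profile extraction

The AP line profile averages a 40 px (configurable: 20 px for stains,
80 px for high-magnification pole crops) band along the pole-to-pole
segment into 100 bins spanning the *full* embryo length; bins overlapping
the unimaged end fractions are undefined. The perimeter profile samples a
band at radial depths [1, 1+width) px inside the embryo contour —
adjacent to but not overlapping the vitelline ring — binned by arc
length; the scan starts at the dorsal-most contour point and proceeds
anterior-first, fixing the bin↔arc map. The contour comes from the truth
mask when available, else an Otsu threshold of the cytosolic signal.

Center background subtraction uses the 40-60 %EL bins (configurable; the
off-region extent is a judgment call on real data), with an optional
per-half split for tilted baselines. The rolling-ball variant
(morphological background with a 50 px ball per z slice, then maximum
projection, then signal-box minus background-box) serves small-field,
low-SNR acquisitions.

## Metrics

Domain width is evaluated at bin granularity with no sub-bin
interpolation — matching the 1 %EL resolution of the binned analysis and
making the brute-force oracle exact. The scan is capped at 50 %EL (the
opposite pole's half belongs to the other measurement). Peak
detectability requires the polar maximum to be positive and to exceed
`detect_k` (default 3) times a noise scale, estimated as the robust SD
(1.4826·MAD) of the center bins when not supplied; a flat profile
reports an undefined width rather than 50. Amplitude windows are
half-open ([5,10) and [90,95) %EL), consistent with the bin contract;
negative window means (over-subtraction) clip to 0. Perimeter peaks are
strict local maxima of the wrapped profile above the median by at least
half the dynamic range and the detectability floor, merged within 10
bins.

## Cellular readouts

The cytoplasmic ring for the translocation-reporter ratio is a 2 px
label expansion minus all nuclei (the dilation-and-subtract recipe; the
width is a free choice). Border-touching nuclei are skipped. The ERK-off
threshold on the cyto:nuclear ratio is 1.0 — nuclear-dominant reporter
means kinase off; the cutoff is a definition, not a fit. Burst detection
thresholds a projection at an absolute level (an automatic median + k·MAD
mode is provided) and keeps connected components of ≥ 2 px (`min_spot_px`,
exposed rather than guessed). Tiled Pearson boxes are centered at evenly
spaced points from stalk to tip endpoint; zero-variance boxes report NaN
rather than a fabricated r.

## FRAP

Diffusion on the membrane patch is integrated with an explicit flux-form
finite-difference scheme with reflecting boundaries: fluxes are
antisymmetric by construction, so total intensity is conserved to machine
precision after the bleach, and the well-mixed plateau is predictable
from bookkeeping alone (post-bleach total / area). The time step obeys
`Δt ≤ 0.9·h²/4D`. Frame 0 is prebleach; the bleach is instantaneous. The
recovery fraction is reported relative to the post-bleach deficit
(ρ = (R−R₀)/(1−R₀)) because "% recovery" is ambiguous under partial
bleaching; both R and ρ are available. Note that with fast diffusion R₀
(measured at the first frame, one interval after the bleach) already
contains early recovery — as it does in real acquisitions.

## Numerical choices and degenerate inputs

Bin means are computed by assigning each band pixel to its bin (no
interpolation), which keeps NaN propagation exact; resampling error is
bounded by the bin-count-invariance and mean-conservation tests. Boxes
are validated to lie inside the image; overlapping signal/background
boxes warn but proceed. Degenerate anchors (min-max normalization),
coincident poles, missing pixel sizes, empty center regions and
prebleach ≤ background all raise immediately rather than producing
numbers.

## Benchmark problem sizes

The acceptance scenes are single 540 × 220 px embryos (500 μm at
1 μm/px), 31-frame 50 × 50 px FRAP series, and 100-bin profiles — sizes
at which a full target runs in seconds while leaving every boundary
measurement at the same 1 %EL / 5 μm granularity as the analysis the
package implements.

## Known limitations

The width/amplitude operators assume the profile's OFF region genuinely
sits inside the center window: for gradients whose decay length is a
substantial fraction of the embryo (λ ≳ 60 μm), the exponential tail
contributes to the center mean and the measured half-max boundary moves
inward relative to the analytic `plateau + λ·ln 2` — a property of the
center-normalization definition itself, shared by any analysis using it,
and visible in the benchmark for the broad downstream channel. The
perimeter scan assumes a single closed contour (no touching embryos).
The FRAP simulator models a homogeneous 2D membrane; it does not include
reversible binding or the lattice texture of the cortex.
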