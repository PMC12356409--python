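"""Summary statistics of binned signaling profiles.

Implements the two headline per-embryo metrics used to compare receptor
activity with downstream pathway activity across nuclear cycles:

* **domain width** — the distance from a pole (in %EL) at which the
  background-subtracted profile drops *permanently* below half of its
  polar maximum, evaluated at bin granularity with no sub-bin
  interpolation;
* **domain amplitude** — the mean background-subtracted intensity over
  the 5–10 %EL (anterior) and 90–95 %EL (posterior) windows, clipped at
  zero.

Plus perimeter-profile peak counting and the 0–1 min-max normalization
used for translocation-reporter and in-situ profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import PCT_EL, BinnedProfile, _center_bin_indices

__all__ = [
    "DomainMetrics",
    "domain_width",
    "domain_amplitude",
    "count_pole_peaks",
    "normalize_minmax",
    "compute_domain_metrics",
    "robust_noise_sigma",
]

ANTERIOR = "anterior"
POSTERIOR = "posterior"


def _half_from_pole(profile: BinnedProfile, pole: str) -> np.ndarray:
    """Bin values ordered by increasing distance from the pole, covering
    at most the pole-near half of the axis."""
    if pole not in (ANTERIOR, POSTERIOR):
        raise ValueError("pole must be 'anterior' or 'posterior'")
    v = profile.values
    k = v.size // 2
    return v[:k] if pole == ANTERIOR else v[::-1][:k]


def robust_noise_sigma(
    profile: BinnedProfile, center_range_pct: tuple[float, float] = (40.0, 60.0)
) -> float:
    """Robust SD (1.4826 * MAD) of the center-region bins, used as the
    bin-level noise scale for peak detectability."""
    idx = _center_bin_indices(profile, *center_range_pct)
    v = profile.values[idx] if idx.size else profile.values
    v = v[~np.isnan(v)]
    if v.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def domain_width(
    profile: BinnedProfile,
    pole: str,
    detect_k: float = 3.0,
    noise_sigma: float | None = None,
) -> float | None:
    """Half-maximum domain width at one pole, in %EL (or the profile's
    distance unit), or ``None`` when there is no detectable peak.

    Let the bins be ordered by increasing distance ``d`` from the pole and
    ``M`` their maximum.  The width is the smallest ``d*`` such that every
    defined bin at ``d >= d*`` is below ``M/2`` — equivalently one bin past
    the last bin at or above half-maximum.  ``M`` must exceed
    ``detect_k * noise_sigma`` (sigma estimated from the center region when
    not supplied) and be positive, else the peak is undetectable.
    """
    half = _half_from_pole(profile, pole)
    defined = ~np.isnan(half)
    if not defined.any():
        raise ValueError("all bins near the pole are undefined")
    m = float(np.nanmax(half))
    if noise_sigma is None:
        noise_sigma = robust_noise_sigma(profile) if profile.axis_kind == PCT_EL else 0.0
    if m <= 0 or m < detect_k * noise_sigma:
        return None
    above = np.nonzero(defined & (half >= m / 2.0))[0]
    return float((above[-1] + 1) * profile.bin_width)


def domain_amplitude(
    profile: BinnedProfile,
    windows_pct: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 10.0), (90.0, 95.0)),
) -> tuple[float, float]:
    """(anterior, posterior) domain amplitude in AU.

    Mean of the background-subtracted bins covering the half-open windows
    [5, 10) and [90, 95) %EL; undefined bins are excluded and negative
    window means are clipped to 0.
    """
    if not profile.background_subtracted:
        raise ValueError("domain amplitude requires a background-subtracted profile")
    out = []
    for lo, hi in windows_pct:
        idx = _center_bin_indices(profile, lo, hi)
        if idx.size == 0:
            raise ValueError(f"no whole bin inside window [{lo}, {hi}) %EL")
        vals = profile.values[idx]
        if np.all(np.isnan(vals)):
            raise ValueError(f"all bins in window [{lo}, {hi}) %EL are undefined")
        out.append(max(float(np.nanmean(vals)), 0.0))
    return out[0], out[1]


def count_pole_peaks(
    profile: BinnedProfile,
    min_separation_bins: int = 10,
    height_frac: float = 0.5,
    detect_k: float = 3.0,
    noise_sigma: float | None = None,
) -> int:
    """Number of distinct activity peaks on a circular perimeter profile.

    A bin is a candidate peak if it is a strict local maximum of the
    wrapped profile and exceeds the median by both ``height_frac`` of the
    (max - median) range and ``detect_k * noise_sigma``; candidates closer
    than ``min_separation_bins`` along the circle are merged, keeping the
    strongest.  A flat profile has no detectable peak.
    """
    v = profile.values
    med = float(np.nanmedian(v))
    m = float(np.nanmax(v))
    filled = np.where(np.isnan(v), med, v)
    if noise_sigma is None:
        dev = filled - med
        noise_sigma = float(1.4826 * np.median(np.abs(dev)))
    rng_height = m - med
    if rng_height <= 0 or rng_height < detect_k * noise_sigma:
        return 0
    threshold = med + max(height_frac * rng_height, detect_k * noise_sigma)

    n = filled.size
    candidates = []
    for i in range(n):
        left, right = filled[(i - 1) % n], filled[(i + 1) % n]
        if filled[i] >= threshold and filled[i] >= left and filled[i] >= right:
            # skip plateau duplicates: keep only the first bin of a plateau
            if filled[i] == left and candidates and (i - 1) % n == candidates[-1]:
                continue
            candidates.append(i)
    if not candidates:
        return 0
    # merge circularly-close candidates, keeping the strongest of each group
    candidates.sort()
    groups: list[list[int]] = [[candidates[0]]]
    for i in candidates[1:]:
        if i - groups[-1][-1] < min_separation_bins:
            groups[-1].append(i)
        else:
            groups.append([i])
    if len(groups) > 1 and (n - groups[-1][-1] + groups[0][0]) < min_separation_bins:
        groups[0] = groups.pop() + groups[0]
    return len(groups)


def normalize_minmax(
    profile: BinnedProfile, low_anchor: float, high_anchor: float
) -> BinnedProfile:
    """Affine map sending ``low_anchor -> 0`` and ``high_anchor -> 1``.

    Values are not clamped: bins outside the anchor range map outside
    [0, 1] exactly as the data dictate.
    """
    span = high_anchor - low_anchor
    if span == 0 or not np.isfinite(span):
        raise ValueError("degenerate normalization range (anchors equal)")
    prov = dict(profile.provenance)
    prov["minmax_anchors"] = [float(low_anchor), float(high_anchor)]
    return profile.with_values((profile.values - low_anchor) / span, provenance=prov)


@dataclass
class DomainMetrics:
    """Per-embryo summary: half-max widths (%EL, None when the pole has no
    detectable peak) and background-subtracted amplitudes (AU, >= 0)."""

    width_anterior_pct_el: float | None
    width_posterior_pct_el: float | None
    amplitude_anterior_au: float
    amplitude_posterior_au: float

    @property
    def detectable_anterior(self) -> bool:
        return self.width_anterior_pct_el is not None

    @property
    def detectable_posterior(self) -> bool:
        return self.width_posterior_pct_el is not None


def compute_domain_metrics(
    profile: BinnedProfile, detect_k: float = 3.0, noise_sigma: float | None = None
) -> DomainMetrics:
    """Widths and amplitudes at both poles from one background-subtracted
    full-axis profile."""
    wa = domain_width(profile, ANTERIOR, detect_k=detect_k, noise_sigma=noise_sigma)
    wp = domain_width(profile, POSTERIOR, detect_k=detect_k, noise_sigma=noise_sigma)
    aa, ap = domain_amplitude(profile)
    return DomainMetrics(
        width_anterior_pct_el=wa,
        width_posterior_pct_el=wp,
        amplitude_anterior_au=aa,
        amplitude_posterior_au=ap,
    )
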