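"""Non-gradient quantifications: apical enrichment, tiled colocalization,
nuclear:cytoplasmic translocation-reporter ratios, ERK-off fraction, and
transcription-burst counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.segmentation import expand_labels

from .metrics import normalize_minmax
from .profiles import PCT_EL, BinnedProfile
from .sceneio import EmbryoGeometry, ImageScene

__all__ = [
    "PearsonProfile",
    "BurstTable",
    "NuclearRatioProfile",
    "apical_enrichment",
    "tiled_pearson",
    "cyto_nuclear_ratio",
    "erk_off_fraction",
    "detect_bursts",
    "mad_threshold",
]


def _as_plane(image, channel=None) -> tuple[np.ndarray, float | None]:
    if isinstance(image, ImageScene):
        return image.plane(channel=channel), image.pixel_size_um
    return np.asarray(image, dtype=float), None


def _sample_polyline(line_px: np.ndarray, spacing_px: float = 1.0) -> np.ndarray:
    """Resample a polyline (or a 2-point segment) at ~pixel spacing."""
    pts = np.asarray(line_px, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("line must be an (N, 2) array of (y, x) points")
    if len(pts) == 2:
        n = max(int(round(np.hypot(*(pts[1] - pts[0])) / spacing_px)) + 1, 2)
        return np.linspace(pts[0], pts[1], n)
    return pts


def _sample_band(plane: np.ndarray, line: np.ndarray, width_px: int) -> np.ndarray:
    """Mean intensity across a band of ``width_px`` centered on the line,
    one value per line sample (NaN-aware)."""
    tangent = np.gradient(line, axis=0)
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    norm[norm == 0] = 1.0
    normal = np.column_stack([-tangent[:, 1] / norm, tangent[:, 0] / norm])
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    samples = []
    for off in offsets:
        coords = (line + off * normal).T
        samples.append(
            ndi.map_coordinates(plane, coords, order=1, mode="constant", cval=np.nan)
        )
    with np.errstate(all="ignore"):
        return np.nanmean(np.stack(samples), axis=0)


def apical_enrichment(
    image,
    apical_line_px,
    cyto_line_px,
    line_width_px: int = 5,
    bin_px: int = 3,
    channel=None,
) -> np.ndarray:
    """Membrane / cytoplasm intensity ratio along the apical surface.

    Both lines are sampled at matching positions with a ``line_width_px``
    band; the per-position ratio is averaged in non-overlapping ``bin_px``
    blocks (a trailing partial block is dropped).  Positions with zero or
    invalid cytoplasmic intensity are excluded from their block mean.
    """
    plane, _ = _as_plane(image, channel)
    apical = _sample_polyline(apical_line_px)
    cyto = _sample_polyline(cyto_line_px)
    if len(apical) != len(cyto):
        # resample the cytoplasmic line onto the apical parameterization
        t_old = np.linspace(0, 1, len(cyto))
        t_new = np.linspace(0, 1, len(apical))
        cyto = np.column_stack(
            [np.interp(t_new, t_old, cyto[:, 0]), np.interp(t_new, t_old, cyto[:, 1])]
        )
    mem = _sample_band(plane, apical, line_width_px)
    cyt = _sample_band(plane, cyto, line_width_px)
    with np.errstate(all="ignore"):
        ratio = np.where((cyt > 0) & ~np.isnan(mem), mem / cyt, np.nan)
    n_blocks = len(ratio) // bin_px
    if n_blocks == 0:
        raise ValueError("line shorter than one block")
    blocks = ratio[: n_blocks * bin_px].reshape(n_blocks, bin_px)
    with np.errstate(all="ignore"):
        return np.nanmean(blocks, axis=1)


@dataclass
class PearsonProfile:
    """Per-box Pearson correlations along a branch axis, stalk -> tip."""

    correlations: np.ndarray  # NaN where a box had zero variance
    centers_px: np.ndarray  # (n_boxes, 2) box centers, (y, x)
    box_side_um: float
    n_boxes: int

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        ok = self.correlations[~np.isnan(self.correlations)]
        if ok.size and (np.any(ok < -1 - 1e-9) or np.any(ok > 1 + 1e-9)):
            raise ValueError("Pearson r outside [-1, 1]")


def tiled_pearson(
    chan_a,
    chan_b,
    branch_axis,
    n_boxes: int,
    box_side_um: float = 4.5,
    pixel_size_um: float | None = None,
    channel_a=None,
    channel_b=None,
) -> PearsonProfile:
    """Pearson correlation between two channels in square boxes tiled
    along a branch axis (stalk endpoint first, tip endpoint last).

    ``branch_axis`` is a pair of (y, x) pixel endpoints; box centers are
    evenly spaced between them.  A box with zero variance in either
    channel reports NaN.
    """
    if not 7 <= n_boxes <= 9:
        raise ValueError("n_boxes must be in [7, 9]")
    a, px_a = _as_plane(chan_a, channel_a)
    b, px_b = _as_plane(chan_b, channel_b)
    px = pixel_size_um or px_a or px_b
    if px is None:
        raise ValueError("pixel_size_um required when passing bare arrays")
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    start, end = (np.asarray(p, dtype=float) for p in branch_axis)
    centers = np.linspace(start, end, n_boxes)
    half = box_side_um / 2.0 / px
    rs = []
    for cy, cx in centers:
        y0, y1 = int(round(cy - half)), int(round(cy + half))
        x0, x1 = int(round(cx - half)), int(round(cx + half))
        if y0 < 0 or x0 < 0 or y1 > a.shape[0] or x1 > a.shape[1]:
            raise ValueError("a correlation box exits the image")
        pa, pb = a[y0:y1, x0:x1].ravel(), b[y0:y1, x0:x1].ravel()
        ok = ~np.isnan(pa) & ~np.isnan(pb)
        pa, pb = pa[ok], pb[ok]
        if pa.size < 2 or np.std(pa) == 0 or np.std(pb) == 0:
            rs.append(np.nan)
        else:
            rs.append(float(np.corrcoef(pa, pb)[0, 1]))
    return PearsonProfile(
        correlations=np.asarray(rs),
        centers_px=centers,
        box_side_um=box_side_um,
        n_boxes=n_boxes,
    )


@dataclass
class NuclearRatioProfile:
    """Cytoplasmic:nuclear reporter ratio binned along the AP axis."""

    ratios: np.ndarray  # per-bin mean ratio, NaN where no nucleus
    n_bins: int
    per_nucleus: pd.DataFrame = field(repr=False, default=None)

    def as_profile(self) -> BinnedProfile:
        return BinnedProfile(values=self.ratios, axis_kind=PCT_EL)

    def normalized(self, center_range_pct=(40.0, 60.0)) -> np.ndarray:
        """0–1 normalization: center-region mean ratio -> 0, the
        anterior-pole-most defined bin -> 1."""
        prof = self.as_profile()
        from .profiles import _center_bin_indices

        idx = _center_bin_indices(prof, *center_range_pct)
        low = float(np.nanmean(self.ratios[idx]))
        defined = np.nonzero(~np.isnan(self.ratios))[0]
        if defined.size == 0:
            raise ValueError("profile has no defined bin")
        high = float(self.ratios[defined[0]])
        return normalize_minmax(prof, low, high).values


def cyto_nuclear_ratio(
    image,
    nuclear_labels: np.ndarray,
    geometry: EmbryoGeometry,
    ring_dilation_px: int = 2,
    n_bins: int = 50,
    channel=None,
    pixel_size_um: float | None = None,
) -> NuclearRatioProfile:
    """Per-nucleus cytoplasmic-ring : nuclear intensity ratio, averaged in
    AP bins by nuclear centroid.

    The cytoplasmic ring is the ``ring_dilation_px`` expansion of each
    nucleus minus all nuclei.  Nuclei touching the image border are
    skipped; nuclei with an empty ring or no valid pixels are skipped.
    """
    plane, px = _as_plane(image, channel)
    px = pixel_size_um or px
    if px is None:
        raise ValueError("pixel_size_um required when passing a bare array")
    labels = np.asarray(nuclear_labels).astype(np.int64)
    if labels.shape != plane.shape:
        raise ValueError("label image shape does not match intensity plane")
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    expanded = expand_labels(labels, distance=ring_dilation_px)
    ring_lab = np.where(labels == 0, expanded, 0)

    ids = np.unique(labels)
    ids = ids[(ids > 0) & ~np.isin(ids, border)]
    if ids.size == 0:
        raise ValueError("no usable (non-border) nuclei in the label image")

    valid = ~np.isnan(plane)
    filled = np.where(valid, plane, 0.0)

    def _means(lab_img):
        sums = np.bincount(lab_img[valid].ravel(), weights=filled[valid].ravel(), minlength=labels.max() + 1)
        counts = np.bincount(lab_img[valid].ravel(), minlength=labels.max() + 1)
        with np.errstate(invalid="ignore"):
            m = sums / counts
        m[counts == 0] = np.nan
        return m

    nuc_mean = _means(labels)
    ring_mean = _means(ring_lab)
    cy = ndi.center_of_mass(np.ones_like(labels), labels, ids)
    centroids = np.asarray(cy, dtype=float)

    ant = np.asarray(geometry.anterior_pole_px, dtype=float)
    post = np.asarray(geometry.posterior_pole_px, dtype=float)
    u = (post - ant) / np.hypot(*(post - ant))
    L = geometry.embryo_length_um

    records = []
    for i, lab in enumerate(ids):
        nm, rm = nuc_mean[lab], ring_mean[lab]
        if np.isnan(nm) or np.isnan(rm) or nm <= 0:
            continue
        t_um = float(np.dot(centroids[i] - ant, u)) * px
        if not 0.0 <= t_um < L:
            continue
        records.append((int(lab), t_um, rm / nm))
    if not records:
        raise ValueError("no nucleus produced a defined ratio")
    df = pd.DataFrame(records, columns=["label", "position_um", "ratio"])
    bin_idx = np.minimum((df["position_um"] / L * n_bins).astype(int), n_bins - 1)
    ratios = np.full(n_bins, np.nan)
    grouped = df.groupby(bin_idx)["ratio"].mean()
    ratios[grouped.index.to_numpy()] = grouped.to_numpy()
    return NuclearRatioProfile(ratios=ratios, n_bins=n_bins, per_nucleus=df)


def erk_off_fraction(profile: NuclearRatioProfile, threshold: float = 1.0) -> float:
    """Fraction of the embryo length in the ERK-off state.

    A bin is ERK-off when its cytoplasmic:nuclear ratio is below
    ``threshold`` (reporter nuclear => kinase inactive).  With no terminal
    activity the metric equals 1.
    """
    v = profile.ratios
    defined = ~np.isnan(v)
    if not defined.any():
        raise ValueError("profile has no defined bin")
    return float(np.sum(v[defined] < threshold) / np.sum(defined))


def mad_threshold(image, k: float = 8.0, channel=None) -> float:
    """Automatic burst threshold: median + k * robust SD of the plane."""
    plane, _ = _as_plane(image, channel)
    v = plane[~np.isnan(plane)]
    med = float(np.median(v))
    return med + k * 1.4826 * float(np.median(np.abs(v - med)))


@dataclass
class BurstTable:
    """Detected transcription-burst particles and their 5 um histogram."""

    table: pd.DataFrame  # distance_um, peak_au, area_px, y_px, x_px
    bin_um: float = 5.0

    def __len__(self) -> int:
        return len(self.table)

    def histogram(self, bin_um: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges_um, counts); counts sum to the particle count."""
        b = bin_um or self.bin_um
        d = self.table["distance_um"].to_numpy()
        if len(d) == 0:
            return np.array([0.0, b]), np.array([0])
        n = int(np.floor(d.max() / b)) + 1
        edges = np.arange(n + 1) * b
        counts, _ = np.histogram(d, bins=edges)
        return edges, counts

    def max_distance_um(self) -> float:
        if len(self.table) == 0:
            raise ValueError("no bursts detected")
        return float(self.table["distance_um"].max())


def detect_bursts(
    image,
    threshold_au: float,
    geometry: EmbryoGeometry,
    min_spot_px: int = 2,
    channel=None,
    pixel_size_um: float | None = None,
) -> BurstTable:
    """Threshold a maximum projection and count burst particles.

    Connected components above ``threshold_au`` with at least
    ``min_spot_px`` pixels are particles; each particle's centroid
    distance to the posterior pole is reported in um, with counts binned
    at 5 um.  An empty table is a valid result.
    """
    plane, px = _as_plane(image, channel)
    px = pixel_size_um or px
    if px is None:
        raise ValueError("pixel_size_um required when passing a bare array")
    mask = np.nan_to_num(plane, nan=-np.inf) >= threshold_au
    lab, n = ndi.label(mask)
    records = []
    if n:
        ids = np.arange(1, n + 1)
        areas = ndi.sum_labels(np.ones_like(lab), lab, index=ids)
        peaks = ndi.maximum(np.nan_to_num(plane, nan=0.0), lab, index=ids)
        cents = ndi.center_of_mass(np.ones_like(lab), lab, ids)
        post = np.asarray(geometry.posterior_pole_px, dtype=float)
        for i, lab_id in enumerate(ids):
            if areas[i] < min_spot_px:
                continue
            cy, cx = cents[i]
            d_um = float(np.hypot(cy - post[0], cx - post[1])) * px
            records.append((d_um, float(peaks[i]), int(areas[i]), cy, cx))
    df = pd.DataFrame(
        records, columns=["distance_um", "peak_au", "area_px", "y_px", "x_px"]
    )
    return BurstTable(table=df)
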