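"""Binned 1D intensity profiles and box-based quantifications.

The central products here are the 100-bin anterior-posterior line scan and
the 100-bin perimeter scan used to quantify polar signaling gradients,
plus the center-region background estimators and the rolling-ball box-pair
readout used for noisy, small-field acquisitions.

Bin contract: bin ``i`` of an ``N``-bin full-axis profile covers
``[i*100/N, (i+1)*100/N)`` % egg length (%EL), anterior = 0.  Undefined
bins (unimaged ends, fully masked regions) are NaN and propagate as empty
CSV cells, never as 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import filters, measure
from skimage.restoration import rolling_ball

from .sceneio import EmbryoGeometry, ImageScene

__all__ = [
    "BinnedProfile",
    "RoiBox",
    "perimeter_profile",
    "ap_line_profile",
    "subtract_center_background",
    "center_box_background",
    "normalize_background_series",
    "box_pair_quant",
]

PCT_EL = "pct_el_full_axis"
UM_FROM_POLE = "um_from_pole"


@dataclass
class BinnedProfile:
    """A binned 1D intensity profile (NaN = undefined bin)."""

    values: np.ndarray
    axis_kind: str = PCT_EL
    bin_width: float | None = None  # %EL (or um for um_from_pole profiles)
    background_subtracted: bool = False
    line_width_px: int | None = None
    channel: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile values must be a non-empty 1D array")
        if self.bin_width is None:
            if self.axis_kind == PCT_EL:
                self.bin_width = 100.0 / self.values.size
            else:
                raise ValueError("bin_width required for um_from_pole profiles")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def with_values(self, values: np.ndarray, **updates) -> "BinnedProfile":
        return replace(self, values=np.asarray(values, dtype=float), **updates)

    def to_dataframe(self) -> pd.DataFrame:
        unit = "pct_el" if self.axis_kind == PCT_EL else "um"
        return pd.DataFrame(
            {
                f"position_{unit}": self.bin_centers(),
                "intensity_au": self.values,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """CSV with one row per bin plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "axis_kind": self.axis_kind,
            "bin_width": self.bin_width,
            "background_subtracted": self.background_subtracted,
            "line_width_px": self.line_width_px,
            "channel": self.channel,
            "provenance": _jsonable(self.provenance),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinnedProfile":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(
            values=df["intensity_au"].to_numpy(),
            axis_kind=meta.get("axis_kind", PCT_EL),
            bin_width=meta.get("bin_width"),
            background_subtracted=meta.get("background_subtracted", False),
            line_width_px=meta.get("line_width_px"),
            channel=meta.get("channel"),
            provenance=meta.get("provenance", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass(frozen=True)
class RoiBox:
    """Square region of interest, physically sized."""

    center_px: tuple[float, float]  # (y, x)
    side_um: float
    purpose: str = ""

    def __post_init__(self) -> None:
        if not self.side_um > 0:
            raise ValueError("side_um must be > 0")

    def slices(self, pixel_size_um: float, shape: tuple[int, int]) -> tuple[slice, slice]:
        half = self.side_um / 2.0 / pixel_size_um
        cy, cx = self.center_px
        y0, y1 = int(round(cy - half)), int(round(cy + half))
        x0, x1 = int(round(cx - half)), int(round(cx + half))
        if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
            raise ValueError(f"box {self.purpose or self.center_px} exits the image")
        return slice(y0, y1), slice(x0, x1)


def _plane_with_exclusion(
    scene: ImageScene, channel, exclude_mask, z: int | None = None
) -> np.ndarray:
    plane = scene.plane(channel=channel, z=z)
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask) != 0
        if exclude_mask.shape != plane.shape:
            raise ValueError("exclude_mask shape does not match image plane")
        plane = plane.copy()
        plane[exclude_mask] = np.nan
    return plane


def _bin_means(bin_idx: np.ndarray, vals: np.ndarray, n_bins: int) -> np.ndarray:
    """nan-aware per-bin means; empty bins -> NaN."""
    ok = ~np.isnan(vals)
    sums = np.bincount(bin_idx[ok], weights=vals[ok], minlength=n_bins)
    counts = np.bincount(bin_idx[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def ap_line_profile(
    scene: ImageScene,
    geometry: EmbryoGeometry,
    channel: int | str | None = None,
    width_px: int = 40,
    n_bins: int = 100,
    exclude_mask: np.ndarray | None = None,
) -> BinnedProfile:
    """Mean intensity in a wide band along the pole-to-pole axis, averaged
    into ``n_bins`` bins spanning the FULL embryo length.

    Bins overlapping the unimaged end fractions of the axis are undefined,
    as are bins containing no valid pixel.  ``width_px`` and ``n_bins``
    default to the receptor-biosensor settings (40 px, 100 bins); narrower
    stains use e.g. 20 px.
    """
    if width_px < 1:
        raise ValueError("band width must be at least 1 px")
    geometry.validate_against(scene.pixel_size_um)
    plane = _plane_with_exclusion(scene, channel, exclude_mask)
    px = scene.pixel_size_um
    L = geometry.embryo_length_um

    ant = np.asarray(geometry.anterior_pole_px, dtype=float)
    post = np.asarray(geometry.posterior_pole_px, dtype=float)
    axis = post - ant
    axis_len = np.hypot(*axis)
    u = axis / axis_len

    yy, xx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]].astype(float)
    dy, dx = yy - ant[0], xx - ant[1]
    t_um = (dy * u[0] + dx * u[1]) * px
    perp_px = np.abs(dy * u[1] - dx * u[0])

    in_band = (perp_px <= width_px / 2.0) & (t_um >= 0.0) & (t_um < L)
    vals = plane[in_band]
    bin_idx = np.minimum((t_um[in_band] / L * n_bins).astype(int), n_bins - 1)
    values = _bin_means(bin_idx, vals, n_bins)

    # unimaged end fractions -> undefined bins
    ua, up = geometry.unimaged_um()
    starts = np.arange(n_bins) * (L / n_bins)
    ends = starts + L / n_bins
    eps = 1e-9 * L
    values[starts < ua - eps] = np.nan
    values[ends > L - up + eps] = np.nan

    prov = {
        "op": "ap_line_profile",
        "width_px": width_px,
        "n_bins": n_bins,
        "embryo_length_um": L,
        "unimaged_um": [ua, up],
        "band_pixel_mean": float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else None,
    }
    ch = scene.channel_names[scene.channel_index(channel)] if scene.channel_names else None
    return BinnedProfile(
        values=values,
        axis_kind=PCT_EL,
        line_width_px=width_px,
        channel=ch,
        provenance=prov,
    )


def _embryo_contour(plane: np.ndarray, contour_mask: np.ndarray | None):
    """Closed embryo-boundary polyline ((N, 2) float (y, x)) and the
    filled embryo mask it bounds."""
    if contour_mask is not None:
        mask = np.asarray(contour_mask) != 0
    else:
        finite = np.nan_to_num(plane, nan=0.0)
        thr = filters.threshold_otsu(finite)
        mask = finite > thr
        mask = ndi.binary_fill_holes(mask)
        lbl, n = ndi.label(mask)
        if n == 0:
            raise ValueError("no embryo found by threshold; supply contour_mask")
        sizes = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no closed embryo contour found")
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if len(contour) < 8:
        raise ValueError("degenerate embryo contour")
    return contour, mask


def perimeter_profile(
    scene: ImageScene,
    geometry: EmbryoGeometry,
    channel: int | str | None = None,
    z_index: int | None = None,
    line_width_px: int = 5,
    n_bins: int = 100,
    exclude_mask: np.ndarray | None = None,
    contour_mask: np.ndarray | None = None,
) -> BinnedProfile:
    """Mean intensity in a band just inside the embryo boundary, binned by
    arc length into ``n_bins`` bins.

    The scan starts at the dorsal-most boundary point (minimum row) and
    proceeds toward the anterior pole first, then the posterior pole, back
    to the start — fixing the bin <-> arc-position map.  The band spans
    radial depths ``[1, 1 + line_width_px)`` px inside the contour, i.e.
    adjacent to but not overlapping the vitelline ring.  Pole cells (or
    any other region) can be dropped via ``exclude_mask``.

    Provenance records ``pole_bins``: the bin indices whose arc positions
    are closest to the anterior and posterior poles.
    """
    plane = _plane_with_exclusion(scene, channel, exclude_mask, z=z_index)
    contour, mask = _embryo_contour(plane, contour_mask)

    # order: start dorsal-most, anterior pole before posterior pole
    start = int(np.argmin(contour[:, 0]))
    contour = np.roll(contour, -start, axis=0)
    tree = cKDTree(contour)
    _, idx_ant = tree.query(np.asarray(geometry.anterior_pole_px, dtype=float))
    _, idx_post = tree.query(np.asarray(geometry.posterior_pole_px, dtype=float))
    if idx_ant > idx_post:
        n_pts = len(contour)
        contour = np.vstack([contour[:1], contour[:0:-1]])
        idx_ant = (n_pts - idx_ant) % n_pts
        idx_post = (n_pts - idx_post) % n_pts

    seg = np.vstack([contour, contour[:1]])
    step = np.hypot(*np.diff(seg, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(step)])[:-1]
    total = s[-1] + step[-1]

    dist_in = ndi.distance_transform_edt(mask)
    band = (dist_in >= 1.0) & (dist_in < 1.0 + line_width_px)
    if not band.any():
        raise ValueError("perimeter band is empty (embryo too small for width)")
    yy, xx = np.nonzero(band)
    tree2 = cKDTree(contour)
    _, nearest = tree2.query(np.column_stack([yy, xx]))
    bin_idx = np.minimum((s[nearest] / total * n_bins).astype(int), n_bins - 1)
    values = _bin_means(bin_idx, plane[yy, xx], n_bins)

    pole_bins = tuple(
        int(min(s[i] / total * n_bins, n_bins - 1)) for i in (idx_ant, idx_post)
    )
    ch = scene.channel_names[scene.channel_index(channel)] if scene.channel_names else None
    return BinnedProfile(
        values=values,
        axis_kind="arc_fraction",
        bin_width=100.0 / n_bins,
        line_width_px=line_width_px,
        channel=ch,
        provenance={
            "op": "perimeter_profile",
            "n_bins": n_bins,
            "line_width_px": line_width_px,
            "pole_bins": pole_bins,
        },
    )


def _nanmean_or_nan(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    return float(values[ok].mean()) if ok.any() else float("nan")


def _center_bin_indices(profile: BinnedProfile, lo: float, hi: float) -> np.ndarray:
    starts = profile.bin_starts()
    ends = starts + profile.bin_width
    return np.nonzero((starts >= lo - 1e-9) & (ends <= hi + 1e-9))[0]


def subtract_center_background(
    profile: BinnedProfile,
    center_range_pct: tuple[float, float] = (40.0, 60.0),
    split_ap: bool = False,
) -> BinnedProfile:
    """Subtract the mean intensity of the center (signaling-OFF) region.

    With ``split_ap`` the background is estimated separately for the
    anterior and posterior halves (center bins below / at-or-above 50 %EL)
    and subtracted from the corresponding half — for embryos mounted
    unevenly so the baseline tilts along the axis.
    """
    if profile.background_subtracted:
        raise ValueError("profile is already background-subtracted")
    lo, hi = center_range_pct
    if not 0.0 < lo < hi < 100.0:
        raise ValueError("center_range_pct must lie inside (0, 100)")
    idx = _center_bin_indices(profile, lo, hi)
    if idx.size == 0:
        raise ValueError("center range covers no whole bin")
    v = profile.values
    out = v.copy()
    prov = dict(profile.provenance)
    if split_ap:
        mid = 50.0
        idx_a = idx[profile.bin_starts()[idx] + profile.bin_width / 2 < mid]
        idx_p = idx[profile.bin_starts()[idx] + profile.bin_width / 2 >= mid]
        bg_a, bg_p = _nanmean_or_nan(v[idx_a]), _nanmean_or_nan(v[idx_p])
        if np.isnan(bg_a) or np.isnan(bg_p):
            raise ValueError("all center bins undefined in one half")
        half = profile.bin_centers() < mid
        out[half] = v[half] - bg_a
        out[~half] = v[~half] - bg_p
        prov["center_background_au"] = [float(bg_a), float(bg_p)]
    else:
        bg = _nanmean_or_nan(v[idx])
        if np.isnan(bg):
            raise ValueError("all center bins undefined")
        out = v - bg
        prov["center_background_au"] = float(bg)
    prov["center_range_pct"] = [lo, hi]
    return profile.with_values(out, background_subtracted=True, provenance=prov)


def center_box_background(
    scene: ImageScene,
    box: RoiBox,
    yolk_mask: np.ndarray | None = None,
    channel: int | str | None = None,
) -> float:
    """Mean biosensor intensity in a center box, skipping yolk granules."""
    plane = _plane_with_exclusion(scene, channel, yolk_mask)
    sl = box.slices(scene.pixel_size_um, plane.shape)
    patch = plane[sl]
    if np.all(np.isnan(patch)):
        raise ValueError("center box contains no valid (non-yolk) pixel")
    return float(np.nanmean(patch))


def normalize_background_series(values) -> dict:
    """Normalize per-nuclear-cycle background intensities to the NC11 value.

    ``values`` is a mapping stage -> intensity (a stage named/keyed
    ``"NC11"`` or ``11`` must be present) or a sequence whose first entry
    is the NC11 value.  Returns ratios with NC11 = 1.
    """
    if isinstance(values, Mapping):
        ref = None
        for key in ("NC11", 11, "11"):
            if key in values:
                ref = float(values[key])
                break
        if ref is None:
            raise ValueError("series must contain an NC11 entry")
        return {k: float(v) / ref for k, v in values.items()}
    seq = [float(v) for v in values]
    if not seq:
        raise ValueError("empty series")
    return {i: v / seq[0] for i, v in enumerate(seq)}


def box_pair_quant(
    scene: ImageScene,
    signal_box: RoiBox,
    background_box: RoiBox,
    rolling_ball_radius_px: int = 50,
    channel: int | str | None = None,
) -> float:
    """Background-subtracted polar signal for noisy small-field imaging.

    Rolling-ball background subtraction (ball radius in pixels) is applied
    to each z slice, slices are maximum-projected, and the mean of the
    background box is subtracted from the mean of the signal box.
    """
    if rolling_ball_radius_px <= 0:
        raise ValueError("rolling-ball radius must be positive")
    if "Z" in scene.axes:
        z_n = scene.pixels.shape[scene.axis_index("Z")]
        slices = [scene.plane(channel=channel, z=i) for i in range(z_n)]
    else:
        slices = [scene.plane(channel=channel)]
    subtracted = []
    for img in slices:
        bg = rolling_ball(np.nan_to_num(img, nan=0.0), radius=rolling_ball_radius_px)
        sub = img - bg
        subtracted.append(sub)
    proj = np.nanmax(np.stack(subtracted), axis=0)

    sl_s = signal_box.slices(scene.pixel_size_um, proj.shape)
    sl_b = background_box.slices(scene.pixel_size_um, proj.shape)
    if (
        max(sl_s[0].start, sl_b[0].start) < min(sl_s[0].stop, sl_b[0].stop)
        and max(sl_s[1].start, sl_b[1].start) < min(sl_s[1].stop, sl_b[1].stop)
    ):
        warnings.warn("signal and background boxes overlap", stacklevel=2)
    return float(np.nanmean(proj[sl_s]) - np.nanmean(proj[sl_b]))
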