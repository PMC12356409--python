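"""Image containers, geometry annotations and TIFF/JSON round-trip I/O.

Coordinate contract used across the package:

* pixel indices are 0-based ``(row, column) = (y, x)``;
* anterior–posterior (AP) positions are expressed as % egg length (%EL)
  in ``[0, 100]`` with 0 at the anterior pole and 100 at the posterior pole;
* bin ``i`` of an ``N``-bin profile covers the half-open interval
  ``[i*100/N, (i+1)*100/N)`` %EL;
* distances "from a pole" are measured toward the embryo center, in %EL
  or in micrometres.

Invalid pixels (e.g. the autofluorescent vitelline membrane after
:func:`mask_exclude`) are carried as NaN and are excluded from every
downstream mean; a region with no valid pixel yields NaN, never 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageScene",
    "EmbryoGeometry",
    "read_scene",
    "write_scene",
    "read_labels",
    "write_labels",
    "max_project",
    "mask_exclude",
]


@dataclass
class ImageScene:
    """A multi-dimensional microscopy image with physical scale metadata.

    Parameters
    ----------
    pixels
        Intensity array. Invalid pixels are NaN.
    axes
        Axis-order string, a subset of ``"TZCYX"`` ending in ``"YX"``,
        one character per array dimension (e.g. ``"CYX"``).
    pixel_size_um
        Lateral pixel size in micrometres; must be positive.
    channel_names
        One name per entry along the ``C`` axis (or a single name for a
        scene without a ``C`` axis).
    frame_times_s
        Optional acquisition time of each ``T`` frame, seconds.
    """

    pixels: np.ndarray
    axes: str
    pixel_size_um: float
    channel_names: tuple[str, ...] = ("ch0",)
    frame_times_s: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel_names = tuple(self.channel_names)
        if self.frame_times_s is not None:
            self.frame_times_s = tuple(float(t) for t in self.frame_times_s)
        if self.pixel_size_um is None or not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive (no silent default)")
        if len(self.axes) != self.pixels.ndim:
            raise ValueError(
                f"axes {self.axes!r} does not match array of ndim {self.pixels.ndim}"
            )
        if not self.axes.endswith("YX"):
            raise ValueError("axes must end in 'YX'")
        if any(a not in "TZCYX" for a in self.axes):
            raise ValueError(f"unknown axis letter in {self.axes!r}")
        if "C" in self.axes:
            n_c = self.pixels.shape[self.axes.index("C")]
            if len(self.channel_names) != n_c:
                raise ValueError(
                    f"{n_c} channels but {len(self.channel_names)} channel names"
                )
        if "T" in self.axes and self.frame_times_s is not None:
            n_t = self.pixels.shape[self.axes.index("T")]
            if len(self.frame_times_s) != n_t:
                raise ValueError("frame_times_s length does not match T axis")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def axis_index(self, axis: str) -> int:
        if axis not in self.axes:
            raise ValueError(f"scene has no {axis!r} axis (axes={self.axes!r})")
        return self.axes.index(axis)

    def channel_index(self, channel: int | str | None) -> int:
        if channel is None:
            return 0
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        return int(channel)

    def plane(
        self,
        channel: int | str | None = None,
        z: int | None = None,
        t: int | None = None,
    ) -> np.ndarray:
        """Return a single 2D ``(Y, X)`` plane as float64 (NaN = invalid)."""
        arr = self.pixels
        axes = self.axes
        for letter, sel in (("T", t), ("Z", z), ("C", None)):
            if letter in axes:
                if letter == "C":
                    idx = self.channel_index(channel)
                else:
                    idx = 0 if sel is None else int(sel)
                arr = np.take(arr, idx, axis=axes.index(letter))
                axes = axes.replace(letter, "")
        if axes != "YX":
            raise ValueError(f"could not reduce scene to a YX plane (left {axes!r})")
        return np.asarray(arr, dtype=float)

    def with_pixels(self, pixels: np.ndarray) -> "ImageScene":
        return replace(self, pixels=pixels)


@dataclass
class EmbryoGeometry:
    """Pole coordinates and physical length of one embryo.

    ``anterior_pole_px`` / ``posterior_pole_px`` are ``(y, x)`` pixel
    coordinates of the embryo tips; anterior is whichever pole is listed
    first (orientation is the mounting convention, never inferred from
    image content).  ``imaged_fraction`` gives, per end, the fraction of
    that half of the AP axis actually captured; the unimaged length at an
    end is ``(1 - fraction) * embryo_length_um / 2`` and the profile bins
    it covers are reported as undefined.
    """

    anterior_pole_px: tuple[float, float]
    posterior_pole_px: tuple[float, float]
    embryo_length_um: float
    imaged_fraction: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.anterior_pole_px = (float(self.anterior_pole_px[0]), float(self.anterior_pole_px[1]))
        self.posterior_pole_px = (float(self.posterior_pole_px[0]), float(self.posterior_pole_px[1]))
        if isinstance(self.imaged_fraction, (int, float)):
            self.imaged_fraction = (float(self.imaged_fraction),) * 2
        self.imaged_fraction = tuple(float(f) for f in self.imaged_fraction)
        if self.anterior_pole_px == self.posterior_pole_px:
            raise ValueError("anterior and posterior poles coincide")
        if not self.embryo_length_um > 0:
            raise ValueError("embryo_length_um must be positive")
        if any(not 0.0 <= f <= 1.0 for f in self.imaged_fraction):
            raise ValueError("imaged_fraction entries must lie in [0, 1]")

    def pole_separation_px(self) -> float:
        (ya, xa), (yp, xp) = self.anterior_pole_px, self.posterior_pole_px
        return math.hypot(yp - ya, xp - xa)

    def validate_against(self, pixel_size_um: float) -> None:
        if self.embryo_length_um + 1e-6 < self.pole_separation_px() * pixel_size_um:
            raise ValueError(
                "embryo_length_um is shorter than the pixel distance between poles"
            )
        if self.pole_separation_px() * pixel_size_um < 2 * pixel_size_um:
            raise ValueError("non-physical geometry: pole separation < 2 pixels")

    def unimaged_um(self) -> tuple[float, float]:
        """Unimaged axis length at the (anterior, posterior) end, in um."""
        half = self.embryo_length_um / 2.0
        fa, fp = self.imaged_fraction
        return ((1.0 - fa) * half, (1.0 - fp) * half)

    def to_dict(self) -> dict:
        return {
            "anterior_pole_px": list(self.anterior_pole_px),
            "posterior_pole_px": list(self.posterior_pole_px),
            "embryo_length_um": self.embryo_length_um,
            "imaged_fraction": list(self.imaged_fraction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoGeometry":
        return cls(
            anterior_pole_px=tuple(d["anterior_pole_px"]),
            posterior_pole_px=tuple(d["posterior_pole_px"]),
            embryo_length_um=float(d["embryo_length_um"]),
            imaged_fraction=tuple(d.get("imaged_fraction", (1.0, 1.0))),
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_scene(scene: ImageScene, path: str | Path) -> None:
    """Write a scene as a TIFF plus a JSON sidecar with the metadata.

    Pixel data round-trips losslessly (float32 for float input, native
    dtype otherwise); NaNs survive the round trip.
    """
    path = Path(path)
    arr = scene.pixels
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {
        "axes": scene.axes,
        "pixel_size_um": scene.pixel_size_um,
        "channel_names": list(scene.channel_names),
        "frame_times_s": list(scene.frame_times_s) if scene.frame_times_s else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_scene(
    path: str | Path,
    pixel_size_um: float | None = None,
    axes: str | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> ImageScene:
    """Read a TIFF written by :func:`write_scene` (or any plain TIFF with
    caller-supplied metadata).

    A missing pixel size is a hard error: physical units are required for
    every downstream quantification and are never silently defaulted.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: no pixel size in sidecar and none supplied")
    ax = axes or meta.get("axes")
    if ax is None:
        ax = "YX" if pixels.ndim == 2 else None
    if ax is None or len(ax) != pixels.ndim:
        raise ValueError(f"{path}: axis metadata missing or inconsistent with data")
    names = channel_names or meta.get("channel_names")
    if names is None:
        names = ("ch0",) if "C" not in ax else tuple(
            f"ch{i}" for i in range(pixels.shape[ax.index("C")])
        )
    times = meta.get("frame_times_s")
    return ImageScene(
        pixels=pixels,
        axes=ax,
        pixel_size_um=float(px),
        channel_names=tuple(names),
        frame_times_s=tuple(times) if times else None,
    )


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a label image as 16-bit TIFF (labels must fit in uint16)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed uint16 range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def max_project(scene: ImageScene, axis: str = "Z") -> ImageScene:
    """Maximum-intensity projection along a named axis.

    NaN pixels are ignored unless every pixel along the axis is NaN, in
    which case the projected pixel stays NaN.
    """
    idx = scene.axis_index(axis)
    pix = np.asarray(scene.pixels, dtype=float)
    with np.errstate(all="ignore"):
        proj = np.nanmax(pix, axis=idx)
    times = scene.frame_times_s if axis != "T" else None
    return ImageScene(
        pixels=proj,
        axes=scene.axes.replace(axis, ""),
        pixel_size_um=scene.pixel_size_um,
        channel_names=scene.channel_names,
        frame_times_s=times,
    )


def mask_exclude(scene: ImageScene, mask: np.ndarray) -> ImageScene:
    """Mark the pixels under ``mask`` invalid (NaN) in every channel.

    ``mask`` is a boolean (or label) image on the scene's YX grid; True /
    nonzero pixels are excluded from all downstream means.  Used for the
    autofluorescent vitelline membrane, bright yolk, and pole cells.
    """
    mask = np.asarray(mask) != 0
    yx_shape = scene.pixels.shape[-2:]
    if mask.shape != yx_shape:
        raise ValueError(f"mask shape {mask.shape} != scene YX shape {yx_shape}")
    pix = np.asarray(scene.pixels, dtype=float).copy()
    pix[..., mask] = np.nan
    return scene.with_pixels(pix)
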