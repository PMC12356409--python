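"""FRAP trace normalization and recovery-fraction extraction.

Raw traces are means over a membrane region inside the bleached spot and a
matching region outside it.  Normalization follows the standard scheme:

    R(t) = (F_in(t) - bg) / (F_in,pre - bg)                    (simple)
    R(t) = R_simple(t) / [(F_out(t) - bg) / (F_out,pre - bg)]  (double)

so R = 1 before the bleach by construction; the double mode additionally
corrects acquisition-induced loss using the unbleached region.  Because
"percent recovery" is ambiguous when the bleach is partial, the recovery
fraction is reported relative to the bleach-induced deficit,

    rho(t) = (R(t) - R(t0+)) / (1 - R(t0+)),

with t0+ the first post-bleach frame; rho is invariant to affine gain /
offset rescaling of the raw intensities given a consistent background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import RoiBox
from .sceneio import ImageScene

__all__ = ["FRAPTrace", "RecoveryCurve", "extract_frap_trace", "normalize_frap", "recovery_at"]


@dataclass
class FRAPTrace:
    """Raw intensity trace of one FRAP experiment.

    Frame 0 (``times_s[0]``) is the prebleach acquisition; the bleach
    happens between frames 0 and 1.
    """

    times_s: np.ndarray
    in_bleach_mean_au: np.ndarray
    out_bleach_mean_au: np.ndarray | None
    background_au: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.in_bleach_mean_au = np.asarray(self.in_bleach_mean_au, dtype=float)
        if self.out_bleach_mean_au is not None:
            self.out_bleach_mean_au = np.asarray(self.out_bleach_mean_au, dtype=float)
            if self.out_bleach_mean_au.shape != self.in_bleach_mean_au.shape:
                raise ValueError("inside/outside traces differ in length")
        if self.times_s.ndim != 1 or self.times_s.size < 2:
            raise ValueError("need at least a prebleach and one post-bleach frame")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times_s.size != self.in_bleach_mean_au.size:
            raise ValueError("times and trace lengths differ")
        if not self.prebleach_in_au > self.background_au:
            raise ValueError("prebleach intensity must exceed the background")

    @property
    def prebleach_in_au(self) -> float:
        return float(self.in_bleach_mean_au[0])

    @property
    def prebleach_out_au(self) -> float | None:
        if self.out_bleach_mean_au is None:
            return None
        return float(self.out_bleach_mean_au[0])


def extract_frap_trace(
    scene: ImageScene,
    in_box: RoiBox,
    out_box: RoiBox | None,
    background_au: float,
    channel=None,
) -> FRAPTrace:
    """Mean in-bleach / out-of-bleach intensities per frame of a T-series."""
    if "T" not in scene.axes:
        raise ValueError("scene has no time axis")
    n_t = scene.pixels.shape[scene.axis_index("T")]
    if scene.frame_times_s is None:
        raise ValueError("scene lacks frame times")
    ins, outs = [], []
    for t in range(n_t):
        plane = scene.plane(channel=channel, t=t)
        ins.append(float(np.nanmean(plane[in_box.slices(scene.pixel_size_um, plane.shape)])))
        if out_box is not None:
            outs.append(float(np.nanmean(plane[out_box.slices(scene.pixel_size_um, plane.shape)])))
    return FRAPTrace(
        times_s=np.asarray(scene.frame_times_s),
        in_bleach_mean_au=np.asarray(ins),
        out_bleach_mean_au=np.asarray(outs) if out_box is not None else None,
        background_au=background_au,
    )


@dataclass
class RecoveryCurve:
    """Normalized FRAP recovery R(t); R(times_s[0]) = 1 by construction."""

    times_s: np.ndarray
    values: np.ndarray
    mode: str = "simple"

    def at(self, t_s: float) -> float:
        """Linear interpolation of R between adjacent frames."""
        t = float(t_s)
        if t < self.times_s[0] or t > self.times_s[-1]:
            raise ValueError("t outside the series span")
        return float(np.interp(t, self.times_s, self.values))


def normalize_frap(trace: FRAPTrace, mode: str = "simple") -> RecoveryCurve:
    """Normalize a raw trace to a recovery curve (see module docstring)."""
    if mode not in ("simple", "double"):
        raise ValueError("mode must be 'simple' or 'double'")
    bg = trace.background_au
    denom = trace.prebleach_in_au - bg
    r = (trace.in_bleach_mean_au - bg) / denom
    if mode == "double":
        if trace.out_bleach_mean_au is None:
            raise ValueError("double normalization requires an outside-region trace")
        out_denom = trace.prebleach_out_au - bg
        if out_denom <= 0:
            raise ValueError("outside-region prebleach must exceed the background")
        correction = (trace.out_bleach_mean_au - bg) / out_denom
        if np.any(correction <= 0):
            raise ValueError("outside-region trace fell to or below the background")
        r = r / correction
    return RecoveryCurve(times_s=trace.times_s.copy(), values=r, mode=mode)


def recovery_at(curve: RecoveryCurve, t_s: float) -> float:
    """Deficit-relative recovery fraction rho(t).

    rho = (R(t) - R0) / (1 - R0) with R0 the first post-bleach value; 0
    means no recovery of the bleached deficit, 1 full recovery.
    """
    t0_post = curve.times_s[1]
    if t_s < t0_post:
        raise ValueError("t precedes the first post-bleach frame")
    r0 = float(curve.values[1])
    deficit = 1.0 - r0
    if deficit <= 0:
        raise ValueError("no bleach-induced deficit (R0 >= 1); rho undefined")
    return (curve.at(t_s) - r0) / deficit
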