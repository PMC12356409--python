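"""Seeded synthetic microscopy scenes with known ground truth.

The generator emulates the imaging regimes quantified by the rest of the
package on the early *Drosophila* embryo: a ~500 um elliptical syncytial
embryo with a cortical membrane lattice carrying polar membrane-recruitment
gradients (receptor biosensor), a broader downstream ERK-like gradient, a
nuclear KTR (miniCic-like) channel, transcription-burst spots near the
posterior pole, autofluorescent vitelline ring and yolk granules, plus a
membrane FRAP simulator and small follicle/tracheal-branch vignettes.

Gradient shape
--------------
Membrane recruitment at distance ``d`` (um) from a pole is

    g(d) = peak_level                                   for d <= plateau_um
    g(d) = peak_level * exp(-(d - plateau_um)/decay_len_um)   otherwise

which makes the half-maximum boundary analytic:
``half_max_um = plateau_um + decay_len_um * ln 2``.  The true profiles are
stored in the returned :class:`SceneTruth` so every downstream operator can
be validated against a known answer.

All randomness (nuclear jitter, yolk placement, noise) derives from the
config seed; identical configs render bit-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .sceneio import EmbryoGeometry, ImageScene

__all__ = [
    "GradientParams",
    "SceneConfig",
    "SceneTruth",
    "FrapTruth",
    "render_embryo",
    "render_frap_series",
    "render_branch",
    "render_follicle",
    "NC_STAGES",
]

NC_STAGES = ("NC10", "NC11", "NC12", "NC13", "NC14")

# Stage defaults: cytosolic biosensor background rises monotonically over
# the nuclear cycles while the receptor-level gradient narrows and loses
# amplitude; the downstream (ERK-like) gradient keeps its reach and gains
# amplitude.  Magnitudes are free parameters of the generator.
_STAGE_BACKGROUND_AU = {"NC10": 55.0, "NC11": 60.0, "NC12": 75.0, "NC13": 95.0, "NC14": 130.0}
_STAGE_TORSO = {  # (plateau_um, decay_len_um, peak_level)
    "NC10": (30.0, 30.0, 200.0),
    "NC11": (30.0, 30.0, 200.0),
    "NC12": (25.0, 25.0, 150.0),
    "NC13": (20.0, 20.0, 60.0),
    "NC14": (15.0, 15.0, 20.0),
}
_STAGE_ERK = {
    "NC10": (30.0, 92.0, 50.0),
    "NC11": (30.0, 92.0, 50.0),
    "NC12": (25.0, 92.0, 65.0),
    "NC13": (20.0, 92.0, 80.0),
    "NC14": (15.0, 92.0, 100.0),
}
_STAGE_NUCLEI = {  # (spacing_um, radius_um); density doubles each cycle
    "NC10": (30.0, 7.0),
    "NC11": (22.0, 6.0),
    "NC12": (16.0, 5.0),
    "NC13": (12.0, 4.0),
    "NC14": (9.0, 3.0),
}


@dataclass(frozen=True)
class GradientParams:
    """Plateau + exponential-decay polar gradient (one pole).

    ``plateau_um``: length from the pole at full activity; ``decay_len_um``:
    exponential decay length; ``peak_level``: membrane signal above the
    cytosolic background at the pole, arbitrary units.
    """

    plateau_um: float
    decay_len_um: float
    peak_level: float

    def __post_init__(self) -> None:
        if self.plateau_um < 0:
            raise ValueError("plateau_um must be >= 0")
        if not self.decay_len_um > 0:
            raise ValueError("decay_len_um must be > 0")
        if self.peak_level < 0:
            raise ValueError("peak_level must be >= 0")

    def __call__(self, d_um):
        """Gradient value at distance ``d_um`` (um) from the pole."""
        d = np.asarray(d_um, dtype=float)
        out = np.where(
            d <= self.plateau_um,
            self.peak_level,
            self.peak_level * np.exp(-(np.maximum(d, self.plateau_um) - self.plateau_um) / self.decay_len_um),
        )
        out = np.where(d < 0, 0.0, out)
        return out if out.ndim else float(out)

    @property
    def half_max_um(self) -> float:
        """Analytic half-maximum boundary: plateau + decay_len * ln 2."""
        return self.plateau_um + self.decay_len_um * math.log(2.0)


PolePair = tuple[GradientParams, GradientParams]


def _as_pair(g) -> PolePair:
    if isinstance(g, GradientParams):
        return (g, g)
    a, p = g
    return (a, p)


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic embryo scene."""

    embryo_length_um: float = 500.0
    embryo_width_um: float = 180.0
    pixel_size_um: float = 1.0
    nc_stage: str = "NC13"
    torso: GradientParams | PolePair | None = None
    erk: GradientParams | PolePair | None = None
    blur_mode: bool = False
    blur_len_um: float = 45.0
    cytosol_background: float | None = None
    dperk_background: float = 20.0
    vitelline_level: float = 400.0
    yolk_count: int = 0
    yolk_radius_um: tuple[float, float] = (2.0, 5.0)
    yolk_level: float = 250.0
    poisson_gain: float = 0.0  # photons per AU; 0 disables shot noise
    read_sigma: float = 0.0  # additive Gaussian read noise, AU; 0 disables
    seed: int = 0
    view: str = "surface"  # "surface" (max-projection-like) or "sagittal"
    psf_sigma_um: float = 0.5
    membrane_spacing_um: float = 8.0
    membrane_angle_deg: float = 15.0
    imaged_fraction: float | tuple[float, float] = 0.98
    margin_um: float = 20.0
    burst_positions_um: tuple[float, ...] | None = None
    burst_level: float = 300.0
    burst_sigma_um: float = 1.0

    def __post_init__(self) -> None:
        if self.nc_stage not in NC_STAGES:
            raise ValueError(f"nc_stage must be one of {NC_STAGES}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.embryo_length_um > self.embryo_width_um > 0:
            raise ValueError("require embryo_length_um > embryo_width_um > 0")
        if self.view not in ("surface", "sagittal"):
            raise ValueError("view must be 'surface' or 'sagittal'")
        if self.embryo_length_um < 2 * self.pixel_size_um:
            raise ValueError("non-physical geometry: pole separation < 2 pixels")
        if self.torso is None:
            self.torso = GradientParams(*_STAGE_TORSO[self.nc_stage])
        if self.erk is None and not self.blur_mode:
            self.erk = GradientParams(*_STAGE_ERK[self.nc_stage])
        if self.cytosol_background is None:
            self.cytosol_background = _STAGE_BACKGROUND_AU[self.nc_stage]
        for name in ("cytosol_background", "dperk_background", "vitelline_level", "yolk_level", "burst_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.burst_positions_um is not None:
            bp = tuple(float(b) for b in self.burst_positions_um)
            if any(b < 0 or b > self.embryo_length_um for b in bp):
                raise ValueError("burst positions must lie in [0, embryo_length_um]")
            self.burst_positions_um = bp

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        """Build a config from plain JSON data; gradient entries are
        ``{"plateau_um":..., "decay_len_um":..., "peak_level":...}`` or a
        two-item [anterior, posterior] list of such objects."""

        def _grad(entry):
            if entry is None:
                return None
            if isinstance(entry, (list, tuple)):
                return tuple(GradientParams(**e) for e in entry)
            return GradientParams(**entry)

        d = dict(d)
        for key in ("torso", "erk"):
            if key in d:
                d[key] = _grad(d[key])
        for key in ("yolk_radius_um", "imaged_fraction", "burst_positions_um"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        def _grad(g):
            if g is None:
                return None
            if isinstance(g, GradientParams):
                return {
                    "plateau_um": g.plateau_um,
                    "decay_len_um": g.decay_len_um,
                    "peak_level": g.peak_level,
                }
            return [_grad(x) for x in g]

        out = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if f in ("torso", "erk"):
                v = _grad(v)
            elif isinstance(v, tuple):
                v = list(v)
            out[f] = v
        return out

    @property
    def torso_pair(self) -> PolePair:
        return _as_pair(self.torso)

    @property
    def erk_pair(self) -> PolePair | None:
        return None if self.erk is None else _as_pair(self.erk)


class AxisProfile:
    """True intensity profile along the AP axis, queryable either by
    absolute axis position or by distance from a pole."""

    def __init__(self, length_um: float, x_um: np.ndarray, values: np.ndarray):
        self.length_um = float(length_um)
        self._x = np.asarray(x_um, dtype=float)
        self._v = np.asarray(values, dtype=float)

    def at_axis(self, x_um):
        return np.interp(np.asarray(x_um, dtype=float), self._x, self._v)

    def __call__(self, d_um, pole: str = "posterior"):
        """Value at distance ``d_um`` (um) from the given pole."""
        d = np.asarray(d_um, dtype=float)
        x = self.length_um - d if pole == "posterior" else d
        out = self.at_axis(x)
        return float(out) if np.ndim(d_um) == 0 else out

    def integral_au_um(self) -> float:
        return float(np.trapezoid(self._v, self._x))


@dataclass
class SceneTruth:
    """Generator ground truth accompanying a rendered scene."""

    geometry: EmbryoGeometry
    true_torso_profile: AxisProfile
    true_erk_profile: AxisProfile
    embryo_mask: np.ndarray
    membrane_mask: np.ndarray
    nuclear_mask: np.ndarray
    yolk_mask: np.ndarray
    vitelline_mask: np.ndarray
    burst_positions_um: tuple[float, ...]
    parameters: SceneConfig

    def exclusion_mask(self, include_yolk: bool = True) -> np.ndarray:
        """Everything the quantification should ignore: outside-embryo
        pixels, the vitelline ring and (optionally) yolk granules."""
        mask = ~self.embryo_mask | self.vitelline_mask
        if include_yolk:
            mask = mask | self.yolk_mask
        return mask


def _pair_axis_profile(length_um: float, pair: PolePair, n: int = 4001) -> AxisProfile:
    x = np.linspace(0.0, length_um, n)
    ant, post = pair
    v = ant(x) + post(length_um - x)
    return AxisProfile(length_um, x, v)


def _blurred_axis_profile(torso: AxisProfile, blur_len_um: float) -> AxisProfile:
    """Downstream profile as the receptor profile convolved with a
    normalized Gaussian of width ``blur_len_um`` (reflecting ends, so the
    spatial integral is conserved exactly)."""
    x = torso._x
    dx = x[1] - x[0]
    v = ndi.gaussian_filter1d(torso._v, sigma=blur_len_um / dx, mode="reflect")
    return AxisProfile(torso.length_um, x, v)


def _hex_lattice_mask(inside: np.ndarray, spacing_px: float, angle_deg: float) -> np.ndarray:
    """Cortical membrane lattice: edges of the Voronoi diagram of a
    hexagonal point grid (edge width ~1 px)."""
    h, w = inside.shape
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    # hexagonal grid in rotated frame, covering the full image
    dy = spacing_px * math.sqrt(3) / 2
    pts = []
    n_i = int(2 * max(h, w) / dy) + 4
    n_j = int(2 * max(h, w) / spacing_px) + 4
    for i in range(-n_i // 2, n_i):
        off = 0.5 * spacing_px * (i % 2)
        for j in range(-n_j // 2, n_j):
            u, v = j * spacing_px + off, i * dy
            pts.append((u * s + v * c, u * c - v * s))  # (y, x)
    tree = cKDTree(np.asarray(pts))
    yy, xx = np.nonzero(inside)
    d, _ = tree.query(np.column_stack([yy, xx]), k=2)
    edge = (d[:, 1] - d[:, 0]) < 1.0
    mask = np.zeros_like(inside, dtype=bool)
    mask[yy[edge], xx[edge]] = True
    return mask


def _nuclei(
    inside: np.ndarray, rng: np.random.Generator, spacing_px: float, radius_px: float
) -> np.ndarray:
    """Jittered hexagonal field of nuclear disks; 16-bit label image."""
    h, w = inside.shape
    labels = np.zeros((h, w), dtype=np.uint16)
    interior = ndi.binary_erosion(inside, iterations=max(1, int(radius_px + 2)))
    dy = spacing_px * math.sqrt(3) / 2
    yy, xx = np.mgrid[0:h, 0:w]
    lab = 0
    for i in range(int(h / dy) + 2):
        off = 0.5 * spacing_px * (i % 2)
        for j in range(int(w / spacing_px) + 2):
            cy = i * dy + rng.uniform(-1, 1)
            cx = j * spacing_px + off + rng.uniform(-1, 1)
            iy, ix = int(round(cy)), int(round(cx))
            if not (0 <= iy < h and 0 <= ix < w) or not interior[iy, ix]:
                continue
            lab += 1
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
            labels[disk & (labels == 0)] = lab
    return labels


def _apply_noise(img: np.ndarray, rng: np.random.Generator, gain: float, read_sigma: float) -> np.ndarray:
    out = img
    if gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * gain).astype(float) / gain
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, size=out.shape)
    return out


def render_embryo(config: SceneConfig) -> tuple[ImageScene, SceneTruth]:
    """Render one synthetic embryo scene plus its ground truth.

    Channels: ``ztsh2`` (membrane-recruitment biosensor over a cytosolic
    background, with vitelline ring and yolk autofluorescence), ``minicic``
    (kinase translocation reporter: nuclear where ERK is off, cytoplasmic
    where on), ``dperk`` (downstream activity as a cytoplasmic stain) and
    ``nuclear`` (nuclear marker).  A ``ms2`` channel with point-like burst
    spots is appended when ``burst_positions_um`` is set.

    The ``surface`` view stands in for a maximum z-projection of the
    cortex (membrane lattice + nuclei); the ``sagittal`` view shows the
    mid-plane with the cortical membrane as a perimeter band.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    px = cfg.pixel_size_um
    L, W, m = cfg.embryo_length_um, cfg.embryo_width_um, cfg.margin_um
    h = int(round((W + 2 * m) / px))
    w = int(round((L + 2 * m) / px))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = L / 2.0 / px, W / 2.0 / px

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    inside = r2 <= 1.0

    ant = (cy, cx - a)
    post = (cy, cx + a)
    geometry = EmbryoGeometry(
        anterior_pole_px=ant,
        posterior_pole_px=post,
        embryo_length_um=L,
        imaged_fraction=cfg.imaged_fraction,
    )

    # distance from each pole measured along the AP axis
    t_um = (xx - ant[1]) * px  # axis position, 0 at anterior
    torso_pair = cfg.torso_pair
    torso_axis = _pair_axis_profile(L, torso_pair)
    if cfg.blur_mode:
        erk_axis = _blurred_axis_profile(torso_axis, cfg.blur_len_um)
    else:
        erk_axis = _pair_axis_profile(L, cfg.erk_pair)
    g_torso = torso_pair[0](np.clip(t_um, 0, None)) + torso_pair[1](np.clip(L - t_um, 0, None))
    g_erk = erk_axis.at_axis(np.clip(t_um, 0, L))

    # masks -------------------------------------------------------------
    dist_in = ndi.distance_transform_edt(inside)
    dist_out = ndi.distance_transform_edt(~inside)
    vitelline = (dist_out >= 1.0) & (dist_out <= 3.0)

    yolk = np.zeros((h, w), dtype=bool)
    for _ in range(cfg.yolk_count):
        rad = rng.uniform(*cfg.yolk_radius_um) / px
        gy = rng.uniform(cy - 0.5 * b, cy + 0.5 * b)
        gx = rng.uniform(cx - 0.5 * a, cx + 0.5 * a)
        yolk |= (yy - gy) ** 2 + (xx - gx) ** 2 <= rad**2
    yolk &= inside

    if cfg.view == "surface":
        membrane = _hex_lattice_mask(inside, cfg.membrane_spacing_um / px, cfg.membrane_angle_deg)
        membrane &= dist_in > 1.0
        spacing_um, radius_um = _STAGE_NUCLEI[cfg.nc_stage]
        nuclei = _nuclei(inside, rng, spacing_um / px, radius_um / px)
    else:
        membrane = (dist_in >= 1.0) & (dist_in < 4.0)
        nuclei = np.zeros((h, w), dtype=np.uint16)

    # channels ----------------------------------------------------------
    psf_px = cfg.psf_sigma_um / px
    blur2d = (lambda im: ndi.gaussian_filter(im, psf_px)) if psf_px > 0 else (lambda im: im)

    ztsh2 = cfg.cytosol_background * inside + blur2d(np.where(membrane, g_torso, 0.0))
    ztsh2 = ztsh2 + cfg.yolk_level * yolk + cfg.vitelline_level * vitelline

    dperk = (cfg.dperk_background + g_erk) * inside

    erk_peak = max(float(erk_axis.at_axis(0.0)), float(erk_axis.at_axis(L)), 1e-12)
    activity = np.clip(g_erk / erk_peak, 0.0, 1.0)
    nuc = nuclei > 0
    minicic = np.where(nuc, 100.0 - 60.0 * activity, 40.0 + 60.0 * activity) * inside

    nuclear = 150.0 * nuc + 10.0 * (inside & ~nuc)

    channels = [ztsh2, minicic, dperk, nuclear]
    names = ["ztsh2", "minicic", "dperk", "nuclear"]
    bursts = cfg.burst_positions_um or ()
    if cfg.burst_positions_um is not None:
        ms2 = 5.0 * inside
        sig = max(cfg.burst_sigma_um / px, 0.5)
        for d in bursts:
            bx, by = post[1] - d / px, cy
            ms2 = ms2 + cfg.burst_level * np.exp(
                -(((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sig**2))
            )
        channels.append(ms2)
        names.append("ms2")

    stack = np.stack([_apply_noise(c, rng, cfg.poisson_gain, cfg.read_sigma) for c in channels])
    scene = ImageScene(
        pixels=stack.astype(np.float64),
        axes="CYX",
        pixel_size_um=px,
        channel_names=tuple(names),
    )
    truth = SceneTruth(
        geometry=geometry,
        true_torso_profile=torso_axis,
        true_erk_profile=erk_axis,
        embryo_mask=inside,
        membrane_mask=membrane,
        nuclear_mask=nuclei,
        yolk_mask=yolk,
        vitelline_mask=vitelline,
        burst_positions_um=tuple(bursts),
        parameters=cfg,
    )
    return scene, truth


# ---------------------------------------------------------------------------
# FRAP simulation


@dataclass
class FrapTruth:
    """Ground truth for a simulated FRAP series."""

    bleach_mask: np.ndarray
    frame_times_s: tuple[float, ...]
    totals_au: tuple[float, ...]  # summed intensity per frame (offset removed)
    init_level: float
    offset_au: float
    well_mixed_level: float  # post-bleach total / area: the D->inf plateau
    parameters: dict


def render_frap_series(
    d_coeff_um2_s: float,
    bleach_radius_um: float,
    bleach_depth: float,
    duration_s: float,
    interval_s: float,
    seed: int = 0,
    domain_um: float = 50.0,
    pixel_size_um: float = 1.0,
    init_level: float = 100.0,
    offset_au: float = 10.0,
    read_sigma: float = 0.0,
) -> tuple[ImageScene, FrapTruth]:
    """Simulate photobleaching and diffusive recovery on a closed 2D
    cortical membrane patch.

    Frame 0 (t = 0) is the prebleach image; the bleach (a disk at the
    patch center losing fraction ``bleach_depth``) happens immediately
    after it, and frames follow at ``interval_s`` spacing.  Diffusion uses
    an explicit flux-form finite-difference scheme with reflecting
    boundaries, so total fluorescence after the bleach is conserved to
    machine precision; the time step respects dt <= h^2/(4D).
    """
    if not bleach_radius_um > 0:
        raise ValueError("bleach_radius_um must be > 0")
    if not duration_s > 0 or not interval_s > 0:
        raise ValueError("duration_s and interval_s must be > 0")
    if d_coeff_um2_s < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if not 0.0 <= bleach_depth <= 1.0:
        raise ValueError("bleach_depth must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    hpx = pixel_size_um
    n = max(int(round(domain_um / hpx)), 4)
    u = np.full((n, n), float(init_level))
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= (bleach_radius_um / hpx) ** 2

    n_frames = int(math.floor(duration_s / interval_s)) + 1
    times = tuple(i * interval_s for i in range(n_frames))
    frames = [u.copy()]
    u = u * np.where(disk, 1.0 - bleach_depth, 1.0)
    totals = [float(frames[0].sum())]

    if d_coeff_um2_s > 0:
        dt_max = 0.9 * hpx**2 / (4.0 * d_coeff_um2_s)
        steps = max(1, int(math.ceil(interval_s / dt_max)))
    else:
        steps = 1
    dt = interval_s / steps
    coef = d_coeff_um2_s * dt / hpx**2

    for _ in range(1, n_frames):
        for _ in range(steps):
            if coef > 0:
                div = np.zeros_like(u)
                fx = u[:, 1:] - u[:, :-1]
                div[:, :-1] += fx
                div[:, 1:] -= fx
                fy = u[1:, :] - u[:-1, :]
                div[:-1, :] += fy
                div[1:, :] -= fy
                u = u + coef * div
        frames.append(u.copy())
        totals.append(float(u.sum()))

    stack = np.stack(frames) + offset_au
    if read_sigma > 0:
        stack = stack + rng.normal(0.0, read_sigma, size=stack.shape)
    scene = ImageScene(
        pixels=stack,
        axes="TYX",
        pixel_size_um=hpx,
        channel_names=("membrane",),
        frame_times_s=times,
    )
    truth = FrapTruth(
        bleach_mask=disk,
        frame_times_s=times,
        totals_au=tuple(totals),
        init_level=float(init_level),
        offset_au=float(offset_au),
        well_mixed_level=float(totals[1] / disk.size),
        parameters={
            "d_coeff_um2_s": d_coeff_um2_s,
            "bleach_radius_um": bleach_radius_um,
            "bleach_depth": bleach_depth,
            "duration_s": duration_s,
            "interval_s": interval_s,
            "domain_um": domain_um,
            "pixel_size_um": pixel_size_um,
            "seed": seed,
        },
    )
    return scene, truth


# ---------------------------------------------------------------------------
# Accessory vignettes


def render_branch(
    n_boxes: int = 8,
    tip_active: bool = True,
    seed: int = 0,
    box_side_um: float = 4.5,
    pixel_size_um: float = 0.3,
    noise_sigma: float = 8.0,
) -> ImageScene:
    """Tracheal-branch vignette for tiled colocalization analysis.

    Two channels, ``biosensor`` and ``membrane``.  The membrane marker
    outlines a tube (walls plus cell septa).  When ``tip_active``, the
    biosensor follows the membrane pattern in the tip-most segment and is
    uncorrelated noise along the stalk; the branch axis runs along the
    image center row.
    """
    if not 7 <= n_boxes <= 9:
        raise ValueError("n_boxes must be in [7, 9]")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    length_um = n_boxes * box_side_um
    w = int(round(length_um / px))
    h = int(round(12.0 / px))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    wall = (np.abs(yy * px - 2.0) < 0.5) | (np.abs(yy * px - 10.0) < 0.5)
    septa = np.zeros((h, w), dtype=bool)
    for x0 in np.arange(5.6, length_um - 1, 5.6):
        septa |= (np.abs(xx * px - x0) < 0.3) & (yy * px > 2.0) & (yy * px < 10.0)
    pattern = 200.0 * (wall | septa)

    membrane = 20.0 + pattern + rng.normal(0, noise_sigma, (h, w))
    tip_start = length_um - 1.5 * box_side_um
    weight = np.clip((xx * px - tip_start) / (0.5 * box_side_um), 0.0, 1.0)
    if not tip_active:
        weight = np.zeros_like(weight)
    biosensor = 30.0 + weight * pattern + rng.normal(0, noise_sigma, (h, w))

    return ImageScene(
        pixels=np.stack([biosensor, membrane]),
        axes="CYX",
        pixel_size_um=px,
        channel_names=("biosensor", "membrane"),
    )


def render_follicle(
    dorsal_active: bool = True,
    seed: int = 0,
    pixel_size_um: float = 0.3,
    cyto_level: float = 60.0,
    active_ratio: float = 2.5,
    noise_sigma: float = 0.0,
) -> ImageScene:
    """Follicle-epithelium vignette for apical-enrichment analysis.

    Single ``biosensor`` channel: an apical membrane line (rows at y = 3-4
    um) over an apical cytoplasm band (y = 5-8 um).  The dorsal half of
    the epithelium (left, x < midpoint) shows apical membrane enrichment
    ``active_ratio`` when ``dorsal_active``; elsewhere the membrane matches
    the cytoplasm.
    """
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    w = int(round(60.0 / px))
    h = int(round(12.0 / px))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    apical = (yy * px >= 3.0) & (yy * px < 4.5)
    cyto = (yy * px >= 5.0) & (yy * px < 9.0)
    dorsal = xx < w / 2
    ratio = np.where(dorsal & dorsal_active, active_ratio, 1.0)
    img = np.zeros((h, w))
    img[apical] = (cyto_level * ratio)[apical]
    img[cyto] = cyto_level
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, img.shape)
    return ImageScene(
        pixels=img[None],
        axes="CYX",
        pixel_size_um=px,
        channel_names=("biosensor",),
    )
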