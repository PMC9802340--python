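"""Seeded synthetic colony and bead image stacks with exact ground truth.

The raw microscopy behind the experiments this package analyses (bright-field
time lapses of expanding *Serratia marcescens* colonies, and fluorescence time
lapses of tracer beads embedded in polyacrylamide substrates) is not publicly
deposited, so every analysis stage is exercised on synthetic stacks rendered
from a prescribed forward model:

* an expanding, roughly circular colony front with a fixed low-order Fourier
  roughness perturbation, so the true radius is well defined per frame;
* tracer beads advected by a prescribed displacement model composed of a slow
  inward contractile term, transient localized "hot spots" on the ~20 µm scale
  near the expanding edge, an optional edge-locked radial annulus (a synthetic
  source of the divergence wave that travels with the colony front), rigid
  stage drift, and imaging noise.

Ground truth is exactly the function used to render the frames — nothing is
re-estimated — which is what makes quantitative recovery tests possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Sequence

import h5py
import numpy as np
from scipy import integrate
from scipy.special import erf

from .stacks import ImageStack

__all__ = [
    "ColonyScenario",
    "Hotspot",
    "EdgeAnnulus",
    "DisplacementModel",
    "BeadScenario",
    "GroundTruth",
    "generate_colony_stack",
    "generate_bead_stack",
    "evaluate_displacement_model",
]

UINT16_MAX = 65535


# --------------------------------------------------------------------------
# Scenario types
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ColonyScenario:
    """Parameters of a rendered expanding-colony bright-field stack.

    The colony front at frame time ``t`` is ``r(θ, t) = R(t) + A·cos(kθ)``
    with ``R(t) = initial_radius + ∫₀ᵗ radial_speed dt``.

    Attributes
    ----------
    initial_radius : float
        Colony radius at frame 0, µm.
    radial_speed : float or callable
        Front speed in µm/min; either a constant or a function of time (min).
    boundary_roughness_amplitude : float
        Amplitude ``A`` of the fixed Fourier roughness, µm.
    boundary_roughness_wavenumber : int
        Azimuthal wavenumber ``k`` of the roughness.
    interior_intensity, exterior_intensity : float
        Grayscale levels inside/outside the colony (16-bit range).
    noise_sd : float
        Additive Gaussian imaging noise, grayscale units.
    pixel_size : float
        µm per pixel.
    frame_interval : float
        Minutes between frames.
    n_frames : int
        Number of frames (≥ 2).
    image_shape : (int, int)
        Frame shape (H, W) in pixels.
    center : (float, float) or None
        Colony center (x, y) in µm; defaults to the image center.
    seed : int
        Seed for the imaging-noise RNG.
    """

    initial_radius: float
    radial_speed: float | Callable[[float], float] = 0.0
    boundary_roughness_amplitude: float = 0.0
    boundary_roughness_wavenumber: int = 0
    interior_intensity: float = 12000.0
    exterior_intensity: float = 32000.0
    noise_sd: float = 0.0
    pixel_size: float = 2.0
    frame_interval: float = 10.0
    n_frames: int = 6
    image_shape: tuple[int, int] = (512, 512)
    center: tuple[float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.initial_radius <= 0:
            raise ValueError("initial_radius must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        for name in ("interior_intensity", "exterior_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= UINT16_MAX:
                raise ValueError(f"{name}={v} outside 16-bit range")
        for t in np.linspace(0, (self.n_frames - 1) * self.frame_interval, 101):
            if self.speed_at(float(t)) < 0:
                raise ValueError(f"radial_speed negative at t={t:.1f} min")

    def speed_at(self, t_min: float) -> float:
        if callable(self.radial_speed):
            return float(self.radial_speed(t_min))
        return float(self.radial_speed)

    def radius_at(self, t_min: float) -> float:
        """True mean radius R(t) = R₀ + ∫₀ᵗ v dt, µm."""
        if callable(self.radial_speed):
            growth, _ = integrate.quad(self.radial_speed, 0.0, t_min)
        else:
            growth = self.radial_speed * t_min
        return self.initial_radius + growth

    def center_um(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        h, w = self.image_shape
        return np.array([(w - 1) / 2.0, (h - 1) / 2.0]) * self.pixel_size


@dataclass(frozen=True)
class Hotspot:
    """A transient localized displacement pulse near the colony edge.

    The displacement contribution is ``amplitude · exp(−|x−center|²/(2·scale²))``
    along ``direction`` while ``onset_frame ≤ t < onset_frame + duration``,
    mimicking the ~20 µm traction hot spots observed near expanding biofilm
    edges.  ``direction`` defaults to radially outward from the contractile
    center (or +x if the hotspot sits exactly on it).
    """

    center: tuple[float, float]
    scale: float
    amplitude: float
    onset_frame: int
    duration: int
    direction: tuple[float, float] | None = None


@dataclass(frozen=True)
class EdgeAnnulus:
    """Radial Gaussian displacement ring locked to a moving colony edge.

    ``u_r(r, t) = amplitude · exp(−(r − R_t)²/(2·width²))`` with ``R_t`` taken
    from ``radius_per_frame``.  Its divergence is an annular wave that travels
    with the front — the synthetic counterpart of the substrate swelling ring
    seen at expanding colony edges.
    """

    amplitude: float
    width: float
    radius_per_frame: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "radius_per_frame", tuple(float(r) for r in self.radius_per_frame))

    @classmethod
    def for_divergence(cls, peak_divergence: float, width: float,
                       radius_per_frame) -> "EdgeAnnulus":
        """Calibrate the amplitude so the peak |∇·u| equals ``peak_divergence``.

        The divergence of the radial ring is ``du_r/dr + u_r/r``; the
        amplitude scales it linearly, so it is solved on a fine radial grid
        at the smallest prescribed edge radius.
        """
        radii = tuple(float(r) for r in radius_per_frame)
        positive = [r for r in radii if r > 0]
        if not positive:
            raise ValueError("need at least one positive edge radius")
        R = min(positive)
        r = np.linspace(max(R - 6 * width, 1e-3), R + 6 * width, 20001)
        ur = np.exp(-((r - R) ** 2) / (2.0 * width**2))  # unit amplitude
        peak_unit = np.max(np.abs(np.gradient(ur, r) + ur / r))
        return cls(peak_divergence / peak_unit, width, radii)


@dataclass(frozen=True)
class DisplacementModel:
    """Prescribed substrate displacement u(x, t), µm, relative to frame 0.

    Frame 0 is the rest configuration: ``u(·, 0) ≡ 0`` by definition.  For
    frame t ≥ 1 the model is the sum of

    * a contractile term pulling toward ``contractile_center`` that grows
      linearly with frame index (accumulated inward creep):
      ``u = −t · A · (x−c)/L · exp(½ − r²/(2L²))``, peak magnitude ``t·A``
      at ``r = L``;
    * Gaussian hot spots while active (see :class:`Hotspot`);
    * an optional edge-locked annulus (see :class:`EdgeAnnulus`);
    * rigid stage drift ``t · drift_per_frame``.
    """

    contractile_amplitude: float = 0.0
    contractile_center: tuple[float, float] = (0.0, 0.0)
    contractile_length_scale: float = 100.0
    hotspots: tuple[Hotspot, ...] = ()
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    edge_annulus: EdgeAnnulus | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.contractile_length_scale <= 0:
            raise ValueError("contractile_length_scale must be positive")
        for h in self.hotspots:
            if h.scale <= 0:
                raise ValueError("hotspot scale must be positive")
            if h.duration < 1:
                raise ValueError("hotspot duration must be >= 1 frame")
        if self.edge_annulus is not None and self.edge_annulus.width <= 0:
            raise ValueError("edge_annulus width must be positive")


def evaluate_displacement_model(
    model: DisplacementModel, points: np.ndarray, frame: int
) -> np.ndarray:
    """Evaluate u(points, frame) in µm.

    ``points`` is ``(N, 2)`` in µm; returns ``(N, 2)``.  Deterministic for a
    fixed model; frame 0 returns zeros (rest configuration).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    u = np.zeros_like(pts)
    if frame == 0:
        return u

    # contractile creep toward the colony center
    if model.contractile_amplitude != 0.0:
        c = np.asarray(model.contractile_center, dtype=float)
        L = model.contractile_length_scale
        d = pts - c
        r2 = np.sum(d * d, axis=1)
        g = np.exp(0.5 - r2 / (2.0 * L * L))
        u -= frame * model.contractile_amplitude / L * d * g[:, None]

    # transient hot spots
    for h in model.hotspots:
        if not (h.onset_frame <= frame < h.onset_frame + h.duration):
            continue
        c = np.asarray(h.center, dtype=float)
        if h.direction is not None:
            direction = np.asarray(h.direction, dtype=float)
        else:
            direction = c - np.asarray(model.contractile_center, dtype=float)
        n = np.hypot(*direction)
        direction = direction / n if n > 0 else np.array([1.0, 0.0])
        d = pts - c
        g = np.exp(-np.sum(d * d, axis=1) / (2.0 * h.scale**2))
        u += h.amplitude * g[:, None] * direction

    # edge-locked radial annulus
    if model.edge_annulus is not None:
        ann = model.edge_annulus
        R = ann.radius_per_frame[min(frame, len(ann.radius_per_frame) - 1)]
        c = np.asarray(model.contractile_center, dtype=float)
        d = pts - c
        r = np.hypot(d[:, 0], d[:, 1])
        g = ann.amplitude * np.exp(-((r - R) ** 2) / (2.0 * ann.width**2))
        rhat = np.where(r[:, None] > 0, d / np.maximum(r, 1e-12)[:, None], 0.0)
        u += g[:, None] * rhat

    u += frame * np.asarray(model.drift_per_frame, dtype=float)
    if not np.all(np.isfinite(u)):  # pragma: no cover - guarded by validate()
        raise FloatingPointError("displacement model produced non-finite values")
    return u


@dataclass(frozen=True)
class BeadScenario:
    """Parameters of a rendered fluorescent-tracer stack.

    Beads (default diameter 4.8 µm, matching the tracers embedded in the
    polyacrylamide gels) are rendered as integrated Gaussian spots whose
    standard deviation combines the optical PSF with the bead size, so
    subpixel positions are exactly meaningful.
    """

    bead_density: float = 0.015  # beads/µm²
    bead_diameter: float = 4.8  # µm
    psf_sd: float = 0.8  # px
    image_shape: tuple[int, int] = (256, 256)
    noise_sd: float = 80.0
    pixel_size: float = 1.6
    peak_intensity: float = 18000.0
    background: float = 1000.0
    periodic: bool = False  # toroidal rendering (for shift-invariance oracles)
    seed: int = 0

    def validate(self, window_size: int = 32) -> None:
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        if self.bead_density <= 0:
            raise ValueError("bead_density must be positive")
        per_window = self.bead_density * (window_size * self.pixel_size) ** 2
        if per_window < 10:
            raise ValueError(
                f"bead_density {self.bead_density}/µm² yields {per_window:.1f} beads "
                f"per {window_size}-px PIV window; need >= 10"
            )

    @property
    def spot_sd_px(self) -> float:
        """Effective Gaussian spot σ in px: PSF ⊕ bead footprint (σ ≈ d/4)."""
        bead_sd = self.bead_diameter / (4.0 * self.pixel_size)
        return float(np.hypot(self.psf_sd, bead_sd))


@dataclass
class GroundTruth:
    """Exact generative state of a synthetic stack.

    Carries whatever the generating operation prescribed — per-frame boundary
    radius/center for colony stacks; the displacement model, its evaluation on
    a regular grid, and clipped-bead flags for bead stacks — plus the scenario
    parameters, so recovery tests compare against the rendering functions
    themselves.
    """

    params: dict
    boundary_radius: np.ndarray | None = None  # (T,) µm
    boundary_center: np.ndarray | None = None  # (T, 2) µm
    displacement: Callable[[np.ndarray, int], np.ndarray] | None = None
    grid_x: np.ndarray | None = None  # (nx,) µm
    grid_y: np.ndarray | None = None  # (ny,) µm
    grid_u: np.ndarray | None = None  # (T, ny, nx, 2) µm
    bead_rest_positions: np.ndarray | None = None  # (N, 2) µm
    clipped_beads: np.ndarray | None = None  # (T, N) bool
    traction: np.ndarray | None = None

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        """Structured HDF5 sidecar; scalar parameters in a JSON attribute."""
        with h5py.File(path, "w") as f:
            f.attrs["params_json"] = json.dumps(self.params, sort_keys=True, default=str)
            for name in ("boundary_radius", "boundary_center", "grid_x", "grid_y",
                         "grid_u", "bead_rest_positions", "clipped_beads", "traction"):
                arr = getattr(self, name)
                if arr is not None:
                    f.create_dataset(name, data=np.asarray(arr), track_times=False)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with h5py.File(path, "r") as f:
            kw = {"params": json.loads(f.attrs["params_json"])}
            for name in ("boundary_radius", "boundary_center", "grid_x", "grid_y",
                         "grid_u", "bead_rest_positions", "clipped_beads", "traction"):
                if name in f:
                    kw[name] = f[name][...]
        return cls(**kw)


# --------------------------------------------------------------------------
# Colony rendering
# --------------------------------------------------------------------------
def _colony_frame(scenario: ColonyScenario, radius_um: float) -> np.ndarray:
    """Render one noiseless colony frame as float64.

    Pixel intensity ramps linearly from interior to exterior across one pixel
    of signed distance to the perturbed front, so the mid-level isocontour of
    the rendered image sits exactly on r(θ) = R + A·cos(kθ).
    """
    h, w = scenario.image_shape
    cx, cy = scenario.center_um() / scenario.pixel_size  # px
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    r_px = np.hypot(dx, dy)
    rb_px = radius_um / scenario.pixel_size
    if scenario.boundary_roughness_amplitude:
        theta = np.arctan2(dy, dx)
        rb_px = rb_px + (scenario.boundary_roughness_amplitude / scenario.pixel_size) * np.cos(
            scenario.boundary_roughness_wavenumber * theta
        )
    d = r_px - rb_px  # signed distance in px, >0 outside
    frac_inside = np.clip(0.5 - d, 0.0, 1.0)  # 1 px wide linear edge
    return scenario.exterior_intensity + (
        scenario.interior_intensity - scenario.exterior_intensity
    ) * frac_inside


def generate_colony_stack(scenario: ColonyScenario) -> tuple[ImageStack, GroundTruth]:
    """Render a bright-field colony time lapse with exact front ground truth.

    Raises
    ------
    ValueError
        If the scenario is invalid, or if the colony front would leave the
        image bounds before ``n_frames`` (the message names the frame).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    h, w = scenario.image_shape
    cx, cy = scenario.center_um()
    margin = min(cx, cy, (w - 1) * scenario.pixel_size - cx, (h - 1) * scenario.pixel_size - cy)

    frames = np.empty((scenario.n_frames, h, w), dtype=np.uint16)
    radii = np.empty(scenario.n_frames)
    for t in range(scenario.n_frames):
        R = scenario.radius_at(t * scenario.frame_interval)
        if R + scenario.boundary_roughness_amplitude >= margin:
            raise ValueError(
                f"colony radius {R:.1f} µm exceeds image bounds at frame {t} "
                f"(usable margin {margin:.1f} µm)"
            )
        img = _colony_frame(scenario, R)
        if scenario.noise_sd > 0:
            img = img + rng.normal(0.0, scenario.noise_sd, img.shape)
        frames[t] = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)
        radii[t] = R

    stack = ImageStack(frames, scenario.pixel_size, scenario.frame_interval, "brightfield")
    truth = GroundTruth(
        params={"scenario": _scenario_dict(scenario)},
        boundary_radius=radii,
        boundary_center=np.tile(scenario.center_um(), (scenario.n_frames, 1)),
    )
    return stack, truth


# --------------------------------------------------------------------------
# Bead rendering
# --------------------------------------------------------------------------
def _render_beads(positions_px: np.ndarray, shape: tuple[int, int],
                  sd: float, amplitude: float) -> np.ndarray:
    """Sum of flux-normalized Gaussian spots, integrated over each pixel.

    Uses separable erf differences — the exact limit of supersampled
    rendering — so subpixel centers shift the image smoothly.
    """
    h, w = shape
    img = np.zeros((h, w))
    half = int(np.ceil(4 * sd))
    s = sd * np.sqrt(2.0)
    for x, y in positions_px:
        ix, iy = int(np.floor(x)), int(np.floor(y))
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        px = np.arange(x0, x1)
        py = np.arange(y0, y1)
        gx = 0.5 * (erf((px + 0.5 - x) / s) - erf((px - 0.5 - x) / s))
        gy = 0.5 * (erf((py + 0.5 - y) / s) - erf((py - 0.5 - y) / s))
        # peak pixel of a centred spot integrates to ~erf(1/(2√2 σ))², rescale
        img[y0:y1, x0:x1] += np.outer(gy, gx)
    peak = (erf(0.5 / s)) ** 2
    return img * (amplitude / peak)


def generate_bead_stack(
    beads: BeadScenario,
    model: DisplacementModel,
    n_frames: int,
    truth_grid_spacing_px: int = 16,
) -> tuple[ImageStack, GroundTruth]:
    """Render a fluorescent-tracer time lapse advected by ``model``.

    Beads sit at seeded uniform rest positions; frame ``t`` renders each bead
    at ``x₀ + u(x₀, t)`` (frame 0 at rest).  Beads displaced outside the frame
    are silently clipped from the rendering but flagged per frame in the
    ground truth.  The ground truth also samples ``u`` on a regular grid
    (spacing ``truth_grid_spacing_px``) for direct comparison with PIV output.
    """
    beads.validate()
    model.validate()
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    h, w = beads.image_shape
    area = (h * beads.pixel_size) * (w * beads.pixel_size)
    n_beads = int(round(beads.bead_density * area))
    if n_beads == 0:
        raise ValueError("bead scenario yields zero beads")

    rng = np.random.default_rng(beads.seed)
    rest = np.column_stack([
        rng.uniform(0, (w - 1) * beads.pixel_size, n_beads),
        rng.uniform(0, (h - 1) * beads.pixel_size, n_beads),
    ])

    sd = beads.spot_sd_px
    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    clipped = np.zeros((n_frames, n_beads), dtype=bool)
    for t in range(n_frames):
        u = evaluate_displacement_model(model, rest, t)
        pos_px = (rest + u) / beads.pixel_size
        if beads.periodic:
            # wrap positions onto the torus and render edge-crossing copies
            pos_px = np.mod(pos_px, [w, h])
            copies = [pos_px]
            for ox in (-w, 0, w):
                for oy in (-h, 0, h):
                    if ox == oy == 0:
                        continue
                    shifted = pos_px + [ox, oy]
                    near = (
                        (shifted[:, 0] > -4 * sd) & (shifted[:, 0] < w + 4 * sd)
                        & (shifted[:, 1] > -4 * sd) & (shifted[:, 1] < h + 4 * sd)
                    )
                    copies.append(shifted[near])
            render_pos = np.vstack(copies)
            out = np.zeros(n_beads, dtype=bool)
        else:
            out = (
                (pos_px[:, 0] < -4 * sd) | (pos_px[:, 0] > w - 1 + 4 * sd)
                | (pos_px[:, 1] < -4 * sd) | (pos_px[:, 1] > h - 1 + 4 * sd)
            )
            render_pos = pos_px[~out]
        clipped[t] = out
        img = beads.background + _render_beads(render_pos, (h, w), sd, beads.peak_intensity)
        if beads.noise_sd > 0:
            img = img + rng.normal(0.0, beads.noise_sd, img.shape)
        frames[t] = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)

    gx = np.arange(truth_grid_spacing_px / 2, w, truth_grid_spacing_px) * beads.pixel_size
    gy = np.arange(truth_grid_spacing_px / 2, h, truth_grid_spacing_px) * beads.pixel_size
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    grid_u = np.stack(
        [evaluate_displacement_model(model, pts, t).reshape(len(gy), len(gx), 2)
         for t in range(n_frames)]
    )

    stack = ImageStack(frames, beads.pixel_size, 10.0, "beads")
    truth = GroundTruth(
        params={"beads": asdict(beads), "model": _model_dict(model), "n_frames": n_frames},
        displacement=lambda pts, t: evaluate_displacement_model(model, pts, t),
        grid_x=gx,
        grid_y=gy,
        grid_u=grid_u,
        bead_rest_positions=rest,
        clipped_beads=clipped,
    )
    return stack, truth


def _scenario_dict(s: ColonyScenario) -> dict:
    d = asdict(s)
    if callable(s.radial_speed):
        d["radial_speed"] = getattr(s.radial_speed, "__name__", "<callable>")
    return d


def _model_dict(m: DisplacementModel) -> dict:
    return asdict(m)
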