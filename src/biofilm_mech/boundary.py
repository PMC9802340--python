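"""Colony front detection, circular-arc fitting, and radial expansion velocimetry.

The colony edge in bright-field imagery separates two intensity phases.  The
original measurements used manually supervised boundary clicks; here the
supervision is replaced by a deterministic chain — between-class-variance
(Otsu) thresholding, largest-connected-component selection, morphological
closing, then subpixel contour extraction at the threshold level — with an
optional prior boundary that reproduces the supervised preference for the
contour nearest the previous frame.

Each detected boundary is fit to a circular arc (algebraic Kåsa seed refined
by orthogonal-distance minimization).  The expansion velocity over a time
increment is the mean length of radial lines connecting consecutive arcs,
anchored at the earlier arc's center, converted to mm/hour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree
from skimage import filters, measure, morphology
from scipy import ndimage

from .stacks import ImageStack

__all__ = [
    "ColonyBoundary",
    "NoColonyError",
    "DegenerateFitError",
    "detect_boundary",
    "fit_arc",
    "radial_velocity",
    "track_boundaries",
    "expansion_curve",
]

log = logging.getLogger(__name__)


class NoColonyError(RuntimeError):
    """Raised when a frame contains no detectable colony region."""


class DegenerateFitError(RuntimeError):
    """Raised when an arc fit is attempted on (near-)collinear points."""


@dataclass
class ColonyBoundary:
    """Per-frame boundary polyline with its fitted circular arc (pixel units)."""

    frame: int
    polyline: np.ndarray  # (N, 2) as (x, y), px
    arc_center: np.ndarray  # (2,) px
    arc_radius: float  # px
    fit_residual: float  # RMS radial misfit, px

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        self.arc_center = np.asarray(self.arc_center, dtype=float)
        if len(self.polyline) < 8:
            raise ValueError("boundary polyline needs at least 8 points")
        if self.arc_radius <= 0:
            raise ValueError("arc_radius must be positive")

    def point_angles(self) -> np.ndarray:
        d = self.polyline - self.arc_center
        return np.arctan2(d[:, 1], d[:, 0])


# --------------------------------------------------------------------------
# Detection
# --------------------------------------------------------------------------
def detect_boundary(
    frame: np.ndarray,
    pixel_size: float | None = None,
    prior: ColonyBoundary | None = None,
    *,
    interior: str = "auto",
    smooth_sigma: float = 1.0,
    closing_radius: int = 2,
    min_area_px: int = 64,
) -> np.ndarray:
    """Detect the colony boundary in one frame; returns an (N, 2) (x, y) polyline in px.

    Parameters
    ----------
    frame
        2D grayscale raster.
    prior
        Previous frame's boundary; when given, the contour nearest the prior
        is selected instead of the longest one ("prior snap").
    interior
        ``"dark"``, ``"bright"``, or ``"auto"`` — which intensity phase is the
        colony.  ``auto`` picks the phase whose largest connected component
        touches the image border least (the inoculum sits centrally).
    smooth_sigma
        Gaussian denoising σ in px applied before thresholding.
    closing_radius
        Radius of the morphological closing applied to the colony mask.

    Raises
    ------
    NoColonyError
        If the frame has no usable intensity contrast or no region of at
        least ``min_area_px`` pixels.
    """
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        raise NoColonyError("empty frame")
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    contrast = img.max() - img.min()
    if contrast <= 0:
        raise NoColonyError("no colony detected: frame has no intensity contrast")
    thr = filters.threshold_otsu(img)

    def largest_component(mask: np.ndarray) -> tuple[np.ndarray | None, int, int]:
        lab, n = ndimage.label(mask)
        if n == 0:
            return None, 0, 0
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        comp = lab == best
        border = int(comp[0].sum() + comp[-1].sum() + comp[:, 0].sum() + comp[:, -1].sum())
        return comp, int(sizes[best - 1]), border

    candidates: dict[str, tuple] = {}
    if interior in ("dark", "auto"):
        candidates["dark"] = largest_component(img < thr)
    if interior in ("bright", "auto"):
        candidates["bright"] = largest_component(img > thr)
    # auto: prefer the phase whose component is interior (least border contact)
    best_mask = None
    best_key = (np.inf, np.inf)
    for comp, size, border in candidates.values():
        if comp is None or size < min_area_px:
            continue
        key = (border, -size)
        if key < best_key:
            best_key, best_mask = key, comp
    if best_mask is None:
        raise NoColonyError("no colony detected: no region above the minimum area")

    mask = morphology.closing(best_mask, morphology.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)

    # subpixel contour at the threshold level, selected against the mask/prior
    contours = measure.find_contours(img, level=thr)
    contours = [c for c in contours if len(c) >= 8]
    if not contours:
        raise NoColonyError("no colony detected: no contour at threshold level")

    if prior is not None:
        tree = cKDTree(prior.polyline)

        def score(c):
            xy = c[:, ::-1]
            return float(np.mean(tree.query(xy)[0]))
    else:
        # contour must trace the selected mask: score by overlap with the mask
        # boundary, tie-broken toward the longest contour
        edge = mask ^ ndimage.binary_erosion(mask)
        edge_pts = np.argwhere(edge)
        tree = cKDTree(edge_pts) if len(edge_pts) else None

        def score(c):
            if tree is None:
                return -float(len(c))
            d = float(np.mean(tree.query(c)[0]))
            return d - 1e-6 * len(c)

    best = min(contours, key=score)
    return best[:, ::-1].copy()  # (row, col) -> (x, y)


# --------------------------------------------------------------------------
# Circle fitting
# --------------------------------------------------------------------------
def fit_arc(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through ``points`` (px); returns (center, radius, residual).

    Algebraic Kåsa fit (exact on noiseless circles, stable on short arcs)
    refined by geometric orthogonal-distance minimization; the residual is the
    RMS radial misfit in px.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegenerateFitError("need at least 3 points for a circle fit")
    x, y = pts[:, 0], pts[:, 1]
    # collinearity check via the smaller singular value of the centred cloud
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateFitError("points are collinear; circle fit is degenerate")

    # Kåsa: x² + y² = 2a·x + 2b·y + c
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (a0, b0, c0), *_ = np.linalg.lstsq(A, b, rcond=None)
    r0 = float(np.sqrt(max(c0 + a0**2 + b0**2, 1e-300)))

    def radial_misfit(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = optimize.least_squares(radial_misfit, [a0, b0, r0], method="lm")
    cx, cy, r = sol.x
    if r <= 0:
        raise DegenerateFitError("circle fit converged to a non-positive radius")
    res = float(np.sqrt(np.mean(radial_misfit(sol.x) ** 2)))
    return np.array([cx, cy]), float(r), res


def _angular_span(bnd: ColonyBoundary) -> tuple[float, float]:
    """Angular interval covered by the polyline about its own arc center.

    Returns (theta0, width); a closed boundary reports width 2π.
    """
    th = np.sort(np.mod(bnd.point_angles(), 2 * np.pi))
    gaps = np.diff(np.concatenate([th, [th[0] + 2 * np.pi]]))
    i = int(np.argmax(gaps))
    if gaps[i] < np.deg2rad(10):  # effectively closed
        return 0.0, 2 * np.pi
    start = th[(i + 1) % len(th)]
    width = 2 * np.pi - gaps[i]
    return float(start), float(width)


# --------------------------------------------------------------------------
# Radial velocimetry
# --------------------------------------------------------------------------
def radial_velocity(
    arc_a: ColonyBoundary,
    arc_b: ColonyBoundary,
    dt_min: float,
    n_rays: int = 50,
    pixel_size: float = 1.0,
) -> float:
    """Mean radial advance from ``arc_a`` to ``arc_b`` over ``dt_min``, in mm/hour.

    Rays are cast from ``arc_a``'s fitted center across the angular range both
    arcs cover; each ray's contribution is the distance from its intersection
    with arc_a's circle (at radius ``R_a``) to its intersection with arc_b's
    circle.  Rays that miss arc_b's angular span or circle are excluded.

    Raises
    ------
    ValueError
        If ``dt_min`` or ``n_rays`` is non-positive, or every ray is excluded.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    a0, wa = _angular_span(arc_a)
    b0, wb = _angular_span(arc_b)
    full = 2 * np.pi - 1e-9
    if wa >= full and wb >= full:
        thetas = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
        b_lo = b_hi = None
    else:
        if wa >= full:
            lo, hi = b0, b0 + wb
        elif wb >= full:
            lo, hi = a0, a0 + wa
        else:
            # shift b's interval to the branch nearest a's before intersecting
            b0 = b0 - 2 * np.pi * np.round((b0 - a0) / (2 * np.pi))
            lo, hi = max(a0, b0), min(a0 + wa, b0 + wb)
            if hi <= lo:
                raise ValueError("arcs do not overlap angularly")
        thetas = np.linspace(lo, hi, n_rays)
        b_lo, b_hi = (None, None) if wb >= full else (b0, b0 + wb)

    ca, cb = arc_a.arc_center, arc_b.arc_center
    lengths = []
    for th in thetas:
        d = np.array([np.cos(th), np.sin(th)])
        delta = cb - ca
        beta = d @ delta
        disc = beta**2 - (delta @ delta - arc_b.arc_radius**2)
        if disc < 0:
            continue  # ray misses arc_b's circle
        t_b = beta + np.sqrt(disc)
        if t_b <= 0:
            continue
        if b_lo is not None:
            # angle of the intersection point about arc_b's center
            p = ca + t_b * d - cb
            ang = np.arctan2(p[1], p[0])
            ang = ang + 2 * np.pi * np.ceil((b_lo - ang) / (2 * np.pi))
            if ang > b_hi:
                continue
        lengths.append(t_b - arc_a.arc_radius)
    if not lengths:
        raise ValueError("all rays excluded; arcs do not overlap")
    mean_px = float(np.mean(lengths))
    return mean_px * pixel_size / 1000.0 / (dt_min / 60.0)  # mm / h


# --------------------------------------------------------------------------
# Per-stack tracking and expansion curves
# --------------------------------------------------------------------------
def track_boundaries(stack: ImageStack, **detect_kwargs) -> list[ColonyBoundary]:
    """Detect and arc-fit the boundary in every frame, snapping to the prior."""
    out: list[ColonyBoundary] = []
    prior = None
    for t in range(stack.n_frames):
        poly = detect_boundary(stack[t], stack.pixel_size, prior=prior, **detect_kwargs)
        center, radius, res = fit_arc(poly)
        prior = ColonyBoundary(t, poly, center, radius, res)
        out.append(prior)
    return out


def expansion_curve(
    stack: ImageStack,
    n_windows: int = 4,
    dt_min: float = 20.0,
    n_rays: int = 50,
    boundaries: list[ColonyBoundary] | None = None,
    **detect_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed expansion-velocity time series and per-colony mean ± SEM.

    The colony periphery is split into ``n_windows`` equal angular sectors
    (the imaging windows).  For each ``dt_min`` increment, the boundary points
    of each sector are arc-fit separately and the radial velocity computed
    between consecutive increments; the colony velocity at each time is the
    mean across surviving windows with its SEM.  Velocities are stamped at
    the interval midpoint.

    Returns
    -------
    records, summary
        ``records``: columns (window, time_min, velocity_mm_per_h).
        ``summary``: columns (time_min, mean_mm_per_h, sem_mm_per_h, n_windows).

    Raises
    ------
    ValueError
        If the stack spans less than ``dt_min`` or fewer than two windows
        survive detection.
    """
    step = int(round(dt_min / stack.frame_interval))
    if step < 1 or stack.n_frames <= step:
        raise ValueError(f"stack must span at least {dt_min} min")
    if boundaries is None:
        boundaries = track_boundaries(stack, **detect_kwargs)

    edges = np.linspace(0, 2 * np.pi, n_windows + 1)
    frame_idx = list(range(0, stack.n_frames - step, step)) or [0]

    def sector_arc(bnd: ColonyBoundary, w: int) -> ColonyBoundary | None:
        ang = np.mod(bnd.point_angles(), 2 * np.pi)
        sel = (ang >= edges[w]) & (ang < edges[w + 1])
        if sel.sum() < 8:
            return None
        try:
            c, r, res = fit_arc(bnd.polyline[sel])
        except DegenerateFitError:
            return None
        return ColonyBoundary(bnd.frame, bnd.polyline[sel], c, r, res)

    rows = []
    surviving = set(range(n_windows))
    for w in range(n_windows):
        arcs = {}
        ok = True
        for i in frame_idx + [frame_idx[-1] + step]:
            arc = sector_arc(boundaries[i], w)
            if arc is None:
                ok = False
                break
            arcs[i] = arc
        if not ok:
            log.warning("window %d dropped: boundary detection/fit failed", w)
            surviving.discard(w)
            continue
        for i in frame_idx:
            v = radial_velocity(arcs[i], arcs[i + step], dt_min, n_rays, stack.pixel_size)
            t_mid = (i + step / 2.0) * stack.frame_interval
            rows.append({"window": w, "time_min": t_mid, "velocity_mm_per_h": v})

    if len(surviving) < 2:
        raise ValueError(f"only {len(surviving)} window(s) survived detection; need >= 2")

    records = pd.DataFrame(rows)
    grp = records.groupby("time_min")["velocity_mm_per_h"]
    summary = pd.DataFrame({
        "time_min": grp.mean().index,
        "mean_mm_per_h": grp.mean().to_numpy(),
        "sem_mm_per_h": grp.sem().to_numpy(),
        "n_windows": grp.count().to_numpy(),
    })
    return records, summary
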