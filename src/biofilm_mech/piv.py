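"""Substrate displacement mapping by windowed cross-correlation (PIV).

Displacements of fluorescent tracer beads embedded in the gel are estimated
per interrogation window by zero-mean cross-correlation with subpixel
three-point Gaussian peak interpolation.  Two reference-frame semantics are
provided: *accumulated* fields correlate every frame directly against the
first (prestressed) frame of the sequence, *instantaneous* fields correlate
consecutive frame pairs.  Rigid stage drift is removed by subtracting the
mean displacement of a stress-free region far from the colony.  Divergence of
the resulting vector field (∂u_x/∂x + ∂u_y/∂y, unitless) flags in-plane
substrate swelling/deswelling; its azimuthal average against signed distance
from the colony edge resolves the divergence wave that travels with the
expanding front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import interpolate, signal
from skimage import feature

from .stacks import ImageStack

__all__ = [
    "DisplacementField",
    "DivergenceField",
    "piv_displacement",
    "accumulate_series",
    "drift_correct",
    "divergence",
    "divergence_wave_profile",
]

log = logging.getLogger(__name__)


@dataclass
class DisplacementField:
    """Gridded 2D displacement field in µm on regular window centers.

    ``reference`` is ``"first_frame"`` (accumulated) or ``"previous_frame"``
    (instantaneous).  ``quality`` is the correlation peak-to-second-peak
    ratio; vectors failing validation are masked (``mask == False``) and set
    to NaN.
    """

    x: np.ndarray  # (nx,) window-center x, µm
    y: np.ndarray  # (ny,) window-center y, µm
    u: np.ndarray  # (ny, nx) x-displacement, µm
    v: np.ndarray  # (ny, nx) y-displacement, µm
    quality: np.ndarray  # (ny, nx) peak ratio
    mask: np.ndarray  # (ny, nx) bool, True where valid
    reference: str = "first_frame"
    frame: int = 0
    window_size: int = 32
    overlap: float = 0.5
    pixel_size: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference not in ("first_frame", "previous_frame"):
            raise ValueError("reference must be 'first_frame' or 'previous_frame'")

    @property
    def spacing(self) -> tuple[float, float]:
        """Grid spacing (dx, dy) in µm."""
        return float(self.x[1] - self.x[0]), float(self.y[1] - self.y[0])

    def to_frame(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.x, self.y)
        return pd.DataFrame({
            "frame": self.frame,
            "x_um": X.ravel(), "y_um": Y.ravel(),
            "ux_um": self.u.ravel(), "uy_um": self.v.ravel(),
            "quality": self.quality.ravel(), "valid": self.mask.ravel(),
        })


@dataclass
class DivergenceField:
    """Unitless divergence of a displacement field on the same grid.

    ``boundary`` flags nodes evaluated with one-sided differences (grid edge)
    or adjacent to masked vectors; interior nodes use central differences.
    ``window_min`` records the time span of the underlying displacement.
    """

    x: np.ndarray
    y: np.ndarray
    div: np.ndarray  # (ny, nx)
    boundary: np.ndarray  # (ny, nx) bool
    frame: int = 0
    window_min: float | None = None


# --------------------------------------------------------------------------
# Core correlation
# --------------------------------------------------------------------------
@lru_cache(maxsize=32)
def _overlap_count(hh: int, ww: int) -> np.ndarray:
    """Pixels contributing at each lag of a full correlation (envelope)."""
    ty = hh - np.abs(np.arange(-(hh - 1), hh))
    tx = ww - np.abs(np.arange(-(ww - 1), ww))
    return np.outer(ty, tx).astype(float)


def _gauss_subpixel(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian peak interpolation; parabolic fallback."""
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm + lp - 2 * l0
        if denom < 0:
            return float(np.clip((lm - lp) / (2 * denom), -1, 1))
    denom = cm + cp - 2 * c0
    if denom < 0:
        return float(np.clip((cm - cp) / (2 * denom), -1, 1))
    return 0.0


def piv_displacement(
    ref: np.ndarray,
    cur: np.ndarray,
    window_size: int = 32,
    overlap: float = 0.5,
    pixel_size: float = 1.0,
    quality_ratio: float = 1.5,
    min_peak: float = 0.5,
    min_std: float = 1e-3,
) -> DisplacementField:
    """Displacement of ``cur`` relative to ``ref`` by windowed cross-correlation.

    Interrogation windows of ``window_size`` px are laid out with the given
    ``overlap`` fraction.  Each reference window is used as a template and
    zero-mean cross-correlated (FFT) against a search region in ``cur``
    extending ``window_size/2`` px beyond the window on every side.  A second
    pass re-correlates against a search window offset by the integer part of
    the first-pass displacement — with offset windows the correlation peak is
    symmetric, so integer shifts are recovered essentially exactly — and the
    peak is refined to subpixel precision by a three-point Gaussian fit per
    axis.

    Vectors are masked (NaN) when a window is effectively featureless
    (standard deviation below ``min_std`` of the frame contrast), the
    normalized correlation coefficient at the peak falls below ``min_peak``
    (no credible match, e.g. content that left the field of view), or the
    peak-to-second-peak ratio falls below ``quality_ratio``.
    """
    ref = np.asarray(ref, dtype=float)
    cur = np.asarray(cur, dtype=float)
    if ref.shape != cur.shape:
        raise ValueError("frames must have the same shape")
    if window_size < 16:
        raise ValueError("window_size must be >= 16 px")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")

    ws = window_size
    step = max(int(round(ws * (1 - overlap))), 1)
    h, w = ref.shape
    ys = np.arange(0, h - ws + 1, step)
    xs = np.arange(0, w - ws + 1, step)
    ny, nx = len(ys), len(xs)
    if ny == 0 or nx == 0:
        raise ValueError("frame smaller than one interrogation window")

    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    quality = np.zeros((ny, nx))
    mask = np.zeros((ny, nx), dtype=bool)
    contrast = max(ref.max() - ref.min(), cur.max() - cur.min(), 1.0)
    std_floor = min_std * contrast
    half = ws // 2  # search margin: displacements up to ±ws/2

    for iy, y0 in enumerate(ys):
        for ix, x0 in enumerate(xs):
            a = ref[y0:y0 + ws, x0:x0 + ws]
            if a.std() < std_floor:
                continue
            # first pass: normalized cross-correlation over a ±half search
            sy0, sy1 = max(y0 - half, 0), min(y0 + ws + half, h)
            sx0, sx1 = max(x0 - half, 0), min(x0 + ws + half, w)
            b = cur[sy0:sy1, sx0:sx1]
            if b.std() < std_floor:
                continue
            ncc = feature.match_template(b, a)
            py, px = np.unravel_index(np.argmax(ncc), ncc.shape)
            peak = ncc[py, px]
            if peak < min_peak:
                continue
            # peak-to-second-peak ratio outside a 3px exclusion zone
            tmp = ncc.copy()
            tmp[max(py - 3, 0):py + 4, max(px - 3, 0):px + 4] = -np.inf
            second = tmp.max()
            q = peak / second if second > 0 else np.inf
            quality[iy, ix] = q
            if q < quality_ratio:
                continue
            dy = (sy0 + py) - y0
            dx = (sx0 + px) - x0
            # second pass: co-located equal-support windows after offsetting
            # cur by the integer displacement (cropped to the common support
            # at frame edges), iterated until the integer correction
            # converges.  Zero-padded full correlation of content-matched
            # windows is exactly symmetric about its peak, so the subpixel
            # fit is unbiased — exact for pure integer shifts.
            corr, py, px = None, 0, 0
            r = 4  # residual search radius after integer offset
            for _ in range(3):
                yb, xb = y0 + dy, x0 + dx
                ay0, ay1 = max(0, -yb), ws - max(0, yb + ws - h)
                ax0, ax1 = max(0, -xb), ws - max(0, xb + ws - w)
                if ay1 - ay0 < ws // 2 or ax1 - ax0 < ws // 2:
                    break
                a2 = a[ay0:ay1, ax0:ax1]
                b2 = cur[yb + ay0:yb + ay1, xb + ax0:xb + ax1]
                corr2 = signal.correlate(b2 - b2.mean(), a2 - a2.mean(),
                                         mode="full", method="fft")
                corr2 /= _overlap_count(ay1 - ay0, ax1 - ax0)
                cy, cx = ay1 - ay0 - 1, ax1 - ax0 - 1  # zero-lag index
                sub = corr2[cy - r:cy + r + 1, cx - r:cx + r + 1]
                if sub.shape != (2 * r + 1, 2 * r + 1):
                    break
                py2, px2 = np.unravel_index(np.argmax(sub), sub.shape)
                if sub[py2, px2] <= 0:
                    break
                corr, py, px = sub, py2, px2
                dy += py2 - r
                dx += px2 - r
                if (py2, px2) == (r, r):
                    break
            if corr is None:
                corr, py, px = ncc, *np.unravel_index(np.argmax(ncc), ncc.shape)
            peak = corr[py, px]
            sx = _gauss_subpixel(corr[py, px - 1], peak, corr[py, px + 1]) \
                if 0 < px < corr.shape[1] - 1 else 0.0
            sy = _gauss_subpixel(corr[py - 1, px], peak, corr[py + 1, px]) \
                if 0 < py < corr.shape[0] - 1 else 0.0
            u[iy, ix] = (dx + sx) * pixel_size
            v[iy, ix] = (dy + sy) * pixel_size
            mask[iy, ix] = True

    x_um = (xs + (ws - 1) / 2.0) * pixel_size
    y_um = (ys + (ws - 1) / 2.0) * pixel_size
    return DisplacementField(
        x=x_um, y=y_um, u=u, v=v, quality=quality, mask=mask,
        window_size=ws, overlap=overlap, pixel_size=pixel_size,
    )


def accumulate_series(
    stack: ImageStack,
    mode: str = "first_frame",
    decorrelation_quality: float = 1.2,
    **piv_kwargs,
) -> list[DisplacementField]:
    """Displacement fields for frames 1..T−1 of a bead stack.

    ``mode="first_frame"`` correlates each frame directly against frame 0
    (accumulated displacement; no integration of instantaneous fields);
    ``mode="previous_frame"`` correlates consecutive pairs (instantaneous).
    Frames whose median valid-vector quality falls below
    ``decorrelation_quality`` are flagged in their metadata.
    """
    if mode not in ("first_frame", "previous_frame"):
        raise ValueError("mode must be 'first_frame' or 'previous_frame'")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    fields = []
    for t in range(1, stack.n_frames):
        ref = stack[0] if mode == "first_frame" else stack[t - 1]
        f = piv_displacement(ref, stack[t], pixel_size=stack.pixel_size, **piv_kwargs)
        f.reference = mode
        f.frame = t
        med_q = float(np.median(f.quality[f.mask])) if f.mask.any() else 0.0
        if med_q < decorrelation_quality:
            f.metadata["decorrelated"] = True
            log.warning("frame %d: median correlation quality %.2f below %.2f",
                        t, med_q, decorrelation_quality)
        fields.append(f)
    return fields


# --------------------------------------------------------------------------
# Drift correction
# --------------------------------------------------------------------------
def drift_correct(
    field: DisplacementField, stress_free_region: tuple[float, float, float, float]
) -> DisplacementField:
    """Subtract rigid stage drift estimated from a stress-free region.

    ``stress_free_region`` is ``(x0, y0, x1, y1)`` in µm, far from the colony.
    The drift is the mean displacement vector over valid vectors inside the
    region; it is subtracted everywhere and recorded in
    ``metadata["drift_um"]``.

    Raises
    ------
    ValueError
        If the region contains fewer than 4 valid vectors.
    """
    x0, y0, x1, y1 = stress_free_region
    X, Y = np.meshgrid(field.x, field.y)
    sel = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1) & field.mask
    if sel.sum() < 4:
        raise ValueError(
            f"stress-free region contains {int(sel.sum())} valid vectors; need >= 4"
        )
    drift = np.array([np.mean(field.u[sel]), np.mean(field.v[sel])])
    out = replace(
        field,
        u=field.u - drift[0],
        v=field.v - drift[1],
        metadata={**field.metadata, "drift_um": (float(drift[0]), float(drift[1]))},
    )
    return out


# --------------------------------------------------------------------------
# Divergence
# --------------------------------------------------------------------------
def divergence(field: DisplacementField, window_min: float | None = None) -> DivergenceField:
    """∂u_x/∂x + ∂u_y/∂y on the PIV grid, unitless (µm per µm).

    Central differences on interior nodes, one-sided at grid edges (flagged
    as boundary nodes, together with nodes adjacent to masked vectors).
    Masked vectors are filled by linear interpolation before differencing.

    Raises
    ------
    ValueError
        If fewer than a 3×3 block of valid interior vectors is available.
    """
    ny, nx = field.u.shape
    if ny < 3 or nx < 3 or field.mask.sum() < 9:
        raise ValueError("divergence needs at least a 3x3 grid of valid vectors")
    u, v = field.u.copy(), field.v.copy()
    invalid = ~field.mask
    if invalid.any():
        X, Y = np.meshgrid(field.x, field.y)
        pts = np.column_stack([X[field.mask], Y[field.mask]])
        for comp in (u, v):
            vals = comp[field.mask]
            filled = interpolate.griddata(pts, vals, (X, Y), method="linear")
            nn = interpolate.griddata(pts, vals, (X, Y), method="nearest")
            filled = np.where(np.isnan(filled), nn, filled)
            comp[invalid] = filled[invalid]
    dudx = np.gradient(u, field.x, axis=1)
    dvdy = np.gradient(v, field.y, axis=0)
    div = dudx + dvdy
    boundary = np.zeros_like(div, dtype=bool)
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    if invalid.any():
        grow = np.zeros_like(boundary)
        grow[invalid] = True
        grow[1:, :] |= invalid[:-1, :]
        grow[:-1, :] |= invalid[1:, :]
        grow[:, 1:] |= invalid[:, :-1]
        grow[:, :-1] |= invalid[:, 1:]
        boundary |= grow
    return DivergenceField(field.x, field.y, div, boundary, frame=field.frame,
                           window_min=window_min)


def divergence_wave_profile(
    div_fields: list[DivergenceField],
    edges: list[tuple[np.ndarray, float]],
    bin_width: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Azimuthally averaged divergence vs. signed distance from the colony edge.

    ``edges`` gives, per frame, the colony front as ``(center_um, radius_um)``
    (e.g. from arc fits converted to µm).  Every grid node is assigned the
    signed distance ``|x − c| − R`` (positive outside the colony) and the
    divergence is averaged in radial bins of width ``bin_width`` (default: one
    grid spacing).

    Returns
    -------
    profiles, peaks
        ``profiles``: long table (frame, distance_um, mean_div, n_nodes).
        ``peaks``: per frame, the bin of maximum |mean divergence|
        (frame, peak_distance_um, peak_div).
    """
    if len(div_fields) != len(edges):
        raise ValueError("need one (center, radius) per divergence field")
    rows, peak_rows = [], []
    for f, (center, radius) in zip(div_fields, edges):
        dx = float(f.x[1] - f.x[0])
        bw = bin_width if bin_width is not None else dx
        X, Y = np.meshgrid(f.x, f.y)
        dist = np.hypot(X - center[0], Y - center[1]) - radius
        ok = np.isfinite(f.div)
        d, val = dist[ok], f.div[ok]
        bins = np.arange(d.min() - bw, d.max() + 2 * bw, bw)
        idx = np.digitize(d, bins)
        for b in np.unique(idx):
            sel = idx == b
            rows.append({
                "frame": f.frame,
                "distance_um": bins[b - 1] + bw / 2.0,
                "mean_div": float(np.mean(val[sel])),
                "n_nodes": int(sel.sum()),
            })
        sub = [r for r in rows if r["frame"] == f.frame and r["n_nodes"] >= 4]
        if sub:
            pk = max(sub, key=lambda r: abs(r["mean_div"]))
            peak_rows.append({"frame": f.frame, "peak_distance_um": pk["distance_um"],
                              "peak_div": pk["mean_div"]})
    return pd.DataFrame(rows), pd.DataFrame(peak_rows)
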