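"""Elastostatic traction reconstruction on a linear elastic substrate.

The gel is modeled as a linear elastic half-space: its thickness (0.8–1 mm)
is orders of magnitude larger than both the observed displacements (µm scale)
and the PIV grid spacing, so the surface response to tangential traction is
the Boussinesq–Cerruti Green tensor, applied as a convolution.  In the
Fourier domain the tensor is, for wavevector k = (k_x, k_y), Young's modulus
E = 2G′(1+ν) and Poisson ratio ν,

    Ĝ(k) = 1/(G′ k³) · [[(1−ν)k² + ν·k_y²,  −ν·k_x·k_y],
                        [−ν·k_x·k_y,  (1−ν)k² + ν·k_x²]]

so forward displacement is û = Ĝ τ̂ and reconstruction solves the
Tikhonov-regularized normal equations (ĜᵀĜ + λI) τ̂ = Ĝᵀ û per wavevector.
The forward operator doubles as the independent oracle for round-trip tests.

Tractions are assumed tangential to the surface (the working assumption of
the measurement); normal components are out of scope.  Surface shear strain
follows the constitutive relation τ = G′ ε.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate

from .piv import DisplacementField

__all__ = [
    "SubstrateSpec",
    "TractionField",
    "forward_displacement",
    "reconstruct_traction",
    "stress_summary",
    "strain_from_stress",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstrateSpec:
    """Linear elastic substrate parameters.

    ``shear_modulus`` is the storage modulus G′ in Pa from rheometry;
    ``loss_modulus`` is carried as metadata only (the reconstruction assumes
    a purely elastic gel).  ``poisson_ratio`` defaults to 0.5 (incompressible
    hydrogel).  ``thickness_um`` matters only when the finite-thickness
    correction is enabled.
    """

    shear_modulus: float  # G', Pa
    poisson_ratio: float = 0.5
    thickness_um: float = 1000.0
    loss_modulus: float | None = None  # G'', Pa; metadata only

    def __post_init__(self) -> None:
        if self.shear_modulus <= 0:
            raise ValueError("shear_modulus must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.thickness_um <= 0:
            raise ValueError("thickness must be positive")

    @property
    def youngs_modulus(self) -> float:
        """E = 2G′(1+ν), Pa."""
        return 2.0 * self.shear_modulus * (1.0 + self.poisson_ratio)


@dataclass
class TractionField:
    """Tangential surface stress field in Pa on a regular grid."""

    x: np.ndarray  # (nx,) µm
    y: np.ndarray  # (ny,) µm
    tx: np.ndarray  # (ny, nx) Pa
    ty: np.ndarray  # (ny, nx) Pa
    reg: float  # regularization actually used (relative units)
    reference: str = "accumulated"
    frame: int = 0
    substrate: SubstrateSpec | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        """|τ| in Pa, nodewise."""
        return np.hypot(self.tx, self.ty)

    def to_frame(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.x, self.y)
        return pd.DataFrame({
            "frame": self.frame, "x_um": X.ravel(), "y_um": Y.ravel(),
            "tx_Pa": self.tx.ravel(), "ty_Pa": self.ty.ravel(),
            "tmag_Pa": self.magnitude.ravel(),
        })


# --------------------------------------------------------------------------
# Green tensor
# --------------------------------------------------------------------------
def _green_tensor(shape: tuple[int, int], spacing: tuple[float, float],
                  substrate: SubstrateSpec, finite_thickness: bool):
    """Fourier-domain Boussinesq tensor components (Gxx, Gxy, Gyy), µm/Pa.

    The k = 0 mode is set to zero (mean displacement/traction is not
    constrained by the half-space problem; fields are treated as zero-mean).
    With ``finite_thickness`` the tensor is damped by ``1 − (1 + 2kh)e^{−2kh}``
    — an interpolation that suppresses response at wavelengths exceeding the
    gel thickness h (rigidly bonded base) and reduces to the half-space for
    kh ≫ 1.
    """
    ny, nx = shape
    dx, dy = spacing
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=dy)
    KX, KY = np.meshgrid(kx, ky)
    k = np.hypot(KX, KY)
    k_safe = np.where(k == 0, 1.0, k)
    nu, G = substrate.poisson_ratio, substrate.shear_modulus
    pref = 1.0 / (G * k_safe**3)
    Gxx = pref * ((1 - nu) * k**2 + nu * KY**2)
    Gyy = pref * ((1 - nu) * k**2 + nu * KX**2)
    Gxy = pref * (-nu * KX * KY)
    if finite_thickness:
        h = substrate.thickness_um
        damp = 1.0 - (1.0 + 2 * k * h) * np.exp(-2 * k * h)
        Gxx, Gxy, Gyy = Gxx * damp, Gxy * damp, Gyy * damp
    Gxx[k == 0] = Gyy[k == 0] = Gxy[k == 0] = 0.0
    return Gxx, Gxy, Gyy


def _padded_fft2(a: np.ndarray, pad: int):
    ny, nx = a.shape
    out = np.zeros((ny * pad, nx * pad))
    out[:ny, :nx] = a
    return np.fft.fft2(out)


# --------------------------------------------------------------------------
# Forward problem
# --------------------------------------------------------------------------
def forward_displacement(
    traction: TractionField,
    substrate: SubstrateSpec,
    pad_factor: int = 1,
    finite_thickness: bool = False,
) -> DisplacementField:
    """Surface displacement (µm) generated by a tangential traction field.

    Spectral convolution of the half-space Green tensor with the traction.
    The default ``pad_factor=1`` treats the grid as periodic (the standard
    Fourier traction-cytometry convention, and the exact inverse of
    :func:`reconstruct_traction` on the same grid); ``pad_factor>1``
    zero-pads to suppress periodic wrap when simulating an isolated patch.
    Linear in the traction and ∝ 1/G′.
    """
    ny, nx = traction.tx.shape
    if ny < 4 or nx < 4:
        raise ValueError("traction grid too small for the convolution support")
    dx = float(traction.x[1] - traction.x[0])
    dy = float(traction.y[1] - traction.y[0])
    shape = (ny * pad_factor, nx * pad_factor)
    Gxx, Gxy, Gyy = _green_tensor(shape, (dx, dy), substrate, finite_thickness)
    tx_hat = _padded_fft2(traction.tx, pad_factor)
    ty_hat = _padded_fft2(traction.ty, pad_factor)
    ux = np.real(np.fft.ifft2(Gxx * tx_hat + Gxy * ty_hat))[:ny, :nx]
    uy = np.real(np.fft.ifft2(Gxy * tx_hat + Gyy * ty_hat))[:ny, :nx]
    return DisplacementField(
        x=traction.x, y=traction.y, u=ux, v=uy,
        quality=np.full((ny, nx), np.inf), mask=np.ones((ny, nx), dtype=bool),
        reference="first_frame" if traction.reference == "accumulated" else "previous_frame",
        frame=traction.frame, pixel_size=dx,
        metadata={"synthetic": "forward elastostatic solution"},
    )


# --------------------------------------------------------------------------
# Inverse problem
# --------------------------------------------------------------------------
def _solve_tikhonov(ux_hat, uy_hat, Gxx, Gxy, Gyy, lam_abs):
    """Per-wavevector regularized 2x2 solve of (GᵀG + λI) τ̂ = Gᵀ û."""
    # normal-equation entries (G is symmetric here)
    A11 = Gxx * Gxx + Gxy * Gxy + lam_abs
    A12 = Gxy * (Gxx + Gyy)
    A22 = Gyy * Gyy + Gxy * Gxy + lam_abs
    b1 = Gxx * ux_hat + Gxy * uy_hat
    b2 = Gxy * ux_hat + Gyy * uy_hat
    det = A11 * A22 - A12 * A12
    det = np.where(det == 0, 1.0, det)
    tx_hat = (A22 * b1 - A12 * b2) / det
    ty_hat = (A11 * b2 - A12 * b1) / det
    return tx_hat, ty_hat


def _lcurve_corner(regs, rho, eta):
    """Index of maximum curvature of the L-curve in log–log coordinates.

    Points where the curve is nearly stationary (below 10% of the peak
    parametric speed) are excluded: numerical curvature is meaningless there.
    """
    lr, le = np.log10(rho), np.log10(eta)
    t = np.log10(regs)
    d1r, d1e = np.gradient(lr, t), np.gradient(le, t)
    d2r, d2e = np.gradient(d1r, t), np.gradient(d1e, t)
    speed2 = d1r**2 + d1e**2
    curv = (d1r * d2e - d2r * d1e) / np.where(speed2 > 0, speed2**1.5, np.inf)
    curv = np.where(np.sqrt(speed2) > 0.1 * np.sqrt(speed2.max()), curv, -np.inf)
    return int(np.argmax(curv))


def reconstruct_traction(
    field: DisplacementField,
    substrate: SubstrateSpec,
    reg: float | str = "auto",
    pad_factor: int = 1,
    finite_thickness: bool = False,
    masked: str = "interpolate",
    reference: str | None = None,
) -> TractionField:
    """Tangential traction (Pa) that best explains a displacement field.

    Minimizes ‖forward(τ) − u‖² + λ‖τ‖² per Fourier mode.  ``reg`` is the
    regularization weight *relative to the squared operator norm* (so results
    are comparable across grids and moduli).  ``reg="auto"`` selects it by
    generalized cross-validation over a log-spaced scan (smooth and stable on
    gradual trade-off curves); ``reg="lcurve"`` uses the maximum-curvature
    corner of the L-curve instead.  The choice is recorded on the result.
    Masked vectors are linearly interpolated (``masked="interpolate"``) or
    rejected (``masked="error"``).

    The k = 0 (net force) mode is outside the model space: reconstructed
    tractions are force-balanced, and displacement fields are treated as
    mean-free (drift correction already enforces this in the pipeline).

    Raises
    ------
    ValueError
        For negative ``reg``, an unusable mask policy, or a field too small
        or too incomplete to invert.
    """
    if isinstance(reg, (int, float)) and reg < 0:
        raise ValueError("reg must be non-negative")
    ny, nx = field.u.shape
    if ny < 4 or nx < 4:
        raise ValueError("displacement grid too small to invert")
    u, v = field.u.copy(), field.v.copy()
    if not field.mask.all():
        if masked == "error":
            raise ValueError("displacement field contains masked vectors")
        X, Y = np.meshgrid(field.x, field.y)
        pts = np.column_stack([X[field.mask], Y[field.mask]])
        if len(pts) < 9:
            raise ValueError("too few valid vectors to interpolate")
        for comp in (u, v):
            vals = comp[field.mask]
            fill = interpolate.griddata(pts, vals, (X, Y), method="linear")
            nn = interpolate.griddata(pts, vals, (X, Y), method="nearest")
            fill = np.where(np.isnan(fill), nn, fill)
            comp[~field.mask] = fill[~field.mask]
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("displacement field contains non-finite values")

    dx, dy = field.spacing
    shape = (ny * pad_factor, nx * pad_factor)
    Gxx, Gxy, Gyy = _green_tensor(shape, (dx, dy), substrate, finite_thickness)
    ux_hat = _padded_fft2(u, pad_factor)
    uy_hat = _padded_fft2(v, pad_factor)
    # operator norm scale: largest eigenvalue magnitude of Ĝ over k
    eig_max = np.max(np.maximum(np.abs(Gxx), np.abs(Gyy)) + np.abs(Gxy))  # Gershgorin bound
    norm2 = eig_max**2

    def solve(rel_reg):
        tx_hat, ty_hat = _solve_tikhonov(ux_hat, uy_hat, Gxx, Gxy, Gyy, rel_reg * norm2)
        tx = np.real(np.fft.ifft2(tx_hat))[:ny, :nx]
        ty = np.real(np.fft.ifft2(ty_hat))[:ny, :nx]
        return tx, ty, tx_hat, ty_hat

    if reg in ("auto", "lcurve"):
        # eigenvalues of the symmetric 2x2 Green tensor at each wavevector,
        # for the GCV effective-degrees-of-freedom term
        half_tr = 0.5 * (Gxx + Gyy)
        disc = np.sqrt(np.maximum(half_tr**2 - (Gxx * Gyy - Gxy**2), 0.0))
        s1, s2 = half_tr + disc, half_tr - disc
        regs = np.logspace(-8, 0, 33)
        rho = np.empty_like(regs)
        eta = np.empty_like(regs)
        gcv = np.empty_like(regs)
        for i, r in enumerate(regs):
            lam = r * norm2
            tx_hat, ty_hat = _solve_tikhonov(ux_hat, uy_hat, Gxx, Gxy, Gyy, lam)
            res_x = Gxx * tx_hat + Gxy * ty_hat - ux_hat
            res_y = Gxy * tx_hat + Gyy * ty_hat - uy_hat
            rss = np.sum(np.abs(res_x) ** 2 + np.abs(res_y) ** 2)
            rho[i] = np.sqrt(rss) + 1e-300
            eta[i] = np.sqrt(np.sum(np.abs(tx_hat) ** 2 + np.abs(ty_hat) ** 2)) + 1e-300
            dof = np.sum(lam / (s1**2 + lam)) + np.sum(lam / (s2**2 + lam))
            gcv[i] = rss / dof**2 if dof > 0 else np.inf
        if reg == "auto":
            chosen = float(regs[int(np.argmin(gcv))])
            log.info("GCV selected relative regularization %.3g", chosen)
        else:
            chosen = float(regs[_lcurve_corner(regs, rho, eta)])
            log.info("L-curve selected relative regularization %.3g", chosen)
    else:
        chosen = float(reg)

    tx, ty, _, _ = solve(chosen)
    if not (np.all(np.isfinite(tx)) and np.all(np.isfinite(ty))):
        raise ArithmeticError("traction reconstruction produced non-finite values")
    ref = reference or ("accumulated" if field.reference == "first_frame" else "instantaneous")
    return TractionField(
        x=np.asarray(field.x, dtype=float), y=np.asarray(field.y, dtype=float),
        tx=tx, ty=ty, reg=chosen, reference=ref, frame=field.frame,
        substrate=substrate,
        metadata={"pad_factor": pad_factor, "finite_thickness": finite_thickness},
    )


# --------------------------------------------------------------------------
# Summaries and strain
# --------------------------------------------------------------------------
def stress_summary(
    traction_fields: list[TractionField],
    masks: list[np.ndarray] | None = None,
    times_h: list[float] | None = None,
    whiskers: str = "minmax",
) -> pd.DataFrame:
    """Box–whisker statistics of |τ| over stress-map nodes, per timepoint.

    ``masks`` optionally restricts each field to an analysis region (boolean
    per node); ``whiskers`` is ``"minmax"`` or ``"tukey"`` (1.5·IQR, clipped
    to the data range).  Returns columns
    (time_h, q1_Pa, median_Pa, q3_Pa, whisker_lo_Pa, whisker_hi_Pa, mean_Pa, n).
    """
    if not traction_fields:
        raise ValueError("traction series is empty")
    if whiskers not in ("minmax", "tukey"):
        raise ValueError("whiskers must be 'minmax' or 'tukey'")
    rows = []
    for i, tf in enumerate(traction_fields):
        mag = tf.magnitude
        if masks is not None:
            sel = np.asarray(masks[i], dtype=bool)
            if not sel.any():
                raise ValueError(f"empty analysis region for field {i}")
            mag = mag[sel]
        mag = mag.ravel()
        q1, med, q3 = np.percentile(mag, [25, 50, 75])
        if whiskers == "minmax":
            lo, hi = float(mag.min()), float(mag.max())
        else:
            iqr = q3 - q1
            lo = float(mag[mag >= q1 - 1.5 * iqr].min())
            hi = float(mag[mag <= q3 + 1.5 * iqr].max())
        rows.append({
            "time_h": times_h[i] if times_h is not None else tf.frame,
            "q1_Pa": float(q1), "median_Pa": float(med), "q3_Pa": float(q3),
            "whisker_lo_Pa": lo, "whisker_hi_Pa": hi,
            "mean_Pa": float(mag.mean()), "n": int(mag.size),
        })
    return pd.DataFrame(rows)


def strain_from_stress(tau, substrate: SubstrateSpec):
    """Surface shear strain from the constitutive relation τ = G′ε, i.e. ε = τ/G′.

    Accepts a scalar, array, or :class:`TractionField` magnitude; returns the
    unitless strain with the same shape.
    """
    if isinstance(tau, TractionField):
        tau = tau.magnitude
    return np.asarray(tau, dtype=float) / substrate.shear_modulus
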