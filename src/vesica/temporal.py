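"""Time dependence of voiding: alpha(t) from the real-time area curve,
geometry interpolation, and volume/flow-rate curves.

During voiding the mid-sagittal bladder cross-sectional area A(t) measured by
real-time imaging falls sigmoidally from A(t0) to A(tend). Under the radial
separable wall-motion model the dimensionless time-dependence is

    alpha(t) = sqrt( (A(t) - A(t0)) / (A(tend) - A(t0)) ),

which runs from 0 at the start of voiding to 1 at the end. The canonical
parametric form used when no real-time curve exists is the square root of a
raised cosine,

    alpha(t) = sqrt( (1 - cos(pi * tau)) / 2 ) = sin(pi * tau / 2),
    tau = (t - t0) / (tend - t0),

whose induced area curve A = A0 + (Aend - A0) * alpha^2 is exactly the
sigmoidal raised cosine seen in real-time imaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .displacement import DisplacementField, SphericalFrame
from .mesh import SurfaceMesh, mesh_volume

__all__ = [
    "AreaCurve",
    "AlphaCurve",
    "VoidingKinematics",
    "detect_void_window",
    "alpha_from_area",
    "alpha_sqrt_cosine",
    "fit_sqrt_cosine",
    "interpolate_geometry",
    "volume_and_flow",
]


@dataclass
class AreaCurve:
    """Bladder mid-sagittal cross-sectional area A(t): times in s, areas in
    mm^2, strictly increasing times."""

    t: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float).ravel()
        self.A = np.asarray(self.A, float).ravel()
        if len(self.t) != len(self.A):
            raise ValueError("t and A must have the same length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.A < 0):
            raise ValueError("areas must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "AreaCurve":
        df = pd.read_csv(path)
        if not {"time_s", "area_mm2"} <= set(df.columns):
            raise ValueError("area CSV needs columns time_s, area_mm2")
        return cls(df["time_s"].to_numpy(), df["area_mm2"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "area_mm2": self.A}).to_csv(path, index=False)


@dataclass
class AlphaCurve:
    """Dimensionless voiding time-dependence alpha(t), clipped to [0, 1]."""

    t: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float).ravel()
        self.alpha = np.asarray(self.alpha, float).ravel()
        if len(self.t) != len(self.alpha):
            raise ValueError("t and alpha must have the same length")
        if np.any((self.alpha < -1e-12) | (self.alpha > 1 + 1e-12)):
            raise ValueError("alpha must lie in [0, 1]")

    def at(self, t) -> np.ndarray:
        return np.interp(t, self.t, self.alpha)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "alpha": self.alpha}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# smoothing / noise estimation
# ---------------------------------------------------------------------------

def moving_average(y: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average with shrinking windows at the ends."""
    if window <= 1:
        return np.asarray(y, float).copy()
    y = np.asarray(y, float)
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def estimate_noise_sd(A: np.ndarray) -> float:
    """Robust noise estimate from second differences (a smooth trend has tiny
    second differences relative to i.i.d. noise): sd ~ MAD(diff2) / (0.6745 *
    sqrt(6))."""
    A = np.asarray(A, float)
    if len(A) < 3:
        return 0.0
    d2 = np.diff(A, n=2)
    return float(np.median(np.abs(d2 - np.median(d2))) / (0.6745 * np.sqrt(6.0)))


def _looks_noisy(A: np.ndarray) -> bool:
    """Smoothness diagnostic: for i.i.d. noise the third differences are
    ~1.8x the second differences (sd ratio sqrt(20/6)), while for a smooth
    trend they are smaller by a factor of the sample spacing. The moving
    average is only worth its bias when noise dominates the curvature."""
    A = np.asarray(A, float)
    if len(A) < 5:
        return False
    d2 = np.median(np.abs(np.diff(A, n=2)))
    d3 = np.median(np.abs(np.diff(A, n=3)))
    return d2 > 0 and d3 > 1.0 * d2


def _smoothed(curve: AreaCurve, window: int) -> np.ndarray:
    """Noise-adaptive smoothing: apply the moving average only when the curve
    actually carries noise; an already-smooth curve passes through untouched
    so the analytic alpha round trip is exact."""
    if np.ptp(curve.A) == 0 or not _looks_noisy(curve.A):
        return curve.A.copy()
    return moving_average(curve.A, window)


# ---------------------------------------------------------------------------
# voiding window and alpha
# ---------------------------------------------------------------------------

def detect_void_window(curve: AreaCurve, rel_threshold: float = 0.01,
                       smooth_window: int = 5, refine: bool = True) -> tuple[float, float]:
    """Locate the voiding event on the (smoothed) area curve.

    Coarse stage: t0 is the last sample before the area first drops below
    A_start - 1 % of the total change; tend is the first sample where the
    area reaches A_end + 1 % of the total change. On a sigmoidal curve the
    threshold crossings lag the true endpoints by ~(2/pi) asin(sqrt(0.01))
    of the voiding duration (the area changes slowest exactly there), so by
    default the coarse window seeds a least-squares fit of the raised-cosine
    area model, which recovers the endpoints to sample precision
    (``refine=False`` returns the bare threshold crossings).
    """
    if len(curve.t) < 8:
        raise ValueError("need at least 8 samples to locate the voiding window")
    A_s = _smoothed(curve, smooth_window)
    A_start, A_end = A_s[0], A_s[-1]
    total = A_start - A_end
    noise = estimate_noise_sd(curve.A)
    if total <= 0 or total <= 10 * noise:
        raise ValueError("no monotone area drop found (constant or noise-dominated curve)")
    below = np.nonzero(A_s < A_start - rel_threshold * total)[0]
    if len(below) == 0:
        raise ValueError("area never drops below the start threshold")
    i0 = max(below[0] - 1, 0)
    reached = np.nonzero(A_s <= A_end + rel_threshold * total)[0]
    j = reached[reached > i0]
    if len(j) == 0:
        raise ValueError("area never reaches the end threshold")
    t0, tend = float(curve.t[i0]), float(curve.t[j[0]])
    if not refine:
        return t0, tend

    # widen the coarse window by its intrinsic threshold lag and fit
    # A(t) = A0 + (Aend - A0) sin^2(pi (t - t0) / (2 T)) for (t0, T)
    lag = (2.0 / np.pi) * np.arcsin(np.sqrt(rel_threshold)) * (tend - t0) * 2.0
    lo = max(t0 - lag, float(curve.t[0]))
    hi = min(tend + lag, float(curve.t[-1]))

    def model(t, t0m, Tm):
        tau = np.clip((t - t0m) / Tm, 0.0, 1.0)
        return A_start + (A_end - A_start) * np.sin(np.pi * tau / 2.0) ** 2

    def residuals(p):
        return model(curve.t, p[0], np.exp(p[1])) - A_s

    result = least_squares(residuals, x0=[lo, np.log(max(hi - lo, 1e-6))],
                           method="lm")
    if result.success:
        t0_fit = float(result.x[0])
        tend_fit = float(t0_fit + np.exp(result.x[1]))
        slack = 0.02 * (tend_fit - t0_fit)
        inside = (curve.t[0] - slack <= t0_fit < tend_fit <= curve.t[-1] + slack)
        if inside:
            return (max(t0_fit, float(curve.t[0])),
                    min(tend_fit, float(curve.t[-1])))
    return t0, tend


def alpha_from_area(curve: AreaCurve, t0: float, tend: float,
                    smooth_window: int = 5) -> AlphaCurve:
    """alpha(t) = sqrt((A(t) - A(t0)) / (A(tend) - A(t0))) on the smoothed
    curve; the square root amplifies noise near t0, so negative pre-sqrt
    ratios are clipped to 0 and ratios above 1 to 1."""
    A_s = _smoothed(curve, smooth_window)
    A0 = float(np.interp(t0, curve.t, A_s))
    A1 = float(np.interp(tend, curve.t, A_s))
    if A1 == A0:
        raise ValueError("A(tend) equals A(t0); alpha is undefined")
    ratio = (A_s - A0) / (A1 - A0)
    return AlphaCurve(curve.t, np.sqrt(np.clip(ratio, 0.0, 1.0)))


def alpha_sqrt_cosine(t, t0: float, tend: float):
    """Canonical square-root-of-cosine time dependence,
    alpha = sqrt((1 - cos(pi tau)) / 2); endpoints 0 and 1 exactly. Times
    outside [t0, tend] are clamped with a warning."""
    if tend <= t0:
        raise ValueError("tend must exceed t0")
    t = np.asarray(t, float)
    tau = (t - t0) / (tend - t0)
    if np.any((tau < -1e-12) | (tau > 1 + 1e-12)):
        warnings.warn("times outside [t0, tend] clamped in alpha_sqrt_cosine")
    tau = np.clip(tau, 0.0, 1.0)
    return np.sqrt((1.0 - np.cos(np.pi * tau)) / 2.0)


class SqrtCosineFit(NamedTuple):
    t0: float
    tend: float
    rmse: float


def fit_sqrt_cosine(alpha_curve: AlphaCurve) -> SqrtCosineFit:
    """Least-squares fit of (t0, tend) of the square-root-of-cosine form to a
    measured alpha curve."""
    t, a = alpha_curve.t, alpha_curve.alpha
    if len(t) < 8:
        raise ValueError("need at least 8 samples to fit the two time parameters")
    # initial guess from the 5 % / 95 % crossings
    lo = t[np.argmax(a > 0.05)] if np.any(a > 0.05) else t[0]
    hi = t[np.argmax(a > 0.95)] if np.any(a > 0.95) else t[-1]
    span = max(hi - lo, (t[-1] - t[0]) * 0.1)

    def residuals(p):
        t0, log_T = p
        return alpha_sqrt_cosine_noclamp(t, t0, t0 + np.exp(log_T)) - a

    def alpha_sqrt_cosine_noclamp(tt, t0, tend):
        tau = np.clip((tt - t0) / (tend - t0), 0.0, 1.0)
        return np.sqrt((1.0 - np.cos(np.pi * tau)) / 2.0)

    result = least_squares(residuals, x0=[lo, np.log(span)], method="lm")
    if not result.success:
        raise RuntimeError(f"sqrt-cosine fit did not converge: {result.message}")
    t0_fit = float(result.x[0])
    tend_fit = float(t0_fit + np.exp(result.x[1]))
    rmse = float(np.sqrt(np.mean(result.fun**2)))
    return SqrtCosineFit(t0_fit, tend_fit, rmse)


# ---------------------------------------------------------------------------
# geometry interpolation and kinematics
# ---------------------------------------------------------------------------

def interpolate_geometry(pre: SurfaceMesh, field: DisplacementField,
                         frame: SphericalFrame, alpha: float) -> SurfaceMesh:
    """Move every pre-void vertex radially toward the frame origin by
    d0 * alpha. Requires the field to be sampled on the pre-void vertices
    (sample i corresponds to vertex i); topology is unchanged."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if field.sampling != "pre_vertices":
        raise ValueError("geometry interpolation needs a pre_vertices-sampled field")
    if field.n_failed:
        raise ValueError("field dropped samples; vertex correspondence is broken")
    if field.n_samples != pre.n_vertices:
        raise ValueError("field sample count does not match pre-void vertex count")
    if alpha == 0.0:
        out = pre.copy()
        out.provenance = f"{pre.provenance} (alpha=0)"
        return out
    offsets = pre.vertices - frame.origin
    r = np.linalg.norm(offsets, axis=1)
    new_r = r - field.d0 * alpha
    if np.any(new_r <= 0):
        raise ValueError("interpolated radius would be non-positive at some vertex")
    vertices = frame.origin + offsets * (new_r / r)[:, None]
    return SurfaceMesh(vertices, pre.faces.copy(),
                       provenance=f"{pre.provenance} (alpha={alpha:g})")


@dataclass
class VoidingKinematics:
    """Interpolated voiding geometries with volume and flow-rate curves.

    ``V`` is the enclosed mesh volume (mm^3) at each time; ``Q = -dV/dt`` in
    mL/s by central differences. The source pre-void mesh, displacement field
    and frame are retained so meshes can be regenerated at arbitrary alpha.
    """

    times: np.ndarray
    alphas: np.ndarray
    V: np.ndarray
    Q: np.ndarray
    pre: SurfaceMesh
    field: DisplacementField
    frame: SphericalFrame

    def mesh_at(self, i: int) -> SurfaceMesh:
        return interpolate_geometry(self.pre, self.field, self.frame,
                                    float(self.alphas[i]))

    @property
    def voided_volume(self) -> float:
        """V(t_first) - V(t_last), mm^3."""
        return float(self.V[0] - self.V[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "alpha": self.alphas,
             "volume_mm3": self.V, "flow_mL_per_s": self.Q}
        )


def volume_and_flow(pre: SurfaceMesh, field: DisplacementField,
                    frame: SphericalFrame, alpha_curve: AlphaCurve) -> VoidingKinematics:
    """Volume curve V(t) from the interpolated geometries and voiding flow
    rate Q(t) = -dV/dt (central differences, one-sided at the ends)."""
    if np.any(np.diff(alpha_curve.alpha) < -1e-12):
        warnings.warn("alpha curve is not monotone non-decreasing; Q may be negative")
    alphas = np.clip(alpha_curve.alpha, 0.0, 1.0)
    V = np.array([
        mesh_volume(interpolate_geometry(pre, field, frame, float(a)))
        for a in alphas
    ])
    Q = -np.gradient(V, alpha_curve.t) / 1000.0  # mm^3/s -> mL/s
    return VoidingKinematics(times=alpha_curve.t.copy(), alphas=alphas, V=V, Q=Q,
                             pre=pre, field=field, frame=frame)
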