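"""Simplified 2D moving-boundary intravesical flow simulation.

The voiding flow is driven one-way by the prescribed radial wall motion of
the displacement model: a mid-plane slice of the interpolated bladder
geometries gives a star-shaped contour r(theta, t) = r_pre(theta) -
d0(theta) * alpha(t); a straight rigid urethra channel of diameter D and
length L is grafted at the inferior pole with an atmospheric (zero gauge
pressure) outlet. Incompressible Navier-Stokes is integrated with a
fractional-step (Chorin projection) scheme on a uniform staggered MAC grid:
explicit first-order upwind advection, implicit (backward Euler) diffusion,
and an exact discrete pressure projection, with the moving wall imposed as a
direct-forcing staircase immersed boundary (wall-adjacent faces carry the
local wall velocity; tangential wall values enter the diffusion stencil
through half-cell ghost mirroring, which keeps plane walls second-order
accurate).

Outputs are the velocity/pressure history plus the swirl metrics used to
compare voiding conditions: the bladder-averaged unsigned vorticity |omega|
(the sign-less average cannot cancel between counter-rotating lobes), its
dimensionless form mean|omega| * D / Ubar with Ubar the mean urethral flow
speed, and the recirculation fraction (share of the bladder where flow is
directed away from the outlet).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.linalg import splu
from shapely.geometry import Polygon, box as shapely_box

from .temporal import VoidingKinematics

__all__ = [
    "FluidProperties",
    "UrethraChannel",
    "PlaneSpec",
    "FlowDomain",
    "FlowSolution",
    "build_domain",
    "solve_voiding_flow",
    "simulate_channel_flow",
    "vorticity_field",
    "mean_vorticity",
    "dimensionless_vorticity",
    "recirculation_fraction",
    "recirculation_from_fields",
]


@dataclass
class FluidProperties:
    """Newtonian fluid; defaults are water at body temperature (urine is
    within a few percent of water)."""

    density: float = 1000.0       # kg/m^3
    viscosity: float = 0.0007     # Pa s

    @property
    def nu(self) -> float:
        """Kinematic viscosity in mm^2/s (solver units)."""
        return self.viscosity / self.density * 1e6


@dataclass
class UrethraChannel:
    """Rigid straight outlet channel: prostatic-urethra diameter D and
    channel length L, both mm."""

    diameter: float = 6.0
    length: float = 20.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("channel diameter and length must be positive")


@dataclass
class PlaneSpec:
    """Cutting plane through the frame origin (plus optional offset along the
    normal). ``normal``/``up`` name frame axes: sagittal = normal 'x'
    (in-plane axes anterior/posterior x superior/inferior); 'y' gives the
    coronal plane containing the left-right axis."""

    normal: str = "x"
    up: str = "z"
    offset: float = 0.0

    def vectors(self, frame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = {"x": frame.axes[0], "y": frame.axes[1], "z": frame.axes[2]}
        if self.normal not in axes or self.up not in axes or self.normal == self.up:
            raise ValueError("plane normal/up must be distinct frame axis names")
        n = axes[self.normal]
        e2 = axes[self.up]
        e1 = np.cross(e2, n)
        return n, e1 / np.linalg.norm(e1), e2


@dataclass
class FlowDomain:
    """Time-resolved 2D fluid domain: bladder contour radii R(t_k, theta)
    about the in-plane origin plus the grafted channel geometry."""

    theta: np.ndarray          # (ntheta,) uniform in [-pi, pi)
    times: np.ndarray          # (nt,)
    R: np.ndarray              # (nt, ntheta) contour radius, mm
    channel: UrethraChannel
    fluid: FluidProperties
    y_channel_top: float       # top of the rigid channel rectangle (mm)
    y_outlet: float            # outlet plane (mm)
    area: np.ndarray           # (nt,) analytic fluid area (bladder U channel)

    def __post_init__(self) -> None:
        if np.any(self.R <= 0):
            raise ValueError("contour radii must be positive")

    def _interp_row(self, t: float) -> np.ndarray:
        t = float(np.clip(t, self.times[0], self.times[-1]))
        k = int(np.searchsorted(self.times, t, side="right") - 1)
        k = min(max(k, 0), len(self.times) - 2)
        w = (t - self.times[k]) / (self.times[k + 1] - self.times[k])
        return (1 - w) * self.R[k] + w * self.R[k + 1]

    def radius_at(self, t: float, theta: np.ndarray) -> np.ndarray:
        """R(theta, t) with periodic interpolation in theta."""
        row = self._interp_row(t)
        return _periodic_interp(theta, self.theta, row)

    def wall_speed_at(self, t: float, theta: np.ndarray) -> np.ndarray:
        """dR/dt(theta, t) (negative while shrinking), piecewise-constant in
        time between contour snapshots."""
        k = int(np.searchsorted(self.times, np.clip(t, self.times[0], self.times[-1]),
                                side="right") - 1)
        k = min(max(k, 0), len(self.times) - 2)
        rate = (self.R[k + 1] - self.R[k]) / (self.times[k + 1] - self.times[k])
        return _periodic_interp(theta, self.theta, rate)

    def area_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.area)

    @property
    def outlet_point(self) -> np.ndarray:
        """Channel mouth (sink location for the recirculation metric)."""
        return np.array([0.0, self.y_channel_top])


def _periodic_interp(q: np.ndarray, theta: np.ndarray, values: np.ndarray) -> np.ndarray:
    q = np.mod(np.asarray(q, float) - theta[0], 2 * np.pi) + theta[0]
    te = np.concatenate([theta, [theta[0] + 2 * np.pi]])
    ve = np.concatenate([values, [values[0]]])
    return np.interp(q, te, ve)


# ---------------------------------------------------------------------------
# domain construction
# ---------------------------------------------------------------------------

def _slice_contour(mesh, frame, plane: PlaneSpec, theta_grid: np.ndarray) -> np.ndarray:
    """Mid-plane contour radii of one mesh on a uniform theta grid."""
    n, e1, e2 = plane.vectors(frame)
    origin = frame.origin + plane.offset * n
    segments = trimesh.intersections.mesh_plane(mesh.to_trimesh(), n, origin)
    if len(segments) < 4:
        raise ValueError("cutting plane misses (or is tangent to) the mesh")
    pts = segments.reshape(-1, 3) - origin
    x2, y2 = pts @ e1, pts @ e2
    th = np.arctan2(y2, x2)
    r = np.hypot(x2, y2)
    order = np.argsort(th)
    th, r = th[order], r[order]
    keep = np.concatenate([[True], np.diff(th) > 1e-12])
    th, r = th[keep], r[keep]
    return np.interp(
        np.mod(theta_grid - th[0], 2 * np.pi) + th[0],
        np.concatenate([th, [th[0] + 2 * np.pi]]),
        np.concatenate([r, [r[0]]]),
    )


def _contour_polygon(theta: np.ndarray, r: np.ndarray) -> Polygon:
    return Polygon(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


def build_domain(kinematics: VoidingKinematics, plane: PlaneSpec | None = None,
                 urethra: UrethraChannel | None = None,
                 fluid: FluidProperties | None = None,
                 n_theta: int = 360) -> FlowDomain:
    """Slice every interpolated voiding geometry with the chosen plane and
    graft the rigid outlet channel at the inferior pole.

    The channel rectangle spans x in [-D/2, D/2], from the outlet plane
    (initial neck position minus L) up to just inside the *final* bladder
    contour, so bladder and channel stay connected throughout voiding.
    """
    plane = plane or PlaneSpec()
    urethra = urethra or UrethraChannel()
    fluid = fluid or FluidProperties()

    theta = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    R = np.array([
        _slice_contour(kinematics.mesh_at(i), kinematics.frame, plane, theta)
        for i in range(len(kinematics.times))
    ])

    D, L = urethra.diameter, urethra.length
    r_bottom_first = float(_periodic_interp(np.array([-np.pi / 2]), theta, R[0])[0])
    r_bottom_last = float(_periodic_interp(np.array([-np.pi / 2]), theta, R[-1])[0])
    if D >= float(R[-1].min()):
        raise ValueError(
            f"channel diameter D={D} mm does not fit the bladder neck "
            f"(final minimum contour radius {R[-1].min():.1f} mm)"
        )
    y_top = -r_bottom_last + 0.1 * D
    y_outlet = -r_bottom_first - L

    channel_box = shapely_box(-D / 2, y_outlet, D / 2, y_top)
    area = np.array([
        _contour_polygon(theta, R[k]).union(channel_box).area
        for k in range(len(R))
    ])

    return FlowDomain(theta=theta, times=kinematics.times.copy(), R=R,
                      channel=urethra, fluid=fluid, y_channel_top=y_top,
                      y_outlet=y_outlet, area=area)


# ---------------------------------------------------------------------------
# staggered-grid solver
# ---------------------------------------------------------------------------

@dataclass
class Grid2D:
    x0: float
    y0: float
    h: float
    nx: int
    ny: int

    @property
    def xc(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.h

    @property
    def yc(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.h

    @property
    def xf(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx + 1) * self.h

    @property
    def yf(self) -> np.ndarray:
        return self.y0 + np.arange(self.ny + 1) * self.h


@dataclass
class Snapshot:
    t: float
    u: np.ndarray          # (nx+1, ny) x-velocity at x-faces, mm/s
    v: np.ndarray          # (nx, ny+1) y-velocity at y-faces, mm/s
    p: np.ndarray          # (nx, ny) pressure, Pa (NaN in solid)
    fluid: np.ndarray      # (nx, ny) fluid mask
    bladder: np.ndarray    # (nx, ny) bladder-region mask (channel excluded)


@dataclass
class FlowSolution:
    """Time-stepped solution: per-step metric series over the full run plus
    a subsampled list of full-field snapshots."""

    grid: Grid2D
    times: np.ndarray               # (nsteps,) end-of-step times
    dts: np.ndarray                 # (nsteps,)
    outlet_flux: np.ndarray         # (nsteps,) mm^2/s, positive out
    domain_area: np.ndarray         # (nsteps,) analytic fluid area, mm^2
    bladder_area: np.ndarray        # (nsteps,) bladder-region cell area, mm^2
    mean_abs_vorticity: np.ndarray  # (nsteps,) 1/s over the bladder region
    recirc_fraction: np.ndarray     # (nsteps,)
    max_divergence: np.ndarray      # (nsteps,) relative post-projection div
    snapshots: list[Snapshot]
    outlet_point: np.ndarray
    fluid: FluidProperties
    channel: UrethraChannel | None = None

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    @property
    def mean_outlet_flux(self) -> float:
        """Time-averaged outlet flux Q_mean (mm^2/s per unit depth)."""
        return float(np.sum(self.outlet_flux * self.dts) / np.sum(self.dts))

    @property
    def recirc_area(self) -> np.ndarray:
        """Per-step recirculated area (mm^2): the recirculation fraction
        scaled by the instantaneous bladder area. The area, not the
        fraction, is the right quantity for comparing the size of
        recirculation regions across runs whose bladders empty to very
        different residual sizes."""
        return self.recirc_fraction * self.bladder_area

    @property
    def mass_error(self) -> float:
        """Relative mismatch between the integrated outlet flux and the
        analytic fluid-area change (global mass conservation)."""
        out = float(np.sum(self.outlet_flux * self.dts))
        shrink = float(self.domain_area[0] - self.domain_area[-1])
        if shrink == 0:
            return abs(out)
        return abs(out - shrink) / abs(shrink)


class _Geometry:
    """Mask-dependent index sets and factorised operators for one wall
    configuration (rebuilt only when a cell changes phase)."""

    def __init__(self, grid: Grid2D, fluid_mask: np.ndarray,
                 open_bottom: np.ndarray, open_top: np.ndarray):
        self.grid = grid
        nx, ny = grid.nx, grid.ny
        self.fluid = fluid_mask
        self.open_bottom = open_bottom      # (nx,) bool, p-Dirichlet at y0
        self.open_top = open_top            # (nx,) bool, p-Dirichlet at y0+ny*h

        f = fluid_mask
        self.u_active = np.zeros((nx + 1, ny), bool)
        self.u_active[1:nx, :] = f[:-1, :] & f[1:, :]
        self.v_active = np.zeros((nx, ny + 1), bool)
        self.v_active[:, 1:ny] = f[:, :-1] & f[:, 1:]

        # open (pressure-BC) v-faces carry a full momentum equation: they are
        # Helmholtz unknowns with zero-gradient diffusion past the boundary
        # and the half-cell pressure gradient against the Dirichlet face value
        self.v_open = np.zeros((nx, ny + 1), bool)
        self.v_open[open_bottom & f[:, 0], 0] = True
        self.v_open[open_top & f[:, -1], ny] = True
        self.v_active |= self.v_open

        self.cell_id = -np.ones((nx, ny), np.int64)
        self.n_cells = int(f.sum())
        self.cell_id[f] = np.arange(self.n_cells)

        self._build_poisson()
        self.uface_id = -np.ones((nx + 1, ny), np.int64)
        self.n_u = int(self.u_active.sum())
        self.uface_id[self.u_active] = np.arange(self.n_u)
        self.vface_id = -np.ones((nx, ny + 1), np.int64)
        self.n_v = int(self.v_active.sum())
        self.vface_id[self.v_active] = np.arange(self.n_v)
        self._helmholtz_cache: dict[float, tuple] = {}

    # -- pressure Poisson -------------------------------------------------
    def _build_poisson(self):
        g = self.grid
        h2 = g.h * g.h
        cid = self.cell_id
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n_cells)

        # horizontal couplings through active u-faces
        act = self.u_active[1:-1, :]
        c1 = cid[:-1, :][act]
        c2 = cid[1:, :][act]
        rows += [c1, c2]
        cols += [c2, c1]
        vals += [np.full(len(c1), 1 / h2), np.full(len(c1), 1 / h2)]
        np.add.at(diag, c1, -1 / h2)
        np.add.at(diag, c2, -1 / h2)

        # vertical couplings through active v-faces
        act = self.v_active[:, 1:-1]
        c1 = cid[:, :-1][act]
        c2 = cid[:, 1:][act]
        rows += [c1, c2]
        cols += [c2, c1]
        vals += [np.full(len(c1), 1 / h2), np.full(len(c1), 1 / h2)]
        np.add.at(diag, c1, -1 / h2)
        np.add.at(diag, c2, -1 / h2)

        # pressure-Dirichlet open faces (half-cell to the face)
        self.open_bottom_cells = cid[:, 0][self.open_bottom & self.fluid[:, 0]]
        self.open_top_cells = cid[:, -1][self.open_top & self.fluid[:, -1]]
        np.add.at(diag, self.open_bottom_cells, -2 / h2)
        np.add.at(diag, self.open_top_cells, -2 / h2)

        self.pinned = len(self.open_bottom_cells) == 0 and len(self.open_top_cells) == 0

        rows.append(np.arange(self.n_cells))
        cols.append(np.arange(self.n_cells))
        vals.append(diag)
        A = sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_cells, self.n_cells),
        )
        if self.pinned:
            # all-Neumann problem: pin the first cell to fix the constant
            A = A.tolil()
            A[0, :] = 0.0
            A[0, 0] = 1.0
            A = A.tocsc()
        self._poisson_lu = splu(A)

    # -- velocity Helmholtz (implicit diffusion) --------------------------
    def _build_helmholtz(self, k_over_h2: float):
        """(I - nu dt lap) for u and v unknowns. Wall-normal Dirichlet
        neighbours couple at distance h (coefficient 1); wall-tangential
        neighbours at the half-cell ghost (coefficient 2). Out-of-grid
        neighbours are zero-gradient."""
        ops = []
        for comp in ("u", "v"):
            active = self.u_active if comp == "u" else self.v_active
            fid = self.uface_id if comp == "u" else self.vface_id
            n = self.n_u if comp == "u" else self.n_v
            shape = active.shape
            rows, cols, vals = [], [], []
            diag = np.ones(n)
            dir_rows, dir_src, dir_coef = [], [], []

            # (dx, dy, ghost coefficient): x-neighbours are wall-normal for
            # u (coef 1) and wall-tangential for v (coef 2); vice versa in y
            steps = (
                [(1, 0, 1.0), (-1, 0, 1.0), (0, 1, 2.0), (0, -1, 2.0)]
                if comp == "u"
                else [(1, 0, 2.0), (-1, 0, 2.0), (0, 1, 1.0), (0, -1, 1.0)]
            )
            idx = np.argwhere(active)
            me = fid[active]
            for dx, dy, coef in steps:
                ni, nj = idx[:, 0] + dx, idx[:, 1] + dy
                inside = (ni >= 0) & (ni < shape[0]) & (nj >= 0) & (nj < shape[1])
                nid = np.full(len(idx), -1, np.int64)
                nid[inside] = fid[ni[inside], nj[inside]]
                is_act = nid >= 0
                # active neighbour: standard coupling
                rows.append(me[is_act])
                cols.append(nid[is_act])
                vals.append(np.full(is_act.sum(), -k_over_h2))
                np.add.at(diag, me[is_act], k_over_h2)
                # Dirichlet neighbour (wall face / ghost)
                is_dir = inside & ~is_act
                np.add.at(diag, me[is_dir], coef * k_over_h2)
                dir_rows.append(me[is_dir])
                dir_src.append(np.ravel_multi_index((ni[is_dir], nj[is_dir]), shape))
                dir_coef.append(np.full(is_dir.sum(), coef * k_over_h2))
                # out-of-grid: zero-gradient, nothing to add

            rows.append(me)
            cols.append(me)
            vals.append(diag[me])
            A = sparse.csc_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, n),
            )
            ops.append(
                (splu(A), np.concatenate(dir_rows), np.concatenate(dir_src),
                 np.concatenate(dir_coef))
            )
        return ops

    def helmholtz(self, k_over_h2: float):
        key = round(float(k_over_h2), 14)
        if key not in self._helmholtz_cache:
            self._helmholtz_cache[key] = self._build_helmholtz(k_over_h2)
        return self._helmholtz_cache[key]


def _upwind_advection(u: np.ndarray, v: np.ndarray, h: float):
    """First-order upwind (u.grad)u and (u.grad)v on the MAC grid, using the
    currently prescribed values on wall faces as boundary data; edges are
    replicated (zero-gradient)."""
    up = np.pad(u, 1, mode="edge")
    vp = np.pad(v, 1, mode="edge")

    # --- u faces ---
    dudx_m = (up[1:-1, 1:-1] - up[:-2, 1:-1]) / h
    dudx_p = (up[2:, 1:-1] - up[1:-1, 1:-1]) / h
    dudy_m = (up[1:-1, 1:-1] - up[1:-1, :-2]) / h
    dudy_p = (up[1:-1, 2:] - up[1:-1, 1:-1]) / h
    # v averaged to u faces: surrounding four v faces
    vpad = np.pad(v, ((1, 1), (0, 0)), mode="edge")
    v_at_u = 0.25 * (vpad[:-1, :-1] + vpad[1:, :-1] + vpad[:-1, 1:] + vpad[1:, 1:])
    adv_u = (
        np.where(u > 0, u * dudx_m, u * dudx_p)
        + np.where(v_at_u > 0, v_at_u * dudy_m, v_at_u * dudy_p)
    )

    # --- v faces ---
    dvdx_m = (vp[1:-1, 1:-1] - vp[:-2, 1:-1]) / h
    dvdx_p = (vp[2:, 1:-1] - vp[1:-1, 1:-1]) / h
    dvdy_m = (vp[1:-1, 1:-1] - vp[1:-1, :-2]) / h
    dvdy_p = (vp[1:-1, 2:] - vp[1:-1, 1:-1]) / h
    upad = np.pad(u, ((0, 0), (1, 1)), mode="edge")
    u_at_v = 0.25 * (upad[:-1, :-1] + upad[1:, :-1] + upad[:-1, 1:] + upad[1:, 1:])
    adv_v = (
        np.where(u_at_v > 0, u_at_v * dvdx_m, u_at_v * dvdx_p)
        + np.where(v > 0, v * dvdy_m, v * dvdy_p)
    )
    return adv_u, adv_v


class _Stepper:
    """One projection step on a fixed grid with time-varying masks."""

    def __init__(self, grid: Grid2D, nu: float):
        self.grid = grid
        self.nu = nu
        self._geom: _Geometry | None = None
        self._mask_key = None

    def geometry(self, fluid_mask, open_bottom, open_top) -> _Geometry:
        key = fluid_mask.tobytes()
        if self._geom is None or key != self._mask_key:
            self._geom = _Geometry(self.grid, fluid_mask, open_bottom, open_top)
            self._mask_key = key
        return self._geom

    def step(self, u, v, phi, geom: _Geometry, Wu, Wv, dt,
             p_bottom: float = 0.0, p_top: float = 0.0):
        """Advance one dt with the incremental pressure-correction scheme:
        the predictor carries the accumulated kinematic pressure ``phi``
        (mm^2/s^2) and the projection solves for its increment, so the
        steady state is independent of dt (a plain non-incremental split
        leaves an O(nu dt / h^2) error at tangential walls).

        Returns (u, v, phi, max_rel_divergence).
        """
        g = self.grid
        h = g.h
        k_over_h2 = self.nu * dt / (h * h)

        # enforce wall values on every non-active face before gradients
        u = np.where(geom.u_active, u, Wu)
        v = np.where(geom.v_active, v, Wv)
        ob = geom.open_bottom & geom.fluid[:, 0]
        ot = geom.open_top & geom.fluid[:, -1]

        adv_u, adv_v = _upwind_advection(u, v, h)
        rhs_u_full = u - dt * adv_u
        rhs_v_full = v - dt * adv_v
        gradx = (phi[1:, :] - phi[:-1, :]) / h
        rhs_u_full[1:-1, :] -= dt * gradx
        grady = (phi[:, 1:] - phi[:, :-1]) / h
        rhs_v_full[:, 1:-1] -= dt * grady
        # open faces: half-cell gradient against the imposed face pressure
        rhs_v_full[ob, 0] -= dt * 2 * (phi[ob, 0] - p_bottom) / h
        rhs_v_full[ot, -1] -= dt * 2 * (p_top - phi[ot, -1]) / h

        (lu_u, dru, dsu, dcu), (lu_v, drv, dsv, dcv) = geom.helmholtz(k_over_h2)

        rhs = rhs_u_full[geom.u_active]
        np.add.at(rhs, dru, dcu * Wu.ravel()[dsu])
        u_star = u.copy()
        u_star[geom.u_active] = lu_u.solve(rhs)

        rhs = rhs_v_full[geom.v_active]
        np.add.at(rhs, drv, dcv * Wv.ravel()[dsv])
        v_star = v.copy()
        v_star[geom.v_active] = lu_v.solve(rhs)

        # pressure-increment projection (increment vanishes on open faces)
        div = (u_star[1:, :] - u_star[:-1, :] + v_star[:, 1:] - v_star[:, :-1]) / h
        rhs_p = div[geom.fluid] / dt
        if geom.pinned:
            rhs_p[0] = 0.0
        psi_vec = geom._poisson_lu.solve(rhs_p)
        psi = np.zeros((g.nx, g.ny))
        psi[geom.fluid] = psi_vec

        u_new, v_new = u_star, v_star
        iu = geom.u_active[1:-1, :]
        gpsi_x = (psi[1:, :] - psi[:-1, :]) / h
        u_new[1:-1, :][iu] -= dt * gpsi_x[iu]
        iv = geom.v_active[:, 1:-1]
        gpsi_y = (psi[:, 1:] - psi[:, :-1]) / h
        v_new[:, 1:-1][iv] -= dt * gpsi_y[iv]
        v_new[ob, 0] -= dt * 2 * psi[ob, 0] / h
        v_new[ot, -1] -= dt * 2 * (0.0 - psi[ot, -1]) / h

        phi_new = phi + psi

        div = (u_new[1:, :] - u_new[:-1, :] + v_new[:, 1:] - v_new[:, :-1]) / h
        vmax = max(np.abs(u_new).max(), np.abs(v_new).max(), 1e-30)
        max_div = float(np.abs(div[geom.fluid]).max() * h / vmax)
        return u_new, v_new, phi_new, max_div


# ---------------------------------------------------------------------------
# driven voiding simulation
# ---------------------------------------------------------------------------

def _masks_for(domain: FlowDomain, grid: Grid2D, t: float):
    """Fluid / bladder masks and wall-velocity face fields at time t."""
    D = domain.channel.diameter
    X, Y = np.meshgrid(grid.xc, grid.yc, indexing="ij")
    th = np.arctan2(Y, X)
    r = np.hypot(X, Y)
    Rth = domain.radius_at(t, th.ravel()).reshape(th.shape)
    in_bladder = r < Rth
    in_channel = (
        (np.abs(X) < D / 2)
        & (Y > domain.y_outlet - 1e-12)
        & (Y < domain.y_channel_top)
    )
    fluid = in_bladder | in_channel
    open_bottom = in_channel[:, 0]

    def wall_field(xg, yg):
        XX, YY = np.meshgrid(xg, yg, indexing="ij")
        thf = np.arctan2(YY, XX)
        rdot = domain.wall_speed_at(t, thf.ravel()).reshape(thf.shape)
        wu = rdot * np.cos(thf)
        wv = rdot * np.sin(thf)
        rigid = (np.abs(XX) < D / 2 + grid.h) & (YY < domain.y_channel_top)
        wu[rigid] = 0.0
        wv[rigid] = 0.0
        return wu, wv

    Wu, _ = wall_field(grid.xf, grid.yc)
    _, Wv = wall_field(grid.xc, grid.yf)
    return fluid, in_bladder, open_bottom, Wu, Wv


def _center_velocities(u: np.ndarray, v: np.ndarray):
    uc = 0.5 * (u[:-1, :] + u[1:, :])
    vc = 0.5 * (v[:, :-1] + v[:, 1:])
    return uc, vc


def _vorticity_centers(u: np.ndarray, v: np.ndarray, h: float) -> np.ndarray:
    uc, vc = _center_velocities(u, v)
    dvdx = np.gradient(vc, h, axis=0)
    dudy = np.gradient(uc, h, axis=1)
    return dvdx - dudy


def _erode(mask: np.ndarray) -> np.ndarray:
    m = mask.copy()
    m[1:, :] &= mask[:-1, :]
    m[:-1, :] &= mask[1:, :]
    m[:, 1:] &= mask[:, :-1]
    m[:, :-1] &= mask[:, 1:]
    return m


def _mean_abs_vorticity(u, v, h, region_mask) -> float:
    interior = _erode(region_mask)
    if not interior.any():
        raise ValueError("vorticity mask is empty")
    return float(np.abs(_vorticity_centers(u, v, h))[interior].mean())


def recirculation_from_fields(uc, vc, region_mask, grid: Grid2D,
                              outlet_point, speed_floor_frac: float = 0.01) -> float:
    """Fraction of region cells whose velocity points more than 90 degrees
    away from the local sink direction (cell -> outlet), counting only cells
    faster than ``speed_floor_frac`` of the instantaneous maximum speed."""
    X, Y = np.meshgrid(grid.xc, grid.yc, indexing="ij")
    sx = outlet_point[0] - X
    sy = outlet_point[1] - Y
    sn = np.hypot(sx, sy)
    sn[sn == 0] = 1.0
    speed = np.hypot(uc, vc)
    vmax = speed[region_mask].max() if region_mask.any() else 0.0
    if vmax == 0:
        warnings.warn("all-quiescent step; recirculation fraction is 0")
        return 0.0
    moving = region_mask & (speed > speed_floor_frac * vmax)
    opposed = moving & ((uc * sx + vc * sy) / sn < 0.0)
    return float(opposed.sum() / region_mask.sum())


def solve_voiding_flow(domain: FlowDomain, grid_h: float, cfl: float = 0.4,
                       n_snapshots: int = 25, margin_cells: int = 2) -> FlowSolution:
    """Integrate the wall-driven voiding flow over the domain's time window.

    ``grid_h`` (mm) must resolve the channel with at least 8 cells across D;
    ``cfl`` in (0, 0.5]. Deterministic: identical inputs give identical
    metrics bit for bit.
    """
    D = domain.channel.diameter
    if D / grid_h < 8 - 1e-9:
        raise ValueError(
            f"grid_h={grid_h} under-resolves the channel (D/h = {D / grid_h:.1f} "
            f"< 8); use grid_h <= {D / 8:.3f}"
        )
    if not 0 < cfl <= 0.5:
        raise ValueError("cfl must lie in (0, 0.5]")

    h = float(grid_h)
    Rmax = float(domain.R.max())
    x_lo = -(Rmax + margin_cells * h)
    x_hi = Rmax + margin_cells * h
    # snap to the grid so x = 0 lies on a face (channel symmetry)
    nx_half = int(np.ceil((Rmax + margin_cells * h) / h))
    x_lo, x_hi = -nx_half * h, nx_half * h
    y_lo = domain.y_outlet
    ny = int(np.ceil((Rmax + margin_cells * h - y_lo) / h))
    grid = Grid2D(x0=x_lo, y0=y_lo, h=h, nx=2 * nx_half, ny=ny)

    stepper = _Stepper(grid, domain.fluid.nu)
    t0, t_end = float(domain.times[0]), float(domain.times[-1])

    # a-priori velocity scale for the initial dt: peak outlet speed
    dA = -np.gradient(domain.area, domain.times)
    u_scale = max(float(dA.max()) / D, float(np.abs(np.diff(domain.R, axis=0)).max()
                  / np.diff(domain.times).min()), 1e-6)
    dt = cfl * h / u_scale

    u = np.zeros((grid.nx + 1, grid.ny))
    v = np.zeros((grid.nx, grid.ny + 1))
    phi = np.zeros((grid.nx, grid.ny))

    times, dts, flux, area_s, vort_s, recirc_s, div_s = [], [], [], [], [], [], []
    blarea_s: list[float] = []
    snapshots: list[Snapshot] = []
    snap_times = np.linspace(t0, t_end, n_snapshots)
    next_snap = 0

    t = t0
    guard = 0
    while t < t_end - 1e-12:
        guard += 1
        if guard > 500_000:
            raise RuntimeError("step-count guard tripped; dt collapsed")
        fluid_mask, bladder_mask, open_bottom, Wu, Wv = _masks_for(
            domain, grid, t + 0.5 * dt
        )
        geom = stepper.geometry(fluid_mask, open_bottom,
                                np.zeros(grid.nx, bool))

        vmax = max(np.abs(u).max(), np.abs(v).max(),
                   np.abs(Wu).max(), np.abs(Wv).max(), u_scale * 0.2)
        dt_allowed = cfl * h / vmax
        if dt > dt_allowed:
            dt = 0.7 * dt_allowed
        elif dt < 0.35 * dt_allowed:
            dt = 0.7 * dt_allowed
        if dt < 1e-9 * (t_end - t0):
            raise RuntimeError("CFL clamping drove dt to zero; flow is unresolvable")
        dt_step = min(dt, t_end - t)

        u, v, phi, max_div = stepper.step(u, v, phi, geom, Wu, Wv, dt_step)
        t += dt_step

        uc, vc = _center_velocities(u, v)
        bl = bladder_mask & fluid_mask
        times.append(t)
        dts.append(dt_step)
        flux.append(float(-(v[geom.open_bottom & fluid_mask[:, 0], 0]).sum() * h))
        area_s.append(float(domain.area_at(t - 0.5 * dt_step)))
        blarea_s.append(float(bl.sum()) * h * h)
        vort_s.append(_mean_abs_vorticity(u, v, h, bl))
        recirc_s.append(
            recirculation_from_fields(uc, vc, bl, grid, domain.outlet_point)
        )
        div_s.append(max_div)

        if next_snap < len(snap_times) and t >= snap_times[next_snap] - 1e-12:
            p = np.full((grid.nx, grid.ny), np.nan)
            p[fluid_mask] = phi[fluid_mask] * domain.fluid.density * 1e-6
            snapshots.append(Snapshot(t=t, u=u.copy(), v=v.copy(), p=p,
                                      fluid=fluid_mask.copy(), bladder=bl.copy()))
            while next_snap < len(snap_times) and snap_times[next_snap] <= t + 1e-12:
                next_snap += 1

    return FlowSolution(
        grid=grid, times=np.array(times), dts=np.array(dts),
        outlet_flux=np.array(flux), domain_area=np.array(area_s),
        bladder_area=np.array(blarea_s),
        mean_abs_vorticity=np.array(vort_s), recirc_fraction=np.array(recirc_s),
        max_divergence=np.array(div_s), snapshots=snapshots,
        outlet_point=domain.outlet_point, fluid=domain.fluid,
        channel=domain.channel,
    )


# ---------------------------------------------------------------------------
# metrics on solutions / snapshots
# ---------------------------------------------------------------------------

def vorticity_field(solution: FlowSolution, step: int) -> np.ndarray:
    """omega = dv/dx - du/dy (1/s) at cell centres for snapshot ``step``
    (central differences; exact for linear velocity fields)."""
    snap = solution.snapshots[step]
    w = _vorticity_centers(snap.u, snap.v, solution.grid.h)
    w[~snap.fluid] = np.nan
    return w


@dataclass
class MeanVorticity:
    per_step: np.ndarray
    time_average: float


def mean_vorticity(solution: FlowSolution) -> MeanVorticity:
    """Area-weighted mean of |omega| over the bladder region (channel
    excluded), per step and dt-weighted over the voiding window."""
    w = solution.mean_abs_vorticity
    avg = float(np.sum(w * solution.dts) / np.sum(solution.dts))
    return MeanVorticity(per_step=w, time_average=avg)


def dimensionless_vorticity(mean_vort: float, Q_mean: float, D: float,
                            mode: str = "2d") -> float:
    """mean|omega| * D / Ubar with Ubar the mean urethral flow speed.

    ``mode="2d"``: Ubar = Q_mean / D with Q_mean the 2D flux per unit depth
    (mm^2/s), so the result is mean_vort * D^2 / Q_mean. ``mode="pseudo3d"``:
    Ubar = Q_mean / (pi D^2 / 4) with Q_mean volumetric (mm^3/s).
    """
    if Q_mean <= 0:
        raise ValueError("dimensionless vorticity undefined for Q_mean <= 0")
    if D <= 0:
        raise ValueError("D must be positive")
    if mode == "2d":
        ubar = Q_mean / D
    elif mode == "pseudo3d":
        ubar = Q_mean / (np.pi * D * D / 4.0)
    else:
        raise ValueError("mode must be '2d' or 'pseudo3d'")
    return float(mean_vort * D / ubar)


def recirculation_fraction(solution: FlowSolution, step: int,
                           outlet_point=None) -> float:
    """Recirculation fraction of snapshot ``step``: share of bladder cells
    with velocity directed > 90 degrees from the local sink direction."""
    snap = solution.snapshots[step]
    uc, vc = _center_velocities(snap.u, snap.v)
    pt = solution.outlet_point if outlet_point is None else np.asarray(outlet_point)
    return recirculation_from_fields(uc, vc, snap.bladder, solution.grid, pt)


# ---------------------------------------------------------------------------
# channel validation flow (Poiseuille)
# ---------------------------------------------------------------------------

@dataclass
class ChannelFlowResult:
    grid: Grid2D
    v_profile: np.ndarray       # mid-height |v| across the channel (mm/s)
    x_profile: np.ndarray       # x positions of the profile (mm)
    v_max_numeric: float
    v_max_analytic: float
    max_divergence: float
    n_steps: int

    @property
    def relative_error(self) -> float:
        return abs(self.v_max_numeric - self.v_max_analytic) / self.v_max_analytic

    @property
    def D(self) -> float:
        return float(self.x_profile[-1] - self.x_profile[0]) + self.grid.h

    @property
    def profile_error(self) -> float:
        """L-infinity error of the whole profile against the analytic
        parabola, relative to the analytic maximum."""
        exact = self.v_max_analytic * (1.0 - (2.0 * self.x_profile / self.D) ** 2)
        return float(np.max(np.abs(self.v_profile - exact)) / self.v_max_analytic)


def simulate_channel_flow(D: float, L: float, n_across: int,
                          dp_over_rho: float, fluid: FluidProperties | None = None,
                          cfl: float = 0.4, steady_tol: float = 1e-10,
                          max_steps: int = 20000) -> ChannelFlowResult:
    """Pressure-driven straight-channel flow marched to steady state;
    validates the solver against the analytic Poiseuille profile
    v_max = (dp/rho) D^2 / (8 nu L)."""
    fluid = fluid or FluidProperties()
    nu = fluid.nu
    h = D / n_across
    ny = int(round(L / h))
    L_eff = ny * h
    grid = Grid2D(x0=-D / 2 - h, y0=0.0, h=h, nx=n_across + 2, ny=ny)

    fluid_mask = np.zeros((grid.nx, grid.ny), bool)
    fluid_mask[1:-1, :] = True
    open_cols = np.zeros(grid.nx, bool)
    open_cols[1:-1] = True

    v_max_analytic = dp_over_rho * D * D / (8.0 * nu * L_eff)
    stepper = _Stepper(grid, nu)
    geom = stepper.geometry(fluid_mask, open_cols, open_cols)
    Wu = np.zeros((grid.nx + 1, grid.ny))
    Wv = np.zeros((grid.nx, grid.ny + 1))
    u = np.zeros_like(Wu)
    v = np.zeros_like(Wv)
    phi = np.zeros((grid.nx, grid.ny))

    dt = cfl * h / max(v_max_analytic, 1e-12)
    max_div = np.inf
    for n in range(1, max_steps + 1):
        u_new, v_new, phi, max_div = stepper.step(
            u, v, phi, geom, Wu, Wv, dt, p_bottom=0.0, p_top=dp_over_rho
        )
        delta = np.abs(v_new - v).max()
        u, v = u_new, v_new
        if delta < steady_tol * max(np.abs(v).max(), 1e-30):
            break
    else:
        warnings.warn("channel flow did not fully reach steady state")

    j = grid.ny // 2
    profile = np.abs(0.5 * (v[:, j] + v[:, j + 1]))[1:-1]
    return ChannelFlowResult(
        grid=grid, v_profile=profile, x_profile=grid.xc[1:-1],
        v_max_numeric=float(profile.max()), v_max_analytic=float(v_max_analytic),
        max_divergence=float(max_div), n_steps=n,
    )
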