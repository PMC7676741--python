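"""Model/Results front end tying the pipeline together.

:class:`VoidingModel` is built from a pre-void mesh, a post-void mesh and
(optionally) a real-time bladder-area curve; ``fit()`` estimates the radial
displacement field, regional statistics, the asymmetry ratio, the voiding
time-dependence alpha(t) and the volume/flow kinematics, returning a
:class:`VoidingResults` with a ``summary()`` table. Flow simulation and
plotting hang off the results object.

Example
-------
>>> from vesica import synthetic, VoidingModel
>>> pre, post, truth = synthetic.make_voiding_pair(synthetic.control_like())
>>> curve = synthetic.area_curve_for_scenario(synthetic.control_like())
>>> res = VoidingModel(pre, post, curve).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import flow as flow_mod
from .displacement import (
    DisplacementField,
    RegionalStats,
    SphericalFrame,
    compute_displacement_field,
    displacement_density,
    regional_stats,
)
from .mesh import SurfaceMesh, mesh_volume, read_stl
from .temporal import (
    AlphaCurve,
    AreaCurve,
    SqrtCosineFit,
    VoidingKinematics,
    alpha_from_area,
    alpha_sqrt_cosine,
    detect_void_window,
    fit_sqrt_cosine,
    volume_and_flow,
)

__all__ = ["VoidingModel", "VoidingResults", "FlowResults"]


class VoidingModel:
    """Radial separable wall-motion model of one voiding event.

    Parameters
    ----------
    pre, post : closed surface meshes (mm) of the bladder before and after
        voiding.
    area_curve : optional real-time area curve A(t); without it the canonical
        square-root-of-cosine alpha over ``(t0, tend)`` is used (the
        one-measured-curve-for-all-subjects situation).
    axes : optional 3x3 anatomical axes (rows: left, anterior, superior) for
        meshes whose orientation is not the canonical one (STL has no
        orientation metadata).
    """

    def __init__(self, pre: SurfaceMesh, post: SurfaceMesh,
                 area_curve: AreaCurve | None = None, axes=None):
        self.pre = pre
        self.post = post
        self.area_curve = area_curve
        self.frame = SphericalFrame.from_meshes(pre, post, axes=axes)

    @classmethod
    def from_stl(cls, pre_path, post_path, area_csv=None, axes=None) -> "VoidingModel":
        curve = AreaCurve.from_csv(area_csv) if area_csv else None
        return cls(read_stl(pre_path), read_stl(post_path), curve, axes=axes)

    def fit(self, sampling="pre_vertices", alpha: str = "measured",
            t0: float | None = None, tend: float | None = None,
            n_time: int = 64) -> "VoidingResults":
        """Estimate displacement, regional statistics and voiding kinematics.

        ``alpha="measured"`` derives alpha(t) from the area curve (detecting
        the voiding window unless ``t0``/``tend`` are given);
        ``alpha="canonical"`` uses the square-root-of-cosine form over
        [t0, tend] (defaults 0-30 s).
        """
        field = compute_displacement_field(self.pre, self.post, self.frame,
                                           sampling=sampling)
        stats = regional_stats(field)

        alpha_fit = None
        if alpha == "measured":
            if self.area_curve is None:
                raise ValueError("alpha='measured' requires an area curve")
            if t0 is None or tend is None:
                t0, tend = detect_void_window(self.area_curve)
            alpha_curve = alpha_from_area(self.area_curve, t0, tend)
            alpha_fit = fit_sqrt_cosine(alpha_curve)
        elif alpha == "canonical":
            t0 = 0.0 if t0 is None else t0
            tend = 30.0 if tend is None else tend
            t = np.linspace(t0, tend, n_time)
            alpha_curve = AlphaCurve(t, alpha_sqrt_cosine(t, t0, tend))
        else:
            raise ValueError("alpha must be 'measured' or 'canonical'")

        kinematics = (volume_and_flow(self.pre, field, self.frame, alpha_curve)
                      if sampling == "pre_vertices" else None)

        return VoidingResults(
            model=self, field=field, stats=stats, alpha_curve=alpha_curve,
            alpha_fit=alpha_fit, kinematics=kinematics,
            window=(float(t0), float(tend)),
        )


@dataclass
class FlowResults:
    """Swirl metrics of one voiding flow simulation."""

    solution: flow_mod.FlowSolution
    domain: flow_mod.FlowDomain
    mean_vorticity: float          # time-averaged mean |omega|, 1/s
    dimensionless_vorticity: float
    peak_recirculation: float      # peak per-step recirculation fraction
    peak_recirc_area: float        # peak recirculated area, mm^2
    mean_outlet_flux: float        # mm^2/s (2D, per unit depth)
    mass_error: float

    def summary(self) -> str:
        lines = [
            "Voiding flow simulation",
            "-" * 47,
            f"grid spacing h            {self.solution.grid.h:10.3f} mm",
            f"time steps                {len(self.solution.times):10d}",
            f"mean |vorticity|          {self.mean_vorticity:10.4f} 1/s",
            f"dimensionless vorticity   {self.dimensionless_vorticity:10.4f}",
            f"peak recirculation frac   {self.peak_recirculation:10.4f}",
            f"peak recirculated area    {self.peak_recirc_area:10.1f} mm^2",
            f"mean outlet flux          {self.mean_outlet_flux:10.2f} mm^2/s",
            f"mass conservation error   {self.mass_error:10.2%}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mean_vorticity_per_s": self.mean_vorticity,
            "dimensionless_vorticity": self.dimensionless_vorticity,
            "peak_recirculation_fraction": self.peak_recirculation,
            "peak_recirc_area_mm2": self.peak_recirc_area,
            "mean_outlet_flux_mm2_per_s": self.mean_outlet_flux,
            "mass_error": self.mass_error,
        }


@dataclass
class VoidingResults:
    """Fitted displacement + kinematics of one voiding event."""

    model: VoidingModel
    field: DisplacementField
    stats: RegionalStats
    alpha_curve: AlphaCurve
    alpha_fit: SqrtCosineFit | None
    kinematics: VoidingKinematics | None
    window: tuple[float, float]

    @property
    def asymmetry_ratio(self) -> float:
        return self.stats.asymmetry_ratio

    @property
    def median_displacement(self) -> float:
        return float(np.median(self.field.d0))

    def density(self, bandwidth="auto"):
        return displacement_density(self.field, bandwidth=bandwidth)

    def summary(self) -> str:
        t0, tend = self.window
        lines = [
            "Radial voiding model fit",
            "=" * 56,
            f"pre-void volume     {mesh_volume(self.model.pre) / 1000:8.1f} mL",
            f"post-void volume    {mesh_volume(self.model.post) / 1000:8.1f} mL",
            f"samples             {self.field.n_samples:8d}"
            f"   (failed rays: {self.field.n_failed})",
            f"median d0           {self.median_displacement:8.2f} mm",
            f"asymmetry ratio     {self.asymmetry_ratio:8.1f} %",
            f"voiding window      [{t0:.1f}, {tend:.1f}] s",
        ]
        if self.alpha_fit is not None:
            lines.append(
                f"sqrt-cos alpha fit  t0={self.alpha_fit.t0:.2f} s, "
                f"tend={self.alpha_fit.tend:.2f} s, rmse={self.alpha_fit.rmse:.2e}"
            )
        if self.kinematics is not None:
            lines.append(
                f"voided volume       {self.kinematics.voided_volume / 1000:8.1f} mL"
            )
            lines.append(
                f"peak flow rate      {self.kinematics.Q.max():8.2f} mL/s"
            )
        lines.append("")
        lines.append("Regional displacement (mm):")
        lines.append(self.stats.to_dataframe().round(2).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "median_d0_mm": self.median_displacement,
            "asymmetry_ratio_pct": self.asymmetry_ratio,
            "n_samples": int(self.field.n_samples),
            "n_failed": int(self.field.n_failed),
            "window_s": list(self.window),
            "regional": self.stats.summaries,
        }
        if self.kinematics is not None:
            d["voided_volume_mL"] = self.kinematics.voided_volume / 1000.0
            d["peak_flow_mL_per_s"] = float(self.kinematics.Q.max())
        if self.alpha_fit is not None:
            d["alpha_fit"] = {"t0": self.alpha_fit.t0, "tend": self.alpha_fit.tend,
                              "rmse": self.alpha_fit.rmse}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=float, **kwargs)

    # -- flow ------------------------------------------------------------
    def simulate_flow(self, urethra: flow_mod.UrethraChannel | None = None,
                      fluid: flow_mod.FluidProperties | None = None,
                      plane: flow_mod.PlaneSpec | None = None,
                      grid_h: float | None = None, cfl: float = 0.4) -> FlowResults:
        """Run the 2D moving-boundary flow simulation driven by this fit."""
        if self.kinematics is None:
            raise ValueError("flow simulation needs pre_vertices kinematics")
        urethra = urethra or flow_mod.UrethraChannel()
        grid_h = urethra.diameter / 8.0 if grid_h is None else grid_h
        domain = flow_mod.build_domain(self.kinematics, plane, urethra, fluid)
        sol = flow_mod.solve_voiding_flow(domain, grid_h=grid_h, cfl=cfl)
        mv = flow_mod.mean_vorticity(sol)
        return FlowResults(
            solution=sol, domain=domain, mean_vorticity=mv.time_average,
            dimensionless_vorticity=flow_mod.dimensionless_vorticity(
                mv.time_average, sol.mean_outlet_flux, urethra.diameter
            ),
            peak_recirculation=float(sol.recirc_fraction.max()),
            peak_recirc_area=float(sol.recirc_area.max()),
            mean_outlet_flux=sol.mean_outlet_flux,
            mass_error=sol.mass_error,
        )

    # -- plotting --------------------------------------------------------
    def plot_displacement_map(self, ax=None):
        """Displacement magnitude coloured on the pre-void surface (3D)."""
        import matplotlib.pyplot as plt

        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        v = self.model.pre.vertices
        sc = ax.scatter(v[:, 0], v[:, 1], v[:, 2], c=self.field.d0, s=4,
                        cmap="viridis")
        ax.figure.colorbar(sc, ax=ax, label="d0 (mm)")
        ax.set_title("bladder wall displacement")
        return ax

    def plot_regional_box(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = list(self.stats.summaries)
        data = [self.field.d0[self.field.region_mask(n)] for n in names]
        ax.boxplot(data, tick_labels=names)
        ax.set_ylabel("displacement d0 (mm)")
        return ax

    def plot_density(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        den = self.density()
        if den.point_mass:
            ax.axvline(den.location)
        else:
            ax.plot(den.grid, den.density)
        ax.set_xlabel("displacement d0 (mm)")
        ax.set_ylabel("probability density")
        return ax

    def plot_kinematics(self, ax=None):
        import matplotlib.pyplot as plt

        if self.kinematics is None:
            raise ValueError("no kinematics fitted")
        if ax is None:
            _, ax = plt.subplots()
        k = self.kinematics
        ax.plot(k.times, k.V / 1000.0, label="V (mL)")
        ax2 = ax.twinx()
        ax2.plot(k.times, k.Q, color="C1", label="Q (mL/s)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("volume (mL)")
        ax2.set_ylabel("flow rate (mL/s)")
        return ax
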