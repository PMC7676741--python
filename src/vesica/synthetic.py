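"""Synthetic voiding fixtures with analytically known ground truth.

No bladder imaging data ship with this package, so tests and examples run on
generated pre/post-void surface pairs whose radial displacement field is an
analytic function of direction, plus sigmoidal area-vs-time curves. The base
shape is an icosphere (star-shaped about its centre by construction, i.e.
inside the radial model's domain of validity) at a full-bladder scale:
the default pre-void radius of 42 mm encloses ~310 mL.

Three displacement patterns are provided:

``uniform``
    d0 = shrink_fraction * r_pre everywhere (concentric shrink).
``dome_weighted``
    the uniform displacement scaled by 1 + (dome_gain - 1) * max(0, cos
    theta_dome), reproducing the dome-dominant motion of healthy voiding.
``asymmetric``
    the left hemisphere (x > 0) displaced asym_gain times more than the
    right, blended smoothly across a 10 degree band at the midplane (a hard
    seam would be unphysical and makes ray-casting recovery ill-posed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Callable

import numpy as np
import trimesh

from .displacement import _fibonacci_directions, asymmetry_ratio
from .mesh import SurfaceMesh
from .temporal import AreaCurve

__all__ = [
    "VoidingScenario",
    "GroundTruth",
    "make_sphere_mesh",
    "make_voiding_pair",
    "make_area_curve",
    "control_like",
    "bph_like",
]

PATTERNS = ("uniform", "dome_weighted", "asymmetric")

#: half-width (rad) of the smooth left/right blend band (10 degrees total)
_BLEND_HALF = np.deg2rad(5.0)


@dataclass
class VoidingScenario:
    """Parameters of one synthetic voiding fixture.

    ``r_pre`` mm, ``shrink_fraction`` in (0, 1) is the fraction of the radius
    lost by the *base* (unscaled) displacement; ``dome_gain`` >= 1 multiplies
    displacement at the dome apex; ``asym_gain`` > 0 multiplies the left
    hemisphere.
    """

    pattern: str = "dome_weighted"
    r_pre: float = 42.0
    shrink_fraction: float = 0.5
    dome_gain: float = 1.5
    asym_gain: float = 1.5
    mesh_subdivisions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if not 0.0 < self.shrink_fraction < 1.0:
            raise ValueError("shrink_fraction must lie strictly in (0, 1)")
        if self.r_pre <= 0:
            raise ValueError("r_pre must be positive")
        if self.dome_gain < 1.0:
            raise ValueError("dome_gain must be >= 1")
        if self.asym_gain <= 0.0:
            raise ValueError("asym_gain must be positive")
        if not 0 <= self.mesh_subdivisions <= 6:
            raise ValueError("mesh_subdivisions must lie in [0, 6]")


@dataclass
class GroundTruth:
    """Analytic oracle for parameter-recovery tests."""

    d0_true: Callable[[np.ndarray], np.ndarray]  # (n,3) unit dirs -> d0 (mm)
    median_left_true: float
    median_right_true: float
    asymmetry_true: float
    scenario: VoidingScenario

    def to_json(self) -> str:
        d = asdict(self.scenario)
        d.update(
            median_left_true=self.median_left_true,
            median_right_true=self.median_right_true,
            asymmetry_true=self.asymmetry_true,
        )
        return json.dumps(d, indent=2)


def make_sphere_mesh(radius: float, subdivisions: int) -> SurfaceMesh:
    """Icosphere of given radius: 10 * 4^n + 2 vertices, 20 * 4^n faces, every
    vertex at distance ``radius`` from the origin."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must lie in [0, 6]")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(ico.vertices, float)
    # re-normalise exactly: trimesh is already on the sphere, this pins the
    # relative radial error below 1e-9
    v = v * (radius / np.linalg.norm(v, axis=1))[:, None]
    return SurfaceMesh(v, np.asarray(ico.faces, np.int64),
                       provenance=f"icosphere(r={radius:g}, sub={subdivisions})")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def displacement_pattern(scenario: VoidingScenario) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic d0(direction) for the scenario, directions as (n, 3) unit
    vectors in the canonical frame (x left, y anterior, z dome)."""
    base = scenario.shrink_fraction * scenario.r_pre

    if scenario.pattern == "uniform":
        def d0(dirs: np.ndarray) -> np.ndarray:
            return np.full(len(np.atleast_2d(dirs)), base)
    elif scenario.pattern == "dome_weighted":
        g = scenario.dome_gain

        def d0(dirs: np.ndarray) -> np.ndarray:
            cos_dome = np.atleast_2d(dirs)[:, 2]  # polar angle from dome apex
            return base * (1.0 + (g - 1.0) * np.maximum(0.0, cos_dome))
    else:  # asymmetric
        a = scenario.asym_gain

        def d0(dirs: np.ndarray) -> np.ndarray:
            x = np.clip(np.atleast_2d(dirs)[:, 0], -1.0, 1.0)
            lat = np.arcsin(x)  # angle from the left/right midplane
            w = _smoothstep((lat + _BLEND_HALF) / (2.0 * _BLEND_HALF))
            return base * (1.0 + (a - 1.0) * w)

    return d0


def make_voiding_pair(scenario: VoidingScenario):
    """Build (pre, post, truth): the post-void vertex in direction u sits at
    radius r_pre - d0_true(u). Raises if any post radius would be <= 0."""
    pre = make_sphere_mesh(scenario.r_pre, scenario.mesh_subdivisions)
    pre = replace(pre, provenance="pre-void (synthetic)")
    dirs = pre.vertices / np.linalg.norm(pre.vertices, axis=1)[:, None]
    d0 = displacement_pattern(scenario)
    disp = d0(dirs)
    post_r = scenario.r_pre - disp
    if np.any(post_r <= 0):
        raise ValueError(
            "scenario displacement exceeds the pre-void radius somewhere; "
            "post-void surface would be degenerate"
        )
    post = SurfaceMesh(dirs * post_r[:, None], pre.faces.copy(),
                       provenance="post-void (synthetic)")

    # analytic medians from a dense uniform sampling of the pattern function
    dense = _fibonacci_directions(200_000)
    dense_d0 = d0(dense)
    left = dense[:, 0] > 0
    ml = float(np.median(dense_d0[left]))
    mr = float(np.median(dense_d0[~left]))
    truth = GroundTruth(
        d0_true=d0,
        median_left_true=ml,
        median_right_true=mr,
        asymmetry_true=asymmetry_ratio(ml, mr),
        scenario=scenario,
    )
    return pre, post, truth


def make_area_curve(t0: float, tend: float, A0: float, Aend: float,
                    n_samples: int = 64, noise_sd: float = 0.0, seed: int = 0,
                    pad_before: float = 0.0, pad_after: float = 0.0) -> AreaCurve:
    """Sigmoidal area curve A(t) = A0 + (Aend - A0) * alpha_ref(t)^2 with
    alpha_ref the square-root-of-cosine form, so that the area-ratio formula
    applied to the noiseless curve recovers alpha_ref exactly.

    With ``pad_before``/``pad_after`` > 0 (seconds) flat plateaus are added
    around the voiding window (for window-detection tests). Gaussian noise of
    the given sd (mm^2) is added when ``noise_sd > 0``; the same seed yields
    an identical curve.
    """
    if tend <= t0:
        raise ValueError("tend must exceed t0")
    if not (A0 > Aend >= 0):
        raise ValueError("need A0 > Aend >= 0")
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    if pad_before < 0 or pad_after < 0:
        raise ValueError("pads must be non-negative")
    t = np.linspace(t0 - pad_before, tend + pad_after, n_samples)
    tau = np.clip((t - t0) / (tend - t0), 0.0, 1.0)
    alpha_ref = np.sqrt((1.0 - np.cos(np.pi * tau)) / 2.0)
    A = A0 + (Aend - A0) * alpha_ref**2
    if noise_sd > 0:
        A = A + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(t))
        A = np.clip(A, 0.0, None)
    return AreaCurve(t, A)


def area_curve_for_scenario(scenario: VoidingScenario, t0: float = 0.0,
                            tend: float = 30.0, noise_sd: float = 0.0,
                            n_samples: int = 64) -> AreaCurve:
    """Mid-sagittal area curve consistent with the scenario's radial scale:
    A0 = pi r_pre^2 and Aend from the base shrink."""
    r_end = scenario.r_pre * (1.0 - scenario.shrink_fraction)
    return make_area_curve(t0, tend, np.pi * scenario.r_pre**2,
                           np.pi * r_end**2, n_samples=n_samples,
                           noise_sd=noise_sd, seed=scenario.seed)


def control_like(subdivisions: int = 4, seed: int = 0) -> VoidingScenario:
    """Healthy-control-like fixture: large, dome-weighted, symmetric motion."""
    return VoidingScenario(pattern="dome_weighted", r_pre=42.0,
                           shrink_fraction=0.5, dome_gain=1.5,
                           mesh_subdivisions=subdivisions, seed=seed)


def bph_like(subdivisions: int = 4, seed: int = 0) -> VoidingScenario:
    """BPH/LUTS-like fixture: small, left-right asymmetric motion at the same
    geometric scale (walls move ~30 % as far as the control fixture)."""
    return VoidingScenario(pattern="asymmetric", r_pre=42.0,
                           shrink_fraction=0.15, asym_gain=1.8,
                           mesh_subdivisions=subdivisions, seed=seed)
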