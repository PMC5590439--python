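"""Strain assembly and quasi-static load-path marching.

The model is stress-driven: total strain is an explicit function of the
stress/temperature history,

    eps = eps_elastic + eps_transform

with the elastic part

    eps_e = -(nu / E(xi)) tr(sigma) I
            + (1 + nu)/E(xi) * 3 sum w (sigma_N N + sigma_T T)

(the sphere integral collapses to ``sigma`` for any quadrature with exact
second moments, so the elastic response is isotropic Hooke behaviour with
the mixture modulus ``E(xi)``), and the transformation part

    eps_tr = eps_star * xi * Lambda(sigma)

where ``Lambda`` is the calibrated sphere integral of the unit shear
projection tensor (see :func:`microsma.quadrature.transformation_direction`).
``Lambda`` is traceless, so transformation is volume-preserving; under
uniaxial tension it equals ``diag(-1/2, -1/2, 1)``, so full transformation
yields the maximum recoverable axial strain ``eps_star``.

A :class:`LoadPath` is a sequence of (stress tensor, temperature) targets
with per-segment step counts; :func:`run_path` interpolates linearly
within each segment and marches the kinetics step by step.  At exactly
zero stress with residual martensite (stress-free thermal recovery) the
transformation direction is frozen from the last non-zero-stress step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kinetics import TransformationState, effective_stress, update_martensite_fraction
from .material import MaterialParams, elastic_modulus
from .quadrature import (
    MicroplaneSystem,
    _check_symmetric,
    resolved_stress_integral,
    transformation_direction,
)

__all__ = [
    "StressPoint",
    "LoadPath",
    "StepResult",
    "PathResult",
    "elastic_strain",
    "transformation_strain",
    "step",
    "run_path",
    "von_mises",
    "principal_strains",
    "loop_area",
]

logger = logging.getLogger(__name__)

#: Stress magnitudes below this (MPa) count as "zero stress" for the
#: purpose of freezing the transformation direction.
_ZERO_STRESS_TOL = 1e-9

DEFAULT_STEPS_PER_SEGMENT = 200


@dataclass(frozen=True)
class StressPoint:
    """A macroscopic stress tensor (MPa) with its temperature (deg C)."""

    sigma: np.ndarray
    T: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", _check_symmetric(self.sigma))

    @staticmethod
    def uniaxial(s: float, T: float, tau: float = 0.0) -> "StressPoint":
        """Axial stress ``s`` along axis 3 plus optional 13-shear ``tau``."""
        sigma = np.zeros((3, 3))
        sigma[2, 2] = s
        sigma[0, 2] = sigma[2, 0] = tau
        return StressPoint(sigma=sigma, T=T)


@dataclass(frozen=True)
class LoadPath:
    """Piecewise-linear stress--temperature program.

    ``segments`` is an ordered list of ``(target, n_steps)``; both the
    stress tensor and the temperature are interpolated linearly within a
    segment (the target itself is always hit exactly).  The path starts
    from ``start`` (default: zero stress at the first target's
    temperature).
    """

    segments: list[tuple[StressPoint, int]]
    start: StressPoint | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a load path needs at least one segment")
        for _, n in self.segments:
            if n < 1:
                raise ValueError(f"every segment needs n_steps >= 1, got {n}")

    def with_steps(self, n_steps: int) -> "LoadPath":
        """Same targets, uniform ``n_steps`` per segment (for refinement studies)."""
        return LoadPath(
            segments=[(p, n_steps) for p, _ in self.segments], start=self.start
        )

    @property
    def n_steps_total(self) -> int:
        return sum(n for _, n in self.segments)


@dataclass(frozen=True)
class StepResult:
    """Constitutive response at one path step (strains are 3x3 tensors)."""

    step: int
    sigma: np.ndarray
    T: float
    sigma_eff: float
    xi: float
    eps_elastic: np.ndarray
    eps_transform: np.ndarray
    eps_total: np.ndarray
    von_mises_stress: float
    max_principal_strain: float


@dataclass(frozen=True)
class PathResult:
    """Ordered step results plus run metadata (parameters, scheme, sizes)."""

    steps: list[StepResult]
    metadata: dict
    final_state: TransformationState

    def __len__(self) -> int:
        return len(self.steps)

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(s, attr) for s in self.steps])


# -- strain assembly ------------------------------------------------------


def elastic_strain(
    sigma: np.ndarray,
    xi: float,
    params: MaterialParams,
    system: MicroplaneSystem,
) -> np.ndarray:
    """Elastic strain tensor for stress ``sigma`` at martensite fraction ``xi``."""
    sigma = _check_symmetric(sigma)
    E = elastic_modulus(params, xi)
    integral = resolved_stress_integral(system, sigma)
    return (-params.nu / E) * np.trace(sigma) * np.eye(3) + (1.0 + params.nu) / E * integral


def transformation_strain(
    sigma: np.ndarray,
    xi: float,
    params: MaterialParams,
    system: MicroplaneSystem,
    direction: np.ndarray | None = None,
) -> np.ndarray:
    """Transformation strain ``eps_star * xi * Lambda(sigma)`` (traceless).

    ``direction`` overrides the direction tensor ``Lambda``; the driver
    uses this to freeze the direction at zero stress during stress-free
    thermal recovery.
    """
    if not (0.0 <= xi <= 1.0):
        raise ValueError(f"martensite fraction must lie in [0, 1], got {xi}")
    if direction is None:
        direction = transformation_direction(system, sigma)
    return params.eps_star * xi * direction


def von_mises(sigma: np.ndarray) -> float:
    """Von Mises equivalent stress, MPa."""
    return effective_stress(sigma)


def principal_strains(eps: np.ndarray) -> np.ndarray:
    """Principal strains, sorted descending."""
    eps = _check_symmetric(eps)
    return np.linalg.eigvalsh(eps)[::-1]


# -- path marching --------------------------------------------------------


def step(
    state: TransformationState,
    point: StressPoint,
    params: MaterialParams,
    system: MicroplaneSystem,
    frozen_direction: np.ndarray | None = None,
) -> tuple[TransformationState, StepResult, np.ndarray]:
    """Advance the state to ``point`` and assemble the full response.

    Pure function of ``(state, point)``: effective stress -> kinetics ->
    strain assembly.  Returns the new state, the step record and the
    transformation-direction tensor actually used (so callers can freeze
    it across a zero-stress stretch).
    """
    sig_eff = effective_stress(point.sigma)
    new_state = update_martensite_fraction(state, sig_eff, point.T, params)
    xi = new_state.xi

    if np.abs(point.sigma).max() > _ZERO_STRESS_TOL:
        direction = transformation_direction(system, point.sigma)
    elif frozen_direction is not None:
        direction = frozen_direction
    else:
        direction = np.zeros((3, 3))

    eps_e = elastic_strain(point.sigma, xi, params, system)
    eps_tr = transformation_strain(point.sigma, xi, params, system, direction=direction)
    eps = eps_e + eps_tr
    result = StepResult(
        step=-1,
        sigma=point.sigma,
        T=point.T,
        sigma_eff=sig_eff,
        xi=xi,
        eps_elastic=eps_e,
        eps_transform=eps_tr,
        eps_total=eps,
        von_mises_stress=von_mises(point.sigma),
        max_principal_strain=float(principal_strains(eps)[0]),
    )
    return new_state, result, direction


def run_path(
    path: LoadPath,
    params: MaterialParams,
    system: MicroplaneSystem,
    initial_state: TransformationState | None = None,
) -> PathResult:
    """March a load path and return the full response history.

    The default initial state is pure austenite at the path start.  Step
    indices are contiguous from 0; step 0 records the starting point
    itself.  A failing step aborts with its index reported.
    """
    start = path.start or StressPoint(np.zeros((3, 3)), path.segments[0][0].T)
    state = initial_state or TransformationState(
        last_sigma_eff=effective_stress(start.sigma), last_T=start.T
    )

    points: list[StressPoint] = [start]
    prev = start
    for target, n_steps in path.segments:
        for k in range(1, n_steps + 1):
            f = k / n_steps
            points.append(
                StressPoint(
                    sigma=(1 - f) * prev.sigma + f * target.sigma,
                    T=(1 - f) * prev.T + f * target.T,
                )
            )
        prev = target

    results: list[StepResult] = []
    frozen: np.ndarray | None = None
    for idx, point in enumerate(points):
        try:
            prev_mode = state.mode
            state, rec, direction = step(state, point, params, system, frozen_direction=frozen)
            if np.abs(point.sigma).max() > _ZERO_STRESS_TOL:
                frozen = direction
            if state.mode != prev_mode:
                logger.info(
                    "step %d: transformation mode %s -> %s (sigma_eff=%.2f MPa, T=%.2f degC, xi=%.4f)",
                    idx, prev_mode, state.mode, rec.sigma_eff, point.T, state.xi,
                )
        except Exception as exc:
            raise RuntimeError(f"load path failed at step {idx}: {exc}") from exc
        results.append(
            StepResult(**{**rec.__dict__, "step": idx})
        )

    metadata = {
        "params": params.to_dict(),
        "nu": params.nu,
        "scheme": system.scheme_name,
        "n_planes": len(system),
        "n_steps": len(results),
    }
    return PathResult(steps=results, metadata=metadata, final_state=state)


def loop_area(result: PathResult) -> float:
    """Hysteresis-loop area as the stress work ``\\oint sigma : d eps`` (MPa).

    For a closed load--unload cycle this is the dissipated work density;
    it is zero for a purely elastic excursion and grows with the amount of
    transformation traversed.
    """
    sig = result.array("sigma")
    eps = result.array("eps_total")
    d_eps = eps[1:] - eps[:-1]
    mid = 0.5 * (sig[1:] + sig[:-1])
    return float(np.einsum("kij,kij->", mid, d_eps))
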