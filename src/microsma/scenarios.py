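"""Named load programs and parameter-sweep studies.

The implant-scale experiments this package emulates apply tensile forces
(N) and torsion torques (N mm) to a thin NiTi device and report stress /
strain summaries per condition.  At a material point those loads become an
axial stress and a shear stress through a reference cross-section
surrogate (:class:`GeometryMap`): ``sigma = F / area`` and
``tau = M * shear_factor``.  The defaults are chosen so that the headline
combined amplitude (50 N with 75 N mm at 38 deg C) drives the effective
stress just past the forward transformation onset at that temperature;
they are a surrogate for a real cross-section, not device values.

Scenario names:

``pseudoelastic_tension``
    Load--unload tension above ``Af``: closed hysteresis loop, zero
    residual strain.
``tension_torsion``
    Proportional load--unload of combined tension and torsion above
    ``Af``.
``sme_tension_torsion``
    The same between ``Ms`` and ``As``: stress-induced martensite
    persists after unloading (shape-memory-effect regime).
``thermal_recovery``
    SME load--unload followed by a stress-free heating ramp above ``Af``
    that recovers the residual strain.
``temperature_sweep``
    One load--unload path per listed temperature at fixed force/torque.

Exactly one of force / torque / temperature may be a list (the swept
variable), mirroring one-factor-at-a-time studies; sweeps run as
independent paths from fresh austenite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .driver import (
    DEFAULT_STEPS_PER_SEGMENT,
    LoadPath,
    PathResult,
    StressPoint,
    loop_area,
    run_path,
)
from .material import MaterialParams, default_niti
from .quadrature import MicroplaneSystem

__all__ = [
    "GeometryMap",
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "force_torque_to_stress",
    "build_scenario",
    "run_study",
    "SUMMARY_COLUMNS",
]

SCENARIO_NAMES = (
    "pseudoelastic_tension",
    "tension_torsion",
    "sme_tension_torsion",
    "thermal_recovery",
    "temperature_sweep",
)

SUMMARY_COLUMNS = [
    "force_N",
    "torque_Nmm",
    "temperature_C",
    "peak_vm_MPa",
    "max_principal_strain",
    "residual_strain",
    "loop_area_MPa",
]


@dataclass(frozen=True)
class GeometryMap:
    """Material-point surrogate for the load-bearing cross-section.

    ``area`` (mm^2) converts force to axial stress; ``shear_factor``
    (mm^-3, an r/J ratio) converts torque to shear stress.  N/mm^2 = MPa,
    so the units close without further factors.
    """

    area: float = 0.25
    shear_factor: float = 1.28

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"area must be positive, got {self.area}")
        if self.shear_factor <= 0:
            raise ValueError(f"shear_factor must be positive, got {self.shear_factor}")


def force_torque_to_stress(
    F: float, M: float, geom: GeometryMap
) -> tuple[float, float]:
    """Map force (N) and torque (N mm) to (axial, shear) stress in MPa."""
    if F < 0 or M < 0:
        raise ValueError(f"force and torque must be >= 0, got F={F}, M={M}")
    return F / geom.area, M * geom.shear_factor


@dataclass(frozen=True)
class ScenarioSpec:
    """A named load program, possibly with one swept variable.

    ``recovery_temperature`` is only used by ``thermal_recovery`` (the
    stress-free heating target, which must exceed ``Af``).
    """

    name: str
    force: float | list = 0.0
    torque: float | list = 0.0
    temperature: float | list = 38.0
    geometry: GeometryMap = field(default_factory=GeometryMap)
    steps: int = DEFAULT_STEPS_PER_SEGMENT
    recovery_temperature: float | None = None

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        n_lists = sum(
            isinstance(v, (list, tuple))
            for v in (self.force, self.torque, self.temperature)
        )
        if n_lists > 1:
            raise ValueError(
                "at most one of force/torque/temperature may be a list (the swept variable)"
            )
        if self.name == "temperature_sweep" and not isinstance(
            self.temperature, (list, tuple)
        ):
            raise ValueError("temperature_sweep requires a list of temperatures")
        if self.steps < 1:
            raise ValueError(f"steps must be >= 1, got {self.steps}")

    def conditions(self) -> list[tuple[float, float, float]]:
        """Expand the swept variable into (force, torque, temperature) triples."""
        forces = self.force if isinstance(self.force, (list, tuple)) else [self.force]
        torques = self.torque if isinstance(self.torque, (list, tuple)) else [self.torque]
        temps = (
            self.temperature
            if isinstance(self.temperature, (list, tuple))
            else [self.temperature]
        )
        return [
            (float(F), float(M), float(T)) for F in forces for M in torques for T in temps
        ]


def _check_regime(name: str, T: float, params: MaterialParams) -> None:
    if name in ("pseudoelastic_tension", "tension_torsion"):
        if T <= params.Af:
            raise ValueError(
                f"{name} is a pseudoelastic scenario and requires T > Af "
                f"({params.Af} degC), got T={T}"
            )
    elif name in ("sme_tension_torsion", "thermal_recovery"):
        if not (params.Ms <= T < params.As):
            raise ValueError(
                f"{name} is a shape-memory-effect scenario and requires "
                f"Ms <= T < As ({params.Ms}..{params.As} degC), got T={T}"
            )
    else:  # temperature_sweep: any supported temperature
        if T < params.Ms:
            raise ValueError(
                f"temperature_sweep requires T >= Ms ({params.Ms} degC), got T={T}"
            )


def _single_path(
    name: str,
    F: float,
    M: float,
    T: float,
    geom: GeometryMap,
    steps: int,
    recovery_T: float | None,
    params: MaterialParams,
) -> LoadPath:
    _check_regime(name, T, params)
    s, tau = force_torque_to_stress(F, M, geom)
    peak = StressPoint.uniaxial(s, T, tau=tau)
    zero = StressPoint.uniaxial(0.0, T)
    segments = [(peak, steps), (zero, steps)]
    if name == "thermal_recovery":
        if recovery_T is None or recovery_T <= params.Af:
            raise ValueError(
                "thermal_recovery requires recovery_temperature > Af "
                f"({params.Af} degC), got {recovery_T}"
            )
        segments.append((StressPoint.uniaxial(0.0, recovery_T), steps))
    return LoadPath(segments=segments)


def build_scenario(
    spec: ScenarioSpec, params: MaterialParams | None = None
) -> LoadPath | list[LoadPath]:
    """Compile a scenario to a :class:`LoadPath` (a list when swept).

    Every path is a proportional load--unload ramp at fixed temperature
    (tension and torsion ramped together; the phasing of combined loads is
    taken as proportional), plus a stress-free heating segment for
    ``thermal_recovery``.
    """
    params = params or default_niti()
    paths = [
        _single_path(
            spec.name, F, M, T, spec.geometry, spec.steps,
            spec.recovery_temperature, params,
        )
        for F, M, T in spec.conditions()
    ]
    swept = any(
        isinstance(v, (list, tuple))
        for v in (spec.force, spec.torque, spec.temperature)
    )
    return paths if swept else paths[0]


def run_study(
    specs: ScenarioSpec | list[ScenarioSpec],
    params: MaterialParams | None = None,
    system: MicroplaneSystem | None = None,
) -> pd.DataFrame:
    """Run scenario(s) and summarise one row per load case.

    Columns: force (N), torque (N mm), temperature (deg C), peak von
    Mises stress (MPa), maximum principal strain over the path, residual
    strain (Frobenius norm of the final total strain) and hysteresis-loop
    area (stress work, MPa).  Deterministic: identical inputs give
    identical rows.
    """
    from .quadrature import build_microplane_system

    params = params or default_niti()
    system = system or build_microplane_system()
    if isinstance(specs, ScenarioSpec):
        specs = [specs]

    rows = []
    for spec in specs:
        for F, M, T in spec.conditions():
            path = _single_path(
                spec.name, F, M, T, spec.geometry, spec.steps,
                spec.recovery_temperature, params,
            )
            result = run_path(path, params, system)
            rows.append(
                {
                    "force_N": F,
                    "torque_Nmm": M,
                    "temperature_C": T,
                    "peak_vm_MPa": float(result.array("von_mises_stress").max()),
                    "max_principal_strain": float(
                        result.array("max_principal_strain").max()
                    ),
                    "residual_strain": float(
                        np.linalg.norm(result.steps[-1].eps_total)
                    ),
                    "loop_area_MPa": loop_area(result),
                }
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
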