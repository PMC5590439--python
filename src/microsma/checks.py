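"""Self-validation oracle suite.

A handful of closed-form identities the model must satisfy regardless of
calibration: quadrature moment identities, the uniaxial Hooke /
recoverable-strain closed form, pseudoelastic loop closure and
shape-memory recovery.  Used by the ``validate`` CLI subcommand and
available programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .driver import LoadPath, StressPoint, elastic_strain, run_path, transformation_strain
from .material import MaterialParams, default_niti, elastic_modulus
from .quadrature import MicroplaneSystem, build_microplane_system

__all__ = ["CheckResult", "run_oracle_suite"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    value: float
    tolerance: float

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return f"{status}  {self.name}: {self.value:.3e} (tol {self.tolerance:.0e})"


def run_oracle_suite(
    params: MaterialParams | None = None,
    system: MicroplaneSystem | None = None,
) -> list[CheckResult]:
    params = params or default_niti()
    system = system or build_microplane_system()
    checks: list[CheckResult] = []

    # quadrature moment identities
    n, w = system.normals, system.weights
    second = np.abs(3 * np.einsum("k,ki,kj->ij", w, n, n) - np.eye(3)).max()
    fourth = abs(3 * np.sum(w * n[:, 2] ** 4) - 0.6)
    checks.append(CheckResult("second-moment identity 3*sum(w n x n) = I", second < 1e-12, second, 1e-12))
    checks.append(CheckResult("fourth-moment identity 3*sum(w n3^4) = 3/5", fourth < 1e-12, fourth, 1e-12))

    # uniaxial closed form: axial sigma/E(xi) + eps*, lateral -nu sigma/E - eps*/2
    s = 100.0
    sigma = np.diag([0.0, 0.0, s])
    worst = 0.0
    for xi in (0.0, 0.3, 1.0):
        E = elastic_modulus(params, xi)
        eps = elastic_strain(sigma, xi, params, system) + transformation_strain(
            sigma, xi, params, system
        )
        worst = max(
            worst,
            abs(eps[2, 2] - (s / E + params.eps_star * xi)),
            abs(eps[0, 0] - (-params.nu * s / E - params.eps_star * xi / 2)),
        )
    checks.append(CheckResult("uniaxial closed-form strain", worst < 1e-10, worst, 1e-10))

    # transformation strain is volume-preserving
    rng = np.random.default_rng(0)
    tr_worst = 0.0
    for _ in range(20):
        a = rng.normal(size=(3, 3)) * 100
        tr_worst = max(
            tr_worst,
            abs(np.trace(transformation_strain(0.5 * (a + a.T), 1.0, params, system))),
        )
    checks.append(CheckResult("transformation strain traceless", tr_worst < 1e-10, tr_worst, 1e-10))

    # pseudoelastic loop closure above Af
    path = LoadPath(
        segments=[
            (StressPoint.uniaxial(550.0, 60.0), 200),
            (StressPoint.uniaxial(0.0, 60.0), 200),
        ]
    )
    res = run_path(path, params, system)
    residual = float(np.linalg.norm(res.steps[-1].eps_total))
    checks.append(CheckResult("pseudoelastic loop closure at 60 degC", residual < 1e-8, residual, 1e-8))

    # shape-memory effect: residual strain below As, recovered above Af
    path = LoadPath(
        segments=[
            (StressPoint.uniaxial(300.0, 28.0), 200),
            (StressPoint.uniaxial(0.0, 28.0), 200),
            (StressPoint.uniaxial(0.0, 38.0), 200),
        ]
    )
    res = run_path(path, params, system)
    unload_idx = 400  # end of the unloading segment (step 0 + 2 x 200)
    sme_residual = float(np.linalg.norm(res.steps[unload_idx].eps_total))
    recovered = float(np.linalg.norm(res.steps[-1].eps_total))
    checks.append(
        CheckResult("SME residual strain after unload at 28 degC > 0", sme_residual > 1e-3, sme_residual, 1e-3)
    )
    checks.append(
        CheckResult("SME residual recovered by heating above Af", recovered < 1e-8, recovered, 1e-8)
    )
    return checks
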