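"""Unit-sphere quadrature and per-plane projection tensors.

The microplane framework resolves the macroscopic stress tensor onto many
oriented planes ("microplanes") through a point and recovers macroscopic
strain by integrating per-plane responses over the unit sphere.  With the
convention used here the spherical average ``(3/(4 pi)) \\int f dphi`` is
discretised as ``3 sum_i w_i f(n_i)`` with weights normalised to
``sum w_i = 1`` over the full sphere.

Two schemes are provided:

``bazant_oh_42``
    The 42-point symmetric Gaussian rule (21 directions per hemisphere
    plus antipodes) of the Bazant--Oh family, shipped as a static table.
    The orbit parameters and weights are the exact solution of the moment
    conditions through polynomial degree 7, so all second- and
    fourth-order tensor moments are reproduced to machine precision.

``dense_grid``
    A product rule (Gauss--Legendre in the polar cosine x midpoint in
    azimuth) used as a brute-force oracle at configurable resolution.

Per-plane quantities for a unit normal ``n`` and symmetric stress
``sigma``:

* normal projection tensor ``N = n (x) n`` with ``sigma_N = N : sigma``;
* shear direction ``t``: the normalised in-plane part of the traction
  ``sigma . n``;
* shear projection tensor ``T = (n (x) t + t (x) n)/2`` with
  ``sigma_T = T : sigma`` the resolved shear magnitude.

``T`` is traceless (``t`` is perpendicular to ``n``), which is what makes
the transformation strain volume-preserving.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Microplane",
    "MicroplaneSystem",
    "build_microplane_system",
    "normal_tensor",
    "shear_direction",
    "shear_tensor",
    "integrate_sphere",
    "transformation_direction",
]

#: Resolved-shear magnitudes below ``_SHEAR_TOL * max(|sigma|, 1 MPa)`` are
#: treated as exactly zero shear (the shear direction is then undefined and
#: its contribution genuinely vanishes).
_SHEAR_TOL = 1e-9

_UNIT_TOL = 1e-12


def _check_symmetric(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (3, 3):
        raise ValueError(f"stress tensor must be 3x3, got shape {sigma.shape}")
    scale = max(np.abs(sigma).max(), 1.0)
    if np.abs(sigma - sigma.T).max() > 1e-9 * scale:
        raise ValueError("stress tensor must be symmetric")
    return sigma


def _check_unit(n: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if n.shape != (3,):
        raise ValueError(f"normal must be a 3-vector, got shape {n.shape}")
    if abs(np.dot(n, n) - 1.0) > 1e-9:
        raise ValueError(f"normal must be a unit vector, |n| = {np.linalg.norm(n)}")
    return n


@dataclass(frozen=True)
class Microplane:
    """A single oriented plane: unit normal ``n`` and quadrature weight ``w``."""

    n: np.ndarray
    w: float


@dataclass(frozen=True)
class MicroplaneSystem:
    """A set of microplane normals with quadrature weights.

    ``normals`` is ``(m, 3)``, ``weights`` is ``(m,)`` with
    ``sum(weights) == 1`` over the full sphere; the point set is symmetric
    under ``n -> -n`` so all even integrands are handled exactly by
    construction.
    """

    normals: np.ndarray
    weights: np.ndarray
    scheme_name: str
    #: Uniaxial calibration constant of the discrete shear-direction
    #: integral: ``1 / (3 sum w |n3| sqrt(1 - n3^2))``.  The continuum
    #: value of that integral is exactly 1; multiplying the discrete
    #: transformation-direction tensor by this constant restores the
    #: defining property of the maximum recoverable strain (axial
    #: transformation strain at full martensite equals eps_star exactly).
    shear_calibration: float = field(init=False)

    def __post_init__(self) -> None:
        n3 = self.normals[:, 2]
        raw = 3.0 * float(np.sum(self.weights * np.abs(n3) * np.sqrt(np.clip(1 - n3 * n3, 0, None))))
        object.__setattr__(self, "shear_calibration", 1.0 / raw)

    @property
    def planes(self) -> list[Microplane]:
        return [Microplane(n, float(w)) for n, w in zip(self.normals, self.weights)]

    def __len__(self) -> int:
        return len(self.weights)


def _load_bazant_oh_42() -> tuple[np.ndarray, np.ndarray]:
    ref = importlib.resources.files("microsma.data") / "bazant_oh_42.txt"
    rows = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split()])
    table = np.array(rows)
    if table.shape != (21, 4):
        raise RuntimeError(f"quadrature table corrupt: shape {table.shape}")
    normals = np.vstack([table[:, :3], -table[:, :3]])
    weights = np.concatenate([table[:, 3], table[:, 3]])
    return normals, weights


def _dense_grid(n_polar: int, n_azimuth: int) -> tuple[np.ndarray, np.ndarray]:
    u, gw = np.polynomial.legendre.leggauss(n_polar)
    phi = 2.0 * np.pi * (np.arange(n_azimuth) + 0.5) / n_azimuth
    st = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
    normals = np.empty((n_polar * n_azimuth, 3))
    normals[:, 0] = np.outer(st, np.cos(phi)).ravel()
    normals[:, 1] = np.outer(st, np.sin(phi)).ravel()
    normals[:, 2] = np.repeat(u, n_azimuth)
    weights = np.repeat(gw / (2.0 * n_azimuth), n_azimuth)
    return normals, weights


def build_microplane_system(
    scheme: str = "bazant_oh_42",
    resolution: tuple[int, int] | None = None,
) -> MicroplaneSystem:
    """Build a quadrature system on the unit sphere.

    Parameters
    ----------
    scheme : {"bazant_oh_42", "dense_grid"}
        ``bazant_oh_42`` is the production rule; ``dense_grid`` is the
        brute-force oracle.
    resolution : (n_polar, n_azimuth), optional
        Only meaningful for ``dense_grid``; defaults to ``(64, 128)``.
    """
    if scheme == "bazant_oh_42":
        if resolution is not None:
            raise ValueError("bazant_oh_42 has a fixed point set; resolution is not configurable")
        normals, weights = _load_bazant_oh_42()
    elif scheme == "dense_grid":
        n_polar, n_azimuth = resolution if resolution is not None else (64, 128)
        if n_polar < 2 or n_azimuth < 4:
            raise ValueError(f"dense_grid resolution too coarse: {(n_polar, n_azimuth)}")
        normals, weights = _dense_grid(int(n_polar), int(n_azimuth))
    else:
        raise ValueError(
            f"unknown quadrature scheme {scheme!r}; expected 'bazant_oh_42' or 'dense_grid'"
        )
    return MicroplaneSystem(normals=normals, weights=weights, scheme_name=scheme)


# -- per-plane projections -----------------------------------------------


def normal_tensor(n: np.ndarray) -> np.ndarray:
    """Normal projection tensor ``N = n (x) n`` (symmetric, trace 1)."""
    n = _check_unit(n)
    return np.outer(n, n)


def _shear_vector(n: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """In-plane (shear) part of the traction vector ``sigma . n``."""
    traction = sigma @ n
    return traction - (n @ traction) * n


def shear_direction(n: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Unit shear direction ``t`` on plane ``n`` under stress ``sigma``.

    ``t`` is the normalised in-plane component of the traction vector;
    it satisfies ``t . n = 0``.  When the resolved shear magnitude is
    negligible (traction parallel to ``n``, e.g. hydrostatic stress) the
    zero vector is returned.
    """
    n = _check_unit(n)
    sigma = _check_symmetric(sigma)
    s = _shear_vector(n, sigma)
    mag = np.linalg.norm(s)
    if mag < _SHEAR_TOL * max(np.abs(sigma).max(), 1.0):
        return np.zeros(3)
    return s / mag


def shear_tensor(n: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Shear projection tensor ``T = (n (x) t + t (x) n) / 2``.

    Symmetric and traceless; ``T : sigma`` equals the resolved shear
    magnitude on the plane.  The zero tensor is returned in the
    degenerate (zero-shear) case.
    """
    t = shear_direction(n, sigma)
    n = np.asarray(n, dtype=float)
    return 0.5 * (np.outer(n, t) + np.outer(t, n))


def integrate_sphere(system: MicroplaneSystem, fn) -> np.ndarray:
    """Discretise ``(3/(4 pi)) \\int f dphi`` as ``3 sum_i w_i f(n_i)``.

    ``fn`` maps a unit normal to a scalar or array; all planes of the
    system are evaluated.
    """
    acc = None
    for n, w in zip(system.normals, system.weights):
        val = np.asarray(fn(n), dtype=float) * w
        acc = val if acc is None else acc + val
    return 3.0 * acc


# -- batched sphere integrals used by the constitutive equations ---------


def _shear_tensors_batched(normals: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Unit shear projection tensors ``T(n_i, sigma)`` for all planes, (m,3,3)."""
    traction = normals @ sigma  # (m, 3)
    sig_n = np.einsum("mi,mi->m", normals, traction)
    shear = traction - sig_n[:, None] * normals
    mag = np.linalg.norm(shear, axis=1)
    tol = _SHEAR_TOL * max(np.abs(sigma).max(), 1.0)
    safe = np.where(mag > tol, mag, 1.0)
    t = np.where((mag > tol)[:, None], shear / safe[:, None], 0.0)
    return 0.5 * (np.einsum("mi,mj->mij", normals, t) + np.einsum("mi,mj->mij", t, normals))


def resolved_stress_integral(system: MicroplaneSystem, sigma: np.ndarray) -> np.ndarray:
    """``3 sum w (sigma_N N + sigma_T T)``: the sphere integral of the
    stress resolved back onto each plane.

    Algebraically the integrand collapses to ``sym(n (x) (sigma . n))``, a
    second-degree polynomial in ``n``, so any scheme with exact second
    moments returns ``sigma`` itself to machine precision.  This is the
    integral through which the elastic strain reduces to isotropic Hooke
    behaviour.
    """
    sigma = _check_symmetric(sigma)
    traction = system.normals @ sigma
    outer = np.einsum("mi,mj->mij", system.normals, traction)
    integrand = 0.5 * (outer + np.transpose(outer, (0, 2, 1)))
    return 3.0 * np.einsum("m,mij->ij", system.weights, integrand)


def transformation_direction(
    system: MicroplaneSystem, sigma: np.ndarray, calibrated: bool = True
) -> np.ndarray:
    """Transformation-strain direction tensor: the sphere integral of the
    unit shear projection ``T`` under the current stress.

    Under uniaxial tension the continuum integral equals
    ``diag(-1/2, -1/2, 1)``: full transformation produces the maximum
    recoverable axial strain with volume-preserving lateral contraction.
    The unit shear field is not polynomial in ``n`` (it carries ``|.|``
    and square-root kinks), so discrete rules carry a systematic bias on
    it; with ``calibrated=True`` (default) the result is scaled by the
    scheme's uniaxial calibration constant so that the uniaxial continuum
    limit is reproduced exactly.  Returns the zero tensor at (numerically)
    zero stress, where the direction is undefined.
    """
    sigma = _check_symmetric(sigma)
    if np.abs(sigma).max() == 0.0:
        return np.zeros((3, 3))
    tensors = _shear_tensors_batched(system.normals, sigma)
    out = 3.0 * np.einsum("m,mij->ij", system.weights, tensors)
    if calibrated:
        out = out * system.shear_calibration
    return out
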