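"""NiTi material calibration and the stress--temperature phase diagram.

The alloy has two solid phases: austenite (stable at high temperature / low
stress) and detwinned martensite (stabilised by stress).  Transformation
between the two is driven by the von Mises effective stress and temperature;
on a stress--temperature diagram both the forward (austenite -> martensite)
and reverse (martensite -> austenite) transformations occupy bands whose
edges shift linearly with temperature at the Clausius--Clapeyron rates
``CM`` and ``CA``.

All temperatures are handled in degrees Celsius and all stresses in MPa.
Only the stress-induced branch of the phase diagram above ``Ms`` is
modelled: every load case this package targets sits at or above room
temperature, where cooling-induced (twinned) martensite cannot form.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path


class RegimeError(ValueError):
    """Raised when an operation is asked for outside its supported regime."""


#: JSON field order for (de)serialisation; ``nu`` is an implementation
#: default (0.33, typical polycrystalline NiTi) and not part of the
#: published calibration.
_FIELDS = (
    "Ea", "Em", "Mf", "Ms", "As", "Af",
    "CM", "CA", "sigma_s_cr", "sigma_f_cr", "eps_star", "nu",
)


@dataclass(frozen=True)
class MaterialParams:
    """Calibration of a NiTi shape-memory alloy.

    Parameters
    ----------
    Ea, Em : float
        Austenite / martensite elastic moduli, MPa.
    Mf, Ms, As, Af : float
        Martensite finish/start and austenite start/finish transformation
        temperatures at zero stress, deg C.  Must satisfy
        ``Mf < Ms <= As < Af``.
    CM, CA : float
        Clausius--Clapeyron slopes of the forward / reverse transformation
        bands, MPa per deg C.
    sigma_s_cr, sigma_f_cr : float
        Critical start / finish stresses of the forward (detwinning) band
        at ``T = Ms``, MPa.
    eps_star : float
        Axial maximum recoverable transformation strain (dimensionless):
        the axial inelastic strain at full transformation under uniaxial
        tension.
    nu : float
        Poisson ratio, dimensionless.
    """

    Ea: float
    Em: float
    Mf: float
    Ms: float
    As: float
    Af: float
    CM: float
    CA: float
    sigma_s_cr: float
    sigma_f_cr: float
    eps_star: float
    nu: float = 0.33

    def __post_init__(self) -> None:
        if not (self.Mf < self.Ms <= self.As < self.Af):
            raise ValueError(
                "transformation temperatures must satisfy Mf < Ms <= As < Af, "
                f"got Mf={self.Mf}, Ms={self.Ms}, As={self.As}, Af={self.Af}"
            )
        if not (0 < self.sigma_s_cr < self.sigma_f_cr):
            raise ValueError(
                "critical stresses must satisfy 0 < sigma_s_cr < sigma_f_cr, "
                f"got sigma_s_cr={self.sigma_s_cr}, sigma_f_cr={self.sigma_f_cr}"
            )
        for name in ("CM", "CA", "Ea", "Em"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.eps_star < 0.2):
            raise ValueError(f"eps_star must lie in (0, 0.2), got {self.eps_star}")
        if not (0 < self.nu < 0.5):
            raise ValueError(f"nu must lie in (0, 0.5), got {self.nu}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "MaterialParams":
        unknown = set(data) - set(_FIELDS)
        if unknown:
            raise ValueError(f"unknown material parameter key(s): {sorted(unknown)}")
        missing = set(_FIELDS) - {"nu"} - set(data)
        if missing:
            raise ValueError(f"missing material parameter key(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MaterialParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_niti() -> MaterialParams:
    """The packaged NiTi calibration (moduli in MPa, temperatures in deg C).

    Note the unusual ordering ``Ea < Em`` (austenite softer than
    martensite); it is kept exactly as calibrated, and both moduli are
    plain config fields so a user may swap them.
    """
    return MaterialParams(
        Ea=26_300.0,
        Em=63_000.0,
        Mf=9.0,
        Ms=18.4,
        As=29.3,
        Af=37.0,
        CM=8.0,
        CA=13.8,
        sigma_s_cr=100.0,
        sigma_f_cr=170.0,
        eps_star=0.067,
        nu=0.33,
    )


def elastic_modulus(params: MaterialParams, xi: float) -> float:
    """Mixture elastic modulus ``E(xi) = Ea + xi (Em - Ea)``, MPa.

    Linear (Reuss-style in the martensite fraction ``xi``), continuous at
    both phase ends.
    """
    if not (0.0 <= xi <= 1.0) or math.isnan(xi):
        raise ValueError(f"martensite fraction must lie in [0, 1], got {xi}")
    return params.Ea + xi * (params.Em - params.Ea)


def forward_band(params: MaterialParams, T: float) -> tuple[float, float]:
    """Forward (austenite -> martensite) stress band at temperature ``T``.

    Returns ``(sigma_start, sigma_finish)`` in MPa: the effective-stress
    levels at which stress-induced transformation starts and completes,

        sigma_start  = sigma_s_cr + CM (T - Ms)
        sigma_finish = sigma_f_cr + CM (T - Ms)

    Only ``T >= Ms`` is supported (no twinned-martensite branch).
    """
    if math.isnan(T):
        raise ValueError("temperature is NaN")
    if T < params.Ms:
        raise RegimeError(
            f"forward band is only defined for T >= Ms ({params.Ms} degC), got T={T}"
        )
    shift = params.CM * (T - params.Ms)
    return params.sigma_s_cr + shift, params.sigma_f_cr + shift


def reverse_band(params: MaterialParams, T: float) -> tuple[float, float] | None:
    """Reverse (martensite -> austenite) stress band at temperature ``T``.

    Returns ``(sigma_low, sigma_high)`` in MPa with

        sigma_low  = max(CA (T - Af), 0)
        sigma_high = CA (T - As)

    Unloading through this band (or heating across it at fixed stress)
    drives the martensite fraction back toward zero.  Below ``As`` no
    reverse transformation is possible and ``None`` is returned.
    """
    if math.isnan(T):
        raise ValueError("temperature is NaN")
    if T <= params.As:
        return None
    return max(params.CA * (T - params.Af), 0.0), params.CA * (T - params.As)
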