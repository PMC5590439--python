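"""Martensite-fraction evolution with hysteresis memory.

The martensite volume fraction ``xi`` follows cosine-shaped transformation
kinetics in the Brinson (1993) form, driven by the von Mises effective
stress and temperature.  Each monotone loading branch is an *event*: the
fraction at the step where a transformation first activates is frozen as
``xi0`` and the cosine formula interpolates between ``xi0`` and the
saturated value while the effective stress traverses the corresponding
band of the phase diagram.

Forward (austenite -> martensite), active while the effective stress is
non-decreasing::

    xi = (1 - xi0)/2 * cos[ pi/(sigma_s_cr - sigma_f_cr)
                            * (sigma_eff - sigma_f_cr - CM (T - Ms)) ]
         + (1 + xi0)/2

Reverse (martensite -> austenite), active above ``As`` while the effective
stress is non-increasing or the temperature is rising at fixed stress::

    xi = xi0/2 * ( cos[ pi/(Af - As) * (T - As - sigma_eff/CA) ] + 1 )

Both cosine arguments are clamped to ``[0, pi]``, which reproduces the
saturation rules (``xi = 1`` above the forward finish stress, ``xi = 0``
below the reverse band at ``T >= Af``) and keeps ``xi`` continuous at band
entry.  Only stress-induced (detwinned) martensite is tracked; the model
is restricted to ``T >= Ms`` where no cooling-induced martensite forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .material import MaterialParams, RegimeError

__all__ = ["TransformationState", "effective_stress", "update_martensite_fraction"]


@dataclass(frozen=True)
class TransformationState:
    """Path-dependent transformation state.

    ``xi`` is the current martensite volume fraction, ``xi_event_start``
    the fraction frozen at the start of the active transformation event,
    ``mode`` one of ``neutral | forward | reverse``; the last seen
    effective stress and temperature provide the loading-direction memory.
    """

    xi: float = 0.0
    xi_event_start: float = 0.0
    mode: str = "neutral"
    last_sigma_eff: float = 0.0
    last_T: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi <= 1.0 and 0.0 <= self.xi_event_start <= 1.0):
            raise ValueError(
                f"martensite fractions must lie in [0, 1], got xi={self.xi}, "
                f"xi_event_start={self.xi_event_start}"
            )
        if self.mode not in ("neutral", "forward", "reverse"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "forward" and self.xi < self.xi_event_start:
            raise ValueError("forward event requires xi >= xi_event_start")
        if self.mode == "reverse" and self.xi > self.xi_event_start:
            raise ValueError("reverse event requires xi <= xi_event_start")


def effective_stress(sigma: np.ndarray) -> float:
    """Von Mises equivalent stress of a symmetric stress tensor, MPa.

    For a state with only an axial stress ``s`` and one shear component
    ``tau`` this reduces exactly to ``sqrt(s^2 + 3 tau^2)``, the scalar
    that drives transformation under combined tension--torsion.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (3, 3):
        raise ValueError(f"stress tensor must be 3x3, got shape {sigma.shape}")
    if np.isnan(sigma).any():
        raise ValueError("stress tensor contains NaN")
    scale = max(np.abs(sigma).max(), 1.0)
    if np.abs(sigma - sigma.T).max() > 1e-9 * scale:
        raise ValueError("stress tensor must be symmetric")
    dev = sigma - np.trace(sigma) / 3.0 * np.eye(3)
    return float(np.sqrt(1.5 * np.sum(dev * dev)))


def _forward_fraction(xi0: float, sigma_eff: float, T: float, p: MaterialParams) -> float:
    arg = math.pi / (p.sigma_s_cr - p.sigma_f_cr) * (
        sigma_eff - p.sigma_f_cr - p.CM * (T - p.Ms)
    )
    arg = min(max(arg, 0.0), math.pi)
    return (1.0 - xi0) / 2.0 * math.cos(arg) + (1.0 + xi0) / 2.0


def _reverse_fraction(xi0: float, sigma_eff: float, T: float, p: MaterialParams) -> float:
    arg = math.pi / (p.Af - p.As) * (T - p.As - sigma_eff / p.CA)
    arg = min(max(arg, 0.0), math.pi)
    return xi0 / 2.0 * (math.cos(arg) + 1.0)


def update_martensite_fraction(
    state: TransformationState,
    sigma_eff: float,
    T: float,
    params: MaterialParams,
) -> TransformationState:
    """Advance the transformation state to a new (effective stress, T) point.

    The loading direction is read from the sign of the effective-stress
    increment; a pure temperature rise at constant stress counts as
    reverse driving (this is what recovers residual strain on stress-free
    heating above ``Af``).  Within an event ``xi`` is kept monotone:
    non-decreasing for forward, non-increasing for reverse.
    """
    if math.isnan(sigma_eff) or math.isnan(T):
        raise ValueError("sigma_eff and T must be finite numbers")
    if sigma_eff < 0:
        raise ValueError(f"effective stress must be >= 0, got {sigma_eff}")
    if T < params.Ms:
        raise RegimeError(
            f"kinetics only supported for T >= Ms ({params.Ms} degC), got T={T}"
        )

    d_sig = sigma_eff - state.last_sigma_eff
    d_T = 0.0 if state.last_T is None else T - state.last_T

    if d_sig > 0.0:
        drive = "forward"
    elif d_sig < 0.0:
        drive = "reverse"
    elif d_T > 0.0:
        drive = "reverse"
    else:
        drive = "neutral"

    # reverse transformation needs T > As; otherwise the drive has nothing
    # to act on (this is what locks in residual martensite below As)
    if drive == "reverse" and T <= params.As:
        drive = "neutral"

    xi = state.xi
    mode = drive
    xi0 = state.xi_event_start if drive == state.mode else state.xi

    if drive == "forward":
        xi = min(max(xi, _forward_fraction(xi0, sigma_eff, T, params)), 1.0)
    elif drive == "reverse":
        xi = max(min(xi, _reverse_fraction(xi0, sigma_eff, T, params)), 0.0)

    return replace(
        state,
        xi=xi,
        xi_event_start=xi0,
        mode=mode,
        last_sigma_eff=sigma_eff,
        last_T=T,
    )
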