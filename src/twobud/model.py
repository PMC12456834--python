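"""Core two-bud auxin-efflux competition model.

Two axillary buds on a stem explant compete to establish canalized auxin
transport into the shared stem. Each bud's auxin efflux (``E`` for the top
bud, ``F`` for the bottom) evolves under three influences: a basal efflux
rate ``v0``, a positive Hill-type feedback of efflux on itself (the
canalization feedback), and linear removal at rate ``mu``. The two buds
inhibit each other through the shared stem sink: the Hill threshold of each
bud's feedback rises with the combined efflux ``D * (E + F)``.

Bud lengths ``N`` and ``M`` grow at a rate given by a second Hill function
of the bud's own efflux, so a bud only elongates appreciably once its efflux
has switched to the high (canalized) branch.

All symbols carry the model's native units: efflux in arbitrary efflux
units, lengths in model length units, time in simulation time steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "ExplantState",
    "DEFAULT_PARAMS",
    "DEFAULT_INIT",
    "efflux_rates",
    "growth_rates",
    "efflux_jacobian",
    "efflux_upper_bound",
]


class ModelValidationError(ValueError):
    """Raised when a state or parameter set violates the model's invariants."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate and shape constants of the efflux and growth equations.

    Parameters
    ----------
    v0 : basal auxin efflux rate (efflux units per time step). Non-polar
        efflux out of the bud; the axis hypothesized to be lowered by BRC1.
    v : maximum feedback-driven efflux rate (efflux units per time step).
    S : efficiency of feedback-driven efflux (dimensionless multiplier on
        the bud's own efflux inside the Hill term).
    n : Hill exponent of the efflux feedback (>= 1).
    K : Hill threshold offset (efflux units, > 0).
    D : strength of mutual inhibition through the shared stem sink
        (dimensionless).
    mu : linear efflux decay rate (per time step, > 0); conceptually PIN1
        removal from the plasma membrane plus auxin degradation.
    Q : growth half-saturation efflux (efflux units, > 0).
    m : growth Hill exponent (>= 1).
    eta : noise scale (dimensionless, >= 0); 0 means deterministic.
    """

    v0: float = 0.09
    v: float = 1.0
    S: float = 1.5
    n: float = 4.0
    K: float = 0.1125
    D: float = 0.45
    mu: float = 0.6
    Q: float = 0.28
    m: float = 10.0
    eta: float = 0.03

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ModelValidationError(f"parameter {f.name} must be finite, got {value!r}")
            if value < 0:
                raise ModelValidationError(f"parameter {f.name} must be >= 0, got {value!r}")
        if self.n < 1 or self.m < 1:
            raise ModelValidationError("Hill exponents n and m must be >= 1")
        if self.mu <= 0:
            raise ModelValidationError("mu must be > 0 (required for bounded efflux)")
        if self.Q <= 0:
            raise ModelValidationError("Q must be > 0")
        if self.K <= 0:
            # K = 0 makes the Hill term 0/0 at E = F = 0; require K > 0.
            raise ModelValidationError("K must be > 0")

    def with_updates(self, **updates: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ModelValidationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class ExplantState:
    """Instantaneous state of a simulated 2-node explant.

    ``E``/``F`` are top/bottom bud auxin efflux, ``N``/``M`` the
    corresponding bud lengths, ``t`` the time in time steps.
    """

    E: float = 0.01
    F: float = 0.01
    N: float = 0.1
    M: float = 0.1
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E", "F", "N", "M", "t"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ModelValidationError(f"state {name} must be finite, got {value!r}")
            if value < 0:
                raise ModelValidationError(f"state {name} must be >= 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.F, self.N, self.M], dtype=float)


#: Calibrated defaults. The published analysis fixes a single slice of
#: parameter space and sweeps only (v0, mu); these values were calibrated
#: (see docs/methods.md) so that the (v0, mu) plane shows the full
#: both -> both-or-one -> one-only / one-or-neither -> neither region
#: sequence as mu rises and v0 falls, and the canalization switch time
#: decreases with v0.
DEFAULT_PARAMS = ModelParameters()

#: Standard initial condition: both buds dormant with equal low efflux.
DEFAULT_INIT = ExplantState(E=0.01, F=0.01, N=0.1, M=0.1, t=0.0)


def _hill_term(x: np.ndarray, total: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Feedback-driven efflux v * (S x)^n / ((S x)^n + (D total + K)^n)."""
    num = (p.S * np.asarray(x, dtype=float)) ** p.n
    den = num + (p.D * np.asarray(total, dtype=float) + p.K) ** p.n
    return p.v * num / den


def efflux_rates(state: ExplantState, params: ModelParameters) -> tuple[float, float]:
    """Right-hand sides (dE/dt, dF/dt) of the efflux equations.

    Each bud gains efflux at the basal rate ``v0`` plus the canalization
    feedback, and loses it at ``mu`` times its own efflux. The feedback
    threshold ``D * (E + F) + K`` couples the buds: a partner exporting
    strongly raises the threshold and suppresses the feedback.
    """
    dE, dF = efflux_rates_arrays(
        np.asarray(state.E, dtype=float), np.asarray(state.F, dtype=float), params
    )
    return float(dE), float(dF)


def efflux_rates_arrays(E: np.ndarray, F: np.ndarray, params: ModelParameters):
    """Vectorized efflux right-hand sides for array-valued ``E``, ``F``."""
    total = E + F
    dE = params.v0 + _hill_term(E, total, params) - params.mu * E
    dF = params.v0 + _hill_term(F, total, params) - params.mu * F
    return dE, dF


def growth_rates(state: ExplantState, params: ModelParameters) -> tuple[float, float]:
    """Right-hand sides (dN/dt, dM/dt) of the growth equations.

    Growth rate is a Hill function of the bud's own efflux with
    half-saturation ``Q`` and exponent ``m``; it lies in [0, 1).
    """
    dN = growth_rate_of_efflux(np.asarray(state.E, dtype=float), params)
    dM = growth_rate_of_efflux(np.asarray(state.F, dtype=float), params)
    return float(dN), float(dM)


def growth_rate_of_efflux(x: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Growth rate x^m / (Q^m + x^m) for array-valued efflux ``x``."""
    xm = np.asarray(x, dtype=float) ** params.m
    return xm / (params.Q**params.m + xm)


def efflux_jacobian(E: float, F: float, params: ModelParameters) -> np.ndarray:
    """2x2 Jacobian of (dE/dt, dF/dt) with respect to (E, F).

    With ``h = (S x)^n`` and ``g = (D (E+F) + K)^n`` the Hill term is
    ``v h / (h + g)``; its partials follow from the quotient rule. At a
    symmetric point the matrix is bisymmetric (equal diagonal and equal
    off-diagonal entries).
    """
    return efflux_jacobian_arrays(
        np.asarray(E, dtype=float), np.asarray(F, dtype=float), params
    )


def efflux_jacobian_arrays(E: np.ndarray, F: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Vectorized Jacobian; returns shape ``E.shape + (2, 2)``."""
    p = params
    E = np.asarray(E, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any(E < 0) or np.any(F < 0):
        raise ModelValidationError("efflux values must be >= 0")
    total = E + F
    thresh = p.D * total + p.K  # > 0 since K > 0
    hE = (p.S * E) ** p.n
    hF = (p.S * F) ** p.n
    g = thresh**p.n
    denE = (hE + g) ** 2
    denF = (hF + g) ** 2
    # d/dx (S x)^n = n (S x)^(n-1) S = n hX / x; guard x = 0 (limit is 0 for
    # n > 1, and for n = 1 the derivative is S, handled via the direct form).
    with np.errstate(divide="ignore", invalid="ignore"):
        dhE = np.where(E > 0, p.n * hE / np.where(E > 0, E, 1.0), 0.0)
        dhF = np.where(F > 0, p.n * hF / np.where(F > 0, F, 1.0), 0.0)
    if p.n == 1:
        dhE = np.full_like(E, p.S)
        dhF = np.full_like(F, p.S)
    dg = p.n * g / thresh * p.D  # d g / d(E or F), same for both
    # dE-equation partials
    j00 = p.v * (dhE * g - hE * dg) / denE - p.mu
    j01 = p.v * (-hE * dg) / denE
    # dF-equation partials (swap roles)
    j10 = p.v * (-hF * dg) / denF
    j11 = p.v * (dhF * g - hF * dg) / denF - p.mu
    out = np.stack(
        [np.stack([j00, j01], axis=-1), np.stack([j10, j11], axis=-1)], axis=-2
    )
    return out


def efflux_upper_bound(params: ModelParameters) -> float:
    """Box bound: dE/dt < 0 whenever E > (v0 + v) / mu."""
    return (params.v0 + params.v) / params.mu
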