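"""Parametric gating models for voltage-gated K+ (Shaker-type) channels.

A channel is described phenomenologically: a Boltzmann steady-state
activation curve with first-order (or multi-gate) kinetics, a
voltage-dependent deactivation time constant, and zero or more
first-order inactivation components (N-type ball-and-chain, C-type
pore collapse, or mechanism-unspecified).  These parameter sets are the
generative model behind every synthetic recording in :mod:`kvclamp.vclamp`.

Units throughout: mV, ms, nA, uS (microsiemens), mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Mechanism",
    "SolutionPair",
    "ActivationParams",
    "DeactivationParams",
    "InactComponent",
    "GatingParams",
    "HeteromerMix",
    "InvalidModelError",
    "steady_state_activation",
    "steady_state_availability",
    "kinetic_rates",
    "activation_tau",
    "deactivation_tau",
    "inactivation_tau",
    "mechanistic_gate_params",
    "REFERENCE_K_OUT",
    "REFERENCE_V_ACT",
    "REFERENCE_V_DEACT",
]

#: External K+ concentration (mM) of the standard recording solution at
#: which fixture inactivation time constants are defined.  C-type rates
#: are scaled relative to this condition.
REFERENCE_K_OUT = 2.0

#: Voltage (mV) at which ``tau_act_ref`` is defined.
REFERENCE_V_ACT = 60.0

#: Voltage (mV) at which ``tau_deact_ref`` is defined.
REFERENCE_V_DEACT = -100.0


class InvalidModelError(ValueError):
    """A gating parameter set violates a model invariant."""


class Mechanism(str, Enum):
    """Inactivation mechanism of one kinetic component.

    N-type is the ball-and-chain block by the channel's own N-terminus
    (removed by N-terminal truncation, insensitive to external K+).
    C-type is the slower pore-collapse process (slowed by external K+,
    unaffected by truncation).  ``UNSPECIFIED`` is used for components
    whose mechanism could not be assigned experimentally; it is removed
    by neither truncation nor K+.
    """

    N_TYPE = "N_type"
    C_TYPE = "C_type"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class SolutionPair:
    """Internal/external K+ concentrations (mM) and temperature (K)."""

    k_in: float = 140.0
    k_out: float = 2.0
    temperature: float = 295.0

    def __post_init__(self) -> None:
        if self.k_in <= 0 or self.k_out <= 0:
            raise InvalidModelError("K+ concentrations must be positive")
        if self.temperature <= 0:
            raise InvalidModelError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class ActivationParams:
    """Steady-state and kinetic parameters of voltage activation.

    ``v50_a``/``s_a`` parameterize the Boltzmann open-probability curve;
    ``n_gates`` is the number of independent gates in mechanistic mode
    (produces the sigmoidal activation delay); ``tau_act_ref`` is the
    activation time constant at +60 mV, with e-fold voltage dependence
    ``tau_act_vslope`` (tau grows as the step becomes less depolarized).
    """

    v50_a: float
    s_a: float
    n_gates: int = 4
    tau_act_ref: float = 1.5
    tau_act_vslope: float = 40.0

    def __post_init__(self) -> None:
        if self.s_a <= 0:
            raise InvalidModelError("activation slope s_a must be > 0")
        if self.n_gates < 1:
            raise InvalidModelError("n_gates must be >= 1")
        if self.tau_act_ref <= 0:
            raise InvalidModelError("tau_act_ref must be > 0")


@dataclass(frozen=True)
class DeactivationParams:
    """Closing kinetics: tau at -100 mV and its e-fold voltage dependence.

    tau_deact(V) = tau_deact_ref * exp((V + 100) / tau_deact_vslope),
    i.e. log(tau) is linear in voltage (semi-logarithmic linearity of
    the tail-current time constants).
    """

    tau_deact_ref: float = 5.0
    tau_deact_vslope: float = 40.0

    def __post_init__(self) -> None:
        if self.tau_deact_ref <= 0:
            raise InvalidModelError("tau_deact_ref must be > 0")


@dataclass(frozen=True)
class InactComponent:
    """One first-order inactivation component.

    ``tau_inact`` is the inactivation time constant at +60 mV in the
    reference external K+ (2 mM); ``fraction`` its fractional amplitude;
    ``v50_i``/``s_i`` the steady-state availability Boltzmann;
    ``tau_recovery`` the recovery time constant used below 0 mV.
    ``k_half_external`` (C-type only) is the external K+ concentration
    at which the C-type rate is halved.
    """

    mechanism: Mechanism
    tau_inact: float
    fraction: float
    v50_i: float
    s_i: float
    tau_recovery: float = 50.0
    k_half_external: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise InvalidModelError("fraction must be in (0, 1]")
        if self.tau_inact <= 0 or self.tau_recovery <= 0:
            raise InvalidModelError("inactivation time constants must be > 0")
        if self.s_i <= 0:
            raise InvalidModelError("inactivation slope s_i must be > 0")
        if self.mechanism is Mechanism.C_TYPE and self.k_half_external is None:
            object.__setattr__(self, "k_half_external", 5.0)

    def k_scale(self, k_out: float) -> float:
        """Multiplier on both inactivation and recovery rates at ``k_out``.

        Identity for non-C-type components.  For C-type the rate follows
        k_half / (k_half + k_out), normalized so the stored time
        constants are exact at the 2 mM reference solution.
        """
        if self.mechanism is not Mechanism.C_TYPE:
            return 1.0
        kh = self.k_half_external
        return (kh + REFERENCE_K_OUT) / (kh + k_out)


@dataclass(frozen=True)
class GatingParams:
    """Full parametric description of one channel species."""

    name: str
    g_max: float
    activation: ActivationParams
    deactivation: DeactivationParams = field(default_factory=DeactivationParams)
    inactivation: tuple[InactComponent, ...] = ()
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise InvalidModelError("g_max must be > 0")
        object.__setattr__(self, "inactivation", tuple(self.inactivation))
        total = sum(c.fraction for c in self.inactivation)
        if total > 1 + 1e-12:
            raise InvalidModelError(
                f"inactivation fractions sum to {total:.3f} > 1"
            )

    @property
    def effective_inactivation(self) -> tuple[InactComponent, ...]:
        """Components after applying N-terminal truncation.

        Truncation removes the N-type ball-and-chain; C-type and
        mechanism-unspecified components are untouched.
        """
        if not self.truncated:
            return self.inactivation
        return tuple(
            c for c in self.inactivation if c.mechanism is not Mechanism.N_TYPE
        )

    @property
    def pedestal(self) -> float:
        """Non-inactivating fraction (1 - sum of effective fractions)."""
        return 1.0 - sum(c.fraction for c in self.effective_inactivation)

    def truncate(self) -> "GatingParams":
        """Return the N-terminally truncated construct."""
        return replace(self, name=self.name + "_trunc", truncated=True)


@dataclass(frozen=True)
class HeteromerMix:
    """Mixture of homomeric and heteromeric channel populations.

    Co-expression of a pore-forming subunit with a regulatory subunit
    yields a mix of homomers and heteromers; ``het_fraction`` is the
    fraction of total conductance carried by heteromers.
    """

    homomer: GatingParams
    heteromer: GatingParams
    het_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.het_fraction <= 1:
            raise InvalidModelError("het_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Steady-state curves
# ---------------------------------------------------------------------------

def steady_state_activation(params: ActivationParams, v) -> np.ndarray | float:
    """Boltzmann open probability 1 / (1 + exp(-(v - v50)/s)).

    Strictly increasing in voltage, range (0, 1).
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - params.v50_a) / params.s_a))
    return out if out.ndim else float(out)


def steady_state_availability(components, v) -> np.ndarray | float:
    """Steady-state availability: pedestal plus per-component Boltzmanns.

    ``pedestal + sum_j fraction_j / (1 + exp((v - v50_j)/s_j))``;
    non-increasing in v and -> 1 as v -> -inf.
    """
    components = tuple(components)
    total = sum(c.fraction for c in components)
    if total > 1 + 1e-12:
        raise InvalidModelError("inactivation fractions sum to > 1")
    v = np.asarray(v, dtype=float)
    out = np.full(v.shape, 1.0 - total)
    for c in components:
        out = out + c.fraction / (1.0 + np.exp((v - c.v50_i) / c.s_i))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def activation_tau(params: ActivationParams, v: float) -> float:
    """Activation time constant (ms): tau_ref * exp((60 - v)/vslope)."""
    return params.tau_act_ref * math.exp(
        (REFERENCE_V_ACT - v) / params.tau_act_vslope
    )


def deactivation_tau(params: DeactivationParams, v: float) -> float:
    """Deactivation time constant (ms): tau_ref * exp((v + 100)/vslope)."""
    return params.tau_deact_ref * math.exp(
        (v - REFERENCE_V_DEACT) / params.tau_deact_vslope
    )


def inactivation_tau(component: InactComponent, v: float, k_out: float) -> float:
    """Relaxation time constant of one inactivation component at ``v``.

    Voltage-independent above 0 mV (value at +60 mV is what steady-step
    fits report); below 0 mV the recovery time constant applies.  For
    C-type components both are slowed by external K+.
    """
    base = component.tau_inact if v >= 0.0 else component.tau_recovery
    return base / component.k_scale(k_out)


def mechanistic_gate_params(params: ActivationParams) -> tuple[float, float]:
    """Per-gate Boltzmann (v50', s') for the independent-gate model.

    With Po = m**n, the per-gate midpoint and slope are set so that the
    macroscopic Po_inf crosses 0.5 at ``v50_a`` and has the same local
    slope there as the single-gate Boltzmann:

        m_inf(v50_a) = 2**(-1/n)
        s' = 2 n s_a (1 - 2**(-1/n))
    """
    n = params.n_gates
    s_p = 2.0 * n * params.s_a * (1.0 - 2.0 ** (-1.0 / n))
    v50_p = params.v50_a + s_p * math.log(2.0 ** (1.0 / n) - 1.0)
    return v50_p, s_p


def kinetic_rates(params: GatingParams, v: float, k_out: float = REFERENCE_K_OUT) -> dict:
    """Forward/backward rates (1/ms) implied by the model at voltage ``v``.

    Returns per-gate activation rates ``alpha``/``beta`` (mechanistic
    closure: alpha + beta = 1/tau, alpha/(alpha+beta) = m_inf) and, per
    effective inactivation component, the inactivation and recovery
    rates with the C-type external-K+ scaling applied.
    """
    act = params.activation
    v50_p, s_p = mechanistic_gate_params(act)
    m_inf = 1.0 / (1.0 + math.exp(-(v - v50_p) / s_p))
    po_now = steady_state_activation(act, v)
    # Direction-dependent tau: opening transitions are governed by the
    # activation tau, closing by the deactivation tau.
    tau_open = activation_tau(act, v)
    tau_close = deactivation_tau(params.deactivation, v)
    tau = tau_open if po_now >= 0.5 else tau_close
    rates = {
        "alpha": m_inf / tau,
        "beta": (1.0 - m_inf) / tau,
        "components": [],
    }
    for c in params.effective_inactivation:
        scale = c.k_scale(k_out)
        rates["components"].append(
            {
                "mechanism": c.mechanism.value,
                "k_inact": scale / c.tau_inact,
                "k_recover": scale / c.tau_recovery,
            }
        )
    return rates
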