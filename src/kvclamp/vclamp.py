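"""Synthetic voltage-clamp engine.

Builds the standard voltage protocols (step families, steady-state
inactivation pre-pulses, isochronal tails, deactivation tails, long
heteromer families), integrates the gating models of
:mod:`kvclamp.gating` into current sweeps, adds linear-leak and
capacitive recording artifacts plus optional Gaussian noise, and
performs P/N leak subtraction.

The macroscopic, mechanistic and instantaneous-activation modes all
relax exponentially within an epoch of constant voltage, so the sweep
integration is closed-form per epoch: state is propagated analytically
to epoch boundaries and evaluated on the sample grid in between.  There
is no ODE-solver truncation error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import constants

from .gating import (
    ActivationParams,
    GatingParams,
    HeteromerMix,
    InvalidModelError,
    SolutionPair,
    activation_tau,
    deactivation_tau,
    inactivation_tau,
    mechanistic_gate_params,
    steady_state_activation,
    steady_state_availability,
)

__all__ = [
    "Epoch",
    "VoltageProtocol",
    "ArtifactParams",
    "SweepRecording",
    "SamplingWarning",
    "PROTOCOL_KINDS",
    "nernst_potential",
    "build_protocol",
    "simulate",
    "pn_leak_subtract",
]

#: Time constant (ms) of the synthetic capacitive transient at epoch
#: boundaries.  Linear in the voltage step, so P/N removes it exactly.
TAU_CAP = 0.1

MODES = ("macroscopic", "mechanistic", "instantaneous_activation")


class SamplingWarning(UserWarning):
    """Sampling interval is coarse relative to the fastest time constant."""


@dataclass(frozen=True)
class Epoch:
    """One constant-voltage segment of a sweep.

    Either ``voltage`` is fixed for all sweeps, or ``start``/``increment``
    define a per-sweep voltage ``start + k * increment`` for sweep k.
    """

    duration: float
    voltage: Optional[float] = None
    start: Optional[float] = None
    increment: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        fixed = self.voltage is not None
        varying = self.start is not None and self.increment is not None
        if fixed == varying:
            raise ValueError(
                "epoch needs either a fixed voltage or (start, increment)"
            )

    def voltage_for(self, sweep: int) -> float:
        if self.voltage is not None:
            return self.voltage
        return self.start + sweep * self.increment


@dataclass(frozen=True)
class VoltageProtocol:
    """Epoch-structured sweep family with a uniform sampling interval."""

    name: str
    dt: float
    holding: float
    n_sweeps: int
    epochs: tuple[Epoch, ...]
    roles: dict = field(default_factory=dict)  # role name -> epoch index

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        for e in self.epochs:
            for k in range(self.n_sweeps):
                e.voltage_for(k)  # must resolve for every sweep

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.epochs)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.dt))

    def time(self) -> np.ndarray:
        """Sample times (ms) referenced to sweep start."""
        return np.arange(self.n_samples) * self.dt

    def epoch_start(self, index: int) -> float:
        """Start time (ms) of epoch ``index``."""
        return sum(e.duration for e in self.epochs[:index])

    def sweep_voltages(self, sweep: int) -> list[float]:
        return [e.voltage_for(sweep) for e in self.epochs]

    def voltage_trace(self, sweep: int) -> np.ndarray:
        """Command voltage at each sample of sweep ``sweep``."""
        t = self.time()
        v = np.empty_like(t)
        t0 = 0.0
        for e in self.epochs:
            sel = t >= t0 - 1e-9
            v[sel] = e.voltage_for(sweep)
            t0 += e.duration
        return v


@dataclass(frozen=True)
class ArtifactParams:
    """Recording artifacts: linear leak, capacitive transients, noise."""

    g_leak: float = 0.0  # uS
    e_leak: float = 0.0  # mV
    c_mem: float = 0.0  # nF
    noise_sd: float = 0.0  # nA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SweepRecording:
    """Time base plus per-sweep current traces and their provenance."""

    time: np.ndarray  # ms, shape (n_samples,)
    currents: np.ndarray  # nA, shape (n_sweeps, n_samples)
    protocol: VoltageProtocol
    solutions: SolutionPair
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.currents = np.atleast_2d(np.asarray(self.currents, dtype=float))
        if self.currents.shape != (self.protocol.n_sweeps, self.time.size):
            raise ValueError(
                "current matrix shape inconsistent with protocol: "
                f"{self.currents.shape} vs ({self.protocol.n_sweeps}, {self.time.size})"
            )
        dt = np.diff(self.time)
        if self.time.size > 1 and not np.allclose(dt, self.protocol.dt, rtol=1e-6):
            raise ValueError("time vector must increase in steps of dt")

    @property
    def n_sweeps(self) -> int:
        return self.protocol.n_sweeps

    def sweep(self, k: int) -> np.ndarray:
        return self.currents[k]


# ---------------------------------------------------------------------------
# Nernst potential
# ---------------------------------------------------------------------------

def nernst_potential(solutions: SolutionPair) -> float:
    """K+ reversal potential (mV): (RT/F) ln(k_out / k_in)."""
    rt_f = constants.R * solutions.temperature / constants.value(
        "Faraday constant"
    )
    return 1e3 * rt_f * math.log(solutions.k_out / solutions.k_in)


# ---------------------------------------------------------------------------
# Protocol builders
# ---------------------------------------------------------------------------

PROTOCOL_KINDS = (
    "activation_family",
    "ssi",
    "gv_tail",
    "deactivation_tails",
    "heteromer_family",
    "heteromer_prepulse",
)

_HOLD_MS = 5.0


def build_protocol(kind: str, **overrides) -> VoltageProtocol:
    """Build one of the standard protocols.

    Supported kinds and their defaults:

    - ``activation_family``: 100 ms steps, -60..+60 mV in 10 mV
      increments (13 sweeps) from a -100 mV holding potential.
    - ``ssi``: 5 s pre-pulses over -120..0 mV (10 mV grid) followed by a
      100 ms test pulse to +60 mV.
    - ``gv_tail``: activation family plus a 60 ms repolarization to
      -100 mV for isochronal tail-current conductance measurements.
    - ``deactivation_tails``: 20 ms step to +50 mV, then 100 ms tails at
      -160, -140, -120, -100 and -80 mV.
    - ``heteromer_family``: 400 ms steps, -20..+20 mV in 10 mV
      increments, with a 400 ms tail at -40 mV.
    - ``heteromer_prepulse``: 5 s pre-pulse at -100 mV (sweep 0,
      hyperpolarized) or +20 mV (sweep 1, depolarized) followed by a
      400 ms test pulse to +60 mV.

    ``overrides`` may adjust ``holding``, ``dt``, ``step_duration``,
    ``prepulse_duration``, ``test_voltage`` and ``tail_voltage`` where
    meaningful for the kind.
    """
    holding = overrides.pop("holding", -100.0)

    if kind == "activation_family":
        dt = overrides.pop("dt", 0.05)
        dur = overrides.pop("step_duration", 100.0)
        _check_overrides(kind, overrides)
        return VoltageProtocol(
            name=kind,
            dt=dt,
            holding=holding,
            n_sweeps=13,
            epochs=(
                Epoch(_HOLD_MS, voltage=holding),
                Epoch(dur, start=-60.0, increment=10.0),
                Epoch(20.0, voltage=holding),
            ),
            roles={"baseline": 0, "step": 1},
        )

    if kind == "gv_tail":
        dt = overrides.pop("dt", 0.05)
        dur = overrides.pop("step_duration", 100.0)
        tail_v = overrides.pop("tail_voltage", -100.0)
        tail_dur = overrides.pop("tail_duration", 60.0)
        _check_overrides(kind, overrides)
        return VoltageProtocol(
            name=kind,
            dt=dt,
            holding=holding,
            n_sweeps=13,
            epochs=(
                Epoch(_HOLD_MS, voltage=holding),
                Epoch(dur, start=-60.0, increment=10.0),
                Epoch(tail_dur, voltage=tail_v),
            ),
            roles={"baseline": 0, "step": 1, "tail": 2},
        )

    if kind == "ssi":
        dt = overrides.pop("dt", 0.25)
        pre = overrides.pop("prepulse_duration", 5000.0)
        test_v = overrides.pop("test_voltage", 60.0)
        test_dur = overrides.pop("test_duration", 100.0)
        _check_overrides(kind, overrides)
        return VoltageProtocol(
            name=kind,
            dt=dt,
            holding=holding,
            n_sweeps=13,
            epochs=(
                Epoch(_HOLD_MS, voltage=holding),
                Epoch(pre, start=-120.0, increment=10.0),
                Epoch(test_dur, voltage=test_v),
            ),
            roles={"baseline": 0, "prepulse": 1, "test": 2},
        )

    if kind == "deactivation_tails":
        dt = overrides.pop("dt", 0.02)
        act_v = overrides.pop("test_voltage", 50.0)
        act_dur = overrides.pop("step_duration", 20.0)
        tail_dur = overrides.pop("tail_duration", 100.0)
        _check_overrides(kind, overrides)
        return VoltageProtocol(
            name=kind,
            dt=dt,
            holding=holding,
            n_sweeps=5,
            epochs=(
                Epoch(_HOLD_MS, voltage=holding),
                Epoch(act_dur, voltage=act_v),
                Epoch(tail_dur, start=-160.0, increment=20.0),
            ),
            roles={"baseline": 0, "step": 1, "tail": 2},
        )

    if kind == "heteromer_family":
        dt = overrides.pop("dt", 0.1)
        dur = overrides.pop("step_duration", 400.0)
        tail_v = overrides.pop("tail_voltage", -40.0)
        tail_dur = overrides.pop("tail_duration", 400.0)
        _check_overrides(kind, overrides)
        return VoltageProtocol(
            name=kind,
            dt=dt,
            holding=holding,
            n_sweeps=5,
            epochs=(
                Epoch(_HOLD_MS, voltage=holding),
                Epoch(dur, start=-20.0, increment=10.0),
                Epoch(tail_dur, voltage=tail_v),
            ),
            roles={"baseline": 0, "step": 1, "tail": 2},
        )

    if kind == "heteromer_prepulse":
        dt = overrides.pop("dt", 0.25)
        pre = overrides.pop("prepulse_duration", 5000.0)
        depol = overrides.pop("depolarized_prepulse", 20.0)
        test_v = overrides.pop("test_voltage", 60.0)
        test_dur = overrides.pop("test_duration", 400.0)
        _check_overrides(kind, overrides)
        return VoltageProtocol(
            name=kind,
            dt=dt,
            holding=holding,
            n_sweeps=2,
            epochs=(
                Epoch(_HOLD_MS, voltage=holding),
                Epoch(pre, start=holding, increment=depol - holding),
                Epoch(test_dur, voltage=test_v),
            ),
            roles={"baseline": 0, "prepulse": 1, "test": 2},
        )

    raise ValueError(f"unknown protocol kind: {kind!r}")


def _check_overrides(kind: str, leftovers: dict) -> None:
    if leftovers:
        raise ValueError(
            f"unsupported overrides for {kind!r}: {sorted(leftovers)}"
        )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _relax(x0: float, x_inf: float, tau: float, t: np.ndarray) -> np.ndarray:
    return x_inf + (x0 - x_inf) * np.exp(-t / tau)


def _gate_trace(
    model: GatingParams,
    protocol: VoltageProtocol,
    sweep: int,
    k_out: float,
    mode: str,
) -> np.ndarray:
    """Open probability Po(t) * availability h(t) for one sweep."""
    act = model.activation
    t = protocol.time()
    n_samp = t.size
    po_h = np.empty(n_samp)

    comps = model.effective_inactivation
    pedestal = model.pedestal

    if mode == "mechanistic":
        v50_p, s_p = mechanistic_gate_params(act)

        def p_inf(v):
            return 1.0 / (1.0 + math.exp(-(v - v50_p) / s_p))

    else:

        def p_inf(v):
            return float(steady_state_activation(act, v))

    # equilibrium state at the holding potential
    vh = protocol.holding
    gate = p_inf(vh)
    h = [
        1.0 / (1.0 + math.exp((vh - c.v50_i) / c.s_i)) for c in comps
    ]

    t0 = 0.0
    taus_seen = []
    for e in protocol.epochs:
        v = e.voltage_for(sweep)
        sel = (t >= t0 - 1e-9) & (t < t0 + e.duration - 1e-9)
        tl = t[sel] - t0

        g_inf = p_inf(v)
        if mode == "instantaneous_activation":
            gate_t = np.full(tl.shape, g_inf)
            gate = g_inf
        else:
            tau_g = (
                activation_tau(act, v)
                if g_inf >= gate
                else deactivation_tau(model.deactivation, v)
            )
            if abs(g_inf - gate) > 1e-9:  # only active relaxations matter
                taus_seen.append(tau_g)
            gate_t = _relax(gate, g_inf, tau_g, tl)
            gate = float(_relax(gate, g_inf, tau_g, np.array([e.duration]))[0])

        po_t = gate_t ** act.n_gates if mode == "mechanistic" else gate_t

        h_t = np.full(tl.shape, pedestal)
        for j, c in enumerate(comps):
            h_inf = 1.0 / (1.0 + math.exp((v - c.v50_i) / c.s_i))
            tau_h = inactivation_tau(c, v, k_out)
            if abs(h[j] - h_inf) > 1e-9:
                taus_seen.append(tau_h)
            h_t = h_t + c.fraction * _relax(h[j], h_inf, tau_h, tl)
            h[j] = float(_relax(h[j], h_inf, tau_h, np.array([e.duration]))[0])

        po_h[sel] = po_t * h_t
        t0 += e.duration

    if taus_seen and protocol.dt > min(taus_seen) / 5.0:
        warnings.warn(
            f"dt = {protocol.dt} ms is coarse relative to the fastest "
            f"time constant ({min(taus_seen):.3g} ms)",
            SamplingWarning,
            stacklevel=3,
        )
    return po_h


def _capacitive_trace(
    protocol: VoltageProtocol, sweep: int, c_mem: float
) -> np.ndarray:
    """Exponential spikes at epoch boundaries carrying charge c_mem*dV."""
    t = protocol.time()
    out = np.zeros_like(t)
    if c_mem == 0.0:
        return out
    v_prev = protocol.holding
    t0 = 0.0
    for e in protocol.epochs:
        v = e.voltage_for(sweep)
        dv = v - v_prev
        if dv != 0.0:
            sel = t >= t0 - 1e-9
            # charge c_mem * dv (nF * mV = pC); peak scaled so the
            # integral of the spike equals that charge, in nA * ms.
            out[sel] += (c_mem * dv / TAU_CAP) * np.exp(-(t[sel] - t0) / TAU_CAP)
        v_prev = v
        t0 += e.duration
    return out


def simulate(
    model: Union[GatingParams, HeteromerMix],
    protocol: VoltageProtocol,
    solutions: SolutionPair = SolutionPair(),
    artifacts: Optional[ArtifactParams] = None,
    mode: str = "macroscopic",
) -> SweepRecording:
    """Simulate the current family for ``model`` under ``protocol``.

    Ionic current per sweep is ``g_max * Po(t) * h(t) * (V - E_K)``.
    A :class:`HeteromerMix` yields ``(1 - f) I_homomer + f I_heteromer``
    (conductance-weighted).  Artifacts add linear leak
    ``g_leak * (V - e_leak)``, capacitive spikes at epoch boundaries and
    optional Gaussian noise; with ``noise_sd = 0`` the output is
    noiseless and bit-reproducible.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")

    e_k = nernst_potential(solutions)
    t = protocol.time()
    n = protocol.n_sweeps
    currents = np.zeros((n, t.size))

    if isinstance(model, HeteromerMix):
        parts = [
            (model.homomer, (1.0 - model.het_fraction)),
            (model.heteromer, model.het_fraction),
        ]
        g_ref = model.homomer.g_max
    else:
        parts = [(model, 1.0)]
        g_ref = model.g_max

    for k in range(n):
        v_cmd = protocol.voltage_trace(k)
        ionic = np.zeros(t.size)
        for sub, weight in parts:
            if weight == 0.0:
                continue
            po_h = _gate_trace(sub, protocol, k, solutions.k_out, mode)
            ionic += weight * sub.g_max * po_h * (v_cmd - e_k)
        currents[k] = ionic

    prov = {
        "model": model,
        "mode": mode,
        "artifacts": artifacts,
        "seed": artifacts.seed if artifacts else None,
        "leak_subtracted": False,
        "g_ref": g_ref,
    }

    if artifacts is not None:
        rng = np.random.default_rng(artifacts.seed)
        for k in range(n):
            v_cmd = protocol.voltage_trace(k)
            currents[k] += artifacts.g_leak * (v_cmd - artifacts.e_leak)
            currents[k] += _capacitive_trace(protocol, k, artifacts.c_mem)
            if artifacts.noise_sd > 0:
                currents[k] += rng.normal(0.0, artifacts.noise_sd, t.size)

    return SweepRecording(
        time=t,
        currents=currents,
        protocol=protocol,
        solutions=solutions,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# P/N leak subtraction
# ---------------------------------------------------------------------------

def _scaled_protocol(
    protocol: VoltageProtocol, n_sub: int, sub_hold: float
) -> VoltageProtocol:
    """P/-N sub-sweep protocol: excursions divided by -n_sub from sub_hold."""
    scale = -1.0 / n_sub

    def tx(v):
        return sub_hold + (v - protocol.holding) * scale

    epochs = []
    for e in protocol.epochs:
        if e.voltage is not None:
            epochs.append(Epoch(e.duration, voltage=tx(e.voltage)))
        else:
            epochs.append(
                Epoch(
                    e.duration,
                    start=tx(e.start),
                    increment=e.increment * scale,
                )
            )
    return VoltageProtocol(
        name=protocol.name + "_pn_sub",
        dt=protocol.dt,
        holding=sub_hold,
        n_sweeps=protocol.n_sweeps,
        epochs=tuple(epochs),
        roles=dict(protocol.roles),
    )


def _baseline(recording: SweepRecording) -> np.ndarray:
    """Per-sweep holding-level current from the initial baseline epoch."""
    proto = recording.protocol
    idx = proto.roles.get("baseline", 0)
    e = proto.epochs[idx]
    if e.voltage is None or not math.isclose(
        e.voltage, proto.holding, abs_tol=1e-9
    ):
        raise ValueError(
            "P/N subtraction needs an initial holding-level baseline epoch"
        )
    t = recording.time
    t0 = proto.epoch_start(idx)
    # skip the first 1 ms in case of capacitive settling, keep the rest
    sel = (t >= t0 + min(1.0, 0.2 * e.duration)) & (t < t0 + e.duration)
    return recording.currents[:, sel].mean(axis=1, keepdims=True)


def pn_leak_subtract(
    main: SweepRecording, n_sub: int = 4, sub_hold: float = -100.0
) -> SweepRecording:
    """Remove linear leak and capacitive transients by P/-N subtraction.

    Sub-sweeps are the main sweeps scaled by -1/n_sub about ``sub_hold``
    (hyperpolarizing, so channels stay closed), replayed through the
    same model and artifact settings recorded in the provenance of
    ``main``; ``n_sub`` repeats are averaged.  The output is
    ``(main - baseline) + n_sub * (mean sub - sub baseline)`` which
    cancels any strictly linear component exactly while preserving the
    nonlinear channel current.
    """
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    prov = main.provenance
    if "model" not in prov or prov.get("artifacts") is None:
        raise ValueError(
            "recording provenance lacks the model/artifact settings needed "
            "to replay P/N sub-sweeps"
        )
    model = prov["model"]
    artifacts: ArtifactParams = prov["artifacts"]
    mode = prov["mode"]

    sub_proto = _scaled_protocol(main.protocol, n_sub, sub_hold)
    subs = []
    for r in range(n_sub):
        sub_art = replace(artifacts, seed=artifacts.seed + 7919 * (r + 1))
        subs.append(
            simulate(model, sub_proto, main.solutions, sub_art, mode).currents
        )
    sub_mean = np.mean(subs, axis=0)

    sub_rec = SweepRecording(
        time=main.time,
        currents=sub_mean,
        protocol=sub_proto,
        solutions=main.solutions,
        provenance={"model": model, "artifacts": artifacts, "mode": mode},
    )

    _warn_if_nonlinear(sub_rec)

    corrected = (main.currents - _baseline(main)) + n_sub * (
        sub_mean - _baseline(sub_rec)
    )

    prov_out = dict(prov)
    prov_out["leak_subtracted"] = True
    prov_out["pn"] = {"n_sub": n_sub, "sub_hold": sub_hold}
    return SweepRecording(
        time=main.time,
        currents=corrected,
        protocol=main.protocol,
        solutions=main.solutions,
        provenance=prov_out,
    )


def _warn_if_nonlinear(sub_rec: SweepRecording) -> None:
    """Warn when sub-sweep currents deviate from a linear leak response.

    The baseline-referenced sub-sweep current should be proportional to
    the voltage excursion (outside capacitive settling windows); channel
    openings during sub-pulses break that proportionality.
    """
    proto = sub_rec.protocol
    t = sub_rec.time
    base = _baseline(sub_rec)
    resid_max = 0.0
    scale = max(np.abs(sub_rec.currents).max(), 1e-30)
    for k in range(proto.n_sweeps):
        dv = proto.voltage_trace(k) - proto.holding
        # mask capacitive settling after each epoch boundary
        mask = np.ones(t.size, dtype=bool)
        t0 = 0.0
        for e in proto.epochs:
            mask &= ~((t >= t0 - 1e-9) & (t < t0 + 10 * TAU_CAP))
            t0 += e.duration
        y = (sub_rec.currents[k] - base[k])[mask]
        x = dv[mask]
        denom = float(x @ x)
        g_est = float(x @ y) / denom if denom > 0 else 0.0
        resid = y - g_est * x
        resid_max = max(resid_max, float(np.abs(resid).max()))
    if resid_max > 1e-3 * scale:
        warnings.warn(
            "P/N sub-sweeps deviate from linearity; channels may be "
            "activating in the sub-pulse range",
            UserWarning,
            stacklevel=3,
        )
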