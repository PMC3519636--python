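"""Biophysical curve fitting and derived statistics.

Implements the quantitative procedures of the characterization
pipeline: Boltzmann fits of conductance-voltage (GV) and steady-state
inactivation (SSI) data, single- and double-exponential fits of current
relaxations, nested-model selection for the number of inactivation
components, the sigmoidal activation-delay statistic, isochronal
tail-current conductance, deactivation tau-voltage curves, and the
pre-pulse subtraction used to isolate heteromeric current components.

Fitted forms
------------
Boltzmann:      g(V) = (A1 - A2) / (1 + exp((V - V50)/s)) + A2
                (A1 = hyperpolarized asymptote, A2 = depolarized; s > 0,
                direction encoded by A1/A2)
Exponential:    I(t) = I_i + A exp(-t/tau)
Double exp.:    I(t) = I_i + A1 exp(-t/tau1) + A2 exp(-t/tau2), tau1 < tau2
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy import stats

from .vclamp import SweepRecording, nernst_potential

__all__ = [
    "BoltzmannFit",
    "ExpFit",
    "DoubleExpFit",
    "GVCurve",
    "SSICurve",
    "ActivationKinetics",
    "FitError",
    "DegenerateFitError",
    "UndefinedDelayError",
    "fit_boltzmann",
    "fit_exponential",
    "fit_double_exponential",
    "select_inactivation_model",
    "activation_delay_and_tau",
    "activation_kinetics_curve",
    "tail_amplitude",
    "build_gv_curve",
    "build_ssi_curve",
    "deactivation_tau_curve",
    "isolate_inactivating_component",
]

#: Samples within this window (ms) after a voltage step are excluded
#: from peak/tail measurements (residual capacitive settling).
BLANK_MS = 0.3


class FitError(RuntimeError):
    """A curve fit could not be carried out."""


class DegenerateFitError(FitError):
    """The data carry no resolvable relaxation (flat trace)."""


class UndefinedDelayError(FitError):
    """The late-phase exponential never crosses the zero-current line."""


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters.

    ``a1`` is the hyperpolarized asymptote, ``a2`` the depolarized one;
    ``s`` is kept positive and the curve direction lives in A1/A2.
    """

    a1: float
    a2: float
    v50: float
    s: float
    rss: float
    converged: bool
    low_confidence: bool = False

    def predict(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return (self.a1 - self.a2) / (1.0 + np.exp((v - self.v50) / self.s)) + self.a2


@dataclass
class ExpFit:
    """Single exponential I(t) = i_i + a exp(-(t - t_ref)/tau).

    ``t_ref`` is the first sample of the fitted window; ``a`` is the
    amplitude at ``t_ref`` (positive for decays, negative for rises).
    """

    i_i: float
    a: float
    tau: float
    rss: float
    converged: bool
    t_ref: float = 0.0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.i_i + self.a * np.exp(-(t - self.t_ref) / self.tau)


@dataclass
class DoubleExpFit:
    """Two-component exponential with tau1 < tau2.

    Fractional amplitudes f_j = |a_j| / (|a1| + |a2|) sum to 1.
    """

    i_i: float
    a1: float
    tau1: float
    a2: float
    tau2: float
    rss: float
    converged: bool
    t_ref: float = 0.0

    @property
    def f1(self) -> float:
        return abs(self.a1) / (abs(self.a1) + abs(self.a2))

    @property
    def f2(self) -> float:
        return abs(self.a2) / (abs(self.a1) + abs(self.a2))

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float) - self.t_ref
        return (
            self.i_i
            + self.a1 * np.exp(-t / self.tau1)
            + self.a2 * np.exp(-t / self.tau2)
        )


@dataclass
class ModelSelection:
    """Outcome of single- vs double-exponential model selection."""

    n_components: int
    single: ExpFit
    double: Optional[DoubleExpFit]

    @property
    def best(self):
        return self.double if self.n_components == 2 else self.single


@dataclass
class VoltageCurve:
    """Normalized mean +/- SEM curve across cells with a Boltzmann fit.

    Reported V50 and s are the means of per-cell fits; the ``fit``
    carries those means in normalized form.
    """

    voltages: np.ndarray
    mean: np.ndarray
    sem: Optional[np.ndarray]
    n: int
    fit: BoltzmannFit
    per_cell_fits: list = field(default_factory=list)


class GVCurve(VoltageCurve):
    pass


class SSICurve(VoltageCurve):
    pass


@dataclass
class ActivationKinetics:
    """Per-voltage sigmoidal delay and late-phase activation tau."""

    records: list  # of (voltage mV, delay ms, tau_late ms)


# ---------------------------------------------------------------------------
# Elementary fits
# ---------------------------------------------------------------------------

def _boltz(v, a1, a2, v50, s):
    return (a1 - a2) / (1.0 + np.exp((v - v50) / s)) + a2


def fit_boltzmann(
    v: Sequence[float],
    g: Sequence[float],
    normalized: bool = False,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of conductance/availability data.

    Direction (increasing for GV, decreasing for SSI) is inferred from
    the data and encoded through A1/A2 with s kept positive.  With
    ``normalized=True`` the asymptotes are constrained: activation data
    are fit with A1 = 0, A2 = 1; inactivation data with A1 = 1 and a
    free pedestal A2 >= 0.
    """
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    if v.size != g.size:
        raise ValueError("v and g must have equal length")
    if v.size < 4:
        raise ValueError("Boltzmann fit needs at least 4 points")

    order = np.argsort(v)
    v, g = v[order], g[order]
    half = v.size // 2
    increasing = g[-half:].mean() >= g[:half].mean()

    g_mid = 0.5 * (g.min() + g.max())
    v50_init = float(v[np.argmin(np.abs(g - g_mid))])

    model = lmfit.Model(_boltz)
    params = model.make_params(
        a1=float(g[0]), a2=float(g[-1]), v50=v50_init, s=5.0
    )
    params["s"].set(min=1e-6)
    if normalized:
        if increasing:
            params["a1"].set(value=0.0, vary=False)
            params["a2"].set(value=1.0, vary=False)
        else:
            params["a1"].set(value=1.0, vary=False)
            params["a2"].set(value=max(float(g.min()), 0.0), min=0.0)

    result = model.fit(g, params, v=v)
    p = result.params
    fit = BoltzmannFit(
        a1=float(p["a1"]),
        a2=float(p["a2"]),
        v50=float(p["v50"]),
        s=float(p["s"]),
        rss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
    )
    span = abs(fit.a1 - fit.a2)
    covered = g.max() - g.min() if span > 0 else 0.0
    fit.low_confidence = v.size < 5 or (span > 0 and covered < 0.8 * span)
    return fit


def _check_not_flat(i: np.ndarray) -> None:
    span = float(np.ptp(i))
    scale = max(float(np.abs(i).max()), 1.0)
    if span <= 1e-9 * scale:
        raise DegenerateFitError("trace is flat; no relaxation to fit")


def fit_exponential(t: Sequence[float], i: Sequence[float]) -> ExpFit:
    """Single-exponential least-squares fit I(t) = I_i + A exp(-t/tau).

    Used for inactivation decays, tail-current decays and the late
    phase of activation (where A < 0).  Times are referenced internally
    to the first sample for numerical conditioning; ``t_ref`` in the
    result records that reference.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    if t.size != i.size:
        raise ValueError("t and i must have equal length")
    if t.size < 4:
        raise ValueError("exponential fit needs at least 4 samples")
    _check_not_flat(i)

    t_ref = float(t[0])
    tl = t - t_ref
    span = i[0] - i[-1]
    target = i[0] - (1.0 - 1.0 / math.e) * span
    idx = np.nonzero(
        (i <= target) if span > 0 else (i >= target)
    )[0]
    tau_init = float(tl[idx[0]]) if idx.size and tl[idx[0]] > 0 else tl[-1] / 3.0
    tau_init = max(tau_init, tl[1] if tl.size > 1 else 1e-3)

    def f(t, i_i, a, tau):
        return i_i + a * np.exp(-t / tau)

    model = lmfit.Model(f)
    params = model.make_params(i_i=float(i[-1]), a=float(span), tau=tau_init)
    params["tau"].set(min=1e-9)
    result = model.fit(i, params, t=tl)
    p = result.params
    return ExpFit(
        i_i=float(p["i_i"]),
        a=float(p["a"]),
        tau=float(p["tau"]),
        rss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
        t_ref=t_ref,
    )


def fit_double_exponential(
    t: Sequence[float], i: Sequence[float]
) -> DoubleExpFit:
    """Two-exponential fit with components ordered fast-first."""
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    if t.size < 6:
        raise ValueError("double-exponential fit needs at least 6 samples")
    _check_not_flat(i)

    single = fit_exponential(t, i)
    t_ref = float(t[0])
    tl = t - t_ref

    def f(t, i_i, a1, tau1, a2, tau2):
        return i_i + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    model = lmfit.Model(f)
    params = model.make_params(
        i_i=single.i_i,
        a1=0.5 * single.a,
        tau1=single.tau / 4.0,
        a2=0.5 * single.a,
        tau2=single.tau * 4.0,
    )
    params["tau1"].set(min=1e-9)
    params["tau2"].set(min=1e-9)
    result = model.fit(i, params, t=tl)
    p = result.params
    a1, tau1 = float(p["a1"]), float(p["tau1"])
    a2, tau2 = float(p["a2"]), float(p["tau2"])
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    return DoubleExpFit(
        i_i=float(p["i_i"]),
        a1=a1,
        tau1=tau1,
        a2=a2,
        tau2=tau2,
        rss=float(np.sum(result.residual**2)),
        converged=bool(result.success),
        t_ref=t_ref,
    )


def select_inactivation_model(
    t: Sequence[float],
    i: Sequence[float],
    alpha: float = 0.01,
    tau_ratio_min: float = 3.0,
    min_fraction: float = 0.05,
) -> ModelSelection:
    """Choose between one and two inactivation components.

    Two components are reported only when (a) a nested F-test rejects
    the single exponential at ``alpha``, (b) the time constants are
    well separated (tau2/tau1 > ``tau_ratio_min``) and (c) both carry a
    practically relevant fractional amplitude (>= ``min_fraction``).
    Ties and degenerate double fits fall back to the simpler model.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    single = fit_exponential(t, i)

    n = t.size
    if n <= 6:
        return ModelSelection(1, single, None)

    # single exponential already at numerical floor: nothing to gain
    scale = float(np.sum((i - i.mean()) ** 2))
    if scale <= 0 or single.rss <= 1e-16 * scale:
        return ModelSelection(1, single, None)

    try:
        double = fit_double_exponential(t, i)
    except FitError:
        return ModelSelection(1, single, None)

    if double.rss <= 0:
        f_stat = math.inf
    else:
        f_stat = ((single.rss - double.rss) / 2.0) / (double.rss / (n - 5))
    f_crit = stats.f.ppf(1.0 - alpha, 2, n - 5)

    accept = (
        double.converged
        and f_stat > f_crit
        and double.tau2 / double.tau1 > tau_ratio_min
        and min(double.f1, double.f2) >= min_fraction
    )
    return ModelSelection(2 if accept else 1, single, double)


# ---------------------------------------------------------------------------
# Activation delay statistic
# ---------------------------------------------------------------------------

def activation_delay_and_tau(
    t: Sequence[float],
    i: Sequence[float],
    t_pulse_start: float,
) -> tuple[float, float]:
    """Sigmoidal delay and late-phase tau of an activating current.

    The late phase (samples at or above 50% of the final rise) is fit
    with a single exponential; the delay is the time from the pulse
    start to where the fitted curve crosses the zero-current line,
    obtained in closed form from the fit parameters.  A purely
    exponential rise from zero has zero delay; multi-gate (sigmoidal)
    activation yields a positive delay.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    sel = t >= t_pulse_start
    t, i = t[sel], i[sel]
    if t.size < 8:
        raise ValueError("too few samples after the pulse start")
    i_final = float(i[-1])
    if i_final <= 0:
        raise FitError("trace does not rise to a positive plateau")
    if i_final < 0.9 * float(i.max()):
        raise FitError(
            "current decays after its peak; activation time course obscured"
        )
    late = i >= 0.5 * i_final
    first = int(np.argmax(late))
    fit = fit_exponential(t[first:], i[first:])

    # zero crossing: 0 = i_i + a exp(-(tz - t_ref)/tau)
    if fit.a >= 0 or fit.i_i <= 0:
        raise UndefinedDelayError(
            "late-phase fit does not describe a rise toward a positive plateau"
        )
    ratio = -fit.i_i / fit.a  # > 0
    t_zero = fit.t_ref - fit.tau * math.log(ratio)
    return t_zero - t_pulse_start, fit.tau


def activation_kinetics_curve(
    recording: SweepRecording,
    min_relative_plateau: float = 0.1,
) -> ActivationKinetics:
    """Delay and late-phase tau for each step of an activation family.

    Sweeps whose plateau current is below ``min_relative_plateau`` of
    the family maximum are skipped (no resolvable rise).
    """
    proto = recording.protocol
    step = proto.roles.get("step")
    if step is None:
        raise ValueError("protocol has no 'step' epoch role")
    t = recording.time
    t0 = proto.epoch_start(step)
    t1 = t0 + proto.epochs[step].duration
    sel = (t >= t0 + BLANK_MS) & (t < t1)

    finals = np.array([recording.currents[k][sel][-1] for k in range(proto.n_sweeps)])
    i_ref = float(np.abs(finals).max())
    records = []
    for k in range(proto.n_sweeps):
        if abs(finals[k]) < min_relative_plateau * i_ref:
            continue
        trace = recording.currents[k][sel]
        sign = 1.0 if finals[k] >= 0 else -1.0
        try:
            delay, tau = activation_delay_and_tau(t[sel], sign * trace, t0)
        except (FitError, ValueError):
            continue
        records.append((proto.epochs[step].voltage_for(k), delay, tau))
    return ActivationKinetics(records=records)


# ---------------------------------------------------------------------------
# Tail currents and voltage curves
# ---------------------------------------------------------------------------

def tail_amplitude(
    t: Sequence[float],
    i: Sequence[float],
    t_repol: float,
    blank: float = BLANK_MS,
) -> float:
    """Isochronal tail amplitude by back-extrapolation to ``t_repol``.

    The tail decay after the blanking window is fit with a single
    exponential and evaluated at the repolarization instant, which is
    robust to the excluded capacitive-settling samples.
    """
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    sel = t >= t_repol + blank
    if np.count_nonzero(sel) < 4:
        raise FitError("no tail decay window after the repolarization")
    try:
        fit = fit_exponential(t[sel], i[sel])
    except DegenerateFitError:
        return 0.0  # fully closed channel: flat zero tail
    return float(fit.predict(t_repol))


def _per_cell_norm(values: np.ndarray) -> np.ndarray:
    m = float(np.abs(values).max())
    if m == 0:
        raise FitError("all-zero curve cannot be normalized")
    return values / m


def build_gv_curve(recordings: Sequence[SweepRecording]) -> GVCurve:
    """Conductance-voltage curve from isochronal tail currents.

    Per cell: tail amplitudes -> conductances (divided by the tail
    driving force V_tail - E_K) -> normalized to the cell maximum ->
    normalized Boltzmann fit.  Reported V50 and s are means of the
    per-cell fits; the displayed curve is the mean +/- SEM of the
    per-cell normalized data.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("need at least one recording")
    proto = recordings[0].protocol
    step = proto.roles.get("step")
    tail = proto.roles.get("tail")
    if step is None or tail is None:
        raise ValueError("protocol lacks 'step'/'tail' epoch roles")
    t_repol = proto.epoch_start(tail)
    v_tail = proto.epochs[tail].voltage_for(0)
    voltages = np.array(
        [proto.epochs[step].voltage_for(k) for k in range(proto.n_sweeps)]
    )

    per_cell_curves = []
    per_cell_fits = []
    for rec in recordings:
        e_k = nernst_potential(rec.solutions)
        drive = v_tail - e_k
        if abs(drive) < 1.0:
            raise FitError("tail driving force too small to measure conductance")
        g = np.array(
            [
                tail_amplitude(rec.time, rec.currents[k], t_repol) / drive
                for k in range(proto.n_sweeps)
            ]
        )
        g_norm = _per_cell_norm(g)
        per_cell_curves.append(g_norm)
        per_cell_fits.append(fit_boltzmann(voltages, g_norm, normalized=True))

    return _assemble_curve(GVCurve, voltages, per_cell_curves, per_cell_fits)


def build_ssi_curve(recordings: Sequence[SweepRecording]) -> SSICurve:
    """Steady-state inactivation curve from pre-pulse/test recordings.

    Availability is the peak absolute test-pulse current (after the
    blanking window) per pre-pulse voltage, normalized per cell, fit
    with a decreasing normalized Boltzmann (A1 = 1, free pedestal).
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("need at least one recording")
    proto = recordings[0].protocol
    pre = proto.roles.get("prepulse")
    test = proto.roles.get("test")
    if pre is None or test is None:
        raise ValueError("protocol lacks 'prepulse'/'test' epoch roles")
    t = recordings[0].time
    t0 = proto.epoch_start(test)
    t1 = t0 + proto.epochs[test].duration
    sel = (t >= t0 + BLANK_MS) & (t < t1)
    voltages = np.array(
        [proto.epochs[pre].voltage_for(k) for k in range(proto.n_sweeps)]
    )

    per_cell_curves = []
    per_cell_fits = []
    for rec in recordings:
        peaks = np.array(
            [np.abs(rec.currents[k][sel]).max() for k in range(proto.n_sweeps)]
        )
        avail = _per_cell_norm(peaks)
        per_cell_curves.append(avail)
        per_cell_fits.append(fit_boltzmann(voltages, avail, normalized=True))

    return _assemble_curve(SSICurve, voltages, per_cell_curves, per_cell_fits)


def _assemble_curve(cls, voltages, per_cell_curves, per_cell_fits):
    data = np.vstack(per_cell_curves)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else None
    fit = BoltzmannFit(
        a1=float(np.mean([f.a1 for f in per_cell_fits])),
        a2=float(np.mean([f.a2 for f in per_cell_fits])),
        v50=float(np.mean([f.v50 for f in per_cell_fits])),
        s=float(np.mean([f.s for f in per_cell_fits])),
        rss=float(np.sum([f.rss for f in per_cell_fits])),
        converged=all(f.converged for f in per_cell_fits),
        low_confidence=any(f.low_confidence for f in per_cell_fits),
    )
    return cls(
        voltages=voltages,
        mean=mean,
        sem=sem,
        n=n,
        fit=fit,
        per_cell_fits=per_cell_fits,
    )


def deactivation_tau_curve(recording: SweepRecording) -> list[tuple[float, float]]:
    """Single-exponential tail tau at each tail voltage.

    For the first-order closing model, log(tau) is linear in voltage.
    """
    proto = recording.protocol
    tail = proto.roles.get("tail")
    if tail is None:
        raise ValueError("protocol lacks a 'tail' epoch role")
    t = recording.time
    t0 = proto.epoch_start(tail)
    t1 = t0 + proto.epochs[tail].duration
    sel = (t >= t0 + BLANK_MS) & (t < t1)
    out = []
    for k in range(proto.n_sweeps):
        fit = fit_exponential(t[sel], recording.currents[k][sel])
        out.append((proto.epochs[tail].voltage_for(k), fit.tau))
    return out


# ---------------------------------------------------------------------------
# Heteromer pre-pulse subtraction
# ---------------------------------------------------------------------------

def isolate_inactivating_component(
    i_hyper: Sequence[float],
    i_depol: Sequence[float],
    n_align: int = 0,
) -> np.ndarray:
    """Difference trace isolating the inactivating (heteromeric) current.

    ``i_hyper``/``i_depol`` are test-pulse currents following
    hyperpolarized and depolarized conditioning pre-pulses.  When
    ``n_align`` > 0, the mean of the first ``n_align`` samples (taken
    from just before the test step) is subtracted from each trace first
    (pre-pulse-end baseline alignment).  For a mixture whose homomer
    does not inactivate, the result is the pure heteromeric current.
    """
    i_hyper = np.asarray(i_hyper, dtype=float)
    i_depol = np.asarray(i_depol, dtype=float)
    if i_hyper.shape != i_depol.shape:
        raise ValueError("trace length mismatch")
    if n_align > 0:
        i_hyper = i_hyper - i_hyper[:n_align].mean()
        i_depol = i_depol - i_depol[:n_align].mean()
    return i_hyper - i_depol
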