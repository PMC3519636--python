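"""End-to-end channel characterization.

Assembles per-channel summaries (inactivation time constants, SSI and
GV Boltzmann parameters, phenotype classes), classifies activation
threshold, and compares heteromer co-expression recordings against the
homomer control to flag regulatory-subunit phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import (
    BLANK_MS,
    FitError,
    build_gv_curve,
    build_ssi_curve,
    fit_exponential,
    isolate_inactivating_component,
    select_inactivation_model,
)
from .vclamp import SweepRecording

__all__ = [
    "ChannelSummary",
    "HeteromerReport",
    "summarize_channel",
    "classify_threshold",
    "compare_heteromer",
    "summaries_to_frame",
]

# Phenotype calibration constants.  The inactivation-class cutoffs are
# calibration values, not physical constants: the qualitative anchors
# are ~1 s for the slowest heteromeric inactivation and completion
# within 50 ms for the fastest.
INACT_CLASS_VERY_FAST_MS = 15.0
INACT_CLASS_FAST_MS = 60.0
#: Homomeric inactivation faster than this (amplitude-weighted tau, ms)
#: is called "fast", otherwise "slow".
HOMOMER_FAST_TAU_MS = 30.0
#: Decay from peak below this fraction counts as non-inactivating.
MIN_INACT_DECAY = 0.05
#: Residual steady current above this fraction of peak = "partial".
PARTIAL_PEDESTAL_MIN = 0.10
#: "Current first appears" = first grid step whose steady current
#: exceeds this fraction of the most-depolarized step's current.
FIRST_APPEARANCE_FRACTION = 0.01
#: Kinetic-ratio cutoffs for heteromer rate flags.
RATE_SLOW_RATIO = 1.5
RATE_FAST_RATIO = 1.0 / 1.5
#: Threshold-shift classes by first-appearance voltage difference (mV).
SHIFT_CLASSES = ((30.0, "large"), (20.0, "medium"), (10.0, "small"))
#: Mixture decay from peak beyond this fraction marks the activation
#: time course as obscured by inactivation (flag undetermined).
ACT_OBSCURED_DECAY = 0.20


@dataclass
class ChannelSummary:
    """One summary-table row for a homomeric channel."""

    name: str
    tau_inact: Optional[list[tuple[float, float]]]  # (tau ms, fraction)
    ssi_v50: Optional[float]
    ssi_slope: Optional[float]
    gv_v50: float
    gv_slope: float
    threshold_class: str  # "low" | "high"
    inactivation_class: str  # "fast" | "slow" | "partial" | "none"
    n_cells: int = 1

    def __post_init__(self) -> None:
        absent_ssi = self.ssi_v50 is None
        if absent_ssi != (self.inactivation_class == "none"):
            raise ValueError(
                "SSI entries must be absent exactly when the channel does "
                "not inactivate"
            )


@dataclass
class HeteromerReport:
    """Qualitative phenotype flags for one co-expression experiment.

    ``None`` marks a property that could not be determined (missing
    recording, or the measurement was obscured).
    """

    inactivation: Optional[str]  # none | slow | fast | very_fast
    threshold_shift: Optional[str]  # none | small | medium | large
    activation_rate: Optional[str]  # none | slow | fast
    deactivation_rate: Optional[str]  # none | slow | fast
    details: dict = field(default_factory=dict)


def classify_threshold(gv_v50: float) -> str:
    """Low- vs high-threshold phenotype; V50 >= 0 mV is ``high``."""
    return "high" if gv_v50 >= 0.0 else "low"


# ---------------------------------------------------------------------------
# Homomer summary
# ---------------------------------------------------------------------------

def _step_window(recording: SweepRecording):
    proto = recording.protocol
    idx = proto.roles.get("step")
    if idx is None:
        raise ValueError("protocol lacks a 'step' epoch role")
    t = recording.time
    t0 = proto.epoch_start(idx)
    t1 = t0 + proto.epochs[idx].duration
    return (t >= t0 + BLANK_MS) & (t < t1), idx


def _inactivation_at_60(recording: SweepRecording):
    """Classify and fit the decay of the +60 mV step current.

    Returns (class, tau list) where the tau list holds (tau, fraction)
    pairs, or (class, None) for non-inactivating channels.
    """
    proto = recording.protocol
    sel, idx = _step_window(recording)
    sweep = None
    for k in range(proto.n_sweeps):
        if math.isclose(proto.epochs[idx].voltage_for(k), 60.0, abs_tol=1e-6):
            sweep = k
    if sweep is None:
        raise ValueError("activation family has no +60 mV step")
    t = recording.time[sel]
    i = recording.currents[sweep][sel]

    peak_idx = int(np.argmax(np.abs(i)))
    peak = i[peak_idx]
    steady = i[-1]
    decay = (abs(peak) - abs(steady)) / abs(peak)
    if decay < MIN_INACT_DECAY:
        return "none", None

    sel_fit = slice(peak_idx, None)
    choice = select_inactivation_model(t[sel_fit], i[sel_fit])
    if choice.n_components == 2:
        d = choice.double
        taus = [(d.tau1, d.f1), (d.tau2, d.f2)]
    else:
        taus = [(choice.single.tau, 1.0)]

    pedestal = abs(steady) / abs(peak)
    if pedestal > PARTIAL_PEDESTAL_MIN:
        return "partial", taus
    w_tau = sum(tau * f for tau, f in taus)
    return ("fast" if w_tau < HOMOMER_FAST_TAU_MS else "slow"), taus


def summarize_channel(
    bundle: dict,
    truncated_bundle: Optional[dict] = None,
) -> ChannelSummary:
    """Assemble a summary-table row from a recordings bundle.

    ``bundle`` maps protocol roles to recordings:

    - ``"activation_family"``: a step-family recording (or list of
      them) used for inactivation kinetics at +60 mV;
    - ``"gv_tail"``: per-cell tail-protocol recordings for the GV
      curve;
    - ``"ssi"``: per-cell pre-pulse recordings for the SSI curve
      (optional; required only when the channel inactivates).

    When ``truncated_bundle`` is given, its ``gv_tail`` recordings
    (from the N-terminally truncated construct, where fast inactivation
    no longer obscures activation) are used for the GV curve instead.
    """
    if "activation_family" not in bundle or "gv_tail" not in bundle:
        raise ValueError("bundle requires 'activation_family' and 'gv_tail'")
    fam = bundle["activation_family"]
    fam = fam[0] if isinstance(fam, (list, tuple)) else fam

    inact_class, taus = _inactivation_at_60(fam)

    gv_source = (truncated_bundle or bundle).get("gv_tail") or bundle["gv_tail"]
    if isinstance(gv_source, SweepRecording):
        gv_source = [gv_source]
    gv = build_gv_curve(gv_source)

    ssi_v50 = ssi_slope = None
    if inact_class != "none":
        if "ssi" not in bundle:
            raise ValueError(
                "channel inactivates but the bundle has no 'ssi' recordings"
            )
        ssi_source = bundle["ssi"]
        if isinstance(ssi_source, SweepRecording):
            ssi_source = [ssi_source]
        ssi = build_ssi_curve(ssi_source)
        ssi_v50, ssi_slope = ssi.fit.v50, ssi.fit.s

    name = fam.provenance.get("model").name if fam.provenance.get("model") else "?"
    return ChannelSummary(
        name=name.removesuffix("_trunc"),
        tau_inact=taus,
        ssi_v50=ssi_v50,
        ssi_slope=ssi_slope,
        gv_v50=gv.fit.v50,
        gv_slope=gv.fit.s,
        threshold_class=classify_threshold(gv.fit.v50),
        inactivation_class=inact_class,
        n_cells=gv.n,
    )


def summaries_to_frame(summaries: Sequence[ChannelSummary]) -> pd.DataFrame:
    """Summary rows as a table mirroring the published column layout."""
    rows = []
    for s in summaries:
        if s.tau_inact is None:
            tau_str = "N.A."
        else:
            tau_str = "; ".join(
                f"{tau:.1f} ({f:.2f})" if len(s.tau_inact) > 1 else f"{tau:.1f}"
                for tau, f in s.tau_inact
            )
        rows.append(
            {
                "name": s.name,
                "tau_inact_ms": tau_str,
                "ssi_v50_mV": s.ssi_v50,
                "ssi_slope_mV": s.ssi_slope,
                "gv_v50_mV": s.gv_v50,
                "gv_slope_mV": s.gv_slope,
                "threshold_class": s.threshold_class,
                "inactivation_class": s.inactivation_class,
                "n": s.n_cells,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Heteromer comparison
# ---------------------------------------------------------------------------

def _first_appearance_voltage(recording: SweepRecording) -> Optional[float]:
    """Most hyperpolarized step whose steady current is >= 1% of the
    most depolarized step's steady current."""
    proto = recording.protocol
    sel, idx = _step_window(recording)
    t = recording.time[sel]
    n_tail = max(int(0.05 * t.size), 1)  # steady = mean of last 5 %
    steadies = np.array(
        [
            np.abs(recording.currents[k][sel][-n_tail:]).mean()
            for k in range(proto.n_sweeps)
        ]
    )
    volts = [proto.epochs[idx].voltage_for(k) for k in range(proto.n_sweeps)]
    order = np.argsort(volts)
    ref = steadies[order[-1]]
    if ref <= 0:
        return None
    for k in order:
        if steadies[k] >= FIRST_APPEARANCE_FRACTION * ref:
            return volts[k]
    return None


def _time_to_half(recording: SweepRecording, sweep: int) -> float:
    """Time (ms) from step onset to half of the peak step current."""
    sel, idx = _step_window(recording)
    t0 = recording.protocol.epoch_start(idx)
    t = recording.time[sel]
    i = np.abs(recording.currents[sweep][sel])
    half = 0.5 * i.max()
    k = int(np.argmax(i >= half))
    return float(t[k] - t0)


def _step_decay_fraction(recording: SweepRecording, sweep: int) -> float:
    sel, _ = _step_window(recording)
    i = np.abs(recording.currents[sweep][sel])
    peak = i.max()
    return float((peak - i[-1]) / peak) if peak > 0 else 0.0


def _tail_tau(recording: SweepRecording) -> float:
    """Tail-decay tau (ms) of the most depolarized sweep."""
    proto = recording.protocol
    tail = proto.roles.get("tail")
    if tail is None:
        raise ValueError("protocol lacks a 'tail' epoch role")
    t = recording.time
    t0 = proto.epoch_start(tail)
    t1 = t0 + proto.epochs[tail].duration
    sel = (t >= t0 + BLANK_MS) & (t < t1)
    sweep = proto.n_sweeps - 1
    return fit_exponential(t[sel], recording.currents[sweep][sel]).tau


def _classify_difference_inactivation(
    mix_prepulse: SweepRecording,
) -> tuple[str, dict]:
    """Inactivation flag from the hyper-vs-depol pre-pulse difference."""
    proto = mix_prepulse.protocol
    test = proto.roles["test"]
    t = mix_prepulse.time
    t_test = proto.epoch_start(test)
    t_end = t_test + proto.epochs[test].duration
    sel = (t >= t_test) & (t < t_end)

    # both sweeps share the test-epoch voltage, so linear backgrounds
    # cancel in the raw difference; baseline alignment is only needed
    # for drifting recordings
    diff = isolate_inactivating_component(
        mix_prepulse.currents[0][sel],
        mix_prepulse.currents[1][sel],
    )
    td = t[sel]
    # a genuine inactivating heteromeric component appears as a
    # *positive* difference in the outward direction (extra current
    # after the hyperpolarized pre-pulse that then decays); activation
    # transients (the depolarized pre-pulse leaves gates partly open)
    # produce a difference of the opposite sign and are additionally
    # skipped by a short settling window
    hyper = mix_prepulse.currents[0][sel]
    n_late = max(int(0.1 * hyper.size), 1)
    sign = 1.0 if hyper[-n_late:].mean() >= 0 else -1.0
    signed = sign * diff
    settle = td >= t_test + 10.0
    diff_s = signed[settle]
    total = np.abs(hyper[settle]).max()
    details = {"difference_peak": float(diff_s.max())}
    if total <= 0 or diff_s.max() < 0.05 * total:
        return "none", details
    peak_idx = int(np.argmax(diff_s))
    fit = fit_exponential(td[settle][peak_idx:], diff_s[peak_idx:])
    details["difference_tau"] = fit.tau
    if fit.tau < INACT_CLASS_VERY_FAST_MS:
        return "very_fast", details
    if fit.tau < INACT_CLASS_FAST_MS:
        return "fast", details
    return "slow", details


def compare_heteromer(
    mix_recordings: dict,
    homomer_recordings: dict,
) -> HeteromerReport:
    """Flag novel properties of a co-expression mix vs the homomer.

    Both bundles map roles to recordings: ``"family"`` (long step
    family with a tail epoch) and/or ``"prepulse"`` (hyperpolarized vs
    depolarized 5 s conditioning followed by a test pulse).  Properties
    whose recording is absent — or whose measurement is obscured by
    inactivation — are reported as undetermined (``None``).
    """
    if not mix_recordings:
        raise ValueError("mix bundle is empty")
    inactivation = None
    threshold_shift = None
    activation_rate = None
    deactivation_rate = None
    details = {}

    if "prepulse" in mix_recordings:
        inactivation, d = _classify_difference_inactivation(
            mix_recordings["prepulse"]
        )
        details.update(d)

    if "family" in mix_recordings:
        if "family" not in homomer_recordings:
            raise ValueError("mix family recording lacks a homomer control")
        mix_fam = mix_recordings["family"]
        hom_fam = homomer_recordings["family"]

        v_mix = _first_appearance_voltage(mix_fam)
        v_hom = _first_appearance_voltage(hom_fam)
        details["first_appearance"] = {"mix": v_mix, "homomer": v_hom}
        if v_mix is None or v_hom is None:
            threshold_shift = None
        else:
            shift = v_hom - v_mix  # hyperpolarizing shifts are positive
            threshold_shift = "none"
            for cutoff, label in SHIFT_CLASSES:
                if shift >= cutoff:
                    threshold_shift = label
                    break

        ref_sweep = mix_fam.protocol.n_sweeps - 1  # most depolarized step
        if _step_decay_fraction(mix_fam, ref_sweep) > ACT_OBSCURED_DECAY:
            activation_rate = None  # inactivation obscures the rise
        else:
            ratio = _time_to_half(mix_fam, ref_sweep) / _time_to_half(
                hom_fam, ref_sweep
            )
            details["half_activation_ratio"] = ratio
            if ratio > RATE_SLOW_RATIO:
                activation_rate = "slow"
            elif ratio < RATE_FAST_RATIO:
                activation_rate = "fast"
            else:
                activation_rate = "none"

        try:
            ratio = _tail_tau(mix_fam) / _tail_tau(hom_fam)
        except FitError:
            deactivation_rate = None
        else:
            details["tail_tau_ratio"] = ratio
            if ratio > RATE_SLOW_RATIO:
                deactivation_rate = "slow"
            elif ratio < RATE_FAST_RATIO:
                deactivation_rate = "fast"
            else:
                deactivation_rate = "none"

    return HeteromerReport(
        inactivation=inactivation,
        threshold_shift=threshold_shift,
        activation_rate=activation_rate,
        deactivation_rate=deactivation_rate,
        details=details,
    )
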