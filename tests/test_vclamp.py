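import warnings

import numpy as np
import pytest

from kvclamp.gating import (
    ActivationParams,
    DeactivationParams,
    GatingParams,
    SolutionPair,
)
from kvclamp.vclamp import (
    ArtifactParams,
    Epoch,
    SamplingWarning,
    VoltageProtocol,
    build_protocol,
    nernst_potential,
    pn_leak_subtract,
    simulate,
)


class TestNernst:
    def test_symmetrical_k_reverses_at_zero(self):
        assert nernst_potential(SolutionPair(140, 140, 295)) == 0.0

    def test_standard_patch_solutions(self):
        # (RT/F) ln(2/140) at 295 K
        assert nernst_potential(SolutionPair(140, 2, 295)) == pytest.approx(-108.0, abs=0.1)

    def test_4mM_external(self):
        assert nernst_potential(SolutionPair(140, 4, 295)) == pytest.approx(-90.4, abs=0.1)


class TestProtocols:
    def test_activation_family_geometry(self):
        p = build_protocol("activation_family")
        assert p.n_sweeps == 13
        volts = [p.epochs[p.roles["step"]].voltage_for(k) for k in range(13)]
        assert volts == list(np.arange(-60.0, 61.0, 10.0))
        assert p.holding == -100.0

    def test_deactivation_tail_voltages(self):
        p = build_protocol("deactivation_tails")
        assert p.n_sweeps == 5
        tails = [p.epochs[p.roles["tail"]].voltage_for(k) for k in range(5)]
        assert tails == [-160.0, -140.0, -120.0, -100.0, -80.0]

    def test_ssi_default_prepulse_is_five_seconds(self):
        p = build_protocol("ssi")
        assert p.epochs[p.roles["prepulse"]].duration == 5000.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown protocol kind"):
            build_protocol("ramp")

    def test_epoch_needs_exactly_one_voltage_spec(self):
        with pytest.raises(ValueError):
            Epoch(10.0)
        with pytest.raises(ValueError):
            Epoch(10.0, voltage=0.0, start=0.0, increment=1.0)


def _flat_protocol(v, dt=0.05, n_sweeps=1):
    return VoltageProtocol(
        "flat", dt, v, n_sweeps,
        (Epoch(5.0, voltage=v), Epoch(50.0, voltage=v)),
        roles={"baseline": 0},
    )


class TestSimulate:
    def test_zero_current_at_reversal_potential(self, nvshak1, symmetric_k):
        rec = simulate(nvshak1, _flat_protocol(0.0), symmetric_k)
        assert np.all(rec.currents == 0.0)

    def test_first_significant_step_for_high_threshold_channel(
        self, nvshak2, patch_solutions
    ):
        # brute force over the 13 steps: the most hyperpolarized step
        # reaching >= 1% of the +60 mV steady conductance is -10 mV
        proto = build_protocol("activation_family")
        rec = simulate(nvshak2, proto, patch_solutions)
        e_k = nernst_potential(patch_solutions)
        step = proto.roles["step"]
        t0 = proto.epoch_start(step)
        t1 = t0 + proto.epochs[step].duration
        sel = (rec.time >= t1 - 1.0) & (rec.time < t1)
        conductances = []
        for k in range(proto.n_sweeps):
            v = proto.epochs[step].voltage_for(k)
            conductances.append(rec.currents[k][sel].mean() / (v - e_k))
        conductances = np.array(conductances)
        ref = conductances[-1]  # +60 mV
        first = next(
            proto.epochs[step].voltage_for(k)
            for k in range(proto.n_sweeps)
            if conductances[k] >= 0.01 * ref
        )
        assert first == -10.0

    def test_instantaneous_mode_decay_is_pure_exponential(
        self, nvshak1, patch_solutions
    ):
        proto = VoltageProtocol(
            "step", 0.05, -100.0, 1,
            (Epoch(5.0, voltage=-100.0), Epoch(100.0, voltage=60.0)),
            roles={"baseline": 0, "step": 1},
        )
        rec = simulate(nvshak1, proto, patch_solutions,
                       mode="instantaneous_activation")
        t = rec.time
        sel = t >= 5.0
        i = rec.currents[0][sel]
        expected = i[0] * np.exp(-(t[sel] - t[sel][0]) / 2.4)
        assert np.allclose(i, expected, rtol=1e-9)

    def test_current_sign_follows_driving_force(self, nvshak2, symmetric_k):
        # fully activated channel: sign(I) = sign(V - E_K); E_K = 0 here
        for v in (-50.0, 30.0):
            proto = VoltageProtocol(
                "p", 0.05, -100.0, 1,
                (Epoch(5.0, voltage=-100.0), Epoch(30.0, voltage=60.0),
                 Epoch(5.0, voltage=v)),
            )
            rec = simulate(nvshak2, proto, symmetric_k)
            tail = rec.currents[0][rec.time >= 35.0 + 0.1][:20]
            assert np.all(np.sign(tail) == np.sign(v))

    def test_gate_occupancy_bounded(self, nvshak4, patch_solutions):
        proto = build_protocol("activation_family")
        rec = simulate(nvshak4, proto, patch_solutions)
        e_k = nernst_potential(patch_solutions)
        for k in range(proto.n_sweeps):
            drive = proto.voltage_trace(k) - e_k
            with np.errstate(divide="ignore", invalid="ignore"):
                po_h = np.where(drive != 0,
                                rec.currents[k] / (nvshak4.g_max * drive), 0.0)
            assert np.all(po_h >= -1e-12)
            assert np.all(po_h <= 1 + 1e-12)

    def test_heteromer_mix_is_conductance_weighted_sum(self, patch_solutions):
        import kvclamp as kc
        mix = kc.load_fixture("R8")
        proto = build_protocol("heteromer_family")
        whole = simulate(mix, proto, patch_solutions)
        hom = simulate(mix.homomer, proto, patch_solutions)
        het = simulate(mix.heteromer, proto, patch_solutions)
        combo = (1 - mix.het_fraction) * hom.currents + mix.het_fraction * het.currents
        assert np.allclose(whole.currents, combo, rtol=1e-12)

    def test_mechanistic_single_gate_matches_macroscopic(self, patch_solutions):
        model = GatingParams(
            "m", 0.05,
            ActivationParams(v50_a=-20.0, s_a=5.0, n_gates=1, tau_act_ref=2.0),
            DeactivationParams(5.0, 40.0),
        )
        proto = build_protocol("activation_family")
        a = simulate(model, proto, patch_solutions, mode="macroscopic")
        b = simulate(model, proto, patch_solutions, mode="mechanistic")
        assert np.allclose(a.currents, b.currents, atol=1e-12)

    def test_noise_reproducible_for_equal_seeds(self, nvshak2, patch_solutions):
        proto = _flat_protocol(-100.0)
        art = ArtifactParams(noise_sd=0.5, seed=42)
        a = simulate(nvshak2, proto, patch_solutions, art)
        b = simulate(nvshak2, proto, patch_solutions, art)
        c = simulate(nvshak2, proto, patch_solutions,
                     ArtifactParams(noise_sd=0.5, seed=43))
        assert np.array_equal(a.currents, b.currents)
        assert not np.array_equal(a.currents, c.currents)

    def test_coarse_sampling_warns(self, nvshak1, patch_solutions):
        proto = VoltageProtocol(
            "coarse", 2.0, -100.0, 1,
            (Epoch(6.0, voltage=-100.0), Epoch(100.0, voltage=60.0)),
        )
        with pytest.warns(SamplingWarning):
            simulate(nvshak1, proto, patch_solutions)


class TestPnLeakSubtraction:
    ART = ArtifactParams(g_leak=0.0004, e_leak=-10.0, c_mem=0.002, seed=1)

    def test_pure_linear_leak_cancels_exactly(self, nvshak2, patch_solutions):
        # sub-threshold steps: the high-threshold channel never opens,
        # so the recording is leak + capacitive only
        proto = VoltageProtocol(
            "sub", 0.05, -100.0, 5,
            (Epoch(5.0, voltage=-100.0), Epoch(50.0, start=-90.0, increment=-10.0),
             Epoch(10.0, voltage=-100.0)),
            roles={"baseline": 0},
        )
        raw = simulate(nvshak2, proto, patch_solutions, self.ART)
        out = pn_leak_subtract(raw, n_sub=4, sub_hold=-100.0)
        assert np.abs(out.currents).max() < 1e-9

    def test_channel_current_preserved(self, nvshak2, patch_solutions):
        proto = build_protocol("activation_family")
        raw = simulate(nvshak2, proto, patch_solutions, self.ART)
        out = pn_leak_subtract(raw, n_sub=4, sub_hold=-100.0)
        clean = simulate(nvshak2, proto, patch_solutions)
        e_k = nernst_potential(patch_solutions)
        tol = 1e-6 * nvshak2.g_max * abs(60.0 - e_k)
        assert np.abs(out.currents - clean.currents).max() < tol

    def test_invariant_under_leak_magnitude(self, nvshak2, patch_solutions):
        from dataclasses import replace
        proto = build_protocol("activation_family")
        out1 = pn_leak_subtract(
            simulate(nvshak2, proto, patch_solutions, self.ART), 4, -100.0
        )
        art2 = replace(self.ART, g_leak=2 * self.ART.g_leak)
        out2 = pn_leak_subtract(
            simulate(nvshak2, proto, patch_solutions, art2), 4, -100.0
        )
        assert np.allclose(out1.currents, out2.currents, atol=1e-9)

    def test_activating_subsweeps_warn(self, nvshak1, patch_solutions):
        # sub-pulses delivered around 0 mV open the low-threshold
        # channel and break sub-sweep linearity
        proto = build_protocol("activation_family")
        raw = simulate(nvshak1, proto, patch_solutions, self.ART)
        with pytest.warns(UserWarning, match="linearity"):
            pn_leak_subtract(raw, n_sub=4, sub_hold=30.0)
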