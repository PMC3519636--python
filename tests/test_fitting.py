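import numpy as np
import pytest

import kvclamp as kc
from kvclamp.fitting import (
    BLANK_MS,
    DegenerateFitError,
    UndefinedDelayError,
    activation_delay_and_tau,
    build_gv_curve,
    build_ssi_curve,
    deactivation_tau_curve,
    fit_boltzmann,
    fit_double_exponential,
    fit_exponential,
    isolate_inactivating_component,
    select_inactivation_model,
    tail_amplitude,
)
from kvclamp.gating import ActivationParams, DeactivationParams, GatingParams
from kvclamp.vclamp import Epoch, VoltageProtocol, build_protocol, simulate

from conftest import grid_boltzmann_oracle, grid_exponential_oracle

GRID = np.arange(-60.0, 61.0, 10.0)


class TestBoltzmannFit:
    def test_recovers_published_activation_parameters(self):
        g = 1.0 / (1.0 + np.exp(-(GRID + 19.5) / 5.7))
        fit = fit_boltzmann(GRID, g, normalized=True)
        assert fit.v50 == pytest.approx(-19.5, abs=1e-6)
        assert fit.s == pytest.approx(5.7, abs=1e-6)
        assert fit.converged

    def test_midpoint_identity(self):
        g = 0.1 + 0.8 / (1.0 + np.exp(-(GRID + 10.0) / 4.0))
        fit = fit_boltzmann(GRID, g)
        assert fit.predict(fit.v50) == pytest.approx((fit.a1 + fit.a2) / 2.0)

    def test_decreasing_data_keeps_positive_slope(self):
        h = 1.0 / (1.0 + np.exp((GRID + 30.0) / 6.0))
        fit = fit_boltzmann(GRID, h, normalized=True)
        assert fit.s > 0
        assert fit.v50 == pytest.approx(-30.0, abs=1e-6)
        assert fit.a1 > fit.a2  # direction encoded in the asymptotes

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_boltzmann([0, 10, 20], [0.1, 0.5, 0.9])

    def test_noise_bias_small(self):
        # Monte-Carlo: gaussian noise sigma = 0.02 on the normalized
        # curve must not bias the recovered midpoint by > 0.3 mV
        rng = np.random.default_rng(7)
        truth = 1.0 / (1.0 + np.exp(-(GRID + 19.5) / 5.7))
        v50s = [
            fit_boltzmann(GRID, truth + rng.normal(0, 0.02, GRID.size),
                          normalized=True).v50
            for _ in range(200)
        ]
        assert abs(np.mean(v50s) - (-19.5)) < 0.3

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            v50 = rng.uniform(-45, 10)
            s = rng.uniform(2, 9)
            a1 = rng.uniform(-0.2, 0.2)
            a2 = rng.uniform(0.8, 1.2)
            g = (a1 - a2) / (1.0 + np.exp((GRID - v50) / s)) + a2
            fit = fit_boltzmann(GRID, g)
            oracle = grid_boltzmann_oracle(GRID, g)
            assert fit.v50 == pytest.approx(oracle["v50"], abs=0.05)
            assert fit.s == pytest.approx(oracle["s"], abs=0.05)


class TestExponentialFit:
    @pytest.mark.parametrize("tau", [2.4, 14.1])
    def test_recovers_decay_constant(self, tau):
        t = np.arange(0.0, 12 * tau, 0.05)
        i = 5.0 * np.exp(-t / tau)
        fit = fit_exponential(t, i)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.a > 0

    def test_rise_has_negative_amplitude(self):
        t = np.arange(0.0, 30.0, 0.05)
        i = 4.0 * (1.0 - np.exp(-t / 3.0))
        fit = fit_exponential(t, i)
        assert fit.tau == pytest.approx(3.0, rel=1e-6)
        assert fit.a < 0

    def test_flat_trace_rejected(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(DegenerateFitError):
            fit_exponential(t, np.full_like(t, 2.0))

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tau = rng.uniform(1.0, 50.0)
            a = rng.uniform(0.5, 10.0)
            off = rng.uniform(-1.0, 1.0)
            t = np.arange(0.0, 8 * tau, tau / 40)
            i = off + a * np.exp(-t / tau)
            fit = fit_exponential(t, i)
            oracle = grid_exponential_oracle(t, i)
            assert fit.tau == pytest.approx(oracle["tau"], rel=5e-3)


class TestDoubleExponentialAndSelection:
    T = np.arange(0.0, 600.0, 0.1)

    def _biexp(self):
        return 0.32 * np.exp(-self.T / 33.5) + 0.68 * np.exp(-self.T / 153.6)

    def test_recovers_two_components_with_fractions(self):
        fit = fit_double_exponential(self.T, self._biexp())
        assert fit.tau1 == pytest.approx(33.5, rel=1e-4)
        assert fit.tau2 == pytest.approx(153.6, rel=1e-4)
        assert fit.f1 == pytest.approx(0.32, abs=1e-3)
        assert fit.f2 == pytest.approx(0.68, abs=1e-3)
        assert fit.f1 + fit.f2 == pytest.approx(1.0)
        assert fit.tau1 < fit.tau2

    def test_selects_two_for_biexponential_decay(self):
        assert select_inactivation_model(self.T, self._biexp()).n_components == 2

    def test_selects_one_for_single_exponential(self):
        t = np.arange(0.0, 30.0, 0.05)
        sel = select_inactivation_model(t, np.exp(-t / 2.4))
        assert sel.n_components == 1

    def test_tiny_second_component_not_reported(self):
        i = 0.99 * np.exp(-self.T / 30.0) + 0.01 * np.exp(-self.T / 150.0)
        assert select_inactivation_model(self.T, i).n_components == 1


class TestActivationDelay:
    def test_pure_exponential_rise_has_zero_delay(self):
        t = np.arange(0.0, 30.0, 0.01)
        i = 3.0 * (1.0 - np.exp(-t / 2.0))
        delay, tau = activation_delay_and_tau(t, i, t_pulse_start=0.0)
        assert delay == pytest.approx(0.0, abs=1e-6)
        assert tau == pytest.approx(2.0, rel=1e-6)

    def test_multi_gate_rise_matches_brute_force_oracle(self):
        # m(t)^4 rise with tau_m = 2 ms; oracle: independent grid-search
        # fit of the late phase + closed-form zero crossing
        t = np.arange(0.0, 40.0, 0.005)
        i = (1.0 - np.exp(-t / 2.0)) ** 4
        delay, tau = activation_delay_and_tau(t, i, t_pulse_start=0.0)
        late = i >= 0.5 * i[-1]
        oracle = grid_exponential_oracle(t[late], i[late])
        t_zero = t[late][0] - oracle["tau"] * np.log(-oracle["i_i"] / oracle["a"])
        assert delay > 0
        assert delay == pytest.approx(t_zero, abs=0.02)
        assert tau == pytest.approx(oracle["tau"], rel=0.01)

    def test_delay_non_decreasing_in_gate_count(self):
        t = np.arange(0.0, 40.0, 0.005)
        delays = []
        for n in (1, 2, 4):
            i = (1.0 - np.exp(-t / 2.0)) ** n
            delays.append(activation_delay_and_tau(t, i, 0.0)[0])
        assert delays == sorted(delays)
        assert delays[0] == pytest.approx(0.0, abs=1e-6)
        assert delays[2] > 0

    def test_flat_trace_raises(self):
        t = np.arange(0.0, 10.0, 0.01)
        with pytest.raises(Exception):
            activation_delay_and_tau(t, np.zeros_like(t) - 1.0, 0.0)

    def test_kinetics_curve_over_step_family(self, nvshak2, patch_solutions):
        # four-gate mechanistic activation: every analyzable step shows
        # a positive sigmoidal delay
        from kvclamp.fitting import activation_kinetics_curve
        proto = build_protocol("activation_family", dt=0.02)
        rec = simulate(nvshak2, proto, patch_solutions, mode="mechanistic")
        kin = activation_kinetics_curve(rec)
        assert len(kin.records) >= 4
        for v, delay, tau in kin.records:
            assert delay > 0
            assert tau > 0


class TestTailAmplitude:
    def _tail(self, amp, tau=5.0, t_repol=100.0):
        t = np.arange(95.0, 160.0, 0.05)
        i = np.where(t >= t_repol, amp * np.exp(-(t - t_repol) / tau), 0.0)
        return t, i

    def test_back_extrapolates_to_repolarization_instant(self):
        t, i = self._tail(-7.5)
        assert tail_amplitude(t, i, 100.0) == pytest.approx(-7.5, rel=1e-6)

    def test_closed_channel_returns_zero(self):
        t = np.arange(95.0, 160.0, 0.05)
        assert tail_amplitude(t, np.zeros_like(t), 100.0) == 0.0

    def test_linear_in_conductance(self):
        t, i = self._tail(-3.0)
        a1 = tail_amplitude(t, i, 100.0)
        a2 = tail_amplitude(t, 4.0 * i, 100.0)
        assert a2 == pytest.approx(4.0 * a1, rel=1e-9)

    def test_amplitude_matches_configured_open_probability(
        self, nvshak5, symmetric_k
    ):
        # macroscopic simulation: tail amplitude at -100 mV must equal
        # g_max * Po(step end) * (V_tail - E_K) within 1 %
        from kvclamp.gating import steady_state_activation
        model = nvshak5.truncate()
        proto = build_protocol("gv_tail")
        rec = simulate(model, proto, symmetric_k)
        t_repol = proto.epoch_start(proto.roles["tail"])
        k = 12  # +60 mV step: fully activated
        amp = tail_amplitude(rec.time, rec.currents[k], t_repol)
        po = steady_state_activation(model.activation, 60.0)
        expected = model.g_max * po * (-100.0 - 0.0)
        assert amp == pytest.approx(expected, rel=0.01)


class TestVoltageCurves:
    def test_gv_curve_recovers_published_row(self, nvshak5, symmetric_k):
        proto = build_protocol("gv_tail")
        cells = [simulate(nvshak5.truncate(), proto, symmetric_k)
                 for _ in range(5)]
        gv = build_gv_curve(cells)
        assert gv.fit.v50 == pytest.approx(-30.1, abs=0.5)
        assert gv.fit.s == pytest.approx(4.3, abs=0.2)
        assert gv.mean.max() == pytest.approx(1.0)
        assert np.all(gv.sem < 1e-12)  # identical cells
        assert gv.n == 5

    def test_ssi_curve_recovers_published_row(self, nvshak5, patch_solutions):
        proto = build_protocol("ssi")
        rec = simulate(nvshak5, proto, patch_solutions,
                       mode="instantaneous_activation")
        ssi = build_ssi_curve([rec])
        assert ssi.fit.v50 == pytest.approx(-59.0, abs=0.5)
        assert ssi.fit.s == pytest.approx(6.1, abs=0.2)
        # most hyperpolarized pre-pulse: full availability
        assert ssi.mean[0] == pytest.approx(1.0)
        assert np.all(np.diff(ssi.mean) <= 1e-12)
        assert ssi.sem is None  # single cell: no SEM

    def test_normalization_idempotent(self):
        from kvclamp.fitting import _per_cell_norm
        x = np.array([0.1, 0.4, 1.7, 0.9])
        once = _per_cell_norm(x)
        assert np.array_equal(_per_cell_norm(once), once)


class TestDeactivation:
    def _model(self, tau_ref):
        return GatingParams(
            "d", 0.05, ActivationParams(-30.0, 4.3, 4, 0.7, 40.0),
            DeactivationParams(tau_deact_ref=tau_ref, tau_deact_vslope=40.0),
        )

    def test_taus_follow_closed_form(self, symmetric_k):
        # tau(V) = 5 * exp((V + 100)/40): 1.12 ms at -160, 8.24 at -80
        rec = simulate(self._model(5.0), build_protocol("deactivation_tails"),
                       symmetric_k)
        taus = dict(deactivation_tau_curve(rec))
        assert taus[-160.0] == pytest.approx(1.12, abs=0.01)
        assert taus[-80.0] == pytest.approx(8.24, abs=0.01)

    def test_ten_fold_ratio_recovered(self, symmetric_k):
        proto = build_protocol("deactivation_tails")
        slow = dict(deactivation_tau_curve(simulate(self._model(12.0), proto, symmetric_k)))
        fast = dict(deactivation_tau_curve(simulate(self._model(1.2), proto, symmetric_k)))
        assert slow[-100.0] / fast[-100.0] == pytest.approx(10.0, rel=0.02)

    def test_log_tau_linear_in_voltage(self, symmetric_k):
        rec = simulate(self._model(5.0), build_protocol("deactivation_tails"),
                       symmetric_k)
        taus = deactivation_tau_curve(rec)
        v = np.array([x[0] for x in taus])
        log_tau = np.log([x[1] for x in taus])
        r = np.corrcoef(v, log_tau)[0, 1]
        assert r**2 > 0.999


class TestHeteromerIsolation:
    def test_zero_heteromer_fraction_gives_zero_difference(self, patch_solutions):
        from kvclamp.gating import HeteromerMix
        base = kc.load_fixture("R8")
        mix = HeteromerMix(base.homomer, base.heteromer, het_fraction=0.0)
        proto = build_protocol("heteromer_prepulse")
        rec = simulate(mix, proto, patch_solutions)
        diff = isolate_inactivating_component(rec.currents[0], rec.currents[1])
        t_test = proto.epoch_start(proto.roles["test"])
        # past the brief homomer activation transient (tau ~1.6 ms) the
        # two sweeps are in identical states, so the difference vanishes
        late = rec.time >= t_test + 50.0
        assert np.abs(diff[late]).max() < 1e-6 * np.abs(rec.currents[0]).max()

    def test_difference_matches_pure_heteromeric_current(self, patch_solutions):
        # homomer does not inactivate, heteromer does: the pre-pulse
        # difference equals f * (pure heteromer current) within 1 %
        mix = kc.load_fixture("R8")
        proto = build_protocol("heteromer_prepulse")
        rmix = simulate(mix, proto, patch_solutions)
        rhet = simulate(mix.heteromer, proto, patch_solutions)
        t_test = proto.epoch_start(proto.roles["test"])
        late = rmix.time >= t_test + 10.0  # past activation transients
        diff = isolate_inactivating_component(
            rmix.currents[0], rmix.currents[1]
        )[late]
        pure = mix.het_fraction * (rhet.currents[0] - rhet.currents[1])[late]
        assert np.abs(diff - pure).max() <= 0.01 * np.abs(pure).max()

    def test_difference_decays_while_depol_trace_does_not(self, patch_solutions):
        mix = kc.load_fixture("R8")
        proto = build_protocol("heteromer_prepulse")
        rec = simulate(mix, proto, patch_solutions)
        t_test = proto.epoch_start(proto.roles["test"])
        late = rec.time >= t_test + 10.0
        diff = isolate_inactivating_component(rec.currents[0], rec.currents[1])[late]
        # difference decays toward ~0 (relative to its own peak)
        assert abs(diff[-1]) < 0.1 * np.abs(diff).max()
        depol = rec.currents[1][late]
        assert abs(depol[-1]) > 0.5 * np.abs(depol).max()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            isolate_inactivating_component(np.zeros(5), np.zeros(6))
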