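"""Generator contracts: closed forms, ledgers, determinism."""
import numpy as np
import pytest

from spinaltone import ParameterError
from spinaltone.synth import (
    CellModel,
    VCGenParams,
    apply_drug,
    gen_cc_response,
    gen_count_matrix,
    gen_gcamp_trace,
    gen_vc_trace,
    get_preset,
    psc_kernel,
    rheobase_shift_pa,
)
from spinaltone.synth.calcium import GCAMP_KERNEL

from conftest import plant_glycine


class TestVCTrace:
    def test_no_events_is_constant_baseline(self, quiet_params):
        trace, truth = gen_vc_trace(quiet_params, seed=0)
        assert np.allclose(trace.values, -20.0)
        assert truth.events == []
        assert truth.true_tonic_current_at_hold_pa == 0.0

    def test_planted_events_listed_in_ledger(self, quiet_params):
        times = np.linspace(0.1, 1.8, 20)
        params = quiet_params.replace(noise_sd=1.0)
        trace, truth = gen_vc_trace(
            params, seed=1, planted_events=plant_glycine(times, amp=10.0)
        )
        assert len(truth.events) == 20
        assert [e["time_s"] for e in truth.events] == pytest.approx(list(times))
        # each planted event rises ≥ half its amplitude above the −20 pA hold
        for t in times:
            i = int(t * params.sample_rate)
            seg = trace.values[i : i + int(0.005 * params.sample_rate)]
            assert seg.max() > -20.0 + 5.0

    def test_tonic_offset_matches_closed_form(self, quiet_params):
        g = 0.4  # nS; hold 0 mV, reversal −70 mV → offset g·70 pA
        with_tonic = quiet_params.replace(tonic_conductance_ns={"gaba": g})
        t0, _ = gen_vc_trace(quiet_params, seed=0)
        t1, truth = gen_vc_trace(with_tonic, seed=0)
        assert np.mean(t1.values) - np.mean(t0.values) == pytest.approx(g * 70.0)
        assert truth.true_tonic_current_at_hold_pa == pytest.approx(g * 70.0)

    def test_tonic_offset_with_noise_within_sampling_error(self, quiet_params):
        g, sd = 0.3, 2.0
        a = quiet_params.replace(noise_sd=sd)
        b = quiet_params.replace(noise_sd=sd, tonic_conductance_ns={"glycine": g})
        ta, _ = gen_vc_trace(a, seed=3)
        tb, _ = gen_vc_trace(b, seed=4)
        n = ta.n_samples
        tol = 3.0 * sd / np.sqrt(n) * np.sqrt(2)
        assert np.mean(tb.values) - np.mean(ta.values) == pytest.approx(
            g * 70.0, abs=tol
        )

    def test_epsc_polarity_is_inward_at_minus70(self):
        params = VCGenParams(
            duration=1.0,
            hold_voltage=-70.0,
            noise_sd=0.0,
            baseline_current=0.0,
            tonic_conductance_ns={},
        )
        trace, _ = gen_vc_trace(
            params,
            seed=0,
            planted_events=[
                {
                    "time_s": 0.5,
                    "event_class": "ampa",
                    "amplitude_pa": 15.0,
                    "tau_decay_ms": 2.5,
                }
            ],
        )
        assert trace.values.min() == pytest.approx(-15.0, rel=0.05)
        assert trace.values.max() <= 1e-9

    def test_seed_reproducibility_bit_for_bit(self, ipsc_params):
        p = ipsc_params.replace(duration=5.0)
        a, ta = gen_vc_trace(p, seed=42)
        b, tb = gen_vc_trace(p, seed=42)
        assert np.array_equal(a.values, b.values)
        assert ta.events == tb.events

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            VCGenParams(duration=0.0)
        with pytest.raises(ParameterError):
            VCGenParams(event_rate_per_class={"glycine": -1.0})
        with pytest.raises(ParameterError):
            VCGenParams(tau_decay_dist_per_class={"gaba": (-5.0, 1.0)})


class TestKernel:
    def test_unit_peak_normalization(self):
        t = np.linspace(0.0, 100.0, 20001)
        k = psc_kernel(t, 0.7, 6.2)
        assert k.max() == pytest.approx(1.0, abs=1e-4)
        assert np.all(k[t < 0] == 0) if (t < 0).any() else True

    def test_causal(self):
        t = np.linspace(-10.0, 10.0, 401)
        k = psc_kernel(t, 0.7, 6.2)
        assert np.all(k[t < 0] == 0.0)


class TestDrugs:
    def test_strychnine_zeroes_glycine_components(self, ipsc_params):
        p = apply_drug(ipsc_params, "strychnine")
        assert p.event_rate_per_class["glycine"] == 0.0
        assert p.tonic_conductance_ns["glycine"] == 0.0
        assert p.mixed_component_weights[0] == 0.0
        # gaba untouched
        assert p.event_rate_per_class["gaba"] == ipsc_params.event_rate_per_class["gaba"]

    def test_strychnine_noop_on_gaba_only_params(self):
        p = VCGenParams(
            event_rate_per_class={"gaba": 2.0},
            tonic_conductance_ns={"gaba": 0.3},
        )
        out = apply_drug(p, "strychnine")
        assert out.event_rate_per_class["gaba"] == 2.0
        assert out.tonic_conductance_ns["gaba"] == 0.3

    def test_cnqx_shifts_baseline_nbqx_does_not(self, ipsc_params):
        cnqx = apply_drug(ipsc_params, "cnqx")
        nbqx = apply_drug(ipsc_params, "nbqx")
        assert cnqx.baseline_current - ipsc_params.baseline_current == pytest.approx(
            -11.5
        )
        assert nbqx.baseline_current == ipsc_params.baseline_current

    def test_ampa_block_fraction(self):
        p = VCGenParams(event_rate_per_class={"ampa": 10.0})
        assert apply_drug(p, "cnqx").event_rate_per_class["ampa"] == pytest.approx(1.0)
        assert apply_drug(p, "nbqx").event_rate_per_class["ampa"] == pytest.approx(1.0)

    def test_grp_respects_responsiveness(self, ipsc_params):
        resp = apply_drug(ipsc_params, "grp", responsive=True)
        nonresp = apply_drug(ipsc_params, "grp", responsive=False)
        assert resp.baseline_current < ipsc_params.baseline_current
        assert nonresp.baseline_current == ipsc_params.baseline_current

    def test_both_antagonists_remove_all_tonic(self, ipsc_params):
        p = apply_drug(apply_drug(ipsc_params, "strychnine"), "bicuculline")
        assert p.total_tonic_conductance_ns == 0.0

    def test_unknown_drug_rejected(self, ipsc_params):
        with pytest.raises(ParameterError):
            apply_drug(ipsc_params, "caffeine")


class TestLIF:
    def test_rest_equilibrium_closed_form(self, study_cell):
        trace, truth = gen_cc_response(
            study_cell, [(0.0, 500.0, 0.0)], sample_rate=20000.0
        )
        expected = study_cell.v_rest_mv()
        assert trace.values[-1] == pytest.approx(expected, abs=1e-6)
        assert truth.spike_times_s == []

    def test_subthreshold_step_gives_input_resistance(self, study_cell):
        step = -10.0
        trace, _ = gen_cc_response(study_cell, [(step, 500.0, 0.0)])
        dv = trace.values[-1] - study_cell.v_rest_mv()
        assert dv == pytest.approx(step / study_cell.total_conductance_ns, rel=1e-3)

    def test_analytic_rheobase_separates_spiking(self, study_cell):
        rheo = study_cell.rheobase_analytic_pa()
        below, tb = gen_cc_response(study_cell, [(rheo - 1.0, 500.0, 0.0)])
        above, ta = gen_cc_response(study_cell, [(rheo + 1.0, 500.0, 0.0)])
        assert len(tb.spike_times_s) == 0
        assert len(ta.spike_times_s) >= 1

    def test_removing_tonic_shifts_rheobase_by_tonic_current_at_threshold(
        self, study_cell
    ):
        shift = (
            study_cell.rheobase_analytic_pa()
            - study_cell.without_tonic().rheobase_analytic_pa()
        )
        assert shift == pytest.approx(rheobase_shift_pa(study_cell), abs=1e-9)

    def test_unstable_step_rejected(self, study_cell):
        with pytest.raises(ParameterError):
            gen_cc_response(study_cell, [(10.0, 500.0, 0.0)], sample_rate=10.0)

    def test_empty_protocol_rejected(self, study_cell):
        with pytest.raises(ParameterError):
            gen_cc_response(study_cell, [])


class TestGcamp:
    def test_no_spikes_no_noise_constant_f0(self):
        tr = gen_gcamp_trace([], duration=10.0, f0=123.0)
        assert np.allclose(tr.values, 123.0)

    def test_single_spike_peak_within_frame_attenuation(self):
        rise, decay, amp = GCAMP_KERNEL
        tr = gen_gcamp_trace([5.0], duration=30.0, f0=100.0)
        dff = 100.0 * (tr.values - 100.0) / 100.0
        # worst-case read-out: kernel value half a frame past its maximum
        t_pk = rise * decay / (decay - rise) * np.log(decay / rise)
        floor = amp * psc_kernel(np.array([t_pk + 500.0]), rise, decay)[0]
        assert floor * 0.99 <= dff.max() <= amp * 1.001

    def test_burst_reaches_high_current_calibration_regime(self):
        # ~19 spikes inside a 500 ms pulse, frame-aligned read-out
        spikes = 10.0 + np.linspace(0.0, 0.5, 19)
        tr = gen_gcamp_trace(spikes, duration=60.0, f0=100.0)
        dff = 100.0 * (tr.values - 100.0) / 100.0
        assert 12.0 < dff.max() < 23.0

    def test_negative_f0_rejected(self):
        with pytest.raises(ParameterError):
            gen_gcamp_trace([], duration=1.0, f0=-1.0)


class TestCountGenerator:
    def test_prevalence_one_gives_all_nonzero(self):
        cm, _ = gen_count_matrix(3, 50, planted_prevalence=1.0, seed=0)
        assert (cm.counts > 0).sum() == 3 * 50

    def test_prevalence_recovered_within_binomial_error(self):
        cm, truth = gen_count_matrix(5, 2000, planted_prevalence=0.5, seed=1)
        frac = np.asarray((cm.counts > 0).mean(axis=1)).ravel()
        assert np.all(np.abs(frac - 0.5) < 0.03)

    def test_full_dataset_shape_generates(self):
        cm, _ = gen_count_matrix(24384, 1545, planted_prevalence=0.05, seed=0)
        assert cm.counts.shape == (24384, 1545)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ParameterError):
            gen_count_matrix(2, 10, planted_prevalence=1.5)

    def test_seeded_reproducibility(self):
        a, _ = gen_count_matrix(20, 100, planted_prevalence=0.3, seed=9)
        b, _ = gen_count_matrix(20, 100, planted_prevalence=0.3, seed=9)
        assert (a.counts != b.counts).nnz == 0
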