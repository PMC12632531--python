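import numpy as np
import pandas as pd
import pytest

from feverspike import fate, intracellular, stats, synthetic, units
from feverspike.config import CellParams, SyntheticCohortConfig
from feverspike.records import default_periods


def _single_fate_config(fate_name, **kw):
    mix = {f: 0.0 for f in ("never", "stay", "stop", "start")}
    mix[fate_name] = 1.0
    return SyntheticCohortConfig(
        n_cells=1,
        fate_mix=(mix["never"], mix["stay"], mix["stop"], mix["start"]),
        noise_sd=0.0,
        **kw,
    )


class TestCohortGenerator:
    def test_determinism_same_seed_identical_output(self):
        cfg = SyntheticCohortConfig(n_cells=3, seed=11)
        s1, t1 = synthetic.generate_pn_cohort(cfg)
        s2, t2 = synthetic.generate_pn_cohort(cfg)
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.vm, b.vm)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        s1, _ = synthetic.generate_pn_cohort(SyntheticCohortConfig(n_cells=2, seed=1))
        s2, _ = synthetic.generate_pn_cohort(SyntheticCohortConfig(n_cells=2, seed=2))
        assert not np.array_equal(s1[0].vm, s2[0].vm)

    def test_zero_noise_stay_cell_spikes_at_all_temperatures(self):
        sweeps, truth = synthetic.generate_pn_cohort(_single_fate_config("stay", seed=5))
        assert truth["spikes"].all()
        for sw in sweeps:
            _, idx = intracellular.detect_spikes(sw)
            assert idx.size >= 1

    def test_zero_noise_never_cell_is_silent_everywhere(self):
        sweeps, truth = synthetic.generate_pn_cohort(_single_fate_config("never", seed=5))
        assert not truth["spikes"].any()
        for sw in sweeps:
            _, idx = intracellular.detect_spikes(sw)
            assert idx.size == 0

    @pytest.mark.parametrize("fate_name", ["never", "stay", "stop", "start"])
    def test_zero_noise_pattern_matches_fate_label(self, fate_name):
        cfg = _single_fate_config(fate_name, seed=8)
        _, truth = synthetic.generate_pn_cohort(cfg)
        flags = truth.sort_values("temperature")["spikes"].tolist()
        assert fate.classify_fate(flags).value == fate_name

    def test_zero_noise_cohort_full_fate_fidelity(self):
        cfg = SyntheticCohortConfig(n_cells=40, noise_sd=0.0, seed=17)
        _, truth = synthetic.generate_pn_cohort(cfg)
        for cell_id, grp in truth.groupby("cell_id"):
            flags = grp.sort_values("temperature")["spikes"].tolist()
            assert fate.classify_fate(flags).value == grp["fate"].iloc[0]

    def test_planted_correlation_psp_peak_vs_threshold(self, cohort200):
        # among cells spiking at every temperature, the generated drive
        # tracks the cell's threshold: positive correlation at 39 degC
        _, truth, _ = cohort200
        stay = truth[(truth["fate"] == "stay") & (truth["temperature"] == 39.0)]
        assert len(stay) >= 30
        r, p = stats.pearson(stay["psp_peak_mv"], stay["theta_mv"])
        assert r > 0
        assert p < 0.05

    def test_invalid_fate_mix_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(fate_mix=(0.5, 0.5, 0.5, 0.5))

    def test_non_increasing_temperatures_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(temperatures=(30.0, 39.0, 36.0))


class TestFICurves:
    def test_all_subthreshold_steps_give_zero_spikes(self):
        cp = CellParams(rin_mohm=100.0, theta_mv=-40.0, v_hold=-80.0)
        # I*Rin < 40 mV for all steps
        sweeps = synthetic.generate_fi_sweeps(cp, [50.0, 100.0, 200.0])
        for sw in sweeps:
            _, idx = intracellular.detect_spikes(sw)
            assert idx.size == 0

    def test_first_spiking_step_matches_threshold_rule(self):
        # theta - v_hold = 30 mV; Rin 600 MOhm gives 12/24/36 mV: first crossing at 60 pA
        cp = CellParams(rin_mohm=600.0, theta_mv=-50.0, v_hold=-80.0, tau_m_ms=5.0)
        sweeps = synthetic.generate_fi_sweeps(cp, [20.0, 40.0, 60.0])
        rheo, curve = intracellular.rheobase_and_fi(sweeps)
        assert rheo == 60.0

    def test_spike_count_nondecreasing_in_current(self):
        cp = CellParams(rin_mohm=150.0, theta_mv=-42.0, v_hold=-80.0)
        sweeps = synthetic.generate_fi_sweeps(cp, list(range(50, 801, 50)))
        _, curve = intracellular.rheobase_and_fi(sweeps)
        counts = [n for _, n in curve]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] >= 1

    @pytest.mark.parametrize("rin,theta", [(100.0, -45.0), (150.0, -42.5), (220.0, -38.0)])
    def test_detected_rheobase_equals_analytic_minimum(self, rin, theta):
        cp = CellParams(rin_mohm=rin, theta_mv=theta, v_hold=-80.0)
        steps = list(range(20, 601, 20))
        sweeps = synthetic.generate_fi_sweeps(cp, steps)
        rheo, _ = intracellular.rheobase_and_fi(sweeps)
        assert rheo == synthetic.analytic_rheobase(cp, steps)

    def test_empty_step_list_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_fi_sweeps(CellParams(), [])


class TestUnitPopulation:
    def test_duration_fraction_matches_mixture(self, unit_population_633):
        durs = np.array([u.true_duration_ms for u in unit_population_633])
        frac = np.mean(durs < 0.6)
        assert frac == pytest.approx(0.221, abs=0.03)

    def test_spike_trains_sorted_with_refractory_floor(self, unit_population_633):
        for u in unit_population_633[:50]:
            isi = np.diff(u.spike_times)
            assert np.all(isi >= 0.002 - 1e-12)
            assert np.all(u.spike_times >= 0.0)

    def test_waveform_single_global_trough(self, unit_population_633):
        for u in unit_population_633[:50]:
            wf = u.mean_waveform
            assert np.sum(wf == wf.min()) == 1

    def test_unit_gain_one_gives_equal_period_rates(self):
        pop = synthetic.generate_unit_population(
            n_units=30, fever_gain_dist=(1.0, 0.0), base_rate_dist=(4.0, 0.0), seed=3
        )
        rates = pd.DataFrame([units.period_firing_rates(u) for u in pop])
        # same underlying Poisson rate in every period
        assert rates["fever"].mean() == pytest.approx(rates["baseline"].mean(), rel=0.05)
        assert rates["recovery"].mean() == pytest.approx(rates["baseline"].mean(), rel=0.05)

    def test_expected_total_spike_count(self):
        pop = synthetic.generate_unit_population(
            n_units=5,
            base_rate_dist=(2.0, 0.0),
            fever_gain_dist=(1.0, 0.0),
            seed=4,
        )
        for u in pop:
            # 2 Hz x 8700 s = 17400, minus ~0.4% refractory thinning
            assert u.spike_times.size == pytest.approx(17400, rel=0.03)

    def test_inverted_mixture_means_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_unit_population(
                n_units=10, duration_mixture=((0.9, 0.1), (0.35, 0.05))
            )

    def test_determinism(self):
        a = synthetic.generate_unit_population(n_units=4, seed=9)
        b = synthetic.generate_unit_population(n_units=4, seed=9)
        for ua, ub in zip(a, b):
            np.testing.assert_array_equal(ua.spike_times, ub.spike_times)
            np.testing.assert_array_equal(ua.mean_waveform, ub.mean_waveform)

    def test_duration_mixture_rejects_unimodality(self, unit_population_633):
        durs = [u.true_duration_ms for u in unit_population_633]
        assert stats.dip_test(durs, seed=0).p_value < 0.001


class TestBodyTemperature:
    def test_six_hours_gives_72_readings(self):
        tb = synthetic.generate_body_temperature(duration_h=6.0, seed=0)
        assert tb.times.size == 72
        assert np.allclose(np.diff(tb.times), 300.0)

    def test_zero_fluct_no_bouts_is_constant_baseline(self):
        tb = synthetic.generate_body_temperature(fluct=0.0, n_fever_bouts=0, seed=0)
        np.testing.assert_allclose(tb.tb, 36.5)

    def test_planted_bouts_recovered_by_detector(self):
        tb = synthetic.generate_body_temperature(n_fever_bouts=2, seed=42)
        summ = fate.summarize_tb(tb, fever_threshold=38.0)
        assert len(summ.bouts) == 2

    def test_infrared_sustained_fever(self):
        tb = synthetic.generate_body_temperature(condition="infrared", seed=1)
        # after the onset ramp the elevation persists above 38 degC
        assert np.all(tb.tb[8:] > 38.0)
        assert tb.tb[0] < 38.0

    def test_bounds_invariant(self):
        tb = synthetic.generate_body_temperature(n_fever_bouts=3, seed=5)
        assert np.all((tb.tb >= 30.0) & (tb.tb <= 43.0))
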