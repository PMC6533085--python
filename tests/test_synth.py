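"""Generator tests: release statistics, rendering, archetypes, spiking, EM."""

import math

import numpy as np
import pytest

from gcmli.morphometry import az_docked_correlation, count_docked
from gcmli.photostim import bin_charge_time_course, mean_time_course
from gcmli.synth import (CLASS_LABELS, GCBurst, QuantalSynapseParams,
                         StimulusProtocol, kernel_peak, make_class_archetype,
                         make_cohort, make_morphometry_fixture,
                         make_photostim_archetype, mean_release_profile,
                         render_sweep, simulate_mli_spiking,
                         simulate_photostim_episode, simulate_release_train,
                         unit_kernel)


def params(**kw):
    base = dict(n_sites=4, p_fr=0.5, q_charge=100.0, facil_increment=0.0,
                tau_facil=40.0, tau_recovery=math.inf, reluctant_gain=1.0,
                noise_sigma=0.0)
    base.update(kw)
    return QuantalSynapseParams(**base)


ONE_PULSE = StimulusProtocol(n_pulses=1)


class TestReleaseTrain:
    def test_failure_fraction_matches_binomial_closed_form(self):
        # P(no release at stimulus 1) = (1 - p)^n
        p = params()
        rng = np.random.default_rng(0)
        n_rep = 10_000
        fails = sum(simulate_release_train(p, ONE_PULSE, rng)[0] == 0
                    for _ in range(n_rep))
        expected = (1 - p.p_fr) ** p.n_sites
        se = math.sqrt(expected * (1 - expected) / n_rep)
        assert abs(fails / n_rep - expected) < 3 * se

    def test_zero_release_probability_yields_all_failures(self):
        p = params(p_fr=0.0)
        counts = simulate_release_train(p, StimulusProtocol(), seed=3)
        assert np.all(counts == 0)

    def test_counts_bounded_by_site_number(self):
        p = params(p_fr=0.9, tau_recovery=20.0, facil_increment=0.2)
        for seed in range(20):
            counts = simulate_release_train(p, StimulusProtocol(), seed)
            assert np.all((counts >= 0) & (counts <= p.n_sites))

    def test_uniquantal_synapse_releases_at_most_one_quantum(self):
        p = make_class_archetype("C4", "WT", seed=5)
        assert p.n_sites == 1
        for seed in range(30):
            counts = simulate_release_train(p, StimulusProtocol(), seed)
            assert set(np.unique(counts)) <= {0, 1}

    def test_mean_first_response_equals_np_q(self):
        # no facilitation has accrued at stimulus 1: E[quanta] = n * p
        p = params(facil_increment=0.3, tau_recovery=30.0)
        rng = np.random.default_rng(7)
        first = [simulate_release_train(p, ONE_PULSE, rng)[0]
                 for _ in range(10_000)]
        se = np.std(first, ddof=1) / math.sqrt(len(first))
        assert abs(np.mean(first) - p.n_sites * p.p_fr) < 3 * se

    def test_pure_depletion_profile_is_non_increasing(self):
        p = params(facil_increment=0.0, tau_recovery=math.inf)
        profile = mean_release_profile(p, StimulusProtocol())
        assert np.all(np.diff(profile) <= 1e-12)

    def test_pure_facilitation_profile_is_non_decreasing(self):
        # near-instant refill disables depletion
        p = params(facil_increment=0.2, tau_recovery=1e-6)
        profile = mean_release_profile(p, StimulusProtocol())
        assert np.all(np.diff(profile) >= -1e-12)

    def test_mean_field_matches_monte_carlo(self):
        p = params(facil_increment=0.25, tau_recovery=30.0, reluctant_gain=2.0)
        proto = StimulusProtocol()
        rng = np.random.default_rng(11)
        sims = np.array([simulate_release_train(p, proto, rng)
                         for _ in range(4000)])
        mc = sims.mean(axis=0)
        se = sims.std(axis=0, ddof=1) / math.sqrt(sims.shape[0])
        expected = mean_release_profile(p, proto)
        assert np.all(np.abs(mc - expected) < 4 * se + 1e-9)

    def test_rejects_non_finite_parameters(self):
        with pytest.raises(ValueError):
            params(p_fr=float("nan"))
        with pytest.raises(ValueError):
            params(q_charge=-5.0)
        with pytest.raises(ValueError):
            params(kernel_rise=3.0, kernel_decay=2.0)

    def test_identical_seeds_give_identical_trains(self):
        p = params(facil_increment=0.2, tau_recovery=25.0)
        a = simulate_release_train(p, StimulusProtocol(), 99)
        b = simulate_release_train(p, StimulusProtocol(), 99)
        assert np.array_equal(a, b)


class TestRenderSweep:
    def test_single_quantum_integral_recovers_quantal_charge(self):
        p = params(noise_sigma=0.0)
        proto = StimulusProtocol()
        quanta = np.array([1] + [0] * 9)
        sweep = render_sweep(quanta, p, proto, seed=0)
        rec = sweep.to_recording()
        t0 = float(rec.stimulus_times[0])
        seg = -rec.slice(t0, t0 + proto.isi_ms)
        charge = np.trapezoid(seg, dx=rec.dt)
        assert charge == pytest.approx(p.q_charge, rel=0.01)

    def test_zero_quanta_zero_noise_is_flat(self):
        sweep = render_sweep(np.zeros(10, int), params(), StimulusProtocol(),
                             seed=0)
        assert np.all(sweep.current == 0.0)

    def test_first_charge_scales_linearly_with_quanta(self):
        proto = StimulusProtocol()
        p = params()
        one = render_sweep(np.array([1] + [0] * 9), p, proto, seed=0)
        two = render_sweep(np.array([2] + [0] * 9), p, proto, seed=0)
        assert np.allclose(two.current, 2 * one.current)

    def test_rejects_undersampled_kernel(self):
        proto = StimulusProtocol(sampling_rate=5000.0)  # 2 samples per rise
        with pytest.raises(ValueError, match="sampling_rate"):
            render_sweep(np.ones(10, int), params(), proto, seed=0)

    def test_unit_kernel_integrates_to_one(self):
        t = np.arange(0, 40, 0.02)
        k = unit_kernel(t, 0.4, 2.0)
        assert np.trapezoid(k, t) == pytest.approx(1.0, abs=1e-3)
        t_pk, v_pk = kernel_peak(0.4, 2.0)
        assert k.max() == pytest.approx(v_pk, rel=1e-3)
        assert t[np.argmax(k)] == pytest.approx(t_pk, abs=0.05)


@pytest.fixture(scope="module")
def noiseless_profiles():
    proto = StimulusProtocol()
    out = {}
    for label in CLASS_LABELS:
        p = make_class_archetype(label, "WT", seed=0, jitter=0.0)
        out[label] = mean_release_profile(p, proto) * p.q_charge
    return out


class TestArchetypes:
    def test_c1_is_largest_and_depresses_after_second_pulse(self, noiseless_profiles):
        c1 = noiseless_profiles["C1"]
        others = [noiseless_profiles[c][0] for c in ("C2", "C3", "C4")]
        assert c1[0] > max(others)
        assert c1[1] / c1[0] > 1.0          # paired-pulse facilitation
        assert c1[4:].mean() < c1[1]        # depression after the 2nd pulse

    def test_c2_facilitates_then_depresses(self, noiseless_profiles):
        c2 = noiseless_profiles["C2"]
        peak = int(np.argmax(c2))
        assert c2[1] / c2[0] > 1.5
        assert peak + 1 in (3, 4, 5)
        assert np.all(np.diff(c2[:peak + 1]) > 0)
        assert c2[9] < c2[3]

    def test_c3_sustains_release_through_the_train(self, noiseless_profiles):
        c3 = noiseless_profiles["C3"]
        assert c3[1] / c3[0] > 1.5
        assert c3[9] >= 0.8 * c3.max()

    def test_c4_uniquantal_and_stable(self, noiseless_profiles):
        c4 = noiseless_profiles["C4"]
        assert make_class_archetype("C4", "WT", 0, jitter=0.0).n_sites == 1
        assert c4[1:].max() / c4[1:].min() <= 1.5

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class_id"):
            make_class_archetype("C9", "WT", 0)
        with pytest.raises(ValueError, match="genotype"):
            make_class_archetype("C1", "het", 0)

    def test_uniquantal_failure_rate_is_one_minus_p(self):
        p = make_class_archetype("C4", "WT", seed=2, jitter=0.0)
        rng = np.random.default_rng(3)
        n_rep = 8000
        fails = sum(simulate_release_train(p, ONE_PULSE, rng)[0] == 0
                    for _ in range(n_rep))
        expected = 1 - p.p_fr
        se = math.sqrt(expected * (1 - expected) / n_rep)
        assert abs(fails / n_rep - expected) < 3 * se

    def test_knockout_raises_failures_and_ppr(self):
        proto = StimulusProtocol()
        wt = make_class_archetype("C3", "WT", seed=0, jitter=0.0)
        ko = make_class_archetype("C3", "KO", seed=0, jitter=0.0)
        assert (1 - ko.p_fr) ** ko.n_sites > (1 - wt.p_fr) ** wt.n_sites
        prof_wt = mean_release_profile(wt, proto)
        prof_ko = mean_release_profile(ko, proto)
        assert prof_ko[1] / prof_ko[0] > prof_wt[1] / prof_wt[0]
        # refill dynamics untouched
        assert ko.tau_recovery == wt.tau_recovery
        assert ko.reluctant_gain == wt.reluctant_gain

    def test_cohorts_are_bit_identical_under_equal_seeds(self):
        proto = StimulusProtocol(n_trains=2)
        a = make_cohort({"C1": 2, "C4": 2}, "WT", proto, seed=77)
        b = make_cohort({"C1": 2, "C4": 2}, "WT", proto, seed=77)
        for ra, rb in zip(a.synapses, b.synapses):
            assert ra.params == rb.params
            for sa, sb in zip(ra.sweeps, rb.sweeps):
                assert np.array_equal(sa.current, sb.current)
                assert np.array_equal(sa.truth_quanta, sb.truth_quanta)

    def test_every_cohort_synapse_has_enough_sweeps(self, wt_cohort):
        assert all(len(rec.sweeps) >= 7 for rec in wt_cohort.synapses)


class TestPhotostim:
    def test_single_spike_at_onset_peaks_early(self):
        p = make_photostim_archetype("phasic_large", seed=0, jitter=0.0)
        p = QuantalSynapseParams(**{**p.__dict__, "noise_sigma": 0.0,
                                    "quantal_cv": 0.0, "p_fr": 0.95})
        burst = GCBurst(n_spikes=1, onset_delay=1.0, jitter_ms=0.0)
        sweep, spikes, quanta = simulate_photostim_episode(p, burst, seed=4)
        course = bin_charge_time_course(sweep.to_recording())
        assert course.delay_to_epsc_peak < 20.0

    def test_empty_burst_releases_nothing(self):
        p = make_photostim_archetype("tonic", seed=0)
        burst = GCBurst(n_spikes=0)
        sweep, spikes, quanta = simulate_photostim_episode(p, burst, seed=1)
        assert spikes.size == 0 and quanta.size == 0
        course = bin_charge_time_course(sweep.to_recording())
        assert abs(course.charge_per_bin.sum()) < 5 * p.noise_sigma

    def test_short_episode_rejected(self):
        p = make_photostim_archetype("tonic", seed=0)
        with pytest.raises(ValueError, match="100 ms"):
            simulate_photostim_episode(p, GCBurst(), seed=0, post_ms=80.0)

    def test_phasic_peaks_before_tonic(self):
        burst = GCBurst()
        delays = {}
        for kind in ("phasic_large", "tonic"):
            rng = np.random.default_rng(8)
            p = make_photostim_archetype(kind, seed=3, jitter=0.0)
            courses = [bin_charge_time_course(
                simulate_photostim_episode(p, burst, rng)[0].to_recording())
                for _ in range(10)]
            delays[kind] = mean_time_course(courses).delay_to_epsc_peak
        assert delays["phasic_large"] < delays["tonic"]


class TestMLISpiking:
    def test_homogeneous_rate_recovered_without_coupling(self):
        edges = np.arange(0.0, 1000.5, 1.0)
        rasters = simulate_mli_spiking(edges, np.zeros(edges.size - 1),
                                       baseline_rate=10.0, gain=0.0,
                                       n_repeats=100, seed=5)
        counts = [r.size for r in rasters]
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_silent_without_baseline_or_drive(self):
        edges = np.arange(0.0, 500.5, 1.0)
        rasters = simulate_mli_spiking(edges, np.zeros(edges.size - 1),
                                       baseline_rate=0.0, gain=0.0,
                                       n_repeats=5, seed=2)
        assert all(r.size == 0 for r in rasters)

    def test_negative_rates_clip_to_zero(self):
        edges = np.array([0.0, 10.0, 20.0])
        density = np.array([-100.0, 0.0])
        rasters = simulate_mli_spiking(edges, density, baseline_rate=5.0,
                                       gain=1.0, n_repeats=50, seed=9)
        for r in rasters:
            assert np.all(r >= 10.0)  # no spikes in the clipped bin

    def test_early_drive_advances_the_psth_peak(self):
        from gcmli.photostim import compute_psth
        edges = np.arange(0.0, 100.5, 1.0)
        early = np.zeros(edges.size - 1)
        early[5:15] = 200.0
        late = np.zeros(edges.size - 1)
        late[70:80] = 200.0
        peaks = []
        for density in (early, late):
            rasters = simulate_mli_spiking(edges, density, baseline_rate=2.0,
                                           gain=1.0, n_repeats=100, seed=13)
            firing = compute_psth(rasters, onset=0.0)
            peaks.append(firing.delay_to_frequency_peak)
        assert peaks[0] < peaks[1]


class TestMorphometryFixture:
    def test_knockout_loses_docked_vesicles(self):
        wt = make_morphometry_fixture(200, "WT", seed=0)
        ko = make_morphometry_fixture(200, "KO", seed=1)
        assert np.mean([count_docked(p) for p in ko]) < \
            np.mean([count_docked(p) for p in wt])
        assert max(p.az_length for p in ko) <= 800.0

    def test_docked_never_exceeds_total(self):
        for p in make_morphometry_fixture(100, "WT", seed=3):
            assert count_docked(p) <= p.vesicle_distances.size

    def test_planted_az_docked_correlation_is_positive(self):
        wt = make_morphometry_fixture(200, "WT", seed=4)
        r, p = az_docked_correlation(wt)
        assert r > 0 and p < 0.05
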