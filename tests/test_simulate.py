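import math

import numpy as np
import pytest

from aepkit.preprocess import average_epochs
from aepkit.simulate import (
    CLICK_LEVELS,
    DEFAULT_TEMPLATE,
    ITI_SERIES_MS,
    AnimalRecord,
    CohortSimConfig,
    EarSimParams,
    Stimulus,
    WaveComponent,
    WaveTemplate,
    heartbeat_train,
    render_epoch,
    simulate_cohort,
    simulate_ear_session,
    template_waveform,
)


class TestTemplate:
    def test_default_template_partitions(self, template):
        assert len(template.abr_components) == 5
        assert len(template.aep_components) == 3
        assert all(c.peak_latency_ms < 10 for c in template.abr_components)
        assert all(15 <= c.peak_latency_ms <= 120 for c in template.aep_components)

    def test_invalid_component_rejected(self):
        with pytest.raises(ValueError):
            WaveComponent(+1, 1.0, -0.5, 1.0)
        with pytest.raises(ValueError):
            WaveComponent(0, 1.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            WaveTemplate((WaveComponent(+1, 12.0, 1.0, 1.0),))  # 10-15 ms gap

    def test_param_validation(self):
        with pytest.raises(ValueError):
            EarSimParams(true_threshold=10.0)
        with pytest.raises(ValueError):
            EarSimParams(noise_sd=-1.0)
        with pytest.raises(ValueError):
            EarSimParams(adaptation_tau=0.0)


class TestRenderEpoch:
    def test_noise_free_matches_template(self, template, quiet_params, rng):
        stim = Stimulus("tone", quiet_params.true_threshold + 30.0, 300.0)
        t, trace = render_epoch(template, quiet_params, stim, rng)
        expected = template_waveform(template, quiet_params, stim, t)
        np.testing.assert_array_equal(trace, expected)
        assert np.max(np.abs(trace)) > 0

    def test_subthreshold_is_silent(self, template, quiet_params, rng):
        stim = Stimulus("click", quiet_params.true_threshold, 50.0)
        _, trace = render_epoch(template, quiet_params, stim, rng)
        np.testing.assert_array_equal(trace, 0.0)
        below = Stimulus("click", quiet_params.true_threshold - 10.0, 50.0)
        _, trace = render_epoch(template, quiet_params, below, rng)
        np.testing.assert_array_equal(trace, 0.0)

    def test_adaptation_ratio_closed_form(self, template, rng):
        # ratio of cortical amplitudes at two intervals follows the
        # saturating-recovery factor exactly
        params = EarSimParams(
            true_threshold=40.0, adaptation_tau=150.0, noise_sd=0.0, heartbeat_amp=0.0
        )
        peaks = {}
        for iti in (200.0, 450.0):
            t, trace = render_epoch(template, params, Stimulus("tone", 80.0, iti), rng)
            mask = (t >= 15) & (t <= 30)
            peaks[iti] = trace[mask].max()
        expected = (1 - math.exp(-200 / 150)) / (1 - math.exp(-450 / 150))
        assert peaks[200.0] / peaks[450.0] == pytest.approx(expected, rel=1e-9)

    def test_stimulus_validation(self, template, quiet_params, rng):
        with pytest.raises(ValueError):
            render_epoch(template, quiet_params, Stimulus("tone", 130.0, 300.0), rng)
        with pytest.raises(ValueError):
            render_epoch(template, quiet_params, Stimulus("tone", 80.0, -5.0), rng)
        with pytest.raises(ValueError):
            render_epoch(
                template, quiet_params, Stimulus("tone", 80.0, 300.0), rng,
                sampling_rate=5000.0,
            )

    def test_noise_has_configured_sd(self, template, rng):
        params = EarSimParams(true_threshold=40.0, noise_sd=2.0, heartbeat_amp=0.0)
        stim = Stimulus("click", 40.0, 50.0)  # silent signal: pure noise
        _, trace = render_epoch(template, params, stim, rng)
        assert trace.std() == pytest.approx(2.0, rel=0.05)

    def test_heartbeat_injection(self, template, rng):
        params = EarSimParams(
            true_threshold=40.0, noise_sd=0.0, heartbeat_amp=10.0, heartbeat_rate=5.0
        )
        stim = Stimulus("click", 40.0, 50.0)
        _, trace = render_epoch(template, params, stim, rng)
        assert np.max(np.abs(trace)) > 5.0

    def test_monotonic_in_level(self, template, quiet_params):
        t = np.arange(0, 10, 0.01)
        peaks = []
        for level in (45.0, 55.0, 65.0, 75.0, 85.0):
            w = template_waveform(
                template, quiet_params, Stimulus("click", level, 50.0), t, "abr"
            )
            peaks.append(w.max())
        assert np.all(np.diff(peaks) >= 0)

    def test_monotonic_in_iti(self, template, quiet_params):
        t = np.arange(0, 150, 0.5)
        peaks = []
        for iti in ITI_SERIES_MS:
            w = template_waveform(
                template, quiet_params, Stimulus("tone", 80.0, iti), t, "aep"
            )
            peaks.append(w.max())
        assert np.all(np.diff(peaks) >= 0)


class TestHeartbeatTrain:
    def test_periodicity_and_amplitude(self):
        t = np.arange(0, 2000.0, 0.5)
        hb = heartbeat_train(t, 5.0, 3.0, phase_ms=37.0)
        assert hb.max() == pytest.approx(3.0, rel=0.01)
        # biphasic: symmetric negative lobe
        assert hb.min() == pytest.approx(-3.0, rel=0.01)
        # beats every 200 ms
        peak_times = t[(hb > 2.9)]
        assert np.any(np.abs(np.diff(peak_times)) > 150)

    def test_zero_rate_or_amp(self):
        t = np.arange(0, 100.0, 0.5)
        np.testing.assert_array_equal(heartbeat_train(t, 0.0, 3.0, 0.0), 0.0)
        np.testing.assert_array_equal(heartbeat_train(t, 5.0, 0.0, 0.0), 0.0)


class TestEarSession:
    def test_click_protocol_counts(self):
        params = EarSimParams(noise_sd=0.1)
        session = simulate_ear_session(params, protocols=("click-series",), seed=0)
        rec = session.recordings["click-series"]
        levels = rec.event_attrs["level_db"]
        assert sorted(levels.unique()) == list(CLICK_LEVELS)
        assert len(CLICK_LEVELS) == 15
        counts = levels.value_counts()
        assert (counts == 500).all()

    def test_iti_protocol_counts(self):
        params = EarSimParams(noise_sd=0.1)
        session = simulate_ear_session(params, protocols=("iti-series",), seed=0)
        rec = session.recordings["iti-series"]
        itis = rec.event_attrs["iti_ms"]
        assert sorted(itis.unique()) == [200.0, 250.0, 300.0, 350.0, 450.0]
        assert (itis.value_counts() == 1000).all()

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            simulate_ear_session(EarSimParams(), protocols=("clicks",), seed=0)

    def test_seed_reproducibility(self):
        params = EarSimParams()
        n_reps = {"tone-80dB": 20}
        a = simulate_ear_session(params, protocols=("tone-80dB",), seed=7, n_reps=n_reps)
        b = simulate_ear_session(params, protocols=("tone-80dB",), seed=7, n_reps=n_reps)
        for name in a.recordings["tone-80dB"].channels:
            np.testing.assert_array_equal(
                a.recordings["tone-80dB"].channels[name],
                b.recordings["tone-80dB"].channels[name],
            )
        c = simulate_ear_session(params, protocols=("tone-80dB",), seed=8, n_reps=n_reps)
        assert not np.array_equal(
            a.recordings["tone-80dB"].channels["cortical"],
            c.recordings["tone-80dB"].channels["cortical"],
        )

    def test_sem_matches_noise_law(self):
        # averaging n noise-only epochs: pointwise SEM ~= noise_sd/sqrt(n)
        params = EarSimParams(true_threshold=40.0, noise_sd=1.5, heartbeat_amp=0.0)
        rng = np.random.default_rng(11)
        n = 1000
        stim = Stimulus("click", 40.0, 300.0)  # at threshold: no signal
        t, _ = render_epoch(DEFAULT_TEMPLATE, params, stim, rng, sampling_rate=10000.0)
        epochs = np.vstack(
            [
                render_epoch(
                    DEFAULT_TEMPLATE, params, stim, rng, sampling_rate=10000.0
                )[1]
                for _ in range(n)
            ]
        )
        avg = average_epochs(t, epochs)
        expected = 1.5 / np.sqrt(n)
        assert np.all(np.abs(avg.sem - expected) < 0.1 * expected * 3)
        assert avg.sem.mean() == pytest.approx(expected, rel=0.05)


class TestCohort:
    def test_empty_cohort(self):
        cohort = simulate_cohort(CohortSimConfig(n_wt=0, n_df1=0, seed=1))
        assert cohort == []

    def test_cohort_structure(self):
        cohort = simulate_cohort(CohortSimConfig(n_wt=3, n_df1=2, seed=1))
        assert len(cohort) == 5
        assert all(isinstance(a, AnimalRecord) for a in cohort)
        assert [a.genotype for a in cohort] == ["WT"] * 3 + ["Df1"] * 2
        ids = [a.animal_id for a in cohort]
        assert len(set(ids)) == 5
        for animal in cohort:
            assert animal.left.metadata["ear"] == "left"
            assert animal.right.metadata["ear"] == "right"
            assert 20 <= animal.left.params.true_threshold <= 90

    def test_hi_fraction_binomial(self):
        # Monte-Carlo check of the mixture weight against the binomial law
        config = CohortSimConfig(n_wt=0, n_df1=200, seed=3, df1_p_hi=0.6)
        cohort = simulate_cohort(config)
        flags = [
            s.metadata["hi_component"]
            for a in cohort
            for s in (a.left, a.right)
        ]
        n_ears = len(flags)
        assert n_ears == 400
        frac = sum(flags) / n_ears
        band = 3 * math.sqrt(0.6 * 0.4 / n_ears)
        assert abs(frac - 0.6) <= band

    def test_ear_independence_null_correlation(self):
        config = CohortSimConfig(n_wt=0, n_df1=500, seed=4, ear_independence=True)
        cohort = simulate_cohort(config)
        left = [a.left.params.true_threshold for a in cohort]
        right = [a.right.params.true_threshold for a in cohort]
        r = np.corrcoef(left, right)[0, 1]
        assert abs(r) < 0.1

    def test_correlated_ears_when_disabled(self):
        config = CohortSimConfig(n_wt=0, n_df1=200, seed=4, ear_independence=False)
        cohort = simulate_cohort(config)
        left = [a.left.params.true_threshold for a in cohort]
        right = [a.right.params.true_threshold for a in cohort]
        assert np.corrcoef(left, right)[0, 1] > 0.8

    def test_genotype_effects_applied(self):
        config = CohortSimConfig(n_wt=1, n_df1=1, seed=0)
        wt, df1 = simulate_cohort(config)
        base = config.base_params
        assert wt.left.params.aep_scale == base.aep_scale
        assert df1.left.params.aep_scale == pytest.approx(
            base.aep_scale + config.genotype_effects["aep_scale"]
        )
        assert df1.left.params.adaptation_tau == pytest.approx(
            base.adaptation_tau + config.genotype_effects["adaptation_tau"]
        )

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CohortSimConfig(n_wt=-1)
        with pytest.raises(ValueError):
            CohortSimConfig(df1_p_hi=1.5)

    def test_cohort_seed_reproducible(self):
        kwargs = dict(n_wt=2, n_df1=2, seed=9)
        a = simulate_cohort(CohortSimConfig(**kwargs))
        b = simulate_cohort(CohortSimConfig(**kwargs))
        for x, y in zip(a, b):
            assert x.animal_id == y.animal_id
            assert x.left.params == y.left.params
            assert x.gender == y.gender
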