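import numpy as np
import pytest
from scipy import stats as sps

from keyscore import (
    LatencyMixtureSpec,
    ScaleSpec,
    SimulationConfig,
    build_default_keymap,
    build_scale_template,
    motion_exclusion,
    score_melodic,
    score_rhythm,
    simulate_aaf_cohort,
    simulate_fd_series,
    simulate_latencies,
    simulate_performance,
)
from keyscore import post_error_intervals


@pytest.fixture(scope="module")
def scale_template():
    return build_scale_template(ScaleSpec(0, "major"), build_default_keymap())


class TestSimulatePerformance:
    def test_deterministic_under_seed(self, scale_template):
        cfg = SimulationConfig(
            substitution_rate=0.2, omission_rate=0.1, insertion_rate=0.1,
            onset_jitter_sd_ms=25.0, seed=7,
        )
        a = simulate_performance(scale_template, cfg)
        b = simulate_performance(scale_template, cfg)
        assert a == b

    def test_noise_free_simulation_is_the_template(self, scale_template, keymap):
        perf = simulate_performance(scale_template, SimulationConfig(seed=0))
        assert score_melodic(perf, scale_template, keymap, separated=False).ratio == 1.0
        assert score_rhythm(perf, scale_template).mean_deviance_pct == 0.0

    def test_event_count_conserved_without_ins_and_om(self, scale_template):
        cfg = SimulationConfig(substitution_rate=0.3, onset_jitter_sd_ms=20.0, seed=3)
        perf = simulate_performance(scale_template, cfg)
        assert len(perf.events) == scale_template.n_expected_keypresses

    def test_full_omission_empty_performance(self, scale_template):
        perf = simulate_performance(scale_template, SimulationConfig(omission_rate=1.0, seed=0))
        assert perf.events == ()

    def test_substitution_rate_calibrated(self, keymap, melody_template=None):
        # over many seeds the fraction of substituted notes matches the rate
        template = build_scale_template(ScaleSpec(5, "major"), keymap)
        rate, n_trials = 0.2, 300
        expected_keys = [g.key_indices[0] for g in template.groups]
        n_sub = n_total = 0
        rng = np.random.default_rng(42)
        for _ in range(n_trials):
            perf = simulate_performance(template, SimulationConfig(substitution_rate=rate), rng=rng)
            played = [ev.key_index for ev in perf.events]
            n_sub += sum(p != e for p, e in zip(played, expected_keys))
            n_total += len(played)
        lo, hi = sps.binom.interval(0.999, n_total, rate)
        assert lo <= n_sub <= hi

    def test_chord_asynchrony_keeps_chords_intact(self, keymap, melody_template):
        cfg = SimulationConfig(chord_asynchrony_sd_ms=15.0, seed=11)
        perf = simulate_performance(melody_template, cfg, keymap=keymap)
        score = score_rhythm(perf, melody_template)
        assert score.n_onsets == melody_template.n_groups

    def test_empty_template_impossible(self):
        from keyscore import Template

        with pytest.raises(ValueError):
            Template("empty", 0, ())


class TestSimulateAAFCohort:
    def test_manifest_structure_and_half_altered(self):
        perfs, manifest = simulate_aaf_cohort(4, 24, 0.0, seed=1)
        assert len(perfs) == 4 * 24
        assert list(manifest.columns) == [
            "participant", "trial", "target_position", "alteration_semitones", "feedback",
        ]
        assert (manifest["feedback"] == "altered").sum() == 4 * 12
        alt = manifest[manifest["feedback"] == "altered"]
        assert alt["alteration_semitones"].abs().isin([1, 2]).all()
        assert alt["target_position"].between(5, 12).all()

    def test_zero_delta_zero_mean_slowing(self):
        perfs, manifest = simulate_aaf_cohort(6, 8, 0.0, seed=2)
        deltas = _trial_deltas(perfs, manifest)
        assert np.mean(deltas) == pytest.approx(0.0, abs=1e-9)

    def test_injected_delta_exact_without_jitter(self):
        perfs, manifest = simulate_aaf_cohort(4, 8, 50.0, seed=3)
        deltas = _trial_deltas(perfs, manifest)
        assert deltas == pytest.approx([50.0] * len(deltas))

    def test_reproducible_and_per_participant_streams(self):
        p1, m1 = simulate_aaf_cohort(3, 6, 25.0, seed=9)
        p2, m2 = simulate_aaf_cohort(3, 6, 25.0, seed=9)
        assert p1 == p2 and m1.equals(m2)


def _trial_deltas(perfs, manifest):
    by_key = {(p.participant_id, p.trial_id): p for p in perfs}
    alt = manifest[manifest["feedback"] == "altered"]
    return [
        post_error_intervals(by_key[(r.participant, r.trial)], int(r.target_position)).delta_ms
        for r in alt.itertuples()
    ]


class TestSimulateLatencies:
    def test_degenerate_weight_is_pure_gaussian(self):
        spec = LatencyMixtureSpec(weights=(1.0, 0.0))
        x = simulate_latencies(spec, n=20000, seed=4)
        assert x.mean() == pytest.approx(spec.means_ms[0], abs=0.02)

    def test_mixture_mean_matches_closed_form(self):
        spec = LatencyMixtureSpec()
        n = 100_000
        x = simulate_latencies(spec, n=n, seed=5)
        mu = 0.82 * 8.77 + 0.18 * 12.67
        var = (
            0.82 * (0.5**2 + 8.77**2) + 0.18 * (0.5**2 + 12.67**2) - mu**2
        )
        se = np.sqrt(var / n)
        assert abs(x.mean() - mu) < 3 * se

    def test_same_seed_identical(self):
        a = simulate_latencies(n=100, seed=6)
        b = simulate_latencies(n=100, seed=6)
        assert np.array_equal(a, b)


class TestSimulateFDSeries:
    def test_exact_spike_count(self):
        fd = simulate_fd_series(300, n_spikes=10, spike_magnitude=2.6, seed=7)
        assert int(np.sum(fd > 2.6)) == 10
        assert motion_exclusion(fd, 2.5, 10).excluded  # spikes exceed 2.5 too

    def test_no_spikes_retained(self):
        fd = simulate_fd_series(300, n_spikes=0, seed=8)
        assert not motion_exclusion(fd).excluded

    def test_nine_spikes_retained(self):
        fd = simulate_fd_series(300, n_spikes=9, spike_magnitude=2.6, seed=9)
        assert not motion_exclusion(fd).excluded

    def test_too_many_spikes_rejected(self):
        with pytest.raises(ValueError):
            simulate_fd_series(5, n_spikes=6)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"substitution_rate": -0.1},
            {"substitution_rate": 1.0},
            {"omission_rate": 1.1},
            {"substitution_rate": 0.5, "omission_rate": 0.6},
            {"base_ioi_ms": 0.0},
            {"onset_jitter_sd_ms": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_invalid_mixture_weights_rejected(self):
        with pytest.raises(ValueError):
            LatencyMixtureSpec(weights=(0.6, 0.6))
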