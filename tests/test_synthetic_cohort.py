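import numpy as np
import pytest

from vagusmap import (
    ElectrodeArray,
    StimParams,
    SyntheticConfig,
    ValidationError,
    generate_cohort,
    generate_nerve,
    generate_trace,
    percent_change,
    simulate_responses,
)
from vagusmap.core import signed_angle_diff_deg
from vagusmap.synthetic_cohort import GroundTruth


def make_truth(direction="tachycardia", rotation=0.0):
    cfg = SyntheticConfig()
    return GroundTruth(
        animal_id="A01",
        cuff_rotation_deg=rotation,
        group_center_angles_deg=dict(cfg.group_center_angles_deg),
        afferent_direction=direction,
    )


class TestGenerateNerve:
    def test_zero_counts_give_empty_nerve(self):
        cfg = SyntheticConfig(
            group_counts={k: (0.0, 0.0) for k in SyntheticConfig().group_counts}
        )
        nerve, _ = generate_nerve(cfg, "A01", np.random.default_rng(0))
        assert nerve.fascicles == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_pure_cardiac_fascicles_are_always_efferent(self, seed):
        nerve, _ = generate_nerve(SyntheticConfig(), "A01", np.random.default_rng(seed))
        cardiac = [f for f in nerve.fascicles if f.organ_label == "cardiac"]
        assert all(f.fiber_class == "efferent" for f in cardiac)

    def test_fascicles_contained_and_disjoint(self):
        nerve, _ = generate_nerve(SyntheticConfig(), "A01", np.random.default_rng(7))
        for f in nerve.fascicles:
            assert f.r_mm + f.radius_mm <= nerve.nerve_radius_mm + 1e-9
        fs = nerve.fascicles
        for i in range(len(fs)):
            for j in range(i + 1, len(fs)):
                d = np.hypot(
                    fs[i].center_x_mm - fs[j].center_x_mm,
                    fs[i].center_y_mm - fs[j].center_y_mm,
                )
                assert d >= fs[i].radius_mm + fs[j].radius_mm - 1e-9

    def test_mean_total_count_matches_configuration(self):
        """Monte-Carlo mean fascicle count ~ the configured 29.2 per nerve."""
        cfg = SyntheticConfig()
        rng = np.random.default_rng(42)
        totals = [len(generate_nerve(cfg, "A", rng)[0].fascicles) for _ in range(1000)]
        mean = np.mean(totals)
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(mean - 29.2) < 2 * se

    def test_angular_placement_is_unbiased(self):
        """Realised fascicle angles centre on the planted group angles."""
        cfg = SyntheticConfig()
        rng = np.random.default_rng(3)
        errs = {organ: [] for organ in cfg.group_counts}
        for _ in range(150):
            nerve, truth = generate_nerve(cfg, "A", rng)
            for f in nerve.fascicles:
                errs[f.organ_label].append(
                    float(
                        signed_angle_diff_deg(
                            f.angle_deg, truth.group_center_angles_deg[f.organ_label]
                        )
                    )
                )
        for organ, e in errs.items():
            se = np.std(e, ddof=1) / np.sqrt(len(e))
            assert abs(np.mean(e)) < 4 * se, organ


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self):
        a = generate_cohort(SyntheticConfig(n_animals=4, seed=9))
        b = generate_cohort(SyntheticConfig(n_animals=4, seed=9))
        assert a.nerves == b.nerves
        assert a.truths == b.truths

    def test_cohort_shape(self):
        c = generate_cohort(SyntheticConfig(n_animals=5, seed=0))
        assert len(c.nerves) == 5
        assert len(c.truths) == 5

    def test_rotation_mode_none(self):
        c = generate_cohort(SyntheticConfig(n_animals=4, seed=0, cuff_rotation_mode="none"))
        assert all(t.cuff_rotation_deg == 0.0 for t in c.truths.values())

    def test_afferent_direction_frequency(self):
        cfg = SyntheticConfig(n_animals=400, seed=21)
        c = generate_cohort(cfg)
        frac = np.mean(
            [t.afferent_direction == "tachycardia" for t in c.truths.values()]
        )
        se = np.sqrt(0.6 * 0.4 / 400)
        assert abs(frac - 0.6) < 3 * se


class TestSimulateResponses:
    def _nerve_with_cardiac_under_pad(self, array, pair, r_mm=0.7):
        from vagusmap import Fascicle, NerveSection
        from vagusmap.core import polar_to_xy

        angle = array.pad_angles_deg[pair - 1]
        x, y = polar_to_xy(angle, r_mm)
        f = Fascicle("F1", x, y, 0.1, "cardiac", "efferent")
        return NerveSection("N1", "A01", 0.92, [f])

    def test_zero_amplitude_is_pure_noise(self, array):
        cfg = SyntheticConfig(noise_sd={"HR": 0.0, "BR": 0.0, "EtCO2": 0.0, "EMG": 0.0})
        nerve, truth = generate_nerve(cfg, "A01", np.random.default_rng(0))
        t = simulate_responses(
            nerve, array, StimParams(amplitude_mA=1e-9), "HR", "pre_vagotomy",
            truth, np.random.default_rng(0), config=cfg,
        )
        np.testing.assert_array_equal(t.pct_change, np.zeros(14))

    def test_response_peaks_under_the_stimulated_pad(self, array):
        cfg = SyntheticConfig(noise_sd={"HR": 0.0, "BR": 0.0, "EtCO2": 0.0, "EMG": 0.0})
        nerve = self._nerve_with_cardiac_under_pad(array, pair=5)
        # amplitude just above the nearest pad's recruitment threshold:
        # only pads close to the fascicle can activate it
        t = simulate_responses(
            nerve, array, StimParams(amplitude_mA=4.0), "HR", "pre_vagotomy",
            make_truth(), np.random.default_rng(0), config=cfg,
        )
        assert np.argmin(t.pct_change) == 4  # pair 5, most negative
        assert t.pct_change[4] < 0
        # far pads not activated
        assert np.all(t.pct_change[8:13] == 0.0)

    def test_bradycardia_abolished_after_double_vagotomy(self, array):
        cfg = SyntheticConfig(noise_sd={"HR": 0.0, "BR": 0.0, "EtCO2": 0.0, "EMG": 0.0})
        nerve, truth = generate_nerve(cfg, "A01", np.random.default_rng(1))
        truth.afferent_direction = "bradycardia"
        t = simulate_responses(
            nerve, array, StimParams(amplitude_mA=1e4), "HR", "post_double_vagotomy",
            truth, np.random.default_rng(0), config=cfg,
        )
        np.testing.assert_array_equal(t.pct_change, np.zeros(14))

    def test_tachycardia_persists_after_double_vagotomy(self, array):
        cfg = SyntheticConfig(noise_sd={"HR": 0.0, "BR": 0.0, "EtCO2": 0.0, "EMG": 0.0})
        rng = np.random.default_rng(2)
        for _ in range(10):
            nerve, truth = generate_nerve(cfg, "A01", rng)
            if any(f.organ_label == "cardiopulmonary" for f in nerve.fascicles):
                break
        truth.afferent_direction = "tachycardia"
        t = simulate_responses(
            nerve, array, StimParams(amplitude_mA=1e4), "HR", "post_double_vagotomy",
            truth, np.random.default_rng(0), config=cfg,
        )
        assert t.pct_change.max() > 0

    def test_unknown_condition_rejected(self, array, small_cohort):
        nerve = small_cohort.nerves[0]
        truth = small_cohort.truths[nerve.animal_id]
        with pytest.raises(ValidationError):
            simulate_responses(
                nerve, array, StimParams(), "HR", "sham", truth,
                np.random.default_rng(0),
            )


class TestGenerateTrace:
    def test_step_response_mean(self):
        trace = generate_trace(
            -10.0, "HR", StimParams(), baseline_level=100.0, delay_s=0.0,
            rng=np.random.default_rng(0),
        )
        # direct window check: on-window sits at 90 bpm
        (pair, t0, t1) = trace.schedule[0]
        i0 = int(t0 * trace.sampling_rate_Hz)
        i1 = int(t1 * trace.sampling_rate_Hz)
        assert np.mean(trace.samples[i0:i1]) == pytest.approx(90.0)
        assert percent_change(trace, 1) == pytest.approx(-10.0)

    def test_zero_response_is_flat(self):
        trace = generate_trace(
            0.0, "HR", StimParams(), 100.0, 0.0, np.random.default_rng(0)
        )
        assert percent_change(trace, 1) == pytest.approx(0.0)

    def test_delay_keeps_early_on_window_at_baseline(self):
        trace = generate_trace(
            -10.0, "HR", StimParams(on_s=15, off_s=15), 100.0, 5.0,
            np.random.default_rng(0),
        )
        fs = trace.sampling_rate_Hz
        on_start = int(15 * fs)
        np.testing.assert_array_equal(
            trace.samples[on_start : on_start + int(5 * fs)], 100.0
        )
        # expressed part reaches the target level
        assert trace.samples[on_start + int(5 * fs)] == pytest.approx(90.0)
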