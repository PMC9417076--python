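import numpy as np
import pytest

from imuagree.cycles import detect_cycles, discard_end_cycles, segment_and_normalize
from imuagree.io import Activity, Device
from imuagree.signal_prep import lowpass_filter, quat_to_euler_zxy
from imuagree.synthetic import (
    CohortSpec,
    IDENTITY_DISTORTION,
    SensorDistortion,
    generate_cohort,
    generate_motion_truth,
    render_sensor_view,
    simulate_range_matrix,
)
from imuagree.validity import LinearFit
from imuagree.reliability import IntraclassCorrelation


def _trough_count_oracle(x, floor):
    """Independent argmin-scan trough counter: strict local minima whose
    depth below the lower of the surrounding maxima exceeds the floor."""
    minima = [
        i for i in range(1, len(x) - 1) if x[i] < x[i - 1] and x[i] <= x[i + 1]
    ]
    count = 0
    for i in minima:
        left = x[:i].max()
        right = x[i + 1:].max()
        if min(left, right) - x[i] >= floor:
            count += 1
    return count


class TestMotionTruth:
    def test_squat_trough_count_matches_oracle(self):
        truth = generate_motion_truth("squat", n_cycles=8, cycle_period=3.0, seed=1)
        x = truth.signal("thigh", "ori", "x")
        assert _trough_count_oracle(x, truth.trough_prominence_floor) == 8

    @pytest.mark.parametrize("activity", [a.value for a in Activity])
    def test_every_activity_has_detectable_cycles(self, activity):
        truth = generate_motion_truth(activity, n_cycles=6, seed=2)
        filt = lowpass_filter(truth.signal("thigh", "ori", "x"), truth.sample_rate)
        assert len(detect_cycles(filt, truth.sample_rate)) == 6

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            generate_motion_truth("squat", amplitude_scale=0.0)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            generate_motion_truth("squat", n_cycles=2)

    def test_unknown_activity_rejected(self):
        with pytest.raises(ValueError):
            generate_motion_truth("cartwheel")

    def test_same_seed_reproduces_signals(self):
        a = generate_motion_truth("walk", seed=9)
        b = generate_motion_truth("walk", seed=9)
        for key in a.signals:
            np.testing.assert_array_equal(a.signals[key], b.signals[key])

    def test_walk_has_direction_reversal(self):
        truth = generate_motion_truth("walk", seed=3)
        assert truth.walk_direction is not None
        assert set(np.unique(truth.walk_direction)) == {-1.0, 1.0}
        n = len(truth.walk_direction)
        assert np.all(truth.walk_direction[: n // 4] == 1.0)
        assert np.all(truth.walk_direction[-n // 4:] == -1.0)

    def test_jump_landing_adds_high_frequency_power(self):
        quiet = generate_motion_truth("squat", seed=4)
        jump = generate_motion_truth("jump", seed=4)

        def hf_power(x, fs):
            freqs = np.fft.rfftfreq(len(x), 1 / fs)
            spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
            return spec[freqs > 10].sum() / spec.sum()

        assert hf_power(jump.signal("shank", "acc", "z"), 60.0) > 10 * hf_power(
            quiet.signal("shank", "acc", "z"), 60.0
        )


class TestRenderSensorView:
    def test_identity_distortion_reproduces_truth(self):
        truth = generate_motion_truth("squat", seed=5)
        rec = render_sensor_view(truth, "thigh", IDENTITY_DISTORTION)
        e = quat_to_euler_zxy(rec.quat, truth.sample_rate)
        for axis, stream in (("z", e.z), ("x", e.x), ("y", e.y)):
            np.testing.assert_allclose(
                stream, truth.signal("thigh", "ori", axis), atol=1e-9
            )
        for i, axis in enumerate(("z", "x", "y")):
            np.testing.assert_allclose(
                rec.free_acc[:, i], truth.signal("thigh", "acc", axis), atol=1e-9
            )

    def test_pure_offset_shifts_acceleration_constantly(self):
        truth = generate_motion_truth("squat", seed=6)
        rec = render_sensor_view(truth, "shank", SensorDistortion(offset=5.0))
        diff = rec.free_acc[:, 0] - truth.signal("shank", "acc", "z")
        np.testing.assert_allclose(diff, 5.0, atol=1e-9)

    def test_lag_exceeding_length_rejected(self):
        truth = generate_motion_truth("squat", n_cycles=3, seed=7)
        n = len(truth.times)
        with pytest.raises(ValueError, match="lag"):
            render_sensor_view(truth, "thigh", SensorDistortion(time_lag=n))

    def test_deterministic_given_seed(self):
        truth = generate_motion_truth("squat", seed=8)
        d = SensorDistortion(noise_sd=0.5)
        a = render_sensor_view(truth, "thigh", d, seed=3)
        b = render_sensor_view(truth, "thigh", d, seed=3)
        np.testing.assert_array_equal(a.free_acc, b.free_acc)
        np.testing.assert_array_equal(a.quat, b.quat)

    def test_distortion_validation(self):
        with pytest.raises(ValueError):
            SensorDistortion(gain=0.0)
        with pytest.raises(ValueError):
            SensorDistortion(noise_sd=-1.0)
        with pytest.raises(ValueError):
            SensorDistortion(misalignment_deg=(40.0, 0, 0))


def _lfm_on_pair(dist, seed, axis="z"):
    """Render a test/criterion thigh pair, run the cycle pipeline, fit LFM."""
    truth = generate_motion_truth("squat", n_cycles=8, seed=seed, locations=("thigh",))
    fs = truth.sample_rate
    out = {}
    for device, d in (("criterion", IDENTITY_DISTORTION), ("test", dist)):
        rec = render_sensor_view(
            truth, "thigh", d, device=device, seed=seed + 1000
        )
        thigh_x = lowpass_filter(
            quat_to_euler_zxy(rec.quat, fs).x, fs
        )
        bounds = discard_end_cycles(detect_cycles(thigh_x, fs))
        i = {"z": 0, "x": 1, "y": 2}[axis]
        stream = lowpass_filter(rec.free_acc[:, i], fs)
        out[device] = segment_and_normalize(stream, bounds)
    return LinearFit.from_cycles(out["test"], out["criterion"]).fit(), truth


class TestParameterRecovery:
    def test_gain_offset_recovery(self):
        res, truth = _lfm_on_pair(
            SensorDistortion(gain=0.9, offset=2.0, noise_sd=0.01), seed=11
        )
        rng_span = np.ptp(truth.signal("thigh", "acc", "z"))
        assert res.alpha1 == pytest.approx(0.9, abs=0.02)
        assert res.alpha0 == pytest.approx(2.0, abs=0.05 * rng_span)

    def test_noise_monotonically_degrades_r2(self):
        medians = []
        for sd in (0.0, 0.5, 2.0):
            r2s = [
                _lfm_on_pair(SensorDistortion(noise_sd=sd), seed=s)[0].r2
                for s in range(5)
            ]
            medians.append(np.median(r2s))
        assert medians[0] >= medians[1] >= medians[2]


class TestCohort:
    def test_no_within_subject_variance_gives_icc_one(self):
        spec = CohortSpec(
            n_participants=8, sigma2_between=1.0, sigma2_within=0.0, seed=21,
            n_sessions=2,
        )
        _, recs = generate_cohort(spec, "squat", locations=("thigh",))
        from imuagree.pipeline import process_study

        table = process_study(recs).range_table
        sub = table[
            (table["device"] == "test") & (table["quantity"] == "ori")
            & (table["axis"] == "x")
        ]
        res = IntraclassCorrelation.from_dataframe(sub).fit()
        assert res.icc == pytest.approx(1.0, abs=1e-6)

    def test_no_between_subject_variance_gives_icc_near_zero(self):
        rng = np.random.default_rng(31)
        estimates = [
            IntraclassCorrelation(simulate_range_matrix(40, 2, 0.0, 1.0, rng=rng)).fit().icc
            for _ in range(200)
        ]
        assert abs(np.mean(estimates)) < 0.05

    def test_outcome_model_recovers_icc_075(self):
        rng = np.random.default_rng(41)
        estimates = [
            IntraclassCorrelation(simulate_range_matrix(200, 2, 3.0, 1.0, rng=rng)).fit().icc
            for _ in range(500)
        ]
        assert np.mean(estimates) == pytest.approx(0.75, abs=0.03)

    def test_cohort_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_participants=1)
        with pytest.raises(ValueError):
            CohortSpec(n_participants=5, sigma2_between=-1.0)

    def test_cohort_writes_files_and_manifest(self, tmp_path):
        spec = CohortSpec(n_participants=2, sigma2_between=0.5, seed=51, n_sessions=1)
        manifest, recs = generate_cohort(
            spec, "walk", locations=("thigh",), out_dir=tmp_path
        )
        manifest.validate_files()
        assert len(manifest.entries) == 2
        # walking entries carry direction spans for the reversal
        assert all(e.direction_spans for e in manifest.entries)
        key = ("P001", 1, Device.TEST, list(recs)[0][3])
        assert key in recs
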