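"""Eye-trace preprocessing, saccade detection, segmentation, decoding."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from driftdecode.design import ConditionLabel, StimulusSpec, build_run_schedule
from driftdecode.eyetrack import (
    EyeTrace,
    detect_saccades,
    eye_svm_decode,
    repair_and_center,
    saccade_stats,
    segment_traversals,
)
from driftdecode.synthdata import OculomotorConfig, simulate_eye_run, target_trajectory

C = ConditionLabel


def flat_trace(n=5000, az=0.0, el=0.0, run_id=0):
    return EyeTrace(
        az=np.full(n, az), el=np.full(n, el),
        blink_mask=np.zeros(n, bool), run_id=run_id,
    )


class TestRepair:
    def test_no_blinks_just_mean_centered(self):
        tr = flat_trace(az=2.0, el=-1.0)
        out = repair_and_center(tr)
        np.testing.assert_allclose(out.az, 0.0)
        np.testing.assert_allclose(out.el, 0.0)

    def test_single_sample_gap_interpolated(self):
        az = np.array([1.0, 0.0, 3.0, 1.0, 1.0])
        mask = np.array([False, True, False, False, False])
        tr = EyeTrace(az=az, el=az.copy(), blink_mask=mask)
        out = repair_and_center(tr)
        # interpolated value is 2 before mean centering
        restored = out.az + np.mean([1.0, 2.0, 3.0, 1.0, 1.0])
        assert restored[1] == pytest.approx(2.0)

    def test_boundary_gap_nearest_extension(self):
        az = np.array([0.0, 0.0, 5.0, 5.0])
        mask = np.array([True, True, False, False])
        out = repair_and_center(EyeTrace(az=az, el=az.copy(), blink_mask=mask))
        np.testing.assert_allclose(out.az, 0.0)  # all samples become 5, centered

    def test_output_channels_zero_mean(self):
        rng = np.random.default_rng(0)
        az = rng.normal(3, 1, 2000)
        mask = rng.random(2000) < 0.05
        out = repair_and_center(EyeTrace(az=az, el=az * 2, blink_mask=mask))
        assert out.az.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.el.mean() == pytest.approx(0.0, abs=1e-12)


class TestSaccadeDetection:
    def test_perfect_pursuit_yields_no_events(self, spec):
        """With the target velocity subtracted, noiseless pursuit has zero
        residual velocity and no detected saccades."""
        sch = build_run_schedule(4, seed=1)
        tr = simulate_eye_run(sch, spec, OculomotorConfig.none(), seed=0)
        assert detect_saccades(tr, target=target_trajectory(sch, spec)) == []

    def test_injected_step_detected_with_amplitude(self):
        """A 0.4 deg displacement over 20 ms on noisy fixation is detected
        as exactly one event with the injected amplitude."""
        rng = np.random.default_rng(5)
        n = 4000
        az = rng.normal(0, 0.01, n)
        el = rng.normal(0, 0.01, n)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(1, 21) / 20))
        az[2000:2020] += 0.4 * ramp
        az[2020:] += 0.4
        events = detect_saccades(EyeTrace(az=az, el=el, blink_mask=np.zeros(n, bool)))
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(0.4, abs=0.05)
        assert abs(events[0].direction) < 0.3  # rightward

    def test_raising_lambda_never_increases_count(self):
        rng = np.random.default_rng(6)
        n = 20000
        az = np.cumsum(rng.normal(0, 0.002, n))
        el = np.cumsum(rng.normal(0, 0.002, n))
        for i in range(0, n - 400, 2000):
            az[i : i + 20] += 0.3 * np.linspace(0, 1, 20)
            az[i + 20 :] += 0.3
        tr = EyeTrace(az=az, el=el, blink_mask=np.zeros(n, bool))
        counts = [len(detect_saccades(tr, lam=lam)) for lam in (4, 6, 8, 12, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_offset_invariance(self):
        rng = np.random.default_rng(7)
        n = 6000
        az = rng.normal(0, 0.02, n)
        el = rng.normal(0, 0.02, n)
        az[3000:3020] += np.linspace(0, 0.5, 20)
        az[3020:] += 0.5
        a = detect_saccades(EyeTrace(az=az, el=el, blink_mask=np.zeros(n, bool)))
        b = detect_saccades(
            EyeTrace(az=az + 3.0, el=el - 2.0, blink_mask=np.zeros(n, bool))
        )
        assert len(a) == len(b)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="differentiation"):
            detect_saccades(flat_trace(n=3))


class TestSaccadeStats:
    def _events(self, rng, n, subject, condition, dir_bias=0.0, amp_shift=0.0):
        return pd.DataFrame(
            {
                "subject": subject,
                "condition": condition,
                "amplitude": rng.gamma(2.0, 0.15, n) + amp_shift,
                "direction": rng.uniform(-np.pi, np.pi, n) + dir_bias,
            }
        )

    def test_identical_distributions_give_null_anova(self):
        rng = np.random.default_rng(8)
        frames = [
            self._events(rng, 50, s, c)
            for s in range(6)
            for c in (C.LEFT_ILLUSION, C.RIGHT_ILLUSION, C.LOCAL_LR, C.LOCAL_RL)
        ]
        out = saccade_stats(pd.concat(frames))
        anova = out["anova"]
        assert anova.loc["C(illusion)", "PR(>F)"] > 0.01

    def test_all_leftward_mass_in_pi_bin(self):
        df = pd.DataFrame(
            {
                "subject": 0,
                "condition": C.LEFT_ILLUSION,
                "amplitude": np.full(30, 0.3),
                "direction": np.full(30, np.pi - 1e-6),
            }
        )
        with pytest.warns(UserWarning, match="ANOVA skipped"):
            out = saccade_stats(df)
        hist = out["direction_hist"]["LEFT_ILLUSION"]
        assert hist[-1] == 30 and hist[:-1].sum() == 0

    def test_balanced_equal_cell_means_give_zero_f(self):
        rows = []
        for s in range(4):
            for cond in (C.LEFT_ILLUSION, C.LOCAL_LR):
                for d in (0.0, np.pi):  # rightward, leftward
                    rows.append(
                        {
                            "subject": s,
                            "condition": cond,
                            # subject offsets only: all cell means equal
                            "amplitude": 0.5 + 0.1 * s,
                            "direction": d,
                        }
                    )
        out = saccade_stats(pd.DataFrame(rows))
        assert out["anova"].loc["C(illusion)", "F"] == pytest.approx(0.0, abs=1e-20)


@pytest.fixture(scope="module")
def traces_and_schedules():
    spec = StimulusSpec()
    out = []
    for i in range(8):
        sch = build_run_schedule(4, seed=50 + i)
        tr = simulate_eye_run(sch, spec, OculomotorConfig(), seed=i)
        tr = dataclasses.replace(tr, run_id=i)
        out.append((repair_and_center(tr), sch))
    return out


class TestSegmentation:
    def test_48_exemplars_from_8_runs(self, traces_and_schedules, spec):
        ex = []
        for tr, sch in traces_and_schedules:
            ex.extend(segment_traversals(tr, sch, spec, segment="illusion"))
        assert len(ex) == 48

    def test_exemplar_vector_length(self, traces_and_schedules, spec):
        tr, sch = traces_and_schedules[0]
        ex = segment_traversals(tr, sch, spec, segment="illusion")
        for e in ex:
            assert e.features.size == 2 * int(spec.traversal_duration * 1000)

    def test_labels_match_source_blocks(self, traces_and_schedules, spec):
        tr, sch = traces_and_schedules[0]
        ex = segment_traversals(tr, sch, spec, segment="illusion")
        expected = [
            b.condition
            for b in sch.stimulus_blocks()
            if b.condition in (C.LEFT_ILLUSION, C.RIGHT_ILLUSION)
        ]
        assert [e.label for e in ex] == expected

    def test_fixation_segments_take_preceding_block(self, traces_and_schedules, spec):
        tr, sch = traces_and_schedules[0]
        ex = segment_traversals(tr, sch, spec, segment="fixation")
        assert len(ex) == 6
        assert {e.label for e in ex} <= {C.LEFT_ILLUSION, C.RIGHT_ILLUSION}

    def test_unknown_segment_rejected(self, traces_and_schedules, spec):
        tr, sch = traces_and_schedules[0]
        with pytest.raises(ValueError, match="unknown segment"):
            segment_traversals(tr, sch, spec, segment="bogus")


class TestEyeDecoding:
    def _exemplars(self, bias, seed0=0, n_runs=6, spec=StimulusSpec()):
        ocfg = dataclasses.replace(OculomotorConfig(), condition_bias=bias)
        ex = []
        for i in range(n_runs):
            sch = build_run_schedule(4, seed=70 + i)
            tr = simulate_eye_run(sch, spec, ocfg, seed=seed0 + i)
            tr = dataclasses.replace(tr, run_id=i)
            ex.extend(segment_traversals(repair_and_center(tr), sch, spec))
        return ex

    def test_injected_bias_is_decodable(self):
        """A 0.5 deg horizontal bias between illusion conditions drives
        eye decoding above its permutation threshold (positive control)."""
        res = eye_svm_decode(self._exemplars(0.5), n_perm=100, seed=0)
        assert res.accuracy > res.threshold_95

    def test_null_bias_not_decodable(self):
        res = eye_svm_decode(self._exemplars(0.0), n_perm=100, seed=0)
        assert res.accuracy <= res.threshold_95

    def test_label_swap_symmetry(self):
        ex = self._exemplars(0.3, n_runs=4)
        res = eye_svm_decode(ex, n_perm=100, seed=1)
        swapped = [
            dataclasses.replace(
                e,
                label=C.RIGHT_ILLUSION if e.label is C.LEFT_ILLUSION else C.LEFT_ILLUSION,
            )
            for e in ex
        ]
        res2 = eye_svm_decode(swapped, n_perm=100, seed=1)
        assert res2.accuracy == res.accuracy
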