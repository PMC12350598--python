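import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sceneprompt.reprompt_control import (
    CusumChannel,
    cusum_update,
    interval_step,
    replay_stream,
    scene_aware_step,
)
from sceneprompt.scene_monitor import SceneSample

from _oracles import cusum_oracle


def drive(stream, **kw):
    """Feed a stream through a single channel with reset-on-trigger."""
    ch = CusumChannel("x", **kw)
    trace = []
    for x in stream:
        trig, sp, sm, thr = cusum_update(ch, float(x))
        trace.append((trig, sp, sm, thr))
        if trig:
            ch.reset()
    return trace


class TestCusumUpdate:
    def test_constant_stream_never_triggers(self):
        trace = drive([7.5] * 100)
        assert all(not t[0] for t in trace)
        assert all(t[1] == 0.0 and t[2] == 0.0 for t in trace)

    def test_single_step_values_after_warmup(self):
        # Window after sliding: [2,3,4,5,10] -> mu=4.8, sample sd sqrt(9.7)
        trace = drive([1, 2, 3, 4, 5, 10], k=0.5, alpha=4.0)
        trig, sp, sm, thr = trace[-1]
        sigma = math.sqrt(9.7)
        assert sp == pytest.approx(5.2 - 0.5 * sigma, abs=1e-12)
        assert sm == 0.0
        assert thr == pytest.approx(4.0 * sigma, abs=1e-12)
        assert not trig

    def test_in_range_value_leaves_sums_at_zero(self):
        # Window [2,3,4,5,3]: dX=-0.4 is inside the k*sigma slack band.
        trace = drive([1, 2, 3, 4, 5, 3], k=0.5, alpha=4.0)
        trig, sp, sm, _ = trace[-1]
        assert (trig, sp, sm) == (False, 0.0, 0.0)

    def test_warmup_window_cannot_trigger(self):
        """The first W observations only fill the window."""
        trace = drive([0, 100, -100, 50, 3], k=0.5, alpha=2.0)
        assert all(not t[0] for t in trace)

    def test_sustained_shift_triggers_low_noise(self):
        rng = np.random.default_rng(7)
        stream = np.concatenate(
            [rng.normal(100, 1.0, 50), rng.normal(150, 1.0, 10)]
        )
        trace = drive(stream, k=0.5, alpha=4.0)
        first = next(i for i, t in enumerate(trace) if t[0])
        assert 50 <= first <= 54

    def test_non_finite_observation_rejected(self):
        ch = CusumChannel("x")
        with pytest.raises(ValueError):
            cusum_update(ch, float("nan"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_recursion(self, seed):
        rng = np.random.default_rng(seed)
        stream = rng.normal(10.0, 2.0, 500)
        got = drive(stream, k=0.5, alpha=3.0)
        want = cusum_oracle(stream, w=5, k=0.5, alpha=3.0)
        for g, w in zip(got, want):
            assert g[0] == w[0]
            assert g[1] == pytest.approx(w[1], abs=1e-12)
            assert g[2] == pytest.approx(w[2], abs=1e-12)
            assert g[3] == pytest.approx(w[3], abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
def test_sums_never_negative(values):
    ch = CusumChannel("x")
    for x in values:
        _, sp, sm, _ = cusum_update(ch, x)
        assert sp >= 0.0
        assert sm >= 0.0


def test_first_trigger_monotone_in_alpha():
    """Raising the threshold factor can only delay the first trigger."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        stream = rng.normal(50, 5, 300)
        stream[150:] += rng.uniform(10, 40)
        firsts = []
        for alpha in (2.0, 4.0, 6.0, 8.0, 10.0):
            trace = drive(stream, alpha=alpha)
            first = next((i for i, t in enumerate(trace) if t[0]), math.inf)
            firsts.append(first)
        assert firsts == sorted(firsts)


def _sample(index, values, invalid=()):
    names = set(values)
    return SceneSample(
        index=index,
        values=dict(values),
        validity={n: (n not in invalid) for n in names},
    )


class TestSceneAwareStep:
    def test_constant_parameters_never_trigger(self):
        chans = [CusumChannel("area_pct", alpha=4.0)]
        for i in range(50):
            d = scene_aware_step(chans, _sample(i, {"area_pct": 25.0}))
            assert not d.triggered

    def test_trigger_names_the_deviating_channel(self):
        chans = [
            CusumChannel("area_pct", alpha=4.0),
            CusumChannel("consistency_iou", alpha=4.0),
        ]
        rng = np.random.default_rng(0)
        triggered = None
        for i in range(60):
            cons = 0.95 + rng.normal(0, 0.004) if i < 30 else 0.55
            d = scene_aware_step(
                chans,
                _sample(i, {"area_pct": 25.0, "consistency_iou": cons}),
            )
            if d.triggered:
                triggered = d
                break
        assert triggered is not None
        assert triggered.reason == "cusum"
        assert triggered.trigger_channel == "consistency_iou"
        # trigger resets every channel
        assert all(len(c.window) == 0 and c.s_plus == 0.0 for c in chans)

    def test_invalid_parameter_skips_channel(self):
        chans = [CusumChannel("consistency_iou", alpha=4.0)]
        d = scene_aware_step(
            chans, _sample(0, {"consistency_iou": 0.0}, invalid=("consistency_iou",))
        )
        assert not d.triggered
        assert len(chans[0].window) == 0

    def test_empty_channel_list_rejected(self):
        with pytest.raises(ValueError):
            scene_aware_step([], _sample(0, {"area_pct": 1.0}))


class TestIntervalStep:
    def test_interval_trigger_positions(self):
        """n=10 on 100 frames prompted at 0 -> re-prompts at 10,20,...,90."""
        last = 0
        triggers = []
        for i in range(1, 100):
            d = interval_step(10, i - last, index=i)
            if d.triggered:
                triggers.append(i)
                last = i
        assert triggers == [10, 20, 30, 40, 50, 60, 70, 80, 90]

    def test_never_mode(self):
        assert not any(
            interval_step(None, fsp).triggered for fsp in range(0, 1000, 7)
        )

    def test_every_frame_mode(self):
        assert not interval_step(1, 0).triggered
        assert all(interval_step(1, fsp).triggered for fsp in range(1, 10))

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_step(0, 5)


def test_replay_counts_fall_with_alpha():
    """On one replayed stream (no resets), higher alpha can only lose triggers."""
    rng = np.random.default_rng(3)
    stream = np.concatenate([rng.normal(30, 1, 200), rng.normal(45, 1, 200)])
    counts = [
        int(replay_stream(stream, alpha=a, reset_on_trigger=False)["triggered"].sum())
        for a in (2.0, 10.0)
    ]
    assert counts[1] <= counts[0]
    trace = replay_stream(stream, alpha=2.0)
    assert {"s_plus", "s_minus", "threshold", "triggered"} <= set(trace.columns)
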