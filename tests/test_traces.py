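"""Ratio extraction, normalization, aggregation, sorting and screening."""

import numpy as np
import pytest

from wormscreen.core import ImageStack, StimulusProtocol
from wormscreen.nuclei import NeuronTrack
from wormscreen.traces import (
    RatioTrace,
    aggregate,
    extract_ratio,
    normalize_min,
    resample,
    screen_stimulus,
    sort_by_reference,
    stimulus_waveform,
)


def _uniform_stack(g=4.0, r=2.0, n_frames=6, shape=(6, 12, 12)):
    data = np.empty((n_frames,) + shape + (2,))
    data[..., 0] = g
    data[..., 1] = r
    return ImageStack(data)


def _center_track(n_frames, center=(3.0, 6.0, 6.0), status=None):
    return NeuronTrack(
        neuron_id=0,
        centers=np.tile(center, (n_frames, 1)),
        status=status or ["tracked"] * n_frames,
        mask_radius=2.0,
    )


class TestExtractRatio:
    def test_g_twice_r_gives_two(self):
        stack = _uniform_stack(g=4.0, r=2.0)
        trace = extract_ratio(stack, _center_track(6))
        assert np.allclose(trace.values, 2.0)

    def test_lost_frames_missing(self):
        stack = _uniform_stack()
        status = ["tracked"] * 3 + ["lost"] * 3
        trace = extract_ratio(stack, _center_track(6, status=status))
        assert np.all(np.isfinite(trace.values[:3]))
        assert np.all(np.isnan(trace.values[3:]))

    def test_reference_below_floor_missing(self):
        stack = _uniform_stack(g=4.0, r=0.0)
        trace = extract_ratio(stack, _center_track(6))
        assert np.all(np.isnan(trace.values))

    def test_invariant_under_common_gain(self):
        """The ratiometric rationale: a gain applied to both channels cancels."""
        stack = _uniform_stack(g=4.0, r=2.0)
        scaled = ImageStack(stack.data * 7.5)
        t1 = extract_ratio(stack, _center_track(6))
        t2 = extract_ratio(scaled, _center_track(6))
        assert np.allclose(t1.values, t2.values)


class TestNormalizeMin:
    def test_definition(self):
        tr = RatioTrace(0, [0, 1, 2], [2.0, 4.0, 8.0])
        assert np.allclose(normalize_min(tr).values, [1, 2, 4])

    def test_constant_becomes_ones(self):
        tr = RatioTrace(0, [0, 1, 2], [3.0, 3.0, 3.0])
        assert np.allclose(normalize_min(tr).values, 1.0)

    def test_idempotent_and_order_preserving(self):
        tr = RatioTrace(0, np.arange(5), [5.0, 2.0, 9.0, 4.0, 2.5])
        once = normalize_min(tr)
        twice = normalize_min(once)
        assert np.allclose(once.values, twice.values)
        assert np.array_equal(np.argsort(once.values), np.argsort(tr.values))
        assert once.normalized

    def test_non_positive_minimum_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_min(RatioTrace(0, [0, 1], [0.0, 1.0]))


class TestAggregate:
    def test_single_trace(self):
        tr = RatioTrace(0, [0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        mean, se = aggregate([tr], np.array([0.0, 1.0, 2.0]))
        assert np.allclose(mean.values, tr.values)
        assert np.allclose(se.values, 0.0)
        assert np.all(mean.n_contributing == 1)

    def test_two_constant_traces(self):
        """Traces {1,1,1} and {3,3,3}: mean 2, SE = sd/sqrt(2) = 1."""
        t = np.array([0.0, 1.0, 2.0])
        a = RatioTrace(0, t, np.ones(3))
        b = RatioTrace(1, t, np.full(3, 3.0))
        mean, se = aggregate([a, b], t)
        assert np.allclose(mean.values, 2.0)
        assert np.allclose(se.values, 1.0)

    def test_interpolation_identity_at_shared_timestamps(self):
        fine = RatioTrace(0, np.arange(0, 4, 0.5), np.arange(8, dtype=float))
        out = resample(fine, np.array([0.0, 1.0, 2.0, 3.0]))
        assert np.allclose(out, [0, 2, 4, 6])

    def test_identical_traces_zero_se(self):
        t = np.arange(4, dtype=float)
        traces = [RatioTrace(i, t, np.array([1.0, 2.0, 1.5, 3.0])) for i in range(5)]
        mean, se = aggregate(traces, t)
        assert np.allclose(mean.values, traces[0].values)
        assert np.allclose(se.values, 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], np.array([0.0]))


class TestSortByReference:
    def test_self_first_negation_last(self):
        t = np.arange(10, dtype=float)
        ref = RatioTrace("ref", t, np.sin(t) + 2)
        neg = RatioTrace("neg", t, 4 - ref.values)
        flat = RatioTrace("flat", t, np.full(10, 2.0))
        ordered = sort_by_reference([neg, flat, ref], ref)
        assert ordered[0][0].neuron_id == "ref" and ordered[0][1] == pytest.approx(1.0)
        assert ordered[1][0].neuron_id == "neg" and ordered[1][1] == pytest.approx(-1.0)
        assert ordered[-1][0].neuron_id == "flat" and np.isnan(ordered[-1][1])

    def test_matches_brute_force_ranking(self, rng):
        t = np.arange(50, dtype=float)
        ref = RatioTrace("ref", t, rng.random(50))
        traces = [RatioTrace(f"n{i}", t, rng.random(50)) for i in range(10)]
        ordered = sort_by_reference(traces, ref)
        brute = sorted(
            (np.corrcoef(tr.values, ref.values)[0, 1] for tr in traces), reverse=True
        )
        assert np.allclose([r for _, r in ordered], brute)


class TestScreenStimulus:
    def test_waveform_itself_positive(self):
        proto = StimulusProtocol()
        t = np.arange(0, 300, 0.5)
        wave = stimulus_waveform(proto, t)
        res = screen_stimulus(RatioTrace(0, t, wave + 1.0), proto)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.classification == "positive"
        assert len(res.cycle_amplitudes) == proto.repeats

    def test_zero_variance_uncorrelated(self):
        proto = StimulusProtocol()
        t = np.arange(0, 300, 0.5)
        res = screen_stimulus(RatioTrace(0, t, np.ones_like(t)), proto)
        assert res.classification == "uncorrelated"
        assert np.isnan(res.pearson_r)

    def test_noiseless_adapting_index(self):
        """gamma = 0.5 over 5 cycles: (A1 - A5)/A1 = 1 - 0.5^4 = 0.9375."""
        from wormscreen.synthetic import NeuronSpec, true_trace

        proto = StimulusProtocol()
        t = np.arange(0, 300, 0.5)
        spec = NeuronSpec(
            center0=(0, 0, 0), response_class="positive_adapting",
            gain=1.0, adaptation_factor=0.5,
        )
        tr = true_trace(spec, t, proto, np.random.default_rng(0))
        res = screen_stimulus(RatioTrace(0, t, tr), proto)
        assert res.adaptation_index == pytest.approx(0.9375, abs=0.01)
        assert res.classification == "positive"
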