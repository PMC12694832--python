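"""Step-wise propagation: wavefront semantics, traces, smoothing, FGM."""

import numpy as np
import pytest

from segnet import stimgen, timesim
from segnet.netcore import NetConfig, SegmentationNetwork, one_hot
from segnet.timesim import (ScheduleConfig, TraceSet, divergence_onset, fgm,
                            init_state, loop_length, run_timecourse,
                            smooth_trace, step)

TINY = NetConfig(image_size=16, v1_channels=3, v2_channels=4, v4_channels=5,
                 it_units=7)


@pytest.fixture(scope="module")
def tiny_net():
    return SegmentationNetwork(TINY, seed=3)


@pytest.fixture(scope="module")
def schedule():
    return ScheduleConfig(noise_mean=0.3, noise_std=0.15)


def rand_img(seed, side=16):
    return np.random.default_rng(seed).uniform(0, 1, (1, side, side)).astype(
        np.float32)


# ---------------------------------------------------------------------------
# initialization and stepping


def test_init_is_deterministic(tiny_net, schedule):
    s1 = init_state(tiny_net, one_hot(0), schedule, seed=5)
    s2 = init_state(tiny_net, one_hot(0), schedule, seed=5)
    assert np.array_equal(s1.v1_feedback(), s2.v1_feedback())
    s3 = init_state(tiny_net, one_hot(0), schedule, seed=6)
    assert not np.array_equal(s1.v1_feedback(), s3.v1_feedback())


def test_zero_noise_init_equals_constant_image_response(tiny_net):
    sch = ScheduleConfig(noise_mean=0.4, noise_std=0.0)
    st = init_state(tiny_net, one_hot(2), sch, seed=1)
    img = np.full((1, 1, 16, 16), 0.4, dtype=np.float32)
    ff, _ = tiny_net.feedforward_pass(img[:, 0])
    assert np.allclose(st.buffers["v1_ff"][0], ff.a[("v1", 0)])


def test_static_image_reaches_feedforward_fixed_point(tiny_net, schedule):
    img = rand_img(7)
    st = init_state(tiny_net, one_hot(0), schedule, seed=2)
    states = [st]
    for _ in range(12):
        states.append(step(states[-1], img))
    # V1m a reaches its stimulus value at step 1 and never changes again
    v1_1 = states[1].buffers["v1_ff"][0]
    for s in states[2:]:
        assert np.array_equal(s.buffers["v1_ff"][0], v1_1)
    # the whole state converges to the direct full evaluation
    ff, _ = tiny_net.feedforward_pass(img[None, 0] if img.ndim == 3 else img)
    assert np.allclose(states[-1].buffers["fc"], ff.scores, atol=1e-6)


def test_wavefront_bound(tiny_net, schedule):
    """A stage's buffer cannot depend on the stimulus before the step equal
    to its connection distance from the input."""
    img_a, img_b = rand_img(8), rand_img(9)
    sa = init_state(tiny_net, one_hot(0), schedule, seed=3)
    sb = init_state(tiny_net, one_hot(0), schedule, seed=3)
    # shortest-path connection distances at per-area granularity; the
    # mirrors are reached early through their local gating by a, long
    # before the class-specific loop through FCm arrives
    dist = {"v1_ff": 1, "v2_ff": 2, "v4_ff": 3, "it": 4, "fc": 5,
            "head": 5, "fb_v4": 4, "fb_v2": 3, "fb_v1": 2}

    def flat(buf):
        out = {}
        for k, v in buf.items():
            if isinstance(v, tuple):
                out[k] = v[0] if not isinstance(v[0], list) else v[0][0]
            elif isinstance(v, list):
                out[k] = v[0]
            else:
                out[k] = v
        return out

    for t in range(1, 10):
        sa, sb = step(sa, img_a), step(sb, img_b)
        fa, fb_ = flat(sa.buffers), flat(sb.buffers)
        for name, d in dist.items():
            if t < d:
                assert np.array_equal(fa[name], fb_[name]), (name, t)
        # the wavefront itself has arrived: stages at distance exactly t differ
        arrived = [n for n, d in dist.items() if d == t]
        for name in arrived:
            assert not np.array_equal(fa[name], fb_[name]), (name, t)


def test_attention_template_fixed_across_steps(tiny_net, schedule):
    st = init_state(tiny_net, one_hot(4), schedule, seed=4)
    img = rand_img(10)
    for _ in range(3):
        st = step(st, img)
    assert np.array_equal(st.attend, np.atleast_2d(one_hot(4)))


def test_per_layer_granularity_runs(tiny_net):
    sch = ScheduleConfig(granularity="per-layer", noise_mean=0.3,
                         noise_std=0.1)
    assert loop_length(sch, tiny_net) == 21  # 9 blocks + it + fc + head + 9 mirrors
    st = init_state(tiny_net, one_hot(0), sch, seed=1)
    st2 = step(st, rand_img(11))
    assert st2.v1_feedback().shape == (1, 16, 16)


# ---------------------------------------------------------------------------
# region traces


@pytest.fixture(scope="module")
def square_stimuli():
    rng = np.random.default_rng(12)
    out = []
    for i in range(3):
        bg = stimgen.TextureSpec(orientation=rng.uniform(0, 180))
        out.append(stimgen.sample_scene(rng, [0], bg))
    return out


@pytest.fixture(scope="module")
def net56():
    return SegmentationNetwork(
        NetConfig(v1_channels=2, v2_channels=3, v4_channels=4, it_units=6),
        seed=0)


def test_run_timecourse_shapes_and_sem(square_stimuli, net56):
    sch = ScheduleConfig(noise_mean=0.3, noise_std=0.1, total_steps=12)
    ts = run_timecourse(square_stimuli, 0, net56, sch, seed=0)
    assert ts.n_stimuli == 3
    for r in ("figure", "edge", "ground"):
        assert ts.per_stimulus[r].shape == (3, 13)
        assert ts.sem[r] is not None
    ts1 = run_timecourse(square_stimuli[:1], 0, net56, sch, seed=0)
    assert ts1.sem["figure"] is None  # SEM undefined for a single stimulus


def test_timecourse_skips_stimuli_without_target(square_stimuli, net56):
    rng = np.random.default_rng(13)
    digit_only = stimgen.sample_scene(rng, [5], stimgen.TextureSpec(30.0))
    sch = ScheduleConfig(noise_mean=0.3, noise_std=0.1, total_steps=10)
    ts = run_timecourse(square_stimuli + [digit_only], 0, net56, sch, seed=0)
    assert ts.n_stimuli == 3
    with pytest.raises(ValueError):
        run_timecourse([digit_only], 0, net56, sch, seed=0)


def test_trace_determinism(square_stimuli, net56):
    sch = ScheduleConfig(noise_mean=0.3, noise_std=0.1, total_steps=10)
    a = run_timecourse(square_stimuli, 0, net56, sch, seed=9)
    b = run_timecourse(square_stimuli, 0, net56, sch, seed=9)
    for r in ("figure", "edge", "ground"):
        assert np.array_equal(a.per_stimulus[r], b.per_stimulus[r])


# ---------------------------------------------------------------------------
# smoothing


def sliding_polyfit(y, window, order):
    """Oracle: direct least-squares polynomial fit in each window."""
    half = window // 2
    out = np.empty_like(y, dtype=float)
    ypad = np.pad(y, half, mode="edge")
    # interior points only (edges use different boundary handling)
    for i in range(len(y)):
        seg = ypad[i:i + window]
        coef = np.polynomial.polynomial.polyfit(np.arange(window), seg, order)
        out[i] = np.polynomial.polynomial.polyval(half, coef)
    return out


def test_smoothing_preserves_constants_and_ramps():
    const = np.full(20, 3.7)
    assert np.allclose(smooth_trace(const), 3.7, atol=1e-8)
    ramp = np.linspace(0, 5, 20)
    sm = smooth_trace(ramp)
    assert np.allclose(sm, np.linspace(0, 5, 160), atol=1e-6)


def test_smoothing_matches_sliding_polyfit_oracle():
    rng = np.random.default_rng(14)
    y = rng.normal(0, 1, 160)
    ours = smooth_trace(y, upsample_to=160, order=3, window=7)
    oracle = sliding_polyfit(y, 7, 3)
    half = 3
    assert np.abs(ours[half:-half] - oracle[half:-half]).max() < 1e-8


def test_smoothing_validation():
    with pytest.raises(ValueError):
        smooth_trace(np.zeros(20), window=6)
    with pytest.raises(ValueError):
        smooth_trace(np.zeros(20), order=9, window=7)
    with pytest.raises(ValueError):
        smooth_trace(np.zeros(5), upsample_to=5, window=7)


# ---------------------------------------------------------------------------
# FGM


def _trace_set(figure, edge, ground):
    ts = TraceSet(layer="v1_fb0", per_stimulus={
        "figure": np.atleast_2d(figure), "edge": np.atleast_2d(edge),
        "ground": np.atleast_2d(ground)})
    return ts.finalize()


def test_fgm_zero_when_figure_equals_ground():
    t = np.linspace(0, 1, 10)
    out = fgm(_trace_set(t, t + 0.5, t))
    assert np.allclose(out["figure"], 0.0)
    assert np.allclose(out["edge"], 0.5)


def test_fgm_invariant_to_common_offset():
    rng = np.random.default_rng(15)
    f, e, g = rng.normal(0, 1, (3, 12))
    a = fgm(_trace_set(f, e, g))
    b = fgm(_trace_set(f + 2.3, e + 2.3, g + 2.3))
    assert np.allclose(a["figure"], b["figure"], atol=1e-12)
    assert np.allclose(a["edge"], b["edge"], atol=1e-12)


def test_fgm_requires_all_regions():
    ts = TraceSet(layer="x", per_stimulus={"figure": np.zeros((1, 4))})
    ts.mean = {"figure": np.zeros(4)}
    with pytest.raises(ValueError):
        fgm(ts)


def test_divergence_onset():
    a = np.zeros(10)
    b = np.zeros(10)
    b[6:] = 1.0
    assert divergence_onset(a, b) == 6
    assert divergence_onset(a, a) is None


def test_traces_to_frame_tidy(square_stimuli, net56):
    sch = ScheduleConfig(noise_mean=0.3, noise_std=0.1, total_steps=8)
    ts = run_timecourse(square_stimuli, 0, net56, sch, seed=0, condition="att")
    df = timesim.traces_to_frame(ts)
    assert set(df.columns) == {"layer", "region", "condition", "step", "mean",
                               "sem", "n"}
    assert len(df) == 3 * 9
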