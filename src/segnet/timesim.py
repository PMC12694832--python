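"""Time-stepped propagation of activity through the trained network.

Wavefront semantics: activity crosses exactly one connection per discrete
time step.  Every processing stage recomputes its output each step from its
predecessors' previous-step values, so new stimulus information advances one
stage per step while the rest of the network still holds values driven by
the initialization.  The network is initialized at its response to a white
noise image with the attentional template already active in FCm, the
stimulus is then presented, and the V1m feedback-unit activity is tracked
over steps.

Because feedback-unit activity b is gated by the local feedforward activity
a, three response phases emerge in V1m with increasing latency: a
stimulus-driven transient (a reaches V1m after one step), figure-ground
modulation (the feedback drive z becomes stimulus-dependent through the
nearby mirrored areas a few steps later), and object-based attention (the
class-specific signal must travel the full loop to FCm and back).

At the default per-area granularity the input -> FCm -> V1m-mirror loop is
9 connections; ``per-layer`` granularity splits each area into its three
blocks/mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter

from . import stimgen
from .nn import F32, sigmoid
from .netcore import NetworkState, SegmentationNetwork, attention_gate, one_hot

REGIONS = ("figure", "edge", "ground")
_REGION_CODE = {"figure": stimgen.FIGURE, "edge": stimgen.EDGE,
                "ground": stimgen.GROUND}


def default_noise_spec(seed: int = 0) -> tuple[float, float]:
    """Mean/std of the white-noise init image, matched to the default
    background texture statistics."""
    tex = stimgen.make_background_texture(
        (stimgen.CANVAS, stimgen.CANVAS), stimgen.TextureSpec(orientation=0.0), seed)
    return float(tex.mean()), float(tex.std())


@dataclass
class ScheduleConfig:
    granularity: str = "per-area"  # or "per-layer"
    total_steps: Optional[int] = None  # default: 2 * loop length + 4
    noise_mean: Optional[float] = None
    noise_std: Optional[float] = None
    attention_preactivation: bool = True

    def __post_init__(self):
        if self.granularity not in ("per-area", "per-layer"):
            raise ValueError("granularity must be 'per-area' or 'per-layer'")
        if self.noise_mean is None or self.noise_std is None:
            m, s = default_noise_spec()
            self.noise_mean = m if self.noise_mean is None else self.noise_mean
            self.noise_std = s if self.noise_std is None else self.noise_std


@dataclass
class Stage:
    name: str
    deps: list
    fn: Callable  # fn(buffers, image, attend) -> value


def _area_ff(net, area, train=False):
    def fn(x):
        for blk in net.blocks[area]:
            x = blk.forward(x, train)
        return x

    return fn


def build_stages(net: SegmentationNetwork, granularity: str) -> list[Stage]:
    """Topologically ordered stage graph; one stage == one connection."""
    nb = net.cfg.blocks_per_area
    stages: list[Stage] = []

    if granularity == "per-area":
        def v1(buf, image, attend):
            a, x = [], image
            for blk in net.blocks["v1"]:
                x = blk.forward(x)
                a.append(x)
            return a

        def mk_area(area, prev_area):
            def fn(buf, image, attend):
                x = net.down[prev_area].forward(buf[f"{prev_area}_ff"][-1])
                a = []
                for blk in net.blocks[area]:
                    x = blk.forward(x)
                    a.append(x)
                return a
            return fn

        def it(buf, image, attend):
            ds4 = net.down["v4"].forward(buf["v4_ff"][-1])
            h = net.it_relu.forward(net.it.forward(ds4.reshape(ds4.shape[0], -1)))
            return ds4, h

        def fc(buf, image, attend):
            return sigmoid(net.fc.forward(buf["it"][1]))

        def head(buf, image, attend):
            gated = attention_gate(buf["fc"], attend)
            return net.feedback_head(gated, buf["it"][0])

        def mk_fb(area, above):
            def fn(buf, image, attend):
                st = NetworkState()
                for j in range(nb):
                    st.a[(area, j)] = buf[f"{area}_ff"][j]
                c_above = buf[above] if above == "head" else buf[above][2]
                c_out = net.feedback_area(area, c_above, st)
                b = [st.b[(area, j)] for j in range(nb)]
                c = [st.c[(area, j)] for j in range(nb)]
                return b, c, c_out
            return fn

        stages = [
            Stage("v1_ff", [], v1),
            Stage("v2_ff", ["v1_ff"], mk_area("v2", "v1")),
            Stage("v4_ff", ["v2_ff"], mk_area("v4", "v2")),
            Stage("it", ["v4_ff"], it),
            Stage("fc", ["it"], fc),
            Stage("head", ["fc", "it"], head),
            Stage("fb_v4", ["head", "v4_ff"], mk_fb("v4", "head")),
            Stage("fb_v2", ["fb_v4", "v2_ff"], mk_fb("v2", "fb_v4")),
            Stage("fb_v1", ["fb_v2", "v1_ff"], mk_fb("v1", "fb_v2")),
        ]
        return stages

    # per-layer: every conv block and every mirror is its own stage
    def mk_block(area, j, prev):
        def fn(buf, image, attend):
            if prev is None:
                x = image
            elif j == 0:
                x = net.down[prev].forward(buf[f"{prev}_ff{nb - 1}"])
            else:
                x = buf[f"{area}_ff{j - 1}"]
            return net.blocks[area][j].forward(x)
        return fn

    for area, prev in (("v1", None), ("v2", "v1"), ("v4", "v2")):
        for j in range(nb):
            dep = ([] if prev is None else [f"{prev}_ff{nb - 1}"]) if j == 0 \
                else [f"{area}_ff{j - 1}"]
            stages.append(Stage(f"{area}_ff{j}", dep, mk_block(area, j, prev)))

    def it(buf, image, attend):
        ds4 = net.down["v4"].forward(buf[f"v4_ff{nb - 1}"])
        return ds4, net.it_relu.forward(net.it.forward(ds4.reshape(ds4.shape[0], -1)))

    def fc(buf, image, attend):
        return sigmoid(net.fc.forward(buf["it"][1]))

    def head(buf, image, attend):
        return net.feedback_head(attention_gate(buf["fc"], attend), buf["it"][0])

    stages.append(Stage("it", [f"v4_ff{nb - 1}"], it))
    stages.append(Stage("fc", ["it"], fc))
    stages.append(Stage("head", ["fc", "it"], head))

    from .netcore import feedback_signal, modulate

    def mk_mirror(area, j, above):
        def fn(buf, image, attend):
            a = buf[f"{area}_ff{j}"]
            if j == nb - 1:
                src = buf[above] if above == "head" else buf[above][1]
                z = net.up[area].forward(src)
            else:
                z = net.lat[area][j].forward(buf[f"{area}_fb{j + 1}"][1])
            b = modulate(a, z, net.betas.params[f"{area}_{j}"])
            return b, feedback_signal(b, a)
        return fn

    for area, above in (("v4", "head"), ("v2", "v4_fb0"), ("v1", "v2_fb0")):
        for j in range(nb - 1, -1, -1):
            dep = [f"{area}_ff{j}"]
            dep.append(above if j == nb - 1 else f"{area}_fb{j + 1}")
            stages.append(Stage(f"{area}_fb{j}", dep, mk_mirror(area, j, above)))
    return stages


@dataclass
class SimState:
    """Buffers of every stage plus the constants of one simulation run."""

    buffers: dict
    stages: list
    attend: np.ndarray
    granularity: str

    def v1_feedback(self, which: str = "b") -> np.ndarray:
        """Lowest V1m mirror activity, channel-averaged: (batch, 56, 56)."""
        if self.granularity == "per-area":
            b_list, c_list, _ = self.buffers["fb_v1"]
            arr = b_list[0] if which == "b" else c_list[0]
        else:
            b, c = self.buffers["v1_fb0"]
            arr = b if which == "b" else c
        return arr.mean(axis=1)

    def seg_map(self, net: SegmentationNetwork) -> np.ndarray:
        if self.granularity == "per-area":
            b0 = self.buffers["fb_v1"][0][0]
        else:
            b0 = self.buffers["v1_fb0"][0]
        return sigmoid(net.readout.forward(b0))[:, 0]


def loop_length(schedule: ScheduleConfig, net: SegmentationNetwork) -> int:
    """Connections on the input -> FCm -> lowest-V1m-mirror path."""
    return len(build_stages(net, schedule.granularity))


def init_state(net: SegmentationNetwork, attend, schedule: ScheduleConfig,
               seed: int, batch: int = 1) -> SimState:
    """Network state at the response to a seeded white-noise image.

    The attention template is active during initialization (and stays fixed
    for the whole simulation).  Deterministic for a fixed seed.
    """
    if not net.param_group("fb"):
        raise ValueError("network lacks feedback parameters")
    attend = np.atleast_2d(np.asarray(attend, dtype=F32))
    if attend.shape[0] == 1 and batch > 1:
        attend = np.repeat(attend, batch, axis=0)
    rng = np.random.default_rng(seed)
    m, s = schedule.noise_mean, schedule.noise_std
    half = np.sqrt(3.0) * s
    side = net.cfg.image_size
    noise = rng.uniform(m - half, m + half,
                        size=(attend.shape[0], 1, side, side))
    noise = np.clip(noise, 0.0, 1.0).astype(F32)
    init_attend = attend if schedule.attention_preactivation else \
        np.eye(attend.shape[1], dtype=F32)[np.zeros(attend.shape[0], dtype=int)]
    stages = build_stages(net, schedule.granularity)
    buffers = {}
    for st in stages:  # topological order -> converged response to the noise
        buffers[st.name] = st.fn(buffers, noise, init_attend)
    return SimState(buffers=buffers, stages=stages, attend=attend,
                    granularity=schedule.granularity)


def step(state: SimState, image: np.ndarray, net: SegmentationNetwork = None) -> SimState:
    """One synchronous update: every stage reads previous-step buffers."""
    x = np.asarray(image, dtype=F32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    new = {st.name: st.fn(state.buffers, x, state.attend) for st in state.stages}
    return SimState(buffers=new, stages=state.stages, attend=state.attend,
                    granularity=state.granularity)


# ---------------------------------------------------------------------------
# trace extraction


@dataclass
class TraceSet:
    """Region-averaged V1m time courses across stimuli.

    ``per_stimulus[region]`` is (n_stimuli, n_steps); step 0 is the
    initialized (pre-stimulus) state, step t the state after t connection
    steps.  ``sem`` entries are None when only one stimulus was run.
    """

    layer: str
    per_stimulus: dict
    mean: dict = field(default_factory=dict)
    sem: dict = field(default_factory=dict)
    n_stimuli: int = 0
    condition: str = ""

    def finalize(self):
        for r, arr in self.per_stimulus.items():
            self.mean[r] = arr.mean(axis=0)
            self.sem[r] = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
                           if arr.shape[0] > 1 else None)
        self.n_stimuli = next(iter(self.per_stimulus.values())).shape[0]
        return self


def _target_region_maps(stimuli, target_class: int, edge_width: int = 2):
    maps, kept = [], []
    for i, s in enumerate(stimuli):
        if not s.labels[target_class]:
            continue
        others = [s.masks[k] for k in s.present_classes() if k != target_class]
        maps.append(stimgen.region_map(s.masks[target_class], edge_width, others))
        kept.append(i)
    return maps, kept


def run_timecourse(stimuli: Sequence[stimgen.Stimulus],
                   attend: Union[int, Sequence[int], Callable],
                   net: SegmentationNetwork,
                   schedule: Optional[ScheduleConfig] = None,
                   seed: int = 0, target_class: int = 0,
                   condition: str = "", return_maps: bool = False):
    """Propagate a batch of stimuli step by step and average over regions.

    ``attend`` may be a class index, one index per stimulus, or a callable
    mapping a stimulus to an index.  Region assignment (figure / edge /
    ground of the ``target_class`` object, other objects excluded) uses the
    generator's ground truth.  Stimuli lacking the target object are
    skipped.  Returns a :class:`TraceSet` (and the raw per-pixel maps if
    ``return_maps``).
    """
    schedule = schedule or ScheduleConfig()
    rmaps, kept = _target_region_maps(stimuli, target_class)
    if not kept:
        raise ValueError(f"no stimulus contains class {target_class}")
    stimuli = [stimuli[i] for i in kept]
    if callable(attend):
        att_idx = [attend(s) for s in stimuli]
    elif np.isscalar(attend):
        att_idx = [int(attend)] * len(stimuli)
    else:
        att_idx = [int(np.asarray(attend)[i]) for i in kept]
    attend_vecs = np.stack([one_hot(k) for k in att_idx])

    total = schedule.total_steps or (2 * loop_length(schedule, net) + 4)
    images = stimgen.images_array(stimuli)
    state = init_state(net, attend_vecs, schedule, seed, batch=len(stimuli))

    region_px = {
        r: [rm.pixels(_REGION_CODE[r]) for rm in rmaps] for r in REGIONS
    }
    side = net.cfg.image_size
    traces = {r: np.zeros((len(stimuli), total + 1)) for r in REGIONS}
    maps = np.zeros((len(stimuli), total + 1, side, side),
                    dtype=F32) if return_maps else None

    def record(t):
        v1b = state.v1_feedback("b")
        if return_maps:
            maps[:, t] = v1b
        for r in REGIONS:
            for i in range(len(stimuli)):
                traces[r][i, t] = v1b[i][region_px[r][i]].mean()

    record(0)
    for t in range(1, total + 1):
        state = step(state, images)
        record(t)
    ts = TraceSet(layer="v1_fb0", per_stimulus=traces, condition=condition).finalize()
    return (ts, maps, kept) if return_maps else ts


def smooth_trace(trace: np.ndarray, upsample_to: int = 160, order: int = 3,
                 window: int = 7) -> np.ndarray:
    """Display smoothing: linear up-sampling then a Savitzky-Golay filter.

    Never feeds statistics; onset analyses use the raw step-resolution
    traces.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than the window")
    trace = np.asarray(trace, dtype=float)
    x = np.linspace(0.0, 1.0, trace.size)
    xi = np.linspace(0.0, 1.0, upsample_to)
    up = np.interp(xi, x, trace)
    if window >= up.size:
        raise ValueError("window must be smaller than the trace length")
    return savgol_filter(up, window, order)


def fgm(traces: TraceSet) -> dict:
    """Figure-ground modulation per step: region trace minus ground trace."""
    for r in REGIONS:
        if r not in traces.mean:
            raise ValueError(f"trace set lacks region {r!r}")
    return {
        "figure": traces.mean["figure"] - traces.mean["ground"],
        "edge": traces.mean["edge"] - traces.mean["ground"],
    }


def divergence_onset(a: np.ndarray, b: np.ndarray, frac: float = 0.25) -> Optional[int]:
    """First step where |a - b| exceeds ``frac`` of its maximum excursion.

    Computed on raw step-resolution traces; None if the traces never
    separate.
    """
    d = np.abs(np.asarray(a) - np.asarray(b))
    peak = d[1:].max()
    if peak <= 0:
        return None
    hits = np.flatnonzero(d >= frac * peak)
    hits = hits[hits > 0]
    return int(hits[0]) if hits.size else None


def response_onset(trace: np.ndarray, frac: float = 0.25) -> Optional[int]:
    """First step where the trace departs from its initialized value."""
    d = np.abs(np.asarray(trace) - trace[0])
    peak = d.max()
    if peak <= 0:
        return None
    return int(np.flatnonzero(d >= frac * peak)[0])


def three_phase_onsets(ts_attended: TraceSet, ts_unattended: TraceSet,
                       frac: float = 0.25) -> dict:
    """Latencies of the three response phases in the V1m traces.

    ``stimulus``: first departure of the figure trace from its initialized
    level; ``figure_ground``: first divergence of figure and ground traces;
    ``attention``: first divergence of the figure traces between the
    attended and unattended conditions.  All traces are baseline-corrected
    to their step-0 (pre-stimulus) values so that small initialization
    differences between conditions do not masquerade as early effects.
    Computed on raw step-resolution traces.
    """
    def base(tr):
        return np.asarray(tr) - tr[0]

    fig_u = base(ts_unattended.mean["figure"])
    gnd_u = base(ts_unattended.mean["ground"])
    fig_a = base(ts_attended.mean["figure"])
    return {
        "stimulus": response_onset(ts_unattended.mean["figure"], frac),
        "figure_ground": divergence_onset(fig_u, gnd_u, frac),
        "attention": divergence_onset(fig_a, base(ts_unattended.mean["figure"]),
                                      frac),
    }


# ---------------------------------------------------------------------------
# space-time profile


@dataclass
class SpaceTimeProfile:
    """FGM as a function of position relative to the figure and time.

    Positions are signed distances to the figure boundary (positive inside);
    FGM in each bin is the bin's mean V1m feedback activity minus the
    far-ground reference bin's, averaged across stimuli.  Empty bins are
    NaN.
    """

    values: np.ndarray  # (n_bins, n_steps)
    bin_labels: list
    bin_edges: np.ndarray
    n_stimuli: int
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, label in enumerate(self.bin_labels):
            for t in range(self.values.shape[1]):
                rows.append({"bin": label, "step": t, "fgm": self.values[bi, t],
                             "condition": self.condition})
        return pd.DataFrame(rows)


DEFAULT_BIN_EDGES = np.array([-np.inf, -6.0, -2.0, 2.0, 5.0, np.inf])
BIN_LABELS = ["ground_far", "ground", "edge", "figure", "center"]


def spacetime_profile(stimuli: Sequence[stimgen.Stimulus], attend,
                      net: SegmentationNetwork,
                      schedule: Optional[ScheduleConfig] = None,
                      seed: int = 0, target_class: int = 0,
                      bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
                      condition: str = "") -> SpaceTimeProfile:
    """Bin per-pixel V1m feedback traces by distance to the figure edge."""
    schedule = schedule or ScheduleConfig()
    _, maps, kept = run_timecourse(stimuli, attend, net, schedule, seed,
                                   target_class, condition, return_maps=True)
    return profile_from_maps(stimuli, maps, kept, target_class, bin_edges,
                             condition)


def profile_from_maps(stimuli, maps, kept, target_class: int = 0,
                      bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
                      condition: str = "") -> SpaceTimeProfile:
    """Build the space-time FGM profile from recorded per-pixel traces."""
    used = [stimuli[i] for i in kept]
    n_bins = len(bin_edges) - 1
    acc = np.zeros((n_bins, maps.shape[1]))
    cnt = np.zeros(n_bins)
    for i, s in enumerate(used):
        mask = s.masks[target_class]
        inside = ndimage.distance_transform_edt(mask)
        outside = ndimage.distance_transform_edt(~mask)
        sd = np.where(mask, inside, -outside)
        excluded = np.zeros_like(mask)
        for k in s.present_classes():
            if k != target_class:
                excluded |= s.masks[k]
        ref_px = (~excluded) & (sd <= bin_edges[1])
        if not ref_px.any():
            continue
        ref = maps[i][:, ref_px].mean(axis=1)
        for bi in range(n_bins):
            px = (~excluded) & (sd > bin_edges[bi]) & (sd <= bin_edges[bi + 1])
            if px.any():
                acc[bi] += maps[i][:, px].mean(axis=1) - ref
                cnt[bi] += 1
    values = np.where(cnt[:, None] > 0, acc / np.maximum(cnt[:, None], 1), np.nan)
    return SpaceTimeProfile(values=values, bin_labels=list(BIN_LABELS),
                            bin_edges=np.asarray(bin_edges),
                            n_stimuli=len(used), condition=condition)


def traces_to_frame(ts: TraceSet) -> pd.DataFrame:
    """Tidy long-format table: layer, region, condition, step, mean, sem, n."""
    rows = []
    for r in REGIONS:
        for t, m in enumerate(ts.mean[r]):
            rows.append({"layer": ts.layer, "region": r, "condition": ts.condition,
                         "step": t, "mean": m,
                         "sem": np.nan if ts.sem[r] is None else ts.sem[r][t],
                         "n": ts.n_stimuli})
    return pd.DataFrame(rows)
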