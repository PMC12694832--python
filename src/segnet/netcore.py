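"""Dual-pathway segmentation network.

A driving feedforward hierarchy of model cortical areas
(V1m -> V2m -> V4m -> ITm -> FCm) maps a 56x56 grayscale stimulus onto
independent per-class detection scores, and a modulatory feedback pathway
maps an attended class back onto pixels.

Every convolutional layer in V1m/V2m/V4m has a mirrored feedback unit of
identical shape, conceptually sitting in the same cortical column.  The
feedback units cannot drive silent feedforward units: with ``a`` the
(rectified, hence non-negative) feedforward activity, ``z`` the feedback
drive arriving from above and ``beta`` a learned offset,

    b = max(0, a * (z + beta))        (modulatory gain, gated by a)
    c = b - a                         (the segmentation signal sent down)

so ``b`` and ``c`` vanish wherever ``a`` does.  Only the short
FCm -> ITm-level head of the feedback pathway is driving (ordinary layers),
mirroring the classification head it inverts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from . import nn
from .nn import F32

AREAS = ("v1", "v2", "v4")  # fine -> coarse
N_CLASSES = 12


@dataclass
class NetConfig:
    """Architecture hyper-parameters.

    The default values are the full-size model: V1m 20x56x56, V2m 50x28x28,
    V4m 100x14x14, the V4m output strided down to 100x7x7, ITm with 500
    units and FCm with one unit per class.
    """

    image_size: int = 56
    n_classes: int = N_CLASSES
    v1_channels: int = 20
    v2_channels: int = 50
    v4_channels: int = 100
    it_units: int = 500
    kernel: int = 3
    blocks_per_area: int = 3
    beta_granularity: str = "channel"  # or "scalar"
    readout_source: str = "b"  # or "c"

    def channels(self, area: str) -> int:
        return {"v1": self.v1_channels, "v2": self.v2_channels,
                "v4": self.v4_channels}[area]

    def spatial(self, area: str) -> int:
        return {"v1": self.image_size, "v2": self.image_size // 2,
                "v4": self.image_size // 4}[area]

    @classmethod
    def from_yaml(cls, path) -> "NetConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def scaled_config() -> NetConfig:
    """Reduced-width architecture for CPU-scale experiments.

    Same depth, areas and resolutions as the full model; only channel
    counts shrink so that two-phase training finishes in minutes on one
    core.
    """
    return NetConfig(v1_channels=8, v2_channels=16, v4_channels=24, it_units=64)


# ---------------------------------------------------------------------------
# modulatory feedback primitives


def modulate(a: np.ndarray, z: np.ndarray, beta) -> np.ndarray:
    """Feedback-unit activity ``b = max(0, a * (z + beta))``.

    ``a`` must be non-negative (it is the output of a rectifier); ``z`` and
    ``beta`` may take either sign.  ``b`` inherits ``a``'s zeros: feedback is
    modulatory, never driving.
    """
    a = np.asarray(a, dtype=F32)
    if np.any(a < 0):
        raise ValueError("feedforward activity a must be non-negative")
    return np.maximum(np.float32(0.0), a * (np.asarray(z, dtype=F32) + beta))


def feedback_signal(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Signed segmentation signal ``c = b - a`` propagated downward."""
    b = np.asarray(b, dtype=F32)
    a = np.asarray(a, dtype=F32)
    if b.shape != a.shape:
        raise ValueError(f"shape mismatch: b {b.shape} vs a {a.shape}")
    return b - a


def attention_gate(scores: np.ndarray, attend: np.ndarray) -> np.ndarray:
    """Multiply the class scores elementwise with a one-hot attention vector."""
    scores = np.atleast_2d(np.asarray(scores, dtype=F32))
    attend = np.atleast_2d(np.asarray(attend, dtype=F32))
    if scores.shape != attend.shape:
        raise ValueError("scores and attention vector shapes differ")
    if not (np.all((attend == 0) | (attend == 1)) and np.all(attend.sum(axis=1) == 1)):
        raise ValueError("attention vector must be one-hot")
    return scores * attend


def one_hot(class_index, n_classes: int = N_CLASSES) -> np.ndarray:
    v = np.zeros(n_classes, dtype=F32)
    v[class_index] = 1.0
    return v


@dataclass
class NetworkState:
    """All pathway activities for one batch of stimuli.

    ``a``/``z``/``b``/``c`` are keyed by ``(area, block_index)`` with block 0
    the lowest (finest) layer of the area.
    """

    a: dict = field(default_factory=dict)
    z: dict = field(default_factory=dict)
    b: dict = field(default_factory=dict)
    c: dict = field(default_factory=dict)
    scores: Optional[np.ndarray] = None
    seg_map: Optional[np.ndarray] = None


class _BetaBank(nn.Layer):
    def __init__(self, cfg: NetConfig):
        super().__init__()
        for area in AREAS:
            c = cfg.channels(area) if cfg.beta_granularity == "channel" else 1
            for j in range(cfg.blocks_per_area):
                self.params[f"{area}_{j}"] = np.zeros((c, 1, 1), dtype=F32)
                self.grads[f"{area}_{j}"] = np.zeros((c, 1, 1), dtype=F32)


class SegmentationNetwork:
    """The full dual-pathway model (parameters + forward/backward passes)."""

    def __init__(self, config: Optional[NetConfig] = None, seed: int = 0):
        self.cfg = cfg = config or NetConfig()
        rng = np.random.default_rng(seed)
        c1, c2, c4 = cfg.v1_channels, cfg.v2_channels, cfg.v4_channels
        nb = cfg.blocks_per_area
        k = cfg.kernel

        # --- feedforward pathway
        self.blocks = {
            "v1": [nn.ResBlock(rng, 1 if j == 0 else c1, c1, k) for j in range(nb)],
            "v2": [nn.ResBlock(rng, c2, c2, k) for _ in range(nb)],
            "v4": [nn.ResBlock(rng, c4, c4, k) for _ in range(nb)],
        }
        self.down = {
            "v1": nn.DownBlock(rng, c1, c2),   # V1m -> V2m
            "v2": nn.DownBlock(rng, c2, c4),   # V2m -> V4m
            "v4": nn.DownBlock(rng, c4, c4),   # V4m -> 7x7 tensor entering ITm
        }
        s7 = cfg.image_size // 8
        self.it = nn.Linear(rng, c4 * s7 * s7, cfg.it_units)
        self.it_relu = nn.ReLU()
        self.fc = nn.Linear(rng, cfg.it_units, cfg.n_classes)

        # --- feedback pathway: driving head (mirrors FCm/ITm) ...
        self.fb_fc1 = nn.Linear(rng, cfg.n_classes, cfg.it_units)
        self.fb_fc2 = nn.Linear(rng, cfg.it_units, c4)
        self.fb_expand = nn.Broadcast2d(rng, c4, c4, s7)
        self.fb_fuse = nn.Conv2d(rng, 2 * c4, c4, 1)
        self.fb_relu = [nn.ReLU() for _ in range(4)]
        # ... inter-area coarse-to-fine projections and intra-area 1x1 mixing
        self.up = {
            "v4": nn.ConvTranspose2d(rng, c4, c4),
            "v2": nn.ConvTranspose2d(rng, c4, c2),
            "v1": nn.ConvTranspose2d(rng, c2, c1),
        }
        self.lat = {
            area: [nn.Conv2d(rng, cfg.channels(area), cfg.channels(area), 1)
                   for _ in range(nb - 1)]
            for area in AREAS
        }
        self.betas = _BetaBank(cfg)
        # the read-out starts as the positive channel mean: feedback-unit
        # activity b itself then carries the segmentation in the positive
        # sense (high b = attended pixels), as the region-trace analyses
        # assume
        self.readout = nn.Conv2d(rng, c1, 1, 1)
        self.readout.params["W"][...] = 1.0 / c1

        self._named = {}
        for area in AREAS:
            for j, blk in enumerate(self.blocks[area]):
                self._named[f"ff/{area}b{j}"] = blk
            self._named[f"ff/down_{area}"] = self.down[area]
        self._named["ff/it"] = self.it
        self._named["ff/fc"] = self.fc
        self._named["fb/fc1"] = self.fb_fc1
        self._named["fb/fc2"] = self.fb_fc2
        self._named["fb/expand"] = self.fb_expand
        self._named["fb/fuse"] = self.fb_fuse
        for area in AREAS:
            self._named[f"fb/up_{area}"] = self.up[area]
            for j, lay in enumerate(self.lat[area]):
                self._named[f"fb/lat_{area}{j}"] = lay
        self._named["fb/readout"] = self.readout
        self._named["beta"] = self.betas
        self.params, self.grads = nn.collect_params(self._named)

    # ------------------------------------------------------------------ util

    def param_group(self, prefix: str) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.params.items() if k.startswith(prefix)}

    def group_checksum(self, prefix: str) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            if k.startswith(prefix):
                h.update(k.encode())
                h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def zero_grad(self):
        for g in self.grads.values():
            g[...] = 0.0

    def _batchnorms(self):
        for prefix, layer in self._named.items():
            for suffix, leaf in nn.iter_layers(layer):
                if isinstance(leaf, nn.BatchNorm2d):
                    yield (prefix if not suffix else f"{prefix}/{suffix}"), leaf

    # ----------------------------------------------------------- feedforward

    def _as_batch(self, image):
        x = np.asarray(image, dtype=F32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        s = self.cfg.image_size
        if x.shape[-2:] != (s, s):
            raise ValueError(f"expected {s}x{s} input, got {x.shape[-2:]}")
        if x.min() < 0 or x.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        return x

    def feedforward_pass(self, image, train: bool = False):
        """Run the driving pathway; returns ``(state, scores)``.

        The state caches every per-layer activity ``a`` plus the 7x7 tensor
        entering ITm (``state.a[("ds4", 0)]``); the feedback pass consumes
        these caches.  The result is independent of any attention setting.
        """
        x = self._as_batch(image)
        st = NetworkState()
        for area in AREAS:
            for j, blk in enumerate(self.blocks[area]):
                x = blk.forward(x, train)
                st.a[(area, j)] = x
            x = self.down[area].forward(x, train)
        st.a[("ds4", 0)] = x
        h = self.it_relu.forward(self.it.forward(x.reshape(x.shape[0], -1), train))
        st.a[("it", 0)] = h
        logits = self.fc.forward(h, train)
        st.scores = nn.sigmoid(logits)
        self._ff_logits = logits
        return st, st.scores

    def backward_ff(self, dlogits):
        dx = self.fc.backward(dlogits)
        dx = self.it.backward(self.it_relu.backward(dx))
        x = self.down["v4"]._mask  # shape reference only
        dx = dx.reshape(x.shape)
        for area in reversed(AREAS):
            dx = self.down[area].backward(dx)
            for blk in reversed(self.blocks[area]):
                dx = blk.backward(dx)
        return dx

    # -------------------------------------------------------------- feedback

    def feedback_head(self, gated, a_ds4, train: bool = False):
        """Driving FCm -> ITm-level feedback segment.

        Expands the gated class vector to a coarse 7x7 map, concatenates it
        with the feedforward tensor entering ITm (200 channels) and fuses
        back to the V4m-output channel count with a 1x1 convolution.
        """
        if gated.ndim != 2 or gated.shape[1] != self.cfg.n_classes:
            raise ValueError("gated vector must be (batch, n_classes)")
        if a_ds4.shape[0] != gated.shape[0]:
            raise ValueError("batch mismatch between gated vector and cache")
        g = self.fb_relu[0].forward(self.fb_fc1.forward(gated, train))
        g = self.fb_relu[1].forward(self.fb_fc2.forward(g, train))
        d = self.fb_relu[2].forward(self.fb_expand.forward(g, train))
        cat = np.concatenate([d, a_ds4], axis=1)
        return self.fb_relu[3].forward(self.fb_fuse.forward(cat, train))

    def _backward_head(self, dfused):
        dcat = self.fb_fuse.backward(self.fb_relu[3].backward(dfused))
        dd = dcat[:, : self.cfg.channels("v4")]  # ds4 branch is frozen ff cache
        dg = self.fb_expand.backward(self.fb_relu[2].backward(dd))
        dg = self.fb_fc2.backward(self.fb_relu[1].backward(dg))
        self.fb_fc1.backward(self.fb_relu[0].backward(dg))

    def feedback_area(self, area: str, c_above, state: NetworkState,
                      train: bool = False):
        """Run the mirrored feedback units of one area, top layer first.

        ``c_above`` is the signal from the next-higher area (or the fused
        head output for V4m); it is spatially up-projected to this area's
        resolution to give ``z`` for the top mirror, then 1x1 mixing layers
        carry ``c`` from mirror to mirror within the area.  Returns the
        ``c`` of the lowest mirror, which is handed to the area below.
        """
        nb = self.cfg.blocks_per_area
        top = nb - 1
        if (area, top) not in state.a:
            raise ValueError(f"missing cached feedforward activity for {area}")
        z = self.up[area].forward(c_above, train)
        for j in range(top, -1, -1):
            a = state.a[(area, j)]
            beta = self.betas.params[f"{area}_{j}"]
            b = modulate(a, z, beta)
            c = feedback_signal(b, a)
            state.z[(area, j)] = z
            state.b[(area, j)] = b
            state.c[(area, j)] = c
            if j > 0:
                z = self.lat[area][j - 1].forward(c, train)
        return state.c[(area, 0)]

    def _backward_area(self, area: str, dc_out, db0_extra, state: NetworkState):
        # Walks the area's mirrors bottom-up; gradients w.r.t. b equal those
        # w.r.t. c because a is a frozen cache during phase-2 training.
        nb = self.cfg.blocks_per_area
        dc = dc_out
        for j in range(nb):
            a = state.a[(area, j)]
            beta = self.betas.params[f"{area}_{j}"]
            db = dc
            if j == 0 and db0_extra is not None:
                db = db0_extra if db is None else db + db0_extra
            gate = (a * (state.z[(area, j)] + beta)) > 0
            dz = db * gate * a
            if self.cfg.beta_granularity == "channel":
                self.betas.grads[f"{area}_{j}"] += dz.sum(axis=(0, 2, 3)).reshape(-1, 1, 1)
            else:
                self.betas.grads[f"{area}_{j}"] += dz.sum()
            if j < nb - 1:
                dc = self.lat[area][j].backward(dz)
            else:
                return self.up[area].backward(dz)

    def feedback_pass(self, state: NetworkState, attend, train: bool = False):
        """Run the whole feedback pathway for an attended class.

        ``state`` must come from :meth:`feedforward_pass` on the same batch.
        Returns ``(state, seg_map)`` with the segmentation map in [0, 1],
        read out from the lowest V1m mirror through a learned 1x1
        convolution and a sigmoid.
        """
        attend = np.atleast_2d(np.asarray(attend, dtype=F32))
        if attend.shape[0] == 1 and state.scores.shape[0] > 1:
            attend = np.repeat(attend, state.scores.shape[0], axis=0)
        gated = attention_gate(state.scores, attend)
        fused = self.feedback_head(gated, state.a[("ds4", 0)], train)
        c = fused
        for area in ("v4", "v2", "v1"):
            c = self.feedback_area(area, c, state, train)
        src = state.b if self.cfg.readout_source == "b" else state.c
        logit_map = self.readout.forward(src[("v1", 0)], train)
        self._fb_logit_map = logit_map
        state.seg_map = nn.sigmoid(logit_map)[:, 0]
        return state, state.seg_map

    def backward_fb(self, dlogit_map, state: NetworkState):
        """Backprop the feedback pathway only (phase 2: ``a`` is constant)."""
        db0 = self.readout.backward(dlogit_map)
        dc = self._backward_area("v1", None, db0, state)
        dc = self._backward_area("v2", dc, None, state)
        dc = self._backward_area("v4", dc, None, state)
        self._backward_head(dc)

    # ----------------------------------------------------------- checkpoints

    def fingerprint(self) -> dict:
        return {"config": asdict(self.cfg),
                "shapes": {k: list(v.shape) for k, v in sorted(self.params.items())}}

    def _leaves(self):
        for prefix, layer in self._named.items():
            for suffix, leaf in nn.iter_layers(layer):
                yield (prefix if not suffix else f"{prefix}/{suffix}"), leaf

    def save(self, path):
        arrays = dict(self.params)
        for name, bn in self._batchnorms():
            arrays[f"{name}/running_mean"] = bn.running_mean
            arrays[f"{name}/running_var"] = bn.running_var
        for name, leaf in self._leaves():
            if getattr(leaf, "in_scale", 1.0) != 1.0:
                arrays[f"{name}/in_scale"] = np.float64(leaf.in_scale)
        fp = json.dumps(self.fingerprint(), sort_keys=True)
        np.savez(path, __fingerprint__=np.frombuffer(fp.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SegmentationNetwork":
        with np.load(path) as data:
            fp = json.loads(bytes(data["__fingerprint__"]).decode())
            net = cls(NetConfig(**fp["config"]))
            if net.fingerprint() != fp:
                raise ValueError("checkpoint fingerprint does not match "
                                 "the reconstructed architecture")
            for k, v in net.params.items():
                v[...] = data[k]
            for name, bn in net._batchnorms():
                bn.running_mean[...] = data[f"{name}/running_mean"]
                bn.running_var[...] = data[f"{name}/running_var"]
            for name, leaf in net._leaves():
                key = f"{name}/in_scale"
                if key in data:
                    leaf.in_scale = float(data[key])
        return net
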