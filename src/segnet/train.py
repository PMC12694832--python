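"""Two-phase optimization and evaluation metrics.

Phase 1 trains the feedforward pathway for multi-label object detection
(per-class sigmoid + binary cross-entropy).  Phase 2 freezes every
feedforward parameter and trains the feedback pathway for
attention-conditioned segmentation: the target map is 1 on the attended
class's pixels and 0 elsewhere, and pure-texture background pixels are
excluded from the loss by default (the class imbalance would otherwise
swamp the objects).  Non-attended object pixels stay in the loss as
0-targets, which is what teaches the network to suppress them.

The three evaluation measures mirror the model's reported scores: a
per-image classification absolute error in [0, 12], a pixel-wise absolute
error over attended-object pixels in [0, 1], and the fraction of true
background pixels mislabeled as the attended class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import stimgen
from .nn import F32, Adam, sigmoid
from .netcore import NetworkState, SegmentationNetwork, one_hot

N_CLASSES = stimgen.N_CLASSES


@dataclass
class TrainConfig:
    """Optimizer settings for one phase.

    The reference values are Adam, learning rate 0.001, weight decay 0.0005
    and 2,500 epochs (batch 1024 for the feedforward phase, 256 for the
    feedback phase); scaled-down runs override epochs/batch and log it.
    """

    phase: str  # "ff" | "fb"
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    epochs: int = 2500
    batch_size: int = 0  # 0 -> phase default
    seed: int = 0
    ignore_policy: str = "background"  # or "all_nonattended"
    calibrate_init: bool = True  # phase 2: rescale fresh feedback weights

    def __post_init__(self):
        if self.phase not in ("ff", "fb"):
            raise ValueError("phase must be 'ff' or 'fb'")
        if self.batch_size == 0:
            self.batch_size = 1024 if self.phase == "ff" else 256


@dataclass
class SegTarget:
    """Per-pixel target for the attended class plus loss-exclusion mask."""

    target: np.ndarray  # (56, 56) in {0, 1}
    ignore: np.ndarray  # (56, 56) bool; True -> excluded from the loss


def make_seg_target(stimulus: stimgen.Stimulus, attended_class: int,
                    policy: str = "background") -> SegTarget:
    """Build the phase-2 target for one stimulus and attended class.

    ``policy='background'`` ignores only pure-texture pixels (non-attended
    objects count as negatives); ``policy='all_nonattended'`` ignores
    everything outside the attended object.
    """
    if not stimulus.labels[attended_class]:
        raise ValueError("attended class is absent from the stimulus")
    target = stimulus.masks[attended_class].astype(F32)
    any_object = stimulus.masks.any(axis=0)
    if policy == "background":
        ignore = ~any_object
    elif policy == "all_nonattended":
        ignore = ~stimulus.masks[attended_class]
    else:
        raise ValueError(f"unknown ignore policy {policy!r}")
    return SegTarget(target=target, ignore=ignore)


# ---------------------------------------------------------------------------
# losses


def _bce_with_logits(logits, targets):
    # numerically stable: max(x,0) - x*t + log1p(exp(-|x|))
    x = np.asarray(logits, dtype=F32)
    t = np.asarray(targets, dtype=F32)
    return np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))


def ff_loss(logits, labels) -> float:
    """Mean binary cross-entropy of the 12 class logits."""
    logits = np.atleast_2d(np.asarray(logits, dtype=F32))
    labels = np.atleast_2d(np.asarray(labels))
    if logits.shape != labels.shape:
        raise ValueError("logits and labels shapes differ")
    if not np.isfinite(logits).all():
        raise ValueError("non-finite logits")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be 0/1 multi-hot")
    return float(_bce_with_logits(logits, labels).mean())


def seg_loss(map_logits, target: SegTarget) -> float:
    """Pixelwise BCE averaged over pixels not covered by the ignore mask."""
    x = np.asarray(map_logits, dtype=F32)
    if x.shape != target.target.shape:
        raise ValueError("logit map and target shapes differ")
    counted = ~target.ignore
    if not counted.any():
        raise ValueError("all pixels ignored: segmentation loss undefined")
    return float(_bce_with_logits(x[counted], target.target[counted]).mean())


# ---------------------------------------------------------------------------
# metrics


def classification_abs_error(scores, labels) -> float:
    """Sum of |score - label| over the 12 classes, averaged over images."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if scores.shape[-1] != N_CLASSES or labels.shape != scores.shape:
        raise ValueError(f"expected length-{N_CLASSES} score/label vectors")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    return float(np.abs(scores - labels).sum(axis=1).mean())


def pixel_abs_error(seg_map, attended_mask) -> float:
    """Mean |map - 1| over attended-object pixels (background not counted)."""
    seg_map = np.asarray(seg_map, dtype=np.float64)
    mask = np.asarray(attended_mask, dtype=bool)
    if seg_map.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    if not mask.any():
        raise ValueError("attended object mask is empty")
    if seg_map.min() < 0 or seg_map.max() > 1:
        raise ValueError("segmentation map must lie in [0, 1]")
    return float(np.abs(seg_map[mask] - 1.0).mean())


def background_false_rate(seg_map, all_masks, threshold: float = 0.5) -> float:
    """Fraction of true-background pixels labeled above ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    seg_map = np.asarray(seg_map, dtype=np.float64)
    background = ~np.asarray(all_masks, dtype=bool).any(axis=0)
    if seg_map.shape != background.shape:
        raise ValueError("map and mask shapes differ")
    return float((seg_map[background] > threshold).mean())


def iou(seg_map, mask, threshold: float = 0.5) -> float:
    pred = np.asarray(seg_map) > threshold
    mask = np.asarray(mask, dtype=bool)
    union = (pred | mask).sum()
    return float((pred & mask).sum() / union) if union else 1.0


def detection_accuracy(scores, labels, classes: Optional[Sequence[int]] = None) -> float:
    """Mean thresholded-score agreement with the multi-hot labels."""
    scores = np.atleast_2d(scores)
    labels = np.atleast_2d(labels)
    sel = list(classes) if classes is not None else list(range(scores.shape[1]))
    return float(((scores[:, sel] > 0.5) == (labels[:, sel] > 0.5)).mean())


# ---------------------------------------------------------------------------
# training loops


def _check_finite(loss, epoch):
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged: loss={loss} at epoch {epoch}")


def train_feedforward(stimuli: Sequence[stimgen.Stimulus], config: TrainConfig,
                      net: Optional[SegmentationNetwork] = None,
                      val_stimuli: Sequence[stimgen.Stimulus] = (),
                      verbose: bool = False):
    """Phase 1: train the feedforward pathway for multi-label detection.

    Returns ``(net, log)``; only ``ff/*`` parameter groups are updated.
    """
    assert config.phase == "ff"
    net = net or SegmentationNetwork(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    images = stimgen.images_array(stimuli)
    labels = stimgen.labels_array(stimuli)
    ff_params = net.param_group("ff")
    opt = Adam(ff_params, lr=config.learning_rate, weight_decay=config.weight_decay)
    log = {"config": vars(config).copy(), "epoch_loss": [], "val": []}
    n = len(stimuli)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            _, _ = net.feedforward_pass(images[idx], train=True)
            logits = net._ff_logits
            p = sigmoid(logits)
            loss = float(_bce_with_logits(logits, labels[idx]).mean())
            total += loss * len(idx)
            net.zero_grad()
            net.backward_ff((p - labels[idx]) / logits.size)
            opt.step({k: net.grads[k] for k in ff_params})
        epoch_loss = total / n
        _check_finite(epoch_loss, epoch)
        log["epoch_loss"].append(epoch_loss)
        if len(val_stimuli) and (epoch % 4 == 3 or epoch == config.epochs - 1):
            m = evaluate_classification(net, val_stimuli)
            m["epoch"] = epoch
            log["val"].append(m)
            if verbose:
                print(f"[ff] epoch {epoch}: loss {epoch_loss:.4f} "
                      f"val_acc {m['detection_accuracy']:.3f}")
        elif verbose:
            print(f"[ff] epoch {epoch}: loss {epoch_loss:.4f}")
    return net, log


def calibrate_feedback_init(net: SegmentationNetwork, stimuli, seed: int = 0,
                            n_calib: int = 64, target_std: float = 1.0,
                            rounds: int = 3, logit_std: float = 0.3):
    """Layer-sequential scale calibration of the freshly initialized
    feedback pathway.

    The modulatory cascade multiplies activities by the (unnormalized)
    feedforward activity ``a`` at every mirrored layer, so with
    fan-in-scaled random weights the feedback drive grows by orders of
    magnitude per area and the read-out starts deep in sigmoid
    saturation.  This routine runs a calibration batch through the trained
    feedforward pathway and rescales each feedback layer's weights so the
    drive ``z`` it produces has unit standard deviation (and the read-out
    logits a small one).  All operations between the scaled layers are
    positively homogeneous, so the correction is exact up to the iteration.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(stimuli), size=min(n_calib, len(stimuli)),
                     replace=False)
    images = stimgen.images_array([stimuli[i] for i in idx])
    attend = np.stack([one_hot(rng.choice(stimuli[i].present_classes()))
                       for i in idx])
    state, _ = net.feedforward_pass(images, train=False)

    def adjust(layer, out_std):
        # raise the fixed input divisor so the output std hits its target
        layer.in_scale = float(getattr(layer, "in_scale", 1.0)) \
            * max(out_std, 1e-4) / target_std

    for _ in range(rounds):
        gated = np.asarray(state.scores * attend, dtype=F32)
        g1 = np.maximum(net.fb_fc1.forward(gated), 0)
        adjust(net.fb_fc1, g1.std())
        g1 = np.maximum(net.fb_fc1.forward(gated), 0)
        g2 = np.maximum(net.fb_fc2.forward(g1), 0)
        adjust(net.fb_fc2, g2.std())
        g2 = np.maximum(net.fb_fc2.forward(g1), 0)
        d = np.maximum(net.fb_expand.forward(g2), 0)
        adjust(net.fb_expand, d.std())
        d = np.maximum(net.fb_expand.forward(g2), 0)
        cat = np.concatenate([d, state.a[("ds4", 0)]], axis=1)
        fused = np.maximum(net.fb_fuse.forward(cat), 0)
        adjust(net.fb_fuse, fused.std())
        # whole-pathway pass to measure the drive each mirror receives
        net.feedback_pass(state, attend, train=False)
        for area in ("v4", "v2", "v1"):
            top = net.cfg.blocks_per_area - 1
            adjust(net.up[area], state.z[(area, top)].std())
            for j in range(top):
                adjust(net.lat[area][j], state.z[(area, j)].std())
    net.feedback_pass(state, attend, train=False)
    net.readout.in_scale = float(getattr(net.readout, "in_scale", 1.0)) * max(
        net._fb_logit_map.std(), 1e-4) / logit_std
    return net


def _precompute_ff_cache(net: SegmentationNetwork, images, batch_size=128):
    """Evaluate the frozen feedforward pathway once for a whole dataset.

    Returns ``(a_store, scores)`` with one array per cached layer; falls
    back to None when the cache would be unreasonably large.
    """
    per_image = sum(
        np.prod([net.cfg.channels(a), net.cfg.spatial(a), net.cfg.spatial(a)])
        * net.cfg.blocks_per_area for a in ("v1", "v2", "v4"))
    if per_image * len(images) * 4 > 2.5e9:
        return None, None
    a_store, scores = {}, []
    for lo in range(0, len(images), batch_size):
        st, sc = net.feedforward_pass(images[lo:lo + batch_size], train=False)
        for k, v in st.a.items():
            a_store.setdefault(k, []).append(v)
        scores.append(sc)
    return ({k: np.concatenate(v) for k, v in a_store.items()},
            np.concatenate(scores))


def train_feedback(stimuli: Sequence[stimgen.Stimulus],
                   net: SegmentationNetwork, config: TrainConfig,
                   val_stimuli: Sequence[stimgen.Stimulus] = (),
                   verbose: bool = False):
    """Phase 2: train the feedback pathway with the feedforward one frozen.

    Each example is paired with an attended class sampled uniformly from the
    classes present in it (resampled every epoch).  Because the feedforward
    pathway is frozen, its activations are precomputed once for the whole
    dataset (when they fit in memory) rather than re-evaluated every step.
    A checksum guards the freeze contract: ``ff/*`` groups are bit-identical
    before and after.
    """
    assert config.phase == "fb"
    rng = np.random.default_rng(config.seed)
    images = stimgen.images_array(stimuli)
    ff_checksum = net.group_checksum("ff")
    if config.calibrate_init:
        calibrate_feedback_init(net, stimuli, seed=config.seed)
    fb_params = {**net.param_group("fb"), **net.param_group("beta")}
    opt = Adam(fb_params, lr=config.learning_rate, weight_decay=config.weight_decay)
    log = {"config": vars(config).copy(), "epoch_loss": [], "val": []}
    n = len(stimuli)
    a_store, score_store = _precompute_ff_cache(net, images)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        attended = np.array([rng.choice(stimuli[i].present_classes()) for i in perm])
        total, total_px = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx, att = perm[lo:lo + config.batch_size], attended[lo:lo + config.batch_size]
            if a_store is not None:
                state = NetworkState(a={k: v[idx] for k, v in a_store.items()},
                                     scores=score_store[idx])
            else:
                state, _ = net.feedforward_pass(images[idx], train=False)
            attend = np.stack([one_hot(a) for a in att])
            net.feedback_pass(state, attend, train=True)
            logit_map = net._fb_logit_map  # (B, 1, 56, 56)
            targets = np.stack([
                make_seg_target(stimuli[i], a, config.ignore_policy).target
                for i, a in zip(idx, att)])
            counted = np.stack([
                ~make_seg_target(stimuli[i], a, config.ignore_policy).ignore
                for i, a in zip(idx, att)])
            n_px = int(counted.sum())
            bce = _bce_with_logits(logit_map[:, 0], targets) * counted
            total += float(bce.sum())
            total_px += n_px
            dlogit = ((sigmoid(logit_map[:, 0]) - targets) * counted / n_px)[:, None]
            net.zero_grad()
            net.backward_fb(dlogit.astype(F32), state)
            opt.step({k: net.grads[k] for k in fb_params})
        epoch_loss = total / total_px
        _check_finite(epoch_loss, epoch)
        log["epoch_loss"].append(epoch_loss)
        if len(val_stimuli) and (epoch % 4 == 3 or epoch == config.epochs - 1):
            m = evaluate_segmentation(net, val_stimuli, seed=config.seed)
            m["epoch"] = epoch
            log["val"].append(m)
            if verbose:
                print(f"[fb] epoch {epoch}: loss {epoch_loss:.4f} "
                      f"val_iou {m['mean_iou']:.3f}")
        elif verbose:
            print(f"[fb] epoch {epoch}: loss {epoch_loss:.4f}")
    if net.group_checksum("ff") != ff_checksum:
        raise RuntimeError("feedforward parameters changed during phase 2")
    return net, log


# ---------------------------------------------------------------------------
# evaluation


def evaluate_classification(net: SegmentationNetwork,
                            stimuli: Sequence[stimgen.Stimulus],
                            batch_size: int = 256) -> dict:
    images = stimgen.images_array(stimuli)
    labels = stimgen.labels_array(stimuli)
    scores = np.concatenate([
        net.feedforward_pass(images[lo:lo + batch_size], train=False)[1]
        for lo in range(0, len(stimuli), batch_size)])
    present = np.flatnonzero(labels.any(axis=0))
    return {
        "detection_accuracy": detection_accuracy(scores, labels, classes=present),
        "classification_abs_error": classification_abs_error(scores, labels),
    }


def evaluate_segmentation(net: SegmentationNetwork,
                          stimuli: Sequence[stimgen.Stimulus],
                          seed: int = 0, batch_size: int = 128,
                          per_present_class: bool = True) -> dict:
    """Attend each present class of each stimulus and score the maps."""
    pairs = []
    rng = np.random.default_rng(seed)
    for i, s in enumerate(stimuli):
        present = s.present_classes()
        if per_present_class:
            pairs.extend((i, k) for k in present)
        else:
            pairs.append((i, int(rng.choice(present))))
    images = stimgen.images_array(stimuli)
    ious, pix_errs, bg_hits, bg_total = [], [], 0, 0
    for lo in range(0, len(pairs), batch_size):
        chunk = pairs[lo:lo + batch_size]
        batch = np.stack([images[i] for i, _ in chunk])
        attend = np.stack([one_hot(k) for _, k in chunk])
        state, _ = net.feedforward_pass(batch, train=False)
        _, seg = net.feedback_pass(state, attend, train=False)
        for (i, k), m in zip(chunk, seg):
            ious.append(iou(m, stimuli[i].masks[k]))
            pix_errs.append(pixel_abs_error(m, stimuli[i].masks[k]))
            background = ~stimuli[i].masks.any(axis=0)
            bg_hits += int((m[background] > 0.5).sum())
            bg_total += int(background.sum())
    return {
        "mean_iou": float(np.mean(ious)),
        "pixel_abs_error": float(np.mean(pix_errs)),
        "background_false_rate": bg_hits / bg_total,
        "n_pairs": len(pairs),
    }
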