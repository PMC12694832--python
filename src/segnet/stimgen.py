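"""SegMNIST-style stimulus generation.

Scenes are 56x56 grayscale images: an oriented background texture of short
line elements, with one to three foreground objects drawn from 12 classes —
a texture-defined square (class 0), a texture-defined rectangle (class 1)
and the digits 0-9 (classes 2-11).  Texture figures are camouflaged: they
differ from the background only in the orientation of their texture
elements, not in mean luminance.  Digits are glyph strokes pasted over the
texture.

Each stimulus carries a multi-hot label vector, one binary mask per class,
and the scene specs that produced it.  For the V1m time-course analyses,
:func:`region_map` partitions the canvas into figure / edge / ground /
excluded regions around one object's mask.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import line_aa

from .glyphs import GLYPH_SIZE, GlyphBank, synth_glyph

CANVAS = 56
N_CLASSES = 12
CLASS_NAMES = ["square", "rectangle"] + [f"digit_{d}" for d in range(10)]

# region codes
GROUND, FIGURE, EDGE, EXCLUDED = 0, 1, 2, 3


class PlacementError(RuntimeError):
    """Raised when scene objects cannot be placed without overlap."""


@dataclass(frozen=True)
class TextureSpec:
    """Oriented texture of short line elements on a jittered grid.

    ``orientation`` is in degrees and wraps mod 180; ``element_density`` is
    elements per 100 px^2; ``jitter`` is the pixel s.d. of element placement
    around the grid; ``contrast`` scales element intensity (0 gives a blank
    field).
    """

    orientation: float
    element_density: float = 8.0
    element_length: float = 5.0
    element_width: float = 1.0
    jitter: float = 1.5
    contrast: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "orientation", float(self.orientation) % 180.0)
        if self.element_density < 0:
            raise ValueError("element_density must be non-negative")
        if self.element_length <= 0 or self.element_width <= 0:
            raise ValueError("element length and width must be positive")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")


@dataclass(frozen=True)
class FigureSpec:
    """A texture-defined square or rectangle."""

    shape: str  # "square" | "rectangle"
    center: tuple  # (row, col)
    side_lengths: tuple  # (h, w) px
    rotation: float  # degrees
    texture: TextureSpec

    def __post_init__(self):
        if self.shape not in ("square", "rectangle"):
            raise ValueError(f"unknown shape {self.shape!r}")
        h, w = self.side_lengths
        if self.shape == "square" and h != w:
            raise ValueError("square must have equal side lengths")
        if h <= 0 or w <= 0:
            raise ValueError("side lengths must be positive")

    @property
    def class_index(self) -> int:
        return 0 if self.shape == "square" else 1

    def corners(self) -> np.ndarray:
        """4x2 array of (row, col) corner coordinates."""
        h, w = self.side_lengths
        phi = np.radians(self.rotation)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        local = np.array([[-h / 2, -w / 2], [-h / 2, w / 2],
                          [h / 2, w / 2], [h / 2, -w / 2]])
        return local @ rot.T + np.asarray(self.center)


@dataclass(frozen=True)
class GlyphSpec:
    """A digit glyph pasted onto the texture."""

    digit_class: int  # 0..9
    center: tuple  # (row, col)
    scale: float = 1.0
    source: str = "procedural"  # or "mnist"
    seed: int = 0  # selects the glyph exemplar

    def __post_init__(self):
        if not 0 <= self.digit_class <= 9:
            raise ValueError("digit class must be in 0..9")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def class_index(self) -> int:
        return 2 + self.digit_class


SceneSpec = Union[FigureSpec, GlyphSpec]


@dataclass
class Stimulus:
    """One generated scene with labels, per-class masks and provenance."""

    image: np.ndarray  # (56, 56) float32 in [0, 1]
    labels: np.ndarray  # (12,) int8 multi-hot
    masks: np.ndarray  # (12, 56, 56) bool
    scene: list = field(default_factory=list)
    background: Optional[TextureSpec] = None

    def present_classes(self) -> np.ndarray:
        return np.flatnonzero(self.labels)


@dataclass
class RegionMap:
    """Per-pixel figure / edge / ground / excluded assignment for one object."""

    assignment: np.ndarray  # (56, 56) uint8 of region codes
    edge_width: int

    def pixels(self, code: int) -> np.ndarray:
        return self.assignment == code


# ---------------------------------------------------------------------------
# textures and figures


def _bar_stamp(spec: TextureSpec) -> np.ndarray:
    """One anti-aliased oriented bar on a small patch (odd side)."""
    half = int(np.ceil(spec.element_length / 2)) + 2
    side = 2 * half + 1
    patch = np.zeros((side, side), dtype=np.float32)
    theta = np.radians(spec.orientation)
    dr = -np.sin(theta) * spec.element_length / 2
    dc = np.cos(theta) * spec.element_length / 2
    rr, cc, val = line_aa(int(round(half - dr)), int(round(half - dc)),
                          int(round(half + dr)), int(round(half + dc)))
    patch[rr, cc] = val
    if spec.element_width > 1:
        patch = ndimage.grey_dilation(patch, size=(int(round(spec.element_width)),) * 2)
    return patch * spec.contrast


def make_background_texture(size, spec: TextureSpec, seed: int) -> np.ndarray:
    """Synthesize an oriented line-element texture.

    Elements sit on a jittered grid whose pitch matches ``element_density``;
    each is an anti-aliased bar of length ``element_length`` at the spec
    orientation, max-composed onto the canvas.  Drawing happens on a padded
    canvas that is cropped, so density is uniform up to the borders.
    Deterministic for a fixed seed.
    """
    rows, cols = size
    if rows <= 0 or cols <= 0:
        raise ValueError("size must be positive")
    if spec.contrast == 0.0:
        return np.zeros((rows, cols), dtype=np.float32)
    n = int(round(spec.element_density * rows * cols / 100.0))
    if n == 0:
        raise ValueError("degenerate texture: zero element density")
    rng = np.random.default_rng(seed)
    stamp = _bar_stamp(spec)
    side = stamp.shape[0]
    pad = side  # ample margin: elements centered off-canvas still contribute
    big = np.zeros((rows + 2 * pad, cols + 2 * pad), dtype=np.float32)

    pitch = np.sqrt(rows * cols / n)
    gr = np.arange(pitch / 2, rows, pitch)
    gc = np.arange(pitch / 2, cols, pitch)
    centers = np.stack(np.meshgrid(gr, gc, indexing="ij"), axis=-1).reshape(-1, 2)
    centers = centers + rng.normal(0.0, spec.jitter, size=centers.shape)

    h = side // 2
    for r, c in np.round(centers).astype(int):
        r0 = min(max(r - h + pad, 0), big.shape[0] - side)
        c0 = min(max(c - h + pad, 0), big.shape[1] - side)
        win = big[r0:r0 + side, c0:c0 + side]
        np.maximum(win, stamp, out=win)
    return np.clip(big[pad:pad + rows, pad:pad + cols], 0.0, 1.0)


def figure_mask(fig: FigureSpec, shape) -> np.ndarray:
    """Rasterize a rotated rectangle with half-open pixel-box semantics.

    A pixel (r, c) belongs to the figure iff its coordinates, rotated into
    the figure frame, fall in [-h/2, h/2) x [-w/2, w/2); an axis-aligned
    10x10 square therefore covers exactly 100 pixels.
    """
    h, w = fig.side_lengths
    phi = np.radians(fig.rotation)
    rr, cc = np.indices(shape)
    dr = rr - fig.center[0]
    dc = cc - fig.center[1]
    u = np.cos(phi) * dr + np.sin(phi) * dc
    v = -np.sin(phi) * dr + np.cos(phi) * dc
    return (u >= -h / 2) & (u < h / 2) & (v >= -w / 2) & (v < w / 2)


def render_texture_figure(canvas: np.ndarray, fig: FigureSpec, seed: int):
    """Paint a rotated texture-defined figure onto a copy of the canvas.

    Pixels whose centers fall inside the rotated shape (half-open box in
    the figure frame) are replaced with a texture drawn from
    ``fig.texture``; returns ``(new_canvas, mask)``.
    """
    h, w = canvas.shape
    corners = fig.corners()
    if corners.min() < 0 or corners[:, 0].max() > h or corners[:, 1].max() > w:
        raise PlacementError("figure crosses the canvas boundary")
    mask = figure_mask(fig, canvas.shape)
    tex = make_background_texture(canvas.shape, fig.texture, seed)
    out = canvas.copy()
    out[mask] = tex[mask]
    return out, mask


def render_glyph(canvas: np.ndarray, glyph: GlyphSpec, threshold: float = 0.3,
                 bank: Optional[GlyphBank] = None):
    """Paste a scaled digit glyph; strokes overwrite the texture.

    Stroke pixels are those of the rescaled bitmap above ``threshold``; they
    define the ground-truth mask.  Raises if the glyph would be clipped.
    """
    bitmap = (bank or GlyphBank()).get(glyph.digit_class, glyph.seed)
    if glyph.scale != 1.0:
        # nearest-neighbour resampling keeps stroke statistics: the stroke
        # pixel count scales with the squared zoom factor
        bitmap = np.clip(ndimage.zoom(bitmap, glyph.scale, order=0), 0.0, 1.0)
    gh, gw = bitmap.shape
    r0 = int(round(glyph.center[0] - (gh - 1) / 2))
    c0 = int(round(glyph.center[1] - (gw - 1) / 2))
    if r0 < 0 or c0 < 0 or r0 + gh > canvas.shape[0] or c0 + gw > canvas.shape[1]:
        raise PlacementError("glyph clipped by the canvas boundary")
    stroke = bitmap > threshold
    out = canvas.copy()
    mask = np.zeros(canvas.shape, dtype=bool)
    region = out[r0:r0 + gh, c0:c0 + gw]
    region[stroke] = bitmap[stroke]
    mask[r0:r0 + gh, c0:c0 + gw] = stroke
    return out, mask


# ---------------------------------------------------------------------------
# scenes and datasets


def compose_scene(scene: Sequence[SceneSpec], background: TextureSpec, seed: int,
                  size: int = CANVAS, bank: Optional[GlyphBank] = None) -> Stimulus:
    """Render a full stimulus from concrete object specs.

    Objects may not overlap (masks dilated by one pixel must stay disjoint);
    a violation raises :class:`PlacementError`.  Labels are derived from the
    masks, so label-mask consistency holds by construction.
    """
    if not 1 <= len(scene) <= 3:
        raise ValueError("scenes contain one to three objects")
    canvas = make_background_texture((size, size), background, seed)
    masks = np.zeros((N_CLASSES, size, size), dtype=bool)
    occupied = np.zeros((size, size), dtype=bool)
    for k, spec in enumerate(scene):
        if isinstance(spec, FigureSpec):
            canvas, mask = render_texture_figure(canvas, spec, seed + 1 + k)
        else:
            canvas, mask = render_glyph(canvas, spec, bank=bank)
        if (occupied & ndimage.binary_dilation(mask)).any():
            raise PlacementError("object masks overlap")
        if masks[spec.class_index].any():
            raise PlacementError("duplicate object class in one scene")
        occupied |= ndimage.binary_dilation(mask)
        masks[spec.class_index] = mask
    labels = masks.any(axis=(1, 2)).astype(np.int8)
    return Stimulus(image=canvas.astype(np.float32), labels=labels, masks=masks,
                    scene=list(scene), background=background)


def _sample_figure(rng, shape: str, bg_orientation: float, size: int) -> FigureSpec:
    if shape == "square":
        side = rng.uniform(14, 28)
        hw = (side, side)
    else:
        # aspect ratio bounded away from 1 so rectangles stay discriminable
        while True:
            h, w = rng.uniform(14, 28, size=2)
            if max(h, w) / min(h, w) >= 1.3:
                break
        hw = (h, w)
    orient = (bg_orientation + rng.uniform(45, 135)) % 180.0
    rotation = rng.uniform(0, 180)
    phi = np.radians(rotation)
    er = (hw[0] * abs(np.cos(phi)) + hw[1] * abs(np.sin(phi))) / 2 + 1
    ec = (hw[0] * abs(np.sin(phi)) + hw[1] * abs(np.cos(phi))) / 2 + 1
    center = (rng.uniform(er, size - er), rng.uniform(ec, size - ec))
    tex = TextureSpec(orientation=orient)
    return FigureSpec(shape=shape, center=center, side_lengths=hw,
                      rotation=rotation, texture=tex)


def _sample_glyph(rng, digit: int, size: int) -> GlyphSpec:
    scale = rng.uniform(0.75, 1.5)
    half = GLYPH_SIZE * scale / 2 + 1
    center = tuple(rng.uniform(half, size - half, size=2))
    return GlyphSpec(digit_class=digit, center=center, scale=scale,
                     seed=int(rng.integers(0, 2**31 - 1)))


def sample_scene(rng, class_pool: Sequence[int], background: TextureSpec,
                 size: int = CANVAS, max_tries: int = 100,
                 bank: Optional[GlyphBank] = None,
                 n_objects: Optional[int] = None) -> Stimulus:
    """Sample object classes and placements, resampling on collision.

    The background is rendered once; each object's spec is resampled (up to
    ``max_tries`` times) until its mask stays clear of the objects already
    placed.  ``n_objects`` overrides the uniform {1..3} object count.
    """
    pool = list(class_pool)
    bank = bank or GlyphBank()
    n_obj = int(rng.integers(1, min(3, len(pool)) + 1)) if n_objects is None \
        else int(n_objects)
    classes = list(rng.choice(pool, size=n_obj, replace=False))
    # big texture figures first: a late large figure may have no room left
    classes.sort(key=lambda c: (c >= 2, rng.random()))
    background_img = make_background_texture((size, size), background,
                                             int(rng.integers(0, 2**31 - 1)))
    # an early unlucky large placement can make the rest infeasible, so the
    # whole scene is restarted when per-object resampling runs out
    for _restart in range(20):
        canvas = background_img
        masks = np.zeros((N_CLASSES, size, size), dtype=bool)
        occupied = np.zeros((size, size), dtype=bool)
        scene = []
        for cls in classes:
            for _ in range(max_tries):
                if cls == 0:
                    spec = _sample_figure(rng, "square", background.orientation, size)
                elif cls == 1:
                    spec = _sample_figure(rng, "rectangle", background.orientation, size)
                else:
                    spec = _sample_glyph(rng, int(cls) - 2, size)
                if isinstance(spec, FigureSpec):
                    # overlap test on the cheap rasterized mask before
                    # paying for the figure's texture synthesis
                    mask = figure_mask(spec, canvas.shape)
                    if (occupied & ndimage.binary_dilation(mask)).any():
                        continue
                    new_canvas, mask = render_texture_figure(
                        canvas, spec, int(rng.integers(0, 2**31 - 1)))
                else:
                    new_canvas, mask = render_glyph(canvas, spec, bank=bank)
                    if (occupied & ndimage.binary_dilation(mask)).any():
                        continue
                canvas = new_canvas
                occupied |= ndimage.binary_dilation(mask)
                masks[spec.class_index] = mask
                scene.append(spec)
                break
            else:
                break  # object exhausted its tries -> restart the scene
        if len(scene) == n_obj:
            labels = masks.any(axis=(1, 2)).astype(np.int8)
            return Stimulus(image=canvas.astype(np.float32), labels=labels,
                            masks=masks, scene=scene, background=background)
    raise PlacementError(f"could not place {n_obj} objects")


def generate_dataset(n: int, class_pool: Sequence[int] = range(N_CLASSES),
                     seed: int = 0, size: int = CANVAS,
                     mnist_dir=None) -> list[Stimulus]:
    """Generate ``n`` stimuli, reproducible under ``seed``.

    Object count per image is uniform on {1, 2, 3} (capped by the pool
    size); classes are drawn without replacement from ``class_pool``; each
    background orientation is uniform on [0, 180).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pool = list(class_pool)
    if not pool:
        raise ValueError("class pool is empty")
    bank = GlyphBank(mnist_dir)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        bg = TextureSpec(orientation=rng.uniform(0, 180))
        out.append(sample_scene(rng, pool, bg, size=size, bank=bank))
    return out


def images_array(stimuli: Sequence[Stimulus]) -> np.ndarray:
    return np.stack([s.image for s in stimuli])


def labels_array(stimuli: Sequence[Stimulus]) -> np.ndarray:
    return np.stack([s.labels for s in stimuli]).astype(np.float32)


# ---------------------------------------------------------------------------
# region maps


def region_map(mask: np.ndarray, edge_width: int = 2,
               other_masks: Sequence[np.ndarray] = ()) -> RegionMap:
    """Partition the canvas around one object's mask.

    The edge band is ``dilate(mask, w) minus erode(mask, w)`` (square
    connectivity), the figure region is the eroded mask, ground is the rest
    of the canvas except pixels of other objects, which are ``excluded``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if edge_width < 1:
        raise ValueError("edge_width must be at least 1")
    structure = np.ones((3, 3), dtype=bool)
    dil = ndimage.binary_dilation(mask, structure, iterations=edge_width)
    ero = ndimage.binary_erosion(mask, structure, iterations=edge_width)
    assignment = np.full(mask.shape, GROUND, dtype=np.uint8)
    assignment[dil] = EDGE
    assignment[ero] = FIGURE
    for om in other_masks:
        assignment[np.asarray(om, dtype=bool) & (assignment == GROUND)] = EXCLUDED
    return RegionMap(assignment=assignment, edge_width=edge_width)


# ---------------------------------------------------------------------------
# on-disk format: PNG + JSON sidecar + NPZ masks + CSV manifest


def _spec_to_json(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["kind"] = "figure" if isinstance(spec, FigureSpec) else "glyph"
    return d


def _spec_from_json(d: dict) -> SceneSpec:
    d = dict(d)
    kind = d.pop("kind")
    if kind == "figure":
        d["texture"] = TextureSpec(**d["texture"])
        d["center"] = tuple(d["center"])
        d["side_lengths"] = tuple(d["side_lengths"])
        return FigureSpec(**d)
    d["center"] = tuple(d["center"])
    return GlyphSpec(**d)


def save_dataset(stimuli: Sequence[Stimulus], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(stimuli):
        stem = f"stim_{i:05d}"
        Image.fromarray((s.image * 255).astype(np.uint8)).save(outdir / f"{stem}.png")
        np.savez_compressed(outdir / f"{stem}_masks.npz", masks=s.masks)
        sidecar = {
            "labels": s.labels.tolist(),
            "scene": [_spec_to_json(sp) for sp in s.scene],
            "background": dataclasses.asdict(s.background) if s.background else None,
        }
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        rows.append({"stem": stem, "n_objects": len(s.scene),
                     "classes": ";".join(CLASS_NAMES[k] for k in s.present_classes())})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)


def load_dataset(indir) -> list[Stimulus]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    out = []
    for stem in manifest["stem"]:
        image = np.asarray(Image.open(indir / f"{stem}.png"), dtype=np.float32) / 255.0
        with np.load(indir / f"{stem}_masks.npz") as z:
            masks = z["masks"]
        sidecar = json.loads((indir / f"{stem}.json").read_text())
        bg = TextureSpec(**sidecar["background"]) if sidecar["background"] else None
        out.append(Stimulus(
            image=image, labels=np.asarray(sidecar["labels"], dtype=np.int8),
            masks=masks, scene=[_spec_from_json(d) for d in sidecar["scene"]],
            background=bg))
    return out
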