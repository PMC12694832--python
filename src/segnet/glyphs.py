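"""Procedural digit glyphs.

Download-free stand-in for handwritten digits: each class 0-9 is a
hand-designed stroke skeleton (polylines and elliptical arcs in a unit box)
rendered anti-aliased onto a 28x28 bitmap, with seeded slant, scale and
thickness jitter so repeated draws of a class vary like handwriting does.
A loader for the standard IDX ubyte files lets real MNIST bitmaps be
substituted when they are available on disk.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line_aa

GLYPH_SIZE = 28


def _arc(cx, cy, rx, ry, a0, a1, n=48):
    t = np.radians(np.linspace(a0, a1, n))
    return list(zip(cx + rx * np.cos(t), cy + ry * np.sin(t)))


# Stroke skeletons in a unit box; x runs right, y runs down.
_SKELETONS = {
    0: [_arc(0.50, 0.50, 0.27, 0.40, 0, 360)],
    1: [[(0.52, 0.10), (0.52, 0.90)], [(0.34, 0.26), (0.52, 0.10)]],
    2: [_arc(0.50, 0.30, 0.26, 0.20, 180, 360),
        [(0.76, 0.30), (0.24, 0.90)], [(0.24, 0.90), (0.78, 0.90)]],
    3: [_arc(0.48, 0.31, 0.26, 0.21, 160, 450),
        _arc(0.48, 0.69, 0.28, 0.22, -90, 200)],
    4: [[(0.62, 0.10), (0.62, 0.92)],
        [(0.62, 0.10), (0.22, 0.62), (0.80, 0.62)]],
    5: [[(0.74, 0.10), (0.28, 0.10), (0.26, 0.46)],
        _arc(0.47, 0.66, 0.27, 0.23, -80, 170)],
    6: [[(0.66, 0.10), (0.40, 0.38), (0.28, 0.62)],
        _arc(0.48, 0.66, 0.23, 0.23, 0, 360)],
    7: [[(0.22, 0.12), (0.78, 0.12), (0.42, 0.92)]],
    8: [_arc(0.50, 0.30, 0.22, 0.19, 0, 360),
        _arc(0.50, 0.70, 0.26, 0.22, 0, 360)],
    9: [_arc(0.50, 0.34, 0.24, 0.22, 0, 360),
        [(0.73, 0.40), (0.68, 0.68), (0.50, 0.92)]],
}

# Unit box mapped into the 28x28 bitmap: taller than wide, like a digit.
_ROW0, _ROW1 = 3.0, 25.0
_COL0, _COL1 = 6.5, 21.5


def synth_glyph(digit_class: int, seed: int) -> np.ndarray:
    """Render one seeded 28x28 glyph bitmap with intensities in [0, 1]."""
    if not (isinstance(digit_class, (int, np.integer)) and 0 <= digit_class <= 9):
        raise ValueError(f"digit class must be in 0..9, got {digit_class!r}")
    rng = np.random.default_rng(seed)
    slant = rng.normal(0.0, 0.06)
    sx, sy = rng.uniform(0.90, 1.05, size=2)
    jx, jy = rng.uniform(-0.02, 0.02, size=2)
    extra_thick = rng.random() < 0.5

    img = np.zeros((GLYPH_SIZE, GLYPH_SIZE), dtype=np.float32)
    for stroke in _SKELETONS[digit_class]:
        pts = []
        for x, y in stroke:
            xs = 0.5 + (x - 0.5) * sx + slant * (0.5 - y) + jx
            ys = 0.5 + (y - 0.5) * sy + jy
            pts.append((_ROW0 + ys * (_ROW1 - _ROW0), _COL0 + xs * (_COL1 - _COL0)))
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc, val = line_aa(int(round(r0)), int(round(c0)),
                                  int(round(r1)), int(round(c1)))
            keep = (rr >= 0) & (rr < GLYPH_SIZE) & (cc >= 0) & (cc < GLYPH_SIZE)
            np.maximum.at(img, (rr[keep], cc[keep]), val[keep].astype(np.float32))
    # handwritten-digit strokes are a few pixels wide; the skeleton lines
    # are dilated so strokes stay locally distinct from thin texture bars
    img = ndimage.grey_dilation(img, size=(2, 2))
    if extra_thick:
        img = ndimage.grey_dilation(img, size=(2, 2))
    return np.clip(img, 0.0, 1.0)


def load_idx_images(path) -> np.ndarray:
    """Read an IDX3 ubyte image file (the standard MNIST on-disk format)."""
    raw = Path(path).read_bytes()
    magic, n, rows, cols = struct.unpack(">IIII", raw[:16])
    if magic != 2051:
        raise ValueError(f"not an IDX3 image file: magic {magic}")
    return (np.frombuffer(raw, dtype=np.uint8, offset=16)
            .reshape(n, rows, cols).astype(np.float32) / 255.0)


def load_idx_labels(path) -> np.ndarray:
    raw = Path(path).read_bytes()
    magic, n = struct.unpack(">II", raw[:8])
    if magic != 2049:
        raise ValueError(f"not an IDX1 label file: magic {magic}")
    return np.frombuffer(raw, dtype=np.uint8, offset=8)


class GlyphBank:
    """Source of digit bitmaps: procedural by default, IDX files optionally.

    ``get(digit_class, seed)`` is deterministic for a fixed bank; with an
    MNIST directory the seed indexes into that class's examples.
    """

    def __init__(self, mnist_dir=None):
        self._by_class = None
        if mnist_dir is not None:
            d = Path(mnist_dir)
            images = load_idx_images(d / "train-images-idx3-ubyte")
            labels = load_idx_labels(d / "train-labels-idx1-ubyte")
            self._by_class = [images[labels == k] for k in range(10)]

    def get(self, digit_class: int, seed: int) -> np.ndarray:
        if self._by_class is None:
            return synth_glyph(digit_class, seed)
        pool = self._by_class[digit_class]
        return pool[seed % len(pool)]
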