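"""Streamline handling: track I/O, fixel assignment and significance
cropping.

For visualisation, a whole-brain template tractogram can be cropped so
that only segments overlying significant fixels remain: every streamline
point is assigned to the fixel in its containing voxel whose direction
is closest to the local streamline tangent (within a maximum angle), and
maximal runs of points whose fixels pass the significance mask are kept.

Supported formats: the common binary ``.tck`` track format (via
nibabel.streamlines, mm coordinates) and a plain-text fallback with one
``x y z`` point per line and blank lines between streamlines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import FixelGrid

__all__ = [
    "Tractogram",
    "read_tracks",
    "write_tracks",
    "assign_streamline_points",
    "crop_tractogram",
]


@dataclass
class Tractogram:
    """Sequences of 3-D points in physical (mm) space."""

    streamlines: list[np.ndarray]

    def __post_init__(self):
        sl = []
        for s in self.streamlines:
            s = np.asarray(s, dtype=float).reshape(-1, 3)
            if s.shape[0] < 2:
                raise ValueError("each streamline needs at least 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline contains non-finite coordinates")
            sl.append(s)
        self.streamlines = sl

    @property
    def count(self) -> int:
        return len(self.streamlines)


def read_tracks(path) -> Tractogram:
    path = Path(path)
    if path.suffix == ".tck":
        tck = nib.streamlines.load(str(path))
        return Tractogram([np.asarray(s) for s in tck.streamlines])
    streamlines, cur = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            if cur:
                streamlines.append(np.asarray(cur))
                cur = []
            continue
        cur.append([float(v) for v in line.split()])
    if cur:
        streamlines.append(np.asarray(cur))
    return Tractogram(streamlines)


def write_tracks(t: Tractogram, path) -> None:
    path = Path(path)
    if path.suffix == ".tck":
        trac = nib.streamlines.Tractogram(t.streamlines,
                                          affine_to_rasmm=np.eye(4))
        nib.streamlines.save(trac, str(path))
        return
    with path.open("w") as fh:
        fh.write("# fba tracks v1\n")
        for s in t.streamlines:
            for p in s:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


def _tangents(points: np.ndarray) -> np.ndarray:
    """Central-difference tangents, one-sided at the endpoints."""
    tan = np.empty_like(points)
    tan[1:-1] = points[2:] - points[:-2]
    tan[0] = points[1] - points[0]
    tan[-1] = points[-1] - points[-2]
    n = np.linalg.norm(tan, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return tan / n


def assign_streamline_points(t: Tractogram, g: FixelGrid,
                             max_angle: float = 30.0) -> list[np.ndarray]:
    """Per-point fixel index (or -1) for every streamline.

    A point maps to the fixel of its containing voxel whose axial
    direction is closest to the local streamline tangent; -1 if the
    voxel is outside the grid or empty, or the best angle exceeds
    ``max_angle`` degrees.
    """
    inv = np.linalg.inv(g.affine)
    cos_thr = np.cos(np.radians(max_angle)) - 1e-12
    out = []
    for s in t.streamlines:
        tan = _tangents(s)
        idx = np.round(s @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        assign = np.full(s.shape[0], -1, dtype=np.int64)
        for k in range(s.shape[0]):
            vox = tuple(idx[k])
            if any(v < 0 or v >= d for v, d in zip(vox, g.shape)):
                continue
            o, c = int(g.offsets[vox]), int(g.counts[vox])
            if c == 0:
                continue
            cosa = np.abs(g.directions[o:o + c] @ tan[k])
            j = int(np.argmax(cosa))
            if cosa[j] >= cos_thr:
                assign[k] = o + j
        out.append(assign)
    return out


def crop_tractogram(t: Tractogram, assignment: list[np.ndarray],
                    mask: np.ndarray) -> Tractogram:
    """Keep maximal runs of consecutive points whose fixels are in-mask.

    Points assigned to no fixel (-1) or to a masked-out fixel are
    removed; surviving runs shorter than 2 points are dropped (they
    cannot be rendered as a segment).  Never creates points.
    """
    mask = np.asarray(mask, dtype=bool)
    kept = []
    for s, a in zip(t.streamlines, assignment):
        good = (a >= 0) & mask[np.clip(a, 0, len(mask) - 1)]
        k = 0
        while k < len(good):
            if good[k]:
                j = k
                while j < len(good) and good[j]:
                    j += 1
                if j - k >= 2:
                    kept.append(s[k:j].copy())
                k = j
            else:
                k += 1
    return Tractogram(kept)
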