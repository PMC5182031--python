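"""Sparse fixel data model, grid geometry and on-disk fixel-directory I/O.

A *fixel* is a specific fibre population within a voxel.  Crossing-fibre
voxels hold several fixels, each with its own (axial) direction and named
scalar metrics such as fibre density ("fd"), fibre-bundle cross-section
("fc") or their product ("fdc").  The on-disk layout is a directory of
NIfTI files:

* ``index.nii[.gz]``       -- 4-D ``(X, Y, Z, 2)`` int volume holding, per
  voxel, the fixel ``count`` and the ``offset`` of its first fixel in the
  flat per-fixel arrays;
* ``directions.nii[.gz]``  -- ``(F, 1, 1, 3)`` unit direction per fixel;
* ``<metric>.nii[.gz]``    -- ``(F, 1, 1, 1)`` scalar per fixel, one file
  per named metric.

NIfTI-1 and NIfTI-2 are both accepted on read; NIfTI-2 is written.
Directions are axial: ``v`` and ``-v`` denote the same fixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FixelGrid",
    "ScalarImage",
    "FixelFormatError",
    "FixelValidationError",
    "read_fixel_dir",
    "write_fixel_dir",
    "voxel_fixels",
]

_DIR_TOL_WARN = 1e-4   # renormalise with a warning beyond this deviation
_DIR_TOL_ERR = 1e-2    # reject directions this far from unit norm


class FixelFormatError(ValueError):
    """The on-disk fixel directory is structurally inconsistent."""


class FixelValidationError(ValueError):
    """In-memory fixel data violates an invariant."""


def _as_shape3(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) == 2:          # 2-D grids ride as 3-D with a singleton z
        shape = shape + (1,)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise FixelValidationError(f"bad grid shape {shape}")
    return shape


@dataclass
class FixelGrid:
    """Sparse per-voxel fixel sets on a regular image grid.

    Parameters
    ----------
    shape : tuple of int
        Grid dimensions; 2-D grids are stored as ``(nx, ny, 1)``.
    affine : (4, 4) ndarray
        Voxel-index to physical (mm) coordinate map.
    counts : ndarray of int, shape ``shape``
        Number of fixels per voxel.
    offsets : ndarray of int, shape ``shape``
        Index of each voxel's first fixel in the flat arrays; voxels are
        stored contiguously in C order.
    directions : (F, 3) ndarray
        Unit axial direction per fixel.
    values : dict of str -> (F,) ndarray
        Named per-fixel scalar metrics.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    counts: np.ndarray
    offsets: np.ndarray
    directions: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.shape = _as_shape3(self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64).reshape(self.shape)
        self.offsets = np.asarray(self.offsets, dtype=np.int64).reshape(self.shape)
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        self.values = {k: np.asarray(v, dtype=float).reshape(-1)
                       for k, v in self.values.items()}
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_fixels(self) -> int:
        return int(self.directions.shape[0])

    def validate(self) -> None:
        f = self.n_fixels
        if int(self.counts.sum()) != f:
            raise FixelFormatError(
                f"index counts sum to {int(self.counts.sum())} but "
                f"directions file holds {f} fixels")
        # offsets must tile [0, F) contiguously in C order
        flat_c = self.counts.reshape(-1)
        flat_o = self.offsets.reshape(-1)
        expect = np.concatenate([[0], np.cumsum(flat_c)[:-1]])
        nz = flat_c > 0
        if np.any(flat_o[nz] != expect[nz]):
            raise FixelFormatError("fixel offsets are not contiguous")
        if f:
            norms = np.linalg.norm(self.directions, axis=1)
            dev = np.abs(norms - 1.0)
            if dev.max() > _DIR_TOL_ERR:
                raise FixelValidationError(
                    f"non-unit fixel direction (max deviation {dev.max():.3g})")
            if dev.max() > _DIR_TOL_WARN:
                warnings.warn("renormalising fixel directions "
                              f"(max deviation {dev.max():.3g})", stacklevel=2)
            if dev.max() > 1e-9:
                self.directions = self.directions / norms[:, None]
        for name, arr in self.values.items():
            if arr.shape != (f,):
                raise FixelFormatError(
                    f"value '{name}' has length {arr.shape[0]}, expected {f}")

    # ------------------------------------------------------------------
    @classmethod
    def from_voxel_lists(cls, shape, affine, per_voxel, values_names=()):
        """Build a grid from ``{voxel: [(direction, {name: val}), ...]}``."""
        shape = _as_shape3(shape)
        counts = np.zeros(shape, dtype=np.int64)
        dirs, vals = [], {n: [] for n in values_names}
        offsets = np.zeros(shape, dtype=np.int64)
        off = 0
        for vox in np.ndindex(shape):
            fx = per_voxel.get(vox, [])
            counts[vox] = len(fx)
            offsets[vox] = off
            off += len(fx)
            for d, rec in fx:
                dirs.append(np.asarray(d, dtype=float))
                for n in vals:
                    vals[n].append(rec.get(n, 0.0))
        directions = (np.asarray(dirs).reshape(-1, 3)
                      if dirs else np.empty((0, 3)))
        return cls(shape, affine, counts, offsets, directions,
                   {n: np.asarray(v) for n, v in vals.items()})

    def fixel_voxels(self) -> np.ndarray:
        """(F, 3) voxel index of every fixel, in storage order."""
        out = np.empty((self.n_fixels, 3), dtype=np.int64)
        for vox in zip(*np.nonzero(self.counts)):
            o, c = self.offsets[vox], self.counts[vox]
            out[o:o + c] = vox
        return out

    def voxel_to_physical(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def with_values(self, **values) -> "FixelGrid":
        """Copy of the grid with the given value arrays added/replaced."""
        vals = dict(self.values)
        vals.update({k: np.asarray(v, dtype=float) for k, v in values.items()})
        return FixelGrid(self.shape, self.affine.copy(), self.counts.copy(),
                         self.offsets.copy(), self.directions.copy(), vals)


@dataclass
class ScalarImage:
    """One scalar per voxel on the same grid geometry as a FixelGrid."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    data: np.ndarray

    def __post_init__(self):
        self.shape = _as_shape3(self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.data = np.asarray(self.data, dtype=float).reshape(self.shape)

    @classmethod
    def load(cls, path) -> "ScalarImage":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        return cls(data.shape[:3], img.affine, data.reshape(data.shape[:3]))

    def save(self, path) -> None:
        nib.save(nib.Nifti2Image(self.data.astype(np.float32), self.affine),
                 str(path))


# ----------------------------------------------------------------------
# Fixel directory I/O


def _find(path: Path, stem: str) -> Path | None:
    for suff in (".nii", ".nii.gz"):
        p = path / (stem + suff)
        if p.exists():
            return p
    return None


def read_fixel_dir(path) -> FixelGrid:
    """Read a fixel directory (index + directions + metric files)."""
    path = Path(path)
    idx_p = _find(path, "index")
    dir_p = _find(path, "directions")
    if idx_p is None or dir_p is None:
        raise FixelFormatError(f"{path}: missing index or directions file")
    idx_img = nib.load(str(idx_p))
    idx = np.asarray(idx_img.dataobj)
    if idx.ndim != 4 or idx.shape[3] != 2:
        raise FixelFormatError(f"{idx_p}: index must be 4-D with last dim 2")
    counts = idx[..., 0].astype(np.int64)
    offsets = idx[..., 1].astype(np.int64)
    dirs = np.asarray(nib.load(str(dir_p)).dataobj, dtype=float).reshape(-1, 3)

    values = {}
    for p in sorted(path.iterdir()):
        name = p.name
        for suff in (".nii.gz", ".nii"):
            if name.endswith(suff):
                stem = name[:-len(suff)]
                break
        else:
            continue
        if stem in ("index", "directions"):
            continue
        values[stem] = np.asarray(nib.load(str(p)).dataobj,
                                  dtype=float).reshape(-1)
    return FixelGrid(counts.shape, idx_img.affine, counts, offsets, dirs,
                     values)


def write_fixel_dir(g: FixelGrid, path) -> None:
    """Write ``g`` as a fixel directory; round-trips through read_fixel_dir."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    idx = np.stack([g.counts, g.offsets], axis=-1).astype(np.int32)
    nib.save(nib.Nifti2Image(idx, g.affine), str(path / "index.nii"))
    dirs = g.directions.astype(np.float32).reshape(-1, 1, 1, 3)
    nib.save(nib.Nifti2Image(dirs, np.eye(4)), str(path / "directions.nii"))
    for name, arr in g.values.items():
        vol = arr.astype(np.float32).reshape(-1, 1, 1, 1)
        nib.save(nib.Nifti2Image(vol, np.eye(4)), str(path / f"{name}.nii"))


def voxel_fixels(g: FixelGrid, voxel) -> list[tuple[np.ndarray, dict]]:
    """Fixels of one voxel as ``(direction, {metric: value})`` records."""
    voxel = tuple(int(v) for v in voxel)
    if len(voxel) == 2:
        voxel = voxel + (0,)
    if any(v < 0 or v >= s for v, s in zip(voxel, g.shape)):
        raise IndexError(f"voxel {voxel} outside grid {g.shape}")
    o, c = int(g.offsets[voxel]), int(g.counts[voxel])
    return [(g.directions[i], {n: a[i] for n, a in g.values.items()})
            for i in range(o, o + c)]
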