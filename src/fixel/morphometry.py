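"""Warp algebra and fibre-bundle morphometry.

A *deformation field* stores, for every template voxel, the corresponding
physical position in subject space (the pull-back convention: the warp
maps template to subject).  Its Jacobian matrix J is the local affine
linearisation of the warp.  From J and a fixel direction v we derive

* the reoriented fixel direction  v' = J v / ||J v||,
* the fibre-bundle cross-section  FC = det(J) / ||J v||,

i.e. the total volume change with the stretch along the fibre factored
out, leaving the expansion (FC > 1: subject bundle larger than template)
or contraction (FC < 1) of the plane perpendicular to the fibre.  The
combined measure FDC = FD * FC modulates microscopic fibre density by
macroscopic cross-section so that total intra-axonal content is preserved
under spatial normalisation.

Jacobians are computed in physical (mm) coordinates through the image
affine, so anisotropic voxels and rotated grids are handled; singleton
axes (2-D grids stored as (nx, ny, 1)) contribute an identity column.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .core import FixelGrid, _as_shape3

__all__ = [
    "DeformationField",
    "DisplacementField",
    "JacobianField",
    "FoldedWarpError",
    "DegenerateWarpError",
    "displacement_to_deformation",
    "deformation_to_displacement",
    "jacobian",
    "reorient_fixel",
    "fibre_cross_section",
    "fc_gram_schmidt_oracle",
    "modulate_fdc",
    "fc_fixel_map",
]


class FoldedWarpError(ValueError):
    """det(J) <= 0 somewhere: the warp folds space and FC is undefined."""


class DegenerateWarpError(ValueError):
    """J annihilates the fixel direction (||Jv|| ~ 0)."""


def _grid_positions(shape, affine) -> np.ndarray:
    """(X, Y, Z, 3) physical coordinate of every voxel centre."""
    shape = _as_shape3(shape)
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).astype(float)
    return idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


@dataclass
class _VectorField:
    shape: tuple[int, int, int]
    affine: np.ndarray
    vectors: np.ndarray          # (X, Y, Z, 3), mm

    def __post_init__(self):
        self.shape = _as_shape3(self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(
            self.shape + (3,))
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vector field contains non-finite values")

    @classmethod
    def load(cls, path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 5 and data.shape[3] == 1:   # NIfTI vector convention
            data = data[:, :, :, 0, :]
        if data.ndim == 4 and data.shape[-1] == 3:
            return cls(data.shape[:3], img.affine, data)
        raise ValueError(f"{path}: expected a 4-D 3-vector volume")

    def save(self, path):
        nib.save(nib.Nifti2Image(self.vectors.astype(np.float32), self.affine),
                 str(path))


class DeformationField(_VectorField):
    """Per-voxel corresponding physical position in the other space (mm)."""

    @property
    def positions(self) -> np.ndarray:
        return self.vectors

    @classmethod
    def identity(cls, shape, affine) -> "DeformationField":
        return cls(shape, affine, _grid_positions(shape, affine))


class DisplacementField(_VectorField):
    """Per-voxel offset vector (mm) from the voxel's own position."""

    @property
    def displacements(self) -> np.ndarray:
        return self.vectors


def displacement_to_deformation(d: DisplacementField) -> DeformationField:
    """positions = voxel physical position + displacement."""
    return DeformationField(d.shape, d.affine,
                            _grid_positions(d.shape, d.affine) + d.vectors)


def deformation_to_displacement(d: DeformationField) -> DisplacementField:
    return DisplacementField(d.shape, d.affine,
                             d.vectors - _grid_positions(d.shape, d.affine))


@dataclass
class JacobianField:
    """Per-voxel 3x3 local affine matrix of a warp (dimensionless)."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    J: np.ndarray                # (X, Y, Z, 3, 3)

    def __post_init__(self):
        self.shape = _as_shape3(self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.J = np.asarray(self.J, dtype=float).reshape(self.shape + (3, 3))

    @property
    def det(self) -> np.ndarray:
        return np.linalg.det(self.J)


def jacobian(deformation: DeformationField) -> JacobianField:
    """Finite-difference Jacobian of a deformation field, in physical units.

    Central differences in the interior, one-sided at the boundary; for a
    deformation that is an affine map of physical coordinates the result
    is exact everywhere.  Singleton axes contribute the identity.
    """
    pos = deformation.vectors
    shape = deformation.shape
    A3 = deformation.affine[:3, :3]
    G = np.empty(shape + (3, 3))          # G[..., i, j] = d pos_i / d index_j
    for ax in range(3):
        if shape[ax] == 1:
            # no variation stored along a singleton axis: the warp is taken
            # as identity there, so d pos / d index = affine column
            G[..., :, ax] = A3[:, ax]
        else:
            eo = 2 if shape[ax] >= 3 else 1
            G[..., :, ax] = np.gradient(pos, axis=ax, edge_order=eo)
    return JacobianField(shape, deformation.affine,
                         G @ np.linalg.inv(A3))


def reorient_fixel(v: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Reorient a fixel direction through a local affine: J v / ||J v||."""
    v = np.asarray(v, dtype=float)
    Jv = np.asarray(J, dtype=float) @ v
    n = np.linalg.norm(Jv)
    if n <= 1e-12:
        raise DegenerateWarpError("J annihilates the fixel direction")
    return Jv / n


def fibre_cross_section(v: np.ndarray, J: np.ndarray) -> float:
    """Fibre-bundle cross-section FC = det(J) / ||J v||.

    ``v`` is the fixel direction in template space and ``J`` the Jacobian
    of the template-to-subject warp at the fixel's voxel.  FC > 1 means
    the subject bundle has a larger cross-section than the template.
    """
    v = np.asarray(v, dtype=float)
    J = np.asarray(J, dtype=float)
    det = np.linalg.det(J)
    if det <= 0:
        raise FoldedWarpError(f"det(J) = {det:.4g} <= 0: folded warp")
    n = np.linalg.norm(J @ v)
    if n <= 1e-12:
        raise DegenerateWarpError("J annihilates the fixel direction")
    return float(det / n)


def fc_gram_schmidt_oracle(v: np.ndarray, J: np.ndarray) -> float:
    """FC by the tensor-based-morphometry decomposition route (test oracle).

    Builds an orthonormal frame (v, e2, e3) by Gram--Schmidt and measures
    the area scaling of the plane perpendicular to the fibre: the image
    parallelogram (J e2, J e3) is projected onto the plane perpendicular
    to the mapped fibre direction.  Mathematically equivalent to
    ``fibre_cross_section`` but computed without a determinant.
    """
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    J = np.asarray(J, dtype=float)
    seed = np.eye(3)[np.argmin(np.abs(v))]
    e2 = seed - (seed @ v) * v
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(v, e2)
    Jv = J @ v
    n = np.linalg.norm(Jv)
    if n <= 1e-12:
        raise DegenerateWarpError("J annihilates the fixel direction")
    area = np.cross(J @ e2, J @ e3) @ (Jv / n)
    if area <= 0:
        raise FoldedWarpError("folded warp (negative perpendicular area)")
    return float(area)


def modulate_fdc(fd: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Combined fibre density and cross-section: FDC = FD * FC, elementwise."""
    fd = np.asarray(fd, dtype=float)
    fc = np.asarray(fc, dtype=float)
    if fd.shape != fc.shape:
        raise ValueError(f"FD and FC lengths differ: {fd.shape} vs {fc.shape}")
    if np.any(fc <= 0):
        raise ValueError("FC must be positive")
    return fd * fc


def fc_fixel_map(template: FixelGrid, warp: DeformationField,
                 log_transform: bool = False) -> FixelGrid:
    """Per-fixel FC over a template fixel mask from a template->subject warp.

    Returns a copy of the template grid with an "fc" value computed from
    the warp Jacobian at each fixel's voxel.  ``log_transform`` stores
    log(FC) instead (off by default).
    """
    if template.shape != warp.shape:
        raise ValueError(
            f"grid mismatch: fixels {template.shape} vs warp {warp.shape}")
    Jf = jacobian(warp)
    vox = template.fixel_voxels()
    J = Jf.J[vox[:, 0], vox[:, 1], vox[:, 2]]
    det = np.linalg.det(J)
    bad = det <= 0
    if np.any(bad):
        where = sorted({tuple(int(x) for x in v) for v in vox[bad]})
        raise FoldedWarpError(
            f"folded warp (det(J) <= 0) at {len(where)} voxel(s): "
            f"{where[:10]}{'...' if len(where) > 10 else ''}")
    Jv = np.einsum("fij,fj->fi", J, template.directions)
    fc = det / np.linalg.norm(Jv, axis=1)
    return template.with_values(fc=np.log(fc) if log_transform else fc)
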