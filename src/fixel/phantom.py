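"""Numerical fibre-bundle phantom and the cross-section conservation
experiment.

The phantom is a straight 2-D fibre bundle oriented along x with fibre
density 1 in every fixel.  Pull-back warps (template -> subject) are
applied to it -- a pure length scaling, a shear, and a smoothed piecewise
cosine displacement that both contracts and expands the bundle -- and the
fixel metrics FD, FC and FDC are computed on the warped (template-space)
bundle.  The validation then integrates FD and FDC across the bundle's
width: FDC must be conserved under all three warps (total intra-axonal
cross-sectional content is invariant to how the bundle is deformed),
while FD alone is conserved only when the cross-section is untouched.

The cosine displacement of amplitude ``s_x / amplitude_divisor`` has
opposite signs above and below the bundle mid-line; the discontinuity at
y = 0 is removed by Gaussian smoothing (sigma in voxels).  The smoothed
step must stay shallower than unit slope or the warp folds (det J < 0):
with the default divisor 8 and sigma 5 this bounds the usable bundle
length, which is why the default grid is 48 voxels long.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import FixelGrid
from .morphometry import (DeformationField, DisplacementField,
                          FoldedWarpError, displacement_to_deformation,
                          jacobian)

__all__ = [
    "PhantomSpec",
    "CrossSectionProfile",
    "make_phantom",
    "linear_warp",
    "cosine_warp",
    "transform_phantom",
    "cross_section_sums",
]

TSCALE = np.array([[2.0, 0.0], [0.0, 1.0]])
TSHEAR = np.array([[1.0, 0.0], [0.5, 1.0]])


@dataclass
class PhantomSpec:
    """Geometry and numerical parameters of the fibre-bundle phantom.

    ``length_vox`` is s_x, the bundle/image length along x; the cosine
    displacement amplitude is ``length_vox / amplitude_divisor`` voxels.
    """

    length_vox: int = 48
    height_vox: int = 48
    width_vox: float = 8.0
    voxel_size: float = 1.0          # mm
    fd0: float = 1.0
    smoothing_sigma: float = 5.0     # voxels
    amplitude_divisor: float = 8.0
    step: float = 0.1                # cross-section sub-voxel step, voxels
    edge_frac: float = 0.05          # bundle-edge threshold, fraction of fd0

    def __post_init__(self):
        if min(self.length_vox, self.height_vox, self.width_vox,
               self.voxel_size, self.fd0, self.step) <= 0:
            raise ValueError("phantom parameters must be positive")
        if self.step >= 1:
            raise ValueError("step must be sub-voxel (< 1)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.length_vox, self.height_vox, 1)

    @property
    def affine(self) -> np.ndarray:
        """Grid centred so the bundle mid-line lies at y = 0."""
        a = np.diag([self.voxel_size] * 3 + [1.0])
        a[0, 3] = -(self.length_vox - 1) / 2 * self.voxel_size
        a[1, 3] = -(self.height_vox - 1) / 2 * self.voxel_size
        return a


@dataclass
class CrossSectionProfile:
    """Sums of FD and FDC across the bundle width along its length."""

    positions: np.ndarray        # physical x of each sampled length position
    sum_fd: np.ndarray
    sum_fdc: np.ndarray | None
    valid: np.ndarray            # False where the traverse left the grid


def make_phantom(spec: PhantomSpec) -> FixelGrid:
    """Straight bundle along x: one fixel (direction x, fd = fd0) per
    in-bundle voxel, nothing elsewhere."""
    nx, ny, _ = spec.shape
    ys = (np.arange(ny) - (ny - 1) / 2) * spec.voxel_size
    inside = np.abs(ys) < spec.width_vox / 2 * spec.voxel_size
    counts = np.zeros(spec.shape, dtype=np.int64)
    counts[:, inside, 0] = 1
    offsets = np.zeros_like(counts)
    offsets.reshape(-1)[:] = np.concatenate(
        [[0], np.cumsum(counts.reshape(-1))[:-1]])
    F = int(counts.sum())
    dirs = np.tile([1.0, 0.0, 0.0], (F, 1))
    return FixelGrid(spec.shape, spec.affine, counts, offsets, dirs,
                     {"fd": np.full(F, spec.fd0)})


def _grid_geometry(grid) -> tuple[tuple[int, int, int], np.ndarray]:
    if isinstance(grid, PhantomSpec):
        return grid.shape, grid.affine
    if isinstance(grid, FixelGrid):
        return grid.shape, grid.affine
    shape, affine = grid
    return tuple(shape), np.asarray(affine, dtype=float)


def linear_warp(T: np.ndarray, grid) -> DeformationField:
    """Pull-back deformation from a linear map: positions = T @ x.

    ``T`` may be 2x2 (embedded with identity z) or 3x3.  Because the
    field is linear in physical coordinates, ``jacobian()`` of the result
    recovers T exactly at every voxel.
    """
    T = np.asarray(T, dtype=float)
    if T.shape == (2, 2):
        T3 = np.eye(3)
        T3[:2, :2] = T
    elif T.shape == (3, 3):
        T3 = T
    else:
        raise ValueError("T must be 2x2 or 3x3")
    if np.linalg.det(T3) <= 0:
        raise FoldedWarpError("linear map must be orientation-preserving")
    shape, affine = _grid_geometry(grid)
    from .morphometry import _grid_positions
    pos = _grid_positions(shape, affine)
    return DeformationField(shape, affine, pos @ T3.T)


def cosine_warp(spec: PhantomSpec, grid=None) -> DeformationField:
    """Smoothed piecewise-cosine pull-back warp of the phantom.

    Unsmoothed displacement along y, in voxels:
    ``+ (s_x/divisor) cos(2 pi x / s_x)`` for y > 0 and its negation for
    y < 0, x being the voxel's position along the bundle.  Each component
    is Gaussian-smoothed (sigma = ``spec.smoothing_sigma`` voxels,
    reflective boundaries) to remove the mid-line discontinuity, then
    converted to a deformation field.
    """
    shape, affine = _grid_geometry(grid if grid is not None else spec)
    nx, ny, _ = shape
    amp = spec.length_vox / spec.amplitude_divisor          # voxels
    ix = np.arange(nx)
    ys = np.arange(ny) * affine[1, 1] + affine[1, 3]        # physical y
    sign = np.where(ys > 0, 1.0, -1.0)
    dy = amp * np.cos(2 * np.pi * ix / spec.length_vox)[:, None] * sign[None, :]
    dy = ndimage.gaussian_filter(dy, spec.smoothing_sigma, mode="reflect")
    disp = np.zeros(shape + (3,))
    disp[..., 1] = dy[..., None] * spec.voxel_size          # mm
    return displacement_to_deformation(
        DisplacementField(shape, affine, disp))


def _dominant_per_voxel(g: FixelGrid, metric: str = "fd"):
    """Per-voxel value map and direction of the largest-``metric`` fixel."""
    val = np.zeros(g.shape)
    dirs = np.zeros(g.shape + (3,))
    has = np.zeros(g.shape, dtype=bool)
    arr = g.values[metric]
    for vox in zip(*np.nonzero(g.counts)):
        o, c = int(g.offsets[vox]), int(g.counts[vox])
        k = o + int(np.argmax(arr[o:o + c]))
        val[vox] = arr[k]
        dirs[vox] = g.directions[k]
        has[vox] = True
    return val, dirs, has


def _interp_field(field: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a scalar volume at fractional indices."""
    return ndimage.map_coordinates(field, idx.T, order=1, mode="constant",
                                   cval=0.0)


def transform_phantom(phantom: FixelGrid, warp: DeformationField,
                      supersample: int = 4,
                      fd_min: float = 1e-3) -> FixelGrid:
    """Warped (template-space) bundle with "fd", "fc" and "fdc" values.

    ``warp`` is the template -> subject pull-back defined on the template
    grid.  The template fibre density is the subject FD pulled through
    the warp (trilinear, anti-aliased by ``supersample``^2 sub-voxel
    samples per voxel so partial-volume edges are represented); template
    fixel directions are the subject directions mapped through the
    inverse Jacobian and renormalised, making the reorientation of the
    template direction by J recover the subject direction; FC comes from
    the Jacobian at each voxel and FDC = FD * FC.
    """
    shape, affine = warp.shape, warp.affine
    sub_val, sub_dir, sub_has = _dominant_per_voxel(phantom)
    # nearest-fixel direction lookup for voxels without fixels
    if not sub_has.all():
        _, nearest = ndimage.distance_transform_edt(~sub_has,
                                                    return_indices=True)
        sub_dir = sub_dir[nearest[0], nearest[1], nearest[2]]

    inv_sub = np.linalg.inv(phantom.affine)
    inv_tpl = np.linalg.inv(affine)

    # supersampled pull of subject FD onto the template grid
    nx, ny, nz = shape
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    fd_t = np.zeros(shape)
    base = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
    disp = warp.vectors - np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                    indexing="ij"), axis=-1) @ affine[:3, :3].T - affine[:3, 3]
    for ox in offs:
        for oy in offs:
            sub_idx = base + [ox, oy, 0.0]
            # warped physical position = sub-sample position + interpolated
            # displacement (edge-extended: positions blend badly with zeros)
            phys = sub_idx @ affine[:3, :3].T + affine[:3, 3]
            d = np.stack([ndimage.map_coordinates(disp[..., i], sub_idx.T,
                                                  order=1, mode="nearest")
                          for i in range(3)], axis=-1)
            sidx = (phys + d) @ inv_sub[:3, :3].T + inv_sub[:3, 3]
            fd_t += _interp_field(sub_val, sidx).reshape(shape)
    fd_t /= supersample ** 2

    Jf = jacobian(warp).J
    keep = fd_t > fd_min * float(phantom.values["fd"].max(initial=1.0))
    counts = keep.astype(np.int64)
    offsets = np.zeros(shape, dtype=np.int64)
    offsets.reshape(-1)[:] = np.concatenate(
        [[0], np.cumsum(counts.reshape(-1))[:-1]])
    vox = np.argwhere(keep)
    J = Jf[vox[:, 0], vox[:, 1], vox[:, 2]]
    det = np.linalg.det(J)
    if np.any(det <= 0):
        raise FoldedWarpError(
            f"folded warp at {int((det <= 0).sum())} bundle voxel(s); "
            "reduce the displacement amplitude or increase smoothing")

    # subject direction at each mapped voxel centre (nearest voxel)
    centre_pos = np.stack([warp.vectors[..., i][keep] for i in range(3)],
                          axis=-1)
    sidx = centre_pos @ inv_sub[:3, :3].T + inv_sub[:3, 3]
    sidx = np.clip(np.round(sidx).astype(int), 0,
                   np.array(phantom.shape) - 1)
    v_s = sub_dir[sidx[:, 0], sidx[:, 1], sidx[:, 2]]
    v_t = np.linalg.solve(J, v_s[..., None])[..., 0]
    v_t /= np.linalg.norm(v_t, axis=1, keepdims=True)

    Jv = np.einsum("fij,fj->fi", J, v_t)
    fc = det / np.linalg.norm(Jv, axis=1)
    fd = fd_t[keep]
    return FixelGrid(shape, affine, counts, offsets, v_t,
                     {"fd": fd, "fc": fc, "fdc": fd * fc})


def _interp_direction(dirs2: np.ndarray, has: np.ndarray, p: np.ndarray,
                      prev: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of an axial 2-D direction field at ``p``.

    Corner directions are sign-aligned with ``prev`` before averaging
    (axial vectors have no polarity); voxels without fixels contribute
    nothing.  Falls back to ``prev`` where no information is available.
    """
    nx, ny = has.shape
    x0 = int(np.floor(p[0])); y0 = int(np.floor(p[1]))
    fx = p[0] - x0; fy = p[1] - y0
    acc = np.zeros(2)
    for dx, wx in ((0, 1 - fx), (1, fx)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            x, y = x0 + dx, y0 + dy
            if 0 <= x < nx and 0 <= y < ny and has[x, y] and wx * wy > 0:
                d = dirs2[x, y]
                if d @ prev < 0:
                    d = -d
                acc += wx * wy * d
    n = np.linalg.norm(acc)
    return acc / n if n > 1e-12 else prev


def cross_section_sums(g: FixelGrid, spec: PhantomSpec,
                       margin: int = 2) -> CrossSectionProfile:
    """Integrate FD (and FDC) across the bundle width along its length.

    At each sampled length position the traverse starts at the bundle
    mid-line (fibre-density centre of mass of the image column), then
    advances in sub-voxel steps perpendicular to the locally interpolated
    fixel orientation -- in both directions -- until the interpolated FD
    drops below ``spec.edge_frac * fd0`` (the bundle edge).  Sums are
    Riemann sums scaled by the step length.  Positions whose traverse
    leaves the grid before reaching the bundle edge are flagged invalid;
    the two columns at each x boundary are not sampled.
    """
    if g.shape[2] != 1:
        raise ValueError("cross-section profiling expects a 2-D (nx, ny, 1) grid")
    nx, ny, _ = g.shape
    fd_map3, dir3, has3 = _dominant_per_voxel(g, "fd")
    fd_map = fd_map3[:, :, 0]
    has = has3[:, :, 0]
    dirs2 = dir3[:, :, 0, :2]
    fdc_map = None
    if "fdc" in g.values:
        fdc_map = _dominant_per_voxel(g, "fdc")[0][:, :, 0]

    vs = float(np.abs(g.affine[0, 0]))
    step = spec.step                      # voxel units
    edge = spec.edge_frac * spec.fd0
    max_steps = int(10 * ny / step)

    def interp(m, p):
        return float(ndimage.map_coordinates(
            m, np.asarray(p, dtype=float).reshape(2, 1), order=1,
            mode="constant", cval=0.0)[0])

    cols = range(margin, nx - margin)
    xs, sfd, sfdc, valid = [], [], [], []
    for ixc in cols:
        w = fd_map[ixc, :]
        if w.sum() <= edge:
            continue
        y0 = float((w * np.arange(ny)).sum() / w.sum())
        # sample only where the section crosses the bundle proper: at the
        # bundle's end-caps (image truncation) the mid-line FD ramps down
        # and a perpendicular traverse is not a cross-section
        if interp(fd_map, (ixc, y0)) < 0.95 * spec.fd0:
            continue
        start = np.array([float(ixc), y0])
        d0 = _interp_direction(dirs2, has, start, np.array([1.0, 0.0]))

        tot_fd = interp(fd_map, start)
        tot_fdc = interp(fdc_map, start) if fdc_map is not None else 0.0
        ok = True
        for s in (+1.0, -1.0):
            p = start.copy()
            d_prev = d0.copy()
            n_prev = s * np.array([-d0[1], d0[0]])
            for _ in range(max_steps):
                d = _interp_direction(dirs2, has, p, d_prev)
                n = np.array([-d[1], d[0]])
                if n @ n_prev < 0:
                    n = -n
                p = p + step * n
                d_prev, n_prev = d, n
                if not (0 <= p[0] <= nx - 1 and 0 <= p[1] <= ny - 1):
                    ok = False           # left the grid inside the bundle
                    break
                f = interp(fd_map, p)
                if f < edge:
                    break
                tot_fd += f
                if fdc_map is not None:
                    tot_fdc += interp(fdc_map, p)
        xs.append(float(ixc * g.affine[0, 0] + g.affine[0, 3]))
        sfd.append(tot_fd * step * vs)
        sfdc.append(tot_fdc * step * vs)
        valid.append(ok)
    if not xs:
        raise ValueError("bundle mid-line not found in any sampled column")
    return CrossSectionProfile(np.asarray(xs), np.asarray(sfd),
                               np.asarray(sfdc) if fdc_map is not None else None,
                               np.asarray(valid, dtype=bool))
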