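"""Fibre orientation distributions: spherical harmonics, lobe segmentation
and fixel-specific apparent fibre density (FD).

An FOD is a function on the sphere stored as real, even-order spherical
harmonic (SH) coefficients.  Its lobes correspond to distinct fibre
populations; the integral of a lobe is proportional to the intra-axonal
volume of axons oriented along it, and is used as the fixel's apparent
fibre density.

SH basis convention
-------------------
Real, even orders only (FODs are antipodally symmetric), orthonormal, in
the convention used by the common FOD ecosystem: with ``Y_l^m`` the complex
spherical harmonic (Condon--Shortley phase, ``scipy.special.sph_harm_y``),

* ``m = 0``:  ``Y_l^0`` (real),
* ``m > 0``:  ``sqrt(2) * Re(Y_l^m)``,
* ``m < 0``:  ``sqrt(2) * Im(Y_l^|m|)``,

ordered ``l = 0, 2, ..., lmax`` and, within each ``l``, ``m = -l ... l``.
A coefficient vector of length ``(lmax+1)(lmax+2)/2`` therefore maps
one-to-one onto an even-order band limit ``lmax``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import scipy.special
import trimesh
from scipy.spatial import SphericalVoronoi, cKDTree

from .core import FixelGrid

__all__ = [
    "SHImage",
    "SphereMesh",
    "Lobe",
    "n_coeffs_for_lmax",
    "lmax_for_n_coeffs",
    "sh_basis",
    "sh_eval",
    "sh_delta",
    "segment_lobes",
    "fixels_from_fod",
]


def n_coeffs_for_lmax(lmax: int) -> int:
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be even and >= 0, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def lmax_for_n_coeffs(n: int) -> int:
    lmax = 0
    while n_coeffs_for_lmax(lmax) < n:
        lmax += 2
    if n_coeffs_for_lmax(lmax) != n:
        raise ValueError(f"{n} is not a valid even-order SH coefficient count")
    return lmax


@dataclass
class SHImage:
    """Volume of real even-order SH coefficient vectors (one FOD per voxel)."""

    shape: tuple[int, ...]
    affine: np.ndarray
    coeffs: np.ndarray          # (*shape, n_coeffs)
    lmax: int = -1

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        n = self.coeffs.shape[-1]
        inferred = lmax_for_n_coeffs(n)
        if self.lmax < 0:
            self.lmax = inferred
        elif self.lmax != inferred:
            raise ValueError(
                f"lmax {self.lmax} inconsistent with {n} coefficients")
        self.shape = tuple(int(s) for s in self.coeffs.shape[:-1])

    @classmethod
    def load(cls, path) -> "SHImage":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError("SH image must be 4-D (x, y, z, coefficients)")
        return cls(data.shape[:3], img.affine, data)

    def save(self, path) -> None:
        nib.save(nib.Nifti2Image(self.coeffs.astype(np.float32), self.affine),
                 str(path))


def sh_basis(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Real even-order SH design matrix, shape ``(n_dirs, n_coeffs)``."""
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    norm = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = dirs / norm
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))   # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])            # azimuth
    cols = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            y = scipy.special.sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * y.real)
            else:
                cols.append(np.sqrt(2.0) * y.imag)
    return np.stack(cols, axis=1)


def sh_eval(coeffs: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Evaluate an SH coefficient vector at unit directions.

    Linear in ``coeffs`` and antipodally symmetric (even orders only).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = lmax_for_n_coeffs(coeffs.shape[-1])
    B = sh_basis(lmax, dirs)
    return B @ coeffs


def sh_delta(direction: np.ndarray, lmax: int,
             apodise: float = 0.0) -> np.ndarray:
    """Coefficients of a band-limited delta aimed at ``direction``.

    The projection of a Dirac delta on the sphere onto the even SH basis
    up to ``lmax``, optionally apodised with the spherical heat kernel
    (band ``l`` damped by ``exp(-l(l+1) apodise^2 / 2)``, ``apodise`` in
    radians) to suppress Gibbs sidelobes -- with apodisation the profile
    is positive everywhere and has a single (axial) peak.  Used to
    construct test FODs with known peak locations.
    """
    c = sh_basis(lmax, np.asarray(direction, dtype=float)[None, :])[0]
    if apodise > 0:
        taper = np.concatenate(
            [np.full(2 * l + 1, np.exp(-l * (l + 1) * apodise ** 2 / 2))
             for l in range(0, lmax + 1, 2)])
        c = c * taper
    return c


# ----------------------------------------------------------------------
# Hemisphere quadrature mesh


@dataclass
class SphereMesh:
    """Dense hemisphere sampling with adjacency and solid-angle weights.

    Vertices are one representative per antipodal pair of an icosphere
    tessellation (FODs are axial, so a hemisphere suffices); ``weights``
    are spherical Voronoi cell areas on the full sphere and sum to 2*pi
    over the hemisphere.
    """

    vertices: np.ndarray                 # (D, 3)
    neighbours: list[np.ndarray]         # adjacency, hemisphere indices
    weights: np.ndarray                  # (D,) steradian
    _basis_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def icosphere(cls, subdivisions: int = 4) -> "SphereMesh":
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
        verts = np.asarray(mesh.vertices, dtype=float)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
        edges = np.asarray(mesh.edges_unique)

        # antipode of every vertex (icosphere is centrally symmetric)
        dist, anti = cKDTree(verts).query(-verts)
        if dist.max() > 1e-8:
            raise RuntimeError("tessellation is not antipodally symmetric")

        # canonical hemisphere: z > 0, ties by y then x
        eps = 1e-9
        z, y, x = verts[:, 2], verts[:, 1], verts[:, 0]
        keep = (z > eps) | ((np.abs(z) <= eps) &
                            ((y > eps) | ((np.abs(y) <= eps) & (x > 0))))
        hemi_idx = np.nonzero(keep)[0]
        full_to_hemi = np.full(len(verts), -1, dtype=int)
        full_to_hemi[hemi_idx] = np.arange(len(hemi_idx))
        # antipodal partner maps to the same hemisphere vertex
        rep = np.where(keep, np.arange(len(verts)), anti[np.arange(len(verts))])

        adj = [set() for _ in hemi_idx]
        for a, b in edges:
            for u, v in ((a, b), (b, a)):
                hu = full_to_hemi[rep[u]]
                hv = full_to_hemi[rep[v]]
                if hu >= 0 and hv >= 0 and hu != hv:
                    adj[hu].add(hv)
                    adj[hv].add(hu)

        areas = SphericalVoronoi(verts).calculate_areas()
        return cls(verts[hemi_idx],
                   [np.array(sorted(s), dtype=int) for s in adj],
                   areas[hemi_idx])

    def basis(self, lmax: int) -> np.ndarray:
        if lmax not in self._basis_cache:
            self._basis_cache[lmax] = sh_basis(lmax, self.vertices)
        return self._basis_cache[lmax]

    @property
    def angular_resolution_deg(self) -> float:
        """Median nearest-neighbour angle of the tessellation, degrees."""
        d0 = self.vertices[0]
        nb = self.vertices[self.neighbours[0]]
        ang = np.degrees(np.arccos(np.clip(np.abs(nb @ d0), 0, 1)))
        return float(np.median(ang))


@dataclass
class Lobe:
    """One FOD lobe: a watershed basin of the positive FOD amplitude."""

    peak_index: int            # hemisphere vertex index of the local maximum
    peak_direction: np.ndarray # refined unit direction
    members: np.ndarray        # hemisphere vertex indices in the lobe
    integral: float            # sum of amplitude * solid-angle weight


def _refine_peak(mesh: SphereMesh, amps: np.ndarray, peak: int) -> np.ndarray:
    """Sub-vertex peak localisation by a quadratic fit in the tangent plane."""
    p = mesh.vertices[peak]
    nbr = mesh.neighbours[peak]
    pts = np.vstack([p, mesh.vertices[nbr]])
    # align antipodal neighbours with the peak before projecting
    pts = pts * np.sign(pts @ p + 1e-30)[:, None]
    vals = np.concatenate([[amps[peak]], amps[nbr]])
    # local tangent frame
    seed = np.array([1.0, 0.0, 0.0]) if abs(p[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ p) * p
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p, e1)
    u = (pts - p) @ e1
    v = (pts - p) @ e2
    A = np.stack([u * u, v * v, u * v, u, v, np.ones_like(u)], axis=1)
    if A.shape[0] < 6:
        return p
    coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
    a, b, c, d, e, _ = coef
    H = np.array([[2 * a, c], [c, 2 * b]])
    try:
        off = np.linalg.solve(H, -np.array([d, e]))
    except np.linalg.LinAlgError:
        return p
    rmax = np.sqrt(u[1:] ** 2 + v[1:] ** 2).max() if len(u) > 1 else 0.0
    r = np.linalg.norm(off)
    if r > rmax:                       # stationary point outside the stencil
        off = off * (rmax / r) if r > 0 else off
    q = p + off[0] * e1 + off[1] * e2
    return q / np.linalg.norm(q)


def _segment_amplitudes(amps: np.ndarray, mesh: SphereMesh) -> list[Lobe]:
    """Watershed lobe segmentation of sampled amplitudes (see segment_lobes)."""
    D = len(amps)
    pos = np.maximum(amps, 0.0)

    # plateaus (exactly equal positive amplitudes on adjacent vertices) act
    # as a single watershed node, so a constant FOD yields one lobe
    parent = np.arange(D)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(D):
        if amps[i] <= 0:
            continue
        for j in mesh.neighbours[i]:
            if j < i and amps[j] == amps[i] and amps[j] > 0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    comp_members: dict[int, list[int]] = {}
    for i in range(D):
        if amps[i] > 0:
            comp_members.setdefault(find(i), []).append(i)

    # steepest ascent between plateau nodes; ties broken by lowest index
    target: dict[int, int] = {}
    for c, members in comp_members.items():
        best_amp, best_idx = amps[members[0]], None
        for i in members:
            for j in mesh.neighbours[i]:
                cj = find(j) if amps[j] > 0 else -1
                if cj == c:
                    continue
                if amps[j] > best_amp or (amps[j] == best_amp
                                          and best_idx is not None
                                          and j < best_idx):
                    best_amp, best_idx = amps[j], j
        target[c] = find(best_idx) if best_idx is not None else c

    root: dict[int, int] = {}

    def find_root(c: int) -> int:
        path = []
        while c not in root and target[c] != c:
            path.append(c)
            c = target[c]
        r = root.get(c, c)
        for p in path:
            root[p] = r
        root[c] = r
        return r

    basins: dict[int, list[int]] = {}
    for c, members in comp_members.items():
        basins.setdefault(find_root(c), []).extend(members)

    out = []
    for r, members in basins.items():
        members = np.asarray(sorted(members), dtype=int)
        peak = int(members[np.argmax(amps[members])])
        integral = float(np.sum(pos[members] * mesh.weights[members]))
        out.append(Lobe(peak, _refine_peak(mesh, amps, peak), members,
                        integral))
    out.sort(key=lambda lb: (-lb.integral, lb.peak_index))
    return out


def segment_lobes(coeffs: np.ndarray, mesh: SphereMesh) -> list[Lobe]:
    """Segment an FOD into lobes by steepest-ascent watershed on the mesh.

    Every hemisphere vertex with positive amplitude walks to its highest
    neighbour (plateaus of exactly equal amplitude move as one node; ties
    broken by lowest vertex index) until a local maximum is reached;
    vertices reaching the same maximum form one lobe.  Negative
    amplitudes are clamped to zero for integration; an all-non-positive
    FOD yields an empty list.  Lobes are sorted by descending integral.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    return _segment_amplitudes(sh_eval(coeffs, mesh.vertices), mesh)


_DEFAULT_MESH: list[SphereMesh] = []


def default_mesh() -> SphereMesh:
    """Shared default hemisphere mesh (1281 vertices, built lazily)."""
    if not _DEFAULT_MESH:
        _DEFAULT_MESH.append(SphereMesh.icosphere(4))
    return _DEFAULT_MESH[0]


def fixels_from_fod(fod: SHImage, mesh: SphereMesh | None = None,
                    fd_threshold: float = 0.10,
                    max_fixels: int = 3) -> FixelGrid:
    """Segment every voxel's FOD into fixels with an "fd" value.

    Per voxel, one fixel is created for each lobe whose integral reaches
    ``fd_threshold``, keeping at most ``max_fixels`` largest lobes.  The
    fixel direction is the lobe's refined peak direction and its "fd" value
    the lobe integral.
    """
    if mesh is None:
        mesh = default_mesh()
    B = mesh.basis(fod.lmax)
    flat = fod.coeffs.reshape(-1, fod.coeffs.shape[-1])
    shape = fod.shape
    counts = np.zeros(np.prod(shape), dtype=np.int64)
    offsets = np.zeros(np.prod(shape), dtype=np.int64)
    dirs, fds = [], []
    off = 0
    for vi in range(flat.shape[0]):
        offsets[vi] = off
        c = flat[vi]
        if not np.any(c):
            continue
        amps = B @ c
        if amps.max() <= 0:
            continue
        sel = [lb for lb in _segment_amplitudes(amps, mesh)
               if lb.integral >= fd_threshold][:max_fixels]
        counts[vi] = len(sel)
        off += len(sel)
        for lb in sel:
            dirs.append(lb.peak_direction)
            fds.append(lb.integral)
    directions = np.asarray(dirs).reshape(-1, 3) if dirs else np.empty((0, 3))
    return FixelGrid(shape, fod.affine, counts.reshape(shape),
                     offsets.reshape(shape), directions,
                     {"fd": np.asarray(fds)})
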