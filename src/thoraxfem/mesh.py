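"""Labelled tetrahedral meshes for the thorax, box and cylinder domains.

The thorax mesh is a single-block structured grid: the torso cross-section is
meshed by transfinite interpolation (TFI) of the ellipse between four corner
angles, extruded along z, and each hexahedral cell is split into six
tetrahedra (Freudenthal split along a common diagonal, which is conforming
when every cell uses the same local orientation).  Local refinement around
the electrode patches is achieved by grading the 1-D gridlines; gridlines are
snapped to the horizontal lung-base and fluid-cut planes so those material
interfaces are mesh-conforming.

Element region labels come from point-classification of element centroids;
airway-lumen cells are removed, which exposes interior faces that become the
insulating ``airway_wall`` patch.  Everything is deterministic for fixed
inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .grading import RefineBand, graded_points
from .thorax import (AIRWAY_LUMEN, CORNER_ANGLES_DEG, LABEL_NAMES,
                     GeometryError, ThoraxGeometry)

__all__ = [
    "TetMesh",
    "REFINEMENT_FACTORS",
    "generate_mesh",
    "region_volumes",
    "box_mesh",
    "cylinder_mesh",
    "write_vtk",
    "read_vtk",
]

# target element-size multipliers relative to the 'normal' level, mirroring a
# four-level convergence ladder spanning roughly a 3x size range
REFINEMENT_FACTORS = {"coarser": 2.2, "coarse": 1.5, "normal": 1.0,
                      "fine": 0.7}

# 'normal' target sizes (m): bulk spacing and electrode-patch spacing
H_BULK_NORMAL = 0.0105
H_ELECTRODE_NORMAL = 0.0025


def _aligned_band(center: float, radius: float,
                  he: float) -> tuple[RefineBand, tuple[float, float]]:
    """Refinement band of exact ``he`` multiples centred on an electrode.

    Snapping the band edges and tiling the interior with a whole number of
    ``he`` cells makes the gridlines inside the band identical at every
    refinement level, so the discrete electrode patches do not jitter across
    the convergence ladder.
    """
    n_half = max(2, math.ceil((radius + he) / he))
    ext = n_half * he
    band = RefineBand(center - ext, center + ext, he)
    return band, (center - ext, center + ext)

ELECTRODE_PATCHES = ("electrode_A", "electrode_B", "electrode_C",
                     "electrode_D")


@dataclass
class TetMesh:
    """Conforming labelled tetrahedral mesh with named boundary patches."""

    nodes: np.ndarray          # (N, 3) float
    tets: np.ndarray           # (M, 4) int
    tet_labels: np.ndarray     # (M,) int
    label_names: dict[int, str]
    boundary_faces: np.ndarray  # (B, 3) int
    face_labels: np.ndarray     # (B,) int
    face_owners: np.ndarray     # (B,) int, owning element of each face
    patch_names: dict[int, str]
    refinement_level: str = "normal"
    # per-element region volume fractions (M, n_labels); where present,
    # assembly mixes admittivities of interface-straddling elements instead
    # of using the binary centroid label (missing mass = insulating lumen)
    region_fractions: np.ndarray | None = field(default=None, repr=False)
    _volumes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        if self._volumes is None:
            p = self.nodes[self.tets]
            self._volumes = np.abs(_signed_volumes(p))
        return self._volumes

    def signed_volumes(self) -> np.ndarray:
        return _signed_volumes(self.nodes[self.tets])

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def patch_id(self, name: str) -> int:
        for pid, pname in self.patch_names.items():
            if pname == name:
                return pid
        raise KeyError(f"unknown boundary patch {name!r}")

    def patch_faces(self, name: str) -> np.ndarray:
        return self.boundary_faces[self.face_labels == self.patch_id(name)]

    def patch_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.patch_faces(name))

    def patch_area(self, name: str) -> float:
        tri = self.nodes[self.patch_faces(name)]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def label_id(self, region: str) -> int:
        for lid, lname in self.label_names.items():
            if lname == region:
                return lid
        raise KeyError(f"unknown region label {region!r}")


def _signed_volumes(p: np.ndarray) -> np.ndarray:
    d = p[:, 1:] - p[:, :1]
    return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0


# ------------------------------------------------------------ building blocks

def _freudenthal_tets(cell_ids: np.ndarray) -> np.ndarray:
    """Split hex cells (given as 8 corner ids, (i,j,k)-bit order) into 6 tets.

    ``cell_ids`` columns are corners indexed by bits (di, dj, dk) ->
    column di*4 + dj*2 + dk.  All six tets share the main diagonal
    (0,0,0)-(1,1,1), which makes the split conforming across cells.
    """
    tets = []
    for perm in permutations(range(3)):
        bits = [0, 0, 0]
        path = [0]
        for ax in perm:
            bits[ax] = 1
            path.append(bits[0] * 4 + bits[1] * 2 + bits[2])
        tets.append(cell_ids[:, path])
    return np.concatenate(tets, axis=0)


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vol = _signed_volumes(nodes[tets])
    flip = vol < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    if np.any(np.abs(_signed_volumes(nodes[tets])) <= 0.0):
        raise GeometryError("mesh generation produced degenerate elements")
    return tets


def _grid_tets(nu: int, nv: int, nw: int) -> np.ndarray:
    """Freudenthal tets for a full structured (nu, nv, nw) node grid."""
    idx = np.arange(nu * nv * nw).reshape(nu, nv, nw)
    corners = []
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                corners.append(
                    idx[di:nu - 1 + di, dj:nv - 1 + dj, dk:nw - 1 + dk]
                    .ravel())
    return _freudenthal_tets(np.column_stack(corners))


def _boundary_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Faces appearing exactly once, with the owning element index."""
    faces = np.concatenate([
        tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
        tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]])
    owners = np.tile(np.arange(len(tets)), 4)
    s = np.sort(faces, axis=1).astype(np.int64)
    n = int(s.max()) + 1
    keys = (s[:, 0] * n + s[:, 1]) * n + s[:, 2]   # fits int64 for n < 2^21
    order = np.argsort(keys, kind="stable")
    sk = keys[order]
    new = np.empty(len(sk), dtype=bool)
    new[0] = True
    new[1:] = sk[1:] != sk[:-1]
    run = np.cumsum(new) - 1
    once = np.bincount(run)[run] == 1
    keep = order[once]
    return faces[keep], owners[keep]


def _compress(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray,
                                                            np.ndarray]:
    used = np.zeros(len(nodes), dtype=bool)
    used[tets.ravel()] = True
    remap = np.cumsum(used) - 1
    return nodes[used], remap[tets]


# ------------------------------------------------------------- thorax meshing

def _tfi_section(geom: ThoraxGeometry, u: np.ndarray,
                 v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transfinite interpolation of the torso ellipse between corner angles.

    Each of the four edges is an ellipse arc parametrized uniformly by arc
    length, so the grid boundary lies exactly on the ellipse and the ``u``
    coordinate along the anterior (top) edge is linear in the unrolled arc
    coordinate ``w``.
    """
    a, b = geom.torso_a, geom.torso_b
    c0, c1, c2, c3 = CORNER_ANGLES_DEG  # anterior-left, -right via [c0,c1]

    def arc(phi_start: float, phi_end: float, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if phi_start > phi_end:
            phi_start, phi_end, t = phi_end, phi_start, 1.0 - t
        phi = np.linspace(math.radians(phi_start), math.radians(phi_end),
                          2001)
        speed = np.hypot(a * np.sin(phi), b * np.cos(phi))
        s = np.concatenate([[0.0], np.cumsum(
            0.5 * (speed[1:] + speed[:-1]) * np.diff(phi))])
        ph = np.interp(t * s[-1], s, phi)
        return np.column_stack([a * np.cos(ph), b * np.sin(ph)])

    tu = (u + 1.0) / 2.0
    tv = (v + 1.0) / 2.0
    # top edge: anterior arc, u=-1 at phi=c0 (patient left) -> u=+1 at c1
    top = arc(c0, c1, tu)
    # bottom edge: posterior arc with matching x-orientation
    bot = arc(c3, c2, tu)
    left = arc(c3 - 360.0, c0, tv)   # through phi=0 (patient left flank)
    right = arc(c2, c1, tv)          # through phi=180 (patient right flank)
    X, Y = _tutte_interior(u, v, top, bot, left, right)
    return X, Y


def _tutte_interior(u, v, top, bot, left, right):
    """Interior section nodes by a weighted graph-Laplace (Tutte) solve.

    Every interior node is the weighted barycentre of its four grid
    neighbours, with weights equal to the inverse parametric spacings; for a
    convex boundary this yields a fold-free grid (Tutte embedding) and on a
    rectangle it reproduces the graded tensor grid exactly.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    nu, nv = len(u), len(v)
    X = np.zeros((nu, nv))
    Y = np.zeros((nu, nv))
    X[:, -1], Y[:, -1] = top[:, 0], top[:, 1]
    X[:, 0], Y[:, 0] = bot[:, 0], bot[:, 1]
    X[0, :], Y[0, :] = left[:, 0], left[:, 1]
    X[-1, :], Y[-1, :] = right[:, 0], right[:, 1]
    if nu <= 2 or nv <= 2:
        return X, Y
    idx = np.arange(nu * nv).reshape(nu, nv)
    interior = idx[1:-1, 1:-1].ravel()
    sub = np.full(nu * nv, -1)
    sub[interior] = np.arange(len(interior))
    A = lil_matrix((len(interior), len(interior)))
    bx = np.zeros(len(interior))
    by = np.zeros(len(interior))
    du = np.diff(u)
    dv = np.diff(v)
    for row, n in enumerate(interior):
        i, j = divmod(n, nv)
        nbrs = (((i - 1, j), 1.0 / du[i - 1]), ((i + 1, j), 1.0 / du[i]),
                ((i, j - 1), 1.0 / dv[j - 1]), ((i, j + 1), 1.0 / dv[j]))
        wsum = sum(w for _, w in nbrs)
        A[row, row] = wsum
        for (ii, jj), w in nbrs:
            nn = idx[ii, jj]
            if sub[nn] >= 0:
                A[row, sub[nn]] = -w
            else:
                bx[row] += w * X[ii, jj]
                by[row] += w * Y[ii, jj]
    A = A.tocsr()
    X.ravel()[interior] = spsolve(A, bx)
    Y.ravel()[interior] = spsolve(A, by)
    return X, Y


def generate_mesh(geom: ThoraxGeometry,
                  refinement_level: str = "normal") -> TetMesh:
    """Generate the labelled thorax mesh at one of four refinement levels."""
    if refinement_level not in REFINEMENT_FACTORS:
        raise ValueError(f"unknown refinement level {refinement_level!r}")
    f = REFINEMENT_FACTORS[refinement_level]
    h0 = H_BULK_NORMAL * f
    # electrode-patch surface resolution is held fixed across refinement
    # levels: the patch shape is a model feature, and freezing it lets the
    # convergence ladder measure bulk discretization alone (the same spirit
    # as physics-controlled meshing, which always resolves small faces)
    he = H_ELECTRODE_NORMAL

    arr = geom.electrode_array
    w_half = geom.anterior_halfwidth()
    u_bands: list[RefineBand] = []
    z_bands: list[RefineBand] = []
    u_snap: list[float] = []
    z_snap: list[float] = [geom.lung_base_height("left"),
                           geom.lung_base_height("right")]
    for spec in geom.fluid.values():
        if spec.cut_height is not None:
            z_snap.append(spec.cut_height)
    if arr is not None:
        r = arr.diameter / 2.0
        for _, w, z in arr.centers:
            band, edges = _aligned_band(w, r, he)
            u_bands.append(band)
            u_snap.extend(edges)
            band, edges = _aligned_band(z, r, he)
            z_bands.append(band)
            z_snap.extend(edges)
    # u gridlines are generated in the unrolled coordinate w (linear in u
    # along the anterior edge) and mapped back to [-1, 1]
    ws = graded_points(-w_half, w_half, h0, tuple(u_bands),
                       snap=tuple(u_snap))
    u = ws / w_half
    # v: posterior -> anterior, mildly refined toward the electrode side
    b_eff = geom.torso_b  # metric scale of v at the mid-section
    v = graded_points(-1.0, 1.0, h0 / b_eff,
                      (RefineBand(0.5, 1.0, max(he, 0.5 * h0) / b_eff),))
    z = graded_points(0.0, geom.height, h0, tuple(z_bands),
                      snap=tuple(z_snap))

    X, Y = _tfi_section(geom, u, v)
    nu, nv, nw = len(u), len(v), len(z)
    nodes = np.empty((nu * nv * nw, 3))
    nodes[:, 0] = np.repeat(X.ravel(), nw)
    nodes[:, 1] = np.repeat(Y.ravel(), nw)
    nodes[:, 2] = np.tile(z, nu * nv)
    tets = _grid_tets(nu, nv, nw)

    centroids = nodes[tets].mean(axis=1)
    labels = geom.label_points(centroids)
    keep = labels != AIRWAY_LUMEN
    tets, labels = tets[keep], labels[keep]
    nodes, tets = _compress(nodes, tets)
    tets = _orient_positive(nodes, tets)
    fractions = _region_fractions(geom, nodes, tets)

    bfaces, owners = _boundary_faces(tets)
    face_labels, patch_names = _label_thorax_faces(geom, nodes, bfaces)
    return TetMesh(nodes=nodes, tets=tets, tet_labels=labels,
                   label_names=dict(LABEL_NAMES), boundary_faces=bfaces,
                   face_labels=face_labels, face_owners=owners,
                   patch_names=patch_names,
                   refinement_level=refinement_level,
                   region_fractions=fractions)


# barycentric sample set for per-element region fractions: four
# vertex-biased points, six edge midpoints and the centroid
_FRACTION_BARY = np.array(
    [[0.58, 0.14, 0.14, 0.14], [0.14, 0.58, 0.14, 0.14],
     [0.14, 0.14, 0.58, 0.14], [0.14, 0.14, 0.14, 0.58],
     [0.5, 0.5, 0.0, 0.0], [0.5, 0.0, 0.5, 0.0], [0.5, 0.0, 0.0, 0.5],
     [0.0, 0.5, 0.5, 0.0], [0.0, 0.5, 0.0, 0.5], [0.0, 0.0, 0.5, 0.5],
     [0.25, 0.25, 0.25, 0.25]])


def _bary_lattice(n: int) -> np.ndarray:
    pts = [(i, j, k, n - i - j - k)
           for i in range(n + 1)
           for j in range(n + 1 - i)
           for k in range(n + 1 - i - j)]
    return np.asarray(pts, dtype=float) / n


_DENSE_BARY = _bary_lattice(8)


def _sample_fractions(geom: ThoraxGeometry, p: np.ndarray,
                      bary_set: np.ndarray, n_lab: int) -> np.ndarray:
    fr = np.zeros((len(p), n_lab), dtype=np.float32)
    wt = 1.0 / len(bary_set)
    for bary in bary_set:
        pts = np.einsum("i,mij->mj", bary, p)
        lab = geom.label_points(pts)
        ok = lab != AIRWAY_LUMEN
        fr[np.nonzero(ok)[0], lab[ok]] += wt
    return fr


def _region_fractions(geom: ThoraxGeometry, nodes: np.ndarray,
                      tets: np.ndarray) -> np.ndarray:
    """Per-element region volume fractions from fixed barycentric samples.

    Fractions over the six tissue labels; mass classified as airway lumen is
    left unassigned (insulating).  Used to homogenize the admittivity of
    elements straddling a material interface.  Elements within reach of a
    rib bar — a feature thinner than the bulk element size — are re-sampled
    on a dense barycentric lattice, which keeps the realized rib volume
    stable across refinement levels.
    """
    n_lab = len(LABEL_NAMES)
    p = nodes[tets]                          # (M, 4, 3)
    fr = _sample_fractions(geom, p, _FRACTION_BARY, n_lab)
    # second pass: any element straddling an interface (mixed fractions or
    # partial lumen mass), plus everything within reach of a rib bar
    near = (fr.max(axis=1) < 0.98) | (fr.sum(axis=1) < 0.98)
    prm = geom.params
    if prm.ribs_enabled and prm.rib_count_pairs > 0:
        cent = p.mean(axis=1)
        radius = np.sqrt(np.max(np.sum((p - cent[:, None, :]) ** 2, axis=2),
                                axis=1))
        near |= _near_rib_shell(geom, cent,
                                radius + prm.rib_cross_section_radius)
    if near.any():
        fr[near] = _sample_fractions(geom, p[near], _DENSE_BARY, n_lab)
    return fr


def _near_rib_shell(geom: ThoraxGeometry, pts: np.ndarray,
                    reach: np.ndarray) -> np.ndarray:
    prm = geom.params
    sa = prm.rib_shell_scale * geom.torso_a
    sb = prm.rib_shell_scale * geom.torso_b
    phi = np.arctan2(pts[:, 1] / sb, pts[:, 0] / sa)
    dp2 = np.sum((pts[:, :2] - np.column_stack(
        [sa * np.cos(phi), sb * np.sin(phi)])) ** 2, axis=1)
    z_lo, z_hi = prm.rib_z_range
    levels = np.linspace(z_lo, z_hi, prm.rib_count_pairs)
    dz = np.min(np.abs(pts[:, 2, None] - levels[None, :]), axis=1)
    return dp2 + dz**2 <= reach**2


def _label_thorax_faces(geom: ThoraxGeometry, nodes: np.ndarray,
                        bfaces: np.ndarray) -> tuple[np.ndarray, dict]:
    patch_names = {0: "outer", 5: "airway_wall"}
    ztol = 1e-9
    r2 = (nodes[:, 0] / geom.torso_a) ** 2 + (nodes[:, 1] / geom.torso_b) ** 2
    on_ellipse = np.abs(r2 - 1.0) < 1e-7
    on_caps = (np.abs(nodes[:, 2]) < ztol) | (
        np.abs(nodes[:, 2] - geom.height) < ztol)
    lateral = on_ellipse[bfaces].all(axis=1)
    caps = on_caps[bfaces].all(axis=1)
    labels = np.zeros(len(bfaces), dtype=np.int32)
    labels[~(lateral | caps)] = 5  # interior faces exposed by lumen removal
    arr = geom.electrode_array
    if arr is not None:
        cent = nodes[bfaces].mean(axis=1)
        w = geom.w_of_xy(cent[:, 0], cent[:, 1])
        rad = arr.diameter / 2.0
        for k, (lab, wc, zc) in enumerate(arr.centers):
            pid = 1 + "ABCD".index(lab)
            patch_names[pid] = f"electrode_{lab}"
            inside = lateral & (
                (w - wc) ** 2 + (cent[:, 2] - zc) ** 2 <= rad**2)
            if not inside.any():
                raise GeometryError(
                    f"electrode patch {lab} captured no boundary faces")
            labels[inside] = pid
    return labels, patch_names


def region_volumes(mesh: TetMesh) -> dict[str, float]:
    """Exact per-region sums of element volumes, keyed by region name."""
    vols = mesh.volumes()
    out: dict[str, float] = {name: 0.0 for name in mesh.label_names.values()}
    for lid in np.unique(mesh.tet_labels):
        if int(lid) not in mesh.label_names:
            raise KeyError(f"mesh contains unknown region label {lid}")
        out[mesh.label_names[int(lid)]] = float(
            vols[mesh.tet_labels == lid].sum())
    return out


# ----------------------------------------------------- oracle domain meshers

def box_mesh(size: tuple[float, float, float], h0: float,
             electrode_centers: dict[str, tuple[float, float]] | None = None,
             electrode_diameter: float = 0.01,
             h_electrode: float | None = None) -> TetMesh:
    """Homogeneous box [-Lx/2, Lx/2] x [-Ly/2, Ly/2] x [-Lz, 0].

    Optional circular electrode patches on the top face (z = 0), given as
    ``label -> (x, y)`` centres; gridlines are refined around them.  Used as
    the half-space analytic oracle domain.
    """
    Lx, Ly, Lz = size
    he = h_electrode or h0
    xb, yb = [], []
    xsnap, ysnap = [], []
    r = electrode_diameter / 2.0
    for _, (cx, cy) in (electrode_centers or {}).items():
        band, edges = _aligned_band(cx, r, he)
        xb.append(band)
        xsnap.extend(edges)
        band, edges = _aligned_band(cy, r, he)
        yb.append(band)
        ysnap.extend(edges)
    xs = graded_points(-Lx / 2, Lx / 2, h0, tuple(xb), snap=tuple(xsnap))
    ys = graded_points(-Ly / 2, Ly / 2, h0, tuple(yb), snap=tuple(ysnap))
    zs = graded_points(-Lz, 0.0, h0,
                       (RefineBand(-4 * he, 0.0, he),) if electrode_centers
                       else (), snap=(-4 * he,) if electrode_centers else ())
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    tets = _grid_tets(nx, ny, nz)
    tets = _orient_positive(nodes, tets)
    bfaces, owners = _boundary_faces(tets)
    labels = np.zeros(len(bfaces), dtype=np.int32)
    patch_names = {0: "outer"}
    if electrode_centers:
        cent = nodes[bfaces].mean(axis=1)
        on_top = np.abs(cent[:, 2]) < 1e-12
        for k, (lab, (cx, cy)) in enumerate(electrode_centers.items()):
            pid = k + 1
            patch_names[pid] = f"electrode_{lab}"
            inside = on_top & ((cent[:, 0] - cx) ** 2
                               + (cent[:, 1] - cy) ** 2 <= r**2)
            if not inside.any():
                raise GeometryError(
                    f"electrode patch {lab} captured no boundary faces")
            labels[inside] = pid
    return TetMesh(nodes=nodes, tets=tets,
                   tet_labels=np.zeros(len(tets), dtype=np.int32),
                   label_names={0: "medium"}, boundary_faces=bfaces,
                   face_labels=labels, face_owners=owners,
                   patch_names=patch_names)


def cylinder_mesh(radius: float, height: float, h0: float) -> TetMesh:
    """Homogeneous circular cylinder with full end-cap electrode patches.

    The z = ``height`` cap is ``electrode_A`` and the z = 0 cap is
    ``electrode_B``; used for the 1-D conduction oracle Z = L / (kappa A).
    """
    n_sec = max(4, int(round(2 * radius / h0)) + 1)
    t = np.linspace(-1.0, 1.0, n_sec)

    def arc(phi_start, phi_end, tt):
        # circle: uniform angle is uniform arc length; direction-safe
        ph = np.radians(phi_start + (phi_end - phi_start) * (tt + 1) / 2)
        return np.column_stack([radius * np.cos(ph), radius * np.sin(ph)])

    top, bot = arc(135, 45, t), arc(225, 315, t)
    left, right = arc(225, 135, t), arc(315, 405, t)  # right passes phi=0
    T = (t + 1) / 2
    U, V = np.meshgrid(T, T, indexing="ij")
    P = ((1 - V)[..., None] * bot[:, None, :] + V[..., None] * top[:, None, :]
         + (1 - U)[..., None] * left[None, :, :]
         + U[..., None] * right[None, :, :]
         - (1 - U)[..., None] * (1 - V)[..., None] * bot[0]
         - (1 - U)[..., None] * V[..., None] * top[0]
         - U[..., None] * (1 - V)[..., None] * bot[-1]
         - U[..., None] * V[..., None] * top[-1])
    zs = graded_points(0.0, height, h0)
    nu = nv = n_sec
    nw = len(zs)
    nodes = np.empty((nu * nv * nw, 3))
    nodes[:, 0] = np.repeat(P[..., 0].ravel(), nw)
    nodes[:, 1] = np.repeat(P[..., 1].ravel(), nw)
    nodes[:, 2] = np.tile(zs, nu * nv)
    tets = _grid_tets(nu, nv, nw)
    tets = _orient_positive(nodes, tets)
    bfaces, owners = _boundary_faces(tets)
    cent = nodes[bfaces].mean(axis=1)
    labels = np.zeros(len(bfaces), dtype=np.int32)
    labels[np.abs(cent[:, 2] - height) < 1e-12] = 1
    labels[np.abs(cent[:, 2]) < 1e-12] = 2
    return TetMesh(nodes=nodes, tets=tets,
                   tet_labels=np.zeros(len(tets), dtype=np.int32),
                   label_names={0: "medium"}, boundary_faces=bfaces,
                   face_labels=labels, face_owners=owners,
                   patch_names={0: "outer", 1: "electrode_A",
                                2: "electrode_B"})


# ------------------------------------------------------------------ VTK export

def write_vtk(mesh: TetMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None,
              include_boundary: bool = True) -> None:
    """Write the mesh and optional fields as a legacy ASCII VTK file.

    Tetrahedra come first, then (optionally) the labelled boundary triangles;
    the ``region`` cell array holds the tissue label on tets and the patch
    label on triangles, and ``is_boundary`` distinguishes the two blocks.
    Extra ``cell_data`` arrays are defined on the tets and padded on the
    triangle block.
    """
    nb = len(mesh.boundary_faces) if include_boundary else 0
    ncells = mesh.n_tets + nb
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nthoraxfem mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.9g")
        fh.write(f"CELLS {ncells} {5 * mesh.n_tets + 4 * nb}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(mesh.n_tets, 4, dtype=np.int64), mesh.tets]), fmt="%d")
        if nb:
            np.savetxt(fh, np.column_stack(
                [np.full(nb, 3, dtype=np.int64), mesh.boundary_faces]),
                fmt="%d")
        fh.write(f"CELL_TYPES {ncells}\n")
        types = np.concatenate([np.full(mesh.n_tets, 10, dtype=np.int64),
                                np.full(nb, 5, dtype=np.int64)])
        np.savetxt(fh, types, fmt="%d")
        fh.write(f"CELL_DATA {ncells}\n")
        region = np.concatenate([mesh.tet_labels.astype(float),
                                 mesh.face_labels.astype(float)[:nb]])
        blocks = {"region": region,
                  "is_boundary": np.concatenate(
                      [np.zeros(mesh.n_tets), np.ones(nb)])}
        for name, arr in (cell_data or {}).items():
            blocks[name] = np.concatenate(
                [np.real(np.asarray(arr)).astype(float), np.zeros(nb)])
        for name, arr in blocks.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.real(arr).astype(float), fmt="%.9g")


def read_vtk(path, label_names: dict[int, str] | None = None,
             patch_names: dict[int, str] | None = None) -> TetMesh:
    """Read a labelled tetrahedral mesh from a legacy ASCII VTK file.

    Supports the layout written by :func:`write_vtk` (tets followed by
    labelled boundary triangles, with a ``region`` cell array); this is the
    entry point for user-supplied labelled meshes.
    """
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0

    def seek(prefix: str) -> list[str]:
        nonlocal i
        while i < len(lines) and not lines[i].startswith(prefix):
            i += 1
        if i == len(lines):
            raise ValueError(f"VTK file lacks a {prefix} section")
        tok = lines[i].split()
        i += 1
        return tok

    tok = seek("POINTS")
    n_pts = int(tok[1])
    nodes = np.loadtxt(lines[i:i + n_pts])
    tok = seek("CELLS")
    n_cells = int(tok[1])
    raw = [np.fromstring(lines[i + k], dtype=np.int64, sep=" ")
           for k in range(n_cells)]
    tets = np.array([r[1:] for r in raw if r[0] == 4], dtype=np.int64)
    tris = np.array([r[1:] for r in raw if r[0] == 3],
                    dtype=np.int64).reshape(-1, 3)
    region = None
    try:
        seek("CELL_DATA")
        while True:
            tok = seek("SCALARS")
            name = tok[1]
            i_lut = i  # LOOKUP_TABLE line
            vals = np.loadtxt(lines[i_lut + 1:i_lut + 1 + n_cells])
            i = i_lut + 1 + n_cells
            if name == "region":
                region = vals
                break
    except ValueError:
        pass
    if region is None:
        region = np.zeros(n_cells)
    tet_labels = region[:len(tets)].astype(np.int32)
    face_labels = region[len(tets):len(tets) + len(tris)].astype(np.int32)
    if label_names is None:
        label_names = {int(l): LABEL_NAMES.get(int(l), f"region_{l}")
                       for l in np.unique(tet_labels)}
    if patch_names is None:
        default = {0: "outer", 5: "airway_wall",
                   1: "electrode_A", 2: "electrode_B",
                   3: "electrode_C", 4: "electrode_D"}
        patch_names = {int(l): default.get(int(l), f"patch_{l}")
                       for l in np.unique(face_labels)} if len(tris) else {}
    # recover face owners by matching sorted node triples against tet faces
    owners = np.zeros(len(tris), dtype=np.int64)
    if len(tris):
        faces = np.concatenate([
            tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
            tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]])
        owner_all = np.tile(np.arange(len(tets)), 4)
        order = np.lexsort(np.sort(faces, axis=1).T)
        skeys = np.sort(faces, axis=1)[order]
        tkeys = np.sort(tris, axis=1)
        pos = np.searchsorted(
            skeys.view([("a", np.int64), ("b", np.int64), ("c", np.int64)]
                       ).ravel(),
            tkeys.view([("a", np.int64), ("b", np.int64),
                        ("c", np.int64)]).ravel())
        owners = owner_all[order][np.clip(pos, 0, len(order) - 1)]
    return TetMesh(nodes=nodes, tets=tets, tet_labels=tet_labels,
                   label_names=label_names, boundary_faces=tris,
                   face_labels=face_labels, face_owners=owners,
                   patch_names=patch_names)
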