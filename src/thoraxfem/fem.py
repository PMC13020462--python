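"""Quasi-static conduction FEM with tetrapolar terminal conditions.

Solves div(kappa grad V) = 0 on a labelled tetrahedral mesh with first-order
elements.  Electrodes follow the complete electrode model with zero contact
impedance: every electrode patch is condensed to a single equipotential
unknown, so a prescribed terminal current enters the weak form as a point
load on that unknown and the discrete net current through each patch is
exact.  All non-electrode boundaries (outer surface, airway walls) are
natural, i.e. insulating.

The drive solve grounds the return electrode; a reciprocal drive through the
sense pair reuses the same factorization with a different right-hand side
(the solution is unique up to an additive constant, which is fixed by
shifting the potential so the requested sink patch reads 0 V).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh
from .tissues import PropertyTable, admittivity

__all__ = [
    "SolveSpec",
    "LinearSystem",
    "FieldSolution",
    "assemble_system",
    "solve_injection",
    "check_current_conservation",
    "SolverError",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolveSpec:
    """Electrical solve parameters."""

    frequency: float = 10e3   # Hz
    I0: float = 1e-3          # injected current amplitude, A (peak)
    mode: str = "real"        # "real" (conduction) or "complex" (admittivity)
    solver: str = "auto"      # "auto", "direct" or "iterative"
    rel_tolerance: float = 1e-10

    def __post_init__(self):
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        if self.mode not in ("real", "complex"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.solver not in ("auto", "direct", "iterative"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if not 0.0 < self.rel_tolerance <= 1e-2:
            raise ValueError("rel_tolerance must lie in (0, 1e-2]")


@dataclass
class LinearSystem:
    """Condensed stiffness operator with electrode terminal unknowns."""

    mesh: TetMesh
    spec: SolveSpec
    K: sp.csr_matrix                 # reduced (condensed) operator
    kappa: np.ndarray                # per-element admittivity
    dof_of_node: np.ndarray          # node -> reduced dof
    electrode_dofs: dict[str, int]   # patch name -> reduced dof
    grad: np.ndarray                 # (M, 4, 3) P1 shape-function gradients
    _factor_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_dofs(self) -> int:
        return self.K.shape[0]


@dataclass
class FieldSolution:
    """Nodal potential and element current density for one injection."""

    mesh: TetMesh
    spec: SolveSpec
    source: str
    sink: str
    V: np.ndarray                    # (N,) nodal potential
    J: np.ndarray                    # (M, 3) element current density -k gradV
    electrode_potentials: dict[str, float | complex]
    patch_currents: dict[str, float | complex]  # consistent (residual) fluxes
    residual: float
    system: LinearSystem | None = None


def _element_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    p = mesh.nodes[mesh.tets]
    D = p[:, 1:] - p[:, :1]                  # (M, 3, 3), rows are edges
    Dinv = np.linalg.inv(D)
    grad = np.empty((len(p), 4, 3))
    grad[:, 1:, :] = np.transpose(Dinv, (0, 2, 1))
    grad[:, 0, :] = -grad[:, 1:, :].sum(axis=1)
    vol = np.abs(np.linalg.det(D)) / 6.0
    return grad, vol


def assemble_system(mesh: TetMesh, table: PropertyTable,
                    spec: SolveSpec | None = None) -> LinearSystem:
    """Assemble the condensed P1 stiffness operator.

    Per-element admittivity is looked up by region label at the requested
    frequency; a missing property row fails naming tissue and frequency.
    """
    spec = spec or SolveSpec()
    dtype = complex if spec.mode == "complex" else float
    kappa_of_label: dict[int, complex] = {}
    for lid in np.unique(mesh.tet_labels):
        region = mesh.label_names[int(lid)]
        try:
            props = table.lookup_region(region, spec.frequency)
        except (KeyError, ValueError) as exc:
            raise KeyError(
                f"no dielectric properties for region {region!r} at "
                f"{spec.frequency:g} Hz: {exc}") from exc
        kappa_of_label[int(lid)] = admittivity(props, spec.mode)
    if mesh.region_fractions is not None:
        # homogenize interface-straddling elements: arithmetic mixture of
        # the region admittivities weighted by volume fractions (airway
        # lumen mass contributes zero)
        n_lab = max(mesh.label_names) + 1
        kvec = np.zeros(n_lab, dtype=dtype)
        for lid in range(n_lab):
            region = mesh.label_names.get(lid)
            if region is None:
                continue
            try:
                props = table.lookup_region(region, spec.frequency)
            except (KeyError, ValueError) as exc:
                raise KeyError(
                    f"no dielectric properties for region {region!r} at "
                    f"{spec.frequency:g} Hz: {exc}") from exc
            kvec[lid] = admittivity(props, spec.mode)
        kappa = mesh.region_fractions.astype(dtype) @ kvec
    else:
        kappa = np.array([kappa_of_label[int(l)] for l in mesh.tet_labels],
                         dtype=dtype)

    grad, vol = _element_gradients(mesh)
    # element stiffness kappa * vol * G G^T, assembled in condensed dofs
    Ke = np.einsum("m,mik,mjk->mij", kappa * vol, grad, grad)

    dof_of_node, electrode_dofs = _condensed_dofs(mesh)
    rows = dof_of_node[mesh.tets][:, :, None].repeat(4, axis=2)
    cols = dof_of_node[mesh.tets][:, None, :].repeat(4, axis=1)
    n = int(dof_of_node.max()) + 1
    K = sp.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())),
                      shape=(n, n)).tocsr()
    return LinearSystem(mesh=mesh, spec=spec, K=K, kappa=kappa,
                        dof_of_node=dof_of_node,
                        electrode_dofs=electrode_dofs, grad=grad)


def _condensed_dofs(mesh: TetMesh) -> tuple[np.ndarray, dict[str, int]]:
    n_nodes = mesh.n_nodes
    patch_of_node = np.full(n_nodes, -1, dtype=np.int64)
    names = [name for _, name in sorted(mesh.patch_names.items())
             if name.startswith("electrode_")]
    for k, name in enumerate(names):
        patch_of_node[mesh.patch_nodes(name)] = k
    free = patch_of_node < 0
    dof = np.empty(n_nodes, dtype=np.int64)
    dof[free] = np.arange(int(free.sum()))
    n_free = int(free.sum())
    electrode_dofs = {}
    for k, name in enumerate(names):
        dof[patch_of_node == k] = n_free + k
        electrode_dofs[name] = n_free + k
    return dof, electrode_dofs


# systems at most this large use the sparse direct factorization on the
# "auto" path; larger ones use Jacobi-preconditioned Krylov iterations,
# whose setup cost scales far better for 3-D stiffness matrices
_AUTO_DIRECT_LIMIT = 30_000


def _factorize(system: LinearSystem, ground_dof: int):
    cache = system._factor_cache
    if ground_dof not in cache:
        n = system.n_dofs
        keep = np.arange(n) != ground_dof
        Kg = system.K[keep][:, keep].tocsc()
        method = system.spec.solver
        if method == "auto":
            method = "direct" if n <= _AUTO_DIRECT_LIMIT else "iterative"
        if method == "direct":
            lu = spla.splu(Kg)
            solve = lu.solve
        else:
            diag = Kg.diagonal()
            M = spla.LinearOperator(Kg.shape, lambda x: x / diag,
                                    dtype=Kg.dtype)
            krylov = spla.cg if not np.iscomplexobj(Kg.data) else \
                spla.bicgstab

            def solve(b, _Kg=Kg, _M=M, _krylov=krylov):
                x, info = _krylov(_Kg, b, M=_M,
                                  rtol=system.spec.rel_tolerance,
                                  maxiter=50_000)
                res = np.linalg.norm(_Kg @ x - b) / np.linalg.norm(b)
                if info != 0:
                    raise SolverError(
                        f"iterative solver did not reach rtol="
                        f"{system.spec.rel_tolerance:g} "
                        f"(info={info}, residual={res:.3e})")
                return x
        cache[ground_dof] = (keep, solve)
    return cache[ground_dof]


def solve_injection(system: LinearSystem, source: str, sink: str,
                    ground: str | None = None) -> FieldSolution:
    """Solve one terminal injection: +I0 into ``source``, -I0 out of ``sink``.

    ``ground`` selects which electrode patch is fixed at 0 V during the
    solve (default: the sink); the returned potential is always shifted so
    the sink patch reads exactly 0 V.  Electrodes other than source and sink
    are floating equipotentials with zero net current.
    """
    spec = system.spec
    for name in (source, sink):
        if name not in system.electrode_dofs:
            raise KeyError(f"no electrode patch named {name!r}")
    if source == sink:
        raise ValueError("source and sink must differ")
    ground = ground or sink
    gdof = system.electrode_dofs[ground]
    keep, solve = _factorize(system, gdof)
    dtype = complex if spec.mode == "complex" else float
    f = np.zeros(system.n_dofs, dtype=dtype)
    f[system.electrode_dofs[source]] += spec.I0
    f[system.electrode_dofs[sink]] -= spec.I0
    fg = f[keep]
    xg = solve(fg)
    x = np.zeros(system.n_dofs, dtype=dtype)
    x[keep] = xg
    residual = float(np.linalg.norm(system.K[keep][:, keep] @ xg - fg)
                     / max(np.linalg.norm(fg), 1e-300))
    # consistent patch currents from the full (un-grounded) operator
    r = system.K @ x
    patch_currents = {name: r[dof]
                      for name, dof in system.electrode_dofs.items()}
    x = x - x[system.electrode_dofs[sink]]
    V = x[system.dof_of_node]
    gradV = np.einsum("mi,mik->mk", V[system.mesh.tets], system.grad)
    J = -system.kappa[:, None] * gradV
    pots = {name: x[dof] for name, dof in system.electrode_dofs.items()}
    return FieldSolution(mesh=system.mesh, spec=spec, source=source,
                         sink=sink, V=V, J=J, electrode_potentials=pots,
                         patch_currents=patch_currents, residual=residual,
                         system=system)


def surface_patch_currents(sol: FieldSolution) -> dict[str, float | complex]:
    """Raw surface integrals of J.n over each boundary patch.

    Unlike the consistent residual fluxes these use the one-sided element
    current density, so they carry the discretization error of the normal
    flux; they quantify mesh quality rather than the terminal constraint.
    """
    mesh = sol.mesh
    tri = mesh.nodes[mesh.boundary_faces]
    normal = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    # orient outward: away from the owning element centroid
    owner_cent = mesh.nodes[mesh.tets[mesh.face_owners]].mean(axis=1)
    outward = np.einsum("ij,ij->i", tri.mean(axis=1) - owner_cent, normal)
    normal[outward < 0] *= -1.0
    Jface = sol.J[mesh.face_owners]
    flux = np.einsum("ij,ij->i", Jface, normal.astype(Jface.dtype)) \
        if np.iscomplexobj(Jface) else np.einsum("ij,ij->i", Jface, normal)
    out: dict[str, float | complex] = {}
    for pid, name in mesh.patch_names.items():
        # sign convention: positive = current injected into the domain,
        # matching the consistent terminal currents
        out[name] = -flux[mesh.face_labels == pid].sum()
    return out


def check_current_conservation(sol: FieldSolution,
                               tol: float = 0.005) -> dict:
    """Report terminal and boundary fluxes; pass/fail at ``tol`` * I0.

    The consistent (residual-based) patch currents express the discrete
    terminal constraint; the surface-integral fluxes are reported alongside
    as a discretization-quality indicator.
    """
    I0 = sol.spec.I0
    consistent = {k: complex(v) if np.iscomplexobj(np.asarray(v)) else float(v)
                  for k, v in sol.patch_currents.items()}
    surface = surface_patch_currents(sol)
    total = sum(consistent.values())
    checks = {
        "source_current_ok":
            abs(consistent[sol.source] - I0) <= tol * I0,
        "sink_current_ok":
            abs(consistent[sol.sink] + I0) <= tol * I0,
        "floating_currents_ok": all(
            abs(consistent[name]) <= tol * I0
            for name in consistent if name not in (sol.source, sol.sink)),
        "total_balance_ok": abs(total) <= tol * I0,
    }
    return {
        "I0": I0,
        "tolerance": tol,
        "consistent_patch_currents": consistent,
        "surface_patch_currents": surface,
        "total_consistent_current": total,
        "residual": sol.residual,
        "passed": all(checks.values()),
        **checks,
    }
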