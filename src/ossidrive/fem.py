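"""Piezoelectric finite-element model of the multilayer stack actuator.

The actuator is a brick of n poled ceramic layers, mechanically in series and
electrically in parallel: electrodes sit at every layer interface, alternate
interfaces share a terminal, and the poling direction alternates layer to
layer so all layers expand together under one terminal voltage.

Discretisation: 8-node trilinear hexahedra, 2x2x2 Gauss quadrature, three
mechanical DOFs plus one electric-potential DOF per node.  The coupled
equations of motion in block form are::

    [Muu 0] [U..]   [Cuu 0] [U.]   [Kuu   Kup ] [U  ]   [ F]
    [0   0] [P..] + [0   0] [P.] + [Kup^T -Kpp] [Phi] = [-Q]

with Kuu = int Bu^T c Bu, Kup = int Bu^T e^T G, Kpp = int G^T eps G
(G the potential-gradient operator, E = -G Phi), Muu = rho int N^T N, and
stiffness-proportional damping Cuu = beta * Kuu.  Kpp is stored positive
definite; the assembled operator is symmetric indefinite.  Q is the nodal
free charge, so the charge drawn from the driven terminal falls out of the
constraint reactions with its physical sign.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import PiezoConstitutive

#: Safety ceiling on the drive voltage (V RMS); exceeding it warns.
VOLTAGE_LIMIT_RMS = 10.5

# 2x2x2 Gauss points/weights on [-1, 1]^3
_GP = 1.0 / np.sqrt(3.0)
_GAUSS = [(-_GP, -_GP, -_GP), (_GP, -_GP, -_GP), (_GP, _GP, -_GP),
          (-_GP, _GP, -_GP), (-_GP, -_GP, _GP), (_GP, -_GP, _GP),
          (_GP, _GP, _GP), (-_GP, _GP, _GP)]

# natural coordinates of the 8 hex nodes (bottom face CCW, then top face)
_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def default_frequency_grid(n: int = 40, f_lo: float = 160.0,
                           f_hi: float = 8000.0) -> np.ndarray:
    """Log-spaced harmonic-analysis grid over the audiometric band, Hz."""
    return np.geomspace(f_lo, f_hi, n)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackSpec:
    """Geometry and refinement of the multilayer stack.

    Defaults are the designed device: 50 layers of 0.04 mm (2 mm total) on a
    2 x 2 mm cross section.
    """

    n_layers: int = 50
    layer_thickness: float = 0.04e-3
    width: float = 2.0e-3
    depth: float = 2.0e-3
    nx: int = 1
    ny: int = 1
    nz_per_layer: int = 1

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.layer_thickness <= 0 or self.width <= 0 or self.depth <= 0:
            raise ValueError("geometry must be positive")
        if min(self.nx, self.ny, self.nz_per_layer) < 1:
            raise ValueError("subdivision counts must be >= 1")

    @property
    def total_thickness(self) -> float:
        return self.n_layers * self.layer_thickness

    @property
    def cross_section_area(self) -> float:
        return self.width * self.depth


@dataclass
class StackMesh:
    """Structured hexahedral mesh of the stack with electrode node sets."""

    spec: StackSpec
    nodes: np.ndarray                 # (N, 3) coordinates, m
    elements: np.ndarray              # (E, 8) node indices
    elem_layer: np.ndarray            # (E,) physical layer of each element
    poling: np.ndarray                # (E,) +-1 poling sign
    electrode_sets: list[np.ndarray]  # n_layers+1 interface node sets

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def face_nodes(self, face: str) -> np.ndarray:
        """Node indices on one of the faces 'bottom'/'top'/'x0'/'x1'/'y0'/'y1'."""
        x, y, z = self.nodes.T
        tol = 1e-12
        lims = {
            "bottom": z < tol, "top": z > self.spec.total_thickness - tol,
            "x0": x < tol, "x1": x > self.spec.width - tol,
            "y0": y < tol, "y1": y > self.spec.depth - tol,
        }
        if face not in lims:
            raise ValueError(f"unknown face {face!r}")
        return np.nonzero(lims[face])[0]


def mesh_stack(spec: StackSpec) -> StackMesh:
    """Structured hex mesh with one node grid shared by all layers.

    Poling alternates with layer parity and is phased against the alternating
    terminal assignment (even interfaces grounded, odd driven) so a positive
    terminal voltage elongates every layer.
    """
    nx, ny = spec.nx, spec.ny
    nz = spec.n_layers * spec.nz_per_layer
    xs = np.linspace(0.0, spec.width, nx + 1)
    ys = np.linspace(0.0, spec.depth, ny + 1)
    zs = np.linspace(0.0, spec.total_thickness, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    # node index = (k*(ny+1) + j)*(nx+1) + i
    nodes = np.column_stack([
        np.transpose(X, (2, 1, 0)).ravel(),
        np.transpose(Y, (2, 1, 0)).ravel(),
        np.transpose(Z, (2, 1, 0)).ravel(),
    ])

    def nid(i: int, j: int, k: int) -> int:
        return (k * (ny + 1) + j) * (nx + 1) + i

    elements = []
    elem_layer = []
    for k in range(nz):
        layer = k // spec.nz_per_layer
        for j in range(ny):
            for i in range(nx):
                elements.append([
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
                elem_layer.append(layer)
    elements = np.asarray(elements, dtype=np.int64)
    elem_layer = np.asarray(elem_layer, dtype=np.int64)
    poling = np.where(elem_layer % 2 == 0, -1.0, 1.0)

    electrode_sets = []
    for l in range(spec.n_layers + 1):
        k = l * spec.nz_per_layer
        ids = [nid(i, j, k) for j in range(ny + 1) for i in range(nx + 1)]
        electrode_sets.append(np.asarray(ids, dtype=np.int64))

    return StackMesh(spec=spec, nodes=nodes, elements=elements,
                     elem_layer=elem_layer, poling=poling,
                     electrode_sets=electrode_sets)


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _shape_gradients(coords: np.ndarray, xi: float, eta: float, zeta: float):
    """Shape values, cartesian gradients (3,8) and Jacobian determinant."""
    rel = np.array([xi, eta, zeta])
    N = np.prod(1.0 + _XI * rel, axis=1) / 8.0
    dN = np.empty((8, 3))
    for a in range(8):
        xa = _XI[a]
        dN[a, 0] = xa[0] * (1 + xa[1] * eta) * (1 + xa[2] * zeta) / 8.0
        dN[a, 1] = xa[1] * (1 + xa[0] * xi) * (1 + xa[2] * zeta) / 8.0
        dN[a, 2] = xa[2] * (1 + xa[0] * xi) * (1 + xa[1] * eta) / 8.0
    J = dN.T @ coords            # (3,3): dx/dxi etc.
    detJ = np.linalg.det(J)
    if detJ <= 0:
        raise ValueError("non-positive Jacobian: degenerate element geometry")
    dNdx = np.linalg.solve(J.T, dN.T)   # (3, 8) cartesian gradients
    return N, dNdx, detJ


def element_matrices(coords: np.ndarray, mat: PiezoConstitutive,
                     poling: float = 1.0):
    """Element Kuu (24x24), Kup (24x8), Kpp (8x8), Muu (24x24).

    ``poling`` (+-1) flips the piezoelectric coupling only; stiffness,
    dielectric and mass blocks are insensitive to poling direction for a
    transversely isotropic ceramic.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (8, 3):
        raise ValueError("coords must be (8, 3)")
    e_eff = poling * mat.e
    Kuu = np.zeros((24, 24))
    Kup = np.zeros((24, 8))
    Kpp = np.zeros((8, 8))
    Muu = np.zeros((24, 24))
    for (xi, eta, zeta) in _GAUSS:
        N, dNdx, detJ = _shape_gradients(coords, xi, eta, zeta)
        Bu = np.zeros((6, 24))
        for a in range(8):
            dx, dy, dz = dNdx[:, a]
            c = 3 * a
            Bu[0, c] = dx
            Bu[1, c + 1] = dy
            Bu[2, c + 2] = dz
            Bu[3, c + 1] = dz
            Bu[3, c + 2] = dy
            Bu[4, c] = dz
            Bu[4, c + 2] = dx
            Bu[5, c] = dy
            Bu[5, c + 1] = dx
        G = dNdx                       # (3, 8); E = -G Phi
        Nmat = np.zeros((3, 24))
        Nmat[0, 0::3] = N
        Nmat[1, 1::3] = N
        Nmat[2, 2::3] = N
        Kuu += detJ * (Bu.T @ mat.cE @ Bu)
        Kup += detJ * (Bu.T @ e_eff.T @ G)
        Kpp += detJ * (G.T @ mat.epsS @ G)
        Muu += detJ * mat.rho * (Nmat.T @ Nmat)
    return Kuu, Kup, Kpp, Muu


# ---------------------------------------------------------------------------
# constraints (shared by the stack solver and the coupled model)
# ---------------------------------------------------------------------------

class Constraints:
    """Ties (equal-DOF groups) and prescribed values over a DOF vector.

    Builds the reduction ``u_full = T u_red + g``: tied DOFs collapse onto a
    group representative, prescribed groups drop out of the reduced system and
    enter through ``g``.
    """

    def __init__(self, ndof: int) -> None:
        self.ndof = ndof
        self._parent = np.arange(ndof)
        self._value: dict[int, float] = {}

    def _root(self, i: int) -> int:
        while self._parent[i] != i:
            self._parent[i] = self._parent[self._parent[i]]
            i = self._parent[i]
        return i

    def tie(self, dofs) -> None:
        dofs = np.atleast_1d(np.asarray(dofs, dtype=np.int64))
        if dofs.size < 2:
            return
        r0 = self._root(int(dofs[0]))
        for d in dofs[1:]:
            r = self._root(int(d))
            if r != r0:
                self._parent[r] = r0

    def fix(self, dofs, value: float = 0.0) -> None:
        for d in np.atleast_1d(np.asarray(dofs, dtype=np.int64)):
            r = self._root(int(d))
            old = self._value.get(r)
            if old is not None and not np.isclose(old, value):
                raise ValueError(
                    f"conflicting prescribed values on tied DOF group: "
                    f"{old} vs {value}")
            self._value[r] = float(value)

    def build(self):
        roots = np.fromiter((self._root(i) for i in range(self.ndof)),
                            dtype=np.int64, count=self.ndof)
        # consolidate prescribed values onto final roots
        values: dict[int, float] = {}
        for r, v in self._value.items():
            rr = self._root(r)
            if rr in values and not np.isclose(values[rr], v):
                raise ValueError("conflicting prescribed values after union")
            values[rr] = v
        free_roots = sorted(set(roots) - set(values))
        red_index = {r: k for k, r in enumerate(free_roots)}
        g = np.zeros(self.ndof)
        rows, cols = [], []
        for i in range(self.ndof):
            r = roots[i]
            if r in values:
                g[i] = values[r]
            else:
                rows.append(i)
                cols.append(red_index[r])
        T = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(self.ndof, len(free_roots)))
        return T, g

    def prescribed_dofs(self) -> np.ndarray:
        roots = np.fromiter((self._root(i) for i in range(self.ndof)),
                            dtype=np.int64, count=self.ndof)
        fixed_roots = {self._root(r) for r in self._value}
        return np.nonzero(np.isin(roots, list(fixed_roots)))[0]


def constrained_solve(A: sp.spmatrix, b: np.ndarray, T: sp.csr_matrix,
                      g: np.ndarray) -> np.ndarray:
    """Solve A u = b + r subject to u = T u_red + g (r = constraint forces)."""
    A = A.tocsc()
    rhs = T.T @ (b - A @ g)
    Ared = (T.T @ A @ T).tocsc()
    if Ared.shape[0] == 0:
        return np.asarray(g, dtype=b.dtype)
    try:
        lu = spla.splu(Ared)
    except RuntimeError as exc:
        raise np.linalg.LinAlgError(
            "constrained system is singular; unconstrained rigid-body or "
            "floating-potential modes remain") from exc
    ured = lu.solve(rhs)
    resid = np.linalg.norm(Ared @ ured - rhs)
    scale = max(np.linalg.norm(rhs), 1e-300)
    if not np.all(np.isfinite(ured)) or resid > 1e-7 * scale:
        raise np.linalg.LinAlgError(
            "constrained solve failed (large residual); system is singular "
            "or severely ill-conditioned")
    return T @ ured + g


# ---------------------------------------------------------------------------
# assembled system and solvers
# ---------------------------------------------------------------------------

@dataclass
class AssembledSystem:
    """Assembled coupled blocks of the stack plus constraint bookkeeping.

    DOF layout: mechanical DOFs ``3*node + comp`` for comp in (x, y, z),
    then one potential DOF per node at ``3*n_nodes + node``.
    """

    mesh: StackMesh
    mat: PiezoConstitutive
    beta: float
    Muu: sp.csr_matrix
    Cuu: sp.csr_matrix
    Kuu: sp.csr_matrix
    Kuphi: sp.csr_matrix
    Kphiphi: sp.csr_matrix
    constraints: Constraints = field(default=None)  # type: ignore[assignment]
    drive_voltage: float | None = None
    driven_sets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.constraints is None:
            self.constraints = Constraints(self.ndof)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def ndof_mech(self) -> int:
        return 3 * self.n_nodes

    @property
    def ndof(self) -> int:
        return 4 * self.n_nodes

    # DOF helpers -----------------------------------------------------------
    def mech_dofs(self, nodes, comp: int | None = None) -> np.ndarray:
        nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
        if comp is None:
            return (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()
        return 3 * nodes + comp

    def elec_dofs(self, nodes) -> np.ndarray:
        return self.ndof_mech + np.atleast_1d(np.asarray(nodes, dtype=np.int64))

    # full operators --------------------------------------------------------
    def stiffness_operator(self) -> sp.csr_matrix:
        """Symmetric indefinite coupled operator [[Kuu, Kup], [Kup^T, -Kpp]]."""
        return sp.bmat([[self.Kuu, self.Kuphi],
                        [self.Kuphi.T, -self.Kphiphi]], format="csr")

    def mass_operator(self) -> sp.csr_matrix:
        n_e = self.n_nodes
        return sp.bmat([[self.Muu, None],
                        [None, sp.csr_matrix((n_e, n_e))]], format="csr")

    def damping_operator(self) -> sp.csr_matrix:
        n_e = self.n_nodes
        return sp.bmat([[self.Cuu, None],
                        [None, sp.csr_matrix((n_e, n_e))]], format="csr")

    def copy(self) -> "AssembledSystem":
        return copy.deepcopy(self)

    # common supports -------------------------------------------------------
    def fix_base(self) -> None:
        """Clamp all mechanical DOFs on the bottom face (mastoid anchor)."""
        self.constraints.fix(self.mech_dofs(self.mesh.face_nodes("bottom")))

    def minimal_supports(self) -> None:
        """Statically determinate 3-2-1 mounts: removes the 6 rigid modes
        without restraining any uniform deformation (free-stroke boundary)."""
        mesh = self.mesh
        bottom = mesh.face_nodes("bottom")
        xy = mesh.nodes[bottom][:, :2]
        origin = bottom[np.argmin(xy[:, 0] + xy[:, 1])]
        corner_x = bottom[np.argmax(xy[:, 0] - xy[:, 1])]
        corner_y = bottom[np.argmax(xy[:, 1] - xy[:, 0])]
        self.constraints.fix(self.mech_dofs(origin))           # x, y, z
        self.constraints.fix(self.mech_dofs(corner_x, 1))      # y
        self.constraints.fix(self.mech_dofs(corner_x, 2))      # z
        self.constraints.fix(self.mech_dofs(corner_y, 2))      # z

    def blocked_supports(self) -> None:
        """Uniform-field clamp: every mechanical DOF fixed (base fixed, tip
        blocked, lateral faces held); the blocked-force oracle boundary."""
        self.constraints.fix(np.arange(self.ndof_mech))


def assemble(mesh: StackMesh, mat: PiezoConstitutive,
             beta: float = 1.0e-4) -> AssembledSystem:
    """Assemble the global sparse blocks; Cuu = beta * Kuu."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    n = mesh.n_nodes
    rows_uu, cols_uu, vals_k, vals_m = [], [], [], []
    rows_up, cols_up, vals_up = [], [], []
    rows_pp, cols_pp, vals_pp = [], [], []
    for el in range(mesh.elements.shape[0]):
        conn = mesh.elements[el]
        coords = mesh.nodes[conn]
        Ke, Kupe, Kppe, Me = element_matrices(coords, mat,
                                              poling=mesh.poling[el])
        mdofs = (3 * conn[:, None] + np.arange(3)[None, :]).ravel()
        r, c = np.meshgrid(mdofs, mdofs, indexing="ij")
        rows_uu.append(r.ravel())
        cols_uu.append(c.ravel())
        vals_k.append(Ke.ravel())
        vals_m.append(Me.ravel())
        r, c = np.meshgrid(mdofs, conn, indexing="ij")
        rows_up.append(r.ravel())
        cols_up.append(c.ravel())
        vals_up.append(Kupe.ravel())
        r, c = np.meshgrid(conn, conn, indexing="ij")
        rows_pp.append(r.ravel())
        cols_pp.append(c.ravel())
        vals_pp.append(Kppe.ravel())

    def _csr(rows, cols, vals, shape):
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=shape)

    Kuu = _csr(rows_uu, cols_uu, vals_k, (3 * n, 3 * n))
    Muu = _csr(rows_uu, cols_uu, vals_m, (3 * n, 3 * n))
    Kuphi = _csr(rows_up, cols_up, vals_up, (3 * n, n))
    Kphiphi = _csr(rows_pp, cols_pp, vals_pp, (n, n))
    return AssembledSystem(mesh=mesh, mat=mat, beta=beta, Muu=Muu,
                           Cuu=beta * Kuu, Kuu=Kuu, Kuphi=Kuphi,
                           Kphiphi=Kphiphi)


def apply_electrodes(system: AssembledSystem, v_drive: float) -> AssembledSystem:
    """Tie each interface node set equipotential and set alternating
    terminals: even interfaces grounded, odd interfaces at ``v_drive``.

    Warns (does not fail) above the 10.5 V RMS safety ceiling.
    """
    sets = system.mesh.electrode_sets
    seen: set[int] = set()
    for s in sets:
        overlap = seen.intersection(s.tolist())
        if overlap:
            raise ValueError(f"electrode sets overlap on nodes {sorted(overlap)}")
        seen.update(s.tolist())
    if v_drive > VOLTAGE_LIMIT_RMS:
        warnings.warn(
            f"drive voltage {v_drive} V RMS exceeds the {VOLTAGE_LIMIT_RMS} V "
            "RMS safety limit", UserWarning, stacklevel=2)
    system.driven_sets = []
    for i, s in enumerate(sets):
        dofs = system.elec_dofs(s)
        system.constraints.tie(dofs)
        pot = v_drive if i % 2 == 1 else 0.0
        system.constraints.fix(dofs[0], pot)
        if i % 2 == 1:
            system.driven_sets.append(i)
    system.drive_voltage = float(v_drive)
    return system


@dataclass
class StaticResult:
    """Static coupled solution with charge and reaction recovery."""

    system: AssembledSystem
    u: np.ndarray            # full DOF vector (mech then potential)
    reactions: np.ndarray    # A u - b on the full DOF vector

    @property
    def displacements(self) -> np.ndarray:
        return self.u[:self.system.ndof_mech].reshape(-1, 3)

    @property
    def potentials(self) -> np.ndarray:
        return self.u[self.system.ndof_mech:]

    def elongation(self) -> float:
        """Mean tip minus mean base axial displacement, m."""
        mesh = self.system.mesh
        d = self.displacements
        return float(d[mesh.face_nodes("top"), 2].mean()
                     - d[mesh.face_nodes("bottom"), 2].mean())

    def face_reaction(self, face: str, comp: int = 2) -> float:
        """Total mechanical constraint reaction on a face, N."""
        dofs = self.system.mech_dofs(self.system.mesh.face_nodes(face), comp)
        return float(self.reactions[dofs].sum())

    def blocked_force(self) -> float:
        """Axial force the stack exerts on a blocking tip support, N
        (the negative of the tip constraint reaction)."""
        return -self.face_reaction("top", 2)

    def terminal_charge(self) -> float:
        """Free charge drawn from the driven terminal, C.

        The electric block rows carry -Q, so Q = -(A u - b) summed over the
        driven electrode potential DOFs.
        """
        q = 0.0
        for i in self.system.driven_sets:
            dofs = self.system.elec_dofs(self.system.mesh.electrode_sets[i])
            q -= self.reactions[dofs].sum()
        return float(q)


def solve_static(system: AssembledSystem,
                 f_ext: np.ndarray | None = None) -> StaticResult:
    """Static coupled solve under the system's current constraints."""
    A = system.stiffness_operator()
    b = np.zeros(system.ndof) if f_ext is None else np.asarray(f_ext, float)
    T, g = system.constraints.build()
    u = constrained_solve(A, b, T, g)
    reactions = A @ u - b
    return StaticResult(system=system, u=u, reactions=reactions)


@dataclass
class HarmonicSweepResult:
    """Complex frequency-domain solutions of the coupled system."""

    system: AssembledSystem
    frequencies: np.ndarray
    U: np.ndarray              # (nf, ndof) complex full solutions
    reactions: np.ndarray      # (nf, ndof) complex A(w) u - b

    @property
    def displacements(self) -> np.ndarray:
        nm = self.system.ndof_mech
        return self.U[:, :nm].reshape(len(self.frequencies), -1, 3)

    def probe_displacement(self, node: int, comp: int = 2) -> np.ndarray:
        """Complex displacement spectrum at one node/component, m."""
        return self.U[:, 3 * node + comp]

    def elongation_spectrum(self) -> np.ndarray:
        mesh = self.system.mesh
        d = self.displacements
        return (d[:, mesh.face_nodes("top"), 2].mean(axis=1)
                - d[:, mesh.face_nodes("bottom"), 2].mean(axis=1))

    def terminal_charge(self) -> np.ndarray:
        """Complex charge phasor drawn from the driven terminal, C."""
        q = np.zeros(len(self.frequencies), dtype=complex)
        for i in self.system.driven_sets:
            dofs = self.system.elec_dofs(self.system.mesh.electrode_sets[i])
            q -= self.reactions[:, dofs].sum(axis=1)
        return q

    def terminal_current(self) -> np.ndarray:
        """Complex current phasor I = j*omega*Q, A (RMS if drive is RMS)."""
        return 1j * 2 * np.pi * self.frequencies * self.terminal_charge()


def solve_harmonic(system: AssembledSystem, frequencies,
                   f_ext: np.ndarray | None = None) -> HarmonicSweepResult:
    """Per-frequency complex solve of (-w^2 M + j w C + K) u = b.

    The drive (voltage or force) is held at its phasor amplitude at every
    frequency; with RMS drive the response magnitudes are RMS.
    """
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(frequencies <= 0):
        raise ValueError("frequencies must be positive")
    K = system.stiffness_operator().tocsc()
    M = system.mass_operator().tocsc()
    C = system.damping_operator().tocsc()
    b = np.zeros(system.ndof) if f_ext is None else np.asarray(f_ext, float)
    T, g = system.constraints.build()
    Tc = T.astype(complex)
    gc = g.astype(complex)
    bc = b.astype(complex)
    U = np.empty((len(frequencies), system.ndof), dtype=complex)
    R = np.empty_like(U)
    for k, f in enumerate(frequencies):
        w = 2 * np.pi * f
        A = (K + 1j * w * C - (w * w) * M).tocsc()
        try:
            u = constrained_solve(A, bc, Tc, gc)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"harmonic solve singular at {f:.6g} Hz; an undamped "
                "resonance was hit — add stiffness-proportional damping "
                "(beta > 0)") from exc
        U[k] = u
        R[k] = A @ u - bc
    return HarmonicSweepResult(system=system, frequencies=frequencies,
                               U=U, reactions=R)


def model_capacitance(system: AssembledSystem,
                      v_probe: float = 1.0) -> dict[str, float]:
    """Terminal capacitance from static solves, F.

    ``clamped``: every mechanical DOF held (strain-free) — the epsilon^S
    parallel-plate value, n layers electrically in parallel.
    ``free``: minimal kinematic supports only — the effective constant-stress
    (epsilon^T-like) value, larger whenever the coupling e is nonzero.
    """
    if not system.driven_sets:
        raise ValueError("apply_electrodes before model_capacitance")
    out: dict[str, float] = {}
    for mode in ("clamped", "free"):
        s = system.copy()
        # rebuild constraints so support choices don't accumulate
        s.constraints = Constraints(s.ndof)
        apply_electrodes(s, v_probe)
        if mode == "clamped":
            s.blocked_supports()
        else:
            s.minimal_supports()
        res = solve_static(s)
        out[mode] = res.terminal_charge() / v_probe
    return out
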