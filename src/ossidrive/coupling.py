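"""Coupling of the piezostack actuator to the middle-ear surrogate.

The stack base is mechanically grounded (mastoid anchor); the stack tip
drives the incus body either through a short coupling rod (0.5 mm diameter,
2.0 mm long, six axial elements by default) or through a rigid direct tie.
The rod is reduced to axial bars because the surrogate ear is a piston
chain — there is no transverse DOF for a bending beam to act on; the
element count of the reference design is kept.

Two design studies run on the coupled model:

* layer-number study — stroke (and hence equivalent SPL) versus the number
  of layers n at fixed total stack thickness and fixed RMS voltage; stroke
  scales like n * d33 * V well below resonance.
* rod-stiffness study — insertion loss Delta-H of the flexible rod versus
  its Young's modulus (titanium 116 GPa vs ceramic 510 GPa), measured
  against the rigid-tie response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import fem
from .fem import (AssembledSystem, Constraints, StackSpec, constrained_solve,
                  default_frequency_grid)
from .middle_ear import MiddleEarNetwork, acoustic_drive, build_default_network
from .metrics import equivalent_spl, rod_effect_db


@dataclass(frozen=True)
class RodSpec:
    """Coupling-rod geometry and material (defaults: titanium variant)."""

    diameter: float = 0.5e-3
    length: float = 2.0e-3
    youngs_modulus: float = 116e9
    density: float = 4500.0
    n_elements: int = 6

    def __post_init__(self) -> None:
        if min(self.diameter, self.length, self.youngs_modulus,
               self.density) <= 0:
            raise ValueError("rod parameters must be positive")
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")

    @property
    def area(self) -> float:
        return np.pi * self.diameter ** 2 / 4.0

    @property
    def axial_stiffness(self) -> float:
        """Static tip stiffness E*A/L of the whole chain, N/m."""
        return self.youngs_modulus * self.area / self.length


@dataclass
class RodChain:
    """Assembled axial bar chain: (n+1) DOFs, consistent mass."""

    spec: RodSpec
    K: np.ndarray
    M: np.ndarray

    @property
    def ndof(self) -> int:
        return self.spec.n_elements + 1


def build_rod(spec: RodSpec) -> RodChain:
    """Chain of n axial two-node bars, each EA/Le stiff, consistent mass."""
    n = spec.n_elements
    Le = spec.length / n
    ke = spec.youngs_modulus * spec.area / Le
    me = spec.density * spec.area * Le / 6.0
    K = np.zeros((n + 1, n + 1))
    M = np.zeros((n + 1, n + 1))
    for e in range(n):
        K[e:e + 2, e:e + 2] += ke * np.array([[1.0, -1.0], [-1.0, 1.0]])
        M[e:e + 2, e:e + 2] += me * np.array([[2.0, 1.0], [1.0, 2.0]])
    return RodChain(spec=spec, K=K, M=M)


@dataclass
class CoupledModel:
    """Stack + (rod) + middle-ear network assembled on one DOF vector.

    Layout: stack DOFs first (mechanical then potential, as in
    :class:`~ossidrive.fem.AssembledSystem`), then rod axial DOFs, then the
    four network DOFs.  The junctions are rigid ties; 'without rod' ties the
    stack tip directly to the incus DOF so both cases share one topology.
    """

    stack: AssembledSystem
    network: MiddleEarNetwork
    rod: RodChain | None
    with_rod: bool
    M: sp.csr_matrix
    C: sp.csr_matrix
    K: sp.csr_matrix
    constraints: Constraints
    rod_offset: int          # first rod DOF (== network offset when no rod)
    network_offset: int

    @property
    def ndof(self) -> int:
        return self.K.shape[0]

    @property
    def stapes_dof(self) -> int:
        return self.network_offset + self.network.probe_port

    @property
    def incus_dof(self) -> int:
        return self.network_offset + self.network.attach_port


def couple(stack_system: AssembledSystem, rod: RodChain | None,
           network: MiddleEarNetwork, with_rod: bool = True) -> CoupledModel:
    """Join the parts; the stack base is fixed and the tip drives the incus.

    ``with_rod=False`` ignores the rod argument and makes the tie rigid.
    """
    if with_rod and rod is None:
        raise ValueError("with_rod=True requires a rod")
    ns = stack_system.ndof
    n_rod = rod.ndof if (with_rod and rod is not None) else 0
    nn = network.ndof
    ndof = ns + n_rod + nn

    blocks_K = [stack_system.stiffness_operator()]
    blocks_M = [stack_system.mass_operator()]
    blocks_C = [stack_system.damping_operator()]
    if n_rod:
        beta = stack_system.beta
        blocks_K.append(sp.csr_matrix(rod.K))
        blocks_M.append(sp.csr_matrix(rod.M))
        blocks_C.append(sp.csr_matrix(beta * rod.K))
    blocks_K.append(sp.csr_matrix(network.K))
    blocks_M.append(sp.csr_matrix(network.M))
    blocks_C.append(sp.csr_matrix(network.C))

    K = sp.block_diag(blocks_K, format="csr")
    M = sp.block_diag(blocks_M, format="csr")
    C = sp.block_diag(blocks_C, format="csr")

    cons = Constraints(ndof)
    # carry over the stack's existing ties/prescriptions (electrodes)
    src = stack_system.constraints
    roots: dict[int, list[int]] = {}
    for i in range(stack_system.ndof):
        roots.setdefault(src._root(i), []).append(i)
    for group in roots.values():
        if len(group) > 1:
            cons.tie(group)
    for dof, value in src._value.items():
        cons.fix(dof, value)

    mesh = stack_system.mesh
    # mastoid anchor
    cons.fix(stack_system.mech_dofs(mesh.face_nodes("bottom")))
    # tip face moves as one in z (rigid end cap), tied to the rod / incus
    tip_z = stack_system.mech_dofs(mesh.face_nodes("top"), 2)
    rod_offset = ns
    network_offset = ns + n_rod
    incus_dof = network_offset + network.attach_port
    if n_rod:
        cons.tie(np.concatenate([tip_z, [rod_offset]]))
        cons.tie([rod_offset + n_rod - 1, incus_dof])
    else:
        cons.tie(np.concatenate([tip_z, [incus_dof]]))

    return CoupledModel(stack=stack_system, network=network,
                        rod=rod if with_rod else None, with_rod=with_rod,
                        M=M, C=C, K=K, constraints=cons,
                        rod_offset=rod_offset, network_offset=network_offset)


def build_coupled(stack_spec: StackSpec | None = None,
                  rod_spec: RodSpec | None = None,
                  network: MiddleEarNetwork | None = None,
                  v_rms: float = 10.5,
                  beta: float = 1.0e-4,
                  with_rod: bool = True) -> CoupledModel:
    """Convenience: mesh, assemble, electrode and couple in one call."""
    stack_spec = stack_spec or StackSpec()
    mesh = fem.mesh_stack(stack_spec)
    system = fem.assemble(mesh, fem_material(), beta=beta)
    fem.apply_electrodes(system, v_rms)
    rod = build_rod(rod_spec or RodSpec()) if with_rod else None
    network = network or build_default_network()
    return couple(system, rod, network, with_rod=with_rod)


def fem_material():
    from .materials import pzt4
    return pzt4()


def harmonic_response(model: CoupledModel, frequencies) -> np.ndarray:
    """Complex solutions (nf, ndof) of the coupled system, voltage-driven."""
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(frequencies <= 0):
        raise ValueError("frequencies must be positive")
    T, g = model.constraints.build()
    Tc = T.astype(complex)
    gc = g.astype(complex)
    b = np.zeros(model.ndof, dtype=complex)
    K = model.K.tocsc()
    M = model.M.tocsc()
    C = model.C.tocsc()
    out = np.empty((len(frequencies), model.ndof), dtype=complex)
    for k, f in enumerate(frequencies):
        w = 2 * np.pi * f
        A = (K + 1j * w * C - w * w * M).tocsc()
        out[k] = constrained_solve(A, b, Tc, gc)
    return out


def transducer_drive(model: CoupledModel, v_rms: float,
                     frequencies) -> np.ndarray:
    """Complex stapes displacement spectrum under voltage drive, m RMS.

    The model's electrodes were prescribed at build time; linearity lets the
    response be rescaled exactly to the requested ``v_rms``.
    """
    if v_rms <= 0:
        raise ValueError("zero drive: v_rms must be positive")
    built_v = model.stack.drive_voltage
    if not built_v:
        raise ValueError("stack has no electrode drive applied")
    sol = harmonic_response(model, frequencies)
    return sol[:, model.stapes_dof] * (v_rms / built_v)


def layer_number_study(layer_counts,
                       v_rms: float = 10.5,
                       spl_ref: float = 100.0,
                       total_thickness: float = 2.0e-3,
                       frequencies=None,
                       rod_spec: RodSpec | None = None,
                       network: MiddleEarNetwork | None = None,
                       with_rod: bool = True,
                       stack_kwargs: dict | None = None) -> pd.DataFrame:
    """Stroke and equivalent SPL versus layer count at fixed envelope.

    Each candidate n gets layer thickness total/n, the full coupled harmonic
    sweep at ``v_rms``, and the equivalent SPL against the acoustic baseline
    at ``spl_ref`` dB SPL.
    """
    layer_counts = list(layer_counts)
    if not layer_counts:
        raise ValueError("layer_counts must be nonempty")
    frequencies = (default_frequency_grid() if frequencies is None
                   else np.atleast_1d(np.asarray(frequencies, float)))
    network = network or build_default_network()
    d_ac = np.abs(acoustic_drive(network, spl_ref, frequencies))
    rows = []
    for n in layer_counts:
        spec = StackSpec(n_layers=int(n),
                         layer_thickness=total_thickness / int(n),
                         **(stack_kwargs or {}))
        model = build_coupled(stack_spec=spec, rod_spec=rod_spec,
                              network=network, v_rms=v_rms,
                              with_rod=with_rod)
        d_tr = np.abs(transducer_drive(model, v_rms, frequencies))
        peq = equivalent_spl(d_tr, d_ac, spl_ref=spl_ref)
        for f, dt, da, p in zip(frequencies, d_tr, d_ac, peq):
            rows.append({"n_layers": int(n), "frequency_hz": f,
                         "d_tr_m": dt, "d_ac_m": da, "peq_db": p})
    return pd.DataFrame(rows)


def rod_stiffness_study(rod_moduli,
                        stack_spec: StackSpec | None = None,
                        v_rms: float = 10.5,
                        frequencies=None,
                        network: MiddleEarNetwork | None = None,
                        rod_template: RodSpec | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rod insertion loss per Young's-modulus variant.

    Returns a per-frequency table of Delta-H (dB, 20*log10 convention,
    negative = drop) and a per-variant summary with the maximum drop
    magnitude and the frequency where it occurs.  The rigid reference d_tr
    ties the stack tip straight to the incus, same topology, rod removed.
    """
    rod_moduli = list(rod_moduli)
    if not rod_moduli:
        raise ValueError("at least one rod variant required")
    frequencies = (default_frequency_grid() if frequencies is None
                   else np.atleast_1d(np.asarray(frequencies, float)))
    stack_spec = stack_spec or StackSpec()
    network = network or build_default_network()
    template = rod_template or RodSpec()

    rigid = build_coupled(stack_spec=stack_spec, network=network,
                          v_rms=v_rms, with_rod=False)
    d_tr = np.abs(transducer_drive(rigid, v_rms, frequencies))

    spectra_rows = []
    summary_rows = []
    for E in rod_moduli:
        spec = replace(template, youngs_modulus=float(E))
        model = build_coupled(stack_spec=stack_spec, rod_spec=spec,
                              network=network, v_rms=v_rms, with_rod=True)
        d_rod = np.abs(transducer_drive(model, v_rms, frequencies))
        dh = rod_effect_db(d_rod, d_tr)
        i_max = int(np.argmin(dh))       # most negative = biggest drop
        for f, v in zip(frequencies, dh):
            spectra_rows.append({"rod_E_gpa": E / 1e9, "frequency_hz": f,
                                 "delta_h_db": v})
        summary_rows.append({"rod_E_gpa": E / 1e9,
                             "max_drop_db": float(-dh[i_max]),
                             "max_abs_dh_db": float(np.max(np.abs(dh))),
                             "at_frequency_hz": float(frequencies[i_max])})
    return pd.DataFrame(spectra_rows), pd.DataFrame(summary_rows)
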