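"""Lumped-parameter surrogate of the human middle ear.

A 4-DOF axial piston chain — eardrum, malleus, incus, stapes — stands in for
a full 3D ossicular-chain model.  Springs follow k = E*A/L with the moduli of
the published component tables (incudostapedial joint 4.00e6 N/m^2, stapedial
annulus ligament 4.10e5 N/m^2, ...) and documented assumed connector
geometry; masses are density times an assumed body volume.  The chain is
grounded at the tympanic annulus (eardrum) and the stapedial annulus
(stapes), carries Rayleigh damping C = alpha*M + beta*K, and sees the
cochlear fluid load as a dashpot on the stapes.

The surrogate reproduces the *structure* of middle-ear transmission — a
linear, passive, band-pass chain whose stapes response is linear in drive and
whose fundamental sits in the usual 0.5–1.5 kHz window — not the response
magnitudes of any individual temporal bone.
"""

from __future__ import annotations

import copy
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.linalg

#: Reference sound pressure, Pa (0 dB SPL).
P_REF = 20e-6

DOF_NAMES = ("eardrum", "malleus", "incus", "stapes")


def spl_to_pressure(spl_db: float) -> float:
    """RMS pressure for a sound pressure level re 20 uPa."""
    return P_REF * 10.0 ** (spl_db / 20.0)


@dataclass(frozen=True)
class Connector:
    """Elastic connector: spring constant k = E * area / length."""

    E: float       # Young's modulus, N/m^2
    area: float    # effective cross section, m^2
    length: float  # effective length, m

    @property
    def k(self) -> float:
        return self.E * self.area / self.length


@dataclass
class SurrogateConfig:
    """Assumed geometry and damping of the surrogate chain.

    Body volumes give anatomical-range ossicle masses with the tabulated
    densities (malleus ~25 mg, incus ~28 mg, stapes ~3 mg, eardrum effective
    moving mass ~6 mg).  Connector areas/lengths place the undamped
    fundamental in the 0.5–1.5 kHz middle-ear window.
    """

    # bodies: (density kg/m^3, volume m^3)
    body_density: dict[str, float] = field(default_factory=lambda: {
        "eardrum": 1.20e3,   # pars tensa
        "malleus": 2.55e3,   # malleus head
        "incus": 2.36e3,     # incus body
        "stapes": 2.20e3,
    })
    body_volume: dict[str, float] = field(default_factory=lambda: {
        "eardrum": 5.0e-9,
        "malleus": 9.8e-9,
        "incus": 1.19e-8,
        "stapes": 1.4e-9,
    })
    # serial connectors along the chain and grounding springs
    connectors: dict[str, Connector] = field(default_factory=lambda: {
        # eardrum (pars tensa) coupling onto the malleus handle
        "drum_malleus": Connector(E=1.00e7, area=1.0e-6, length=1.0e-3),
        # incudomalleolar joint (near-rigid ossicular bone/joint modulus)
        "malleus_incus": Connector(E=1.41e10, area=0.5e-6, length=0.5e-3),
        # incudostapedial joint
        "incus_stapes": Connector(E=4.00e6, area=0.5e-6, length=0.5e-3),
        # tympanic annulus ligament (eardrum to bony rim)
        "tympanic_annulus": Connector(E=4.00e5, area=1.0e-6, length=1.0e-3),
        # stapedial annulus ligament (footplate to oval window rim)
        "stapedial_annulus": Connector(E=4.10e5, area=1.0e-6, length=1.0e-3),
    })
    eardrum_area: float = 3.2e-5        # effective piston area, m^2
    alpha: float = 0.0                   # mass-proportional damping, 1/s
    beta: float = 1.0e-4                 # stiffness-proportional damping, s
    cochlear_damping: float = 0.05       # cochlear load dashpot, N*s/m
    cv: float = 0.0                      # lognormal perturbation CV
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, c in self.connectors.items():
            if c.E <= 0 or c.area <= 0 or c.length <= 0:
                raise ValueError(f"connector {name!r} must have positive E/A/L")
        for b in DOF_NAMES:
            if self.body_density[b] <= 0 or self.body_volume[b] <= 0:
                raise ValueError(f"body {b!r} must have positive density/volume")
        if self.eardrum_area <= 0:
            raise ValueError("eardrum_area must be positive")
        if self.alpha < 0 or self.beta < 0 or self.cochlear_damping < 0:
            raise ValueError("damping values must be non-negative")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


# (name, dof_i, dof_j or None for ground)
_TOPOLOGY = [
    ("drum_malleus", 0, 1),
    ("malleus_incus", 1, 2),
    ("incus_stapes", 2, 3),
    ("tympanic_annulus", 0, None),
    ("stapedial_annulus", 3, None),
]


@dataclass
class MiddleEarNetwork:
    """Assembled 4-DOF mass/stiffness/damping network.

    ``C`` is alpha*M + beta*K plus the cochlear dashpot on the stapes DOF;
    ``springs`` retains the per-connector constants so perturbation and
    round-tripping act on physical parameters, not matrix entries.
    """

    dof_names: tuple[str, ...]
    M: np.ndarray
    K: np.ndarray
    C: np.ndarray
    eardrum_area: float
    springs: dict[str, float]          # connector name -> k, N/m
    masses: dict[str, float]           # body name -> kg
    alpha: float
    beta: float
    cochlear_damping: float
    drive_port: int = 0
    attach_port: int = 2
    probe_port: int = 3

    @property
    def ndof(self) -> int:
        return len(self.dof_names)

    def rayleigh_damping(self) -> np.ndarray:
        """The alpha*M + beta*K part of C (cochlear dashpot excluded)."""
        return self.alpha * self.M + self.beta * self.K

    def natural_frequencies(self) -> np.ndarray:
        """Undamped natural frequencies, Hz, ascending."""
        lam = scipy.linalg.eigh(self.K, self.M, eigvals_only=True)
        lam = np.clip(lam, 0.0, None)
        return np.sqrt(lam) / (2 * np.pi)

    def is_passive(self, tol: float = 1e-8) -> bool:
        """All damped-system eigenvalues in the closed left half plane."""
        n = self.ndof
        A = np.zeros((2 * n, 2 * n))
        A[:n, n:] = np.eye(n)
        A[n:, :n] = -np.linalg.solve(self.M, self.K)
        A[n:, n:] = -np.linalg.solve(self.M, self.C)
        ev = np.linalg.eigvals(A)
        scale = max(np.abs(ev).max(), 1.0)
        return bool(np.all(ev.real <= tol * scale))

    def harmonic_solve(self, force: np.ndarray, frequencies) -> np.ndarray:
        """Complex displacement solutions (nf, ndof) for a force phasor."""
        frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
        out = np.empty((len(frequencies), self.ndof), dtype=complex)
        for i, f in enumerate(frequencies):
            w = 2 * np.pi * f
            Z = self.K + 1j * w * self.C - w * w * self.M
            out[i] = np.linalg.solve(Z, force)
        return out

    def copy(self) -> "MiddleEarNetwork":
        return copy.deepcopy(self)


def build_default_network(config: SurrogateConfig | None = None) -> MiddleEarNetwork:
    """Assemble the default eardrum–malleus–incus–stapes chain."""
    config = config or SurrogateConfig()
    n = len(DOF_NAMES)
    masses = {b: config.body_density[b] * config.body_volume[b]
              for b in DOF_NAMES}
    M = np.diag([masses[b] for b in DOF_NAMES])
    springs = {name: c.k for name, c in config.connectors.items()}
    K = np.zeros((n, n))
    grounded = False
    for name, i, j in _TOPOLOGY:
        k = springs[name]
        K[i, i] += k
        if j is None:
            grounded = True
        else:
            K[j, j] += k
            K[i, j] -= k
            K[j, i] -= k
    if not grounded or np.linalg.matrix_rank(K) < n:
        raise ValueError("network stiffness is singular: no grounding spring")
    C = config.alpha * M + config.beta * K
    C[3, 3] += config.cochlear_damping
    net = MiddleEarNetwork(
        dof_names=DOF_NAMES, M=M, K=K, C=C,
        eardrum_area=config.eardrum_area, springs=springs, masses=masses,
        alpha=config.alpha, beta=config.beta,
        cochlear_damping=config.cochlear_damping,
    )
    if config.cv > 0:
        net = randomize_network(net, config.cv, config.seed)
    return net


def _rebuild_matrices(net: MiddleEarNetwork) -> None:
    n = net.ndof
    net.M = np.diag([net.masses[b] for b in net.dof_names])
    K = np.zeros((n, n))
    for name, i, j in _TOPOLOGY:
        k = net.springs[name]
        K[i, i] += k
        if j is not None:
            K[j, j] += k
            K[i, j] -= k
            K[j, i] -= k
    net.K = K
    net.C = net.alpha * net.M + net.beta * net.K
    net.C[net.probe_port, net.probe_port] += net.cochlear_damping


def acoustic_drive(network: MiddleEarNetwork, spl_db: float,
                   frequencies) -> np.ndarray:
    """Complex stapes displacement spectrum under eardrum pressure drive, m.

    The drive force is p_rms * eardrum_area at the eardrum DOF, so returned
    magnitudes are RMS displacements.
    """
    if not np.isfinite(spl_db):
        raise ValueError("spl_db must be finite")
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(frequencies <= 0):
        raise ValueError("frequencies must be positive")
    force = np.zeros(network.ndof)
    force[network.drive_port] = spl_to_pressure(spl_db) * network.eardrum_area
    sol = network.harmonic_solve(force, frequencies)
    return sol[:, network.probe_port]


def stapes_stf(network: MiddleEarNetwork, spl_db: float,
               frequencies) -> np.ndarray:
    """Stapes velocity transfer function magnitude spectrum, (m/s)/Pa."""
    from .metrics import stf
    d = np.abs(acoustic_drive(network, spl_db, frequencies))
    return stf(d, frequencies, spl_to_pressure(spl_db))


def randomize_network(network: MiddleEarNetwork, cv: float,
                      seed: int | None = None) -> MiddleEarNetwork:
    """Perturb each spring constant and mass by independent lognormal factors.

    Factors have unit mean and the given coefficient of variation; cv = 0
    returns the network unchanged.  Perturbing physical parameters (not
    matrix entries) keeps the network symmetric and passive for every draw.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return network
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    mu = -0.5 * sigma2    # unit-mean lognormal
    out = network.copy()
    for name in sorted(out.springs):
        out.springs[name] *= float(rng.lognormal(mu, sigma))
    for name in out.dof_names:
        out.masses[name] *= float(rng.lognormal(mu, sigma))
    _rebuild_matrices(out)
    return out


# ---------------------------------------------------------------------------
# TOML round-trip
# ---------------------------------------------------------------------------

def save_network(net: MiddleEarNetwork, path: str | Path) -> None:
    """Write the network's physical parameters as TOML."""
    lines = ["[network]"]
    lines.append(f'dof_names = [{", ".join(repr(n) for n in net.dof_names)}]')
    for key in ("eardrum_area", "alpha", "beta", "cochlear_damping"):
        lines.append(f"{key} = {getattr(net, key)!r}")
    lines.append("")
    lines.append("[network.masses]")
    for b, m in net.masses.items():
        lines.append(f'"{b}" = {m!r}')
    lines.append("")
    lines.append("[network.springs]")
    for s, k in net.springs.items():
        lines.append(f'"{s}" = {k!r}')
    Path(path).write_text("\n".join(lines) + "\n")


def load_network(path: str | Path) -> MiddleEarNetwork:
    """Rebuild a network from a TOML file written by :func:`save_network`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)["network"]
    net = build_default_network()
    net.eardrum_area = raw["eardrum_area"]
    net.alpha = raw["alpha"]
    net.beta = raw["beta"]
    net.cochlear_damping = raw["cochlear_damping"]
    net.masses = dict(raw["masses"])
    net.springs = dict(raw["springs"])
    _rebuild_matrices(net)
    return net
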