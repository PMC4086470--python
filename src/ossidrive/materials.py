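"""Constitutive models: PZT-4 piezoceramic and isotropic elastic components.

The piezoceramic is transversely isotropic about its poling axis (local
3-axis).  All matrices use Voigt notation in the order
(11, 22, 33, 23, 13, 12) with engineering shear strains; this ordering is a
package-wide convention and every strain-displacement operator in
:mod:`ossidrive.fem` follows it.

Stress/charge form of the piezoelectric constitutive law::

    T = cE : S - e^T . E        (stress,   Pa)
    D = e : S + epsS . E        (electric displacement, C/m^2)

where ``cE`` is the elastic stiffness at constant electric field, ``e`` the
piezoelectric stress matrix and ``epsS`` the clamped (constant-strain)
permittivity.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

_FIXTURE_COLUMNS = ["name", "youngs_modulus_pa", "density_kg_m3"]


@dataclass(frozen=True)
class PiezoConstitutive:
    """Piezoelectric material operators in SI units.

    Attributes
    ----------
    cE : (6, 6) ndarray
        Elastic stiffness at constant electric field, Pa.
    e : (3, 6) ndarray
        Piezoelectric stress matrix, C/m^2.
    epsS : (3, 3) ndarray
        Clamped permittivity, F/m.
    rho : float
        Mass density, kg/m^3.
    poling_axis : str
        Label of the local poling axis; always the 3- (z-) axis here.
    """

    cE: np.ndarray
    e: np.ndarray
    epsS: np.ndarray
    rho: float
    poling_axis: str = "z"

    def __post_init__(self) -> None:
        cE = np.asarray(self.cE, dtype=float)
        if cE.shape != (6, 6):
            raise ValueError("cE must be 6x6")
        if not np.allclose(cE, cE.T, rtol=1e-12, atol=0.0):
            raise ValueError("cE must be symmetric")
        # positive definiteness guards against transcription errors
        try:
            np.linalg.cholesky(cE)
        except np.linalg.LinAlgError as exc:
            raise ValueError("cE is not positive definite") from exc
        eps = np.asarray(self.epsS, dtype=float)
        if eps.shape != (3, 3) or np.any(np.diag(eps) <= 0):
            raise ValueError("epsS must be 3x3 with positive diagonal")


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic elastic component with Rayleigh damping coefficients.

    ``alpha`` (1/s) multiplies mass, ``beta`` (s) multiplies stiffness in the
    damping matrix C = alpha*M + beta*K.
    """

    E: float
    nu: float
    rho: float
    alpha: float = 0.0
    beta: float = 1.0e-4
    name: str = ""

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.rho <= 0:
            raise ValueError("density must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("damping coefficients must be non-negative")

    def stiffness(self) -> np.ndarray:
        """6x6 isotropic Hooke operator in the package Voigt convention."""
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        c = np.zeros((6, 6))
        c[:3, :3] = lam
        c[np.arange(3), np.arange(3)] += 2 * mu
        c[np.arange(3, 6), np.arange(3, 6)] = mu
        return c


def build_piezo_constitutive(
    c11: float,
    c12: float,
    c13: float,
    c33: float,
    c44: float,
    c66: float,
    e15: float,
    e31: float,
    e33: float,
    eps11_rel: float,
    eps33_rel: float,
    rho: float,
) -> PiezoConstitutive:
    """Assemble a transversely isotropic piezoceramic from its constants.

    Stiffness arguments are in Pa; permittivities are *relative* clamped
    values (multiplied internally by the vacuum permittivity).
    """
    for name, v in [("c11", c11), ("c12", c12), ("c13", c13), ("c33", c33),
                    ("c44", c44), ("c66", c66)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if eps11_rel <= 0 or eps33_rel <= 0:
        raise ValueError("relative permittivities must be positive")

    cE = np.array([
        [c11, c12, c13, 0.0, 0.0, 0.0],
        [c12, c11, c13, 0.0, 0.0, 0.0],
        [c13, c13, c33, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, c44, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, c44, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, c66],
    ])
    e = np.zeros((3, 6))
    e[0, 4] = e15  # E1 <-> 13 shear
    e[1, 3] = e15  # E2 <-> 23 shear
    e[2, 0] = e[2, 1] = e31
    e[2, 2] = e33
    epsS = np.diag([eps11_rel, eps11_rel, eps33_rel]) * EPS0
    return PiezoConstitutive(cE=cE, e=e, epsS=epsS, rho=rho)


def pzt4(path: str | Path | None = None) -> PiezoConstitutive:
    """Load the shipped PZT-4 constants (stiffness in GPa in the file)."""
    if path is None:
        src = resources.files("ossidrive.data").joinpath("pzt4.toml")
        raw = tomllib.loads(src.read_text())
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    p = raw["pzt4"]
    return build_piezo_constitutive(
        c11=p["c11_gpa"] * 1e9,
        c12=p["c12_gpa"] * 1e9,
        c13=p["c13_gpa"] * 1e9,
        c33=p["c33_gpa"] * 1e9,
        c44=p["c44_gpa"] * 1e9,
        c66=p["c66_gpa"] * 1e9,
        e15=p["e15"],
        e31=p["e31"],
        e33=p["e33"],
        eps11_rel=p["eps11_rel"],
        eps33_rel=p["eps33_rel"],
        rho=p["density_kg_m3"],
    )


def derive_strain_constants(mat: PiezoConstitutive) -> np.ndarray:
    """Piezoelectric strain (d) matrix, C/N: d = e . sE with sE = inv(cE).

    Used by analytic actuator oracles (free stroke n*d33*V); the FEM path
    never touches it, which keeps the cross-check independent.
    """
    try:
        sE = np.linalg.inv(mat.cE)
    except np.linalg.LinAlgError as exc:
        raise ValueError("cE is singular; cannot derive strain constants") from exc
    return mat.e @ sE


def build_isotropic_elastic(
    E: float,
    nu: float,
    rho: float,
    alpha: float = 0.0,
    beta: float = 1.0e-4,
    name: str = "",
) -> ElasticMaterial:
    """Validated isotropic material; ``.stiffness()`` gives the 6x6 operator."""
    return ElasticMaterial(E=E, nu=nu, rho=rho, alpha=alpha, beta=beta, name=name)


def load_material_fixtures(path: str | Path | None = None,
                           which: str = "components") -> pd.DataFrame:
    """Load a named-material table (ossicles/eardrum/joints or ligaments).

    Parameters
    ----------
    path : optional
        External CSV with columns ``name, youngs_modulus_pa, density_kg_m3``.
        When omitted, the shipped fixture selected by ``which`` is used.
    which : {"components", "boundaries"}
        ``components`` = eardrum/ossicle/joint materials (11 records);
        ``boundaries`` = ligament/tendon boundary materials (9 records).
    """
    if path is None:
        fname = {"components": "ear_components.csv",
                 "boundaries": "ear_boundaries.csv"}.get(which)
        if fname is None:
            raise ValueError(f"unknown fixture selector: {which!r}")
        src = resources.files("ossidrive.data").joinpath(fname)
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if list(df.columns) != _FIXTURE_COLUMNS:
        raise ValueError(
            f"material fixture must have columns {_FIXTURE_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    if df["name"].duplicated().any():
        raise ValueError("duplicate material names in fixture")
    return df


def material_by_name(name: str, which: str = "components",
                     nu: float = 0.3, alpha: float = 0.0,
                     beta: float = 1.0e-4) -> ElasticMaterial:
    """Look up a fixture row and build an :class:`ElasticMaterial` from it.

    A Poisson ratio of 0.3 is assumed for every middle-ear component.
    """
    df = load_material_fixtures(which=which)
    row = df[df["name"] == name]
    if row.empty:
        raise KeyError(f"no material named {name!r} in the {which} fixture")
    r = row.iloc[0]
    return build_isotropic_elastic(
        E=float(r["youngs_modulus_pa"]), nu=nu,
        rho=float(r["density_kg_m3"]), alpha=alpha, beta=beta, name=name,
    )
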