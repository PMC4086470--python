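"""TOML run configuration: schema, unit suffixes, strict key checking.

Configs are SI throughout; convenience keys suffixed ``_mm``, ``_um`` or
``_gpa`` are converted at load so geometry can be written in natural units.
Unknown keys are rejected — a typo in a physical parameter must fail loudly,
not fall back to a default.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coupling import RodSpec
from .fem import StackSpec
from .middle_ear import SurrogateConfig

SCHEMA_VERSION = 1

_SUFFIX_SCALE = {"_mm": 1e-3, "_um": 1e-6, "_gpa": 1e9}


def _convert_units(table: dict) -> dict:
    out = {}
    for key, val in table.items():
        for suffix, scale in _SUFFIX_SCALE.items():
            if key.endswith(suffix):
                if isinstance(val, list):
                    out[key[: -len(suffix)]] = [v * scale for v in val]
                else:
                    out[key[: -len(suffix)]] = val * scale
                break
        else:
            out[key] = val
    return out


def _check_keys(section: str, table: dict, allowed: set[str]) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


_STACK_KEYS = {"n_layers", "layer_thickness", "width", "depth",
               "nx", "ny", "nz_per_layer"}
_ROD_KEYS = {"diameter", "length", "youngs_modulus", "density", "n_elements"}
_SURROGATE_KEYS = {"alpha", "beta", "cochlear_damping", "eardrum_area",
                   "cv", "seed"}
_DRIVE_KEYS = {"type", "v_rms", "spl_db", "spl_ref", "f_lo", "f_hi", "n_freq"}
_OUTPUT_KEYS = {"directory", "stem"}
_STUDY_KEYS = {"layer_counts", "rod_moduli", "power_frequency_hz",
               "power_v_rms", "capacitance_override_nf"}
_TOP_KEYS = {"schema_version", "seed", "stack", "rod", "surrogate", "drive",
             "outputs", "study"}


@dataclass
class DriveSpec:
    """Exactly one of voltage (V RMS) or acoustic (dB SPL) drive."""

    kind: str                      # "voltage" | "spl"
    v_rms: float | None = None
    spl_db: float | None = None
    spl_ref: float = 100.0
    f_lo: float = 160.0
    f_hi: float = 8000.0
    n_freq: int = 40

    def __post_init__(self) -> None:
        if self.kind not in ("voltage", "spl"):
            raise ValueError("drive type must be 'voltage' or 'spl'")
        if self.kind == "voltage":
            if self.v_rms is None or self.spl_db is not None:
                raise ValueError("voltage drive needs v_rms and no spl_db")
            if self.v_rms == 0:
                raise ValueError("zero drive")
        else:
            if self.spl_db is None or self.v_rms is not None:
                raise ValueError("spl drive needs spl_db and no v_rms")
        if not (1.0 <= self.f_lo < self.f_hi <= 20000.0):
            raise ValueError("frequency grid must lie within [1, 20000] Hz")
        if self.n_freq < 2:
            raise ValueError("n_freq must be >= 2")

    def grid(self) -> np.ndarray:
        return np.geomspace(self.f_lo, self.f_hi, self.n_freq)


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    stack: StackSpec = field(default_factory=StackSpec)
    rod: RodSpec = field(default_factory=RodSpec)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    drive: DriveSpec = field(default_factory=lambda: DriveSpec(
        kind="voltage", v_rms=10.5))
    out_dir: str = "results"
    stem: str = "run"
    seed: int = 0
    layer_counts: list[int] = field(default_factory=lambda: [10, 25, 50])
    rod_moduli: list[float] = field(default_factory=lambda: [116e9, 510e9])
    power_frequency_hz: float = 1000.0
    power_v_rms: float = 1.0
    capacitance_override_nf: float | None = None

    def resolved(self) -> dict:
        """Flat name -> value map of every resolved parameter (for run logs)."""
        out = {"schema_version": SCHEMA_VERSION, "seed": self.seed,
               "out_dir": self.out_dir, "stem": self.stem}
        for prefix, obj in [("stack", self.stack), ("rod", self.rod),
                            ("drive", self.drive)]:
            for k, v in vars(obj).items():
                out[f"{prefix}.{k}"] = v
        sc = self.surrogate
        for k in _SURROGATE_KEYS:
            out[f"surrogate.{k}"] = getattr(sc, k)
        out["study.layer_counts"] = self.layer_counts
        out["study.rod_moduli"] = self.rod_moduli
        out["study.power_frequency_hz"] = self.power_frequency_hz
        out["study.power_v_rms"] = self.power_v_rms
        out["study.capacitance_override_nf"] = self.capacitance_override_nf
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load, unit-convert and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    _check_keys("<top level>", raw, _TOP_KEYS)
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")

    stack_tbl = _convert_units(raw.get("stack", {}))
    _check_keys("stack", stack_tbl, _STACK_KEYS)
    rod_tbl = _convert_units(raw.get("rod", {}))
    _check_keys("rod", rod_tbl, _ROD_KEYS)
    sur_tbl = _convert_units(raw.get("surrogate", {}))
    _check_keys("surrogate", sur_tbl, _SURROGATE_KEYS)
    drive_tbl = _convert_units(raw.get("drive", {}))
    _check_keys("drive", drive_tbl, _DRIVE_KEYS)
    out_tbl = raw.get("outputs", {})
    _check_keys("outputs", out_tbl, _OUTPUT_KEYS)
    study_tbl = _convert_units(raw.get("study", {}))
    _check_keys("study", study_tbl, _STUDY_KEYS)

    drive_kind = drive_tbl.pop("type", "voltage")
    drive = DriveSpec(kind=drive_kind, **drive_tbl)

    cfg = RunConfig(
        stack=StackSpec(**stack_tbl),
        rod=RodSpec(**rod_tbl),
        surrogate=SurrogateConfig(**sur_tbl),
        drive=drive,
        out_dir=out_tbl.get("directory", "results"),
        stem=out_tbl.get("stem", "run"),
        seed=int(raw.get("seed", 0)),
    )
    if "layer_counts" in study_tbl:
        cfg.layer_counts = [int(n) for n in study_tbl["layer_counts"]]
    if "rod_moduli" in study_tbl:
        cfg.rod_moduli = [float(E) for E in study_tbl["rod_moduli"]]
    if "power_frequency_hz" in study_tbl:
        cfg.power_frequency_hz = float(study_tbl["power_frequency_hz"])
    if "power_v_rms" in study_tbl:
        cfg.power_v_rms = float(study_tbl["power_v_rms"])
    if "capacitance_override_nf" in study_tbl:
        cfg.capacitance_override_nf = float(study_tbl["capacitance_override_nf"])
    return cfg
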