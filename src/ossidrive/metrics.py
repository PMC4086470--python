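"""Evaluation metrics and the electrical budget of the stack transducer.

* STF — stapes (footplate) velocity transfer function, v / P_TM with
  v = 2*pi*f*D, in (m/s)/Pa.
* Delta-H — decibel change of transducer-excited stapes displacement caused
  by the flexible coupling rod, 20*log10(d_tr_rod / d_tr) by default
  (negative values are drops).  The "literal" convention drops the factor
  of 20 for the plain log10 ratio.
* Peq — equivalent sound pressure level: the SPL at the eardrum that would
  move the stapes as much as the transducer does,
  Peq = spl_ref + 20*log10(d_tr / d_ac).
* Capacitance / current / power of the stack below resonance, treating the
  n layers as parallel-plate capacitors electrically in parallel:
  C = n*eps0*eps33*A/t, I_rms = 2*pi*f*C*V_rms.  The reactive "half power"
  (1/2)*I*V and the apparent power I*V are both reported because they are
  distinct quantities and both appear in the design literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import EPS0


def _pos(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"{name} must be positive everywhere")
    return x


def stf(displacement_spectrum, frequencies, p_tm: float) -> np.ndarray:
    """Velocity transfer function STF(f) = 2*pi*f*D(f) / P_TM, (m/s)/Pa."""
    if p_tm <= 0:
        raise ValueError("p_tm must be positive")
    D = np.asarray(displacement_spectrum, dtype=float)
    f = _pos(frequencies, "frequencies")
    return 2.0 * np.pi * f * D / p_tm


def rod_effect_db(d_tr_rod, d_tr, convention: str = "db") -> np.ndarray:
    """Rod insertion effect Delta-H.

    ``convention="db"`` (default): 20*log10(d_tr_rod/d_tr), matching drops
    quoted in dB of a displacement ratio.  ``convention="literal"``: plain
    log10 of the ratio.
    """
    d_tr = _pos(d_tr, "d_tr")
    d_rod = np.asarray(d_tr_rod, dtype=float)
    if np.any(d_rod <= 0):
        raise ValueError("d_tr_rod must be positive everywhere")
    ratio = np.log10(d_rod / d_tr)
    if convention == "db":
        return 20.0 * ratio
    if convention == "literal":
        return ratio
    raise ValueError(f"unknown convention {convention!r}")


def equivalent_spl(d_tr, d_ac, spl_ref: float = 100.0) -> np.ndarray:
    """Peq(f) = spl_ref + 20*log10(d_tr/d_ac), dB SPL."""
    d_ac = _pos(d_ac, "d_ac")
    d_tr = np.asarray(d_tr, dtype=float)
    if np.any(d_tr <= 0):
        raise ValueError("d_tr must be positive everywhere")
    return spl_ref + 20.0 * np.log10(d_tr / d_ac)


def capacitance(n: int, eps33_rel: float, area: float,
                thickness: float) -> float:
    """Stack capacitance C = n * eps0 * eps33 * A / t, F.

    ``thickness`` is the single-layer thickness; the n layers are
    electrically in parallel so their capacitances sum.
    """
    if n <= 0 or eps33_rel <= 0 or area <= 0 or thickness <= 0:
        raise ValueError("all capacitance inputs must be positive")
    return n * EPS0 * eps33_rel * area / thickness


@dataclass(frozen=True)
class ElectricalReport:
    """Drive-point electrical quantities of the capacitive stack."""

    capacitance_f: float
    frequency_hz: float
    v_rms: float
    i_rms_a: float
    p_half_w: float       # (1/2) * I_rms * V_rms
    p_apparent_w: float   # I_rms * V_rms = 2*pi*f*C*V_rms^2


def current_and_power(c_farads: float, f: float,
                      v_rms: float) -> ElectricalReport:
    """Capacitive current and power at one frequency and RMS voltage.

    Both printed power variants are returned as distinct named fields:
    ``p_half_w`` is (1/2)*I*V, ``p_apparent_w`` the apparent power I*V.
    """
    if c_farads < 0 or f < 0 or v_rms < 0:
        raise ValueError("inputs must be non-negative")
    i_rms = 2.0 * np.pi * f * c_farads * v_rms
    return ElectricalReport(
        capacitance_f=c_farads, frequency_hz=f, v_rms=v_rms,
        i_rms_a=i_rms, p_half_w=0.5 * i_rms * v_rms,
        p_apparent_w=i_rms * v_rms,
    )
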