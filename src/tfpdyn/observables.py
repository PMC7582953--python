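"""Chemical-shift and sequence descriptors used as analysis filters.

Amide-proton temperature coefficients and H/D exchange half-times feed
the hydrogen-bond criteria (slope > -4.5 ppb/K; half-exchange > 20 min,
both strict inequalities as printed); the methanol-d4 chemical-shift
thermometer cross-calibrates spectrometer temperatures; the sequence
profile gives the mean Kyte-Doolittle hydrophobicity index and a charge
census counting Arg/Lys plus the N-terminus as positive and Asp/Glu
plus the C-terminus as negative, with His tallied separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

# Named threshold constants (strict ">" comparisons)
HBOND_TEMP_COEFF_PPB_K = -4.5
HBOND_HD_HALFTIME_MIN = 20.0

# Kyte & Doolittle (1982) hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class TempCoefficient:
    residue_id: Optional[int]
    slope_ppb_k: float
    slope_err_ppb_k: float
    r_squared: float
    hbond_candidate: bool


def temp_coefficient(
    temperatures_c: Sequence[float],
    shifts_ppm: Sequence[float],
    residue_id: Optional[int] = None,
) -> TempCoefficient:
    """Amide 1HN temperature gradient by ordinary least squares.

    Slope reported in ppb/K; a slope more positive than -4.5 ppb/K marks
    the amide as a hydrogen-bond candidate. R^2 is reported because a
    linear dependence over the measured range is itself evidence of the
    absence of structural transitions.
    """
    t = np.asarray(temperatures_c, dtype=float)
    d = np.asarray(shifts_ppm, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 temperature points")
    if np.unique(t).size != t.size:
        raise ValueError("temperatures must be distinct")
    res = stats.linregress(t, d * 1000.0)  # ppm -> ppb; per degree C == per K
    return TempCoefficient(
        residue_id=residue_id,
        slope_ppb_k=float(res.slope),
        slope_err_ppb_k=float(res.stderr),
        r_squared=float(res.rvalue**2),
        hbond_candidate=bool(res.slope > HBOND_TEMP_COEFF_PPB_K),
    )


@dataclass(frozen=True)
class HDExchange:
    half_time_min: float
    half_time_err_min: float
    slow_exchange: bool  # t1/2 > 20 min (strict)
    decaying: bool


def hd_half_exchange(times_min: Sequence[float], intensities: Sequence[float]) -> HDExchange:
    """H/D exchange half-time from a monoexponential intensity decay.

    t1/2 = ln(2)/k. Amides with t1/2 > 20 min are flagged as protected
    (hydrogen-bond candidates). Non-decaying series are flagged rather
    than silently fitted.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")

    def model(tt, i0, k):
        return i0 * np.exp(-k * tt)

    k0 = max(1e-4, math.log(max(y[0] / y[-1], 1.01)) / max(t[-1] - t[0], 1e-9))
    popt, pcov = optimize.curve_fit(model, t, y, p0=[y[0], k0], maxfev=10000)
    i0, k = popt
    if k <= 0:
        warnings.warn("intensity series does not decay; amide excluded from analysis")
        return HDExchange(math.inf, math.inf, slow_exchange=False, decaying=False)
    k_err = math.sqrt(max(pcov[1, 1], 0.0))
    t_half = math.log(2.0) / k
    t_half_err = t_half * k_err / k
    return HDExchange(
        half_time_min=t_half,
        half_time_err_min=t_half_err,
        slow_exchange=bool(t_half > HBOND_HD_HALFTIME_MIN),
        decaying=True,
    )


# Methanol-d4 chemical-shift thermometer, Findeisen, Hackbusch & Berger,
# Magn. Reson. Chem. 45 (2007) 175-178: T/K as a quadratic in the
# CH3-OH 1H shift difference (ppm), valid ~278-330 K.
_METHANOL_COEFFS = (-16.7467, -52.5130, 419.1381)  # a*x^2 + b*x + c
_METHANOL_T_RANGE = (278.0, 330.0)


def methanol_temperature(delta_ppm: float) -> float:
    """Sample temperature (K) from the methanol-d4 CH3-OH shift difference.

    Monotone decreasing in delta; raises outside the calibration's
    validity range.
    """
    a, b, c = _METHANOL_COEFFS
    t = a * delta_ppm**2 + b * delta_ppm + c
    lo, hi = _METHANOL_T_RANGE
    if not (lo <= t <= hi):
        raise ValueError(
            f"shift difference {delta_ppm} ppm maps to {t:.1f} K, outside the "
            f"calibration validity range {lo}-{hi} K"
        )
    return t


def methanol_shift_for_temperature(temperature_k: float) -> float:
    """Invert the thermometer: expected shift difference at a temperature."""
    lo, hi = _METHANOL_T_RANGE
    if not (lo <= temperature_k <= hi):
        raise ValueError(f"temperature outside calibration range {lo}-{hi} K")
    a, b, c = _METHANOL_COEFFS
    # positive root of a*x^2 + b*x + (c - T) = 0 in the physical branch
    disc = b * b - 4.0 * a * (c - temperature_k)
    return (-b - math.sqrt(disc)) / (2.0 * a)


@dataclass(frozen=True)
class SequenceProfile:
    sequence: str
    mean_kd_index: float
    positive_count: int
    negative_count: int
    his_count: int


def sequence_profile(sequence: str) -> SequenceProfile:
    """Hydrophobicity and charge census of a one-letter sequence.

    Mean Kyte-Doolittle index (bounded by -4.5 for poly-Arg and +4.5 for
    poly-Ile); positives = Arg + Lys + 1 (N-terminal amine), negatives =
    Asp + Glu + 1 (C-terminal carboxyl); His counted separately because
    its ionization switches near pH 6. Free Cys are not counted.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    for pos, aa in enumerate(seq):
        if aa not in KYTE_DOOLITTLE:
            raise ValueError(f"unknown amino-acid letter {aa!r} at position {pos}")
    mean_kd = float(np.mean([KYTE_DOOLITTLE[aa] for aa in seq]))
    return SequenceProfile(
        sequence=seq,
        mean_kd_index=mean_kd,
        positive_count=seq.count("R") + seq.count("K") + 1,
        negative_count=seq.count("D") + seq.count("E") + 1,
        his_count=seq.count("H"),
    )
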