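"""Lipari-Szabo forward model for backbone 15N relaxation.

Spectral densities for isotropic and axially symmetric rotational
diffusion, the five standard motional models of the model-free
formalism, and the dipolar + CSA (+ exchange) expressions linking
J(omega) to the observable R1, R2 and steady-state heteronuclear
15N-{1H} NOE.

Unit policy: correlation times ns, rates s^-1, angular frequencies
rad/s, fields as proton MHz. The 15N gyromagnetic ratio is negative
and all frequency combinations are handled with their signs before
taking magnitudes, so the NOE comes out with the correct sign (down
to ~-3.9 in the extreme-narrowing limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from .constants import GAMMA_H, GAMMA_N, DEFAULT_CONSTANTS, NuclearConstants

NS = 1e-9
PS = 1e-12

VALID_MODELS = (1, 2, 3, 4, 5)

# Tolerance for the model-5 invariant S2 == S2_f * S2_s
_S2_PRODUCT_TOL = 1e-9


class OrientationRequiredError(ValueError):
    """An axially symmetric tensor needs the NH bond orientation."""


@dataclass(frozen=True)
class SpectrometerField:
    """A static magnetic field expressed by its proton frequency.

    Angular frequencies are derived from the gyromagnetic ratios so that
    omega_N / omega_H always equals gamma_N / gamma_H (negative).
    """

    proton_mhz: float
    temperature_k: float = 310.15

    def __post_init__(self) -> None:
        if self.proton_mhz <= 0:
            raise ValueError(f"proton frequency must be positive, got {self.proton_mhz}")

    @property
    def b0_tesla(self) -> float:
        return 2.0 * math.pi * self.proton_mhz * 1e6 / GAMMA_H

    @property
    def omega_h(self) -> float:
        """1H angular frequency, rad/s (positive)."""
        return 2.0 * math.pi * self.proton_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """15N angular frequency, rad/s (negative: gamma_N < 0)."""
        return self.omega_h * GAMMA_N / GAMMA_H


@dataclass(frozen=True)
class ModelFreeParams:
    """Per-residue internal-motion parameters for models 1-5.

    model 1: S2
    model 2: S2, tau_e (ps)
    model 3: S2, rex (s^-1 at rex_field_mhz)
    model 4: S2, tau_e, rex
    model 5: S2_f, S2_s, tau_s (ns); overall S2 = S2_f * S2_s

    R_EX is always stored at an explicit reference field and scaled
    explicitly (never implicitly) via :func:`rex_at_field`.
    """

    model_id: int
    s2: Optional[float] = None
    tau_e_ps: Optional[float] = None
    rex: Optional[float] = None
    rex_field_mhz: float = 800.0
    s2_f: Optional[float] = None
    s2_s: Optional[float] = None
    tau_s_ns: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_id not in VALID_MODELS:
            raise ValueError(f"model_id must be one of {VALID_MODELS}, got {self.model_id}")
        m = self.model_id
        if m in (1, 2, 3, 4):
            if self.s2 is None:
                raise ValueError(f"model {m} requires S2")
            if not (0.0 <= self.s2 <= 1.0):
                raise ValueError(f"S2 must lie in [0, 1], got {self.s2}")
            if self.s2_f is not None or self.s2_s is not None or self.tau_s_ns is not None:
                raise ValueError(f"model {m} does not use S2_f/S2_s/tau_s")
        if m in (2, 4):
            if self.tau_e_ps is None or self.tau_e_ps < 0:
                raise ValueError(f"model {m} requires tau_e >= 0 ps")
        elif m in (1, 3) and self.tau_e_ps is not None:
            raise ValueError(f"model {m} does not use tau_e")
        if m in (3, 4):
            if self.rex is None or self.rex < 0:
                raise ValueError(f"model {m} requires rex >= 0")
        elif m in (1, 2, 5) and self.rex is not None:
            raise ValueError(f"model {m} does not use rex")
        if m == 5:
            for name, v in (("S2_f", self.s2_f), ("S2_s", self.s2_s)):
                if v is None or not (0.0 <= v <= 1.0):
                    raise ValueError(f"model 5 requires {name} in [0, 1]")
            if self.tau_s_ns is None or self.tau_s_ns <= 0:
                raise ValueError("model 5 requires tau_s > 0 ns")
            prod = self.s2_f * self.s2_s
            if self.s2 is not None and abs(self.s2 - prod) > _S2_PRODUCT_TOL:
                raise ValueError(
                    f"model 5 invariant violated: S2={self.s2} != S2_f*S2_s={prod}"
                )
            object.__setattr__(self, "s2", prod)

    @property
    def order_parameter(self) -> float:
        """Overall S2 (for model 5 the product S2_f * S2_s)."""
        return float(self.s2)


@dataclass(frozen=True)
class DiffusionTensor:
    """Overall rotational diffusion: isotropic or axially symmetric.

    tau_r is the isotropic correlation time 1/(6 D_iso) in ns. For the
    axially symmetric kind, ``anisotropy`` is D_par/D_perp (equal to the
    2Dz/(Dx+Dy) ratio reported for oblate/prolate tensors) and the
    unique-axis orientation is given by polar angles (theta, phi) in the
    laboratory frame of the structure coordinates.
    """

    kind: str  # "isotropic" | "axially_symmetric"
    tau_r_ns: float
    anisotropy: float = 1.0
    axis_theta: float = 0.0
    axis_phi: float = 0.0
    tau_r_err_ns: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("isotropic", "axially_symmetric"):
            raise ValueError(f"unknown tensor kind {self.kind!r}")
        if self.tau_r_ns <= 0:
            raise ValueError(f"tau_R must be positive, got {self.tau_r_ns}")
        if self.kind == "isotropic" and abs(self.anisotropy - 1.0) > 1e-12:
            raise ValueError("isotropic tensor must have anisotropy 1")
        if self.anisotropy <= 0:
            raise ValueError("anisotropy must be positive")

    @property
    def unique_axis(self) -> np.ndarray:
        st, ct = math.sin(self.axis_theta), math.cos(self.axis_theta)
        return np.array([st * math.cos(self.axis_phi), st * math.sin(self.axis_phi), ct])

    def local_correlations(self, nh_orientation: Optional[Sequence[float]]):
        """Weights A_k and correlation times tau_k (s) for the J(w) sum.

        Isotropic: single term A=1, tau = tau_r. Axial: the standard
        three-Lorentzian orientation-weighted form with
        1/tau_1 = 6 D_perp, 1/tau_2 = 5 D_perp + D_par,
        1/tau_3 = 2 D_perp + 4 D_par and weights depending on the angle
        between the NH vector and the unique axis.
        """
        if self.kind == "isotropic":
            return np.array([1.0]), np.array([self.tau_r_ns * NS])
        if nh_orientation is None:
            raise OrientationRequiredError(
                "axially symmetric diffusion requires the NH bond orientation"
            )
        v = np.asarray(nh_orientation, dtype=float)
        v = v / np.linalg.norm(v)
        cos_t = float(np.clip(np.dot(v, self.unique_axis), -1.0, 1.0))
        c2, s2 = cos_t * cos_t, 1.0 - cos_t * cos_t
        weights = np.array(
            [(3.0 * c2 - 1.0) ** 2 / 4.0, 3.0 * s2 * c2, 0.75 * s2 * s2]
        )
        d_iso = 1.0 / (6.0 * self.tau_r_ns * NS)
        d_perp = 3.0 * d_iso / (2.0 + self.anisotropy)
        d_par = self.anisotropy * d_perp
        rates = np.array([6.0 * d_perp, 5.0 * d_perp + d_par, 2.0 * d_perp + 4.0 * d_par])
        return weights, 1.0 / rates


@dataclass(frozen=True)
class RelaxationTriple:
    """R1, R2 (s^-1) and heteronuclear NOE, optionally with uncertainties."""

    r1: float
    r2: float
    noe: float
    r1_err: Optional[float] = None
    r2_err: Optional[float] = None
    noe_err: Optional[float] = None


def spectral_density(
    params: ModelFreeParams,
    tensor: DiffusionTensor,
    omega: float,
    nh_orientation: Optional[Sequence[float]] = None,
) -> float:
    """Model-free spectral density J(omega) in s/rad.

    Models 1-4 use the classic two-Lorentzian form; model 5 the extended
    two-timescale form in which the fast internal motion is taken in the
    tau_f -> 0 limit and the slow motion enters with effective correlation
    time 1/tau' = 1/tau_c + 1/tau_s per overall-tumbling component.
    """
    omega = abs(float(omega))
    weights, taus = tensor.local_correlations(nh_orientation)
    if params.model_id == 5:
        s2 = params.s2_f * params.s2_s
        amp_slow = params.s2_f - s2
        tau_int = params.tau_s_ns * NS
    else:
        s2 = params.s2
        amp_slow = 1.0 - s2
        tau_int = (params.tau_e_ps or 0.0) * PS
    j = 0.0
    for a_k, tau_k in zip(weights, taus):
        term = s2 * tau_k / (1.0 + (omega * tau_k) ** 2)
        if amp_slow > 0.0 and tau_int > 0.0:
            tau_p = tau_k * tau_int / (tau_k + tau_int)
            term += amp_slow * tau_p / (1.0 + (omega * tau_p) ** 2)
        j += a_k * term
    return 0.4 * j


def rex_at_field(rex_ref: float, ref_field_mhz: float, target_field_mhz: float) -> float:
    """Scale an exchange contribution between fields.

    Fast microsecond-millisecond exchange contributes to R2 in proportion
    to the square of the NMR frequency, so
    rex(target) = rex(ref) * (target/ref)^2.
    """
    if ref_field_mhz <= 0 or target_field_mhz <= 0:
        raise ValueError("spectrometer fields must be positive")
    if rex_ref < 0:
        raise ValueError("rex must be non-negative")
    return rex_ref * (target_field_mhz / ref_field_mhz) ** 2


def predict_relaxation(
    params: ModelFreeParams,
    tensor: DiffusionTensor,
    spec_field: SpectrometerField,
    constants: NuclearConstants = DEFAULT_CONSTANTS,
    nh_orientation: Optional[Sequence[float]] = None,
) -> RelaxationTriple:
    """Forward-model R1, R2 and NOE for one residue at one field.

    Dipolar (15N-1H) and 15N CSA mechanisms; any R_EX stored in ``params``
    is scaled to the requested field and added to R2 only.
    """
    wh = spec_field.omega_h
    wn = spec_field.omega_n  # negative
    d2 = constants.dipolar_d2  # d^2/4
    c2 = constants.csa_c2(wn)

    def j(w: float) -> float:
        return spectral_density(params, tensor, w, nh_orientation)

    j0 = j(0.0)
    jwn = j(wn)
    jwh = j(wh)
    j_diff = j(wh - wn)  # |wh - wn| = wh + |wn|
    j_sum = j(wh + wn)   # |wh + wn| = wh - |wn|

    r1 = d2 * (j_diff + 3.0 * jwn + 6.0 * j_sum) + c2 * jwn
    r2 = 0.5 * d2 * (4.0 * j0 + j_diff + 3.0 * jwn + 6.0 * jwh + 6.0 * j_sum) + (
        c2 / 6.0
    ) * (4.0 * j0 + 3.0 * jwn)
    if params.rex is not None:
        r2 += rex_at_field(params.rex, params.rex_field_mhz, spec_field.proton_mhz)
    sigma = d2 * (6.0 * j_sum - j_diff)  # cross-relaxation rate
    noe = 1.0 + (constants.gamma_h / constants.gamma_n) * sigma / r1
    return RelaxationTriple(r1=r1, r2=r2, noe=noe)
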