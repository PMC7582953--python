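"""Conformational entropy and affinity estimates from order parameters.

The diffusion-in-a-cone relation links the generalized order parameter
of a bond vector to the conformational entropy of its orientational
distribution:

    S_p / k_B = ln[ pi * (3 - sqrt(1 + 8*S)) ],   S = +sqrt(S^2)

(the "cone_full" convention). Rigid limit S^2 -> 1 sends the entropy to
-infinity; the relation is only meaningful for 0 < S^2 < 1. Summing the
per-residue difference over a stretch of n residues converts a change
in average S^2 upon binding into a backbone conformational entropy
change, an entropic free-energy penalty -T*dS, and, via the Boltzmann
relation, a bound on the affinity ratio between a "mobile" and a
"stabilized" ligand.

Published estimates of this penalty are convention-dependent (a 1/2
prefactor halves every value); the convention is therefore recorded as
``formula_id`` in every output. "cone_half" applies the 1/2 prefactor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import T_30C, kbt_kcal_per_mol, kbt_to_kcal_per_mol, kcal_per_mol_to_kbt

FORMULAS = ("cone_full", "cone_half")


def residue_entropy(s2: float, formula_id: str = "cone_full") -> float:
    """Per-residue backbone conformational entropy in units of k_B.

    Monotone decreasing in S^2. Raises for S^2 outside (0, 1): the
    rigid limit is -infinity and S^2 <= 0 is unphysical for this
    relation.
    """
    if formula_id not in FORMULAS:
        raise ValueError(f"unknown formula_id {formula_id!r}; choose from {FORMULAS}")
    if s2 <= 0.0:
        raise ValueError(f"S^2 must be positive, got {s2}")
    if s2 >= 1.0:
        raise ValueError("S^2 >= 1: entropy diverges to -infinity in the rigid limit")
    s = math.sqrt(s2)
    value = math.log(math.pi * (3.0 - math.sqrt(1.0 + 8.0 * s)))
    if formula_id == "cone_half":
        value *= 0.5
    return value


@dataclass(frozen=True)
class EntropyEstimate:
    s2_initial: float
    s2_final: float
    n_residues: int
    temperature_k: float
    delta_s_kb: float            # total dS in units of k_B (per molecule)
    delta_s_cal_mol_k: float     # dS in cal mol^-1 K^-1
    minus_t_ds_kcal_mol: float   # -T*dS in kcal/mol
    minus_t_ds_kbt: float        # -T*dS in units of k_B*T
    formula_id: str


def entropy_penalty(
    s2_initial: float,
    s2_final: float,
    n_residues: int,
    temperature_k: float = T_30C,
    formula_id: str = "cone_full",
) -> EntropyEstimate:
    """Entropy change for n residues whose average S^2 moves initial->final.

    dS = n * [S_p(final) - S_p(initial)]; stiffening (final > initial)
    gives dS < 0 and a positive penalty -T*dS.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    ds_kb = n_residues * (
        residue_entropy(s2_final, formula_id) - residue_entropy(s2_initial, formula_id)
    )
    kbt = kbt_kcal_per_mol(temperature_k)  # kcal/mol per k_B*T
    minus_t_ds_kbt = -ds_kb
    return EntropyEstimate(
        s2_initial=s2_initial,
        s2_final=s2_final,
        n_residues=n_residues,
        temperature_k=temperature_k,
        delta_s_kb=ds_kb,
        delta_s_cal_mol_k=ds_kb * kbt * 1000.0 / temperature_k,
        minus_t_ds_kcal_mol=minus_t_ds_kbt * kbt,
        minus_t_ds_kbt=minus_t_ds_kbt,
        formula_id=formula_id,
    )


@dataclass(frozen=True)
class AffinityRatio:
    delta_g_kbt: float
    ratio: float
    log10_ratio: float


def affinity_ratio(
    delta_g_kbt: float | None = None,
    delta_g_kcal_mol: float | None = None,
    temperature_k: float = T_30C,
) -> AffinityRatio:
    """Boltzmann fold-change in affinity for a free-energy difference.

    ratio = exp(dG / k_B*T). Provide dG either directly in k_B*T units
    or in kcal/mol together with the temperature.
    """
    if (delta_g_kbt is None) == (delta_g_kcal_mol is None):
        raise ValueError("provide exactly one of delta_g_kbt or delta_g_kcal_mol")
    if delta_g_kbt is None:
        delta_g_kbt = kcal_per_mol_to_kbt(delta_g_kcal_mol, temperature_k)
    ratio = math.exp(delta_g_kbt)
    return AffinityRatio(delta_g_kbt=delta_g_kbt, ratio=ratio, log10_ratio=math.log10(ratio))
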