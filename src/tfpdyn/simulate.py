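"""Synthetic relaxation data and structural ensembles with known truth.

The generator emulates the statistical structure of backbone dynamics
in a three-finger protein: a rigid disulfide-stabilized head (S^2
around 0.85-0.9), mobile loop tips (S^2 down to ~0.5, the third loop
the most mobile), sparse conformational-exchange sites, isotropic
tumbling of a small (~10 kDa) protein at tau_R 3-6 ns, two-field
measurements (full R1/R2/NOE at the high field plus R2 at the low
field), and 20-model coordinate ensembles whose disorder tracks the
region scheme. Every stochastic call is a pure function of
(spec, seed); ground truth is returned alongside so recovery can be
scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .classify import RegionScheme
from .constants import DEFAULT_CONSTANTS, NuclearConstants
from .ensemble import StructureEnsemble
from .fitting import RelaxationDataset, RelaxationRecord
from .relaxation import (
    DiffusionTensor,
    ModelFreeParams,
    SpectrometerField,
    predict_relaxation,
)

# Delay schedules of the relaxation experiments (s): eight R1 delays and
# eight CPMG sequence lengths, with the repeated planes used for the
# uncertainty estimate.
R1_DELAYS_S = (0.100, 0.200, 0.300, 0.500, 0.800, 1.000, 1.200, 1.500)
R1_DUPLICATE_DELAYS_S = (0.300, 0.800)
R2_CPMG_DELAYS_S = (0.017, 0.034, 0.051, 0.068, 0.085, 0.102, 0.136, 0.170)
R2_DUPLICATE_DELAYS_S = (0.034, 0.136)


def default_region_scheme(n_residues: int = 100) -> RegionScheme:
    """A three-finger-like region scheme for a synthetic chain.

    Residues are numbered from 0 (the expression-artifact N-terminal
    Met) to n-1. Proportions follow the ~95-residue LU-domain layout:
    three loops of 12-18 residues separated by head segments, plus a
    short C-terminal tail.
    """
    if n_residues < 60:
        raise ValueError("need at least 60 residues for the default scheme")
    scale = n_residues / 100.0
    r = lambda x: int(round(x * scale))
    loop1 = (r(7), r(20))
    loop2 = (r(30), r(45))
    loop3 = (r(58), r(72))
    c_tail = (r(86), n_residues - 1)
    head_ranges = (
        (1, loop1[0] - 1),
        (loop1[1] + 1, loop2[0] - 1),
        (loop2[1] + 1, loop3[0] - 1),
        (loop3[1] + 1, c_tail[0] - 1),
    )
    return RegionScheme(
        {
            "loop_I": (loop1,),
            "loop_II": (loop2,),
            "loop_III": (loop3,),
            "c_tail": (c_tail,),
            "head": head_ranges,
        },
        name=f"synthetic_tfp_{n_residues}",
    )


@dataclass(frozen=True)
class DynamicsProfileSpec:
    """Study conditions for the synthetic dynamics profile.

    Defaults are the packaged "TFP-like" preset: 100 residues, isotropic
    tau_R 4.3 ns at 310.15 K, full triple at 800 MHz supplemented by R2
    at 600 MHz, 3% fractional noise on rates and 0.02 absolute on NOE,
    region-mean S^2 ordered head > loop I > loop II > loop III, and
    eight exchange sites of 3-8 s^-1 (at 800 MHz).
    """

    n_residues: int = 100
    tau_r_ns: float = 4.3
    fields_mhz: Tuple[float, ...] = (600.0, 800.0)
    full_triple_fields_mhz: Tuple[float, ...] = (800.0,)
    temperature_k: float = 310.15
    # per-region (mean, sd) of a truncated-normal S^2 draw
    s2_by_region: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "head": (0.88, 0.02),
            "loop_I": (0.86, 0.03),
            "loop_II": (0.78, 0.05),
            "loop_III": (0.66, 0.06),
            "c_tail": (0.60, 0.07),
        }
    )
    s2_bounds: Tuple[float, float] = (0.30, 0.98)
    tau_e_range_ps: Tuple[float, float] = (20.0, 80.0)
    # fraction of residues given a measurable tau_e (model 2 vs model 1)
    tau_e_fraction_mobile: float = 1.0
    tau_e_fraction_rigid: float = 0.3
    n_rex_sites: int = 8
    rex_range_s1: Tuple[float, float] = (3.0, 8.0)
    n_model5_sites: int = 2
    tau_s_range_ns: Tuple[float, float] = (0.8, 2.0)
    n_doubled: int = 2
    n_broadened: int = 2
    n_proline: int = 3
    noise_rate_frac: float = 0.03
    noise_noe_abs: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rex_sites + self.n_model5_sites > self.n_residues:
            raise ValueError("more special sites than residues")
        for name, (lo, hi) in (
            ("rex_range_s1", self.rex_range_s1),
            ("tau_e_range_ps", self.tau_e_range_ps),
        ):
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")

    @property
    def scheme(self) -> RegionScheme:
        return default_region_scheme(self.n_residues)


@dataclass
class GroundTruth:
    """Per-residue true parameters plus annotation sites."""

    params: Dict[int, ModelFreeParams]
    flags: Dict[int, frozenset]
    tensor: DiffusionTensor
    scheme: RegionScheme

    def s2_map(self) -> Dict[int, float]:
        return {rid: p.order_parameter for rid, p in self.params.items()}

    def rex_map(self) -> Dict[int, float]:
        return {
            rid: p.rex for rid, p in self.params.items() if p.rex is not None and p.rex > 0
        }


def make_profile(spec: DynamicsProfileSpec) -> GroundTruth:
    """Draw the ground-truth per-residue model-free parameters."""
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme
    lo, hi = spec.s2_bounds
    params: Dict[int, ModelFreeParams] = {}
    flags: Dict[int, frozenset] = {}

    residue_ids = list(range(spec.n_residues))
    region_of = {rid: scheme.region_of(rid) for rid in residue_ids}
    # residue 0 is the N-terminal Met (no region): excluded from analysis
    analysable = [rid for rid in residue_ids if region_of[rid] is not None]

    # special sites: exchange in head/loop_II beta-structure, a couple of
    # extended-model sites in the mobile loops, annotations elsewhere
    candidates_rex = [r for r in analysable if region_of[r] in ("head", "loop_II")]
    rex_sites = list(
        rng.choice(candidates_rex, size=min(spec.n_rex_sites, len(candidates_rex)),
                   replace=False)
    )
    candidates_m5 = [
        r for r in analysable
        if region_of[r] in ("loop_III", "c_tail") and r not in rex_sites
    ]
    m5_sites = list(
        rng.choice(candidates_m5, size=min(spec.n_model5_sites, len(candidates_m5)),
                   replace=False)
    )
    remaining = [r for r in analysable if r not in rex_sites and r not in m5_sites]
    special = {}
    for label, count in (("doubled", spec.n_doubled), ("broadened", spec.n_broadened),
                         ("proline", spec.n_proline)):
        take = list(rng.choice(remaining, size=min(count, len(remaining)), replace=False))
        for rid in take:
            special[rid] = label
        remaining = [r for r in remaining if r not in take]

    def draw_s2(region: str) -> float:
        mean, sd = spec.s2_by_region[region]
        if sd == 0.0:
            return float(np.clip(mean, lo, hi))
        for _ in range(100):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return float(v)
        return float(np.clip(mean, lo, hi))

    for rid in analysable:
        region = region_of[rid]
        s2 = draw_s2(region)
        label = special.get(rid)
        if label == "proline":
            flags[rid] = frozenset({"proline"})
            continue
        if rid in m5_sites:
            s2_s = draw_s2(region)
            s2_f = float(np.clip(s2 / max(s2_s, 1e-6), 0.4, 0.98))
            tau_s = float(rng.uniform(*spec.tau_s_range_ns))
            params[rid] = ModelFreeParams(5, s2_f=s2_f, s2_s=s2_s, tau_s_ns=tau_s)
        elif rid in rex_sites:
            rex = float(rng.uniform(*spec.rex_range_s1))
            tau_e = float(rng.uniform(*spec.tau_e_range_ps))
            params[rid] = ModelFreeParams(4, s2=s2, tau_e_ps=tau_e, rex=rex,
                                          rex_field_mhz=800.0)
        else:
            mobile = region != "head"
            frac = spec.tau_e_fraction_mobile if mobile else spec.tau_e_fraction_rigid
            if rng.random() < frac:
                tau_e = float(rng.uniform(*spec.tau_e_range_ps))
                params[rid] = ModelFreeParams(2, s2=s2, tau_e_ps=tau_e)
            else:
                params[rid] = ModelFreeParams(1, s2=s2)
        flags[rid] = frozenset({label}) if label else frozenset()

    # residue 0: Met0, no data by convention
    flags[0] = frozenset({"missing"})
    tensor = DiffusionTensor("isotropic", spec.tau_r_ns)
    return GroundTruth(params=params, flags=flags, tensor=tensor, scheme=scheme)


_AA_CYCLE = "ACDEFGHIKLMNQRSTVWY"  # no Pro: prolines are flagged explicitly


def simulate_dataset(
    truth: GroundTruth,
    spec: DynamicsProfileSpec,
    constants: NuclearConstants = DEFAULT_CONSTANTS,
) -> RelaxationDataset:
    """Forward-model the relaxation dataset for a ground-truth profile.

    At each requested field the full R1/R2/NOE triple is emitted only
    for fields listed in ``full_triple_fields_mhz``; other fields carry
    R2 alone (the supplementary low-field design). Gaussian noise:
    fractional on rates, absolute on NOE. Reported uncertainties equal
    the generating noise sigma; with zero noise a nominal floor is
    reported so downstream weighting stays defined.
    """
    rng = np.random.default_rng(spec.seed + 1)
    records: List[RelaxationRecord] = []
    err_floor_frac = spec.noise_rate_frac if spec.noise_rate_frac > 0 else 0.03
    err_floor_noe = spec.noise_noe_abs if spec.noise_noe_abs > 0 else 0.02
    for rid in sorted(truth.params):
        p = truth.params[rid]
        fl = truth.flags.get(rid, frozenset())
        name = _AA_CYCLE[rid % len(_AA_CYCLE)]
        for f_mhz in spec.fields_mhz:
            triple = predict_relaxation(
                p, truth.tensor, SpectrometerField(f_mhz, spec.temperature_k), constants
            )
            full = f_mhz in spec.full_triple_fields_mhz
            r1_err = err_floor_frac * triple.r1
            r2_err = err_floor_frac * triple.r2
            noe_err = err_floor_noe
            r1 = triple.r1 + (rng.normal(0, spec.noise_rate_frac * triple.r1)
                              if spec.noise_rate_frac else 0.0)
            r2 = triple.r2 + (rng.normal(0, spec.noise_rate_frac * triple.r2)
                              if spec.noise_rate_frac else 0.0)
            noe = triple.noe + (rng.normal(0, spec.noise_noe_abs)
                                if spec.noise_noe_abs else 0.0)
            records.append(
                RelaxationRecord(
                    residue_id=rid, field_mhz=f_mhz, residue_name=name,
                    r1=r1 if full else None, r1_err=r1_err if full else None,
                    r2=r2, r2_err=r2_err,
                    noe=noe if full else None, noe_err=noe_err if full else None,
                    flags=fl,
                )
            )
    # flagged-only residues (prolines etc.) appear as records with no values?
    # they are omitted: absence of data is what the flag means downstream.
    return RelaxationDataset(
        name=f"synthetic_{spec.n_residues}res", temperature_k=spec.temperature_k,
        records=records,
    )


def simulate_decay_table(
    rate_s1: float,
    delays_s: Sequence[float] = R1_DELAYS_S,
    duplicate_delays_s: Sequence[float] = R1_DUPLICATE_DELAYS_S,
    i0: float = 100.0,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Intensity-vs-delay table at the printed schedules, with duplicates."""
    rng = np.random.default_rng(seed)
    delays = np.array(list(delays_s) + list(duplicate_delays_s))
    intensities = i0 * np.exp(-rate_s1 * delays)
    if noise_frac:
        intensities = intensities + rng.normal(0.0, noise_frac * i0, size=delays.size)
    return delays, intensities


def simulate_ensemble(
    n_models: int,
    scheme: RegionScheme,
    sigma_by_region: Mapping[str, float],
    seed: int = 0,
    n_residues: Optional[int] = None,
    template: str = "extended",
) -> StructureEnsemble:
    """Synthetic multi-model ensemble with region-scaled disorder.

    An idealized backbone (N, CA, C' per residue) is perturbed per model
    by isotropic Gaussian atom displacements whose sigma depends on the
    residue's region (sigma 0 for regions not listed). With per-axis
    sigma the expected displacement from the mean scales as
    sigma*sqrt(3) per atom. Templates: "extended" (straight chain, the
    default, requires no structure input) or "globular" (NH bond
    vectors sampling directions quasi-uniformly, needed when the
    ensemble feeds an axially-symmetric diffusion fit).
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    for region, s in sigma_by_region.items():
        if s < 0:
            raise ValueError(f"negative displacement sigma for region {region}")
    rng = np.random.default_rng(seed)
    if n_residues is None:
        n_residues = max(stop for rs in scheme.regions.values() for _, stop in rs) + 1
    residue_ids = np.arange(n_residues)
    base = np.zeros((n_residues, 3, 3))
    if template == "extended":
        # residues every 3.6 A along x, atoms offset within
        for i in range(n_residues):
            x = 3.6 * i
            base[i, 0] = (x, 0.0, 0.0)          # N
            base[i, 1] = (x + 1.2, 1.0, 0.0)    # CA
            base[i, 2] = (x + 2.4, 0.0, 0.0)    # C'
    elif template == "globular":
        # NH bond vectors sampling directions quasi-uniformly over the
        # sphere (golden-spiral set), as in a folded beta-rich domain;
        # needed when the ensemble feeds an axially symmetric diffusion
        # fit, which is unidentifiable if all NH vectors are parallel.
        golden = math.pi * (3.0 - math.sqrt(5.0))
        for i in range(n_residues):
            z = 1.0 - 2.0 * (i + 0.5) / n_residues
            r = math.sqrt(max(0.0, 1.0 - z * z))
            d = np.array([r * math.cos(golden * i), r * math.sin(golden * i), z])
            u = np.cross(d, [0.0, 0.0, 1.0])
            if np.linalg.norm(u) < 1e-6:
                u = np.cross(d, [1.0, 0.0, 0.0])
            u /= np.linalg.norm(u)
            n_pos = np.array([5.0 * i, 0.0, 0.0])
            v1 = -d + 0.8 * u
            v2 = -d - 0.8 * u
            base[i, 0] = n_pos                                   # N(i)
            base[i, 1] = n_pos + 1.45 * v1 / np.linalg.norm(v1)  # CA(i)
        # second pass: place C'(i-1) relative to N(i) to realize the NH set
        for i in range(1, n_residues):
            z = 1.0 - 2.0 * (i + 0.5) / n_residues
            r = math.sqrt(max(0.0, 1.0 - z * z))
            d = np.array([r * math.cos(golden * i), r * math.sin(golden * i), z])
            u = np.cross(d, [0.0, 0.0, 1.0])
            if np.linalg.norm(u) < 1e-6:
                u = np.cross(d, [1.0, 0.0, 0.0])
            u /= np.linalg.norm(u)
            v2 = -d - 0.8 * u
            base[i - 1, 2] = base[i, 0] + 1.33 * v2 / np.linalg.norm(v2)
        base[n_residues - 1, 2] = base[n_residues - 1, 1] + np.array([1.5, 0.0, 0.0])
    else:
        raise ValueError(f"unknown template {template!r}")
    sigmas = np.zeros(n_residues)
    for i, rid in enumerate(residue_ids):
        region = scheme.region_of(int(rid))
        if region is not None:
            sigmas[i] = sigma_by_region.get(region, 0.0)
    coords = np.repeat(base[None], n_models, axis=0)
    noise = rng.normal(size=coords.shape) * sigmas[None, :, None, None]
    coords = coords + noise
    return StructureEnsemble(
        residue_ids=residue_ids,
        residue_names=[_AA_CYCLE[i % len(_AA_CYCLE)] for i in range(n_residues)],
        coords=coords,
        name=f"synthetic_ensemble_{n_models}x{n_residues}",
    )
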