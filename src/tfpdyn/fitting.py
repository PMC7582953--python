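"""Inverse problem: from relaxation observables to model-free parameters.

Stages, mirroring the usual analysis workflow:

1. :func:`fit_exponential_decay` converts pseudo-3D intensity-vs-delay
   tables into R1/R2 rates (duplicate delays supply the experimental
   uncertainty via a pairwise-difference estimator).
2. :func:`estimate_tauR_initial` seeds the overall correlation time from
   the S^2-independent R2/R1 ratio of a rigid-residue subset.
3. :func:`fit_diffusion` refines an isotropic or axially symmetric
   rotational diffusion tensor jointly with per-residue internal-motion
   fits, iterating until tau_R is stable.
4. :func:`fit_residue_models` performs per-residue fits of the five
   standard motional models with stepwise chi^2/F-test model selection
   (Mandel-style; AIC available by switch) and Monte-Carlo parameter
   uncertainties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .constants import DEFAULT_CONSTANTS, NuclearConstants
from .relaxation import (
    DiffusionTensor,
    ModelFreeParams,
    SpectrometerField,
    rex_at_field,
)

EXCLUDE_FLAGS = frozenset({"proline", "overlapped", "missing"})

# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class RelaxationRecord:
    """Relaxation observables of one residue at one field.

    Any of R1/R2/NOE may be absent (e.g., supplementary low-field rows
    carrying only R2). Uncertainties must be positive whenever the value
    is present.
    """

    residue_id: int
    field_mhz: float
    residue_name: str = "XXX"
    r1: Optional[float] = None
    r1_err: Optional[float] = None
    r2: Optional[float] = None
    r2_err: Optional[float] = None
    noe: Optional[float] = None
    noe_err: Optional[float] = None
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "noe"):
            val = getattr(self, name)
            err = getattr(self, f"{name}_err")
            if val is not None and (err is None or err <= 0):
                raise ValueError(
                    f"residue {self.residue_id} @ {self.field_mhz} MHz: "
                    f"{name} present but uncertainty not positive"
                )
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def n_observables(self) -> int:
        return sum(v is not None for v in (self.r1, self.r2, self.noe))


@dataclass
class RelaxationDataset:
    """Per-residue, per-field relaxation records of one protein sample."""

    name: str
    temperature_k: float
    records: List[RelaxationRecord]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.residue_id, rec.field_mhz)
            if key in seen:
                raise ValueError(f"duplicate record for residue {key[0]} at {key[1]} MHz")
            seen.add(key)

    @property
    def fields_mhz(self) -> List[float]:
        return sorted({r.field_mhz for r in self.records})

    @property
    def residue_ids(self) -> List[int]:
        return sorted({r.residue_id for r in self.records})

    def records_for(self, residue_id: int) -> List[RelaxationRecord]:
        return [r for r in self.records if r.residue_id == residue_id]

    def get(self, residue_id: int, field_mhz: float) -> Optional[RelaxationRecord]:
        for r in self.records:
            if r.residue_id == residue_id and r.field_mhz == field_mhz:
                return r
        return None


# ---------------------------------------------------------------------------
# fast forward evaluation


@dataclass(frozen=True)
class _FieldCtx:
    """Precomputed per-field constants for the forward model."""

    field_mhz: float
    omegas: np.ndarray          # |[0, wN, wH, wH-wN, wH+wN]|
    d2: float
    c2: float
    gamma_ratio: float

    @classmethod
    def build(cls, field_mhz: float, constants: NuclearConstants) -> "_FieldCtx":
        f = SpectrometerField(field_mhz)
        wh, wn = f.omega_h, f.omega_n
        omegas = np.abs(np.array([0.0, wn, wh, wh - wn, wh + wn]))
        return cls(
            field_mhz=field_mhz,
            omegas=omegas,
            d2=constants.dipolar_d2,
            c2=constants.csa_c2(wn),
            gamma_ratio=constants.gamma_h / constants.gamma_n,
        )


def _j_values(
    omegas: np.ndarray,
    weights: np.ndarray,
    taus: np.ndarray,
    s2: float,
    amp_slow: float,
    tau_int_s: float,
) -> np.ndarray:
    """Model-free J at the given angular frequencies (vectorized)."""
    tk = taus[:, None]
    j = s2 * tk / (1.0 + (omegas[None, :] * tk) ** 2)
    if amp_slow > 0.0 and tau_int_s > 0.0:
        tp = tk * tau_int_s / (tk + tau_int_s)
        j = j + amp_slow * tp / (1.0 + (omegas[None, :] * tp) ** 2)
    return 0.4 * (weights[:, None] * j).sum(axis=0)


def _forward_triple(
    ctx: _FieldCtx,
    weights: np.ndarray,
    taus: np.ndarray,
    s2: float,
    amp_slow: float,
    tau_int_s: float,
    rex_800: float,
) -> Tuple[float, float, float]:
    j0, jn, jh, jd, js = _j_values(ctx.omegas, weights, taus, s2, amp_slow, tau_int_s)
    r1 = ctx.d2 * (jd + 3.0 * jn + 6.0 * js) + ctx.c2 * jn
    r2 = 0.5 * ctx.d2 * (4.0 * j0 + jd + 3.0 * jn + 6.0 * jh + 6.0 * js) + (
        ctx.c2 / 6.0
    ) * (4.0 * j0 + 3.0 * jn)
    if rex_800:
        r2 += rex_800 * (ctx.field_mhz / 800.0) ** 2
    noe = 1.0 + ctx.gamma_ratio * ctx.d2 * (6.0 * js - jd) / r1
    return r1, r2, noe


_NS = 1e-9
_PS = 1e-12


def _unpack(model_id: int, theta: np.ndarray) -> Tuple[float, float, float, float]:
    """(s2, amp_slow, tau_int_s, rex_800) from a parameter vector."""
    if model_id == 1:
        return theta[0], 0.0, 0.0, 0.0
    if model_id == 2:
        return theta[0], 1.0 - theta[0], theta[1] * _PS, 0.0
    if model_id == 3:
        return theta[0], 0.0, 0.0, theta[1]
    if model_id == 4:
        return theta[0], 1.0 - theta[0], theta[1] * _PS, theta[2]
    if model_id == 5:
        s2f, s2s, tau_s = theta
        s2 = s2f * s2s
        return s2, s2f - s2, tau_s * _NS, 0.0
    raise ValueError(model_id)


def _params_from_theta(model_id: int, theta: np.ndarray) -> ModelFreeParams:
    t = [float(x) for x in theta]
    if model_id == 1:
        return ModelFreeParams(1, s2=min(t[0], 1.0))
    if model_id == 2:
        return ModelFreeParams(2, s2=min(t[0], 1.0), tau_e_ps=t[1])
    if model_id == 3:
        return ModelFreeParams(3, s2=min(t[0], 1.0), rex=max(t[1], 0.0), rex_field_mhz=800.0)
    if model_id == 4:
        return ModelFreeParams(
            4, s2=min(t[0], 1.0), tau_e_ps=t[1], rex=max(t[2], 0.0), rex_field_mhz=800.0
        )
    return ModelFreeParams(5, s2_f=min(t[0], 1.0), s2_s=min(t[1], 1.0), tau_s_ns=t[2])


_MODEL_BOUNDS = {
    1: (np.array([0.0]), np.array([1.0])),
    2: (np.array([0.0, 0.0]), np.array([1.0, 3000.0])),
    3: (np.array([0.0, 0.0]), np.array([1.0, 50.0])),
    4: (np.array([0.0, 0.0, 0.0]), np.array([1.0, 3000.0, 50.0])),
    5: (np.array([0.0, 0.0, 0.05]), np.array([1.0, 1.0, 10.0])),
}

_MODEL_STARTS = {
    1: [[0.5], [0.85]],
    2: [[s, t] for s in (0.5, 0.8) for t in (20.0, 100.0, 600.0)],
    3: [[s, r] for s in (0.6, 0.88) for r in (1.0, 5.0)],
    4: [[s, t, r] for s in (0.55, 0.85) for t in (30.0, 300.0) for r in (1.0, 6.0)],
    5: [[f, s, t] for f in (0.65, 0.85) for s in (0.6, 0.9) for t in (0.5, 2.0)],
}

_MODEL_NPARAMS = {1: 1, 2: 2, 3: 2, 4: 3, 5: 3}


# ---------------------------------------------------------------------------
# exponential decays


@dataclass(frozen=True)
class DecayFit:
    rate: float
    rate_err: float
    i0: float
    decaying: bool
    sigma_intensity: Optional[float] = None


def fit_exponential_decay(
    delays_s: Sequence[float], intensities: Sequence[float]
) -> DecayFit:
    """Two-parameter monoexponential fit I(t) = I0 * exp(-R t).

    When duplicate delays are present (the standard repeated planes),
    the intensity noise is estimated from their pairwise differences
    (sigma = sqrt(mean(diff^2)/2)) and propagated into the rate
    uncertainty; otherwise the covariance of the unweighted fit is used.
    Non-decaying data (R <= 0) are flagged, never silently returned.
    """
    t = np.asarray(delays_s, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct delays")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")

    sigma = None
    diffs = []
    for val in np.unique(t):
        group = y[t == val]
        if group.size > 1:
            diffs.extend((group[i] - group[j]) for i in range(group.size) for j in range(i + 1, group.size))
    if diffs:
        sigma = math.sqrt(float(np.mean(np.square(diffs))) / 2.0)

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    slope = np.polyfit(t, np.log(y), 1)[0]
    p0 = [float(y.max()), max(-slope, 1e-3)]
    kwargs = {}
    if sigma and sigma > 0:
        kwargs = {"sigma": np.full_like(y, sigma), "absolute_sigma": True}
    popt, pcov = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000, **kwargs)
    i0, rate = popt
    rate_err = math.sqrt(max(pcov[1, 1], 0.0))
    if rate <= 0:
        warnings.warn("fitted rate is non-positive; decay flagged as non-decaying")
        return DecayFit(rate, rate_err, i0, decaying=False, sigma_intensity=sigma)
    return DecayFit(rate, rate_err, i0, decaying=True, sigma_intensity=sigma)


# ---------------------------------------------------------------------------
# rigid subset and initial tau_R


def rigid_subset(
    dataset: RelaxationDataset,
    noe_min: float = 0.65,
    r2_sd_window: float = 1.5,
    trim: float = 0.10,
) -> List[int]:
    """Residues suitable for the overall-tumbling fit.

    Keeps residues with NOE >= noe_min at the highest field and R2
    within trimmed mean +/- r2_sd_window * SD (exchange-broadened and
    highly mobile residues are excluded); excluded flags are honored.
    """
    top = max(dataset.fields_mhz)
    cands = [
        r
        for r in dataset.records
        if r.field_mhz == top
        and r.noe is not None
        and r.r1 is not None
        and r.r2 is not None
        and not (r.flags & (EXCLUDE_FLAGS | {"doubled", "broadened"}))
        and r.noe >= noe_min
    ]
    if not cands:
        return []
    r2s = np.array([r.r2 for r in cands])
    center = stats.trim_mean(r2s, trim) if r2s.size >= 3 else float(np.mean(r2s))
    # trimmed SD: the spread estimate must not be inflated by the very
    # exchange outliers the window is meant to reject
    if r2s.size > 4:
        lo_q, hi_q = np.quantile(r2s, [trim, 1.0 - trim])
        core = r2s[(r2s >= lo_q) & (r2s <= hi_q)]
        spread = float(np.std(core, ddof=1))
    elif r2s.size > 1:
        spread = float(np.std(r2s, ddof=1))
    else:
        spread = 0.0
    keep = [
        r.residue_id
        for r in cands
        if spread == 0.0 or abs(r.r2 - center) <= r2_sd_window * spread
    ]
    return sorted(keep)


def _tau_r_from_ratio(
    ratio: float, field_mhz: float, constants: NuclearConstants
) -> Optional[float]:
    """Solve R2/R1 = ratio for tau_R in the rigid (S^2-independent) limit."""
    ctx = _FieldCtx.build(field_mhz, constants)
    w = np.array([1.0])

    def f(tau_ns: float) -> float:
        r1, r2, _ = _forward_triple(ctx, w, np.array([tau_ns * _NS]), 1.0, 0.0, 0.0, 0.0)
        return r2 / r1 - ratio

    lo, hi = 0.1, 50.0
    if f(lo) > 0 or f(hi) < 0:
        return None
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def estimate_tauR_initial(
    dataset: RelaxationDataset,
    constants: NuclearConstants = DEFAULT_CONSTANTS,
    min_rigid: int = 5,
    trim: float = 0.10,
) -> float:
    """Initial isotropic tau_R (ns) from per-residue R2/R1 ratios.

    The R2/R1 ratio of a rigid residue depends only on tau_R (S^2
    cancels when internal motion is fast and exchange absent), so the
    trimmed mean over the rigid subset is a robust starting value.
    """
    subset = rigid_subset(dataset)
    if len(subset) < min_rigid:
        raise ValueError(
            f"only {len(subset)} rigid residues available (< {min_rigid}); "
            "supply tau_R manually"
        )
    top = max(dataset.fields_mhz)
    estimates = []
    for rid in subset:
        rec = dataset.get(rid, top)
        tau = _tau_r_from_ratio(rec.r2 / rec.r1, top, constants)
        if tau is not None:
            estimates.append(tau)
    if len(estimates) < min_rigid:
        raise ValueError("too few solvable R2/R1 ratios; supply tau_R manually")
    return float(stats.trim_mean(estimates, trim))


# ---------------------------------------------------------------------------
# per-residue fits


@dataclass
class ResidueFit:
    residue_id: int
    residue_name: str
    params: Optional[ModelFreeParams]
    chi2: float
    dof: int
    p_gof: float
    satisfactory: bool
    param_errors: Dict[str, float] = field(default_factory=dict)
    skipped: Optional[str] = None
    flags: frozenset = frozenset()

    @property
    def model_id(self) -> Optional[int]:
        return self.params.model_id if self.params is not None else None


@dataclass
class FitResult:
    tensor: DiffusionTensor
    residues: Dict[int, ResidueFit]
    n_iterations: int = 1
    tau_r_trace: Tuple[float, ...] = ()

    def s2_map(self) -> Dict[int, float]:
        return {
            rid: rf.params.order_parameter
            for rid, rf in self.residues.items()
            if rf.params is not None
        }


def _gather_observables(
    records: Sequence[RelaxationRecord], contexts: Mapping[float, _FieldCtx]
):
    """(ctx, kind-index, value, err) tuples for one residue's records."""
    obs = []
    for rec in records:
        ctx = contexts[rec.field_mhz]
        for idx, (val, err) in enumerate(
            ((rec.r1, rec.r1_err), (rec.r2, rec.r2_err), (rec.noe, rec.noe_err))
        ):
            if val is not None:
                obs.append((ctx, idx, val, err))
    return obs


def _residuals(theta, model_id, obs, weights, taus):
    s2, amp, tau_int, rex = _unpack(model_id, np.asarray(theta))
    out = np.empty(len(obs))
    cache: Dict[float, Tuple[float, float, float]] = {}
    for i, (ctx, idx, val, err) in enumerate(obs):
        key = ctx.field_mhz
        if key not in cache:
            cache[key] = _forward_triple(ctx, weights, taus, s2, amp, tau_int, rex)
        out[i] = (cache[key][idx] - val) / err
    return out


def _fit_one_model(model_id, obs, weights, taus, starts=None, tol=1e-12):
    lo, hi = _MODEL_BOUNDS[model_id]
    best = None
    for x0 in starts or _MODEL_STARTS[model_id]:
        x0c = np.clip(np.asarray(x0, dtype=float), lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                _residuals,
                x0c,
                bounds=(lo, hi),
                args=(model_id, obs, weights, taus),
                xtol=tol,
                ftol=tol,
                gtol=tol,
            )
        except Exception:
            continue
        chi2 = float(2.0 * res.cost)
        if best is None or chi2 < best[0]:
            best = (chi2, res.x)
    return best


def _select_model(
    fits: Dict[int, Tuple[float, np.ndarray]],
    n_obs: int,
    alpha_chi2: float,
    alpha_f: float,
    zero_dof_chi2: float,
    protocol: str,
) -> Tuple[int, bool]:
    """Return (model_id, satisfactory) per the configured protocol."""
    def dof(m):
        return n_obs - _MODEL_NPARAMS[m]

    def gof_ok(m):
        d = dof(m)
        chi2 = fits[m][0]
        if d > 0:
            return stats.chi2.sf(chi2, d) >= alpha_chi2
        return chi2 < zero_dof_chi2

    def f_ok(simple, complex_):
        c_simple, c_complex = fits[simple][0], fits[complex_][0]
        d_s, d_c = dof(simple), dof(complex_)
        ddof = d_s - d_c
        if c_complex >= c_simple or ddof <= 0:
            return False
        if d_c <= 0 or c_complex <= 0:
            return c_complex < zero_dof_chi2
        f_stat = ((c_simple - c_complex) / ddof) / (c_complex / d_c)
        return stats.f.sf(f_stat, ddof, d_c) <= alpha_f

    avail = sorted(fits)
    if protocol == "aic":
        aic = {m: fits[m][0] + 2 * _MODEL_NPARAMS[m] for m in avail}
        best = min(avail, key=lambda m: aic[m])
        return best, gof_ok(best)

    if 1 in fits and gof_ok(1):
        return 1, True
    stage2 = [
        m for m in (2, 3)
        if m in fits and (gof_ok(m) or (1 in fits and f_ok(1, m)))
    ]
    if stage2:
        return min(stage2, key=lambda m: fits[m][0]), True
    # stage 3: the extended models must improve significantly over the best
    # simpler model -- goodness-of-fit alone would accept overfitted models
    simple = [m for m in (1, 2, 3) if m in fits]
    base = min(simple, key=lambda m: fits[m][0], default=None)
    stage3 = [m for m in (4, 5) if m in fits and base is not None and f_ok(base, m)]
    if stage3:
        return min(stage3, key=lambda m: fits[m][0]), True
    # nothing satisfactory: report the most parsimonious adequate description
    if simple:
        return min(simple, key=lambda m: fits[m][0]), False
    return min(avail, key=lambda m: fits[m][0]), False


def fit_residue_models(
    dataset: RelaxationDataset,
    tensor: DiffusionTensor,
    constants: NuclearConstants = DEFAULT_CONSTANTS,
    nh_orientations: Optional[Mapping[int, np.ndarray]] = None,
    mc_reps: int = 500,
    seed: int = 0,
    alpha_chi2: float = 0.10,
    alpha_f: float = 0.20,
    zero_dof_chi2: float = 1e-2,
    protocol: str = "ftest",
    models: Sequence[int] = (1, 2, 3, 4, 5),
) -> FitResult:
    """Fit motional models 1-5 residue by residue against a fixed tensor.

    Nested models are tried in order and selected by the stepwise
    chi^2 goodness-of-fit / F-test protocol (significance alpha_chi2 for
    the GOF test, alpha_f for the F-test), or by AIC with
    ``protocol='aic'``. Parameter uncertainties come from Monte-Carlo
    resampling of the observables within their experimental errors
    (``mc_reps`` draws, seeded). Residues flagged proline/overlapped/
    missing, or with fewer than two observables, are skipped.
    """
    rng = np.random.default_rng(seed)
    contexts = {f: _FieldCtx.build(f, constants) for f in dataset.fields_mhz}
    results: Dict[int, ResidueFit] = {}
    for rid in dataset.residue_ids:
        records = dataset.records_for(rid)
        name = records[0].residue_name
        all_flags = frozenset().union(*(r.flags for r in records))
        if all_flags & EXCLUDE_FLAGS:
            reason = ", ".join(sorted(all_flags & EXCLUDE_FLAGS))
            results[rid] = ResidueFit(rid, name, None, math.nan, 0, math.nan, False,
                                      skipped=reason, flags=all_flags)
            continue
        obs = _gather_observables(records, contexts)
        if len(obs) < 2:
            warnings.warn(f"residue {rid}: fewer observables than parameters; skipped")
            results[rid] = ResidueFit(rid, name, None, math.nan, 0, math.nan, False,
                                      skipped="insufficient observables", flags=all_flags)
            continue
        if tensor.kind == "isotropic":
            weights, taus = tensor.local_correlations(None)
        else:
            ori = (nh_orientations or {}).get(rid)
            if ori is None:
                results[rid] = ResidueFit(rid, name, None, math.nan, 0, math.nan, False,
                                          skipped="no NH orientation for axial tensor",
                                          flags=all_flags)
                continue
            weights, taus = tensor.local_correlations(ori)

        fits = {}
        for m in models:
            if _MODEL_NPARAMS[m] > len(obs):
                continue
            got = _fit_one_model(m, obs, weights, taus)
            if got is not None:
                fits[m] = got
        if not fits:
            results[rid] = ResidueFit(rid, name, None, math.nan, 0, math.nan, False,
                                      skipped="no model could be fitted", flags=all_flags)
            continue
        chosen, satisfactory = _select_model(
            fits, len(obs), alpha_chi2, alpha_f, zero_dof_chi2, protocol
        )
        chi2, theta = fits[chosen]
        d = len(obs) - _MODEL_NPARAMS[chosen]
        p_gof = float(stats.chi2.sf(chi2, d)) if d > 0 else math.nan
        params = _params_from_theta(chosen, theta)

        errors: Dict[str, float] = {}
        if mc_reps > 0:
            draws = []
            for _ in range(mc_reps):
                obs_mc = [
                    (ctx, idx, val + rng.normal(0.0, err), err)
                    for ctx, idx, val, err in obs
                ]
                got = _fit_one_model(chosen, obs_mc, weights, taus, starts=[theta], tol=1e-8)
                if got is not None:
                    draws.append(got[1])
            if len(draws) > 2:
                sds = np.std(np.asarray(draws), axis=0, ddof=1)
                names = {
                    1: ["s2"], 2: ["s2", "tau_e_ps"], 3: ["s2", "rex"],
                    4: ["s2", "tau_e_ps", "rex"], 5: ["s2_f", "s2_s", "tau_s_ns"],
                }[chosen]
                errors = {n: float(s) for n, s in zip(names, sds)}
        results[rid] = ResidueFit(rid, name, params, chi2, d, p_gof, satisfactory,
                                  param_errors=errors, flags=all_flags)
    return FitResult(tensor=tensor, residues=results)


# ---------------------------------------------------------------------------
# diffusion tensor


def _tensor_residuals(x, kind, dataset, residue_params, contexts, nh_orientations):
    if kind == "isotropic":
        tensor = DiffusionTensor("isotropic", float(x[0]))
    else:
        tensor = DiffusionTensor(
            "axially_symmetric", float(x[0]), anisotropy=float(x[1]),
            axis_theta=float(x[2]), axis_phi=float(x[3]),
        )
    out = []
    for rid, params in residue_params.items():
        ori = None if kind == "isotropic" else nh_orientations.get(rid)
        if kind != "isotropic" and ori is None:
            continue
        weights, taus = tensor.local_correlations(ori)
        s2, amp, tau_int, rex = _unpack(params.model_id, _theta_of(params))
        for rec in dataset.records_for(rid):
            ctx = contexts[rec.field_mhz]
            pred = _forward_triple(ctx, weights, taus, s2, amp, tau_int, rex)
            for idx, (val, err) in enumerate(
                ((rec.r1, rec.r1_err), (rec.r2, rec.r2_err), (rec.noe, rec.noe_err))
            ):
                if val is not None:
                    out.append((pred[idx] - val) / err)
    return np.asarray(out)


def _theta_of(params: ModelFreeParams) -> np.ndarray:
    m = params.model_id
    if m == 1:
        return np.array([params.s2])
    if m == 2:
        return np.array([params.s2, params.tau_e_ps])
    if m == 3:
        return np.array([params.s2, params.rex])
    if m == 4:
        return np.array([params.s2, params.tau_e_ps, params.rex])
    return np.array([params.s2_f, params.s2_s, params.tau_s_ns])


class DiffusionFitError(RuntimeError):
    def __init__(self, message: str, trace: Sequence[float]):
        super().__init__(message)
        self.trace = tuple(trace)


def fit_diffusion(
    dataset: RelaxationDataset,
    structure=None,
    kind: str = "isotropic",
    constants: NuclearConstants = DEFAULT_CONSTANTS,
    conformers: Sequence[int] = (0,),
    max_rounds: int = 25,
    rel_tol: float = 0.005,
    tau_r_initial: Optional[float] = None,
) -> DiffusionTensor:
    """Global rotational-diffusion fit over the rigid-residue subset.

    Alternates per-residue internal-motion fits (models 1-2, which cover
    the rigid subset) with a tensor update minimizing the aggregate
    chi^2, until tau_R changes by less than ``rel_tol`` (0.5% default)
    between rounds. The axially symmetric kind requires a structure for
    NH orientations and is run once per requested ensemble conformer,
    averaging the resulting tensors (scatter across conformers is the
    tensor's reproducibility).
    """
    if kind not in ("isotropic", "axially_symmetric"):
        raise ValueError(f"unknown tensor kind {kind!r}")
    if kind == "axially_symmetric" and structure is None:
        raise ValueError("axially symmetric fit requires a structure ensemble")

    subset = rigid_subset(dataset)
    if len(subset) < 5:
        raise ValueError("too few rigid residues for a diffusion fit")
    sub_records = [r for r in dataset.records if r.residue_id in subset]
    sub = RelaxationDataset(dataset.name, dataset.temperature_k, sub_records)
    contexts = {f: _FieldCtx.build(f, constants) for f in sub.fields_mhz}
    tau0 = tau_r_initial if tau_r_initial is not None else estimate_tauR_initial(
        dataset, constants
    )

    def one_run(nh: Optional[Mapping[int, np.ndarray]]) -> DiffusionTensor:
        tensor = (
            DiffusionTensor("isotropic", tau0)
            if kind == "isotropic"
            else DiffusionTensor("axially_symmetric", tau0, anisotropy=1.001)
        )
        trace = [tensor.tau_r_ns]
        for _ in range(max_rounds):
            # model 2 only: tau_e free (nests model 1 at the tau_e = 0 bound),
            # so internal motion can never be silently absorbed into tau_R
            fit = fit_residue_models(
                sub, tensor, constants, nh_orientations=nh, mc_reps=0,
                models=(2,),
            )
            residue_params = {
                rid: rf.params for rid, rf in fit.residues.items() if rf.params is not None
            }
            if kind == "isotropic":
                x0, lo, hi = [tensor.tau_r_ns], [0.3], [50.0]
            else:
                x0 = [tensor.tau_r_ns, tensor.anisotropy, tensor.axis_theta, tensor.axis_phi]
                lo = [0.3, 0.3, 0.0, -math.pi]
                hi = [50.0, 3.0, math.pi, math.pi]
            res = optimize.least_squares(
                _tensor_residuals, x0, bounds=(lo, hi),
                args=(kind, sub, residue_params, contexts, nh or {}),
                xtol=1e-10,
            )
            if kind == "isotropic":
                new = DiffusionTensor("isotropic", float(res.x[0]))
            else:
                new = DiffusionTensor(
                    "axially_symmetric", float(res.x[0]), anisotropy=float(res.x[1]),
                    axis_theta=float(res.x[2]), axis_phi=float(res.x[3]),
                )
            trace.append(new.tau_r_ns)
            if abs(new.tau_r_ns - tensor.tau_r_ns) / tensor.tau_r_ns < rel_tol:
                return new
            tensor = new
        raise DiffusionFitError(
            f"diffusion fit did not converge in {max_rounds} rounds", trace
        )

    if kind == "isotropic":
        return one_run(None)
    runs = [one_run(structure.nh_orientations(c)) for c in conformers]
    taus = [t.tau_r_ns for t in runs]
    anisos = [t.anisotropy for t in runs]
    ref = runs[0]
    return DiffusionTensor(
        "axially_symmetric",
        float(np.mean(taus)),
        anisotropy=float(np.mean(anisos)),
        axis_theta=ref.axis_theta,
        axis_phi=ref.axis_phi,
        tau_r_err_ns=float(np.std(taus, ddof=1)) if len(runs) > 1 else None,
    )
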