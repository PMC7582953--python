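"""Threshold classification of backbone motions and region aggregation.

Residue-level motional classes follow the thresholds used for the
Fig-2-style maps: high-amplitude ps-ns motion when S^2 < 0.8 (for the
extended two-timescale model: when S2_f, S2_s or their product drops
below 0.8), microsecond-millisecond exchange when R_EX exceeds a
field-dependent threshold anchored at 3.0 s^-1 at 800 MHz, and slower
millisecond-second processes flagged from doubled or broadened
resonances. Region aggregation uses Cys-anchored loop/head/C-tail
schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .relaxation import ModelFreeParams, rex_at_field

S2_THRESHOLD = 0.8
REX_ANCHOR_S1 = 3.0
REX_ANCHOR_MHZ = 800.0

LABEL_FAST = "fast_ps_ns"
LABEL_EXCHANGE = "us_ms_exchange"
LABEL_TWO_CONFORMERS = "ms_s_two_conformers"
LABEL_BROADENED = "broadened"
LABEL_NO_DATA = "no_data"
LABEL_ORDERED = "ordered"


@dataclass(frozen=True)
class RegionScheme:
    """Named residue-range regions anchored on the conserved Cys scaffold.

    ``regions`` maps region name -> list of inclusive (start, stop)
    residue-id ranges. Regions must be disjoint. The conventional names
    are loop_I, loop_II, loop_III, c_tail and head (head = everything
    else excluding the first residue).
    """

    regions: Mapping[str, Tuple[Tuple[int, int], ...]]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        seen: Dict[int, str] = {}
        for region, ranges in self.regions.items():
            for start, stop in ranges:
                if stop < start:
                    raise ValueError(f"region {region}: empty range {start}-{stop}")
                for rid in range(start, stop + 1):
                    if rid in seen:
                        raise ValueError(
                            f"residue {rid} in both {seen[rid]} and {region}"
                        )
                    seen[rid] = region

    @classmethod
    def from_ranges(cls, name: str = "unnamed", **ranges: Tuple[int, int]) -> "RegionScheme":
        return cls({k: (tuple(v),) if isinstance(v[0], int) else tuple(v) for k, v in ranges.items()}, name=name)

    @classmethod
    def from_cys_anchors(
        cls,
        cys_positions: Sequence[int],
        last_residue: int,
        c_tail_start: Optional[int] = None,
        first_residue: int = 0,
        name: str = "cys_anchored",
    ) -> "RegionScheme":
        """Derive default loop boundaries from the four invariant Cys.

        ``cys_positions`` are the residue ids of the four invariant head
        cysteines in sequence order (C1..C4). Loop I runs between C1 and
        C2, loop II between C2 and C3, loop III between C3 and C4, all
        exclusive of the anchors themselves; the C-terminal tail (if any)
        starts at ``c_tail_start``. Everything else except the first
        residue is the head. Published analyses encode boundaries
        per-protein; this constructor is the documented default.
        """
        if len(cys_positions) != 4:
            raise ValueError("need the four invariant Cys anchor positions")
        c1, c2, c3, c4 = sorted(cys_positions)
        tail_end = last_residue
        regions: Dict[str, Tuple[Tuple[int, int], ...]] = {
            "loop_I": ((c1 + 1, c2 - 1),),
            "loop_II": ((c2 + 1, c3 - 1),),
            "loop_III": ((c3 + 1, c4 - 1),),
        }
        head_ranges: List[Tuple[int, int]] = []
        if c_tail_start is not None:
            regions["c_tail"] = ((c_tail_start, tail_end),)
            after_c4_end = c_tail_start - 1
        else:
            after_c4_end = tail_end
        # head: everything not in a loop/tail, excluding the first residue
        if first_residue + 1 <= c1:
            head_ranges.append((first_residue + 1, c1))
        head_ranges.append((c2, c2))
        head_ranges.append((c3, c3))
        if c4 <= after_c4_end:
            head_ranges.append((c4, after_c4_end))
        regions["head"] = tuple(head_ranges)
        return cls(regions, name=name)

    def region_of(self, residue_id: int) -> Optional[str]:
        for region, ranges in self.regions.items():
            for start, stop in ranges:
                if start <= residue_id <= stop:
                    return region
        return None

    def residues(self, region: str) -> List[int]:
        out: List[int] = []
        for start, stop in self.regions[region]:
            out.extend(range(start, stop + 1))
        return out

    @property
    def region_names(self) -> List[str]:
        return list(self.regions)


def rex_threshold(field_mhz: float) -> float:
    """Exchange threshold at a field, anchored at 3.0 s^-1 @ 800 MHz.

    Exact quadratic scaling is retained internally; report with one
    decimal (3.0, 2.3, 1.7 s^-1 at 800, 700, 600 MHz).
    """
    if field_mhz <= 0:
        raise ValueError("field must be positive")
    return REX_ANCHOR_S1 * (field_mhz / REX_ANCHOR_MHZ) ** 2


def rex_threshold_reported(field_mhz: float) -> float:
    """The threshold rounded to one decimal, as printed in reports."""
    return round(rex_threshold(field_mhz), 1)


def classify_residue(
    params: Optional[ModelFreeParams],
    flags: Iterable[str] = (),
    field_mhz: float = 800.0,
    scale_rex_to_800: bool = True,
) -> frozenset:
    """Motional class labels for one residue.

    Pure function of (params, flags, field). ``no_data`` (proline, Met0,
    spectral overlap, missing) excludes every other label. By default
    R_EX is compared after scaling to 800 MHz; set
    ``scale_rex_to_800=False`` to compare at the measurement field.
    """
    flags = set(flags)
    if params is None or flags & {"proline", "overlapped", "missing"}:
        return frozenset({LABEL_NO_DATA})
    labels = set()
    if params.model_id == 5:
        fast = min(params.s2_f, params.s2_s, params.s2_f * params.s2_s) < S2_THRESHOLD
    else:
        fast = params.s2 < S2_THRESHOLD
    if fast:
        labels.add(LABEL_FAST)
    if params.rex is not None and params.rex > 0:
        compare_field = REX_ANCHOR_MHZ if scale_rex_to_800 else field_mhz
        rex = rex_at_field(params.rex, params.rex_field_mhz, compare_field)
        if rex > rex_threshold(compare_field):
            labels.add(LABEL_EXCHANGE)
    if "doubled" in flags:
        labels.add(LABEL_TWO_CONFORMERS)
    if "broadened" in flags:
        labels.add(LABEL_BROADENED)
    if not labels:
        labels.add(LABEL_ORDERED)
    return frozenset(labels)


def r1r2_indicator(
    residue_ids: Sequence[int],
    r1: Sequence[float],
    r2: Sequence[float],
    trim: float = 0.10,
) -> Dict[int, bool]:
    """Advisory exchange flag from elevated R1*R2 products.

    The R1*R2 product removes most of the overall-tumbling dependence, so
    residues whose product exceeds the 10%-trimmed mean + 1 SD of the
    distribution are likely exchange sites. Advisory only; the headline
    classification uses fitted R_EX.
    """
    products = np.asarray(r1, dtype=float) * np.asarray(r2, dtype=float)
    if len(products) < 3:
        warnings.warn("too few residues for R1*R2 population statistics; no flags set")
        return {rid: False for rid in residue_ids}
    center = stats.trim_mean(products, trim)
    spread = float(np.std(products, ddof=1))
    cutoff = center + spread
    return {rid: bool(p > cutoff) for rid, p in zip(residue_ids, products)}


@dataclass
class RegionMean:
    region: str
    mean: Optional[float]
    n_available: int
    n_total: int


def region_mean(
    values: Mapping[int, float], scheme: RegionScheme
) -> Dict[str, RegionMean]:
    """Arithmetic per-region mean of a per-residue scalar.

    Residues without data are skipped but counted, mirroring the
    n_available/n_total annotation of the region bar plots. A region
    with no data at all gets a null mean and a warning (its aggregate
    would carry a large degree of uncertainty).
    """
    out: Dict[str, RegionMean] = {}
    for region in scheme.region_names:
        residues = scheme.residues(region)
        avail = [values[r] for r in residues if r in values and values[r] is not None]
        if not avail:
            warnings.warn(f"region {region!r}: no residues with data")
            mean = None
        else:
            mean = float(np.mean(avail))
        out[region] = RegionMean(region, mean, len(avail), len(residues))
    return out
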