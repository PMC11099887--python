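"""Lipid class/adduct-specific linear CCS correction-function ensembles.

For every lipid class-adduct combination with at least three matched
U13C-labeled lipids, up to ``cap`` (default 100) distinct subsets of 3-6
labeled lipids are drawn and an ordinary least-squares line

    CCS_reference = slope * CCS_measured + intercept

is fitted on each subset.  A corrected CCS is obtained by plugging a measured
CCS directly into a function, and every lipid of the class-adduct combination
is corrected with every function irrespective of its labeling status.
Functions whose slope leaves a plausibility band or whose r^2 is poor are
flagged and excluded from per-lipid point estimates (the median corrected
value over non-flagged functions) but retained in all reports.

Subset sampling when the number of eligible subsets exceeds the cap is
uniform without replacement over all subset sizes pooled, seeded and
therefore reproducible; subsets are materialized by combinatorial unranking
so no enumeration of the full subset space is needed.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .bias import MatchedPair, MeasuredIon, ccs_bias_percent, mean_measured

__all__ = [
    "CorrectionFunction",
    "LipidCorrection",
    "GroupCorrection",
    "DegenerateFitError",
    "eligible_groups",
    "enumerate_subsets",
    "fit_correction",
    "apply_correction",
    "flag_poor_functions",
    "evaluate_corrections",
    "correct_group",
    "correct_dataset",
    "DEFAULT_SLOPE_BAND",
    "DEFAULT_R2_MIN",
]

DEFAULT_SLOPE_BAND = (0.8, 1.2)
DEFAULT_R2_MIN = 0.99


class DegenerateFitError(ValueError):
    """Raised when the regression predictor is constant."""


@dataclass
class CorrectionFunction:
    """One affine correction for one class-adduct fit on one lipid subset."""

    lipid_class: str
    adduct: str
    subset_ids: frozenset[str]
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    function_index: int
    flagged: bool = False
    flag_reason: str = ""
    mean_after_bias: Optional[float] = None  # filled by evaluate_corrections

    def __post_init__(self) -> None:
        if not (3 <= self.n_points <= 6):
            raise ValueError(f"n_points must be in [3, 6], got {self.n_points}")
        if self.n_points != len(self.subset_ids):
            raise ValueError("n_points must equal |subset_ids|")


@dataclass
class LipidCorrection:
    """Corrected CCS values for one lipid of a group.

    ``corrected`` holds one value per non-flagged function (in function-index
    order); ``point_estimate`` is their median.  Bias fields are populated
    only for labeled lipids with a library reference.
    """

    lipid_name: str
    adduct: str
    labeled: bool
    ccs_input: float
    corrected: list[float]
    point_estimate: float
    bias_before: Optional[float] = None
    bias_after: Optional[list[float]] = None


@dataclass
class GroupCorrection:
    """All correction output for one lipid class-adduct combination."""

    lipid_class: str
    adduct: str
    functions: list[CorrectionFunction]
    lipids: list[LipidCorrection]
    before_biases: list[float]  # labeled lipids, one per lipid
    after_biases: list[float]  # labeled lipids x non-flagged functions, pooled

    @property
    def mean_abs_bias_before(self) -> float:
        return statistics.fmean(abs(b) for b in self.before_biases)

    @property
    def mean_abs_bias_after(self) -> float:
        return statistics.fmean(abs(b) for b in self.after_biases)

    @property
    def mean_bias_before(self) -> float:
        return statistics.fmean(self.before_biases)

    @property
    def mean_bias_after(self) -> float:
        return statistics.fmean(self.after_biases)


# ---------------------------------------------------------------------------
# Group eligibility and subset enumeration


def eligible_groups(pairs: Iterable[MatchedPair]) -> list[tuple[str, str, int]]:
    """Class-adduct combinations with >= 3 distinct matched labeled lipids.

    Returns ``(lipid_class, adduct, n_available)`` sorted by class then
    adduct.  Three labeled internal standards are the minimum for a linear
    correction fit.
    """
    counts: dict[tuple[str, str], set[str]] = {}
    for p in pairs:
        if p.measured.labeled:
            counts.setdefault((p.lipid_class, p.adduct), set()).add(
                p.reference.species.name
            )
    return [
        (cls, adduct, len(names))
        for (cls, adduct), names in sorted(counts.items())
        if len(names) >= 3
    ]


def _unrank_combination(n: int, k: int, rank: int) -> tuple[int, ...]:
    """The ``rank``-th (lexicographic) k-combination of range(n)."""
    out = []
    x = 0
    for slot in range(k, 0, -1):
        while True:
            c = math.comb(n - x - 1, slot - 1)
            if rank < c:
                out.append(x)
                x += 1
                break
            rank -= c
            x += 1
    return tuple(out)


def n_subsets(n: int, k_min: int = 3, k_max: int = 6) -> int:
    """Number of subsets of sizes k_min..min(k_max, n) of an n-set."""
    return sum(math.comb(n, k) for k in range(k_min, min(k_max, n) + 1))


def enumerate_subsets(
    ids: Sequence[str],
    k_min: int = 3,
    k_max: int = 6,
    cap: int = 100,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Distinct lipid subsets of size 3-6 used to build correction functions.

    Returns every subset when there are at most ``cap``; otherwise exactly
    ``cap`` subsets sampled uniformly without replacement over all eligible
    subsets (sizes pooled), deterministically for a fixed ``seed``.  Subsets
    are in (size, lexicographic-rank) order.
    """
    ids = list(ids)
    n = len(ids)
    if n < k_min:
        raise ValueError(f"need at least {k_min} lipids, got {n}")
    k_hi = min(k_max, n)
    sizes = list(range(k_min, k_hi + 1))
    counts = [math.comb(n, k) for k in sizes]
    total = sum(counts)
    if total <= cap:
        ranks = np.arange(total)
    else:
        rng = np.random.default_rng(seed)
        ranks = np.sort(rng.choice(total, size=cap, replace=False))
    # map pooled rank -> (size, within-size rank) -> concrete subset
    subsets: list[tuple[str, ...]] = []
    for r in ranks:
        r = int(r)
        for k, c in zip(sizes, counts):
            if r < c:
                idx = _unrank_combination(n, k, r)
                subsets.append(tuple(ids[i] for i in idx))
                break
            r -= c
    return subsets


# ---------------------------------------------------------------------------
# Fitting, application, evaluation


def fit_correction(
    subset_pairs: Sequence[MatchedPair], function_index: int = 0
) -> CorrectionFunction:
    """OLS fit of reference CCS on measured CCS for one lipid subset."""
    n = len(subset_pairs)
    if not (3 <= n <= 6):
        raise ValueError(f"subset size must be in [3, 6], got {n}")
    x = np.array([p.measured.ccs_measured for p in subset_pairs], dtype=float)
    y = np.array([p.reference.dtccs for p in subset_pairs], dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("all measured CCS values identical; cannot fit a line")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CorrectionFunction(
        lipid_class=subset_pairs[0].lipid_class,
        adduct=subset_pairs[0].adduct,
        subset_ids=frozenset(p.reference.species.name for p in subset_pairs),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(r_squared, 1.0)),
        n_points=n,
        function_index=function_index,
    )


def apply_correction(fn: CorrectionFunction, ccs_measured: float) -> float:
    """Corrected CCS: plug the measured value into the affine function."""
    if ccs_measured <= 0:
        raise ValueError("ccs_measured must be positive")
    return fn.slope * ccs_measured + fn.intercept


def flag_poor_functions(
    fns: Iterable[CorrectionFunction],
    slope_band: tuple[float, float] = DEFAULT_SLOPE_BAND,
    r2_min: float = DEFAULT_R2_MIN,
) -> list[CorrectionFunction]:
    """Flag functions with an implausible slope or a poor linear fit.

    A slope far from 1 (the published poor examples were 0.01, 0.46 and
    2.42) indicates the subset does not carry a usable linear relationship.
    Flagged functions stay in reports but are excluded from point estimates.
    """
    lo, hi = slope_band
    out = []
    for fn in fns:
        reasons = []
        if not (lo <= fn.slope <= hi):
            reasons.append(f"slope {fn.slope:.3f} outside [{lo}, {hi}]")
        if fn.r_squared < r2_min:
            reasons.append(f"r2 {fn.r_squared:.4f} < {r2_min}")
        fn.flagged = bool(reasons)
        fn.flag_reason = "; ".join(reasons)
        out.append(fn)
    return out


def evaluate_corrections(
    fns: Sequence[CorrectionFunction], pairs: Sequence[MatchedPair]
) -> tuple[list[float], list[float]]:
    """Before/after bias distributions for labeled lipids of one group.

    Fills each function's ``mean_after_bias`` (over the labeled lipids) and
    returns ``(before_biases, after_biases)`` where the after distribution
    pools labeled lipids across *non-flagged* functions.
    """
    before = [p.bias_pct for p in pairs]
    after: list[float] = []
    for fn in fns:
        fn_biases = [
            ccs_bias_percent(apply_correction(fn, p.measured.ccs_measured), p.reference.dtccs)
            for p in pairs
        ]
        fn.mean_after_bias = statistics.fmean(fn_biases) if fn_biases else None
        if not fn.flagged:
            after.extend(fn_biases)
    return before, after


# ---------------------------------------------------------------------------
# High-level workflow


def correct_group(
    pairs: Sequence[MatchedPair],
    group_ions: Sequence[MeasuredIon],
    k_min: int = 3,
    k_max: int = 6,
    cap: int = 100,
    seed: int = 0,
    slope_band: tuple[float, float] = DEFAULT_SLOPE_BAND,
    r2_min: float = DEFAULT_R2_MIN,
) -> GroupCorrection:
    """Build, flag and apply the correction ensemble for one group.

    ``pairs`` are the matched labeled lipids of one class-adduct combination
    (used for fitting and bias evaluation); ``group_ions`` are all measured
    ions of the combination, labeled and unlabeled, that receive corrected
    values.
    """
    by_name = {p.reference.species.name: p for p in pairs}
    ids = sorted(by_name)
    subsets = enumerate_subsets(ids, k_min=k_min, k_max=k_max, cap=cap, seed=seed)
    fns = [
        fit_correction([by_name[name] for name in subset], function_index=i + 1)
        for i, subset in enumerate(subsets)
    ]
    fns = flag_poor_functions(fns, slope_band=slope_band, r2_min=r2_min)
    if all(fn.flagged for fn in fns):
        # never leave a group without a usable function: keep the best slope
        best = min(fns, key=lambda f: abs(f.slope - 1.0))
        best.flagged = False
        best.flag_reason += "; retained as least-poor function"
    before, after = evaluate_corrections(fns, pairs)

    usable = [fn for fn in fns if not fn.flagged]
    lipids: list[LipidCorrection] = []
    for ion in group_ions:
        corrected = [apply_correction(fn, ion.ccs_measured) for fn in usable]
        point = statistics.median(corrected)
        pair = by_name.get(ion.species.name) if ion.labeled else None
        lipids.append(
            LipidCorrection(
                lipid_name=ion.species.name,
                adduct=ion.adduct.name,
                labeled=ion.labeled,
                ccs_input=ion.ccs_measured,
                corrected=corrected,
                point_estimate=point,
                bias_before=pair.bias_pct if pair else None,
                bias_after=[
                    ccs_bias_percent(c, pair.reference.dtccs) for c in corrected
                ]
                if pair
                else None,
            )
        )
    return GroupCorrection(
        lipid_class=pairs[0].lipid_class,
        adduct=pairs[0].adduct,
        functions=fns,
        lipids=lipids,
        before_biases=before,
        after_biases=after,
    )


def correct_dataset(
    measured: Sequence[MeasuredIon],
    library,
    mode: Literal["per-file", "mean"] = "mean",
    k_min: int = 3,
    k_max: int = 6,
    cap: int = 100,
    seed: int = 0,
    slope_band: tuple[float, float] = DEFAULT_SLOPE_BAND,
    r2_min: float = DEFAULT_R2_MIN,
) -> list[GroupCorrection]:
    """Run the full correction workflow over a measured dataset.

    In ``mean`` mode measured CCS values are first averaged per ion across
    files (the granularity used when correcting the mean of a measurement
    sequence); ``per-file`` keeps every file's values.  All lipids of an
    eligible class-adduct combination are corrected irrespective of labeling.
    """
    from .bias import match_to_library

    ions = mean_measured(measured) if mode == "mean" else list(measured)
    pairs, _ = match_to_library(ions, library)
    groups = eligible_groups(pairs)
    results: list[GroupCorrection] = []
    for cls, adduct, _n in groups:
        group_pairs = [p for p in pairs if p.lipid_class == cls and p.adduct == adduct]
        # deduplicate labeled pairs per species for fitting (per-file mode may
        # carry replicates): average measured CCS per species
        if mode == "per-file":
            group_pairs = _dedup_pairs(group_pairs)
        group_ions = [
            m
            for m in ions
            if m.species.lipid_class.value == cls and m.adduct.name == adduct
        ]
        results.append(
            correct_group(
                group_pairs,
                group_ions,
                k_min=k_min,
                k_max=k_max,
                cap=cap,
                seed=seed,
                slope_band=slope_band,
                r2_min=r2_min,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Report tables (roles: correction functions / corrected CCS / bias summaries)


def functions_frame(results: Sequence[GroupCorrection]):
    """One row per correction function: coefficients, diagnostics, flag."""
    import pandas as pd

    rows = []
    for g in results:
        for fn in g.functions:
            rows.append(
                {
                    "lipid_class": g.lipid_class,
                    "adduct": g.adduct,
                    "function_index": fn.function_index,
                    "n_points": fn.n_points,
                    "subset": "|".join(sorted(fn.subset_ids)),
                    "slope": round(fn.slope, 6),
                    "intercept": round(fn.intercept, 4),
                    "r_squared": round(fn.r_squared, 6),
                    "mean_after_bias_pct": round(fn.mean_after_bias, 4)
                    if fn.mean_after_bias is not None
                    else "",
                    "flagged": fn.flagged,
                    "flag_reason": fn.flag_reason,
                }
            )
    return pd.DataFrame(rows)


def corrected_frame(results: Sequence[GroupCorrection]):
    """One row per corrected lipid: input CCS, point estimate, ensemble span."""
    import pandas as pd

    rows = []
    for g in results:
        for lip in g.lipids:
            rows.append(
                {
                    "lipid_class": g.lipid_class,
                    "adduct": g.adduct,
                    "lipid_name": lip.lipid_name,
                    "label": "U13C" if lip.labeled else "12C",
                    "ccs_input": round(lip.ccs_input, 4),
                    "ccs_corrected": round(lip.point_estimate, 4),
                    "n_functions": len(lip.corrected),
                    "ccs_corrected_min": round(min(lip.corrected), 4),
                    "ccs_corrected_max": round(max(lip.corrected), 4),
                    "bias_before_pct": round(lip.bias_before, 4)
                    if lip.bias_before is not None
                    else "",
                }
            )
    return pd.DataFrame(rows)


def group_bias_frame(results: Sequence[GroupCorrection]):
    """Before/after bias summary per class-adduct combination."""
    import pandas as pd

    rows = []
    for g in results:
        rows.append(
            {
                "lipid_class": g.lipid_class,
                "adduct": g.adduct,
                "n_standards": len(g.before_biases),
                "n_functions": len(g.functions),
                "n_flagged": sum(fn.flagged for fn in g.functions),
                "mean_bias_before_pct": round(g.mean_bias_before, 4),
                "mean_abs_bias_before_pct": round(g.mean_abs_bias_before, 4),
                "mean_bias_after_pct": round(g.mean_bias_after, 4),
                "mean_abs_bias_after_pct": round(g.mean_abs_bias_after, 4),
            }
        )
    return pd.DataFrame(rows)


def _dedup_pairs(pairs: Sequence[MatchedPair]) -> list[MatchedPair]:
    groups: dict[str, list[MatchedPair]] = {}
    for p in pairs:
        groups.setdefault(p.reference.species.name, []).append(p)
    out = []
    for name in sorted(groups):
        ps = groups[name]
        m0 = ps[0].measured
        mean_ion = MeasuredIon(
            file_id="mean",
            species=m0.species,
            adduct=m0.adduct,
            measured_mz=statistics.fmean(p.measured.measured_mz for p in ps),
            rt=statistics.fmean(p.measured.rt for p in ps),
            ccs_measured=statistics.fmean(p.measured.ccs_measured for p in ps),
        )
        out.append(MatchedPair(measured=mean_ion, reference=ps[0].reference))
    return out
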