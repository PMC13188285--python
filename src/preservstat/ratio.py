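"""Material-stratified permutation test for treatment effects on scalar metrics.

The statistic: for each source material, take the ratio of the metric's mean
in the numerator treatment (dried) to its mean in the denominator treatment
(frozen), then average those per-material ratios.  An average ratio above
(below) 1 indicates an overall positive (negative) effect of the numerator
treatment.  Forming ratios within materials before averaging controls for
baseline differences between materials.

The null model permutes treatment labels independently within each material,
preserving per-material group sizes, thereby breaking any metric-treatment
association while keeping material structure intact.  When the number of
distinct stratified label assignments is small the null is enumerated
exhaustively and the p-value is the exact tail fraction; otherwise the null
is sampled (Monte-Carlo) and p uses the (b+1)/(N+1) estimator, which is
always positive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd

from .study import StudyTable, ValidationError

__all__ = [
    "RatioTestResult",
    "average_ratio",
    "count_stratified_assignments",
    "ratio_permutation_test",
    "metric_ratio_summary",
    "benjamini_hochberg",
]

SIDEDNESS_OPTIONS = ("two_sided", "less", "greater")
DEFAULT_EXHAUSTIVE_LIMIT = 100_000

NULL_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass(frozen=True)
class RatioTestResult:
    """Outcome of the stratified ratio permutation test for one metric."""

    metric: str
    per_material_ratios: dict[str, float]
    average_ratio: float
    p_value: float
    n_permutations: int
    mode: str  # "exhaustive" | "monte_carlo"
    sidedness: str
    null_mean: float
    null_sd: float
    null_quantiles: dict[float, float]
    n_dropped_missing: int = 0
    average: str = "arithmetic"


def _material_groups(
    study: StudyTable, metric: str, numerator: str, denominator: str
) -> tuple[list[str], list[np.ndarray], list[int], int]:
    """Per-material pooled values with the numerator-treatment count first.

    Returns (materials, pooled value arrays [numerator values first],
    numerator counts, number of samples dropped for missing values).
    """
    vals = study.metric(metric)
    df = study.data
    treatments = df["treatment"].astype(str)
    for t in (numerator, denominator):
        if t not in set(treatments):
            raise ValidationError(
                f"treatment {t!r} absent; available: {sorted(set(treatments))}"
            )
    mask = treatments.isin([numerator, denominator]).to_numpy()
    values = vals.to_numpy()
    missing = np.isnan(values) & mask
    n_dropped = int(missing.sum())
    mask &= ~np.isnan(values)

    materials, pooled, k_num = [], [], []
    for m in dict.fromkeys(df["material"].astype(str)):
        sel = mask & (df["material"].astype(str) == m).to_numpy()
        is_num = sel & (treatments == numerator).to_numpy()
        is_den = sel & (treatments == denominator).to_numpy()
        if not is_num.any() or not is_den.any():
            raise ValidationError(
                f"material {m!r} lacks non-missing {metric!r} values in both treatments"
            )
        materials.append(m)
        pooled.append(np.concatenate([values[is_num], values[is_den]]))
        k_num.append(int(is_num.sum()))
    return materials, pooled, k_num, n_dropped


def _avg(ratios: np.ndarray, average: str) -> np.ndarray:
    if average == "arithmetic":
        return np.mean(ratios, axis=0)
    if average == "geometric":
        return np.exp(np.mean(np.log(ratios), axis=0))
    raise ValueError(f"unknown averaging {average!r}")


def average_ratio(
    study: StudyTable,
    metric: str,
    numerator_treatment: str = "dried",
    denominator_treatment: str = "frozen",
    average: str = "arithmetic",
) -> tuple[dict[str, float], float]:
    """Per-material mean ratios (numerator/denominator) and their average."""
    materials, pooled, k_num, _ = _material_groups(
        study, metric, numerator_treatment, denominator_treatment
    )
    ratios = {}
    for m, v, k in zip(materials, pooled, k_num):
        den = v[k:].mean()
        if den == 0.0:
            raise ValidationError(
                f"zero {denominator_treatment!r} mean for material {m!r}"
            )
        ratios[m] = v[:k].mean() / den
    avg = float(_avg(np.array(list(ratios.values())), average))
    return ratios, avg


def count_stratified_assignments(
    study: StudyTable,
    numerator_treatment: str = "dried",
    denominator_treatment: str = "frozen",
    metric: str | None = None,
) -> int:
    """Number of distinct within-material treatment-label assignments.

    The product over materials of C(n_m, k_m), where n_m is the material's
    sample count and k_m its numerator-treatment count.  When ``metric`` is
    given, samples missing that metric are excluded first (matching the test).
    """
    if metric is not None:
        _, pooled, k_num, _ = _material_groups(
            study, metric, numerator_treatment, denominator_treatment
        )
        return int(
            np.prod([math.comb(len(v), k) for v, k in zip(pooled, k_num)], dtype=object)
        )
    total = 1
    df = study.data
    treatments = df["treatment"].astype(str)
    for m in dict.fromkeys(df["material"].astype(str)):
        sel = (df["material"].astype(str) == m).to_numpy() & treatments.isin(
            [numerator_treatment, denominator_treatment]
        ).to_numpy()
        k = int((treatments[sel] == numerator_treatment).sum())
        total *= math.comb(int(sel.sum()), k)
    return total


def _material_null_ratios(v: np.ndarray, k: int) -> np.ndarray:
    """Mean ratio for every C(n, k) split of pooled values v (first k = numerator)."""
    n = len(v)
    total = v.sum()
    out = np.empty(math.comb(n, k))
    for i, idx in enumerate(itertools.combinations(range(n), k)):
        num = v[list(idx)].sum() / k
        den = (total - v[list(idx)].sum()) / (n - k)
        out[i] = num / den
    return out


def _extremity_count(null_avg: np.ndarray, observed: float, sidedness: str) -> int:
    """Count null averages at least as extreme as the observed one (ties count)."""
    if sidedness == "two_sided":
        if observed <= 0 or (null_avg <= 0).any():
            raise ValidationError(
                "two-sided log-scale extremity requires positive average ratios"
            )
        return int((np.abs(np.log(null_avg)) >= np.abs(np.log(observed)) - 1e-12).sum())
    if sidedness == "less":
        return int((null_avg <= observed + 1e-12).sum())
    if sidedness == "greater":
        return int((null_avg >= observed - 1e-12).sum())
    raise ValueError(f"sidedness must be one of {SIDEDNESS_OPTIONS}")


def ratio_permutation_test(
    study: StudyTable,
    metric: str,
    numerator_treatment: str = "dried",
    denominator_treatment: str = "frozen",
    n_perm: int = 10_000,
    sidedness: str = "two_sided",
    seed: int | None = None,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    average: str = "arithmetic",
) -> RatioTestResult:
    """Test the average treatment ratio against the stratified permutation null.

    Two-sided extremity is measured on the log scale (|ln avg-ratio|); ties
    count as extreme.  With at most ``exhaustive_limit`` distinct stratified
    assignments the null is enumerated exactly and p is the exact tail
    fraction; otherwise ``n_perm`` Monte-Carlo draws are used with the
    (b+1)/(N+1) estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sidedness not in SIDEDNESS_OPTIONS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS_OPTIONS}")
    materials, pooled, k_num, n_dropped = _material_groups(
        study, metric, numerator_treatment, denominator_treatment
    )
    per_material, observed = average_ratio(
        study, metric, numerator_treatment, denominator_treatment, average
    )

    n_assign = int(
        np.prod([math.comb(len(v), k) for v, k in zip(pooled, k_num)], dtype=object)
    )
    if n_assign <= exhaustive_limit:
        mode = "exhaustive"
        per_mat_nulls = [_material_null_ratios(v, k) for v, k in zip(pooled, k_num)]
        if average == "arithmetic":
            sums = reduce(np.add.outer, per_mat_nulls).ravel()
            null_avg = sums / len(per_mat_nulls)
        else:
            sums = reduce(np.add.outer, [np.log(r) for r in per_mat_nulls]).ravel()
            null_avg = np.exp(sums / len(per_mat_nulls))
        n_used = n_assign
        p = _extremity_count(null_avg, observed, sidedness) / n_assign
    else:
        mode = "monte_carlo"
        rng = np.random.default_rng(seed)
        ratios = np.empty((len(materials), n_perm))
        for i, (v, k) in enumerate(zip(pooled, k_num)):
            n = len(v)
            # first-k columns of a random permutation per replicate
            order = np.argsort(rng.random((n_perm, n)), axis=1)
            chosen = v[order[:, :k]].sum(axis=1)
            ratios[i] = (chosen / k) / ((v.sum() - chosen) / (n - k))
        null_avg = _avg(ratios, average)
        n_used = n_perm
        p = (1 + _extremity_count(null_avg, observed, sidedness)) / (1 + n_perm)

    qs = np.quantile(null_avg, NULL_QUANTILES)
    return RatioTestResult(
        metric=metric,
        per_material_ratios=per_material,
        average_ratio=observed,
        p_value=float(p),
        n_permutations=n_used,
        mode=mode,
        sidedness=sidedness,
        null_mean=float(null_avg.mean()),
        null_sd=float(null_avg.std(ddof=1)) if len(null_avg) > 1 else 0.0,
        null_quantiles=dict(zip(NULL_QUANTILES, map(float, qs))),
        n_dropped_missing=n_dropped,
        average=average,
    )


def metric_ratio_summary(
    study: StudyTable,
    metrics: list[str] | None = None,
    numerator_treatment: str = "dried",
    denominator_treatment: str = "frozen",
    n_perm: int = 10_000,
    sidedness: str = "two_sided",
    seed: int | None = None,
    adjust: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Ratio test over several metrics; one row per metric (Table-S2 style).

    ``adjust=True`` appends Benjamini-Hochberg adjusted p-values (off by
    default: results are conventionally reported per metric).
    """
    metrics = list(metrics) if metrics is not None else list(study.metric_names)
    rows = []
    for i, metric in enumerate(metrics):
        res = ratio_permutation_test(
            study,
            metric,
            numerator_treatment,
            denominator_treatment,
            n_perm=n_perm,
            sidedness=sidedness,
            seed=None if seed is None else seed + i,
            **kwargs,
        )
        row = {"metric": metric}
        row.update({f"ratio[{m}]": r for m, r in res.per_material_ratios.items()})
        row.update(
            average_ratio=res.average_ratio,
            p_value=res.p_value,
            mode=res.mode,
            n_permutations=res.n_permutations,
            n_dropped_missing=res.n_dropped_missing,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
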