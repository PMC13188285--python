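"""Treatment-consistency test on feature proportions within one material.

For one source material, each feature's mean proportion is computed
separately over the dried and frozen replicates; agreement between the two
treatments is summarized as the squared Pearson correlation (r²) of the
log-transformed mean proportions across features.  Perfect consistency (no
treatment effect, no noise) puts every feature on the diagonal and gives
r² = 1.

The permutation null reassigns treatment labels among that material's
samples (preserving group sizes) — material identity is never broken — and
the p-value is the probability that the null generates a *lower* r² than
observed, i.e. less consistency between the shuffled "treatments" than
between the real ones.  A low p means the real treatments disagree more than
replicate-level noise alone explains.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .diversity import threshold_filter
from .study import FeatureTable, StudyTable, ValidationError, to_proportions

__all__ = [
    "ConsistencyResult",
    "treatment_mean_proportions",
    "log_r2",
    "consistency_permutation_test",
]

ZERO_POLICIES = ("half_min_pseudocount", "drop")
DEFAULT_EXHAUSTIVE_LIMIT = 100_000


@dataclass(frozen=True)
class ConsistencyResult:
    r_squared: float
    n_features: int
    p_value: float
    n_permutations: int
    mode: str  # "exhaustive" | "monte_carlo"
    material: str
    feature_ids: tuple[str, ...]
    dried_means: np.ndarray
    frozen_means: np.ndarray
    zero_policy_used: str


def _material_matrix(
    table: FeatureTable,
    study: StudyTable,
    material: str,
    treatments: tuple[str, str],
) -> tuple[np.ndarray, int, FeatureTable]:
    """Proportion submatrix for one material, numerator-treatment columns first."""
    sub = study.subset(materials=[material])
    cols = []
    k = 0
    for t in treatments:
        ids = [s for s, tt in zip(sub.sample_ids, sub.data["treatment"].astype(str)) if tt == t]
        missing = [s for s in ids if s not in table.sample_ids]
        if missing:
            raise ValidationError(
                f"samples {missing} of material {material!r} absent from feature table"
            )
        if not ids:
            raise ValidationError(
                f"material {material!r} has no {t!r} samples"
            )
        if t == treatments[0]:
            k = len(ids)
        cols.extend(ids)
    ordered = table.subset_samples(cols)
    # subset_samples preserves the table's column order; re-order explicitly
    idx = [ordered.sample_ids.index(s) for s in cols]
    sub_table = FeatureTable(
        ordered.feature_ids,
        tuple(cols),
        ordered.values[:, idx],
        ordered.kind,
    )
    if sub_table.kind != "proportions":
        sub_table = to_proportions(sub_table)
    return sub_table.values, k, sub_table


def treatment_mean_proportions(
    table: FeatureTable,
    study: StudyTable,
    material: str,
    treatments: tuple[str, str] = ("dried", "frozen"),
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Per-feature mean proportions for each treatment within one material.

    Returns (numerator means, denominator means, feature_ids), aligned.
    """
    v, k, sub = _material_matrix(table, study, material, treatments)
    return v[:, :k].mean(axis=1), v[:, k:].mean(axis=1), sub.feature_ids


def _adjust_zeros(
    x: np.ndarray, y: np.ndarray, zero_policy: str
) -> tuple[np.ndarray, np.ndarray]:
    if zero_policy == "half_min_pseudocount":
        pooled = np.concatenate([x, y])
        nonzero = pooled[pooled > 0]
        if nonzero.size == 0:
            raise ValidationError("all mean proportions are zero")
        eps = 0.5 * nonzero.min()
        return np.where(x > 0, x, eps), np.where(y > 0, y, eps)
    if zero_policy == "drop":
        keep = (x > 0) & (y > 0)
        return x[keep], y[keep]
    raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}")


def log_r2(
    x: np.ndarray,
    y: np.ndarray,
    zero_policy: str = "half_min_pseudocount",
) -> float:
    """Squared Pearson correlation of ln(x) vs ln(y) after zero adjustment.

    ``half_min_pseudocount`` replaces zero entries by half the smallest
    nonzero value of the pooled pair; ``drop`` removes features that are zero
    in either vector.  At least 3 usable features and nonzero variance in
    both log-vectors are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("mean-proportion vectors must be aligned")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("mean proportions must be nonnegative")
    xa, ya = _adjust_zeros(x, y, zero_policy)
    if xa.size < 3:
        raise ValidationError(
            f"only {xa.size} usable features after zero handling (need >= 3)"
        )
    lx, ly = np.log(xa), np.log(ya)
    if np.ptp(lx) == 0.0 or np.ptp(ly) == 0.0:
        raise ValidationError("zero variance in log mean proportions; r2 undefined")
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r * r)


def consistency_permutation_test(
    table: FeatureTable,
    study: StudyTable,
    material: str,
    min_prop: float = 1e-4,
    n_perm: int = 9_999,
    seed: int | None = None,
    treatments: tuple[str, str] = ("dried", "frozen"),
    zero_policy: str = "half_min_pseudocount",
    threshold_mode: str = "per_sample",
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> ConsistencyResult:
    """Permutation test of between-treatment consistency (lower-tail on r²).

    The abundance threshold (``min_prop``, default 0.01%) is applied to the
    material's samples before testing.  Extremity is *strictly* lower: the
    p-value estimates the probability that label shuffling alone yields a
    lower r² than observed.  With C(n, k) distinct assignments at most
    ``exhaustive_limit`` the null is enumerated exactly (p = exact fraction,
    which can be 0); otherwise Monte-Carlo with the (b+1)/(N+1) estimator.
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}")
    mat_samples = study.subset(materials=[material]).sample_ids
    sub_study = study.subset(materials=[material])
    t = table.subset_samples([s for s in mat_samples if s in table.sample_ids])
    if t.kind != "proportions":
        t = to_proportions(t)
    if min_prop > 0:
        t = threshold_filter(
            t, min_prop, mode=threshold_mode, study=sub_study, group_col="treatment"
        )
    v, k, sub = _material_matrix(t, study, material, treatments)
    n = v.shape[1]

    def r2_for(cols_num: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[cols_num] = True
        return log_r2(v[:, mask].mean(axis=1), v[:, ~mask].mean(axis=1), zero_policy)

    observed = r2_for(np.arange(k))
    x_means, y_means = v[:, :k].mean(axis=1), v[:, k:].mean(axis=1)

    n_assign = math.comb(n, k)
    if n_assign <= exhaustive_limit:
        mode = "exhaustive"
        null = np.array(
            [r2_for(np.array(c)) for c in itertools.combinations(range(n), k)]
        )
        n_used = n_assign
        p = float((null < observed - 1e-12).sum() / n_assign)
    else:
        mode = "monte_carlo"
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = r2_for(rng.choice(n, size=k, replace=False))
        n_used = n_perm
        p = float((1 + (null < observed - 1e-12).sum()) / (1 + n_perm))

    return ConsistencyResult(
        r_squared=observed,
        n_features=sub.n_features,
        p_value=p,
        n_permutations=n_used,
        mode=mode,
        material=material,
        feature_ids=sub.feature_ids,
        dried_means=x_means,
        frozen_means=y_means,
        zero_policy_used=zero_policy,
    )
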