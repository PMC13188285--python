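"""Beta-diversity machinery: Bray-Curtis, PERMANOVA, metric MDS.

PERMANOVA follows the classic distance-based sum-of-squares decomposition:
with N samples in a groups, SS_total = (1/N) * sum_{i<j} d_ij^2,
SS_within = sum over groups g of (1/n_g) * sum_{i<j in g} d_ij^2,
SS_between = SS_total - SS_within, and
pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).  Significance comes from
uniform permutation of group labels; the standardized effect size (SES) is
(F_obs - mean F_null) / sd F_null.

Metric MDS minimizes raw stress sum_{i<j} (d_ij - dhat_ij)^2 by iterative
majorization (SMACOF/Guttman transform) from a classical-scaling start plus
random restarts, and reports Kruskal stress-1 =
sqrt(sum (d - dhat)^2 / sum d^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .study import FeatureTable, ValidationError, to_proportions

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "OrdinationResult",
    "bray_curtis",
    "dissimilarity_matrix",
    "permanova",
    "mmds",
]

DEFAULT_EXHAUSTIVE_LIMIT = 100_000


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    sample_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(d)):
            raise ValidationError("non-finite distance")
        if (d < 0).any():
            raise ValidationError("negative distance")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("nonzero diagonal")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("asymmetric distance matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    ses: float
    n_permutations: int
    n_groups: int
    mode: str  # "exhaustive" | "monte_carlo"


@dataclass(frozen=True)
class OrdinationResult:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # N x k
    stress: float  # Kruskal stress-1
    n_restarts_used: int
    converged: bool


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Abundance-weighted Bray-Curtis: sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be nonnegative")
    denom = (x + y).sum()
    if denom == 0.0:
        raise ValidationError("both vectors are all-zero; Bray-Curtis undefined")
    return float(np.abs(x - y).sum() / denom)


def dissimilarity_matrix(table: FeatureTable) -> DistanceMatrix:
    """All pairwise Bray-Curtis dissimilarities between sample columns.

    Count tables are normalized to proportions first, so the result is the
    abundance-weighted dissimilarity of relative compositions.
    """
    t = table if table.kind == "proportions" else to_proportions(table)
    v = t.values
    n = t.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(v[:, i : i + 1] - v[:, i + 1 :]).sum(axis=0)
        sums = (v[:, i : i + 1] + v[:, i + 1 :]).sum(axis=0)
        if (sums == 0).any():
            raise ValidationError("all-zero sample column")
        d[i, i + 1 :] = diff / sums
    d = d + d.T
    return DistanceMatrix(t.sample_ids, d)


def _group_indicators(labels: list[str]) -> tuple[list[str], np.ndarray]:
    levels = list(dict.fromkeys(labels))
    z = np.array([[lab == g for lab in labels] for g in levels], dtype=float)
    return levels, z


def _pseudo_f(a2: np.ndarray, z: np.ndarray, n: int, a: int) -> tuple[float, float]:
    """(pseudo-F, R^2) from the squared-distance matrix and group indicators z (a x N)."""
    ss_total = a2.sum() / (2.0 * n)
    sizes = z.sum(axis=1)
    ss_within = sum(
        (z[g] @ a2 @ z[g]) / (2.0 * sizes[g]) for g in range(a)
    )
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_within <= 0.0:
        return math.inf, r2
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return float(f), float(r2)


def permanova(
    dm: DistanceMatrix,
    labels: list[str] | dict[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``labels`` gives one group label per sample (list aligned to
    ``dm.sample_ids``, or a mapping sample_id -> label).  Labels are permuted
    uniformly across all samples; with few distinct label arrangements
    (<= ``exhaustive_limit``) the null is enumerated exactly.
    """
    if isinstance(labels, dict):
        labels = [labels[s] for s in dm.sample_ids]
    labels = [str(l) for l in labels]
    n = dm.n_samples
    if len(labels) != n:
        raise ValueError("one label per sample required")
    levels, z = _group_indicators(labels)
    a = len(levels)
    if a < 2:
        raise ValidationError("PERMANOVA requires >= 2 groups")
    sizes = z.sum(axis=1).astype(int)
    if (sizes < 2).any():
        small = [g for g, s in zip(levels, sizes) if s < 2]
        raise ValidationError(f"group(s) {small} have fewer than 2 samples")

    a2 = dm.d**2
    f_obs, r2 = _pseudo_f(a2, z, n, a)

    n_arrangements = math.factorial(n)
    for s in sizes:
        n_arrangements //= math.factorial(int(s))
    if n_arrangements <= exhaustive_limit:
        from sympy.utilities.iterables import multiset_permutations

        mode = "exhaustive"
        f_null = np.array(
            [
                _pseudo_f(a2, _group_indicators(list(perm))[1], n, a)[0]
                for perm in multiset_permutations(labels)
            ]
        )
        n_used = n_arrangements
        p = float((f_null >= f_obs - 1e-12).sum() / n_arrangements)
    else:
        mode = "monte_carlo"
        rng = np.random.default_rng(seed)
        lab_arr = np.array(labels)
        f_null = np.empty(n_perm)
        for i in range(n_perm):
            perm = lab_arr[rng.permutation(n)]
            zp = np.array([perm == g for g in levels], dtype=float)
            f_null[i] = _pseudo_f(a2, zp, n, a)[0]
        n_used = n_perm
        p = float((1 + (f_null >= f_obs - 1e-12).sum()) / (1 + n_perm))

    finite = f_null[np.isfinite(f_null)]
    sd = finite.std(ddof=1) if finite.size > 1 else 0.0
    ses = (f_obs - finite.mean()) / sd if sd > 0 and math.isfinite(f_obs) else math.nan
    return PermanovaResult(
        pseudo_f=f_obs,
        r_squared=r2,
        p_value=p,
        ses=float(ses),
        n_permutations=n_used,
        n_groups=a,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Metric MDS (SMACOF)
# ---------------------------------------------------------------------------


def _raw_stress(d: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    delta = _euclidean(x)
    iu = np.triu_indices_from(d, k=1)
    return float(((d[iu] - delta[iu]) ** 2).sum()), delta


def _euclidean(x: np.ndarray) -> np.ndarray:
    sq = (x**2).sum(axis=1)
    g = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.clip(g, 0.0, None, out=g)
    return np.sqrt(g)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def _smacof_run(
    d: np.ndarray, x0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, bool]:
    n = d.shape[0]
    x = x0.copy()
    stress, delta = _raw_stress(d, x)
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, d / delta, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n  # Guttman transform
        new_stress, delta = _raw_stress(d, x)
        if stress - new_stress <= tol * max(stress, 1e-300):
            stress = new_stress
            converged = True
            break
        stress = new_stress
    return x, stress, converged


def mmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 10,
    tol: float = 1e-9,
    max_iter: int = 1000,
    seed: int | None = None,
) -> OrdinationResult:
    """Metric MDS embedding minimizing the Kruskal stress function.

    The first start is classical scaling (PCoA) of the input dissimilarities;
    the remaining ``n_restarts - 1`` starts are random.  Raw stress is
    non-increasing within each majorization run; the best run (lowest raw
    stress) is returned, with Kruskal stress-1 reported.
    """
    d = dm.d
    n = dm.n_samples
    if n < k + 1:
        raise ValidationError(f"need at least k+1 = {k + 1} samples, got {n}")
    iu = np.triu_indices(n, k=1)
    total = (d[iu] ** 2).sum()
    if total == 0.0:
        raise ValidationError("all dissimilarities are zero; ordination undefined")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    scale = d[iu].mean()
    best = None
    for r in range(n_restarts):
        x0 = (
            _classical_scaling(d, k)
            if r == 0
            else rng.normal(scale=scale, size=(n, k))
        )
        x, stress, conv = _smacof_run(d, x0, tol, max_iter)
        if best is None or stress < best[1]:
            best = (x, stress, conv)
    x, raw, conv = best
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=x,
        stress=float(np.sqrt(raw / total)),
        n_restarts_used=n_restarts,
        converged=conv,
    )
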