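"""Synthetic study designs, scalar metrics and compositional feature tables.

The generators emulate the paired-preservation design: M source materials,
each contributing R replicate samples per treatment (dried vs frozen).
Scalar metrics are positive with material-specific baselines, a
multiplicative treatment effect delta on the dried group and log-normal
replicate noise — the structure the ratio-of-means statistic targets.
Community tables draw per-taxon log-abundances with material-specific
offsets, add a fixed log fold-change to a random subset of taxa in dried
samples, and sample multinomial read counts at a chosen depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study import FeatureTable, StudyTable

__all__ = [
    "MetricSimParams",
    "CommunitySimParams",
    "simulate_metric_table",
    "simulate_communities",
]

TREATMENTS = ("dried", "frozen")


def _default_baselines(n_materials: int) -> np.ndarray:
    # spread baselines over two orders of magnitude, like DNA yields across
    # heterogeneous source materials
    return np.logspace(1.0, 3.0, n_materials)


@dataclass(frozen=True)
class MetricSimParams:
    """Design and noise parameters for scalar-metric simulation.

    ``delta`` multiplies the dried group (delta = 1 is the null);
    ``noise_sigma`` is the standard deviation of log-normal replicate noise.
    """

    n_materials: int = 6
    n_replicates: int = 5
    material_baselines: tuple[float, ...] | None = None
    delta: float = 1.0
    noise_sigma: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_materials < 1 or self.n_replicates < 1:
            raise ValueError("need at least one material and one replicate")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        baselines = (
            _default_baselines(self.n_materials)
            if self.material_baselines is None
            else np.asarray(self.material_baselines, dtype=float)
        )
        if baselines.shape != (self.n_materials,) or (baselines <= 0).any():
            raise ValueError("material_baselines must be positive, one per material")
        object.__setattr__(self, "material_baselines", tuple(baselines))


@dataclass(frozen=True)
class CommunitySimParams:
    """Parameters for compositional community simulation.

    ``material_divergence`` is the sd of per-(material, taxon) log-abundance
    offsets; ``affected_fraction`` of taxa receive ``effect_log_fc`` extra
    log-abundance in dried samples; ``replicate_sigma`` is per-sample
    replicate noise; ``depth`` is the multinomial read depth.
    """

    n_materials: int = 6
    n_replicates: int = 5
    n_taxa: int = 500
    material_divergence: float = 1.0
    affected_fraction: float = 0.0
    effect_log_fc: float = 0.0
    depth: int = 100_000
    replicate_sigma: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.material_divergence < 0 or self.replicate_sigma < 0:
            raise ValueError("noise scales must be >= 0")


def _design(n_materials: int, n_replicates: int) -> pd.DataFrame:
    rows = []
    for m in range(n_materials):
        material = f"material_{m + 1}"
        for t in TREATMENTS:
            for r in range(n_replicates):
                rows.append(
                    {
                        "sample_id": f"{material}.{t}.{r + 1}",
                        "material": material,
                        "treatment": t,
                    }
                )
    return pd.DataFrame(rows)


def simulate_metric_table(
    params: MetricSimParams, metric_name: str = "metric", seed: int | None = None
) -> StudyTable:
    """Simulate one scalar success metric over the full design.

    value(material m, treatment t) = baseline_m * (delta if dried else 1)
    * exp(sigma * z), z ~ N(0, 1), independently per sample.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    df = _design(params.n_materials, params.n_replicates)
    baselines = dict(
        zip((f"material_{i + 1}" for i in range(params.n_materials)),
            params.material_baselines)
    )
    z = rng.standard_normal(len(df))
    effect = np.where(df["treatment"] == "dried", params.delta, 1.0)
    df[metric_name] = (
        df["material"].map(baselines).to_numpy()
        * effect
        * np.exp(params.noise_sigma * z)
    )
    return StudyTable(df, (metric_name,))


def simulate_communities(
    params: CommunitySimParams,
    seed: int | None = None,
    return_affected: bool = False,
):
    """Simulate a taxon count table plus its study design.

    Log-abundance of taxon i in sample s of material m:
    base_i + offset_{m,i} + (effect_log_fc if s dried and i affected)
    + eps_{s,i}, with base ~ N(0,1), offset ~ N(0, material_divergence),
    eps ~ N(0, replicate_sigma).  Counts ~ multinomial(depth, softmax).
    The affected-taxon subset is drawn once per simulation, so the treatment
    effect is a reproducible community-level signal.  With
    ``return_affected=True`` the affected taxon indices are returned as a
    third element.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    design = _design(params.n_materials, params.n_replicates)
    n_taxa, n_samples = params.n_taxa, len(design)

    base = rng.standard_normal(n_taxa)
    offsets = rng.normal(
        0.0, params.material_divergence, size=(params.n_materials, n_taxa)
    )
    n_affected = int(round(params.affected_fraction * n_taxa))
    affected = rng.choice(n_taxa, size=n_affected, replace=False)

    counts = np.zeros((n_taxa, n_samples), dtype=float)
    material_index = {f"material_{i + 1}": i for i in range(params.n_materials)}
    for j, row in enumerate(design.itertuples()):
        log_abund = base + offsets[material_index[row.material]]
        if row.treatment == "dried" and n_affected:
            log_abund = log_abund.copy()
            log_abund[affected] += params.effect_log_fc
        log_abund = log_abund + rng.normal(0.0, params.replicate_sigma, size=n_taxa)
        p = np.exp(log_abund - log_abund.max())
        p /= p.sum()
        counts[:, j] = rng.multinomial(params.depth, p)

    table = FeatureTable(
        tuple(f"taxon_{i + 1}" for i in range(n_taxa)),
        tuple(design["sample_id"]),
        counts,
        "counts",
    )
    study = StudyTable(design, ())
    if return_affected:
        return table, study, np.sort(affected)
    return table, study
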