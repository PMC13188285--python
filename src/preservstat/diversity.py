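"""Per-sample alpha-diversity metrics and the abundance-threshold filter."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .study import FeatureTable, StudyTable, ValidationError, to_proportions

__all__ = ["MetricVector", "richness", "shannon", "threshold_filter"]


@dataclass(frozen=True)
class MetricVector:
    """One scalar value per sample (e.g. richness or Shannon diversity)."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.sample_ids),):
            raise ValidationError("one value per sample required")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"non-finite {self.metric_name} value")


def richness(table: FeatureTable) -> MetricVector:
    """Number of features present (value > 0) in each sample."""
    counts = (table.values > 0).sum(axis=0)
    return MetricVector(table.sample_ids, counts.astype(float), "richness")


def shannon(table: FeatureTable, base: float | None = None) -> MetricVector:
    """Shannon diversity H = -sum_i p_i log p_i per sample.

    Columns are normalized to proportions internally; the sum runs over
    features with p_i > 0.  Natural log by default (``base`` switches it).
    """
    props = to_proportions(table).values
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    h = -plogp.sum(axis=0)
    h = np.maximum(h, 0.0)  # clip -0.0 / rounding at single-feature columns
    if base is not None:
        h = h / np.log(base)
    return MetricVector(table.sample_ids, h, "shannon")


def threshold_filter(
    table: FeatureTable,
    min_prop: float,
    mode: str = "per_sample",
    study: StudyTable | None = None,
    group_col: str = "treatment",
) -> FeatureTable:
    """Keep features reaching ``min_prop`` relative abundance somewhere.

    ``per_sample`` (default) keeps a feature whose proportion is >= min_prop
    in at least one sample column — the rule used for taxon tables (e.g.
    >=0.01%, i.e. ``min_prop=1e-4``).  ``per_group_mean`` keeps a feature
    whose *group-mean* proportion reaches the threshold in at least one group
    (groups taken from ``study``'s ``group_col``) — the rule used for gene
    tables (>=0.001%, ``min_prop=1e-5``).

    Retained columns are NOT renormalized: values stay interpretable as
    proportions of the original community.
    """
    if not 0.0 <= min_prop < 1.0:
        raise ValueError(f"min_prop must lie in [0, 1), got {min_prop}")
    if table.kind != "proportions":
        raise ValidationError("threshold_filter requires a proportions table")
    if mode == "per_sample":
        keep = (table.values >= min_prop).any(axis=1)
    elif mode == "per_group_mean":
        if study is None:
            raise ValueError("per_group_mean mode requires the study table")
        labels = dict(
            zip(study.data["sample_id"].astype(str), study.data[group_col].astype(str))
        )
        keep = np.zeros(table.n_features, dtype=bool)
        for g in dict.fromkeys(labels.get(s) for s in table.sample_ids):
            cols = [j for j, s in enumerate(table.sample_ids) if labels.get(s) == g]
            if cols:
                keep |= table.values[:, cols].mean(axis=1) >= min_prop
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return table.subset_features(keep)
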