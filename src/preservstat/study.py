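"""Core data containers and TSV readers/writers.

The study design is a set of samples, each belonging to one source *material*
(the blocking factor, e.g. "feces 1" or "soil 2") and one *treatment* (the
preservation method, e.g. "dried" vs "frozen"), with an arbitrary number of
scalar success metrics attached (DNA yield, read counts, richness, ...).
Feature tables hold nonnegative abundances (counts or proportions) of
features (OTUs, ASVs, genera, KOs, KEGG groups) across those samples, in the
classic features-as-rows / samples-as-columns orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "StudyTable",
    "FeatureTable",
    "MagRecord",
    "read_metadata",
    "write_metadata",
    "read_feature_table",
    "write_feature_table",
    "to_proportions",
    "subset",
    "filter_mags",
    "read_mag_table",
]

PROPORTION_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Input violates a data-model invariant (duplicate ids, negative values...)."""


class FormatError(ValueError):
    """File does not conform to the expected tabular layout."""


@dataclass(frozen=True)
class StudyTable:
    """Sample records with material/treatment labels and scalar metrics.

    Parameters
    ----------
    data:
        One row per sample with columns ``sample_id``, ``material``,
        ``treatment`` plus one numeric column per metric.  Missing metric
        values are NaN.
    metric_names:
        Metric columns, in original file order.
    """

    data: pd.DataFrame
    metric_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for col in ("sample_id", "material", "treatment"):
            if col not in self.data.columns:
                raise ValidationError(f"study table lacks required column {col!r}")
        sids = self.data["sample_id"].astype(str)
        if sids.duplicated().any():
            dups = sorted(sids[sids.duplicated()].unique())
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        for col in ("material", "treatment"):
            labels = self.data[col].astype(str)
            if (labels.str.len() == 0).any() or labels.isna().any():
                raise ValidationError(f"empty {col} label in study table")
        for m in self.metric_names:
            vals = self.data[m].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise ValidationError(f"non-finite value in metric {m!r}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].astype(str).tolist()

    @property
    def materials(self) -> list[str]:
        """Distinct material labels, in order of first appearance."""
        return list(dict.fromkeys(self.data["material"].astype(str)))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.data["treatment"].astype(str)))

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def metric(self, name: str) -> pd.Series:
        """Metric values indexed by sample_id (NaN where missing)."""
        if name not in self.metric_names:
            raise KeyError(
                f"unknown metric {name!r}; available: {list(self.metric_names)}"
            )
        return pd.Series(
            self.data[name].to_numpy(dtype=float),
            index=self.data["sample_id"].astype(str),
            name=name,
        )

    def subset(
        self,
        materials: Iterable[str] | None = None,
        treatments: Iterable[str] | None = None,
    ) -> "StudyTable":
        mask = _selection_mask(self.data, materials, treatments)
        return StudyTable(self.data.loc[mask].reset_index(drop=True), self.metric_names)


def _selection_mask(df, materials, treatments) -> np.ndarray:
    mask = np.ones(len(df), dtype=bool)
    for col, wanted in (("material", materials), ("treatment", treatments)):
        if wanted is None:
            continue
        wanted = {str(w) for w in (wanted if not isinstance(wanted, str) else [wanted])}
        have = set(df[col].astype(str))
        unknown = wanted - have
        if unknown:
            raise ValidationError(
                f"unknown {col} label(s) {sorted(unknown)}; available: {sorted(have)}"
            )
        mask &= df[col].astype(str).isin(wanted).to_numpy()
    return mask


@dataclass(frozen=True)
class FeatureTable:
    """Nonnegative features × samples matrix (counts or proportions)."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    kind: str = "counts"  # "counts" | "proportions"

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(map(str, self.feature_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {v.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_ids")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite value in feature table")
        if (v < 0).any():
            i, j = np.argwhere(v < 0)[0]
            raise ValidationError(
                f"negative value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.kind not in ("counts", "proportions"):
            raise ValidationError(f"unknown table kind {self.kind!r}")
        if self.kind == "proportions" and v.shape[1]:
            # Columns sum to 1 within 1e-9; an abundance-filtered table is a
            # subcomposition whose columns may sum to less than 1, never more.
            sums = v.sum(axis=0)
            bad = (sums > 1.0 + 1e-9) | (sums <= 0.0)
            if bad.any():
                j = int(np.argmax(bad))
                raise ValidationError(
                    f"proportion column {self.sample_ids[j]!r} sums to {sums[j]!r}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(str(sample_id))
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return self.values[:, j]

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Columns for the given samples, preserving this table's column order."""
        wanted = set(map(str, sample_ids))
        unknown = wanted - set(self.sample_ids)
        if unknown:
            raise ValidationError(
                f"unknown sample(s) {sorted(unknown)}; available: {list(self.sample_ids)}"
            )
        keep = [j for j, s in enumerate(self.sample_ids) if s in wanted]
        return FeatureTable(
            self.feature_ids,
            tuple(self.sample_ids[j] for j in keep),
            self.values[:, keep],
            self.kind,
        )

    def subset_features(self, keep: np.ndarray) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return FeatureTable(
            tuple(self.feature_ids[i] for i in idx),
            self.sample_ids,
            self.values[idx, :],
            self.kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class MagRecord:
    """A metagenome-assembled genome with checkM-style quality estimates."""

    mag_id: str
    group: str
    completeness: float  # percent, in [0, 100]
    contamination: float  # percent, >= 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"completeness {self.completeness} outside [0, 100] for {self.mag_id!r}"
            )
        if self.contamination < 0.0:
            raise ValidationError(
                f"negative contamination for {self.mag_id!r}"
            )


# ---------------------------------------------------------------------------
# Readers / writers (TSV, UTF-8, '.' decimal, no quoting of ids)
# ---------------------------------------------------------------------------


def read_metadata(
    path: str | Path,
    material_col: str = "material",
    treatment_col: str = "treatment",
) -> StudyTable:
    """Read a sample-metadata TSV into a :class:`StudyTable`.

    The file must carry ``sample_id``, the material column and the treatment
    column; every remaining column is registered as a scalar metric, in file
    order.  Non-numeric metric cells become missing (NaN).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", material_col, treatment_col):
        if col not in df.columns:
            raise FormatError(f"metadata file {path} lacks required column {col!r}")
    metric_cols = [
        c for c in df.columns if c not in ("sample_id", material_col, treatment_col)
    ]
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "material": df[material_col].astype(str),
            "treatment": df[treatment_col].astype(str),
        }
    )
    for c in metric_cols:
        out[c] = pd.to_numeric(df[c], errors="coerce")
    return StudyTable(out, tuple(metric_cols))


def write_metadata(study: StudyTable, path: str | Path) -> None:
    cols = ["sample_id", "material", "treatment", *study.metric_names]
    study.data[cols].to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature TSV (first column = feature id, remaining = samples).

    ``kind`` is inferred as ``proportions`` iff every sample column sums to
    1 within ``1e-6``, else ``counts``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if values.size and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative value at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    kind = "counts"
    if values.shape[1] and np.allclose(values.sum(axis=0), 1.0, atol=PROPORTION_SUM_TOL):
        kind = "proportions"
        values = values / values.sum(axis=0)  # snap to exact unit sums
    return FeatureTable(
        tuple(map(str, df.index)), tuple(map(str, df.columns)), values, kind
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def to_proportions(table: FeatureTable) -> FeatureTable:
    """Normalize each sample column to sum to 1."""
    sums = table.values.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        j = int(np.argmax(zero))
        raise ValidationError(
            f"cannot normalize all-zero sample {table.sample_ids[j]!r}"
        )
    return FeatureTable(
        table.feature_ids, table.sample_ids, table.values / sums, "proportions"
    )


def subset(
    obj: StudyTable | FeatureTable,
    study: StudyTable | None = None,
    materials: Iterable[str] | None = None,
    treatments: Iterable[str] | None = None,
):
    """Select samples by material and/or treatment, preserving order.

    For a :class:`FeatureTable`, the design must be supplied via ``study`` so
    labels can be resolved to sample ids.
    """
    if isinstance(obj, StudyTable):
        return obj.subset(materials, treatments)
    if study is None:
        raise ValueError("subsetting a FeatureTable requires the study table")
    chosen = study.subset(materials, treatments).sample_ids
    keep = [s for s in chosen if s in obj.sample_ids]
    return obj.subset_samples(keep)


def filter_mags(
    mags: Sequence[MagRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[MagRecord]:
    """Medium-or-better quality filter: completeness >= min, contamination <= max.

    Boundaries are inclusive; input order is preserved.
    """
    if not 0.0 <= min_completeness <= 100.0:
        raise ValueError("min_completeness must lie in [0, 100]")
    if max_contamination < 0.0:
        raise ValueError("max_contamination must be >= 0")
    return [
        m
        for m in mags
        if m.completeness >= min_completeness and m.contamination <= max_contamination
    ]


def read_mag_table(path: str | Path) -> list[MagRecord]:
    """Read a MAG quality TSV with columns mag_id, group, completeness, contamination."""
    df = pd.read_csv(path, sep="\t")
    for col in ("mag_id", "group", "completeness", "contamination"):
        if col not in df.columns:
            raise FormatError(f"MAG table {path} lacks required column {col!r}")
    return [
        MagRecord(str(r.mag_id), str(r.group), float(r.completeness), float(r.contamination))
        for r in df.itertuples()
    ]
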