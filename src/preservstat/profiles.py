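"""Gene-centric functional profile arithmetic from tabular mapping outputs.

The pipeline is pure proportion arithmetic over tables produced upstream by
read mapping (MAPQ >= 30 filtered counts per contig), gene prediction
(PCG -> host contig) and HMM annotation (PCG -> KO, E <= 1e-10; KO -> KEGG
level-C group):

1. contig coverage  = mapped reads / contig length, normalized to sum 1 per
   sample ("contig proportions");
2. each PCG inherits its host contig's proportion; PCG values are
   renormalized to sum 1 per sample;
3. a KO's proportion is the sum of proportions of all PCGs mapped to it
   (no renormalization — unannotated PCGs make the KO total fall below 1);
4. a KEGG level-C group's proportion is the sum over its member KOs, with
   the standard non-functional catch-all groups excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .study import FeatureTable, FormatError, ValidationError

__all__ = [
    "ContigCoverageTable",
    "FeatureMap",
    "DEFAULT_EXCLUDED_GROUPS",
    "contig_proportions",
    "pcg_proportions",
    "ko_proportions",
    "kegg_group_proportions",
    "profile_table",
    "read_contig_table",
    "read_two_column_map",
    "read_feature_map",
]

# KEGG level-C groups that are not defined by function; excluded from group
# profiles (matched case-insensitively).
DEFAULT_EXCLUDED_GROUPS = frozenset(
    {
        "brite hierarchies",
        "enzymes with ec numbers",
        "not included in pathway or brite",
        "poorly characterized",
        "general function prediction only",
        "others",
        "unclassified viral proteins",
        "function unknown",
    }
)


@dataclass(frozen=True)
class ContigCoverageTable:
    """Per-contig read counts (MAPQ-filtered upstream) and contig lengths."""

    contig_ids: tuple[str, ...]
    lengths: np.ndarray  # bp, >= 1
    counts: np.ndarray  # contigs x samples, >= 0
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "contig_ids", tuple(map(str, self.contig_ids)))
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        lengths = np.asarray(self.lengths, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "counts", counts)
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise ValidationError("duplicate contig ids")
        if lengths.shape != (len(self.contig_ids),):
            raise ValidationError("one length per contig required")
        if (lengths < 1).any():
            raise ValidationError("contig lengths must be >= 1 bp")
        if counts.shape != (len(self.contig_ids), len(self.sample_ids)):
            raise ValidationError("counts must be contigs x samples")
        if (counts < 0).any() or not np.all(np.isfinite(counts)):
            raise ValidationError("read counts must be finite and nonnegative")


@dataclass(frozen=True)
class FeatureMap:
    """PCG -> contig, PCG -> KO(s) and KO -> KEGG-C group(s) mappings."""

    pcg_to_contig: dict[str, str]
    pcg_to_ko: dict[str, tuple[str, ...]] = field(default_factory=dict)
    ko_to_group: dict[str, tuple[str, ...]] = field(default_factory=dict)
    excluded_groups: frozenset[str] = DEFAULT_EXCLUDED_GROUPS

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "pcg_to_ko",
            {p: tuple(v) if not isinstance(v, str) else (v,) for p, v in self.pcg_to_ko.items()},
        )
        object.__setattr__(
            self,
            "ko_to_group",
            {k: tuple(v) if not isinstance(v, str) else (v,) for k, v in self.ko_to_group.items()},
        )
        object.__setattr__(
            self,
            "excluded_groups",
            frozenset(g.lower() for g in self.excluded_groups),
        )
        for ko, groups in self.ko_to_group.items():
            if any(not g for g in groups):
                raise ValidationError(f"empty group label for KO {ko!r}")


def contig_proportions(cov: ContigCoverageTable, sample: str) -> pd.Series:
    """Length-normalized coverages of one sample, scaled to sum to 1."""
    try:
        j = cov.sample_ids.index(str(sample))
    except ValueError:
        raise KeyError(f"unknown sample {sample!r}") from None
    coverage = cov.counts[:, j] / cov.lengths
    total = coverage.sum()
    if total <= 0:
        raise ValidationError(f"sample {sample!r} has no mapped reads")
    return pd.Series(coverage / total, index=list(cov.contig_ids), name=str(sample))


def pcg_proportions(contig_props: pd.Series, fmap: FeatureMap) -> pd.Series:
    """Each PCG inherits its host contig's proportion; renormalized to sum 1."""
    pcgs = list(fmap.pcg_to_contig)
    unknown = [p for p in pcgs if fmap.pcg_to_contig[p] not in contig_props.index]
    if unknown:
        raise ValidationError(
            f"PCG(s) mapped to unknown contig(s): {unknown[:5]}"
        )
    raw = contig_props.loc[[fmap.pcg_to_contig[p] for p in pcgs]].to_numpy()
    total = raw.sum()
    if total <= 0:
        raise ValidationError("no PCG lies on a contig with positive proportion")
    return pd.Series(raw / total, index=pcgs, name=contig_props.name)


def ko_proportions(
    pcg_props: pd.Series, fmap: FeatureMap, mode: str = "all_hits"
) -> pd.Series:
    """KO proportion = sum of proportions of PCGs mapped to that KO.

    ``all_hits`` (default): a PCG with several KO hits contributes its full
    proportion to each.  ``best_hit``: only the first-listed (top-ranked) KO
    receives it.  PCGs without a KO contribute to none, so the KO total can
    fall below 1 (no renormalization).
    """
    if mode not in ("all_hits", "best_hit"):
        raise ValueError(f"unknown multi-KO mode {mode!r}")
    acc: dict[str, float] = {}
    for pcg, value in pcg_props.items():
        kos = fmap.pcg_to_ko.get(pcg, ())
        if mode == "best_hit" and kos:
            kos = kos[:1]
        for ko in kos:
            acc[ko] = acc.get(ko, 0.0) + float(value)
    return pd.Series(acc, dtype=float, name=pcg_props.name).sort_index()


def kegg_group_proportions(ko_props: pd.Series, fmap: FeatureMap) -> pd.Series:
    """KEGG level-C group proportion = sum over member KOs; catch-alls excluded.

    A KO belonging to several groups contributes to each of them.
    """
    acc: dict[str, float] = {}
    for ko, value in ko_props.items():
        for group in fmap.ko_to_group.get(ko, ()):
            if group.lower() in fmap.excluded_groups:
                continue
            acc[group] = acc.get(group, 0.0) + float(value)
    return pd.Series(acc, dtype=float, name=ko_props.name).sort_index()


def profile_table(
    cov: ContigCoverageTable,
    fmap: FeatureMap,
    level: str = "ko",
    mode: str = "all_hits",
) -> FeatureTable:
    """Per-sample functional profile at ``level`` in {contig, pcg, ko, group}."""
    if level not in ("contig", "pcg", "ko", "group"):
        raise ValueError(f"unknown profile level {level!r}")
    columns: list[pd.Series] = []
    for s in cov.sample_ids:
        vec = contig_proportions(cov, s)
        if level != "contig":
            vec = pcg_proportions(vec, fmap)
        if level in ("ko", "group"):
            vec = ko_proportions(vec, fmap, mode=mode)
        if level == "group":
            vec = kegg_group_proportions(vec, fmap)
        columns.append(vec)
    df = pd.concat(columns, axis=1).fillna(0.0)
    # contig/PCG columns sum to 1; KO/group totals can fall below 1 (unannotated
    # PCGs), so those tables are stored as plain nonnegative values ("counts").
    kind = "proportions" if level in ("contig", "pcg") else "counts"
    return FeatureTable(tuple(df.index), tuple(cov.sample_ids), df.to_numpy(), kind)


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------


def read_contig_table(path: str | Path) -> ContigCoverageTable:
    """Contig TSV: columns contig_id, length, then one read-count column per sample."""
    df = pd.read_csv(path, sep="\t")
    for col in ("contig_id", "length"):
        if col not in df.columns:
            raise FormatError(f"contig table {path} lacks required column {col!r}")
    samples = [c for c in df.columns if c not in ("contig_id", "length")]
    return ContigCoverageTable(
        tuple(df["contig_id"].astype(str)),
        df["length"].to_numpy(dtype=float),
        df[samples].to_numpy(dtype=float),
        tuple(samples),
    )


def read_two_column_map(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (with header) of (key, value) pairs; duplicates allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"map file {path} must have exactly two columns")
    return [(str(a), str(b)) for a, b in df.itertuples(index=False)]


def read_feature_map(
    pcg_contig_path: str | Path,
    pcg_ko_path: str | Path | None = None,
    ko_group_path: str | Path | None = None,
    excluded_groups: frozenset[str] = DEFAULT_EXCLUDED_GROUPS,
) -> FeatureMap:
    pcg_to_contig: dict[str, str] = {}
    for pcg, contig in read_two_column_map(pcg_contig_path):
        if pcg in pcg_to_contig and pcg_to_contig[pcg] != contig:
            raise ValidationError(f"PCG {pcg!r} mapped to multiple contigs")
        pcg_to_contig[pcg] = contig
    pcg_to_ko: dict[str, list[str]] = {}
    if pcg_ko_path is not None:
        for pcg, ko in read_two_column_map(pcg_ko_path):
            pcg_to_ko.setdefault(pcg, []).append(ko)
    ko_to_group: dict[str, list[str]] = {}
    if ko_group_path is not None:
        for ko, group in read_two_column_map(ko_group_path):
            ko_to_group.setdefault(ko, []).append(group)
    return FeatureMap(
        pcg_to_contig,
        {p: tuple(v) for p, v in pcg_to_ko.items()},
        {k: tuple(v) for k, v in ko_to_group.items()},
        excluded_groups,
    )
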