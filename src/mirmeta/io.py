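"""Readers, writers and domain containers for every file the pipeline touches.

All downstream modules operate on the in-memory types defined here:
ranked per-study miRNA lists, feature-by-sample expression matrices with
tumor/normal labels, per-patient clinical tables and GMT-style target-gene
set collections.  File formats are plain TSV/GMT (tab separator, ``.``
decimal, UTF-8, ``#`` comment lines); readers validate strictly and report
offending line numbers, so later stages can assume well-formed inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UP = "up"
DOWN = "down"
DIRECTIONS = (UP, DOWN)

#: expression units understood by the pipeline
UNITS = ("RPM", "RPKM", "log2RPM", "log2RPKM", "raw_count")

#: reserved GMT source name that marks the experimentally validated target set
VALIDATED_SOURCE = "validated"


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Ranked study lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedEntry:
    """One miRNA in a study's significant list, with optional evidence."""

    mirna_id: str
    p_value: float | None = None
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise ValueError("mirna_id must be a nonempty string")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"p_value must lie in (0, 1], got {self.p_value!r} "
                f"for {self.mirna_id}"
            )
        if self.fold_change is not None and self.fold_change <= 0:
            raise ValueError(
                f"fold_change must be positive, got {self.fold_change!r} "
                f"for {self.mirna_id}"
            )


@dataclass(frozen=True)
class RankedStudyList:
    """One study's ordered significant-miRNA list for one direction.

    ``platform_size`` is the number of miRNA probes the study assayed; the
    list itself is the (much shorter) significant subset, already ordered
    best-first.
    """

    study_id: str
    direction: str
    entries: tuple[RankedEntry, ...]
    platform_size: int

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.platform_size < 1:
            raise ValueError("platform_size must be a positive integer")
        if not (1 <= len(self.entries) <= self.platform_size):
            raise ValueError(
                f"list for ({self.study_id}, {self.direction}) has "
                f"{len(self.entries)} entries but platform_size="
                f"{self.platform_size}"
            )
        ids = [e.mirna_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({m for m in ids if ids.count(m) > 1})
            raise ValueError(
                f"duplicate miRNA ids within ({self.study_id}, "
                f"{self.direction}): {dupes}"
            )

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(e.mirna_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


_RANKED_HEADER = [
    "study_id", "direction", "rank", "mirna_id",
    "p_value", "fold_change", "platform_size",
]


def _fmt_opt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def read_ranked_lists(path: str | Path) -> list[RankedStudyList]:
    """Read ranked study lists from TSV, one row per (study, direction, rank).

    The rank column must be 1..k without gaps within each (study, direction)
    group; optional ``p_value`` / ``fold_change`` cells may be empty.
    """
    path = Path(path)
    rows: dict[tuple[str, str], dict[int, tuple[int, RankedEntry, int]]] = {}
    platform: dict[tuple[str, str], int] = {}
    seen: set[tuple[str, str, str]] = set()
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != _RANKED_HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: expected header "
                        f"{_RANKED_HEADER}, got {header}"
                    )
                continue
            if len(fields) != len(_RANKED_HEADER):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_RANKED_HEADER)} "
                    f"columns, got {len(fields)}"
                )
            study, direction, rank_s, mirna, p_s, fc_s, psize_s = fields
            key = (study, direction)
            trip = (study, direction, mirna)
            if trip in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate miRNA {mirna!r} within "
                    f"({study}, {direction})"
                )
            seen.add(trip)
            try:
                rank = int(rank_s)
                psize = int(psize_s)
                p = float(p_s) if p_s else None
                fc = float(fc_s) if fc_s else None
                entry = RankedEntry(mirna, p, fc)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            grp = rows.setdefault(key, {})
            if rank in grp:
                raise FormatError(
                    f"{path}:{lineno}: duplicate rank {rank} within {key}"
                )
            grp[rank] = (lineno, entry, psize)
            platform.setdefault(key, psize)
            if platform[key] != psize:
                raise FormatError(
                    f"{path}:{lineno}: inconsistent platform_size within {key}"
                )
    if header is None:
        raise FormatError(f"{path}: empty file")
    out = []
    for key, grp in rows.items():
        ranks = sorted(grp)
        if ranks != list(range(1, len(ranks) + 1)):
            missing = sorted(set(range(1, max(ranks) + 1)) - set(ranks))
            raise FormatError(
                f"{path}: rank gaps within {key}: missing ranks {missing}"
            )
        entries = tuple(grp[r][1] for r in ranks)
        out.append(RankedStudyList(key[0], key[1], entries, platform[key]))
    return out


def write_ranked_lists(lists: Iterable[RankedStudyList],
                       path: str | Path) -> None:
    """Write ranked study lists in the canonical TSV layout."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_RANKED_HEADER) + "\n")
        for lst in lists:
            for rank, e in enumerate(lst.entries, start=1):
                fh.write("\t".join([
                    lst.study_id, lst.direction, str(rank), e.mirna_id,
                    _fmt_opt(e.p_value), _fmt_opt(e.fold_change),
                    str(lst.platform_size),
                ]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression values with tumor/normal labels.

    ``data`` has feature ids as the index and sample ids as columns;
    ``groups`` maps every sample to ``"tumor"`` or ``"normal"``.
    """

    data: pd.DataFrame
    unit: str
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected {UNITS}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing from group labels: {missing}")
        bad = set(self.groups.loc[self.data.columns]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"group labels must be tumor/normal, got {bad}")
        self.groups = self.groups.loc[self.data.columns]
        vals = self.data.to_numpy()
        if self.unit in ("RPM", "RPKM", "raw_count") and (vals < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit}")
        if self.unit == "raw_count" and not np.allclose(vals, np.round(vals)):
            raise ValueError("raw_count matrix must contain integers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, feature: str, group: str) -> np.ndarray:
        """Values of one feature restricted to one sample group."""
        return self.data.loc[feature, self.samples_in_group(group)].to_numpy(
            dtype=float)

    def n_tumor(self) -> int:
        return int((self.groups == "tumor").sum())

    def n_normal(self) -> int:
        return int((self.groups == "normal").sum())


def read_expression_matrix(path: str | Path, unit: str,
                           groups_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (features x samples) plus a group-label TSV."""
    data = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                       float_precision="round_trip")
    data.index = data.index.astype(str)
    data.index.name = None
    data.columns = data.columns.astype(str)
    grp = pd.read_csv(groups_path, sep="\t", comment="#")
    if list(grp.columns) != ["sample_id", "group"]:
        raise FormatError(
            f"{groups_path}: expected columns ['sample_id', 'group']")
    groups = pd.Series(grp["group"].values,
                       index=grp["sample_id"].astype(str).values)
    unlabeled = [s for s in data.columns if s not in groups.index]
    if unlabeled:
        raise FormatError(
            f"{path}: samples absent from groups file: {unlabeled}")
    return ExpressionMatrix(data=data, unit=unit, groups=groups)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            groups_path: str | Path | None = None) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")
    if groups_path is not None:
        pd.DataFrame({
            "sample_id": matrix.sample_ids,
            "group": matrix.groups.loc[matrix.sample_ids].values,
        }).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "age", "psa", "race", "gleason", "positive_nodes", "pN", "pT", "histology",
]


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates (age, PSA, Gleason grade, staging...).

    ``data`` is indexed by sample id; numeric columns may contain NaN for
    missing values, categorical staging columns may be empty strings.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("clinical sample_ids must be unique")
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        psa = self.data["psa"].dropna()
        if (psa < 0).any():
            raise ValueError("psa must be nonnegative")
        gl = self.data["gleason"].dropna()
        if ((gl < 2) | (gl > 10)).any():
            raise ValueError("gleason score must lie in 2..10 when present")
        pn = self.data["pN"].dropna()
        bad = set(pn) - {"pN0", "pN1", ""}
        if bad:
            raise ValueError(f"pN must be pN0/pN1, got {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     keep_default_na=True)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Target gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class TargetSetCollection:
    """Predicted target-gene sets per source per miRNA, plus validated sets.

    The GMT set name encodes ``source|mirna``; the reserved source name
    ``validated`` holds the CLIP-derived experimentally supported targets.
    """

    predicted: dict[str, dict[str, set[str]]]
    validated: dict[str, set[str]]

    def __post_init__(self) -> None:
        if not self.predicted:
            raise ValueError("at least one predicted source is required")
        for source, per_mir in self.predicted.items():
            for mir, genes in per_mir.items():
                if any(not g for g in genes):
                    raise ValueError(
                        f"empty gene id in {source}|{mir}")

    @property
    def sources(self) -> list[str]:
        return sorted(self.predicted)

    def predicted_for(self, mirna: str) -> dict[str, set[str]]:
        """Map source -> gene set for one miRNA (missing sources omitted)."""
        return {
            src: per_mir[mirna]
            for src, per_mir in self.predicted.items() if mirna in per_mir
        }


def read_target_sets(path: str | Path) -> TargetSetCollection:
    """Read a GMT-like file: set_name<TAB>description<TAB>gene1<TAB>gene2..."""
    path = Path(path)
    predicted: dict[str, dict[str, set[str]]] = {}
    validated: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or "|" not in fields[0]:
                raise FormatError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(need 'source|mirna<TAB>description<TAB>genes...')")
            source, mirna = fields[0].split("|", 1)
            genes_list = [g for g in fields[2:] if g]
            genes = set(genes_list)
            if len(genes) < len(genes_list):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes within "
                    f"{fields[0]}; deduplicated")
            target = validated if source == VALIDATED_SOURCE else \
                predicted.setdefault(source, {})
            if source == VALIDATED_SOURCE:
                validated[mirna] = validated.get(mirna, set()) | genes
            else:
                target[mirna] = target.get(mirna, set()) | genes
    if not predicted:
        raise FormatError(f"{path}: no predicted sources found")
    return TargetSetCollection(predicted=predicted, validated=validated)


def write_target_sets(collection: TargetSetCollection,
                      path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for source in collection.sources:
            for mirna in sorted(collection.predicted[source]):
                genes = sorted(collection.predicted[source][mirna])
                fh.write("\t".join([f"{source}|{mirna}", "predicted"]
                                   + genes) + "\n")
        for mirna in sorted(collection.validated):
            genes = sorted(collection.validated[mirna])
            fh.write("\t".join([f"{VALIDATED_SOURCE}|{mirna}", "validated"]
                               + genes) + "\n")


# ---------------------------------------------------------------------------
# Study sample bookkeeping
# ---------------------------------------------------------------------------

def count_samples(lists: Sequence[RankedStudyList],
                  sample_counts: Mapping[str, tuple[int, int]],
                  ) -> tuple[int, int]:
    """Total (tumor, normal) samples over the distinct studies in ``lists``.

    ``sample_counts`` maps study_id -> (n_tumor, n_normal); paired designs
    are encoded as equal counts in both groups, so a 20-pair study
    contributes 20 to each total.
    """
    studies = sorted({lst.study_id for lst in lists})
    missing = [s for s in studies if s not in sample_counts]
    if missing:
        raise ValueError(f"no sample counts for studies: {missing}")
    tumor = sum(sample_counts[s][0] for s in studies)
    normal = sum(sample_counts[s][1] for s in studies)
    return tumor, normal
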