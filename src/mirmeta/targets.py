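"""Target-gene integration: consensus, overlaps, correlation filtering.

The target set of each miRNA is narrowed in three steps — genes predicted
by at least ``min_sources`` independent algorithms, intersected with the
experimentally validated (CLIP-derived) set and with the differentially
expressed genes, then filtered by significant Spearman correlation between
miRNA and gene expression.  The retained sets feed a clustered
miRNA-by-gene correlation heatmap and the shared-target detector (genes
surviving for every miRNA in the panel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .diagnostics import CorrelationRecord, spearman


@dataclass
class TargetOverlapResult:
    """Stepwise target selection for one miRNA."""

    mirna_id: str
    consensus_predicted: set[str]
    overlap_genes: set[str]
    retained_genes: set[str]
    correlations: list[CorrelationRecord]

    def __post_init__(self) -> None:
        if not self.overlap_genes <= self.consensus_predicted:
            raise ValueError("overlap must be a subset of the consensus")
        if not self.retained_genes <= self.overlap_genes:
            raise ValueError("retained must be a subset of the overlap")


@dataclass
class CorrelationMatrixResult:
    """Signed miRNA-gene correlation matrix with clustering orders."""

    values: pd.DataFrame          # genes x miRNAs
    significant: pd.DataFrame     # boolean mask, same shape
    row_order: list[str]
    col_order: list[str]


def consensus_predicted(predicted: Mapping[str, set[str]],
                        min_sources: int = 2) -> set[str]:
    """Genes predicted by at least ``min_sources`` of the supplied sources."""
    if min_sources > len(predicted):
        raise ValueError(
            f"min_sources={min_sources} exceeds the {len(predicted)} "
            "supplied sources")
    counts: dict[str, int] = {}
    for genes in predicted.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_sources}


def overlap_selection(consensus: set[str], validated: set[str],
                      de_genes: set[str]) -> set[str]:
    """Consensus-predicted AND validated AND differentially expressed."""
    return set(consensus) & set(validated) & set(de_genes)


def correlation_filter(mirna_values: pd.Series,
                       gene_matrix: pd.DataFrame,
                       alpha: float = 0.05,
                       expected_sign: str | None = None,
                       ) -> tuple[set[str], list[CorrelationRecord]]:
    """Retain genes whose expression correlates with the miRNA.

    ``gene_matrix`` is genes x samples, aligned on sample ids with
    ``mirna_values``.  Genes with zero expression variance are dropped with
    a note.  ``expected_sign="negative"`` additionally requires r_s < 0
    (the canonical miRNA-represses-target relation); the default keeps both
    signs.
    """
    if expected_sign not in (None, "negative", "positive"):
        raise ValueError("expected_sign must be None/'negative'/'positive'")
    shared = [s for s in gene_matrix.columns if s in mirna_values.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    mv = mirna_values.loc[shared].to_numpy(dtype=float)
    retained: set[str] = set()
    records: list[CorrelationRecord] = []
    for gene in gene_matrix.index:
        gv = gene_matrix.loc[gene, shared].to_numpy(dtype=float)
        if np.ptp(gv) == 0.0:
            warnings.warn(f"{gene}: zero expression variance; dropped")
            continue
        rec = spearman(mv, gv, str(mirna_values.name), str(gene))
        records.append(rec)
        if rec.p_value < alpha:
            if expected_sign == "negative" and rec.r_s >= 0:
                continue
            if expected_sign == "positive" and rec.r_s <= 0:
                continue
            retained.add(str(gene))
    return retained, records


def _leaf_order(profile: pd.DataFrame) -> list[str]:
    """Average-linkage leaf order on 1 - Spearman distance between rows."""
    ids = sorted(profile.index)  # lexicographic tie-break, then cluster
    if len(ids) < 2:
        return list(ids)
    mat = profile.loc[ids].to_numpy(dtype=float)
    corr = stats.spearmanr(mat, axis=1).statistic
    if np.ndim(corr) == 0:  # scipy collapses the 2-row case to a scalar
        r = float(corr)
        corr = np.array([[1.0, r], [r, 1.0]])
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return [ids[i] for i in hierarchy.leaves_list(Z)]


def correlation_matrix(mirna_matrix: pd.DataFrame,
                       gene_matrix: pd.DataFrame,
                       alpha: float = 0.05) -> CorrelationMatrixResult:
    """All pairwise miRNA-gene Spearman correlations, clustered.

    Rows (genes) and columns (miRNAs) are ordered by average-linkage
    hierarchical clustering with distance 1 - correlation; ties and leaf
    order are made deterministic by pre-sorting ids lexicographically.
    Constant rows/columns get correlation 0 with a masked (non-significant)
    cell.
    """
    if len(gene_matrix.index) < 2 or len(mirna_matrix.index) < 2:
        raise ValueError("need at least 2 genes and 2 miRNAs")
    shared = [s for s in gene_matrix.columns if s in mirna_matrix.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    genes = list(gene_matrix.index)
    mirnas = list(mirna_matrix.index)
    vals = pd.DataFrame(0.0, index=genes, columns=mirnas)
    sig = pd.DataFrame(False, index=genes, columns=mirnas)
    for g in genes:
        gv = gene_matrix.loc[g, shared].to_numpy(dtype=float)
        for m in mirnas:
            mv = mirna_matrix.loc[m, shared].to_numpy(dtype=float)
            if np.ptp(gv) == 0.0 or np.ptp(mv) == 0.0:
                continue
            r, p = stats.spearmanr(gv, mv)
            vals.loc[g, m] = r
            sig.loc[g, m] = bool(p < alpha)
    row_order = _leaf_order(gene_matrix.loc[genes, shared])
    col_order = _leaf_order(mirna_matrix.loc[mirnas, shared])
    return CorrelationMatrixResult(values=vals, significant=sig,
                                   row_order=row_order, col_order=col_order)


def shared_targets(results: Sequence[TargetOverlapResult]) -> set[str]:
    """Genes retained for every miRNA in the panel."""
    if len(results) < 2:
        raise ValueError("need results for at least 2 miRNAs")
    shared = set(results[0].retained_genes)
    for res in results[1:]:
        shared &= res.retained_genes
    return shared


def integrate_targets(collection,
                      de_genes: set[str],
                      mirna_matrix: pd.DataFrame,
                      gene_matrix: pd.DataFrame,
                      mirnas: Sequence[str] | None = None,
                      min_sources: int = 2,
                      alpha: float = 0.05,
                      expected_sign: str | None = None,
                      ) -> tuple[list[TargetOverlapResult], set[str]]:
    """Run the full per-miRNA target-selection chain and find shared genes.

    ``collection`` is a TargetSetCollection; ``mirna_matrix`` holds marker
    expression (miRNAs x samples) and ``gene_matrix`` mRNA expression
    (genes x samples).  Genes absent from ``gene_matrix`` cannot be
    correlation-tested and are dropped from the retained set.
    """
    if mirnas is None:
        mirnas = sorted({m for per in collection.predicted.values()
                         for m in per})
    results = []
    for mirna in mirnas:
        cons = consensus_predicted(collection.predicted_for(mirna),
                                   min_sources)
        overlap = overlap_selection(cons,
                                    collection.validated.get(mirna, set()),
                                    de_genes)
        testable = [g for g in sorted(overlap) if g in gene_matrix.index]
        if testable and mirna in mirna_matrix.index:
            retained, records = correlation_filter(
                mirna_matrix.loc[mirna], gene_matrix.loc[testable],
                alpha=alpha, expected_sign=expected_sign)
        else:
            retained, records = set(), []
        results.append(TargetOverlapResult(
            mirna_id=mirna, consensus_predicted=cons,
            overlap_genes=overlap, retained_genes=retained,
            correlations=records))
    return results, shared_targets(results)
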