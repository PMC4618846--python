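"""Leave-one-out stability filter over the rank aggregation.

A miRNA whose aggregate significance hinges on a single input list is a
fragile candidate.  The filter repeatedly drops one list, re-aggregates,
and averages each miRNA's corrected p-value across drops; only miRNAs whose
mean stays below alpha are kept.  With K lists there are exactly K
leave-one-out configurations, so the sampled variant (T random drops) has
the enumerated variant as its exact expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import RankedStudyList
from .rra import AggregationRecord, aggregate


@dataclass(frozen=True)
class StabilityRecord:
    """Leave-one-out stability summary for one miRNA in one direction."""

    mirna_id: str
    direction: str
    mean_loocv_p: float
    n_iterations: int
    keep: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_loocv_p <= 1.0):
            raise ValueError("mean_loocv_p must lie in (0,1]")


def _config_pvalues(lists: Sequence[RankedStudyList],
                    universe: Sequence[str]) -> np.ndarray:
    """Matrix (K configs x M miRNAs) of corrected p's, one row per drop.

    A miRNA absent from every remaining list scores p = 1 in that
    configuration (the harshest probability-preserving choice).
    """
    K = len(lists)
    index = {m: i for i, m in enumerate(universe)}
    P = np.ones((K, len(universe)))
    for k in range(K):
        remaining = [lst for i, lst in enumerate(lists) if i != k]
        for rec in aggregate(remaining):
            P[k, index[rec.mirna_id]] = rec.corrected_p
    return P


def loocv_stability(lists: Sequence[RankedStudyList],
                    T: int = 10_000,
                    alpha: float = 0.05,
                    mode: str = "sampled",
                    seed: int | None = None) -> list[StabilityRecord]:
    """Leave-one-out stability records for all miRNAs of one direction.

    ``mode="sampled"`` performs T iterations, each dropping one list chosen
    uniformly at random; ``mode="enumerate"`` weights the K configurations
    equally (the exact expectation of sampling, and seed-free).
    """
    dirs = {lst.direction for lst in lists}
    if len(dirs) != 1:
        raise ValueError(f"lists mix directions {sorted(dirs)}; "
                         "filter each direction separately")
    direction = dirs.pop()
    K = len(lists)
    if K < 3:
        raise ValueError("need at least 3 lists so that dropping one "
                         "leaves a valid aggregation")
    if mode not in ("sampled", "enumerate"):
        raise ValueError("mode must be 'sampled' or 'enumerate'")
    universe = sorted({e.mirna_id for lst in lists for e in lst.entries})
    P = _config_pvalues(lists, universe)
    if mode == "enumerate":
        weights = np.full(K, 1.0 / K)
        n_iter = K
    else:
        if T < K:
            raise ValueError(f"T={T} undersamples the {K} leave-one-out "
                             "configurations")
        if seed is None:
            raise ValueError("sampled mode requires a seed")
        rng = np.random.default_rng(seed)
        counts = np.bincount(rng.integers(0, K, size=T), minlength=K)
        weights = counts / T
        n_iter = T
    means = weights @ P
    return [
        StabilityRecord(
            mirna_id=m,
            direction=direction,
            mean_loocv_p=float(means[i]),
            n_iterations=n_iter,
            keep=bool(means[i] < alpha),
        )
        for i, m in enumerate(universe)
    ]


def select_meta_signature(aggregation: Sequence[AggregationRecord],
                          stability: Sequence[StabilityRecord],
                          alpha: float = 0.05) -> dict[str, set[str]]:
    """miRNAs per direction that are both aggregate-significant and stable."""
    agg_index = {(r.mirna_id, r.direction): r for r in aggregation}
    selected: dict[str, set[str]] = {}
    for srec in stability:
        key = (srec.mirna_id, srec.direction)
        if key not in agg_index:
            raise ValueError(
                f"stability record for {key} has no aggregation record")
        arec = agg_index[key]
        if arec.is_significant(alpha) and srec.keep:
            selected.setdefault(srec.direction, set()).add(srec.mirna_id)
    return selected
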