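"""Robust rank aggregation of heterogeneous ranked miRNA lists.

Each miRNA is scored only on the lists where it appears.  Its observed
normalized ranks are compared against the order statistics of uniform
random ranks (the fully shuffled baseline): if a miRNA sits at normalized
rank r_(j) in the j-th best of its n lists, the probability that the j-th
order statistic of n independent uniforms falls at or below r_(j) is the
binomial tail

    p_j = sum_{i=j..n} C(n, i) r_(j)^i (1 - r_(j))^{n-i},

equivalently the Beta(j, n - j + 1) CDF at r_(j).  The rho score is the
minimum p_j over j, and the corrected p-value applies a Bonferroni factor
of n for that minimization.  An optional permutation test recomputes rho
under the shuffled-list null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special

from .io import DIRECTIONS, RankedEntry, RankedStudyList


@dataclass(frozen=True)
class AggregationRecord:
    """Aggregation result for one miRNA in one direction."""

    mirna_id: str
    direction: str
    rho: float
    corrected_p: float
    permutation_p: float | None
    n_lists_present: int
    total_lists: int

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must lie in (0,1], got {self.rho}")
        if not (0.0 < self.corrected_p <= 1.0):
            raise ValueError("corrected_p must lie in (0,1]")
        # Bonferroni correction never decreases the score
        if self.corrected_p < self.rho - 1e-12:
            raise ValueError("corrected_p may not be smaller than rho")
        if self.n_lists_present > self.total_lists:
            raise ValueError("n_lists_present may not exceed total_lists")

    def is_significant(self, alpha: float = 0.05) -> bool:
        return self.corrected_p < alpha


def prioritize_list(lst: RankedStudyList) -> RankedStudyList:
    """Order a study list by its evidence.

    P-values win over fold changes: ascending p if every entry carries one,
    otherwise descending |log2 FC| if every entry carries a fold change,
    otherwise the input order is kept (the list is taken as pre-ranked).
    Ties break by input order (stable sort).
    """
    has_p = [e.p_value is not None for e in lst.entries]
    has_fc = [e.fold_change is not None for e in lst.entries]
    if all(has_p):
        key = np.array([e.p_value for e in lst.entries], dtype=float)
        order = np.argsort(key, kind="stable")
    elif any(has_p):
        raise ValueError(
            f"({lst.study_id}, {lst.direction}): mixed evidence — some "
            "entries have p-values and some do not")
    elif all(has_fc):
        key = np.array([-abs(math.log2(e.fold_change)) for e in lst.entries])
        order = np.argsort(key, kind="stable")
    elif any(has_fc):
        raise ValueError(
            f"({lst.study_id}, {lst.direction}): mixed evidence — some "
            "entries have fold changes and some do not")
    else:
        return lst
    entries = tuple(lst.entries[i] for i in order)
    return RankedStudyList(lst.study_id, lst.direction, entries,
                           lst.platform_size)


def normalized_ranks(lists: Sequence[RankedStudyList],
                     ) -> dict[str, np.ndarray]:
    """Map each miRNA to its vector of normalized ranks across lists.

    A miRNA at 1-based position k in a list drawn from a platform of N
    probes gets normalized rank k/N; lists not containing it contribute
    nothing (the rank vector has one entry per list of presence).
    """
    if not lists:
        raise ValueError("need at least one list")
    dirs = {lst.direction for lst in lists}
    if len(dirs) != 1:
        raise ValueError(f"lists mix directions {sorted(dirs)}; "
                         "aggregate each direction separately")
    out: dict[str, list[float]] = {}
    for lst in lists:
        if lst.platform_size < len(lst.entries):
            raise ValueError(
                f"({lst.study_id}, {lst.direction}): platform_size "
                f"{lst.platform_size} smaller than list length {len(lst)}")
        for k, entry in enumerate(lst.entries, start=1):
            out.setdefault(entry.mirna_id, []).append(k / lst.platform_size)
    return {m: np.asarray(v, dtype=float) for m, v in out.items()}


def order_stat_pvalues(ranks: Sequence[float]) -> np.ndarray:
    """Tail probabilities p_j of the n uniform order statistics at the
    sorted observed ranks: p_j = P(U_(j) <= r_(j)) = I_{r_(j)}(j, n-j+1)."""
    r = np.sort(np.asarray(ranks, dtype=float))
    if r.size == 0:
        raise ValueError("empty rank vector")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError(f"normalized ranks must lie in (0, 1], got {r}")
    n = r.size
    j = np.arange(1, n + 1)
    return special.betainc(j, n - j + 1, r)


def beta_score(ranks: Sequence[float]) -> float:
    """The rho score: minimum order-statistic tail probability."""
    return float(order_stat_pvalues(ranks).min())


def corrected_p(rho: float, n: int) -> float:
    """Bonferroni correction over the n minimized order statistics."""
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"rho must lie in (0,1], got {rho}")
    if n < 1:
        raise ValueError("n must be at least 1")
    return min(1.0, rho * n)


def _null_rho_matrix(B: int, lengths: np.ndarray, platforms: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """B null rho draws for one miRNA present in len(lengths) lists.

    Under the shuffled-list null conditioned on presence, the rank within a
    significant list of length L from a platform of N probes is uniform on
    {1..L}, normalized by N.
    """
    n = lengths.size
    ranks = rng.integers(1, lengths + 1, size=(B, n)) / platforms
    ranks.sort(axis=1)
    j = np.arange(1, n + 1)
    p = special.betainc(j, n - j + 1, ranks)
    return p.min(axis=1)


def permutation_p(lists: Sequence[RankedStudyList],
                  rho_observed: Mapping[str, float],
                  B: int = 1000,
                  seed: int | None = None) -> dict[str, float]:
    """Permutation p-values against the shuffled-list null.

    Every list's content is reshuffled uniformly over its platform universe
    (keeping list lengths); each miRNA's rho is recomputed with its observed
    presence pattern, and p = (1 + #{null rho <= observed}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if seed is None:
        raise ValueError("a seed is required (no ambient randomness)")
    rng = np.random.default_rng(seed)
    presence: dict[str, list[tuple[int, int]]] = {}
    for lst in lists:
        for entry in lst.entries:
            presence.setdefault(entry.mirna_id, []).append(
                (len(lst.entries), lst.platform_size))
    out: dict[str, float] = {}
    for mirna in sorted(presence):
        if mirna not in rho_observed:
            continue
        cfg = presence[mirna]
        lengths = np.array([c[0] for c in cfg])
        platforms = np.array([c[1] for c in cfg], dtype=float)
        null = _null_rho_matrix(B, lengths, platforms, rng)
        hits = int(np.sum(null <= rho_observed[mirna]))
        out[mirna] = (1 + hits) / (B + 1)
    return out


def aggregate(lists: Sequence[RankedStudyList],
              alpha: float = 0.05,
              B: int = 0,
              seed: int | None = None,
              strict: bool = False) -> list[AggregationRecord]:
    """Aggregate ranked lists into per-miRNA records, per direction.

    Lists are prioritized by their evidence, ranks are normalized by
    platform size, and each miRNA gets a rho score and Bonferroni-corrected
    p over the lists where it appears.  With ``strict=True`` absences count
    as worst rank 1.0 and n equals the total list count.  ``B > 0`` adds
    permutation p-values (requires ``seed``).
    """
    by_dir: dict[str, list[RankedStudyList]] = {}
    for lst in lists:
        by_dir.setdefault(lst.direction, []).append(lst)
    records: list[AggregationRecord] = []
    for direction in sorted(by_dir):
        dlists = [prioritize_list(l) for l in by_dir[direction]]
        if len(dlists) < 2:
            raise ValueError(
                f"direction {direction!r}: need at least 2 lists, "
                f"got {len(dlists)}")
        total = len(dlists)
        ranks = normalized_ranks(dlists)
        rho_map: dict[str, float] = {}
        for mirna, r in sorted(ranks.items()):
            if strict:
                r = np.concatenate([r, np.ones(total - r.size)])
            rho_map[mirna] = beta_score(r)
        perm = (permutation_p(dlists, rho_map, B=B, seed=seed)
                if B else {})
        for mirna, r in sorted(ranks.items()):
            n_present = total if strict else int(r.size)
            rho = rho_map[mirna]
            records.append(AggregationRecord(
                mirna_id=mirna,
                direction=direction,
                rho=rho,
                corrected_p=corrected_p(rho, n_present),
                permutation_p=perm.get(mirna),
                n_lists_present=int(r.size),
                total_lists=total,
            ))
    records.sort(key=lambda rec: (rec.direction, rec.corrected_p,
                                  rec.mirna_id))
    return records
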