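"""Canonical study designs and simulation scenarios for the pipeline.

The study design table encodes the meta-analysis bookkeeping inputs (per
study: tumor/normal sample counts and miRNA platform size; paired designs
carry equal counts in both groups).  The scenario builders assemble the
standard synthetic configurations the analysis scripts and acceptance
checks run: an 11-study meta-analysis with planted robust and fragile
signals, a PRAD-scale validation matrix, a 19-cancer pattern panel, a
clinical cohort and a target-integration scenario.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io import RankedEntry, RankedStudyList
from .synthetic import (ExpressionSimSpec, SignalSpec,
                        simulate_expression, simulate_ranked_studies)

#: per-study (study_id, n_tumor, n_normal, platform probe count); paired
#: designs are encoded with equal tumor/normal counts
STUDY_DESIGN = [
    ("study01", 60, 16, 329),
    ("study02", 21, 21, 847),
    ("study03", 20, 20, 847),
    ("study04", 12, 12, 470),
    ("study05", 72, 15, 723),
    ("study06", 20, 20, 667),
    ("study07", 13, 10, 667),
    ("study08", 56, 7, 2285),
    ("study09", 20, 20, 114),
    ("study10", 16, 10, 480),
    ("study11", 37, 37, 88),
]

#: 19 cancer-type labels for the pan-cancer pattern scenario
CANCER_TYPES = [
    "PRAD", "BLCA", "CHOL", "COAD", "ESCA", "HNSC", "KICH", "KIRC",
    "KIRP", "LIHC", "LUAD", "LUSC", "PCPG", "READ", "STAD", "THCA",
    "THYM", "PAAD", "SKCM",
]

#: miRNA marker panel and its tumor sign pattern in the index cancer
PANEL = ["mir-up-1", "mir-up-2", "mir-down-1"]
PANEL_PATTERN = {"mir-up-1": "up", "mir-up-2": "up", "mir-down-1": "down"}


def study_sample_counts() -> dict[str, tuple[int, int]]:
    return {sid: (t, n) for sid, t, n, _ in STUDY_DESIGN}


def meta_analysis_lists(seed: int,
                        universe_size: int = 300,
                        significant_fraction: float = 0.05,
                        signals: Sequence[SignalSpec] | None = None,
                        fragile_id: str | None = "mir-fragile",
                        ) -> list[RankedStudyList]:
    """Eleven truncated significant lists with planted signals.

    Platform sizes follow the study design; list lengths are the
    significant fraction of each platform (at least 10).  Five robust
    up-signals (penetrance 0.8, strength 0.02) are planted by default;
    ``fragile_id`` adds a miRNA at rank 1 of the first list only — the
    single-study artifact the stability filter exists to remove.
    """
    universe = [f"mir{i:03d}" for i in range(universe_size)]
    if signals is None:
        signals = [SignalSpec(f"mir{i:03d}", "up", 0.8, 0.02)
                   for i in range(5)]
    platforms = [min(p, universe_size) for _, _, _, p in STUDY_DESIGN]
    lengths = [max(10, int(round(significant_fraction * p)))
               for p in platforms]
    lists = simulate_ranked_studies(
        len(STUDY_DESIGN), universe, platforms, lengths, signals,
        seed=seed)
    lists = [RankedStudyList(STUDY_DESIGN[i][0], l.direction, l.entries,
                             l.platform_size)
             for i, l in enumerate(lists)]
    if fragile_id is not None:
        l0 = lists[0]
        entries = (RankedEntry(fragile_id),) + l0.entries[:-1]
        lists[0] = RankedStudyList(l0.study_id, l0.direction, entries,
                                   l0.platform_size)
    return lists


def null_complete_lists(seed: int, n_lists: int = 11,
                        universe_size: int = 500) -> list[RankedStudyList]:
    """Fully shuffled complete rankings: the aggregation's null baseline."""
    universe = [f"mir{i:03d}" for i in range(universe_size)]
    return simulate_ranked_studies(
        n_lists, universe, [universe_size] * n_lists,
        [universe_size] * n_lists, [], seed=seed)


#: planted log2 fold changes for the PRAD-scale validation scenario:
#: three true markers and three near-miss candidates the joint
#: FDR/fold-change rule should reject
VALIDATION_PLANT = {
    "mir-up-1": 2.56,     # FC ~ 5.9
    "mir-up-2": 1.81,     # FC ~ 3.5
    "mir-down-1": -1.29,  # FC ~ 0.41
    "mir-down-2": -0.94,  # FC ~ 0.52: misses the symmetric cutoff
    "mir-down-3": -0.15,  # FC ~ 0.90
    "mir-down-4": -0.94,
}

#: expected directions submitted to the validation step
VALIDATION_CANDIDATES = {
    "mir-up-1": "up", "mir-up-2": "up", "mir-down-1": "down",
    "mir-down-2": "down", "mir-down-3": "down", "mir-down-4": "down",
}


def prad_validation_matrix(seed: int, n_features: int = 300,
                           n_tumor: int = 498, n_normal: int = 52):
    """RPM matrix at the validation cohort's scale with planted markers."""
    ids = [f"g{i:04d}" for i in range(1, n_features + 1)]
    renames = dict(zip(ids[:len(VALIDATION_PLANT)],
                       VALIDATION_PLANT))
    spec = ExpressionSimSpec(
        n_features=n_features, n_tumor=n_tumor, n_normal=n_normal,
        planted={g: VALIDATION_PLANT[name]
                 for g, name in renames.items()},
        seed=seed)
    raw, rpm = simulate_expression(spec)
    mapping = {g: name for g, name in renames.items()}
    raw.data.rename(index=mapping, inplace=True)
    rpm.data.rename(index=mapping, inplace=True)
    return raw, rpm


def pan_cancer_pattern(planted_in: Sequence[str]):
    """Sign-pattern map planting the panel pattern in the given cancers."""
    pattern = {c: {m: "flat" for m in PANEL} for c in CANCER_TYPES}
    for c in planted_in:
        pattern[c] = dict(PANEL_PATTERN)
    return pattern
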