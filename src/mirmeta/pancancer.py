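"""Per-cancer direction calls for a miRNA panel and pattern uniqueness.

Given one tumor/normal expression matrix per cancer type and a small miRNA
panel, each (cancer, miRNA) pair is called up, down or flat from a
rank-sum test (BH-corrected across the panel within the cancer) and the
median fold change.  A cancer "matches" a target sign pattern when its
calls equal the pattern on every target miRNA; the pattern is unique when
exactly one cancer matches — the property that singles a cancer out as
carrying the panel's combined signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expression import (bh_fdr, direction_call, log2_transform,
                         median_fold_change, rank_sum_test)
from .io import ExpressionMatrix


@dataclass
class PatternCall:
    """Direction calls for one cancer type across the miRNA panel."""

    cancer_type: str
    calls: dict[str, str]            # mirna -> up/down/flat
    log2_fcs: dict[str, float]
    significant: dict[str, bool]
    low_power: bool = False

    def __post_init__(self) -> None:
        for mirna, call in self.calls.items():
            if call not in ("up", "down", "flat"):
                raise ValueError(f"call for {mirna} must be up/down/flat")
            if call != "flat" and not self.significant.get(mirna, False):
                raise ValueError(
                    f"{self.cancer_type}/{mirna}: non-flat call requires "
                    "significance")


def call_directions(matrices: Mapping[str, ExpressionMatrix],
                    panel: Sequence[str],
                    fdr_cut: float = 0.05,
                    fc_cut: float = 2.0,
                    pseudocount: float = 1.0) -> list[PatternCall]:
    """Call each panel miRNA up/down/flat in every cancer type.

    Panel members missing from a cancer's matrix are called flat with a
    warning; cancers with fewer than 2 normal samples are flagged
    ``low_power`` but still called.
    """
    out: list[PatternCall] = []
    for cancer in sorted(matrices):
        matrix = matrices[cancer]
        if matrix.n_tumor() == 0 or matrix.n_normal() == 0:
            raise ValueError(f"{cancer}: both groups must be nonempty")
        low_power = matrix.n_normal() < 2
        if low_power:
            warnings.warn(f"{cancer}: fewer than 2 normal samples; "
                          "calls are low-power")
        logm = log2_transform(matrix, pseudocount)
        present = [m for m in panel if m in matrix.data.index]
        for m in panel:
            if m not in matrix.data.index:
                warnings.warn(f"{cancer}: panel miRNA {m} absent; "
                              "called flat")
        pvals = []
        fcs = {}
        for m in present:
            _, p = rank_sum_test(logm.group_values(m, "tumor"),
                                 logm.group_values(m, "normal"))
            pvals.append(p)
            fcs[m] = median_fold_change(matrix.group_values(m, "tumor"),
                                        matrix.group_values(m, "normal"))
        fdrs = dict(zip(present, bh_fdr(pvals)))
        calls, lfc, sig = {}, {}, {}
        for m in panel:
            if m not in present:
                calls[m], lfc[m], sig[m] = "flat", float("nan"), False
                continue
            call = direction_call(fcs[m], fdrs[m], fdr_cut, fc_cut)
            calls[m] = call if call != "ns" else "flat"
            with np.errstate(divide="ignore"):
                lfc[m] = float(np.log2(fcs[m])) if fcs[m] > 0 else float("-inf")
            sig[m] = calls[m] != "flat"
        out.append(PatternCall(cancer_type=cancer, calls=calls,
                               log2_fcs=lfc, significant=sig,
                               low_power=low_power))
    return out


def unique_pattern_cancers(calls: Sequence[PatternCall],
                           target: Mapping[str, str],
                           ) -> tuple[list[str], bool]:
    """Cancers whose calls equal the target sign pattern; uniqueness flag.

    ``target`` maps miRNA -> up/down.  A cancer matches when every target
    miRNA's call equals the target direction (flat never matches); panel
    members outside the target are ignored.  ``unique`` is True iff exactly
    one cancer matches.
    """
    if not target:
        raise ValueError("target pattern must be nonempty")
    bad = set(target.values()) - {"up", "down"}
    if bad:
        raise ValueError(f"target directions must be up/down, got {bad}")
    for pc in calls:
        missing = set(target) - set(pc.calls)
        if missing:
            raise ValueError(
                f"{pc.cancer_type}: target miRNAs {sorted(missing)} not in "
                "the called panel")
    matches = sorted(
        pc.cancer_type for pc in calls
        if all(pc.calls[m] == d for m, d in target.items())
    )
    return matches, len(matches) == 1
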