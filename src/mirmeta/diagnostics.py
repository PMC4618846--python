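"""Clinical association battery and diagnostic ROC evaluation.

Association side: tie-aware Spearman correlations for continuous
covariates, rank-sum tests for two-level strata (Gleason low/high, nodal
status) and Kruskal-Wallis for multi-level strata, one row per
(marker, covariate).

Diagnostic side: ROC curves with AUC by concordant-pair counting
(ties count half, identical to the trapezoidal area), DeLong or bootstrap
confidence intervals, a hand-rolled IRLS logistic fit to combine several
markers into one score, and the Youden-optimal cutoff (maximal
sensitivity + specificity, ties resolved toward higher specificity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import kruskal_wallis, rank_sum_test
from .io import ClinicalTable, ExpressionMatrix


@dataclass(frozen=True)
class CorrelationRecord:
    var_a: str
    var_b: str
    r_s: float
    p_value: float
    n: int
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.r_s) and abs(self.r_s) > 1 + 1e-12:
            raise ValueError("|r_s| may not exceed 1")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc + 1e-12
                and self.auc <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the AUC")


def spearman(x: Sequence[float], y: Sequence[float],
             var_a: str = "x", var_b: str = "y") -> CorrelationRecord:
    """Tie-aware Spearman correlation with two-tailed t-approximation p.

    Missing values are removed pairwise; a constant vector yields an
    undefined (NaN) coefficient with a degenerate-input note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return CorrelationRecord(var_a, var_b, float("nan"), float("nan"),
                                 n, note="zero variance")
    r, p = stats.spearmanr(x, y)
    return CorrelationRecord(var_a, var_b, float(r), float(p), n)


# ---------------------------------------------------------------------------
# Clinical battery
# ---------------------------------------------------------------------------

#: continuous covariates tested by Spearman correlation
_CONTINUOUS = ("age", "psa", "positive_nodes")


def _gleason_split(gleason: pd.Series) -> pd.Series:
    """Dichotomize Gleason scores: 'low' for <= 7, 'high' for >= 8."""
    out = pd.Series(index=gleason.index, dtype=object)
    out[gleason <= 7] = "low"
    out[gleason >= 8] = "high"
    return out


def clinical_battery(markers: ExpressionMatrix,
                     clinical: ClinicalTable) -> pd.DataFrame:
    """All marker x clinical-feature association tests, one row each.

    Continuous covariates (age, PSA, positive-node count) use Spearman;
    two-level strata (Gleason low 6-7 vs high >= 8, node-positive vs
    negative, pN0 vs pN1) use the rank-sum test; covariates with three or
    more observed levels (race, pT, histology) use Kruskal-Wallis.
    Markers are expected on the log2 scale.  Covariates with a single
    observed level are skipped with a note.
    """
    if not markers.unit.startswith("log2"):
        raise ValueError("clinical_battery expects log2-scale markers")
    shared = [s for s in markers.sample_ids if s in clinical.data.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples shared between the "
                         "marker matrix and the clinical table")
    cdf = clinical.data.loc[shared]
    rows = []
    for marker in markers.feature_ids:
        mvals = markers.data.loc[marker, shared].to_numpy(dtype=float)

        for cov in _CONTINUOUS:
            vals = pd.to_numeric(cdf[cov], errors="coerce").to_numpy()
            mask = np.isfinite(vals)
            if mask.sum() < 3 or np.ptp(vals[mask]) == 0:
                rows.append((marker, cov, "spearman", np.nan, np.nan,
                             int(mask.sum()), "skipped: degenerate"))
                continue
            rec = spearman(mvals[mask], vals[mask], marker, cov)
            rows.append((marker, cov, "spearman", rec.r_s, rec.p_value,
                         rec.n, rec.note))

        binary: dict[str, pd.Series] = {
            "gleason_grade": _gleason_split(cdf["gleason"]),
            "node_status": pd.Series(
                np.where(pd.to_numeric(cdf["positive_nodes"],
                                       errors="coerce") > 0,
                         "positive", "negative"),
                index=cdf.index).where(
                    pd.to_numeric(cdf["positive_nodes"],
                                  errors="coerce").notna()),
            "pN_stage": cdf["pN"],
        }
        for cov, levels in binary.items():
            lv = levels.dropna()
            lv = lv[lv != ""]
            observed = pd.unique(lv)
            if len(observed) < 2:
                rows.append((marker, cov, "rank_sum", np.nan, np.nan,
                             len(lv), "skipped: single level"))
                continue
            a, b = sorted(observed)[:2]
            idx = lv.index
            m = pd.Series(mvals, index=shared).loc[idx]
            stat, p = rank_sum_test(m[lv == a], m[lv == b])
            rows.append((marker, cov, "rank_sum", stat, p, len(lv), ""))

        for cov in ("race", "pT", "histology"):
            lv = cdf[cov].dropna()
            lv = lv[lv != ""]
            observed = pd.unique(lv)
            m = pd.Series(mvals, index=shared).loc[lv.index]
            if len(observed) < 2:
                rows.append((marker, cov, "kruskal", np.nan, np.nan,
                             len(lv), "skipped: single level"))
            elif len(observed) == 2:
                a, b = sorted(observed)
                stat, p = rank_sum_test(m[lv == a], m[lv == b])
                rows.append((marker, cov, "rank_sum", stat, p, len(lv),
                             "two observed levels"))
            else:
                stat, p = kruskal_wallis(m.to_numpy(), lv.to_numpy())
                rows.append((marker, cov, "kruskal", stat, p, len(lv), ""))
    return pd.DataFrame(rows, columns=[
        "marker", "feature", "test", "statistic", "p_value", "n", "note"])


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """ROC points plus AUC; positives are scores at or above a threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    flipped: bool = False
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None


def _pair_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = (concordant pairs + 0.5 ties) / (n_pos * n_neg), via ranks."""
    r = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc(scores: Sequence[float], labels: Sequence[int],
        positive_direction: str = "higher") -> RocCurve:
    """ROC curve and AUC for a score against binary labels.

    ``positive_direction="lower"`` negates the scores (markers where the
    positive class scores low); ``"auto"`` picks the orientation with
    AUC >= 0.5 and records the flip.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    flipped = False
    if positive_direction == "lower":
        scores = -scores
        flipped = True
    elif positive_direction == "auto":
        if _pair_auc(scores, labels) < 0.5:
            scores = -scores
            flipped = True
    elif positive_direction != "higher":
        raise ValueError("positive_direction must be higher/lower/auto")
    auc = _pair_auc(scores, labels)
    # thresholds: midpoints between consecutive unique scores plus extremes
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    spec = np.array([(scores[labels == 0] < t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc, n_pos=n_pos, n_neg=n_neg,
                    flipped=flipped, scores=scores, labels=labels)


def trapezoid_auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve (independent of pair counting)."""
    fpr = 1.0 - curve.specificity
    order = np.lexsort((curve.sensitivity, fpr))
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Ties break toward higher specificity, then toward the higher threshold,
    so the output is deterministic.
    """
    j = curve.sensitivity + curve.specificity
    best = np.flatnonzero(j >= j.max() - 1e-12)
    order = np.lexsort((-curve.thresholds[best], -curve.specificity[best]))
    i = best[order[0]]
    return (float(curve.thresholds[i]), float(curve.sensitivity[i]),
            float(curve.specificity[i]))


def _placements(scores: np.ndarray, labels: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10 = np.array([(neg < s).mean() + 0.5 * (neg == s).mean() for s in pos])
    v01 = np.array([(pos > s).mean() + 0.5 * (pos == s).mean() for s in neg])
    return v10, v01


def auc_ci(scores: Sequence[float], labels: Sequence[int],
           level: float = 0.95, method: str = "delong",
           seed: int | None = None, B: int = 2000,
           ) -> tuple[float, float]:
    """Confidence interval for the AUC.

    ``delong`` uses the asymptotic variance from placement values; for a
    degenerate AUC of exactly 0 or 1 it falls back to the stratified
    percentile bootstrap (which then requires a seed).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = _pair_auc(scores, labels)
    if method == "delong":
        if auc in (0.0, 1.0):
            warnings.warn("degenerate AUC; falling back to bootstrap CI")
            return auc_ci(scores, labels, level, "bootstrap", seed, B)
        v10, v01 = _placements(scores, labels)
        var = (v10.var(ddof=1) / v10.size) + (v01.var(ddof=1) / v01.size)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap CI requires a seed")
        rng = np.random.default_rng(seed)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        aucs = np.empty(B)
        for b in range(B):
            ps = rng.choice(pos, size=pos.size, replace=True)
            ns = rng.choice(neg, size=neg.size, replace=True)
            s = np.concatenate([ps, ns])
            l = np.concatenate([np.ones(ps.size, int),
                                np.zeros(ns.size, int)])
            aucs[b] = _pair_auc(s, l)
        lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
        return (min(float(lo), auc), max(float(hi), auc))
    raise ValueError("method must be 'delong' or 'bootstrap'")


# ---------------------------------------------------------------------------
# Logistic combination
# ---------------------------------------------------------------------------

def logistic_combine(features: np.ndarray | pd.DataFrame,
                     labels: Sequence[int],
                     tol: float = 1e-8,
                     max_iter: int = 100,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic fit combining markers into one score.

    Returns (weights, linear_predictor) where weights[0] is the intercept.
    Fitting is by iteratively reweighted least squares; convergence when
    the largest coefficient change drops below ``tol``.  Perfect separation
    (diverging coefficients) stops the iteration with a warning and returns
    the last iterate — its score ordering remains usable for ROC analysis.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValueError("labels must align with feature rows")
    if n <= p + 1:
        raise ValueError("need more samples than markers + 1")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant feature columns are not identifiable")
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = Xd * w[:, None]
        try:
            beta_new = np.linalg.solve(Xd.T @ Xw, Xd.T @ (w * z))
        except np.linalg.LinAlgError:
            warnings.warn("IRLS normal equations singular (perfect "
                          "separation?); returning last iterate")
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > 1e3:
            warnings.warn("perfect separation detected (diverging "
                          "coefficients); returning last iterate")
            break
        if step < tol:
            break
    else:
        warnings.warn("IRLS did not converge in "
                      f"{max_iter} iterations (possible perfect "
                      "separation); returning last iterate")
    return beta, Xd @ beta
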