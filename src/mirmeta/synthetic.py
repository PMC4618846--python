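"""Synthetic generators for every pipeline input, with planted ground truth.

The generators emulate the statistical structure of the study inputs —
per-study significant miRNA lists from heterogeneous platforms, RNA-seq
style count matrices with tumor/normal groups, a clinical covariate table
with copula-controlled Spearman associations, per-cancer expression
matrices carrying sign patterns, and multi-source target-gene sets with
anti-correlated expression — without reproducing any real dataset's
content.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (ClinicalTable, ExpressionMatrix, RankedEntry,
                 RankedStudyList, TargetSetCollection, CLINICAL_COLUMNS)


@dataclass(frozen=True)
class SignalSpec:
    """A planted miRNA signal for the ranked-list generator.

    ``penetrance`` is the probability the signal shows up (near the top) in
    a given study; ``rank_strength`` is its expected normalized rank when
    present (small = strong).
    """

    mirna_id: str
    direction: str
    penetrance: float
    rank_strength: float

    def __post_init__(self) -> None:
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must lie in (0,1]")
        if not (0.0 < self.rank_strength <= 1.0):
            raise ValueError("rank_strength must lie in (0,1]")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Negative-binomial count simulation spec (variance = mu + alpha mu^2)."""

    n_features: int
    n_tumor: int
    n_normal: int
    planted: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 0.2
    baseline_mean: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_features, self.n_tumor, self.n_normal) < 1:
            raise ValueError("feature and sample counts must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")


def feature_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Ranked study lists
# ---------------------------------------------------------------------------

def simulate_ranked_studies(n_studies: int,
                            universe: Sequence[str],
                            platform_sizes: Sequence[int],
                            list_lengths: Sequence[int],
                            signals: Sequence[SignalSpec] = (),
                            seed: int | None = None,
                            direction: str = "up",
                            beta_concentration: float = 20.0,
                            ) -> list[RankedStudyList]:
    """Simulate per-study significant lists with planted signals.

    Each study assays a ``platform_size`` subset of the universe (planted
    signal ids are always on the platform so that penetrance is the only
    absence mechanism); non-signal probes are a uniform shuffle.  When a
    signal penetrates a study, its position is drawn from a Beta
    distribution with mean ``rank_strength`` (concentration
    ``beta_concentration``) over the platform; otherwise it behaves like
    background.  The top ``list_length`` probes form the emitted list.
    """
    if seed is None:
        raise ValueError("a seed is required (no ambient randomness)")
    if not universe:
        raise ValueError("universe must be nonempty")
    if len(platform_sizes) != n_studies or len(list_lengths) != n_studies:
        raise ValueError("platform_sizes and list_lengths must have one "
                         "entry per study")
    universe = list(universe)
    uset = set(universe)
    sig_ids = [s.mirna_id for s in signals]
    if len(set(sig_ids)) != len(sig_ids):
        raise ValueError("duplicate signal miRNA ids")
    missing = [s for s in sig_ids if s not in uset]
    if missing:
        raise ValueError(f"signal ids not in universe: {missing}")
    use_signals = [s for s in signals if s.direction == direction]
    rng = np.random.default_rng(seed)
    background = [m for m in universe if m not in set(sig_ids)]
    lists = []
    for i in range(n_studies):
        N, L = int(platform_sizes[i]), int(list_lengths[i])
        if L > N:
            raise ValueError(f"study {i}: list_length {L} > platform {N}")
        if N > len(universe):
            raise ValueError(f"study {i}: platform {N} exceeds universe")
        n_bg = N - len(use_signals)
        order = list(rng.choice(len(background), size=n_bg,
                                replace=False))
        ranked = [background[k] for k in rng.permutation(order)]
        # place each signal: Beta position if it penetrates, uniform else
        placements = []
        for s in use_signals:
            if rng.random() < s.penetrance:
                m = s.rank_strength
                a = m * beta_concentration
                b = (1.0 - m) * beta_concentration
                pos = max(1, int(np.ceil(rng.beta(a, b) * N)))
            else:
                pos = int(rng.integers(1, N + 1))
            placements.append((pos, s.mirna_id))
        for pos, mirna in sorted(placements):
            ranked.insert(min(pos - 1, len(ranked)), mirna)
        entries = tuple(RankedEntry(m) for m in ranked[:L])
        lists.append(RankedStudyList(f"study{i + 1:02d}", direction,
                                     entries, N))
    return lists


# ---------------------------------------------------------------------------
# Expression count matrices
# ---------------------------------------------------------------------------

def simulate_expression(spec: ExpressionSimSpec,
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Simulate an NB raw-count matrix and its RPM-normalized twin.

    Per-feature baselines are log-normal around ``baseline_mean``; tumor
    means are shifted by the planted log2 fold changes.  The RPM twin
    scales every sample to a total of 10^6.
    """
    rng = np.random.default_rng(spec.seed)
    feats = feature_ids(spec.n_features)
    fset = set(feats)
    for f in spec.planted:
        if f not in fset:
            raise ValueError(f"planted feature {f!r} not among the "
                             f"{spec.n_features} features")
    n = spec.n_tumor + spec.n_normal
    samples = [f"T{i:03d}" for i in range(1, spec.n_tumor + 1)] + \
              [f"N{i:03d}" for i in range(1, spec.n_normal + 1)]
    groups = pd.Series(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal,
                       index=samples)
    base = spec.baseline_mean * rng.lognormal(0.0, 1.0, size=spec.n_features)
    lfc = np.array([spec.planted.get(f, 0.0) for f in feats])
    mu = np.tile(base[:, None], (1, n))
    mu[:, :spec.n_tumor] *= 2.0 ** lfc[:, None]
    r = 1.0 / spec.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=feats, columns=samples,
                             dtype=float)
    raw = ExpressionMatrix(data=counts_df, unit="raw_count", groups=groups)
    totals = counts_df.sum(axis=0)
    rpm = ExpressionMatrix(data=counts_df / totals * 1e6, unit="RPM",
                           groups=groups.copy())
    return raw, rpm


# ---------------------------------------------------------------------------
# Clinical tables with copula-controlled correlations
# ---------------------------------------------------------------------------

def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= 1e-10:
        return corr
    vals = np.clip(vals, 1e-10, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def simulate_clinical(n: int,
                      targets: Mapping[tuple[str, str], float],
                      group_shifts: Mapping[tuple[str, str, str], float]
                      = None,
                      seed: int | None = None,
                      markers: Sequence[str] = ("mirA", "mirB", "mirC"),
                      gleason_probs: Mapping[int, float] | None = None,
                      ) -> tuple[ClinicalTable, ExpressionMatrix]:
    """Simulate a clinical table and a log2 marker matrix.

    ``targets`` maps unordered variable pairs — markers or the continuous
    covariates age / psa / positive_nodes — to desired Spearman rho.  A
    Gaussian copula (latent Pearson rho = 2 sin(pi rho_s / 6)) makes the
    targets survive the monotone marginal transforms.  ``group_shifts``
    maps (marker, covariate, level) to a location shift, in marker SDs,
    added to samples at that level (gleason levels are 'low' (<=7) /
    'high' (>=8); other covariates use literal level values).
    """
    if seed is None:
        raise ValueError("a seed is required (no ambient randomness)")
    for pair, rho in targets.items():
        if abs(rho) >= 1.0:
            raise ValueError(f"|rho| must be < 1 for {pair}")
    rng = np.random.default_rng(seed)
    continuous = ["age", "psa", "positive_nodes"]
    variables = list(markers) + continuous
    idx = {v: i for i, v in enumerate(variables)}
    unknown = [v for pair in targets for v in pair if v not in idx]
    if unknown:
        raise ValueError(f"unknown variables in targets: {sorted(set(unknown))}")
    d = len(variables)
    corr = np.eye(d)
    for (a, b), rho in targets.items():
        latent = 2.0 * math.sin(math.pi * rho / 6.0)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = latent
    corr = _nearest_psd(corr)
    z = rng.multivariate_normal(np.zeros(d), corr, size=n)
    u = stats.norm.cdf(z)
    samples = [f"P{i:04d}" for i in range(1, n + 1)]

    marker_vals = {m: 8.0 + 2.0 * z[:, idx[m]] for m in markers}
    age = np.round(60.4 + 7.0 * z[:, idx["age"]]).astype(float)
    psa = np.clip(np.exp(2.0 + 0.9 * z[:, idx["psa"]]), 0.1, None)
    nodes = stats.poisson.ppf(u[:, idx["positive_nodes"]], mu=0.7)

    if gleason_probs is None:
        gleason_probs = {6: 0.35, 7: 0.40, 8: 0.15, 9: 0.08, 10: 0.02}
    g_levels = sorted(gleason_probs)
    g_p = np.array([gleason_probs[g] for g in g_levels], dtype=float)
    gleason = rng.choice(g_levels, size=n, p=g_p / g_p.sum()).astype(float)
    race = rng.choice(["white", "black", "asian"], size=n, p=[0.7, 0.2, 0.1])
    pT = rng.choice(["T2", "T3", "T4"], size=n, p=[0.6, 0.35, 0.05])
    histology = rng.choice(["acinar", "other"], size=n, p=[0.9, 0.1])
    pN = np.where(nodes > 0, "pN1", "pN0")

    derived = {
        "gleason": pd.Series(np.where(gleason >= 8, "high", "low"),
                             index=samples),
        "race": pd.Series(race, index=samples),
        "pT": pd.Series(pT, index=samples),
        "histology": pd.Series(histology, index=samples),
        "pN": pd.Series(pN, index=samples),
    }
    if group_shifts:
        for (marker, cov, level), shift in group_shifts.items():
            if marker not in marker_vals:
                raise ValueError(f"unknown marker {marker!r} in group_shifts")
            if cov not in derived:
                raise ValueError(f"unknown covariate {cov!r} in group_shifts")
            mask = (derived[cov] == level).to_numpy()
            sd = marker_vals[marker].std()
            marker_vals[marker] = marker_vals[marker] + shift * sd * mask

    clin = pd.DataFrame({
        "age": age, "psa": psa, "race": race, "gleason": gleason,
        "positive_nodes": nodes, "pN": pN, "pT": pT,
        "histology": histology,
    }, index=samples)[CLINICAL_COLUMNS]
    marker_df = pd.DataFrame(marker_vals, index=samples).T
    groups = pd.Series("tumor", index=samples)
    matrix = ExpressionMatrix(data=marker_df, unit="log2RPM", groups=groups)
    return ClinicalTable(clin), matrix


# ---------------------------------------------------------------------------
# Pan-cancer matrices
# ---------------------------------------------------------------------------

def simulate_pan_cancer(cancer_types: Sequence[str],
                        pattern: Mapping[str, Mapping[str, str]],
                        n_tumor: int = 40,
                        n_normal: int = 15,
                        effect_lfc: float = 2.0,
                        sigma: float = 1.0,
                        base_log2: float = 6.0,
                        seed: int | None = None,
                        ) -> dict[str, ExpressionMatrix]:
    """One RPM matrix per cancer carrying planted direction patterns.

    ``pattern`` maps cancer -> (miRNA -> up/down/flat); 'flat' plants a
    log2 FC of zero.  Values are log-normal with per-feature noise sigma.
    """
    if seed is None:
        raise ValueError("a seed is required (no ambient randomness)")
    mirnas = sorted({m for per in pattern.values() for m in per})
    for cancer, per in pattern.items():
        if cancer not in cancer_types:
            raise ValueError(f"pattern references unknown cancer {cancer!r}")
        bad = set(per.values()) - {"up", "down", "flat"}
        if bad:
            raise ValueError(f"{cancer}: directions must be "
                             f"up/down/flat, got {bad}")
    rng = np.random.default_rng(seed)
    out = {}
    for cancer in cancer_types:
        per = pattern.get(cancer, {})
        samples = [f"{cancer}.T{i:03d}" for i in range(1, n_tumor + 1)] + \
                  [f"{cancer}.N{i:03d}" for i in range(1, n_normal + 1)]
        groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal,
                           index=samples)
        log2vals = base_log2 + sigma * rng.standard_normal(
            (len(mirnas), n_tumor + n_normal))
        for r, m in enumerate(mirnas):
            call = per.get(m, "flat")
            if call == "up":
                log2vals[r, :n_tumor] += effect_lfc
            elif call == "down":
                log2vals[r, :n_tumor] -= effect_lfc
        data = pd.DataFrame(2.0 ** log2vals, index=mirnas, columns=samples)
        out[cancer] = ExpressionMatrix(data=data, unit="RPM", groups=groups)
    return out


# ---------------------------------------------------------------------------
# Target sets with anti-correlated expression
# ---------------------------------------------------------------------------

@dataclass
class TargetSimulation:
    """Planted target-set scenario: sets, expression and ground truth."""

    collection: TargetSetCollection
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    truth: dict


def simulate_targets(mirnas: Sequence[str],
                     n_sources: int = 3,
                     source_overlap: float = 0.8,
                     validated_fraction: float = 0.5,
                     anti_correlated_genes: Mapping[str, set[str]]
                     | None = None,
                     shared_gene: str | None = None,
                     seed: int | None = None,
                     n_samples: int = 400,
                     pool_size: int = 60,
                     universe_size: int = 1000,
                     anti_rho: float = -0.4,
                     ) -> TargetSimulation:
    """Simulate prediction sources, a validated set and expression data.

    Each miRNA gets a true target pool; every prediction source includes
    each pool gene with probability ``source_overlap`` plus
    ``(1 - source_overlap) * pool_size`` private noise genes, so
    ``source_overlap=1`` makes all sources identical.  The validated set
    samples ``validated_fraction`` of the pool.  Genes named in
    ``anti_correlated_genes`` (and the optional ``shared_gene``) are forced
    into every source, the validated set and the DE truth, and their
    expression is generated rank-correlated at ``anti_rho`` with their
    miRNA (the shared gene with all miRNAs).  ``truth`` records pools,
    the DE gene set and the planted genes.
    """
    if seed is None:
        raise ValueError("a seed is required (no ambient randomness)")
    if not (0.0 <= validated_fraction <= 1.0):
        raise ValueError("validated_fraction must lie in [0,1]")
    if not (0.0 <= source_overlap <= 1.0):
        raise ValueError("source_overlap must lie in [0,1]")
    rng = np.random.default_rng(seed)
    anti = {m: set(g) for m, g in (anti_correlated_genes or {}).items()}
    unknown = set(anti) - set(mirnas)
    if unknown:
        raise ValueError(f"anti_correlated_genes references unknown "
                         f"miRNAs: {sorted(unknown)}")
    genes = feature_ids(universe_size, prefix="G")
    forced_all = sorted(set().union(*anti.values()) if anti else set())
    if shared_gene:
        forced_all.append(shared_gene)
    extra = [g for g in forced_all if g not in set(genes)]
    genes = genes + sorted(set(extra))

    pools: dict[str, set[str]] = {}
    sources = [f"source{k + 1}" for k in range(n_sources)]
    predicted: dict[str, dict[str, set[str]]] = {s: {} for s in sources}
    validated: dict[str, set[str]] = {}
    pool_candidates = [g for g in genes if g not in set(forced_all)]
    for m in mirnas:
        forced = set(anti.get(m, set()))
        if shared_gene:
            forced.add(shared_gene)
        drawn = rng.choice(len(pool_candidates),
                           size=max(0, pool_size - len(forced)),
                           replace=False)
        pool = forced | {pool_candidates[i] for i in drawn}
        pools[m] = pool
        free = sorted(pool - forced)
        n_noise = int(round((1.0 - source_overlap) * pool_size))
        outside = [g for g in pool_candidates if g not in pool]
        for s in sources:
            keep = {g for g in free if rng.random() < source_overlap}
            noise_idx = rng.choice(len(outside), size=n_noise, replace=False) \
                if n_noise else []
            predicted[s][m] = forced | keep | {outside[i] for i in noise_idx}
        val = {g for g in free if rng.random() < validated_fraction}
        validated[m] = forced | val
    collection = TargetSetCollection(predicted=predicted,
                                     validated=validated)

    # expression: latent miRNA scores, planted genes anti-correlated
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    zm = rng.standard_normal((len(mirnas), n_samples))
    mirna_df = pd.DataFrame(8.0 + 1.5 * zm, index=list(mirnas),
                            columns=samples)
    latent_rho = 2.0 * math.sin(math.pi * anti_rho / 6.0)
    expressed = sorted(set().union(*pools.values()))
    gexpr = {}
    zshared = zm.mean(axis=0) / max(zm.mean(axis=0).std(), 1e-9)
    for g in expressed:
        owners = [m for m in mirnas if g in anti.get(m, set())]
        if shared_gene and g == shared_gene:
            zg = latent_rho * zshared + math.sqrt(
                max(0.0, 1 - latent_rho ** 2)) * rng.standard_normal(n_samples)
        elif owners:
            zi = zm[list(mirnas).index(owners[0])]
            zg = latent_rho * zi + math.sqrt(
                1 - latent_rho ** 2) * rng.standard_normal(n_samples)
        else:
            zg = rng.standard_normal(n_samples)
        gexpr[g] = 6.0 + 1.0 * zg
    mrna_df = pd.DataFrame(gexpr, index=samples).T
    groups = pd.Series("tumor", index=samples)
    truth = {
        "pools": pools,
        "de_genes": set(expressed),
        "planted_anti": anti,
        "shared_gene": shared_gene,
    }
    return TargetSimulation(
        collection=collection,
        mrna=ExpressionMatrix(data=mrna_df, unit="log2RPKM",
                              groups=groups),
        mirna=ExpressionMatrix(data=mirna_df, unit="log2RPM",
                               groups=groups.copy()),
        truth=truth,
    )
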