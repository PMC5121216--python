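"""Evaluation of AR sets: reference-regulon Jaccard, CLR support,
cross-genome role-set comparison, subsampling sensitivity and 2-fold
cross-validation.

The CLR (context likelihood of relatedness) check is a small-scale
reimplementation of the mutual-information network score: pairwise MI is
estimated on equal-frequency-binned profiles and z-scored against each
gene's own MI background, ``score_ij = sqrt(max(z_i,0)^2 + max(z_j,0)^2)``;
pairs at least ``k_sd`` standard deviations above the mean score (default
4) count as supported regulatory interactions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .config import RunConfig
from .inference import ARResult, infer_atomic_regulons
from .io import ExpressionMatrix, FeatureTable, RegulonReference, RoleMap

__all__ = [
    "CLRResult",
    "SupportReport",
    "jaccard",
    "best_jaccard_per_regulon",
    "similarity_fraction_at_least",
    "clr_scores",
    "clr_cutoff",
    "support_fraction",
    "support_report",
    "role_set_jaccard",
    "subsample_sensitivity",
    "summarize_sensitivity",
    "crossval_jaccard",
    "CrossValTable",
]

SUPPORT_BINS = ("0-20%", "20-40%", "40-60%", "60-80%", "80-100%", "100%")


# ---------------------------------------------------------------------------
# Jaccard comparisons
# ---------------------------------------------------------------------------


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|. Undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def best_jaccard_per_regulon(reference: RegulonReference, clusters) -> pd.Series:
    """Max Jaccard of each reference regulon against any cluster.

    An empty cluster list gives 0 for every regulon (vacuous max), with a
    warning.
    """
    clusters = [set(getattr(c, "members", c)) for c in clusters]
    if not clusters:
        warnings.warn("empty cluster list: best Jaccard is 0 for every regulon")
    out = {}
    for rid, members in reference.regulons.items():
        out[rid] = max((jaccard(members, c) for c in clusters), default=0.0)
    return pd.Series(out, name="best_jaccard").sort_index()


def similarity_fraction_at_least(best: pd.Series, levels=(0.5, 0.7)) -> dict[float, float]:
    """Fraction of reference regulons whose best Jaccard reaches each level."""
    return {lvl: float((best >= lvl).mean()) for lvl in levels}


# ---------------------------------------------------------------------------
# CLR: mutual information + background z-scoring
# ---------------------------------------------------------------------------


@dataclass
class CLRResult:
    """Symmetric CLR score matrix with optional cutoff and supported pairs."""

    scores: pd.DataFrame
    cutoff: float | None = None
    supported_pairs: set[frozenset[str]] | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    def pair_scores(self) -> np.ndarray:
        """All C(n,2) pairwise scores (upper triangle, row-major)."""
        arr = self.scores.to_numpy(dtype=float)
        return arr[np.triu_indices(arr.shape[0], k=1)]

    @property
    def fraction_retained(self) -> float | None:
        if self.supported_pairs is None:
            return None
        n_pairs = math.comb(len(self.scores), 2)
        return len(self.supported_pairs) / n_pairs if n_pairs else 0.0


def _equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency bin indices; NaN -> -1 (excluded)."""
    out = np.full(values.shape, -1, dtype=int)
    mask = ~np.isnan(values)
    m = int(mask.sum())
    if m:
        order = np.argsort(values[mask], kind="mergesort")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(m)
        out[mask] = (ranks * n_bins) // m
    return out


def clr_scores(expr: ExpressionMatrix, n_bins: int | None = None) -> CLRResult:
    """Pairwise CLR scores from binned mutual information.

    MI is estimated per pair on equal-frequency discretized profiles
    (``n_bins`` defaults to min(10, floor(sqrt(#experiments)))), restricted
    to experiments where both genes are observed. Each MI value is
    z-scored within both genes' MI distributions and combined as
    ``sqrt(max(z_i,0)^2 + max(z_j,0)^2)``. A constant gene has MI 0
    against every partner (logged).
    """
    m = expr.n_experiments
    if m < 8:
        warnings.warn(f"only {m} experiments: MI estimates will be coarse")
    if n_bins is None:
        n_bins = max(2, min(10, int(math.isqrt(m))))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = expr.data.to_numpy(dtype=float)
    n = values.shape[0]
    binned = np.vstack([_equal_frequency_bins(values[i], n_bins) for i in range(n)])
    constant = [
        expr.gene_ids[i]
        for i in range(n)
        if np.nanstd(values[i]) == 0
    ]
    if constant:
        warnings.warn(f"{len(constant)} constant gene(s) have MI 0 against all partners")
    mi = np.zeros((n, n))
    for i in range(n):
        bi = binned[i]
        for j in range(i + 1, n):
            mask = (bi >= 0) & (binned[j] >= 0)
            if mask.sum() >= 2:
                mi[i, j] = mi[j, i] = mutual_info_score(bi[mask], binned[j][mask])
    # background correction: z-score each pair's MI within both genes' rows
    off = ~np.eye(n, dtype=bool)
    row_mean = np.array([mi[i, off[i]].mean() for i in range(n)]) if n > 1 else np.zeros(n)
    row_std = np.array([mi[i, off[i]].std() for i in range(n)]) if n > 1 else np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mi - row_mean[:, None]) / row_std[:, None]
    z = np.where(np.isfinite(z), z, 0.0)
    z = np.maximum(z, 0.0)
    scores = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(scores, 0.0)
    return CLRResult(pd.DataFrame(scores, index=expr.gene_ids, columns=expr.gene_ids))


def clr_cutoff(result: CLRResult, k_sd: float = 4.0) -> CLRResult:
    """Threshold at mean + k_sd * SD of all pairwise scores.

    Pairs with score >= cutoff are the CLR-supported interactions. A zero
    SD degenerates to cutoff = mean (every pair supported), with a
    warning. Raising ``k_sd`` never grows the supported set.
    """
    pair_scores = result.pair_scores()
    if pair_scores.size < 2:
        raise ValueError("need at least 2 gene pairs to set a cutoff")
    mean, sd = float(pair_scores.mean()), float(pair_scores.std())
    if sd == 0.0:
        warnings.warn("zero SD of CLR scores: cutoff degenerates to the mean")
    cutoff = mean + k_sd * sd
    genes = result.gene_ids
    arr = result.scores.to_numpy(dtype=float)
    ii, jj = np.triu_indices(len(genes), k=1)
    keep = arr[ii, jj] >= cutoff
    supported = {frozenset((genes[i], genes[j])) for i, j in zip(ii[keep], jj[keep])}
    return CLRResult(result.scores, cutoff=cutoff, supported_pairs=supported)


# ---------------------------------------------------------------------------
# per-AR CLR support
# ---------------------------------------------------------------------------


@dataclass
class SupportReport:
    """CLR support of one AR: supported fraction of its C(n,2) member pairs."""

    ar_id: str
    n_genes: int
    n_pairs: int
    n_supported: int

    @property
    def fraction(self) -> float:
        return self.n_supported / self.n_pairs

    @property
    def bin(self) -> str:
        f = self.fraction
        if f == 1.0:
            return "100%"
        lo = int(f * 100) // 20 * 20
        return f"{lo}-{lo + 20}%"


def support_fraction(ar, supported_pairs, ar_id: str = "") -> SupportReport:
    """Fraction of an AR's unordered member pairs predicted by CLR.

    A 3-gene AR with 2 of its 3 pairs supported scores 2/3 = 0.667.
    Singleton ARs have no pairs and are rejected.
    """
    members = sorted(set(getattr(ar, "members", ar)))
    if len(members) < 2:
        raise ValueError("support fraction undefined for a singleton AR")
    pairs = list(itertools.combinations(members, 2))
    n_supported = sum(1 for p in pairs if frozenset(p) in supported_pairs)
    return SupportReport(
        ar_id=ar_id or getattr(ar, "ar_id", ""),
        n_genes=len(members),
        n_pairs=len(pairs),
        n_supported=n_supported,
    )


def support_report(ars, supported_pairs) -> pd.DataFrame:
    """Support fractions and histogram bins for every multi-gene AR."""
    rows = []
    for ar in ars:
        members = set(getattr(ar, "members", ar))
        if len(members) < 2:
            continue  # singletons carry no pair evidence
        rep = support_fraction(ar, supported_pairs, ar_id=getattr(ar, "ar_id", ""))
        rows.append(
            {
                "ar_id": rep.ar_id,
                "n_genes": rep.n_genes,
                "n_pairs": rep.n_pairs,
                "n_supported": rep.n_supported,
                "fraction": rep.fraction,
                "bin": rep.bin,
            }
        )
    return pd.DataFrame(rows, columns=["ar_id", "n_genes", "n_pairs", "n_supported", "fraction", "bin"])


# ---------------------------------------------------------------------------
# cross-genome role-set comparison
# ---------------------------------------------------------------------------


def role_set_jaccard(ar_a, ar_b, roles_a: RoleMap, roles_b: RoleMap) -> float | None:
    """Jaccard of two ARs' subsystem-role sets, restricted to shared roles.

    Gene ids are genome-specific, so cross-genome ARs are compared through
    the functional roles (within subsystems) that occur in *both* genomes.
    Returns None (skipped, logged) when the first AR has no shared role.
    """
    shared = roles_a.roles_of(roles_a.data["gene_id"]) & roles_b.roles_of(roles_b.data["gene_id"])
    re_ = roles_a.roles_of(getattr(ar_a, "members", ar_a)) & shared
    rx = roles_b.roles_of(getattr(ar_b, "members", ar_b)) & shared
    if not re_:
        warnings.warn("AR has no roles shared across genomes; comparison skipped")
        return None
    if not rx:
        return 0.0
    return jaccard(re_, rx)


# ---------------------------------------------------------------------------
# subsampling sensitivity (Figure-4-style protocol)
# ---------------------------------------------------------------------------


def subsample_sensitivity(
    expr: ExpressionMatrix,
    features: FeatureTable,
    roles: RoleMap,
    always_on,
    fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    reps: int = 10,
    seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Re-infer ARs on random experiment subsets and record the four metrics.

    For each fraction and repetition, that share of experiments is drawn
    without replacement, the full pipeline is rerun, and the number of
    genes in multi-gene ARs, the number of multi-gene ARs, and the
    always-ON / always-OFF gene counts are recorded. Deterministic under
    ``seed``. Fractions leaving fewer than 2 experiments are skipped with
    a warning. Returns one row per (fraction, rep).
    """
    rng = np.random.default_rng(seed)
    m = expr.n_experiments
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {frac}")
        k = int(round(frac * m))
        if k < 2:
            warnings.warn(f"fraction {frac} leaves {k} experiment(s); skipped")
            continue
        for rep in range(reps):
            cols = sorted(rng.choice(m, size=k, replace=False))
            sub = expr.subset_experiments([expr.experiment_ids[c] for c in cols])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = infer_atomic_regulons(sub, features, roles, always_on, config)
            rows.append({"fraction": frac, "rep": rep, "n_experiments": k, **res.summary()})
    return pd.DataFrame(rows)


def summarize_sensitivity(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each metric per fraction (the Figure-4 layout)."""
    metrics = [
        "genes_in_multigene_ars",
        "n_multigene_ars",
        "n_always_on_genes",
        "n_always_off_genes",
    ]
    return table.groupby("fraction")[metrics].agg(["mean", "std"])


# ---------------------------------------------------------------------------
# 2-fold cross-validation (Table-1-style)
# ---------------------------------------------------------------------------


@dataclass
class CrossValTable:
    """Pairwise best-Jaccard comparison of AR sets from data halves.

    ``mean``/``sd`` are square DataFrames over {Set1, Set2, All}: cell
    (X, Y) aggregates, over the multi-gene ARs inferred from X, the best
    Jaccard against any AR inferred from Y. Diagonal is 1 (sd 0).
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    results: dict[str, ARResult]

    def formatted(self) -> pd.DataFrame:
        out = self.mean.copy().astype(object)
        for x in self.mean.index:
            for y in self.mean.columns:
                out.loc[x, y] = f"{self.mean.loc[x, y]:.2f} ± {self.sd.loc[x, y]:.2f}"
        return out


def crossval_jaccard(
    expr: ExpressionMatrix,
    features: FeatureTable,
    roles: RoleMap,
    always_on,
    seed: int = 0,
    config: RunConfig | None = None,
    split: tuple[list[str], list[str]] | None = None,
) -> CrossValTable:
    """2-fold cross-validation of AR stability.

    Experiments are split at random into two equal non-overlapping halves
    (or per an explicit ``split``); ARs are inferred on each half and on
    the full set, and each pair of AR sets is compared by per-AR best
    Jaccard, reported as mean and SD.
    """
    if expr.n_experiments < 4:
        raise ValueError("cross-validation needs at least 4 experiments")
    if split is None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(expr.n_experiments)
        half = expr.n_experiments // 2
        ids = expr.experiment_ids
        split = (
            sorted(ids[i] for i in perm[:half]),
            sorted(ids[i] for i in perm[half : 2 * half]),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = {
            "Set1": infer_atomic_regulons(expr.subset_experiments(split[0]), features, roles, always_on, config),
            "Set2": infer_atomic_regulons(expr.subset_experiments(split[1]), features, roles, always_on, config),
            "All": infer_atomic_regulons(expr, features, roles, always_on, config),
        }
    names = list(results)
    mean = pd.DataFrame(1.0, index=names, columns=names)
    sd = pd.DataFrame(0.0, index=names, columns=names)
    for x in names:
        for y in names:
            if x == y:
                continue
            targets = [a.members for a in results[y].ars]
            best = [
                max((jaccard(a.members, t) for t in targets), default=0.0)
                for a in results[x].multigene_ars
            ]
            mean.loc[x, y] = float(np.mean(best)) if best else 0.0
            sd.loc[x, y] = float(np.std(best)) if best else 0.0
    return CrossValTable(mean, sd, results)
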