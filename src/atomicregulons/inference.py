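"""The six-step atomic regulon (AR) inference algorithm.

An atomic regulon is a maximal set of genes with essentially identical
ON/OFF behaviour across an expression compendium; unlike classical
regulons, ARs partition the genes they cover. The pipeline:

1. seed clusters from genome context (predicted operons, subsystems);
2. compute all pairwise Pearson correlations (PCC) over the compendium;
3. split every seed so that all pairwise PCCs inside a multi-gene cluster
   exceed a threshold (default 0.7);
4. merge overlapping clusters by transitive closure so membership becomes
   a partition;
5. re-split each merged cluster by distance accretion: grow sub-clusters
   from the closest pair, adding the gene with the smallest average
   distance while that average stays at or below 0.25, where distance
   maps PCC onto [0, 1] via (1 - PCC)/2;
6. vote each cluster's per-experiment ON/OFF profile and merge clusters
   with exactly identical profiles; clusters whose profile is ON (OFF) in
   every experiment are the static always-ON (always-OFF) ARs.

Every split/merge decision is deterministic: ties are broken by
lexicographic gene id, so reruns are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .calling import OFF, ON, CallMatrix, call_states
from .config import RunConfig
from .genome import GeneCluster, predict_operons, subsystem_clusters
from .io import ExpressionMatrix, FeatureTable, RoleMap

__all__ = [
    "CorrelationMatrix",
    "AtomicRegulon",
    "ARResult",
    "pearson_matrix",
    "pcc_to_distance",
    "split_by_pcc",
    "transitive_merge",
    "accretion_split",
    "ar_profile",
    "merge_by_profile",
    "infer_atomic_regulons",
]


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson correlation matrix.

    Entries are NaN where the PCC is undefined (zero-variance gene or
    fewer than ``min_periods`` shared non-missing experiments); the
    diagonal is fixed at 1. Undefined entries are treated as "no
    correlation evidence" downstream: they never exceed a PCC threshold
    and map to the maximal distance.
    """

    data: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def pcc(self, a: str, b: str) -> float:
        return float(self.data.at[a, b])

    def is_defined(self, a: str, b: str) -> bool:
        return not np.isnan(self.data.at[a, b])


def pearson_matrix(expr: ExpressionMatrix, genes=None, min_periods: int = 3) -> CorrelationMatrix:
    """All-pairs Pearson correlation, pairwise-complete on non-missing values.

    Pairs sharing fewer than ``min_periods`` experiments, and genes with
    zero variance, get NaN (flagged undefined). The diagonal is set to 1.
    """
    data = expr.data if genes is None else expr.data.loc[list(genes)]
    corr = data.T.corr(min_periods=min_periods)
    np.fill_diagonal(corr.values, 1.0)
    # guard against floating-point |r| marginally above 1
    corr = corr.clip(-1.0, 1.0)
    n_undef = int(np.isnan(corr.values[np.triu_indices(len(corr), k=1)]).sum())
    if n_undef:
        warnings.warn(f"{n_undef} gene pair(s) have undefined PCC (zero variance or <{min_periods} shared experiments)")
    return CorrelationMatrix(corr)


def pcc_to_distance(pcc, form: str = "linear"):
    """Map a PCC in [-1, 1] onto a non-negative co-expression distance.

    ``linear`` (default): (1 - PCC)/2, a bijection [-1, 1] -> [0, 1].
    ``squared``: (1 - PCC)^2, an alternative reading of the same printed
    formula; both give exactly 0.25 at PCC = 0.5, the accretion cutoff,
    so the single-pair accretion boundary is identical either way.
    """
    arr = np.asarray(pcc, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(arr) > 1 + 1e-12):
            raise ValueError("PCC outside [-1, 1]")
    if form == "linear":
        out = (1.0 - arr) / 2.0
    elif form == "squared":
        out = (1.0 - arr) ** 2
    else:
        raise ValueError(f"unknown distance form {form!r}")
    return out if out.ndim else float(out)


def _max_distance(form: str) -> float:
    return 1.0 if form == "linear" else 4.0


# ---------------------------------------------------------------------------
# step 3: split seeds so all pairwise PCCs exceed the threshold
# ---------------------------------------------------------------------------


def split_by_pcc(
    cluster: GeneCluster, pcc: CorrelationMatrix, threshold: float = 0.7
) -> list[GeneCluster]:
    """Split a seed cluster so every multi-gene output is a > threshold clique.

    Greedy complete-linkage accretion: seed with the highest-PCC unassigned
    pair above the threshold, then repeatedly add the unassigned member
    whose *minimum* PCC to the current sub-cluster exceeds the threshold
    (taking the candidate with the largest such minimum). Members that
    never join a pair are returned as singletons. Ties break by
    lexicographic gene id; undefined PCCs never exceed the threshold.
    """
    members = sorted(cluster.members)
    if len(members) == 1:
        return [cluster]
    sub = pcc.data.loc[members, members].to_numpy(dtype=float)
    n = len(members)
    unassigned = list(range(n))
    parts: list[list[int]] = []
    while len(unassigned) >= 2:
        # best remaining pair: max PCC above threshold, lexicographic tie-break
        candidates = [
            (-sub[a, b], members[a], members[b], a, b)
            for ai, a in enumerate(unassigned)
            for b in unassigned[ai + 1 :]
            if not np.isnan(sub[a, b]) and sub[a, b] > threshold
        ]
        if not candidates:
            break
        _, _, _, a, b = min(candidates)
        current = [a, b]
        unassigned = [k for k in unassigned if k not in current]
        while unassigned:
            # grow by the max-min-PCC candidate still exceeding the threshold
            growth = []
            for c in unassigned:
                vals = sub[c, current]
                if not np.isnan(vals).any() and vals.min() > threshold:
                    growth.append((-vals.min(), members[c], c))
            if not growth:
                break
            _, _, best_c = min(growth)
            current.append(best_c)
            unassigned.remove(best_c)
        parts.append(sorted(current))
    parts.extend([k] for k in unassigned)
    if len(parts) == 1:
        return [GeneCluster(cluster.cluster_id, cluster.members, cluster.provenance)]
    return [
        GeneCluster(
            f"{cluster.cluster_id}.s{j}",
            frozenset(members[k] for k in part),
            "split",
        )
        for j, part in enumerate(sorted(parts, key=lambda p: members[p[0]]), start=1)
    ]


# ---------------------------------------------------------------------------
# step 4: transitive-closure merge
# ---------------------------------------------------------------------------


def transitive_merge(clusters) -> list[GeneCluster]:
    """Union clusters that share genes into connected components.

    Each input cluster contributes pairwise edges between its members; the
    output is one cluster per connected component, so no gene remains in
    more than one cluster. Output order: size descending, then smallest
    member gene id.
    """
    graph = nx.Graph()
    for cl in clusters:
        members = sorted(getattr(cl, "members", cl))
        graph.add_nodes_from(members)
        graph.add_edges_from(zip(members, members[1:]))  # path suffices for components
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    return [
        GeneCluster(f"merged{k:04d}", frozenset(comp), "merged")
        for k, comp in enumerate(components, start=1)
    ]


# ---------------------------------------------------------------------------
# step 5: distance accretion split
# ---------------------------------------------------------------------------


def accretion_split(
    cluster: GeneCluster,
    pcc: CorrelationMatrix,
    max_avg_dist: float = 0.25,
    form: str = "linear",
) -> list[GeneCluster]:
    """Re-split a merged cluster by average-distance accretion.

    Sub-clusters are grown from the closest unassigned pair (joined only
    if its distance is within ``max_avg_dist``); at each step the
    unassigned member with the minimum average distance to the growing
    sub-cluster is added while that average stays <= ``max_avg_dist``
    (inclusive). When no gene qualifies the sub-cluster closes and the
    procedure restarts on the remainder; leftovers become singletons.
    Undefined PCCs count as maximally distant. If accretion yields a
    single sub-cluster the input is returned unchanged.
    """
    members = sorted(cluster.members)
    if len(members) == 1:
        return [cluster]
    dist = pcc_to_distance(pcc.data.loc[members, members].to_numpy(dtype=float), form)
    dist = np.where(np.isnan(dist), _max_distance(form), dist)
    unassigned = list(range(len(members)))
    parts: list[list[int]] = []
    while len(unassigned) >= 2:
        best_pair, best_d = None, np.inf
        for ai, a in enumerate(unassigned):
            for b in unassigned[ai + 1 :]:
                if dist[a, b] < best_d:
                    best_pair, best_d = (a, b), dist[a, b]
        if best_d > max_avg_dist:
            break
        current = list(best_pair)
        unassigned = [k for k in unassigned if k not in current]
        while unassigned:
            avgs = [(dist[c, current].mean(), members[c], c) for c in unassigned]
            best_avg, _, best_c = min(avgs)
            if best_avg > max_avg_dist:
                break
            current.append(best_c)
            unassigned.remove(best_c)
        parts.append(sorted(current))
    parts.extend([k] for k in unassigned)
    if len(parts) == 1:
        return [GeneCluster(cluster.cluster_id, cluster.members, cluster.provenance)]
    return [
        GeneCluster(
            f"{cluster.cluster_id}.a{j}",
            frozenset(members[k] for k in part),
            "split",
        )
        for j, part in enumerate(sorted(parts, key=lambda p: members[p[0]]), start=1)
    ]


# ---------------------------------------------------------------------------
# step 6: profile voting and identity merge
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomicRegulon:
    """A final AR: disjoint gene set plus its voted per-experiment profile."""

    ar_id: str
    members: frozenset[str]
    profile: tuple[int, ...]  # per-experiment state codes (ON/OFF/UNKNOWN)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def is_always_on(self) -> bool:
        return len(self.profile) > 0 and all(s == ON for s in self.profile)

    @property
    def is_always_off(self) -> bool:
        return len(self.profile) > 0 and all(s == OFF for s in self.profile)


def ar_profile(members, calls: CallMatrix) -> tuple[int, ...]:
    """Plurality-vote a gene set's per-experiment ON/OFF/UNKNOWN profile.

    Same rule as call voting: ON wins if ON votes outnumber OFF votes and
    vice versa; ties and all-UNKNOWN give UNKNOWN.
    """
    members = set(getattr(members, "members", members))
    sub = calls.data.loc[sorted(members)].to_numpy()
    n_on = (sub == ON).sum(axis=0)
    n_off = (sub == OFF).sum(axis=0)
    states = np.where(n_on > n_off, ON, np.where(n_off > n_on, OFF, 0))
    return tuple(int(s) for s in states)


def merge_by_profile(clusters, calls: CallMatrix) -> list[AtomicRegulon]:
    """Union clusters whose voted profiles are exactly identical.

    Identity includes UNKNOWN positions. Profiles are recomputed on the
    merged membership (for clusters merged under this rule the recomputed
    profile always equals the shared one, since vote margins add). The
    result is order-independent: ARs are numbered by size descending then
    smallest member id.
    """
    groups: dict[tuple[int, ...], set[str]] = {}
    for cl in clusters:
        members = set(getattr(cl, "members", cl))
        prof = ar_profile(members, calls)
        groups.setdefault(prof, set()).update(members)
    merged = sorted(groups.values(), key=lambda m: (-len(m), min(m)))
    return [
        AtomicRegulon(f"AR{k:04d}", frozenset(m), ar_profile(m, calls))
        for k, m in enumerate(merged, start=1)
    ]


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


@dataclass
class ARResult:
    """Final AR set plus the four summary metrics and a provenance log.

    ``ars`` holds every final disjoint gene set including singletons;
    the headline metrics count multi-gene ARs only, matching the usual
    reporting convention. Genes that end in singleton, non-static ARs are
    considered unassigned ("the AR set is not comprehensive").
    """

    ars: list[AtomicRegulon]
    experiment_ids: list[str]
    log: list[str] = field(default_factory=list)

    @property
    def multigene_ars(self) -> list[AtomicRegulon]:
        return [a for a in self.ars if len(a) >= 2]

    @property
    def n_multigene_ars(self) -> int:
        return len(self.multigene_ars)

    @property
    def genes_in_multigene_ars(self) -> int:
        return sum(len(a) for a in self.multigene_ars)

    @property
    def n_always_on_genes(self) -> int:
        return sum(len(a) for a in self.ars if a.is_always_on and len(a) >= 2)

    @property
    def n_always_off_genes(self) -> int:
        return sum(len(a) for a in self.ars if a.is_always_off and len(a) >= 2)

    @property
    def unassigned_genes(self) -> set[str]:
        return {g for a in self.ars if len(a) == 1 for g in a.members}

    def summary(self) -> dict[str, int]:
        return {
            "genes_in_multigene_ars": self.genes_in_multigene_ars,
            "n_multigene_ars": self.n_multigene_ars,
            "n_always_on_genes": self.n_always_on_genes,
            "n_always_off_genes": self.n_always_off_genes,
        }

    def membership(self) -> dict[str, str]:
        """gene id -> ar id over all ARs (singletons included)."""
        return {g: a.ar_id for a in self.ars for g in a.members}


def infer_atomic_regulons(
    expr: ExpressionMatrix,
    features: FeatureTable,
    roles: RoleMap,
    always_on,
    config: RunConfig | None = None,
) -> ARResult:
    """Run the full six-step pipeline and return the final AR set.

    Genes present in the expression matrix drive the inference; features
    or roles naming genes without expression are ignored with a warning,
    and expression genes missing from the feature table enter as
    singleton seeds. With fewer than 3 experiments no PCC is defined, so
    correlation-driven steps degenerate to singletons and the result
    contains only profile-merged (static/identical-profile) ARs.
    """
    cfg = config or RunConfig()
    log: list[str] = []
    expr_genes = set(expr.gene_ids)

    # step 1: genome-context seeds
    operons = predict_operons(features, max_gap=cfg.max_operon_gap)
    subsystems = subsystem_clusters(roles)
    log.append(f"step1: {len(operons)} operons, {len(subsystems)} subsystem sets")

    dropped = {g for cl in operons + subsystems for g in cl.members} - expr_genes
    if dropped:
        warnings.warn(f"{len(dropped)} annotated gene(s) lack expression data and are ignored")

    def restrict(clusters, kind):
        out = []
        for cl in clusters:
            kept = frozenset(cl.members & expr_genes)
            if kept:
                out.append(GeneCluster(cl.cluster_id, kept, cl.provenance))
        return out

    operons_e = restrict(operons, "operon")
    subsystems_e = restrict(subsystems, "subsystem")
    covered = {g for cl in operons_e for g in cl.members}
    orphans = sorted(expr_genes - covered)
    seeds = operons_e + subsystems_e + [
        GeneCluster(f"orphan:{g}", frozenset([g]), "operon") for g in orphans
    ]
    if orphans:
        log.append(f"step1: {len(orphans)} expression genes absent from features -> singleton seeds")

    # step 2: calls + correlations
    calls = call_states(
        expr,
        always_on,
        operons=operons_e,
        subsystem_sets=subsystems_e,
        on_percentile=cfg.on_percentile,
        off_percentile=cfg.off_percentile,
        d_percentile=cfg.d_percentile,
    )
    if expr.n_experiments < 3:
        warnings.warn(
            "fewer than 3 experiments: no PCC is defined; only profile-derived ARs are possible"
        )
    pcc = pearson_matrix(expr)
    log.append(f"step2: PCC over {expr.n_experiments} experiments")

    # step 3: expression-informed splitting of every seed
    split = []
    for seed in seeds:
        split.extend(split_by_pcc(seed, pcc, threshold=cfg.pcc_threshold))
    log.append(f"step3: {len(seeds)} seeds -> {len(split)} clusters (all pairwise PCC > {cfg.pcc_threshold})")

    # step 4: transitive closure -> disjoint clusters
    merged = transitive_merge(split)
    log.append(f"step4: transitive closure -> {len(merged)} disjoint clusters")

    # step 5: accretion re-split
    accreted = []
    for cl in merged:
        accreted.extend(
            accretion_split(cl, pcc, max_avg_dist=cfg.max_avg_dist, form=cfg.distance_form)
        )
    log.append(f"step5: accretion (avg distance <= {cfg.max_avg_dist}, {cfg.distance_form}) -> {len(accreted)} clusters")

    # step 6: profile voting + identity merge
    ars = merge_by_profile(accreted, calls)
    log.append(f"step6: profile-identity merge -> {len(ars)} ARs")

    result = ARResult(ars, list(expr.experiment_ids), log)
    log.append(
        "summary: "
        + ", ".join(f"{k}={v}" for k, v in result.summary().items())
        + f", unassigned={len(result.unassigned_genes)}"
    )
    return result
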