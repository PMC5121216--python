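"""Genome-context cluster seeds: predicted operons and subsystem gene sets.

Operons are predicted from coordinates alone: genes on the same contig and
strand are chained whenever the intergenic gap between coordinate-adjacent
genes is at most ``max_gap`` (200 bp by default, the standard
distance-based rule). Subsystem seeds group every gene holding at least
one functional role in a given subsystem; unlike operons they may overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import FeatureTable, RoleMap

__all__ = ["GeneCluster", "predict_operons", "subsystem_clusters"]


@dataclass(frozen=True)
class GeneCluster:
    """A named gene set with a provenance tag for the audit trail."""

    cluster_id: str
    members: frozenset[str]
    provenance: str  # operon | subsystem | split | merged

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


def predict_operons(features: FeatureTable, max_gap: int = 200) -> list[GeneCluster]:
    """Chain same-strand neighbours within ``max_gap`` bp into operons.

    The intergenic gap between coordinate-sorted neighbours is
    ``next.start - chain_end - 1`` where ``chain_end`` is the rightmost end
    seen in the current chain (1-based inclusive coordinates); overlapping
    or nested genes have gap <= 0 and always chain. Singleton operons are
    returned too, so operons partition each (contig, strand) gene list.
    The result is independent of input row order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    df = features.data.sort_values(
        ["contig", "strand", "start", "end", "gene_id"], kind="mergesort"
    )
    operons: list[list[str]] = []
    prev_key = None
    chain_end = None
    for gene_id, contig, strand, start, end in df.itertuples(index=False):
        key = (contig, strand)
        if key == prev_key and start - chain_end - 1 <= max_gap:
            operons[-1].append(gene_id)
            chain_end = max(chain_end, end)
        else:
            operons.append([gene_id])
            chain_end = end
        prev_key = key
    return [
        GeneCluster(f"operon{k:04d}", frozenset(members), "operon")
        for k, members in enumerate(operons, start=1)
    ]


def subsystem_clusters(roles: RoleMap) -> list[GeneCluster]:
    """One cluster per subsystem, containing every gene with a role in it.

    Genes whose roles all lie outside subsystems appear in no cluster; a
    gene with roles in two subsystems appears in both (overlap is resolved
    later by transitive-closure merging).
    """
    return [
        GeneCluster(f"subsystem:{ss}", frozenset(genes), "subsystem")
        for ss, genes in sorted(roles.subsystems().items())
    ]
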