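"""Readers and writers for every file the pipeline touches.

All formats are plain tab-separated text (plus a GFF3 subset for gene
features). Readers validate strictly and raise :class:`FormatError` with
the offending identifier or line number; downstream modules only ever see
the validated in-memory types defined here.

Conventions
-----------
* Gene coordinates are 1-based inclusive (GFF convention).
* Missing expression values are written/read as ``NA`` and held as NaN;
  they propagate as "missing" into pairwise-complete correlation and
  UNKNOWN expression calls.
* Writers are deterministic: atomic regulons are ordered by size
  (descending) then by lexicographically smallest member gene id, so
  reruns produce byte-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "FeatureTable",
    "RoleMap",
    "RegulonReference",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_feature_table",
    "write_feature_table",
    "read_role_map",
    "write_role_map",
    "read_regulon_reference",
    "write_regulon_reference",
    "read_gene_list",
    "read_clusters",
    "write_clusters",
    "write_atomic_regulons",
    "read_call_matrix",
    "write_call_matrix",
    "write_profiles",
]


class FormatError(ValueError):
    """An input file violates the documented format or an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes x experiments.

    ``data`` is a float DataFrame indexed by gene id with experiment ids as
    columns; NaN marks missing entries. Values are assumed to be on a
    normalized log2-like intensity scale but this is not enforced.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate experiment id: {dup!r}")
        if self.data.shape[1] < 1:
            raise FormatError("expression matrix needs at least one experiment")
        self.data = self.data.astype(float)
        all_missing = self.data.isna().all(axis=1)
        if all_missing.any():
            gene = self.data.index[all_missing][0]
            raise FormatError(f"gene {gene!r} has no non-missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.data.shape[1]

    def subset_experiments(self, experiment_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(experiment_ids)].copy())

    def __eq__(self, other) -> bool:  # round-trip equality in tests
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


@dataclass
class FeatureTable:
    """Gene coordinates: gene_id, contig, strand (+/-), start <= end (1-based)."""

    data: pd.DataFrame  # columns: gene_id, contig, strand, start, end

    COLUMNS = ("gene_id", "contig", "strand", "start", "end")

    def __post_init__(self) -> None:
        df = self.data
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"feature table missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            sym = df.loc[bad_strand, "strand"].iloc[0]
            raise FormatError(f"unknown strand symbol: {sym!r}")
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] < 1).any():
            raise FormatError("coordinates are 1-based; start must be >= 1")
        bad = df["start"] > df["end"]
        if bad.any():
            g = df.loc[bad, "gene_id"].iloc[0]
            raise FormatError(f"start > end for gene {g!r}")
        self.data = df.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"])

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)


@dataclass
class RoleMap:
    """gene -> functional role -> subsystem records.

    A gene may carry several roles; a role may map to several genes; the
    subsystem field is empty for roles outside any subsystem.
    """

    data: pd.DataFrame  # columns: gene_id, role, subsystem

    COLUMNS = ("gene_id", "role", "subsystem")

    def __post_init__(self) -> None:
        df = self.data
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"role map missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["subsystem"] = df["subsystem"].fillna("")
        if df.duplicated(subset=["gene_id", "role"]).any():
            row = df.loc[df.duplicated(subset=["gene_id", "role"])].iloc[0]
            raise FormatError(
                f"duplicate (gene, role) pair: ({row['gene_id']!r}, {row['role']!r})"
            )
        self.data = df.reset_index(drop=True)

    def subsystems(self) -> dict[str, set[str]]:
        """Map subsystem id -> set of member gene ids (empty subsystem skipped)."""
        df = self.data[self.data["subsystem"] != ""]
        return {ss: set(g) for ss, g in df.groupby("subsystem")["gene_id"]}

    def roles_of(self, genes, subsystem_only: bool = True) -> set[str]:
        df = self.data[self.data["gene_id"].isin(set(genes))]
        if subsystem_only:
            df = df[df["subsystem"] != ""]
        return set(df["role"])

    def __eq__(self, other) -> bool:
        return isinstance(other, RoleMap) and self.data.equals(other.data)


@dataclass
class RegulonReference:
    """Reference regulons: regulon id -> member gene set. Overlap allowed."""

    regulons: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, members in self.regulons.items():
            if not members:
                raise FormatError(f"regulon {rid!r} has an empty member set")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x experiments TSV (header = experiment ids, col 1 = gene ids).

    Cells are decimal numbers or the token ``NA`` (missing). Duplicate ids,
    non-numeric cells and matrices with fewer than 2 experiment columns are
    rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    experiments = header[1:]
    if len(experiments) < 2:
        raise FormatError(
            f"{path}: expected at least 2 experiment columns, found {len(experiments)}"
        )
    seen: set[str] = set()
    for e in experiments:
        if e in seen:
            raise FormatError(f"{path}: duplicate experiment id: {e!r}")
        seen.add(e)
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        header=None,
        names=["gene_id", *experiments],
        skiprows=1,
        na_values=["NA"],
        keep_default_na=False,
        dtype=str,
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id: {dup!r}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric cell at gene {gene!r}, experiment {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        values[col] = converted
    return ExpressionMatrix(values)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# feature table (TSV or GFF3 subset)
# ---------------------------------------------------------------------------


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if chunk and "=" in chunk:
            key, val = chunk.split("=", 1)
            out[key] = val
    return out


def _read_gff3_features(path) -> FeatureTable:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 fields, got {len(fields)}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "CDS"):
                continue
            attributes = _parse_gff_attributes(attrs)
            if "ID" not in attributes:
                raise FormatError(f"{path}:{lineno}: {ftype} record without an ID attribute")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            rows.append((attributes["ID"], contig, strand, start_i, end_i))
    return FeatureTable(pd.DataFrame(rows, columns=list(FeatureTable.COLUMNS)))


def _looks_like_gff3(path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#"):
                continue
            return len(line.split("\t")) == 9
    return False


def read_feature_table(path) -> FeatureTable:
    """Read gene features from a 5-column TSV or a GFF3 subset (gene/CDS rows)."""
    if _looks_like_gff3(path):
        return _read_gff3_features(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "strand": str})
    return FeatureTable(df)


def write_feature_table(features: FeatureTable, path) -> None:
    features.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# role map / regulon reference / gene lists
# ---------------------------------------------------------------------------


def read_role_map(path) -> RoleMap:
    """Read ``gene_id<TAB>role<TAB>subsystem`` records (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        warnings.warn(f"{path}: empty role map")
    return RoleMap(df)


def write_role_map(roles: RoleMap, path) -> None:
    roles.data.to_csv(path, sep="\t", index=False)


def read_regulon_reference(path) -> RegulonReference:
    """Read ``regulon_id<TAB>gene_id`` rows; genes may appear in several regulons."""
    regulons: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            warnings.warn(f"{path}: empty regulon file")
            return RegulonReference({})
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            regulons.setdefault(parts[0], set()).add(parts[1])
    return RegulonReference(regulons)


def write_regulon_reference(reference: RegulonReference, path) -> None:
    with open(path, "w") as fh:
        fh.write("regulon_id\tgene_id\n")
        for rid in sorted(reference.regulons):
            for gene in sorted(reference.regulons[rid]):
                fh.write(f"{rid}\t{gene}\n")


def read_gene_list(path) -> list[str]:
    """One identifier per line (gene ids or role names); blank lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token:
                out.append(token)
    if not out:
        warnings.warn(f"{path}: empty gene list")
    return out


# ---------------------------------------------------------------------------
# clusters / atomic regulons
# ---------------------------------------------------------------------------


def _sorted_gene_sets(gene_sets) -> list[tuple[str, set[str]]]:
    """Deterministic order: size descending, then smallest member gene id."""
    items = []
    for gs in gene_sets:
        members = set(gs)
        items.append((-len(members), min(members), members))
    items.sort(key=lambda t: (t[0], t[1]))
    return [(t[1], t[2]) for t in items]


def write_clusters(gene_sets, path, id_prefix: str = "AR") -> None:
    """Write gene sets as ``cluster_id<TAB>gene_id`` in deterministic order."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tgene_id\n")
        for k, (_, members) in enumerate(_sorted_gene_sets(gene_sets), start=1):
            cid = f"{id_prefix}{k:04d}"
            for gene in sorted(members):
                fh.write(f"{cid}\t{gene}\n")


def read_clusters(path) -> list[set[str]]:
    clusters: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            warnings.warn(f"{path}: empty cluster file")
            return []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            clusters.setdefault(parts[0], set()).add(parts[1])
    return [members for _, members in sorted(clusters.items())]


def write_atomic_regulons(ar_sets, path) -> None:
    """Write atomic regulon membership as ``ar_id<TAB>gene_id``.

    ``ar_sets`` is any iterable of gene-id sets (or objects with a
    ``members`` attribute, e.g. :class:`~atomicregulons.inference.AtomicRegulon`).
    """
    write_clusters([getattr(a, "members", a) for a in ar_sets], path, id_prefix="AR")


# ---------------------------------------------------------------------------
# call matrices / AR profiles
# ---------------------------------------------------------------------------

_STATE_LABELS = {1: "ON", -1: "OFF", 0: "UNKNOWN"}
_LABEL_STATES = {v: k for k, v in _STATE_LABELS.items()}


def write_call_matrix(calls, path) -> None:
    """Write a gene x experiment matrix of ON/OFF/UNKNOWN labels."""
    labels = calls.data.apply(lambda col: col.map(lambda s: _STATE_LABELS[int(s)]))
    labels.index.name = "gene_id"
    labels.to_csv(path, sep="\t")


def read_call_matrix(path):
    from .calling import CallMatrix  # deferred to avoid an import cycle

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not df.isin(list(_LABEL_STATES)).all(axis=None):
        raise FormatError(f"{path}: call matrix cells must be ON, OFF or UNKNOWN")
    codes = df.apply(lambda col: col.map(_LABEL_STATES)).astype(np.int8)
    return CallMatrix(codes)


def write_profiles(ars, experiment_ids, path) -> None:
    """Write per-AR ON/OFF/UNKNOWN profiles, same AR order as the AR TSV."""
    order = _sorted_gene_sets([a.members for a in ars])
    by_key = {min(a.members): a for a in ars}
    with open(path, "w") as fh:
        fh.write("ar_id\t" + "\t".join(experiment_ids) + "\n")
        for k, (first, _) in enumerate(order, start=1):
            ar = by_key[first]
            labels = [_STATE_LABELS[int(s)] for s in ar.profile]
            fh.write(f"AR{k:04d}\t" + "\t".join(labels) + "\n")
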