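"""Trinary ON/OFF/UNKNOWN discretization of expression values.

The scheme anchors per-experiment thresholds to an a-priori set of
"always ON" genes (constitutive machinery such as ribosomal proteins and
RNA polymerase): the ON threshold ``N_i`` for experiment *i* is the 10th
percentile of the always-ON genes' values in *i*, and the OFF threshold
``F_i`` is the 80th percentile of all values strictly below ``N_i``. A
global floor on the gap ``D_i = N_i - F_i`` (the 25th percentile of the
gaps, ``D_25th``) keeps the two thresholds from collapsing in quiet
experiments. Initial per-gene calls are then refined by majority voting
inside trusted co-expression sets (operons, then subsystems).

States are encoded as int8: ON = 1, OFF = -1, UNKNOWN = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "ON",
    "OFF",
    "UNKNOWN",
    "CallMatrix",
    "ExperimentThresholds",
    "ConfigurationError",
    "MembershipError",
    "compute_thresholds",
    "initial_calls",
    "vote_calls",
    "call_states",
]

ON: int = 1
OFF: int = -1
UNKNOWN: int = 0


class ConfigurationError(ValueError):
    """Invalid calling configuration (e.g. unusable always-ON set)."""


class MembershipError(KeyError):
    """A voting gene set references gene ids absent from the call matrix."""


@dataclass
class CallMatrix:
    """Genes x experiments matrix of trinary states (int8 codes)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(np.int8)
        if not self.data.isin([ON, OFF, UNKNOWN]).all(axis=None):
            raise ValueError("call states must be ON (1), OFF (-1) or UNKNOWN (0)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_labels(self) -> pd.DataFrame:
        return self.data.apply(lambda col: col.map({ON: "ON", OFF: "OFF", UNKNOWN: "UNKNOWN"}))

    def __eq__(self, other) -> bool:
        return isinstance(other, CallMatrix) and self.data.equals(other.data)


@dataclass
class ExperimentThresholds:
    """Per-experiment ON (``n_on``) and OFF (``f_off``) thresholds.

    After construction ``f_off <= n_on`` and ``n_on - f_off >= d_25th``
    hold for every experiment.
    """

    experiment_ids: list[str]
    n_on: np.ndarray
    f_off: np.ndarray
    d_25th: float

    @property
    def d(self) -> np.ndarray:
        return self.n_on - self.f_off


def compute_thresholds(
    expr: ExpressionMatrix,
    always_on,
    *,
    on_percentile: float = 10.0,
    off_percentile: float = 80.0,
    d_percentile: float = 25.0,
) -> ExperimentThresholds:
    """Derive per-experiment ON/OFF thresholds from the always-ON anchor genes.

    For each experiment *i*: ``N_i`` = `on_percentile`-th percentile of the
    always-ON genes' values; ``F_i`` = `off_percentile`-th percentile of all
    values strictly below ``N_i``; experiments whose gap ``D_i = N_i - F_i``
    falls below the `d_percentile`-th percentile of the gaps (``D_25th``)
    have ``F_i`` reset to ``N_i - D_25th``. Percentiles use sorted-value
    linear interpolation. Missing values are ignored.
    """
    always_on = set(always_on)
    if not always_on:
        raise ConfigurationError("always-ON gene set is empty")
    anchor = [g for g in expr.gene_ids if g in always_on]
    if not anchor:
        raise ConfigurationError("always-ON gene set is disjoint from the expression matrix")
    if len(anchor) < len(always_on):
        missing = sorted(always_on - set(anchor))
        warnings.warn(f"{len(missing)} always-ON gene(s) absent from the matrix: {missing[:5]}")

    values = expr.data.to_numpy(dtype=float)
    anchor_rows = expr.data.index.get_indexer(anchor)
    n_exp = expr.n_experiments
    n_on = np.empty(n_exp)
    f_off = np.full(n_exp, np.nan)
    for i in range(n_exp):
        col_anchor = values[anchor_rows, i]
        col_anchor = col_anchor[~np.isnan(col_anchor)]
        if col_anchor.size == 0:
            raise ConfigurationError(
                f"no always-ON values in experiment {expr.experiment_ids[i]!r}"
            )
        n_on[i] = np.percentile(col_anchor, on_percentile)
        col = values[:, i]
        below = col[~np.isnan(col) & (col < n_on[i])]
        if below.size:
            f_off[i] = np.percentile(below, off_percentile)
        else:
            warnings.warn(
                f"experiment {expr.experiment_ids[i]!r}: no values below the ON "
                "threshold; OFF threshold set from the global gap floor"
            )
    d = n_on - f_off
    if np.isnan(d).all():
        warnings.warn("no experiment has values below its ON threshold; gap floor set to 0")
        d_25th = 0.0
    else:
        d_25th = float(np.percentile(d[~np.isnan(d)], d_percentile))
    reset = np.isnan(f_off) | (d < d_25th)
    f_off[reset] = n_on[reset] - d_25th
    return ExperimentThresholds(list(expr.experiment_ids), n_on, f_off, d_25th)


def initial_calls(expr: ExpressionMatrix, thresholds: ExperimentThresholds) -> CallMatrix:
    """Threshold each value: OFF below ``F_i``, ON above ``N_i``, else UNKNOWN.

    Inequalities are strict, so values exactly at a threshold — and missing
    values — are UNKNOWN.
    """
    if list(expr.experiment_ids) != thresholds.experiment_ids:
        raise ValueError("thresholds do not cover the matrix's experiments in order")
    values = expr.data.to_numpy(dtype=float)
    codes = np.zeros(values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        codes[values > thresholds.n_on[np.newaxis, :]] = ON
        codes[values < thresholds.f_off[np.newaxis, :]] = OFF
    return CallMatrix(pd.DataFrame(codes, index=expr.data.index, columns=expr.data.columns))


def vote_calls(calls: CallMatrix, gene_sets) -> CallMatrix:
    """Majority-vote calls within trusted co-expression gene sets.

    Per set and experiment, ON and OFF votes are counted among the input
    calls (UNKNOWN abstains): a plurality sets every member to the winning
    state; ties and all-UNKNOWN sets become UNKNOWN. All set votes are
    computed from the input matrix; if a gene belongs to several sets whose
    votes conflict (ON vs OFF) it becomes UNKNOWN, a definite vote beats
    UNKNOWN votes. Genes in no set keep their input calls.
    """
    gene_index = {g: k for k, g in enumerate(calls.gene_ids)}
    codes = calls.data.to_numpy()
    any_on = np.zeros(codes.shape, dtype=bool)
    any_off = np.zeros(codes.shape, dtype=bool)
    in_set = np.zeros(codes.shape[0], dtype=bool)
    for gs in gene_sets:
        members = set(getattr(gs, "members", gs))
        unknown_ids = members - gene_index.keys()
        if unknown_ids:
            raise MembershipError(f"gene set references unknown gene ids: {sorted(unknown_ids)}")
        rows = [gene_index[g] for g in members]
        sub = codes[rows, :]
        n_on = (sub == ON).sum(axis=0)
        n_off = (sub == OFF).sum(axis=0)
        any_on[rows] |= n_on > n_off
        any_off[rows] |= n_off > n_on
        in_set[rows] = True
    out = codes.copy()
    voted = in_set[:, np.newaxis]
    out[voted & any_on & ~any_off] = ON
    out[voted & any_off & ~any_on] = OFF
    out[voted & (any_on == any_off)] = UNKNOWN
    return CallMatrix(pd.DataFrame(out, index=calls.data.index, columns=calls.data.columns))


def call_states(
    expr: ExpressionMatrix,
    always_on,
    operons=(),
    subsystem_sets=(),
    *,
    on_percentile: float = 10.0,
    off_percentile: float = 80.0,
    d_percentile: float = 25.0,
) -> CallMatrix:
    """Full discretization: thresholds, initial calls, then two voting passes.

    Voting runs over operons first and subsystem sets second, each pass
    reading the previous pass's calls. With no sets the result equals the
    initial calls.
    """
    thresholds = compute_thresholds(
        expr,
        always_on,
        on_percentile=on_percentile,
        off_percentile=off_percentile,
        d_percentile=d_percentile,
    )
    calls = initial_calls(expr, thresholds)
    operon_sets = [s for s in operons if len(getattr(s, "members", s)) >= 2]
    if operon_sets:
        calls = vote_calls(calls, operon_sets)
    subsystem_sets = [s for s in subsystem_sets if len(getattr(s, "members", s)) >= 2]
    if subsystem_sets:
        calls = vote_calls(calls, subsystem_sets)
    return calls
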