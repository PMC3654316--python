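"""Grouped multi-position merging with consistent indexing.

Sub-datasets collected from several crystal positions are screened for
lattice consistency, reindexed onto a common convention via the group's
ambiguity operators, put on a common scale, and merged; statistics are
recorded incrementally as each sub-dataset is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reflection_model import (
    ReflectionTable,
    SymmetryGroup,
    UnitCell,
    unique_keys,
)
from .shell_statistics import (
    ResolutionShell,
    compute_shell_stats,
    overall_stats,
)

__all__ = [
    "SubDataset",
    "GroupedMergeResult",
    "check_lattice_consistency",
    "choose_reference",
    "resolve_indexing",
    "merge_grouped",
]

MATCH_LENGTH_TOL = 0.03   # relative
MATCH_ANGLE_TOL = 2.0     # degrees
EXCLUDE_LENGTH_TOL = 0.10
EXCLUDE_ANGLE_TOL = 10.0
MIN_COMMON_REFLECTIONS = 10


class InsufficientOverlapError(ValueError):
    pass


class NoReferenceError(ValueError):
    pass


@dataclass
class SubDataset:
    dataset_id: str
    table: ReflectionTable
    cell: UnitCell
    lattice_symbol: str
    position: str = ""

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError(f"sub-dataset {self.dataset_id} has no reflections")


@dataclass
class Increment:
    k: int
    dataset_id: str
    shells: list[ResolutionShell]
    overall: ResolutionShell


@dataclass
class GroupedMergeResult:
    reference_id: str
    group_symbol: str
    verdicts: dict[str, str]                 # matched | re_integrated | excluded
    operators: dict[str, np.ndarray]         # applied reindexing matrix
    scale_factors: dict[str, float]
    increments: list[Increment]
    merged: ReflectionTable


def _cell_deviation(cell: UnitCell, ref: UnitCell) -> tuple[float, float]:
    dl = max(
        abs(a - b) / b for a, b in zip(cell.lengths(), ref.lengths())
    )
    da = max(abs(a - b) for a, b in zip(cell.angles(), ref.angles()))
    return dl, da


def check_lattice_consistency(
    subs: list[SubDataset],
    consensus_group: SymmetryGroup,
    consensus_cell: UnitCell,
    length_tol: float = MATCH_LENGTH_TOL,
    angle_tol: float = MATCH_ANGLE_TOL,
) -> dict[str, str]:
    """Verdict per sub-dataset against the consensus lattice.

    ``matched``: same Bravais symbol and cell within tolerance (re-merge as
    is); ``re_integrated``: usable but needs re-merging under the consensus
    convention; ``excluded``: cell grossly incompatible.
    """
    if not subs:
        raise ValueError("need at least one sub-dataset")
    verdicts: dict[str, str] = {}
    for sub in subs:
        dl, da = _cell_deviation(sub.cell, consensus_cell)
        if dl > EXCLUDE_LENGTH_TOL or da > EXCLUDE_ANGLE_TOL:
            verdicts[sub.dataset_id] = "excluded"
        elif (
            sub.lattice_symbol == consensus_group.bravais_lattice
            and dl <= length_tol
            and da <= angle_tol
        ):
            verdicts[sub.dataset_id] = "matched"
        else:
            verdicts[sub.dataset_id] = "re_integrated"
    return verdicts


def choose_reference(subs: list[SubDataset], verdicts: dict[str, str]) -> str:
    """First matched sub-dataset in collection order, else first re-merged."""
    for sub in subs:
        if verdicts.get(sub.dataset_id) == "matched":
            return sub.dataset_id
    for sub in subs:
        if verdicts.get(sub.dataset_id) == "re_integrated":
            return sub.dataset_id
    raise NoReferenceError("every sub-dataset was excluded")


def _merged_intensities(
    table: ReflectionTable, group: SymmetryGroup, op: np.ndarray | None = None
) -> pd.Series:
    hkl = table.hkl
    if op is not None:
        hkl = hkl @ np.asarray(op).T
    keys = unique_keys(hkl, group, friedel_merged=True)
    return pd.Series(table.df["intensity"].to_numpy(), index=keys).groupby(level=0).mean()


def resolve_indexing(
    sub: SubDataset,
    reference: SubDataset,
    group: SymmetryGroup,
    min_common: int = MIN_COMMON_REFLECTIONS,
) -> np.ndarray:
    """Reindexing operator aligning ``sub`` with the reference convention.

    Tries the identity and every ambiguity operator; returns the one with
    the highest Pearson correlation of merged intensities on common unique
    indices.  Ties break toward the identity.  Groups without ambiguity
    operators short-circuit to the identity.
    """
    identity = np.eye(3, dtype=int)
    ops = [identity] + group.ambiguity_matrices
    if len(ops) == 1:
        return identity
    ref_merged = _merged_intensities(reference.table, group)
    best_op, best_corr = None, -np.inf
    for op in ops:
        sub_merged = _merged_intensities(sub.table, group, op)
        common = ref_merged.index.intersection(sub_merged.index)
        if len(common) < min_common:
            raise InsufficientOverlapError(
                f"only {len(common)} common unique reflections for operator "
                f"{op.flatten().tolist()}"
            )
        a = ref_merged.loc[common].to_numpy()
        b = sub_merged.loc[common].to_numpy()
        if np.std(a) == 0 or np.std(b) == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(a, b)[0, 1])
        if corr > best_corr + 1e-12:
            best_op, best_corr = op, corr
    return best_op


def _apply_operator(table: ReflectionTable, op: np.ndarray) -> ReflectionTable:
    df = table.df.copy()
    hkl = df[["h", "k", "l"]].to_numpy() @ np.asarray(op).T
    df[["h", "k", "l"]] = hkl
    return ReflectionTable(df, validate=False)


def merge_grouped(
    subs: list[SubDataset],
    consensus_group: SymmetryGroup,
    consensus_cell: UnitCell,
    edges: np.ndarray,
    verdicts: dict[str, str] | None = None,
) -> GroupedMergeResult:
    """Reindex, rescale and merge sub-datasets in collection order.

    Scaling is a single multiplicative factor per sub-dataset — the ratio
    of mean merged intensities on unique indices shared with the reference
    (1.0 when there is no overlap).  After each addition the per-shell and
    overall statistics of the growing merged table are recorded.
    """
    if verdicts is None:
        verdicts = check_lattice_consistency(subs, consensus_group, consensus_cell)
    reference_id = choose_reference(subs, verdicts)
    reference = next(s for s in subs if s.dataset_id == reference_id)
    ref_merged = _merged_intensities(reference.table, consensus_group)

    operators: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    increments: list[Increment] = []
    merged: ReflectionTable | None = None
    k = 0
    for sub in subs:
        if verdicts[sub.dataset_id] == "excluded":
            continue
        if sub.dataset_id == reference_id:
            op = np.eye(3, dtype=int)
        else:
            op = resolve_indexing(sub, reference, consensus_group)
        operators[sub.dataset_id] = op
        reindexed = _apply_operator(sub.table, op)
        if sub.dataset_id == reference_id:
            scale = 1.0
        else:
            sub_merged = _merged_intensities(reindexed, consensus_group)
            common = ref_merged.index.intersection(sub_merged.index)
            denom = sub_merged.loc[common].mean() if len(common) else 0.0
            scale = (
                float(ref_merged.loc[common].mean() / denom)
                if len(common) and denom > 0
                else 1.0
            )
        scales[sub.dataset_id] = scale
        df = reindexed.df.copy()
        df["intensity"] *= scale
        df["sigma"] *= abs(scale)
        scaled = ReflectionTable(df, validate=False)
        merged = scaled if merged is None else merged.concat(scaled)
        k += 1
        increments.append(
            Increment(
                k=k,
                dataset_id=sub.dataset_id,
                shells=compute_shell_stats(
                    merged, consensus_cell, consensus_group, True, edges
                ),
                overall=overall_stats(
                    merged, consensus_cell, consensus_group, True, edges
                ),
            )
        )
    return GroupedMergeResult(
        reference_id=reference_id,
        group_symbol=consensus_group.symbol,
        verdicts=verdicts,
        operators=operators,
        scale_factors=scales,
        increments=increments,
        merged=merged,
    )
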