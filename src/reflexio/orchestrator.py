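"""Desk-scale program flow: fast mode, full mode, and report writing.

Fast mode: shell statistics → Wilson rejection and re-merge → automatic
resolution limit → both Friedel branches → reports.  Full mode repeats the
statistics/cutoff evaluation under every registry group whose metric
constraints the cell satisfies (P1 always included, listed first) and
ranks the candidates by overall R-meas.

Everything is deterministic given the inputs; report files contain no
timestamps so reruns are byte-identical (the log file is the exception and
is not part of the comparable outputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats, resolution_limit, shell_statistics, wilson_outliers
from .io_formats import DatasetHeader, read_reflections
from .reflection_model import ReflectionTable, SymmetryGroup, UnitCell, get_group, load_registry
from .resolution_limit import CutoffParameters, CutoffResult, determine_resolution_limit
from .shell_statistics import shell_edges, shell_table

__all__ = ["RunConfig", "run_fast", "run_full", "write_run_report", "candidate_groups"]


@dataclass
class RunConfig:
    mode: str  # fast | full
    input_path: str | Path
    output_dir: str | Path
    dialect: str = "xds_ascii"
    n_shells: int = 10
    user_d_min: float | None = None
    i_sigma_cutoff: float = resolution_limit.DEFAULT_I_SIGMA_CUTOFF
    completeness_cutoff: float = resolution_limit.DEFAULT_COMPLETENESS_CUTOFF
    z_threshold: float = wilson_outliers.DEFAULT_Z_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fast", "full"):
            raise ValueError("mode must be 'fast' or 'full'")


def _branch(
    table: ReflectionTable,
    cell: UnitCell,
    group: SymmetryGroup,
    friedel_merged: bool,
    edges: np.ndarray,
    n_rejected: int,
    params: CutoffParameters,
    user_d_min: float | None,
) -> dict:
    shells = shell_statistics.compute_shell_stats(
        table, cell, group, friedel_merged, edges
    )
    if user_d_min is not None:
        cutoff = CutoffResult(
            d_min_new=user_d_min, retained_shells=(), rule="user_supplied"
        )
    else:
        cutoff = determine_resolution_limit(shells, params)
    return {
        "friedel_merged": friedel_merged,
        "n_rejected": n_rejected,
        "shells": shells,
        "overall": shell_statistics.overall_stats(
            table, cell, group, friedel_merged, edges
        ),
        "cutoff": cutoff,
    }


def _process_one_group(
    table: ReflectionTable,
    cell: UnitCell,
    group: SymmetryGroup,
    config: RunConfig,
    log: list[str],
) -> dict:
    """Rejection + re-merge + both Friedel branches under one group."""
    params = CutoffParameters(config.i_sigma_cutoff, config.completeness_cutoff)
    edges, _ = shell_statistics.assign_shells(table, cell, config.n_shells)
    rejections = []
    clean = table
    if math.isfinite(config.z_threshold):
        try:
            fit = wilson_outliers.fit_wilson(table, cell, edges)
            clean, rejections = wilson_outliers.reject_wilson_outliers(
                table, cell, fit, config.z_threshold
            )
            log.append(
                f"wilson_rejection[{group.symbol}]: rejected {len(rejections)} rows"
            )
        except wilson_outliers.WilsonFitError as exc:
            log.append(f"wilson_rejection[{group.symbol}]: FAILED: {exc}")
    branches = []
    for friedel_merged in (True, False):
        try:
            branches.append(
                _branch(clean, cell, group, friedel_merged, edges,
                        len(rejections), params, config.user_d_min)
            )
            log.append(
                f"branch[{group.symbol}, friedel_merged={friedel_merged}]: "
                f"d_min={branches[-1]['cutoff'].d_min_new:.4f} "
                f"({branches[-1]['cutoff'].rule})"
            )
        except Exception as exc:  # keep going: summary marks the stage failed
            log.append(
                f"branch[{group.symbol}, friedel_merged={friedel_merged}]: "
                f"FAILED: {exc}"
            )
    return {
        "group_symbol": group.symbol,
        "branches": branches,
        "rejections": rejections,
        "edges": edges,
    }


def run_fast(config: RunConfig) -> dict:
    """Fast-processing flow on a single reflection file."""
    log: list[str] = [f"mode=fast input={config.input_path}"]
    header, table, n_dropped = read_reflections(config.input_path, config.dialect)
    log.append(f"read {len(table)} rows ({n_dropped} dropped on sigma<=0)")
    group = get_group(header.group_symbol)
    result = _process_one_group(table, header.cell, group, config, log)
    return {
        "mode": "fast",
        "header": header,
        "branches": result["branches"],
        "rejections": result["rejections"],
        "log": log,
    }


# metric constraints per Bravais family (lengths relative, angles degrees)
def _metric_compatible(cell: UnitCell, bravais: str,
                       ltol: float = 0.03, atol: float = 2.0) -> bool:
    a, b, c = cell.lengths()
    al, be, ga = cell.angles()

    def eq(x, y, tol):
        return abs(x - y) <= tol

    def len_eq(x, y):
        return abs(x - y) / max(x, y) <= ltol

    family = bravais[0]
    if family == "a":
        return True
    if family == "m":  # b-unique
        return eq(al, 90, atol) and eq(ga, 90, atol)
    if family == "o":
        return eq(al, 90, atol) and eq(be, 90, atol) and eq(ga, 90, atol)
    if family == "t":
        return (eq(al, 90, atol) and eq(be, 90, atol) and eq(ga, 90, atol)
                and len_eq(a, b))
    if family == "h":
        return (eq(al, 90, atol) and eq(be, 90, atol) and eq(ga, 120, atol)
                and len_eq(a, b))
    if family == "c":
        return (eq(al, 90, atol) and eq(be, 90, atol) and eq(ga, 90, atol)
                and len_eq(a, b) and len_eq(b, c))
    return False


def candidate_groups(cell: UnitCell) -> list[SymmetryGroup]:
    """Registry groups whose lattice fits the cell metric; P1 always first."""
    registry = load_registry()
    out = [registry["P1"]]
    for symbol, group in registry.items():
        if symbol == "P1":
            continue
        if _metric_compatible(cell, group.bravais_lattice):
            out.append(group)
    return out


def run_full(config: RunConfig) -> dict:
    """Full-processing flow: evaluate all metric-compatible candidate groups."""
    log: list[str] = [f"mode=full input={config.input_path}"]
    header, table, n_dropped = read_reflections(config.input_path, config.dialect)
    log.append(f"read {len(table)} rows ({n_dropped} dropped on sigma<=0)")
    candidates = candidate_groups(header.cell)
    log.append(f"candidate lattices: {[g.symbol for g in candidates]}")
    results = []
    for group in candidates:
        results.append(_process_one_group(table, header.cell, group, config, log))

    def rank_key(res):
        merged = [b for b in res["branches"] if b["friedel_merged"]]
        r_meas = merged[0]["overall"].r_meas if merged else float("inf")
        # tie-break toward higher symmetry
        return (round(r_meas, 12), -get_group(res["group_symbol"]).n_rotations)

    ranked = sorted(results, key=rank_key)
    best = ranked[0]
    log.append(f"best lattice: {best['group_symbol']} "
               f"(r_meas={best['branches'][0]['overall'].r_meas:.4f})")
    return {
        "mode": "full",
        "header": header,
        "branches": best["branches"],
        "rejections": best["rejections"],
        "candidates": ranked,
        "log": log,
    }


def write_run_report(bundle: dict, outdir) -> list[Path]:
    """Write the XML summary, per-shell TSVs and the run log; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    results = {"branches": bundle["branches"]}
    if "grouped" in bundle:
        results["grouped"] = bundle["grouped"]
    if "sad_triage" in bundle:
        results["sad_triage"] = bundle["sad_triage"]
    xml_path = outdir / "summary.xml"
    io_formats.write_xml_summary(results, xml_path)
    written.append(xml_path)

    for branch in bundle["branches"]:
        tag = "friedel_merged" if branch["friedel_merged"] else "friedel_separate"
        tsv = outdir / f"shells_{tag}.tsv"
        shell_table(branch["shells"]).to_csv(tsv, sep="\t", index=False)
        written.append(tsv)

    if bundle.get("rejections"):
        rem = outdir / "removals.hkl"
        wilson_outliers.write_removal_file(bundle["rejections"], rem)
        written.append(rem)

    if "grouped" in bundle:
        inc = outdir / "increments.tsv"
        io_formats.write_increment_plot_data(bundle["grouped"], inc)
        written.append(inc)

    log_path = outdir / "run.log"
    log_path.write_text("\n".join(bundle.get("log", [])) + "\n")
    written.append(log_path)
    return written
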