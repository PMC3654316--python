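"""Resolution binning and per-shell merging statistics.

Shells have equal reciprocal-space volume (equal width in 1/d^3).  R-merge /
R-meas follow the standard conventions: sums run over canonical groups with
at least two observations, negative intensities are retained unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reflection_model import (
    ReflectionTable,
    SymmetryGroup,
    UnitCell,
    enumerate_unique,
    d_spacing_array,
    unique_keys,
)

__all__ = [
    "ResolutionShell",
    "assign_shells",
    "compute_shell_stats",
    "overall_stats",
    "shell_table",
]


@dataclass
class ResolutionShell:
    """Quality statistics over one resolution range [d_min, d_max]."""

    d_max: float
    d_min: float
    n_obs: int
    n_unique: int
    n_theoretical: int
    completeness: float | None  # percent; None when n_theoretical == 0
    mean_i_over_sigma: float
    r_merge: float
    r_meas: float
    multiplicity: float

    def __post_init__(self) -> None:
        if not self.d_max > self.d_min:
            raise ValueError("require d_max > d_min")
        if self.completeness is not None and not -1e-9 <= self.completeness <= 100 + 1e-9:
            raise ValueError("completeness out of [0, 100]")


def assign_shells(
    table: ReflectionTable, cell: UnitCell, n_shells: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Split the table's d range into equal-volume shells.

    Returns ``(edges, labels)`` where ``edges`` is a strictly decreasing
    array of n_shells+1 d values spanning the data and ``labels[i]`` is the
    0-based shell of row i (0 = lowest resolution).
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if len(table) == 0:
        raise ValueError("cannot bin an empty table")
    d = table.d_spacings(cell)
    edges = shell_edges(float(d.max()), float(d.min()), n_shells)
    labels = label_shells(d, edges)
    return edges, labels


def shell_edges(d_max: float, d_min: float, n_shells: int) -> np.ndarray:
    """Equal-volume (1/d^3-linear) shell edges from d_max down to d_min."""
    if not d_max > d_min > 0:
        if d_max == d_min:  # single-valued data: widen trivially
            d_max, d_min = d_max * (1 + 1e-9), d_min * (1 - 1e-9)
        else:
            raise ValueError("require d_max > d_min > 0")
    s3 = np.linspace(d_max ** -3, d_min ** -3, n_shells + 1)
    return s3 ** (-1.0 / 3.0)


def label_shells(d: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Shell label per d value; values at edges go to the lower-res bin."""
    n = len(edges) - 1
    labels = np.searchsorted(-edges, -np.asarray(d), side="left") - 1
    return np.clip(labels, 0, n - 1)


def _group_stats(intensity: np.ndarray, sigma: np.ndarray, keys: np.ndarray):
    """Per-row group assignment and merging sums on canonical-key groups.

    Returns (n_unique, r_merge, r_meas, merged mean I, merged sigma,
    group sizes) with the R factors computed over multiply-observed groups.
    """
    order = np.argsort(keys, kind="stable")
    k = keys[order]
    i = intensity[order]
    boundaries = np.flatnonzero(np.r_[True, k[1:] != k[:-1]])
    sizes = np.diff(np.r_[boundaries, len(k)])
    gidx = np.repeat(np.arange(len(sizes)), sizes)
    sums = np.bincount(gidx, weights=i)
    means = sums / sizes
    absdev = np.abs(i - means[gidx])
    dev_sums = np.bincount(gidx, weights=absdev)
    multi = sizes >= 2
    num_merge = dev_sums[multi].sum()
    den = sums[multi].sum()
    factor = np.sqrt(sizes[multi] / (sizes[multi] - 1.0))
    num_meas = (factor * dev_sums[multi]).sum()
    r_merge = float(num_merge / den) if den != 0 else 0.0
    r_meas = float(num_meas / den) if den != 0 else 0.0
    return len(sizes), r_merge, r_meas


def _shell_from_mask(
    intensity: np.ndarray,
    sigma: np.ndarray,
    keys: np.ndarray,
    d_max: float,
    d_min: float,
    n_theoretical: int,
    merged_i_over_sigma: bool,
) -> ResolutionShell:
    n_obs = len(intensity)
    if n_obs == 0:
        return ResolutionShell(
            d_max, d_min, 0, 0, n_theoretical,
            0.0 if n_theoretical else None, 0.0, 0.0, 0.0, 0.0,
        )
    n_unique, r_merge, r_meas = _group_stats(intensity, sigma, keys)
    if merged_i_over_sigma:
        df = pd.DataFrame({"k": keys, "w": sigma ** -2.0, "iw": intensity / sigma ** 2})
        g = df.groupby("k", sort=False).sum()
        i_m = g["iw"] / g["w"]
        s_m = np.sqrt(1.0 / g["w"])
        mean_ios = float(np.mean(i_m / s_m))
    else:
        mean_ios = float(np.mean(intensity / sigma))
    completeness = (
        100.0 * min(n_unique, n_theoretical) / n_theoretical
        if n_theoretical > 0
        else None
    )
    return ResolutionShell(
        d_max=d_max,
        d_min=d_min,
        n_obs=n_obs,
        n_unique=n_unique,
        n_theoretical=n_theoretical,
        completeness=completeness,
        mean_i_over_sigma=mean_ios,
        r_merge=r_merge,
        r_meas=r_meas,
        multiplicity=n_obs / n_unique,
    )


def compute_shell_stats(
    table: ReflectionTable,
    cell: UnitCell,
    group: SymmetryGroup,
    friedel_merged: bool,
    edges: np.ndarray,
    merged_i_over_sigma: bool = False,
) -> list[ResolutionShell]:
    """Per-shell statistics for the given shell edges (decreasing d).

    Completeness denominators come from :func:`enumerate_unique` binned with
    the same edge rule as the observations, so edge reflections are never
    double-counted.
    """
    d = table.d_spacings(cell)
    labels = label_shells(d, edges)
    keys = unique_keys(table.hkl, group, friedel_merged)
    theo = enumerate_unique(
        cell, group, float(edges[-1]), float(edges[0]), friedel_merged
    )
    if len(theo):
        theo_d = d_spacing_array(theo, cell)
        theo_labels = label_shells(theo_d, edges)
        theo_counts = np.bincount(theo_labels, minlength=len(edges) - 1)
    else:
        theo_counts = np.zeros(len(edges) - 1, dtype=int)
    intensity = table.df["intensity"].to_numpy()
    sigma = table.df["sigma"].to_numpy()
    shells = []
    for b in range(len(edges) - 1):
        m = labels == b
        shells.append(
            _shell_from_mask(
                intensity[m],
                sigma[m],
                keys[m],
                float(edges[b]),
                float(edges[b + 1]),
                int(theo_counts[b]),
                merged_i_over_sigma,
            )
        )
    return shells


def overall_stats(
    table: ReflectionTable,
    cell: UnitCell,
    group: SymmetryGroup,
    friedel_merged: bool,
    edges: np.ndarray,
    merged_i_over_sigma: bool = False,
) -> ResolutionShell:
    """Summary row recomputed from the pooled observations."""
    one = np.array([float(edges[0]), float(edges[-1])])
    return compute_shell_stats(
        table, cell, group, friedel_merged, one, merged_i_over_sigma
    )[0]


def shell_table(shells: list[ResolutionShell]) -> pd.DataFrame:
    """Shell statistics as a DataFrame (for TSV reports)."""
    return pd.DataFrame(
        {
            "d_max": [s.d_max for s in shells],
            "d_min": [s.d_min for s in shells],
            "n_obs": [s.n_obs for s in shells],
            "n_unique": [s.n_unique for s in shells],
            "n_theoretical": [s.n_theoretical for s in shells],
            "completeness": [s.completeness for s in shells],
            "mean_i_over_sigma": [s.mean_i_over_sigma for s in shells],
            "r_merge": [s.r_merge for s in shells],
            "r_meas": [s.r_meas for s in shells],
            "multiplicity": [s.multiplicity for s in shells],
        }
    )
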