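"""Wilson-plot fit and Z-score outlier rejection.

Reflections far above their Wilson-expected intensity are written to a
removal list and excluded from a single re-merge pass.  All reflections
are treated as acentric (exponential intensity law); the Z score is
intensity over the fitted expected mean at that resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reflection_model import ReflectionTable, UnitCell
from .shell_statistics import label_shells

__all__ = [
    "WilsonFit",
    "RejectionRecord",
    "fit_wilson",
    "reject_wilson_outliers",
    "write_removal_file",
]

DEFAULT_Z_THRESHOLD = 10.0


@dataclass(frozen=True)
class WilsonFit:
    """ln〈I〉 = log_scale − 2·B·s² with s = 1/(2d)."""

    log_scale: float
    b_factor: float
    shell_s2: tuple[float, ...]
    shell_expected: tuple[float, ...]

    def expected_intensity(self, d: np.ndarray) -> np.ndarray:
        s2 = 1.0 / (4.0 * np.asarray(d, dtype=float) ** 2)
        return np.exp(self.log_scale - 2.0 * self.b_factor * s2)


@dataclass(frozen=True)
class RejectionRecord:
    row: int
    h: int
    k: int
    l: int
    z_score: float
    reason: str = "wilson_z"


class WilsonFitError(ValueError):
    pass


def fit_wilson(
    table: ReflectionTable, cell: UnitCell, edges: np.ndarray
) -> WilsonFit:
    """Least-squares Wilson line through per-shell mean intensities.

    Shells with non-positive mean intensity are excluded; at least three
    usable shells are required.
    """
    d = table.d_spacings(cell)
    labels = label_shells(d, edges)
    intensity = table.df["intensity"].to_numpy()
    n_shells = len(edges) - 1
    s2_pts, log_means = [], []
    for b in range(n_shells):
        m = labels == b
        if not m.any():
            continue
        mean_i = intensity[m].mean()
        if mean_i <= 0:
            continue
        mean_s2 = float(np.mean(1.0 / (4.0 * d[m] ** 2)))
        s2_pts.append(mean_s2)
        log_means.append(np.log(mean_i))
    if len(s2_pts) < 3:
        raise WilsonFitError(
            f"need >= 3 shells with positive mean intensity, have {len(s2_pts)}"
        )
    slope, intercept = np.polyfit(s2_pts, log_means, 1)
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise WilsonFitError("Wilson fit did not converge to finite parameters")
    expected = np.exp(intercept + slope * np.asarray(s2_pts))
    return WilsonFit(
        log_scale=float(intercept),
        b_factor=float(-slope / 2.0),
        shell_s2=tuple(s2_pts),
        shell_expected=tuple(float(e) for e in expected),
    )


def z_scores(table: ReflectionTable, cell: UnitCell, fit: WilsonFit) -> np.ndarray:
    d = table.d_spacings(cell)
    return table.df["intensity"].to_numpy() / fit.expected_intensity(d)


def reject_wilson_outliers(
    table: ReflectionTable,
    cell: UnitCell,
    fit: WilsonFit,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[ReflectionTable, list[RejectionRecord]]:
    """Remove rows with Z strictly above the threshold.

    Returns the clean table and the removal records (mirroring a
    REMOVE.HKL-style rejection file).  The removal list and the clean table
    partition the input rows exactly.
    """
    z = z_scores(table, cell, fit)
    bad = z > z_threshold
    records = [
        RejectionRecord(
            row=int(i),
            h=int(table.df.at[i, "h"]),
            k=int(table.df.at[i, "k"]),
            l=int(table.df.at[i, "l"]),
            z_score=float(z[i]),
        )
        for i in np.flatnonzero(bad)
    ]
    clean = ReflectionTable(table.df.loc[~bad].reset_index(drop=True), validate=False)
    return clean, records


def write_removal_file(records: list[RejectionRecord], path) -> None:
    """Write 'h k l z' lines, one per rejected reflection."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.h} {r.k} {r.l} {r.z_score:.4f}\n")
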