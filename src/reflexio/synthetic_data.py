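"""Synthetic reflection-data generator.

Produces unmerged reflection tables with the statistical structure every
pipeline stage assumes: exponential (acentric Wilson) true intensities
with B-factor falloff, counting-statistics-like Gaussian noise, optional
non-Wilson outliers, optional Friedel-difference injection, and grouped
sub-datasets with per-dataset scales and alternative indexing.  A single
seed drives independent named streams so adding one stage never perturbs
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grouped_merging import SubDataset
from .io_formats import DatasetHeader
from .reflection_model import (
    ReflectionTable,
    UnitCell,
    d_spacing_array,
    enumerate_unique,
    get_group,
)

__all__ = ["SyntheticConfig", "generate_dataset", "generate_subdatasets"]

# named sub-stream ids (stable across releases)
_STREAM_TRUE = 1
_STREAM_ANOM = 2
_STREAM_NOISE = 3
_STREAM_OUTLIER = 4
_STREAM_COVERAGE = 5


@dataclass(frozen=True)
class SyntheticConfig:
    cell: UnitCell
    group_symbol: str = "P1"
    d_min: float = 2.0
    d_max: float | None = None
    b_factor: float = 20.0
    scale: float = 1.0e4
    noise_floor: float = 2.0
    multiplicity: int = 4
    friedel_separate: bool = False
    outlier_fraction: float = 0.0
    outlier_z: float = 100.0
    anomalous_fraction: float = 0.0
    anomalous_delta: float = 0.0
    n_images: int = 100
    oscillation_range: float = 1.0
    starting_angle: float = 0.0
    dataset_id: str = "ds0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")
        for name in ("outlier_fraction", "anomalous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.friedel_separate and self.multiplicity < 2:
            raise ValueError("friedel_separate needs multiplicity >= 2")
        if self.n_images < 1 or self.oscillation_range <= 0:
            raise ValueError("invalid image metadata")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _wilson_means(d: np.ndarray, scale: float, b: float) -> np.ndarray:
    s2 = 1.0 / (4.0 * d * d)
    return scale * np.exp(-2.0 * b * s2)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[DatasetHeader, ReflectionTable, dict]:
    """Generate one unmerged dataset plus a truth record.

    The truth record carries the generator parameters, per-unique true
    intensities, injected outlier row positions and injected anomalous
    index set — everything the tests need for bookkeeping oracles.
    """
    group = get_group(config.group_symbol)
    d_max = config.d_max or (max(config.cell.lengths()) + 1.0)
    uniq = enumerate_unique(config.cell, group, config.d_min, d_max, True)
    if not len(uniq):
        raise ValueError("no reflections in the requested resolution range")
    d_uniq = d_spacing_array(uniq, config.cell)
    means = _wilson_means(d_uniq, config.scale, config.b_factor)
    i_true = _rng(config, _STREAM_TRUE).exponential(means)

    n_uniq = len(uniq)
    anom = np.zeros(n_uniq, dtype=bool)
    if config.anomalous_fraction > 0:
        n_anom = int(round(config.anomalous_fraction * n_uniq))
        pick = _rng(config, _STREAM_ANOM).choice(n_uniq, size=n_anom, replace=False)
        anom[pick] = True

    m = config.multiplicity
    if config.friedel_separate:
        m_plus = m - m // 2
        m_minus = m // 2
        f = np.sqrt(i_true)
        delta = np.where(anom, config.anomalous_delta, 0.0)
        i_plus = (f * (1.0 + delta / 2.0)) ** 2
        i_minus = (f * (1.0 - delta / 2.0)) ** 2
        hkl = np.concatenate([
            np.repeat(uniq, m_plus, axis=0),
            np.repeat(-uniq, m_minus, axis=0),
        ])
        i_obs_true = np.concatenate([
            np.repeat(i_plus, m_plus),
            np.repeat(i_minus, m_minus),
        ])
        uid = np.concatenate([
            np.repeat(np.arange(n_uniq), m_plus),
            np.repeat(np.arange(n_uniq), m_minus),
        ])
    else:
        hkl = np.repeat(uniq, m, axis=0)
        i_obs_true = np.repeat(i_true, m)
        uid = np.repeat(np.arange(n_uniq), m)

    sigma = np.sqrt(np.maximum(i_obs_true, 0.0) + config.noise_floor ** 2)
    noise = _rng(config, _STREAM_NOISE).standard_normal(len(sigma))
    intensity = i_obs_true + sigma * noise

    outlier_rows = np.empty(0, dtype=int)
    if config.outlier_fraction > 0:
        n_out = int(round(config.outlier_fraction * len(intensity)))
        outlier_rows = np.sort(
            _rng(config, _STREAM_OUTLIER).choice(
                len(intensity), size=n_out, replace=False
            )
        )
        d_rows = d_spacing_array(hkl[outlier_rows], config.cell)
        intensity[outlier_rows] = config.outlier_z * _wilson_means(
            d_rows, config.scale, config.b_factor
        )

    image = (np.arange(len(intensity)) % config.n_images) + 1
    table = ReflectionTable.from_arrays(
        hkl[:, 0], hkl[:, 1], hkl[:, 2], intensity, sigma,
        image=image, dataset_id=config.dataset_id,
    )
    header = DatasetHeader(
        cell=config.cell,
        group_symbol=config.group_symbol,
        oscillation_range=config.oscillation_range,
        starting_angle=config.starting_angle,
        n_images=config.n_images,
        dataset_id=config.dataset_id,
    )
    truth = {
        "b_factor": config.b_factor,
        "scale": config.scale,
        "n_unique": n_uniq,
        "unique_hkl": uniq,
        "true_intensity": i_true,
        "row_unique_id": uid,
        "outlier_rows": outlier_rows,
        "anomalous_mask": anom,
        "sum_intensity": float(intensity.sum()),
    }
    return header, table, truth


def generate_subdatasets(
    config: SyntheticConfig,
    k: int,
    coverage_scheme: str = "disjoint_wedges",
    scale_factors: list[float] | None = None,
    applied_ops: dict[int, np.ndarray] | None = None,
) -> tuple[list[SubDataset], dict]:
    """Split one underlying truth into ``k`` sub-datasets.

    ``disjoint_wedges`` assigns each sub-dataset a distinct slice of the
    unique-index set (so incremental completeness strictly increases);
    ``random`` samples overlapping random subsets.  ``applied_ops`` maps a
    0-based sub-dataset position to an indexing operator applied to its
    indices (recorded in the truth for apply-and-recover tests).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if coverage_scheme not in ("disjoint_wedges", "random"):
        raise ValueError(f"unknown coverage scheme {coverage_scheme!r}")
    _, table, truth = generate_dataset(config)
    n_uniq = truth["n_unique"]
    if coverage_scheme == "disjoint_wedges" and k > n_uniq:
        raise ValueError(f"k={k} exceeds the {n_uniq} available unique sectors")
    scale_factors = scale_factors or [1.0] * k
    if len(scale_factors) != k:
        raise ValueError("need one scale factor per sub-dataset")
    applied_ops = applied_ops or {}
    uid = truth["row_unique_id"]

    if coverage_scheme == "disjoint_wedges":
        sector = (np.arange(n_uniq) * k) // n_uniq  # contiguous slices
        member = [sector == j for j in range(k)]
    else:
        rng = _rng(config, _STREAM_COVERAGE)
        member = [rng.random(n_uniq) < 0.7 for _ in range(k)]
        for j in range(k):  # never emit an empty sub-dataset
            if not member[j].any():
                member[j][rng.integers(n_uniq)] = True

    subs: list[SubDataset] = []
    op_truth: dict[str, np.ndarray] = {}
    group = get_group(config.group_symbol)
    for j in range(k):
        rows = member[j][uid]
        df = table.df.loc[rows].reset_index(drop=True).copy()
        df["intensity"] *= scale_factors[j]
        df["sigma"] *= scale_factors[j]
        ds_id = f"sub{j:02d}"
        df["dataset_id"] = ds_id
        op = applied_ops.get(j)
        if op is not None:
            op = np.asarray(op, dtype=int)
            df[["h", "k", "l"]] = df[["h", "k", "l"]].to_numpy() @ op.T
            op_truth[ds_id] = op
        subs.append(
            SubDataset(
                dataset_id=ds_id,
                table=ReflectionTable(df, validate=False),
                cell=config.cell,
                lattice_symbol=group.bravais_lattice,
                position=f"position {j}",
            )
        )
    truth["applied_ops"] = op_truth
    truth["scale_factors"] = dict(zip((s.dataset_id for s in subs), scale_factors))
    truth["membership"] = member
    return subs, truth
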