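"""Anomalous-signal triage and SAD trial planning.

Per-shell Friedel-difference strength 〈d″/σ(d″)〉 drives the decision to
launch phasing trials; the trial grid covers three solvent fractions and
both enantiomorphs, and a solved structure is flagged on strict
correlation and fragment-length thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reflection_model import ReflectionTable, SymmetryGroup, UnitCell, unique_keys
from .shell_statistics import label_shells

__all__ = [
    "AnomalousSummary",
    "TrialPlan",
    "SolutionAssessment",
    "anomalous_signal",
    "evaluate_trigger",
    "estimate_mw",
    "build_trial_plan",
    "assess_solution",
]

ANOMALOUS_TRIGGER_THRESHOLD = 1.3
DEFAULT_SOLVENT_FRACTION = 0.47
TRIAL_SOLVENT_FRACTIONS = (0.37, 0.47, 0.57)
HANDS = ("original", "inverted")
SUCCESS_CC_THRESHOLD = 25.0          # percent
SUCCESS_FRAGMENT_LENGTH_THRESHOLD = 10.0  # residues
PROTEIN_SPECIFIC_VOLUME = 1.23       # Å^3 per Dalton


class NoAnomalousPairsError(ValueError):
    pass


@dataclass(frozen=True)
class AnomalousSummary:
    """Per-shell anomalous-difference statistics and the submission trigger."""

    d_max: tuple[float, ...]
    d_min: tuple[float, ...]
    n_pairs: tuple[int, ...]
    danom_over_sigma: tuple[float | None, ...]  # None where no pairs exist
    trigger: bool
    threshold: float = ANOMALOUS_TRIGGER_THRESHOLD


@dataclass(frozen=True)
class TrialPlan:
    estimated_mw: float
    solvent_fractions: tuple[float, ...]
    hands: tuple[str, ...]
    trials: tuple[tuple[float, str], ...]


@dataclass(frozen=True)
class SolutionAssessment:
    cc_partial: float
    mean_fragment_length: float
    success: bool


def _merge_by_key(keys, intensity, sigma):
    """Inverse-variance merge per key -> (keys, I, sigma) arrays."""
    df = pd.DataFrame(
        {"k": keys, "w": sigma ** -2.0, "iw": intensity * sigma ** -2.0}
    )
    g = df.groupby("k", sort=True).sum()
    i_m = (g["iw"] / g["w"]).to_numpy()
    s_m = np.sqrt(1.0 / g["w"].to_numpy())
    return g.index.to_numpy(), i_m, s_m


def evaluate_trigger(
    per_shell_values, threshold: float = ANOMALOUS_TRIGGER_THRESHOLD
) -> bool:
    """True when any defined shell statistic strictly exceeds the threshold."""
    return any(v is not None and v > threshold for v in per_shell_values)


def anomalous_signal(
    table: ReflectionTable,
    cell: UnitCell,
    group: SymmetryGroup,
    edges: np.ndarray,
    threshold: float = ANOMALOUS_TRIGGER_THRESHOLD,
    mean_of_ratios: bool = False,
) -> AnomalousSummary:
    """Per-shell 〈d″/σ(d″)〉 from Friedel-separate observations.

    Observations are merged per (canonical index, Friedel sign); amplitude
    differences d″ = |F⁺ − F⁻| with F = sqrt(max(I, 0)) and a guarded
    first-order sigma propagation.  The default shell statistic is the
    ratio of means (mean d″ over mean σ).
    """
    hkl = table.hkl
    keys_sep = unique_keys(hkl, group, friedel_merged=False)
    base = keys_sep // 2       # canonical index without the sign bit
    sign_neg = (keys_sep % 2).astype(bool)
    intensity = table.df["intensity"].to_numpy()
    sigma = table.df["sigma"].to_numpy()

    kp, ip, sp = _merge_by_key(base[~sign_neg], intensity[~sign_neg], sigma[~sign_neg])
    km, im, sm = _merge_by_key(base[sign_neg], intensity[sign_neg], sigma[sign_neg])
    common, ia, ib = np.intersect1d(kp, km, return_indices=True)
    if len(common) == 0:
        raise NoAnomalousPairsError("no unique index has both Friedel mates")

    def amp(i, s):
        f = np.sqrt(np.maximum(i, 0.0))
        sf = s / (2.0 * np.maximum(f, np.sqrt(s)))
        return f, sf

    fp, sfp = amp(ip[ia], sp[ia])
    fm, sfm = amp(im[ib], sm[ib])
    danom = np.abs(fp - fm)
    sdanom = np.sqrt(sfp ** 2 + sfm ** 2)

    # place each pair in a shell via the d-spacing of its canonical index
    decoded = _decode_keys(common)
    from .reflection_model import d_spacing_array

    d = d_spacing_array(decoded, cell)
    labels = label_shells(d, edges)
    n_shells = len(edges) - 1
    n_pairs, stat = [], []
    for b in range(n_shells):
        m = labels == b
        n_pairs.append(int(m.sum()))
        if not m.any():
            stat.append(None)
        elif mean_of_ratios:
            stat.append(float(np.mean(danom[m] / sdanom[m])))
        else:
            stat.append(float(danom[m].mean() / sdanom[m].mean()))
    return AnomalousSummary(
        d_max=tuple(float(e) for e in edges[:-1]),
        d_min=tuple(float(e) for e in edges[1:]),
        n_pairs=tuple(n_pairs),
        danom_over_sigma=tuple(stat),
        trigger=evaluate_trigger(stat, threshold),
        threshold=threshold,
    )


def _decode_keys(keys: np.ndarray) -> np.ndarray:
    from .reflection_model import _ENC

    keys = keys.astype(np.int64)
    l = keys % _ENC
    l = np.where(l >= _ENC // 2, l - _ENC, l)
    rem = (keys - l) // _ENC
    k = rem % _ENC
    k = np.where(k >= _ENC // 2, k - _ENC, k)
    h = (rem - k) // _ENC
    return np.stack([h, k, l], axis=1)


def estimate_mw(
    cell: UnitCell,
    group: SymmetryGroup,
    solvent_fraction: float = DEFAULT_SOLVENT_FRACTION,
) -> float:
    """Tentative molecular weight (Da) from the Matthews relation.

    MW = V_cell · (1 − solvent) / (Z · ν̄) with Z = number of rotation
    operators of the group and ν̄ = 1.23 Å³/Da.
    """
    if not 0.0 < solvent_fraction < 1.0:
        raise ValueError("solvent_fraction must be in (0, 1)")
    z = group.n_rotations
    return cell.volume * (1.0 - solvent_fraction) / (z * PROTEIN_SPECIFIC_VOLUME)


def build_trial_plan(cell: UnitCell, group: SymmetryGroup) -> TrialPlan:
    """Deterministic grid of phasing trials: 3 solvent fractions × 2 hands."""
    trials = tuple(
        (sf, hand) for sf in TRIAL_SOLVENT_FRACTIONS for hand in HANDS
    )
    return TrialPlan(
        estimated_mw=estimate_mw(cell, group),
        solvent_fractions=TRIAL_SOLVENT_FRACTIONS,
        hands=HANDS,
        trials=trials,
    )


def assess_solution(cc_partial: float, mean_fragment_length: float) -> SolutionAssessment:
    """Solved-structure flag: strict CC and fragment-length thresholds."""
    if not -100.0 <= cc_partial <= 100.0:
        raise ValueError("cc_partial must be in [-100, 100]")
    if mean_fragment_length < 0:
        raise ValueError("mean_fragment_length must be >= 0")
    success = (
        cc_partial > SUCCESS_CC_THRESHOLD
        and mean_fragment_length > SUCCESS_FRAGMENT_LENGTH_THRESHOLD
    )
    return SolutionAssessment(cc_partial, mean_fragment_length, success)
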