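"""Automatic high-resolution-limit determination.

The shell walk retains low-resolution bins while their signal-to-noise
stays above the cutoff; at the first failing bin the limit is either the
previous bin edge (when completeness has also collapsed) or a linear
interpolation of resolution against 〈I/σ〉 between the last good bin and
the failing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .shell_statistics import ResolutionShell

__all__ = [
    "CutoffParameters",
    "CutoffResult",
    "interpolate_resolution",
    "determine_resolution_limit",
]

DEFAULT_I_SIGMA_CUTOFF = 2.0
DEFAULT_COMPLETENESS_CUTOFF = 80.0


@dataclass(frozen=True)
class CutoffParameters:
    """User-adjustable cutoffs; defaults are the pipeline's standard values."""

    i_sigma_cutoff: float = DEFAULT_I_SIGMA_CUTOFF
    completeness_cutoff: float = DEFAULT_COMPLETENESS_CUTOFF

    def __post_init__(self) -> None:
        if not self.i_sigma_cutoff > 0:
            raise ValueError("i_sigma_cutoff must be > 0")
        if not 0 < self.completeness_cutoff <= 100:
            raise ValueError("completeness_cutoff must be in (0, 100]")


@dataclass(frozen=True)
class CutoffResult:
    d_min_new: float
    retained_shells: tuple[int, ...]
    rule: str  # all_retained | both_below_boundary | interpolated
    warning: str | None = None


def interpolate_resolution(
    prev: ResolutionShell, outer: ResolutionShell, i_cutoff: float
) -> float:
    """Linear interpolation of the limit between two shells' 〈I/σ〉 values.

    ``prev`` is the last shell above the cutoff, ``outer`` the first one
    below it; the returned d lies between their high-resolution edges.
    """
    if not prev.mean_i_over_sigma > i_cutoff:
        raise ValueError("prev shell must have 〈I/σ〉 above the cutoff")
    if not outer.mean_i_over_sigma < i_cutoff:
        raise ValueError("outer shell must have 〈I/σ〉 below the cutoff")
    if not prev.d_min > outer.d_min:
        raise ValueError("prev shell must be at lower resolution than outer")
    d_prev, d_outer = prev.d_min, outer.d_min
    i_prev, i_outer = prev.mean_i_over_sigma, outer.mean_i_over_sigma
    return d_prev + (d_outer - d_prev) * (i_prev - i_cutoff) / (i_prev - i_outer)


def determine_resolution_limit(
    shells: list[ResolutionShell],
    params: CutoffParameters = CutoffParameters(),
) -> CutoffResult:
    """Walk shells from low to high resolution and pick the new d_min.

    Retention requires 〈I/σ〉 strictly greater than the cutoff.  At the
    first failing shell: completeness below its own threshold too means the
    limit snaps back to the previous shell's edge; otherwise the limit is
    interpolated between the two shells.  Completeness is evaluated only at
    the failing shell, not cumulatively.
    """
    if not shells:
        raise ValueError("need at least one shell")
    for a, b in zip(shells, shells[1:]):
        if not a.d_min > b.d_min:
            raise ValueError("shells must be ordered low to high resolution")
    retained: list[int] = []
    for idx, shell in enumerate(shells):
        if shell.mean_i_over_sigma > params.i_sigma_cutoff:
            retained.append(idx)
            continue
        # first failing shell
        completeness = shell.completeness if shell.completeness is not None else 0.0
        if idx == 0:
            return CutoffResult(
                d_min_new=shell.d_max,
                retained_shells=(),
                rule="both_below_boundary",
                warning="no usable data at cutoff",
            )
        prev = shells[idx - 1]
        if completeness < params.completeness_cutoff:
            return CutoffResult(
                d_min_new=prev.d_min,
                retained_shells=tuple(retained),
                rule="both_below_boundary",
            )
        if shell.mean_i_over_sigma == params.i_sigma_cutoff:
            d_new = shell.d_min  # interpolation formula limit, avoids 0/0 concerns
        else:
            d_new = interpolate_resolution(prev, shell, params.i_sigma_cutoff)
        return CutoffResult(
            d_min_new=d_new,
            retained_shells=tuple(retained),
            rule="interpolated",
        )
    return CutoffResult(
        d_min_new=shells[-1].d_min,
        retained_shells=tuple(retained),
        rule="all_retained",
    )
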