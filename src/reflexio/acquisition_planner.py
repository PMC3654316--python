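"""Spot-wedge acquisition planning.

The first wedge covers the first 20 images; a second 10-image wedge is
placed so that it starts 90° away from the dataset's starting angle,
relaxing the separation in 5° steps until a non-overlapping wedge exists.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["WedgePlan", "plan_spot_wedges", "format_spot_ranges"]

DEFAULT_FIRST_WIDTH = 20   # images
DEFAULT_SECOND_WIDTH = 10  # images
DEFAULT_TARGET_SEPARATION = 90.0  # degrees
DEFAULT_DECREMENT = 5.0           # degrees


@dataclass(frozen=True)
class WedgePlan:
    wedges: tuple[tuple[int, int], ...]
    achieved_separation: float | None
    requested_separation: float

    def __post_init__(self) -> None:
        last_end = 0
        for first, last in self.wedges:
            if first < 1 or last < first:
                raise ValueError("invalid wedge range")
            if first <= last_end:
                raise ValueError("wedges must not overlap")
            last_end = last
        if self.wedges and self.wedges[0][0] != 1:
            raise ValueError("first wedge must start at image 1")


def plan_spot_wedges(
    n_images: int,
    starting_angle: float = 0.0,
    oscillation_range: float = 1.0,
    first_width: int = DEFAULT_FIRST_WIDTH,
    second_width: int = DEFAULT_SECOND_WIDTH,
    target_sep: float = DEFAULT_TARGET_SEPARATION,
    decrement: float = DEFAULT_DECREMENT,
) -> WedgePlan:
    """Plan the spot-picking image wedges for a dataset.

    The second wedge starts at the image whose start angle is
    ``starting_angle + sep`` for the largest feasible ``sep`` in
    {target_sep, target_sep − decrement, ...}; the search stops once
    ``sep`` falls below one oscillation step (no distinct images remain).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if oscillation_range <= 0:
        raise ValueError("oscillation_range must be > 0")
    wedge1 = (1, min(first_width, n_images))
    sep = target_sep
    while sep >= oscillation_range:
        first = int(sep / oscillation_range) + 1
        last = first + second_width - 1
        if last <= n_images and first > wedge1[1]:
            return WedgePlan(
                wedges=(wedge1, (first, last)),
                achieved_separation=sep,
                requested_separation=target_sep,
            )
        sep -= decrement
    return WedgePlan(
        wedges=(wedge1,),
        achieved_separation=None,
        requested_separation=target_sep,
    )


def format_spot_ranges(plan: WedgePlan) -> str:
    """Render the plan as SPOT_RANGE= lines for integration-control files."""
    return "\n".join(f"SPOT_RANGE= {a} {b}" for a, b in plan.wedges)
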