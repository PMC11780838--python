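"""Walking-condition grid and spatiotemporal helpers.

The study design crosses three walking speeds, three step-length-asymmetry
levels and three step widths into a 3 x 3 x 3 grid of gait conditions, each
analyzed separately for the left and right leg and for two muscle sets
(the full 43-muscle leg roster and an 8-muscle surface-EMG-like subset).
Normal walking at 1.1 m/s with symmetric steps and 0.1 m step width serves
as the reference condition for all structure and recruitment comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

SPEEDS: tuple[float, ...] = (0.8, 1.1, 1.45)
ASYMMETRIES: tuple[float, ...] = (0.0, 0.15, 0.30)
STEP_WIDTHS: tuple[float, ...] = (0.1, 0.2, 0.3)
LEGS: tuple[str, ...] = ("left", "right")
MUSCLE_SETS: tuple[str, ...] = ("full_43", "subset_8")

#: Number of grid points on the normalized gait cycle (heel strike to
#: ipsilateral heel strike), endpoint included.
N_GRID_POINTS: int = 101


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the condition grid for one leg and muscle set.

    Parameters
    ----------
    speed : float
        Average walking speed in m/s; one of 0.8, 1.1, 1.45.
    asymmetry : float
        Step length asymmetry (RSL - LSL)/(RSL + LSL); one of 0.0, 0.15, 0.30.
        Positive values mean larger right steps.
    step_width : float
        Minimum mediolateral foot separation in m; one of 0.1, 0.2, 0.3.
    leg : str
        "left" or "right".
    muscle_set : str
        "full_43" or "subset_8".
    """

    speed: float
    asymmetry: float
    step_width: float
    leg: str = "right"
    muscle_set: str = "subset_8"

    def __post_init__(self) -> None:
        if self.speed not in SPEEDS:
            raise ValueError(f"speed must be one of {SPEEDS}, got {self.speed}")
        if self.asymmetry not in ASYMMETRIES:
            raise ValueError(
                f"asymmetry must be one of {ASYMMETRIES}, got {self.asymmetry}"
            )
        if self.step_width not in STEP_WIDTHS:
            raise ValueError(
                f"step_width must be one of {STEP_WIDTHS}, got {self.step_width}"
            )
        if self.leg not in LEGS:
            raise ValueError(f"leg must be one of {LEGS}, got {self.leg!r}")
        if self.muscle_set not in MUSCLE_SETS:
            raise ValueError(
                f"muscle_set must be one of {MUSCLE_SETS}, got {self.muscle_set!r}"
            )

    @property
    def is_reference(self) -> bool:
        """True for the reference gait (1.1 m/s, symmetric, 0.1 m width)."""
        return (self.speed, self.asymmetry, self.step_width) == (1.1, 0.0, 0.1)

    @property
    def grid_index(self) -> int:
        """Stable 0..26 index of this cell in the condition grid."""
        return (
            SPEEDS.index(self.speed) * 9
            + ASYMMETRIES.index(self.asymmetry) * 3
            + STEP_WIDTHS.index(self.step_width)
        )

    def label(self) -> str:
        """Compact condition label, e.g. ``speed1.1_asym0.00_width0.1_right``."""
        return (
            f"speed{self.speed:g}_asym{self.asymmetry:.2f}"
            f"_width{self.step_width:g}_{self.leg}"
        )

    def with_leg(self, leg: str) -> "ConditionSpec":
        return ConditionSpec(
            self.speed, self.asymmetry, self.step_width, leg, self.muscle_set
        )


def reference_condition(leg: str = "right", muscle_set: str = "subset_8") -> ConditionSpec:
    """The reference gait condition for a given leg and muscle set."""
    return ConditionSpec(1.1, 0.0, 0.1, leg, muscle_set)


def condition_grid(
    leg: str = "right", muscle_set: str = "subset_8"
) -> Iterator[ConditionSpec]:
    """Iterate the 27 conditions (speed-major order) for one leg."""
    for speed, asym, width in itertools.product(SPEEDS, ASYMMETRIES, STEP_WIDTHS):
        yield ConditionSpec(speed, asym, width, leg, muscle_set)


def step_length_asymmetry(rsl: float, lsl: float) -> float:
    """Step length asymmetry (RSL - LSL) / (RSL + LSL).

    Positive values correspond to larger right step lengths. Both step
    lengths must be strictly positive (in meters).
    """
    if rsl <= 0 or lsl <= 0:
        raise ValueError(
            f"step lengths must be positive, got rsl={rsl}, lsl={lsl}"
        )
    return (rsl - lsl) / (rsl + lsl)
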