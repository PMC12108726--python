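"""The eight motion directions and their grid offsets.

Direction index ``d`` runs 0..7. Index 0 is rightward (0 degrees) and each
increment rotates counterclockwise by 45 degrees. Image coordinates follow the
usual raster convention (rows increase downward), so "upward" motion means the
row index decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

N_DIRECTIONS = 8

#: (row offset, col offset) for each direction index, raster coordinates.
DIRECTION_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),    # 0:   0 deg, rightward
    (-1, 1),   # 1:  45 deg, upper-right
    (-1, 0),   # 2:  90 deg, upward
    (-1, -1),  # 3: 135 deg, upper-left
    (0, -1),   # 4: 180 deg, leftward
    (1, -1),   # 5: 225 deg, lower-left
    (1, 0),    # 6: 270 deg, downward
    (1, 1),    # 7: 315 deg, lower-right
)

DIRECTION_NAMES = (
    "rightward", "upper-right", "upward", "upper-left",
    "leftward", "lower-left", "downward", "lower-right",
)


@dataclass(frozen=True)
class DirectionOffset:
    """One motion direction: its index, angle and raster offset."""

    d: int

    def __post_init__(self) -> None:
        if not 0 <= self.d < N_DIRECTIONS:
            raise ValueError(f"direction index must be in 0..7, got {self.d}")

    @property
    def angle(self) -> float:
        return 45.0 * self.d

    @property
    def alpha(self) -> int:
        """Row offset."""
        return DIRECTION_OFFSETS[self.d][0]

    @property
    def beta(self) -> int:
        """Column offset."""
        return DIRECTION_OFFSETS[self.d][1]

    @property
    def offset(self) -> tuple[int, int]:
        return DIRECTION_OFFSETS[self.d]

    @property
    def name(self) -> str:
        return DIRECTION_NAMES[self.d]


def direction_angle(d: int) -> float:
    """Angle in degrees for direction index ``d`` (counterclockwise from rightward)."""
    return DirectionOffset(d).angle
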