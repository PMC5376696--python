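"""Membrane layout model.

A filter macroarray is organised as a rectangular grid of blocks. Each block
is a 3x3 lattice of spots: the central position holds a non-protein ink guide
dot used to orient the grid, and the 8 peripheral positions hold protein
spots. Every clone is deposited twice within its block (duplex spotting), so
each block carries 4 distinct clones.

Coordinate conventions: pixel coordinates are 0-based ``(row, col)`` with the
origin at the top-left; block indices are 1-based. Within-block positions are
numbered 0-8, 0 being the central guide dot and 1-8 the peripheral positions
in row-major order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .errors import InvalidDesignError

#: Within-block position -> (row, col) offset on the 3x3 lattice, in units of
#: the spot pitch. Position 0 is the central ink guide dot.
POSITION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 0),
    1: (-1, -1), 2: (-1, 0), 3: (-1, 1),
    4: (0, -1),              5: (0, 1),
    6: (1, -1),  7: (1, 0),  8: (1, 1),
}

PERIPHERAL_POSITIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)

#: Default duplicate pairing: position p pairs with 9-p, i.e. the two
#: replicates of a clone sit point-symmetric about the central guide dot —
#: the classical filter-array convention.
DEFAULT_DUPLICATE_MAP: dict[int, tuple[int, int]] = {
    1: (1, 8), 2: (2, 7), 3: (3, 6), 4: (4, 5),
}

CLONE_SLOTS: tuple[int, ...] = (1, 2, 3, 4)


@dataclass(frozen=True)
class ArrayDesign:
    """Geometric and logical layout of a spotted membrane.

    Parameters
    ----------
    n_block_rows, n_block_cols
        Number of 3x3 blocks along each axis.
    block_pitch
        Center-to-center distance between adjacent blocks, pixels (both axes).
    spot_pitch
        Within-block spot spacing, pixels.
    spot_radius
        Radius of a protein spot, pixels.
    guide_dot_radius
        Radius of the central ink dot, pixels.
    margin
        Distance from the image edge to the first block center, pixels.
    duplicate_map
        Clone slot (1-4) -> pair of within-block peripheral positions at
        which that clone is deposited. The four pairs must partition
        positions 1-8.
    clone_table
        ``(block_row, block_col, slot) -> clone identifier``.
    """

    n_block_rows: int
    n_block_cols: int
    block_pitch: float = 36.0
    spot_pitch: float = 12.0
    spot_radius: float = 4.0
    guide_dot_radius: float = 6.0
    margin: float = 24.0
    duplicate_map: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DUPLICATE_MAP)
    )
    clone_table: Mapping[tuple[int, int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_block_rows < 1 or self.n_block_cols < 1:
            raise InvalidDesignError("block counts must be >= 1")
        for name in ("block_pitch", "spot_pitch", "spot_radius",
                     "guide_dot_radius", "margin"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"{name} must be strictly positive")
        if self.spot_radius >= self.spot_pitch / 2:
            raise InvalidDesignError(
                "spot_radius must be < spot_pitch/2 (spots must not overlap)")
        if set(self.duplicate_map) != set(CLONE_SLOTS):
            raise InvalidDesignError("duplicate_map must have slots 1..4")
        flat = [p for pair in self.duplicate_map.values() for p in pair]
        if sorted(flat) != list(PERIPHERAL_POSITIONS):
            raise InvalidDesignError(
                "duplicate pairs must partition peripheral positions 1..8")
        if self.clone_table:
            ids = list(self.clone_table.values())
            if len(set(ids)) != len(ids):
                raise InvalidDesignError("clone identifiers must be distinct")
            for (br, bc, slot) in self.clone_table:
                if not (1 <= br <= self.n_block_rows
                        and 1 <= bc <= self.n_block_cols
                        and slot in CLONE_SLOTS):
                    raise InvalidDesignError(
                        f"clone_table key {(br, bc, slot)} outside design")

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return self.n_block_rows * self.n_block_cols

    def blocks(self) -> Iterator[tuple[int, int]]:
        """Iterate 1-based (block_row, block_col) in row-major order."""
        return itertools.product(range(1, self.n_block_rows + 1),
                                 range(1, self.n_block_cols + 1))

    def block_center(self, block_row: int, block_col: int) -> np.ndarray:
        """Nominal pixel coordinates (row, col) of a block's guide dot."""
        return np.array([
            self.margin + (block_row - 1) * self.block_pitch,
            self.margin + (block_col - 1) * self.block_pitch,
        ])

    def spot_center(self, block_row: int, block_col: int,
                    position: int) -> np.ndarray:
        dr, dc = POSITION_OFFSETS[position]
        return self.block_center(block_row, block_col) + np.array(
            [dr * self.spot_pitch, dc * self.spot_pitch])

    def nominal_shape(self, padding: float = 0.0) -> tuple[int, int]:
        """Smallest (rows, cols) image shape containing the nominal grid."""
        h = 2 * self.margin + (self.n_block_rows - 1) * self.block_pitch
        w = 2 * self.margin + (self.n_block_cols - 1) * self.block_pitch
        return (int(np.ceil(h + 2 * padding)), int(np.ceil(w + 2 * padding)))

    # ------------------------------------------------------------------
    # logical layout
    # ------------------------------------------------------------------
    def clone_ids(self) -> list[str]:
        return sorted(self.clone_table.values())

    def n_clones(self) -> int:
        return len(self.clone_table)

    def clone_spots(self) -> dict[str, tuple[tuple[int, int, int], ...]]:
        """clone id -> its replicate spot addresses (block_row, block_col, pos),
        ordered by ascending within-block position."""
        out: dict[str, tuple[tuple[int, int, int], ...]] = {}
        for (br, bc, slot), clone in self.clone_table.items():
            pair = sorted(self.duplicate_map[slot])
            out[clone] = tuple((br, bc, p) for p in pair)
        return out

    def slot_of_position(self, position: int) -> int:
        """Clone slot whose duplicate pair contains a peripheral position."""
        for slot, pair in self.duplicate_map.items():
            if position in pair:
                return slot
        raise KeyError(position)

    def clone_at(self, block_row: int, block_col: int,
                 position: int) -> str | None:
        """Clone deposited at a peripheral spot position, if any."""
        if position == 0:
            return None
        slot = self.slot_of_position(position)
        return self.clone_table.get((block_row, block_col, slot))

    def with_clone_ids(self, renames: Mapping[tuple[int, int, int], str]
                       ) -> "ArrayDesign":
        """Return a copy with selected (block_row, block_col, slot) entries
        renamed; used to pin well-known clone ids in fixtures."""
        table = dict(self.clone_table)
        table.update(renames)
        return replace(self, clone_table=table)


def make_design(n_block_rows: int, n_block_cols: int, *,
                block_pitch: float = 36.0, spot_pitch: float = 12.0,
                spot_radius: float = 4.0, guide_dot_radius: float = 6.0,
                margin: float = 24.0,
                duplicate_map: Mapping[int, tuple[int, int]] | None = None,
                clone_prefix: str = "clone") -> ArrayDesign:
    """Build a fully populated design with auto-generated clone ids.

    Every block receives 4 distinct clones, each spotted in duplicate at the
    positions of its slot's duplicate pair. Clone ids are
    ``{prefix}-{block_row:03d}{block_col:03d}-{slot}``.
    """
    clone_table = {
        (br, bc, slot): f"{clone_prefix}-{br:03d}{bc:03d}-{slot}"
        for br in range(1, n_block_rows + 1)
        for bc in range(1, n_block_cols + 1)
        for slot in CLONE_SLOTS
    }
    return ArrayDesign(
        n_block_rows=n_block_rows, n_block_cols=n_block_cols,
        block_pitch=block_pitch, spot_pitch=spot_pitch,
        spot_radius=spot_radius, guide_dot_radius=guide_dot_radius,
        margin=margin,
        duplicate_map=dict(duplicate_map or DEFAULT_DUPLICATE_MAP),
        clone_table=clone_table,
    )


def default_design(clone_prefix: str = "clone") -> ArrayDesign:
    """Full-size membrane: 50 x 40 blocks = 8000 distinct clones in duplicate,
    the scale of a commercial high-density expression filter."""
    return make_design(50, 40, clone_prefix=clone_prefix)
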