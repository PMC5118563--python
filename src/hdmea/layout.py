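"""Electrode-array geometry and overlapping high-density block tiling.

A planar CMOS microelectrode array is modelled as a regular rectangular grid
of electrodes (default pitch 18 μm) of which at most ``max_simultaneous``
(default 126 readout channels) can be recorded at the same time.  The area a
tissue preparation occupies is scanned with a sequence of dense rectangular
"block" configurations (default 6 columns x 18 rows = 108 electrodes) that
overlap by a fixed electrode fraction (default 25%), so that units sitting on
a block boundary are seen by two configurations and can later be merged.

Coordinates are in μm, 0-based, with the origin at the top-left electrode,
x increasing rightward and y increasing downward (image convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "RegionOfInterest",
    "BlockConfiguration",
    "build_layout",
    "tile_blocks",
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Regular rectangular electrode grid.

    Electrode ids are row-major and 0-based: electrode ``i`` sits at row
    ``i // n_cols``, column ``i % n_cols``, i.e. at position
    ``(col * pitch, row * pitch)`` μm.
    """

    n_rows: int
    n_cols: int
    pitch: float = 18.0
    max_simultaneous: int = 126

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def array_extent(self) -> tuple[float, float]:
        """(width, height) in μm spanned by electrode centers."""
        return ((self.n_cols - 1) * self.pitch, (self.n_rows - 1) * self.pitch)

    def rowcol(self, electrode_id: int | np.ndarray):
        return np.asarray(electrode_id) // self.n_cols, np.asarray(electrode_id) % self.n_cols

    def position(self, electrode_id: int | np.ndarray) -> np.ndarray:
        """(x, y) position(s) in μm; shape (..., 2)."""
        row, col = self.rowcol(electrode_id)
        return np.stack([col * self.pitch, row * self.pitch], axis=-1).astype(float)

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n_electrodes) % self.n_cols) * self.pitch

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.n_electrodes) // self.n_cols) * self.pitch

    def electrode_at(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"(row, col)=({row}, {col}) outside the {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch": self.pitch,
            "max_simultaneous": self.max_simultaneous,
        }


def build_layout(
    n_rows: int, n_cols: int, pitch: float = 18.0, max_simultaneous: int = 126
) -> ElectrodeLayout:
    """Construct a regular rectangular electrode layout.

    Raises
    ------
    ValueError
        for non-positive dimensions or pitch.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if max_simultaneous < 1:
        raise ValueError("max_simultaneous must be >= 1")
    return ElectrodeLayout(n_rows=n_rows, n_cols=n_cols, pitch=pitch, max_simultaneous=max_simultaneous)


@dataclass(frozen=True)
class RegionOfInterest:
    """Subset of layout electrodes covered by the tissue.

    Stored as a frozenset of electrode ids; constructors accept explicit ids,
    rectangles in grid indices, or a polygon in μm coordinates.
    """

    electrode_ids: frozenset[int]

    def __post_init__(self):
        if not self.electrode_ids:
            raise ValueError("region is empty")

    @classmethod
    def from_ids(cls, layout: ElectrodeLayout, ids: Iterable[int]) -> "RegionOfInterest":
        ids = frozenset(int(i) for i in ids)
        bad = [i for i in ids if not (0 <= i < layout.n_electrodes)]
        if bad:
            raise ValueError(f"electrode ids outside layout: {sorted(bad)[:5]}")
        return cls(ids)

    @classmethod
    def full(cls, layout: ElectrodeLayout) -> "RegionOfInterest":
        return cls(frozenset(range(layout.n_electrodes)))

    @classmethod
    def from_rect(
        cls, layout: ElectrodeLayout, row0: int, col0: int, n_rows: int, n_cols: int
    ) -> "RegionOfInterest":
        ids = [
            layout.electrode_at(r, c)
            for r in range(row0, row0 + n_rows)
            for c in range(col0, col0 + n_cols)
        ]
        return cls.from_ids(layout, ids)

    @classmethod
    def from_polygon(cls, layout: ElectrodeLayout, vertices_um: Sequence[tuple[float, float]]) -> "RegionOfInterest":
        """Electrodes whose centers fall inside a boundary polygon (μm)."""
        from matplotlib.path import Path

        pts = np.stack([layout.x, layout.y], axis=1)
        inside = Path(np.asarray(vertices_um, dtype=float)).contains_points(pts, radius=1e-9)
        if not inside.any():
            raise ValueError("polygon contains no electrodes")
        return cls(frozenset(np.flatnonzero(inside).tolist()))

    def __len__(self) -> int:
        return len(self.electrode_ids)

    def __contains__(self, electrode_id: int) -> bool:
        return electrode_id in self.electrode_ids


@dataclass(frozen=True)
class BlockConfiguration:
    """One simultaneously recorded electrode set (the unit of acquisition).

    ``carried_ids`` is the subset shared with the previous block in scan
    order (empty for the first block).
    """

    block_index: int
    electrode_ids: tuple[int, ...]
    carried_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValueError("duplicate electrode ids in block")
        if not set(self.carried_ids) <= set(self.electrode_ids):
            raise ValueError("carried_ids must be a subset of electrode_ids")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    @property
    def overlap_fraction(self) -> float:
        return len(self.carried_ids) / len(self.electrode_ids)

    def to_dict(self) -> dict:
        return {
            "block_index": self.block_index,
            "electrode_ids": list(self.electrode_ids),
            "carried_ids": list(self.carried_ids),
        }


def _scan_order(layout: ElectrodeLayout, ids: Sequence[int], block_rows: int) -> list[int]:
    # Column-band-major scan: electrodes grouped into horizontal bands of
    # block_rows rows (measured from the region's top row), bands top to
    # bottom, columns left to right within a band, rows top to bottom within
    # a column.  This realizes the acquisition order "smaller value on y
    # axis, larger value on x axis".
    rows, cols = layout.rowcol(np.asarray(ids))
    r0 = int(rows.min())
    keys = ((rows - r0) // block_rows, cols, rows)
    order = np.lexsort((keys[2], keys[1], keys[0]))
    return [int(np.asarray(ids)[i]) for i in order]


def tile_blocks(
    layout: ElectrodeLayout,
    region: RegionOfInterest,
    block_rows: int = 18,
    block_cols: int = 6,
    overlap_fraction: float = 0.25,
) -> list[BlockConfiguration]:
    """Tile a region with overlapping block configurations.

    The first block is the ``block_cols`` x ``block_rows`` electrode group at
    the region's upper-left corner.  Each subsequent block consists of the
    next ``ceil((1 - overlap_fraction) * B)`` not-yet-covered region
    electrodes in scan order plus the ``floor(overlap_fraction * B)``
    electrodes of the previous block closest (Euclidean, ties by ascending
    electrode id) to the centroid of those new electrodes, where
    ``B = block_rows * block_cols``.  For the default 6x18 block at 25%
    overlap an interior block therefore holds 27 carried + 81 new = 108
    electrodes and consecutive blocks share exactly 25% of their electrodes.
    """
    B = block_rows * block_cols
    if B > layout.max_simultaneous:
        raise ValueError(
            f"block of {B} electrodes exceeds the {layout.max_simultaneous} readout channels"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")

    scan = _scan_order(layout, sorted(region.electrode_ids), block_rows)
    if len(scan) < B:
        warnings.warn(
            f"region of {len(scan)} electrodes is smaller than one {block_rows}x{block_cols} "
            "block; emitting a single truncated block",
            stacklevel=2,
        )
        return [BlockConfiguration(0, tuple(scan))]

    n_new = math.ceil((1 - overlap_fraction) * B)
    n_carry = math.floor(overlap_fraction * B)

    covered: set[int] = set()
    blocks: list[BlockConfiguration] = []
    pos = {i: layout.position(i) for i in scan}
    remaining = [e for e in scan]

    while True:
        uncovered = [e for e in remaining if e not in covered]
        if not uncovered:
            break
        if not blocks:
            new = uncovered[:B]
            carried: list[int] = []
        else:
            new = uncovered[:n_new]
            centroid = np.mean([pos[e] for e in new], axis=0)
            prev = blocks[-1].electrode_ids
            d = [(float(np.hypot(*(pos[e] - centroid))), e) for e in prev]
            d.sort()
            carried = [e for _, e in d[: min(n_carry, len(prev))]]
        blocks.append(
            BlockConfiguration(len(blocks), tuple(carried) + tuple(new), tuple(carried))
        )
        covered.update(new)
        covered.update(carried)

    return blocks
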