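"""Reference resolution ranges and powder-ring positions for crystalline ice.

Polycrystalline hexagonal (Ih) or cubic (Ic) ice in or around a
cryocooled sample produces Debye-Scherrer rings at characteristic
d-spacings. Detection is restricted to a curated table of 25 resolution
ranges where such rings are expected; the table is treated as opaque
constants. Helper functions also compute theoretical ring positions for
ideal cubic (face-centred) and hexagonal ice lattices so a user can
eyeball whether observed rings sit where ice rings belong.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DRange",
    "IceRangeTable",
    "curated_ranges",
    "load_ranges",
    "powder_ring_positions",
    "in_ice_range",
    "CUBIC_ICE_A",
    "HEX_ICE_A",
    "HEX_ICE_C",
]

# standard literature lattice constants for ambient-pressure ice
CUBIC_ICE_A = 6.358  # Angstrom
HEX_ICE_A = 4.497
HEX_ICE_C = 7.322


@dataclass(frozen=True)
class DRange:
    """A resolution range in Angstrom, stated high-to-low resolution
    (d_start > d_end); membership is closed at both ends."""

    d_start: float
    d_end: float

    def __post_init__(self) -> None:
        if not self.d_start > self.d_end > 0:
            raise ValueError("require d_start > d_end > 0")

    def contains(self, d: float | np.ndarray) -> bool | np.ndarray:
        return (np.asarray(d) >= self.d_end) & (np.asarray(d) <= self.d_start)


@dataclass(frozen=True)
class IceRangeTable:
    """Ordered, non-overlapping resolution ranges searched for ice rings."""

    ranges: tuple[DRange, ...]
    source: str = "curated"

    def __post_init__(self) -> None:
        starts = [r.d_start for r in self.ranges]
        ends = [r.d_end for r in self.ranges]
        if any(e <= s for e, s in zip(ends[:-1], starts[1:])):
            raise ValueError("ranges must be strictly decreasing in d and non-overlapping")

    def __len__(self) -> int:
        return len(self.ranges)

    def __iter__(self):
        return iter(self.ranges)


def curated_ranges() -> IceRangeTable:
    """The 25 curated ice-ring resolution ranges bundled with the package."""
    with resources.files("icediag.data").joinpath("ice_ranges.csv").open("r") as fh:
        df = pd.read_csv(fh)
    ranges = tuple(DRange(row.d_start, row.d_end) for row in df.itertuples())
    return IceRangeTable(ranges=ranges, source="curated")


def load_ranges(path: str | Path) -> IceRangeTable:
    """Load a user-supplied replacement table (CSV with d_start,d_end)."""
    df = pd.read_csv(path)
    ranges = tuple(DRange(float(r.d_start), float(r.d_end)) for r in df.itertuples())
    return IceRangeTable(ranges=ranges, source="user")


def in_ice_range(table: IceRangeTable, d) -> bool | np.ndarray:
    """True where d (Angstrom) lies inside some range (closed intervals)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d must be positive")
    hit = np.zeros(d.shape, dtype=bool)
    for r in table:
        hit |= r.contains(d)
    if hit.ndim == 0:
        return bool(hit)
    return hit


def powder_ring_positions(
    lattice: str,
    a: float,
    c: float | None = None,
    d_min: float = 1.0,
    max_index: int = 12,
) -> np.ndarray:
    """Unique allowed powder-ring d-spacings >= d_min, descending.

    ``lattice='cubic'`` treats the diamond-type oxygen lattice of cubic
    ice: reflections with h,k,l all odd, or all even with h+k+l = 4n
    (the face-centring plus diamond-glide extinctions, which is why only
    three rings — 111, 220, 311 — appear above 1.9 A), with
    1/d^2 = (h^2+k^2+l^2)/a^2. ``'hexagonal'`` uses
    1/d^2 = 4(h^2+hk+k^2)/(3a^2) + l^2/c^2 and requires ``c``.
    """
    if a <= 0 or d_min <= 0:
        raise ValueError("a and d_min must be positive")
    if lattice == "cubic":
        inv_d2 = []
        for h, k, l in itertools.product(range(-max_index, max_index + 1), repeat=3):
            if (h, k, l) == (0, 0, 0):
                continue
            parities = {h % 2, k % 2, l % 2}
            if len(parities) != 1:  # mixed parity: extinct for face-centring
                continue
            if h % 2 == 0 and (h + k + l) % 4 != 0:  # diamond-glide extinction
                continue
            inv_d2.append((h * h + k * k + l * l) / (a * a))
    elif lattice == "hexagonal":
        if c is None or c <= 0:
            raise ValueError("hexagonal lattice requires a positive c")
        inv_d2 = []
        for h, k, l in itertools.product(range(-max_index, max_index + 1), repeat=3):
            if (h, k, l) == (0, 0, 0):
                continue
            inv_d2.append(4.0 * (h * h + h * k + k * k) / (3.0 * a * a) + l * l / (c * c))
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    d = 1.0 / np.sqrt(np.asarray(inv_d2))
    d = d[d >= d_min]
    d = np.sort(d)[::-1]
    # de-duplicate rings that coincide within 1e-6 A
    keep = np.concatenate([[True], np.diff(d) < -1e-6])
    return d[keep]
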