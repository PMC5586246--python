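"""Fixed-width inverse-resolution binning and per-bin intensity statistics.

Reflections are partitioned into equally spaced bins in 1/d (default
width 0.001 1/Angstrom) and each bin is summarized by its count N, sample
mean <I>, sample standard deviation s and standardized mean m = <I>/s.
The standardized mean is scale-free: rescaling every intensity by a
positive constant leaves it unchanged, which is what lets a single score
threshold work across arbitrarily scaled datasets. Negative intensities
are deliberately retained — they carry the ice-ring signature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reflection_io import ReflectionSet

__all__ = ["BinSeries", "assign_bins", "bin_statistics"]

DEFAULT_BIN_WIDTH = 0.001  # 1/Angstrom, the method's default binning fineness
DEFAULT_N_MIN = 3  # a sample SD needs >=2 points; 3 avoids two-point bins


@dataclass
class BinSeries:
    """Per-bin statistics on a fixed 1/d grid.

    ``table`` columns: index (bin number k, interval [k*w, (k+1)*w) in 1/d),
    center (1/d at bin midpoint), N, meanI, sd, stdmean, valid.
    Bins with no observations are absent. ``stdmean`` is NaN where invalid.
    """

    width: float
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centers(self) -> np.ndarray:
        return self.table["center"].values

    @property
    def d_centers(self) -> np.ndarray:
        """Bin centers expressed as d-spacing (Angstrom)."""
        return 1.0 / self.table["center"].values

    def valid(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]

    def to_csv(self, path) -> None:
        t = self.table
        out = pd.DataFrame(
            {
                "index": t["index"],
                "d_min": 1.0 / ((t["index"] + 1) * self.width),
                "d_max": 1.0 / np.maximum(t["index"] * self.width, 1e-300),
                "N": t["N"],
                "meanI": t["meanI"],
                "sd": t["sd"],
                "stdmean": t["stdmean"],
            }
        )
        out.to_csv(path, index=False)


def assign_bins(d_values, width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Bin index k = floor((1/d)/width) for each d; intervals are
    half-open, [k*width, (k+1)*width) in inverse resolution."""
    d = np.asarray(d_values, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d-spacings must be positive")
    if width <= 0:
        raise ValueError("bin width must be positive")
    return np.floor((1.0 / d) / width).astype(np.int64)


def bin_statistics(
    rs: ReflectionSet,
    width: float = DEFAULT_BIN_WIDTH,
    n_min: int = DEFAULT_N_MIN,
) -> BinSeries:
    """Compute N, <I>, sample SD and standardized mean per 1/d bin.

    Intensities are used when present; otherwise amplitudes stand in and
    the downstream score pipeline is unchanged. The sample SD uses the
    N-1 denominator. A bin is valid when N >= n_min and sd > 0.
    """
    if len(rs) == 0:
        raise ValueError("empty reflection set")
    if rs.has_intensities:
        values = rs.data["I"].values
    elif rs.has_amplitudes:
        values = rs.data["F"].values
    else:
        raise ValueError("reflection set has neither intensities nor amplitudes")
    mask = np.isfinite(values)
    d = rs.d_spacings()[mask]
    values = values[mask]
    idx = assign_bins(d, width)
    g = pd.DataFrame({"bin": idx, "v": values}).groupby("bin")["v"]
    table = pd.DataFrame(
        {
            "index": g.size().index.values,
            "N": g.size().values,
            "meanI": g.mean().values,
            "sd": g.std(ddof=1).values,  # NaN for N=1
        }
    )
    table["center"] = (table["index"] + 0.5) * width
    table["sd"] = table["sd"].fillna(0.0)
    table["valid"] = (table["N"] >= n_min) & (table["sd"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["stdmean"] = np.where(table["valid"], table["meanI"] / table["sd"], np.nan)
    table = table[["index", "center", "N", "meanI", "sd", "stdmean", "valid"]]
    return BinSeries(width=width, table=table.reset_index(drop=True))
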