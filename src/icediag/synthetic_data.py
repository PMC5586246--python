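"""Synthetic reflection datasets with the statistical structure the
detector assumes.

The generator enumerates the unique reflections of a cell to a
resolution limit, draws true intensities from Wilson statistics with a
B-factor falloff — exponential with mean Sigma(d) for acentrics,
Sigma(d) * chi-squared(1) for centrics, where
Sigma(d) = K * exp(-B / (2 d^2)) — adds Gaussian measurement noise with
a two-term sigma model, and applies a resolution-stepped multiplicity
law whose repeats are merged with the unweighted-mean algebra (merged
sigma = sigma/sqrt(N) for equal per-repeat sigmas, the mechanism behind
the low-resolution I/sigI "ladder").

Ice contamination emulates what poor background estimation does to
integrated intensities near a powder ring: intensities in the core of a
resolution range are inflated by a raised-cosine bump and the two flanks
are deflated by matching negative lobes (producing the characteristic
large negative intensities), all scaled by the local Wilson mean so the
perturbation is scale-free. Sigmas are untouched — the bias sits in the
background model, not in the counting noise. The exact lobe shape is a
stand-in; real profiles vary with the integration software.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ice_reference import DRange
from .reflection_io import (
    ReflectionSet,
    UnitCell,
    _canonical_hkl,
    centric_flags,
    compute_d_spacing,
)

__all__ = [
    "SyntheticSpec",
    "generate_clean",
    "inject_ice",
    "multiplicity_steps",
    "P212121_SYMOPS",
    "DEFAULT_MULT_STEPS",
]

P212121_SYMOPS = [
    "x,y,z",
    "-x+1/2,-y,z+1/2",
    "-x,y+1/2,-z+1/2",
    "x+1/2,-y+1/2,-z",
]

# multiplicity steps as (d threshold, multiplicity), highest resolution last
DEFAULT_MULT_STEPS = ((6.0, 8), (4.0, 4), (2.5, 2), (0.0, 1))


def multiplicity_steps(steps: Sequence[tuple[float, int]] = DEFAULT_MULT_STEPS) -> Callable:
    """Step multiplicity law: the first (threshold, mult) with d > threshold wins."""
    steps = sorted(steps, key=lambda t: -t[0])

    def law(d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.ones(d.shape, dtype=int)
        remaining = np.ones(d.shape, dtype=bool)
        for thr, m in steps:  # coarsest threshold first
            hit = remaining & (d >= thr)
            out[hit] = m
            remaining &= ~hit
        return out

    return law


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    wilson_K: overall intensity scale (arbitrary units); wilson_B:
    temperature factor in A^2 damping Sigma(d) = K exp(-B/(2 d^2)).
    noise_a, noise_b: per-reflection sigma model
    sigma = noise_a * Sigma(d) + noise_b * sqrt(max(J, 0)).
    contamination: (range, amplitude, flank_fraction) triples applied
    after clean generation. A fixed seed makes output bit-reproducible.
    """

    cell: UnitCell = UnitCell(40.0, 50.0, 60.0, 90.0, 90.0, 90.0)
    symops: tuple[str, ...] = tuple(P212121_SYMOPS)
    d_min: float = 1.6
    wilson_K: float = 100.0
    wilson_B: float = 20.0
    noise_a: float = 0.05
    noise_b: float = 0.3
    mult_law: Callable | None = None
    contamination: tuple[tuple[DRange, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_min <= 0 or self.wilson_K <= 0 or self.wilson_B < 0:
            raise ValueError("require d_min > 0, wilson_K > 0, wilson_B >= 0")

    def sigma_of_d(self, d) -> np.ndarray:
        """The Wilson falloff Sigma(d) = K exp(-B/(2 d^2))."""
        d = np.asarray(d, dtype=float)
        return self.wilson_K * np.exp(-self.wilson_B / (2.0 * d * d))


def _unique_reflections(spec: SyntheticSpec) -> np.ndarray:
    """All unique (canonical, Friedel-merged) hkl with d >= d_min."""
    cell = spec.cell
    # |h| <= a/d_min is exact for any cell: h = s . a for reciprocal vector s
    hmax = int(np.floor(cell.a / spec.d_min))
    kmax = int(np.floor(cell.b / spec.d_min))
    lmax = int(np.floor(cell.c / spec.d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[~np.all(hkl == 0, axis=1)]
    d = np.asarray(compute_d_spacing(cell, hkl[:, 0], hkl[:, 1], hkl[:, 2]))
    hkl = hkl[d >= spec.d_min]
    ch, ck, cl = _canonical_hkl(spec.symops, hkl[:, 0], hkl[:, 1], hkl[:, 2])
    canon = np.stack([ch, ck, cl], axis=1)
    uniq = np.unique(canon, axis=0)
    if len(uniq) == 0:
        raise ValueError("d_min too large for this cell: no reflections")
    return uniq


def generate_clean(spec: SyntheticSpec) -> ReflectionSet:
    """Generate a merged ReflectionSet of Wilson-distributed intensities."""
    rng = np.random.default_rng(spec.seed)
    hkl = _unique_reflections(spec)
    d = np.asarray(compute_d_spacing(spec.cell, hkl[:, 0], hkl[:, 1], hkl[:, 2]))
    sigma_d = spec.sigma_of_d(d)
    centric = centric_flags(spec.symops, hkl[:, 0], hkl[:, 1], hkl[:, 2])
    n = len(hkl)
    j_acent = rng.exponential(scale=sigma_d)
    j_cent = sigma_d * rng.chisquare(1, size=n)
    J = np.where(centric, j_cent, j_acent)
    mult_law = spec.mult_law if spec.mult_law is not None else multiplicity_steps()
    mult = np.asarray(mult_law(d), dtype=int)
    if np.any(mult < 1):
        raise ValueError("multiplicity law must return integers >= 1")
    # per-repeat sigma; merging N equal-sigma repeats divides sigma by sqrt(N)
    sig_single = spec.noise_a * sigma_d + spec.noise_b * np.sqrt(np.maximum(J, 0.0))
    sig_merged = sig_single / np.sqrt(mult)
    noise = rng.normal(size=n) * sig_merged
    I = J + noise
    sig_floor = 1e-9 * spec.wilson_K
    data = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "I": I,
            "sigI": np.maximum(sig_merged, sig_floor),
            "mult": mult.astype(float),
        }
    )
    rs = ReflectionSet(cell=spec.cell, symops=list(spec.symops), data=data, merged=True)
    for rng_range, amplitude, flank_fraction in spec.contamination:
        rs = inject_ice(rs, rng_range, amplitude, flank_fraction, sigma_of_d=spec.sigma_of_d)
    return rs


def inject_ice(
    rs: ReflectionSet,
    drange: DRange,
    amplitude: float,
    flank_fraction: float = 0.3,
    flank_scale: float = 0.5,
    sigma_of_d: Callable | None = None,
) -> ReflectionSet:
    """Bias intensities in ``drange`` like a poorly modelled ice ring.

    The central (1 - flank_fraction) of the range (in 1/d) gains a
    raised-cosine bump of height ``amplitude`` times the local mean
    intensity; the two flanks lose matching cosine lobes scaled by
    ``flank_scale``. Sigmas are unchanged. ``sigma_of_d`` supplies the
    local mean-intensity scale; when None it is estimated from the data
    in and around the range.
    """
    if not np.isfinite(amplitude):
        raise ValueError("amplitude must be finite")
    if not 0.0 <= flank_fraction < 1.0:
        raise ValueError("flank_fraction must lie in [0, 1)")
    d = rs.d_spacings()
    x = 1.0 / d
    x_lo, x_hi = 1.0 / drange.d_start, 1.0 / drange.d_end
    inside = (x >= x_lo) & (x <= x_hi)
    if amplitude == 0.0 or not inside.any():
        return replace(rs, data=rs.data.copy())
    if sigma_of_d is None:
        width = x_hi - x_lo
        near = (x >= x_lo - width) & (x <= x_hi + width)
        local_mean = float(np.nanmean(rs.data["I"].values[near]))
        scale = np.full(d.shape, max(local_mean, 0.0))
    else:
        scale = np.asarray(sigma_of_d(d), dtype=float)
    u = 2.0 * (x - x_lo) / (x_hi - x_lo) - 1.0  # position in [-1, 1]
    core_half = 1.0 - flank_fraction
    delta = np.zeros_like(x)
    in_core = inside & (np.abs(u) <= core_half)
    delta[in_core] = amplitude * 0.5 * (1.0 + np.cos(np.pi * u[in_core] / core_half))
    if flank_fraction > 0:
        in_flank = inside & (np.abs(u) > core_half)
        t = (np.abs(u[in_flank]) - core_half) / flank_fraction
        delta[in_flank] = -amplitude * flank_scale * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    data = rs.data.copy()
    data["I"] = data["I"].values + delta * scale
    return replace(rs, data=data)
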