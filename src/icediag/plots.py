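"""Diagnostic scatter plots of per-reflection statistics versus resolution.

One panel per selected quantity (I, I/sigI, sigI and the amplitude
counterparts), every reflection a point, x axis in 1/d^2 with tick
labels in Angstrom. Candidate ice-ring resolution ranges are shaded
grey; ranges the detector flagged are shaded red. Intensity-type panels
clip the y axis to a robust quantile band so a handful of outliers does
not flatten the cloud the eye needs to see.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ice_reference import IceRangeTable, curated_ranges
from .icefinder import IcefinderResult
from .reflection_io import ReflectionSet

__all__ = ["PlotConfig", "render_diagnostics", "available_panels"]

_PANELS = ("I", "I_over_sigI", "sigI", "F", "F_over_sigF", "sigF")
_CLIPPED = {"I", "sigI", "F", "sigF"}  # robust y-limit panels


@dataclass
class PlotConfig:
    panels: tuple[str, ...] = ("I", "I_over_sigI", "sigI")
    color_by_multiplicity: bool = False
    out_dir: Path = Path(".")
    image_format: str = "png"
    y_clip: tuple[float, float] = (0.5, 99.5)  # percentiles

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("at least one panel must be selected")
        unknown = set(self.panels) - set(_PANELS)
        if unknown:
            raise ValueError(f"unknown panel(s): {sorted(unknown)}")
        self.out_dir = Path(self.out_dir)


def available_panels(rs: ReflectionSet) -> tuple[str, ...]:
    """Panels the data supports; both sets when both I and F exist."""
    panels: list[str] = []
    if rs.has_intensities:
        panels += ["I", "I_over_sigI", "sigI"]
    if rs.has_amplitudes:
        panels += ["F", "F_over_sigF", "sigF"]
    return tuple(panels)


def _panel_values(rs: ReflectionSet, panel: str) -> np.ndarray:
    df = rs.data
    if panel == "I":
        return df["I"].values
    if panel == "sigI":
        return df["sigI"].values
    if panel == "I_over_sigI":
        return df["I"].values / df["sigI"].values
    if panel == "F":
        return df["F"].values
    if panel == "sigF":
        return df["sigF"].values
    if panel == "F_over_sigF":
        return df["F"].values / df["sigF"].values
    raise ValueError(panel)


_LABELS = {
    "I": "I",
    "I_over_sigI": "I / σ(I)",
    "sigI": "σ(I)",
    "F": "F",
    "F_over_sigF": "F / σ(F)",
    "sigF": "σ(F)",
}


def render_diagnostics(
    rs: ReflectionSet,
    result: IcefinderResult | None = None,
    cfg: PlotConfig | None = None,
    table: IceRangeTable | None = None,
) -> list[Path]:
    """Render one figure per selected panel; returns the written paths.

    Output is deterministic for a given input and configuration (fixed
    figure metadata, no timestamps), so vector output is reproducible.
    """
    if cfg is None:
        cfg = PlotConfig(panels=available_panels(rs) or ("I",))
    if table is None:
        table = curated_ranges()
    plt.rcParams["svg.hashsalt"] = "icediag"  # reproducible SVG ids
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    d = rs.d_spacings()
    x = 1.0 / d**2
    flagged = result.flagged_ranges if result is not None else []
    paths: list[Path] = []
    for panel in cfg.panels:
        y = _panel_values(rs, panel)
        ok = np.isfinite(y)
        if not ok.any():
            continue
        fig, ax = plt.subplots(figsize=(9, 4.5))
        for r in table:
            ax.axvspan(1.0 / r.d_start**2, 1.0 / r.d_end**2, color="0.85", zorder=0)
        for r in flagged:
            ax.axvspan(1.0 / r.d_start**2, 1.0 / r.d_end**2, color="#ffb0b0", zorder=1)
        if cfg.color_by_multiplicity and rs.data["mult"].notna().any():
            sc = ax.scatter(x[ok], y[ok], s=2, c=rs.data["mult"].values[ok], cmap="viridis", zorder=2)
            fig.colorbar(sc, ax=ax, label="multiplicity")
        else:
            ax.scatter(x[ok], y[ok], s=2, color="#30527a", alpha=0.5, linewidths=0, zorder=2)
        if panel in _CLIPPED:
            lo, hi = np.percentile(y[ok], cfg.y_clip)
            pad = 0.05 * (hi - lo) if hi > lo else 1.0
            ax.set_ylim(lo - pad, hi + pad)
        # x ticks in 1/d^2, labelled in Angstrom
        ticks = ax.get_xticks()
        ticks = ticks[ticks > 0]
        ax.set_xticks(ticks)
        ax.set_xticklabels([f"{1.0 / np.sqrt(t):.2f}" for t in ticks])
        ax.set_xlim(0, x.max() * 1.02)
        ax.set_xlabel("resolution d (Å)")
        ax.set_ylabel(_LABELS[panel])
        out = cfg.out_dir / f"{panel}.{cfg.image_format}"
        fig.savefig(out, dpi=120, metadata=_deterministic_metadata(cfg.image_format))
        plt.close(fig)
        paths.append(out)
    return paths


def _deterministic_metadata(fmt: str) -> dict | None:
    if fmt == "svg":
        return {"Date": None}
    if fmt == "png":
        return {"Software": None}
    return None
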