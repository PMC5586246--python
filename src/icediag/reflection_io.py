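"""Reflection-data containers, I/O and symmetry-aware geometry.

The central container is :class:`ReflectionSet`: a table of observations
(Miller indices, intensities, uncertainties, optional amplitudes and
multiplicities) together with the unit cell and the symmetry operators
needed to place each reflection in reciprocal space, decide centricity
and merge symmetry equivalents.

Two on-disk representations are supported: the CCP4 MTZ binary format
(read and written through gemmi) and a plain-text CSV dialect whose
header comment lines carry the cell and the symmetry-operator triplets::

    #cell 40.0 50.0 60.0 90.0 90.0 90.0
    #symop x,y,z
    #symop -x,y+1/2,-z
    h,k,l,I,sigI
    1,0,0,12.5,1.1
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("icediag")

__all__ = [
    "UnitCell",
    "ReflectionSet",
    "FormatError",
    "GeometryError",
    "read_reflections",
    "write_reflections",
    "compute_d_spacing",
    "is_centric",
    "merge_equivalents",
    "parse_symops",
]


class FormatError(ValueError):
    """A reflection file violates the expected format."""


class GeometryError(ValueError):
    """Unit-cell or Miller-index geometry is unusable."""


# --------------------------------------------------------------------------
# unit cell and d-spacing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise GeometryError("cell angles must lie in (0, 180) degrees")
        # positive-definiteness of the metric is checked via its determinant
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise GeometryError("cell angles give a non-positive cell volume")

    def metric_tensor(self) -> np.ndarray:
        """Real-space metric tensor G (dot products of the basis vectors)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1; 1/d^2 = h^T G* h."""
        return np.linalg.inv(self.metric_tensor())

    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))


def compute_d_spacing(cell: UnitCell, h, k, l) -> np.ndarray | float:
    """Resolution d (Angstrom) of reflection(s) (h, k, l) under ``cell``.

    Uses the reciprocal metric tensor, 1/d^2 = h^T G* h, valid for any
    (including triclinic) cell. Accepts scalars or equal-length arrays.
    """
    h = np.asarray(h)
    k = np.asarray(k)
    l = np.asarray(l)
    if np.any((h == 0) & (k == 0) & (l == 0)):
        raise GeometryError("d-spacing undefined for (0,0,0)")
    gstar = cell.reciprocal_metric_tensor()
    hkl = np.stack([h, k, l], axis=-1).astype(float)
    inv_d2 = np.einsum("...i,ij,...j->...", hkl, gstar, hkl)
    d = 1.0 / np.sqrt(inv_d2)
    if d.ndim == 0:
        return float(d)
    return d


# --------------------------------------------------------------------------
# symmetry operators
# --------------------------------------------------------------------------

def parse_symops(triplets: Sequence[str]) -> list[gemmi.Op]:
    """Parse symmetry-operator triplet strings (e.g. ``-x,y+1/2,-z``)."""
    ops = []
    for t in triplets:
        try:
            ops.append(gemmi.Op(t))
        except (ValueError, RuntimeError) as exc:
            raise FormatError(f"unparseable symmetry operator {t!r}") from exc
    return ops


def _rotation_parts(symops: Sequence[str]) -> np.ndarray:
    """Integer rotation matrices R of the operators, shape (n_ops, 3, 3)."""
    ops = parse_symops(symops)
    den = gemmi.Op.DEN
    rots = np.array([op.rot for op in ops], dtype=float) / den
    if not np.allclose(rots, np.round(rots)):
        raise FormatError("non-integer rotation part in symmetry operator")
    return np.round(rots).astype(int)


def is_centric(symops: Sequence[str], h: int, k: int, l: int) -> bool:
    """True iff some operator's rotation R satisfies R^T (h,k,l) = -(h,k,l).

    Centric reflections are mapped onto their Friedel mates by the space
    group and follow a different intensity distribution from acentric ones.
    """
    rots = _rotation_parts(symops)
    hkl = np.array([h, k, l])
    mapped = np.einsum("nij,i->nj", rots, hkl)  # R^T h  (h^T R per operator)
    return bool(np.any(np.all(mapped == -hkl, axis=1)))


def centric_flags(symops: Sequence[str], h, k, l) -> np.ndarray:
    """Vectorized centricity test over arrays of Miller indices."""
    rots = _rotation_parts(symops)
    hkl = np.stack([np.asarray(h), np.asarray(k), np.asarray(l)], axis=-1)
    mapped = np.einsum("nij,mi->nmj", rots, hkl)
    return np.any(np.all(mapped == -hkl[None, :, :], axis=2), axis=0)


def _canonical_hkl(symops: Sequence[str], h, k, l) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical representative per reflection: the lexicographically
    greatest among all R^T h and their Friedel mates -R^T h."""
    rots = _rotation_parts(symops)
    hkl = np.stack([np.asarray(h), np.asarray(k), np.asarray(l)], axis=-1)
    mapped = np.einsum("nij,mi->nmj", rots, hkl)  # (n_ops, m, 3)
    cands = np.concatenate([mapped, -mapped], axis=0)
    # lexicographic maximum via a collision-free integer key
    span = int(np.abs(cands).max()) + 1
    base = 2 * span + 1
    key = (cands[..., 0] * base + cands[..., 1]) * base + cands[..., 2]
    best = np.argmax(key, axis=0)
    chosen = cands[best, np.arange(cands.shape[1]), :]
    return chosen[:, 0], chosen[:, 1], chosen[:, 2]


# --------------------------------------------------------------------------
# the reflection set
# --------------------------------------------------------------------------

_COLUMNS = ["h", "k", "l", "I", "sigI", "F", "sigF", "mult"]


@dataclass
class ReflectionSet:
    """Reflection observations plus their unit-cell and symmetry context.

    ``data`` is a DataFrame with integer columns h, k, l and float columns
    I, sigI (NaN when absent), F, sigF (NaN when absent) and mult
    (NaN when unknown). ``merged`` declares that each (h,k,l) appears once.
    """

    cell: UnitCell
    symops: list[str] = field(default_factory=lambda: ["x,y,z"])
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COLUMNS))
    merged: bool = False

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[_COLUMNS]
        for col in ("h", "k", "l"):
            df[col] = df[col].astype(int)
        for col in ("I", "sigI", "F", "sigF", "mult"):
            df[col] = df[col].astype(float)
        if len(df) and np.any((df.h == 0) & (df.k == 0) & (df.l == 0)):
            raise GeometryError("(0,0,0) is not a valid reflection")
        has_i = df["I"].notna()
        if np.any(has_i & ~(df.loc[has_i, "sigI"] > 0)):
            raise FormatError("sigI must be > 0 wherever I is present")
        if np.any(df["F"].dropna() < 0):
            raise FormatError("amplitudes F must be >= 0")
        self.data = df.reset_index(drop=True)
        if self.merged:
            if df.duplicated(subset=["h", "k", "l"]).any():
                raise FormatError("merged set contains duplicate (h,k,l)")

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_intensities(self) -> bool:
        return bool(self.data["I"].notna().any())

    @property
    def has_amplitudes(self) -> bool:
        return bool(self.data["F"].notna().any())

    def d_spacings(self) -> np.ndarray:
        return np.asarray(
            compute_d_spacing(self.cell, self.data.h.values, self.data.k.values, self.data.l.values)
        )

    def centric(self) -> np.ndarray:
        return centric_flags(self.symops, self.data.h.values, self.data.k.values, self.data.l.values)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

# MTZ column-label preference, tried in order; intensities first
_MTZ_PREFS = [
    ("I", "SIGI", "I", "sigI"),
    ("IMEAN", "SIGIMEAN", "I", "sigI"),
    ("F", "SIGF", "F", "sigF"),
    ("FP", "SIGFP", "F", "sigF"),
]


def read_reflections(path: str | Path, format: str | None = None) -> ReflectionSet:
    """Read an MTZ or dialect-CSV reflection file into a ReflectionSet.

    ``format`` is ``"mtz"`` or ``"csv"``; when None it is inferred from the
    file suffix. The file must provide H,K,L and at least one of (I, sigI)
    or (F, sigF); amplitude-only files are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtz" if path.suffix.lower() == ".mtz" else "csv"
    if format == "mtz":
        return _read_mtz(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_mtz(path: Path) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    sg = mtz.spacegroup
    symops = [op.triplet() for op in sg.operations()] if sg else ["x,y,z"]
    labels = {c.label for c in mtz.columns}
    if not {"H", "K", "L"} <= labels:
        missing = {"H", "K", "L"} - labels
        raise FormatError(f"MTZ missing Miller-index column(s): {sorted(missing)}")
    arr = np.array(mtz, copy=True)
    cols = {c.label: i for i, c in enumerate(mtz.columns)}
    df = pd.DataFrame(
        {
            "h": arr[:, cols["H"]].astype(int),
            "k": arr[:, cols["K"]].astype(int),
            "l": arr[:, cols["L"]].astype(int),
        }
    )
    found = False
    for val, sig, out_val, out_sig in _MTZ_PREFS:
        if val in cols and sig in cols and np.isnan(df.get(out_val, np.nan)).all():
            df[out_val] = arr[:, cols[val]]
            df[out_sig] = arr[:, cols[sig]]
            logger.info("MTZ column choice: %s/%s -> %s/%s", val, sig, out_val, out_sig)
            found = True
    if not found:
        raise FormatError("MTZ contains neither (I,SIGI)/(IMEAN,SIGIMEAN) nor (F,SIGF)/(FP,SIGFP)")
    for lbl in ("MULT", "M_ISYM", "MULTIPLICITY", "NOBS"):
        if lbl in cols and lbl in ("MULT", "MULTIPLICITY", "NOBS"):
            df["mult"] = arr[:, cols[lbl]]
            break
    # drop rows where every datum is missing (MTZ NaN padding)
    keep = df.get("I", pd.Series(np.nan, index=df.index)).notna() | df.get(
        "F", pd.Series(np.nan, index=df.index)
    ).notna()
    df = df[keep]
    return ReflectionSet(cell=cell, symops=symops, data=df, merged=True)


def _read_csv(path: Path) -> ReflectionSet:
    cell = None
    symops: list[str] = []
    header_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("cell"):
                parts = body.split()[1:]
                if len(parts) != 6:
                    raise FormatError("#cell line must carry 6 numbers")
                cell = UnitCell(*(float(x) for x in parts))
            elif body.startswith("symop"):
                symops.append(body.split(None, 1)[1].strip())
    if cell is None:
        raise GeometryError("CSV lacks a '#cell a b c alpha beta gamma' line")
    if not symops:
        symops = ["x,y,z"]
    parse_symops(symops)  # validate early
    df = pd.read_csv(path, skiprows=header_lines)
    df.columns = [c.strip() for c in df.columns]
    for col in ("h", "k", "l"):
        if col not in df.columns:
            raise FormatError(f"CSV missing required column {col!r}")
    if "I" not in df.columns and "F" not in df.columns:
        raise FormatError("CSV must contain an 'I' (with 'sigI') or 'F' (with 'sigF') column")
    if "I" in df.columns and "sigI" not in df.columns:
        raise FormatError("CSV missing required column 'sigI'")
    if "F" in df.columns and "sigF" not in df.columns:
        raise FormatError("CSV missing required column 'sigF'")
    return ReflectionSet(cell=cell, symops=symops, data=df, merged=False)


def write_reflections(rs: ReflectionSet, path: str | Path, format: str | None = None) -> Path:
    """Write a ReflectionSet to the CSV dialect or to MTZ."""
    path = Path(path)
    if format is None:
        format = "mtz" if path.suffix.lower() == ".mtz" else "csv"
    if format == "csv":
        return _write_csv(rs, path)
    if format == "mtz":
        return _write_mtz(rs, path)
    raise ValueError(f"unknown format {format!r}")


def _write_csv(rs: ReflectionSet, path: Path) -> Path:
    df = rs.data
    cols = ["h", "k", "l"]
    if rs.has_intensities:
        cols += ["I", "sigI"]
    if rs.has_amplitudes:
        cols += ["F", "sigF"]
    if df["mult"].notna().any():
        cols += ["mult"]
    c = rs.cell
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#cell {c.a:.6g} {c.b:.6g} {c.c:.6g} {c.alpha:.6g} {c.beta:.6g} {c.gamma:.6g}\n")
        for op in rs.symops:
            fh.write(f"#symop {op}\n")
        df[cols].to_csv(fh, index=False, float_format="%.8g", lineterminator="\n")
    return path


def _write_mtz(rs: ReflectionSet, path: Path) -> Path:
    mtz = gemmi.Mtz(with_base=True)  # provides H K L columns
    mtz.cell = gemmi.UnitCell(rs.cell.a, rs.cell.b, rs.cell.c, rs.cell.alpha, rs.cell.beta, rs.cell.gamma)
    ops = gemmi.GroupOps([gemmi.Op(t) for t in rs.symops])
    sg = gemmi.find_spacegroup_by_ops(ops)
    mtz.spacegroup = sg if sg is not None else gemmi.SpaceGroup("P1")
    df = rs.data
    arrays = [df.h.values.astype(float), df.k.values.astype(float), df.l.values.astype(float)]
    if rs.has_intensities:
        mtz.add_column("I", "J")
        mtz.add_column("SIGI", "Q")
        arrays += [df.I.values, df.sigI.values]
    if rs.has_amplitudes:
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
        arrays += [df.F.values, df.sigF.values]
    if df["mult"].notna().any():
        mtz.add_column("MULT", "I")
        arrays += [df["mult"].values]
    mtz.set_data(np.column_stack(arrays).astype(np.float32))
    mtz.write_to_file(str(path))
    return path


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------

def merge_equivalents(rs: ReflectionSet) -> ReflectionSet:
    """Merge symmetry-equivalent observations (Friedel mates included).

    Per unique reflection the merged intensity is the unweighted mean
    I = (1/N) sum I_i and, because independent errors add in quadrature,
    sigma^2 = (1/N^2) sum sigma_i^2 — so with equal sigmas the merged
    sigma is sigma/sqrt(N). The multiplicity column records N.
    """
    if rs.merged:
        raise ValueError("reflection set is already merged")
    if not rs.has_intensities:
        raise ValueError("merging requires intensities")
    df = rs.data
    ch, ck, cl = _canonical_hkl(rs.symops, df.h.values, df.k.values, df.l.values)
    g = pd.DataFrame({"h": ch, "k": ck, "l": cl, "I": df.I.values, "var": df.sigI.values**2})
    grouped = g.groupby(["h", "k", "l"], sort=True)
    agg = grouped.agg(I=("I", "mean"), var_sum=("var", "sum"), mult=("I", "size")).reset_index()
    agg["sigI"] = np.sqrt(agg.var_sum) / agg["mult"]
    out = agg[["h", "k", "l", "I", "sigI", "mult"]].copy()
    out["mult"] = out["mult"].astype(float)
    return ReflectionSet(cell=rs.cell, symops=list(rs.symops), data=out, merged=True)
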