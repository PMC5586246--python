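import math

import gemmi
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from icediag import (
    FormatError,
    GeometryError,
    ReflectionSet,
    UnitCell,
    compute_d_spacing,
    is_centric,
    merge_equivalents,
    read_reflections,
    write_reflections,
)
from icediag.reflection_io import _canonical_hkl, centric_flags

from conftest import brute_force_reciprocal_d


# ---------------------------------------------------------------- d-spacing

def test_d_spacing_cubic_ice_111():
    """(111) of the cubic-ice lattice sits at 3.67 A."""
    cell = UnitCell(6.358, 6.358, 6.358, 90, 90, 90)
    assert compute_d_spacing(cell, 1, 1, 1) == pytest.approx(3.67, abs=0.005)


def test_d_spacing_unit_cube_identity():
    assert compute_d_spacing(UnitCell(1, 1, 1, 90, 90, 90), 1, 0, 0) == pytest.approx(1.0)


def test_d_spacing_cubic_reduces_to_closed_form():
    cell = UnitCell(23.4, 23.4, 23.4, 90, 90, 90)
    for hkl in [(1, 2, 3), (4, 0, 1), (2, 2, 2)]:
        expected = 23.4 / math.sqrt(sum(x * x for x in hkl))
        assert compute_d_spacing(cell, *hkl) == pytest.approx(expected, rel=1e-12)


def test_d_spacing_triclinic_vs_brute_force():
    params = (7.2, 8.1, 9.3, 95.0, 101.0, 112.0)
    cell = UnitCell(*params)
    got = compute_d_spacing(cell, 2, -1, 3)
    expected = brute_force_reciprocal_d(*params, 2, -1, 3)
    assert got == pytest.approx(expected, rel=1e-9)


def test_d_spacing_zero_triple_rejected():
    with pytest.raises(GeometryError):
        compute_d_spacing(UnitCell(10, 10, 10, 90, 90, 90), 0, 0, 0)


@given(
    st.tuples(
        st.floats(5, 80), st.floats(5, 80), st.floats(5, 80),
        st.floats(60, 120), st.floats(60, 120), st.floats(60, 120),
    ),
    st.tuples(st.integers(-8, 8), st.integers(-8, 8), st.integers(-8, 8)).filter(
        lambda t: t != (0, 0, 0)
    ),
)
def test_d_spacing_matches_gemmi(params, hkl):
    """Cross-check the metric-tensor route against gemmi on random cells."""
    try:
        cell = UnitCell(*params)
    except GeometryError:  # degenerate angle combination
        return
    ours = compute_d_spacing(cell, *hkl)
    ref = gemmi.UnitCell(*params).calculate_d(hkl)
    assert ours == pytest.approx(ref, rel=1e-9)


# ---------------------------------------------------------------- centricity

def test_centricity_p1_p1bar_and_p2():
    p1 = ["x,y,z"]
    p1bar = ["x,y,z", "-x,-y,-z"]
    p2 = ["x,y,z", "-x,y,-z"]
    for hkl in [(1, 2, 3), (0, 0, 4), (3, 0, 2)]:
        assert not is_centric(p1, *hkl)
        assert is_centric(p1bar, *hkl)
    assert is_centric(p2, 3, 0, 2)  # h0l maps to -h,0,-l
    assert not is_centric(p2, 3, 1, 2)


def test_centricity_invariant_under_equivalents():
    symops = ["x,y,z", "-x,-y,z", "-x,y,-z", "x,-y,-z"]  # 222
    rng = np.random.default_rng(0)
    rots = [np.eye(3, dtype=int), np.diag([-1, -1, 1]), np.diag([-1, 1, -1]), np.diag([1, -1, -1])]
    for _ in range(50):
        hkl = rng.integers(-6, 7, size=3)
        if not hkl.any():
            continue
        base = is_centric(symops, *hkl)
        for R in rots:
            eq = R.T @ hkl
            assert is_centric(symops, *eq) == base
            assert is_centric(symops, *(-eq)) == base


def test_unparseable_symop_raises():
    with pytest.raises(FormatError):
        is_centric(["x,y"], 1, 2, 3)


# ------------------------------------------------------------------ merging

def _make_set(rows, symops=("x,y,z", "-x,-y,z", "-x,y,-z", "x,-y,-z")):
    df = pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigI"])
    return ReflectionSet(
        cell=UnitCell(20, 25, 30, 90, 90, 90), symops=list(symops), data=df, merged=False
    )


def test_merge_equal_sigmas_gives_sigma_over_sqrt_n():
    """Four equivalent measurements with sigma 2 merge to sigma 1."""
    rows = [(1, 2, 3, 10.0, 2.0), (-1, -2, 3, 12.0, 2.0), (-1, 2, -3, 8.0, 2.0), (1, -2, -3, 14.0, 2.0)]
    merged = merge_equivalents(_make_set(rows))
    assert len(merged) == 1
    row = merged.data.iloc[0]
    assert row.I == pytest.approx(11.0)
    assert row.sigI == pytest.approx(1.0)
    assert row.mult == 4


def test_merge_unequal_sigmas():
    """sigma_i = {1,2,2,3} -> merged sigma = sqrt(18)/4."""
    rows = [(1, 2, 3, 10.0, 1.0), (-1, -2, 3, 10.0, 2.0), (-1, 2, -3, 10.0, 2.0), (1, -2, -3, 10.0, 3.0)]
    merged = merge_equivalents(_make_set(rows))
    assert merged.data.iloc[0].sigI == pytest.approx(math.sqrt(18) / 4)


def test_merge_single_observation_unchanged():
    merged = merge_equivalents(_make_set([(1, 2, 3, 5.5, 0.7)]))
    row = merged.data.iloc[0]
    assert (row.I, row.sigI, row.mult) == (5.5, 0.7, 1)


def test_merge_conserves_total_signal_and_canonical_choice():
    rng = np.random.default_rng(3)
    rows = []
    for _ in range(200):
        h, k, l = rng.integers(1, 5, size=3)
        rows.append((int(h), int(k), int(l), float(rng.normal(10, 3)), float(rng.uniform(0.5, 2))))
        # scatter some equivalents / Friedel mates of the same reflection
        rows.append((-int(h), -int(k), int(l), float(rng.normal(10, 3)), float(rng.uniform(0.5, 2))))
    rs = _make_set(rows)
    merged = merge_equivalents(rs)
    total_before = rs.data.I.sum()
    total_after = (merged.data.I * merged.data.mult).sum()
    assert total_after == pytest.approx(total_before, rel=1e-12)
    # canonical representative is the lexicographically greatest equivalent
    assert (merged.data[["h", "k", "l"]].values >= 0).all(axis=1).any()
    ch, ck, cl = _canonical_hkl(rs.symops, merged.data.h.values, merged.data.k.values, merged.data.l.values)
    assert np.array_equal(np.stack([ch, ck, cl], axis=1), merged.data[["h", "k", "l"]].values)


def test_merged_i_over_sigma_follows_sqrt_n_ladder():
    """With equal per-measurement sigmas, merged I/sigma = sqrt(N) * (I/sigma)."""
    for n in (1, 2, 4, 8):
        rows = []
        mates = [(1, 2, 3), (-1, -2, 3), (-1, 2, -3), (1, -2, -3),
                 (-1, -2, -3), (1, 2, -3), (1, -2, 3), (-1, 2, 3)]
        for i in range(n):
            h, k, l = mates[i]
            rows.append((h, k, l, 10.0, 2.0))
        merged = merge_equivalents(_make_set(rows))
        row = merged.data.iloc[0]
        assert row.I / row.sigI == pytest.approx(math.sqrt(n) * 10.0 / 2.0)


# ---------------------------------------------------------------------- I/O

def test_csv_roundtrip_preserves_fields(tmp_path, clean_set):
    sub = ReflectionSet(
        cell=clean_set.cell, symops=list(clean_set.symops),
        data=clean_set.data.head(500), merged=True,
    )
    path = tmp_path / "refl.csv"
    write_reflections(sub, path)
    back = read_reflections(path)
    assert back.cell.a == pytest.approx(sub.cell.a, rel=1e-6)
    assert len(back) == len(sub)
    for col in ("h", "k", "l"):
        assert np.array_equal(back.data[col].values, sub.data[col].values)
    for col in ("I", "sigI", "mult"):
        np.testing.assert_allclose(back.data[col].values, sub.data[col].values, rtol=1e-6)


def test_mtz_roundtrip(tmp_path, clean_set):
    sub = ReflectionSet(
        cell=clean_set.cell, symops=list(clean_set.symops),
        data=clean_set.data.head(500), merged=True,
    )
    path = tmp_path / "refl.mtz"
    write_reflections(sub, path)
    back = read_reflections(path)
    assert len(back) == len(sub)
    order = np.lexsort((back.data.l, back.data.k, back.data.h))
    order0 = np.lexsort((sub.data.l, sub.data.k, sub.data.h))
    np.testing.assert_allclose(
        back.data.I.values[order], sub.data.I.values[order0], rtol=1e-5
    )


def test_csv_simple_parse(tmp_path):
    path = tmp_path / "mini.csv"
    path.write_text(
        "#cell 10 10 10 90 90 90\n#symop x,y,z\n"
        "h,k,l,I,sigI\n1,0,0,5.0,1.0\n0,1,0,4.0,1.0\n0,0,1,3.0,1.0\n"
    )
    rs = read_reflections(path)
    assert len(rs) == 3 and not rs.merged
    assert rs.data.I.tolist() == [5.0, 4.0, 3.0]


def test_csv_missing_observables_is_format_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("#cell 10 10 10 90 90 90\nh,k,l\n1,0,0\n")
    with pytest.raises(FormatError):
        read_reflections(path)


def test_amplitude_only_csv_accepted(tmp_path):
    path = tmp_path / "amps.csv"
    path.write_text(
        "#cell 10 10 10 90 90 90\nh,k,l,F,sigF\n1,0,0,5.0,0.5\n0,1,0,4.0,0.5\n"
    )
    rs = read_reflections(path)
    assert rs.has_amplitudes and not rs.has_intensities


def test_invalid_cell_rejected():
    with pytest.raises(GeometryError):
        UnitCell(-1, 10, 10, 90, 90, 90)
    with pytest.raises(GeometryError):
        UnitCell(10, 10, 10, 1, 1, 170)  # impossible angle combination
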