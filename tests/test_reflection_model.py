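import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflexio.reflection_model import (
    InvalidCellError,
    InvalidReflectionError,
    ReflectionTable,
    UnitCell,
    canonicalize,
    canonicalize_array,
    d_spacing,
    enumerate_unique,
    get_group,
    load_registry,
)


def oracle_d_spacing(hkl, cell):
    """Independent oracle: build real-space basis vectors, derive the
    reciprocal basis via cross products, measure |h a* + k b* + l c*|."""
    a, b, c = cell.a, cell.b, cell.c
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    va = np.array([a, 0, 0])
    vb = np.array([b * math.cos(ga), b * math.sin(ga), 0])
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz = math.sqrt(c * c - cx * cx - cy * cy)
    vc = np.array([cx, cy, cz])
    vol = float(np.dot(va, np.cross(vb, vc)))
    astar = np.cross(vb, vc) / vol
    bstar = np.cross(vc, va) / vol
    cstar = np.cross(va, vb) / vol
    s = hkl[0] * astar + hkl[1] * bstar + hkl[2] * cstar
    return 1.0 / float(np.linalg.norm(s))


class TestUnitCell:
    def test_cubic_volume(self, cubic_cell):
        assert cubic_cell.volume == pytest.approx(1000.0)

    @pytest.mark.parametrize("bad", [
        dict(a=-1, b=10, c=10),
        dict(a=10, b=0, c=10),
        dict(a=10, b=10, c=10, alpha=0),
        dict(a=10, b=10, c=10, gamma=180),
    ])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(InvalidCellError):
            UnitCell(**{**dict(a=10, b=10, c=10), **bad})

    def test_degenerate_angles_rejected(self):
        # angles that cannot close a parallelepiped
        with pytest.raises(InvalidCellError):
            UnitCell(10, 10, 10, 170, 170, 170)

    def test_metric_tensor_positive_definite(self, triclinic_cell):
        eig = np.linalg.eigvalsh(triclinic_cell.metric_tensor)
        assert (eig > 0).all()


class TestDSpacing:
    def test_cubic_axis(self, cubic_cell):
        assert d_spacing((1, 0, 0), cubic_cell) == pytest.approx(10.0)

    def test_zero_triple_rejected(self, cubic_cell):
        with pytest.raises(InvalidReflectionError):
            d_spacing((0, 0, 0), cubic_cell)

    def test_triclinic_matches_vector_oracle(self, triclinic_cell):
        expected = oracle_d_spacing((1, 2, 3), triclinic_cell)
        assert d_spacing((1, 2, 3), triclinic_cell) == pytest.approx(
            expected, abs=1e-12
        )

    @given(
        hkl=st.tuples(
            st.integers(-9, 9), st.integers(-9, 9), st.integers(-9, 9)
        ).filter(lambda t: t != (0, 0, 0))
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_property(self, hkl):
        cell = UnitCell(10, 12, 15, 85, 95, 100)
        assert d_spacing(hkl, cell) == pytest.approx(
            oracle_d_spacing(hkl, cell), rel=1e-12
        )

    def test_invariant_under_group_rotations(self, triclinic_cell):
        # use the group whose lattice is compatible with each test cell
        cases = [
            ("P1", UnitCell(10, 12, 15, 85, 95, 100)),
            ("P2", UnitCell(10, 12, 15, 90, 95, 90)),
            ("P222", UnitCell(10, 12, 15)),
            ("P422", UnitCell(10, 10, 15)),
            ("P321", UnitCell(10, 10, 15, 90, 90, 120)),
            ("P6", UnitCell(10, 10, 15, 90, 90, 120)),
            ("P23", UnitCell(10, 10, 10)),
        ]
        rng = np.random.default_rng(0)
        for symbol, cell in cases:
            group = get_group(symbol)
            for _ in range(20):
                hkl = rng.integers(-6, 7, 3)
                if (hkl == 0).all():
                    continue
                d0 = d_spacing(tuple(hkl), cell)
                for rot in group.rotation_matrices:
                    assert d_spacing(tuple(rot @ hkl), cell) == pytest.approx(d0)


class TestRegistry:
    def test_all_groups_load(self):
        reg = load_registry()
        assert {"P1", "P2", "C2", "P222", "P212121", "P4", "P422",
                "P3", "P321", "P6", "P23", "I213"} <= set(reg)

    def test_group_closure_and_identity(self):
        for group in load_registry().values():
            mats = group.rotation_matrices
            keys = {m.tobytes() for m in mats}
            assert np.eye(3, dtype=int).tobytes() in keys
            for a in mats:
                assert round(float(np.linalg.det(a))) == 1
                for b in mats:
                    assert (a @ b).tobytes() in keys

    def test_ambiguity_ops_outside_laue(self):
        for group in load_registry().values():
            laue = {m.tobytes() for m in group.laue_matrices}
            for amb in group.ambiguity_matrices:
                assert amb.tobytes() not in laue

    def test_no_ambiguity_when_lattice_equals_laue(self):
        for symbol in ("P1", "P2", "P222", "P422"):
            assert get_group(symbol).ambiguity_ops == ()

    def test_unknown_symbol(self):
        with pytest.raises(KeyError):
            get_group("P63")


class TestCanonicalize:
    def test_friedel_pair_merges(self, p1):
        assert canonicalize((1, 2, 3), p1).hkl == canonicalize((-1, -2, -3), p1).hkl

    def test_friedel_separate_signs(self, p1):
        a = canonicalize((1, 2, 3), p1, friedel_merged=False)
        b = canonicalize((-1, -2, -3), p1, friedel_merged=False)
        assert a.hkl == b.hkl
        assert (a.friedel_sign, b.friedel_sign) == (1, -1)

    def test_orbit_collapses_p222(self, p222):
        hkl = np.array([1, 2, 3])
        orbit = set()
        for rot in p222.rotation_matrices:
            orbit.add(tuple(rot @ hkl))
            orbit.add(tuple(-(rot @ hkl)))
        assert len(orbit) == 8  # explicit matrix enumeration
        canons = {canonicalize(t, p222).hkl for t in orbit}
        assert len(canons) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        for symbol in ("P1", "P222", "P4", "P321", "P23"):
            group = get_group(symbol)
            hkl = rng.integers(-8, 9, (50, 3))
            hkl[(hkl == 0).all(axis=1)] = (1, 0, 0)
            once, _ = canonicalize_array(hkl, group)
            twice, _ = canonicalize_array(once, group)
            assert (once == twice).all()

    @given(st.integers(-8, 8), st.integers(-8, 8), st.integers(-8, 8))
    @settings(max_examples=60, deadline=None)
    def test_mates_share_canonical_p4(self, h, k, l):
        if (h, k, l) == (0, 0, 0):
            return
        group = get_group("P4")
        base = canonicalize((h, k, l), group).hkl
        for rot in group.laue_matrices:
            assert canonicalize(tuple(rot @ np.array([h, k, l])), group).hkl == base


class TestEnumerateUnique:
    def test_cubic_p1_shell_matches_bruteforce(self, cubic_cell, p1):
        got = enumerate_unique(cubic_cell, p1, 5.0, 10.0)
        # exhaustive loop over |h|,|k|,|l| <= 2 with Friedel dedup
        seen = set()
        for h in range(-2, 3):
            for k in range(-2, 3):
                for l in range(-2, 3):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    d = d_spacing((h, k, l), cubic_cell)
                    if 5.0 <= d <= 10.0:
                        seen.add(max((h, k, l), (-h, -k, -l)))
        assert len(got) == len(seen)
        assert {tuple(r) for r in got} == seen

    def test_empty_shell_above_longest_axis(self, cubic_cell, p1):
        assert len(enumerate_unique(cubic_cell, p1, 11.0, 20.0)) == 0

    def test_symmetry_reduces_count(self, cubic_cell):
        n_p1 = len(enumerate_unique(cubic_cell, get_group("P1"), 2.0, 10.0))
        n_p2 = len(enumerate_unique(cubic_cell, get_group("P2"), 2.0, 10.0))
        assert n_p2 <= n_p1

    def test_counts_match_bruteforce_to_3A(self, cubic_cell):
        for symbol in ("P1", "P2", "P222", "P4", "P23"):
            group = get_group(symbol)
            got = enumerate_unique(cubic_cell, group, 3.0, 11.0)
            uniq = set()
            lim = 4
            for h in range(-lim, lim + 1):
                for k in range(-lim, lim + 1):
                    for l in range(-lim, lim + 1):
                        if (h, k, l) == (0, 0, 0):
                            continue
                        if 3.0 <= d_spacing((h, k, l), cubic_cell) <= 11.0:
                            uniq.add(canonicalize((h, k, l), group).hkl)
            assert len(got) == len(uniq), symbol

    def test_invalid_range(self, cubic_cell, p1):
        with pytest.raises(ValueError):
            enumerate_unique(cubic_cell, p1, -1.0, 5.0)
        with pytest.raises(ValueError):
            enumerate_unique(cubic_cell, p1, 5.0, 5.0)


class TestReflectionTable:
    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(InvalidReflectionError):
            ReflectionTable.from_arrays([1], [0], [0], [5.0], [0.0])

    def test_rejects_zero_index(self):
        with pytest.raises(InvalidReflectionError):
            ReflectionTable.from_arrays([0], [0], [0], [5.0], [1.0])

    def test_rejects_bad_image(self):
        with pytest.raises(InvalidReflectionError):
            ReflectionTable.from_arrays([1], [0], [0], [5.0], [1.0], image=0)
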