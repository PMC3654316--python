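import numpy as np
import pytest

from reflexio.grouped_merging import (
    InsufficientOverlapError,
    NoReferenceError,
    SubDataset,
    check_lattice_consistency,
    choose_reference,
    merge_grouped,
    resolve_indexing,
)
from reflexio.reflection_model import ReflectionTable, UnitCell, get_group
from reflexio.shell_statistics import shell_edges
from reflexio.synthetic_data import SyntheticConfig, generate_subdatasets


def ops_equivalent(a, b, group):
    """Operators equal modulo the Laue group (same reindexing effect)."""
    prod = np.asarray(a) @ np.round(np.linalg.inv(b)).astype(int)
    return any((prod == m).all() for m in group.laue_matrices)


def make_sub(ds_id, cell=None, lattice="oP", seed=0):
    cfg = SyntheticConfig(cell=cell or UnitCell(30, 40, 50),
                          group_symbol="P222", d_min=3.0, seed=seed)
    from reflexio.synthetic_data import generate_dataset

    _, table, _ = generate_dataset(cfg)
    return SubDataset(dataset_id=ds_id, table=table, cell=cfg.cell,
                      lattice_symbol=lattice)


class TestLatticeConsistency:
    def test_all_matched_within_tolerance(self):
        consensus = UnitCell(30, 40, 50)
        subs = [
            make_sub("a", UnitCell(30.1, 40.05, 49.9)),
            make_sub("b", UnitCell(29.9, 39.9, 50.2)),
            make_sub("c", consensus),
        ]
        verdicts = check_lattice_consistency(subs, get_group("P222"), consensus)
        assert set(verdicts.values()) == {"matched"}

    def test_wrong_symbol_re_integrated(self):
        consensus = UnitCell(30, 40, 50)
        subs = [make_sub("a", lattice="aP"), make_sub("b"), make_sub("c")]
        verdicts = check_lattice_consistency(subs, get_group("P222"), consensus)
        assert verdicts["a"] == "re_integrated"
        assert verdicts["b"] == verdicts["c"] == "matched"

    def test_gross_mismatch_excluded(self):
        consensus = UnitCell(30, 40, 50)
        subs = [make_sub("a", UnitCell(30 * 1.15, 40, 50))]  # 15% off
        verdicts = check_lattice_consistency(subs, get_group("P222"), consensus)
        assert verdicts["a"] == "excluded"

    def test_intermediate_deviation_re_integrated(self):
        consensus = UnitCell(30, 40, 50)
        subs = [make_sub("a", UnitCell(30 * 1.05, 40, 50))]  # 5% off
        verdicts = check_lattice_consistency(subs, get_group("P222"), consensus)
        assert verdicts["a"] == "re_integrated"


class TestChooseReference:
    def test_first_matched_wins(self):
        subs = [make_sub("a"), make_sub("b"), make_sub("c")]
        verdicts = {"a": "re_integrated", "b": "matched", "c": "matched"}
        assert choose_reference(subs, verdicts) == "b"

    def test_first_in_collection_order(self):
        subs = [make_sub("a"), make_sub("b")]
        assert choose_reference(subs, {"a": "matched", "b": "matched"}) == "a"

    def test_fallback_to_re_integrated(self):
        subs = [make_sub("a"), make_sub("b")]
        verdicts = {"a": "excluded", "b": "re_integrated"}
        assert choose_reference(subs, verdicts) == "b"

    def test_all_excluded_errors(self):
        subs = [make_sub("a")]
        with pytest.raises(NoReferenceError):
            choose_reference(subs, {"a": "excluded"})


class TestResolveIndexing:
    def test_copy_of_reference_gives_identity(self):
        group = get_group("P4")
        cfg = SyntheticConfig(cell=UnitCell(40, 40, 60), group_symbol="P4",
                              d_min=3.0, seed=5)
        subs, _ = generate_subdatasets(cfg, 2, "random")
        op = resolve_indexing(subs[1], subs[0], group)
        assert (op == np.eye(3, dtype=int)).all()

    def test_apply_and_recover(self):
        group = get_group("P4")
        T = group.ambiguity_matrices[0]
        cfg = SyntheticConfig(cell=UnitCell(40, 40, 60), group_symbol="P4",
                              d_min=3.0, seed=6)
        subs, truth = generate_subdatasets(cfg, 2, "random", applied_ops={1: T})
        op = resolve_indexing(subs[1], subs[0], group)
        assert ops_equivalent(op, np.round(np.linalg.inv(T)).astype(int), group)

    def test_no_ambiguity_short_circuits(self):
        group = get_group("P222")
        a, b = make_sub("a", seed=1), make_sub("b", seed=2)
        op = resolve_indexing(a, b, group)
        assert (op == np.eye(3, dtype=int)).all()

    def test_insufficient_overlap_error(self):
        group = get_group("P4")
        t1 = ReflectionTable.from_arrays([10], [3], [4], [5.0], [1.0])
        t2 = ReflectionTable.from_arrays([8], [2], [6], [5.0], [1.0])
        cell = UnitCell(40, 40, 60)
        a = SubDataset("a", t1, cell, "tP")
        b = SubDataset("b", t2, cell, "tP")
        with pytest.raises(InsufficientOverlapError):
            resolve_indexing(a, b, group)


class TestMergeGrouped:
    def _merge(self, subs, cell, group_symbol="P222", n_shells=5):
        group = get_group(group_symbol)
        d = np.concatenate([s.table.d_spacings(cell) for s in subs])
        edges = shell_edges(float(d.max()), float(d.min()), n_shells)
        return merge_grouped(subs, group, cell, edges)

    def test_identical_copies_duplication_law(self):
        base = make_sub("a", seed=3)
        copies = []
        for i in range(3):
            df = base.table.df.copy()
            df["dataset_id"] = f"copy{i}"
            copies.append(SubDataset(f"copy{i}", ReflectionTable(df),
                                     base.cell, "oP"))
        res = self._merge(copies, base.cell)
        c = [inc.overall.completeness for inc in res.increments]
        m = [inc.overall.multiplicity for inc in res.increments]
        assert c[0] == pytest.approx(c[1]) == pytest.approx(c[2])
        assert m[1] == pytest.approx(2 * m[0])
        assert m[2] == pytest.approx(3 * m[0])

    def test_disjoint_wedges_strictly_increasing(self):
        cfg = SyntheticConfig(cell=UnitCell(30, 40, 50), group_symbol="P222",
                              d_min=2.8, seed=4)
        subs, _ = generate_subdatasets(
            cfg, 5, "disjoint_wedges", scale_factors=[1, 2, 0.5, 1.5, 3]
        )
        res = self._merge(subs, cfg.cell)
        c = [inc.overall.completeness for inc in res.increments]
        assert all(b > a for a, b in zip(c, c[1:]))
        m = [inc.overall.multiplicity for inc in res.increments]
        assert all(b >= a - 1e-12 for a, b in zip(m, m[1:]))

    def test_single_subdataset(self):
        sub = make_sub("only", seed=7)
        res = self._merge([sub], sub.cell)
        assert len(res.increments) == 1
        assert res.reference_id == "only"
        assert (res.operators["only"] == np.eye(3, dtype=int)).all()

    def test_reference_operator_is_identity(self):
        cfg = SyntheticConfig(cell=UnitCell(40, 40, 60), group_symbol="P4",
                              d_min=3.2, seed=8)
        subs, _ = generate_subdatasets(cfg, 3, "random")
        res = self._merge(subs, cfg.cell, "P4")
        assert (res.operators[res.reference_id] == np.eye(3, dtype=int)).all()

    def test_final_stats_order_invariant(self):
        cfg = SyntheticConfig(cell=UnitCell(30, 40, 50), group_symbol="P222",
                              d_min=3.0, seed=9)
        subs, _ = generate_subdatasets(cfg, 3, "random",
                                       scale_factors=[1.0, 1.0, 1.0])
        fwd = self._merge(subs, cfg.cell)
        rev = self._merge(subs[::-1], cfg.cell)
        a, b = fwd.increments[-1].overall, rev.increments[-1].overall
        assert a.n_obs == b.n_obs
        assert a.completeness == pytest.approx(b.completeness)
        assert a.r_merge == pytest.approx(b.r_merge, rel=1e-9)
        assert a.multiplicity == pytest.approx(b.multiplicity)

    def test_scale_factors_recovered(self):
        cfg = SyntheticConfig(cell=UnitCell(30, 40, 50), group_symbol="P222",
                              d_min=3.0, noise_floor=0.5, seed=10)
        subs, truth = generate_subdatasets(cfg, 3, "random",
                                           scale_factors=[1.0, 4.0, 0.25])
        res = self._merge(subs, cfg.cell)
        # applied per-dataset scales are undone relative to the reference
        assert res.scale_factors[res.reference_id] == 1.0
        assert res.scale_factors["sub01"] == pytest.approx(0.25, rel=0.1)
        assert res.scale_factors["sub02"] == pytest.approx(4.0, rel=0.1)

    def test_ambiguity_recovery_rate(self):
        # seeded trials across every registry group with ambiguity operators
        group = get_group("P4")
        T = group.ambiguity_matrices[0]
        Tinv = np.round(np.linalg.inv(T)).astype(int)
        ok = 0
        trials = 40
        for seed in range(trials):
            cfg = SyntheticConfig(cell=UnitCell(40, 40, 60), group_symbol="P4",
                                  d_min=3.5, seed=seed)
            subs, _ = generate_subdatasets(cfg, 2, "random", applied_ops={1: T})
            op = resolve_indexing(subs[1], subs[0], group)
            ok += ops_equivalent(op, Tinv, group)
        assert ok == trials
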