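"""Normalization, differential expression, model classification, assembly."""

import numpy as np
import pandas as pd
import pytest

from phasnet.config import LibraryManifest, RunConfig
from phasnet.network import (
    assemble_network,
    benjamini_hochberg,
    classify_triple,
    correlation_edges,
    differential,
    normalize_rp10m,
    zscore_rows,
)


class TestRp10m:
    def test_definition(self):
        raw = pd.DataFrame({"l1": [5, 1, 0]}, index=["a", "b", "c"])
        expr = normalize_rp10m(raw, {"l1": 10_000_000})
        assert expr.rp10m.loc["a", "l1"] == pytest.approx(5.0)

    def test_half_depth_doubles(self):
        raw = pd.DataFrame({"l1": [1]}, index=["a"])
        expr = normalize_rp10m(raw, {"l1": 5_000_000})
        assert expr.rp10m.loc["a", "l1"] == pytest.approx(2.0)

    def test_zero_count_maps_to_zero(self):
        raw = pd.DataFrame({"l1": [0]}, index=["a"])
        expr = normalize_rp10m(raw, {"l1": 1_000_000})
        assert expr.rp10m.loc["a", "l1"] == 0.0
        assert expr.log2.loc["a", "l1"] == 0.0

    def test_zero_total_rejected(self):
        raw = pd.DataFrame({"l1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            normalize_rp10m(raw, {"l1": 0})


class TestZscore:
    def test_simple_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"], columns=list("xyz"))
        z = zscore_rows(m)
        assert list(z.loc["a"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_with_warning(self):
        m = pd.DataFrame([[4.0, 4.0, 4.0]], index=["a"], columns=list("xyz"))
        with pytest.warns(UserWarning):
            z = zscore_rows(m)
        assert list(z.loc["a"]) == [0.0, 0.0, 0.0]

    def test_column_permutation_equivariance(self, rng):
        m = pd.DataFrame(rng.random((4, 6)), columns=list("abcdef"))
        perm = list("fcbdea")
        z1 = zscore_rows(m)[perm]
        z2 = zscore_rows(m[perm])
        assert np.allclose(z1.to_numpy(), z2.to_numpy())


def brute_force_bh(pvalues):
    """Definitional BH: q_(i) = min_{j >= i} p_(j) * n / j, capped at 1."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    out = [0.0] * n
    for rank_idx, i in enumerate(order):
        q = min(
            pvalues[order[j]] * n / (j + 1) for j in range(rank_idx, n)
        )
        out[i] = min(q, 1.0)
    return out


class TestBenjaminiHochberg:
    def test_worked_example(self):
        assert list(benjamini_hochberg([0.01, 0.02, 0.04])) == pytest.approx([0.03, 0.03, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_definitional_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for n in (1, 2, 5, 10):
            p = rng.random(n)
            assert list(benjamini_hochberg(p)) == pytest.approx(brute_force_bh(list(p)))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(50)
        ours = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_monotone_after_sorting_by_p(self, rng):
        p = rng.random(30)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _manifest(n_rep=3, n_veg=3, total=1_000_000):
    libs = [LibraryManifest(f"r{i}", "ovule", total_clean_reads=total) for i in range(n_rep)]
    libs += [LibraryManifest(f"v{i}", "leaf", total_clean_reads=total) for i in range(n_veg)]
    return libs


class TestDifferential:
    def test_fold_change_arithmetic(self):
        """Mean RP10M 400 vs 100 gives log2FC = log2(400.5/100.5) ~ 1.99."""
        manifest = _manifest(2, 2, 10_000_000)
        raw = pd.DataFrame(
            {"r0": [400], "r1": [400], "v0": [100], "v1": [100]}, index=["f"]
        )
        de = differential(raw, manifest, "miRNA")
        assert de.loc["f", "log2fc"] == pytest.approx(np.log2(400.5 / 100.5))

    def test_identical_groups_do_not_pass(self):
        manifest = _manifest(2, 2, 10_000_000)
        raw = pd.DataFrame({"r0": [50], "r1": [50], "v0": [50], "v1": [50]}, index=["f"])
        de = differential(raw, manifest, "miRNA")
        assert de.loc["f", "log2fc"] == 0.0
        assert not de.loc["f", "passes"]

    def test_low_expression_excluded_before_testing(self):
        manifest = _manifest(2, 2, 10_000_000)
        # RP10M = count here (totals are 1e7): max 9 < 10 -> excluded
        raw = pd.DataFrame({"r0": [9], "r1": [8], "v0": [0], "v1": [1]}, index=["low"])
        de = differential(raw, manifest, "miRNA")
        assert "low" not in de.index

    def test_empty_group_is_error(self):
        manifest = [LibraryManifest("r0", "ovule", total_clean_reads=100)]
        raw = pd.DataFrame({"r0": [5]}, index=["f"])
        with pytest.raises(ValueError):
            differential(raw, manifest, "miRNA")

    def test_class_thresholds(self):
        manifest = _manifest(3, 3, 10_000_000)
        # log2FC just above 1 (PHAS passes at >=1, miRNA needs >=2)
        raw = pd.DataFrame(
            {f"r{i}": [2100] for i in range(3)} | {f"v{i}": [1000] for i in range(3)},
            index=["f"],
        )
        de_phas = differential(raw, manifest, "PHAS")
        de_mir = differential(raw, manifest, "miRNA")
        assert de_phas.loc["f", "passes"]
        assert not de_mir.loc["f", "passes"]


GRID = [-3.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 3.0]


def oracle_classify(mi, phas, mrna):
    """Direct transcription of the model definitions."""
    shared = mi * mrna < 0 and abs(mi) > 1 and abs(mrna) > 1
    model1 = shared and (mi * phas < 0 or abs(phas) < 1)
    model2 = shared and (mi * phas > 0 and abs(phas) > 1)
    if model1:
        return 1
    if model2:
        return 2
    return 0


class TestClassifyTriple:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((2.0, 1.5, -2.0), 2),
            ((2.0, -0.5, -1.5), 1),
            ((0.5, 2.0, -2.0), 0),  # |mi| not > 1
            ((2.0, 1.0, -2.0), 0),  # boundary |phas| = 1, strict
            ((2.0, None, -2.0), 1),  # no PHAS: model-1 candidate
            ((1.0, 0.0, -2.0), 0),  # boundary |mi| = 1, strict
        ],
    )
    def test_examples(self, triple, expected):
        assert classify_triple(*triple) == expected

    def test_full_grid_against_oracle(self):
        """All 729 fold-change combinations match the predicate oracle, and
        the two models are mutually exclusive."""
        for mi in GRID:
            for phas in GRID:
                for mrna in GRID:
                    got = classify_triple(mi, phas, mrna)
                    assert got == oracle_classify(mi, phas, mrna)
                    shared = mi * mrna < 0 and abs(mi) > 1 and abs(mrna) > 1
                    m1 = shared and (mi * phas < 0 or abs(phas) < 1)
                    m2 = shared and (mi * phas > 0 and abs(phas) > 1)
                    assert not (m1 and m2)


class TestCorrelation:
    def test_identical_profiles_kept(self):
        rows = {"a": [1, 5, 20, 3], "b": [1, 5, 20, 3]}
        expr = normalize_rp10m(pd.DataFrame(rows, index=[f"l{i}" for i in range(4)]).T,
                               {f"l{i}": 1_000_000 for i in range(4)})
        kept = correlation_edges(expr, [("a", "b")], 0.7)
        assert len(kept) == 1 and kept[0][2] == pytest.approx(1.0)

    def test_anticorrelated_dropped(self):
        rows = {"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]}
        expr = normalize_rp10m(pd.DataFrame(rows, index=[f"l{i}" for i in range(4)]).T,
                               {f"l{i}": 1_000_000 for i in range(4)})
        assert correlation_edges(expr, [("a", "b")], 0.7) == []

    def test_constant_profile_dropped_with_warning(self):
        rows = {"a": [5, 5, 5, 5], "b": [1, 2, 3, 4]}
        expr = normalize_rp10m(pd.DataFrame(rows, index=[f"l{i}" for i in range(4)]).T,
                               {f"l{i}": 1_000_000 for i in range(4)})
        with pytest.warns(UserWarning):
            assert correlation_edges(expr, [("a", "b")], 0.7) == []

    def test_unknown_feature_is_error(self):
        rows = {"a": [1, 2, 3, 4]}
        expr = normalize_rp10m(pd.DataFrame(rows, index=[f"l{i}" for i in range(4)]).T,
                               {f"l{i}": 1_000_000 for i in range(4)})
        with pytest.raises(ValueError):
            correlation_edges(expr, [("a", "zz")], 0.7)


class TestAssembly:
    """Join semantics on a hand-built miniature network."""

    def _inputs(self):
        from phasnet.targets import TargetInteraction, TriggerAssignment

        triggers = [TriggerAssignment("mi1", "phas1", 1.0, "+", 100, 150, True)]
        targets = [
            TargetInteraction("mi1", "miRNA", "tx1", 10, 31, 2.0, 0.9, 21, True, ""),
            TargetInteraction("mi2", "miRNA", "tx2", 10, 31, 2.0, 0.9, 21, True, ""),
        ]
        phasi_pairs = [("phas1", "tx3")]
        de_mi = pd.DataFrame({"log2fc": [2.0, 3.0]}, index=["mi1", "mi2"])
        de_phas = pd.DataFrame({"log2fc": [1.5]}, index=["phas1"])
        de_mrna = pd.DataFrame({"log2fc": [-2.0, -3.0, -2.5]}, index=["tx1", "tx2", "tx3"])
        return triggers, targets, phasi_pairs, de_mi, de_phas, de_mrna

    def test_triples_and_models(self):
        triggers, targets, phasi_pairs, de_mi, de_phas, de_mrna = self._inputs()
        triples, edges = assemble_network(triggers, targets, phasi_pairs, de_mi, de_phas, de_mrna)
        by_key = {(r.mirna_id, r.phas_id, r.mrna_id): r.model for _, r in triples.iterrows()}
        assert by_key[("mi1", "phas1", "tx1")] == 2  # concordant PHAS
        assert by_key[("mi1", "phas1", "tx3")] == 2  # via phasiRNA target
        assert by_key[("mi2", "", "tx2")] == 1  # no trigger: miRNA-only
        assert set(edges.edge_type) == {"miRNA->mRNA", "miRNA->PHAS"}

    def test_removing_trigger_demotes_model2(self):
        triggers, targets, phasi_pairs, de_mi, de_phas, de_mrna = self._inputs()
        triples, _ = assemble_network([], targets, phasi_pairs, de_mi, de_phas, de_mrna)
        by_key = {(r.mirna_id, r.phas_id, r.mrna_id): r.model for _, r in triples.iterrows()}
        # without the trigger the mi1-phas1 route disappears entirely
        assert ("mi1", "phas1", "tx1") not in by_key
        assert by_key[("mi1", "", "tx1")] == 1

    def test_dangling_id_is_error(self):
        triggers, targets, phasi_pairs, de_mi, de_phas, de_mrna = self._inputs()
        with pytest.raises(ValueError, match="dangling"):
            assemble_network(triggers, targets, phasi_pairs, de_mi.drop("mi2"), de_phas, de_mrna)

    def test_non_de_mrna_yields_no_model(self):
        triggers, targets, phasi_pairs, de_mi, de_phas, de_mrna = self._inputs()
        de_mrna.loc["tx1", "log2fc"] = 0.2
        triples, _ = assemble_network(triggers, targets, phasi_pairs, de_mi, de_phas, de_mrna)
        by_key = {(r.mirna_id, r.phas_id, r.mrna_id): r.model for _, r in triples.iterrows()}
        assert by_key[("mi1", "phas1", "tx1")] == 0
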