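import numpy as np
import pandas as pd
import pytest

import oracles
from pcfidelity import subtypes
from pcfidelity.core_io import GeneSet, Thresholds


def toy_expression(values, genes=None, sample="S1"):
    genes = genes or [f"G{i}" for i in range(len(values))]
    return pd.DataFrame({sample: values}, index=genes)


class TestSsgsea:
    def test_hand_traced_running_sum(self):
        # 6 genes with expressions {6..1}; set = the five most expressed.
        # Walking genes in descending order, the weighted in-set ECDF minus
        # the out-set ECDF accumulates to the value traced by hand below.
        expr = toy_expression([6.0, 5, 4, 3, 2, 1])
        inset = ["G0", "G1", "G2", "G3", "G4"]
        scores = subtypes.ssgsea(expr, [GeneSet("S", frozenset(inset))], alpha=0.25)
        w = np.array([6.0, 5, 4, 3, 2]) ** 0.25  # ranks of the in-set genes
        p_in = np.cumsum(np.append(w, 0.0)) / w.sum()
        p_out = np.array([0, 0, 0, 0, 0, 1.0])
        expected = float((p_in - p_out).sum())
        assert scores.loc["S1", "S"] == pytest.approx(expected, abs=1e-12)

    def test_alpha_zero_reduces_to_unweighted_running_sum(self):
        # closed form on a 6-gene toy with distinct values: each walk step
        # adds (in-count/|set| - out-count/|out|)
        expr = toy_expression([6.0, 5, 4, 3, 2, 1])
        inset = {"G0", "G2", "G3", "G4", "G5"}
        scores = subtypes.ssgsea(expr, [GeneSet("S", frozenset(inset))], alpha=0.0)
        p_in = np.array([1, 1, 2, 3, 4, 5]) / 5
        p_out = np.array([0, 1, 1, 1, 1, 1]) / 1
        expected = float((p_in - p_out).sum())
        assert scores.loc["S1", "S"] == pytest.approx(expected, abs=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(30)]
        df = pd.DataFrame(rng.normal(5, 2, size=(30, 4)).clip(0), index=genes)
        sets = [GeneSet("S", frozenset(genes[:8]))]
        base = subtypes.ssgsea(df, sets)
        shuffled = subtypes.ssgsea(df.sample(frac=1, random_state=1), sets)
        pd.testing.assert_frame_equal(base, shuffled)

    def test_small_intersection_raises(self):
        expr = toy_expression([1.0, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError, match="TINY"):
            subtypes.ssgsea(expr, [GeneSet("TINY", frozenset({"G0", "G1", "NOPE1", "NOPE2", "NOPE3"}))])

    def test_matches_literal_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        genes = [f"G{i}" for i in range(50)]
        for _ in range(10):
            values = rng.choice([0.0, 1, 2, 3, 4, 5], size=50)  # ties included
            inset = set(rng.choice(genes, size=12, replace=False))
            expr = toy_expression(list(values), genes)
            got = subtypes.ssgsea(expr, [GeneSet("S", frozenset(inset))], alpha=0.25)
            want = oracles.ssgsea_running_sum(genes, list(values), inset, 0.25)
            assert got.loc["S1", "S"] == pytest.approx(want, abs=1e-8)


class TestCallMspc:
    def scores(self):
        rng = np.random.default_rng(0)
        n = 40
        emt = rng.normal(0, 1, n)
        stem = rng.normal(0, 1, n)
        idx = [f"S{i}" for i in range(n)]
        return pd.DataFrame({"EMT": emt, "STEMNESS": stem}, index=idx)

    def test_double_quartile_rule(self):
        s = self.scores()
        both_high = (s["EMT"] >= s["EMT"].quantile(0.75)) & (
            s["STEMNESS"] >= s["STEMNESS"].quantile(0.75)
        )
        calls = subtypes.call_mspc(s)
        assert (calls == "MSPC").sum() == both_high.sum()
        one_high = (s["EMT"] >= s["EMT"].quantile(0.75)) & (
            s["STEMNESS"] < s["STEMNESS"].quantile(0.5)
        )
        assert (calls[one_high] == "unassigned").all()

    def test_label_map_takes_precedence(self):
        s = self.scores()
        top = s["EMT"].idxmax()
        calls = subtypes.call_mspc(s, {top: "ARPC"})
        assert calls[top] == "ARPC"
        with pytest.raises(ValueError, match="ARPC/NEPC"):
            subtypes.call_mspc(s, {top: "MSPC"})

    def test_every_sample_gets_exactly_one_label(self):
        calls = subtypes.call_mspc(self.scores())
        assert set(calls.index) == set(self.scores().index)
        assert calls.isin(["ARPC", "NEPC", "MSPC", "unassigned"]).all()


class TestMarkerCalls:
    def test_high_marker_wins(self):
        rng = np.random.default_rng(0)
        n = 50
        df = pd.DataFrame(
            rng.normal(2, 0.1, size=(3, n)),
            index=["AR", "SYP", "CD44"],
            columns=[f"C{i}" for i in range(n)],
        )
        df.loc["AR", "C0"] = 10.0
        calls = subtypes.call_subtype_markers(df)
        assert calls["C0"] == "ARPC"

    def test_all_markers_at_mean_is_unassigned(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 0.0], [1.0, 0.0, 2.0], [1.0, 2.0, 0.0]],
            index=["AR", "SYP", "CD44"],
            columns=["C_mid", "C_a", "C_b"],
        )
        calls = subtypes.call_subtype_markers(df)
        assert calls["C_mid"] == "unassigned"

    def test_missing_marker_raises(self):
        df = pd.DataFrame({"C0": [1.0]}, index=["AR"])
        with pytest.raises(KeyError, match="SYP"):
            subtypes.call_subtype_markers(df)


class TestLineage:
    def reference(self):
        genes = [f"G{i}" for i in range(12)]
        rng = np.random.default_rng(1)
        cells = {}
        labels = {}
        for t in ("luminal", "basal", "neuroendocrine"):
            profile = rng.normal(5, 2, 12).clip(0)
            cells[f"{t}_1"] = profile
            labels[f"{t}_1"] = t
        df = pd.DataFrame(cells, index=genes)
        return df, pd.Series(labels)

    def test_single_cell_pseudo_bulk_equals_the_cell(self):
        df, labels = self.reference()
        ref = subtypes.build_lineage_reference(df, labels, n_lineage_genes=12)
        np.testing.assert_allclose(ref.pseudo_bulk["basal"], df["basal_1"])

    def test_constant_gene_excluded_before_varying(self):
        df, labels = self.reference()
        df.loc["G0"] = 3.0  # constant across every cell type
        ref = subtypes.build_lineage_reference(df, labels, n_lineage_genes=11)
        assert "G0" not in ref.panel

    def test_panel_matches_hand_variance_sort(self):
        df, labels = self.reference()
        ref = subtypes.build_lineage_reference(df, labels, n_lineage_genes=3)
        pseudo = pd.DataFrame(
            {t: df[[c for c in df if labels[c] == t]].mean(axis=1) for t in sorted(set(labels))}
        )
        expected = pseudo.var(axis=1).sort_values(ascending=False).index[:3].tolist()
        assert ref.panel == expected

    def test_exact_match_assigns_with_rho_one(self):
        df, labels = self.reference()
        ref = subtypes.build_lineage_reference(df, labels, n_lineage_genes=12)
        lineage, rhos = subtypes.assign_lineage(df["basal_1"], ref)
        assert lineage == "basal"
        assert rhos["basal"] == pytest.approx(1.0)

    def test_constant_profile_raises(self):
        df, labels = self.reference()
        ref = subtypes.build_lineage_reference(df, labels, n_lineage_genes=12)
        with pytest.raises(ValueError, match="constant"):
            subtypes.assign_lineage(pd.Series(1.0, index=df.index), ref)

    def test_monotone_transform_invariance(self):
        df, labels = self.reference()
        ref = subtypes.build_lineage_reference(df, labels, n_lineage_genes=12)
        profile = df["luminal_1"] + np.random.default_rng(0).normal(0, 0.5, len(df))
        l1, r1 = subtypes.assign_lineage(profile, ref)
        l2, r2 = subtypes.assign_lineage(np.exp(profile / 2), ref)
        assert l1 == l2
        pd.testing.assert_series_equal(r1, r2)


class TestPc1Loadings:
    def test_planted_separating_features_dominate(self):
        rng = np.random.default_rng(0)
        n_feat, planted = 100, 10
        a = rng.normal(0, 0.1, size=(n_feat, 5))
        b = rng.normal(0, 0.1, size=(n_feat, 5))
        b[:planted] += 5.0  # separating block, higher in group B
        df = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"F{i}" for i in range(n_feat)],
            columns=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
        )
        top, loadings, scores = subtypes.pc1_top_loadings(
            df, planted, orient_toward=[f"B{i}" for i in range(5)]
        )
        assert set(top) == {f"F{i}" for i in range(planted)}
        assert scores[[f"B{i}" for i in range(5)]].mean() > 0

    def test_duplicate_columns_keep_pc1_direction(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame(
            rng.normal(size=(20, 4)), index=[f"F{i}" for i in range(20)],
            columns=list("abcd"),
        )
        dup = pd.concat([base, base.add_suffix("_2", axis=1)], axis=1)
        t1, l1, _ = subtypes.pc1_top_loadings(base, 5, orient_toward=["a"])
        t2, l2, _ = subtypes.pc1_top_loadings(dup, 5, orient_toward=["a"])
        assert abs(np.corrcoef(l1, l2)[0, 1]) > 0.999

    def test_too_few_columns_and_too_many_features(self):
        df = pd.DataFrame(np.eye(3), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            subtypes.pc1_top_loadings(df.iloc[:, :2], 2)
        with pytest.warns(UserWarning, match="exceeds"):
            top, _, _ = subtypes.pc1_top_loadings(df, 10)
        assert len(top) == 3


class TestOra:
    def test_disjoint_set_has_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        out = subtypes.ora_hypergeometric(
            universe[:5], [GeneSet("S", frozenset(universe[10:15]))], universe
        )
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_perfect_overlap_matches_enumeration(self):
        universe = [f"G{i}" for i in range(20)]
        gs = GeneSet("S", frozenset(universe[:5]))
        out = subtypes.ora_hypergeometric(universe[:5], [gs], universe)
        from math import comb

        assert out.loc[0, "p"] == pytest.approx(1 / comb(20, 5), abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(
            oracles.hypergeom_upper_tail(5, 20, 5, 5), abs=1e-12
        )

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            subtypes.ora_hypergeometric(["G1"], [GeneSet("S", frozenset({"G1"}))], [])
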