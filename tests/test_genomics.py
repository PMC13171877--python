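import numpy as np
import pandas as pd
import pytest

import oracles
from pcfidelity import genomics
from pcfidelity._stats import bh_adjust, rank_sum_test
from pcfidelity.core_io import MutationRecord, SampleAnnotation, Thresholds
from pcfidelity.core_io import CnvSegment, GeneModel


def ann_primary(n, prefix="P"):
    return [SampleAnnotation(f"{prefix}{i}", "primary", "primary") for i in range(n)]


def ann_met(n, site, prefix=None):
    prefix = prefix or site[0].upper()
    return [SampleAnnotation(f"{prefix}{i}", "metastatic", site) for i in range(n)]


# ---------------------------------------------------------------------------
# Mutation matrix
# ---------------------------------------------------------------------------


class TestMutationMatrix:
    def test_silent_flag_controls_qualification(self):
        records = [MutationRecord("G1", "S0", "Silent")]
        ann = ann_primary(1, "S")
        with_flag = genomics.mutation_matrix(records, ann, exclude_silent=True)
        assert with_flag.shape == (0, 1)
        without = genomics.mutation_matrix(records, ann, exclude_silent=False)
        assert without.loc["G1", "S0"] == 1

    def test_no_records_gives_all_zero_matrix(self):
        mat = genomics.mutation_matrix([], ann_primary(3, "S"))
        assert mat.shape == (0, 3)

    def test_unannotated_sample_raises(self):
        records = [MutationRecord("G1", "UNKNOWN", "Missense_Mutation")]
        with pytest.raises(ValueError, match="UNKNOWN"):
            genomics.mutation_matrix(records, ann_primary(2, "S"))

    def test_multiple_variants_binarize(self):
        records = [
            MutationRecord("G1", "S0", "Missense_Mutation", "p.A1B"),
            MutationRecord("G1", "S0", "Nonsense_Mutation", "p.C2*"),
        ]
        mat = genomics.mutation_matrix(records, ann_primary(1, "S"))
        assert mat.loc["G1", "S0"] == 1


# ---------------------------------------------------------------------------
# Fisher / BH
# ---------------------------------------------------------------------------


class TestFisherAndBh:
    def test_identical_margins_give_p_one(self):
        mat = pd.DataFrame(0, index=["G"], columns=[f"S{i}" for i in range(110)])
        p = genomics.fisher_gene_test(
            mat, [f"S{i}" for i in range(50)], [f"S{i}" for i in range(50, 110)], "G"
        )
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(5, 5, 0, 10), (10, 0, 0, 10), (3, 2, 1, 7)])
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        mat = pd.DataFrame(
            [[1] * a + [0] * b + [1] * c + [0] * d],
            index=["G"],
            columns=[f"S{i}" for i in range(a + b + c + d)],
        )
        ga = [f"S{i}" for i in range(a + b)]
        gb = [f"S{i}" for i in range(a + b, a + b + c + d)]
        assert genomics.fisher_gene_test(mat, ga, gb, "G") == pytest.approx(
            oracles.fisher_two_sided(a, b, c, d), abs=1e-10
        )

    def test_absent_gene_and_bad_groups(self):
        mat = pd.DataFrame(0, index=["G"], columns=["S0", "S1"])
        with pytest.raises(KeyError):
            genomics.fisher_gene_test(mat, ["S0"], ["S1"], "NOPE")
        with pytest.raises(ValueError, match="disjoint"):
            genomics.fisher_gene_test(mat, ["S0"], ["S0", "S1"], "G")

    def test_bh_hand_computed_vectors(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_bh_matches_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            adj = bh_adjust(p)
            np.testing.assert_allclose(adj, oracles.bh_step_up(p), atol=1e-12)
            # monotone in the input ranks: sorting by p sorts adj
            assert np.all(np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15)
            # re-adjustment never lowers a value and stays in [0, 1]
            again = bh_adjust(np.sort(adj))
            assert np.all(again >= np.sort(adj) - 1e-12)
            assert np.all(again <= 1.0 + 1e-12)
        # constant vectors are exact fixed points of the step-up
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


def toy_panel_cohort():
    """Two metastatic sites (20 each) vs 40 primaries with controlled freqs."""
    ann = ann_primary(40) + ann_met(20, "bone", "B") + ann_met(20, "liver", "L")
    samples = [a.sample for a in ann]
    mat = pd.DataFrame(0, index=["BOTH", "ONE", "FLAT"], columns=samples, dtype=np.int8)
    mat.loc["BOTH", [f"B{i}" for i in range(10)]] = 1
    mat.loc["BOTH", [f"L{i}" for i in range(10)]] = 1
    mat.loc["ONE", [f"B{i}" for i in range(10)]] = 1
    mat.loc["FLAT", [f"P{i}" for i in range(4)]] = 1
    mat.loc["FLAT", ["B0", "L0"]] = 1
    return mat, ann


class TestPanelSelection:
    def test_diff_requires_two_sites(self):
        mat, ann = toy_panel_cohort()
        table, diff = genomics.select_diff_genes(mat, ann)
        assert "BOTH" in diff  # significant in bone and liver
        assert "ONE" not in diff  # significant in bone only
        assert "FLAT" not in diff

    def test_diff_needs_multiple_sites(self):
        mat, _ = toy_panel_cohort()
        ann = ann_primary(40) + ann_met(20, "bone", "B")
        with pytest.raises(ValueError, match="two sites"):
            genomics.select_diff_genes(mat[[a.sample for a in ann]], ann)

    def test_high_gene_rule_is_strict(self):
        ann = ann_primary(5) + ann_met(40, "bone", "B") + ann_met(40, "liver", "L")
        samples = [a.sample for a in ann]
        mat = pd.DataFrame(0, index=["TWO", "ONESITE", "EDGE"], columns=samples, dtype=np.int8)
        # 3/40 = 0.075 in both sites: retained
        mat.loc["TWO", ["B0", "B1", "B2", "L0", "L1", "L2"]] = 1
        # 0.075 in one site only: dropped
        mat.loc["ONESITE", ["B0", "B1", "B2"]] = 1
        # exactly 2/40 = 0.05 in both sites: excluded by the strict inequality
        mat.loc["EDGE", ["B0", "B1", "L0", "L1"]] = 1
        high = genomics.select_high_genes(mat, ann)
        assert high == ["TWO"]


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


class TestRanking:
    def test_min_rank_ties(self):
        lines = [f"CL{i}" for i in range(5)]
        counts = {"CL0": 8, "CL1": 3, "CL2": 3, "CL3": 1, "CL4": 0}
        genes = [f"G{i}" for i in range(8)]
        mat = pd.DataFrame(0, index=genes, columns=lines, dtype=np.int8)
        for line, k in counts.items():
            mat.loc[genes[:k], line] = 1
        out = genomics.rank_by_panel(mat, genes, lines).set_index("model")
        assert out.loc[["CL0", "CL1", "CL2", "CL3", "CL4"], "rank"].tolist() == [1, 2, 2, 4, 5]

    def test_normalized_ratio_arithmetic_and_exclusion(self):
        counts = pd.Series({"A": 10, "B": 0, "C": 5})
        burden = pd.Series({"A": 200, "B": 50, "C": 0})
        with pytest.warns(UserWarning, match="zero-burden"):
            out = genomics.normalized_ratio(counts, burden).set_index("model")
        assert out.loc["A", "ratio"] == pytest.approx(0.05)
        assert out.loc["B", "ratio"] == 0.0
        assert "C" not in out.index

    def test_ratio_reorders_relative_to_raw_count(self):
        # A has more panel hits but a 10x burden; B wins on the ratio
        counts = pd.Series({"A": 20, "B": 10, "C": 1})
        burden = pd.Series({"A": 2000, "B": 200, "C": 100})
        raw_rank = counts.rank(method="min", ascending=False)
        out = genomics.normalized_ratio(counts, burden).set_index("model")
        assert raw_rank["A"] == 1
        assert out.loc["B", "rank"] == 1
        assert out.loc["A", "rank"] != 1


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


class TestHotspots:
    def test_recurrence_threshold_and_silent_exclusion(self):
        met = [f"M{i}" for i in range(6)]
        records = (
            [MutationRecord("AR", m, "Missense_Mutation", "p.T878A") for m in met[:3]]
            + [MutationRecord("TP53", m, "Missense_Mutation", "p.R175H") for m in met[:2]]
            + [MutationRecord("KRT5", m, "Silent", "p.X1X") for m in met[:5]]
        )
        catalog = genomics.find_hotspots(records, met)
        keys = catalog.keys()
        assert ("AR", "p.T878A") in keys
        assert ("TP53", "p.R175H") not in keys  # only two carriers
        assert all(g != "KRT5" for g, _ in keys)  # silent never qualifies

    def test_presence_is_exact_string_match(self):
        met = [f"M{i}" for i in range(3)]
        records = [MutationRecord("AR", m, "Missense_Mutation", "p.T878A") for m in met]
        catalog = genomics.find_hotspots(records, met)
        lines = ["CL1", "CL2"]
        line_records = [
            MutationRecord("AR", "CL1", "Missense_Mutation", "p.T878A"),
            MutationRecord("AR", "CL2", "Missense_Mutation", "p.L702H"),
        ]
        pres = genomics.hotspot_presence(catalog, line_records, lines)
        assert bool(pres.loc[("AR", "p.T878A"), "CL1"])
        assert not bool(pres.loc[("AR", "p.T878A"), "CL2"])

    def test_empty_catalog_gives_empty_matrix(self):
        catalog = genomics.find_hotspots([], ["M0"])
        pres = genomics.hotspot_presence(catalog, [], ["CL1"])
        assert pres.shape == (0, 1)


# ---------------------------------------------------------------------------
# Hypermutation
# ---------------------------------------------------------------------------


class TestHypermutation:
    def test_equal_burdens_raise_no_cutoff_flag(self):
        burdens = pd.Series(100, index=[f"S{i}" for i in range(30)])
        call = genomics.hypermutation_cutoff(burdens)
        assert call.no_cutoff
        assert call.hypermutated == []

    def test_hand_computed_gap_position(self):
        values = [5000, 4800, 4500] + [100 - i for i in range(27)]
        burdens = pd.Series(values, index=[f"S{i}" for i in range(30)])
        call = genomics.hypermutation_cutoff(burdens)
        assert not call.no_cutoff
        assert call.gap_index == 3  # largest log gap between ranks 3 and 4
        assert sorted(call.hypermutated) == ["S0", "S1", "S2"]
        assert all(burdens[s] > call.cutoff_burden for s in call.hypermutated)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        burdens = pd.Series(
            np.concatenate([rng.poisson(30, 40), rng.poisson(2000, 3)]).astype(float),
            index=[f"S{i}" for i in range(43)],
        )
        base = genomics.hypermutation_cutoff(burdens)
        for c in (7.0, 0.5, 1000.0):
            scaled = genomics.hypermutation_cutoff(burdens * c)
            assert scaled.hypermutated == base.hypermutated
            assert scaled.no_cutoff == base.no_cutoff

    def test_requires_twenty_positive_burdens(self):
        with pytest.raises(ValueError, match="20"):
            genomics.hypermutation_cutoff(pd.Series([5.0] * 10))


class TestMmr:
    def test_identical_groups_p_one(self):
        mat = pd.DataFrame(
            1, index=["MLH1", "MSH2"], columns=[f"S{i}" for i in range(10)], dtype=np.int8
        )
        _, p = genomics.mmr_comparison(
            mat, ["MLH1", "MSH2"], [f"S{i}" for i in range(5)], [f"S{i}" for i in range(5, 10)]
        )
        assert p == pytest.approx(1.0)

    def test_empty_gene_list_raises(self):
        mat = pd.DataFrame(0, index=["G"], columns=["S0", "S1"])
        with pytest.raises(ValueError, match="empty"):
            genomics.mmr_comparison(mat, [], ["S0"], ["S1"])
        with pytest.raises(ValueError, match="none of"):
            genomics.mmr_comparison(mat, ["MLH1"], ["S0"], ["S1"])


# ---------------------------------------------------------------------------
# CNV
# ---------------------------------------------------------------------------


class TestCnv:
    def test_overlap_weighted_mean(self):
        gene_inside = GeneModel("A", "chr1", 100, 200)
        gene_split = GeneModel("B", "chr1", 950, 1050)
        gene_orphan = GeneModel("C", "chr2", 0, 100)
        segs = [
            CnvSegment("S1", "chr1", 0, 1000, 0.8),
            CnvSegment("S1", "chr1", 1000, 2000, 0.0),
        ]
        out = genomics.segments_to_gene_cnv(segs, [gene_inside, gene_split, gene_orphan])
        assert out.loc["A", "S1"] == pytest.approx(0.8)
        # half in a 0.8... no: B is half in value-0.8, half in value-0 segments
        assert out.loc["B", "S1"] == pytest.approx(0.4)
        assert np.isnan(out.loc["C", "S1"])

    def test_half_half_weighted_mean_unit_values(self):
        gene = GeneModel("B", "chr1", 950, 1050)
        segs = [
            CnvSegment("S1", "chr1", 0, 1000, 1.0),
            CnvSegment("S1", "chr1", 1000, 2000, 0.0),
        ]
        out = genomics.segments_to_gene_cnv(segs, [gene])
        assert out.loc["B", "S1"] == pytest.approx(0.5)

    def test_identical_cohorts_yield_no_significant_genes(self):
        rng = np.random.default_rng(0)
        ann = ann_primary(20) + ann_met(20, "bone", "M")
        vals = rng.normal(0, 0.1, size=(30, 40))
        cnv = pd.DataFrame(vals, index=[f"G{i}" for i in range(30)],
                           columns=[a.sample for a in ann])
        out = genomics.differential_cnv(cnv, ann)
        assert not out["significant"].any()

    def test_significance_requires_both_conditions(self):
        # large delta but tiny n: rank-sum p cannot reach significance
        ann = ann_primary(3) + ann_met(3, "bone", "M")
        cnv = pd.DataFrame(
            [[0.0, 0.01, -0.01, 0.4, 0.41, 0.39]],
            index=["G"],
            columns=[a.sample for a in ann],
        )
        out = genomics.differential_cnv(cnv, ann)
        assert out.loc[0, "delta"] == pytest.approx(0.4, abs=0.02)
        assert not out.loc[0, "significant"]


def test_rank_sum_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 7))
        a = rng.integers(0, 4, n1).astype(float)  # heavy ties
        b = rng.integers(0, 4, n2).astype(float)
        assert rank_sum_test(a, b) == pytest.approx(
            oracles.rank_sum_two_sided(a, b), abs=1e-10
        )
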