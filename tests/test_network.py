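"""The DC statistic and its gates: Spearman, BH, Fisher r-to-z, calling,
classification, DE accounting. The Fisher z closed form is checked against
an independently coded high-precision (mpmath, 60 digits) evaluation."""

import mpmath
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from interdc.datatypes import ValidationError
from interdc.network import (
    DCNetwork,
    InterRegionDCAnalysis,
    bh_adjust,
    call_dc_edges,
    classify_dc_edge,
    correlated_pair_universe,
    fisher_z_dc_test,
    flag_de_driven,
    spearman_rho,
    wilcoxon_de,
)
from synthcases import make_paired


def oracle_fisher_z(rho1, n1, rho2, n2):
    """High-precision independent evaluation of the DC z-score."""
    with mpmath.workdps(60):
        z = (mpmath.atanh(rho2) - mpmath.atanh(rho1)) / mpmath.sqrt(
            mpmath.mpf(1) / (n2 - 3) + mpmath.mpf(1) / (n1 - 3)
        )
        return float(z)


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
            ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], 0.8),  # 1 - 6*4/(5*24)
        ],
    )
    def test_hand_examples(self, x, y, expected):
        rho, p = spearman_rho(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)
        if abs(expected) == 1.0:
            assert p == 0.0

    def test_matches_scipy_with_ties(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, 30).astype(float)  # heavy ties
        y = rng.integers(0, 5, 30).astype(float)
        rho, p = spearman_rho(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_variance_flagged_nan(self):
        rho, p = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError, match="4"):
            spearman_rho([1, 2, 3], [1, 2, 3])


class TestBH:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_equal_inputs_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_at_least_p_and_order_preserving(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)
        # order preserved w.r.t. input index
        assert len(q) == len(pvals)


class TestFisherZ:
    def test_identical_correlations_give_zero(self):
        z, p = fisher_z_dc_test(0.6, 100, 0.6, 80)
        assert z == 0.0 and p == 1.0

    def test_cohort_scale_example(self):
        # rho 0 -> 0.5 at the 372-CTL / 264-AD cohort sizes
        z, _ = fisher_z_dc_test(0.0, 372, 0.5, 264)
        assert z == pytest.approx(6.79, abs=0.01)
        assert z == pytest.approx(oracle_fisher_z(0.0, 372, 0.5, 264), abs=1e-10)

    def test_oracle_equivalence_on_random_tuples(self):
        rng = np.random.default_rng(42)
        rho1 = rng.uniform(-0.99, 0.99, 1000)
        rho2 = rng.uniform(-0.99, 0.99, 1000)
        n1 = rng.integers(5, 2000, 1000)
        n2 = rng.integers(5, 2000, 1000)
        z, _ = fisher_z_dc_test(rho1, n1, rho2, n2)
        worst = max(
            abs(z[i] - oracle_fisher_z(rho1[i], n1[i], rho2[i], n2[i]))
            for i in range(1000)
        )
        assert worst < 1e-10

    @given(
        st.floats(-0.99, 0.99), st.floats(-0.99, 0.99),
        st.integers(4, 1000), st.integers(4, 1000),
    )
    def test_antisymmetry_under_group_swap(self, r1, r2, n1, n2):
        z_fwd, _ = fisher_z_dc_test(r1, n1, r2, n2)
        z_rev, _ = fisher_z_dc_test(r2, n2, r1, n1)
        assert z_fwd == pytest.approx(-z_rev, abs=1e-12)

    def test_monotone_in_correlation_gap(self):
        gaps = [0.1, 0.3, 0.5, 0.7]
        zs = [abs(fisher_z_dc_test(0.0, 150, g, 150)[0]) for g in gaps]
        assert zs == sorted(zs)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValidationError, match="3"):
            fisher_z_dc_test(0.1, 3, 0.2, 100)

    def test_perfect_correlation_clamped(self):
        z, p = fisher_z_dc_test(0.0, 100, 1.0, 100)
        assert np.isfinite(z) and 0 <= p <= 1


class TestClassification:
    @pytest.mark.parametrize(
        "rho_ctl,rho_ad,category,cls",
        [
            (0.05, 0.6, "PG", "PG"),
            (0.0, -0.6, "NG", "NG"),
            (0.55, 0.02, "LC_pos", "LC"),
            (-0.55, -0.02, "LC_neg", "LC"),
        ],
    )
    def test_four_category_rule(self, rho_ctl, rho_ad, category, cls):
        from interdc.network import CATEGORY_TO_CLASS

        assert classify_dc_edge(rho_ctl, rho_ad) == category
        assert CATEGORY_TO_CLASS[category] == cls


def monotone_pair_cohort():
    """Tiny paired dataset with controlled cross-region structure.

    Gene A000/B000 correlate strongly in CTL only; A001/B001 in AD only;
    remaining genes are independent noise.
    """
    rng = np.random.default_rng(123)
    n_ctl, n_ad = 60, 60
    n = n_ctl + n_ad
    base_ctl = rng.normal(size=n_ctl)
    base_ad = rng.normal(size=n_ad)
    mat1 = rng.normal(size=(4, n))
    mat2 = rng.normal(size=(4, n))
    mat1[0, :n_ctl] = base_ctl
    mat2[0, :n_ctl] = base_ctl + rng.normal(0, 0.2, n_ctl)
    mat1[1, n_ctl:] = base_ad
    mat2[1, n_ctl:] = base_ad + rng.normal(0, 0.2, n_ad)
    return make_paired(mat1, mat2, n_ctl)


class TestUniverse:
    def test_union_rule_and_gates(self):
        paired = monotone_pair_cohort()
        uni = correlated_pair_universe(paired)
        pairs = set(zip(uni["gene_a"], uni["gene_b"]))
        assert ("A000", "B000") in pairs  # via CTL side
        assert ("A001", "B001") in pairs  # via AD side
        row = uni.set_index(["gene_a", "gene_b"]).loc[("A000", "B000")]
        assert row["correlated_ctl"] and not row["correlated_ad"]
        # flags equal the two-criterion definition
        recomputed = (uni["q_ctl"] <= 0.01) & (uni["rho_ctl"].abs() >= 0.4)
        assert (uni["correlated_ctl"] == recomputed).all()
        assert (uni["q_ctl"] >= uni["p_ctl"] - 1e-15).all()

    def test_block_size_independence(self):
        paired = monotone_pair_cohort()
        uni_small = correlated_pair_universe(paired, block_size=1)
        uni_big = correlated_pair_universe(paired, block_size=512)
        pd.testing.assert_frame_equal(uni_small, uni_big)

    def test_zero_variance_gene_excluded(self):
        rng = np.random.default_rng(5)
        mat1 = rng.normal(size=(3, 40))
        mat2 = rng.normal(size=(3, 40))
        mat1[2] = 7.0  # constant gene
        paired = make_paired(mat1, mat2, 20)
        uni = correlated_pair_universe(paired, fdr_corr=1.0, rho_min=0.0)
        assert "A002" not in set(uni["gene_a"])
        # the rest of the grid is intact: 2 x 3 pairs at fully open gates
        assert len(uni) == 6

    def test_tiny_group_rejected(self):
        rng = np.random.default_rng(6)
        paired = make_paired(rng.normal(size=(2, 10)), rng.normal(size=(2, 10)), 3)
        with pytest.raises(ValidationError, match="fewer than 4"):
            correlated_pair_universe(paired)


class TestCallEdges:
    def test_equal_correlations_give_no_edges(self):
        uni = pd.DataFrame(
            {
                "gene_a": ["a", "b"], "gene_b": ["x", "y"],
                "rho_ctl": [0.6, -0.5], "rho_ad": [0.6, -0.5],
                "n_ctl": 100, "n_ad": 100,
            }
        )
        net = call_dc_edges(uni)
        assert len(net.edges) == 0
        assert net.dysregulation_percentage == 0.0

    def test_dysregulation_percentage_definition(self):
        edges = pd.DataFrame({"gene_a": [f"g{i}" for i in range(14)],
                              "gene_b": [f"h{i}" for i in range(14)]})
        net = DCNetwork(edges=edges, tested_pair_count=100, region_pair=("BR1", "BR2"))
        assert net.dysregulation_percentage == pytest.approx(14.0)

    def test_rewired_pairs_called_and_classified(self):
        paired = monotone_pair_cohort()
        est = InterRegionDCAnalysis().fit(paired)
        edges = est.network_.edges.set_index(["gene_a", "gene_b"])
        assert ("A000", "B000") in edges.index
        assert ("A001", "B001") in edges.index
        assert edges.loc[("A000", "B000"), "dc_class"] == "LC"
        assert edges.loc[("A000", "B000"), "z"] < 0
        assert edges.loc[("A001", "B001"), "category"] == "PG"
        assert edges.loc[("A001", "B001"), "z"] > 0
        assert est.dysregulation_percentage_ == pytest.approx(
            100 * len(est.network_.edges) / est.tested_pair_count_
        )

    def test_group_swap_negates_z(self):
        paired = monotone_pair_cohort()
        swapped = make_paired(
            np.hstack([paired.br1.expr.to_numpy()[:, 60:], paired.br1.expr.to_numpy()[:, :60]]),
            np.hstack([paired.br2.expr.to_numpy()[:, 60:], paired.br2.expr.to_numpy()[:, :60]]),
            60,
        )
        uni = correlated_pair_universe(paired).set_index(["gene_a", "gene_b"])
        uni_sw = correlated_pair_universe(swapped).set_index(["gene_a", "gene_b"])
        common = uni.index.intersection(uni_sw.index)
        assert len(common) >= 2
        for pair in common:
            z1, _ = fisher_z_dc_test(uni.loc[pair, "rho_ctl"], 60, uni.loc[pair, "rho_ad"], 60)
            z2, _ = fisher_z_dc_test(uni_sw.loc[pair, "rho_ctl"], 60, uni_sw.loc[pair, "rho_ad"], 60)
            assert z1 == pytest.approx(-z2, abs=1e-10)


class TestWilcoxonDE:
    def test_exact_small_sample_p(self):
        expr = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g"],
                            columns=[f"S{i}" for i in range(6)])
        groups = np.array(["CTL"] * 3 + ["AD"] * 3)
        out = wilcoxon_de(expr, groups)
        assert out.loc[0, "p"] == pytest.approx(0.1, abs=1e-12)

    def test_null_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(1000, 200)),
                            index=[f"g{i}" for i in range(1000)],
                            columns=[f"S{i}" for i in range(200)])
        groups = np.array(["CTL"] * 100 + ["AD"] * 100)
        out = wilcoxon_de(expr, groups)
        assert abs((out["p"] < 0.05).mean() - 0.05) < 0.02

    def test_constant_gene_flagged(self):
        expr = pd.DataFrame([[5.0] * 10, list(range(10))], index=["c", "g"],
                            columns=[f"S{i}" for i in range(10)])
        groups = np.array(["CTL"] * 5 + ["AD"] * 5)
        out = wilcoxon_de(expr, groups).set_index("gene")
        assert out.loc["c", "constant"] and out.loc["c", "p"] == 1.0
        assert not out.loc["g", "constant"]

    def test_small_group_rejected(self):
        expr = pd.DataFrame([[1, 2, 3, 4]], index=["g"], columns=list("wxyz"))
        with pytest.raises(ValidationError, match="3 samples"):
            wilcoxon_de(expr, np.array(["CTL", "CTL", "AD", "AD"]))


class TestDEDriven:
    def make_net(self, n_edges=10):
        edges = pd.DataFrame({
            "gene_a": [f"g{i}" for i in range(n_edges)],
            "gene_b": [f"h{i}" for i in range(n_edges)],
        })
        return DCNetwork(edges=edges, tested_pair_count=50, region_pair=("R1", "R2"))

    def test_either_side_counts(self):
        net, pct = flag_de_driven(self.make_net(), {"R1": {"g0"}, "R2": {"h1", "h2"}})
        assert net.edges["de_driven"].tolist()[:4] == [True, True, True, False]
        assert pct == pytest.approx(30.0)

    def test_empty_de_sets_give_zero(self):
        _, pct = flag_de_driven(self.make_net(), {})
        assert pct == 0.0

    def test_wrong_region_does_not_count(self):
        net, _ = flag_de_driven(self.make_net(), {"R1": {"h0"}, "R2": {"g0"}})
        assert not net.edges["de_driven"].any()
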