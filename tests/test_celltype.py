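"""Surrogate proportion variables must track true composition and, once
regressed out, remove composition-driven structure from the matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from interdc.celltype import (
    CellTypeCorrector,
    MarkerSet,
    correct_cell_types,
    estimate_spvs,
    filter_robust_markers,
    select_marker_model,
    validate_marker_sets,
)
from interdc.datatypes import ValidationError


def dirichlet_mixture(n_types=4, n_markers=20, n_samples=300, loading=5.0,
                      noise=1.0, seed=0):
    """Markers loading on standardized Dirichlet proportions, plus noise."""
    rng = np.random.default_rng(seed)
    props = rng.dirichlet([8, 4, 2, 2][:n_types], size=n_samples).T
    w = (props - props.mean(axis=1, keepdims=True)) / props.std(axis=1, keepdims=True)
    rows, genes, sets = [], [], []
    for t in range(n_types):
        ids = [f"CT{t+1}_M{j:02d}" for j in range(n_markers)]
        genes += ids
        sets.append(MarkerSet(f"CT{t+1}", ids))
        for _ in ids:
            rows.append(loading * w[t] + rng.normal(0, noise, n_samples))
    expr = pd.DataFrame(rows, index=genes,
                        columns=[f"S{i:03d}" for i in range(n_samples)])
    groups = np.array(["CTL"] * (n_samples // 2) + ["AD"] * (n_samples - n_samples // 2))
    return expr, props, sets, groups


class TestRobustMarkerFilter:
    def test_null_markers_retained_at_one_minus_alpha(self):
        rng = np.random.default_rng(0)
        n_markers, n = 400, 200
        expr = pd.DataFrame(rng.normal(size=(n_markers, n)),
                            index=[f"M{i}" for i in range(n_markers)],
                            columns=[f"S{i}" for i in range(n)])
        groups = np.array(["CTL"] * 100 + ["AD"] * 100)
        kept = filter_robust_markers(expr, MarkerSet("CT1", list(expr.index)), groups, alpha=0.05)
        frac = len(kept) / n_markers
        assert abs(frac - 0.95) < 0.04  # binomial sd ~ 0.011

    def test_strongly_de_marker_removed(self):
        rng = np.random.default_rng(1)
        n = 200
        null = rng.normal(size=(5, n))
        de = rng.normal(size=n) + 2.0 * (np.arange(n) >= 100)
        expr = pd.DataFrame(np.vstack([null, de]),
                            index=[f"M{i}" for i in range(6)],
                            columns=[f"S{i}" for i in range(n)])
        groups = np.array(["CTL"] * 100 + ["AD"] * 100)
        kept = filter_robust_markers(expr, MarkerSet("CT1", list(expr.index)), groups)
        assert "M5" not in kept

    def test_single_group_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(2).normal(size=(4, 20)),
                            index=list("ABCD"), columns=[f"S{i}" for i in range(20)])
        with pytest.raises(ValidationError, match="two groups"):
            filter_robust_markers(expr, MarkerSet("CT1", list("ABCD")),
                                  np.repeat("CTL", 20))

    def test_overlapping_marker_sets_rejected(self):
        with pytest.raises(ValidationError, match="assigned to both"):
            validate_marker_sets([MarkerSet("CT1", ["A", "B"]), MarkerSet("CT2", ["B"])])


class TestSPVEstimation:
    def test_spv_tracks_true_proportions(self):
        expr, props, sets, groups = dirichlet_mixture()
        model = estimate_spvs(expr, sets, groups)
        for t in range(4):
            rho = spearmanr(model.spvs.loc[f"CT{t+1}"].to_numpy(), props[t]).statistic
            assert abs(rho) >= 0.9, f"CT{t+1}: {rho}"

    def test_exact_rank_one_recovery(self):
        # markers that are exact copies of one proportion vector
        rng = np.random.default_rng(3)
        v = rng.dirichlet([4, 4], size=100).T[0]
        expr = pd.DataFrame([v * s for s in (1.0, 2.0, 5.0)], index=list("ABC"),
                            columns=[f"S{i}" for i in range(100)])
        groups = np.array(["CTL"] * 50 + ["AD"] * 50)
        model = estimate_spvs(expr, [MarkerSet("CT1", list("ABC"))], groups, alpha=0.0)
        r = np.corrcoef(model.spvs.loc["CT1"].to_numpy(), v)[0, 1]
        assert abs(r - 1.0) < 1e-8

    def test_spv_unit_norm_and_positive_orientation(self):
        expr, _, sets, groups = dirichlet_mixture(seed=4)
        model = estimate_spvs(expr, sets, groups)
        for ct in model.spvs.index:
            spv = model.spvs.loc[ct].to_numpy()
            assert abs(np.linalg.norm(spv) - 1.0) < 1e-12
            sub = expr.loc[model.robust_markers[ct]].to_numpy()
            corr = np.mean([np.corrcoef(row, spv)[0, 1] for row in sub])
            assert corr > 0

    def test_too_few_markers_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(5).normal(size=(2, 30)),
                            index=["A", "B"], columns=[f"S{i}" for i in range(30)])
        groups = np.array(["CTL"] * 15 + ["AD"] * 15)
        with pytest.raises(ValidationError, match="3"):
            estimate_spvs(expr, [MarkerSet("CT1", ["A", "B"])], groups, alpha=0.0)

    def test_monotone_in_loading_strength(self):
        scores = []
        for loading in (0.5, 2.0, 5.0):
            expr, props, sets, groups = dirichlet_mixture(loading=loading, seed=6)
            model = estimate_spvs(expr, sets, groups)
            scores.append(abs(spearmanr(model.spvs.loc["CT1"], props[0]).statistic))
        assert scores[0] <= scores[1] <= scores[2]


class TestModelSelection:
    def test_informative_top_markers_selected(self):
        # only the top 20 markers carry signal; beyond that, pure noise
        rng = np.random.default_rng(7)
        n = 200
        props = rng.dirichlet([5, 5], size=n).T
        w = (props - props.mean(axis=1, keepdims=True)) / props.std(axis=1, keepdims=True)
        ranked = {}
        rows, idx = [], []
        for t in range(2):
            ids = [f"CT{t+1}_M{j:03d}" for j in range(60)]
            ranked[f"CT{t+1}"] = ids
            for j, g in enumerate(ids):
                signal = 5.0 * w[t] if j < 20 else 0.0
                rows.append(signal + rng.normal(0, 1, n))
            idx += ids
        expr = pd.DataFrame(rows, index=idx, columns=[f"S{i}" for i in range(n)])
        groups = np.array(["CTL"] * 100 + ["AD"] * 100)
        truth = pd.Series(props[0], index=expr.columns)
        best = select_marker_model(expr, ranked, [20, 40, 60], truth, groups, "CT1")
        assert best == 20

    def test_tie_breaks_to_smaller_size(self):
        # noise-free rank-1 markers: every candidate is equivalent
        rng = np.random.default_rng(8)
        v = rng.dirichlet([4, 4], size=150).T[0]
        ids = [f"M{j}" for j in range(40)]
        expr = pd.DataFrame([v * (j + 1) for j in range(40)], index=ids,
                            columns=[f"S{i}" for i in range(150)])
        groups = np.array(["CTL"] * 75 + ["AD"] * 75)
        truth = pd.Series(v, index=expr.columns)
        best = select_marker_model(expr, {"CT1": ids}, [10, 20, 40], truth, groups,
                                   "CT1", alpha=0.0)
        assert best == 10


class TestCorrection:
    def test_linear_combination_of_spvs_reduced_to_constant(self):
        expr, _, sets, groups = dirichlet_mixture(seed=9)
        model = estimate_spvs(expr, sets, groups)
        combo = 2.0 * model.spvs.iloc[0] - 1.5 * model.spvs.iloc[2] + 7.0
        target = pd.DataFrame([combo.to_numpy()], index=["COMBO"], columns=expr.columns)
        corrected = correct_cell_types(target, model)
        assert corrected.to_numpy().var() < 1e-12
        # mean preserved
        assert abs(corrected.to_numpy().mean() - combo.mean()) < 1e-9

    def test_zero_spvs_is_identity(self):
        expr = pd.DataFrame(np.random.default_rng(10).normal(size=(4, 20)),
                            index=list("ABCD"), columns=[f"S{i}" for i in range(20)])
        pd.testing.assert_frame_equal(correct_cell_types(expr, None), expr)

    def test_idempotent_given_same_spvs(self):
        expr, _, sets, groups = dirichlet_mixture(seed=11)
        model = estimate_spvs(expr, sets, groups)
        once = correct_cell_types(expr, model)
        twice = correct_cell_types(once, model)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-8)

    def test_sklearn_transformer_roundtrip(self):
        expr, props, sets, groups = dirichlet_mixture(seed=12)
        ct = CellTypeCorrector(marker_sets=sets, alpha=0.0).fit(expr.T, groups)
        out = ct.transform(expr.T)
        assert out.shape == expr.T.shape
        assert set(ct.get_params()) == {"marker_sets", "alpha"}
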