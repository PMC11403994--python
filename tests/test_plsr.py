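"""Excess-phosphorylation correction, NIPALS PLSR and VIP scoring."""
import numpy as np
import pandas as pd
import pytest

from sizescale import (
    PhosphoPanel,
    PLSRModel,
    compute_vip,
    correct_phospho,
    fit_plsr,
    generate_phospho_panel,
    select_components,
    select_hits,
)
from sizescale.errors import DomainError, InputError


def _panel_from_arrays(phospho, total, response=None):
    phospho = np.asarray(phospho, dtype=float)
    lines = [f"l{i}" for i in range(phospho.shape[0])]
    peps = [f"p{j}" for j in range(phospho.shape[1])]
    response = (
        pd.Series(np.arange(len(lines), dtype=float) + 1, index=lines)
        if response is None
        else pd.Series(response, index=lines)
    )
    return PhosphoPanel(
        phospho=pd.DataFrame(phospho, index=lines, columns=peps),
        total=pd.DataFrame(np.asarray(total, dtype=float), index=lines, columns=peps),
        response=response,
        peptide_info=pd.DataFrame(index=peps),
    )


class TestCorrection:
    def test_hand_ols_worked_example(self):
        # totals (1,2,3), phospho (1.1, 1.9, 3.2):
        # slope 1.05, intercept -1/30, residuals (1/12, -1/6, 1/12)
        panel = _panel_from_arrays([[1.1], [1.9], [3.2]], [[1.0], [2.0], [3.0]])
        out = correct_phospho(panel, scale="none")
        assert out.slopes.iloc[0] == pytest.approx(1.05, abs=1e-12)
        assert out.intercepts.iloc[0] == pytest.approx(-1.0 / 30.0, abs=1e-12)
        np.testing.assert_allclose(
            out.residuals.iloc[:, 0], [1.0 / 12, -1.0 / 6, 1.0 / 12], atol=1e-12
        )

    def test_perfect_proportionality_gives_zero_residuals(self):
        total = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        panel = _panel_from_arrays(2.0 * total, total)
        for scale in ("zscore", "none"):
            out = correct_phospho(panel, scale=scale)
            np.testing.assert_allclose(out.residuals, 0.0, atol=1e-12)

    def test_row_offset_absorbed_by_intercept(self):
        total = np.array([[1.0], [2.0], [3.0], [4.0]])
        phospho = np.array([[1.1], [1.9], [3.2], [3.9]])
        r1 = correct_phospho(_panel_from_arrays(phospho, total), scale="none").residuals
        r2 = correct_phospho(_panel_from_arrays(phospho + 5.0, total), scale="none").residuals
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_ols_orthogonality(self, default_panel):
        out = correct_phospho(default_panel)
        resid = out.residuals.to_numpy()
        np.testing.assert_allclose(resid.sum(axis=0), 0.0, atol=1e-9)
        t = default_panel.total.to_numpy()
        tc = t - t.mean(axis=0)
        rc = resid - resid.mean(axis=0)
        num = (tc * rc).sum(axis=0)
        denom = np.sqrt((tc**2).sum(axis=0) * (rc**2).sum(axis=0))
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        np.testing.assert_allclose(corr, 0.0, atol=1e-9)

    def test_zero_variance_total_flagged(self):
        total = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        phospho = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correct_phospho(_panel_from_arrays(phospho, total), scale="none")
        assert out.flagged == ["p0"]
        np.testing.assert_allclose(out.residuals["p0"], [-1.0, 0.0, 1.0], atol=1e-12)


class TestComponentSelection:
    def test_rank_one_design_selects_one(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(8)
        X = np.outer(t, rng.standard_normal(5))
        sel = select_components(X, 2.0 * t, folds=10, seed=0)
        assert sel.n_components == 1

    def test_pure_noise_majority_one_component_low_signal(self):
        picks, low = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((10, 15))
            y = rng.standard_normal(10)
            sel = select_components(X, y, folds=10, seed=seed)
            picks.append(sel.n_components)
            low.append(sel.low_signal)
        assert np.median(picks) == 1
        assert sum(low) > 10

    def test_folds_capped_at_sample_count(self, default_panel):
        corrected = correct_phospho(default_panel)
        sel = select_components(corrected.residuals, default_panel.response, folds=10, seed=0)
        assert sel.folds_used == 8

    def test_bad_max_components(self):
        with pytest.raises(InputError):
            select_components(np.zeros((5, 3)), np.zeros(5), max_components=0)


class TestFitPLSR:
    def test_single_perfect_predictor_exact(self):
        x = np.linspace(-2, 2, 9)[:, None]
        y = 3.0 * x.ravel() + 1.0
        model = fit_plsr(x, y, 1)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-9)
        assert model.n_components == 1

    def test_matches_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 6))
        y = X @ rng.standard_normal(6) + 0.2 * rng.standard_normal(12)
        mine = fit_plsr(X, y, 3)
        ref = PLSRegression(n_components=3, scale=True).fit(X, y)
        np.testing.assert_allclose(mine.predict(X), ref.predict(X).ravel(), atol=1e-9)
        np.testing.assert_allclose(
            np.abs(mine.weights), np.abs(ref.x_weights_), atol=1e-9
        )

    def test_unit_norm_weights_and_nonneg_ssy(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 7))
        y = rng.standard_normal(10)
        model = fit_plsr(X, y, 4)
        np.testing.assert_allclose(
            np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-12
        )
        assert (model.ssy >= 0).all()
        assert model.ssy_total == pytest.approx(model.ssy.sum())

    def test_training_mse_nonincreasing_in_components(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 8))
        y = X @ rng.standard_normal(8) + rng.standard_normal(15)
        mses = [fit_plsr(X, y, f).training_mse(X, y) for f in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(mses, mses[1:]))

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(6)
        t = rng.standard_normal(6)
        X = np.outer(t, rng.standard_normal(4))  # rank 1
        with pytest.warns(UserWarning, match="truncated"):
            model = fit_plsr(X, 2 * t, 3)
        assert model.n_components < 3


def _manual_model(weights, ssy):
    weights = np.asarray(weights, dtype=float)
    j, f = weights.shape
    return PLSRModel(
        n_components=f,
        weights=weights,
        x_loadings=weights,
        y_loadings=np.ones(f),
        scores=np.zeros((1, f)),
        ssy=np.asarray(ssy, dtype=float),
        x_mean=np.zeros(j),
        x_std=np.ones(j),
        y_mean=0.0,
        y_std=1.0,
        feature_names=[f"p{i}" for i in range(j)],
    )


class TestVIP:
    def test_single_variable_forced_to_one(self):
        x = np.linspace(1, 5, 6)[:, None]
        model = fit_plsr(x, 2 * x.ravel() + np.r_[0.1, -0.1, 0.2, -0.2, 0.0, 0.0], 1)
        vip = compute_vip(model)
        assert vip["vip"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_component_worked_example(self):
        # J=2, w=(0.8, 0.6): VIP = (sqrt(2*0.64), sqrt(2*0.36)); SSY cancels
        model = _manual_model([[0.8], [0.6]], [3.7])
        vip = compute_vip(model)["vip"].to_numpy()
        np.testing.assert_allclose(vip, [np.sqrt(1.28), np.sqrt(0.72)], atol=1e-12)

    def test_equal_weights_all_one(self):
        w = np.full((4, 2), 0.5) * np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]])
        model = _manual_model(w, [2.0, 1.0])
        np.testing.assert_allclose(compute_vip(model)["vip"], 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sum_of_squares_equals_j(self, seed):
        panel = generate_phospho_panel(seed=seed, n_peptides=60, n_informative=5)
        corrected = correct_phospho(panel)
        model = fit_plsr(corrected.residuals, panel.response, 3)
        vip = compute_vip(model)["vip"].to_numpy()
        assert (vip**2).sum() == pytest.approx(60.0, abs=1e-9)

    def test_zero_ssy_rejected(self):
        model = _manual_model([[1.0]], [0.0])
        with pytest.raises(DomainError):
            compute_vip(model)

    def test_column_scaling_leaves_vip_unchanged(self, default_panel):
        def vips(panel):
            corrected = correct_phospho(panel)
            model = fit_plsr(corrected.residuals, panel.response, 2)
            return compute_vip(model)["vip"]

        base = vips(default_panel)
        scaled = PhosphoPanel(
            phospho=default_panel.phospho.assign(
                pep0003=default_panel.phospho["pep0003"] * 7.0
            ),
            total=default_panel.total,
            response=default_panel.response,
            peptide_info=default_panel.peptide_info,
        )
        np.testing.assert_allclose(vips(scaled), base, atol=1e-9)


class TestHitSelection:
    def test_boundary_is_strict(self):
        table = pd.DataFrame({"vip": [1.0, 1.0], "hit": [False, False], "sign": [1, -1]})
        assert len(select_hits(table)) == 0

    def test_threshold_zero_returns_all_ranked(self):
        table = pd.DataFrame({"vip": [0.5, 2.0, 1.2], "hit": [0, 1, 1], "sign": [1, 1, -1]})
        hits = select_hits(table, threshold=0.0)
        assert list(hits["vip"]) == [2.0, 1.2, 0.5]
        assert list(hits["rank"]) == [1, 2, 3]
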