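import itertools

import numpy as np
import pytest

from fwsolv.freewilson import (
    DEFAULT_ALPHA_GRID,
    FWModel,
    coefficient_report,
    fit,
    loo_errors,
    predict,
)
from fwsolv.rgroups import DesignMatrix

from conftest import ALPHA_GRID


def _toy_design(pool_sizes=(3, 2)):
    """Fully-enumerated one-hot design over the given per-site pool sizes."""
    sites = range(1, len(pool_sizes) + 1)
    columns = [
        (site, f"*G{site}{j}") for site, n in zip(sites, pool_sizes) for j in range(n)
    ]
    offsets = np.cumsum([0, *pool_sizes[:-1]])
    combos = list(itertools.product(*(range(n) for n in pool_sizes)))
    X = np.zeros((len(combos), sum(pool_sizes)), dtype=np.int8)
    for i, combo in enumerate(combos):
        for off, j in zip(offsets, combo):
            X[i, off + j] = 1
    return (
        DesignMatrix(X=X, column_index=columns, ligand_ids=[str(i) for i in range(len(combos))]),
        combos,
        offsets,
    )


class TestFit:
    def test_noise_free_fit_matches_least_squares_oracle(self, noisefree_bundle):
        """At negligible penalty a noise-free additive series is fit exactly;
        the pseudo-inverse (minimum-norm OLS) solution is the oracle."""
        dm, y, model = (
            noisefree_bundle["design"],
            noisefree_bundle["y"],
            noisefree_bundle["model"],
        )
        X = dm.X.astype(float)
        ones = np.ones((len(y), 1))
        beta_ols = np.linalg.pinv(np.hstack([ones, X])) @ y
        pred_oracle = np.hstack([ones, X]) @ beta_ols
        pred_model = predict(model, noisefree_bundle["assignments"])
        np.testing.assert_allclose(pred_model, pred_oracle, atol=1e-6)
        np.testing.assert_allclose(pred_model, y, atol=1e-6)

    def test_noise_free_within_site_differences_recover_truth(self, noisefree_bundle):
        """Per-site coefficient *differences* are identified and must match the
        generating contributions; absolute coefficients are not identified."""
        model = noisefree_bundle["model"]
        truth = noisefree_bundle["truth"]["coefficients"]
        for site in model.sites:
            fitted = model.site_coefficients(site)
            for g1, g2 in itertools.combinations(sorted(fitted), 2):
                assert fitted[g1] - fitted[g2] == pytest.approx(
                    truth[(site, g1)] - truth[(site, g2)], abs=1e-6
                )

    def test_constant_response_gives_intercept_only(self):
        dm, _, _ = _toy_design()
        model = fit(dm, np.full(dm.shape[0], 5.5), alpha_grid=[1e-2, 1.0])
        assert model.intercept == pytest.approx(5.5, abs=1e-10)
        assert all(abs(c) < 1e-8 for c in model.coefficients.values())
        assert not model.metrics_defined
        assert np.isnan(model.r_squared)

    def test_fewer_than_three_rows_rejected(self):
        dm, _, _ = _toy_design((2, 1))
        dm2 = DesignMatrix(X=dm.X[:2], column_index=dm.column_index, ligand_ids=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            fit(dm2, [1.0, 2.0])

    def test_nonpositive_alpha_rejected(self):
        dm, _, _ = _toy_design()
        with pytest.raises(ValueError, match="positive"):
            fit(dm, np.zeros(dm.shape[0]), alpha_grid=[0.0, 1.0])

    def test_shift_equivariance_of_intercept(self, noisefree_bundle):
        """Adding c to all activities moves only the (unpenalized) intercept."""
        dm, y = noisefree_bundle["design"], noisefree_bundle["y"]
        m0 = fit(dm, y, alpha_grid=(1e-2, 1.0))
        m1 = fit(dm, y + 3.7, alpha_grid=(1e-2, 1.0))
        assert m1.intercept - m0.intercept == pytest.approx(3.7, abs=1e-8)
        for key in m0.coefficients:
            assert m1.coefficients[key] == pytest.approx(m0.coefficients[key], abs=1e-8)

    def test_monotone_shrinkage_in_alpha(self, noisefree_bundle):
        dm, y = noisefree_bundle["design"], noisefree_bundle["y"]
        norms = []
        for alpha in (1e-4, 1e-2, 1.0, 10.0, 1e3):
            m = fit(dm, y, alpha_grid=[alpha])
            norms.append(np.linalg.norm(list(m.coefficients.values())))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_loo_tie_broken_toward_smallest_alpha(self):
        dm, _, _ = _toy_design()
        y = np.full(dm.shape[0], 2.0)  # constant: every alpha has LOO error 0
        model = fit(dm, y, alpha_grid=[10.0, 0.1, 1.0])
        assert model.alpha == 0.1


class TestClosedFormLOO:
    @pytest.mark.parametrize("n,seed", [(6, 0), (12, 1), (30, 2)])
    @pytest.mark.parametrize("alpha", [1e-3, 1.0, 50.0])
    def test_equals_explicit_refits(self, n, seed, alpha):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(n, 5)).astype(float)
        y = rng.normal(6.0, 1.0, size=n)
        closed = loo_errors(X, y, [alpha])[0]
        errs = []
        for i in range(n):
            mask = np.arange(n) != i
            Xi, yi = X[mask], y[mask]
            xb, yb = Xi.mean(axis=0), yi.mean()
            U, s, Vt = np.linalg.svd(Xi - xb, full_matrices=False)
            beta = Vt.T @ ((s / (s**2 + alpha)) * (U.T @ (yi - yb)))
            errs.append((y[i] - (X[i] - xb) @ beta - yb) ** 2)
        assert closed == pytest.approx(np.mean(errs), abs=1e-8)

    def test_agrees_with_sklearn_ridgecv(self):
        """Independent route: sklearn's RidgeCV (exact LOO, unpenalized
        intercept) must select the same alpha and produce the same
        coefficients on a well-conditioned problem."""
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.5, size=60)
        grid = [1e-3, 1e-1, 1.0, 10.0, 100.0]
        skm = sklearn_lm.RidgeCV(alphas=grid, fit_intercept=True).fit(X, y)
        dm = DesignMatrix(
            X=X, column_index=[(1, f"*G{j}") for j in range(8)],
            ligand_ids=[str(i) for i in range(60)],
        )
        ours = fit(dm, y, alpha_grid=grid)
        assert ours.alpha == pytest.approx(skm.alpha_)
        np.testing.assert_allclose(
            list(ours.coefficients.values()), skm.coef_, atol=1e-8
        )
        assert ours.intercept == pytest.approx(skm.intercept_, abs=1e-8)


class TestPredict:
    def test_manual_summation_oracle(self):
        model = FWModel(
            coefficients={(1, "*A"): 0.3, (1, "*B"): -0.1, (2, "*X"): 0.8, (2, "*Y"): 0.0},
            intercept=6.0, alpha=1.0, alpha_grid=(1.0,),
            r_pearson=1.0, r_squared=1.0, loo_r2=1.0,
        )
        pred = predict(model, [{1: "*B", 2: "*X"}])
        assert pred[0] == pytest.approx(6.0 - 0.1 + 0.8)

    def test_in_sample_predictions_consistent_with_r_squared(self, noisefree_bundle):
        model, dm, y = (
            noisefree_bundle["model"],
            noisefree_bundle["design"],
            noisefree_bundle["y"],
        )
        pred = predict(model, noisefree_bundle["assignments"])
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(model.r_squared, abs=1e-10)

    def test_unseen_substituent_rejected_by_name(self, noisefree_bundle):
        model = noisefree_bundle["model"]
        with pytest.raises(ValueError, match=r"\*Br.*R1|R1.*\*Br"):
            predict(model, [{1: "*Br", 2: "*[H]", 3: "*[H]"}])

    def test_toy_five_ligand_holdout(self):
        """Fit 4 combinations of a {2,2} space, predict the 5th... the 4th
        unseen one; prediction is hand-summed intercept + coefficients."""
        dm, combos, offsets = _toy_design((2, 2))
        keep = [0, 1, 2]
        sub = DesignMatrix(
            X=dm.X[keep], column_index=dm.column_index,
            ligand_ids=[str(i) for i in keep],
        )
        y = np.array([6.0, 6.5, 7.0])
        model = fit(sub, y, alpha_grid=[1e-6])
        held_out = {1: "*G11", 2: "*G21"}
        expected = (
            model.intercept
            + model.coefficients[(1, "*G11")]
            + model.coefficients[(2, "*G21")]
        )
        assert predict(model, [held_out])[0] == pytest.approx(expected)


class TestCoefficientReport:
    def test_strong_booster_tops_table_and_singletons_flagged(self, noisefree_bundle):
        model = noisefree_bundle["model"]
        report = coefficient_report(model, noisefree_bundle["assignments"])
        assert list(report.columns) == [
            "site", "substituent", "coefficient", "n_occurrences", "effect", "low_support",
        ]
        assert report.coefficient.is_monotonic_decreasing
        assert (report.loc[report.coefficient > 0, "effect"] == "booster").all()
        assert (report.loc[report.coefficient <= 0, "effect"] == "degrader").all()
        assert (report.loc[report.n_occurrences <= 1, "low_support"]).all()

    def test_constructed_top_group(self):
        dm, combos, _ = _toy_design((2, 2))
        # G12 at site 1 carries a +2 contribution; everything else is 0
        y = np.array([6.0 + 2.0 * combo[0] for combo in combos])
        model = fit(dm, y, alpha_grid=[1e-6])
        report = coefficient_report(model)
        assert report.iloc[0].substituent == "*G11"
        assert report.iloc[0].site == 1


class TestSerialization:
    def test_json_round_trip(self, noisefree_bundle, tmp_path):
        model = noisefree_bundle["model"]
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FWModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.intercept == model.intercept
        assert back.alpha == model.alpha
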