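import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from pbsakit import (
    BindingEnergyModel,
    Dataset,
    DielectricPair,
    ModelSpec,
    compute_metrics,
    correlations,
    fit,
    mue_family,
    predictive_index,
    scan_dielectrics,
    score_frame,
)
from pbsakit.errors import ConfigError, MetricError, SingularDesignError

from conftest import study_dataset


class TestPredictiveIndex:
    def test_perfect_and_inverted_agreement(self):
        exp = np.array([-9.0, -7.5, -4.0, -1.0])
        assert predictive_index(exp, exp) == pytest.approx(1.0)
        assert predictive_index(-exp, exp) == pytest.approx(-1.0)

    def test_three_point_fixture_by_pair_enumeration(self):
        # pairs (1,2): w=1 c=+1; (1,3): w=2 c=+1; (2,3): w=1 c=-1 → 2/4
        assert predictive_index([1.0, 3.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_tied_prediction_contributes_zero(self):
        # pairs: (1,2) pred diff 0 → c=0 w=1; (1,3) +1 w=2; (2,3) +1 w=1
        assert predictive_index([1.0, 1.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(0.75)

    def test_all_experimental_equal_is_undefined(self):
        with pytest.raises(MetricError):
            predictive_index([1.0, 2.0], [3.0, 3.0])


class TestMueFamily:
    def test_constant_shift(self):
        exp = np.array([-8.0, -6.0, -2.0])
        mue, muetr, muesc = mue_family(exp + 5.0, exp)
        assert mue == pytest.approx(5.0)
        assert muetr == pytest.approx(0.0, abs=1e-12)
        assert muesc == pytest.approx(0.0, abs=1e-12)

    def test_affine_predictions_have_zero_muesc(self):
        exp = np.array([-8.0, -6.0, -2.0, -1.0])
        mue, muetr, muesc = mue_family(2.0 * exp + 3.0, exp)
        assert muesc == pytest.approx(0.0, abs=1e-12)
        assert mue > 0

    def test_hand_computed_three_point_fixture(self):
        # pred=(0,1,2), exp=(0,1,5): MUE=1; mean signed error=-1 → MUEtr=4/3;
        # least-squares exp = 2.5*pred - 0.5 → |errors|=(0.5,1,0.5) → MUEsc=2/3
        mue, muetr, muesc = mue_family([0.0, 1.0, 2.0], [0.0, 1.0, 5.0])
        assert mue == pytest.approx(1.0)
        assert muetr == pytest.approx(4.0 / 3.0)
        assert muesc == pytest.approx(2.0 / 3.0)

    def test_zero_variance_predictions_rejected(self):
        with pytest.raises(MetricError):
            mue_family([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestCorrelations:
    def test_affine_increasing_gives_unity(self):
        exp = np.array([-9.0, -6.0, -3.0, -1.0])
        r, rho = correlations(3.0 * exp + 1.0, exp)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_monotone_nonlinear_transform(self):
        exp = np.array([1.0, 2.0, 3.0, 4.0])
        r, rho = correlations(np.exp(exp), exp)
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_four_point_fixture_matches_direct_formula(self):
        pred = np.array([0.2, -1.0, 3.0, 1.5])
        exp = np.array([-0.5, -2.0, 2.0, 2.5])
        r, _ = correlations(pred, exp)
        pc, ec = pred - pred.mean(), exp - exp.mean()
        direct = (pc @ ec) / np.sqrt((pc @ pc) * (ec @ ec))
        assert r == pytest.approx(direct, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(
    scale=st.floats(0.1, 50.0),
    shift=st.floats(-100.0, 100.0),
    seed=st.integers(0, 2**16),
)
def test_affine_invariance_of_rank_metrics(scale, shift, seed):
    """PI, Pearson, Spearman and MUEsc are invariant under positive-affine
    transforms of the predictions; MUEtr under shifts only."""
    rng = np.random.default_rng(seed)
    exp = rng.normal(-7.0, 3.0, size=12)
    pred = exp + rng.normal(0.0, 1.0, size=12)
    base = compute_metrics(pred, exp)
    moved = compute_metrics(scale * pred + shift, exp)
    assert moved.pi == pytest.approx(base.pi, abs=1e-9)
    assert moved.pearson_r == pytest.approx(base.pearson_r, abs=1e-9)
    assert moved.spearman_r == pytest.approx(base.spearman_r, abs=1e-9)
    assert moved.muesc == pytest.approx(base.muesc, abs=1e-7)
    shifted = compute_metrics(pred + shift, exp)
    assert shifted.muetr == pytest.approx(base.muetr, abs=1e-9)


def test_muetr_bounded_by_mue_plus_mean_signed_error():
    rng = np.random.default_rng(7)
    for _ in range(100):
        exp = rng.normal(size=10)
        pred = exp + rng.normal(size=10)
        mue, muetr, _ = mue_family(pred, exp)
        assert muetr <= mue + abs((pred - exp).mean()) + 1e-12


class TestFit:
    def test_zero_noise_recovers_truth_exactly(self):
        ds, truth = study_dataset(seed=11, noise_sd=0.0)
        res = fit(ds, "spt")
        for name, val in truth["coefficients"].items():
            assert res.model.coefficients[name] == pytest.approx(val, abs=1e-8)
        assert res.metrics_train.pearson_r == pytest.approx(1.0)

    def test_pinned_coefficients_held_fixed(self):
        ds, truth = study_dataset(seed=12, noise_sd=0.5)
        res = fit(ds, "spt", fixed={"b": 0.0})
        assert res.model.coefficients["b"] == 0.0
        assert "b" not in res.coef_stderr

    def test_refitting_with_returned_coefficients_reproduces_metrics(self):
        ds, _ = study_dataset(seed=13, noise_sd=1.0)
        res = fit(ds, "spt")
        pred = score_frame(ds.terms, res.model, res.pair)
        again = compute_metrics(pred.to_numpy(), ds.exp.to_numpy())
        assert again.pearson_r == pytest.approx(res.metrics_train.pearson_r, abs=1e-10)
        assert again.mue == pytest.approx(res.metrics_train.mue, abs=1e-10)

    def test_collinear_design_is_singular_error(self):
        ds, _ = study_dataset(seed=14, noise_sd=0.0)
        terms = ds.terms.copy()
        terms["dSAV"] = terms["dSASA"]  # exactly collinear fixture
        with pytest.raises(SingularDesignError):
            fit(Dataset(terms=terms, exp=ds.exp), "spt")

    def test_fit_is_local_sse_minimum(self):
        ds, _ = study_dataset(seed=15, noise_sd=1.0)
        res = fit(ds, "spt")

        def sse(coeffs):
            pred = score_frame(ds.terms, ModelSpec("spt", coeffs), res.pair)
            return float(((pred - ds.exp) ** 2).sum())

        best = dict(res.model.coefficients)
        base = sse(best)
        for name in best:
            for delta in (-1e-4, 1e-4):
                perturbed = dict(best, **{name: best[name] + delta})
                assert sse(perturbed) >= base - 1e-9

    def test_noise_recovery_bias_within_mc_stderr(self):
        """σ=1 kcal/mol noise, 54 complexes: OLS recovery is unbiased."""
        gammas = []
        truth_gamma = None
        for rep in range(100):
            ds, truth = study_dataset(seed=1000 + rep, noise_sd=1.0)
            truth_gamma = truth["coefficients"]["gamma"]
            gammas.append(fit(ds, "spt").model.coefficients["gamma"])
        gammas = np.asarray(gammas)
        mc_stderr = gammas.std(ddof=1) / np.sqrt(len(gammas))
        assert abs(gammas.mean() - truth_gamma) < 2 * mc_stderr

    def test_too_few_complexes_rejected(self):
        ds, _ = study_dataset(seed=16, noise_sd=0.0, n=2)
        with pytest.raises(ConfigError):
            fit(ds, "spt")


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = BindingEnergyModel(regime="spt", eps_pb=2.1, pins={"b": 0.0})
        est2 = clone(est)
        assert est2.get_params()["eps_pb"] == 2.1
        est2.set_params(eps_pb=4.0)
        assert est2.eps_pb == 4.0

    def test_fit_predict_roundtrip(self):
        ds, truth = study_dataset(seed=21, noise_sd=0.0)
        est = BindingEnergyModel(regime="spt").fit(ds.terms, ds.exp.to_numpy())
        pred = est.predict(ds.terms)
        assert np.abs(pred - ds.exp.to_numpy()).max() < 1e-6
        assert est.score(ds.terms, ds.exp.to_numpy()) == pytest.approx(1.0)

    def test_unfitted_predict_raises(self):
        with pytest.raises(ConfigError):
            BindingEnergyModel().predict(pd.DataFrame())


class TestDielectricScan:
    def test_two_valued_scan_recovers_constructed_truth(self):
        ds, _ = study_dataset(
            seed=31, noise_sd=0.0, pair=DielectricPair(1, 4),
            coefficients={"gamma": 0.12, "p": 0.02, "b": 0.0},
        )
        table, best = scan_dielectrics(ds, "spt", range(1, 11), two_valued=True, refit=True)
        assert (best.eps_ele, best.eps_pb) == (1.0, 4.0)
        assert table.pearson_r.max() == pytest.approx(1.0)

    def test_single_valued_scan_is_strictly_worse_off_diagonal_truth(self):
        ds, _ = study_dataset(
            seed=31, noise_sd=0.0, pair=DielectricPair(1, 4),
            coefficients={"gamma": 0.12, "p": 0.02, "b": 0.0},
        )
        table, _ = scan_dielectrics(ds, "spt", range(1, 11), two_valued=False, refit=True)
        assert table.pearson_r.max() < 1.0 - 1e-9

    def test_diagonal_of_two_valued_equals_single_valued(self):
        ds, _ = study_dataset(seed=33, noise_sd=0.5, n=20)
        grid = [1.0, 2.0, 4.0]
        two, _ = scan_dielectrics(ds, "spt", grid, two_valued=True, refit=True)
        single, _ = scan_dielectrics(ds, "spt", grid, two_valued=False, refit=True)
        diag = two[two.eps_ele == two.eps_pb].reset_index(drop=True)
        pd.testing.assert_frame_equal(diag, single.reset_index(drop=True))

    def test_scan_without_refit_matches_manual_score(self):
        ds, truth = study_dataset(seed=34, noise_sd=0.5, n=20)
        model = ModelSpec("spt", truth["coefficients"])
        grid = [2.0]
        table, _ = scan_dielectrics(ds, model, grid, two_valued=False, refit=False)
        pred = score_frame(ds.terms, model, DielectricPair(2.0, 2.0))
        manual = compute_metrics(pred.to_numpy(), ds.exp.to_numpy())
        assert table.loc[0, "pearson_r"] == pytest.approx(manual.pearson_r, abs=1e-12)
        assert table.loc[0, "mue"] == pytest.approx(manual.mue, abs=1e-12)

    def test_empty_grid_rejected(self):
        ds, _ = study_dataset(seed=35, noise_sd=0.0, n=10)
        with pytest.raises(ConfigError):
            scan_dielectrics(ds, "spt", [], refit=True)

    def test_tie_breaks_toward_smaller_pair(self):
        # constant-prediction-free dataset where eps has no effect: dE_ele=dG_pb=0
        ds, _ = study_dataset(seed=36, noise_sd=0.0, n=10)
        terms = ds.terms.copy()
        terms["dE_ele"] = 0.0
        terms["dG_pb"] = 0.0
        model = ModelSpec("spt", {"gamma": 0.1, "p": 0.01, "b": 0.0})
        pred = score_frame(terms, model)
        ds2 = Dataset(terms=terms, exp=pred)
        _, best = scan_dielectrics(ds2, model, [1.0, 2.0, 3.0], two_valued=True, refit=False)
        assert (best.eps_ele, best.eps_pb) == (1.0, 1.0)


def test_held_out_split_reported():
    ds, _ = study_dataset(seed=41, noise_sd=1.0, n=40)
    split = pd.Series(["A"] * 30 + ["B"] * 10, index=ds.terms.index)
    ds = Dataset(terms=ds.terms, exp=ds.exp, split=split)
    res = fit(ds, "spt", train_label="A")
    assert res.metrics_test is not None
    assert np.isfinite(res.metrics_test.pearson_r)
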