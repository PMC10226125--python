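import numpy as np
import pandas as pd
import pytest

from pbsakit import (
    DielectricPair,
    ModelSpec,
    gnp_one_term,
    gnp_spt,
    gnp_two_term,
    rescale_dielectric,
    score,
    score_frame,
)
from pbsakit.errors import ConfigError
from pbsakit.estimators import REGIMES, design_matrix

from conftest import make_delta


class TestNonpolarBuildingBlocks:
    def test_one_term_presets(self):
        assert gnp_one_term(1000.0, 0.00542, 0.92) == pytest.approx(6.34)
        assert gnp_one_term(0.0, 0.1, 0.92) == pytest.approx(0.92)
        assert gnp_one_term(-800.0, 0.0072, 0.0) == pytest.approx(-5.76)

    def test_spt_and_reductions(self):
        assert gnp_spt(-800.0, -800.0, 0.1394, 0.0163, 0.0) == pytest.approx(-124.56)
        assert gnp_spt(-800.0, -123.0, 0.0072, 0.0, 0.0) == gnp_one_term(-800.0, 0.0072)
        assert gnp_spt(-800.0, -123.0, 0.0, 0.5, 0.0) == pytest.approx(0.5 * -123.0)

    def test_two_term(self):
        assert gnp_two_term(-700.0, -20.0, 0.0378, -0.5692) == pytest.approx(-47.0292)
        assert gnp_two_term(-700.0, 0.0, 0.1, 0.3) == gnp_one_term(-700.0, 0.1, 0.3)


class TestRescaleDielectric:
    def test_identity_pair(self, delta):
        out = rescale_dielectric(delta, DielectricPair(1, 1))
        assert out == delta

    def test_division(self, delta):
        out = rescale_dielectric(delta, DielectricPair(2, 4))
        assert out.dE_ele == pytest.approx(delta.dE_ele / 2)
        assert out.dG_pb == pytest.approx(delta.dG_pb / 4)
        assert out.dE_vdw == delta.dE_vdw

    def test_magnitude_monotone_in_eps(self, delta):
        mags = [
            abs(rescale_dielectric(delta, DielectricPair(e, 1)).dE_ele)
            for e in (1, 2, 4, 8)
        ]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_eps_below_one_rejected(self):
        with pytest.raises(ConfigError):
            DielectricPair(0.5, 1.0)


class TestScore:
    def test_sasa_only_hand_sum(self, delta):
        model = ModelSpec("sasa_only", {"gamma": 0.0072, "b": 0.0})
        out = score(delta, model, DielectricPair(1, 1))
        assert out.dg_pred == pytest.approx(-40 - 30 + 50 - 5.76)

    def test_spt_all_zero_deltas_gives_b(self):
        zero = make_delta(dE_vdw=0, dE_ele=0, dG_pb=0, dSASA=0, dSAV=0)
        model = ModelSpec("spt", {"gamma": 0.1, "p": 0.01, "b": 0.77})
        assert score(zero, model).dg_pred == pytest.approx(0.77)

    @pytest.mark.parametrize("regime", sorted(REGIMES))
    def test_contributions_sum_to_prediction(self, regime, delta):
        coeffs = {c: 0.1 * (i + 1) for i, c in enumerate(REGIMES[regime]["coefs"])}
        model = ModelSpec(regime, coeffs)
        out = score(delta, model, DielectricPair(1.5, 2.5))
        assert sum(out.contributions.values()) == pytest.approx(out.dg_pred, abs=1e-10)

    def test_pbsa_e_shared_scaling_equals_prescaled_terms(self, delta):
        model = ModelSpec.preset("pbsa-e-original")
        scaled = score(delta, model, DielectricPair(2.1, 2.1))
        pre = rescale_dielectric(delta, DielectricPair(2.1, 2.1))
        unscaled = score(pre, model, DielectricPair(1, 1))
        assert scaled.dg_pred == pytest.approx(unscaled.dg_pred, abs=1e-12)

    def test_missing_required_term_names_it(self, delta):
        broken = make_delta(dE_sp=None)
        model = ModelSpec("ani_spt", {"a": 1.0, "gamma": 0.1, "p": 0.01, "b": 0.0})
        with pytest.raises(ConfigError, match="dE_sp"):
            score(broken, model)

    def test_unknown_regime_and_missing_coefficient(self):
        with pytest.raises(ConfigError, match="regime"):
            ModelSpec("nope", {})
        with pytest.raises(ConfigError, match="p"):
            ModelSpec("spt", {"gamma": 0.1, "b": 0.0})


class TestRegimeAlgebra:
    def test_spt_reduces_to_one_term_models(self, delta):
        spt_p0 = ModelSpec("spt", {"gamma": 0.08, "p": 0.0, "b": 0.3})
        sasa = ModelSpec("sasa_only", {"gamma": 0.08, "b": 0.3})
        assert score(delta, spt_p0).dg_pred == pytest.approx(score(delta, sasa).dg_pred)

        spt_g0 = ModelSpec("spt", {"gamma": 0.0, "p": 0.02, "b": 0.3})
        sav = ModelSpec("sav_only", {"gamma": 0.02, "b": 0.3})
        assert score(delta, spt_g0).dg_pred == pytest.approx(score(delta, sav).dg_pred)

    def test_ani_spt_with_mm_energy_recovers_spt(self, delta):
        d = make_delta(dE_sp=delta.dE_vdw + delta.dE_ele)
        ani = ModelSpec("ani_spt", {"a": 1.0, "gamma": 0.1, "p": 0.01, "b": 0.2})
        spt = ModelSpec("spt", {"gamma": 0.1, "p": 0.01, "b": 0.2})
        for eps_pb in (1.0, 2.1, 4.0):
            assert score(d, ani, DielectricPair(1, eps_pb)).dg_pred == pytest.approx(
                score(d, spt, DielectricPair(1, eps_pb)).dg_pred, abs=1e-12
            )

    def test_linear_dispersion_collapses_two_term_onto_spt(self):
        # when E_disp = c1*dSAV + c0 exactly, sav_disp == spt with mapped coefficients
        c1, c0 = 0.031, -2.5
        gamma, b = 0.0378, -0.5692
        rng = np.random.default_rng(4)
        for _ in range(10):
            sav = float(rng.normal(-750, 150))
            d = make_delta(dSAV=sav, dE_disp=c1 * sav + c0)
            two = ModelSpec("sav_disp", {"gamma": gamma, "b": b})
            spt = ModelSpec("spt", {"gamma": 0.0, "p": gamma + c1, "b": b + c0})
            assert score(d, two).dg_pred == pytest.approx(score(d, spt).dg_pred, abs=1e-10)

    @pytest.mark.parametrize("regime", sorted(REGIMES))
    def test_two_valued_matches_single_valued_on_diagonal(self, regime, delta):
        coeffs = {c: 0.05 * (i + 1) for i, c in enumerate(REGIMES[regime]["coefs"])}
        model = ModelSpec(regime, coeffs)
        eps = 2.1
        via_pair = score(delta, model, DielectricPair(eps, eps))
        via_rescale = score(
            rescale_dielectric(delta, DielectricPair(eps, eps)), model, DielectricPair(1, 1)
        )
        assert via_pair.dg_pred == pytest.approx(via_rescale.dg_pred, abs=1e-12)

    @pytest.mark.parametrize("regime", sorted(REGIMES))
    def test_prediction_affine_in_each_coefficient(self, regime, delta):
        """Finite-difference slope equals the analytic design-matrix column."""
        coeffs = {c: 0.1 for c in REGIMES[regime]["coefs"]}
        pair = DielectricPair(1.3, 2.2)
        df = pd.DataFrame([make_delta().to_dict()]).set_index("complex_id")
        fixed, X, names = design_matrix(df, regime, pair)
        for k, name in enumerate(names):
            for h in (1e-3, 1e-4):
                up = dict(coeffs, **{name: coeffs[name] + h})
                dn = dict(coeffs, **{name: coeffs[name] - h})
                s_up = score(delta, ModelSpec(regime, up), pair).dg_pred
                s_dn = score(delta, ModelSpec(regime, dn), pair).dg_pred
                slope = (s_up - s_dn) / (2 * h)
                assert slope == pytest.approx(X[0, k], rel=1e-8, abs=1e-8)


def test_score_frame_matches_scalar_score(delta):
    model = ModelSpec("spt", {"gamma": 0.1394, "p": 0.0163, "b": 0.0})
    pair = DielectricPair(1, 2.1)
    df = pd.DataFrame([make_delta(complex_id=f"c{i}", dSASA=-700 - 10 * i).to_dict()
                       for i in range(4)]).set_index("complex_id")
    vec = score_frame(df, model, pair)
    for cid, row in df.iterrows():
        d = make_delta(complex_id=cid, dSASA=row["dSASA"])
        assert vec[cid] == pytest.approx(score(d, model, pair).dg_pred, abs=1e-12)
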