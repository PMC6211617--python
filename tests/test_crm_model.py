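import warnings

import numpy as np
import pandas as pd
import pytest

from svase.containers import EmbryoSpec
from svase.crm_model import (
    CRMModel,
    build_design,
    fit_crm_model,
    perturb_and_predict_ase,
    perturb_coefficients,
    predict_expression,
    scan_perturbations,
    select_model,
    select_training_nuclei,
)
from svase.atlas_bias import normalize_atlas_gene
from svase.synthetic_data import (
    default_crm_model,
    simulate_atlas_pair,
    simulate_tf_profiles,
)


@pytest.fixture(scope="module")
def tf_data():
    emb = EmbryoSpec("m")
    return emb, simulate_tf_profiles(emb, n_nuclei=2000, noise_sd=0.05, seed=41)


class TestDesign:
    def test_quadratic_column_is_square_of_linear(self, tf_data):
        _, data = tf_data
        design = build_design(data, ["bcd", "hkb"])
        np.testing.assert_allclose(design["bcd2"], design["bcd"] ** 2)
        assert list(design.columns) == ["intercept", "bcd", "hkb", "bcd2"]

    def test_no_quadratic_without_bicoid(self, tf_data):
        _, data = tf_data
        design = build_design(data, ["hkb", "kni"])
        assert "bcd2" not in design.columns


class TestFitAndPredict:
    def test_known_coefficients_recovered_in_sign_and_magnitude(self, tf_data):
        """At typical atlas noise the AP gradients are strongly collinear,
        so a 2000-nucleus fit recovers signs exactly and magnitudes
        approximately; the precise recovery calibration lives in the
        acceptance suite at higher inter-nucleus variability."""
        emb, data = tf_data
        model = default_crm_model()
        design = build_design(data, model.tf_list)
        rng = np.random.default_rng(5)
        p = predict_expression(model, design)
        y = pd.Series(rng.binomial(1, p), index=data.index)
        fit = fit_crm_model(design, y)
        assert (np.sign(fit.coefficients) == np.sign(model.coefficients)).all()
        rel = np.abs((fit.coefficients - model.coefficients) / model.coefficients)
        assert (rel < 0.5).all()
        assert not fit.separation

    def test_unrelated_response_has_near_zero_pseudo_r2(self, tf_data):
        _, data = tf_data
        design = build_design(data, ["bcd", "kni"])
        rng = np.random.default_rng(6)
        y = pd.Series(rng.binomial(1, 0.4, len(data)), index=data.index)
        fit = fit_crm_model(design, y)
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=0.01)

    def test_perfect_separation_flagged_with_finite_coefficients(self):
        n = 200
        x = np.linspace(-1, 1, n)
        data = pd.DataFrame(
            {"x": x * 100, "y": 0.0, "z": 0.0, "tf": x},
            index=pd.Index([f"n{i}" for i in range(n)]),
        )
        design = build_design(data, ["tf"])
        y = pd.Series((x > 0).astype(int), index=data.index)
        fit = fit_crm_model(design, y)
        assert fit.separation
        assert np.all(np.isfinite(fit.coefficients))

    def test_single_class_response_rejected(self, tf_data):
        _, data = tf_data
        design = build_design(data, ["bcd"])
        with pytest.raises(ValueError, match="both classes"):
            fit_crm_model(design, pd.Series(1, index=data.index))

    def test_zero_predictor_gives_half(self):
        model = CRMModel(
            tf_list=["tf"],
            coefficients=pd.Series({"intercept": 0.0, "tf": 0.0}),
            pseudo_r2=0.0,
        )
        design = pd.DataFrame({"intercept": [1.0], "tf": [3.0]})
        assert predict_expression(model, design).iloc[0] == pytest.approx(0.5)

    def test_design_mismatch_rejected(self, tf_data):
        _, data = tf_data
        model = default_crm_model()
        wrong = build_design(data, ["bcd", "hkb"])
        with pytest.raises(ValueError, match="do not match"):
            predict_expression(model, wrong)

    def test_monotone_in_each_tf_with_coefficient_sign(self, tf_data):
        _, data = tf_data
        model = default_crm_model()
        base = data.iloc[:1].copy()
        design0 = build_design(base, model.tf_list)
        p0 = predict_expression(model, design0).iloc[0]
        # raising a repressor's concentration lowers predicted expression
        up = base.copy()
        up["hkb"] = up["hkb"] + 1.0
        p_up = predict_expression(model, build_design(up, model.tf_list)).iloc[0]
        assert p_up < p0


class TestTrainingSelection:
    def test_posterior_domain_excluded(self, embryo):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            atlas, _, _ = simulate_atlas_pair(
                embryo, default_crm_model(), "none", 1.0, seed=43, n_nuclei=2000,
                posterior_stripe=True,
            )
            keep, resp = select_training_nuclei(atlas, "hb")
        xf = atlas.x_fraction()
        expr = atlas.data["hb"]
        posterior_on = (xf > 0.75) & (expr > 0.5 * expr.max())
        assert posterior_on.sum() > 50  # the posterior stripe exists
        assert not posterior_on.loc[keep].any()  # and is excluded from training

    def test_on_threshold_boundary(self, embryo):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            atlas, _, _ = simulate_atlas_pair(
                embryo, default_crm_model(), "none", 1.0, seed=44, n_nuclei=800,
            )
            expr = normalize_atlas_gene(atlas, "hb")
            keep, resp = select_training_nuclei(atlas, "hb", on_threshold=0.2,
                                                normalized=expr)
        thr = 0.2 * expr.max()
        below = expr.loc[keep] < thr
        assert (resp[below.loc[resp.index]] == 0).all()

    def test_single_domain_retains_all_with_warning(self, embryo):
        atlas, _, _ = simulate_atlas_pair(
            embryo, default_crm_model(), "none", 1.0, seed=45, n_nuclei=800,
            posterior_stripe=False, expr_noise_sd=0.02,
        )
        with pytest.warns(UserWarning, match="fewer than two"):
            keep, _ = select_training_nuclei(atlas, "hb")
        assert len(keep) == len(atlas.data)


class TestModelSelection:
    def test_required_only_when_max_extra_zero(self, embryo):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            atlas, _, _ = simulate_atlas_pair(
                embryo, default_crm_model(), "none", 1.0, seed=46, n_nuclei=1000,
            )
            model, _ = select_model(
                atlas, "hb", required_tfs=["bcd"], candidate_tfs=["hkb", "kni"],
                max_extra=0,
            )
        assert model.tf_list == ["bcd"]

    def test_budget_overflow_rejected(self, embryo):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            atlas, _, _ = simulate_atlas_pair(
                embryo, default_crm_model(), "none", 1.0, seed=47, n_nuclei=500,
            )
            with pytest.raises(ValueError, match="budget"):
                select_model(
                    atlas, "hb", required_tfs=["bcd"],
                    candidate_tfs=[f"tf{i}" for i in range(30)],
                    max_extra=4, budget=100,
                )

    def test_true_regulator_selected(self, embryo):
        """Truth uses {bcd, bcd^2, hkb}; hkb must appear in the chosen subset."""
        coefs = pd.Series({"intercept": -3.0, "bcd": 14.0, "hkb": -8.0, "bcd2": -2.0})
        truth = CRMModel(
            tf_list=["bcd", "hkb"],
            coefficients=coefs.reindex(["intercept", "bcd", "hkb", "bcd2"]),
            pseudo_r2=np.nan,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            atlas, _, _ = simulate_atlas_pair(
                embryo, truth, "none", 1.0, seed=48, n_nuclei=2000,
            )
            model, score = select_model(
                atlas, "hb", required_tfs=["bcd"],
                candidate_tfs=["hkb", "gt", "kr", "tll"], max_extra=2,
            )
        assert "hkb" in model.tf_list
        assert score > 0.5


class TestPerturbation:
    def test_identity_multiplier_is_a_no_op(self, tf_data):
        emb, data = tf_data
        model = default_crm_model()
        design = build_design(data, model.tf_list)
        xf = (data["x"] / emb.length_um).clip(0, 1)
        res = perturb_and_predict_ase(model, "hkb", 1.0, design, xf,
                                      observed_mean=0.12)
        np.testing.assert_allclose(res.nucleus_ase.dropna(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.slice_ase.dropna(), 0.12, atol=1e-12)

    def test_tandem_equals_both_terms(self):
        model = default_crm_model()
        a = perturb_coefficients(model, "bcd_tandem", 0.5)
        b = perturb_coefficients(model, ["bcd", "bcd2"], 0.5)
        pd.testing.assert_series_equal(a.coefficients, b.coefficients)

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            perturb_coefficients(default_crm_model(), "gt", 2.0)

    def test_antisymmetric_under_model_swap(self, tf_data):
        emb, data = tf_data
        model = default_crm_model()
        pert = perturb_coefficients(model, "hkb", 2.0)
        design = build_design(data, model.tf_list)
        xf = (data["x"] / emb.length_um).clip(0, 1)
        fwd = perturb_and_predict_ase(model, "hkb", 2.0, design, xf)
        p_base = predict_expression(model, design).to_numpy()
        p_pert = predict_expression(pert, design).to_numpy()
        manual = (p_pert - p_base) / (p_pert + p_base)
        np.testing.assert_allclose(fwd.nucleus_ase.to_numpy(), manual, atol=1e-12)
        # swapping base and perturbed negates the per-nucleus ASE
        np.testing.assert_allclose(
            (p_base - p_pert) / (p_base + p_pert), -manual, atol=1e-12
        )

    def test_weakened_anterior_activator_depresses_the_anterior(self, tf_data):
        emb, data = tf_data
        model = default_crm_model()
        design = build_design(data, model.tf_list)
        xf = (data["x"] / emb.length_um).clip(0, 1)
        res = perturb_and_predict_ase(model, "bcd", 0.7, design, xf)
        ase = res.slice_ase.dropna()
        anterior = ase[ase.index < 0.2]
        assert anterior.mean() < -0.05


class TestScan:
    def test_singleton_identity_grid(self, tf_data):
        emb, data = tf_data
        model = default_crm_model()
        design = build_design(data, model.tf_list)
        xf = (data["x"] / emb.length_um).clip(0, 1)
        base = perturb_and_predict_ase(model, "hkb", 1.0, design, xf)
        obs = base.slice_ase
        scan = scan_perturbations(model, ["hkb"], [1.0], design, xf, obs)
        assert len(scan) == 1
        assert scan.loc[0, "multiplier"] == 1.0

    def test_constant_observed_ranks_identity_first(self, tf_data):
        emb, data = tf_data
        model = default_crm_model()
        design = build_design(data, model.tf_list)
        xf = (data["x"] / emb.length_um).clip(0, 1)
        base = perturb_and_predict_ase(model, "hkb", 1.0, design, xf)
        obs = base.slice_ase * 0.0  # constant zero over callable bins
        scan = scan_perturbations(model, ["hkb", "bcd"], [0.5, 1.0, 2.0], design, xf, obs)
        assert (scan["var_explained"] <= 1e-9).all()
        assert scan.loc[0, "multiplier"] == 1.0

    def test_perturbed_term_identified(self, tf_data):
        emb, data = tf_data
        model = default_crm_model()
        design = build_design(data, model.tf_list)
        xf = (data["x"] / emb.length_um).clip(0, 1)
        rng = np.random.default_rng(50)
        truth = perturb_and_predict_ase(model, "hkb", 2.0, design, xf)
        obs = truth.slice_ase + rng.normal(0, 0.02, len(truth.slice_ase))
        grid = np.round(np.arange(-1.0, 3.01, 0.1), 2)
        scan = scan_perturbations(
            model, ["bcd", "bcd2", "hkb", "kni", "bcd_tandem"], grid, design, xf, obs
        )
        top = scan.iloc[0]
        assert top["tf"] == "hkb"
        assert abs(top["multiplier"] - 2.0) <= 0.1 + 1e-9
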