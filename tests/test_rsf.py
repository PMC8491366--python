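"""Used–available design, weighted logistic RSF, mixed model, blocked CV."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy import stats
from shapely.geometry import LineString

from jackalkit import rsf as R
from jackalkit.synthetic import LandscapeLayers, MovementConfig, gen_availability, gen_movement
from conftest import BETA_TRUE, FEATURES, make_design

COVS = ("dist_dense_forest", "dist_road", "dist_stream")


class TestSampleAvailable:
    def test_count_containment_and_determinism(self):
        poly = shapely.box(0, 0, 5000, 5000)
        pts = R.sample_available(poly, 100, ratio=10, seed=4)
        assert pts.shape == (1000, 2)
        assert shapely.contains_xy(poly, pts[:, 0], pts[:, 1]).all()
        np.testing.assert_array_equal(pts, R.sample_available(poly, 100, ratio=10, seed=4))

    def test_uniformity_chi_square(self):
        poly = shapely.box(0, 0, 4000, 4000)
        pts = R.sample_available(poly, 1000, ratio=10, seed=5)
        hx = np.histogram2d(pts[:, 0], pts[:, 1], bins=4, range=[[0, 4000], [0, 4000]])[0]
        chi2 = ((hx - hx.mean()) ** 2 / hx.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, 15)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            R.sample_available(shapely.Polygon(), 10)


class TestDistanceCovariates:
    @staticmethod
    def layers(shift=(0.0, 0.0)):
        dx, dy = shift
        road = LineString([(3 + dx, 4 + dy), (3 + dx, 100 + dy)])
        return LandscapeLayers(
            layers={"road": [road], "stream": [], "dense_forest": [], "ddf": []},
            extent=(-1000 + dx, -1000 + dy, 1000 + dx, 1000 + dy),
        )

    def test_point_on_feature_is_zero(self):
        d = R.distance_covariates(np.array([[3.0, 50.0]]), self.layers(), ("road",))
        assert d["dist_road"].iloc[0] == pytest.approx(0.0)

    def test_point_segment_geometry(self):
        d = R.distance_covariates(np.array([[0.0, 0.0]]), self.layers(), ("road",))
        assert d["dist_road"].iloc[0] == pytest.approx(5.0)

    def test_rigid_translation_invariance(self):
        pts = np.array([[0.0, 0.0], [10.0, -20.0]])
        d0 = R.distance_covariates(pts, self.layers(), ("road",))
        d1 = R.distance_covariates(pts + [500.0, -300.0],
                                   self.layers(shift=(500.0, -300.0)), ("road",))
        pd.testing.assert_frame_equal(d0, d1)


class TestPreprocess:
    def test_standardized_columns(self, strong_selection_design):
        design, _ = strong_selection_design
        for c in COVS:
            assert design[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert design[c].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_covariate_dropped(self, rng):
        raw = pd.DataFrame({"dist_a": rng.uniform(0, 100, 500)})
        raw["dist_b"] = raw["dist_a"]
        out, scaler, report = R.preprocess(raw)
        assert scaler.covariates == ("dist_a",)
        assert scaler.dropped == ("dist_b",)
        assert report["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_constructed_correlation_flagged(self, rng):
        a = rng.uniform(0, 2000, 2000)
        raw = pd.DataFrame({"dist_a": a})
        # correlate on the log scale, where the screen operates
        raw["dist_b"] = np.expm1(0.9 * np.log1p(a) + rng.normal(0, 0.3, 2000))
        _, scaler, report = R.preprocess(raw)
        assert len(report) == 1 and abs(report["pearson_r"].iloc[0]) >= 0.7
        assert "dist_b" in scaler.dropped

    def test_priority_list_controls_victim(self, rng):
        a = rng.uniform(0, 100, 300)
        raw = pd.DataFrame({"dist_ddf": a, "dist_dense_forest": a * 1.01})
        _, scaler, _ = R.preprocess(raw)
        assert scaler.dropped == ("dist_ddf",)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            R.preprocess(pd.DataFrame({"dist_a": np.ones(50)}))


class TestFixedEffectsFit:
    def test_sign_pattern_recovery(self, strong_selection_design):
        design, scaler = strong_selection_design
        model = R.fit_rsf(design, scaler.covariates, random_effects="none")
        # truth: avoid dense forest (+), select roads (−), avoid streams (+)
        assert model.coef_["dist_dense_forest"] > 0
        assert model.coef_["dist_road"] < 0
        assert model.coef_["dist_stream"] > 0
        assert model.conf_int_.loc["dist_road", "ucl"] < 0

    def test_weight_rescaling_leaves_beta_unchanged(self, strong_selection_design):
        design, scaler = strong_selection_design
        m1 = R.fit_rsf(design, scaler.covariates, random_effects="none")
        scaled = design.assign(weight=design["weight"] * 37.0)
        m2 = R.fit_rsf(scaled, scaler.covariates, random_effects="none")
        np.testing.assert_allclose(m1.coef_, m2.coef_, rtol=1e-6)

    def test_estimates_stabilize_as_available_weight_grows(self, landscape):
        betas = {}
        for w in (100.0, 1000.0, 10_000.0):
            design, scaler = make_design(landscape, BETA_TRUE, n_animals=2,
                                         n_fixes=400, seed=31)
            design["weight"] = np.where(design["case"] == 1, 1.0, w)
            betas[w] = R.fit_rsf(design, scaler.covariates, random_effects="none").coef_
        d1 = np.abs(betas[1000.0] - betas[100.0]) / np.abs(betas[1000.0])
        d2 = np.abs(betas[10_000.0] - betas[1000.0]) / np.abs(betas[10_000.0])
        assert (d2 < 0.01).all()
        assert (d2 <= d1 + 1e-12).all()

    def test_null_simulation_coverage(self, landscape):
        # with no true selection, each coefficient should satisfy |beta| < 2 SE
        # in >= 93 % of fits (2 SE is a ~95.4 % Wald interval); the availability
        # sample is enlarged because the likelihood SE does not account for
        # Monte-Carlo noise in the available points
        hits = pd.Series(0, index=list(COVS))
        for rep in range(100):
            design, scaler = make_design(landscape, {f: 0.0 for f in FEATURES},
                                         n_animals=1, n_fixes=150, ratio=30,
                                         seed=500 + rep)
            m = R.fit_rsf(design, scaler.covariates, random_effects="none")
            hits += (m.coef_.abs() < 2 * m.se_).astype(int)
        assert (hits >= 93).all(), hits.to_dict()


@pytest.fixture(scope="module")
def small_design(landscape):
    design, scaler = make_design(landscape, {"road": -0.5, "stream": 0.3},
                                 n_animals=3, n_fixes=150, seed=61)
    return design, scaler


class TestMixedModel:

    def test_agrees_with_glmmTMB_oracle(self, small_design, tmp_path):
        # independent cross-check: the same model (fixed intercept variance,
        # random slopes by animal) fit by TMB's Laplace approximation in R
        design, scaler = small_design
        covs = list(scaler.covariates)
        model = R.fit_rsf(design, covs, random_effects="slopes")

        csv = tmp_path / "design.csv"
        design.to_csv(csv, index=False)
        terms = " + ".join(f"(0 + {c} | animal_id)" for c in covs)
        n_theta = len(covs) + 1
        mapping = ", ".join(["NA"] + [str(i + 1) for i in range(len(covs))])
        script = f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv("{csv}")
        m <- glmmTMB(case ~ {' + '.join(covs)} + (1 | animal_id) + {terms},
                     family = binomial(), weights = weight, data = d, doFit = FALSE)
        m$parameters$theta[1] <- log(1e3)
        m$mapArg <- list(theta = factor(c({mapping})))
        fit <- glmmTMB:::fitTMB(m)
        cat(jsonlite::toJSON(as.list(fixef(fit)$cond), auto_unbox = TRUE))
        """
        rfile = tmp_path / "oracle.R"
        rfile.write_text(script)
        proc = subprocess.run(["Rscript", str(rfile)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr[-800:]
        oracle = json.loads(proc.stdout.strip().splitlines()[-1])
        for c in covs:
            assert model.coef_[c] == pytest.approx(oracle[c], abs=0.02)

    def test_reduces_to_fixed_effects_without_heterogeneity(self, small_design):
        # all animals share one true coefficient vector, so the random-slopes
        # fit must agree with the plain weighted fit within one standard error
        design, scaler = small_design
        fe = R.fit_rsf(design, scaler.covariates, random_effects="none")
        mm = R.fit_rsf(design, scaler.covariates, random_effects="slopes")
        for c in scaler.covariates:
            assert abs(mm.coef_[c] - fe.coef_[c]) < max(fe.se_[c], mm.se_[c])

    def test_requires_groups_and_two_animals(self, small_design):
        design, scaler = small_design
        with pytest.raises(ValueError, match="groups"):
            R.ResourceSelectionFunction(random_effects="slopes").fit(
                design[list(scaler.covariates)], design["case"],
                sample_weight=design["weight"],
            )
        one = design[design["animal_id"] == "A1"]
        with pytest.raises(ValueError, match="2 groups"):
            R.fit_rsf(one, scaler.covariates, random_effects="slopes")


class TestPredict:
    def test_zero_covariates_score_one(self, strong_selection_design):
        design, scaler = strong_selection_design
        model = R.fit_rsf(design, scaler.covariates, random_effects="none")
        assert model.predict(np.zeros((1, 3)))[0] == pytest.approx(1.0)

    def test_ranking_matches_hand_computed_linear_predictor(self, strong_selection_design):
        design, scaler = strong_selection_design
        model = R.fit_rsf(design, scaler.covariates, random_effects="none")
        X = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.5], [-1.0, 1.0, -0.5]])
        lp = X @ model.coef_.to_numpy()
        scores = model.predict(X)
        assert list(np.argsort(scores)) == list(np.argsort(lp))
        np.testing.assert_allclose(np.log(scores), lp)


class TestBlockedCV:
    def test_perfectly_monotone_frequencies_give_rho_one(self):
        freq = np.arange(1, 11, dtype=float)
        rho, _ = stats.spearmanr(np.arange(1, 11), freq)
        assert rho == pytest.approx(1.0)

    def test_bins_hold_equal_available_shares(self, strong_selection_design, rng):
        design, scaler = strong_selection_design
        model = R.fit_rsf(design, scaler.covariates, random_effects="none")
        test = design[design["animal_id"] == "A1"]
        s_avail = model.predict(test.loc[test["case"] == 0, list(scaler.covariates)])
        edges = np.quantile(s_avail, np.linspace(0, 1, 11))
        counts, _ = np.histogram(s_avail, bins=edges)
        share = counts / counts.sum()
        assert np.all(np.abs(share - 0.1) < 0.01)

    def test_random_scores_produce_no_ranking_signal(self, rng):
        rhos = []
        for _ in range(20):
            s_avail = rng.random(2000)
            s_pres = rng.random(300)
            freq = R.area_adjusted_frequencies(s_avail, s_pres)
            rhos.append(stats.spearmanr(np.arange(1, 11), freq)[0])
        assert abs(np.mean(rhos)) < 0.35

    def test_strong_selection_is_well_ranked(self, strong_selection_design):
        design, scaler = strong_selection_design
        cv = R.blocked_kfold_cv(design, scaler.covariates)
        assert cv.mean_rho >= 0.8
        assert len(cv.folds) == 5
        assert cv.pooled_p < 0.001
        assert ((cv.folds["rho"] >= -1) & (cv.folds["rho"] <= 1)).all()

    def test_sparse_animal_fold_skipped(self, strong_selection_design):
        design, scaler = strong_selection_design
        thin = pd.concat(
            [design, design[design["animal_id"] == "A1"]
             .head(5).assign(animal_id="A9")],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="A9"):
            cv = R.blocked_kfold_cv(thin, scaler.covariates)
        assert "A9" not in set(cv.folds["animal_id"])
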