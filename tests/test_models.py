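import json
import subprocess

import numpy as np
import pandas as pd
import pytest

import odflows as od
from odflows.models import (LognormalFlowModel, MixedLognormalFlowModel,
                            NegativeBinomialFlowModel, PoissonFlowModel,
                            make_model, model_from_dict)
from odflows.synthetic import GravityTruth

from conftest import design_for

SIMPLE_FEATURES = ["log_pop_i", "log_pop_j", "inv_distance", "same_country",
                   "log_maxc", "stops"]
SIMPLE_TRUTH = {"intercept": -3.0, "log_pop_i": 0.4, "log_pop_j": 0.4,
                "inv_distance": 300.0, "same_country": 0.7, "log_maxc": 0.2,
                "stops[1]": -0.5, "stops[2]": -1.0}


def _noise_free_data(seed=21):
    truth = GravityTruth(fixed_coefficients=SIMPLE_TRUTH, sigma_origin=0,
                         sigma_dest=0, sigma_hierarchy=0, sigma_resid=0)
    w = od.simulate_world(n_airports=50, mean_degree=6, n_flows=600,
                          truth=truth, seed=seed)
    g = od.build_graph(w.edges, w.airports)
    m = od.node_metrics(g)
    scheme = od.classify_hierarchies(w.airports, m)
    flows = od.generate_flows(w.airports, w.edges, w.routes, truth, seed=seed,
                              round_to_int=False)
    X = od.build_design(w.routes, w.airports, m, scheme)
    X = X.merge(flows, on=["origin", "dest"], how="inner")
    return X, X["passengers"].to_numpy()


class TestLognormal:
    def test_noise_free_exact_recovery(self):
        X, y = _noise_free_data()
        model = LognormalFlowModel(features=SIMPLE_FEATURES).fit(X, y)
        for name, true in SIMPLE_TRUTH.items():
            assert model.coefficients_[name] == pytest.approx(true, abs=1e-6)

    def test_intercept_only_is_mean_log_flow(self, small_design):
        X, y = small_design
        model = LognormalFlowModel(features=[]).fit(X, y)
        assert model.coefficients_["intercept"] == pytest.approx(np.log(y).mean())

    def test_degenerate_variance_collapses_interval(self):
        X, y = _noise_free_data()
        model = LognormalFlowModel(features=SIMPLE_FEATURES).fit(X, y)
        out = model.predict_interval(X.head(20))
        np.testing.assert_allclose(out["lo"], out["point"], rtol=1e-5)
        np.testing.assert_allclose(out["hi"], out["point"], rtol=1e-5)

    def test_mean_correction_identity(self, small_design):
        X, y = small_design
        naive = LognormalFlowModel(features=SIMPLE_FEATURES).fit(X, y)
        corrected = LognormalFlowModel(features=SIMPLE_FEATURES,
                                       mean_correction=True).fit(X, y)
        ratio = corrected.predict(X.head(10)) / naive.predict(X.head(10))
        np.testing.assert_allclose(ratio, np.exp(naive.sigma2_ / 2), rtol=1e-10)

    def test_rank_deficiency_names_aliased_columns(self, small_design):
        X, y = small_design
        with pytest.raises(np.linalg.LinAlgError, match="log_pop_i"):
            LognormalFlowModel(features=["log_pop_i", "log_pop_i"]).fit(X, y)

    def test_flows_below_one_rejected(self, small_design):
        X, y = small_design
        y = y.copy()
        y[0] = 0.2
        with pytest.raises(ValueError, match=">= 1"):
            LognormalFlowModel(features=SIMPLE_FEATURES).fit(X, y)


@pytest.fixture(scope="module")
def poisson_data(small_design):
    X, _ = small_design
    rng = np.random.default_rng(17)
    mu = np.exp(3.0 + 0.3 * (X["log_pop_i"].to_numpy() - 13.0))
    y = np.maximum(rng.poisson(mu), 1).astype(float)
    return X, y


class TestCountModels:
    def test_poisson_and_negbin_coincide_without_overdispersion(self, poisson_data):
        X, y = poisson_data
        pois = PoissonFlowModel(features=["log_pop_i"], interactions=[]).fit(X, y)
        nb = NegativeBinomialFlowModel(features=["log_pop_i"],
                                       interactions=[]).fit(X, y)
        assert nb.dispersion_ < 0.01
        for name in pois.coefficients_:
            assert nb.coefficients_[name] == pytest.approx(
                pois.coefficients_[name], abs=1e-4)

    def test_count_interval_brackets_mean(self, poisson_data):
        X, y = poisson_data
        model = PoissonFlowModel(features=["log_pop_i"], interactions=[]).fit(X, y)
        out = model.predict_interval(X.head(50))
        assert (out["lo"] <= out["point"]).all()
        assert (out["point"] <= out["hi"]).all()

    def test_negbin_widens_intervals_under_overdispersion(self, small_design):
        X, y = small_design
        pois = PoissonFlowModel(features=SIMPLE_FEATURES, interactions=[]).fit(X, y)
        nb = NegativeBinomialFlowModel(features=SIMPLE_FEATURES,
                                       interactions=[]).fit(X, y)
        wp = pois.predict_interval(X)
        wn = nb.predict_interval(X)
        assert (wn["hi"] - wn["lo"]).median() > (wp["hi"] - wp["lo"]).median()


class TestMixedLognormal:
    def test_forced_zero_components_reduce_to_ols(self, small_design):
        X, y = small_design
        ols = LognormalFlowModel(features=SIMPLE_FEATURES).fit(X, y)
        mixed = MixedLognormalFlowModel(
            features=SIMPLE_FEATURES, interactions=[],
            variance_ratios={"origin": 0, "dest": 0, "degree_link_type": 0},
        ).fit(X, y)
        for name, value in ols.coefficients_.items():
            assert mixed.coefficients_[name] == pytest.approx(value, abs=1e-6)
        assert all(v == 0 for v in mixed.variance_components_.values())

    def test_matches_lme4_reference(self, small_design, tmp_path):
        X, y = small_design
        feats = ["log_pop_i", "log_pop_j", "inv_distance", "same_country",
                 "log_maxc"]
        mine = MixedLognormalFlowModel(features=feats, interactions=[]).fit(X, y)
        df = X[["origin", "dest", "degree_link_type"] + feats].copy()
        df["logy"] = np.log(y)
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "ref.R"
        script.write_text(f"""
suppressMessages({{library(lme4); library(jsonlite)}})
d <- read.csv("{csv}")
f <- lmer(logy ~ log_pop_i+log_pop_j+inv_distance+same_country+log_maxc+
          (1|origin)+(1|dest)+(1|degree_link_type), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(f))
cat(toJSON(list(fixef=as.list(fixef(f)),
                vc=setNames(as.list(vc$vcov), vc$grp)), digits=10, auto_unbox=TRUE))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        assert mine.coefficients_["intercept"] == pytest.approx(
            ref["fixef"]["(Intercept)"], abs=1e-3)
        for name in feats:
            assert mine.coefficients_[name] == pytest.approx(
                ref["fixef"][name], rel=1e-3, abs=1e-5)
        for term in ("origin", "dest", "degree_link_type"):
            assert mine.variance_components_[term] == pytest.approx(
                ref["vc"][term], rel=1e-3, abs=1e-6)
        assert mine.sigma2_ == pytest.approx(ref["vc"]["Residual"], rel=1e-3)

    def test_single_seed_variance_recovery_within_tolerance(self):
        truth = GravityTruth(fixed_coefficients=dict(SIMPLE_TRUTH, intercept=-5.0),
                             sigma_origin=0.5, sigma_dest=0, sigma_hierarchy=0,
                             sigma_resid=0.3)
        w = od.simulate_world(n_airports=400, mean_degree=8, n_flows=5000,
                              truth=truth, seed=0)
        X, y = design_for(w)
        model = MixedLognormalFlowModel(features=SIMPLE_FEATURES, interactions=[],
                                        random_effects=("origin",)).fit(X, y)
        assert model.variance_components_["origin"] == pytest.approx(0.25, rel=0.25)
        assert model.sigma2_ == pytest.approx(0.09, rel=0.25)
        for name, true in truth.fixed_coefficients.items():
            se = model.coef_se_[name]
            assert abs(model.coefficients_[name] - true) < 2 * se, name

    def test_unseen_group_gets_zero_blup_and_wider_interval(self, small_design):
        X, y = small_design
        model = MixedLognormalFlowModel(features=SIMPLE_FEATURES,
                                        interactions=[]).fit(X, y)
        row = X.head(1).copy()
        seen = model.predict_interval(row)
        row_unseen = row.copy()
        row_unseen["origin"] = "ZZZ"
        unseen = model.predict_interval(row_unseen)
        width = np.log(seen["hi"][0]) - np.log(seen["lo"][0])
        width_unseen = np.log(unseen["hi"][0]) - np.log(unseen["lo"][0])
        assert width_unseen > width

    def test_interval_brackets_point(self, small_design):
        X, y = small_design
        model = MixedLognormalFlowModel(features=SIMPLE_FEATURES,
                                        interactions=[]).fit(X, y)
        out = model.predict_interval(X)
        assert (out["lo"] <= out["point"]).all()
        assert (out["point"] <= out["hi"]).all()


class TestSharedBehaviour:
    def test_predictions_invariant_to_row_order(self, small_design):
        X, y = small_design
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(X))
        for family in ("lognormal_main", "lognormal_mixed"):
            kwargs = {"features": SIMPLE_FEATURES}
            if family == "lognormal_mixed":
                kwargs["interactions"] = []
            model = make_model(family, **kwargs).fit(X, y)
            direct = model.predict(X)
            shuffled = model.predict(X.iloc[perm])
            np.testing.assert_allclose(shuffled, direct[perm], rtol=1e-12)

    def test_unseen_categorical_level_named_in_error(self, small_design):
        X, y = small_design
        train = X[X["stops"].astype(str) != "2"]
        model = LognormalFlowModel(features=SIMPLE_FEATURES).fit(
            train, y[(X["stops"].astype(str) != "2").to_numpy()])
        with pytest.raises(ValueError, match="'2'"):
            model.predict(X[X["stops"].astype(str) == "2"])

    @pytest.mark.parametrize("family", ["lognormal_main", "poisson_interactions",
                                        "negbin_interactions", "lognormal_mixed"])
    def test_serialization_round_trip(self, small_design, family):
        X, y = small_design
        kwargs = {"features": SIMPLE_FEATURES, "interactions": []}
        if family == "lognormal_main":
            kwargs.pop("interactions")
        model = make_model(family, **kwargs).fit(X, y)
        clone = model_from_dict(json.loads(json.dumps(model.to_dict())))
        np.testing.assert_allclose(clone.predict(X.head(30)),
                                   model.predict(X.head(30)), rtol=1e-12)
        out = clone.predict_interval(X.head(5))
        assert list(out.columns) == ["point", "lo", "hi"]

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone
        model = MixedLognormalFlowModel(features=SIMPLE_FEATURES,
                                        mean_correction=True)
        twin = clone(model)
        assert twin.get_params() == model.get_params()
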