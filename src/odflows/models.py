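"""Spatial-interaction (gravity-type) flow models.

Four competing specifications for annual OD passenger flows P_ij, all sharing
the same covariate surface (log-transformed node masses, route separation and
hierarchy link types):

1. ``LognormalFlowModel`` — OLS on log P_ij, main effects only; the classic
   log-linear gravity model.
2. ``PoissonFlowModel`` — Poisson GLM with log link, main effects plus
   two-way interactions.
3. ``NegativeBinomialFlowModel`` — NB2 GLM with log link, accommodating
   overdispersion; dispersion alpha estimated by maximum likelihood.
4. ``MixedLognormalFlowModel`` — lognormal mixed model with the same fixed
   effects plus crossed random intercepts on origin airport, destination
   airport and the degree-link-type group, fitted by REML.  Flows are
   independent across degree-link-type groups but correlated within one.

All estimators follow the scikit-learn protocol: ``fit(X, y)`` with ``X`` a
covariate DataFrame (as produced by :func:`odflows.covariates.build_design`)
and ``y`` positive flows; fitted attributes carry a trailing underscore; they
compose with ``sklearn.base.clone`` and pipelines.  ``predict_interval``
returns point predictions with 95% prediction bounds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._reml import fit_crossed_reml

#: default fixed-effect covariate set (Table-style node + route characteristics)
DEFAULT_FEATURES = [
    "log_pop_i", "log_pop_j", "log_ppp_i", "log_ppp_j",
    "log_pda_i", "log_pda_j", "log_strength_i", "log_strength_j",
    "log_degree_out_i", "log_degree_in_j",
    "log_closeness_i", "log_closeness_j",
    "log_betweenness_i", "log_betweenness_j",
    "inv_distance", "same_country", "n_alternatives", "log_maxc",
    "stops", "haul_type", "degree_link_type", "economic_link_type",
]

#: default two-way interaction set; the full categorical cross is
#: combinatorially explosive, so a curated list is used and configurable.
DEFAULT_INTERACTIONS = [
    ("stops", "inv_distance"),
    ("haul_type", "inv_distance"),
    ("stops", "same_country"),
    ("degree_link_type", "log_maxc"),
]

_KNOWN_CATEGORICAL = {"stops", "haul_type", "degree_link_type", "economic_link_type"}

Z95 = float(st.norm.ppf(0.975))


class DesignEncoder:
    """Freeze a covariate frame into a numeric design matrix.

    Numeric columns pass through; categorical columns are one-hot encoded
    with the first (sorted) level as reference.  Interactions are columnwise
    products of the encoded blocks.  Levels are frozen at fit; unseen levels
    at transform raise ``ValueError`` naming the level.
    """

    def __init__(self, features, interactions):
        self.features = list(features)
        self.interactions = [tuple(p) for p in interactions]
        self.levels_: dict[str, list] = {}

    def _is_categorical(self, X, col):
        return (col in _KNOWN_CATEGORICAL
                or isinstance(X[col].dtype, pd.CategoricalDtype)
                or X[col].dtype == object)

    def fit(self, X: pd.DataFrame):
        for col in self.features:
            if col not in X.columns:
                raise KeyError(f"design frame missing covariate {col!r}")
            if self._is_categorical(X, col):
                self.levels_[col] = sorted(pd.unique(X[col].astype(str)))
        return self

    def _block(self, X, col):
        """Encoded columns and names for one covariate."""
        if col in self.levels_:
            vals = X[col].astype(str).to_numpy()
            levels = self.levels_[col]
            unseen = set(vals) - set(levels)
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(unseen)} in categorical {col!r}")
            cols = [(vals == lv).astype(float) for lv in levels[1:]]
            names = [f"{col}[{lv}]" for lv in levels[1:]]
            return cols, names
        return [X[col].to_numpy(dtype=float)], [col]

    def transform(self, X: pd.DataFrame):
        n = len(X)
        cols = [np.ones(n)]
        names = ["intercept"]
        blocks = {}
        for col in self.features:
            b, nm = self._block(X, col)
            blocks[col] = (b, nm)
            cols.extend(b)
            names.extend(nm)
        for a, b in self.interactions:
            for col in (a, b):
                if col not in blocks:
                    blocks[col] = self._block(X, col)
            for ca, na in zip(*blocks[a]):
                for cb, nb in zip(*blocks[b]):
                    cols.append(ca * cb)
                    names.append(f"{na}:{nb}")
        return np.column_stack(cols), names

    def to_dict(self):
        return {"features": self.features,
                "interactions": [list(p) for p in self.interactions],
                "levels": self.levels_}

    @classmethod
    def from_dict(cls, d):
        enc = cls(d["features"], [tuple(p) for p in d["interactions"]])
        enc.levels_ = {k: list(v) for k, v in d["levels"].items()}
        return enc


def _check_rank(M: np.ndarray, names):
    """Raise on rank deficiency, naming the aliased columns."""
    r = np.linalg.matrix_rank(M)
    if r < M.shape[1]:
        import scipy.linalg as sla
        _, _, pivots = sla.qr(M, mode="economic", pivoting=True)
        aliased = sorted(names[i] for i in pivots[r:])
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({r}/{M.shape[1]}); aliased columns: {aliased}")


def _validate_xy(X, y, min_flow=1.0):
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if np.any(y < min_flow):
        raise ValueError(f"flows must be >= {min_flow}")
    return y


class BaseFlowModel(RegressorMixin, BaseEstimator):
    """Shared covariate handling for the four flow specifications."""

    family = "base"

    def __init__(self, features=None, interactions=None):
        self.features = features
        self.interactions = interactions

    def _default_interactions(self):
        return DEFAULT_INTERACTIONS

    def _make_encoder(self, X):
        features = list(self.features) if self.features is not None else list(DEFAULT_FEATURES)
        inter = (self._default_interactions() if self.interactions is None
                 else list(self.interactions))
        enc = DesignEncoder(features, inter).fit(X)
        return enc

    def _design(self, X, fit=False):
        if fit:
            self.encoder_ = self._make_encoder(X)
        check_is_fitted(self, "encoder_")
        M, names = self.encoder_.transform(X)
        if fit:
            if len(X) < M.shape[1] + 1:
                raise ValueError("fewer observations than fixed-effect parameters")
            if len(X) < 10 * M.shape[1]:
                warnings.warn("fewer than 10 observations per fixed-effect "
                              "parameter; estimates may be unstable", stacklevel=3)
            _check_rank(M, names)
            self.feature_names_ = names
        return M, names

    def predict_interval(self, X, level=0.95) -> pd.DataFrame:
        """Point prediction with prediction-interval bounds.

        Returns a frame with columns point, lo, hi (index aligned with X).
        """
        raise NotImplementedError

    # -- shared serialization helpers ------------------------------------
    def _state_dict(self):
        return {
            "family": self.family,
            "params": self.get_params(),
            "encoder": self.encoder_.to_dict(),
            "feature_names": self.feature_names_,
            "coefficients": {k: float(v) for k, v in self.coefficients_.items()},
            "coef_se": {k: float(v) for k, v in self.coef_se_.items()},
            "n_obs": int(self.n_obs_),
            "converged": bool(self.converged_),
        }

    def _load_state(self, d):
        self.encoder_ = DesignEncoder.from_dict(d["encoder"])
        self.feature_names_ = list(d["feature_names"])
        self.coefficients_ = dict(d["coefficients"])
        self.coef_se_ = dict(d["coef_se"])
        self.n_obs_ = d["n_obs"]
        self.converged_ = d["converged"]
        self.coef_ = np.array([self.coefficients_[n] for n in self.feature_names_])


class LognormalFlowModel(BaseFlowModel):
    """Log-linear gravity model: OLS of log P_ij on main effects.

    ``mean_correction`` switches the back-transform from the naive
    exp(linear predictor) (the lognormal median) to the mean-unbiased
    exp(lp + sigma^2/2).
    """

    family = "lognormal_main"

    def __init__(self, features=None, interactions=(), mean_correction=False):
        super().__init__(features=features, interactions=interactions)
        self.mean_correction = mean_correction

    def _default_interactions(self):
        return []

    def fit(self, X, y):
        y = _validate_xy(X, y)
        M, names = self._design(X, fit=True)
        res = sm.OLS(np.log(y), M).fit()
        self.coef_ = res.params
        self.coefficients_ = dict(zip(names, res.params))
        self.coef_se_ = dict(zip(names, res.bse))
        self.cov_beta_ = np.asarray(res.cov_params())
        self.sigma2_ = float(res.mse_resid)
        self.dispersion_ = self.sigma2_
        self.n_obs_ = len(y)
        self.converged_ = True
        return self

    def _linpred(self, X):
        M, _ = self._design(X)
        lp = M @ self.coef_
        var_fix = np.einsum("ij,jk,ik->i", M, self.cov_beta_, M)
        return lp, var_fix

    def predict(self, X):
        lp, _ = self._linpred(X)
        shift = self.sigma2_ / 2.0 if self.mean_correction else 0.0
        return np.exp(lp + shift)

    def predict_interval(self, X, level=0.95):
        lp, var_fix = self._linpred(X)
        z = float(st.norm.ppf(0.5 + level / 2.0))
        sd = np.sqrt(var_fix + self.sigma2_)
        shift = self.sigma2_ / 2.0 if self.mean_correction else 0.0
        return pd.DataFrame({
            "point": np.exp(lp + shift),
            "lo": np.exp(lp - z * sd),
            "hi": np.exp(lp + shift + z * sd) if shift > 0 else np.exp(lp + z * sd),
        }, index=getattr(X, "index", None))

    def to_dict(self):
        d = self._state_dict()
        d.update(sigma2=self.sigma2_, cov_beta=self.cov_beta_.tolist())
        return d

    @classmethod
    def from_dict(cls, d):
        m = cls(**d["params"])
        m._load_state(d)
        m.sigma2_ = m.dispersion_ = float(d["sigma2"])
        m.cov_beta_ = np.asarray(d["cov_beta"])
        return m


class _CountFlowModel(BaseFlowModel):
    """Shared machinery for the Poisson / negative-binomial GLMs."""

    def _fit_glm(self, M, y):
        raise NotImplementedError

    def fit(self, X, y):
        y = _validate_xy(X, y)
        M, names = self._design(X, fit=True)
        params, bse, cov = self._fit_glm(M, np.round(y).astype(np.int64))
        self.coef_ = params
        self.coefficients_ = dict(zip(names, params))
        self.coef_se_ = dict(zip(names, bse))
        self.cov_beta_ = cov
        self.n_obs_ = len(y)
        return self

    def predict(self, X):
        M, _ = self._design(X)
        return np.exp(M @ self.coef_)

    def _count_quantiles(self, mu, level):
        raise NotImplementedError

    def predict_interval(self, X, level=0.95):
        mu = self.predict(X)
        lo, hi = self._count_quantiles(mu, level)
        return pd.DataFrame({"point": mu, "lo": lo, "hi": hi},
                            index=getattr(X, "index", None))


class PoissonFlowModel(_CountFlowModel):
    """Poisson log-link GLM with main effects and two-way interactions.

    Prediction intervals are quantiles of the Poisson distribution at the
    predicted mean — very narrow for large flows, which is exactly the
    under-coverage this specification exhibits on overdispersed data.
    """

    family = "poisson_interactions"

    def _fit_glm(self, M, y):
        res = sm.GLM(y, M, family=sm.families.Poisson()).fit()
        self.dispersion_ = 1.0
        self.converged_ = bool(res.converged)
        return np.asarray(res.params), np.asarray(res.bse), np.asarray(res.cov_params())

    def _count_quantiles(self, mu, level):
        a = (1.0 - level) / 2.0
        return st.poisson.ppf(a, mu), st.poisson.ppf(1.0 - a, mu)

    def to_dict(self):
        return self._state_dict()

    @classmethod
    def from_dict(cls, d):
        m = cls(**d["params"])
        m._load_state(d)
        m.dispersion_ = 1.0
        return m


class NegativeBinomialFlowModel(_CountFlowModel):
    """NB2 log-link GLM; the dispersion alpha is estimated by ML.

    Var(y) = mu + alpha * mu^2; alpha -> 0 recovers the Poisson model.
    """

    family = "negbin_interactions"

    def _fit_glm(self, M, y):
        from statsmodels.discrete.discrete_model import NegativeBinomial
        start = sm.GLM(y, M, family=sm.families.Poisson()).fit().params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = NegativeBinomial(y, M, loglike_method="nb2").fit(
                start_params=np.append(start, 0.05), method="bfgs",
                maxiter=500, disp=0)
        self.dispersion_ = float(max(res.params[-1], 1e-10))
        self.converged_ = bool(res.mle_retvals.get("converged", True))
        params = np.asarray(res.params[:-1])
        bse = np.asarray(res.bse[:-1])
        cov = np.asarray(res.cov_params())[:-1, :-1]
        return params, bse, cov

    def _count_quantiles(self, mu, level):
        a = (1.0 - level) / 2.0
        alpha = self.dispersion_
        size = 1.0 / alpha
        p = size / (size + mu)
        return st.nbinom.ppf(a, size, p), st.nbinom.ppf(1.0 - a, size, p)

    def to_dict(self):
        d = self._state_dict()
        d["dispersion"] = self.dispersion_
        return d

    @classmethod
    def from_dict(cls, d):
        m = cls(**d["params"])
        m._load_state(d)
        m.dispersion_ = float(d["dispersion"])
        return m


class MixedLognormalFlowModel(BaseFlowModel):
    """Lognormal mixed model with crossed random intercepts (REML).

    Random intercepts on the origin airport, the destination airport, and the
    degree-link-type group: flows sharing an endpoint or a hierarchy stratum
    are correlated; flows in different degree-link-type groups are
    independent.  The grouping columns must be present in ``X`` (``origin``,
    ``dest``, ``degree_link_type`` by default).

    Prediction uses the conditional-mean (BLUP) intercept for groups seen in
    training and 0 for unseen ones; the interval variance adds the fixed-
    effect variance, the residual variance, and for each random term either
    the BLUP's conditional variance (seen) or the full component variance
    (unseen).
    """

    family = "lognormal_mixed"

    def __init__(self, features=None, interactions=None,
                 random_effects=("origin", "dest", "degree_link_type"),
                 mean_correction=False, variance_ratios=None):
        super().__init__(features=features, interactions=interactions)
        self.random_effects = random_effects
        self.mean_correction = mean_correction
        # optional map term -> fixed sigma_k^2/sigma^2 ratio (0 drops the
        # term entirely; all-zero reduces the fit to OLS)
        self.variance_ratios = variance_ratios

    def _make_encoder(self, X):
        features = list(self.features) if self.features is not None else [
            f for f in DEFAULT_FEATURES if f not in self.random_effects]
        inter = (self._default_interactions() if self.interactions is None
                 else list(self.interactions))
        inter = [p for p in inter
                 if p[0] not in self.random_effects and p[1] not in self.random_effects]
        return DesignEncoder(features, inter).fit(X)

    def fit(self, X, y):
        y = _validate_xy(X, y)
        M, names = self._design(X, fit=True)
        groups = {}
        for term in self.random_effects:
            if term not in X.columns:
                raise KeyError(f"random-effect column {term!r} missing from design")
            groups[term] = X[term].astype(str).to_numpy()
        fixed_ll = None
        if self.variance_ratios is not None:
            fixed_ll = {t: float(np.log(r)) for t, r in self.variance_ratios.items()
                        if r > 0}
            groups = {t: g for t, g in groups.items() if t in fixed_ll}
        res = fit_crossed_reml(M, np.log(y), groups, fixed_log_lambda=fixed_ll)
        self.coef_ = res.beta
        self.coefficients_ = dict(zip(names, res.beta))
        self.coef_se_ = dict(zip(names, np.sqrt(np.diag(res.cov_beta))))
        self.cov_beta_ = res.cov_beta
        self.sigma2_ = res.sigma2
        self.dispersion_ = res.sigma2
        self.variance_components_ = {t: res.varcomps.get(t, 0.0)
                                     for t in self.random_effects}
        self.blups_ = {t: ({str(lv): (float(u), float(cv))
                            for lv, u, cv in zip(*res.blups[t])}
                           if t in res.blups else {})
                       for t in self.random_effects}
        self.n_obs_ = len(y)
        self.converged_ = res.converged
        if not res.converged:
            raise RuntimeError(f"REML did not converge after {res.n_iter} evaluations")
        return self

    def _linpred(self, X):
        M, _ = self._design(X)
        lp = M @ self.coef_
        var = np.einsum("ij,jk,ik->i", M, self.cov_beta_, M)
        for term in self.random_effects:
            codes = X[term].astype(str).to_numpy()
            table = self.blups_[term]
            comp = self.variance_components_[term]
            add = np.empty(len(codes))
            addv = np.empty(len(codes))
            for i, c in enumerate(codes):
                if c in table:
                    u, cv = table[c]
                    add[i], addv[i] = u, cv
                else:
                    add[i], addv[i] = 0.0, comp
            lp = lp + add
            var = var + addv
        return lp, var

    def predict(self, X):
        lp, _ = self._linpred(X)
        shift = self.sigma2_ / 2.0 if self.mean_correction else 0.0
        return np.exp(lp + shift)

    def predict_interval(self, X, level=0.95):
        lp, var = self._linpred(X)
        z = float(st.norm.ppf(0.5 + level / 2.0))
        sd = np.sqrt(var + self.sigma2_)
        shift = self.sigma2_ / 2.0 if self.mean_correction else 0.0
        return pd.DataFrame({
            "point": np.exp(lp + shift),
            "lo": np.exp(lp - z * sd),
            "hi": np.exp(lp + shift + z * sd) if shift > 0 else np.exp(lp + z * sd),
        }, index=getattr(X, "index", None))

    def to_dict(self):
        d = self._state_dict()
        d["params"] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in d["params"].items()}
        d.update(sigma2=self.sigma2_, cov_beta=self.cov_beta_.tolist(),
                 variance_components=self.variance_components_,
                 blups=self.blups_)
        return d

    @classmethod
    def from_dict(cls, d):
        params = dict(d["params"])
        if isinstance(params.get("random_effects"), list):
            params["random_effects"] = tuple(params["random_effects"])
        m = cls(**params)
        m._load_state(d)
        m.sigma2_ = m.dispersion_ = float(d["sigma2"])
        m.cov_beta_ = np.asarray(d["cov_beta"])
        m.variance_components_ = dict(d["variance_components"])
        m.blups_ = {t: {k: tuple(v) for k, v in tab.items()}
                    for t, tab in d["blups"].items()}
        return m


MODEL_FAMILIES = {
    "lognormal_main": LognormalFlowModel,
    "poisson_interactions": PoissonFlowModel,
    "negbin_interactions": NegativeBinomialFlowModel,
    "lognormal_mixed": MixedLognormalFlowModel,
}


def make_model(family: str, **kwargs) -> BaseFlowModel:
    """Instantiate one of the four flow-model specifications by name."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}; "
                         f"choose from {sorted(MODEL_FAMILIES)}")
    return MODEL_FAMILIES[family](**kwargs)


def model_from_dict(d: dict) -> BaseFlowModel:
    return MODEL_FAMILIES[d["family"]].from_dict(d)


def predict_with_interval(model: BaseFlowModel, X: pd.DataFrame,
                          level: float = 0.95) -> pd.DataFrame:
    """Prediction records: origin, dest, stops, point, lo, hi."""
    out = model.predict_interval(X, level=level)
    rec = pd.DataFrame({
        "origin": X["origin"].to_numpy() if "origin" in X else "",
        "dest": X["dest"].to_numpy() if "dest" in X else "",
        "stops": X["stops"].to_numpy() if "stops" in X else -1,
    }, index=out.index)
    return pd.concat([rec, out], axis=1)
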