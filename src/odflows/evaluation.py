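"""Model evaluation: CV, coverage criteria, magnitude errors, multilevel R2.

Three headline criteria compare observed and predicted flows:

* 95% prediction-interval coverage — share of observations inside the
  model's stated intervals;
* +/-30% observation-band coverage — share of predictions within 30% of the
  observation (inclusive at both ends);
* successful prediction rate — share of predictions landing in the observed
  flow's magnitude category (decade bins: <=1e2, 1e2-1e3, 1e3-1e4, 1e4-1e5,
  >1e5).

RMSE/MAE are reported per magnitude category of the observation.  10-fold
cross-validation reports per-fold [min, max] ranges alongside averages.
A Snijders-Bosker style proportional-reduction-in-variance R2 summarises
the mixed model at the observation level (level 1) and the group level
(level 2), and a geometric-mean log-ratio diagnostic compares predictions
(or raw seat capacities) to observed flows on direct routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.base import clone

MAGNITUDE_EDGES = (100.0, 1_000.0, 10_000.0, 100_000.0)


def magnitude_category(flow) -> int | np.ndarray:
    """Decade bin of a flow: 1 (<=100) through 5 (>100,000)."""
    arr = np.asarray(flow, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("flows must be positive")
    cat = 1 + np.searchsorted(MAGNITUDE_EDGES, arr, side="left")
    # values exactly at an edge belong to the lower category
    return int(cat) if arr.ndim == 0 else cat


def _paired(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0:
        raise ValueError("empty input")
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    return obs, pred


def success_rate(observed, predicted) -> float:
    """Percent of predictions in the observed flow's magnitude category."""
    obs, pred = _paired(observed, predicted)
    return 100.0 * float(np.mean(magnitude_category(obs) == magnitude_category(pred)))


def band30_coverage(observed, predicted) -> float:
    """Percent of predictions within +/-30% of the observation (inclusive)."""
    obs, pred = _paired(observed, predicted)
    inside = (pred >= 0.7 * obs) & (pred <= 1.3 * obs)
    return 100.0 * float(np.mean(inside))


def pi_coverage(observed, lo, hi) -> float:
    """Percent of observations inside their prediction intervals."""
    obs = np.asarray(observed, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if obs.size == 0:
        raise ValueError("empty input")
    if np.any(lo > hi):
        raise ValueError("crossed interval bounds")
    return 100.0 * float(np.mean((obs >= lo) & (obs <= hi)))


def error_by_category(observed, predicted) -> pd.DataFrame:
    """RMSE and MAE grouped by the observation's magnitude category."""
    obs, pred = _paired(observed, predicted)
    cat = magnitude_category(obs)
    rows = []
    for c in sorted(np.unique(cat)):
        m = cat == c
        err = pred[m] - obs[m]
        rows.append({"category": int(c), "n": int(m.sum()),
                     "rmse": float(np.sqrt(np.mean(err ** 2))),
                     "mae": float(np.mean(np.abs(err)))})
    return pd.DataFrame(rows).set_index("category")


def log_ratio_diagnostic(observed, values, method: str = "ratio_of_logs") -> dict:
    """Geometric-mean log-ratio of predictions (or capacities) to observations.

    With ``method="ratio_of_logs"`` the per-pair ratio is
    log(value)/log(observed); ``"log_of_ratio"`` uses value/observed instead.
    Returns the geometric mean of the ratios with a normal-theory 95% CI and
    a paired t-test of log(value) vs log(observed).  All inputs must exceed
    1 so that the logs are positive.
    """
    obs, val = _paired(observed, values)
    bad = np.flatnonzero((obs <= 1) | (val <= 1))
    if bad.size:
        raise ValueError(f"values must exceed 1 for log ratios; rows {bad[:5].tolist()}")
    if method == "ratio_of_logs":
        r = np.log(val) / np.log(obs)
    elif method == "log_of_ratio":
        r = val / obs
    else:
        raise ValueError(f"unknown method {method!r}")
    logr = np.log(r)
    gm = float(np.exp(logr.mean()))
    diff = np.log(val) - np.log(obs)
    spread = diff.std(ddof=1) if len(r) > 1 else 0.0
    if spread > 1e-12 * max(1.0, float(np.abs(diff).max())):
        se = logr.std(ddof=1) / np.sqrt(len(r))
        with np.errstate(all="ignore"):
            tt = st.ttest_rel(np.log(val), np.log(obs))
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    elif float(np.abs(diff).max()) > 1e-12:
        # constant nonzero log-difference: exactly significant
        se, t_stat, p = 0.0, float(np.inf) * np.sign(diff.mean()), 0.0
    else:
        # identical series: zero difference, nothing to test
        se, t_stat, p = 0.0, 0.0, 1.0
    z = float(st.norm.ppf(0.975))
    return {"geometric_mean_ratio": gm,
            "ci95": (float(np.exp(logr.mean() - z * se)),
                     float(np.exp(logr.mean() + z * se))),
            "t_statistic": t_stat, "p_value": p, "n": int(len(r))}


@dataclass
class EvaluationReport:
    """Cross-validation summary: criterion averages with per-fold ranges."""

    pi_coverage_pct: float
    band30_coverage_pct: float
    success_rate_pct: float
    pi_coverage_range: tuple
    band30_coverage_range: tuple
    success_rate_range: tuple
    rmse_by_category: dict = field(default_factory=dict)
    mae_by_category: dict = field(default_factory=dict)
    n_by_category: dict = field(default_factory=dict)
    fold_metrics: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)


def kfold_assignments(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition into k near-equal folds (sizes differ <= 1)."""
    if n < k:
        raise ValueError("need at least k observations")
    rng = np.random.default_rng(seed)
    return [np.sort(part) for part in np.array_split(rng.permutation(n), k)]


def kfold_cv(model, X: pd.DataFrame, y, k: int = 10, seed: int = 0,
             level: float = 0.95) -> EvaluationReport:
    """K-fold cross-validation of a flow model with the three criteria.

    The model is cloned and refitted on each training complement and
    evaluated on the held-out fold; metrics are averaged over folds with
    [min, max] ranges.  RMSE/MAE by category are pooled over the
    concatenated out-of-fold predictions.
    """
    y = np.asarray(y, dtype=float)
    folds = kfold_assignments(len(y), k, seed)
    per_fold = []
    all_obs, all_pred = [], []
    for i, test_idx in enumerate(folds):
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        try:
            fitted = clone(model).fit(X.iloc[~mask], y[~mask])
            pred = fitted.predict_interval(X.iloc[mask], level=level)
        except Exception as exc:
            raise RuntimeError(f"model fit failed in fold {i}: {exc}") from exc
        obs = y[mask]
        per_fold.append({
            "fold": i,
            "n": int(mask.sum()),
            "pi_coverage": pi_coverage(obs, pred["lo"], pred["hi"]),
            "band30_coverage": band30_coverage(obs, pred["point"]),
            "success_rate": success_rate(obs, pred["point"]),
        })
        all_obs.append(obs)
        all_pred.append(pred["point"].to_numpy())
    obs = np.concatenate(all_obs)
    pred = np.concatenate(all_pred)
    errs = error_by_category(obs, np.maximum(pred, 1e-12))

    def stats(key):
        vals = [f[key] for f in per_fold]
        return float(np.mean(vals)), (float(min(vals)), float(max(vals)))

    pi_avg, pi_rng = stats("pi_coverage")
    b_avg, b_rng = stats("band30_coverage")
    s_avg, s_rng = stats("success_rate")
    return EvaluationReport(
        pi_coverage_pct=pi_avg, band30_coverage_pct=b_avg, success_rate_pct=s_avg,
        pi_coverage_range=pi_rng, band30_coverage_range=b_rng,
        success_rate_range=s_rng,
        rmse_by_category={int(c): float(v) for c, v in errs["rmse"].items()},
        mae_by_category={int(c): float(v) for c, v in errs["mae"].items()},
        n_by_category={int(c): int(v) for c, v in errs["n"].items()},
        fold_metrics=per_fold,
    )


def multilevel_r2(full_model, null_model, group: str = "degree_link_type",
                  group_sizes=None) -> dict:
    """Snijders-Bosker proportional reduction in variance, as percentages.

    ``full_model`` and ``null_model`` (intercept-only, same random-effect
    structure, same rows) must expose ``sigma2_`` and
    ``variance_components_``.  Level 1 compares total residual + random
    variance; level 2 compares sigma2/B + random variance with B a
    representative (harmonic mean) size of the level-2 ``group``.
    """
    if full_model.n_obs_ != null_model.n_obs_:
        raise ValueError("full and null fits must use the same rows")

    def total(m):
        return m.sigma2_ + sum(m.variance_components_.values())

    lvl1 = 1.0 - total(full_model) / total(null_model)
    if group_sizes is not None:
        sizes = np.asarray(group_sizes, dtype=float)
        B = len(sizes) / np.sum(1.0 / sizes)
    else:
        B = full_model.n_obs_ / max(len(full_model.blups_.get(group, {1: 0})), 1)

    def lvl2_var(m):
        return m.sigma2_ / B + sum(m.variance_components_.values())

    lvl2 = 1.0 - lvl2_var(full_model) / lvl2_var(null_model)
    return {"level1_r2_pct": 100.0 * lvl1, "level2_r2_pct": 100.0 * lvl2,
            "group_size_B": float(B)}


def comparison_table(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Model-comparison table: criterion averages and CV ranges per model."""
    rows = []
    for name, r in reports.items():
        rows.append({
            "model": name,
            "pi_coverage_avg": r.pi_coverage_pct,
            "pi_coverage_range": f"[{r.pi_coverage_range[0]:.2f},{r.pi_coverage_range[1]:.2f}]",
            "band30_avg": r.band30_coverage_pct,
            "band30_range": f"[{r.band30_coverage_range[0]:.2f},{r.band30_coverage_range[1]:.2f}]",
            "success_avg": r.success_rate_pct,
            "success_range": f"[{r.success_rate_range[0]:.2f},{r.success_rate_range[1]:.2f}]",
        })
    return pd.DataFrame(rows).set_index("model")
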