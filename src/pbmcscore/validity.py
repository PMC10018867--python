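"""Construct- and predictive-validity regressions.

Each variable is regressed on the barrier score in a univariate model:
linear for continuous variables (coefficient estimates, CE), logistic for
binary (odds ratios, OR), multinomial logistic for polytomous
(relative-risk ratios, RRR), Poisson for counts (incidence-rate ratios,
IRR).  All fits use sampling weights and a sandwich variance clustered on
the household identifier (CR0).  Predicted outcomes are evaluated at
representative score values (0, 1, 2) with delta-method intervals built on
the linear-predictor scale and back-transformed, so bounds respect the
outcome's range.

Binary/linear/count families are fit through statsmodels (GLM / WLS with
``cov_type="cluster"``); the weighted multinomial logit, which statsmodels
does not weight, is a small in-module Newton fit with an analytic
score-based cluster sandwich.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

FAMILY_ESTIMATE = {
    "linear": "CE",
    "logistic": "OR",
    "multinomial": "RRR",
    "poisson": "IRR",
}

Z95 = stats.norm.ppf(0.975)


class ValidityError(ValueError):
    """Raised for invalid regression inputs or failed fits."""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class RegressionSpec:
    """One univariate validity regression.

    ``subset`` names a boolean column restricting the analysis sample (e.g.
    respondents with a recent illness); ``base_category`` applies to the
    multinomial family only.
    """

    outcome: str
    family: str
    group: str = ""
    subset: str | None = None
    base_category: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_ESTIMATE:
            raise ValidityError(f"unknown family {self.family!r}")

    @property
    def estimate_label(self) -> str:
        return FAMILY_ESTIMATE[self.family]


@dataclass
class ValidityResult:
    """Fit of one univariate regression on the reporting scale.

    For exponentiated families the estimate is exp(slope) with a
    delta-method SE; the p-value is the Wald test of the slope on the link
    scale.  ``params``/``cov`` keep the link-scale intercept+slope and their
    cluster-robust covariance (per category for the multinomial).
    """

    spec: RegressionSpec
    estimate: float | dict[str, float]
    se: float | dict[str, float]
    p_value: float | dict[str, float]
    n: int
    n_clusters: int
    params: np.ndarray | dict[str, np.ndarray]
    cov: np.ndarray | dict[str, np.ndarray]
    converged: bool = True

    def stars(self) -> str | dict[str, str]:
        if isinstance(self.p_value, dict):
            return {k: significance_stars(v) for k, v in self.p_value.items()}
        return significance_stars(self.p_value)


@dataclass
class PredictionSet:
    """Predicted outcomes at representative score values with 95% CIs."""

    points: tuple[float, ...]
    predicted: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    family: str


@dataclass
class CheFlags:
    """Catastrophic-health-expenditure shares and nested threshold flags."""

    share: np.ndarray
    flags: dict[int, np.ndarray] = field(default_factory=dict)


def _prepare(score: pd.Series, spec: RegressionSpec, data) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Align score, outcome, weights and clusters on the analysis sample."""
    df = data.data if hasattr(data, "data") else data
    weight_col = getattr(data, "weight_col", "weight")
    cluster_col = getattr(data, "household_col", "household_id")
    if spec.outcome not in df.columns:
        raise ValidityError(f"outcome {spec.outcome!r} not in data")
    mask = score.notna() & df[spec.outcome].notna()
    if spec.subset is not None:
        mask &= df[spec.subset].astype(bool)
    sub = df.loc[mask]
    y = sub[spec.outcome]
    w = sub[weight_col].astype(float)
    if (w <= 0).any():
        raise ValidityError("sampling weights must be positive")
    g = sub[cluster_col]
    if g.nunique() < 2:
        raise ValidityError("need at least 2 clusters for a clustered variance")
    X = pd.DataFrame({"const": 1.0, "score": score.loc[mask].astype(float)})
    return X, y, w, g


def _fit_mnlogit_weighted(
    y: pd.Series, x: np.ndarray, w: np.ndarray, groups: np.ndarray, base: str | None
) -> tuple[list[str], str, dict[str, np.ndarray], dict[str, np.ndarray], int]:
    """Weighted multinomial logit with cluster-robust (CR0) sandwich.

    Newton-Raphson on the weighted log-likelihood; returns per-category
    link-scale params (intercept, slope) and covariance blocks.
    """
    cats = [str(c) for c in pd.unique(y.astype(str))]
    cats.sort()
    if base is None:
        base = cats[0]
    if base not in cats:
        raise ValidityError(f"base category {base!r} not among outcome levels {cats}")
    others = [c for c in cats if c != base]
    K = len(others)
    if K < 1:
        raise ValidityError("multinomial outcome needs at least 2 levels")
    X = np.column_stack([np.ones_like(x), x])
    n, q = X.shape
    Y = np.zeros((n, K))
    yv = y.astype(str).to_numpy()
    for k, c in enumerate(others):
        Y[:, k] = yv == c

    beta = np.zeros(K * q)

    def probs(b: np.ndarray) -> np.ndarray:
        eta = X @ b.reshape(K, q).T  # n x K
        em = np.exp(eta - eta.max(axis=1, keepdims=True).clip(min=0))
        denom = np.exp(-eta.max(axis=1, keepdims=True).clip(min=0)) + em.sum(axis=1, keepdims=True)
        return em / denom

    for _ in range(100):
        P = probs(beta)
        grad = np.concatenate([((Y[:, k] - P[:, k]) * w) @ X for k in range(K)])
        H = np.zeros((K * q, K * q))
        for k in range(K):
            for l in range(K):
                wkl = w * (P[:, k] * ((k == l) - P[:, l]))
                H[k * q : (k + 1) * q, l * q : (l + 1) * q] = -(X * wkl[:, None]).T @ X
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError as exc:
            raise ValidityError("multinomial fit failed: singular Hessian") from exc
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    else:
        raise ValidityError("multinomial fit did not converge in 100 iterations")

    P = probs(beta)
    # cluster sandwich: A^-1 B A^-1 with per-cluster summed scores
    scores = np.concatenate(
        [((Y[:, k] - P[:, k]) * w)[:, None] * X for k in range(K)], axis=1
    )  # n x (K q)
    dfc = pd.DataFrame(scores)
    dfc["_g"] = groups
    U = dfc.groupby("_g").sum().to_numpy()
    B = U.T @ U
    Ainv = np.linalg.inv(-H)
    G_cl = len(np.unique(groups))
    k_par = K * q
    # same small-sample scaling the GLM cluster sandwich uses
    correction = G_cl / (G_cl - 1) * (n - 1) / max(n - k_par, 1)
    cov_full = correction * (Ainv @ B @ Ainv)
    params = {}
    covs = {}
    b = beta.reshape(K, q)
    for k, c in enumerate(others):
        params[c] = b[k]
        covs[c] = cov_full[k * q : (k + 1) * q, k * q : (k + 1) * q]
    return others, base, params, covs, len(np.unique(groups))


def fit_univariate(score: pd.Series, spec: RegressionSpec, data) -> ValidityResult:
    """Fit one dependent variable on the score with weights and clustering.

    ``data`` is a SurveyDataset (or plain DataFrame with ``weight`` and
    ``household_id`` columns).  The estimate is reported on the family's
    scale: CE for linear, exponentiated slope for OR/IRR/RRR, with a
    delta-method SE of the reported quantity and a two-sided Wald p-value.
    """
    X, y, w, g = _prepare(score, spec, data)
    n = len(y)
    groups = g.to_numpy()

    if spec.family == "multinomial":
        others, base, params, covs, n_cl = _fit_mnlogit_weighted(
            y, X["score"].to_numpy(), w.to_numpy(), groups, spec.base_category
        )
        est, se, pv = {}, {}, {}
        for c in others:
            b1 = params[c][1]
            s1 = np.sqrt(covs[c][1, 1])
            est[c] = float(np.exp(b1))
            se[c] = float(np.exp(b1) * s1)
            pv[c] = float(2 * stats.norm.sf(abs(b1 / s1)))
        return ValidityResult(spec, est, se, pv, n, n_cl, params, covs)

    yv = y.astype(float)
    cov_kwds = {"groups": groups}
    import warnings

    try:
        warn_ctx = warnings.catch_warnings()
        warn_ctx.__enter__()
        # statsmodels flags cov_type with var_weights as not fully supported,
        # but the clustered sandwich it returns matches the manual CR0 with
        # Stata-style small-sample scaling; verified in the test suite.
        warnings.filterwarnings("ignore", message="cov_type not fully supported")
        if spec.family == "linear":
            res = sm.WLS(yv, X, weights=w).fit(cov_type="cluster", cov_kwds=cov_kwds)
        elif spec.family == "logistic":
            uniq = set(np.unique(yv))
            if not uniq <= {0.0, 1.0}:
                raise ValidityError(f"logistic outcome must be binary 0/1, got {sorted(uniq)}")
            res = sm.GLM(yv, X, family=sm.families.Binomial(), var_weights=w).fit(
                cov_type="cluster", cov_kwds=cov_kwds
            )
        elif spec.family == "poisson":
            res = sm.GLM(yv, X, family=sm.families.Poisson(), var_weights=w).fit(
                cov_type="cluster", cov_kwds=cov_kwds
            )
    except ValidityError:
        raise
    except Exception as exc:  # statsmodels raises assorted linalg/perfect-separation errors
        raise ValidityError(f"fit failed for {spec.outcome!r}: {exc}") from exc
    finally:
        warn_ctx.__exit__(None, None, None)
    if not getattr(res, "converged", True):
        raise ValidityError(f"{spec.family} fit did not converge for {spec.outcome!r}")

    b1 = float(res.params.iloc[1])
    s1 = float(res.bse.iloc[1])
    if not np.isfinite(b1) or not np.isfinite(s1) or s1 <= 0:
        raise ValidityError(f"unstable fit for {spec.outcome!r} (slope {b1:.3g}, se {s1:.3g})")
    if spec.family in ("logistic", "poisson") and abs(b1) > 50:
        raise ValidityError(
            f"diverging slope for {spec.outcome!r} ({b1:.3g}); possible perfect separation"
        )
    p_value = float(2 * stats.norm.sf(abs(b1 / s1)))
    if spec.family == "linear":
        estimate, se_rep = b1, s1
    else:
        estimate, se_rep = float(np.exp(b1)), float(np.exp(b1) * s1)
    return ValidityResult(
        spec=spec,
        estimate=estimate,
        se=se_rep,
        p_value=p_value,
        n=n,
        n_clusters=int(pd.Series(groups).nunique()),
        params=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
    )


def _invlink(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "logistic":
        return expit(eta)
    if family == "poisson":
        return np.exp(eta)
    return eta


def predict_from_coefficients(
    intercept: float, slope: float, family: str, points=(0.0, 1.0, 2.0)
) -> np.ndarray:
    """Closed-form predictions: inverse link of intercept + slope * point."""
    pts = np.asarray(points, dtype=float)
    return _invlink(family, intercept + slope * pts)


def predict_at(result: ValidityResult, points=(0.0, 1.0, 2.0)) -> PredictionSet:
    """Predictions at representative score values with delta-method CIs.

    The CI is built on the linear-predictor scale and transformed through
    the inverse link; the reported SE is of the prediction itself
    (derivative of the inverse link times the SE of the linear predictor).
    """
    if result.spec.family == "multinomial":
        raise ValidityError("predict_at supports linear/logistic/poisson fits")
    pts = np.asarray(points, dtype=float)
    if np.any((pts < 0) | (pts > 2)):
        import warnings

        warnings.warn("prediction points outside the score range [0, 2]", stacklevel=2)
    params = np.asarray(result.params, dtype=float)
    cov = np.asarray(result.cov, dtype=float)
    eta = params[0] + params[1] * pts
    var_eta = cov[0, 0] + 2 * pts * cov[0, 1] + pts**2 * cov[1, 1]
    se_eta = np.sqrt(np.clip(var_eta, 0, None))
    pred = _invlink(result.spec.family, eta)
    lo = _invlink(result.spec.family, eta - Z95 * se_eta)
    hi = _invlink(result.spec.family, eta + Z95 * se_eta)
    if result.spec.family == "logistic":
        dmu = pred * (1 - pred)
    elif result.spec.family == "poisson":
        dmu = pred
    else:
        dmu = np.ones_like(pred)
    return PredictionSet(
        points=tuple(pts),
        predicted=pred,
        se=dmu * se_eta,
        ci_low=lo,
        ci_high=hi,
        family=result.spec.family,
    )


def compute_che_flags(oop, nonfood, thresholds=(40, 30, 20)) -> CheFlags:
    """Catastrophic-expenditure flags: OOP health share of non-food spending.

    flag_t = (share >= t/100); by construction the 40% flag implies the 30%
    flag implies the 20% flag.
    """
    oop = np.asarray(oop, dtype=float)
    nonfood = np.asarray(nonfood, dtype=float)
    if np.any(nonfood <= 0):
        raise ValidityError("non-food expenditures must be positive")
    share = oop / nonfood
    flags = {int(t): share >= t / 100.0 for t in thresholds}
    return CheFlags(share=share, flags=flags)


def validity_battery(
    score: pd.Series, data, specs: list[RegressionSpec], predictions_at=None
) -> pd.DataFrame:
    """Run a list of univariate regressions; one output row per estimate.

    Failures of individual specs are recorded in the ``error`` column
    without aborting the battery.  When ``predictions_at`` is given (e.g.
    ``(0, 1, 2)``), prediction columns are added for non-multinomial rows.
    """
    rows = []
    for spec in specs:
        try:
            res = fit_univariate(score, spec, data)
        except ValidityError as exc:
            rows.append(
                {
                    "group": spec.group,
                    "outcome": spec.outcome,
                    "model": spec.family,
                    "estimate_type": spec.estimate_label,
                    "error": str(exc),
                }
            )
            continue
        if isinstance(res.estimate, dict):
            for cat in res.estimate:
                rows.append(
                    {
                        "group": spec.group,
                        "outcome": spec.outcome,
                        "model": spec.family,
                        "estimate_type": f"{spec.estimate_label} ({cat})",
                        "estimate": res.estimate[cat],
                        "se": res.se[cat],
                        "p_value": res.p_value[cat],
                        "stars": significance_stars(res.p_value[cat]),
                        "n": res.n,
                        "error": "",
                    }
                )
        else:
            row = {
                "group": spec.group,
                "outcome": spec.outcome,
                "model": spec.family,
                "estimate_type": spec.estimate_label,
                "estimate": res.estimate,
                "se": res.se,
                "p_value": res.p_value,
                "stars": res.stars(),
                "n": res.n,
                "error": "",
            }
            if predictions_at is not None:
                preds = predict_at(res, predictions_at)
                for pt, pr, se in zip(preds.points, preds.predicted, preds.se):
                    row[f"pred_at_{pt:g}"] = pr
                    row[f"pred_se_at_{pt:g}"] = se
            rows.append(row)
    return pd.DataFrame(rows)
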