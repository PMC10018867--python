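"""Psychometric primitives for ordinal survey items.

Closed-form statistics (KMO, Bartlett sphericity, Cronbach's alpha) and
exploratory factor analysis by principal-axis factoring with optional
varimax rotation.  All statistics operate on listwise-complete rows and
are invariant to row order.

Correlations are Pearson on the 0/1/2 item codes by default, matching the
standard survey-software workflow; a two-step polychoric estimator is
available via ``method="polychoric"``.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats


class PsychometricsError(ValueError):
    """Raised for invalid inputs to psychometric computations."""


# ---------------------------------------------------------------------------
# Correlation matrices


@dataclass
class CorrelationMatrix:
    """Square symmetric matrix of pairwise item correlations.

    Attributes
    ----------
    values : ndarray, shape (p, p)
        Unit-diagonal symmetric correlation matrix.
    items : list of str
        Item labels in matrix order.
    n_obs : int
        Number of listwise-complete rows used.
    method : str
        ``"pearson"`` or ``"polychoric"``.
    """

    values: np.ndarray
    items: list[str]
    n_obs: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p) or len(self.items) != p:
            raise PsychometricsError("correlation matrix must be square with one label per item")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise PsychometricsError("correlation matrix must be symmetric within 1e-10")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise PsychometricsError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise PsychometricsError("correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def subset(self, items: list[str]) -> "CorrelationMatrix":
        idx = [self.items.index(it) for it in items]
        return CorrelationMatrix(self.values[np.ix_(idx, idx)], list(items), self.n_obs, self.method)


def _listwise(items: pd.DataFrame) -> pd.DataFrame:
    complete = items.dropna(axis=0, how="any")
    if len(complete) < 3:
        raise PsychometricsError("need at least 3 complete rows")
    return complete


def correlation_matrix(items: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise item correlations on listwise-complete rows.

    Parameters
    ----------
    items : DataFrame
        One column per item, ordinal codes (0/1/2) or any numeric values.
    method : {"pearson", "polychoric"}

    Raises
    ------
    PsychometricsError
        If fewer than 2 items or 3 complete rows, or an item has zero variance.
    """
    if items.shape[1] < 2:
        raise PsychometricsError("need at least 2 items")
    if method not in ("pearson", "polychoric"):
        raise PsychometricsError(f"unknown correlation method {method!r}")
    complete = _listwise(items)
    variances = complete.var(axis=0, ddof=1)
    dead = [str(c) for c, v in variances.items() if v <= 0]
    if dead:
        raise PsychometricsError(f"zero-variance item(s): {', '.join(dead)}")
    if method == "pearson":
        corr = complete.corr(method="pearson").to_numpy()
    else:
        corr = _polychoric_matrix(complete.to_numpy())
    # clean up round-off so the invariants hold exactly
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, [str(c) for c in items.columns], len(complete), method)


def _polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation of two ordinal variables.

    Thresholds come from the marginal cumulative proportions; the latent
    correlation maximizes the bivariate-normal contingency likelihood.
    """

    def thresholds(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cats, counts = np.unique(v, return_counts=True)
        cum = np.cumsum(counts)[:-1] / len(v)
        return cats, stats.norm.ppf(cum)

    cx, tx = thresholds(x)
    cy, ty = thresholds(y)
    table = np.zeros((len(cx), len(cy)))
    for i, cxi in enumerate(cx):
        for j, cyj in enumerate(cy):
            table[i, j] = np.sum((x == cxi) & (y == cyj))
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    ay = np.concatenate(([-np.inf], ty, [np.inf]))

    def neg_loglik(rho: float) -> float:
        dist = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

        def cdf(a: float, b: float) -> float:
            if a == -np.inf or b == -np.inf:
                return 0.0
            return float(dist.cdf([min(a, 8.0), min(b, 8.0)]))

        ll = 0.0
        for i in range(len(cx)):
            for j in range(len(cy)):
                if table[i, j] == 0:
                    continue
                pr = (
                    cdf(ax[i + 1], ay[j + 1])
                    - cdf(ax[i], ay[j + 1])
                    - cdf(ax[i + 1], ay[j])
                    + cdf(ax[i], ay[j])
                )
                ll += table[i, j] * np.log(max(pr, 1e-300))
        return -ll

    res = optimize.minimize_scalar(neg_loglik, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def _polychoric_matrix(data: np.ndarray) -> np.ndarray:
    p = data.shape[1]
    corr = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            corr[i, j] = corr[j, i] = _polychoric_pair(data[:, i], data[:, j])
    return corr


# ---------------------------------------------------------------------------
# Sampling adequacy


def kmo(corr: CorrelationMatrix) -> tuple[float, pd.Series]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Contrasts raw correlations with anti-image partial correlations:
    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum a_ij^2)`` over i != j, where
    ``a_ij = -inv_ij / sqrt(inv_ii * inv_jj)`` from the inverse correlation
    matrix.  Returns the overall measure and the per-item analogues.
    """
    R = corr.values
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise PsychometricsError(
            "correlation matrix is singular; remove collinear items before computing KMO"
        ) from exc
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    r2 = R**2
    a2 = partial**2
    np.fill_diagonal(r2, 0.0)
    np.fill_diagonal(a2, 0.0)
    overall = r2.sum() / (r2.sum() + a2.sum())
    per_item = r2.sum(axis=1) / (r2.sum(axis=1) + a2.sum(axis=1))
    return float(overall), pd.Series(per_item, index=corr.items, name="kmo")


def bartlett_sphericity(corr: CorrelationMatrix) -> tuple[float, int, float]:
    """Bartlett test that the correlation matrix is an identity.

    statistic = -(n - 1 - (2p + 5)/6) * ln det(R); df = p(p-1)/2; p-value
    from the chi-square distribution.
    """
    p = corr.p
    if corr.n_obs <= p:
        raise PsychometricsError("Bartlett test requires n_obs > number of items")
    det = np.linalg.det(corr.values)
    if det <= 0:
        raise PsychometricsError("correlation matrix has non-positive determinant")
    statistic = -(corr.n_obs - 1 - (2 * p + 5) / 6.0) * np.log(det)
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(statistic, df))
    return float(statistic), df, p_value


# ---------------------------------------------------------------------------
# Reliability


@dataclass
class ReliabilityResult:
    """Cronbach's alpha with corrected item-total correlations."""

    alpha: float
    k_items: int
    item_total: pd.Series
    n_obs: int

    def __post_init__(self) -> None:
        if self.k_items < 2:
            raise PsychometricsError("alpha requires at least 2 items")
        if self.alpha > 1 + 1e-12:
            raise PsychometricsError("alpha cannot exceed 1")


def cronbach_alpha(items: pd.DataFrame, subset: list[str] | None = None) -> ReliabilityResult:
    """Cronbach's alpha on listwise-complete rows.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum).
    Item-total correlations are corrected (each item against the sum of the
    remaining items).
    """
    cols = list(items.columns) if subset is None else list(subset)
    if len(cols) < 2:
        raise PsychometricsError("alpha requires at least 2 items")
    data = _listwise(items[cols])
    total = data.sum(axis=1)
    var_total = total.var(ddof=1)
    if var_total <= 0:
        raise PsychometricsError("zero total variance; alpha undefined")
    k = len(cols)
    alpha = k / (k - 1) * (1 - data.var(ddof=1).sum() / var_total)
    item_total = pd.Series(
        {c: data[c].corr(total - data[c]) for c in cols}, name="item_total_corr"
    )
    return ReliabilityResult(float(alpha), k, item_total, len(data))


# ---------------------------------------------------------------------------
# Factor extraction and rotation


@dataclass
class FactorAnalysisResult:
    """Result of a principal-axis (or principal-component) factor extraction.

    ``eigenvalues`` are those of the reduced correlation matrix (SMC
    communality estimates on the diagonal for principal factoring; unit
    diagonal for principal components), sorted descending.
    ``proportion_variance`` is eigenvalue / number of items, i.e. the share
    of TOTAL item variance, the convention in which one factor of a 5-item
    analysis with eigenvalue 2.13 explains 42.6%.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray  # unrotated, items x retained factors
    rotated_loadings: np.ndarray | None
    communalities: np.ndarray
    n_factors_retained: int
    proportion_variance: np.ndarray
    items: list[str]
    rotation_method: str = "none"
    extraction: str = "pf"

    def __post_init__(self) -> None:
        eig = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(eig) > 1e-10):
            raise PsychometricsError("eigenvalues must be sorted descending")

    @property
    def final_loadings(self) -> np.ndarray:
        return self.loadings if self.rotated_loadings is None else self.rotated_loadings


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations: 1 - 1/diag(R^-1)."""
    try:
        inv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise PsychometricsError("singular correlation matrix; SMC undefined") from exc
    return 1.0 - 1.0 / np.diag(inv)


def _sign_align(L: np.ndarray) -> np.ndarray:
    """Flip each factor so its largest-magnitude loading is positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def extract_factors(
    corr: CorrelationMatrix,
    n_factors: int,
    extraction: str = "pcf",
    iterate: bool = False,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> FactorAnalysisResult:
    """Factor extraction from a correlation matrix.

    ``extraction="pcf"`` (default) is principal-component factoring: the
    correlation matrix is eigendecomposed with its unit diagonal, so the
    reported eigenvalues are the classical scree-plot/Kaiser eigenvalues
    and ``proportion_variance`` is the share of total item variance.
    ``extraction="pf"`` performs principal-axis factoring instead: the
    diagonal is replaced by squared-multiple-correlation communality
    estimates before eigendecomposition; with ``iterate=True``
    communalities are refined until they change by less than ``tol``.
    Loadings are eigenvectors scaled by the square roots of the (positive)
    eigenvalues in either case.
    """
    p = corr.p
    if not 1 <= n_factors <= p - 1:
        raise PsychometricsError(f"n_factors must be in [1, {p - 1}]")
    if extraction not in ("pf", "pcf"):
        raise PsychometricsError(f"unknown extraction method {extraction!r}")
    R = corr.values.copy()
    h2 = _smc(corr.values) if extraction == "pf" else np.ones(p)

    def decompose(h2: np.ndarray):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        eigvals, eigvecs = np.linalg.eigh(Rr)
        order = np.argsort(eigvals)[::-1]
        return eigvals[order], eigvecs[:, order]

    if extraction == "pf" and iterate:
        for it in range(max_iter):
            eigvals, eigvecs = decompose(h2)
            lam = eigvecs[:, :n_factors] * np.sqrt(np.clip(eigvals[:n_factors], 0, None))
            h2_new = np.sum(lam**2, axis=1)
            if np.max(np.abs(h2_new - h2)) < tol:
                h2 = h2_new
                break
            h2 = h2_new
        else:
            raise PsychometricsError(
                f"communality iteration did not converge in {max_iter} iterations"
            )
    eigvals, eigvecs = decompose(h2)
    loadings = eigvecs[:, :n_factors] * np.sqrt(np.clip(eigvals[:n_factors], 0, None))
    loadings = _sign_align(loadings)
    communalities = np.sum(loadings**2, axis=1)
    return FactorAnalysisResult(
        eigenvalues=eigvals,
        loadings=loadings,
        rotated_loadings=None,
        communalities=communalities,
        n_factors_retained=n_factors,
        proportion_variance=eigvals[:n_factors] / p,
        items=list(corr.items),
        rotation_method="none",
        extraction=extraction,
    )


def _varimax(L: np.ndarray, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Raw varimax rotation (SVD algorithm)."""
    p, k = L.shape
    Rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ Rot
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (1.0 / p) * Lr @ np.diag(np.sum(Lr**2, axis=0)))
        )
        Rot = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return L @ Rot


def varimax_criterion(L: np.ndarray) -> float:
    """The varimax objective: sum over factors of the variance of squared loadings."""
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def rotate_loadings(
    result: FactorAnalysisResult, method: str = "varimax", kaiser_normalize: bool = True
) -> FactorAnalysisResult:
    """Orthogonal rotation of the retained loadings.

    Communalities are invariant under orthogonal rotation.  A single-factor
    solution is returned unchanged up to the sign convention (largest
    magnitude loading positive).
    """
    if method not in ("varimax", "none"):
        raise PsychometricsError(f"unknown rotation method {method!r}")
    L = result.loadings
    if method == "none" or L.shape[1] == 1:
        rotated = _sign_align(L)
        return replace(result, rotated_loadings=rotated, rotation_method=method)
    if kaiser_normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        h = np.where(h > 0, h, 1.0)
        rotated = _varimax(L / h[:, None]) * h[:, None]
    else:
        rotated = _varimax(L)
    rotated = _sign_align(rotated)
    return replace(result, rotated_loadings=rotated, rotation_method=method)


def retain_dimensions(eigenvalues: np.ndarray, threshold: float = 1.1) -> int:
    """Kaiser-style retention: eigenvalues strictly greater than ``threshold``.

    The default 1.1 is a conservative variant of the classical
    eigenvalue-greater-than-one rule.  At least one dimension is always
    retained; if no eigenvalue exceeds the threshold a warning is issued.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise PsychometricsError("empty eigenvalue list")
    if threshold <= 0:
        raise PsychometricsError("threshold must be positive")
    count = int(np.sum(eig > threshold))
    if count == 0:
        warnings.warn(
            f"no eigenvalue exceeds {threshold}; retaining one dimension anyway",
            stacklevel=2,
        )
        return 1
    return count
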