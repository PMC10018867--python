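"""One-factor confirmatory factor analysis by normal-theory ML.

The model is Sigma = lambda lambda' + diag(theta) with the factor variance
fixed to 1, estimated on the sample covariance matrix of the (0/1/2) item
codes.  Fit indices follow the standard definitions: the chi-square is
(n - 1) times the ML discrepancy, RMSEA comes from the non-centrality
parameter, CFI/TLI compare against the independence (diagonal) model, and
SRMR is the root mean square of standardized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class CFAError(ValueError):
    """Raised for non-convergence, Heywood cases, or invalid inputs."""


@dataclass
class CFAResult:
    """Fitted one-factor model and its goodness-of-fit summary."""

    items: list[str]
    loadings: np.ndarray  # unstandardized (covariance-metric)
    std_loadings: np.ndarray
    residual_variances: np.ndarray
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    tli: float
    srmr: float
    n_obs: int
    converged: bool
    item_set_label: str = ""

    def fit_indices(self) -> dict[str, float]:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "chi_square_per_df": self.chi_square / self.df if self.df > 0 else float("nan"),
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "tli": self.tli,
            "srmr": self.srmr,
        }


def one_factor_df(p: int) -> int:
    """Degrees of freedom: p(p+1)/2 moments minus 2p free parameters."""
    return p * (p + 1) // 2 - 2 * p


def _discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - p."""
    p = S.shape[0]
    sign, logdet_sig = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sig + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def fit_one_factor_cfa(
    items: pd.DataFrame, item_set: list[str] | None = None, label: str = ""
) -> CFAResult:
    """Fit a one-factor model to the named items (complete-case).

    Raises
    ------
    CFAError
        On fewer than 3 items, insufficient sample, non-convergence, or a
        Heywood case (a residual variance driven to its lower bound).
    """
    cols = list(items.columns) if item_set is None else list(item_set)
    if len(cols) < 3:
        raise CFAError("one-factor CFA needs at least 3 items")
    data = items[cols].dropna(axis=0, how="any")
    n, p = data.shape
    if n < 10 * p:
        raise CFAError(f"need at least {10 * p} complete rows, got {n}")
    S = np.cov(data.to_numpy(dtype=float), rowvar=False, ddof=1)
    diag = np.diag(S)
    if np.any(diag <= 0):
        dead = [cols[i] for i in np.where(diag <= 0)[0]]
        raise CFAError(f"zero-variance item(s): {', '.join(dead)}")

    lam0 = np.sqrt(0.5 * diag) * np.sign(np.sum(S, axis=1))
    theta0 = 0.5 * diag
    x0 = np.concatenate([lam0, theta0])
    floor = 1e-6 * diag

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        lam, theta = x[:p], x[p:]
        Sigma = np.outer(lam, lam) + np.diag(theta)
        sign, _ = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e10, np.zeros_like(x)
        Sinv = np.linalg.inv(Sigma)
        G = Sinv - Sinv @ S @ Sinv  # dF/dSigma
        grad_lam = 2.0 * G @ lam
        grad_theta = np.diag(G)
        return _discrepancy(S, Sigma), np.concatenate([grad_lam, grad_theta])

    bounds = [(None, None)] * p + [(float(f), None) for f in floor]
    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.fun > 1e-8:
        raise CFAError(f"CFA did not converge: {res.message}")
    lam, theta = res.x[:p], res.x[p:]
    at_floor = theta <= 2 * floor
    if np.any(at_floor):
        bad = [cols[i] for i in np.where(at_floor)[0]]
        raise CFAError(f"Heywood case: residual variance at bound for {', '.join(bad)}")
    # sign convention: majority of loadings positive
    if np.sum(lam) < 0:
        lam = -lam

    Sigma = np.outer(lam, lam) + np.diag(theta)
    F = max(float(res.fun), 0.0)
    df = one_factor_df(p)
    chi2 = (n - 1) * F
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # independence (diagonal) baseline
    F_base = _discrepancy(S, np.diag(diag))
    chi2_base = (n - 1) * F_base
    df_base = p * (p - 1) // 2

    ncp = max(chi2 - df, 0.0)
    rmsea = np.sqrt(ncp / (df * (n - 1))) if df > 0 else 0.0
    denom = max(chi2_base - df_base, ncp, 0.0)
    cfi = 1.0 - (ncp / denom if denom > 0 else 0.0)
    if df > 0 and df_base > 0 and chi2_base / df_base > 1:
        tli = ((chi2_base / df_base) - (chi2 / df)) / ((chi2_base / df_base) - 1.0)
    else:
        tli = 1.0
    d = np.sqrt(diag)
    resid = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))

    return CFAResult(
        items=cols,
        loadings=lam,
        std_loadings=lam / np.sqrt(np.diag(Sigma)),
        residual_variances=theta,
        chi_square=float(chi2),
        df=df,
        p_value=p_value,
        rmsea=float(rmsea),
        cfi=float(cfi),
        tli=float(min(tli, 1.0)),
        srmr=srmr,
        n_obs=n,
        converged=True,
        item_set_label=label,
    )


#: index -> True if lower values indicate better fit
_LOWER_BETTER = {
    "chi_square_per_df": True,
    "rmsea": True,
    "srmr": True,
    "cfi": False,
    "tli": False,
}


def compare_cfa(reduced: CFAResult, full: CFAResult, tol: float = 1e-10) -> pd.DataFrame:
    """Side-by-side fit indices with a better/worse/equal flag per index.

    The flag says which model ('reduced' or 'full') fits better on that
    index; chi-square is compared per degree of freedom.
    """
    if not (reduced.converged and full.converged):
        raise CFAError("both models must have converged")
    rows = []
    red_idx = reduced.fit_indices()
    full_idx = full.fit_indices()
    for name, lower_better in _LOWER_BETTER.items():
        a, b = red_idx[name], full_idx[name]
        if np.isnan(a) or np.isnan(b) or abs(a - b) <= tol:
            flag = "equal"
        elif (a < b) == lower_better:
            flag = "reduced"
        else:
            flag = "full"
        rows.append({"index": name, "reduced": a, "full": b, "better": flag})
    return pd.DataFrame(rows)
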