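"""Stepwise descendant EFA item selection and the factor-based barrier score.

The selection loop starts from the full item set and, at each step, compares
the current analysis with every leave-one-out reduced analysis under a
composite fit criterion; when removing an item does not hurt sampling
adequacy and raises the share of variance carried by the retained factors,
that item is dropped and the loop repeats.  On the final set the Kaiser
rule (eigenvalue > 1.1 by default) fixes the number of dimensions, loadings
are rotated, and only items loading above the cutoff (|loading| > 0.4)
enter the score.  The score itself is the arithmetic mean of the retained
0/1/2 items, so it lives on the same 0-2 scale as the items: 0 means "not a
problem" on every retained barrier, 2 means "a big problem" on all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometrics import (
    FactorAnalysisResult,
    bartlett_sphericity,
    correlation_matrix,
    cronbach_alpha,
    extract_factors,
    kmo,
    retain_dimensions,
    rotate_loadings,
)


class ScoreBuildError(ValueError):
    """Raised when item selection cannot produce a valid score."""


@dataclass
class StepwiseConfig:
    """Tunables of the stepwise descendant EFA.

    ``kmo_tol`` is the largest drop in overall KMO a removal may cause and
    still count as "not reducing the quality" of the analysis; a removal is
    accepted only if it also strictly increases the proportion of total
    variance explained by the retained factors.
    """

    corr_method: str = "pearson"
    extraction: str = "pcf"
    kaiser_threshold: float = 1.1
    loading_cutoff: float = 0.4
    kmo_tol: float = 0.01
    kmo_floor: float = 0.5
    rotation: str = "varimax"
    min_items: int = 2


@dataclass
class FitSummary:
    """Fit of one candidate analysis during the stepwise loop."""

    items: tuple[str, ...]
    kmo_overall: float
    leading_eigenvalue: float
    n_factors: int
    variance_share: float
    alpha: float


@dataclass
class StepwiseStep:
    """One evaluated leave-one-out candidate."""

    removed_item: str
    fit: FitSummary
    accepted: bool
    reason: str


@dataclass
class StepwiseTrace:
    """Ordered record of the stepwise loop plus the final loading cutoff."""

    initial_items: tuple[str, ...]
    steps: list[StepwiseStep] = field(default_factory=list)
    cutoff_dropped: tuple[str, ...] = ()
    adequacy: dict | None = None


@dataclass
class ScoreDefinition:
    """Retained item set and the (fixed) aggregation rule: arithmetic mean."""

    items: tuple[str, ...]
    aggregation: str = "mean"
    range: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise ScoreBuildError("a score needs at least 2 retained items")


@dataclass
class ScoreVector:
    """Per-respondent score in [0, 2] (NaN where any retained item is missing)."""

    values: pd.Series
    definition: ScoreDefinition


def _fit_summary(items: pd.DataFrame, subset: tuple[str, ...], cfg: StepwiseConfig) -> FitSummary:
    corr = correlation_matrix(items[list(subset)], method=cfg.corr_method)
    overall_kmo, _ = kmo(corr)
    fa = extract_factors(corr, n_factors=1, extraction=cfg.extraction)
    eig = fa.eigenvalues
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = retain_dimensions(eig, cfg.kaiser_threshold)
    k = min(k, len(subset) - 1)
    share = float(np.sum(np.clip(eig[:k], 0, None)) / len(subset))
    alpha = cronbach_alpha(items, subset=list(subset)).alpha
    return FitSummary(
        items=subset,
        kmo_overall=overall_kmo,
        leading_eigenvalue=float(eig[0]),
        n_factors=k,
        variance_share=share,
        alpha=alpha,
    )


def stepwise_descendant_efa(
    items: pd.DataFrame, config: StepwiseConfig | None = None
) -> tuple[ScoreDefinition, StepwiseTrace, FactorAnalysisResult]:
    """Select score items by stepwise descendant exploratory factor analysis.

    Returns the score definition over the surviving items, the full trace of
    removals, and the final (rotated) factor analysis on the post-loop set.

    Raises
    ------
    ScoreBuildError
        If fewer than 2 items survive the loading cutoff.
    """
    cfg = config or StepwiseConfig()
    current: tuple[str, ...] = tuple(str(c) for c in items.columns)
    if len(current) < 3:
        raise ScoreBuildError("stepwise selection needs at least 3 items")
    trace = StepwiseTrace(initial_items=current)

    # sampling-adequacy gate on the full set
    full_corr = correlation_matrix(items[list(current)], method=cfg.corr_method)
    stat, df, p_value = bartlett_sphericity(full_corr)
    overall_kmo, _ = kmo(full_corr)
    trace.adequacy = {"bartlett_statistic": stat, "bartlett_df": df, "bartlett_p": p_value,
                      "kmo": overall_kmo}
    if p_value >= 0.05:
        warnings.warn("Bartlett sphericity not rejected; items may be uncorrelated", stacklevel=2)
    if overall_kmo < cfg.kmo_floor:
        warnings.warn(
            f"overall KMO {overall_kmo:.3f} below floor {cfg.kmo_floor}; "
            "factor analysis may be inadequate",
            stacklevel=2,
        )

    while len(current) > cfg.min_items:
        base = _fit_summary(items, current, cfg)
        base_fa = extract_factors(
            correlation_matrix(items[list(current)], method=cfg.corr_method),
            n_factors=1,
            extraction=cfg.extraction,
        )
        communality = dict(zip(base_fa.items, base_fa.communalities))
        candidates: list[StepwiseStep] = []
        for item in current:
            reduced = tuple(i for i in current if i != item)
            fit = _fit_summary(items, reduced, cfg)
            ok_kmo = fit.kmo_overall >= base.kmo_overall - cfg.kmo_tol
            ok_var = fit.variance_share > base.variance_share
            accepted = ok_kmo and ok_var
            reason = (
                f"kmo {fit.kmo_overall:.4f} vs base {base.kmo_overall:.4f} "
                f"(tol {cfg.kmo_tol}); variance share {fit.variance_share:.4f} "
                f"vs base {base.variance_share:.4f}"
            )
            candidates.append(StepwiseStep(item, fit, accepted, reason))
        accepted = [c for c in candidates if c.accepted]
        trace.steps.extend(candidates)
        if not accepted:
            break
        # best criterion value; ties broken by lowest communality, then order
        best_share = max(c.fit.variance_share for c in accepted)
        tied = [c for c in accepted if c.fit.variance_share >= best_share - 1e-12]
        tied.sort(key=lambda c: (communality[c.removed_item], current.index(c.removed_item)))
        winner = tied[0]
        for c in candidates:
            if c is not winner:
                c.accepted = False
        current = winner.fit.items

    # final analysis on the post-loop set
    corr = correlation_matrix(items[list(current)], method=cfg.corr_method)
    fa = extract_factors(corr, n_factors=1, extraction=cfg.extraction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n_keep = retain_dimensions(fa.eigenvalues, cfg.kaiser_threshold)
    n_keep = min(n_keep, len(current) - 1)
    fa = extract_factors(corr, n_factors=n_keep, extraction=cfg.extraction)
    fa = rotate_loadings(fa, method=cfg.rotation)
    loadings = fa.final_loadings
    surviving = tuple(
        item
        for i, item in enumerate(current)
        if np.max(np.abs(loadings[i, :])) > cfg.loading_cutoff
    )
    trace.cutoff_dropped = tuple(i for i in current if i not in surviving)
    if len(surviving) < 2:
        raise ScoreBuildError(
            f"fewer than 2 items survive the |loading| > {cfg.loading_cutoff} rule; "
            f"trace: removed {[s.removed_item for s in trace.steps if s.accepted]}, "
            f"cutoff dropped {trace.cutoff_dropped}"
        )
    return ScoreDefinition(items=surviving), trace, fa


def compute_score(items: pd.DataFrame, definition: ScoreDefinition) -> ScoreVector:
    """Arithmetic mean of the retained items, complete-case per respondent."""
    missing_cols = [c for c in definition.items if c not in items.columns]
    if missing_cols:
        raise ScoreBuildError(f"items not present in data: {missing_cols}")
    sub = items[list(definition.items)]
    values = sub.mean(axis=1).where(~sub.isna().any(axis=1))
    values.name = "pbmc_score"
    return ScoreVector(values=values, definition=definition)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Weighted quantiles with linear interpolation.

    Uses midpoint-of-mass positions p_i = (cumw_i - w_i/2) / sum(w), which
    reduces to the usual midpoint convention for the even-n median when all
    weights are equal.
    """
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, p, x)


def score_summary(score: ScoreVector, weights: pd.Series | None = None) -> dict:
    """Mean, SD, median, and IQR of the score, unweighted and weighted.

    Quantiles use linear interpolation (the weighted version interpolates on
    midpoint-of-mass positions).  The weighted SD uses the reliability-weight
    formula sqrt(sum w (x - mw)^2 / (sum w - sum w^2 / sum w)).
    """
    vals = score.values.dropna()
    if len(vals) == 0:
        raise ScoreBuildError("no non-missing scores")
    x = vals.to_numpy(dtype=float)
    q = np.array([0.25, 0.5, 0.75])
    unw_q = _weighted_quantile(x, np.ones_like(x), q)
    out = {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "median": float(unw_q[1]),
        "iqr": (float(unw_q[0]), float(unw_q[2])),
    }
    if weights is not None:
        w = weights.loc[vals.index].to_numpy(dtype=float)
        sw = w.sum()
        mw = float(np.sum(w * x) / sw)
        denom = sw - np.sum(w**2) / sw
        var_w = float(np.sum(w * (x - mw) ** 2) / denom) if denom > 0 else 0.0
        wq = _weighted_quantile(x, w, q)
        out.update(
            {
                "mean_weighted": mw,
                "sd_weighted": float(np.sqrt(max(var_w, 0.0))),
                "median_weighted": float(wq[1]),
                "iqr_weighted": (float(wq[0]), float(wq[2])),
            }
        )
    return out
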