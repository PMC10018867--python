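"""End-to-end analysis pipeline and report assembly.

Stage order mirrors the scale-development workflow: sampling-adequacy gate
(KMO, Bartlett) -> stepwise descendant EFA -> reliability (alpha) -> score
computation and summary -> validity battery -> predictions at score 0/1/2
-> optional CFA confirmation on a second dataset.  Results are written as a
JSON bundle plus delimited tables; everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cfa import CFAError, compare_cfa, fit_one_factor_cfa
from .psychometrics import cronbach_alpha
from .score import StepwiseConfig, compute_score, score_summary, stepwise_descendant_efa
from .simulate import (
    ITEM_NAMES,
    OUTCOME_FAMILIES,
    OUTCOME_SUBSETS,
    SimulationConfig,
    SurveyDataset,
    generate_dataset,
    marginal_item_table,
)
from .validity import RegressionSpec, validity_battery

logger = logging.getLogger("pbmcscore")

#: default construct-validity battery: (outcome, family, group)
DEFAULT_CONSTRUCT_SPECS: tuple[tuple[str, str, str], ...] = (
    ("primary_education", "logistic", "determinants"),
    ("female", "logistic", "determinants"),
    ("in_union", "logistic", "determinants"),
    ("age", "linear", "determinants"),
    ("poor_monetary", "logistic", "determinants"),
    ("poor_food", "logistic", "determinants"),
    ("poor_subjective", "logistic", "determinants"),
    ("consumption_cfa", "linear", "determinants"),
    ("adult_equivalents", "linear", "determinants"),
    ("distance_health_km", "linear", "determinants"),
    ("distance_cbhi_km", "linear", "determinants"),
    ("insurance_status", "multinomial", "other"),
    ("wtp_cfa", "linear", "other"),
    ("chronic_illness", "logistic", "other"),
    ("handicap", "logistic", "other"),
    ("sf12_mcs", "linear", "other"),
    ("sf12_pcs", "linear", "other"),
    ("perception_quality", "linear", "other"),
    ("risk_tolerance", "linear", "other"),
    ("trust", "linear", "other"),
    ("che_40", "logistic", "che"),
    ("che_30", "logistic", "che"),
    ("che_20", "logistic", "che"),
)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    input_path: str | None = None  # CSV with one row per respondent
    simulation: SimulationConfig | None = None
    item_cols: tuple[str, ...] = ITEM_NAMES
    id_col: str = "respondent_id"
    household_col: str = "household_id"
    stratum_col: str = "stratum"
    weight_col: str = "weight"
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    seed: int = 0
    output_dir: str = "pbmc_results"
    cfa_input_path: str | None = None  # optional confirmation dataset

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if d.get("stepwise") is not None and not isinstance(d["stepwise"], StepwiseConfig):
            d["stepwise"] = StepwiseConfig(**d["stepwise"])
        if "item_cols" in d:
            d["item_cols"] = tuple(d["item_cols"])
        return cls(**d)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_dataset(config: PipelineConfig) -> SurveyDataset:
    """Load the input CSV or simulate a dataset per the config."""
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        data = pd.read_csv(path)
        missing = [c for c in config.item_cols if c not in data.columns]
        if missing:
            raise ValueError(f"input lacks item columns: {missing}")
        return SurveyDataset(
            data=data,
            item_cols=config.item_cols,
            id_col=config.id_col,
            household_col=config.household_col,
            stratum_col=config.stratum_col,
            weight_col=config.weight_col,
        )
    sim = config.simulation or SimulationConfig(seed=config.seed)
    return generate_dataset(sim)


def default_specs(data: pd.DataFrame) -> list[RegressionSpec]:
    """Construct-validity specs for the columns actually present."""
    specs = []
    for outcome, family, group in DEFAULT_CONSTRUCT_SPECS:
        if outcome in data.columns:
            specs.append(
                RegressionSpec(
                    outcome=outcome,
                    family=family,
                    group=group,
                    base_category="none" if family == "multinomial" else None,
                )
            )
    return specs


def predictive_specs(data: pd.DataFrame) -> list[RegressionSpec]:
    specs = []
    for outcome, family in OUTCOME_FAMILIES.items():
        if outcome in data.columns:
            specs.append(
                RegressionSpec(
                    outcome=outcome,
                    family=family,
                    group="predictive",
                    subset=OUTCOME_SUBSETS.get(outcome),
                )
            )
    return specs


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns the in-memory results bundle (also written as
    ``results.json`` in the output directory, alongside CSV tables and a
    plain-text log).  Raises PipelineError naming the failing stage;
    partial outputs written so far are preserved.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"software": {"package": "pbmcscore", "version": __version__},
                    "seed": config.seed}

    def flush() -> None:
        (outdir / "results.json").write_text(json.dumps(_jsonable(bundle), indent=2))

    stage = "load"
    try:
        dataset = load_dataset(config)
        df = dataset.data
        bundle["n_respondents"] = len(df)
        if dataset.stratum_col in df.columns:
            bundle["strata"] = df[dataset.stratum_col].value_counts().to_dict()
        marginals = marginal_item_table(dataset)
        marginals.to_csv(outdir / "item_marginals.csv")
        bundle["item_marginals"] = {i: row.to_dict() for i, row in marginals.iterrows()}
        flush()

        stage = "score_building"
        items = dataset.items
        definition, trace, fa = stepwise_descendant_efa(items, config.stepwise)
        alpha = cronbach_alpha(items, subset=list(definition.items))
        bundle["adequacy"] = trace.adequacy
        bundle["score_definition"] = {
            "items": list(definition.items),
            "aggregation": definition.aggregation,
        }
        bundle["stepwise"] = {
            "removed": [s.removed_item for s in trace.steps if s.accepted],
            "cutoff_dropped": list(trace.cutoff_dropped),
            "n_factors": fa.n_factors_retained,
            "leading_eigenvalue": float(fa.eigenvalues[0]),
            "proportion_variance_total": float(fa.proportion_variance[0]),
            "loadings": dict(zip(fa.items, fa.final_loadings[:, 0].tolist())),
        }
        bundle["reliability"] = {"cronbach_alpha": alpha.alpha, "k_items": alpha.k_items}
        flush()

        stage = "score"
        score = compute_score(items, definition)
        weights = df[dataset.weight_col] if dataset.weight_col in df.columns else None
        bundle["score_summary"] = score_summary(score, weights=weights)
        score.values.to_frame().assign(respondent_id=df[dataset.id_col]
                                       if dataset.id_col in df.columns else df.index).to_csv(
            outdir / "scores.csv", index=False
        )
        flush()

        stage = "construct_validity"
        construct = validity_battery(score.values, dataset, default_specs(df))
        construct.to_csv(outdir / "construct_validity.csv", index=False)
        bundle["construct_validity"] = construct.to_dict(orient="records")
        flush()

        stage = "predictive_validity"
        predictive = validity_battery(
            score.values, dataset, predictive_specs(df), predictions_at=(0.0, 1.0, 2.0)
        )
        predictive.to_csv(outdir / "predictive_validity.csv", index=False)
        bundle["predictive_validity"] = predictive.to_dict(orient="records")
        flush()

        if config.cfa_input_path is not None:
            stage = "cfa"
            cfa_df = pd.read_csv(config.cfa_input_path)
            cfa_items = cfa_df[list(config.item_cols)]
            reduced = fit_one_factor_cfa(cfa_items, list(definition.items), label="reduced")
            bundle["cfa"] = {"reduced": reduced.fit_indices()}
            try:
                full = fit_one_factor_cfa(cfa_items, list(config.item_cols), label="full")
                comparison = compare_cfa(reduced, full)
                bundle["cfa"]["full"] = full.fit_indices()
                bundle["cfa"]["comparison"] = comparison.to_dict(orient="records")
                comparison.to_csv(outdir / "cfa_comparison.csv", index=False)
            except CFAError as exc:
                bundle["cfa"]["full_error"] = str(exc)
            flush()
    except Exception as exc:
        flush()
        raise PipelineError(stage, exc) from exc

    flush()
    (outdir / "run.log").write_text(
        f"pbmcscore {__version__}\nseed={config.seed}\n"
        f"stages=load,score_building,score,construct_validity,predictive_validity"
        + (",cfa" if config.cfa_input_path else "")
        + "\n"
    )
    return bundle
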