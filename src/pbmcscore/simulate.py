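"""Seeded synthetic survey generator.

Emulates a choice-based stratified household survey of rural adults with
six ordinal (0/1/2) perceived-barrier items, household clustering, sampling
weights, socio-demographic covariates, and utilization outcomes driven by
the realized barrier score.

The generative model for the items is a thresholded (graded-response-style)
Gaussian latent variable: respondent i in household h has latent trait

    T_ih = b_h + e_ih + sum_k beta_k * z_k(ih),   normalized to unit variance,

with var(b) = household_icc, var(e) = 1 - household_icc and z_k standardized
covariates.  Item j's latent response is lambda_j * T + sqrt(1 - lambda_j^2)
* noise, cut at two increasing thresholds into categories 0 ("not a
problem"), 1 ("a small problem"), 2 ("a big problem").  Default loadings
leave items 1-2 essentially unloaded and nearly constant while items 3-6
share one factor; default thresholds reproduce the marginal distributions
typical of such data (e.g. >98% "not a problem" on knowing where to go,
55% "a big problem" on having the money to pay).

Utilization outcomes are drawn from logistic/Poisson models whose linear
predictor is intercept + slope * (realized mean of items 3-6).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

ITEM_NAMES = (
    "knowing_where_to_go",
    "getting_permission",
    "having_money",
    "distance_to_facility",
    "finding_transport",
    "going_alone",
)

#: Default two-threshold cuts per item on the latent N(0,1) scale, chosen so
#: category proportions match the marginals of the barrier items in rural
#: Senegalese survey data (items 1-2 near-degenerate at "not a problem";
#: money mostly "a big problem"; distance/transport mixed; going alone rare).
DEFAULT_THRESHOLDS: tuple[tuple[float, float], ...] = (
    (2.120, 2.576),  # 98.3% / ~1.2% / ~0.5%
    (2.197, 2.652),  # 98.6%
    (-1.028, -0.128),  # 15.2% / 29.7% / 55.1%
    (0.181, 1.045),  # 57.2% / 28.0% / 14.8%
    (0.282, 1.254),  # 61.1% / 28.4% / 10.5%
    (1.180, 1.911),  # 88.1% / 9.1% / 2.8%
)

DEFAULT_LOADINGS: tuple[float, ...] = (0.05, 0.05, 0.60, 0.60, 0.65, 0.50)

#: Effects of standardized covariates on the latent trait.  Signs follow the
#: construct-validity pattern: women, the poor, the chronically ill and those
#: living far from care perceive higher barriers; the educated, partnered,
#: trusting and risk-tolerant perceive lower ones.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "female": 0.22,
    "primary_education": -0.20,
    "in_union": -0.12,
    "poor_monetary": 0.14,
    "poor_food": 0.16,
    "poor_subjective": 0.22,
    "log_consumption": -0.12,
    "adult_equivalents": -0.12,
    "distance_health_km": 0.30,
    "distance_cbhi_km": 0.12,
    "chronic_illness": 0.12,
    "handicap": 0.10,
    "sf12_pcs": -0.10,
    "risk_tolerance": -0.16,
    "trust": -0.12,
    "wtp_log": -0.18,
    # enrollment-stratum dummies: voluntary subscribers perceive fewer
    # barriers, subsidized (cash-transfer) households more
    "insurance_voluntary": -0.30,
    "insurance_subsidized": 0.25,
}

#: (intercept, slope) on the link scale for each outcome regressed on the
#: realized 4-item score; magnitudes typical of primary-care utilization in
#: this setting (e.g. odds of forgoing a consultation tripling per score
#: point, predicted prenatal consultations falling from ~3.7 to ~2.8).
DEFAULT_OUTCOME_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "forgone_consultation": (-1.3863, 1.1314),  # P(0)=0.20, OR=3.10
    "forgone_treatment": (-1.3249, 0.2624),  # P(0)=0.21, OR=1.30
    "consulted": (-0.3640, -0.4620),  # P(0)=0.41, OR=0.63
    "self_medicated": (-1.3863, 0.7372),  # P(0)=0.20, OR=2.09
    "facility_birth": (0.7538, -0.7765),  # P(0)=0.68, OR=0.46
    "prenatal_consultations": (1.3056, -0.1393),  # mu(0)=3.69, IRR=0.87
}

OUTCOME_FAMILIES: dict[str, str] = {
    "forgone_consultation": "logistic",
    "forgone_treatment": "logistic",
    "consulted": "logistic",
    "self_medicated": "logistic",
    "facility_birth": "logistic",
    "prenatal_consultations": "poisson",
}

OUTCOME_SUBSETS: dict[str, str | None] = {
    "forgone_consultation": None,
    "forgone_treatment": None,
    "consulted": "recent_illness",
    "self_medicated": "recent_illness",
    "facility_birth": "recent_birth",
    "prenatal_consultations": "recent_birth",
}


class SimulationConfigError(ValueError):
    """Raised when a SimulationConfig field is invalid."""


@dataclass
class SimulationConfig:
    """Full specification of one synthetic survey draw.

    ``strata_sizes`` are respondent counts for the (voluntary subscriber,
    cash-transfer recipient, non-enrolled) strata of a choice-based design;
    sampling weights are population share / sample share per stratum.
    ``n_households`` is only used when ``strata_sizes`` is None (single
    stratum of that many households).
    """

    strata_sizes: tuple[int, int, int] | None = (285, 176, 1326)
    strata_labels: tuple[str, ...] = ("voluntary", "bsf", "non_enrolled")
    population_shares: tuple[float, ...] = (0.05, 0.04, 0.91)
    n_households: int = 900
    mean_household_adults: float = 2.0
    item_loadings: tuple[float, ...] = DEFAULT_LOADINGS
    item_thresholds: tuple[tuple[float, float], ...] = DEFAULT_THRESHOLDS
    household_icc: float = 0.30
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    outcome_coefficients: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS)
    )
    illness_rate: float = 0.234
    birth_rate: float = 0.215  # among women
    seed: int = 0

    def validate(self) -> None:
        if self.mean_household_adults <= 0:
            raise SimulationConfigError("mean_household_adults must be positive")
        if not 0 <= self.household_icc < 1:
            raise SimulationConfigError("household_icc must be in [0, 1)")
        if self.strata_sizes is not None:
            if len(self.strata_sizes) != len(self.strata_labels) or len(
                self.strata_sizes
            ) != len(self.population_shares):
                raise SimulationConfigError(
                    "strata_sizes, strata_labels and population_shares must align"
                )
            if any(s < 1 for s in self.strata_sizes):
                raise SimulationConfigError("strata_sizes must all be >= 1")
        elif self.n_households < 1:
            raise SimulationConfigError("n_households must be >= 1")
        if len(self.item_loadings) != len(ITEM_NAMES):
            raise SimulationConfigError("item_loadings must have one entry per item")
        if any(not 0 <= l <= 1 for l in self.item_loadings):
            raise SimulationConfigError("item_loadings must lie in [0, 1]")
        if len(self.item_thresholds) != len(ITEM_NAMES):
            raise SimulationConfigError("item_thresholds must have one entry per item")
        for j, (t1, t2) in enumerate(self.item_thresholds):
            if not t1 < t2:
                raise SimulationConfigError(
                    f"item_thresholds[{j}] must be strictly increasing"
                )
        if not 0 <= self.illness_rate <= 1 or not 0 <= self.birth_rate <= 1:
            raise SimulationConfigError("subset rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcome_coefficients"] = {
            k: list(v) for k, v in self.outcome_coefficients.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "strata_sizes" in d and d["strata_sizes"] is not None:
            d["strata_sizes"] = tuple(d["strata_sizes"])
        for key in ("strata_labels", "population_shares", "item_loadings"):
            if key in d:
                d[key] = tuple(d[key])
        if "item_thresholds" in d:
            d["item_thresholds"] = tuple(tuple(t) for t in d["item_thresholds"])
        if "outcome_coefficients" in d:
            d["outcome_coefficients"] = {
                k: tuple(v) for k, v in d["outcome_coefficients"].items()
            }
        return cls(**d)


@dataclass
class SurveyDataset:
    """A generated survey: one row per adult respondent.

    ``data`` holds respondent id, household id, stratum, sampling weight,
    the six items, covariates, subset flags, and outcomes (NaN outside the
    relevant subset).  Column-role attributes name the design columns.
    """

    data: pd.DataFrame
    config: SimulationConfig | None = None
    item_cols: tuple[str, ...] = ITEM_NAMES
    id_col: str = "respondent_id"
    household_col: str = "household_id"
    stratum_col: str = "stratum"
    weight_col: str = "weight"

    @property
    def items(self) -> pd.DataFrame:
        return self.data[list(self.item_cols)]

    @property
    def weights(self) -> pd.Series:
        return self.data[self.weight_col]

    @property
    def clusters(self) -> pd.Series:
        return self.data[self.household_col]

    def write(self, csv_path: str | Path, sidecar: bool = True) -> None:
        """Write the dataset as CSV plus a JSON sidecar echoing the config."""
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False)
        if sidecar and self.config is not None:
            meta = {"config": self.config.to_dict(), "seed": self.config.seed}
            csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _standardized_covariates(
    n_resp: int,
    household_of: np.ndarray,
    n_households: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw covariates; return (raw values, standardized versions).

    Household-level covariates are drawn once per household and broadcast.
    Standardization uses the generative parameters, not sample moments, so
    configured effect sizes are on a fixed scale.
    """
    raw = {}
    std = {}

    def bern(name: str, p: float, hh: bool = False) -> None:
        x = rng.binomial(1, p, n_households if hh else n_resp)
        if hh:
            x = x[household_of]
        raw[name] = x
        std[name] = (x - p) / np.sqrt(p * (1 - p))

    def gauss(name: str, mu: float, sd: float, hh: bool = False) -> None:
        x = rng.normal(mu, sd, n_households if hh else n_resp)
        if hh:
            x = x[household_of]
        raw[name] = x
        std[name] = (x - mu) / sd

    bern("female", 0.52)
    age = np.clip(rng.normal(38.0, 14.0, n_resp), 18, 95)
    raw["age"] = age
    std["age"] = (age - 38.0) / 14.0
    bern("primary_education", 0.35)
    bern("in_union", 0.75)
    bern("poor_monetary", 0.40, hh=True)
    bern("poor_food", 0.35, hh=True)
    bern("poor_subjective", 0.50, hh=True)
    log_cons = rng.normal(10.0, 0.6, n_households)[household_of]
    raw["consumption_cfa"] = np.exp(log_cons)
    std["log_consumption"] = (log_cons - 10.0) / 0.6
    ae = 1.0 + rng.gamma(2.0, 1.5, n_households)[household_of]
    raw["adult_equivalents"] = ae
    std["adult_equivalents"] = (ae - 4.0) / np.sqrt(2.0 * 1.5**2)
    dist = rng.gamma(2.0, 1.6, n_households)[household_of]
    raw["distance_health_km"] = dist
    std["distance_health_km"] = (dist - 3.2) / np.sqrt(2.0 * 1.6**2)
    dcb = rng.gamma(2.0, 2.0, n_households)[household_of]
    raw["distance_cbhi_km"] = dcb
    std["distance_cbhi_km"] = (dcb - 4.0) / np.sqrt(2.0 * 2.0**2)
    bern("chronic_illness", 0.10)
    bern("handicap", 0.06)
    gauss("sf12_mcs", 50.0, 10.0)
    gauss("sf12_pcs", 50.0, 10.0)
    gauss("perception_quality", 6.0, 2.0)
    gauss("risk_tolerance", 5.0, 2.5)
    gauss("trust", 5.0, 2.5)
    wtp_log = rng.normal(8.0, 0.8, n_resp)
    raw["wtp_cfa"] = np.exp(wtp_log)
    std["wtp_log"] = (wtp_log - 8.0) / 0.8
    # household out-of-pocket and non-food spending, independent of the trait
    oop = np.exp(rng.normal(8.5, 1.2, n_households))[household_of]
    nonfood = np.exp(rng.normal(10.5, 0.7, n_households))[household_of]
    raw["oop_health_cfa"] = oop
    raw["nonfood_cfa"] = nonfood
    return pd.DataFrame(raw), pd.DataFrame(std)


def generate_dataset(config: SimulationConfig) -> SurveyDataset:
    """Draw one synthetic survey under ``config``.

    Fully reproducible: identical config (including seed) gives an identical
    dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- households and strata -------------------------------------------
    if config.strata_sizes is not None:
        strata = list(zip(config.strata_labels, config.strata_sizes, config.population_shares))
    else:
        strata = [("all", None, 1.0)]
    hh_sizes: list[int] = []
    hh_stratum: list[str] = []
    resp_household: list[int] = []
    resp_stratum: list[str] = []
    hh_id = 0
    total_by_stratum: dict[str, int] = {}
    for label, target, _share in strata:
        count = 0
        n_hh_drawn = 0
        while (target is not None and count < target) or (
            target is None and n_hh_drawn < config.n_households
        ):
            size = 1 + rng.poisson(max(config.mean_household_adults - 1.0, 0.0))
            if target is not None:
                size = min(size, target - count)
            hh_sizes.append(size)
            hh_stratum.append(label)
            resp_household.extend([hh_id] * size)
            resp_stratum.extend([label] * size)
            hh_id += 1
            count += size
            n_hh_drawn += 1
        total_by_stratum[label] = count
    n_households = hh_id
    household_of = np.asarray(resp_household)
    n_resp = len(household_of)
    stratum_arr = np.asarray(resp_stratum)

    # choice-based sampling weights: population share / sample share
    n_total = n_resp
    weight_by_stratum = {
        label: share / (total_by_stratum[label] / n_total) for label, _t, share in strata
    }
    weights = np.array([weight_by_stratum[s] for s in stratum_arr])

    # --- covariates and latent trait -------------------------------------
    raw_cov, std_cov = _standardized_covariates(n_resp, household_of, n_households, rng)
    # stratum dummies enter the trait like any other covariate
    for dummy, lab in (("insurance_voluntary", "voluntary"), ("insurance_subsidized", "bsf")):
        x = (stratum_arr == lab).astype(float)
        share = x.mean()
        if 0 < share < 1:
            std_cov[dummy] = (x - share) / np.sqrt(share * (1 - share))
        else:
            std_cov[dummy] = 0.0
    icc = config.household_icc
    b_h = rng.normal(0.0, np.sqrt(icc), n_households)[household_of]
    e_i = rng.normal(0.0, np.sqrt(1.0 - icc), n_resp)
    trait = b_h + e_i
    beta_sq = 0.0
    for name, beta in config.covariate_effects.items():
        if name not in std_cov.columns:
            raise SimulationConfigError(f"unknown covariate in covariate_effects: {name!r}")
        trait = trait + beta * std_cov[name].to_numpy()
        beta_sq += beta**2
    trait = trait / np.sqrt(1.0 + beta_sq)

    # --- ordinal items ----------------------------------------------------
    items = np.empty((n_resp, len(ITEM_NAMES)), dtype=int)
    for j, (lam, (t1, t2)) in enumerate(zip(config.item_loadings, config.item_thresholds)):
        latent = lam * trait + np.sqrt(max(1.0 - lam**2, 0.0)) * rng.normal(size=n_resp)
        items[:, j] = np.digitize(latent, [t1, t2])

    # --- subset flags and outcomes ---------------------------------------
    score = items[:, 2:6].mean(axis=1)
    female = raw_cov["female"].to_numpy()
    recent_illness = rng.binomial(1, config.illness_rate, n_resp).astype(bool)
    recent_birth = (female == 1) & rng.binomial(1, config.birth_rate, n_resp).astype(bool)
    subset_flags = {"recent_illness": recent_illness, "recent_birth": recent_birth}

    outcomes: dict[str, np.ndarray] = {}
    for name, (intercept, slope) in config.outcome_coefficients.items():
        family = OUTCOME_FAMILIES.get(name, "logistic")
        eta = intercept + slope * score
        if family == "poisson":
            y = rng.poisson(np.exp(eta)).astype(float)
        else:
            y = rng.binomial(1, expit(eta)).astype(float)
        subset = OUTCOME_SUBSETS.get(name)
        if subset is not None:
            y = np.where(subset_flags[subset], y, np.nan)
        outcomes[name] = y

    insurance = pd.Categorical(
        np.select(
            [stratum_arr == "voluntary", stratum_arr == "bsf"],
            ["voluntary", "subsidized"],
            default="none",
        ),
        categories=["none", "voluntary", "subsidized"],
    )

    data = pd.DataFrame(
        {
            "respondent_id": np.arange(n_resp),
            "household_id": household_of,
            "stratum": stratum_arr,
            "weight": weights,
        }
    )
    for j, name in enumerate(ITEM_NAMES):
        data[name] = items[:, j]
    data = pd.concat([data, raw_cov], axis=1)
    data["insurance_status"] = insurance
    data["recent_illness"] = recent_illness
    data["recent_birth"] = recent_birth
    for name, y in outcomes.items():
        data[name] = y
    return SurveyDataset(data=data, config=config)


def marginal_item_table(dataset: SurveyDataset | pd.DataFrame) -> pd.DataFrame:
    """Per-item category proportions over {0, 1, 2} on non-missing responses.

    Rows are items, columns the three categories; each row sums to 1.
    """
    items = dataset.items if isinstance(dataset, SurveyDataset) else dataset
    rows = {}
    for col in items.columns:
        vals = items[col].dropna()
        if len(vals) == 0:
            raise ValueError(f"item {col!r} has no non-missing responses")
        counts = vals.value_counts()
        rows[col] = [counts.get(c, 0) / len(vals) for c in (0, 1, 2)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["not_a_problem", "small_problem", "big_problem"]
    )
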