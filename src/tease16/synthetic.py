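"""Synthetic jurisdictions and packaged published-table fixtures.

The generator produces policy codings and consumption inputs with the
statistical structure the analysis assumes: ordinal stringency codings with
between-area heterogeneity, three-level enforcement, and income-adjusted
consumption that is log-linear in the baseline policy score with Gaussian
noise on the log scale.  Defaults are chosen to emulate the nine western
Pacific study areas: totals dispersed over roughly 25-70 points and a
semi-elasticity of 1.8% per score point.

``load_fixture`` ships the published score and sensitivity tables for the
nine real study areas, so downstream arithmetic (medians, ranges,
correlations) is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import (
    DOMAINS,
    AreaFramework,
    EnforcementLevel,
    PolicyCodebook,
    PolicyObservation,
    default_codebook,
)
from .consumption import ConsumptionRecord
from .scoring import score_area, star_weight_scheme


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the synthetic-jurisdiction generator.

    stringency_bias: per-domain propensity toward stringent levels in
        [0, 1]; 0.5 is neutral, 1 forces every topic to its most stringent
        level.  Between-area heterogeneity enters through a per-area
        log-normal tilt of the bias.
    enforcement_probs: probabilities of (poor, moderate, strong).
    true_loglinear: parameters of the consumption model
        adjusted = exp(intercept + slope * score + Normal(0, noise_sd)).
    """

    n_areas: int = 9
    seed: int = 0
    stringency_bias: Mapping[str, float] = field(
        default_factory=lambda: {d: 0.5 for d in DOMAINS}
    )
    enforcement_probs: tuple[float, float, float] = (0.25, 0.40, 0.35)
    true_loglinear: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": 0.9, "slope": -0.018, "noise_sd": 0.15}
    )
    area_spread: float = 0.8  # sd of the per-area log-tilt on the bias

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")
        if abs(sum(self.enforcement_probs) - 1.0) > 1e-9:
            raise ValueError("enforcement_probs must sum to 1")
        if any(p < 0 for p in self.enforcement_probs):
            raise ValueError("enforcement_probs must be non-negative")
        if self.true_loglinear["noise_sd"] < 0:
            raise ValueError("noise_sd must be >= 0")
        for d, b in self.stringency_bias.items():
            if not 0 <= b <= 1:
                raise ValueError(f"stringency_bias[{d!r}] must lie in [0, 1]")


def generate_frameworks(
    config: SimConfig, codebook: PolicyCodebook | None = None
) -> list[AreaFramework]:
    """Draw ``n_areas`` complete, valid frameworks, reproducibly by seed.

    Each area gets a latent quality tilt z ~ Normal(0, area_spread); the
    stringency index of a k-level topic is Binomial(k-1, p) with
    p = bias ** exp(-z), so bias 1 pins every topic at maximum stringency
    and bias 0 at minimum regardless of the tilt.
    """
    cb = codebook if codebook is not None else default_codebook()
    rng = np.random.default_rng(config.seed)
    frameworks = []
    for i in range(config.n_areas):
        area = f"area_{i+1:02d}"
        z = rng.normal(0.0, config.area_spread)
        obs = []
        for topic in cb:
            bias = config.stringency_bias[topic.domain]
            if bias in (0.0, 1.0):
                p = bias
            else:
                p = float(bias ** np.exp(-z))
            idx = int(rng.binomial(topic.n_levels - 1, p))
            enf = rng.choice(ENFORCEMENT_ORDER, p=config.enforcement_probs)
            obs.append(
                PolicyObservation(
                    area, topic.id, topic.stringency_levels[idx], EnforcementLevel(enf)
                )
            )
        frameworks.append(AreaFramework(area, tuple(obs)))
    return frameworks


ENFORCEMENT_ORDER = ("poor", "moderate", "strong")


def generate_consumption(
    frameworks: Sequence[AreaFramework],
    config: SimConfig,
    codebook: PolicyCodebook | None = None,
) -> list[ConsumptionRecord]:
    """Consumption records whose income-adjusted values follow the
    log-linear model in the baseline (star weights, 50:50) policy score.

    The intended adjusted value is back-converted into a plausible
    (volume, ABV, population, GDP) tuple consistent with the per-capita
    conversion, so running the conversion forward reproduces it exactly.
    """
    cb = codebook if codebook is not None else default_codebook()
    # consumption noise drawn from a stream decoupled from the policy stream
    rng = np.random.default_rng((config.seed, 1))
    scheme = star_weight_scheme("baseline", cb)
    params = config.true_loglinear
    records = []
    for f in frameworks:
        score = score_area(f, scheme, "fifty_fifty", cb).total
        log_adj = (
            params["intercept"]
            + params["slope"] * score
            + rng.normal(0.0, params["noise_sd"])
        )
        adjusted = float(np.exp(log_adj))  # litres per capita per 1000 I$
        gdp = float(np.exp(rng.uniform(np.log(3_000), np.log(60_000))))
        population = float(np.exp(rng.uniform(np.log(1.0), np.log(150.0))))
        abv = float(rng.uniform(0.04, 0.12))
        litres_pc = adjusted * gdp / 1000.0
        volume_sold = litres_pc * population / abv
        records.append(
            ConsumptionRecord(
                area=f.area,
                volume_sold=volume_sold,
                abv=abv,
                population=population,
                gdp_ppp_pc=gdp,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Published-table fixtures (nine western Pacific study areas, 2011)
# ---------------------------------------------------------------------------

_T2_COLUMNS = [
    "rank",
    "physical_availability",
    "drinking_context",
    "alcohol_prices",
    "alcohol_advertising",
    "motor_vehicles",
    "total",
]

_T2_ROWS: dict[str, list[float]] = {
    "Australia": [1, 11.2, 5.3, 18.4, 0.4, 32.2, 67.5],
    "Singapore": [2, 14.5, 5.3, 23.7, 0.4, 20.5, 64.4],
    "New Zealand": [3, 3.9, 3.9, 23.7, 0.4, 30.3, 62.3],
    "Hong Kong SAR": [4, 10.5, 5.3, 17.8, 1.5, 23.0, 58.1],
    "Japan": [5, 5.9, 3.9, 21.1, 0.4, 25.0, 56.4],
    "Malaysia": [6, 9.6, 3.9, 23.7, 2.0, 16.6, 55.8],
    "China": [7, 5.9, 0.0, 17.8, 0.0, 26.4, 50.1],
    "Viet Nam": [8, 5.9, 7.9, 11.8, 2.6, 13.6, 41.8],
    "Philippines": [9, 5.9, 0.0, 17.8, 0.4, 0.0, 24.1],
}

_T2_MEDIAN = [5.9, 3.9, 18.4, 0.4, 23.0, 56.4]
_T2_MAXIMUM = [28.9, 10.5, 23.7, 2.6, 34.2, 100.0]

_T3_COLUMNS = [
    "baseline_rank",
    "median_rank",
    "rank_min",
    "rank_max",
    "baseline_score",
    "median_score",
    "score_min",
    "score_max",
]

_T3_ROWS: dict[str, list[float]] = {
    "Australia": [1, 1, 1, 2, 67.5, 62.2, 36, 83],
    "Singapore": [2, 3, 2, 4, 64.4, 56.7, 30, 80],
    "New Zealand": [3, 3, 1, 3, 62.3, 56.3, 32, 74],
    "Hong Kong SAR": [4, 5, 4, 7, 58.1, 51.8, 24, 73],
    "Japan": [5, 4, 3, 6, 56.4, 50.7, 26, 65],
    "Malaysia": [6, 6, 4, 7, 55.8, 49.9, 25, 71],
    "China": [7, 7, 5, 7, 50.1, 46.7, 22, 58],
    "Viet Nam": [8, 8, 8, 9, 41.8, 39.1, 11, 56],
    "Philippines": [9, 9, 8, 9, 24.1, 20.9, 8, 26],
}


@dataclass(frozen=True)
class ScoreTableFixture:
    """Published per-area domain scores with their median and maximum rows."""

    data: pd.DataFrame
    median: pd.Series
    maximum: pd.Series


def load_fixture(name: str):
    """Return a published table as a DataFrame-backed fixture.

    ``"table2"`` -> :class:`ScoreTableFixture` of the nine areas' domain
    points, totals and ranks; ``"table3"`` -> DataFrame of the sensitivity
    summary (baseline/median/range of rank and score per area).
    """
    if name == "table2":
        df = pd.DataFrame.from_dict(_T2_ROWS, orient="index", columns=_T2_COLUMNS)
        df.index.name = "area"
        cols = _T2_COLUMNS[1:]
        return ScoreTableFixture(
            data=df,
            median=pd.Series(_T2_MEDIAN, index=cols, name="median"),
            maximum=pd.Series(_T2_MAXIMUM, index=cols, name="maximum"),
        )
    if name == "table3":
        df = pd.DataFrame.from_dict(_T3_ROWS, orient="index", columns=_T3_COLUMNS)
        df.index.name = "area"
        return df
    raise KeyError(f"unknown fixture {name!r}; expected 'table2' or 'table3'")
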