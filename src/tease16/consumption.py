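"""Income-adjusted per-capita alcohol consumption and its link to policy scores.

Total volume of alcoholic drinks sold (millions of litres per year) is
converted to litres of pure alcohol per person per year using the mean
fraction of alcohol by volume (ABV) and the population in millions.
Because consumption rises with national income, the per-capita figure is
divided by GDP per capita in purchasing-power-parity international dollars
and reported per 1000 international dollars.

The policy-score -> consumption relationship is fitted by ordinary least
squares, either on the raw adjusted consumption (``linear``) or on its
natural log (``loglinear``).  Under the log-linear model a slope b implies
a semi-elasticity of 100 * (1 - exp(b)) percent change in consumption per
one-point score increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class ConsumptionError(ValueError):
    pass


@dataclass(frozen=True)
class ConsumptionRecord:
    """Raw sales/consumption inputs for one jurisdiction.

    volume_sold: millions of litres of alcoholic drinks sold over the year
    abv: mean alcohol fraction by volume, in (0, 1]
    population: millions of persons
    gdp_ppp_pc: GDP per capita, purchasing-power-parity international dollars
    """

    area: str
    volume_sold: float
    abv: float
    population: float
    gdp_ppp_pc: float

    def __post_init__(self) -> None:
        if self.volume_sold < 0:
            raise ConsumptionError(f"{self.area}: volume_sold must be >= 0")
        if not 0 < self.abv <= 1:
            raise ConsumptionError(
                f"{self.area}: abv must be a fraction in (0, 1] "
                f"(got {self.abv}; a percentage like 5 should be 0.05)"
            )
        if self.population <= 0:
            raise ConsumptionError(f"{self.area}: population must be positive")
        if self.gdp_ppp_pc <= 0:
            raise ConsumptionError(f"{self.area}: gdp_ppp_pc must be positive")


@dataclass(frozen=True)
class AdjustedConsumption:
    area: str
    litres_pc: float  # litres pure alcohol / person / year
    adjusted: float  # litres / person / year per 1000 international dollars


@dataclass
class RegressionFit:
    model: str  # "linear" | "loglinear"
    intercept: float
    slope: float
    r: float
    p: float
    n: int
    semi_elasticity_pct: float | None = None  # loglinear only


def pure_alcohol_per_capita(record: ConsumptionRecord) -> float:
    """Litres of pure alcohol per person per year.

    volume (millions L) * abv gives millions of litres of pure alcohol;
    multiplying by 1e6 and dividing by the population in millions times 1e6
    yields the per-person figure.
    """
    return record.volume_sold * record.abv * 1e6 / (record.population * 1e6)


def income_adjust(litres_pc: float, gdp_ppp_pc: float) -> float:
    """Litres per capita per 1000 international dollars of GDP per capita."""
    if gdp_ppp_pc <= 0:
        raise ConsumptionError("gdp_ppp_pc must be positive")
    return litres_pc / (gdp_ppp_pc / 1000.0)


def adjust_record(record: ConsumptionRecord) -> AdjustedConsumption:
    litres = pure_alcohol_per_capita(record)
    return AdjustedConsumption(
        area=record.area,
        litres_pc=litres,
        adjusted=income_adjust(litres, record.gdp_ppp_pc),
    )


def fit_policy_consumption(
    scores: Mapping[str, float],
    adjusted: Mapping[str, AdjustedConsumption] | Mapping[str, float],
    model: str = "loglinear",
) -> RegressionFit:
    """OLS of (log-)income-adjusted consumption on policy score.

    Areas are matched by name; only areas present in both inputs are used.
    ``r`` is the Pearson correlation of the fitted pair.
    """
    if model not in ("linear", "loglinear"):
        raise ConsumptionError(f"unknown model {model!r}")
    areas = sorted(set(scores) & set(adjusted))
    if len(areas) < 3:
        raise ConsumptionError("need at least 3 matched areas")
    x = np.array([scores[a] for a in areas], dtype=float)
    y = np.array(
        [
            adjusted[a].adjusted if isinstance(adjusted[a], AdjustedConsumption) else adjusted[a]
            for a in areas
        ],
        dtype=float,
    )
    if np.ptp(x) == 0:
        raise ConsumptionError("policy scores have zero variance")
    if model == "loglinear":
        if np.any(y <= 0):
            raise ConsumptionError("log-linear model requires positive consumption")
        y = np.log(y)
    res = stats.linregress(x, y)
    fit = RegressionFit(
        model=model,
        intercept=float(res.intercept),
        slope=float(res.slope),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(areas),
    )
    if model == "loglinear":
        fit.semi_elasticity_pct = semi_elasticity_pct(fit.slope)
    return fit


def semi_elasticity_pct(slope: float) -> float:
    """Percent decrease in consumption per one-point score increase implied
    by a log-linear slope: 100 * (1 - exp(slope))."""
    return 100.0 * (1.0 - math.exp(slope))


def predict_change(
    fit: RegressionFit, baseline_adjusted: float, score_delta: float
) -> float:
    """Reduction in income-adjusted consumption (litres per 1000 I$) from a
    ``score_delta``-point score increase at a given baseline consumption.

    Only valid for the log-linear model, where the effect is proportional:
    change = baseline * (1 - exp(slope * delta)).
    """
    if fit.model != "loglinear":
        raise ConsumptionError(
            "predict_change requires a log-linear fit; the percent "
            "interpretation is invalid for the linear model"
        )
    return baseline_adjusted * (1.0 - math.exp(fit.slope * score_delta))
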