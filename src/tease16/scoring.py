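"""Calibrated 0-100 scoring of policy frameworks.

A jurisdiction's composite score is built topic by topic:

* each topic gets a maximum number of points proportional to its weight
  (star-derived or area-specific), with all 16 maxima summing to 100;
* the points actually awarded combine a stringency fraction sigma (the
  ordinal position of the coded level, mapped linearly onto [0, 1]) with an
  enforcement fraction epsilon, under one of three combination rules:

  ==================  ======================================
  fifty_fifty         max * (0.5*sigma + 0.5*epsilon)
  twentyfive_seventyfive  max * (0.25*sigma + 0.75*epsilon)
  multiplicative      max * sigma * (raw enforcement / 3)
  ==================  ======================================

  For the additive rules epsilon is 0 / 0.5 / 1 for poor / moderate /
  strong; the multiplicative rule uses a third of the raw 1/2/3 rating.

Scores are calibrated so every (weighting, combination) assumption spans
[0, 100]: a framework at maximum stringency and strong enforcement scores
exactly 100 under every assumption set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .codebook import (
    DOMAINS,
    AreaFramework,
    EnforcementLevel,
    PolicyCodebook,
    PolicyObservation,
    PolicyTopic,
    default_codebook,
)

WEIGHTINGS = ("baseline", "heavy", "equal", "area_specific")
COMBINATIONS = ("fifty_fifty", "twentyfive_seventyfive", "multiplicative")

#: star rating -> weight for the two star-based schemes
_STAR_WEIGHTS = {"baseline": {1: 1.0, 2: 2.0, 3: 3.0}, "heavy": {1: 1.0, 2: 3.0, 3: 5.0}}

#: additive-rule enforcement fractions (poor anchors at 0, strong at 1)
_ADDITIVE_ENFORCEMENT = {"poor": 0.0, "moderate": 0.5, "strong": 1.0}

#: stringency vs enforcement shares for the additive rules
_COMBO_SHARES = {"fifty_fifty": (0.5, 0.5), "twentyfive_seventyfive": (0.25, 0.75)}


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class WeightScheme:
    """A named assignment of non-negative weights to topics.

    Only relative weights matter: calibrated scores are invariant to
    rescaling all weights by a positive constant.
    """

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ScoringError(f"scheme {self.name!r}: negative weight")
        if sum(self.weights.values()) <= 0:
            raise ScoringError(f"scheme {self.name!r}: total weight must be positive")

    def weight(self, topic_id: str) -> float:
        try:
            return self.weights[topic_id]
        except KeyError:
            raise ScoringError(
                f"scheme {self.name!r} has no weight for topic {topic_id!r}"
            ) from None

    @property
    def total(self) -> float:
        return sum(self.weights.values())


def star_weight_scheme(name: str, codebook: PolicyCodebook) -> WeightScheme:
    """Build the baseline (1/2/3), heavy (1/3/5) or equal scheme for a codebook."""
    if name == "equal":
        return WeightScheme("equal", {t.id: 1.0 for t in codebook})
    if name in _STAR_WEIGHTS:
        table = _STAR_WEIGHTS[name]
        return WeightScheme(name, {t.id: table[t.stars] for t in codebook})
    raise ScoringError(
        f"unknown star-based scheme {name!r}; expected baseline, heavy or equal"
    )


@dataclass(frozen=True)
class AssumptionSet:
    """One cell of the 4 x 3 (weighting x combination) grid."""

    weighting: str
    combination: str

    def __post_init__(self) -> None:
        if self.weighting not in WEIGHTINGS:
            raise ScoringError(f"unknown weighting {self.weighting!r}")
        if self.combination not in COMBINATIONS:
            raise ScoringError(f"unknown combination rule {self.combination!r}")

    @property
    def label(self) -> str:
        return f"{self.weighting}/{self.combination}"


def assumption_grid() -> tuple[AssumptionSet, ...]:
    """All 12 assumption sets, weighting-major order."""
    return tuple(
        AssumptionSet(w, c) for w in WEIGHTINGS for c in COMBINATIONS
    )


@dataclass
class ScoreReport:
    """Per-topic, per-domain and total calibrated points for one area."""

    area: str
    assumption: AssumptionSet
    topic_points: dict[str, float]
    domain_points: dict[str, float]
    total: float
    rank: int | None = None


# ---------------------------------------------------------------------------
# Elementary fractions
# ---------------------------------------------------------------------------


def stringency_fraction(topic: PolicyTopic, stringency_label: str) -> float:
    """Linear ordinal map: level i of k (1-based) -> (i-1)/(k-1).

    The least stringent level anchors at 0, the most stringent at 1.
    """
    i = topic.level_index(stringency_label)
    return i / (topic.n_levels - 1)


def enforcement_fraction(level: EnforcementLevel, rule: str) -> float:
    """Enforcement fraction under a combination rule.

    Additive rules anchor poor at 0; the multiplicative rule uses a third
    of the raw 1/2/3 rating, so even poorly enforced stringent policies
    retain a third of their points.
    """
    if rule in _COMBO_SHARES:
        return _ADDITIVE_ENFORCEMENT[level.label]
    if rule == "multiplicative":
        return level.raw / 3.0
    raise ScoringError(f"unknown combination rule {rule!r}")


def combined_fraction(
    topic: PolicyTopic, obs: PolicyObservation, rule: str
) -> float:
    """The weight-free attainment in [0, 1] for one coded topic."""
    sigma = stringency_fraction(topic, obs.stringency_label)
    eps = enforcement_fraction(obs.enforcement, rule)
    if rule == "multiplicative":
        return sigma * eps
    s_share, e_share = _COMBO_SHARES[rule]
    return s_share * sigma + e_share * eps


def topic_max_points(
    topic: PolicyTopic, scheme: WeightScheme, codebook: PolicyCodebook
) -> float:
    """Maximum attainable points for a topic: 100 * w_topic / sum of weights."""
    total = sum(scheme.weight(t.id) for t in codebook)
    if total <= 0:
        raise ScoringError("total weight is zero")
    return 100.0 * scheme.weight(topic.id) / total


def score_topic(
    obs: PolicyObservation,
    topic: PolicyTopic,
    scheme: WeightScheme,
    rule: str,
    codebook: PolicyCodebook,
) -> float:
    """Points awarded for one topic under a weighting scheme and rule."""
    return topic_max_points(topic, scheme, codebook) * combined_fraction(
        topic, obs, rule
    )


# ---------------------------------------------------------------------------
# Area-level scoring
# ---------------------------------------------------------------------------


def max_attainable_score(scheme: WeightScheme, rule: str, codebook: PolicyCodebook) -> float:
    """Score of the all-max-stringency, strong-enforcement framework.

    With the fraction conventions above this is exactly 100 for every
    scheme and rule, but it is computed rather than assumed so that
    calibration stays correct under exotic user-supplied conventions.
    """
    best = AreaFramework(
        "__max__",
        tuple(
            PolicyObservation(
                "__max__", t.id, t.stringency_levels[-1], EnforcementLevel("strong")
            )
            for t in codebook
        ),
    )
    return _raw_score(best, scheme, rule, codebook)


def calibrate(
    raw_score: float, scheme: WeightScheme, rule: str, codebook: PolicyCodebook | None = None
) -> float:
    """Rescale a raw score so the maximum attainable becomes 100."""
    cb = codebook if codebook is not None else default_codebook()
    m = max_attainable_score(scheme, rule, cb)
    if m <= 0:
        raise ScoringError("maximum attainable score is non-positive")
    return 100.0 * raw_score / m


def _raw_score(
    framework: AreaFramework, scheme: WeightScheme, rule: str, codebook: PolicyCodebook
) -> float:
    return sum(
        score_topic(framework.observation(t.id), t, scheme, rule, codebook)
        for t in codebook
    )


def score_area(
    framework: AreaFramework,
    scheme: WeightScheme,
    rule: str,
    codebook: PolicyCodebook | None = None,
    assumption: AssumptionSet | None = None,
) -> ScoreReport:
    """Score one validated framework; rank is left unset.

    Topic and domain points are calibrated jointly with the total, so
    conservation (domain points sum to the total) holds exactly.
    """
    cb = codebook if codebook is not None else default_codebook()
    m = max_attainable_score(scheme, rule, cb)
    if m <= 0:
        raise ScoringError("maximum attainable score is non-positive")
    scale = 100.0 / m
    topic_points = {
        t.id: scale * score_topic(framework.observation(t.id), t, scheme, rule, cb)
        for t in cb
    }
    domain_points = {
        d: sum(topic_points[t.id] for t in cb.domain_topics(d)) for d in DOMAINS
    }
    total = sum(topic_points.values())
    if assumption is None:
        weighting = scheme.name if scheme.name in WEIGHTINGS else "area_specific"
        assumption = AssumptionSet(weighting, rule)
    return ScoreReport(
        area=framework.area,
        assumption=assumption,
        topic_points=topic_points,
        domain_points=domain_points,
        total=total,
    )


def rank_areas(reports: Sequence[ScoreReport]) -> list[ScoreReport]:
    """Assign competition ranks (rank 1 = highest score; ties share the
    minimum rank).  Returns reports sorted by descending score, ties broken
    by area name for stable output only."""
    if not reports:
        raise ScoringError("cannot rank an empty list of reports")
    ordered = sorted(reports, key=lambda r: (-r.total, r.area))
    ranked: list[ScoreReport] = []
    for pos, rep in enumerate(ordered):
        if pos > 0 and rep.total == ranked[-1].total:
            rank = ranked[-1].rank
        else:
            rank = pos + 1
        ranked.append(replace_rank(rep, rank))
    return ranked


def replace_rank(report: ScoreReport, rank: int) -> ScoreReport:
    return ScoreReport(
        area=report.area,
        assumption=report.assumption,
        topic_points=dict(report.topic_points),
        domain_points=dict(report.domain_points),
        total=report.total,
        rank=rank,
    )


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Display rounding: half away from zero (spreadsheet convention)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
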