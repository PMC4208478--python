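"""Policy codebook: the 16-topic schema of TEASE-16.

The Toolkit for Evaluating Alcohol policy Stringency and Enforcement
(TEASE-16) rates 16 national alcohol-control policies grouped into five
regulatory domains.  Each topic carries

* an effectiveness *star rating* (1-3 stars, from expert reviews of the
  policy literature) that drives its weight in the composite score,
* an ordered list of *stringency levels* (least to most stringent), and
* a three-level *enforcement* rating (poor / moderate / strong).

This module defines the schema types, ships the default 16-topic codebook
as a built-in, and validates per-jurisdiction codings against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DOMAINS = (
    "physical_availability",
    "drinking_context",
    "alcohol_prices",
    "alcohol_advertising",
    "motor_vehicles",
)

DOMAIN_LABELS = {
    "physical_availability": "Physical availability",
    "drinking_context": "Drinking context",
    "alcohol_prices": "Alcohol prices",
    "alcohol_advertising": "Alcohol advertising",
    "motor_vehicles": "Motor vehicle regulations",
}

ENFORCEMENT_LEVELS = ("poor", "moderate", "strong")
#: raw 1/2/3 codes for poor/moderate/strong, used by the multiplicative rule
ENFORCEMENT_RAW = {"poor": 1, "moderate": 2, "strong": 3}


class CodebookError(ValueError):
    """Raised for malformed codebooks or codings that violate the schema."""


@dataclass(frozen=True)
class EnforcementLevel:
    """One of the three enforcement categories."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in ENFORCEMENT_LEVELS:
            raise CodebookError(
                f"unknown enforcement label {self.label!r}; "
                f"expected one of {ENFORCEMENT_LEVELS}"
            )

    @property
    def raw(self) -> int:
        return ENFORCEMENT_RAW[self.label]


@dataclass(frozen=True)
class PolicyTopic:
    """A single policy topic with its ordinal stringency scale.

    ``stringency_levels`` are ordered least -> most stringent; scoring maps
    ordinal position i (1-based, k levels) to the fraction (i-1)/(k-1).
    """

    id: str
    domain: str
    label: str
    stars: int
    stringency_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise CodebookError(f"topic {self.id!r}: unknown domain {self.domain!r}")
        if self.stars not in (1, 2, 3):
            raise CodebookError(
                f"topic {self.id!r}: star rating must be 1, 2 or 3, got {self.stars}"
            )
        if len(self.stringency_levels) < 2:
            raise CodebookError(
                f"topic {self.id!r}: needs at least 2 stringency levels"
            )
        if len(set(self.stringency_levels)) != len(self.stringency_levels):
            raise CodebookError(f"topic {self.id!r}: duplicate stringency labels")

    @property
    def n_levels(self) -> int:
        return len(self.stringency_levels)

    def level_index(self, label: str) -> int:
        """0-based ordinal position of a stringency label."""
        try:
            return self.stringency_levels.index(label)
        except ValueError:
            raise CodebookError(
                f"topic {self.id!r}: unknown stringency label {label!r}; "
                f"levels are {list(self.stringency_levels)}"
            ) from None


@dataclass(frozen=True)
class PolicyCodebook:
    """An ordered collection of policy topics."""

    topics: tuple[PolicyTopic, ...]

    def __post_init__(self) -> None:
        ids = [t.id for t in self.topics]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CodebookError(f"duplicate topic ids: {dupes}")
        if not self.topics:
            raise CodebookError("codebook has no topics")

    def __iter__(self):
        return iter(self.topics)

    def __len__(self) -> int:
        return len(self.topics)

    @property
    def topic_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.topics)

    def topic(self, topic_id: str) -> PolicyTopic:
        for t in self.topics:
            if t.id == topic_id:
                return t
        raise CodebookError(f"unknown topic id {topic_id!r}")

    def domain_topics(self, domain: str) -> tuple[PolicyTopic, ...]:
        return tuple(t for t in self.topics if t.domain == domain)

    @property
    def star_sum(self) -> int:
        return sum(t.stars for t in self.topics)

    def to_dict(self) -> dict:
        return {
            "topics": [
                {
                    "id": t.id,
                    "domain": t.domain,
                    "label": t.label,
                    "stars": t.stars,
                    "stringency_levels": list(t.stringency_levels),
                }
                for t in self.topics
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


@dataclass(frozen=True)
class PolicyObservation:
    """One jurisdiction's coded stringency + enforcement for one topic."""

    area: str
    topic_id: str
    stringency_label: str
    enforcement: EnforcementLevel


@dataclass(frozen=True)
class AreaFramework:
    """A jurisdiction's complete set of policy observations, one per topic."""

    area: str
    observations: tuple[PolicyObservation, ...] = field(default_factory=tuple)

    def observation(self, topic_id: str) -> PolicyObservation:
        for obs in self.observations:
            if obs.topic_id == topic_id:
                return obs
        raise CodebookError(f"area {self.area!r}: no observation for {topic_id!r}")

    def replace(self, obs: PolicyObservation) -> "AreaFramework":
        """Return a copy with the observation for ``obs.topic_id`` swapped."""
        new = tuple(o if o.topic_id != obs.topic_id else obs for o in self.observations)
        return AreaFramework(self.area, new)


# ---------------------------------------------------------------------------
# Default codebook
# ---------------------------------------------------------------------------

# 16 topics in 5 domains.  Star census: seven 3-star, eight 2-star, one
# 1-star (star sum 38).  Continuous quantities (price indices, blood-alcohol
# limits, breath-testing frequency) are banded and treated purely ordinally.
_DEFAULT_TOPICS: tuple[tuple[str, str, str, int, tuple[str, ...]], ...] = (
    (
        "purchase_age",
        "physical_availability",
        "Legal minimum age for alcohol purchase (years)",
        3,
        ("16", "17", "18", "19", ">=20"),
    ),
    (
        "server_liability",
        "physical_availability",
        "Alcohol server liability for damages caused by actions of patrons",
        2,
        ("No", "Yes"),
    ),
    (
        "retail_monopoly",
        "physical_availability",
        "Government monopoly of alcohol retail sales",
        2,
        ("None", "Partial government monopoly", "Full government monopoly"),
    ),
    (
        "outlet_density",
        "physical_availability",
        "Restrictions on density of outlets",
        2,
        ("None", "On wine only", "On wine and spirits", "On wine, spirits and beer"),
    ),
    (
        "hours_days_sale",
        "physical_availability",
        "Restrictions on the hours and days of sale",
        2,
        ("None", "On hours or days", "On both hours and days"),
    ),
    (
        "community_mobilization",
        "drinking_context",
        "Community mobilization programmes to increase public awareness "
        "or prevent alcohol problems",
        2,
        ("No", "Yes"),
    ),
    (
        "bar_staff_training",
        "drinking_context",
        "Mandatory training of bar staff and management to better manage aggression",
        2,
        ("No", "Yes"),
    ),
    (
        "beer_price_index",
        "alcohol_prices",
        "Beer price index",
        3,
        ("0-0.29", "0.30-0.59", "0.60-0.89", ">=0.90"),
    ),
    (
        "wine_price_index",
        "alcohol_prices",
        "Wine price index",
        3,
        ("0-0.9", "1.0-1.9", "2.0-2.9", ">=3.0"),
    ),
    (
        "spirit_price_index",
        "alcohol_prices",
        "Spirit price index",
        3,
        ("0-2.9", "3.0-5.9", "6.0-8.9", ">=9.0"),
    ),
    (
        "advertising_restrictions",
        "alcohol_advertising",
        "Restrictions imposed on the majority of alcohol advertising media",
        1,
        (
            "No restrictions",
            "Industry self-regulation",
            "Partial statutory restrictions",
            "Ban",
        ),
    ),
    (
        "random_breath_testing",
        "motor_vehicles",
        "Frequency of random breath testing",
        3,
        ("Never", "Rarely", "Occasionally", "Often", "Very often"),
    ),
    (
        "bac_limit_adult",
        "motor_vehicles",
        "Legal blood alcohol concentration limit in adult drivers",
        3,
        (">=0.08", "0.03-0.07", "0-0.02"),
    ),
    (
        "bac_limit_youth",
        "motor_vehicles",
        "Legal blood alcohol concentration limit in youth drivers",
        3,
        (">=0.04", "0.02-0.03", "0-0.01"),
    ),
    (
        "mandatory_penalties",
        "motor_vehicles",
        "Mandatory penalties for exceeding the legal maximum blood "
        "alcohol concentration",
        2,
        (
            "No penalty",
            "Fine",
            "Penalty points",
            "Disqualification or licence suspension",
            "Imprisonment",
            "Other",
        ),
    ),
    (
        "graduated_licensing",
        "motor_vehicles",
        "Graduated licensing for young drivers",
        2,
        ("No", "Yes"),
    ),
)

#: Numeric bands for topics whose stringency scale discretizes a continuous
#: quantity.  Each band is half-open, closed on its printed lower bound; the
#: value is the list of lower bounds aligned with the topic's levels.  For
#: the blood-alcohol topics the scale runs from lax (high limit) to strict
#: (low limit), so bands are matched on the *upper* side instead.
_NUMERIC_BANDS: dict[str, tuple[str, tuple[float, ...]]] = {
    "beer_price_index": ("lower", (0.0, 0.30, 0.60, 0.90)),
    "wine_price_index": ("lower", (0.0, 1.0, 2.0, 3.0)),
    "spirit_price_index": ("lower", (0.0, 3.0, 6.0, 9.0)),
    # descending thresholds: a *lower* legal limit is more stringent
    "bac_limit_adult": ("upper", (0.08, 0.03, 0.0)),
    "bac_limit_youth": ("upper", (0.04, 0.02, 0.0)),
}


def default_codebook() -> PolicyCodebook:
    """The built-in 16-topic codebook."""
    return PolicyCodebook(
        tuple(PolicyTopic(i, d, lab, s, lv) for i, d, lab, s, lv in _DEFAULT_TOPICS)
    )


def band_for_value(topic_id: str, value: float) -> str:
    """Map a numeric quantity to its ordinal stringency band.

    Convenience converter for the banded topics (price indices,
    blood-alcohol limits).  Bands are half-open, closed on the printed
    bound; scoring itself never sees the number, only the band label.
    """
    if topic_id not in _NUMERIC_BANDS:
        raise CodebookError(f"topic {topic_id!r} has no numeric bands")
    side, bounds = _NUMERIC_BANDS[topic_id]
    topic = default_codebook().topic(topic_id)
    if value < 0:
        raise CodebookError(f"negative value {value} for {topic_id!r}")
    if side == "lower":
        idx = 0
        for j, lo in enumerate(bounds):
            if value >= lo:
                idx = j
    else:  # 'upper': thresholds descend; stricter band = lower limit
        idx = 0
        for j in range(1, len(bounds)):
            if value < bounds[j - 1]:
                idx = j
    return topic.stringency_levels[idx]


def load_codebook(source: str | Path | Mapping = "default") -> PolicyCodebook:
    """Load a codebook from the built-in default, a JSON file, or a mapping.

    The JSON layout mirrors :meth:`PolicyCodebook.to_dict`:
    ``{"topics": [{"id", "domain", "label", "stars", "stringency_levels"}]}``.
    """
    if isinstance(source, str) and source == "default":
        return default_codebook()
    if isinstance(source, Mapping):
        data = source
    else:
        data = json.loads(Path(source).read_text(encoding="utf-8"))
    if "topics" not in data or not isinstance(data["topics"], list):
        raise CodebookError("codebook source must contain a 'topics' list")
    topics = []
    for entry in data["topics"]:
        try:
            topics.append(
                PolicyTopic(
                    id=str(entry["id"]),
                    domain=str(entry["domain"]),
                    label=str(entry.get("label", entry["id"])),
                    stars=int(entry["stars"]),
                    stringency_levels=tuple(str(x) for x in entry["stringency_levels"]),
                )
            )
        except KeyError as exc:
            raise CodebookError(f"codebook topic entry missing field {exc}") from None
    return PolicyCodebook(tuple(topics))


def validate_framework(
    framework: AreaFramework, codebook: PolicyCodebook
) -> AreaFramework:
    """Check that a framework covers every topic exactly once with legal labels.

    Returns the framework unchanged if valid; raises :class:`CodebookError`
    naming the area and topic otherwise.
    """
    seen: dict[str, int] = {}
    for obs in framework.observations:
        if obs.area != framework.area:
            raise CodebookError(
                f"area {framework.area!r}: observation labelled for "
                f"different area {obs.area!r}"
            )
        seen[obs.topic_id] = seen.get(obs.topic_id, 0) + 1
        topic = codebook.topic(obs.topic_id)  # raises on unknown topic
        if obs.stringency_label not in topic.stringency_levels:
            raise CodebookError(
                f"area {framework.area!r}, topic {obs.topic_id!r}: "
                f"unknown stringency label {obs.stringency_label!r}"
            )
    dupes = sorted(t for t, n in seen.items() if n > 1)
    if dupes:
        raise CodebookError(
            f"area {framework.area!r}: duplicate observations for topics {dupes}"
        )
    missing = sorted(set(codebook.topic_ids) - set(seen))
    if missing:
        raise CodebookError(
            f"area {framework.area!r}: missing observations for topics {missing}"
        )
    return framework


def make_framework(
    area: str,
    codings: Mapping[str, tuple[str, str]],
    codebook: PolicyCodebook | None = None,
) -> AreaFramework:
    """Build and validate a framework from ``{topic_id: (stringency, enforcement)}``."""
    cb = codebook if codebook is not None else default_codebook()
    obs = tuple(
        PolicyObservation(area, tid, s, EnforcementLevel(e))
        for tid, (s, e) in codings.items()
    )
    return validate_framework(AreaFramework(area, obs), cb)
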