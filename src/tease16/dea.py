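"""Area-specific weights by data envelopment analysis (DEA).

Each jurisdiction is allowed to choose the topic weights most favourable to
itself, subject to shared plausibility constraints:

* weights respect the effectiveness star ordering — every 3-star topic
  weight strictly exceeds every 2-star weight, which strictly exceeds every
  1-star weight (strictness realized with a small gap, LPs cannot express
  strict inequalities);
* the largest weight is at most ``ratio_bound`` (default 12) times the
  smallest, which also keeps every weight strictly positive;
* no jurisdiction's calibrated score under the chosen weights may exceed
  100.

With weights w and weight-free topic attainments a_j in [0, 1], the
calibrated score is 100 * sum(w_j a_j) / sum(w_j) — a ratio of linear
forms, homogeneous of degree zero in w.  The fractional program is
linearized Charnes-Cooper style by fixing sum(w_j) = 1, after which the
objective and every constraint are linear and the problem is solved exactly
with :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .codebook import AreaFramework, PolicyCodebook, default_codebook
from .scoring import WeightScheme, combined_fraction


class DEAError(ValueError):
    pass


@dataclass(frozen=True)
class DEAProblem:
    """One focal-area weight-optimization instance.

    ``attainments`` maps area -> {topic_id -> fraction in [0, 1]} under a
    fixed combination rule; ``star_order`` maps topic_id -> stars.
    """

    attainments: Mapping[str, Mapping[str, float]]
    focal_area: str
    star_order: Mapping[str, int]
    ratio_bound: float = 12.0
    order_gap: float = 1e-6

    def __post_init__(self) -> None:
        if self.ratio_bound <= 1:
            raise DEAError("ratio_bound must exceed 1")
        if self.order_gap <= 0:
            raise DEAError("order_gap must be positive")
        if self.focal_area not in self.attainments:
            raise DEAError(f"focal area {self.focal_area!r} not among areas")


@dataclass
class DEASolution:
    weights: dict[str, float]
    focal_score: float
    status: str  # "optimal" | "infeasible"
    message: str = ""


def topic_attainment(
    framework: AreaFramework,
    rule: str,
    codebook: PolicyCodebook | None = None,
) -> dict[str, float]:
    """Weight-free attainment per topic: the topic score divided by its
    maximum points.  The calibrated score under weights w is then
    100 * sum(w_j a_j) / sum(w_j)."""
    cb = codebook if codebook is not None else default_codebook()
    return {
        t.id: combined_fraction(t, framework.observation(t.id), rule) for t in cb
    }


def score_under_weights(
    attainment: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Calibrated score 100 * sum(w a) / sum(w); degree-zero homogeneous in w."""
    total = sum(weights.values())
    if total <= 0:
        raise DEAError("weights must have positive total")
    return 100.0 * sum(weights[t] * attainment[t] for t in weights) / total


def solve_area_weights(problem: DEAProblem) -> DEASolution:
    """Maximize the focal area's calibrated score over admissible weights.

    Linearization: with sum(w) = 1, maximize sum(w_j a_j^focal) subject to
    sum(w_j a_j^k) <= 1 for every area k, pairwise star-order constraints
    with gap, and w_j <= ratio_bound * m with m <= w_j for an auxiliary
    lower-bound variable m.
    """
    topics = list(problem.attainments[problem.focal_area].keys())
    n = len(topics)
    idx = {t: j for j, t in enumerate(topics)}
    a_focal = np.array(
        [problem.attainments[problem.focal_area][t] for t in topics]
    )

    # variables: w_0..w_{n-1}, m (auxiliary lower bound on weights)
    nvar = n + 1
    c = np.zeros(nvar)
    c[:n] = -a_focal  # linprog minimizes

    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []

    # every area's normalized weighted attainment stays <= 1 (score <= 100)
    for area, att in problem.attainments.items():
        row = np.zeros(nvar)
        for t in topics:
            row[idx[t]] = att[t]
        A_ub.append(row)
        b_ub.append(1.0)

    # star ordering: higher-star weight exceeds lower-star weight by the gap
    stars = {t: problem.star_order[t] for t in topics}
    for ti in topics:
        for tj in topics:
            if stars[ti] > stars[tj]:
                row = np.zeros(nvar)
                row[idx[tj]] = 1.0
                row[idx[ti]] = -1.0
                A_ub.append(row)  # w_j - w_i <= -gap
                b_ub.append(-problem.order_gap)

    # m <= w_j  and  w_j <= ratio_bound * m
    for t in topics:
        row = np.zeros(nvar)
        row[-1] = 1.0
        row[idx[t]] = -1.0
        A_ub.append(row)  # m - w <= 0
        b_ub.append(0.0)
        row = np.zeros(nvar)
        row[idx[t]] = 1.0
        row[-1] = -problem.ratio_bound
        A_ub.append(row)  # w - R*m <= 0
        b_ub.append(0.0)

    A_eq = np.zeros((1, nvar))
    A_eq[0, :n] = 1.0  # sum(w) = 1
    b_eq = [1.0]

    res = linprog(
        c,
        A_ub=np.vstack(A_ub),
        b_ub=np.array(b_ub),
        A_eq=A_eq,
        b_eq=np.array(b_eq),
        bounds=[(0.0, None)] * n + [(0.0, None)],
        method="highs",
    )
    if not res.success:
        return DEASolution(
            weights={}, focal_score=float("nan"), status="infeasible", message=res.message
        )
    assert res.status == 0, "normalized LP cannot be unbounded"
    weights = {t: float(res.x[idx[t]]) for t in topics}
    focal_score = float(100.0 * a_focal @ res.x[:n])
    return DEASolution(weights=weights, focal_score=focal_score, status="optimal")


def solve_all_areas(
    frameworks: Sequence[AreaFramework],
    rule: str,
    codebook: PolicyCodebook | None = None,
    ratio_bound: float = 12.0,
    order_gap: float = 1e-6,
) -> dict[str, DEASolution]:
    """One independent weight optimization per area; an infeasible area is
    reported in its own solution and does not abort the others."""
    cb = codebook if codebook is not None else default_codebook()
    attainments = {f.area: topic_attainment(f, rule, cb) for f in frameworks}
    star_order = {t.id: t.stars for t in cb}
    out: dict[str, DEASolution] = {}
    for f in frameworks:
        problem = DEAProblem(
            attainments=attainments,
            focal_area=f.area,
            star_order=star_order,
            ratio_bound=ratio_bound,
            order_gap=order_gap,
        )
        out[f.area] = solve_area_weights(problem)
    return out


def dea_weight_scheme(solution: DEASolution) -> WeightScheme:
    """Wrap an optimal DEA solution as a scoring weight scheme."""
    if solution.status != "optimal":
        raise DEAError(f"cannot build scheme from {solution.status} solution")
    return WeightScheme("area_specific", dict(solution.weights))
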