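"""Sensitivity analysis over the 12-assumption scoring grid.

The robustness of the composite index is probed by recomputing every
jurisdiction's calibrated score and rank under all 12 assumption sets
(4 weightings x 3 combination rules), then summarizing each jurisdiction by
the median and range of its 12 ranks and scores and correlating the medians
(and the extremes) against the baseline configuration
(baseline star weights + 50:50 combination).
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import AreaFramework, PolicyCodebook, default_codebook
from .dea import dea_weight_scheme, solve_all_areas
from .scoring import (
    COMBINATIONS,
    AssumptionSet,
    assumption_grid,
    rank_areas,
    score_area,
    star_weight_scheme,
)

BASELINE = AssumptionSet("baseline", "fifty_fifty")


@dataclass
class AreaSummary:
    area: str
    baseline_rank: int
    median_rank: int
    rank_range: tuple[int, int]
    baseline_score: float
    median_score: float
    score_range: tuple[float, float]


@dataclass
class SensitivityResult:
    per_area: dict[str, AreaSummary]
    correlations: dict[str, dict[str, float]]
    scores: pd.DataFrame  # area x assumption-label
    ranks: pd.DataFrame


def run_grid(
    frameworks: Sequence[AreaFramework],
    codebook: PolicyCodebook | None = None,
    ratio_bound: float = 12.0,
    order_gap: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibrated scores and ranks for every area under all 12 assumptions.

    Returns ``(scores, ranks)`` DataFrames indexed by area with one column
    per assumption set (label ``weighting/combination``).  The
    area-specific columns use each area's own DEA-optimized weights.
    """
    if len(frameworks) < 2:
        raise ValueError("sensitivity grid needs at least 2 areas")
    cb = codebook if codebook is not None else default_codebook()
    areas = [f.area for f in frameworks]
    scores = pd.DataFrame(index=areas, dtype=float)
    ranks = pd.DataFrame(index=areas, dtype=float)
    for assumption in assumption_grid():
        reports = []
        if assumption.weighting == "area_specific":
            solutions = solve_all_areas(
                frameworks, assumption.combination, cb, ratio_bound, order_gap
            )
            for f in frameworks:
                sol = solutions[f.area]
                if sol.status != "optimal":
                    raise RuntimeError(
                        f"DEA infeasible for area {f.area!r} under "
                        f"{assumption.label}: {sol.message}"
                    )
                scheme = dea_weight_scheme(sol)
                reports.append(
                    score_area(f, scheme, assumption.combination, cb, assumption)
                )
        else:
            scheme = star_weight_scheme(assumption.weighting, cb)
            reports = [
                score_area(f, scheme, assumption.combination, cb, assumption)
                for f in frameworks
            ]
        ranked = {r.area: r for r in rank_areas(reports)}
        scores[assumption.label] = [ranked[a].total for a in areas]
        ranks[assumption.label] = [ranked[a].rank for a in areas]
    return scores, ranks


def median_rank(values: Sequence[float]) -> int:
    """Median of ranks reported as an integer; an exact .5 rounds toward the
    better (smaller) rank, matching how integer medians arise from an even
    number of assumption sets."""
    med = float(np.median(values))
    frac = med - math.floor(med)
    if abs(frac - 0.5) < 1e-12:
        return math.floor(med)
    return round(med)


def summarize(scores: pd.DataFrame, ranks: pd.DataFrame) -> SensitivityResult:
    """Per-area medians/ranges plus correlations of medians and extremes
    against the baseline assumption."""
    base = BASELINE.label
    per_area: dict[str, AreaSummary] = {}
    for area in scores.index:
        srow = scores.loc[area]
        rrow = ranks.loc[area]
        per_area[area] = AreaSummary(
            area=area,
            baseline_rank=int(rrow[base]),
            median_rank=median_rank(rrow.to_numpy()),
            rank_range=(int(rrow.min()), int(rrow.max())),
            baseline_score=float(srow[base]),
            median_score=float(srow.median()),
            score_range=(float(srow.min()), float(srow.max())),
        )

    def extreme(row: pd.Series, baseline: float) -> float:
        # the range endpoint farthest from the baseline value
        lo, hi = row.min(), row.max()
        return float(lo if abs(baseline - lo) >= abs(hi - baseline) else hi)

    base_ranks = [per_area[a].baseline_rank for a in scores.index]
    base_scores = [per_area[a].baseline_score for a in scores.index]
    med_ranks = [per_area[a].median_rank for a in scores.index]
    med_scores = [per_area[a].median_score for a in scores.index]
    ext_ranks = [extreme(ranks.loc[a], per_area[a].baseline_rank) for a in scores.index]
    ext_scores = [
        extreme(scores.loc[a], per_area[a].baseline_score) for a in scores.index
    ]
    def _corr(x, y, method):
        # degenerate grids (e.g. identical areas) have no defined correlation
        try:
            return correlate(x, y, method)
        except ValueError:
            return {"r": float("nan"), "p": float("nan")}

    correlations = {
        "rank_median_vs_baseline": _corr(base_ranks, med_ranks, "spearman"),
        "score_median_vs_baseline": _corr(base_scores, med_scores, "pearson"),
        "rank_extreme_vs_baseline": _corr(base_ranks, ext_ranks, "spearman"),
        "score_extreme_vs_baseline": _corr(base_scores, ext_scores, "pearson"),
    }
    return SensitivityResult(
        per_area=per_area, correlations=correlations, scores=scores, ranks=ranks
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> dict[str, float]:
    """Pearson or tie-corrected Spearman correlation with its p-value.

    Spearman assigns average ranks to ties and computes Pearson on the
    ranks; p-values come from the t approximation on n-2 degrees of
    freedom.  Zero variance in either margin is an error (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return {"r": float(r), "p": float(p)}


def format_p(p: float) -> str:
    """Report small p-values as '<0.0001' (conventional display)."""
    return "<0.0001" if p < 1e-4 else f"{p:.4g}"


def run_sensitivity(
    frameworks: Sequence[AreaFramework],
    codebook: PolicyCodebook | None = None,
    ratio_bound: float = 12.0,
) -> SensitivityResult:
    """Full pipeline: 12-assumption grid then per-area summary."""
    scores, ranks = run_grid(frameworks, codebook, ratio_bound)
    return summarize(scores, ranks)
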