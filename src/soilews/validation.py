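"""Stratified validation of the hazard map against expert labels.

Mirrors a standard ground-truthing protocol: sample 100 points from the
hazard map, half from the severe stratum (hazard classes 4-5) and half
from the low stratum (classes 1-2), score each point on a trichotomous
agreement scale — 0 when model and expert class coincide, +1 when the
model over-predicts, -1 when it under-predicts — and compare score
distributions between strata with the nonparametric Mann-Whitney U test.
The mean agreement score is reported alongside as a -1..1 summary of bias.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SamplePoint",
    "SEVERE_CLASSES",
    "LOW_CLASSES",
    "stratified_sample",
    "agreement_scores",
    "mann_whitney_u",
    "validate_map",
]

#: Hazard classes treated as the severe-erosion stratum.
SEVERE_CLASSES = (4, 5)
#: Hazard classes treated as the low-erosion stratum (class 3 is excluded
#: from sampling as an intermediate band).
LOW_CLASSES = (1, 2)


@dataclass
class SamplePoint:
    row: int
    col: int
    stratum: str  # "severe" | "low"
    model_class: int
    expert_class: int | None = None
    score: int | None = None


def stratified_sample(
    hazard: np.ndarray,
    n_total: int = 100,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> list[SamplePoint]:
    """Sample ``n_total`` pixels without replacement, half per stratum.

    Raises when a stratum has fewer eligible pixels than requested, naming
    the stratum.
    """
    hazard = np.asarray(hazard)
    if n_total % 2:
        raise ValueError("n_total must be even (equal split across strata)")
    if mask is None:
        mask = np.zeros(hazard.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    per_stratum = n_total // 2
    points: list[SamplePoint] = []
    for name, classes in (("severe", SEVERE_CLASSES), ("low", LOW_CLASSES)):
        eligible = np.flatnonzero(np.isin(hazard, classes).ravel() & ~mask.ravel())
        if eligible.size < per_stratum:
            raise ValueError(
                f"stratum {name!r} has only {eligible.size} eligible pixels; "
                f"need {per_stratum}"
            )
        chosen = rng.choice(eligible, size=per_stratum, replace=False)
        chosen.sort()
        for flat in chosen:
            r, c = np.unravel_index(flat, hazard.shape)
            points.append(
                SamplePoint(row=int(r), col=int(c), stratum=name,
                            model_class=int(hazard[r, c]))
            )
    return points


def agreement_scores(points: list[SamplePoint]) -> list[int]:
    """sign(model class - expert class) per point; scores stored in place.

    Points without an expert label are excluded with a warning.
    """
    scores = []
    for pt in points:
        if pt.expert_class is None:
            warnings.warn(f"point ({pt.row},{pt.col}) has no expert label; excluded")
            continue
        pt.score = int(np.sign(pt.model_class - pt.expert_class))
        scores.append(pt.score)
    return scores


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U (statistic of sample_a) with two-sided p.

    Exact enumeration when n_a + n_b <= 12 and there are no ties;
    tie-corrected normal approximation otherwise. U is reported for
    sample_a, so identical samples give U = n_a*n_b/2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.unique(np.concatenate([a, b]))
    if pooled.size == 1:  # degenerate: every observation identical
        return float(a.size * b.size / 2), 1.0
    no_ties = pooled.size == a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def validate_map(
    hazard: np.ndarray,
    expert: np.ndarray,
    n_total: int = 100,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> dict:
    """Full validation pass: sample, score against an expert raster, test.

    ``expert`` is a co-registered raster of expert hazard classes (the
    synthetic generator's truth-derived classes serve as pseudo-expert
    input). Returns the points table, the U statistic and p comparing
    severe-vs-low score distributions, and the mean agreement score.
    """
    expert = np.asarray(expert)
    if expert.shape != np.asarray(hazard).shape:
        raise ValueError("expert raster must be co-registered with the hazard raster")
    points = stratified_sample(hazard, n_total=n_total, seed=seed, mask=mask)
    for pt in points:
        pt.expert_class = int(expert[pt.row, pt.col])
    scores = agreement_scores(points)
    severe = [pt.score for pt in points if pt.stratum == "severe" and pt.score is not None]
    low = [pt.score for pt in points if pt.stratum == "low" and pt.score is not None]
    u, p = mann_whitney_u(severe, low)
    table = pd.DataFrame(
        [
            {
                "row": pt.row, "col": pt.col, "stratum": pt.stratum,
                "model_class": pt.model_class, "expert_class": pt.expert_class,
                "score": pt.score,
            }
            for pt in points
        ]
    )
    return {
        "points": table,
        "U": u,
        "p": p,
        "mean_agreement": float(np.mean(scores)) if scores else float("nan"),
    }
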