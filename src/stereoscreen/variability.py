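"""Stereoselectivity screening by docking-score variability.

A protein whose four isomer scores spread widely is stereoselective; one
whose scores are nearly equal binds all isomers alike.  This module
computes per-protein descriptive variability (sample variance and SD of the
four isomer scores, n−1 denominator) and, when replicate scores per isomer
are available (e.g. per-GA-run docking energies), a one-way ANOVA across
isomers.

Note on reported quantities: the published screen labels its per-protein
spread values "SD", but those printed values coincide numerically with the
*sample variance* of the four tabulated scores.  Both quantities are
therefore reported here under unambiguous names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .score_io import IsomerId, ProteinRecord, ScoreTable

__all__ = [
    "VarianceResult",
    "AnovaResult",
    "isomer_variance",
    "rank_by_variability",
    "one_way_anova",
    "ANOVA_ALPHA",
]

ANOVA_ALPHA = 0.01


@dataclass(frozen=True)
class VarianceResult:
    protein: str
    n: int
    sample_variance: float
    sample_sd: float


@dataclass(frozen=True)
class AnovaResult:
    protein: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ANOVA_ALPHA


def isomer_variance(record: ProteinRecord) -> VarianceResult:
    """Sample variance and SD of one protein's four isomer scores."""
    scores = [record.isomer_scores[i] for i in IsomerId]
    return _variance(record.name, scores)


def _variance(name: str, scores: Sequence[float]) -> VarianceResult:
    if len(scores) < 2:
        raise ValueError(f"{name}: need at least 2 scores, got {len(scores)}")
    if not all(math.isfinite(s) for s in scores):
        raise ValueError(f"{name}: non-finite score")
    var = float(np.var(scores, ddof=1))
    return VarianceResult(
        protein=name, n=len(scores), sample_variance=var, sample_sd=math.sqrt(var)
    )


def rank_by_variability(
    table: ScoreTable, restrict: Iterable[str] | None = None
) -> list[VarianceResult]:
    """Per-protein variance results, descending; name-ordered within ties."""
    if restrict is not None:
        table = table.restrict(restrict)
    results = [isomer_variance(rec) for rec in table]
    results.sort(key=lambda r: (-r.sample_variance, r.protein))
    return results


def one_way_anova(
    replicates: Mapping[IsomerId, Sequence[float]] | Mapping[str, Sequence[float]],
    protein: str = "",
) -> AnovaResult:
    """One-way ANOVA across isomer groups from replicate docking scores.

    Computed from the textbook between/within sums of squares; the p-value
    is the upper tail of the F(df_between, df_within) distribution.
    Requires ≥2 groups each with ≥2 replicates — with a single score per
    isomer the within-group variance is undefined and the test ill-posed.
    """
    groups = [np.asarray(v, dtype=float) for v in replicates.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for key, g in zip(replicates, groups):
        if g.size < 2:
            raise ValueError(f"group {key} has {g.size} replicate(s); need >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {key} contains non-finite values")

    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = sum(g.sum() for g in groups) / n_total
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        # all groups internally constant: F is 0 when means agree, else infinite
        f = 0.0 if ss_between == 0.0 else math.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(
        protein=protein,
        f_statistic=float(f),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
    )
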