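"""Rank-and-weight scoring of stereoisomer docking results.

Docking scores alone often fail to separate stereoisomers: within one
protein the four scores may differ by less than the docking error.  The
scoring system implemented here converts each protein's four isomer scores
into competition ranks (best = 4, worst = 1; ties share the rank of their
block), multiplies by a 3/2/1 drug-accessibility weight derived from the
protein's subcellular localization, and sums ranks and weighted ranks within
each functional protein group.  The isomer with the highest weighted sum is
the group's preferred stereoisomer.

Competition rank of isomer *i* is defined as ``4 - #{j : s_j < s_i}`` with
scores in kcal/mol (more negative = better), so tied scores share the
max-style rank and the ranks of an untied quartet are exactly {4, 3, 2, 1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .score_io import IsomerId, Localization, ProteinGroup, ProteinRecord, ScoreTable

__all__ = [
    "RankVector",
    "WeightedRankVector",
    "GroupScoreSummary",
    "competition_ranks",
    "apply_weight",
    "summarize_group",
    "preferred_isomer_report",
]


@dataclass(frozen=True)
class RankVector:
    """Per-protein competition ranks of the four isomers (4 = best)."""

    protein: str
    ranks: Mapping[IsomerId, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", {i: int(self.ranks[i]) for i in IsomerId})
        for iso, r in self.ranks.items():
            if not 1 <= r <= 4:
                raise ValueError(f"{self.protein}: rank {r} for {iso} outside 1..4")


@dataclass(frozen=True)
class WeightedRankVector:
    """Ranks multiplied by the protein's accessibility weight."""

    protein: str
    weight: int
    weighted: Mapping[IsomerId, int]

    def __post_init__(self) -> None:
        if self.weight not in (1, 2, 3):
            raise ValueError(f"{self.protein}: weight {self.weight} outside {{1,2,3}}")
        object.__setattr__(self, "weighted", {i: int(self.weighted[i]) for i in IsomerId})


@dataclass(frozen=True)
class GroupScoreSummary:
    """Per-group rank sums, weighted sums, and the preferred isomer.

    ``preferred_isomer`` attains the maximal weighted sum; if several isomers
    tie for the maximum, ``tie`` is True and ``tied_isomers`` lists all of
    them (``preferred_isomer`` is then the first in fixed isomer order).
    """

    group: ProteinGroup
    sum_scores: Mapping[IsomerId, int]
    weighted_sums: Mapping[IsomerId, int]
    preferred_isomer: IsomerId
    tie: bool
    tied_isomers: tuple[IsomerId, ...]
    n_proteins: int


def competition_ranks(
    scores: Mapping[IsomerId, float] | ProteinRecord, protein: str | None = None
) -> RankVector:
    """Competition-rank the four isomer scores of one protein.

    rank(i) = 4 − number of isomers with a strictly more negative score than
    i, so the best isomer gets 4 and tied isomers share a rank.
    """
    if isinstance(scores, ProteinRecord):
        protein = scores.name
        scores = scores.isomer_scores
    values = {i: float(scores[i]) for i in IsomerId}
    for iso, s in values.items():
        if not math.isfinite(s):
            raise ValueError(f"non-finite score {s} for {iso}")
    ranks = {
        i: 4 - sum(1 for j in IsomerId if values[j] < values[i]) for i in IsomerId
    }
    return RankVector(protein=protein or "", ranks=ranks)


def apply_weight(ranks: RankVector, localization: Localization) -> WeightedRankVector:
    """Multiply each rank by the localization's accessibility weight (3/2/1)."""
    w = localization.weight
    return WeightedRankVector(
        protein=ranks.protein,
        weight=w,
        weighted={i: ranks.ranks[i] * w for i in IsomerId},
    )


def summarize_group(table: ScoreTable, group: ProteinGroup) -> GroupScoreSummary:
    """Sum ranks and weighted ranks over a protein group; pick the winner."""
    records = table.group_records(group)
    if not records:
        raise ValueError(f"no proteins in group {group.value!r}")
    sums = {i: 0 for i in IsomerId}
    wsums = {i: 0 for i in IsomerId}
    for rec in records:
        rv = competition_ranks(rec)
        wv = apply_weight(rv, rec.localization)
        for iso in IsomerId:
            sums[iso] += rv.ranks[iso]
            wsums[iso] += wv.weighted[iso]
    best = max(wsums.values())
    tied = tuple(i for i in IsomerId if wsums[i] == best)
    return GroupScoreSummary(
        group=group,
        sum_scores=sums,
        weighted_sums=wsums,
        preferred_isomer=tied[0],
        tie=len(tied) > 1,
        tied_isomers=tied,
        n_proteins=len(records),
    )


def preferred_isomer_report(table: ScoreTable) -> dict[ProteinGroup, GroupScoreSummary]:
    """One :class:`GroupScoreSummary` per protein group present in the table."""
    return {g: summarize_group(table, g) for g in table.groups_present()}


def per_protein_table(table: ScoreTable) -> list[WeightedRankVector]:
    """Weighted rank vectors for every protein, in table order (audit view)."""
    out = []
    for rec in table:
        out.append(apply_weight(competition_ranks(rec), rec.localization))
    return out
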