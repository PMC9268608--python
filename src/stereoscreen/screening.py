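"""Two-criterion target-selection gate.

A protein passes for a given stereoisomer when (1) the isomer's docking
score is strictly lower (more negative) than the known inhibitor's score,
and (2) the isomer's docked pose engages a binding site similar to the
inhibitor's.  Site similarity, judged visually in the original screen, is
made reproducible here as the Jaccard index of interacting-residue sets:
|A∩B| / |A∪B| over the residues contacted through the selected interaction
types.  The default acceptance threshold is 0.1 — any shared pocket residue
among the small printed residue sets passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .score_io import InteractionProfile, IsomerId, ScoreTable

__all__ = [
    "TargetCall",
    "passes_energy_criterion",
    "residue_overlap",
    "call_targets",
    "DEFAULT_SITE_THRESHOLD",
]

DEFAULT_SITE_THRESHOLD = 0.1


@dataclass(frozen=True)
class TargetCall:
    """Screening verdict for one protein and one stereoisomer.

    ``site_similarity``/``site_pass`` are None when no interaction profiles
    are available for the pair; ``overall_pass`` then falls back to the
    energy criterion alone, with ``site_data_missing`` flagging the fallback.
    ``vacuous_site`` flags a similarity of 1.0 obtained from two empty
    residue sets.
    """

    protein: str
    isomer: IsomerId
    energy_pass: bool
    site_similarity: float | None
    site_pass: bool | None
    overall_pass: bool
    site_data_missing: bool
    vacuous_site: bool = False


def passes_energy_criterion(isomer_score: float, inhibitor_score: float) -> bool:
    """True iff the isomer docks strictly better (more negative) than the inhibitor."""
    if not (math.isfinite(isomer_score) and math.isfinite(inhibitor_score)):
        raise ValueError("docking scores must be finite")
    return isomer_score < inhibitor_score


def residue_overlap(
    profile_a: InteractionProfile,
    profile_b: InteractionProfile,
    types: Iterable[str] | str = "all",
) -> float:
    """Jaccard index of the two profiles' residue sets over selected types.

    Returns 1.0 when both unions are empty (vacuously similar; callers that
    need to distinguish this case should test the unions themselves).
    """
    if profile_a.protein != profile_b.protein:
        raise ValueError(
            f"profiles refer to different proteins: "
            f"{profile_a.protein!r} vs {profile_b.protein!r}"
        )
    a = profile_a.residues(types)
    b = profile_b.residues(types)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def _profile_lookup(
    profiles: Sequence[InteractionProfile],
) -> dict[tuple[str, str], InteractionProfile]:
    return {(p.protein, p.ligand): p for p in profiles}


def call_targets(
    table: ScoreTable,
    profiles: Sequence[InteractionProfile],
    threshold: float = DEFAULT_SITE_THRESHOLD,
    isomer: IsomerId = IsomerId.trans_minus,
    types: Iterable[str] | str = "all",
    inhibitor_ligands: Iterable[str] | None = None,
) -> list[TargetCall]:
    """Apply both selection criteria to every protein in the table.

    The isomer profile is looked up as (protein, isomer name); the inhibitor
    profile as (protein, inhibitor name from the score table, lowercased) —
    or any ligand name in ``inhibitor_ligands`` if given.  Proteins without
    both profiles degrade to the energy criterion with
    ``site_data_missing=True``.  Results are sorted by protein name.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    lookup = _profile_lookup(profiles)
    inhibitor_names = {n.lower() for n in inhibitor_ligands} if inhibitor_ligands else None

    calls = []
    for rec in table:
        energy = passes_energy_criterion(rec.score(isomer), rec.inhibitor_score)
        iso_profile = lookup.get((rec.name, isomer.value))
        inh_profile = None
        for (prot, lig), prof in lookup.items():
            if prot != rec.name or lig == isomer.value:
                continue
            if inhibitor_names is not None:
                if lig.lower() in inhibitor_names:
                    inh_profile = prof
                    break
            elif lig.lower() == rec.inhibitor_name.lower():
                inh_profile = prof
                break
        if iso_profile is not None and inh_profile is not None:
            sim = residue_overlap(iso_profile, inh_profile, types)
            vacuous = not (iso_profile.residues(types) | inh_profile.residues(types))
            site_pass = sim >= threshold
            calls.append(
                TargetCall(
                    protein=rec.name,
                    isomer=isomer,
                    energy_pass=energy,
                    site_similarity=sim,
                    site_pass=site_pass,
                    overall_pass=energy and site_pass,
                    site_data_missing=False,
                    vacuous_site=vacuous,
                )
            )
        else:
            calls.append(
                TargetCall(
                    protein=rec.name,
                    isomer=isomer,
                    energy_pass=energy,
                    site_similarity=None,
                    site_pass=None,
                    overall_pass=energy,
                    site_data_missing=True,
                )
            )
    calls.sort(key=lambda c: c.protein)
    return calls
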