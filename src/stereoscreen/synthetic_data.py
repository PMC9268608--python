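"""Synthetic docking tables and toy trajectories with planted structure.

The generators stand in for a docking engine and an MD engine so the whole
prioritization pipeline can be exercised end to end with known ground
truth: score tables carry planted per-group isomer preferences under
Gaussian docking noise, and Cα pseudo-protein trajectories carry planted
per-residue fluctuation amplitudes, planted bound-state radial shifts, and
an optional ligand dissociation drift.  Neither generator attempts physical
realism (no force field, no solvent); they target the statistical structure
the analyses consume.

Reproducibility: one integer seed governs each generator; internally,
independent streams are derived per stage tag so adding a stage never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .score_io import IsomerId, Localization, ProteinGroup, ProteinRecord, ScoreTable
from .trajectory_metrics import ELEMENT_MASSES, Trajectory

__all__ = [
    "ScoreSimConfig",
    "TrajSimConfig",
    "generate_score_table",
    "generate_trajectory_pair",
    "write_trajectory_pdb",
    "default_group_isomer_effects",
]


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent deterministic stream for one generator stage."""
    return np.random.default_rng([seed, zlib.crc32(tag.encode())])


def default_group_isomer_effects() -> dict[tuple[ProteinGroup, IsomerId], float]:
    """Planted effects mirroring the published conclusion: trans-(−) is the
    best binder in three groups, cis-(+) in the metastasis group."""
    effects: dict[tuple[ProteinGroup, IsomerId], float] = {}
    for group in ProteinGroup:
        if group is ProteinGroup.metastasis:
            per_isomer = {
                IsomerId.trans_minus: -0.4,
                IsomerId.trans_plus: 0.0,
                IsomerId.cis_minus: -0.5,
                IsomerId.cis_plus: -1.0,
            }
        else:
            per_isomer = {
                IsomerId.trans_minus: -1.0,
                IsomerId.trans_plus: 0.0,
                IsomerId.cis_minus: -0.5,
                IsomerId.cis_plus: -0.4,
            }
        for iso, eff in per_isomer.items():
            effects[(group, iso)] = eff
    return effects


@dataclass
class ScoreSimConfig:
    """Configuration of the docking-score table generator.

    score(protein, isomer) = base_score_mean + effect(group, isomer)
    + N(0, noise_sd²), rounded to the 0.01 kcal/mol print precision of
    docking output.  The inhibitor score is base_score_mean +
    inhibitor_offset, noiseless.  Defaults approximate the published
    60-protein table: scores near −9 kcal/mol, planted preferences of
    ~0.4–1.0 kcal/mol, docking noise 0.1 kcal/mol, localization mix
    dominated by cytoplasmic proteins.
    """

    proteins_per_group: int = 20
    base_score_mean: float = -9.0
    group_isomer_effects: Mapping[tuple[ProteinGroup, IsomerId], float] = field(
        default_factory=default_group_isomer_effects
    )
    noise_sd: float = 0.1
    inhibitor_offset: float = 0.5
    localization_probabilities: Mapping[Localization, float] = field(
        default_factory=lambda: {
            Localization.membrane: 0.10,
            Localization.cytoplasm: 0.75,
            Localization.nucleus: 0.15,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proteins_per_group < 1:
            raise ValueError("proteins_per_group must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        probs = [float(self.localization_probabilities.get(l, 0.0)) for l in Localization]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("localization_probabilities must be a simplex over "
                             "membrane/cytoplasm/nucleus")


def generate_score_table(config: ScoreSimConfig) -> ScoreTable:
    """Draw a synthetic score table with the configured planted structure."""
    rng_scores = _rng(config.seed, "scores")
    rng_loc = _rng(config.seed, "localization")
    locs = list(Localization)
    probs = [config.localization_probabilities.get(l, 0.0) for l in locs]

    records = []
    counter = 0
    for group in ProteinGroup:
        for k in range(config.proteins_per_group):
            counter += 1
            loc = locs[rng_loc.choice(len(locs), p=probs)]
            scores = {}
            for iso in IsomerId:
                eff = config.group_isomer_effects.get((group, iso), 0.0)
                value = (
                    config.base_score_mean
                    + eff
                    + rng_scores.normal(0.0, config.noise_sd)
                )
                scores[iso] = round(value, 2)
            records.append(
                ProteinRecord(
                    name=f"SYN_{group.value}_{k + 1:03d}",
                    pdb_code=f"{counter % 10}S{counter // 10 % 10}{counter // 100 % 10}",
                    group=group,
                    localization=loc,
                    isomer_scores=scores,
                    inhibitor_name="synthetic_inhibitor",
                    inhibitor_score=round(config.base_score_mean + config.inhibitor_offset, 2),
                )
            )
    return ScoreTable(records, provenance=f"synthetic (seed={config.seed})")


@dataclass
class TrajSimConfig:
    """Configuration of the toy Cα trajectory generator.

    The pseudo-protein is a fixed helix-like scaffold (radius 8 Å, rise
    1.5 Å per residue, 100° twist) so residue-to-COM distances are
    non-degenerate.  The ligand-free state jitters every Cα isotropically
    with per-residue ``fluctuation_sd``; the ligand-bound state additionally
    displaces the ``planted_shift`` residues radially away from the scaffold
    center of mass and adds a single ligand pseudo-atom that drifts away
    from the protein at ``ligand_drift`` Å/ns.
    """

    n_residues: int = 50
    n_frames: int = 300
    time_step: float = 1.0        # ns per frame
    fluctuation_sd: float | np.ndarray = 0.2   # Å, scalar or per-residue
    planted_shift: Mapping[int, float] = field(default_factory=dict)  # 1-based
    ligand_drift: float = 0.0     # Å/ns
    ligand_offset: float = 5.0    # Å initial ligand distance from scaffold COM
    seed: int = 0

    # scaffold constants
    HELIX_RADIUS: float = 8.0
    HELIX_RISE: float = 1.5
    HELIX_TWIST_DEG: float = 100.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        sd = np.broadcast_to(np.asarray(self.fluctuation_sd, float), (self.n_residues,))
        if np.any(sd < 0):
            raise ValueError("fluctuation_sd must be >= 0 elementwise")
        self.fluctuation_sd = sd.copy()
        for res in self.planted_shift:
            if not 1 <= int(res) <= self.n_residues:
                raise ValueError(
                    f"planted_shift residue {res} outside 1..{self.n_residues}"
                )

    def scaffold(self) -> np.ndarray:
        """(n_residues, 3) Cα scaffold coordinates."""
        i = np.arange(self.n_residues)
        theta = np.deg2rad(self.HELIX_TWIST_DEG) * i
        return np.column_stack(
            [
                self.HELIX_RADIUS * np.cos(theta),
                self.HELIX_RADIUS * np.sin(theta),
                self.HELIX_RISE * i,
            ]
        )


def _make_traj(coords: np.ndarray, has_ligand: bool, config: TrajSimConfig) -> Trajectory:
    n_res = config.n_residues
    n_atoms = coords.shape[1]
    resindex = np.arange(1, n_res + 1)
    resnames = np.array(["ALA"] * n_res, dtype=object)
    names = np.array(["CA"] * n_res, dtype=object)
    masses = np.full(n_res, ELEMENT_MASSES["C"])
    is_lig = np.zeros(n_res, bool)
    if has_ligand:
        resindex = np.append(resindex, n_res + 1)
        resnames = np.append(resnames, "LIG")
        names = np.append(names, "C1")
        masses = np.append(masses, ELEMENT_MASSES["C"])
        is_lig = np.append(is_lig, True)
    assert len(resindex) == n_atoms
    return Trajectory(
        coords=coords,
        resindex=resindex,
        resnames=resnames,
        atom_names=names,
        masses=masses,
        is_ligand=is_lig,
        time_step=config.time_step,
    )


def generate_trajectory_pair(config: TrajSimConfig) -> tuple[Trajectory, Trajectory]:
    """Matched (ligand-bound, ligand-free) toy trajectories."""
    scaffold = config.scaffold()
    com = scaffold.mean(axis=0)  # equal-mass Cα scaffold
    sd = np.asarray(config.fluctuation_sd)

    # bound-state mean structure: planted residues pushed radially outward
    bound_mean = scaffold.copy()
    for res, shift in config.planted_shift.items():
        idx = int(res) - 1
        radial = scaffold[idx] - com
        norm = np.linalg.norm(radial)
        if norm == 0:
            raise ValueError(f"residue {res} sits at the scaffold COM; no radial direction")
        bound_mean[idx] = scaffold[idx] + shift * radial / norm

    n_f, n_r = config.n_frames, config.n_residues
    noise_free = _rng(config.seed, "free-noise").normal(0.0, 1.0, (n_f, n_r, 3))
    noise_bound = _rng(config.seed, "bound-noise").normal(0.0, 1.0, (n_f, n_r, 3))
    free_coords = scaffold[None] + noise_free * sd[None, :, None]
    bound_prot = bound_mean[None] + noise_bound * sd[None, :, None]

    # ligand: starts ligand_offset Å from the COM along +x, drifts outward
    t = np.arange(n_f) * config.time_step
    lig_noise = _rng(config.seed, "ligand-noise").normal(0.0, 0.05, (n_f, 3))
    lig = np.tile(com + np.array([config.ligand_offset, 0.0, 0.0]), (n_f, 1))
    lig[:, 0] += config.ligand_drift * t
    lig += lig_noise
    bound_coords = np.concatenate([bound_prot, lig[:, None, :]], axis=1)

    bound = _make_traj(bound_coords, has_ligand=True, config=config)
    free = _make_traj(free_coords, has_ligand=False, config=config)
    return bound, free


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"MODEL     {t + 1:4d}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[t, a]
                record = "HETATM" if traj.is_ligand[a] else "ATOM  "
                name = str(traj.atom_names[a])[:4]
                elem = "C" if name.upper().startswith("C") else name[:1].upper()
                fh.write(
                    f"{record}{(a + 1) % 100000:5d} {name:<4s}"
                    f"{str(traj.resnames[a])[:3]:>4s} A"
                    f"{int(traj.resindex[a]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {elem:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
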