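"""Conformational statistics over MD trajectories.

Implements the four post-simulation analyses used to compare ligand-bound
and ligand-free receptor conformations:

* RMSD of each frame to a reference frame (conformational stability),
* per-residue Cα RMSF about the mean structure (flexibility),
* ligand-to-protein center-of-mass distance over time (dissociation),
* the per-residue Δd profile: Δd(n) = d(n, bound) − d(n, free), where
  d(n, state) is the time-averaged distance from residue n's α-carbon to
  the protein center of mass.  |Δd| > 2 Å is considered a significant
  conformational shift; Δd > 0 means the residue moved away from the
  protein center in the ligand-bound state, Δd < 0 that it moved closer.

Trajectories are held as plain coordinate arrays (Å) with per-atom
metadata; multi-model PDB and XYZ files are read through MDAnalysis.
Rigid-body superposition uses the least-squares (Kabsch) solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "RmsdSeries",
    "RmsfProfile",
    "DistanceSeries",
    "ResidueDistanceProfile",
    "DeltaDProfile",
    "TrajectoryFormatError",
    "read_trajectory",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "com_distance_series",
    "residue_distance_profile",
    "delta_d_profile",
    "DELTA_D_THRESHOLD",
]

DELTA_D_THRESHOLD = 2.0

# masses (Da) for elements commonly seen in protein/ligand coordinates
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "SE": 78.971,
}
FALLBACK_MASS = 12.011


class TrajectoryFormatError(ValueError):
    """Trajectory file violates the expected multi-frame layout."""


@dataclass
class Trajectory:
    """Coordinate frames (Å) plus per-atom metadata.

    ``resindex`` is 1-based and shared by all atoms of a residue; the ligand
    is marked by ``is_ligand`` and excluded from all protein statistics.
    """

    coords: np.ndarray            # (n_frames, n_atoms, 3)
    resindex: np.ndarray          # (n_atoms,) int, 1-based
    resnames: np.ndarray          # (n_atoms,) str
    atom_names: np.ndarray        # (n_atoms,) str
    masses: np.ndarray            # (n_atoms,) Da
    is_ligand: np.ndarray         # (n_atoms,) bool
    time_step: float = 1.0        # ns per frame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise TrajectoryFormatError("trajectory has zero frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        n_atoms = self.coords.shape[1]
        for name in ("resindex", "resnames", "atom_names", "masses", "is_ligand"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n_atoms:
                raise ValueError(f"{name} length {arr.shape[0]} != n_atoms {n_atoms}")
            setattr(self, name, arr)
        self.resindex = self.resindex.astype(int)
        self.masses = self.masses.astype(float)
        self.is_ligand = self.is_ligand.astype(bool)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.is_ligand

    @property
    def ca_mask(self) -> np.ndarray:
        """Protein α-carbons (atom name CA)."""
        names = np.char.upper(self.atom_names.astype(str))
        return (names == "CA") & self.protein_mask

    def ca_residue_ids(self) -> np.ndarray:
        """Residue indices that own exactly one Cα, in ascending order.

        Protein residues lacking a Cα are excluded with a warning.
        """
        ca = self.ca_mask
        have = np.unique(self.resindex[ca])
        all_res = np.unique(self.resindex[self.protein_mask])
        missing = np.setdiff1d(all_res, have)
        if missing.size:
            warnings.warn(
                f"residue(s) {missing.tolist()} lack a CA atom and are excluded",
                stacklevel=3,
            )
        return have

    def times(self) -> np.ndarray:
        """Frame times in ns (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.time_step


@dataclass
class RmsdSeries:
    rmsd: np.ndarray              # (n_frames,) Å
    reference: int
    superposed: bool
    time_step: float = 1.0

    def times(self) -> np.ndarray:
        return np.arange(len(self.rmsd)) * self.time_step


@dataclass
class RmsfProfile:
    residue_ids: np.ndarray       # (n_residues,)
    rmsf: np.ndarray              # (n_residues,) Å


@dataclass
class DistanceSeries:
    """Ligand-COM to protein-COM distance per frame, with a drift estimate."""

    distances: np.ndarray         # (n_frames,) Å
    time_step: float = 1.0        # ns
    slope: float = field(init=False)          # Å/ns, least-squares drift
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.mean = float(self.distances.mean())
        if len(self.distances) >= 2:
            t = np.arange(len(self.distances)) * self.time_step
            self.slope = float(np.polyfit(t, self.distances, 1)[0])
        else:
            self.slope = 0.0

    def times(self) -> np.ndarray:
        return np.arange(len(self.distances)) * self.time_step

    def window_mean(self, start: int, stop: int | None = None) -> float:
        return float(self.distances[start:stop].mean())


@dataclass
class ResidueDistanceProfile:
    """Time-averaged Cα-to-protein-COM distance per residue for one state."""

    residue_ids: np.ndarray
    d: np.ndarray                 # (n_residues,) Å
    state: str                    # "ligand-bound" or "ligand-free"


@dataclass
class DeltaDProfile:
    """Per-residue bound-minus-free distance shift with 2 Å classification."""

    residue_ids: np.ndarray
    delta_d: np.ndarray
    classes: np.ndarray           # "closer" | "further" | "unchanged"
    threshold: float = DELTA_D_THRESHOLD

    def residues_classified(self, cls: str) -> list[int]:
        return [int(r) for r in self.residue_ids[self.classes == cls]]


# ---------------------------------------------------------------------------
# reading

def _element_of(atom_name: str, element: str | None) -> str:
    if element:
        return element.strip().upper()
    # strip leading digits, take leading alphabetic run; protein atom names
    # start with the element symbol's first letter (CA is a carbon, not Ca)
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def _masses_for(atom_names: Sequence[str], elements: Sequence[str] | None) -> np.ndarray:
    masses = np.empty(len(atom_names))
    unknown = []
    for i, name in enumerate(atom_names):
        elem = _element_of(name, elements[i] if elements is not None else None)
        if elem in ELEMENT_MASSES:
            masses[i] = ELEMENT_MASSES[elem]
        else:
            masses[i] = FALLBACK_MASS
            unknown.append(name)
    if unknown:
        warnings.warn(
            f"unknown element for atom(s) {sorted(set(unknown))}; "
            f"using fallback mass {FALLBACK_MASS} Da",
            stacklevel=3,
        )
    return masses


def _validate_pdb_models(path: Path) -> None:
    """Check MODEL blocks for consistent atom counts; report the bad frame."""
    counts = []
    current = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0  # single unnumbered model
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None:
        counts.append(current)
    if not counts or sum(counts) == 0:
        raise TrajectoryFormatError(f"{path}: no frames found")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"{path}: inconsistent atom count in frame {bad + 1} "
            f"({counts[bad]} atoms, expected {counts[0]})"
        )


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    ligand_selector: str = "LIG",
    time_step: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a :class:`Trajectory`.

    ``ligand_selector`` is matched against residue names (PDB) or atom
    names (XYZ, which carries no residue metadata; there every atom becomes
    its own residue).  Masses come from a standard element table with a
    12.011 Da fallback and warning for unrecognized atoms.
    """
    import MDAnalysis as mda

    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "pdb"
    format = format.lower()
    if format not in ("pdb", "xyz"):
        raise ValueError(f"unsupported trajectory format {format!r}")

    if format == "pdb":
        _validate_pdb_models(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guessing chatter
        u = mda.Universe(str(path), format=format)
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)

    n_atoms = u.atoms.n_atoms
    atom_names = np.array([a.name for a in u.atoms], dtype=object)

    if format == "pdb":
        resnames = np.array([a.resname for a in u.atoms], dtype=object)
        resids = np.array([a.resid for a in u.atoms], dtype=int)
        try:
            elements = [a.element for a in u.atoms]
        except Exception:
            elements = None
        is_ligand = np.array(
            [rn.strip().upper() == ligand_selector.upper() for rn in resnames]
        )
    else:
        resnames = atom_names.copy()
        resids = np.arange(1, n_atoms + 1)
        elements = [str(n) for n in atom_names]
        is_ligand = np.array(
            [str(n).upper() == ligand_selector.upper() for n in atom_names]
        )

    masses = _masses_for([str(n) for n in atom_names], elements)
    return Trajectory(
        coords=coords,
        resindex=resids,
        resnames=resnames,
        atom_names=atom_names,
        masses=masses,
        is_ligand=is_ligand,
        time_step=time_step,
    )


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Optimal least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    Returns the transformed mobile coordinates.  Standard Kabsch algorithm:
    center both point sets, rotate by the SVD-derived proper rotation.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    h = (w[:, None] * m0).T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return m0 @ rot.T + rc


def _selection_mask(traj: Trajectory, selection: str) -> np.ndarray:
    if selection in ("ca", "protein-ca", "protein_ca"):
        mask = traj.ca_mask
    elif selection == "all":
        mask = np.ones(traj.n_atoms, bool)
    elif selection == "protein":
        mask = traj.protein_mask
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    return mask


# ---------------------------------------------------------------------------
# metrics

def rmsd_series(
    traj: Trajectory,
    reference: int = 0,
    selection: str = "ca",
    superpose: bool = True,
) -> RmsdSeries:
    """RMSD of every frame to the reference frame over the atom selection."""
    if not -traj.n_frames <= reference < traj.n_frames:
        raise IndexError(f"reference frame {reference} out of range")
    mask = _selection_mask(traj, selection)
    ref = traj.coords[reference][mask]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        x = traj.coords[t][mask]
        if superpose:
            x = kabsch_superpose(x, ref)
        out[t] = math.sqrt(float(((x - ref) ** 2).sum(axis=1).mean()))
    return RmsdSeries(
        rmsd=out, reference=reference, superposed=superpose, time_step=traj.time_step
    )


def _resolve_window(window, n_frames: int) -> slice:
    if window is None:
        return slice(0, n_frames)
    if window == "last-third":
        return slice(n_frames - max(1, n_frames // 3), n_frames)
    if isinstance(window, slice):
        return window
    start, stop = window
    return slice(start, stop)


def rmsf_profile(traj: Trajectory, window=None) -> RmsfProfile:
    """Per-residue Cα RMSF about the window-mean structure.

    Every frame in the window is superposed onto the mean structure (two
    alignment passes: first onto the initial window frame to build a mean,
    then onto that mean) before fluctuations are measured.
    """
    win = _resolve_window(window, traj.n_frames)
    res_ids = traj.ca_residue_ids()
    ca = traj.ca_mask
    frames = traj.coords[win][:, ca, :]
    if frames.shape[0] == 0:
        raise ValueError("window selects no frames")

    aligned = np.array([kabsch_superpose(f, frames[0]) for f in frames])
    mean = aligned.mean(axis=0)
    aligned = np.array([kabsch_superpose(f, mean) for f in aligned])
    mean = aligned.mean(axis=0)

    # order Cα rows by residue id
    ca_res = traj.resindex[ca]
    order = np.argsort(ca_res)
    fluct = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # per Cα atom
    rmsf = np.sqrt(fluct[order])
    return RmsfProfile(residue_ids=ca_res[order], rmsf=rmsf)


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = masses / masses.sum()
    return (w[:, None] * coords).sum(axis=0)


def com_distance_series(traj: Trajectory) -> DistanceSeries:
    """Per-frame distance between ligand and protein mass-weighted centers."""
    lig = traj.is_ligand
    prot = traj.protein_mask
    if not lig.any():
        raise ValueError("trajectory contains no ligand atoms")
    if not prot.any():
        raise ValueError("trajectory contains no protein atoms")
    d = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        com_l = _com(traj.coords[t][lig], traj.masses[lig])
        com_p = _com(traj.coords[t][prot], traj.masses[prot])
        d[t] = float(np.linalg.norm(com_l - com_p))
    return DistanceSeries(distances=d, time_step=traj.time_step)


def residue_distance_profile(
    traj: Trajectory, window="last-third", state: str = "ligand-bound"
) -> ResidueDistanceProfile:
    """Time-mean distance of each residue's Cα to the protein center of mass.

    The protein COM is mass-weighted over protein atoms only (ligand
    excluded) and recomputed per frame.  The default analysis window is the
    final third of the trajectory, the equilibrated tail.
    """
    win = _resolve_window(window, traj.n_frames)
    res_ids = traj.ca_residue_ids()
    ca = traj.ca_mask
    prot = traj.protein_mask
    frames = traj.coords[win]
    if frames.shape[0] == 0:
        raise ValueError("window selects no frames")
    ca_res = traj.resindex[ca]
    order = np.argsort(ca_res)
    acc = np.zeros(ca.sum())
    for frame in frames:
        com_p = _com(frame[prot], traj.masses[prot])
        acc += np.linalg.norm(frame[ca] - com_p, axis=1)
    d = (acc / frames.shape[0])[order]
    return ResidueDistanceProfile(residue_ids=ca_res[order], d=d, state=state)


def delta_d_profile(
    bound: ResidueDistanceProfile,
    free: ResidueDistanceProfile,
    threshold: float = DELTA_D_THRESHOLD,
) -> DeltaDProfile:
    """Δd(n) = d(n, bound) − d(n, free) with strict ±threshold classification."""
    if not np.array_equal(bound.residue_ids, free.residue_ids):
        only_b = np.setdiff1d(bound.residue_ids, free.residue_ids).tolist()
        only_f = np.setdiff1d(free.residue_ids, bound.residue_ids).tolist()
        raise ValueError(
            f"residue sets differ: only in bound {only_b}, only in free {only_f}"
        )
    dd = bound.d - free.d
    classes = np.where(
        dd > threshold, "further", np.where(dd < -threshold, "closer", "unchanged")
    )
    return DeltaDProfile(
        residue_ids=bound.residue_ids.copy(),
        delta_d=dd,
        classes=classes,
        threshold=threshold,
    )
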