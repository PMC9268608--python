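"""Data model and I/O for docking-score and interaction-residue tables.

The central objects are :class:`ScoreTable` — one row per candidate protein
holding the docking scores (kcal/mol, more negative = stronger predicted
binding) of the four kusunokinin stereoisomers plus a known inhibitor — and
:class:`InteractionProfile` — the residues a docked ligand contacts, split by
interaction type.  Two fixtures transcribed from the published screen ship
with the package: the 60-protein score table and the CSF1R/EGFR interaction
table.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "IsomerId",
    "ProteinGroup",
    "Localization",
    "ProteinRecord",
    "ScoreTable",
    "ResidueLabel",
    "InteractionProfile",
    "SchemaError",
    "TableParseError",
    "load_score_table",
    "write_score_table",
    "load_interaction_table",
    "write_results",
    "packaged_score_table",
    "packaged_interaction_table",
    "fixture_path",
]


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


class TableParseError(ValueError):
    """A cell of an input table could not be parsed."""


class IsomerId(enum.Enum):
    """The four kusunokinin stereoisomers, in fixed column order."""

    trans_minus = "trans_minus"
    trans_plus = "trans_plus"
    cis_minus = "cis_minus"
    cis_plus = "cis_plus"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ProteinGroup(enum.Enum):
    """Functional grouping of the candidate proteins by cancer-progression role."""

    anti_apoptosis_survival = "anti_apoptosis_survival"
    cell_growth_proliferation = "cell_growth_proliferation"
    metastasis = "metastasis"
    signaling = "signaling"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Localization(enum.Enum):
    """Subcellular localization, carrying the drug-accessibility weight.

    Membrane-bound targets are the most exposed to an extracellular drug
    (weight 3), cytoplasmic targets intermediate (2), nuclear targets the
    least accessible (1).
    """

    membrane = "membrane"
    cytoplasm = "cytoplasm"
    nucleus = "nucleus"

    @property
    def weight(self) -> int:
        return _LOC_WEIGHTS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_LOC_WEIGHTS = {
    Localization.membrane: 3,
    Localization.cytoplasm: 2,
    Localization.nucleus: 1,
}

_PDB_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate protein with its isomer and inhibitor docking scores."""

    name: str
    pdb_code: str
    group: ProteinGroup
    localization: Localization
    isomer_scores: Mapping[IsomerId, float]
    inhibitor_name: str
    inhibitor_score: float

    def __post_init__(self) -> None:
        if not _PDB_RE.match(self.pdb_code):
            raise ValueError(
                f"{self.name}: invalid PDB code {self.pdb_code!r} "
                "(expected digit followed by 3 alphanumerics)"
            )
        missing = [i for i in IsomerId if i not in self.isomer_scores]
        if missing:
            raise ValueError(f"{self.name}: missing isomer scores {missing}")
        for iso in IsomerId:
            if not math.isfinite(self.isomer_scores[iso]):
                raise ValueError(f"{self.name}: non-finite score for {iso}")
        if not math.isfinite(self.inhibitor_score):
            raise ValueError(f"{self.name}: non-finite inhibitor score")
        # freeze the mapping so records are safely hashable by field identity
        object.__setattr__(
            self,
            "isomer_scores",
            dict((i, float(self.isomer_scores[i])) for i in IsomerId),
        )

    def score(self, isomer: IsomerId) -> float:
        return self.isomer_scores[isomer]


@dataclass
class ScoreTable:
    """Ordered collection of :class:`ProteinRecord` with unique names."""

    records: list[ProteinRecord]
    provenance: str = ""
    _index: dict[str, ProteinRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for rec in self.records:
            if rec.name in self._index:
                raise ValueError(f"duplicate protein name {rec.name!r}")
            self._index[rec.name] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> ProteinRecord:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return self.records == other.records

    def group_records(self, group: ProteinGroup) -> list[ProteinRecord]:
        return [r for r in self.records if r.group is group]

    def groups_present(self) -> list[ProteinGroup]:
        seen = {r.group for r in self.records}
        return [g for g in ProteinGroup if g in seen]

    def restrict(self, names: Iterable[str]) -> "ScoreTable":
        """Sub-table containing only the named proteins, in table order."""
        wanted = set(names)
        unknown = wanted - set(self._index)
        if unknown:
            raise KeyError(f"unknown protein name(s): {sorted(unknown)}")
        return ScoreTable(
            [r for r in self.records if r.name in wanted],
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame view (one row per protein, fixture column order)."""
        rows = []
        for r in self.records:
            row = {
                "protein": r.name,
                "pdb": r.pdb_code,
                "group": r.group.value,
                "localization": r.localization.value,
            }
            for iso in IsomerId:
                row[iso.value] = r.isomer_scores[iso]
            row["inhibitor"] = r.inhibitor_name
            row["inhibitor_score"] = r.inhibitor_score
            rows.append(row)
        return pd.DataFrame(rows)


_AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}

_RESIDUE_RE = re.compile(r"^([A-Za-z]{3})(\d+)$")


class ResidueLabel(tuple):
    """A residue as (three-letter code, sequence number), e.g. Trp550.

    The code is stored in canonical title case so comparison is effectively
    case-insensitive on the code part.
    """

    __slots__ = ()

    def __new__(cls, code: str, number: int) -> "ResidueLabel":
        code = code.capitalize()
        if code not in _AA3:
            raise TableParseError(f"unknown amino-acid code in residue label {code}{number}")
        return super().__new__(cls, (code, int(number)))

    @property
    def code(self) -> str:
        return self[0]

    @property
    def number(self) -> int:
        return self[1]

    @classmethod
    def parse(cls, token: str) -> "ResidueLabel":
        m = _RESIDUE_RE.match(token.strip())
        if not m:
            raise TableParseError(f"unparseable residue label {token!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.code}{self.number}"

    def __repr__(self) -> str:
        return f"ResidueLabel({self.code}{self.number})"


INTERACTION_TYPES = ("pi_pi", "hydrogen_bond", "pi_sulfur", "hydrophobic")


@dataclass
class InteractionProfile:
    """Residue contacts of one ligand docked into one protein, by interaction type."""

    protein: str
    ligand: str
    interactions: dict[str, frozenset[ResidueLabel]]

    def __post_init__(self) -> None:
        for itype in self.interactions:
            if itype not in INTERACTION_TYPES:
                raise SchemaError(f"unknown interaction_type {itype!r}")
        self.interactions = {
            t: frozenset(self.interactions.get(t, frozenset())) for t in INTERACTION_TYPES
        }

    def residues(self, types: Iterable[str] | str = "all") -> frozenset[ResidueLabel]:
        """Union of residues over the selected interaction types."""
        if types == "all":
            selected: Iterable[str] = INTERACTION_TYPES
        else:
            selected = list(types)
            for t in selected:
                if t not in INTERACTION_TYPES:
                    raise SchemaError(f"unknown interaction_type {t!r}")
        out: frozenset[ResidueLabel] = frozenset()
        for t in selected:
            out |= self.interactions[t]
        return out


_SCORE_COLUMNS = [
    "protein", "pdb", "group", "localization",
    "trans_minus", "trans_plus", "cis_minus", "cis_plus",
    "inhibitor", "inhibitor_score",
]


def load_score_table(path: str | Path, format: str | None = None) -> ScoreTable:
    """Read a docking-score table from TSV or CSV.

    The header must name the columns ``protein, pdb, group, localization,
    trans_minus, trans_plus, cis_minus, cis_plus, inhibitor,
    inhibitor_score``.  Row order is preserved.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    records = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, after header
        try:
            group = ProteinGroup(row["group"])
        except ValueError:
            raise TableParseError(f"{path}:{rowno}: unknown group {row['group']!r}") from None
        try:
            loc = Localization(row["localization"])
        except ValueError:
            raise TableParseError(
                f"{path}:{rowno}: unknown localization {row['localization']!r}"
            ) from None
        scores = {}
        for iso in IsomerId:
            try:
                scores[iso] = float(row[iso.value])
            except ValueError:
                raise TableParseError(
                    f"{path}:{rowno}: non-numeric score {row[iso.value]!r} "
                    f"in column {iso.value}"
                ) from None
        try:
            inh_score = float(row["inhibitor_score"])
        except ValueError:
            raise TableParseError(
                f"{path}:{rowno}: non-numeric inhibitor_score {row['inhibitor_score']!r}"
            ) from None
        records.append(
            ProteinRecord(
                name=row["protein"],
                pdb_code=row["pdb"],
                group=group,
                localization=loc,
                isomer_scores=scores,
                inhibitor_name=row["inhibitor"],
                inhibitor_score=inh_score,
            )
        )
    names = [r.name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise SchemaError(f"{path}: duplicate protein name(s) {sorted(dupes)}")
    return ScoreTable(records, provenance=str(path))


def write_score_table(table: ScoreTable, path: str | Path, format: str | None = None) -> None:
    """Write a score table as TSV/CSV; inverse of :func:`load_score_table`.

    Scores are printed with two decimals, exactly as stored.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if format == "tsv" else ","
    df = table.to_frame()
    for col in [i.value for i in IsomerId] + ["inhibitor_score"]:
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep=sep, index=False)


def load_interaction_table(path: str | Path) -> list[InteractionProfile]:
    """Read an interaction-residue table (one row per protein/ligand/type).

    Residues are ``;``-separated labels like ``Trp550`` and are aggregated
    across rows into one :class:`InteractionProfile` per (protein, ligand).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["protein", "ligand", "interaction_type", "residues"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    acc: dict[tuple[str, str], dict[str, set[ResidueLabel]]] = {}
    order: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        itype = row["interaction_type"]
        if itype not in INTERACTION_TYPES:
            raise SchemaError(
                f"{path}:{int(idx) + 2}: unknown interaction_type {itype!r}"
            )
        labels = set()
        for token in row["residues"].split(";"):
            token = token.strip()
            if token:
                labels.add(ResidueLabel.parse(token))
        key = (row["protein"], row["ligand"])
        if key not in acc:
            acc[key] = {t: set() for t in INTERACTION_TYPES}
            order.append(key)
        acc[key][itype] |= labels
    return [
        InteractionProfile(
            protein=p,
            ligand=l,
            interactions={t: frozenset(s) for t, s in acc[(p, l)].items()},
        )
        for p, l in order
    ]


def _jsonable(obj):
    """Recursively convert pipeline objects to plain JSON-compatible data."""
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, ResidueLabel):
        return str(obj)
    if isinstance(obj, Mapping):
        return {str(_jsonable(k)): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(str(_jsonable(v)) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {
            f: _jsonable(getattr(obj, f))
            for f in obj.__dataclass_fields__
            if not f.startswith("_")
        }
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_results(results, path: str | Path, format: str = "json") -> None:
    """Serialize pipeline output to JSON (sorted keys, stable) or CSV."""
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        data = _jsonable(results)
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (``table1_scores.tsv`` etc.)."""
    return Path(resources.files("stereoscreen") / "data" / name)


def packaged_score_table() -> ScoreTable:
    """The published 60-protein docking-score table."""
    table = load_score_table(fixture_path("table1_scores.tsv"), format="tsv")
    table.provenance = "packaged 60-protein docking-score fixture"
    return table


def packaged_interaction_table() -> list[InteractionProfile]:
    """The published CSF1R/EGFR interaction-residue table."""
    return load_interaction_table(fixture_path("table3_interactions.tsv"))
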