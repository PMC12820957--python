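"""Domain types and file I/O for docking-score tables, scoring-function
metadata, ligand annotations, PLIP interaction reports and activity tables.

Score tables are plain CSV (``ligand_id`` column followed by one column per
scoring function); empty cells and the token ``NA`` both encode a missing
score, which is how a whole-protocol docking failure for a ligand surfaces
in the table.  Interaction records come either from a PLIP XML report or
from an equivalent flat CSV; both readers yield identical record lists for
equivalent content.
"""

from __future__ import annotations

import csv
import enum
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Direction",
    "MechClass",
    "InteractionType",
    "ScoringFunctionSpec",
    "ScoreTable",
    "LigandAnnotation",
    "InteractionRecord",
    "ActivityTable",
    "read_score_table",
    "write_score_table",
    "read_function_specs",
    "write_function_specs",
    "read_annotations",
    "write_annotations",
    "read_plip_records",
    "write_interaction_csv",
    "read_activity_table",
    "write_activity_table",
]

MISSING_TOKENS = ("", "NA")


class Direction(str, enum.Enum):
    """Ranking direction of a scoring function."""

    lower_is_better = "lower_is_better"
    higher_is_better = "higher_is_better"


class MechClass(str, enum.Enum):
    """Mechanistic ligand class: complex I inhibitor, complex III inhibitor
    or protonophoric uncoupler (the nonbinder class)."""

    CI_inhibitor = "CI_inhibitor"
    CIII_inhibitor = "CIII_inhibitor"
    uncoupler = "uncoupler"


class InteractionType(str, enum.Enum):
    hydrophobic_interaction = "hydrophobic_interaction"
    hydrogen_bond = "hydrogen_bond"
    pi_stack = "pi_stack"
    pi_cation = "pi_cation"
    salt_bridge = "salt_bridge"
    water_bridge = "water_bridge"
    halogen_bond = "halogen_bond"
    metal_complex = "metal_complex"


@dataclass(frozen=True)
class ScoringFunctionSpec:
    """Identity, program of origin and ranking direction of one scoring
    function.

    ``direction`` must always be given explicitly: docking programs mix
    energy-like scores (lower is better) with fitness scores (higher is
    better) and a silent default would corrupt every downstream rank.
    """

    name: str
    program: str
    direction: Direction

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("scoring function name must be nonempty")
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))


def _check_unique_specs(specs: Sequence[ScoringFunctionSpec]) -> None:
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate scoring function names: {sorted(dupes)}")


@dataclass
class ScoreTable:
    """Ligand x scoring-function score matrix for one protein target.

    ``scores`` is a float DataFrame indexed by ligand_id with one column per
    scoring function; NaN marks a missing score.  A ligand may be all-NaN
    (its docking run failed for every protocol).
    """

    target_id: str
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            dup = self.scores.index[self.scores.index.duplicated()].tolist()
            raise ValueError(f"duplicate ligand ids: {dup}")
        self.scores = self.scores.astype(float)

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def function_names(self) -> list[str]:
        return list(self.scores.columns)

    def n_missing(self) -> int:
        return int(self.scores.isna().sum().sum())


@dataclass(frozen=True)
class LigandAnnotation:
    ligand_id: str
    mech_class: MechClass

    def __post_init__(self) -> None:
        if not isinstance(self.mech_class, MechClass):
            object.__setattr__(self, "mech_class", MechClass(self.mech_class))


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One typed residue contact reported for a (ligand, program) pose."""

    interaction_type: InteractionType
    residue_number: int
    residue_type: str
    chain: str
    ligand_id: str
    program: str

    def __post_init__(self) -> None:
        if not isinstance(self.interaction_type, InteractionType):
            object.__setattr__(
                self, "interaction_type", InteractionType(self.interaction_type)
            )
        if self.residue_number < 1:
            raise ValueError(f"residue_number must be >= 1, got {self.residue_number}")
        rt = self.residue_type.upper()
        if len(rt) != 3:
            raise ValueError(f"residue_type must be a 3-letter code, got {rt!r}")
        object.__setattr__(self, "residue_type", rt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """The merge key: (interaction_type, residue_number, residue_type,
        chain) — the level at which poses from two programs are compared."""
        return (
            self.interaction_type.value,
            self.residue_number,
            self.residue_type,
            self.chain,
        )


@dataclass
class ActivityTable:
    """Experimental potencies: ligand_id -> pIC50 (-log10 molar), with an
    optional standard deviation per ligand."""

    pic50: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lig, v in self.pic50.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite pIC50 for {lig!r}")
        for lig, s in self.sd.items():
            if s < 0:
                raise ValueError(f"negative sd for {lig!r}")

    def __len__(self) -> int:
        return len(self.pic50)


# ---------------------------------------------------------------------------
# score tables


def read_score_table(
    path: str | Path,
    specs: Sequence[ScoringFunctionSpec],
    target_id: str = "",
) -> ScoreTable:
    """Read a score-table CSV and validate it against the function specs.

    The header must be ``ligand_id`` followed by function names; every
    column must have a spec.  Empty cells and ``NA`` are missing scores.
    """
    _check_unique_specs(specs)
    known = {s.name for s in specs}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.columns[0] != "ligand_id":
        raise ValueError(
            f"first column must be 'ligand_id', got {raw.columns[0]!r}"
        )
    unknown = [c for c in raw.columns[1:] if c not in known]
    if unknown:
        raise ValueError(f"unknown scoring function column(s): {unknown}")
    ligands = raw["ligand_id"].tolist()
    dupes = {l for l in ligands if ligands.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate ligand_id: {sorted(dupes)}")

    data: dict[str, list[float]] = {}
    for col in raw.columns[1:]:
        vals = []
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                vals.append(float("nan"))
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"non-numeric score {cell!r} at row {i + 2}, column {col!r}"
                ) from None
        data[col] = vals
    df = pd.DataFrame(data, index=pd.Index(ligands, name="ligand_id"))
    return ScoreTable(target_id=target_id, scores=df)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as CSV; NaN becomes an empty cell.  Values are
    written with shortest round-tripping decimal representation."""
    df = table.scores
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ligand_id", *df.columns])
        for lig, row in df.iterrows():
            w.writerow(
                [lig]
                + ["" if pd.isna(v) else repr(float(v)) for v in row.tolist()]
            )


# ---------------------------------------------------------------------------
# scoring-function specs


def read_function_specs(path: str | Path) -> list[ScoringFunctionSpec]:
    """Read scoring-function metadata from CSV (name,program,direction) or
    YAML (list of mappings with those fields)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            entries = yaml.safe_load(fh)
        if not isinstance(entries, list):
            raise ValueError("YAML spec file must contain a list of mappings")
    else:
        with open(path, newline="") as fh:
            entries = list(csv.DictReader(fh))
    specs = [
        ScoringFunctionSpec(
            name=e["name"], program=e["program"], direction=Direction(e["direction"])
        )
        for e in entries
    ]
    _check_unique_specs(specs)
    return specs


def write_function_specs(
    specs: Sequence[ScoringFunctionSpec], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "program", "direction"])
        for s in specs:
            w.writerow([s.name, s.program, s.direction.value])


# ---------------------------------------------------------------------------
# ligand annotations


def read_annotations(path: str | Path) -> list[LigandAnnotation]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    seen: set[str] = set()
    out = []
    for r in rows:
        lig = r["ligand_id"]
        if lig in seen:
            raise ValueError(f"duplicate ligand_id in annotations: {lig!r}")
        seen.add(lig)
        out.append(LigandAnnotation(ligand_id=lig, mech_class=MechClass(r["mech_class"])))
    return out


def write_annotations(anns: Sequence[LigandAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ligand_id", "mech_class"])
        for a in anns:
            w.writerow([a.ligand_id, a.mech_class.value])


# ---------------------------------------------------------------------------
# PLIP interaction reports

# PLIP groups contacts under plural container elements; map the singular
# child element names onto the interaction-type enum.
_PLIP_ELEMENT_MAP = {
    "hydrophobic_interaction": InteractionType.hydrophobic_interaction,
    "hydrogen_bond": InteractionType.hydrogen_bond,
    "pi_stack": InteractionType.pi_stack,
    "pi_cation_interaction": InteractionType.pi_cation,
    "pi_cation": InteractionType.pi_cation,
    "salt_bridge": InteractionType.salt_bridge,
    "water_bridge": InteractionType.water_bridge,
    "halogen_bond": InteractionType.halogen_bond,
    "metal_complex": InteractionType.metal_complex,
}


def _parse_plip_xml(path: Path, ligand_id: str, program: str) -> list[InteractionRecord]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"unparseable PLIP XML {path}: {exc}") from exc
    root = tree.getroot()
    containers = root.findall(".//interactions")
    if root.tag == "interactions":
        containers = [root]
    if not containers:
        raise ValueError(f"no <interactions> element found in {path}")
    records: list[InteractionRecord] = []
    for cont in containers:
        for group in cont:
            for elem in group:
                itype = _PLIP_ELEMENT_MAP.get(elem.tag)
                if itype is None:
                    raise ValueError(
                        f"unknown interaction element <{elem.tag}> in {path}"
                    )
                resnr = elem.findtext("resnr")
                restype = elem.findtext("restype")
                chain = elem.findtext("reschain")
                if resnr is None or restype is None or chain is None:
                    raise ValueError(
                        f"<{elem.tag}> missing resnr/restype/reschain in {path}"
                    )
                records.append(
                    InteractionRecord(
                        interaction_type=itype,
                        residue_number=int(resnr),
                        residue_type=restype.upper(),
                        chain=chain,
                        ligand_id=ligand_id,
                        program=program,
                    )
                )
    return records


def _parse_interaction_csv(
    path: Path, ligand_id: str, program: str
) -> list[InteractionRecord]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    records = []
    for r in rows:
        records.append(
            InteractionRecord(
                interaction_type=InteractionType(r["interaction_type"]),
                residue_number=int(r["residue_number"]),
                residue_type=r["residue_type"].upper(),
                chain=r["chain"],
                ligand_id=r.get("ligand_id", ligand_id) or ligand_id,
                program=r.get("program", program) or program,
            )
        )
    return records


def read_plip_records(
    path: str | Path, ligand_id: str = "", program: str = ""
) -> list[InteractionRecord]:
    """Read typed residue contacts from a PLIP XML report or a flat CSV.

    The XML and CSV paths produce identical record lists for equivalent
    content; unknown XML attributes are tolerated, unknown interaction
    element names are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return _parse_plip_xml(path, ligand_id, program)
    return _parse_interaction_csv(path, ligand_id, program)


def write_interaction_csv(
    records: Iterable[InteractionRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["interaction_type", "residue_number", "residue_type", "chain",
             "ligand_id", "program"]
        )
        for r in records:
            w.writerow(
                [r.interaction_type.value, r.residue_number, r.residue_type,
                 r.chain, r.ligand_id, r.program]
            )


# ---------------------------------------------------------------------------
# activity tables


def read_activity_table(path: str | Path) -> ActivityTable:
    """Read a CSV with columns ``ligand_id,pIC50[,sd]``."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    pic50: dict[str, float] = {}
    sd: dict[str, float] = {}
    for i, r in enumerate(rows):
        lig = r["ligand_id"]
        if lig in pic50:
            raise ValueError(f"duplicate ligand_id in activity table: {lig!r}")
        try:
            pic50[lig] = float(r["pIC50"])
        except ValueError:
            raise ValueError(
                f"non-numeric pIC50 {r['pIC50']!r} at row {i + 2}"
            ) from None
        if r.get("sd") not in (None, ""):
            sd[lig] = float(r["sd"])
    return ActivityTable(pic50=pic50, sd=sd)


def write_activity_table(table: ActivityTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ligand_id", "pIC50", "sd"])
        for lig, v in table.pic50.items():
            w.writerow([lig, repr(float(v)),
                        "" if lig not in table.sd else repr(float(table.sd[lig]))])


def scores_as_mapping(table: ScoreTable, function_name: str) -> dict[str, float]:
    """Extract one function's column as ligand -> score (NaN kept)."""
    return table.scores[function_name].to_dict()
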