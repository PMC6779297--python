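"""Curation of raw activity tables into a sensitive/resistant pair database.

The pipeline turns ChEMBL-style assay rows (IC50/GI50/CC50 measurements of a
compound against a cell line) into a curated database of ligand-cell-line
associations (LCLA), each labeled *sensitive* or *resistant*:

1. keep only IC50/GI50/CC50 rows with a usable SMILES, value and unit;
2. reduce salts and mixtures to the largest fragment, canonicalized;
3. convert the concentration to mol/L and label the pair sensitive when the
   endpoint is <= 1e-5 M (>=50% growth inhibition at <=10 uM), resistant
   otherwise;
4. pool all assay rows for the same (structure, cell line) pair across assay
   types and discard the pair unless every replicate agrees on the label;
5. drop any cell line sensitive to fewer than ``min_sensitive`` compounds
   (all its pairs, both labels).

Rows carrying a censored relation ('>' or '<') are dropped by default: a
censored value cannot be placed on either side of the 10 uM threshold.  An
optional flag admits '>' values strictly above 10 uM as resistant, which is
safe because the true value can only be larger.

Two input ids with the same canonical largest-fragment SMILES are one
compound: replicate agreement operates on structures, not accession ids.
The surviving key is the lexicographically smallest merged id, and the merge
map is kept in the audit report.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .errors import FormatError, InvalidStructureError, UnitError

__all__ = [
    "RawActivityRecord",
    "LCLA",
    "LCLADatabase",
    "parse_activity_table",
    "strip_to_largest_fragment",
    "to_molar",
    "label_activity",
    "resolve_replicates",
    "filter_cell_lines",
    "build_lcla_database",
    "build_database_from_pairs",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"

ADMITTED_ASSAY_TYPES = frozenset({"IC50", "GI50", "CC50"})
SENSITIVITY_THRESHOLD_M = 1e-5

_UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

REQUIRED_COLUMNS = (
    "compound_id",
    "smiles",
    "cell_line_id",
    "assay_type",
    "standard_value",
    "standard_units",
    "standard_relation",
)


@dataclass(frozen=True)
class RawActivityRecord:
    """One assay measurement linking a compound to a cell line."""

    compound_id: str
    smiles: str
    cell_line_id: str
    assay_type: str
    value: float
    units: str
    relation: str = "="


@dataclass(frozen=True)
class LCLA:
    """A labeled ligand-cell-line association."""

    compound_id: str
    cell_line_id: str
    label: str


@dataclass
class LCLADatabase:
    """Curated pair database indexed by cell line.

    ``compounds`` maps a compound id to its canonical largest-fragment
    SMILES; ``pairs`` holds at most one LCLA per (compound, cell line).
    """

    compounds: dict[str, str] = field(default_factory=dict)
    pairs: list[LCLA] = field(default_factory=list)

    @property
    def per_cell_index(self) -> dict[str, tuple[list[str], list[str]]]:
        """cell_line_id -> (sorted sensitive ids, sorted resistant ids)."""
        idx: dict[str, tuple[list[str], list[str]]] = {}
        for p in self.pairs:
            sens, res = idx.setdefault(p.cell_line_id, ([], []))
            (sens if p.label == SENSITIVE else res).append(p.compound_id)
        return {c: (sorted(s), sorted(r)) for c, (s, r) in sorted(idx.items())}

    @property
    def cell_lines(self) -> list[str]:
        return sorted({p.cell_line_id for p in self.pairs})

    def sensitive_ids(self, cell_line_id: str) -> list[str]:
        return self.per_cell_index.get(cell_line_id, ([], []))[0]

    def resistant_ids(self, cell_line_id: str) -> list[str]:
        return self.per_cell_index.get(cell_line_id, ([], []))[1]

    def n_pairs(self, label: str | None = None) -> int:
        if label is None:
            return len(self.pairs)
        return sum(1 for p in self.pairs if p.label == label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.compound_id, self.compounds[p.compound_id], p.cell_line_id, p.label)
            for p in self.pairs
        ]
        df = pd.DataFrame(
            rows, columns=["compound_id", "canonical_smiles", "cell_line_id", "label"]
        )
        return df.sort_values(["cell_line_id", "compound_id"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LCLADatabase":
        compounds = dict(zip(df["compound_id"], df["canonical_smiles"]))
        pairs = [
            LCLA(r.compound_id, r.cell_line_id, r.label) for r in df.itertuples()
        ]
        return cls(compounds=compounds, pairs=pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LCLADatabase):
            return NotImplemented
        return self.compounds == other.compounds and set(self.pairs) == set(other.pairs)


def parse_activity_table(
    path: str | Path, dialect: str = "auto"
) -> tuple[list[RawActivityRecord], dict[str, int]]:
    """Read a CSV/TSV raw activity table into records.

    Rows whose assay type is not IC50/GI50/CC50, or whose SMILES or value is
    missing/non-numeric, are dropped and counted in the returned audit dict.
    A missing required column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    delimiter = {"csv": ",", "tsv": "\t"}.get(dialect)
    text = path.read_text()
    if delimiter is None:
        head = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if head.count("\t") > head.count(",") else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    cols = set(reader.fieldnames or [])
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise FormatError(f"missing required columns: {missing}")

    audit = {"rows_read": 0, "dropped_assay_type": 0, "dropped_missing_field": 0}
    records: list[RawActivityRecord] = []
    for row in reader:
        audit["rows_read"] += 1
        assay = (row["assay_type"] or "").strip().upper()
        if assay not in ADMITTED_ASSAY_TYPES:
            audit["dropped_assay_type"] += 1
            continue
        smiles = (row["smiles"] or "").strip()
        raw_value = (row["standard_value"] or "").strip()
        try:
            value = float(raw_value)
        except ValueError:
            value = float("nan")
        if not smiles or not raw_value or not value > 0:
            audit["dropped_missing_field"] += 1
            continue
        records.append(
            RawActivityRecord(
                compound_id=(row["compound_id"] or "").strip(),
                smiles=smiles,
                cell_line_id=(row["cell_line_id"] or "").strip(),
                assay_type=assay,
                value=value,
                units=(row["standard_units"] or "").strip(),
                relation=(row["standard_relation"] or "").strip(),
            )
        )
    return records, audit


def strip_to_largest_fragment(smiles: str) -> str:
    """Canonical SMILES of the fragment with the most heavy atoms.

    Salts and mixtures reduce to their principal component; ties break by
    molecular weight, then by lexicographic canonical SMILES, so the output
    is deterministic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return Chem.MolToSmiles(mol)
    best = max(
        frags,
        key=lambda f: (
            f.GetNumHeavyAtoms(),
            Descriptors.MolWt(f),
            # invert lexicographic order so max() prefers the smallest string
            [-ord(ch) for ch in Chem.MolToSmiles(f)],
        ),
    )
    return Chem.MolToSmiles(best)


def to_molar(value: float, units: str) -> float:
    """Convert a concentration to mol/L; unknown units raise UnitError."""
    factor = _UNIT_FACTORS.get(units.strip())
    if factor is None:
        raise UnitError(f"unknown concentration unit: {units!r}")
    return value * factor


def label_activity(concentration_molar: float) -> str:
    """Sensitive iff the endpoint concentration is <= 1e-5 M (10 uM)."""
    if not concentration_molar > 0:
        raise ValueError(f"concentration must be positive, got {concentration_molar}")
    return SENSITIVE if concentration_molar <= SENSITIVITY_THRESHOLD_M else RESISTANT


def resolve_replicates(labels: list[str]) -> str | None:
    """Common label when all replicates agree; None (discard) on conflict.

    Replicates are pooled across assay types: a pair with both an IC50 and a
    GI50 row must agree across both under the single classification rule.
    """
    if not labels:
        raise ValueError("no labels to resolve")
    unique = set(labels)
    if len(unique) == 1:
        return labels[0]
    return None


def filter_cell_lines(db: LCLADatabase, min_sensitive: int = 10) -> LCLADatabase:
    """Drop every pair of any cell line sensitive to < min_sensitive compounds.

    Compounds left without pairs disappear from the compound map too.
    """
    keep_cells = {
        cell
        for cell, (sens, _) in db.per_cell_index.items()
        if len(sens) >= min_sensitive
    }
    pairs = [p for p in db.pairs if p.cell_line_id in keep_cells]
    used = {p.compound_id for p in pairs}
    compounds = {cid: smi for cid, smi in db.compounds.items() if cid in used}
    return LCLADatabase(compounds=compounds, pairs=pairs)


def _curate_labeled(
    labeled: list[tuple[str, str, str, str]],
    min_sensitive: int,
    audit: dict,
) -> LCLADatabase:
    """Shared tail of the pipeline: id merge, replicate resolution, cell filter.

    ``labeled`` rows are (compound_id, canonical_smiles, cell_line_id, label).
    """
    # merge ids that share a structure; the smallest id wins
    by_structure: dict[str, set[str]] = defaultdict(set)
    for cid, smi, _, _ in labeled:
        by_structure[smi].add(cid)
    canonical_id = {smi: min(ids) for smi, ids in by_structure.items()}
    merged = {
        smi: sorted(ids) for smi, ids in by_structure.items() if len(ids) > 1
    }
    audit["merged_compound_ids"] = merged
    audit["n_compounds_merged"] = sum(len(v) - 1 for v in merged.values())

    grouped: dict[tuple[str, str], list[str]] = defaultdict(list)
    structures: dict[str, str] = {}
    for cid, smi, cell, label in labeled:
        key_id = canonical_id[smi]
        structures[key_id] = smi
        grouped[(key_id, cell)].append(label)

    pairs: list[LCLA] = []
    n_conflicts = 0
    for (cid, cell), labels in grouped.items():
        resolved = resolve_replicates(labels)
        if resolved is None:
            n_conflicts += 1
            continue
        pairs.append(LCLA(cid, cell, resolved))
    audit["dropped_replicate_conflict"] = n_conflicts

    used = {p.compound_id for p in pairs}
    db = LCLADatabase(
        compounds={cid: smi for cid, smi in structures.items() if cid in used},
        pairs=pairs,
    )
    audit["pairs_before_cell_filter"] = len(db.pairs)
    db = filter_cell_lines(db, min_sensitive=min_sensitive)
    audit["pairs_after_cell_filter"] = len(db.pairs)
    audit["cell_lines_retained"] = len(db.cell_lines)
    return db


def build_lcla_database(
    records: list[RawActivityRecord],
    min_sensitive: int = 10,
    admit_censored_resistant: bool = False,
) -> tuple[LCLADatabase, dict]:
    """Run the whole curation pipeline on raw assay records.

    Returns the curated database and an audit report counting the rows
    dropped at each stage.
    """
    audit: dict = {"records_in": len(records)}
    n_relation = n_structure = n_unit = 0
    labeled: list[tuple[str, str, str, str]] = []
    for rec in records:
        if rec.assay_type not in ADMITTED_ASSAY_TYPES:
            audit["dropped_assay_type"] = audit.get("dropped_assay_type", 0) + 1
            continue
        relation = rec.relation or "="
        censored_resistant = False
        if relation != "=":
            if (
                admit_censored_resistant
                and relation == ">"
            ):
                censored_resistant = True
            else:
                n_relation += 1
                continue
        try:
            smi = strip_to_largest_fragment(rec.smiles)
        except InvalidStructureError:
            n_structure += 1
            continue
        try:
            molar = to_molar(rec.value, rec.units)
        except UnitError:
            n_unit += 1
            continue
        if censored_resistant:
            # '>' above the threshold can only mean resistant; below it the
            # true value is unknowable and the row is dropped
            if molar > SENSITIVITY_THRESHOLD_M:
                label = RESISTANT
            else:
                n_relation += 1
                continue
        else:
            label = label_activity(molar)
        labeled.append((rec.compound_id, smi, rec.cell_line_id, label))
    audit["dropped_relation"] = n_relation
    audit["dropped_invalid_structure"] = n_structure
    audit["dropped_unknown_unit"] = n_unit
    audit["records_labeled"] = len(labeled)
    db = _curate_labeled(labeled, min_sensitive, audit)
    return db, audit


def build_database_from_pairs(
    df: pd.DataFrame, min_sensitive: int = 10
) -> tuple[LCLADatabase, dict]:
    """Ingest a pre-curated pair table (compound_id, smiles, cell_line_id, label).

    The same structure normalization, replicate resolution and cell-line
    filter run again, so ingesting an already-curated table is idempotent.
    """
    smiles_col = "canonical_smiles" if "canonical_smiles" in df.columns else "smiles"
    audit: dict = {"records_in": len(df)}
    labeled = []
    n_bad = 0
    for row in df.itertuples():
        label = str(row.label).strip().lower()
        if label not in (SENSITIVE, RESISTANT):
            n_bad += 1
            continue
        try:
            smi = strip_to_largest_fragment(getattr(row, smiles_col))
        except InvalidStructureError:
            n_bad += 1
            continue
        labeled.append((str(row.compound_id), smi, str(row.cell_line_id), label))
    audit["dropped_malformed"] = n_bad
    db = _curate_labeled(labeled, min_sensitive, audit)
    return db, audit
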