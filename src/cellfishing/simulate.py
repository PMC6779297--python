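"""Synthetic compound libraries and activity tables with planted structure.

The generator emulates the data regime the similarity principle assumes:
compounds come in scaffold families (decorated cores), structurally similar
compounds tend to share per-cell-line sensitivity, and the raw assay table
carries the usual ChEMBL-style noise — replicate measurements, occasional
replicate conflicts, counter-ion salts, and off-type assay rows.

Libraries are assembled by decorating a fixed internal whitelist of core
scaffolds (substituted benzenes, azines, amides, sulfonamides, ...) with
substituent pairs, so every emitted SMILES is valid by construction and
within-family Tanimoto similarity exceeds between-family similarity on
average.  Per (scaffold, cell line) a sensitivity *tendency* is drawn; each
member compound inherits it, flipped with a small label-noise probability.
Sensitive pairs receive endpoint values drawn log-uniformly in [10 nM,
10 uM], resistant pairs in (10 uM, 1 mM], straddling the 1e-5 M labeling
threshold.

Everything is deterministic given (config, seed): the same configuration
always regenerates byte-identical fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import RESISTANT, SENSITIVE

__all__ = [
    "GeneratorConfig",
    "SCAFFOLD_TEMPLATES",
    "generate_library",
    "generate_truth",
    "generate_raw_table",
    "scaffold_of",
]

# dual-slot cores; {a}/{b} take any branch-safe substituent below
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "c1cc({a})ccc1{b}",
    "c1cc({a})cnc1{b}",
    "c1nc({a})cnc1{b}",
    "c1cc({a})sc1{b}",
    "c1cc({a})oc1{b}",
    "c1cc({a})n(C)c1{b}",
    "C({a})CC(=O)N({b})C",
    "O=C(N{a})c1ccc({b})cc1",
    "C({a})OC(=O)c1ccc({b})cc1",
    "c1ccc({a})cc1Oc1ccc({b})cc1",
    "c1ccc({a})cc1Cc1ccc({b})cc1",
    "C({a})N1CCN(CC1){b}",
    "C({a})N1CCC(CC1){b}",
    "O=S(=O)(N{a})c1ccc({b})cc1",
    "C({a})Sc1nc2ccccc2n1{b}",
    "C({a})c1nnc(o1){b}",
    "C({a})c1csc(n1){b}",
    "C({a})C1CCCCC1{b}",
    "C(=O)({a})Nc1cccc({b})c1",
)

SUBSTITUENTS: tuple[str, ...] = (
    "C", "N", "O", "F", "Cl", "Br", "CC", "CO", "CN", "CCO", "CCN",
    "C(C)C", "C#N", "C(F)(F)F", "CCC", "OC", "C=C", "OCC", "CC(C)C", "CCF",
)

SALT_FRAGMENTS: tuple[str, ...] = ("Cl", "[Na+]", "O=S(=O)(O)O", "OC(=O)C")

ASSAY_TYPES: tuple[str, ...] = ("IC50", "GI50", "CC50")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic fixture.

    ``p_scaffold_active`` is the probability a (scaffold, cell line) pair is
    sensitive-prone; ``label_noise`` the probability a member compound flips
    away from its scaffold's tendency.  ``scaffold_offset`` shifts which
    core templates are used, so a query library can be built on scaffolds
    absent from the reference library.
    """

    n_scaffolds: int = 12
    n_per_scaffold: int = 10
    n_cell_lines: int = 15
    p_scaffold_active: float = 0.35
    label_noise: float = 0.05
    replicate_rate: float = 0.2
    conflict_rate: float = 0.0
    salt_rate: float = 0.1
    off_type_rate: float = 0.02
    min_guaranteed_sensitive: int = 10
    guaranteed_fraction: float = 1.0
    scaffold_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_scaffold_active", "label_noise", "replicate_rate",
                     "conflict_rate", "salt_rate", "off_type_rate",
                     "guaranteed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if min(self.n_scaffolds, self.n_per_scaffold, self.n_cell_lines) < 1:
            raise ValueError("all counts must be >= 1")


def scaffold_of(compound_id: str) -> int:
    """Scaffold family index encoded in a generated compound id."""
    return int(compound_id.split("C")[0][1:])


def generate_library(config: GeneratorConfig) -> list[tuple[str, str]]:
    """Emit (compound_id, SMILES) pairs in scaffold families.

    Ids are ``S<scaffold>C<member>``.  Structures are unique across the
    library (checked on canonical SMILES); requesting more decorations than
    a scaffold supports raises a capacity error.
    """
    first, last = config.scaffold_offset, config.scaffold_offset + config.n_scaffolds
    if last > len(SCAFFOLD_TEMPLATES):
        raise ValueError(
            f"only {len(SCAFFOLD_TEMPLATES)} scaffold templates available, "
            f"requested indices {first}..{last - 1}"
        )
    rng = np.random.default_rng(config.seed)
    combos = list(itertools.product(SUBSTITUENTS, SUBSTITUENTS))
    library: list[tuple[str, str]] = []
    seen: set[str] = set()
    for s in range(first, last):
        template = SCAFFOLD_TEMPLATES[s]
        order = rng.permutation(len(combos))
        picked = 0
        for idx in order:
            if picked == config.n_per_scaffold:
                break
            a, b = combos[idx]
            smiles = template.format(a=a, b=b)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:  # whitelist guarantees validity; belt and braces
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            library.append((f"S{s:02d}C{picked:03d}", smiles))
            picked += 1
        if picked < config.n_per_scaffold:
            raise ValueError(
                f"scaffold {s} cannot yield {config.n_per_scaffold} distinct compounds"
            )
    return library


def generate_truth(
    library: list[tuple[str, str]], config: GeneratorConfig
) -> pd.DataFrame:
    """Per (compound, cell line) truth labels driven by scaffold tendencies.

    Cell lines in the guaranteed fraction are re-drawn (activating extra
    scaffolds) until they reach ``min_guaranteed_sensitive`` sensitive
    compounds, so downstream curation retains them.
    """
    rng = np.random.default_rng(config.seed + 1)
    scaffolds = sorted({scaffold_of(cid) for cid, _ in library})
    members: dict[int, list[tuple[str, str]]] = {s: [] for s in scaffolds}
    for cid, smi in library:
        members[scaffold_of(cid)].append((cid, smi))
    cells = [f"CELL{j:03d}" for j in range(config.n_cell_lines)]
    n_guaranteed = int(round(config.guaranteed_fraction * len(cells)))

    rows = []
    for j, cell in enumerate(cells):
        tendency = {
            s: rng.random() < config.p_scaffold_active for s in scaffolds
        }
        labels: dict[str, str] = {}

        def draw_labels(scaffold_set):
            for s in scaffold_set:
                for cid, _ in members[s]:
                    prone = tendency[s]
                    if rng.random() < config.label_noise:
                        prone = not prone
                    labels[cid] = SENSITIVE if prone else RESISTANT

        draw_labels(scaffolds)
        if j < n_guaranteed:
            need = config.min_guaranteed_sensitive
            attempts = 0
            while sum(l == SENSITIVE for l in labels.values()) < need:
                inactive = [s for s in scaffolds if not tendency[s]]
                if inactive and attempts < 10 * len(scaffolds):
                    s = inactive[rng.integers(len(inactive))]
                    tendency[s] = True
                    draw_labels([s])
                    attempts += 1
                else:  # pathological config: force labels directly
                    for cid in sorted(labels):
                        if labels[cid] == RESISTANT:
                            labels[cid] = SENSITIVE
                            if sum(l == SENSITIVE for l in labels.values()) >= need:
                                break
        for cid, smi in library:
            rows.append((cid, smi, cell, labels[cid]))
    return pd.DataFrame(
        rows, columns=["compound_id", "smiles", "cell_line_id", "label"]
    )


def _draw_value_molar(rng: np.random.Generator, label: str) -> float:
    """Log-uniform endpoint concentration consistent with the label."""
    if label == SENSITIVE:
        lo, hi = 1e-8, 1e-5
    else:
        lo, hi = 1e-5, 1e-3
    v = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
    if label == RESISTANT and v <= 1e-5:
        v = 1.001e-5
    return v


def generate_raw_table(truth: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Expand truth pairs into ChEMBL-style assay rows.

    Each pair yields one consistent measurement; extra consistent replicates
    appear at ``replicate_rate``, contradicting replicates at
    ``conflict_rate``, salt/mixture SMILES at ``salt_rate`` and off-type
    (EC50) duplicate rows at ``off_type_rate``.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for rec in truth.itertuples():
        smiles = rec.smiles
        if rng.random() < config.salt_rate:
            smiles = smiles + "." + SALT_FRAGMENTS[rng.integers(len(SALT_FRAGMENTS))]

        def emit(label: str, assay: str | None = None) -> None:
            molar = _draw_value_molar(rng, label)
            if rng.random() < 0.5:
                value, units = molar * 1e9, "nM"
            else:
                value, units = molar * 1e6, "uM"
            rows.append(
                (
                    rec.compound_id,
                    smiles,
                    rec.cell_line_id,
                    assay or ASSAY_TYPES[rng.integers(len(ASSAY_TYPES))],
                    value,
                    units,
                    "=",
                )
            )

        emit(rec.label)
        if rng.random() < config.replicate_rate:
            emit(rec.label)
        if rng.random() < config.conflict_rate:
            emit(RESISTANT if rec.label == SENSITIVE else SENSITIVE)
        if rng.random() < config.off_type_rate:
            molar = _draw_value_molar(rng, rec.label)
            rows.append(
                (
                    rec.compound_id,
                    smiles,
                    rec.cell_line_id,
                    "EC50",
                    molar * 1e9,
                    "nM",
                    "=",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "smiles",
            "cell_line_id",
            "assay_type",
            "standard_value",
            "standard_units",
            "standard_relation",
        ],
    )


def config_dict(config: GeneratorConfig) -> dict:
    """JSON-serializable echo of a configuration."""
    return asdict(config)
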