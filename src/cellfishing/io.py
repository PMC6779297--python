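"""Table readers/writers, configuration files and run manifests."""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .curation import RESISTANT, SENSITIVE
from .errors import FormatError
from .fishing import Prediction

__all__ = [
    "read_pair_table",
    "write_pair_table",
    "write_predictions",
    "read_predictions",
    "load_config",
    "write_json",
    "write_manifest",
]

PAIR_COLUMNS = ("compound_id", "cell_line_id", "label")

# S2-style ChEMBL export headers mapped onto our schema
DEFAULT_ALIASES = {
    "molregno": "compound_id",
    "chembl_id": "compound_id",
    "cell_id": "cell_line_id",
    "cell_chembl_id": "cell_line_id",
    "activity": "label",
    "classification": "label",
}


def read_pair_table(
    path: str | Path, aliases: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Read a curated pair table CSV/TSV; malformed rows are skipped and counted.

    Column aliases (e.g. an S2-style export's headers) are renamed onto the
    canonical schema first.  More than 50% malformed rows is fatal.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = dict(DEFAULT_ALIASES)
    rename.update(aliases or {})
    df = df.rename(columns={c: rename.get(c, c) for c in df.columns})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pair table missing columns: {missing}")
    if "smiles" not in df.columns and "canonical_smiles" not in df.columns:
        raise FormatError("pair table needs a smiles column")

    n_in = len(df)
    df["label"] = df["label"].astype(str).str.strip().str.lower()
    ok = df["label"].isin([SENSITIVE, RESISTANT])
    smiles_col = "canonical_smiles" if "canonical_smiles" in df.columns else "smiles"
    for col in ("compound_id", "cell_line_id", smiles_col):
        ok &= df[col].notna() & (df[col].astype(str).str.strip() != "")
    audit = {"rows_read": n_in, "rows_rejected": int((~ok).sum())}
    if n_in and audit["rows_rejected"] > 0.5 * n_in:
        raise FormatError(
            f"{audit['rows_rejected']}/{n_in} rows malformed; refusing to continue"
        )
    return df[ok].reset_index(drop=True), audit


def write_pair_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_predictions(path: str | Path, predictions: list[Prediction]) -> None:
    rows = [
        (p.compound_id, p.cell_line_id, p.score, p.label, p.method,
         "" if p.covered is None else p.covered)
        for p in predictions
    ]
    pd.DataFrame(
        rows,
        columns=["compound_id", "cell_line_id", "score", "label", "method", "covered"],
    ).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[Prediction]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        covered = None if pd.isna(r.covered) or r.covered == "" else bool(r.covered)
        out.append(
            Prediction(
                str(r.compound_id), str(r.cell_line_id), float(r.score),
                str(r.label), str(r.method), covered,
            )
        )
    return out


def load_config(path: str | Path) -> dict:
    """Flat key-value YAML configuration; CLI flags override these values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("config file must be a flat key-value mapping")
    return data


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def write_manifest(path: str | Path, command: str, params: dict) -> None:
    """Record run parameters and library versions next to an output."""
    import rdkit
    import sklearn
    import numpy
    import scipy

    manifest = {
        "command": command,
        "params": {k: str(v) for k, v in params.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": sys.version.split()[0],
        "versions": {
            "rdkit": rdkit.__version__,
            "scikit-learn": sklearn.__version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    write_json(path, manifest)
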