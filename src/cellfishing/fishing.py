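"""Similarity-based cell-line sensitivity prediction ("cell fishing").

For a query compound, each cell line is scored by the mean Tanimoto
similarity between the query and the top ``n_top`` most similar compounds
known to be *sensitive* for that cell line.  The cell line is called
sensitive when the score reaches the similarity cutoff (score >= cutoff,
inclusive).  No model is fitted: the reference database of sensitive
compounds IS the predictor, which makes the approach trivially scalable as
new activity data accrue.

Below-cutoff cell lines are reported as resistant so a full confusion
matrix is defined, while *coverage* is a separate compound-level flag:
a compound is covered when at least one cell line was called sensitive.
Uncovered compounds therefore contribute only resistant calls.

When the similarity method leaves a compound uncovered, a per-cell-line SVM
can fill in its predictions; that hybrid is ``combined_predict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import LCLADatabase, RESISTANT, SENSITIVE
from .errors import ConfigurationError, NoReferenceError
from .fingerprints import Fingerprint, bulk_tanimoto, morgan_fingerprint

__all__ = [
    "Prediction",
    "SimilarityReference",
    "top_n_mean",
    "sensitivity_score",
    "fish",
    "compound_coverage",
    "combined_predict",
]

DEFAULT_N_TOP = 3
DEFAULT_CUTOFF = 0.25


@dataclass(frozen=True)
class Prediction:
    """A predicted label for one (compound, cell line) pair.

    ``score`` is the mean top-n Tanimoto similarity for the similarity
    method, or the signed decision value for the SVM. ``covered`` is only
    meaningful for the similarity method.
    """

    compound_id: str
    cell_line_id: str
    score: float
    label: str
    method: str
    covered: bool | None = None


@dataclass
class SimilarityReference:
    """Per-cell-line lists of sensitive reference fingerprints.

    ``per_cell`` maps cell_line_id to a list of (compound_id,
    canonical_smiles, Fingerprint) for every sensitive compound of that
    cell line; all fingerprints share (radius, n_bits).
    """

    radius: int
    n_bits: int
    n_top: int = DEFAULT_N_TOP
    per_cell: dict[str, list[tuple[str, str, Fingerprint]]] = field(
        default_factory=dict
    )

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.per_cell)

    @classmethod
    def from_database(
        cls,
        db: LCLADatabase,
        radius: int,
        n_bits: int,
        n_top: int = DEFAULT_N_TOP,
        fp_cache: dict[str, Fingerprint] | None = None,
        restrict_to: set[str] | None = None,
    ) -> "SimilarityReference":
        """Build references from a curated database's sensitive pairs.

        ``restrict_to`` limits reference compounds to the given ids (used to
        exclude held-out compounds during cross-validation).  ``fp_cache``
        maps compound id to a precomputed fingerprint.
        """
        cache = fp_cache if fp_cache is not None else {}
        per_cell: dict[str, list[tuple[str, str, Fingerprint]]] = {}
        for cell, (sens, _) in db.per_cell_index.items():
            entries = []
            for cid in sens:
                if restrict_to is not None and cid not in restrict_to:
                    continue
                smi = db.compounds[cid]
                if cid not in cache:
                    cache[cid] = morgan_fingerprint(smi, radius, n_bits)
                entries.append((cid, smi, cache[cid]))
            if entries:
                per_cell[cell] = entries
        return cls(radius=radius, n_bits=n_bits, n_top=n_top, per_cell=per_cell)


def top_n_mean(similarities: np.ndarray, n_top: int) -> float:
    """Mean of the n_top largest values; all values if fewer are available."""
    sims = np.asarray(similarities, dtype=float)
    if sims.size == 0:
        raise NoReferenceError("no reference similarities supplied")
    if sims.size > n_top:
        sims = np.partition(sims, -n_top)[-n_top:]
    # average in descending order so the result is bit-identical to a
    # sort-all-then-average computation
    return float(np.sort(sims)[::-1].mean())


def sensitivity_score(
    query_fp: Fingerprint,
    cell_refs: list[Fingerprint],
    n_top: int = DEFAULT_N_TOP,
) -> float:
    """Mean Tanimoto of the query to a cell line's top-n sensitive compounds."""
    if not cell_refs:
        raise NoReferenceError("cell line has no sensitive reference compounds")
    return top_n_mean(bulk_tanimoto(query_fp, cell_refs), n_top)


def fish(
    query_smiles: str,
    reference: SimilarityReference,
    cutoff: float = DEFAULT_CUTOFF,
    compound_id: str = "query",
    exclude_self: bool = True,
) -> list[Prediction]:
    """Score a query compound against every referenced cell line.

    Self-exclusion removes reference entries whose canonical SMILES equals
    the query's, so a validation compound never matches itself; the match is
    structural, not by id, because duplicate structures under different ids
    would leak.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    from .curation import strip_to_largest_fragment

    canon = strip_to_largest_fragment(query_smiles)
    query_fp = morgan_fingerprint(canon, reference.radius, reference.n_bits)
    preds = []
    any_sensitive = False
    for cell in reference.cell_lines:
        entries = reference.per_cell[cell]
        if exclude_self:
            entries = [e for e in entries if e[1] != canon]
        if not entries:
            preds.append(
                Prediction(compound_id, cell, 0.0, RESISTANT, "similarity")
            )
            continue
        score = sensitivity_score(
            query_fp, [e[2] for e in entries], reference.n_top
        )
        label = SENSITIVE if score >= cutoff else RESISTANT
        any_sensitive = any_sensitive or label == SENSITIVE
        preds.append(Prediction(compound_id, cell, score, label, "similarity"))
    return [
        Prediction(p.compound_id, p.cell_line_id, p.score, p.label, p.method,
                   covered=any_sensitive)
        for p in preds
    ]


def compound_coverage(predictions: list[Prediction]) -> bool:
    """True when the similarity method called at least one cell line sensitive."""
    if any(p.method != "similarity" for p in predictions):
        raise ValueError("coverage is defined for similarity predictions only")
    return any(p.label == SENSITIVE for p in predictions)


def combined_predict(
    query_smiles: str,
    reference: SimilarityReference,
    svm_models: dict,
    cutoff: float = DEFAULT_CUTOFF,
    compound_id: str = "query",
    exclude_self: bool = True,
) -> list[Prediction]:
    """Similarity predictions when the compound is covered, SVM otherwise.

    Both models must span the same cell-line set so the hybrid answers over
    one space.  The method field records which route produced each call.
    """
    from .svm import predict_cell_svm

    if set(svm_models) != set(reference.cell_lines):
        raise ConfigurationError(
            "similarity reference and SVM models cover different cell-line sets"
        )
    sim_preds = fish(
        query_smiles, reference, cutoff,
        compound_id=compound_id, exclude_self=exclude_self,
    )
    if compound_coverage(sim_preds):
        return sim_preds
    from .curation import strip_to_largest_fragment

    canon = strip_to_largest_fragment(query_smiles)
    out = []
    for cell in reference.cell_lines:
        model = svm_models[cell]
        fp = morgan_fingerprint(canon, model.radius, model.n_bits)
        pred = predict_cell_svm(model, fp, compound_id=compound_id)
        out.append(pred)
    return out
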