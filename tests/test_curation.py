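"""Curation pipeline: filters, labeling, replicate resolution, cell-line floor."""

import random

import pandas as pd
import pytest
from rdkit import Chem

import cellfishing as cf
from cellfishing.curation import RESISTANT, SENSITIVE


def _write_csv(tmp_path, rows, header=None):
    header = header or (
        "compound_id,smiles,cell_line_id,assay_type,"
        "standard_value,standard_units,standard_relation"
    )
    path = tmp_path / "raw.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestParseActivityTable:
    def test_off_type_assays_are_dropped_and_counted(self, tmp_path):
        rows = [
            "c1,CCO,X,IC50,5000,nM,=",
            "c2,CCN,X,GI50,2,uM,=",
            "c3,CCC,X,CC50,50,uM,=",
            "c4,CCF,Y,IC50,1,uM,=",
            "c5,CCBr,Y,EC50,1,uM,=",
        ]
        records, audit = cf.parse_activity_table(_write_csv(tmp_path, rows))
        assert len(records) == 4
        assert audit["dropped_assay_type"] == 1

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        records, audit = cf.parse_activity_table(_write_csv(tmp_path, []))
        assert records == [] and audit["rows_read"] == 0

    def test_missing_smiles_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,cell_line_id\nc1,X\n")
        with pytest.raises(cf.FormatError, match="smiles"):
            cf.parse_activity_table(path)


class TestStripToLargestFragment:
    @pytest.mark.parametrize(
        "smiles, expected_fragment",
        [
            ("CCO", "CCO"),  # single fragment: canonical identity
            ("CCO.Cl", "CCO"),  # 3 heavy atoms beat 1
            ("[Na+].CC(=O)[O-]", "CC(=O)[O-]"),  # 4 heavy atoms beat 1
        ],
    )
    def test_largest_fragment_by_heavy_atoms(self, smiles, expected_fragment):
        assert cf.strip_to_largest_fragment(smiles) == Chem.CanonSmiles(
            expected_fragment
        )

    def test_unparseable_smiles_raises(self):
        with pytest.raises(cf.InvalidStructureError):
            cf.strip_to_largest_fragment("not_a_smiles")

    def test_output_is_canonical(self):
        assert cf.strip_to_largest_fragment("OCC") == Chem.CanonSmiles("CCO")


class TestUnitConversionAndLabeling:
    @pytest.mark.parametrize(
        "value, units, molar",
        [(5000, "nM", 5e-6), (10, "uM", 1e-5), (0.01, "M", 1e-2), (2, "mM", 2e-3)],
    )
    def test_to_molar(self, value, units, molar):
        assert cf.to_molar(value, units) == pytest.approx(molar)

    def test_unknown_unit_raises(self):
        with pytest.raises(cf.UnitError):
            cf.to_molar(1.0, "parsec")

    @pytest.mark.parametrize(
        "molar, label",
        [(5e-6, SENSITIVE), (1e-5, SENSITIVE), (2e-5, RESISTANT)],
    )
    def test_threshold_is_inclusive_at_10_uM(self, molar, label):
        assert cf.label_activity(molar) == label

    def test_nonpositive_concentration_raises(self):
        with pytest.raises(ValueError):
            cf.label_activity(0.0)


class TestResolveReplicates:
    def test_unanimous_and_single_labels_pass(self):
        assert cf.resolve_replicates([SENSITIVE] * 3) == SENSITIVE
        assert cf.resolve_replicates([RESISTANT]) == RESISTANT

    def test_any_disagreement_discards_the_pair(self):
        assert cf.resolve_replicates([SENSITIVE, RESISTANT]) is None


def _toy_db(cells):
    """cells: {cell_id: (n_sensitive, n_resistant)} with unique compounds."""
    pairs, compounds, k = [], {}, 0
    for cell, (ns, nr) in cells.items():
        for label, n in ((SENSITIVE, ns), (RESISTANT, nr)):
            for _ in range(n):
                cid = f"c{k}"
                k += 1
                compounds[cid] = "C" * (k % 5 + 1)
                pairs.append(cf.LCLA(cid, cell, label))
    return cf.LCLADatabase(compounds=compounds, pairs=pairs)


class TestFilterCellLines:
    def test_cell_below_floor_is_removed_entirely(self):
        db = _toy_db({"A": (9, 100)})
        assert cf.filter_cell_lines(db, min_sensitive=10).pairs == []

    def test_cell_at_floor_is_retained(self):
        db = _toy_db({"A": (10, 0)})
        assert len(cf.filter_cell_lines(db, min_sensitive=10).pairs) == 10

    def test_empty_database_passes_through(self):
        out = cf.filter_cell_lines(cf.LCLADatabase())
        assert out.pairs == [] and out.compounds == {}

    def test_raising_floor_never_adds_cell_lines(self, low_noise_db):
        previous = None
        for floor in (1, 5, 10, 20, 40):
            n = len(cf.filter_cell_lines(low_noise_db, floor).cell_lines)
            if previous is not None:
                assert n <= previous
            previous = n


# hand-traced 12-row table, min_sensitive=2: cell X keeps sensitive
# {c1,c2,c4} and resistant {c3,c10}; c5 conflicts, c6 is off-type, c9 is
# censored, c11 has an unknown unit; cell Y has 1 sensitive -> dropped
HAND_TRACED_ROWS = [
    "c1,CCO,X,IC50,5000,nM,=",
    "c2,CCN,X,GI50,2,uM,=",
    "c3,CCC,X,CC50,50,uM,=",
    "c4,CCCl.Cl,X,IC50,1,uM,=",
    "c5,CCBr,X,IC50,1,uM,=",
    "c5,CCBr,X,CC50,100,uM,=",
    "c6,CCI,X,EC50,1,uM,=",
    "c7,CCF,Y,IC50,1,uM,=",
    "c8,CC(C)O,Y,IC50,200,uM,=",
    "c9,CC(C)N,X,IC50,50,uM,>",
    "c10,CC(C)C,X,IC50,0.05,mM,=",
    "c11,C=CC,X,IC50,1,parsec,=",
]


class TestBuildLclaDatabase:
    def test_hand_traced_pipeline(self, tmp_path):
        records, _ = cf.parse_activity_table(_write_csv(tmp_path, HAND_TRACED_ROWS))
        db, audit = cf.build_lcla_database(records, min_sensitive=2)
        assert db.cell_lines == ["X"]
        assert db.sensitive_ids("X") == ["c1", "c2", "c4"]
        assert db.resistant_ids("X") == ["c10", "c3"]  # lexicographic order
        assert db.compounds["c4"] == Chem.CanonSmiles("CCCl")
        assert audit["dropped_replicate_conflict"] == 1
        assert audit["dropped_relation"] == 1
        assert audit["dropped_unknown_unit"] == 1

    def test_all_conflicting_pairs_yield_empty_database(self):
        records = [
            cf.RawActivityRecord("c1", "CCO", "X", "IC50", v, "uM")
            for v in (1.0, 100.0)
        ]
        db, _ = cf.build_lcla_database(records, min_sensitive=1)
        assert db.pairs == [] and db.compounds == {}

    def test_curation_is_idempotent(self, low_noise_truth):
        db1, _ = cf.build_database_from_pairs(low_noise_truth)
        db2, _ = cf.build_database_from_pairs(db1.to_frame())
        assert db1 == db2
        assert db1.to_frame().equals(db2.to_frame())

    def test_row_order_does_not_matter(self, tmp_path):
        records, _ = cf.parse_activity_table(_write_csv(tmp_path, HAND_TRACED_ROWS))
        shuffled = records[:]
        random.Random(7).shuffle(shuffled)
        db1, _ = cf.build_lcla_database(records, min_sensitive=2)
        db2, _ = cf.build_lcla_database(shuffled, min_sensitive=2)
        assert db1 == db2

    def test_duplicate_structures_merge_under_one_id(self):
        # same molecule under two accession ids, consistent labels
        records = [
            cf.RawActivityRecord("zzz", "OCC", "X", "IC50", 1.0, "uM"),
            cf.RawActivityRecord("aaa", "CCO", "X", "GI50", 2.0, "uM"),
        ]
        db, audit = cf.build_lcla_database(records, min_sensitive=1)
        assert [p.compound_id for p in db.pairs] == ["aaa"]
        assert audit["n_compounds_merged"] == 1

    def test_censored_records_admitted_as_resistant_only_above_threshold(self):
        records = [
            cf.RawActivityRecord("c1", "CCO", "X", "IC50", 50, "uM", ">"),
            cf.RawActivityRecord("c2", "CCN", "X", "IC50", 1, "uM", ">"),
            cf.RawActivityRecord("c3", "CCC", "X", "IC50", 1, "uM", "="),
        ]
        db, audit = cf.build_lcla_database(
            records, min_sensitive=1, admit_censored_resistant=True
        )
        labels = {p.compound_id: p.label for p in db.pairs}
        assert labels == {"c1": RESISTANT, "c3": SENSITIVE}
        assert audit["dropped_relation"] == 1

    def test_retained_pairs_agree_with_uncorrupted_truth(self, low_noise_library,
                                                         low_noise_config):
        """With conflicts injected, every surviving pair still matches truth."""
        from dataclasses import replace

        cfg = replace(low_noise_config, conflict_rate=0.3, seed=9)
        truth = cf.generate_truth(low_noise_library, cfg)
        raw = cf.generate_raw_table(truth, cfg)
        records = [
            cf.RawActivityRecord(
                r.compound_id, r.smiles, r.cell_line_id, r.assay_type,
                float(r.standard_value), r.standard_units, r.standard_relation,
            )
            for r in raw.itertuples()
        ]
        db, _ = cf.build_lcla_database(records, min_sensitive=1)
        truth_label = {
            (t.compound_id, t.cell_line_id): t.label for t in truth.itertuples()
        }
        assert db.pairs  # conflicts remove some but far from all pairs
        for p in db.pairs:
            assert truth_label[(p.compound_id, p.cell_line_id)] == p.label
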