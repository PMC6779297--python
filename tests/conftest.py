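"""Shared fixtures: synthetic databases built once per session."""

import pytest
from rdkit import RDLogger

import cellfishing as cf

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def low_noise_config() -> cf.GeneratorConfig:
    """Scaffold-structured fixture with a strong similarity signal."""
    return cf.GeneratorConfig(
        n_scaffolds=12,
        n_per_scaffold=10,
        n_cell_lines=15,
        p_scaffold_active=0.35,
        label_noise=0.05,
        seed=3,
    )


@pytest.fixture(scope="session")
def low_noise_library(low_noise_config):
    return cf.generate_library(low_noise_config)


@pytest.fixture(scope="session")
def low_noise_truth(low_noise_config, low_noise_library):
    return cf.generate_truth(low_noise_library, low_noise_config)


@pytest.fixture(scope="session")
def low_noise_db(low_noise_truth) -> cf.LCLADatabase:
    db, _ = cf.build_database_from_pairs(low_noise_truth)
    return db


@pytest.fixture(scope="session")
def small_db(low_noise_db) -> cf.LCLADatabase:
    """The low-noise database restricted to 4 cell lines (fast SVM runs)."""
    keep = set(low_noise_db.cell_lines[:4])
    pairs = [p for p in low_noise_db.pairs if p.cell_line_id in keep]
    used = {p.compound_id for p in pairs}
    return cf.LCLADatabase(
        compounds={c: s for c, s in low_noise_db.compounds.items() if c in used},
        pairs=pairs,
    )
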