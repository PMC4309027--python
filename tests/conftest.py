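import numpy as np
import pytest

from phosphoid import peptide_db, synthetic


@pytest.fixture(scope="session")
def bundled_db() -> peptide_db.CompositeDB:
    """Composite DB built from the bundled synthetic proteins."""
    targets = synthetic.bundled_proteins()
    decoys = peptide_db.build_decoy(targets)
    return peptide_db.build_composite(targets, decoys)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def fasta_file(tmp_path):
    path = tmp_path / "proteins.fasta"
    synthetic.write_bundled_fasta(path)
    return path
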