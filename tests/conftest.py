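import numpy as np
import pytest

from ribointron import insert_map
from ribointron import synthetic_data as synth


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One seeded default-scenario dataset shared across tests."""
    cfg = synth.default_config()
    outdir = tmp_path_factory.mktemp("dataset")
    return synth.generate_dataset(cfg, seed=11, outdir=outdir)


@pytest.fixture(scope="session")
def detected(default_dataset):
    aln = default_dataset["alignment"]
    inserts = insert_map.detect_inserts(aln, "REF", gene="18S")
    return aln, inserts, default_dataset["truth"]


@pytest.fixture
def toy_alignment():
    """Three-row toy with one 4-column insert carried by s2."""
    from ribointron.seqio import MultipleAlignment, SequenceRecord

    return MultipleAlignment(
        [
            SequenceRecord(id="ref", residues="ACGT----ACGT", aligned=True),
            SequenceRecord(id="s2", residues="ACGTTTAAACGT", aligned=True),
            SequenceRecord(id="s3", residues="ACGT----ACGT", aligned=True),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
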