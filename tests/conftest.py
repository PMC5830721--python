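import numpy as np
import pytest

from cystmine.fixtures import generate_corpus, generate_ensemble
from cystmine.mapping import load_chain_table, load_fasta
from cystmine.mining import scan_corpus
from cystmine.pdbfile import parse_pdb

CORPUS_SEED = 101


@pytest.fixture(scope="session")
def corpus_paths(tmp_path_factory):
    """A 20-protein synthetic corpus (~80 structures) with truth tables."""
    outdir = tmp_path_factory.mktemp("corpus")
    ensembles = generate_corpus(n_proteins=20, seed=CORPUS_SEED)
    return generate_ensemble(ensembles, outdir)


@pytest.fixture(scope="session")
def corpus_models(corpus_paths):
    return [
        parse_pdb(path.read_text())
        for path in sorted(corpus_paths["structures"].glob("*.pdb"))
    ]


@pytest.fixture(scope="session")
def corpus_scan(corpus_paths, corpus_models):
    chain_index = load_chain_table(corpus_paths["chains"])
    sequences = load_fasta(corpus_paths["fasta"])
    return scan_corpus(corpus_models, chain_index, sequences)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
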