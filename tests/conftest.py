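import numpy as np
import pytest
from hypothesis import settings

from symcore.synthetic import SimulationConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

FULL_POLY = {
    (g, b): 1.0
    for g in ("core", "sym")
    for b in ("orientalis", "officinalis")
}

NEUTRAL_OMEGA = {
    (g, b): [(1.0, 1.0)]
    for g in ("core", "sym")
    for b in ("orientalis", "officinalis")
}


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same deterministic stream
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 14-strain collection small enough for per-test analysis."""
    cfg = SimulationConfig(
        seed=101, n_core_genes=30, gene_length_codons=(100, 200)
    )
    return generate_dataset(cfg, tmp_path_factory.mktemp("smallds"))


@pytest.fixture(scope="session")
def small_sequences(small_dataset):
    """gene_id -> {strain_id: sequence} for the small collection."""
    from Bio import SeqIO

    seqs = {}
    for strain_id, path in small_dataset.fasta_paths.items():
        for rec in SeqIO.parse(str(path), "fasta"):
            gid, sid = rec.id.split("|")
            seqs.setdefault(gid, {})[sid] = str(rec.seq)
    return seqs
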