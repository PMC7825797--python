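import pytest

from arcgen.sequence_io import GenomeProteome, GenomeSet, SequenceRecord
from arcgen.synthetic_data import SimulationConfig, generate_dataset


def make_genome(genome_id: str, proteins: dict[str, str], cds: dict[str, str] | None = None):
    prots = [SequenceRecord(pid, seq, "protein") for pid, seq in proteins.items()]
    nts = (
        [SequenceRecord(pid, seq, "nucleotide") for pid, seq in cds.items()]
        if cds
        else None
    )
    return GenomeProteome(genome_id, prots, nts)


def make_genome_set(*genomes):
    gs = GenomeSet()
    for g in genomes:
        gs.add(g)
    return gs


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One default-condition synthetic dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("synthetic")
    truth = generate_dataset(SimulationConfig(seed=11), outdir)
    return str(outdir), truth
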