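import numpy as np
import pytest

from barcodeval.io import LabeledAlignment, Sample


def make_aln(seqs, species, genus=None, marker="m"):
    """Build a LabeledAlignment from {id: sequence} and {id: species}."""
    genus = genus or {}
    rows = [
        Sample(sid, species[sid], genus.get(sid, "genus_x"), seq)
        for sid, seq in seqs.items()
    ]
    return LabeledAlignment(marker, rows)


def two_species_aln(seq_a, seq_b, n_a=2, n_b=2, marker="m"):
    """n_a copies of seq_a (species sp1) and n_b of seq_b (sp2)."""
    seqs, species = {}, {}
    for i in range(n_a):
        seqs[f"a{i}"] = seq_a
        species[f"a{i}"] = "sp1"
    for i in range(n_b):
        seqs[f"b{i}"] = seq_b
        species[f"b{i}"] = "sp2"
    return make_aln(seqs, species, marker=marker)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def metadata_file(tmp_path):
    path = tmp_path / "metadata.tsv"
    path.write_text(
        "sample_id\tspecies\tgenus\torigin\n"
        "s1\tspA\tgenX\tloc1\n"
        "s2\tspA\tgenX\tloc2\n"
        "s3\tspB\tgenX\tloc3\n"
        "s4\tspB\tgenX\tloc4\n"
    )
    return path


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "marker.fasta"
    path.write_text(
        ">s1\nACGTACGTAC\n>s2\nACGTACGTAC\n>s3\nACGTTCGTAC\n>s4\nACGTTCGTAC\n"
    )
    return path
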