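import pytest

from digestomics.sequence_db import ProteinRecord, load_fasta, packaged_path


@pytest.fixture(scope="session")
def lmw_gs():
    """The packaged synthetic LMW glutenin subunit stand-in.

    A synthetic sequence whose landmark coordinates (signal peptide 1-20,
    repetitive domain 34-197, the multi-locus 16-mer at 77-92 and 115-130,
    the 20-mer at 142-161, Met344-Cys345, Thr354-Thr355) follow the published
    Tri a 36 peptide map; it is not the real UniProt B2Y2Q7 sequence.
    """
    return load_fasta(packaged_path("lmw_gs_synthetic.fasta"))[0]


@pytest.fixture
def toy_protein():
    return ProteinRecord(accession="TOY1", sequence="MKVILFSQQQPPFSGLRAAY")


def write_fasta_text(path, entries):
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path
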