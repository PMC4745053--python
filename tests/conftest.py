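import pytest

from primerkit import DesignParams, simulate
from primerkit.seqio import SequenceRecord

# PCR-validated primers spanning the C. elegans ZK5204a transcript;
# names carry the 5'-terminus plus-strand coordinate after the underscore.
VALIDATED_PRIMERS = {
    "F1_83": "TCCCCGAAAATCTTCAGTG",
    "F2_84a": "CCCCGAAAATCTTCAGTGT",
    "F3_84b": "CCCCGAAAATCTTCAGTG",
    "F4_129a": "TTCACCGTCCACAGGCAAA",
    "F5_129b": "TTCACCGTCCACAGGCAA",
    "R1_554": "TAACCTGTGGACGAGGTGGA",
    "R2_555a": "AACCTGTGGACGAGGTGGA",
    "R3_555b": "TAACCTGTGGACGAGGTGG",
    "R4_555c": "ATAACCTGTGGACGAGGTG",
    "R5_556": "TAACCTGTGGACGAGGTG",
    "R6_557a": "CATAACCTGTGGACGAGGT",
    "R7_557b": "CATAACCTGTGGACGAGG",
    "R8_614": "ATGGTCTCAACTGCACCCAT",
    "R9_615": "TGGTCTCAACTGCACCCA",
}


@pytest.fixture(scope="session")
def default_params() -> DesignParams:
    return DesignParams()


@pytest.fixture(scope="session")
def dna_records():
    return simulate.random_dna_records(3, 600, seed=11)


@pytest.fixture(scope="session")
def snp_records():
    return simulate.random_snp_records(4, 1001, seed=17)


@pytest.fixture()
def two_record_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">alpha first toy record\nACGTACGTGGCCTTAA\nTTGGCCAACC\n"
        ">beta second toy record\nacgtacgtacgt\n"
    )
    return path


@pytest.fixture()
def rs_fasta(tmp_path):
    seq = ("AT" * 250 + "R" + "GC" * 250)  # 1001 nt, 'R' at position 501
    path = tmp_path / "toy_snp.fasta"
    path.write_text(f">rs0000001 pos = 501|len1001\n{seq}\n")
    return path


def make_record(residues: str, rec_id: str = "rec") -> SequenceRecord:
    return SequenceRecord(id=rec_id, residues=residues)
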