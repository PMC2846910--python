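import numpy as np
import pytest

from trdkit.simulate import LocusConfig, generate_germline_locus


@pytest.fixture(scope="session")
def locus():
    """One synthetic germline locus shared across tests (fixed seed)."""
    return generate_germline_locus(LocusConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# independent V-REGION template builder (construction oracle for numbering)
# ---------------------------------------------------------------------------

# framework scaffolds distinct from the simulator's, anchors in the same
# IMGT positions: C23 / W41 / L89 / Y102-F103-C104
T_FR1 = "GDSVTQTEGPVTLSEGASLELRCNYS"  # 26 aa, C at 23
T_FR2 = "VHWYRQDPGQGLRLIYY"  # 17 aa, W at 41
T_FR3 = "TSNDKSEHNGRLSLEHDKASKHFLSHITDTQPGDSAYFC"  # 39 aa, L at 89
T_LEADER = "MKRLLGELLGLLSAGEATGQ"  # 20 aa


def build_v_template(
    cdr1="ESTGSNH",
    cdr2="QGS",
    post104="ASWN",  # Trp at IMGT 107
    cdr2_deleted=False,
):
    """Assemble a V-REGION amino-acid string with known IMGT placement."""
    if cdr2_deleted:
        # deletion of last FR2 residue (55) through fifth FR3 residue (70)
        return T_FR1 + cdr1 + T_FR2[:-1] + T_FR3[5:] + post104
    return T_FR1 + cdr1 + T_FR2 + cdr2 + T_FR3 + post104


# minimal aa->codon map for reverse translation in tests
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACA", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}


def encode_aa(aa_seq: str) -> str:
    return "".join(_CODON[a] for a in aa_seq)
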