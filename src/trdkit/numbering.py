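"""IMGT unique numbering of V-DOMAINs, feature extraction and functionality calls.

The IMGT unique numbering fixes the framework regions of every V-DOMAIN at
constant spans — FR1-IMGT positions 1–26, FR2-IMGT 39–55, FR3-IMGT 66–104 —
so that all length variation is absorbed by the CDR loops (CDR1-IMGT 27–38,
CDR2-IMGT 56–65, CDR3-IMGT from 105).  Four anchor residues are conserved
across V-DOMAINs: 1st-CYS at position 23, CONSERVED-TRP at 41, a hydrophobic
residue (canonically Leu) at 89 and 2nd-CYS at 104.

Numbering is implemented as an anchored constraint search: candidate
(CDR1 length, CDR2 length) pairs are enumerated, each pair fully determines
where every IMGT position falls in the input sequence, and the pair that
best satisfies the anchors (plus the YFC motif closing FR3) is kept.  A
deletion variant lacking CDR2 — spanning the last FR2 residue through the
fifth FR3 residue, as seen in several ruminant TRDV1 genes — is searched as
an alternative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from trdkit.locus import GermlineGene

__all__ = [
    "VDomainNumbering",
    "VFeatureSet",
    "FunctionalityCall",
    "NumberingError",
    "number_v_domain",
    "extract_features",
    "classify_functionality",
    "coding_sequence",
]

HYDROPHOBIC_89 = set("LIVMFA")

# fixed IMGT framework spans (positions, inclusive)
FR1_SPAN = (1, 26)
CDR1_SPAN = (27, 38)
FR2_SPAN = (39, 55)
CDR2_SPAN = (56, 65)
FR3_SPAN = (66, 104)

_FR1_LEN = 26
_FR2_LEN = 17
_FR3_LEN = 39
# CDR2-deleted variant: last FR2 residue (55) through fifth FR3 residue (70) absent
_FR2_DEL_LEN = 16
_FR3_DEL_LEN = 34

MAX_CDR1 = 18  # long CDR1 (18 aa) occurs in one bovine TRDV1 gene; no upper bound enforced
MAX_CDR2 = 10


class NumberingError(ValueError):
    """Raised when a V-DOMAIN cannot be mapped onto IMGT positions.

    Carries the best-scoring partial map (if any candidate placed at least
    one cysteine anchor) for diagnostics.
    """

    def __init__(self, message: str, partial: "VDomainNumbering | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass
class VDomainNumbering:
    """Mapping of a V amino-acid sequence onto IMGT unique positions."""

    position_map: dict[str, str]  # IMGT position label -> residue
    anchors: dict[int, bool]  # {23, 41, 89, 104} -> present
    cdr_lengths: tuple[int, int, int]  # CDR1, CDR2, CDR3 germline contribution
    fr_spans: dict[str, tuple[int, int]]
    cdr_spans: dict[str, tuple[int, int]]
    cdr2_deleted: bool = False
    residues_through_104: int = 0  # count of residues up to and including 104
    score: int = 0

    @property
    def cdr1_length(self) -> int:
        return self.cdr_lengths[0]

    @property
    def cdr2_length(self) -> int:
        return self.cdr_lengths[1]


def _cdr_labels(span: tuple[int, int], n: int) -> list[str]:
    """IMGT labels for a CDR loop of n residues within its span.

    Positions fill from both ends toward the loop top (gaps in the middle);
    loops longer than the span get inserted sublabels at the top.
    """
    lo, hi = span
    width = hi - lo + 1
    if n <= width:
        head = (n + 1) // 2
        tail = n - head
        return [str(lo + i) for i in range(head)] + [
            str(hi - tail + 1 + i) for i in range(tail)
        ]
    half = width // 2
    top = lo + half - 1
    extra = n - width
    return (
        [str(lo + i) for i in range(half)]
        + [f"{top}.{j + 1}" for j in range(extra)]
        + [str(lo + half + i) for i in range(width - half)]
    )


def _try_candidate(seq: str, a: int, b: int, deleted: bool) -> VDomainNumbering | None:
    """Evaluate one (CDR1, CDR2) placement; return numbering or None if the CYS
    anchors cannot hold."""
    fr2 = _FR2_DEL_LEN if deleted else _FR2_LEN
    fr3 = _FR3_DEL_LEN if deleted else _FR3_LEN
    total = _FR1_LEN + a + fr2 + b + fr3
    if total > len(seq):
        return None

    def idx_fr3(pos: int) -> int:  # index of an FR3 position
        start = 71 if deleted else 66
        return _FR1_LEN + a + fr2 + b + (pos - start)

    i23 = 22
    i41 = _FR1_LEN + a + 2  # FR2 runs 39,40,41,... in both models
    i89 = idx_fr3(89)
    i104 = idx_fr3(104)
    assert i104 == total - 1

    c23 = seq[i23] == "C"
    c104 = seq[i104] == "C"
    if not (c23 and c104):
        return None
    w41 = seq[i41] == "W"
    h89 = seq[i89] in HYDROPHOBIC_89
    y102 = seq[idx_fr3(102)] == "Y"
    f103 = seq[idx_fr3(103)] == "F"
    score = 4 * (c23 + c104) + 2 * (w41 + h89) + y102 + f103

    # assemble the position map
    position_map: dict[str, str] = {}
    cursor = 0
    for p in range(1, 27):
        position_map[str(p)] = seq[cursor]
        cursor += 1
    for lab in _cdr_labels(CDR1_SPAN, a):
        position_map[lab] = seq[cursor]
        cursor += 1
    fr2_positions = range(39, 55) if deleted else range(39, 56)
    for p in fr2_positions:
        position_map[str(p)] = seq[cursor]
        cursor += 1
    for lab in _cdr_labels(CDR2_SPAN, b):
        position_map[lab] = seq[cursor]
        cursor += 1
    fr3_positions = range(71, 105) if deleted else range(66, 105)
    for p in fr3_positions:
        position_map[str(p)] = seq[cursor]
        cursor += 1
    cdr3_germline = len(seq) - total
    for j in range(cdr3_germline):
        position_map[str(105 + j)] = seq[cursor]
        cursor += 1

    return VDomainNumbering(
        position_map=position_map,
        anchors={23: c23, 41: w41, 89: h89, 104: c104},
        cdr_lengths=(a, 0 if deleted else b, cdr3_germline),
        fr_spans={"FR1": FR1_SPAN, "FR2": FR2_SPAN, "FR3": FR3_SPAN},
        cdr_spans={"CDR1": CDR1_SPAN, "CDR2": CDR2_SPAN},
        cdr2_deleted=deleted,
        residues_through_104=total,
        score=score,
    )


def number_v_domain(aa_seq: str) -> VDomainNumbering:
    """Number a translated V-REGION (leader excluded) onto IMGT positions.

    Enumerates all admissible CDR1/CDR2 length pairs (and the CDR2-deleted
    model), requires both cysteine anchors, and returns the placement with
    the best anchor/motif score.  Ties prefer canonical loop lengths (CDR2
    closest to 3, then CDR1 closest to 9) and the intact-CDR2 model.
    """
    seq = aa_seq.upper().strip("*")
    if not (70 <= len(seq) <= 140):
        raise NumberingError(
            f"V-REGION length {len(seq)} outside the admissible 70-140 aa range"
        )
    candidates: list[VDomainNumbering] = []
    for a in range(0, MAX_CDR1 + 1):
        for b in range(0, MAX_CDR2 + 1):
            cand = _try_candidate(seq, a, b, deleted=False)
            if cand is not None:
                candidates.append(cand)
        cand = _try_candidate(seq, a, 0, deleted=True)
        if cand is not None:
            candidates.append(cand)
    if not candidates:
        raise NumberingError(
            "no cysteine pair in admissible windows: cannot anchor 1st-CYS 23 "
            "and 2nd-CYS 104",
            partial=None,
        )
    candidates.sort(
        key=lambda c: (
            -c.score,
            c.cdr2_deleted,
            abs(c.cdr_lengths[1] - 3),
            abs(c.cdr_lengths[0] - 9),
        )
    )
    return candidates[0]


@dataclass
class VFeatureSet:
    """Classification features of a TRDV gene read off its numbering."""

    cdr1_length: int
    residue_57: str | None  # None encodes "absent"
    trp_107: str  # "present" | "absent" | "not-applicable"
    qxs_motif: bool
    yfc_motif: bool
    cdr2_deleted: bool
    post104_extension: int
    leader_length: int | None = None


def extract_features(
    numbering: VDomainNumbering,
    aa_seq: str,
    leader_aa: str | None = None,
) -> VFeatureSet:
    """Populate the feature set used for TRDV1 set classification.

    ``trp_107`` is computed from the germline residues encoded beyond
    2nd-CYS 104 (position 107 is the third of them) and is
    ``"not-applicable"`` when fewer than three such residues exist.
    """
    seq = aa_seq.upper().strip("*")
    pm = numbering.position_map
    a, b, ext = numbering.cdr_lengths

    residue_57 = pm.get("57") if not numbering.cdr2_deleted else None
    cdr2_residues = "".join(
        pm[lab] for lab in _cdr_labels(CDR2_SPAN, b) if lab in pm
    )
    qxs = any(
        cdr2_residues[i] == "Q" and cdr2_residues[i + 2] == "S"
        for i in range(len(cdr2_residues) - 2)
    )
    yfc = (
        pm.get("102") == "Y" and pm.get("103") == "F" and pm.get("104") == "C"
    )
    post104 = seq[numbering.residues_through_104 :]
    if len(post104) >= 3:
        trp107 = "present" if post104[2] == "W" else "absent"
    else:
        trp107 = "not-applicable"
    return VFeatureSet(
        cdr1_length=a,
        residue_57=residue_57,
        trp_107=trp107,
        qxs_motif=qxs,
        yfc_motif=yfc,
        cdr2_deleted=numbering.cdr2_deleted,
        post104_extension=len(post104),
        leader_length=len(leader_aa) if leader_aa else None,
    )


@dataclass
class FunctionalityCall:
    """IMGT-style functionality label with the rules that triggered it."""

    label: str  # "functional" | "ORF" | "pseudogene"
    reasons: list[str] = field(default_factory=list)


def coding_sequence(gene: GermlineGene) -> str:
    """Spliced coding sequence of a gene from its exon structure.

    Exon coordinates are scaffold coordinates; for minus-orientation genes
    they are mapped onto the stored coding-strand sequence.
    """
    if gene.sequence is None:
        raise ValueError(f"gene {gene.name} has no sequence")
    if not gene.exons:
        return gene.sequence
    parts = []
    exons = sorted(gene.exons, key=lambda e: e[1], reverse=(gene.orientation == "-"))
    for _, estart, eend in exons:
        if gene.orientation == "+":
            rel_start, rel_end = estart - gene.start, eend - gene.start + 1
        else:
            rel_start, rel_end = gene.end - eend, gene.end - estart + 1
        parts.append(gene.sequence[rel_start:rel_end])
    return "".join(parts)


def classify_functionality(
    gene: GermlineGene,
    numbering: VDomainNumbering | None,
    features: VFeatureSet | None,
    post104_orf_threshold: int = 4,
) -> FunctionalityCall:
    """Call a gene functional, ORF or pseudogene.

    Pseudogene: premature stop codon or frameshift (coding length not a
    multiple of 3) in the coding region — such genes are excluded from
    downstream analyses.  ORF: the frame is open but the structure is
    anomalous — CDR2 deleted, the RS displaced so that more than
    ``post104_orf_threshold`` residues are encoded beyond 2nd-CYS 104, loss
    of a non-CYS anchor, or numbering failure.  Otherwise functional.
    """
    reasons: list[str] = []
    coding = coding_sequence(gene)
    if len(coding) % 3 != 0:
        return FunctionalityCall("pseudogene", ["frameshift"])
    aa = str(Seq(coding).translate())
    internal = aa[:-1] if aa.endswith("*") else aa
    if "*" in internal:
        return FunctionalityCall("pseudogene", ["premature-stop"])

    if numbering is None:
        return FunctionalityCall("ORF", ["numbering-failure"])
    if features is not None:
        if features.cdr2_deleted:
            reasons.append("cdr2-deleted")
        if features.post104_extension > post104_orf_threshold:
            reasons.append("post104-extension")
    if not numbering.anchors.get(41, False):
        reasons.append("lost-TRP-41")
    if not numbering.anchors.get(89, False):
        reasons.append("lost-hydrophobic-89")
    if reasons:
        return FunctionalityCall("ORF", reasons)
    return FunctionalityCall("functional", [])
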