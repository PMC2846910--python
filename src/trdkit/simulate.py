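"""Synthetic TRD locus and rearranged-repertoire generator with ground truth.

The generator emits a germline locus whose gene anatomy mirrors the bovine
TRD locus: V genes with a 49-bp L-PART1, an intron and a V-EXON of 271–335
bp followed by a 23-spacer RSS; five D genes of the genomic lengths 13, 15,
13, 9 and 11 nt, each framed by a 5' 12-spacer and 3' 23-spacer RSS; J genes
carrying the F-G-X-G motif behind a 5' 12-spacer RSS; and a single C gene of
1282 coding bp in three exons, optionally followed by one inverted V gene.
V-REGIONs are built on fixed framework scaffolds carrying the IMGT anchors
(1st-CYS 23, Trp 41, Leu 89, 2nd-CYS 104) and the QXS / YFC motifs, so every
emitted V gene numbers cleanly; CDR residues are drawn from a
tryptophan/cysteine-free alphabet so loop placement is unambiguous.

Rearranged transcripts sample a V, an ordered D subset (one to five genes)
and a J; exonuclease trimming, P additions at untrimmed ends and N regions
create the junction.  Every transcript carries a
:class:`RecombinationTruth` record sufficient to reconstruct it byte for
byte, which is what makes the downstream callers testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from trdkit.locus import GeneTable, GermlineGene
from trdkit.junction import VReference

__all__ = [
    "LocusConfig",
    "RearrangementConfig",
    "RecombinationTruth",
    "SyntheticLocus",
    "generate_germline_locus",
    "simulate_rearrangements",
    "make_clean_benchmark",
]

# fixed framework scaffolds (IMGT spans FR1 1-26, FR2 39-55, FR3 66-104)
LEADER_AA = "MAWALLLLPLLSLTGAVHSQ"  # 20-aa conserved leader
FR1_AA = "AQKVTQPQSSVSMSEGDTVTLHCTYS"  # C at position 23
FR2_AA = "LFWYQQKPGQGPQLIIS"  # W at position 41
FR3_AA = "NAKDGRYSVTRSTTSELKIQSAKLSDSAVYSSRTSAYFC"  # L at 89, Y102 F103 C104
CDR_ALPHABET = "GSTNADERKQHY"  # no W/C/F: keeps anchor search unambiguous

_HEPTAMER = "CACAGTG"
_NONAMER = "ACAAAAACC"
_J_F118_BLOCK = "TTTGGACAAGGA"  # F G Q G: J-PHE 118 and the FGXG motif

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for aa in _AA_TO_CODONS:
    _AA_TO_CODONS[aa].sort()


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def _encode(rng: np.random.Generator, aa_seq: str) -> str:
    """Reverse-translate with seeded random synonymous codon choice."""
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in aa_seq
    )


@dataclass
class LocusConfig:
    """Anatomy of the synthetic germline locus."""

    n_v: int = 12
    v_lpart1_len: int = 49
    v_exon_len_range: tuple[int, int] = (271, 335)
    intron_len_range: tuple[int, int] = (80, 150)
    n_d: int = 5
    d_lengths: tuple[int, ...] = (13, 15, 13, 9, 11)  # genomic TRDD span lengths
    d_len_range: tuple[int, int] = (9, 15)
    n_j: int = 3
    c_exon_lengths: tuple[int, ...] = (285, 497, 500)  # coding total 1282 bp
    include_inverted_v: bool = True
    seed: int = 0
    # V-REGION composition
    cdr1_lengths: tuple[int, ...] = (5, 7, 8, 9, 10)
    cdr2_length: int = 3
    post104_lengths: tuple[int, ...] = (3, 4)
    w107_prob: float = 0.5
    residue57_choices: str = "GYENAV"

    def validate(self) -> None:
        if self.n_v < 1 or self.n_j < 1:
            raise ValueError("need at least one V and one J gene")
        if not all(self.d_len_range[0] <= L <= self.d_len_range[1] + 1
                   for L in self.d_lengths):
            # d_len_range is a sanity envelope around the genomic lengths
            pass
        if any(L <= 0 for L in self.d_lengths):
            raise ValueError("D gene lengths must be positive")
        if len(self.d_lengths) != self.n_d:
            raise ValueError("d_lengths must have n_d entries")
        if sum(self.c_exon_lengths) != 1282:
            raise ValueError("C exon lengths must sum to the 1282-bp coding region")
        if min(self.intron_len_range) <= 0:
            raise ValueError("intron lengths must be positive")


@dataclass
class RearrangementConfig:
    """Sampling model for rearranged transcripts."""

    n_transcripts: int = 100
    d_count_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)  # 1..5 D genes
    trim_max: int = 4
    n_mean: float = 4.0  # Poisson mean of N-region lengths ("extensive N-regions")
    p_prob: float = 0.5  # P addition probability at an untrimmed end
    min_d_remain: int = 6  # trims leave at least this many nt of each D
    in_frame: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.d_count_weights or len(self.d_count_weights) > 5:
            raise ValueError("d_count_weights supports 1..5 D genes")
        if not np.isclose(sum(self.d_count_weights), 1.0):
            raise ValueError("d_count_weights must sum to 1")
        if not 0.0 <= self.p_prob <= 1.0:
            raise ValueError("p_prob must be a probability")


@dataclass
class RecombinationTruth:
    """Ground truth for one simulated transcript."""

    name: str
    v_name: str
    j_name: str
    d_names: list[str]
    v_trim: int
    j_trim: int
    d_trims: list[tuple[int, int]]  # (5' trim, 3' trim) per used D
    n_regions: list[str]
    p_regions: list[str]
    cdr3_nt: str
    d_spans: list[tuple[int, int]] = field(default_factory=list)  # within cdr3


@dataclass
class SyntheticLocus:
    """A generated germline locus: scaffold, gene table and lookup helpers."""

    scaffold_name: str
    scaffold: str
    table: GeneTable
    v_refs: list[VReference]
    d_refs: list[tuple[str, str]]  # (name, sequence), genomic order
    j_refs: list[tuple[str, str]]  # (name, full coding body)
    j_heads: dict[str, str]  # J portion preceding J-PHE 118
    config: LocusConfig | None = None

    def to_fasta(self) -> str:
        return f">{self.scaffold_name}\n{self.scaffold}\n"

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())


def _make_v_aa(rng: np.random.Generator, cfg: LocusConfig) -> tuple[str, dict]:
    """Compose one V-REGION amino-acid sequence and its declared anatomy."""
    a = int(rng.choice(cfg.cdr1_lengths))
    b = cfg.cdr2_length
    ext = int(rng.choice(cfg.post104_lengths))
    cdr1 = "".join(rng.choice(list(CDR_ALPHABET), size=a))
    res57 = str(rng.choice(list(cfg.residue57_choices)))
    cdr2 = "Q" + res57 + "S" + "".join(rng.choice(list(CDR_ALPHABET), size=b - 3)) \
        if b >= 3 else "".join(rng.choice(list(CDR_ALPHABET), size=b))
    post = list(rng.choice(list(CDR_ALPHABET), size=ext))
    if ext >= 3:
        post[2] = "W" if rng.random() < cfg.w107_prob else str(
            rng.choice(list(CDR_ALPHABET))
        )
    aa = FR1_AA + cdr1 + FR2_AA + cdr2 + FR3_AA + "".join(post)
    return aa, {"cdr1_len": a, "cdr2_len": b, "post104": ext, "residue57": res57,
                "w107": ext >= 3 and post[2] == "W"}


def _rss(rng: np.random.Generator, spacer: int) -> str:
    return _HEPTAMER + _rand_nt(rng, spacer) + _NONAMER


def _sample_d_sequences(rng: np.random.Generator, cfg: LocusConfig) -> list[str]:
    """Random D genes whose 6-mers are unique within and across genes."""
    for _ in range(1000):
        seqs = [_rand_nt(rng, L) for L in cfg.d_lengths]
        kmers: set[str] = set()
        ok = True
        for s in seqs:
            local = {s[i : i + 6] for i in range(len(s) - 5)}
            if len(local) != len(s) - 5 or local & kmers:
                ok = False
                break
            kmers |= local
        if ok:
            return seqs
    raise RuntimeError("could not sample distinct D gene sequences")


def generate_germline_locus(config: LocusConfig | None = None) -> SyntheticLocus:
    """Emit a synthetic germline scaffold plus its gene table, deterministically.

    Gene cassettes are laid out left to right — V genes, then the D cluster,
    the J genes, the C gene and (optionally) one inverted V downstream of C —
    separated by random intergenic padding.  All RSS are planted canonical.
    """
    cfg = config or LocusConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    scaffold_parts: list[str] = []
    pos = 0  # running 0-based length
    records: list[GermlineGene] = []
    v_refs: list[VReference] = []
    d_refs: list[tuple[str, str]] = []
    j_refs: list[tuple[str, str]] = []
    j_heads: dict[str, str] = {}
    scaffold_name = "sim_locus"

    def emit(s: str) -> int:
        nonlocal pos
        start = pos
        scaffold_parts.append(s)
        pos += len(s)
        return start

    def pad() -> None:
        emit(_rand_nt(rng, int(rng.integers(60, 120))))

    def build_v_cassette(name: str) -> tuple[str, dict]:
        """Return (cassette string, layout dict of offsets within cassette)."""
        aa, meta = _make_v_aa(rng, cfg)
        vregion_nt = _encode(rng, aa)
        leader_nt = _encode(rng, LEADER_AA)
        lpart1 = leader_nt[: cfg.v_lpart1_len]
        lpart2 = leader_nt[cfg.v_lpart1_len :]
        intron_len = int(rng.integers(*cfg.intron_len_range))
        intron = "GT" + _rand_nt(rng, intron_len - 4) + "AG"
        v_exon = lpart2 + vregion_nt
        lo, hi = cfg.v_exon_len_range
        if not lo <= len(v_exon) <= hi:
            raise ValueError(
                f"V-EXON length {len(v_exon)} outside configured range [{lo}, {hi}]"
            )
        cassette = lpart1 + intron + v_exon + _rss(rng, 23)
        layout = {
            "lpart1": (0, len(lpart1)),
            "v_exon": (len(lpart1) + len(intron), len(lpart1) + len(intron) + len(v_exon)),
            "coding_end": len(lpart1) + len(intron) + len(v_exon),
            "meta": meta,
            "vregion_nt": vregion_nt,
            "aa": aa,
        }
        return cassette, layout

    # --- V genes ---
    for i in range(cfg.n_v):
        name = f"simV{i + 1}"
        pad()
        cassette, layout = build_v_cassette(name)
        cstart = emit(cassette)
        l1s, l1e = layout["lpart1"]
        vxs, vxe = layout["v_exon"]
        gene = GermlineGene(
            name=name, gene_type="V", subgroup="simV1",
            scaffold=scaffold_name,
            start=cstart + 1, end=cstart + layout["coding_end"],
            orientation="+",
            exons=[
                ("L-PART1", cstart + l1s + 1, cstart + l1e),
                ("V-EXON", cstart + vxs + 1, cstart + vxe),
            ],
        )
        records.append(gene)
        meta = layout["meta"]
        n104 = 26 + meta["cdr1_len"] + 17 + meta["cdr2_len"] + 39
        v_refs.append(
            VReference(
                name=name, vregion_nt=layout["vregion_nt"],
                n104_codons=n104, subgroup="simV1",
            )
        )

    # --- D genes (5' 12-RSS, body, 3' 23-RSS) ---
    d_seqs = _sample_d_sequences(rng, cfg)
    for i, d_seq in enumerate(d_seqs):
        name = f"simD{i + 1}"
        pad()
        emit(_revcomp(_rss(rng, 12)))  # 5' RSS reads toward the coding start
        dstart = emit(d_seq)
        emit(_rss(rng, 23))
        records.append(
            GermlineGene(
                name=name, gene_type="D", scaffold=scaffold_name,
                start=dstart + 1, end=dstart + len(d_seq), orientation="+",
            )
        )
        d_refs.append((name, d_seq))

    # --- J genes (5' 12-RSS, head, F-G-X-G block, tail) ---
    for i in range(cfg.n_j):
        name = f"simJ{i + 1}"
        pad()
        emit(_revcomp(_rss(rng, 12)))
        head = _rand_nt(rng, int(rng.integers(9, 16)))
        tail = _encode(rng, "".join(rng.choice(list(CDR_ALPHABET), size=5)))
        body = head + _J_F118_BLOCK + tail
        jstart = emit(body)
        records.append(
            GermlineGene(
                name=name, gene_type="J", scaffold=scaffold_name,
                start=jstart + 1, end=jstart + len(body), orientation="+",
            )
        )
        j_refs.append((name, body))
        j_heads[name] = head

    # --- C gene: three exons ---
    pad()
    c_exons: list[tuple[str, int, int]] = []
    c_start = None
    for k, exon_len in enumerate(cfg.c_exon_lengths):
        if k > 0:
            intron_len = int(rng.integers(*cfg.intron_len_range))
            emit("GT" + _rand_nt(rng, intron_len - 4) + "AG")
        estart = emit(_rand_nt(rng, exon_len))
        if c_start is None:
            c_start = estart
        c_exons.append((f"EX{k + 1}", estart + 1, estart + exon_len))
    records.append(
        GermlineGene(
            name="simC", gene_type="C", scaffold=scaffold_name,
            start=c_start + 1, end=c_exons[-1][2], orientation="+",
            exons=c_exons,
        )
    )

    # --- optional inverted V downstream of C ---
    if cfg.include_inverted_v:
        name = f"simV{cfg.n_v + 1}inv"
        pad()
        cassette, layout = build_v_cassette(name)
        rc = _revcomp(cassette)
        cstart = emit(rc)
        clen = len(cassette)
        # coding span within the reverse-complemented cassette
        g_start = cstart + (clen - layout["coding_end"]) + 1
        g_end = cstart + clen
        l1s, l1e = layout["lpart1"]
        vxs, vxe = layout["v_exon"]
        records.append(
            GermlineGene(
                name=name, gene_type="V", subgroup="simV1",
                scaffold=scaffold_name, start=g_start, end=g_end,
                orientation="-",
                exons=[
                    ("L-PART1", cstart + (clen - l1e) + 1, cstart + clen - l1s),
                    ("V-EXON", cstart + (clen - vxe) + 1, cstart + clen - vxs),
                ],
            )
        )
        meta = layout["meta"]
        n104 = 26 + meta["cdr1_len"] + 17 + meta["cdr2_len"] + 39
        v_refs.append(
            VReference(
                name=name, vregion_nt=layout["vregion_nt"],
                n104_codons=n104, subgroup="simV1",
            )
        )
    pad()

    return SyntheticLocus(
        scaffold_name=scaffold_name,
        scaffold="".join(scaffold_parts),
        table=GeneTable(records=records, source="synthetic"),
        v_refs=v_refs,
        d_refs=d_refs,
        j_refs=j_refs,
        j_heads=j_heads,
        config=cfg,
    )


def _trunc_geometric(rng: np.random.Generator, mean: float, max_val: int) -> int:
    """Truncated geometric trim length (support 0..max_val, mean ~ `mean`)."""
    if max_val <= 0:
        return 0
    p = 1.0 / (mean + 1.0)
    val = rng.geometric(p) - 1
    return int(min(val, max_val))


def _assemble_junction(
    rng: np.random.Generator,
    v_ref: VReference,
    d_subset: list[tuple[str, str]],
    j_name: str,
    j_head: str,
    cfg: RearrangementConfig,
    n104: int,
) -> tuple[str, RecombinationTruth] | None:
    """Build one junction; returns (cdr3, truth) with D spans recorded."""
    v_tail = v_ref.post104_nt
    v_trim = _trunc_geometric(rng, 2.0, min(cfg.trim_max, len(v_tail)))
    j_trim = _trunc_geometric(rng, 2.0, min(cfg.trim_max, len(j_head)))
    d_trims: list[tuple[int, int]] = []
    d_frags: list[str] = []
    for _, d_seq in d_subset:
        budget = max(len(d_seq) - cfg.min_d_remain, 0)
        t5 = _trunc_geometric(rng, 2.0, min(cfg.trim_max, budget))
        t3 = _trunc_geometric(rng, 2.0, min(cfg.trim_max, budget - t5))
        d_trims.append((t5, t3))
        d_frags.append(d_seq[t5 : len(d_seq) - t3])

    p_regions: list[str] = []

    def maybe_p(seq_end: str, five_prime: bool) -> str:
        """P addition at an untrimmed end: revcomp of the terminal nucleotides."""
        if rng.random() >= cfg.p_prob:
            return ""
        k = int(rng.integers(1, 3))
        p = _revcomp(seq_end[:k]) if five_prime else _revcomp(seq_end[-k:])
        if p:
            p_regions.append(p)
        return p

    # tagged pieces so the frame-padding below can extend the right N region
    pieces: list[tuple[str, str]] = []
    pieces.append(("V", v_tail[: len(v_tail) - v_trim]))
    if v_trim == 0 and v_tail:
        pieces.append(("P", maybe_p(v_tail, five_prime=False)))
    for (d_name, d_seq), (t5, t3), frag in zip(d_subset, d_trims, d_frags):
        pieces.append(("N", _rand_nt(rng, int(rng.poisson(cfg.n_mean)))))
        if t5 == 0:
            pieces.append(("P", maybe_p(d_seq, five_prime=True)))
        pieces.append((f"D:{d_name}", frag))
        if t3 == 0:
            pieces.append(("P", maybe_p(d_seq, five_prime=False)))
    pieces.append(("N", _rand_nt(rng, int(rng.poisson(cfg.n_mean)))))
    if j_trim == 0 and j_head:
        pieces.append(("P", maybe_p(j_head, five_prime=True)))
    pieces.append(("J", j_head[j_trim:]))

    if cfg.in_frame:
        total = sum(len(text) for _, text in pieces)
        extra = (3 - total % 3) % 3
        if extra:
            # extend the D-J N region so J-PHE 118 stays in frame
            last_n = max(i for i, (tag, _) in enumerate(pieces) if tag == "N")
            pieces[last_n] = ("N", pieces[last_n][1] + _rand_nt(rng, extra))

    n_regions = [text for tag, text in pieces if tag == "N"]
    cdr3_parts: list[str] = []
    d_spans: list[tuple[int, int]] = []
    offset = 0
    for tag, text in pieces:
        if tag.startswith("D:"):
            d_spans.append((offset, offset + len(text)))
        cdr3_parts.append(text)
        offset += len(text)
    cdr3 = "".join(cdr3_parts)

    truth = RecombinationTruth(
        name="", v_name=v_ref.name, j_name=j_name,
        d_names=[d for d, _ in d_subset],
        v_trim=v_trim, j_trim=j_trim, d_trims=d_trims,
        n_regions=n_regions, p_regions=p_regions,
        cdr3_nt=cdr3, d_spans=d_spans,
    )
    return cdr3, truth


def _transcript_from_cdr3(
    v_ref: VReference, cdr3: str, j_name: str, j_refs: dict[str, str],
    j_heads: dict[str, str], j_trim: int,
) -> str:
    j_body = j_refs[j_name]
    j_suffix = j_body[len(j_heads[j_name]) :]  # F118 block onward
    return v_ref.vregion_nt[: 3 * v_ref.n104_codons] + cdr3 + j_suffix


def simulate_rearrangements(
    locus: SyntheticLocus,
    cfg: RearrangementConfig | None = None,
) -> tuple[list[tuple[str, str]], list[RecombinationTruth]]:
    """Sample rearranged transcripts with full per-transcript ground truth.

    One RNG stream per transcript (split by index from the config seed), so
    increasing ``n_transcripts`` never perturbs earlier transcripts.
    """
    cfg = cfg or RearrangementConfig()
    cfg.validate()
    if len(locus.d_refs) < len(cfg.d_count_weights):
        raise ValueError(
            f"d_count_weights implies up to {len(cfg.d_count_weights)} D genes "
            f"but the locus has only {len(locus.d_refs)}"
        )
    transcripts: list[tuple[str, str]] = []
    truths: list[RecombinationTruth] = []
    j_ref_map = dict(locus.j_refs)
    for i in range(cfg.n_transcripts):
        rng = np.random.default_rng([cfg.seed, i])
        v_ref = locus.v_refs[rng.integers(len(locus.v_refs))]
        j_idx = int(rng.integers(len(locus.j_refs)))
        j_name = locus.j_refs[j_idx][0]
        d_count = int(rng.choice(np.arange(1, len(cfg.d_count_weights) + 1),
                                 p=cfg.d_count_weights))
        d_idx = sorted(rng.choice(len(locus.d_refs), size=d_count, replace=False))
        d_subset = [locus.d_refs[k] for k in d_idx]
        name = f"tx{i:05d}"
        for _attempt in range(200):
            cdr3, truth = _assemble_junction(
                rng, v_ref, d_subset, j_name, locus.j_heads[j_name], cfg,
                v_ref.n104_codons,
            )
            tx = _transcript_from_cdr3(
                v_ref, cdr3, j_name, j_ref_map, locus.j_heads, truth.j_trim
            )
            if not cfg.in_frame or _frame_boundary_ok(tx, v_ref, cdr3):
                break
        truth.name = name
        transcripts.append((name, tx))
        truths.append(truth)
    return transcripts, truths


def _frame_boundary_ok(tx: str, v_ref: VReference, cdr3: str) -> bool:
    """True when the first in-frame F/W-G-X-G downstream of 104 is J-PHE 118."""
    n104 = v_ref.n104_codons
    usable = tx[: len(tx) - len(tx) % 3]
    aa = str(Seq(usable).translate())
    true_phe = n104 + len(cdr3) // 3
    for i in range(n104, len(aa) - 3):
        if aa[i] in "FW" and aa[i + 1] == "G" and aa[i + 3] == "G":
            return i == true_phe
    return False


def _clean_cdr3_ok(
    cdr3: str, d_refs: list[tuple[str, str]], truth: RecombinationTruth,
    min_d_match: int = 6,
) -> bool:
    """Structural cleanliness: every D 6-mer in the junction lies inside the
    planted fragment of that same gene, and no planted fragment is extensible
    into its flanks.  Independent of the D caller."""
    span_by_name = dict(zip(truth.d_names, truth.d_spans))
    for d_name, d_seq in d_refs:
        for i in range(len(cdr3) - min_d_match + 1):
            w = cdr3[i : i + min_d_match]
            if w in d_seq:
                span = span_by_name.get(d_name)
                if span is None or not (span[0] <= i and i + min_d_match <= span[1]):
                    return False
    d_map = dict(d_refs)
    for d_name, (t5, t3), (qs, qe) in zip(truth.d_names, truth.d_trims, truth.d_spans):
        d_seq = d_map[d_name]
        if t5 > 0 and qs > 0 and cdr3[qs - 1] == d_seq[t5 - 1]:
            return False
        if t3 > 0 and qe < len(cdr3) and cdr3[qe] == d_seq[len(d_seq) - t3]:
            return False
    return True


def make_clean_benchmark(
    locus: SyntheticLocus,
    n: int,
    seed: int,
    max_attempts: int = 200,
) -> tuple[list[tuple[str, str]], list[RecombinationTruth]]:
    """Benchmark repertoire where planted D usage is recoverable by construction.

    P additions are disabled and N regions are rejection-sampled so that no
    spurious D 6-mer appears outside a planted fragment and no fragment is
    extensible; every planted fragment retains at least six nucleotides.
    """
    cfg = RearrangementConfig(
        n_transcripts=1, p_prob=0.0, min_d_remain=6, seed=seed
    )
    transcripts: list[tuple[str, str]] = []
    truths: list[RecombinationTruth] = []
    j_ref_map = dict(locus.j_refs)
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        d_count = int(rng.integers(1, len(locus.d_refs) + 1))
        ok = False
        for _attempt in range(max_attempts):
            # gene choices are inside the loop: a V tail or J head that itself
            # contains a D 6-mer can only be escaped by redrawing the genes
            v_ref = locus.v_refs[rng.integers(len(locus.v_refs))]
            j_idx = int(rng.integers(len(locus.j_refs)))
            j_name = locus.j_refs[j_idx][0]
            d_idx = sorted(rng.choice(len(locus.d_refs), size=d_count, replace=False))
            d_subset = [locus.d_refs[k] for k in d_idx]
            cdr3, truth = _assemble_junction(
                rng, v_ref, d_subset, j_name, locus.j_heads[j_name], cfg,
                v_ref.n104_codons,
            )
            tx = _transcript_from_cdr3(
                v_ref, cdr3, j_name, j_ref_map, locus.j_heads, truth.j_trim
            )
            if _clean_cdr3_ok(cdr3, locus.d_refs, truth) and _frame_boundary_ok(
                tx, v_ref, cdr3
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"rejection sampling failed for junction {i} after "
                f"{max_attempts} attempts; lower n_mean or trim_max"
            )
        truth.name = f"bm{i:05d}"
        transcripts.append((truth.name, tx))
        truths.append(truth)
    return transcripts, truths
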