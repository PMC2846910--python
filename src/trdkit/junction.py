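"""CDR3 junction analysis: V assignment, multi-TRDD calling, P/N annotation.

A rearranged TRD transcript is assigned to its germline V gene by ungapped
comparison over the V-REGION (six or fewer nucleotide differences, no ties).
The CDR3 spans IMGT codons 105–117, between 2nd-CYS 104 and J-PHE 118 of the
F/W-G-X-G motif.  Within the CDR3, usage of a diversity gene is claimed only
when at least six contiguous nucleotides of that gene are present, and only
combinations whose order matches the genomic TRDD order are retained — both
criteria taken from junction analysis practice for loci where one to five D
genes can be incorporated into a single rearrangement.  Leftover nucleotides
are palindromic P additions (at untrimmed germline ends, up to 2 nt, reverse
complement of the adjacent germline terminus) or non-templated N additions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from trdkit.locus import GermlineGene

__all__ = [
    "JunctionConfig",
    "VReference",
    "VAssignment",
    "Segment",
    "JunctionAnnotation",
    "assign_germline_v",
    "extract_cdr3",
    "call_trdd_usage",
    "call_trdd_usage_exhaustive",
    "annotate_np_regions",
    "summarize_d_usage",
    "d_usage_percentages",
]


@dataclass(frozen=True)
class JunctionConfig:
    """Thresholds governing junction interpretation."""

    min_d_match: int = 6  # minimum contiguous nt to claim D usage
    max_v_mismatch: int = 6  # max nt differences for a germline V assignment
    max_p_len: int = 2  # classic P-nucleotide length per end
    rounding: str = "half-up"  # usage-percentage rounding: "half-up" | "truncate"

    def __post_init__(self) -> None:
        if self.min_d_match < 1:
            raise ValueError("min_d_match must be >= 1")


DEFAULT_CONFIG = JunctionConfig()


@dataclass
class VReference:
    """Germline V reference for transcript assignment.

    ``vregion_nt`` is the V-REGION nucleotide sequence starting at codon 1
    (leader excluded) and running through the last germline-encoded residue
    before the RS; ``n104_codons`` counts codons up to and including
    2nd-CYS 104.
    """

    name: str
    vregion_nt: str
    n104_codons: int
    subgroup: str = ""

    @property
    def post104_nt(self) -> str:
        """Germline nucleotides encoded beyond 2nd-CYS 104 (the V 3' tail)."""
        return self.vregion_nt[3 * self.n104_codons :]


@dataclass
class VAssignment:
    query: str
    gene: str | None
    mismatches: int | None
    ties: list[str] = field(default_factory=list)
    set_id: int | None = None

    @property
    def assigned(self) -> bool:
        return self.gene is not None


def assign_germline_v(
    cdna: str,
    germline: Sequence[VReference],
    config: JunctionConfig = DEFAULT_CONFIG,
    query_name: str = "",
) -> VAssignment:
    """Assign a cDNA to its closest germline V gene by ungapped comparison.

    The comparison runs over the germline V-REGION through position 104.
    More than ``max_v_mismatch`` differences, or a tie between equally close
    genes, leaves the query unassigned (with diagnostics).
    """
    cdna = cdna.upper()
    if len(cdna) < 150:
        raise ValueError(
            f"cDNA {query_name or '<unnamed>'} is {len(cdna)} nt; "
            "need at least 150 nt covering the V-REGION"
        )
    scored: list[tuple[int, str]] = []
    for ref in germline:
        span = min(3 * ref.n104_codons, len(cdna))
        mm = sum(a != b for a, b in zip(cdna[:span], ref.vregion_nt[:span]))
        mm += max(0, 3 * ref.n104_codons - len(cdna))  # uncovered positions count
        scored.append((mm, ref.name))
    scored.sort()
    best_mm, best_name = scored[0]
    ties = [name for mm, name in scored[1:] if mm == best_mm]
    if best_mm > config.max_v_mismatch:
        return VAssignment(query=query_name, gene=None, mismatches=best_mm)
    if ties:
        return VAssignment(
            query=query_name, gene=None, mismatches=best_mm,
            ties=[best_name] + ties,
        )
    return VAssignment(query=query_name, gene=best_name, mismatches=best_mm)


@dataclass
class Segment:
    """One tiled piece of a CDR3: V3', P, N, a D fragment, or J5'."""

    kind: str  # "V3'" | "P" | "N" | "D" | "J5'"
    source: str | None  # gene name for V3'/D/J5', None for N; adjacent gene for P
    start: int  # 0-based within cdr3_nt
    end: int  # exclusive
    matched_len: int = 0
    germ_start: int | None = None  # for D: 0-based offset within the germline D
    germ_end: int | None = None


@dataclass
class JunctionAnnotation:
    """A CDR3 segmented into V3'/P/N/D.../J5' parts with ordered D calls."""

    query: str
    cdr3_nt: str
    cdr3_aa_length: int
    v_gene: str | None = None
    j_gene: str | None = None
    subgroup: str = ""
    segments: list[Segment] = field(default_factory=list)
    d_calls: list[str] = field(default_factory=list)
    ambiguous_d: list[str] = field(default_factory=list)

    def segment_string(self) -> str:
        parts = []
        for s in self.segments:
            parts.append(s.source if s.kind == "D" else s.kind)
        return "|".join(parts)


class JunctionBoundaryError(ValueError):
    pass


def extract_cdr3(
    cdna: str,
    v_ref: VReference,
    j_refs: Sequence[tuple[str, str]],
    query_name: str = "",
) -> JunctionAnnotation:
    """Extract the CDR3 (IMGT codons 105–117) from an assigned transcript.

    The 3' boundary is J-PHE 118, located as the first in-frame F/W-G-X-G
    motif downstream of codon 104.  The J gene is identified by best suffix
    match of the transcript against the germline J sequences.
    """
    cdna = cdna.upper()
    n104 = v_ref.n104_codons
    usable = cdna[: len(cdna) - len(cdna) % 3]
    aa = str(Seq(usable).translate())
    phe = None
    for i in range(n104, len(aa) - 3):
        if aa[i] in "FW" and aa[i + 1] == "G" and aa[i + 3] == "G":
            phe = i
            break
    if phe is None:
        raise JunctionBoundaryError(
            f"junction boundary not found for {query_name or '<unnamed>'}: "
            "no in-frame F/W-G-X-G motif downstream of position 104"
        )
    cdr3_nt = cdna[3 * n104 : 3 * phe]
    best_j = None
    for j_name, j_seq in j_refs:
        j_seq = j_seq.upper()
        k = min(len(cdna), len(j_seq))
        mm = sum(a != b for a, b in zip(cdna[-k:], j_seq[-k:]))
        cand = (mm, j_name)
        if best_j is None or cand < best_j:
            best_j = cand
    return JunctionAnnotation(
        query=query_name,
        cdr3_nt=cdr3_nt,
        cdr3_aa_length=phe - n104,
        v_gene=v_ref.name,
        j_gene=best_j[1] if best_j else None,
        subgroup=v_ref.subgroup,
    )


def _d_sequences(d_genes: Sequence) -> list[tuple[str, str]]:
    """Normalize D-gene input to [(name, sequence)] in genomic order."""
    out = []
    for d in d_genes:
        if isinstance(d, GermlineGene):
            if d.sequence is None:
                raise ValueError(f"D gene {d.name} has no sequence")
            out.append((d.name, d.sequence.upper()))
        else:
            name, seq = d
            out.append((name, seq.upper()))
    return out


def _candidate_fragments(
    cdr3: str, d_list: list[tuple[str, str]], min_len: int
) -> list[dict]:
    """All exact matches of contiguous D-gene fragments (>= min_len nt).

    Each candidate records every admissible germline offset; when the same
    query window matches more than one D gene, each match is kept (order
    constraints and tie-breaking decide later) and flagged as a collision.
    """
    frags = []
    window_owners: dict[tuple[int, int], set[int]] = {}
    for d_idx, (d_name, d_seq) in enumerate(d_list):
        for qstart in range(len(cdr3)):
            for length in range(min_len, min(len(d_seq), len(cdr3) - qstart) + 1):
                sub = cdr3[qstart : qstart + length]
                offsets = [
                    k for k in range(len(d_seq) - length + 1)
                    if d_seq[k : k + length] == sub
                ]
                if not offsets:
                    break  # longer windows at this qstart cannot match either
                frags.append(
                    {
                        "d_idx": d_idx,
                        "d_name": d_name,
                        "qstart": qstart,
                        "qend": qstart + length,
                        "length": length,
                        "offsets": offsets,
                    }
                )
                window_owners.setdefault((qstart, length), set()).add(d_idx)
    for f in frags:
        owners = window_owners[(f["qstart"], f["length"])]
        f["collision"] = len(owners) > 1
    return frags


def _chain_key(chain: list[dict]) -> tuple:
    """Selection objective: max total matched nt, fewest segments, leftmost,
    lowest genomic indices."""
    total = sum(f["length"] for f in chain)
    return (
        -total,
        len(chain),
        tuple(f["qstart"] for f in chain),
        tuple(f["d_idx"] for f in chain),
    )


def call_trdd_usage(
    cdr3_nt: str,
    d_genes: Sequence,
    config: JunctionConfig = DEFAULT_CONFIG,
    annotation: JunctionAnnotation | None = None,
) -> JunctionAnnotation:
    """Call ordered TRDD usage within a CDR3.

    Finds exact contiguous matches of length >= ``min_d_match`` to each
    germline D gene and selects the non-overlapping subset whose genomic
    order is strictly increasing, maximizing total matched nucleotides
    (ties: fewer segments, then leftmost, then lower genomic indices).  Each
    D gene is used at most once.  Unmatched stretches are provisionally
    labeled N; :func:`annotate_np_regions` refines them into V3'/P/N/J5'.
    """
    cdr3 = cdr3_nt.upper()
    d_list = _d_sequences(d_genes)
    frags = _candidate_fragments(cdr3, d_list, config.min_d_match)
    frags.sort(key=lambda f: (f["qstart"], f["qend"], f["d_idx"]))

    # chain DP: best chain ending at each fragment
    best_chain: list[list[dict]] = []
    for i, f in enumerate(frags):
        best = [f]
        for j in range(i):
            g = frags[j]
            if g["qend"] <= f["qstart"] and g["d_idx"] < f["d_idx"]:
                cand = best_chain[j] + [f]
                if _chain_key(cand) < _chain_key(best):
                    best = cand
        best_chain.append(best)
    chosen: list[dict] = []
    for chain in best_chain:
        if not chosen or _chain_key(chain) < _chain_key(chosen):
            chosen = chain

    if annotation is None:
        annotation = JunctionAnnotation(
            query="", cdr3_nt=cdr3, cdr3_aa_length=len(cdr3) // 3
        )
    annotation.d_calls = [f["d_name"] for f in chosen]
    annotation.ambiguous_d = sorted(
        {f["d_name"] for f in chosen if f["collision"]}
    )
    segments: list[Segment] = []
    cursor = 0
    for f in chosen:
        if f["qstart"] > cursor:
            segments.append(Segment("N", None, cursor, f["qstart"]))
        # canonical germline placement: prefer an untrimmed end, else leftmost
        offsets = f["offsets"]
        d_len = len(d_list[f["d_idx"]][1])
        ranked = sorted(
            offsets,
            key=lambda k: (not (k == 0 or k + f["length"] == d_len), k),
        )
        off = ranked[0]
        segments.append(
            Segment(
                "D", f["d_name"], f["qstart"], f["qend"],
                matched_len=f["length"], germ_start=off, germ_end=off + f["length"],
            )
        )
        cursor = f["qend"]
    if cursor < len(cdr3):
        segments.append(Segment("N", None, cursor, len(cdr3)))
    annotation.segments = segments
    return annotation


def call_trdd_usage_exhaustive(
    cdr3_nt: str,
    d_genes: Sequence,
    config: JunctionConfig = DEFAULT_CONFIG,
) -> list[str]:
    """Reference D caller by exhaustive enumeration of ordered subsets.

    Enumerates, per D gene, every candidate fragment (or skipping the gene),
    takes the product across genes in genomic order, filters combinations to
    non-overlapping, position-increasing ones, and scores each with the same
    objective as :func:`call_trdd_usage`.  Intended as an independent check
    on small junctions; cost grows multiplicatively with junction length.
    """
    cdr3 = cdr3_nt.upper()
    d_list = _d_sequences(d_genes)
    per_gene: list[list[dict | None]] = []
    for d_idx, (d_name, d_seq) in enumerate(d_list):
        opts: list[dict | None] = [None]
        for qstart in range(len(cdr3)):
            for qend in range(qstart + config.min_d_match, len(cdr3) + 1):
                sub = cdr3[qstart:qend]
                if len(sub) <= len(d_seq) and sub in d_seq:
                    opts.append(
                        {"d_idx": d_idx, "d_name": d_name,
                         "qstart": qstart, "qend": qend, "length": qend - qstart}
                    )
        per_gene.append(opts)
    best_key, best_calls = None, []
    for combo in itertools.product(*per_gene):
        chain = [f for f in combo if f is not None]
        ok = all(
            chain[i]["qend"] <= chain[i + 1]["qstart"]
            for i in range(len(chain) - 1)
        )
        if not ok:
            continue
        key = _chain_key(chain)
        if best_key is None or key < best_key:
            best_key = key
            best_calls = [f["d_name"] for f in chain]
    return best_calls


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def annotate_np_regions(
    annotation: JunctionAnnotation,
    d_genes: Sequence,
    v_ref: VReference | None = None,
    j_head: str | None = None,
    config: JunctionConfig = DEFAULT_CONFIG,
) -> JunctionAnnotation:
    """Refine provisional N stretches into V3', P and N segments (and J5').

    V3' is the longest CDR3 prefix matching the germline V tail beyond
    2nd-CYS 104; J5' the longest suffix matching the 3' end of the germline
    J region preceding J-PHE 118 (``j_head``).  At every untrimmed germline
    end — a D fragment reaching its germline terminus, a complete V tail, or
    a complete J head — up to ``max_p_len`` adjacent unassigned nucleotides
    equal to the reverse complement of the terminal germline nucleotides are
    labeled P (ambiguity between P and N resolves in favor of P).  Everything
    else left unassigned is N.
    """
    cdr3 = annotation.cdr3_nt
    d_map = dict(_d_sequences(d_genes))
    n = len(cdr3)
    owner: list[Segment | None] = [None] * n
    d_segments = [s for s in annotation.segments if s.kind == "D"]
    for s in d_segments:
        for i in range(s.start, s.end):
            owner[i] = s

    new_segments: list[Segment] = list(d_segments)

    # V 3' germline continuation
    v_tail = v_ref.post104_nt.upper() if v_ref is not None else ""
    v3_len = 0
    if v_tail:
        limit = d_segments[0].start if d_segments else n
        while (
            v3_len < min(len(v_tail), limit)
            and cdr3[v3_len] == v_tail[v3_len]
        ):
            v3_len += 1
        if v3_len:
            seg = Segment("V3'", v_ref.name, 0, v3_len, matched_len=v3_len)
            new_segments.append(seg)
            for i in range(v3_len):
                owner[i] = seg

    # J 5' germline portion
    j5_len = 0
    if j_head:
        j_head = j_head.upper()
        limit = n - (d_segments[-1].end if d_segments else 0)
        while (
            j5_len < min(len(j_head), limit)
            and cdr3[n - 1 - j5_len] == j_head[len(j_head) - 1 - j5_len]
        ):
            j5_len += 1
        if j5_len:
            seg = Segment(
                "J5'", annotation.j_gene, n - j5_len, n, matched_len=j5_len
            )
            new_segments.append(seg)
            for i in range(n - j5_len, n):
                owner[i] = seg

    def _claim_p(start: int, end: int, source: str) -> None:
        for i in range(start, end):
            if owner[i] is not None:
                return
        seg = Segment("P", source, start, end, matched_len=end - start)
        new_segments.append(seg)
        for i in range(start, end):
            owner[i] = seg

    # P nucleotides at untrimmed ends, longest admissible first
    for s in d_segments:
        d_seq = d_map[s.source]
        if s.germ_start == 0:  # untrimmed 5' end
            for k in range(config.max_p_len, 0, -1):
                if s.start - k >= 0 and cdr3[s.start - k : s.start] == _revcomp(
                    d_seq[:k]
                ):
                    _claim_p(s.start - k, s.start, s.source)
                    break
        if s.germ_end == len(d_seq):  # untrimmed 3' end
            for k in range(config.max_p_len, 0, -1):
                if s.end + k <= n and cdr3[s.end : s.end + k] == _revcomp(
                    d_seq[-k:]
                ):
                    _claim_p(s.end, s.end + k, s.source)
                    break
    if v_tail and v3_len == len(v_tail) and v_ref is not None:
        for k in range(config.max_p_len, 0, -1):
            if v3_len + k <= n and cdr3[v3_len : v3_len + k] == _revcomp(
                v_tail[-k:]
            ):
                _claim_p(v3_len, v3_len + k, v_ref.name)
                break
    if j_head and j5_len == len(j_head):
        jstart = n - j5_len
        for k in range(config.max_p_len, 0, -1):
            if jstart - k >= 0 and cdr3[jstart - k : jstart] == _revcomp(
                j_head[:k]
            ):
                _claim_p(jstart - k, jstart, annotation.j_gene or "J")
                break

    # remaining unassigned nucleotides are N
    i = 0
    while i < n:
        if owner[i] is None:
            j = i
            while j < n and owner[j] is None:
                j += 1
            new_segments.append(Segment("N", None, i, j))
            i = j
        else:
            i += 1
    new_segments.sort(key=lambda s: s.start)
    annotation.segments = new_segments
    return annotation


_ROUND_MODES = {"half-up", "truncate"}


def _round1(value: float, mode: str) -> float:
    if mode == "half-up":
        return float(Decimal(str(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    if mode == "truncate":
        return int(value * 10) / 10.0
    raise ValueError(f"unknown rounding mode {mode!r}")


def d_usage_percentages(
    counts: Mapping[str, int], rounding: str = "half-up"
) -> dict[str, float]:
    """Percentages of all D occurrences, rounded to 1 decimal."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: _round1(100.0 * v / total, rounding) for k, v in counts.items()}


def summarize_d_usage(
    annotations: Iterable[JunctionAnnotation],
    d_names: Sequence[str] | None = None,
    rounding: str = "half-up",
) -> pd.DataFrame:
    """Tabulate D usage per V subgroup: counts and percentage of all D calls.

    One row per subgroup with the number of sequences evaluated and, per D
    gene, the occurrence count and its percentage of all D occurrences in
    that subgroup (1 decimal).
    """
    annotations = list(annotations)
    if d_names is None:
        d_names = sorted({d for a in annotations for d in a.d_calls})
    rows = {}
    for a in annotations:
        key = a.subgroup or "unknown"
        rows.setdefault(key, {"n": 0, "counts": {d: 0 for d in d_names}})
        rows[key]["n"] += 1
        for d in a.d_calls:
            rows[key]["counts"].setdefault(d, 0)
            rows[key]["counts"][d] += 1
    out = []
    for subgroup in sorted(rows):
        rec = {"subgroup": subgroup, "sequences_evaluated": rows[subgroup]["n"]}
        pct = d_usage_percentages(rows[subgroup]["counts"], rounding)
        for d in d_names:
            rec[f"{d}_count"] = rows[subgroup]["counts"].get(d, 0)
            rec[f"{d}_pct"] = pct.get(d, 0.0)
        out.append(rec)
    if not out:
        return pd.DataFrame(
            columns=["subgroup", "sequences_evaluated"]
        ).set_index("subgroup")
    return pd.DataFrame(out).set_index("subgroup")
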