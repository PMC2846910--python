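"""Recombination signal sequence (RSS) detection and conservation matrices.

An RSS is a conserved heptamer and nonamer separated by a 12-bp spacer (5' of
D and J genes) or a 23-bp spacer (3' of V and D genes).  All matching here is
performed reading *away from the coding end* on the coding strand, so the
single consensus heptamer ``CACAGTG`` / nonamer ``ACAAAAACC`` serves both
sides: a 5' RSS is scored on the reverse complement of the upstream flank.

The first three heptamer positions (``CAC``) are required exactly — they are
critical for recombination — while the remaining heptamer and the nonamer
tolerate a configurable number of mismatches (nonamer conservation is known
to be less rigid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2

import numpy as np

from Bio.Seq import Seq

from trdkit.locus import GermlineGene

__all__ = [
    "RSSConsensus",
    "RSSMatch",
    "ConservationMatrix",
    "score_rss_window",
    "scan_sequence",
    "find_flanking_rss",
    "conservation_matrix",
]


@dataclass(frozen=True)
class RSSConsensus:
    """Consensus model and acceptance thresholds for RSS scoring."""

    heptamer: str = "CACAGTG"
    nonamer: str = "ACAAAAACC"
    mandatory_prefix: str = "CAC"
    max_heptamer_mismatches: int = 2  # in positions 4-7, beyond the CAC rule
    max_nonamer_mismatches: int = 3
    spacer_tolerance: int = 1

    def __post_init__(self) -> None:
        if not self.heptamer.startswith(self.mandatory_prefix):
            raise ValueError("mandatory_prefix must be a prefix of the heptamer")


DEFAULT_CONSENSUS = RSSConsensus()


@dataclass
class RSSMatch:
    """A scored heptamer–spacer–nonamer hit."""

    gene_name: str
    side: str  # one of {"3'V", "5'D", "3'D", "5'J", ""}
    spacer_class: int  # 12 or 23
    observed_spacer_len: int
    heptamer_seq: str
    nonamer_seq: str
    heptamer_mismatches: int
    nonamer_mismatches: int
    position: int  # 1-based heptamer start on the strand that was scanned

    @property
    def total_mismatches(self) -> int:
        return self.heptamer_mismatches + self.nonamer_mismatches


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def score_rss_window(
    window: str,
    spacer_class: int,
    consensus: RSSConsensus = DEFAULT_CONSENSUS,
    gene_name: str = "",
    side: str = "",
    position: int = 1,
) -> RSSMatch | None:
    """Score one candidate window (heptamer + spacer + nonamer) against the consensus.

    The window must read away from the coding end.  Returns an
    :class:`RSSMatch` on acceptance, ``None`` on rejection.  Window lengths
    implying a spacer outside ``spacer_class ± tolerance`` are an error.
    """
    if spacer_class not in (12, 23):
        raise ValueError(f"spacer_class must be 12 or 23, got {spacer_class}")
    window = window.upper()
    spacer_len = len(window) - len(consensus.heptamer) - len(consensus.nonamer)
    if abs(spacer_len - spacer_class) > consensus.spacer_tolerance:
        raise ValueError(
            f"window of impossible length {len(window)} for spacer class "
            f"{spacer_class} (implies spacer {spacer_len})"
        )
    hept = window[: len(consensus.heptamer)]
    nona = window[len(consensus.heptamer) + spacer_len :]
    k = len(consensus.mandatory_prefix)
    if hept[:k] != consensus.mandatory_prefix:
        return None
    hept_mm = _hamming(hept[k:], consensus.heptamer[k:])
    nona_mm = _hamming(nona, consensus.nonamer)
    if hept_mm > consensus.max_heptamer_mismatches:
        return None
    if nona_mm > consensus.max_nonamer_mismatches:
        return None
    return RSSMatch(
        gene_name=gene_name,
        side=side,
        spacer_class=spacer_class,
        observed_spacer_len=spacer_len,
        heptamer_seq=hept,
        nonamer_seq=nona,
        heptamer_mismatches=hept_mm,
        nonamer_mismatches=nona_mm,
        position=position,
    )


def scan_sequence(
    seq: str,
    spacer_class: int,
    consensus: RSSConsensus = DEFAULT_CONSENSUS,
) -> list[RSSMatch]:
    """Exhaustively scan every window of ``seq`` for accepted RSS matches.

    All spacer lengths within the tolerance are tried at every offset.
    Matches are reported with 1-based heptamer start positions, sorted by
    position then mismatch count.
    """
    seq = seq.upper()
    matches: list[RSSMatch] = []
    for spacer in range(
        spacer_class - consensus.spacer_tolerance,
        spacer_class + consensus.spacer_tolerance + 1,
    ):
        wlen = len(consensus.heptamer) + spacer + len(consensus.nonamer)
        for i in range(len(seq) - wlen + 1):
            m = score_rss_window(
                seq[i : i + wlen], spacer_class, consensus, position=i + 1
            )
            if m is not None:
                matches.append(m)
    matches.sort(key=lambda m: (m.position, m.total_mismatches))
    return matches


# sides mandated per gene type: (side label, spacer class, 3'-of-gene?)
_MANDATED_SIDES = {
    "V": [("3'V", 23, True)],
    "D": [("5'D", 12, False), ("3'D", 23, True)],
    "J": [("5'J", 12, False)],
}


def find_flanking_rss(
    gene: GermlineGene,
    context: str,
    gene_span: tuple[int, int] | None = None,
    consensus: RSSConsensus = DEFAULT_CONSENSUS,
    warn: bool = True,
) -> list[RSSMatch]:
    """Locate the RSS flanking a gene on its mandated sides.

    ``context`` is coding-strand sequence containing the gene;  ``gene_span``
    gives the gene's 1-based inclusive span within ``context`` (defaults to
    the whole string, i.e. context == gene body is not useful — pass flanks).
    The heptamer must abut the coding end: only windows starting immediately
    beyond the gene end (3' side) or ending immediately before the gene start
    (5' side, scored on the reverse complement) are considered.  The
    best-scoring spacer length within tolerance is kept per side.
    """
    import warnings as _warnings

    if gene.gene_type not in _MANDATED_SIDES:
        return []
    if gene_span is None:
        gene_span = (1, len(context))
    gstart, gend = gene_span
    context = context.upper()
    results: list[RSSMatch] = []
    for side, spacer_class, three_prime in _MANDATED_SIDES[gene.gene_type]:
        candidates: list[RSSMatch] = []
        for spacer in range(
            spacer_class - consensus.spacer_tolerance,
            spacer_class + consensus.spacer_tolerance + 1,
        ):
            wlen = len(consensus.heptamer) + spacer + len(consensus.nonamer)
            if three_prime:
                # window begins right after the coding end, read forward
                wstart = gend  # 0-based index of first nt after gene end
                window = context[wstart : wstart + wlen]
                pos = wstart + 1
            else:
                # window ends right before the coding start; normalize strand
                wend = gstart - 1  # 0-based exclusive end of upstream flank
                if wend - wlen < 0:
                    continue
                window = str(Seq(context[wend - wlen : wend]).reverse_complement())
                pos = wend - wlen + 1
            if len(window) != wlen:
                continue
            m = score_rss_window(
                window, spacer_class, consensus,
                gene_name=gene.name, side=side, position=pos,
            )
            if m is not None:
                candidates.append(m)
        if candidates:
            # lowest mismatch count wins; ties resolved toward the canonical
            # spacer length (closest to the class), then lowest position
            candidates.sort(
                key=lambda m: (
                    m.total_mismatches,
                    abs(m.observed_spacer_len - m.spacer_class),
                    m.position,
                )
            )
            results.append(candidates[0])
        elif warn:
            _warnings.warn(
                f"no acceptable {side} RSS found for {gene.name}", stacklevel=2
            )
    return results


@dataclass
class ConservationMatrix:
    """Per-position nucleotide counts, frequencies and information content.

    Information is ``2 − H`` bits per position (Shannon entropy against a
    uniform ACGT background, no small-sample correction).
    """

    alphabet: str
    counts: np.ndarray  # (positions, 4)
    frequencies: np.ndarray
    information: np.ndarray
    n_sequences: int = 0

    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.alphabet),
            "counts": self.counts.tolist(),
            "frequencies": self.frequencies.tolist(),
            "information": self.information.tolist(),
            "n_sequences": self.n_sequences,
        }


def conservation_matrix(seqs: list[str]) -> ConservationMatrix:
    """Build a conservation matrix from aligned, equal-length DNA strings."""
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    alphabet = "ACGT"
    index = {c: i for i, c in enumerate(alphabet)}
    counts = np.zeros((length, 4), dtype=int)
    for s in seqs:
        s = s.upper()
        if len(s) != length:
            raise ValueError(
                f"length mismatch: expected {length}, got {len(s)} for {s!r}"
            )
        for pos, ch in enumerate(s):
            if ch not in index:
                raise ValueError(f"non-ACGT symbol {ch!r} at position {pos + 1}")
            counts[pos, index[ch]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = 2.0 - entropy
    return ConservationMatrix(
        alphabet=alphabet,
        counts=counts,
        frequencies=freqs,
        information=information,
        n_sequences=len(seqs),
    )
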