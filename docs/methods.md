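# Methods

This note documents the models and procedures implemented in `trdkit`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical/design decisions made
where the underlying biology or published practice leaves the choice open.

## Locus model and gene-table handling

Genes are held as records with 1-based inclusive scaffold coordinates (the
convention of published gene tables and of GFF3, which the package writes
natively). V genes carry two exons (L-PART1 and V-EXON), C genes three
(EX1–EX3); for minus-orientation genes the stored sequence is always the
coding strand (reverse complement of the genome slice).

Assemblies of large multigene families often contain several gene-prediction
models for one gene (duplicated or misassembled scaffold regions).
`collapse_redundant_models` merges models sharing an explicit
redundancy-group marker, keeping the first-named model as representative and
recording the absorbed members — both interpretations (one gene vs. true
duplication) stay recoverable from the members list. On the shipped gene
table this collapses 67 TRDV1 models to 52 unique genes and 73 V models to
56. A marker on a single record is ignored with a warning. One shipped J-gene
row is printed with start > end; the parser normalizes the pair with a
warning rather than rejecting the row. Scaffold orientations are taken as
given — the package does not try to detect misoriented scaffolds.

## RSS model

A recombination signal sequence is scored as heptamer + spacer + nonamer
read *away from the coding end* on the coding strand; the 5' RSS of D and J
genes is scored on the reverse complement of the upstream flank, so a single
consensus (`CACAGTG` / `ACAAAAACC`) serves both sides. Acceptance requires:

- heptamer positions 1–3 exactly `CAC` (critical for recombination);
- at most 2 mismatches in heptamer positions 4–7;
- at most 3 mismatches in the 9-nt nonamer (nonamer conservation is known to
  be less rigid than the heptamer's);
- spacer length within ±1 bp of the 12- or 23-bp class.

These thresholds are carried on `RSSConsensus` and can be tightened or
relaxed. `find_flanking_rss` searches only the sides mandated by gene type
(V: 3' with 23-spacer; D: 5' with 12 and 3' with 23; J: 5' with 12) and
requires the heptamer to abut the coding end; among accepted spacer lengths
the lowest mismatch count wins, ties resolving toward the canonical spacer
length. Conservation matrices report per-position counts, frequencies and
information content (2 − H bits against a uniform background, log base 2,
no small-sample correction — the correction applied by common logo tools is
deliberately omitted and documented here).

## IMGT numbering

The IMGT unique numbering fixes framework spans (FR1 positions 1–26, FR2
39–55, FR3 66–104) and lets the CDR loops absorb all length variation
(CDR1 27–38, CDR2 56–65; loops fill from both ends toward the top, with
inserted sublabels for loops longer than their span — CDR1 of 18 aa is
accepted, no upper bound is enforced). Numbering is an anchored constraint
search: every admissible (CDR1, CDR2) length pair fully determines where
each IMGT position falls, both cysteine anchors (23, 104) are required, and
candidates are scored on the remaining anchors (Trp 41; hydrophobic 89,
accepting L/I/V/M/F/A with Leu canonical) plus the YF of the FR3-closing
YFC motif. Ties prefer the intact-CDR2 model, then canonical loop lengths
(CDR2 closest to 3, CDR1 closest to 9). A deletion variant spanning the
last FR2 residue through the fifth FR3 residue — producing genes that lack
CDR2 entirely, as seen in several ruminant TRDV1 genes — is searched as an
alternative model. Failure to place the cysteine pair raises a diagnostic
error.

Feature extraction reads off CDR1 length, the residue at position 57
(second CDR2 residue; absent when CDR2 is deleted or shorter than 3), the
presence of Trp at 107 computed from the germline residues beyond 104
(`not-applicable` when fewer than three are encoded), the Q-x-S motif in
CDR2, the YFC motif, and the post-104 extension length.

Functionality follows IMGT practice: **pseudogene** on a premature stop or a
frameshift in the spliced coding region (such genes are excluded
downstream); **ORF** when the frame is open but the structure is anomalous —
CDR2 deleted, more than 4 residues beyond 2nd-CYS 104 (normal V genes
encode 3–4; displaced RS can push this to 12–15), or loss of a non-CYS
anchor; otherwise **functional**. The post-104 threshold of 4 is
configurable; the list of ORF triggers is open for extension.

## Phylogeny and set classification

Distances are p-distances (proportion of differing sites) with complete
deletion: any column containing a gap in any sequence is removed before
computation. Neighbor joining is the classic agglomeration; determinism is
pinned by breaking Q-criterion ties on the lexicographically smallest label
pair (each cluster labelled by its smallest leaf name). Negative branch
lengths are retained by default (matching common phylogeny-software
behavior) with an option to clamp at zero. Support values resample
alignment columns with replacement, rebuild the tree per replicate and
score each original internal bipartition by the percentage of replicates
containing it; taxon order is canonicalized before resampling so support is
independent of input order. This site-bootstrap partition frequency stands
in for both the bootstrap and the interior-branch style of support — the
t-statistic variant of the interior-branch test is out of scope.

TRDV1 sets 1–11 are defined by CDR feature rules (CDR1 length, residue 57
chemistry, Trp 107). Three published per-gene exceptions (TRDV1t with CDR1
of 8 in set 2, TRDV1o with CDR1 of 18 in set 9, TRDV1d with Q at 107 in
set 5) are honored via an explicit exception list rather than widened
rules. Sets 5/8 and 4/6 share feature tuples; with a tree and reference
members the query joins the set whose reference member shares the smallest
clade with it, otherwise the assignment is flagged ambiguous with the
candidate list. (The rule table also leaves CDR1=7 / 57=G / W107-present
shared between sets 10 and 11; the classifier flags any multi-match the
same way.)

## Junction analysis

Germline V assignment compares the transcript against each reference
V-REGION through position 104, ungapped; more than 6 nt differences or a
tie leaves the query unassigned with diagnostics. The CDR3 spans IMGT
codons 105–117; its 3' boundary, J-PHE 118, is located as the first
in-frame F/W-G-X-G motif downstream of codon 104 (out-of-frame junctions
raise a boundary error). The J gene is identified by best suffix match.

D usage within the CDR3 is claimed only for exact contiguous matches of at
least 6 nt — the floor below which a claim is not distinguishable from
chance in a junction containing N additions; exact matching is the default
because a mismatch-tolerant 6-nt floor would be meaningless. The caller
selects, among all candidate fragments, the non-overlapping subset whose
genomic D order is strictly increasing (each D used at most once — the
deletional model of sequential rearrangement), maximizing total matched
nucleotides with ties broken by fewer segments, then leftmost placement,
then lower genomic indices. The same objective is implemented twice: a
chain dynamic program (production path) and an exhaustive enumeration over
ordered fragment subsets (reference oracle); the two are checked against
each other on hundreds of seeded junctions. A ≥6-nt window matching two
different D genes resolves to the lower genomic index and is flagged
ambiguous.

Remaining nucleotides are partitioned into: the germline V 3' continuation
(longest prefix matching the V tail beyond 104), the germline J 5' portion
(longest suffix), P nucleotides — at every untrimmed germline end, up to 2
adjacent unassigned nucleotides equal to the reverse complement of the
terminal germline nucleotides (P placed before N when both could explain
the sequence) — and N elsewhere. Segments always tile the CDR3 exactly.

Usage summaries count every D occurrence per V subgroup; percentages are
100 × count / total D occurrences in the subgroup, rounded half-up to one
decimal. A truncate mode exists because one published cell (10/31 printed
as 32.2 rather than 32.3) is only reproducible by truncation; neither
behavior is asserted for that cell.

## Synthetic data generator

The generator emits the study conditions as defaults: V genes with a 49-bp
L-PART1 (the TRDV1/TRDV2 value), an intron and a V-EXON whose length must
fall in 271–335 bp; five D genes with the genomic span lengths 13, 15, 13,
9 and 11 nt; J genes with an F-G-X-G block behind the junction head; a
single C gene of 1282 coding bp in three exons; optionally one inverted V
downstream of C. All RSS are planted canonical with the correct spacer
class per side. V-REGIONs are built on fixed framework scaffolds carrying
the anchors and motifs, with CDR1 lengths drawn from {5, 7, 8, 9, 10},
CDR2 fixed at 3 (Q-x-S), 3–4 germline residues beyond 104 and Trp 107
present with probability 0.5. CDR and extension residues are drawn from a
tryptophan/cysteine/phenylalanine-free alphabet so that anchor placement is
unambiguous by construction — a deliberate idealization: real CDRs can
contain W/C/F, and on real data the numbering relies on its anchor scoring
rather than on this guarantee.

Rearrangements sample a V, an ordered D subset (1–5 genes, uniform by
default) and a J. Published junction data give no trimming or insertion
distributions, so these were fixed once at field-plausible values:
exonuclease trims are truncated-geometric with mean 2 (cap 4 per end, and
never cutting a D below 6 remaining nt by default), N-region lengths are
Poisson with mean 4 (junctions with multiple D genes show extensive
N-regions), and P additions of 1–2 nt occur at untrimmed ends with
probability 0.5. By default one N region is extended by 0–2 nt so J-PHE 118
stays in frame (disable `in_frame` for raw concatenation experiments). One
RNG stream is spawned per transcript index, so enlarging a repertoire never
perturbs earlier transcripts.

The **clean benchmark** used for recovery measurement disables P additions
and rejection-samples each junction until, independently of the caller,
(i) every 6-mer of the junction that occurs in any D gene lies inside the
planted fragment of that same gene, and (ii) no planted fragment can be
extended into its flanking nucleotides. Gene choices are redrawn inside the
rejection loop because a V tail or J head that itself contains a D 6-mer
cannot be escaped by resampling N regions alone. D gene sequences are
sampled so that no 6-mer is shared within or between genes, which removes
cross-gene collisions from the benchmark; real TRDD genes are G-rich and
can share short words, so recovery on real data would be bounded by that
ambiguity in a way the benchmark does not measure.

What passing the simulation-based tests shows: the scanners, numbering and
callers invert the generator's construction exactly under the stated
conditions. What it does not show: robustness to somatic mutation,
sequencing error, allelic variation or cross-D sequence sharing — none of
which the generator models.

## Problem sizes and numerical choices

The shipped checks use 500 junctions for the caller-vs-oracle comparison,
a 2,000-junction clean benchmark, 200 numbering templates, 100 seeded 1-kb
RSS backgrounds, and additive matrices up to 6 taxa for NJ exactness
(checked against exhaustive topology enumeration with least-squares branch
fitting); these sizes make the whole suite run in seconds while keeping the
binomial noise on the recovery rate well under the 1% margin of the 99%
recovery requirement. NJ exactness is asserted to 1e-9 absolute on branch
lengths; p-distance and conservation computations are exact rational
arithmetic in floating point. Percentage rounding uses decimal half-up (not
banker's rounding) to match published table conventions.

## Known limitations

- Redundancy collapsing relies on the explicit markers of the input table;
  the flank-identity rule for novel data (identical coding sequence plus
  ≥99% identity over 200 bp of flank) is a stated convention, not a
  validated threshold.
- The IMGT numbering implemented here covers anchors, CDR delineation and
  the features needed for set classification; it is not a full germline
  alignment engine (no allele database, no insertion/deletion handling
  inside frameworks).
- The interior-branch support is a partition-frequency approximation, not
  the t-statistic test.
- TRAV/DV disambiguation and rearrangement-competence prediction are out of
  scope; assignment of a V gene to the TRD repertoire requires
  rearrangement evidence.
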