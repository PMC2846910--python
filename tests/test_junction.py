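"""V assignment, CDR3 extraction, D calling vs oracle, P/N annotation, usage."""

import numpy as np
import pytest
from Bio.Seq import Seq

from trdkit import (
    JunctionConfig,
    annotate_np_regions,
    assign_germline_v,
    call_trdd_usage,
    call_trdd_usage_exhaustive,
    extract_cdr3,
    summarize_d_usage,
)
from trdkit.junction import (
    JunctionAnnotation,
    JunctionBoundaryError,
    VReference,
    d_usage_percentages,
)
from trdkit.simulate import RearrangementConfig, simulate_rearrangements

CFG = JunctionConfig()


def _clean_random_nt(rng, n, d_refs):
    """Random nucleotides containing no 6-mer of any D gene."""
    kmers = {
        s[i : i + 6] for _, s in d_refs for i in range(len(s) - 5)
    }
    for _ in range(500):
        cand = "".join(rng.choice(list("ACGT"), size=n))
        if not any(cand[i : i + 6] in kmers for i in range(max(0, n - 5))):
            return cand
    raise RuntimeError("could not sample clean random nucleotides")


class TestAssignGermlineV:
    def test_exact_match_zero_mismatches(self, locus):
        ref = locus.v_refs[0]
        va = assign_germline_v(ref.vregion_nt, locus.v_refs, CFG, query_name="q")
        assert va.gene == ref.name and va.mismatches == 0

    def test_seven_mismatches_unassigned(self, locus):
        ref = locus.v_refs[0]
        seq = list(ref.vregion_nt)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in range(0, 7 * 9, 9):  # 7 scattered mutations before codon 104
            seq[i] = flip[seq[i]]
        va = assign_germline_v("".join(seq), [ref], CFG)
        assert not va.assigned and va.mismatches == 7

    def test_tie_unassigned_with_diagnostics(self):
        base = "ACGT" * 60
        a = VReference(name="Va", vregion_nt=base, n104_codons=70)
        flip = list(base)
        flip[30] = "T"
        b = VReference(name="Vb", vregion_nt="".join(flip), n104_codons=70)
        query = list(base)
        query[30] = "A"  # differs from both references at the same position
        qa = sum(x != y for x, y in zip("".join(query), base))
        qb = sum(x != y for x, y in zip("".join(query), b.vregion_nt))
        assert qa == qb == 1
        va = assign_germline_v("".join(query), [a, b], CFG)
        assert not va.assigned
        assert sorted(va.ties) == ["Va", "Vb"]

    def test_short_cdna_errors(self, locus):
        with pytest.raises(ValueError, match="150"):
            assign_germline_v("ACGT" * 10, locus.v_refs, CFG)


class TestExtractCDR3:
    def test_simulated_transcripts_match_truth(self, locus):
        txs, truths = simulate_rearrangements(
            locus, RearrangementConfig(n_transcripts=30, seed=77)
        )
        for (name, tx), truth in zip(txs, truths):
            v_ref = next(v for v in locus.v_refs if v.name == truth.v_name)
            ann = extract_cdr3(tx, v_ref, locus.j_refs, query_name=name)
            assert ann.cdr3_nt == truth.cdr3_nt
            assert ann.j_gene == truth.j_name
            assert ann.cdr3_aa_length == len(truth.cdr3_nt) // 3

    def test_mutated_j_motif_raises(self, locus):
        v_ref = locus.v_refs[0]
        cdr3 = "GGTAGCACA"  # 3 codons, no FGXG
        tx = v_ref.vregion_nt[: 3 * v_ref.n104_codons] + cdr3 + "TTTGGACAAGCA"
        # FGQA instead of FGQG: boundary must not be found
        with pytest.raises(JunctionBoundaryError, match="junction boundary"):
            extract_cdr3(tx, v_ref, locus.j_refs)


class TestCallTrddUsage:
    def test_full_d_flanked_by_clean_n(self, locus, rng):
        d_name, d_seq = locus.d_refs[1]
        cdr3 = (
            _clean_random_nt(rng, 6, locus.d_refs)
            + d_seq
            + _clean_random_nt(rng, 5, locus.d_refs)
        )
        ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
        assert ann.d_calls == [d_name]

    def test_five_nt_fragment_not_called(self, locus, rng):
        _, d_seq = locus.d_refs[0]
        kmers = {s[i : i + 6] for _, s in locus.d_refs for i in range(len(s) - 5)}
        for _ in range(200):
            cdr3 = (
                _clean_random_nt(rng, 5, locus.d_refs)
                + d_seq[:5]
                + _clean_random_nt(rng, 5, locus.d_refs)
            )
            # boundary windows must not extend the 5-nt fragment to six
            if not any(cdr3[i : i + 6] in kmers for i in range(len(cdr3) - 5)):
                break
        ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
        assert ann.d_calls == []

    def test_two_fragments_in_genomic_order(self, locus, rng):
        d1, s1 = locus.d_refs[0]
        d4, s4 = locus.d_refs[3]
        cdr3 = s1[:8] + _clean_random_nt(rng, 4, locus.d_refs) + s4[:7]
        ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
        assert ann.d_calls == [d1, d4]

    def test_order_violation_keeps_single_best(self, locus, rng):
        d1, s1 = locus.d_refs[0]
        d3, s3 = locus.d_refs[2]
        # planted in anti-genomic order: D3 fragment (8 nt) before D1 (7 nt)
        cdr3 = s3[:8] + _clean_random_nt(rng, 4, locus.d_refs) + s1[:7]
        ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
        assert ann.d_calls == [d3]  # larger single match wins; never [D3, D1]

    def test_each_d_used_at_most_once(self, locus, rng):
        _, s2 = locus.d_refs[1]
        cdr3 = s2 + _clean_random_nt(rng, 4, locus.d_refs) + s2
        ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
        assert ann.d_calls.count(locus.d_refs[1][0]) == 1

    def test_segments_tile_cdr3(self, locus, rng):
        for _ in range(20):
            L = int(rng.integers(9, 50))
            cdr3 = "".join(rng.choice(list("ACGT"), size=L))
            ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
            tiled = "".join(cdr3[s.start : s.end] for s in ann.segments)
            assert tiled == cdr3

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, locus, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            L = int(rng.integers(10, 61))
            cdr3 = "".join(rng.choice(list("ACGT"), size=L))
            if rng.random() < 0.7:
                dn, ds = locus.d_refs[rng.integers(5)]
                k = int(rng.integers(6, len(ds) + 1))
                pos = int(rng.integers(0, L - 5))
                cdr3 = cdr3[:pos] + ds[:k] + cdr3[pos:]
            ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
            assert ann.d_calls == call_trdd_usage_exhaustive(
                cdr3, locus.d_refs, CFG
            )


def _revcomp(s):
    return str(Seq(s).reverse_complement())


class TestAnnotateNP:
    def test_p_at_untrimmed_d_five_prime(self, locus, rng):
        d_name, d_seq = locus.d_refs[2]
        p = _revcomp(d_seq[:2])
        left = _clean_random_nt(rng, 4, locus.d_refs)
        cdr3 = left + p + d_seq + _clean_random_nt(rng, 3, locus.d_refs)
        ann = call_trdd_usage(cdr3, locus.d_refs, CFG)
        assert ann.d_calls == [d_name]
        ann = annotate_np_regions(ann, locus.d_refs)
        p_segs = [s for s in ann.segments if s.kind == "P"]
        assert any(
            s.source == d_name and cdr3[s.start : s.end] == p for s in p_segs
        )

    def test_trimmed_end_gets_n_not_p(self, locus, rng):
        d_name, d_seq = locus.d_refs[2]
        # trimmed 5' end (2 nt removed): adjacent leftovers stay N
        left = _clean_random_nt(rng, 4, locus.d_refs)
        frag = d_seq[2:]
        cdr3 = left + frag + _clean_random_nt(rng, 3, locus.d_refs)
        ann = annotate_np_regions(
            call_trdd_usage(cdr3, locus.d_refs, CFG), locus.d_refs
        )
        d_seg = next(s for s in ann.segments if s.kind == "D")
        before = [s for s in ann.segments if s.end == d_seg.start]
        assert before and before[0].kind == "N"

    def test_fully_tiled_junction_no_n_no_p(self, locus):
        v_ref = locus.v_refs[0]
        d_name, d_seq = locus.d_refs[0]
        j_name, j_body = locus.j_refs[0]
        j_head = locus.j_heads[j_name]
        cdr3 = v_ref.post104_nt + d_seq + j_head
        ann = JunctionAnnotation(
            query="q", cdr3_nt=cdr3, cdr3_aa_length=len(cdr3) // 3,
            v_gene=v_ref.name, j_gene=j_name,
        )
        call_trdd_usage(cdr3, locus.d_refs, CFG, annotation=ann)
        annotate_np_regions(ann, locus.d_refs, v_ref=v_ref, j_head=j_head)
        kinds = [s.kind for s in ann.segments]
        assert "N" not in kinds and "P" not in kinds
        assert kinds[0] == "V3'" and kinds[-1] == "J5'"

    def test_segments_always_tile(self, locus):
        txs, truths = simulate_rearrangements(
            locus, RearrangementConfig(n_transcripts=40, seed=13)
        )
        for (name, tx), truth in zip(txs, truths):
            v_ref = next(v for v in locus.v_refs if v.name == truth.v_name)
            ann = extract_cdr3(tx, v_ref, locus.j_refs, query_name=name)
            call_trdd_usage(ann.cdr3_nt, locus.d_refs, CFG, annotation=ann)
            annotate_np_regions(
                ann, locus.d_refs, v_ref=v_ref,
                j_head=locus.j_heads[ann.j_gene],
            )
            tiled = "".join(ann.cdr3_nt[s.start : s.end] for s in ann.segments)
            assert tiled == ann.cdr3_nt


class TestUsageSummary:
    def test_published_trdv1_row(self):
        counts = {"TRDD1": 33, "TRDD2": 33, "TRDD3": 18, "TRDD4": 23, "TRDD5": 29}
        pct = d_usage_percentages(counts)
        assert pct == {
            "TRDD1": 24.3, "TRDD2": 24.3, "TRDD3": 13.2,
            "TRDD4": 16.9, "TRDD5": 21.3,
        }

    def test_published_trdv2_row(self):
        pct = d_usage_percentages(
            {"TRDD1": 6, "TRDD2": 9, "TRDD3": 7, "TRDD4": 9, "TRDD5": 6}
        )
        assert pct == {
            "TRDD1": 16.2, "TRDD2": 24.3, "TRDD3": 18.9,
            "TRDD4": 24.3, "TRDD5": 16.2,
        }

    def test_single_call_is_100(self):
        ann = JunctionAnnotation(
            query="q", cdr3_nt="ACGTACGTA", cdr3_aa_length=3,
            subgroup="TRDV1", d_calls=["TRDD2"],
        )
        df = summarize_d_usage([ann])
        assert df.loc["TRDV1", "TRDD2_pct"] == 100.0
        assert df.loc["TRDV1", "sequences_evaluated"] == 1

    def test_percentages_sum_to_100(self, rng):
        anns = []
        for i in range(60):
            calls = list(
                rng.choice(["TRDD%d" % k for k in range(1, 6)],
                           size=rng.integers(1, 4), replace=False)
            )
            anns.append(
                JunctionAnnotation(
                    query=f"q{i}", cdr3_nt="ACG", cdr3_aa_length=1,
                    subgroup="TRDV%d" % (1 + i % 2), d_calls=calls,
                )
            )
        df = summarize_d_usage(anns)
        for _, row in df.iterrows():
            total = sum(row[f"TRDD{k}_pct"] for k in range(1, 6))
            assert abs(total - 100.0) <= 0.3

    def test_empty_input(self):
        df = summarize_d_usage([])
        assert df.empty

    def test_truncate_mode(self):
        pct = d_usage_percentages(
            {"TRDD1": 9, "TRDD2": 3, "TRDD3": 10, "TRDD4": 4, "TRDD5": 5},
            rounding="truncate",
        )
        assert pct["TRDD3"] == 32.2  # 10/31 truncated, as printed
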