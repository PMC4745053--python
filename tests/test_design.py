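import numpy as np
import pytest

from primerkit import design, simulate
from primerkit.design import (
    DesignParams,
    apply_filters,
    design_allele_specific,
    design_batch,
    design_snp_flanking,
    dimer_report,
    enumerate_candidates,
    specificity_count,
)
from primerkit.seqio import COMPLEMENT, SequenceRecord, reverse_complement

from conftest import make_record
from oracles import brute_specificity
from verifier import verify_candidate


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestEnumerate:
    def test_window_combinatorics(self):
        # starts s with s + len - 1 <= 30: 13 + 12 + 11 candidates
        rec = make_record("ACGT" * 15)
        params = DesignParams(primer_len_min=18, primer_len_max=20,
                              window5=30, window3=18)
        fwd = [c for c in enumerate_candidates(rec, params) if c.orientation == "forward"]
        assert len(fwd) == 36
        assert all(c.start + c.length - 1 <= 30 for c in fwd)

    def test_window_clipped_to_sequence(self):
        rec = make_record("ACGT" * 10)   # 40 nt
        params = DesignParams(window5=500, window3=500)
        cands = enumerate_candidates(rec, params)
        assert all(1 <= c.plus_span[0] and c.plus_span[1] <= 40 for c in cands)
        starts = {c.start for c in cands if c.orientation == "forward"}
        assert 1 in starts  # whole sequence is searchable

    def test_sequence_shorter_than_min_length(self):
        with pytest.raises(ValueError):
            enumerate_candidates(make_record("ACGTACGTAC"), DesignParams())

    def test_reverse_candidate_geometry(self):
        rec = make_record("A" * 30 + "GCGC" * 10)   # 70 nt
        params = DesignParams(window3=20, window5=18)
        rev = [c for c in enumerate_candidates(rec, params) if c.orientation == "reverse"]
        for c in rev:
            lo, hi = c.plus_span
            assert lo >= 70 - 20 + 1 and hi <= 70
            assert c.sequence == reverse_complement(rec.subsequence(lo, hi))
            assert c.start == hi          # 5' terminus of a reverse primer
            assert c.name == str(hi)


class TestFilters:
    def test_repeat_rejection_reason(self):
        rec = make_record("ACAAAAAAGT" + "GCGATCGTTAGCCATGAC" * 3)
        params = DesignParams(window5=len(rec.residues), window3=18)
        cands = enumerate_candidates(rec, params)
        with_runs = [c for c in cands if "AAAAAA" in c.sequence]
        assert with_runs
        _, rejections = apply_filters(with_runs, [rec], params, collect_rejections=True)
        assert any("mononucleotide" in r.reason for r in rejections)

    def test_all_a_record_yields_nothing(self):
        rec = make_record("A" * 50)
        accepted = apply_filters(enumerate_candidates(rec, DesignParams()), [rec],
                                 DesignParams())
        assert accepted == []

    def test_accepted_primers_repass_independent_verifier(self, default_params):
        records = simulate.random_dna_records(4, 500, seed=23)
        result = design_batch(records, default_params)
        total = 0
        for rec in records:
            for primer in result.primers_by_record[rec.id]:
                assert verify_candidate(primer, rec, records, default_params) == []
                total += 1
        assert total > 0

    def test_gc_clamp_enforced_when_required(self):
        records = simulate.random_dna_records(2, 400, seed=31)
        params = DesignParams(require_gc_clamp=True)
        for primer in design_batch(records, params).all_primers:
            assert primer.sequence[-1] in "GC"

    def test_dedup_keeps_smallest_start(self):
        # identical 20-mer planted at starts 1 and 31 within the 5' window
        motif = "CAGTTACCGATGGACTTAGG"
        rec = make_record(motif + "ACGTACGTAC" + motif + "ACGTACGTACGTACGTAGGC")
        params = DesignParams(primer_len_min=20, primer_len_max=20,
                              window5=len(rec.residues), window3=20,
                              tm_min=0, tm_max=100, gc_min=0, gc_max=100)
        accepted = apply_filters(enumerate_candidates(rec, params), [rec], params)
        dupes = [c for c in accepted if c.sequence == motif and c.orientation == "forward"]
        assert len(dupes) == 1 and dupes[0].start == 1


class TestSpecificity:
    def test_planted_once(self):
        rng = np.random.default_rng(0)
        primer = "GATTACAGATTACAGATTAC"
        rec = SequenceRecord(id="r", residues="GGGCGC" * 20 + primer + "CCCGCG" * 20)
        assert specificity_count(primer, [rec], 0) == 1

    def test_planted_on_both_strands(self):
        primer = "GATTACAGATTACAGATTAC"
        body = "GGGCGC" * 10 + primer + "CCCGCG" * 10 + reverse_complement(primer) + "GGCGCG" * 5
        rec = SequenceRecord(id="r", residues=body)
        assert specificity_count(primer, [rec], 0) == 2

    def test_mismatch_tolerance(self):
        primer = "GATTACAGATTACAGATTAC"
        variant = "GATTACAGATTACAGATTAG"   # one substitution
        body = "GGGCGC" * 10 + primer + "CCCGCG" * 10 + variant + "GGCGCG" * 5
        rec = SequenceRecord(id="r", residues=body)
        assert specificity_count(primer, [rec], 0) == 1
        assert specificity_count(primer, [rec], 1) == 2

    def test_primer_longer_than_records(self):
        rec = make_record("ACGTACGTACGTACG")
        assert specificity_count("A" * 30, [rec], 0) == 0

    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_oracle_agreement(self, m):
        rng = np.random.default_rng(7)
        records = [SequenceRecord(id=f"r{i}", residues=random_dna(rng, 300))
                   for i in range(5)]
        for _ in range(10):
            primer = random_dna(rng, int(rng.integers(18, 28)))
            assert specificity_count(primer, records, m) == \
                brute_specificity(primer, [r.residues for r in records], m)


class TestBatch:
    def test_conservation_and_order(self, dna_records, default_params):
        result = design_batch(dna_records, default_params)
        assert [r.id for r in result.records] == [r.id for r in dna_records]
        assert len(result.all_primers) == \
            sum(len(v) for v in result.primers_by_record.values())

    def test_deterministic(self, dna_records, default_params):
        a = design_batch(dna_records, default_params)
        b = design_batch(dna_records, default_params)
        assert a.all_primers == b.all_primers

    def test_per_record_failures_do_not_abort(self, default_params):
        ok = simulate.random_dna_records(1, 400, seed=5)[0]
        result = design_batch([ok, make_record("A" * 50, "allA")], default_params)
        assert result.primers_by_record["allA"] == []
        assert len(result.primers_by_record[ok.id]) > 0


class TestSnpFlanking:
    def test_primers_bracket_the_snp(self, snp_records, default_params):
        snp = snp_records[0]
        accepted = design_snp_flanking(snp, default_params)
        fwd = [p for p in accepted if p.orientation == "forward"]
        rev = [p for p in accepted if p.orientation == "reverse"]
        assert fwd and rev
        assert max(p.plus_span[1] for p in fwd) <= snp.snp_position - 1
        assert min(p.plus_span[0] for p in rev) >= snp.snp_position + 1

    def test_candidate_windows_never_include_the_ambiguity_code(self, snp_records,
                                                                default_params):
        snp = snp_records[1]
        for p in design_snp_flanking(snp, default_params):
            lo, hi = p.plus_span
            assert not lo <= snp.snp_position <= hi
            assert set(p.sequence) <= set("ACGT")

    def test_snp_too_close_to_an_end(self):
        from primerkit.seqio import SnpRecord
        rec = SequenceRecord(id="rs1", residues="ACGT" + "R" + "ACGT" * 30)
        snp = SnpRecord(record=rec, snp_position=5, declared_length=len(rec.residues))
        with pytest.raises(ValueError, match="5' end"):
            design_snp_flanking(snp, DesignParams())


class TestAlleleSpecific:
    def test_three_prime_terminus_rules(self, snp_records, default_params):
        for snp in snp_records:
            primers, _ = design_allele_specific(snp, default_params)
            for ap in primers:
                cand = ap.candidate
                lo, hi = cand.plus_span
                if cand.orientation == "forward":
                    assert hi == snp.snp_position
                    assert cand.sequence[-1] == ap.allele
                else:
                    assert lo == snp.snp_position
                    assert cand.sequence[-1] == COMPLEMENT[ap.allele]

    def test_same_length_mates_differ_only_at_terminus(self, snp_records, default_params):
        snp = snp_records[0]
        primers, _ = design_allele_specific(snp, default_params)
        fwd = [p for p in primers if p.candidate.orientation == "forward"]
        if len(fwd) == 2 and fwd[0].candidate.length == fwd[1].candidate.length:
            a, b = fwd[0].candidate.sequence, fwd[1].candidate.sequence
            diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
            assert diffs == [len(a) - 1]

    def test_wildtype_label_is_first_allele(self, snp_records, default_params):
        snp = snp_records[0]
        primers, _ = design_allele_specific(snp, default_params)
        for ap in primers:
            expected = "wildtype" if ap.allele == snp.alleles[0] else "polymorphic"
            assert ap.label == expected

    def test_gc_clamp_requirement_is_exempt(self, snp_records):
        params = DesignParams(require_gc_clamp=True)
        base = DesignParams(require_gc_clamp=False)
        for snp in snp_records:
            with_clamp, _ = design_allele_specific(snp, params)
            without, _ = design_allele_specific(snp, base)
            assert [(p.allele, p.candidate.sequence) for p in with_clamp] == \
                [(p.allele, p.candidate.sequence) for p in without]

    def test_tm_selection_targets_midpoint(self, snp_records, default_params):
        from primerkit import thermo as th
        mid = (default_params.tm_min + default_params.tm_max) / 2
        snp = snp_records[2]
        primers, _ = design_allele_specific(snp, default_params)
        for ap in primers:
            cand = ap.candidate
            assert default_params.tm_min <= cand.tm <= default_params.tm_max
            # no admissible length of the same construction does better
            for length in range(default_params.primer_len_min,
                                default_params.primer_len_max + 1):
                if cand.orientation == "forward":
                    lo = snp.snp_position - length + 1
                    seq = snp.record.subsequence(lo, snp.snp_position - 1) + ap.allele
                else:
                    hi = snp.snp_position + length - 1
                    seq = reverse_complement(
                        ap.allele + snp.record.subsequence(snp.snp_position + 1, hi))
                tm_val = th.tm(seq, default_params.thermo)
                if default_params.tm_min <= tm_val <= default_params.tm_max:
                    assert abs(cand.tm - mid) <= abs(tm_val - mid) + 1e-9


class TestDimerReport:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (10, 45), (40, 780)])
    def test_pair_count_closed_form(self, n, expected):
        rng = np.random.default_rng(n)
        primers = [
            design.PrimerCandidate("r", "forward", i + 1, 20, random_dna(rng, 20))
            for i in range(n)
        ]
        report = dimer_report(primers)
        assert len(report.pairs) == expected == n * (n - 1) // 2
        labels = {frozenset((a, b)) for a, b, _ in report.pairs}
        assert len(labels) == expected   # each unordered pair exactly once

    def test_scores_symmetric(self):
        from primerkit.scoring import cross_dimer_score
        rng = np.random.default_rng(3)
        primers = [
            design.PrimerCandidate("r", "forward", i + 1, 18, random_dna(rng, 18))
            for i in range(6)
        ]
        by_label = {p.label: p.sequence for p in primers}
        for a, b, score in dimer_report(primers).pairs:
            assert score == cross_dimer_score(by_label[b], by_label[a])

    def test_fewer_than_two_is_an_error(self):
        with pytest.raises(ValueError):
            dimer_report([design.PrimerCandidate("r", "forward", 1, 18, "A" * 18)])
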