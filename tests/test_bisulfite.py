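"""Reference conversion, alignment, methylation calling and clone QC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintscan.bisulfite import (
    METHYLATED,
    MISSING,
    UNMETHYLATED,
    AlignParams,
    BisulfiteClone,
    Snp,
    UnmappableReadError,
    align_clone,
    ambiguous_reference,
    build_clone,
    call_methylation,
    conversion_efficiency,
    deduplicate,
    filter_clones,
    in_silico_convert,
    score_read,
)
from imprintscan.synthetic import simulate_clones

from .conftest import amplicon_from_sequence, make_clone, zero_noise_scenario
from ._oracles import gotoh_score, random_bisulfite_read


class TestInSilicoConvert:
    @pytest.mark.parametrize(
        "seq, expected, ambiguous",
        [
            ("ACGTCCA", "ACGTTTA", {1}),  # CpG C stays ambiguous, lone Cs convert
            ("AGTTGA", "AGTTGA", set()),  # no C: identity
            ("CG", "CG", {0}),
            ("CCGG", "TCGG", {1}),
        ],
    )
    def test_top_strand(self, seq, expected, ambiguous):
        converted, amb = in_silico_convert(seq, "top")
        assert converted == expected
        assert set(amb) == ambiguous

    def test_bottom_strand_mirrors_g_to_a(self):
        converted, amb = in_silico_convert("ACGTGGA", "bottom")
        # the CpG guanine (offset 2) stays ambiguous; other Gs become A
        assert converted == "ACGTAAA"
        assert set(amb) == {2}

    def test_non_acgt_rejected_with_offset(self):
        with pytest.raises(ValueError, match="offset 2"):
            in_silico_convert("ACNGT")


class TestAlignClone:
    def test_converted_reference_read_is_perfect(self, amplicon):
        converted, _ = in_silico_convert(amplicon.sequence)
        aln = align_clone(converted, amplicon)
        assert aln.score == len(amplicon.sequence)
        assert aln.identity == 1.0
        assert "-" not in aln.read_bases and "" not in aln.read_bases

    def test_fully_methylated_read_scores_equally(self, amplicon):
        # CpG Cs retained, non-CpG Cs converted: ambiguity makes this perfect too
        converted, amb = in_silico_convert(amplicon.sequence)
        read = "".join(
            amplicon.sequence[i] if i in amb else converted[i]
            for i in range(len(converted))
        )
        aln = align_clone(read, amplicon)
        assert aln.score == len(amplicon.sequence)
        assert aln.identity == 1.0

    def test_reverse_complement_recovers_same_calls(self, amplicon):
        reads, _ = simulate_clones(amplicon, zero_noise_scenario(end_trim_max=0))
        from Bio.Seq import reverse_complement

        for clone_id, read in reads[:5]:
            fwd = align_clone(read, amplicon)
            rev = align_clone(reverse_complement(read), amplicon)
            assert rev.orientation == "reverse"
            assert call_methylation(fwd, amplicon) == call_methylation(rev, amplicon)

    def test_garbage_read_is_unmappable(self, amplicon):
        with pytest.raises(UnmappableReadError):
            align_clone("AT" * 40, amplicon)

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_score_matches_dp_oracle(self, seed):
        """Property: aligner score equals the independent Gotoh oracle."""
        rng = np.random.default_rng(seed)
        ref, read = random_bisulfite_read(rng)
        converted, amb = in_silico_convert(ref)
        ambiguous = "".join(
            "Y" if i in amb else converted[i] for i in range(len(converted))
        )
        params = AlignParams(min_read_length=5, identity_floor=0.0)
        assert score_read(ambiguous, read, params) == pytest.approx(
            gotoh_score(ambiguous, read)
        )

    def test_align_clone_takes_best_orientation_score(self, toy_params, rng):
        from Bio.Seq import reverse_complement

        for _ in range(20):
            ref, read = random_bisulfite_read(rng)
            amp = amplicon_from_sequence(ref)
            ambiguous = ambiguous_reference(amp)
            expected = max(
                gotoh_score(ambiguous, read),
                gotoh_score(ambiguous, reverse_complement(read)),
            )
            aln = align_clone(read, amp, toy_params, check_identity=False)
            assert aln.score == pytest.approx(expected)


class TestCallMethylation:
    def test_calls_follow_read_bases(self):
        amp = amplicon_from_sequence("AACGTACGTACGAA")  # CpGs at 2, 6, 10
        # keep C at first CpG (methylated), convert the rest
        read = "AACGTATGTATGAA"
        aln = align_clone(read, amp, AlignParams(min_read_length=5))
        assert call_methylation(aln, amp) == METHYLATED + UNMETHYLATED + UNMETHYLATED

    def test_deletion_spanning_cpg_is_missing(self):
        # A/G context around the CpGs keeps the optimal gap placement unique
        amp = amplicon_from_sequence("AAGGAACGAAGGAACGAAGGAA")  # CpGs at 6, 14
        read = "AAGGAAAAGGAATGAAGGAA"  # CG at 6 deleted; second CpG converted
        aln = align_clone(read, amp, AlignParams(min_read_length=5))
        calls = call_methylation(aln, amp)
        assert calls[0] == MISSING
        assert calls[1] == UNMETHYLATED

    def test_zero_noise_maternal_clone_fully_methylated(self, amplicon):
        reads, truth = simulate_clones(
            amplicon, zero_noise_scenario(maternal=1.0, paternal=0.0, end_trim_max=0)
        )
        truth_map = dict(zip(truth["clone_id"], truth["allele"]))
        for clone_id, read in reads:
            aln = align_clone(read, amplicon)
            calls = call_methylation(aln, amplicon)
            expected = METHYLATED if truth_map[clone_id] == "maternal" else UNMETHYLATED
            assert calls == expected * amplicon.n_cpg


class TestConversionEfficiency:
    def test_complete_conversion_is_one(self, amplicon):
        converted, _ = in_silico_convert(amplicon.sequence)
        aln = align_clone(converted, amplicon)
        assert conversion_efficiency(aln, amplicon) == 1.0

    def test_formula_exact_for_constructed_retention(self, amplicon):
        """Retaining k of n non-CpG Cs gives exactly 1 - k/n."""
        converted, amb = in_silico_convert(amplicon.sequence)
        positions = amplicon.non_cpg_c_positions()
        n = len(positions)
        assert n >= 10
        for k in (0, 1, 2, n // 2, n):
            read = list(converted)
            for p in positions[:k]:
                read[p] = "C"
            aln = align_clone("".join(read), amplicon, check_identity=False)
            assert conversion_efficiency(aln, amplicon) == pytest.approx(1 - k / n)

    def test_undefined_when_no_informative_position_covered(self):
        amp = amplicon_from_sequence("ACGTT" + "A" * 30 + "TTCCATT")
        # read covers only the C-free prefix region
        read = "ACGTT" + "A" * 30
        aln = align_clone(read, amp, AlignParams(min_read_length=5))
        assert conversion_efficiency(aln, amp) is None

    def test_efficiency_in_unit_interval_whenever_defined(self, amplicon, rng):
        scenario = zero_noise_scenario(seed=7)
        reads, _ = simulate_clones(amplicon, scenario)
        for clone_id, read in reads:
            aln = align_clone(read, amplicon)
            eff = conversion_efficiency(aln, amplicon)
            assert eff is None or 0.0 <= eff <= 1.0


class TestFilterClones:
    def test_low_conversion_rejected_with_reason(self):
        good = make_clone("111", "s|a")
        bad = make_clone("111", "s|b")
        bad.conversion_efficiency = 0.94
        kept, rejected = filter_clones([good, bad], n_cpg=3)
        assert kept == [good]
        assert rejected == [(bad, "low_conversion")]

    def test_few_calls_rejected(self):
        sparse = make_clone("1...", "s|a")
        kept, rejected = filter_clones([sparse], n_cpg=4)
        assert kept == []
        assert rejected[0][1] == "few_cpg_calls"

    def test_perfect_clones_all_kept(self):
        clones = [make_clone("1100", f"s|{i}") for i in range(5)]
        kept, rejected = filter_clones(clones, n_cpg=4)
        assert kept == clones and rejected == []

    def test_opt_out_of_conversion_filter(self):
        bad = make_clone("111", "s|b")
        bad.conversion_efficiency = 0.5
        kept, _ = filter_clones([bad], min_efficiency=None, n_cpg=3)
        assert kept == [bad]


class TestDeduplicate:
    def test_identical_sequences_collapse_with_multiplicity(self):
        clones = [
            BisulfiteClone(f"s|c{i}", "s", seq)
            for i, seq in enumerate(["AAA", "TTT", "AAA", "CCC", "GGG"])
        ]
        unique = deduplicate(clones)
        assert len(unique) == 4
        by_seq = {c.raw_sequence: c for c in unique}
        assert by_seq["AAA"].multiplicity == 2
        assert by_seq["AAA"].clone_id == "s|c0"  # lexicographically smallest id

    def test_no_duplicates_identity(self):
        clones = [BisulfiteClone(f"s|c{i}", "s", seq) for i, seq in enumerate("ACGT")]
        unique = deduplicate(clones)
        assert [c.clone_id for c in unique] == [c.clone_id for c in clones]
        assert all(c.multiplicity == 1 for c in unique)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from(["AA", "AC", "AG", "AT"]), min_size=1, max_size=30))
    def test_conservation_and_idempotence(self, seqs):
        clones = [BisulfiteClone(f"s|c{i:02d}", "s", seq) for i, seq in enumerate(seqs)]
        unique = deduplicate(clones)
        assert sum(c.multiplicity for c in unique) == len(clones)
        assert len(unique) == len(set(seqs))
        again = deduplicate(unique)
        assert [(c.clone_id, c.multiplicity) for c in again] == [
            (c.clone_id, c.multiplicity) for c in unique
        ]

    def test_unique_count_matches_truth_without_seq_error(self, amplicon):
        """With no sequencing error, unique reads = distinct read sequences."""
        scenario = zero_noise_scenario(
            maternal=0.7, paternal=0.3, n_molecules=40, seed=11, pcr_duplicate_rate=0.3
        )
        reads, truth = simulate_clones(amplicon, scenario)
        clones = [BisulfiteClone(cid, "s", seq) for cid, seq in reads]
        unique = deduplicate(clones)
        originals = truth[truth["dup_of"] == ""]
        assert len(reads) == len(originals) + (truth["dup_of"] != "").sum()
        assert len(unique) == len({seq for _, seq in reads})
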