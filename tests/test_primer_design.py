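"""Window enumeration, similarity search, distinctness and in-silico PCR."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from fastseqs import primer_design as pdx

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestEnumerateWindows:
    def test_exact_fit_single_window(self):
        ws = pdx.enumerate_windows("chr21", 1, 150)
        assert len(ws) == 1
        assert (ws[0].start, ws[0].end) == (1, 150)

    def test_three_windows_at_50bp_steps(self):
        ws = pdx.enumerate_windows("chr21", 1, 250)
        assert [(w.start, w.end) for w in ws] == \
            [(1, 150), (51, 200), (101, 250)]

    def test_closed_form_count_on_large_region(self):
        # the chromosome-21 search region used to pick the repeat blocks
        start, end = 35_888_786, 42_648_523
        length = end - start + 1
        ws = pdx.enumerate_windows("chr21", start, end)
        assert len(ws) == (length - 150) // 50 + 1
        assert ws[-1].end <= end

    def test_short_region_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert pdx.enumerate_windows("chr1", 1, 100) == []


class TestFindSimilarBlocks:
    def test_planted_exact_copies_found(self):
        rng = np.random.default_rng(0)
        q = random_seq(rng, 150)
        parts = [random_seq(rng, 3000) for _ in range(5)]
        genome = {"c1": parts[0] + q + parts[1] + q + parts[2],
                  "c2": parts[3] + q + parts[4] + q + random_seq(rng, 500)}
        matches = pdx.find_similar_blocks(q, genome, min_seed=20, max_variants=0)
        assert len(matches) == 4
        assert all(m.variant_bases == 0 and m.span == 150 for m in matches)

    def test_planted_substitutions_counted_vs_bruteforce(self):
        rng = np.random.default_rng(1)
        q = random_seq(rng, 150)
        mutated = list(q)
        # 15 substitutions in the back half so a 20-mer seed stays intact
        for p in rng.choice(np.arange(60, 150), size=15, replace=False):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        mutated = "".join(mutated)
        genome = {"c1": random_seq(rng, 2000) + mutated + random_seq(rng, 2000)}
        matches = pdx.find_similar_blocks(q, genome, min_seed=20, max_variants=30)
        assert any(m.variant_bases == 15 and m.start == 2001 for m in matches)

        # brute-force Hamming scan oracle: no qualifying offset missed
        subj = genome["c1"]
        brute = []
        for off in range(len(subj) - 150 + 1):
            window = subj[off:off + 150]
            mm_pos = [i for i in range(150) if q[i] != window[i]]
            has_seed = any(
                all(i < s or i >= s + 20 for i in mm_pos)
                for s in range(150 - 20 + 1)
            )
            if len(mm_pos) <= 30 and has_seed:
                brute.append((off + 1, len(mm_pos)))
        found = {(m.start, m.variant_bases) for m in matches if m.span == 150}
        assert set(brute) <= found

    def test_max_variants_zero_only_exact(self):
        rng = np.random.default_rng(2)
        q = random_seq(rng, 150)
        near = q[:-1] + ("A" if q[-1] != "A" else "C")
        genome = {"c1": q + "ACGT" * 50 + near}
        matches = pdx.find_similar_blocks(q, genome, min_seed=20, max_variants=0)
        assert all(m.variant_bases == 0 for m in matches)
        assert any(m.start == 1 for m in matches)

    def test_empty_subject(self):
        assert pdx.find_similar_blocks("ACGT" * 10, {}, min_seed=20) == []


class TestFilterCandidateBlocks:
    def block(self, variants, spans=None, chrom="chr21", n=None):
        spans = spans or [150] * len(variants)
        b = pdx.CandidateBlock(chrom="chr21", start=1, end=150)
        b.matches = [
            pdx.BlockMatch(chrom=chrom, start=1000 * (i + 1),
                           end=1000 * (i + 1) + s - 1, variant_bases=v, span=s)
            for i, (v, s) in enumerate(zip(variants, spans))
        ]
        return b

    def test_canonical_pass(self):
        b = self.block([12, 15, 20])
        assert pdx.filter_candidate_blocks([b]) == [b]

    def test_too_few_variants_fails(self):
        b = self.block([12, 15, 10])
        assert pdx.filter_candidate_blocks([b]) == []

    def test_span_boundary(self):
        ok = self.block([12, 15, 20], spans=[180, 150, 150])
        bad = self.block([12, 15, 20], spans=[181, 150, 150])
        assert pdx.filter_candidate_blocks([ok, bad]) == [ok]

    def test_sibling_requirement(self):
        b = self.block([12, 15])  # only two same-chromosome matches
        assert pdx.filter_candidate_blocks([b]) == []
        other = self.block([12, 15, 20], chrom="chr1")
        assert pdx.filter_candidate_blocks([other]) == []


class TestDistinctness:
    def test_confusable_pair_not_counted(self):
        assert pdx.distinctness_under_errors(["AAAA", "AAAT"], e=1) == 0

    def test_distance_five_survives_two_errors(self):
        assert pdx.distinctness_under_errors(["AAAAA", "TTTTT"], e=2) == 2

    def test_random_150mers_all_distinct(self):
        rng = np.random.default_rng(7)
        seqs = [random_seq(rng, 150) for _ in range(100)]
        assert pdx.distinctness_under_errors(seqs, e=3) == 100

    def test_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        base = random_seq(rng, 30)
        seqs = [base]
        for _ in range(20):
            s = list(seqs[rng.integers(0, len(seqs))])
            for _ in range(rng.integers(1, 6)):
                s[rng.integers(0, 30)] = str(rng.choice(BASES))
            seqs.append("".join(s))
        for e in (1, 2, 3):
            expected = sum(
                all(sum(a != b for a, b in zip(s, t)) > 2 * e
                    for j, t in enumerate(seqs) if j != i)
                for i, s in enumerate(seqs)
            )
            assert pdx.distinctness_under_errors(seqs, e) == expected

    @given(st.lists(st.text(alphabet="ACGT", min_size=12, max_size=12),
                    min_size=2, max_size=15))
    def test_monotone_nonincreasing_in_e(self, seqs):
        counts = [pdx.distinctness_under_errors(seqs, e) for e in (0, 1, 2, 3)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pdx.distinctness_under_errors(["AAA", "AAAA"], e=1)


class TestPredictAmplicons:
    FWD = "ACGTACGTACGTACGTTTGA"
    REV = "CCGGAATTCCGGAATTGGCC"

    def genome_with_inserts(self, lengths, rng):
        rc_rev = str(Seq(self.REV).reverse_complement())
        chunks, truth = [], []
        pos = 0
        for L in lengths:
            pad = random_seq(rng, 800)
            insert = random_seq(rng, L - len(self.FWD) - len(self.REV))
            amp = self.FWD + insert + rc_rev
            chunks.append(pad + amp)
            truth.append((pos + len(pad) + 1, L))
            pos += len(pad) + len(amp)
        chunks.append(random_seq(rng, 500))
        return {"c1": "".join(chunks)}, truth

    def test_planted_inserts_recovered_exactly(self):
        rng = np.random.default_rng(10)
        lengths = list(range(120, 146, 3))[:10]
        genome, truth = self.genome_with_inserts(lengths, rng)
        pair = pdx.PrimerPair(self.FWD, self.REV, max_product=200)
        amps = pdx.predict_amplicons(pair, genome)
        found = {(a.start, a.product_len) for a in amps if a.strand == "+"}
        assert set(truth) <= found
        assert len([a for a in amps if a.strand == "+"]) == len(truth)

    def test_product_longer_than_max_not_reported(self):
        rng = np.random.default_rng(11)
        genome, truth = self.genome_with_inserts([300], rng)
        pair = pdx.PrimerPair(self.FWD, self.REV, max_product=200)
        assert pdx.predict_amplicons(pair, genome) == []

    def test_mismatch_budget(self):
        rng = np.random.default_rng(12)
        genome, truth = self.genome_with_inserts([140], rng)
        seq = genome["c1"]
        start = truth[0][0] - 1
        # plant one internal mismatch in the fwd site (not the 3' terminus)
        mutated = (seq[:start + 5]
                   + ("A" if seq[start + 5] != "A" else "C")
                   + seq[start + 6:])
        genome = {"c1": mutated}
        pair = pdx.PrimerPair(self.FWD, self.REV, max_product=200)
        assert pdx.predict_amplicons(pair, genome, max_mm_per_primer=0) == []
        hits = pdx.predict_amplicons(pair, genome, max_mm_per_primer=1)
        assert [(a.start, a.product_len) for a in hits] == [truth[0]]

    def test_three_prime_terminus_must_match(self):
        rng = np.random.default_rng(13)
        genome, truth = self.genome_with_inserts([140], rng)
        seq = genome["c1"]
        tpos = truth[0][0] - 1 + len(self.FWD) - 1  # fwd 3' terminal base
        genome = {"c1": seq[:tpos] + ("A" if seq[tpos] != "A" else "C")
                  + seq[tpos + 1:]}
        pair = pdx.PrimerPair(self.FWD, self.REV, max_product=200)
        assert pdx.predict_amplicons(pair, genome, max_mm_per_primer=2) == []

    def test_iupac_degenerate_primer_matches(self):
        rng = np.random.default_rng(14)
        genome, truth = self.genome_with_inserts([140], rng)
        degenerate = "N" + self.FWD[1:10] + "R" + self.FWD[11:] \
            if self.FWD[10] in "AG" else "N" + self.FWD[1:]
        pair = pdx.PrimerPair(degenerate, self.REV, max_product=200)
        hits = pdx.predict_amplicons(pair, genome)
        assert [(a.start, a.product_len) for a in hits] == [truth[0]]

    def test_strand_symmetry(self):
        """Reverse-complementing the subject mirrors every amplicon."""
        rng = np.random.default_rng(15)
        genome, _ = self.genome_with_inserts([125, 140], rng)
        pair = pdx.PrimerPair(self.FWD, self.REV, max_product=200)
        fwd_hits = pdx.predict_amplicons(pair, genome)
        n = len(genome["c1"])
        rc = {"c1": str(Seq(genome["c1"]).reverse_complement())}
        rc_hits = pdx.predict_amplicons(pair, rc)
        mirrored = {
            (n - a.end + 1, n - a.start + 1, a.product_len,
             "-" if a.strand == "+" else "+")
            for a in fwd_hits
        }
        assert {(a.start, a.end, a.product_len, a.strand)
                for a in rc_hits} == mirrored

    def test_invalid_primer_rejected(self):
        with pytest.raises(ValueError):
            pdx.PrimerPair("ACGTX", "ACGT")
        with pytest.raises(ValueError):
            pdx.PrimerPair("", "ACGT")


class TestScanWorkflow:
    def test_repeat_family_scan_finds_planted_siblings(self):
        """A dispersed repeat with moderate divergence passes the filters."""
        rng = np.random.default_rng(20)
        consensus = random_seq(rng, 150)

        def diverged(n_subs):
            s = list(consensus)
            for p in rng.choice(150, size=n_subs, replace=False):
                s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
            return "".join(s)

        # query region holds the pristine copy; 4 siblings on chr21 carry
        # 12-20 substitutions each
        chr21 = (random_seq(rng, 400) + consensus + random_seq(rng, 400)
                 + diverged(12) + random_seq(rng, 300) + diverged(15)
                 + random_seq(rng, 300) + diverged(18) + random_seq(rng, 300)
                 + diverged(20) + random_seq(rng, 200))
        genome = {"chr21": chr21}
        blocks = pdx.scan_candidate_blocks(
            genome, "chr21", 401, 550, window=150, step=50)
        assert len(blocks) == 1
        passing = pdx.filter_candidate_blocks(blocks)
        assert passing and passing[0].n_same_chrom >= 4
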