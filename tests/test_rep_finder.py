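import numpy as np
import pytest

from sorfscape.genome_io import GenomeRecord, IgrSet, reverse_complement
from sorfscape.rep_finder import (
    BR_REP1_CONSENSUS,
    BR_REP2_CONSENSUS,
    RepeatConsensus,
    RepeatHit,
    derive_consensus,
    discover_repeats,
    find_palindromes,
    nussinov_fold,
    palindrome_mismatches,
    restrict_to_igr,
    scan_consensus,
)


def random_genome(rng, n, gc=0.64, seq_id="g"):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return GenomeRecord(seq_id, "".join(rng.choice(list("ACGT"), size=n, p=p)))


class TestPalindromeMismatches:
    @pytest.mark.parametrize(
        "seq,count",
        [
            (BR_REP1_CONSENSUS, 0),  # the 20-nt stem-loop consensus is perfect
            ("ACGT", 0),
            ("AAAA", 2),
        ],
    )
    def test_examples(self, seq, count):
        assert palindrome_mismatches(seq) == count

    def test_perfect_palindromes_score_zero(self, rng):
        for _ in range(20):
            arm = "".join(rng.choice(list("ACGT"), size=8))
            assert palindrome_mismatches(arm + reverse_complement(arm)) == 0

    def test_odd_length_center_ignored(self):
        assert palindrome_mismatches("ACGAT") == palindrome_mismatches("ACAT")


class TestFindPalindromes:
    def test_embedded_rep_stem_found(self):
        genome = GenomeRecord("g", "G" * 6 + BR_REP1_CONSENSUS + "G" * 6)
        hits = find_palindromes(genome)
        best = max(hits, key=lambda h: h.arm_len)
        assert (best.arm_len, best.loop_len, best.arm_mismatches) == (8, 4, 0)
        assert (best.start, best.end) == (6, 26)

    def test_poly_a_has_no_hits(self):
        assert find_palindromes(GenomeRecord("g", "A" * 60)) == []

    def test_matches_brute_force_enumeration(self, rng):
        genome = random_genome(rng, 2000)

        def brute():
            out = set()
            s = genome.sequence
            for arm in range(6, 13):
                for loop in range(3, 9):
                    w = 2 * arm + loop
                    for i in range(len(s) - w + 1):
                        window = s[i: i + w]
                        mism = sum(
                            window[k] != reverse_complement(window[-1 - k])
                            for k in range(arm)
                        )
                        if mism <= 1:
                            out.add((i + arm, i + arm + loop))  # loop interval
            return out

        got = {(h.start + h.arm_len, h.start + h.arm_len + h.loop_len)
               for h in find_palindromes(genome)}
        assert got == brute()


class TestScanConsensus:
    def test_exact_consensus_once_strand_both(self, rng):
        genome = GenomeRecord("g", "A" * 50 + BR_REP1_CONSENSUS + "A" * 50)
        cons = RepeatConsensus("br1", BR_REP1_CONSENSUS, max_mismatches=0)
        hits = scan_consensus(genome, cons)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand, hits[0].n_mismatches) == (50, "both", 0)

    def test_zero_mismatch_scan_equals_substring_search(self, rng):
        genome = random_genome(rng, 50_000)
        motif = "ACGGATTACGGCATCGAATC"
        cons = RepeatConsensus("m", motif, max_mismatches=0)
        hits = scan_consensus(genome, cons)
        expected = set()
        for probe, _ in ((motif, "+"), (reverse_complement(motif), "-")):
            start = genome.sequence.find(probe)
            while start != -1:
                expected.add(start)
                start = genome.sequence.find(probe, start + 1)
        assert {h.start for h in hits} == expected

    def test_mismatch_monotonicity(self, rng):
        genome = random_genome(rng, 20_000)
        starts = {}
        for mm in (0, 1, 2, 3):
            cons = RepeatConsensus("m", "ACGGATTACGGCATCGAATC", max_mismatches=mm)
            starts[mm] = {h.start for h in scan_consensus(genome, cons)}
        assert starts[0] <= starts[1] <= starts[2] <= starts[3]

    def test_hits_verified_within_hamming_distance(self, rng):
        genome = random_genome(rng, 30_000)
        cons = RepeatConsensus("m", "ACGGATTACGGCATCGAATC", max_mismatches=3)
        for h in scan_consensus(genome, cons):
            window = genome.sequence[h.start: h.end]
            d_fwd = sum(a != b for a, b in zip(window, cons.sequence))
            d_rev = sum(
                a != b
                for a, b in zip(window, reverse_complement(cons.sequence))
            )
            assert min(d_fwd, d_rev) == h.n_mismatches <= 3

    def test_iupac_codes_match_denoted_bases(self):
        genome = GenomeRecord("g", "AAAACGTAAAAAAAAAAAAAAAAAA")
        cons = RepeatConsensus("m", "AAAASGTAAAAAAA", max_mismatches=0)
        hits = scan_consensus(genome, cons)
        assert any(h.start == 0 for h in hits)

    def test_n_in_genome_never_matches(self):
        genome = GenomeRecord("g", "N" * 40)
        cons = RepeatConsensus("m", "A" * 12, max_mismatches=2)
        assert scan_consensus(genome, cons) == []


class TestRestrictToIgr:
    def test_full_containment_rule(self):
        igrs = IgrSet("g", [(100, 200)])
        hits = [
            RepeatHit("g", 150, 170, "+", 0),
            RepeatHit("g", 95, 115, "+", 0),  # straddles the gene/IGR boundary
        ]
        hits, count = restrict_to_igr(hits, igrs)
        assert [h.in_igr for h in hits] == [True, False]
        assert count == 1

    def test_seq_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            restrict_to_igr([RepeatHit("other", 0, 10, "+", 0)], IgrSet("g", [(0, 50)]))


class TestNussinovFold:
    def test_simple_hairpin(self):
        fold = nussinov_fold("GGGAAACCC")
        assert fold.n_pairs == 3
        assert fold.structure == "(((...)))"

    def test_unpairable_sequence(self):
        assert nussinov_fold("AAAAAAAAAA").n_pairs == 0

    def test_rep1_folds_with_eight_pair_stem(self):
        fold = nussinov_fold(BR_REP1_CONSENSUS)
        assert fold.n_pairs >= 8
        assert fold.structure == "((((((((....))))))))"

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            nussinov_fold("ACG")
        with pytest.raises(ValueError):
            nussinov_fold("A" * 300)

    def test_loop_floor_and_pair_bound(self, rng):
        for _ in range(20):
            L = int(rng.integers(10, 40))
            seq = "".join(rng.choice(list("ACGU"), size=L))
            fold = nussinov_fold(seq)
            assert fold.n_pairs <= (L - 3) // 2
            # balanced brackets with no loop shorter than 3
            stack = []
            for i, c in enumerate(fold.structure):
                if c == "(":
                    stack.append(i)
                elif c == ")":
                    j = stack.pop()
                    assert i - j - 1 >= 3 or any(
                        fold.structure[k] in "()" for k in range(j + 1, i)
                    )
            assert not stack

    def test_matches_exhaustive_enumeration_small(self, rng):
        def exhaustive(seq, min_loop=3):
            pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                     ("G", "T"), ("T", "G")}
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def best(i, j):
                if j - i <= min_loop:
                    return 0
                options = [best(i + 1, j)]
                for k in range(i + min_loop + 1, j + 1):
                    if (seq[i], seq[k]) in pairs:
                        options.append(
                            1
                            + (best(i + 1, k - 1) if k - 1 > i + 1 else 0)
                            + (best(k + 1, j) if k + 1 <= j else 0)
                        )
                return max(options)

            return best(0, len(seq) - 1)

        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=12))
            assert nussinov_fold(seq).n_pairs == exhaustive(seq)


class TestDeriveConsensus:
    def test_majority(self):
        assert derive_consensus(["ACGT", "ACGT", "ACGA"]) == "ACGT"

    def test_tie_gives_iupac_code(self):
        assert derive_consensus(["ACAAAAAAAA", "AGAAAAAAAA"]) == "ASAAAAAAAA"

    def test_single_instance_rejected(self):
        with pytest.raises(ValueError):
            derive_consensus(["ACGT"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            derive_consensus(["ACGT", "ACG"])


class TestDiscoverRepeats:
    def _genome_with_igrs(self, rng, n_igrs=16, igr_len=300):
        # alternating "gene" blocks and IGRs; genes cover everything else
        from sorfscape.genome_io import FeatureRecord, compute_igrs

        pieces, feats, cursor = [], [], 0
        for i in range(n_igrs):
            gene = "".join(rng.choice(list("ACGT"), size=400))
            pieces.append(gene)
            feats.append(FeatureRecord("g", cursor, cursor + 400, "+", "gene", f"x{i}"))
            cursor += 400
            pieces.append("".join(rng.choice(list("ACGT"), size=igr_len)))
            cursor += igr_len
        gene = "".join(rng.choice(list("ACGT"), size=400))
        pieces.append(gene)
        feats.append(FeatureRecord("g", cursor, cursor + 400, "+", "gene", "xe"))
        genome = GenomeRecord("g", "".join(pieces))
        return genome, feats, compute_igrs(feats, genome)

    def test_planted_family_recovered(self, rng):
        genome, feats, igrs = self._genome_with_igrs(rng)
        seq = list(genome.sequence)
        for s, e in igrs.intervals[:15]:
            seq[s + 50: s + 70] = list(BR_REP1_CONSENSUS)
        genome = GenomeRecord("g", "".join(seq))
        from sorfscape.genome_io import compute_igrs

        igrs = compute_igrs(feats, genome)
        candidates = discover_repeats(genome, igrs, k=20, min_igr_count=10)
        assert len(candidates) == 1
        got = candidates[0].consensus.sequence
        assert got in (BR_REP1_CONSENSUS, reverse_complement(BR_REP1_CONSENSUS))
        assert candidates[0].n_igr_occurrences == 15

    def test_no_repeats_no_candidates(self, rng):
        genome, _, igrs = self._genome_with_igrs(rng)
        assert discover_repeats(genome, igrs, k=20, min_igr_count=10) == []

    def test_two_distant_families_not_merged(self, rng):
        fam_a = BR_REP1_CONSENSUS
        fam_b = "ATTCCGGGTTCGGCTCTTCG"  # differs from fam_a at >8 positions
        assert sum(a != b for a, b in zip(fam_a, fam_b)) > 8
        genome, feats, igrs = self._genome_with_igrs(rng)
        seq = list(genome.sequence)
        for s, e in igrs.intervals[:12]:
            seq[s + 10: s + 30] = list(fam_a)
            seq[s + 100: s + 120] = list(fam_b)
        genome = GenomeRecord("g", "".join(seq))
        from sorfscape.genome_io import compute_igrs

        igrs = compute_igrs(feats, genome)
        candidates = discover_repeats(genome, igrs, k=20, min_igr_count=10)
        consensuses = {
            min(c.consensus.sequence, reverse_complement(c.consensus.sequence))
            if set(c.consensus.sequence) <= set("ACGT") else c.consensus.sequence
            for c in candidates
        }
        assert min(fam_a, reverse_complement(fam_a)) in consensuses
        assert min(fam_b, reverse_complement(fam_b)) in consensuses
        assert len(candidates) == 2


class TestPublishedConsensuses:
    def test_rep2_central_palindrome_is_imperfect(self):
        from sorfscape.rep_finder import BR_REP2_CORE

        assert len(BR_REP2_CONSENSUS) == 40
        assert palindrome_mismatches(BR_REP2_CORE) > 0  # imperfect by design
        assert nussinov_fold(BR_REP2_CORE).n_pairs >= 10
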