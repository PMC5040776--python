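
import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from sncrnakit.homology import (
    DEFAULT_SCHEME,
    MIRNA_PRESET,
    ScoringScheme,
    best_identity,
    evalue,
    extend_seed,
    find_seeds,
    reverse_complement,
    search,
    smith_waterman,
)
from sncrnakit.io import Contig

DNA = st.text(alphabet="ACGT", min_size=1, max_size=60)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_seeds(query, subject, w):
    """Exhaustive w-mer scan on both strands (reference implementation)."""
    out = []
    for strand, oriented in (("+", query), ("-", reverse_complement(query))):
        for q in range(len(oriented) - w + 1):
            word = oriented[q : q + w]
            if "N" in word:
                continue
            for s in range(len(subject) - w + 1):
                if subject[s : s + w] == word:
                    out.append((q, s, strand))
    return sorted(out, key=lambda t: (t[2], t[0], t[1]))


class TestReverseComplement:
    def test_known_values(self):
        assert reverse_complement("ACGT") == "ACGT"
        assert reverse_complement("AAAC") == "GTTT"
        assert reverse_complement("ANT") == "ANT"

    @given(DNA)
    @settings(max_examples=50, derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestFindSeeds:
    def test_verbatim_embedding_yields_plus_seed(self):
        rng = np.random.default_rng(1)
        q = random_dna(rng, 22)
        subject = random_dna(rng, 200) + q + random_dna(rng, 200)
        seeds = find_seeds(q, subject, 19)
        assert any(s == "+" for _, _, s in seeds)

    def test_reverse_complement_embedding_yields_minus_seeds_only(self):
        rng = np.random.default_rng(2)
        q = random_dna(rng, 30)
        subject = random_dna(rng, 200) + reverse_complement(q) + random_dna(rng, 200)
        seeds = find_seeds(q, subject, 19)
        strands = {s for _, _, s in seeds}
        assert strands == {"-"}

    @pytest.mark.parametrize("w, qlen, slen", [(19, 20, 3000), (7, 25, 300)])
    def test_equals_brute_force_scan(self, w, qlen, slen):
        rng = np.random.default_rng(w * 100 + qlen)
        q = random_dna(rng, qlen)
        subject = random_dna(rng, slen)
        # embed fragments to guarantee matches at small w
        subject = subject[: slen // 2] + q + subject[slen // 2 :]
        assert find_seeds(q, subject, w) == brute_force_seeds(q, subject, w)

    def test_n_never_matches_even_itself(self):
        q = "ACGTACGTNNACGTACGTAC"
        subject = "TTT" + q + "TTT"
        assert all(
            "N" not in q[qp : qp + 10] for qp, _, s in find_seeds(q, subject, 10)
            if s == "+"
        )

    def test_word_longer_than_query_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning):
            assert find_seeds("ACGTACGT", "ACGTACGTACGT", 19) == []


def biopython_local(a, b, scheme=DEFAULT_SCHEME):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner.score(a, b)


class TestSmithWaterman:
    def test_identical_sequences_score_full_match(self):
        aln = smith_waterman("ACGTAC", "ACGTAC")
        assert aln.score == 6 * DEFAULT_SCHEME.match
        assert aln.identity == 100.0

    def test_disjoint_alphabets_give_empty_alignment(self):
        scheme = ScoringScheme(match=1, mismatch=-2)
        aln = smith_waterman("AAAA", "TTTT", scheme)
        assert aln.score == 0 and aln.aln_len == 0

    @pytest.mark.parametrize("seed", [3, 7, 13, 29])
    def test_score_matches_independent_dp(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, 30)
        b = random_dna(rng, 300)
        assert smith_waterman(a, b).score == pytest.approx(biopython_local(a, b))

    def test_score_matches_oracle_with_gapped_homology(self):
        rng = np.random.default_rng(41)
        core = random_dna(rng, 60)
        a = core
        b = random_dna(rng, 50) + core[:30] + "GGGG" + core[30:] + random_dna(rng, 50)
        assert smith_waterman(a, b).score == pytest.approx(biopython_local(a, b))

    def test_size_guard(self):
        with pytest.raises(ValueError, match="5000"):
            smith_waterman("A" * 5001, "ACGT")


class TestExtendSeed:
    def test_exact_embedding_gives_full_identity(self):
        rng = np.random.default_rng(4)
        q = random_dna(rng, 22)
        subject = random_dna(rng, 100) + q + random_dna(rng, 100)
        seeds = find_seeds(q, subject, 19)
        hit = extend_seed(seeds[0], q, subject)
        assert hit.identity == 100.0
        assert hit.aln_len == 22
        assert subject[hit.s_start : hit.s_end] == q

    def test_single_substitution_drops_one_match(self):
        rng = np.random.default_rng(5)
        q = random_dna(rng, 60)
        mutated = q[:30] + ("A" if q[30] != "A" else "C") + q[31:]
        subject = random_dna(rng, 100) + mutated + random_dna(rng, 100)
        seeds = find_seeds(q, subject, 19)
        hit = extend_seed(seeds[0], q, subject)
        assert hit.matches == len(q) - 1
        assert hit.aln_len == len(q)

    def test_identity_close_to_smith_waterman_on_mutated_pairs(self):
        rng = np.random.default_rng(6)
        worst = 0.0
        tested = 0
        for _ in range(50):
            q = random_dna(rng, int(rng.integers(40, 120)))
            arr = list(q)
            for i in range(len(arr)):
                if rng.random() < 0.08:
                    arr[i] = "ACGT"[int(rng.integers(4))]
            subject = random_dna(rng, 400) + "".join(arr) + random_dna(rng, 400)
            seeds = find_seeds(q, subject, DEFAULT_SCHEME.word_size)
            if not seeds:
                continue
            hits = search(q, [Contig("s", subject)], MIRNA_PRESET)
            if not hits:
                continue
            oracle = smith_waterman(q, subject)
            worst = max(worst, abs(hits[0].identity - oracle.identity))
            tested += 1
        assert tested >= 25
        assert worst <= 2.0


class TestSearch:
    def make_genome(self, rng, q, n=50000):
        pos = 20000
        background = random_dna(rng, n)
        seq = background[:pos] + q + background[pos + len(q) :]
        return [Contig("c1", seq)], pos

    def test_planted_exact_copy_found_once_at_locus(self):
        rng = np.random.default_rng(8)
        q = random_dna(rng, 100)
        genome, pos = self.make_genome(rng, q)
        hits = search(q, genome)
        assert len(hits) == 1
        assert hits[0].identity == 100.0
        assert (hits[0].s_start, hits[0].s_end) == (pos, pos + 100)
        assert hits[0].evalue <= DEFAULT_SCHEME.evalue_cutoff

    def test_no_shared_word_means_no_hits(self):
        q = "A" * 30
        genome = [Contig("c1", "CGT" * 5000)]
        assert search(q, genome) == []

    def test_hits_at_word_20_are_subset_of_word_19(self):
        rng = np.random.default_rng(9)
        q = random_dna(rng, 80)
        arr = list(q)
        for i in range(0, len(arr), 23):
            arr[i] = "ACGT"[int(rng.integers(4))]
        subject = random_dna(rng, 5000) + "".join(arr) + random_dna(rng, 5000)
        genome = [Contig("c1", subject)]
        h19 = {
            (h.subject_id, h.s_start, h.s_end, h.strand)
            for h in search(q, genome, ScoringScheme(word_size=19))
        }
        h20 = {
            (h.subject_id, h.s_start, h.s_end, h.strand)
            for h in search(q, genome, ScoringScheme(word_size=20))
        }
        assert h20 <= h19

    def test_hit_count_non_increasing_in_word_size(self):
        rng = np.random.default_rng(10)
        q = random_dna(rng, 60)
        subject = random_dna(rng, 2000) + q + random_dna(rng, 2000)
        genome = [Contig("c1", subject)]
        counts = [
            len(search(q, genome, ScoringScheme(word_size=w)))
            for w in (16, 19, 22, 25)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(12)
        q = random_dna(rng, 70)
        subject = (
            random_dna(rng, 1000)
            + q
            + random_dna(rng, 1000)
            + reverse_complement(q)
            + random_dna(rng, 1000)
        )
        genome = [Contig("c1", subject)]
        fwd = search(q, genome)
        rev = search(reverse_complement(q), genome)
        flip = {"+": "-", "-": "+"}
        assert {(h.s_start, h.s_end, h.strand) for h in fwd} == {
            (h.s_start, h.s_end, flip[h.strand]) for h in rev
        }

    def test_results_sorted_and_deduplicated(self):
        rng = np.random.default_rng(14)
        q = random_dna(rng, 50)
        subject = random_dna(rng, 500) + q + random_dna(rng, 500) + q
        hits = search(q, [Contig("c1", subject)])
        keys = [(h.subject_id, h.s_start, h.s_end, h.strand) for h in hits]
        assert len(keys) == len(set(keys))
        evs = [h.evalue for h in hits]
        assert evs == sorted(evs)


class TestEvalue:
    def test_decreases_with_score(self):
        e = [evalue(s, 100, 1e5, DEFAULT_SCHEME) for s in (20, 40, 60)]
        assert e[0] > e[1] > e[2] >= 0

    def test_doubles_with_subject_size(self):
        e1 = evalue(50, 100, 1e5, DEFAULT_SCHEME)
        e2 = evalue(50, 100, 2e5, DEFAULT_SCHEME)
        assert e2 == pytest.approx(2 * e1)


class TestBestIdentity:
    def test_zero_when_nothing_passes(self):
        genome = [Contig("c1", "CGT" * 4000)]
        assert best_identity("A" * 40, genome) == 0.0

    def test_hundred_for_exact_planted_copy(self):
        rng = np.random.default_rng(15)
        q = random_dna(rng, 120)
        genome = [Contig("c1", random_dna(rng, 3000) + q + random_dna(rng, 3000))]
        assert best_identity(q, genome) == 100.0

    def test_tracks_applied_substitution_fraction(self):
        rng = np.random.default_rng(16)
        q = random_dna(rng, 200)
        arr = list(q)
        n_subs = 0
        for i in range(len(arr)):
            if rng.random() < 0.1:
                old = arr[i]
                arr[i] = "ACGT"[(("ACGT".index(old)) + 1) % 4]
                n_subs += 1
        genome = [
            Contig("c1", random_dna(rng, 5000) + "".join(arr) + random_dna(rng, 5000))
        ]
        expected = 100.0 * (1 - n_subs / len(q))
        assert best_identity(q, genome) == pytest.approx(expected, abs=5.0)
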