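"""Ordering strategies, minimizer selection, super-mer decomposition."""

import itertools

import numpy as np
import pytest

from minicount import build_ordering, encode, minimizer_of, super_mers
from minicount.minimizers import _window_minimizers, sample_frequencies
from minicount import ReadRecord

from conftest import random_dna

BASES = "ACGT"


def all_mmers(m):
    return ["".join(t) for t in itertools.product(BASES, repeat=m)]


class TestBuildOrdering:
    def test_cgat_m1(self):
        ranks = build_ordering("cgat", 1).rank
        # rank indexed by code A,C,G,T; C<G<A<T
        assert ranks.tolist() == [2, 0, 1, 3]

    def test_random_seeded_determinism(self):
        a = build_ordering("random", 3, seed=5).rank
        b = build_ordering("random", 3, seed=5).rank
        c = build_ordering("random", 3, seed=6).rank
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("strategy", ["lex", "cgat", "roberts", "kmc2", "random", "dfp"])
    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    def test_bijection(self, strategy, m):
        kwargs = {}
        if strategy == "random":
            kwargs["seed"] = 3
        if strategy == "dfp":
            rng = np.random.default_rng(3)
            kwargs["frequencies"] = rng.integers(0, 50, size=4**m)
            kwargs["pivot"] = 0.8
        rank = build_ordering(strategy, m, **kwargs).rank
        assert np.array_equal(np.sort(rank), np.arange(4**m))

    def test_kmc2_demotes_aaa_aca_prefixes(self):
        ordering = build_ordering("kmc2", 3)
        ranks = {mm: int(ordering.rank[i]) for i, mm in enumerate(all_mmers(3))}
        demoted = {"AAA", "ACA"}
        allowed = [mm for mm in all_mmers(3) if mm not in demoted]
        assert max(ranks[mm] for mm in allowed) < min(ranks[mm] for mm in demoted)
        # relative order stays lexicographic in both classes
        assert sorted(allowed, key=ranks.get) == allowed
        assert sorted(demoted, key=ranks.get) == sorted(demoted)

    def test_roberts_matches_reference(self):
        # Independent reference: complement even positions, sort by C<A<T<G.
        key_order = {"C": 0, "A": 1, "T": 2, "G": 3}
        comp = str.maketrans("ACGT", "TGCA")

        def key(mm):
            transformed = "".join(
                ch.translate(comp) if i % 2 == 0 else ch for i, ch in enumerate(mm)
            )
            return [key_order[ch] for ch in transformed]

        expected = {mm: r for r, mm in enumerate(sorted(all_mmers(3), key=key))}
        ordering = build_ordering("roberts", 3)
        for i, mm in enumerate(all_mmers(3)):
            assert int(ordering.rank[i]) == expected[mm], mm

    @pytest.mark.parametrize("pivot", [0.0, 0.5, 1.0])
    def test_dfp_matches_reference(self, pivot):
        m = 2
        rng = np.random.default_rng(31)
        freqs = rng.integers(0, 20, size=16)
        mmers = all_mmers(m)
        initial = sorted(range(16), key=lambda v: (freqs[v], v))
        pos = {v: i for i, v in enumerate(initial)}
        resorted = sorted(range(16), key=lambda v: (abs(pos[v] - 16 * pivot), v))
        expected = {v: r for r, v in enumerate(resorted)}
        rank = build_ordering("dfp", m, frequencies=freqs, pivot=pivot).rank
        assert {v: int(rank[v]) for v in range(16)} == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            build_ordering("nope", 3)
        with pytest.raises(ValueError):
            build_ordering("lex", 0)
        with pytest.raises(ValueError):
            build_ordering("dfp", 3)  # missing frequencies
        with pytest.raises(ValueError):
            build_ordering("random", 3)  # missing seed


class TestSampleFrequencies:
    def test_single_read(self):
        freq = sample_frequencies([ReadRecord("r", "AAAA")], 3)
        assert freq[0] == 2  # AAA twice
        assert freq.sum() == 2

    def test_empty_stream(self):
        assert sample_frequencies([], 3).sum() == 0

    def test_conservation(self):
        rng = np.random.default_rng(7)
        reads = [ReadRecord(f"r{i}", random_dna(rng, 50)) for i in range(20)]
        freq = sample_frequencies(reads, 4)
        assert freq.sum() == 20 * (50 - 4 + 1)

    def test_sample_size_limits_fragments(self):
        reads = [ReadRecord("a", "ACGTACGT"), ReadRecord("b", "ACGTACGT")]
        full = sample_frequencies(reads, 3)
        half = sample_frequencies(reads, 3, sample_size=1)
        assert half.sum() == full.sum() // 2


class TestMinimizerOf:
    def test_examples_lex(self, lex3):
        assert str(minimizer_of(encode("CAAG"), lex3)[0]) == "AAG"
        assert str(minimizer_of(encode("AAAA"), lex3)[0]) == "AAA"
        assert str(minimizer_of(encode("ACAG"), lex3)[0]) == "ACA"

    def test_k_less_than_m(self, lex3):
        with pytest.raises(ValueError):
            minimizer_of(encode("AC"), lex3)

    def test_canonical_mode_strand_invariant_rank(self, lex3):
        rng = np.random.default_rng(2)
        for _ in range(200):
            x = encode(random_dna(rng, 9))
            _, r1 = minimizer_of(x, lex3, canonical_mode=True)
            _, r2 = minimizer_of(x.reverse_complement(), lex3, canonical_mode=True)
            assert r1 == r2


class TestSuperMers:
    def test_worked_example(self, lex3):
        sms = super_mers(encode("CAAGAACAGTG"), 4, lex3, canonical_mode=False)
        assert [str(s.bases) for s in sms] == ["CAAGA", "AGAA", "GAACA", "ACAG", "CAGTG"]

    def test_fragment_of_length_k(self, lex3):
        sms = super_mers(encode("ACGT"), 4, lex3)
        assert len(sms) == 1 and str(sms[0].bases) == "ACGT"
        assert sms[0].kmer_count == 1

    def test_too_short_rejected(self, lex3):
        with pytest.raises(ValueError):
            super_mers(encode("ACG"), 4, lex3)

    @pytest.mark.parametrize("canonical_mode", [False, True])
    def test_kmer_conservation_random_fragments(self, lex3, canonical_mode):
        rng = np.random.default_rng(7)
        k = 8
        for _ in range(100):
            frag = encode(random_dna(rng, int(rng.integers(k, 120))))
            sms = super_mers(frag, k, lex3, canonical_mode)
            assert sum(s.kmer_count for s in sms) == frag.length - k + 1
            # reconstructed window scan equals the direct scan, once each
            windows = [
                str(s.bases)[j : j + k]
                for s in sms
                for j in range(s.bases.length - k + 1)
            ]
            direct = [str(frag)[j : j + k] for j in range(frag.length - k + 1)]
            assert windows == direct

    def test_runs_match_minimizer_occurrences(self, lex3):
        rng = np.random.default_rng(8)
        frag = encode(random_dna(rng, 200))
        k = 10
        occ, rank, _ = _window_minimizers(frag.codes, k, lex3, False)
        sms = super_mers(frag, k, lex3, False)
        # decomposition boundaries are exactly the occurrence changes
        runs = 1 + int(np.count_nonzero(np.diff(occ)))
        assert len(sms) == runs
        w = 0
        for s in sms:
            span = occ[w : w + s.kmer_count]
            assert np.all(span == span[0])  # one occurrence per super-mer
            if w + s.kmer_count < occ.size:
                assert occ[w + s.kmer_count] != span[0]  # adjacent runs differ
            assert int(rank[w]) == s.minimizer_rank
            w += s.kmer_count
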