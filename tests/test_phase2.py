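"""Hash functions, table insertion, pass planning, and per-bin counting."""

from collections import Counter

import numpy as np
import pytest
import scipy.stats

from minicount import (
    AlphaEstimator,
    CountTable,
    InsertStatus,
    Phase1Config,
    Phase2Config,
    ReadRecord,
    build_ordering,
    count_bin,
    encode,
    part_hash,
    plan_passes,
    probe_hash,
    run_phase1,
    shard_id,
    table_size,
    update_alpha,
)
from minicount.phase2 import FailureBuffer, part_hash_vec, probe_hash0, probe_hash0_vec
from minicount.simulate import oracle_count

from conftest import random_dna, random_kmer_words


class TestProbeHash:
    def test_deterministic(self):
        x = encode("ACGTACGTACGTACGTACGTACGTACGT")
        assert probe_hash(x, 3) == probe_hash(x, 3)
        assert probe_hash(x, 0) != probe_hash(x, 1)

    def test_scalar_matches_vectorized(self):
        rng = np.random.default_rng(5)
        for k in (28, 40, 64, 200):
            words = random_kmer_words(rng, 50, k)
            vec = probe_hash0_vec(words)
            for j in range(50):
                assert probe_hash0(words[j]) == int(vec[j])

    def test_quadratic_schedule_coverage_pow2(self):
        # over a power-of-two table the triangular schedule revisits little
        T = 1024
        x = encode("ACGTACGTACGTACGTACGTACGTACGT")
        slots = {probe_hash(x, i) % T for i in range(T)}
        assert len(slots) >= T // 2

    def test_single_base_avalanche(self):
        rng = np.random.default_rng(5)
        T = 1 << 20
        n = 10_000
        codes = rng.integers(0, 4, size=(n, 28)).astype(np.uint8)
        mutated = codes.copy()
        pos = rng.integers(0, 28, size=n)
        mutated[np.arange(n), pos] = (mutated[np.arange(n), pos] + rng.integers(1, 4, n)) % 4
        from minicount.packing import codes_to_words

        h_a = probe_hash0_vec(codes_to_words(codes)) % T
        h_b = probe_hash0_vec(codes_to_words(mutated)) % T
        assert (h_a == h_b).mean() < 0.01


class TestPartHash:
    def test_deterministic_and_small_range(self):
        x = encode("ACGTACGTACGTACGTACGTACGTACGT")
        assert part_hash(x) == part_hash(x)
        assert 0 <= part_hash(x) < 1 << 16

    def test_scalar_matches_vectorized(self):
        rng = np.random.default_rng(9)
        words = random_kmer_words(rng, 100, 28)
        vec = part_hash_vec(words)
        for j in range(100):
            assert part_hash(words[j]) == int(vec[j])

    def test_uniformity_256_buckets(self):
        rng = np.random.default_rng(9)
        h = part_hash_vec(random_kmer_words(rng, 100_000, 28))
        counts = np.bincount((h % np.uint64(256)).astype(int), minlength=256)
        assert counts.max() / counts.mean() <= 1.3

    def test_independent_of_probe_hash(self):
        rng = np.random.default_rng(5)
        words = random_kmer_words(rng, 100_000, 28)
        a = (probe_hash0_vec(words) % np.uint64(16)).astype(int)
        b = (part_hash_vec(words) % np.uint64(16)).astype(int)
        table = np.zeros((16, 16))
        np.add.at(table, (a, b), 1)
        _, p, _, _ = scipy.stats.chi2_contingency(table)
        assert p > 0.01


class TestTableSize:
    def test_formula(self):
        assert table_size(1000, 0.15, 0.4) == 375
        assert table_size(1000, AlphaEstimator(alpha=0.15), 0.4) == 375

    def test_degenerate(self):
        assert table_size(0, 0.5, 0.4) == 1

    def test_rejects_bad_beta(self):
        with pytest.raises(ValueError):
            table_size(10, 0.5, 1.0)


class TestInsert:
    def test_double_insert_one_key_counter_two(self):
        t = CountTable(16, k=8)
        x = encode("ACGTACGT")
        assert t.insert(x) is InsertStatus.COUNTED
        assert t.insert(x) is InsertStatus.COUNTED
        items = list(t.items())
        assert len(items) == 1
        assert items[0][0] == x and items[0][1] == 2

    def test_imax_zero_always_fails(self):
        t = CountTable(16, k=8, i_max=0)
        assert t.insert(encode("ACGTACGT")) is InsertStatus.FAILED
        assert t.inserted == 0

    def test_saturated_table_fails_unchanged(self):
        rng = np.random.default_rng(4)
        t = CountTable(8, k=8, i_max=50)
        filled = 0
        while filled < 8:  # saturate with random other keys
            if t.insert(encode(random_dna(rng, 8))) is InsertStatus.COUNTED:
                filled = t.inserted
        before = dict((str(k), c) for k, c in t.items())
        assert t.insert(encode("ACGTACGT")) is InsertStatus.FAILED
        assert dict((str(k), c) for k, c in t.items()) == before

    def test_multiplicity_matches_repeats(self):
        a, b = CountTable(32, k=8), CountTable(32, k=8)
        x = encode("AACCGGTT")
        for _ in range(5):
            a.insert(x)
        b.insert(x, count=5)
        assert dict(a.items()) == dict(b.items())


class TestShardAndPasses:
    def test_single_shard(self):
        assert shard_id(encode("ACGTACGT"), 1) == 0

    def test_duplicates_one_shard(self):
        x, y = encode("ACGTACGT"), encode("ACGTACGT")
        assert shard_id(x, 7) == shard_id(y, 7)

    def test_shard_balance(self):
        rng = np.random.default_rng(13)
        h = part_hash_vec(random_kmer_words(rng, 100_000, 28))
        loads = np.bincount((h % np.uint64(4)).astype(int), minlength=4)
        assert loads.max() / loads.mean() <= 1.1

    def test_plan_passes_examples(self):
        assert plan_passes(10, 4).p == 3
        assert plan_passes(10, 10).p == 1
        assert plan_passes(0, 5).p == 1

    def test_pass_selection_partitions(self):
        rng = np.random.default_rng(13)
        words = random_kmer_words(rng, 10_000, 28)
        h = part_hash_vec(words)
        p = 3
        masks = [h % np.uint64(p) == np.uint64(i) for i in range(p)]
        total = np.zeros(10_000, dtype=int)
        for m in masks:
            total += m.astype(int)
        assert (total == 1).all()  # union is everything, pairwise disjoint


class TestAlpha:
    def test_ratio(self):
        est = update_alpha(AlphaEstimator(), 150, 1000)
        assert est.alpha == pytest.approx(0.15)
        assert est.alpha_prev == pytest.approx(0.5)

    def test_empty_bin_unchanged(self):
        est = AlphaEstimator(alpha=0.3)
        assert update_alpha(est, 0, 0) is est

    def test_converges_on_identical_bins(self):
        est = AlphaEstimator()
        est1 = update_alpha(est, 200, 800)
        est2 = update_alpha(est1, 200, 800)
        assert est1.alpha == est2.alpha == pytest.approx(0.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            AlphaEstimator(alpha=0.0)
        with pytest.raises(ValueError):
            update_alpha(AlphaEstimator(), 5, 3)


class TestFailureBuffer:
    def test_spill_drain_round_trip(self, tmp_path):
        rng = np.random.default_rng(17)
        keys = random_kmer_words(rng, 100, 40)
        counts = rng.integers(1, 10, size=100).astype(np.uint64)
        fb = FailureBuffer(tmp_path / "fb", keys.shape[1])
        fb.spill_batch(keys[:60], counts[:60])
        fb.spill_batch(keys[60:], counts[60:])
        assert len(fb) == 100
        k2, c2 = fb.drain()
        assert np.array_equal(k2, keys) and np.array_equal(c2, counts)
        assert not (tmp_path / "fb").exists()


def _bin_oracle(bins, k, canonical):
    seqs = []
    from minicount.phase1 import read_bin_records

    for b in bins:
        for codes, _ in read_bin_records(b.path):
            seqs.append("".join("ACGT"[c] for c in codes))
    return oracle_count(seqs, k, canonical_mode=canonical)


class TestCountBin:
    def _make_bin(self, reads, k, tmp_path, canonical=False, m=3):
        cfg = Phase1Config(
            k=k, ordering=build_ordering("lex", m), canonical=canonical, F=1,
            temp_dir=tmp_path,
        )
        bins, _ = run_phase1(reads, cfg)
        return bins[0]

    def test_worked_example_all_distinct(self, tmp_path):
        b = self._make_bin([ReadRecord("r", "CAAGAACAGTG")], 4, tmp_path)
        got = {str(k): c for k, c in count_bin(b, Phase2Config(k=4, canonical=False, temp_dir=tmp_path))}
        assert len(got) == 8 and set(got.values()) == {1}

    def test_repeated_window(self, tmp_path):
        b = self._make_bin([ReadRecord("r", "AAAAA")], 4, tmp_path)
        got = {str(k): c for k, c in count_bin(b, Phase2Config(k=4, canonical=False, temp_dir=tmp_path))}
        assert got == {"AAAA": 2}

    @pytest.mark.parametrize("i_max", [1, 2, 30])
    @pytest.mark.parametrize("force_p", [1, 3])
    @pytest.mark.parametrize("canonical", [False, True])
    def test_oracle_equivalence(self, tmp_path, i_max, force_p, canonical):
        rng = np.random.default_rng(17)
        reads = [ReadRecord(f"r{i}", random_dna(rng, 80)) for i in range(50)]
        k = 12
        b = self._make_bin(reads, k, tmp_path, canonical=canonical, m=5)
        T_max = b.n_kmers if force_p == 1 else (b.n_kmers + 2) // 3
        cfg = Phase2Config(
            k=k, canonical=canonical, T_max=T_max, i_max=i_max,
            n_shards=2, temp_dir=tmp_path,
        )
        got = {str(kmer): c for kmer, c in count_bin(b, cfg)}
        assert got == _bin_oracle([b], k, canonical)

    def test_corrupt_bin_reports_record(self, tmp_path):
        from minicount.phase2 import count_bin_arrays
        from minicount.phase1 import BinFile

        p = tmp_path / "bad.smr"
        p.write_bytes(b"\x08\x00\x01\x00\x00\x00\xaa")
        with pytest.raises(ValueError, match="corrupt bin"):
            count_bin_arrays(BinFile(path=p, file_id=0), Phase2Config(k=4, temp_dir=tmp_path))
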