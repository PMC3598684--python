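import numpy as np
import pytest

from pistarv.io_formats import SequenceRecord, reverse_complement
from pistarv.read_mapping import (
    build_index,
    classify,
    encode,
    map_library,
    map_pair,
    summarize_mapping,
)
from pistarv.synthetic_data import SimulationConfig, simulate_library, simulate_transcriptome


def _seq(id_, s):
    return SequenceRecord(id=id_, sequence=s)


class TestIndex:
    def test_positions_indexed(self):
        idx = build_index([_seq("t", "ACGTACGT")], k=4)
        assert idx.n_positions == 5
        tis, tps = idx.lookup(encode("ACGT"))
        assert set(tps.tolist()) == {0, 4}  # ACGT occurs twice

    def test_duplicate_transcripts_both_indexed(self):
        idx = build_index([_seq("a", "ACGTACGTACGT"), _seq("b", "ACGTACGTACGT")], k=6)
        tis, _ = idx.lookup(encode("ACGTAC"))
        assert set(tis.tolist()) == {0, 1}

    def test_short_transcripts_skipped(self):
        idx = build_index([_seq("tiny", "ACGT"), _seq("big", "A" * 30)], k=12)
        assert idx.skipped == ["tiny"]

    def test_lookup_agrees_with_naive_substring_search(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(5)]
        recs = [_seq(f"t{i}", s) for i, s in enumerate(seqs)]
        k = 12
        idx = build_index(recs, k=k)
        for _ in range(100):
            i = int(rng.integers(0, 5))
            p = int(rng.integers(0, 200 - k))
            query = seqs[i][p:p + k]
            tis, tps = idx.lookup(encode(query))
            got = set(zip(tis.tolist(), tps.tolist()))
            want = {
                (j, q)
                for j, s in enumerate(seqs)
                for q in range(len(s) - k + 1)
                if s[q:q + k] == query
            }
            assert got == want


def _make_pair(seq, start, insert, rl=100):
    m1 = seq[start:start + rl]
    m2 = reverse_complement(seq[start + insert - rl:start + insert])
    return _seq("p/1", m1), _seq("p/2", m2)


class TestMapPair:
    def test_error_free_pair_unique(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        idx = build_index([_seq("t0", seq)], k=21)
        m1, m2 = _make_pair(seq, 50, 260)
        rec = map_pair(m1, m2, idx)
        assert rec is not None
        assert (rec.transcript_id, rec.start, rec.strand) == ("t0", 50, "+")
        assert rec.n_best_locations == 1 and rec.fragment_length == 260

    def test_two_identical_copies_multi(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        idx = build_index([_seq("a", seq), _seq("b", seq)], k=21)
        m1, m2 = _make_pair(seq, 10, 300)
        rec = map_pair(m1, m2, idx)
        assert rec.n_best_locations == 2
        assert classify(rec) == "multi"
        assert rec.transcript_id == "a"  # deterministic lexicographic report

    def test_swapped_mates_map_minus_strand(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        idx = build_index([_seq("t0", seq)], k=21)
        m1, m2 = _make_pair(seq, 120, 250)
        rec = map_pair(m2, m1, idx)
        assert rec is not None and rec.strand == "-" and rec.start == 120

    def test_insert_out_of_bounds_unaligned(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        idx = build_index([_seq("t0", seq)], k=21)
        m1, m2 = _make_pair(seq, 0, 900)  # far beyond mean + 4 sd
        assert map_pair(m1, m2, idx) is None

    def test_mismatch_budget_enforced(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        idx = build_index([_seq("t0", seq)], k=21)
        m1, m2 = _make_pair(seq, 50, 260)
        bad = "ACG" + m1.sequence[3:]
        mutated = _seq("p/1", bad)
        rec = map_pair(mutated, m2, idx, max_mismatches_per_mate=2)
        mm = sum(a != b for a, b in zip(bad, m1.sequence))
        if mm <= 2:
            assert rec is not None and rec.mismatches_total == mm
        else:
            assert rec is None

    def test_agrees_with_exhaustive_oracle_on_small_instances(self, rng):
        """Brute force over every (transcript, offset, orientation)."""
        cfg = SimulationConfig(seed=21, n_transcripts=8, library_depth=100,
                               error_rate=0.01)
        recs, truth = simulate_transcriptome(cfg)
        r1, r2, _ = simulate_library(recs, truth, "root", "starved", 1, cfg)
        idx = build_index(recs, k=21)
        lo, hi = 140, 380
        for m1, m2 in list(zip(r1, r2))[:100]:
            got = map_pair(m1, m2, idx, 2, (lo, hi))
            want = _oracle_pair(m1.sequence, m2.sequence, recs, 2, lo, hi)
            if want is None:
                assert got is None
            else:
                tid, start, strand, mm, nbest = want
                assert got is not None
                assert (got.transcript_id, got.start, got.strand,
                        got.mismatches_total, got.n_best_locations) == (
                    tid, start, strand, mm, min(nbest, 2))

    def test_true_source_recovery_error_free(self):
        cfg = SimulationConfig(seed=3, n_transcripts=40, library_depth=1500,
                               error_rate=0.0)
        recs, truth = simulate_transcriptome(cfg)
        r1, r2, _ = simulate_library(recs, truth, "shoot", "control", 1, cfg)
        idx = build_index(recs, k=21)
        records, summary = map_library(zip(r1, r2), idx)
        ok = sum(1 for rec in records
                 if rec is not None and rec.is_unique
                 and rec.pair_id.split(":")[2] == rec.transcript_id)
        assert ok / summary.total >= 0.99

    def test_input_order_independence(self):
        cfg = SimulationConfig(seed=6, n_transcripts=20, library_depth=300)
        recs, truth = simulate_transcriptome(cfg)
        r1, r2, _ = simulate_library(recs, truth, "root", "control", 1, cfg)
        idx = build_index(recs, k=21)
        fwd, _ = map_library(zip(r1, r2), idx)
        rev, _ = map_library(zip(r1[::-1], r2[::-1]), idx)
        assert fwd == rev[::-1]


def _count_mm(a, b):
    return sum(x != y for x, y in zip(a, b))


def _oracle_pair(s1, s2, recs, max_mm, lo, hi):
    locations = {}
    for rec in recs:
        seq = rec.seq if hasattr(rec, "seq") else rec.sequence
        L = len(seq)
        for strand1, left, right in (("+", s1, s2), ("-", s2, s1)):
            rl, rr = len(left), len(right)
            right_f = reverse_complement(right)
            for a in range(L - rl + 1):
                if _count_mm(left, seq[a:a + rl]) > max_mm:
                    continue
                for b in range(a, L - rr + 1):
                    frag = b + rr - a
                    if not lo <= frag <= hi:
                        continue
                    if _count_mm(right_f, seq[b:b + rr]) > max_mm:
                        continue
                    mm = _count_mm(left, seq[a:a + rl]) + _count_mm(right_f, seq[b:b + rr])
                    key = (rec.id, a, strand1)
                    if key not in locations or mm < locations[key]:
                        locations[key] = mm
    if not locations:
        return None
    best_mm = min(locations.values())
    best = sorted(k for k, v in locations.items() if v == best_mm)
    tid, start, strand = best[0]
    return tid, start, strand, best_mm, len(best)


class TestSummary:
    def test_class_partition_and_percent_sum(self):
        s = summarize_mapping(unique=7, multi=2, unaligned=1)
        assert s.total == 10
        assert s.pct_unique + s.pct_multi + s.pct_unaligned == pytest.approx(100, abs=0.2)

    def test_all_unique(self):
        s = summarize_mapping(unique=5, multi=0, unaligned=0)
        assert (s.pct_unique, s.pct_multi, s.pct_unaligned) == (100.0, 0.0, 0.0)

    def test_empty_library_is_error(self):
        with pytest.raises(ValueError):
            summarize_mapping([])
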