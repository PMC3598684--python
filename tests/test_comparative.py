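import re

import pytest

from pistarv.io_formats import HitRecord, reverse_complement
from pistarv.comparative import (
    de_overlap,
    filter_orthologs,
    find_orfs,
    go_tally,
    reciprocal_best_hits,
    scan_p1bs,
)
from pistarv.synthetic_data import SimulationConfig, simulate_cross_species, simulate_transcriptome

CODONS = ["TTT", "GGG", "CCC", "AAA"]


def _hit(q, s, evalue=1e-20, bitscore=500.0, identity=80.0, qlen_aligned=100):
    return HitRecord(q, s, identity, qlen_aligned, 0, 0, 1, qlen_aligned,
                     1, qlen_aligned, evalue, bitscore)


class TestFindOrfs:
    def test_simple_orf(self):
        body = "".join(CODONS * 15)  # 60 codons
        seq = "CC" + "ATG" + body + "TAG" + "AA"
        orf = find_orfs(seq, min_aa=50)
        assert orf is not None
        assert orf.frame == 2 and orf.start == 2
        assert len(orf.protein) == 61
        assert orf.protein.startswith("M")

    def test_no_atg_returns_none(self):
        assert find_orfs("TTT" * 100, min_aa=10) is None

    def test_below_min_aa_returns_none(self):
        seq = "ATG" + "AAA" * 10 + "TAG"
        assert find_orfs(seq, min_aa=50) is None

    def test_reverse_strand_found(self):
        fwd = "ATG" + "".join(CODONS * 15) + "TAA"
        seq = reverse_complement("C" + fwd + "GG")
        orf = find_orfs(seq, min_aa=50)
        assert orf is not None and orf.strand == "-"

    def test_agrees_with_exhaustive_enumeration(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            got = find_orfs(seq, min_aa=20)
            want = _orf_oracle(seq, min_aa=20)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (len(got.protein), got.frame, got.start) == want


def _orf_oracle(seq, min_aa):
    """Enumerate every ATG..stop span in all six frames."""
    stops = {"TAA", "TAG", "TGA"}
    best = None  # (n_aa, frame, start) with max n_aa, min frame, min start
    for frame in range(6):
        s = seq if frame < 3 else reverse_complement(seq)
        off = frame % 3
        codons = [s[i:i + 3] for i in range(off, len(s) - 2, 3)]
        for ci, codon in enumerate(codons):
            if codon != "ATG":
                continue
            for cj in range(ci + 1, len(codons)):
                if codons[cj] in stops:
                    n_aa = cj - ci
                    if n_aa >= min_aa:
                        cand = (n_aa, frame, off + 3 * ci)
                        if (best is None or cand[0] > best[0]
                                or (cand[0] == best[0] and (cand[1], cand[2])
                                    < (best[1], best[2]))):
                            best = cand
                    break
    return best


class TestRbh:
    def test_mutual_top_pair_emitted(self):
        pairs = reciprocal_best_hits([_hit("a1", "b1")], [_hit("b1", "a1")])
        assert [(p.id_a, p.id_b) for p in pairs] == [("a1", "b1")]

    def test_non_mutual_top_rejected(self):
        pairs = reciprocal_best_hits([_hit("a1", "b1")], [_hit("b1", "a2")])
        assert pairs == []

    def test_evalue_cutoff_applied(self):
        pairs = reciprocal_best_hits([_hit("a1", "b1", evalue=1e-3)],
                                     [_hit("b1", "a1")])
        assert pairs == []

    def test_top_hit_tie_breaks(self):
        hits_ab = [_hit("a1", "b2", evalue=1e-20, bitscore=400),
                   _hit("a1", "b1", evalue=1e-20, bitscore=500)]
        hits_ba = [_hit("b1", "a1")]
        pairs = reciprocal_best_hits(hits_ab, hits_ba)
        assert [(p.id_a, p.id_b) for p in pairs] == [("a1", "b1")]

    def test_recovers_planted_pairs_with_decoys(self, small_config, small_experiment):
        transcripts, truth = small_experiment
        _, hab, hba = simulate_cross_species(transcripts, truth, small_config)
        pairs = reciprocal_best_hits(hab, hba, 1e-6, truth.lengths)
        assert {(p.id_a, p.id_b) for p in pairs} == set(truth.ortholog_pairs)

    def test_symmetric_under_species_swap(self, small_config, small_experiment):
        transcripts, truth = small_experiment
        _, hab, hba = simulate_cross_species(transcripts, truth, small_config)
        fwd = {(p.id_a, p.id_b) for p in reciprocal_best_hits(hab, hba)}
        rev = {(p.id_b, p.id_a) for p in reciprocal_best_hits(hba, hab)}
        assert fwd == rev


class TestOrthologFilter:
    def test_boundary_exclusive_below(self):
        pairs = reciprocal_best_hits(
            [_hit("a", "b", identity=59.9)], [_hit("b", "a")],
            query_lengths_a={"a": 100})
        assert filter_orthologs(pairs) == []

    def test_boundary_inclusive_at_60(self):
        pairs = reciprocal_best_hits(
            [_hit("a", "b", identity=60.0, qlen_aligned=60)],
            [_hit("b", "a")], query_lengths_a={"a": 100})
        kept = filter_orthologs(pairs)
        assert len(kept) == 1 and kept[0].passes_ortholog_filter

    def test_filter_commutes_with_rbh(self, small_config, small_experiment):
        transcripts, truth = small_experiment
        _, hab, hba = simulate_cross_species(transcripts, truth, small_config)
        rbh_then_filter = filter_orthologs(
            reciprocal_best_hits(hab, hba, 1e-6, truth.lengths))
        # pre-filter the hit tables on the same identity gate, then RBH
        def _cov_ok(h, lens):
            return (h.pct_identity >= 60
                    and (h.q_end - h.q_start + 1) / lens.get(h.query_id, 1e9) * 100 >= 60)
        hab_f = [h for h in hab if _cov_ok(h, truth.lengths)]
        hba_f = [h for h in hba if h.pct_identity >= 60]
        filter_then_rbh = filter_orthologs(
            reciprocal_best_hits(hab_f, hba_f, 1e-6, truth.lengths))
        assert {(p.id_a, p.id_b) for p in rbh_then_filter} == {
            (p.id_a, p.id_b) for p in filter_then_rbh}

    def test_missing_coverage_is_error(self):
        pairs = reciprocal_best_hits([_hit("a", "b")], [_hit("b", "a")])
        with pytest.raises(ValueError):
            filter_orthologs(pairs)


class TestDeOverlap:
    def test_disjoint_up_sets_empty(self):
        res = de_overlap({"root": {"a1"}}, {"root": {"b2"}}, {"a1": {"b1"}})
        assert res.per_tissue["root"] == set()

    def test_identity_map_overlap_is_intersection(self):
        up = {"root": {"x", "y"}, "shoot": {"x"}}
        res = de_overlap(up, up, {"x": {"x"}, "y": {"y"}})
        assert res.per_tissue["root"] == {"x", "y"}
        assert res.per_tissue["shoot"] == {"x"}
        assert res.intersection == {"x"}

    def test_multi_ortholog_counted_and_flagged(self):
        res = de_overlap({"root": {"a"}}, {"root": {"b2"}},
                         {"a": {"b1", "b2"}})
        assert res.per_tissue["root"] == {"a"}
        assert res.multi_ortholog_flagged == {"a"}

    def test_monotone_in_up_sets(self):
        omap = {"a1": {"b1"}, "a2": {"b2"}}
        small = de_overlap({"root": {"a1"}}, {"root": {"b1", "b2"}}, omap)
        big = de_overlap({"root": {"a1", "a2"}}, {"root": {"b1", "b2"}}, omap)
        assert small.per_tissue["root"] <= big.per_tissue["root"]

    def test_planted_shared_up_recovered(self):
        up_a = {"root": {"a1", "a2", "a3"}, "shoot": {"a1"}}
        up_b = {"root": {"b1", "b3"}, "shoot": {"b1"}}
        omap = {"a1": {"b1"}, "a2": {"b2"}, "a3": {"b3"}}
        res = de_overlap(up_a, up_b, omap)
        assert res.per_tissue["root"] == {"a1", "a3"}
        assert res.intersection == {"a1"}


class TestScanP1bs:
    def test_planted_octamer_found(self):
        seq = "T" * 100 + "GAATATCC" + "T" * 92
        hits = scan_p1bs(seq, "s")
        assert ("s", 100, "+") in {(h.sequence_id, h.start, h.strand) for h in hits}
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].matched_octamer == "GAATATCC"

    def test_motif_free_background_empty(self):
        assert scan_p1bs("ACCA" * 300) == []

    def test_window_limits_scan(self):
        seq = "GAATATCC" + "T" * 2000
        assert scan_p1bs(seq, upstream_window=1000) == []
        assert scan_p1bs(seq, upstream_window=len(seq)) != []

    def test_short_sequence_no_hits(self):
        assert scan_p1bs("GAATATC") == []

    def test_ambiguous_base_never_matches(self):
        assert scan_p1bs("T" * 50 + "GNATATNC" + "T" * 50) == []

    def test_equals_exhaustive_enumeration(self, rng):
        pat = re.compile("G[ACGT]ATAT[ACGT]C")
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            got = {(h.start, h.strand) for h in scan_p1bs(seq)}
            want = set()
            for i in range(len(seq) - 7):
                if pat.fullmatch(seq[i:i + 8]):
                    want |= {(i, "+"), (i, "-")}
            assert got == want

    def test_palindrome_strand_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        hits = scan_p1bs(seq)
        plus = {h.start for h in hits if h.strand == "+"}
        minus = {h.start for h in hits if h.strand == "-"}
        assert plus == minus
        rc_hits = scan_p1bs(reverse_complement(seq))
        assert len(rc_hits) == len(hits)


class TestGoTally:
    def test_single_category(self):
        table, un = go_tally({"t1": ["GO:1"], "t2": ["GO:1"], "t3": ["GO:1"]},
                             ["t1", "t2", "t3"])
        assert table.iloc[0].tolist() == ["GO:1", 3] and un == 0

    def test_empty_subset(self):
        table, un = go_tally({"t1": ["GO:1"]}, [])
        assert table.empty and un == 0

    def test_unannotated_reported(self):
        _, un = go_tally({"t1": ["GO:1"]}, ["t1", "t2"])
        assert un == 1

    def test_matches_brute_force_groupby(self, rng):
        cats = [f"GO:{i}" for i in range(8)]
        ann = {f"t{i}": list(rng.choice(cats,
                                        size=int(rng.integers(1, 4)),
                                        replace=False))
               for i in range(50)}
        subset = [f"t{i}" for i in range(0, 50, 2)]
        table, _ = go_tally(ann, subset, top_n=5)
        brute = {}
        for t in subset:
            for c in set(ann[t]):
                brute[c] = brute.get(c, 0) + 1
        expected = sorted(brute.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        assert list(map(tuple, table.itertuples(index=False))) == expected
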