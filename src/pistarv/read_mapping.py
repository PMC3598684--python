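"""Seed-and-extend paired-end mapper with unique/multi/unaligned
classification.

Reads are placed by exact k-mer seeding into a sorted k-mer index over the
forward strands of the transcript set, then verified by gapless extension
(substitutions only, counted over the full mate). A read pair aligns at a
location only concordantly: both mates on the same transcript, opposite
strands, FR orientation, each mate within the per-mate mismatch budget and
the implied insert within configured bounds. Among valid locations the
minimal-total-mismatch ones are kept; a pair is *unique* when exactly one
best location exists, *multi* when two or more tie (counting stops at
``report_limit``), *unaligned* otherwise.

With ``max_mismatches_per_mate`` errors allowed in a read of length R,
seeding at ceil(R/k) disjoint offsets plus the final window guarantees at
least one error-free seed whenever floor(R/k) > max mismatches (true for
the 100-bp/k=21/2-mismatch defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "AlignmentRecord",
    "MappingSummary",
    "SeedIndex",
    "build_index",
    "map_pair",
    "map_library",
    "summarize_mapping",
    "classify",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """2-bit base codes; anything outside {A,C,G,T} becomes 4 (never matches)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes[::-1]]


@dataclass(frozen=True)
class AlignmentRecord:
    """A concordant placement of a read pair on a transcript."""

    pair_id: str
    transcript_id: str
    start: int  # 0-based leftmost base of the fragment
    strand: str  # strand of mate 1
    mismatches_total: int
    n_best_locations: int
    fragment_length: int

    @property
    def is_unique(self) -> bool:
        return self.n_best_locations == 1


@dataclass(frozen=True)
class MappingSummary:
    total: int
    unique: int
    multi: int
    unaligned: int
    pct_unique: float
    pct_multi: float
    pct_unaligned: float


class SeedIndex:
    """Sorted exact-k-mer index over the forward strand of each transcript.

    K-mers are packed into 2k-bit integers and stored sorted, so lookup is
    a binary search rather than a hash probe; reverse-complement queries
    are handled at map time by seeding the reverse-complemented mate.
    """

    def __init__(self, transcripts: Sequence[SequenceRecord], k: int):
        if k < 1:
            raise ValueError("seed length k must be positive")
        if k > 31:
            raise ValueError("seed length k must be <= 31 (2k-bit packing)")
        self.k = k
        self.ids = [t.id for t in transcripts]
        self.codes = [encode(t.sequence) for t in transcripts]
        self.lengths = np.array([len(c) for c in self.codes])
        self.skipped = [t.id for t in transcripts if len(t) < k]
        kvals, tidx, tpos = [], [], []
        weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        for i, codes in enumerate(self.codes):
            if len(codes) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            vals = win.astype(np.int64) @ weights
            ok = (win != 4).all(axis=1)
            kvals.append(vals[ok])
            tpos.append(np.nonzero(ok)[0])
            tidx.append(np.full(int(ok.sum()), i, dtype=np.int32))
        allv = np.concatenate(kvals) if kvals else np.empty(0, dtype=np.int64)
        order = np.argsort(allv, kind="stable")
        self._kvals = allv[order]
        self._tidx = np.concatenate(tidx)[order] if kvals else np.empty(0, np.int32)
        self._tpos = np.concatenate(tpos)[order] if kvals else np.empty(0, np.int64)
        self._weights = weights

    @property
    def n_positions(self) -> int:
        """Total (transcript, offset) positions indexed."""
        return int(self._kvals.size)

    def lookup(self, kmer_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(transcript indices, offsets) of exact matches of one k-mer."""
        if (kmer_codes == 4).any():
            return np.empty(0, np.int32), np.empty(0, np.int64)
        val = int(kmer_codes.astype(np.int64) @ self._weights)
        lo = np.searchsorted(self._kvals, val, side="left")
        hi = np.searchsorted(self._kvals, val, side="right")
        return self._tidx[lo:hi], self._tpos[lo:hi]


def build_index(transcripts: Sequence[SequenceRecord], k: int = 21) -> SeedIndex:
    return SeedIndex(transcripts, k)


def _candidate_starts(codes: np.ndarray, index: SeedIndex) -> set[tuple[int, int]]:
    k, rl = index.k, len(codes)
    if rl < k:
        return set()
    offsets = list(range(0, rl - k + 1, k))
    if offsets[-1] != rl - k:
        offsets.append(rl - k)
    out: set[tuple[int, int]] = set()
    for off in offsets:
        tis, tps = index.lookup(codes[off:off + k])
        for ti, tp in zip(tis.tolist(), tps.tolist()):
            start = tp - off
            if start >= 0 and start + rl <= index.lengths[ti]:
                out.add((ti, start))
    return out


def _verified(codes: np.ndarray, index: SeedIndex, max_mm: int) -> dict[tuple[int, int], int]:
    """Candidate placements that survive full gapless verification."""
    out: dict[tuple[int, int], int] = {}
    rl = len(codes)
    for ti, start in _candidate_starts(codes, index):
        mm = int(np.count_nonzero(index.codes[ti][start:start + rl] != codes))
        if mm <= max_mm:
            out[(ti, start)] = mm
    return out


def map_pair(
    mate1: SequenceRecord | str,
    mate2: SequenceRecord | str,
    index: SeedIndex,
    max_mismatches_per_mate: int = 2,
    insert_bounds: tuple[int, int] = (140, 380),
    report_limit: int = 2,
    pair_id: str = "",
) -> AlignmentRecord | None:
    """Place one read pair; ``None`` means unaligned."""
    s1 = mate1.sequence if isinstance(mate1, SequenceRecord) else mate1
    s2 = mate2.sequence if isinstance(mate2, SequenceRecord) else mate2
    if not pair_id and isinstance(mate1, SequenceRecord):
        pair_id = mate1.id
    c1, c2 = encode(s1), encode(s2)
    rl1, rl2 = len(c1), len(c2)
    lo, hi = insert_bounds
    fw1 = _verified(c1, index, max_mismatches_per_mate)
    rc1 = _verified(_revcomp_codes(c1), index, max_mismatches_per_mate)
    fw2 = _verified(c2, index, max_mismatches_per_mate)
    rc2 = _verified(_revcomp_codes(c2), index, max_mismatches_per_mate)

    locations: dict[tuple[int, int, str], tuple[int, int]] = {}

    def _pair_up(fw: dict, rc: dict, fw_len: int, rc_len: int, strand1: str) -> None:
        # fw = leftmost mate on '+'; rc = rightmost mate reverse-complemented
        rc_by_t: dict[int, list[tuple[int, int]]] = {}
        for (ti, st), mm in rc.items():
            rc_by_t.setdefault(ti, []).append((st, mm))
        for (ti, st), mm in fw.items():
            for st2, mm2 in rc_by_t.get(ti, ()):
                if st2 < st:
                    continue
                frag = st2 + rc_len - st
                if lo <= frag <= hi:
                    key = (ti, st, strand1)
                    tot = (mm + mm2, frag)
                    if key not in locations or tot < locations[key]:
                        locations[key] = tot

    _pair_up(fw1, rc2, rl1, rl2, "+")   # mate 1 forward, mate 2 reverse
    _pair_up(fw2, rc1, rl2, rl1, "-")   # mate 2 forward, mate 1 reverse

    if not locations:
        return None
    best_mm = min(mm for mm, _ in locations.values())
    best = [(index.ids[ti], st, strand, frag)
            for (ti, st, strand), (mm, frag) in locations.items() if mm == best_mm]
    n_best = min(len(best), report_limit)
    tid, start, strand, frag = min(best)
    return AlignmentRecord(
        pair_id=pair_id, transcript_id=tid, start=start, strand=strand,
        mismatches_total=best_mm, n_best_locations=n_best, fragment_length=frag,
    )


def classify(record: AlignmentRecord | None) -> str:
    if record is None:
        return "unaligned"
    return "unique" if record.n_best_locations == 1 else "multi"


def map_library(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    index: SeedIndex,
    max_mismatches_per_mate: int = 2,
    insert_bounds: tuple[int, int] = (140, 380),
    report_limit: int = 2,
) -> tuple[list[AlignmentRecord | None], MappingSummary]:
    records = [
        map_pair(m1, m2, index, max_mismatches_per_mate, insert_bounds, report_limit)
        for m1, m2 in pairs
    ]
    return records, summarize_mapping(records)


def summarize_mapping(
    records: Iterable[AlignmentRecord | None] | None = None,
    *,
    unique: int | None = None,
    multi: int | None = None,
    unaligned: int | None = None,
) -> MappingSummary:
    """Tally classes and percentages (1 decimal, against the total).

    Accepts either per-pair records or pre-computed class tallies.
    """
    if records is not None:
        unique = multi = unaligned = 0
        for rec in records:
            cls = classify(rec)
            if cls == "unique":
                unique += 1
            elif cls == "multi":
                multi += 1
            else:
                unaligned += 1
    if unique is None or multi is None or unaligned is None:
        raise ValueError("provide records or all three class tallies")
    total = unique + multi + unaligned
    if total == 0:
        raise ValueError("cannot summarize an empty library")
    pct = lambda c: round(c / total * 100.0, 1)
    return MappingSummary(total, unique, multi, unaligned,
                          pct(unique), pct(multi), pct(unaligned))
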