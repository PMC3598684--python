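"""Contig de-redundancy and assembly assessment.

De-redundancy follows the cd-hit-est style rule used for de novo plant
transcriptomes: a shorter contig that is (nearly) entirely covered by a
longer one at high identity is removed; of the isoforms sharing a locus,
only the longest is kept. Assessment scores how well each full-length
reference transcript is reconstructed by its single best-matching contig.

Candidate pairs are pre-filtered by shared sampled k-mers, then aligned
with edlib's banded bit-vector algorithm in infix mode (the shorter
sequence as the query, free end-gaps on the longer only). Identity is
matches / alignment columns, read off the extended cigar.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .io_formats import SequenceRecord

__all__ = [
    "ContigStats",
    "ReconstructionReport",
    "remove_contained",
    "select_longest_isoform",
    "contig_stats",
    "assess_reconstruction",
    "combine_transcript_sets",
    "locus_of",
    "infix_identity",
]


@dataclass(frozen=True)
class ContigStats:
    n_contigs: int
    max_len: int
    mean_len: int
    median_len: int
    n_over_1kb: int
    n50: int


@dataclass
class ReconstructionReport:
    """Per-reference best single-contig coverage and the gate counts."""

    per_reference: pd.DataFrame  # columns: reference_id, best_identity, best_coverage
    n_references: int
    counts: dict[float, int]     # coverage gate -> references passing it
    fractions: dict[float, float]


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an extended cigar (=/X/I/D)."""
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def infix_identity(query: str, target: str) -> tuple[float, tuple[int, int]]:
    """Best infix alignment of query into target.

    Returns (identity = matches/columns, (target start, target end)
    half-open). Identity 0.0 when edlib finds no alignment.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, (0, 0)
    matches, columns = _cigar_stats(res["cigar"])
    s, e = res["locations"][0]
    return (matches / columns if columns else 0.0), (s, e + 1)


def _sampled_kmers(seq: str, k: int, step: int) -> set[str]:
    return {seq[i:i + k] for i in range(0, max(len(seq) - k + 1, 1), step)}


def _all_kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _is_contained(shorter: str, longer: str, min_identity: float,
                  min_cover: float) -> bool:
    ident, _ = infix_identity(shorter, longer)
    if ident >= min_identity:
        return True
    if min_cover < 1.0:
        # allow up to (1 - min_cover) of the shorter's length to hang off:
        # retry with trimmed queries (both-end and one-sided trims)
        t = int((1.0 - min_cover) * len(shorter))
        if t >= 1:
            for a, b in ((t // 2, t - t // 2), (t, 0), (0, t)):
                core = shorter[a:len(shorter) - b]
                ident, _ = infix_identity(core, longer)
                if ident >= min_identity:
                    return True
    return False


def remove_contained(
    contigs: Sequence[SequenceRecord],
    min_identity: float = 0.90,
    min_cover_of_shorter: float = 0.90,
    k: int = 15,
) -> list[SequenceRecord]:
    """Drop every contig covered >= ``min_cover_of_shorter`` of its length
    at >= ``min_identity`` by a retained longer (or equal, earlier) contig.

    Greedy pass in descending length order (ties by input order, so the
    first of an exact duplicate pair survives); survivors are returned in
    input order. Idempotent by construction.
    """
    if not contigs:
        raise ValueError("empty contig set")
    order = sorted(range(len(contigs)), key=lambda i: (-len(contigs[i]), i))
    kept: list[int] = []
    kmer_map: dict[str, set[int]] = {}
    for i in order:
        seq = contigs[i].sequence
        # a fragment at >=90% identity retains long exact runs; probing every
        # position of the shorter against sampled k-mers of retained contigs
        # finds any such run
        cands = set()
        for km in _all_kmers(seq, k) if len(seq) >= k else {seq}:
            cands |= kmer_map.get(km, set())
        dropped = False
        for j in sorted(cands, key=lambda j: (-len(contigs[j]), j)):
            if len(contigs[j]) < len(seq):
                continue
            if _is_contained(seq, contigs[j].sequence, min_identity,
                             min_cover_of_shorter):
                dropped = True
                break
        if not dropped:
            kept.append(i)
            step = max(k // 2, 1)
            for km in _sampled_kmers(seq, k, step):
                kmer_map.setdefault(km, set()).add(i)
    kept_set = set(kept)
    return [contigs[i] for i in range(len(contigs)) if i in kept_set]


def locus_of(record: SequenceRecord) -> str:
    """Locus label: a ``locus=`` tag in the description, else the id
    itself (a contig without a label is its own locus)."""
    for tok in record.description.split():
        if tok.startswith("locus="):
            return tok[6:]
    return record.id


def select_longest_isoform(
    contigs: Sequence[SequenceRecord],
    locus_fn=locus_of,
) -> list[SequenceRecord]:
    """Keep the longest member of each locus (ties by lexicographic id);
    output preserves input order of the survivors."""
    best: dict[str, SequenceRecord] = {}
    for rec in contigs:
        loc = locus_fn(rec)
        cur = best.get(loc)
        if cur is None or (len(rec), ) > (len(cur), ) or (
            len(rec) == len(cur) and rec.id < cur.id
        ):
            best[loc] = rec
    chosen = {id(rec) for rec in best.values()}
    return [rec for rec in contigs if id(rec) in chosen]


def contig_stats(contigs: Sequence[SequenceRecord]) -> ContigStats:
    """Length summary; mean rounded to the bp, median = lower middle for
    even counts, N50 = length at which the descending cumulative sum first
    reaches half the total."""
    if not contigs:
        raise ValueError("empty contig set")
    lengths = sorted(len(c) for c in contigs)
    n = len(lengths)
    total = sum(lengths)
    half = total / 2.0
    acc = 0
    n50 = lengths[-1]
    for ln in reversed(lengths):
        acc += ln
        if acc >= half:
            n50 = ln
            break
    return ContigStats(
        n_contigs=n,
        max_len=lengths[-1],
        mean_len=int(round(total / n)),
        median_len=lengths[(n - 1) // 2],
        n_over_1kb=sum(1 for ln in lengths if ln > 1000),
        n50=n50,
    )


def assess_reconstruction(
    contigs: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    id_threshold: float = 0.90,
    cov_thresholds: Iterable[float] = (0.50, 0.90),
    k: int = 15,
) -> ReconstructionReport:
    """Score each reference by the single contig covering most of it at
    >= ``id_threshold`` identity.

    Coverage is measured on the reference: the fraction of reference bases
    spanned by the best contig's alignment. Monotone in the contig set.
    """
    if not contigs or not references:
        raise ValueError("contigs and references must be non-empty")
    gates = sorted(cov_thresholds)
    step = max(k // 2, 1)
    kmer_map: dict[str, set[int]] = {}
    for ci, c in enumerate(contigs):
        for km in _sampled_kmers(c.sequence, k, step):
            kmer_map.setdefault(km, set()).add(ci)
    rows = []
    for ref in references:
        rseq = ref.sequence
        cands = set()
        for km in _all_kmers(rseq, k) if len(rseq) >= k else {rseq}:
            cands |= kmer_map.get(km, set())
        best_cov = 0.0
        best_ident = 0.0
        for ci in cands:
            cseq = contigs[ci].sequence
            if len(cseq) <= len(rseq):
                ident, (s, e) = infix_identity(cseq, rseq)
                cov = (e - s) / len(rseq)
            else:
                ident, _ = infix_identity(rseq, cseq)
                cov = 1.0
            best_ident = max(best_ident, ident)
            if ident >= id_threshold:
                best_cov = max(best_cov, cov)
        rows.append((ref.id, round(best_ident * 100.0, 2), round(best_cov * 100.0, 2)))
    per_ref = pd.DataFrame(rows, columns=["reference_id", "best_identity", "best_coverage"])
    counts = {g: int((per_ref["best_coverage"] >= g * 100.0).sum()) for g in gates}
    fractions = {g: counts[g] / len(references) for g in gates}
    return ReconstructionReport(per_ref, len(references), counts, fractions)


def combine_transcript_sets(
    contigs: Sequence[SequenceRecord], cdnas: Sequence[SequenceRecord]
) -> list[SequenceRecord]:
    """Union of the non-redundant contig set and the reference cDNA set,
    de-duplicated by id (first occurrence wins)."""
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for rec in list(contigs) + list(cdnas):
        if rec.id not in seen:
            seen.add(rec.id)
            out.append(rec)
    return out
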