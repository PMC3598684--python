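"""Cross-species comparison: ORF finding, reciprocal-best-hit orthology,
shared differential-expression overlap, P1BS motif scanning and GO
tallying.

Orthology follows the classical reciprocal-top-hit recipe: each query's
best cross-species hit is its minimal-e-value hit (ties broken by maximal
bitscore, then lexicographic subject id); a pair is kept when the two
directions agree and both e-values pass the cutoff, then filtered at
>= 60% identity and >= 60% query coverage.

P1BS is the PHR1-binding site GNATATNC found in the 1-kb upstream region
of phosphate-starvation-responsive genes. The pattern is an imperfect
palindrome equal to its own reverse complement, so every matching octamer
is simultaneously a '+' and a '-' strand hit at the same position.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io_formats import HitRecord, SequenceRecord, reverse_complement

__all__ = [
    "Orf",
    "OrthologPair",
    "MotifHit",
    "OverlapResult",
    "find_orfs",
    "reciprocal_best_hits",
    "filter_orthologs",
    "de_overlap",
    "scan_p1bs",
    "go_tally",
]


@dataclass(frozen=True)
class Orf:
    protein: str
    frame: int          # 0..2 forward, 3..5 reverse strand
    start: int          # 0-based, on the scanned strand
    end: int            # half-open, includes the stop codon

    @property
    def strand(self) -> str:
        return "+" if self.frame < 3 else "-"


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    identity: float            # percent, from the A->B hit
    coverage: float | None     # percent of the A query aligned; None if unknown
    evalue_ab: float
    evalue_ba: float
    passes_ortholog_filter: bool = False


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int   # 0-based on the forward sequence
    strand: str
    matched_octamer: str


@dataclass
class OverlapResult:
    per_tissue: dict[str, set[str]]      # species-A ids common-up per tissue
    intersection: set[str]               # common-up in every tissue
    matched_orthologs: dict[str, set[str]]
    multi_ortholog_flagged: set[str]


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(sequence: str, min_aa: int = 50) -> Orf | None:
    """Longest ATG-to-stop ORF over all six frames, or None.

    Ties break to the lowest frame index (three forward frames first),
    then to the leftmost start on that frame's strand. ``min_aa`` counts
    codons before the stop.
    """
    seq = sequence.upper().replace("U", "T")
    best: Orf | None = None
    for frame in range(6):
        strand_seq = seq if frame < 3 else reverse_complement(seq)
        off = frame % 3
        atg = -1
        for pos in range(off, len(strand_seq) - 2, 3):
            codon = strand_seq[pos:pos + 3]
            if codon == "ATG" and atg < 0:
                atg = pos
            elif codon in _STOPS and atg >= 0:
                n_aa = (pos - atg) // 3
                if n_aa >= min_aa:
                    if best is None or n_aa > len(best.protein):
                        protein = str(Seq(strand_seq[atg:pos]).translate())
                        best = Orf(protein, frame, atg, pos + 3)
                atg = -1
    return best


def _top_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: minimal e-value, then maximal bitscore, then
    lexicographic subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue, -cur.bitscore, cur.subject_id
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    evalue_max: float = 1e-6,
    query_lengths_a: Mapping[str, int] | None = None,
) -> list[OrthologPair]:
    """Mutual-top-hit pairs with both directional e-values <= ``evalue_max``.

    Identity is taken from the A->B hit; coverage is the A-side aligned
    query fraction when query lengths are supplied.
    """
    top_ab = _top_hits(hits_ab)
    top_ba = _top_hits(hits_ba)
    pairs: list[OrthologPair] = []
    for a, hab in sorted(top_ab.items()):
        b = hab.subject_id
        hba = top_ba.get(b)
        if hba is None or hba.subject_id != a:
            continue
        if hab.evalue > evalue_max or hba.evalue > evalue_max:
            continue
        cov = None
        if query_lengths_a is not None:
            cov = (hab.q_end - hab.q_start + 1) / query_lengths_a[a] * 100.0
        pairs.append(OrthologPair(a, b, hab.pct_identity, cov,
                                  hab.evalue, hba.evalue))
    return pairs


def filter_orthologs(
    pairs: Iterable[OrthologPair],
    min_identity: float = 60.0,
    min_coverage: float = 60.0,
) -> list[OrthologPair]:
    """Keep pairs with identity >= ``min_identity`` and query coverage >=
    ``min_coverage`` (inclusive thresholds); ``passes_ortholog_filter`` is
    set on the survivors."""
    kept = []
    for p in pairs:
        if p.coverage is None:
            raise ValueError(
                f"pair ({p.id_a}, {p.id_b}) has no coverage; supply query lengths"
            )
        if p.identity >= min_identity and p.coverage >= min_coverage:
            kept.append(replace(p, passes_ortholog_filter=True))
    return kept


def de_overlap(
    up_a: Mapping[str, set[str]],
    up_b: Mapping[str, set[str]],
    ortholog_map: Mapping[str, set[str] | str],
) -> OverlapResult:
    """Species-A transcripts upregulated in both species, per tissue.

    A transcript is common-up in a tissue iff it is up in species A and
    any of its mapped orthologs is up in species B for that tissue;
    transcripts matched through more than one ortholog are flagged. The
    intersection is over every tissue present in both species' up sets.
    """
    omap: dict[str, set[str]] = {
        a: ({bs} if isinstance(bs, str) else set(bs))
        for a, bs in ortholog_map.items()
    }
    per_tissue: dict[str, set[str]] = {}
    matched: dict[str, set[str]] = defaultdict(set)
    flagged: set[str] = set()
    tissues = [t for t in up_a if t in up_b]
    for tissue in tissues:
        common = set()
        for a in up_a[tissue]:
            partners = omap.get(a, set())
            hit = partners & up_b[tissue]
            if hit:
                common.add(a)
                matched[a] |= hit
                if len(partners) > 1:
                    flagged.add(a)
        per_tissue[tissue] = common
    inter = set.intersection(*per_tissue.values()) if per_tissue else set()
    return OverlapResult(per_tissue, inter, dict(matched), flagged)


P1BS_PATTERN = re.compile(r"(?=(G[ACGT]ATAT[ACGT]C))")


def scan_p1bs(
    sequence: str,
    sequence_id: str = "",
    upstream_window: int = 1000,
) -> list[MotifHit]:
    """All P1BS (GNATATNC) occurrences in the last ``upstream_window``
    bases.

    Ambiguity codes in the subject never match the N positions. Because
    the pattern is self-reverse-complementary, every matching octamer is
    reported once per strand at the same start.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) < 8:
        return []
    window_start = max(len(seq) - upstream_window, 0)
    hits: list[MotifHit] = []
    for m in P1BS_PATTERN.finditer(seq, window_start):
        octamer = seq[m.start():m.start() + 8]
        hits.append(MotifHit(sequence_id, m.start(), "+", octamer))
        hits.append(MotifHit(sequence_id, m.start(), "-", reverse_complement(octamer)))
    return hits


def go_tally(
    annotations: Mapping[str, Iterable[str]],
    subset: Iterable[str],
    top_n: int = 20,
) -> tuple[pd.DataFrame, int]:
    """Top-N GO biological-process categories over a transcript subset.

    Counts are transcripts per category (a transcript appears once per
    distinct category it carries), sorted descending with alphabetical
    tie-break. Returns (table, number of unannotated subset members).
    """
    counter: Counter[str] = Counter()
    unannotated = 0
    for tid in subset:
        terms = set(annotations.get(tid, ()))
        if not terms:
            unannotated += 1
            continue
        counter.update(terms)
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(ranked, columns=["category", "n_transcripts"]), unannotated
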