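"""Unique-read counting, replicate merging, RPKM and coverage statistics.

RPKM = 10^9 * C / (N * L) with C the transcript's uniquely-aligned read
count, N the library's total uniquely-aligned reads and L the transcript
length in bp. The reported value adds a pseudocount of 1 to the RPKM
itself (not to the counts), so unexpressed transcripts report exactly 1.00
and fold changes are always defined.

By default a concordant unique pair contributes 2 reads to C (both mates
are uniquely aligned); ``count_unit="pairs"`` counts fragments instead.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_mapping import AlignmentRecord

__all__ = [
    "count_unique",
    "merge_replicates",
    "compute_rpkm",
    "replicate_correlation",
    "coverage_stats",
]


def count_unique(
    alignments: Iterable[AlignmentRecord | None],
    transcript_ids: Sequence[str],
    count_unit: str = "reads",
) -> pd.Series:
    """Per-transcript counts from uniquely-mapped pairs only.

    Transcripts with no alignments appear with count 0; an alignment to an
    unknown transcript is an error.
    """
    if count_unit not in ("reads", "pairs"):
        raise ValueError("count_unit must be 'reads' or 'pairs'")
    per = 2 if count_unit == "reads" else 1
    counts = pd.Series(0, index=pd.Index(transcript_ids, name="transcript_id"),
                       dtype=np.int64)
    known = set(transcript_ids)
    tally: dict[str, int] = {}
    for rec in alignments:
        if rec is None or rec.n_best_locations != 1:
            continue
        if rec.transcript_id not in known:
            raise KeyError(f"alignment references unknown transcript "
                           f"{rec.transcript_id!r}")
        tally[rec.transcript_id] = tally.get(rec.transcript_id, 0) + per
    for tid, c in tally.items():
        counts.at[tid] = c
    return counts


def merge_replicates(counts_by_replicate: Sequence[pd.Series]) -> pd.Series:
    """Element-wise sum over replicates of one treatment."""
    if not counts_by_replicate:
        raise ValueError("no replicates supplied")
    first = counts_by_replicate[0]
    for s in counts_by_replicate[1:]:
        if not first.index.equals(s.index):
            raise ValueError("replicates cover different transcript universes")
    return sum(counts_by_replicate[1:], first.copy())


def compute_rpkm(
    counts: pd.Series,
    library_total: int,
    lengths: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """RPKM table with raw and pseudocount-incremented values.

    Internal arithmetic is unrounded; output tables round to 2 decimals.
    """
    if library_total <= 0:
        raise ValueError("library total must be positive")
    lens = pd.Series(lengths).reindex(counts.index)
    if lens.isna().any() or (lens < 1).any():
        raise ValueError("every transcript needs a length >= 1")
    raw = 1e9 * counts / (library_total * lens)
    return pd.DataFrame(
        {
            "count": counts,
            "length": lens.astype(int),
            "rpkm_raw": raw,
            "rpkm_reported": raw + 1.0,
        }
    )


def replicate_correlation(
    rpkm_by_replicate: pd.DataFrame,
) -> tuple[tuple[str, str], float, pd.DataFrame]:
    """Pearson correlation of per-transcript RPKM between every replicate
    pair; returns (best pair, its coefficient, all pairwise values)."""
    cols = list(rpkm_by_replicate.columns)
    if len(cols) < 2:
        raise ValueError("need at least two replicates")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x, y = rpkm_by_replicate[a], rpkm_by_replicate[b]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"zero-variance replicate in pair ({a}, {b})")
                r = float("nan")
            else:
                r = float(stats.pearsonr(x, y).statistic)
            rows.append((a, b, r))
    table = pd.DataFrame(rows, columns=["rep_a", "rep_b", "pearson_r"])
    if table["pearson_r"].isna().all():
        best = table.iloc[0]
    else:
        best = table.loc[table["pearson_r"].idxmax(skipna=True)]
    return (best["rep_a"], best["rep_b"]), float(best["pearson_r"]), table


def coverage_stats(
    alignments: Iterable[AlignmentRecord | None],
    lengths: Mapping[str, int],
    read_length: int,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Breadth (percent of bases covered >= 1x) and mean depth per
    transcript, from the two mate intervals of each aligned pair."""
    diffs: dict[str, np.ndarray] = {}
    for rec in alignments:
        if rec is None or (unique_only and rec.n_best_locations != 1):
            continue
        L = lengths[rec.transcript_id]
        d = diffs.get(rec.transcript_id)
        if d is None:
            d = diffs[rec.transcript_id] = np.zeros(L + 1, dtype=np.int32)
        s, f = rec.start, rec.fragment_length
        d[s] += 1
        d[min(s + read_length, L)] -= 1
        d[max(s + f - read_length, 0)] += 1
        d[min(s + f, L)] -= 1
    rows = []
    for tid, L in lengths.items():
        d = diffs.get(tid)
        if d is None:
            rows.append((tid, 0.0, 0.0))
            continue
        depth = np.cumsum(d[:-1])
        rows.append((
            tid,
            float((depth > 0).sum()) / L * 100.0,
            float(depth.sum()) / L,
        ))
    return pd.DataFrame(rows, columns=["transcript_id", "breadth_pct", "mean_depth"]
                        ).set_index("transcript_id")
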