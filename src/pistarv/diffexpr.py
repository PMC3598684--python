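"""Differential expression between control and -P treatments.

The test is a G-test (likelihood-ratio test of independence) on the 2x2
table of a transcript's uniquely-aligned reads versus the remainder of the
merged library, one table per transcript:

    [[c_ctrl, N_ctrl - c_ctrl],
     [c_trt,  N_trt  - c_trt ]]

G = 2 * sum O * ln(O/E) over the four cells (empty cells contribute 0),
asymptotically chi-square with 1 degree of freedom. Multiple testing is
controlled per tissue by Benjamini-Hochberg; a transcript is called up
(down) when q < threshold and its incremented-RPKM fold change is above
(below) 1.

No Williams or Yates correction is applied by default; the test consumes
merged-replicate counts and therefore models technical (Poisson) rather
than biological variability — a deliberate reproduction of the classical
read-count G-test workflow, not a best-practice endorsement (a
dispersion-aware model such as edgeR/DESeq2 is the modern choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["DEResult", "g_test", "g_test_many", "bh_fdr", "fold_change", "call_de"]


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    count_ctrl: int
    count_trt: int
    total_ctrl: int
    total_trt: int
    g_stat: float
    p_value: float
    q_value: float
    fold_change: float
    call: str  # up | down | ns


def g_test(count_ctrl: int, total_ctrl: int, count_trt: int, total_trt: int,
           williams: bool = False) -> tuple[float, float]:
    """G statistic and p-value for one transcript's 2x2 table.

    Both counts zero is no signal: (0, 1). ``williams`` applies the
    Williams continuity correction (off by default, exposed for
    sensitivity analysis).
    """
    g, p = g_test_many(np.array([count_ctrl]), total_ctrl,
                       np.array([count_trt]), total_trt, williams=williams)
    return float(g[0]), float(p[0])


def g_test_many(
    counts_ctrl: np.ndarray,
    total_ctrl: int,
    counts_trt: np.ndarray,
    total_trt: int,
    williams: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized G-test over many transcripts sharing library totals."""
    c1 = np.asarray(counts_ctrl, dtype=float)
    c2 = np.asarray(counts_trt, dtype=float)
    if (c1 > total_ctrl).any() or (c2 > total_trt).any():
        raise ValueError("count exceeds its library total")
    if total_ctrl <= 0 or total_trt <= 0:
        raise ValueError("library totals must be positive")
    n = float(total_ctrl + total_trt)
    O = np.stack([c1, total_ctrl - c1, c2, total_trt - c2], axis=-1)
    col1 = c1 + c2
    col2 = n - col1
    E = np.stack([
        total_ctrl * col1, total_ctrl * col2,
        total_trt * col1, total_trt * col2,
    ], axis=-1) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(np.where(O > 0, O, 1.0) / E), 0.0)
    g = 2.0 * terms.sum(axis=-1)
    g = np.maximum(g, 0.0)
    if williams:
        q = 1.0 + ((n / total_ctrl + n / total_trt - 1.0)
                   * (np.where(col1 > 0, n / col1, 0.0)
                      + np.where(col2 > 0, n / col2, 0.0) - 1.0)) / (6.0 * n)
        g = g / q
    # degenerate tables (an all-zero column) carry no signal
    degenerate = (col1 == 0) | (col2 == 0)
    g = np.where(degenerate, 0.0, g)
    p = chi2.sf(g, df=1)
    p = np.where(degenerate, 1.0, p)
    return g, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min over j >= i of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_change(rpkm_reported_trt: float, rpkm_reported_ctrl: float) -> float:
    """Treatment/control ratio of pseudocount-incremented RPKM."""
    return rpkm_reported_trt / rpkm_reported_ctrl


def call_de(
    table: pd.DataFrame,
    fdr_threshold: float = 0.01,
    williams: bool = False,
) -> pd.DataFrame:
    """Per-transcript DE calls for one tissue.

    ``table`` must carry columns count_ctrl, count_trt, rpkm_ctrl,
    rpkm_trt (incremented RPKM) and attrs or columns total_ctrl/total_trt.
    Transcripts with zero counts in both treatments are excluded from
    testing (and from m in the BH correction); they are returned with
    call 'ns' and NaN statistics.
    """
    t = table.copy()
    total_ctrl = int(t["total_ctrl"].iloc[0]) if "total_ctrl" in t else int(t.attrs["total_ctrl"])
    total_trt = int(t["total_trt"].iloc[0]) if "total_trt" in t else int(t.attrs["total_trt"])
    tested = (t["count_ctrl"] + t["count_trt"]) > 0
    g = np.full(len(t), np.nan)
    p = np.full(len(t), np.nan)
    q = np.full(len(t), np.nan)
    if tested.any():
        g_t, p_t = g_test_many(
            t.loc[tested, "count_ctrl"].to_numpy(),
            total_ctrl,
            t.loc[tested, "count_trt"].to_numpy(),
            total_trt,
            williams=williams,
        )
        g[tested.to_numpy()] = g_t
        p[tested.to_numpy()] = p_t
        q[tested.to_numpy()] = bh_fdr(p_t)
    fold = t["rpkm_trt"] / t["rpkm_ctrl"]
    call = np.where(
        tested & (q < fdr_threshold) & (fold > 1.0), "up",
        np.where(tested & (q < fdr_threshold) & (fold < 1.0), "down", "ns"),
    )
    out = t.assign(
        total_ctrl=total_ctrl, total_trt=total_trt,
        g_stat=g, p_value=p, q_value=q, fold_change=fold, call=call,
    )
    return out
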