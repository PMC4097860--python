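"""Binomial methylation calling calibrated on an unmethylated spike-in.

Whole-genome bisulfite data report, per cytosine, the number of reads in
which the base escaped conversion (read as methylated, ``k``) out of the
total covering reads (``n``).  An unmethylated control genome (lambda phage
spiked into the library) measures the bisulfite non-conversion error rate
``e``: any methylated read at a control cytosine is a conversion failure.
A cytosine in the sample is called methylated when its counts are
inconsistent with pure non-conversion error, i.e. when the binomial upper
tail P(X >= k | n, e) survives Benjamini-Hochberg FDR control at ``alpha``.

Strands are tested independently (counts are per strand); sites below
``min_depth`` are reported as untested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STATUS_METHYLATED = "methylated"
STATUS_UNMETHYLATED = "unmethylated"
STATUS_UNTESTED = "untested"


def estimate_nonconversion(lambda_sites: pd.DataFrame) -> tuple[float, int]:
    """Pooled non-conversion rate from control cytosines.

    Returns ``(e, total_reads)`` with e = sum(k) / sum(n) over all control
    sites; the total read count supports a binomial confidence interval.
    """
    n_total = int(lambda_sites["eff_CT_count"].sum())
    if n_total == 0:
        raise ValueError("control has no covered cytosines (sum n == 0)")
    k_total = int(lambda_sites["C_count"].sum())
    return k_total / n_total, n_total


def assign_context(sequence: str, pos: int, strand: str) -> str:
    """Sequence context (CG/CHG/CHH) of the cytosine at 1-based ``pos``.

    On the minus strand the reverse complement is read right-to-left.
    Contexts truncated by the chromosome end default to CHH (the
    asymmetric fallback); this touches O(1) sites per chromosome.
    """
    i = pos - 1
    if strand == "+":
        if i >= len(sequence) or sequence[i] != "C":
            raise ValueError(f"base at {pos}(+) is not C")
        nxt = sequence[i + 1] if i + 1 < len(sequence) else None
        nxt2 = sequence[i + 2] if i + 2 < len(sequence) else None
    elif strand == "-":
        if i < 0 or i >= len(sequence) or sequence[i] != "G":
            raise ValueError(f"base at {pos}(-) is not C (G on forward)")
        nxt = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(sequence[i - 1]) if i - 1 >= 0 else None
        nxt2 = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(sequence[i - 2]) if i - 2 >= 0 else None
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if nxt == "G":
        return "CG"
    if nxt is None or nxt2 is None:
        return "CHH"
    return "CHG" if nxt2 == "G" else "CHH"


def binomial_upper_tail(k, n, e) -> np.ndarray:
    """P(X >= k) for X ~ Binomial(n, e); vectorised."""
    k = np.asarray(k)
    n = np.asarray(n)
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return stats.binom.sf(k - 1, n, e)


def call_sites(
    sites: pd.DataFrame,
    e: float,
    alpha: float = 0.05,
    min_depth: int = 1,
    per_context: bool = False,
) -> pd.DataFrame:
    """Binomial test + BH FDR over all sites; returns the calls table.

    Adds ``p_value``, ``q_value``, ``status`` and ``ratio`` columns.  BH is
    applied across all contexts jointly by default; ``per_context=True``
    corrects within each context separately.
    """
    if not (0.0 <= e < 1.0):
        raise ValueError("non-conversion rate e must be in [0, 1)")
    calls = sites.copy()
    if calls.empty:
        for col in ("p_value", "q_value"):
            calls[col] = pd.Series(dtype=float)
        calls["status"] = pd.Series(dtype=object)
        calls["ratio"] = pd.Series(dtype=float)
        return calls

    n = calls["eff_CT_count"].to_numpy()
    k = calls["C_count"].to_numpy()
    if (k > n).any() or (k < 0).any():
        raise ValueError("require 0 <= k <= n at every site")
    tested = n >= min_depth

    p = np.full(len(calls), np.nan)
    p[tested] = binomial_upper_tail(k[tested], n[tested], e)

    q = np.full(len(calls), np.nan)
    if per_context:
        for ctx in calls["context"].unique():
            m = tested & (calls["context"] == ctx).to_numpy()
            if m.any():
                q[m] = multipletests(p[m], method="fdr_bh")[1]
    elif tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    status = np.where(tested, STATUS_UNMETHYLATED, STATUS_UNTESTED).astype(object)
    status[tested & (q < alpha)] = STATUS_METHYLATED

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n > 0, k / np.where(n > 0, n, 1), np.nan)

    calls["p_value"] = p
    calls["q_value"] = q
    calls["status"] = status
    calls["ratio"] = ratio
    return calls
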