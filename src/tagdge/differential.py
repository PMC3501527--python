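"""Differential expression between two tag libraries.

The Audic-Claverie statistic treats the count of a transcript's tag in
each library as Poisson; conditional on the count x observed in library
1, the count y in library 2 follows

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

where N1, N2 are the library totals.  Equivalently, y | x is negative
binomial with x+1 successes and success probability N1/(N1+N2).  The
two-sided p-value doubles the smaller of the inclusive tails and is
capped at 1.  Everything is computed in log space (log-gamma) so counts
up to ~1e6 are stable.

A gene is called differentially expressed when FDR <= 0.001 and
|log2 ratio| >= 1 (both configurable).  FDR control is the
Benjamini-Hochberg step-up (Benjamini-Yekutieli by flag).  A ddCt
utility converts qRT-PCR Ct values to fold changes for validation.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


def _check_counts(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"negative counts: x={x}, y={y}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library sizes must be positive: N1={n1}, N2={n2}")


def log_ac_probability(x: int, y: int, n1: float, n2: float) -> float:
    """log p(y|x) under the Audic-Claverie model."""
    _check_counts(x, y, n1, n2)
    r = n2 / n1
    return (y * math.log(r)
            + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * math.log1p(r))


def ac_probability(x: int, y: int, n1: float, n2: float) -> float:
    """p(y|x): probability of y tags in library 2 given x in library 1."""
    return math.exp(log_ac_probability(x, y, n1, n2))


def _lower_tail(x: int, y: int, n1: float, n2: float) -> float:
    """P(K <= y) for K|x, by log-gamma summation over k = 0..y."""
    if y < 0:
        return 0.0
    k = np.arange(y + 1)
    log_q = math.log(n2) - math.log(n1 + n2)
    log_1mq = math.log(n1) - math.log(n1 + n2)
    logs = (k * log_q + gammaln(x + k + 1) - gammaln(x + 1) - gammaln(k + 1)
            + (x + 1) * log_1mq)
    return float(min(1.0, math.exp(logsumexp(logs))))


def _upper_tail_direct(x: int, y: int, n1: float, n2: float) -> float:
    """P(K >= y) by scaled recurrence summation from k = y upward.

    Terms follow t(k+1) = t(k) * q * (x+k+1)/(k+1); past the mode the
    ratio is < 1 and the remainder is bounded geometrically, so the sum
    stops when the bound drops below 1e-14 of the running total.
    """
    q = n2 / (n1 + n2)
    log_first = log_ac_probability(x, y, n1, n2)
    t = 1.0  # terms scaled by the first term
    total = 1.0
    k = y
    while True:
        ratio = q * (x + k + 1) / (k + 1)
        t *= ratio
        total += t
        k += 1
        if ratio < 1.0 and t * ratio / (1.0 - ratio) < 1e-14 * total:
            break
    return float(min(1.0, math.exp(log_first) * total))


def ac_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value: 2*min(P(K<=y), P(K>=y)), capped at 1."""
    _check_counts(x, y, n1, n2)
    mean = (x + 1) * n2 / n1  # mean of K|x
    lower = _lower_tail(x, y, n1, n2)
    if y <= mean:
        # upper tail is the large one; 1 - lower(y-1) loses nothing here
        upper = 1.0 - _lower_tail(x, y - 1, n1, n2) if y > 0 else 1.0
    else:
        upper = _upper_tail_direct(x, y, n1, n2)
    p = min(1.0, 2.0 * min(lower, upper))
    # both tails include y, so x = y with N1 = N2 caps at exactly 1;
    # absorb the last ulp of log-gamma roundoff
    return 1.0 if p > 1.0 - 1e-12 else p


def bh_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Step-up adjusted values controlling the FDR.

    ``method``: "bh" (Benjamini-Hochberg, default) or "by"
    (Benjamini-Yekutieli).  Adjusted values are monotone after sorting,
    each in [p_i, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if key is None:
        raise ValueError(f"unknown FDR method: {method!r}")
    return multipletests(p, method=key)[1]


def call_degs(
    counts: pd.DataFrame,
    n1: float,
    n2: float,
    fdr_threshold: float = 0.001,
    log2_threshold: float = 1.0,
    fdr_method: str = "bh",
    tpm_floor: float | None = None,
) -> pd.DataFrame:
    """Call differentially expressed genes between two libraries.

    Parameters
    ----------
    counts
        DataFrame with columns ``gene_id``, ``count_a``, ``count_b``
        (unambiguous tag counts in libraries A and B).
    n1, n2
        Normalisation totals of the two libraries (same denominator
        convention as the TPM step).
    tpm_floor
        Floor applied to each TPM before the log2 ratio so ratios stay
        finite; defaults to the TPM of a single tag in each library.

    Genes with zero counts in both libraries carry no evidence and are
    excluded from testing (they would only inflate the number of tests).
    """
    if fdr_threshold <= 0 or log2_threshold <= 0:
        raise ValueError("thresholds must be positive")
    df = counts.copy()
    if df.empty:
        return df.assign(tpm_a=[], tpm_b=[], log2_ratio=[], p_value=[],
                         fdr=[], significant=[], direction=[])
    df = df[(df["count_a"] > 0) | (df["count_b"] > 0)].reset_index(drop=True)
    if df.empty:
        return df.assign(tpm_a=[], tpm_b=[], log2_ratio=[], p_value=[],
                         fdr=[], significant=[], direction=[])

    df["tpm_a"] = 1e6 * df["count_a"] / n1
    df["tpm_b"] = 1e6 * df["count_b"] / n2
    floor_a = tpm_floor if tpm_floor is not None else 1e6 / n1
    floor_b = tpm_floor if tpm_floor is not None else 1e6 / n2
    df["log2_ratio"] = np.log2(np.maximum(df["tpm_b"], floor_b)
                               / np.maximum(df["tpm_a"], floor_a))
    df["p_value"] = [
        ac_pvalue(int(xa), int(yb), n1, n2)
        for xa, yb in zip(df["count_a"], df["count_b"])
    ]
    df["fdr"] = bh_fdr(df["p_value"].to_numpy(), method=fdr_method)
    df["significant"] = (df["fdr"] <= fdr_threshold) & \
                        (df["log2_ratio"].abs() >= log2_threshold)
    df["direction"] = np.where(
        ~df["significant"], "none",
        np.where(df["log2_ratio"] > 0, "up", "down"))
    return df


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qRT-PCR quantification: fold change = 2^(-ddCt).

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the calibrator.
    """
    ddct = ((ct_target_sample - ct_ref_sample)
            - (ct_target_calibrator - ct_ref_calibrator))
    return 2.0 ** (-ddct)
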