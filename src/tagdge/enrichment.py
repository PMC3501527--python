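"""Hypergeometric term enrichment of a DEG set against the annotated background.

For a term annotating M of the N annotated background genes, with n DEGs
drawn of which m carry the term, the enrichment p-value is the upper
tail of the hypergeometric distribution,

    P = 1 - sum_{i=0}^{m-1} C(M,i) * C(N-M, n-i) / C(N,n)  =  P(X >= m),

computed here with log-gamma binomial coefficients.  Terms are tested
flat (no ontology-graph propagation); a gene counts once per term
regardless of evidence lines.  In GO mode significance is
corrected P <= alpha; in pathway mode the BH q-value <= alpha.
"""

from __future__ import annotations

import logging
import math
from typing import Collection

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .differential import bh_fdr

log = logging.getLogger(__name__)


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _check_input(N: int, n: int, M: int, m: int) -> None:
    if not (0 <= m <= min(n, M) and n <= N and M <= N and n >= 0 and M >= 0):
        raise ValueError(
            f"invalid enrichment input: N={N}, n={n}, M={M}, m={m}")


def hypergeom_pvalue(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    Summed directly over i = m..min(n, M); terms with n - i > N - M are
    impossible and contribute zero.  m = 0 always yields 1.
    """
    _check_input(N, n, M, m)
    if m == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    terms = []
    for i in range(m, min(n, M) + 1):
        if n - i > N - M:
            continue
        terms.append(_log_comb(M, i) + _log_comb(N - M, n - i) - log_denom)
    if not terms:
        return 0.0
    top = max(terms)
    return float(min(1.0, math.exp(top) * sum(math.exp(t - top) for t in terms)))


def enrich_terms(
    deg_genes: Collection[str],
    annotation_table: pd.DataFrame,
    mode: str = "go",
    alpha: float = 0.05,
    correction: str = "bh",
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Test every annotation term for enrichment in the DEG set.

    Parameters
    ----------
    deg_genes
        Differentially expressed gene ids.  DEGs without any annotation
        are dropped (with a logged count): the background is the
        annotated gene universe.
    annotation_table
        DataFrame with columns ``gene_id`` and ``term_id`` (extra
        columns ignored).
    mode
        "go" (significant when corrected P <= alpha) or "pathway"
        (significant when q-value <= alpha).
    correction
        "bh" (default) or "bonferroni" for the corrected P column; the
        q-value column is always the BH-adjusted value.
    min_term_size
        Terms annotating fewer than this many genes are skipped.

    Returns a DataFrame sorted by raw p-value with columns term_id, N,
    n, M, m, p_raw, p_corrected, q_value, significant.
    """
    if mode not in ("go", "pathway"):
        raise ValueError(f"unknown mode: {mode!r}")
    if annotation_table.empty:
        raise ValueError("empty annotation table")
    ann = annotation_table[["gene_id", "term_id"]].drop_duplicates()
    universe = set(ann["gene_id"])
    N = len(universe)
    degs = set(deg_genes)
    dropped = len(degs - universe)
    if dropped:
        log.info("dropping %d unannotated DEGs from enrichment", dropped)
    degs &= universe
    n = len(degs)

    rows = []
    for term_id, genes in ann.groupby("term_id")["gene_id"]:
        term_genes = set(genes)
        M = len(term_genes)
        if M < min_term_size:
            continue
        m = len(term_genes & degs)
        rows.append({"term_id": term_id, "N": N, "n": n, "M": M, "m": m,
                     "p_raw": hypergeom_pvalue(N, n, M, m)})
    if not rows:
        raise ValueError("no terms left to test (min_term_size too high?)")
    df = pd.DataFrame(rows)
    if correction == "bh":
        df["p_corrected"] = bh_fdr(df["p_raw"].to_numpy())
    elif correction == "bonferroni":
        df["p_corrected"] = np.minimum(df["p_raw"] * len(df), 1.0)
    else:
        raise ValueError(f"unknown correction: {correction!r}")
    df["q_value"] = bh_fdr(df["p_raw"].to_numpy())
    sig_col = "p_corrected" if mode == "go" else "q_value"
    df["significant"] = df[sig_col] <= alpha
    return df.sort_values(["p_raw", "term_id"], kind="mergesort",
                          ignore_index=True)
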