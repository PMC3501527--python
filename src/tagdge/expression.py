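"""Tag-to-gene mapping and TPM quantification.

Clean tags are mapped to the reference tag library permitting at most a
one-base mismatch.  A tag is *unambiguous* when its matches fall within
exactly one gene, *ambiguous* when they span two or more genes, and
*unknown* when nothing in the reference lies within Hamming distance 1.
Gene expression is the sum of unambiguous tag counts, scaled to TPM
(transcripts per million tags).

The one-mismatch search enumerates the 63 Hamming-1 neighbours of each
query against a hash index of the reference; the contract is defined by
the brute-force Hamming oracle in the test suite, not by this strategy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .tag_library import ReferenceTagLibrary, TAG_LENGTH

_BASES = "ACGT"


@dataclass(frozen=True)
class TagAssignment:
    tag: str
    count: int
    match_class: str            # exact | one_mismatch | unknown
    matched_genes: frozenset[str]

    @property
    def status(self) -> str:
        """unambiguous / ambiguous / unknown, by |matched_genes| alone."""
        n = len(self.matched_genes)
        if n == 0:
            return "unknown"
        return "unambiguous" if n == 1 else "ambiguous"


@dataclass
class MappingStats:
    clean_total: int
    clean_distinct: int
    all_mapped_total: int
    distinct_mapped: int
    unambiguous_total: int
    distinct_unambiguous: int
    genes_mapped: int
    genes_unambiguous: int
    unknown_total: int
    distinct_unknown: int
    genes_total: int

    def validate(self) -> None:
        if self.all_mapped_total + self.unknown_total != self.clean_total:
            raise ValueError("mapping conservation violated: "
                             f"{self.all_mapped_total} + {self.unknown_total} "
                             f"!= {self.clean_total}")


def hamming1_neighbors(tag: str) -> Iterable[str]:
    """The 3*len(tag) sequences at Hamming distance exactly 1 from *tag*."""
    for i, base in enumerate(tag):
        for alt in _BASES:
            if alt != base:
                yield tag[:i] + alt + tag[i + 1:]


def match_tag(
    tag: str,
    library: ReferenceTagLibrary,
    prefer_exact: bool = True,
) -> tuple[str, frozenset[str]]:
    """Classify one clean tag against the reference.

    Returns ``(match_class, matched reference tag sequences)``.  With
    ``prefer_exact`` (default) a verbatim hit preempts the one-mismatch
    search; with ``prefer_exact=False`` exact and distance-1 hits are
    pooled.
    """
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag length {len(tag)} != {TAG_LENGTH}: {tag!r}")
    exact = tag in library.tags
    if exact and prefer_exact:
        return "exact", frozenset([tag])
    near = frozenset(n for n in hamming1_neighbors(tag) if n in library.tags)
    if exact:
        return "exact", near | {tag}
    if near:
        return "one_mismatch", near
    return "unknown", frozenset()


def assign_tags(
    clean_tags: Mapping[str, int],
    library: ReferenceTagLibrary,
    prefer_exact: bool = True,
) -> tuple[list[TagAssignment], MappingStats]:
    """Map a clean tag set; returns per-tag assignments plus summary stats.

    Totals aggregate over read counts; *distinct* figures count tag
    species.  Ambiguous tags are included in the all-mapped totals but
    contribute to no gene's unambiguous count.
    """
    assignments: list[TagAssignment] = []
    mapped_total = mapped_distinct = 0
    unamb_total = unamb_distinct = 0
    unknown_total = unknown_distinct = 0
    genes_any: set[str] = set()
    genes_unamb: set[str] = set()
    for tag in sorted(clean_tags):
        count = clean_tags[tag]
        match_class, matched = match_tag(tag, library, prefer_exact=prefer_exact)
        genes = frozenset().union(*(library.genes_of(m) for m in matched)) \
            if matched else frozenset()
        a = TagAssignment(tag=tag, count=count, match_class=match_class,
                          matched_genes=genes)
        assignments.append(a)
        if a.status == "unknown":
            unknown_total += count
            unknown_distinct += 1
        else:
            mapped_total += count
            mapped_distinct += 1
            genes_any |= genes
            if a.status == "unambiguous":
                unamb_total += count
                unamb_distinct += 1
                genes_unamb |= genes
    stats = MappingStats(
        clean_total=sum(clean_tags.values()),
        clean_distinct=len(clean_tags),
        all_mapped_total=mapped_total,
        distinct_mapped=mapped_distinct,
        unambiguous_total=unamb_total,
        distinct_unambiguous=unamb_distinct,
        genes_mapped=len(genes_any),
        genes_unambiguous=len(genes_unamb),
        unknown_total=unknown_total,
        distinct_unknown=unknown_distinct,
        genes_total=library.genes_total,
    )
    stats.validate()
    return assignments, stats


def count_genes(
    assignments: Iterable[TagAssignment],
    library: ReferenceTagLibrary,
) -> pd.DataFrame:
    """Per-gene unambiguous tag counts (zero-count genes included).

    Ambiguous tags contribute to no gene; unknown tags to none either.
    """
    counts: Counter = Counter()
    for a in assignments:
        if a.status == "unambiguous":
            (gene,) = a.matched_genes
            counts[gene] += a.count
    return pd.DataFrame({
        "gene_id": library.gene_ids,
        "unambiguous_count": [counts.get(g, 0) for g in library.gene_ids],
    })


def tpm_normalize(
    records: pd.DataFrame,
    denominator_mode: str = "clean_total",
    clean_total: int | None = None,
) -> pd.DataFrame:
    """Fill the ``tpm`` column: 1e6 * unambiguous_count / denominator.

    ``denominator_mode="clean_total"`` (tags per million clean tags;
    requires *clean_total*) or ``"unambiguous_total"`` (TPMs then sum to
    1e6).  A zero denominator is an error.
    """
    if denominator_mode == "clean_total":
        if clean_total is None:
            raise ValueError("clean_total required for denominator_mode='clean_total'")
        denom = clean_total
    elif denominator_mode == "unambiguous_total":
        denom = int(records["unambiguous_count"].sum())
    else:
        raise ValueError(f"unknown denominator_mode: {denominator_mode!r}")
    if denom <= 0:
        raise ValueError("TPM denominator must be positive")
    out = records.copy()
    out["tpm"] = 1e6 * out["unambiguous_count"] / denom
    return out


def quantify_library(
    clean_tags: Mapping[str, int],
    library: ReferenceTagLibrary,
    denominator_mode: str = "clean_total",
    prefer_exact: bool = True,
) -> tuple[pd.DataFrame, MappingStats]:
    """Convenience: assign -> count -> TPM for one clean library."""
    assignments, stats = assign_tags(clean_tags, library, prefer_exact=prefer_exact)
    records = count_genes(assignments, library)
    records = tpm_normalize(records, denominator_mode=denominator_mode,
                            clean_total=stats.clean_total)
    return records, stats
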