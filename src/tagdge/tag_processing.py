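"""Raw-tag cleaning and library statistics.

Raw DGE reads come in four classes: genuine 21-base tags, adapter-only
("empty") reads, reads containing undetermined bases (N), and spurious
singletons.  Cleaning removes, in order, adapter-only reads, N-containing
reads, and finally every tag whose remaining copy number is exactly 1
(singletons are most likely sequencing errors).  The surviving multiset
is the clean tag set; every clean tag has count >= 2.

This module also produces the library summary (raw/clean/mapped counts
and percentages) and the copy-number distribution of clean tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Sentinel for adapter-only reads; deliberately not a valid 21-mer.
ADAPTER_SENTINEL = "ADAPTER_ONLY"


def round_half_up(x: float | Decimal, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage rounded half-up; 0.00 when the denominator is zero."""
    if denominator == 0:
        return 0.0
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass
class FilterStats:
    raw_total: int
    raw_distinct: int
    n_adapter_only: int
    n_containing_N: int
    n_copy_number_1: int
    clean_total: int
    clean_distinct: int

    @property
    def clean_pct_of_raw(self) -> float:
        return pct(self.clean_total, self.raw_total)

    def validate(self) -> None:
        expected = (self.raw_total - self.n_adapter_only
                    - self.n_containing_N - self.n_copy_number_1)
        if self.clean_total != expected:
            raise ValueError(
                f"filter conservation violated: clean_total={self.clean_total}, "
                f"expected {expected}")


def _as_counter(raw_tags: Mapping[str, int] | Iterable[str]) -> Counter:
    if isinstance(raw_tags, Mapping):
        counter = Counter()
        for tag, count in raw_tags.items():
            if count < 0:
                raise ValueError(f"negative count for {tag!r}")
            if count:
                counter[tag] = int(count)
        return counter
    return Counter(raw_tags)


def filter_raw_tags(
    raw_tags: Mapping[str, int] | Iterable[str],
) -> tuple[Counter, FilterStats]:
    """Clean a raw tag multiset; returns (clean counts, FilterStats).

    Removal order: adapter-only sentinel reads first, then any read whose
    sequence contains 'N', then every tag whose total count within the
    library is exactly 1.  Empty input yields empty output with zeroed
    statistics.
    """
    raw = _as_counter(raw_tags)
    raw_total = sum(raw.values())
    raw_distinct = len(raw)

    n_adapter = raw.pop(ADAPTER_SENTINEL, 0)
    n_with_n = 0
    kept = Counter()
    for tag, count in raw.items():
        if "N" in tag:
            n_with_n += count
        else:
            kept[tag] = count
    n_singleton = sum(c for c in kept.values() if c == 1)
    clean = Counter({tag: c for tag, c in kept.items() if c >= 2})

    stats = FilterStats(
        raw_total=raw_total,
        raw_distinct=raw_distinct,
        n_adapter_only=n_adapter,
        n_containing_N=n_with_n,
        n_copy_number_1=n_singleton,
        clean_total=sum(clean.values()),
        clean_distinct=len(clean),
    )
    stats.validate()
    return clean, stats


# ---------------------------------------------------------------------------
# Copy-number distribution (distribution of clean-tag expression levels)
# ---------------------------------------------------------------------------

#: Default bins over copy number, lower/upper inclusive; None = open-ended.
DEFAULT_BINS: tuple[tuple[int, int | None], ...] = (
    (2, 5), (6, 10), (11, 20), (21, 50), (51, 100), (101, None),
)


def _check_bins(bins: Sequence[tuple[int, int | None]]) -> None:
    if not bins:
        raise ValueError("no bins given")
    prev_upper = 1
    for i, (lo, hi) in enumerate(bins):
        if lo != prev_upper + 1:
            raise ValueError(
                f"bins must partition [2, inf) contiguously; bin {i} starts at "
                f"{lo}, expected {prev_upper + 1}")
        if hi is None:
            if i != len(bins) - 1:
                raise ValueError("only the last bin may be open-ended")
            return
        if hi < lo:
            raise ValueError(f"empty bin ({lo}, {hi})")
        prev_upper = hi
    raise ValueError("last bin must be open-ended to cover [2, inf)")


def copy_number_distribution(
    clean_tags: Mapping[str, int],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Bin clean tags by copy number.

    Returns a DataFrame with one row per bin: label, total tag count,
    distinct tag count, and each as a percentage of the clean totals.
    Bin totals conserve the clean totals exactly.
    """
    _check_bins(bins)
    clean_total = sum(clean_tags.values())
    clean_distinct = len(clean_tags)
    totals = [0] * len(bins)
    distincts = [0] * len(bins)
    for count in clean_tags.values():
        for i, (lo, hi) in enumerate(bins):
            if count >= lo and (hi is None or count <= hi):
                totals[i] += count
                distincts[i] += 1
                break
    rows = []
    for (lo, hi), total, distinct in zip(bins, totals, distincts):
        label = f"[{lo},{hi}]" if hi is not None else f">{lo - 1}"
        rows.append({
            "bin": label,
            "total": total,
            "distinct": distinct,
            "pct_of_total_clean": pct(total, clean_total),
            "pct_of_distinct_clean": pct(distinct, clean_distinct),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Library summary report
# ---------------------------------------------------------------------------

ROW_NAMES = [
    "Raw Data",
    "Distinct Raw Data",
    "Clean Tag",
    "Distinct Clean Tag",
    "Clean Tag/Raw Tag (%)",
    "All Tag Mapping to Gene",
    "All Tag Mapping to Gene (% of Clean Tag)",
    "Distinct All Tag Mapping to Gene",
    "Distinct All Tag Mapping to Gene (% of Distinct Clean Tag)",
    "Unambiguous Tag Mapping to Gene",
    "Unambiguous Tag Mapping to Gene (% of Clean Tag)",
    "Distinct Unambiguous Tag Mapping to Gene",
    "Distinct Unambiguous Tag Mapping to Gene (% of Distinct Clean Tag)",
    "All Tag-mapped Genes",
    "All Tag-mapped Genes (% of Reference Genes)",
    "Unambiguous Tag-mapped Genes",
    "Unambiguous Tag-mapped Genes (% of Reference Genes)",
    "Unknown Tag",
    "Unknown Tag (% of Clean Tag)",
    "Distinct Unknown Tag",
    "Distinct Unknown Tag (% of Distinct Clean Tag)",
]


def library_stats(filter_stats: FilterStats, mapping_stats) -> dict[str, float]:
    """One library's summary row set (counts and half-up 2-decimal %)."""
    fs, ms = filter_stats, mapping_stats
    return {
        "Raw Data": fs.raw_total,
        "Distinct Raw Data": fs.raw_distinct,
        "Clean Tag": fs.clean_total,
        "Distinct Clean Tag": fs.clean_distinct,
        "Clean Tag/Raw Tag (%)": fs.clean_pct_of_raw,
        "All Tag Mapping to Gene": ms.all_mapped_total,
        "All Tag Mapping to Gene (% of Clean Tag)":
            pct(ms.all_mapped_total, fs.clean_total),
        "Distinct All Tag Mapping to Gene": ms.distinct_mapped,
        "Distinct All Tag Mapping to Gene (% of Distinct Clean Tag)":
            pct(ms.distinct_mapped, fs.clean_distinct),
        "Unambiguous Tag Mapping to Gene": ms.unambiguous_total,
        "Unambiguous Tag Mapping to Gene (% of Clean Tag)":
            pct(ms.unambiguous_total, fs.clean_total),
        "Distinct Unambiguous Tag Mapping to Gene": ms.distinct_unambiguous,
        "Distinct Unambiguous Tag Mapping to Gene (% of Distinct Clean Tag)":
            pct(ms.distinct_unambiguous, fs.clean_distinct),
        "All Tag-mapped Genes": ms.genes_mapped,
        "All Tag-mapped Genes (% of Reference Genes)":
            pct(ms.genes_mapped, ms.genes_total),
        "Unambiguous Tag-mapped Genes": ms.genes_unambiguous,
        "Unambiguous Tag-mapped Genes (% of Reference Genes)":
            pct(ms.genes_unambiguous, ms.genes_total),
        "Unknown Tag": ms.unknown_total,
        "Unknown Tag (% of Clean Tag)": pct(ms.unknown_total, fs.clean_total),
        "Distinct Unknown Tag": ms.distinct_unknown,
        "Distinct Unknown Tag (% of Distinct Clean Tag)":
            pct(ms.distinct_unknown, fs.clean_distinct),
    }


def summary_table(per_library: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Assemble per-library rows into a summary table with an Averages column.

    Count rows are averaged and rounded half-up to integers; percentage
    rows are the mean of the per-library (already rounded) percentages,
    rounded half-up to 2 decimals — the convention of printed summaries.
    """
    df = pd.DataFrame(per_library, index=ROW_NAMES, dtype=object)
    averages = []
    for row in df.index:
        mean = sum(df.loc[row]) / len(df.columns)
        if "%" in row:
            averages.append(round_half_up(mean, 2))
        else:
            averages.append(int(round_half_up(mean, 0)))
    df["Averages"] = averages
    return df


def write_tag_counts_tsv(counts: Mapping[str, int], path) -> None:
    """Write a (tag, count) table, tags sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for tag in sorted(counts):
            fh.write(f"{tag}\t{counts[tag]}\n")


def read_tag_counts_tsv(path) -> Counter:
    """Read raw tags: either a (tag, count) TSV with header, or one tag per line."""
    counts: Counter = Counter()
    with open(path) as fh:
        first = fh.readline()
        if not first:
            return counts
        header = first.rstrip("\n").split("\t")
        if header[:2] == ["tag", "count"]:
            for line in fh:
                if not line.strip():
                    continue
                tag, count = line.rstrip("\n").split("\t")[:2]
                counts[tag] += int(count)
        else:
            for line in [first] + fh.readlines():
                tag = line.strip()
                if tag:
                    counts[tag] += 1
    return counts
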