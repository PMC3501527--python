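"""Synthetic transcriptomes, expression truths, tag libraries and annotations.

The generators emulate the statistical structure the downstream analysis
assumes: a transcriptome of unigene-like sequences containing CATG
anchor sites, log-normally distributed transcript abundances, multinomial
tag sampling at library sizes of 1e5-1e6, independent per-base
substitution errors, adapter-only and N-containing reads, unique random
singleton noise, and a configurable set of truly differentially
expressed genes with known log2 fold changes.  Every generator is
deterministic under its seed.

The simulator emits only each gene's *canonical* tag (the 3'-most
qualifying CATG site), mirroring the bead-bound 3'-fragment chemistry;
the reference library downstream still indexes all sites.  That
asymmetry is intentional and mirrors the protocol.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tag_library import canonical_tag, extract_tags, TAG_LENGTH
from .tag_processing import ADAPTER_SENTINEL

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeParams:
    """Parameters of a synthetic transcriptome.

    Lengths are log-normal with the given median and log-space sigma,
    clipped below at ``min_length`` (25 bp: one CATG plus 17 downstream
    bases with a little slack).  The default median length of 474 bp
    matches a typical short-read unigene assembly.
    """

    n_genes: int
    length_median: float = 474.0
    length_sigma: float = 0.6
    gc: float = 0.42
    fraction_untaggable: float = 0.0
    min_length: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        if not 0.0 <= self.fraction_untaggable <= 1.0:
            raise ValueError("fraction_untaggable must lie in [0, 1]")
        if self.length_median < self.min_length or self.length_sigma < 0:
            raise ValueError("invalid length distribution parameters")


@dataclass
class SyntheticTranscriptome:
    records: list[tuple[str, str]]
    untaggable_ids: frozenset[str]
    params: TranscriptomeParams

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.records]

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.records)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _decode(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode()


def _has_qualifying_site(seq: str) -> bool:
    return len(extract_tags(seq)) > 0


def generate_transcriptome(params: TranscriptomeParams) -> SyntheticTranscriptome:
    """Generate gene sequences with a controlled number of untaggable genes.

    Exactly ``round(fraction_untaggable * n_genes)`` genes contain no
    CATG site with >= 17 downstream bases; every taggable gene contains
    at least one (planted if the random sequence happens to lack one).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    n_untag = _round_half_up(params.fraction_untaggable * n)
    untag_idx = set(rng.choice(n, size=n_untag, replace=False).tolist())

    records: list[tuple[str, str]] = []
    untaggable: set[str] = set()
    width = max(5, len(str(n)))
    for i in range(n):
        gene_id = f"gene{i + 1:0{width}d}"
        length = max(params.min_length,
                     int(rng.lognormal(np.log(params.length_median),
                                       params.length_sigma)))
        seq = _random_sequence(rng, length, params.gc)
        text = _decode(seq)
        if i in untag_idx:
            text = _destroy_sites(rng, text)
            untaggable.add(gene_id)
        elif not _has_qualifying_site(text):
            pos = int(rng.integers(0, length - TAG_LENGTH + 1))
            seq[pos:pos + 4] = [1, 0, 3, 2]  # C A T G in index space
            text = _decode(seq)
        records.append((gene_id, text))
    return SyntheticTranscriptome(records=records,
                                  untaggable_ids=frozenset(untaggable),
                                  params=params)


def _destroy_sites(rng: np.random.Generator, seq: str) -> str:
    """Mutate bases until no CATG site has >= 17 downstream bases."""
    chars = list(seq)
    while True:
        tags = extract_tags("".join(chars))
        if not tags:
            return "".join(chars)
        for pos, _ in tags:
            chars[pos] = "ACGT"[int(rng.integers(0, 4))]
            while chars[pos] == "C":
                chars[pos] = "ACGT"[int(rng.integers(0, 4))]


# ---------------------------------------------------------------------------
# Expression truth
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """True relative abundances per library plus the DE truth table.

    ``abundance`` is genes x libraries, each column on the simplex
    (sums to 1).  ``log2fc`` holds the assigned true log2 fold change of
    library 2 relative to library 1 (0 for non-DE genes), *before* the
    renormalisation that returns library 2 to the simplex.
    """

    abundance: pd.DataFrame
    log2fc: pd.Series

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.log2fc.index[self.log2fc != 0.0])


def make_expression_truth(
    gene_ids: Sequence[str],
    base_sigma: float = 2.0,
    de_fraction: float = 0.0,
    log2fc_values: Sequence[float] = (2.0, -2.0),
    n_libraries: int = 2,
    seed: int = 0,
    de_eligible: Sequence[str] | None = None,
) -> ExpressionTruth:
    """Draw log-normal base abundances and plant DE genes.

    Library 1 is the reference.  For each DE gene the library-2
    abundance is the reference abundance times 2^(assigned log2fc);
    all libraries are then renormalised to the simplex.  Libraries
    beyond the second copy the reference.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if de_fraction > 0 and not log2fc_values:
        raise ValueError("log2fc_values must be nonempty when de_fraction > 0")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    n = len(genes)
    base = rng.lognormal(mean=0.0, sigma=base_sigma, size=n)
    base = base / base.sum()

    eligible = list(de_eligible) if de_eligible is not None else genes
    n_de = min(_round_half_up(de_fraction * n), len(eligible))
    de_pick = rng.choice(len(eligible), size=n_de, replace=False)
    log2fc = pd.Series(0.0, index=genes, name="true_log2fc")
    fc_values = np.asarray(log2fc_values, dtype=float)
    for j in de_pick:
        log2fc[eligible[int(j)]] = float(fc_values[int(rng.integers(len(fc_values)))])

    cols = {}
    lib_names = [f"lib{i + 1}" for i in range(n_libraries)]
    cols[lib_names[0]] = base
    if n_libraries >= 2:
        lib2 = base * np.power(2.0, log2fc.to_numpy())
        cols[lib_names[1]] = lib2 / lib2.sum()
    for name in lib_names[2:]:
        cols[name] = base
    abundance = pd.DataFrame(cols, index=genes)
    return ExpressionTruth(abundance=abundance, log2fc=log2fc)


def assign_expression(
    transcriptome: SyntheticTranscriptome,
    base_sigma: float = 2.0,
    de_fraction: float = 0.0,
    log2fc_values: Sequence[float] = (2.0, -2.0),
    n_libraries: int = 2,
    seed: int = 0,
    de_eligible: Sequence[str] | None = None,
) -> ExpressionTruth:
    """Expression truth for a transcriptome.

    Like :func:`make_expression_truth`, but DE genes default to being
    drawn from taggable genes only — the assay cannot observe a gene
    without a qualifying CATG site.
    """
    if de_eligible is None:
        de_eligible = [g for g in transcriptome.gene_ids
                       if g not in transcriptome.untaggable_ids]
    return make_expression_truth(
        transcriptome.gene_ids, base_sigma=base_sigma,
        de_fraction=de_fraction, log2fc_values=log2fc_values,
        n_libraries=n_libraries, seed=seed, de_eligible=de_eligible)


def simulate_counts(truth: ExpressionTruth, library_id: str,
                    library_size: int, seed: int = 0) -> pd.Series:
    """Count-level sampling: multinomial gene counts, no reads or errors.

    Useful for large calibration experiments where only the per-gene
    counts matter.
    """
    rng = np.random.default_rng(seed)
    p = truth.abundance[library_id].to_numpy(dtype=float)
    counts = rng.multinomial(library_size, p / p.sum())
    return pd.Series(counts, index=truth.abundance.index, name=library_id)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLibrary:
    """One simulated raw tag library with its emission ground truth."""

    library_id: str
    raw_tags: Counter
    library_size: int
    error_rate: float
    adapter_fraction: float
    n_fraction: float
    singleton_noise_fraction: float
    seed: int
    n_adapter: int = 0
    n_n_reads: int = 0
    n_noise: int = 0
    n_tag_reads: int = 0
    true_gene_counts: Counter = field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.raw_tags.values())


def _mutate_reads(rng: np.random.Generator, rows: np.ndarray,
                  error_rate: float) -> np.ndarray:
    """Apply >= 1 substitution to every row (exact conditional distribution).

    Masks are per-base Bernoulli(error_rate); all-zero masks are redrawn
    until nonzero, which is rejection sampling from the conditional law
    given at least one substitution.
    """
    n = rows.shape[0]
    mask = rng.random(rows.shape) < error_rate
    empty = ~mask.any(axis=1)
    while empty.any():
        mask[empty] = rng.random((int(empty.sum()), rows.shape[1])) < error_rate
        empty = ~mask.any(axis=1)
    shifts = rng.integers(1, 4, size=rows.shape, dtype=np.uint8)
    out = rows.copy()
    out[mask] = (out[mask] + shifts[mask]) % 4
    return out


def _random_kmers(rng: np.random.Generator, n: int, k: int,
                  forbidden: set[str]) -> list[str]:
    """n distinct random k-mers avoiding *forbidden* (rejection sampling)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        idx = rng.integers(0, 4, size=k).astype(np.uint8)
        kmer = _decode(idx)
        if kmer in seen or kmer in forbidden:
            continue
        seen.add(kmer)
        out.append(kmer)
    return out


def simulate_library(
    transcriptome: SyntheticTranscriptome,
    truth: ExpressionTruth,
    library_id: str,
    library_size: int,
    error_rate: float = 0.0,
    adapter_fraction: float = 0.0,
    n_fraction: float = 0.0,
    singleton_noise_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedLibrary:
    """Sample one raw tag library.

    Reads fall into four classes whose counts are drawn multinomially
    from (adapter_fraction, n_fraction, singleton_noise_fraction, rest)
    and always sum to *library_size* exactly.  Tag reads draw each
    gene's canonical tag multinomially from the truth abundances, with
    independent per-base substitution at *error_rate*; N-reads are tag
    draws with one position overwritten by 'N'; noise reads are unique
    random 21-mers (copy number 1); adapter-only reads are a sentinel
    that is never a valid 21-mer.

    Abundance assigned to untaggable genes is zeroed and redistributed
    proportionally (such transcripts yield no tag in the real protocol);
    a warning is logged when this happens.
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    fractions = (adapter_fraction, n_fraction, singleton_noise_fraction)
    if any(f < 0 for f in fractions) or sum(fractions) >= 1.0:
        raise ValueError("read-class fractions must be nonnegative and sum to < 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    if library_id not in truth.abundance.columns:
        raise ValueError(f"unknown library_id: {library_id!r}")
    rng = np.random.default_rng(seed)

    genes = transcriptome.gene_ids
    abundance = truth.abundance[library_id].to_numpy(dtype=float).copy()
    canon = {g: canonical_tag(s) for g, s in transcriptome.records}
    untagged_mass = sum(abundance[i] for i, g in enumerate(genes)
                        if canon[g] is None)
    if untagged_mass > 0:
        log.warning("%s: zeroing abundance %.3g assigned to untaggable genes "
                    "and renormalising", library_id, untagged_mass)
        for i, g in enumerate(genes):
            if canon[g] is None:
                abundance[i] = 0.0
    if abundance.sum() <= 0:
        raise ValueError("no taggable gene has positive abundance")
    abundance = abundance / abundance.sum()

    n_adapter, n_n, n_noise, n_tags = rng.multinomial(
        library_size,
        [adapter_fraction, n_fraction, singleton_noise_fraction,
         1.0 - sum(fractions)])

    raw: Counter = Counter()
    if n_adapter:
        raw[ADAPTER_SENTINEL] = int(n_adapter)

    # tag reads: multinomial over genes, then error injection
    gene_counts = rng.multinomial(int(n_tags), abundance)
    true_counts = Counter({g: int(c) for g, c in zip(genes, gene_counts) if c})
    p_any_err = 1.0 - (1.0 - error_rate) ** TAG_LENGTH if error_rate else 0.0
    err_rows: list[np.ndarray] = []
    lut = np.full(256, 255, dtype=np.uint8)
    for b, v in zip(b"ACGT", range(4)):
        lut[b] = v
    for g, c in true_counts.items():
        tag = canon[g]
        n_err = int(rng.binomial(c, p_any_err)) if p_any_err else 0
        if c - n_err:
            raw[tag] += c - n_err
        if n_err:
            row = lut[np.frombuffer(tag.encode(), dtype=np.uint8)]
            err_rows.append(np.tile(row, (n_err, 1)))
    if err_rows:
        rows = _mutate_reads(rng, np.concatenate(err_rows), error_rate)
        for read in rows:
            raw[_decode(read)] += 1

    # N-containing reads: tag draws with one base overwritten by N
    if n_n:
        picks = rng.choice(len(genes), size=int(n_n), p=abundance)
        positions = rng.integers(0, TAG_LENGTH, size=int(n_n))
        for i, pos in zip(picks, positions):
            tag = canon[genes[int(i)]]
            raw[tag[:int(pos)] + "N" + tag[int(pos) + 1:]] += 1

    # singleton noise: unique random 21-mers, never a canonical tag
    canonical_set = {t for t in canon.values() if t is not None}
    for kmer in _random_kmers(rng, int(n_noise), TAG_LENGTH, canonical_set):
        raw[kmer] += 1

    lib = SimulatedLibrary(
        library_id=library_id, raw_tags=raw, library_size=library_size,
        error_rate=error_rate, adapter_fraction=adapter_fraction,
        n_fraction=n_fraction, singleton_noise_fraction=singleton_noise_fraction,
        seed=seed, n_adapter=int(n_adapter), n_n_reads=int(n_n),
        n_noise=int(n_noise), n_tag_reads=int(n_tags),
        true_gene_counts=true_counts,
    )
    assert lib.total_reads == library_size
    return lib


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def term_universe(n_terms: int) -> list[str]:
    """Term ids of a synthetic annotation universe: term0001, term0002, ..."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    return [f"term{i + 1:04d}" for i in range(n_terms)]


def assign_annotations(
    gene_ids: Sequence[str],
    n_terms: int,
    enriched_term_id: str,
    target_genes: Sequence[str],
    background_rate: float = 0.05,
    enriched_rate: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene -> term table with one term planted in the target set.

    Every (gene, term) pair is annotated independently at
    ``background_rate``, except the enriched term, which annotates each
    *target* gene at ``enriched_rate`` (non-targets stay at background).
    Returns a DataFrame with columns gene_id, term_id, sorted for
    determinism.
    """
    if not 0.0 <= background_rate < enriched_rate <= 1.0:
        raise ValueError("need 0 <= background_rate < enriched_rate <= 1")
    terms = term_universe(n_terms)
    if enriched_term_id not in terms:
        raise ValueError(
            f"enriched_term_id {enriched_term_id!r} not in the term universe "
            f"of {n_terms} terms")
    rng = np.random.default_rng(seed)
    targets = set(target_genes)
    unknown_targets = targets - set(gene_ids)
    if unknown_targets:
        raise ValueError(f"target genes not in gene_ids: {sorted(unknown_targets)[:5]}")
    hits = rng.random((len(gene_ids), n_terms))
    rows = []
    enriched_col = terms.index(enriched_term_id)
    for i, gene in enumerate(gene_ids):
        for j, term in enumerate(terms):
            rate = enriched_rate if (j == enriched_col and gene in targets) \
                else background_rate
            if hits[i, j] < rate:
                rows.append((gene, term))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---------------------------------------------------------------------------
# Writers (plain-text exchange formats)
# ---------------------------------------------------------------------------

def write_transcriptome_fasta(transcriptome: SyntheticTranscriptome, path,
                              width: int = 70) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in transcriptome.records:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_tsv(truth: ExpressionTruth, path) -> None:
    """TSV with header (gene_id, library_id, abundance, true_log2fc)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tlibrary_id\tabundance\ttrue_log2fc\n")
        for lib in truth.abundance.columns:
            for gene, value in truth.abundance[lib].items():
                fh.write(f"{gene}\t{lib}\t{value:.12g}\t"
                         f"{truth.log2fc[gene]:.6g}\n")


def write_annotation_tsv(table: pd.DataFrame, path) -> None:
    table.sort_values(["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)
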