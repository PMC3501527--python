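"""Generators: transcriptomes, expression truths, libraries, annotations."""

import re
from collections import Counter

import numpy as np
import pytest

from tagdge import synthetic as syn
from tagdge.tag_library import canonical_tag, extract_tags
from tagdge.tag_processing import ADAPTER_SENTINEL


def naive_untaggable(seq):
    """Oracle: regex scan — no CATG with >= 17 downstream bases."""
    return not any(m.start() + 21 <= len(seq)
                   for m in re.finditer("CATG", seq))


def test_forced_fully_untaggable():
    t = syn.generate_transcriptome(
        syn.TranscriptomeParams(n_genes=1, fraction_untaggable=1.0, seed=7))
    (gene_id, seq), = t.records
    assert naive_untaggable(seq)
    assert extract_tags(seq) == []


def test_seed_determinism():
    params = syn.TranscriptomeParams(n_genes=100, seed=42)
    a = syn.generate_transcriptome(params)
    b = syn.generate_transcriptome(params)
    assert a.records == b.records


def test_untaggable_count_matches_oracle():
    t = syn.generate_transcriptome(
        syn.TranscriptomeParams(n_genes=50, fraction_untaggable=0.2, seed=1))
    untaggable = {g for g, s in t.records if naive_untaggable(s)}
    assert len(untaggable) == 10
    assert untaggable == set(t.untaggable_ids)


def test_taggable_genes_have_a_site_and_min_length():
    t = syn.generate_transcriptome(
        syn.TranscriptomeParams(n_genes=100, fraction_untaggable=0.1, seed=5))
    for gene_id, seq in t.records:
        if gene_id not in t.untaggable_ids:
            assert len(seq) >= 25
            assert canonical_tag(seq) is not None


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        syn.generate_transcriptome(syn.TranscriptomeParams(n_genes=0))
    with pytest.raises(ValueError):
        syn.generate_transcriptome(
            syn.TranscriptomeParams(n_genes=5, fraction_untaggable=1.5))
    with pytest.raises(ValueError):
        syn.generate_transcriptome(
            syn.TranscriptomeParams(n_genes=5, length_median=10.0))


# ---------------------------------------------------------------------------
# expression truth
# ---------------------------------------------------------------------------

def test_abundances_on_simplex(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, de_fraction=0.1, seed=2)
    assert np.allclose(truth.abundance.sum(axis=0), 1.0, atol=1e-9)


def test_no_de_means_unit_ratios(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, de_fraction=0.0, seed=2)
    ratio = truth.abundance["lib2"] / truth.abundance["lib1"]
    assert np.allclose(ratio, 1.0)
    assert truth.de_genes == frozenset()


def test_assigned_fold_change_realised_before_renormalisation(
        small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, de_fraction=0.05,
                                  log2fc_values=(2.0,), seed=3)
    ratio = truth.abundance["lib2"] / truth.abundance["lib1"]
    non_de = [g for g in truth.abundance.index if g not in truth.de_genes]
    # all libraries share one renormalisation constant, so the DE/non-DE
    # ratio of ratios recovers 2^log2fc exactly
    for g in truth.de_genes:
        assert ratio[g] / ratio[non_de[0]] == pytest.approx(4.0)
    assert (truth.log2fc[sorted(truth.de_genes)] == 2.0).all()


def test_de_genes_drawn_from_taggable_only(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, de_fraction=0.2, seed=4)
    assert not (truth.de_genes & small_transcriptome.untaggable_ids)


def test_de_fraction_out_of_range():
    t = syn.generate_transcriptome(syn.TranscriptomeParams(n_genes=5, seed=0))
    with pytest.raises(ValueError):
        syn.assign_expression(t, de_fraction=1.5)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def test_pure_library_contains_only_canonical_tags(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, seed=5)
    lib = syn.simulate_library(small_transcriptome, truth, "lib1", 5000,
                               seed=6)
    canonical = {canonical_tag(s) for _, s in small_transcriptome.records}
    assert set(lib.raw_tags) <= canonical - {None}
    assert lib.total_reads == 5000


def test_read_class_conservation(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, seed=5)
    lib = syn.simulate_library(
        small_transcriptome, truth, "lib1", 10_000, error_rate=0.01,
        adapter_fraction=0.05, n_fraction=0.02,
        singleton_noise_fraction=0.02, seed=8)
    assert lib.n_adapter + lib.n_n_reads + lib.n_noise + lib.n_tag_reads \
        == lib.library_size == lib.total_reads
    assert lib.raw_tags[ADAPTER_SENTINEL] == lib.n_adapter
    n_reads = sum(c for t, c in lib.raw_tags.items() if "N" in t
                  and t != ADAPTER_SENTINEL)
    assert n_reads == lib.n_n_reads
    assert sum(lib.true_gene_counts.values()) == lib.n_tag_reads


def test_degenerate_single_gene_library():
    t = syn.generate_transcriptome(syn.TranscriptomeParams(n_genes=1, seed=9))
    truth = syn.assign_expression(t, seed=9)
    lib = syn.simulate_library(t, truth, "lib1", 1000, seed=10)
    tag = canonical_tag(t.records[0][1])
    assert lib.raw_tags == Counter({tag: 1000})


def test_untaggable_abundance_reassigned_with_warning(caplog):
    t = syn.generate_transcriptome(
        syn.TranscriptomeParams(n_genes=10, fraction_untaggable=0.5, seed=11))
    truth = syn.make_expression_truth(t.gene_ids, seed=11)  # mass everywhere
    with caplog.at_level("WARNING"):
        lib = syn.simulate_library(t, truth, "lib1", 2000, seed=12)
    assert "untaggable" in caplog.text
    assert lib.total_reads == 2000


def test_empirical_frequencies_converge_to_truth(small_transcriptome):
    """Total-variation distance to the (taggable-renormalised) truth is
    below 3*sqrt(G/N) at N = 1e5, zero error and contamination."""
    truth = syn.assign_expression(small_transcriptome, seed=13)
    N = 100_000
    lib = syn.simulate_library(small_transcriptome, truth, "lib1", N, seed=14)
    canon = {g: canonical_tag(s) for g, s in small_transcriptome.records}
    p = truth.abundance["lib1"].copy()
    for g in small_transcriptome.untaggable_ids:
        p[g] = 0.0
    p = p / p.sum()
    obs = np.array([lib.raw_tags.get(canon[g], 0) if canon[g] else 0
                    for g in p.index], dtype=float)
    # shared canonical tags would double-count; the 200-gene fixture has none
    obs = obs / obs.sum()
    tv = 0.5 * np.abs(obs - p.to_numpy()).sum()
    G = int((p > 0).sum())
    assert tv < 3 * np.sqrt(G / N)


def test_error_rate_perturbs_tags(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, seed=15)
    lib = syn.simulate_library(small_transcriptome, truth, "lib1", 20_000,
                               error_rate=0.01, seed=16)
    canonical = {canonical_tag(s) for _, s in small_transcriptome.records}
    off = sum(c for t, c in lib.raw_tags.items() if t not in canonical)
    p_any = 1 - 0.99 ** 21
    # errored reads within 5 sigma of the binomial expectation
    expected = lib.n_tag_reads * p_any
    sigma = np.sqrt(lib.n_tag_reads * p_any * (1 - p_any))
    assert abs(off - expected) < 5 * sigma + 50  # few may revert to canonical


def test_simulation_is_seed_deterministic(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, seed=17)
    kw = dict(error_rate=0.01, adapter_fraction=0.02, n_fraction=0.01,
              singleton_noise_fraction=0.01, seed=18)
    a = syn.simulate_library(small_transcriptome, truth, "lib1", 5000, **kw)
    b = syn.simulate_library(small_transcriptome, truth, "lib1", 5000, **kw)
    assert a.raw_tags == b.raw_tags


def test_invalid_fractions_rejected(small_transcriptome):
    truth = syn.assign_expression(small_transcriptome, seed=19)
    with pytest.raises(ValueError):
        syn.simulate_library(small_transcriptome, truth, "lib1", 100,
                             adapter_fraction=0.6, n_fraction=0.5)
    with pytest.raises(ValueError):
        syn.simulate_library(small_transcriptome, truth, "lib1", 0)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def test_extreme_rates_give_exact_annotation():
    genes = [f"g{i}" for i in range(20)]
    ann = syn.assign_annotations(genes, 3, "term0002", genes[:5],
                                 background_rate=0.0, enriched_rate=1.0,
                                 seed=1)
    assert set(ann["term_id"]) == {"term0002"}
    assert set(ann["gene_id"]) == set(genes[:5])


def test_annotation_determinism():
    genes = [f"g{i}" for i in range(50)]
    kw = dict(n_terms=10, enriched_term_id="term0001",
              target_genes=genes[:10], background_rate=0.1,
              enriched_rate=0.7, seed=2)
    assert syn.assign_annotations(genes, **kw).equals(
        syn.assign_annotations(genes, **kw))


def test_realized_enriched_rate_within_binomial_error():
    genes = [f"g{i}" for i in range(2000)]
    targets = genes[:400]
    rate = 0.8
    ann = syn.assign_annotations(genes, 5, "term0001", targets,
                                 background_rate=0.05, enriched_rate=rate,
                                 seed=3)
    hits = len(set(ann.loc[ann["term_id"] == "term0001", "gene_id"])
               & set(targets))
    se = np.sqrt(rate * (1 - rate) / len(targets))
    assert abs(hits / len(targets) - rate) < 3 * se


def test_unknown_enriched_term_rejected():
    with pytest.raises(ValueError):
        syn.assign_annotations(["g1"], 3, "term9999", [],
                               background_rate=0.1, enriched_rate=0.9)
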