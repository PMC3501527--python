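"""End-to-end DGE pipeline orchestration.

Stages: reference build -> per-library filter/map/quantify -> pairwise
differential expression -> term enrichment -> plain-text reports.  All
randomness (in the simulation harness) flows from a single config seed;
outputs are byte-identical under an identical config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .tag_library import build_reference_library_from_fasta, write_reference_tsv
from .tag_processing import (filter_raw_tags, read_tag_counts_tsv,
                             write_tag_counts_tsv, library_stats,
                             summary_table, copy_number_distribution)
from .expression import assign_tags, count_genes, tpm_normalize
from .differential import call_degs
from .enrichment import enrich_terms
from . import synthetic

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    transcriptome_fasta: str
    libraries: dict[str, str]            # library_id -> raw tag table path
    comparisons: list[tuple[str, str]]   # (reference library, test library)
    outdir: str
    annotation_tsv: str | None = None
    strand_mode: str = "sense_only"
    denominator_mode: str = "clean_total"
    fdr_threshold: float = 0.001
    log2_threshold: float = 1.0
    enrichment_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.fdr_threshold <= 0 or self.log2_threshold <= 0 \
                or self.enrichment_alpha <= 0:
            raise ValueError("thresholds must be positive")
        missing = [p for p in
                   [self.transcriptome_fasta, *self.libraries.values()]
                   + ([self.annotation_tsv] if self.annotation_tsv else [])
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")
        for a, b in self.comparisons:
            if a not in self.libraries or b not in self.libraries:
                raise ValueError(f"comparison ({a}, {b}) references unknown library")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["comparisons"] = [list(c) for c in self.comparisons]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["comparisons"] = [tuple(c) for c in data.get("comparisons", [])]
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns a dict of in-memory results: per-library stats and
    expression tables, the summary table, DEG tables keyed by
    comparison, and enrichment tables.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    library = build_reference_library_from_fasta(
        config.transcriptome_fasta, strand_mode=config.strand_mode)
    write_reference_tsv(library, outdir / "reference_tags.tsv")
    log.info("stage build-ref: %d genes -> %d tags", library.genes_total,
             len(library))

    per_lib_rows: dict[str, dict] = {}
    expression: dict[str, pd.DataFrame] = {}
    filter_stats = {}
    mapping_stats = {}
    for lib_id, path in config.libraries.items():
        raw = read_tag_counts_tsv(path)
        clean, fstats = filter_raw_tags(raw)
        log.info("stage filter[%s]: %d raw -> %d clean reads", lib_id,
                 fstats.raw_total, fstats.clean_total)
        write_tag_counts_tsv(clean, outdir / f"clean_tags_{lib_id}.tsv")
        assignments, mstats = assign_tags(clean, library)
        log.info("stage map[%s]: %d mapped + %d unknown = %d clean", lib_id,
                 mstats.all_mapped_total, mstats.unknown_total,
                 mstats.clean_total)
        records = count_genes(assignments, library)
        denom = fstats.clean_total if config.denominator_mode == "clean_total" \
            else None
        records = tpm_normalize(records, denominator_mode=config.denominator_mode,
                                clean_total=denom)
        records.insert(1, "library_id", lib_id)
        records.to_csv(outdir / f"expression_{lib_id}.tsv", sep="\t",
                       index=False, float_format="%.6f")
        copy_number_distribution(clean).to_csv(
            outdir / f"copy_number_{lib_id}.tsv", sep="\t", index=False)
        per_lib_rows[lib_id] = library_stats(fstats, mstats)
        expression[lib_id] = records
        filter_stats[lib_id] = fstats
        mapping_stats[lib_id] = mstats

    summary = summary_table(per_lib_rows)
    summary.to_csv(outdir / "library_summary.tsv", sep="\t")

    denominators = {
        lib_id: (filter_stats[lib_id].clean_total
                 if config.denominator_mode == "clean_total"
                 else mapping_stats[lib_id].unambiguous_total)
        for lib_id in config.libraries
    }

    deg_tables: dict[str, pd.DataFrame] = {}
    de_summary = []
    for lib_a, lib_b in config.comparisons:
        counts = pd.DataFrame({
            "gene_id": expression[lib_a]["gene_id"],
            "count_a": expression[lib_a]["unambiguous_count"].to_numpy(),
            "count_b": expression[lib_b]["unambiguous_count"].to_numpy(),
        })
        degs = call_degs(counts, denominators[lib_a], denominators[lib_b],
                         fdr_threshold=config.fdr_threshold,
                         log2_threshold=config.log2_threshold)
        name = f"{lib_a}_vs_{lib_b}"
        degs.to_csv(outdir / f"degs_{name}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        n_up = int((degs["direction"] == "up").sum())
        n_down = int((degs["direction"] == "down").sum())
        de_summary.append({"comparison": name, "tested": len(degs),
                           "up": n_up, "down": n_down, "total": n_up + n_down})
        log.info("stage de[%s]: %d up, %d down of %d tested", name, n_up,
                 n_down, len(degs))
        deg_tables[name] = degs
    pd.DataFrame(de_summary).to_csv(outdir / "de_summary.tsv", sep="\t",
                                    index=False)

    enrichment_tables: dict[str, pd.DataFrame] = {}
    if config.annotation_tsv:
        annotation = pd.read_csv(config.annotation_tsv, sep="\t")
        ann_genes = set(annotation["gene_id"])
        ref_genes = set(library.gene_ids)
        extra = len(ann_genes - ref_genes)
        if extra:
            log.warning("%d annotated gene ids absent from the transcriptome",
                        extra)
        for name, degs in deg_tables.items():
            sig = degs.loc[degs["significant"], "gene_id"]
            if sig.empty:
                continue
            result = enrich_terms(sig, annotation,
                                  alpha=config.enrichment_alpha)
            result.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t",
                          index=False, float_format="%.6g")
            enrichment_tables[name] = result

    run_log = {
        "tagdge_version": __version__,
        "seed": config.seed,
        "parameters": {
            "strand_mode": config.strand_mode,
            "denominator_mode": config.denominator_mode,
            "fdr_threshold": config.fdr_threshold,
            "log2_threshold": config.log2_threshold,
            "enrichment_alpha": config.enrichment_alpha,
        },
        "libraries": {k: Path(v).name for k, v in config.libraries.items()},
        "comparisons": [list(c) for c in config.comparisons],
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    return {
        "reference": library,
        "filter_stats": filter_stats,
        "mapping_stats": mapping_stats,
        "expression": expression,
        "summary": summary,
        "degs": deg_tables,
        "enrichment": enrichment_tables,
    }


# ---------------------------------------------------------------------------
# Simulation harness
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Conditions of a two-condition simulated DGE experiment."""

    n_genes: int = 2000
    library_size: int = 200_000
    de_fraction: float = 0.05
    log2fc_values: tuple[float, ...] = (2.0, -2.0)
    fraction_untaggable: float = 0.05
    error_rate: float = 0.005
    adapter_fraction: float = 0.01
    n_fraction: float = 0.005
    singleton_noise_fraction: float = 0.005
    n_terms: int = 50
    enriched_term_id: str = "term0001"
    background_rate: float = 0.05
    enriched_rate: float = 0.8
    seed: int = 0


def simulate_experiment(sim: SimulationConfig, datadir) -> dict:
    """Generate a two-library experiment on disk; returns paths + truth."""
    datadir = Path(datadir)
    datadir.mkdir(parents=True, exist_ok=True)
    transcriptome = synthetic.generate_transcriptome(
        synthetic.TranscriptomeParams(
            n_genes=sim.n_genes, fraction_untaggable=sim.fraction_untaggable,
            seed=sim.seed))
    truth = synthetic.assign_expression(
        transcriptome, de_fraction=sim.de_fraction,
        log2fc_values=sim.log2fc_values, seed=sim.seed + 1)
    fasta = datadir / "transcriptome.fasta"
    synthetic.write_transcriptome_fasta(transcriptome, fasta)
    synthetic.write_truth_tsv(truth, datadir / "truth.tsv")
    lib_paths = {}
    for i, lib_id in enumerate(truth.abundance.columns):
        lib = synthetic.simulate_library(
            transcriptome, truth, lib_id, sim.library_size,
            error_rate=sim.error_rate, adapter_fraction=sim.adapter_fraction,
            n_fraction=sim.n_fraction,
            singleton_noise_fraction=sim.singleton_noise_fraction,
            seed=sim.seed + 10 + i)
        path = datadir / f"raw_tags_{lib_id}.tsv"
        write_tag_counts_tsv(lib.raw_tags, path)
        lib_paths[lib_id] = str(path)
    # DE genes are targets of the planted enriched term
    annotation = synthetic.assign_annotations(
        transcriptome.gene_ids, sim.n_terms, sim.enriched_term_id,
        sorted(truth.de_genes), background_rate=sim.background_rate,
        enriched_rate=sim.enriched_rate, seed=sim.seed + 2)
    ann_path = datadir / "annotation.tsv"
    synthetic.write_annotation_tsv(annotation, ann_path)
    return {"transcriptome": transcriptome, "truth": truth,
            "fasta": str(fasta), "libraries": lib_paths,
            "annotation": str(ann_path)}


def simulate_and_run(sim: SimulationConfig, workdir,
                     pipeline_overrides: dict | None = None) -> dict:
    """Simulate, run the full pipeline, and compare calls to the truth.

    Returns the pipeline results plus a truth-vs-called comparison:
    confusion matrix, sensitivity, empirical FDR, and the Spearman
    correlation between measured TPM and true abundance in the
    reference library.
    """
    workdir = Path(workdir)
    data = simulate_experiment(sim, workdir / "data")
    cfg = PipelineConfig(
        transcriptome_fasta=data["fasta"],
        libraries=data["libraries"],
        comparisons=[("lib1", "lib2")],
        annotation_tsv=data["annotation"],
        outdir=str(workdir / "results"),
        seed=sim.seed,
    )
    if pipeline_overrides:
        for k, v in pipeline_overrides.items():
            setattr(cfg, k, v)
    results = run_pipeline(cfg)

    truth = data["truth"]
    degs = results["degs"]["lib1_vs_lib2"]
    called = set(degs.loc[degs["significant"], "gene_id"])
    true_de = set(truth.de_genes)
    all_genes = set(truth.abundance.index)
    tp = len(called & true_de)
    fp = len(called - true_de)
    fn = len(true_de - called)
    tn = len(all_genes - called - true_de)
    comparison = {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / len(true_de) if true_de else float("nan"),
        "empirical_fdr": fp / len(called) if called else 0.0,
    }
    expr = results["expression"]["lib1"].set_index("gene_id")
    taggable = [g for g in expr.index
                if g not in data["transcriptome"].untaggable_ids]
    obs = expr.loc[taggable, "tpm"]
    exp = truth.abundance["lib1"].reindex(obs.index)
    comparison["tpm_spearman"] = float(obs.corr(exp, method="spearman"))
    results["comparison"] = comparison
    results["truth"] = truth
    with open(workdir / "results" / "truth_comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True)
    return results
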