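"""End-to-end driver: identify -> quantify -> test -> curate -> report.

Every stage is a pure file contract: inputs are read from (or written to)
the output directory as TSV, so deleting intermediates and re-running a
later stage from the saved files reproduces the same outputs.  All
randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as spio
from .curation import apply_exclusion_rules, curation_report
from .differential import call_differential, differential_table
from .identification import accept_protein_groups, filter_psms, group_proteins_parsimony
from .quantitation import CountMatrix, normalize_counts
from .reporting import (
    assign_categories,
    category_distribution,
    export_gene_lists,
    hierarchical_cluster,
    load_category_map,
    sample_correlation_matrix,
)
from .synthetic import SimulationConfig, simulate_dataset, simulate_psms, truth_recovery_report

log = logging.getLogger("spcdelta")

__all__ = ["run_pipeline"]


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return result

        return run

    return wrap


@_stage("simulate")
def _simulate(config: spio.PipelineConfig, outdir: Path):
    sim = SimulationConfig(seed=config.seed, **(config.simulation or {}))
    matrix, proteins, truth = simulate_dataset(sim)
    psms = simulate_psms(proteins, seed=config.seed + 1)
    spio.write_count_matrix(matrix, outdir / "counts.tsv")
    spio.write_table(proteins, outdir / "proteins.tsv")
    spio.write_table(truth, outdir / "ground_truth.tsv")
    spio.write_table(psms, outdir / "psms.tsv")
    log.info("simulated %d proteins x %d samples", *matrix.counts.shape)
    return matrix, proteins, truth, psms


@_stage("identify")
def _identify(config: spio.PipelineConfig, psms: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    kept = filter_psms(psms, config.min_probability)
    groups = group_proteins_parsimony(kept)
    accepted = accept_protein_groups(
        groups,
        min_protein_probability=config.min_protein_probability,
        min_unique_peptides=config.min_unique_peptides,
        max_fdr=config.max_fdr,
    )
    spio.write_table(accepted, outdir / "accepted_proteins.tsv")
    log.info(
        "identification: %d PSMs in, %d pass probability, %d groups, %d accepted",
        len(psms), len(kept), len(groups), len(accepted),
    )
    return accepted


@_stage("quantify")
def _quantify(matrix: CountMatrix, outdir: Path) -> pd.DataFrame:
    nspc = normalize_counts(matrix)
    nspc.to_csv(outdir / "nspc.tsv", sep="\t", index_label="accession")
    return nspc


@_stage("test")
def _test(config: spio.PipelineConfig, matrix: CountMatrix, outdir: Path) -> pd.DataFrame:
    compartments = sorted(matrix.samples["compartment"].unique())
    per_compartment = [
        differential_table(matrix, compartment, conditions=config.conditions, f=config.f)
        for compartment in compartments
    ]
    results = pd.concat(per_compartment, ignore_index=True)
    results = call_differential(
        results,
        rsc_threshold=config.rsc_threshold,
        alpha=config.alpha,
        use_adjusted=config.use_adjusted,
    )
    spio.write_results_table(results, outdir / "results.tsv")
    log.info("tested %d protein x compartment pairs", len(results))
    return results


@_stage("curate")
def _curate(results: pd.DataFrame, proteins: pd.DataFrame, outdir: Path):
    retained, report = apply_exclusion_rules(results, proteins)
    text, frame = curation_report(report)
    spio.write_results_table(retained, outdir / "curated_results.tsv")
    spio.write_table(frame, outdir / "curation_report.tsv")
    log.info("%s", text)
    return retained, report


@_stage("report")
def _report(config: spio.PipelineConfig, retained: pd.DataFrame, proteins: pd.DataFrame,
            nspc: pd.DataFrame, outdir: Path) -> None:
    cmap = load_category_map(config.category_map_path) if config.category_map_path else {}
    meta = proteins.set_index("accession")
    annotated = retained.copy()
    annotated["gene"] = [meta.loc[a, "gene_symbol"] if a in meta.index else a
                         for a in annotated["accession"]]
    annotated = assign_categories(annotated, cmap, key="gene")
    spio.write_table(annotated, outdir / "annotated_results.tsv")

    tables = {}
    for compartment in sorted(annotated["compartment"].unique()):
        for direction in ("up", "down"):
            sub = annotated[
                (annotated["compartment"] == compartment) & (annotated["call"] == direction)
            ]
            tables[(compartment, direction)] = sub
            if len(sub):
                dist = category_distribution(sub)
                spio.write_table(dist, outdir / f"categories_{compartment}_{direction}.tsv")
    export_gene_lists(tables, outdir)

    corr = sample_correlation_matrix(nspc)
    order, reordered, _ = hierarchical_cluster(corr)
    reordered.to_csv(outdir / "sample_correlation.tsv", sep="\t", index_label="sample")
    (outdir / "sample_order.txt").write_text("\n".join(order) + "\n")


def run_pipeline(config: spio.PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Stages run in order identify -> quantify -> test -> curate -> report
    (preceded by simulation when configured); each stage logs its in/out
    counts and any stage error aborts with the stage name and cause.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_json(outdir / "config.json")
        truth = None
        psms = None
        if config.simulation is not None:
            matrix, proteins, truth, psms = _simulate(config, outdir)
        else:
            matrix = spio.read_count_matrix(config.counts_path)
            proteins = (
                spio.read_table(config.proteins_path)
                if config.proteins_path
                else pd.DataFrame(
                    {
                        "accession": matrix.accessions,
                        "reported_accession": matrix.accessions,
                        "gene_symbol": matrix.accessions,
                        "description": "",
                        "decoy": False,
                    }
                )
            )
            if config.psms_path:
                psms = spio.read_table(config.psms_path)

        if psms is not None:
            accepted = _identify(config, psms, outdir)
            members = set()
            for cell in accepted["member_accessions"]:
                members.update(str(cell).split(";"))
            keep = [a for a in matrix.accessions if a in members]
            if keep:
                matrix = matrix.subset_proteins(keep)
            log.info("count matrix restricted to %d accepted proteins", len(matrix.accessions))

        nspc = _quantify(matrix, outdir)
        results = _test(config, matrix, outdir)
        retained, _report_obj = _curate(results, proteins, outdir)
        _report(config, retained, proteins, nspc, outdir)

        if truth is not None:
            recovery = truth_recovery_report(truth, results)
            spio.write_table(pd.DataFrame([recovery]), outdir / "recovery.tsv")
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
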