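"""End-to-end orchestration: simulate -> cluster -> assign -> filter ->
biogeo -> phylo -> cellcounts, driven by one flat config.

Every stage writes plain-text artifacts into the run directory and records
them in a manifest (parameters, per-stage seeds, SHA-256 of each output), so
a rerun with an identical config reproduces byte-identical tables. All
randomness derives from one root seed expanded per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biogeo, cellcounts, cluster, occfilter, phylo, synthdata, taxonomy
from .iolib import OtuTable, SampleTable, write_fasta, write_otu_table
from .iolib import format_size_annotation

logger = logging.getLogger("marfungi")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_STAGES = ("simulate", "cluster", "assign", "filter", "biogeo", "phylo",
           "cellcounts")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    outdir: str = "marfungi_run"
    seed: int = 42
    # synthetic data (ignored when reads/samples paths are given)
    synth: synthdata.SynthConfig = field(default_factory=synthdata.SynthConfig)
    reads_path: str | None = None
    samples_path: str | None = None
    # clustering
    d: int = 1
    recluster_max_diff: int = 1
    # taxonomy
    min_identity: float = taxonomy.DEFAULT_MIN_IDENTITY
    # biogeo
    min_sites: int = 3
    # phylo
    bootstrap_reps: int = 1000
    mask_max_gap_fraction: float = 0.5
    logdet_pseudocount: float = phylo.DEFAULT_PSEUDOCOUNT
    # cellcounts
    cellcounts_path: str | None = None
    n_cellcount_samples: int = 10

    def stage_seed(self, stage: str) -> int:
        """Per-stage child seed (stable, < 2**31) from the root seed."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed)
        return int(ss.generate_state(len(_STAGES))[idx] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the run report
    (also written to ``<outdir>/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    report: dict = {"seed": config.seed, "stages": {}}

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        if config.reads_path is not None:
            raise PipelineError(
                stage, "external read input is not wired into run_pipeline; "
                "use the stage subcommands for real data")
        refdb = synthdata.generate_reference_db(
            config.synth, seed=config.stage_seed(stage))
        reads, sample_table, truth = synthdata.simulate_dataset(
            refdb, config.synth, seed=config.stage_seed(stage) + 1)
        paths = synthdata.write_dataset(outdir, refdb, reads, sample_table, truth)
        outputs.update(paths)
        report["stages"][stage] = {
            "n_reads": len(reads), "n_samples": len(sample_table),
            "n_references": len(refdb)}
        logger.info("simulate: %d reads across %d samples",
                    len(reads), len(sample_table))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- cluster -----------------------------------------------------------
    stage = "cluster"
    try:
        amplicons = cluster.dereplicate(reads)
        otus = cluster.swarm_cluster(amplicons, d=config.d)
        read_samples = {r.read_id: r.sample_id for r in reads}
        clusters = cluster.recluster_representatives(
            otus, read_samples, max_diff=config.recluster_max_diff)
        assert sum(c.total_reads for c in clusters) == len(reads), \
            "read-count conservation violated across clustering"
        reps_path = outdir / "representatives.fasta"
        write_fasta(
            [(format_size_annotation(c.cluster_id, c.total_reads),
              c.representative_sequence) for c in clusters], reps_path)
        table = OtuTable(pd.DataFrame(
            {c.cluster_id: c.sample_counts for c in clusters}
        ).T.reindex(columns=sample_table.sample_ids).fillna(0).astype(int))
        table_path = outdir / "otu_clusters.tsv"
        write_otu_table(table, table_path)
        outputs["representatives"] = reps_path
        outputs["otu_table"] = table_path
        report["stages"][stage] = {
            "n_amplicons": len(amplicons), "n_otus": len(otus),
            "n_clusters": len(clusters)}
        logger.info("cluster: %d amplicons -> %d OTUs -> %d clusters",
                    len(amplicons), len(otus), len(clusters))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- assign ------------------------------------------------------------
    stage = "assign"
    try:
        assignments = [
            taxonomy.assign_taxonomy(c.cluster_id, c.representative_sequence,
                                     refdb, config.min_identity)
            for c in clusters]
        flags = {
            c.cluster_id: taxonomy.flag_marine(
                c.cluster_id, c.representative_sequence, refdb)
            for c in clusters}
        lineages = taxonomy.partition_by_lineage(assignments)
        assign_path = outdir / "assignments.tsv"
        pd.DataFrame([{
            "cluster_id": a.cluster_id,
            "best_ref": a.best_ref_id or "",
            "identity": round(a.percent_identity, 3),
            "taxonomy": ";".join(a.taxonomy_path),
            "lineage": lineages[a.cluster_id].value,
            "marine_flag": int(flags[a.cluster_id].flagged),
            "best_marine_identity": round(
                flags[a.cluster_id].best_marine_identity, 3),
        } for a in assignments]).to_csv(assign_path, sep="\t", index=False)
        outputs["assignments"] = assign_path
        n_marine = sum(f.flagged for f in flags.values())
        report["stages"][stage] = {
            "n_assigned": sum(a.assigned for a in assignments),
            "n_marine_flagged": n_marine}
        logger.info("assign: %d/%d assigned, %d marine-flagged",
                    sum(a.assigned for a in assignments), len(assignments),
                    n_marine)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- filter ------------------------------------------------------------
    stage = "filter"
    try:
        fungal_ids = {
            a.cluster_id for a in assignments
            if a.assigned and a.taxonomy_path
            and a.taxonomy_path[0].lower() == "fungi"}
        fungal_clusters = [c for c in clusters if c.cluster_id in fungal_ids]
        retained, excluded, summary = occfilter.apply_filter(
            fungal_clusters, sample_table)
        census = occfilter.exclusion_census(excluded, sample_table,
                                            total_cleaned_reads=len(reads))
        summary_path = outdir / "filter_summary.json"
        summary_path.write_text(json.dumps({
            "summary": summary.report(),
            "census": dataclasses.asdict(census),
        }, indent=2) + "\n")
        retained_path = outdir / "retained_clusters.tsv"
        pd.DataFrame({c.cluster_id: c.sample_counts for c in retained}).T \
            .reindex(columns=sample_table.sample_ids).fillna(0).astype(int) \
            .rename_axis("cluster_id").to_csv(retained_path, sep="\t")
        outputs["filter_summary"] = summary_path
        outputs["retained"] = retained_path
        report["stages"][stage] = summary.report()
        logger.info("filter: %d fungal clusters -> %d retained",
                    len(fungal_clusters), len(retained))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- biogeo ------------------------------------------------------------
    stage = "biogeo"
    try:
        matrix = biogeo.provenance_matrix(retained, sample_table, ["site"])
        multi = biogeo.multi_site_clusters(matrix, config.min_sites)
        substrate_totals: dict[str, int] = {}
        for r in reads:
            sub = sample_table[r.sample_id].substrate
            substrate_totals[sub] = substrate_totals.get(sub, 0) + 1
        fungal_by_sub: dict[str, int] = {}
        for c in retained:
            for sid, count in c.sample_counts.items():
                sub = sample_table[sid].substrate
                fungal_by_sub[sub] = fungal_by_sub.get(sub, 0) + count
        fractions = biogeo.substrate_fungal_fraction(
            fungal_by_sub, substrate_totals)
        read_seqs = {r.read_id: r.sequence for r in reads}
        sim = biogeo.within_cluster_similarity(retained, read_seqs)
        matrix_path = outdir / "provenance_site.tsv"
        matrix.rename_axis("cluster_id").to_csv(matrix_path, sep="\t")
        biogeo_path = outdir / "biogeo_summary.json"
        biogeo_path.write_text(json.dumps({
            "multi_site_clusters": multi,
            "min_sites": config.min_sites,
            "substrate_fungal_pct": {k: round(v, 4)
                                     for k, v in fractions.items()},
            "similarity": {
                "grand_mean": round(sim.grand_mean, 4),
                "sem": round(sim.sem, 4),
                "minimum": round(sim.minimum, 4),
                "n_singleton_clusters": len(sim.singleton_clusters),
            },
        }, indent=2) + "\n")
        outputs["provenance_matrix"] = matrix_path
        outputs["biogeo_summary"] = biogeo_path
        report["stages"][stage] = {
            "n_multi_site": len(multi),
            "similarity_grand_mean": round(sim.grand_mean, 4)}
        logger.info("biogeo: %d multi-site clusters; similarity %.2f%%",
                    len(multi), sim.grand_mean)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- phylo -------------------------------------------------------------
    stage = "phylo"
    try:
        tree_path = outdir / "retained_nj.nwk"
        reps = [(c.cluster_id, c.representative_sequence) for c in retained]
        lengths = {len(seq) for _, seq in reps}
        if len(reps) < 3:
            report["stages"][stage] = {"skipped": "fewer than 3 clusters"}
            tree_path.write_text(";\n")
        elif len(lengths) > 1:
            raise PipelineError(
                stage, "representatives are not equal length; supply an "
                "externally aligned FASTA via the phylo subcommand")
        else:
            aln = phylo.MultipleAlignment(
                ids=[r[0] for r in reps], rows=[r[1] for r in reps])
            masked = phylo.mask_columns(aln, config.mask_max_gap_fraction)
            supported = phylo.bootstrap_support(
                masked, n_reps=config.bootstrap_reps,
                seed=config.stage_seed(stage),
                pseudocount=config.logdet_pseudocount)
            tree_path.write_text(supported.to_newick() + "\n")
            report["stages"][stage] = {
                "n_leaves": len(reps),
                "kept_columns": masked.n_columns,
                "bootstrap_reps": config.bootstrap_reps}
            logger.info("phylo: NJ tree on %d leaves, %d kept columns",
                        len(reps), masked.n_columns)
        outputs["tree"] = tree_path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- cellcounts --------------------------------------------------------
    stage = "cellcounts"
    try:
        if config.cellcounts_path is not None:
            records = cellcounts.read_cellcount_table(config.cellcounts_path)
        else:
            df = synthdata.generate_cellcount_records(
                n_samples=config.n_cellcount_samples,
                seed=config.stage_seed(stage))
            cc_path = outdir / "cellcounts.tsv"
            df.to_csv(cc_path, sep="\t", index=False)
            outputs["cellcounts_input"] = cc_path
            records = cellcounts.read_cellcount_table(cc_path)
        conc = cellcounts.abundance_concordance(records)
        per_sample = []
        for r in records:
            mean, sd, single = cellcounts.filter_count_stats(r.chitin_replicates)
            per_sample.append({
                "sample_id": r.sample_id,
                "chitin_mean": round(mean, 3),
                "chitin_sd": round(sd, 3),
                "pct_chitin": round(
                    cellcounts.chitin_percent(mean, r.total_eukaryote_density), 4),
                "pct_rna_fungal_reads": r.pct_rna_fungal_reads,
            })
        cc_out = outdir / "cellcount_concordance.json"
        cc_out.write_text(json.dumps({
            "concordance": dataclasses.asdict(conc),
            "per_sample": per_sample,
        }, indent=2) + "\n")
        outputs["cellcount_concordance"] = cc_out
        report["stages"][stage] = {
            "n": conc.n, "r_squared": round(conc.r_squared, 4),
            "p_value": round(conc.p_value, 4)}
        logger.info("cellcounts: R^2=%.4f p=%.4f over %d samples",
                    conc.r_squared, conc.p_value, conc.n)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- manifest ----------------------------------------------------------
    report["parameters"] = {
        "d": config.d, "recluster_max_diff": config.recluster_max_diff,
        "min_identity": config.min_identity, "min_sites": config.min_sites,
        "bootstrap_reps": config.bootstrap_reps,
        "mask_max_gap_fraction": config.mask_max_gap_fraction,
        "logdet_pseudocount": config.logdet_pseudocount,
        "synth": dataclasses.asdict(config.synth),
    }
    report["outputs"] = {
        name: {"path": str(p), "sha256": _sha256(p)}
        for name, p in sorted(outputs.items())}
    (outdir / "manifest.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
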