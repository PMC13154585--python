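"""End-to-end orchestration of the translatome analysis.

Runs the stages in dependency order on a self-contained input bundle
(the layout written by :func:`translatome.simulate.write_bundle`):
Ribo-seq QC, ORF catalog consolidation and classification, gene-level
differential expression / differential TE with the four-class regulatory
categorization, 5'UTR feature comparison, co-expression modules with hub
selection, and peptide-to-ORF cross-referencing.  Each enabled stage
writes TSV outputs plus entries in a consolidated JSON summary; a
failing stage halts the run with a stage-named error.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import catalog as cat
from . import dte, io, network, peptides, riboqc
from .annotation import Annotation

log = logging.getLogger("translatome")

STAGES = ("qc", "catalog", "dte", "utr", "modules", "peptides")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, stage toggles and stage parameters for one pipeline run."""

    input_dir: str
    output_dir: str
    stages: list = field(default_factory=lambda: list(STAGES))
    min_samples: int = 2
    q_low: float = 0.10
    alpha_sig: float = 0.05
    fdr: bool = False
    ires_threshold: float = 0.5
    network: network.NetworkParams = field(default_factory=network.NetworkParams)
    trait: str = "trait"
    gs_min: float = 0.4
    mm_min: float = 0.7
    min_peptide_len: int = 7
    max_peptide_len: int = 16
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        net = raw.pop("network", {})
        config = cls(**raw)
        config.network = network.NetworkParams(**net)
        return config

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input bundle not found: {self.input_dir}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha_sig < 1:
            raise ValueError("alpha_sig must be in (0, 1)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the JSON-ready summary dict."""
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    enabled = [s for s in STAGES if s in config.stages]

    dte_results = None
    for stage in enabled:
        t0 = time.time()
        try:
            runner = _STAGE_RUNNERS[stage]
            if stage == "utr":
                stage_summary = runner(config, indir, outdir, dte_results)
            else:
                stage_summary = runner(config, indir, outdir)
            if stage == "dte":
                stage_summary, dte_results = stage_summary
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        summary["stages"][stage] = stage_summary
        log.info("stage %s finished in %.2fs", stage, time.time() - t0)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _run_qc(config, indir, outdir):
    reads = pd.read_csv(indir / "psite_reads.tsv", sep="\t")
    annotation = Annotation.from_gtf(str(indir / "annotation.gtf"))
    report = riboqc.qc_report(reads, annotation)
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    return {
        "frame_fractions": [round(f, 6) for f in report.frame_fractions],
        "region_fractions": {
            k: round(v, 6) for k, v in report.region_fractions.items()
        },
        "n_lengths": len(report.length_hist),
    }


def _run_catalog(config, indir, outdir):
    callsets = io.read_callsets(indir / "callsets")
    groups = io.read_groups(indir / "callset_groups.tsv")
    annotation = Annotation.from_gtf(str(indir / "annotation.gtf"))
    ribo = io.read_counts(indir / "orf_ribo_counts.tsv")
    rna = io.read_counts(indir / "orf_rna_counts.tsv")
    lengths = pd.read_csv(indir / "orf_lengths.tsv", sep="\t", index_col=0)["length"]

    design = pd.DataFrame(
        {"sample_id": list(ribo.columns), "condition": [groups[s] for s in ribo.columns]}
    )
    rna_de = ribo_de = None
    if "dte" in config.stages:
        rna_cm = dte.CountMatrix(rna, design.assign(assay="rna"), "rna")
        ribo_cm = dte.CountMatrix(ribo, design.assign(assay="ribo"), "ribo")
        rna_de = dte.test_deg(rna_cm).rename(
            columns={"log2FC": "log2FC", "pvalue": "pvalue"}
        )
        ribo_de = dte.test_deg(ribo_cm)

    catalog = cat.build_catalog(
        callsets,
        groups,
        annotation,
        ribo,
        lengths,
        rna_de=rna_de,
        ribo_de=ribo_de,
        min_samples=config.min_samples,
        q_low=config.q_low,
        alpha=config.alpha_sig,
    )
    if ribo_de is not None:
        upreg = cat.upregulated_set(
            catalog["specificity"], ribo_de, config.alpha_sig
        )
        catalog["upregulated"] = catalog.index.isin(upreg)
    catalog.to_csv(outdir / "orf_catalog.tsv", sep="\t")
    io.write_bed12(catalog, outdir / "orf_catalog.bed")

    stage_summary = {
        "catalog_size": int(len(catalog)),
        "by_category": catalog["category"].value_counts().to_dict(),
        "by_specificity": catalog["specificity"].value_counts().to_dict(),
    }
    if "expression_cluster" in catalog.columns:
        stage_summary["by_cluster"] = (
            catalog["expression_cluster"].value_counts().to_dict()
        )
    if "upregulated" in catalog.columns:
        stage_summary["n_upregulated"] = int(catalog["upregulated"].sum())
    return stage_summary


def _run_dte(config, indir, outdir):
    rna = io.read_count_matrix(indir / "rna_counts.tsv", indir / "design.tsv", "rna")
    ribo = io.read_count_matrix(indir / "ribo_counts.tsv", indir / "design.tsv", "ribo")
    results = dte.run_dte(rna, ribo, alpha_sig=config.alpha_sig, fdr=config.fdr)
    results.to_csv(outdir / "dte_results.tsv", sep="\t")
    counts = results["regulatory_class"].value_counts().to_dict()
    n_deg = int((results["p_rna"] < config.alpha_sig).sum())
    n_dteg = int((results["p_te"] < config.alpha_sig).sum())
    stage_summary = {
        "n_genes": int(len(results)),
        "n_deg": n_deg,
        "n_deg_up": int(
            ((results["p_rna"] < config.alpha_sig) & (results["log2FC_rna"] > 0)).sum()
        ),
        "n_deg_down": int(
            ((results["p_rna"] < config.alpha_sig) & (results["log2FC_rna"] < 0)).sum()
        ),
        "n_dteg": n_dteg,
        "n_dteg_up": int(
            ((results["p_te"] < config.alpha_sig) & (results["log2FC_te"] > 0)).sum()
        ),
        "n_dteg_down": int(
            ((results["p_te"] < config.alpha_sig) & (results["log2FC_te"] < 0)).sum()
        ),
        "by_class": {k: int(v) for k, v in counts.items()},
    }
    return stage_summary, results


def _run_utr(config, indir, outdir, dte_results):
    from . import utr

    features = io.read_features(indir / "utr_features.tsv")
    target = io.read_gene_list(indir / "target_genes.txt")
    control = io.read_gene_list(indir / "control_genes.txt")
    comparison = utr.compare_sets(
        target, control, features, ires_threshold=config.ires_threshold
    )
    comparison.to_csv(outdir / "utr_comparison.tsv", sep="\t")
    return {
        "n_target": len(target),
        "n_control": len(control),
        "significant_features": sorted(
            comparison.index[comparison["pvalue"] < config.alpha_sig]
        ),
    }


def _run_modules(config, indir, outdir):
    te = io.read_counts(indir / "te_matrix.tsv")
    traits = pd.read_csv(indir / "traits.tsv", sep="\t").set_index("sample_id")
    keep = network.filter_genes(te, config.network)
    result = network.detect_modules(te.loc[keep], config.network)
    result = network.module_trait_stats(result, traits)
    hubs = network.select_hubs(
        result, config.trait, gs_min=config.gs_min, mm_min=config.mm_min,
        alpha=config.alpha_sig,
    )
    result.labels.to_frame("module").to_csv(outdir / "module_assignments.tsv", sep="\t")
    result.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    result.module_trait_cor.to_csv(outdir / "module_trait_cor.tsv", sep="\t")
    result.module_trait_p.to_csv(outdir / "module_trait_p.tsv", sep="\t")
    pd.Series(sorted(hubs), name="gene_id").to_csv(
        outdir / "hub_genes.tsv", sep="\t", index=False
    )
    sizes = result.module_sizes()
    hub_per_module = result.labels.loc[hubs].value_counts().to_dict()
    return {
        "n_genes_filtered": int(len(keep)),
        "n_modules": int(len(result.eigengenes.columns)),
        "module_sizes": {k: int(v) for k, v in sizes.items()},
        "n_hubs": int(len(hubs)),
        "hubs_per_module": {k: int(v) for k, v in hub_per_module.items()},
    }


def _run_peptides(config, indir, outdir):
    peps = io.read_peptides(indir / "peptides.tsv")
    proteins = io.read_fasta(indir / "orf_proteins.fasta")
    sidecar = pd.read_csv(indir / "orf_sidecar.tsv", sep="\t")
    categories = dict(zip(sidecar["orf_id"], sidecar["category"]))
    records = peptides.match_peptides(
        peps,
        proteins,
        categories,
        min_len=config.min_peptide_len,
        max_len=config.max_peptide_len,
    )
    records.to_csv(outdir / "peptides_annotated.tsv", sep="\t", index=False)
    counts = peptides.summary_counts(records)
    counts.to_csv(outdir / "peptide_summary.tsv", sep="\t")
    return {
        "n_records": int(len(records)),
        "n_unique_peptides": int(records["peptide"].nunique()),
        "n_tumour_specific": int(
            records.loc[records["tumour_specific"], "peptide"].nunique()
        ),
        "by_category": {
            k: int(v) for k, v in counts["n_peptides"].to_dict().items()
        },
    }


_STAGE_RUNNERS = {
    "qc": _run_qc,
    "catalog": _run_catalog,
    "dte": _run_dte,
    "utr": _run_utr,
    "modules": _run_modules,
    "peptides": _run_peptides,
}
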