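"""End-to-end orchestration: simulate -> call SNPs -> count -> classify.

Runs the stages with one configuration and a single seed, writes every
result as a plain-text table, and records a manifest (config, versions,
thresholds, attrition counts, output checksums) so a rerun with the same
configuration is byte-identical and auditable.
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

from . import __version__
from .allele_counts import (
    LibraryInfo,
    aggregate_gene_counts,
    channel_offsets,
    count_alleles,
    pileup_from_alignments,
    pool_pileups,
)
from .inference import (
    UNCLASSIFIED,
    GeneClassification,
    ModelConfig,
    classify_genes,
    tissue_support_summary,
)
from .motif import MotifPattern, enrichment_test, extract_upstream, motif_presence
from .simulate import (
    GENOME_TYPES,
    SimConfig,
    make_true_genes,
    plant_motifs,
    simulate_alignments,
    simulate_parental_genomes,
    write_fasta,
    write_gene_models_gff,
    write_sam,
    write_truth_table,
)
from .variants import assign_snps_to_genes, call_fixed_differences, write_snp_vcf

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Configuration of a full simulated run.

    ``libraries`` defaults to one library per genome type per tissue (the
    nine-library design at three tissues); validation requires exactly one
    chimera library per tissue.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    outdir: str | Path = "chimera_lse_run"
    depth: float = 20.0
    read_length: int = 50
    min_depth: int = 4
    purity: float = 0.9
    min_base_quality: int = 20
    min_mapping_quality: int = 10
    libraries: list[LibraryInfo] | None = None
    with_motif: bool = False
    motif_window: int = 1000
    motif_pattern: str = "TAAATGYA"

    def library_list(self) -> list[LibraryInfo]:
        if self.libraries is not None:
            return list(self.libraries)
        return [
            LibraryInfo(library_id=f"{g}_{t}", genome_type=g, tissue=t)
            for t in self.sim.tissues
            for g in GENOME_TYPES
        ]

    def validate(self) -> None:
        libs = self.library_list()
        for t in self.sim.tissues:
            chims = [l for l in libs if l.genome_type == "chimera" and l.tissue == t]
            if len(chims) != 1:
                raise ValueError(
                    f"tissue {t!r} must have exactly one chimera library, found {len(chims)}"
                )
            for g in ("lyc", "penn"):
                if not any(l.genome_type == g and l.tissue == t for l in libs):
                    raise ValueError(f"tissue {t!r} lacks a {g} library")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.with_motif and self.sim.upstream_flank < self.motif_window:
            raise ValueError(
                "upstream_flank must cover motif_window when the motif stage is enabled"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


class StageError(RuntimeError):
    """A pipeline stage failed; the failing stage is named in the message."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full simulated analysis; returns paths and dataframes."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scratch = outdir / "scratch"
    scratch.mkdir(exist_ok=True)
    stage = "setup"
    outputs: dict[str, Path] = {}
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim = config.sim
        genes = make_true_genes(sim)
        lyc_genome, penn_genome, truth_snps = simulate_parental_genomes(sim, genes)
        planted: dict[str, bool] = {}
        if config.with_motif:
            rng = np.random.default_rng([sim.seed, 6])
            chosen = [
                g.gene_id
                for g in genes
                if rng.random() < (0.5 if g.label.startswith("L1") else 0.1)
            ]
            lyc_genome, penn_genome = plant_motifs(
                (lyc_genome, penn_genome),
                sim.upstream_flank,
                chosen,
                pattern=config.motif_pattern,
                seed=sim.seed,
            )
            planted = {g.gene_id: g.gene_id in set(chosen) for g in genes}
        outputs["genome_lyc"] = outdir / "genome_lyc.fasta"
        outputs["genome_penn"] = outdir / "genome_penn.fasta"
        write_fasta(lyc_genome, outputs["genome_lyc"])
        write_fasta(penn_genome, outputs["genome_penn"])
        outputs["gene_models"] = outdir / "genes.gff3"
        write_gene_models_gff(genes, sim, outputs["gene_models"])
        outputs["truth_snps"] = outdir / "truth_snps.vcf"
        write_snp_vcf(truth_snps, outputs["truth_snps"])
        outputs["truth_genes"] = outdir / "truth_genes.tsv"
        write_truth_table(genes, outputs["truth_genes"])

        stage = "simulate-alignments"
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        libs = config.library_list()
        sam_paths: dict[str, Path] = {}
        for idx, lib in enumerate(libs):
            if lib.genome_type == "lyc":
                pf: float | dict[str, float] = 0.0
            elif lib.genome_type == "penn":
                pf = 1.0
            else:
                pf = {g.gene_id: g.penn_read_fraction(sim.p_l1) for g in genes}
            scale = sim.library_size(lib.genome_type, lib.tissue)
            reads, _ = simulate_alignments(
                (lyc_genome, penn_genome),
                genes,
                depth=config.depth * scale,
                read_length=config.read_length,
                penn_fraction=pf,
                stochastic=True,
                error_rate=sim.error_rate,
                seed=sim.seed + 101 * idx,
                upstream_flank=sim.upstream_flank,
            )
            sam = aln_dir / f"{lib.library_id}.sam"
            write_sam(reads, lyc_genome, sam)
            sam_paths[lib.library_id] = sam

        # --- call SNPs ----------------------------------------------------
        stage = "call-snps"
        pools = {}
        for g in ("lyc", "penn"):
            pileups = [
                pileup_from_alignments(sam_paths[l.library_id], workdir=scratch)
                for l in libs
                if l.genome_type == g
            ]
            pools[g] = pool_pileups(pileups)
        snps = call_fixed_differences(
            pools["lyc"], pools["penn"], min_depth=config.min_depth, purity=config.purity
        )
        outputs["snps"] = outdir / "snps.vcf"
        write_snp_vcf(snps, outputs["snps"])

        stage = "assign-snps"
        snp_map, n_dropped = assign_snps_to_genes(snps, outputs["gene_models"])

        # --- count alleles ------------------------------------------------
        stage = "count-alleles"
        all_sites = [s for sites in snp_map.values() for s in sites]
        site_frames = []
        for lib in libs:
            site_frames.append(
                count_alleles(
                    sam_paths[lib.library_id],
                    all_sites,
                    lib.library_id,
                    min_base_quality=config.min_base_quality,
                    min_mapping_quality=config.min_mapping_quality,
                    workdir=scratch,
                )
            )
        site_counts = pd.concat(site_frames, ignore_index=True)
        outputs["site_counts"] = outdir / "site_counts.tsv"
        _write_tsv(site_counts, outputs["site_counts"])

        stage = "aggregate"
        meta = {l.library_id: l for l in libs}
        counts = aggregate_gene_counts(site_counts, snp_map, meta)
        counts = channel_offsets(counts)
        outputs["factorial_counts"] = outdir / "factorial_counts.tsv"
        _write_tsv(counts, outputs["factorial_counts"])

        # --- classify -----------------------------------------------------
        stage = "classify"
        results, per_tissue, classifications = classify_genes(counts, config.model)
        outputs["contrast_results"] = outdir / "contrast_results.tsv"
        _write_tsv(results, outputs["contrast_results"])
        outputs["per_tissue_labels"] = outdir / "per_tissue_labels.tsv"
        _write_tsv(per_tissue, outputs["per_tissue_labels"])
        class_df = pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "label": c.label,
                    "tissues": ",".join(sorted(c.supporting_tissues)),
                    "conflict": c.conflict,
                }
                for c in classifications
            ],
            columns=["gene_id", "label", "tissues", "conflict"],
        )
        outputs["classifications"] = outdir / "classifications.tsv"
        _write_tsv(class_df, outputs["classifications"])

        # --- motif (optional) ---------------------------------------------
        enrichment = None
        if config.with_motif:
            stage = "motif"
            promoters = extract_upstream(
                lyc_genome, outputs["gene_models"], window=config.motif_window
            )
            presence = motif_presence(promoters, MotifPattern(config.motif_pattern))
            classes = dict(zip(class_df["gene_id"], class_df["label"]))
            try:
                enrichment = enrichment_test(presence, classes)
            except ValueError:
                logger.info("motif enrichment skipped (empty class)")
            enr_rows = [
                {"gene_id": g, "motif_present": presence.get(g, False),
                 "planted": planted.get(g, False)}
                for g in sorted(presence)
            ]
            outputs["motif_presence"] = outdir / "motif_presence.tsv"
            _write_tsv(pd.DataFrame(enr_rows), outputs["motif_presence"])

        # --- reports & manifest -------------------------------------------
        stage = "report"
        truth_df = pd.read_csv(outputs["truth_genes"], sep="\t")
        report_paths = write_reports(
            outdir, results, class_df, classifications, truth=truth_df
        )
        outputs.update(report_paths)

        funnel = {
            "n_genes_simulated": int(sim.n_genes),
            "n_snps_called": len(snps),
            "n_snps_outside_cds": int(n_dropped),
            "n_genes_with_snp": len(snp_map),
            "n_gene_tissue_expressed": int(counts["expressed"].sum()),
            "n_genes_classified": int((class_df["label"] != UNCLASSIFIED).sum()),
        }
        logger.info("attrition: %s", funnel)
        manifest = {
            "package": "chimera-lse",
            "version": __version__,
            "seed": sim.seed,
            "config": {
                "sim": dataclasses.asdict(sim),
                "model": dataclasses.asdict(config.model),
                "depth": config.depth,
                "read_length": config.read_length,
                "min_depth": config.min_depth,
                "purity": config.purity,
            },
            "funnel": funnel,
            "outputs": {
                k: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                for k, p in sorted(outputs.items())
                if p.suffix != ".png"
            },
        }
        if enrichment is not None:
            manifest["motif_enrichment"] = {
                "table": enrichment.table,
                "odds_ratio": enrichment.odds_ratio,
                "p": enrichment.p,
                "fractions": enrichment.fractions,
            }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "outputs": {k: str(v) for k, v in outputs.items()},
        "manifest": str(manifest_path),
        "counts": counts,
        "results": results,
        "classifications": classifications,
        "class_df": class_df,
        "funnel": funnel,
        "enrichment": enrichment,
    }


def write_reports(
    outdir: str | Path,
    results: pd.DataFrame,
    class_df: pd.DataFrame,
    classifications: list[GeneClassification],
    truth: pd.DataFrame | None = None,
    plot: bool = True,
) -> dict[str, Path]:
    """Summary tables (label counts, tissue support, confusion) and plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    label_counts = (
        class_df.groupby("label").size().rename("n_genes").reset_index()
        if len(class_df)
        else pd.DataFrame(columns=["label", "n_genes"])
    )
    paths["label_counts"] = outdir / "label_counts.tsv"
    _write_tsv(label_counts, paths["label_counts"])

    support = tissue_support_summary(classifications)
    paths["tissue_support"] = outdir / "tissue_support.tsv"
    _write_tsv(support, paths["tissue_support"])

    if truth is not None and len(class_df):
        merged = class_df.merge(
            truth[["gene_id", "label"]].rename(columns={"label": "true_label"}),
            on="gene_id",
            how="left",
        )
        confusion = (
            merged.groupby(["true_label", "label"]).size().rename("n").reset_index()
        )
        paths["confusion"] = outdir / "confusion.tsv"
        _write_tsv(confusion, paths["confusion"])

    if plot and len(results):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
        for ax, contrast in zip(axes.ravel(), "abcd"):
            sub = results[results["contrast"] == contrast]
            ax.scatter(
                sub["logFC"],
                -np.log10(np.maximum(sub["p"], 1e-300)),
                s=8,
                alpha=0.5,
                color="grey",
            )
            ax.set_title(f"contrast {contrast}")
            ax.set_xlabel("logFC")
            ax.set_ylabel("-log10 p")
        fig.tight_layout()
        png = outdir / "contrast_panels.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        paths["contrast_panels"] = png
    return paths
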