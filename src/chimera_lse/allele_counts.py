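"""Parental-origin allele counting at SNP sites and gene-level aggregation.

Every read overlapping a fixed-difference site carries either the lyc base,
the penn base, or neither (sequencing error, a deletion at the site, or a
quality failure); the three tallies are kept separately.  Site counts are
summed per gene within each library and arranged into the four factorial
cells Lw, Pw, Lc, Pc per gene x tissue, using library metadata to identify
which library is the lyc parent, the penn parent and the chimera.

A read overlapping k SNPs of a gene contributes k site-level counts: counts
are per site, not de-duplicated per read (matching SNP-position-wise
quantification); a per-read majority vote is available via
``per_read_vote=True`` in :func:`aggregate_gene_counts` callers that build
site counts with :func:`count_alleles`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .variants import SnpSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryInfo:
    """Metadata for one sequencing library."""

    library_id: str
    genome_type: str  # "lyc", "penn" or "chimera"
    tissue: str
    path: str | None = None

    def __post_init__(self) -> None:
        if self.genome_type not in ("lyc", "penn", "chimera"):
            raise ValueError(f"unknown genome_type {self.genome_type!r}")


@dataclass
class SiteAlleleCount:
    """Per-site, per-library read support for each parental allele."""

    chrom: str
    pos: int
    library_id: str
    n_lyc: int
    n_penn: int
    n_other: int


def ensure_bam(path: str | Path, workdir: str | Path | None = None) -> Path:
    """Return a coordinate-sorted, indexed BAM for a SAM/BAM input.

    Plain-text SAM cannot be randomly accessed, so it is converted (and
    indexed) into ``workdir`` (defaults to the input's directory).
    """
    path = Path(path)
    workdir = Path(workdir) if workdir else path.parent
    if path.suffix == ".bam" and Path(str(path) + ".bai").exists():
        return path
    bam = workdir / (path.stem + ".sorted.bam")
    pysam.sort("-o", str(bam), str(path))
    pysam.index(str(bam))
    return bam


def count_alleles_at_site(
    aln: pysam.AlignmentFile,
    site: SnpSite,
    min_base_quality: int = 20,
    min_mapping_quality: int = 10,
) -> SiteAlleleCount:
    """Tally reads overlapping one site by the parental allele they carry.

    Each overlapping read contributes to exactly one of n_lyc / n_penn /
    n_other; reads whose projected base is deleted at the site, below base
    or mapping quality, or a third base, count as other.  The projection is
    CIGAR-aware via the alignment's aligned pairs.
    """
    lengths = dict(zip(aln.references, aln.lengths))
    if site.chrom not in lengths or not 0 <= site.pos < lengths[site.chrom]:
        raise ValueError(f"site {site.chrom}:{site.pos} outside reference bounds")
    n_lyc = n_penn = n_other = 0
    for read in aln.fetch(site.chrom, site.pos, site.pos + 1):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapping_quality:
            n_other += 1
            continue
        qpos = None
        for q, r in read.get_aligned_pairs():
            if r == site.pos:
                qpos = q
                break
        if qpos is None:
            n_other += 1  # deletion or reference skip at the site
            continue
        quals = read.query_qualities
        if quals is not None and quals[qpos] < min_base_quality:
            n_other += 1
            continue
        base = read.query_sequence[qpos].upper()
        if base == site.lyc_allele:
            n_lyc += 1
        elif base == site.penn_allele:
            n_penn += 1
        else:
            n_other += 1
    return SiteAlleleCount(site.chrom, site.pos, "", n_lyc, n_penn, n_other)


def count_alleles(
    aln_path: str | Path,
    sites: Iterable[SnpSite],
    library_id: str,
    min_base_quality: int = 20,
    min_mapping_quality: int = 10,
    workdir: str | Path | None = None,
) -> pd.DataFrame:
    """Count alleles at every site in one library's alignments."""
    bam = ensure_bam(aln_path, workdir)
    rows = []
    with pysam.AlignmentFile(str(bam)) as aln:
        for site in sites:
            c = count_alleles_at_site(aln, site, min_base_quality, min_mapping_quality)
            rows.append(
                {
                    "chrom": c.chrom,
                    "pos": c.pos,
                    "library_id": library_id,
                    "n_lyc": c.n_lyc,
                    "n_penn": c.n_penn,
                    "n_other": c.n_other,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "library_id", "n_lyc", "n_penn", "n_other"]
    )


def pileup_from_alignments(
    aln_path: str | Path,
    min_base_quality: int = 0,
    workdir: str | Path | None = None,
) -> pd.DataFrame:
    """Whole-reference base-count pileup (chrom, pos, A, C, G, T)."""
    bam = ensure_bam(aln_path, workdir)
    rows = []
    with pysam.AlignmentFile(str(bam)) as aln:
        for chrom, length in zip(aln.references, aln.lengths):
            cov = aln.count_coverage(
                chrom, 0, length, quality_threshold=min_base_quality
            )
            arr = np.asarray(cov)  # rows A, C, G, T
            nz = np.nonzero(arr.sum(axis=0))[0]
            for pos in nz:
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(pos),
                        "A": int(arr[0, pos]),
                        "C": int(arr[1, pos]),
                        "G": int(arr[2, pos]),
                        "T": int(arr[3, pos]),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "A", "C", "G", "T"])


def pool_pileups(pileups: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum base counts of several pileups position-wise (library pooling)."""
    if not pileups:
        raise ValueError("no pileups to pool")
    merged = pd.concat(pileups, ignore_index=True)
    return (
        merged.groupby(["chrom", "pos"], as_index=False)[["A", "C", "G", "T"]]
        .sum()
        .sort_values(["chrom", "pos"], ignore_index=True)
    )


def aggregate_gene_counts(
    site_counts: pd.DataFrame,
    snp_map: Mapping[str, Sequence[SnpSite]],
    library_meta: Mapping[str, LibraryInfo],
) -> pd.DataFrame:
    """Sum site counts to the factorial cells per gene x tissue.

    Per tissue: Lw is the lyc-allele total over the gene's sites in the lyc
    parent library, Pw the penn-allele total in the penn parent library,
    and Lc / Pc the lyc- / penn-allele totals in the chimera library.
    Genes with zero total in any plant type get ``expressed = False``.
    """
    for lib in site_counts["library_id"].unique():
        if lib not in library_meta:
            raise ValueError(f"library {lib!r} has no genome_type metadata")
    site_to_gene: dict[tuple[str, int], str] = {}
    for gene, sites in snp_map.items():
        for s in sites:
            site_to_gene[(s.chrom, s.pos)] = gene
    df = site_counts.copy()
    keys = list(zip(df["chrom"], df["pos"]))
    df["gene_id"] = [site_to_gene.get(k) for k in keys]
    df = df[df["gene_id"].notna()]
    df["genome_type"] = df["library_id"].map(lambda l: library_meta[l].genome_type)
    df["tissue"] = df["library_id"].map(lambda l: library_meta[l].tissue)

    rows = []
    for (gene, tissue), block in df.groupby(["gene_id", "tissue"], sort=True):
        lyc_block = block[block["genome_type"] == "lyc"]
        penn_block = block[block["genome_type"] == "penn"]
        chim_block = block[block["genome_type"] == "chimera"]
        Lw = int(lyc_block["n_lyc"].sum())
        Pw = int(penn_block["n_penn"].sum())
        Lc = int(chim_block["n_lyc"].sum())
        Pc = int(chim_block["n_penn"].sum())
        expressed = (Lw + lyc_block["n_penn"].sum() > 0) and (
            Pw + penn_block["n_lyc"].sum() > 0
        ) and (Lc + Pc > 0)
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "Lw": Lw,
                "Pw": Pw,
                "Lc": Lc,
                "Pc": Pc,
                "expressed": bool(expressed),
            }
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "tissue", "Lw", "Pw", "Lc", "Pc", "expressed"]
    )
    n_flagged = int((~out["expressed"]).sum()) if len(out) else 0
    if n_flagged:
        logger.info("flagged %d gene x tissue rows as not expressed", n_flagged)
    return out


def compute_offsets(totals: Mapping[str, float]) -> dict[str, float]:
    """Log library-size offsets: log(total / geometric mean of totals)."""
    if not totals:
        raise ValueError("no library totals given")
    for lib, t in totals.items():
        if t <= 0:
            raise ValueError(f"library {lib!r} has non-positive total {t}")
    logs = {lib: math.log(t) for lib, t in totals.items()}
    mean_log = sum(logs.values()) / len(logs)
    return {lib: lg - mean_log for lib, lg in logs.items()}


def channel_offsets(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-channel normalization offsets from column totals, per tissue.

    Each of the four factorial cells is treated as its own count channel
    (the parental libraries each contribute one informative allele channel,
    the chimera library two), and the offset of a channel is the log of its
    total over all genes, centred by the geometric mean of the four totals.
    Genome-wide, the chimera's penn channel carries roughly the L1 tissue
    fraction of its library's reads, so this normalization absorbs both
    library size and tissue composition — without it, every uniformly
    expressed gene would look chimera-depleted on its penn allele.
    """
    df = counts.copy()
    cells = ["Lw", "Pw", "Lc", "Pc"]
    cols = ["off_lw", "off_pw", "off_lc", "off_pc"]
    for col in cols:
        df[col] = 0.0
    for tissue, block in counts.groupby("tissue"):
        totals = np.maximum(block[cells].sum(axis=0).to_numpy(dtype=float), 1.0)
        offs = np.log(totals) - np.log(totals).mean()
        df.loc[block.index, cols] = np.tile(offs, (len(block), 1))
    return df


def attach_offsets(
    counts: pd.DataFrame,
    offsets: Mapping[str, float],
    library_meta: Mapping[str, LibraryInfo],
) -> pd.DataFrame:
    """Join per-library offsets onto the factorial cells of a counts table."""
    by_role: dict[tuple[str, str], str] = {}
    for lib, info in library_meta.items():
        by_role[(info.genome_type, info.tissue)] = lib
    df = counts.copy()
    for col, role in (
        ("off_lw", "lyc"),
        ("off_pw", "penn"),
        ("off_lc", "chimera"),
        ("off_pc", "chimera"),
    ):
        df[col] = [
            offsets[by_role[(role, t)]] for t in df["tissue"]
        ]
    return df
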