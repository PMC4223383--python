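"""Fixed-difference SNP detection between pooled parental samples.

The two parental lines are inbred and effectively homozygous, so an
informative site is one where each parental pool is (nearly) pure for a
different base — a fixed difference.  Reads from the chimera can then be
assigned a parental origin at such sites.  Sites are called from
positionally matched base-count pileups of the pooled lyc and penn
samples, requiring a minimum depth in *both* pools (default 4 reads) and a
within-pool majority-base purity (default 0.9).

All internal coordinates are 0-based, half-open; conversion to/from the
1-based conventions of VCF and GFF3 happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import reduce
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: Expected columns of a pileup table (0-based positions).
PILEUP_COLUMNS = ("chrom", "pos", "A", "C", "G", "T")


@dataclass(frozen=True)
class SnpSite:
    """A fixed parental difference at one genomic position (0-based)."""

    chrom: str
    pos: int
    lyc_allele: str
    penn_allele: str
    depth_lyc: int = 0
    depth_penn: int = 0
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.lyc_allele == self.penn_allele:
            raise ValueError("a SNP site requires two different parental alleles")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.lyc_allele, self.penn_allele)


def call_fixed_differences(
    lyc: pd.DataFrame,
    penn: pd.DataFrame,
    min_depth: int = 4,
    purity: float = 0.9,
) -> list[SnpSite]:
    """Call fixed-difference SNPs from two positionally matched pileups.

    A site is returned iff both pools have depth >= ``min_depth``, each
    pool's majority base has within-pool frequency >= ``purity``, and the
    two majority bases differ.
    """
    if not (0.5 < purity <= 1.0):
        raise ValueError(f"purity must be in (0.5, 1], got {purity}")
    for name, df in (("lyc", lyc), ("penn", penn)):
        missing = set(PILEUP_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{name} pileup is missing columns {sorted(missing)}")
    if set(lyc["chrom"].unique()) != set(penn["chrom"].unique()):
        raise ValueError("pileups cover different references (chromosome sets differ)")

    merged = lyc.merge(
        penn, on=["chrom", "pos"], suffixes=("_l", "_p"), how="inner"
    )
    if merged.empty:
        return []
    cl = merged[[f"{b}_l" for b in BASES]].to_numpy(dtype=float)
    cp = merged[[f"{b}_p" for b in BASES]].to_numpy(dtype=float)
    dl, dp = cl.sum(axis=1), cp.sum(axis=1)
    il, ip = cl.argmax(axis=1), cp.argmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fl = np.where(dl > 0, cl.max(axis=1) / np.maximum(dl, 1), 0.0)
        fp = np.where(dp > 0, cp.max(axis=1) / np.maximum(dp, 1), 0.0)
    ok = (
        (dl >= min_depth)
        & (dp >= min_depth)
        & (fl >= purity)
        & (fp >= purity)
        & (il != ip)
    )
    sites = [
        SnpSite(
            chrom=row.chrom,
            pos=int(row.pos),
            lyc_allele=BASES[il[i]],
            penn_allele=BASES[ip[i]],
            depth_lyc=int(dl[i]),
            depth_penn=int(dp[i]),
        )
        for i, row in enumerate(merged.itertuples(index=False))
        if ok[i]
    ]
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def intersect_snp_sets(sets: Sequence[Iterable[SnpSite]]) -> list[SnpSite]:
    """Sites present in every input set, keyed by (chrom, pos, alleles).

    Depths (and any gene assignment) are taken from the first set, matching
    a caller-consensus workflow where one caller's evidence is reported.
    """
    if len(sets) == 0:
        raise ValueError("need at least one SNP set to intersect")
    materialized = [list(s) for s in sets]
    first = {s.key: s for s in materialized[0]}
    common = reduce(
        lambda acc, s: acc & {x.key for x in s},
        materialized[1:],
        set(first),
    )
    out = [first[k] for k in common]
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


def snp_density(n_snps: int, n_bases: int) -> float:
    """SNPs per 100 examined bases (a percentage)."""
    if n_bases <= 0:
        raise ValueError("n_bases must be positive")
    if n_snps < 0:
        raise ValueError("n_snps must be non-negative")
    return 100.0 * n_snps / n_bases


# ---------------------------------------------------------------------------
# Gene assignment
# ---------------------------------------------------------------------------

def _gene_id_of(db: gffutils.FeatureDB, feature: gffutils.Feature) -> str:
    """Resolve a CDS feature to its top-level gene identifier."""
    cur = feature
    seen = set()
    while True:
        parents = [p for p in db.parents(cur, level=1)]
        if not parents or cur.id in seen:
            break
        seen.add(cur.id)
        cur = parents[0]
    for key in ("gene_id", "ID", "Name"):
        if key in cur.attributes:
            return cur.attributes[key][0]
    return cur.id


def load_cds_intervals(gff_path: str | Path) -> dict[str, IntervalTree]:
    """Build per-chromosome interval trees of CDS (0-based half-open).

    Raises ``ValueError`` naming the offending line for malformed GFF3.
    """
    gff_path = Path(gff_path)
    for lineno, line in enumerate(gff_path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"malformed GFF3 at {gff_path}:{lineno}: {line[:80]!r}")
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    trees: dict[str, IntervalTree] = {}
    for cds in db.features_of_type("CDS"):
        gene = _gene_id_of(db, cds)
        tree = trees.setdefault(cds.seqid, IntervalTree())
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        tree.addi(cds.start - 1, cds.end, gene)
    return trees


def assign_snps_to_genes(
    snps: Iterable[SnpSite], gene_models: str | Path | Mapping[str, IntervalTree]
) -> tuple[dict[str, list[SnpSite]], int]:
    """Assign SNPs to genes via CDS overlap; intergenic SNPs are dropped.

    Returns ``(mapping gene_id -> sorted sites, n_dropped)``.  The set of
    genes with at least one SNP is the mapping's key set.
    """
    trees = (
        gene_models
        if isinstance(gene_models, Mapping)
        else load_cds_intervals(gene_models)
    )
    by_gene: dict[str, list[SnpSite]] = {}
    dropped = 0
    for snp in snps:
        tree = trees.get(snp.chrom)
        hits = tree[snp.pos] if tree is not None else set()
        if not hits:
            dropped += 1
            continue
        for iv in hits:
            gene = iv.data
            by_gene.setdefault(gene, []).append(replace(snp, gene_id=gene))
    for gene in by_gene:
        by_gene[gene].sort(key=lambda s: (s.chrom, s.pos))
    if dropped:
        logger.info("dropped %d SNP(s) outside annotated CDS", dropped)
    return by_gene, dropped


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=LYC_AL,Number=1,Type=String,Description="S. lycopersicum allele">
##INFO=<ID=PENN_AL,Number=1,Type=String,Description="S. pennellii allele">
##INFO=<ID=DP_LYC,Number=1,Type=Integer,Description="Pooled lyc depth">
##INFO=<ID=DP_PENN,Number=1,Type=Integer,Description="Pooled penn depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snp_vcf(snps: Iterable[SnpSite], path: str | Path) -> None:
    """Write sites as VCF v4.2 (REF = lyc allele, ALT = penn allele)."""
    lines = [_VCF_HEADER]
    for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        info = (
            f"LYC_AL={s.lyc_allele};PENN_AL={s.penn_allele};"
            f"DP_LYC={s.depth_lyc};DP_PENN={s.depth_penn}"
        )
        lines.append(
            f"{s.chrom}\t{s.pos + 1}\t.\t{s.lyc_allele}\t{s.penn_allele}"
            f"\t.\tPASS\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def read_snp_vcf(path: str | Path) -> list[SnpSite]:
    """Read fixed-difference sites from a VCF written by this package or a
    compatible caller (biallelic substitutions only; others are skipped)."""
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(path)):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        lyc = v.INFO.get("LYC_AL") or v.REF
        penn = v.INFO.get("PENN_AL") or v.ALT[0]
        out.append(
            SnpSite(
                chrom=v.CHROM,
                pos=v.POS - 1,
                lyc_allele=lyc,
                penn_allele=penn,
                depth_lyc=int(v.INFO.get("DP_LYC") or 0),
                depth_penn=int(v.INFO.get("DP_PENN") or 0),
            )
        )
    return out
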