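"""Synthetic data with the statistical structure the inference assumes.

Generates paired parental gene sequences that differ only by substitutions
at known sites, layer-resolved expression rates per gene, factorial count
tables for the three plant types (lyc parent, penn parent, chimera), toy
ungapped alignments with known allele of origin, and chromatogram peak
heights — so every downstream stage is testable without external data.

The count model mirrors the measurement process: a gene has per-layer
rates lambda_l1 (epidermis) and lambda_l23 (inner layers), a fraction
``p_l1`` of the tissue is L1, and a library with scale s measures

    wild type (genotype G):  s * (p_l1*lambda_l1 + (1-p_l1)*lambda_l23),
                             all reads carrying allele G
    chimera, penn origin:    s * p_l1 * lambda_l1
    chimera, lyc origin:     s * (1-p_l1) * lambda_l23

with counts drawn NB(mu, phi), Var = mu + phi*mu^2 (phi = 0 is Poisson).
Per-label rates are scaled so every gene has the same wild-type mean
``mean_expression``; an L1-specific gene has lambda_l23 = 0, hence its
chimera lyc-origin expectation is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .inference import (
    L1_RELATED,
    L1_SPECIFIC,
    L2L3_RELATED,
    L2L3_SPECIFIC,
    UNIFORM,
)
from .specificity import ChromatogramSite
from .variants import SnpSite

BASES = np.array(list("ACGT"))
TISSUES = ("leaf", "dehydrated_leaf", "fruit")
GENOME_TYPES = ("lyc", "penn", "chimera")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the system being emulated: an L1 tissue fraction of 0.2,
    coding divergence of ~1% between the parental lines, a fixed common NB
    dispersion of 0.1 and one library per genome x tissue (no biological
    replication).  Label proportions may sum to less than 1; the remainder
    are uniformly expressed genes.
    """

    n_genes: int = 200
    gene_length: int = 500
    snp_rate: float = 0.01
    p_l1: float = 0.2
    frac_l1_specific: float = 0.1
    frac_l1_related: float = 0.1
    frac_l2l3_specific: float = 0.1
    frac_l2l3_related: float = 0.1
    mean_expression: float = 100.0
    dispersion: float = 0.1
    library_sizes: Mapping[str, float] | None = None
    n_tissues: int = 1
    related_ratio: float = 4.0
    error_rate: float = 0.0
    upstream_flank: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_l1_specific,
            self.frac_l1_related,
            self.frac_l2l3_specific,
            self.frac_l2l3_related,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise ValueError("label proportions must be >= 0 and sum to <= 1")
        if not 0.0 <= self.p_l1 <= 1.0:
            raise ValueError("p_l1 must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be positive")
        if not 0.0 <= self.snp_rate < 1.0:
            raise ValueError("snp_rate must lie in [0, 1)")
        if not 1 <= self.n_tissues <= len(TISSUES):
            raise ValueError(f"n_tissues must be in 1..{len(TISSUES)}")
        if self.related_ratio <= 1.0:
            raise ValueError("related_ratio must exceed 1")
        if self.upstream_flank < 0:
            raise ValueError("upstream_flank must be >= 0")
        if self.library_sizes is not None and any(
            s <= 0 for s in self.library_sizes.values()
        ):
            raise ValueError("library sizes must be positive")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUES[: self.n_tissues]

    def library_size(self, genome: str, tissue: str) -> float:
        if self.library_sizes is None:
            return 1.0
        for key in (f"{genome}:{tissue}", genome):
            if key in self.library_sizes:
                return float(self.library_sizes[key])
        return 1.0

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TrueGene:
    """Ground-truth expression program of one simulated gene."""

    gene_id: str
    label: str
    lambda_l1: float
    lambda_l23: float
    snp_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.lambda_l23 < 0:
            raise ValueError("expression rates must be >= 0")
        if self.label == L1_SPECIFIC and self.lambda_l23 != 0:
            raise ValueError("an L1-specific gene must have lambda_l23 = 0")
        if self.label == L2L3_SPECIFIC and self.lambda_l1 != 0:
            raise ValueError("an L2/L3-specific gene must have lambda_l1 = 0")

    def penn_read_fraction(self, p_l1: float) -> float:
        """Expected penn-origin share of this gene's reads in the chimera."""
        total = p_l1 * self.lambda_l1 + (1.0 - p_l1) * self.lambda_l23
        if total == 0:
            return 0.0
        return p_l1 * self.lambda_l1 / total


def _label_rates(label: str, config: SimConfig) -> tuple[float, float]:
    m, p, r = config.mean_expression, config.p_l1, config.related_ratio
    if label == UNIFORM:
        return m, m
    if label == L1_SPECIFIC:
        return (m / p if p > 0 else 0.0), 0.0
    if label == L2L3_SPECIFIC:
        return 0.0, (m / (1 - p) if p < 1 else 0.0)
    if label == L1_RELATED:
        l23 = m / (p * r + (1 - p))
        return r * l23, l23
    if label == L2L3_RELATED:
        l1 = m / (p + (1 - p) * r)
        return l1, r * l1
    raise ValueError(f"unknown label {label!r}")


def make_true_genes(config: SimConfig) -> list[TrueGene]:
    """Assign labels (exact proportions, seeded shuffle) and rates."""
    n = config.n_genes
    counts = {
        L1_SPECIFIC: round(config.frac_l1_specific * n),
        L1_RELATED: round(config.frac_l1_related * n),
        L2L3_SPECIFIC: round(config.frac_l2l3_specific * n),
        L2L3_RELATED: round(config.frac_l2l3_related * n),
    }
    labels = [lbl for lbl, k in counts.items() for _ in range(k)]
    labels += [UNIFORM] * (n - len(labels))
    order = config.rng(1).permutation(n)
    genes = []
    for i in range(n):
        label = labels[order[i]]
        l1, l23 = _label_rates(label, config)
        genes.append(TrueGene(gene_id=f"gene{i + 1:04d}", label=label, lambda_l1=l1, lambda_l23=l23))
    return genes


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def simulate_parental_genomes(
    config: SimConfig, genes: Sequence[TrueGene] | None = None
) -> tuple[dict[str, str], dict[str, str], list[SnpSite]]:
    """Two parental sequence sets differing only at the returned SNP sites.

    One contig per gene, named after it: an optional non-coding upstream
    flank (identical between parents) followed by the coding sequence, with
    substitutions at Bernoulli(``snp_rate``) positions within the CDS.  If
    ``genes`` is given, each gene's ``snp_positions`` (CDS-relative,
    0-based) is filled in.
    """
    if genes is None:
        genes = make_true_genes(config)
    rng = config.rng(0)
    L, flank = config.gene_length, config.upstream_flank
    lyc: dict[str, str] = {}
    penn: dict[str, str] = {}
    truth: list[SnpSite] = []
    for gene in genes:
        flank_seq = "".join(rng.choice(BASES, size=flank)) if flank else ""
        cds = rng.choice(BASES, size=L)
        is_snp = rng.random(L) < config.snp_rate
        cds_penn = cds.copy()
        offsets = np.nonzero(is_snp)[0]
        for off in offsets:
            alternatives = [b for b in BASES if b != cds[off]]
            cds_penn[off] = rng.choice(alternatives)
        lyc[gene.gene_id] = flank_seq + "".join(cds)
        penn[gene.gene_id] = flank_seq + "".join(cds_penn)
        gene.snp_positions = [int(o) for o in offsets]
        for off in offsets:
            truth.append(
                SnpSite(
                    chrom=gene.gene_id,
                    pos=flank + int(off),
                    lyc_allele=str(cds[off]),
                    penn_allele=str(cds_penn[off]),
                    gene_id=gene.gene_id,
                )
            )
    return lyc, penn, truth


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_models_gff(
    genes: Iterable[TrueGene], config: SimConfig, path: str | Path
) -> None:
    """GFF3 gene models: one +strand single-CDS gene per contig."""
    flank, L = config.upstream_flank, config.gene_length
    lines = ["##gff-version 3\n"]
    for g in genes:
        gid = g.gene_id
        start, end = flank + 1, flank + L  # 1-based inclusive
        lines.append(f"{gid}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")
        lines.append(
            f"{gid}\tsim\tmRNA\t{start}\t{end}\t.\t+\t.\tID={gid}.1;Parent={gid}\n"
        )
        lines.append(
            f"{gid}\tsim\tCDS\t{start}\t{end}\t.\t+\t0\tID={gid}.1.cds;Parent={gid}.1\n"
        )
    Path(path).write_text("".join(lines))


def write_truth_table(genes: Iterable[TrueGene], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "label": g.label,
            "lambda_l1": g.lambda_l1,
            "lambda_l23": g.lambda_l23,
            "n_snps": len(g.snp_positions),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def perfect_pileup(genome: Mapping[str, str], depth: int = 10) -> pd.DataFrame:
    """Error-free uniform-coverage pileup of a haploid pool."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rows = []
    for chrom, seq in genome.items():
        for pos, base in enumerate(seq):
            row = {"chrom": chrom, "pos": pos, "A": 0, "C": 0, "G": 0, "T": 0}
            row[base] = depth
            rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "pos", "A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimConfig, genes: Sequence[TrueGene] | None = None) -> pd.DataFrame:
    """Draw the four factorial cells per gene x tissue.

    Returns one row per gene x tissue with columns ``Lw, Pw, Lc, Pc``, the
    true per-channel log offsets ``off_lw .. off_pc`` and the truth label.
    The offsets are the channel scales of the generative model — library
    size for the parental cells, library size times the layer fraction for
    the two chimera allele channels — so a uniformly expressed gene is null
    in every contrast once offsets are accounted for, mirroring how the
    empirical column-total normalization behaves on real data.
    """
    if genes is None:
        genes = make_true_genes(config)
    rng = config.rng(2)
    p, phi = config.p_l1, config.dispersion
    rows = []
    for tissue in config.tissues:
        s_lyc = config.library_size("lyc", tissue)
        s_penn = config.library_size("penn", tissue)
        s_chim = config.library_size("chimera", tissue)
        lam1 = np.array([g.lambda_l1 for g in genes])
        lam23 = np.array([g.lambda_l23 for g in genes])
        total = p * lam1 + (1 - p) * lam23
        mu = np.column_stack(
            [s_lyc * total, s_penn * total, s_chim * (1 - p) * lam23, s_chim * p * lam1]
        )
        draws = _nb_draw(rng, mu, phi)
        # channel scales; clipped so degenerate mixtures (p in {0,1}) keep
        # finite offsets for the zero channel
        off = np.log(
            np.clip(
                [s_lyc, s_penn, s_chim * (1 - p), s_chim * p], 1e-8, None
            )
        )
        for i, g in enumerate(genes):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "tissue": tissue,
                    "Lw": int(draws[i, 0]),
                    "Pw": int(draws[i, 1]),
                    "Lc": int(draws[i, 2]),
                    "Pc": int(draws[i, 3]),
                    "off_lw": off[0],
                    "off_pw": off[1],
                    "off_lc": off[2],
                    "off_pc": off[3],
                    "label": g.label,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    qname: str
    chrom: str
    pos: int  # 0-based leftmost
    seq: str
    origin: str  # "lyc" or "penn"


def simulate_alignments(
    genomes: tuple[Mapping[str, str], Mapping[str, str]],
    genes: Sequence[TrueGene],
    depth: float,
    read_length: int | None = None,
    penn_fraction: float | Mapping[str, float] = 0.0,
    stochastic: bool = False,
    expression: Mapping[str, float] | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    upstream_flank: int = 0,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Ungapped error-free (by default) reads tiling each gene's CDS.

    Each read is drawn from one haplotype; ``penn_fraction`` (scalar or per
    gene) sets the penn-origin share, e.g. 0 for the lyc parent library, 1
    for the penn parent, and the gene's mixture share for the chimera.  In
    the default exact mode read counts and start positions are
    deterministic (coverage ~= ``depth``); with ``stochastic=True`` counts
    are Poisson around ``depth`` scaled by the gene's relative
    ``expression`` and starts are uniform.  Returns the reads (sorted) and
    the per-SNP-site truth tally of covering reads by origin.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    lyc, penn = genomes
    rng = np.random.default_rng([seed, 3])
    reads: list[SimRead] = []
    tally_rows = []
    for gene in genes:
        gid = gene.gene_id
        if gid not in lyc:
            raise KeyError(f"gene {gid} absent from genomes")
        cds_len = len(lyc[gid]) - upstream_flank
        rl = min(read_length or cds_len, cds_len)
        pf = (
            penn_fraction.get(gid, 0.0)
            if isinstance(penn_fraction, Mapping)
            else float(penn_fraction)
        )
        if not 0.0 <= pf <= 1.0:
            raise ValueError("penn_fraction must lie in [0, 1]")
        mean_reads = depth * cds_len / rl
        if expression is not None:
            mean_reads *= expression.get(gid, 1.0)
        if stochastic:
            n_reads = int(rng.poisson(mean_reads))
            starts = (
                rng.integers(0, cds_len - rl + 1, size=n_reads)
                if n_reads
                else np.array([], dtype=int)
            )
            n_penn = int(rng.binomial(n_reads, pf)) if n_reads else 0
            origins = np.array(["lyc"] * n_reads)
            origins[rng.permutation(n_reads)[:n_penn]] = "penn"
        else:
            n_reads = max(1, round(mean_reads))
            if n_reads == 1:
                starts = np.array([0])
            else:
                starts = np.round(np.linspace(0, cds_len - rl, n_reads)).astype(int)
            n_penn = round(n_reads * pf)
            origins = np.array(["lyc"] * n_reads)
            if n_penn:
                pick = np.round(np.linspace(0, n_reads - 1, n_penn)).astype(int)
                origins[pick] = "penn"
        starts = np.sort(starts) + upstream_flank
        per_site = {flankpos(gene, upstream_flank, o): [0, 0] for o in gene.snp_positions}
        for i in range(n_reads):
            hap = lyc[gid] if origins[i] == "lyc" else penn[gid]
            s = int(starts[i])
            seq = list(hap[s : s + rl])
            if error_rate > 0:
                errs = np.nonzero(rng.random(rl) < error_rate)[0]
                for e in errs:
                    seq[e] = str(rng.choice([b for b in BASES if b != seq[e]]))
            reads.append(
                SimRead(
                    qname=f"{gid}:{i}:{origins[i]}",
                    chrom=gid,
                    pos=s,
                    seq="".join(seq),
                    origin=str(origins[i]),
                )
            )
            for off in gene.snp_positions:
                gpos = off + upstream_flank
                if s <= gpos < s + rl:
                    per_site[gpos][0 if origins[i] == "lyc" else 1] += 1
        for gpos, (nl, np_) in sorted(per_site.items()):
            tally_rows.append(
                {"chrom": gid, "pos": gpos, "n_lyc": nl, "n_penn": np_}
            )
    reads.sort(key=lambda r: (r.chrom, r.pos, r.qname))
    tally = pd.DataFrame(tally_rows, columns=["chrom", "pos", "n_lyc", "n_penn"])
    return reads, tally


def flankpos(gene: TrueGene, flank: int, cds_offset: int) -> int:
    return flank + cds_offset


def write_sam(
    reads: Sequence[SimRead], genome: Mapping[str, str], path: str | Path
) -> None:
    """Write reads as coordinate-sorted plain-text SAM (M-only CIGARs)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.qname
            a.flag = 0
            a.reference_id = ref_ids[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigartuples = [(0, len(r.seq))]
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            out.write(a)


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

def simulate_chromatogram(
    f: float,
    n_sites: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    material: str = "cDNA",
    scale: float = 1000.0,
) -> list[ChromatogramSite]:
    """Peak heights at ``n_sites`` polymorphic positions with penn share ~f.

    Heights carry independent multiplicative log-normal noise per allele;
    with ``noise_sd=0`` every site yields exactly ``f``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("allele fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng([seed, 4])
    sites = []
    for i in range(n_sites):
        noise_l = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd else 1.0
        noise_p = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd else 1.0
        sites.append(
            ChromatogramSite(
                site_id=f"site{i + 1}",
                height_lyc=scale * (1.0 - f) * noise_l,
                height_penn=scale * f * noise_p,
                quality=40.0,
                material=material,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(
    genomes: tuple[dict[str, str], dict[str, str]],
    flank: int,
    gene_ids: Iterable[str],
    motif: str = "TAAATGCA",
    pattern: str = "TAAATGYA",
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Plant a motif instance in chosen genes' upstream flanks.

    First scrubs every accidental occurrence of ``pattern`` from all flanks
    (so background genes are exactly motif-free), then writes ``motif`` at a
    seeded random flank position of each chosen gene, identically in both
    parental haplotypes.  Returns new genome dicts.
    """
    from .motif import MotifPattern, scan_motif

    if flank < len(motif):
        raise ValueError("upstream flank too short to hold the motif")
    rng = np.random.default_rng([seed, 5])
    pat = MotifPattern(pattern=pattern)
    lyc, penn = dict(genomes[0]), dict(genomes[1])
    chosen = set(gene_ids)
    for gid in lyc:
        fl = list(lyc[gid][:flank])
        guard = 0
        while True:
            hits = scan_motif("".join(fl), pat)
            hits = [h for h in hits if h < flank - 1]
            if not hits:
                break
            for h in hits:
                current = fl[h]
                fl[h] = str(rng.choice([b for b in BASES if b != current and b != "T"]))
            guard += 1
            if guard > 100:  # pragma: no cover - pathological flanks only
                raise RuntimeError("failed to scrub motif from flank")
        rest_l = lyc[gid][flank:]
        rest_p = penn[gid][flank:]
        if gid in chosen:
            start = int(rng.integers(0, flank - len(motif) + 1))
            fl[start : start + len(motif)] = list(motif)
        new_flank = "".join(fl)
        lyc[gid] = new_flank + rest_l
        penn[gid] = new_flank + rest_p
    return lyc, penn
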