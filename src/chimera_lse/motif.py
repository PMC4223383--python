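"""Promoter extraction, L1-box motif scanning and enrichment testing.

The L1 box (IUPAC TAAATGYA, Y = C/T) is a promoter element associated with
epidermis-specific transcription.  Enrichment among genes classified as L1
is assessed on the 1000 bp windows upstream of translation start sites with
a two-sided Fisher exact test on the 2x2 presence table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from pyfaidx import Fasta
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC nucleotide pattern; default is the L1 box."""

    pattern: str = "TAAATGYA"
    strand_policy: str = "forward"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in pattern")
        if self.strand_policy not in ("forward", "both"):
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")

    def regex(self, pattern: str | None = None) -> re.Pattern:
        pat = (pattern or self.pattern).upper()
        # N must not match the ambiguous base N in the subject, so each
        # position is an explicit A/C/G/T class; lookahead allows overlaps.
        body = "".join(f"[{IUPAC[c]}]" for c in pat)
        return re.compile(f"(?=({body}))")


@dataclass
class PromoterRecord:
    """An upstream window, on the gene's promoter strand."""

    gene_id: str
    sequence: str
    length: int
    truncated: bool
    chrom: str | None = None
    start: int | None = None  # 0-based half-open genome interval of the window
    end: int | None = None
    strand: str = "+"


@dataclass
class EnrichmentResult:
    """Fisher exact test of motif presence, focal class vs background."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    fractions: dict = field(default_factory=dict)
    focal: str = "L1"
    background: str = "all-others"


def extract_upstream(
    genome: str | Path | Mapping[str, str],
    gene_models: str | Path,
    window: int = 1000,
) -> list[PromoterRecord]:
    """Windows upstream of each gene's translation start site.

    For + strand genes the window ends immediately before the first CDS
    base (0-based half-open ``[start - window, start)``); for - strand
    genes it is the reverse complement of the window beginning after the
    last CDS base.  Windows are truncated at contig edges
    (``truncated=True``); genes without CDS are skipped with a log message.
    """
    import gffutils

    if isinstance(genome, Mapping):
        seqs = {k: str(v) for k, v in genome.items()}
    else:
        fa = Fasta(str(genome))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    db = gffutils.create_db(
        str(gene_models), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    from .variants import _gene_id_of

    by_gene: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        by_gene.setdefault(_gene_id_of(db, cds), []).append(cds)

    records = []
    gene_ids_with_cds = set(by_gene)
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        if gid not in gene_ids_with_cds:
            logger.info("gene %s has no CDS; skipped", gid)
            continue
    for gid in sorted(by_gene):
        cdss = by_gene[gid]
        chrom = cdss[0].seqid
        strand = cdss[0].strand
        contig = seqs.get(chrom)
        if contig is None:
            logger.info("gene %s on unknown contig %s; skipped", gid, chrom)
            continue
        if strand == "-":
            tss = max(c.end for c in cdss)  # 1-based inclusive end == 0-based exclusive
            start0, end0 = tss, min(tss + window, len(contig))
            seq = reverse_complement(contig[start0:end0])
        else:
            tss = min(c.start for c in cdss) - 1  # 0-based first CDS base
            start0, end0 = max(tss - window, 0), tss
            seq = contig[start0:end0]
        records.append(
            PromoterRecord(
                gene_id=gid,
                sequence=seq.upper(),
                length=len(seq),
                truncated=len(seq) < window,
                chrom=chrom,
                start=start0,
                end=end0,
                strand=strand,
            )
        )
    return records


def scan_motif(
    record: PromoterRecord | str, motif: MotifPattern | str = MotifPattern()
) -> list[int]:
    """All (possibly overlapping) match start offsets of the motif.

    Under ``strand_policy="both"`` matches of the reverse-complement
    pattern are included too.  ``N`` in the subject never matches.
    """
    if isinstance(motif, str):
        motif = MotifPattern(pattern=motif)
    seq = (record if isinstance(record, str) else record.sequence).upper()
    hits = [m.start() for m in motif.regex().finditer(seq)]
    if motif.strand_policy == "both":
        rc = reverse_complement(motif.pattern)
        hits.extend(m.start() for m in motif.regex(rc).finditer(seq))
    return sorted(set(hits))


def motif_presence(
    records: Iterable[PromoterRecord], motif: MotifPattern | str = MotifPattern()
) -> dict[str, bool]:
    """Per gene: does the promoter window contain at least one motif hit."""
    return {r.gene_id: len(scan_motif(r, motif)) > 0 for r in records}


def layer_of(label: str) -> str:
    """Collapse specific/related grades to L1 / L2/L3 / other."""
    if label.startswith("L1"):
        return "L1"
    if label.startswith("L2/L3"):
        return "L2/L3"
    return "other"


def enrichment_test(
    presence: Mapping[str, bool],
    classes: Mapping[str, str],
    focal: str = "L1",
    background: str = "all-others",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of motif presence in the focal class.

    ``classes`` maps genes to L1 / L2/L3 / other (full classification
    labels are collapsed automatically).  ``background`` is either
    ``"all-others"`` (every examined non-focal gene) or a named class.
    Per-class presence fractions are always reported.
    """
    genes = [g for g in presence if g in classes]
    if not genes:
        raise ValueError("no genes shared between presence and classes")
    collapsed = {g: layer_of(classes[g]) for g in genes}
    focal_genes = [g for g in genes if collapsed[g] == focal]
    if background == "all-others":
        bg_genes = [g for g in genes if collapsed[g] != focal]
    else:
        bg_genes = [g for g in genes if collapsed[g] == background]
    if not focal_genes or not bg_genes:
        raise ValueError("focal and background groups must both be non-empty")
    a = sum(presence[g] for g in focal_genes)
    b = len(focal_genes) - a
    c = sum(presence[g] for g in bg_genes)
    d = len(bg_genes) - c
    table = ((a, b), (c, d))
    odds, p = fisher_exact(np.array(table), alternative="two-sided")
    fractions = {}
    for cls in sorted(set(collapsed.values())):
        members = [g for g in genes if collapsed[g] == cls]
        fractions[cls] = sum(presence[g] for g in members) / len(members)
    return EnrichmentResult(
        table=table,
        odds_ratio=float(odds),
        p=float(p),
        fractions=fractions,
        focal=focal,
        background=background,
    )
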