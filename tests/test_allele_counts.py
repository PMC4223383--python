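"""CIGAR-aware allele counting and gene-level factorial aggregation."""

import math

import numpy as np
import pandas as pd
import pysam
import pytest

from chimera_lse.allele_counts import (
    LibraryInfo,
    aggregate_gene_counts,
    attach_offsets,
    channel_offsets,
    compute_offsets,
    count_alleles,
    count_alleles_at_site,
    ensure_bam,
)
from chimera_lse.simulate import simulate_alignments, write_sam
from chimera_lse.variants import SnpSite


def _make_bam(tmp_path, reads, ref_len=100, name="t"):
    """reads: list of (qname, pos, seq, cigar, qual_char, mapq)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "c1", "LN": ref_len}]}
    sam = tmp_path / f"{name}.sam"
    with pysam.AlignmentFile(str(sam), "w", header=header) as out:
        for qname, pos, seq, cigar, qual, mapq in sorted(reads, key=lambda r: r[1]):
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual * len(seq))
            out.write(a)
    return ensure_bam(sam, tmp_path)


SITE = SnpSite("c1", 10, "A", "G")


class TestCountAllelesAtSite:
    def _count(self, tmp_path, reads, **kwargs):
        bam = _make_bam(tmp_path, reads)
        with pysam.AlignmentFile(str(bam)) as aln:
            return count_alleles_at_site(aln, SITE, **kwargs)

    def test_single_lyc_read(self, tmp_path):
        c = self._count(tmp_path, [("r1", 5, "CCCCCACCCC", "10M", "I", 60)])
        assert (c.n_lyc, c.n_penn, c.n_other) == (1, 0, 0)

    def test_single_penn_read(self, tmp_path):
        c = self._count(tmp_path, [("r1", 5, "CCCCCGCCCC", "10M", "I", 60)])
        assert (c.n_lyc, c.n_penn, c.n_other) == (0, 1, 0)

    def test_hand_tally_with_third_base(self, tmp_path):
        reads = [
            ("r1", 5, "CCCCCACCCC", "10M", "I", 60),
            ("r2", 8, "CCACCCCCCC", "10M", "I", 60),
            ("r3", 6, "CCCCGCCCCC", "10M", "I", 60),
            ("r4", 3, "CCCCCCCTCC", "10M", "I", 60),
        ]
        c = self._count(tmp_path, reads)
        assert (c.n_lyc, c.n_penn, c.n_other) == (2, 1, 1)

    def test_deletion_at_site_counts_as_other(self, tmp_path):
        # 5M3D5M starting at 7: deletion spans refs 12..14? choose start 8:
        # matches 8-12, deletion 13-15 -> site 10 must be inside deletion:
        # use start 5 with 5M3D5M: matches 5-9, deletion 10-12 -> site 10.
        c = self._count(tmp_path, [("r1", 5, "CCCCCCCCCC", "5M3D5M", "I", 60)])
        assert (c.n_lyc, c.n_penn, c.n_other) == (0, 0, 1)

    def test_low_base_quality_counts_as_other(self, tmp_path):
        c = self._count(
            tmp_path, [("r1", 5, "CCCCCACCCC", "10M", "#", 60)],
            min_base_quality=20,
        )
        assert (c.n_lyc, c.n_penn, c.n_other) == (0, 0, 1)

    def test_low_mapping_quality_counts_as_other(self, tmp_path):
        c = self._count(
            tmp_path, [("r1", 5, "CCCCCACCCC", "10M", "I", 2)],
            min_mapping_quality=10,
        )
        assert (c.n_lyc, c.n_penn, c.n_other) == (0, 0, 1)

    def test_conservation_of_overlapping_reads(self, tmp_path):
        reads = [(f"r{i}", 5 + i, "A" * 10, "10M", "I", 60) for i in range(6)]
        c = self._count(tmp_path, reads)
        assert c.n_lyc + c.n_penn + c.n_other == 6

    def test_site_outside_reference_rejected(self, tmp_path):
        bam = _make_bam(tmp_path, [("r1", 5, "A" * 10, "10M", "I", 60)])
        with pysam.AlignmentFile(str(bam)) as aln:
            with pytest.raises(ValueError):
                count_alleles_at_site(aln, SnpSite("c1", 500, "A", "G"))


class TestSimulatedTruthEquivalence:
    def test_counts_match_simulator_tallies_exactly(self, small_world, tmp_path):
        genes = small_world["genes"]
        reads, tally = simulate_alignments(
            (small_world["lyc"], small_world["penn"]), genes,
            depth=8, read_length=50, penn_fraction=0.4,
        )
        sam = tmp_path / "mix.sam"
        write_sam(reads, small_world["lyc"], sam)
        sites = [s for s in small_world["truth"]]
        df = count_alleles(sam, sites, "mix", workdir=tmp_path)
        merged = df.merge(tally, on=["chrom", "pos"])
        assert len(merged) == len(tally)
        assert (merged["n_lyc_x"] == merged["n_lyc_y"]).all()
        assert (merged["n_penn_x"] == merged["n_penn_y"]).all()
        assert (merged["n_other"] == 0).all()

    def test_parental_library_has_no_penn_signal(self, small_world, tmp_path):
        reads, _ = simulate_alignments(
            (small_world["lyc"], small_world["penn"]), small_world["genes"],
            depth=5, read_length=60, penn_fraction=0.0,
        )
        sam = tmp_path / "lyc.sam"
        write_sam(reads, small_world["lyc"], sam)
        df = count_alleles(sam, small_world["truth"], "lyc_leaf", workdir=tmp_path)
        assert df["n_penn"].sum() == 0


class TestAggregate:
    META = {
        "lyc_leaf": LibraryInfo("lyc_leaf", "lyc", "leaf"),
        "penn_leaf": LibraryInfo("penn_leaf", "penn", "leaf"),
        "chim_leaf": LibraryInfo("chim_leaf", "chimera", "leaf"),
    }
    SNP_MAP = {
        "geneA": [SnpSite("c1", 10, "A", "G", gene_id="geneA"),
                  SnpSite("c1", 20, "C", "T", gene_id="geneA")],
        "geneB": [SnpSite("c2", 5, "G", "A", gene_id="geneB")],
    }

    def _site_counts(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "library_id", "n_lyc", "n_penn", "n_other"]
        )

    def test_summation_over_sites(self):
        sc = self._site_counts([
            ("c1", 10, "chim_leaf", 3, 0, 0),
            ("c1", 20, "chim_leaf", 2, 1, 0),
            ("c1", 10, "lyc_leaf", 5, 0, 0),
            ("c1", 20, "lyc_leaf", 4, 0, 0),
            ("c1", 10, "penn_leaf", 0, 6, 0),
            ("c1", 20, "penn_leaf", 0, 7, 0),
        ])
        out = aggregate_gene_counts(sc, self.SNP_MAP, self.META)
        row = out[out["gene_id"] == "geneA"].iloc[0]
        assert (row.Lw, row.Pw, row.Lc, row.Pc) == (9, 13, 5, 1)
        assert row.expressed

    def test_gene_without_sites_absent(self):
        sc = self._site_counts([("c1", 10, "lyc_leaf", 5, 0, 0)])
        out = aggregate_gene_counts(sc, self.SNP_MAP, self.META)
        assert "geneB" not in set(out["gene_id"])

    def test_all_zero_gene_flagged_not_expressed(self):
        sc = self._site_counts([
            ("c2", 5, "lyc_leaf", 4, 0, 0),
            ("c2", 5, "penn_leaf", 0, 4, 0),
            ("c2", 5, "chim_leaf", 0, 0, 0),
        ])
        out = aggregate_gene_counts(sc, self.SNP_MAP, self.META)
        row = out[out["gene_id"] == "geneB"].iloc[0]
        assert not row.expressed

    def test_unknown_library_rejected(self):
        sc = self._site_counts([("c1", 10, "mystery", 1, 0, 0)])
        with pytest.raises(ValueError):
            aggregate_gene_counts(sc, self.SNP_MAP, self.META)


class TestOffsets:
    def test_equal_totals_zero_offsets(self):
        offs = compute_offsets({"a": 100, "b": 100, "c": 100})
        assert all(v == pytest.approx(0.0) for v in offs.values())

    def test_hand_computed_log_ratios(self):
        offs = compute_offsets({"a": 100, "b": 100, "c": 400})
        assert offs["a"] == pytest.approx(-0.462, abs=1e-3)
        assert offs["b"] == pytest.approx(-0.462, abs=1e-3)
        assert offs["c"] == pytest.approx(0.924, abs=1e-3)

    def test_single_library_zero_offset(self):
        assert compute_offsets({"only": 777}) == {"only": 0.0}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_offsets({"a": 0})

    def test_attach_offsets_maps_roles(self):
        counts = pd.DataFrame(
            {"gene_id": ["g"], "tissue": ["leaf"], "Lw": [1], "Pw": [1],
             "Lc": [1], "Pc": [1]}
        )
        meta = TestAggregate.META
        offs = {"lyc_leaf": 0.1, "penn_leaf": -0.2, "chim_leaf": 0.3}
        out = attach_offsets(counts, offs, meta)
        assert out.loc[0, "off_lw"] == 0.1
        assert out.loc[0, "off_pw"] == -0.2
        assert out.loc[0, "off_lc"] == 0.3 == out.loc[0, "off_pc"]

    def test_channel_offsets_absorb_tissue_composition(self):
        rng = np.random.default_rng(0)
        n = 500
        counts = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "tissue": "leaf",
            "Lw": rng.poisson(100, n), "Pw": rng.poisson(100, n),
            "Lc": rng.poisson(80, n), "Pc": rng.poisson(20, n),
        })
        out = channel_offsets(counts)
        # offsets are centred and reproduce the log column-total ratios
        offs = out[["off_lw", "off_pw", "off_lc", "off_pc"]].iloc[0].to_numpy()
        assert offs.sum() == pytest.approx(0.0, abs=1e-12)
        assert offs[3] - offs[2] == pytest.approx(math.log(20 / 80), abs=0.05)
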