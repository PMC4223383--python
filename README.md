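# chimera-lse

Layer-specific gene expression inference from periclinal chimeras via
parental-origin allele-specific RNA-seq.

## The problem

A plant organ mixes cell types from three clonally distinct layers: the
epidermis (L1), the sub-epidermal layer (L2) and the inner corpus (L3).
Bulk RNA-seq of a whole organ sums over all of them, so it cannot say which
layer expresses a gene. A periclinal chimera whose L1 layer derives from
*Solanum pennellii* and whose L2/L3 layers derive from *S. lycopersicum*
genetically tags each layer: wherever the two parental genomes differ by a
fixed SNP, a read from the chimera can be assigned to the layer it came
from. This package implements that inference end to end:

1. **Fixed-difference SNP calling** between pooled parental samples
   (minimum 4x coverage in both pools, 0.9 majority-base purity).
2. **Allele counting**: CIGAR-aware tallies of reads supporting each
   parental allele at SNP sites, aggregated per gene into the four cells of
   a 2x2 factorial — `Lw`, `Pw` (lyc/penn allele in the parental wild
   types) and `Lc`, `Pc` (lyc/penn allele in the chimera).
3. **Layer classification** with a negative-binomial GLM,
   `log mu = offset + b0 + b_origin + b_genome + b_int`, Var(y) = mu + phi mu^2,
   testing four treatment contrasts by likelihood-ratio:
   (a) `Lc` vs `Lw`, (b) `Pc` vs `Pw`, (c) the interaction,
   (d) `Pc` vs `Lc` within the chimera. After per-contrast BH (or BY) FDR
   at alpha = 0.05, a gene is **L1**-classified when its lyc allele drops in
   the chimera (a), its penn allele does not (b), and the interaction is
   significant (c); it is L1-*specific* (rather than L1-*related*) when the
   penn allele additionally dominates within the chimera (d). L2/L3 calls
   are the mirror image, and multi-tissue evidence is combined with
   conflict tracking.
4. **%L1 specificity** from Sanger chromatogram peak heights: the penn peak
   fraction `f` at polymorphic sites, normalized by the L1 tissue fraction
   `p` (estimated from genomic DNA) as the odds share
   `%L1 = 100 (f/p) / (f/p + (1-f)/(1-p))`, so uniform expression reads 50%.
5. **L1-box motif enrichment** (IUPAC `TAAATGYA`) in 1000 bp windows
   upstream of translation starts, Fisher exact test of presence in L1 vs
   other genes.

A first-class synthetic-data module simulates parental genomes, chimera
read mixtures (L1 fraction 0.2 by default), NB counts, alignments and
chromatograms, so the whole stack is testable without external data.

## Worked example

`examples/01_simulate_and_classify.py` simulates 400 genes (10% truly
L1-specific, 10% L2/L3-specific, the rest uniform) at mean 100 counts and
dispersion 0.1, and classifies them:

```
(true label, called label): count
  ('L1-specific', 'L1-specific'): 40
  ('L2/L3-specific', 'L2/L3-specific'): 40
  ('uniform', 'L2/L3-related'): 1
  ('uniform', 'L2/L3-specific'): 1
  ('uniform', 'unclassified'): 318
```

All 80 truly specific genes are recovered to the correct layer and 318/320
uniform genes are left unclassified — the two stray calls are within the
FDR budget. `examples/03_specificity_table.py` shows the chromatogram path:

```
L1 tissue fraction from gDNA: 19.6% +/- 0.4 (40 sites)
  epidermis-only gene (f ~ 1): %L1 = 100.0 (n=6)
  uniform gene (f = p): %L1 = 50.0 (n=6)
  inner-layer gene (f ~ 0): %L1 = 0.0 (n=6)
```

The other examples cover SNP calling (`02`), motif enrichment (`04`) and
the full read-level pipeline with its attrition funnel (`05`). A thin CLI
wraps the same library: `chimera-lse simulate | call-snps | intersect-vcf |
count-alleles | classify | specificity | motif | run-all`.

## Layout

- `src/chimera_lse/` — `simulate`, `variants`, `allele_counts`,
  `inference`, `specificity`, `motif`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — model, assumptions, parameter choices, limitations
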