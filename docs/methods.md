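# Methods

## Measurement model

A periclinal chimera with an L1 (epidermal) layer from *S. pennellii*
("penn") and L2/L3 layers from *S. lycopersicum* ("lyc") turns layer
membership into allele identity. Let a gene have per-layer expression
rates `lambda_1` (L1) and `lambda_23` (L2/L3), and let `p` be the fraction
of the sampled tissue that is L1 (about 0.2 in leaf). A sequencing library
with scale `s` then measures, at the gene's fixed-difference SNP sites:

| cell | library            | allele | expectation                            |
|------|--------------------|--------|----------------------------------------|
| Lw   | lyc parent         | lyc    | `s (p lambda_1 + (1-p) lambda_23)`     |
| Pw   | penn parent        | penn   | `s (p lambda_1 + (1-p) lambda_23)`     |
| Lc   | chimera            | lyc    | `s (1-p) lambda_23`                    |
| Pc   | chimera            | penn   | `s p lambda_1`                         |

A gene expressed only in L1 has `lambda_23 = 0`, hence `E[Lc] = 0`: its
lyc-allele signal vanishes in the chimera while the penn-allele signal
persists. Counts are modelled as negative binomial with
`Var = mu + phi mu^2`; `phi = 0` recovers Poisson.

## Normalization: per-channel offsets

Each factorial cell is treated as its own count channel with offset
`log(channel total) - mean(log totals)` per tissue, the same normalization
edgeR applies to the columns of a count matrix. This is essential, not
cosmetic: the chimera's penn channel carries only ~`p` of that library's
reads, so without a channel-level offset every uniformly expressed gene
would appear strongly penn-depleted in the chimera and the classifier's
false-positive rate would be near 1 instead of below the FDR target. The
channel totals absorb both library size (e.g. the higher coverage of
dehydrated-leaf libraries) and tissue composition in one step. The
simulator emits the true channel scales `(s, s, s(1-p), s p)`; the
pipeline estimates them from column totals. A per-library offset helper
(`compute_offsets`, geometric-mean centred) is provided for workflows that
normalize at the library level; in that case contrast (d) can be tested
against the composition ratio `log(p/(1-p))` via
`ModelConfig(contrast_d_offset="tissue_fraction")` instead.

## The factorial GLM and its contrasts

Per gene and tissue the four counts are fitted with the log-linear model
`log mu = offset + b0 + b_origin [penn] + b_genome [chimera] + b_int
[penn x chimera]`. With one observation per cell the full model is
saturated (fitted means equal counts). Each contrast —

- (a) `b_genome` (`Lc` vs `Lw`),
- (b) `b_genome + b_int` (`Pc` vs `Pw`),
- (c) `b_int` (the interaction; for all-positive cells the log cross-ratio
  `log((Lw Pc)/(Lc Pw))`),
- (d) `b_origin + b_int` (`Pc` vs `Lc`)

— is tested by a likelihood-ratio test of the saturated model against the
model with that contrast constrained to its null value, implemented by
reparameterizing the design so the contrast is one coefficient and fitting
the reduced model with a small batched IRLS (fixed NB dispersion,
step-halving-free Newton updates, linear predictor clipped at +/-30 so
zero cells converge to their likelihood supremum). The statistic is
compared to chi-square with 1 df. Log-fold-changes are reported from the
saturated fit; when any cell is zero a +0.5 continuity correction is
applied to all four cells for the logFC only, never for the statistic.

Dispersion cannot be estimated per gene (zero residual df), so a fixed
common `phi = 0.1` is the default — a typical bulk RNA-seq value — with an
optional cross-gene estimate (`dispersion_mode="common_estimated"`) that
equates the Pearson statistic of the additive (no-interaction) Poisson fit
to its residual degrees of freedom (one per gene).

## Classification rules

With q-values from per-contrast BH (or BY) adjustment across genes within
a tissue, at FDR alpha = 0.05:

- **L1**: significant *down*-regulation in (a), no significant
  *down*-regulation in (b), significant interaction (c). The sign matters
  in (b): a genuinely L1-concentrated gene rises in the normalized penn
  channel, and an up-regulated (b) must not veto the call.
- **L1-specific** additionally requires (d) significant with `Pc > Lc`
  (after offsets); otherwise **L1-related**.
- **L2/L3** labels mirror the rule with the alleles swapped, which the
  implementation guarantees exactly (swapping the lyc/penn roles of the
  input maps every L1 call to the corresponding L2/L3 call).
- Anything else is unclassified. No extra logFC threshold is applied
  beyond significance.

Across tissues, a gene's final label is the layer supported by at least
one tissue provided no tissue supports the opposite layer (otherwise
unclassified with a conflict flag); the grade is the strongest among
supporting tissues, specific over related. Per-tissue support shares
(supported / solely supported) are reported.

## SNP calling and allele counting

Fixed differences are called from positionally matched base-count pileups
of the pooled parental samples: depth >= 4 in both pools, majority base
frequency >= 0.9 in each pool, differing majority bases. The purity
threshold is this package's choice (the parental lines are inbred, and 0.9
tolerates ~10% alignment error); only biallelic substitutions are
considered. Consensus across external callers is supported by
intersecting VCFs keyed on (chrom, pos, alleles), with depths taken from
the first set. SNPs are assigned to genes by CDS overlap (0-based
half-open internally; conversions only at the GFF/VCF/SAM boundaries).

At each SNP site, every overlapping read contributes to exactly one of
`n_lyc`, `n_penn`, `n_other`; deletions at the site, third bases, and
bases or alignments below quality (defaults: base quality 20, mapping
quality 10) count as other. A read spanning k sites contributes k
site-level counts; counts are summed per gene, per library, and arranged
into the factorial cells using library metadata (genome type x tissue).
Genes with zero total in any plant type are flagged not expressed and
skipped by the classifier.

## %L1 specificity from chromatograms

The penn allele fraction at a polymorphic base is
`f = height_penn / (height_penn + height_lyc)` from the trace peak
heights; sites with both peaks zero, or a third-base peak above 20% of the
total, are dropped. The L1 tissue fraction `p` is the mean `f` over
genomic-DNA sites (with its standard error). The tissue-normalized
specificity is the odds share `%L1 = 100 (f/p) / (f/p + (1-f)/(1-p))`,
chosen for its fixed points — `f = p -> 50`, `f = 1 -> 100`, `f = 0 -> 0`,
and the complement symmetry `%L1(f, p) + %L1(1-f, 1-p) = 100`. **This
functional form is a reconstruction** (the equivalent of reading the
observed allele ratio against the composition baseline on the log-odds
scale); it is isolated in `normalize_l1_specificity` so an alternative
can be swapped in. Per-gene summaries average per-site %L1 values
(optionally quality-weighted) with the SE across whatever site/replicate
rows are supplied; a single site reports SE as NaN.

## Motif enrichment

Promoter windows are the 1000 bp immediately upstream of the translation
start (first CDS base; strand-aware, reverse-complemented for minus-strand
genes, truncated at contig edges). The L1 box `TAAATGYA` is scanned as an
IUPAC pattern with overlapping matches; `N` in the subject never matches;
the default is forward-strand only (the motif is defined on the promoter
strand) with a both-strands option. Presence (>= 1 hit) is tested with a
two-sided Fisher exact test, L1 genes (specific + related) against all
other examined genes by default, with per-class presence fractions always
reported.

## Synthetic data

The simulator's defaults encode the study conditions: ~1% coding
divergence between parents, L1 tissue fraction 0.2, NB dispersion 0.1,
mean 100 counts per gene per library, one library per genome x tissue (no
biological replication), up to three tissues (leaf, dehydrated leaf,
fruit). Per-label rates are scaled so every gene has the same wild-type
mean `m`: L1-specific genes have `lambda_1 = m/p, lambda_23 = 0`;
"related" genes use a 4:1 per-layer rate ratio (a continuum point between
uniform and specific); the remainder are uniform. Reads are ungapped and
error-free by default (a uniform substitution rate is available to
exercise the "other" counting path); alignments tile the CDS either
deterministically or with Poisson read counts and binomial haplotype
assignment. Chromatogram peaks carry multiplicative log-normal noise.
What the simulator does not emulate — alignment bias around SNPs, indels,
isoform structure, fragment-level correlation between nearby sites, PCR
duplicates — means passing tests demonstrate the statistical machinery,
not robustness to those artefacts on real libraries.

## Problem sizes and numerical choices

The acceptance computations use 5000 genes for null calibration, 1000 for
recovery, and a 40-gene read-level pipeline run; these sizes give
Monte-Carlo errors well inside the stated margins while keeping the whole
suite fast. IRLS runs at most 200 iterations to relative tolerance 1e-12
with a 1e-12 ridge; LRT statistics are clipped at zero; q-values come from
`statsmodels.multipletests`. All tabular output is written with `%.6g`
floats so repeated runs are byte-identical; the run manifest records the
configuration, seed, attrition funnel and SHA-256 of every table and
deliberately contains no timestamps.

## Known limitations

- The NB dispersion is common across genes by necessity of the
  unreplicated design; genuinely gene-specific overdispersion will inflate
  or deflate individual p-values.
- The %L1 normalization formula is a principled reconstruction, not a
  published derivation; Table-style values depending on it should be read
  with that caveat.
- The caller handles biallelic substitutions only; sites that are
  multi-allelic across pools, or indels, are never called.
- Motif enrichment uses presence/absence, not hit counts or positional
  weight matrices.
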