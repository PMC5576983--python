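# Methods

## The scientific question

Synonymous codon usage (SCU) differs between human functional gene
categories — most visibly between genes involved in cellular proliferation
and in differentiation. Two candidate explanations make distinct,
measurable predictions:

1. **Translational selection**: SCU co-adapts with the tRNA pool of the
   cells where a gene is expressed. This can only act on amino acids
   decoded by several tRNA isoacceptors, because for a mono-isoacceptor
   amino acid the anticodon supply cannot differ between cell types.
2. **GC-biased gene conversion (gBGC)**: meiotic recombination repairs
   heteroduplex DNA with a transmission bias toward G/C alleles, raising
   equilibrium GC wherever long-term crossover rate is high. This acts on
   *all* positions — third codon positions, introns, flanks — and predicts
   that GC3 tracks local non-coding GC and intragenic crossover rate, with
   meiotic expression entering the chain because highly expressed genes in
   meiosis suppress intragenic crossovers.

The package implements the measurements that separate the two: partitioned
(mono/multi-isoacceptor) GC3 across gene sets, PCA of gene-set RSCU,
expression-stratified crossover-rate contrasts and metagene profiles, and a
sequential variance partition of GC3.

## Statistical machinery

### RSCU and GC statistics

`RSCU_xy = C_xy / (A_x / n_x)`; Met and Trp are excluded (single-codon
amino acids carry no synonymous signal), so RSCU vectors span 59 codons and
the default GC3 universe is those same 59 codons (switchable to all 61
sense codons). Amino acids never observed yield NaN, not 0/0. Codons
containing N are skipped and tallied; an internal stop codon is an error
naming the codon position. GC fractions exclude N from the denominator.

### Genetic-map arithmetic

A map is piecewise-linear cumulative cM per chromosome. The rate of an
interval is `ΔcM / ΔMb`, which makes rates exactly additive over
partitions. Positions beyond the marker span clamp to terminal values
(real maps stop short of chromosome ends); every interval carries a
`covered_fraction` so poorly covered genes can be filtered rather than
silently mis-measured. Metagene profiles lay 1-kb windows in
transcriptional orientation around the TSS or polyA site (minus-strand
genes flipped), average across genes and report mean ± 1.96·SEM as the 95%
confidence band. Hotspot densities count hotspot midpoints per kb, so a
hotspot straddling a window edge is counted exactly once.

### Quantile binning

All "equal sample size" bins (expression deciles, terciles) are rank-based
with a deterministic tie-break on gene id, so bin sizes never differ by
more than one and reruns are reproducible even with tied FPKM values.
Realized cut points are reported alongside the labels.

### Sequential ANOVA

Predictors enter an OLS model of GC3 in a stated order (default: GCi,
GC-flank, log₁₀ crossover rate, log₁₀ meiotic expression, category with
reference level "other"). Each step is charged its increment in explained
sum of squares (Type-I); F statistics test the increment against the full
model's residual mean square by default (the current nested model's
residual is available via `f_denominator="sequential"` — the two coincide
at the last step). The design matrix is built explicitly rather than
through a formula interface because formula parsers reorder categorical
terms, which would change the sequential decomposition. Pairwise R² for the
categorical factor is its one-way eta². An all-pairwise-interactions
variant is available. Identity maintained (and tested): sequential SS +
residual SS = total SS; final cumulative R² = full-model R².

### PCA of RSCU

Centred, unscaled PCA (RSCU is already degeneracy-normalized; column
scaling is a flag). Undefined entries are imputed with the column mean and
counted. PC1's sign is fixed so it correlates positively with set GC3,
making factorial maps comparable across runs.

## The synthetic world

The generator's defaults are one stated world, chosen once:

| Parameter | Default | Why |
|---|---|---|
| chromosomes × length | 4 × 20 Mb | desk-scale genome that still holds 2,000 well-separated genes |
| `n_genes` | 2,000 | enough for decile contrasts and variance partitions |
| gene length | 5–15 kb | matches the ≥5 kb analysis filter below which map resolution fails |
| `base_rate` | 1.2 cM/Mb | human genome-average crossover rate |
| `isochore_scale` | 1 Mb | isochore-like correlation length of the landscape |
| log-rate marginal sd | 0.7 (internal) | few-fold rate variation, as in human maps |
| `gbgc_slope` | 1.2 | equilibrium GC3 spans ≈0.25–0.85, the observed human range |
| `suppression_strength` | 0.75 | bottom/top decile rate ratio ≈3.3, matching reported 3.5–5.4-fold contrasts |
| expression (µ, σ) | (1.7, 1.6) ln-FPKM | heavy-tailed FPKM with tercile cuts of a few / a few tens of FPKM |
| `replicate_sigma` | 0.3 | typical RNA-seq replicate scatter |
| gene sets | 600, 40–400 genes | GO-like redundancy and the ≥40-gene filter |
| `expression_bias_of_sets` | 1.0 | functional sets are expression-stratified, as GO sets are |
| `noise_sd_gc` | 0.02 | residual per-gene GC variation not explained by recombination |

**Landscape.** Log crossover rate is Gaussian-smoothed white noise
(circular smoothing, kernel σ = isochore_scale/2, rescaled by the exact
kernel norm to the marginal sd above), exponentiated, then rescaled so the
genome-wide mean equals `base_rate` exactly. In the degenerate limit
(smoothing scale ≥ chromosome length) the field becomes constant per
chromosome, and with one chromosome, constant at exactly the base rate.

**Suppression.** Gene *i* with meiotic-expression rank `r_i` (ascending,
1…n) multiplies its intragenic rate — the whole transcription unit, flanks
untouched — by `f_i = 1 − strength · r_i / n`. Rank, not raw FPKM, is used
because the empirical phenomenon is reported as monotone decile effects;
the linear-in-rank form is a declared stand-in, recorded in the truth table
so recovery tests compare against the realized factors, never a formula.

**Sequences.** Equilibrium GC is
`logistic(gbgc_slope · ln(rate / base_rate)) + N(0, noise_sd_gc)`, truncated
to (0, 1), with the *suppressed* intragenic rate for gene bodies and the
unsuppressed local rate for flanks (flanks sit outside the suppressed
transcription unit). The log-ratio argument makes GC = 0.5 at the
genome-mean rate and lets equilibrium GC fall below 0.5 in cold regions — a
logistic of the raw (non-negative) rate cannot. Codons are drawn per amino
acid with third-base probabilities `P(G) = P(C) = p/2`, `P(A) = P(T) =
(1−p)/2`, so expected GC3 equals the equilibrium GC for every degeneracy
class; introns and 10-kb flanks are sampled at the gene's (respectively
flank's) GC; remaining intergenic DNA sits at GC 0.40. In the
`trna_coadapted` regime each gene belongs to one of 30 co-expression
programs; multi-isoacceptor codons follow the program's random
preferred-codon table (preferred codon probability 0.75), while
mono-isoacceptor codons stay GC-driven — exactly the asymmetry the
isoacceptor test exploits.

**Expression and sets.** True per-gene meiotic means are lognormal; female
and male meiotic group means diverge by a lognormal(0.25) factor, somatic
groups are independent fresh draws (so meiotic samples, and only they,
predict GC3); replicates add lognormal noise of sd `replicate_sigma`
(mean-corrected, so zero noise reproduces group means exactly). Gene-set
membership is tilted exponentially in the standardized expression rank;
~10% of sets get proliferation-flavoured names and positive tilt, ~20%
differentiation-flavoured names and negative tilt, reproducing the
enrichment of proliferation sets among meiotically expressed genes. In the
tRNA regime, membership is additionally boosted for the set's program.

**Determinism.** One seed spawns independent per-stage streams, so the same
`(config, seed)` is byte-identical, and skipping sequence synthesis does not
change maps, expression or sets.

### What the generator does *not* emulate

Human chromosome counts and karyotype, hotspot fine structure (PRDM9
motifs), linked selection, codon-position-1/2 composition constraints,
amino-acid composition of real proteins, UTRs, alternative transcripts,
cross-protocol expression batch effects, and realistic GO term hierarchies.
A green test therefore establishes that the *operations* are correct and
that the causal chain is recoverable when present — not that any particular
biological magnitude is right.

## Numerical and policy choices

* Undefined values are NaN, dropped with counts logged, everywhere except
  PCA (column-mean imputation, counted) — mirroring analyses whose gene
  counts legitimately differ per measurement.
* Log transforms use log₁₀ with pseudocount 1 for FPKM and 0.01 cM/Mb for
  rates (suppressed intragenic rates approach zero).
* Canonical transcript = longest total CDS, ties broken by lexicographic
  transcript id; mitochondrial contigs dropped; CDS length not divisible by
  3 excludes the gene with a logged reason.
* GC-flank defaults to 10 kb each side of the transcription unit, trimmed
  to chromosome bounds and neighbouring gene spans; the width is a
  parameter because no canonical value exists.
* The bundled human tRNA repertoire table is a synthetic stand-in
  reproducing the published census summary (48 isoacceptors; mono =
  Phe/Asp/His/Cys); wobble rules are deliberately not modelled — only
  distinct-anticodon counts per amino acid matter to the test.
* Male meiotic expression defaults to the spermatocyte (meiotic-stage)
  group alone; pooling spermatocytes with spermatids is supported, as the
  appropriate choice is genuinely ambiguous.

## Known limitations

* Interval rates assume the map's piecewise-linear interpolation is exact
  between markers; `covered_fraction` flags extrapolated spans but the
  caller decides the threshold.
* The metagene CI is a normal approximation (mean ± 1.96·SEM); rate
  distributions are right-skewed, so coverage is approximate at small n.
* The suppression functional form (linear in rank) is a stand-in; only its
  monotonicity, not its shape, is supported by the phenomenon it emulates.
* Sequential (Type-I) partitions depend on predictor order by design;
  reported contributions are increments in the stated order, not unique
  variable importances.
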