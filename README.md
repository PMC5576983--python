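# gbgc-codon

Toolkit for asking *why* synonymous codon usage (SCU) varies among human
genes: is it translational selection (co-adaptation with the tRNA pool), or
GC-biased gene conversion (gBGC) — the meiotic repair bias that raises GC
content wherever recombination is high?

The package implements the complete analysis chain behind that question as
reusable, tested components, together with a synthetic-genome generator so
every stage can be verified end to end without downloading genome-scale
resources.

## What it computes

* **Codon usage** — per-gene and per-gene-set codon counts and relative
  synonymous codon usage, `RSCU_xy = C_xy / (A_x / n_x)` for codon *y* of
  amino acid *x* with degeneracy `n_x`; GC at third codon positions (GC3),
  intronic GC (GCi) and flanking-region GC (GC-flank).
* **Recombination** — piecewise-linear genetic-map arithmetic (cM/Mb of any
  interval), DSB-hotspot densities, expression-decile contrasts of
  intragenic crossover rate, and strand-aware metagene profiles of crossover
  rate around the TSS and polyadenylation site in 1-kb windows.
* **The isoacceptor selection test** — GC3 computed separately for amino
  acids decoded by one vs several tRNA isoacceptors (in the human repertoire
  the mono-isoacceptor amino acids are Phe, Asp, His, Cys). Under
  tRNA-driven selection the two cannot covary across gene sets; a high
  mono~multi R² rules the tRNA pool out as the driver of SCU.
* **Statistics** — PCA of gene-set RSCU matrices, Pearson R² tables,
  per-sample GC3 ~ expression rankings, Kruskal–Wallis / Wilcoxon group
  tests, and a sequential (Type-I) ANOVA that partitions GC3 variance over
  GCi, GC-flank, log crossover rate, log meiotic expression and the
  proliferation/differentiation category, in that order.
* **Synthetic worlds** — genomes with an isochore-scale recombination
  landscape, expression-rank-dependent intragenic crossover suppression, a
  logistic gBGC link from recombination to equilibrium GC, replicated
  expression samples and overlapping GO-like gene sets — under a `gbgc`
  regime and a `trna_coadapted` counterfactual.

## Worked example

```python
import gbgc_codon as g

cfg = g.SyntheticConfig(n_genes=300, n_chromosomes=2, chrom_length=8_000_000,
                        n_gene_sets=80, set_size_range=(40, 120), seed=1)
ds = g.simulate(cfg)          # genome, maps, expression, gene sets, truth
res = g.run_pipeline(ds)      # the full analysis
print(f"PC1 ~ set GC3 R^2:    {res.pc1_gc3_r2:.3f}")
print(f"mono ~ multi GC3 R^2: {res.isoacceptor.r_squared:.3f}")
print(f"decile fold change:   {res.decile.fold_change:.2f}")
print(res.anova.partition_[["predictor", "pairwise_r2", "model_r2", "F"]].round(3))
```

prints

```
PC1 ~ set GC3 R^2:    1.000
mono ~ multi GC3 R^2: 0.987
decile fold change:   4.16
     predictor  pairwise_r2  model_r2         F
           gci        0.989     0.989 27087.358
      gc_flank        0.786     0.989     0.010
      log_rate        0.946     0.989     1.869
log_expression        0.123     0.989     0.066
      category        0.016     0.989     0.454
```

Reading the output: gene-set RSCU collapses onto a single GC3 axis (PC1);
mono- and multi-isoacceptor GC3 move together across sets (R² = 0.99), which
tRNA co-adaptation cannot produce; intragenic crossover rate is ~4-fold
lower in the top meiotic-expression decile than in the bottom one; and
intronic GC alone explains ~99% of GC3 variance in this synthetic world,
with the functional category adding essentially nothing — the gBGC causal
chain, recovered from sequence and maps alone. The per-sample ranking
(`res.sample_ranking`) places the meiotic samples at the top, with negative
correlations between expression and GC3.

A command-line mirror exists for every stage:

```sh
gbgc-codon simulate --seed 1 --out data/
gbgc-codon run-all --data data/ --out results/
gbgc-codon features|recmap|isotest|sets|expr|model --help
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic world from a seed
and runs the complete pipeline end to end (all stages above), writing its
JSON output to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

* `src/gbgc_codon/sequence_features.py` — codon counts, RSCU, GC3/GCi/GC-flank, gene models (GFF3/BED12)
* `src/gbgc_codon/recombination.py` — genetic maps, interval rates, hotspots, decile contrasts, metagene profiles
* `src/gbgc_codon/isoacceptor.py` — tRNA repertoires, mono/multi partition, selection test
* `src/gbgc_codon/gene_sets.py` — GMT IO, size/exclusion filters, keyword categories
* `src/gbgc_codon/expression.py` — replicate averaging, sex-averaged meiotic expression, binning
* `src/gbgc_codon/stats.py` — RSCU PCA, pairwise R², sequential ANOVA, sample rankings, group tests
* `src/gbgc_codon/synthetic.py` — the two-regime synthetic-genome generator
* `docs/methods.md` — models, assumptions, parameter choices and limitations
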