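# ratiotax

Ratio-based morphometrics and multilocus sequence distances for
integrative taxonomy — the kind of evidence used to decide whether two
sets of land-snail populations are one species or two.

Closely related snail species (for example within *Monacha*) often have
indistinguishable shells but differ in the proportions of their distal
genitalia and in mitochondrial/nuclear sequence divergence. `ratiotax`
implements the two quantitative toolchains such a study needs:

1. **Multivariate Ratio Analysis (MRA)** of specimen-by-measurement
   tables. Log measurements are decomposed into an isometric *size*
   axis — the log of the geometric-mean *isosize*
   `(∏ᵥ xᵥ)^(1/p)` — and a *shape* space of centered log-ratios
   `ln xᵥ − mean(ln x)`. On top of this sit:
   - PCA in shape space, with the **PCA Ratio Spectrum**: the loadings of
     a component, read as positions of the variables along an axis; the
     pair at opposite ends forms the ratio `x_i/x_j` explaining most of
     that component (importance `|loading_i − loading_j|`), with
     percentile bootstrap confidence intervals over specimens
     (999 replicates, 68% by default);
   - the **Allometry Ratio Spectrum**: OLS slopes of each shape
     coordinate on log isosize, flagging the ratios that change most
     with size;
   - the **LDA ratio extractor** for two groups: every pair's log-ratio
     is scored by the standard distance
     `D_ij = |r̄_A − r̄_B| / s_pooled`, the best and the least-correlated
     second-best ratios are reported with per-group ranges, and the
     separation is decomposed into `D_size` (standard distance of log
     isosize) and `D_shape` (Mahalanobis distance between group shape
     means) giving **δ = D_size / (D_size + D_shape)** — δ near 0 means
     the groups differ in shape, δ near 1 means they merely differ in
     size.
2. **Multilocus sequence workflow**: aligned FASTA ingestion and
   trimming, collapsing identical sequences to haplotypes, multilocus
   concatenation with a haplotype ledger, and **Kimura two-parameter
   (K2P)** distances `d = −½ ln((1 − 2P − Q)√(1 − 2Q))` (P transitions,
   Q transversions, complete or pairwise deletion of gap/ambiguous
   columns) summarised within and between groups.

Synthetic generators (`ratiotax.simulate`) produce two-group
morphometric tables with planted size or shape effects and two-clade
alignments at configurable within/between K2P divergences, so the whole
pipeline is testable without external data.

## Worked example

```python
import ratiotax as rt

cfg = rt.MorphoSimConfig(
    n_per_group=30, variables=rt.GENITAL_VARIABLES,
    planted_pair=("V", "VA"), offset_sd_units=3.0, seed=42,
)
table = rt.simulate_measurements(cfg)     # or rt.MeasurementTable.from_csv(...)

pca = rt.ShapePCA(table).fit()
print(pca.summary())
```

```
Shape PCA (centered log-ratio space)
========================================
specimens: 60  variables: 6

component  eigenvalue  % variance
PC1           0.00874       47.1
PC2           0.00360       19.4
...
```

PC1 carries 47.1% of the shape variance, and its ratio spectrum puts V
and VA at opposite ends — `pca.ratio_spectrum(1).best_ratio()` returns
`('VA', 'V', 1.406)` — exactly the pair the generator planted. Size is
uninvolved: `pca.size_shape_correlation(1)` prints

```
Pearson correlation, log isosize vs PC1: t = -0.3114, df = 58, p-value = 0.757, cor = -0.04
```

The discriminant search confirms the planted contrast and its nature:

```python
res = rt.LDARatioExtractor(table, "A", "B").fit()
print(res.summary())
```

```
LDA ratio extractor: A (n=30) vs B (n=30)
============================================================
D_size = 0.069   D_shape = 3.705   delta = 0.018

rank    ratio      D      range A    range B    key
best    V/VA       3.40    0.71-0.88    0.87-1.21
second  F/VA       2.28    1.35-1.77    1.59-2.06

|corr(best, second log-ratio)| = 0.381
```

V/VA is recovered with standard distance 3.40 (3 pooled sd were
planted) and δ = 0.018: the separation is almost purely shape. The
per-group ranges nearly separate (they meet at 0.87–0.88), so the ratio
would be marked key-suitable only in cleaner samples.

On the sequence side, a two-clade simulation at the default 0.5%/19%
regime, summarised Table-7-style in percent:

```python
aln, pops = rt.simulate_sequences(rt.SeqSimConfig(n_per_clade=10, seed=42))
summary = rt.group_summary(aln, dict(zip(pops.specimen_id, pops.species_group)))
```

```
               comparison     range  mean
            Within cladeA   0.2-1.1   0.6
            Within cladeB   0.2-1.0   0.5
Between cladeA and cladeB 18.9-20.8  19.8
```

A shallow within-clade cloud against an ~19% between-clade gulf — the
pattern that, combined with genital ratios, supports ranking two
population systems as distinct species.

The same analyses run from the shell:

```bash
ratiotax simulate morpho --config sim.yaml --seed 42 --out table.csv
ratiotax mra --input table.csv --groups A,B --n-boot 999 --ci 0.68 --seed 42 --out out/
ratiotax hap --fasta coi.fasta --locus COI --out out/
ratiotax k2p --fasta coi.fasta --map pops.tsv --deletion complete --out out/
ratiotax ledger
```

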