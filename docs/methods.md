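# Methods

## Size/shape decomposition

All morphometric machinery works on natural-log measurements. For a
specimen with strictly positive measurements `x_1 … x_p`:

- isosize `g = (∏ x_v)^(1/p)`; `log g` is the arithmetic mean of the log
  measurements and serves as the isometric size axis;
- the shape vector is the centered log-ratio (clr)
  `z_v = ln x_v − log g`, which sums to zero and is invariant to
  uniform rescaling of a specimen.

Changing the unit of a single variable adds a constant to one log
column; it shifts clr columns by constants but leaves between-specimen
contrasts, covariances, eigenvalues, all standard distances and δ
unchanged. This unit invariance is tested.

## Shape PCA and ratio spectra

Shape PCA eigendecomposes the sample covariance (divisor `n − 1`) of the
column-centered clr matrix. The decomposition is computed inside an
explicit orthonormal basis of the zero-sum subspace (a Helmert basis),
so exactly `p − 1` components are returned and every eigenvector —
including zero-eigenvalue ones — lies in shape space with components
summing to zero. Sign convention: the largest-magnitude loading of each
eigenvector is positive. Percent variance is `100 λ_k / Σλ`.

A component's loadings, read as per-variable positions, form the PCA
Ratio Spectrum; the importance of `x_i/x_j` for the component is
`|position_i − position_j|` (translation-invariant, zero for tied
loadings). The Allometry Ratio Spectrum uses OLS slopes of each clr
column on log isosize; because the clr columns sum to zero, so do the
slopes. Both spectra accept a specimen bootstrap: specimens are resampled
with replacement, replicate eigenvectors are sign-aligned to the point
estimate by dot product, resamples on which any variable is constant
(or, for allometry, isosize is constant) are skipped and counted, and
percentile intervals are formed at the requested coverage (defaults:
999 replicates, 68%). The percentile intervals are widened, when
necessary, to include the point estimate, so `ci_lo ≤ position ≤ ci_hi`
holds for every variable by construction. Whether to bootstrap PC1 only
or further components is left to the caller: `bootstrap_ratio_spectrum(k)`
accepts any component index.

Size–shape correlation reports Pearson `r` between log isosize and a
component's scores with `t = r √(df/(1 − r²))`, `df = n − 2`, and a
two-sided p-value from the t distribution; a numerically perfect
correlation is flagged (`p = 0`, unbounded t) rather than propagated.

## LDA ratio extractor

For two groups (each ≥ 3 specimens) every unordered variable pair's
log-ratio is scored by the standard distance: absolute between-group
mean difference over the df-weighted pooled within-group standard
deviation, `√(((n_A−1)s_A² + (n_B−1)s_B²)/(n_A+n_B−2))`. Ties in the
argmax are broken lexicographically by variable-name pair. The
second-best ratio maximises D among pairs whose pooled within-group
|correlation| with the best log-ratio is below a configurable threshold
(default 0.5, "as little correlated as possible"); when no pair
qualifies the least-correlated pair is reported and flagged. With only
two variables there is a single ratio and no second entry.

The size/shape decomposition is comparison-level: `D_size` is the
standard distance of log isosize; `D_shape` is the Mahalanobis distance
between group shape means under the pooled within-group clr covariance,
evaluated by eigendecomposition with directions below `1e-12·λ_max`
dropped (the clr null direction always is); a mean difference outside
the span of the within-group covariance is rejected as undefined rather
than silently truncated. Then `δ = D_size/(D_size + D_shape)`, reported
as NaN when both components vanish (identical groups). δ belongs to the
comparison as a whole and is attached to both reported ratios; reference
analyses in the literature sometimes print ratio-specific delta values,
but no per-ratio definition consistent with the published component
values exists, so this package deliberately reports the well-defined
comparison-level quantity.

Reported ratios are oriented by the conventions of the snail
morphometrics literature when the variable names match (AW/SH, V/VA,
E/VA, F/V, DBC/V, LWmH/SD, AH/LWaH); otherwise the numerator is the
variable with the larger group-A mean log. Per-group min–max ranges of
the reported ratios are computed on the original measurement scale, and
a ratio whose group ranges do not overlap is marked suitable for an
identification key. Report tables round ranges, D and δ to 2 decimals;
JSON outputs keep full precision.

## Sequence workflow

Alignments are read from FASTA (Biopython), uppercased, and validated
for equal lengths, unique ids and the `{A,C,G,T,N,-}` alphabet
(extendable). Trimming uses 0-based half-open column intervals.
Haplotype collapsing is exact string identity — gaps and `N` are
ordinary characters, with no IUPAC subsumption; this mirrors
straightforward collapsing tools and is a documented divergence risk
from any ambiguity-aware behaviour. Labels are `"<locus> k"` in
first-occurrence order. Concatenation is in scheme order with length
additivity, produces a ledger mapping per-locus haplotype tuples to
concatenated labels (so the multilocus partition refines every
single-locus partition), and by default excludes, with a warning,
specimens missing from any locus (strict mode rejects them).

K2P distances compare only columns where both sequences have an
unambiguous base; under complete deletion (the default) every column
with a gap/`N` in any sequence is removed for all pairs, under pairwise
deletion per pair. `d = −½ ln((1−2P−Q)√(1−2Q))`; pairs with
`1−2P−Q ≤ 0` or `1−2Q ≤ 0` are flagged saturated and carry NaN, and
group summaries exclude them with a count instead of propagating
non-numbers. Rates are assumed uniform across sites (no gamma
correction), matching the plain form of the estimator. Within-group
summaries use unordered distinct pairs (groups with < 2 members are
omitted), between-group summaries all cross pairs; percentages are kept
at full precision and rounded to 1 decimal only in report tables.

## Synthetic generators

Morphometric model: `ln x_sv = μ_v + β_v s_s + δ_v(group) + ε_sv` with
`s ~ N(0, σ_size²)`, `ε ~ N(0, σ_noise²)`. Defaults (chosen once as the
study conditions the analyses target): 30 specimens/group, the 7-shell
or 6-genital variable set with baseline means at realistic ~1 cm-snail
dimensions, isometric β = 1, σ_size = 0.15, σ_noise = 0.05. A planted
shape effect adds `±off/2` to the two variables of a chosen pair in
group B with opposite signs — cancelling in isosize, hence pure shape —
with `off` expressed in pooled within-group sd units of that pair's
log-ratio (`√(2σ_noise² + ((β_i−β_j)σ_size)²)`). A separate pure-size
knob shifts all of group B's log measurements equally, in sd units of
log isosize. The generator does not emulate measurement rounding,
within-group population structure, correlated residuals or allometry
curvature; passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to those
real-data features.

Sequence model: a uniform-random ancestor evolves through clade stems of
`(d_between − d_within)/2` expected substitutions/site and star-like tip
branches of `d_within/2`, so cross-clade tip pairs span `d_between` and
within-clade pairs `d_within` in expectation. Substitutions follow the
two-parameter process with transition rate α and per-class transversion
rate β (`κ = α/β`, default 4.0, a typical mitochondrial transition
bias); per-branch changes are drawn from the exact closed-form expected
transition/transversion proportions, so branch composition is Markov and
the K2P estimator is consistent for the configured targets (defaults
0.005 within, 0.19 between over 615 positions — a shallow
intraspecific vs deep interspecific regime). A sharing knob
(`shared_haplotype_prob`, default 0) lets specimens copy an existing
clade haplotype; it is off by default because sharing biases realized
within-clade means below the target. An optional gap-injection knob
places `-` characters to exercise the deletion policies. No coalescent
genealogy, recombination, rate heterogeneity or indel evolution is
modelled.

## Numerical and reproducibility choices

- Natural logs throughout; PCA on the covariance (not correlation) of
  clr values, which are already commensurable.
- All resampling and simulation flows through `numpy.random.default_rng`
  seeded from a single integer; identical seeds give byte-identical
  outputs (JSON reports are key-sorted and timestamp-free, and each CLI
  run writes a manifest with inputs, seed, parameters and a parameter
  hash).
- Eigenvalues are clipped at zero; tiny negative round-off never leaks
  into percent-variance or Mahalanobis computations.
- Degenerate inputs are rejected with specific messages (non-positive or
  missing measurement cells with the offending cell named, constant
  isosize for allometry, < 3 specimens for PCA, < 3 per group for the
  extractor, ragged/duplicated/ill-lettered alignments, empty trim
  intervals, zero comparable sites).

## Problem sizes in the shipped checks

The test suite exercises the planted-pair recovery at 100 seeds of
30 + 30 specimens, the brute-force equivalence at 100 random tables with
up to 5 variables, the K2P engine against a column-enumeration oracle on
100 random pairs (and against R/ape's `dist.dna` on one alignment), and
generator calibration at 40 seeds of 10 + 10 sequences of 615 positions
— sizes at which the Monte-Carlo tolerances quoted in the tests are
comfortable while the whole suite runs in seconds.

## Known limitations

- The per-ratio delta printed by some reference analyses is not
  reproducible from published definitions; only the comparison-level δ
  is computed (see above).
- Haplotype collapsing is ambiguity-blind by design.
- K2P assumes uniform rates; no gamma-corrected variant is provided.
- No multi-group (> 2) discriminant analysis, tree inference, or de
  novo alignment; inputs are pre-aligned and pre-oriented.
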