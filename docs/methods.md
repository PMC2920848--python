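# Methods

This note documents the statistical model behind `gwasea`, the defaults and
why they were chosen, the numerical conventions, and the known limitations —
in particular what the synthetic-data generator does and does not emulate.

## Gene model

Transcripts are collapsed per gene symbol to the most extreme start/end over
all isoforms.  Genes whose transcripts lie on different chromosomes, or whose
collapsed span exceeds 1 Mb despite having two or more transcripts, are
excluded as annotation artefacts (the same symbol reused for distant loci);
transcripts disagreeing on strand also exclude the gene.  refFlat `txStart`
is 0-based and `txEnd` 1-based; internally coordinates are 1-based with
closed intervals, so a SNP exactly on a region boundary is assigned.  Both
conventions the field uses for "upstream" are supported: strand-aware
extension (biologically literal, the default) and strand-ignorant extension
(exact mirror symmetry; use it to reproduce symmetric-boundary analyses).
The default extension is −110 kb/+40 kb around the collapsed gene,
approximating the span of common *cis*-regulatory variation; ±50 kb is the
preset for sparser genotyped scans.

## Gene score

`p_best(g)` is the minimum association p-value over the gene's regional
SNPs — the right reducer when one or a few causal variants per gene are
expected (the reducer is pluggable for other designs).  The z-transform is
one-tailed, `z = Φ⁻¹(1−p)`, so larger z means more significant; every
downstream step is rank-based or invariant to a global monotone transform,
so this sign convention is a pure bookkeeping choice.  Ties on the minimum
are broken by genomic position, then SNP id, for determinism.  p = 0 inputs
are clamped to 1e-300 at load time (and counted), since the quantile
transform is undefined at 0.

Under a null of independent uniform SNP p-values, `p_best` for a gene with
N SNPs is Beta(1, N) — the source of the confounding this package exists to
remove, the exactness of the Sidak correction, and a property test.

## Step-wise regression correction

The raw z-scores are regressed on per-gene covariates by forward selection
(candidate with the smallest partial t-test p enters while p < 0.05) with
backward elimination (any included covariate with p > 0.10 leaves), iterated
to stability.  The entry/removal thresholds are the standard step-wise
defaults.  The inclusion statistic (t vs partial F) and candidate ordering
are not uniquely determined by the method's description; the partial t-test
with best-candidate-first ordering is used, fixed, and deterministic.

The default candidate set is five covariates: region size (kb), SNPs/kb,
LD-pruned independent SNPs/kb, recombination hotspots/kb, and LD units/kb.
Genetic distance (cM/kb) is computed but excluded by default, as it is the
one gene property that is generally not a significant confounder once the
others are in the model; the set is configurable.  Map-based covariates need
two markers inside the region; genes with fewer get a masked value, and
masked values are mean-imputed inside the regression (listwise exclusion of
the covariate is selectable).  Collinear candidates are dropped with a
warning (detected by rank deficiency of the candidate design matrix).

**Corrected score.**  `z_corrected` is the OLS residual standardised to unit
variance, and `p_corrected = 1 − Φ(z_corrected)`.  Standardisation is what
makes the "treat the corrected z as standard normal" mapping meaningful: the
raw residual of a max-statistic has standard deviation well below 1 (≈0.6 at
~17 SNPs/gene), and without rescaling the corrected p-values would pile up
near 0.5.  Note that standardisation is rank-preserving, so the enrichment
test is unaffected by it; only the nominal uniformity of `p_corrected`
depends on it.

The normal approximation is good but not perfect: the null distribution of a
max-of-N statistic is right-skewed, and a linear regression on covariates
cannot remove that shape.  On a full-scale synthetic null genome
(17,000 genes, ~17 SNPs/gene, ~10× density range) the corrected p-values are
close to uniform but retain a KS distance of ≈0.023 from the uniform; the
residual deviation shrinks with the number of *effective independent* SNPs
per gene, so real data with strong LD sit closer to uniform than an LD-free
synthetic background.  The correction removes the covariate structure
essentially completely (|r| ≤ 0.05 between corrected scores and every
covariate) and agrees with the permutation gold standard (Pearson r ≈ 0.94
against p-values computed from a 500-scan null stack).

**Fit engines.**  The one-shot public API refits the selected model through
statsmodels OLS (its coefficients and p-values are what the regression
report prints).  The selection loop, and the thousands of fits inside power
simulations, use a thin numpy least-squares routine with analytic t-tests;
the two are verified against each other in the test suite.

## Alternative corrections

* Sidak: `p = 1 − (1−p_best)^N` — exact under SNP independence (Beta(1,N)
  tail), hence conservative under LD.
* Modified Sidak: exponent `(N+1)/2`, discounting ~50% of regional SNPs as
  tightly linked.  Its implicit LD fraction is panel-dependent; the regression
  adapts to the data and is the default.
* Permutation: `p = #{null ≤ observed}/n_nulls` against a user-supplied stack
  of null score vectors (e.g. phenotype-permuted scans), floored at
  `1/n_nulls`; genes below a refinement threshold (default 1e-3) are flagged
  so the caller can supply a deeper stack.  Computing the stack requires
  genotypes and is outside this package's scope.

## Enrichment test

The cutoff is a percentile of significance over **all** scored genes
genome-wide (default 95th: the top 5% most significant corrected p-values),
computed before any set-specific pruning.  Within a set, genes assigned the
same best SNP are pruned to the single most significant gene (ties:
lexicographically smallest symbol), preventing a physically clustered locus
from being counted repeatedly.  The same pruning is applied to every sampled
null set — an asymmetry there would bias the test.  Set members are *not*
excluded from the sampling pool, and sampled sets are drawn at the observed
effective size (their own pruning may shrink them slightly; this secondary
fluctuation is accepted).  "Equal or larger" on leading-edge fractions is an
exact float comparison — fractions are small rationals, so no tolerance is
needed.

When no two scored genes share a best SNP (provable no-op pruning), the
sampling null is exactly hypergeometric: `p = P(X ≥ k)`,
`X ~ Hypergeom(N_genes, K_hits, n_set)`.  The package then uses the closed
form (labelled in the output), which is also the independent oracle the
Monte-Carlo path is tested against.  Because the hit count is discrete, the
nominal p-value is conservative (super-uniform) rather than exactly uniform
under the null — visible as a false-positive rate slightly below the nominal
α in the specificity simulations.

The rank-sum variant computes a one-tailed Mann-Whitney p (members more
significant than the rest of the genome) from precomputed global mid-ranks
via the tie-corrected normal approximation without continuity correction,
then calibrates it against the same sampled-and-pruned null.  The analytic p
serves only as an ordering statistic, so its approximation quality does not
affect the calibrated result.

Null sampling uses a dedicated generator per gene set, seeded from
`(run seed, CRC32(set id))`, so results are reproducible and adding sets to
a batch never perturbs existing ones.  Bonferroni correction multiplies the
nominal p by the number of sets in the batch (one GMT file per invocation),
capped at 1.  Sets smaller than 10 members are flagged, not refused.  With
`adaptive` (default), a Monte-Carlo null is escalated tenfold whenever the
estimate drops below 1e-4, up to 1e6 sampled sets.

## Power and specificity simulations

Each run draws a fresh null background (i.i.d. uniform SNP p-values) over a
fixed synthetic genome, picks the simulated set and its causal members
uniformly at random, places the remaining causal genes outside the set
(keeping the genome-wide causal total fixed), spikes one random regional SNP
per causal gene, recomputes scores and the step-wise correction from
scratch, and applies the leading-edge test.  Success is a nominal enrichment
p ≤ α (default 0.01); power is the success fraction over `n_runs` (default
1,000), with binomial standard error.  Per-run generators derive from
`(master seed, run index)`, so two specs sharing a seed see common random
backgrounds — the directional comparisons (power vs causal fraction, vs
total causal count, 95th vs 99th percentile cutoff) use this common-random-
numbers pairing.

The spiked statistic is X ~ noncentral χ²(1 df, NCP), matching a 1-df
additive allelic test; NCP = 10 gives ≈1.1% single-SNP power at p ≤ 5e-8 and
NCP = 2.5 gives ≈1.0% at p ≤ 1e-4 (the `power_single_snp` calibration).  The
statistic enters the background as a z-score, its square root, and hence as
`p = 1 − Φ(√X)` under the package's one-tailed z convention.  A consequence
worth knowing: a central (NCP = 0) spike maps to Uniform(0, 0.5), not
Uniform(0, 1); specificity runs therefore spike nothing at all (causal
fraction 0).  The spike *replaces* the background value at the chosen SNP.
When the causal count implied by a fraction is non-integral it is rounded to
the nearest gene.

Inside simulation runs on genomes whose extended regions are disjoint
(guaranteed by the default generator), best-SNP sharing is impossible and
the exact hypergeometric null is used; this is what keeps 1,000-run grids at
~25 ms/run.  On genomes with overlapping regions the Monte-Carlo null is
used instead.

### Simulation problem sizes and observed operating points

The study-scale configuration is 17,000 genes on 22 chromosomes, log-normal
transcript spans (median 24 kb, log-sd 1.0), gamma-distributed per-gene SNP
density (shape 3, mean 1 SNP/8 kb — a genotyped-scan-like map; an imputed
meta-analysis-like preset at 1 SNP/1.3 kb exists) with ±50 kb boundaries,
giving ~293k SNPs and ~17 SNPs per gene.  At these conditions, 1,000-run
estimates give a false-positive rate of ~0.1–0.6% at nominal α = 0.01 (the
discreteness-driven conservatism above) and detection power of roughly 35–45%
for both benchmark designs (100-gene set / 10 causal genes, and 1,000-gene
set / 30 causal genes, NCP = 10, 100 causal genes genome-wide), varying a few
points with the genome realisation.

## What the synthetic background does not emulate

The generator reproduces the structural drivers of gene-score confounding —
size and density heterogeneity, SNP-less genes, hotspot/map resources, an
LD-pruned SNP list, optional overlapping-region clusters for exercising the
pruning — but SNP p-values are independent: **LD between markers is not
modelled**.  Two consequences follow, both understood and accepted:

1. With LD, the effective number of independent draws per gene region is
   smaller than the marker count, so a real background's per-gene null
   quantiles are less extreme.  A spiked effect of fixed size therefore beats
   the genome-wide cutoff more easily in LD-structured data: power estimates
   on the LD-free background are conservative, sitting ~10 percentage points
   below what the same designs achieve on permuted genotype-backed scans.
2. For the same reason the max-of-N skew is maximal, so the corrected
   p-values' residual deviation from uniformity (KS ≈ 0.023 at these
   densities) is an upper bound on what LD-structured data show.

Null calibration of the enrichment test itself (the false-positive rate) is
unaffected — it is checked directly and holds.

## Numerical conventions

* `p ↔ z` via `scipy.special.ndtri`/`ndtr` on the complementary tail for full
  precision at small p; round-trips are accurate to <1e-10 across
  [1e-12, 1−1e-12].
* Sidak corrections via `-expm1(N·log1p(−p))`, with the N = 1 identity
  returned exactly.
* Corrected p-values are clamped into (0, 1) before quantile transforms.
* Percentiles use numpy's default linear interpolation.
* All stochastic components take explicit seeds; every derived stream uses
  `numpy.random.default_rng` with structured seed lists, never global state.

## Limitations

* Gene boundaries are contiguous physical windows; discontinuous
  regulatory-element maps and linkage-based distances are not supported.
* One score per gene per phenotype; LD-block-level scoring is not
  implemented (the reducer hook is the extension point).
* Bonferroni is the only multiplicity correction across sets (by design);
  across GMT files correction is the user's responsibility.
* The normal mapping from corrected z to p is approximate (see above); the
  enrichment machinery is rank-based and insensitive to it, but the
  tail `p_corrected` values themselves should not be over-interpreted.
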