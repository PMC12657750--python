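# Methods

## Differential expression convention

The classification layer needs, per gene and contrast, only a log2 fold
change and a p-value; the upstream test is therefore kept simple and fully
specified rather than delegated to a heavier framework:

1. genes with total count < `min_total` (default 10) are dropped;
2. **size factors** are median-of-ratios: for each sample, the median over
   everywhere-positive genes of count / (per-gene geometric mean across
   samples). If no gene is positive everywhere, factors fall back to
   total-count ratios with a warning. Factors are not rescaled afterwards,
   so two samples with counts (10, 20) and (20, 40) get factors 1/√2 and
   √2 exactly.
3. expression = log2(count / factor + pseudocount), pseudocount 1;
4. per-gene **Welch t-test** between the two groups (log2fc = mean(b) −
   mean(a)), Benjamini–Hochberg adjustment across the tested genes.
   Degenerate genes with zero variance in both groups get p = 1 when the
   means agree and the smallest positive double when they differ, so they
   sort deterministically instead of producing NaNs.
5. **volcano rule**: up ⇔ log2fc ≥ τ and p < α; down mirrored; τ =
   log2 1.5, α = 0.05 on the adjusted p by default (`use_adjusted=False`
   switches to raw p; the published main text does not state which was
   used, and both are standard).

Welch-t on log-normalized counts is defensible at n = 5 per group and
keeps the package dependency-free; because the DiPa layer consumes only
`(log2fc, p_raw, p_adj)` tables, a negative-binomial GLM backend can be
swapped in without touching anything downstream.

## DiPa geometry

The published plots do not print their region boundaries, so the package
fixes a single-threshold geometry and documents it:

* the **normal band** is |y| < τ, reusing the volcano threshold — a gene is
  fully rescued when its residual effect under treatment is below the same
  fold change used to call it deregulated;
* the **diagonal band** has half-width τ: a gene counts as partially
  rescued only if treatment moved it at least 1.5-fold back from its
  disease value (y ≤ x − τ for up-regulation);
* `nta`/`ntb` ("not treatable") covers the diagonal band *and* the region
  beyond it — genes unaffected or worsened by treatment. This reconciles
  the two informal readings of the group (unaffected vs. enhanced);
* a sign flip past the normal band gets its own `overshoot` labels rather
  than being silently counted as rescued;
* x-deregulation requires both |x| ≥ τ and significance; the y-region
  assignment is purely fold-change-based ("back in the normal range" is a
  magnitude statement), except that drug-only groups 3a/3b additionally
  require y-significance so that noise around ±τ in non-deregulated genes
  is not called a drug effect;
* boundary values belong to the more-rescued group (y = τ is 2a, not nta);
* the **extreme region** cutoff is |x| ≥ log2 17 ≈ 4.0875 (2⁴ = 16 is
  excluded by design: "at least 17-fold").

Every gene receives exactly one label; the vectorized classifier is tested
against a scalar re-implementation point by point.

## Migration

The migration universe is the intersection of the two stages' post-filter
gene sets — the only choice under which conservation (row sums = origin
group sizes, grand total = universe) is well defined. Genes outside the
intersection are listed in the report, not counted. Both stages use
identical DE thresholds.

## Morphometry

Quartiles use linear interpolation (numpy default, R type 7); the
published text states no convention and type 7 is the most common default.
"Exceeding" the fence is strict (>). Strata are the treatment × timepoint
experimental groups. Percent changes in the subsampling analysis are
100 |subsample − full| / |full| against the *per-stratum* full sample (not
a pooled baseline). Each (stratum, size) pair draws once, without
replacement, from an independent seeded stream, matching a single-draw
design while letting Monte-Carlo tests rerun the draw over many seeds. The
sd of a single value is reported as 0.

## Synthetic-data generator

The generator emulates the study frame: 3 arms (sham + vehicle, BDL +
vehicle, BDL + treated), 4 treatment-start stages, n = 5 per group, and
gene archetypes RESCUED / PARTIAL / REFRACTORY / DRUG_ONLY / NULL. Counts
are gamma-Poisson with

* per-gene baseline mean 2^U(3, 9) (≈ 8–512 counts) — spanning the range
  where both Poisson- and dispersion-dominated noise occur;
* per-gene dispersion log-uniform on (0.005, 0.1), i.e. a biological
  coefficient of variation of about 0.07–0.32 centred near 0.15, the
  conventional magnitude for genetically identical mice;
* BDL effects |log2FC| ~ U(1, 4) with random sign for the deregulated
  archetypes;
* treated mean on the log2 scale: β(1 − a) for RESCUED, β(1 − a/2) for
  PARTIAL, β for REFRACTORY, a drug-only shift γ for DRUG_ONLY, where a is
  the stage's rescue attenuation — default (1.0, 0.8, 0.5, 0.25) for
  S1→S4, a monotone schedule emulating the loss of efficacy with later
  treatment start;
* archetype fractions default to 25% rescued, 10% partial, 10% refractory,
  5% drug-only, 50% null — a deregulation burden (45%) of the order seen
  in severe-injury transcriptomes;
* library sizes log-normal (σ = 0.15) around the design's nominal 10⁶, so
  normalization is exercised.

Archetypes are allocated by largest-remainder integer counts and then
shuffled, so small simulations carry the configured composition exactly.
Diameters are two-component log-normal mixtures per stratum (base
exp(N(0, 0.35)) in relative µm units, minority "dilated" component shifted
by 1.2 natural-log units, i.e. ≈ 3.3-fold wider), the simplest model with
a heavy dilated tail.

**What the generator does not emulate:** gene–gene correlation, count
outliers, batch effects, GC/length biases, or the composition of real
kidney/liver transcriptomes. Passing tests therefore demonstrate that the
pipeline recovers the classes *its own model generates* under realistic
noise — not that any particular published gene list is reproduced (that
would require the deposited sequencing data).

One observed interaction worth knowing: when a large fraction of genes is
strongly down-regulated, those genes hit zeros and drop out of the
median-of-ratios reference, which can bias size factors of the affected
arm and push a few percent of refractory down-genes across the 2b
boundary. This is a property of reference-based normalization under
asymmetric composition, not of the classifier.

## Problem sizes

Default analyses use 2,000 genes x 60 samples; Monte-Carlo properties use
10–20 seeds at 400–1,000 genes; the subsampling-stability computation uses
one 10⁶-point stratum with subsets down to 10³ by tenths, and the default
end-to-end report scales the diameter strata to 5 x 10⁴ points with
subsets 10⁴ and 10³. These sizes were chosen so the full pipeline and its
property suites run comfortably on a single CPU while keeping all
statistical margins (binomial error bands, SE-of-mean bounds) intact.

## Known limitations

* The Welch-on-log2 test is mildly conservative at n = 5 (null rejection
  ≈ 0.042 at α = 0.05 in the calibration suite) — acceptable for the
  classification layer, which is threshold-based, but a dispersion-sharing
  NB model would gain power for low-count genes.
* Pseudocount compression shrinks |log2fc| of strongly down-regulated,
  low-baseline genes, so observed x underestimates the true displacement
  near the count floor.
* Rescue percentages compare *counts* of deregulated genes, not gene
  identity; a direction can show negative rescue when treatment introduces
  its own deregulation.
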