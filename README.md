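# dipaseq

Stage-dependent treatment-rescue analysis of bulk RNA-seq count data, with
sham-referenced Tukey-fence morphometry.

## The problem

In obstructive cholestasis (modelled by bile-duct ligation, BDL, in mice),
an ASBT inhibitor can "rescue" disease-driven gene-expression changes —
but how much it rescues depends on how late treatment starts. Quantifying
that stage dependence needs more than two volcano plots: every gene has to
be followed across *two* contrasts at once,

* x = log2(BDL + vehicle / sham + vehicle) — what the disease did,
* y = log2(BDL + treatment / sham + vehicle) — what remains under therapy,

and classified by where it falls in the (x, y) plane (the **DiPa plot**).
`dipaseq` implements that classification, the summary statistics built on
it, and a synthetic-data generator that emulates the study design (3 arms x
4 treatment-start stages x 5 mice, negative-binomial counts), so the whole
pipeline is testable without sequencing data.

## The model

With fold-change threshold τ = log2 1.5 and BH-adjusted α = 0.05, a gene
significantly deregulated by disease (volcano rule on x) is assigned to

| group | meaning | rule (x-upregulated case) |
|---|---|---|
| 1a / 1b | fully rescued | \|y\| < τ (back in the normal band) |
| 2a / 2b | partially rescued | τ ≤ y ≤ x − τ (moved ≥ τ back) |
| nta / ntb | not treatable | y > x − τ (on/beyond the diagonal band) |
| overshoot | pushed past normal to the other sign | y ≤ −τ |

Genes untouched by disease are `3a`/`3b` (drug-only responders, by y-volcano
significance) or `unchanged`. On top of the labels:

* **rescue percentage** per direction: 100 (1 − n<sub>dereg,treated</sub> /
  n<sub>dereg,vehicle</sub>);
* **extreme region**: deregulated genes with at least 17-fold disease
  response (|x| ≥ log2 17);
* **migration matrix**: cross-tabulation of labels between two
  treatment-start stages over the shared gene universe, with a conservation
  check (row sums must equal origin group sizes);
* **morphometry**: a diameter is "abnormally wide" when it exceeds the Tukey
  fence Q3 + 1.5 (Q3 − Q1) of the sham reference distribution, and the
  stability of per-stratum means/SDs is probed by fixed-size subsampling.

## Worked example

```python
import dipaseq as d

design = d.make_design(n_per_group=5)                 # 3 arms x 4 stages x 5 mice
cfg = d.SimConfig(n_genes=2000, seed=42)
counts, truth = d.simulate_counts(design, cfg)

kept = d.filter_genes(counts)
em = d.normalize_log2(kept, d.size_factors(kept))

cx = d.test_contrast(em, design, "SHAM_VEH", "BDL_VEH", stage="S1")
cy = d.test_contrast(em, design, "SHAM_VEH", "BDL_TRT", stage="S1")
_, vx = d.classify_volcano(cx)
_, vy = d.classify_volcano(cy)
up, down = d.rescue_summary(vx, vy, organ="KIDNEY", stage="S1")
print(vx.n_up, vx.n_down, down.rescue_pct)
dt = d.build_dipa_table(cx, cy)
print(dt["label"].value_counts().to_dict())
```

prints (stage S1, treatment from day 3, full rescue attenuation):

```
458 434 50.0
{'unchanged': 1004, '1a': 258, '1b': 244, 'nta': 111, 'ntb': 104,
 '2a': 86, '2b': 84, '3a': 57, '3b': 47, 'overshoot_down': 3, 'overshoot_up': 2}
```

458 genes up- and 434 down-regulated by BDL; treatment rescues 50.0% of the
down-regulated ones, and most deregulated genes land in the fully-rescued
groups 1a/1b. Repeating at stage S4 (attenuation 0.25) gives a *negative*
rescue percentage (−7.6%): late treatment leaves nearly all disease genes
deregulated and adds drug-only effects. Cross-tabulating the two stages:

```python
dt4 = d.build_dipa_table(
    d.test_contrast(em, design, "SHAM_VEH", "BDL_VEH", stage="S4"),
    d.test_contrast(em, design, "SHAM_VEH", "BDL_TRT", stage="S4"),
)
mm = d.migration_matrix(dt, dt4, "S1", "S4")
print(mm.table.loc["1a"][lambda r: r > 0].to_dict())
```

```
{'1a': 5, '2a': 136, '3a': 1, 'nta': 112, 'unchanged': 4}
```

— of the 258 genes fully rescued at S1, only 5 remain fully rescued at S4;
most become partially rescued or not treatable, the qualitative signature
of stage-dependent therapy.

The same pipeline runs from the shell:

```
dipaseq report --seed 17 --outdir out/       # simulate -> DE -> DiPa -> migrate -> morphometry
dipaseq simulate --n-genes 2000 --outdir out/
dipaseq de --counts out/counts.tsv --samples out/samples.tsv \
    --contrast BDL_VEH:SHAM_VEH --stage S1 --out out/cx.tsv
dipaseq morphometry --diameters d.tsv --reference-stratum SHAM_VEH_S1 \
    --sizes 10000,1000 --seed 17 --outdir out/
```

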