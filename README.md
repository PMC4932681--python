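# dsresist

Pharmacogenomic analysis of acquired drug resistance in isogenic cancer
cell-line pairs: high-throughput dose-response scoring, differential
drug-response statistics, exome-based copy-number calling, somatic-variant
filtering, and drug-target integration that joins the two layers.

## Who this is for

Groups that derive drug-resistant variants of a parental cell line (for
example tamoxifen-resistant breast-cancer clones), screen both against a
drug library at several doses, exome-sequence the pair, and want to know
*which drugs gained or lost activity* and *which genomic lesions sit under
the targets of those drugs*. Every stage works on flat text tables and is
usable on its own.

## The models and statistics

**Dose-response and DSS.** Per-plate raw signals are normalized to negative
(vehicle) and positive (full-kill) controls,
`inhibition = 100 (neg − signal)/(neg − pos)`, then a four-parameter
logistic curve

```
y(x) = b + (t − b) / (1 + 10^{s(m − x)}),    x = log10 concentration [M]
```

is fitted per drug × cell line by bounded least squares with multi-start
initialization. The drug sensitivity score integrates the fitted curve
above an activity threshold `Amin` (default 10%) over the tested window
`[x1, x2]`, in closed form:

```
DSS = 100 · ∫ max(y(x) − Amin, 0) dx / ((100 − Amin)(x2 − x1))
```

The differential score `dDSS = DSS(resistant) − DSS(parental)` is positive
for acquired sensitivity and negative for co-resistance; |dDSS| > 5 marks a
hit.

**Differential statistics.** Hit drugs are clustered (complete linkage;
1 − Spearman between drug profiles, Euclidean between samples) and tested
for consistency across resistant/parental pairs with the rank product
`RP = (∏ₚ rₚ)^{1/k}` — the geometric mean of a drug's per-pair ranks —
calibrated by within-pair rank permutations and corrected with
Benjamini–Hochberg FDR (q < 0.05).

**Copy number.** Capture regions < 76 bp apart are merged; per-region RPKM
and approximate coverage are computed for both samples; regions under 25×
coverage in either sample are dropped; `log2(RPKM ratio)` tracks are
segmented with circular binary segmentation (max-t arc scan, permutation
p < α); genes take segment values via an extreme rule (lowest value if any
overlapped segment ≤ −0.6, highest if any ≥ +0.5, else the median) and are
called at log2 limits −1.2 / −0.4 / +0.5 / +1.3 (homozygous deletion /
heterozygous deletion / gain / amplification).

**Variants.** The somatic statistic is a one-tailed Fisher's exact test for
alt-read enrichment in the resistant sample, followed by sequential filters
(normal depth ≥ 8, tumor depth ≥ 6, VAF ≥ 0.05, strand bias, dbSNP-style
population list, protein-altering effect classes). Variants with p < 0.05
and VAF > 30% are high confidence.

**Targets.** Ki/Kd/IC50 bioactivities integrate into one KIBA-like score
per drug-target pair (per-type medians, IC50 adjusted); a drug's *specific*
targets score below 50× its best score (if that is < 0.1) or below 3 units
otherwise. Pairs with ≥ 3 effector drugs per direction yield drug → target
tables annotated with copy-number calls and high-confidence mutations.

A synthetic-data module generates all inputs with known ground truth
(384-well plates with 5 doses over a 10,000-fold range, exome count pairs
with embedded CNV blocks, paired variant tables, bioactivity tables with
designated specific targets), so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from dsresist import synthetic as syn, dose_response as dr, differential as diff

truth, designated = syn.paired_screen_truth(
    n_drugs=8, n_sensitizing=2, n_coresistant=1,
    config=syn.ScreenConfig(noise_cv=0.02), seed=11,
)
readout, _ = syn.generate_screen(truth)
inhibition, controls = dr.normalize_plate(readout)
curves = dr.fit_screen(inhibition, amin=10.0)
ddss = dr.compute_ddss(dr.dss_matrix(curves), {"T1": ("resistant", "parental")})
hits, omitted = diff.select_hits(ddss, cutoff=5.0)
print(hits[["drug_id", "direction", "ddss"]].round(1).to_string(index=False))
```

prints

```
 drug_id    direction  ddss
drug0002 co-resistant -39.0
drug0000  sensitizing  69.9
drug0001  sensitizing  43.2
```

The two drugs made potent only in the resistant line (`drug0000`,
`drug0001`) come out with large positive dDSS — acquired sensitivity — and
the drug potent only in the parental line shows the mirror-image
co-resistance; the five drugs with identical true curves in both lines have
dDSS ≈ 0 and are omitted from hit displays.

The same stages are available from the shell:

```
dsresist fit-dss --plates plates.csv --pairs pairs.tsv --amin 10 --out out/
dsresist differential --ddss out/ddss.tsv --cutoff 5 --perms 10000 --seed 1 --out out/
dsresist cnv --targets targets.bed --counts-sample s.tsv --counts-ref r.tsv \
         --genes genes.bed --alpha 0.01 --seed 1 --out out/
dsresist somatic-filter --variants variants.tsv --out out/
dsresist targets --bioactivity bio.tsv --hits out/hits.tsv \
         --gene-calls out/gene_calls.tsv --variants out/variants_filtered.tsv --out out/
```

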