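# bindexpr

Integration of differential transcription-factor binding (ChIP-Seq) with
differential gene expression (RNA-Seq) for two-group cell-line panel
designs — the setting where one asks whether a factor's occupancy changes
between two biological subtypes (for example the GCB-like and ABC-like
subtypes of diffuse large B-cell lymphoma) and whether those binding changes
track expression changes of the nearby genes.

The package is written for computational biologists who have, per cell line,
reproducible peak calls and aligned-fragment counts, plus gene-level read
counts per RNA library, and who want a tested, reproducible implementation of
the classic count-based analysis rather than a point-and-click workflow. A
seeded synthetic-data generator stands in for raw sequencing data, so every
stage can be exercised and validated end to end without any external
download.

## What it computes

1. **Binding regions (BRs).** Per-cell-line peaks are pooled; every chain of
   overlapping or abutting peaks (zero gap in half-open coordinates) is
   merged into one BR. BRs supported by fewer than two distinct cell lines
   are discarded. Fragments are then rescored against the BRs (≥ 1 bp
   overlap) into a BR × library count matrix.

2. **NB differential testing** (binding and expression alike):
   - size factors by the median-of-ratios estimator,
     `s_j = median_i k_ij / (Π_v k_iv)^{1/m}` over features with no zeros;
   - per-group method-of-moments dispersions α with variance
     `μ + α μ²`, a fitted mean–dispersion trend `α(q) = a₀ + a₁/q`;
   - a two-sided conditioned exact test: with group sums
     `K_A, K_B` modelled as NB with moment-matched means and variances under
     the null of a common concentration,
     `p = Σ_{a+b=K_A+K_B, P(a,b) ≤ P(K_A,K_B)} P(a,b) / Σ_{a+b=K_A+K_B} P(a,b)`;
   - Benjamini–Hochberg adjustment; significance is strict FDR < 0.05.
   Fold changes are reported as group-A over group-B normalized means
   (`N/A` when the denominator is zero), and genes significant in one group
   with a minor-group mean below 5 are flagged "on/off".

3. **Regulatory-domain association.** Each gene gets a basal domain (5 kb
   upstream / 1 kb downstream of its TSS, strand-aware) extended up to 1 Mb
   per side but stopping at the nearest neighboring basal domain; a BR is
   associated with every gene whose extended domain it overlaps. Signed
   TSS-relative positions are taken from BR midpoints (upstream negative).
   Region/ontology enrichment uses the binomial upper tail
   `P(X ≥ hits)`, `X ~ Bin(n_regions, annotated genome fraction)`.

4. **Concordance.** Gene/BR pairs significant on both axes are tabulated
   into four direction quadrants; observed counts are compared with expected
   counts formed from the product of the genome-wide binding and expression
   direction marginals by a χ² goodness-of-fit statistic with 3 degrees of
   freedom.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1, default scale: 1,600 genes, ~1,260 planted binding regions,
4 + 4 cell lines):

```bash
python analysis/01_simulate.py        --seed 1 --outdir results
python analysis/02_binding_regions.py --seed 1 --outdir results
python analysis/03_differential.py    --seed 1 --outdir results
python analysis/04_associate.py       --seed 1 --outdir results
python analysis/05_integrate.py       --seed 1 --outdir results
python analysis/06_enrichment.py      --seed 1 --outdir results
```

which prints, among other things:

```
8141 peaks -> 1260 binding regions; 1200 occupied in >= 2 cell lines
binding: 438 of 1200 features differential at FDR < 0.05 (293 group-A up, 145 group-B up; 33% B-enriched)
expression: 127 of 1600 features differential at FDR < 0.05 (104 group-A up, 23 group-B up; 18% B-enriched)
1533 gene/BR pairs from 1200 BRs and 1600 genes
1533 gene/BR pairs; 310 significant in both binding and expression at FDR < 0.05
quadrant counts {'A+/A+': 219, 'A+/B+': 11, 'B+/A+': 41, 'B+/B+': 39}
concordance chi2 = 77.49 (df = 3), P = 1.06e-16
on/off genes (minor-group mean < 5): 52 expressed in group A only, 6 in group B only
A-up: 293 regions; top term T01_target (hits 178, P = 1.22e-90)
```

Reading: roughly a third of binding regions and ~8% of genes are
differential (as planted); the dominant quadrant is increased binding with
increased expression in group A, and the χ² test rejects independence of the
two axes decisively — the generator plants concordant regulation, and the
pipeline recovers it. The `results/bundle/` directory holds the differential
tables, the pair table, the quadrant/concordance summary, on/off gene list,
the clustering-ready matrix and a JSON run manifest; reruns with the same
seed are byte-identical.

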