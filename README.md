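# wdnafld

Analysis toolkit for long-term **Western-diet (WD) mouse NAFLD time-course
studies**: male mice fed a Western or standard diet (SD) and profiled every
3–6 weeks over 48 weeks by RNA-seq, whole-slide histology and MRI.  The
package implements the full computational chain for such a design and ships
a first-class synthetic-data module that emulates every input, so each
stage can be validated by recovery of planted ground truth.

## What it computes

* **Differential expression** (`wdnafld.diffexpr`) — median-of-ratios size
  factors, method-of-moments NB dispersion with trend shrinkage, and a
  per-gene negative-binomial Wald GLM over the one-factor diet×week design
  (levels SD3 … WD48).  DEGs pass |log2FC| ≥ log2(1.5) and BH-FDR ≤ 0.001
  (both configurable); the standard comparison plan runs all WD levels vs
  SD3, all SD levels vs SD3, and WD vs SD per control week.
* **Rest-and-jump genes** (`wdnafld.rjg`) — genes unaltered up to a
  cutpoint of the ordered series TS = (SD3, WD3, …, WD48) and persistently
  deregulated after it.  For every cutpoint after WD3 and before WD36 the
  series is split into before/after groups; a stringent DEG filter
  (|log2FC| ≥ log2 4, FDR ≤ 0.05) is combined with |Pearson r| ≥ 0.9
  between the gene's per-level mean expression and the binary step profile
  (a week-12 jump is `(0,0,0,1,1,1,1,1,1,1)`).
* **Profile clustering** (`wdnafld.clustering`) — log2(normalized+1)
  variance stabilization, top-1000 variance gene selection, Euclidean
  k-means on per-level means, mean-silhouette model selection, and
  hypergeometric over-representation of gene sets per cluster.
* **Cross-species overlap** (`wdnafld.xspecies`) — precision/recall of
  mouse DEG lists against human liver-disease gene lists per feeding
  period and direction, with both denominator conventions behind a flag.
* **Histology quantification** (`wdnafld.histoquant`) — pixel
  classification, 20 µm tissue-margin exclusion, marker-controlled
  watershed on the Euclidean distance transform to split touching lipid
  droplets, size (> 2.3 µm) and roundness (4πA/P²) filtering, lipogranuloma
  ("macrophage crown") detection by annulus macrophage coverage with the
  4.42 µm size rule, and per-lobular-zone (pericentral vs
  periportal/midzonal) summarization.
* **MRI T1 mapping** (`wdnafld.mrit1`) — pixel-wise variable-flip-angle
  SPGR fitting (S = M0·sin α·(1−E1)/(1−E1·cos α), E1 = e^(−TR/T1); angles
  2/5/15/20/25°, TR 7.92 ms), relative enhancement RE = ΔT1/T1pre after a
  hepatobiliary contrast agent, and ROI statistics / dynamic time courses.
* **Synthetic data** (`wdnafld.synth`) — NB counts with planted monotone /
  two-peak / step / null gene archetypes over the study design, disease
  lists with exact overlap fractions, tissue slides with elliptical
  droplets, crowns and zone masks, SPGR stacks from known T1/M0 maps, and
  worked-example validation of the study's printed diet and cohort tables.

## Worked example

```python
from wdnafld import synth, rjg
from wdnafld.design import make_design

design = make_design(replicates_per_level=5)          # SD3..WD48, 5 mice each
spec = synth.GeneSpec(n_null=1500, n_rjg_up=60, n_rjg_down=40, log2fc=3.0,
                      dispersion=0.05, rjg_jump_level="WD18",
                      baseline_mean=(100.0, 1000.0))
counts, truth = synth.simulate_counts(design, spec, seed=21)
result = rjg.scan_rjg(counts, design)                 # fold 4, FDR 0.05, |r|>=0.9
best = rjg.best_hits(result)
print(best["cutpoint"].value_counts().to_string())
print(best.head(3).to_string(index=False))
```

prints

```
cutpoint
WD18    100
  gene cutpoint direction   log2fc           fdr  correlation
G01500     WD18        up 2.894741 2.452287e-148     0.995948
G01501     WD18        up 2.997432 2.483065e-189     0.993689
G01502     WD18        up 2.926944 8.209646e-146     0.993732
```

All 100 reported genes are planted step genes (8-fold, jumping at week 18),
every one recovered at its true cutpoint: the estimated log2 fold changes
sit near the planted value 3, the step-profile correlations are ≈ 1, and no
null gene is called.  The diet/cohort worked examples are one call away:

```python
print(synth.validate_study_tables())
# ValidationReport(total_grams=904.05, total_kcal=4056.0,
#                  protein_kcal_pct=20, fat_kcal_pct=40, cohort_total=39)
```

A command-line pipeline wraps the same stages behind one YAML config:

```sh
wdnafld all --out out/ --seed 7          # simulate -> deg -> rjg/cluster/overlap -> histo -> mri
```

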