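# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Study design

The design is a one-factor layout whose levels are diet×week combinations:
WD at weeks 3, 6, 12, 18, 24, 30, 36, 42, 48 and SD controls at weeks 3,
6, 30, 36, 42, 48.  `make_design()` defaults to the reference cohort's
RNA-seq replicate numbers (3–8 mice per level, e.g. WD12 n=5); every level
must keep ≥ 2 replicates so within-group variances exist.

## Count simulation

Counts are negative binomial with the standard RNA-seq parameterization
**var = µ + φµ²** (dispersion φ; the Poisson limit is taken for
φ < 10⁻¹²).  Per-gene baseline means are drawn log-uniformly from a
configurable range (default 20–2000 normalized counts) and per-gene level
means follow one of six archetypes:

* `null` — one mean everywhere;
* `monotone_up`/`monotone_down` — log2 mean ramps **linearly in WD week**
  from week 3 to week 48, reaching ± the planted log2 fold change.  Real
  monotone clusters plateau around week 12; the linear ramp is the
  simplest monotone shape and is all the clustering and correlation tests
  require.  SD levels stay at baseline;
* `two_peak` — elevated by the planted fold at WD6 and WD36 only;
* `rjg_up`/`rjg_down` — baseline before the jump level, multiplied by
  2^(±log2fc) at the jump level and all later WD levels.  The noiseless
  level-mean profile of a step gene correlates exactly ±1 with its step
  template, which pins down the cutpoint semantics (the first "1" sits at
  the jump level).

All randomness flows from one integer seed through `numpy.random.default_rng`;
there is no global state, and fixed seeds reproduce matrices bit-for-bit.

What the generator does **not** emulate: library-size trends correlated
with condition, gene–gene correlation, GC/length biases, outlier samples,
and count–dispersion relationships beyond a single shared φ.  Passing
recovery tests therefore demonstrate correctness of the decision rules,
not robustness to every artifact of real RNA-seq data.

## Differential expression

* **Size factors** — median-of-ratios: factor_j = median over genes with
  all-positive counts of count_gj / (geometric mean of gene g).  A matrix
  without any all-positive gene is rejected with advice to filter or add a
  pseudo-count.
* **Dispersion** — per-gene method of moments on normalized counts,
  φ_raw = (pooled within-group variance − mean)/mean², blended 50/50 in
  log space with a parametric trend φ(µ) = a₀ + a₁/µ fitted across genes,
  floored at 10⁻⁸.  Genes at or below Poisson variance take the floor.
  This is a deliberately simple stand-in for shrinkage estimators: it
  reproduces the decision behaviour (measured null type-I error ≈ 0.05 at
  α = 0.05) without claiming bit-compatibility with any published tool.
* **Test** — per-gene NB GLM with log link, intercept + group indicator,
  log(size factor) offsets, fitted by vectorized Fisher scoring (25
  iterations, tolerance 10⁻⁸, coefficients clipped to ±30; degenerate
  normal equations fall back to closed-form group means).  Wald p from the
  coefficient and its observed-information SE.  Genes with zero counts in
  both groups are flagged untestable (p = 1, log2FC = 0) rather than
  dropped.  No independent filtering, LFC shrinkage, or outlier refitting.
* **Multiple testing** — Benjamini–Hochberg step-up (NaN p-values are
  propagated and excluded from m).
* **DEG calls** — |log2FC| ≥ log2(fold) and FDR ≤ threshold.  Defaults
  fold 1.5, FDR 0.001; a looser FDR (e.g. 0.01) is a config override.
* **Comparison plan** — three families against the SD week-3 reference:
  WD_t vs SD3 (9), SD_t vs SD3 (5) and WD_t vs SD_t (6; the week-3 entry
  is the same two-group test as WD3 vs SD3 and is computed once).  Per
  control week the plan annotates which WD-vs-SD3 DEGs are also SD-vs-SD3
  DEGs (ageing-driven changes).

Scale invariance: multiplying all counts by one integer factor leaves fold
estimates unchanged through the size factors; hypothesis-test decisions
can flip only for genes sitting exactly on the FDR boundary, because the
NB variance structure is not scale-free.

## Rest-and-jump genes

The series is TS = (SD3, WD3, WD6, …, WD48); later SD levels are not part
of the scan.  Admissible cutpoints default to the WD levels strictly after
WD3 and strictly before WD36 ({WD6 … WD30}), configurable.  For a cutpoint
c the "before" group merges all samples of levels preceding c (including
SD3) and the "after" group everything from c onward — the step template's
first 1 is at c, so the cutpoint level belongs to the jumped phase.  A hit
must pass |log2FC| ≥ log2(4) and FDR ≤ 0.05 on the merged two-group test
**and** |Pearson r| ≥ 0.9 between the per-level means of log2(normalized+1)
expression and the step template.  Correlation uses level means (not
replicate values) for consistency with the clustering input; the choice is
configurable.  A gene may be reported at several cutpoints; `best_hits`
reduces to the max-|r| cutpoint, ties going to the earliest.

Properties worth knowing: a log-linear monotone ramp over this series
correlates at most ≈ 0.89 with any admissible step template, so the
correlation filter alone excludes monotone genes.  Conversely, when
planted step genes carry a true fold exactly equal to the fold filter
(4-fold vs log2(4)), roughly half of them fall below the threshold by
estimation symmetry — recovery of threshold-level effects is ~30–50%, and
only effects clearly above the filter are recovered near-completely.  The
normalization itself contributes a small downward bias when many planted
genes point one way (composition bias of median-of-ratios).

## Clustering and over-representation

VST is log2(count/size factor + 1) — monotone, variance-flattening, and
adequate for Euclidean clustering; it is not a fitted mean–variance
transform.  The top-n genes (default 1000) by sample variance (ties broken
lexicographically) are clustered on their per-level means with k-means
(n_init 50, max 300 iterations, tol 10⁻⁶, seeded).  Mean silhouette width
is scanned over k ∈ {2 … 10} by default (the grid is an assumption); a
local optimum must strictly beat both neighbours, so grid endpoints never
qualify.  Because profiles are not row-centered, genes separate by both
shape and absolute level — archetype-recovery fixtures therefore use a
common baseline.  Over-representation is a plain upper-tail
hypergeometric test per gene set with BH correction across sets; sets with
fewer than three overlapping genes are flagged excluded rather than
tested.  No length-bias correction or ranked enrichment is attempted.

## Cross-species overlap

Matching is by uppercased symbol only; orthology mapping is out of scope,
which makes all overlap statistics conservative.  Two denominator
conventions circulate for precision/recall of a mouse list against a
human disease list; the default (`results_text`) defines recall =
overlap/|human| and precision = overlap/|mouse|, and `methods_text` swaps
them — the two conventions are exact transposes of each other.  The
synthetic list builder solves the integer counting problem exactly
(overlap = precision·|mouse|, |human| = overlap/recall) and rejects
targets that no integer configuration satisfies.

## Histology quantification

Pixel classification is priority-ordered channel thresholding
(lipid > macrophage > zone marker > tissue > background, default
threshold 0.5 per channel); the raw zone mask is kept alongside the
priority-resolved classes so zone membership of droplet centroids remains
well defined.  Structures closer than 20 µm to the tissue boundary are
cleared (Euclidean distance of in-tissue pixels to the nearest non-tissue
pixel).  Touching droplets are separated by watershed on the negated
Euclidean distance transform, seeded at EDT local maxima with a minimum
separation of 2.3 µm (tied to the minimum droplet diameter to suppress
plateau over-seeding); labeling is 4-connected and tie-breaks follow
scanline order, so the segmentation is deterministic.  Objects are
measured in micrometers (area, equivalent diameter 2√(A/π), perimeter,
roundness 4πA/P² clamped to ≤ 1) and kept when diameter > 2.3 µm and
roundness ≥ 0.5 — the roundness formula and cutoff are this package's
choices, validated only against synthetic truth.  Lipogranuloma
("macrophage crown") classification replaces a trained object classifier
with a transparent rule: crown coverage is the macrophage-positive
fraction of a 3 µm annulus just outside the droplet, a droplet is crowned
when coverage ≥ 0.3 and its diameter is at least 4.42 µm; all three
parameters are exposed.  Zonal summaries assign droplets by centroid
membership in the zone-marker-positive (pericentral) region — centroid
assignment, not area-weighted overlap — and report per-zone lipid area
fraction, droplet count and crowns per mm² of zone tissue.

The slide generator renders axis-aligned ellipses on a uniform tissue
rectangle with a half-plane zone split and draws crowns with the same
distance rule the classifier uses, so planted crowns have coverage 1 by
construction.  It does not emulate staining texture, intensity gradients,
out-of-focus blur, or non-elliptical droplet shapes; recovery results
bound algorithmic correctness, not stain robustness.

## Variable-flip-angle T1 mapping

The signal model is SPGR: S(α) = M0·sin α·(1−E1)/(1−E1·cos α) with
E1 = exp(−TR/T1); the default acquisition is flip angles 2/5/15/20/25° at
TR 7.92 ms.  Fitting initializes from the linearized form (S/sin α vs
S/tan α, slope = E1 → T1 = −TR/ln slope) and refines T1 and M0 jointly by
a damped, bounds-clipped Gauss–Newton iteration vectorized across pixels
(T1 ∈ [1, 10000] ms, steps limited to half the current T1, 50 iterations,
relative tolerance 10⁻¹⁰).  Pixels whose maximum signal falls below 1% of
the stack maximum or whose linearized slope leaves (0, 1) are marked
invalid rather than raising.  On noiseless stacks the round trip is exact
to well below 0.1% across T1 ∈ [100, 5000] ms; with 1%-of-peak Gaussian
noise the median T1 error at 1000 ms stays below 5%.  Simulation noise is
Gaussian, not Rician — magnitude bias correction is out of scope, and the
fits assume no B1 inhomogeneity.  Relative enhancement after a
hepatobiliary contrast agent is RE = (T1pre − T1post)/T1pre, computed
where both maps are valid; ROI statistics use valid pixels only, and
dynamic series are summarized as mean ROI signal per frame ordered by
timestamp (frame index with a warning when timestamps are missing).
Fat-fraction maps are consumed as ready-made images for ROI statistics;
no Dixon reconstruction is performed.

## Pipeline

One YAML configuration drives all stages (simulate → deg → {rjg, cluster,
overlap}; histo; mri), each writing plain-text tables plus a manifest
(config hash, seed, version) that reproduces every table byte-for-byte;
the run log carries wall-clock timings and is the only
non-reproducible file.  User-supplied `synthetic` sub-blocks replace the
default blocks wholesale, since the generator dataclasses carry their own
defaults.  Exit codes: 0 success, 2 configuration error, 3 stage failure.

## Validation sizes

The shipped checks run at sizes chosen to exercise the full design while
staying lightweight: the step-gene recovery suite uses 10,000 genes (300
planted at WD18) over the 15-level design at 5 replicates per level; null
calibration uses 2,000 genes across two 10-sample groups; clustering
recovery uses 300 genes of three archetypes; slides are ~600² px at
0.44 µm/px with 20–30 droplets; T1 validation uses small grids plus a
100×100 Monte-Carlo noise study.

## Known limitations

* The DE engine approximates shrinkage-based tools; borderline calls near
  thresholds will differ from any specific implementation.
* Overlap statistics ignore orthology and directionality subtleties
  beyond up/down lists.
* The crown rule is a fixed geometric criterion, not a learned classifier;
  its parameters were chosen for synthetic geometry and must be
  re-examined on real stains.
* Images are single-plane 2-D; whole-slide pyramids, stain deconvolution
  and inflammatory-foci counting are out of scope.
* T1 fitting assumes ideal spoiling and a uniform flip angle across the
  field of view.
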