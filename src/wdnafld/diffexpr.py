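"""Negative-binomial differential expression over a diet/time one-factor design.

The machinery mirrors the standard count-based RNA-seq workflow: per-sample
size factors by the median-of-ratios rule, a per-gene method-of-moments
dispersion estimate shrunk toward a fitted mean-dispersion trend, and a
per-gene NB generalized linear model with a log link and a single two-group
indicator, tested by a Wald statistic.  It is a documented approximation of
that workflow, not a re-implementation of any particular package: no
independent filtering, no fold-change shrinkage, no outlier refitting.

A gene is called differentially expressed when it passes both a fold-change
and an FDR threshold (defaults: fold 1.5, FDR 0.001).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign

DISPERSION_FLOOR = 1e-8
_MAX_ITER = 25
_TOL = 1e-8
_BETA_BOUND = 30.0


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix dimensions do not match the id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts must be integral")
            self.values = self.values.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(frame.to_numpy(), list(map(str, frame.index)), list(map(str, frame.columns)))

    def column_indices(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)


@dataclass
class DEResult:
    """Per-gene two-group test result (log2 fold change is group B over A)."""

    comparison: str
    table: pd.DataFrame  # gene-indexed: mean_a, mean_b, log2fc, se, p, fdr, untestable


@dataclass
class DEGSet:
    comparison: str
    up: list[str]
    down: list[str]
    lfc_log2: float
    fdr: float

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down sets must be disjoint")


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    factor_j = median over genes positive in every sample of
    count_gj / geometric_mean_g.
    """
    vals = counts.values.astype(float)
    allpos = np.all(vals > 0, axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "filter genes or add a pseudo-count before normalization"
        )
    logv = np.log(vals[allpos])
    log_ratios = logv - logv.mean(axis=1, keepdims=True)
    return np.exp(np.median(log_ratios, axis=0))


def estimate_dispersion(counts: CountMatrix, size_factors: np.ndarray, groups) -> np.ndarray:
    """Per-gene NB dispersion phi (variance = mu + phi*mu^2).

    Method-of-moments on normalized counts using the pooled within-group
    variance, blended 50/50 in log space with a fitted mean-dispersion
    trend (phi_trend = a0 + a1/mu), floored at 1e-8.  Genes whose raw
    moment estimate is non-positive (at or below Poisson) take the floor.
    """
    groups = np.asarray(groups)
    norm = counts.values / np.asarray(size_factors)[None, :]
    labels = [g for g in pd.unique(groups) if (groups == g).sum() >= 2]
    if not labels:
        raise ValueError("dispersion estimation needs >=2 replicates in at least one group")
    ss = np.zeros(norm.shape[0])
    df = 0
    for g in labels:
        cols = norm[:, groups == g]
        ss += ((cols - cols.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += cols.shape[1] - 1
    within_var = ss / df
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (within_var - mu) / mu**2
    raw = np.where(np.isfinite(raw), raw, 0.0)

    # parametric trend phi ~ a0 + a1/mu, fitted on informative genes
    fit_mask = (mu > 0) & (raw > 0)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, raw[fit_mask], rcond=None)
        a0, a1 = max(coef[0], DISPERSION_FLOOR), max(coef[1], 0.0)
    else:
        a0 = max(np.median(raw[raw > 0]), DISPERSION_FLOOR) if (raw > 0).any() else DISPERSION_FLOOR
        a1 = 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, DISPERSION_FLOOR)

    blended = np.exp(
        0.5 * np.log(np.maximum(raw, DISPERSION_FLOOR))
        + 0.5 * np.log(np.maximum(trend, DISPERSION_FLOOR))
    )
    phi = np.where(raw <= 0, DISPERSION_FLOOR, blended)
    return np.maximum(phi, DISPERSION_FLOOR)


def _fisher_scoring(y, x, offset, phi):
    """Vectorized NB GLM fit (log link, intercept + binary indicator).

    y : (G, n) counts, x : (n,) 0/1 indicator, offset : (n,) log size factors,
    phi : (G,) dispersions.  Returns (b0, b1, se1, converged).
    """
    G, n = y.shape
    phi = phi[:, None]
    eps = 1e-8
    in_b = x == 1
    mean_a = np.maximum((y[:, ~in_b] / np.exp(offset[~in_b])[None, :]).mean(axis=1), eps)
    mean_b = np.maximum((y[:, in_b] / np.exp(offset[in_b])[None, :]).mean(axis=1), eps)
    b0 = np.log(mean_a)
    b1 = np.log(mean_b) - np.log(mean_a)
    b0 = np.clip(b0, -_BETA_BOUND, _BETA_BOUND)
    b1 = np.clip(b1, -_BETA_BOUND, _BETA_BOUND)
    converged = np.zeros(G, dtype=bool)
    for _ in range(_MAX_ITER):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -_BETA_BOUND - 5, _BETA_BOUND + 5))
        w = mu / (1.0 + phi * mu)
        z = eta - offset[None, :] + (y - mu) / np.maximum(mu, eps)
        sw = w.sum(axis=1)
        swx = w[:, in_b].sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w[:, in_b] * z[:, in_b]).sum(axis=1)
        det = sw * swx - swx**2
        ok = det > eps * np.maximum(sw, 1.0) ** 2 * 1e-6
        new_b0 = np.where(ok, (swx * swz - swx * swxz) / np.where(ok, det, 1.0), b0)
        new_b1 = np.where(ok, (sw * swxz - swx * swz) / np.where(ok, det, 1.0), b1)
        new_b0 = np.clip(new_b0, -_BETA_BOUND, _BETA_BOUND)
        new_b1 = np.clip(new_b1, -_BETA_BOUND, _BETA_BOUND)
        step = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        converged |= step < _TOL
        if converged.all():
            break
    # Wald SE of the group coefficient from the final weights
    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -_BETA_BOUND - 5, _BETA_BOUND + 5))
    w = mu / (1.0 + phi * mu)
    sw = w.sum(axis=1)
    swx = w[:, in_b].sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, sw / det, np.inf))
    return b0, b1, se1, converged


def nb_wald_test(
    counts: CountMatrix,
    size_factors: np.ndarray,
    dispersion: np.ndarray,
    group_a_samples,
    group_b_samples,
    comparison: str | None = None,
) -> DEResult:
    """Two-group NB Wald test; log2fc is group B over group A.

    Genes with zero counts in every sample of both groups are flagged
    untestable and reported with p = 1, log2fc = 0.
    """
    a = list(group_a_samples)
    b = list(group_b_samples)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    ia = counts.column_indices(a)
    ib = counts.column_indices(b)
    cols = np.concatenate([ia, ib])
    y = counts.values[:, cols].astype(float)
    sf = np.asarray(size_factors, dtype=float)[cols]
    x = np.concatenate([np.zeros(len(ia)), np.ones(len(ib))])
    offset = np.log(sf)
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 0:
        phi = np.full(y.shape[0], float(phi))

    untestable = y.sum(axis=1) == 0
    b0, b1, se1, _ = _fisher_scoring(y, x, offset, phi)

    ln2 = np.log(2.0)
    log2fc = b1 / ln2
    se = se1 / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se1 > 0, b1 / se1, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    p = np.where(np.isfinite(p), p, 1.0)

    log2fc = np.where(untestable, 0.0, log2fc)
    p = np.where(untestable, 1.0, p)
    se = np.where(untestable, np.nan, se)

    norm = counts.values[:, cols] / sf[None, :]
    mean_a = norm[:, : len(ia)].mean(axis=1)
    mean_b = norm[:, len(ia):].mean(axis=1)

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "fdr": bh_adjust(p),
            "untestable": untestable,
        },
        index=pd.Index(counts.gene_ids, name="gene"),
    )
    return DEResult(comparison or "B vs A", table)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1.

    NaN entries are propagated and excluded from the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_degs(
    de_result: DEResult,
    lfc_threshold_fold: float = 1.5,
    fdr_threshold: float = 0.001,
) -> DEGSet:
    """Threshold a test result into up/down DEG lists.

    up: log2fc >= log2(fold) and fdr <= fdr_threshold; down symmetric.
    """
    if lfc_threshold_fold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    lfc = np.log2(lfc_threshold_fold)
    t = de_result.table
    testable = ~t["untestable"]
    sig = testable & (t["fdr"] <= fdr_threshold)
    up = list(t.index[sig & (t["log2fc"] >= lfc)])
    down = list(t.index[sig & (t["log2fc"] <= -lfc)])
    return DEGSet(de_result.comparison, up, down, lfc, fdr_threshold)


@dataclass
class ComparisonPlanResult:
    #: family -> comparison label -> DEGSet; families are "wd_vs_sd3",
    #: "sd_vs_sd3" and "wd_vs_sd_same_week" (the week-3 diet comparison is
    #: the same two-group test as WD3 vs SD3 and appears in both families)
    families: dict[str, dict[str, DEGSet]]
    results: dict[str, DEResult]
    #: per SD control week: WD-vs-SD3 DEGs that are also SD-vs-SD3 DEGs
    sd_overlap: dict[int, set[str]] = field(default_factory=dict)

    @property
    def n_comparisons(self) -> int:
        return sum(len(f) for f in self.families.values())

    @property
    def deg_sets(self) -> dict[str, DEGSet]:
        flat: dict[str, DEGSet] = {}
        for fam in self.families.values():
            flat.update(fam)
        return flat


def run_comparison_plan(
    counts: CountMatrix,
    design: StudyDesign,
    lfc_threshold_fold: float = 1.5,
    fdr_threshold: float = 0.001,
) -> ComparisonPlanResult:
    """Run the study's pairwise comparison families.

    Three families with SD week 3 as the reference: every WD level vs SD3,
    every later SD level vs SD3, and WD vs SD at each week with controls.
    Additionally annotates, per control week, which WD-vs-SD3 DEGs are also
    SD-vs-SD3 DEGs.
    """
    levels = design.levels
    if "SD3" not in levels:
        raise ValueError("comparison plan requires the SD3 reference level")
    sf = size_factors(counts)
    group_labels = np.array([design.level_of(s) for s in counts.sample_ids])
    phi = estimate_dispersion(counts, sf, group_labels)

    wd_weeks = sorted(int(l[2:]) for l in levels if l.startswith("WD"))
    sd_weeks = sorted(int(l[2:]) for l in levels if l.startswith("SD"))
    plan = {
        "wd_vs_sd3": [(f"WD{w} vs SD3", "SD3", f"WD{w}") for w in wd_weeks],
        "sd_vs_sd3": [(f"SD{w} vs SD3", "SD3", f"SD{w}") for w in sd_weeks if w != 3],
        "wd_vs_sd_same_week": [
            (f"WD{w} vs SD{w}", f"SD{w}", f"WD{w}")
            for w in sorted(set(wd_weeks) & set(sd_weeks))
        ],
    }

    results: dict[str, DEResult] = {}
    families: dict[str, dict[str, DEGSet]] = {}
    cache: dict[tuple[str, str], tuple[DEResult, DEGSet]] = {}
    for family, comparisons in plan.items():
        families[family] = {}
        for label, ref, alt in comparisons:
            if (ref, alt) not in cache:
                res = nb_wald_test(
                    counts, sf, phi,
                    design.samples_for_level(ref), design.samples_for_level(alt),
                    comparison=label,
                )
                cache[(ref, alt)] = (res, call_degs(res, lfc_threshold_fold, fdr_threshold))
            res, degset = cache[(ref, alt)]
            results[label] = res
            families[family][label] = degset

    deg_sets = {lbl: ds for fam in families.values() for lbl, ds in fam.items()}
    sd_overlap: dict[int, set[str]] = {}
    for w in sd_weeks:
        if w == 3 or f"WD{w} vs SD3" not in deg_sets:
            continue
        wd = deg_sets[f"WD{w} vs SD3"]
        sd = deg_sets[f"SD{w} vs SD3"]
        sd_overlap[w] = (set(wd.up) | set(wd.down)) & (set(sd.up) | set(sd.down))
    return ComparisonPlanResult(families, results, sd_overlap)
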