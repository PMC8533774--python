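"""Rest-and-jump gene (RJG) detection over the ordered condition series.

A rest-and-jump gene stays unaltered up to some cutpoint of the series
TS = (SD3, WD3, WD6, ..., WD48) and is persistently deregulated from the
cutpoint onward.  Detection scans every admissible cutpoint (by default
the WD levels strictly after WD3 and strictly before WD36): samples of
levels before the cutpoint form one group, samples at and after it the
other; a stringent two-group NB Wald test (default fold 4, FDR 0.05) is
combined with a step-profile correlation filter (default |r| >= 0.9
between the gene's per-level mean variance-stabilized expression and the
binary step profile, e.g. (0,0,0,1,1,1,1,1,1,1) for a week-12 jump).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StudyDesign
from .diffexpr import (
    CountMatrix,
    bh_adjust,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)

DEFAULT_FOLD = 4.0
DEFAULT_FDR = 0.05
DEFAULT_CORR = 0.9


@dataclass(frozen=True)
class TimeSeriesOrder:
    labels: tuple

    def __post_init__(self) -> None:
        if len(self.labels) < 4:
            raise ValueError("the series needs at least 4 levels")
        if self.labels[0] != "SD3":
            raise ValueError("the series must start with SD3")
        weeks = [int(l[2:]) for l in self.labels[1:]]
        if any(not l.startswith("WD") for l in self.labels[1:]):
            raise ValueError("all levels after SD3 must be WD levels")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("WD weeks must be strictly increasing")

    def index(self, level: str) -> int:
        return self.labels.index(level)


@dataclass(frozen=True)
class StepProfile:
    values: tuple  # 0/1 per series position
    cutpoint: str

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class RJGResult:
    ts: TimeSeriesOrder
    hits: pd.DataFrame  # gene, cutpoint, direction, log2fc, fdr, correlation
    thresholds: dict


def order_series(design: StudyDesign) -> TimeSeriesOrder:
    """SD3 followed by the WD levels in increasing week order."""
    levels = design.levels
    if "SD3" not in levels:
        raise ValueError("the series requires the SD3 reference level")
    wd = sorted((int(l[2:]) for l in levels if l.startswith("WD")))
    if len(wd) < 3:
        raise ValueError("the series requires at least 3 WD levels")
    return TimeSeriesOrder(("SD3",) + tuple(f"WD{w}" for w in wd))


def step_profile(ts: TimeSeriesOrder, cutpoint: str) -> StepProfile:
    """Binary template: zeros strictly before the cutpoint, ones from it on."""
    if cutpoint not in ts.labels:
        raise ValueError(f"cutpoint {cutpoint!r} is not in the series")
    pos = ts.index(cutpoint)
    if pos == 0:
        raise ValueError("the first series element cannot be a cutpoint (no rest phase)")
    values = tuple(0 if i < pos else 1 for i in range(len(ts.labels)))
    return StepProfile(values, cutpoint)


def profile_correlation(level_means, profile: StepProfile) -> float:
    """Pearson correlation between per-level means and the step template.

    Returns NaN when either vector is constant.
    """
    x = np.asarray(level_means, dtype=float)
    y = profile.as_array()
    if x.shape != y.shape:
        raise ValueError("level means and profile lengths differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def default_cutpoints(ts: TimeSeriesOrder) -> list[str]:
    """WD levels strictly after WD3 and strictly before WD36."""
    return [l for l in ts.labels if l.startswith("WD") and 3 < int(l[2:]) < 36]


def _level_mean_vst(counts: CountMatrix, design: StudyDesign, sf, ts) -> np.ndarray:
    """Per-level mean of log2(normalized + 1), genes x series positions."""
    norm = counts.values / np.asarray(sf)[None, :]
    vst = np.log2(norm + 1.0)
    cols = []
    for level in ts.labels:
        idx = counts.column_indices(design.samples_for_level(level))
        cols.append(vst[:, idx].mean(axis=1))
    return np.column_stack(cols)


def scan_rjg(
    counts: CountMatrix,
    design: StudyDesign,
    cutpoint_set=None,
    fold_threshold: float = DEFAULT_FOLD,
    fdr_threshold: float = DEFAULT_FDR,
    corr_threshold: float = DEFAULT_CORR,
) -> RJGResult:
    """Scan cutpoints for rest-and-jump genes.

    A gene may be reported at several cutpoints; use :func:`best_hits`
    for the max-|r| reduction.
    """
    ts = order_series(design)
    cutpoints = list(cutpoint_set) if cutpoint_set is not None else default_cutpoints(ts)
    for c in cutpoints:
        if c not in ts.labels or ts.index(c) == 0:
            raise ValueError(f"invalid cutpoint {c!r}")

    sf = size_factors(counts)
    groups = np.array([design.level_of(s) for s in counts.sample_ids])
    phi = estimate_dispersion(counts, sf, groups)
    level_means = _level_mean_vst(counts, design, sf, ts)
    lfc_min = np.log2(fold_threshold)

    rows = []
    for cut in cutpoints:
        pos = ts.index(cut)
        before = [s for l in ts.labels[:pos] for s in design.samples_for_level(l)]
        after = [s for l in ts.labels[pos:] for s in design.samples_for_level(l)]
        if len(before) < 2 or len(after) < 2:
            raise ValueError(f"cutpoint {cut}: a merged group has fewer than 2 samples")
        res = nb_wald_test(counts, sf, phi, before, after, comparison=f"{cut} jump")
        t = res.table
        fdr = bh_adjust(t["p"].to_numpy())

        prof = step_profile(ts, cut).as_array()
        pc = prof - prof.mean()
        mc = level_means - level_means.mean(axis=1, keepdims=True)
        denom = np.sqrt((mc**2).sum(axis=1)) * np.sqrt((pc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, mc @ pc / denom, np.nan)

        keep = (
            (~t["untestable"].to_numpy())
            & (np.abs(t["log2fc"].to_numpy()) >= lfc_min)
            & (fdr <= fdr_threshold)
            & (np.abs(corr) >= corr_threshold)
        )
        for i in np.flatnonzero(keep):
            lfc = t["log2fc"].iloc[i]
            rows.append(
                (
                    counts.gene_ids[i],
                    cut,
                    "up" if lfc > 0 else "down",
                    float(lfc),
                    float(fdr[i]),
                    float(corr[i]),
                )
            )
    hits = pd.DataFrame(
        rows, columns=["gene", "cutpoint", "direction", "log2fc", "fdr", "correlation"]
    )
    return RJGResult(
        ts,
        hits,
        {"fold": fold_threshold, "fdr": fdr_threshold, "corr": corr_threshold},
    )


def best_hits(result: RJGResult) -> pd.DataFrame:
    """One row per gene: maximum |correlation|, ties broken by earliest cutpoint."""
    if result.hits.empty:
        return result.hits.copy()
    order = {l: i for i, l in enumerate(result.ts.labels)}
    h = result.hits.assign(
        _abs_r=result.hits["correlation"].abs(),
        _pos=result.hits["cutpoint"].map(order),
    )
    h = h.sort_values(["gene", "_abs_r", "_pos"], ascending=[True, False, True])
    return h.drop_duplicates("gene").drop(columns=["_abs_r", "_pos"]).reset_index(drop=True)
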