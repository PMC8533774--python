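"""Negative-binomial count simulation with planted temporal archetypes.

Counts are NB(mu, phi) draws with variance mu + phi*mu^2.  Per-gene mean
profiles over the condition levels follow one of six archetypes:

* ``null`` - one mean across all levels;
* ``monotone_up`` / ``monotone_down`` - log2 mean ramps linearly in WD
  week from week 3 to week 48, reaching +-true_log2fc; SD levels stay at
  baseline;
* ``two_peak`` - elevated by 2^true_log2fc at WD6 and WD36 only;
* ``rjg_up`` / ``rjg_down`` - baseline until the jump level, then
  multiplied by 2^(+-true_log2fc) at the jump level and every later WD
  level ("rest-and-jump").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..design import StudyDesign
from ..diffexpr import CountMatrix

ARCHETYPES = ("null", "monotone_up", "monotone_down", "two_peak", "rjg_up", "rjg_down")
_WD_RAMP_SPAN = (3, 48)


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    archetype: str
    jump_level: str | None
    true_log2fc: float
    baseline_mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if (self.jump_level is not None) != (self.archetype in ("rjg_up", "rjg_down")):
            raise ValueError("jump_level is set iff the archetype is rjg_up/rjg_down")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")


@dataclass
class GeneSpec:
    """How many genes of each archetype to plant, and with what parameters."""

    n_null: int = 1000
    n_monotone_up: int = 0
    n_monotone_down: int = 0
    n_two_peak: int = 0
    n_rjg_up: int = 0
    n_rjg_down: int = 0
    log2fc: float = 2.0
    dispersion: float = 0.1
    baseline_mean: tuple[float, float] = (20.0, 2000.0)  # log-uniform range
    rjg_jump_level: str = "WD18"
    two_peak_levels: tuple[str, str] = ("WD6", "WD36")

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.baseline_mean
        if lo <= 0 or hi < lo:
            raise ValueError("baseline_mean range must be positive and ordered")


def level_mean_profile(truth: GeneTruth, levels, two_peak_levels=("WD6", "WD36")) -> np.ndarray:
    """Noiseless expected mean of one gene over the condition levels."""
    mu = np.full(len(levels), truth.baseline_mean, dtype=float)
    sign = -1.0 if truth.archetype.endswith("down") else 1.0
    for i, level in enumerate(levels):
        if not level.startswith("WD"):
            continue
        week = int(level[2:])
        if truth.archetype in ("monotone_up", "monotone_down"):
            w0, w1 = _WD_RAMP_SPAN
            frac = (week - w0) / (w1 - w0)
            mu[i] = truth.baseline_mean * 2.0 ** (sign * truth.true_log2fc * frac)
        elif truth.archetype == "two_peak" and level in two_peak_levels:
            mu[i] = truth.baseline_mean * 2.0**truth.true_log2fc
        elif truth.archetype in ("rjg_up", "rjg_down"):
            jump_week = int(truth.jump_level[2:])
            if week >= jump_week:
                mu[i] = truth.baseline_mean * 2.0 ** (sign * truth.true_log2fc)
    return mu


def nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) sample with the Poisson limit at phi -> 0."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = phi < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    design: StudyDesign, gene_spec: GeneSpec, seed: int
) -> tuple[CountMatrix, list[GeneTruth]]:
    """Simulate an NB count matrix over the design and return the truth table."""
    rng = np.random.default_rng(seed)
    levels = design.levels
    plan = [
        ("null", gene_spec.n_null),
        ("monotone_up", gene_spec.n_monotone_up),
        ("monotone_down", gene_spec.n_monotone_down),
        ("two_peak", gene_spec.n_two_peak),
        ("rjg_up", gene_spec.n_rjg_up),
        ("rjg_down", gene_spec.n_rjg_down),
    ]
    truths: list[GeneTruth] = []
    idx = 0
    lo, hi = gene_spec.baseline_mean
    for archetype, n in plan:
        if n < 0:
            raise ValueError("archetype counts must be >= 0")
        for _ in range(n):
            baseline = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            truths.append(
                GeneTruth(
                    gene_id=f"G{idx:05d}",
                    archetype=archetype,
                    jump_level=gene_spec.rjg_jump_level if archetype.startswith("rjg") else None,
                    true_log2fc=gene_spec.log2fc if archetype != "null" else 0.0,
                    baseline_mean=baseline,
                    dispersion=gene_spec.dispersion,
                )
            )
            idx += 1
    if not truths:
        raise ValueError("gene_spec plants no genes")

    mu_levels = np.vstack(
        [level_mean_profile(t, levels, gene_spec.two_peak_levels) for t in truths]
    )
    level_pos = {lv: i for i, lv in enumerate(levels)}
    sample_level = [level_pos[design.level_of(s)] for s in design.sample_ids]
    mu_samples = mu_levels[:, sample_level]
    phi = np.array([t.dispersion for t in truths])[:, None]
    values = nb_draw(rng, mu_samples, phi)
    counts = CountMatrix(values, [t.gene_id for t in truths], list(design.sample_ids))
    return counts, truths
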