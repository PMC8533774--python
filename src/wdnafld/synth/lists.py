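"""Constructed human disease gene lists with exact overlap fractions.

Stand-in for curated human liver-disease signatures: given the planted
mouse truth, lists are built so that the requested recall
(overlap / human-list size) and precision (overlap / mouse-list size)
hold exactly by counting.
"""

from __future__ import annotations

import math

import numpy as np

from .counts import GeneTruth

_UP_ARCHETYPES = ("monotone_up", "rjg_up", "two_peak")
_DOWN_ARCHETYPES = ("monotone_down", "rjg_down")


def true_deg_symbols(gene_truth: list[GeneTruth]) -> dict[str, list[str]]:
    """Planted non-null genes split by direction, symbols uppercased."""
    return {
        "up": [t.gene_id.upper() for t in gene_truth if t.archetype in _UP_ARCHETYPES],
        "down": [t.gene_id.upper() for t in gene_truth if t.archetype in _DOWN_ARCHETYPES],
    }


def _solve_sizes(n_mouse: int, target_recall: float, target_precision: float):
    n_overlap_f = target_precision * n_mouse
    n_overlap = int(round(n_overlap_f))
    if abs(n_overlap_f - n_overlap) > 1e-6:
        raise ValueError(
            f"target_precision {target_precision} is not achievable by counting "
            f"against a mouse list of {n_mouse} genes"
        )
    if target_recall == 0:
        if n_overlap != 0:
            raise ValueError("target_recall 0 requires zero overlap (precision 0)")
        return 0, n_mouse  # disjoint human list of matching size
    n_human_f = n_overlap / target_recall
    n_human = int(round(n_human_f))
    if n_overlap > 0 and (n_human == 0 or abs(n_human_f - n_human) > 1e-6):
        raise ValueError(
            f"targets recall={target_recall}, precision={target_precision} are not "
            f"jointly achievable by counting (overlap {n_overlap})"
        )
    if n_human < n_overlap or n_overlap > n_mouse:
        raise ValueError("requested overlap exceeds a list size")
    return n_overlap, max(n_human, n_overlap)


def simulate_disease_lists(
    gene_truth: list[GeneTruth],
    target_recall: float,
    target_precision: float,
    seed: int,
    diseases=("NAFLD",),
) -> tuple[dict[str, dict[str, list[str]]], dict[tuple[str, str], dict[str, int]]]:
    """Build per-disease, per-direction human lists with exact targets.

    Returns ``(lists, truth)`` where ``lists[disease][direction]`` is the
    human symbol list and ``truth[(disease, direction)]`` records
    ``n_overlap``, ``n_mouse`` and ``n_human``.
    """
    for t in (target_recall, target_precision):
        if not (0.0 <= t <= 1.0) or math.isnan(t):
            raise ValueError("targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mouse = true_deg_symbols(gene_truth)
    if not mouse["up"] and not mouse["down"] and (target_recall or target_precision):
        raise ValueError("no planted deregulated genes: only zero targets are feasible")
    lists: dict[str, dict[str, list[str]]] = {}
    truth: dict[tuple[str, str], dict[str, int]] = {}
    for disease in diseases:
        lists[disease] = {}
        for direction in ("up", "down"):
            m = mouse[direction]
            if not m:
                # no planted genes for this direction: the cell is empty
                lists[disease][direction] = []
                truth[(disease, direction)] = {"n_overlap": 0, "n_mouse": 0, "n_human": 0}
                continue
            n_overlap, n_human = _solve_sizes(len(m), target_recall, target_precision)
            shared = list(rng.choice(m, size=n_overlap, replace=False)) if n_overlap else []
            novel = [
                f"{disease.upper()}_{direction.upper()}_HS{i:04d}"
                for i in range(n_human - n_overlap)
            ]
            lists[disease][direction] = shared + novel
            truth[(disease, direction)] = {
                "n_overlap": n_overlap,
                "n_mouse": len(m),
                "n_human": n_human,
            }
    return lists, truth
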