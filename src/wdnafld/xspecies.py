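"""Cross-species disease-gene overlap: precision and recall per feeding
period, disease and direction.

Gene matching is by harmonized (uppercased) symbol only - orthology
mapping is deliberately out of scope, which makes the statistics
conservative.  Two denominator conventions exist in the field's usage:
under ``results_text`` (the default), recall = overlap / |human list| and
precision = overlap / |mouse list|; ``methods_text`` swaps the two
denominators.  Both are exposed behind a flag; swapping the convention
exactly transposes the two statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

CONVENTIONS = ("results_text", "methods_text")


@dataclass(frozen=True)
class OverlapStats:
    n_overlap: int
    n_mouse: int
    n_human: int
    precision: float
    recall: float
    convention: str


def harmonize_symbols(symbols) -> list[str]:
    """Trim, uppercase, deduplicate preserving first occurrence."""
    seen = set()
    out = []
    for s in symbols:
        u = str(s).strip().upper()
        if u and u not in seen:
            seen.add(u)
            out.append(u)
    return out


def overlap_stats(mouse_degs, human_list, convention: str = "results_text") -> OverlapStats:
    """Set overlap between a mouse DEG list and a human disease list."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    mouse = set(harmonize_symbols(mouse_degs))
    human = set(harmonize_symbols(human_list))
    n_overlap = len(mouse & human)
    over_human = n_overlap / len(human) if human else float("nan")
    over_mouse = n_overlap / len(mouse) if mouse else float("nan")
    if not human:
        warnings.warn("empty human list: the human-denominator statistic is NaN", stacklevel=2)
    if not mouse:
        warnings.warn("empty mouse list: the mouse-denominator statistic is NaN", stacklevel=2)
    if convention == "results_text":
        recall, precision = over_human, over_mouse
    else:
        recall, precision = over_mouse, over_human
    return OverlapStats(n_overlap, len(mouse), len(human), precision, recall, convention)


def overlap_timecourse(
    deg_map: dict, disease_lists: dict, convention: str = "results_text"
) -> pd.DataFrame:
    """Overlap statistics per (week, disease, direction).

    ``deg_map`` maps feeding week to ``{"up": [...], "down": [...]}`` mouse
    DEG lists (e.g. from the WD-vs-SD3 comparison family);
    ``disease_lists`` maps disease to per-direction human lists.
    """
    rows = []
    for week in sorted(deg_map):
        for disease in disease_lists:
            for direction in ("up", "down"):
                mouse = deg_map[week].get(direction)
                human = disease_lists[disease].get(direction)
                if mouse is None or human is None:
                    warnings.warn(
                        f"missing {direction!r} list for week {week}, {disease}", stacklevel=2
                    )
                    rows.append((week, disease, direction, 0, 0, 0,
                                 float("nan"), float("nan")))
                    continue
                s = overlap_stats(mouse, human, convention)
                rows.append((week, disease, direction, s.n_overlap, s.n_mouse,
                             s.n_human, s.precision, s.recall))
    return pd.DataFrame(
        rows,
        columns=["week", "disease", "direction", "n_overlap", "n_mouse",
                 "n_human", "precision", "recall"],
    )
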