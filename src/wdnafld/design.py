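"""Study design: diet (SD/WD) x feeding week x replicate sample layout.

The experimental factor has one level per (diet, week) combination, written
``"WD12"`` or ``"SD3"``.  Western-diet animals are profiled at weeks
3-48; standard-diet controls only at weeks 3, 6, 30, 36, 42 and 48.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: weeks at which any animal may be analyzed
STUDY_WEEKS = (3, 6, 12, 18, 24, 30, 36, 42, 48)
#: weeks with standard-diet controls
SD_WEEKS = (3, 6, 30, 36, 42, 48)

#: RNA-seq replicate numbers per condition in the reference cohort
RNASEQ_REPLICATES = {
    ("WD", 3): 5, ("WD", 6): 5, ("WD", 12): 5, ("WD", 18): 5, ("WD", 24): 5,
    ("WD", 30): 5, ("WD", 36): 5, ("WD", 42): 4, ("WD", 48): 8,
    ("SD", 3): 7, ("SD", 6): 5, ("SD", 30): 5, ("SD", 36): 7,
    ("SD", 42): 3, ("SD", 48): 5,
}


@dataclass(frozen=True)
class Sample:
    sample_id: str
    diet: str          # "SD" or "WD"
    week: int
    replicate: int

    @property
    def level(self) -> str:
        return f"{self.diet}{self.week}"


@dataclass
class StudyDesign:
    """Immutable sample sheet with the ordered condition levels.

    Levels are ordered SD by increasing week, then WD by increasing week
    (SD3, SD6, ..., SD48, WD3, ..., WD48).
    """

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for s in self.samples:
            if s.diet not in ("SD", "WD"):
                raise ValueError(f"unknown diet {s.diet!r}")
            if s.week not in STUDY_WEEKS:
                raise ValueError(f"week {s.week} is not on the study grid {STUDY_WEEKS}")
            if s.diet == "SD" and s.week not in SD_WEEKS:
                raise ValueError(f"no SD controls at week {s.week}; SD weeks are {SD_WEEKS}")
        for level in self.levels:
            if len(self.samples_for_level(level)) < 2:
                raise ValueError(f"level {level} has fewer than 2 replicates")

    @property
    def levels(self) -> list[str]:
        sd = sorted({s.week for s in self.samples if s.diet == "SD"})
        wd = sorted({s.week for s in self.samples if s.diet == "WD"})
        return [f"SD{w}" for w in sd] + [f"WD{w}" for w in wd]

    def samples_for_level(self, level: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.level == level]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def level_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.level
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.diet, s.week, s.replicate) for s in self.samples],
            columns=["sample_id", "diet", "week", "replicate"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDesign":
        samples = [
            Sample(str(r.sample_id), str(r.diet), int(r.week), int(r.replicate))
            for r in frame.itertuples()
        ]
        return cls(samples)


def make_design(
    wd_weeks=None,
    sd_weeks=None,
    replicates_per_level=None,
    seed: int = 0,
) -> StudyDesign:
    """Build a study design over the diet x week grid.

    Defaults mirror the reference cohort's RNA-seq column: WD at all nine
    weeks, SD at weeks 3-48 where controls exist, with the per-condition
    replicate numbers of that cohort (3-8 mice per level).

    Parameters
    ----------
    wd_weeks, sd_weeks
        Iterables of feeding weeks; must be subsets of the study grid.
    replicates_per_level
        ``None`` (reference replicate numbers, 5 where a condition is not
        in the reference table), an integer applied to every level, or a
        mapping ``{(diet, week): n}``.
    seed
        Accepted for API uniformity; the construction is deterministic.
    """
    wd_weeks = tuple(sorted(wd_weeks)) if wd_weeks is not None else STUDY_WEEKS
    sd_weeks = tuple(sorted(sd_weeks)) if sd_weeks is not None else SD_WEEKS
    for w in wd_weeks:
        if w not in STUDY_WEEKS:
            raise ValueError(f"week {w} is not on the study grid {STUDY_WEEKS}")
    for w in sd_weeks:
        if w not in SD_WEEKS:
            raise ValueError(f"week {w} is not an SD control week {SD_WEEKS}")

    def n_reps(diet: str, week: int) -> int:
        if replicates_per_level is None:
            return RNASEQ_REPLICATES.get((diet, week), 5)
        if isinstance(replicates_per_level, int):
            return replicates_per_level
        return int(replicates_per_level[(diet, week)])

    samples = []
    for diet, weeks in (("SD", sd_weeks), ("WD", wd_weeks)):
        for week in weeks:
            n = n_reps(diet, week)
            if n < 2:
                raise ValueError(f"level {diet}{week} needs >=2 replicates, got {n}")
            for r in range(1, n + 1):
                samples.append(Sample(f"{diet}{week}_r{r}", diet, week, r))
    return StudyDesign(samples)
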