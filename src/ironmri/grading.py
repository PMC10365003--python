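"""Iron-overload severity grading from organ T2*.

Lower T2* means more iron, so severity is a monotone step function of
decreasing T2*: each organ has three boundaries ``b_severe < b_moderate
< b_mild`` splitting (0, inf) into severe / moderate / mild / normal.
Boundaries live in a YAML config; the shipped defaults are conventional
literature values, not study-verified constants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError

__all__ = ["Severity", "OrganThresholds", "ThresholdConfig", "OrganGrade",
           "classify", "grade_cohort", "default_thresholds", "ORGANS"]

ORGANS = ("heart", "liver", "pancreas")

#: cohort column holding each organ's T2*
ORGAN_COLUMNS = {o: f"t2s_{o}_ms" for o in ORGANS}


class Severity(str, enum.Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def rank(self) -> int:
        """0 = normal ... 3 = severe; grows with iron burden."""
        return [Severity.NORMAL, Severity.MILD,
                Severity.MODERATE, Severity.SEVERE].index(self)


@dataclass(frozen=True)
class OrganThresholds:
    """Severity boundaries for one organ, in ms, strictly increasing."""

    b_severe: float
    b_moderate: float
    b_mild: float

    def __post_init__(self) -> None:
        if not 0 < self.b_severe < self.b_moderate < self.b_mild:
            raise InvalidInputError(
                f"boundaries must satisfy 0 < b_severe < b_moderate < b_mild, "
                f"got {(self.b_severe, self.b_moderate, self.b_mild)}"
            )


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-organ severity boundaries."""

    heart: OrganThresholds
    liver: OrganThresholds
    pancreas: OrganThresholds

    def for_organ(self, organ: str) -> OrganThresholds:
        if organ not in ORGANS:
            raise InvalidInputError(f"unknown organ {organ!r}")
        return getattr(self, organ)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        return cls(**{o: OrganThresholds(**d[o]) for o in ORGANS})

    def to_dict(self) -> dict:
        return {o: {"b_severe": t.b_severe, "b_moderate": t.b_moderate,
                    "b_mild": t.b_mild}
                for o in ORGANS for t in [self.for_organ(o)]}

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_thresholds() -> ThresholdConfig:
    """Load the shipped literature-based default boundaries."""
    text = resources.files("ironmri").joinpath(
        "data/default_thresholds.yaml").read_text()
    return ThresholdConfig.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class OrganGrade:
    organ: str
    t2star: float
    category: Severity


def classify(organ: str, t2star: float,
             config: ThresholdConfig | None = None) -> OrganGrade:
    """Grade one organ T2* value.

    A boundary value belongs to the less-severe side: e.g. exactly
    ``b_mild`` is normal.

    Raises
    ------
    InvalidInputError
        For non-positive or non-finite t2star, or an unknown organ.
    """
    if config is None:
        config = default_thresholds()
    t = config.for_organ(organ)
    t2star = float(t2star)
    if not np.isfinite(t2star) or t2star <= 0:
        raise InvalidInputError(f"t2star must be positive, got {t2star}")
    if t2star < t.b_severe:
        cat = Severity.SEVERE
    elif t2star < t.b_moderate:
        cat = Severity.MODERATE
    elif t2star < t.b_mild:
        cat = Severity.MILD
    else:
        cat = Severity.NORMAL
    return OrganGrade(organ=organ, t2star=t2star, category=cat)


def grade_cohort(cohort: pd.DataFrame,
                 config: ThresholdConfig | None = None) -> pd.DataFrame:
    """Add ``<organ>_grade`` columns to a cohort table.

    Idempotent: re-grading a graded cohort returns an identical table.
    Rows with a missing or non-positive organ T2* keep the row but get a
    missing grade for that organ.
    """
    if config is None:
        config = default_thresholds()
    out = cohort.copy()
    for organ, col in ORGAN_COLUMNS.items():
        if col not in out.columns:
            continue
        grades = []
        for v in out[col]:
            try:
                grades.append(classify(organ, v, config).category.value)
            except (InvalidInputError, TypeError):
                grades.append(pd.NA)
        out[f"{organ}_grade"] = grades
    return out
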