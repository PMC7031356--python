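"""Four-group stratification: lesion-burden median split x anthropometric obesity.

Cells are named lw-no, lw-o, hw-no, hw-o (low/high burden x non-obese/obese).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CELLS
from .datatypes import SubjectRecord

CRITERIA = ("total", "deep", "periventricular")

_CRITERION_ATTR = {
    "total": "wmh_total",
    "deep": "wmh_deep",
    "periventricular": "wmh_peri",
}

# Sex-specific waist-hip-ratio cutoffs; obesity requires a strictly larger ratio.
WHR_CUTOFF = {"male": 0.90, "female": 0.85}

BMI_CUTOFFS = (25.0, 30.0)  # healthy/overweight and overweight/obese, reporting only


def normalize_criterion(criterion: str) -> str:
    aliases = {"peri": "periventricular", "periventricular": "periventricular",
               "total": "total", "deep": "deep"}
    try:
        return aliases[criterion]
    except KeyError:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of {CRITERIA}"
        ) from None


def classify_obesity(subject: SubjectRecord) -> str:
    """'obese' iff waist/hip strictly exceeds the sex-specific cutoff."""
    if subject.sex not in WHR_CUTOFF:
        raise ValueError(f"subject {subject.subject_id}: sex is missing or invalid")
    if not subject.waist > 0:
        raise ValueError(f"subject {subject.subject_id}: waist must be positive")
    if not subject.hip > 0:
        raise ValueError(f"subject {subject.subject_id}: hip must be positive")
    return "obese" if subject.whr > WHR_CUTOFF[subject.sex] else "non-obese"


def bmi_category(bmi: float) -> str:
    """Reporting-only BMI bands; never used for stratification."""
    if bmi < BMI_CUTOFFS[0]:
        return "healthy"
    if bmi < BMI_CUTOFFS[1]:
        return "overweight"
    return "obese"


def split_by_median(volumes: Sequence[float]) -> tuple[list[str], float]:
    """Label each volume 'high' iff it strictly exceeds the cohort median.

    The median is the standard midpoint of order statistics; ties at the
    median go to 'low'.  Returns (levels, median).
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size < 2:
        raise ValueError("median split needs at least 2 subjects")
    if np.any(volumes < 0):
        raise ValueError("volumes must be >= 0")
    median = float(np.median(volumes))
    return ["high" if v > median else "low" for v in volumes], median


def assign_groups(
    subjects: Sequence[SubjectRecord],
    criterion: str,
) -> pd.DataFrame:
    """One GroupAssignment row per subject for a single lesion criterion.

    Columns: subject_id, criterion, wmh_level, obesity_level, cell.
    Empty cells raise a warning (inference rejects them later).
    """
    criterion = normalize_criterion(criterion)
    if not subjects:
        raise ValueError("no subjects to assign")
    attr = _CRITERION_ATTR[criterion]
    levels, _ = split_by_median([getattr(s, attr) for s in subjects])
    rows = []
    for subject, wmh_level in zip(subjects, levels):
        obesity = classify_obesity(subject)
        cell = ("hw" if wmh_level == "high" else "lw") + (
            "-o" if obesity == "obese" else "-no"
        )
        rows.append(
            {
                "subject_id": subject.subject_id,
                "criterion": criterion,
                "wmh_level": wmh_level,
                "obesity_level": obesity,
                "cell": cell,
            }
        )
    assignments = pd.DataFrame(rows)
    counts = assignments["cell"].value_counts()
    for cell in CELLS:
        if counts.get(cell, 0) == 0:
            warnings.warn(
                f"criterion {criterion!r}: cell {cell!r} is empty", stacklevel=2
            )
    return assignments


def assign_all_criteria(
    subjects: Sequence[SubjectRecord],
    criteria: Iterable[str] = CRITERIA,
) -> pd.DataFrame:
    """Stack assignments for several criteria into one long table."""
    frames = [assign_groups(subjects, criterion) for criterion in criteria]
    return pd.concat(frames, ignore_index=True)


def cell_counts(assignments: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-criterion cell counts as a plain nested dict (JSON-friendly)."""
    out: dict[str, dict[str, int]] = {}
    for criterion, group in assignments.groupby("criterion"):
        counts = group["cell"].value_counts()
        out[str(criterion)] = {cell: int(counts.get(cell, 0)) for cell in CELLS}
    return out
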