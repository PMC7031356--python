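"""Core record types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_REL_TOL = 1e-9


@dataclass
class SubjectRecord:
    """One participant: demographics, anthropometry and lesion volumes.

    ``whr`` is derived (waist / hip) and validated against the stored
    measurements; lesion volumes must satisfy ``total = deep + peri``.
    """

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    waist: float  # cm
    hip: float  # cm
    wmh_total: float  # mm^3
    wmh_deep: float  # mm^3
    wmh_peri: float  # mm^3
    bmi: float | None = None  # kg/m^2, reporting only

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(
                f"subject {self.subject_id}: sex must be 'male' or 'female', got {self.sex!r}"
            )
        if not self.waist > 0:
            raise ValueError(f"subject {self.subject_id}: waist must be > 0")
        if not self.hip > 0:
            raise ValueError(f"subject {self.subject_id}: hip must be > 0")
        for name in ("wmh_total", "wmh_deep", "wmh_peri"):
            if getattr(self, name) < 0:
                raise ValueError(f"subject {self.subject_id}: {name} must be >= 0")
        if not np.isclose(
            self.wmh_total, self.wmh_deep + self.wmh_peri,
            rtol=1e-6, atol=1e-6 * max(self.wmh_total, 1.0),
        ):
            raise ValueError(
                f"subject {self.subject_id}: wmh_total must equal wmh_deep + wmh_peri"
            )

    @property
    def whr(self) -> float:
        """Waist-hip ratio."""
        return self.waist / self.hip


@dataclass
class RegionTimeSeries:
    """T x R matrix of node signals for one subject.

    Rows are timepoints, columns are regions ordered by ``region_ids``.
    """

    subject_id: str
    data: np.ndarray
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T x R) array")
        if self.data.shape[0] < 3:
            raise ValueError("time series must have at least 3 timepoints")
        if not self.region_ids:
            self.region_ids = list(range(1, self.data.shape[1] + 1))
        if len(self.region_ids) != self.data.shape[1]:
            raise ValueError("region_ids length must match the number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]
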