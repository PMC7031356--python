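"""Synthetic factorial cohort generation.

Generates subject tables, region time series and toy 4-D image/label pairs
carrying a known 2x2 (lesion burden x obesity) structure, so the whole
downstream analysis can be exercised and calibrated without restricted data.

The generative model is deliberately minimal: demographics are Gaussian,
lesion volumes log-normal per burden level (with a Beta-distributed
periventricular fraction so deep + periventricular = total exactly), and
region signals are zero-mean multivariate normal with a single "effect node"
whose correlation to every other node shifts by cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import RegionTimeSeries, SubjectRecord

CELLS = ("lw-no", "lw-o", "hw-no", "hw-o")

# Default waist-hip-ratio model: mean/sd per (obesity level, sex).  Means sit
# a few SD away from the sex-specific classification cutoffs (>0.90 male,
# >0.85 female) so that the anthropometric rule recovers the true obesity
# label for essentially all subjects at default noise.
DEFAULT_WHR_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "non-obese": {"male": (0.82, 0.030), "female": (0.79, 0.025)},
    "obese": {"male": (0.96, 0.030), "female": (0.91, 0.025)},
}

# Log-mean / log-sd of total lesion volume (mm^3) per burden level.  Chosen
# so the two levels are well separated on the log scale (cohort-median split
# recovers >= 90% of true labels) while keeping the strong right skew seen
# in real volume distributions.
DEFAULT_WMH_LOGNORMAL_PARAMS: dict[str, tuple[float, float]] = {
    "low": (math.log(1150.0), 0.35),
    "high": (math.log(5200.0), 0.55),
}

DEFAULT_BMI_PARAMS: dict[str, tuple[float, float]] = {
    "non-obese": (25.5, 3.6),
    "obese": (28.5, 4.0),
}


def _as_sexed_params(
    params: Mapping,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Accept either {level: (mean, sd)} or {level: {sex: (mean, sd)}}."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for level in ("non-obese", "obese"):
        if level not in params:
            raise ValueError(f"whr_params missing obesity level {level!r}")
        entry = params[level]
        if isinstance(entry, Mapping):
            out[level] = {sex: tuple(entry[sex]) for sex in ("male", "female")}
        else:
            mean, sd = entry
            out[level] = {"male": (mean, sd), "female": (mean, sd)}
    return out


@dataclass
class CohortSpec:
    """All parameters of one synthetic cohort.

    Correlation parameters are validated eagerly: every cell's implied
    correlation matrix must be positive semi-definite or the spec is
    rejected with a diagnostic naming the offending parameter.
    """

    n_subjects: int = 48
    n_regions: int = 10
    n_timepoints: int = 200
    seed: int = 0
    age_mean: float = 55.21
    age_sd: float = 7.16
    male_fraction: float = 100.0 / 182.0
    hip_mean: float = 103.21
    hip_sd: float = 7.67
    whr_params: Mapping = field(default_factory=lambda: DEFAULT_WHR_PARAMS)
    bmi_params: Mapping = field(default_factory=lambda: DEFAULT_BMI_PARAMS)
    wmh_lognormal_params: Mapping = field(
        default_factory=lambda: DEFAULT_WMH_LOGNORMAL_PARAMS
    )
    peri_fraction_mean: float = 0.87  # ~2758.91 / 3145.21
    # High concentration keeps the deep/periventricular split tight enough
    # that the median split recovers burden labels on all three criteria.
    peri_fraction_concentration: float = 150.0
    base_correlation: float = 0.2
    background_correlation: float = 0.1
    effect_node: int = 0
    # The effect node carries the implanted correlation to this many
    # designated neighbors (the next regions, cyclically); a small set keeps
    # strong cell correlations positive semi-definite and makes the effect
    # node's centrality shift k-fold larger than any neighbor's.
    n_effect_neighbors: int = 3
    obesity_main_delta: float = 0.0
    interaction_delta: float = 0.0
    noise_sd: float = 1.0
    # Per-subject uniform shift of off-diagonal correlations, linear in the
    # covariates; makes the downstream residualization falsifiable.
    confound_age_slope: float = 0.0  # correlation units per year (centered)
    confound_sex_delta: float = 0.0  # correlation units, male = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 8:
            raise ValueError("n_subjects must be >= 8 (4 nonempty cells)")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.age_sd <= 0 or self.hip_sd <= 0:
            raise ValueError("age_sd and hip_sd must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0 (columns must not be constant)")
        if not 0 <= self.effect_node < self.n_regions:
            raise ValueError("effect_node must index a region")
        if not 1 <= self.n_effect_neighbors <= self.n_regions - 1:
            raise ValueError(
                "n_effect_neighbors must lie in [1, n_regions - 1]"
            )
        for name in ("base_correlation", "background_correlation"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        for name in ("obesity_main_delta", "interaction_delta"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if not 0.0 < self.peri_fraction_mean < 1.0:
            raise ValueError("peri_fraction_mean must lie in (0, 1)")
        self.whr_params = _as_sexed_params(self.whr_params)
        for level in ("low", "high"):
            if level not in self.wmh_lognormal_params:
                raise ValueError(f"wmh_lognormal_params missing level {level!r}")
        # Eager PSD validation of every cell's correlation matrix.
        for cell in CELLS:
            matrix = self.cell_correlation_matrix(cell)
            check_psd(
                matrix,
                context=(
                    f"correlation matrix for cell {cell!r} "
                    "(base_correlation/background_correlation/"
                    "obesity_main_delta/interaction_delta)"
                ),
            )

    def cell_effect_correlation(self, cell: str) -> float:
        """Target correlation of the effect node with every other node."""
        rho = self.base_correlation
        if cell in ("lw-o", "hw-o"):
            rho += self.obesity_main_delta
        if cell == "hw-o":
            rho += self.interaction_delta
        return rho

    def effect_neighbors(self) -> list[int]:
        """Indices of the effect node's designated neighbor set."""
        return [
            (self.effect_node + i) % self.n_regions
            for i in range(1, self.n_effect_neighbors + 1)
        ]

    def cell_correlation_matrix(self, cell: str) -> np.ndarray:
        rho = self.cell_effect_correlation(cell)
        if not -1.0 < rho < 1.0:
            raise ValueError(
                f"cell {cell!r}: implied effect-node correlation {rho:.3f} is "
                "outside (-1, 1); reduce obesity_main_delta/interaction_delta"
            )
        r = self.n_regions
        matrix = np.full((r, r), self.background_correlation)
        for j in self.effect_neighbors():
            matrix[self.effect_node, j] = rho
            matrix[j, self.effect_node] = rho
        np.fill_diagonal(matrix, 1.0)
        return matrix


def check_psd(matrix: np.ndarray, context: str = "correlation matrix",
              tol: float = 1e-10) -> None:
    """Reject matrices that are not positive semi-definite."""
    eigmin = float(np.linalg.eigvalsh(matrix).min())
    if eigmin < -tol:
        raise ValueError(
            f"{context} is not positive semi-definite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )


def exclusion_cascade(n_candidates: int, exclusions: Mapping[str, int]) -> int:
    """Apply labelled exclusion counts to a candidate pool sequentially.

    Returns the number of subjects remaining; rejects negative counts and
    cascades that exhaust the pool.
    """
    if n_candidates < 0:
        raise ValueError("n_candidates must be >= 0")
    remaining = n_candidates
    for label, count in exclusions.items():
        if count < 0:
            raise ValueError(f"exclusion {label!r}: count must be >= 0")
        if count > remaining:
            raise ValueError(
                f"exclusion {label!r}: removes {count} but only "
                f"{remaining} candidates remain"
            )
        remaining -= count
    return remaining


def _cell_sizes(n: int) -> dict[str, int]:
    """Split n into the 4 cells as evenly as n allows (deterministic)."""
    base, extra = divmod(n, 4)
    return {cell: base + (1 if i < extra else 0) for i, cell in enumerate(CELLS)}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def generate_subjects(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Draw the subject table plus the true (generative) group labels.

    Returns ``(subjects, labels)`` where ``labels`` has one row per subject
    with columns subject_id, cell, wmh_level, obesity_level.
    """
    rng = _rng(spec.seed, 1)
    n = spec.n_subjects
    sizes = _cell_sizes(n)
    cells = [cell for cell in CELLS for _ in range(sizes[cell])]

    # Exact male count, randomly placed, so the sex ratio tracks
    # male_fraction without binomial jitter.
    n_male = int(round(spec.male_fraction * n))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)

    ages = rng.normal(spec.age_mean, spec.age_sd, size=n)
    hips = np.maximum(rng.normal(spec.hip_mean, spec.hip_sd, size=n), 60.0)

    # Beta parameters for the periventricular fraction of total volume.
    conc = spec.peri_fraction_concentration
    beta_a = spec.peri_fraction_mean * conc
    beta_b = (1.0 - spec.peri_fraction_mean) * conc

    records: list[SubjectRecord] = []
    rows = []
    for i, cell in enumerate(cells):
        obesity = "obese" if cell.endswith("-o") else "non-obese"
        burden = "high" if cell.startswith("hw") else "low"
        sex = str(sexes[i])

        whr_mean, whr_sd = spec.whr_params[obesity][sex]
        whr = rng.normal(whr_mean, whr_sd)
        whr = float(np.clip(whr, 0.4, 1.4))
        waist = whr * hips[i]

        mu, sigma = spec.wmh_lognormal_params[burden]
        total = float(rng.lognormal(mu, sigma))
        peri_frac = float(rng.beta(beta_a, beta_b))
        peri = peri_frac * total
        deep = total - peri

        bmi_mean, bmi_sd = spec.bmi_params[obesity]
        bmi = float(np.clip(rng.normal(bmi_mean, bmi_sd), 14.0, 60.0))

        subject_id = f"sub-{i + 1:04d}"
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                age=float(ages[i]),
                sex=sex,
                waist=float(waist),
                hip=float(hips[i]),
                wmh_total=total,
                wmh_deep=deep,
                wmh_peri=peri,
                bmi=bmi,
            )
        )
        rows.append(
            {
                "subject_id": subject_id,
                "cell": cell,
                "wmh_level": burden,
                "obesity_level": obesity,
            }
        )
    return records, pd.DataFrame(rows)


def _correlation_factor(matrix: np.ndarray) -> np.ndarray:
    """Symmetric factor F with F @ F.T = matrix (eigendecomposition)."""
    eigval, eigvec = np.linalg.eigh(matrix)
    eigval = np.clip(eigval, 0.0, None)
    return eigvec * np.sqrt(eigval)


def generate_timeseries(
    spec: CohortSpec,
    labels: pd.DataFrame,
    subjects: Sequence[SubjectRecord] | None = None,
) -> list[RegionTimeSeries]:
    """Draw each subject's T x R series from the cell's multivariate normal.

    When ``subjects`` is given and confound slopes are nonzero, a uniform
    per-subject shift (linear in centered age and in sex) is added to all
    off-diagonal correlations so that downstream degree centrality depends
    on the covariates.
    """
    if len(labels) != spec.n_subjects:
        raise ValueError(
            f"labels has {len(labels)} rows but spec.n_subjects = {spec.n_subjects}"
        )
    use_confounds = spec.confound_age_slope != 0.0 or spec.confound_sex_delta != 0.0
    if use_confounds and subjects is None:
        raise ValueError("confound slopes require the subject records")
    by_id = {s.subject_id: s for s in subjects} if subjects is not None else {}

    rng = _rng(spec.seed, 2)
    factors: dict[str, np.ndarray] = {}
    out: list[RegionTimeSeries] = []
    region_ids = list(range(1, spec.n_regions + 1))
    for row in labels.itertuples(index=False):
        cell = row.cell
        if use_confounds:
            subject = by_id[row.subject_id]
            shift = spec.confound_age_slope * (subject.age - spec.age_mean)
            shift += spec.confound_sex_delta * (1.0 if subject.sex == "male" else 0.0)
            matrix = spec.cell_correlation_matrix(cell)
            off = ~np.eye(spec.n_regions, dtype=bool)
            matrix[off] = np.clip(matrix[off] + shift, -0.99, 0.99)
            check_psd(matrix, context=f"subject {row.subject_id} correlation matrix")
            factor = _correlation_factor(matrix)
        else:
            if cell not in factors:
                factors[cell] = _correlation_factor(spec.cell_correlation_matrix(cell))
            factor = factors[cell]
        z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
        data = spec.noise_sd * (z @ factor.T)
        out.append(
            RegionTimeSeries(
                subject_id=row.subject_id, data=data, region_ids=list(region_ids)
            )
        )
    return out


def generate_toy_image(
    series: RegionTimeSeries,
    voxels_per_region: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a region time series into a toy 4-D image + 3-D label volume.

    Each region occupies ``voxels_per_region`` voxels whose signal is the
    region signal plus independent Gaussian noise; labels run 1..R with 0
    reserved for background.
    """
    if voxels_per_region < 1:
        raise ValueError("voxels_per_region must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_t, n_r = series.data.shape
    labels = np.zeros((n_r, voxels_per_region, 1), dtype=np.int16)
    image = np.zeros((n_r, voxels_per_region, 1, n_t), dtype=float)
    rng = np.random.default_rng(seed)
    for j in range(n_r):
        labels[j, :, 0] = series.region_ids[j]
        signal = series.data[:, j]  # (T,)
        noise = (
            rng.normal(0.0, noise_sd, size=(voxels_per_region, n_t))
            if noise_sd > 0
            else 0.0
        )
        image[j, :, 0, :] = signal[None, :] + noise
    return image, labels
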