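"""Weighted connectivity graphs and covariate-adjusted degree centrality.

Pipeline per subject: Pearson correlation of region time series ->
soft-threshold ((r + 1) / 2) ** beta -> Fisher r-to-z (arctanh) -> degree
centrality as the sum of incident edge weights.  Centrality is then
residualized on age and sex across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import RegionTimeSeries

DEFAULT_BETA = 6.0

#: correlations of 1 are clipped to 1 - FISHER_EPS before arctanh
FISHER_EPS = 1e-7

_R_TOL = 1e-12


@dataclass
class ConnectivityGraph:
    """R x R symmetric matrix of nonnegative Fisher-z edge weights, zero diagonal."""

    subject_id: str
    weights: np.ndarray
    beta: float = DEFAULT_BETA
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero (self-connections excluded)")
        if not self.region_ids:
            self.region_ids = list(range(1, self.weights.shape[0] + 1))
        if len(self.region_ids) != self.weights.shape[0]:
            raise ValueError("region_ids length must match matrix size")


def correlation_matrix(ts: RegionTimeSeries) -> np.ndarray:
    """Pearson correlation between all region pairs (diagonal = 1)."""
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [ts.region_ids[i] for i in constant]
        raise ValueError(f"constant time series for region(s) {names}")
    r = np.corrcoef(data, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def soft_threshold(r, beta: float = DEFAULT_BETA):
    """Map correlation r in [-1, 1] to ((r + 1) / 2) ** beta in [0, 1]."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < -1.0 - _R_TOL) or np.any(r > 1.0 + _R_TOL):
        raise ValueError("correlation outside [-1, 1]")
    out = ((np.clip(r, -1.0, 1.0) + 1.0) / 2.0) ** beta
    return out if out.ndim else float(out)


def fisher_z(weight):
    """arctanh of a weight in [0, 1]; the w = 1 pole is clipped at 1 - 1e-7."""
    weight = np.asarray(weight, dtype=float)
    if np.any(weight < -_R_TOL) or np.any(weight > 1.0 + _R_TOL):
        raise ValueError("weight outside [0, 1]")
    out = np.arctanh(np.clip(weight, 0.0, 1.0 - FISHER_EPS))
    return out if out.ndim else float(out)


def connectivity_graph(
    ts: RegionTimeSeries, beta: float = DEFAULT_BETA
) -> ConnectivityGraph:
    """Full per-subject chain: Pearson -> soft-threshold -> Fisher z."""
    weights = fisher_z(soft_threshold(correlation_matrix(ts), beta))
    np.fill_diagonal(weights, 0.0)
    return ConnectivityGraph(
        subject_id=ts.subject_id,
        weights=weights,
        beta=beta,
        region_ids=list(ts.region_ids),
    )


def degree_centrality(graph: ConnectivityGraph) -> np.ndarray:
    """Sum of incident edge weights per node (diagonal excluded)."""
    return graph.weights.sum(axis=1)


def adjust_covariates(
    centrality: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> np.ndarray:
    """Residualize node centrality on intercept + age + sex across subjects.

    ``centrality`` is (n_subjects, n_nodes); ``sex`` is binary 0/1.  A
    covariate with no variation is dropped with a warning so a single-sex
    cohort still adjusts for age.  Residuals of an intercept model have
    column mean ~0 and are orthogonal to the retained covariates.
    """
    y = np.asarray(centrality, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects to adjust covariates")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if age.shape[0] != n or sex.shape[0] != n:
        raise ValueError("age/sex length must match the number of subjects")
    if np.any(np.isnan(age)) or np.any(np.isnan(sex)):
        raise ValueError("missing covariate values")
    columns = [np.ones(n)]
    for name, col in (("age", age), ("sex", sex)):
        if np.ptp(col) == 0:
            warnings.warn(
                f"covariate {name!r} has no variation and was dropped",
                stacklevel=2,
            )
        else:
            columns.append(col)
    design = np.column_stack(columns)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def centrality_table(
    graphs: list[ConnectivityGraph],
    age: np.ndarray,
    sex: np.ndarray,
) -> pd.DataFrame:
    """Long-format table (subject_id, region_id, raw, adjusted) for a cohort.

    Graphs must share one region set; subject order defines the covariate order.
    """
    if not graphs:
        raise ValueError("no graphs supplied")
    region_ids = graphs[0].region_ids
    for g in graphs[1:]:
        if g.region_ids != region_ids:
            raise ValueError("all graphs must share the same region ids")
    raw = np.vstack([degree_centrality(g) for g in graphs])
    adjusted = adjust_covariates(raw, age, sex)
    rows = []
    for i, g in enumerate(graphs):
        for j, region_id in enumerate(region_ids):
            rows.append(
                {
                    "subject_id": g.subject_id,
                    "region_id": region_id,
                    "raw": raw[i, j],
                    "adjusted": adjusted[i, j],
                }
            )
    return pd.DataFrame(rows)


def scale_free_fit(graph: ConnectivityGraph, n_bins: int = 10) -> float:
    """R^2 of the log-log degree-distribution fit (diagnostic only).

    Bins weighted degrees, regresses log10(frequency) on log10(mean degree)
    over nonempty bins, and returns the squared correlation.  Not used for
    beta selection.
    """
    degrees = degree_centrality(graph)
    edges = np.linspace(degrees.min(), degrees.max() + 1e-12, n_bins + 1)
    which = np.digitize(degrees, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        members = degrees[which == b]
        if members.size and members.mean() > 0:
            xs.append(np.log10(members.mean()))
            ys.append(np.log10(members.size))
    if len(xs) < 3:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)
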