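"""Per-node 2x2 factorial inference with Benjamini-Hochberg FDR.

Main effects (burden, obesity) and their interaction are tested per node
with a two-way between-subjects ANOVA (Type III sums of squares under
sum-to-zero contrasts by default; Type II by flag).  ANOVA p-values are
FDR-corrected across nodes separately per effect; pairwise post-hoc pooled
t-tests are FDR-corrected across the 6 group comparisons within a node.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CELLS

EFFECTS = ("wmh", "obesity", "interaction")

#: the 6 group comparisons, in reporting order
PAIRS = tuple(combinations(CELLS, 2))

_ZERO_VAR_TOL = 1e-12


def _cell_factors(cells: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero (+1/-1) codes for burden and obesity from cell labels."""
    cells = np.asarray(cells)
    unknown = set(cells) - set(CELLS)
    if unknown:
        raise ValueError(f"unknown cell labels: {sorted(unknown)}")
    a = np.where(np.char.startswith(cells.astype(str), "hw"), 1.0, -1.0)
    b = np.where(np.char.endswith(cells.astype(str), "-o"), 1.0, -1.0)
    return a, b


def _rss(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of y under OLS on design."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return (resid * resid).sum(axis=0)


def two_way_anova(
    values: np.ndarray,
    cells: Sequence[str],
    ss_type: int = 3,
) -> pd.DataFrame:
    """F and p for both main effects and the interaction, per node.

    ``values`` is (n_subjects,) or (n_subjects, n_nodes).  Every effect has
    numerator df 1; denominator df is N - 4.  Unbalanced designs use Type
    III sums of squares with sum-to-zero contrasts (``ss_type=2`` selects
    Type II); the two agree when the design is balanced.
    """
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    y = np.asarray(values, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n = y.shape[0]
    if len(cells) != n:
        raise ValueError("cells length must match the number of subjects")
    if n < 8:
        raise ValueError("need at least 8 subjects (2 per cell)")
    a, b = _cell_factors(cells)  # also rejects unknown labels
    counts = pd.Series(cells).value_counts()
    empty = [c for c in CELLS if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"empty cell(s): {empty}")

    ones = np.ones(n)
    full = np.column_stack([ones, a, b, a * b])
    rss_full = _rss(full, y)
    df_denom = n - 4

    if ss_type == 3:
        reduced = {
            "wmh": np.column_stack([ones, b, a * b]),
            "obesity": np.column_stack([ones, a, a * b]),
            "interaction": np.column_stack([ones, a, b]),
        }
        ss = {k: _rss(x, y) - rss_full for k, x in reduced.items()}
    else:  # Type II: main effects adjusted for each other, ignoring interaction
        main = np.column_stack([ones, a, b])
        rss_main = _rss(main, y)
        ss = {
            "wmh": _rss(np.column_stack([ones, b]), y) - rss_main,
            "obesity": _rss(np.column_stack([ones, a]), y) - rss_main,
            "interaction": rss_main - rss_full,
        }

    mse = rss_full / df_denom
    rows = []
    zero_var = mse <= _ZERO_VAR_TOL
    if np.any(zero_var):
        warnings.warn("zero residual variance; p reported as 0", stacklevel=2)
    for node in range(y.shape[1]):
        for effect in EFFECTS:
            ss_val = max(float(ss[effect][node]), 0.0)
            if zero_var[node]:
                # no residual noise: any nonzero effect SS is infinitely
                # significant, a fully degenerate node is not significant
                if ss_val > _ZERO_VAR_TOL:
                    f_val, p_val = np.inf, 0.0
                else:
                    f_val, p_val = 0.0, 1.0
            else:
                f_val = ss_val / float(mse[node])
                p_val = float(stats.f.sf(f_val, 1, df_denom))
            rows.append(
                {
                    "node": node,
                    "effect": effect,
                    "F": f_val,
                    "df1": 1,
                    "df2": df_denom,
                    "p": p_val,
                }
            )
    return pd.DataFrame(rows)


def fdr_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def posthoc_pairwise(
    values: np.ndarray,
    cells: Sequence[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-tests for all 6 cell pairs on one node's values.

    Pooled-variance Student's t by default (df = n1 + n2 - 2); Welch by
    flag.  T > 0 when the first-listed group's mean is larger.  q-values
    are BH-corrected across the pairs actually tested; pairs with a group
    of size < 2 are skipped with a warning.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("posthoc_pairwise works on a single node's values")
    cells = np.asarray(cells)
    if cells.shape[0] != y.shape[0]:
        raise ValueError("cells length must match values")
    groups = {c: y[cells == c] for c in CELLS}
    rows = []
    for g1, g2 in PAIRS:
        x1, x2 = groups[g1], groups[g2]
        if x1.size < 2 or x2.size < 2:
            warnings.warn(
                f"pair {g1} vs {g2} skipped (group of size < 2)", stacklevel=2
            )
            continue
        res = stats.ttest_ind(x1, x2, equal_var=equal_var)
        df = x1.size + x2.size - 2 if equal_var else float(res.df)
        rows.append(
            {
                "pair": f"{g1} vs {g2}",
                "n1": int(x1.size),
                "n2": int(x2.size),
                "T": float(res.statistic),
                "df": df,
                "p": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = fdr_correct(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def run_analysis(
    centrality: pd.DataFrame,
    assignments: pd.DataFrame,
    alpha: float = 0.05,
    ss_type: int = 3,
    equal_var: bool = True,
    posthoc_all: bool = False,
    value_column: str = "adjusted",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full inferential pass over every criterion in the assignments table.

    ``centrality`` is long format (subject_id, region_id, raw, adjusted);
    ``assignments`` is the stratification output.  Per criterion: ANOVA per
    node with BH over nodes (separately per effect), then post-hoc pairwise
    tests for nodes whose interaction q < alpha (all nodes if
    ``posthoc_all``).  Output rows are ordered by (criterion, region_id,
    pair).
    """
    wide = centrality.pivot(
        index="subject_id", columns="region_id", values=value_column
    ).sort_index()
    if wide.isna().any().any():
        raise ValueError("centrality table has missing subject x region entries")
    region_ids = list(wide.columns)

    anova_frames, posthoc_frames = [], []
    for criterion in sorted(assignments["criterion"].unique()):
        sub = assignments[assignments["criterion"] == criterion]
        missing = sorted(set(sub["subject_id"]) - set(wide.index))
        extra = sorted(set(wide.index) - set(sub["subject_id"]))
        if missing or extra:
            raise ValueError(
                f"criterion {criterion!r}: subject mismatch between centrality "
                f"and assignments (missing {missing}, unassigned {extra})"
            )
        cells = (
            sub.set_index("subject_id").loc[wide.index, "cell"].to_numpy()
        )
        anova = two_way_anova(wide.to_numpy(), list(cells), ss_type=ss_type)
        anova.insert(0, "criterion", criterion)
        anova["region_id"] = [region_ids[i] for i in anova["node"]]
        anova["q"] = np.nan
        for effect in EFFECTS:
            mask = anova["effect"] == effect
            anova.loc[mask, "q"] = fdr_correct(anova.loc[mask, "p"].to_numpy())
        anova_frames.append(
            anova[["criterion", "region_id", "effect", "F", "df1", "df2", "p", "q"]]
        )

        hits = anova[(anova["effect"] == "interaction") & (anova["q"] < alpha)]
        nodes = region_ids if posthoc_all else list(hits["region_id"])
        for region_id in nodes:
            table = posthoc_pairwise(
                wide[region_id].to_numpy(), cells, equal_var=equal_var
            )
            table.insert(0, "region_id", region_id)
            table.insert(0, "criterion", criterion)
            posthoc_frames.append(table)

    # Stable sort keeps the canonical effect and pair orders within a node.
    anova_out = (
        pd.concat(anova_frames, ignore_index=True)
        .sort_values(["criterion", "region_id"], kind="stable")
        .reset_index(drop=True)
    )
    posthoc_cols = ["criterion", "region_id", "pair", "n1", "n2", "T", "df", "p", "q"]
    if posthoc_frames:
        posthoc_out = (
            pd.concat(posthoc_frames, ignore_index=True)
            .sort_values(["criterion", "region_id"], kind="stable")
            .reset_index(drop=True)[posthoc_cols]
        )
    else:
        posthoc_out = pd.DataFrame(columns=posthoc_cols)
    return anova_out, posthoc_out
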