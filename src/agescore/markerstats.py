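"""Per-well aggregation, condition testing and marker binarization.

The well is the biological replicate: per-cell readouts are averaged per
well before any testing, and technical replicates never count towards n.
Condition effects are tested per timepoint by a Welch t-test, a one-way
ANOVA with Tukey-adjusted pairwise comparisons, or a two-way
(condition × timepoint) ANOVA with Sidak-adjusted per-timepoint contrasts
— the families used for multi-timepoint marker panels.  Each marker is
then binarized: rating 1 only when the effect is significant *and* in the
direction expected with age; a significant effect in the opposite
direction scores 0.  No cross-marker multiple-testing correction is
applied: each marker of the panel is rated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerCall",
    "aggregate_per_well",
    "compare_conditions",
    "binarize_marker",
    "simulate_well_table",
]

TESTS = ("t_test", "anova1_tukey", "anova2_sidak")


@dataclass(frozen=True)
class MarkerCall:
    """Binarized per-marker, per-timepoint result."""

    marker_name: str
    timepoint_days: int
    p_value: float
    observed_direction: str  # "up" | "down" | "none"
    rating: int  # 1 iff significant and age-consistent
    note: str = ""


def aggregate_per_well(
    cell_records: pd.DataFrame,
    value_col: str = "value",
    marker_col: str = "marker",
    well_col: str = "well_id",
    min_cells: int | None = 20,
) -> pd.DataFrame:
    """Per-well arithmetic mean of a per-cell readout.

    Input is long format with one row per cell per marker; the output has
    one row per well × marker with the mean value and the cell count.
    Wells with fewer than ``min_cells`` cells are kept but warned about
    (image markers expect at least 20 analyzed cells per replicate);
    wells with zero finite values are dropped with a warning.
    """
    keys = [c for c in (well_col, "condition", "timepoint_days", marker_col)
            if c in cell_records.columns]
    grouped = cell_records.groupby(keys, sort=False, dropna=False)[value_col]
    out = grouped.agg(value="mean", n_cells="count").reset_index()
    empty = out[out["n_cells"] == 0]
    if not empty.empty:
        warnings.warn(
            f"dropping {len(empty)} well×marker group(s) with zero cells"
        )
        out = out[out["n_cells"] > 0]
    if min_cells is not None:
        low = out[out["n_cells"] < min_cells]
        if not low.empty:
            wells = sorted(low[well_col].unique())
            warnings.warn(
                f"{len(low)} well×marker group(s) built from fewer than "
                f"{min_cells} cells (wells {wells[:5]}...)"
            )
    return out


def _direction(diff: float) -> str:
    if diff > 0:
        return "up"
    if diff < 0:
        return "down"
    return "none"


def _welch(treated: np.ndarray, control: np.ndarray) -> float:
    if np.var(treated) == 0 and np.var(control) == 0:
        return 1.0 if np.mean(treated) == np.mean(control) else 0.0
    return float(stats.ttest_ind(treated, control, equal_var=False).pvalue)


def compare_conditions(
    well_values: pd.DataFrame,
    test: str,
    control_condition: str,
    treated_condition: str | None = None,
    value_col: str = "value",
    condition_col: str = "condition",
    timepoint_col: str = "timepoint_days",
) -> pd.DataFrame:
    """Condition effect per timepoint for one marker's per-well values.

    Returns one row per timepoint with ``p_value`` (adjusted where the
    test family adjusts), ``direction`` (sign of treated mean minus
    control mean) and the mean difference.

    * ``t_test`` — two-sided Welch t-test of treated vs. control within
      each timepoint.
    * ``anova1_tukey`` — one-way ANOVA across all condition groups within
      each timepoint; the reported p is the Tukey-HSD-adjusted p for the
      treated-vs-control pair.
    * ``anova2_sidak`` — two-way condition × timepoint layout: the
      per-timepoint treated-vs-control contrast uses the pooled residual
      variance of the full design and its p is Sidak-adjusted for the
      number of timepoints (the per-figure family).
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; one of {TESTS}")
    conditions = list(pd.unique(well_values[condition_col]))
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from data")
    if treated_condition is None:
        others = [c for c in conditions if c != control_condition]
        if len(others) != 1 and test != "anova1_tukey":
            raise ValueError("specify treated_condition when more than two arms exist")
        treated_condition = others[0]

    counts = well_values.groupby([condition_col, timepoint_col])[value_col].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 wells per arm per timepoint; too few in {bad}")

    timepoints = sorted(pd.unique(well_values[timepoint_col]))
    rows = []

    if test == "anova2_sidak":
        pair = well_values[well_values[condition_col].isin(
            [control_condition, treated_condition])]
        # pooled within-cell residual variance of the condition × timepoint design
        cells = pair.groupby([condition_col, timepoint_col])[value_col]
        ss_resid = float(((pair[value_col] - cells.transform("mean")) ** 2).sum())
        df_resid = len(pair) - cells.ngroups
        mse = ss_resid / df_resid if df_resid > 0 else 0.0
        m = len(timepoints)
        for tp in timepoints:
            t_vals = pair[(pair[timepoint_col] == tp)
                          & (pair[condition_col] == treated_condition)][value_col].values
            c_vals = pair[(pair[timepoint_col] == tp)
                          & (pair[condition_col] == control_condition)][value_col].values
            diff = float(t_vals.mean() - c_vals.mean())
            se = np.sqrt(mse * (1.0 / len(t_vals) + 1.0 / len(c_vals)))
            if se == 0:
                p_raw = 1.0 if diff == 0 else 0.0
            else:
                p_raw = 2.0 * stats.t.sf(abs(diff) / se, df_resid)
            p_adj = float(1.0 - (1.0 - p_raw) ** m)
            rows.append({timepoint_col: tp, "p_value": p_adj, "p_unadjusted": p_raw,
                         "direction": _direction(diff), "mean_difference": diff})
    else:
        for tp in timepoints:
            at_tp = well_values[well_values[timepoint_col] == tp]
            t_vals = at_tp[at_tp[condition_col] == treated_condition][value_col].values
            c_vals = at_tp[at_tp[condition_col] == control_condition][value_col].values
            diff = float(t_vals.mean() - c_vals.mean())
            if test == "t_test":
                p = _welch(t_vals, c_vals)
                p_raw = p
            else:  # anova1_tukey
                groups = [
                    at_tp[at_tp[condition_col] == c][value_col].values
                    for c in conditions
                ]
                if all(np.var(g) == 0 for g in groups) and diff == 0:
                    p = p_raw = 1.0
                else:
                    res = stats.tukey_hsd(*groups)
                    i = conditions.index(treated_condition)
                    j = conditions.index(control_condition)
                    p = p_raw = float(res.pvalue[i, j])
            rows.append({timepoint_col: tp, "p_value": float(p),
                         "p_unadjusted": float(p_raw),
                         "direction": _direction(diff), "mean_difference": diff})
    return pd.DataFrame(rows)


def binarize_marker(
    test_result: pd.DataFrame,
    marker_name: str,
    expected_direction: str,
    alpha: float = 0.05,
    timepoint_col: str = "timepoint_days",
) -> list[MarkerCall]:
    """0/1 rating per timepoint from a :func:`compare_conditions` table.

    Rating 1 requires both significance (``p < alpha``) and an observed
    direction matching the direction expected with age; a significant
    effect in the opposite direction is rated 0 and annotated.
    """
    if expected_direction not in ("up", "down"):
        raise ValueError("expected_direction must be 'up' or 'down'")
    calls = []
    for _, row in test_result.iterrows():
        significant = row["p_value"] < alpha
        matches = row["direction"] == expected_direction
        note = ""
        if significant and not matches:
            note = (
                f"significant but opposite to the expected '{expected_direction}' "
                "direction; rated 0"
            )
        calls.append(
            MarkerCall(
                marker_name=marker_name,
                timepoint_days=int(row[timepoint_col]),
                p_value=float(row["p_value"]),
                observed_direction=str(row["direction"]),
                rating=int(significant and matches),
                note=note,
            )
        )
    return calls


def simulate_well_table(
    rng: np.random.Generator,
    wells_per_arm: int = 6,
    timepoints: tuple[int, ...] = (3, 7, 14),
    shift_sd: float | dict[int, float] = 0.0,
    conditions: tuple[str, str] = ("-DOX", "+DOX"),
) -> pd.DataFrame:
    """Gaussian per-well values for power / type-I simulations.

    Control wells are N(0, 1); treated wells are shifted by ``shift_sd``
    standard deviations (optionally per timepoint).  This simulates the
    per-well summary directly — the input scale of the testing stage.
    """
    rows = []
    for tp in timepoints:
        s = shift_sd.get(tp, 0.0) if isinstance(shift_sd, dict) else shift_sd
        for cond in conditions:
            mu = s if cond != conditions[0] else 0.0
            for w, v in enumerate(rng.normal(mu, 1.0, wells_per_arm)):
                rows.append(
                    {"well_id": f"{cond}_{tp}d_w{w + 1}", "condition": cond,
                     "timepoint_days": tp, "value": v}
                )
    return pd.DataFrame(rows)
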