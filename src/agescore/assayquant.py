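"""Tabular-assay computations.

Relative gene expression by the delta-delta-Ct method, telomere content
as a T/S ratio from a standard dilution series with a coefficient-of-
variation QC gate, technical-replicate averaging for ELISA/qPCR tables,
and scratch-wound closure percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "average_technical_replicates",
    "ddct_relative_expression",
    "telomere_ts_ratio",
    "wound_closure",
    "wound_mask_from_image",
]


def average_technical_replicates(
    table: pd.DataFrame,
    group_keys: list[str],
    value_col: str = "value",
) -> pd.DataFrame:
    """One value per biological replicate: arithmetic mean within group.

    Technical replicates contribute to precision only; they never inflate
    the biological n.  A single replicate passes through unchanged.
    """
    out = table.groupby(group_keys, as_index=False, sort=False)[value_col].mean()
    return out


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    sample_col: str = "sample_id",
    gene_col: str = "gene",
    ct_col: str = "ct",
    condition_col: str = "condition",
    group_within: list[str] | None = None,
) -> pd.DataFrame:
    """Fold change per sample and target gene by the ΔΔCt method.

    Technical replicates are averaged first.  Then per sample
    ``ΔCt = Ct(target) − Ct(reference)``; the control baseline is the
    arithmetic mean ΔCt over control-condition samples (computed within
    each group of ``group_within``, e.g. per timepoint), and
    ``fold = 2^(−ΔΔCt)`` with ``ΔΔCt = ΔCt − mean(ΔCt control)``.
    """
    keep = [sample_col, condition_col, gene_col] + (group_within or [])
    averaged = average_technical_replicates(ct_table, keep, ct_col)
    ref = averaged[averaged[gene_col] == reference_gene].rename(
        columns={ct_col: "_ref_ct"}
    )
    targets = averaged[averaged[gene_col] != reference_gene]
    join_keys = [sample_col, condition_col] + (group_within or [])
    merged = targets.merge(
        ref[join_keys + ["_ref_ct"]], on=join_keys, how="left", validate="m:1"
    )
    missing = merged[merged["_ref_ct"].isna()]
    if not missing.empty:
        bad = sorted(missing[sample_col].unique())
        raise ValueError(
            f"reference gene {reference_gene!r} missing for sample(s) {bad}"
        )
    merged["delta_ct"] = merged[ct_col] - merged["_ref_ct"]
    baseline_keys = [gene_col] + (group_within or [])
    control = merged[merged[condition_col] == control_condition]
    if control.empty:
        raise ValueError(f"no samples in control condition {control_condition!r}")
    baseline = (
        control.groupby(baseline_keys)["delta_ct"].mean().rename("_control_delta_ct")
    )
    merged = merged.merge(baseline, on=baseline_keys, how="left")
    merged["ddct"] = merged["delta_ct"] - merged["_control_delta_ct"]
    merged["fold_change"] = 2.0 ** (-merged["ddct"])
    return merged.drop(columns=["_ref_ct", "_control_delta_ct"])


@dataclass(frozen=True)
class _StandardCurve:
    slope: float
    intercept: float

    def quantity(self, ct: np.ndarray) -> np.ndarray:
        """Invert the Ct ~ log2(quantity) regression."""
        return 2.0 ** ((np.asarray(ct) - self.intercept) / self.slope)


def _fit_standard(conc: np.ndarray, ct: np.ndarray) -> _StandardCurve:
    logq = np.log2(conc)
    order = np.argsort(logq)
    d = np.diff(np.asarray(ct)[order])
    if not (np.all(d < 0) or np.all(d > 0)):
        raise ValueError("standard dilution series is not monotone in concentration")
    fit = stats.linregress(logq, ct)
    return _StandardCurve(float(fit.slope), float(fit.intercept))


def telomere_ts_ratio(
    runs: pd.DataFrame,
    standard: pd.DataFrame,
    cv_limit: float = 0.3,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Telomere-to-single-copy-gene ratio (TLR) per sample, with QC.

    ``runs`` carries triplicate Ct readings (columns ``t_ct``, ``s_ct``,
    ``replicate``); ``standard`` the dilution series (``concentration``,
    ``t_ct``, ``s_ct``).  T and S quantities are interpolated separately
    on the log-concentration scale, each replicate yields a T/S ratio,
    and the reported TLR is the mean of the three.  QC fails when the
    intra-assay coefficient of variation of the replicate ratios reaches
    ``cv_limit`` or replicates are missing; the TLR is in arbitrary units
    (it is invariant to a common scale factor on both signals).
    """
    t_curve = _fit_standard(standard["concentration"].values, standard["t_ct"].values)
    s_curve = _fit_standard(standard["concentration"].values, standard["s_ct"].values)
    rows = []
    for sample, grp in runs.groupby(sample_col, sort=False):
        t_q = t_curve.quantity(grp["t_ct"].values)
        s_q = s_curve.quantity(grp["s_ct"].values)
        ratios = t_q / s_q
        tlr = float(np.mean(ratios))
        cv = float(np.std(ratios, ddof=1) / np.mean(ratios)) if len(ratios) > 1 else np.nan
        qc_pass = len(ratios) == 3 and np.isfinite(cv) and cv < cv_limit
        reason = ""
        if len(ratios) != 3:
            reason = f"expected 3 replicates, got {len(ratios)}"
        elif not qc_pass:
            reason = f"intra-assay CV {cv:.2f} >= {cv_limit}"
        rows.append(
            {sample_col: sample, "tlr": tlr, "cv": cv, "qc_pass": qc_pass,
             "qc_reason": reason}
        )
    return pd.DataFrame(rows)


def wound_closure(
    gap_mask_first: np.ndarray, gap_mask_last: np.ndarray
) -> float:
    """Percent closure of a scratch wound between first and last day.

    ``closure% = 100 × (area_first − area_last) / area_first`` from two
    binary gap masks of identical shape.  Bounded above by 100 (empty
    final gap); can be negative if the gap widened.
    """
    first = np.asarray(gap_mask_first, dtype=bool)
    last = np.asarray(gap_mask_last, dtype=bool)
    if first.shape != last.shape:
        raise ValueError("gap masks must share a shape")
    a0 = int(first.sum())
    if a0 == 0:
        raise ValueError("first-day gap mask is empty: no wound to close")
    return float(100.0 * (a0 - int(last.sum())) / a0)


def wound_mask_from_image(
    image: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Binary gap mask from a phase-contrast-like image.

    The cell-free gap is the low-intensity region; ``threshold`` defaults
    to the midpoint between the image's 5th and 95th percentile.
    """
    img = np.asarray(image, dtype=float)
    if threshold is None:
        lo, hi = np.percentile(img, [5, 95])
        threshold = 0.5 * (lo + hi)
    return img < threshold
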