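"""Composite AgeScore aggregation and scorecard rendering.

The AgeScore sums the 0/1 ratings of the marker panel: the *primary*
score over markers of the damage-causing hallmarks (DNA damage,
heterochromatin loss, telomere attrition), the *antagonistic* score over
the response hallmarks (cell-cycle arrest, SA-βGal, SASP cytokines,
Lamin B1, nuclear morphology), and the *full* score as their total.  The
score is a categorical sum over statistically binarized markers, so no
uncertainty is propagated onto it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .markerstats import MarkerCall
from .panel import Panel, default_panel

__all__ = [
    "AgeScoreResult",
    "compute_agescore",
    "write_scorecard",
    "read_scorecard",
    "load_reference_ratings",
    "reference_marker_calls",
    "REFERENCE_COLUMNS",
]

#: Column labels of the packaged reference scorecard: the non-induced
#: control arm and the induced arm at 3, 7 and 14 days of induction.
REFERENCE_COLUMNS = ("control", "day3", "day7", "day14")


@dataclass(frozen=True)
class AgeScoreResult:
    """Primary/antagonistic/full score for one arm × timepoint."""

    timepoint_days: int | None
    primary_score: int
    antagonistic_score: int
    full_score: int
    breakdown: tuple[tuple[str, str, int], ...]  # (marker, category, rating)
    label: str = ""

    def __post_init__(self) -> None:
        assert self.full_score == self.primary_score + self.antagonistic_score


def compute_agescore(
    marker_calls: list[MarkerCall],
    panel: Panel | None = None,
) -> list[AgeScoreResult]:
    """Sum binarized marker calls into AgeScores, one result per timepoint.

    Requires exactly one call per panel marker per timepoint; a missing or
    duplicate call raises with the marker's name.  Marker order never
    affects the scores.
    """
    panel = panel or default_panel()
    by_tp: dict[int | None, dict[str, MarkerCall]] = {}
    for call in marker_calls:
        tp_calls = by_tp.setdefault(call.timepoint_days, {})
        if call.marker_name in tp_calls:
            raise ValueError(
                f"duplicate call for marker {call.marker_name!r} at "
                f"timepoint {call.timepoint_days}"
            )
        tp_calls[call.marker_name] = call
    results = []
    for tp in sorted(by_tp, key=lambda t: (t is None, t)):
        tp_calls = by_tp[tp]
        missing = [m.name for m in panel if m.name not in tp_calls]
        if missing:
            raise ValueError(f"missing call(s) for marker(s) {missing} at timepoint {tp}")
        extra = sorted(set(tp_calls) - {m.name for m in panel})
        if extra:
            raise ValueError(f"call(s) for marker(s) {extra} not in the panel")
        breakdown = tuple(
            (m.name, m.category, int(tp_calls[m.name].rating)) for m in panel
        )
        primary = sum(r for _, cat, r in breakdown if cat == "primary")
        antagonistic = sum(r for _, cat, r in breakdown if cat == "antagonistic")
        results.append(
            AgeScoreResult(
                timepoint_days=tp,
                primary_score=primary,
                antagonistic_score=antagonistic,
                full_score=primary + antagonistic,
                breakdown=breakdown,
            )
        )
    return results


# ---------------------------------------------------------------------------
# reference scorecard fixture


def load_reference_ratings() -> pd.DataFrame:
    """The published progerin-microglia rating matrix (10 markers × 4 arms).

    Columns: ``marker``, ``category`` and one 0/1 rating column per arm
    (:data:`REFERENCE_COLUMNS`): the non-induced control and the induced
    arm after 3, 7 and 14 days.
    """
    ref = resources.files("agescore.data") / "progerin_hmc3_ratings.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_marker_calls(column: str) -> list[MarkerCall]:
    """Marker calls for one column of the reference rating matrix."""
    ratings = load_reference_ratings()
    if column not in ratings.columns:
        raise KeyError(f"unknown scorecard column {column!r}; one of {REFERENCE_COLUMNS}")
    tp = {"control": None, "day3": 3, "day7": 7, "day14": 14}[column]
    return [
        MarkerCall(
            marker_name=row["marker"],
            timepoint_days=tp,
            p_value=math.nan,
            observed_direction="none",
            rating=int(row[column]),
            note="from reference scorecard",
        )
        for _, row in ratings.iterrows()
    ]


# ---------------------------------------------------------------------------
# scorecard rendering


def _results_table(results: dict[str, AgeScoreResult]) -> pd.DataFrame:
    """Marker-by-arm rating table with category and summary rows."""
    if not results:
        return pd.DataFrame(columns=["marker", "category"])
    first = next(iter(results.values()))
    rows = []
    for marker, category, _ in first.breakdown:
        row = {"marker": marker, "category": category}
        for col, res in results.items():
            lut = {m: r for m, _, r in res.breakdown}
            row[col] = lut[marker]
        rows.append(row)
    for label, attr in (
        ("primary AgeScore", "primary_score"),
        ("antagonistic AgeScore", "antagonistic_score"),
        ("full AgeScore", "full_score"),
    ):
        row = {"marker": label, "category": ""}
        for col, res in results.items():
            row[col] = getattr(res, attr)
        rows.append(row)
    return pd.DataFrame(rows)


def write_scorecard(
    results: dict[str, AgeScoreResult], out_path: str | Path
) -> tuple[Path, Path]:
    """Write a scorecard as CSV and a markdown table.

    ``results`` maps a column label (arm or arm × timepoint) to its
    :class:`AgeScoreResult`.  Empty results produce header-only files.
    Returns the two paths written.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table = _results_table(results)
    csv_path = out_path.with_suffix(".csv")
    md_path = out_path.with_suffix(".md")
    table.to_csv(csv_path, index=False)
    md_path.write_text(table.to_markdown(index=False) + "\n")
    return csv_path, md_path


def read_scorecard(csv_path: str | Path) -> pd.DataFrame:
    """Parse a scorecard CSV back into the marker rating table (no summary
    rows), suitable for recomputing the scores."""
    table = pd.read_csv(csv_path)
    return table[table["category"].notna() & (table["category"] != "")].reset_index(
        drop=True
    )
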