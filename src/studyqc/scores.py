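"""Biomarker score computation, distribution summaries and outlier flagging.

A :class:`ScoreDefinition` maps a form's item fields to a single score (sum,
mean, or a single field), e.g. GAD-7 anxiety = sum of 7 items (0-21) and
PHQ-9 depression = sum of 9 items (0-27).  Scores are computed only for
completed forms and never imputed: any missing item leaves the instance
unscored.  Summaries are grouped by visit x surgical cohort; outliers are
flagged with Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR] within each group,
using linear interpolation between order statistics for the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import STATUS_COMPLETE, StudySchema, is_missing

__all__ = [
    "ScoreDefinition",
    "default_score_definitions",
    "score_form",
    "score_table",
    "distribution_summary",
    "flag_outliers",
    "plot_score_distributions",
]

#: minimum group size before any outlier is flagged
MIN_OUTLIER_GROUP = 4


@dataclass(frozen=True)
class ScoreDefinition:
    form_id: str
    items: tuple[str, ...]
    rule: str = "sum"  # sum | mean | single
    lo: float = 0.0
    hi: float = 100.0

    def __post_init__(self):
        if self.rule not in ("sum", "mean", "single"):
            raise ValueError(f"unknown scoring rule {self.rule!r}")
        if self.rule == "single" and len(self.items) != 1:
            raise ValueError("'single' rule takes exactly one item")
        if not np.isfinite([self.lo, self.hi]).all():
            raise ValueError("score range must be finite")


def default_score_definitions(schema: StudySchema) -> list[ScoreDefinition]:
    """GAD-7 and PHQ-9 sum scores for the example study."""
    defs = []
    for form_id, n, hi in (("gad7", 7, 21.0), ("phq9", 9, 27.0)):
        try:
            form = schema.form(form_id)
        except KeyError:
            continue
        items = tuple(f.name for f in form.fields if f.name.startswith(f"{form_id}_item_"))
        assert len(items) == n
        defs.append(ScoreDefinition(form_id, items, "sum", 0.0, hi))
    return defs


def score_form(values: dict, definition: ScoreDefinition) -> float | None:
    """Score one completed form instance; any missing item yields None."""
    items = [values.get(name) for name in definition.items]
    if any(is_missing(v) for v in items):
        return None
    items = [float(v) for v in items]
    if definition.rule == "sum":
        return float(sum(items))
    if definition.rule == "mean":
        return float(np.mean(items))
    return items[0]


def score_table(
    records: pd.DataFrame, schema: StudySchema, definitions: list[ScoreDefinition] | None = None
) -> pd.DataFrame:
    """Scores of every completed, fully itemized form instance.

    Columns: subject_id, site_id, visit, cohort, form_id, score,
    range_violation (score outside the declared valid range).
    """
    definitions = default_score_definitions(schema) if definitions is None else definitions
    rows = []
    for definition in definitions:
        form = schema.form(definition.form_id)
        sub = records[records["form_id"] == definition.form_id]
        if sub.empty:
            continue
        wide = sub.pivot(
            index=["subject_id", "site_id", "cohort", "visit"], columns="field_name", values="value"
        ).reset_index()
        for _, row in wide.iterrows():
            status = row.get(form.status_field)
            if is_missing(status) or float(status) != STATUS_COMPLETE:
                continue
            score = score_form(row.to_dict(), definition)
            if score is None:
                continue
            rows.append(
                {
                    "subject_id": row["subject_id"],
                    "site_id": row["site_id"],
                    "visit": row["visit"],
                    "cohort": row["cohort"],
                    "form_id": definition.form_id,
                    "score": score,
                    "range_violation": not (definition.lo <= score <= definition.hi),
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "site_id", "visit", "cohort", "form_id", "score", "range_violation"]
    )


def distribution_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per (form, visit, cohort) group: n, mean, median, quartiles.

    Groups over the full visit x cohort cross product of the observed values,
    so empty groups appear with n = 0 rather than vanishing.
    """
    if scores.empty:
        return pd.DataFrame(columns=["form_id", "visit", "cohort", "n", "mean", "median", "q1", "q3"])
    rows = []
    visits = list(dict.fromkeys(scores["visit"]))
    cohorts = list(dict.fromkeys(scores["cohort"]))
    for form_id in dict.fromkeys(scores["form_id"]):
        for visit in visits:
            for cohort in cohorts:
                group = scores.query("form_id == @form_id and visit == @visit and cohort == @cohort")["score"]
                if group.empty:
                    rows.append(dict(form_id=form_id, visit=visit, cohort=cohort, n=0, mean=np.nan,
                                     median=np.nan, q1=np.nan, q3=np.nan))
                    continue
                values = group.to_numpy(dtype=float)
                q1, median, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
                rows.append(dict(form_id=form_id, visit=visit, cohort=cohort, n=len(values),
                                 mean=float(values.mean()), median=float(median), q1=float(q1), q3=float(q3)))
    return pd.DataFrame(rows, columns=["form_id", "visit", "cohort", "n", "mean", "median", "q1", "q3"])


def flag_outliers(scores: pd.DataFrame) -> pd.DataFrame:
    """Tukey-fence outliers within each (form, visit, cohort) group.

    Groups smaller than four are never flagged.  Returns the input with an
    ``outlier`` boolean column.
    """
    out = scores.copy()
    out["outlier"] = False
    for _, index in out.groupby(["form_id", "visit", "cohort"]).groups.items():
        values = out.loc[index, "score"].to_numpy(dtype=float)
        if len(values) < MIN_OUTLIER_GROUP:
            continue
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        out.loc[index, "outlier"] = (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)
    return out


def plot_score_distributions(scores: pd.DataFrame, path, form_id: str | None = None) -> None:
    """Violin plot of score distributions by visit and cohort (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = scores if form_id is None else scores[scores["form_id"] == form_id]
    fig, ax = plt.subplots(figsize=(8, 4))
    groups, labels = [], []
    for (visit, cohort), group in data.groupby(["visit", "cohort"]):
        groups.append(group["score"].to_numpy(dtype=float))
        labels.append(f"{visit}\n{cohort}")
    if groups:
        ax.violinplot(groups, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
    ax.set_ylabel("score")
    ax.set_title(form_id or "scores")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
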