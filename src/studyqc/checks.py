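"""Declarative edit-check engine over tidy observation records.

Each check is one :class:`CheckDefinition` — a rule kind plus the form and
fields it inspects.  ``run_checks`` evaluates a registry of checks over a
tidy record table and returns a deterministic, stably ordered error-flag
table.  Six rule kinds cover the usual case-report-form edit checks:

* ``missingness``            — a required field is blank on a completed form
* ``pair_mismatch``          — duplicate-entry fields disagree beyond tolerance
* ``conditional_missingness``— a dependent field is blank when its trigger holds
* ``chronology``             — time/date fields out of declared order
* ``location_mismatch``      — performed-at vs entered-for site designators differ
* ``reason_unspecified``     — a test is marked not done but no reason is given

All checks evaluate only form instances whose status field says complete:
blanks on incomplete forms count as incompleteness, not as errors, which
keeps the completed-with-errors and incomplete statuses disjoint.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import pandas as pd
import yaml

from .schema import STATUS_COMPLETE, StudySchema, is_missing

__all__ = [
    "CheckDefinition",
    "CheckConfigError",
    "check_missing",
    "check_pair_mismatch",
    "check_conditional_missing",
    "check_chronology",
    "check_location_mismatch",
    "check_reason_unspecified",
    "run_checks",
    "default_registry",
    "load_registry",
    "write_registry",
    "FLAG_COLUMNS",
]

CHECK_KINDS = (
    "missingness",
    "pair_mismatch",
    "conditional_missingness",
    "chronology",
    "location_mismatch",
    "reason_unspecified",
)

#: fixed flag-table column order (extra provenance columns follow the core ten)
FLAG_COLUMNS = (
    "subject_id",
    "site_id",
    "domain",
    "form_id",
    "visit",
    "check_id",
    "fields",
    "values",
    "flag_date",
    "message",
    "center",
    "cohort",
    "delivery_instrument",
)


class CheckConfigError(ValueError):
    """A check references a form or field that does not resolve."""


@dataclass(frozen=True)
class CheckDefinition:
    check_id: str
    form_id: str
    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)
    message: str = ""

    def __post_init__(self):
        if self.kind not in CHECK_KINDS:
            raise CheckConfigError(f"unknown check kind {self.kind!r}")
        if self.kind == "pair_mismatch" and float(self.params.get("tolerance", 0)) < 0:
            raise CheckConfigError(f"{self.check_id}: tolerance must be >= 0")
        if self.kind == "chronology" and len(self.params.get("fields", ())) < 2:
            raise CheckConfigError(f"{self.check_id}: chronology needs >= 2 time fields")

    def referenced_fields(self) -> list[str]:
        p = self.params
        if self.kind in ("missingness", "chronology"):
            return list(p["fields"])
        if self.kind == "pair_mismatch":
            return [p["field_a"], p["field_b"]]
        if self.kind == "conditional_missingness":
            return [p["trigger_field"], *p["dependent_fields"]]
        if self.kind == "location_mismatch":
            return [p["performed_site_field"], p["entered_site_field"]]
        return [p["completed_field"], p["reason_field"]]

    def validate(self, schema: StudySchema) -> None:
        form = schema.form(self.form_id)  # KeyError -> config error below
        names = set(form.field_names())
        for name in self.referenced_fields():
            if name not in names:
                raise CheckConfigError(f"check {self.check_id!r}: field {name!r} not on form {self.form_id!r}")


# ---------------------------------------------------------------------------
# rule evaluators: each takes the form instance (field -> value) and returns
# the implicated (fields, values) or None
# ---------------------------------------------------------------------------

Hit = tuple[list[str], list[Any]] | None


def check_missing(row: Mapping[str, Any], fields: list[str]) -> Hit:
    missing = [f for f in fields if is_missing(row.get(f))]
    if missing:
        return missing, [None] * len(missing)
    return None


def check_pair_mismatch(row: Mapping[str, Any], field_a: str, field_b: str, tolerance: float = 0.0) -> Hit:
    a, b = row.get(field_a), row.get(field_b)
    if is_missing(a) or is_missing(b):
        return None  # defer to missingness
    mismatch = abs(float(a) - float(b)) > tolerance if isinstance(a, (int, float)) else a != b
    if mismatch:
        return [field_a, field_b], [a, b]
    return None


def check_conditional_missing(
    row: Mapping[str, Any], trigger_field: str, trigger_value: Any, dependent_fields: list[str]
) -> Hit:
    trigger = row.get(trigger_field)
    if is_missing(trigger) or trigger != trigger_value:
        return None
    missing = [f for f in dependent_fields if is_missing(row.get(f))]
    if missing:
        return [trigger_field, *missing], [trigger, *[None] * len(missing)]
    return None


def check_chronology(row: Mapping[str, Any], fields: list[str]) -> Hit:
    present = [(f, row.get(f)) for f in fields if not is_missing(row.get(f))]
    if len(present) < 2:
        return None
    for (fa, va), (fb, vb) in zip(present, present[1:]):
        if vb < va:  # strictly decreasing where non-decreasing required
            return [fa, fb], [va, vb]
    return None


def check_location_mismatch(row: Mapping[str, Any], performed_site_field: str, entered_site_field: str) -> Hit:
    performed, entered = row.get(performed_site_field), row.get(entered_site_field)
    if is_missing(performed) or is_missing(entered):
        return None  # defer to missingness
    if performed != entered:
        return [performed_site_field, entered_site_field], [performed, entered]
    return None


def check_reason_unspecified(row: Mapping[str, Any], completed_field: str, reason_field: str) -> Hit:
    completed = row.get(completed_field)
    if is_missing(completed) or completed != "no":
        return None
    if is_missing(row.get(reason_field)):
        return [completed_field, reason_field], [completed, None]
    return None


_EVALUATORS: dict[str, Callable[..., Hit]] = {
    "missingness": check_missing,
    "pair_mismatch": check_pair_mismatch,
    "conditional_missingness": check_conditional_missing,
    "chronology": check_chronology,
    "location_mismatch": check_location_mismatch,
    "reason_unspecified": check_reason_unspecified,
}


def _format_value(v) -> str:
    if v is None or is_missing(v):
        return "<missing>"
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    if isinstance(v, dt.time):
        return v.isoformat(timespec="minutes")
    return str(v)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


def run_checks(records: pd.DataFrame, registry: list[CheckDefinition], schema: StudySchema) -> pd.DataFrame:
    """Evaluate every check over every completed form instance.

    Pure function of (records, registry): identical inputs yield an identical,
    stably ordered flag table — one flag at most per (subject, visit, check).
    Output is sorted by (site, subject, visit order, check id).
    """
    for check in registry:
        try:
            check.validate(schema)
        except KeyError as exc:
            raise CheckConfigError(f"check {check.check_id!r}: {exc}") from exc

    by_form: dict[str, list[CheckDefinition]] = {}
    for check in registry:
        by_form.setdefault(check.form_id, []).append(check)

    flags: list[dict] = []
    if not records.empty:
        for form_id, checks in by_form.items():
            form = schema.form(form_id)
            sub = records[records["form_id"] == form_id]
            if sub.empty:
                continue
            meta_cols = ["subject_id", "site_id", "cohort", "visit", "entry_timestamp", "delivery_instrument"]
            # tidy contract guarantees a unique (subject, visit, field) cell
            wide = sub.pivot(index=meta_cols, columns="field_name", values="value").reset_index()
            for _, row in wide.iterrows():
                status = row.get(form.status_field)
                if is_missing(status) or float(status) != STATUS_COMPLETE:
                    continue  # checks only apply to completed forms
                for check in checks:
                    hit = _EVALUATORS[check.kind](row, **check.params)
                    if hit is None:
                        continue
                    fields, values = hit
                    flags.append(
                        {
                            "subject_id": row["subject_id"],
                            "site_id": row["site_id"],
                            "domain": form.domain,
                            "form_id": form_id,
                            "visit": row["visit"],
                            "check_id": check.check_id,
                            "fields": ";".join(fields),
                            "values": ";".join(_format_value(v) for v in values),
                            "flag_date": row["entry_timestamp"],
                            "message": check.message or f"{check.kind} on {form_id}",
                            "center": schema.site_center(row["site_id"]),
                            "cohort": row["cohort"],
                            "delivery_instrument": row["delivery_instrument"],
                        }
                    )

    table = pd.DataFrame(flags, columns=list(FLAG_COLUMNS))
    if not table.empty:
        order = {v.name: i for i, v in enumerate(schema.visits)}
        table = (
            table.assign(_v=table["visit"].map(order))
            .sort_values(["site_id", "subject_id", "_v", "check_id"], kind="mergesort")
            .drop(columns="_v")
            .reset_index(drop=True)
        )
    return table


# ---------------------------------------------------------------------------
# registry I/O and the shipped default registry
# ---------------------------------------------------------------------------


def write_registry(registry: list[CheckDefinition], path: str | Path) -> None:
    doc = [
        {"check_id": c.check_id, "form": c.form_id, "kind": c.kind, "params": dict(c.params), "message": c.message}
        for c in registry
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_registry(path: str | Path) -> list[CheckDefinition]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        CheckDefinition(
            check_id=entry["check_id"],
            form_id=entry["form"],
            kind=entry["kind"],
            params=entry.get("params", {}),
            message=entry.get("message", ""),
        )
        for entry in doc
    ]


def default_registry(schema: StudySchema) -> list[CheckDefinition]:
    """Edit checks for the example study.

    One rule per classic per-domain check (conditional missingness after a
    resting-state scan, duplicate-entry mismatches, performed-vs-entered site,
    blood processing chronology, unspecified skip reasons) plus a missingness
    check per form.  Within each form the checks reference disjoint field
    sets, so every check polices its own fields and a single data defect
    raises exactly one flag.
    """
    checks = [
        CheckDefinition(
            "imaging_rs_pain_missing",
            "imaging",
            "conditional_missingness",
            {
                "trigger_field": "resting_state_scan",
                "trigger_value": "yes",
                "dependent_fields": ["surgical_site_pain", "surgical_site_pain_2"],
            },
            "resting-state scan performed but surgical site pain missing",
        ),
        CheckDefinition(
            "imaging_cuff_mismatch",
            "imaging",
            "pair_mismatch",
            {"field_a": "cuff_pain_initial", "field_b": "cuff_pain_mid", "tolerance": 0.0},
            "mismatched cuff pain ratings during mid-scan",
        ),
        CheckDefinition(
            "qst_ppt_mismatch",
            "qst",
            "pair_mismatch",
            {"field_a": "ppt_remote_rating", "field_b": "ppt_remote_rating_2", "tolerance": 0.0},
            "mismatched pressure pain threshold ratings for the remote site",
        ),
        CheckDefinition(
            "qst_ppt_location",
            "qst",
            "location_mismatch",
            {"performed_site_field": "ppt_performed_site", "entered_site_field": "ppt_entered_site"},
            "PPT performed at one site but entered for the other",
        ),
        CheckDefinition(
            "functional_pain_mismatch",
            "functional_testing",
            "pair_mismatch",
            {"field_a": "initial_pain_rating_1", "field_b": "initial_pain_rating_2", "tolerance": 0.0},
            "discrepant first and second initial pain ratings",
        ),
        CheckDefinition(
            "functional_reason_unspecified",
            "functional_testing",
            "reason_unspecified",
            {"completed_field": "test_completed", "reason_field": "incomplete_reason"},
            "reason for incomplete test not specified",
        ),
        CheckDefinition(
            "blood_chronology",
            "blood_collection",
            "chronology",
            {"fields": ["blood_draw_time", "centrifuge_time", "freezer_time"]},
            "blood draw / centrifuge / freezer times out of order",
        ),
    ]
    # per-form missingness over required fields no other check references
    missing_fields = {
        "imaging": ["overall_image_quality"],
        "qst": ["ppt_index_rating"],
        "functional_testing": ["walk_test_distance"],
        "blood_collection": ["vaccination_status"],
    }
    referenced = {name for c in checks for name in c.referenced_fields()}
    for form in schema.forms:
        if form.kind == "PRO":
            fields = [f.name for f in form.fields if f.required and f.name != form.status_field]
        else:
            fields = [f for f in missing_fields.get(form.form_id, []) if f in set(form.field_names())]
        fields = [f for f in fields if f not in referenced]
        if fields:
            checks.append(
                CheckDefinition(
                    f"{form.form_id}_missing",
                    form.form_id,
                    "missingness",
                    {"fields": fields},
                    f"missing required data on {form.form_id}",
                )
            )
    return checks
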