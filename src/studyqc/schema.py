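"""Study schema and tidy-record ingest for multi-site longitudinal studies.

A study is described by a :class:`StudySchema`: recruiting sites grouped into
two multisite clinical centers (MCC1/MCC2), two surgical cohorts, an ordered
visit schedule, and a set of forms (in-person case report forms, CRFs, and
remotely collected patient-reported outcomes, PROs).  Flat REDCap-style
exports — one row per subject x event, one column per field — are melted into
a tidy observation table: one row per (subject, visit, form, field) cell,
carrying the typed value, the entry date and the survey delivery instrument.
"""

from __future__ import annotations

import datetime as dt
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "FieldDef",
    "FormDef",
    "Applicability",
    "VisitDef",
    "SiteDef",
    "StudySchema",
    "SchemaViolation",
    "IngestError",
    "IngestResult",
    "MISSING",
    "is_missing",
    "load_dictionary",
    "write_dictionary",
    "load_records",
    "applicable_forms",
    "example_schema",
]

#: canonical missing sentinel for tidy values (blank cells in exports)
MISSING = pd.NA

VALUE_TYPES = ("numeric", "categorical", "date", "time", "text")

#: REDCap form-completion coding; unverified is treated as incomplete downstream
STATUS_INCOMPLETE, STATUS_UNVERIFIED, STATUS_COMPLETE = 0, 1, 2

#: reserved metadata columns of the wide export, before field columns
RESERVED_COLUMNS = ("record_id", "redcap_event_name", "site_id", "cohort", "event_date")


def is_missing(value) -> bool:
    """True for the missing sentinel / None / NaN / empty string."""
    if value is None:
        return True
    try:
        if bool(pd.isna(value)):
            return True
    except (TypeError, ValueError):
        pass
    return isinstance(value, str) and value == ""


# ---------------------------------------------------------------------------
# schema types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldDef:
    """One form field: name, declared type, allowed values and required flag."""

    name: str
    value_type: str = "text"
    choices: tuple[str, ...] | None = None  # categorical levels
    lo: float | None = None  # numeric range
    hi: float | None = None
    required: bool = True

    def __post_init__(self):
        if self.value_type not in VALUE_TYPES:
            raise ValueError(f"unknown value_type {self.value_type!r} for field {self.name!r}")

    def coerce(self, raw):
        """Typed value, or raise ValueError if the text cannot be coerced."""
        if is_missing(raw):
            return MISSING
        if self.value_type == "numeric":
            return float(raw)
        if self.value_type == "date":
            return raw if isinstance(raw, dt.date) else dt.date.fromisoformat(str(raw))
        if self.value_type == "time":
            return raw if isinstance(raw, dt.time) else dt.time.fromisoformat(str(raw))
        value = str(raw)
        if self.value_type == "categorical" and self.choices and value not in self.choices:
            raise ValueError(f"{value!r} not among choices {self.choices}")
        return value

    def choices_or_range(self) -> str:
        if self.value_type == "numeric" and self.lo is not None and self.hi is not None:
            return f"{self.lo:g}:{self.hi:g}"
        if self.choices:
            return "|".join(self.choices)
        return ""


@dataclass(frozen=True)
class Applicability:
    """Which visit x cohort combinations a form is collected in.

    ``None`` means unrestricted; the complement of the predicate defines the
    "not collected by design" cells of the status table.
    """

    visits: frozenset[str] | None = None
    cohorts: frozenset[str] | None = None

    def applies(self, cohort: str, visit: str) -> bool:
        if self.visits is not None and visit not in self.visits:
            return False
        if self.cohorts is not None and cohort not in self.cohorts:
            return False
        return True

    def to_string(self) -> str:
        parts = []
        if self.visits is not None:
            parts.append("visits=" + ",".join(sorted(self.visits)))
        if self.cohorts is not None:
            parts.append("cohorts=" + ",".join(sorted(self.cohorts)))
        return ";".join(parts) or "all"

    @classmethod
    def from_string(cls, text: str) -> "Applicability":
        text = (text or "").strip()
        if text in ("", "all"):
            return cls()
        visits = cohorts = None
        for part in text.split(";"):
            key, _, values = part.partition("=")
            values = frozenset(v.strip() for v in values.split(",") if v.strip())
            if key.strip() == "visits":
                visits = values
            elif key.strip() == "cohorts":
                cohorts = values
            else:
                raise ValueError(f"unknown applicability key {key!r}")
        return cls(visits=visits, cohorts=cohorts)


@dataclass(frozen=True)
class FormDef:
    """A CRF or PRO: fields, domain, applicability and its status field."""

    form_id: str
    kind: str = "CRF"  # CRF | PRO
    domain: str = ""
    fields: tuple[FieldDef, ...] = ()
    applicability: Applicability = Applicability()
    status_field: str = ""

    def __post_init__(self):
        if self.kind not in ("CRF", "PRO"):
            raise ValueError(f"form kind must be CRF or PRO, got {self.kind!r}")
        if not self.fields:
            raise ValueError(f"form {self.form_id!r} declares no fields")

    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def field(self, name: str) -> FieldDef:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(f"form {self.form_id!r} has no field {name!r}")


@dataclass(frozen=True)
class VisitDef:
    name: str
    offset_days: int  # nominal day offset from baseline


@dataclass(frozen=True)
class SiteDef:
    site_id: str
    center: str  # MCC1 | MCC2


@dataclass(frozen=True)
class StudySchema:
    sites: tuple[SiteDef, ...]
    cohorts: tuple[str, ...]
    visits: tuple[VisitDef, ...]
    forms: tuple[FormDef, ...]

    def __post_init__(self):
        offsets = [v.offset_days for v in self.visits]
        if offsets and offsets[0] != 0:
            raise ValueError("baseline visit must have offset 0")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("visit offsets must be strictly increasing")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site identifiers must be unique")
        for form in self.forms:
            if form.status_field and form.status_field not in form.field_names():
                raise ValueError(f"status field {form.status_field!r} missing from form {form.form_id!r}")

    # -- lookups -----------------------------------------------------------

    def form(self, form_id: str) -> FormDef:
        for f in self.forms:
            if f.form_id == form_id:
                return f
        raise KeyError(f"unknown form {form_id!r}")

    def visit(self, name: str) -> VisitDef:
        for v in self.visits:
            if v.name == name:
                return v
        raise KeyError(f"unknown visit {name!r}")

    def visit_order(self, name: str) -> int:
        return [v.name for v in self.visits].index(name)

    def site_center(self, site_id: str) -> str:
        for s in self.sites:
            if s.site_id == site_id:
                return s.center
        raise KeyError(f"unknown site {site_id!r}")

    def instrument_for(self, form_id: str, site_id: str) -> str:
        """Survey delivery instrument: PROs go through REDCap at MCC1 sites and
        MyDataHelps at MCC2 sites; CRFs are collected in person."""
        form = self.form(form_id)
        if form.kind == "PRO":
            return "REDCap" if self.site_center(site_id) == "MCC1" else "MyDataHelps"
        return "in-person"

    def field_columns(self) -> list[str]:
        cols: list[str] = []
        for form in self.forms:
            cols.extend(form.field_names())
        return cols

    def field_form(self) -> dict[str, str]:
        """Mapping field name -> owning form id."""
        return {name: form.form_id for form in self.forms for name in form.field_names()}

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "sites": [{"site_id": s.site_id, "center": s.center} for s in self.sites],
            "cohorts": list(self.cohorts),
            "visits": [{"name": v.name, "offset_days": v.offset_days} for v in self.visits],
            "forms": [
                {
                    "form_id": f.form_id,
                    "kind": f.kind,
                    "domain": f.domain,
                    "status_field": f.status_field,
                    "applicability": f.applicability.to_string(),
                    "fields": [
                        {
                            "name": fd.name,
                            "value_type": fd.value_type,
                            "choices_or_range": fd.choices_or_range(),
                            "required": fd.required,
                        }
                        for fd in f.fields
                    ],
                }
                for f in self.forms
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudySchema":
        doc = yaml.safe_load(Path(path).read_text())
        forms = []
        for f in doc["forms"]:
            fields = tuple(
                _field_from_parts(fd["name"], fd["value_type"], fd.get("choices_or_range", ""), fd.get("required", True))
                for fd in f["fields"]
            )
            forms.append(
                FormDef(
                    form_id=f["form_id"],
                    kind=f.get("kind", "CRF"),
                    domain=f.get("domain", f["form_id"]),
                    fields=fields,
                    applicability=Applicability.from_string(f.get("applicability", "all")),
                    status_field=f.get("status_field", ""),
                )
            )
        return cls(
            sites=tuple(SiteDef(s["site_id"], s["center"]) for s in doc["sites"]),
            cohorts=tuple(doc["cohorts"]),
            visits=tuple(VisitDef(v["name"], int(v["offset_days"])) for v in doc["visits"]),
            forms=tuple(forms),
        )


def _field_from_parts(name: str, value_type: str, choices_or_range: str, required) -> FieldDef:
    choices: tuple[str, ...] | None = None
    lo = hi = None
    cr = (choices_or_range or "").strip()
    if cr:
        if value_type == "numeric" and ":" in cr:
            lo_s, hi_s = cr.split(":", 1)
            lo, hi = float(lo_s), float(hi_s)
        else:
            choices = tuple(c.strip() for c in cr.split("|"))
    if isinstance(required, str):
        required = required.strip().lower() in ("1", "true", "yes", "y")
    return FieldDef(name=name, value_type=value_type, choices=choices, lo=lo, hi=hi, required=bool(required))


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------


class IngestError(ValueError):
    """Fatal problem with an export or dictionary file."""


@dataclass(frozen=True)
class SchemaViolation:
    """One non-fatal ingest problem; never silently dropped."""

    location: str  # row/column of the source file
    rule: str
    detail: str


@dataclass
class IngestResult:
    """Tidy observation table plus the violations found while building it."""

    records: pd.DataFrame
    violations: list[SchemaViolation] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.violations)


DICTIONARY_COLUMNS = ("field_name", "form_name", "field_type", "choices_or_range", "required", "applicability")

#: tidy observation-table columns
RECORD_COLUMNS = (
    "subject_id",
    "site_id",
    "cohort",
    "visit",
    "form_id",
    "field_name",
    "value",
    "entry_timestamp",
    "delivery_instrument",
)


def write_dictionary(schema: StudySchema, path: str | Path) -> None:
    """Write the per-field data dictionary (REDCap-style CSV dialect)."""
    rows = []
    for form in schema.forms:
        for fd in form.fields:
            rows.append(
                {
                    "field_name": fd.name,
                    "form_name": form.form_id,
                    "field_type": fd.value_type,
                    "choices_or_range": fd.choices_or_range(),
                    "required": "yes" if fd.required else "no",
                    "applicability": form.applicability.to_string(),
                    "form_kind": form.kind,
                    "domain": form.domain,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def load_dictionary(
    path: str | Path,
    sites: Sequence[SiteDef] | None = None,
    cohorts: Sequence[str] | None = None,
    visits: Sequence[VisitDef] | None = None,
) -> StudySchema:
    """Build a :class:`StudySchema` from a data-dictionary CSV.

    The dictionary describes fields and forms only; sites, cohorts and the
    visit schedule are taken from the arguments (defaulting to the example
    study's).  Forms without a ``<form>_complete`` field acquire one.
    """
    table = pd.read_csv(path, dtype=str).fillna("")
    mandatory = ("field_name", "form_name", "field_type")
    for col in mandatory:
        if col not in table.columns:
            raise IngestError(f"dictionary is missing mandatory column {col!r}")
    if table["field_name"].duplicated().any():
        dupes = sorted(table.loc[table["field_name"].duplicated(), "field_name"])
        raise IngestError(f"duplicate field_name in dictionary: {dupes}")

    forms: list[FormDef] = []
    for form_id, group in table.groupby("form_name", sort=False):
        fields = [
            _field_from_parts(
                row["field_name"],
                row["field_type"],
                row.get("choices_or_range", ""),
                row.get("required", "yes") or "yes",
            )
            for _, row in group.iterrows()
        ]
        status_field = f"{form_id}_complete"
        if status_field not in [f.name for f in fields]:
            fields.append(FieldDef(status_field, "numeric", lo=0, hi=2, required=False))
        first = group.iloc[0]
        forms.append(
            FormDef(
                form_id=str(form_id),
                kind=str(first.get("form_kind", "") or "CRF"),
                domain=str(first.get("domain", "") or form_id),
                fields=tuple(fields),
                applicability=Applicability.from_string(str(first.get("applicability", "all"))),
                status_field=status_field,
            )
        )

    base = example_schema()
    return StudySchema(
        sites=tuple(sites) if sites is not None else base.sites,
        cohorts=tuple(cohorts) if cohorts is not None else base.cohorts,
        visits=tuple(visits) if visits is not None else base.visits,
        forms=tuple(forms),
    )


def load_records(path: str | Path | io.IOBase, schema: StudySchema) -> IngestResult:
    """Melt a wide flat export into validated tidy observation records.

    One wide row per subject x event; reserved columns ``record_id``,
    ``redcap_event_name``, ``site_id``, ``cohort``, ``event_date`` precede the
    field columns.  Values are coerced to their declared type; uncoercible
    cells are retained as text and reported as :class:`SchemaViolation`.
    """
    wide = pd.read_csv(path, dtype=str).fillna("")
    violations: list[SchemaViolation] = []

    for col in ("record_id", "redcap_event_name"):
        if col not in wide.columns:
            raise IngestError(f"export is missing mandatory column {col!r}")
    dupes = wide.duplicated(subset=["record_id", "redcap_event_name"])
    if dupes.any():
        pairs = wide.loc[dupes, ["record_id", "redcap_event_name"]].values.tolist()
        raise IngestError(f"duplicate (subject, event) rows: {pairs}")

    field_form = schema.field_form()
    declared = [c for c in wide.columns if c in field_form]
    for col in wide.columns:
        if col not in field_form and col not in RESERVED_COLUMNS:
            violations.append(SchemaViolation(f"column {col!r}", "unknown column", "not in dictionary; skipped"))

    rows: list[tuple] = []
    for i, row in wide.iterrows():
        subject = row["record_id"]
        visit = row["redcap_event_name"]
        site = row.get("site_id", "")
        cohort = row.get("cohort", "")
        try:
            entry = dt.date.fromisoformat(row["event_date"]) if row.get("event_date", "") else MISSING
        except ValueError:
            entry = MISSING
            violations.append(SchemaViolation(f"row {i}, column 'event_date'", "bad date", repr(row["event_date"])))
        for col in declared:
            form_id = field_form[col]
            fdef = schema.form(form_id).field(col)
            raw = row[col]
            try:
                value = fdef.coerce(raw)
            except ValueError as exc:
                value = str(raw)  # kept as text
                violations.append(
                    SchemaViolation(f"row {i}, column {col!r}", f"uncoercible {fdef.value_type}", str(exc))
                )
            rows.append(
                (subject, site, cohort, visit, form_id, col, value, entry, schema.instrument_for(form_id, site))
            )

    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    if not records.empty:
        key = records[["subject_id", "visit", "form_id", "field_name"]]
        if key.duplicated().any():  # tidy contract
            raise IngestError("duplicate (subject, visit, form, field) records after melt")
    return IngestResult(records=records, violations=violations)


def applicable_forms(schema: StudySchema, cohort: str, visit: str) -> set[str]:
    """Forms collected for this cohort at this visit; complement is
    "not collected by design"."""
    schema.visit(visit)  # raises on unknown visit
    return {f.form_id for f in schema.forms if f.applicability.applies(cohort, visit)}


# ---------------------------------------------------------------------------
# example study schema
# ---------------------------------------------------------------------------


def _items(prefix: str, n: int, hi: float) -> list[FieldDef]:
    return [FieldDef(f"{prefix}_item_{i}", "numeric", lo=0, hi=hi) for i in range(1, n + 1)]


def example_schema() -> StudySchema:
    """Illustrative two-center study schema.

    Four sites (two per center), two surgical cohorts (total knee
    arthroplasty and thoracic surgery), four visits, five data domains:
    imaging, quantitative sensory testing (QST), functional testing, blood
    collection, and two PRO questionnaires (GAD-7 anxiety, PHQ-9 depression).
    Fields that are only conditionally required (e.g. surgical-site pain when
    a resting-state scan was done, or the reason a test was skipped) are
    marked required=False.
    """
    yn = ("yes", "no")
    ri = ("remote", "index")

    def status(form_id):
        return FieldDef(f"{form_id}_complete", "numeric", lo=0, hi=2, required=False)

    imaging = FormDef(
        "imaging",
        kind="CRF",
        domain="Imaging",
        fields=(
            FieldDef("resting_state_scan", "categorical", choices=yn),
            FieldDef("surgical_site_pain", "numeric", lo=0, hi=10, required=False),
            FieldDef("surgical_site_pain_2", "numeric", lo=0, hi=10, required=False),
            FieldDef("cuff_pain_initial", "numeric", lo=0, hi=10),
            FieldDef("cuff_pain_mid", "numeric", lo=0, hi=10),
            FieldDef("overall_image_quality", "numeric", lo=1, hi=5),
            status("imaging"),
        ),
        status_field="imaging_complete",
    )
    qst = FormDef(
        "qst",
        kind="CRF",
        domain="QST",
        fields=(
            FieldDef("ppt_remote_rating", "numeric", lo=0, hi=10),
            FieldDef("ppt_remote_rating_2", "numeric", lo=0, hi=10),
            FieldDef("ppt_performed_site", "categorical", choices=ri),
            FieldDef("ppt_entered_site", "categorical", choices=ri),
            FieldDef("ppt_index_rating", "numeric", lo=0, hi=10),
            status("qst"),
        ),
        status_field="qst_complete",
    )
    functional = FormDef(
        "functional_testing",
        kind="CRF",
        domain="FunctionalTesting",
        fields=(
            FieldDef("initial_pain_rating_1", "numeric", lo=0, hi=10),
            FieldDef("initial_pain_rating_2", "numeric", lo=0, hi=10),
            FieldDef("test_completed", "categorical", choices=yn),
            FieldDef("incomplete_reason", "text", required=False),
            FieldDef("walk_test_distance", "numeric", lo=0, hi=1000),
            status("functional_testing"),
        ),
        status_field="functional_testing_complete",
    )
    blood = FormDef(
        "blood_collection",
        kind="CRF",
        domain="BloodCollection",
        fields=(
            FieldDef("vaccination_status", "categorical", choices=yn),
            FieldDef("blood_draw_time", "time"),
            FieldDef("centrifuge_time", "time"),
            FieldDef("freezer_time", "time"),
            status("blood_collection"),
        ),
        applicability=Applicability(visits=frozenset({"baseline", "post-op"})),
        status_field="blood_collection_complete",
    )
    gad7 = FormDef(
        "gad7",
        kind="PRO",
        domain="PRO-GAD7",
        fields=tuple(_items("gad7", 7, 3)) + (status("gad7"),),
        applicability=Applicability(visits=frozenset({"baseline", "3-month", "6-month"})),
        status_field="gad7_complete",
    )
    phq9 = FormDef(
        "phq9",
        kind="PRO",
        domain="PRO-PHQ9",
        fields=tuple(_items("phq9", 9, 3)) + (status("phq9"),),
        applicability=Applicability(visits=frozenset({"baseline", "3-month", "6-month"})),
        status_field="phq9_complete",
    )

    return StudySchema(
        sites=(
            SiteDef("MCC1-A", "MCC1"),
            SiteDef("MCC1-B", "MCC1"),
            SiteDef("MCC2-A", "MCC2"),
            SiteDef("MCC2-B", "MCC2"),
        ),
        cohorts=("TKA", "thoracic"),
        visits=(
            VisitDef("baseline", 0),
            VisitDef("post-op", 14),
            VisitDef("3-month", 90),
            VisitDef("6-month", 180),
        ),
        forms=(imaging, qst, functional, blood, gad7, phq9),
    )
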