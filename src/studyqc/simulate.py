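"""Synthetic multi-site longitudinal study generator with error injection.

Generates a complete study — enrollment across sites and calendar months,
visit schedule, clean form data — and then injects data-quality violations
one edit check at a time, recording every perturbation in a ground-truth
injection log.  The emitted files use the same wide CSV / dictionary dialect
the ingest layer reads, so the whole pipeline is testable end to end without
any external data.

The baseline per-check injection probability decays geometrically by
calendar month (``p * (1 - monthly_decay) ** month``), emulating a study
whose error rate falls as site feedback and training take hold.  Missingness
on patient-reported outcomes is driven by a per-delivery-instrument
probability instead, so instrument comparisons can be simulated with matched
or unmatched rates.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .checks import CheckDefinition, default_registry, write_registry
from .schema import (
    RESERVED_COLUMNS,
    FieldDef,
    FormDef,
    IngestResult,
    StudySchema,
    example_schema,
    load_records,
    write_dictionary,
)

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "add_months", "months_between"]


def add_months(date: dt.date, n: int) -> dt.date:
    """Calendar-month shift, clamping the day to the target month's end."""
    month = date.month - 1 + n
    year = date.year + month // 12
    month = month % 12 + 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def months_between(start: dt.date, end: dt.date) -> int:
    """Whole calendar months from start's month to end's month."""
    return (end.year - start.year) * 12 + (end.month - start.month)


_REASONS = ("equipment failure", "scheduling conflict", "participant declined")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a modest two-center study: four sites enrolling four
    subjects per month each for a year, observed a year after enrollment
    began, with a sixty-forty knee-arthroplasty/thoracic cohort mix, a few
    percent of forms left incomplete or with an unrecorded completion status,
    and per-check error rates that decay ten percent per calendar month.
    """

    seed: int = 0
    study_start: dt.date = dt.date(2024, 9, 1)
    as_of: dt.date = dt.date(2025, 9, 1)
    months_of_enrollment: int = 12
    enrollment_per_site_per_month: int = 4
    cohort_mix: float = 0.6  # P(TKA)
    injection_prob: float = 0.08  # baseline per-check probability
    injection_probs: dict = dc_field(default_factory=dict)  # per-check overrides
    monthly_decay: float = 0.10  # r in p*(1-r)^month
    pro_missing_prob: dict = dc_field(default_factory=lambda: {"REDCap": 0.06, "MyDataHelps": 0.06})
    incomplete_prob: float = 0.08
    unknown_status_prob: float = 0.03
    visit_day_jitter: int = 4  # max days a follow-up visit slips past nominal

    def __post_init__(self):
        if isinstance(self.study_start, str):
            self.study_start = dt.date.fromisoformat(self.study_start)
        if isinstance(self.as_of, str):
            self.as_of = dt.date.fromisoformat(self.as_of)
        probs = [self.injection_prob, self.monthly_decay, self.incomplete_prob,
                 self.unknown_status_prob, self.cohort_mix, *self.pro_missing_prob.values(),
                 *self.injection_probs.values()]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0.0 <= self.monthly_decay < 1.0:
            raise ValueError("monthly_decay must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


LOG_COLUMNS = ("subject_id", "site_id", "cohort", "visit", "form_id", "domain", "check_id", "perturbation")


@dataclass
class SimulatedStudy:
    """Wide export, schema, check registry and ground-truth injection log."""

    config: SimulationConfig
    schema: StudySchema
    registry: list[CheckDefinition]
    wide: pd.DataFrame  # one row per subject x event, string cells
    injection_log: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write records.csv, dictionary.csv, schema.yaml, registry.yaml and
        injection_log.csv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": outdir / "records.csv",
            "dictionary": outdir / "dictionary.csv",
            "schema": outdir / "schema.yaml",
            "registry": outdir / "registry.yaml",
            "injection_log": outdir / "injection_log.csv",
        }
        self.wide.to_csv(paths["records"], index=False, lineterminator="\n")
        write_dictionary(self.schema, paths["dictionary"])
        self.schema.to_yaml(paths["schema"])
        write_registry(self.registry, paths["registry"])
        self.injection_log.to_csv(paths["injection_log"], index=False, lineterminator="\n")
        return paths

    def ingest(self) -> IngestResult:
        """Melt the wide table through the same path file loading uses."""
        import io

        buffer = io.StringIO()
        self.wide.to_csv(buffer, index=False, lineterminator="\n")
        buffer.seek(0)
        return load_records(buffer, self.schema)


# ---------------------------------------------------------------------------
# clean value generation
# ---------------------------------------------------------------------------


def _draw_value(fdef: FieldDef, rng: np.random.Generator, event_date: dt.date) -> str:
    if fdef.value_type == "numeric":
        lo = int(fdef.lo) if fdef.lo is not None else 0
        hi = int(fdef.hi) if fdef.hi is not None else 100
        return str(int(rng.integers(lo, hi + 1)))
    if fdef.value_type == "categorical":
        choices = fdef.choices or ("yes", "no")
        return str(choices[int(rng.integers(len(choices)))])
    if fdef.value_type == "time":
        minutes = 8 * 60 + int(rng.integers(0, 300))
        return f"{minutes // 60:02d}:{minutes % 60:02d}"
    if fdef.value_type == "date":
        return event_date.isoformat()
    return str(_REASONS[int(rng.integers(len(_REASONS)))])


def _fill_form(
    form: FormDef,
    row: dict,
    rng: np.random.Generator,
    event_date: dt.date,
    complete: bool,
    registry: list[CheckDefinition],
) -> None:
    """Fill a form instance with clean (check-passing) values in place."""
    for fdef in form.fields:
        if fdef.name == form.status_field:
            continue
        fill = fdef.required if complete else rng.random() < 0.5
        if not fdef.required and complete:
            fill = rng.random() < 0.5  # optional fields present about half the time
        row[fdef.name] = _draw_value(fdef, rng, event_date) if fill else ""

    # enforce every check's clean-data constraint
    for check in (c for c in registry if c.form_id == form.form_id):
        p = check.params
        if check.kind == "pair_mismatch":
            a, b = row.get(p["field_a"], ""), row.get(p["field_b"], "")
            if a and b:
                row[p["field_b"]] = a
        elif check.kind == "chronology":
            present = [f for f in p["fields"] if row.get(f, "")]
            for name, value in zip(present, sorted(row[f] for f in present)):
                row[name] = value
        elif check.kind == "location_mismatch":
            a, b = row.get(p["performed_site_field"], ""), row.get(p["entered_site_field"], "")
            if a and b:
                row[p["entered_site_field"]] = a
        elif check.kind == "reason_unspecified":
            if row.get(p["completed_field"], "") == "no" and not row.get(p["reason_field"], ""):
                row[p["reason_field"]] = str(_REASONS[int(rng.integers(len(_REASONS)))])
        elif check.kind == "conditional_missingness":
            if row.get(p["trigger_field"], "") == p["trigger_value"]:
                for name in p["dependent_fields"]:
                    if not row.get(name, ""):
                        row[name] = _draw_value(form.field(name), rng, event_date)
        elif check.kind == "missingness" and complete:
            for name in p["fields"]:
                if not row.get(name, ""):
                    row[name] = _draw_value(form.field(name), rng, event_date)


# ---------------------------------------------------------------------------
# perturbations — each makes its check (and only its check) fire
# ---------------------------------------------------------------------------


def _other_choice(fdef: FieldDef, current: str, rng: np.random.Generator) -> str:
    options = [c for c in (fdef.choices or ()) if c != current]
    return str(options[int(rng.integers(len(options)))])


def _bump_numeric(fdef: FieldDef, current: str, tolerance: float) -> str:
    value = float(current)
    step = tolerance + 1.0
    bumped = value + step if fdef.hi is None or value + step <= fdef.hi else value - step
    return str(int(bumped)) if bumped == int(bumped) else str(bumped)


def _shift_time_back(value: str) -> str:
    hh, mm = map(int, value.split(":"))
    minutes = max(hh * 60 + mm - 10, 0)
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def _perturb(
    check: CheckDefinition, form: FormDef, row: dict, rng: np.random.Generator, event_date: dt.date
) -> str:
    """Apply the violation for one check to a clean complete instance.

    Establishes the check's own precondition (fills its fields if blank), then
    breaks its rule.  Checks within a form reference disjoint fields, so
    multiple perturbations on the same instance compose without interference.
    """
    p = check.params

    def ensure(name: str) -> str:
        if not row.get(name, ""):
            row[name] = _draw_value(form.field(name), rng, event_date)
        return row[name]

    if check.kind == "missingness":
        target = p["fields"][int(rng.integers(len(p["fields"])))]
        row[target] = ""
        return f"blanked {target}"
    if check.kind == "pair_mismatch":
        a = ensure(p["field_a"])
        fdef = form.field(p["field_b"])
        row[p["field_b"]] = (
            _bump_numeric(fdef, a, float(p.get("tolerance", 0.0)))
            if fdef.value_type == "numeric"
            else _other_choice(fdef, a, rng)
        )
        return f"set {p['field_b']}={row[p['field_b']]} vs {p['field_a']}={a}"
    if check.kind == "conditional_missingness":
        row[p["trigger_field"]] = p["trigger_value"]
        for name in p["dependent_fields"]:
            ensure(name)
        target = p["dependent_fields"][int(rng.integers(len(p["dependent_fields"])))]
        row[target] = ""
        return f"set {p['trigger_field']}={p['trigger_value']}, blanked {target}"
    if check.kind == "chronology":
        fields = p["fields"]
        for name in fields:
            ensure(name)
        i = int(rng.integers(len(fields) - 1))
        row[fields[i + 1]] = _shift_time_back(row[fields[i]])
        return f"set {fields[i + 1]} before {fields[i]}"
    if check.kind == "location_mismatch":
        performed = ensure(p["performed_site_field"])
        row[p["entered_site_field"]] = _other_choice(form.field(p["entered_site_field"]), performed, rng)
        return f"entered site {row[p['entered_site_field']]} vs performed {performed}"
    # reason_unspecified
    row[p["completed_field"]] = "no"
    row[p["reason_field"]] = ""
    return f"set {p['completed_field']}=no, blanked {p['reason_field']}"


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate_study(
    config: SimulationConfig,
    schema: StudySchema | None = None,
    registry: list[CheckDefinition] | None = None,
) -> SimulatedStudy:
    """Generate a full study: clean data first, then per-check injection.

    Three independent pseudo-random streams (enrollment, values, injection)
    are spawned from the master seed so adding draws to one concern cannot
    shift the others.  The same seed and config always produce byte-identical
    output files.
    """
    schema = schema or example_schema()
    registry = default_registry(schema) if registry is None else registry
    for check in registry:
        check.validate(schema)  # schema/check mismatch fails before generation

    ss = np.random.SeedSequence(config.seed)
    rng_enroll, rng_values, rng_inject = (np.random.default_rng(s) for s in ss.spawn(3))

    field_columns = schema.field_columns()
    by_form: dict[str, list[CheckDefinition]] = {}
    for check in registry:
        by_form.setdefault(check.form_id, []).append(check)

    wide_rows: list[dict] = []
    log_rows: list[dict] = []
    counter = 0
    for site in schema.sites:
        for month in range(config.months_of_enrollment):
            month_start = add_months(config.study_start, month)
            days_in_month = calendar.monthrange(month_start.year, month_start.month)[1]
            for _ in range(config.enrollment_per_site_per_month):
                counter += 1
                subject = f"{site.site_id}-{counter:04d}"
                day = int(rng_enroll.integers(0, days_in_month))
                baseline = dt.date(month_start.year, month_start.month, 1) + dt.timedelta(days=day)
                cohort = "TKA" if rng_enroll.random() < config.cohort_mix else "thoracic"
                for visit in schema.visits:
                    jitter = 0 if visit.offset_days == 0 else int(rng_enroll.integers(0, config.visit_day_jitter + 1))
                    event_date = baseline + dt.timedelta(days=visit.offset_days + jitter)
                    if event_date > config.as_of:
                        continue
                    row = {col: "" for col in (*RESERVED_COLUMNS, *field_columns)}
                    row.update(
                        record_id=subject,
                        redcap_event_name=visit.name,
                        site_id=site.site_id,
                        cohort=cohort,
                        event_date=event_date.isoformat(),
                    )
                    elapsed_months = months_between(config.study_start, event_date)
                    decay = (1.0 - config.monthly_decay) ** elapsed_months
                    for form in schema.forms:
                        if not form.applicability.applies(cohort, visit.name):
                            continue
                        u = rng_values.random()
                        if u < config.unknown_status_prob:
                            status, complete = "", False
                            _fill_form(form, row, rng_values, event_date, True, registry)
                        elif u < config.unknown_status_prob + config.incomplete_prob:
                            status, complete = str(int(rng_values.integers(0, 2))), False
                            _fill_form(form, row, rng_values, event_date, False, registry)
                        else:
                            status, complete = "2", True
                            _fill_form(form, row, rng_values, event_date, True, registry)
                        row[form.status_field] = status
                        if not complete:
                            continue
                        instrument = schema.instrument_for(form.form_id, site.site_id)
                        for check in by_form.get(form.form_id, []):
                            if check.kind == "missingness" and form.kind == "PRO":
                                base_p = config.pro_missing_prob.get(instrument, config.injection_prob)
                            else:
                                base_p = config.injection_probs.get(check.check_id, config.injection_prob)
                            if rng_inject.random() < base_p * decay:
                                perturbation = _perturb(check, form, row, rng_inject, event_date)
                                log_rows.append(
                                    {
                                        "subject_id": subject,
                                        "site_id": site.site_id,
                                        "cohort": cohort,
                                        "visit": visit.name,
                                        "form_id": form.form_id,
                                        "domain": form.domain,
                                        "check_id": check.check_id,
                                        "perturbation": perturbation,
                                    }
                                )
                    wide_rows.append(row)

    wide = pd.DataFrame(wide_rows, columns=[*RESERVED_COLUMNS, *field_columns])
    log = pd.DataFrame(log_rows, columns=list(LOG_COLUMNS))
    return SimulatedStudy(config=config, schema=schema, registry=registry, wide=wide, injection_log=log)
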