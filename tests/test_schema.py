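"""Schema construction, dictionary/record ingest and applicability."""

import datetime as dt
import io

import pytest

from studyqc.schema import (
    Applicability,
    FieldDef,
    FormDef,
    IngestError,
    SiteDef,
    StudySchema,
    VisitDef,
    applicable_forms,
    example_schema,
    load_dictionary,
    load_records,
    write_dictionary,
)


def tiny_schema():
    """One form, five fields, two visits — enough for ingest arithmetic."""
    fields = (
        FieldDef("age", "numeric", lo=0, hi=120),
        FieldDef("color", "categorical", choices=("red", "blue")),
        FieldDef("when", "date"),
        FieldDef("note", "text", required=False),
        FieldDef("demo_complete", "numeric", lo=0, hi=2, required=False),
    )
    form = FormDef("demo", fields=fields, domain="Demo", status_field="demo_complete")
    return StudySchema(
        sites=(SiteDef("MCC1-A", "MCC1"),),
        cohorts=("TKA", "thoracic"),
        visits=(VisitDef("baseline", 0), VisitDef("3-month", 90)),
        forms=(form,),
    )


def wide_csv(rows):
    header = "record_id,redcap_event_name,site_id,cohort,event_date,age,color,when,note,demo_complete\n"
    return io.StringIO(header + "\n".join(rows) + "\n")


class TestSchemaInvariants:
    def test_visit_offsets_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            StudySchema(
                sites=(SiteDef("a", "MCC1"),),
                cohorts=("TKA",),
                visits=(VisitDef("baseline", 0), VisitDef("v1", 30), VisitDef("v2", 30)),
                forms=tiny_schema().forms,
            )

    def test_baseline_offset_zero(self):
        with pytest.raises(ValueError, match="offset 0"):
            StudySchema(
                sites=(SiteDef("a", "MCC1"),),
                cohorts=("TKA",),
                visits=(VisitDef("baseline", 7),),
                forms=tiny_schema().forms,
            )

    def test_duplicate_sites_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            StudySchema(
                sites=(SiteDef("a", "MCC1"), SiteDef("a", "MCC2")),
                cohorts=("TKA",),
                visits=(VisitDef("baseline", 0),),
                forms=tiny_schema().forms,
            )

    def test_form_needs_fields(self):
        with pytest.raises(ValueError, match="no fields"):
            FormDef("empty")

    def test_instrument_assignment(self):
        schema = example_schema()
        assert schema.instrument_for("gad7", "MCC1-A") == "REDCap"
        assert schema.instrument_for("gad7", "MCC2-A") == "MyDataHelps"
        assert schema.instrument_for("imaging", "MCC1-A") == "in-person"


class TestDictionary:
    def test_round_trip_preserves_forms(self, tmp_path):
        schema = example_schema()
        path = tmp_path / "dictionary.csv"
        write_dictionary(schema, path)
        loaded = load_dictionary(path)
        assert loaded.forms == schema.forms

    def test_yaml_round_trip_is_identity(self, tmp_path):
        schema = example_schema()
        path = tmp_path / "schema.yaml"
        schema.to_yaml(path)
        assert StudySchema.from_yaml(path) == schema

    def test_missing_mandatory_column_named(self, tmp_path):
        path = tmp_path / "dictionary.csv"
        path.write_text("field_name,form_name\nage,demo\n")
        with pytest.raises(IngestError, match="field_type"):
            load_dictionary(path)

    def test_duplicate_field_rejected(self, tmp_path):
        path = tmp_path / "dictionary.csv"
        path.write_text("field_name,form_name,field_type\nage,demo,numeric\nage,demo,numeric\n")
        with pytest.raises(IngestError, match="duplicate"):
            load_dictionary(path)

    def test_status_field_auto_appended(self, tmp_path):
        path = tmp_path / "dictionary.csv"
        path.write_text("field_name,form_name,field_type\nage,demo,numeric\n")
        schema = load_dictionary(path)
        assert schema.form("demo").status_field == "demo_complete"
        assert "demo_complete" in schema.form("demo").field_names()


class TestLoadRecords:
    def test_cell_count_conserved(self):
        rows = [
            "s1,baseline,MCC1-A,TKA,2024-09-01,50,red,2024-09-01,hello,2",
            "s1,3-month,MCC1-A,TKA,2024-12-01,50,blue,2024-12-01,,2",
            "s2,baseline,MCC1-A,thoracic,2024-09-02,61,red,2024-09-02,,2",
            "s2,3-month,MCC1-A,thoracic,2024-12-02,61,blue,2024-12-02,x,2",
        ]
        result = load_records(wide_csv(rows), tiny_schema())
        assert len(result.records) == 4 * 5  # rows x declared fields
        assert result.n_violations == 0
        # tidy uniqueness
        key = result.records[["subject_id", "visit", "form_id", "field_name"]]
        assert not key.duplicated().any()

    def test_uncoercible_value_kept_as_text(self):
        rows = ["s1,baseline,MCC1-A,TKA,2024-09-01,abc,red,2024-09-01,,2"]
        result = load_records(wide_csv(rows), tiny_schema())
        assert result.n_violations == 1
        assert "age" in result.violations[0].location
        kept = result.records.query("field_name == 'age'")["value"].iloc[0]
        assert kept == "abc"

    def test_duplicate_subject_event_rejected(self):
        rows = [
            "s1,baseline,MCC1-A,TKA,2024-09-01,50,red,2024-09-01,,2",
            "s1,baseline,MCC1-A,TKA,2024-09-01,51,red,2024-09-01,,2",
        ]
        with pytest.raises(IngestError, match="duplicate"):
            load_records(wide_csv(rows), tiny_schema())

    def test_unknown_column_is_warning_violation(self):
        header = "record_id,redcap_event_name,site_id,cohort,event_date,age,color,when,note,demo_complete,mystery\n"
        body = "s1,baseline,MCC1-A,TKA,2024-09-01,50,red,2024-09-01,,2,77\n"
        result = load_records(io.StringIO(header + body), tiny_schema())
        assert any(v.rule == "unknown column" for v in result.violations)
        assert "mystery" not in set(result.records["field_name"])

    def test_typed_values(self):
        rows = ["s1,baseline,MCC1-A,TKA,2024-09-01,50,red,2024-09-03,,2"]
        records = load_records(wide_csv(rows), tiny_schema()).records
        values = records.set_index("field_name")["value"]
        assert values["age"] == 50.0
        assert values["when"] == dt.date(2024, 9, 3)
        assert records["entry_timestamp"].iloc[0] == dt.date(2024, 9, 1)


class TestApplicability:
    def test_universal_form_everywhere(self, schema):
        for cohort in schema.cohorts:
            for visit in schema.visits:
                assert "imaging" in applicable_forms(schema, cohort, visit.name)

    def test_cohort_restricted_form_excluded(self):
        base = tiny_schema()
        thoracic_only = FormDef(
            "chest",
            fields=(FieldDef("pain", "numeric"), FieldDef("chest_complete", "numeric", required=False)),
            applicability=Applicability(cohorts=frozenset({"thoracic"})),
            status_field="chest_complete",
        )
        schema = StudySchema(base.sites, base.cohorts, base.visits, base.forms + (thoracic_only,))
        assert "chest" not in applicable_forms(schema, "TKA", "baseline")
        assert "chest" in applicable_forms(schema, "thoracic", "baseline")

    def test_mixed_predicates_match_hand_enumeration(self):
        base = tiny_schema()
        forms = (
            FormDef("all_f", fields=(FieldDef("a1"), FieldDef("all_f_complete", "numeric", required=False)),
                    status_field="all_f_complete"),
            FormDef("base_only", fields=(FieldDef("b1"), FieldDef("base_only_complete", "numeric", required=False)),
                    applicability=Applicability(visits=frozenset({"baseline"})),
                    status_field="base_only_complete"),
            FormDef("tka_only", fields=(FieldDef("t1"), FieldDef("tka_only_complete", "numeric", required=False)),
                    applicability=Applicability(cohorts=frozenset({"TKA"})),
                    status_field="tka_only_complete"),
            FormDef("tka_base", fields=(FieldDef("tb1"), FieldDef("tka_base_complete", "numeric", required=False)),
                    applicability=Applicability(visits=frozenset({"baseline"}), cohorts=frozenset({"TKA"})),
                    status_field="tka_base_complete"),
        )
        schema = StudySchema(base.sites, base.cohorts, base.visits, forms)
        assert applicable_forms(schema, "TKA", "baseline") == {"all_f", "base_only", "tka_only", "tka_base"}
        assert applicable_forms(schema, "TKA", "3-month") == {"all_f", "tka_only"}
        assert applicable_forms(schema, "thoracic", "baseline") == {"all_f", "base_only"}
        assert applicable_forms(schema, "thoracic", "3-month") == {"all_f"}

    def test_unknown_visit_raises(self, schema):
        with pytest.raises(KeyError):
            applicable_forms(schema, "TKA", "12-month")


class TestSimulatorContract:
    def test_simulator_output_ingests_cleanly(self, records):
        assert not records.empty  # the fixture asserts zero violations

    def test_file_round_trip_reproduces_records(self, study, records, tmp_path):
        paths = study.write(tmp_path)
        loaded = load_dictionary(paths["dictionary"])
        assert loaded.forms == study.schema.forms
        rereads = load_records(paths["records"], study.schema)
        assert rereads.n_violations == 0
        assert rereads.records.equals(records)
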