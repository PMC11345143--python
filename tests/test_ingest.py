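import pytest

from faerspv.ingest import (
    assemble_cases,
    deduplicate_cases,
    filter_target_reports,
    parse_faers_table,
)
from faerspv.term_model import builtin_synonym_map


def _write(tmp_path, name, lines):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParse:
    def test_row_count_preserved(self, tmp_path):
        path = _write(tmp_path, "DEMO24Q1.txt", [
            "primaryid$caseid$fda_dt$age",
            "101$1$20200101$45",
            "102$2$20200102$",
            "103$3$20200103$77",
        ])
        records, skipped = parse_faers_table(path, "DEMO")
        assert len(records) == 3 and skipped == 0
        assert records[1]["age"] is None  # empty field -> missing

    def test_malformed_row_skipped_and_counted(self, tmp_path):
        path = _write(tmp_path, "DEMO.txt", [
            "primaryid$caseid$fda_dt",
            "101$1$20200101",
            "102$2",  # wrong field count
        ])
        records, skipped = parse_faers_table(path, "DEMO")
        assert len(records) == 1 and skipped == 1

    def test_missing_required_column_is_hard_error(self, tmp_path):
        path = _write(tmp_path, "DEMO.txt", ["primaryid$fda_dt", "101$20200101"])
        with pytest.raises(ValueError, match="caseid"):
            parse_faers_table(path, "DEMO")

    def test_drug_role_code_carried_through(self, tmp_path):
        path = _write(tmp_path, "DRUG.txt", [
            "primaryid$caseid$drug_seq$role_cod$drugname",
            "101$1$1$PS$LOVENOX",
        ])
        records, _ = parse_faers_table(path, "DRUG")
        assert records[0]["role_cod"] == "PS"


class TestDeduplicate:
    def test_latest_fda_dt_kept(self):
        recs = [
            {"primaryid": "70", "caseid": "7", "fda_dt": "20200101"},
            {"primaryid": "72", "caseid": "7", "fda_dt": "20210101"},
        ]
        kept, report = deduplicate_cases(recs)
        assert [r["primaryid"] for r in kept] == ["72"]
        assert report.removed_primaryids == [70]

    def test_tie_broken_by_max_primaryid(self):
        recs = [
            {"primaryid": "70", "caseid": "7", "fda_dt": "20200101"},
            {"primaryid": "71", "caseid": "7", "fda_dt": "20200101"},
        ]
        kept, _ = deduplicate_cases(recs)
        # brute-force oracle: sort all versions by (fda_dt, primaryid), keep last
        oracle = sorted(recs, key=lambda r: (r["fda_dt"], int(r["primaryid"])))[-1]
        assert kept == [oracle]

    def test_no_duplicates_is_identity(self):
        recs = [
            {"primaryid": str(100 + i), "caseid": str(i), "fda_dt": "20200101"}
            for i in range(10)
        ]
        kept, report = deduplicate_cases(recs)
        assert report.n_kept == 10 and report.removed_primaryids == []

    def test_primaryid_key_disables_collapsing(self):
        recs = [
            {"primaryid": "70", "caseid": "7", "fda_dt": "20200101"},
            {"primaryid": "71", "caseid": "7", "fda_dt": "20210101"},
        ]
        kept, report = deduplicate_cases(recs, key="primaryid")
        assert report.n_kept == 2 and report.removed_primaryids == []
        with pytest.raises(ValueError, match="dedup key"):
            deduplicate_cases(recs, key="fda_dt")

    def test_idempotent_and_counts_distinct_caseids(self):
        recs = [
            {"primaryid": str(i), "caseid": str(i % 4), "fda_dt": f"202001{i + 1:02d}"}
            for i in range(12)
        ]
        kept, _ = deduplicate_cases(recs)
        assert len(kept) == 4  # distinct caseids
        again, report2 = deduplicate_cases(kept)
        assert again == kept and report2.removed_primaryids == []


class TestAssemble:
    def _tables(self):
        demo = [{"primaryid": "101", "caseid": "1", "fda_dt": "20200101",
                 "age": "54", "age_cod": "YR", "sex": "F"}]
        drug = [{"primaryid": "101", "drug_seq": "1", "role_cod": "PS",
                 "drugname": "LOVENOX", "route": "SUBCUTANEOUS"}]
        reac = [{"primaryid": "101", "pt": "10071408"},
                {"primaryid": "101", "pt": "10071408"},
                {"primaryid": "999", "pt": "10071408"}]  # orphan
        return demo, drug, reac

    def test_within_report_reaction_dedup_and_orphan_drop(self):
        demo, drug, reac = self._tables()
        cases = assemble_cases(demo, drug, reac, [], [], [], builtin_synonym_map())
        assert len(cases) == 1
        assert cases[0].reactions == (10071408,)
        assert cases[0].drugs[0].ingredient == "enoxaparin"

    def test_report_without_reactions_excluded(self):
        demo, drug, _ = self._tables()
        assert assemble_cases(demo, drug, [], [], [], [], None) == []

    def test_age_unit_conversion(self):
        demo = [{"primaryid": "1", "caseid": "1", "fda_dt": "20200101",
                 "age": "6", "age_cod": "MON"}]
        reac = [{"primaryid": "1", "pt": "123"}]
        (case,) = assemble_cases(demo, [], reac, [], [], [], None)
        assert case.age_years == pytest.approx(0.5)

    def test_joined_counts_match_generator_manifest(self, small_bundle, assembled_cases):
        total = sum(len(c.reactions) for c in assembled_cases)
        assert total == small_bundle.manifest.totals["n_events"]


class TestFilterTarget:
    def test_ps_role_required(self, assembled_cases, small_bundle):
        targets = small_bundle.dictionary.synonyms.target_ingredients
        selected = filter_target_reports(assembled_cases, targets)
        manifest_targets = {
            pid
            for pid, rec in small_bundle.manifest.case_labels.items()
            if rec["is_target"]
        }
        assert {c.primaryid for c in selected} == manifest_targets

    def test_concomitant_only_excluded(self):
        from faerspv.ingest import DrugEntry, ReportCase

        case = ReportCase(primaryid=1, caseid=1, fda_dt="20200101",
                          reactions=(1,),
                          drugs=[DrugEntry("LOVENOX", "enoxaparin", "C")])
        assert filter_target_reports([case], {"enoxaparin"}) == []

    def test_idempotent(self, assembled_cases, small_bundle):
        targets = small_bundle.dictionary.synonyms.target_ingredients
        once = filter_target_reports(assembled_cases, targets)
        assert filter_target_reports(once, targets) == once

    def test_empty_target_set_is_error(self, assembled_cases):
        with pytest.raises(ValueError):
            filter_target_reports(assembled_cases, set())
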