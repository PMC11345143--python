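import pytest

from faerspv.cohort_pregnancy import (
    DEFINITIVE,
    EXCLUDED,
    NON_PREGNANCY,
    OTHER,
    CohortConfig,
    build_cohort,
    classify_pregnancy,
    flag_smq_events,
    flag_smq_indications,
)
from faerspv.ingest import DrugEntry, ReportCase
from faerspv.term_model import builtin_dictionary


def make_case(reactions=(), indications=(), route="SUBCUTANEOUS",
              age=30.0, sex="F", pid=1):
    return ReportCase(
        primaryid=pid, caseid=pid, fda_dt="20200101",
        age_years=age, sex=sex,
        reactions=tuple(reactions), indications=tuple(indications),
        drugs=[DrugEntry("LOVENOX", "enoxaparin", "PS", route=route)],
    )


@pytest.fixture(scope="module")
def dictionary():
    return builtin_dictionary()


class TestSmqFlags:
    def test_event_member_hit(self, dictionary):
        assert flag_smq_events(make_case(reactions=[10071408]), dictionary)

    def test_disjoint_reactions_miss(self, dictionary):
        assert not flag_smq_events(make_case(reactions=[90000001]), dictionary)

    def test_multiple_member_pts_fire_once(self, dictionary):
        case = make_case(reactions=[10071408, 10073513, 10000210])
        assert flag_smq_events(case, dictionary) is True

    def test_indication_member_hit(self, dictionary):
        assert flag_smq_indications(make_case(indications=[10071408]), dictionary)

    def test_empty_indications_miss(self, dictionary):
        assert not flag_smq_indications(make_case(), dictionary)

    def test_event_only_smq_member_not_in_indication_list(self, dictionary):
        # a PT that is a member only of event SMQs must not fire the
        # indication flag; verified against the fixture dictionary sets
        indi_members = dictionary.smq_members(dictionary.pregnancy.indication_smqs)
        event_members = dictionary.smq_members(dictionary.pregnancy.event_smqs)
        only_event = sorted(event_members - indi_members)
        assert only_event, "fixture must contain event-only members"
        case = make_case(indications=[only_event[0]])
        assert not flag_smq_indications(case, dictionary)


class TestClassify:
    def test_definitive_pt(self, dictionary):
        label = classify_pregnancy(make_case(reactions=[10071408]),
                                   dictionary.pregnancy)
        assert label.label == DEFINITIVE and "definitive_pt" in label.reasons

    def test_transplacental_route_alone(self, dictionary):
        case = make_case(reactions=[10000210], route="TRANSPLACENTAL")
        label = classify_pregnancy(case, dictionary.pregnancy)
        assert label.label == DEFINITIVE
        assert "transplacental_route" in label.reasons

    def test_paternal_excluded_even_with_definitive_evidence(self, dictionary):
        case = make_case(reactions=[10050425, 10071408])
        label = classify_pregnancy(case, dictionary.pregnancy)
        assert label.label == EXCLUDED and "paternal" in label.reasons

    def test_pediatric_age_excluded(self, dictionary):
        case = make_case(reactions=[10000210], age=7.0)
        label = classify_pregnancy(case, dictionary.pregnancy)
        assert label.label == EXCLUDED and "pediatric" in label.reasons

    def test_smq_only_is_other(self, dictionary):
        label = classify_pregnancy(make_case(reactions=[10000210]),
                                   dictionary.pregnancy)
        assert label.label == OTHER

    def test_male_retained_by_default_excludable_by_config(self, dictionary):
        case = make_case(reactions=[10000210], sex="M")
        assert classify_pregnancy(case, dictionary.pregnancy).label == OTHER
        strict = CohortConfig(exclude_male=True)
        assert classify_pregnancy(case, dictionary.pregnancy, strict).label == EXCLUDED


class TestBuildCohort:
    def test_double_hit_counted_once(self, dictionary):
        case = make_case(reactions=[10000210], indications=[10000210])
        cohort, labels, audit = build_cohort([case], dictionary)
        assert len(cohort) == 1
        assert audit.n_smq_event == audit.n_smq_indication == 1
        assert audit.n_union == 1 and audit.n_final == 1

    def test_all_excluded_gives_empty_cohort(self, dictionary):
        cases = [make_case(reactions=[10050425], pid=i) for i in range(3)]
        cohort, _, audit = build_cohort(cases, dictionary)
        assert cohort == [] and audit.n_final == 0 and audit.n_excluded == 3

    def test_partition_exclusive_and_exhaustive(self, dictionary, assembled_cases):
        _, labels, audit = build_cohort(assembled_cases, dictionary)
        assert len(labels) == len(assembled_cases)
        counts = {DEFINITIVE: 0, OTHER: 0, EXCLUDED: 0, NON_PREGNANCY: 0}
        for label in labels.values():
            counts[label.label] += 1
        assert counts[DEFINITIVE] == audit.n_definitive
        assert counts[EXCLUDED] == audit.n_excluded
        assert audit.n_final == audit.n_definitive + audit.n_other
        assert audit.n_union <= audit.n_smq_event + audit.n_smq_indication

    def test_classification_is_pure(self, dictionary, assembled_cases):
        _, labels1, _ = build_cohort(assembled_cases, dictionary)
        _, labels2, _ = build_cohort(assembled_cases, dictionary)
        assert labels1 == labels2

    def test_manifest_cohort_recovered_exactly(self, dictionary, small_bundle,
                                               assembled_cases):
        cohort, _, audit = build_cohort(assembled_cases, small_bundle.dictionary)
        expected = small_bundle.manifest.pregnancy_primaryids()
        assert {c.primaryid for c in cohort} == expected
        assert audit.n_final == len(expected)
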