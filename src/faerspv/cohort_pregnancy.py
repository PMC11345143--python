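"""SMQ-based retrieval and classification of pregnancy-related reports.

Spontaneous-report databases have no dedicated "pregnant" field, so
pregnancy-related reports are retrieved through standardized MedDRA query
(SMQ) code lists applied to the adverse-event and indication fields, then
partitioned:

* **definitive** — the report carries a maternal/foetal exposure PT or a
  drug administered by the transplacental route;
* **excluded** — paternal-exposure terms, pediatric ages, or demographics
  configured as ineligible;
* **other** — SMQ-retrieved but neither definitive nor excluded.

The final cohort is the union of definitive and other reports, each case
counted once even when both the event and the indication fields matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from faerspv.ingest import ReportCase
from faerspv.term_model import PregnancyTermLists, TermDictionary

__all__ = [
    "CohortLabel",
    "CohortConfig",
    "CohortAudit",
    "flag_smq_events",
    "flag_smq_indications",
    "classify_pregnancy",
    "build_cohort",
]

DEFINITIVE = "definitive"
OTHER = "other"
EXCLUDED = "excluded"
NON_PREGNANCY = "non_pregnancy"


@dataclass(frozen=True)
class CohortLabel:
    """Cohort partition label plus the rule identifiers that fired."""

    label: str
    reasons: frozenset[str]


@dataclass
class CohortConfig:
    """Tunable cohort rules.

    ``pediatric_age_cutoff`` — reports with age strictly below this (years)
    are excluded as pediatric medical care rather than maternal exposure.
    ``exclude_male`` — off by default: male-sex pregnancy reports are
    retained (annotated only), matching the practice of tabulating them as
    presumed sex misreporting rather than dropping them.
    """

    pediatric_age_cutoff: float = 12.0
    exclude_male: bool = False


@dataclass
class CohortAudit:
    n_input: int = 0
    n_smq_event: int = 0
    n_smq_indication: int = 0
    n_union: int = 0
    n_definitive: int = 0
    n_excluded: int = 0
    n_other: int = 0
    n_final: int = 0
    reasons: dict[str, int] = field(default_factory=dict)


def flag_smq_events(case: ReportCase, dictionary: TermDictionary) -> bool:
    """True iff any reaction PT belongs to a pregnancy event SMQ."""
    members = dictionary.smq_members(dictionary.pregnancy.event_smqs)
    return not members.isdisjoint(case.reactions)


def flag_smq_indications(case: ReportCase, dictionary: TermDictionary) -> bool:
    """True iff any indication PT belongs to a pregnancy indication SMQ."""
    members = dictionary.smq_members(dictionary.pregnancy.indication_smqs)
    return not members.isdisjoint(case.indications)


def classify_pregnancy(
    case: ReportCase,
    lists: PregnancyTermLists,
    config: CohortConfig | None = None,
) -> CohortLabel:
    """Partition an SMQ-retrieved case into definitive / other / excluded.

    Exclusion rules are checked first; definitive exposure evidence does not
    override a paternal-exposure or pediatric exclusion.
    """
    config = config or CohortConfig()
    terms = set(case.reactions) | set(case.indications)
    reasons: set[str] = set()

    if terms & lists.paternal_pts:
        reasons.add("paternal")
    if case.age_years is not None and case.age_years < config.pediatric_age_cutoff:
        reasons.add("pediatric")
    if config.exclude_male and case.sex == "M":
        reasons.add("ineligible_demographics")
    if reasons:
        return CohortLabel(EXCLUDED, frozenset(reasons))

    if terms & lists.definitive_pts:
        reasons.add("definitive_pt")
    if any(
        d.route.upper() == lists.transplacental_route.upper() for d in case.drugs
    ):
        reasons.add("transplacental_route")
    if reasons:
        return CohortLabel(DEFINITIVE, frozenset(reasons))
    return CohortLabel(OTHER, frozenset({"smq_only"}))


def build_cohort(
    cases: list[ReportCase],
    dictionary: TermDictionary,
    config: CohortConfig | None = None,
) -> tuple[list[ReportCase], dict[int, CohortLabel], CohortAudit]:
    """Classify every case and return the pregnancy cohort with audit counts.

    Returns ``(cohort_cases, labels_by_primaryid, audit)``. The cohort is
    the union of definitive and other reports; a case matched by both the
    event-field and indication-field SMQ lists appears once.
    """
    config = config or CohortConfig()
    audit = CohortAudit(n_input=len(cases))
    event_members = dictionary.smq_members(dictionary.pregnancy.event_smqs)
    indi_members = dictionary.smq_members(dictionary.pregnancy.indication_smqs)

    labels: dict[int, CohortLabel] = {}
    cohort: list[ReportCase] = []
    for case in cases:
        hit_event = not event_members.isdisjoint(case.reactions)
        hit_indi = not indi_members.isdisjoint(case.indications)
        audit.n_smq_event += hit_event
        audit.n_smq_indication += hit_indi
        if not (hit_event or hit_indi):
            labels[case.primaryid] = CohortLabel(NON_PREGNANCY, frozenset())
            continue
        audit.n_union += 1
        label = classify_pregnancy(case, dictionary.pregnancy, config)
        reasons = set(label.reasons)
        if hit_event:
            reasons.add("smq_event")
        if hit_indi:
            reasons.add("smq_indication")
        label = CohortLabel(label.label, frozenset(reasons))
        labels[case.primaryid] = label
        for reason in label.reasons:
            audit.reasons[reason] = audit.reasons.get(reason, 0) + 1
        if label.label == DEFINITIVE:
            audit.n_definitive += 1
            cohort.append(case)
        elif label.label == OTHER:
            audit.n_other += 1
            cohort.append(case)
        else:
            audit.n_excluded += 1
    audit.n_final = audit.n_definitive + audit.n_other
    return cohort, labels, audit
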