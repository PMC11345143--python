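"""Reading FAERS-dialect quarterly tables and assembling deduplicated cases.

FAERS quarterly data ships as one "$"-delimited ASCII file per table
(DEMO, DRUG, REAC, INDI, THER, OUTC) with a single header row. Records
belonging to one report version share a ``primaryid``; successive versions
of the same case share a ``caseid``. Assembly here follows standard FAERS
practice: keep only the latest version of each case, join child tables on
``primaryid``, normalize drug names through the synonym dictionary, and
restrict the analysis set to reports naming a target ingredient as the
primary suspect (PS) drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from faerspv.term_model import DrugSynonymMap, normalize_drug_name

logger = logging.getLogger("faerspv.ingest")

__all__ = [
    "DrugEntry",
    "ReportCase",
    "DedupReport",
    "TABLE_SCHEMAS",
    "parse_faers_table",
    "deduplicate_cases",
    "assemble_cases",
    "filter_target_reports",
]

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

# Required columns per table kind; extra columns are tolerated and ignored.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "DEMO": ["primaryid", "caseid", "fda_dt"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "INDI": ["primaryid", "indi_pt"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
    "OUTC": ["primaryid", "outc_cod"],
}

# Column-name aliases across FAERS era changes (old name -> canonical).
DEFAULT_ALIASES: dict[str, str] = {
    "isr": "primaryid",
    "case": "caseid",
    "gndr_cod": "sex",
    "pt_code": "pt",
    "indi_pt_code": "indi_pt",
}

_AGE_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report: raw name, normalized ingredient, role, route."""

    raw_name: str
    ingredient: str | None
    role: str
    route: str = "UNK"
    start_dt: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"invalid drug role {self.role!r}")


@dataclass
class ReportCase:
    """A deduplicated safety report with its joined child records."""

    primaryid: int
    caseid: int | None
    fda_dt: str
    event_dt: str | None = None
    age_years: float | None = None
    sex: str = "UNK"
    reporter: str = "UNK"
    country: str = "UNK"
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: tuple[int, ...] = ()
    indications: tuple[int, ...] = ()
    outcomes: frozenset[str] = frozenset()


@dataclass
class DedupReport:
    n_input: int
    n_kept: int
    removed_primaryids: list[int]


def parse_faers_table(
    path: str | Path,
    schema: str,
    aliases: dict[str, str] | None = None,
) -> tuple[list[dict[str, str | None]], int]:
    """Parse one "$"-delimited FAERS table.

    Returns ``(records, n_skipped)``: records as dicts keyed by canonical
    lower-case column names with empty fields mapped to ``None``, and the
    count of malformed rows (wrong field count) that were logged and
    skipped. Dates are kept as their raw digit strings and validated only
    where arithmetic needs them.
    """
    schema = schema.upper()
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {schema!r}")
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(aliases)

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        columns = [
            alias_map.get(c.strip().lower(), c.strip().lower())
            for c in header_line.split("$")
        ]
        missing = [c for c in TABLE_SCHEMAS[schema] if c not in columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        n_cols = len(columns)
        records: list[dict[str, str | None]] = []
        skipped = 0
        for line in fh:
            fields = line.rstrip("\n").split("$")
            if len(fields) != n_cols:
                skipped += 1
                continue
            records.append(
                {c: (v if v != "" else None) for c, v in zip(columns, fields)}
            )
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    logger.info("%s: parsed %d row(s)", path, len(records))
    return records, skipped


def deduplicate_cases(
    demo_records: list[dict],
    key: str = "caseid",
) -> tuple[list[dict], DedupReport]:
    """Keep one DEMO record per case: latest ``fda_dt``, ties to max primaryid.

    ``key`` selects the grouping field: the default ``caseid`` collapses
    successive versions of the same case; ``primaryid`` treats every
    version as distinct (no collapsing), exposed as a sensitivity knob.
    A record missing the key cannot be matched to other versions and is
    treated as its own singleton case (kept, with a warning).
    """
    if key not in ("caseid", "primaryid"):
        raise ValueError(f"dedup key must be caseid or primaryid, got {key!r}")
    best: dict[object, dict] = {}
    singletons: list[dict] = []
    for rec in demo_records:
        caseid = rec.get(key)
        if caseid is None:
            logger.warning(
                "DEMO record primaryid=%s has no %s; kept as singleton",
                rec.get("primaryid"),
                key,
            )
            singletons.append(rec)
            continue
        group = str(caseid)
        cur = best.get(group)
        if cur is None or _version_rank(rec) > _version_rank(cur):
            best[group] = rec
    kept = list(best.values()) + singletons
    kept_ids = {id(r) for r in kept}
    removed = [
        int(r["primaryid"]) for r in demo_records if id(r) not in kept_ids
    ]
    report = DedupReport(
        n_input=len(demo_records), n_kept=len(kept), removed_primaryids=removed
    )
    logger.info(
        "dedup: %d record(s) -> %d case(s), removed %d",
        report.n_input,
        report.n_kept,
        len(removed),
    )
    return kept, report


def _version_rank(rec: dict) -> tuple[str, int]:
    return (rec.get("fda_dt") or "", int(rec["primaryid"]))


def _age_years(age: str | None, age_cod: str | None) -> float | None:
    if age is None:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    factor = _AGE_TO_YEARS.get((age_cod or "YR").upper())
    if factor is None:
        return None
    years = value * factor
    return years if years >= 0 else None


def assemble_cases(
    demo: list[dict],
    drug: list[dict],
    reac: list[dict],
    indi: list[dict],
    ther: list[dict],
    outc: list[dict],
    synonym_map: DrugSynonymMap | None = None,
) -> list[ReportCase]:
    """Join deduplicated DEMO records with their child rows into ReportCases.

    Reaction PT codes are de-duplicated within a report; reports with no
    reaction rows are dropped (a spontaneous report without an adverse event
    carries no analyzable signal); child rows whose ``primaryid`` has no
    surviving DEMO parent are dropped and counted.
    """
    by_pid: dict[int, ReportCase] = {}
    for rec in demo:
        pid = int(rec["primaryid"])
        country = rec.get("occr_country") or rec.get("reporter_country") or "UNK"
        by_pid[pid] = ReportCase(
            primaryid=pid,
            caseid=int(rec["caseid"]) if rec.get("caseid") is not None else None,
            fda_dt=rec.get("fda_dt") or "",
            event_dt=rec.get("event_dt"),
            age_years=_age_years(rec.get("age"), rec.get("age_cod")),
            sex=(rec.get("sex") or "UNK").upper(),
            reporter=rec.get("occp_cod") or "UNK",
            country=country,
        )

    orphans = 0
    start_by_seq: dict[tuple[int, str], str] = {}
    for rec in ther:
        pid = int(rec["primaryid"])
        if pid not in by_pid:
            orphans += 1
            continue
        if rec.get("start_dt") is not None:
            start_by_seq[(pid, str(rec["dsg_drug_seq"]))] = rec["start_dt"]

    for rec in drug:
        pid = int(rec["primaryid"])
        case = by_pid.get(pid)
        if case is None:
            orphans += 1
            continue
        raw = rec.get("drugname") or ""
        ingredient = None
        if synonym_map is not None:
            ingredient = normalize_drug_name(raw, synonym_map)
            if ingredient is None and rec.get("prod_ai"):
                ingredient = normalize_drug_name(rec["prod_ai"], synonym_map)
        role = (rec.get("role_cod") or "C").upper()
        case.drugs.append(
            DrugEntry(
                raw_name=raw,
                ingredient=ingredient,
                role=role if role in ROLE_CODES else "C",
                route=(rec.get("route") or "UNK").upper(),
                start_dt=start_by_seq.get((pid, str(rec.get("drug_seq")))),
            )
        )

    reac_by_pid: dict[int, list[int]] = {}
    for rec in reac:
        pid = int(rec["primaryid"])
        if pid not in by_pid:
            orphans += 1
            continue
        if rec.get("pt") is not None:
            reac_by_pid.setdefault(pid, []).append(int(rec["pt"]))

    indi_by_pid: dict[int, list[int]] = {}
    for rec in indi:
        pid = int(rec["primaryid"])
        if pid not in by_pid:
            orphans += 1
            continue
        if rec.get("indi_pt") is not None:
            indi_by_pid.setdefault(pid, []).append(int(rec["indi_pt"]))

    outc_by_pid: dict[int, set[str]] = {}
    for rec in outc:
        pid = int(rec["primaryid"])
        if pid not in by_pid:
            orphans += 1
            continue
        if rec.get("outc_cod") is not None:
            outc_by_pid.setdefault(pid, set()).add(rec["outc_cod"].upper())

    if orphans:
        logger.info("assemble: dropped %d orphan child row(s)", orphans)

    cases: list[ReportCase] = []
    no_reaction = 0
    for pid, case in by_pid.items():
        pts = reac_by_pid.get(pid)
        if not pts:
            no_reaction += 1
            continue
        case.reactions = tuple(sorted(set(pts)))
        case.indications = tuple(sorted(set(indi_by_pid.get(pid, []))))
        case.outcomes = frozenset(outc_by_pid.get(pid, set()))
        cases.append(case)
    if no_reaction:
        logger.info("assemble: dropped %d report(s) with no reactions", no_reaction)
    return cases


def filter_target_reports(
    cases: list[ReportCase], target_ingredients
) -> list[ReportCase]:
    """Reports where a target ingredient appears as the primary-suspect drug.

    A case carrying the ingredient only as secondary suspect, concomitant or
    interacting is excluded — the disproportionality contrast is defined on
    primary-suspect exposure.
    """
    targets = frozenset(target_ingredients)
    if not targets:
        raise ValueError("target ingredient set is empty")
    return [
        case
        for case in cases
        if any(d.role == "PS" and d.ingredient in targets for d in case.drugs)
    ]
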