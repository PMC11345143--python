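"""Controlled vocabulary: MedDRA-like term hierarchy, SMQ sets, drug synonyms.

MedDRA itself is licensed content, so the package works against user-supplied
dictionary files (or the built-in synthetic fixture dictionary) that carry the
same structure: preferred terms (PTs) each mapped to exactly one system organ
class (SOC), standardized MedDRA queries (SMQs) as sets of member PT codes,
and a drug synonym map folding brand names and active-ingredient strings onto
normalized ingredient labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PTerm",
    "SmqSet",
    "PregnancyTermLists",
    "DrugSynonymMap",
    "TermDictionary",
    "load_dictionary",
    "write_dictionary",
    "normalize_drug_name",
    "fold_name",
    "builtin_dictionary",
    "builtin_synonym_map",
    "LMWH_INGREDIENTS",
    "DEFINITIVE_PREGNANCY_PTS",
    "PATERNAL_PTS",
    "PREGNANCY_EVENT_SMQS",
    "PREGNANCY_INDICATION_SMQS",
    "TRANSPLACENTAL_ROUTE",
]


@dataclass(frozen=True)
class PTerm:
    """A preferred term: 8-digit numeric code, name, and its single SOC."""

    code: int
    name: str
    soc: str


@dataclass(frozen=True)
class SmqSet:
    """A standardized MedDRA query: a code plus its member PT codes."""

    smq_code: int
    member_pts: frozenset[int]

    def __post_init__(self) -> None:
        if not self.member_pts:
            raise ValueError(f"SMQ {self.smq_code} has no member PTs")


@dataclass(frozen=True)
class PregnancyTermLists:
    """Code lists driving the pregnancy-cohort classification.

    ``definitive_pts`` are maternal/foetal exposure terms whose presence (in
    reactions or indications) marks a report as definitively pregnancy
    related; ``paternal_pts`` mark paternal-exposure reports that are
    excluded from the cohort; the SMQ code lists select candidate reports
    from the adverse-event and indication fields respectively.
    """

    definitive_pts: frozenset[int]
    paternal_pts: frozenset[int]
    indication_smqs: frozenset[int]
    event_smqs: frozenset[int]
    transplacental_route: str = "TRANSPLACENTAL"

    def __post_init__(self) -> None:
        if self.definitive_pts & self.paternal_pts:
            overlap = sorted(self.definitive_pts & self.paternal_pts)
            raise ValueError(f"definitive and paternal PT lists overlap: {overlap}")


@dataclass
class DrugSynonymMap:
    """Folded-name lookup from raw drug strings to normalized ingredients."""

    entries: dict[str, str]
    target_ingredients: frozenset[str]

    def __post_init__(self) -> None:
        values = set(self.entries.values())
        missing = self.target_ingredients - values
        if missing:
            raise ValueError(
                f"target ingredients with no synonym entry: {sorted(missing)}"
            )


@dataclass
class TermDictionary:
    """Bundle of PT index, SMQ index, pregnancy code lists, and synonyms."""

    pts: dict[int, PTerm]
    smqs: dict[int, SmqSet]
    pregnancy: PregnancyTermLists
    synonyms: DrugSynonymMap | None = None

    def soc_of(self, pt_code: int) -> str | None:
        term = self.pts.get(pt_code)
        return term.soc if term else None

    def smq_members(self, smq_codes) -> frozenset[int]:
        """Union of member PTs over the given SMQ codes.

        Raises ``KeyError`` for an SMQ code absent from the dictionary: a
        typo in a config code list must not silently select nothing.
        """
        members: set[int] = set()
        for code in smq_codes:
            if code not in self.smqs:
                raise KeyError(f"unknown SMQ code {code}")
            members |= self.smqs[code].member_pts
        return frozenset(members)


_FOLD_RE = re.compile(r"[^a-z0-9]+")


def fold_name(raw: str) -> str:
    """Fold a drug name: lowercase, strip non-alphanumerics to single spaces."""
    return _FOLD_RE.sub(" ", raw.lower()).strip()


def normalize_drug_name(raw: str, synonym_map: DrugSynonymMap) -> str | None:
    """Resolve a raw drug string to a normalized ingredient, or ``None``.

    Lookup is an exact match on the folded name; no fuzzy matching is
    attempted, so the result is deterministic and auditable. Absence is a
    valid outcome (the drug is simply not in the dictionary).
    """
    if not raw:
        return None
    return synonym_map.entries.get(fold_name(raw))


def _read_delim(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a "$"- or tab-delimited dictionary file with a header row."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "$" if "$" in header else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def load_dictionary(
    pt_table: str | Path,
    smq_table: str | Path,
    synonym_table: str | Path | None = None,
    pregnancy: PregnancyTermLists | None = None,
    known_socs: set[str] | None = None,
) -> TermDictionary:
    """Load a term dictionary from delimited PT / SMQ (and synonym) files.

    Parameters
    ----------
    pt_table
        File with columns ``pt_code, pt_name, soc_name``.
    smq_table
        File with columns ``smq_code, pt_code`` (one row per membership).
    synonym_table
        Optional file with columns ``raw_name, ingredient``.
    pregnancy
        Code lists for the pregnancy cohort; defaults to the built-in lists.
    known_socs
        If given, any SOC name outside this set is rejected.
    """
    pt_df = _read_delim(pt_table, ["pt_code", "pt_name", "soc_name"])
    pts: dict[int, PTerm] = {}
    for row in pt_df.itertuples(index=False):
        code = int(row.pt_code)
        if code in pts:
            raise ValueError(f"duplicate PT code {code} in {pt_table}")
        soc = row.soc_name.strip()
        if known_socs is not None and soc not in known_socs:
            raise ValueError(f"unknown SOC name {soc!r} for PT {code}")
        pts[code] = PTerm(code=code, name=row.pt_name.strip(), soc=soc)

    smq_df = _read_delim(smq_table, ["smq_code", "pt_code"])
    members: dict[int, set[int]] = {}
    for row in smq_df.itertuples(index=False):
        smq_code, pt_code = int(row.smq_code), int(row.pt_code)
        if pt_code not in pts:
            raise ValueError(
                f"SMQ {smq_code} references PT {pt_code} absent from the PT table"
            )
        members.setdefault(smq_code, set()).add(pt_code)
    smqs = {c: SmqSet(c, frozenset(m)) for c, m in members.items()}

    synonyms = None
    if synonym_table is not None:
        syn_df = _read_delim(synonym_table, ["raw_name", "ingredient"])
        entries = {
            fold_name(r.raw_name): r.ingredient.strip().lower()
            for r in syn_df.itertuples(index=False)
        }
        synonyms = DrugSynonymMap(
            entries=entries, target_ingredients=frozenset(entries.values())
        )

    return TermDictionary(
        pts=pts,
        smqs=smqs,
        pregnancy=pregnancy or default_pregnancy_lists(),
        synonyms=synonyms,
    )


def write_dictionary(
    dictionary: TermDictionary, pt_table: str | Path, smq_table: str | Path
) -> None:
    """Write PT and SMQ indexes back to the tab-delimited format."""
    pt_rows = [
        {"pt_code": t.code, "pt_name": t.name, "soc_name": t.soc}
        for t in sorted(dictionary.pts.values(), key=lambda t: t.code)
    ]
    pd.DataFrame(pt_rows).to_csv(pt_table, sep="\t", index=False)
    smq_rows = [
        {"smq_code": s.smq_code, "pt_code": pt}
        for s in sorted(dictionary.smqs.values(), key=lambda s: s.smq_code)
        for pt in sorted(s.member_pts)
    ]
    pd.DataFrame(smq_rows).to_csv(smq_table, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Built-in fixture content
#
# Real MedDRA/SMQ member lists are licensed and cannot ship here. The codes
# below are the publicly printed maternal/foetal/paternal exposure PT codes
# and pregnancy SMQ codes used in LMWH pharmacovigilance work; the SMQ
# *memberships* and the filler vocabulary are synthetic fixture content.
# ---------------------------------------------------------------------------

DEFINITIVE_PREGNANCY_PTS: dict[int, str] = {
    10071407: "maternal exposure during delivery",
    10071409: "foetal exposure during delivery",
    10071406: "maternal exposure before pregnancy",
    10071408: "maternal exposure during pregnancy",
    10071404: "foetal exposure during pregnancy",
    10073513: "exposure during pregnancy",
    10071415: "maternal exposure timing unspecified",
    10071405: "foetal exposure timing unspecified",
    10026923: "maternal drugs affecting foetus",
    10064998: "drug exposure before pregnancy",
}

PATERNAL_PTS: dict[int, str] = {
    10050425: "paternal drugs affecting the fetus",
    10071403: "exposure via father",
    10080091: "paternal exposure during pregnancy",
    10080092: "paternal exposure timing unspecified",
    10080093: "paternal exposure before pregnancy",
    10084938: "maternal exposure via partner during pregnancy",
}

PREGNANCY_EVENT_SMQS = (20000077, 20000186, 20000190, 20000191, 20000192, 20000193)
PREGNANCY_INDICATION_SMQS = (20000186, 20000190, 20000193)
TRANSPLACENTAL_ROUTE = "TRANSPLACENTAL"

# Synthetic pregnancy-outcome PTs used to populate the fixture SMQ members
# beyond the exposure terms above (codes in a reserved synthetic range).
_FIXTURE_PREGNANCY_OUTCOME_PTS: dict[int, str] = {
    10000210: "abortion",
    10000234: "abortion spontaneous",
    10036595: "premature baby",
    10035132: "placental necrosis",
    10055379: "peripartum haemorrhage",
    10036601: "premature separation of placenta",
    10016479: "foetal vascular malperfusion",
}

_PREGNANCY_SOC = "Pregnancy, puerperium and perinatal conditions"

_FIXTURE_SOCS = (
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Musculoskeletal and connective tissue disorders",
    "Nervous system disorders",
    _PREGNANCY_SOC,
    "Product issues",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Vascular disorders",
)


def default_pregnancy_lists() -> PregnancyTermLists:
    return PregnancyTermLists(
        definitive_pts=frozenset(DEFINITIVE_PREGNANCY_PTS),
        paternal_pts=frozenset(PATERNAL_PTS),
        indication_smqs=frozenset(PREGNANCY_INDICATION_SMQS),
        event_smqs=frozenset(PREGNANCY_EVENT_SMQS),
        transplacental_route=TRANSPLACENTAL_ROUTE,
    )


LMWH_INGREDIENTS = (
    "enoxaparin",
    "nadroparin",
    "dalteparin",
    "tinzaparin",
    "bemiparin",
    "reviparin",
    "parnaparin",
    "low molecular weight heparin",
)

_BRAND_SYNONYMS: dict[str, str] = {
    "lovenox": "enoxaparin",
    "clexane": "enoxaparin",
    "enoxaparin sodium": "enoxaparin",
    "fraxiparine": "nadroparin",
    "nadroparin calcium": "nadroparin",
    "fragmin": "dalteparin",
    "dalteparin sodium": "dalteparin",
    "innohep": "tinzaparin",
    "tinzaparin sodium": "tinzaparin",
    "zibor": "bemiparin",
    "bemiparin sodium": "bemiparin",
    "clivarine": "reviparin",
    "reviparin sodium": "reviparin",
    "fluxum": "parnaparin",
    "parnaparin sodium": "parnaparin",
    "lmwh": "low molecular weight heparin",
    "heparin low molecular weight": "low molecular weight heparin",
}


def builtin_synonym_map() -> DrugSynonymMap:
    """Synonym map for the LMWH drug class (generics, brands, ingredients)."""
    entries = {fold_name(k): v for k, v in _BRAND_SYNONYMS.items()}
    for ingredient in LMWH_INGREDIENTS:
        entries[fold_name(ingredient)] = ingredient
    return DrugSynonymMap(
        entries=entries, target_ingredients=frozenset(LMWH_INGREDIENTS)
    )


def builtin_dictionary(n_filler_pts: int = 0) -> TermDictionary:
    """Build the synthetic fixture dictionary.

    Contains the printed pregnancy exposure/paternal PT codes, six pregnancy
    SMQs with synthetic member lists, a handful of named pregnancy-outcome
    PTs, and optionally ``n_filler_pts`` synthetic filler terms (codes from
    90000001 upward) spread round-robin over the fixture SOCs — the general
    adverse-event vocabulary used by the synthetic report generator.
    """
    pts: dict[int, PTerm] = {}
    for code, name in DEFINITIVE_PREGNANCY_PTS.items():
        pts[code] = PTerm(code, name, _PREGNANCY_SOC)
    for code, name in PATERNAL_PTS.items():
        pts[code] = PTerm(code, name, _PREGNANCY_SOC)
    for code, name in _FIXTURE_PREGNANCY_OUTCOME_PTS.items():
        pts[code] = PTerm(code, name, _PREGNANCY_SOC)
    for i in range(n_filler_pts):
        code = 90000001 + i
        soc = _FIXTURE_SOCS[i % len(_FIXTURE_SOCS)]
        pts[code] = PTerm(code, f"synthetic term {i + 1:04d}", soc)

    outcome_codes = sorted(_FIXTURE_PREGNANCY_OUTCOME_PTS)
    definitive = sorted(DEFINITIVE_PREGNANCY_PTS)
    paternal = sorted(PATERNAL_PTS)
    # Synthetic memberships: each SMQ covers a slice of the fixture
    # pregnancy terms; together they cover all of them.
    smq_members: dict[int, frozenset[int]] = {
        20000077: frozenset(definitive + outcome_codes),
        20000186: frozenset(definitive[:5] + outcome_codes[:2]),
        20000190: frozenset(definitive[5:] + outcome_codes[2:4]),
        20000191: frozenset(paternal),
        20000192: frozenset(outcome_codes),
        20000193: frozenset(definitive + paternal),
    }
    smqs = {c: SmqSet(c, m) for c, m in smq_members.items()}
    return TermDictionary(
        pts=pts,
        smqs=smqs,
        pregnancy=default_pregnancy_lists(),
        synonyms=builtin_synonym_map(),
    )
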