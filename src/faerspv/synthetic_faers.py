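"""Synthetic FAERS-dialect report generator with planted ground truth.

Emits the six quarterly tables (DEMO, DRUG, REAC, INDI, THER, OUTC) in the
"$"-delimited dialect the ingest module reads, together with a manifest of
ground-truth labels: which cases are duplicates, which belong to the
pregnancy cohort (and why), and the true relative risk planted for each
(target drug, PT) pair. This makes the whole pipeline testable end to end
without any external download.

The generative model, per case:

* one primary-suspect (PS) drug — the target ingredient class with
  probability ``target_drug_share``, else one of ``n_drugs`` comparator
  drugs; optionally a concomitant drug row;
* 1 + Poisson(lambda - 1) reaction PTs drawn from a Zipf(s) marginal over
  the filler vocabulary (duplicates within a report collapse, mirroring
  distinct-PT counting); for target cases the selection odds of planted
  PTs are multiplied by their relative risk and renormalized;
* with probability ``pregnancy_fraction`` the case carries pregnancy SMQ
  evidence, subdivided into paternal-excluded, pediatric-excluded,
  definitive (exposure PT or transplacental route) and "other" cases;
* with probability ``duplicate_rate`` an extra, older case version is
  emitted sharing the caseid.

The filler vocabulary is disjoint from the SMQ member terms, so cohort
membership is exactly decidable from the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from faerspv import cohort_pregnancy as cp
from faerspv.term_model import (
    DEFINITIVE_PREGNANCY_PTS,
    LMWH_INGREDIENTS,
    PATERNAL_PTS,
    TRANSPLACENTAL_ROUTE,
    TermDictionary,
    builtin_dictionary,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticManifest",
    "GeneratedBundle",
    "generate",
    "evaluate_recovery",
    "RecoveryReport",
]

# Pregnancy-outcome PT codes of the fixture dictionary that are SMQ members
# but neither definitive-exposure nor paternal terms ("other" evidence).
_OUTCOME_EVIDENCE_PTS = (10000210, 10000234, 10036595, 10055379)
# The subset that is also a member of the indication-field SMQ lists, used
# for indication-only evidence.
_INDI_EVIDENCE_PTS = (10000210, 10000234, 10035132)

_TARGET_RAW_NAMES = (
    "ENOXAPARIN",
    "Lovenox",
    "CLEXANE",
    "enoxaparin sodium",
    "DALTEPARIN",
    "Fragmin",
    "NADROPARIN",
    "Fraxiparine",
    "TINZAPARIN",
    "Innohep",
    "BEMIPARIN",
    "REVIPARIN",
    "PARNAPARIN",
    "LMWH",
)

_SEX_GENERAL = (("F", 0.45), ("M", 0.40), ("UNK", 0.15))
_SEX_PREGNANCY = (("F", 0.85), ("M", 0.05), ("UNK", 0.10))
_REPORTERS = (("MD", 0.25), ("PH", 0.25), ("CN", 0.30), ("OT", 0.15), ("LW", 0.05))
_COUNTRIES = (("US", 0.45), ("FR", 0.12), ("GB", 0.08), ("BR", 0.08), ("UNK", 0.27))
_OUTCOMES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; the defaults define the study conditions for tests."""

    n_cases: int = 10_000
    n_drugs: int = 20
    n_pts: int = 800
    zipf_s: float = 1.2
    reactions_mean: float = 2.5
    target_drug_share: float = 0.02
    planted_signals: tuple[tuple[int, float], ...] = ()
    pregnancy_fraction: float = 0.08
    definitive_fraction: float = 0.40
    paternal_fraction: float = 0.03
    pediatric_fraction: float = 0.02
    duplicate_rate: float = 0.05
    age_missing_rate: float = 0.30
    concomitant_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "target_drug_share",
            "pregnancy_fraction",
            "definitive_fraction",
            "paternal_fraction",
            "pediatric_fraction",
            "duplicate_rate",
            "age_missing_rate",
            "concomitant_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(rr <= 0 for _, rr in self.planted_signals):
            raise ValueError("planted relative risks must be positive")
        if self.reactions_mean < 1.0:
            raise ValueError("reactions_mean must be >= 1")


@dataclass
class SyntheticManifest:
    """Ground truth emitted alongside a generated bundle."""

    seed: int
    n_cases: int
    case_labels: dict[int, dict]  # primaryid -> caseid / is_target / label
    duplicate_primaryids: list[int]
    planted: list[dict]  # pt_code / rr / expected_a
    totals: dict[str, int]  # n_reports / n_events / drug_total
    pt_a: dict[int, int]  # realized target events per PT
    pt_total: dict[int, int]  # realized events per PT over all drugs

    def pregnancy_primaryids(self) -> set[int]:
        return {
            pid
            for pid, rec in self.case_labels.items()
            if rec["label"] in (cp.DEFINITIVE, cp.OTHER)
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_cases": self.n_cases,
            "case_labels": {str(k): v for k, v in self.case_labels.items()},
            "duplicate_primaryids": self.duplicate_primaryids,
            "planted": self.planted,
            "totals": self.totals,
            "pt_a": {str(k): v for k, v in self.pt_a.items()},
            "pt_total": {str(k): v for k, v in self.pt_total.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticManifest":
        raw = json.loads(Path(path).read_text())
        return cls(
            seed=raw["seed"],
            n_cases=raw["n_cases"],
            case_labels={int(k): v for k, v in raw["case_labels"].items()},
            duplicate_primaryids=raw["duplicate_primaryids"],
            planted=raw["planted"],
            totals=raw["totals"],
            pt_a={int(k): v for k, v in raw["pt_a"].items()},
            pt_total={int(k): v for k, v in raw["pt_total"].items()},
        )


@dataclass
class GeneratedBundle:
    paths: dict[str, Path]
    manifest: SyntheticManifest
    dictionary: TermDictionary


def zipf_weights(n_pts: int, s: float) -> np.ndarray:
    """Normalized Zipf(s) marginal over ranks 1..n_pts."""
    ranks = np.arange(1, n_pts + 1, dtype=float)
    w = ranks**-s
    return w / w.sum()


def _draw(rng: np.random.Generator, cdf: np.ndarray, size: int) -> np.ndarray:
    return np.searchsorted(cdf, rng.random(size), side="right")

def _categorical(rng: np.random.Generator, pairs, size: int) -> list[str]:
    labels = [p[0] for p in pairs]
    cdf = np.cumsum([p[1] for p in pairs])
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(size), side="right")
    return [labels[i] for i in idx]


def _fmt_date(d: date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def generate(
    config: SyntheticConfig, outdir: str | Path
) -> GeneratedBundle:
    """Generate a FAERS-dialect bundle plus its ground-truth manifest.

    The same seed yields a byte-identical bundle: every stochastic choice
    is drawn from a single seeded generator in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dictionary = builtin_dictionary(n_filler_pts=config.n_pts)
    vocab = np.array(sorted(pt for pt in dictionary.pts if pt >= 90000001))
    if len(vocab) < len(config.planted_signals):
        raise ValueError("vocabulary smaller than the planted-signal list")
    planted_codes = [pt for pt, _ in config.planted_signals]
    unknown = [pt for pt in planted_codes if pt not in set(vocab.tolist())]
    if unknown:
        raise ValueError(f"planted PT(s) not in the filler vocabulary: {unknown}")

    base_w = zipf_weights(len(vocab), config.zipf_s)
    boost_w = base_w.copy()
    code_to_idx = {int(c): i for i, c in enumerate(vocab)}
    for pt, rr in config.planted_signals:
        boost_w[code_to_idx[pt]] *= rr
    boost_w = boost_w / boost_w.sum()
    base_cdf, boost_cdf = np.cumsum(base_w), np.cumsum(boost_w)
    base_cdf[-1] = boost_cdf[-1] = 1.0

    n = config.n_cases
    is_target = rng.random(n) < config.target_drug_share
    n_react = 1 + rng.poisson(config.reactions_mean - 1.0, n)
    is_preg = rng.random(n) < config.pregnancy_fraction
    preg_u = rng.random(n)
    route_u = rng.random(n)
    dup = rng.random(n) < config.duplicate_rate

    # Reaction PT draws, grouped by target status for the planted boost.
    totals = int(n_react.sum())
    draws = np.empty(totals, dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(n_react)])
    tgt_mask = np.repeat(is_target, n_react)
    draws[~tgt_mask] = vocab[_draw(rng, base_cdf, int((~tgt_mask).sum()))]
    draws[tgt_mask] = vocab[_draw(rng, boost_cdf, int(tgt_mask.sum()))]

    drug_names = [f"COMPARATOR_{i:02d}" for i in range(config.n_drugs)]
    comparator_pick = rng.integers(0, config.n_drugs, n)
    target_name_pick = rng.integers(0, len(_TARGET_RAW_NAMES), n)
    conc = rng.random(n) < config.concomitant_rate
    conc_pick = rng.integers(0, config.n_drugs, n)

    sex_general = _categorical(rng, _SEX_GENERAL, n)
    sex_preg = _categorical(rng, _SEX_PREGNANCY, n)
    reporters = _categorical(rng, _REPORTERS, n)
    countries = _categorical(rng, _COUNTRIES, n)
    age_missing = rng.random(n) < config.age_missing_rate
    ages_general = rng.integers(18, 90, n)
    ages_preg = rng.integers(18, 45, n)
    n_outc = rng.integers(0, 3, n)
    outc_pick = rng.integers(0, len(_OUTCOMES), (n, 2))
    year = rng.integers(2004, 2025, n)
    month = rng.integers(1, 13, n)
    day = rng.integers(1, 29, n)
    onset = rng.integers(0, 61, n)
    dup_back = rng.integers(30, 400, n)
    evidence_pick = rng.integers(0, 10**9, n)

    definitive_codes = sorted(DEFINITIVE_PREGNANCY_PTS)
    paternal_codes = sorted(PATERNAL_PTS)

    demo_rows: list[str] = []
    drug_rows: list[str] = []
    reac_rows: list[str] = []
    indi_rows: list[str] = []
    ther_rows: list[str] = []
    outc_rows: list[str] = []

    case_labels: dict[int, dict] = {}
    duplicate_primaryids: list[int] = []
    pt_a: dict[int, int] = {}
    pt_total: dict[int, int] = {}
    n_events = 0
    drug_total = 0

    p_pat = config.paternal_fraction
    p_ped = p_pat + config.pediatric_fraction
    p_def = p_ped + config.definitive_fraction * (1.0 - p_ped)

    for i in range(n):
        caseid = 3_000_000 + i
        pid = caseid * 10 + 2
        reactions = sorted(set(draws[offsets[i] : offsets[i + 1]].tolist()))
        indications: list[int] = []
        route = "SUBCUTANEOUS"
        label = cp.NON_PREGNANCY
        age: float | None = None if age_missing[i] else float(ages_general[i])
        sex = sex_general[i]

        if is_preg[i]:
            sex = sex_preg[i]
            if not age_missing[i]:
                age = float(ages_preg[i])
            pick = evidence_pick[i]
            if preg_u[i] < p_pat:
                reactions = sorted(
                    set(reactions) | {paternal_codes[pick % len(paternal_codes)]}
                )
                label = cp.EXCLUDED
            elif preg_u[i] < p_ped:
                # pediatric: SMQ outcome evidence plus an under-cutoff age
                reactions = sorted(
                    set(reactions)
                    | {_OUTCOME_EVIDENCE_PTS[pick % len(_OUTCOME_EVIDENCE_PTS)]}
                )
                age = float(pick % 12)
                label = cp.EXCLUDED
            elif preg_u[i] < p_def:
                if route_u[i] < 0.3:
                    # definitive by route; still SMQ-retrieved via outcome PT
                    route = TRANSPLACENTAL_ROUTE
                    reactions = sorted(
                        set(reactions)
                        | {_OUTCOME_EVIDENCE_PTS[pick % len(_OUTCOME_EVIDENCE_PTS)]}
                    )
                else:
                    reactions = sorted(
                        set(reactions)
                        | {definitive_codes[pick % len(definitive_codes)]}
                    )
                label = cp.DEFINITIVE
            else:
                if pick % 2 == 0:
                    evidence = _OUTCOME_EVIDENCE_PTS[pick % len(_OUTCOME_EVIDENCE_PTS)]
                    reactions = sorted(set(reactions) | {evidence})
                else:
                    # indication-only evidence: retrieved via the
                    # indication-field SMQ list
                    indications.append(
                        _INDI_EVIDENCE_PTS[pick % len(_INDI_EVIDENCE_PTS)]
                    )
                label = cp.OTHER

        fda = date(int(year[i]), int(month[i]), int(day[i]))
        start = fda - timedelta(days=int(onset[i]) + 10)
        event = start + timedelta(days=int(onset[i]))

        if is_target[i]:
            drugname = _TARGET_RAW_NAMES[target_name_pick[i]]
        else:
            drugname = drug_names[comparator_pick[i]]

        age_field = "" if age is None else f"{age:g}"
        demo_rows.append(
            f"{pid}${caseid}${_fmt_date(fda)}${_fmt_date(event)}${age_field}$YR$"
            f"{sex}${reporters[i]}${countries[i]}${countries[i]}"
        )
        drug_rows.append(f"{pid}${caseid}$1$PS${drugname}$${route}")
        ther_rows.append(f"{pid}${caseid}$1${_fmt_date(start)}")
        if conc[i]:
            drug_rows.append(
                f"{pid}${caseid}$2$C${drug_names[conc_pick[i]]}$$ORAL"
            )
        for pt in reactions:
            reac_rows.append(f"{pid}${caseid}${pt}")
        for k, pt in enumerate(indications, start=1):
            indi_rows.append(f"{pid}${caseid}${k}${pt}")
        if not indications and not is_preg[i]:
            indi_rows.append(f"{pid}${caseid}$1${int(vocab[comparator_pick[i]])}")
        for j in range(int(n_outc[i])):
            outc_rows.append(f"{pid}${caseid}${_OUTCOMES[outc_pick[i, j]]}")

        if dup[i]:
            old_pid = caseid * 10 + 1
            old_fda = fda - timedelta(days=int(dup_back[i]))
            demo_rows.append(
                f"{old_pid}${caseid}${_fmt_date(old_fda)}${_fmt_date(event)}$"
                f"{age_field}$YR${sex}${reporters[i]}${countries[i]}${countries[i]}"
            )
            drug_rows.append(f"{old_pid}${caseid}$1$PS${drugname}$${route}")
            for pt in reactions[:1]:
                reac_rows.append(f"{old_pid}${caseid}${pt}")
            duplicate_primaryids.append(old_pid)

        case_labels[pid] = {
            "caseid": caseid,
            "is_target": bool(is_target[i]),
            "label": label,
        }
        n_events += len(reactions)
        for pt in reactions:
            pt_total[pt] = pt_total.get(pt, 0) + 1
            if is_target[i]:
                pt_a[pt] = pt_a.get(pt, 0) + 1
        if is_target[i]:
            drug_total += len(reactions)

    expected_target_events = (
        config.n_cases * config.target_drug_share * config.reactions_mean
    )
    planted = [
        {
            "pt_code": int(pt),
            "rr": float(rr),
            "expected_a": float(
                expected_target_events * boost_w[code_to_idx[pt]]
            ),
        }
        for pt, rr in config.planted_signals
    ]

    headers = {
        "DEMO": "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod"
        "$reporter_country$occr_country",
        "DRUG": "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$route",
        "REAC": "primaryid$caseid$pt",
        "INDI": "primaryid$caseid$indi_drug_seq$indi_pt",
        "THER": "primaryid$caseid$dsg_drug_seq$start_dt",
        "OUTC": "primaryid$caseid$outc_cod",
    }
    tables = {
        "DEMO": demo_rows,
        "DRUG": drug_rows,
        "REAC": reac_rows,
        "INDI": indi_rows,
        "THER": ther_rows,
        "OUTC": outc_rows,
    }
    paths: dict[str, Path] = {}
    for kind, rows in tables.items():
        path = outdir / f"{kind}24Q1.txt"
        path.write_text("\n".join([headers[kind], *rows]) + "\n")
        paths[kind] = path

    manifest = SyntheticManifest(
        seed=config.seed,
        n_cases=config.n_cases,
        case_labels=case_labels,
        duplicate_primaryids=sorted(duplicate_primaryids),
        planted=planted,
        totals={
            "n_reports": config.n_cases,
            "n_events": n_events,
            "drug_total": drug_total,
        },
        pt_a=pt_a,
        pt_total=pt_total,
    )
    manifest.to_json(outdir / "manifest.json")
    paths["manifest"] = outdir / "manifest.json"
    return GeneratedBundle(paths=paths, manifest=manifest, dictionary=dictionary)


@dataclass
class RecoveryReport:
    """Detection outcome per planted signal plus the global false-signal rate."""

    planted: list[dict]
    n_unplanted_eligible: int
    n_false_signals: int

    @property
    def false_signal_rate(self) -> float:
        if self.n_unplanted_eligible == 0:
            return 0.0
        return self.n_false_signals / self.n_unplanted_eligible


def evaluate_recovery(signal_table, manifest: SyntheticManifest) -> RecoveryReport:
    """Compare a full per-PT stats table against the manifest ground truth.

    ``signal_table`` is the DataFrame from ``rank_signals(...,
    signals_only=False)`` with PT codes as the ``term`` column. For each
    planted signal it records the detection flag, the EBGM estimate, and
    whether the true relative risk lies in [ebgm05, inf); the false-signal
    rate is computed over unplanted PTs with a >= 3.
    """
    df = signal_table.set_index(signal_table["term"].astype(int))
    planted_codes = {p["pt_code"] for p in manifest.planted}
    out = []
    for p in manifest.planted:
        code = p["pt_code"]
        if code in df.index:
            row = df.loc[code]
            if int(row["n"]) != manifest.pt_a.get(code, 0):
                raise ValueError(
                    f"manifest/bundle mismatch for PT {code}: table a={row['n']} "
                    f"manifest a={manifest.pt_a.get(code, 0)}"
                )
            out.append(
                {
                    **p,
                    "a": int(row["n"]),
                    "ebgm": float(row["ebgm"]),
                    "detected": bool(row["signal"]),
                    "covered": bool(row["ebgm05"] <= p["rr"]),
                }
            )
        else:
            out.append({**p, "a": 0, "ebgm": float("nan"),
                        "detected": False, "covered": False})
    eligible = df[(~df.index.isin(planted_codes)) & (df["n"] >= 3)]
    n_false = int(eligible["signal"].sum())
    return RecoveryReport(
        planted=out,
        n_unplanted_eligible=len(eligible),
        n_false_signals=n_false,
    )
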