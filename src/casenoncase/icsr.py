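"""Domain model and CSV interchange for individual case safety reports (ICSRs).

An ICSR is one spontaneous report of suspected adverse drug reaction(s) in one
patient: demographics, one or more coded reaction terms (WHO-ART or MedDRA
preferred terms), and one or more drugs with their reported role (suspected,
concomitant, interacting) and ATC code.

The interchange format is three normalized UTF-8 CSV tables sharing a
``report_id`` key:

* ``reports.csv``   — report_id, age_years, sex, report_year, country, reporter_type
* ``drugs.csv``     — report_id, drug_name, atc_code, role, dechallenge_action,
  dechallenge_result, rechallenge_action, rechallenge_result
* ``reactions.csv`` — report_id, term, terminology, onset_days, outcome

Missing values are empty fields; enum values outside the vocabulary are mapped
to missing with a logged warning. Preferred-term comparison elsewhere in the
package is case-insensitive with internal whitespace collapsed — use
:func:`normalise_term`.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger("casenoncase")

__all__ = [
    "ReportRecord",
    "ReactionEntry",
    "DrugEntry",
    "Dataset",
    "Provenance",
    "SchemaError",
    "IntegrityError",
    "load_dataset",
    "write_dataset",
    "normalise_term",
    "is_valid_atc",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


class IntegrityError(ValueError):
    """Referential or uniqueness constraint violated (e.g. duplicate report_id)."""


SEXES = frozenset({"M", "F", "U"})
REPORTER_TYPES = frozenset(
    {"general_practitioner", "physician", "specialist", "hospital",
     "manufacturer", "consumer", "other"}
)
DRUG_ROLES = frozenset({"suspected", "concomitant", "interacting"})
TERMINOLOGIES = frozenset({"WHOART", "MedDRA"})
REACTION_OUTCOMES = frozenset({"recovered", "not_recovered", "recovered_with_sequelae"})
DECHALLENGE_ACTIONS = frozenset({"withdrawn", "dose_not_changed"})
DECHALLENGE_RESULTS = frozenset({"abated", "no_effect", "not_applicable"})
RECHALLENGE_ACTIONS = frozenset({"rechallenge", "no_rechallenge"})
RECHALLENGE_RESULTS = frozenset({"recurred", "not_applicable"})

# ATC grammar: L DD [L [L [DD]]] — truncations at levels 1-4 permitted.
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

_WS_RE = re.compile(r"\s+")


def normalise_term(term: str) -> str:
    """Canonical form of a preferred term: lower-case, internal whitespace collapsed."""
    return _WS_RE.sub(" ", term.strip()).lower()


def is_valid_atc(code: str) -> bool:
    """True if ``code`` is a syntactically valid ATC code or level-1..4 truncation."""
    return bool(_ATC_RE.match(code))


@dataclass(frozen=True)
class ReactionEntry:
    term: str
    terminology: str = "WHOART"
    onset_days: Optional[int] = None  # days from suspected drug start to onset
    outcome: Optional[str] = None


@dataclass(frozen=True)
class DrugEntry:
    drug_name: str
    atc_code: Optional[str] = None
    role: Optional[str] = "suspected"
    dechallenge_action: Optional[str] = None
    dechallenge_result: Optional[str] = None
    rechallenge_action: Optional[str] = None
    rechallenge_result: Optional[str] = None


@dataclass(frozen=True)
class ReportRecord:
    """One ICSR: the atomic unit of the case/non-case analysis."""

    report_id: str
    age_years: Optional[int]
    sex: str  # M, F or U (unknown)
    report_year: int
    country: Optional[str] = None
    reporter_type: Optional[str] = None
    reactions: tuple[ReactionEntry, ...] = ()
    drugs: tuple[DrugEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.age_years is not None and not (0 <= self.age_years <= 120):
            raise ValueError(f"age_years out of range [0, 120]: {self.age_years}")
        year_now = datetime.date.today().year
        if not (1960 <= self.report_year <= year_now):
            raise ValueError(f"report_year out of range [1960, {year_now}]: {self.report_year}")
        for d in self.drugs:
            if d.atc_code is not None and not is_valid_atc(d.atc_code):
                raise ValueError(f"invalid ATC code {d.atc_code!r} on report {self.report_id}")
        for r in self.reactions:
            if not r.term.strip():
                raise ValueError(f"empty reaction term on report {self.report_id}")


@dataclass(frozen=True)
class Provenance:
    source: str
    loaded_at: str
    n_reports: int
    n_drug_rows: int
    n_reaction_rows: int
    n_orphan_drug_rows: int = 0
    n_orphan_reaction_rows: int = 0


@dataclass
class Dataset:
    """A collection of reports with load provenance.

    Reports keep their input order; ``by_id`` gives O(1) lookup.
    """

    reports: list[ReportRecord]
    provenance: Optional[Provenance] = None
    _index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {r.report_id: i for i, r in enumerate(self.reports)}
        if len(self._index) != len(self.reports):
            seen: set[str] = set()
            for r in self.reports:
                if r.report_id in seen:
                    raise IntegrityError(f"duplicate report_id {r.report_id!r}")
                seen.add(r.report_id)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def by_id(self, report_id: str) -> ReportRecord:
        try:
            return self.reports[self._index[report_id]]
        except KeyError:
            raise IntegrityError(f"unknown report_id {report_id!r}") from None

    def __contains__(self, report_id: str) -> bool:
        return report_id in self._index

    def equals(self, other: "Dataset") -> bool:
        """Field-for-field equality modulo report order (entries keep their order)."""
        if set(self._index) != set(other._index):
            return False
        return all(self.by_id(rid) == other.by_id(rid) for rid in self._index)


REPORTS_COLUMNS = ["report_id", "age_years", "sex", "report_year", "country", "reporter_type"]
DRUGS_COLUMNS = [
    "report_id", "drug_name", "atc_code", "role",
    "dechallenge_action", "dechallenge_result", "rechallenge_action", "rechallenge_result",
]
REACTIONS_COLUMNS = ["report_id", "term", "terminology", "onset_days", "outcome"]


def _read_table(path: Path | str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _enum_or_none(value: str, vocab: frozenset[str], what: str, report_id: str) -> Optional[str]:
    value = value.strip()
    if not value or value == "missing":
        return None
    if value not in vocab:
        logger.warning("report %s: %s value %r outside vocabulary; treated as missing",
                       report_id, what, value)
        return None
    return value


def _int_or_none(value: str) -> Optional[int]:
    value = value.strip()
    return int(value) if value else None


def load_dataset(reports_path, drugs_path, reactions_path) -> Dataset:
    """Load and join the three-table CSV interchange into a validated :class:`Dataset`.

    Drug/reaction rows whose ``report_id`` does not occur in the reports table are
    orphans: they are excluded, counted in provenance, and logged. Enum fields
    outside their vocabulary map to missing with a warning. A duplicate
    ``report_id`` raises :class:`IntegrityError`; a missing column raises
    :class:`SchemaError` naming the column.
    """
    rep_df = _read_table(reports_path, REPORTS_COLUMNS)
    drug_df = _read_table(drugs_path, DRUGS_COLUMNS)
    rxn_df = _read_table(reactions_path, REACTIONS_COLUMNS)

    ids = rep_df["report_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = rep_df["report_id"][rep_df["report_id"].duplicated()].unique()
        raise IntegrityError(f"duplicate report_id(s) in reports table: {list(dupes)[:5]}")
    known = set(ids)

    drugs_by_report: dict[str, list[DrugEntry]] = {rid: [] for rid in known}
    n_orphan_drugs = 0
    for row in drug_df.itertuples(index=False):
        rid = row.report_id
        if rid not in known:
            n_orphan_drugs += 1
            continue
        atc = row.atc_code.strip().upper() or None
        if atc is not None and not is_valid_atc(atc):
            logger.warning("report %s: invalid ATC code %r treated as missing", rid, atc)
            atc = None
        drugs_by_report[rid].append(DrugEntry(
            drug_name=row.drug_name,
            atc_code=atc,
            role=_enum_or_none(row.role, DRUG_ROLES, "role", rid),
            dechallenge_action=_enum_or_none(row.dechallenge_action, DECHALLENGE_ACTIONS,
                                             "dechallenge_action", rid),
            dechallenge_result=_enum_or_none(row.dechallenge_result, DECHALLENGE_RESULTS,
                                             "dechallenge_result", rid),
            rechallenge_action=_enum_or_none(row.rechallenge_action, RECHALLENGE_ACTIONS,
                                             "rechallenge_action", rid),
            rechallenge_result=_enum_or_none(row.rechallenge_result, RECHALLENGE_RESULTS,
                                             "rechallenge_result", rid),
        ))
    if n_orphan_drugs:
        logger.warning("excluded %d orphan drug row(s) with unknown report_id", n_orphan_drugs)

    rxns_by_report: dict[str, list[ReactionEntry]] = {rid: [] for rid in known}
    n_orphan_rxns = 0
    for row in rxn_df.itertuples(index=False):
        rid = row.report_id
        if rid not in known:
            n_orphan_rxns += 1
            continue
        terminology = _enum_or_none(row.terminology, TERMINOLOGIES, "terminology", rid)
        rxns_by_report[rid].append(ReactionEntry(
            term=row.term,
            terminology=terminology if terminology is not None else "WHOART",
            onset_days=_int_or_none(row.onset_days),
            outcome=_enum_or_none(row.outcome, REACTION_OUTCOMES, "outcome", rid),
        ))
    if n_orphan_rxns:
        logger.warning("excluded %d orphan reaction row(s) with unknown report_id", n_orphan_rxns)

    reports = []
    for row in rep_df.itertuples(index=False):
        rid = row.report_id
        sex = row.sex.strip()
        if sex not in SEXES:
            if sex:
                logger.warning("report %s: sex value %r outside vocabulary; treated as unknown",
                               rid, sex)
            sex = "U"
        reports.append(ReportRecord(
            report_id=rid,
            age_years=_int_or_none(row.age_years),
            sex=sex,
            report_year=int(row.report_year),
            country=row.country.strip() or None,
            reporter_type=_enum_or_none(row.reporter_type, REPORTER_TYPES, "reporter_type", rid),
            reactions=tuple(rxns_by_report[rid]),
            drugs=tuple(drugs_by_report[rid]),
        ))

    prov = Provenance(
        source=str(reports_path),
        loaded_at=datetime.datetime.now().isoformat(timespec="seconds"),
        n_reports=len(reports),
        n_drug_rows=len(drug_df),
        n_reaction_rows=len(rxn_df),
        n_orphan_drug_rows=n_orphan_drugs,
        n_orphan_reaction_rows=n_orphan_rxns,
    )
    return Dataset(reports=reports, provenance=prov)


def _blank(value) -> str:
    return "" if value is None else str(value)


def write_dataset(ds: Dataset, out_dir) -> dict[str, Path]:
    """Write ``ds`` as the three interchange CSVs under ``out_dir``.

    Round-trip contract: ``load_dataset(*write_dataset(ds))`` equals ``ds``
    field-for-field (modulo row order).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep_rows, drug_rows, rxn_rows = [], [], []
    for r in ds:
        rep_rows.append({
            "report_id": r.report_id, "age_years": _blank(r.age_years), "sex": r.sex,
            "report_year": r.report_year, "country": _blank(r.country),
            "reporter_type": _blank(r.reporter_type),
        })
        for d in r.drugs:
            drug_rows.append({
                "report_id": r.report_id, "drug_name": d.drug_name,
                "atc_code": _blank(d.atc_code), "role": _blank(d.role),
                "dechallenge_action": _blank(d.dechallenge_action),
                "dechallenge_result": _blank(d.dechallenge_result),
                "rechallenge_action": _blank(d.rechallenge_action),
                "rechallenge_result": _blank(d.rechallenge_result),
            })
        for x in r.reactions:
            rxn_rows.append({
                "report_id": r.report_id, "term": x.term, "terminology": x.terminology,
                "onset_days": _blank(x.onset_days), "outcome": _blank(x.outcome),
            })
    paths = {
        "reports": out / "reports.csv",
        "drugs": out / "drugs.csv",
        "reactions": out / "reactions.csv",
    }
    pd.DataFrame(rep_rows, columns=REPORTS_COLUMNS).to_csv(paths["reports"], index=False)
    pd.DataFrame(drug_rows, columns=DRUGS_COLUMNS).to_csv(paths["drugs"], index=False)
    pd.DataFrame(rxn_rows, columns=REACTIONS_COLUMNS).to_csv(paths["reactions"], index=False)
    return paths
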