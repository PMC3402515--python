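"""Report-level drug exposure and covariate classification from ATC codes.

Exposure is defined by a set of ATC code prefixes (the WHO Anatomical
Therapeutic Chemical hierarchy is prefix-closed, so plain string-prefix
matching on upper-case codes implements class membership) together with the
drug roles that count — for statins the prefixes are C10AA (HMG-CoA reductase
inhibitors) plus the combination classes C10BA and C10BX, and the primary
definition counts suspected drugs only.

Covariates are co-medication class flags (any drug role); each class is a
prefix set, optionally minus an excluded prefix set so that, e.g., the
"non-statin lipid modifying agents" class is C10 with the statin codes carved
out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .icsr import Dataset, DrugEntry, ReportRecord, IntegrityError, is_valid_atc
from .cohort import MatchedCohort

__all__ = [
    "ExposureDefinition",
    "CovariateClass",
    "CovariateMap",
    "STATIN_ATC_PREFIXES",
    "default_exposure_definition",
    "default_covariate_map",
    "classify_exposure",
    "flag_covariates",
    "build_analysis_table",
    "ANALYSIS_COLUMNS",
]

STATIN_ATC_PREFIXES = frozenset({"C10AA", "C10BA", "C10BX"})


def _check_prefixes(prefixes, what: str) -> frozenset[str]:
    out = frozenset(p.upper() for p in prefixes)
    bad = [p for p in out if not is_valid_atc(p)]
    if bad:
        raise ValueError(f"{what}: invalid ATC prefix(es) {sorted(bad)}")
    return out


@dataclass(frozen=True)
class ExposureDefinition:
    atc_prefixes: frozenset[str] = STATIN_ATC_PREFIXES
    roles: frozenset[str] = frozenset({"suspected"})

    def __post_init__(self) -> None:
        if not self.atc_prefixes:
            raise ValueError("atc_prefixes must be non-empty")
        object.__setattr__(self, "atc_prefixes",
                           _check_prefixes(self.atc_prefixes, "ExposureDefinition"))
        object.__setattr__(self, "roles", frozenset(self.roles))


@dataclass(frozen=True)
class CovariateClass:
    """A drug class: included ATC prefixes minus excluded ones."""

    include: frozenset[str]
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", _check_prefixes(self.include, "CovariateClass"))
        object.__setattr__(self, "exclude", _check_prefixes(self.exclude, "CovariateClass"))

    def matches(self, atc_code: str) -> bool:
        code = atc_code.upper()
        return any(code.startswith(p) for p in self.include) and not any(
            code.startswith(p) for p in self.exclude
        )


class CovariateMap(dict):
    """Ordered mapping covariate name -> :class:`CovariateClass` (any drug role counts)."""

    def __init__(self, classes: dict[str, CovariateClass]):
        super().__init__(classes)

    @property
    def names(self) -> list[str]:
        return list(self)


def default_exposure_definition(roles=("suspected",)) -> ExposureDefinition:
    return ExposureDefinition(atc_prefixes=STATIN_ATC_PREFIXES, roles=frozenset(roles))


def default_covariate_map() -> CovariateMap:
    """Co-medication classes flagged at baseline, as ATC prefix sets.

    The map is data, not code: it can be overridden wholesale from the run
    configuration. The non-statin lipid class excludes the statin prefixes so
    the partition of C10 is exact.
    """
    c = CovariateClass
    return CovariateMap({
        "anti_arrhythmics": c(frozenset({"C01B"})),
        "antihypertensives": c(frozenset({"C02", "C03", "C07", "C08", "C09"})),
        "antidiabetics": c(frozenset({"A10"})),
        "non_statin_lipid": c(frozenset({"C10"}), exclude=STATIN_ATC_PREFIXES),
        "nsaids": c(frozenset({"M01A"})),
        "corticosteroids": c(frozenset({"H02AB"})),
        "dmards": c(frozenset({"P01BA", "L04A", "M01CB", "M01CC", "A07EC01", "L01BA01"})),
        "antidepressants": c(frozenset({"N06A"})),
        "antiepileptics": c(frozenset({"N03A"})),
        "acid_inhibitors": c(frozenset({"A02BC", "A02BA"})),
    })


def classify_exposure(r: ReportRecord, ed: ExposureDefinition) -> bool:
    """True iff some drug has a qualifying role and an ATC code under a qualifying prefix.

    A missing ATC code never matches; a missing role never matches. Exposure is
    report-level: one qualifying drug suffices.
    """
    for d in r.drugs:
        if d.role in ed.roles and d.atc_code is not None:
            if any(d.atc_code.startswith(p) for p in ed.atc_prefixes):
                return True
    return False


def flag_covariates(r: ReportRecord, cm: CovariateMap) -> dict[str, bool]:
    """One boolean per covariate class: any drug, any role, ATC under the class."""
    flags = dict.fromkeys(cm, False)
    for d in r.drugs:
        if d.atc_code is None:
            continue
        for name, cls in cm.items():
            if not flags[name] and cls.matches(d.atc_code):
                flags[name] = True
    return flags


ANALYSIS_COLUMNS = [
    "report_id", "set_id", "is_case", "age_years", "sex", "report_year",
    "exposed", "reporter_type", "n_reactions",
]


def build_analysis_table(
    mc: MatchedCohort,
    ds: Dataset,
    ed: ExposureDefinition,
    cm: CovariateMap,
) -> pd.DataFrame:
    """One analysis row per cohort member.

    Columns: ``report_id, set_id, is_case, age_years, sex, report_year,
    exposed, reporter_type, n_reactions`` plus one boolean column per covariate
    in ``cm``. Raises :class:`IntegrityError` if a cohort id is absent from the
    dataset.
    """
    rows = []
    for set_id, (case_id, noncase_ids) in enumerate(mc.matched_sets):
        for rid, is_case in [(case_id, True)] + [(n, False) for n in noncase_ids]:
            if rid not in ds:
                raise IntegrityError(f"cohort report_id {rid!r} not present in dataset")
            r = ds.by_id(rid)
            row = {
                "report_id": rid,
                "set_id": set_id,
                "is_case": is_case,
                "age_years": r.age_years,
                "sex": r.sex,
                "report_year": r.report_year,
                "exposed": classify_exposure(r, ed),
                "reporter_type": r.reporter_type,
                "n_reactions": len(r.reactions),
            }
            row.update(flag_covariates(r, cm))
            rows.append(row)
    return pd.DataFrame(rows, columns=ANALYSIS_COLUMNS + list(cm))
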