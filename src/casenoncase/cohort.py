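"""Case selection and matched non-case sampling for the case/non-case design.

In a spontaneous-reporting database, "cases" are reports carrying the adverse
event term of interest and "non-cases" are reports of any other event. Each
case is matched without replacement to ``ratio`` non-cases on age (integer
years), sex, and calendar year of reporting, sampled uniformly at random from
the exact-match stratum under a fixed seed.

Reports carrying an excluded term (e.g. the "aggravated" variant of the event,
which flags prevalent rather than incident disease) are removed from both the
case series and the non-case pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .icsr import Dataset, ReportRecord, normalise_term

logger = logging.getLogger("casenoncase")

__all__ = ["CaseDefinition", "MatchedCohort", "select_cases", "select_noncase_pool", "match"]


@dataclass(frozen=True)
class CaseDefinition:
    """Which reports count as cases of the event of interest.

    Terms are matched case-insensitively with internal whitespace collapsed.
    ``single_reaction_only`` restricts cases to reports whose event is the sole
    coded reaction term (used by the misclassification sensitivity analyses).
    """

    include_terms: frozenset[str]
    exclude_terms: frozenset[str] = frozenset()
    require_age: bool = True
    require_sex: bool = True
    single_reaction_only: bool = False

    def __post_init__(self) -> None:
        inc = frozenset(normalise_term(t) for t in self.include_terms)
        exc = frozenset(normalise_term(t) for t in self.exclude_terms)
        if not inc:
            raise ValueError("include_terms must be non-empty")
        if inc & exc:
            raise ValueError(f"include/exclude terms overlap: {sorted(inc & exc)}")
        object.__setattr__(self, "include_terms", inc)
        object.__setattr__(self, "exclude_terms", exc)


@dataclass
class MatchedCohort:
    """Cases with their matched non-case sets plus the matching metadata."""

    matched_sets: list[tuple[str, list[str]]]
    ratio: int
    matching_variables: list[str]
    dropped_cases: list[tuple[str, str]]
    seed: int

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _ in self.matched_sets]

    @property
    def noncase_ids(self) -> list[str]:
        return [n for _, ns in self.matched_sets for n in ns]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for set_id, (case, noncases) in enumerate(self.matched_sets):
            rows.append({"set_id": set_id, "role": "case", "report_id": case})
            rows.extend({"set_id": set_id, "role": "noncase", "report_id": n} for n in noncases)
        return pd.DataFrame(rows, columns=["set_id", "role", "report_id"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _terms(r: ReportRecord) -> set[str]:
    return {normalise_term(x.term) for x in r.reactions}


def _eligible_demographics(r: ReportRecord, cd: CaseDefinition) -> bool:
    if cd.require_age and r.age_years is None:
        return False
    if cd.require_sex and r.sex not in ("M", "F"):
        return False
    return True


def select_cases(ds: Dataset, cd: CaseDefinition) -> list[str]:
    """Report ids satisfying the case definition, in dataset order.

    A case has at least one reaction term in ``include_terms``, no term in
    ``exclude_terms``, age/sex recorded where required, and — under
    ``single_reaction_only`` — exactly one reaction entry.
    """
    out = []
    for r in ds:
        terms = _terms(r)
        if not (terms & cd.include_terms):
            continue
        if terms & cd.exclude_terms:
            continue
        if not _eligible_demographics(r, cd):
            continue
        if cd.single_reaction_only and len(r.reactions) != 1:
            continue
        out.append(r.report_id)
    return out


def select_noncase_pool(ds: Dataset, cd: CaseDefinition) -> list[str]:
    """Report ids eligible as non-cases: no case or excluded term, age and sex present.

    Demographic completeness mirrors the case rule so the matching variables are
    always defined.
    """
    blocked = cd.include_terms | cd.exclude_terms
    out = []
    for r in ds:
        if _terms(r) & blocked:
            continue
        if not _eligible_demographics(r, cd):
            continue
        out.append(r.report_id)
    return out


def _stratum_key(r: ReportRecord, age_offset: int = 0):
    return (r.age_years, r.sex, r.report_year)


def match(
    cases: list[str],
    pool: list[str],
    ds: Dataset,
    ratio: int = 5,
    seed: int = 0,
    policy: str = "strict_drop",
    widen_age_cap: int = 5,
) -> MatchedCohort:
    """Greedy 1:``ratio`` matching on exact age, sex, and reporting year.

    Cases are processed in ascending ``report_id`` order; each draws ``ratio``
    non-cases uniformly at random, without replacement, from the non-cases that
    equal it on every matching variable. Under ``strict_drop`` a case whose
    stratum has too few remaining non-cases is dropped (and logged with its
    deficit); under ``widen_age`` the age criterion is relaxed stepwise
    (±1, ±2, … up to ``widen_age_cap`` years) before dropping.

    Deterministic: equal (cases, pool, dataset, ratio, seed, policy) gives an
    identical cohort.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    if policy not in ("strict_drop", "widen_age"):
        raise ValueError(f"unknown matching policy {policy!r}")
    overlap = set(cases) & set(pool)
    if overlap:
        raise ValueError(f"cases and pool overlap: {sorted(overlap)[:5]}")

    rng = np.random.default_rng(seed)
    # Shuffled per-stratum stacks: popping from the end is a uniform draw
    # without replacement, and keeps the whole procedure O(pool).
    strata: dict[tuple, list[str]] = {}
    for rid in pool:
        strata.setdefault(_stratum_key(ds.by_id(rid)), []).append(rid)
    for key in sorted(strata, key=repr):
        ids = sorted(strata[key])
        rng.shuffle(ids)
        strata[key] = ids

    matched_sets: list[tuple[str, list[str]]] = []
    dropped: list[tuple[str, str]] = []
    for cid in sorted(cases):
        case = ds.by_id(cid)
        age, sex, year = case.age_years, case.sex, case.report_year
        exact = strata.get((age, sex, year), [])
        if len(exact) >= ratio:
            chosen = [exact.pop() for _ in range(ratio)]
            matched_sets.append((cid, chosen))
            continue
        if policy == "widen_age":
            widened = None
            for width in range(1, widen_age_cap + 1):
                candidate_strata = [
                    strata.get((age + off, sex, year), [])
                    for off in range(-width, width + 1)
                ]
                if sum(len(s) for s in candidate_strata) >= ratio:
                    widened = (width, candidate_strata)
                    break
            if widened is not None:
                width, candidate_strata = widened
                # Uniform over the widened set: pool the stacks and draw.
                merged = [rid for s in candidate_strata for rid in s]
                idx = rng.choice(len(merged), size=ratio, replace=False)
                chosen = [merged[i] for i in sorted(idx)]
                chosen_set = set(chosen)
                for s in candidate_strata:
                    s[:] = [rid for rid in s if rid not in chosen_set]
                matched_sets.append((cid, chosen))
                logger.info("case %s matched with age window ±%d", cid, width)
                continue
        deficit = ratio - len(exact)
        dropped.append((cid, f"insufficient stratum: short {deficit} non-case(s)"))
        logger.warning("case %s dropped: stratum (age=%s, sex=%s, year=%s) short %d non-case(s)",
                       cid, age, sex, year, deficit)

    return MatchedCohort(
        matched_sets=matched_sets,
        ratio=ratio,
        matching_variables=["age_years", "sex", "report_year"],
        dropped_cases=dropped,
        seed=seed,
    )
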