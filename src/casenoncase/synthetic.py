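"""Synthetic ICSR generation with known ground truth.

Real spontaneous-report databases are not redistributable, so the package
ships two substitutes, both clearly synthetic:

* :func:`generate` — a seeded simulator producing case and non-case reports
  with configurable demographics, a controllable true exposure-outcome odds
  ratio, and optional confounder classes. Exposure is assigned conditionally
  on outcome (the case/non-case design conditions on outcome, which gives
  exact control of the target reporting odds ratio): per report,

      logit P(exposed) = logit(p_exposure_noncase)
                         + log(true_or) * is_case
                         + sum_j log(or_with_exposure_j) * confounder_j

  and each confounder is Bernoulli with its prevalence among non-cases,
  oversampled among cases to hit its odds ratio with the outcome. Non-case
  demographics are emitted stratified on the case strata (``pool_multiplier *
  ratio`` non-cases copying each case's age/sex/year), so every matching
  stratum is guaranteed ample; case demographics are independent draws.

* :func:`margins_fixture` — a seed-free, fully deterministic 327-case /
  1,635-non-case dataset whose exposure, age, reporter, single-reaction, and
  descriptive-profile margins equal a published statin/polymyalgia-rheumatica
  disproportionality analysis, usable as a worked example with known expected
  counts at every pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .icsr import Dataset, DrugEntry, ReactionEntry, ReportRecord

__all__ = ["SimConfig", "ConfounderSpec", "GroundTruth", "generate", "margins_fixture",
           "PMR_TERM", "STATIN_SUBSTANCES"]

PMR_TERM = "Polymyalgia rheumatica"

# 7-character ATC codes for the individual statin substances.
STATIN_SUBSTANCES = {
    "C10AA01": "simvastatin",
    "C10AA02": "lovastatin",
    "C10AA03": "pravastatin",
    "C10AA04": "fluvastatin",
    "C10AA05": "atorvastatin",
    "C10AA06": "cerivastatin",
    "C10AA07": "rosuvastatin",
}

DEFAULT_BACKGROUND_TERMS = (
    "Nausea", "Rash", "Headache", "Dizziness", "Pruritus", "Vomiting", "Diarrhoea",
    "Fatigue", "Urticaria", "Dyspnoea",
)

# Neutral background drugs, outside every default covariate class.
_BACKGROUND_DRUGS = (
    ("Amoxicillin", "J01CA04"),
    ("Paracetamol", "N02BE01"),
    ("Salbutamol", "R03AC02"),
    ("Levothyroxine", "H03AA01"),
)

_SIM_STATINS = ("C10AA01", "C10AA03", "C10AA04", "C10AA05", "C10AA07")


@dataclass(frozen=True)
class ConfounderSpec:
    """A binary co-medication confounder class.

    ``or_with_exposure`` acts on the exposure-assignment logit;
    ``or_with_outcome`` sets the confounder's prevalence among cases relative
    to ``prevalence`` (its prevalence among non-cases) on the odds scale.
    """

    name: str
    atc_prefix: str
    prevalence: float
    or_with_exposure: float = 1.0
    or_with_outcome: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError(f"confounder {self.name}: prevalence must be in (0, 1)")
        if self.or_with_exposure <= 0 or self.or_with_outcome <= 0:
            raise ValueError(f"confounder {self.name}: odds ratios must be positive")

    def case_prevalence(self) -> float:
        odds = self.prevalence / (1 - self.prevalence) * self.or_with_outcome
        p = odds / (1 + odds)
        if not (0 < p < 1):
            raise ValueError(
                f"confounder {self.name}: or_with_outcome {self.or_with_outcome} "
                f"unreachable at prevalence {self.prevalence}")
        return p


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Demographic defaults follow the profile of the published study population
    (mean age 67.7 y, SD 11.0, 62.1% female, reports from 1990–2006); the
    default exposure parameters put non-case statin exposure at 2.9% with a
    true reporting odds ratio of 14.
    """

    n_cases: int = 327
    ratio: int = 5
    pool_multiplier: float = 3.0
    true_or: float = 14.0
    p_exposure_noncase: float = 0.029
    age_mean: float = 67.7
    age_sd: float = 11.0
    p_female: float = 0.621
    year_range: tuple[int, int] = (1990, 2006)
    confounders: tuple[ConfounderSpec, ...] = ()
    background_terms: tuple[str, ...] = DEFAULT_BACKGROUND_TERMS
    onset_bin_weights: tuple[float, float, float, float] = (35 / 96, 17 / 96, 23 / 96, 21 / 96)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.ratio < 1 or self.pool_multiplier <= 0:
            raise ValueError("n_cases, ratio must be >= 1 and pool_multiplier > 0")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not (0 < self.p_exposure_noncase < 1):
            raise ValueError("p_exposure_noncase must be in (0, 1)")
        if not (0 <= self.p_female <= 1):
            raise ValueError("p_female must be a probability")
        if abs(sum(self.onset_bin_weights) - 1) > 1e-9 or min(self.onset_bin_weights) < 0:
            raise ValueError("onset_bin_weights must be a probability vector over 4 bins")


@dataclass(frozen=True)
class GroundTruth:
    """Latent state of a simulated dataset; regenerates exactly from its SimConfig."""

    true_log_or: float
    seed: int
    assignments: pd.DataFrame  # report_id, is_case, exposed, one column per confounder


def _pad_atc(prefix: str) -> str:
    """Extend an ATC prefix to a syntactically complete 7-character code."""
    code = prefix
    while len(code) < 5:
        code += "A"
    if len(code) < 7:
        code += "01"
    return code


def generate(sc: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate a dataset of ``n_cases`` case reports plus a stratified non-case pool.

    Deterministic in ``sc`` (including ``sc.seed``): identical configurations
    yield byte-identical CSVs via :func:`casenoncase.icsr.write_dataset`.
    """
    rng = np.random.default_rng(sc.seed)
    n_cases = sc.n_cases
    m_per_case = int(round(sc.pool_multiplier * sc.ratio))
    n_noncases = m_per_case * n_cases

    case_ages = np.clip(np.rint(rng.normal(sc.age_mean, sc.age_sd, n_cases)), 18, 100).astype(int)
    case_sex = np.where(rng.random(n_cases) < sc.p_female, "F", "M")
    y0, y1 = sc.year_range
    case_years = rng.integers(y0, y1 + 1, n_cases)

    parent = np.repeat(np.arange(n_cases), m_per_case)
    ages = np.concatenate([case_ages, case_ages[parent]])
    sexes = np.concatenate([case_sex, case_sex[parent]])
    years = np.concatenate([case_years, case_years[parent]])
    is_case = np.concatenate([np.ones(n_cases, bool), np.zeros(n_noncases, bool)])
    n = len(is_case)

    conf_flags = {}
    for conf in sc.confounders:
        p = np.where(is_case, conf.case_prevalence(), conf.prevalence)
        conf_flags[conf.name] = rng.random(n) < p

    logit = math.log(sc.p_exposure_noncase / (1 - sc.p_exposure_noncase)) \
        + math.log(sc.true_or) * is_case.astype(float)
    for conf in sc.confounders:
        logit = logit + math.log(conf.or_with_exposure) * conf_flags[conf.name].astype(float)
    exposed = rng.random(n) < 1 / (1 + np.exp(-logit))

    onset_bin = rng.choice(4, size=n, p=np.asarray(sc.onset_bin_weights))
    onset_low = np.array([1, 91, 366, 0])[onset_bin]
    onset_high = np.array([90, 365, 2100, 0])[onset_bin]
    onset_days = rng.integers(onset_low, onset_high + 1)
    statin_codes = rng.choice(_SIM_STATINS, size=n)
    bg_terms = rng.choice(np.asarray(sc.background_terms, dtype=object), size=n)
    bg_drug_idx = rng.integers(0, len(_BACKGROUND_DRUGS), size=n)

    id_width = len(str(n))
    reports = []
    for i in range(n):
        rid = (f"C{i:0{id_width}d}" if is_case[i] else f"N{i:0{id_width}d}")
        if is_case[i]:
            onset = int(onset_days[i]) if onset_bin[i] < 3 else None
            reactions = (ReactionEntry(term=PMR_TERM, onset_days=onset),)
        else:
            reactions = (ReactionEntry(term=str(bg_terms[i])),)
        drugs = []
        if exposed[i]:
            code = str(statin_codes[i])
            drugs.append(DrugEntry(drug_name=STATIN_SUBSTANCES[code], atc_code=code,
                                   role="suspected"))
        else:
            name, atc = _BACKGROUND_DRUGS[bg_drug_idx[i]]
            drugs.append(DrugEntry(drug_name=name, atc_code=atc, role="suspected"))
        for conf in sc.confounders:
            if conf_flags[conf.name][i]:
                drugs.append(DrugEntry(drug_name=conf.name, atc_code=_pad_atc(conf.atc_prefix),
                                       role="concomitant"))
        reports.append(ReportRecord(
            report_id=rid,
            age_years=int(ages[i]),
            sex=str(sexes[i]),
            report_year=int(years[i]),
            reporter_type="general_practitioner",
            reactions=reactions,
            drugs=tuple(drugs),
        ))

    assignments = pd.DataFrame({
        "report_id": [r.report_id for r in reports],
        "is_case": is_case,
        "exposed": exposed,
        **{name: flags for name, flags in conf_flags.items()},
    })
    truth = GroundTruth(true_log_or=math.log(sc.true_or), seed=sc.seed, assignments=assignments)
    return Dataset(reports=reports), truth


# ---------------------------------------------------------------------------
# Deterministic margins fixture
# ---------------------------------------------------------------------------

def _ranges(*counts: int) -> list[range]:
    """Consecutive index ranges with the given lengths, starting at 0."""
    out, start = [], 0
    for c in counts:
        out.append(range(start, start + c))
        start += c
    return out


def _cycle(seq: Sequence, i: int):
    return seq[i % len(seq)]


def margins_fixture() -> Dataset:
    """Deterministic 1,962-report dataset reproducing the published 2x2 margins.

    327 polymyalgia-rheumatica cases and 1,635 non-cases in pre-matched strata
    (each case shares its age/sex/year with exactly five non-cases, so 1:5
    exact matching always succeeds and consumes the whole pool). Margins:

    * statin exposure: cases 96 suspected + 8 concomitant-only (104 total);
      non-cases 47 suspected + 82 concomitant-only (129 total);
    * age under 50: 20 cases (8 of them suspected-exposed) and 100 non-cases
      (4 suspected-exposed), so the over-50 restriction retains 307 cases /
      1,535 non-cases with 88 / 43 suspected exposures;
    * 157 cases carry the event as their single reaction term, 44 of them with
      a suspected statin and 46 with a suspected-or-concomitant statin;
    * physician-type reporters cover 76 cases (18 suspected-exposed) and 848
      non-cases (19 suspected-exposed);
    * the 96 suspected-statin cases carry the published descriptive profile
      (statin substance, onset bins 35/17/23/21, outcomes, dechallenge and
      rechallenge tabulations, country, reporting-period split 59/37);
    * co-medication flags: antidepressants 4 cases vs 74 non-cases,
      anti-arrhythmics 9 vs 93.

    Entirely synthetic: margins, not individual reports, match the published
    tables. No randomness — repeated calls are identical.
    """
    n_cases, ratio = 327, 5

    # --- case attribute index sets ------------------------------------------
    susp = set(range(0, 96))             # suspected statin
    conc = set(range(96, 104))           # concomitant-only statin
    young = set(range(0, 8)) | set(range(104, 116))          # age < 50 (20)
    single = set(range(0, 44)) | {96, 97} | set(range(104, 215))  # 157 single-reaction
    physician = set(range(44, 62)) | set(range(216, 274))    # 76; 18 suspected
    case_antidep = set(range(280, 284))                      # 4
    case_antiarr = set(range(285, 294))                      # 9

    # Table-style descriptive attributes for the 96 suspected-statin cases,
    # assigned as independent consecutive blocks (the profile tallies each
    # breakdown marginally).
    statin_assign = []
    for code, count in [("C10AA01", 35), ("C10AA03", 8), ("C10AA02", 10), ("C10AA05", 26),
                        ("C10AA04", 6), ("C10AA06", 6), ("C10AA07", 5)]:
        statin_assign.extend([code] * count)
    onset_assign = [45] * 35 + [200] * 17 + [400] * 23 + [None] * 21
    outcome_assign = (["recovered"] * 15 + ["not_recovered"] * 23
                      + ["recovered_with_sequelae"] * 3 + [None] * 55)
    dech_action = ["withdrawn"] * 26 + ["dose_not_changed"] * 12 + [None] * 58
    dech_result = ["abated"] * 8 + ["no_effect"] * 8 + ["not_applicable"] * 12 + [None] * 68
    rech_action = ["rechallenge"] * 6 + ["no_rechallenge"] * 20 + [None] * 70
    rech_result = ["recurred"] * 6 + ["not_applicable"] * 20 + [None] * 70
    country_assign = []
    for cc, count in [("AU", 9), ("CA", 4), ("FI", 2), ("FR", 2), ("DE", 18), ("GB", 15),
                      ("IE", 1), ("NZ", 3), ("NO", 1), ("SE", 3), ("CH", 1), ("NL", 3),
                      ("US", 34)]:
        country_assign.extend([cc] * count)

    physician_types = ("general_practitioner", "physician", "specialist", "hospital")
    lay_types = ("consumer", "manufacturer", "other", None)

    case_records = []
    for i in range(n_cases):
        age = 40 + (i % 10) if i in young else 52 + (i % 30)
        # Interleaved so sex is not collinear with the attribute index blocks
        # above; exactly 203/327 female (gcd(203, 327) = 1 makes the residues
        # a permutation of 0..326).
        sex = "F" if (203 * i) % 327 < 203 else "M"
        if i in susp:
            year = 1990 + (i % 10) if i < 59 else 2000 + (i % 7)
        else:
            year = 1990 + (i % 17)
        reporter = _cycle(physician_types, i) if i in physician else _cycle(lay_types, i)

        reactions = [ReactionEntry(term=PMR_TERM,
                                   onset_days=onset_assign[i] if i in susp else None,
                                   outcome=outcome_assign[i] if i in susp else None)]
        if i not in single:
            reactions.append(ReactionEntry(term="Myalgia"))

        drugs = []
        if i in susp:
            code = statin_assign[i]
            drugs.append(DrugEntry(
                drug_name=STATIN_SUBSTANCES[code], atc_code=code, role="suspected",
                dechallenge_action=dech_action[i], dechallenge_result=dech_result[i],
                rechallenge_action=rech_action[i], rechallenge_result=rech_result[i],
            ))
        else:
            name, atc = _cycle(_BACKGROUND_DRUGS, i)
            drugs.append(DrugEntry(drug_name=name, atc_code=atc, role="suspected"))
            if i in conc:
                drugs.append(DrugEntry(drug_name="simvastatin", atc_code="C10AA01",
                                       role="concomitant"))
        if i in case_antidep:
            drugs.append(DrugEntry(drug_name="citalopram", atc_code="N06AB04", role="concomitant"))
        if i in case_antiarr:
            drugs.append(DrugEntry(drug_name="amiodarone", atc_code="C01BD01", role="concomitant"))

        case_records.append(ReportRecord(
            report_id=f"C{i:04d}", age_years=age, sex=sex, report_year=year,
            country=country_assign[i] if i in susp else None,
            reporter_type=reporter,
            reactions=tuple(reactions), drugs=tuple(drugs),
        ))

    # --- non-case attribute index sets (global index j = 5*i + k) -----------
    nc_susp = {5 * i for i in range(0, 4)} | {5 * i for i in range(8, 51)}       # 47, 4 young
    nc_conc = {5 * i + 1 for i in range(120, 202)}                               # 82, all >= 50
    nc_physician = ({5 * i for i in range(8, 27)}                                # 19 suspected
                    | {5 * i + 2 for i in range(n_cases)}
                    | {5 * i + 3 for i in range(n_cases)}
                    | {5 * i + 4 for i in range(0, 175)})                        # 848 total
    nc_antidep = {5 * i + 1 for i in range(0, 74)}                               # 74
    nc_antiarr = {5 * i + 2 for i in range(0, 93)}                               # 93

    noncase_records = []
    for j in range(n_cases * ratio):
        i = j // ratio
        parent = case_records[i]
        reporter = _cycle(physician_types, j) if j in nc_physician else _cycle(lay_types, j)
        reactions = (ReactionEntry(term=_cycle(DEFAULT_BACKGROUND_TERMS, i)),)
        drugs = []
        if j in nc_susp:
            drugs.append(DrugEntry(drug_name="simvastatin", atc_code="C10AA01", role="suspected"))
        else:
            name, atc = _cycle(_BACKGROUND_DRUGS, j)
            drugs.append(DrugEntry(drug_name=name, atc_code=atc, role="suspected"))
            if j in nc_conc:
                drugs.append(DrugEntry(drug_name="simvastatin", atc_code="C10AA01",
                                       role="concomitant"))
        if j in nc_antidep:
            drugs.append(DrugEntry(drug_name="citalopram", atc_code="N06AB04", role="concomitant"))
        if j in nc_antiarr:
            drugs.append(DrugEntry(drug_name="amiodarone", atc_code="C01BD01", role="concomitant"))

        noncase_records.append(ReportRecord(
            report_id=f"N{j:05d}", age_years=parent.age_years, sex=parent.sex,
            report_year=parent.report_year, reporter_type=reporter,
            reactions=reactions, drugs=tuple(drugs),
        ))

    return Dataset(reports=case_records + noncase_records)
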