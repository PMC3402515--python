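"""Study orchestration: primary analysis, sensitivity scenarios, tables.

``run_primary`` executes the whole primary chain — case selection, 1:k matched
non-case sampling, exposure/covariate classification, crude reporting odds
ratio from the implied 2x2 table, and the change-in-estimate adjusted estimate
— and ``run_scenarios`` replays it under the five protocol sensitivity
scenarios. Scenarios re-filter the primary matched cohort (they never
re-match), so the non-case series is held fixed and only eligibility or the
exposure definition moves:

1. exposure widened to suspected-or-concomitant statins;
2. restriction to physician-type reporters;
3. restriction to patients aged 50 or older;
4. cases restricted to single-reaction-term reports (suspected exposure);
5. scenario 4 with the widened exposure definition.

Everything is driven by a YAML run configuration; results serialise to CSV
plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .icsr import Dataset, IntegrityError, load_dataset
from .cohort import CaseDefinition, MatchedCohort, match, select_cases, select_noncase_pool
from .exposure import (CovariateClass, CovariateMap, ExposureDefinition,
                       build_analysis_table, classify_exposure,
                       default_covariate_map, default_exposure_definition)
from .stats import (ContingencyTable, EstimateResult, baseline_test,
                    change_in_estimate_select, ror_2x2, round_half_up)

logger = logging.getLogger("casenoncase")

__all__ = [
    "ConfigError", "EmptyCohortError", "DegenerateExposureError",
    "RowFilter", "ScenarioSpec", "RunConfig", "default_scenarios",
    "PrimaryResults", "ScenarioResult", "DescriptiveProfile",
    "run_primary", "run_scenarios", "descriptive_profile", "write_results",
]

PHYSICIAN_REPORTER_TYPES = ("general_practitioner", "physician", "specialist", "hospital")
FORCED_TERMS = ["age_years", "sex", "report_year"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class EmptyCohortError(RuntimeError):
    """Case selection produced no cases."""


class DegenerateExposureError(RuntimeError):
    """Exposure has no variation in the cohort (all or none exposed)."""


@dataclass(frozen=True)
class RowFilter:
    """A predicate over analysis-table rows: ``field <op> value``."""

    field: str
    op: str  # in | eq | ge | gt | le | lt
    value: object

    def apply(self, rows: pd.DataFrame) -> pd.Series:
        col = rows[self.field]
        if self.op == "in":
            return col.isin(list(self.value))
        if self.op == "eq":
            return col == self.value
        if self.op == "ge":
            return col >= self.value
        if self.op == "gt":
            return col > self.value
        if self.op == "le":
            return col <= self.value
        if self.op == "lt":
            return col < self.value
        raise ConfigError(f"unknown filter op {self.op!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    exposure_roles: Optional[frozenset[str]] = None  # None -> inherit primary
    single_reaction_only: bool = False
    row_filters: tuple[RowFilter, ...] = ()
    reuse_matched_noncases: bool = True


def default_scenarios(
    physician_types=PHYSICIAN_REPORTER_TYPES,
    age_threshold: int = 50,
    age_strict: bool = False,
) -> list[ScenarioSpec]:
    """The five protocol sensitivity scenarios.

    The age restriction defaults to >= 50 (``age_strict=False``): the protocol
    phrase is "older than 50", but the published counts retain the 50-year-olds.
    """
    age_op = "gt" if age_strict else "ge"
    both = frozenset({"suspected", "concomitant"})
    return [
        ScenarioSpec(name="1_concomitant_exposure", exposure_roles=both),
        ScenarioSpec(name="2_physician_reported",
                     row_filters=(RowFilter("reporter_type", "in", tuple(physician_types)),)),
        ScenarioSpec(name="3_age_50_plus",
                     row_filters=(RowFilter("age_years", age_op, age_threshold),)),
        ScenarioSpec(name="4_single_term", single_reaction_only=True),
        ScenarioSpec(name="5_single_term_concomitant", single_reaction_only=True,
                     exposure_roles=both),
    ]


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`RunConfig.from_yaml`)."""

    reports_path: Optional[str] = None
    drugs_path: Optional[str] = None
    reactions_path: Optional[str] = None
    case_definition: CaseDefinition = field(default_factory=lambda: CaseDefinition(
        include_terms=frozenset({"Polymyalgia rheumatica"}),
        exclude_terms=frozenset({"Polymyalgia rheumatica aggravated"}),
    ))
    ratio: int = 5
    seed: int = 0
    policy: str = "strict_drop"
    widen_age_cap: int = 5
    exposure: ExposureDefinition = field(default_factory=default_exposure_definition)
    covariates: CovariateMap = field(default_factory=default_covariate_map)
    threshold: float = 0.10
    alpha: float = 0.05
    zero_correction: bool = True
    scenarios: list[ScenarioSpec] = field(default_factory=default_scenarios)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ConfigError(f"matching ratio must be >= 1, got {self.ratio}")
        if not (0 < self.threshold <= 1):
            raise ConfigError(f"change-in-estimate threshold must be in (0, 1], got {self.threshold}")
        if not (0 < self.alpha <= 0.5):
            raise ConfigError(f"alpha must be in (0, 0.5], got {self.alpha}")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ConfigError("scenario names must be unique")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            kw: dict = {}
            inp = raw.get("input", {})
            kw["reports_path"] = inp.get("reports")
            kw["drugs_path"] = inp.get("drugs")
            kw["reactions_path"] = inp.get("reactions")
            cd = raw.get("case_definition", {})
            if cd:
                kw["case_definition"] = CaseDefinition(
                    include_terms=frozenset(cd.get("include_terms", ["Polymyalgia rheumatica"])),
                    exclude_terms=frozenset(cd.get("exclude_terms", [])),
                    require_age=bool(cd.get("require_age", True)),
                    require_sex=bool(cd.get("require_sex", True)),
                )
            m = raw.get("matching", {})
            kw["ratio"] = int(m.get("ratio", 5))
            kw["seed"] = int(m.get("seed", 0))
            kw["policy"] = m.get("policy", "strict_drop")
            kw["widen_age_cap"] = int(m.get("widen_age_cap", 5))
            e = raw.get("exposure", {})
            if e:
                kw["exposure"] = ExposureDefinition(
                    atc_prefixes=frozenset(e.get("atc_prefixes", ["C10AA", "C10BA", "C10BX"])),
                    roles=frozenset(e.get("roles", ["suspected"])),
                )
            cov = raw.get("covariates")
            if cov is not None:
                kw["covariates"] = CovariateMap({
                    name: CovariateClass(include=frozenset(spec.get("include", [])),
                                         exclude=frozenset(spec.get("exclude", [])))
                    for name, spec in cov.items()
                })
            mod = raw.get("model", {})
            kw["threshold"] = float(mod.get("threshold", 0.10))
            kw["alpha"] = float(mod.get("alpha", 0.05))
            kw["zero_correction"] = bool(mod.get("zero_correction", True))
            sc = raw.get("scenarios", "default")
            if sc == "default" or sc is None:
                kw["scenarios"] = default_scenarios()
            else:
                kw["scenarios"] = [
                    ScenarioSpec(
                        name=s["name"],
                        exposure_roles=(frozenset(s["exposure_roles"])
                                        if s.get("exposure_roles") else None),
                        single_reaction_only=bool(s.get("single_reaction_only", False)),
                        row_filters=tuple(RowFilter(f["field"], f["op"], f["value"])
                                          for f in s.get("row_filters", [])),
                    )
                    for s in sc
                ]
            kw["output_dir"] = raw.get("output", {}).get("dir", "results")
            return cls(**kw)
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def load_input(self) -> Dataset:
        if not (self.reports_path and self.drugs_path and self.reactions_path):
            raise ConfigError("input paths (reports, drugs, reactions) are required")
        return load_dataset(self.reports_path, self.drugs_path, self.reactions_path)


@dataclass
class ScenarioResult:
    name: str
    exposure_roles: frozenset[str]
    table: ContingencyTable
    crude: EstimateResult
    adjusted: EstimateResult
    covariates_selected: list[str]


@dataclass
class PrimaryResults:
    cohort: MatchedCohort
    rows: pd.DataFrame
    table: ContingencyTable
    crude: EstimateResult
    adjusted: EstimateResult
    covariates_selected: list[str]
    baseline: pd.DataFrame


def _estimates_for_rows(rows: pd.DataFrame, cfg: RunConfig,
                        name: str) -> tuple[ContingencyTable, EstimateResult, EstimateResult, list[str]]:
    table = ContingencyTable.from_rows(rows)
    n_exposed = table.a + table.c
    if n_exposed == 0 or n_exposed == len(rows):
        raise DegenerateExposureError(
            f"{name}: exposure has no variation ({n_exposed} exposed of {len(rows)})")
    crude = ror_2x2(table, zero_correction=cfg.zero_correction, alpha=cfg.alpha)
    selected, _, adj_fit = change_in_estimate_select(
        rows, candidates=list(cfg.covariates), threshold=cfg.threshold, forced=FORCED_TERMS)
    adjusted = adj_fit.estimate_result(
        "exposed", kind="adjusted", covariates_selected=tuple(selected), alpha=cfg.alpha)
    return table, crude, adjusted, selected


def _baseline_table(rows: pd.DataFrame, ds: Dataset, cfg: RunConfig) -> pd.DataFrame:
    """Baseline-characteristics table with half-up one-decimal percentages."""
    cases = rows[rows["is_case"]]
    noncases = rows[~rows["is_case"]]
    n_ca, n_nc = len(cases), len(noncases)
    out = []

    age_ca, age_nc = cases["age_years"].astype(float), noncases["age_years"].astype(float)
    _, t_stat, t_p = baseline_test(age_ca, age_nc, "continuous")
    out.append({"characteristic": "age_mean", "cases_value": round_half_up(age_ca.mean(), 1),
                "cases_pct": None, "noncases_value": round_half_up(age_nc.mean(), 1),
                "noncases_pct": None, "test": "welch_t", "p_value": t_p})
    out.append({"characteristic": "age_sd", "cases_value": round_half_up(age_ca.std(ddof=1), 1),
                "cases_pct": None, "noncases_value": round_half_up(age_nc.std(ddof=1), 1),
                "noncases_pct": None, "test": None, "p_value": None})

    def flag_row(name: str, flag_ca: pd.Series, flag_nc: pd.Series) -> dict:
        test, _, p = baseline_test(flag_ca.to_numpy(dtype=bool), flag_nc.to_numpy(dtype=bool),
                                   "categorical")
        return {"characteristic": name,
                "cases_value": int(flag_ca.sum()),
                "cases_pct": round_half_up(100 * flag_ca.sum() / n_ca, 1),
                "noncases_value": int(flag_nc.sum()),
                "noncases_pct": round_half_up(100 * flag_nc.sum() / n_nc, 1),
                "test": test, "p_value": p}

    out.append(flag_row("age_lt_50", cases["age_years"] < 50, noncases["age_years"] < 50))
    out.append(flag_row("sex_female", cases["sex"] == "F", noncases["sex"] == "F"))

    out.append(flag_row("statin_suspected", cases["exposed"], noncases["exposed"]))
    ed_both = replace(cfg.exposure, roles=frozenset({"suspected", "concomitant"}))
    both = rows["report_id"].map(lambda rid: classify_exposure(ds.by_id(rid), ed_both))
    out.append(flag_row("statin_suspected_or_concomitant",
                        both[rows["is_case"]], both[~rows["is_case"]]))

    for cov in cfg.covariates:
        out.append(flag_row(cov, cases[cov], noncases[cov]))

    return pd.DataFrame(out, columns=["characteristic", "cases_value", "cases_pct",
                                      "noncases_value", "noncases_pct", "test", "p_value"])


def run_primary(cfg: RunConfig, ds: Optional[Dataset] = None) -> PrimaryResults:
    """Execute the primary analysis chain on ``ds`` (or the configured input files)."""
    if ds is None:
        ds = cfg.load_input()
    cases = select_cases(ds, cfg.case_definition)
    if not cases:
        raise EmptyCohortError("case selection returned no reports")
    pool = select_noncase_pool(ds, cfg.case_definition)
    cohort = match(cases, pool, ds, ratio=cfg.ratio, seed=cfg.seed,
                   policy=cfg.policy, widen_age_cap=cfg.widen_age_cap)
    if not cohort.matched_sets:
        raise EmptyCohortError("no case could be matched at the requested ratio")
    logger.info("primary cohort: %d cases, %d non-cases (%d dropped), seed %d",
                len(cohort.matched_sets), len(cohort.noncase_ids),
                len(cohort.dropped_cases), cfg.seed)
    rows = build_analysis_table(cohort, ds, cfg.exposure, cfg.covariates)
    table, crude, adjusted, selected = _estimates_for_rows(rows, cfg, "primary")
    logger.info("primary 2x2 a/b/c/d = %d/%d/%d/%d; covariates selected: %s",
                table.a, table.b, table.c, table.d, ", ".join(selected) or "none")
    baseline = _baseline_table(rows, ds, cfg)
    return PrimaryResults(cohort=cohort, rows=rows, table=table, crude=crude,
                          adjusted=adjusted, covariates_selected=selected, baseline=baseline)


def run_scenarios(cfg: RunConfig, primary: PrimaryResults,
                  ds: Optional[Dataset] = None) -> list[ScenarioResult]:
    """Run the configured sensitivity scenarios against the primary matched cohort.

    Each scenario re-filters the primary cohort's rows (cases and matched
    non-cases), optionally restricts cases to single-reaction reports, and
    optionally re-classifies exposure under its own role set. A scenario whose
    filters leave no cases is skipped with a warning.
    """
    if ds is None:
        ds = cfg.load_input()
    results = []
    for spec in cfg.scenarios:
        rows = primary.rows.copy()
        roles = spec.exposure_roles if spec.exposure_roles is not None else cfg.exposure.roles
        if roles != cfg.exposure.roles:
            ed = replace(cfg.exposure, roles=frozenset(roles))
            rows["exposed"] = rows["report_id"].map(
                lambda rid: classify_exposure(ds.by_id(rid), ed))
        keep = pd.Series(True, index=rows.index)
        for f in spec.row_filters:
            keep &= f.apply(rows)
        if spec.single_reaction_only:
            keep &= ~rows["is_case"] | (rows["n_reactions"] == 1)
        rows = rows[keep]
        n_cases = int(rows["is_case"].sum())
        if n_cases == 0:
            logger.warning("scenario %s: no cases after filtering; skipped", spec.name)
            continue
        try:
            table, crude, adjusted, selected = _estimates_for_rows(rows, cfg, spec.name)
        except DegenerateExposureError as exc:
            logger.warning("scenario %s skipped: %s", spec.name, exc)
            continue
        logger.info("scenario %s: %d cases / %d non-cases; a/c = %d/%d",
                    spec.name, table.n_cases, table.n_noncases, table.a, table.c)
        results.append(ScenarioResult(name=spec.name, exposure_roles=frozenset(roles),
                                      table=table, crude=crude, adjusted=adjusted,
                                      covariates_selected=selected))
    return results


@dataclass
class DescriptiveProfile:
    """Descriptive tallies for the exposed case series (each sums to ``n_reports``)."""

    n_reports: int
    statin_substance: dict[str, int]
    reporting_year: dict[int, int]
    time_to_onset: dict[str, int]
    outcome: dict[str, int]
    dechallenge_action: dict[str, int]
    dechallenge_result: dict[str, int]
    rechallenge_action: dict[str, int]
    rechallenge_result: dict[str, int]
    reporter: dict[str, int]
    country: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section in ("statin_substance", "reporting_year", "time_to_onset", "outcome",
                        "dechallenge_action", "dechallenge_result", "rechallenge_action",
                        "rechallenge_result", "reporter", "country"):
            for category, count in getattr(self, section).items():
                rows.append({"section": section, "category": category, "count": count})
        return pd.DataFrame(rows, columns=["section", "category", "count"])


def _onset_bin(days: Optional[int]) -> str:
    if days is None:
        return "not_recorded"
    if days <= 90:
        return "1-90"
    if days <= 365:
        return "91-365"
    return ">365"


def descriptive_profile(ds: Dataset, case_ids: list[str],
                        ed: Optional[ExposureDefinition] = None) -> DescriptiveProfile:
    """Tabulate the descriptive case profile for exposed cases.

    Time-to-onset uses the first recorded ``onset_days`` with bin boundaries
    [1, 90], [91, 365], (365, inf); drug-level dechallenge/rechallenge fields
    come from the first drug matching the exposure definition; the statin
    substance is resolved from the 7-character ATC code.
    """
    if ed is None:
        ed = default_exposure_definition()
    profile = {name: Counter() for name in
               ("statin_substance", "reporting_year", "time_to_onset", "outcome",
                "dechallenge_action", "dechallenge_result", "rechallenge_action",
                "rechallenge_result", "reporter", "country")}
    from .synthetic import STATIN_SUBSTANCES

    for rid in case_ids:
        r = ds.by_id(rid)
        profile["reporting_year"][r.report_year] += 1
        profile["reporter"][r.reporter_type or "not_reported"] += 1
        profile["country"][r.country or "not_recorded"] += 1

        onset = next((x.onset_days for x in r.reactions if x.onset_days is not None), None)
        profile["time_to_onset"][_onset_bin(onset)] += 1
        outcome = next((x.outcome for x in r.reactions if x.outcome is not None), None)
        profile["outcome"][outcome or "not_recorded"] += 1

        drug = next(
            (d for d in r.drugs
             if d.role in ed.roles and d.atc_code is not None
             and any(d.atc_code.startswith(p) for p in ed.atc_prefixes)),
            None)
        if drug is not None:
            profile["statin_substance"][STATIN_SUBSTANCES.get(drug.atc_code, drug.atc_code)] += 1
            profile["dechallenge_action"][drug.dechallenge_action or "not_recorded"] += 1
            profile["dechallenge_result"][drug.dechallenge_result or "not_recorded"] += 1
            profile["rechallenge_action"][drug.rechallenge_action or "not_recorded"] += 1
            profile["rechallenge_result"][drug.rechallenge_result or "not_recorded"] += 1
        else:
            for section in ("statin_substance", "dechallenge_action", "dechallenge_result",
                            "rechallenge_action", "rechallenge_result"):
                profile[section]["not_recorded"] += 1

    return DescriptiveProfile(n_reports=len(case_ids),
                              **{k: dict(v) for k, v in profile.items()})


def _estimate_row(name: str, roles: frozenset[str], table: ContingencyTable,
                  crude: EstimateResult, adjusted: EstimateResult,
                  selected: list[str]) -> dict:
    return {
        "scenario": name,
        "exposure_definition": "+".join(sorted(roles)),
        "n_cases": table.n_cases, "n_noncases": table.n_noncases,
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
        "crude_ror": crude.estimate, "crude_ci_low": crude.ci_low,
        "crude_ci_high": crude.ci_high,
        "adjusted_ror": adjusted.estimate, "adjusted_ci_low": adjusted.ci_low,
        "adjusted_ci_high": adjusted.ci_high,
        "p_value": adjusted.p_value,
        "covariates_selected": ";".join(selected),
    }


def write_results(cfg: RunConfig, primary: PrimaryResults,
                  scenarios: list[ScenarioResult], out_dir=None) -> dict[str, Path]:
    """Serialise a completed run: ror_results, baseline, matched_sets, analysis_table, manifest."""
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    est_rows = [_estimate_row("primary", cfg.exposure.roles, primary.table,
                              primary.crude, primary.adjusted, primary.covariates_selected)]
    est_rows += [_estimate_row(s.name, s.exposure_roles, s.table, s.crude, s.adjusted,
                               s.covariates_selected) for s in scenarios]
    paths = {
        "ror_results": out / "ror_results.csv",
        "baseline": out / "baseline.csv",
        "matched_sets": out / "matched_sets.csv",
        "analysis_table": out / "analysis_table.csv",
        "run_manifest": out / "run_manifest.json",
    }
    pd.DataFrame(est_rows).to_csv(paths["ror_results"], index=False)
    primary.baseline.to_csv(paths["baseline"], index=False)
    primary.cohort.write_csv(paths["matched_sets"])
    primary.rows.to_csv(paths["analysis_table"], index=False)

    from . import __version__
    cfg_repr = repr(cfg).encode()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
        "seed": cfg.seed,
        "version": __version__,
        "n_cases": primary.table.n_cases,
        "n_noncases": primary.table.n_noncases,
        "dropped_cases": len(primary.cohort.dropped_cases),
        "covariates_selected": primary.covariates_selected,
        "scenarios": [s.name for s in scenarios],
    }
    paths["run_manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
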