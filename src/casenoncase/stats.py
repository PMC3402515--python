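"""Reporting odds ratios, logistic regression, and confounder selection.

The reporting odds ratio (ROR) for a 2x2 exposure-by-status table

    =============  ========  ============
                   cases     non-cases
    exposed        a         c
    unexposed      b         d
    =============  ========  ============

is ``(a/b) / (c/d) = ad/(bc)``: the odds of exposure among reports of the
event of interest divided by the odds among all other reports. Its standard
error on the log scale is the Woolf formula ``sqrt(1/a + 1/b + 1/c + 1/d)``,
giving the log-normal CI ``exp(log ROR ± z * se)`` and a two-sided Wald test.
When a cell is zero the Haldane–Anscombe correction (0.5 added to every cell)
can be opted in.

Adjusted RORs come from unconditional maximum-likelihood logistic regression
of case status on exposure, the matching variables, and the co-medication
covariates retained by the change-in-estimate rule: a candidate confounder is
kept iff adding it alone moves the exposure coefficient (log-odds beta) by at
least ``threshold`` (default 10%) relative to the crude model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("casenoncase")

__all__ = [
    "ContingencyTable",
    "EstimateResult",
    "LogisticFit",
    "StatsError",
    "SingularityError",
    "ror_2x2",
    "fit_logistic",
    "change_in_estimate_select",
    "baseline_test",
    "round_half_up",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


class SingularityError(StatsError):
    """Design matrix is rank deficient."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"design matrix rank deficient; aliased term(s): {aliased}")


@dataclass(frozen=True)
class ContingencyTable:
    """Exposure-by-status counts: a/c exposed, b/d unexposed; a,b cases, c,d non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise StatsError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise StatsError("each status group must contain at least one report")

    @classmethod
    def from_rows(cls, rows: pd.DataFrame) -> "ContingencyTable":
        """Tabulate an analysis table (``is_case`` x ``exposed``)."""
        is_case = rows["is_case"].to_numpy(dtype=bool)
        exposed = rows["exposed"].to_numpy(dtype=bool)
        return cls(
            a=int((is_case & exposed).sum()),
            b=int((is_case & ~exposed).sum()),
            c=int((~is_case & exposed).sum()),
            d=int((~is_case & ~exposed).sum()),
        )

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_noncases(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class EstimateResult:
    """A point estimate on the odds-ratio scale with its Wald/Woolf inference."""

    estimate: float
    ci_low: float
    ci_high: float
    log_beta: float
    se_log: float
    p_value: float
    kind: str  # crude | adjusted
    covariates_selected: tuple[str, ...] = ()
    alpha: float = 0.05


def ror_2x2(t: ContingencyTable, zero_correction: bool = False, alpha: float = 0.05) -> EstimateResult:
    """Crude reporting odds ratio ``ad/(bc)`` with Woolf CI and two-sided Wald p.

    With ``zero_correction`` and any zero cell, 0.5 is added to all four cells
    (Haldane–Anscombe) before both the estimate and the standard error; without
    it a zero cell raises :class:`StatsError`.
    """
    cells = [float(t.a), float(t.b), float(t.c), float(t.d)]
    if any(x == 0 for x in cells):
        if not zero_correction:
            raise StatsError("zero cell in 2x2 table; enable zero_correction or collect more data")
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    log_ror = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    p = 2 * sps.norm.sf(abs(log_ror) / se)
    return EstimateResult(
        estimate=math.exp(log_ror),
        ci_low=math.exp(log_ror - z * se),
        ci_high=math.exp(log_ror + z * se),
        log_beta=log_ror,
        se_log=se,
        p_value=float(p),
        kind="crude",
        alpha=alpha,
    )


@dataclass(frozen=True)
class LogisticFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    n_iterations: int
    log_likelihood: float
    separation_warning: bool = False

    def estimate_result(self, term: str = "exposed", kind: str = "adjusted",
                        covariates_selected: tuple[str, ...] = (), alpha: float = 0.05) -> EstimateResult:
        """Wald inference for one coefficient on the odds-ratio scale."""
        beta = self.coefficients[term]
        se = self.standard_errors[term]
        z = sps.norm.ppf(1 - alpha / 2)

        def safe_exp(x: float) -> float:
            try:
                return math.exp(x)
            except OverflowError:
                return math.inf

        return EstimateResult(
            estimate=safe_exp(beta),
            ci_low=safe_exp(beta - z * se),
            ci_high=safe_exp(beta + z * se),
            log_beta=beta,
            se_log=se,
            p_value=float(2 * sps.norm.sf(abs(beta) / se)),
            kind=kind,
            covariates_selected=covariates_selected,
            alpha=alpha,
        )


def _design_matrix(rows: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = rows["is_case"].to_numpy(dtype=float)
    cols = [np.ones(len(rows))]
    names = ["intercept"]
    for t in terms:
        if t == "sex":
            cols.append((rows["sex"] == "F").to_numpy(dtype=float))
        else:
            cols.append(rows[t].to_numpy(dtype=float))
        names.append(t)
    return np.column_stack(cols), y, names


def _aliased_terms(X: np.ndarray, names: list[str]) -> list[str]:
    # QR with column pivoting: columns whose R diagonal collapses are aliased.
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return sorted(names[piv[i]] for i in range(len(names)) if i >= len(diag) or diag[i] <= tol)


def fit_logistic(rows: pd.DataFrame, terms: list[str], maxiter: int = 50) -> LogisticFit:
    """Maximum-likelihood binary logistic regression of ``is_case`` on ``terms``.

    Newton's method with an intercept always included; ``sex`` enters as a
    female indicator, booleans as 0/1, continuous terms untransformed.
    Standard errors come from the observed information matrix. A constant
    outcome raises :class:`StatsError`; rank deficiency raises
    :class:`SingularityError` naming the aliased terms; any coefficient with
    magnitude above 15 at convergence sets ``separation_warning``.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)

    X, y, names = _design_matrix(rows, list(terms))
    if y.min() == y.max():
        raise StatsError("outcome is_case has no variation")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularityError(_aliased_terms(X, names))

    model = sm.Logit(y, X)
    separation = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=0,
                            warn_convergence=False)
        separation = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
        converged = bool(res.mle_retvals.get("converged", False))
        n_iter = int(res.mle_retvals.get("iterations", maxiter))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        # Complete/quasi separation: Newton's information matrix degenerates.
        res = model.fit(method="lbfgs", maxiter=200, disp=0)
        converged = False
        n_iter = maxiter
        separation = True

    params = np.asarray(res.params, dtype=float)
    try:
        bse = np.asarray(res.bse, dtype=float)
    except np.linalg.LinAlgError:
        bse = np.full_like(params, np.nan)
    # The intercept is excluded: with uncentered continuous covariates (e.g.
    # calendar year) a large intercept is expected, not a separation signal.
    slope_max = np.max(np.abs(params[1:])) if len(params) > 1 else 0.0
    if slope_max > 15:
        separation = True
        logger.warning("possible separation: |coefficient| > 15 (max %.2f)", slope_max)

    return LogisticFit(
        coefficients=dict(zip(names, params)),
        standard_errors=dict(zip(names, bse)),
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=float(res.llf),
        separation_warning=separation,
    )


def change_in_estimate_select(
    rows: pd.DataFrame,
    candidates: list[str],
    threshold: float = 0.10,
    forced: list[str] = (),
) -> tuple[list[str], LogisticFit, LogisticFit]:
    """Change-in-estimate confounder selection around the exposure coefficient.

    Crude model: ``is_case ~ exposed + forced``. Each candidate is added singly
    and retained iff ``|beta_with - beta_crude| / |beta_crude| >= threshold``;
    the adjusted model refits with all retained candidates jointly. Returns
    ``(selected, crude_fit, adjusted_fit)`` with ``selected`` in candidate
    order. If the crude exposure coefficient is exactly zero the relative
    change is undefined and selection falls back to an absolute change of
    ``threshold * 0.1`` with a logged warning. Candidates whose single-addition
    fit fails (aliasing, no variation) are never selected.
    """
    forced = list(forced)
    candidates = list(candidates)
    if set(candidates) & set(forced):
        raise StatsError("candidates and forced terms must be disjoint")

    crude = fit_logistic(rows, ["exposed"] + forced)
    beta_crude = crude.coefficients["exposed"]

    selected = []
    for cand in candidates:
        try:
            fit_c = fit_logistic(rows, ["exposed"] + forced + [cand])
        except StatsError as exc:
            logger.warning("candidate %s skipped: %s", cand, exc)
            continue
        delta = abs(fit_c.coefficients["exposed"] - beta_crude)
        if beta_crude == 0.0:
            logger.warning("crude exposure beta is 0; using absolute change criterion for %s", cand)
            keep = delta >= threshold * 0.1
        else:
            keep = delta / abs(beta_crude) >= threshold
        if keep:
            selected.append(cand)

    adjusted = fit_logistic(rows, ["exposed"] + forced + selected)
    return selected, crude, adjusted


def baseline_test(values_cases, values_noncases, kind: str) -> tuple[str, float, float]:
    """Between-group test for one baseline characteristic.

    ``continuous``: Welch two-sample t-test on the raw values. ``categorical``
    (binary flags): Pearson chi-square without continuity correction when every
    expected cell is at least 5, otherwise the two-sided Fisher exact test
    (summing hypergeometric probabilities no larger than the observed table's).
    Returns ``(test_name, statistic, p_value)``; for Fisher the statistic is
    the conditional odds ratio.
    """
    x = np.asarray(values_cases)
    y = np.asarray(values_noncases)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("both groups must be non-empty")
    if kind == "continuous":
        stat, p = sps.ttest_ind(x.astype(float), y.astype(float), equal_var=False)
        return "welch_t", float(stat), float(p)
    if kind != "categorical":
        raise StatsError(f"unknown test kind {kind!r}")
    levels = np.unique(np.concatenate([x, y]))
    if len(levels) > 2:
        raise StatsError(f"categorical baseline test supports 2 levels, got {len(levels)}")
    x_bool = x.astype(bool)
    y_bool = y.astype(bool)
    table = np.array([
        [int(x_bool.sum()), int((~x_bool).sum())],
        [int(y_bool.sum()), int((~y_bool).sum())],
    ])
    expected = sps.contingency.expected_freq(table)
    if (expected >= 5).all():
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return "chi_square", float(stat), float(p)
    stat, p = sps.fisher_exact(table, alternative="two-sided")
    return "fisher_exact", float(stat), float(p)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (matches tabulated percentage conventions)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
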