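"""Survival and comparison statistics used throughout the package.

The estimators that carry the scientific weight of the cutpoint procedure —
the Kaplan–Meier product-limit curve, the two-group log-rank test (including
a vectorised variant evaluated over a whole grid of dichotomising
thresholds), the Welch unequal-variance t test, Fisher's exact test, and the
logit (Mudholkar–George) p-value combination — are implemented here directly
so that their behaviour is fully specified by this module. Cox proportional
hazards fitting delegates to :mod:`lifelines` (Efron tie handling, Wald
inference) behind a small result contract.

All functions are pure: they take in-memory vectors/tables and return plain
result objects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KmCurve",
    "TestResult",
    "CoxResult",
    "km_estimate",
    "km_median_followup",
    "logrank_test",
    "logrank_grid",
    "welch_t",
    "fisher_exact",
    "logit_combine",
    "cox_fit",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve.

    ``times`` holds the distinct event times in increasing order; ``survival``
    the estimate S(t) just after each, ``at_risk`` and ``n_events`` the risk
    set size and event count at each time. ``median`` is the smallest event
    time with S(t) <= 0.5, or ``nan`` if the curve never reaches 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float

    def survival_at(self, t: float) -> float:
        """S(t) by right-continuous step interpolation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method_name: str
    df: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CoxCovariate:
    name: str
    coefficient: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float


@dataclass(frozen=True)
class CoxResult:
    covariates: tuple[CoxCovariate, ...]
    n: int
    n_events: int
    log_likelihood: float
    converged: bool

    def __getitem__(self, name: str) -> CoxCovariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


def _check_time_event(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")
    return time, event


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KmCurve:
    """Kaplan–Meier product-limit estimate for a single group.

    Ties are grouped: each distinct event time contributes one multiplicative
    factor (1 - d/n). Censoring times falling at an event time are treated as
    still at risk at that time (the standard convention).
    """
    time, event = _check_time_event(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size

    ev_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    d_at = []
    s = 1.0
    for et in ev_times:
        r = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        d_at.append(d)
    surv = np.asarray(surv)
    ev_times = np.asarray(ev_times, dtype=float)
    below = ev_times[surv <= 0.5] if surv.size else np.array([])
    median = float(below[0]) if below.size else math.nan
    return KmCurve(
        times=ev_times,
        survival=surv,
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(d_at),
        median=median,
    )


def km_median_followup(time, event) -> float:
    """Median follow-up by the reverse Kaplan–Meier method.

    Censoring is treated as the event of interest; the median of that curve
    is the conventional 'median follow-up time'.
    """
    time, event = _check_time_event(time, event)
    return km_estimate(time, 1 - event).median


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def logrank_test(time, event, group) -> TestResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; the statistic is
    (sum(O - E))^2 / sum(V), referred to chi-square with 1 df. Event times at
    which the hypergeometric variance vanishes contribute nothing.

    With zero events overall the test is degenerate: statistic 0, p = 1,
    flagged in ``extra['degenerate']``.
    """
    time, event = _check_time_event(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise ValueError("group must have the same length as time")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"logrank_test requires exactly 2 groups, got {levels.size}")
    if event.sum() == 0:
        return TestResult(0.0, 1.0, "logrank", df=1, extra={"degenerate": True})

    in1 = group == levels[1]
    o_minus_e, var = _logrank_terms(time, event, in1[:, None])
    o_minus_e, var = float(o_minus_e[0]), float(var[0])
    if var == 0.0:
        return TestResult(0.0, 1.0, "logrank", df=1, extra={"degenerate": True})
    chi2 = o_minus_e**2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), p, "logrank", df=1,
                      extra={"observed_minus_expected": o_minus_e, "variance": var})


def _logrank_terms(time, event, member):
    """Sum of (O - E) and hypergeometric variance for column-wise groupings.

    ``member`` is an (n, k) boolean matrix; column j defines "group 1" for
    the j-th grouping. Returns two length-k arrays. Vectorising over k makes
    threshold-grid scans cheap.
    """
    order = np.argsort(time, kind="stable")
    t, e, m = time[order], event[order], member[order]
    n = t.size

    # distinct event times and, for each, total deaths / deaths in group 1
    ev_mask = e == 1
    ev_times = np.unique(t[ev_mask])
    # at-risk index: number with t >= et == n - searchsorted(t, et, 'left')
    start = np.searchsorted(t, ev_times, side="left")
    n_risk = n - start

    # suffix cumulative membership count -> at risk in group 1
    suffix = np.vstack([np.cumsum(m[::-1], axis=0)[::-1], np.zeros((1, m.shape[1]))])
    n1_risk = suffix[start]

    # deaths per distinct time (total and in group 1)
    d_total = np.zeros(ev_times.size)
    d1 = np.zeros((ev_times.size, m.shape[1]))
    idx = np.searchsorted(ev_times, t[ev_mask])
    np.add.at(d_total, idx, 1.0)
    np.add.at(d1, idx, m[ev_mask].astype(float))

    with np.errstate(divide="ignore", invalid="ignore"):
        expect = d_total[:, None] * n1_risk / n_risk[:, None]
        var = (
            d_total[:, None]
            * (n1_risk / n_risk[:, None])
            * (1.0 - n1_risk / n_risk[:, None])
            * (n_risk[:, None] - d_total[:, None])
            / np.maximum(n_risk[:, None] - 1.0, 1.0)
        )
    var = np.where(n_risk[:, None] > 1, var, 0.0)
    o_minus_e = (d1 - expect).sum(axis=0)
    return o_minus_e, var.sum(axis=0)


def logrank_grid(time, event, values, thresholds) -> np.ndarray:
    """Log-rank p-value for dichotomisation ``values > tau`` at each tau.

    Evaluates the two-group log-rank test simultaneously for every threshold
    in ``thresholds``; thresholds whose split leaves an empty group or zero
    variance get p = 1. Returns an array of p-values aligned with
    ``thresholds``.
    """
    time, event = _check_time_event(time, event)
    values = np.asarray(values, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    member = values[:, None] > thresholds[None, :]
    n_high = member.sum(axis=0)
    o_minus_e, var = _logrank_terms(time, event, member)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / np.where(var > 0, var, 1.0), 0.0)
    p = sps.chi2.sf(chi2, df=1)
    p = np.where((var > 0) & (n_high > 0) & (n_high < values.size), p, 1.0)
    return p


# ---------------------------------------------------------------------------
# Welch t and Fisher exact
# ---------------------------------------------------------------------------


def welch_t(x, y) -> TestResult:
    """Welch two-sample t test (unequal variances), two-sided.

    Uses the Welch–Satterthwaite degrees of freedom. Identical inputs yield
    statistic 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        return TestResult(0.0, 1.0, "welch_t", df=float(nx + ny - 2))
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(float(t), min(p, 1.0), "welch_t", df=float(df))


def fisher_exact(table, *, seed: int | None = None, n_draws: int = 100_000) -> TestResult:
    """Fisher's exact test, two-sided by the probability-mass rule.

    The p-value sums the margin-conditional (multivariate hypergeometric)
    probability of every table whose probability does not exceed that of the
    observed table (with a 1e-7 relative slack for float ties). Tables with a
    2-row or 2-column layout are enumerated exactly when the enumeration is
    small enough (this covers 2x2 and the histology x factor tables this
    package produces); anything larger falls back to a seeded Monte-Carlo
    estimate over ``n_draws`` samples of the fixed-margins table
    distribution. The statistic is the sample odds ratio for 2x2 tables and
    NaN otherwise.
    """
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValueError("contingency table cells must be non-negative")
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate margin: a row or column sums to zero")

    odds = math.nan
    if table.shape == (2, 2):
        odds = math.inf if table[0, 1] * table[1, 0] == 0 else (
            table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0])
        )

    work = table if table.shape[0] == 2 else table.T
    if work.shape[0] == 2:
        r1 = int(work[0].sum())
        cmargins = work.sum(axis=0)
        n_combo = float(np.prod([min(r1, int(c)) + 1 for c in cmargins]))
        if n_combo <= 5e5:
            p = _fisher_2xc_exact(work[0], r1, cmargins)
            name = "fisher_exact" if table.shape == (2, 2) else "fisher_exact_rxc"
            return TestResult(float(odds), min(p, 1.0), name)

    rng = np.random.default_rng(seed)
    logp_obs = _log_table_prob(table, rows, cols)
    samples = sps.random_table(rows, cols).rvs(n_draws, random_state=rng)
    logp = np.array([_log_table_prob(s, rows, cols) for s in np.asarray(samples)])
    p = float(np.mean(logp <= logp_obs + 1e-9))
    return TestResult(odds, p, "fisher_exact_mc", extra={"n_draws": n_draws})


def _fisher_2xc_exact(observed_row, r1, cols) -> float:
    """Probability-mass two-sided p for a 2 x c table by full enumeration.

    Enumerates every first row ``a`` with 0 <= a_j <= col_j and sum(a) = r1;
    the table probability is prod_j C(col_j, a_j) / C(n, r1).
    """
    from scipy.special import gammaln

    cols = np.asarray(cols, dtype=int)
    n = int(cols.sum())
    log_denom = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)

    def log_choose(c, a):
        return gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)

    logp_obs = sum(log_choose(int(c), int(a)) for c, a in zip(cols, observed_row)) - log_denom

    logps: list[float] = []

    def rec(j: int, remaining: int, acc: float) -> None:
        if j == len(cols) - 1:
            if 0 <= remaining <= cols[j]:
                logps.append(acc + log_choose(int(cols[j]), remaining))
            return
        tail = int(cols[j + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(int(cols[j]), remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, acc + log_choose(int(cols[j]), a))

    rec(0, r1, 0.0)
    logps_arr = np.asarray(logps) - log_denom
    probs = np.exp(logps_arr)
    return float(probs[logps_arr <= logp_obs + math.log(1 + 1e-7)].sum())


def _log_table_prob(table, rows, cols):
    """Log-probability of a table under the fixed-margins null."""
    from scipy.special import gammaln

    n = rows.sum()
    return float(
        gammaln(rows + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(n + 1)
        - gammaln(np.asarray(table) + 1).sum()
    )


# ---------------------------------------------------------------------------
# logit p-value combination (Mudholkar–George)
# ---------------------------------------------------------------------------

_LOGIT_EPS = 1e-15


def logit_combine(p_values) -> float:
    """Combine p-values by the logit method.

    With k p-values, G = -sum(log(p_i / (1 - p_i))) is referred to C * t_nu
    with nu = 5k + 4 and C = sqrt(k * pi^2 * (5k + 2) / (3 * (5k + 4))); the
    combined p is the upper-tail probability, so uniformly small inputs give
    a small output. Inputs are clipped into [1e-15, 1 - 1e-15] to keep the
    logit finite.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("logit_combine requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    k = p.size
    g = -np.sum(np.log(p / (1.0 - p)))
    nu = 5 * k + 4
    c = math.sqrt(k * math.pi**2 * (5 * k + 2) / (3.0 * nu))
    return float(sps.t.sf(g / c, df=nu))


# ---------------------------------------------------------------------------
# Cox proportional hazards (lifelines-backed)
# ---------------------------------------------------------------------------


class CoxConvergenceError(RuntimeError):
    """Raised when the partial likelihood cannot be maximised (e.g. monotone
    likelihood under perfect separation)."""


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            covariate_cols: Sequence[str] | None = None) -> CoxResult:
    """Fit a Cox proportional-hazards model (Efron ties, Wald inference).

    ``df`` must contain the duration and event columns plus numeric covariate
    columns (categorical covariates are expected to be pre-expanded to
    indicator contrasts). Monotone likelihood / separation is raised as
    :class:`CoxConvergenceError` rather than returned silently.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (duration_col, event_col)]
    cols = [duration_col, event_col, *covariate_cols]
    data = df[cols].dropna()
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise ValueError("cox_fit requires at least one event")
    if not np.all(np.isfinite(data[covariate_cols].to_numpy(dtype=float))):
        raise ValueError("covariates must be finite")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # numeric noise from doomed steps
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(data, duration_col=duration_col, event_col=event_col,
                    fit_options={"precision": 1e-9})
    except (ConvergenceError, ConvergenceWarning, Exception) as exc:
        if isinstance(exc, (ConvergenceError, ConvergenceWarning)) or \
                "convergence" in str(exc).lower() or "delta contains nan" in str(exc).lower():
            raise CoxConvergenceError(str(exc)) from exc
        raise

    summ = cph.summary
    coefs = summ["coef"].to_numpy(dtype=float)
    ses = summ["se(coef)"].to_numpy(dtype=float)
    if not np.all(np.isfinite(coefs)) or not np.all(np.isfinite(ses)) \
            or np.any(np.abs(coefs) > 50):
        raise CoxConvergenceError(
            "monotone likelihood suspected (diverging coefficient); "
            "a covariate may perfectly separate events")
    covs = tuple(
        CoxCovariate(
            name=str(name),
            coefficient=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
            se=float(row["se(coef)"]),
        )
        for name, row in summ.iterrows()
    )
    return CoxResult(
        covariates=covs,
        n=int(len(data)),
        n_events=n_events,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
    )
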