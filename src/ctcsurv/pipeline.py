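"""End-to-end cohort analysis: exclusions, stratification, descriptive
tables, count comparisons, cutpoint optimisation and dichotomised survival
models.

The entry point :func:`run_full_analysis` reproduces the structure of a
histology-stratified CTC/DTC study on any conforming cohort table: it drops
records with missing histology or CTC count, partitions by enumeration
method and treatment strategy, compares marker counts between histologies
(raw Welch test on means, covariate-adjusted linear model on
log10(x+1)-transformed counts), builds characteristics tables, optimises
prognostic thresholds per histology and marker by Monte-Carlo
cross-validation, and fits dichotomised and four-group survival models
(Kaplan–Meier, log-rank, univariate and multivariate Cox).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st
from .cutpoint import MccvConfig, classify_high_low, four_group_label, mccv_optimize
from .schema import HISTOLOGIES, METHODS, SUBTYPES, TREATMENTS, validate_cohort

__all__ = [
    "ExclusionReport",
    "StratifiedCohorts",
    "ComparisonResult",
    "AnalysisConfig",
    "apply_exclusions",
    "stratify",
    "positivity_rate",
    "compare_counts",
    "characteristics_table",
    "survival_by_group",
    "run_full_analysis",
    "format_percent",
]


# ---------------------------------------------------------------------------
# exclusions and stratification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_excluded: int
    n_retained: int
    reasons: dict  # reason -> count (not mutually exclusive)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "reasons": dict(self.reasons),
        }


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop records with missing histology or missing CTC count."""
    miss_hist = records["histology"].isna()
    miss_ctc = records["ctc_per_ml"].isna()
    drop = miss_hist | miss_ctc
    retained = records.loc[~drop].copy()
    report = ExclusionReport(
        n_input=len(records),
        n_excluded=int(drop.sum()),
        n_retained=len(retained),
        reasons={
            "missing_histology": int(miss_hist.sum()),
            "missing_ctc": int(miss_ctc.sum()),
            "missing_histology_or_ctc": int(drop.sum()),
        },
    )
    return retained, report


@dataclass(frozen=True)
class StratifiedCohorts:
    """Partition of retained records by enumeration method and treatment."""

    subsets: dict  # (method, treatment) -> DataFrame

    def subset(self, method: str, treatment: str) -> pd.DataFrame:
        return self.subsets[(method, treatment)]

    def by_method(self, method: str) -> pd.DataFrame:
        parts = [df for (m, _), df in self.subsets.items() if m == method]
        return pd.concat(parts) if parts else next(iter(self.subsets.values())).iloc[:0]

    @property
    def sizes(self) -> dict:
        return {f"{m}/{t}": len(df) for (m, t), df in self.subsets.items()}


def stratify(records: pd.DataFrame) -> StratifiedCohorts:
    subsets = {
        (m, t): records[(records["method"] == m) & (records["treatment"] == t)].copy()
        for m in METHODS
        for t in TREATMENTS
    }
    return StratifiedCohorts(subsets=subsets)


# ---------------------------------------------------------------------------
# marker comparisons
# ---------------------------------------------------------------------------


def positivity_rate(records: pd.DataFrame, marker: str) -> dict:
    """Fraction with marker value > 0 per histology, with a Fisher exact p
    for the histology x positivity 2x2 table."""
    col = f"{marker}_per_ml"
    data = records.dropna(subset=[col, "histology"])
    out = {}
    table = []
    for h in HISTOLOGIES:
        vals = data.loc[data["histology"] == h, col]
        pos = int((vals > 0).sum())
        out[h] = {"n": int(len(vals)), "n_positive": pos,
                  "rate": pos / len(vals) if len(vals) else math.nan}
        table.append([pos, len(vals) - pos])
    if all(r[0] + r[1] > 0 for r in table):
        try:
            out["fisher_p"] = st.fisher_exact(np.array(table, dtype=int)).p_value
        except ValueError:
            # constant positivity (all zero or all positive): no association
            out["fisher_p"] = 1.0
    else:
        out["fisher_p"] = math.nan
    return out


@dataclass(frozen=True)
class ComparisonResult:
    marker: str
    group_means: dict   # histology -> raw-scale mean
    group_n: dict
    difference: float   # ILC mean - IDC mean
    p_unadjusted: float
    p_adjusted: float | None
    transform: str
    n_complete: int | None = None
    dropped_covariates: tuple = ()

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "group_means": dict(self.group_means),
            "group_n": dict(self.group_n),
            "difference": self.difference,
            "p_unadjusted": self.p_unadjusted,
            "p_adjusted": self.p_adjusted,
            "transform": self.transform,
            "n_complete": self.n_complete,
            "dropped_covariates": list(self.dropped_covariates),
        }


_ADJUST_COVARIATES = ("age", "grade", "stage", "receptor_subtype")


def compare_counts(subset: pd.DataFrame, marker: str, adjust: bool = True,
                   transform: str = "log10p1") -> ComparisonResult:
    """Compare marker counts between histologies.

    Raw-scale group means with a Welch two-sample t test (mirroring how such
    means are reported), and optionally a covariate-adjusted p-value: the
    Wald test of the histology coefficient in an OLS model of the
    transformed count on histology + age + grade + stage + receptor subtype,
    complete cases only. ``transform`` is 'log10p1' (log10(x + 1), default,
    tames the right skew) or 'raw'. Covariates with a single observed level
    are dropped with a record in ``dropped_covariates``.
    """
    import warnings

    col = f"{marker}_per_ml"
    data = subset.dropna(subset=[col, "histology"]).copy()
    groups = {h: data.loc[data["histology"] == h, col].to_numpy(dtype=float)
              for h in HISTOLOGIES}
    for h, v in groups.items():
        if v.size < 2:
            raise ValueError(f"need at least 2 {h} records with {marker} values")
    welch = st.welch_t(groups["ILC"], groups["IDC"])

    p_adj = None
    n_complete = None
    dropped: list[str] = []
    if adjust:
        import statsmodels.formula.api as smf

        model_df = data[[col, "histology", *_ADJUST_COVARIATES]].dropna().copy()
        y = model_df[col].to_numpy(dtype=float)
        model_df["y"] = np.log10(y + 1.0) if transform == "log10p1" else y
        model_df["ilc"] = (model_df["histology"] == "ILC").astype(float)
        terms = ["ilc"]
        for cov in _ADJUST_COVARIATES:
            if model_df[cov].nunique() < 2:
                dropped.append(cov)
                warnings.warn(f"covariate {cov!r} has a single level; dropped from adjustment")
            elif cov == "age":
                terms.append("age")
            else:
                terms.append(f"C({cov})")
        fit = smf.ols("y ~ " + " + ".join(terms), data=model_df).fit()
        p_adj = float(fit.pvalues["ilc"])
        n_complete = int(len(model_df))

    return ComparisonResult(
        marker=marker,
        group_means={h: float(v.mean()) for h, v in groups.items()},
        group_n={h: int(v.size) for h, v in groups.items()},
        difference=float(groups["ILC"].mean() - groups["IDC"].mean()),
        p_unadjusted=welch.p_value,
        p_adjusted=p_adj,
        transform=transform if adjust else "raw",
        n_complete=n_complete,
        dropped_covariates=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# characteristics table
# ---------------------------------------------------------------------------


def format_percent(p: float) -> str:
    """Table-style percentage: one decimal below 10%, whole numbers above."""
    pct = 100.0 * p
    return f"{pct:.1f}%" if pct < 10 else f"{pct:.0f}%"


_CATEGORICAL_VARS = {
    "treatment": list(TREATMENTS),
    "receptor_subtype": list(SUBTYPES),
    "stage": [1.0, 2.0, 3.0],
    "grade": [1.0, 2.0, 3.0],
}


def characteristics_table(subset: pd.DataFrame, grouping: str = "histology",
                          variables: tuple = ("treatment", "age", "receptor_subtype",
                                              "stage", "grade")) -> pd.DataFrame:
    """Per-variable summaries by group with Welch (continuous) or Fisher
    (categorical) p-values.

    Percentages use non-missing totals as denominators; per-variable unknown
    counts are reported on their own rows. Returns a tidy frame with one row
    per (variable, level) plus an 'Unknown' row per variable.
    """
    data = subset.dropna(subset=[grouping])
    group_levels = [g for g in
                    (HISTOLOGIES if grouping == "histology" else sorted(data[grouping].unique()))
                    if (data[grouping] == g).any()]
    if not group_levels:
        raise ValueError(f"no groups present for {grouping!r}")
    for g in group_levels:
        if len(data[data[grouping] == g]) == 0:
            raise ValueError(f"empty group {g!r}")

    rows = []
    for var in variables:
        if var == grouping:
            continue
        nonmiss = data.dropna(subset=[var])
        unknown = {g: int(data[(data[grouping] == g)][var].isna().sum()) for g in group_levels}
        if var == "age":
            p = math.nan
            if all(len(nonmiss[nonmiss[grouping] == g]) >= 2 for g in group_levels) \
                    and len(group_levels) == 2:
                p = st.welch_t(
                    nonmiss.loc[nonmiss[grouping] == group_levels[0], var],
                    nonmiss.loc[nonmiss[grouping] == group_levels[1], var],
                ).p_value
            row = {"variable": var, "level": "mean_sd", "n_nonmissing": len(nonmiss),
                   "p_value": p, "test": "welch_t"}
            for g in group_levels:
                v = nonmiss.loc[nonmiss[grouping] == g, var]
                row[f"{g}_summary"] = f"{v.mean():.0f} ({v.std(ddof=1):.0f})" if len(v) else ""
                row[f"{g}_n"] = int(len(v))
                row[f"{g}_pct"] = math.nan
            rows.append(row)
        else:
            levels = [lv for lv in _CATEGORICAL_VARS.get(var, sorted(nonmiss[var].unique()))
                      if (nonmiss[var] == lv).any()]
            table = np.array(
                [[int(((nonmiss[grouping] == g) & (nonmiss[var] == lv)).sum())
                  for lv in levels] for g in group_levels], dtype=int)
            p = math.nan
            if table.size and table.shape[1] >= 2 and np.all(table.sum(axis=1) > 0) \
                    and np.all(table.sum(axis=0) > 0):
                p = st.fisher_exact(table).p_value
            for j, lv in enumerate(levels):
                row = {"variable": var, "level": str(lv), "n_nonmissing": len(nonmiss),
                       "p_value": p if j == 0 else math.nan,
                       "test": "fisher_exact" if j == 0 else ""}
                for i, g in enumerate(group_levels):
                    denom = int(table[i].sum())
                    cnt = int(table[i, j])
                    row[f"{g}_n"] = cnt
                    row[f"{g}_pct"] = 100.0 * cnt / denom if denom else math.nan
                    row[f"{g}_summary"] = (
                        f"{cnt} ({format_percent(cnt / denom)})" if denom else str(cnt))
                rows.append(row)
        urow = {"variable": var, "level": "Unknown",
                "n_nonmissing": len(nonmiss), "p_value": math.nan, "test": ""}
        for g in group_levels:
            urow[f"{g}_n"] = unknown[g]
            urow[f"{g}_pct"] = math.nan
            urow[f"{g}_summary"] = str(unknown[g])
        rows.append(urow)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival analyses
# ---------------------------------------------------------------------------


def _covariate_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Indicator-expanded model covariates with documented reference levels:
    age continuous; stage 1, grade 1 and HR+HER2- as references."""
    out = pd.DataFrame(index=data.index)
    out["age"] = data["age"]
    for lv in (2, 3):
        out[f"stage_{lv}"] = (data["stage"] == lv).astype(float)
        out[f"grade_{lv}"] = (data["grade"] == lv).astype(float)
    out.loc[data["stage"].isna(), ["stage_2", "stage_3"]] = np.nan
    out.loc[data["grade"].isna(), ["grade_2", "grade_3"]] = np.nan
    for name, lv in (("subtype_hrneg", "HR-/HER2-"), ("subtype_her2pos", "HER2+")):
        out[name] = (data["receptor_subtype"] == lv).astype(float)
    out.loc[data["receptor_subtype"].isna(), ["subtype_hrneg", "subtype_her2pos"]] = np.nan
    return out


def _cox_summary(result: st.CoxResult, contrast_names) -> dict:
    out = {}
    for c in result.covariates:
        if c.name in contrast_names:
            out[c.name] = {
                "hazard_ratio": c.hazard_ratio,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
                "coefficient": c.coefficient,
            }
    out["n"] = result.n
    out["n_events"] = result.n_events
    return out


def survival_by_group(subset: pd.DataFrame, endpoint: str, labels: pd.Series,
                      reference: str | None = None,
                      multivariate: bool = True) -> dict:
    """Kaplan–Meier curves, log-rank test and Cox models across group labels.

    ``labels`` is a per-record label series ('high'/'low', the four-group
    cross-classification, or any categorical); 'missing'/'incomplete' labels
    are dropped. The reference level defaults to 'low' (or 'low/low') when
    present, else the lexicographically first level. Levels with zero events
    are reported as non-estimable contrasts and excluded from the Cox fits.
    The multivariate model adds age, stage, grade and receptor subtype
    (complete cases).
    """
    if endpoint not in ("drfs", "bcss"):
        raise ValueError("endpoint must be 'drfs' or 'bcss'")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    data = subset.copy()
    data["_group"] = labels.reindex(data.index)
    data = data[~data["_group"].isin(["missing", "incomplete"]) & data["_group"].notna()]
    if len(data) == 0:
        raise ValueError("no records with usable group labels")
    levels = sorted(data["_group"].unique())
    if reference is None:
        reference = "low" if "low" in levels else ("low/low" if "low/low" in levels else levels[0])
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent")

    km = {}
    level_counts = {}
    for lv in levels:
        sub = data[data["_group"] == lv]
        km[lv] = st.km_estimate(sub[tcol], sub[ecol])
        level_counts[lv] = {"n": int(len(sub)), "n_events": int(sub[ecol].sum())}

    if data[ecol].sum() == 0:
        raise ValueError("no events in subset")

    # log-rank across all levels (own test for 2 groups, lifelines for k>2)
    if len(levels) == 2:
        logrank_p = st.logrank_test(data[tcol], data[ecol], data["_group"]).p_value
    else:
        from lifelines.statistics import multivariate_logrank_test

        logrank_p = float(multivariate_logrank_test(
            data[tcol], data["_group"], data[ecol]).p_value)

    non_estimable = [lv for lv in levels
                     if lv != reference and level_counts[lv]["n_events"] == 0]
    estimable = [lv for lv in levels if lv not in non_estimable]
    fit_data = data[data["_group"].isin(estimable)].copy()
    contrast_cols = []
    for lv in estimable:
        if lv == reference:
            continue
        cname = f"group_{lv}".replace("/", "_").replace(" ", "_")
        fit_data[cname] = (fit_data["_group"] == lv).astype(float)
        contrast_cols.append(cname)

    def run_cox(df, cols):
        try:
            res = st.cox_fit(df[[tcol, ecol, *cols]], tcol, ecol, cols)
            return _cox_summary(res, cols)
        except (st.CoxConvergenceError, ValueError) as exc:
            return {"non_estimable": True, "reason": str(exc)[:200]}

    univariate = run_cox(fit_data, contrast_cols) if contrast_cols else {
        "non_estimable": True, "reason": "no estimable non-reference level"}
    multi = None
    if multivariate:
        covs = _covariate_frame(fit_data)
        mdf = pd.concat([fit_data[[tcol, ecol, *contrast_cols]], covs], axis=1).dropna()
        if contrast_cols and len(mdf) and mdf[ecol].sum() > 0:
            multi = run_cox(mdf, contrast_cols + list(covs.columns))
        else:
            multi = {"non_estimable": True, "reason": "no complete cases with events"}

    return {
        "endpoint": endpoint,
        "levels": level_counts,
        "reference": reference,
        "km": {lv: {"times": km[lv].times.tolist(),
                    "survival": km[lv].survival.tolist(),
                    "at_risk": km[lv].at_risk.tolist(),
                    "n_events": km[lv].n_events.tolist(),
                    "median": km[lv].median}
               for lv in levels},
        "logrank_p": float(logrank_p),
        "non_estimable_levels": non_estimable,
        "cox_univariate": univariate,
        "cox_multivariate": multi,
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    mccv: MccvConfig = field(default_factory=MccvConfig)
    transform: str = "log10p1"
    seed: int = 0
    min_subset_for_mccv: int = 20

    def to_dict(self) -> dict:
        return {
            "mccv": {
                "n_iterations": self.mccv.n_iterations,
                "train_fraction": self.mccv.train_fraction,
                "percentile_band": list(self.mccv.percentile_band),
                "endpoint_policy": self.mccv.endpoint_policy,
                "min_group_size": self.mccv.min_group_size,
                "seed": self.mccv.seed,
            },
            "transform": self.transform,
            "seed": self.seed,
            "min_subset_for_mccv": self.min_subset_for_mccv,
        }


def _safe(section_name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except ValueError as exc:
        return {"skipped": True, "reason": f"{section_name}: {exc}"}


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Run the whole analysis on a conforming cohort table; returns a
    JSON-serialisable report. Sections that cannot be computed on the given
    cohort (e.g. no neoadjuvant records) are marked skipped rather than
    failing the run."""
    config = config or AnalysisConfig()
    cohort = validate_cohort(cohort)
    report: dict = {"config": config.to_dict()}

    retained, excl = apply_exclusions(cohort)
    report["exclusions"] = excl.to_dict()
    strata = stratify(retained)
    report["stratification"] = {
        "sizes": strata.sizes,
        "n_by_method": {m: int(len(strata.by_method(m))) for m in METHODS},
        "n_by_histology": {h: int((retained["histology"] == h).sum()) for h in HISTOLOGIES},
    }

    # overall and per-method comparisons
    report["overall"] = {}
    overall_cmp = _safe("overall ctc", compare_counts, retained, "ctc", False)
    report["overall"]["ctc_by_histology"] = (
        overall_cmp.to_dict() if isinstance(overall_cmp, ComparisonResult) else overall_cmp)
    cellsearch = strata.by_method("CellSearch")
    if len(cellsearch):
        report["overall"]["cellsearch_positivity"] = _safe(
            "cellsearch positivity", positivity_rate, cellsearch, "ctc")
    else:
        report["overall"]["cellsearch_positivity"] = {"skipped": True,
                                                      "reason": "no CellSearch records"}

    # IE/FC cohorts A (primary surgery) and B (neoadjuvant)
    cohorts = {"cohort_A": strata.subset("IEFC", "primary_surgery"),
               "cohort_B": strata.subset("IEFC", "neoadjuvant")}
    for name, sub in cohorts.items():
        section: dict = {"n": int(len(sub))}
        if len(sub) == 0:
            section["skipped"] = True
            section["reason"] = "no records in this cohort"
            report[name] = section
            continue
        for marker in ("ctc", "dtc"):
            cmp_res = _safe(f"{name} {marker} comparison", compare_counts, sub, marker,
                            True, config.transform)
            section[f"{marker}_comparison"] = (
                cmp_res.to_dict() if isinstance(cmp_res, ComparisonResult) else cmp_res)
        tab = _safe(f"{name} characteristics", characteristics_table, sub)
        section["characteristics"] = (
            tab.to_dict(orient="records") if isinstance(tab, pd.DataFrame) else tab)
        for ep in ("drfs", "bcss"):
            t = sub[f"{ep}_time"].to_numpy(dtype=float)
            e = sub[f"{ep}_event"].to_numpy(dtype=int)
            section[f"{ep}_median_followup"] = st.km_median_followup(t, e)
            section[f"{ep}_n_events"] = int(e.sum())
        report[name] = section

    # cutpoint optimisation + survival, primary-surgery cohort only
    cohort_a = cohorts["cohort_A"]
    surv_section: dict = {}
    for h in HISTOLOGIES:
        hsub = cohort_a[cohort_a["histology"] == h]
        hres: dict = {"n": int(len(hsub))}
        thresholds = {}
        for marker in ("ctc", "dtc"):
            usable = hsub[f"{marker}_per_ml"].notna().sum()
            if usable < config.min_subset_for_mccv:
                hres[f"{marker}_cutpoint"] = {
                    "skipped": True,
                    "reason": f"only {usable} usable records (< {config.min_subset_for_mccv})"}
                continue
            try:
                res = mccv_optimize(hsub, marker, config.mccv)
            except ValueError as exc:
                hres[f"{marker}_cutpoint"] = {"skipped": True, "reason": str(exc)[:200]}
                continue
            thresholds[marker] = res.chosen_threshold
            hres[f"{marker}_cutpoint"] = {
                "chosen_threshold": res.chosen_threshold,
                "combined_p": res.combined_p,
                "n_usable_iterations": res.n_usable_iterations,
                "n_candidates": len(res.candidate_grid),
            }
            lab = classify_high_low(hsub, marker, res.chosen_threshold)
            hres[f"{marker}_high_rate"] = {
                "n_high": int((lab == "high").sum()),
                "n_total": int(len(hsub)),
                "pct_high": 100.0 * float((lab == "high").sum()) / len(hsub),
            }
            for ep in ("drfs", "bcss"):
                hres[f"{marker}_{ep}_survival"] = _safe(
                    f"{h} {marker} {ep}", survival_by_group, hsub, ep, lab)
        if "ctc" in thresholds and "dtc" in thresholds:
            four = four_group_label(
                classify_high_low(hsub, "ctc", thresholds["ctc"]),
                classify_high_low(hsub, "dtc", thresholds["dtc"]),
            )
            counts = four.value_counts().to_dict()
            complete = int(sum(v for k, v in counts.items() if k != "incomplete"))
            hres["four_group_counts"] = {str(k): int(v) for k, v in counts.items()}
            hres["four_group_pct"] = {
                str(k): 100.0 * v / complete
                for k, v in counts.items() if k != "incomplete"} if complete else {}
            for ep in ("drfs", "bcss"):
                hres[f"four_group_{ep}_survival"] = _safe(
                    f"{h} four-group {ep}", survival_by_group, hsub, ep, four)
        surv_section[h] = hres
    report["cohort_A_survival"] = surv_section
    return report
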