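"""Monte-Carlo cross-validated prognostic cutpoint optimisation.

The procedure dichotomises a biomarker (cells/mL) at candidate thresholds
drawn from the observed values whose percentile rank falls inside a band
(20th–80th by default), and repeats many random half-splits: on each
training half the candidate with the smallest log-rank p-value (reduced
across the configured endpoints) is selected, and that threshold's log-rank
p-value is then recorded on the held-out half. After all iterations the
test-set p-values are grouped by selected threshold, each group is combined
with the logit method, and the threshold with the smallest combined p-value
wins.

The candidate grid is computed once on the *full* subset rather than per
training half, so that thresholds selected in different iterations are
identical values that can be grouped and combined; thresholds are observed
marker values and "high" always means strictly greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import logit_combine, logrank_grid

__all__ = [
    "MccvConfig",
    "CutpointResult",
    "candidate_thresholds",
    "mccv_optimize",
    "classify_high_low",
    "four_group_label",
]

ENDPOINT_POLICIES = ("combine_logit", "drfs_only", "bcss_only")


@dataclass(frozen=True)
class MccvConfig:
    n_iterations: int = 1000
    train_fraction: float = 0.5
    percentile_band: tuple[float, float] = (20.0, 80.0)
    endpoint_policy: str = "combine_logit"
    min_group_size: int = 5
    seed: int = 0

    def validate(self) -> "MccvConfig":
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        low, high = self.percentile_band
        if not 0 <= low < high <= 100:
            raise ValueError("percentile_band must satisfy 0 <= low < high <= 100")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.endpoint_policy not in ENDPOINT_POLICIES:
            raise ValueError(f"endpoint_policy must be one of {ENDPOINT_POLICIES}")
        if self.min_group_size < 0:
            raise ValueError("min_group_size must be >= 0")
        return self


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    threshold: float | None
    train_p: float | None
    test_p: float | None
    usable: bool


@dataclass(frozen=True)
class CutpointResult:
    chosen_threshold: float
    combined_p: float
    per_threshold: dict  # threshold -> {"times_selected": int, "combined_p": float}
    per_iteration: tuple[IterationRecord, ...]
    n_usable_iterations: int
    candidate_grid: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "chosen_threshold": self.chosen_threshold,
            "combined_p": self.combined_p,
            "n_usable_iterations": self.n_usable_iterations,
            "candidate_grid": list(self.candidate_grid),
            "per_threshold": {
                str(t): dict(v) for t, v in sorted(self.per_threshold.items())
            },
            "per_iteration": [
                {
                    "iteration": r.iteration,
                    "threshold": r.threshold,
                    "train_p": r.train_p,
                    "test_p": r.test_p,
                    "usable": r.usable,
                }
                for r in self.per_iteration
            ],
        }


def candidate_thresholds(values, band=(20.0, 80.0)) -> np.ndarray:
    """Distinct observed values whose percentile rank lies within ``band``.

    The rank of a value v is 100 * #(values <= v) / n (so a value at the
    80th-percentile rank leaves exactly 20% of the subset strictly above
    it). Requires at least 5 distinct values overall and at least 2 inside
    the band; returned sorted ascending.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if np.unique(v).size < 5:
        raise ValueError("need at least 5 distinct marker values")
    low, high = band
    distinct = np.unique(v)
    rank = 100.0 * np.searchsorted(np.sort(v), distinct, side="right") / v.size
    grid = distinct[(rank >= low) & (rank <= high)]
    if grid.size < 2:
        raise ValueError("fewer than 2 candidate thresholds inside the percentile band")
    return grid


def classify_high_low(records: pd.DataFrame | pd.Series, marker: str,
                      threshold: float) -> pd.Series:
    """Label each record 'high' (value strictly > threshold), 'low', or
    'missing'. ``marker`` is 'ctc' or 'dtc' when passing a cohort frame, or
    ignored when a Series of values is given."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if isinstance(records, pd.DataFrame):
        vals = records[f"{marker}_per_ml"]
    else:
        vals = records
    out = pd.Series(
        np.where(vals.isna(), "missing", np.where(vals > threshold, "high", "low")),
        index=vals.index,
        name=f"{marker}_group" if isinstance(records, pd.DataFrame) else "group",
    )
    return out


def four_group_label(ctc_label: pd.Series, dtc_label: pd.Series) -> pd.Series:
    """Cross-classify CTC and DTC high/low labels; any missing component
    yields 'incomplete'."""
    out = ctc_label.str.cat(dtc_label, sep="/")
    out = out.where((ctc_label != "missing") & (dtc_label != "missing"), "incomplete")
    return out.rename("ctc_dtc_group")


def _endpoint_p(reduced: dict[str, np.ndarray], policy: str) -> np.ndarray:
    """Reduce per-endpoint p-value arrays (aligned on thresholds) to one."""
    if policy == "drfs_only":
        return reduced["drfs"]
    if policy == "bcss_only":
        return reduced["bcss"]
    ps = np.stack([reduced["drfs"], reduced["bcss"]])
    return np.array([logit_combine(ps[:, j]) for j in range(ps.shape[1])])


def mccv_optimize(records: pd.DataFrame, marker: str, config: MccvConfig,
                  splits=None) -> CutpointResult:
    """Run the Monte-Carlo cross-validated threshold search on one cohort
    subset (typically one histology within one treatment cohort).

    ``records`` must carry the marker column and both endpoint columns; rows
    with a missing marker value are dropped. ``splits`` optionally supplies
    an explicit iterable of training-index arrays (positions into the
    marker-complete subset) in place of seeded random half-splits — used for
    audit and exhaustive small-n verification.

    Iterations whose selected threshold leaves a group smaller than
    ``min_group_size`` in either half are recorded as unusable and excluded
    from the combination step.
    """
    config.validate()
    if marker not in ("ctc", "dtc"):
        raise ValueError("marker must be 'ctc' or 'dtc'")
    col = f"{marker}_per_ml"
    data = records.dropna(subset=[col]).reset_index(drop=True)
    if len(data) == 0:
        raise ValueError(f"marker {marker} entirely missing in subset")
    if splits is None and len(data) < 20:
        raise ValueError("subset too small for Monte-Carlo cross-validation (< 20 usable records)")

    values = data[col].to_numpy(dtype=float)
    grid = candidate_thresholds(values, config.percentile_band)
    endpoints = (("drfs", "bcss") if config.endpoint_policy == "combine_logit"
                 else (config.endpoint_policy.split("_")[0],))
    times = {ep: data[f"{ep}_time"].to_numpy(dtype=float) for ep in endpoints}
    events = {ep: data[f"{ep}_event"].to_numpy(dtype=int) for ep in endpoints}

    n = len(data)
    n_train = int(round(n * config.train_fraction))
    rng = np.random.default_rng(config.seed)
    if splits is None:
        splits = (rng.permutation(n)[:n_train] for _ in range(config.n_iterations))

    per_iteration = []
    test_ps: dict[float, list[float]] = {}
    policy = config.endpoint_policy
    all_idx = np.arange(n)

    for it, train_idx in enumerate(splits):
        train_idx = np.asarray(train_idx)
        test_mask = np.ones(n, dtype=bool)
        test_mask[train_idx] = False
        test_idx = all_idx[test_mask]

        train_p = _endpoint_p(
            {ep: logrank_grid(times[ep][train_idx], events[ep][train_idx],
                              values[train_idx], grid) for ep in endpoints},
            policy,
        )
        j = int(np.argmin(train_p))  # argmin takes the first (smallest) threshold on ties
        tau = float(grid[j])

        high_train = values[train_idx] > tau
        high_test = values[test_idx] > tau
        sizes = [high_train.sum(), (~high_train).sum(), high_test.sum(), (~high_test).sum()]
        usable = min(sizes) >= config.min_group_size
        if usable:
            test_p = float(
                _endpoint_p(
                    {ep: logrank_grid(times[ep][test_idx], events[ep][test_idx],
                                      values[test_idx], np.array([tau])) for ep in endpoints},
                    policy,
                )[0]
            )
            test_ps.setdefault(tau, []).append(test_p)
        else:
            test_p = None
        per_iteration.append(IterationRecord(it, tau, float(train_p[j]), test_p, usable))

    n_usable = sum(1 for r in per_iteration if r.usable)
    if n_usable == 0:
        raise ValueError("all Monte-Carlo iterations were unusable (groups too small)")

    per_threshold = {
        tau: {"times_selected": len(ps), "combined_p": logit_combine(ps)}
        for tau, ps in test_ps.items()
    }
    # smallest combined p wins; ties break toward the smaller threshold
    chosen = min(per_threshold, key=lambda t: (per_threshold[t]["combined_p"], t))
    return CutpointResult(
        chosen_threshold=float(chosen),
        combined_p=float(per_threshold[chosen]["combined_p"]),
        per_threshold=per_threshold,
        per_iteration=tuple(per_iteration),
        n_usable_iterations=n_usable,
        candidate_grid=tuple(float(g) for g in grid),
    )
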