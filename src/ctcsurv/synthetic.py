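"""Seeded synthetic cohorts with the statistical structure of an early
breast cancer CTC/DTC enumeration study.

The generator emulates a two-histology (ILC/IDC) cohort with zero-inflated,
right-skewed tumor-cell counts whose means differ by histology and treatment
strategy, marginal clinicopathologic covariate distributions given
histology, long follow-up with low event rates on two censored endpoints
(distant recurrence-free survival and breast cancer-specific survival), and
an optional *planted* prognostic effect: a multiplicative hazard step for
patients whose marker value exceeds a configurable threshold. Planting a
known cutpoint is what makes the downstream threshold-optimisation machinery
testable end to end.

Marker counts are drawn as exact zeros with a per-stratum zero-inflation
probability and log-normally otherwise, then rounded to 2 decimals (the
per-mL resolution at which such assays are reported). Event times are
exponential; censoring is uniform over a per-endpoint follow-up window.
Covariates are generated independently given histology.

One master seed drives everything; independent substreams are derived per
column group so that adding a new column group cannot perturb earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import (
    COHORT_COLUMNS,
    ENDPOINTS,
    GRADES,
    HISTOLOGIES,
    METHODS,
    STAGES,
    SUBTYPES,
    TREATMENTS,
    validate_cohort,
)

__all__ = [
    "MarkerModel",
    "PlantedCutpoint",
    "EndpointModel",
    "SurvivalModel",
    "CohortSpec",
    "SpecValidationError",
    "generate_cohort",
    "default_study_spec",
]

MARKERS = ("ctc", "dtc")

# substream order is append-only: new column groups must be added at the end
_STREAMS = (
    "histology", "treatment", "method", "age", "subtype", "stage", "grade",
    "ctc", "dtc", "drfs", "bcss", "missing",
)


class SpecValidationError(ValueError):
    """A cohort specification field violates its invariant."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{fieldname}: {msg}")


def _check_probs(probs, fieldname, k=None):
    p = np.asarray(probs, dtype=float)
    _check(np.all(p >= 0), fieldname, "probabilities must be non-negative")
    _check(abs(p.sum() - 1.0) <= 1e-9, fieldname, "probabilities must sum to 1")
    if k is not None:
        _check(p.size == k, fieldname, f"expected {k} probabilities")


@dataclass(frozen=True)
class MarkerModel:
    """Zero-inflated log-normal model for one (marker, histology, treatment)
    stratum: an atom at zero with probability ``zero_prob``, else
    LogNormal(log_mean, log_sd)."""

    zero_prob: float
    log_mean: float
    log_sd: float

    @property
    def mean(self) -> float:
        """Overall (zeros included) expected count per mL."""
        return (1.0 - self.zero_prob) * math.exp(self.log_mean + self.log_sd**2 / 2)

    @staticmethod
    def from_mean(mean: float, zero_prob: float, log_sd: float) -> "MarkerModel":
        """Solve the log-scale location so the overall mean hits ``mean``."""
        if not 0 <= zero_prob < 1:
            raise SpecValidationError("zero_prob: must be in [0, 1) to target a positive mean")
        if mean <= 0:
            raise SpecValidationError("mean: must be positive")
        mu = math.log(mean / (1.0 - zero_prob)) - log_sd**2 / 2
        return MarkerModel(zero_prob=zero_prob, log_mean=mu, log_sd=log_sd)

    def validate(self, fieldname: str) -> None:
        _check(0 <= self.zero_prob <= 1, fieldname, "zero_prob must be in [0, 1]")
        _check(self.log_sd > 0, fieldname, "log_sd must be positive")
        _check(math.isfinite(self.log_mean), fieldname, "log_mean must be finite")


@dataclass(frozen=True)
class PlantedCutpoint:
    """Hazard step: patients with ``marker`` strictly above ``threshold``
    have their event hazard multiplied by ``hazard_ratio`` on the listed
    endpoints."""

    marker: str
    threshold: float
    hazard_ratio: float
    endpoints: tuple[str, ...] = ENDPOINTS

    def validate(self) -> None:
        _check(self.marker in MARKERS, "planted_cutpoint.marker", f"must be one of {MARKERS}")
        _check(self.hazard_ratio > 0, "planted_cutpoint.hazard_ratio", "must be > 0")
        _check(math.isfinite(self.threshold), "planted_cutpoint.threshold", "must be finite")
        _check(all(e in ENDPOINTS for e in self.endpoints),
               "planted_cutpoint.endpoints", f"must be subset of {ENDPOINTS}")


@dataclass(frozen=True)
class EndpointModel:
    """Exponential event times at ``baseline_rate`` per year; censoring
    uniform on [censor_low, censor_high] years."""

    baseline_rate: float
    censor_low: float
    censor_high: float

    def validate(self, fieldname: str) -> None:
        _check(self.baseline_rate > 0, f"{fieldname}.baseline_rate", "must be > 0")
        _check(0 < self.censor_low < self.censor_high,
               f"{fieldname}.censor_window", "need 0 < censor_low < censor_high")


@dataclass(frozen=True)
class SurvivalModel:
    drfs: EndpointModel
    bcss: EndpointModel
    planted_cutpoint: PlantedCutpoint | None = None

    def validate(self) -> None:
        self.drfs.validate("survival_model.drfs")
        self.bcss.validate("survival_model.bcss")
        if self.planted_cutpoint is not None:
            self.planted_cutpoint.validate()


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Per-histology dictionaries are keyed ``'ILC'``/``'IDC'``;
    ``marker_models`` is keyed ``(marker, histology, treatment)`` with marker
    in ``('ctc', 'dtc')`` and treatment in ``('primary_surgery',
    'neoadjuvant')``. ``missing_rates`` maps column names to the fraction of
    values masked missing-at-random after generation.
    """

    n_patients: int
    prop_ilc: float
    prop_neoadjuvant: float
    prop_cellsearch: float
    subtype_probs: dict
    stage_probs: dict
    grade_probs: dict
    age_mean_by_histology: dict
    age_sd: float
    marker_models: dict
    survival_model: SurvivalModel
    missing_rates: dict = field(default_factory=dict)
    marker_decimals: int = 2
    seed: int = 0

    def validate(self) -> "CohortSpec":
        _check(self.n_patients >= 2, "n_patients", "must be >= 2")
        for name in ("prop_ilc", "prop_neoadjuvant", "prop_cellsearch"):
            v = getattr(self, name)
            _check(0 <= v <= 1, name, "must be a fraction in [0, 1]")
        for name, d, k in (("subtype_probs", self.subtype_probs, len(SUBTYPES)),
                           ("stage_probs", self.stage_probs, len(STAGES)),
                           ("grade_probs", self.grade_probs, len(GRADES))):
            for h in HISTOLOGIES:
                _check(h in d, name, f"missing histology key {h!r}")
                _check_probs(d[h], f"{name}[{h}]", k)
        for h in HISTOLOGIES:
            _check(h in self.age_mean_by_histology, "age_mean_by_histology",
                   f"missing histology key {h!r}")
            _check(self.age_mean_by_histology[h] > 0, "age_mean_by_histology",
                   "means must be positive")
        _check(self.age_sd > 0, "age_sd", "must be positive")
        _check(0 <= self.marker_decimals <= 6, "marker_decimals", "must be in [0, 6]")
        for m in MARKERS:
            for h in HISTOLOGIES:
                for tr in TREATMENTS:
                    key = (m, h, tr)
                    _check(key in self.marker_models, "marker_models",
                           f"missing stratum {key}")
                    self.marker_models[key].validate(f"marker_models[{key}]")
        self.survival_model.validate()
        for col, rate in self.missing_rates.items():
            _check(col in COHORT_COLUMNS, "missing_rates", f"unknown column {col!r}")
            _check(0 <= rate <= 1, f"missing_rates[{col}]", "must be in [0, 1]")
        return self

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from ``spec``.

    ``seed`` overrides ``spec.seed`` when given. The same (spec, seed) pair
    always yields an identical table.
    """
    spec.validate()
    rngs = _streams(spec.seed if seed is None else seed)
    n = spec.n_patients

    histology = np.where(rngs["histology"].random(n) < spec.prop_ilc, "ILC", "IDC")
    treatment = np.where(rngs["treatment"].random(n) < spec.prop_neoadjuvant,
                         "neoadjuvant", "primary_surgery")
    method = np.where(rngs["method"].random(n) < spec.prop_cellsearch,
                      "CellSearch", "IEFC")

    age_mean = np.vectorize(spec.age_mean_by_histology.__getitem__)(histology)
    age = np.clip(rngs["age"].normal(age_mean, spec.age_sd), 18.0, 100.0).round(1)

    def categorical(rng, probs_by_hist, levels):
        out = np.empty(n, dtype=object)
        u = rng.random(n)
        for h in HISTOLOGIES:
            cum = np.cumsum(np.asarray(probs_by_hist[h], dtype=float))
            mask = histology == h
            out[mask] = np.asarray(levels, dtype=object)[
                np.searchsorted(cum, u[mask], side="right").clip(0, len(levels) - 1)
            ]
        return out

    subtype = categorical(rngs["subtype"], spec.subtype_probs, list(SUBTYPES))
    stage = categorical(rngs["stage"], spec.stage_probs, list(STAGES)).astype(float)
    grade = categorical(rngs["grade"], spec.grade_probs, list(GRADES)).astype(float)

    markers = {}
    for m in MARKERS:
        rng = rngs[m]
        zero_u = rng.random(n)
        lognorm = rng.normal(size=n)  # one normal per patient, scaled per stratum
        vals = np.zeros(n)
        for h in HISTOLOGIES:
            for tr in TREATMENTS:
                model = spec.marker_models[(m, h, tr)]
                mask = (histology == h) & (treatment == tr)
                pos = zero_u[mask] >= model.zero_prob
                v = np.zeros(mask.sum())
                v[pos] = np.exp(model.log_mean + model.log_sd * lognorm[mask][pos])
                vals[mask] = v
        markers[m] = np.round(vals, spec.marker_decimals)

    planted = spec.survival_model.planted_cutpoint
    columns = {
        "patient_id": np.array([f"P{i:05d}" for i in range(1, n + 1)], dtype=object),
        "histology": histology,
        "age": age,
        "receptor_subtype": subtype,
        "stage": stage,
        "grade": grade,
        "treatment": treatment,
        "method": method,
        "ctc_per_ml": markers["ctc"],
        "dtc_per_ml": markers["dtc"],
    }
    for ep in ENDPOINTS:
        model = getattr(spec.survival_model, ep)
        rate = np.full(n, model.baseline_rate)
        if planted is not None and ep in planted.endpoints:
            above = markers[planted.marker] > planted.threshold
            rate = rate * np.where(above, planted.hazard_ratio, 1.0)
        rng = rngs[ep]
        event_time = rng.exponential(1.0 / rate)
        censor_time = rng.uniform(model.censor_low, model.censor_high, n)
        # floor at the 1e-4-year recording resolution: times are strictly positive
        columns[f"{ep}_time"] = np.maximum(
            np.round(np.minimum(event_time, censor_time), 4), 1e-4)
        columns[f"{ep}_event"] = (event_time <= censor_time).astype(int)

    df = pd.DataFrame(columns)[COHORT_COLUMNS]

    # missing-at-random masking, one substream shared across columns in a
    # fixed order so rates are independent per column
    rng = rngs["missing"]
    for col in COHORT_COLUMNS:
        rate = spec.missing_rates.get(col, 0.0)
        if rate > 0:
            df.loc[rng.random(n) < rate, col] = np.nan
    return validate_cohort(df)


def default_study_spec(seed: int = 0) -> CohortSpec:
    """Spec emulating the IE/FC-enumerated subset of an early breast cancer
    CTC/DTC cohort: 382 patients, ~22% ILC, a 284/98 primary-surgery /
    neoadjuvant split, per-histology covariate mixes, and stratum marker
    means of 2.11/0.71 (CTC, primary surgery ILC/IDC), 0.89/1.06 (CTC,
    neoadjuvant), 21/16 and 11.1/19.6 (DTC) cells per mL.

    No prognostic cutpoint is planted by default; the cohort is null with
    respect to marker–outcome association.
    """
    ctc_sd, dtc_sd = 1.2, 1.5
    ctc_zero, dtc_zero = 0.35, 0.30
    marker_means = {
        ("ctc", "ILC", "primary_surgery"): 2.11,
        ("ctc", "IDC", "primary_surgery"): 0.71,
        ("ctc", "ILC", "neoadjuvant"): 0.89,
        ("ctc", "IDC", "neoadjuvant"): 1.06,
        ("dtc", "ILC", "primary_surgery"): 21.0,
        ("dtc", "IDC", "primary_surgery"): 16.0,
        ("dtc", "ILC", "neoadjuvant"): 11.1,
        ("dtc", "IDC", "neoadjuvant"): 19.6,
    }
    marker_models = {
        key: MarkerModel.from_mean(
            mean,
            zero_prob=ctc_zero if key[0] == "ctc" else dtc_zero,
            log_sd=ctc_sd if key[0] == "ctc" else dtc_sd,
        )
        for key, mean in marker_means.items()
    }
    return CohortSpec(
        n_patients=382,
        prop_ilc=83 / 382,
        prop_neoadjuvant=98 / 382,
        prop_cellsearch=0.0,
        subtype_probs={
            "IDC": (189 / 286, 34 / 286, 63 / 286),
            "ILC": (72 / 82, 3 / 82, 7 / 82),
        },
        stage_probs={
            "IDC": (196 / 289, 56 / 289, 37 / 289),
            "ILC": (47 / 78, 17 / 78, 14 / 78),
        },
        grade_probs={
            "IDC": (83 / 246, 94 / 246, 69 / 246),
            "ILC": (30 / 75, 39 / 75, 6 / 75),
        },
        age_mean_by_histology={"ILC": 54.0, "IDC": 50.0},
        age_sd=11.0,
        marker_models=marker_models,
        survival_model=SurvivalModel(
            drfs=EndpointModel(baseline_rate=0.02, censor_low=2.0, censor_high=18.0),
            bcss=EndpointModel(baseline_rate=0.012, censor_low=6.0, censor_high=20.0),
        ),
        missing_rates={
            "receptor_subtype": 14 / 382,
            "stage": 15 / 382,
            "grade": 61 / 382,
            "dtc_per_ml": 0.05,
        },
        seed=seed,
    )
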