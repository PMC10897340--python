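"""YAML configuration handling for the command-line interface.

A config file is a mapping with up to three sections — ``cohort`` (fields of
:class:`~ctcsurv.synthetic.CohortSpec`), ``mccv`` (fields of
:class:`~ctcsurv.cutpoint.MccvConfig`) and ``analysis`` (transform choice) —
each optional; anything omitted falls back to the package defaults, i.e. the
382-patient study emulation. Marker models are given per marker, histology
and treatment as ``{mean, zero_prob, log_sd}`` (the log-scale location is
solved from the mean) or ``{log_mean, zero_prob, log_sd}``.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .cutpoint import MccvConfig
from .pipeline import AnalysisConfig
from .synthetic import (
    CohortSpec,
    EndpointModel,
    MarkerModel,
    PlantedCutpoint,
    SurvivalModel,
    default_study_spec,
)


def load_config(path: str | None) -> dict:
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def _marker_model_from(d: dict) -> MarkerModel:
    if "mean" in d:
        return MarkerModel.from_mean(float(d["mean"]), float(d["zero_prob"]),
                                     float(d["log_sd"]))
    return MarkerModel(zero_prob=float(d["zero_prob"]),
                       log_mean=float(d["log_mean"]), log_sd=float(d["log_sd"]))


def spec_from_config(cfg: dict, seed: int | None = None) -> CohortSpec:
    """Build a CohortSpec from the ``cohort`` section, starting from the
    default study emulation and overriding the provided fields."""
    spec = default_study_spec()
    section = dict(cfg.get("cohort", {}))

    if "marker_models" in section:
        models = dict(spec.marker_models)
        for marker, by_hist in section.pop("marker_models").items():
            for hist, by_treat in by_hist.items():
                for treat, params in by_treat.items():
                    models[(marker, hist, treat)] = _marker_model_from(params)
        spec = replace(spec, marker_models=models)

    if "survival_model" in section:
        sm = section.pop("survival_model")
        endpoints = {}
        for ep in ("drfs", "bcss"):
            if ep in sm:
                endpoints[ep] = EndpointModel(**{k: float(v) for k, v in sm[ep].items()})
            else:
                endpoints[ep] = getattr(spec.survival_model, ep)
        planted = spec.survival_model.planted_cutpoint
        if "planted_cutpoint" in sm:
            pc = sm["planted_cutpoint"]
            planted = None if pc is None else PlantedCutpoint(
                marker=pc["marker"],
                threshold=float(pc["threshold"]),
                hazard_ratio=float(pc["hazard_ratio"]),
                endpoints=tuple(pc.get("endpoints", ("drfs", "bcss"))),
            )
        spec = replace(spec, survival_model=SurvivalModel(
            drfs=endpoints["drfs"], bcss=endpoints["bcss"], planted_cutpoint=planted))

    for key, value in section.items():
        if key in ("subtype_probs", "stage_probs", "grade_probs"):
            value = {h: tuple(float(p) for p in ps) for h, ps in value.items()}
        elif key == "age_mean_by_histology":
            value = {h: float(v) for h, v in value.items()}
        elif key == "missing_rates":
            value = {c: float(v) for c, v in value.items()}
        spec = replace(spec, **{key: value})

    if seed is not None:
        spec = replace(spec, seed=int(seed))
    return spec.validate()


def mccv_from_config(cfg: dict, seed: int | None = None) -> MccvConfig:
    section = dict(cfg.get("mccv", {}))
    if "percentile_band" in section:
        section["percentile_band"] = tuple(float(v) for v in section["percentile_band"])
    if seed is not None:
        section["seed"] = int(seed)
    return MccvConfig(**section).validate()


def analysis_from_config(cfg: dict, seed: int | None = None) -> AnalysisConfig:
    section = dict(cfg.get("analysis", {}))
    mccv = mccv_from_config(cfg, seed)
    return AnalysisConfig(
        mccv=mccv,
        transform=section.get("transform", "log10p1"),
        seed=int(seed) if seed is not None else int(section.get("seed", 0)),
        min_subset_for_mccv=int(section.get("min_subset_for_mccv", 20)),
    )
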