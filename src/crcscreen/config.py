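"""YAML parameter files: load/dump with schema validation.

Errors are raised as :class:`~crcscreen.errors.ConfigurationError` with
the offending key path (e.g. ``policy.test.sensitivity.small_adenoma``).
"""

from __future__ import annotations

import numpy as np
import yaml

from .errors import ConfigurationError
from .natural_history import (LifeTable, N_STATES, NaturalHistoryParams,
                              STATE_NAMES)
from .population import PopulationSpec
from .screening import (ColonoscopyCharacteristics, ParticipationModel,
                        ScreeningPolicy, SurveillanceThresholds,
                        TestCharacteristics)


def _get(d: dict, path: str, *keys, default=None, required=True):
    cur = d
    trail = path
    for k in keys:
        if not isinstance(cur, dict) or k not in cur:
            if required:
                raise ConfigurationError(f"missing key: {trail}.{k}")
            return default
        trail = f"{trail}.{k}"
        cur = cur[k]
    return cur


def _load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return doc


def _state_dict(vec) -> dict:
    return {STATE_NAMES[s]: float(vec[s]) for s in range(N_STATES)}


# ---------------------------------------------------------------------------
# Natural history + lifetables


def params_to_dict(params: NaturalHistoryParams) -> dict:
    return {
        "onset_age_edges": [float(x) for x in params.onset_age_edges],
        "onset_rates": [float(x) for x in params.onset_rates],
        "frailty_variance": float(params.frailty_variance),
        "p_progressive": float(params.p_progressive),
        "rate_small_to_large": float(params.rate_small_to_large),
        "rate_large_to_preclinical": float(params.rate_large_to_preclinical),
        "stage_progression_rates": [float(x) for x in
                                    params.stage_progression_rates],
        "sojourn_rates": [float(x) for x in params.sojourn_rates],
        "cure_fraction": [float(x) for x in params.cure_fraction],
        "excess_mortality": [float(x) for x in params.excess_mortality],
    }


def params_from_dict(sex: str, d: dict, path="natural_history") -> NaturalHistoryParams:
    try:
        return NaturalHistoryParams(sex=sex, **d)
    except TypeError as e:
        raise ConfigurationError(f"{path}.{sex}: {e}") from e


def lifetable_to_dict(lt: LifeTable) -> dict:
    return {"ages": [float(a) for a in lt.ages],
            "survival": [float(s) for s in lt.survival]}


def lifetable_from_dict(sex: str, d: dict, path="lifetable") -> LifeTable:
    if "survival" in d:
        return LifeTable(sex=sex, ages=d["ages"], survival=d["survival"])
    if "hazard" in d:
        return LifeTable.from_hazard(sex, d["ages"], d["hazard"])
    raise ConfigurationError(f"{path}.{sex}: needs a survival or hazard column")


def load_params(path):
    """Read a params.yaml -> (params by sex, lifetables by sex)."""
    doc = _load_yaml(path)
    nh = _get(doc, "", "natural_history")
    lt = _get(doc, "", "lifetable")
    params = {sex: params_from_dict(sex, d) for sex, d in nh.items()}
    tables = {sex: lifetable_from_dict(sex, d) for sex, d in lt.items()}
    return params, tables


def dump_params(params: dict, lifetables: dict, path) -> None:
    doc = {
        "comment": ("Illustrative natural-history parameters; not "
                    "calibrated to the Basque cancer registry."),
        "natural_history": {s: params_to_dict(p) for s, p in params.items()},
        "lifetable": {s: lifetable_to_dict(t) for s, t in lifetables.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Policy


def policy_to_dict(policy: ScreeningPolicy) -> dict:
    return {
        "programme_start_year": float(policy.programme_start_year),
        "start_age": float(policy.start_age),
        "stop_age": float(policy.stop_age),
        "interval": float(policy.interval),
        "test": {"sensitivity": _state_dict(policy.test.sensitivity),
                 "specificity": float(policy.test.specificity),
                 "cutoff_label": policy.test.cutoff_label},
        "participation": {
            sex: {"first_round": m.first_round
                  if np.isscalar(m.first_round) else list(m.first_round),
                  "retention": m.retention, "conversion": m.conversion}
            for sex, m in policy.participation.items()},
        "colonoscopy_adherence": float(policy.colonoscopy_adherence),
        "colonoscopy": {
            "sensitivity": _state_dict(policy.colonoscopy.sensitivity),
            "completeness": float(policy.colonoscopy.completeness)},
        "surveillance": {
            "intermediate_total": policy.thresholds.intermediate_total,
            "high_large": policy.thresholds.high_large,
            "high_total": policy.thresholds.high_total},
        "surveillance_stop_age": float(policy.surveillance_stop_age),
        "exclusion_colonoscopy_years": float(policy.exclusion_colonoscopy_years),
    }


def policy_from_dict(d: dict, path="policy") -> ScreeningPolicy:
    test = _get(d, path, "test")
    colo = _get(d, path, "colonoscopy")
    part = _get(d, path, "participation")
    surv = d.get("surveillance", {})
    try:
        return ScreeningPolicy(
            programme_start_year=d.get("programme_start_year", 2009.0),
            start_age=d.get("start_age", 50.0),
            stop_age=d.get("stop_age", 70.0),
            interval=d.get("interval", 2.0),
            test=TestCharacteristics(
                sensitivity=_get(test, f"{path}.test", "sensitivity"),
                specificity=_get(test, f"{path}.test", "specificity"),
                cutoff_label=test.get("cutoff_label", "")),
            participation={
                sex: ParticipationModel(
                    first_round=m.get("first_round", 0.65),
                    retention=_get(m, f"{path}.participation.{sex}",
                                   "retention"),
                    conversion=m.get("conversion", 0.0))
                for sex, m in part.items()},
            colonoscopy_adherence=d.get("colonoscopy_adherence", 1.0),
            colonoscopy=ColonoscopyCharacteristics(
                sensitivity=_get(colo, f"{path}.colonoscopy", "sensitivity"),
                completeness=colo.get("completeness", 1.0)),
            thresholds=SurveillanceThresholds(**surv),
            surveillance_stop_age=d.get("surveillance_stop_age", 74.0),
            exclusion_colonoscopy_years=d.get("exclusion_colonoscopy_years",
                                              5.0))
    except TypeError as e:
        raise ConfigurationError(f"{path}: {e}") from e


def load_policy(path) -> ScreeningPolicy:
    return policy_from_dict(_get(_load_yaml(path), "", "policy"))


def dump_policy(policy: ScreeningPolicy, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"policy": policy_to_dict(policy)}, fh,
                       sort_keys=False)


# ---------------------------------------------------------------------------
# Population


def load_population(path) -> PopulationSpec:
    d = _get(_load_yaml(path), "", "population")
    strata = _get(d, "population", "strata")
    try:
        return PopulationSpec(
            baseline_year=d.get("baseline_year", 2008.0),
            strata={sex: {int(a): float(n) for a, n in ages.items()}
                    for sex, ages in strata.items()},
            sample_size=int(d.get("sample_size", 200_000)),
            horizon=int(d.get("horizon", 30)),
            renewal=bool(d.get("renewal", False)))
    except (TypeError, ValueError) as e:
        raise ConfigurationError(f"population: {e}") from e


def dump_population(spec: PopulationSpec, path) -> None:
    doc = {"population": {
        "baseline_year": float(spec.baseline_year),
        "sample_size": int(spec.sample_size),
        "horizon": int(spec.horizon),
        "renewal": bool(spec.renewal),
        "strata": {sex: {int(a): float(n) for a, n in ages.items()}
                   for sex, ages in spec.strata.items()},
    }}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
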