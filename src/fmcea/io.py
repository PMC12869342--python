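"""Reading and writing the pipeline's file formats.

All files are UTF-8 comma-separated CSV with mandatory headers and "."
decimals, except the run configuration which is flat YAML. Numbers are
serialized at full precision (`repr` round-trip); display rounding lives in
the report rendering only.

Formats:
    life_table.csv     age,sex,qx
    transitions.csv    strategy,from_state,to_state,prob
    state_econ.csv     state,utility,direct_medical,direct_nonmedical,indirect
                       (indirect is the 3-month estimate; annualized x4 on read)
    drug_costs.csv     strategy,drug_cost_annual
    dist_specs.csv     parameter,family,mean,se
    dsa_ranges.csv     parameter,low,high
    config.yaml        flat keys matching ModelConfig and CohortSpec fields
    results.csv        strategy,expected_cost,expected_qaly,icer_or_status,
                       inmb_50k,inmb_100k,inmb_150k (iNMB columns follow the
                       configured WTP thresholds)
    ceac.csv           strategy,wtp,probability
    tornado.csv        parameter,low,high,inmb_low,inmb_high,width
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .inputs import ModelInputs
from .states import ALIVE_STATES, CohortSpec, DiseaseTransitionMatrix, LifeTable, ModelConfig
from .uncertainty import (
    DistributionSpec,
    beta_from_moments,
    fixed_spec,
    gamma_from_moments,
    lognormal_from_moments,
)

INDIRECT_ANNUALIZATION = 4.0  # source study reports 3-month indirect costs


def _read_csv(path, columns: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    missing = columns - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_life_table(path) -> LifeTable:
    frame = _read_csv(path, {"age", "sex", "qx"})
    try:
        return LifeTable(frame)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_life_table(path, life_table: LifeTable) -> None:
    life_table.to_frame().to_csv(path, index=False)


def read_transitions(path) -> dict[str, DiseaseTransitionMatrix]:
    frame = _read_csv(path, {"strategy", "from_state", "to_state", "prob"})
    out: dict[str, DiseaseTransitionMatrix] = {}
    for strategy, grp in frame.groupby("strategy", sort=False):
        probs = np.full((3, 3), np.nan)
        for row in grp.itertuples():
            if row.from_state not in ALIVE_STATES or row.to_state not in ALIVE_STATES:
                raise ValidationError(
                    f"{path}: unknown state in row "
                    f"({row.strategy!r}, {row.from_state!r} -> {row.to_state!r})"
                )
            probs[
                ALIVE_STATES.index(row.from_state), ALIVE_STATES.index(row.to_state)
            ] = row.prob
        if np.isnan(probs).any():
            i, j = np.argwhere(np.isnan(probs))[0]
            raise ValidationError(
                f"{path}: strategy {strategy!r} missing transition "
                f"{ALIVE_STATES[i]} -> {ALIVE_STATES[j]}"
            )
        try:
            out[str(strategy)] = DiseaseTransitionMatrix(str(strategy), probs)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    if not out:
        raise ValidationError(f"{path}: no transition rows")
    return out


def write_transitions(path, transitions: Mapping[str, DiseaseTransitionMatrix]) -> None:
    rows = []
    for strategy, mat in transitions.items():
        for i, fs in enumerate(ALIVE_STATES):
            for j, ts in enumerate(ALIVE_STATES):
                rows.append((strategy, fs, ts, repr(float(mat.probs[i, j]))))
    pd.DataFrame(
        rows, columns=["strategy", "from_state", "to_state", "prob"]
    ).to_csv(path, index=False)


def read_state_economics(path):
    """Returns (utilities, direct_medical, direct_nonmedical, indirect).

    The ``indirect`` CSV column is a 3-month estimate and is annualized
    (x4) here; internal values are always $/year.
    """
    frame = _read_csv(
        path, {"state", "utility", "direct_medical", "direct_nonmedical", "indirect"}
    )
    frame = frame.set_index("state")
    missing = set(ALIVE_STATES) - set(frame.index)
    if missing:
        raise ValidationError(f"{path}: missing states {sorted(missing)}")
    utilities = {s: float(frame.loc[s, "utility"]) for s in ALIVE_STATES}
    dm = {s: float(frame.loc[s, "direct_medical"]) for s in ALIVE_STATES}
    dnm = {s: float(frame.loc[s, "direct_nonmedical"]) for s in ALIVE_STATES}
    ind = {
        s: float(frame.loc[s, "indirect"]) * INDIRECT_ANNUALIZATION
        for s in ALIVE_STATES
    }
    return utilities, dm, dnm, ind


def write_state_economics(path, utilities, direct_medical, direct_nonmedical, indirect) -> None:
    pd.DataFrame(
        {
            "state": list(ALIVE_STATES),
            "utility": [repr(float(utilities[s])) for s in ALIVE_STATES],
            "direct_medical": [repr(float(direct_medical[s])) for s in ALIVE_STATES],
            "direct_nonmedical": [
                repr(float(direct_nonmedical[s])) for s in ALIVE_STATES
            ],
            "indirect": [
                repr(float(indirect[s]) / INDIRECT_ANNUALIZATION)
                for s in ALIVE_STATES
            ],
        }
    ).to_csv(path, index=False)


def read_drug_costs(path) -> dict[str, float]:
    frame = _read_csv(path, {"strategy", "drug_cost_annual"})
    out = {}
    for row in frame.itertuples():
        cost = float(row.drug_cost_annual)
        if cost < 0:
            raise ValidationError(
                f"{path}: negative drug cost for strategy {row.strategy!r}"
            )
        out[str(row.strategy)] = cost
    return out


def write_drug_costs(path, drug_costs: Mapping[str, float]) -> None:
    pd.DataFrame(
        {
            "strategy": list(drug_costs),
            "drug_cost_annual": [repr(float(v)) for v in drug_costs.values()],
        }
    ).to_csv(path, index=False)


_CONFIG_FIELDS = {
    "discount_rate",
    "cycle_length",
    "wtp_thresholds",
    "perspective",
    "extinction_epsilon",
    "max_age",
    "half_cycle",
    "max_cycles",
}
_COHORT_FIELDS = {
    "mean_age",
    "sd_age",
    "prop_female",
    "initial_state_split",
    "age_bounds",
}


def read_config(path) -> tuple[ModelConfig, CohortSpec]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a flat mapping")
    unknown = set(raw) - _CONFIG_FIELDS - _COHORT_FIELDS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg_kw = {k: v for k, v in raw.items() if k in _CONFIG_FIELDS}
    coh_kw = {k: v for k, v in raw.items() if k in _COHORT_FIELDS}
    for key in ("wtp_thresholds",):
        if key in cfg_kw:
            cfg_kw[key] = tuple(float(x) for x in cfg_kw[key])
    for key in ("initial_state_split", "age_bounds"):
        if key in coh_kw:
            coh_kw[key] = tuple(coh_kw[key])
    try:
        return ModelConfig(**cfg_kw), CohortSpec(**coh_kw)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_config(path, config: ModelConfig, cohort: CohortSpec) -> None:
    data = {
        "discount_rate": config.discount_rate,
        "cycle_length": config.cycle_length,
        "wtp_thresholds": list(config.wtp_thresholds),
        "perspective": config.perspective,
        "extinction_epsilon": config.extinction_epsilon,
        "max_age": config.max_age,
        "half_cycle": config.half_cycle,
        "max_cycles": config.max_cycles,
        "mean_age": cohort.mean_age,
        "sd_age": cohort.sd_age,
        "prop_female": cohort.prop_female,
        "initial_state_split": list(cohort.initial_state_split),
        "age_bounds": list(cohort.age_bounds),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_dist_specs(path) -> dict[str, DistributionSpec]:
    frame = _read_csv(path, {"parameter", "family", "mean", "se"})
    out: dict[str, DistributionSpec] = {}
    for row in frame.itertuples():
        name = str(row.parameter)
        family = str(row.family)
        mean, se = float(row.mean), float(row.se)
        upper = 1.0 if name.split(".")[0] in ("tp", "utility") else None
        try:
            if family == "fixed" or se == 0.0:
                out[name] = fixed_spec(mean, upper)
            elif family == "beta":
                out[name] = beta_from_moments(mean, se)
            elif family == "gamma":
                out[name] = gamma_from_moments(mean, se)
            elif family == "lognormal":
                out[name] = lognormal_from_moments(mean, se, upper)
            else:
                raise ValidationError(f"unknown family {family!r}")
        except ValidationError as exc:
            raise ValidationError(f"{path}: parameter {name!r}: {exc}") from exc
    return out


def write_dist_specs(path, specs: Mapping[str, DistributionSpec]) -> None:
    pd.DataFrame(
        {
            "parameter": list(specs),
            "family": [s.family for s in specs.values()],
            "mean": [repr(float(s.target_mean)) for s in specs.values()],
            "se": [repr(float(s.target_se)) for s in specs.values()],
        }
    ).to_csv(path, index=False)


def read_dsa_ranges(path) -> dict[str, tuple[float, float]]:
    frame = _read_csv(path, {"parameter", "low", "high"})
    out = {}
    for row in frame.itertuples():
        low, high = float(row.low), float(row.high)
        if low > high:
            raise ValidationError(
                f"{path}: low > high for parameter {row.parameter!r}"
            )
        out[str(row.parameter)] = (low, high)
    return out


def write_dsa_ranges(path, ranges: Mapping[str, tuple[float, float]]) -> None:
    pd.DataFrame(
        {
            "parameter": list(ranges),
            "low": [repr(float(lo)) for lo, _ in ranges.values()],
            "high": [repr(float(hi)) for _, hi in ranges.values()],
        }
    ).to_csv(path, index=False)


INPUT_FILES = (
    "config.yaml",
    "life_table.csv",
    "transitions.csv",
    "state_econ.csv",
    "drug_costs.csv",
    "dist_specs.csv",
)


def read_inputs(directory) -> tuple[ModelInputs, dict[str, DistributionSpec]]:
    """Load a complete input directory (the layout `fmcea synth` writes)."""
    directory = Path(directory)
    config, cohort = read_config(directory / "config.yaml")
    life_table = read_life_table(directory / "life_table.csv")
    transitions = read_transitions(directory / "transitions.csv")
    utilities, dm, dnm, ind = read_state_economics(directory / "state_econ.csv")
    drug_costs = read_drug_costs(directory / "drug_costs.csv")
    inputs = ModelInputs(
        transitions=transitions,
        utilities=utilities,
        direct_medical=dm,
        direct_nonmedical=dnm,
        indirect=ind,
        drug_costs=drug_costs,
        life_table=life_table,
        cohort=cohort,
        config=config,
    )
    specs_path = directory / "dist_specs.csv"
    specs = read_dist_specs(specs_path) if specs_path.exists() else {}
    return inputs, specs


def write_inputs(directory, inputs: ModelInputs, specs=None) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_config(directory / "config.yaml", inputs.config, inputs.cohort)
    write_life_table(directory / "life_table.csv", inputs.life_table)
    write_transitions(directory / "transitions.csv", inputs.transitions)
    write_state_economics(
        directory / "state_econ.csv",
        inputs.utilities,
        inputs.direct_medical,
        inputs.direct_nonmedical,
        inputs.indirect if inputs.indirect is not None else {s: 0.0 for s in ALIVE_STATES},
    )
    write_drug_costs(directory / "drug_costs.csv", inputs.drug_costs)
    written = [directory / name for name in INPUT_FILES[:-1]]
    if specs is not None:
        write_dist_specs(directory / "dist_specs.csv", specs)
        written.append(directory / "dist_specs.csv")
    return written


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
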