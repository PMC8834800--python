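"""Configuration files and tabular output.

Run configurations are single YAML documents (JSON, being a YAML subset,
is accepted too). A configuration names any subset of the nine bundled
study scenarios and/or defines fully custom scenarios inline; all
defaults (240-month replacement cycle, 360-month horizon, start 2021-01,
target ratio 0.7, flat mode) are applied on load and unknown keys are
rejected. Trajectories are written as plain CSV: one row per month with
the date (YYYY-MM), per-species counts, monthly PM absorption and the
Shannon index.
"""

from __future__ import annotations

import importlib.resources
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import PlantingPolicy, TurnoverSettings
from .metrics import SeasonalProfileParams
from .params import SiteComposition, SpeciesParams, ValidationError, default_species_table
from .scenarios import SCENARIO_NAMES, ScenarioSpec, Trajectory, build_study_scenarios

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "default_config_path",
    "write_trajectory",
]

_TOP_KEYS = {
    "species",
    "scenarios",
    "mode",
    "target_ratio",
    "output_dir",
    "seed",
    "log_level",
    "seasonal_profile",
}
_SPECIES_KEYS = {"species_id", "annual_pm_g", "phenology", "monthly_weights"}
_SCENARIO_KEYS = {
    "name",
    "initial_composition",
    "policy",
    "settings",
    "start_year",
    "start_month",
    "horizon_months",
    "mode",
}
_POLICY_KEYS = {"mode", "priority_species", "target_ratio", "mix"}
_SETTINGS_KEYS = {"replacement_period_months", "dt_months", "turnover"}
_PROFILE_KEYS = {
    "leaf_on_start_month",
    "leaf_on_end_month",
    "ramp_months",
    "evergreen_winter_fraction",
}


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration with all defaults applied."""

    species: tuple[SpeciesParams, ...] = field(default_factory=default_species_table)
    scenarios: tuple[ScenarioSpec, ...] = ()
    mode: str = "flat"
    target_ratio: float = 0.7
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    seasonal_profile: SeasonalProfileParams = field(default_factory=SeasonalProfileParams)


def _reject_unknown(mapping: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def _parse_policy(raw: Mapping) -> PlantingPolicy:
    _reject_unknown(raw, _POLICY_KEYS, "policy block")
    return PlantingPolicy(**raw)


def _parse_settings(raw: Mapping) -> TurnoverSettings:
    _reject_unknown(raw, _SETTINGS_KEYS, "settings block")
    return TurnoverSettings(**raw)


def _parse_scenario(
    raw, default_mode: str, target_ratio: float
) -> ScenarioSpec:
    if isinstance(raw, str):
        by_name = {
            s.name.lower(): s
            for s in build_study_scenarios(target_ratio=target_ratio, mode=default_mode)
        }
        key = raw.lower()
        if key not in by_name:
            raise ValidationError(
                f"unknown scenario name {raw!r}; known scenarios: {list(SCENARIO_NAMES)}"
            )
        return by_name[key]
    if not isinstance(raw, Mapping):
        raise ValidationError(f"scenario entry must be a name or a mapping, got {raw!r}")
    _reject_unknown(raw, _SCENARIO_KEYS, f"scenario block {raw.get('name', '?')!r}")
    data = dict(raw)
    if "name" not in data or "initial_composition" not in data or "policy" not in data:
        raise ValidationError(
            "custom scenario blocks need name, initial_composition and policy"
        )
    data["initial_composition"] = SiteComposition(data["initial_composition"])
    data["policy"] = _parse_policy(data["policy"])
    if "settings" in data:
        data["settings"] = _parse_settings(data["settings"])
    data.setdefault("mode", default_mode)
    return ScenarioSpec(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Applies all defaults, resolves bundled scenario names
    (case-insensitively) into full scenario specs, and rejects unknown
    keys and out-of-range values with distinct messages.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ValidationError(f"cannot read config {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"config parse error in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ValidationError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")

    mode = raw.get("mode", "flat")
    if mode not in ("flat", "seasonal"):
        raise ValidationError(f"mode must be 'flat' or 'seasonal', got {mode!r}")
    target_ratio = float(raw.get("target_ratio", 0.7))
    if not (0.0 <= target_ratio <= 1.0):
        raise ValidationError(f"target_ratio must lie in [0, 1], got {target_ratio}")

    if "species" in raw:
        species = []
        for entry in raw["species"]:
            _reject_unknown(entry, _SPECIES_KEYS, "species block")
            if "monthly_weights" in entry:
                entry = {**entry, "monthly_weights": tuple(entry["monthly_weights"])}
            species.append(SpeciesParams(**entry))
        species = tuple(species)
    else:
        species = default_species_table()

    profile_raw = raw.get("seasonal_profile", {})
    _reject_unknown(profile_raw, _PROFILE_KEYS, "seasonal_profile block")
    profile = SeasonalProfileParams(**profile_raw)

    scenarios = tuple(
        _parse_scenario(entry, mode, target_ratio) for entry in raw.get("scenarios", [])
    )
    return RunConfig(
        species=species,
        scenarios=scenarios,
        mode=mode,
        target_ratio=target_ratio,
        output_dir=str(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        seasonal_profile=profile,
    )


def _policy_to_raw(policy: PlantingPolicy) -> dict:
    out: dict = {"mode": policy.mode}
    if policy.mode == "single_priority":
        out["priority_species"] = policy.priority_species
        out["target_ratio"] = policy.target_ratio
    if policy.mode == "fixed_mix":
        out["mix"] = dict(policy.mix)
    return out


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML; round-trips through load_config."""
    raw = {
        "mode": config.mode,
        "target_ratio": config.target_ratio,
        "output_dir": config.output_dir,
        "seed": config.seed,
        "log_level": config.log_level,
        "species": [
            {
                "species_id": s.species_id,
                "annual_pm_g": s.annual_pm_g,
                "phenology": s.phenology,
                "monthly_weights": list(s.monthly_weights),
            }
            for s in config.species
        ],
        "seasonal_profile": {
            "leaf_on_start_month": config.seasonal_profile.leaf_on_start_month,
            "leaf_on_end_month": config.seasonal_profile.leaf_on_end_month,
            "ramp_months": config.seasonal_profile.ramp_months,
            "evergreen_winter_fraction": config.seasonal_profile.evergreen_winter_fraction,
        },
        "scenarios": [
            {
                "name": s.name,
                "initial_composition": dict(s.initial_composition.counts),
                "policy": _policy_to_raw(s.policy),
                "settings": {
                    "replacement_period_months": s.settings.replacement_period_months,
                    "dt_months": s.settings.dt_months,
                    "turnover": s.settings.turnover,
                },
                "start_year": s.start_year,
                "start_month": s.start_month,
                "horizon_months": s.horizon_months,
                "mode": s.mode,
            }
            for s in config.scenarios
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(raw, sort_keys=False, default_flow_style=False),
        encoding="utf-8",
    )


def default_config_path() -> Path:
    """Path of the packaged default configuration (all nine scenarios)."""
    return Path(importlib.resources.files("arborsim") / "data" / "default_config.yaml")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV.

    Columns: ``date`` (YYYY-MM), one ``count_<species_id>`` column per
    species, ``mpa_g``, ``shannon``. Floats are printed at 6 significant
    digits; UTF-8 with LF line endings.
    """
    frame = trajectory.to_frame()
    frame.to_csv(
        path, index=False, float_format="%.6g", lineterminator="\n", encoding="utf-8"
    )
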