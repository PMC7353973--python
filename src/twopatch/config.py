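"""Run configuration: a flat YAML (or JSON) mapping validated against a
fixed schema before any computation runs.

A config file holds a ``model`` block with the flat parameter keys
(``r_H, r_L, K_H, K_L, alpha, c, mu, beta, lam, p`` and optional
``gamma``), plus optional blocks for the initial state, sweep scenario,
grid and levels, and scalar solver settings. Unknown keys anywhere are
rejected with an error naming them — a misspelled key silently falling
back to a default is the classic way to run the wrong model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .equilibria import ConservedTotal
from .experiments import SCENARIOS, SweepConfig, build_grid
from .model import CovaryRule, ModelParams, SystemState, params_from_mapping

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]

_TOP_KEYS = {
    "model", "C_T", "init", "scenario", "grid", "levels",
    "horizon", "rtol", "atol", "sample_dt", "seed", "method",
}
_INIT_KEYS = {"R_H", "R_L", "C_H", "C_L"}
_GRID_KEYS = {"start", "stop", "count", "spacing", "include_zero"}
_LEVEL_KEYS = {"name", "values"}


class ConfigError(ValueError):
    """A config file failed schema validation; the message names the key."""


@dataclass
class RunConfig:
    """Validated run configuration (see module docstring for the schema)."""

    model: dict
    C_T: float | None = None
    init: dict | None = None
    scenario: str | None = None
    grid: dict | None = None
    levels: dict | None = None
    horizon: float = 5000.0
    rtol: float = 1e-10
    atol: float = 1e-12
    sample_dt: float | None = None
    seed: int = 20200247
    method: str = "auto"

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "model" not in raw:
            raise ConfigError("missing required key 'model'")
        try:
            params, _ = params_from_mapping(raw["model"])
        except ValueError as exc:
            raise ConfigError(f"model block: {exc}") from exc
        if raw.get("init") is not None:
            bad = set(raw["init"]) ^ _INIT_KEYS
            if bad:
                raise ConfigError(
                    f"init block must have exactly keys {sorted(_INIT_KEYS)}; "
                    f"mismatch on {sorted(bad)}"
                )
        if raw.get("grid") is not None:
            unknown = set(raw["grid"]) - _GRID_KEYS
            if unknown:
                raise ConfigError(f"grid block: unknown keys {sorted(unknown)}")
            for key in ("start", "stop", "count"):
                if key not in raw["grid"]:
                    raise ConfigError(f"grid block: missing key '{key}'")
        if raw.get("levels") is not None:
            bad = set(raw["levels"]) ^ _LEVEL_KEYS
            if bad:
                raise ConfigError(
                    f"levels block must have exactly keys {sorted(_LEVEL_KEYS)}"
                )
        scenario = raw.get("scenario")
        if scenario is not None and scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {scenario!r}; one of {sorted(SCENARIOS)}"
            )
        if params.p == 0 and raw.get("C_T") is None:
            raise ConfigError(
                "missing key 'C_T': the conserved mean consumer density is "
                "required when demography is off (p = 0)"
            )
        cfg = cls(
            model=dict(raw["model"]),
            C_T=raw.get("C_T"),
            init=dict(raw["init"]) if raw.get("init") else None,
            scenario=scenario,
            grid=dict(raw["grid"]) if raw.get("grid") else None,
            levels=dict(raw["levels"]) if raw.get("levels") else None,
            horizon=float(raw.get("horizon", 5000.0)),
            rtol=float(raw.get("rtol", 1e-10)),
            atol=float(raw.get("atol", 1e-12)),
            sample_dt=float(raw["sample_dt"]) if raw.get("sample_dt") is not None else None,
            seed=int(raw.get("seed", 20200247)),
            method=str(raw.get("method", "auto")),
        )
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    # -- typed accessors ---------------------------------------------------

    def build_params(self) -> tuple[ModelParams, CovaryRule | None]:
        return params_from_mapping(self.model)

    def build_total(self) -> ConservedTotal | None:
        return ConservedTotal(float(self.C_T)) if self.C_T is not None else None

    def build_init(self) -> SystemState | None:
        if self.init is None:
            return None
        return SystemState(**{k: float(v) for k, v in self.init.items()})

    def build_grid(self):
        if self.grid is None:
            raise ConfigError("missing key 'grid' (required for sweeps)")
        return build_grid(
            start=float(self.grid["start"]),
            stop=float(self.grid["stop"]),
            count=int(self.grid["count"]),
            spacing=str(self.grid.get("spacing", "linear")),
            include_zero=bool(self.grid.get("include_zero", False)),
        )

    def build_sweep_config(self, seed: int | None = None) -> SweepConfig:
        if self.scenario is None:
            raise ConfigError("missing key 'scenario' (required for sweeps)")
        if self.levels is None:
            raise ConfigError("missing key 'levels' (required for sweeps)")
        params, _ = self.build_params()
        return SweepConfig(
            scenario=self.scenario,
            base_params=params,
            grid=self.build_grid(),
            fixed_levels=tuple(float(v) for v in self.levels["values"]),
            total=self.build_total(),
            seed=self.seed if seed is None else seed,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML; ``load_config`` of the result equals
    ``cfg`` (round-trip identity)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
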