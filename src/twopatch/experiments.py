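"""Parameter sweeps and summaries over the movement scenarios.

Four sweep scenarios cover the questions the model is built to answer:

* ``vary_lambda_p0`` — demography off; the equilibrium depends on the
  fitness sensitivity ``lam`` only (mobility drops out of the fixed
  point), so sweeping ``lam`` also describes the covarying case.
* ``vary_beta_fixed_lambda_p1`` — demography on; mobility swept at fixed
  fitness-sensitivity levels.
* ``vary_lambda_fixed_beta_p1`` — demography on; fitness sensitivity
  swept at fixed mobility levels.
* ``covary_p1`` — demography on; mobility swept with ``lam = gamma*beta``
  slaved to it, one sweep per ``gamma`` level. This is the scenario that
  produces the unimodal (hump-shaped) disparity pattern: random mixing
  dominates at low movement, fitness-directed movement at high movement.

Each sweep emits a tidy table, one row per (level, grid value), with the
equilibrium densities, fitness, regional means, and diagnostics. A
random subsample of rows is re-derived by an independent route (numeric
root for analytic rows, long integration for numeric rows) as a
continuous cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq, minimize_scalar

from .equilibria import (
    ConservedTotal,
    EquilibriumError,
    EquilibriumResult,
    equilibrium_no_demography,
    equilibrium_no_movement,
    equilibrium_numeric,
    find_equilibrium,
    integrate_to_equilibrium,
)
from .model import CovaryRule, ModelParams, SystemState, apply_covary, params_from_mapping, simulate

__all__ = [
    "SCENARIOS",
    "SWEEP_COLUMNS",
    "SweepConfig",
    "SweepError",
    "FigurePreset",
    "run_sweep",
    "write_sweep_csv",
    "regional_resource_trend",
    "time_to_equilibrium",
    "default_convergence_init",
    "disparity_profile",
    "DisparityProfile",
    "covary_disparity_minimum",
    "figure_presets",
    "build_grid",
]

#: scenario -> (fixed-level parameter name, swept parameter name, required p)
SCENARIOS = {
    "vary_lambda_p0": ("beta", "lam", 0),
    "vary_beta_fixed_lambda_p1": ("lam", "beta", 1),
    "vary_lambda_fixed_beta_p1": ("beta", "lam", 1),
    "covary_p1": ("gamma", "beta", 1),
}

SWEEP_COLUMNS = [
    "scenario",
    "level_name",
    "level_value",
    "swept_name",
    "swept_value",
    "R_H",
    "R_L",
    "C_H",
    "C_L",
    "w_H",
    "w_L",
    "mean_C",
    "mean_R",
    "stable",
    "residual",
]


class SweepError(RuntimeError):
    """A sweep failed; the message names the offending (level, value)."""


@dataclass(frozen=True)
class SweepConfig:
    """Specification of one sweep: which scenario, over which grid, at
    which fixed levels of the non-swept movement parameter.

    ``total`` (the conserved mean consumer density C_T) is required for
    the demography-free scenario and ignored otherwise. ``seed`` drives
    only the choice of rows for the independent cross-check.
    """

    scenario: str
    base_params: ModelParams
    grid: np.ndarray
    fixed_levels: tuple
    total: ConservedTotal | None = None
    cross_check_fraction: float = 0.1
    seed: int = 20200247

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {sorted(SCENARIOS)}")
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if grid[0] < 0:
            raise ValueError("grid values must be >= 0")
        object.__setattr__(self, "grid", grid)
        if len(self.fixed_levels) == 0:
            raise ValueError("fixed_levels must be nonempty")
        _, _, p = SCENARIOS[self.scenario]
        if self.base_params.p != p:
            raise ValueError(
                f"scenario {self.scenario!r} requires p = {p}, got p = {self.base_params.p}"
            )
        if p == 0 and self.total is None:
            raise ValueError("demography-free sweeps need the conserved total C_T")


def build_grid(start: float, stop: float, count: int, spacing: str = "linear",
               include_zero: bool = False) -> np.ndarray:
    """Construct a sweep grid; ``log`` spacing requires ``start > 0``
    (prepend zero via ``include_zero`` when the zero-movement endpoint is
    wanted)."""
    if spacing == "linear":
        grid = np.linspace(start, stop, count)
    elif spacing == "log":
        if start <= 0:
            raise ValueError("log spacing requires start > 0")
        grid = np.geomspace(start, stop, count)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    if include_zero and grid[0] > 0:
        grid = np.concatenate(([0.0], grid))
    return grid


def _params_at(config: SweepConfig, level: float, value: float) -> ModelParams:
    """Parameters at one sweep coordinate."""
    base = config.base_params
    if config.scenario == "vary_lambda_p0":
        return replace(base, beta=level, lam=value)
    if config.scenario == "vary_beta_fixed_lambda_p1":
        return replace(base, beta=value, lam=level)
    if config.scenario == "vary_lambda_fixed_beta_p1":
        return replace(base, beta=level, lam=value)
    # covary_p1
    return apply_covary(base, CovaryRule(gamma=level), value)


def _solve_point(
    config: SweepConfig, params: ModelParams, guess: SystemState | None
) -> EquilibriumResult:
    """Cheapest valid equilibrium route for one grid point."""
    if params.p == 0:
        return equilibrium_no_demography(params, config.total)
    if params.beta == 0:
        return equilibrium_no_movement(params)
    # numeric root with long-integration fallback on non-convergence
    return find_equilibrium(params, guess=guess, method="numeric")


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the sweep and return the tidy table (one row per fixed level
    and grid value, ordered by level then grid value).

    Along each level the previous grid point's equilibrium seeds the next
    solve (continuation), which keeps the quasi-Newton iteration inside
    the positive-density basin even at extreme fitness sensitivity. A
    ~10% random subsample of rows is recomputed by an independent route
    and must agree componentwise within 1e-6.
    """
    level_name, swept_name, _ = SCENARIOS[config.scenario]
    rows: list[dict] = []
    coords: list[tuple[float, float, EquilibriumResult, ModelParams]] = []
    for level in config.fixed_levels:
        guess: SystemState | None = None
        for value in config.grid:
            params = _params_at(config, level, value)
            try:
                res = _solve_point(config, params, guess)
            except EquilibriumError as exc:
                raise SweepError(
                    f"scenario {config.scenario}: {level_name}={level:g}, "
                    f"{swept_name}={value:g}: {exc}"
                ) from exc
            guess = res.state
            rec = res.to_record()
            rows.append(
                {
                    "scenario": config.scenario,
                    "level_name": level_name,
                    "level_value": float(level),
                    "swept_name": swept_name,
                    "swept_value": float(value),
                    "R_H": rec["R_H"],
                    "R_L": rec["R_L"],
                    "C_H": rec["C_H"],
                    "C_L": rec["C_L"],
                    "w_H": rec["w_H"],
                    "w_L": rec["w_L"],
                    "mean_C": (rec["C_H"] + rec["C_L"]) / 2.0,
                    "mean_R": (rec["R_H"] + rec["R_L"]) / 2.0,
                    "stable": rec["stable"],
                    "residual": rec["residual"],
                }
            )
            coords.append((float(level), float(value), res, params))
    _cross_check(config, coords)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


_PERTURB = np.array([1.02, 0.98, 1.05, 0.95])


def _cross_check(config: SweepConfig, coords: list) -> None:
    """Recompute a random subsample of rows by an independent route."""
    if config.cross_check_fraction <= 0 or not coords:
        return
    rng = np.random.default_rng(config.seed)
    k = max(1, int(round(config.cross_check_fraction * len(coords))))
    idx = rng.choice(len(coords), size=min(k, len(coords)), replace=False)
    for i in idx:
        level, value, res, params = coords[i]
        y = res.state.as_array()
        perturbed = SystemState.from_array(y * _PERTURB)
        if res.method in ("implicit_no_demography", "closed_form_no_movement"):
            other = equilibrium_numeric(params, guess=perturbed, total=config.total)
        else:
            other = integrate_to_equilibrium(params, perturbed)
        diff = float(np.max(np.abs(other.state.as_array() - y)))
        if diff > 1e-6:
            raise SweepError(
                f"cross-check failed at level={level:g}, value={value:g}: "
                f"independent route disagrees by {diff:.3g}"
            )


def write_sweep_csv(table: pd.DataFrame, path) -> None:
    """Write a sweep table as CSV with the canonical header and %.12g
    floats (byte-reproducible output)."""
    table.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Regional density trend (demography off)


def regional_resource_trend(base_params: ModelParams) -> str:
    """Predicted trend of regional (mean) resource density as fitness
    sensitivity increases, for the demography-free model.

    The direction is set by the between-patch comparison of the
    density-dependent mortality coefficient r/K of the resource:
    equal ratios leave the regional mean invariant; a larger ratio in the
    high-quality patch makes consumer concentration there relax resource
    self-limitation, raising the regional mean; a smaller ratio lowers
    it. Returns ``constant``, ``increasing`` or ``decreasing``.
    """
    if base_params.p != 0:
        raise ValueError("the regional trend classification applies to p = 0")
    q_H = base_params.high.r / base_params.high.K
    q_L = base_params.low.r / base_params.low.K
    scale = max(q_H, q_L)
    if abs(q_H - q_L) <= 1e-12 * scale:
        return "constant"
    return "increasing" if q_H > q_L else "decreasing"


# ---------------------------------------------------------------------------
# Convergence time (demography off)


def default_convergence_init(params: ModelParams, total: ConservedTotal) -> SystemState:
    """Strongly unequal consumer split (90/10) with resources at half
    carrying capacity — a nondegenerate start for convergence timing."""
    two_CT = 2.0 * total.C_T
    return SystemState(
        R_H=params.high.K / 2.0,
        R_L=params.low.K / 2.0,
        C_H=0.9 * two_CT,
        C_L=0.1 * two_CT,
    )


def time_to_equilibrium(
    params: ModelParams,
    init: SystemState,
    total: ConservedTotal,
    epsilon: float = 1e-3,
    horizon: float = 5000.0,
) -> float:
    """First time at which the trajectory from ``init`` is within
    relative max-norm distance ``epsilon`` of the demography-free
    equilibrium and stays there through the horizon.

    Returns 0.0 if the start is already (and remains) inside the
    epsilon-ball, ``inf`` if the trajectory has not settled by the
    horizon. The crossing is refined on the dense interpolant by
    bracketed root-finding.
    """
    if not 0 < epsilon < 1:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    target = equilibrium_no_demography(params, total).state.as_array()
    sol = simulate(params, init, horizon, dense_output=True)

    def dist(t: float) -> float:
        y = sol.sol(t)
        return float(np.max(np.abs(y - target) / np.abs(target)))

    ts = np.linspace(0.0, horizon, 4001)
    ys = sol.sol(ts)
    ds = np.max(np.abs(ys - target[:, None]) / np.abs(target[:, None]), axis=0)
    above = np.nonzero(ds >= epsilon)[0]
    if above.size == 0:
        return 0.0
    i = above[-1]
    if i == ts.size - 1:
        return math.inf
    return float(brentq(lambda t: dist(t) - epsilon, ts[i], ts[i + 1], xtol=1e-8))


# ---------------------------------------------------------------------------
# Disparity profiles


@dataclass(frozen=True)
class DisparityProfile:
    """Between-patch disparity series per fixed level.

    ``series`` maps each level value to a frame with columns
    ``swept_value``, ``dC`` (= C_H - C_L) and ``dR`` (= R_H - R_L);
    ``extrema`` holds, per level and series, the grid locations of the
    minimum and maximum.
    """

    series: dict = field(default_factory=dict)
    extrema: pd.DataFrame = field(default_factory=pd.DataFrame)


def disparity_profile(table: pd.DataFrame) -> DisparityProfile:
    """Disparity series C_H - C_L and R_H - R_L per fixed level of a
    sweep table, with the grid location of each series' extremum."""
    series: dict = {}
    rows = []
    for level, sub in table.groupby("level_value", sort=True):
        sub = sub.sort_values("swept_value")
        frame = pd.DataFrame(
            {
                "swept_value": sub["swept_value"].to_numpy(),
                "dC": (sub["C_H"] - sub["C_L"]).to_numpy(),
                "dR": (sub["R_H"] - sub["R_L"]).to_numpy(),
            }
        )
        series[float(level)] = frame
        for name in ("dC", "dR"):
            v = frame[name].to_numpy()
            x = frame["swept_value"].to_numpy()
            rows.append(
                {
                    "level_value": float(level),
                    "series": name,
                    "argmin_swept": float(x[int(np.argmin(v))]),
                    "argmax_swept": float(x[int(np.argmax(v))]),
                    "min": float(v.min()),
                    "max": float(v.max()),
                }
            )
    return DisparityProfile(series=series, extrema=pd.DataFrame(rows))


def covary_disparity_minimum(
    base_params: ModelParams,
    gamma: float,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mobility at which the consumer-density disparity C_H* - C_L* is
    smallest under covarying movement (lam = gamma*beta), and the
    disparity there.

    A grid scan brackets the discrete argmin; when it is interior, the
    turning point is refined by bounded golden-section/parabolic search
    on the continuous equilibrium map. Returns ``(beta_at_min, dC_min)``.
    """
    if grid is None:
        grid = build_grid(0.2, 10.0, 50)
    grid = np.asarray(grid, dtype=float)
    rule = CovaryRule(gamma=gamma)

    guess_holder: dict = {}
    states: list[SystemState] = []

    def disparity(beta: float) -> float:
        params = apply_covary(base_params, rule, beta)
        res = find_equilibrium(params, guess=guess_holder.get("g"), method="numeric")
        guess_holder["g"] = res.state
        return res.state.C_H - res.state.C_L

    values = []
    for b in grid:
        values.append(disparity(b))
        states.append(guess_holder["g"])
    values = np.asarray(values)
    i = int(np.argmin(values))
    if i == grid.size - 1:
        # monotone decrease across the grid: no interior turning point
        return float(grid[i]), float(values[i])
    if i == 0:
        # the dip may sit below the first grid point: the zero-movement
        # limit (the no-movement closed form) has the full demographic
        # disparity, so bracket down toward beta = 0
        cf = equilibrium_no_movement(replace(base_params, beta=0.0, lam=0.0))
        d0 = cf.state.C_H - cf.state.C_L
        if d0 <= values[0]:
            return float(grid[0]), float(values[0])
        lo, hi = grid[0] / 1e4, grid[1]
    else:
        lo, hi = grid[i - 1], grid[i + 1]
    guess_holder["g"] = states[i]
    opt = minimize_scalar(
        disparity,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return float(opt.x), float(opt.fun)


# ---------------------------------------------------------------------------
# Presets


@dataclass(frozen=True)
class FigurePreset:
    """A named, ready-to-run sweep specification."""

    name: str
    params: ModelParams
    rule: CovaryRule | None
    scenario: str
    level_name: str
    levels: tuple
    grid: np.ndarray
    total: ConservedTotal | None

    def sweep_config(self, seed: int = 20200247,
                     cross_check_fraction: float = 0.1) -> SweepConfig:
        return SweepConfig(
            scenario=self.scenario,
            base_params=self.params,
            grid=self.grid,
            fixed_levels=self.levels,
            total=self.total,
            seed=seed,
            cross_check_fraction=cross_check_fraction,
        )


def figure_presets() -> dict[str, FigurePreset]:
    """The named scenario presets shipped with the package (fig1,
    fig2_solid/dashed/dotted, fig3, fig4, fig5), loaded from the YAML
    fixture."""
    text = resources.files("twopatch").joinpath("data/presets.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, FigurePreset] = {}
    for name, entry in raw.items():
        params, rule = params_from_mapping(entry["model"])
        grid_spec = dict(entry["grid"])
        grid_spec.pop("name", None)
        grid = build_grid(**grid_spec)
        total = ConservedTotal(float(entry["C_T"])) if "C_T" in entry else None
        out[name] = FigurePreset(
            name=name,
            params=params,
            rule=rule,
            scenario=entry["scenario"],
            level_name=entry["levels"]["name"],
            levels=tuple(float(v) for v in entry["levels"]["values"]),
            grid=grid,
            total=total,
        )
    return out
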