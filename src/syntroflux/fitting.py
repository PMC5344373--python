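"""Parameter estimation from batch time-course observations.

The free parameters (uptake Vmax/Km, branching ratios, biomass demands)
are estimated by minimising a weighted sum of squared standardized
residuals between the simulated community and observed channels (OD600,
metabolite concentrations, qPCR gene copies).  This replaces by-hand
tuning with a reproducible derivative-free search: multi-start
Nelder-Mead over the parameter box, Latin-hypercube start points, fully
determined by the seed.

Channel conventions: concentrations and OD are compared on a linear
scale; qPCR copy numbers span decades and are compared on log10.
Ratio parameters are searched on a log scale to preserve positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from . import config as _config
from .dfba import SimulationConfig, TimeCourse, simulate_batch

__all__ = [
    "ObservationModel",
    "FitSpec",
    "FitResult",
    "default_observation_model",
    "map_trajectory",
    "loss",
    "fit_parameters",
]

#: channel name -> shared metabolite id
CHANNEL_METABOLITES = {
    "glucose": "glc_e",
    "acetate": "ac_e",
    "butyrate": "but_e",
    "h2": "h2_e",
    "co2": "co2_e",
    "formate": "for_e",
    "no3": "no3_e",
    "no2": "no2_e",
    "nh4": "nh4_e",
}
_LOG_EPS = 1.0  # floor (copies/mL) before log10 of qPCR channels


@dataclass
class ObservationModel:
    """Maps simulated state onto measurement channels.

    ``od_coefficients``: OD600 per gDW/L per species (summed over species);
    ``copies_per_gdw``: qPCR gene copies per gDW (reported per mL);
    ``observed_channels``: (channel, noise_sd, kind) with kind in
    {additive, lognormal}; sd in channel units (log10 units for lognormal).
    """

    od_coefficients: dict[str, float]
    copies_per_gdw: dict[str, float]
    observed_channels: list[tuple[str, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.od_coefficients.values()):
            raise ValueError("OD coefficients must be positive")
        if any(v <= 0 for v in self.copies_per_gdw.values()):
            raise ValueError("copy-number coefficients must be positive")
        for ch, sd, kind in self.observed_channels:
            if sd < 0:
                raise ValueError(f"negative noise sd for channel {ch!r}")
            if kind not in ("additive", "lognormal"):
                raise ValueError(f"unknown noise kind {kind!r} for {ch!r}")

    def channel_names(self) -> list[str]:
        return [ch for ch, _, _ in self.observed_channels]

    def noise_sd(self, channel: str) -> float:
        for ch, sd, _ in self.observed_channels:
            if ch == channel:
                return sd
        raise KeyError(channel)


def default_observation_model(
    species: Sequence[str] = ("clostridium", "wolinella"),
) -> ObservationModel:
    """Instrument defaults: OD 2.5 per gDW/L; 1e12 genome-corrected gene
    copies per gDW; HPLC/GC channels with ~2%-of-max additive noise, OD
    0.01, qPCR 0.1 log10 units (lognormal)."""
    channels: list[tuple[str, float, str]] = [("od600", 0.01, "additive")]
    for ch in ("glucose", "acetate", "butyrate", "h2", "co2", "no3", "no2"):
        channels.append((ch, 0.06, "additive"))
    for sp in species:
        channels.append((f"copies_{sp}", 0.1, "lognormal"))
    return ObservationModel(
        od_coefficients={sp: 2.5 for sp in species},
        copies_per_gdw={sp: 1e12 for sp in species},
        observed_channels=channels,
    )


def map_trajectory(
    tc: TimeCourse,
    obs_model: ObservationModel,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Noise-free observation channels evaluated at ``times``
    (simulation grid by default); wide format, one column per channel."""
    times = tc.times if times is None else np.asarray(times, dtype=float)
    if times.size and (times.min() < tc.times[0] - 1e-9 or
                       times.max() > tc.times[-1] + 1e-9):
        raise ValueError(
            f"observation times [{times.min()}, {times.max()}] outside the "
            f"simulated span [{tc.times[0]}, {tc.times[-1]}]"
        )
    out = {"time_h": times}
    for ch in obs_model.channel_names():
        if ch == "od600":
            od = np.zeros_like(tc.times)
            for sp, coef in obs_model.od_coefficients.items():
                if sp in tc.biomass:
                    od = od + coef * tc.biomass[sp]
            vals = od
        elif ch.startswith("copies_"):
            sp = ch[len("copies_"):]
            if sp not in tc.biomass:
                continue
            # gDW/L -> gDW/mL is /1000
            vals = obs_model.copies_per_gdw[sp] * tc.biomass[sp] / 1000.0
        elif ch in CHANNEL_METABOLITES:
            met = CHANNEL_METABOLITES[ch]
            if met not in tc.concentration:
                continue
            vals = tc.concentration[met]
        else:
            raise KeyError(f"unknown observation channel {ch!r}")
        out[ch] = np.interp(times, tc.times, vals)
    return pd.DataFrame(out)


def loss(
    tc: TimeCourse,
    observations: pd.DataFrame,
    obs_model: ObservationModel,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted SSE of standardized residuals.

    ``observations``: long format (time_h, channel, replicate, value).
    Residuals are standardized by the channel's noise sd (or by the
    channel's observed range when the sd is zero); qPCR channels are
    compared on log10.
    """
    if observations.empty:
        raise ValueError("empty observation table")
    weights = weights or {}
    total = 0.0
    pred_cache = map_trajectory(
        tc, obs_model, np.sort(observations["time_h"].unique())
    )
    for ch, grp in observations.groupby("channel"):
        if ch not in pred_cache.columns:
            continue
        pred = np.interp(
            grp["time_h"].to_numpy(), pred_cache["time_h"], pred_cache[ch]
        )
        obs = grp["value"].to_numpy(dtype=float)
        if ch.startswith("copies_"):
            pred = np.log10(np.maximum(pred, _LOG_EPS))
            obs = np.log10(np.maximum(obs, _LOG_EPS))
        sd = obs_model.noise_sd(ch)
        if sd <= 0:
            rng_ = obs.max() - obs.min()
            sd = rng_ if rng_ > 0 else 1.0
        r = (pred - obs) / sd
        total += weights.get(ch, 1.0) * float(np.dot(r, r))
    return total


@dataclass
class FitSpec:
    """What to fit: free parameters with boxes, fixed overrides, the
    conditions fitted jointly, channel weights and search budget."""

    free_parameters: list[tuple[str, float, float, float]]  # name, lo, hi, init
    fixed_parameters: dict[str, float] = field(default_factory=dict)
    conditions: list[str] = field(default_factory=lambda: ["NH4_NO3"])
    weights: dict[str, float] = field(default_factory=dict)
    species: tuple[str, ...] = ("clostridium", "wolinella")
    n_starts: int = 10
    max_evaluations: int = 200

    def __post_init__(self) -> None:
        for name, lo, hi, init in self.free_parameters:
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")
            if not (lo <= init <= hi):
                raise ValueError(f"{name}: initial value outside bounds")


@dataclass
class FitResult:
    estimates: dict[str, float]
    loss: float
    residuals: dict[str, float]
    n_evaluations: int
    converged: bool
    seed: int


def _is_log_scaled(name: str) -> bool:
    return name.startswith("ratio.")


def _to_internal(name: str, v: float) -> float:
    return np.log10(v) if _is_log_scaled(name) else v


def _from_internal(name: str, v: float) -> float:
    return 10.0 ** v if _is_log_scaled(name) else v


def fit_parameters(
    observations: pd.DataFrame | Mapping[str, pd.DataFrame],
    spec: FitSpec,
    seed: int = 0,
    obs_model: ObservationModel | None = None,
    sim_config: SimulationConfig | None = None,
) -> FitResult:
    """Multi-start Nelder-Mead estimation of the free parameters.

    ``observations``: one long-format table, or a mapping
    condition -> table when several conditions are fitted jointly.
    Deterministic for a given seed.
    """
    if isinstance(observations, pd.DataFrame):
        obs_by_cond = {spec.conditions[0]: observations}
    else:
        obs_by_cond = dict(observations)
    missing = [c for c in spec.conditions if c not in obs_by_cond]
    if missing:
        raise ValueError(f"no observations for conditions {missing}")
    for c, df in obs_by_cond.items():
        if df["channel"].nunique() < 2:
            raise ValueError(
                f"observations for {c} cover fewer than 2 channels"
            )
    obs_model = obs_model or default_observation_model(spec.species)
    sim_config = sim_config or SimulationConfig()
    names = [p[0] for p in spec.free_parameters]
    n_eval = 0

    def objective(x_internal: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        overrides = dict(spec.fixed_parameters)
        overrides.update(
            {n: _from_internal(n, v) for n, v in zip(names, x_internal)}
        )
        total = 0.0
        for cname in spec.conditions:
            cond = _config.condition(cname, params=overrides)
            com = _config.build_community(cond, species=spec.species)
            try:
                tc = simulate_batch(com, cond.initial_state, sim_config)
            except RuntimeError:
                return 1e12
            total += loss(tc, obs_by_cond[cname], obs_model, spec.weights)
        return total

    if not names:
        value = objective(np.array([]))
        return FitResult(
            estimates={}, loss=value, residuals={}, n_evaluations=n_eval,
            converged=True, seed=seed,
        )

    lo = np.array([_to_internal(n, p[1]) for n, p in zip(names, spec.free_parameters)])
    hi = np.array([_to_internal(n, p[2]) for n, p in zip(names, spec.free_parameters)])
    x0_list = [
        np.array([_to_internal(n, p[3]) for n, p in zip(names, spec.free_parameters)])
    ]
    if spec.n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        pts = sampler.random(spec.n_starts - 1)
        x0_list.extend(lo + p * (hi - lo) for p in pts)

    best_x, best_val, converged = None, np.inf, False
    per_start_budget = max(spec.max_evaluations // max(len(x0_list), 1), 10)
    for x0 in x0_list:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": per_start_budget, "xatol": 1e-4, "fatol": 1e-8},
        )
        if res.fun < best_val:
            best_val, best_x, converged = res.fun, res.x, bool(res.success)
    if best_x is None or not np.isfinite(best_val) or best_val >= 1e12:
        raise RuntimeError(
            "all starts failed to produce a feasible simulation; tried "
            f"{len(x0_list)} start points"
        )

    estimates = {n: _from_internal(n, v) for n, v in zip(names, best_x)}
    # per-channel residual breakdown at the optimum
    overrides = dict(spec.fixed_parameters)
    overrides.update(estimates)
    residuals: dict[str, float] = {}
    for cname in spec.conditions:
        cond = _config.condition(cname, params=overrides)
        com = _config.build_community(cond, species=spec.species)
        tc = simulate_batch(com, cond.initial_state, sim_config)
        for ch in obs_by_cond[cname]["channel"].unique():
            sub = obs_by_cond[cname][obs_by_cond[cname]["channel"] == ch]
            try:
                residuals[ch] = residuals.get(ch, 0.0) + loss(
                    tc, sub, obs_model, spec.weights
                )
            except ValueError:
                continue
    return FitResult(
        estimates=estimates, loss=float(best_val), residuals=residuals,
        n_evaluations=n_eval, converged=converged, seed=seed,
    )
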