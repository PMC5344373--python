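"""Optimal community behaviour: release the fitted ratio constraints.

The fitted co-culture encodes observed suboptimal branching (butyrate
formation, NO2- co-assimilation) as hard flux-ratio constraints.  This
module re-simulates the same batch with those two ratios released —
nutrient kinetics unchanged — and compares yields and growth rates, which
quantifies how far the experimental community sits from its in-silico
optimum and how much additional interspecies H2 transfer is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import config as _config
from .dfba import SimulationConfig, TimeCourse, interaction_yields, simulate_batch

__all__ = ["OptimalComparison", "simulate_optimal", "compare_optimal", "run_comparison"]


@dataclass
class OptimalComparison:
    condition: str
    fitted_yields: dict[str, float]
    optimal_yields: dict[str, float]
    fitted_mu: float
    optimal_mu: float
    #: signed percent change of each yield, 100*(optimal - fitted)/fitted
    percent_changes: dict[str, float] = field(default_factory=dict)

    @property
    def mu_ratio_percent(self) -> float:
        """Fitted growth rate as a percentage of the optimal one."""
        return 100.0 * self.fitted_mu / self.optimal_mu

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": k,
                "fitted": self.fitted_yields.get(k),
                "optimal": self.optimal_yields.get(k),
                "percent_change": self.percent_changes.get(k),
            }
            for k in sorted(set(self.fitted_yields) | set(self.optimal_yields))
        ]
        rows.append(
            {
                "variable": "growth_rate",
                "fitted": self.fitted_mu,
                "optimal": self.optimal_mu,
                "percent_change": self.mu_ratio_percent - 100.0,
            }
        )
        return pd.DataFrame(rows)


def simulate_optimal(
    community_or_condition,
    condition_name: str | None = None,
    sim_config: SimulationConfig | None = None,
) -> TimeCourse:
    """Batch simulation with all ratio constraints removed.

    Accepts either a condition name (community rebuilt without ratios) or
    an existing community (ratios stripped per species).  Kinetic uptake
    bounds are retained: "optimal" means optimal branching, not magical
    transport.
    """
    if isinstance(community_or_condition, str):
        cond = _config.condition(community_or_condition)
        com = _config.build_community(cond, optimal=True)
        initial = cond.initial_state
    else:
        com = community_or_condition
        from .community import CommunityModel, couple_models

        stripped = [sp.without_ratio_constraints() for sp in com.species]
        com = CommunityModel(
            species=stripped,
            shared_metabolites=com.shared_metabolites,
            exchange_map=com.exchange_map,
        )
        if condition_name is None:
            raise ValueError("condition_name required with an explicit community")
        cond = _config.condition(condition_name)
        initial = cond.initial_state
    tc = simulate_batch(com, initial, sim_config)
    tc.condition = cond.name
    tc.meta["optimal"] = True
    tc.meta["community"] = com
    return tc


def _peak_growth_rate(tc: TimeCourse, species: str = "clostridium") -> float:
    """Peak specific growth rate over the batch — the exponential-phase
    rate, robust to the late glucose-exhaustion crash."""
    return float(tc.growth_rate[species].max())


def compare_optimal(
    fitted_tc: TimeCourse,
    optimal_tc: TimeCourse,
    community,
    optimal_community=None,
    species: str = "clostridium",
) -> OptimalComparison:
    """Yield and growth-rate comparison between fitted and optimal runs.

    Both trajectories must come from the same condition.  Yields are
    cumulative over the full batch, normalised per mol of the species'
    reference substrate (glucose); growth rates are the peak specific
    rates.
    """
    if fitted_tc.condition and optimal_tc.condition and (
        fitted_tc.condition != optimal_tc.condition
    ):
        raise ValueError(
            f"condition mismatch: {fitted_tc.condition!r} vs "
            f"{optimal_tc.condition!r}"
        )
    fitted_y = interaction_yields(fitted_tc, community)[species]
    optimal_y = interaction_yields(
        optimal_tc, optimal_community or community
    )[species]
    changes = {}
    for k, fv in fitted_y.items():
        ov = optimal_y.get(k)
        if ov is None or abs(fv) < 1e-12:
            continue
        changes[k] = 100.0 * (ov - fv) / fv
    return OptimalComparison(
        condition=fitted_tc.condition or "",
        fitted_yields=fitted_y,
        optimal_yields=optimal_y,
        fitted_mu=_peak_growth_rate(fitted_tc, species),
        optimal_mu=_peak_growth_rate(optimal_tc, species),
        percent_changes=changes,
    )


def run_comparison(
    condition_name: str,
    sim_config: SimulationConfig | None = None,
) -> OptimalComparison:
    """Convenience: simulate fitted and optimal batches for one condition
    and compare them."""
    cond = _config.condition(condition_name)
    fitted_com = _config.build_community(cond)
    optimal_com = _config.build_community(cond, optimal=True)
    fitted_tc = simulate_batch(fitted_com, cond.initial_state, sim_config)
    fitted_tc.condition = cond.name
    optimal_tc = simulate_batch(optimal_com, cond.initial_state, sim_config)
    optimal_tc.condition = cond.name
    return compare_optimal(fitted_tc, optimal_tc, fitted_com, optimal_com)
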