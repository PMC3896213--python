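"""End-to-end in-silico experiments on arbor architecture.

Three computational experiments probe how the grouping of transduction
units at spike initiation zones shapes touch-evoked firing:

* grouping perturbations -- move units into primary or secondary clusters
  of the four prototypical arbors and measure the percent firing-rate
  change (paired noise, identical transduction parameters);
* fill-up survey -- grow an arbor one unit at a time, either by raising
  secondary clusters to the primary size (skew-preserving) or by topping
  up the smallest clusters (equalizing), and track the percent change from
  baseline;
* architecture comparison -- contrast a small skewed arbor against a large
  even one through their displacement-response exponentials (kappa, Y0)
  and extra-sum-of-squares F tests.

Percent changes use the summed static-phase rates over the stimulation
battery (the sustained response the structural comparisons target),
optionally restricted to suprathreshold depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import (
    compare_exponential_fits,
    fit_displacement_response,
    percent_fr_change,
    percent_fr_change_signed,
)
from .arbor import ArborConfiguration, fill_up_sequence
from .model import AfferentModel, SimulationResult
from .transduction import TransductionParameters

__all__ = [
    "PROTOTYPICAL_ARBORS",
    "TABLE_GROUPING_PAIRS",
    "simulate_pair",
    "suprathreshold_percent_change",
    "run_grouping_experiment",
    "per_unit_gains",
    "run_fillup_survey",
    "compare_architectures",
]

# The four prototypical end organs (3-5 zones, 13-20 units) whose fitted
# configurations anchor the structural surveys.
PROTOTYPICAL_ARBORS: dict[int, ArborConfiguration] = {
    1: ArborConfiguration((8, 5, 3, 1), label="Arbor 1"),
    2: ArborConfiguration((7, 6, 4, 2, 1), label="Arbor 2"),
    3: ArborConfiguration((6, 4, 3), label="Arbor 3"),
    4: ArborConfiguration((5, 4, 3, 1), label="Arbor 4"),
}

# Grouping perturbation pairs: for each prototypical arbor, one pair where
# units move into the primary cluster and one where they move into the
# secondary cluster (total units conserved within each pair).
TABLE_GROUPING_PAIRS: tuple[dict, ...] = (
    {"arbor": 1, "which": "primary", "before": (6, 5, 3, 3), "after": (10, 5, 1, 1), "delta": 4},
    {"arbor": 1, "which": "secondary", "before": (8, 3, 3, 3), "after": (8, 7, 1, 1), "delta": 4},
    {"arbor": 2, "which": "primary", "before": (6, 6, 4, 2, 2), "after": (9, 6, 3, 1, 1), "delta": 3},
    {"arbor": 2, "which": "secondary", "before": (7, 4, 4, 3, 2), "after": (7, 7, 4, 1, 1), "delta": 3},
    {"arbor": 3, "which": "primary", "before": (4, 4, 3, 2), "after": (6, 4, 2, 1), "delta": 2},
    {"arbor": 3, "which": "secondary", "before": (5, 3, 3, 2), "after": (5, 5, 2, 1), "delta": 2},
    {"arbor": 4, "which": "primary", "before": (5, 4, 4), "after": (7, 4, 2), "delta": 2},
    {"arbor": 4, "which": "secondary", "before": (6, 4, 3), "after": (6, 6, 1), "delta": 2},
)


def _sibling(model: AfferentModel, arbor: ArborConfiguration) -> AfferentModel:
    return AfferentModel(
        arbor,
        target=model.target,
        protocol=model.protocol,
        skin=model.skin,
        lif=model.lif,
        noise=model.noise,
    )


def simulate_pair(
    base_model: AfferentModel,
    other: ArborConfiguration,
    params: TransductionParameters,
    seed: int = 0,
) -> tuple[SimulationResult, SimulationResult]:
    """Simulate two configurations with identical parameters and paired noise."""
    sim_a = base_model.simulate(params, seed=seed)
    sim_b = _sibling(base_model, other).simulate(params, seed=seed)
    return sim_a, sim_b


def suprathreshold_percent_change(
    sim_new: SimulationResult, sim_ref: SimulationResult, signed: bool = True
) -> float:
    """Percent firing-rate change over depths suprathreshold in the reference."""
    depths = sim_ref.suprathreshold_depths()
    if not depths:
        raise ValueError("reference configuration never fires; no suprathreshold depths")
    a = sim_new.static_rates_at(depths)
    b = sim_ref.static_rates_at(depths)
    return percent_fr_change_signed(a, b) if signed else percent_fr_change(a, b)


def run_grouping_experiment(
    template: AfferentModel,
    params_by_arbor: dict[int, TransductionParameters],
    pairs=TABLE_GROUPING_PAIRS,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent firing-rate change for each grouping perturbation pair.

    Each pair's "before" and "after" groupings are simulated with the same
    (per-arbor) parameters and paired noise; the unsigned percent change is
    taken over summed static rates across all stimulations.
    """
    rows = []
    for pair in pairs:
        before = ArborConfiguration(pair["before"])
        after = ArborConfiguration(pair["after"])
        if before.total_units != after.total_units:
            raise ValueError(f"unit total not conserved in pair {pair}")
        params = params_by_arbor[pair["arbor"]]
        sim_b = _sibling(template, before).simulate(params, seed=seed)
        sim_a = _sibling(template, after).simulate(params, seed=seed)
        change = percent_fr_change(sim_a.hfr, sim_b.hfr)
        rows.append(
            {
                "arbor": pair["arbor"],
                "which": pair["which"],
                "before": str(before),
                "after": str(after),
                "delta_units": pair["delta"],
                "pct_change": change,
                "pct_change_signed": percent_fr_change_signed(sim_a.hfr, sim_b.hfr),
                "pct_per_unit": change / pair["delta"],
            }
        )
    return pd.DataFrame(rows)


def per_unit_gains(table: pd.DataFrame) -> dict[str, float]:
    """Mean percent gain per unit moved, split by destination cluster."""
    return {
        which: float(table.loc[table["which"] == which, "pct_per_unit"].mean())
        for which in ("primary", "secondary")
    }


def run_fillup_survey(
    base_model: AfferentModel,
    params: TransductionParameters,
    strategies: tuple[str, ...] = ("secondary", "smallest"),
    max_added: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent change vs units added, for each fill strategy.

    Returns one row per (strategy, units_added) with the signed percent
    change of summed static rates relative to the unmodified baseline.
    """
    baseline = base_model.simulate(params, seed=seed)
    cap = max_added if max_added is not None else 10_000
    rows = [
        {"strategy": s, "units_added": 0, "config": str(base_model.arbor),
         "total_units": base_model.arbor.total_units, "pct_change": 0.0}
        for s in strategies
    ]
    for strategy in strategies:
        for k, config in enumerate(
            fill_up_sequence(base_model.arbor, strategy, cap), start=1
        ):
            sim = _sibling(base_model, config).simulate(params, seed=seed)
            rows.append(
                {
                    "strategy": strategy,
                    "units_added": k,
                    "config": str(config),
                    "total_units": config.total_units,
                    "pct_change": percent_fr_change_signed(sim.hfr, baseline.hfr),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ArchitectureComparison:
    """Displacement-response contrast between two configurations."""

    fits: dict
    f_kappa: float
    p_kappa: float
    f_y0: float
    p_y0: float
    table: pd.DataFrame


def compare_architectures(
    template: AfferentModel,
    config_a: ArborConfiguration,
    config_b: ArborConfiguration,
    params: TransductionParameters,
    seed: int = 0,
) -> ArchitectureComparison:
    """Contrast two arbors via exponential displacement-response fits.

    Every (depth, acceleration, repetition) static rate contributes one
    point per depth, so the default protocol yields 15 simulations per
    displacement for each configuration.
    """
    sims = {}
    for name, cfg in (("a", config_a), ("b", config_b)):
        sims[name] = _sibling(template, cfg).simulate(params, seed=seed)
    depths = {n: s.rates["depth_mm"].to_numpy(float) for n, s in sims.items()}
    rates = {n: s.hfr for n, s in sims.items()}
    fits = {
        "a": fit_displacement_response(depths["a"], rates["a"]),
        "b": fit_displacement_response(depths["b"], rates["b"]),
    }
    f_k, p_k = compare_exponential_fits(
        depths["a"], rates["a"], depths["b"], rates["b"], parameter="kappa"
    )
    f_y, p_y = compare_exponential_fits(
        depths["a"], rates["a"], depths["b"], rates["b"], parameter="y0"
    )
    table = pd.concat(
        [
            sims["a"].rates.assign(config=str(config_a)),
            sims["b"].rates.assign(config=str(config_b)),
        ],
        ignore_index=True,
    )
    return ArchitectureComparison(
        fits=fits, f_kappa=f_k, p_kappa=p_k, f_y0=f_y, p_y0=p_y, table=table
    )
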