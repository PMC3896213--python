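"""Synthetic study inputs: the prototypical SAI target response and arbors.

The fitting target emulates a prototypical slowly-adapting type I response:
linear regressions of ramp-phase rate vs displacement (one per ramp
acceleration) and a single pooled static-phase regression, evaluated at
every protocol stimulus and clipped at zero.  The regression coefficients
are synthetic defaults chosen to be qualitatively consistent with published
mouse SAI displacement-response data (static rates of a few to ~12 Hz over
0.04-0.36 mm; ramp rates rising steeply with acceleration); they are
configuration values, not measurements.

Arbor sampling emulates the anatomical survey statistics: 3-5 spike
initiation zones, 13-20 transduction units and skew magnitudes of roughly
0.6-4.5, with units partitioned by seeded rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arbor import ArborConfiguration, skew_slope
from .protocol import StimulusProtocol

__all__ = [
    "PrototypicalRegression",
    "PrototypicalResponse",
    "ArborPopulationModel",
    "make_prototypical_response",
    "sample_arbor",
    "sample_arbors",
]


@dataclass(frozen=True)
class PrototypicalRegression:
    """Linear rate-vs-displacement regressions defining the fitting target.

    ``ramp`` maps ramp acceleration (mm/s^2) to (slope Hz/mm, intercept Hz);
    ``static`` is the single pooled static-phase regression.
    """

    ramp: dict = field(
        default_factory=lambda: {
            20.0: (150.0, 5.0),
            81.0: (300.0, 10.0),
            1143.0: (700.0, 20.0),
        }
    )
    static: tuple[float, float] = (30.0, 1.0)

    def ramp_rate(self, depth_mm: float, acceleration: float) -> float:
        slope, intercept = self.ramp[acceleration]
        return max(slope * depth_mm + intercept, 0.0)

    def static_rate(self, depth_mm: float) -> float:
        slope, intercept = self.static
        return max(slope * depth_mm + intercept, 0.0)

    def validate_against(self, protocol: StimulusProtocol) -> None:
        """Ramp targets must increase with acceleration at every depth."""
        accs = sorted(protocol.accelerations_mm_s2)
        for d in protocol.depths_mm:
            rates = [self.ramp_rate(d, a) for a in accs]
            if any(r1 > r2 for r1, r2 in zip(rates, rates[1:])):
                raise ValueError(
                    f"ramp regressions are not ordered by acceleration at {d} mm"
                )


@dataclass(frozen=True)
class PrototypicalResponse:
    """Target ramp/static rates for each of the indexed stimulations."""

    table: pd.DataFrame  # columns: index, depth_mm, acceleration_mm_s2, rep,
    #          rfr_target_hz, hfr_target_hz

    @property
    def hfr(self) -> np.ndarray:
        return self.table["hfr_target_hz"].to_numpy(float)

    @property
    def rfr(self) -> np.ndarray:
        return self.table["rfr_target_hz"].to_numpy(float)

    @property
    def usable(self) -> bool:
        """False when a whole phase is zero (fractional SS undefined)."""
        return bool(np.any(self.hfr > 0) and np.any(self.rfr > 0))

    def __len__(self) -> int:
        return len(self.table)


def make_prototypical_response(
    regression: PrototypicalRegression | None = None,
    protocol: StimulusProtocol | None = None,
) -> PrototypicalResponse:
    """Evaluate the regressions at every protocol stimulus (clipped at 0)."""
    regression = regression or PrototypicalRegression()
    protocol = protocol or StimulusProtocol()
    regression.validate_against(protocol)
    rows = []
    for i, d, a, rep in protocol.indexed():
        rows.append(
            {
                "index": i,
                "depth_mm": d,
                "acceleration_mm_s2": a,
                "rep": rep,
                "rfr_target_hz": regression.ramp_rate(d, a),
                "hfr_target_hz": regression.static_rate(d),
            }
        )
    return PrototypicalResponse(pd.DataFrame(rows))


@dataclass(frozen=True)
class ArborPopulationModel:
    """Sampling ranges for synthetic end-organ architectures."""

    zone_range: tuple[int, int] = (3, 5)
    unit_range: tuple[int, int] = (13, 20)
    skew_range: tuple[float, float] = (0.6, 4.5)
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.zone_range[0] < 2 or self.zone_range[1] < self.zone_range[0]:
            raise ValueError("zone range must be increasing with >= 2 zones")
        if self.unit_range[1] < self.unit_range[0] or self.unit_range[0] < self.zone_range[0]:
            raise ValueError("unit range must be increasing and feasible")
        if self.skew_range[1] < self.skew_range[0] or self.skew_range[0] < 0:
            raise ValueError("skew range must be non-negative and increasing")


def _random_partition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform composition of ``total`` into ``parts`` positive integers."""
    cuts = rng.choice(total - 1, size=parts - 1, replace=False) + 1
    cuts.sort()
    edges = np.concatenate(([0], cuts, [total]))
    return np.diff(edges)


def sample_arbor(
    model: ArborPopulationModel, rng: np.random.Generator
) -> ArborConfiguration:
    """Draw one arbor whose skew magnitude falls in the requested range."""
    lo_s, hi_s = model.skew_range
    for _ in range(model.max_attempts):
        z = int(rng.integers(model.zone_range[0], model.zone_range[1] + 1))
        u = int(rng.integers(model.unit_range[0], model.unit_range[1] + 1))
        if u < z:
            continue
        sizes = _random_partition(u, z, rng)
        config = ArborConfiguration(tuple(int(s) for s in sizes))
        if lo_s - 1e-9 <= config.skew <= hi_s + 1e-9:
            return config
    raise RuntimeError(
        f"no arbor satisfying skew in [{lo_s}, {hi_s}] found in "
        f"{model.max_attempts} attempts; the range combination is infeasible"
    )


def sample_arbors(
    model: ArborPopulationModel, n: int, rng: np.random.Generator
) -> list[ArborConfiguration]:
    return [sample_arbor(model, rng) for _ in range(n)]
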