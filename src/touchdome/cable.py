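"""Cable-theory checks justifying the point-neuron abstraction.

The network model collapses each heminode to a point and ignores neurite
and branch lengths.  That is defensible when (1) unmyelinated neurites are
electrotonically compact (path lengths far below the cable length
constant), (2) receptor-current spread to heminodes is fast relative to
sodium-channel inactivation, and (3) spike travel through myelinated
branches to the convergence node is fast relative to the refractory
period.  This module computes the closed-form quantities behind those
three criteria.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

__all__ = [
    "CableParameters",
    "length_constant_um",
    "conduction_delay_ms",
    "point_neuron_report",
    "PointNeuronReport",
]


@dataclass(frozen=True)
class CableParameters:
    """Passive cable and conduction constants.

    Rm = 15,000 Ohm*cm^2 and Ri = 125 Ohm*cm are published mammalian
    values; neurite diameter 1 um is estimated from whole-mount imaging.
    Conduction velocities: 0.7 m/s in unmyelinated neurites, 13 m/s in
    myelinated branches.  The sodium-inactivation timescale is a cited
    order of magnitude (default 1 ms), configurable.
    """

    rm_ohm_cm2: float = 15_000.0
    ri_ohm_cm: float = 125.0
    diameter_um: float = 1.0
    neurite_velocity_m_s: float = 0.7
    myelinated_velocity_m_s: float = 13.0
    refractory_ms: float = 1.0
    na_inactivation_ms: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def length_constant_um(params: CableParameters | None = None) -> float:
    """Cable length constant sqrt(Rm d / (4 Ri)), returned in um."""
    p = params or CableParameters()
    d_cm = p.diameter_um * 1e-4
    lam_cm = math.sqrt(p.rm_ohm_cm2 * d_cm / (4.0 * p.ri_ohm_cm))
    return lam_cm * 1e4


def conduction_delay_ms(path_length_um: float, velocity_m_s: float) -> float:
    """Travel time (ms) over a path at a given conduction velocity."""
    if path_length_um < 0 or velocity_m_s <= 0:
        raise ValueError("path length must be >= 0 and velocity > 0")
    return (path_length_um * 1e-6) / velocity_m_s * 1e3


@dataclass(frozen=True)
class PointNeuronReport:
    """Three-criterion verdict with margins (each margin is a safety ratio)."""

    length_constant_um: float
    compactness_margin: float  # length constant / mean neurite path
    neurite_delay_ms: float
    inactivation_margin: float  # Na inactivation / longest neurite delay
    branch_delay_ms: float
    refractory_margin: float  # refractory / longest branch delay
    criteria_pass: tuple[bool, bool, bool]
    margin_factor: float
    assumptions: str

    @property
    def all_pass(self) -> bool:
        return all(self.criteria_pass)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "length_constant_um": self.length_constant_um,
                    "compactness_margin": self.compactness_margin,
                    "neurite_delay_ms": self.neurite_delay_ms,
                    "inactivation_margin": self.inactivation_margin,
                    "branch_delay_ms": self.branch_delay_ms,
                    "refractory_margin": self.refractory_margin,
                    "criteria_pass": list(self.criteria_pass),
                    "all_pass": self.all_pass,
                    "margin_factor": self.margin_factor,
                    "assumptions": self.assumptions,
                },
                fh,
                indent=2,
            )

    def __str__(self) -> str:
        ok = ["PASS" if c else "FAIL" for c in self.criteria_pass]
        return (
            "Point-neuron abstraction report\n"
            f"  (1) electrotonic compactness: {ok[0]}  "
            f"(length constant {self.length_constant_um:.0f} um, "
            f"margin {self.compactness_margin:.1f}x)\n"
            f"  (2) receptor-current spread:  {ok[1]}  "
            f"(longest neurite delay {self.neurite_delay_ms:.3f} ms, "
            f"margin {self.inactivation_margin:.1f}x)\n"
            f"  (3) branch spike travel:      {ok[2]}  "
            f"(longest branch delay {self.branch_delay_ms:.3f} ms, "
            f"margin {self.refractory_margin:.1f}x)\n"
            f"  {self.assumptions}"
        )


def point_neuron_report(
    mean_neurite_path_um: float,
    max_neurite_path_um: float,
    max_branch_path_um: float,
    params: CableParameters | None = None,
    margin_factor: float = 10.0,
) -> PointNeuronReport:
    """Evaluate the three point-neuron criteria for a measured geometry.

    Each criterion passes when its safety ratio is at least
    ``margin_factor`` (default: one order of magnitude).
    """
    p = params or CableParameters()
    lam = length_constant_um(p)
    compact = lam / mean_neurite_path_um
    neurite_delay = conduction_delay_ms(max_neurite_path_um, p.neurite_velocity_m_s)
    inact = p.na_inactivation_ms / neurite_delay if neurite_delay > 0 else math.inf
    branch_delay = conduction_delay_ms(max_branch_path_um, p.myelinated_velocity_m_s)
    refr = p.refractory_ms / branch_delay if branch_delay > 0 else math.inf
    return PointNeuronReport(
        length_constant_um=lam,
        compactness_margin=compact,
        neurite_delay_ms=neurite_delay,
        inactivation_margin=inact,
        branch_delay_ms=branch_delay,
        refractory_margin=refr,
        criteria_pass=(
            compact >= margin_factor,
            inact >= margin_factor,
            refr >= margin_factor,
        ),
        margin_factor=margin_factor,
        assumptions=(
            f"assumed Na-inactivation timescale {p.na_inactivation_ms} ms, "
            f"refractory {p.refractory_ms} ms, pass margin {margin_factor}x"
        ),
    )
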