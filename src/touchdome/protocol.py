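"""Stimulation protocol: the indexed battery of ramp-and-hold stimuli.

The fitting and survey experiments use five displacement depths crossed
with three ramp accelerations, each repeated five times, giving 75 indexed
simulations (15 unique stimulations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mechanics import DisplacementStimulus, make_ramp_hold

__all__ = ["StimulusProtocol", "DEFAULT_DEPTHS_MM", "DEFAULT_ACCELERATIONS_MM_S2"]

DEFAULT_DEPTHS_MM = (0.04, 0.12, 0.20, 0.28, 0.36)
DEFAULT_ACCELERATIONS_MM_S2 = (20.0, 81.0, 1143.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Depths x accelerations x repetitions battery (default 5 x 3 x 5 = 75)."""

    depths_mm: tuple[float, ...] = DEFAULT_DEPTHS_MM
    accelerations_mm_s2: tuple[float, ...] = DEFAULT_ACCELERATIONS_MM_S2
    hold_s: float = 5.0
    repetitions: int = 5

    def __post_init__(self) -> None:
        if len(self.depths_mm) < 1 or len(self.accelerations_mm_s2) < 1:
            raise ValueError("protocol needs at least one depth and acceleration")
        if any(not (0.01 <= d <= 0.36) for d in self.depths_mm):
            raise ValueError("depths must lie within [0.01, 0.36] mm")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.hold_s <= 0:
            raise ValueError("hold must be positive")

    @property
    def n_unique(self) -> int:
        return len(self.depths_mm) * len(self.accelerations_mm_s2)

    @property
    def n_total(self) -> int:
        return self.n_unique * self.repetitions

    def unique_stimulations(self) -> list[tuple[float, float]]:
        """(depth_mm, acceleration) pairs, depth-major order."""
        return [(d, a) for d in self.depths_mm for a in self.accelerations_mm_s2]

    def stimulus(self, depth_mm: float, acceleration_mm_s2: float,
                 sampling_rate_hz: float = 1000.0) -> DisplacementStimulus:
        return make_ramp_hold(depth_mm, acceleration_mm_s2, self.hold_s,
                              sampling_rate_hz)

    def indexed(self) -> list[tuple[int, float, float, int]]:
        """All (index, depth, acceleration, repetition) rows, index 0-based."""
        rows = []
        i = 0
        for d, a in self.unique_stimulations():
            for rep in range(self.repetitions):
                rows.append((i, d, a, rep))
                i += 1
        return rows
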