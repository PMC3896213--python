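"""Spike initiation: an array of leaky integrate-and-fire zones.

Each spike initiation zone (heminode) is a leaky integrate-and-fire unit,

    R C du/dt = -u(t) + R I(t),

integrated with fourth-order Runge-Kutta on the current grid.  A spike at
any zone antidromically resets every zone and starts a shared 1-ms absolute
refractory period, so the zone with the highest intrinsic rate acts as the
driver for the afferent as a whole.  Conduction delays between zones are
zero (branch travel times are orders of magnitude below the refractory
period; see :mod:`touchdome.cable`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import lif_array_core
from .transduction import CurrentTrace, TransductionParameters

__all__ = [
    "LIFParameters",
    "SpikeTrain",
    "integrate_afferent",
    "baseline_subthreshold_check",
    "constant_drive_isi",
    "read_spike_train",
    "write_spike_train",
]


@dataclass(frozen=True)
class LIFParameters:
    """Fixed membrane constants of every spike initiation zone.

    tau = 5 ms, C = 1e-8 mF and a 30-mV threshold give R = tau/C = 5e8 Ohm,
    so mA-scale receptor currents map onto tens of mV.  ``substeps``
    subdivides each current sample for the RK4 integrator (spike times are
    reported on the integration grid; no sub-step interpolation).
    """

    tau_ms: float = 5.0
    capacitance_mF: float = 1e-8
    threshold_mV: float = 30.0
    refractory_ms: float = 1.0
    reset_mV: float = 0.0
    substeps: int = 1
    clamp_during_refractory: bool = True

    def __post_init__(self) -> None:
        if min(self.tau_ms, self.capacitance_mF, self.threshold_mV, self.refractory_ms) <= 0:
            raise ValueError("tau, C, threshold and refractory period must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")

    @property
    def resistance_ohm(self) -> float:
        """R = tau / C (ms / mF = Ohm)."""
        return self.tau_ms / self.capacitance_mF


@dataclass(frozen=True)
class SpikeTrain:
    """Merged afferent spike times (ms) with originating-zone labels."""

    times_ms: np.ndarray
    zones: np.ndarray
    n_zones: int = 1
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        z = np.asarray(self.zones, dtype=int)
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "zones", z)
        if t.shape != z.shape or t.ndim != 1:
            raise ValueError("times and zones must be matching 1-D arrays")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_ms.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times_ms)

    def count_in(self, t0_ms: float, t1_ms: float) -> int:
        """Spikes with t0 <= t < t1."""
        return int(np.sum((self.times_ms >= t0_ms) & (self.times_ms < t1_ms)))


def integrate_afferent(
    currents: list[CurrentTrace] | tuple[CurrentTrace, ...],
    params: LIFParameters | None = None,
) -> SpikeTrain:
    """Run the coupled LIF array on one current trace per zone."""
    params = params or LIFParameters()
    if len(currents) == 0:
        raise ValueError("at least one zone is required")
    t0 = currents[0].time_ms
    for c in currents[1:]:
        if c.time_ms.shape != t0.shape or not np.allclose(c.time_ms, t0):
            raise ValueError("all zone currents must share one time grid")
    arr = np.ascontiguousarray(np.stack([c.current_mA for c in currents]))
    return integrate_currents(arr, float(t0[1] - t0[0]), params)


def integrate_currents(
    currents: np.ndarray, dt_ms: float, params: LIFParameters
) -> SpikeTrain:
    """Kernel entry point on a raw (n_zones, n_samples) current array."""
    n_zones, n_samples = currents.shape
    cap = n_samples * params.substeps + 1
    out_t = np.empty(cap)
    out_z = np.empty(cap, dtype=np.int64)
    count = lif_array_core(
        currents,
        dt_ms,
        params.substeps,
        params.resistance_ohm,
        params.tau_ms,
        params.threshold_mV,
        params.reset_mV,
        params.refractory_ms,
        params.clamp_during_refractory,
        out_t,
        out_z,
    )
    return SpikeTrain(
        out_t[:count].copy(),
        out_z[:count].copy(),
        n_zones=n_zones,
        duration_ms=n_samples * dt_ms,
    )


def constant_drive_isi(current_mA: float, params: LIFParameters | None = None) -> float:
    """Closed-form steady ISI (ms) of one zone under constant suprathreshold drive.

    ISI = refractory + tau * ln(RI / (RI - vbar)); infinite when RI <= vbar.
    """
    params = params or LIFParameters()
    ri = params.resistance_ohm * current_mA
    if ri <= params.threshold_mV:
        return math.inf
    return params.refractory_ms + params.tau_ms * math.log(ri / (ri - params.threshold_mV))


def baseline_subthreshold_check(
    lif: LIFParameters, trans: TransductionParameters
) -> dict:
    """Sanity gate: the offset current alone must not drive firing.

    Returns the boolean verdict and the voltage margin vbar - R*beta (mV).
    """
    drive = lif.resistance_ohm * trans.beta_mA
    margin = lif.threshold_mV - drive
    return {
        "passes": bool(margin > 0),
        "offset_drive_mV": drive,
        "threshold_mV": lif.threshold_mV,
        "margin_mV": margin,
    }


def write_spike_train(train: SpikeTrain, path) -> None:
    """Write a spike train as CSV (time_ms, zone)."""
    pd.DataFrame({"time_ms": train.times_ms, "zone": train.zones}).to_csv(
        path, index=False
    )


def read_spike_train(path, refractory_ms: float | None = None) -> SpikeTrain:
    """Read a spike-train CSV; validates sortedness and refractory spacing."""
    df = pd.read_csv(path)
    missing = {"time_ms", "zone"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required columns: {sorted(missing)}")
    train = SpikeTrain(df["time_ms"].to_numpy(float), df["zone"].to_numpy(int),
                       n_zones=int(df["zone"].max()) + 1 if len(df) else 1)
    if refractory_ms is not None and len(train) > 1:
        if np.any(np.diff(train.times_ms) < refractory_ms - 1e-9):
            raise ValueError("spike train violates the refractory period")
    return train
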