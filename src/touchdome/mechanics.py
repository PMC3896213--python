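"""Skin mechanics: ramp-and-hold indentation to strain energy density (SED).

The skin stage is a reduced-order surrogate for a full finite-element model
of indented skin.  Commanded probe depth is partitioned by uniaxial force
balance between an incompressible Mooney-Rivlin tissue column (epidermis +
dermis + subcutis) and a linear-elastic substrate column underneath.  The
instantaneous strain energy density of the tissue column is then passed
through a quasi-linear viscoelastic (QLV) hereditary integral with a
two-branch Prony reduced relaxation function, yielding the SED time series
that drives the mechanotransduction stage.  The downstream model consumes a
single spatially uniform SED signal (the probe is ~30x wider than a touch
dome), so the surrogate deliberately carries no spatial field; externally
computed FEM SED traces can be imported via :func:`read_sed_trace`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "DisplacementStimulus",
    "SkinParameters",
    "SEDTrace",
    "StimulusError",
    "MechanicsError",
    "SEDFormatError",
    "make_ramp_hold",
    "instantaneous_sed",
    "qlv_convolve",
    "sed_trace",
    "read_sed_trace",
    "write_sed_trace",
]


class StimulusError(ValueError):
    """Invalid stimulus definition."""


class MechanicsError(RuntimeError):
    """Force-balance solver failure in the skin surrogate."""


class SEDFormatError(ValueError):
    """Malformed SED trace file."""


@dataclass(frozen=True)
class DisplacementStimulus:
    """Ramp-and-hold probe trajectory.

    Parameters
    ----------
    depth_mm : float
        Commanded indentation depth in mm, in [0, 0.5].
    ramp_acceleration_mm_s2 : float
        Constant probe acceleration during the ramp, mm/s^2.
    hold_s : float
        Duration of the hold at commanded depth, s.
    sampling_rate_hz : float
        Grid rate for the trajectory and everything downstream (default
        1000 Hz, i.e. a 1-ms grid).
    """

    depth_mm: float
    ramp_acceleration_mm_s2: float
    hold_s: float
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth_mm <= 0.5):
            raise StimulusError(f"depth must lie in [0, 0.5] mm, got {self.depth_mm}")
        if self.ramp_acceleration_mm_s2 <= 0:
            raise StimulusError("ramp acceleration must be positive")
        if self.hold_s <= 0:
            raise StimulusError("hold duration must be positive")
        if self.sampling_rate_hz <= 0:
            raise StimulusError("sampling rate must be positive")

    @property
    def ramp_duration_s(self) -> float:
        """Time to reach commanded depth under constant acceleration."""
        return math.sqrt(2.0 * self.depth_mm / self.ramp_acceleration_mm_s2)

    @property
    def duration_s(self) -> float:
        return self.ramp_duration_s + self.hold_s

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def trajectory(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (time_ms, displacement_mm) on the uniform grid.

        d(t) = a t^2 / 2 during the ramp, then the commanded depth; the
        final sample equals the commanded depth exactly.
        """
        n = int(round(self.duration_s * self.sampling_rate_hz))
        t_ms = np.arange(n + 1) * self.dt_ms
        t_s = t_ms / 1000.0
        d = 0.5 * self.ramp_acceleration_mm_s2 * t_s**2
        d = np.minimum(d, self.depth_mm)
        d[t_s >= self.ramp_duration_s] = self.depth_mm
        d[-1] = self.depth_mm
        return t_ms, d


def make_ramp_hold(
    depth_mm: float,
    acceleration_mm_s2: float,
    hold_s: float,
    sampling_rate_hz: float = 1000.0,
) -> DisplacementStimulus:
    """Construct a constant-acceleration ramp-and-hold stimulus."""
    return DisplacementStimulus(depth_mm, acceleration_mm_s2, hold_s, sampling_rate_hz)


@dataclass(frozen=True)
class SkinParameters:
    """Material constants of the two-column skin surrogate.

    Mooney-Rivlin constants ``c10_pa``/``c01_pa`` and the Prony pairs
    parameterize the tissue column; ``substrate_modulus_pa`` the linear
    elastic substrate in series underneath.  The tissue stack is 342 um
    (17 um epidermis + 224 um dermis + 101 um subcutis).  Probe friction
    and diameter are recorded for provenance but unused by the uniaxial
    surrogate.
    """

    c10_pa: float = 14847.0
    c01_pa: float = 41410.0
    substrate_modulus_pa: float = 906098.0
    prony_g1: float = 0.391
    prony_tau1_s: float = 0.25
    prony_g2: float = 0.226
    prony_tau2_s: float = 9.371
    tissue_thickness_um: float = 342.0
    substrate_thickness_um: float = 2000.0
    friction_coefficient: float = 0.3
    probe_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.prony_g1 < 0 or self.prony_g2 < 0 or self.prony_g1 + self.prony_g2 >= 1:
            raise ValueError("Prony weights must be non-negative with g1 + g2 < 1")
        for name in ("c10_pa", "c01_pa", "substrate_modulus_pa",
                     "tissue_thickness_um", "substrate_thickness_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.prony_tau2_s > self.prony_tau1_s > 0):
            raise ValueError("Prony time constants must satisfy tau2 > tau1 > 0")

    @property
    def g_inf(self) -> float:
        """Long-time residual of the reduced relaxation function."""
        return 1.0 - self.prony_g1 - self.prony_g2


@dataclass(frozen=True)
class SEDTrace:
    """Strain energy density vs time at the end organ (one value per sample).

    SED is assumed spatially uniform across all Merkel cell-neurite
    complexes, so a single trace serves every transduction cluster.
    """

    time_ms: np.ndarray
    sed_pa: np.ndarray
    stimulus: DisplacementStimulus | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        s = np.asarray(self.sed_pa, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "sed_pa", s)
        if t.ndim != 1 or t.shape != s.shape or t.size < 2:
            raise SEDFormatError("time and SED must be 1-D arrays of equal length >= 2")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise SEDFormatError("time grid must be uniform")
        neg = np.flatnonzero(s < 0)
        if neg.size:
            raise SEDFormatError(f"negative SED at sample {neg[0]} (t={t[neg[0]]} ms)")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def __len__(self) -> int:
        return self.time_ms.size


def _mooney_rivlin_w(lam: float, p: SkinParameters) -> float:
    """Strain energy density of an incompressible MR column at stretch lam."""
    i1 = lam**2 + 2.0 / lam
    i2 = 1.0 / lam**2 + 2.0 * lam
    return p.c10_pa * (i1 - 3.0) + p.c01_pa * (i2 - 3.0)


def _mr_nominal_stress_mag(lam: float, p: SkinParameters) -> float:
    # |P| for uniaxial incompressible Mooney-Rivlin in compression (lam < 1)
    return 2.0 * (1.0 / lam**2 - lam) * (p.c10_pa + p.c01_pa / lam)


def instantaneous_sed(depth_mm: float, params: SkinParameters) -> float:
    """Elastic SED (Pa) of the tissue column at a given probe depth.

    Partitions the commanded depth between tissue and substrate by matching
    the tissue's uniaxial Mooney-Rivlin nominal stress against the linear
    substrate stress.  W(0) = 0 and W is strictly increasing in depth.
    """
    if depth_mm < 0:
        raise MechanicsError(f"negative depth {depth_mm}")
    if depth_mm == 0:
        return 0.0
    d_um = depth_mm * 1000.0
    h_t = params.tissue_thickness_um
    h_s = params.substrate_thickness_um
    e_sub = params.substrate_modulus_pa

    def balance(d_t: float) -> float:
        lam = 1.0 - d_t / h_t
        return _mr_nominal_stress_mag(lam, params) - e_sub * (d_um - d_t) / h_s

    upper = min(d_um, 0.995 * h_t)
    try:
        if balance(upper) <= 0.0:
            # substrate effectively rigid relative to the tissue at this depth
            d_t = upper
        else:
            d_t = brentq(balance, 0.0, upper, xtol=1e-10, rtol=1e-12)
    except ValueError as exc:  # pragma: no cover - defensive
        raise MechanicsError(
            f"force balance failed at depth {depth_mm} mm "
            f"(bracket [0, {upper:.3f}] um): {exc}"
        ) from exc
    lam = 1.0 - d_t / h_t
    return _mooney_rivlin_w(lam, params)


def qlv_convolve(
    time_ms: np.ndarray,
    w_pa: np.ndarray,
    params: SkinParameters,
    stimulus: DisplacementStimulus | None = None,
) -> SEDTrace:
    """Quasi-linear viscoelastic SED from the elastic SED history.

    eps(t) = int_0^t G(t-s) dW/ds ds with the reduced relaxation function
    G(t) = g_inf + g1 exp(-t/tau1) + g2 exp(-t/tau2).  Each Prony branch is
    advanced with the recursive exponential update (dW/dt taken constant
    over a step), so the cost is linear in the number of samples.
    """
    t = np.asarray(time_ms, dtype=float)
    w = np.asarray(w_pa, dtype=float)
    if t.shape != w.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("time and W must be matching 1-D arrays")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("qlv_convolve requires a uniform time grid")
    dt_ms = float(dt[0])

    eps = np.empty_like(w)
    eps[0] = w[0]
    dw = np.diff(w)
    acc = params.g_inf * w[1:]
    for g, tau_s in ((params.prony_g1, params.prony_tau1_s),
                     (params.prony_g2, params.prony_tau2_s)):
        if g == 0.0:
            continue
        tau_ms = tau_s * 1000.0
        a = math.exp(-dt_ms / tau_ms)
        b = g * (tau_ms / dt_ms) * (1.0 - a)
        h = np.empty_like(dw)
        # h[n] = a h[n-1] + b dw[n]  -- scan, seeded by the initial value w[0]
        prev = g * w[0]
        for n in range(dw.size):
            prev = a * prev + b * dw[n]
            h[n] = prev
        acc = acc + h
    eps[1:] = acc
    # hereditary integral of a non-negative, non-decreasing-then-constant W
    # is non-negative; clip round-off only
    np.clip(eps, 0.0, None, out=eps)
    return SEDTrace(t, eps, stimulus)


def sed_trace(stimulus: DisplacementStimulus, params: SkinParameters | None = None) -> SEDTrace:
    """Full skin stage: stimulus -> elastic SED -> QLV SED trace."""
    params = params or SkinParameters()
    t_ms, d_mm = stimulus.trajectory()
    # solve the force balance once per distinct depth (the hold repeats one)
    w = np.empty_like(d_mm)
    cache: dict[float, float] = {}
    for i, d in enumerate(d_mm):
        if d not in cache:
            cache[d] = instantaneous_sed(float(d), params)
        w[i] = cache[d]
    return qlv_convolve(t_ms, w, params, stimulus)


def write_sed_trace(trace: SEDTrace, path) -> None:
    """Write a SED trace as CSV with columns time_ms, sed_pa."""
    pd.DataFrame({"time_ms": trace.time_ms, "sed_pa": trace.sed_pa}).to_csv(
        path, index=False
    )


def read_sed_trace(path) -> SEDTrace:
    """Read and validate a SED trace CSV (columns time_ms, sed_pa)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SEDFormatError(f"unreadable SED trace {path}: {exc}") from exc
    missing = {"time_ms", "sed_pa"} - set(df.columns)
    if missing:
        raise SEDFormatError(f"{path} lacks required columns: {sorted(missing)}")
    if len(df) < 2:
        raise SEDFormatError(f"{path} holds fewer than 2 samples")
    return SEDTrace(df["time_ms"].to_numpy(float), df["sed_pa"].to_numpy(float))
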