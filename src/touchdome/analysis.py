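"""Response statistics: firing rates, displacement-response fits, ISIs.

Ramp-phase rate is the spike count during the ramp divided by ramp
duration; static rate is the count during the final 2.5 s of the hold
divided by 2.5 s (excluding the rapid-adaptation period that follows the
ramp).  Displacement-response relations are fitted with a single
exponential rate(D) = Y0 * exp(kappa * D), where kappa (mm^-1) measures
mechanical sensitivity and Y0 (Hz) the threshold firing rate; competing
fits are compared with extra-sum-of-squares F tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .mechanics import DisplacementStimulus
from .spikes import SpikeTrain

__all__ = [
    "DisplacementResponseFit",
    "ramp_rate",
    "static_rate",
    "static_window_ms",
    "static_isis",
    "fit_displacement_response",
    "compare_exponential_fits",
    "percent_fr_change",
    "percent_fr_change_signed",
    "normalized_isi",
    "first_spike_latency",
]

STATIC_WINDOW_S = 2.5


def ramp_rate(train: SpikeTrain, stim: DisplacementStimulus) -> float:
    """Spikes in [0, t_ramp) divided by the ramp duration, in Hz."""
    t_ramp_ms = stim.ramp_duration_s * 1000.0
    if t_ramp_ms <= 0:
        raise ValueError("ramp rate is undefined for a zero-duration ramp")
    return train.count_in(0.0, t_ramp_ms) / stim.ramp_duration_s


def static_window_ms(stim: DisplacementStimulus) -> tuple[float, float]:
    """[start, end) of the static-rate window: the final 2.5 s of the hold."""
    if stim.hold_s < STATIC_WINDOW_S:
        raise ValueError(
            f"hold of {stim.hold_s} s is shorter than the {STATIC_WINDOW_S}-s "
            "static analysis window"
        )
    end_ms = stim.duration_s * 1000.0
    return end_ms - STATIC_WINDOW_S * 1000.0, end_ms


def static_rate(train: SpikeTrain, stim: DisplacementStimulus) -> float:
    """Firing rate (Hz) during the final 2.5 s of the hold."""
    t0, t1 = static_window_ms(stim)
    return train.count_in(t0, t1 + 1e-9) / STATIC_WINDOW_S


def static_isis(train: SpikeTrain, stim: DisplacementStimulus) -> np.ndarray:
    """Interspike intervals (ms) between spikes inside the static window."""
    t0, t1 = static_window_ms(stim)
    mask = (train.times_ms >= t0) & (train.times_ms <= t1 + 1e-9)
    return np.diff(train.times_ms[mask])


def first_spike_latency(train: SpikeTrain) -> float:
    """Time of the first spike after stimulus onset (ms); NaN if none."""
    return float(train.times_ms[0]) if len(train) else math.nan


@dataclass(frozen=True)
class DisplacementResponseFit:
    """Single-exponential displacement-response fit rate = Y0 exp(kappa D)."""

    y0_hz: float
    kappa_per_mm: float
    r_squared: float
    ssr: float
    n: int

    def predict(self, depths_mm: np.ndarray) -> np.ndarray:
        return self.y0_hz * np.exp(self.kappa_per_mm * np.asarray(depths_mm, float))


def _exp_model(d, y0, kappa):
    return y0 * np.exp(kappa * d)


def _exp_p0(depths: np.ndarray, rates: np.ndarray) -> tuple[float, float]:
    pos = rates > 0
    if pos.sum() >= 2 and np.ptp(depths[pos]) > 0:
        k, logy0 = np.polyfit(depths[pos], np.log(rates[pos]), 1)
        return float(np.exp(logy0)), float(k)
    return max(float(rates.mean()), 1e-3), 1.0


def fit_displacement_response(
    depths_mm, rates_hz
) -> DisplacementResponseFit:
    """Nonlinear least squares for (Y0, kappa); reports R^2 about the mean."""
    d = np.asarray(depths_mm, dtype=float)
    r = np.asarray(rates_hz, dtype=float)
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct depths for the exponential fit")
    p0 = _exp_p0(d, r)
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, d, r, p0=p0, bounds=([0.0, -np.inf], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential fit failed to converge (initial guess {p0})"
        ) from exc
    pred = _exp_model(d, *popt)
    ssr = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ssr / ss_tot
    return DisplacementResponseFit(float(popt[0]), float(popt[1]), r2, ssr, d.size)


def _joint_shared_ssr(dA, rA, dB, rB, shared: str) -> float:
    """SSR of the nested model sharing kappa or Y0 between datasets."""

    def resid(theta):
        if shared == "kappa":
            y0a, y0b, kappa = theta
            ka = kb = kappa
        else:  # shared y0
            y0a, ka, kb = theta[0], theta[1], theta[2]
            y0b = y0a
        return np.concatenate([
            rA - _exp_model(dA, y0a, ka),
            rB - _exp_model(dB, y0b, kb),
        ])

    p0a = _exp_p0(dA, rA)
    p0b = _exp_p0(dB, rB)
    if shared == "kappa":
        x0 = [p0a[0], p0b[0], 0.5 * (p0a[1] + p0b[1])]
    else:
        x0 = [0.5 * (p0a[0] + p0b[0]), p0a[1], p0b[1]]
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
    return float(np.sum(sol.fun**2))


def compare_exponential_fits(
    depths_a, rates_a, depths_b, rates_b, parameter: str = "kappa"
) -> tuple[float, float]:
    """Extra-sum-of-squares F test for a shared kappa (or Y0) across datasets.

    Fits the full model (separate Y0 and kappa per dataset, 4 parameters)
    and the nested model sharing the named parameter (3 parameters);
    returns (F, p).  Identical datasets give F ~ 0 and p ~ 1.
    """
    if parameter not in ("kappa", "y0"):
        raise ValueError("parameter must be 'kappa' or 'y0'")
    dA, rA = np.asarray(depths_a, float), np.asarray(rates_a, float)
    dB, rB = np.asarray(depths_b, float), np.asarray(rates_b, float)
    fitA = fit_displacement_response(dA, rA)
    fitB = fit_displacement_response(dB, rB)
    ssr_full = fitA.ssr + fitB.ssr
    df_full = dA.size + dB.size - 4
    if df_full < 1:
        raise ValueError("too few points for the extra-sum-of-squares test")
    ssr_red = _joint_shared_ssr(dA, rA, dB, rB, parameter)
    num = max(ssr_red - ssr_full, 0.0)
    if ssr_full <= 1e-300:
        return (0.0, 1.0) if num <= 1e-300 else (math.inf, 0.0)
    f_stat = (num / 1.0) / (ssr_full / df_full)
    p = float(stats.f.sf(f_stat, 1, df_full))
    return float(f_stat), p


def percent_fr_change(rates_a, rates_b) -> float:
    """Unsigned percent change in summed firing rate between configurations.

    (sum_a - sum_b) / sum_b * 100 with the larger-sum configuration in the
    numerator, so the value is always >= 0 and symmetric in argument order.
    """
    a = float(np.sum(rates_a))
    b = float(np.sum(rates_b))
    hi, lo = max(a, b), min(a, b)
    if lo == 0.0:
        raise ZeroDivisionError("summed firing rate of the reference is zero")
    return (hi - lo) / lo * 100.0


def percent_fr_change_signed(rates_new, rates_ref) -> float:
    """Signed variant: positive when the first configuration fires more."""
    a = float(np.sum(rates_new))
    b = float(np.sum(rates_ref))
    if min(a, b) == 0.0:
        raise ZeroDivisionError("summed firing rate of the reference is zero")
    sign = 1.0 if a >= b else -1.0
    return sign * percent_fr_change(rates_new, rates_ref)


def normalized_isi(isi_groups) -> np.ndarray:
    """Pool ISIs normalized by their per-stimulus mean.

    ``isi_groups`` is an iterable of ISI arrays, one per stimulus (pooled
    over repetitions).  The pooled sample has mean 1 by construction.
    """
    pooled = []
    for isis in isi_groups:
        isis = np.asarray(isis, dtype=float)
        if isis.size == 0:
            continue
        pooled.append(isis / isis.mean())
    if not pooled:
        raise ValueError("no interspike intervals to normalize")
    return np.concatenate(pooled)
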