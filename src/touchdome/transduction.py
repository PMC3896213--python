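"""Mechanotransduction: SED to noisy receptor current per cluster.

A cluster of M Merkel cell-neurite complexes converging on one spike
initiation zone produces the current

    I(t) = beta + M * (alpha * eps(t) + lambda * d eps/dt) + omega(t)

where eps is SED (Pa), d eps/dt its per-sample backward difference (Pa/ms),
beta an offset (mA), alpha a static gain (mA/Pa) and lambda a dynamic gain
(mA*ms/Pa).  omega is a 7-point moving average of zero-mean Gaussian
deviates drawn with the Box-Muller transform; it is attached per cluster
and is not scaled by M.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .mechanics import SEDTrace

__all__ = [
    "TransductionParameters",
    "NoiseConfig",
    "CurrentTrace",
    "transduce",
    "noise_series",
    "box_muller",
]

# Default noise amplitude (mA) of the pre-averaging Gaussian deviates.
# Calibrated once so the static-phase normalized-ISI coefficient of
# variation of the fitted four-zone reference model falls in 0.3-0.8
# (see docs/methods.md); the moving average reduces variance by 1/7.
DEFAULT_SIGMA_MA = 8e-9


@dataclass(frozen=True)
class TransductionParameters:
    """The three free parameters of the cluster transduction function."""

    beta_mA: float
    alpha_mA_per_Pa: float
    lambda_mA_ms_per_Pa: float

    def __post_init__(self) -> None:
        for name in ("beta_mA", "alpha_mA_per_Pa", "lambda_mA_ms_per_Pa"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.alpha_mA_per_Pa < 0 or self.lambda_mA_ms_per_Pa < 0:
            raise ValueError("alpha and lambda must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta_mA": self.beta_mA,
                    "alpha_mA_per_Pa": self.alpha_mA_per_Pa,
                    "lambda_mA_ms_per_Pa": self.lambda_mA_ms_per_Pa,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "TransductionParameters":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["beta_mA"], d["alpha_mA_per_Pa"], d["lambda_mA_ms_per_Pa"])


# Printed fitted parameter sets for the four prototypical arbors and their
# average, obtained against the original finite-element skin model.  Kept
# for provenance and for reduced-order "refit" comparisons.
PRINTED_PARAMETERS: dict[str, TransductionParameters] = {
    "{8,5,3,1}": TransductionParameters(5.643e-8, 2.539e-14, 5.833e-11),
    "{7,6,4,2,1}": TransductionParameters(5.648e-8, 2.386e-14, 4.994e-11),
    "{6,4,3}": TransductionParameters(5.669e-8, 2.612e-14, 6.211e-11),
    "{5,4,3,1}": TransductionParameters(5.672e-8, 2.641e-14, 6.491e-11),
    "average": TransductionParameters(5.658e-8, 2.545e-14, 5.882e-11),
}


@dataclass(frozen=True)
class NoiseConfig:
    """Configuration of the receptor-current noise term omega(t).

    ``sigma_mA`` is the standard deviation of the underlying Gaussian
    deviates *before* the moving average (which divides the interior-sample
    variance by ``window``).  ``shared_across_clusters`` switches from one
    independent series per cluster (default) to a single series reused by
    every cluster of an afferent.
    """

    sigma_mA: float = DEFAULT_SIGMA_MA
    window: int = 7
    enabled: bool = True
    shared_across_clusters: bool = False

    def __post_init__(self) -> None:
        if self.sigma_mA < 0:
            raise ValueError("sigma must be non-negative")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")

    def disabled(self) -> "NoiseConfig":
        return replace(self, enabled=False)


@dataclass(frozen=True)
class CurrentTrace:
    """Receptor current (mA) on the SED time grid for one cluster of size M."""

    time_ms: np.ndarray
    current_mA: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        c = np.asarray(self.current_mA, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "current_mA", c)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time and current must be matching 1-D arrays")
        if self.n_units < 1 or self.n_units != int(self.n_units):
            raise ValueError(f"cluster size must be a positive integer, got {self.n_units}")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


def box_muller(n: int, rng: np.random.Generator) -> np.ndarray:
    """n standard-normal deviates via the Box-Muller transform."""
    m = (n + 1) // 2
    # uniforms on (0, 1]: avoids log(0)
    u1 = 1.0 - rng.random(m)
    u2 = rng.random(m)
    r = np.sqrt(-2.0 * np.log(u1))
    z = np.empty(2 * m)
    z[0::2] = r * np.cos(2.0 * np.pi * u2)
    z[1::2] = r * np.sin(2.0 * np.pi * u2)
    return z[:n]


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a shrinking window at both edges."""
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def noise_series(n: int, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """One noise series omega(t): smoothed Box-Muller Gaussian deviates (mA)."""
    if n < 1:
        raise ValueError("need at least one sample")
    if not noise.enabled or noise.sigma_mA == 0.0:
        return np.zeros(n)
    z = noise.sigma_mA * box_muller(n, rng)
    if noise.window == 1:
        return z
    return moving_average(z, noise.window)


def transduce(
    sed: SEDTrace,
    n_units: int,
    params: TransductionParameters,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CurrentTrace:
    """Receptor current of a cluster of ``n_units`` complexes driven by SED."""
    if n_units < 1:
        raise ValueError(f"cluster must contain at least one unit, got {n_units}")
    noise = noise or NoiseConfig(enabled=False)
    eps = sed.sed_pa
    deps = np.empty_like(eps)
    deps[0] = 0.0
    deps[1:] = np.diff(eps) / sed.dt_ms  # Pa/ms -> lambda needs no conversion
    current = params.beta_mA + n_units * (
        params.alpha_mA_per_Pa * eps + params.lambda_mA_ms_per_Pa * deps
    )
    if noise.enabled and noise.sigma_mA > 0.0:
        if rng is None:
            raise ValueError("noise is enabled but no random generator was supplied")
        current = current + noise_series(len(sed), noise, rng)
    return CurrentTrace(sed.time_ms, current, n_units)
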