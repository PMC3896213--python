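"""Numerical kernel for the leaky integrate-and-fire array.

The inner loop is compiled with numba when available; the pure-Python
fallback is identical (and is what the tests exercise if numba is absent).
"""

from __future__ import annotations

import numpy as np

__all__ = ["lif_array_core"]


def _lif_array_core(
    currents: np.ndarray,  # (n_zones, n_samples) mA, constant over each sample
    dt_ms: float,
    substeps: int,
    r_ohm: float,
    tau_ms: float,
    threshold_mv: float,
    reset_mv: float,
    refractory_ms: float,
    clamp_refractory: bool,
    out_times: np.ndarray,
    out_zones: np.ndarray,
) -> int:
    """Integrate the coupled LIF array; returns the number of spikes.

    Each zone obeys tau du/dt = -u + R I(t) (RK4, I held constant over a
    sample).  When any zone reaches threshold at the end of a substep, a
    spike is recorded at that time, every zone is reset (antidromic
    invasion) and a shared absolute refractory period begins.  Simultaneous
    crossings are won by the largest overshoot, ties by the lowest zone id.
    """
    n_zones, n_samples = currents.shape
    h = dt_ms / substeps
    u = np.zeros(n_zones)
    ref_until = -1.0e30
    count = 0
    eps = 1e-9
    for n in range(n_samples):
        for s in range(substeps):
            t_end = n * dt_ms + (s + 1) * h
            in_ref = t_end <= ref_until + eps
            if in_ref and clamp_refractory:
                continue
            for z in range(n_zones):
                drive = r_ohm * currents[z, n]
                # RK4 on tau u' = -u + drive with constant drive
                k1 = (-u[z] + drive) / tau_ms
                k2 = (-(u[z] + 0.5 * h * k1) + drive) / tau_ms
                k3 = (-(u[z] + 0.5 * h * k2) + drive) / tau_ms
                k4 = (-(u[z] + h * k3) + drive) / tau_ms
                u[z] = u[z] + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if in_ref:
                continue  # integrating through refractoriness, threshold ignored
            best = -1
            best_over = -1.0
            for z in range(n_zones):
                if u[z] >= threshold_mv:
                    over = u[z] - threshold_mv
                    if over > best_over + 0.0:
                        best_over = over
                        best = z
            if best >= 0:
                out_times[count] = t_end
                out_zones[count] = best
                count += 1
                for z in range(n_zones):
                    u[z] = reset_mv
                ref_until = t_end + refractory_ms
    return count


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    lif_array_core = njit(cache=False)(_lif_array_core)
except Exception:  # pragma: no cover
    lif_array_core = _lif_array_core
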