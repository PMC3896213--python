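"""Gradient-free transduction-parameter fitting (LHS response-surface search).

The three free parameters (beta, alpha, lambda) are selected by maximizing
the combined fractional sum of squares between simulated and target
ramp/static firing rates over the 75 indexed stimulations,

    fss_combined = (1 - sum (hfr_bar - hfr)^2 / sum hfr_bar^2)
                 + (1 - sum (rfr_bar - rfr)^2 / sum rfr_bar^2),

which equals 2 for a perfect match.  The search starts from a 50-point
Latin-hypercube domain design over the full bounds, then iterates 20-point
Latin-hypercube designs recentered on the incumbent best with the search
region halving each iteration.  alpha and lambda are searched in log10
space (they span decades); beta linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .transduction import TransductionParameters

__all__ = [
    "FitResult",
    "combined_fss",
    "lhs_design",
    "rsm_fit",
    "DEFAULT_BOUNDS",
]

# (low, high, log-scale?) per parameter: beta (mA), alpha (mA/Pa),
# lambda (mA*ms/Pa).  beta is capped below threshold/R so the offset alone
# can never drive firing.
DEFAULT_BOUNDS = (
    (1e-8, 6e-8, False),
    (1e-16, 1e-12, True),
    (1e-13, 1e-9, True),
)


def combined_fss(
    hfr_sim, rfr_sim, hfr_target, rfr_target
) -> tuple[float, float, float]:
    """Combined fractional sum of squares; returns (combined, static, ramp)."""
    hs = np.asarray(hfr_sim, float)
    rs = np.asarray(rfr_sim, float)
    ht = np.asarray(hfr_target, float)
    rt = np.asarray(rfr_target, float)
    if hs.shape != ht.shape or rs.shape != rt.shape:
        raise ValueError("simulated and target rate vectors must align")
    h_norm = float(np.sum(ht**2))
    r_norm = float(np.sum(rt**2))
    if h_norm == 0.0 or r_norm == 0.0:
        raise ZeroDivisionError(
            "a target phase is identically zero; the fractional sum of "
            "squares is undefined"
        )
    h_fss = 1.0 - float(np.sum((ht - hs) ** 2)) / h_norm
    r_fss = 1.0 - float(np.sum((rt - rs) ** 2)) / r_norm
    return h_fss + r_fss, h_fss, r_fss


def lhs_design(
    n_points: int,
    bounds: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Latin-hypercube design: one point per equal-probability stratum per dim."""
    if n_points < 2:
        raise ValueError("a design needs at least 2 points")
    lows = np.array([b[0] for b in bounds], dtype=float)
    highs = np.array([b[1] for b in bounds], dtype=float)
    if np.any(highs <= lows) or not np.all(np.isfinite(lows) & np.isfinite(highs)):
        raise ValueError("bounds must be finite with low < high")
    sampler = qmc.LatinHypercube(d=len(bounds), seed=rng)
    unit = sampler.random(n_points)
    return qmc.scale(unit, lows, highs)


@dataclass(frozen=True)
class FitResult:
    """Outcome of the response-surface search."""

    params: TransductionParameters
    score: float
    static_fss: float
    ramp_fss: float
    n_evaluations: int
    trace: tuple[float, ...]
    on_boundary: bool
    seed: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FitResult(score={self.score:.4f}, static_fss={self.static_fss:.4f}, "
            f"ramp_fss={self.ramp_fss:.4f}, beta={self.params.beta_mA:.4g}, "
            f"alpha={self.params.alpha_mA_per_Pa:.4g}, "
            f"lambda={self.params.lambda_mA_ms_per_Pa:.4g})"
        )


def _to_search_space(bounds):
    out = []
    for lo, hi, is_log in bounds:
        if is_log:
            out.append((np.log10(lo), np.log10(hi)))
        else:
            out.append((lo, hi))
    return out


def _from_search(x, bounds):
    theta = []
    for xi, (_, _, is_log) in zip(x, bounds):
        theta.append(10.0**xi if is_log else xi)
    return np.array(theta)


def _to_search_point(theta, bounds):
    return np.array(
        [np.log10(t) if is_log else t for t, (_, _, is_log) in zip(theta, bounds)]
    )


def rsm_fit(
    runner: Callable[[TransductionParameters], tuple[np.ndarray, np.ndarray]],
    hfr_target: np.ndarray,
    rfr_target: np.ndarray,
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
    n_domain: int = 50,
    n_design: int = 20,
    max_iterations: int = 20,
    tol: float = 1e-4,
    shrink: float = 0.65,
    patience: int = 3,
    n_starts: int = 5,
    domain_points: np.ndarray | None = None,
    initial_half_width: np.ndarray | None = None,
) -> FitResult:
    """Fit (beta, alpha, lambda) by iterated Latin-hypercube designs.

    ``runner`` maps a parameter set to (hfr, rfr) vectors over the 75
    indexed stimulations (repetitions already simulated and aligned with
    the target).  The objective surface is multi-modal (alpha and lambda
    span decades), so the ``n_starts`` best domain-search points each seed
    an independent shrinking-design track; the global incumbent is never
    discarded, so the score trace is non-decreasing.
    """
    rng = np.random.default_rng(seed)
    space = _to_search_space(bounds)
    lows = np.array([s[0] for s in space])
    highs = np.array([s[1] for s in space])

    def evaluate(x):
        theta = _from_search(x, bounds)
        params = TransductionParameters(*theta)
        hfr, rfr = runner(params)
        return combined_fss(hfr, rfr, hfr_target, rfr_target)

    n_evals = 0
    trace: list[float] = []

    if domain_points is not None:
        domain = np.array(
            [_to_search_point(theta, bounds) for theta in np.asarray(domain_points)]
        )
        domain = np.clip(domain, lows, highs)
    else:
        domain = lhs_design(n_domain, list(zip(lows, highs)), rng)
    domain_scores = []
    for x in domain:
        score = evaluate(x)
        n_evals += 1
        domain_scores.append(score)
    order = np.argsort([-s[0] for s in domain_scores])
    best_x = domain[order[0]]
    best = domain_scores[order[0]]
    trace.append(best[0])

    base_half_width = (
        np.asarray(initial_half_width, dtype=float)
        if initial_half_width is not None
        else (highs - lows) / 2.0
    )
    for start in order[: max(n_starts, 1)]:
        track_x = domain[start]
        track = domain_scores[start]
        half_width = base_half_width.copy()
        stagnant = 0
        for _ in range(max_iterations):
            half_width = half_width * shrink
            lo = np.clip(track_x - half_width, lows, highs)
            hi = np.clip(track_x + half_width, lows, highs)
            design = lhs_design(n_design, list(zip(lo, hi)), rng)
            incumbent = track[0]
            for x in design:
                score = evaluate(x)
                n_evals += 1
                if score[0] > track[0]:
                    track, track_x = score, x
            if track[0] > best[0]:
                best, best_x = track, track_x
            trace.append(best[0])
            # a stagnant design is weak evidence of convergence while the
            # region is wide; require `patience` of them in a row
            stagnant = stagnant + 1 if track[0] - incumbent < tol else 0
            if stagnant >= patience:
                break

    theta = _from_search(best_x, bounds)
    on_boundary = bool(
        np.any(np.isclose(best_x, lows, rtol=1e-6))
        or np.any(np.isclose(best_x, highs, rtol=1e-6))
    )
    return FitResult(
        params=TransductionParameters(*theta),
        score=best[0],
        static_fss=best[1],
        ramp_fss=best[2],
        n_evaluations=n_evals,
        trace=tuple(trace),
        on_boundary=on_boundary,
        seed=seed,
    )
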