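"""End-organ arbor architectures: clusters of transduction units per zone.

An arbor configuration is the ordered list of Merkel cell-neurite complex
counts converging on each spike initiation zone, written largest (primary)
first, e.g. {8,5,3,1}.  The skew of a configuration is the magnitude of the
ordinary-least-squares slope of cluster size against cluster rank; it
quantifies how asymmetrically transduction units are grouped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArborConfiguration",
    "skew_slope",
    "move_units",
    "fill_up_sequence",
]


@dataclass(frozen=True)
class ArborConfiguration:
    """Cluster sizes per spike initiation zone, sorted descending."""

    clusters: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        c = tuple(int(x) for x in self.clusters)
        if len(c) < 1:
            raise ValueError("an arbor needs at least one cluster")
        if any(x < 1 for x in c):
            raise ValueError(f"cluster sizes must be >= 1, got {c}")
        # brace notation is unordered; canonical storage is descending
        object.__setattr__(self, "clusters", tuple(sorted(c, reverse=True)))

    @property
    def n_zones(self) -> int:
        return len(self.clusters)

    @property
    def total_units(self) -> int:
        return sum(self.clusters)

    @property
    def skew(self) -> float:
        """Skew magnitude |OLS slope of size vs rank|."""
        return abs(skew_slope(self)[0])

    def __str__(self) -> str:
        return "{" + ",".join(str(c) for c in self.clusters) + "}"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(list(self.clusters), fh)

    @classmethod
    def from_json(cls, path) -> "ArborConfiguration":
        with open(path) as fh:
            return cls(tuple(json.load(fh)))


def skew_slope(config: ArborConfiguration) -> tuple[float, float]:
    """OLS slope (units per rank) and R^2 of cluster size vs rank 1..Z.

    A constant configuration has slope 0 (and R^2 reported as 1.0, a perfect
    horizontal fit).  Undefined for a single cluster.
    """
    if config.n_zones < 2:
        raise ValueError("skew is undefined for a single-cluster arbor")
    ranks = np.arange(1, config.n_zones + 1, dtype=float)
    sizes = np.asarray(config.clusters, dtype=float)
    # explicit OLS: exactly zero for constant configurations
    dx = ranks - ranks.mean()
    dy = sizes - sizes.mean()
    slope = float(np.dot(dx, dy) / np.dot(dx, dx))
    intercept = sizes.mean() - slope * ranks.mean()
    pred = slope * ranks + intercept
    ss_tot = float(np.sum((sizes - sizes.mean()) ** 2))
    ss_res = float(np.sum((sizes - pred) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def move_units(
    config: ArborConfiguration, from_rank: int, to_rank: int, n: int
) -> ArborConfiguration:
    """Move ``n`` units between clusters identified by rank (1-based).

    The total is conserved and the result is re-sorted into canonical
    (descending) order.  A source cluster may never be emptied.
    """
    if n < 0:
        raise ValueError("cannot move a negative number of units")
    if n == 0:
        return config
    z = config.n_zones
    if not (1 <= from_rank <= z and 1 <= to_rank <= z):
        raise ValueError(f"ranks must lie in 1..{z}")
    sizes = list(config.clusters)
    if sizes[from_rank - 1] - n < 1:
        raise ValueError(
            f"moving {n} units would empty cluster at rank {from_rank} "
            f"(size {sizes[from_rank - 1]})"
        )
    sizes[from_rank - 1] -= n
    sizes[to_rank - 1] += n
    return ArborConfiguration(tuple(sizes), label=config.label)


def fill_up_sequence(
    config: ArborConfiguration, strategy: str, max_added: int
) -> list[ArborConfiguration]:
    """Grow an arbor one transduction unit at a time toward a filled state.

    strategy "secondary": raise the secondary cluster to the primary size one
    unit at a time, then the tertiary, and so on (skew-preserving growth).
    strategy "smallest": each step increments the currently smallest cluster
    (ties broken toward the last rank; distribution-equalizing growth).  No
    cluster ever exceeds the primary size.  One configuration is emitted per
    added unit; the sequence is empty if all clusters already equal the
    primary.
    """
    if strategy not in ("secondary", "smallest"):
        raise ValueError(f"unknown fill strategy {strategy!r}")
    if max_added < 1:
        raise ValueError("max_added must be >= 1")
    sizes = list(config.clusters)
    primary = sizes[0]
    out: list[ArborConfiguration] = []
    added = 0
    while added < max_added:
        if strategy == "secondary":
            target = next((i for i in range(1, len(sizes)) if sizes[i] < primary), None)
        else:
            smallest = min(sizes)
            if smallest == primary:
                target = None
            else:
                target = max(i for i, s in enumerate(sizes) if s == smallest)
        if target is None:
            break
        sizes[target] += 1
        added += 1
        out.append(ArborConfiguration(tuple(sizes), label=config.label))
        sizes = list(out[-1].clusters)  # keep canonical ordering as we grow
    return out
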