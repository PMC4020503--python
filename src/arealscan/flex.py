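"""Flexibly shaped spatial scan: adjacency-constrained irregular windows.

Candidate clusters are the connected subsets of each anchor region's
K-nearest-neighbor set that contain the anchor.  Scoring, Monte Carlo
significance and secondary-cluster reporting are shared with the circular
scan, so circular and flexible p-values are comparable under identical
seeds.  Enumeration is exponential in K; the default K = 10 keeps a
67-region map tractable and a warning is issued above K = 15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geo import RegionMap, distances
from .registry import ExpectedCounts
from .scan import (
    ClusterResult,
    ReplicateDistribution,
    ScanConfig,
    attach_pvalues,
    monte_carlo_null,
    scan,
)

__all__ = ["FlexWindow", "knn_neighborhood", "enumerate_flex_windows", "flexible_scan"]

K_WARN_THRESHOLD = 15


@dataclass(frozen=True)
class FlexWindow:
    """Connected, possibly irregular window inside an anchor's K-neighborhood."""

    members: tuple[str, ...]
    anchor: str
    K: int

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.members)
        object.__setattr__(self, "members", members)
        if not members or len(set(members)) != len(members):
            raise ValueError("window members must be nonempty and unique")
        if self.anchor not in members:
            raise ValueError("anchor must be a member")
        if len(members) > self.K:
            raise ValueError("window larger than its neighborhood size K")

    @property
    def center(self) -> str:
        return self.anchor

    @property
    def size(self) -> int:
        return len(self.members)


def knn_neighborhood(region_map: RegionMap, anchor: str, K: int) -> tuple[str, ...]:
    """The anchor plus its K-1 nearest regions by centroid distance, sorted by
    (distance, id); ties broken lexicographically."""
    if not (1 <= K <= region_map.n_regions):
        raise ValueError(f"K must be in [1, {region_map.n_regions}]")
    ai = region_map.index(anchor)
    dm = distances(region_map).values
    ids = region_map.region_ids
    order = sorted(range(len(ids)), key=lambda j: (dm[ai, j], ids[j]))
    return tuple(ids[j] for j in order[:K])


def _connected_subsets(anchor: str, allowed: frozenset, nbrs: dict[str, set[str]]):
    """All connected subsets of *allowed* containing *anchor*, each once.

    Classic fixed-root enumeration: extend the current set by one frontier
    vertex at a time, forbidding previously branched-on vertices so no
    subset is produced twice.
    """

    def rec(current: frozenset, frontier: list[str], forbidden: frozenset):
        yield current
        for i, v in enumerate(frontier):
            new = current | {v}
            newly_forbidden = forbidden | frozenset(frontier[:i])
            new_frontier = [u for u in frontier[i + 1 :]]
            for u in sorted(nbrs[v]):
                if u in allowed and u not in new and u not in newly_forbidden and u not in new_frontier:
                    new_frontier.append(u)
            yield from rec(new, new_frontier, newly_forbidden)

    start_frontier = sorted(u for u in nbrs[anchor] if u in allowed)
    yield from rec(frozenset([anchor]), start_frontier, frozenset())


def enumerate_flex_windows(region_map: RegionMap, K: int) -> list[FlexWindow]:
    """All irregular candidate windows for every anchor, deduplicated.

    Each window is a connected subset (in the adjacency graph) of the
    anchor's K-neighborhood containing the anchor.  A disconnected
    adjacency graph only triggers a warning: anchors in small components
    simply yield fewer windows.
    """
    if not region_map.adjacency:
        raise ValueError("region map has no adjacency; build it first")
    if K > K_WARN_THRESHOLD:
        warnings.warn(
            f"K={K} > {K_WARN_THRESHOLD}: flexible-window enumeration is "
            "exponential in K and may be very slow",
            stacklevel=2,
        )
    if not region_map.is_connected():
        warnings.warn("adjacency graph is disconnected; windows stay within components", stacklevel=2)
    nbrs = region_map.neighbor_sets()
    seen: set[frozenset] = set()
    out: list[FlexWindow] = []
    for anchor in sorted(region_map.region_ids):
        allowed = frozenset(knn_neighborhood(region_map, anchor, K))
        for subset in _connected_subsets(anchor, allowed, nbrs):
            if subset not in seen:
                seen.add(subset)
                out.append(FlexWindow(tuple(sorted(subset)), anchor, K))
    return out


def flexible_scan(
    observed: Sequence[float] | np.ndarray,
    expected: ExpectedCounts,
    region_map: RegionMap,
    K: int = 10,
    config: ScanConfig = ScanConfig(),
) -> tuple[list[ClusterResult], ReplicateDistribution]:
    """Run the flexible scan end to end (enumerate, score, Monte Carlo).

    With K = 1 this degenerates to the circular scan restricted to
    singleton windows.
    """
    windows = enumerate_flex_windows(region_map, K)
    results = scan(observed, expected, windows, config)
    dist = monte_carlo_null(expected, windows, R=config.replicates, seed=config.seed)
    return attach_pvalues(results, dist, gumbel=config.gumbel), dist
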