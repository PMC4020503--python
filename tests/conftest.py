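"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately reimplement window enumeration and scoring
with naive loops so they stay independent of the package's vectorized
implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from arealscan.geo import RegionMap, build_adjacency


# ----------------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------------


def oracle_llr(n: float, E: float, N: float) -> float:
    """Naive evaluation of the scan llr (independent arithmetic path)."""
    if n <= E:
        return 0.0
    val = n * math.log(n / E)
    if N - n > 0:
        val += (N - n) * math.log((N - n) / (N - E))
    return val


def oracle_circular_windows(coords, ids, weights, max_fraction):
    """Brute-force circular window family as a set of frozensets."""
    total = sum(weights)
    cap = max_fraction * total
    fams = set()
    for ci in range(len(ids)):
        dist = [
            (math.dist(coords[ci], coords[j]), ids[j], j) for j in range(len(ids))
        ]
        dist.sort()
        members, cum = [], 0.0
        for rank, (_, _, j) in enumerate(dist, start=1):
            cum += weights[j]
            members.append(ids[j])
            if rank > 1 and cum > cap:
                break
            fams.add(frozenset(members))
            if cum > cap:
                break
    return fams


def oracle_best_circular(coords, ids, weights, obs, exp, N, max_fraction=0.5):
    """Exhaustive max llr over every circular window (brute force)."""
    idx = {r: i for i, r in enumerate(ids)}
    best = (-1.0, None)
    for fam in oracle_circular_windows(coords, ids, weights, max_fraction):
        n = sum(obs[idx[r]] for r in fam)
        e = sum(exp[idx[r]] for r in fam)
        llr = oracle_llr(n, e, N)
        if llr > best[0]:
            best = (llr, fam)
    return best


def oracle_connected_subsets(members, edges):
    """All connected subsets of *members*, by powerset + BFS check."""
    members = tuple(members)
    nbrs = {m: set() for m in members}
    for a, b in edges:
        if a in nbrs and b in nbrs:
            nbrs[a].add(b)
            nbrs[b].add(a)
    out = set()
    for r in range(1, len(members) + 1):
        for sub in itertools.combinations(members, r):
            s = set(sub)
            start = sub[0]
            seen = {start}
            stack = [start]
            while stack:
                for v in nbrs[stack.pop()] & s:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if seen == s:
                out.add(frozenset(sub))
    return out


def oracle_best_flexible(region_map, K, obs, exp, N):
    """Exhaustive max llr over connected subsets within K-neighborhoods."""
    from arealscan.flex import knn_neighborhood

    idx = {r: i for i, r in enumerate(region_map.region_ids)}
    fams = set()
    for anchor in region_map.region_ids:
        hood = knn_neighborhood(region_map, anchor, K)
        for sub in oracle_connected_subsets(hood, region_map.adjacency):
            if anchor in sub:
                fams.add(sub)
    best = (-1.0, None)
    for fam in fams:
        n = sum(obs[idx[r]] for r in fam)
        e = sum(exp[idx[r]] for r in fam)
        llr = oracle_llr(n, e, N)
        if llr > best[0]:
            best = (llr, fam)
    return best


# ----------------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------------


@pytest.fixture
def square_map() -> RegionMap:
    """Four regions at the unit-square corners."""
    return RegionMap(
        ("A", "B", "C", "D"),
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
    )


@pytest.fixture
def line_map() -> RegionMap:
    """Five regions on a line at x = 0..4, chain adjacency."""
    ids = ("L1", "L2", "L3", "L4", "L5")
    coords = np.array([[float(i), 0.0] for i in range(5)])
    adj = frozenset({("L1", "L2"), ("L2", "L3"), ("L3", "L4"), ("L4", "L5")})
    return RegionMap(ids, coords, adjacency=adj)


@pytest.fixture
def triangle_map() -> RegionMap:
    ids = ("A", "B", "C")
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.9]])
    adj = frozenset({("A", "B"), ("A", "C"), ("B", "C")})
    return RegionMap(ids, coords, adjacency=adj)


@pytest.fixture
def random_map():
    """Factory for reproducible random planar maps with Delaunay adjacency."""

    def make(n: int, seed: int = 0) -> RegionMap:
        rng = np.random.default_rng(seed)
        ids = tuple(f"R{i:02d}" for i in range(1, n + 1))
        m = RegionMap(ids, rng.uniform(0, 1, size=(n, 2)))
        return build_adjacency(m, method="delaunay") if n >= 3 else m

    return make
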