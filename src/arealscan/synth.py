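"""Synthetic county-registry generator.

Emulates the structure the scans assume: a map of areal units with
centroids and adjacency, per-region populations stratified by age group,
sex and race, and Poisson case counts under regionally varying relative
risks, an optional statewide temporal trend, and optional space-time
interaction.  Defaults mirror a 67-region registry with a baseline
incidence of 7.3 per 100,000 person-years over 9 annual periods.

All randomness is driven by the spec seed through named child streams, so
the full generator chain is deterministic and each stage is reproducible
in isolation.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .geo import RegionMap, build_adjacency
from .registry import StratifiedCounts

__all__ = [
    "ClusterSpec",
    "SyntheticSpec",
    "make_map",
    "make_population",
    "sample_cases",
    "ground_truth",
    "generate",
]

DEFAULT_AGE_LEVELS = ("15-19", "20-24", "25-29", "30-34", "35-39")
DEFAULT_SEX_LEVELS = ("F", "M")
DEFAULT_RACE_LEVELS = ("white", "black", "other")

# Multiplicative rate profile per axis level; population-weighted mean is
# rescaled to the spec baseline.  Female:male 3:1 and rates rising with age
# make covariate adjustment do real work: an adjusted scan must not flag a
# region that is merely demographically skewed.
DEFAULT_RATE_PROFILE: dict[str, dict[str, float]] = {
    "age": {"15-19": 0.3, "20-24": 0.6, "25-29": 1.0, "30-34": 1.4, "35-39": 1.8},
    "sex": {"F": 3.0, "M": 1.0},
    "race": {"white": 1.0, "black": 0.8, "other": 0.9},
}


@dataclass(frozen=True)
class ClusterSpec:
    """An elevated-risk zone to inject.

    Either an explicit region set or ``size`` for an auto-grown contiguous
    zone.  ``periods`` restricts the elevation to a contiguous period range
    (inclusive labels); ``None`` means all periods.
    """

    rr: float
    regions: tuple[str, ...] | None = None
    size: int | None = None
    periods: tuple | None = None

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("relative risk must be positive")
        if (self.regions is None) == (self.size is None):
            raise ValueError("give exactly one of regions= or size=")
        if self.regions is not None:
            object.__setattr__(self, "regions", tuple(str(r) for r in self.regions))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic registry."""

    n_regions: int = 67
    axes: tuple[str, ...] = ("age", "sex", "race")
    levels: tuple[tuple[str, ...], ...] = (
        DEFAULT_AGE_LEVELS,
        DEFAULT_SEX_LEVELS,
        DEFAULT_RACE_LEVELS,
    )
    baseline_rate: float = 7.3  # cases per 100,000 person-years
    periods: tuple = tuple(range(2000, 2009))
    pop_scale: float = 80_000.0  # log-normal mean of a region's total population
    pop_sigma: float = 1.0
    dirichlet_conc: float = 20.0
    clusters: tuple[ClusterSpec, ...] = ()
    trend: tuple[float, ...] | None = None  # per-period multiplicative factor
    rate_profile: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if self.trend is not None and len(self.trend) != len(self.periods):
            raise ValueError("trend length must match the period count")
        object.__setattr__(self, "clusters", tuple(self.clusters))
        explicit = [set(c.regions) for c in self.clusters if c.regions is not None]
        for a, b in itertools.combinations(explicit, 2):
            if a & b:
                raise ValueError("cluster region sets must be disjoint")

    def region_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_regions))
        return tuple(f"R{i:0{width}d}" for i in range(1, self.n_regions + 1))


def _rng(spec: SyntheticSpec, stage: str) -> np.random.Generator:
    # stable per-stage child stream (string hashes are process-randomized)
    tag = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence((spec.seed, tag)))


def make_map(spec: SyntheticSpec) -> RegionMap:
    """Uniform random centroids on the unit square with Delaunay adjacency."""
    rng = _rng(spec, "map")
    coords = rng.uniform(0.0, 1.0, size=(spec.n_regions, 2))
    base = RegionMap(spec.region_ids(), coords, mode="planar")
    return build_adjacency(base, method="delaunay")


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integerize ``total * shares`` so the parts sum to *total* exactly."""
    raw = total * shares
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def make_population(region_map: RegionMap, spec: SyntheticSpec) -> StratifiedCounts:
    """Stratified populations, constant across periods.

    Region totals are log-normal around ``pop_scale``; stratum shares come
    from a symmetric Dirichlet and are integerized by largest-remainder
    rounding so stratum sums hit the region totals exactly.
    """
    rng = _rng(spec, "population")
    n = region_map.n_regions
    n_strata = int(np.prod([len(lv) for lv in spec.levels]))
    mu = np.log(spec.pop_scale) - spec.pop_sigma**2 / 2.0
    totals = np.maximum(1, np.rint(rng.lognormal(mu, spec.pop_sigma, size=n))).astype(
        np.int64
    )
    shares = rng.dirichlet(np.full(n_strata, spec.dirichlet_conc), size=n)
    per_region = np.stack(
        [_largest_remainder(int(t), s) for t, s in zip(totals, shares)]
    )
    vals = np.repeat(per_region[:, :, None], len(spec.periods), axis=2)
    return StratifiedCounts(
        region_map.region_ids, spec.axes, spec.levels, spec.periods, vals
    )


def _stratum_profile(spec: SyntheticSpec) -> np.ndarray:
    """Unnormalized relative rate per stratum (product over axis levels)."""
    profile = spec.rate_profile if spec.rate_profile is not None else DEFAULT_RATE_PROFILE
    out = np.ones(int(np.prod([len(lv) for lv in spec.levels])))
    for si, stratum in enumerate(itertools.product(*spec.levels)):
        f = 1.0
        for ax, level in zip(spec.axes, stratum):
            f *= profile.get(ax, {}).get(level, 1.0)
        out[si] = f
    return out


def ground_truth(
    spec: SyntheticSpec, region_map: RegionMap
) -> list[ClusterSpec]:
    """Materialize the cluster answer key (auto-contiguous sets resolved).

    Auto clusters are grown by seeded BFS over the adjacency graph,
    avoiding regions already claimed by earlier clusters.  The result is
    reproducible given the spec seed and always connected.
    """
    rng = _rng(spec, "clusters")
    nbrs = region_map.neighbor_sets()
    taken: set[str] = set()
    for c in spec.clusters:
        if c.regions is not None:
            taken.update(c.regions)
    resolved: list[ClusterSpec] = []
    for c in spec.clusters:
        if c.regions is not None:
            unknown = set(c.regions) - set(region_map.region_ids)
            if unknown:
                raise ValueError(f"cluster references unknown regions {sorted(unknown)}")
            if len(c.regions) > 1 and not _is_connected(set(c.regions), nbrs):
                raise ValueError(f"cluster regions {c.regions} are not contiguous")
            resolved.append(c)
            continue
        free = [r for r in sorted(region_map.region_ids) if r not in taken]
        if not free:
            raise ValueError("no regions left for auto-contiguous cluster")
        for _ in range(100):  # retry seeds whose free component is too small
            seed_region = free[int(rng.integers(len(free)))]
            grown = _grow(seed_region, c.size, nbrs, taken)
            if grown is not None:
                break
        else:
            raise ValueError(f"could not grow a contiguous cluster of size {c.size}")
        taken.update(grown)
        resolved.append(replace(c, regions=tuple(sorted(grown)), size=None))
    return resolved


def _is_connected(members: set[str], nbrs: dict[str, set[str]]) -> bool:
    start = next(iter(members))
    seen = {start}
    stack = [start]
    while stack:
        for v in nbrs[stack.pop()] & members:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen == members


def _grow(seed_region, size, nbrs, taken):
    grown = {seed_region}
    frontier = sorted(nbrs[seed_region] - taken)
    while len(grown) < size:
        if not frontier:
            return None
        v = frontier.pop(0)
        grown.add(v)
        for u in sorted(nbrs[v] - grown - taken):
            if u not in frontier:
                frontier.append(u)
    return grown


def sample_cases(
    population: StratifiedCounts,
    spec: SyntheticSpec,
    region_map: RegionMap,
    truth: Sequence[ClusterSpec] | None = None,
) -> StratifiedCounts:
    """Poisson case counts per (region, stratum, period).

    The mean for cell ``(i, s, t)`` is ``P_ist * r_s * trend_t * RR_i(t)``
    where the stratum rates ``r_s`` follow the configured profile rescaled
    so their population-weighted mean equals the spec baseline, and
    ``RR_i(t)`` multiplies the relative risks of every cluster covering the
    region in that period (1 elsewhere).
    """
    if truth is None:
        truth = ground_truth(spec, region_map)
    rng = _rng(spec, "cases")
    P = population.values.astype(float)  # (nr, ns, nt)
    profile = _stratum_profile(spec)
    pop_by_stratum = P.sum(axis=(0, 2))
    weighted_mean = (pop_by_stratum * profile).sum() / pop_by_stratum.sum()
    r_s = profile * (spec.baseline_rate / 1e5) / weighted_mean
    trend = np.asarray(spec.trend, dtype=float) if spec.trend is not None else np.ones(
        len(spec.periods)
    )
    rr = np.ones((len(population.regions), len(spec.periods)))
    pidx = {p: i for i, p in enumerate(spec.periods)}
    ridx = {r: i for i, r in enumerate(population.regions)}
    for c in truth:
        if c.periods is None:
            t_lo, t_hi = 0, len(spec.periods) - 1
        else:
            t_lo, t_hi = pidx[c.periods[0]], pidx[c.periods[1]]
        for r in c.regions:
            rr[ridx[r], t_lo : t_hi + 1] *= c.rr
    mean = P * r_s[None, :, None] * trend[None, None, :] * rr[:, None, :]
    vals = rng.poisson(mean)
    return StratifiedCounts(
        population.regions, population.axes, population.levels, population.periods, vals
    )


def plan_embedded_clusters(
    region_map: RegionMap,
    population: StratifiedCounts,
    primary_share: float = 0.26,
    primary_rr: float = 1.26,
    secondary_share: float = 0.03,
    secondary_rr: float = 1.71,
    min_separation: float = 0.5,
) -> tuple[ClusterSpec, ClusterSpec]:
    """Place a large-population zone and a small distant zone on a map.

    The primary zone is grown over the adjacency graph around the
    highest-population region, preferring centroid-near neighbors so it
    stays compact, until it holds ``primary_share`` of the population.  The
    secondary zone grows the same way from the region farthest from the
    primary, restricted to regions at least ``min_separation`` away so a
    single circular window cannot cover both zones.  Both zones are
    connected by construction.
    """
    totals = population.region_totals().astype(float) / len(population.periods)
    total = totals.sum()
    ids = list(region_map.region_ids)
    coords = region_map.coords
    nbrs = region_map.neighbor_sets()

    def grow(seed_id: str, target: float, allowed: set[str]) -> list[str]:
        center = coords[ids.index(seed_id)]
        zone = [seed_id]
        share = totals[ids.index(seed_id)] / total
        while share < target:
            frontier = sorted(
                {u for z in zone for u in nbrs[z] if u in allowed and u not in zone},
                key=lambda r: (float(np.linalg.norm(coords[ids.index(r)] - center)), r),
            )
            if not frontier:
                break
            zone.append(frontier[0])
            share += totals[ids.index(frontier[0])] / total
        return zone

    everything = set(ids)
    primary = grow(ids[int(np.argmax(totals))], primary_share, everything)
    p_coords = coords[[ids.index(r) for r in primary]]
    sep = np.array(
        [float(np.linalg.norm(p_coords - coords[j], axis=1).min()) for j in range(len(ids))]
    )
    far = {r for j, r in enumerate(ids) if sep[j] >= min_separation} - set(primary)
    if not far:
        raise ValueError("no regions far enough from the primary zone")
    seed_id = ids[int(np.argmax(np.where([r in far for r in ids], sep, -1.0)))]
    secondary = grow(seed_id, secondary_share, far)
    return (
        ClusterSpec(rr=primary_rr, regions=tuple(sorted(primary))),
        ClusterSpec(rr=secondary_rr, regions=tuple(sorted(secondary))),
    )


def generate(
    spec: SyntheticSpec,
) -> tuple[RegionMap, StratifiedCounts, StratifiedCounts, list[ClusterSpec]]:
    """Run the whole chain: map, population, resolved truth, cases."""
    region_map = make_map(spec)
    population = make_population(region_map, spec)
    truth = ground_truth(spec, region_map)
    cases = sample_cases(population, spec, region_map, truth)
    return region_map, population, cases, truth
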