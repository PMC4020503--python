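"""Analysis orchestration and report rendering.

Ties the pieces together: standardize, enumerate windows, scan, test, and
render a summary table (study-area column plus one column per reported
cluster), sex-specific and covariate-subset reruns, and a GeoJSON overlay
of the cluster memberships.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .geo import RegionMap, exclude_regions
from .registry import (
    ExpectedCounts,
    StratifiedCounts,
    annual_rate_per_100k,
    indirect_standardize,
)
from .scan import (
    ClusterResult,
    ReplicateDistribution,
    ScanConfig,
    circular_windows,
    run_scan,
)

__all__ = [
    "AnalysisReport",
    "run_spatial_analysis",
    "summarize",
    "stratified_rerun",
    "export_geojson",
]


@dataclass(frozen=True)
class ClusterBlock:
    rank: int
    members: tuple[str, ...]
    population: int
    n: int
    expected: float
    annual_rate: float
    rr: float
    llr: float
    p_mc: float | None
    p_gumbel: float | None
    interval: tuple | None = None


@dataclass(frozen=True)
class AnalysisReport:
    """Summary of one scan run, renderable as text, CSV rows or JSON."""

    label: str
    covariates: tuple[str, ...]
    study_population: int
    study_cases: int
    study_rate: float
    study_years: int
    replicates: int
    clusters: tuple[ClusterBlock, ...]
    trend_artifact: bool | None = None

    def _fmt_p(self, p: float | None) -> str:
        if p is None:
            return ""
        floor = 1.0 / (self.replicates + 1)
        return f"<{floor:g}" if p <= floor else f"{p:.3f}"

    def to_text(self) -> str:
        cols = ["State"] + [f"Cluster {c.rank}" for c in self.clusters]
        rows = [
            ("Population", [f"{self.study_population:,}"] + [f"{c.population:,}" for c in self.clusters]),
            ("Number of cases", [f"{self.study_cases:,}"] + [f"{c.n:,}" for c in self.clusters]),
            (
                "Annual cases per 100,000",
                [f"{self.study_rate:.1f}"] + [f"{c.annual_rate:.1f}" for c in self.clusters],
            ),
            ("Relative risk", [""] + [f"{c.rr:.2f}" for c in self.clusters]),
            ("Log likelihood ratio", [""] + [f"{c.llr:.2f}" for c in self.clusters]),
            ("P value", [""] + [self._fmt_p(c.p_mc) for c in self.clusters]),
        ]
        widths = [
            max(len(h), *(len(r[1][i]) for r in rows)) for i, h in enumerate(cols)
        ]
        name_w = max(len(r[0]) for r in rows)
        lines = [f"== {self.label} (adjusted for: {', '.join(self.covariates) or 'none'}) =="]
        lines.append(
            " " * name_w + "  " + "  ".join(h.rjust(w) for h, w in zip(cols, widths))
        )
        for name, cells in rows:
            lines.append(
                name.ljust(name_w)
                + "  "
                + "  ".join(c.rjust(w) for c, w in zip(cells, widths))
            )
        for c in self.clusters:
            extra = f" periods {c.interval[0]}-{c.interval[1]}" if c.interval else ""
            lines.append(f"Cluster {c.rank} regions{extra}: {', '.join(c.members)}")
        if self.trend_artifact is not None:
            lines.append(f"trend_artifact: {self.trend_artifact}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "covariates": list(self.covariates),
            "study": {
                "population": self.study_population,
                "cases": self.study_cases,
                "annual_rate_per_100k": self.study_rate,
                "years": self.study_years,
            },
            "replicates": self.replicates,
            "trend_artifact": self.trend_artifact,
            "clusters": [
                {
                    "rank": c.rank,
                    "members": list(c.members),
                    "population": c.population,
                    "cases": c.n,
                    "expected": c.expected,
                    "annual_rate_per_100k": c.annual_rate,
                    "relative_risk": c.rr,
                    "llr": c.llr,
                    "p_mc": c.p_mc,
                    "p_gumbel": c.p_gumbel,
                    "interval": list(c.interval) if c.interval else None,
                }
                for c in self.clusters
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_csv(self) -> str:
        lines = ["rank,members,population,cases,expected,annual_rate,rr,llr,p_mc,p_gumbel"]
        for c in self.clusters:
            lines.append(
                f"{c.rank},{';'.join(c.members)},{c.population},{c.n},"
                f"{c.expected:.6f},{c.annual_rate:.6f},{c.rr:.6f},{c.llr:.6f},"
                f"{'' if c.p_mc is None else c.p_mc},"
                f"{'' if c.p_gumbel is None else c.p_gumbel}"
            )
        return "\n".join(lines) + "\n"


def run_spatial_analysis(
    cases: StratifiedCounts,
    population: StratifiedCounts,
    region_map: RegionMap,
    adjust_axes: Sequence[str] | None = None,
    config: ScanConfig = ScanConfig(),
) -> tuple[list[ClusterResult], ReplicateDistribution, ExpectedCounts]:
    """Full circular-scan pipeline from registry tables to tested clusters."""
    if config.excluded_regions:
        region_map = exclude_regions(region_map, config.excluded_regions)
        cases = _drop_regions(cases, config.excluded_regions)
        population = _drop_regions(population, config.excluded_regions)
    if tuple(population.regions) != tuple(region_map.region_ids):
        cases = _reorder(cases, region_map.region_ids)
        population = _reorder(population, region_map.region_ids)
    expected = indirect_standardize(cases, population, adjust_axes)
    weights = population.region_totals()
    windows = circular_windows(region_map, weights, config.max_population_fraction)
    observed = cases.region_totals()
    results, dist = run_scan(observed, expected, windows, config)
    return results, dist, expected


def _drop_regions(counts: StratifiedCounts, excluded: Sequence[str]) -> StratifiedCounts:
    excl = set(excluded)
    keep = [i for i, r in enumerate(counts.regions) if r not in excl]
    return StratifiedCounts(
        tuple(counts.regions[i] for i in keep),
        counts.axes,
        counts.levels,
        counts.periods,
        counts.values[keep],
    )


def _reorder(counts: StratifiedCounts, regions: Sequence[str]) -> StratifiedCounts:
    idx = [counts.regions.index(r) for r in regions]
    return StratifiedCounts(
        tuple(regions), counts.axes, counts.levels, counts.periods, counts.values[idx]
    )


def summarize(
    results: Sequence[ClusterResult],
    cases: StratifiedCounts,
    population: StratifiedCounts,
    *,
    label: str = "purely spatial analysis",
    covariates: Sequence[str] = (),
    study_years: int = 9,
    replicates: int = 999,
    alpha: float | None = 0.05,
    trend_artifact: bool | None = None,
) -> AnalysisReport:
    """Build the summary table from scan results and the raw registry tables.

    Populations are person counts (period-constant populations are averaged
    over periods); annual rates use the configured study span.  When
    *alpha* is given only clusters significant at that level get a column,
    mirroring the reported-cluster convention; pass ``None`` to keep all.
    """
    pop_by_region = population.region_totals() / len(population.periods)
    study_pop = int(round(pop_by_region.sum()))
    study_cases = cases.total()
    ridx = {r: i for i, r in enumerate(population.regions)}
    blocks = []
    for res in results:
        if alpha is not None and (res.p_mc is None or res.p_mc >= alpha):
            continue
        cluster_pop = int(round(sum(pop_by_region[ridx[r]] for r in res.members)))
        blocks.append(
            ClusterBlock(
                rank=res.rank,
                members=res.members,
                population=cluster_pop,
                n=res.n,
                expected=res.expected,
                annual_rate=annual_rate_per_100k(res.n, cluster_pop, study_years),
                rr=res.rr,
                llr=res.llr,
                p_mc=res.p_mc,
                p_gumbel=res.p_gumbel,
                interval=res.interval,
            )
        )
    return AnalysisReport(
        label=label,
        covariates=tuple(covariates),
        study_population=study_pop,
        study_cases=study_cases,
        study_rate=annual_rate_per_100k(study_cases, study_pop, study_years),
        study_years=study_years,
        replicates=replicates,
        clusters=tuple(blocks),
        trend_artifact=trend_artifact,
    )


def stratified_rerun(
    cases: StratifiedCounts,
    population: StratifiedCounts,
    region_map: RegionMap,
    axis: str,
    levels: Sequence[str] | None = None,
    config: ScanConfig = ScanConfig(),
    *,
    adjust_axes: Sequence[str] | None = None,
    study_years: int = 9,
) -> dict[str, AnalysisReport]:
    """Rerun the full spatial scan separately per level of a stratum axis.

    The filtered axis is dropped from adjustment (e.g. a females-only run
    adjusts for the remaining axes).  Returns one report per level.
    """
    if axis not in cases.axes:
        raise ValueError(f"unknown stratum axis {axis!r}")
    if levels is None:
        levels = cases.levels[cases.axes.index(axis)]
    remaining = [ax for ax in cases.axes if ax != axis]
    adjust = [ax for ax in (adjust_axes or remaining) if ax != axis]
    out: dict[str, AnalysisReport] = {}
    for level in levels:
        c = cases.select(axis, level)
        p = population.select(axis, level)
        if c.total() == 0:
            raise ValueError(f"no cases left after selecting {axis}={level}")
        results, _, _ = run_spatial_analysis(c, p, region_map, adjust, config)
        out[level] = summarize(
            results,
            c,
            p,
            label=f"{axis}={level}",
            covariates=adjust,
            study_years=study_years,
            replicates=config.replicates,
            alpha=config.alpha,
        )
    return out


def export_geojson(
    results: Sequence[ClusterResult], region_map: RegionMap
) -> dict:
    """Point FeatureCollection: one feature per region, tagged with the rank
    of the cluster containing it (or null), the cluster RR and p-value."""
    by_region: dict[str, ClusterResult] = {}
    for res in results:
        for r in res.members:
            by_region.setdefault(r, res)
    features = []
    for rid, (x, y) in zip(region_map.region_ids, region_map.coords):
        res = by_region.get(rid)
        if region_map.mode == "latlong":
            coords = [float(y), float(x)]  # GeoJSON wants [lon, lat]
        else:
            coords = [float(x), float(y)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": coords},
                "properties": {
                    "region_id": rid,
                    "cluster": None if res is None else res.rank,
                    "relative_risk": None if res is None else res.rr,
                    "p_value": None if res is None else res.p_mc,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
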