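"""Stratified registry counts and covariate-adjusted expected counts.

:class:`StratifiedCounts` holds case or population counts indexed by
(region, stratum, period), where a stratum is a tuple of levels over
declared axes (e.g. age group x sex x race).  :func:`indirect_standardize`
turns a case/population pair into the expected counts ``E`` under the null
hypothesis of equal covariate-adjusted risk everywhere, conditioned so that
``sum(E) == N`` (the observed case total).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedCounts",
    "ExpectedCounts",
    "indirect_standardize",
    "annual_rate_per_100k",
    "annual_rates_by_period",
    "read_cases",
    "read_population",
    "write_cases",
    "write_population",
]

ALL_PERIODS = "all"


@dataclass(frozen=True)
class StratifiedCounts:
    """Nonnegative integer counts per (region, stratum, period).

    ``values`` has shape ``(n_regions, n_strata, n_periods)`` where strata
    are the cartesian product of ``levels`` in axis order (C order, last
    axis fastest).
    """

    regions: tuple[str, ...]
    axes: tuple[str, ...]
    levels: tuple[tuple[str, ...], ...]
    periods: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        regions = tuple(str(r) for r in self.regions)
        object.__setattr__(self, "regions", regions)
        if len(set(regions)) != len(regions):
            raise ValueError("duplicate region ids")
        axes = tuple(self.axes)
        levels = tuple(tuple(str(l) for l in lv) for lv in self.levels)
        if len(axes) != len(levels):
            raise ValueError("axes/levels length mismatch")
        for ax, lv in zip(axes, levels):
            if len(set(lv)) != len(lv) or not lv:
                raise ValueError(f"axis {ax!r} has empty or duplicated levels")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "levels", levels)
        periods = tuple(self.periods)
        if len(set(periods)) != len(periods) or not periods:
            raise ValueError("periods must be nonempty and unique")
        object.__setattr__(self, "periods", periods)
        vals = np.asarray(self.values)
        if not np.issubdtype(vals.dtype, np.integer):
            rounded = np.rint(vals)
            if not np.allclose(vals, rounded):
                raise ValueError("counts must be integers")
            vals = rounded.astype(np.int64)
        else:
            vals = vals.astype(np.int64)
        expected_shape = (len(regions), self.n_strata, len(periods))
        if vals.shape != expected_shape:
            raise ValueError(f"values shape {vals.shape} != {expected_shape}")
        if np.any(vals < 0):
            raise ValueError("counts must be nonnegative")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    # -- structure ---------------------------------------------------------

    @property
    def n_strata(self) -> int:
        out = 1
        for lv in self.levels:
            out *= len(lv)
        return out

    @property
    def strata(self) -> tuple[tuple[str, ...], ...]:
        return tuple(itertools.product(*self.levels))

    def total(self) -> int:
        return int(self.values.sum())

    def region_totals(self) -> np.ndarray:
        """Counts per region, summed over strata and periods."""
        return self.values.sum(axis=(1, 2))

    def region_period_totals(self) -> np.ndarray:
        """Counts per (region, period), summed over strata."""
        return self.values.sum(axis=1)

    def period_totals(self) -> np.ndarray:
        return self.values.sum(axis=(0, 1))

    # -- reshaping ---------------------------------------------------------

    def _axis_shape(self) -> tuple[int, ...]:
        return tuple(len(lv) for lv in self.levels)

    def collapse_axes(self, keep_axes: Sequence[str]) -> "StratifiedCounts":
        """Sum out every stratum axis not in *keep_axes* (order preserved)."""
        keep = [ax for ax in self.axes if ax in set(keep_axes)]
        unknown = set(keep_axes) - set(self.axes)
        if unknown:
            raise ValueError(f"unknown axes {sorted(unknown)}")
        shape = (len(self.regions),) + self._axis_shape() + (len(self.periods),)
        cube = self.values.reshape(shape)
        drop = tuple(1 + i for i, ax in enumerate(self.axes) if ax not in keep)
        cube = cube.sum(axis=drop) if drop else cube
        new_levels = tuple(lv for ax, lv in zip(self.axes, self.levels) if ax in keep)
        n_strata = int(np.prod([len(lv) for lv in new_levels])) if new_levels else 1
        vals = cube.reshape(len(self.regions), n_strata, len(self.periods))
        return StratifiedCounts(self.regions, tuple(keep), new_levels, self.periods, vals)

    def select(self, axis: str, level: str) -> "StratifiedCounts":
        """Restrict to one level of *axis* and drop the axis."""
        if axis not in self.axes:
            raise ValueError(f"unknown axis {axis!r}")
        ai = self.axes.index(axis)
        lv = self.levels[ai]
        if level not in lv:
            raise ValueError(f"unknown level {level!r} for axis {axis!r}")
        shape = (len(self.regions),) + self._axis_shape() + (len(self.periods),)
        cube = self.values.reshape(shape)
        cube = np.take(cube, lv.index(level), axis=1 + ai)
        new_axes = self.axes[:ai] + self.axes[ai + 1 :]
        new_levels = self.levels[:ai] + self.levels[ai + 1 :]
        n_strata = int(np.prod([len(l) for l in new_levels])) if new_levels else 1
        vals = cube.reshape(len(self.regions), n_strata, len(self.periods))
        return StratifiedCounts(self.regions, new_axes, new_levels, self.periods, vals)

    def collapse_periods(self) -> "StratifiedCounts":
        """Sum over periods, leaving the single period ``"all"``."""
        vals = self.values.sum(axis=2, keepdims=True)
        return StratifiedCounts(self.regions, self.axes, self.levels, (ALL_PERIODS,), vals)

    def same_grid(self, other: "StratifiedCounts") -> bool:
        return (
            self.regions == other.regions
            and self.axes == other.axes
            and self.levels == other.levels
            and self.periods == other.periods
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        regions: Sequence[str],
        axes: Sequence[str],
        levels: Sequence[Sequence[str]],
        periods: Sequence,
    ) -> "StratifiedCounts":
        """Build from ``(region, stratum_tuple, period, count)`` records.

        Duplicate keys accumulate; missing cells are zero.
        """
        regions = tuple(str(r) for r in regions)
        levels = tuple(tuple(str(l) for l in lv) for lv in levels)
        periods = tuple(periods)
        ridx = {r: i for i, r in enumerate(regions)}
        sidx = {s: i for i, s in enumerate(itertools.product(*levels))}
        pidx = {p: i for i, p in enumerate(periods)}
        vals = np.zeros((len(regions), len(sidx), len(periods)), dtype=np.int64)
        for region, stratum, period, count in records:
            region = str(region)
            stratum = tuple(str(x) for x in stratum)
            if region not in ridx:
                raise ValueError(f"undeclared region {region!r}")
            if stratum not in sidx:
                raise ValueError(f"undeclared stratum {stratum!r}")
            if period not in pidx:
                raise ValueError(f"undeclared period {period!r}")
            vals[ridx[region], sidx[stratum], pidx[period]] += int(count)
        return cls(regions, tuple(axes), levels, periods, vals)


@dataclass(frozen=True)
class ExpectedCounts:
    """Null expectations ``E`` per (region, period), conditioned on the total.

    Invariant: ``sum(values) == N`` to 1e-9 relative tolerance.
    """

    regions: tuple[str, ...]
    periods: tuple
    values: np.ndarray  # (n_regions, n_periods)
    N: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.shape != (len(self.regions), len(self.periods)):
            raise ValueError("expected-counts shape mismatch")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("expected counts must be finite and nonnegative")
        total = vals.sum()
        if self.N > 0 and abs(total - self.N) > 1e-9 * max(self.N, 1):
            raise ValueError(
                f"expected counts are not conditioned: sum={total!r}, N={self.N}"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "regions", tuple(str(r) for r in self.regions))
        object.__setattr__(self, "periods", tuple(self.periods))

    def region_totals(self) -> np.ndarray:
        """Spatial-only expectations (summed over periods)."""
        return self.values.sum(axis=1)


def indirect_standardize(
    cases: StratifiedCounts,
    population: StratifiedCounts,
    adjust_axes: Sequence[str] | None = None,
) -> ExpectedCounts:
    """Covariate-adjusted expected counts by indirect standardization.

    For each region ``i`` (and period ``t`` when there are several),

        ``E_i(t) = sum_s P_{i,s,t} * C_{s,t} / P_{s,t}``

    where ``C`` and ``P`` are study-wide stratum totals over *adjust_axes*
    (unadjusted axes are collapsed first).  With multiple periods the
    stratum rates are computed per (stratum, period), so temporal trends
    are absorbed into ``E``.  ``sum(E) == N`` by construction.

    Raises
    ------
    ValueError
        If the two inputs are not on the same grid, or a stratum has cases
        but zero population (named in the message).
    """
    if not cases.same_grid(population):
        raise ValueError("cases and population must share regions, axes and periods")
    if adjust_axes is None:
        adjust_axes = cases.axes
    c = cases.collapse_axes(adjust_axes)
    p = population.collapse_axes(adjust_axes)
    N = c.total()
    if N <= 0:
        raise ValueError("total case count must be positive")
    C_st = c.values.sum(axis=0)  # (n_strata, n_periods)
    P_st = p.values.sum(axis=0).astype(float)
    bad = (C_st > 0) & (P_st == 0)
    if np.any(bad):
        s_i, t_i = np.argwhere(bad)[0]
        stratum = c.strata[s_i] if c.axes else ("<pooled>",)
        raise ValueError(
            f"stratum {stratum} in period {c.periods[t_i]!r} has cases but zero population"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(P_st > 0, C_st / np.where(P_st > 0, P_st, 1.0), 0.0)
    E = np.einsum("ist,st->it", p.values.astype(float), rate)
    # renormalize away accumulated floating error so sum(E) == N exactly
    E *= N / E.sum()
    return ExpectedCounts(cases.regions, cases.periods, E, N)


def annual_rate_per_100k(cases: float, population: float, years: int) -> float:
    """Average annual incidence per 100,000 person-years.

    ``cases / (population * years) * 100000``; *population* must be positive
    and *years* at least 1.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if years < 1:
        raise ValueError("years must be >= 1")
    return cases / (population * years) * 100_000.0


def annual_rates_by_period(
    cases: StratifiedCounts, population: StratifiedCounts
) -> pd.Series:
    """Study-wide annual rate per 100,000 for every period (years = 1 each)."""
    if cases.periods != population.periods:
        raise ValueError("cases and population must cover the same periods")
    c_t = cases.period_totals()
    p_t = population.period_totals()
    if np.any(p_t <= 0):
        missing = [p for p, v in zip(cases.periods, p_t) if v <= 0]
        raise ValueError(f"zero population in periods {missing}")
    rates = [annual_rate_per_100k(int(c), int(p), 1) for c, p in zip(c_t, p_t)]
    return pd.Series(rates, index=list(cases.periods), name="rate_per_100k")


# ----------------------------------------------------------------------------
# SaTScan-dialect text files
#
# .cas:  <region id> <count> [<period>] [<covariate levels>...]
# .pop:  <region id> <period> <count> [<covariate levels>...]
#
# Whitespace delimited; blank lines and '#' comments ignored.  Covariate
# columns follow the declared axis order.  Levels, regions and periods are
# taken from the data (sorted) unless supplied.
# ----------------------------------------------------------------------------


def _open(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _parse_table(
    source, n_fixed: int, n_axes: int, what: str, ignore_extra: bool = False
) -> list[list[str]]:
    stream, close = _open(source)
    want = n_fixed + n_axes
    rows = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != want and not (ignore_extra and len(parts) > want):
                raise ValueError(
                    f"{what} line {lineno}: expected {want} fields, got {len(parts)}"
                )
            rows.append(parts[:want])
    finally:
        if close:
            stream.close()
    return rows


def _grid_from_rows(rows, axes, regions, levels, periods):
    regions = tuple(regions) if regions is not None else tuple(
        sorted({r[0] for r in rows})
    )
    if levels is None:
        levels = tuple(
            tuple(sorted({row[3 + i] for row in rows})) for i in range(len(axes))
        )
    if periods is None:
        raw = sorted({row[1] for row in rows})
        try:
            periods = tuple(int(p) for p in raw)
        except ValueError:
            periods = tuple(raw)
    return regions, tuple(levels), tuple(periods)


def read_cases(
    source,
    axes: Sequence[str] = (),
    *,
    with_period: bool = True,
    regions: Sequence[str] | None = None,
    levels: Sequence[Sequence[str]] | None = None,
    periods: Sequence | None = None,
    ignore_extra: bool = False,
) -> StratifiedCounts:
    """Read a case file (``id count [period] covariates...``).

    With ``ignore_extra`` trailing covariate columns beyond the declared
    axes are dropped (their counts are aggregated).
    """
    axes = tuple(axes)
    n_fixed = 3 if with_period else 2
    rows = _parse_table(source, n_fixed, len(axes), "case file", ignore_extra)
    # normalize to (id, period, count, covs...) for the shared grid builder
    norm = []
    for row in rows:
        if with_period:
            norm.append([row[0], row[2], row[1], *row[3:]])
        else:
            norm.append([row[0], ALL_PERIODS, row[1], *row[2:]])
    if not with_period:
        periods = (ALL_PERIODS,)
    regions, levels, periods = _grid_from_rows(norm, axes, regions, levels, periods)
    period_lookup = {str(p): p for p in periods}
    records = []
    for row in norm:
        period = period_lookup.get(row[1])
        if period is None:
            raise ValueError(f"undeclared period {row[1]!r} in case file")
        records.append((row[0], tuple(row[3:]), period, int(row[2])))
    return StratifiedCounts.from_records(records, regions, axes, levels, periods)


def read_population(
    source,
    axes: Sequence[str] = (),
    *,
    regions: Sequence[str] | None = None,
    levels: Sequence[Sequence[str]] | None = None,
    periods: Sequence | None = None,
    ignore_extra: bool = False,
) -> StratifiedCounts:
    """Read a population file (``id period count covariates...``)."""
    axes = tuple(axes)
    rows = _parse_table(source, 3, len(axes), "population file", ignore_extra)
    norm = [[row[0], row[1], row[2], *row[3:]] for row in rows]
    regions, levels, periods = _grid_from_rows(norm, axes, regions, levels, periods)
    period_lookup = {str(p): p for p in periods}
    records = []
    for row in norm:
        period = period_lookup.get(row[1])
        if period is None:
            raise ValueError(f"undeclared period {row[1]!r} in population file")
        records.append((row[0], tuple(row[3:]), period, int(float(row[2]))))
    return StratifiedCounts.from_records(records, regions, axes, levels, periods)


def write_cases(counts: StratifiedCounts, dest) -> None:
    """Write nonzero cells in case-file format (``id count period covs``)."""
    stream, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(
        dest, (str, Path)
    ) else (dest, False)
    try:
        strata = counts.strata
        for i, region in enumerate(counts.regions):
            for s, stratum in enumerate(strata):
                for t, period in enumerate(counts.periods):
                    v = counts.values[i, s, t]
                    if v:
                        cov = " ".join(stratum)
                        line = f"{region} {v} {period}"
                        stream.write(f"{line} {cov}\n" if cov else f"{line}\n")
    finally:
        if close:
            stream.close()


def write_population(counts: StratifiedCounts, dest) -> None:
    """Write all cells in population-file format (``id period count covs``)."""
    stream, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(
        dest, (str, Path)
    ) else (dest, False)
    try:
        strata = counts.strata
        for i, region in enumerate(counts.regions):
            for s, stratum in enumerate(strata):
                for t, period in enumerate(counts.periods):
                    cov = " ".join(stratum)
                    line = f"{region} {period} {counts.values[i, s, t]}"
                    stream.write(f"{line} {cov}\n" if cov else f"{line}\n")
    finally:
        if close:
            stream.close()


def harmonize(
    cases: StratifiedCounts, population: StratifiedCounts
) -> StratifiedCounts:
    """Reindex *cases* onto *population*'s grid (missing cells become zero).

    Every case cell must exist in the population grid.
    """
    if cases.axes != population.axes:
        raise ValueError("cases and population declare different stratum axes")
    ridx = {r: i for i, r in enumerate(population.regions)}
    sidx = {s: i for i, s in enumerate(population.strata)}
    pidx = {p: i for i, p in enumerate(population.periods)}
    vals = np.zeros(
        (len(population.regions), population.n_strata, len(population.periods)),
        dtype=np.int64,
    )
    strata = cases.strata
    for i, region in enumerate(cases.regions):
        if region not in ridx:
            raise ValueError(f"case region {region!r} missing from population")
        for s, stratum in enumerate(strata):
            for t, period in enumerate(cases.periods):
                v = cases.values[i, s, t]
                if not v:
                    continue
                if stratum not in sidx:
                    raise ValueError(f"case stratum {stratum} missing from population")
                if period not in pidx:
                    raise ValueError(f"case period {period!r} missing from population")
                vals[ridx[region], sidx[stratum], pidx[period]] += v
    return StratifiedCounts(
        population.regions,
        population.axes,
        population.levels,
        population.periods,
        vals,
    )
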