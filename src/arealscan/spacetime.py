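"""Space-time scans over cylindrical windows.

Two statistics share the cylinder family:

* the space-time Poisson scan — the spatial statistic applied to (window x
  contiguous period interval) cylinders with per-cell expected counts; and
* the space-time permutation scan, whose expected counts are products of
  the spatial and temporal case marginals and whose null permutes the
  period labels of individual cases, so purely spatial clusters and purely
  temporal trends cannot trigger it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .registry import ExpectedCounts
from .scan import (
    ClusterResult,
    ReplicateDistribution,
    ScanConfig,
    Window,
    _greedy_no_overlap,
    _llr_array,
    attach_pvalues,
    membership_matrix,
    relative_risk,
)

__all__ = [
    "Cylinder",
    "SpaceTimeMarginals",
    "cylinders",
    "st_poisson_scan",
    "st_monte_carlo_null",
    "stp_expected",
    "stp_scan",
    "trend_artifact",
]


@dataclass(frozen=True)
class Cylinder:
    """A spatial window crossed with a contiguous period interval."""

    window: Window
    start: object  # period label (inclusive)
    end: object

    @property
    def members(self) -> tuple[str, ...]:
        return self.window.members

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)

    @property
    def center(self) -> str:
        return self.window.center


@dataclass(frozen=True)
class SpaceTimeMarginals:
    """Case marginals over space and time; sum(n_z) == sum(n_t) == N."""

    regions: tuple[str, ...]
    periods: tuple
    n_z: np.ndarray
    n_t: np.ndarray
    N: int

    def __post_init__(self) -> None:
        n_z = np.asarray(self.n_z, dtype=np.int64)
        n_t = np.asarray(self.n_t, dtype=np.int64)
        if n_z.shape != (len(self.regions),) or n_t.shape != (len(self.periods),):
            raise ValueError("marginal shapes do not match regions/periods")
        if n_z.sum() != self.N or n_t.sum() != self.N:
            raise ValueError("marginals must each sum to N")
        object.__setattr__(self, "n_z", n_z)
        object.__setattr__(self, "n_t", n_t)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, regions: Sequence[str], periods: Sequence
    ) -> "SpaceTimeMarginals":
        counts = np.asarray(counts)
        return cls(
            tuple(regions),
            tuple(periods),
            counts.sum(axis=1),
            counts.sum(axis=0),
            int(counts.sum()),
        )


def _interval_indices(n_periods: int, max_time_fraction: float) -> list[tuple[int, int]]:
    if not (0 < max_time_fraction <= 1.0):
        raise ValueError("max_time_fraction must be in (0, 1]")
    max_len = max(1, math.floor(max_time_fraction * n_periods))
    out = [
        (i, j)
        for length in range(1, max_len + 1)
        for i in range(n_periods - length + 1)
        for j in [i + length - 1]
    ]
    return out


def cylinders(
    windows: Sequence[Window],
    periods: Sequence,
    max_time_fraction: float = 0.5,
) -> list[Cylinder]:
    """Every (window x contiguous interval) pair within the temporal cap.

    The interval length cap is ``max(1, floor(max_time_fraction * n))`` so
    single-period cylinders always exist.
    """
    periods = tuple(periods)
    if not periods:
        raise ValueError("need at least one period")
    ivals = _interval_indices(len(periods), max_time_fraction)
    return [
        Cylinder(w, periods[i], periods[j]) for w in windows for (i, j) in ivals
    ]


def _cylinder_grid(cyls: Sequence[Cylinder], regions, periods):
    """Factor an arbitrary cylinder list into unique windows x intervals."""
    periods = tuple(periods)
    pidx = {p: i for i, p in enumerate(periods)}
    win_key = {}
    win_list: list[Window] = []
    ival_key = {}
    ival_list: list[tuple[int, int]] = []
    w_of = np.empty(len(cyls), dtype=np.int64)
    t_of = np.empty(len(cyls), dtype=np.int64)
    for ci, cyl in enumerate(cyls):
        k = frozenset(cyl.members)
        if k not in win_key:
            win_key[k] = len(win_list)
            win_list.append(cyl.window)
        w_of[ci] = win_key[k]
        iv = (pidx[cyl.start], pidx[cyl.end])
        if iv[0] > iv[1]:
            raise ValueError(f"cylinder interval reversed: {cyl.interval}")
        if iv not in ival_key:
            ival_key[iv] = len(ival_list)
            ival_list.append(iv)
        t_of[ci] = ival_key[iv]
    return win_list, ival_list, w_of, t_of


def _interval_sums(win_by_period: np.ndarray, ivals: Sequence[tuple[int, int]]):
    """Sum (n_win, n_periods[, ...]) arrays over each interval, via cumsum."""
    cs = np.cumsum(win_by_period, axis=1)
    zeros = np.zeros_like(cs[:, :1, ...])
    cs = np.concatenate([zeros, cs], axis=1)
    return [cs[:, j + 1, ...] - cs[:, i, ...] for (i, j) in ivals]


def st_poisson_scan(
    observed: np.ndarray,
    expected: ExpectedCounts,
    cyls: Sequence[Cylinder],
    config: ScanConfig = ScanConfig(),
) -> list[ClusterResult]:
    """Rank cylinders by the Poisson llr on per-cell expected counts.

    *observed* is a ``(n_regions, n_periods)`` count grid aligned with
    ``expected``.  With a single period this is exactly the purely spatial
    scan.  Secondary cylinders are reported under the same no-spatial-
    overlap rule as the spatial scan.
    """
    if not cyls:
        raise ValueError("cylinder list must be nonempty")
    obs = np.asarray(observed, dtype=float)
    E = expected.values
    N = expected.N
    if obs.shape != E.shape:
        raise ValueError("observed grid does not match expected grid")
    if abs(E.sum() - N) > 1e-6 * max(N, 1):
        raise ValueError("expected counts are not conditioned on the total")
    if int(round(obs.sum())) != N:
        raise ValueError("observed total != conditioning total N")
    win_list, ival_list, w_of, t_of = _cylinder_grid(
        cyls, expected.regions, expected.periods
    )
    M = membership_matrix(win_list, expected.regions)
    n_wt = _interval_sums(M @ obs, ival_list)  # list over intervals, (n_win,)
    E_wt = _interval_sums(M @ E, ival_list)
    llr_wt = [
        _llr_array(n_vec, np.maximum(e_vec, 1e-300), N)
        for n_vec, e_vec in zip(n_wt, E_wt)
    ]
    entries = []
    for ci, cyl in enumerate(cyls):
        llr = float(llr_wt[t_of[ci]][w_of[ci]])
        if llr > 0:
            entries.append(
                (llr, cyl, float(n_wt[t_of[ci]][w_of[ci]]), float(E_wt[t_of[ci]][w_of[ci]]))
            )
    entries.sort(key=_st_sort_key)
    results = []
    for rank, (llr, cyl, n, e) in enumerate(_greedy_no_overlap(entries), start=1):
        results.append(
            ClusterResult(
                window=cyl,
                members=cyl.members,
                n=int(round(n)),
                expected=e,
                N=N,
                llr=llr,
                rr=relative_risk(n, e, N),
                rank=rank,
                interval=cyl.interval,
            )
        )
    return results


def _st_sort_key(entry):
    llr, cyl, *_ = entry
    length = 0
    if hasattr(cyl, "interval"):
        s, e = cyl.interval
        try:
            length = e - s
        except TypeError:
            length = 0
    return (-llr, len(cyl.members), length, cyl.center, cyl.members, str(cyl.interval))


def st_monte_carlo_null(
    expected: ExpectedCounts,
    cyls: Sequence[Cylinder],
    R: int = 999,
    seed: int | None = None,
) -> ReplicateDistribution:
    """Conditional multinomial null over the (region x period) grid."""
    if R < 1:
        raise ValueError("R must be >= 1")
    E = expected.values
    N = expected.N
    if N == 0:
        return ReplicateDistribution(np.zeros(R), seed, R)
    nr, nt = E.shape
    win_list, ival_list, _, _ = _cylinder_grid(cyls, expected.regions, expected.periods)
    M = membership_matrix(win_list, expected.regions)
    E_wt = _interval_sums(M @ E, ival_list)
    rng = np.random.default_rng(seed)
    p = (E / E.sum()).ravel()
    maxima = np.empty(R)
    chunk = max(1, int(4e6 // max(len(win_list) * nt, 1)))
    done = 0
    while done < R:
        m = min(chunk, R - done)
        counts = rng.multinomial(N, p, size=m).astype(float)  # (m, nr*nt)
        grid = counts.reshape(m, nr, nt)
        W = np.einsum("wr,mrt->wtm", M, grid)
        n_by_ival = _interval_sums(W, ival_list)  # list of (n_win, m)
        best = np.zeros(m)
        for n_mat, e_vec in zip(n_by_ival, E_wt):
            llr = _llr_array(n_mat, e_vec[:, None], N)
            best = np.maximum(best, llr.max(axis=0))
        maxima[done : done + m] = best
        done += m
    return ReplicateDistribution(maxima, seed, R)


def run_st_poisson(
    observed: np.ndarray,
    expected: ExpectedCounts,
    cyls: Sequence[Cylinder],
    config: ScanConfig = ScanConfig(),
) -> tuple[list[ClusterResult], ReplicateDistribution]:
    results = st_poisson_scan(observed, expected, cyls, config)
    dist = st_monte_carlo_null(expected, cyls, R=config.replicates, seed=config.seed)
    return attach_pvalues(results, dist, gumbel=config.gumbel), dist


# ----------------------------------------------------------------------------
# space-time permutation scan
# ----------------------------------------------------------------------------


def stp_expected(marginals: SpaceTimeMarginals, cyl: Cylinder) -> float:
    """Product-of-marginals expectation summed over a cylinder's cells.

    ``mu_A = sum over (z, t) in A of n_z * n_t / N``.
    """
    if marginals.N == 0:
        raise ValueError("no cases: marginals sum to zero")
    ridx = {r: i for i, r in enumerate(marginals.regions)}
    pidx = {p: i for i, p in enumerate(marginals.periods)}
    zsum = sum(int(marginals.n_z[ridx[r]]) for r in cyl.members)
    i, j = pidx[cyl.start], pidx[cyl.end]
    tsum = int(marginals.n_t[i : j + 1].sum())
    return zsum * tsum / marginals.N


def stp_scan(
    cases: np.ndarray,
    regions: Sequence[str],
    periods: Sequence,
    cyls: Sequence[Cylinder],
    R: int = 999,
    seed: int | None = None,
    gumbel: bool = False,
) -> tuple[list[ClusterResult], ReplicateDistribution]:
    """Space-time permutation scan on a ``(n_regions, n_periods)`` count grid.

    Cylinders are scored by the Poisson generalized llr with the expected
    count replaced by the product-of-marginals ``mu``.  Null replicates
    permute the period labels of individual cases uniformly, which holds
    both marginals fixed in every replicate, so the scan responds only to
    space-time interaction.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    counts = np.asarray(cases)
    if np.any(counts < 0):
        raise ValueError("case counts must be nonnegative")
    regions = tuple(regions)
    periods = tuple(periods)
    nr, nt = len(regions), len(periods)
    if counts.shape != (nr, nt):
        raise ValueError("case grid shape mismatch")
    marg = SpaceTimeMarginals.from_counts(counts, regions, periods)
    N = marg.N
    win_list, ival_list, w_of, t_of = _cylinder_grid(cyls, regions, periods)
    M = membership_matrix(win_list, regions)
    # mu depends only on the marginals, which every permutation preserves
    z_w = M @ marg.n_z.astype(float)
    t_sums = _interval_sums(marg.n_t[None, :].astype(float), ival_list)
    mu_wt = [z_w * float(ts[0]) / N if N else z_w * 0.0 for ts in t_sums]
    n_wt = _interval_sums(M @ counts.astype(float), ival_list)
    llr_wt = [
        _llr_array(n_vec, np.maximum(mu_vec, 1e-300), N)
        for n_vec, mu_vec in zip(n_wt, mu_wt)
    ]
    entries = []
    for ci, cyl in enumerate(cyls):
        llr = float(llr_wt[t_of[ci]][w_of[ci]])
        if llr > 0:
            entries.append(
                (llr, cyl, float(n_wt[t_of[ci]][w_of[ci]]), float(mu_wt[t_of[ci]][w_of[ci]]))
            )
    entries.sort(key=_st_sort_key)
    results = []
    for rank, (llr, cyl, n, mu) in enumerate(_greedy_no_overlap(entries), start=1):
        results.append(
            ClusterResult(
                window=cyl,
                members=cyl.members,
                n=int(round(n)),
                expected=mu,
                N=N,
                llr=llr,
                rr=relative_risk(n, mu, N) if mu > 0 else math.inf,
                rank=rank,
                interval=cyl.interval,
            )
        )
    # permutation null
    rng = np.random.default_rng(seed)
    maxima = np.zeros(R)
    if N > 0:
        zone_of_case = np.repeat(np.arange(nr), counts.sum(axis=1))
        t_labels = np.repeat(
            np.tile(np.arange(nt), nr), counts.ravel()
        )  # period label per case, region-major
        mu_cols = [mu[:, None] for mu in mu_wt]
        chunk = max(1, int(2e6 // max(len(win_list) * nt, 1)))
        done = 0
        while done < R:
            m = min(chunk, R - done)
            perms = rng.permuted(np.tile(t_labels, (m, 1)), axis=1)
            flat = zone_of_case[None, :] * nt + perms
            grid = np.zeros((m, nr * nt), dtype=np.int64)
            rows = np.repeat(np.arange(m), N)
            np.add.at(grid, (rows, flat.ravel()), 1)
            grid = grid.reshape(m, nr, nt).astype(float)
            W = np.einsum("wr,mrt->wtm", M, grid)
            n_by_ival = _interval_sums(W, ival_list)
            best = np.zeros(m)
            for n_mat, mu_col in zip(n_by_ival, mu_cols):
                llr = _llr_array(n_mat, np.maximum(mu_col, 1e-300), N)
                best = np.maximum(best, llr.max(axis=0))
            maxima[done : done + m] = best
            done += m
    dist = ReplicateDistribution(maxima, seed, R)
    return attach_pvalues(results, dist, gumbel=gumbel), dist


def trend_artifact(
    st_results: Sequence[ClusterResult],
    stp_results: Sequence[ClusterResult],
    alpha: float = 0.05,
) -> bool:
    """True when the Poisson space-time scan flags a cluster the permutation
    scan does not confirm — i.e. the space-time signal is attributable to a
    statewide trend rather than a genuine interaction cluster."""
    st_sig = any(r.p_mc is not None and r.p_mc < alpha for r in st_results)
    stp_sig = any(r.p_mc is not None and r.p_mc < alpha for r in stp_results)
    return st_sig and not stp_sig
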