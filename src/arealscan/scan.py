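"""Purely spatial Poisson scan statistic over circular windows.

The statistic for a window with ``n`` observed and ``E`` expected cases out
of a study total ``N`` is the log likelihood ratio

    ``llr = n*log(n/E) + (N-n)*log((N-n)/(N-E))``   if ``n > E``, else 0,

maximized over a family of candidate windows.  Significance is assessed by
conditional Monte Carlo: the fixed total ``N`` is redistributed across
regions with probabilities ``E_i/N``, every window is rescored, and the
replicate maxima form the null distribution of the scan statistic.  A
Gumbel extreme-value fit to the replicate maxima provides a smoother tail
p-value than the Monte Carlo rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geo import RegionMap, distances
from .registry import ExpectedCounts

__all__ = [
    "Window",
    "ClusterResult",
    "ReplicateDistribution",
    "ScanConfig",
    "circular_windows",
    "poisson_llr",
    "relative_risk",
    "scan",
    "monte_carlo_null",
    "mc_pvalue",
    "gumbel_pvalue",
    "attach_pvalues",
    "run_scan",
]

EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class Window:
    """A circular candidate cluster: a center region plus its nearest neighbors.

    ``members`` are exactly the ``radius_rank`` regions closest to the
    center (the center itself first).
    """

    members: tuple[str, ...]
    center: str
    radius_rank: int

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise ValueError("window must be nonempty")
        if len(set(members)) != len(members):
            raise ValueError("duplicate members in window")
        if self.center not in members:
            raise ValueError("window center must be a member")
        if self.radius_rank != len(members):
            raise ValueError("radius_rank must equal the member count")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterResult:
    """A scored (and optionally significance-tested) cluster."""

    window: object
    members: tuple[str, ...]
    n: int
    expected: float
    N: int
    llr: float
    rr: float
    p_mc: float | None = None
    p_gumbel: float | None = None
    rank: int | None = None
    interval: tuple | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.N):
            raise ValueError("observed count outside [0, N]")
        if self.expected < 0 or self.expected > self.N + 1e-9:
            raise ValueError("expected count outside [0, N]")
        if self.llr < 0:
            raise ValueError("llr must be nonnegative")


@dataclass(frozen=True)
class ReplicateDistribution:
    """Maximum llr per Monte Carlo replicate."""

    max_llr: np.ndarray
    seed: int | None
    R: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.max_llr, dtype=float)
        if vals.shape != (self.R,):
            raise ValueError("replicate vector length must equal R")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("replicate maxima must be finite and nonnegative")
        vals.setflags(write=False)
        object.__setattr__(self, "max_llr", vals)


@dataclass(frozen=True)
class ScanConfig:
    """Analysis parameters shared by the spatial and space-time scans."""

    max_population_fraction: float = 0.5
    replicates: int = 999
    seed: int | None = None
    alpha: float = 0.05
    secondary_rule: str = "no-overlap"
    excluded_regions: tuple[str, ...] = ()
    max_time_fraction: float = 0.5
    gumbel: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.max_population_fraction <= 0.5):
            raise ValueError("max_population_fraction must be in (0, 0.5]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.secondary_rule != "no-overlap":
            raise ValueError("only the no-overlap secondary rule is supported")
        if not (0 < self.max_time_fraction <= 0.5) and self.max_time_fraction != 1.0:
            raise ValueError("max_time_fraction must be in (0, 0.5] (or 1.0)")
        object.__setattr__(self, "excluded_regions", tuple(self.excluded_regions))


# ----------------------------------------------------------------------------
# statistic primitives
# ----------------------------------------------------------------------------


def poisson_llr(n: float, E: float, N: float) -> float:
    """Poisson scan log likelihood ratio for one window.

    Zero whenever ``n <= E`` (the high-rate indicator).  Terms with a zero
    count use the convention ``0*log(0/x) = 0``.
    """
    if n < 0 or n > N:
        raise ValueError("need 0 <= n <= N")
    if E <= 0 and n > 0:
        raise ValueError("E must be positive when the window has cases")
    if n <= E:
        return 0.0
    out = n * math.log(n / E)
    if N - n > 0:
        out += (N - n) * math.log((N - n) / (N - E))
    return out


def _llr_array(n: np.ndarray, E: np.ndarray, N: float) -> np.ndarray:
    """Vectorized llr; assumes 0 <= n <= N and E > 0 elementwise."""
    n = np.asarray(n, dtype=float)
    E = np.asarray(E, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = n * np.log(np.where(n > 0, n / E, 1.0))
        rest = N - n
        t2 = rest * np.log(np.where(rest > 0, rest / (N - E), 1.0))
    out = t1 + t2
    return np.where(n > E, out, 0.0)


def relative_risk(n: float, E: float, N: float) -> float:
    """Rate inside the window relative to the rate outside it.

    ``(n/E) / ((N-n)/(N-E))``; returns ``inf`` when every case is inside
    (``n == N``) and 0 when the window is empty.
    """
    if n < 0 or n > N:
        raise ValueError("need 0 <= n <= N")
    if n == 0:
        return 0.0
    if E <= 0:
        raise ValueError("E must be positive when the window has cases")
    if n == N:
        return math.inf
    return (n / E) / ((N - n) / (N - E))


# ----------------------------------------------------------------------------
# window construction
# ----------------------------------------------------------------------------


def circular_windows(
    region_map: RegionMap,
    weights: Sequence[float] | np.ndarray,
    max_fraction: float = 0.5,
) -> list[Window]:
    """All circular candidate windows, deduplicated.

    For every center the nested window sequence {center}, {center + nearest
    neighbor}, ... is emitted, truncated once the cumulative weight
    (population at risk) would exceed ``max_fraction`` of the total.  A
    center whose own weight exceeds the cap still yields its singleton
    window.  Distance ties are broken by lexicographic region id.
    """
    if not (0 < max_fraction <= 0.5):
        raise ValueError("max_fraction must be in (0, 0.5]")
    w = np.asarray(weights, dtype=float)
    if w.shape != (region_map.n_regions,):
        raise ValueError("weights must align with the region list")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    cap = max_fraction * total
    dm = distances(region_map).values
    ids = region_map.region_ids
    seen: set[frozenset] = set()
    out: list[Window] = []
    for ci in sorted(range(len(ids)), key=lambda i: ids[i]):
        order = sorted(range(len(ids)), key=lambda j: (dm[ci, j], ids[j]))
        # center sorts first since its distance is 0
        cum = 0.0
        members: list[str] = []
        for rank, j in enumerate(order, start=1):
            cum += w[j]
            members.append(ids[j])
            if rank > 1 and cum > cap:
                break
            key = frozenset(members)
            if key not in seen:
                seen.add(key)
                out.append(Window(tuple(members), ids[ci], rank))
            if cum > cap:
                break
    return out


def membership_matrix(
    windows: Sequence, regions: Sequence[str]
) -> np.ndarray:
    """Dense 0/1 matrix of shape (n_windows, n_regions)."""
    idx = {r: i for i, r in enumerate(regions)}
    M = np.zeros((len(windows), len(regions)), dtype=float)
    for wi, win in enumerate(windows):
        for r in win.members:
            M[wi, idx[r]] = 1.0
    return M


# ----------------------------------------------------------------------------
# scanning and ranking
# ----------------------------------------------------------------------------


def _sort_key(entry):
    # llr descending, then smaller window, then lexicographic center id,
    # then member tuple for full determinism
    llr, win, *_ = entry
    size = len(win.members)
    center = getattr(win, "center", getattr(win, "anchor", win.members[0]))
    return (-llr, size, center, win.members)


def _greedy_no_overlap(ranked):
    """Yield entries whose member sets are disjoint from all yielded so far."""
    used: set[str] = set()
    for entry in ranked:
        members = entry[1].members
        if used.isdisjoint(members):
            used.update(members)
            yield entry


def scan(
    observed: Sequence[float] | np.ndarray,
    expected: ExpectedCounts,
    windows: Sequence[Window],
    config: ScanConfig = ScanConfig(),
) -> list[ClusterResult]:
    """Score every window and report ranked, non-overlapping clusters.

    Only windows with ``llr > 0`` are reported; the rank-1 result is the
    most likely cluster and lower ranks are secondary clusters that share
    no region with any higher-ranked cluster.  p-values are not attached
    here (see :func:`monte_carlo_null` / :func:`attach_pvalues`).
    """
    if not windows:
        raise ValueError("window list must be nonempty")
    E = expected.region_totals()
    N = expected.N
    if abs(E.sum() - N) > 1e-6 * max(N, 1):
        raise ValueError("expected counts are not conditioned on the total (sum E != N)")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != E.shape:
        raise ValueError("observed counts must align with expected.regions")
    if int(round(obs.sum())) != N:
        raise ValueError(f"observed total {obs.sum()} != conditioning total N={N}")
    M = membership_matrix(windows, expected.regions)
    n_w = M @ obs
    E_w = M @ E
    llr = _llr_array(n_w, E_w, N)
    entries = [
        (float(llr[i]), windows[i], float(n_w[i]), float(E_w[i]))
        for i in range(len(windows))
        if llr[i] > 0
    ]
    entries.sort(key=_sort_key)
    results = []
    for rank, (l, win, n, e) in enumerate(_greedy_no_overlap(entries), start=1):
        results.append(
            ClusterResult(
                window=win,
                members=tuple(win.members),
                n=int(round(n)),
                expected=e,
                N=N,
                llr=l,
                rr=relative_risk(n, e, N),
                rank=rank,
                interval=getattr(win, "interval", None),
            )
        )
    return results


def monte_carlo_null(
    expected: ExpectedCounts,
    windows: Sequence[Window],
    R: int = 999,
    seed: int | None = None,
) -> ReplicateDistribution:
    """Conditional Monte Carlo null distribution of the scan maximum.

    Each replicate redistributes the fixed total ``N`` across regions as a
    multinomial with probabilities ``E_i/N``, rescans every window, and
    records the maximum llr.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    E = expected.region_totals()
    N = expected.N
    if abs(E.sum() - N) > 1e-6 * max(N, 1):
        raise ValueError("expected counts are not conditioned on the total")
    if N == 0:
        return ReplicateDistribution(np.zeros(R), seed, R)
    rng = np.random.default_rng(seed)
    p = E / E.sum()
    M = membership_matrix(windows, expected.regions)
    E_w = (M @ E)[:, None]
    maxima = np.empty(R)
    chunk = max(1, min(R, int(4e6 // max(len(windows), 1)) or 1))
    done = 0
    while done < R:
        m = min(chunk, R - done)
        counts = rng.multinomial(N, p, size=m).T.astype(float)  # (n_regions, m)
        n_w = M @ counts
        llr = _llr_array(n_w, np.broadcast_to(E_w, n_w.shape), N)
        maxima[done : done + m] = llr.max(axis=0)
        done += m
    return ReplicateDistribution(maxima, seed, R)


def mc_pvalue(observed_llr: float, dist: ReplicateDistribution) -> float:
    """Monte Carlo rank p-value ``(1 + #{replicates >= observed}) / (R + 1)``."""
    if dist.R < 1:
        raise ValueError("empty replicate distribution")
    exceed = int(np.count_nonzero(dist.max_llr >= observed_llr))
    return (1 + exceed) / (dist.R + 1)


def gumbel_pvalue(observed_llr: float, dist: ReplicateDistribution) -> float:
    """Gumbel tail p-value from a method-of-moments fit to replicate maxima.

    ``beta = s*sqrt(6)/pi``, ``mu = m - gamma*beta`` with ``m``/``s`` the
    replicate mean and standard deviation; the p-value is the Gumbel upper
    tail at the observed llr, clipped to the open interval (0, 1).
    """
    if dist.R < 10:
        raise ValueError("need at least 10 replicates for a Gumbel fit")
    m = float(np.mean(dist.max_llr))
    s = float(np.std(dist.max_llr, ddof=1))
    if s <= 0:
        raise ValueError(
            "replicate maxima have zero variance; use the Monte Carlo p-value"
        )
    beta = s * math.sqrt(6.0) / math.pi
    mu = m - EULER_GAMMA * beta
    z = (observed_llr - mu) / beta
    # upper tail 1 - exp(-exp(-z)), computed stably
    p = -math.expm1(-math.exp(-z)) if z > -30 else 1.0
    tiny = math.nextafter(0.0, 1.0)
    return min(max(p, tiny), 1.0 - 1e-16)


def attach_pvalues(
    results: Sequence[ClusterResult],
    dist: ReplicateDistribution,
    gumbel: bool = False,
) -> list[ClusterResult]:
    """Return results with Monte Carlo (and optionally Gumbel) p-values set.

    Every cluster, whatever its rank, is compared against the distribution
    of the replicate *maximum*, which is what controls for the multiplicity
    of candidate windows.
    """
    out = []
    for res in results:
        out.append(
            replace(
                res,
                p_mc=mc_pvalue(res.llr, dist),
                p_gumbel=gumbel_pvalue(res.llr, dist) if gumbel else None,
            )
        )
    return out


def run_scan(
    observed,
    expected: ExpectedCounts,
    windows: Sequence[Window],
    config: ScanConfig = ScanConfig(),
) -> tuple[list[ClusterResult], ReplicateDistribution]:
    """Score, rank, run the Monte Carlo null and attach p-values."""
    results = scan(observed, expected, windows, config)
    dist = monte_carlo_null(expected, windows, R=config.replicates, seed=config.seed)
    return attach_pvalues(results, dist, gumbel=config.gumbel), dist


def significant(results: Sequence[ClusterResult], alpha: float = 0.05) -> list[ClusterResult]:
    """Clusters whose Monte Carlo p-value is below *alpha*."""
    return [r for r in results if r.p_mc is not None and r.p_mc < alpha]
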