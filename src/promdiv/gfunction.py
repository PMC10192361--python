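"""G-function test for non-random accumulation of events along an alignment.

Given the sorted positions of ``n`` events (e.g. indel starts) in an
alignment of ``L`` columns, the G function measures, at each event, the
difference between the relative rank of the event and its relative position:

    G_j = j / n - site_j / L,   j = 1..n,  site_j = position_j + 1

Under a uniform scatter of events the trajectory hovers around zero; a
cluster of events produces a run of positive increments dG. Significance is
assessed against a Monte Carlo null in which ``n`` distinct sites are drawn
uniformly without replacement from the ``L`` columns. The global statistic
is the maximal increase of G over any event interval (a one-sided scan
statistic, clamped at zero), with G_0 = 0 at a virtual site 0 so a leading
cluster is detectable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_REPLICATES = 100_000

__all__ = [
    "GTrajectory",
    "g_function",
    "max_increase",
    "monte_carlo_null",
    "exhaustive_null",
    "g_test",
    "DEFAULT_REPLICATES",
]


@dataclass
class GTrajectory:
    """G-function trajectory with optional Monte Carlo significance.

    ``x`` holds the 0-based event columns; ``G`` and ``dG`` the trajectory
    and its increments (``dG[0]`` is measured from the virtual G_0 = 0).
    ``stretches`` are half-open column intervals flagged as significant
    runs of clustered events.
    """

    L: int
    n: int
    x: np.ndarray
    G: np.ndarray
    dG: np.ndarray
    statistic: float | None = None
    p_global: float | None = None
    null_q95: float | None = None
    stretches: list[tuple[int, int]] = field(default_factory=list)
    gap_p: np.ndarray | None = None  # per-increment Monte Carlo p-values

    def to_dict(self) -> dict:
        d = {
            "L": self.L,
            "n": self.n,
            "statistic": self.statistic,
            "p_global": self.p_global,
            "null_q95": self.null_q95,
            "stretches": [list(s) for s in self.stretches],
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_frame(self):
        """Cumulative-G curve table: one row per event (j, site, G, dG)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "j": np.arange(1, self.n + 1),
                "site": self.x + 1,
                "G": self.G,
                "dG": self.dG,
            }
        )


def g_function(x, L: int) -> GTrajectory:
    """Compute the G trajectory for sorted 0-based event positions ``x``."""
    x = np.asarray(x, dtype=np.int64)
    n = len(x)
    if n == 0:
        raise ValueError("need at least one event position")
    if n > L:
        raise ValueError(f"n={n} events cannot exceed L={L} columns")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing (sorted, no duplicates)")
    if x[0] < 0 or x[-1] >= L:
        raise ValueError(f"positions must lie in [0, {L})")
    sites = x + 1  # 1-based site index
    G = np.arange(1, n + 1) / n - sites / L
    dG = np.diff(G, prepend=0.0)
    return GTrajectory(L=L, n=n, x=x, G=G, dG=dG)


def max_increase(G: np.ndarray) -> float:
    """Maximal increase of G over any event interval, clamped at zero.

    Evaluates max over 0 <= j < k <= n of G_k - G_j with G_0 = 0.
    """
    Gfull = np.concatenate(([0.0], np.asarray(G, dtype=float)))
    runmin = np.minimum.accumulate(Gfull[:-1])
    return float(max(0.0, np.max(Gfull[1:] - runmin)))


def _batch_statistics(sites: np.ndarray, n: int, L: int) -> np.ndarray:
    """Scan statistic for a (B, n) matrix of sorted 1-based sites."""
    ranks = np.arange(1, n + 1) / n
    G = ranks[None, :] - sites / L
    Gfull = np.concatenate([np.zeros((G.shape[0], 1)), G], axis=1)
    runmin = np.minimum.accumulate(Gfull[:, :-1], axis=1)
    stats = np.max(Gfull[:, 1:] - runmin, axis=1)
    return np.maximum(stats, 0.0)


def monte_carlo_null(
    n: int,
    L: int,
    B: int = DEFAULT_REPLICATES,
    seed: int | np.random.Generator | None = None,
    chunk: int = 2048,
) -> np.ndarray:
    """Null distribution of the scan statistic under uniform event placement.

    Each replicate draws ``n`` distinct sites without replacement from the
    ``L`` alignment columns. Returns ``B`` statistic values.
    """
    if not (1 <= n <= L):
        raise ValueError(f"need 1 <= n <= L, got n={n}, L={L}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(B)
    done = 0
    while done < B:
        c = min(chunk, B - done)
        # rank the first n of a random permutation via argpartition on uniforms
        u = rng.random((c, L))
        idx = np.argpartition(u, n - 1, axis=1)[:, :n] if n < L else np.tile(np.arange(L), (c, 1))
        sites = np.sort(idx, axis=1) + 1
        out[done : done + c] = _batch_statistics(sites, n, L)
        done += c
    return out


def exhaustive_null(n: int, L: int, limit: int = 200_000) -> np.ndarray:
    """Exact null: the statistic for every one of the C(L, n) site subsets."""
    from math import comb

    if not (1 <= n <= L):
        raise ValueError(f"need 1 <= n <= L, got n={n}, L={L}")
    total = comb(L, n)
    if total > limit:
        raise ValueError(f"C({L},{n}) = {total} exceeds limit {limit}")
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(1, L + 1), n)),
        dtype=np.int64,
        count=total * n,
    ).reshape(total, n)
    return _batch_statistics(combos, n, L)


def _interval_matrix(G: np.ndarray) -> np.ndarray:
    """M[j, k] = G_k - G_j for 0 <= j < k <= n (else -inf), with G_0 = 0."""
    Gfull = np.concatenate(([0.0], G))
    m = Gfull[None, :] - Gfull[:, None]
    return np.where(np.triu(np.ones_like(m, dtype=bool), k=1), m, -np.inf)


def _call_stretches(
    traj: GTrajectory, threshold: float, alpha_hit: bool
) -> list[tuple[int, int]]:
    """Greedy non-overlapping stretch calling.

    The maximal-excess interval is reported whenever the global test rejects;
    further disjoint intervals are added while their G-excess exceeds
    ``threshold`` (the null 95th percentile).
    """
    if not alpha_hit:
        return []
    m = _interval_matrix(traj.G)
    stretches: list[tuple[int, int]] = []
    first = True
    while True:
        j, k = np.unravel_index(np.argmax(m), m.shape)
        val = m[j, k]
        if not np.isfinite(val):
            break
        if not first and val <= threshold:
            break
        # interval (j, k] covers events of rank j+1 .. k -> columns x[j] .. x[k-1]
        stretches.append((int(traj.x[j]), int(traj.x[k - 1]) + 1))
        # invalidate every interval (a, b] overlapping ranks j+1..k
        m[:k, j + 1 :] = -np.inf
        first = False
    stretches.sort()
    return stretches


def _gap_pvalues(
    traj: GTrajectory, B: int, seed: int | np.random.Generator | None
) -> np.ndarray:
    """Per-increment one-sided Monte Carlo p-values for each observed dG.

    Spacings of uniform order statistics are exchangeable, so null
    increments pooled across ranks share the marginal distribution of any
    single dG_j; each observed increment is referred to that pooled null.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, L = traj.n, traj.L
    reps = max(1, B // max(n, 1))
    u = rng.random((reps, L))
    idx = np.argpartition(u, n - 1, axis=1)[:, :n] if n < L else np.tile(np.arange(L), (reps, 1))
    sites = np.sort(idx, axis=1) + 1
    G = np.arange(1, n + 1) / n - sites / L
    null_dg = np.diff(G, prepend=0.0, axis=1).ravel()
    obs = traj.dG[:, None]
    hits = np.sum(null_dg[None, :] >= obs - 1e-12, axis=1)
    return (1 + hits) / (1 + null_dg.size)


def g_test(
    x,
    L: int,
    B: int = DEFAULT_REPLICATES,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    exhaustive: bool = False,
) -> GTrajectory:
    """Full G-function test: trajectory, Monte Carlo p-value and stretches.

    ``p_global`` uses the add-one estimator (1 + #{null >= observed}) /
    (1 + B), which never returns 0. With ``exhaustive=True`` the null is the
    complete enumeration of site subsets (feasible only for tiny C(L, n)),
    and the p-value is the exact tail proportion.
    """
    traj = g_function(x, L)
    traj.statistic = max_increase(traj.G)
    if exhaustive:
        null = exhaustive_null(traj.n, L)
        traj.p_global = float(np.mean(null >= traj.statistic - 1e-12))
    else:
        null = monte_carlo_null(traj.n, L, B=B, seed=seed)
        traj.p_global = float((1 + np.sum(null >= traj.statistic - 1e-12)) / (1 + len(null)))
    traj.null_q95 = float(np.quantile(null, 0.95))
    traj.gap_p = _gap_pvalues(traj, B=min(B, 5000), seed=seed)
    traj.stretches = _call_stretches(
        traj, threshold=traj.null_q95, alpha_hit=traj.p_global <= alpha
    )
    return traj
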