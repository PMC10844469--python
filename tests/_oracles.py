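"""Independent brute-force / numerical oracles used by the test suite.

Everything here is deliberately written without reference to the package's
own implementations: a finite-volume radial diffusion solver, exhaustive
enumeration of resampling nulls, and O(n^2) spatial brute force.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import solve_banded
from scipy.stats import binom, rankdata


# --------------------------------------------------------------------------
# radial diffusion around a continuous point source above a reflecting plane
# --------------------------------------------------------------------------

class RadialDiffusionOracle:
    """Finite-volume solver for spherically symmetric diffusion around a
    continuous point source.

    The dispensing problem (source at height h over a reflecting plane,
    observed on the plane at in-plane distance r) maps to free-space
    diffusion from a source of doubled strength, observed at the 3-D
    distance sqrt(r^2 + h^2).  Works in um / s / nM units.
    """

    def __init__(self, source_nM_um3_per_s: float, diffusivity_um2_per_s: float,
                 r_max_um: float = 1500.0, dr_um: float = 2.0):
        self.S = source_nM_um3_per_s
        self.D = diffusivity_um2_per_s
        self.edges = np.arange(0.0, r_max_um + dr_um, dr_um)
        self.centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        self.volumes = 4.0 / 3.0 * np.pi * (self.edges[1:] ** 3 - self.edges[:-1] ** 3)
        self.face_areas = 4.0 * np.pi * self.edges[1:-1] ** 2  # interior faces
        self.dr = dr_um

    def steady_state(self) -> np.ndarray:
        """Solve the steady balance (flux divergence = source) directly."""
        m = self.centers.size
        g = self.D * self.face_areas / self.dr  # conductance across each interior face
        sub = np.zeros(m)   # A[i, i-1]
        diag = np.zeros(m)  # A[i, i]
        sup = np.zeros(m)   # A[i, i+1]
        rhs = np.zeros(m)
        rhs[0] = -self.S
        for i in range(m):
            if i > 0:
                sub[i] = g[i - 1]
                diag[i] -= g[i - 1]
            if i < m - 1:
                sup[i] = g[i]
                diag[i] -= g[i]
            else:
                # outer face held at C = 0 (far-field sink)
                g_out = self.D * 4.0 * np.pi * self.edges[-1] ** 2 / (self.dr / 2.0)
                diag[i] -= g_out
        ab = np.zeros((3, m))
        ab[0, 1:] = sup[:-1]
        ab[1, :] = diag
        ab[2, :-1] = sub[1:]
        return solve_banded((1, 1), ab, rhs)

    def transient(self, t_on: float, t_total: float, dt: float | None = None) -> np.ndarray:
        """Explicit stepping: source on for t_on seconds, observed at t_total."""
        if dt is None:
            dt = 0.2 * self.dr**2 / self.D
        c = np.zeros(self.centers.size)
        g = self.D * self.face_areas / self.dr
        t = 0.0
        while t < t_total - 1e-12:
            step = min(dt, t_total - t)
            flux = g * (c[:-1] - c[1:])  # outward flux across interior faces
            dc = np.zeros_like(c)
            dc[:-1] -= flux
            dc[1:] += flux
            if t < t_on:
                dc[0] += self.S
            c = c + step * dc / self.volumes
            t += step
        return c

    def at(self, profile: np.ndarray, r_um) -> np.ndarray:
        return np.interp(np.asarray(r_um, dtype=float), self.centers, profile)


def oracle_for_conditions(cond, r_max_um: float = 1500.0, dr_um: float = 2.0):
    """Build the oracle matching a DispenseConditions (image-doubled source)."""
    source = 2.0 * cond.flow_m3_per_s * cond.c0_nM * 1e18  # m^3 -> um^3
    return RadialDiffusionOracle(
        source_nM_um3_per_s=source,
        diffusivity_um2_per_s=cond.diffusivity_m2_per_s * 1e12,
        r_max_um=r_max_um,
        dr_um=dr_um,
    )


# --------------------------------------------------------------------------
# resampling enumeration oracles
# --------------------------------------------------------------------------

def exceedance_distribution_exact(pool: np.ndarray, n_target: int) -> dict[int, float]:
    """Exact law of the with-replacement resampled activated count, by full
    product enumeration over pool^n_target sequences."""
    pool = np.asarray(pool).astype(int)
    counts: dict[int, int] = {}
    total = 0
    for seq in itertools.product(pool, repeat=n_target):
        k = int(sum(seq))
        counts[k] = counts.get(k, 0) + 1
        total += 1
    return {k: v / total for k, v in counts.items()}


def exceedance_tail_binomial(pool_positive: int, pool_size: int, n_target: int,
                             observed_count: int) -> float:
    """P(resampled count >= observed) in closed form: draws are iid
    Bernoulli(pool_positive / pool_size)."""
    return float(binom.sf(observed_count - 1, n_target, pool_positive / pool_size))


def anova_p_bruteforce(groups) -> float:
    """Exhaustive permutation p for the between-group SS statistic, by
    brute force over *all* orderings of the pooled values."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    values = np.concatenate(arrays)
    sizes = [a.size for a in arrays]

    def stat(vals):
        grand = np.mean(vals)
        ss = 0.0
        start = 0
        for n in sizes:
            ss += n * (np.mean(vals[start:start + n]) - grand) ** 2
            start += n
        return ss

    obs = stat(values)
    tol = 1e-12 * max(1.0, abs(obs))
    total = 0
    extreme = 0
    for perm in itertools.permutations(values):
        total += 1
        if stat(np.array(perm)) >= obs - tol:
            extreme += 1
    return extreme / total


def rank_sum_p_bruteforce(a, b) -> float:
    """Two-sided rank-sum p by enumerating all choices of group-A ranks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na, n = a.size, pooled.size
    mean = na * (n + 1) / 2.0
    obs = abs(ranks[:na].sum() - mean)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        if abs(ranks[list(combo)].sum() - mean) >= obs - 1e-9:
            extreme += 1
    return extreme / total


# --------------------------------------------------------------------------
# spatial brute force
# --------------------------------------------------------------------------

def neighbor_counts_bruteforce(xy: np.ndarray, radius: float) -> np.ndarray:
    n = xy.shape[0]
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1]) <= radius:
                counts[i] += 1
    return counts
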