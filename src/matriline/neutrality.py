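"""Neutrality statistics with an internal coalescent null.

Tajima's D contrasts the pairwise-difference estimator of theta with
Watterson's segregating-sites estimator; Fu's Fs contrasts the observed
haplotype count with the Ewens sampling expectation at theta_pi.
Significance for both is calibrated by simulating the standard neutral
Kingman coalescent with infinite-sites mutation at the theta estimated
from the observed data, the approach of the classical population-genetics
packages for non-recombining haplotype data.

Two simulator entry points are provided: :func:`simulate_neutral_sample`
builds an explicit genealogy and haplotype sequences for one replicate;
:func:`simulate_summaries` is a vectorized path that produces the
summary statistics (S, mean pairwise differences, haplotype count) for
many replicates at once without materialising trees. Both are exact
samplers of the same process and are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

# ---------------------------------------------------------------------------
# Tajima's D


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """The standard normalising constants of Tajima's (1989) test."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(n: int, S: int, pi_total: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences per locus.

    Returns NaN (flagged "not computable") when S == 0.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    denom = math.sqrt(c.e1 * S + c.e2 * S * (S - 1))
    return (pi_total - S / c.a1) / denom


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling distribution

_LOG_STIRLING_CACHE: dict[int, np.ndarray] = {}


def log_stirling1_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, 1st kind).

    Computed by the log-space recurrence
    |s(n+1, k)| = n |s(n, k)| + |s(n, k-1)|, stable to n in the
    hundreds (well beyond the sample sizes of control-region surveys).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n in _LOG_STIRLING_CACHE:
        return _LOG_STIRLING_CACHE[n]
    row = np.full(n + 1, -np.inf)
    row[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        # new[k] = log(m * row[k] + row[k-1])
        new[1 : m + 2] = np.logaddexp(math.log(m) + row[1 : m + 2], row[0 : m + 1])
        row = new
    _LOG_STIRLING_CACHE[n] = row
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta) for k = 0..n under the Ewens distribution.

    P(K=k) = |s(n,k)| theta^k / theta^(n rising).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    k = np.arange(n + 1)
    log_rising = gammaln(theta + n) - gammaln(theta)
    return log_stirling1_row(n) + k * math.log(theta) - log_rising


def ewens_k_tail(n: int, theta: float, k_obs: int) -> float:
    """S' = P(K >= k_obs | theta) under the Ewens sampling distribution."""
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in 1..n")
    logp = ewens_log_pmf(n, theta)
    return float(np.exp(logsumexp(logp[k_obs:])))


def fus_fs(n: int, theta_pi: float, k_obs: int) -> float:
    """Fu's Fs = ln(S' / (1 - S')) with S' = P(K >= k_obs | theta_pi).

    theta_pi is the per-locus mean pairwise differences. Returns +inf
    when S' is numerically 1 (k_obs = 1) and -inf when S' underflows;
    both are the achievable bounds of the statistic.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta_pi <= 0:
        raise ValueError("theta_pi must be positive")
    logp = ewens_log_pmf(n, theta_pi)
    log_tail = logsumexp(logp[k_obs:])
    log_head = logsumexp(logp[:k_obs]) if k_obs > 1 else -np.inf
    if log_head == -np.inf:
        return float("inf")
    if log_tail == -np.inf:
        return float("-inf")
    return float(log_tail - log_head)


# ---------------------------------------------------------------------------
# Neutral infinite-sites coalescent simulator


@dataclass(frozen=True)
class CoalescentParams:
    n: int
    theta: float  # per-locus population mutation parameter
    L: int = 1232  # site count used only to place mutations for output
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


@dataclass
class SimulatedSample:
    """One replicate: genealogy, mutation placements and haplotypes."""

    n: int
    parent: np.ndarray  # parent index per node (2n-1 nodes; root = -1)
    node_time: np.ndarray  # coalescent-unit times
    mutations: list[tuple[int, int]]  # (node whose parent-branch mutated, site)
    sequences: list[frozenset[int]]  # derived-site sets per leaf
    tmrca: float

    @property
    def S_sim(self) -> int:
        segregating = set()
        for node, site in self.mutations:
            size = self._leaf_count(node)
            if 0 < size < self.n:
                segregating.add(site)
        return len(segregating)

    def _leaf_count(self, node: int) -> int:
        # leaves are nodes 0..n-1
        count = 0
        stack = [node]
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        while stack:
            v = stack.pop()
            if v < self.n:
                count += 1
            stack.extend(children.get(v, []))
        return count

    @property
    def pi_sim(self) -> float:
        n = self.n
        total = sum(
            len(self.sequences[i] ^ self.sequences[j])
            for i in range(n)
            for j in range(i + 1, n)
        )
        return total / (n * (n - 1) / 2)

    @property
    def k_sim(self) -> int:
        return len(set(self.sequences))


def simulate_neutral_sample(
    params: CoalescentParams, rng: np.random.Generator | None = None
) -> SimulatedSample:
    """Simulate one sample under the neutral infinite-sites coalescent.

    While k lineages remain, the waiting time to the next coalescence is
    exponential with rate k(k-1)/2 (time in units of 2N generations);
    mutations fall on each branch as Poisson(theta/2 x branch length),
    every mutation hitting a fresh site. Sites are mapped to distinct
    integer positions drawn without replacement from 0..L-1 for output.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node_time[nxt] = t
        parent[a] = parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    tmrca = t

    # Branch lengths and Poisson mutation counts per branch
    mutations: list[tuple[int, int]] = []
    site_counter = 0
    for v in range(n_nodes - 1):
        blen = node_time[parent[v]] - node_time[v]
        m = rng.poisson(params.theta / 2.0 * blen)
        for _ in range(m):
            mutations.append((v, site_counter))
            site_counter += 1
    if site_counter > params.L:
        raise ValueError(
            f"{site_counter} mutations exceed the {params.L} available sites; "
            "theta too large for the frame"
        )
    # Map abstract sites to distinct integer positions
    positions = rng.choice(params.L, size=site_counter, replace=False)
    mutations = [(v, int(positions[s])) for v, s in mutations]

    # Haplotypes: derived-site set per leaf = mutations on its root path
    mut_by_node: dict[int, list[int]] = {}
    for v, site in mutations:
        mut_by_node.setdefault(v, []).append(site)
    sequences = []
    for leaf in range(n):
        sites: set[int] = set()
        v = leaf
        while parent[v] >= 0:
            sites.update(mut_by_node.get(v, ()))
            v = parent[v]
        sequences.append(frozenset(sites))
    return SimulatedSample(
        n=n,
        parent=parent,
        node_time=node_time,
        mutations=mutations,
        sequences=sequences,
        tmrca=tmrca,
    )


def simulate_summaries(
    n: int,
    theta: float | np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized neutral coalescent summaries for many replicates.

    Returns arrays (S, pi, k) of shape (n_reps,): segregating sites,
    mean pairwise differences per locus, and haplotype count, sampled
    from the identical process as :func:`simulate_neutral_sample`.
    ``theta`` may be a scalar or a per-replicate array.

    Per interval with k active lineages the total mutation count is
    Poisson(k * t * theta/2), each mutation assigned to a uniform
    lineage; a mutation on a lineage subtending i leaves contributes
    i(n-i) differing pairs. Haplotype counts use the stem-class
    recursion: each lineage tracks the number of haplotype classes among
    its leaves and whether the class adjacent to its top survives
    unmutated; merging two unmutated stems fuses their classes.
    """
    R = n_reps
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (R,)).copy()
    sizes = np.ones((R, n), dtype=np.int64)
    classes = np.ones((R, n), dtype=np.int64)
    stem_open = np.ones((R, n), dtype=bool)
    S = np.zeros(R, dtype=np.int64)
    pi_sum = np.zeros(R)
    rows = np.arange(R)
    for k in range(n, 1, -1):
        t = rng.exponential(2.0 / (k * (k - 1)), size=R)
        m = rng.poisson(theta / 2.0 * t * k)
        total = int(m.sum())
        if total:
            rep_idx = np.repeat(rows, m)
            lin_idx = rng.integers(0, k, size=total)
            sz = sizes[rep_idx, lin_idx]
            S += m
            np.add.at(pi_sum, rep_idx, sz * (n - sz))
            stem_open[rep_idx, lin_idx] = False
        # coalesce a uniform pair (a < b); merged lineage kept in slot a,
        # slot b refilled from the last active slot k-1
        i = rng.integers(0, k, size=R)
        j = rng.integers(0, k - 1, size=R)
        j = np.where(j >= i, j + 1, j)
        a = np.minimum(i, j)
        b = np.maximum(i, j)
        both_open = stem_open[rows, a] & stem_open[rows, b]
        classes[rows, a] = classes[rows, a] + classes[rows, b] - both_open
        stem_open[rows, a] = stem_open[rows, a] | stem_open[rows, b]
        sizes[rows, a] += sizes[rows, b]
        move = b != (k - 1)
        mrows = rows[move]
        mb = b[move]
        sizes[mrows, mb] = sizes[mrows, k - 1]
        classes[mrows, mb] = classes[mrows, k - 1]
        stem_open[mrows, mb] = stem_open[mrows, k - 1]
    pi = pi_sum / (n * (n - 1) / 2.0)
    k_hap = classes[:, 0]
    return S, pi, k_hap


# ---------------------------------------------------------------------------
# Simulation p-values


@dataclass(frozen=True)
class NeutralityResult:
    n: int
    S: int
    pi_total: float  # mean pairwise differences per locus
    k_obs: int
    D: float
    Fs: float
    p_D: float  # one-tailed on the side of the observed sign
    p_Fs: float
    p_D_lower: float  # P(D_sim <= D_obs): the expansion-side tail
    p_Fs_lower: float
    n_reps: int = 0
    seed: int | None = None
    theta_null: float = float("nan")


def _fs_for_replicates(n: int, pi: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Fu's Fs for each simulated replicate (vectorized over reps)."""
    logw = log_stirling1_row(n)  # (n+1,)
    ks = np.arange(n + 1)
    fs = np.full(len(pi), np.inf)
    ok = pi > 0
    if ok.any():
        theta = pi[ok][:, None]
        logp = logw[None, :] + ks[None, :] * np.log(theta) - (
            gammaln(theta + n) - gammaln(theta)
        )
        # tail log-sum for each replicate at its own k
        out = np.empty(ok.sum())
        kk = k[ok]
        for idx in range(len(out)):
            lt = logsumexp(logp[idx, kk[idx] :])
            lh = logsumexp(logp[idx, : kk[idx]]) if kk[idx] > 1 else -np.inf
            if lh == -np.inf:
                out[idx] = np.inf
            elif lt == -np.inf:
                out[idx] = -np.inf
            else:
                out[idx] = lt - lh
        fs[ok] = out
    return fs


def neutrality_pvalues(
    n: int,
    S: int,
    pi_total: float,
    k_obs: int,
    n_reps: int = 1000,
    seed: int | None = None,
    theta_estimator: str = "pi",
) -> NeutralityResult:
    """Tajima's D and Fu's Fs with coalescent-simulation p-values.

    The null is the neutral infinite-sites coalescent at theta estimated
    from the observed data (theta_pi by default, Watterson optional).
    One-tailed p-values are reported on the side of the observed sign
    (the convention of the classical packages) alongside the fixed
    lower-tail probabilities; all include the observed statistic via the
    (b+1)/(m+1) correction. Replicates where a statistic is undefined
    (S_sim = 0 for D) are excluded from that statistic's tail count.
    """
    D_obs = tajimas_d(n, S, pi_total) if S > 0 else float("nan")
    Fs_obs = fus_fs(n, pi_total, k_obs) if pi_total > 0 else float("inf")
    if theta_estimator == "pi":
        theta_null = pi_total
    elif theta_estimator == "watterson":
        theta_null = S / tajima_constants(n).a1
    else:
        raise ValueError(f"unknown theta estimator {theta_estimator!r}")
    if theta_null <= 0:
        raise ValueError("observed data are monomorphic; null theta is zero")

    rng = np.random.default_rng(seed)
    S_sim, pi_sim, k_sim = simulate_summaries(n, theta_null, n_reps, rng)

    c = tajima_constants(n)
    defined = S_sim > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(c.e1 * S_sim + c.e2 * S_sim * (S_sim - 1.0))
        D_sim = np.where(defined, (pi_sim - S_sim / c.a1) / np.where(denom > 0, denom, 1.0), np.nan)
    Fs_sim = _fs_for_replicates(n, pi_sim, k_sim)

    def tail(sim: np.ndarray, obs: float, lower: bool) -> float:
        ok = ~np.isnan(sim)
        m = int(ok.sum())
        if m == 0 or math.isnan(obs):
            return float("nan")
        b = int((sim[ok] <= obs).sum()) if lower else int((sim[ok] >= obs).sum())
        return (b + 1) / (m + 1)

    p_D_lower = tail(D_sim, D_obs, lower=True)
    p_Fs_lower = tail(Fs_sim, Fs_obs, lower=True)
    p_D = p_D_lower if (not math.isnan(D_obs) and D_obs < 0) else tail(D_sim, D_obs, lower=False)
    p_Fs = p_Fs_lower if Fs_obs < 0 else tail(Fs_sim, Fs_obs, lower=False)
    return NeutralityResult(
        n=n,
        S=S,
        pi_total=pi_total,
        k_obs=k_obs,
        D=D_obs,
        Fs=Fs_obs,
        p_D=p_D,
        p_Fs=p_Fs,
        p_D_lower=p_D_lower,
        p_Fs_lower=p_Fs_lower,
        n_reps=n_reps,
        seed=seed,
        theta_null=float(theta_null),
    )
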