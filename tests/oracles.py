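"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (quadratic loops, exact rational
arithmetic, exhaustive enumeration) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

# ---------------------------------------------------------------------------
# Affine-gap global alignment (Gotoh), returning the optimal score


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0):
    """Optimal global affine-gap alignment score (first gap char costs
    gap_open, each further char gap_extend)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def alignment_score_of_states(ref: str, states: str, insertions: dict[int, str],
                              match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0):
    """Score of the alignment implied by per-position states + insertions."""
    score = 0.0
    run = 0  # current gap run length
    for i, s in enumerate(states):
        if i in insertions:  # insertion after breaking any deletion run
            ins = insertions[i]
            score += gap_open + (len(ins) - 1) * gap_extend
            run = 0
        if s == "-":
            score += gap_open if run == 0 else gap_extend
            run += 1
        else:
            score += match if s == ref[i] else mismatch
            run = 0
    if len(states) in insertions:
        ins = insertions[len(states)]
        score += gap_open + (len(ins) - 1) * gap_extend
    return score


# ---------------------------------------------------------------------------
# Diversity statistics, quadratic brute force


def brute_hd(seqs: list[str]) -> float:
    """Nei unbiased gene diversity by explicit pair counting.

    sum p_i^2 = (2 * #matching unordered pairs + n) / n^2.
    """
    n = len(seqs)
    same = sum(seqs[i] == seqs[j] for i in range(n) for j in range(i + 1, n))
    sum2 = (2 * same + n) / n**2
    return n / (n - 1) * (1 - sum2)


def brute_pi(seqs: list[str]) -> float:
    """Mean pairwise proportion of differing sites (complete data)."""
    n = len(seqs)
    L = len(seqs[0])
    total = sum(
        sum(x != y for x, y in zip(seqs[i], seqs[j]))
        for i in range(n)
        for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2) / L


def brute_tajimas_d(n: int, S: int, pi_total: float) -> float:
    """Textbook Tajima constants, written out independently."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# Exact Ewens sampling probabilities with rational Stirling numbers


def exact_stirling1_unsigned(n: int) -> list[int]:
    """|s(n, k)| for k = 0..n by the exact integer recurrence."""
    row = [0, 1]  # n = 1
    for m in range(1, n):
        new = [0] * (m + 2)
        for k in range(1, m + 2):
            new[k] = m * (row[k] if k < len(row) else 0) + row[k - 1]
        row = new
    return row


def exact_ewens_tail(n: int, theta: Fraction, k_obs: int) -> Fraction:
    """P(K >= k_obs | theta) as an exact rational."""
    stirling = exact_stirling1_unsigned(n)
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    return sum(Fraction(stirling[k]) * theta**k / rising for k in range(k_obs, n + 1))


# ---------------------------------------------------------------------------
# Spanning / Steiner trees over Hamming distances


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_force_mst_cost(states: list[str]) -> int:
    """Minimum spanning tree cost by exhaustive enumeration (Prüfer)."""
    n = len(states)
    if n <= 1:
        return 0
    best = None
    # enumerate all labelled trees via Prüfer sequences (n <= 6!)
    for pruefer in itertools.product(range(n), repeat=max(n - 2, 0)):
        degree = [1] * n
        for v in pruefer:
            degree[v] += 1
        edges = []
        seq = list(pruefer)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        deg = degree[:]
        import heapq

        heap = leaves[:]
        heapq.heapify(heap)
        for v in seq:
            leaf = heapq.heappop(heap)
            edges.append((leaf, v))
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(heap, v)
        u, w = heapq.heappop(heap), heapq.heappop(heap)
        edges.append((u, w))
        cost = sum(hamming(states[x], states[y]) for x, y in edges)
        if best is None or cost < best:
            best = cost
    return best


def all_msts(states: list[str]) -> list[frozenset[tuple[int, int]]]:
    """Every minimum spanning tree (edge sets) by enumeration."""
    n = len(states)
    best_cost = brute_force_mst_cost(states)
    result = []
    edges_all = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for combo in itertools.combinations(edges_all, n - 1):
        # check spanning tree
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v in combo:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if not ok:
            continue
        cost = sum(hamming(states[u], states[v]) for u, v in combo)
        if cost == best_cost:
            result.append(frozenset(combo))
    return result


def dreyfus_wagner_steiner_cost(terminals: list[str], n_sites: int, alphabet="ACGT") -> int:
    """Exact Steiner minimal tree cost in the Hamming graph over all
    state vectors of length n_sites, restricted to the states observed
    at each site (Dreyfus-Wagner dynamic program)."""
    # candidate vertex set: cartesian product of observed per-site states
    per_site = [sorted({t[k] for t in terminals}) for k in range(n_sites)]
    vertices = ["".join(v) for v in itertools.product(*per_site)]
    vidx = {v: i for i, v in enumerate(vertices)}
    V = len(vertices)
    term_idx = [vidx[t] for t in terminals]
    t = len(term_idx)
    if t <= 1:
        return 0
    # all-pairs shortest path = Hamming distance (graph is a Hamming graph)
    dist = np.array(
        [[hamming(a, b) for b in vertices] for a in vertices], dtype=np.int64
    )
    INF = 10**9
    full = 1 << t
    # S[mask][v]: min cost tree spanning terminals in mask plus vertex v
    S = np.full((full, V), INF, dtype=np.int64)
    for i, ti in enumerate(term_idx):
        S[1 << i] = dist[ti]
    masks = sorted(range(1, full), key=lambda m: bin(m).count("1"))
    for mask in masks:
        if bin(mask).count("1") < 2:
            continue
        # merge submasks
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if other and sub < other:
                merged = S[sub] + S[other]
                np.minimum(S[mask], merged, out=S[mask])
            sub = (sub - 1) & mask
        # relax through the graph
        S[mask] = (S[mask][None, :] + dist).min(axis=1)
    return int(S[full - 1][term_idx[0]])


# ---------------------------------------------------------------------------
# AMOVA sums of squares, written out from the textbook definitions


def hand_amova(d2: np.ndarray, pops: list[str], groups_of: dict[str, str]):
    """Three-level variance components via explicit double loops."""
    N = len(pops)
    pop_names = sorted(set(pops))
    grp_names = sorted(set(groups_of[p] for p in pop_names))
    P, G = len(pop_names), len(grp_names)

    def ss_block(idx):
        tot = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                tot += d2[idx[a], idx[b]]
        return tot / len(idx)

    ss_total = ss_block(list(range(N)))
    ss_wp = sum(ss_block([i for i in range(N) if pops[i] == p]) for p in pop_names)
    ss_wg = sum(
        ss_block([i for i in range(N) if groups_of[pops[i]] == g]) for g in grp_names
    )
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    n_p = {p: sum(1 for x in pops if x == p) for p in pop_names}
    n_g = {g: sum(1 for x in pops if groups_of[x] == g) for g in grp_names}
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in pop_names if groups_of[p] == g) / n_g[g] for g in grp_names
    )
    sigma_c = ss_wp / (N - P)
    if P - G > 0:
        n1 = (N - sum_np2_over_ng) / (P - G)
        sigma_b = (ss_ap / (P - G) - sigma_c) / n1
    else:
        sigma_b = 0.0
    if G - 1 > 0:
        n2 = (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / N) / (G - 1)
        n3 = (N - sum(v**2 for v in n_g.values()) / N) / (G - 1)
        sigma_a = (ss_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c, (ss_ag, ss_ap, ss_wp)
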