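"""Population structure: pairwise PhiST, hierarchical AMOVA, PCoA.

AMOVA follows the Excoffier-Smouse-Quattro (1992) decomposition of
molecular variance from the matrix of pairwise sequence differences
(raw differing-site counts serve as squared distances, the convention
for haplotype data). Pairwise PhiST between two populations is the
Phi_ST of the two-population, single-group AMOVA. Significance uses
label permutations with the (b+1)/(m+1) correction. Negative variance
components are reported as computed, not truncated, so percentages can
fall outside [0, 100] on near-panmictic data.

PCoA is classical Gower double-centering of the squared distance
transform of the PhiST matrix: B = -1/2 J D^2 J, eigendecomposition,
coordinates scaled by the square roots of positive eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import pairwise_differences
from .seqio import AlignedSequence


# ---------------------------------------------------------------------------
# Sums of squares


def _ss_total(d2: np.ndarray) -> float:
    n = d2.shape[0]
    return float(np.triu(d2, k=1).sum()) / n


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        block = d2[np.ix_(idx, idx)]
        ss += float(np.triu(block, k=1).sum()) / len(idx)
    return ss


@dataclass(frozen=True)
class AmovaResult:
    layout: dict[str, list[str]]  # group -> populations
    df: tuple[int, int, int]  # among groups, among pops within groups, within pops
    ss: tuple[float, float, float]
    sigma2: tuple[float, float, float]  # sigma2_a, sigma2_b, sigma2_c
    percentages: tuple[float, float, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_phi_ct: float = float("nan")
    p_phi_sc: float = float("nan")
    p_phi_st: float = float("nan")
    n_permutations: int = 0
    seed: int | None = None


def _amova_components(
    d2: np.ndarray, pops: np.ndarray, groups: np.ndarray
) -> tuple[tuple, tuple, tuple, float, float, float]:
    """Variance components from the ESQ sums-of-squares decomposition."""
    N = d2.shape[0]
    pop_ids, pop_inv = np.unique(pops, return_inverse=True)
    P = len(pop_ids)
    grp_ids = np.unique(groups)
    G = len(grp_ids)
    # group of each population (populations are nested in groups)
    pop_group = np.empty(P, dtype=object)
    for p in range(P):
        gs = np.unique(groups[pop_inv == p])
        if len(gs) != 1:
            raise ValueError(f"population {pop_ids[p]!r} spans multiple groups")
        pop_group[p] = gs[0]

    ss_total = _ss_total(d2)
    ss_wp = _ss_within(d2, pops)
    ss_wg = _ss_within(d2, groups)
    ss_ap = ss_wg - ss_wp  # among populations within groups
    ss_ag = ss_total - ss_wg  # among groups

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P
    if df_wp <= 0:
        raise ValueError("AMOVA needs more sequences than populations")

    n_p = np.array([(pop_inv == p).sum() for p in range(P)], dtype=float)
    n_g = np.array([(groups == g).sum() for g in grp_ids], dtype=float)
    sum_np2_over_ng = sum(
        (n_p[pop_group == g] ** 2).sum() / n_g[i] for i, g in enumerate(grp_ids)
    )

    sigma_c = ss_wp / df_wp
    if df_ap > 0:
        n1 = (N - sum_np2_over_ng) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n2 = (sum_np2_over_ng - (n_p**2).sum() / N) / df_ag
        n3 = (N - (n_g**2).sum() / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0

    total = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / total if total != 0 else float("nan")
    phi_ct = sigma_a / total if total != 0 else float("nan")
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else float("nan")
    return (
        (df_ag, df_ap, df_wp),
        (ss_ag, ss_ap, ss_wp),
        (sigma_a, sigma_b, sigma_c),
        phi_ct,
        phi_sc,
        phi_st,
    )


def amova(
    alns: list[AlignedSequence],
    popmap: pd.DataFrame,
    layout: dict[str, list[str]] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on pairwise sequence differences.

    ``layout`` maps group names to population lists; when omitted, all
    populations form a single group ("no grouping") and only Phi_ST (the
    among-population fixation index) is testable. Permutation schemes:
    Phi_ST permutes sequences among populations irrespective of groups,
    Phi_SC permutes sequences among populations within their group,
    Phi_CT permutes whole populations among groups.
    """
    ids = [a.sample_id for a in alns]
    meta = popmap.set_index("sample_id").loc[ids]
    pops = meta["population"].to_numpy()
    unique_pops = list(dict.fromkeys(pops))
    if len(unique_pops) < 2:
        raise ValueError("AMOVA requires at least two populations")
    if layout is None:
        layout = {"all": unique_pops}
    pop_to_group = {}
    for g, plist in layout.items():
        for p in plist:
            pop_to_group[p] = g
    missing = set(unique_pops) - set(pop_to_group)
    if missing:
        raise ValueError(f"populations absent from layout: {sorted(missing)}")
    groups = np.array([pop_to_group[p] for p in pops], dtype=object)
    single_group = len(set(groups)) == 1

    d2, _ = pairwise_differences(alns)
    d2 = d2.astype(float)
    df, ss, sigma2, phi_ct, phi_sc, phi_st = _amova_components(d2, pops, groups)

    rng = np.random.default_rng(seed)
    p_st = p_sc = p_ct = float("nan")
    if n_perm > 0:
        # Phi_ST: shuffle individuals among populations (groups follow pops)
        b_st = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pops))
            pp = pops[perm]
            gg = np.array([pop_to_group[p] for p in pp], dtype=object)
            stat = _amova_components(d2, pp, gg)[5]
            if stat >= phi_st:
                b_st += 1
        p_st = (b_st + 1) / (n_perm + 1)
        if not single_group:
            # Phi_SC: shuffle individuals among populations within groups
            b_sc = 0
            for _ in range(n_perm):
                pp = pops.copy()
                for g in set(groups):
                    idx = np.nonzero(groups == g)[0]
                    pp[idx] = pp[idx[rng.permutation(len(idx))]]
                stat = _amova_components(d2, pp, groups)[4]
                if stat >= phi_sc:
                    b_sc += 1
            p_sc = (b_sc + 1) / (n_perm + 1)
            # Phi_CT: permute whole populations among groups
            b_ct = 0
            pop_list = np.array(unique_pops, dtype=object)
            group_of_pop = np.array([pop_to_group[p] for p in unique_pops], dtype=object)
            for _ in range(n_perm):
                shuffled = group_of_pop[rng.permutation(len(pop_list))]
                mapping = dict(zip(pop_list, shuffled))
                gg = np.array([mapping[p] for p in pops], dtype=object)
                stat = _amova_components(d2, pops, gg)[3]
                if stat >= phi_ct:
                    b_ct += 1
            p_ct = (b_ct + 1) / (n_perm + 1)

    total = sum(sigma2)
    pct = tuple(100.0 * s / total for s in sigma2) if total != 0 else (np.nan,) * 3
    return AmovaResult(
        layout=layout,
        df=df,
        ss=ss,
        sigma2=sigma2,
        percentages=pct,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        p_phi_ct=p_ct,
        p_phi_sc=p_sc,
        p_phi_st=p_st,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pairwise PhiST


@dataclass(frozen=True)
class FstResult:
    populations: list[str]
    matrix: np.ndarray  # pairwise PhiST
    p_matrix: np.ndarray
    n_permutations: int
    seed: int | None = None
    excluded: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.populations, columns=self.populations)


def _phi_st_two_pop(d2: np.ndarray, n1: int) -> float:
    """Phi_ST of a 2-population AMOVA; first n1 rows are population 1."""
    N = d2.shape[0]
    n2 = N - n1
    ss_total = _ss_total(d2)
    ss_wp = (
        float(np.triu(d2[:n1, :n1], k=1).sum()) / n1
        + float(np.triu(d2[n1:, n1:], k=1).sum()) / n2
    )
    sigma_c = ss_wp / (N - 2)
    n_coef = (N - (n1**2 + n2**2) / N) / 1.0
    sigma_ab = ((ss_total - ss_wp) / 1.0 - sigma_c) / n_coef
    total = sigma_ab + sigma_c
    return sigma_ab / total if total != 0 else float("nan")


def pairwise_fst(
    alns: list[AlignedSequence],
    popmap: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | None = None,
) -> FstResult:
    """Distance-based pairwise PhiST matrix with permutation p-values.

    Each pair's statistic is the two-population AMOVA Phi_ST on raw
    pairwise difference counts; the p-value is the proportion of
    permutations (individuals shuffled between the two populations) with
    PhiST_perm >= PhiST_obs. Populations with fewer than two sequences
    are excluded with a warning recorded in ``excluded``.

    Permutations are evaluated through a quadratic-form identity: for a
    permuted membership indicator z, the within-group sum of squared
    distances is z' D2 z / 2, so all permutations reduce to two matrix
    products.
    """
    ids = [a.sample_id for a in alns]
    meta = popmap.set_index("sample_id").loc[ids]
    pops = meta["population"].to_numpy()
    counts = pd.Series(pops).value_counts()
    keep_pops = [p for p in dict.fromkeys(pops) if counts[p] >= 2]
    excluded = tuple(p for p in dict.fromkeys(pops) if counts[p] < 2)

    d2_full, _ = pairwise_differences(alns)
    d2_full = d2_full.astype(float)
    rng = np.random.default_rng(seed)

    P = len(keep_pops)
    if P < 2:
        raise ValueError("pairwise PhiST requires >= 2 populations with >= 2 sequences")
    fst = np.zeros((P, P))
    pmat = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            idx1 = np.nonzero(pops == keep_pops[i])[0]
            idx2 = np.nonzero(pops == keep_pops[j])[0]
            idx = np.concatenate([idx1, idx2])
            sub = d2_full[np.ix_(idx, idx)]
            n1, n2 = len(idx1), len(idx2)
            N = n1 + n2
            obs = _phi_st_two_pop(sub, n1)
            fst[i, j] = fst[j, i] = obs

            if n_perm > 0:
                # vectorized permutations via z' D z
                Z = np.zeros((N, n_perm))
                for pidx in range(n_perm):
                    sel = rng.permutation(N)[:n1]
                    Z[sel, pidx] = 1.0
                q1 = np.einsum("ij,ij->j", sub @ Z, Z) / 2.0  # within pop-1 SS sums
                Zc = 1.0 - Z
                q2 = np.einsum("ij,ij->j", sub @ Zc, Zc) / 2.0
                ss_total = float(np.triu(sub, k=1).sum()) / N
                ss_wp = q1 / n1 + q2 / n2
                sigma_c = ss_wp / (N - 2)
                n_coef = N - (n1**2 + n2**2) / N
                sigma_ab = (ss_total - ss_wp - sigma_c) / n_coef
                totals = sigma_ab + sigma_c
                with np.errstate(invalid="ignore", divide="ignore"):
                    stats = np.where(totals != 0, sigma_ab / totals, np.nan)
                b = int(np.nansum(stats >= obs))
                pmat[i, j] = pmat[j, i] = (b + 1) / (n_perm + 1)
    return FstResult(
        populations=keep_pops,
        matrix=fst,
        p_matrix=pmat,
        n_permutations=n_perm,
        seed=seed,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# PCoA


@dataclass(frozen=True)
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray  # (P, n_axes) over positive eigenvalues
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variation: np.ndarray  # per positive axis, % of positive mass
    degenerate: bool = False

    @property
    def cumulative_first_two(self) -> float:
        return float(self.percent_variation[: min(2, len(self.percent_variation))].sum())


def pcoa_from_fst(fst: FstResult | np.ndarray, labels: list[str] | None = None) -> PcoaResult:
    """Classical PCoA of a distance matrix (here, pairwise PhiST).

    Gower double-centering of the elementwise-squared distance matrix,
    eigendecomposition, coordinates = eigenvectors scaled by sqrt of the
    positive eigenvalues; percent variation is relative to the positive
    eigenvalue mass. An all-zero matrix yields a flagged degenerate
    result.
    """
    if isinstance(fst, FstResult):
        D = np.asarray(fst.matrix, dtype=float)
        labels = list(fst.populations)
    else:
        D = np.asarray(fst, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(D.shape[0])]
    P = D.shape[0]
    if P < 3:
        raise ValueError("PCoA requires at least 3 populations")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    J = np.eye(P) - np.ones((P, P)) / P
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > max(1e-12 * abs(eigval).max(initial=0.0), 0.0)
    if not pos.any():
        return PcoaResult(
            labels=labels,
            coordinates=np.zeros((P, 0)),
            eigenvalues=eigval,
            percent_variation=np.zeros(0),
            degenerate=True,
        )
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    return PcoaResult(
        labels=labels, coordinates=coords, eigenvalues=eigval, percent_variation=pct
    )
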