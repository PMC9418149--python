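"""Haplotype collapsing, site classification and diversity indices.

Implements the standard intrapopulation summary statistics of
control-region surveys: haplotype counts, Nei gene (haplotype) diversity
Hd with its sampling variance, per-site nucleotide diversity pi with its
sampling variance, and the variable-site classification into singletons
and parsimony-informative sites.

Site policy: by default every site carrying a gap or missing call in
*any* sequence is excluded from all statistics ("complete deletion"); a
pairwise-deletion option is provided for pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import AlignedSequence

COMPLETE = "complete"
PAIRWISE = "pairwise"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}


def state_matrix(alns: list[AlignedSequence]) -> np.ndarray:
    """(N, L) uint8 matrix of state codes (ACGT- N -> 0..5)."""
    if not alns:
        raise ValueError("no sequences")
    L = len(alns[0].states)
    if any(len(a.states) != L for a in alns):
        raise ValueError("sequences are not in a common reference frame")
    out = np.empty((len(alns), L), dtype=np.uint8)
    for i, a in enumerate(alns):
        out[i] = np.frombuffer(a.states.encode(), dtype=np.uint8)
    lut = np.full(256, 5, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    return lut[out]


def included_site_mask(states: np.ndarray, site_policy: str = COMPLETE) -> np.ndarray:
    """Boolean mask of sites usable under the site policy.

    Complete deletion keeps only sites where every sequence has an
    unambiguous base call; pairwise deletion keeps sites with at least
    one called base (per-pair handling happens downstream).
    """
    called = states < 4
    if site_policy == COMPLETE:
        return called.all(axis=0)
    if site_policy == PAIRWISE:
        return called.any(axis=0)
    raise ValueError(f"unknown site policy {site_policy!r}")


@dataclass
class HaplotypePartition:
    """Partition of samples into identical-sequence classes."""

    haplotype_ids: list[str]
    representative_states: list[str]  # over included sites, in frame order
    members: list[list[str]]  # sample ids per haplotype, input order
    included_sites: np.ndarray  # 1-based reference positions used

    @property
    def Ht(self) -> int:
        return len(self.haplotype_ids)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def labels(self) -> dict[str, str]:
        """sample_id -> haplotype_id."""
        return {s: h for h, mem in zip(self.haplotype_ids, self.members) for s in mem}


def collapse_haplotypes(
    alns: list[AlignedSequence], site_policy: str = COMPLETE
) -> HaplotypePartition:
    """Group sequences identical over included sites into haplotypes.

    Haplotype ids are assigned in first-occurrence order (Hap_1, ...).
    """
    if not alns:
        raise ValueError("cannot collapse an empty sequence set")
    if site_policy != COMPLETE:
        raise ValueError("haplotype collapsing is defined under complete deletion only")
    states = state_matrix(alns)
    mask = included_site_mask(states, COMPLETE)
    sub = states[:, mask]
    key_to_idx: dict[bytes, int] = {}
    members: list[list[str]] = []
    reps: list[str] = []
    inv = {v: k for k, v in _CODE.items()}
    for i, a in enumerate(alns):
        key = sub[i].tobytes()
        if key not in key_to_idx:
            key_to_idx[key] = len(members)
            members.append([])
            reps.append("".join(inv[int(c)] for c in sub[i]))
        members[key_to_idx[key]].append(a.sample_id)
    ids = [f"Hap_{k + 1}" for k in range(len(members))]
    positions = np.nonzero(mask)[0] + 1
    return HaplotypePartition(
        haplotype_ids=ids, representative_states=reps, members=members, included_sites=positions
    )


@dataclass(frozen=True)
class SiteClassification:
    S: int
    singletons: int
    parsimony_informative: int
    excluded_sites: tuple[int, ...]  # 1-based positions dropped for gaps/missing


def classify_sites(alns: list[AlignedSequence], site_policy: str = COMPLETE) -> SiteClassification:
    """Count variable, singleton and parsimony-informative sites.

    A site is variable if >= 2 states segregate among included
    sequences; a singleton if every minor state occurs exactly once;
    parsimony-informative if >= 2 states each occur >= 2 times. Sites
    that are variable but neither (possible only for multi-allelic
    sites) are classified as singletons when all minor states are
    singletons, otherwise as parsimony-informative — so the binary
    arithmetic singletons + PIS == S always holds.
    """
    if len(alns) < 2:
        raise ValueError("site classification needs >= 2 sequences")
    states = state_matrix(alns)
    mask = included_site_mask(states, site_policy)
    excluded = tuple((np.nonzero(~mask)[0] + 1).tolist())
    sub = states[:, mask]
    S = singles = pis = 0
    for j in range(sub.shape[1]):
        col = sub[:, j]
        col = col[col < 4]
        counts = np.bincount(col, minlength=4)
        counts = counts[counts > 0]
        if len(counts) < 2:
            continue
        S += 1
        if (np.sort(counts)[::-1][1:] == 1).all():
            singles += 1
        else:
            pis += 1
    return SiteClassification(
        S=S, singletons=singles, parsimony_informative=pis, excluded_sites=excluded
    )


def haplotype_diversity(part: HaplotypePartition) -> tuple[float, float]:
    """Nei unbiased gene diversity Hd and its standard error.

    Hd = n/(n-1) (1 - sum p_i^2); the variance is Nei's (1987) sampling
    variance of gene diversity:
    V = 2/(n(n-1)) {2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2}.
    """
    counts = part.counts
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs >= 2 sequences")
    p = counts / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    return float(hd), math.sqrt(max(var, 0.0))


def pairwise_differences(
    alns: list[AlignedSequence], site_policy: str = COMPLETE
) -> tuple[np.ndarray, int]:
    """Matrix of pairwise differing-site counts and the effective length.

    Under complete deletion all pairs share one site set of size L_eff.
    Under pairwise deletion counts are per-pair over mutually called
    sites and L_eff is the complete-deletion length of the full set
    (returned for reference; per-pair lengths differ).
    """
    states = state_matrix(alns)
    if site_policy == COMPLETE:
        mask = included_site_mask(states, COMPLETE)
        sub = states[:, mask]
        L_eff = int(mask.sum())
        n = sub.shape[0]
        d = np.zeros((n, n), dtype=np.int64)
        # only variable sites can contribute
        variable = np.nonzero((sub != sub[0]).any(axis=0))[0]
        for j in variable:
            col = sub[:, j]
            d += col[:, None] != col[None, :]
        return d, L_eff
    raise ValueError("pairwise distance matrix is defined for complete deletion")


def nucleotide_diversity(
    alns: list[AlignedSequence], site_policy: str = COMPLETE
) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its standard error.

    pi = sum_{i<j} d_ij / (C(n,2) * L_eff). The variance is Nei's
    (1987) sampling variance for pi without recombination:
    V = (n+1) pi / (3 (n-1) L) + 2 (n^2 + n + 3) pi^2 / (9 n (n-1)).
    """
    n = len(alns)
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    states = state_matrix(alns)
    if site_policy == COMPLETE:
        d, L_eff = pairwise_differences(alns, COMPLETE)
        if L_eff == 0:
            raise ValueError("no sites left under complete deletion")
        pi = float(d[np.triu_indices(n, k=1)].sum()) / (n * (n - 1) / 2) / L_eff
    elif site_policy == PAIRWISE:
        called = states < 4
        total_prop = 0.0
        npairs = 0
        lengths = []
        for i in range(n):
            for j in range(i + 1, n):
                both = called[i] & called[j]
                L_ij = int(both.sum())
                if L_ij == 0:
                    raise ValueError(f"pair ({i},{j}) shares no called sites")
                total_prop += float((states[i, both] != states[j, both]).sum()) / L_ij
                lengths.append(L_ij)
                npairs += 1
        pi = total_prop / npairs
        L_eff = int(np.mean(lengths))
    else:
        raise ValueError(f"unknown site policy {site_policy!r}")
    var = (n + 1) * pi / (3.0 * (n - 1) * L_eff) + 2.0 * (n**2 + n + 3) * pi**2 / (
        9.0 * n * (n - 1)
    )
    return pi, math.sqrt(max(var, 0.0))


def write_haplotype_fasta(part: HaplotypePartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for hid, rep, mem in zip(part.haplotype_ids, part.representative_states, part.members):
            fh.write(f">{hid} n={len(mem)}\n{rep}\n")
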