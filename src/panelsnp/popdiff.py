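"""Hierarchical variance partitioning (AMOVA) and Weir-Cockerham F_ST.

AMOVA follows the classic three-level decomposition for diploid data —
among populations / among individuals within populations / within
individuals — computed from squared pairwise distances between the 2N allele
copies, where the distance between two copies is the number of loci at which
their alleles differ (scaled up for pairwise-missing loci). Variance
components come from the usual method-of-moments equations; negative
components are reported as computed, never truncated.

F_ST between subpopulations is the Weir-Cockerham (1984) theta: per-locus,
per-allele components a (among populations), b (among individuals within
populations) and c (within individuals), combined across loci as
``theta = sum(a) / sum(a + b + c)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .formats import MISSING, DataError, GenotypeMatrix


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaRow:
    source: str
    df: int
    ss: float
    ms: float
    variance: float
    percentage: float


@dataclass
class AmovaResult:
    rows: list[AmovaRow]  # among / among-within / within / total
    phi_st: float
    phi_is: float | None
    phi_it: float | None

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.rows[0].variance, self.rows[1].variance, self.rows[2].variance)


def percentages_from_components(components: list[float] | tuple[float, ...]) -> list[float]:
    """Percentage of variation per component, on the printed convention
    (100 * component / sum of components)."""
    total = float(sum(components))
    if total == 0:
        raise DataError("variance components sum to zero")
    return [100.0 * c / total for c in components]


def _haplotype_codes(gm: GenotypeMatrix) -> np.ndarray:
    """(2N, L) allele-index matrix; rows 2i, 2i+1 are variety i's two copies;
    -1 marks a missing genotype (both copies)."""
    n, L = gm.n_varieties, gm.n_loci
    H = np.full((2 * n, L), MISSING, dtype=np.int16)
    for j in range(L):
        col = gm.calls[:, j]
        alleles = sorted({a for c in col if c is not None for a in c})
        index = {a: k for k, a in enumerate(alleles)}
        for i, c in enumerate(col):
            if c is not None:
                H[2 * i, j] = index[c[0]]
                H[2 * i + 1, j] = index[c[1]]
    return H


def squared_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared distances between all 2N allele copies: number of
    mismatching loci among pairwise-complete loci, rescaled to the full locus
    count. Zero when two copies share no called locus."""
    H = _haplotype_codes(gm)
    m, L = H.shape
    valid = H >= 0
    D2 = np.zeros((m, m), dtype=float)
    chunk = 256
    for start in range(0, m, chunk):
        rows = slice(start, min(start + chunk, m))
        both = valid[rows][:, None, :] & valid[None, :, :]
        mism = (H[rows][:, None, :] != H[None, :, :]) & both
        used = both.sum(axis=2)
        D2[rows] = L * mism.sum(axis=2) / np.maximum(used, 1)
    return D2


def _ss_of_group(D2: np.ndarray, idx: np.ndarray) -> float:
    block = D2[np.ix_(idx, idx)]
    return float(block.sum() / (2.0 * len(idx)))


def amova(gm: GenotypeMatrix, subgroup_map: dict[str, str]) -> AmovaResult:
    """Three-level AMOVA over the matrix's varieties.

    Requires >=2 subpopulations with >=2 varieties each (a singleton
    subpopulation leaves the within-population level with no information).
    """
    groups: dict[str, list[int]] = {}
    for i, v in enumerate(gm.varieties):
        if v not in subgroup_map:
            raise DataError(f"variety {v!r} has no subgroup assignment")
        groups.setdefault(subgroup_map[v], []).append(i)
    K = len(groups)
    if K < 2:
        raise DataError("AMOVA requires at least 2 subpopulations")
    for label, members in groups.items():
        if len(members) < 2:
            raise DataError(
                f"subpopulation {label!r} has a single variety; "
                "within-population degrees of freedom would be zero"
            )
    N = gm.n_varieties
    D2 = squared_distance_matrix(gm)
    all_idx = np.arange(2 * N)
    ss_total = _ss_of_group(D2, all_idx)
    ss_within_pop = 0.0
    for members in groups.values():
        hap_idx = np.array([h for i in members for h in (2 * i, 2 * i + 1)])
        ss_within_pop += _ss_of_group(D2, hap_idx)
    ss_within_ind = 0.0
    for i in range(N):
        ss_within_ind += _ss_of_group(D2, np.array([2 * i, 2 * i + 1]))
    ss_among_pop = ss_total - ss_within_pop
    ss_among_ind = ss_within_pop - ss_within_ind

    df_among_pop = K - 1
    df_among_ind = N - K
    df_within_ind = N
    df_total = 2 * N - 1

    ms_among_pop = ss_among_pop / df_among_pop
    ms_among_ind = ss_among_ind / df_among_ind
    ms_within_ind = ss_within_ind / df_within_ind

    hap_sizes = np.array([2 * len(m) for m in groups.values()], dtype=float)
    n_tot = hap_sizes.sum()
    n_c = (n_tot - (hap_sizes ** 2).sum() / n_tot) / (K - 1)

    sigma_c = ms_within_ind
    sigma_b = (ms_among_ind - ms_within_ind) / 2.0
    sigma_a = (ms_among_pop - ms_among_ind) / n_c
    components = [sigma_a, sigma_b, sigma_c]
    pct = percentages_from_components(components)
    total_var = sum(components)

    rows = [
        AmovaRow("Among populations", df_among_pop, ss_among_pop, ms_among_pop,
                 sigma_a, pct[0]),
        AmovaRow("Among individuals within populations", df_among_ind,
                 ss_among_ind, ms_among_ind, sigma_b, pct[1]),
        AmovaRow("Within individuals", df_within_ind, ss_within_ind,
                 ms_within_ind, sigma_c, pct[2]),
        AmovaRow("Total", df_total, ss_total, ss_total / df_total, total_var, 100.0),
    ]
    phi_st = sigma_a / total_var if total_var else 0.0
    denom_is = sigma_b + sigma_c
    phi_is = sigma_b / denom_is if denom_is else None
    phi_it = (sigma_a + sigma_b) / total_var if total_var else None
    return AmovaResult(rows=rows, phi_st=phi_st, phi_is=phi_is, phi_it=phi_it)


def amova_table(result: AmovaResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.source, r.df, r.ss, r.ms, r.variance, r.percentage)
            for r in result.rows
        ],
        columns=["source", "df", "sum_of_squares", "mean_square",
                 "variance_component", "percentage_of_variation"],
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _locus_components(
    cols: list[np.ndarray],
) -> tuple[float, float, float] | None:
    """a, b, c summed over alleles at one locus; ``cols`` holds one array of
    calls per population. Returns None when the locus is uninformative."""
    pops = [np.array([c for c in col if c is not None], dtype=object) for col in cols]
    pops = [p for p in pops if len(p) > 0]
    r = len(pops)
    if r < 2:
        return None
    n = np.array([len(p) for p in pops], dtype=float)
    n_bar = n.mean()
    if n.sum() <= r:  # need n_bar > 1 for the moment equations
        return None
    alleles = sorted({a for p in pops for call in p for a in call})
    if len(alleles) < 2:
        return (0.0, 0.0, 0.0)  # monomorphic: contributes nothing
    n_c = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array([
            sum((call[0] == allele) + (call[1] == allele) for call in p) / (2 * len(p))
            for p in pops
        ])
        h_i = np.array([
            sum(call[0] != call[1] and allele in call for call in p) / len(p)
            for p in pops
        ])
        p_bar = (n * p_i).sum() / n.sum()
        s2 = (n * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n * h_i).sum() / n.sum()
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return (a_sum, b_sum, c_sum)


def wc_theta(
    gm: GenotypeMatrix, subgroup_map: dict[str, str], pops: list[str] | None = None
) -> tuple[float | None, int]:
    """Multi-locus Weir-Cockerham theta across the given subpopulations (all
    by default). Returns (theta, number of informative loci); theta is None
    when every locus is uninformative or monomorphic."""
    groups: dict[str, list[int]] = {}
    for i, v in enumerate(gm.varieties):
        g = subgroup_map.get(v)
        if g is None:
            raise DataError(f"variety {v!r} has no subgroup assignment")
        if pops is None or g in pops:
            groups.setdefault(g, []).append(i)
    if pops is not None:
        for label in pops:
            if label not in groups:
                raise DataError(f"subpopulation {label!r} has no varieties")
    if len(groups) < 2:
        raise DataError("theta requires at least 2 subpopulations")
    labels = sorted(groups)
    a_tot = d_tot = 0.0
    n_used = 0
    for j in range(gm.n_loci):
        cols = [gm.calls[groups[g], j] for g in labels]
        comp = _locus_components(cols)
        if comp is None:
            continue
        a, b, c = comp
        if a + b + c != 0.0:
            n_used += 1
        a_tot += a
        d_tot += a + b + c
    if d_tot == 0.0:
        return None, 0
    return a_tot / d_tot, n_used


@dataclass
class PairwiseFst:
    pop_a: str
    pop_b: str
    theta: float | None
    n_loci_used: int


def pairwise_fst(gm: GenotypeMatrix, subgroup_map: dict[str, str]) -> list[PairwiseFst]:
    """Weir-Cockerham theta for every subpopulation pair."""
    labels = sorted(set(subgroup_map[v] for v in gm.varieties))
    out: list[PairwiseFst] = []
    for a, b in combinations(labels, 2):
        theta, n_used = wc_theta(gm, subgroup_map, pops=[a, b])
        out.append(PairwiseFst(pop_a=a, pop_b=b, theta=theta, n_loci_used=n_used))
    return out


def fst_matrix(pairs: list[PairwiseFst]) -> pd.DataFrame:
    """Symmetric matrix of pairwise theta with zeros on the diagonal."""
    labels = sorted({p.pop_a for p in pairs} | {p.pop_b for p in pairs})
    df = pd.DataFrame(0.0, index=labels, columns=labels)
    for p in pairs:
        val = np.nan if p.theta is None else p.theta
        df.loc[p.pop_a, p.pop_b] = val
        df.loc[p.pop_b, p.pop_a] = val
    return df
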