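"""Pairwise variety discrimination, minimal core-SNP selection, kinship from
differential-genotype counts, and core (backbone) variety identification.

Two varieties are distinguished at a locus when both calls are non-missing
and their unordered allele pairs differ; a missing genotype is null and never
distinguishes a pair. The same rule drives the kinship matrix (pairwise counts
of differential genotypes), core-SNP selection (a set-cover over variety
pairs) and core-variety selection (lowest mean differential count within each
subpopulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .formats import DataError, GenotypeMatrix
from .diversity import locus_stats

#: feasibility bound for the exhaustive minimal-set search
EXHAUSTIVE_MAX_LOCI = 25
EXHAUSTIVE_MAX_VARIETIES = 50


# ---------------------------------------------------------------------------
# Kinship (differential-genotype counts)
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    varieties: list[str]
    counts: np.ndarray  # symmetric, diagonal 0: differential-genotype counts
    comparable: np.ndarray  # per-pair number of both-non-missing loci

    def mean_differential(self, members: list[str] | None = None) -> dict[str, float]:
        """Mean differential count of each variety against the others (within
        ``members`` when given, else against all varieties)."""
        if members is None:
            members = self.varieties
        idx = [self.varieties.index(v) for v in members]
        sub = self.counts[np.ix_(idx, idx)]
        out: dict[str, float] = {}
        for k, v in enumerate(members):
            others = [x for x in range(len(members)) if x != k]
            out[v] = float(sub[k, others].mean()) if others else 0.0
        return out


def differential_matrix(gm: GenotypeMatrix) -> KinshipMatrix:
    """Count differential genotypes for every variety pair.

    entry(u, v) = number of loci where both calls are non-missing and differ;
    ``comparable`` records the number of both-non-missing loci per pair.
    """
    if gm.n_varieties < 2:
        raise DataError("need at least 2 varieties")
    coded = gm.encode()  # -1 missing
    valid = coded >= 0
    n = gm.n_varieties
    counts = np.zeros((n, n), dtype=np.int32)
    comparable = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        both = valid[i] & valid
        diff = (coded[i] != coded) & both
        counts[i] = diff.sum(axis=1)
        comparable[i] = both.sum(axis=1)
    np.fill_diagonal(counts, 0)
    return KinshipMatrix(list(gm.varieties), counts, comparable)


# ---------------------------------------------------------------------------
# Core SNP selection
# ---------------------------------------------------------------------------

@dataclass
class CoreSet:
    loci: list[str]  # in selection order
    curve: list[tuple[int, int, float]]  # (k, distinguished pairs, fraction)
    total_pairs: int
    distinguishable_pairs: int  # using ALL loci of the input matrix
    unresolved_pairs: list[tuple[str, str]]
    unique_profile_fraction: float  # varieties with a unique core-set profile

    @property
    def final_fraction(self) -> float:
        return self.curve[-1][2] if self.curve else 0.0


def _pair_resolution(gm: GenotypeMatrix) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Boolean (n_loci, n_pairs) matrix: locus j distinguishes pair p."""
    coded = gm.encode()
    valid = coded >= 0
    pairs = list(combinations(range(gm.n_varieties), 2))
    res = np.zeros((gm.n_loci, len(pairs)), dtype=bool)
    for p, (u, v) in enumerate(pairs):
        res[:, p] = (coded[u] != coded[v]) & valid[u] & valid[v]
    return res, pairs


def select_core_snps(
    gm: GenotypeMatrix,
    mode: str = "greedy",
    max_size: int | None = None,
) -> CoreSet:
    """Select a minimal (greedy or provably minimal) locus subset that
    distinguishes as many variety pairs as the full panel does.

    greedy: repeatedly add the locus resolving the most currently unresolved
    pairs, ties broken by higher PIC then input (genome) order, until no pair
    gains or ``max_size`` is reached. exhaustive: size-increasing subset
    search, feasible only for small inputs.
    """
    if gm.n_loci == 0 or gm.n_varieties < 2:
        raise DataError("matrix must have >=1 locus and >=2 varieties")
    res, pairs = _pair_resolution(gm)
    n_pairs = len(pairs)
    target = int(res.any(axis=0).sum())  # distinguishable with all loci

    if mode == "greedy":
        order = _greedy_order(gm, res, target, max_size)
    elif mode == "exhaustive":
        if gm.n_loci > EXHAUSTIVE_MAX_LOCI or gm.n_varieties > EXHAUSTIVE_MAX_VARIETIES:
            raise DataError(
                f"exhaustive search bounded at {EXHAUSTIVE_MAX_LOCI} loci / "
                f"{EXHAUSTIVE_MAX_VARIETIES} varieties; use mode='greedy'"
            )
        order = _exhaustive_minimal(res, target)
        if max_size is not None:
            order = order[:max_size]
    else:
        raise DataError(f"unknown mode {mode!r}")

    curve: list[tuple[int, int, float]] = []
    covered = np.zeros(n_pairs, dtype=bool)
    for k, j in enumerate(order, start=1):
        covered |= res[j]
        curve.append((k, int(covered.sum()), covered.sum() / n_pairs))
    unresolved = [
        (gm.varieties[pairs[p][0]], gm.varieties[pairs[p][1]])
        for p in np.flatnonzero(~covered)
    ]
    # alternative denominator: varieties whose selected-loci profile is unique
    sel = sorted(order)
    coded = gm.encode()[:, sel] if sel else np.zeros((gm.n_varieties, 0), dtype=int)
    profiles: dict[tuple, int] = {}
    for i in range(gm.n_varieties):
        key = tuple(coded[i])
        profiles[key] = profiles.get(key, 0) + 1
    unique_frac = sum(1 for i in range(gm.n_varieties)
                      if profiles[tuple(coded[i])] == 1) / gm.n_varieties
    return CoreSet(
        loci=[gm.loci[j] for j in order],
        curve=curve,
        total_pairs=n_pairs,
        distinguishable_pairs=target,
        unresolved_pairs=unresolved,
        unique_profile_fraction=unique_frac,
    )


def _greedy_order(
    gm: GenotypeMatrix, res: np.ndarray, target: int, max_size: int | None
) -> list[int]:
    pic_of = np.empty(gm.n_loci)
    for j, locus in enumerate(gm.loci):
        try:
            pic_of[j] = locus_stats(gm, locus).pic
        except DataError:
            pic_of[j] = -1.0  # all-missing locus: lowest priority
    covered = np.zeros(res.shape[1], dtype=bool)
    order: list[int] = []
    remaining = set(range(gm.n_loci))
    while remaining and (max_size is None or len(order) < max_size):
        gains = {j: int((res[j] & ~covered).sum()) for j in remaining}
        best_gain = max(gains.values())
        if best_gain == 0:
            break
        # tie-break: higher PIC, then genome (input) order
        best = min(
            (j for j in remaining if gains[j] == best_gain),
            key=lambda j: (-pic_of[j], j),
        )
        order.append(best)
        covered |= res[best]
        remaining.discard(best)
        if covered.sum() >= target:
            break
    return order


def _exhaustive_minimal(res: np.ndarray, target: int) -> list[int]:
    """Smallest subset reaching the all-loci distinguished-pair count, by
    size-increasing search with a simple best-case pruning bound."""
    n_loci = res.shape[0]
    per_locus = res.sum(axis=1)
    ranked = np.argsort(-per_locus)  # try strong loci first
    for k in range(1, n_loci + 1):
        if per_locus[ranked[:k]].sum() < target:
            continue  # even the k best loci cannot cover enough pairs
        for combo in combinations(ranked.tolist(), k):
            if int(np.any(res[list(combo)], axis=0).sum()) >= target:
                return list(combo)
    return list(range(n_loci))


# ---------------------------------------------------------------------------
# Core (backbone) varieties
# ---------------------------------------------------------------------------

@dataclass
class CoreVarieties:
    per_subpop_mean_differential: dict[str, dict[str, float]]
    selected: dict[str, list[str]]  # subpop -> chosen varieties

    @property
    def all_selected(self) -> list[str]:
        return [v for sel in self.selected.values() for v in sel]


def select_core_varieties(
    km: KinshipMatrix,
    subgroup_map: dict[str, str],
    fraction: float = 0.1,
) -> CoreVarieties:
    """Per subpopulation, rank varieties by mean differential-genotype count
    against the other members (ascending: closest kinship first) and keep the
    top ``ceil(fraction * size)``. Ties are broken by variety-id order."""
    groups: dict[str, list[str]] = {}
    for v in km.varieties:
        g = subgroup_map.get(v)
        if g is None:
            raise DataError(f"variety {v!r} has no subgroup assignment")
        groups.setdefault(g, []).append(v)
    means: dict[str, dict[str, float]] = {}
    selected: dict[str, list[str]] = {}
    for label in sorted(groups):
        members = groups[label]
        if not members:
            raise DataError(f"subpopulation {label} is empty")
        mean_diff = km.mean_differential(members)
        means[label] = mean_diff
        k = math.ceil(fraction * len(members))
        ranked = sorted(members, key=lambda v: (mean_diff[v], v))
        selected[label] = ranked[:k]
    return CoreVarieties(per_subpop_mean_differential=means, selected=selected)


# ---------------------------------------------------------------------------
# Distance / similarity matrices and matrix correlation
# ---------------------------------------------------------------------------

def allele_sharing_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Simple genetic distance: 1 - (shared alleles / 2) averaged over
    pairwise-complete loci. NaN for pairs with no comparable locus."""
    n = gm.n_varieties
    dist = np.full((n, n), np.nan)
    np.fill_diagonal(dist, 0.0)
    cols = gm.calls
    for i in range(n):
        for j in range(i + 1, n):
            shared_sum = 0.0
            used = 0
            for l in range(gm.n_loci):
                a, b = cols[i, l], cols[j, l]
                if a is None or b is None:
                    continue
                used += 1
                shared_sum += _shared_alleles(a, b) / 2.0
            if used:
                d = 1.0 - shared_sum / used
                dist[i, j] = dist[j, i] = d
    return dist


def _shared_alleles(a: tuple[str, str], b: tuple[str, str]) -> int:
    """Number of allele copies shared between two unordered pairs (0, 1, 2)."""
    pool = list(b)
    shared = 0
    for x in a:
        if x in pool:
            pool.remove(x)
            shared += 1
    return shared


def genetic_similarity(gm: GenotypeMatrix) -> np.ndarray:
    """Complement of the allele-sharing distance."""
    return 1.0 - allele_sharing_distance(gm)


def matrix_correlation(m1: np.ndarray, m2: np.ndarray) -> float | None:
    """Pearson r between two same-shaped symmetric variety matrices over the
    strictly-lower-triangle entries; pairs missing in either matrix are
    dropped. None when either triangle is constant (r undefined)."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] != m1.shape[1]:
        raise DataError(f"matrices must be square and same-shaped: {m1.shape} vs {m2.shape}")
    il = np.tril_indices(m1.shape[0], k=-1)
    x, y = m1[il], m2[il]
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    return float(np.corrcoef(x, y)[0, 1])
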