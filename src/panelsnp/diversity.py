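"""Per-locus and per-subpopulation genetic diversity statistics.

With allele frequencies ``P_i`` at a locus:

* ``He = D = 1 - sum(P_i^2)``      expected heterozygosity / Simpson diversity
* ``PIC = 1 - sum(P_i^2) - sum_{i<j} 2 P_i^2 P_j^2``
* ``Ho``                           fraction of heterozygous calls
* ``F = 1 - Ho / He``              inbreeding coefficient (undefined at He=0)

``He`` is Nei's gene diversity without small-sample correction, which makes
``He`` and ``D`` coincide per locus; a bias-corrected variant
(``* 2n/(2n-1)``) is available by flag. Note that the PIC of a biallelic
locus is bounded by 0.375 (at P = 0.5) while D reaches 0.5, so the two are
never interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats import DataError, GenotypeMatrix


def _check_freqs(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(freqs), dtype=float)
    if (p < 0).any():
        raise DataError(f"negative allele frequency in {list(freqs)}")
    if abs(p.sum() - 1.0) > 1e-6:
        raise DataError(f"allele frequencies sum to {p.sum()}, expected 1")
    return p


def pic(freqs: Sequence[float]) -> float:
    """Polymorphic information content."""
    p = _check_freqs(freqs)
    p2 = p ** 2
    cross = (p2.sum() ** 2 - (p2 ** 2).sum()) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - p2.sum() - 2.0 * cross)


def simpson_d(freqs: Sequence[float]) -> float:
    """Simpson's index of diversity, 1 - sum(P_i^2)."""
    p = _check_freqs(freqs)
    return float(1.0 - (p ** 2).sum())


def expected_het(freqs: Sequence[float], n: int | None = None, corrected: bool = False) -> float:
    """Expected heterozygosity; optionally bias-corrected by 2n/(2n-1)."""
    he = simpson_d(freqs)
    if corrected:
        if n is None or n < 1:
            raise DataError("sample size required for the bias-corrected He")
        he *= 2 * n / (2 * n - 1)
    return he


def inbreeding_f(ho: float, he: float) -> float | None:
    """F = 1 - Ho/He; None (missing) when He = 0."""
    if he == 0:
        return None
    return 1.0 - ho / he


@dataclass
class LocusStats:
    locus: str
    freqs: dict[str, float]
    maf: float
    ho: float
    he: float
    pic: float
    d: float
    f: float | None
    n: int  # non-missing sample count


def locus_stats(
    gm: GenotypeMatrix,
    locus: str,
    subset: list[str] | None = None,
    corrected_he: bool = False,
) -> LocusStats:
    """Diversity statistics at one locus, each variety contributing two allele
    copies; frequencies computed over non-missing calls only."""
    col = gm.locus_column(locus)
    if subset is not None:
        idx = [gm.varieties.index(v) for v in subset]
        col = col[idx]
    calls = [c for c in col if c is not None]
    if not calls:
        raise DataError(f"{locus}: no non-missing calls in subset")
    counts: dict[str, int] = {}
    n_het = 0
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        if a != b:
            n_het += 1
    total = 2 * len(calls)
    freqs = {allele: c / total for allele, c in sorted(counts.items())}
    p = list(freqs.values())
    ordered = sorted(p, reverse=True)
    maf = ordered[1] if len(ordered) > 1 else 0.0
    ho = n_het / len(calls)
    he = expected_het(p, n=len(calls), corrected=corrected_he)
    return LocusStats(
        locus=locus,
        freqs=freqs,
        maf=maf,
        ho=ho,
        he=he,
        pic=pic(p),
        d=simpson_d(p),
        f=inbreeding_f(ho, he),
        n=len(calls),
    )


def all_locus_stats(
    gm: GenotypeMatrix, subset: list[str] | None = None, corrected_he: bool = False
) -> list[LocusStats]:
    return [locus_stats(gm, l, subset, corrected_he) for l in gm.loci]


@dataclass
class SubpopStats:
    subpop: str
    n_varieties: int
    mean_pic: float
    mean_maf: float
    mean_ho: float
    mean_he: float
    mean_f: float | None
    mean_differential_markers: float | None = None


def subpop_summary(
    gm: GenotypeMatrix,
    subgroup_map: dict[str, str],
    mean_differential: dict[str, float] | None = None,
    corrected_he: bool = False,
) -> list[SubpopStats]:
    """Per-subpopulation means of the locus statistics.

    F is computed per locus and averaged over loci where it is defined
    (He > 0); when no locus defines it the mean is reported missing. Mean
    pairwise differential-marker counts, when supplied (from the kinship
    module), are attached per subpopulation.
    """
    missing = set(gm.varieties) - set(subgroup_map)
    if missing:
        raise DataError(f"varieties without subgroup assignment: {sorted(missing)[:5]}")
    groups: dict[str, list[str]] = {}
    for v in gm.varieties:
        groups.setdefault(subgroup_map[v], []).append(v)
    out: list[SubpopStats] = []
    for label in sorted(groups):
        members = groups[label]
        if not members:
            raise DataError(f"subpopulation {label} is empty")
        stats = []
        for locus in gm.loci:
            try:
                stats.append(locus_stats(gm, locus, members, corrected_he))
            except DataError:
                continue  # all-missing locus within this subpop
        if not stats:
            raise DataError(f"subpopulation {label}: no callable loci")
        f_vals = [s.f for s in stats if s.f is not None]
        out.append(
            SubpopStats(
                subpop=label,
                n_varieties=len(members),
                mean_pic=float(np.mean([s.pic for s in stats])),
                mean_maf=float(np.mean([s.maf for s in stats])),
                mean_ho=float(np.mean([s.ho for s in stats])),
                mean_he=float(np.mean([s.he for s in stats])),
                mean_f=float(np.mean(f_vals)) if f_vals else None,
                mean_differential_markers=(
                    mean_differential.get(label) if mean_differential else None
                ),
            )
        )
    return out
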