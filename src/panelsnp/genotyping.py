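"""Depth-based genotype calling for targeted-amplicon SNP assays.

At each variety x locus the allele with the most reads is the major allele and
the runner-up the minor allele. Calls use the major-allele ratio
``r = major / (major + minor)``:

* major depth below the floor (default 20 reads)  -> missing (low_depth)
* r < het_ratio_max (default 0.7)                 -> heterozygous major/minor
* r >= hom_ratio_min (default 0.8)                -> homozygous major
* otherwise                                       -> missing (ambiguous_ratio)

The 0.7-0.8 band is deliberately uncallable: treating it as missing is what
makes the confident-call rate (het band + hom band) a lower bound on accuracy.
Reads of any third allele at a biallelic locus never enter the ratio; they are
reported as contamination depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .formats import DataError, DepthRecord, GenotypeMatrix, canonical_call

logger = logging.getLogger(__name__)


@dataclass
class CallThresholds:
    min_major_depth: int = 20
    het_ratio_max: float = 0.7
    hom_ratio_min: float = 0.8

    def __post_init__(self) -> None:
        if not (0.5 <= self.het_ratio_max <= self.hom_ratio_min <= 1.0):
            raise DataError(
                "require 0.5 <= het_ratio_max <= hom_ratio_min <= 1.0, got "
                f"{self.het_ratio_max}/{self.hom_ratio_min}"
            )
        if self.min_major_depth < 1:
            raise DataError("min_major_depth must be >= 1")


@dataclass
class GenotypeCall:
    variety: str
    locus: str
    call: tuple[str, str] | None  # unordered allele pair, None = missing
    major_allele: str | None
    minor_allele: str | None
    major_depth: int
    minor_depth: int
    total_depth: int
    major_ratio: float | None
    missing_reason: str | None  # low_depth | ambiguous_ratio | no_data | None
    contamination_depth: int = 0

    @property
    def is_het(self) -> bool:
        return self.call is not None and self.call[0] != self.call[1]

    @property
    def is_hom(self) -> bool:
        return self.call is not None and self.call[0] == self.call[1]


def call_genotype(rec: DepthRecord, thresholds: CallThresholds | None = None) -> GenotypeCall:
    """Classify one depth record. A depth tie between the top two alleles is
    maximal evidence of heterozygosity: the lexically smaller allele is named
    major and the call is het (its ratio 0.5 sits below any het threshold)."""
    if thresholds is None:
        thresholds = CallThresholds()
    if not rec.allele_depths:
        return _missing(rec, "no_data")
    # sort by depth desc, then allele asc, so ties name the smaller allele major
    ranked = sorted(rec.allele_depths.items(), key=lambda kv: (-kv[1], kv[0]))
    major_allele, major_depth = ranked[0]
    if len(ranked) > 1:
        minor_allele, minor_depth = ranked[1]
    else:
        minor_allele, minor_depth = None, 0
    contamination = sum(d for _, d in ranked[2:])
    total = rec.total_depth
    if major_depth < thresholds.min_major_depth:
        return _missing(rec, "low_depth", major_allele, minor_allele,
                        major_depth, minor_depth, total, contamination)
    ratio = major_depth / (major_depth + minor_depth)
    if ratio < thresholds.het_ratio_max or (minor_depth == major_depth):
        call = canonical_call(major_allele, minor_allele)
    elif ratio >= thresholds.hom_ratio_min:
        call = (major_allele, major_allele)
    else:
        return GenotypeCall(
            rec.variety, rec.locus, None, major_allele, minor_allele,
            major_depth, minor_depth, total, ratio, "ambiguous_ratio",
            contamination,
        )
    return GenotypeCall(
        rec.variety, rec.locus, call, major_allele, minor_allele,
        major_depth, minor_depth, total, ratio, None, contamination,
    )


def _missing(
    rec: DepthRecord, reason: str, major=None, minor=None,
    major_depth=0, minor_depth=0, total=0, contamination=0,
) -> GenotypeCall:
    return GenotypeCall(
        rec.variety, rec.locus, None, major, minor, major_depth, minor_depth,
        total, None, reason, contamination,
    )


def build_matrix(
    records: Iterable[DepthRecord],
    panel: list[str],
    varieties: list[str],
    thresholds: CallThresholds | None = None,
) -> tuple[GenotypeMatrix, list[GenotypeCall]]:
    """Call every record and assemble the full varieties x panel matrix.

    Cells with no record become missing (no_data); records for loci outside
    the panel are dropped with a warning.
    """
    if thresholds is None:
        thresholds = CallThresholds()
    panel_set = set(panel)
    calls: dict[tuple[str, str], GenotypeCall] = {}
    n_dropped = 0
    all_calls: list[GenotypeCall] = []
    for rec in records:
        if rec.locus not in panel_set:
            n_dropped += 1
            continue
        gc = call_genotype(rec, thresholds)
        calls[(rec.variety, rec.locus)] = gc
        all_calls.append(gc)
    if n_dropped:
        logger.warning("dropped %d depth records for loci outside the panel", n_dropped)
    matrix = np.empty((len(varieties), len(panel)), dtype=object)
    for i, v in enumerate(varieties):
        for j, l in enumerate(panel):
            gc = calls.get((v, l))
            if gc is None:
                gc = GenotypeCall(v, l, None, None, None, 0, 0, 0, None, "no_data")
                all_calls.append(gc)
            matrix[i, j] = gc.call
    return GenotypeMatrix(list(varieties), list(panel), matrix), all_calls


# ---------------------------------------------------------------------------
# QC summaries
# ---------------------------------------------------------------------------

@dataclass
class QcSummary:
    """Depth and ratio distributions plus the locus exclusion list."""

    depth_band_fractions: dict[str, float]  # of records, by total depth
    ratio_band_fractions: dict[str, float]  # of depth-passing records
    mean_depth_per_locus: dict[str, float]
    mean_depth_per_variety: dict[str, float]
    call_rate_per_locus: dict[str, float]
    excluded_loci: list[str]
    exclusion_reasons: dict[str, list[str]]

    @property
    def confident_call_rate(self) -> float:
        """Fraction of depth-passing records in the het band (ratio below the
        het threshold) plus the hom band (ratio at or above the hom threshold);
        a lower bound on genotype accuracy under the band model."""
        return self.ratio_band_fractions["het_band"] + self.ratio_band_fractions["hom_band"]


def qc_summaries(
    calls: list[GenotypeCall],
    locus_pic: dict[str, float] | None = None,
    pic_min: float = 0.1,
    miss_max: float = 0.1,
    depth_bands: tuple[int, int] = (100, 5000),
    thresholds: CallThresholds | None = None,
) -> QcSummary:
    """Summarize depth/ratio distributions and flag weak loci.

    Loci are flagged for exclusion when their polymorphic information content
    falls below ``pic_min`` or their missing rate exceeds ``miss_max``.
    ``locus_pic`` comes from the diversity module.
    """
    lo, hi = depth_bands
    totals = np.array([c.total_depth for c in calls], dtype=float)
    n = len(calls)
    if n == 0:
        raise DataError("no calls to summarize")
    depth_fracs = {
        f"below_{lo}": float((totals < lo).mean()),
        f"{lo}_to_{hi}": float(((totals >= lo) & (totals <= hi)).mean()),
        f"above_{hi}": float((totals > hi).mean()),
    }
    with_ratio = [c for c in calls if c.major_ratio is not None]
    thr = thresholds if thresholds is not None else CallThresholds()
    if with_ratio:
        ratios = np.array([c.major_ratio for c in with_ratio])
        ratio_fracs = {
            "het_band": float((ratios < thr.het_ratio_max).mean()),
            "ambiguous_band": float(
                ((ratios >= thr.het_ratio_max) & (ratios < thr.hom_ratio_min)).mean()
            ),
            "hom_band": float((ratios >= thr.hom_ratio_min).mean()),
        }
    else:
        ratio_fracs = {"het_band": 0.0, "ambiguous_band": 0.0, "hom_band": 0.0}

    by_locus: dict[str, list[GenotypeCall]] = {}
    by_variety: dict[str, list[GenotypeCall]] = {}
    for c in calls:
        by_locus.setdefault(c.locus, []).append(c)
        by_variety.setdefault(c.variety, []).append(c)
    mean_depth_locus = {
        l: float(np.mean([c.total_depth for c in cs])) for l, cs in by_locus.items()
    }
    mean_depth_var = {
        v: float(np.mean([c.total_depth for c in cs])) for v, cs in by_variety.items()
    }
    call_rate = {
        l: float(np.mean([c.call is not None for c in cs]))
        for l, cs in by_locus.items()
    }
    excluded: list[str] = []
    reasons: dict[str, list[str]] = {}
    for locus, rate in call_rate.items():
        r: list[str] = []
        missing_rate = 1.0 - rate
        if missing_rate > miss_max:
            r.append(f"missing_rate {missing_rate:.3f} > {miss_max}")
        if locus_pic is not None and locus in locus_pic and locus_pic[locus] < pic_min:
            r.append(f"PIC {locus_pic[locus]:.3f} < {pic_min}")
        if r:
            excluded.append(locus)
            reasons[locus] = r
    return QcSummary(
        depth_band_fractions=depth_fracs,
        ratio_band_fractions=ratio_fracs,
        mean_depth_per_locus=mean_depth_locus,
        mean_depth_per_variety=mean_depth_var,
        call_rate_per_locus=call_rate,
        excluded_loci=sorted(excluded),
        exclusion_reasons=reasons,
    )
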