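"""Discovery of "perfect" SNPs from population variant calls.

A perfect SNP is a biallelic SNP whose flanking windows map uniquely to the
reference genome, contain no other variant or microsatellite across the
accession panel, and whose population statistics pass heterozygosity, missing
rate and minor-allele-frequency thresholds. A subgroup-differential rescue
rule additionally retains sites that are near-fixed (>=0.95) for an allele in
exactly one subgroup while rare (<=0.05) in every other subgroup — low global
MAF, but diagnostic for the subgroup.

Boundary semantics are taken literally from the filter definitions:
heterozygosity passes at "no more than" the threshold (<=), missing rate at
"less than" (<), and MAF at "above" (strict >).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .formats import (
    MISSING,
    DataError,
    ReferenceGenome,
    VariantSite,
    VariantTable,
    reverse_complement,
)

#: MISA-convention minimum copy numbers per microsatellite motif length
DEFAULT_SSR_MIN_COPIES: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class FilterThresholds:
    """Thresholds of the perfect-SNP filter chain."""

    flank_bp: int = 30
    het_max: float = 0.2
    miss_max: float = 0.2
    maf_min: float = 0.4
    subgroup_hi: float = 0.95
    subgroup_lo: float = 0.05
    ssr_min_copies: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_SSR_MIN_COPIES)
    )

    def __post_init__(self) -> None:
        if self.flank_bp < 1:
            raise DataError("flank_bp must be >= 1")
        for name in ("het_max", "miss_max", "maf_min", "subgroup_hi", "subgroup_lo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        for m, c in self.ssr_min_copies.items():
            if not (1 <= m <= 6) or c < 2:
                raise DataError(f"invalid SSR rule: motif length {m}, copies {c}")


@dataclass
class SiteFrequencies:
    """Per-site allele frequencies and rates over non-missing accessions."""

    freqs: dict[str, float]
    subgroup_freqs: dict[str, dict[str, float]] | None
    het_rate: float
    missing_rate: float
    n_called: int

    @property
    def maf(self) -> float:
        ordered = sorted(self.freqs.values(), reverse=True)
        return ordered[1] if len(ordered) > 1 else 0.0


@dataclass
class SiteAudit:
    """Verdict of every criterion for one candidate site."""

    locus: str
    biallelic: bool
    flanking_unique: bool
    flanking_reason: str | None
    neighborhood_clean: bool
    neighborhood_reasons: list[str]
    het_pass: bool
    missing_pass: bool
    maf_pass: bool
    subgroup_differential: bool
    het_rate: float
    missing_rate: float
    maf: float
    subgroup_freqs: dict[str, dict[str, float]] | None

    @property
    def final(self) -> bool:
        return (
            self.biallelic
            and self.flanking_unique
            and self.neighborhood_clean
            and self.het_pass
            and self.missing_pass
            and (self.maf_pass or self.subgroup_differential)
        )

    @property
    def failed_criteria(self) -> list[str]:
        failed = []
        if not self.biallelic:
            failed.append("biallelic")
        if not self.flanking_unique:
            failed.append("flanking_unique")
        if not self.neighborhood_clean:
            failed.append("neighborhood_clean")
        if not self.het_pass:
            failed.append("heterozygosity")
        if not self.missing_pass:
            failed.append("missing_rate")
        if not (self.maf_pass or self.subgroup_differential):
            failed.append("maf")
        return failed


def site_frequencies(
    site: VariantSite, subgroup_map: dict[str, str] | None = None,
    samples: list[str] | None = None,
) -> SiteFrequencies:
    """Allele frequencies, het rate and missing rate for one site.

    Frequencies and het rate are computed over non-missing accessions only;
    missing rate over all accessions. When a subgroup map is given, per-
    subgroup allele frequencies are computed the same way within each group.
    """
    states = site.states
    called = states[:, 0] != MISSING
    n_total = states.shape[0]
    n_called = int(called.sum())
    if n_called == 0:
        raise DataError(f"{site.locus_id}: all accessions missing")
    alleles = site.alleles

    def freqs_of(mask: np.ndarray) -> dict[str, float]:
        sub = states[mask]
        counts = np.bincount(sub.ravel(), minlength=len(alleles))
        total = counts.sum()
        return {a: counts[k] / total for k, a in enumerate(alleles)} if total else {
            a: 0.0 for a in alleles
        }

    het = states[:, 0] != states[:, 1]
    out_sub: dict[str, dict[str, float]] | None = None
    if subgroup_map is not None:
        if samples is None:
            raise DataError("samples required with subgroup_map")
        groups = sorted(set(subgroup_map.values()))
        sample_group = np.array([subgroup_map[s] for s in samples])
        out_sub = {}
        for g in groups:
            mask = called & (sample_group == g)
            if mask.any():
                out_sub[g] = freqs_of(mask)
    return SiteFrequencies(
        freqs=freqs_of(called),
        subgroup_freqs=out_sub,
        het_rate=float(het[called].sum()) / n_called,
        missing_rate=float(n_total - n_called) / n_total,
        n_called=n_called,
    )


def flanking_unique(
    site: VariantSite, genome: ReferenceGenome, flank_bp: int = 30
) -> tuple[bool, int, str | None]:
    """Does the (2*flank_bp + 1)-mer centered on the site occur exactly once
    over both strands of the genome?

    Returns (verdict, occurrence_count, failure_reason). Sites too close to a
    chromosome end fail with reason "edge"; windows containing N fail with
    reason "ambiguous base".
    """
    seq = genome.sequences.get(site.chrom)
    if seq is None:
        raise DataError(f"{site.locus_id}: chromosome {site.chrom!r} not in genome")
    start = site.pos - 1 - flank_bp
    end = site.pos + flank_bp  # exclusive
    if start < 0 or end > len(seq):
        return False, 0, "edge"
    kmer = seq[start:end]
    if "N" in kmer:
        return False, 0, "ambiguous base"
    count = 0
    rc = reverse_complement(kmer)
    for chrom_seq in genome.sequences.values():
        count += _count_overlapping(chrom_seq, kmer)
        count += _count_overlapping(chrom_seq, rc)
    return count == 1, count, None if count == 1 else "multiple hits"


def _count_overlapping(haystack: str, needle: str) -> int:
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def find_ssrs(seq: str, min_copies: dict[int, int]) -> list[str]:
    """Microsatellites in ``seq`` per the configured motif/copy thresholds.

    A run counts only if its motif is not itself a repetition of a shorter
    unit (so poly-A is a mononucleotide SSR, never a dinucleotide "AA" one).
    Returns motif strings like "(AT)7".
    """
    found: list[str] = []
    for m, copies in sorted(min_copies.items()):
        pattern = re.compile(r"([ACGT]{%d})\1{%d,}" % (m, copies - 1))
        pos = 0
        while True:
            match = pattern.search(seq, pos)
            if match is None:
                break
            motif = match.group(1)
            if not _is_repetition(motif):
                n = len(match.group(0)) // m
                found.append(f"({motif}){n}")
            pos = match.start() + 1
    return found


def _is_repetition(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return True
    return False


def neighborhood_clean(
    site: VariantSite,
    table: VariantTable,
    genome: ReferenceGenome,
    thresholds: FilterThresholds,
) -> tuple[bool, list[str]]:
    """No other variant (SNP or indel) within +-flank_bp, and no SSR in the
    flanking window. Returns (verdict, offending features)."""
    reasons: list[str] = []
    flank = thresholds.flank_bp
    for other in table.sites:
        if other is site or other.chrom != site.chrom:
            continue
        offset = other.pos - site.pos
        if other.pos == site.pos and other is not site:
            reasons.append("variant@+0")
            continue
        if 0 < abs(offset) <= flank:
            kind = "Indel" if other.is_indel else "SNP"
            reasons.append(f"{kind}@{offset:+d}")
    seq = genome.sequences.get(site.chrom)
    if seq is not None:
        start = max(site.pos - 1 - flank, 0)
        end = min(site.pos + flank, len(seq))
        window = seq[start:end]
        for motif in find_ssrs(window, thresholds.ssr_min_copies):
            reasons.append(f"SSR{motif.split(')')[0] + ')'}")
    return (not reasons), reasons


def _subgroup_differential(
    sf: SiteFrequencies, thresholds: FilterThresholds
) -> bool:
    """True iff some allele is near-fixed (>= subgroup_hi) in exactly one
    subgroup and rare (<= subgroup_lo) in every other subgroup."""
    if not sf.subgroup_freqs or len(sf.subgroup_freqs) < 2:
        return False
    groups = list(sf.subgroup_freqs)
    alleles = list(sf.freqs)
    for allele in alleles:
        for g in groups:
            if sf.subgroup_freqs[g].get(allele, 0.0) >= thresholds.subgroup_hi and all(
                sf.subgroup_freqs[h].get(allele, 0.0) <= thresholds.subgroup_lo
                for h in groups
                if h != g
            ):
                return True
    return False


def audit_site(
    site: VariantSite,
    table: VariantTable,
    genome: ReferenceGenome,
    thresholds: FilterThresholds,
    subgroup_map: dict[str, str] | None = None,
) -> SiteAudit:
    """Run every perfect-SNP criterion on one site."""
    sf = site_frequencies(site, subgroup_map, table.samples)
    uniq, _count, reason = flanking_unique(site, genome, thresholds.flank_bp)
    clean, clean_reasons = neighborhood_clean(site, table, genome, thresholds)
    return SiteAudit(
        locus=site.locus_id,
        biallelic=site.is_biallelic_snp,
        flanking_unique=uniq,
        flanking_reason=reason,
        neighborhood_clean=clean,
        neighborhood_reasons=clean_reasons,
        het_pass=sf.het_rate <= thresholds.het_max,
        missing_pass=sf.missing_rate < thresholds.miss_max,
        maf_pass=sf.maf > thresholds.maf_min,
        subgroup_differential=_subgroup_differential(sf, thresholds),
        het_rate=sf.het_rate,
        missing_rate=sf.missing_rate,
        maf=sf.maf,
        subgroup_freqs=sf.subgroup_freqs,
    )


@dataclass
class PanelResult:
    panel: list[VariantSite]
    audits: list[SiteAudit]

    @property
    def funnel(self) -> dict[str, int]:
        """How many sites fail each criterion (a site may fail several)."""
        counts = {
            "input": len(self.audits),
            "biallelic": 0,
            "flanking_unique": 0,
            "neighborhood_clean": 0,
            "heterozygosity": 0,
            "missing_rate": 0,
            "maf": 0,
            "rescued_by_subgroup": 0,
            "panel": len(self.panel),
        }
        for a in self.audits:
            for c in a.failed_criteria:
                counts[c] += 1
            if a.final and not a.maf_pass and a.subgroup_differential:
                counts["rescued_by_subgroup"] += 1
        return counts


def select_perfect_snps(
    table: VariantTable,
    genome: ReferenceGenome,
    thresholds: FilterThresholds | None = None,
    subgroup_map: dict[str, str] | None = None,
) -> PanelResult:
    """Apply all criteria to every site; return the panel plus one audit per
    input site. Verdicts depend only on site content, never on input order."""
    if not table.sites:
        raise DataError("variant table is empty")
    if thresholds is None:
        thresholds = FilterThresholds()
    if subgroup_map is None:
        subgroup_map = table.subgroup_map
    audits = [
        audit_site(site, table, genome, thresholds, subgroup_map)
        for site in table.sites
    ]
    panel = [site for site, a in zip(table.sites, audits) if a.final]
    return PanelResult(panel=panel, audits=audits)


def subsample_evenly(panel: list[VariantSite], n: int) -> list[VariantSite]:
    """Convenience reducer: pick ``n`` panel sites spread evenly along the
    genome (by rank of genomic coordinate). Used to thin a large panel to an
    assay-sized one; makes no claim of optimality."""
    if n >= len(panel):
        return list(panel)
    ordered = sorted(panel, key=lambda s: (s.chrom, s.pos))
    idx = np.linspace(0, len(ordered) - 1, n).round().astype(int)
    return [ordered[i] for i in sorted(set(idx.tolist()))]
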