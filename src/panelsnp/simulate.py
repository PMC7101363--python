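"""Synthetic structured populations and targeted-amplicon read depths.

The generator emulates a panel of inbred crop varieties drawn from a small
number of diverged subpopulations, genotyped by deep amplicon sequencing:

* per-locus ancestral allele frequencies drawn from a configurable spectrum;
* subpopulation frequencies diverged around the ancestral frequency under a
  Balding–Nichols (beta) model whose variance is set by ``fst_target``;
* varieties homozygous at almost every locus, heterozygous with a small
  residual probability (seed-lot contamination / incomplete inbreeding);
* per variety x locus sequencing depth drawn from a negative binomial whose
  overdispersion reproduces the wide (~50-fold) spread seen in multiplexed
  amplicon runs, with reads split binomially between the two true alleles.

Defaults correspond to a 261-variety, 4-subpopulation panel typed at 163 loci
with ~2000x mean coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats import (
    DataError,
    DepthRecord,
    GenotypeMatrix,
    ReferenceGenome,
    VariantSite,
    VariantTable,
)

_BASES = "ACGT"


@dataclass
class SimConfig:
    """All knobs of the generator; a single seed fixes the full output stream."""

    n_subpops: int = 4
    subpop_sizes: tuple[int, ...] = (78, 105, 58, 20)
    n_loci: int = 163
    #: target differentiation (Balding–Nichols F) between subpopulations
    fst_target: float = 0.43
    #: ancestral minor-allele frequency drawn Uniform(maf_low, maf_high)
    maf_low: float = 0.3
    maf_high: float = 0.5
    #: probability a variety is heterozygous at a locus (attained wherever the
    #: subpopulation frequency permits; expected allele frequencies are
    #: preserved exactly)
    residual_het: float = 0.17
    #: negative-binomial coverage law per variety x locus
    mean_depth: float = 2000.0
    depth_dispersion: float = 1.2
    #: per-read probability of reporting the wrong allele (homozygotes)
    error_rate: float = 0.002
    #: probability a record's depth is resampled below the caller's depth
    #: floor, forcing a missing call
    missing_rate: float = 0.05
    #: the caller's major-depth floor (used only to force missingness)
    min_major_depth: int = 20
    #: spacing between simulated SNPs on the synthetic chromosome (bp)
    locus_spacing: int = 400
    seed: int = 0

    def validate(self) -> None:
        if self.n_subpops < 1 or len(self.subpop_sizes) != self.n_subpops:
            raise DataError("subpop_sizes must list one size per subpopulation")
        if any(s < 1 for s in self.subpop_sizes):
            raise DataError("subpopulation sizes must be >= 1")
        if self.n_loci < 1:
            raise DataError("n_loci must be >= 1")
        for name in ("fst_target", "residual_het", "error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise DataError("require 0 < maf_low <= maf_high <= 0.5")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise DataError("mean_depth and depth_dispersion must be positive")
        if self.locus_spacing < 100:
            raise DataError("locus_spacing must leave room for flanking windows")

    @property
    def n_varieties(self) -> int:
        return int(sum(self.subpop_sizes))

    @property
    def subpop_labels(self) -> list[str]:
        return [f"Pop{k + 1}" for k in range(self.n_subpops)]


@dataclass
class TruthSet:
    """Ground truth emitted by :func:`simulate_population`."""

    config: SimConfig
    genome: ReferenceGenome
    variant_table: VariantTable
    genotypes: GenotypeMatrix
    subgroup_map: dict[str, str]
    ancestral_freqs: np.ndarray  # alt-allele frequency per locus
    subpop_freqs: np.ndarray  # (n_subpops, n_loci) alt-allele frequency

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthSet):
            return NotImplemented
        return (
            self.config == other.config
            and self.genome.sequences == other.genome.sequences
            and self.variant_table.sites == other.variant_table.sites
            and self.genotypes == other.genotypes
            and self.subgroup_map == other.subgroup_map
            and np.array_equal(self.ancestral_freqs, other.ancestral_freqs)
            and np.array_equal(self.subpop_freqs, other.subpop_freqs)
        )


def simulate_population(cfg: SimConfig) -> TruthSet:
    """Draw a structured population with known per-locus truth.

    Subpopulation alt-allele frequencies follow the Balding–Nichols model:
    ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ancestral frequency ``p`` and
    ``F = fst_target`` (``F = 0`` collapses to ``p_k = p``). Varieties are
    heterozygous with probability ``residual_het`` and otherwise homozygous
    for an allele drawn from their subpopulation frequency.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # synthetic chromosome with one SNP every locus_spacing bp
    chrom = "chr1"
    genome_len = cfg.locus_spacing * (cfg.n_loci + 1)
    seq = rng.choice(list(_BASES), size=genome_len)
    positions = [(i + 1) * cfg.locus_spacing for i in range(cfg.n_loci)]

    # ancestral alt frequency: minor freq ~ U(maf_low, maf_high), the alt
    # allele is the minor or major one with equal probability
    minor = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_loci)
    flip = rng.random(cfg.n_loci) < 0.5
    ancestral = np.where(flip, minor, 1.0 - minor)

    F = cfg.fst_target
    if F == 0.0:
        subpop_freqs = np.tile(ancestral, (cfg.n_subpops, 1))
    elif F == 1.0:
        subpop_freqs = (
            rng.random((cfg.n_subpops, cfg.n_loci)) < ancestral
        ).astype(float)
    else:
        scale = (1.0 - F) / F
        subpop_freqs = rng.beta(
            ancestral * scale, (1.0 - ancestral) * scale,
            size=(cfg.n_subpops, cfg.n_loci),
        )

    labels = cfg.subpop_labels
    varieties: list[str] = []
    subgroup_map: dict[str, str] = {}
    pop_of: list[int] = []
    for k, size in enumerate(cfg.subpop_sizes):
        for i in range(size):
            name = f"{labels[k]}_v{i + 1:03d}"
            varieties.append(name)
            subgroup_map[name] = labels[k]
            pop_of.append(k)
    n_var = len(varieties)

    # genotype truth as alt-allele dosage of each copy: (n_var, n_loci, 2).
    # A variety is heterozygous with probability residual_het wherever the
    # subpopulation frequency allows it (h_eff = min(h, 2q, 2(1-q))); the
    # homozygous alt probability is corrected so the expected alt frequency
    # is exactly the subpopulation frequency q — heterozygosity never biases
    # the realized differentiation.
    q = subpop_freqs[np.array(pop_of), :]  # (n_var, n_loci) alt freq
    h_eff = np.minimum(cfg.residual_het, np.minimum(2 * q, 2 * (1 - q)))
    het_mask = rng.random((n_var, cfg.n_loci)) < h_eff
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hom_alt = np.where(h_eff < 1.0, (q - h_eff / 2) / (1.0 - h_eff), 0.5)
    hom_alt = rng.random((n_var, cfg.n_loci)) < p_hom_alt
    copies = np.zeros((n_var, cfg.n_loci, 2), dtype=np.int16)
    copies[hom_alt] = 1
    copies[het_mask, 0] = 0
    copies[het_mask, 1] = 1

    sites: list[VariantSite] = []
    call_matrix = np.empty((n_var, cfg.n_loci), dtype=object)
    seq_list = seq.copy()
    for j, pos in enumerate(positions):
        ref = str(seq_list[pos - 1])
        alt = rng.choice([b for b in _BASES if b != ref])
        states = copies[:, j, :]
        sites.append(
            VariantSite(
                chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=[alt],
                states=states.copy(),
            )
        )
        alleles = (ref, alt)
        for i in range(n_var):
            a, b = alleles[states[i, 0]], alleles[states[i, 1]]
            call_matrix[i, j] = (a, b) if a <= b else (b, a)

    genome = ReferenceGenome({chrom: "".join(seq_list)})
    table = VariantTable(sites=sites, samples=varieties, subgroup_map=subgroup_map)
    loci = [s.locus_id for s in sites]
    genotypes = GenotypeMatrix(varieties, loci, call_matrix)
    return TruthSet(
        config=replace(cfg),
        genome=genome,
        variant_table=table,
        genotypes=genotypes,
        subgroup_map=subgroup_map,
        ancestral_freqs=ancestral,
        subpop_freqs=subpop_freqs,
    )


def simulate_depths(truth: TruthSet, cfg: SimConfig | None = None) -> list[DepthRecord]:
    """Draw per variety x locus allele depths from the truth genotypes.

    Total depth is negative-binomial (mean ``mean_depth``, shape
    ``depth_dispersion``); reads split ``Binomial(n, 0.5)`` between the two
    alleles of a heterozygote and ``Binomial(n, 1 - error_rate)`` toward the
    true allele of a homozygote. With probability ``missing_rate`` the total
    depth is resampled uniformly below ``min_major_depth`` so the caller must
    emit a missing genotype.
    """
    if cfg is None:
        cfg = truth.config
    if cfg.n_loci != truth.config.n_loci or cfg.subpop_sizes != truth.config.subpop_sizes:
        raise DataError("cfg does not match the truth set's population layout")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    gm = truth.genotypes
    n_var, n_loci = gm.n_varieties, gm.n_loci

    k = cfg.depth_dispersion
    p_nb = k / (k + cfg.mean_depth)
    totals = rng.negative_binomial(k, p_nb, size=(n_var, n_loci))
    forced = rng.random((n_var, n_loci)) < cfg.missing_rate
    totals[forced] = rng.integers(0, cfg.min_major_depth, size=int(forced.sum()))

    site_alleles = [tuple(s.alleles) for s in truth.variant_table.sites]
    records: list[DepthRecord] = []
    for i, variety in enumerate(gm.varieties):
        for j, locus in enumerate(gm.loci):
            a, b = gm.calls[i, j]
            total = int(totals[i, j])
            ref, alt = site_alleles[j]
            if a != b:  # heterozygote: unbiased split
                n_a = int(rng.binomial(total, 0.5)) if total else 0
                depths = {a: n_a, b: total - n_a}
            else:  # homozygote: errors leak to the other site allele
                other = alt if a == ref else ref
                n_true = int(rng.binomial(total, 1.0 - cfg.error_rate)) if total else 0
                depths = {a: n_true, other: total - n_true}
            # present both site alleles even when one has zero depth
            for allele in (ref, alt):
                depths.setdefault(allele, 0)
            records.append(DepthRecord(variety=variety, locus=locus, allele_depths=depths))
    return records
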