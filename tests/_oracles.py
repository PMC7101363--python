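"""Independent brute-force re-implementations used as test oracles.

Everything here deliberately avoids the package's own code paths: uniqueness
is checked with a k-mer occurrence index, microsatellites with direct slice
comparison, statistics with plain Python tallies, and AMOVA sums of squares
with explicit double loops over the haplotype distance matrix.
"""

from __future__ import annotations

import numpy as np

from panelsnp.formats import ReferenceGenome, VariantSite, VariantTable

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Naive perfect-SNP filter
# ---------------------------------------------------------------------------

def kmer_occurrences(genome: ReferenceGenome, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def naive_perfect_filter(
    table: VariantTable,
    genome: ReferenceGenome,
    subgroup_map: dict[str, str] | None = None,
    flank_bp: int = 30,
    het_max: float = 0.2,
    miss_max: float = 0.2,
    maf_min: float = 0.4,
    hi: float = 0.95,
    lo: float = 0.05,
    ssr_min_copies: dict[int, int] | None = None,
) -> list[str]:
    """Re-check every criterion per site with plain loops; return the panel."""
    if ssr_min_copies is None:
        ssr_min_copies = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    k = 2 * flank_bp + 1
    index = kmer_occurrences(genome, k)
    panel: list[str] = []
    for site in table.sites:
        if not _naive_site_ok(site, table, genome, index, subgroup_map, flank_bp,
                              het_max, miss_max, maf_min, hi, lo, ssr_min_copies):
            continue
        panel.append(site.locus_id)
    return panel


def _naive_site_ok(site, table, genome, index, subgroup_map, flank_bp,
                   het_max, miss_max, maf_min, hi, lo, ssr_min_copies) -> bool:
    # (1) biallelic SNP
    if len(site.alt_alleles) != 1:
        return False
    if len(site.ref_allele) != 1 or len(site.alt_alleles[0]) != 1:
        return False
    # (2) unique flanking window (both strands)
    seq = genome.sequences[site.chrom]
    start, end = site.pos - 1 - flank_bp, site.pos + flank_bp
    if start < 0 or end > len(seq):
        return False
    window = seq[start:end]
    if "N" in window:
        return False
    if index.get(window, 0) + index.get(revcomp(window), 0) != 1:
        return False
    # (3) no other variant or SSR within the flanks
    for other in table.sites:
        if other is site or other.chrom != site.chrom:
            continue
        if abs(other.pos - site.pos) <= flank_bp:
            return False
    if naive_find_ssrs(window, ssr_min_copies):
        return False
    # (4)-(6) heterozygosity, missing rate, MAF / subgroup rescue
    states = site.states
    called = [i for i in range(states.shape[0]) if states[i, 0] != -1]
    if not called:
        return False
    n_het = sum(1 for i in called if states[i, 0] != states[i, 1])
    if n_het / len(called) > het_max:
        return False
    if (states.shape[0] - len(called)) / states.shape[0] >= miss_max:
        return False
    n_alleles = 1 + len(site.alt_alleles)
    counts = [0] * n_alleles
    for i in called:
        counts[states[i, 0]] += 1
        counts[states[i, 1]] += 1
    total = sum(counts)
    freqs = [c / total for c in counts]
    maf = sorted(freqs, reverse=True)[1]
    if maf > maf_min:
        return True
    # rescue: one subgroup >= hi for an allele, every other subgroup <= lo
    if subgroup_map is None:
        return False
    groups = sorted(set(subgroup_map.values()))
    gfreq: dict[str, list[float]] = {}
    for g in groups:
        members = [i for i in called if subgroup_map[table.samples[i]] == g]
        if not members:
            continue
        c = [0] * n_alleles
        for i in members:
            c[states[i, 0]] += 1
            c[states[i, 1]] += 1
        t = sum(c)
        gfreq[g] = [x / t for x in c]
    for a in range(n_alleles):
        for g in gfreq:
            if gfreq[g][a] >= hi and all(
                gfreq[h][a] <= lo for h in gfreq if h != g
            ):
                return True
    return False


def naive_find_ssrs(seq: str, min_copies: dict[int, int]) -> list[str]:
    """Microsatellite scan by direct slice comparison (no regex)."""
    hits: list[str] = []
    for m, copies in min_copies.items():
        for start in range(len(seq) - m * copies + 1):
            motif = seq[start : start + m]
            if any(
                len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d)
                for d in range(1, m)
            ):
                continue
            if seq[start : start + m * copies] == motif * copies:
                hits.append(motif)
    return hits


# ---------------------------------------------------------------------------
# Planted-violation variant tables
# ---------------------------------------------------------------------------

def build_planted_table(
    n_sites: int, seed: int, n_per_group: int = 10, n_groups: int = 4
) -> tuple[VariantTable, ReferenceGenome, dict[str, str]]:
    """Random variant table over a random genome with violations of every
    perfect-SNP criterion planted at known intervals."""
    rng = np.random.default_rng(seed)
    spacing = 200
    bases = np.array(list("ACGT"))
    genome_len = spacing * (n_sites + 4)
    seq = rng.choice(bases, size=genome_len)
    positions = [(i + 2) * spacing for i in range(n_sites)]

    # plant an (AT)7 microsatellite in the flank of every 29th site
    for idx in range(0, n_sites, 29):
        p = positions[idx]
        seq[p + 4 : p + 18] = list("AT" * 7)

    n_samples = n_per_group * n_groups
    samples = [f"s{i:03d}" for i in range(n_samples)]
    subgroup_map = {s: f"G{i // n_per_group}" for i, s in enumerate(samples)}

    sites: list[VariantSite] = []
    extra_sites: list[VariantSite] = []
    for idx, pos in enumerate(positions):
        ref = str(seq[pos - 1])
        others = [b for b in "ACGT" if b != ref]
        alts = [str(rng.choice(others))]
        if idx % 13 == 5:  # multi-allelic
            alts = list(rng.choice(others, size=2, replace=False))
        if idx % 17 == 7:  # indel
            alts = [ref + "T"]
        n_alleles = 1 + len(alts)

        if idx % 11 == 3:  # subgroup-differential pattern (low global MAF)
            g_fixed = int(rng.integers(n_groups))
            states = np.zeros((n_samples, 2), dtype=np.int16)
            block = slice(g_fixed * n_per_group, (g_fixed + 1) * n_per_group)
            states[block] = 1
        else:
            p = rng.uniform(0.15, 0.85)
            hom = (rng.random(n_samples) < p).astype(np.int16)
            states = np.stack([hom, hom], axis=1)
            het_rate = 0.6 if idx % 19 == 9 else 0.1  # planted high het
            het = rng.random(n_samples) < het_rate
            states[het, 0] = 0
            states[het, 1] = np.int16(min(1, n_alleles - 1))
        miss_rate = 0.3 if idx % 23 == 11 else 0.05  # planted high missing
        miss = rng.random(n_samples) < miss_rate
        states[miss] = -1
        sites.append(VariantSite("chr1", pos, ref, alts, states))

        if idx % 10 == 4:  # neighbouring SNP 1-30 bp away
            off = int(rng.integers(1, 31))
            npos = pos + off
            nref = str(seq[npos - 1])
            nalt = str(rng.choice([b for b in "ACGT" if b != nref]))
            nstates = np.zeros((n_samples, 2), dtype=np.int16)
            nstates[rng.random(n_samples) < 0.5] = 1
            extra_sites.append(VariantSite("chr1", npos, nref, [nalt], nstates))

    # duplicate the flanking window of every 31st site elsewhere in the genome
    full = "".join(seq)
    appended = ""
    for idx in range(0, n_sites, 31):
        p = positions[idx]
        appended += "GGGG" + full[p - 31 : p + 30]
    genome = ReferenceGenome({"chr1": full + appended})

    all_sites = sorted(sites + extra_sites, key=lambda s: s.pos)
    table = VariantTable(all_sites, samples, subgroup_map)
    return table, genome, subgroup_map
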