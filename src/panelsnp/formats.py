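"""Readers, writers and in-memory containers for every external format the
pipeline touches: FASTA reference, VCF variant calls, per-amplicon allele-depth
tables, genotype matrices, subgroup assignments and BED panel exports.

Conventions fixed here and nowhere else:

* positions are 1-based internally and in VCF; BED export is 0-based half-open;
* genotypes are *unordered* allele pairs (phase is never used downstream);
* one missing sentinel (``None`` for calls, ``-1`` for allele indices) at every
  layer — the "null" genotype of the kinship stage maps to the same sentinel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: allele-index sentinel for a missing allele copy
MISSING = -1

#: token used for a missing genotype in TSV round trips
MISSING_TOKEN = "./."

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PanelSnpError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PanelSnpError):
    """A file could not be parsed or violates a format invariant."""


class DataError(PanelSnpError):
    """Input data are structurally valid but semantically unusable."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ParseError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def base_at(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[chrom][pos - 1]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; duplicate headers are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"{path}: duplicate FASTA header {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

@dataclass
class VariantSite:
    """One variant record: position, alleles and per-accession states.

    ``states`` is an ``(n_samples, 2)`` int16 array of allele indices into
    ``[ref_allele] + alt_alleles``; :data:`MISSING` marks a missing copy.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: list[str]
    states: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"{self.locus_id}: position must be >= 1")
        self.states = np.asarray(self.states, dtype=np.int16)
        n_alleles = 1 + len(self.alt_alleles)
        valid = (self.states == MISSING) | (
            (self.states >= 0) & (self.states < n_alleles)
        )
        if not valid.all():
            raise DataError(f"{self.locus_id}: genotype references undeclared allele")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele, *self.alt_alleles]

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt_alleles) == 1
            and len(self.ref_allele) == 1
            and len(self.alt_alleles[0]) == 1
        )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != 1 or any(len(a) != 1 for a in self.alt_alleles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantSite):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.pos == other.pos
            and self.ref_allele == other.ref_allele
            and self.alt_alleles == other.alt_alleles
            and np.array_equal(self.states, other.states)
        )


@dataclass
class VariantTable:
    """Ordered variant sites over a fixed accession panel."""

    sites: list[VariantSite]
    samples: list[str]
    subgroup_map: dict[str, str] | None = None
    multiallelic_excluded: int = 0

    def __post_init__(self) -> None:
        for site in self.sites:
            if site.states.shape[0] != len(self.samples):
                raise DataError(
                    f"{site.locus_id}: {site.states.shape[0]} states for "
                    f"{len(self.samples)} samples"
                )

    def sites_by_chrom(self) -> dict[str, list[VariantSite]]:
        out: dict[str, list[VariantSite]] = {}
        for site in self.sites:
            out.setdefault(site.chrom, []).append(site)
        return out


def read_vcf(path: str | Path, require_biallelic: bool = False) -> VariantTable:
    """Read a VCF 4.x file with GT fields into a :class:`VariantTable`.

    Multi-allelic records are retained (biallelic enforcement is a panel
    filter, not a reader concern) unless ``require_biallelic`` is set, in
    which case they are dropped and counted in ``multiallelic_excluded``.
    Non-monotone positions trigger a warning and a stable sort.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    n_excluded = 0
    for variant in vcf:
        if variant.FORMAT is None or "GT" not in variant.FORMAT:
            raise ParseError(
                f"{path}: record {variant.CHROM}:{variant.POS} has no GT field"
            )
        alts = list(variant.ALT)
        if require_biallelic and len(alts) != 1:
            n_excluded += 1
            continue
        states = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                states[i] = (a, b)
        sites.append(
            VariantSite(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref_allele=variant.REF,
                alt_alleles=alts,
                states=states,
            )
        )
    # enforce per-chromosome monotone positions (stable sort on violation)
    by_chrom: dict[str, int] = {}
    monotone = True
    for site in sites:
        last = by_chrom.get(site.chrom)
        if last is not None and site.pos <= last:
            monotone = False
        by_chrom[site.chrom] = max(site.pos, last or 0)
    if not monotone:
        logger.warning("%s: positions not strictly increasing; applying stable sort", path)
        sites.sort(key=lambda s: (s.chrom, s.pos))
    return VariantTable(
        sites=sites, samples=samples, multiallelic_excluded=n_excluded
    )


def write_vcf(table: VariantTable, path: str | Path, genome: ReferenceGenome | None = None) -> None:
    """Write a minimal well-formed VCF 4.2 file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelsnp\n")
        if genome is not None:
            for name, length in genome.lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for site in table.sites:
            gts = []
            for a, b in site.states:
                if a == MISSING or b == MISSING:
                    gts.append("./.")
                else:
                    gts.append(f"{a}/{b}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.locus_id}\t{site.ref_allele}\t"
                f"{','.join(site.alt_alleles)}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Allele-depth records
# ---------------------------------------------------------------------------

@dataclass
class DepthRecord:
    """Read counts per allele for one variety at one locus."""

    variety: str
    locus: str
    allele_depths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.allele_depths:
            raise DataError(
                f"({self.variety}, {self.locus}): at least one allele required"
            )
        for allele, depth in self.allele_depths.items():
            if depth < 0:
                raise DataError(
                    f"({self.variety}, {self.locus}): negative depth {depth} for {allele}"
                )

    @property
    def total_depth(self) -> int:
        return sum(self.allele_depths.values())


def read_depth_table(path: str | Path) -> list[DepthRecord]:
    """Read a tab-delimited depth table (variety, locus, allele, depth).

    Alleles absent for a (variety, locus) that appear for the same locus in
    other varieties are filled in with depth 0, so every record at a locus
    declares the same allele universe.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variety": str, "locus": str, "allele": str})
    required = {"variety", "locus", "allele", "depth"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise DataError(
            f"{path}: negative depth {bad['depth']} at ({bad['variety']}, {bad['locus']})"
        )
    dup = df.duplicated(subset=["variety", "locus", "allele"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise DataError(
            f"{path}: duplicate (variety, locus, allele) row "
            f"({bad['variety']}, {bad['locus']}, {bad['allele']})"
        )
    locus_alleles: dict[str, set[str]] = {}
    for locus, sub in df.groupby("locus", sort=False):
        locus_alleles[locus] = set(sub["allele"])
    records: list[DepthRecord] = []
    for (variety, locus), sub in df.groupby(["variety", "locus"], sort=False):
        depths = dict.fromkeys(sorted(locus_alleles[locus]), 0)
        depths.update(dict(zip(sub["allele"], sub["depth"].astype(int))))
        records.append(DepthRecord(variety=variety, locus=locus, allele_depths=depths))
    return records


def write_depth_table(records: list[DepthRecord], path: str | Path) -> None:
    rows = [
        (r.variety, r.locus, allele, depth)
        for r in records
        for allele, depth in sorted(r.allele_depths.items())
    ]
    pd.DataFrame(rows, columns=["variety", "locus", "allele", "depth"]).to_csv(
        path, sep="\t", index=False
    )


def read_depths_from_vcf(path: str | Path) -> list[DepthRecord]:
    """Extract per-sample allele depths from a VCF's AD field."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[DepthRecord] = []
    for variant in vcf:
        ad = variant.format("AD")
        if ad is None:
            raise ParseError(f"{path}: record {variant.CHROM}:{variant.POS} has no AD field")
        alleles = [variant.REF, *variant.ALT]
        locus = f"{variant.CHROM}:{variant.POS}"
        for i, sample in enumerate(samples):
            depths = {
                allele: max(int(d), 0) for allele, d in zip(alleles, ad[i])
            }
            records.append(DepthRecord(variety=sample, locus=locus, allele_depths=depths))
    return records


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

def canonical_call(a: str, b: str) -> tuple[str, str]:
    """Unordered allele pair, alleles sorted lexically."""
    return (a, b) if a <= b else (b, a)


_CALL_RE = re.compile(r"^([A-Z*]+)/([A-Z*]+)$")


@dataclass
class GenotypeMatrix:
    """Varieties x loci table of unordered allele pairs (``None`` = missing).

    This is the fingerprint object every downstream stage consumes.
    """

    varieties: list[str]
    loci: list[str]
    calls: np.ndarray  # object array, shape (n_varieties, n_loci)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.varieties), len(self.loci)):
            raise DataError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.varieties)}, {len(self.loci)})"
            )

    @property
    def n_varieties(self) -> int:
        return len(self.varieties)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def call(self, variety: str, locus: str) -> tuple[str, str] | None:
        return self.calls[self.varieties.index(variety), self.loci.index(locus)]

    def locus_column(self, locus: str) -> np.ndarray:
        return self.calls[:, self.loci.index(locus)]

    def subset_varieties(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.varieties.index(v) for v in keep]
        return GenotypeMatrix(list(keep), list(self.loci), self.calls[idx, :])

    def subset_loci(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.loci.index(l) for l in keep]
        return GenotypeMatrix(list(self.varieties), list(keep), self.calls[:, idx])

    def encode(self) -> np.ndarray:
        """Integer coding of calls per locus: -1 missing, else an index into the
        sorted set of distinct calls observed at that locus. Equality of codes
        within a column is equality of genotypes."""
        coded = np.full(self.calls.shape, -1, dtype=np.int32)
        for j in range(self.n_loci):
            col = self.calls[:, j]
            seen = sorted({c for c in col if c is not None})
            mapping = {c: k for k, c in enumerate(seen)}
            for i, c in enumerate(col):
                if c is not None:
                    coded[i, j] = mapping[c]
        return coded

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.varieties == other.varieties
            and self.loci == other.loci
            and all(
                self.calls[i, j] == other.calls[i, j]
                for i in range(self.n_varieties)
                for j in range(self.n_loci)
            )
        )


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    """TSV: header row = locus ids, first column = variety id; calls encoded
    "A/G" with alleles sorted lexically, missing "./."."""
    with open(path, "w") as fh:
        fh.write("variety\t" + "\t".join(gm.loci) + "\n")
        for i, variety in enumerate(gm.varieties):
            tokens = []
            for j in range(gm.n_loci):
                call = gm.calls[i, j]
                if call is None:
                    tokens.append(MISSING_TOKEN)
                else:
                    a, b = canonical_call(*call)
                    tokens.append(f"{a}/{b}")
            fh.write(variety + "\t" + "\t".join(tokens) + "\n")


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header must have a variety column and >=1 locus")
        loci = header[1:]
        varieties: list[str] = []
        rows: list[list[tuple[str, str] | None]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: {len(fields)} fields, expected {len(header)}"
                )
            varieties.append(fields[0])
            row: list[tuple[str, str] | None] = []
            for token in fields[1:]:
                if token == MISSING_TOKEN:
                    row.append(None)
                    continue
                m = _CALL_RE.match(token)
                if m is None:
                    raise ParseError(
                        f"{path}: line {lineno}: unknown genotype token {token!r}"
                    )
                row.append(canonical_call(m.group(1), m.group(2)))
            rows.append(row)
    calls = np.empty((len(varieties), len(loci)), dtype=object)
    for i, row in enumerate(rows):
        for j, call in enumerate(row):
            calls[i, j] = call
    return GenotypeMatrix(varieties, loci, calls)


# ---------------------------------------------------------------------------
# Subgroup assignments and BED export
# ---------------------------------------------------------------------------

def read_subgroups(path: str | Path) -> dict[str, str]:
    """TSV with columns (variety, subgroup) -> assignment map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variety", "subgroup"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns variety, subgroup")
    if df["variety"].duplicated().any():
        raise DataError(f"{path}: duplicate variety in subgroup table")
    return dict(zip(df["variety"], df["subgroup"]))


def write_subgroups(subgroup_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(subgroup_map.items()), columns=["variety", "subgroup"]
    ).to_csv(path, sep="\t", index=False)


def to_bed_interval(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def from_bed_interval(start: int, end: int) -> int:
    """0-based half-open single-base interval -> 1-based position."""
    if end != start + 1:
        raise DataError(f"expected single-base interval, got [{start}, {end})")
    return start + 1


def write_panel_bed(sites: list[VariantSite], path: str | Path) -> None:
    """Export panel loci as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for site in sites:
            start, end = to_bed_interval(site.pos)
            fh.write(f"{site.chrom}\t{start}\t{end}\t{site.locus_id}\n")
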