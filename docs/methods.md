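# Methods

This note records the statistical models implemented in `panelsnp`, the
default parameter choices and their rationale, what the simulator does and
does not emulate, and numerical/implementation decisions. It makes no
empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## 1. Perfect-SNP discovery (`panelsnp.panel`)

A candidate site passes when all of the following hold:

1. **Biallelic SNP.** Exactly one alternate allele; both alleles single
   bases. Multi-allelic sites and indels are rejected (indels additionally
   disqualify any site whose flank they fall into, see 3).
2. **Unique flanking window.** The `2·flank_bp + 1` = 61-mer centred on the
   site occurs exactly once in the genome counting both strands (forward
   occurrences of the window plus forward occurrences of its reverse
   complement). Windows reaching a contig edge or containing `N` fail.
3. **Clean neighborhood.** No other variant of the input table within
   ±`flank_bp` (30 bp), and no microsatellite inside the window. The SSR
   convention is minimum copy numbers {mono: 10, di: 6, tri–hexa: 5}, with
   motifs that are repetitions of a shorter unit excluded (an `(AT)6` run is
   not also reported as `(ATAT)3`).
4. **Heterozygosity** ≤ 0.2 over called samples.
5. **Missing rate** < 0.2 (strict).
6. **MAF** > 0.4 (strict), **or** subgroup-differential rescue: some allele
   has frequency ≥ 0.95 in exactly one subgroup and ≤ 0.05 in *all* others.
   The rescue exists because markers fixed in a small subpopulation are
   exactly the ones that identify it, yet have low global MAF.

The high MAF floor targets maximally informative markers (PIC approaches
its biallelic maximum 0.375 as MAF → 0.5). Every site receives an audit
record listing pass/fail per criterion, so filter decisions are fully
inspectable (`discover` writes it as `audit.tsv`).

## 2. Depth-based genotype calling (`panelsnp.genotyping`)

Per variety × locus, alleles are ranked by read depth; the top two are
major/minor and the ratio is `r = major/(major + minor)`:

- major depth < 20 → missing (`low_depth`);
- `r < 0.7` → heterozygous (a depth tie is maximal het evidence; the
  lexically smaller allele is reported as major);
- `r ≥ 0.8` → homozygous major;
- `0.7 ≤ r < 0.8` → missing (`ambiguous_ratio`).

The 0.7–0.8 dead band is deliberate: at real amplicon depths (hundreds to
thousands of reads) a true heterozygote's binomial ratio almost never
reaches 0.7 and a true homozygote's almost never drops to 0.8, so records in
the band indicate contamination or paralogy and are safer dropped. The
*confident-call rate* — the fraction of depth-passing records in the het
band plus the hom band — is therefore a lower bound on call accuracy under
the band model. Reads of a third allele at a biallelic locus never enter the
ratio; they are reported as contamination depth.

QC flags loci with PIC < 0.1 (nearly uninformative) or missing rate > 0.1.

## 3. Diversity statistics (`panelsnp.diversity`)

With allele frequencies `P_i` at a locus (two copies per variety,
non-missing calls only):

- expected heterozygosity / Simpson diversity `He = D = 1 − ΣP_i²`;
- `PIC = 1 − ΣP_i² − Σ_{i<j} 2P_i²P_j²`, computed via the identity
  `Σ_{i<j} p_i²p_j² = ((Σp_i²)² − Σp_i⁴)/2`;
- observed heterozygosity `Ho`;
- inbreeding coefficient `F = 1 − Ho/He`, reported missing when `He = 0`.

`He` is Nei's gene diversity without small-sample correction so that `He`
and `D` coincide per locus; a bias-corrected variant (`× 2n/(2n−1)`) is
available by flag. For a biallelic locus `PIC ≤ 0.375` and `D ≤ 0.5`, both
attained at `P = 0.5`; `PIC ≤ D` always. Subpopulation summaries average
per-locus values, with `F` averaged over loci where it is defined.

## 4. AMOVA (`panelsnp.popdiff`)

Three-level decomposition for diploids — among populations (df `K−1`),
among individuals within populations (df `N−K`), within individuals
(df `N`), total (df `2N−1`) — computed from squared pairwise distances
between the `2N` allele copies. The distance between two copies is the
number of mismatching loci among pairwise-complete loci, rescaled to the
full locus count `L` (`L·mismatches/used`); copies sharing no called locus
get distance 0. Group sums of squares use
`SS(G) = Σ_{i<j∈G} d²_ij / |G|`. Variance components come from the
method-of-moments equations

```
σ²_c = MS_within-individuals
σ²_b = (MS_among-individuals − MS_within-individuals) / 2
σ²_a = (MS_among-populations − MS_among-individuals) / n_c
```

with `n_c = (n_tot − Σn_k²/n_tot)/(K−1)` in haplotype counts. Negative
components are reported as computed, never truncated; percentages of
variation are `100·σ²/Σσ²`, and Φ_ST = σ²_a/Σσ². Singleton subpopulations
are rejected (the within-population level would have no information).

## 5. Weir–Cockerham θ

F_ST is the Weir–Cockerham (1984) estimator: per locus and allele, the
components `a` (among populations), `b` (among individuals within
populations), `c` (within individuals) are computed from sample sizes,
allele frequencies and heterozygote frequencies per population, and
combined across loci and alleles as `θ = Σa / Σ(a+b+c)`. Monomorphic loci
contribute nothing; loci with fewer than two populations carrying data, or
with ≤ 1 sample per population on average, are skipped. θ is reported
overall and for every subpopulation pair (NaN when undefined).

## 6. Core SNP sets and core varieties (`panelsnp.coreset`)

Two varieties are *distinguished* at a locus when both calls are
non-missing and their unordered allele pairs differ; missing never
distinguishes a pair. Core-SNP selection is a set cover over the C(n,2)
variety pairs:

- **greedy**: repeatedly add the locus resolving the most unresolved pairs,
  ties broken by higher PIC then input (genome) order — standard ln(n)
  approximation guarantee;
- **exhaustive**: size-increasing subset search with a best-case pruning
  bound, provably minimal but bounded at 25 loci / 50 varieties (the
  problem is NP-hard).

Both report the saturation curve (pairs distinguished after k markers) and,
as an alternative denominator, the fraction of varieties with a unique
profile over the selected loci.

The kinship matrix counts differential genotypes per variety pair. Core
(backbone) varieties are, per subpopulation, the `ceil(0.1·size)` varieties
with the lowest mean differential count against the other members (ties by
variety id). Genetic distance for matrix correlation is the simple
allele-sharing distance `1 − (shared copies / 2)` averaged over
pairwise-complete loci; matrix correlation is Pearson r over the strict
lower triangle with missing pairs dropped.

## 7. Simulator (`panelsnp.simulate`)

**Population model.** One synthetic chromosome with loci every
`locus_spacing` (400 bp). Ancestral minor-allele frequencies are drawn
uniform on (`maf_low`, `maf_high`) = (0.3, 0.5) and randomly assigned to
ref/alt. Subpopulation frequencies follow the Balding–Nichols model:
`p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = fst_target`, so the
expected multi-locus Weir–Cockerham θ across subpopulations is close to the
target (verified by the recovery tests). `F = 0` copies the ancestral
frequencies; `F = 1` fixes alleles.

**Genotypes.** Varieties are mostly inbred lines: each genotype is
heterozygous with probability `h_eff = min(residual_het, 2q, 2(1−q))` and
otherwise homozygous with `P(hom alt) = (q − h_eff/2)/(1 − h_eff)`, which
preserves the allele frequency exactly (`E[alt freq] = q`) while capping
heterozygosity where the frequency makes the nominal rate unattainable.

**Depths.** Per record, total depth is negative-binomial with mean
`mean_depth` (2000) and dispersion 1.2, which places roughly 90 % of
records in the 100–5000× band typical of deep amplicon data. Heterozygotes
split reads Binomial(total, 0.5); homozygotes draw
Binomial(total, 1 − error_rate) for the true allele with the remainder
assigned to the other site allele. Forced missingness resamples the total
below the 20-read floor for a `missing_rate` fraction of records.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| `n_subpops` / `subpop_sizes` | 4 / (78, 105, 58, 20) | a realistic unbalanced multi-subpopulation panel (261 varieties) |
| `n_loci` | 163 | a typical targeted-panel size |
| `fst_target` | 0.43 | strong structure, as seen in crop variety panels |
| `maf_low`–`maf_high` | 0.3–0.5 | candidate markers pre-enriched toward the MAF filter region |
| `residual_het` | 0.17 | realized Ho of mostly-inbred varieties |
| `mean_depth` / `depth_dispersion` | 2000× / 1.2 | deep amplicon sequencing with heavy-tailed per-amplicon variation |
| `error_rate` | 0.002 | short-read per-base error scale |
| `missing_rate` | 0.05 | failed amplifications |
| `min_major_depth` | 20 | matches the caller's depth floor |

**What it does not emulate:** linkage between loci (loci are independent),
selection, shared pedigree within subpopulations beyond the Balding–Nichols
drift, mapping/alignment artifacts, index hopping, allele-specific
amplification bias, or genotyping of multi-allelic sites.

## 8. Numerical and implementation choices

- All randomness flows from `numpy.random.default_rng` seeded by the single
  config seed; the depth stage derives an independent child stream via
  `SeedSequence([seed, 7])`. Same seed → byte-identical outputs.
- Flank-uniqueness uses an overlapping `str.find` scan of the window and
  its reverse complement rather than a genome-wide k-mer index: memory-free
  and fast at these genome sizes.
- AMOVA's 2N×2N distance matrix is built in 256-row chunks to bound the
  memory of the broadcast mismatch computation.
- Genotype calls are stored canonically (alleles sorted within the pair) so
  equality comparisons are order-free.
- Degrees of freedom follow the standard accounting `K−1 / N−K / N` with
  total `2N−1`.
- Problem sizes in the examples and tests (tens of varieties, hundreds of
  loci) are this package's own choice of desk-scale configurations; the
  algorithms have no hard limits besides the exhaustive-search bound.

## 9. Limitations

- The perfect-SNP filter checks variant neighborhoods only against the
  variants present in the input table; variation absent from the input
  cannot be excluded.
- The Weir–Cockerham estimator is moment-based; with few loci or very small
  subpopulations θ̂ is noisy and can be negative.
- Greedy core sets are near-minimal, not minimal; the exhaustive mode is
  exponential and bounded accordingly.
- `F = 1 − Ho/He` conflates inbreeding with any other source of
  heterozygote deficit (null alleles, Wahlund effect).
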