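# panelsnp

Design and evaluation of minimal SNP panels for DNA fingerprinting of crop
varieties, built around targeted-amplicon (deep multiplex-PCR) genotyping.

Given population variant data, `panelsnp`:

1. **discovers "perfect" SNPs** — biallelic sites whose 30-bp flanks map
   uniquely to the reference on both strands, carry no other variant or
   microsatellite, and pass heterozygosity / missing-rate / minor-allele
   frequency filters (with a subgroup-differential rescue for markers fixed
   in exactly one subpopulation);
2. **calls genotypes from allele read depths** using the major-allele ratio
   `r = major / (major + minor)`: `r < 0.7` → heterozygous, `r ≥ 0.8` →
   homozygous, the 0.7–0.8 band and records below 20 major reads → missing;
3. **computes diversity statistics** per locus and subpopulation —
   `He = D = 1 − ΣPᵢ²`, `PIC = 1 − ΣPᵢ² − Σᵢ<ⱼ 2Pᵢ²Pⱼ²`, observed
   heterozygosity `Ho`, inbreeding coefficient `F = 1 − Ho/He`;
4. **partitions variance** with a three-level AMOVA (among populations /
   among individuals within populations / within individuals) and estimates
   F_ST as the multi-locus Weir–Cockerham θ, overall and pairwise;
5. **selects a minimal core SNP set** — the smallest marker subset (greedy
   set cover, or provably minimal exhaustive search on small inputs) that
   distinguishes as many variety pairs as the full panel, with its
   saturation curve;
6. **identifies core (backbone) varieties** — the lowest decile of mean
   pairwise differential-genotype count within each subpopulation;
7. ships a **simulator** (Balding–Nichols population structure plus a
   negative-binomial amplicon depth model) so the whole pipeline runs and is
   testable without any external data.

## Worked example

A fully synthetic end-to-end run (4 subpopulations × 20 varieties,
120 candidate loci, divergence 0.43, 2000× mean depth):

```sh
cat > demo.yaml <<'EOF'
sim:
  n_subpops: 4
  subpop_sizes: [20, 20, 20, 20]
  n_loci: 120
  fst_target: 0.43
  mean_depth: 2000
  seed: 11
EOF
panelsnp pipeline --config demo.yaml --outdir demo_run
```

prints

```
pipeline complete: panel 39, core set 8 loci (100.0% of pairs), 8 core varieties
```

39 of the 120 candidate sites survive the perfect-SNP filters, and 8 of
those 39 markers already distinguish all C(80,2) = 3,160 variety pairs. The
saturation curve (`demo_run/saturation_curve.tsv`) shows the usual steep
set-cover profile — the first marker alone resolves 64 % of the pairs:

| k | distinguished pairs | fraction |
|---|--------------------:|---------:|
| 1 | 2029 | 0.642 |
| 2 | 2736 | 0.866 |
| 3 | 3001 | 0.950 |
| 4 | 3102 | 0.982 |
| 8 | 3160 | 1.000 |

The AMOVA table (`demo_run/amova.tsv`) recovers the simulated structure —
about 46 % of molecular variance lies among populations:

| source | df | SS | MS | variance | % of variation |
|---|---:|---:|---:|---:|---:|
| Among populations | 3 | 638.57 | 212.86 | 5.10 | 46.43 |
| Among individuals within populations | 76 | 688.00 | 9.05 | 3.17 | 28.92 |
| Within individuals | 80 | 216.40 | 2.70 | 2.70 | 24.65 |
| Total | 159 | 1542.96 | 9.70 | 10.97 | 100.00 |

Pairwise Weir–Cockerham θ between the four subpopulations ranges from 0.39
(Pop1–Pop2) to 0.53 (Pop3–Pop4), and the per-subpopulation inbreeding
coefficients sit at 0.32–0.50 (`demo_run/subpop_stats.tsv`), reflecting the
mostly-inbred varieties the simulator produces.

Every stage is also available as its own subcommand (`simulate`,
`discover`, `genotype`, `diversity`, `amova`, `fst`, `coreset`, `kinship`)
so runs can be resumed from intermediates; each output directory carries a
`manifest.json` with the package version, seed, thresholds, and input
checksums. Exit codes: 0 ok, 2 usage error, 3 data error.

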