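"""Perfect-SNP criteria: frequencies, uniqueness, clean flanks, rescue rule."""

import re

import numpy as np
import pytest

from _oracles import build_planted_table, kmer_occurrences, naive_perfect_filter, revcomp
from panelsnp.formats import DataError, ReferenceGenome, VariantSite, VariantTable
from panelsnp.panel import (
    FilterThresholds,
    find_ssrs,
    flanking_unique,
    neighborhood_clean,
    select_perfect_snps,
    site_frequencies,
    subsample_evenly,
)


def make_site(pos, genos, ref="A", alts=("G",), chrom="chr1"):
    """genos: list of (a, b) allele-index pairs or None for missing."""
    states = np.array(
        [(-1, -1) if g is None else g for g in genos], dtype=np.int16
    )
    return VariantSite(chrom, pos, ref, list(alts), states)


class TestSiteFrequencies:
    def test_hand_count(self):
        site = make_site(100, [(0, 0)] * 4 + [(1, 1)] * 4 + [(0, 1)] * 2)
        sf = site_frequencies(site)
        assert sf.freqs["A"] == pytest.approx(0.5)
        assert sf.het_rate == pytest.approx(0.2)
        assert sf.missing_rate == 0.0
        assert sf.maf == pytest.approx(0.5)

    def test_monomorphic(self):
        sf = site_frequencies(make_site(100, [(0, 0)] * 10))
        assert sf.freqs["A"] == 1.0 and sf.maf == 0.0

    def test_missing_rate(self):
        sf = site_frequencies(make_site(100, [(0, 0)] * 8 + [None] * 2))
        assert sf.missing_rate == pytest.approx(0.2)

    def test_all_missing_rejected(self):
        with pytest.raises(DataError, match="missing"):
            site_frequencies(make_site(100, [None] * 4))

    def test_subgroup_frequencies(self):
        site = make_site(100, [(1, 1)] * 5 + [(0, 0)] * 5)
        samples = [f"s{i}" for i in range(10)]
        sub = {s: ("g1" if i < 5 else "g2") for i, s in enumerate(samples)}
        sf = site_frequencies(site, sub, samples)
        assert sf.subgroup_freqs["g1"]["G"] == 1.0
        assert sf.subgroup_freqs["g2"]["G"] == 0.0


class TestFlankingUnique:
    def _genome(self, seed=0, n=5000):
        rng = np.random.default_rng(seed)
        return ReferenceGenome({"chr1": "".join(rng.choice(list("ACGT"), n))})

    def test_unique_window_passes_and_matches_bruteforce(self):
        genome = self._genome()
        ok, count, reason = flanking_unique(
            make_site(2500, [(0, 0)]), genome, flank_bp=30
        )
        seq = genome.sequences["chr1"]
        window = seq[2469:2530]
        index = kmer_occurrences(genome, 61)
        expected = index.get(window, 0) + index.get(revcomp(window), 0)
        assert count == expected
        assert ok == (expected == 1)

    def test_duplicated_block_fails(self):
        rng = np.random.default_rng(1)
        block = "".join(rng.choice(list("ACGT"), 5000))
        genome = ReferenceGenome({"chr1": block + block})
        ok, count, reason = flanking_unique(make_site(2500, [(0, 0)]), genome)
        assert not ok and count >= 2 and reason == "multiple hits"

    def test_edge_fails(self):
        genome = self._genome()
        ok, count, reason = flanking_unique(make_site(15, [(0, 0)]), genome)
        assert not ok and reason == "edge"

    def test_ambiguous_base_fails(self):
        seq = "ACGT" * 20 + "N" + "ACGT" * 20
        genome = ReferenceGenome({"chr1": seq})
        ok, _, reason = flanking_unique(make_site(80, [(0, 0)]), genome)
        assert not ok and reason == "ambiguous base"


class TestSsrScan:
    def test_dinucleotide_repeat_found(self):
        seq = "GGCC" + "AT" * 7 + "GGCC"
        assert "(AT)7" in find_ssrs(seq, {2: 6})

    def test_below_copy_threshold_clean(self):
        seq = "GGCC" + "AT" * 5 + "GGCC"
        assert find_ssrs(seq, {2: 6}) == []

    def test_mononucleotide_not_reported_as_dinucleotide(self):
        seq = "GC" + "A" * 14 + "GC"
        hits = find_ssrs(seq, {1: 10, 2: 6})
        assert any(h.startswith("(A)") for h in hits)
        assert not any(h.startswith("(AA)") for h in hits)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_slice_comparison_oracle(self, seed):
        from _oracles import naive_find_ssrs

        rng = np.random.default_rng(seed)
        rules = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
        seq = "".join(rng.choice(list("ACGT"), 300))
        if seed % 2:
            seq = seq[:100] + "TAC" * 6 + seq[100:]
        got = {re.match(r"\((\w+)\)", h).group(1) for h in find_ssrs(seq, rules)}
        assert got == set(naive_find_ssrs(seq, rules))


class TestNeighborhood:
    def _setup(self, other_offset):
        rng = np.random.default_rng(3)
        genome = ReferenceGenome({"chr1": "".join(rng.choice(list("ACGT"), 2000))})
        site = make_site(1000, [(0, 1)] * 4)
        other = make_site(1000 + other_offset, [(0, 0)] * 4)
        table = VariantTable([site, other] if other_offset > 0 else [other, site],
                             [f"s{i}" for i in range(4)])
        return site, table, genome

    def test_snp_at_12bp_fails(self):
        site, table, genome = self._setup(12)
        ok, reasons = neighborhood_clean(site, table, genome, FilterThresholds())
        assert not ok and "SNP@+12" in reasons

    def test_variant_at_31bp_passes(self):
        site, table, genome = self._setup(31)
        ok, reasons = neighborhood_clean(site, table, genome, FilterThresholds())
        assert ok and reasons == []

    def test_ssr_in_flank_fails(self):
        seq = "ACGT" * 250
        seq = seq[:1010] + "AT" * 7 + seq[1024:]
        genome = ReferenceGenome({"chr1": seq})
        site = make_site(1000, [(0, 1)] * 4)
        table = VariantTable([site], [f"s{i}" for i in range(4)])
        ok, reasons = neighborhood_clean(site, table, genome, FilterThresholds())
        assert not ok and any(r.startswith("SSR(") for r in reasons)


class TestSelectPerfectSnps:
    def _clean_setup(self, genos_builder, n_samples=40, subgroups=False):
        """One site per 200 bp over a random genome; genotypes injected."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        genome = ReferenceGenome({"chr1": seq})
        site = VariantSite(
            "chr1", 1000, seq[999], [next(b for b in "ACGT" if b != seq[999])],
            np.array(genos_builder(n_samples), dtype=np.int16),
        )
        samples = [f"s{i:02d}" for i in range(n_samples)]
        sub = None
        if subgroups:
            sub = {s: f"G{i // (n_samples // 4)}" for i, s in enumerate(samples)}
        return VariantTable([site], samples, sub), genome, sub

    def test_maf_just_below_threshold_rejected(self):
        # 39 of 100 allele copies alt -> MAF 0.39, everything else clean
        def genos(n):
            g = [(1, 1)] * 19 + [(0, 1)] + [(0, 0)] * 30
            return g

        table, genome, _ = self._clean_setup(genos, n_samples=50)
        res = select_perfect_snps(table, genome)
        assert res.panel == []
        assert res.audits[0].maf == pytest.approx(0.39)
        assert "maf" in res.audits[0].failed_criteria

    def test_subgroup_differential_rescue(self):
        # fixed alt in group 0 (freq 1.0 >= 0.95), absent elsewhere: global
        # MAF 0.25 fails, rescue retains
        def genos(n):
            return [(1, 1)] * 10 + [(0, 0)] * 30

        table, genome, sub = self._clean_setup(genos, subgroups=True)
        res = select_perfect_snps(table, genome)
        audit = res.audits[0]
        assert not audit.maf_pass
        assert audit.subgroup_differential
        assert audit.final and len(res.panel) == 1
        # without subgroup information the same site is rejected
        table.subgroup_map = None
        res2 = select_perfect_snps(table, genome, subgroup_map=None)
        assert res2.panel == []

    def test_planted_violations_match_naive_filter(self):
        table, genome, sub = build_planted_table(n_sites=120, seed=5)
        res = select_perfect_snps(table, genome, subgroup_map=sub)
        got = {s.locus_id for s in res.panel}
        expected = set(naive_perfect_filter(table, genome, sub))
        assert got == expected
        assert 0 < len(got) < len(table.sites)

    def test_rejected_sites_name_a_criterion(self):
        table, genome, sub = build_planted_table(n_sites=60, seed=9)
        res = select_perfect_snps(table, genome, subgroup_map=sub)
        for a in res.audits:
            if not a.final:
                assert a.failed_criteria

    def test_order_independence(self):
        table, genome, sub = build_planted_table(n_sites=60, seed=11)
        res1 = select_perfect_snps(table, genome, subgroup_map=sub)
        perm = np.random.default_rng(0).permutation(len(table.sites))
        shuffled = VariantTable(
            [table.sites[i] for i in perm], table.samples, table.subgroup_map
        )
        res2 = select_perfect_snps(shuffled, genome, subgroup_map=sub)
        assert {s.locus_id for s in res1.panel} == {s.locus_id for s in res2.panel}

    def test_threshold_monotonicity(self):
        table, genome, sub = build_planted_table(n_sites=80, seed=13)
        loose = select_perfect_snps(
            table, genome, FilterThresholds(maf_min=0.2), subgroup_map=sub
        )
        strict = select_perfect_snps(
            table, genome, FilterThresholds(maf_min=0.45), subgroup_map=sub
        )
        assert {s.locus_id for s in strict.panel} <= {s.locus_id for s in loose.panel}
        wide = select_perfect_snps(
            table, genome, FilterThresholds(flank_bp=40), subgroup_map=sub
        )
        base = select_perfect_snps(table, genome, subgroup_map=sub)
        assert {s.locus_id for s in wide.panel} <= {s.locus_id for s in base.panel}

    def test_empty_table_rejected(self):
        genome = ReferenceGenome({"chr1": "ACGT" * 100})
        with pytest.raises(DataError):
            select_perfect_snps(VariantTable([], ["s1"]), genome)

    def test_even_subsampling(self):
        table, genome, sub = build_planted_table(n_sites=80, seed=13)
        res = select_perfect_snps(table, genome, subgroup_map=sub)
        thinned = subsample_evenly(res.panel, 5)
        assert len(thinned) == 5
        assert set(s.locus_id for s in thinned) <= {s.locus_id for s in res.panel}
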