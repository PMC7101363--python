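"""Kinship counts, minimal core-SNP selection, and backbone varieties."""

import numpy as np
import pytest

from conftest import make_matrix, random_matrix
from panelsnp.coreset import (
    CoreSet,
    allele_sharing_distance,
    differential_matrix,
    genetic_similarity,
    matrix_correlation,
    select_core_snps,
    select_core_varieties,
)
from panelsnp.formats import DataError


class TestDifferentialMatrix:
    def test_trivial_counts(self):
        gm = make_matrix(
            {"v1": ["A/A", "C/C"], "v2": ["A/G", "C/C"], "v3": ["A/A", "C/C"]},
            ["L1", "L2"],
        )
        km = differential_matrix(gm)
        assert km.counts[0, 1] == 1  # differ at L1 only
        assert km.counts[0, 2] == 0  # identical
        assert km.counts[1, 2] == 1
        assert (km.counts == km.counts.T).all()
        assert (np.diag(km.counts) == 0).all()

    def test_missing_never_distinguishes(self):
        gm = make_matrix(
            {"v1": ["A/A", "C/C"], "v2": [None, "C/T"]}, ["L1", "L2"]
        )
        km = differential_matrix(gm)
        assert km.counts[0, 1] == 1  # only L2 counts; L1 is null
        assert km.comparable[0, 1] == 1

    def test_matches_bruteforce_recount(self):
        gm = random_matrix(30, 50, seed=13)
        km = differential_matrix(gm)
        for i in range(30):
            for j in range(i + 1, 30):
                expected = sum(
                    1
                    for l in range(50)
                    if gm.calls[i, l] is not None
                    and gm.calls[j, l] is not None
                    and gm.calls[i, l] != gm.calls[j, l]
                )
                assert km.counts[i, j] == expected

    def test_mean_differential_subset(self):
        gm = make_matrix(
            {"v1": ["A/A"], "v2": ["G/G"], "v3": ["A/A"]}, ["L1"]
        )
        km = differential_matrix(gm)
        md = km.mean_differential(["v1", "v2", "v3"])
        assert md["v1"] == pytest.approx(0.5)  # differs from v2 only
        assert md["v2"] == pytest.approx(1.0)


class TestCoreSnps:
    def test_single_discriminating_locus_suffices(self):
        gm = make_matrix(
            {"v1": ["A/A", "C/C", "C/C"], "v2": ["G/G", "C/C", "C/C"]},
            ["L1", "L2", "L3"],
        )
        cs = select_core_snps(gm)
        assert cs.loci == ["L1"]
        assert cs.total_pairs == 1
        assert cs.final_fraction == 1.0
        assert cs.unresolved_pairs == []

    def test_identical_varieties_stay_unresolved(self):
        gm = make_matrix(
            {"v1": ["A/A"], "v2": ["A/A"], "v3": ["G/G"]}, ["L1"]
        )
        cs = select_core_snps(gm)
        assert ("v1", "v2") in cs.unresolved_pairs
        assert cs.final_fraction == pytest.approx(2 / 3)
        assert cs.distinguishable_pairs == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_matches_target_of_exhaustive(self, seed):
        """Greedy reaches the same covered-pair count; exhaustive is never
        larger than greedy."""
        gm = random_matrix(12, 15, seed=seed, missing_rate=0.1)
        g = select_core_snps(gm, mode="greedy")
        e = select_core_snps(gm, mode="exhaustive")
        assert g.curve[-1][1] == e.curve[-1][1] == g.distinguishable_pairs
        assert len(e.loci) <= len(g.loci)

    def test_saturation_curve_monotone(self):
        gm = random_matrix(25, 40, seed=19)
        cs = select_core_snps(gm)
        counts = [c[1] for c in cs.curve]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == cs.distinguishable_pairs

    def test_max_size_truncates(self):
        gm = random_matrix(25, 40, seed=19)
        cs = select_core_snps(gm, max_size=3)
        assert len(cs.loci) <= 3

    def test_exhaustive_bound_enforced(self):
        gm = random_matrix(10, 30, seed=1)
        with pytest.raises(DataError, match="bounded"):
            select_core_snps(gm, mode="exhaustive")

    def test_unique_profile_fraction(self):
        gm = make_matrix(
            {"v1": ["A/A"], "v2": ["A/A"], "v3": ["G/G"]}, ["L1"]
        )
        cs = select_core_snps(gm)
        assert cs.unique_profile_fraction == pytest.approx(1 / 3)

    def test_empty_matrix_rejected(self):
        gm = make_matrix({"v1": ["A/A"]}, ["L1"])
        with pytest.raises(DataError):
            select_core_snps(gm)


class TestCoreVarieties:
    def test_ceil_rule_and_ranking(self):
        # 20 varieties, one subpop: ceil(0.1*20)=2 lowest mean differential.
        # Staircase design: variety i carries G/G at loci 0..i-1, so varieties
        # i and j differ at exactly |i - j| loci and the expected selection is
        # computable by hand.
        rows = {}
        base = ["A/A"] * 30
        for i in range(20):
            row = list(base)
            for l in range(i):
                row[l] = "G/G"
            rows[f"v{i:02d}"] = row
        gm = make_matrix(rows, [f"L{j}" for j in range(30)])
        km = differential_matrix(gm)
        cv = select_core_varieties(km, {v: "P" for v in rows}, fraction=0.1)
        assert len(cv.selected["P"]) == 2
        # mean |i - j| is minimized at the two central varieties
        mean_abs = {
            i: np.mean([abs(i - j) for j in range(20) if j != i]) for i in range(20)
        }
        expected = sorted(sorted(mean_abs, key=lambda i: (mean_abs[i], i))[:2])
        assert cv.selected["P"] == [f"v{i:02d}" for i in expected]

    def test_tie_broken_by_variety_id(self):
        gm = make_matrix(
            {"b": ["A/A"], "a": ["A/A"], "c": ["G/G"], "d": ["G/G"]}, ["L1"]
        )
        km = differential_matrix(gm)
        cv = select_core_varieties(km, {v: "P" for v in "abcd"}, fraction=0.25)
        assert cv.selected["P"] == ["a"]  # all means tie at 2/3; id order wins

    def test_per_subpop_independent(self):
        gm = random_matrix(30, 20, seed=23)
        sub = {v: ("P1" if i < 15 else "P2") for i, v in enumerate(gm.varieties)}
        km = differential_matrix(gm)
        cv = select_core_varieties(km, sub, fraction=0.2)
        assert len(cv.selected["P1"]) == 3 and len(cv.selected["P2"]) == 3
        assert set(cv.selected["P1"]) <= set(gm.varieties[:15])
        assert len(cv.all_selected) == 6

    def test_unassigned_rejected(self):
        gm = make_matrix({"v1": ["A/A"], "v2": ["G/G"]}, ["L1"])
        km = differential_matrix(gm)
        with pytest.raises(DataError, match="subgroup"):
            select_core_varieties(km, {"v1": "P"})


class TestDistancesAndCorrelation:
    def test_allele_sharing_hand_values(self):
        gm = make_matrix(
            {"v1": ["A/A", "A/G"], "v2": ["A/A", "A/G"], "v3": ["G/G", "A/A"]},
            ["L1", "L2"],
        )
        d = allele_sharing_distance(gm)
        assert d[0, 1] == pytest.approx(0.0)  # identical
        # v1 vs v3: L1 shares 0, L2 shares 1 -> 1 - (0 + 0.5)/2 = 0.75
        assert d[0, 2] == pytest.approx(0.75)
        s = genetic_similarity(gm)
        assert s[0, 2] == pytest.approx(0.25)

    def test_matrix_correlation_extremes(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        assert matrix_correlation(m, m) == pytest.approx(1.0)
        assert matrix_correlation(m, -m) == pytest.approx(-1.0)
        const = np.ones((3, 3))
        assert matrix_correlation(m, const) is None

    def test_matrix_correlation_matches_bruteforce(self):
        rng = np.random.default_rng(29)
        a = rng.random((6, 6))
        b = rng.random((6, 6))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        il = np.tril_indices(6, k=-1)
        expected = np.corrcoef(a[il], b[il])[0, 1]
        assert matrix_correlation(a, b) == pytest.approx(expected)

    def test_kinship_correlates_with_distance(self):
        gm = random_matrix(20, 40, seed=31, missing_rate=0.0)
        km = differential_matrix(gm)
        d = allele_sharing_distance(gm)
        r = matrix_correlation(km.counts.astype(float), d)
        assert r is not None and r > 0.8
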