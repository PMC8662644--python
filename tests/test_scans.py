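import numpy as np
import pandas as pd
import pytest

from colonpop import scans
from colonpop.core import HaplotypeMatrix
from conftest import random_matrix
from oracles import (ehh_oracle, garud_oracle, hudson_oracle, ihh_oracle,
                     tajima_oracle)


def matrix_from(alleles, pos_bp=None, cm_per_mb=1.0):
    alleles = np.asarray(alleles, dtype=np.int8)
    S, H = alleles.shape
    if pos_bp is None:
        pos_bp = np.arange(1, S + 1) * 1000
    ids = [f"i{k}" for k in range(H)]
    return HaplotypeMatrix(alleles, np.array(["chr1"] * S, dtype=object),
                           pos_bp, np.asarray(pos_bp) * cm_per_mb / 1e6, ids)


class TestEhh:
    def test_focal_ehh_is_one(self, rng):
        m = random_matrix(rng, n_sites=30, n_haps=8)
        carriers = np.arange(6)
        curve = scans.ehh_decay(m, 15, carriers)
        assert curve.loc[curve.site == 15, "ehh"].item() == 1.0

    def test_identical_carriers_truncation(self):
        m = matrix_from(np.zeros((20, 6)))
        curve = scans.ehh_decay(m, 10, np.arange(6))
        assert (curve["ehh"] == 1.0).all()
        assert curve.attrs["truncated"]

    def test_two_pair_split_gives_one_third(self):
        # 4 carriers; identical in pairs beyond the focal site
        al = np.zeros((5, 4), dtype=np.int8)
        al[3] = [0, 0, 1, 1]   # split into two pairs at site 3
        m = matrix_from(al)
        curve = scans.ehh_decay(m, 2, np.arange(4), cutoff=0.0)
        assert curve.loc[curve.site == 3, "ehh"].item() \
            == pytest.approx(2 / 6)

    def test_matches_pairwise_enumeration(self, rng):
        m = random_matrix(rng, n_sites=40, n_haps=10, missing_rate=0.05)
        carriers = np.flatnonzero(m.alleles[20] == 0)  # a real allele class
        assert len(carriers) >= 4
        curve = scans.ehh_decay(m, 20, carriers, cutoff=0.0)
        for _, row in curve.iterrows():
            want = ehh_oracle(m.alleles, 20, carriers, int(row["site"]))
            assert row["ehh"] == pytest.approx(want, abs=1e-12)

    def test_fewer_than_two_carriers_rejected(self, rng):
        m = random_matrix(rng, n_sites=10, n_haps=4)
        with pytest.raises(ValueError):
            scans.ehh_decay(m, 5, np.array([0]))


class TestIhs:
    def test_matches_bruteforce_oracle(self):
        """iHH and unstandardized iHS equal pairwise-enumeration + trapezoid
        to 1e-9 on a random toy matrix."""
        rng = np.random.default_rng(7)
        m = random_matrix(rng, n_sites=50, n_haps=20, missing_rate=0.02)
        res = scans.ihs(m)
        for _, row in res.table.iterrows():
            if row["flag"] not in ("ok", "truncated"):
                continue
            s = int(row["site"])
            dcar = np.flatnonzero(m.alleles[s] == 1)
            acar = np.flatnonzero(m.alleles[s] == 0)
            ihh_a, _ = ihh_oracle(m.alleles, m.pos_cM, s, acar, 0, 49,
                                  pos_bp=m.pos_bp,
                                  max_gap_bp=scans.MAX_GAP_BP,
                                  max_extend_bp=scans.MAX_EXTEND_BP)
            ihh_d, _ = ihh_oracle(m.alleles, m.pos_cM, s, dcar, 0, 49,
                                  pos_bp=m.pos_bp,
                                  max_gap_bp=scans.MAX_GAP_BP,
                                  max_extend_bp=scans.MAX_EXTEND_BP)
            assert row["ihh_a"] == pytest.approx(ihh_a, abs=1e-9)
            assert row["ihh_d"] == pytest.approx(ihh_d, abs=1e-9)

    def test_mirror_symmetry_gives_zero(self):
        # derived and ancestral carrier sets with identical structure
        block = np.array([[0, 1], [0, 1], [1, 0], [0, 0], [1, 1]],
                         dtype=np.int8)
        al = np.hstack([block, 1 - block])  # mirrored classes
        focal = np.zeros((1, 4), dtype=np.int8)
        focal[0, 2:] = 1
        al = np.vstack([block.repeat(2, axis=1)[:, :4], focal,
                        block.repeat(2, axis=1)[:, :4]])
        al[2] = [0, 0, 1, 1]
        m = matrix_from(al)
        res = scans.ihs(m)
        row = res.table.iloc[2]
        if row["flag"] == "ok":
            assert row["score"] == pytest.approx(0.0, abs=1e-12)

    def test_long_derived_haplotype_negative_score(self):
        rng = np.random.default_rng(1)
        S, H = 60, 20
        al = (rng.random((S, H)) < 0.5).astype(np.int8)
        focal = 30
        al[focal] = 0
        al[focal, :8] = 1
        # derived carriers share one long haplotype around the focal site
        al[10:50, :8] = al[10:50, [0]]
        m = matrix_from(al)
        res = scans.ihs(m)
        row = res.table.iloc[focal]
        assert row["flag"] == "ok"
        assert row["score"] < 0

    def test_low_frequency_excluded(self, rng):
        m = random_matrix(rng, n_sites=20, n_haps=40)
        m.alleles[5] = 0
        m.alleles[5, 0] = 1  # derived frequency 0.025 < 0.05
        res = scans.ihs(m)
        assert res.table.iloc[5]["flag"] == "low_freq"


class TestNsl:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, n_sites=40, n_haps=12)
        res = scans.nsl(m)
        units = np.arange(40, dtype=float)
        for _, row in res.table.iterrows():
            if row["flag"] not in ("ok", "truncated"):
                continue
            s = int(row["site"])
            dcar = np.flatnonzero(m.alleles[s] == 1)
            acar = np.flatnonzero(m.alleles[s] == 0)
            ihh_a, _ = ihh_oracle(m.alleles, units, s, acar, 0, 39,
                                  max_steps=scans.MAX_EXTEND_SNPS)
            ihh_d, _ = ihh_oracle(m.alleles, units, s, dcar, 0, 39,
                                  max_steps=scans.MAX_EXTEND_SNPS)
            assert row["ihh_a"] == pytest.approx(ihh_a, abs=1e-9)
            assert row["ihh_d"] == pytest.approx(ihh_d, abs=1e-9)


class TestXpehh:
    def test_same_population_zero(self, rng):
        m = random_matrix(rng, n_sites=30, n_haps=20)
        cols = np.arange(10)
        res = scans.xpehh(m, cols, cols)
        ok = res.table[res.table.flag == "ok"]
        assert np.allclose(ok["score"], 0.0, atol=1e-12)

    def test_swap_flips_sign(self, rng):
        m = random_matrix(rng, n_sites=30, n_haps=24)
        a, b = np.arange(12), np.arange(12, 24)
        r1 = scans.xpehh(m, a, b).table
        r2 = scans.xpehh(m, b, a).table
        ok = (r1.flag == "ok") & (r2.flag == "ok")
        np.testing.assert_allclose(r1.loc[ok, "score"],
                                   -r2.loc[ok, "score"], atol=1e-12)

    def test_minimum_haplotype_count(self, rng):
        m = random_matrix(rng, n_sites=10, n_haps=12)
        with pytest.raises(ValueError):
            scans.xpehh(m, np.arange(4), np.arange(4, 12))


class TestStandardize:
    def test_bin_calibration_normal_scores(self):
        rng = np.random.default_rng(3)
        n = 4000
        table = pd.DataFrame({
            "chrom": "chr1", "pos_bp": np.arange(n), "site": np.arange(n),
            "freq_derived": rng.uniform(0.05, 0.95, n),
            "ihh_a": 1.0, "ihh_d": 1.0,
            "score": rng.normal(size=n), "flag": "ok"})
        res = scans.standardize(scans.ScanResult(table, "ihs"))
        frac = (res.table["z"].abs() > 1.96).mean()
        assert frac == pytest.approx(0.05, abs=0.015)
        # empirical p of the most extreme SNP is 1/(n+1)
        assert res.table["p_empirical"].min() == pytest.approx(1 / (n + 1))

    def test_degenerate_bin_flagged(self):
        table = pd.DataFrame({
            "chrom": "chr1", "pos_bp": [1, 2, 3], "site": [0, 1, 2],
            "freq_derived": [0.5, 0.5, 0.5], "ihh_a": 1.0, "ihh_d": 1.0,
            "score": [2.0, 2.0, 2.0], "flag": "ok"})
        res = scans.standardize(scans.ScanResult(table, "ihs"), n_bins=5)
        assert (res.table["flag"] == "degenerate_bin").all()

    def test_bin_moments(self):
        rng = np.random.default_rng(5)
        n = 20000
        table = pd.DataFrame({
            "chrom": "chr1", "pos_bp": np.arange(n), "site": np.arange(n),
            "freq_derived": rng.uniform(0.05, 0.95, n),
            "ihh_a": 1.0, "ihh_d": 1.0,
            "score": rng.normal(size=n) + 1.0, "flag": "ok"})
        res = scans.standardize(scans.ScanResult(table, "ihs"), n_bins=20)
        z = res.table["z"]
        f = res.table["freq_derived"]
        for lo in np.arange(0.05, 0.95, 0.09):
            m = (f >= lo) & (f < lo + 0.09)
            if m.sum() >= 500:
                assert abs(z[m].mean()) < 0.05
                assert abs(z[m].std(ddof=0) - 1) < 0.05


class TestGarud:
    def test_all_identical(self):
        m = matrix_from(np.ones((10, 6)))
        t = scans.garud_h(m, window_snps=10, step_snps=10)
        assert t.iloc[0]["h1"] == 1.0
        assert t.iloc[0]["h12"] == 1.0
        assert t.iloc[0]["h2_h1"] == 0.0

    def test_two_equal_haplotypes(self):
        al = np.zeros((4, 8), dtype=np.int8)
        al[:, 4:] = 1
        t = scans.garud_h(matrix_from(al), 4, 4)
        row = t.iloc[0]
        assert row["h1"] == pytest.approx(0.5)
        assert row["h12"] == pytest.approx(1.0)
        assert row["h2_h1"] == pytest.approx(0.5)

    def test_three_haplotype_spectrum(self):
        """Frequencies (0.6, 0.2, 0.2): H1=0.44, H12=0.68, H2/H1=0.1818."""
        al = np.zeros((3, 10), dtype=np.int8)
        al[:, 6:8] = [[1], [0], [1]]
        al[:, 8:] = 1
        t = scans.garud_h(matrix_from(al), 3, 3)
        row = t.iloc[0]
        assert row["h1"] == pytest.approx(0.44)
        assert row["h12"] == pytest.approx(0.68)
        assert row["h2_h1"] == pytest.approx(0.08 / 0.44)

    def test_matches_oracle_with_missing_drop(self, rng):
        m = random_matrix(rng, n_sites=12, n_haps=10, missing_rate=0.05)
        t = scans.garud_h(m, 12, 12)
        sub = m.alleles
        keep = (sub >= 0).all(axis=0)
        strings = ["".join(map(str, sub[:, j])) for j in range(10) if keep[j]]
        h1, h12, h2, ratio = garud_oracle(strings)
        row = t.iloc[0]
        assert row["h1"] == pytest.approx(h1, abs=1e-12)
        assert row["h12"] == pytest.approx(h12, abs=1e-12)
        assert row["h2_h1"] == pytest.approx(ratio, abs=1e-12)


class TestTajima:
    def test_no_segregating_flagged(self):
        m = matrix_from(np.zeros((5, 6)))
        t = scans.tajima_d(m, window_bp=10_000, step_bp=10_000)
        assert (t["flag"] == "no_segregating").all()

    def test_matches_textbook_oracle(self, rng):
        m = random_matrix(rng, n_sites=40, n_haps=12)
        t = scans.tajima_d(m, window_bp=2_000_000, step_bp=2_000_000)
        want = tajima_oracle(m.alleles)
        got = t[t.flag == "ok"]["tajima_d"].iloc[0]
        assert got == pytest.approx(want, abs=1e-12)

    def test_hard_sweep_window_negative_on_average(self):
        """A window homogenized by a recent hard sweep has negative D
        (excess rare variants) on average over 20 seeds."""
        from colonpop import simulate as sim

        deltas = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = random_matrix(r, n_sites=120, n_haps=30,
                              chrom_len=1_000_000)
            neutral = scans.tajima_d(m, 10**9, 10**9).iloc[0]["tajima_d"]
            spec = sim.SweepSpec("chr1", 500_000, "hard", 0.9,
                                 window_bp=500_000)
            sim.inject_sweep(m, spec, r)
            swept = scans.tajima_d(m, 10**9, 10**9).iloc[0]["tajima_d"]
            deltas.append(swept - neutral)
        assert np.mean(deltas) < 0


class TestHudsonFst:
    def test_per_site_hand_value(self):
        """p=(0.8, 0.2) at very large n: ratio -> 0.36/0.68."""
        n = np.array([10**9])
        num, den, _ = scans.hudson_fst_sites(np.array([0.8]), np.array([0.2]),
                                             n, n)
        assert num[0] / den[0] == pytest.approx(0.36 / 0.68, abs=1e-6)

    def test_identical_groups_near_zero(self, rng):
        m = random_matrix(rng, n_sites=400, n_haps=40)
        inds = [f"ind{i}" for i in range(20)]
        t = scans.hudson_fst_windows(m, inds[:10], inds[10:],
                                     window_bp=10**9)
        assert abs(t["fst"].iloc[0]) < 0.02

    def test_fixed_difference_gives_one(self):
        al = np.zeros((6, 8), dtype=np.int8)
        al[:, 4:] = 1
        m = matrix_from(al)
        m.sample_ids[:] = np.repeat(["a", "b", "c", "d"], 2)
        t = scans.hudson_fst_windows(m, ["a", "b"], ["c", "d"],
                                     window_bp=10**9)
        assert t["fst"].iloc[0] == pytest.approx(1.0)

    def test_window_matches_oracle(self, rng):
        m = random_matrix(rng, n_sites=60, n_haps=20, missing_rate=0.05)
        a = [f"ind{i}" for i in range(5)]
        b = [f"ind{i}" for i in range(5, 10)]
        t = scans.hudson_fst_windows(m, a, b, window_bp=10**9)
        ca = m.haplotypes_of(a)
        cb = m.haplotypes_of(b)
        pa, na = scans._group_freqs_for_cols(m, ca)
        pb, nb = scans._group_freqs_for_cols(m, cb)
        assert t["fst"].iloc[0] == pytest.approx(
            hudson_oracle(np.nan_to_num(pa), np.nan_to_num(pb), na, nb),
            abs=1e-12)

    def test_permutation_p_on_true_difference(self, rng):
        al = np.zeros((30, 20), dtype=np.int8)
        al[:, 10:] = 1
        al[rng.random(al.shape) < 0.05] = 0
        m = matrix_from(al)
        m.sample_ids[:] = np.repeat([f"i{k}" for k in range(10)], 2)
        t = scans.fst_permutation_test(m, [f"i{k}" for k in range(5)],
                                       [f"i{k}" for k in range(5, 10)],
                                       np.random.default_rng(0),
                                       window_bp=10**9, n_perm=99)
        # a permutation can reproduce the observed split (or its mirror),
        # so the smallest attainable p may be slightly above 1/(n_perm+1)
        assert t["p_perm"].iloc[0] <= 3 / 100
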