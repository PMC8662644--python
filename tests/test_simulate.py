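import json

import numpy as np
import pandas as pd
import pytest

from colonpop import core, simulate as sim
from colonpop.load import ancestry_proportions
from oracles import hudson_oracle


def small_config(**kw):
    defaults = dict(
        n_sources=2, source_fst=0.1, n_sites=2000, n_chromosomes=1,
        chromosome_length_bp=2_000_000, pool_size=30, chain_rounds=10,
        n_private_deleterious=10,
        groups=(sim.GroupSpec("Hpg1", (1.0, 0.0), 8),
                sim.GroupSpec("Mix", (0.5, 0.5), 8)),
        env=sim.EnvConfig(n_groups=3, n_refs=8),
    )
    defaults.update(kw)
    return sim.ScenarioConfig(**defaults)


class TestSourcePools:
    def test_fst_matches_drift_parameter(self):
        """Hudson FST between two Balding–Nichols pools ~ F (10 seeds)."""
        fsts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pools = sim.simulate_source_pools(
                small_config(n_sites=4000, n_private_deleterious=0), rng)
            a, b = pools.pools
            pa = a.mean(axis=1)
            pb = b.mean(axis=1)
            na = np.full(len(pa), a.shape[1])
            fsts.append(hudson_oracle(pa, pb, na, na))
        assert np.mean(fsts) == pytest.approx(0.1, abs=0.02)

    def test_low_f_low_fst(self):
        rng = np.random.default_rng(0)
        pools = sim.simulate_source_pools(
            small_config(source_fst=0.005, n_private_deleterious=0), rng)
        a, b = pools.pools
        pa, pb = a.mean(axis=1), b.mean(axis=1)
        n = np.full(len(pa), a.shape[1])
        assert abs(hudson_oracle(pa, pb, n, n)) < 0.03

    def test_private_fixed_deleterious_construction(self):
        rng = np.random.default_rng(1)
        pools = sim.simulate_source_pools(small_config(), rng)
        for g, sites in pools.private_sites.items():
            assert len(sites) == 10
            assert np.all(pools.category[sites] == "nonsyn_deleterious")
            assert np.all(pools.pools[g][sites] == 1)
            other = 1 - g
            assert np.all(pools.pools[other][sites] == 0)
            assert np.all(pools.outgroup_pool[sites] == 0)

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            small_config(source_fst=0.0).validate()
        with pytest.raises(ValueError):
            small_config(source_fst=1.0).validate()


class TestAdmixedGroup:
    def test_single_source_proportion_one(self):
        rng = np.random.default_rng(2)
        pools = sim.simulate_source_pools(small_config(), rng)
        _, _, tracts = sim.simulate_admixed_group(
            pools, (1.0, 0.0), 5, selfing=0.9, switch_rate=1.0, rng=rng)
        assert set(tracts["source"]) == {"Source1"}
        prop = ancestry_proportions(core.AncestryTracts(tracts))
        assert np.allclose(prop["Source1"], 1.0)

    def test_mean_ancestry_recovers_proportions(self):
        """50/50 mosaic, many tracts: mean truth ancestry 0.5 +/- 0.03."""
        means = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            pools = sim.simulate_source_pools(
                small_config(n_sites=200, n_chromosomes=4,
                             chromosome_length_bp=5_000_000,
                             n_private_deleterious=0), rng)
            _, _, tracts = sim.simulate_admixed_group(
                pools, (0.5, 0.5), 40, selfing=0.97, switch_rate=20.0,
                rng=rng)
            prop = ancestry_proportions(core.AncestryTracts(tracts))
            means.append(float(prop["Source1"].mean()))
        assert np.mean(means) == pytest.approx(0.5, abs=0.03)

    def test_selfing_one_duplicates_haplotypes(self):
        rng = np.random.default_rng(3)
        pools = sim.simulate_source_pools(small_config(), rng)
        alleles, _, _ = sim.simulate_admixed_group(
            pools, (0.5, 0.5), 6, selfing=1.0, switch_rate=1.0, rng=rng)
        for i in range(6):
            np.testing.assert_array_equal(alleles[:, 2 * i],
                                          alleles[:, 2 * i + 1])

    def test_tracts_cover_genome_without_overlap(self):
        rng = np.random.default_rng(4)
        cfg = small_config(n_chromosomes=2)
        pools = sim.simulate_source_pools(cfg, rng)
        _, _, tracts = sim.simulate_admixed_group(
            pools, (0.3, 0.7), 4, selfing=0.5, switch_rate=5.0, rng=rng)
        tr = core.AncestryTracts(tracts)  # validates non-overlap
        for (hap, chrom), sub in tracts.groupby(["haplotype", "chrom"]):
            s = sub.sort_values("start")
            assert s["start"].iloc[0] == 1
            assert s["end"].iloc[-1] == cfg.chromosome_length_bp
            gaps = s["start"].values[1:] - s["end"].values[:-1]
            assert np.all(gaps == 1)


class TestSweeps:
    def _matrix(self, seed=5, n_haps=40):
        rng = np.random.default_rng(seed)
        n_sites = 400
        alleles = (rng.random((n_sites, n_haps)) < 0.3).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), n_sites,
                                 replace=False))
        ids = np.repeat([f"i{k}" for k in range(n_haps // 2)], 2)
        return core.HaplotypeMatrix(
            alleles, np.array(["chr1"] * n_sites, dtype=object), pos,
            pos * 3.5e-6, ids), rng

    def test_hard_sweep_to_fixation_homogenizes_window(self):
        m, rng = self._matrix()
        focal = 200
        m.alleles[focal] = 0
        m.alleles[focal, 0] = 1  # single initial carrier = the founder
        spec = sim.SweepSpec("chr1", int(m.pos_bp[focal]), "hard", 1.0,
                             window_bp=50_000)
        truth = sim.inject_sweep(m, spec, rng)
        window = np.flatnonzero(np.abs(m.pos_bp - m.pos_bp[focal]) <= 50_000)
        assert np.all(m.alleles[focal] == 1)
        # every haplotype's window equals the founder's
        f = truth["founders"][0]
        assert np.all(m.alleles[np.ix_(window)] ==
                      m.alleles[np.ix_(window, [f])])

    def test_soft_sweep_keeps_multiple_backgrounds(self):
        m, rng = self._matrix()
        spec = sim.SweepSpec("chr1", int(m.pos_bp[200]), "soft", 0.9,
                             n_founders=4, window_bp=50_000)
        truth = sim.inject_sweep(m, spec, rng)
        assert len(set(truth["founders"])) == 4

    def test_target_below_current_rejected(self):
        m, rng = self._matrix()
        m.alleles[200] = 1
        spec = sim.SweepSpec("chr1", int(m.pos_bp[200]), "hard", 0.1)
        with pytest.raises(ValueError):
            sim.inject_sweep(m, spec, rng)

    def test_no_sweep_leaves_matrix_unchanged(self):
        cfg = small_config(sweeps=())
        scn = sim.simulate_scenario(cfg, 11)
        scn2 = sim.simulate_scenario(cfg, 11)
        np.testing.assert_array_equal(scn.matrix.alleles, scn2.matrix.alleles)


class TestEnvResponse:
    def test_zero_noise_exactly_linear(self):
        rng = np.random.default_rng(6)
        env = sim.EnvConfig(sigma=0.0, tau=0.0, n_groups=4, n_refs=10)
        _, design = sim.make_env_design(env, rng)
        out, truth = sim.simulate_env_response(design, env, rng)
        X = out[list(sim.ENV_VARIABLES)].to_numpy()
        want = env.intercept + X @ np.asarray(env.betas)
        np.testing.assert_allclose(out["y"].to_numpy(), want, atol=1e-12)

    def test_null_betas_uncorrelated(self):
        cors = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            env = sim.EnvConfig(betas=(0, 0, 0, 0), tau=0.0, n_groups=10,
                                n_refs=40)
            _, design = sim.make_env_design(env, rng)
            out, _ = sim.simulate_env_response(design, env, rng)
            cors.append(np.corrcoef(out["prec"], out["y"])[0, 1])
        assert abs(np.mean(cors)) < 0.03

    def test_ols_recovers_slope(self):
        """OLS on the simulated design recovers beta_prec = -0.18 +/- 0.05."""
        slopes = []
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            env = sim.EnvConfig(sigma=0.4, tau=0.0, n_groups=6, n_refs=100)
            _, design = sim.make_env_design(env, rng)
            out, _ = sim.simulate_env_response(design, env, rng)
            X = np.column_stack([np.ones(len(out)),
                                 out[list(sim.ENV_VARIABLES)].to_numpy()])
            coef, *_ = np.linalg.lstsq(X, out["y"].to_numpy(), rcond=None)
            slopes.append(coef[2])
        assert np.mean(slopes) == pytest.approx(-0.18, abs=0.05)


class TestScenarioContracts:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = small_config()
        p1 = tmp_path / "a"
        p2 = tmp_path / "b"
        sim.emit_scenario(sim.simulate_scenario(cfg, 42), str(p1))
        sim.emit_scenario(sim.simulate_scenario(cfg, 42), str(p2))
        for name in ("genotypes.vcf", "groups.tsv", "categories.tsv",
                     "map.tsv", "tracts.tsv", "env.tsv", "design.tsv",
                     "truth.json"):
            assert (p1 / name).read_bytes() == (p2 / name).read_bytes(), name

    def test_emitted_vcf_round_trips(self, tmp_path):
        scn = sim.simulate_scenario(small_config(), 7)
        paths = sim.emit_scenario(scn, str(tmp_path))
        m = core.read_vcf(paths["vcf"])
        np.testing.assert_array_equal(m.alleles, scn.matrix.alleles)
        np.testing.assert_array_equal(m.pos_bp, scn.matrix.pos_bp)
        assert list(m.sample_ids) == list(scn.matrix.sample_ids)

    def test_tract_tsv_matches_truth_proportions(self, tmp_path):
        scn = sim.simulate_scenario(small_config(), 8)
        paths = sim.emit_scenario(scn, str(tmp_path))
        reread = core.read_tracts(paths["tracts"])
        p1 = ancestry_proportions(scn.tracts)
        p2 = ancestry_proportions(reread)
        pd.testing.assert_frame_equal(p1, p2)

    def test_truth_json_round_trips(self, tmp_path):
        scn = sim.simulate_scenario(small_config(), 9)
        paths = sim.emit_scenario(scn, str(tmp_path))
        with open(paths["truth"]) as fh:
            truth = json.load(fh)
        assert truth["group_proportions"] == {"Hpg1": [1.0, 0.0],
                                              "Mix": [0.5, 0.5]}
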