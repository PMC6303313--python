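import numpy as np
import pytest
from scipy import stats

from popgen import diversity as dv
from popgen import synthetic_data as sd
from popgen.synthetic_data import DemographyConfig, PopulationConfig
from popgen.variants_io import RegionMask, read_vcf

from conftest import A, H, M, R


class TestConfigValidation:
    def test_preset_passes_invariants(self):
        config = sd.preset_qingke()
        assert config.mutation_rate == 6.5e-9
        assert config.generation_time == 1.0

    def test_preset_eastern_size_during_founder_window(self):
        config = sd.preset_qingke()
        size = config.pop["eastern"].size_between(2_000, 4_500)
        assert 4_374 <= size <= 4_500

    def test_bad_pulse_fraction_rejected(self):
        with pytest.raises(ValueError):
            DemographyConfig(
                populations=[
                    PopulationConfig("a", 2, [(0, 100)]),
                    PopulationConfig("b", 2, [(0, 100)]),
                ],
                splits=[(10.0, "b", "a")],
                pulses=[(5.0, "a", "b", 1.5)],
            )

    def test_unknown_split_population_rejected(self):
        with pytest.raises(ValueError):
            DemographyConfig(
                populations=[PopulationConfig("a", 2, [(0, 100)])],
                splits=[(10.0, "ghost", "a")],
            )

    def test_epoch_order_enforced(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            DemographyConfig(
                populations=[PopulationConfig("a", 2, [(0, 100), (50, 10), (20, 5)])]
            )

    def test_round_trip_through_dict(self):
        config = sd.preset_qingke()
        back = DemographyConfig.from_dict(config.to_dict())
        assert back.to_dict() == config.to_dict()


class TestSimulate:
    def test_pairwise_diversity_expectation_n2(self):
        """E[pi per site] = 2*Ne*mu for two haploid lineages."""
        ne = 100_000
        config = sd.single_population_config(ne, 2, n_loci=400, locus_length=10_000)
        gm, _ = sd.simulate(config, seed=9)
        per_locus = []
        for chrom in [f"chr{i+1}" for i in range(400)]:
            sub = gm.take_sites(gm.sites["chrom"].to_numpy() == chrom)
            site = dv.site_diversity_arrays(sub)
            per_locus.append(site["pi_site"].sum() / 10_000)
        per_locus = np.array(per_locus)
        se = per_locus.std(ddof=1) / np.sqrt(len(per_locus))
        assert abs(per_locus.mean() - 2 * ne * config.mutation_rate) < 3 * se

    def test_watterson_segregating_site_expectation(self):
        """E[S] per locus = theta * L * a_{n-1} at n=10."""
        ne = 100_000
        config = sd.single_population_config(ne, 10, n_loci=400, locus_length=10_000)
        gm, _ = sd.simulate(config, seed=10)
        theta = 2 * ne * config.mutation_rate
        a9 = sum(1 / i for i in range(1, 10))
        expected = theta * 10_000 * a9
        p, n = gm.alt_freq()
        seg = (p > 0) & (p < 1)
        counts = np.zeros(400)
        chroms = gm.sites["chrom"].to_numpy()
        for i, chrom in enumerate(f"chr{k+1}" for k in range(400)):
            counts[i] = seg[chroms == chrom].sum()
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_determinism_same_seed_same_data(self):
        config = sd.preset_qingke(n_loci=5, locus_length=5_000)
        gm1, t1 = sd.simulate(config, seed=77)
        gm2, t2 = sd.simulate(config, seed=77)
        assert (gm1.calls == gm2.calls).all()
        assert gm1.sites.equals(gm2.sites)
        assert t1.locus_seeds == t2.locus_seeds

    def test_sfs_matches_neutral_expectation(self):
        """Unfolded SFS of a constant-size run follows E[xi_i] ~ 1/i.

        Sites within one locus share a genealogy (no recombination), so a
        naive multinomial chi-square would be wildly anticonservative.  The
        goodness-of-fit statistic instead uses a cluster-robust covariance
        built from per-locus class counts (300 independent loci), which is
        chi-square with 10 degrees of freedom under the neutral model.
        """
        n_loci = 300
        config = sd.single_population_config(
            200_000, 12, n_loci=n_loci, locus_length=10_000
        )
        gm, _ = sd.simulate(config, seed=14)
        p, _ = gm.alt_freq()
        seg = (p > 0) & (p < 1)
        counts = np.round(p * 12).astype(int)
        chroms = gm.sites["chrom"].to_numpy()
        q = 1 / np.arange(1, 12)
        q = q / q.sum()
        per_locus = np.array(
            [
                np.bincount(counts[seg & (chroms == f"chr{i+1}")], minlength=12)[1:12]
                for i in range(n_loci)
            ],
            dtype=float,
        )
        observed = per_locus.sum(axis=0)
        resid = per_locus - per_locus.sum(axis=1, keepdims=True) * q
        cov = resid.T @ resid
        d = observed - observed.sum() * q
        T = float(d @ np.linalg.solve(cov, d))
        pval = stats.chi2.sf(T, df=10)
        assert observed.sum() >= 10_000
        assert pval > 0.01

    def test_diversity_ordering_under_preset(self):
        config = sd.preset_qingke(n_loci=60)
        wins = 0
        for seed in range(5):
            gm, truth = sd.simulate(config, seed=8_000 + seed)
            idx = {
                g: np.array([i for i, s in enumerate(gm.samples) if truth.labels[s] == g])
                for g in ("wild", "eastern", "qingke")
            }
            mask = RegionMask({f"chr{i+1}": np.array([[0, 10_000]]) for i in range(60)})
            pis = {g: dv.group_summary(gm, mask, ix).pi for g, ix in idx.items()}
            wins += pis["wild"] > pis["eastern"] > pis["qingke"]
        assert wins == 5


class TestEmitDataset:
    def test_lossless_path_without_noise(self, tmp_path):
        """With zero noise and flat coverage every segregating site survives
        the full filter chain."""
        from popgen import filtering as ft
        from popgen.variants_io import compute_effective_region, read_depth_table

        config = sd.preset_qingke(n_loci=4, locus_length=4_000)
        gm, truth = sd.simulate(config, seed=21)
        paths = sd.emit_dataset(
            gm, truth, tmp_path / "d",
            het_error_rate=0.0, missing_rate=0.0, mean_coverage=30.0,
        )
        back = read_vcf(paths["vcf"])
        track = read_depth_table(paths["depth"])
        mask = compute_effective_region(track)
        cfg = ft.FilterConfig()
        out = ft.site_filter(ft.genotype_level_filter(back, cfg), mask, cfg)
        p, n = gm.alt_freq()
        polymorphic = ((p > 0) & (p < 1)).sum()
        assert out.n_sites == polymorphic

    def test_byte_identical_reruns(self, tmp_path):
        config = sd.preset_qingke(n_loci=3, locus_length=3_000)
        gm, truth = sd.simulate(config, seed=33)
        p1 = sd.emit_dataset(gm, truth, tmp_path / "a")
        gm2, truth2 = sd.simulate(config, seed=33)
        p2 = sd.emit_dataset(gm2, truth2, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_collision_without_overwrite_flag(self, tmp_path):
        config = sd.preset_qingke(n_loci=2, locus_length=2_000)
        gm, truth = sd.simulate(config, seed=3)
        sd.emit_dataset(gm, truth, tmp_path / "x")
        with pytest.raises(FileExistsError):
            sd.emit_dataset(gm, truth, tmp_path / "x")
        sd.emit_dataset(gm, truth, tmp_path / "x", overwrite=True)

    def test_missing_rate_drives_site_attrition(self, tmp_path):
        """Sites exceed the 20%-missing rule at roughly the binomial rate."""
        from popgen import filtering as ft

        config = sd.single_population_config(200_000, 10, n_loci=40)
        gm, truth = sd.simulate(config, seed=44)
        noisy = sd.add_noise(gm, missing_rate=0.3, seed=45)
        n_miss = (noisy.calls == M).sum(axis=1)
        dropped = (n_miss / 10 > 0.2).mean()
        expected = stats.binom.sf(2, 10, 0.3)  # P(X > 2) with n=10, p=0.3
        se3 = 3 * np.sqrt(expected * (1 - expected) / gm.n_sites)
        assert abs(dropped - expected) < se3

    def test_het_noise_recovered(self):
        config = sd.single_population_config(200_000, 10, n_loci=20)
        gm, _ = sd.simulate(config, seed=46)
        noisy = sd.add_noise(gm, het_error_rate=0.05, seed=47)
        frac = (noisy.calls == H).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_planted_deletion_recovered_at_10x(self, tmp_path):
        from popgen import haplotypes as hp
        from popgen.variants_io import read_depth_table

        config = sd.preset_qingke(n_loci=3, locus_length=4_000)
        gm, truth = sd.simulate(config, seed=55)
        target = [s for s, g in truth.labels.items() if g == "qingke"][:4]
        deletion = {"chrom": "chr2", "start": 1_000, "end": 2_600, "samples": target}
        paths = sd.emit_dataset(
            gm, truth, tmp_path / "d", mean_coverage=10.0, deletion=deletion
        )
        track = read_depth_table(paths["depth"])
        calls = hp.depth_deletion_scan(track, ("chr2", 1_000, 2_600))
        got = set(calls[calls["status"] == "deleted"]["sample"])
        assert got == set(target)
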