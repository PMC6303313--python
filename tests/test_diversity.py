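from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from popgen import diversity as dv
from popgen import synthetic_data as sd
from popgen.variants_io import RegionMask

from conftest import A, H, M, R, make_gm


def enumerated_pi(calls_row):
    """Mean pairwise difference over all haplotype pairs (independent oracle)."""
    vals = [c for c in calls_row if c in (R, A)]
    pairs = list(combinations(vals, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


def full_mask(n_chroms=1, length=10_000):
    return RegionMask(
        {f"chr{i+1}": np.array([[0, length]]) for i in range(n_chroms)}
    )


class TestSiteDiversity:
    def test_half_frequency_four_samples(self):
        gm = make_gm([[A, A, R, R]])
        site = dv.site_diversity_arrays(gm)
        assert site["he_site"][0] == pytest.approx(0.5)
        assert site["pi_site"][0] == pytest.approx(2 / 3)
        assert site["theta_site"][0] == pytest.approx(1 / (1 + 1 / 2 + 1 / 3))

    def test_monomorphic_contributes_nothing(self):
        gm = make_gm([[R] * 10])
        site = dv.site_diversity_arrays(gm)
        assert site[["he_site", "pi_site", "theta_site"]].to_numpy().sum() == 0
        assert not site["segregating"][0]

    def test_two_sample_closed_form(self):
        gm = make_gm([[R, A]])
        site = dv.site_diversity_arrays(gm)
        assert site["pi_site"][0] == pytest.approx(1.0)
        assert site["theta_site"][0] == pytest.approx(1.0)
        assert site["he_site"][0] == pytest.approx(0.5)

    def test_single_call_skipped(self):
        gm = make_gm([[A, M, M]])
        site = dv.site_diversity_arrays(gm)
        assert not site["segregating"][0]
        assert site["pi_site"][0] == 0.0

    @given(hst.integers(0, 2**32 - 1))
    def test_pi_equals_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([R, A, M], size=(rng.integers(1, 60), rng.integers(2, 12)))
        gm = make_gm(calls)
        site = dv.site_diversity_arrays(gm)
        for i in range(gm.n_sites):
            assert site["pi_site"][i] == pytest.approx(
                enumerated_pi(calls[i]), abs=1e-12
            )

    @given(hst.integers(2, 50), hst.integers(1, 49))
    def test_he_never_exceeds_pi(self, n, k_alt):
        k = min(k_alt, n - 1)
        gm = make_gm([[A] * k + [R] * (n - k)])
        site = dv.site_diversity_arrays(gm)
        assert site["he_site"][0] <= site["pi_site"][0] + 1e-15


class TestTajimasD:
    def test_worked_example_n4_single_snp(self):
        gm = make_gm([[A, A, R, R]])
        # independent hand evaluation: a1 = 11/6, e1 = 0.005510, S = 1
        a1 = 1 + 1 / 2 + 1 / 3
        e1 = dv.tajima_constants(4)["e1"]
        assert e1 == pytest.approx(0.00551, abs=5e-6)
        expected = (2 / 3 - 1 / a1) / np.sqrt(e1)
        assert dv.tajimas_d(gm) == pytest.approx(expected)
        assert dv.tajimas_d(gm) == pytest.approx(1.63, abs=0.01)

    def test_zero_when_pi_equals_watterson_term(self):
        # n=4: 3 doubleton sites (pi 2/3) + 8 singleton sites (pi 1/2)
        # give Pi = 6 = S/a1 = 11/(11/6) -> numerator exactly 0
        doubleton = [A, A, R, R]
        singleton = [A, R, R, R]
        gm = make_gm([doubleton] * 3 + [singleton] * 8)
        assert dv.tajimas_d(gm) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        gm = make_gm([[R, R, R]])
        assert np.isnan(dv.tajimas_d(gm))

    def test_neutral_constant_size_mean_near_zero(self):
        """Mean per-locus D under the standard neutral model is ~0."""
        config = sd.single_population_config(
            230_000, 20, n_loci=200, locus_length=10_000
        )
        gm, _ = sd.simulate(config, seed=42)
        ds = []
        for chrom in gm.sites["chrom"].unique():
            sub = gm.take_sites(gm.sites["chrom"].to_numpy() == chrom)
            d = dv.tajimas_d(sub)
            if not np.isnan(d):
                ds.append(d)
        ds = np.array(ds)
        se = ds.std(ddof=1) / np.sqrt(len(ds))
        assert abs(ds.mean()) < 3 * se + 0.05


class TestWindowedDiversity:
    def test_masked_out_window_omitted(self):
        gm = make_gm([[R, A]], positions=[5000])
        mask = RegionMask({"chr1": np.array([[0, 1000]])})  # only first window covered
        win = dv.windowed_diversity(gm, mask, min_effective=2000)
        assert win.empty

    def test_single_snp_per_bp_value(self):
        gm = make_gm([[A, A, R, R]], positions=[500])
        win = dv.windowed_diversity(gm, full_mask(), window=10_000, step=10_000)
        assert len(win) == 1
        assert win["pi"][0] == pytest.approx((2 / 3) / 10_000)
        assert win["effective_length"][0] == 10_000

    def test_window_smaller_than_step_rejected(self):
        gm = make_gm([[R, A]])
        with pytest.raises(ValueError):
            dv.windowed_diversity(gm, full_mask(), window=1000, step=2000)

    def test_windowed_mean_consistent_with_genome_value(self):
        config = sd.single_population_config(230_000, 12, n_loci=30)
        gm, _ = sd.simulate(config, seed=7)
        mask = full_mask(30)
        win = dv.windowed_diversity(gm, mask, window=10_000, step=10_000)
        genome = dv.group_summary(gm, mask, np.arange(12)).pi
        per_window = win["pi"].to_numpy()
        se = per_window.std(ddof=1) / np.sqrt(len(per_window))
        assert abs(per_window.mean() - genome) < 3 * se


class TestGroupSummary:
    def test_single_snp_large_mask(self):
        gm = make_gm([[A, A, R, R]])
        mask = full_mask(length=10**6)
        s = dv.group_summary(gm, mask, np.arange(4))
        assert s.pi == pytest.approx((2 / 3) / 1e6)

    def test_no_segregating_sites(self):
        gm = make_gm([[R, R, R]])
        s = dv.group_summary(gm, full_mask(), np.arange(3))
        assert s.pi == s.theta_w == s.he == 0.0
        assert np.isnan(s.tajimas_d)

    def test_zero_length_mask_is_error(self):
        gm = make_gm([[R, A]])
        with pytest.raises(ValueError):
            dv.group_summary(gm, RegionMask({}), np.arange(2))

    def test_watterson_recovers_simulated_theta(self):
        """theta_W estimates 2*Ne*mu under the constant-size coalescent."""
        ne = 230_769  # per-bp theta = 2*Ne*mu ~= 3e-3
        config = sd.single_population_config(ne, 20, n_loci=100)
        gm, _ = sd.simulate(config, seed=123)
        mask = full_mask(100)
        theta_true = 2 * ne * config.mutation_rate
        # per-locus theta estimates give the SE of the mean
        per_locus = []
        for chrom in mask.chroms():
            rows = gm.sites["chrom"].to_numpy() == chrom
            sub = gm.take_sites(rows)
            site = dv.site_diversity_arrays(sub)
            per_locus.append(site["theta_site"].sum() / 10_000)
        per_locus = np.array(per_locus)
        se = per_locus.std(ddof=1) / np.sqrt(len(per_locus))
        assert abs(per_locus.mean() - theta_true) < 3 * se

    def test_invariant_under_chromosome_relabelling(self):
        config = sd.single_population_config(50_000, 8, n_loci=10)
        gm, _ = sd.simulate(config, seed=2)
        mask = full_mask(10)
        s1 = dv.group_summary(gm, mask, np.arange(8))
        # merge all loci into one long chromosome
        sites = gm.sites.copy()
        offsets = {f"chr{i+1}": i * 10_000 for i in range(10)}
        sites["pos"] = sites["pos"] + sites["chrom"].map(offsets)
        sites["chrom"] = "chrAll"
        gm2 = make_gm(gm.calls, positions=sites["pos"], samples=gm.samples)
        mask2 = RegionMask({"chr1": np.array([[0, 100_000]])})
        s2 = dv.group_summary(gm2, mask2, np.arange(8))
        assert s1.pi == pytest.approx(s2.pi)
        assert s1.theta_w == pytest.approx(s2.theta_w)
        assert s1.S == s2.S


class TestMafSpectrum:
    def test_single_site_at_half(self):
        gm = make_gm([[A, A, R, R]])
        _, props = dv.maf_spectrum(gm, bins=5)
        assert props[-1] == 1.0

    def test_normalized(self):
        rng = np.random.default_rng(4)
        gm = make_gm(rng.choice([R, A], size=(100, 10)))
        _, props = dv.maf_spectrum(gm)
        assert props.sum() == pytest.approx(1.0)

    def test_growth_skews_spectrum_low(self):
        from popgen.synthetic_data import DemographyConfig, PopulationConfig

        grown = DemographyConfig(
            populations=[PopulationConfig("p", 20, [(0, 100_000), (2_000, 5_000)])],
            n_loci=80,
        )
        const = sd.single_population_config(20_000, 20, n_loci=80)
        gm_g, _ = sd.simulate(grown, seed=31)
        gm_c, _ = sd.simulate(const, seed=31)
        _, pg = dv.maf_spectrum(gm_g, bins=5)
        _, pc = dv.maf_spectrum(gm_c, bins=5)
        assert pg[0] > pc[0]


def test_bottleneck_reduces_diversity_vs_source(qingke_dataset, group_indices):
    gm, truth = qingke_dataset
    idx = group_indices(gm, truth)
    mask = full_mask(truth.config.n_loci, truth.config.locus_length)
    pi_q = dv.group_summary(gm, mask, idx["qingke"]).pi
    pi_e = dv.group_summary(gm, mask, idx["eastern"]).pi
    assert pi_q < pi_e
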