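"""Simulation engine: coalescent expectations, label consistency,
ascertainment and error models."""

import numpy as np
import pytest
from scipy import stats

from tmrcanet.simulate import (
    DEFAULT_ARRAY_SPECTRUM,
    DemographicModel,
    EmptyRegionError,
    GeneticMap,
    HaplotypePanel,
    SimulationConfig,
    ascertain_array,
    inject_errors,
    simulate_dataset,
    simulate_pairwise_tmrcas,
)

NE = 10_000
MU = 1.65e-8


def constant_config(**kw):
    base = dict(
        demographic_model=DemographicModel.constant(NE),
        n_haplotypes=20,
        region_length=1_000_000,
        mutation_rate=MU,
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_demography_rejects_bad_epochs(self):
        with pytest.raises(ValueError):
            DemographicModel(epochs=((1.0, 100.0),))  # must start at 0
        with pytest.raises(ValueError):
            DemographicModel(epochs=((0.0, 100.0), (0.0, 50.0)))
        with pytest.raises(ValueError):
            DemographicModel(epochs=((0.0, -5.0),))

    def test_beta_alpha_outside_range_rejected(self):
        for alpha in (0.9, 1.0, 2.5):
            with pytest.raises(ValueError):
                constant_config(beta_alpha=alpha)

    def test_odd_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            constant_config(n_haplotypes=7)

    def test_genetic_map_invariants(self):
        with pytest.raises(ValueError):
            GeneticMap(positions=[0, 0], map_cM=[0, 1])
        with pytest.raises(ValueError):
            GeneticMap(positions=[0, 10], map_cM=[1, 0])


@pytest.fixture(scope="module")
def replicates():
    out = []
    for rep in range(20):
        panel, labels = simulate_dataset(constant_config(seed=200 + rep))
        out.append((panel, labels))
    return out


@pytest.fixture(scope="module")
def panel():
    panel, _ = simulate_dataset(constant_config(seed=30, region_length=2_000_000))
    return panel


class TestCoalescentExpectations:
    """Monte-Carlo checks against closed-form constant-Ne expectations."""

    def test_pairwise_diversity_matches_4_ne_mu(self, replicates):
        # E[pi] = 4*Ne*mu per bp under the Kingman coalescent
        pis = []
        for panel, _ in replicates:
            dc = panel.derived_counts
            n = panel.n_haplotypes
            pi = (2 * dc * (n - dc) / (n * (n - 1))).sum() / 1_000_000
            pis.append(pi)
        expected = 4 * NE * MU
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - expected) < 4 * se + 0.05 * expected

    def test_mean_pairwise_tmrca_is_2_ne(self, replicates):
        means = []
        for _, labels in replicates:
            m = labels.mean_tmrca_matrix()
            means.append(m[np.triu_indices(m.shape[0], 1)].mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 2 * NE) < 4 * se + 0.05 * 2 * NE

    def test_watterson_segregating_sites(self, replicates):
        # E[S] = theta * L * a_{n-1}
        n = 20
        a = sum(1 / i for i in range(1, n))
        expected = 4 * NE * MU * 1_000_000 * a
        counts = [panel.n_sites for panel, _ in replicates]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se + 0.05 * expected


class TestLabels:
    def test_no_recombination_single_segment(self):
        panel, labels = simulate_dataset(
            constant_config(recombination_rate=0.0, region_length=100_000)
        )
        for pair in [(0, 1), (3, 10)]:
            segs = labels.segments(pair)
            assert len(segs) == 1
            assert segs[0][0] == 0 and segs[0][1] == panel.n_sites
            assert labels.breakpoint_sites(pair).size == 0

    def test_segments_tile_sites_and_match_genealogy(self):
        panel, labels = simulate_dataset(constant_config(seed=5, region_length=300_000))
        ts = labels.ts
        for pair in [(0, 1), (2, 17)]:
            segs = labels.segments(pair)
            assert segs[0][0] == 0 and segs[-1][1] == panel.n_sites
            for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
                assert b0 == a1
            # exact check against the simulator's local trees
            site_t = labels.site_tmrca(pair)
            u, v = labels.sample_nodes[pair[0]], labels.sample_nodes[pair[1]]
            for tree in ts.trees():
                lo = np.searchsorted(panel.positions, tree.interval.left)
                hi = np.searchsorted(panel.positions, tree.interval.right)
                if hi > lo:
                    assert np.all(site_t[lo:hi] == tree.tmrca(u, v))

    def test_breakpoint_indicator_convention(self):
        panel, labels = simulate_dataset(constant_config(seed=6, region_length=300_000))
        pair = (0, 1)
        ind = labels.breakpoint_indicator(pair)
        t = labels.site_tmrca(pair)
        assert ind[0] == 0
        np.testing.assert_array_equal(ind[1:], (t[1:] != t[:-1]).astype(np.uint8))

    def test_determinism(self):
        cfg = constant_config(seed=77, region_length=200_000)
        p1, l1 = simulate_dataset(cfg)
        p2, l2 = simulate_dataset(cfg)
        assert p1 == p2
        np.testing.assert_array_equal(l1.site_tmrca((0, 1)), l2.site_tmrca((0, 1)))
        np.testing.assert_array_equal(l1.mutation_times, l2.mutation_times)

    def test_empty_region_signal(self):
        with pytest.raises(EmptyRegionError):
            simulate_dataset(constant_config(region_length=50, mutation_rate=1e-12))


class TestInjectErrors:
    def test_zero_rates_identity(self):
        panel, _ = simulate_dataset(constant_config(seed=8, region_length=100_000))
        assert inject_errors(panel, 0.0, 0.0, seed=1) == panel

    def test_full_genotyping_rate_flips_everything(self):
        panel = HaplotypePanel(
            alleles=np.array([[0], [1], [1], [0]]), positions=[10.0], map_cM=[0.0]
        )
        out = inject_errors(panel, 0.0, 1.0, seed=3)
        np.testing.assert_array_equal(out.alleles, 1 - panel.alleles)

    def test_genotyping_rate_binomial(self):
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(100, 1000)).astype(np.uint8)
        panel = HaplotypePanel(alleles, np.arange(1000, dtype=float), np.zeros(1000))
        out = inject_errors(panel, 0.0, 0.01, seed=9)
        flipped = (out.alleles != panel.alleles).mean()
        sd = np.sqrt(0.01 * 0.99 / alleles.size)
        assert abs(flipped - 0.01) < 3 * sd

    def test_switch_error_swaps_from_het_site_onward(self):
        # one diploid, alleles differ at every site: a switch at the first
        # het site with rate 1 swaps, the next het site swaps back, etc.
        a = np.array([[0, 0, 0, 0], [1, 1, 1, 1]], dtype=np.uint8)
        panel = HaplotypePanel(a, np.arange(4, dtype=float), np.zeros(4))
        out = inject_errors(panel, 1.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.alleles[0], [1, 0, 1, 0])
        np.testing.assert_array_equal(out.alleles[1], [0, 1, 0, 1])

    def test_switch_requires_paired_haplotypes(self):
        panel = HaplotypePanel(
            alleles=np.zeros((3, 2), dtype=np.uint8),
            positions=[1.0, 2.0],
            map_cM=[0.0, 0.0],
        )
        with pytest.raises(ValueError):
            inject_errors(panel, 0.1, 0.0, seed=0)

    def test_labels_untouched_by_error_injection(self):
        clean = constant_config(seed=12, region_length=200_000)
        noisy = constant_config(
            seed=12, region_length=200_000, switch_error_rate=0.01, genotyping_error_rate=0.01
        )
        p_clean, l_clean = simulate_dataset(clean)
        p_noisy, l_noisy = simulate_dataset(noisy)
        assert p_clean != p_noisy
        np.testing.assert_array_equal(
            l_clean.site_tmrca((0, 1)), l_noisy.site_tmrca((0, 1))
        )


class TestArrayAscertainment:
    def test_density_halving_halves_site_count(self, panel):
        total_cm = panel.map_cM[-1] - panel.map_cM[0]
        density = panel.n_sites / total_cm / 2
        out = ascertain_array(panel, target_density=density, seed=1)
        assert abs(out.n_sites - panel.n_sites / 2) <= 10  # rounding + feasibility

    def test_single_bin_mass_confines_output_mafs(self, panel):
        spectrum = np.zeros(10)
        spectrum[5] = 1.0  # MAF in (0.25, 0.30]
        out = ascertain_array(panel, target_spectrum=spectrum, target_density=5.0, seed=2)
        maf = out.maf
        assert np.all((maf > 0.25) & (maf <= 0.30))

    def test_mass_on_empty_bin_warns_and_renormalizes(self):
        # panel whose sites all sit at MAF 0.5: mass on the rare bin is
        # infeasible and must be redistributed with a warning
        alleles = np.tile(np.array([[0], [0], [1], [1]], dtype=np.uint8), (1, 40))
        panel = HaplotypePanel(alleles, np.arange(40, dtype=float), np.arange(40) * 1e-3)
        spectrum = np.zeros(10)
        spectrum[0] = 0.5
        spectrum[9] = 0.5
        with pytest.warns(UserWarning, match="empty MAF bins"):
            out = ascertain_array(panel, target_spectrum=spectrum, seed=2)
        assert out.n_sites == 40  # everything feasible lives in the top bin

    def test_order_preserved_and_subset(self, panel):
        out = ascertain_array(panel, target_density=20.0, seed=3)
        assert np.all(np.diff(out.positions) > 0)
        assert np.isin(out.positions, panel.positions).all()

    def test_default_spectrum_normalized(self):
        assert np.isclose(DEFAULT_ARRAY_SPECTRUM.sum(), 1.0)

    def test_array_modality_end_to_end(self):
        cfg = constant_config(seed=31, modality="array", array_density=30.0)
        panel, labels = simulate_dataset(cfg)
        assert panel.n_sites == labels.n_sites
        assert panel.n_sites > 0


class TestModelExtensions:
    def test_ncgc_zero_rate_matches_plain_config(self):
        a = constant_config(seed=40, region_length=200_000)
        b = constant_config(seed=40, region_length=200_000, ncgc_rate=0.0)
        pa, _ = simulate_dataset(a)
        pb, _ = simulate_dataset(b)
        assert pa == pb

    def test_ncgc_adds_discordance_in_recent_segments(self):
        # NCGC tracts import alleles into regions of recent shared ancestry,
        # so discordant sites inside young true-TMRCA segments become more
        # common than under crossover-only simulation
        def young_discordance(ncgc_rate, reps=20):
            counts = []
            for rep in range(reps):
                cfg = constant_config(
                    seed=500 + rep,
                    region_length=500_000,
                    n_haplotypes=10,
                    ncgc_rate=ncgc_rate,
                    ncgc_tract_length=300.0,
                )
                panel, labels = simulate_dataset(cfg)
                c = 0
                for i in range(panel.n_haplotypes):
                    for j in range(i + 1, panel.n_haplotypes):
                        t = labels.site_tmrca((i, j))
                        xor = panel.alleles[i] ^ panel.alleles[j]
                        c += int(((t < 100) & (xor == 1)).sum())
                counts.append(c)
            return np.mean(counts)

        assert young_discordance(4e-8) > young_discordance(0.0)

    def test_beta_coalescent_compresses_recent_times(self):
        def frac_recent(alpha):
            vals = [
                simulate_pairwise_tmrcas(
                    constant_config(
                        seed=60 + r,
                        n_haplotypes=30,
                        region_length=1000,
                        recombination_rate=0.0,
                        beta_alpha=alpha,
                    )
                )
                for r in range(3)
            ]
            v = np.concatenate(vals)
            q05 = -2 * NE * np.log(0.95)  # Kingman 5th percentile
            return (v < q05).mean()

        assert frac_recent(1.2) > frac_recent(1.9)


class TestSequencingAscertainment:
    def test_reference_panel_polymorphism_filter(self):
        # a small reference subset discards sites private to the extras
        cfg = constant_config(
            seed=70, region_length=200_000, polymorphism_reference_size=10
        )
        panel, _ = simulate_dataset(cfg)
        dc = panel.derived_counts
        assert np.all((dc > 0) & (dc < panel.n_haplotypes))
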