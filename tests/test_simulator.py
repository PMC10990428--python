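import numpy as np
import pytest

from divland.demography import SpeciesTree
from divland.landscapes import WindowGrid
from divland.mutation_maps import build_map, overlay_mutations
from divland.correlation import spearman
from divland.simulator import (
    DFEConfig,
    RecombinationMap,
    SimulationConfig,
    rescale,
    simulate_forward,
    simulate_neutral_windows,
)


def single_pop_tree(ne=100, samples=5):
    return SpeciesTree({"A": (None, 0, ne, samples)})


def two_pop_tree(ne=100, ne_anc=200, T=400, samples=4):
    return SpeciesTree(
        {
            "anc": (None, 0, ne_anc, None),
            "A": ("anc", T, ne, samples),
            "B": ("anc", T, ne, samples),
        }
    )


class TestRecombinationMap:
    def test_tiling_enforced(self):
        with pytest.raises(ValueError):
            RecombinationMap([0, 200], [100, 300], [1e-8, 1e-8])

    def test_window_morgans_and_sampling(self):
        m = RecombinationMap([0, 100], [100, 200], [1e-4, 3e-4])
        grid = WindowGrid("c", 200, 100)
        np.testing.assert_allclose(m.window_morgans(grid), [1e-2, 3e-2])
        rng = np.random.default_rng(0)
        pos = m.sample_positions(rng, 4000)
        # three quarters of crossovers land in the high-rate half
        assert (pos >= 100).mean() == pytest.approx(0.75, abs=0.03)

    def test_tsv_roundtrip(self, tmp_path):
        m = RecombinationMap([0, 100], [100, 250], [1e-8, 5e-8])
        p = str(tmp_path / "m.tsv")
        m.to_tsv(p)
        back = RecombinationMap.from_tsv(p)
        np.testing.assert_allclose(back.rates, m.rates)


class TestRescale:
    def _cfg(self, ne=10_000):
        tree = single_pop_tree(ne=ne, samples=2)
        grid = WindowGrid("c", 10_000, 10_000)
        return SimulationConfig(tree=tree, grid=grid, mu=2e-8, recomb_map=RecombinationMap.uniform(10_000, 1e-8))

    def test_identity(self):
        cfg = self._cfg()
        out = rescale(cfg, 1)
        assert out.mu == cfg.mu and out.Q == 1
        assert out.tree.ne("A") == cfg.tree.ne("A")

    def test_compound_parameters_preserved(self):
        cfg = self._cfg()
        out = rescale(cfg, 50)
        assert out.tree.ne("A") == 200
        assert out.mu == pytest.approx(1e-6)
        assert out.recomb_map.rates[0] == pytest.approx(5e-7)
        assert 4 * out.tree.ne("A") * out.mu == pytest.approx(4 * 10_000 * 2e-8)
        assert out.Q == 50

    def test_too_large_q_rejected(self):
        with pytest.raises(ValueError):
            rescale(self._cfg(ne=80), 50)


class TestForward:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(
            tree=two_pop_tree(), grid=WindowGrid("c", 20_000, 10_000), mu=1e-6,
            recomb_map=RecombinationMap.uniform(20_000, 1e-7), seed=4,
        )
        r1, r2 = simulate_forward(cfg), simulate_forward(cfg)
        for k in r1.landscapes:
            np.testing.assert_array_equal(r1.landscapes[k].values, r2.landscapes[k].values)
        assert r1.fixations == r2.fixations
        r3 = simulate_forward(cfg, seed=5)
        assert any(
            not np.array_equal(r1.landscapes[k].values, r3.landscapes[k].values) for k in r1.landscapes
        )

    def test_neutral_diversity_calibration(self):
        """Single population at stationarity: mean pi within 3 SE of 4 Ne mu."""
        ne, mu = 100, 1e-6
        grid = WindowGrid("c", 30_000, 10_000)
        means = []
        for seed in range(8):
            cfg = SimulationConfig(
                tree=single_pop_tree(ne=ne), grid=grid, mu=mu,
                recomb_map=RecombinationMap.uniform(30_000, 2e-6), seed=100 + seed,
            )
            means.append(simulate_forward(cfg).pi("A").values.mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert means.mean() == pytest.approx(4 * ne * mu, abs=3 * se)

    def test_background_selection_reduces_diversity(self):
        """Fully deleterious exonic mutations with 4N|s| >> 1 and no
        recombination depress pi below the matched neutral run."""
        ne = 100
        grid = WindowGrid("c", 20_000, 20_000)
        exons = np.array([[0, 20_000]])
        sel_pi, neu_pi = [], []
        for seed in range(5):
            common = dict(
                tree=single_pop_tree(ne=ne), grid=grid, mu=2e-6,
                recomb_map=RecombinationMap.uniform(20_000, 0.0),
            )
            dfe = DFEConfig(frac_deleterious=1.0, gamma_shape=4.0, mean_s_del=-0.05)
            sel = simulate_forward(SimulationConfig(exons=exons, dfe=dfe, **common), seed=200 + seed)
            neu = simulate_forward(SimulationConfig(**common), seed=200 + seed)
            sel_pi.append(sel.pi("A").values.mean())
            neu_pi.append(neu.pi("A").values.mean())
        assert np.mean(sel_pi) < np.mean(neu_pi)

    def test_fixations_recorded_with_classes(self):
        grid = WindowGrid("c", 10_000, 10_000)
        dfe = DFEConfig(frac_beneficial=0.3, mean_s_ben=0.05)
        cfg = SimulationConfig(
            tree=single_pop_tree(ne=50), grid=grid, mu=5e-6, exons=np.array([[0, 10_000]]),
            dfe=dfe, recomb_map=RecombinationMap.uniform(10_000, 0.0), seed=8,
        )
        res = simulate_forward(cfg)
        classes = {f.mutation_class for f in res.fixations}
        assert "neutral" in classes and "beneficial" in classes
        for f in res.fixations:
            assert 0 <= f.position < 10_000
            assert (f.s == 0) == (f.mutation_class == "neutral")


class TestNeutralMode:
    def test_single_population_mean_tmrca(self):
        ne = 5_000
        tree = single_pop_tree(ne=ne, samples=5)
        grid = WindowGrid("c", 200 * 10_000, 10_000)
        res = simulate_neutral_windows(tree, grid, RecombinationMap.uniform(grid.length, 0.0), seed=21)
        t = res.coal_times["pi:A"].to_numpy()
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert t.mean() == pytest.approx(2 * ne, abs=3 * se)

    def test_two_tips_cross_coalescence(self):
        # tiny within-branch Ne: cross-pair coalescence ~ T + 2 Ne_anc
        T, ne_anc = 50_000, 2_000
        tree = two_pop_tree(ne=100, ne_anc=ne_anc, T=T, samples=3)
        grid = WindowGrid("c", 200 * 10_000, 10_000)
        res = simulate_neutral_windows(tree, grid, RecombinationMap.uniform(grid.length, 0.0), seed=22)
        t = res.coal_times["dxy:A|B"].to_numpy()
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert t.mean() == pytest.approx(T + 2 * ne_anc, abs=3 * se)

    def test_more_loci_reduce_window_variance(self):
        tree = single_pop_tree(ne=2_000, samples=4)
        grid = WindowGrid("c", 100 * 1_000_000, 1_000_000)
        r1 = simulate_neutral_windows(tree, grid, RecombinationMap.uniform(grid.length, 0.0), seed=23)
        r20 = simulate_neutral_windows(tree, grid, RecombinationMap.uniform(grid.length, 2e-8), seed=23)
        v1 = r1.coal_times["pi:A"].var(ddof=1)
        v20 = r20.coal_times["pi:A"].var(ddof=1)
        assert v1 > 2 * v20

    def test_deterministic_under_seed(self):
        tree = two_pop_tree(samples=2)
        grid = WindowGrid("c", 10 * 10_000, 10_000)
        a = simulate_neutral_windows(tree, grid, seed=24).coal_times
        b = simulate_neutral_windows(tree, grid, seed=24).coal_times
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_zero_samples_rejected(self):
        tree = single_pop_tree(samples=2)
        grid = WindowGrid("c", 10_000, 10_000)
        with pytest.raises(ValueError):
            simulate_neutral_windows(tree, grid, samples={"A": 0}, seed=1)

    def test_ils_sharing_decays_with_split_time(self):
        """Sister tips that split recently (high probability of ancestral
        coalescence sharing) have more correlated pi landscapes than
        anciently diverged tips."""
        ne = 5_000
        tree = SpeciesTree(
            {
                "root": (None, 0, ne, None),
                "AB": ("root", 98_000, ne, None),
                "A": ("AB", 2_000, ne, 3),
                "B": ("AB", 2_000, ne, 3),
                "C": ("root", 100_000, ne, 3),
            }
        )
        grid = WindowGrid("c", 150 * 100_000, 100_000)
        res = simulate_neutral_windows(tree, grid, RecombinationMap.uniform(grid.length, 0.0), seed=25)
        lands = overlay_mutations(res.coal_times, build_map(grid, 2e-8, 0.0), seed=26)
        rho_sisters = spearman(lands["pi:A"].values, lands["pi:B"].values)
        rho_distant = spearman(lands["pi:A"].values, lands["pi:C"].values)
        assert rho_sisters > rho_distant
        assert rho_sisters > 0.3
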