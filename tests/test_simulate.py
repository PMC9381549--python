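import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ecoassembly import (
    EstuaryConfig,
    ScenarioConfig,
    evolve_niche_traits,
    parse_tree,
    plant_cooccurrence,
    simulate_dispersal_limited,
    simulate_estuary_dataset,
    simulate_neutral_communities,
    simulate_scenario,
    simulate_selection_communities,
    simulate_tree,
    to_relative_abundance,
    bray_curtis,
)


class TestSimulateTree:
    def test_tip_count_and_names_unique(self):
        tree = simulate_tree(4, seed=0)
        names = [t.name for t in tree.tips()]
        assert len(names) == 4 and len(set(names)) == 4

    def test_deterministic_newick(self):
        a = str(simulate_tree(10, seed=3))
        b = str(simulate_tree(10, seed=3))
        c = str(simulate_tree(10, seed=4))
        assert a == b
        assert a != c

    def test_ultrametric_unit_height(self):
        tree = simulate_tree(25, seed=1)
        depths = [tree.distance(t) for t in tree.tips()]
        assert np.allclose(depths, 1.0, atol=1e-9)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestNicheTraits:
    def test_zero_rate_returns_root_value(self):
        tree = simulate_tree(6, seed=0)
        traits = evolve_niche_traits(tree, sigma_bm=0.0, root_value=17.0, seed=1)
        assert np.allclose(traits, 17.0)

    def test_brownian_variance_on_two_tip_tree(self):
        # closed form: Var(tip) = sigma^2 * depth; depth = 0.5 on this tree
        tree = parse_tree("(A:0.5,B:0.5);")
        sigma = 1.5
        tips = np.array(
            [evolve_niche_traits(tree, sigma, 0.0, seed=s)["A"] for s in range(1500)]
        )
        expect = sigma**2 * 0.5
        assert tips.var() == pytest.approx(expect, rel=0.12)

    def test_trait_distance_tracks_patristic_distance(self):
        # Brownian similarity decays with phylogenetic distance
        rhos = []
        for seed in range(15):
            tree = simulate_tree(20, seed=seed)
            traits = evolve_niche_traits(tree, 1.0, seed=seed + 100)
            pat = tree.tip_tip_distances()
            ii, jj = np.triu_indices(20, k=1)
            tdist = np.abs(
                traits.reindex(pat.ids).to_numpy()[ii] - traits.reindex(pat.ids).to_numpy()[jj]
            )
            rhos.append(spearmanr(tdist, pat.data[ii, jj]).statistic)
        assert np.mean(rhos) > 0


class TestSelectionCommunities:
    def test_infinite_breadth_recovers_metacommunity(self):
        tree = simulate_tree(30, seed=0)
        traits = evolve_niche_traits(tree, 1.0, seed=1)
        base = np.random.default_rng(2).lognormal(0, 1, 30)
        table = simulate_selection_communities(
            tree, traits, [0.0], sigma_f=1e6, depth=2_000_000, seed=3, base_abundances=base
        )
        p = table.data.to_numpy()[0] / 2_000_000
        assert np.abs(p - base / base.sum()).max() < 1e-3

    def test_extreme_environment_dominated_by_nearest_taxon(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        traits = pd.Series({"A": 0.0, "B": 1.0, "C": 2.0, "D": 10.0})
        table = simulate_selection_communities(
            tree, traits, [100.0], sigma_f=0.05, depth=5000, seed=0,
            base_abundances=np.ones(4),
        )
        rel = table.data.to_numpy()[0] / 5000
        assert rel[list(table.taxon_ids).index("D")] > 0.99

    def test_deterministic(self):
        tree = simulate_tree(12, seed=0)
        traits = evolve_niche_traits(tree, 1.0, seed=1)
        a = simulate_selection_communities(tree, traits, [0.0, 0.5], 0.5, 500, seed=9)
        b = simulate_selection_communities(tree, traits, [0.0, 0.5], 0.5, 500, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_invalid_breadth(self):
        tree = simulate_tree(4, seed=0)
        traits = evolve_niche_traits(tree, 1.0, seed=1)
        with pytest.raises(ValueError):
            simulate_selection_communities(tree, traits, [0.0], sigma_f=0.0, depth=10)


class TestNeutralCommunities:
    def test_mean_proportions_match_metacommunity(self):
        tree = simulate_tree(20, seed=4)
        table = simulate_neutral_communities(tree, 200, 1000, seed=5)
        # all samples share exact proportions; recover them from the totals
        p_hat = table.data.sum(axis=0) / table.data.to_numpy().sum()
        rel = table.data.to_numpy() / 1000
        se = np.sqrt(p_hat * (1 - p_hat) / 1000 / 200)
        assert (np.abs(rel.mean(axis=0) - p_hat) < 3 * se + 1e-6).all()

    def test_high_depth_bray_curtis_vanishes(self):
        tree = simulate_tree(15, seed=6)
        table = simulate_neutral_communities(tree, 2, 1_000_000, seed=7)
        bc = bray_curtis(to_relative_abundance(table))
        assert bc.data[0, 1] < 0.01

    def test_deterministic(self):
        tree = simulate_tree(8, seed=8)
        a = simulate_neutral_communities(tree, 3, 100, seed=1)
        b = simulate_neutral_communities(tree, 3, 100, seed=1)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestDispersalLimited:
    def test_richness_bounded_by_founders(self):
        tree = simulate_tree(50, seed=0)
        table = simulate_dispersal_limited(tree, 10, founders=5, depth=1000, seed=1)
        assert ((table.data > 0).sum(axis=1) <= 5).all()

    def test_too_many_founders_rejected(self):
        tree = simulate_tree(10, seed=0)
        with pytest.raises(ValueError):
            simulate_dispersal_limited(tree, 2, founders=10, depth=100)

    def test_shared_founder_count_matches_hypergeometric_mean(self):
        n_taxa, founders = 60, 12
        tree = simulate_tree(n_taxa, seed=2)
        table = simulate_dispersal_limited(tree, 400, founders, depth=10_000, seed=3)
        present = table.data.to_numpy() > 0
        shared = [
            (present[2 * i] & present[2 * i + 1]).sum() for i in range(200)
        ]
        expect = founders**2 / n_taxa
        assert np.mean(shared) == pytest.approx(expect, rel=0.10)


class TestPlantCooccurrence:
    def test_zero_strength_is_identity(self, toy_counts):
        out = plant_cooccurrence(toy_counts, {"A": "g"}, 0.0, seed=0)
        pd.testing.assert_frame_equal(out.data, toy_counts.data)

    def test_depth_preserved(self):
        tree = simulate_tree(20, seed=0)
        table = simulate_neutral_communities(tree, 10, 777, seed=1)
        groups = {t.name: "g" for t in list(tree.tips())[:6]}
        out = plant_cooccurrence(table, groups, 0.8, seed=2)
        assert (out.sample_totals() == 777).all()

    def test_same_group_taxa_positively_correlated(self):
        tree = simulate_tree(30, seed=3)
        table = simulate_neutral_communities(tree, 100, 3000, seed=4)
        tips = [t.name for t in tree.tips()]
        groups = {tips[0]: "g", tips[1]: "g"}
        out = plant_cooccurrence(table, groups, 1.0, seed=5)
        rel = out.data.div(out.data.sum(axis=1), axis=0)
        r = np.corrcoef(rel[tips[0]], rel[tips[1]])[0, 1]
        assert r > 0.3

    def test_antagonistic_groups_negatively_correlated(self):
        tree = simulate_tree(30, seed=6)
        table = simulate_neutral_communities(tree, 100, 3000, seed=7)
        tips = [t.name for t in tree.tips()]
        groups = {tips[0]: "g1", tips[1]: "g2"}
        out = plant_cooccurrence(table, groups, 1.0, seed=8, antagonistic_groups=("g2",))
        rel = out.data.div(out.data.sum(axis=1), axis=0)
        r = np.corrcoef(rel[tips[0]], rel[tips[1]])[0, 1]
        assert r < -0.3

    def test_invalid_strength_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            plant_cooccurrence(toy_counts, {}, 1.5, seed=0)


class TestScenarios:
    def test_pure_functions_of_seed(self):
        cfg = ScenarioConfig(n_taxa=30, n_samples=5, depth=300, seed=11)
        t1, tr1, _ = simulate_scenario(cfg)
        t2, tr2, _ = simulate_scenario(cfg)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert str(tr1) == str(tr2)

    def test_selection_lowers_beta_mntd_relative_to_neutral(self):
        from ecoassembly import beta_mntd

        # drift-only turnover (no local extinction) so the two scenarios put
        # comparable abundance mass on unshared taxa and the comparison
        # isolates phylogenetic clustering rather than richness differences
        common = dict(n_taxa=80, n_samples=8, depth=1500, seed=2,
                      extinction_prob=0.0, drift_sdlog=1.0)
        sel_cfg = ScenarioConfig(process="homogeneous_selection", **common)
        neu_cfg = ScenarioConfig(process="neutral", **common)
        sel_tab, sel_tree, _ = simulate_scenario(sel_cfg)
        neu_tab, neu_tree, _ = simulate_scenario(neu_cfg)
        sel_bm = beta_mntd(to_relative_abundance(sel_tab), sel_tree)
        neu_bm = beta_mntd(to_relative_abundance(neu_tab), neu_tree)
        n = sel_bm.shape[0]
        iu = np.triu_indices(n, k=1)
        assert sel_bm.data[iu].mean() < neu_bm.data[iu].mean()

    def test_invalid_process_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(process="magic")


class TestEstuaryDataset:
    @pytest.fixture(scope="class")
    def small_estuary(self):
        return simulate_estuary_dataset(EstuaryConfig(n_taxa=80, depth=1500, seed=0))

    def test_design_counts(self, small_estuary):
        md = small_estuary.metadata
        assert len(md) == 90
        assert md["fraction"].value_counts().to_dict() == {"FL": 45, "PA": 45}
        assert md["station"].nunique() == 9
        assert md["date"].nunique() == 5

    def test_nutrients_follow_dilution_line(self, small_estuary):
        md = small_estuary.metadata
        assert spearmanr(md["DIN"], md["salinity"]).statistic < -0.9
        assert spearmanr(md["silicate"], md["salinity"]).statistic < -0.9

    def test_skew_increases_flpa_dissimilarity(self):
        means = {}
        for skew in (0.0, 2.0):
            ds = simulate_estuary_dataset(
                EstuaryConfig(n_taxa=60, depth=1200, pa_skew=skew, lambda_strength=0.0, seed=1)
            )
            rel = to_relative_abundance(ds.table)
            bc = bray_curtis(rel)
            md = ds.metadata
            vals = []
            for (st, dt), sub in md.groupby(["station", "date"]):
                fl = sub.index[sub.fraction == "FL"][0]
                pa = sub.index[sub.fraction == "PA"][0]
                vals.append(bc[fl, pa])
            means[skew] = np.mean(vals)
        assert means[2.0] > means[0.0]

    def test_provenance_records_parameters(self, small_estuary):
        prov = small_estuary.provenance
        assert prov["n_taxa"] == 80
        assert prov["design"].startswith("9 stations")
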