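"""Synthetic scenario generators: trees, planted regimes, richness, ranges."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from divarrest import synthetic_data as syn
from divarrest.dispersion import mpd, patristic_distance_matrix
from divarrest.errors import ConfigurationError
from divarrest.treeio import leaf_depths


def small_config(**kw):
    defaults = dict(n_families=30, n_trees=8, seed=1)
    defaults.update(kw)
    return syn.ScenarioConfig(**defaults)


class TestScenarioConfig:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            syn.ScenarioConfig(n_families=5)
        with pytest.raises(ConfigurationError):
            syn.ScenarioConfig(low_rate_fraction=1.5)
        with pytest.raises(ConfigurationError):
            syn.ScenarioConfig(regime="bogus")

    def test_yaml_roundtrip(self, tmp_path):
        cfg = small_config(regime="planted_clustered", age_jitter=0.07)
        cfg.to_yaml(tmp_path / "s.yaml")
        assert syn.ScenarioConfig.from_yaml(tmp_path / "s.yaml") == cfg


class TestGenerateTreeSet:
    def test_no_jitter_gives_identical_trees(self):
        ts = syn.generate_tree_set(small_config(age_jitter=0.0))
        ref = leaf_depths(ts[0])
        for tree in ts:
            d = leaf_depths(tree)
            assert d == pytest.approx(ref)

    def test_all_trees_ultrametric_and_share_tips(self):
        ts = syn.generate_tree_set(small_config())
        ts.validate()
        for tree in ts:
            depths = np.array(list(leaf_depths(tree).values()))
            assert (depths.max() - depths.min()) / depths.max() < 1e-9

    def test_stem_ages_right_skewed_across_trees(self):
        cfg = small_config(n_trees=150, age_jitter=0.2)
        ts = syn.generate_tree_set(cfg)
        from divarrest.treeio import summarize_ages
        ages = summarize_ages(ts).ages
        skews = [skew(ages[f]) for f in ages.columns]
        assert np.mean(skews) > 0.1

    def test_stem_ages_bounded_away_from_zero(self):
        """Family-level pendant edges are deep splits, not twigs."""
        ts = syn.generate_tree_set(small_config(age_jitter=0.0))
        pendants = [lf.edge.length for lf in ts[0].leaf_node_iter()]
        assert min(pendants) > 0.05 * small_config().tree_depth

    def test_determinism(self):
        a = syn.generate_tree_set(small_config())
        b = syn.generate_tree_set(small_config())
        assert a[3].as_string(schema="newick") == b[3].as_string(schema="newick")


class TestPlantRegime:
    def _planted_mpd(self, regime, seed=1):
        cfg = small_config(n_families=60, n_trees=3, regime=regime, seed=seed)
        ts = syn.generate_tree_set(cfg)
        arrested = syn.select_arrested(cfg, ts.families)
        ts = syn.plant_regime(ts, arrested, regime, seed=cfg.seed)
        out = []
        for tree in ts:
            labels, D = patristic_distance_matrix(tree)
            idx = [labels.index(f) for f in arrested]
            rng = np.random.default_rng(0)
            random_mpds = [mpd(D, rng.choice(60, len(idx), replace=False))
                           for _ in range(100)]
            out.append((mpd(D, idx), random_mpds))
        return out

    def test_clustered_below_every_random_placement(self):
        for obs, random_mpds in self._planted_mpd("planted_clustered"):
            assert obs < min(random_mpds)

    def test_overdispersed_above_975th_percentile(self):
        for obs, random_mpds in self._planted_mpd("planted_overdispersed"):
            assert obs > np.quantile(random_mpds, 0.975)

    def test_random_regime_is_a_permutation(self):
        cfg = small_config(regime="random")
        ts = syn.generate_tree_set(cfg)
        fams_before = set(ts.families)
        arrested = syn.select_arrested(cfg, ts.families)
        ts = syn.plant_regime(ts, arrested, "random", seed=cfg.seed)
        assert set(ts.families) == fams_before

    def test_requires_two_arrested(self):
        ts = syn.generate_tree_set(small_config())
        with pytest.raises(ConfigurationError):
            syn.plant_regime(ts, ["F01"], "random")


class TestGenerateRichness:
    def test_zero_noise_zero_rate_gives_monotypic_arrested(self):
        cfg = small_config(rate_low=1e-9, rate_spread=0.0,
                           richness_dispersion=0.0)
        ts = syn.generate_tree_set(cfg)
        arrested = syn.select_arrested(cfg, ts.families)
        table = syn.generate_richness(cfg, ts, arrested)
        assert (table.n_species[arrested] == 1).all()

    def test_all_richness_at_least_one(self):
        cfg = small_config()
        ts = syn.generate_tree_set(cfg)
        table = syn.generate_richness(cfg, ts)
        assert (table.n_species >= 1).all()

    def test_groups_separate_in_realized_rates(self):
        """High-group realized rates exceed low-group rates for ~all pairs."""
        from divarrest.rates import diversification_rate
        wins = trials = 0
        for seed in range(5):
            cfg = small_config(n_families=60, seed=seed)
            ts = syn.generate_tree_set(cfg)
            arrested = syn.select_arrested(cfg, ts.families)
            table = syn.generate_richness(cfg, ts, arrested)
            r = pd.Series(
                diversification_rate(table.n_species.values,
                                     table.stem_age_summary.values),
                index=table.families)
            low, high = r[arrested], r.drop(arrested)
            wins += (high.values[:, None] > low.values[None, :]).sum()
            trials += high.size * low.size
        assert wins / trials >= 0.99

    def test_richness_spans_orders_of_magnitude(self):
        cfg = small_config(n_families=80)
        ts = syn.generate_tree_set(cfg)
        table = syn.generate_richness(cfg, ts)
        assert table.n_species.max() / table.n_species.min() >= 100


class TestGenerateRanges:
    def _rate_table(self, n=25):
        return pd.DataFrame({
            "family": [f"F{i:02d}" for i in range(n)],
            "quantile": [1 + i % 5 for i in range(n)],
        })

    def test_bounds_respected(self):
        df = syn.generate_ranges(self._rate_table(), "incongruent", seed=4)
        assert (df["lon_min"] >= -180).all() and (df["lon_max"] <= 180).all()
        assert (df["lat_min"] >= -90).all() and (df["lat_max"] <= 90).all()
        assert (df["lon_min"] <= df["lon_max"]).all()

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        rt = self._rate_table()
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        syn.generate_ranges(rt, "congruent", seed=9).to_csv(a, index=False)
        syn.generate_ranges(rt, "congruent", seed=9).to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_congruent_overlap_exceeds_incongruent(self):
        def mean_within_quantile_overlap(df, rt):
            df = df.merge(rt, on="family")
            overlaps = []
            for q, g in df.groupby("quantile"):
                rows = list(g.itertuples(index=False))
                for i, a in enumerate(rows):
                    for b in rows[i + 1:]:
                        w = (min(a.lon_max, b.lon_max)
                             - max(a.lon_min, b.lon_min))
                        h = (min(a.lat_max, b.lat_max)
                             - max(a.lat_min, b.lat_min))
                        overlaps.append(max(w, 0) * max(h, 0))
            return np.mean(overlaps)

        rt = self._rate_table(40)
        con = mean_within_quantile_overlap(
            syn.generate_ranges(rt, "congruent", seed=2), rt)
        inc = mean_within_quantile_overlap(
            syn.generate_ranges(rt, "incongruent", seed=2), rt)
        assert con > inc


class TestScenarioDeterminism:
    def test_generate_scenario_pure_function_of_seed(self):
        a = syn.generate_scenario(small_config(regime="planted_clustered"))
        b = syn.generate_scenario(small_config(regime="planted_clustered"))
        assert a.arrested == b.arrested
        pd.testing.assert_series_equal(a.family_table.n_species,
                                       b.family_table.n_species)
        pd.testing.assert_frame_equal(a.ranges, b.ranges)
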