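# divarrest

Phylogenetic and spatial structure of slowly diversifying ("arrested")
lineages.

Species richness is spread very unevenly across the tree of life. Most
attention goes to the fast radiations; this package implements the mirror
analysis: identifying the clades that diversify *disproportionately slowly*
and asking whether they are phylogenetically clustered or scattered
(overdispersed), and whether they occupy coherent or idiosyncratic
geographic regions.

The pipeline, for a set of dated family-level phylogenies (e.g. a posterior
sample) with per-family species richness:

1. **Rates** — each family *i* gets the stem-age diversification rate
   r_i = ln(N_i) / t_i, with N_i its species richness and t_i its stem age
   in Myr (median across the tree set). Families are ranked and cut into
   five equal-count quantiles; quantile 1 holds the slowest diversifiers.
2. **Dispersion** — on every tree, each quantile's mean pairwise distance
   (MPD: the mean patristic distance over all unordered pairs of its
   families) is compared with a size-preserving permutation null: families
   are reassigned to quantiles at random 1000 times and a 95% envelope is
   taken from the 2.5th/97.5th order statistics. MPD above the envelope =
   overdispersed, below = clustered. A Spearman rank test (permutation
   p-value) summarises the MPD-vs-quantile trend across the whole tree set.
3. **Simulation null** — because "family" is a taxonomic convention, a
   second null grows 1000 pure-birth (Yule) trees of 10,000 tips, declares
   every branch alive at the start of the last fifth of the clade's age a
   family (its descendant tips the richness, its parent node's age the stem
   age), rescales to an empirical clade age, and pushes those families
   through the same rate/quantile/MPD machinery. Under pure birth the
   per-quantile MPD distributions are indistinguishable, so any empirical
   quantile effect is not a by-product of tree geometry.
4. **Maps** — family ranges are rasterized onto the global 1° grid
   (presence = any overlap with a cell's interior) and per-quantile
   richness maps are emitted.
5. **Synthetic data** — a first-class generator produces posterior-like
   jittered tree sets, richness spanning orders of magnitude, *planted*
   phylogenetic regimes (overdispersed / clustered / random placement of
   the low-rate families), and ranges with controllable congruence, so the
   whole pipeline is testable end to end without any downloads.

## Worked example

Recover a planted signal: 100 families on 50 jittered trees, with the 20
low-rate families placed at maximally spread positions.

```python
import divarrest as d
from divarrest.synthetic_data import ScenarioConfig, generate_scenario
from divarrest.rates import make_rate_table

config = ScenarioConfig(n_families=100, n_trees=50,
                        regime="planted_overdispersed", seed=1)
scenario = generate_scenario(config)
rate_table = make_rate_table(scenario.family_table)
print(rate_table.head(5).to_string(index=False))

result = d.dispersion_over_tree_set(scenario.tree_set, rate_table,
                                    n_reps=1000, seed=1)
print(result.flag_rates())
print(result.trend)
```

Output:

```text
family  n_species  stem_age     rate  quantile
  F001         18 61.016895 0.047370         2
  F002         24 61.614256 0.051580         2
  F003       6641 92.507501 0.095138         5
  F004          2 64.293724 0.010781         1
  F005      24191 87.694855 0.115101         5
          overdispersed  clustered
quantile
1                   1.0       0.00
2                   0.0       0.00
3                   0.0       0.00
4                   0.0       0.00
5                   0.0       0.88
{'statistic': -0.4422050219394878, 'p_value': 0.000999000999000999,
 'direction': 'decreasing', 'degenerate': False, 'n_reps': 1000}
```

Reading it: each family's rate is ln(N)/t (F004, with 2 species on a
64-Myr stem, is a slow diversifier in quantile 1). The planted quantile 1
is flagged overdispersed on 100% of the 50 trees; the complementary
crowding of fast diversifiers shows up as clustering in quantile 5; and
MPD falls significantly with increasing rate quantile (Spearman rho =
-0.44, permutation p ≈ 0.001) — the qualitative pattern the method is
designed to detect.

The same run from the shell:

```sh
divarrest run --seed 1 -o out/    # default synthetic scenario, full report
divarrest synth --regime planted_overdispersed -o syn/
divarrest rates --trees syn/trees.nwk --richness syn/families.csv -o rt.csv
divarrest simnull --n-sims 50 --n-tips 2000 -o simnull.csv
```

`divarrest run` writes the rate table, per-tree dispersion results with
null envelopes, the trend JSON, per-quantile richness grids, figures, and
a `MANIFEST.json` recording seed, config hash and warnings.

## Layout

- `src/divarrest/treeio.py` — tree-set I/O, pruning to one tip per family,
  stem ages and their medians
- `src/divarrest/rates.py` — ln(N)/t estimator, equal-count quantiles
- `src/divarrest/dispersion.py` — patristic distances, MPD, permutation
  nulls, trend test
- `src/divarrest/famsim.py` — Yule simulation, tree slicing, the
  simulation null
- `src/divarrest/spatial.py` — presence–absence rasterization, richness
  grids and maps
- `src/divarrest/synthetic_data.py` — scenario generator with planted
  regimes
- `src/divarrest/pipeline.py`, `cli.py` — orchestration and the
  `divarrest` command
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions, limitations
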