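"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator stands in for the empirical ingredients of the analysis —
posterior samples of dated family-level trees, per-family species richness
spanning orders of magnitude, and geographic ranges — while planting a known
truth the dispersion machinery must recover:

* a base family-level Yule tree rescaled to a chosen depth, replicated with
  multiplicative log-normal node-age jitter (right-skewed across replicates,
  as node-age distributions are in real posterior samples);
* a designated "arrested" subset of families given a low target
  diversification rate (the rest a high one), with richness drawn as
  round(exp(r * stem_age) * lognormal noise) and floored at 1 so realized
  ln(N)/t clusters around the targets;
* a placement regime for the arrested families: scattered across the tree
  (``planted_overdispersed``, greedy max-min placement), packed into one
  clade (``planted_clustered``), or uniform (``random``);
* bounding-box ranges whose spatial congruence between quantiles is
  controllable.

All generators are pure functions of (config, seed): named substreams are
spawned from the scenario seed, so regenerating one component never
perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.random import Generator, SeedSequence, default_rng

from .errors import ConfigurationError
from .dispersion import mpd, patristic_distance_matrix
from .famsim import rescale_tree, simulate_pure_birth, slice_families, tree_height
from .treeio import FamilyTable, TreeSet, summarize_ages

log = logging.getLogger(__name__)

REGIMES = ("random", "planted_overdispersed", "planted_clustered")
CONGRUENCE = ("congruent", "incongruent")

# named substreams fanned out from the scenario seed
_STREAMS = {"tree": 0, "jitter": 1, "plant": 2, "richness": 3, "ranges": 4}


def substream(seed: int, name: str) -> Generator:
    """Deterministic named random stream derived from a master seed."""
    return default_rng(SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass
class ScenarioConfig:
    """Knobs of a synthetic scenario; defaults are the reference conditions.

    ``tree_depth`` is the root age of the base family tree in Myr;
    ``age_jitter`` is the log-scale standard deviation of the per-node
    multiplicative age noise; ``richness_dispersion`` the log-scale spread
    of richness noise; ``rate_low``/``rate_high`` are the median target
    stem-age rates (1/Myr) of arrested and ordinary families, and
    ``rate_spread`` the log-scale spread of the per-family target around
    its group median (real clades vary continuously in rate; a single
    shared group rate would make the realized ranking depend only on the
    richness noise and the stem age, which is not how empirical rate
    variation behaves).
    """

    n_families: int = 100
    n_trees: int = 50
    tree_depth: float = 200.0
    birth_rate: float = 1.0
    regime: str = "random"
    low_rate_fraction: float = 0.2
    rate_low: float = 0.005
    rate_high: float = 0.08
    rate_spread: float = 0.3
    richness_dispersion: float = 0.4
    age_jitter: float = 0.1
    topology_noise: int = 0
    spatial_congruence: str = "incongruent"
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 10:
            raise ConfigurationError("n_families must be >= 10")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not (0.0 < self.low_rate_fraction < 1.0):
            raise ConfigurationError("low_rate_fraction must be in (0, 1)")
        if self.regime not in REGIMES:
            raise ConfigurationError(f"regime must be one of {REGIMES}")
        if self.spatial_congruence not in CONGRUENCE:
            raise ConfigurationError(
                f"spatial_congruence must be one of {CONGRUENCE}")
        if not self.rate_low < self.rate_high:
            raise ConfigurationError("rate_low must be < rate_high")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def n_arrested(self) -> int:
        return int(self.low_rate_fraction * self.n_families)


# ---------------------------------------------------------------------------
# Tree sets
# ---------------------------------------------------------------------------


def _node_ages(tree) -> None:
    """Annotate each node with its age before present (tips at 0)."""
    tree.seed_node._depth = 0.0
    depth_max = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node._depth = node.parent_node._depth + (node.edge.length or 0.0)
        if node.is_leaf():
            depth_max = max(depth_max, node._depth)
    for node in tree.preorder_node_iter():
        node._age = 0.0 if node.is_leaf() else depth_max - node._depth


def _ages_to_branch_lengths(tree) -> None:
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node._age - node._age


#: tips in the source species-level tree per family tip of the base tree;
#: slicing a 4x-richer Yule tree where exactly n_families lineages exist
#: puts family stem ages at roughly the last fifth of the clade age, the
#: ratio family-level trees show empirically
_SOURCE_TIP_FACTOR = 4


def _base_family_tree(config: ScenarioConfig, rng: Generator):
    """Family-level base tree: the rootward part of a larger Yule tree.

    Pendant branches of a family-level tree are family *stem* ages —
    splits from sister families, which sit deep in the species tree —
    so the base tree is obtained by slicing a Yule tree of
    ``_SOURCE_TIP_FACTOR * n_families`` tips at the midpoint of the time
    interval in which exactly ``n_families`` lineages existed.  This
    keeps every stem age comfortably away from zero, as in real family
    trees.
    """
    n = config.n_families
    source = simulate_pure_birth(_SOURCE_TIP_FACTOR * n, config.birth_rate,
                                 rng, extend=True)
    depths = sorted(
        node._split_depth for node in _annotate_split_depths(source))
    # after the j-th split (root split first, depth 0) there are j+1 lineages
    lo, hi = depths[n - 2], depths[n - 1]
    tstar = 0.5 * (lo + hi)
    root_age = tree_height(source)
    sliced = slice_families(source, tstar / root_age)
    assert sliced.n_families == n
    return sliced.family_tree()


def _annotate_split_depths(tree):
    tree.seed_node._split_depth = 0.0
    internals = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node._split_depth = (node.parent_node._split_depth
                                 + (node.edge.length or 0.0))
        if not node.is_leaf():
            internals.append(node)
    return internals


def generate_tree_set(config: ScenarioConfig) -> TreeSet:
    """A posterior-like sample of ultrametric family-level trees.

    A single base family-level tree (see :func:`_base_family_tree`) is
    rescaled to ``tree_depth``; each replicate multiplies every internal
    node age by an independent LogNormal(0, age_jitter) factor and
    restores parent-older-than-child monotonicity by clipping in
    preorder, keeping the trees ultrametric while making per-family stem
    ages right-skewed across replicates.
    """
    rng = substream(config.seed, "tree")
    base = _base_family_tree(config, rng)
    base = rescale_tree(base, config.tree_depth)
    base.seed_node.edge.length = None  # family-level trees carry no stem
    width = len(str(config.n_families))
    for i, leaf in enumerate(base.leaf_node_iter()):
        leaf.taxon.label = f"F{i + 1:0{width}d}"
    jrng = substream(config.seed, "jitter")
    trees = []
    for _ in range(config.n_trees):
        rep = base.clone(depth=1)
        _node_ages(rep)
        if config.age_jitter > 0:
            for node in rep.preorder_node_iter():
                if not node.is_leaf():
                    node._age *= np.exp(jrng.normal(0.0, config.age_jitter))
            for node in rep.preorder_node_iter():  # enforce monotone ages
                if node.parent_node is not None and not node.is_leaf():
                    node._age = min(node._age, node.parent_node._age)
        _ages_to_branch_lengths(rep)
        trees.append(rep)
    ts = TreeSet(trees=trees, source_id=f"synthetic(seed={config.seed})")
    ts.validate()
    return ts


def select_arrested(config: ScenarioConfig, families: list[str]) -> list[str]:
    """The designated low-rate families (deterministic given the seed)."""
    rng = substream(config.seed, "plant")
    chosen = rng.choice(sorted(families), size=config.n_arrested, replace=False)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Planting phylogenetic regimes
# ---------------------------------------------------------------------------


def _greedy_max_mpd(D: np.ndarray, m: int) -> np.ndarray:
    """Greedy MPD-maximising selection: maximally spread tip subset.

    Starts from the most distant pair and repeatedly adds the tip with
    the largest total distance to the current selection (exact maximum-
    dispersion subset selection is NP-hard; the greedy heuristic plants a
    strong, deterministic signal).
    """
    first = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(first[0]), int(first[1])]
    total = D[selected[0]] + D[selected[1]]
    while len(selected) < m:
        total[selected] = -np.inf
        nxt = int(np.argmax(total))
        selected.append(nxt)
        total = total + D[nxt]
    sel = np.array(selected[:m], dtype=np.intp)
    # deterministic 1-swap local search: replace a selected tip with an
    # outside tip whenever that raises the selection's total pairwise distance
    n = D.shape[0]
    in_sel = np.zeros(n, dtype=bool)
    in_sel[sel] = True
    for _ in range(100):
        contrib = D[np.ix_(sel, sel)].sum(axis=1)           # per-member load
        cand = D[:, sel].sum(axis=1)                        # outside tips
        cand[in_sel] = -np.inf
        worst = int(np.argmin(contrib))
        best = int(np.argmax(cand))
        gain = cand[best] - D[best, sel[worst]] - contrib[worst]
        if gain <= 1e-12:
            break
        in_sel[sel[worst]] = False
        in_sel[best] = True
        sel[worst] = best
    return sel


def _clade_positions(tree, labels: list[str], m: int) -> list[str]:
    """Tip labels of the clade whose size best matches m (tight low-MPD set)."""
    best, best_count = None, None
    for node in tree.postorder_internal_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        count = len(leaves)
        if count >= len(labels):  # whole tree: not a proper clade choice
            continue
        if best is None or abs(count - m) < abs(best_count - m):
            best, best_count = leaves, count
    if best is None:
        raise ConfigurationError("tree has no proper clade to plant into")
    if not (m / 2 <= best_count <= 2 * m):
        log.warning("no clade within factor 2 of size %d; using closest (%d)",
                    m, best_count)
    if best_count >= m:
        return best[:m]
    # clade too small: top up with the phylogenetically nearest outside tips
    all_labels, D = patristic_distance_matrix(tree)
    pos = {l: i for i, l in enumerate(all_labels)}
    inside = np.array([pos[l] for l in best], dtype=np.intp)
    outside = [l for l in all_labels if l not in set(best)]
    dist_to_clade = {l: D[pos[l], inside].min() for l in outside}
    extra = sorted(outside, key=lambda l: (dist_to_clade[l], l))[: m - best_count]
    return best + extra


def plant_regime(
    tree_set: TreeSet, arrested: list[str], regime: str, seed: int = 0
) -> TreeSet:
    """Permute tip identities so the arrested set occupies planted positions.

    ``planted_overdispersed`` assigns the arrested labels to a greedy
    max-min (maximally spread) tip subset of the first tree;
    ``planted_clustered`` packs them into the clade whose size best
    matches; ``random`` applies a uniform label permutation.  The same
    relabelling is applied to every tree (the trees share one taxon
    namespace), so the planted truth is consistent across the set.
    """
    if regime not in REGIMES:
        raise ConfigurationError(f"unknown regime {regime!r}")
    if len(arrested) < 2:
        raise ConfigurationError("arrested set must have >= 2 families")
    rng = default_rng(SeedSequence(seed, spawn_key=(_STREAMS["plant"], 1)))
    # plant against the set's central geometry: the mean distance matrix
    # across replicates (for a one-tree set this is just that tree)
    labels, D = patristic_distance_matrix(tree_set[0])
    for tree in tree_set.trees[1:]:
        D += patristic_distance_matrix(tree, labels=labels)[1]
    D /= len(tree_set)
    missing = set(arrested) - set(labels)
    if missing:
        raise ConfigurationError(f"arrested families not in trees: {sorted(missing)[:5]}")
    if regime == "random":
        positions = [labels[i] for i in
                     rng.choice(len(labels), size=len(arrested), replace=False)]
    elif regime == "planted_overdispersed":
        positions = [labels[i] for i in _greedy_max_mpd(D, len(arrested))]
    else:
        positions = _clade_positions(tree_set[0], labels, len(arrested))

    # build the label permutation: arrested names onto the planted positions,
    # remaining names shuffled over the remaining positions
    others = [l for l in labels if l not in set(arrested)]
    free_positions = [l for l in labels if l not in set(positions)]
    others = list(rng.permutation(others))
    new_label = dict(zip(positions, arrested))
    new_label.update(zip(free_positions, others))
    namespaces = {id(t.taxon_namespace): t.taxon_namespace for t in tree_set}
    for ns in namespaces.values():
        for taxon in ns:
            taxon.label = new_label[taxon.label]
    return tree_set


# ---------------------------------------------------------------------------
# Richness
# ---------------------------------------------------------------------------


def generate_richness(
    config: ScenarioConfig, tree_set: TreeSet, arrested: list[str] | None = None
) -> FamilyTable:
    """Draw per-family richness so realized rates cluster around the targets.

    Each family gets an iid target rate r = r_group * LogNormal(0,
    rate_spread), with r_group = ``rate_low`` for arrested families and
    ``rate_high`` otherwise; richness is then N = max(1, round(exp(r *
    stem_age_summary) * LogNormal(0, richness_dispersion))), so realized
    ln(N)/t clusters around the target with the two groups well
    separated.
    """
    table = summarize_ages(tree_set)
    if arrested is None:
        arrested = select_arrested(config, table.families)
    arrested_set = set(arrested)
    rng = substream(config.seed, "richness")
    n = {}
    for fam in table.families:
        base = config.rate_low if fam in arrested_set else config.rate_high
        r = base * float(np.exp(rng.normal(0.0, config.rate_spread)))
        t = table.stem_age_summary[fam]
        noise = float(np.exp(rng.normal(0.0, config.richness_dispersion)))
        n[fam] = max(1, int(round(np.exp(r * t) * noise)))
    return table.with_richness(pd.Series(n))


# ---------------------------------------------------------------------------
# Ranges
# ---------------------------------------------------------------------------


def generate_ranges(
    rate_table: pd.DataFrame, spatial_congruence: str = "incongruent",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-family bounding boxes with controllable quantile congruence.

    ``congruent``: families of a quantile draw range centres around one
    shared cluster centre per quantile (s.d. 10 degrees); ``incongruent``:
    centres uniform worldwide.  Extents are log-normal (median 8 degrees)
    and boxes are clipped to the lat/lon bounds.

    Returns a ``family,lon_min,lon_max,lat_min,lat_max`` frame.
    """
    if spatial_congruence not in CONGRUENCE:
        raise ConfigurationError(
            f"spatial_congruence must be one of {CONGRUENCE}")
    rng = default_rng(SeedSequence(seed, spawn_key=(_STREAMS["ranges"],)))
    centres = {}
    if spatial_congruence == "congruent":
        for q in sorted(rate_table["quantile"].unique()):
            centres[int(q)] = (rng.uniform(-150, 150), rng.uniform(-55, 55))
    rows = []
    for row in rate_table.sort_values("family").itertuples(index=False):
        if spatial_congruence == "congruent":
            cx, cy = centres[int(row.quantile)]
            cx += rng.normal(0.0, 10.0)
            cy += rng.normal(0.0, 10.0)
        else:
            cx = rng.uniform(-180, 180)
            cy = rng.uniform(-90, 90)
        w = float(np.exp(rng.normal(np.log(8.0), 0.5)))
        h = float(np.exp(rng.normal(np.log(8.0), 0.5)))
        rows.append({
            "family": row.family,
            "lon_min": max(cx - w / 2, -180.0),
            "lon_max": min(cx + w / 2, 180.0),
            "lat_min": max(cy - h / 2, -90.0),
            "lat_max": min(cy + h / 2, 90.0),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole scenarios
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """All synthetic inputs for one configuration."""

    config: ScenarioConfig
    tree_set: TreeSet
    arrested: list[str]
    family_table: FamilyTable
    ranges: pd.DataFrame = field(repr=False)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Trees, planted regime, richness and ranges from one seed."""
    from .rates import make_rate_table

    tree_set = generate_tree_set(config)
    arrested = select_arrested(config, tree_set.families)
    tree_set = plant_regime(tree_set, arrested, config.regime, seed=config.seed)
    family_table = generate_richness(config, tree_set, arrested)
    rate_table = make_rate_table(family_table)
    ranges = generate_ranges(rate_table, config.spatial_congruence,
                             seed=config.seed)
    return Scenario(config=config, tree_set=tree_set, arrested=arrested,
                    family_table=family_table, ranges=ranges)


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, str]:
    """Emit the formats the pipeline consumes; returns artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trees": str(outdir / "trees.nwk"),
        "families": str(outdir / "families.csv"),
        "ranges": str(outdir / "ranges.csv"),
        "scenario": str(outdir / "scenario.yaml"),
    }
    scenario.tree_set.write(paths["trees"])
    scenario.family_table.write_csv(paths["families"])
    scenario.ranges.to_csv(paths["ranges"], index=False)
    scenario.config.to_yaml(paths["scenario"])
    return paths
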