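"""Pure-birth simulation null: tree growth, slicing into families, MPD.

Family boundaries are a taxonomic convention, so an observed association
between diversification quantile and MPD could in principle be an artefact
of how tree geometry interacts with that convention.  This module builds the
corresponding null: grow Yule (pure-birth) trees to a fixed tip number,
declare every branch alive at the start of the last fifth of the clade's age
a "family" (its descendant tips are the family's richness, its parent node's
age the stem age), rescale to an empirical clade age, and push the resulting
families through the same rate-quantile-MPD pipeline.  Under pure birth the
per-quantile MPD distributions should be mutually indistinguishable.

Conventions fixed here (the underlying events have measure zero or are
underdetermined by the process itself):

* the Yule simulation starts from a single lineage and stops at the instant
  the n-th tip appears, so the two youngest sibling tips have zero-length
  branches; the pre-root (stem) period is kept as the seed edge length, and
  ``tree_height(include_stem=True)`` measures from the origin of that first
  lineage;
* a node falling exactly on the slice time belongs to the rootward side, so
  its subtending branch counts as crossing (closed on the tipward side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .errors import ConfigurationError, DegenerateTreeError, DomainError
from .dispersion import mpd, nearest_rank_interval
from .rates import assign_quantiles, diversification_rate

log = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.8
DEFAULT_N_SIMS = 1000
DEFAULT_N_TIPS = 10000


# ---------------------------------------------------------------------------
# Yule simulation
# ---------------------------------------------------------------------------


def simulate_pure_birth(
    n_tips: int,
    birth_rate: float = 1.0,
    rng: Generator | int | None = None,
    extend: bool = False,
) -> dendropy.Tree:
    """Grow an ultrametric tree under the Yule process to ``n_tips`` tips.

    Every extant lineage splits at rate ``birth_rate`` (lambda), so the
    waiting time from k to k+1 lineages is Exponential(k*lambda) and the
    splitting lineage is uniform among the extant ones.  The process runs
    from a single origin lineage and stops at the instant the n-th tip is
    born, which leaves the two youngest sibling tips with zero-length
    branches; ``extend=True`` instead runs on for one further
    Exponential(n*lambda) waiting time (up to, not including, the next
    split), giving strictly positive pendant branches.  The origin-to-root
    period is stored as the seed edge length.
    """
    if n_tips < 2:
        raise DomainError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise DomainError("birth_rate must be > 0")
    if not isinstance(rng, Generator):
        rng = default_rng(rng)
    k = np.arange(1, n_tips, dtype=float)
    waits = rng.standard_exponential(n_tips - 1) / (birth_rate * k)
    split_times = np.cumsum(waits)  # absolute, origin at 0
    # which lineage splits at each event: uniform over the k extant ones
    picks = (rng.random(n_tips - 1) * np.arange(1, n_tips)).astype(np.intp)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root._time = split_times[0]
    a = dendropy.Node()
    b = dendropy.Node()
    a._birth = b._birth = split_times[0]
    root.add_child(a)
    root.add_child(b)
    leaves = [a, b]
    for ev in range(1, n_tips - 1):
        t = split_times[ev]
        node = leaves[picks[ev]]
        node._time = t
        ca, cb = dendropy.Node(), dendropy.Node()
        ca._birth = cb._birth = t
        node.add_child(ca)
        node.add_child(cb)
        leaves[picks[ev]] = ca
        leaves.append(cb)
    end = split_times[-1]
    if extend:
        end += rng.standard_exponential() / (birth_rate * n_tips)
    width = len(str(n_tips))
    for i, leaf in enumerate(leaves):
        leaf.taxon = tns.new_taxon(f"T{i + 1:0{width}d}")
        leaf.edge.length = end - leaf._birth
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            node.edge.length = split_times[0]  # stem: origin -> root
        else:
            node.edge.length = node._time - node.parent_node._time
    tree.is_rooted = True
    return tree


def tree_height(tree: dendropy.Tree, include_stem: bool = False) -> float:
    """Maximum root-to-tip path length, optionally adding the stem edge."""
    from .treeio import leaf_depths

    h = max(leaf_depths(tree).values())
    if include_stem and tree.seed_node.edge.length:
        h += float(tree.seed_node.edge.length)
    return h


def rescale_tree(tree: dendropy.Tree, target_root_age: float) -> dendropy.Tree:
    """Multiply every branch so the root age equals ``target_root_age``.

    Topology is untouched; the stem edge (if any) is scaled by the same
    factor.  Operates on and returns a clone.
    """
    if target_root_age <= 0:
        raise DomainError("target_root_age must be > 0")
    current = tree_height(tree)
    if current <= 0:
        raise DegenerateTreeError("cannot rescale a zero-height tree")
    factor = target_root_age / current
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


# ---------------------------------------------------------------------------
# Slicing into families
# ---------------------------------------------------------------------------


@dataclass
class SlicedFamilySet:
    """Families defined by the branches crossing a time slice.

    ``families`` has one row per crossing branch: family (synthetic id),
    stem_age (age of the branch's parent node, Myr before present),
    n_tips (descendant richness), representative (one descendant tip
    label, used to measure family-level distances on the source tree).
    ``distance_matrix`` holds patristic distances on the derived
    family-level tree, whose tips run from each crossing branch's parent
    node to the present.
    """

    tree: dendropy.Tree
    slice_age: float          # Myr before present
    root_age: float
    families: pd.DataFrame
    distance_matrix: np.ndarray = field(repr=False)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_tree(self) -> dendropy.Tree:
        """Materialise the family-level tree (tips relabelled to family ids)."""
        reps = dict(zip(self.families["representative"], self.families["family"]))
        out = self.tree.clone(depth=1)
        out.retain_taxa_with_labels(list(reps))
        out.migrate_taxon_namespace(dendropy.TaxonNamespace())
        for leaf in out.leaf_node_iter():
            leaf.taxon.label = reps[leaf.taxon.label]
        return out


def slice_families(tree: dendropy.Tree, fraction: float = DEFAULT_FRACTION) -> SlicedFamilySet:
    """Cut ``tree`` at ``fraction`` of its root age and define families.

    The slice sits at t* = fraction * root_age from the root, i.e. at age
    (1 - fraction) * root_age before present.  A branch crosses when its
    parent node is older than the slice and its child node is at or below
    it.  Family richness is the number of descendant tips; family stem
    age is the age of the branch's parent node.
    """
    if not (0.0 < fraction < 1.0):
        raise DomainError("fraction must be in (0, 1)")
    root = tree.seed_node
    root._depth = 0.0
    nodes = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node._depth = node.parent_node._depth + (node.edge.length or 0.0)
        nodes.append(node)
    root_age = max(n._depth for n in nodes if n.is_leaf())
    if root_age <= 0:
        raise DegenerateTreeError("tree has zero height")
    tstar = fraction * root_age

    # crossing branches, their richness and one representative tip each
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._ntips = 1
            node._rep = node.taxon.label
        else:
            kids = node.child_nodes()
            node._ntips = sum(c._ntips for c in kids)
            node._rep = kids[0]._rep
    crossing = []
    for node in nodes:
        parent = node.parent_node
        if parent is None:
            continue
        if parent._depth < tstar <= node._depth:
            crossing.append(node)
    width = len(str(max(len(crossing), 1)))
    records = [
        {
            "family": f"F{i + 1:0{width}d}",
            "stem_age": root_age - node.parent_node._depth,
            "n_tips": node._ntips,
            "representative": node._rep,
        }
        for i, node in enumerate(crossing)
    ]
    fam_index = {id(node): i for i, node in enumerate(crossing)}

    # distances on the derived family tree: both tips sit at the present,
    # so d(i, j) = 2 * (root_age - depth of their MRCA); one sweep over the
    # rootward part of the tree suffices.
    m = len(crossing)
    D = np.zeros((m, m))
    for node in tree.postorder_node_iter():
        if node._depth >= tstar and id(node) not in fam_index:
            node._fams = None
            continue
        if id(node) in fam_index:
            node._fams = np.array([fam_index[id(node)]], dtype=np.intp)
            continue
        groups = [c._fams for c in node.child_nodes() if c._fams is not None
                  and c._fams.size]
        dist = 2.0 * (root_age - node._depth)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                D[np.ix_(groups[a], groups[b])] = dist
                D[np.ix_(groups[b], groups[a])] = dist
        node._fams = (np.concatenate(groups) if groups
                      else np.empty(0, dtype=np.intp))
    for node in nodes:  # drop scratch attributes
        for attr in ("_fams", "_ntips", "_rep"):
            if hasattr(node, attr):
                delattr(node, attr)

    return SlicedFamilySet(
        tree=tree,
        slice_age=root_age - tstar,
        root_age=root_age,
        families=pd.DataFrame.from_records(records),
        distance_matrix=D,
    )


# ---------------------------------------------------------------------------
# The simulation null
# ---------------------------------------------------------------------------


@dataclass
class SimNull:
    """Per-quantile MPD distribution across simulated pure-birth trees."""

    mpd_table: pd.DataFrame   # columns sim_index, quantile, mpd
    lower: pd.Series          # per-quantile 2.5th order statistic
    upper: pd.Series          # per-quantile 97.5th order statistic
    n_sims: int
    n_tips: int
    fraction: float
    target_root_age: float | None
    seed: int
    n_redraws: int = 0


def _sliced_quantile_mpds(sliced: SlicedFamilySet, k: int) -> dict[int, float]:
    fam = sliced.families
    rates = pd.Series(
        diversification_rate(fam["n_tips"].values, fam["stem_age"].values),
        index=fam["family"].values,
    )
    quantiles = assign_quantiles(rates, k=k)
    out = {}
    for q in range(1, k + 1):
        idx = np.flatnonzero((quantiles == q).values)
        out[q] = mpd(sliced.distance_matrix, idx)
    return out


def simulation_null(
    n_sims: int = DEFAULT_N_SIMS,
    n_tips: int = DEFAULT_N_TIPS,
    birth_rate: float = 1.0,
    fraction: float = DEFAULT_FRACTION,
    target_root_age: float | None = None,
    k: int = 5,
    seed: int = 0,
    max_redraws: int = 100,
) -> SimNull:
    """MPD-by-quantile envelope from sliced, rescaled pure-birth trees.

    Each simulated tree is (optionally) rescaled to ``target_root_age``,
    sliced at ``fraction`` of its root age into families, the families
    binned into ``k`` rate quantiles, and each quantile's MPD measured on
    the family-level tree.  A simulation yielding fewer than max(k, 2*k)
    usable families (every quantile needs >= 2 members) is redrawn, up to
    ``max_redraws`` times in total.
    """
    ss = SeedSequence(seed)
    streams = ss.spawn(n_sims + max_redraws)
    rows = []
    redraws = 0
    stream_i = 0
    for sim in range(n_sims):
        while True:
            if stream_i >= len(streams):
                raise ConfigurationError(
                    f"exceeded {max_redraws} redraws of degenerate simulations"
                )
            rng = default_rng(streams[stream_i])
            stream_i += 1
            tree = simulate_pure_birth(n_tips, birth_rate, rng)
            if target_root_age is not None:
                tree = rescale_tree(tree, target_root_age)
            sliced = slice_families(tree, fraction)
            if sliced.n_families >= 2 * k:
                break
            redraws += 1
            log.warning("simulation %d yielded only %d families; redrawing",
                        sim, sliced.n_families)
        for q, value in _sliced_quantile_mpds(sliced, k).items():
            rows.append({"sim_index": sim, "quantile": q, "mpd": value})
    table = pd.DataFrame(rows)
    wide = table.pivot(index="sim_index", columns="quantile", values="mpd")
    lo, hi = nearest_rank_interval(wide.to_numpy())
    return SimNull(
        mpd_table=table,
        lower=pd.Series(lo, index=wide.columns),
        upper=pd.Series(hi, index=wide.columns),
        n_sims=n_sims,
        n_tips=n_tips,
        fraction=fraction,
        target_root_age=target_root_age,
        seed=seed,
        n_redraws=redraws,
    )


def plot_simulation_null(sim_null: SimNull, ax=None, title: str = ""):
    """Boxplots of simulated per-quantile MPD with the dashed envelope."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    quantiles = sorted(sim_null.mpd_table["quantile"].unique())
    data = [sim_null.mpd_table.loc[sim_null.mpd_table["quantile"] == q, "mpd"]
            for q in quantiles]
    cmap = plt.get_cmap("viridis")
    bp = ax.boxplot(data, positions=quantiles, widths=0.6, patch_artist=True)
    for i, patch in enumerate(bp["boxes"]):
        patch.set_facecolor(cmap(i / max(len(quantiles) - 1, 1)))
    ax.plot(quantiles, sim_null.lower.loc[quantiles], "k--", lw=1)
    ax.plot(quantiles, sim_null.upper.loc[quantiles], "k--", lw=1)
    ax.set_xlabel("diversification quantile (1 = lowest rates)")
    ax.set_ylabel("simulated MPD")
    if title:
        ax.set_title(title)
    return ax
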