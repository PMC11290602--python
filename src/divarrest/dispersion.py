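"""Mean pairwise distance (MPD) of rate quantiles against permutation nulls.

For each tree in a posterior set and each diversification quantile, the
observed MPD — the mean patristic distance over all unordered pairs of the
quantile's family tips — is compared with a size-preserving label-permutation
null: families are reassigned to quantiles uniformly at random (keeping the
observed bin sizes), the per-quantile MPDs recomputed, and a 95% envelope
taken from the 2.5th/97.5th order statistics of the replicates.  A quantile
sitting above the envelope is phylogenetically *overdispersed* (its families
are scattered across the tree), below it *clustered*.

The whole-set trend of MPD against quantile index is summarised by a
Spearman rank correlation with a label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.stats import rankdata, spearmanr

from .errors import ConfigurationError, TreeFormatError, UndefinedMPDError
from .rates import quantile_members
from .treeio import TreeSet

_EMPTY_I = np.empty(0, dtype=np.intp)
_EMPTY_F = np.empty(0, dtype=float)


# ---------------------------------------------------------------------------
# Patristic distances and MPD
# ---------------------------------------------------------------------------


def patristic_distance_matrix(
    tree: dendropy.Tree, labels: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of path-length distances between tips.

    ``labels`` restricts (and orders) the tips considered; by default all
    tips in sorted label order.  Runs one post-order sweep, filling cross
    pairs at each internal node, so the cost is O(n + m^2) for m tracked
    tips on an n-tip tree.  The root/stem edge never contributes.
    """
    if labels is None:
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != len(labels):
        raise ConfigurationError("duplicate tip labels requested")
    m = len(labels)
    D = np.zeros((m, m))
    seen = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab in index:
                length = node.edge.length
                if length is None and node.parent_node is not None:
                    raise TreeFormatError(f"missing branch length above tip {lab!r}")
                node._tips = np.array([index[lab]], dtype=np.intp)
                node._tipd = np.array([float(length or 0.0)])
                seen += 1
            else:
                node._tips, node._tipd = _EMPTY_I, _EMPTY_F
            continue
        groups = [(c._tips, c._tipd) for c in node.child_nodes()]
        for c in node.child_nodes():
            del c._tips, c._tipd
        for a in range(len(groups)):
            ia, da = groups[a]
            if not ia.size:
                continue
            for b in range(a + 1, len(groups)):
                ib, db = groups[b]
                if not ib.size:
                    continue
                block = da[:, None] + db[None, :]
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        tips = np.concatenate([g[0] for g in groups])
        tipd = np.concatenate([g[1] for g in groups])
        if node.parent_node is not None:
            if node.edge.length is None:
                raise TreeFormatError("missing internal branch length")
            tipd = tipd + float(node.edge.length)
        node._tips, node._tipd = tips, tipd
    del tree.seed_node._tips, tree.seed_node._tipd
    if seen != m:
        missing = set(labels) - {lf.taxon.label for lf in tree.leaf_node_iter()}
        raise KeyError(f"labels not found as tips: {sorted(missing)[:10]}")
    return labels, D


def mpd(distance_matrix: np.ndarray, tip_indices) -> float:
    """Mean of the |S|(|S|-1)/2 unordered pairwise distances in a tip set."""
    idx = np.asarray(tip_indices, dtype=np.intp)
    s = idx.size
    if s < 2:
        raise UndefinedMPDError("MPD needs at least two tips")
    sub = distance_matrix[np.ix_(idx, idx)]
    return float(sub.sum() / (s * (s - 1)))


def nearest_rank_interval(samples: np.ndarray, alpha: float = 0.025):
    """Per-column [alpha, 1-alpha] envelope by symmetric nearest-rank.

    With n sorted replicates the bounds are the ceil(alpha*n)-th order
    statistic from each end (for n = 1000, alpha = 0.025: the 25th and
    976th values).
    """
    x = np.sort(np.atleast_2d(samples), axis=0)
    n = x.shape[0]
    m = int(np.ceil(alpha * n))
    m = max(m, 1)
    return x[m - 1], x[n - m]


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Replicate MPDs and the derived per-quantile envelope."""

    replicates: np.ndarray  # (n_reps, k)
    lower: np.ndarray       # (k,) 2.5th order statistic
    upper: np.ndarray       # (k,) 97.5th order statistic


def permutation_null(
    distance_matrix: np.ndarray,
    bin_sizes,
    n_reps: int = 1000,
    rng: Generator | int | None = None,
    chunk: int = 200,
) -> PermutationNull:
    """Size-preserving random reassignment null for per-quantile MPD.

    Each replicate partitions all tips uniformly at random into bins of
    the observed sizes and records each bin's MPD.  Fully reproducible
    given ``rng`` (a Generator or a seed).
    """
    sizes = [int(s) for s in bin_sizes]
    n = distance_matrix.shape[0]
    if sum(sizes) != n:
        raise ConfigurationError(
            f"bin sizes sum to {sum(sizes)} but matrix has {n} tips"
        )
    if any(s < 2 for s in sizes):
        raise ConfigurationError("every quantile needs at least 2 families")
    if not isinstance(rng, Generator):
        rng = default_rng(rng)
    k = len(sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    reps = np.empty((n_reps, k))
    done = 0
    while done < n_reps:
        c = min(chunk, n_reps - done)
        perm = np.argsort(rng.random((c, n)), axis=1)
        for q in range(k):
            idx = perm[:, offsets[q]:offsets[q + 1]]
            sub = distance_matrix[idx[:, :, None], idx[:, None, :]]
            s = sizes[q]
            reps[done:done + c, q] = sub.sum(axis=(1, 2)) / (s * (s - 1))
        done += c
    lower, upper = nearest_rank_interval(reps)
    return PermutationNull(replicates=reps, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# Dispersion across a tree set
# ---------------------------------------------------------------------------


@dataclass
class DispersionResult:
    """Observed per-(tree, quantile) MPD with null envelopes and trend.

    ``per_tree`` has columns tree_index, quantile, mpd_obs, null_lo,
    null_hi, flag ('overdispersed' / 'clustered' / 'ns'); ``pooled`` holds
    one envelope per quantile from all replicates over all trees; ``trend``
    is the rank-correlation summary of MPD against quantile index.
    """

    per_tree: pd.DataFrame
    pooled: pd.DataFrame
    trend: dict
    n_permutations: int
    seed: int

    def flag_rates(self) -> pd.DataFrame:
        """Per-quantile fraction of trees flagged each way."""
        g = self.per_tree.groupby("quantile")["flag"]
        return pd.DataFrame({
            "overdispersed": g.apply(lambda s: (s == "overdispersed").mean()),
            "clustered": g.apply(lambda s: (s == "clustered").mean()),
        })


def _flag(obs: float, lo: float, hi: float) -> str:
    if obs > hi:
        return "overdispersed"
    if obs < lo:
        return "clustered"
    return "ns"


def dispersion_over_tree_set(
    tree_set: TreeSet,
    rate_table: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    trend_reps: int = 1000,
) -> DispersionResult:
    """Observed vs null MPD for every (tree, quantile) of a posterior set.

    The quantile assignment is fixed once (from the summary ages backing
    ``rate_table``) and applied to every tree; phylogenetic uncertainty
    enters through the per-tree distances.  Per-tree random streams are
    spawned deterministically from the master seed by tree index, so
    results do not depend on iteration order.
    """
    members = quantile_members(rate_table)
    quantiles = sorted(members)
    bin_sizes = [len(members[q]) for q in quantiles]
    ss = SeedSequence(seed)
    children = ss.spawn(len(tree_set) + 1)  # last stream: trend test
    rows = []
    pooled_reps = []
    for ti, tree in enumerate(tree_set):
        labels, D = patristic_distance_matrix(tree)
        index = {lab: i for i, lab in enumerate(labels)}
        null = permutation_null(D, bin_sizes, n_reps=n_reps,
                                rng=default_rng(children[ti]))
        pooled_reps.append(null.replicates)
        for qi, q in enumerate(quantiles):
            idx = [index[f] for f in members[q]]
            obs = mpd(D, idx)
            rows.append({
                "tree_index": ti,
                "quantile": q,
                "mpd_obs": obs,
                "null_lo": null.lower[qi],
                "null_hi": null.upper[qi],
                "flag": _flag(obs, null.lower[qi], null.upper[qi]),
            })
    per_tree = pd.DataFrame(rows)
    all_reps = np.concatenate(pooled_reps, axis=0)
    lo, hi = nearest_rank_interval(all_reps)
    pooled = pd.DataFrame({"quantile": quantiles, "null_lo": lo, "null_hi": hi})
    result = DispersionResult(per_tree=per_tree, pooled=pooled, trend={},
                              n_permutations=n_reps, seed=seed)
    result.trend = trend_test(result, n_reps=trend_reps,
                              rng=default_rng(children[-1]))
    return result


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------


def trend_test(
    result: DispersionResult,
    n_reps: int = 1000,
    rng: Generator | int | None = None,
) -> dict:
    """Rank correlation of MPD with quantile index, permutation p-value.

    Observations are pooled over trees; the null redraws the quantile
    labels uniformly (a two-sided test on Spearman's rho).  A negative
    statistic means MPD decreases as diversification rate increases.
    """
    if not isinstance(rng, Generator):
        rng = default_rng(rng)
    q = result.per_tree["quantile"].to_numpy(dtype=float)
    m = result.per_tree["mpd_obs"].to_numpy(dtype=float)
    if np.allclose(m, m[0]):
        return {"statistic": 0.0, "p_value": 1.0, "direction": "none",
                "degenerate": True, "n_reps": n_reps}
    rho = float(spearmanr(q, m).statistic)
    rq = rankdata(q)
    rm = rankdata(m)
    rq_c = rq - rq.mean()
    rm_c = rm - rm.mean()
    denom = np.sqrt((rq_c ** 2).sum() * (rm_c ** 2).sum())
    hits = 0
    for _ in range(n_reps):
        perm = rng.permutation(rm_c)
        rho_p = float(rq_c @ perm / denom)
        if abs(rho_p) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_reps)
    return {
        "statistic": rho,
        "p_value": p,
        "direction": "decreasing" if rho < 0 else "increasing",
        "degenerate": False,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_dispersion(result: DispersionResult, ax=None, title: str = ""):
    """Per-quantile distribution of observed MPD with the dashed null envelope."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    quantiles = sorted(result.per_tree["quantile"].unique())
    data = [result.per_tree.loc[result.per_tree["quantile"] == q, "mpd_obs"]
            for q in quantiles]
    cmap = plt.get_cmap("viridis")
    bp = ax.boxplot(data, positions=quantiles, widths=0.6, patch_artist=True)
    for i, patch in enumerate(bp["boxes"]):
        patch.set_facecolor(cmap(i / max(len(quantiles) - 1, 1)))
    pooled = result.pooled.set_index("quantile")
    ax.plot(quantiles, pooled.loc[quantiles, "null_lo"], "k--", lw=1)
    ax.plot(quantiles, pooled.loc[quantiles, "null_hi"], "k--", lw=1)
    ax.set_xlabel("diversification quantile (1 = lowest rates)")
    ax.set_ylabel("MPD (Myr)")
    if title:
        ax.set_title(title)
    return ax
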