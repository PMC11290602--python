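"""Reading, pruning and summarising time-calibrated family-level tree sets.

The analyses downstream operate on a *posterior tree set*: an ordered sample
of rooted, ultrametric trees whose tips are taxonomic families and whose
branch lengths are in millions of years (Myr).  Species-level trees are first
pruned so that each family is represented by exactly one tip; per-family stem
ages are then collected across the tree set and summarised by their median,
which is robust to the strong right skew that node-age distributions show
across posterior samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateTreeError,
    DomainError,
    EmptyInputError,
    MappingError,
    TreeFormatError,
    UltrametricityError,
)

log = logging.getLogger(__name__)

#: relative root-to-tip depth spread accepted silently
ULTRAMETRIC_TOL = 1e-6
#: spread up to this bound is accepted with a warning; beyond it is an error
ULTRAMETRIC_WARN_TOL = 1e-3


# ---------------------------------------------------------------------------
# TreeSet
# ---------------------------------------------------------------------------


@dataclass
class TreeSet:
    """An ordered collection of rooted trees sharing one family tip set.

    Parameters
    ----------
    trees:
        Trees in input order, branch lengths in Myr.  All trees must carry
        the same tip label set once :meth:`validate` passes.
    source_id:
        Free-text provenance tag (file path, scenario name, ...).
    """

    trees: list[dendropy.Tree]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> dendropy.Tree:
        return self.trees[i]

    @property
    def families(self) -> list[str]:
        """Sorted tip labels of the first tree."""
        return sorted(lf.taxon.label for lf in self.trees[0].leaf_node_iter())

    def validate(self) -> None:
        """Check shared tip sets and non-negative branch lengths."""
        if not self.trees:
            raise EmptyInputError("tree set contains no trees")
        ref = set(self.families)
        for i, tree in enumerate(self.trees):
            labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
            if labels != ref:
                raise TreeFormatError(
                    f"tree {i + 1} tip set differs from tree 1 "
                    f"(e.g. {sorted(labels ^ ref)[:5]})"
                )
            for edge in tree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    raise TreeFormatError(
                        f"tree {i + 1} has a negative branch length "
                        f"({edge.length})"
                    )

    def write(self, path: str | Path, schema: str = "newick") -> None:
        tl = dendropy.TreeList(self.trees, taxon_namespace=self.trees[0].taxon_namespace)
        tl.write(path=str(path), schema=schema, suppress_rooting=True)


def _normalize_labels(trees: Iterable[dendropy.Tree]) -> None:
    seen = set()
    for tree in trees:
        ns = tree.taxon_namespace
        if id(ns) in seen:
            continue
        seen.add(id(ns))
        for taxon in ns:
            taxon.label = " ".join(taxon.label.split())


def read_tree_set(path: str | Path, format: str = "newick") -> TreeSet:
    """Read a multi-tree file into a :class:`TreeSet`, preserving order.

    ``format`` is ``"newick"`` (newline/semicolon separated trees) or
    ``"nexus"`` (a TREES block).  Tip labels are whitespace-normalized.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path}: file is empty")
    kwargs = {"rooting": "default-rooted"}
    if format == "newick":
        kwargs["preserve_underscores"] = True
    try:
        tl = dendropy.TreeList.get(data=text, schema=format, **kwargs)
    except Exception as exc:  # locate the offending tree for the message
        index = 1
        if format == "newick":
            chunks = [c for c in text.split(";") if c.strip()]
            for i, chunk in enumerate(chunks):
                try:
                    dendropy.Tree.get(data=chunk + ";", schema="newick", **kwargs)
                except Exception:
                    index = i + 1
                    break
        raise TreeFormatError(f"{path}: failed to parse tree {index}: {exc}") from exc
    if len(tl) == 0:
        raise EmptyInputError(f"{path}: no trees found")
    _normalize_labels(tl)
    for tree in tl:
        tree.is_rooted = True
    return TreeSet(trees=list(tl), source_id=str(path))


# ---------------------------------------------------------------------------
# Pruning species-level trees to one representative per family
# ---------------------------------------------------------------------------


def prune_to_families(
    tree: dendropy.Tree, species_to_family: Mapping[str, str]
) -> dendropy.Tree:
    """Return a copy of ``tree`` with exactly one tip per family.

    The retained tip for each family is the lexicographically smallest
    species name mapped to it, and it is relabelled with the family name.
    Degree-2 nodes created by pruning are suppressed with their edge
    lengths summed, so every retained tip keeps its root-to-tip path
    length.  Families whose tips are not monophyletic are handled by the
    same rule (keep the chosen representative, drop the rest) with a
    logged warning.
    """
    tip_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unmapped = sorted(l for l in tip_labels if l not in species_to_family)
    if unmapped:
        raise MappingError(
            f"{len(unmapped)} tip(s) missing from species_to_family map: "
            f"{unmapped[:10]}"
        )
    by_family: dict[str, list[str]] = {}
    for label in tip_labels:
        by_family.setdefault(species_to_family[label], []).append(label)
    representatives = {fam: min(labels) for fam, labels in by_family.items()}

    pruned = tree.clone(depth=1)
    pruned.is_rooted = True

    # warn on non-monophyletic families (only worth computing when pruning)
    multi = {f: ls for f, ls in by_family.items() if len(ls) > 1}
    if multi:
        tn = pruned.taxon_namespace
        for fam, labels in multi.items():
            mrca = pruned.mrca(taxa=[tn.get_taxon(l) for l in labels])
            clade_size = sum(1 for _ in mrca.leaf_iter())
            if clade_size != len(labels):
                log.warning(
                    "family %s is not monophyletic (%d tips, MRCA spans %d); "
                    "keeping representative %s",
                    fam, len(labels), clade_size, representatives[fam],
                )

    pruned.retain_taxa_with_labels(list(representatives.values()))
    pruned.migrate_taxon_namespace(dendropy.TaxonNamespace())
    family_of = {rep: fam for fam, rep in representatives.items()}
    for leaf in pruned.leaf_node_iter():
        leaf.taxon.label = family_of[leaf.taxon.label]
    return pruned


def prune_tree_set(
    tree_set: TreeSet, species_to_family: Mapping[str, str]
) -> TreeSet:
    """Apply :func:`prune_to_families` to every tree of a set."""
    return TreeSet(
        trees=[prune_to_families(t, species_to_family) for t in tree_set],
        source_id=tree_set.source_id,
    )


# ---------------------------------------------------------------------------
# Stem ages
# ---------------------------------------------------------------------------


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label (stem/seed edge excluded)."""
    depths: dict[str, float] = {}
    tree.seed_node._depth = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node._depth = node.parent_node._depth + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node._depth
    return depths


def check_ultrametric(
    tree: dendropy.Tree,
    tol: float = ULTRAMETRIC_TOL,
    warn_tol: float = ULTRAMETRIC_WARN_TOL,
) -> float:
    """Validate that all root-to-tip depths agree within tolerance.

    Returns the relative depth spread.  Spread in ``(tol, warn_tol]``
    produces a warning (posterior trees often carry rounding noise);
    beyond ``warn_tol`` an :class:`UltrametricityError` is raised.
    """
    depths = np.fromiter(leaf_depths(tree).values(), dtype=float)
    dmax = depths.max()
    if dmax <= 0:
        raise DegenerateTreeError("tree has zero height")
    spread = (dmax - depths.min()) / dmax
    if spread > warn_tol:
        raise UltrametricityError(
            f"tree is not ultrametric: relative depth spread {spread:.3g} "
            f"exceeds {warn_tol:g}"
        )
    if spread > tol:
        warnings.warn(
            f"tree is only approximately ultrametric (spread {spread:.3g})",
            stacklevel=2,
        )
    return spread


def stem_age(tree: dendropy.Tree, family: str) -> float:
    """Age (Myr before present) of the parent node of ``family``'s tip.

    On an ultrametric tree this equals the tip's terminal branch length.
    """
    check_ultrametric(tree)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == family:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"family {family!r} is not a tip of the tree")
    if leaf.parent_node is None:
        raise DegenerateTreeError("single-tip tree: stem age undefined")
    return float(leaf.edge.length or 0.0)


# ---------------------------------------------------------------------------
# FamilyTable
# ---------------------------------------------------------------------------


@dataclass
class FamilyTable:
    """Per-family richness and stem ages across a tree set.

    ``ages`` is a (n_trees x n_families) frame of per-tree stem ages;
    ``stem_age_summary`` is their per-family median (or the single value
    for a one-tree set); ``n_species`` may be absent until a richness
    table is joined in.
    """

    ages: pd.DataFrame
    stem_age_summary: pd.Series
    n_species: pd.Series | None = None
    source_id: str = field(default="")

    @property
    def families(self) -> list[str]:
        return list(self.stem_age_summary.index)

    def with_richness(self, n_species: pd.Series | Mapping[str, int]) -> "FamilyTable":
        s = pd.Series(n_species, dtype=int).reindex(self.families)
        if s.isna().any():
            missing = list(s.index[s.isna()])
            raise MappingError(f"richness missing for families: {missing[:10]}")
        if (s < 1).any():
            bad = list(s.index[s < 1])
            raise DomainError(
                f"n_species must be >= 1; offending families: {bad[:10]}"
            )
        return FamilyTable(self.ages, self.stem_age_summary, s, self.source_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "family": self.families,
            "stem_age": self.stem_age_summary.values,
        })
        if self.n_species is not None:
            df.insert(1, "n_species", self.n_species.values)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def summarize_ages(tree_set: TreeSet, use_median: bool = True) -> FamilyTable:
    """Collect per-tree stem ages and their per-family summary.

    The default summary is the median, which resists the right-skewed
    node-age distributions typical of posterior tree samples; passing
    ``use_median=False`` gives the mean instead.
    """
    tree_set.validate()
    families = tree_set.families
    rows = []
    for i, tree in enumerate(tree_set):
        check_ultrametric(tree)
        ages = {lf.taxon.label: float(lf.edge.length or 0.0)
                for lf in tree.leaf_node_iter()}
        rows.append([ages[f] for f in families])
    df = pd.DataFrame(rows, columns=families)
    if (df.values <= 0).any():
        bad = [families[j] for j in np.where((df.values <= 0).any(axis=0))[0]]
        raise DegenerateTreeError(
            f"non-positive stem age for families {bad[:10]}; "
            "is the tree family-level and strictly bifurcating above tips?"
        )
    summary = df.median(axis=0) if use_median else df.mean(axis=0)
    return FamilyTable(ages=df, stem_age_summary=summary,
                       source_id=tree_set.source_id)


def read_family_csv(path: str | Path) -> pd.DataFrame:
    """Read a ``family,n_species[,stem_age]`` CSV (UTF-8, header required)."""
    df = pd.read_csv(path)
    required = {"family", "n_species"}
    if not required.issubset(df.columns):
        raise TreeFormatError(
            f"{path}: family CSV must have columns family,n_species "
            f"(got {list(df.columns)})"
        )
    if df.empty:
        raise EmptyInputError(f"{path}: family CSV has no rows")
    return df
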