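"""Polyphyletic species combinations and their phylogenetic branch features.

A combination of k species drawn from a rooted tree decomposes into its
*independent lineages*: maximal clades whose MRCA has only chosen species
as leaf descendants. A subset counts as polyphyletic (m >= 2 lineages)
when the MRCA of all chosen species is a strict ancestor of every
lineage MRCA. Singleton lineages are allowed — their MRCA is the leaf
itself (walking up through any unary nodes).

Four branch features summarize a combination on the tree:

- POB: product of the m origin-branch lengths (the branch entering each
  lineage's MRCA). Long ancestral origin branches give more time for
  chance convergence, making POB the feature that tracks background
  convergent substitution counts.
- PTB: product of the k terminal branch lengths.
- DTB: sum over species of all branch lengths from the tree's root (the
  MRCA of the full species set) down to each terminal taxon.
- DTN: same sums stopped at each terminal taxon's parent node, so that
  DTB - DTN equals the summed terminal branch lengths exactly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy


class FeatureError(ValueError):
    """A required branch (e.g. a root-adjacent origin branch) does not exist."""


class TreeIndex:
    """Bitmask/depth index over a rooted dendropy tree for fast clade tests."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
        self.leaf_labels: list[str] = [n.taxon.label for n in leaves]
        self.bit: dict[str, int] = {lab: 1 << i for i, lab in enumerate(self.leaf_labels)}
        self.leaf_node: dict[str, dendropy.Node] = {
            n.taxon.label: n for n in leaves
        }
        self.mask: dict[dendropy.Node, int] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self.mask[node] = self.bit[node.taxon.label]
            else:
                m = 0
                for c in node.child_nodes():
                    m |= self.mask[c]
                self.mask[node] = m
        # depth: summed branch lengths from the root (root edge excluded)
        self.depth: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                self.depth[node] = 0.0
            else:
                self.depth[node] = self.depth[node.parent_node] + (
                    node.edge.length or 0.0
                )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def subset_mask(self, species: Iterable[str]) -> int:
        m = 0
        for lab in species:
            m |= self.bit[lab]
        return m


@dataclass(slots=True)
class SpeciesCombination:
    """A k-species subset with (optionally) its lineage decomposition."""

    species: tuple[str, ...]
    lineages: Optional[tuple[tuple[str, ...], ...]] = None

    @property
    def k(self) -> int:
        return len(self.species)

    @property
    def m(self) -> Optional[int]:
        return None if self.lineages is None else len(self.lineages)

    @property
    def combo_id(self) -> str:
        return "|".join(sorted(self.species))


def lineage_decomposition(
    index: TreeIndex, species: Iterable[str]
) -> list[tuple[dendropy.Node, tuple[str, ...]]]:
    """Maximal chosen-only clades of a species subset.

    Returns ``(clade_mrca_node, clade_leaves)`` pairs sorted by the
    smallest leaf label, independent of input order.
    """
    species = sorted(set(species))
    smask = index.subset_mask(species)
    groups: dict[int, tuple[dendropy.Node, list[str]]] = {}
    for lab in species:
        node = index.leaf_node[lab]
        top = node
        p = node.parent_node
        while p is not None and (index.mask[p] & ~smask) == 0:
            top = p
            p = p.parent_node
        key = id(top)
        if key in groups:
            groups[key][1].append(lab)
        else:
            groups[key] = (top, [lab])
    out = [(node, tuple(labs)) for node, labs in groups.values()]
    out.sort(key=lambda t: t[1][0])
    return out


def decompose(index: TreeIndex, species: Iterable[str]) -> SpeciesCombination:
    decomp = lineage_decomposition(index, species)
    return SpeciesCombination(
        species=tuple(sorted(set(species))),
        lineages=tuple(labs for _, labs in decomp),
    )


def enumerate_combinations(
    tree: dendropy.Tree | TreeIndex,
    k: int,
    m: Optional[int] = None,
    required_clades: Optional[Sequence[Iterable[str]]] = None,
) -> Iterator[SpeciesCombination]:
    """Stream k-species subsets of the tree's leaves in lexicographic order.

    With ``m`` set, only subsets decomposing into exactly m independent
    lineages (polyphyletic: global MRCA strictly above every lineage MRCA)
    are yielded, with their decomposition attached. With ``m=None`` all
    C(n, k) subsets stream through undecomposed. ``required_clades``
    optionally demands at least one chosen species from each given leaf
    set.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    n = index.n_leaves
    if k > n:
        raise ValueError(f"k={k} exceeds leaf count {n}")
    if m is not None and m > k:
        raise ValueError(f"m={m} exceeds k={k}")
    required = (
        [frozenset(c) for c in required_clades] if required_clades else None
    )
    for subset in itertools.combinations(index.leaf_labels, k):
        if required is not None and any(not (set(subset) & c) for c in required):
            continue
        if m is None:
            yield SpeciesCombination(species=subset)
            continue
        combo = decompose(index, subset)
        if combo.m == m and m >= 2:
            yield combo
        elif combo.m == m == 1:
            # a single clade is monophyletic, never a polyphyletic combination
            continue


def filter_core_controls(
    tree: dendropy.Tree | TreeIndex,
    combos: Iterable[SpeciesCombination],
    focal_clades: Mapping[str, Iterable[str]],
) -> list[SpeciesCombination]:
    """Keep combinations shaped like the focal polyphyletic trait group.

    A core control has exactly three lineages: two lying inside two
    *distinct* focal clades, and one disjoint from every focal clade.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    clades = {name: frozenset(members) for name, members in focal_clades.items()}
    names = list(clades)
    for a, b in itertools.combinations(names, 2):
        if clades[a] & clades[b]:
            raise ValueError(f"focal clades {a!r} and {b!r} overlap")
    focal_union = frozenset().union(*clades.values())

    kept = []
    for combo in combos:
        if combo.lineages is None:
            combo = decompose(index, combo.species)
        if combo.m != 3:
            continue
        focal_hits: set[str] = set()
        n_outside = 0
        ok = True
        for lineage in combo.lineages:
            ls = set(lineage)
            homes = [nm for nm in names if ls <= clades[nm]]
            if homes:
                focal_hits.update(homes[:1])
            elif not ls & focal_union:
                n_outside += 1
            else:
                ok = False  # straddles a focal clade boundary
                break
        if ok and len(focal_hits) == 2 and n_outside == 1:
            kept.append(combo)
    return kept


@dataclass(frozen=True)
class PhyloFeatures:
    pob: float
    ptb: float
    dtb: float
    dtn: float


def compute_phylo_features(
    tree: dendropy.Tree | TreeIndex, combo: SpeciesCombination
) -> PhyloFeatures:
    """POB, PTB, DTB, DTN for one combination on the tree."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    decomp = lineage_decomposition(index, combo.species)

    pob = 1.0
    for mrca, labs in decomp:
        if mrca.parent_node is None:
            raise FeatureError(
                f"lineage {labs} originates at the tree root; no origin branch"
            )
        length = mrca.edge.length
        if length is None:
            raise FeatureError(f"origin branch of lineage {labs} has no length")
        if length == 0:
            warnings.warn(f"zero-length origin branch for lineage {labs}; POB is 0")
        pob *= length

    ptb = 1.0
    dtb = 0.0
    dtn = 0.0
    for lab in combo.species:
        leaf = index.leaf_node[lab]
        term = leaf.edge.length or 0.0
        ptb *= term
        dtb += index.depth[leaf]
        dtn += index.depth[leaf.parent_node]
    return PhyloFeatures(pob=pob, ptb=ptb, dtb=dtb, dtn=dtn)


def count_combinations(n: int, k: int) -> int:
    """C(n, k); the closed form behind the streaming enumeration."""
    return math.comb(n, k)
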