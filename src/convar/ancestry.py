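"""Ancestral state reconstruction on a fixed rooted tree and
evolutionary-path labeling of target-group variants.

Two reconstruction modes are provided:

- ``parsimony``: unit-cost Sankoff dynamic programming (equivalent to
  Fitch on binary trees, defined on any multifurcation). Every internal
  node gets the set of states attainable in at least one
  most-parsimonious reconstruction, with a uniform posterior over that
  set.
- ``ml``: marginal posteriors under a single-rate, time-reversible
  K-state model with uniform equilibrium frequencies (the K-state
  generalization of Jukes–Cantor), computed by the pruning recursion
  followed by an outside pass and per-node marginalization. Branch
  lengths are in expected substitutions per site.

A variant's evolutionary path is *simple* (parallel) when every target
lineage changed directly from one shared ancestral state to its derived
state on its origin branch, with no differing intermediates below; any
other resolved configuration is *complex* (convergence via
intermediates). Ties in the maximum-a-posteriori state are reported as
unresolved rather than broken arbitrarily, so path labels never depend
on iteration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .combin import TreeIndex, lineage_decomposition
from .core_scan import ScanLevel, SiteProfilePair, SpeciesPartition
from .seqio import Level, MultipleAlignment

_TIE_TOL = 1e-9


class UnresolvableError(ValueError):
    """Column carries no state information (e.g. all-gap)."""


@dataclass
class AncestralStateMap:
    """Per-node posteriors and MAP states for one alignment site."""

    site: int
    states: tuple[str, ...]
    posteriors: dict[dendropy.Node, np.ndarray]
    mode: str

    def posterior(self, node: dendropy.Node) -> dict[str, float]:
        return dict(zip(self.states, self.posteriors[node]))

    def map_state(self, node: dendropy.Node) -> Optional[str]:
        """Maximum-posterior state, or ``None`` on a tie."""
        p = self.posteriors[node]
        order = np.argsort(p)[::-1]
        if len(p) > 1 and p[order[0]] - p[order[1]] <= _TIE_TOL:
            return None
        return self.states[order[0]]


def _leaf_states(
    aln: MultipleAlignment, site: int, level: ScanLevel
) -> dict[str, str]:
    from .core_scan import _state_at  # shared state accessor

    return {sp: _state_at(aln, sp, site, level) for sp in aln.species_ids}


def _column_alphabet(obs: dict[str, str], level: ScanLevel) -> tuple[str, ...]:
    from .core_scan import _is_ambiguous

    states = sorted({s for s in obs.values() if not _is_ambiguous(s, level)})
    if not states or states == ["-"] or states == ["---"]:
        raise UnresolvableError("column has no resolvable states")
    return tuple(states)


def _jc_transition(k: int, t: float) -> np.ndarray:
    """K-state equal-rates transition matrix at branch length ``t``."""
    e = np.exp(-k * t / (k - 1)) if k > 1 else 1.0
    same = 1.0 / k + (k - 1) / k * e
    diff = 1.0 / k - 1.0 / k * e
    return np.full((k, k), diff) + np.eye(k) * (same - diff)


def reconstruct_marginal_states(
    tree: dendropy.Tree,
    aln: MultipleAlignment,
    site: int,
    mode: str = "ml",
    level: ScanLevel | str | None = None,
) -> AncestralStateMap:
    """Reconstruct ancestral states for one site on a fixed rooted tree.

    The state space is the set of unambiguous states observed in the
    column (``-`` included when present); ambiguous leaves contribute a
    flat likelihood. Leaves are included in the returned map with
    point-mass posteriors.
    """
    from .core_scan import _is_ambiguous

    if level is None:
        level = (
            ScanLevel.AMINO_ACID
            if aln.level is Level.AMINO_ACID
            else ScanLevel.NUCLEOTIDE
        )
    level = ScanLevel(level)
    leaves = {n.taxon.label for n in tree.leaf_node_iter()}
    if not leaves <= set(aln.species_ids):
        raise ValueError("tree leaves must be a subset of alignment species")
    obs = {sp: s for sp, s in _leaf_states(aln, site, level).items() if sp in leaves}
    states = _column_alphabet(obs, level)
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}

    if mode not in ("parsimony", "ml"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ml":
        total_len = sum(
            n.edge.length or 0.0
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        if total_len == 0:
            warnings.warn("all branch lengths are 0; falling back to parsimony")
            mode = "parsimony"

    nodes = list(tree.postorder_node_iter())
    posteriors: dict[dendropy.Node, np.ndarray] = {}

    if mode == "parsimony":
        INF = float("inf")
        up: dict[dendropy.Node, np.ndarray] = {}
        for node in nodes:
            if node.is_leaf():
                s = obs[node.taxon.label]
                if _is_ambiguous(s, level):
                    up[node] = np.zeros(k)
                else:
                    v = np.full(k, INF)
                    v[sidx[s]] = 0.0
                    up[node] = v
            else:
                v = np.zeros(k)
                for c in node.child_nodes():
                    # min over child state of (cost + up); unit cost
                    child_min = np.empty(k)
                    cu = up[c]
                    best = cu.min()
                    for i in range(k):
                        child_min[i] = min(cu[i], best + 1.0)
                    v += child_min
                up[node] = v
        down: dict[dendropy.Node, np.ndarray] = {tree.seed_node: np.zeros(k)}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            for c in children:
                sib_sum = np.zeros(k)
                for c2 in children:
                    if c2 is c:
                        continue
                    cu = up[c2]
                    best = cu.min()
                    sib_sum += np.minimum(cu, best + 1.0)
                base = down[node] + sib_sum  # cost by parent state
                cu_best = base.min()
                down[c] = np.minimum(base, cu_best + 1.0)
        for node in nodes:
            total = up[node] + down[node]
            optimal = np.isclose(total, total.min())
            p = optimal.astype(float)
            posteriors[node] = p / p.sum()
    else:
        up_l: dict[dendropy.Node, np.ndarray] = {}
        P: dict[dendropy.Node, np.ndarray] = {}
        for node in nodes:
            if node.parent_node is not None:
                P[node] = _jc_transition(k, node.edge.length or 0.0)
            if node.is_leaf():
                s = obs[node.taxon.label]
                if _is_ambiguous(s, level):
                    up_l[node] = np.ones(k)
                else:
                    v = np.zeros(k)
                    v[sidx[s]] = 1.0
                    up_l[node] = v
            else:
                v = np.ones(k)
                for c in node.child_nodes():
                    v = v * (P[c] @ up_l[c])
                up_l[node] = v
        pi = np.full(k, 1.0 / k)
        out: dict[dendropy.Node, np.ndarray] = {tree.seed_node: pi.copy()}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            msgs = {c: P[c] @ up_l[c] for c in children}
            for c in children:
                sib = out[node].copy()
                for c2 in children:
                    if c2 is not c:
                        sib = sib * msgs[c2]
                out[c] = sib @ P[c]
        for node in nodes:
            m = out[node] * up_l[node]
            total = m.sum()
            if total <= 0:
                raise UnresolvableError("zero marginal likelihood at a node")
            posteriors[node] = m / total

    return AncestralStateMap(site=site, states=states, posteriors=posteriors, mode=mode)


def encode_indels_binary(aln: MultipleAlignment) -> np.ndarray:
    """Presence/absence matrix: 0 where ``-``, 1 otherwise; shape preserved.

    All-gap columns are retained so column indices stay aligned with the
    source alignment.
    """
    return np.array([[0 if c == "-" else 1 for c in row] for row in aln.rows], dtype=int)


@dataclass
class CladeOrigin:
    leaves: tuple[str, ...]
    parent_state: Optional[str]
    derived_state: Optional[str]
    within_clade_ok: Optional[bool]  # None when any relevant MAP is tied


@dataclass
class EvolutionaryPath:
    clades: list[CladeOrigin]
    path_class: str  # simple | complex | unresolved


def classify_path(
    tree: dendropy.Tree,
    part: SpeciesPartition,
    states: AncestralStateMap,
    derived_profile: SiteProfilePair,
) -> EvolutionaryPath:
    """Label a target-group variant's path as simple (parallel) or complex.

    Simple requires (a) identical MAP states at every origin-branch
    parent node and (b) a direct change on each origin branch from that
    shared parent state to the clade's derived state, with every node
    between the clade MRCA and the target leaves already carrying the
    derived state. Ties anywhere relevant yield ``unresolved``.
    """
    index = TreeIndex(tree)
    decomp = lineage_decomposition(index, part.group_a)
    clades: list[CladeOrigin] = []
    complex_proven = False  # resolved evidence against "simple"
    any_tie = False
    parent_states: list[Optional[str]] = []

    for mrca, labs in decomp:
        parent = mrca.parent_node
        if parent is None:
            raise ValueError(f"target lineage {labs} sits at the tree root")
        p_state = states.map_state(parent)
        parent_states.append(p_state)
        if p_state is None:
            any_tie = True

        leaf_map = {states.map_state(index.leaf_node[lab]) for lab in labs}
        leaf_tie = None in leaf_map
        if leaf_tie:
            any_tie = True
            leaf_map.discard(None)
        derived = leaf_map.pop() if len(leaf_map) == 1 else None

        within_ok: Optional[bool]
        if derived is None and len(leaf_map) >= 1:
            # two or more resolved leaf states: clade not fixed for one state
            within_ok = False
            complex_proven = True
        elif derived is None:
            within_ok = None
        else:
            # mismatch anywhere in the clade subtree dominates a tie
            mismatch = False
            tie = False
            stack = [mrca]
            while stack:
                node = stack.pop()
                s = states.map_state(node)
                if s is None:
                    tie = True
                elif s != derived:
                    mismatch = True
                stack.extend(node.child_nodes())
            if mismatch:
                within_ok = False
                complex_proven = True
            elif tie:
                within_ok = None
                any_tie = True
            else:
                within_ok = True
        clades.append(CladeOrigin(labs, p_state, derived, within_ok))

    resolved_parents = {s for s in parent_states if s is not None}
    if len(resolved_parents) > 1:
        complex_proven = True

    if complex_proven:
        path_class = "complex"
    elif any_tie:
        path_class = "unresolved"
    else:
        path_class = "simple"
    return EvolutionaryPath(clades=clades, path_class=path_class)


# ---------------------------------------------------------------------------
# Adapter for externally produced marginal-ancestral-state files
# ---------------------------------------------------------------------------

def read_marginal_ancestral_states(path: str) -> dict[str, str]:
    """Read a ``node-label<whitespace>sequence`` marginal-states file.

    This is the plain-text format emitted by common ML phylogenetics
    tools for marginal ancestral sequences; used only for parity checks
    against the in-package reconstruction.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            label, seq = line.split(None, 1)
            out[label] = seq.replace(" ", "").upper()
    return out


def reinsert_dropped_columns(
    seq: str, kept_columns: Sequence[int], total_length: int, fill: str = "-"
) -> str:
    """Re-expand a reduced ancestral sequence to full alignment coordinates.

    ``kept_columns`` are the 1-based columns the external tool retained
    (it typically drops all-gap columns); dropped columns are filled with
    ``fill``.
    """
    if len(seq) != len(kept_columns):
        raise ValueError("sequence length does not match kept column count")
    out = [fill] * total_length
    for ch, col in zip(seq, kept_columns):
        out[col - 1] = ch
    return "".join(out)
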