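"""Exon-vs-intron tree incongruence screening.

Horizontally transferred introns betray themselves by sitting somewhere else
in the intron genealogy than their host does in the exon genealogy.  This
module quantifies that with the unrooted Robinson-Foulds (RF) distance over
non-trivial bipartitions of the shared leaf set, and ranks "transfer
candidate" leaves greedily: repeatedly drop the leaf whose removal shrinks
the RF distance the most.  Polytomies are allowed; rf_max counts the
bipartitions actually present in both trees.  Likelihood-based topology tests
are deliberately out of scope — this is a combinatorial screen, not a
significance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .io_formats import parse_newick


class CongruenceError(ValueError):
    pass


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return parse_newick(tree)


def _leaf_set(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def nontrivial_bipartitions(tree: dendropy.Tree,
                            leaves: set[str] | None = None) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf subsets.

    Each internal edge splits the leaves into two parts; the part not
    containing the lexicographically smallest leaf is the canonical
    representative.  Trivial splits (single leaf / all-but-one) are dropped.
    """
    all_leaves = leaves if leaves is not None else _leaf_set(tree)
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = {l.taxon.label for l in node.leaf_iter()} & all_leaves
        side = below if anchor not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(frozenset(side))
    return splits


def prune_to_shared(t1: dendropy.Tree | str,
                    t2: dendropy.Tree | str) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Restrict both trees to their shared leaf set (degree-2 nodes suppressed)."""
    t1, t2 = _as_tree(t1), _as_tree(t2)
    shared = _leaf_set(t1) & _leaf_set(t2)
    if not shared:
        raise CongruenceError("trees share no leaves")

    def _prune(tree: dendropy.Tree) -> dendropy.Tree:
        clone = tree.clone(depth=1)
        keep = [t for t in clone.taxon_namespace if t.label in shared]
        clone.retain_taxa(keep)
        return clone

    return _prune(t1), _prune(t2)


def rf_distance(t1: dendropy.Tree | str,
                t2: dendropy.Tree | str) -> tuple[int, int]:
    """Unrooted Robinson-Foulds distance and its maximum on the shared leaves.

    Returns ``(rf, rf_max)`` where rf is the symmetric difference of the
    non-trivial bipartition sets and rf_max is the total number of
    non-trivial bipartitions present in the two (possibly non-binary) trees.
    """
    p1, p2 = prune_to_shared(t1, t2)
    shared = _leaf_set(p1)
    if len(shared) < 4:
        raise CongruenceError(
            f"need >= 4 shared leaves for an informative comparison, "
            f"got {len(shared)}")
    b1 = nontrivial_bipartitions(p1, shared)
    b2 = nontrivial_bipartitions(p2, shared)
    return len(b1 ^ b2), len(b1) + len(b2)


@dataclass
class TransferCandidate:
    leaf: str
    rf_after_removal: int


@dataclass
class CongruenceReport:
    shared_leaves: set[str]
    rf: int
    rf_max: int
    candidates: list[TransferCandidate] = field(default_factory=list)

    @property
    def normalized_rf(self) -> float:
        return self.rf / self.rf_max if self.rf_max else 0.0


def _remove_leaf(tree: dendropy.Tree, leaf: str) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    keep = [t for t in clone.taxon_namespace if t.label != leaf]
    clone.retain_taxa(keep)
    return clone


def transfer_candidates(exon_tree: dendropy.Tree | str,
                        intron_tree: dendropy.Tree | str,
                        max_k: int = 5) -> CongruenceReport:
    """Rank leaves whose removal most reduces exon/intron incongruence.

    Greedy: at each round remove the single leaf minimizing the remaining RF
    distance (ties broken lexicographically); stop at rf 0, when no removal
    helps, when fewer than 5 leaves remain, or after ``max_k`` rounds.  For a
    single regrafted (horizontally transferred) leaf, removing that leaf —
    or its donor — restores congruence, so either tops the ranking.
    """
    t1, t2 = prune_to_shared(exon_tree, intron_tree)
    shared = _leaf_set(t1)
    if len(shared) < 5:
        raise CongruenceError(
            f"need >= 5 shared leaves to rank transfer candidates, "
            f"got {len(shared)}")
    rf, rf_max = rf_distance(t1, t2)
    report = CongruenceReport(shared_leaves=shared, rf=rf, rf_max=rf_max)
    current = rf
    while len(report.candidates) < max_k and current > 0:
        remaining = sorted(_leaf_set(t1))
        if len(remaining) <= 5:
            break
        best_leaf, best_rf = None, current
        for leaf in remaining:
            r1 = _remove_leaf(t1, leaf)
            r2 = _remove_leaf(t2, leaf)
            rf_l, _ = rf_distance(r1, r2)
            if rf_l < best_rf:
                best_leaf, best_rf = leaf, rf_l
        if best_leaf is None:
            break
        t1 = _remove_leaf(t1, best_leaf)
        t2 = _remove_leaf(t2, best_leaf)
        report.candidates.append(TransferCandidate(best_leaf, best_rf))
        current = best_rf
    return report
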