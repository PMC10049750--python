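"""Out-paralog pruning, in-paralog consensus, and occupancy filtering.

Gene trees for each orthologous group (leaf labels ``taxon@seq_id``) are
screened for out-paralogs by selecting the maximally inclusive subtree:
over every rooted subtree induced by directing each edge both ways (plus
the whole tree), the one covering the most distinct taxa is kept, subject
to the constraint that any taxon represented more than once has all its
copies forming a clade inside the subtree (in-paralogs). Remaining
same-taxon duplicates are collapsed to a per-taxon majority-rule
consensus, and groups retaining fewer than the required fraction of taxa
are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)


def parse_leaf_label(label: str) -> tuple[str, str]:
    """Split a ``taxon@seq_id`` leaf label."""
    if "@" not in label:
        raise ValueError(f"leaf label {label!r} does not parse as taxon@seq_id")
    taxon, seq_id = label.split("@", 1)
    return taxon, seq_id


@dataclass
class PrunedGroup:
    """One orthologous group after pruning and consensus."""

    group_id: str
    consensus: dict[str, str]  # taxon -> single sequence
    pruned_leaves: list[str] = field(default_factory=list)
    collapsed_inparalogs: dict[str, list[str]] = field(default_factory=dict)
    had_out_paralogs: bool = False

    @property
    def taxa(self) -> set[str]:
        return set(self.consensus)


# ---------------------------------------------------------------------------
# Support collapse


def collapse_low_support(tree: dendropy.Tree, threshold: float = 0.0) -> dendropy.Tree:
    """Contract internal edges with support below ``threshold``.

    Supports are read from the ``support`` attribute set by the Newick
    reader (internal-node-label dialect) or from numeric node labels.
    ``threshold`` 0 is the identity. Works on a clone; the input tree is
    untouched.
    """
    tree = tree.clone(depth=1)
    if threshold <= 0:
        return tree
    supports = []
    to_collapse = []
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        support = getattr(node, "support", None)
        if support is None and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None:
            supports.append(support)
            if support < threshold:
                to_collapse.append(node)
    if supports:
        dialect_max = 1.0 if max(supports) <= 1.0 else 100.0
        if threshold > dialect_max:
            raise ValueError(
                f"threshold {threshold} exceeds the support dialect range (max {dialect_max})"
            )
    for node in to_collapse:
        node.edge.collapse()
    return tree


# ---------------------------------------------------------------------------
# Maximally inclusive subtree


def _candidate_subtrees(tree: dendropy.Tree) -> list[tuple[frozenset[str], set[frozenset[str]]]]:
    """All induced rooted subtrees as (leaf set, set of clade leaf sets).

    Every node's descendant leaf set is a candidate (the subtree below it
    in the given orientation), whose clades are the descendant sets of
    the nodes inside it. When the input is unrooted (seed node not
    bifurcating) each edge is additionally directed the other way: the
    complement side becomes a candidate rooted at that edge, with clades
    obtained by flipping the ancestor path (the below-set of an ancestor
    ``a`` in the flipped orientation is the complement of the descendant
    set of ``a``'s child on the path).
    """
    nodes = list(tree.preorder_node_iter())
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            s: set[str] = set()
            for child in node.child_nodes():
                s |= below[id(child)]
            below[id(node)] = frozenset(s)
    all_leaves = below[id(tree.seed_node)]

    def subtree_clades(root) -> set[frozenset[str]]:
        stack, out = [root], set()
        while stack:
            v = stack.pop()
            out.add(below[id(v)])
            stack.extend(v.child_nodes())
        return out

    candidates: list[tuple[frozenset[str], set[frozenset[str]]]] = [
        (below[id(v)], subtree_clades(v)) for v in nodes
    ]
    unrooted = len(tree.seed_node.child_nodes()) != 2
    if unrooted:
        for v in nodes:
            if v is tree.seed_node:
                continue
            cand = all_leaves - below[id(v)]
            if not cand:
                continue
            clades: set[frozenset[str]] = {cand}
            # nodes outside v's subtree keep their descendant sets;
            # ancestors of v contribute the flipped complements
            ancestors = set()
            a = v
            while a.parent_node is not None:
                clades.add(all_leaves - below[id(a)])
                ancestors.add(id(a.parent_node))
                a = a.parent_node
            in_subtree = set()
            stack = [v]
            while stack:
                u = stack.pop()
                in_subtree.add(id(u))
                stack.extend(u.child_nodes())
            for u in nodes:
                if id(u) not in in_subtree and id(u) not in ancestors:
                    clades.add(below[id(u)])
            candidates.append((cand, clades))
    return candidates


def max_inclusive_subtree(tree: dendropy.Tree) -> frozenset[str]:
    """Leaf set of the maximally inclusive out-paralog-free subtree.

    A candidate subtree is valid when every taxon represented more than
    once inside it has all its sequences forming a clade of the subtree
    (in-paralogs); the valid candidate covering the most distinct taxa
    wins. Ties break by (more sequences, lexicographically smallest
    sorted leaf-label list). Rooted input is evaluated in its given
    orientation; unrooted input in both directions of every edge.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        return frozenset(leaves)

    def taxon_of(label: str) -> str:
        return parse_leaf_label(label)[0]

    best: tuple | None = None
    for cand, clades in _candidate_subtrees(tree):
        by_taxon: dict[str, set[str]] = {}
        for label in cand:
            by_taxon.setdefault(taxon_of(label), set()).add(label)
        valid = all(
            frozenset(labels) in clades
            for labels in by_taxon.values()
            if len(labels) > 1
        )
        if not valid:
            continue
        key = (-len(by_taxon), -len(cand), tuple(sorted(cand)))
        if best is None or key < best[0]:
            best = (key, cand)
    assert best is not None  # single-leaf candidates are always valid
    return frozenset(best[1])


# ---------------------------------------------------------------------------
# Consensus

_PROT_TIE = "X"
_NUC_TIE = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
            frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}


def consensus_inparalogs(sequences: Sequence[str], alphabet: str = "protein") -> str:
    """Majority-rule consensus of same-taxon in-paralog sequences.

    Unequal-length inputs are first padded to the longest with gaps on
    the right (a deliberately simple anchor; upstream sequences come from
    a shared alignment in normal operation). Column ties give 'X' for
    protein or the IUPAC ambiguity code for nucleotide; gap wins only if
    it is the strict majority.
    """
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        return sequences[0]
    width = max(len(s) for s in sequences)
    padded = [s + "-" * (width - len(s)) for s in sequences]
    out = []
    for col in range(width):
        column = [s[col] for s in padded]
        tally: dict[str, int] = {}
        for c in column:
            tally[c] = tally.get(c, 0) + 1
        top = max(tally.values())
        winners = sorted(c for c, n in tally.items() if n == top)
        if len(winners) == 1:
            out.append(winners[0])
        else:
            residues = [w for w in winners if w != "-"]
            if len(residues) == 1:
                out.append(residues[0])
            elif alphabet == "nucleotide":
                out.append(_NUC_TIE.get(frozenset(residues), "N"))
            else:
                out.append(_PROT_TIE)
    return "".join(out)


# ---------------------------------------------------------------------------
# Occupancy filter and group pruning


def occupancy_filter(
    groups: Sequence[PrunedGroup], total_taxa: int, min_fraction: float = 0.75
) -> list[PrunedGroup]:
    """Keep groups with taxa_present / total_taxa >= min_fraction.

    The boundary is inclusive: a group at exactly the threshold is kept
    ("fewer than" rule discards only strictly below).
    """
    if total_taxa < 1:
        raise ValueError("total_taxa must be >= 1")
    return [g for g in groups if len(g.taxa) / total_taxa >= min_fraction]


def prune_group(
    tree: dendropy.Tree,
    sequences: Mapping[str, str],
    group_id: str = "group",
    support_threshold: float = 0.0,
    alphabet: str = "protein",
) -> PrunedGroup:
    """Full per-group protocol: support collapse, subtree selection, consensus.

    ``sequences`` maps leaf labels (``taxon@seq_id``) to sequences; every
    tree leaf must have one. The result records which leaves were pruned
    (out-paralog evidence) and which in-paralogs were collapsed.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in sequences]
    if missing:
        raise ValueError(f"group {group_id}: sequences missing for leaves {missing}")
    collapsed = collapse_low_support(tree, support_threshold)
    keep = max_inclusive_subtree(collapsed)
    pruned = sorted(set(leaves) - keep)
    by_taxon: dict[str, list[str]] = {}
    for label in sorted(keep):
        taxon, _ = parse_leaf_label(label)
        by_taxon.setdefault(taxon, []).append(label)
    consensus: dict[str, str] = {}
    collapsed_log: dict[str, list[str]] = {}
    for taxon, labels in by_taxon.items():
        seqs = [sequences[l] for l in labels]
        consensus[taxon] = consensus_inparalogs(seqs, alphabet=alphabet)
        if len(labels) > 1:
            collapsed_log[taxon] = labels
    if pruned:
        logger.info("group %s: out-paralog evidence, pruned %d leaves", group_id, len(pruned))
    return PrunedGroup(
        group_id=group_id,
        consensus=consensus,
        pruned_leaves=pruned,
        collapsed_inparalogs=collapsed_log,
        had_out_paralogs=bool(pruned),
    )
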