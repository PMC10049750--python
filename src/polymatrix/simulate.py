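"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here at desk scale:
protein similarity clusters with a controlled mean pairwise identity,
gene families with in- and out-paralogs produced by a duplication/loss
birth-death process on a species tree, transcript-like coding fragments,
and binary traits evolved under ER/ARD Markov models with a configurable
fraction of unknown-state tips.

All generators take an explicit integer seed and use a private
``numpy.random.Generator``; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .submat import AMINO_ACIDS, Cluster

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    """Sense codons per amino acid, standard genetic code."""
    if _CODONS_BY_AA:
        return _CODONS_BY_AA
    from Bio.Data.CodonTable import standard_dna_table

    for codon, aa in standard_dna_table.forward_table.items():
        _CODONS_BY_AA.setdefault(aa, []).append(codon)
    for aa in _CODONS_BY_AA:
        _CODONS_BY_AA[aa].sort()
    return _CODONS_BY_AA


# ---------------------------------------------------------------------------
# Protein clusters


def _mutation_prob_for_identity(target_identity: float) -> float:
    """Per-site substitution probability giving the requested mean identity.

    Each sequence is derived independently from a common ancestor; a site
    mutates with probability m to one of the 19 other residues, uniformly.
    Two derived sequences then match at a site with probability
    ``I(m) = (1-m)^2 + m^2/19``; this inverts that relation for m in [0,1].
    """
    if target_identity >= 1.0:
        return 0.0
    # (1 + 1/19) m^2 - 2 m + (1 - I) = 0; take the root in [0, 1].
    a = 1.0 + 1.0 / 19.0
    b = -2.0
    c = 1.0 - target_identity
    disc = b * b - 4 * a * c
    m = (-b - math.sqrt(disc)) / (2 * a)
    return min(max(m, 0.0), 1.0)


def simulate_cluster(
    n_seqs: int, length: int, target_identity: float, seed: int
) -> Cluster:
    """Generate an aligned, gap-free protein cluster at a target identity.

    The realized mean pairwise identity concentrates around
    ``target_identity`` as length grows (within ~0.05 for length >= 200).
    Deterministic given ``seed``.
    """
    if n_seqs < 2:
        raise ValueError("n_seqs must be >= 2")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    ancestor = rng.integers(0, 20, size=length)
    m = _mutation_prob_for_identity(target_identity)
    members = []
    for i in range(n_seqs):
        seq = ancestor.copy()
        hit = rng.random(length) < m
        # replacement residue uniform among the 19 alternatives
        shift = rng.integers(1, 20, size=length)
        seq[hit] = (seq[hit] + shift[hit]) % 20
        members.append((f"taxon{i}", f"seq{i}", "".join(aas[seq])))
    return Cluster(id=f"sim_cluster_{seed}", members=members)


# ---------------------------------------------------------------------------
# Gene families


@dataclass
class SimulatedFamily:
    """A gene family evolved on a species tree by duplication and loss.

    ``gene_tree`` leaves are labelled ``taxon@copyN``; ``sequences`` maps
    each leaf label to a protein sequence; ``events`` is a reproducible
    log of (kind, species_edge_head, lineage_label) tuples.
    """

    gene_tree: dendropy.Tree
    sequences: dict[str, str]
    events: list[tuple[str, str, str]] = field(default_factory=list)
    cds: dict[str, str] = field(default_factory=dict)

    @property
    def taxa(self) -> set[str]:
        return {label.split("@")[0] for label in self.sequences}


class _GeneLineage:
    __slots__ = ("node", "copy")

    def __init__(self, node, copy):
        self.node = node  # dendropy node in the growing gene tree
        self.copy = copy


def simulate_gene_family(
    species_tree: dendropy.Tree,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    seq_length: int = 120,
    subs_per_unit: float = 0.05,
) -> SimulatedFamily:
    """Evolve a gene family along a species tree under duplication/loss.

    Duplications split a gene lineage into two independently evolving
    copies; losses prune the lineage. With both rates zero the gene tree
    is label-isomorphic to the species tree with one copy per taxon.
    Protein sequences evolve by per-site substitution at ``subs_per_unit``
    expected replacements per unit branch length; matching CDS are
    generated codon-wise so back-translation round-trips.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    events: list[tuple[str, str, str]] = []

    gene_tree = dendropy.Tree()
    root_seq = rng.integers(0, 20, size=seq_length)

    copy_counter: dict[str, int] = {}

    def next_copy(taxon: str) -> int:
        copy_counter[taxon] = copy_counter.get(taxon, 0) + 1
        return copy_counter[taxon]

    # state carried down the species tree: list of (gene_node, sequence)
    leaf_seqs: dict[str, np.ndarray] = {}

    def evolve(seq: np.ndarray, t: float) -> np.ndarray:
        p = 1.0 - math.exp(-subs_per_unit * t)
        out = seq.copy()
        hit = rng.random(len(seq)) < p
        shift = rng.integers(1, 20, size=len(seq))
        out[hit] = (out[hit] + shift[hit]) % 20
        return out

    def walk(sp_node, lineages: list[tuple[dendropy.Node, np.ndarray]]):
        label = _node_label(sp_node)
        for child in sp_node.child_nodes():
            t = child.edge.length or 0.0
            child_lineages: list[tuple[dendropy.Node, np.ndarray]] = []
            for gnode, seq in lineages:
                # simulate dup/loss events along this species branch
                segments = [(gnode, seq, 0.0)]
                survivors = []
                while segments:
                    node, s, t0 = segments.pop()
                    total = dup_rate + loss_rate
                    wait = rng.exponential(1.0 / total) if total > 0 else math.inf
                    if t0 + wait >= t:
                        dt = t - t0
                        nxt = dendropy.Node()
                        nxt.edge.length = (getattr(node, "_pending_len", 0.0)) + dt
                        node.add_child(nxt)
                        survivors.append((nxt, evolve(s, dt)))
                        continue
                    is_dup = rng.random() < (dup_rate / total)
                    s2 = evolve(s, wait)
                    if is_dup:
                        mid = dendropy.Node()
                        mid.edge.length = (getattr(node, "_pending_len", 0.0)) + wait
                        node.add_child(mid)
                        events.append(("duplication", _node_label(child), ""))
                        segments.append((mid, s2, t0 + wait))
                        segments.append((mid, s2.copy(), t0 + wait))
                    else:
                        events.append(("loss", _node_label(child), ""))
                child_lineages.extend(survivors)
            if child.is_leaf():
                taxon = child.taxon.label
                for gnode, s in child_lineages:
                    copy = next_copy(taxon)
                    gnode.taxon = gene_tree.taxon_namespace.new_taxon(
                        label=f"{taxon}@copy{copy}"
                    )
                    leaf_seqs[gnode.taxon.label] = s
            else:
                walk(child, child_lineages)

    sp_root = species_tree.seed_node
    walk(sp_root, [(gene_tree.seed_node, root_seq)])

    # tidy: drop extinct lineages, then suppress degree-2 bookkeeping nodes
    changed = True
    while changed:
        changed = False
        for node in list(gene_tree.leaf_node_iter()):
            if node.taxon is None and node.parent_node is not None:
                node.parent_node.remove_child(node)
                changed = True
    gene_tree.suppress_unifurcations()

    aas = np.array(list(AMINO_ACIDS))
    sequences = {label: "".join(aas[s]) for label, s in leaf_seqs.items()}
    codons = _codon_table()
    cds = {}
    for label, prot in sequences.items():
        picks = rng.integers(0, 8, size=len(prot))
        cds[label] = "".join(
            codons[aa][int(k) % len(codons[aa])] for aa, k in zip(prot, picks)
        )
    return SimulatedFamily(gene_tree=gene_tree, sequences=sequences, events=events, cds=cds)


def _node_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"n{id(node) % 100000}"


# ---------------------------------------------------------------------------
# Binary traits


@dataclass
class RateModel:
    """Two-state Markov rate model: ER (one rate) or ARD (two rates)."""

    kind: str  # "ER" | "ARD"
    q01: float
    q10: float

    @classmethod
    def er(cls, q: float) -> "RateModel":
        return cls("ER", q, q)

    @classmethod
    def ard(cls, q01: float, q10: float) -> "RateModel":
        return cls("ARD", q01, q10)

    @property
    def n_free(self) -> int:
        return 1 if self.kind == "ER" else 2


@dataclass
class SimulatedTraitSet:
    tip_states: dict[str, int]
    true_node_states: dict[str, int]
    model_used: RateModel
    seed: int


def _transition_probs(model: RateModel, t: float) -> np.ndarray:
    from .mkasr import transition_matrix

    return transition_matrix(model, t)


def simulate_binary_trait(
    tree: dendropy.Tree,
    model: RateModel,
    root_state,
    seed: int,
) -> SimulatedTraitSet:
    """Evolve a binary character along a tree under a 2-state Markov chain.

    ``root_state`` is either a fixed state (0 or 1) or a length-2 prior to
    draw it from. Child states are drawn from the exact transition
    probabilities of the chain over each branch, so tip and internal node
    states are exact draws from the model. Deterministic given ``seed``.
    """
    if model.q01 < 0 or model.q10 < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    if isinstance(root_state, (int, np.integer)):
        state = int(root_state)
    else:
        prior = np.asarray(root_state, dtype=float)
        state = int(rng.choice(2, p=prior / prior.sum()))

    node_states: dict[int, int] = {id(tree.seed_node): state}
    tip_states: dict[str, int] = {}
    true_node_states: dict[str, int] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node is tree.seed_node:
            s = state
        else:
            parent_s = node_states[id(node.parent_node)]
            P = _transition_probs(model, node.edge.length or 0.0)
            s = int(rng.random() >= P[parent_s, 0])
            node_states[id(node)] = s
        if node.is_leaf():
            tip_states[node.taxon.label] = s
        else:
            label = node.label or f"node{i}"
            true_node_states[label] = s
    return SimulatedTraitSet(tip_states, true_node_states, model, seed)


def apply_missingness(
    traits: dict[str, int | str], fraction_unknown: float, seed: int
) -> dict[str, int | str]:
    """Recode exactly ``round(fraction * n)`` tips as ``"unknown"``.

    Selection is without replacement and reproducible from ``seed``; the
    input mapping is not modified.
    """
    if not 0.0 <= fraction_unknown <= 1.0:
        raise ValueError("fraction_unknown must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tips = sorted(traits)
    k = int(round(fraction_unknown * len(tips)))
    chosen = set(rng.choice(len(tips), size=k, replace=False).tolist()) if k else set()
    return {
        tip: ("unknown" if i in chosen else traits[tip])
        for i, tip in enumerate(tips)
    }


# ---------------------------------------------------------------------------
# Trees


def simulate_species_tree(
    n_taxa: int, seed: int, mean_branch_length: float = 0.3, prefix: str = "T"
) -> dendropy.Tree:
    """Random rooted binary species tree with exponential branch lengths."""
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    taxa = [f"{prefix}{i:02d}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for label in taxa[:2]:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        tree.seed_node.add_child(node)
        nodes.append(node)
    for label in taxa[2:]:
        # attach to a random existing leaf by splitting it
        target = nodes[rng.integers(0, len(nodes))]
        parent = dendropy.Node()
        grand = target.parent_node
        grand.remove_child(target)
        grand.add_child(parent)
        parent.add_child(target)
        new_leaf = dendropy.Node(taxon=ns.get_taxon(label))
        parent.add_child(new_leaf)
        nodes.append(new_leaf)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(mean_branch_length))
    for i, node in enumerate(tree.preorder_node_iter()):
        if not node.is_leaf():
            node.label = f"N{i}"
    return tree
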