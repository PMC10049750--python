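"""Clade-specific log-odds substitution matrix construction.

Builds a BLOSUM-style amino-acid scoring matrix from curated similarity
clusters: conserved gap-free alignment blocks are extracted, sequences are
down-weighted by single-linkage similarity grouping, weighted residue-pair
frequencies are accumulated, and integer log-odds scores are computed
against the background expectation. The same machinery curates the
core-orthologue cluster set (singleton removal, identity cutoff, reference
taxon selection).

The construction is Henikoff-style throughout: observed pair frequencies
``q_ij``, background frequencies ``p_i = q_ii + sum_{j!=i} q_ij / 2``,
expectations ``e_ii = p_i^2`` and ``e_ij = 2 p_i p_j``, and scores
``s_ij = round(scale * log2(q_ij / e_ij))`` in half-bits by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical residue order used for all 20x20 matrices.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Averaging rules for extended-alphabet rows in emitted matrices.
_AMBIG_PAIRS = {"B": ("N", "D"), "Z": ("Q", "E")}


@dataclass
class Cluster:
    """An aligned set of protein sequences from one similarity cluster.

    ``members`` is a list of (taxon, sequence_id, aligned_sequence); all
    sequences must have the same aligned length.
    """

    id: str
    members: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.id}: no members")
        lengths = {len(seq) for _, _, seq in self.members}
        if len(lengths) != 1:
            raise ValueError(f"cluster {self.id}: unequal aligned lengths {lengths}")

    @property
    def width(self) -> int:
        return len(self.members[0][2])

    @property
    def taxa(self) -> set[str]:
        return {taxon for taxon, _, _ in self.members}

    @property
    def sequences(self) -> list[str]:
        return [seq for _, _, seq in self.members]


@dataclass
class AlignmentBlock:
    """A gap-free run of alignment columns from one cluster."""

    cluster_id: str
    start: int
    end: int  # half-open
    sequences: list[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("block width must be >= 1")
        if any("-" in s for s in self.sequences):
            raise ValueError("block contains gap characters")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PairCounts:
    """Symmetric weighted counts of unordered residue pairs."""

    alphabet: str
    counts: np.ndarray  # (K, K) symmetric, diagonal counts stored once

    @property
    def total(self) -> float:
        return float(np.triu(self.counts).sum())


@dataclass
class SubstitutionMatrix:
    """Integer log-odds scores with their construction metadata."""

    alphabet: str
    scores: np.ndarray  # (K, K) int
    scale: float  # bits divisor, 2 => half-bits
    background: np.ndarray  # p_i
    pseudocount: float = 0.0
    metadata: dict = field(default_factory=dict)

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.alphabet.index(a), self.alphabet.index(b)])

    def expected_score(self) -> float:
        """Mean per-pair score under the background, in score units."""
        p = self.background
        return float(p @ self.scores @ p)

    def as_dict(self) -> dict[tuple[str, str], int]:
        return {
            (a, b): int(self.scores[i, j])
            for i, a in enumerate(self.alphabet)
            for j, b in enumerate(self.alphabet)
        }


# ---------------------------------------------------------------------------
# Cluster curation


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions among columns where neither has a gap."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


def percent_identity(cluster: Cluster) -> float:
    """Mean pairwise identity over all unordered member pairs.

    Positions where either sequence has a gap are ignored per pair.
    Raises on singleton clusters; callers filter those first.
    """
    seqs = cluster.sequences
    if len(seqs) < 2:
        raise ValueError(f"cluster {cluster.id}: percent identity undefined for singleton")
    idents = [pairwise_identity(a, b) for a, b in combinations(seqs, 2)]
    return sum(idents) / len(idents)


def curate_clusters(
    clusters: Iterable[Cluster],
    min_identity: float = 0.70,
    drop_singletons: bool = True,
) -> list[Cluster]:
    """Drop singleton clusters, then clusters below the identity cutoff.

    The cutoff is exclusive: a cluster at exactly ``min_identity`` is
    retained ("less than" rule). Input order is preserved.
    """
    kept = []
    for cluster in clusters:
        if len(cluster.members) < 2:
            if drop_singletons:
                continue
            kept.append(cluster)
            continue
        if percent_identity(cluster) < min_identity:
            continue
        kept.append(cluster)
    return kept


def select_reference_taxon(
    clusters: Sequence[Cluster], priority: Sequence[str] | None = None
) -> tuple[str, int]:
    """Pick the taxon present in the most clusters.

    Ties are broken by the caller-supplied ``priority`` ranking (a
    relatedness ordering), then lexicographically.
    """
    if not clusters:
        raise ValueError("no clusters given")
    counts: dict[str, int] = {}
    for cluster in clusters:
        for taxon in cluster.taxa:
            counts[taxon] = counts.get(taxon, 0) + 1
    rank = {t: i for i, t in enumerate(priority or [])}

    def key(taxon: str):
        return (-counts[taxon], rank.get(taxon, len(rank)), taxon)

    best = min(counts, key=key)
    return best, counts[best]


# ---------------------------------------------------------------------------
# Blocks


def extract_blocks(
    cluster: Cluster, min_width: int = 1, min_column_identity: float = 0.0
) -> list[AlignmentBlock]:
    """Extract maximal conserved, gap-free column runs as blocks.

    A column qualifies if no member has a gap there and, when
    ``min_column_identity > 0``, its majority-residue fraction meets the
    threshold. Runs shorter than ``min_width`` are discarded; blocks are
    returned in start-column order.
    """
    seqs = cluster.sequences
    width = cluster.width
    ok = np.ones(width, dtype=bool)
    for j in range(width):
        column = [s[j] for s in seqs]
        if "-" in column:
            ok[j] = False
            continue
        if min_column_identity > 0:
            top = max(column.count(c) for c in set(column))
            if top / len(column) < min_column_identity:
                ok[j] = False
    blocks = []
    start = None
    for j in range(width + 1):
        if j < width and ok[j]:
            if start is None:
                start = j
        elif start is not None:
            if j - start >= min_width:
                blocks.append(
                    AlignmentBlock(
                        cluster_id=cluster.id,
                        start=start,
                        end=j,
                        sequences=[s[start:j] for s in seqs],
                    )
                )
            start = None
    return blocks


def weight_sequences(
    block: AlignmentBlock, clustering_threshold: float = 0.90
) -> list[float]:
    """Henikoff-style redundancy weights within a block.

    Sequences at pairwise identity >= threshold are grouped by single
    linkage; each sequence gets weight 1/(group size), so each group
    contributes one effective sequence. A threshold above 1 disables
    grouping (all weights 1).
    """
    if not block.sequences:
        raise ValueError("empty block")
    n = len(block.sequences)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if pairwise_identity(block.sequences[i], block.sequences[j]) >= clustering_threshold:
            parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    for i in range(n):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return [1.0 / sizes[find(i)] for i in range(n)]


# ---------------------------------------------------------------------------
# Pair counting and log-odds


def count_pairs(
    blocks: Sequence[AlignmentBlock],
    weights: Sequence[Sequence[float]],
    alphabet: str = AMINO_ACIDS,
    on_unknown: str = "skip",
) -> PairCounts:
    """Accumulate weighted unordered residue-pair counts over block columns.

    For each column, every unordered sequence pair (i < j) contributes
    ``w_i * w_j`` to the count of its residue pair. Residues outside the
    alphabet are skipped with a log entry (or raise if
    ``on_unknown='error'``).
    """
    K = len(alphabet)
    index = {c: k for k, c in enumerate(alphabet)}
    counts = np.zeros((K, K))
    skipped = 0
    for block, w in zip(blocks, weights, strict=True):
        if len(w) != len(block.sequences):
            raise ValueError("weights do not match block sequences")
        for col in range(block.width):
            residues = [s[col] for s in block.sequences]
            for i, j in combinations(range(len(residues)), 2):
                a, b = residues[i], residues[j]
                if a not in index or b not in index:
                    if on_unknown == "error":
                        raise ValueError(f"residue outside alphabet: {a}{b}")
                    skipped += 1
                    continue
                x, y = index[a], index[b]
                contrib = w[i] * w[j]
                counts[x, y] += contrib
                if x != y:
                    counts[y, x] += contrib
    if skipped:
        logger.info("count_pairs: skipped %d non-alphabet residue pairs", skipped)
    return PairCounts(alphabet=alphabet, counts=counts)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def compute_log_odds(
    counts: PairCounts,
    scale: float = 2.0,
    pseudocount: float = 0.0,
) -> SubstitutionMatrix:
    """Turn pair counts into an integer log-odds matrix.

    ``q_ij`` are pair frequencies (with ``pseudocount`` added to every
    unordered cell), ``p_i`` the implied background frequencies, and
    ``s_ij = round(scale * log2(q_ij / e_ij))`` with round-half-away-from-
    zero. Zero-frequency cells at pseudocount 0 are floored at
    ``round(scale * log2(eps))`` with ``eps = 1 / (2 * total)``, keeping
    the matrix finite and monotone in total evidence.
    """
    K = len(counts.alphabet)
    total = counts.total
    if total <= 0:
        raise ValueError("no pair counts")
    n_cells = K * (K + 1) / 2
    denom = total + pseudocount * n_cells
    q = np.zeros((K, K))
    for i in range(K):
        for j in range(i, K):
            q[i, j] = q[j, i] = (counts.counts[i, j] + pseudocount) / denom
    p = np.array([q[i, i] + (q[i].sum() - q[i, i]) / 2.0 for i in range(K)])
    eps = 1.0 / (2.0 * denom)
    floor_score = _round_half_away(scale * math.log2(eps))
    scores = np.zeros((K, K), dtype=int)
    floored = 0
    for i in range(K):
        for j in range(i, K):
            e = p[i] * p[i] if i == j else 2.0 * p[i] * p[j]
            if q[i, j] <= 0.0 or e <= 0.0:
                s = floor_score if e > 0.0 else 0
                floored += 1
            else:
                s = _round_half_away(scale * math.log2(q[i, j] / e))
            scores[i, j] = scores[j, i] = s
    if floored:
        logger.warning(
            "compute_log_odds: %d zero-frequency cells floored at %d", floored, floor_score
        )
    return SubstitutionMatrix(
        alphabet=counts.alphabet,
        scores=scores,
        scale=scale,
        background=p,
        pseudocount=pseudocount,
        metadata={"total_pairs": total, "floor_score": floor_score},
    )


def build_matrix_pipeline(
    clusters: Sequence[Cluster],
    min_block_width: int = 1,
    min_column_identity: float = 0.0,
    clustering_threshold: float = 0.90,
    scale: float = 2.0,
    pseudocount: float = 0.0,
    alphabet: str = AMINO_ACIDS,
) -> SubstitutionMatrix:
    """Blocks -> weights -> pair counts -> log-odds, end to end."""
    if not clusters:
        raise ValueError("no usable blocks: empty cluster list")
    blocks: list[AlignmentBlock] = []
    for cluster in clusters:
        blocks.extend(
            extract_blocks(cluster, min_width=min_block_width,
                           min_column_identity=min_column_identity)
        )
    if not blocks:
        raise ValueError("no usable blocks")
    weights = [weight_sequences(b, clustering_threshold) for b in blocks]
    counts = count_pairs(blocks, weights, alphabet=alphabet)
    logger.info(
        "build_matrix_pipeline: %d blocks, %.1f weighted pairs", len(blocks), counts.total
    )
    matrix = compute_log_odds(counts, scale=scale, pseudocount=pseudocount)
    matrix.metadata["n_blocks"] = len(blocks)
    matrix.metadata["clustering_threshold"] = clustering_threshold
    matrix.metadata["min_column_identity"] = min_column_identity
    return matrix


def extended_alphabet_matrix(matrix: SubstitutionMatrix) -> tuple[str, np.ndarray]:
    """Add B/Z/X/* rows for alignment-tool compatibility.

    B and Z average their constituent residues (N/D and Q/E), X is the
    background-weighted mean score against each residue, and '*' scores
    the floor everywhere except *-* which scores 1.
    """
    base = matrix.alphabet
    ext = base + "BZX*"
    K = len(ext)
    floor = int(matrix.metadata.get("floor_score", matrix.scores.min()))
    out = np.full((K, K), floor, dtype=int)
    out[: len(base), : len(base)] = matrix.scores
    p = matrix.background

    def col_score(i: int, letter: str) -> float:
        if letter in _AMBIG_PAIRS:
            a, b = _AMBIG_PAIRS[letter]
            return (matrix.scores[i, base.index(a)] + matrix.scores[i, base.index(b)]) / 2.0
        if letter == "X":
            return float(p @ matrix.scores[:, i])
        return float(floor)

    for letter in "BZX":
        k = ext.index(letter)
        for i in range(len(base)):
            s = _round_half_away(col_score(i, letter))
            out[i, k] = out[k, i] = s
        # letter-vs-extended cells: average of the averages
        for other in "BZX":
            m = ext.index(other)
            vals = []
            for li in (_AMBIG_PAIRS.get(letter) or base):
                for lj in (_AMBIG_PAIRS.get(other) or base):
                    vals.append(matrix.scores[base.index(li), base.index(lj)])
            out[k, m] = out[m, k] = _round_half_away(float(np.mean(vals)))
    star = ext.index("*")
    out[star, star] = 1
    return ext, out
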