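"""Two-state Mk model fitting and marginal ancestral state reconstruction.

The character is mode of development (state 0 = indirect, with a
free-swimming larval stage; state 1 = direct). Two rate models are fitted
by maximum likelihood on a fixed tree: ER (one symmetric rate q, which
for two states is also the SYM model) and ARD (separate forward q01 and
reverse q10 rates). Model choice is by AICc. Marginal "scaled
likelihoods" at each internal node are the proportions of total
likelihood attributable to each state, computed with an up/down pass of
the Felsenstein pruning algorithm; tips whose state is unknown — or
coded "both" because congeners show both strategies — contribute equal
conditional likelihoods (1, 1) and are therefore likelihood-neutral.

A node's state is called significant when the log-likelihood difference
between the two states is at least 2 (proportional-likelihood rule of
thumb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize

from .simulate import RateModel

STATE_TOKENS = {"indirect": 0, "direct": 1, "0": 0, "1": 1}
AMBIG_TOKENS = {"both", "unknown", "?", "na", ""}

_RESCALE = 1e-120


@dataclass
class TraitTable:
    """Tip observations in {indirect, direct, both, unknown}.

    State indexing is fixed: 0 = indirect, 1 = direct. "both" and
    "unknown" both receive equal tip likelihoods when used in a fit.
    """

    observations: dict[str, str]

    def __post_init__(self) -> None:
        bad = {
            t: o for t, o in self.observations.items()
            if o not in STATE_TOKENS and o.lower() not in AMBIG_TOKENS
        }
        if bad:
            raise ValueError(f"unrecognised observations: {bad}")

    def partial(self, tip: str) -> tuple[float, float]:
        obs = self.observations[tip]
        if obs in STATE_TOKENS:
            return (1.0, 0.0) if STATE_TOKENS[obs] == 0 else (0.0, 1.0)
        return (1.0, 1.0)

    def observed_states(self) -> set[int]:
        return {STATE_TOKENS[o] for o in self.observations.values() if o in STATE_TOKENS}


@dataclass
class MkFit:
    model: RateModel
    lnL: float
    K: int
    n: int
    AICc: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class NodeReconstruction:
    """Per-node scaled-likelihood vectors with significance calls."""

    nodes: dict[str, tuple[float, float]]
    significant: dict[str, bool]
    direction: dict[str, int | None]
    fit: MkFit


# ---------------------------------------------------------------------------
# Trait coding


def code_traits(
    species_records: Sequence[tuple[str, str, str]],
    level: str = "genus",
    overrides: Mapping[str, str] | None = None,
) -> TraitTable:
    """Code tip observations at species or genus level.

    ``species_records`` rows are (species, genus, observed_mode) with
    mode in {indirect, direct, both, unknown}. At genus level a species
    inherits the union of known modes across its congeners: both modes
    present -> "both"; one mode -> that mode; none known -> "unknown".
    Per-tip ``overrides`` (e.g. family-level coding for an undescribed
    species) are applied last.
    """
    if level not in {"genus", "species"}:
        raise ValueError("level must be 'genus' or 'species'")
    by_genus: dict[str, set[str]] = {}
    for species, genus, mode in species_records:
        mode = mode.lower()
        if mode == "both":
            by_genus.setdefault(genus, set()).update({"indirect", "direct"})
        elif mode in {"indirect", "direct"}:
            by_genus.setdefault(genus, set()).add(mode)
        else:
            by_genus.setdefault(genus, set())
    observations: dict[str, str] = {}
    for species, genus, mode in species_records:
        mode = mode.lower()
        if level == "species":
            observations[species] = mode if mode in {"indirect", "direct", "both"} else "unknown"
            continue
        modes = by_genus[genus]
        if modes == {"indirect", "direct"}:
            observations[species] = "both"
        elif len(modes) == 1:
            observations[species] = next(iter(modes))
        else:
            observations[species] = "unknown"
    for tip, value in (overrides or {}).items():
        if tip not in observations:
            raise ValueError(f"override for unknown tip {tip!r}")
        observations[tip] = value
    return TraitTable(observations)


# ---------------------------------------------------------------------------
# Transition probabilities


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the 2-state chain, in closed form.

    Q = [[-q01, q01], [q10, -q10]]; with s = q01 + q10 and
    E = exp(-s t), P00 = (q10 + q01 E)/s and P11 = (q01 + q10 E)/s.
    s = 0 gives the identity.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    q01, q10 = model.q01, model.q10
    s = q01 + q10
    if s == 0.0:
        return np.eye(2)
    E = math.exp(-s * t)
    p00 = (q10 + q01 * E) / s
    p11 = (q01 + q10 * E) / s
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


# ---------------------------------------------------------------------------
# Tree indexing


class TreeIndex:
    """Flat postorder arrays over a dendropy tree for fast pruning.

    Multifurcations are handled natively; zero-length branches give the
    identity transition. Internal nodes without labels get stable
    preorder names ``N0, N1, ...``.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.parent = [
            self.index[id(n.parent_node)] if n.parent_node is not None else -1
            for n in nodes
        ]
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.child_nodes()] for n in nodes
        ]
        self.length = [float(n.edge.length or 0.0) for n in nodes]
        self.is_leaf = [n.is_leaf() for n in nodes]
        self.tip_label = [n.taxon.label if n.is_leaf() else None for n in nodes]
        self.root = self.index[id(tree.seed_node)]
        labels: dict[int, str] = {}
        for k, node in enumerate(tree.preorder_node_iter()):
            i = self.index[id(node)]
            if node.is_leaf():
                labels[i] = node.taxon.label
            else:
                labels[i] = node.label if node.label else f"N{k}"
        self.node_label = labels


def _tip_partials(ti: TreeIndex, traits: TraitTable) -> list[tuple[float, float]]:
    partials: list[tuple[float, float]] = [(1.0, 1.0)] * len(ti.nodes)
    missing = [
        ti.tip_label[i]
        for i in range(len(ti.nodes))
        if ti.is_leaf[i] and ti.tip_label[i] not in traits.observations
    ]
    if missing:
        raise ValueError(f"tips without trait observations: {sorted(missing)}")
    for i in range(len(ti.nodes)):
        if ti.is_leaf[i]:
            partials[i] = traits.partial(ti.tip_label[i])
    return partials


def _up_pass(
    ti: TreeIndex, partials: list[tuple[float, float]], model: RateModel
) -> tuple[list[tuple[float, float]], list[np.ndarray], float]:
    """Postorder conditional likelihoods with underflow rescaling.

    Returns (up partials, per-node P(t) matrices, accumulated log scale).
    """
    P = [transition_matrix(model, ti.length[i]) for i in range(len(ti.nodes))]
    up: list[tuple[float, float]] = list(partials)
    log_scale = 0.0
    for i in range(len(ti.nodes)):  # postorder
        if ti.is_leaf[i]:
            continue
        l0 = l1 = 1.0
        for c in ti.children[i]:
            Pc = P[c]
            u0, u1 = up[c]
            m0 = Pc[0, 0] * u0 + Pc[0, 1] * u1
            m1 = Pc[1, 0] * u0 + Pc[1, 1] * u1
            l0 *= m0
            l1 *= m1
        m = max(l0, l1)
        if 0.0 < m < _RESCALE:
            l0 /= m
            l1 /= m
            log_scale += math.log(m)
        up[i] = (l0, l1)
    return up, P, log_scale


def log_likelihood(
    tree: dendropy.Tree | TreeIndex,
    traits: TraitTable,
    model: RateModel,
    root_prior: Sequence[float] = (0.5, 0.5),
) -> float:
    """Felsenstein pruning log-likelihood of the tip data.

    Unknown/"both" tips enter with partials (1, 1); the root conditional
    likelihoods are combined with ``root_prior``. Returns -inf when the
    data have zero probability.
    """
    ti = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    partials = _tip_partials(ti, traits)
    up, _, log_scale = _up_pass(ti, partials, model)
    r0, r1 = up[ti.root]
    like = root_prior[0] * r0 + root_prior[1] * r1
    if like <= 0.0:
        return -math.inf
    return math.log(like) + log_scale


# ---------------------------------------------------------------------------
# AICc and fitting


def aicc(lnL: float, K: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n}, K={K} (need n > K + 1)")
    return -2.0 * lnL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


_START_GRID = (0.01, 0.05, 0.1, 0.5, 2.0)


def fit_mk(
    tree: dendropy.Tree | TreeIndex,
    traits: TraitTable,
    kind: str = "ER",
    root_prior: Sequence[float] = (0.5, 0.5),
    bounds: tuple[float, float] = (1e-9, 100.0),
    n_starts: int = 5,
    tol: float = 1e-10,
) -> MkFit:
    """Maximum-likelihood Mk fit with multi-start bounded optimisation.

    Rates are optimised on a log scale with L-BFGS-B from ``n_starts``
    deterministic grid starts; the best converged solution wins. AICc
    uses n = number of tips. Data with fewer than two observed states
    are fitted anyway but flagged ``degenerate`` (the rate then runs to
    the lower bound).
    """
    kind = kind.upper()
    if kind not in {"ER", "ARD"}:
        raise ValueError("kind must be 'ER' or 'ARD'")
    ti = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    n_tips = sum(ti.is_leaf)
    K = 1 if kind == "ER" else 2
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    degenerate = len(traits.observed_states()) < 2

    def neg_lnl(x: np.ndarray) -> float:
        if kind == "ER":
            model = RateModel.er(math.exp(x[0]))
        else:
            model = RateModel.ard(math.exp(x[0]), math.exp(x[1]))
        val = log_likelihood(ti, traits, model, root_prior)
        return -val if math.isfinite(val) else 1e18

    starts = [[math.log(q)] * K for q in _START_GRID[:n_starts]]
    if kind == "ARD" and len(starts) >= 2:
        # make the last start asymmetric so the optimiser sees both regimes
        starts[-1] = [math.log(0.5), math.log(0.05)]

    best = None
    n_converged = 0
    for x0 in starts:
        res = minimize(
            neg_lnl,
            np.array(x0),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * K,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if res.success or math.isfinite(res.fun):
            n_converged += res.success
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError(
            f"Mk {kind} fit failed to converge from {len(starts)} starts"
        )
    rates = np.exp(best.x)
    model = RateModel.er(float(rates[0])) if kind == "ER" else RateModel.ard(
        float(rates[0]), float(rates[1])
    )
    lnL = -float(best.fun)
    return MkFit(
        model=model,
        lnL=lnL,
        K=K,
        n=n_tips,
        AICc=aicc(lnL, K, n_tips),
        diagnostics={
            "n_starts": len(starts),
            "n_converged": int(n_converged),
            "degenerate": degenerate,
            "root_prior": tuple(root_prior),
        },
    )


# ---------------------------------------------------------------------------
# Marginal ASR


def marginal_asr(
    tree: dendropy.Tree | TreeIndex,
    traits: TraitTable,
    fit: MkFit,
    root_prior: Sequence[float] = (0.5, 0.5),
    sig_threshold: float = 2.0,
) -> NodeReconstruction:
    """Marginal scaled likelihoods at every internal node (up/down pass).

    For each node the vector is proportional to the total likelihood of
    the data with that node fixed in each state, normalised to sum to 1.
    Significance per node uses :func:`significance_call`.
    """
    ti = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    model = fit.model
    partials = _tip_partials(ti, traits)
    up, P, _ = _up_pass(ti, partials, model)

    n = len(ti.nodes)
    # messages from child c to its parent: M_c[s_parent]
    msg: list[tuple[float, float]] = [(0.0, 0.0)] * n
    for c in range(n):
        if ti.parent[c] < 0:
            continue
        Pc = P[c]
        u0, u1 = up[c]
        msg[c] = (Pc[0, 0] * u0 + Pc[0, 1] * u1, Pc[1, 0] * u0 + Pc[1, 1] * u1)

    down: list[tuple[float, float]] = [(1.0, 1.0)] * n
    down[ti.root] = (float(root_prior[0]), float(root_prior[1]))
    for i in reversed(range(n)):  # preorder over the postorder array
        if ti.is_leaf[i]:
            continue
        d0, d1 = down[i]
        for c in ti.children[i]:
            # sibling product at the parent, excluding c
            s0, s1 = d0, d1
            for w in ti.children[i]:
                if w != c:
                    s0 *= msg[w][0]
                    s1 *= msg[w][1]
            Pc = P[c]
            down[c] = (
                Pc[0, 0] * s0 + Pc[1, 0] * s1,
                Pc[0, 1] * s0 + Pc[1, 1] * s1,
            )

    nodes: dict[str, tuple[float, float]] = {}
    significant: dict[str, bool] = {}
    direction: dict[str, int | None] = {}
    for i in range(n):
        if ti.is_leaf[i]:
            continue
        v0 = up[i][0] * down[i][0]
        v1 = up[i][1] * down[i][1]
        total = v0 + v1
        if total <= 0:
            raise ArithmeticError("zero total likelihood at a node")
        vec = (v0 / total, v1 / total)
        label = ti.node_label[i]
        nodes[label] = vec
        sig, direc = significance_call(vec, threshold=sig_threshold)
        significant[label] = sig
        direction[label] = direc
    return NodeReconstruction(nodes, significant, direction, fit)


def significance_call(
    vector: Sequence[float], threshold: float = 2.0, eps: float = 1e-12
) -> tuple[bool, int | None]:
    """Proportional-likelihood significance: |ln p0 - ln p1| >= threshold.

    Zero entries are clamped at ``eps`` (a zero scaled likelihood is an
    arbitrarily strong call, so the clamp only guards the logarithm).
    Returns (significant, argmax state or None when not significant).
    """
    p0 = max(float(vector[0]), eps)
    p1 = max(float(vector[1]), eps)
    diff = abs(math.log(p0) - math.log(p1))
    if diff >= threshold:
        return True, (0 if p0 > p1 else 1)
    return False, None


def model_select(fits: Sequence[MkFit]) -> MkFit:
    """Lowest AICc wins; ties go to the earlier fit in the given order."""
    if not fits:
        raise ValueError("no fits to select from")
    best = fits[0]
    for fit in fits[1:]:
        if fit.AICc < best.AICc:
            best = fit
    return best


# ---------------------------------------------------------------------------
# Output helpers


def annotate_tree(tree: dendropy.Tree, recon: NodeReconstruction) -> dendropy.Tree:
    """Attach scaled-likelihood vectors as node comments on a tree clone."""
    tree = tree.clone(depth=1)
    ti = TreeIndex(tree)
    for i, node in enumerate(ti.nodes):
        if ti.is_leaf[i]:
            continue
        label = ti.node_label[i]
        if label in recon.nodes:
            p0, p1 = recon.nodes[label]
            node.comments.append(f"p_indirect={p0:.6f},p_direct={p1:.6f}")
    return tree


def reconstruction_rows(recon: NodeReconstruction) -> list[tuple[str, float, float, bool, str]]:
    rows = []
    for label in recon.nodes:
        p0, p1 = recon.nodes[label]
        direc = recon.direction[label]
        rows.append(
            (label, p0, p1, recon.significant[label],
             {0: "indirect", 1: "direct", None: ""}[direc])
        )
    return rows
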