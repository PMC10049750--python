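# Methods

This note documents the models and procedures implemented in
`polymatrix`, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical decisions a maintainer
would want written down.

## Substitution-matrix construction

The matrix is Henikoff-style log-odds over the 20 canonical residues.
Input is a set of aligned protein clusters; curation removes singleton
clusters first and then clusters whose mean pairwise identity is below
70 % (the boundary is inclusive: exactly 70 % is retained, matching a
"less than" removal rule). Percent identity for a pair ignores columns
where either sequence has a gap — standard practice where the source
protocol is silent.

**Blocks.** A block is a maximal run of columns with no gap in any
member. "Conserved" is operationalised as gap-free plus an optional
per-column majority-residue threshold (`min_column_identity`, default 0,
i.e. off); the threshold is recorded in the output metadata so a run's
block definition is always reconstructible.

**Weights.** Within each block, sequences at ≥ 90 % pairwise identity
are grouped by single linkage, and each sequence gets weight 1/(group
size), so a group of near-duplicates contributes one effective sequence.
A threshold above 1 disables grouping, which reduces the procedure to
unweighted counting (used as an equivalence check in the tests).

**Scores.** For pair counts `c_ij` with total `T` and pseudocount `b`
added to every unordered cell, `q_ij = (c_ij + b) / (T + b·K(K+1)/2)`,
`p_i = q_ii + Σ_{j≠i} q_ij / 2`, `e_ii = p_i²`, `e_ij = 2 p_i p_j`, and
`s_ij = round(scale · log2(q_ij / e_ij))` with round-half-away-from-zero
(matching common BLOSUM tooling) and `scale = 2` (half-bits) by default.
Zero-frequency cells at pseudocount 0 are floored at
`round(scale · log2(1 / (2T)))` — finite, and monotone in the total
evidence, so more data pushes the floor lower rather than clipping it.
Emitted matrices add B/Z/X/* rows: B and Z average their constituent
residues (N/D, Q/E), X is the background-weighted mean score, and `*`
scores the floor (with `*`–`*` = 1), so downstream local aligners see a
full alphabet.

## Orthology assignment

The profile search is an **ungapped PSSM scorer, not a profile HMM**:
each alignment column scores residue `a` as the mean substitution score
`s(a, b)` over the non-gap residues `b` observed in that column, and a
query's score is the best ungapped sliding placement against the
profile. This keeps the two-step filtering logic (the contribution)
testable in pure Python; externally produced HMMER per-domain tabular
files can be imported in place of the scorer and flow through identical
filtering.

**E-values** for profile hits come from an empirical null: the query is
shuffled 200 times (seeded), the best window score recomputed, and a
Gumbel (extreme-value) distribution fitted to the null scores; the
E-value is the fitted upper-tail probability, cached per (profile,
query-length bucket of 10).

**Filtering** drops hits with E-value above 1e-5 and keeps the
top-scoring quartile, `ceil(n × 0.25)` rows per orthologous group with
boundary ties retained — the ceiling guarantees a group with any passing
hit keeps at least one. Because the search processes one transcriptome
at a time, the quartile is taken within each taxon's hit list; a
cross-taxon quartile would discard most taxa per group whenever each
taxon contributes about one candidate, which is a property of desk-scale
input rather than of the method. The quartile is recorded on the hit
table and taken once; re-filtering re-applies only the E-value cutoff.

**Reciprocal best hit** accepts a candidate iff (i) its best local
alignment in the reference proteome is the group's reference sequence,
(ii) the reference sequence's best hit among the candidate's own taxon's
sequences is the candidate, and (iii) both alignments pass 1e-5. The
reverse search space is the same-taxon candidate set, mirroring the
intent of a per-species reciprocal test. Alignment E-values use a fixed
Karlin–Altschul-style form `E = K·m·n·e^(−λS)` with `K = 0.1`,
`λ = 0.3`: it is monotone in the score, so best-hit ordering — the part
that carries the orthology decision — is exact, and the analytic form
avoids hundreds of extra alignments per test that an empirical null
would cost.

**Smith–Waterman** is a Gotoh three-layer DP with affine gaps (defaults:
open 11, extend 1 — standard protein values), a zero floor, and a
deterministic traceback preferring diagonal over up over left on ties.
Scores are verified exactly against an independent aligner in the tests.

## Paralog pruning

Gene-tree leaves are `taxon@seq_id`. After optionally contracting edges
below a support threshold (default 0 — no collapse — since the upstream
protocol's default is unstated; both percent and fraction support
dialects are auto-detected), the **maximally inclusive subtree** is
selected: every node's subtree is a candidate (plus, for unrooted input
with a non-bifurcating base, the complement side of every edge,
evaluated rooted at that edge), and a candidate is valid when every
taxon with more than one sequence inside it has all its copies forming a
clade of the candidate in its own orientation. The valid candidate with
the most distinct taxa wins; ties break by more sequences, then the
lexicographically smallest sorted leaf list, making runs reproducible.
Rooted input is evaluated in its given orientation only — enumerating
complements of rooted trees would let a candidate win merely by shaving
one copy of a duplicated taxon off an otherwise intact tree.

Surviving same-taxon duplicates (in-paralogs) are collapsed to a
majority-rule consensus per column; ties give `X` (protein) or the IUPAC
code (nucleotide), and a gap wins only as a strict majority.
Unequal-length inputs are right-padded before voting — a deliberately
simple anchor, as in normal operation the inputs come from one
alignment. Groups retaining fewer than 75 % of the run's taxa are then
discarded (boundary inclusive: 27 of 36 stays, 26 of 36 goes). One
denominator — the run's taxon set — is used wherever the occupancy rule
is applied.

## Supermatrix

Back-translation replaces each aligned residue with its source codon and
each protein gap with `---`, after verifying that the ungapped protein
equals the CDS translation (trailing stop tolerated). Groups concatenate
in lexicographic id order (deterministic across filesystems), absent
taxa are gap-filled, and per-gene column ranges are recorded 0-based
half-open. A codon column survives when at least `min_col_taxa = 4` taxa
have ≥ 1 unambiguous, non-gap nucleotide in the triple (configurable to
require a complete codon). Completeness counts non-gap cells; ambiguity
counts N and partial IUPAC codes; `-` and `?` are gaps and are *not*
counted as ambiguous. Partition files use 1-based inclusive
`start-end\3` strides per codon position per gene range, the convention
of the ML tools that consume them.

## Mk model and ancestral states

The character is binary (0 = indirect, 1 = direct development). The
rate matrix is `Q = [[−q01, q01], [q10, −q10]]`; ER constrains
`q01 = q10` (for two states this is also the symmetric model), ARD
leaves both free. Transition probabilities use the closed form
`P00(t) = (q10 + q01·e^(−st))/s` with `s = q01 + q10` (identity at
`s = 0` or `t = 0`).

The likelihood is Felsenstein pruning over the (possibly multifurcating)
tree with per-node rescaling against underflow. Tips observed in a state
get indicator partials; tips coded **unknown**, and tips coded **both**
because congeners show both modes, get partials (1, 1) — the
equal-likelihood convention — which makes them exactly
likelihood-neutral. Trait coding operates at genus level by default: a
species inherits the union of its congeners' known modes (both → "both",
one → that mode, none → "unknown"), with per-tip overrides for cases
like family-level coding of an undescribed species.

**Fitting** optimises log-rates with L-BFGS-B in bounds [1e-9, 100],
five deterministic grid starts (the last ARD start asymmetric),
convergence 1e-10 on the objective; the best converged start wins.
Degenerate data (one observed state) fit with the rate at the lower
bound and are flagged. AICc uses `n` = number of tips — the conventional
choice for comparative models, reported in the fit so it can be audited.
The **root prior is equal (0.5, 0.5)** by default, matching the default
of the reconstruction tooling this class of analysis typically uses;
stationary or custom priors are accepted and recorded.

**Marginal reconstruction** combines the upward conditional likelihoods
with a downward pass (messages exclude the focal child), giving at each
node a vector proportional to the total likelihood with that node fixed
in each state, normalised to sum to 1 — the "scaled likelihoods". A node
is **significant** when `|ln p0 − ln p1| ≥ 2` (proportional-likelihood
rule of thumb); zero entries are clamped at 1e-12 purely to guard the
logarithm. Model choice is lowest AICc, ties to the first-listed model
(ER before ARD), with the ΔAICc table logged.

## Synthetic data

The generators exist to exercise every stage with known ground truth,
not to be realistic sequence evolution:

- **Clusters**: each member derives independently from one random
  ancestor; a site mutates with probability `m` to a uniform other
  residue, so two members match at a site with probability
  `(1−m)² + m²/19`, which is inverted to hit a target mean identity.
  The realized identity concentrates within ~0.05 of the target for
  lengths ≥ 200 and is monotone in the target at a fixed seed.
- **Gene families**: a birth–death process along the species tree;
  duplications split a lineage into two independently evolving copies,
  losses prune it, and every event is logged. Sequences evolve by
  per-site substitution (0.05 expected replacements per unit branch
  length); matched CDS are drawn codon-wise so back-translation
  round-trips. No rate heterogeneity, no indels, no GTR/LG realism —
  the downstream logic only needs alignable sequences and controllable
  paralogy.
- **Traits**: node states are exact draws from the 2-state chain's
  transition probabilities branch by branch, verified against the
  closed-form probability of discordant tips on two-tip trees.
  Missingness recodes exactly `round(fraction × n)` tips (default
  11/36 ≈ 31 %) chosen without replacement, so fixtures have exact
  counts.

Because clusters are gap-free and mutationally uniform, passing tests
show the counting and log-odds machinery is correct, not that the
matrix equals one built from real curated clusters; likewise the
orthology tests show the filters recover planted ground truth, not
performance on real transcriptome noise (fragmentation, frameshifts,
contamination are out of scope).

## Problem sizes and defaults

The end-to-end demonstration runs 36 taxa for the trait analysis (with
11 unknown tips), 12 matrix clusters of 6 × 240-residue sequences at
92 % identity, and 6 gene families over an 8-taxon subset for the
sequence stages — sizes chosen so a full run finishes in seconds while
every filter still has work to do. The rate-recovery study uses a
500-tip tree, ER `q = 0.1`, 100 replicates; with exponential branch
lengths of mean 0.3 this yields roughly 30 expected transitions per
replicate, enough for the one-parameter rate to be recoverable with a
median relative error well under 20 %.

## Known limitations

- The profile scorer is ungapped; highly fragmented queries that need
  gapped or splice-aware placement are better served by importing
  external hit tables.
- Alignment E-values use fixed Karlin–Altschul constants rather than
  matrix-specific ones; they gate an accept/reject at 1e-5 and should
  not be interpreted as calibrated database E-values.
- Consensus of unaligned in-paralogs uses right-padding, which is only
  sensible for near-identical copies (the in-paralog case by
  construction).
- Hidden rate classes, correlated characters, stochastic character
  mapping and time calibration are out of scope; the Mk machinery is
  single-rate-class ER/ARD only.
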