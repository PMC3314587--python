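# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations behind `ppiloc`, in the spirit of a
package-level methods appendix. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Network model and data handling

The object of study is an undirected PPI graph whose nodes are proteins and
whose edges are physical interactions supported by at least
`min_publications` distinct publications (default 2, the standard
literature-confirmation filter; single-publication interactions are treated
as unreplicated noise). Self-interactions are rejected at parse time and
duplicate observations collapse onto one edge that remembers, per
experiment source, how many distinct publications reported it. Protein
identifiers are opaque, case-sensitive strings (yeast ORF names in
practice); no alias resolution is attempted. When the largest connected
component is requested and two components tie in size, the one containing
the lexicographically smallest identifier is kept — an arbitrary but
deterministic rule; real networks have a unique giant component.

A protein is *uncharacterized* if it has no annotation or carries the
reserved `ambiguous` token. A protein whose annotation mixes the token with
concrete labels is still treated as uncharacterized — the token signals
that the assay could not pin the protein down, so its other labels are not
trusted as training signal — but those labels are surfaced separately so
audits can still compare predictions against them.

## Reliability estimation and weighting

Sources are (experiment system, throughput) groups; systems reported
without a throughput split form single `unsplit` groups. Reliability `r_i`
is estimated from *distinct* annotated pairs (evidence multiplicity is
deliberately ignored: repeated observations of one pair are one datum
about co-localization, many data about the edge's existence). Groups with
no annotated pair fall back to the mean reliability over estimable groups,
with a warning; there is no shrinkage or calibration beyond the empirical
fraction. Inside cross-validation, reliabilities are re-estimated per fold
from training labels only, so the weighting never sees a test label.

The noisy-OR combination is computed in log space
(`1 − exp(Σ n_i log(1−r_i))`) for numerical stability, clamped to [0, 1].
An edge whose weight collapses to 0 (every contributing source fully
unreliable) falls back to weight 1 rather than vanishing, keeping the
weighted and unweighted topologies identical.

The overlap correlation utility computes a Pearson correlation between two
injectable per-edge series; the default pairs the label-set intersection
size with the smaller endpoint label count. Significance testing is out of
scope.

## Predictors

*Tie-breaking everywhere*: higher score first, then lower label index;
ranking ties in evaluation keep protein-ID order. All predictors are
deterministic given (network, annotations, seed).

**Majority** calls up to `max_labels = 3` positive-score labels. The
weighted variant uses the weighted sum both for ranking and for the top-3
cut.

**χ²** uses unweighted hop distance for its σ-neighborhood (σ ∈ {1,2,3});
the statistic has no natural weighted extension, and none is offered.
Labels absent from the training annotations score 0 (logged). Only
over-representation (`n_k > e_k`) scores; depletion is not evidence of
presence.

**GenMultiCut** is solved per label as a binary problem. The objective
rewards (i) agreement along edges between uncharacterized proteins and
(ii) agreement with annotated neighbors. The `h̄` term — rewarding `x_u=0`
for annotated neighbors *not* carrying the label — is included by default
so the problem is a proper two-way cut: without it the all-ones assignment
is never penalized by negative neighbors. A flag (`include_negative=False`)
restores the positive-agreement-only objective. The ILP linearizes the
agreement indicator per U–U edge with one continuous variable `a_e ∈ [0,1]`
and two inequalities `a_e ≤ 1 ± (x_u − x_v)`; since agreement weights are
positive, `a_e` is tight at optimality and integral at binary `x`. HiGHS
(via `scipy.optimize.milp`) solves it exactly; a configurable time limit
raises a per-label error rather than returning a silent incumbent.
Components of the U–U subgraph with no annotated anchor are degenerate
(all-zero and all-one score identically); the all-zero solution is imposed
by post-processing rather than by an objective epsilon, which solver
tolerances would ignore. The local-search solver does seeded single-flip
hill climbing warm-started from the Majority calls; by construction its
objective never exceeds the ILP's. Ranking scores are the agreement mass
`h_u + Σ_{U-U} w_uv x_v` — note this makes the GMC *ranking* closely track
Majority's; the cut structure expresses itself in the calls.

**FunctionalFlow** uses synchronous (Jacobi) rounds. The per-edge capacity
rule is `min(w_uv, (w_uv/Σ_z w_uz) · R(u))` — an infinite reservoir
saturates the edge at its weight, a finite one is split across incident
edges in proportion to their weights, which guarantees a node never ships
more than its reservoir in a round. The rule lives in one small function
(`_edge_flow_capacity`) so it can be swapped. The horizon default `d = 6`
follows the method's convention of propagating roughly half a
yeast-network diameter; on small or dense graphs a smaller `d` is
reasonable and configurable. The call threshold defaults to 0, which makes
the flow classifier call every label with any inflow — recall-heavy by
design; its strength is the ranking.

## Evaluation

Test folds are masked atomically: a multi-label protein's labels are
hidden together, since partial masking would leak. AP is computed on
predictions pooled across folds (per-fold AP is also reported): pooling
stabilizes sparse labels that may lack positives in single folds. MAP
averages only labels with ≥ 1 pooled test positive, and the skipped labels
are listed. Stratified folding (greedy iterative stratification) is
available but not default. The audit categories — exact match, partial
overlap, disjoint, empty prediction — partition all cases by construction.

## Ensemble

Fusion weights are per label (`w_ck = AP_k^c / Σ_c AP_k^c`), fitted from
cross-validation on the labeled proteins and frozen before predicting the
uncharacterized set. Fusion consumes binary calls, not raw scores: the four
score scales (counts, χ² statistics, cut indicators, flow units) are not
commensurable and no principled joint normalization exists; a flag fuses
per-label min–max-normalized scores instead for sensitivity analysis. The
call threshold 0.5 gives weighted-majority semantics. Labels on which every
base classifier has zero AP get uniform weights (logged).

## Synthetic generator

The generator emulates the statistical skeleton of a yeast-scale network:

- 22 compartments with the empirical class-size profile, and a label
  multiplicity mix of 68.8 / 29.6 / 2.2 % for 1 / 2 / ≥3 labels. Label
  *mass* is dealt from a quota pool, so realized label shares match the
  target frequencies up to rounding regardless of the multiplicity mix.
- Edges from a two-component mixture: with probability `p_mix` a
  co-localized pair, else a uniform pair. `p_mix` is solved from the
  Monte-Carlo random-pair co-localization baseline so the expected
  co-localized edge fraction hits the target (default 0.5, within the
  empirically observed 0.4–0.6 band); an infeasible target (below the
  baseline) raises with the feasible range. Rejected draws (duplicates,
  self-pairs) are retried *within* the chosen branch, otherwise placement
  drifts toward the uniform branch as structure fills in.
- Co-localized partners are drawn inside seeded "complex-like" modules of
  4–9 co-members per label, giving each compartment locally clustered
  communities rather than an Erdős–Rényi smear. Only the pairwise
  co-localization fraction is controlled; a full stochastic block model
  over 2²² label sets is deliberately avoided.
- Evidence: 1–3 source groups per edge from 28 groups (12 systems split by
  throughput + 4 unsplit), planted reliabilities evenly spaced in
  [0.3, 0.7]. Groups are assigned by quota so each group's reported-edge
  co-localization fraction equals its planted reliability *exactly* up to
  rounding — "planted" is literal, and recovery error comes only from the
  annotation masking. Every edge carries ≥ 2 distinct publications and so
  survives the default filter.
- 17% of proteins are masked to uncharacterized (the released annotation
  set); ground truth is returned separately. Mean degree defaults to 8,
  the yeast-network figure.

What the generator does **not** emulate: heavy-tailed degree
distributions (the uniform branch gives Poisson-like degrees),
compartment-adjacency structure in the non-co-localized edges, correlated
multi-label combinations, and assay-specific topology (e.g. bait–prey
stars). Consequences measured by the test suite: on these networks the
σ=1 χ² ranking — which normalizes neighbor counts by global label
frequency and is very stable when every neighborhood has ~8 members — is
usually the strongest single ranking, and the global methods (whose gains
on real networks come through multi-hop label coherence and sparse
neighborhoods) do not separate from the local ones in MAP. Passing tests
on this generator therefore validate correctness and calibration of every
component, not the real-data performance ordering of the four classifiers;
the frozen reference fixture captures the local-vs-global behavioral
contrast in a controlled motif instead.

The frozen fixture (58 proteins, 161 interactions, pinned) contains two
dense communities, six scattered "transit" proteins bridging them with a
held-out bridge protein, and a hub whose same-label clique is entirely
masked — the data-sparsity failure mode in which no predictor can recover
the label.

## Numerical and degenerate-input choices

- Noisy-OR in log1p/expm1 space; weights clamped to [0, 1].
- AP is undefined without positives: the label is skipped and excluded
  from MAP rather than imputed.
- Recall for a label with no true positive is reported 0 and flagged.
- Isolated or neighborless proteins get all-zero scores and no calls.
- Floating-point outputs print with 6 significant digits; tests compare
  with tolerances, never string equality.
- All randomness flows from explicit seeds through `numpy` generators; no
  global random state is touched.

## Known limitations

- The GMC ILP is solved once per label; very large unlabeled sets with
  dense U–U structure may need the time limit or the local-search solver.
- The χ² score ignores edge weights by construction.
- The ensemble's binary-vote fusion discards within-classifier score
  resolution; the normalized-score flag is a blunt alternative.
- Reliability estimation assumes source independence (noisy-OR); shared
  publications across sources violate it mildly.
- The generator's scope is calibration and correctness testing, as
  described above — it is not a yeast-network surrogate for benchmarking
  relative classifier performance.
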