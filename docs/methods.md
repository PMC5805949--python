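# Methods

## The model

`iapsim` implements an innovate-and-propagate (IAP) process: a network of
agents who both coin new cultural conventions and re-use old ones, with
re-use governed by a Chinese-restaurant-style rich-get-richer rule.  Each
agent is a "restaurant": a table per convention it knows, with `t_c` tokens
("customers") counting how often the agent has produced convention `c` or
heard it from a neighbour after learning it.  With `M = Σ_c t_c` tokens
stored, one production draws

    P(c)   = t_c / (M + 1)        (re-use)
    P(new) = 1  / (M + 1)         (invention)

which is a concentration-1 CRP.  An invention receives a globally fresh id
and a difficulty class, *Easy* with probability 0.5 and *Hard* otherwise.
Easy conventions (the lexical analogue) are learned from a single exposure;
Hard conventions (the structural analogue) require `hard_exposures`
(default 2) pooled exposures — from the same or different neighbours —
before they are seated as a one-token table.  Pending exposures are never
converted into tokens and never decay; they are erased only by death.

Each iteration every agent speaks exactly once, in a fresh uniformly random
order, delivering its utterance to one uniformly chosen neighbour.  Updates
are asynchronous — a listener can re-use within the iteration what it just
learned — with a `synchronous` option that draws all productions against the
iteration-start repertoires for sensitivity analysis.

Two mutually exclusive loss mechanisms close the dynamics:

* **horizontal** (immortal but forgetful peers): on every token-adding event
  (own production, accepted reception) each previously stored token is
  independently forgotten with probability `p` *before* the new token is
  seated.  Because every sweep accompanies exactly one token gain, the
  per-agent load equilibrates where `M·p = 1`, i.e. `M ≈ 1/p`; the
  acceptance script measures this balance directly.
* **vertical** (mortal peers): no forgetting; after conveying its utterance
  a speaker dies with probability `p` and is replaced in place by a blank
  slate (tokens, pending exposures and history all cleared).

A convention that loses its last token is dropped from the repertoire and
must be relearned from scratch (its exposure count restarts at zero), but it
remains in the agent's `ever_known` history, which is cleared only by death.

## Networks

Agents sit on simple undirected connected graphs whose mean degree follows
the superlinear contact scaling `k = n**(β−1)` with β = 1.677 (so the
smallest population, n = 30, has mean degree 10) and whose average local
clustering coefficient is held near 0.25 at every size, as in empirical
mobile-phone contact networks.  Sampling fixes the edge count at
`m = round(n·k/2)` — the mean degree is exact by construction — and anneals
the clustering: starting from Erdős–Rényi `G(n, m)`, a Metropolis chain over
single-endpoint edge rewirings minimises `(C − C_target)²` under geometric
cooling (T from 1e−4 down to 1e−9 across the step budget), stopping when
`|C − C_target| ≤ tolerance` (default 0.005).  Per-node triangle counts are
maintained incrementally, so a proposal costs O(k) set operations; moves
that would isolate a node are rejected, and in the rare event the final
graph is disconnected the chain restarts from a fresh initial state under a
derived seed.  Non-convergence within `max_steps` (default 2·10⁵ proposals,
scaled up with edge count inside experiment grids) produces a warning flag
in the graph metadata, not an exception.  Clustering is the average *local*
coefficient with degree-<2 nodes contributing 0; the global-transitivity
alternative is indistinguishable at the precision of the published network
table and was not adopted.

## Measures

Three end-of-run measures, split by class, in absolute and relative form:

1. **successful conventions per agent** — currently-held conventions that at
   least one neighbour knows.  "Knows" defaults to the *historical* basis
   (ever learned or generated since the neighbour's last rebirth), matching
   the at-some-point-across-iterations reading; a stricter *current* basis
   (holds now) is always emitted alongside.  The mean runs over all agents,
   empty repertoires included.
2. **population-shared conventions** — conventions currently held by at
   least `ceil(fraction·n)` agents (fraction default 0.10, with a 1e−9 guard
   against float noise in the product).
3. **neighbour sharing** — over all (agent, held-convention) pairs, the mean
   fraction of that agent's neighbours currently holding the convention;
   empty repertoires contribute no pairs rather than zeros.

## Randomness and reproducibility

One seed per run spawns five named child streams (scheduling, production,
class assignment, forgetting, death), so runs are bit-reproducible and
individual mechanisms can be varied in isolation.  The forgetting sweep is
implemented as a Binomial(M, p) draw for the number of losses plus uniform
removal from the flat token store, which reproduces the independent
per-token Bernoulli law exactly at O(k) cost instead of O(M).  Experiment
grids derive per-network and per-run seeds from the base seed through
`numpy.random.SeedSequence` with an index path, so any single run can be
re-executed in isolation.  JSON checkpoints carry agents, registry, network
and the exact RNG stream states, making resumption bit-identical (the flat
token list is serialized in order for this reason).

## Default problem sizes

The full grid reproduces the study conditions: n ∈ {30, 50, 100, 200, 500},
five networks per size, five 1000-iteration runs per condition (run *r* on
network *r*; a crossed design is available via `crossed=True`),
p ∈ {1/500, 1/200}, both transmission modes.  The bundled cross-over test
uses a scaled-down grid — n ∈ {30, 100, 500}, three networks × three runs —
which already resolves the population-size trend cleanly; the trend
statistics are Spearman rank correlations over condition means, with the
cross-over size defined as the smallest n at which the Easy condition mean
exceeds the Hard one.

## What the simulations do and do not show

The generator emulates the *structure* of the study conditions: abstract
conventions with a two-level learnability split, contact networks with
realistic density scaling and clustering, and memory turnover calibrated by
`M·p = 1`.  It does not model semantic content, convention similarity or
compositionality, agent heterogeneity, population growth, or network
rewiring during a run, so passing tests demonstrate the diffusion mechanism
under idealised conditions, not quantitative predictions for real speech
communities.

Within these conditions the relative share of Hard conventions declines
strictly with population size for every measure, both loss modes and both p
values — the direction of the population-size effect is fully robust here.
The share at n = 30 reaches roughly 0.05–0.20 depending on condition, so
Easy conventions remain the majority at every simulated size: with memories
equilibrating at `M = 1/p` tokens, one-exposure learning keeps many
low-count Easy tables alive per agent, and symmetric invention then cannot
push distinct Hard types past distinct Easy types.  An actual majority
cross-over within n ∈ [30, 500] would require a larger gap in learning
thresholds (or smaller memories) than the default 1-vs-2 setting; the
thresholds, class probability and loss rates are all configurable for
exactly this kind of exploration.

## Numerical choices

* Edge counts round half-to-even; the complete graph is returned directly
  when `m` saturates `n(n−1)/2`.
* Production probabilities are exact rationals in
  `production_distribution` (common denominator `M+1`), so normalization
  is exact, while the hot path draws by uniform indexing.
* `relative_split` returns (0, 0) when both class counts are zero; a class
  with no (agent, convention) pairs yields NaN in the neighbour-sharing
  mean rather than a fabricated zero.
* Isolated nodes are a configuration error at start-up, never mid-run.
* Iterations with `p = 0` are legal in both modes (no loss), which the
  no-loss growth tests rely on.
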