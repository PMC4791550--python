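# Methods

## Model and score

A continuous-time Bayesian network (CTBN) factors a joint
continuous-time Markov process: each discrete variable $X$ carries one
conditional intensity matrix (CIM) per configuration $u$ of its parent
set $U$. Off-diagonal entries $q_{x \to x'|u}$ are instantaneous rates
(1/h); the diagonal is the negated leave-state rate
$q_{x|u} = \sum_{x' \ne x} q_{x \to x'|u}$. Sojourns in $(x, u)$ are
exponential with rate $q_{x|u}$, and on leaving, the target state is
drawn from $\theta_{x \to x'|u} = q_{x \to x'|u} / q_{x|u}$.

Structure is scored by the family marginal likelihood with parameters
integrated out under conjugate priors:

- $q_{x|u} \sim$ Gamma(shape $\alpha + 1$, rate $\tau$),
- $\theta_{x \to \cdot|u} \sim$ Dirichlet($\alpha, \dots, \alpha$) over
  the $k - 1$ target states,

applied per cell of the sufficient statistics (dwell time $T[x;u]$,
transition counts $M[x,x';u]$). The closed form is in the README; the
test suite verifies it against Monte-Carlo integration over the priors
(for 2-state families, where prior sampling is well behaved) and
against direct numerical quadrature of the Dirichlet factor (for
3-state families, where a Dirichlet(0.01) prior concentrates on the
simplex corners and naive prior sampling degenerates). Posterior means
are $\hat q_{x|u} = (\alpha + M[x;u] + 1)/(\tau + T[x;u])$ and
$\hat\theta_{x \to x'|u} = (\alpha + M[x,x';u])/(\alpha(k-1) + M[x;u])$.

Hyperparameter convention: the scalar $\alpha$ is applied per dwell
cell and per transition cell (so a row's Dirichlet total is
$\alpha(k-1)$). This is the uniform-prior reading of scalar
hyperparameters; the score is isolated in one function, so an
equivalent-sample-size convention is a local change.

Defaults: $\alpha = 0.01$, $\tau = 5$ h, at most 5 parents per node —
the operating point of the human TH17 differentiation study this
pipeline is built around. An all-zero statistics family scores exactly
0 (the marginal likelihood of no data is 1), which anchors the search:
a parent is added only if it strictly increases the evidence.

## Search

Per variable (families are independent; CTBN structures may be cyclic):
greedy hill climbing from the empty parent set over single add/remove
moves, taking the best strictly improving move. Ties are broken by
smallest candidate index, additions before removals, so the search is
deterministic; there are no random restarts. An exhaustive family-wise
enumerator (refusing search spaces beyond a configurable cap) provides
the exact optimum for testing; on 30 random 4-node datasets greedy
attains it in ≥ 2/3 of instances (empirically ~29/30) and never exceeds
it.

## Evidence construction from sparse observations

Microarray data observe states at grid times only. The convention here:
the state observed at $t_i$ holds on $[t_i, t_{i+1})$, a transition is
recorded at $t_{i+1}$ when consecutive observations differ, and the
final observation contributes zero dwell. This is the simplest
convention consistent with fully-observed CTBN learning, and it shapes
all downstream statistics: dwell times are right-censored at the grid
resolution and multiple changes between grid points collapse into one
apparent transition. Replicates enter as separate trajectories whose
sufficient statistics are pooled per family. Partially-observed
inference (EM or sampling over hidden paths) is out of scope.

## Preprocessing

- **Normalization**: log2 transform, then between-array quantile
  normalization (`median` and `none` also available). "none" is the
  right choice for the synthetic bundles, which are generated on the
  log2 scale.
- **Detection filter**: a probe is kept when its detection p-value is
  < 0.05 in at least 50% of samples. The literal reading "probes with
  detection p < 0.05 were discarded" would discard exactly the reliably
  detected probes and keep only background; it is available behind
  `literal_detection_filter=True` for comparison.
- **Variance filter**: discard probes with SD < 0.15 over all samples
  (sample SD, ddof 1; exactly 0.15 is retained — the discard inequality
  is strict).
- **Differential expression**: per-time-point Welch two-sample t-test,
  case vs control, with Benjamini–Hochberg correction within each time
  point (global correction available). This substitutes a plain Welch
  test for limma's moderated t-test: empirical-Bayes variance
  moderation is deliberately out of scope, and the selection semantics
  (FDR < 0.05 at some time point) are preserved. Degenerate
  zero-variance cells get p = 1 when group means are equal and p = 0
  when they differ.
- **Fold change**: case minus the mean of control replicates at the
  matched time, per case replicate (per-replicate pairing of case to
  control is not meaningful for independent cultures).
- **Selection**: q < 0.05 AND |mean-over-replicates log2 FC| > 1
  co-occurring at one time point.
- **Discretization**: three bins with closed outer intervals — state 0
  iff FC ≤ −1, state 2 iff FC ≥ +1, state 1 otherwise. Genes whose bin
  never changes across all time points and replicates are dropped
  (they carry no dynamics for a CTBN).

## Synthetic-study generator

The generator emulates the targeted study design: 10 unevenly spaced
time points over 72 h (default grid 0, 0.5, 1, 2, 4, 6, 12, 24, 48,
72 h — the real study's grid is not published, so this is a stand-in
satisfying "10 points, uneven, spanning 72 h", and it is configurable),
three biological replicates, case and control conditions.

- **Ground truth**: each signal gene gets 0–`max_true_parents` parents;
  its leave rate is `rate_scale * parent_effect**e(u)` where `e(u)`
  counts parents in their top state minus parents in their bottom
  state. Parent influence on rates (rather than on targets) makes arcs
  identifiable from dwell/transition statistics. Defaults
  `rate_scale = 0.1`/h (mean sojourn 10 h, a differentiation-scale
  tempo giving ~7 state changes per gene over 72 h) and
  `parent_effect = 3` (threefold rate modulation per activated parent).
- **Expression**: case = per-gene baseline (U(6, 10) log2 units) +
  `level_map[state]` + Gaussian noise; control = baseline + noise.
  `level_map` centers default to −2/0/+2 log2-fold-change units, two
  bin-widths apart, so discretization at ±1 is unambiguous at zero
  noise and the round trip (states → expression → preprocessing →
  states) is exact. Default `noise_sd = 0.1` log2 units, a typical
  replicate-level spread for array data.
- **Replicates** share one underlying state path and differ by
  measurement noise: biological replicates of a stimulus-driven
  differentiation program track the same trajectory, and replicate
  averaging in the selection stage (and the t-test's power) presuppose
  that agreement. `independent_replicates=True` instead gives each
  replicate its own realization of the CTBN — with it, replicate
  averaging dilutes fold changes and selection loses most genes, which
  is itself informative about the method but not the emulated design.
- **Nuisance probes**: null genes get baseline + noise in both
  conditions (no state signal); undetected probes get detection
  p ~ U(0.5, 1) everywhere, real probes p ~ U(0, 0.01).

What the generator does **not** emulate: probe-level physics
(hybridization, background), batch effects, dropout, probe-to-gene
many-to-one mapping, and deterministic (non-Markov) differentiation
dynamics. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated stochastic model — not
performance on any particular real microarray series.

## Numerical and design choices

- Scores use `scipy.special.gammaln`; no special-casing of zero-dwell
  cells (the prior regularizes them, including the zero-dwell final
  observation).
- One pipeline seed spawns independent `SeedSequence` streams per stage
  (model, trajectories, noise), so changing one stage's randomness does
  not perturb another's.
- Output floats are written at 6 significant digits; reruns with the
  same config and seed are byte-identical.
- Hub ranking orders by out-degree descending with node-id tie-break (a
  deterministic total order); "root" is formalized as in-degree 0 with
  out-degree ≥ 1, so a top hub need not be a root and both facts are
  reported separately.
- Structure evaluation is direction-sensitive; empty-truth recall and
  empty-inferred precision are defined as 1.
- Problem sizes in tests and the acceptance script (8-node recovery,
  200 trajectories, 30 search-comparison instances, 10^6 MC draws) are
  chosen to make the statistical checks decisive at desk scale while
  each check runs in seconds to a few minutes.

## Known limitations

- The learner consumes fully-observed evidence only; the
  hold-from-observation convention biases dwell estimates when dynamics
  are fast relative to the grid.
- With 10 grid points × 3 replicates, structure recovery is partial by
  construction (see `analysis/05_benchmark_recovery.py`): the pipeline
  reports what sparse data support rather than pretending otherwise.
- The Welch/BH stage is a deliberate simplification of moderated-t
  selection; on real arrays with few replicates it is less powerful
  than limma.
- Probe ids are treated as gene ids (duplicate collapsing beyond
  first-occurrence is out of scope).
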