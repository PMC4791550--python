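# ctbnet — gene regulatory network inference with continuous-time Bayesian networks

`ctbnet` reconstructs gene regulatory networks from case/control
time-course expression data using continuous-time Bayesian networks
(CTBNs). It is aimed at the setting of a stimulus-driven differentiation
experiment — the motivating example is TH17 T-helper-cell polarisation —
measured by microarray at a handful of unevenly spaced time points
(10 points over 72 h, three biological replicates), where the goal is to
read a regulatory hierarchy out of the dynamics: which genes act as
persistent master regulators (hubs and roots of the network), which act
transiently at intermediate levels, and which are pure outputs (leaves,
e.g. cytokines).

## The model

A CTBN is a factored continuous-time Markov process over discrete
variables $X_1, \dots, X_n$. Each variable evolves with a conditional
intensity matrix (CIM) per configuration $u$ of its parents: off-diagonal
entries $q_{x \to x'|u} \ge 0$ (1/h) are instantaneous transition rates
and rows sum to zero. Unlike dynamic Bayesian networks, nothing is
assumed about sampling intervals, which suits unevenly spaced time
courses. Structures may contain cycles, so each variable's parent set is
optimised independently.

Given dwell times $T[x;u]$ and transition counts $M[x,x';u]$
(with $M[x;u] = \sum_{x'} M[x,x';u]$), the marginal likelihood of a
family $(X, U)$ under Gamma$(\alpha+1, \tau)$ priors on intensities and
Dirichlet$(\alpha)$ priors on transition rows is, in log form,

$$
\ln ML_q = \sum_{u,x}\Big[\ln\Gamma(\alpha{+}M[x;u]{+}1) - \ln\Gamma(\alpha{+}1)
+ (\alpha{+}1)\ln\tau - (\alpha{+}M[x;u]{+}1)\ln(\tau{+}T[x;u])\Big]
$$

$$
\ln ML_\theta = \sum_{u,x}\Big[\ln\Gamma(\alpha(k{-}1)) - \ln\Gamma(\alpha(k{-}1){+}M[x;u])
+ \sum_{x'\neq x}\big(\ln\Gamma(\alpha{+}M[x,x';u]) - \ln\Gamma(\alpha)\big)\Big]
$$

The structure score $\ln ML_q + \ln ML_\theta$ decomposes over families;
greedy hill-climbing (add/remove one parent, best strict improvement,
deterministic tie-breaks) optimises each parent set under a cap of 5
parents, with defaults $\alpha = 0.01$, $\tau = 5$ h. An exhaustive
family-wise enumerator serves as an exact reference on small problems.

The expression front end mirrors standard microarray practice: log2
transform and between-array normalization; discard probes not reliably
detected (detection p < 0.05) or with SD < 0.15 over all samples;
per-time-point Welch t-tests with Benjamini–Hochberg correction; keep
genes with q < 0.05 and |log2 fold change| > 1 at the same time point;
discretize fold changes into three bins (≤ −1 / between / ≥ +1); drop
genes whose bin never changes. Each replicate's state series becomes a
piecewise-constant trajectory (a state observed at $t_i$ holds until
$t_{i+1}$) and replicates pool their sufficient statistics.

A synthetic-study generator produces microarray-like case/control
bundles from a known ground-truth CTBN — including null genes and
undetected probes — so the entire pipeline is testable without any
download, and inferred networks can be scored (precision/recall/F1 over
directed arcs) against the truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_learn_network.py
python analysis/04_analyze_network.py
python analysis/05_benchmark_recovery.py
```

Stage 2 prints the probe accounting — 20 probes in, 5 removed as
undetected, 5 as low-SD (the unregulated null genes), 10 selected as
differentially expressed, 0 constant after discretization:

```
input probes:            20
removed (not detected):  5
removed (SD < 0.15):     5
retained after filters:  10
selected (DE & |FC|>1):  10
dropped (constant bin):  0
final genes:             10
```

Stage 4 reads the learned graph as a regulatory hierarchy — the top hub
(here `G002`, out-degree 3, a root: outgoing arcs only) is the
candidate master regulator; leaves receive regulation only:

```
nodes: 10  arcs: 7
hub ranking (gene, out-degree, class):
  G002  3  root
  G005  2  intermediate
  ...
vs ground truth: precision=0.571 recall=0.308 f1=0.400
```

Stage 5 shows the two regimes: with fully observed trajectories the
learner recovers the 8-node ground truth perfectly from 25 trajectories
up (F1 = 1.0), while the microarray-like pipeline — 10 time points,
three replicates, discretized — recovers only part of the structure and
degrades as measurement noise grows (mean F1 0.22 at zero noise down to
0.0 at 1.0 log2-units noise). That gap is the price of sparse
observation, not of the learner.

The same stages are available as a CLI (`ctbnet simulate | preprocess |
learn | analyze | run-all`), driven by a YAML config with one seed;
`run-all` writes a manifest with per-stage counts and is byte-identical
across reruns for a fixed seed.

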