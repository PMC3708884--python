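# Methods

`animaze` simulates the evolution of *animats* — minimal agents with a
12-node binary Markov brain — in procedurally generated planar mazes,
and quantifies the complexity of the evolved circuits with four
information-theoretic measures. This note records the model, the
conventions the implementation fixes where the problem is genuinely
open, the numerical choices, and the limits of what the synthetic setup
can show.

## The world

A maze is a grid corridor of `height` rows and
`(n_walls + 1) * wall_spacing` columns, traversed in the +column
direction. Full lateral walls stand every `wall_spacing` columns, each
pierced by one door at a uniformly random row. Every doorway carries a
one-bit cue, the *door bit*: 1 when the next wall's door lies strictly
in the +row ("right") direction, 0 otherwise; the last wall's bit is 0.
The bit is readable only while the agent stands in the doorway, so
exploiting it requires a one-bit memory. The corridor wraps
horizontally: a forward step from the last column re-enters at column 0
and counts as an *exit*. Rows 0 and `height - 1` behave as walls for
lateral sensing and movement.

Defaults (`height=16`, `n_walls=20`, `wall_spacing=4`, width 84) are
engineering choices: tall enough that finding doors dominates the task,
small enough for desk-scale runs. All are configurable.

Distance-to-exit fields are computed with Dijkstra's algorithm
(scipy's csgraph) on the *reversed* move graph — the agent can step
forward or laterally, never backward — sourced at the exit column. The
test suite checks the field against an independent breadth-first-search
oracle (all edges have unit weight, so BFS is exact).

## The agent

Twelve binary nodes: b0–b2 retina (wall straight ahead, front-left,
front-right), b3 door bit, b4–b5 lateral collision sensors, b6–b9
internal logic, b10–b11 actuators. The actuator pair decodes as
(0,0) stay, (0,1) step +row, (1,0) step −row, (1,1) step forward; a move
into a wall or border is a collision and leaves the position unchanged.
The specific action code assignment is arbitrary and fixed for
reproducibility.

The brain is encoded in a circular byte-string genome. Wherever the
start codon (byte pair 42, 213) occurs, a stochastic logic gate is
expressed: two header bytes give fan-in and fan-out (reduced mod 4 into
1–4), then that many input node ids (mod 12) and output node ids (mod 6,
mapped into b6–b11 — sensors are written by the environment only), then
`2^n_in * 2^n_out` raw table bytes, normalized row-wise (an all-zero row
becomes uniform, so every byte string decodes). Per update, every gate
reads its inputs from the current state and samples one row; writes
combine by OR; unwritten non-sensor nodes fall to 0. The genome layout
and the OR-combination rule follow the common Markov-brain convention;
they are conventions, not derivable facts, and are frozen for
reproducibility.

## Fitness

Every open cell scores `1 − d(p)/d_max`, with `d` the distance to the
exit column and `d_max` its maximum over the maze. A trial places the
agent at a uniform random row of column 0 and runs it for `lifetime`
(default 300) steps; its raw progress is

    (d(p_0) − d(p_T)) + n_exit * d_max,

where the first term removes the offset of the non-zero starting score
and each completed traversal is worth a full `d_max`. Trial fitness is
raw progress divided by the progress of a scripted walker that follows
the distance gradient greedily from the same start (the "optimal
score"), clipped to [0, 1]. Reported fitness is the geometric mean over
10 trial repetitions, with a per-trial floor of 1e−6 so a single zero
trial does not annihilate a genotype's measured fitness. The algebraic
pieces (per-cell score, exit credit, start offset, geometric mean) are a
reconstruction that reproduces all the stated qualitative properties of
the original fitness; the greedy walker defines the normalizer by
construction, so a perfect navigator scores 1.

## Evolution

Populations of 100 (desk scale; 300 at full scale) evolve for
thousands of generations. The fittest genome (*elite*) is copied
byte-for-byte into slot 0 of the next generation; the remaining slots
draw parents with probability proportional to fitness (uniform when all
fitnesses are 0) and mutate the copies. Substitution hits each site
independently at 2.5%. Deletion (5%) and insertion (2.5%) are applied
as per-genome chunk events (chunk length uniform in [16, 256], genome
length clamped to [500, 20000]): applying the quoted rates per site
would shred genomes, so the per-event reading is the default; both
knobs live in `OperatorRates`. The test maze is renewed every 100
generations so agents evolve a general door-seeking rule rather than a
per-maze habit. Reproduction is asexual, so the line of descent (LOD)
of the final fittest agent is a single chain of parent pointers; genome
samples are taken along it every `lod_sample_interval` generations.

## Complexity measures

All measures are computed for the exact brain dynamics or from recorded
activity; nothing is fitted.

* **SMMI** `I(S_t ; M_{t+1})`: plug-in mutual information between the
  six sensor bits and the two motor bits one step later, pooled over all
  within-episode consecutive state pairs of a 20-maze recording battery.
  Bounded by 2 bits.
* **Predictive information** `I(X_t ; X_{t+1})` over full 12-bit states,
  same records; bounded by 12 bits. Estimators are maximum-likelihood
  plug-in with no bias correction; with 6,000 recorded states and the
  concentrated state distributions of real agents the bias is small, but
  it is a known limitation for near-uniform activity.
* **Integrated information (phi)**: from the exact transition model.
  For a node subset, the model conditions out-of-subset inputs at
  maximum entropy (the perturbational convention; a frozen-zero rule is
  available). Effective information of a partition is the uniform
  state-average of the KL divergence between the whole next-state
  repertoire and the product of the parts' independently perturbed
  repertoires. The *minimal information partition* minimizes
  `ei / K(P)` with `K(P) = (m − 1) min_k |M_k|`; phi is the
  **non-normalized** ei at that partition. Ties break toward fewer
  parts, then lexicographically. Exhaustive partition search is used up
  to 8 nodes (Bell(8) = 4140); above that only bipartitions are
  scanned. The *main complex* is the subset with maximal phi: exact
  power-set search inside causal components of up to 6 nodes, greedy
  single-node removal above (greedy descent alone can miss the optimum;
  the exact small-n search is what makes the oracle-equivalence tests
  meaningful). Subsets whose causal graph is disconnected get phi = 0
  without model evaluation — a disconnected cut carries zero effective
  information exactly.
* **Stochastic interaction (atomic phi)**: the effective information at
  the all-singletons partition, computed as
  `sum_i H(X'_i|X_i) − H(X'|X)`.

State averaging defaults to maximum entropy in all phi quantities; an
empirical weighting over observed states is available but not used in
the shipped experiments, since the original convention is perturbational
and the choice is not settled by the source material.

**Numerical shortcut.** Under the uniform state average, every part
repertoire is the uniform-averaged marginal of the whole repertoire, so
the KL cross-terms collapse and

    ei(P) = sum_k H(M'_k | M_k) − H(X' | X)

exactly. The MIP search therefore precomputes one conditional entropy
per submask by a single lattice descent (each part model obtained from a
parent by marginalizing one node) and scores any partition with scalar
sums. `effective_information` keeps the direct KL evaluation; the two
routes are cross-checked to 1e−10 in the tests, as are the
sampled-versus-analytic transition probabilities (4 binomial standard
errors) and the partition enumeration against a restricted-growth-string
oracle.

## Experiments and statistics

A *sweep* evolves `n_histories` histories and measures every LOD sample
on a fresh battery of 20 random mazes (fitness, SMMI, predictive
information, phi of the main complex, atomic phi). Spearman rank
correlation (scipy, average ranks) between fitness and main-complex phi
is reported per history. The headline claim — minimal complexity rises
with fitness — is operationalized as: pool all LOD samples, bin into
fitness quantile deciles (duplicate edges merged), take the per-decile
minimum of each measure, and require it to be non-decreasing up to one
inversion. The tolerance acknowledges that a minimum over a handful of
points per bin is a fragile statistic at desk scale.

Two controls: (1) *no selection* — uniform parent choice from
generation 0, elite copying disabled; (2) *degeneration* — evolve
normally, then switch to uniform parent choice and let the population
drift, comparing LOD fitness before and after.

## Problem sizes

The desk-scale defaults (3 histories x 2,000 generations x population
100, LOD sampled every 200 generations; controls with 5 histories x 400
generations x population 60, drift runs 800 + 400 generations) are
chosen so the full pipeline — including the acceptance script — runs in
minutes on one core while still showing selection-driven fitness gains,
the boundary shape, and the drift collapse. The cluster-scale profile
of the original study (`ExperimentConfig.paper_profile()`: 126 x 60,000
x 300) is supported but not exercised by the shipped tests; quantities
that only emerge at that scale (fitness above 90%, the printed Spearman
values) are out of reach at desk scale and are not asserted.

## What the synthetic setup does and does not show

The generator *is* the study system here — the original experiment is
itself synthetic — so there is no gap between fixture and subject in
that sense. What desk scale cannot show: saturation-level fitness,
dense coverage of the fitness axis, or stable per-history rank
correlations (11 LOD samples give noisy Spearman estimates). The
hand-designed `pathfinder` navigator is a synthetic stand-in for a
near-optimal agent: its published-agent counterpart's connectome is not
available, so only qualitative statements (high fitness, non-zero
integrated information, little excess complexity) should be read from
it. Known limitations: plug-in entropy bias at small sample counts;
bipartitions-only MIP search above 8 nodes is an upper-bound
approximation to the true normalized minimum; the greedy main-complex
search above 6 active nodes can underestimate phi of the true complex.
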