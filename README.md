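# animaze

Evolution of maze-navigating *animats* — minimal agents with a 12-node
binary Markov brain — and the information-theoretic complexity of the
circuits that evolution produces. The package asks a concrete version
of a classic question: how does the *minimal* circuit complexity needed
to reach a given fitness level change as fitness grows?

It is aimed at researchers in artificial life, evolutionary computation,
and integrated-information theory who want a self-contained, exactly
analyzable testbed: the whole experiment (world, genome, brain, genetic
algorithm, measures) is generated in software, and all phi-type
quantities are computed from the exact gate dynamics rather than by
sampling.

## The model in brief

**World.** A planar grid maze crossed left to right, blocked by full
lateral walls each pierced by one random door. Each doorway carries a
one-bit cue: `door_bit = 1` iff the next wall's door lies laterally to
the right. The bit is readable only inside the doorway, so using it
requires a one-bit memory. The maze wraps horizontally; passing the
exit column scores an exit and re-enters at column 0.

**Agent.** Twelve binary nodes `b0..b11`: a 3-bit retina, the door-bit
sensor, two lateral collision sensors, four internal logic units, and
two actuators (stay / left / right / forward). A circular byte-string
genome encodes stochastic logic gates (hidden-Markov-style units):
wherever the start codon appears, fan-in/fan-out, node ids, and a
row-stochastic truth table are read off. Gates fire synchronously;
writes OR together. There is no lifetime learning.

**Evolution.** Populations of agents are scored by how far along the
shortest path they progress: cell score `1 − d(p)/d_max` with `d` the
Dijkstra distance to the exit, trial fitness
`[(d(p_0) − d(p_T)) + n_exit·d_max] / optimal`, and reported fitness
the geometric mean over 10 trials. Selection is elitist and
fitness-proportional, with per-site substitution (2.5%) and per-genome
chunk deletion/insertion (5% / 2.5%); the test maze is renewed every
100 generations. Because reproduction is asexual, the line of descent
(LOD) of the final fittest agent is a single ancestor chain, sampled
periodically for measurement.

**Complexity measures**, each evaluated per LOD sample on a fresh
battery of 20 random mazes:

| measure | definition | bound |
|---|---|---|
| SMMI | `I(S_t ; M_{t+1})`, sensors to motors one step later | 2 bits |
| predictive information | `I(X_t ; X_{t+1})` over full brain states | 12 bits |
| `Φ` (integrated information) | non-normalized effective information at the minimal information partition (MIP) of the exact transition model | 12 bits |
| `Φ_atomic` (stochastic interaction) | effective information at the all-singletons partition, `Σ_i H(X'_i|X_i) − H(X'|X)` | 12 bits |

The *main complex* is the node subset maximizing `Φ`. Effective
information uses uniform perturbational state averaging; partition
search is exhaustive up to 8 nodes (Bell-number growth) and
bipartitions-only above. See `docs/methods.md` for conventions,
numerical shortcuts, and limitations.

## Worked example

Evolve one small history, then measure its line of descent:

```bash
cat > quick.yaml <<EOF
n_histories: 1
n_generations: 300
pop_size: 60
lod_sample_interval: 100
measure_maze_count: 10
EOF
animaze evolve  --config quick.yaml --seed 7 --out run7
animaze measure --lod run7/lod --config quick.yaml --mazes 10 --seed 1 --out run7/measures.csv
animaze report  --measures run7/measures.csv --out run7/plots
```

The measure step prints (this exact output, seeds as above):

```
 generation  fitness  smmi_bits  ipred_bits  phi_atomic_bits  phi_mc_bits     mc_subset
          0 0.003919   0.008732    0.966122         0.074837     0.034810 2,7,8,9,10,11
        100 0.070424   0.061300    1.713944         0.188476     0.188476 0,2,6,8,10,11
        200 0.082026   0.093247    1.741876         0.252030     0.252030 0,2,6,7,10,11
        300 0.002843   0.077419    1.287334         0.341861     0.341861 0,2,6,7,10,11
```

Reading it: over 300 generations fitness climbs from the random-agent
baseline (~0.4%) to ~8% of the optimal path score, and every complexity
measure rises with it — sensors start informing motors (SMMI), state
dynamics become predictable structure (`I_pred`), and an irreducible
sensor-memory-motor core forms (`Φ`, here a 6-node main complex
containing retina, internal, and both motor nodes). The gen-300 dip in
fitness is measurement noise on a fresh maze battery at this small
scale, not a loss of the circuit: `Φ` keeps rising. Longer runs
(`animaze sweep` with the defaults: 3 histories x 2,000 generations x
population 100) push fitness into the tens of percent — 20% to 50%
depending on the seed — with SMMI approaching or exceeding 1 bit;
saturation-level fitness needs the cluster-scale profile.

A hand-designed reference navigator with a one-bit door memory
(`animaze.agents.pathfinder_brain`) reaches ~95% fitness and sits just
above the minimal complexity its fitness requires — a useful anchor at
the top of the fitness axis.

## Layout

```
src/animaze/
  maze.py        maze generation, Dijkstra distance fields, sensing, kinematics
  brain.py       genome decoding, gate dynamics, exact transition models
  evolution.py   fitness, elitist GA, line-of-descent bookkeeping
  info.py        SMMI, predictive information, effective information,
                 MIP search, main complex, stochastic interaction
  experiment.py  sweeps, controls, Spearman and boundary statistics
  agents.py      hand-specified fixture brains (incl. the reference navigator)
  config.py      ExperimentConfig profiles (desk-scale default, cluster-scale)
  cli.py         `animaze evolve | measure | sweep | control | report`
```
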