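# hiersim

Agent-based simulation of how multi-level *advice hierarchies* emerge
spontaneously among self-interested individuals, together with the network
statistics used to quantify flow hierarchy.

## The model

A group of *n* agents lives in an environment that is in one of *l* states
and flips to a random other state with probability *p* between rounds.
Agent *i* guesses the state on its own correctly with probability *a_i*
(its **ability**, drawn once from a configurable distribution and known
only to itself).  Because abilities differ, agents profit from copying
others — but they can only *estimate* who is worth copying.  Agent *i*
tracks, for every potential adviser *j*, the number of rounds *n_ij* it
received information from *j* and the number *s_ij* in which that
information was correct, and summarizes them with the Laplace–Bayes
estimate

&nbsp;&nbsp;&nbsp;&nbsp;*t_ij* = (*s_ij* + 1) / (*n_ij* + *l*),

the **perceived fitness** of *j* (equal to 1/*l* before any contact).
Each round has five phases: agents *nominate* their top
⌈*k*(1 − *a_i*)⌉ advisers by perceived fitness (optionally perturbed by
Gaussian **relative noise** ξ, expressed as a fraction of the mean
ability); advisers *accept* at most *c_j* requesters (their link
capacity), preferring last round's contacts, and rejected requesters fall
back to backup nominees; accepted links *propagate* the adviser's decided
response of the previous round; each agent *decides* by a weighted
plurality of its own fresh guess (weight *a_i*) and the received messages
(weights *t_ij*); and finally the true state is revealed and scores and
trust counters are updated.  Individual scores are exponential moving
averages with half-life λ = 50 rounds; group performance is their mean,
and the **relative improvement** is group performance divided by the mean
ability, minus one.

The directed network of used transfers (adviser → receiver) in one round
is the *communication network*.  Its hierarchy is measured by

* **global reaching centrality** — GRC = Σ_i (C_R^max − C_R(i))/(n − 1),
  where C_R(i) is the fraction of nodes reachable from *i* via directed
  paths (1 for an out-star, ≈ 0 for random graphs), and
* the **normalized largest cycle-free arc set** — the largest number of
  edges kept by any node ordering (found with a greedy source/sink-peeling
  heuristic), normalized against the mean of directed Erdős–Rényi graphs
  with the same *n* and *m*: (F_obs − F_ER)/(m − F_ER).

Fat-tailed ability distributions are modelled with the bounded Pareto law
on [L, H] (density ∝ x^(−α−1)), with (α, L) moment-matched to a requested
mean and variance at H = 1.

## Worked example

```python
import hiersim as hs

cfg = hs.SimConfig(
    n=67, k=3, capacity_low=3, capacity_high=10,
    ability_spec=hs.AbilitySpec(family="bounded_pareto",
                                target_mean=0.25, target_variance=1/48),
    noise_schedule=0.40, rounds=1000, seed=1, compute_forward=False,
)
res = hs.run_simulation(cfg)
final = res.series.iloc[-1]
print(f"group performance  {final['group_perf']:.3f}")
print(f"rel. improvement   {final['rel_improvement']:.1%}")
print(f"GRC                {final['grc']:.3f}")
print(f"average degree     {final['avg_degree']:.3f}")
```

prints

```
group performance  0.365
rel. improvement   45.1%
GRC                0.165
average degree     2.746
```

i.e. after 1000 rounds this 67-agent group answers 45% better than the
same agents would without communication, and its communication network
(about 2.7 used advice links per agent) shows clear reaching-centrality
hierarchy.  Averaging over 20 independent runs of this preset gives
GRC ≈ 0.16, close to the 0.181 reported for the prison social network the
parameters were tuned to mimic (`hiersim experiment real-network
--preset prison` prints the comparison).

The same API drives the bundled experiment presets
(`hiersim.experiments`): an ability-distribution sweep, a transient-noise
protocol, and the four real-network parameterizations (prison friendship,
Liskaland camp, yeast transcriptional regulation, *C. elegans*
metabolism).  A `hiersim` command-line tool exposes `simulate`, `metrics`,
`experiment` and `fit-pareto`.

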