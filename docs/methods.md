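# Methods

## Model definition

`hiersim` simulates *n* agents guessing the state of a changing
environment.  The environment holds one of *l* states (labelled 1..*l*)
and is resampled uniformly from the other *l* − 1 states with probability
*p* between rounds, so advice — which always refers to the previous round
— loses value at rate *p*.  Agent *i* has a fixed ability *a_i* ∈ (0, 1]:
deciding alone, it names the current state with probability *a_i* and a
uniformly random other state otherwise.

Each round consists of five phases executed simultaneously for all
agents:

1. **Nomination.**  Agent *i* ranks the other agents by perceived fitness
   *t_ij* = (*s_ij* + 1)/(*n_ij* + *l*) — the posterior-mean estimate of
   *j*'s usefulness after *n_ij* received messages of which *s_ij* were
   correct, equal to 1/*l* with no history — and requests advice from the
   top *m_i* = ⌈*k*(1 − *a_i*)⌉, listing the next *m_i* as backups.  Under
   relative noise ξ a fresh Gaussian perturbation with standard deviation
   ξ · mean(*a*) is added to each *t_ij* before ranking, each round
   independently; the perturbation is never stored.  All exact ties, here
   and below, are broken uniformly at random from the run's single seeded
   generator.
2. **Acceptance.**  Adviser *j* accepts at most *c_j* requesters (its
   link capacity, drawn once per run uniformly from the integer interval
   [c_low, c_high]), giving absolute priority to agents it was in contact
   with (in either direction) in the previous round and choosing uniformly
   at random within a priority class.  Acceptance runs in two waves:
   primary requests are resolved first against full capacities, then every
   requester contacts one backup per rejection (in nomination order) and
   these are resolved against the remaining capacity.  A rejected backup
   request is not replaced again, so an agent uses at most *m_i* advisers
   per round.
3. **Propagation.**  Each accepted link carries the adviser's *decided
   response of the previous round* (in round 1 nothing is propagated; the
   links are still recorded).
4. **Decision.**  Agent *i* draws a fresh own guess and takes a weighted
   plurality over states: its own guess votes with weight *a_i*, each
   received message with weight *t_ij*.
5. **Feedback.**  The true state is revealed.  Correct agents receive
   score 1, others 0, folded into an exponential moving average with
   half-life λ = 50 rounds (decay β = 2^(−1/λ), initialised at *a_i*,
   which is exactly an infinite pre-history of *a_i*-level feedback).  For
   every received message, *n_ij* is incremented and *s_ij* is
   incremented when the message named the revealed state of the *current*
   round — stale advice from before an environment flip counts as wrong,
   which is the model's price for copying.

The round's *communication network* has an edge adviser → receiver for
every used transfer.  Group performance is the mean EMA score; relative
improvement is group performance over mean ability, minus one.

### Design choices in ambiguous corners

* **Two-wave acceptance.**  With single-pass acceptance (primaries and
  backups competing at once) unused backup requests consume scarce
  adviser capacity; this measurably disperses the emergent structure —
  the prison preset's mean GRC falls from 0.16 to about 0.10 and the
  fat-tailed improvement benchmark loses ~15 percentage points.  The
  two-wave rule implements backups as what they are, replacements for
  rejections.
* **Decided responses propagate**, not raw own guesses.  Propagating raw
  guesses removes transitive copying entirely: hierarchy measures inflate
  (prison GRC ≈ 0.40) while the group improvement collapses to ~65%,
  inconsistent with the behaviour this model is built to exhibit.
* **Round-1 bootstrap.**  There is no round-0 response to forward, so
  round 1 records the negotiated links but decisions use own guesses only
  and no trust counters are updated.
* **Message correctness** is judged against the current round's revealed
  state (not the state the adviser originally guessed at).  Judging
  against the adviser's own round was also tried and produces strictly
  flatter hierarchies.
* **Contact preference** covers both directions of last round's used
  links.
* **Noise scale** is ξ times the realized mean ability of the population,
  fixed at initialization.

## Ability distributions

Four families, all matched to a target mean (default 0.25) and variance
(default 1/48, the variance of the uniform law on [0, 0.5]):

* *constant* — every agent gets the mean;
* *normal* and *log-normal* — parameterized to the untruncated targets,
  with draws outside (0, 1] rejected and redrawn.  Rejection preserves
  the shape inside the support; for the default targets the truncation
  shifts the realized normal mean by < 0.02 and the log-normal one by
  < 0.003 (the tests pin the samples to the truncated laws' closed-form
  moments instead of the nominal targets);
* *bounded Pareto* on [L, H] with density α L^α x^(−α−1) / (1 − (L/H)^α).
  Sampling is by inverse transform (monotone, exact endpoints).  Raw
  moments use the closed form E[X^m] = C·(H^(m−α) − L^(m−α))/(m − α) with
  C = α L^α / (1 − (L/H)^α), switching to the logarithmic limit
  C·ln(H/L) within 1e−9 of the removable singularity m = α.  Fitting
  (α, L) at fixed H = 1 minimizes the two moment residuals with a
  deterministic trust-region least-squares solve from a fixed start in
  (log α, logit L/H) coordinates, so fitted parameters are bit-for-bit
  reproducible; the fit must land within 1e−6 of both targets or an error
  carrying the residuals is raised.  For the default targets it yields
  α ≈ 1.808, L ≈ 0.1357.  Unlike truncating an unbounded power law at H,
  the bounded form places no probability atom at the upper limit.

## Hierarchy metrics

*Local reaching centrality* C_R(i) is the fraction of the other *n* − 1
nodes reachable from *i* along directed paths (sparse BFS per node);
*global reaching centrality* averages C_R^max − C_R(i).  The *largest
cycle-free arc set* is approximated by the greedy peeling heuristic:
repeatedly move zero-in-degree nodes to a front queue and zero-out-degree
nodes to a back queue, and when neither exists move one node maximizing
out-degree − in-degree (lowest index on ties, for reproducibility) to the
front; edges pointing forward in the resulting order are kept.  On DAGs
the peeling is a topological sort and retains every edge; on general
digraphs it keeps at least m/2 edges but is *not* optimal — exhaustive
enumeration finds 4-node digraphs where it keeps one edge fewer than the
brute-force maximum, as expected for a greedy approximation to an NP-hard
problem.  The observed count is normalized against the mean heuristic
count on 1000 directed G(n, m) graphs (uniform over graphs with exactly
*m* arcs, no self-loops): (F_obs − F_ER)/(m − F_ER), which is 1 for DAGs
and ≈ 0 for ER-like graphs.  The ER expectation is a null-model constant:
it is computed with a generator seeded from (n, m) and cached, so
simulation results do not depend on evaluation order.  For very sparse
graphs with m ≤ F_ER the score is reported as 0 with a logged warning.
Self-loops and duplicate edges are discarded by all metrics (a self-loop
can never be a forward arc).

## Experiment presets and problem sizes

* **Distribution sweep** (`run_distribution_sweep`): 256 agents, 1000
  rounds, k = 3, capacities uniform on [2, 7], the four ability families
  at mean 0.25 / variance 1/48, noise levels 0 and 20% by default.  The
  published curves average 500 replicates; the package defaults to 50
  (SE scales with 1/√replicates) and any value can be requested.
  Hierarchy metrics are evaluated on a round stride (default 100) because
  reachability and the ER normalization dominate runtime.
* **Transient noise** (`run_transient_noise`): after a noise-free burn-in
  (default 1000 rounds; the reported round 0 is the converged state), 40%
  relative noise is applied for rounds [500, 3500) and removed; the run
  ends at round 4000.  Trust matrices are captured just before noise
  onset and at the end.  Two robust signatures are tested: the improvement
  in the noisy quasi-stationary window (rounds 600–1600) falls below the
  pre-noise plateau, and the post-noise level (rounds 3600–4000) exceeds
  it.  The degradation window deliberately starts 100 rounds after onset:
  the score EMA (half-life 50) and the cumulative trust counters both
  respond with a lag, so the first ~100 noisy rounds mostly reflect the
  pre-noise structure.
* **Real-network presets** (`run_real_network_preset`): the four
  parameterizations (prison n=67, Liskaland n=71, TRN-Yeast n=688,
  C. elegans n=1173; 5 states, p = 0.1, bounded-Pareto abilities with
  variance 1/48 and preset-specific mean, capacities, k and noise).
  Statistics are the average degree (m/n) and GRC of the round-1000
  snapshot, averaged over independent instances (20 by default; the
  acceptance tests use 10 for the yeast preset, whose instance-to-instance
  spread is an order of magnitude below the comparison tolerance).

All drivers spawn per-replicate generators from one seed sequence, so
(preset, seed) determines every output bit-for-bit.

## What the model reproduces, and known limitations

With the defaults above the package reproduces: the published model-side
average degree and GRC of the prison and Liskaland presets and the yeast
average degree within three printed standard deviations (prison
GRC ≈ 0.16 vs 0.181 ± 0.11; Liskaland ≈ 0.22 vs 0.288 ± 0.09); a mean
relative improvement near 100% for fat-tailed abilities at t = 1000
(≈ 0.97 ± 0.05 over 80 replicates, still rising to ≈ 1.09 by t = 3000 —
convergence here is somewhat slower than the published curves, whose
exact k and capacity settings are not recorded); and the transient-noise
drop/overshoot signatures.

Three honest gaps are worth recording.  First, the yeast preset's GRC
(≈ 0.03 vs 0.158 ± 0.07, i.e. ~1.9 printed sd low) reflects a structural
regime difference: at n = 688 with k = 2, capacities ≤ 3 and only 10%
noise, the converged communication network here is dominated by one giant
strongly connected component — agents echo a circulating consensus, which
keeps every incumbent adviser's perceived fitness high and leaves no
force to re-point links toward intrinsically able agents.  Several
alternative readings of the model's ambiguous corners were evaluated and
made other reproduced quantities worse (see the design-choices section);
the discrepancy is reported rather than tuned away.  Second, the slower
fat-tailed convergence just mentioned.  Third, the greedy forward-arc
heuristic is an approximation: its count can fall below the true maximum
acyclic arc set even on 4-node graphs (it is exact on DAGs and never
below m/2).

The synthetic environment is also idealized in ways real advice networks
are not: abilities are constant in time, the environment is a single
categorical variable with memoryless flips, communication is error-free,
and agents differ only in ability and capacity.  Passing tests therefore
validate the mechanism and its implementation, not the sociology of any
particular real network.
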