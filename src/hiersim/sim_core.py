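"""Five-phase agent-based model of spontaneously emerging advice hierarchies.

A group of n agents repeatedly guesses the state of a changing environment
(one of l states, randomly replaced with a different one with probability p
between rounds).  Agent i guesses correctly on its own with probability
``a_i`` (its *ability*), known only to itself.  Because abilities differ,
agents benefit from copying others — but they can only estimate how good
others are.  Agent i keeps, for every potential adviser j, the counters
``n_ij`` (rounds it received information from j) and ``s_ij`` (rounds that
information was correct), summarized by the *perceived fitness*
``t_ij = (s_ij + 1) / (n_ij + l)`` — the Laplace-Bayes estimate for l
outcomes, equal to 1/l before any interaction.  ``t_ii`` is fixed to
``a_i``.

Each round has five phases:

1. *Nomination*: agent i ranks the others by perceived fitness (plus, under
   noise, a fresh Gaussian perturbation) and requests advice from the top
   ``ceil(k * (1 - a_i))`` of them, nominating an equally long backup list
   in case of rejections.
2. *Acceptance*: agent j accepts at most ``c_j`` requesters (its link
   capacity), preferring those it was in contact with in the previous
   round; remaining requesters are rejected.  Each rejected requester then
   contacts one backup per rejection (in nomination order), resolved
   against the advisers' remaining capacity; a rejected backup request is
   not replaced again.
3. *Propagation*: accepted requests carry the adviser's *decided response
   of the previous round* — advice is always one round stale, which is the
   price of relying on others when the environment may have flipped.
4. *Decision*: agent i draws a fresh own guess (correct with probability
   ``a_i``) and takes a weighted plurality vote: its own guess weighted by
   ``a_i``, each received message weighted by ``t_ij``.  At most
   ``ceil(k * (1 - a_i))`` advisers contribute, taken in nomination
   preference order.
5. *Feedback*: the true state is revealed; correct agents score 1, others
   0 (folded into an exponential moving average), and the ``n_ij`` /
   ``s_ij`` counters of every used transfer are updated.

The directed graph of used transfers (adviser -> receiver) in a round is
the *communication network* whose hierarchy the metrics module measures.

All randomness (including every tie-break) flows from a single seeded
generator, so full trajectories are reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ability_dist import AbilitySpec, sample_abilities
from .hierarchy_metrics import global_reaching_centrality, normalized_forward_fraction
from .perf_metrics import ema_decay, group_performance, relative_improvement

__all__ = [
    "SimConfig",
    "ConfigError",
    "Environment",
    "RoundSnapshot",
    "SimulationResult",
    "Simulation",
    "step_environment",
    "perceived_fitness",
    "nomination_count",
    "nominate",
    "accept",
    "decide",
    "relative_noise_at",
    "run_simulation",
]

#: Tiny uniform perturbation used to break exact ties uniformly at random
#: inside vectorized rankings; far below any meaningful score difference.
_TIE_EPS = 1e-12


class ConfigError(ValueError):
    """Invalid simulation configuration."""


NoiseSchedule = Union[float, Mapping[int, float]]


@dataclass
class SimConfig:
    """All model parameters plus run controls.

    ``noise_schedule`` is either a constant relative-noise level xi or a
    mapping {round -> xi} meaning "from this round on"; xi is the standard
    deviation of the nomination noise as a fraction of the mean ability.
    ``hierarchy_stride`` controls how often the (relatively expensive)
    network-hierarchy metrics are evaluated; the final round is always
    evaluated.
    """

    n: int
    l: int = 5
    p: float = 0.1
    k: int = 3
    capacity_low: int = 2
    capacity_high: int = 7
    ability_spec: AbilitySpec = field(default_factory=AbilitySpec)
    noise_schedule: NoiseSchedule = 0.0
    rounds: int = 1000
    half_life: float = 50.0
    seed: Optional[int] = None
    hierarchy_stride: Optional[int] = None
    er_replicates: int = 1000
    compute_forward: bool = True
    trust_snapshot_rounds: Sequence[int] = ()

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be a positive integer, got {self.n}")
        if self.l < 2:
            raise ConfigError(f"l must be at least 2, got {self.l}")
        if not 0.0 <= self.p <= 1.0:
            raise ConfigError(f"p must lie in [0, 1], got {self.p}")
        if self.k < 0:
            raise ConfigError(f"k must be non-negative, got {self.k}")
        if not 1 <= self.capacity_low <= self.capacity_high:
            raise ConfigError(
                "need 1 <= capacity_low <= capacity_high, got "
                f"[{self.capacity_low}, {self.capacity_high}]"
            )
        if self.rounds < 1:
            raise ConfigError(f"rounds must be positive, got {self.rounds}")
        if self.half_life <= 0:
            raise ConfigError(f"half_life must be positive, got {self.half_life}")
        if self.hierarchy_stride is not None and self.hierarchy_stride < 1:
            raise ConfigError("hierarchy_stride must be a positive integer")
        if isinstance(self.noise_schedule, (int, float)):
            if self.noise_schedule < 0:
                raise ConfigError("noise_schedule must be non-negative")
        else:
            for key, val in self.noise_schedule.items():
                if val < 0:
                    raise ConfigError(f"noise_schedule[{key}] must be non-negative")
        self.ability_spec.validate()


def relative_noise_at(schedule: NoiseSchedule, round_index: int) -> float:
    """Relative noise xi in force at a given round (0 before any breakpoint)."""
    if isinstance(schedule, (int, float)):
        return float(schedule)
    xi = 0.0
    best = None
    for start, val in schedule.items():
        if start <= round_index and (best is None or start > best):
            best, xi = start, float(val)
    return xi


@dataclass
class Environment:
    """The external state the agents try to guess; states are labelled 1..l."""

    state: int
    history: list[int] = field(default_factory=list)


def step_environment(env: Environment, p: float, l: int,
                     rng: np.random.Generator) -> Environment:
    """Flip the state with probability p to a uniformly chosen *other* state."""
    if l < 2:
        raise ConfigError(f"l must be at least 2, got {l}")
    env.history.append(env.state)
    if rng.random() < p:
        new = int(rng.integers(1, l))  # 1..l-1
        env.state = new + (new >= env.state)
    return env


def perceived_fitness(s_ij: int, n_ij: int, l: int) -> float:
    """Laplace-Bayes estimate ``(s_ij + 1) / (n_ij + l)`` of an adviser's ability.

    Equals 1/l with no history, tends to the empirical success rate as the
    history grows, and stays strictly inside (0, 1).
    """
    if l < 2:
        raise ConfigError(f"l must be at least 2, got {l}")
    if not 0 <= s_ij <= n_ij:
        raise ValueError(f"need 0 <= s_ij <= n_ij, got s={s_ij}, n={n_ij}")
    return (s_ij + 1) / (n_ij + l)


def nomination_count(a_i: float, k: int) -> int:
    """Number of advisers agent i asks per round: ``ceil(k * (1 - a_i))``.

    Scales from k for hopeless agents down to 0 for a perfectly able one.
    The half-ulp guard keeps exact integer products from rounding up.
    """
    if not 0.0 < a_i <= 1.0:
        raise ValueError(f"ability must lie in (0, 1], got {a_i}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    return max(0, math.ceil(k * (1.0 - a_i) - 1e-9))


def nominate(
    i: int,
    trust_row: np.ndarray,
    count: int,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
) -> tuple[list[int], list[int]]:
    """Phase 1 for one agent: primary and backup adviser lists.

    Candidates (everyone but i) are ranked by perceived fitness plus, when
    ``noise_sd > 0``, a fresh zero-mean Gaussian perturbation; exact ties
    are broken uniformly at random.  The primary list holds the top
    ``count`` candidates and the backup list the next ``count``, truncated
    to the available n-1 others.
    """
    n = len(trust_row)
    scores = np.asarray(trust_row, dtype=float).copy()
    if noise_sd > 0:
        scores += rng.normal(0.0, noise_sd, n)
    tie = rng.random(n)
    scores[i] = -np.inf
    order = np.lexsort((tie, -scores))
    order = order[order != i][: n - 1]
    count = max(0, min(count, n - 1))
    primary = order[:count]
    backup = order[count: min(2 * count, n - 1)]
    return list(primary), list(backup)


def accept(
    requesters: Sequence[int],
    previous_partners: set[int],
    capacity: int,
    rng: np.random.Generator,
) -> tuple[set[int], set[int]]:
    """Phase 2 for one adviser: keep at most ``capacity`` requesters.

    Requesters who were communication partners in the previous round are
    all accepted before any new one; within each class the choice is
    uniform at random.
    """
    requesters = list(requesters)
    key = np.array([r in previous_partners for r in requesters], dtype=float)
    key += rng.random(len(requesters))
    order = np.argsort(-key, kind="stable")
    keep = max(0, capacity)
    accepted = {requesters[j] for j in order[:keep]}
    rejected = {requesters[j] for j in order[keep:]}
    return accepted, rejected


def decide(
    own_guess: int,
    a_i: float,
    messages: Sequence[tuple[int, float]],
    l: int,
    rng: np.random.Generator,
) -> int:
    """Phase 4 for one agent: weighted plurality over states 1..l.

    ``messages`` is a sequence of (state, weight) pairs, the weight being
    the perceived fitness of the adviser; the own guess votes with weight
    ``a_i``.  Ties are broken uniformly at random.
    """
    votes = np.zeros(l)
    votes[own_guess - 1] += a_i
    for state, weight in messages:
        votes[state - 1] += weight
    best = votes.max()
    winners = np.flatnonzero(votes >= best - 1e-12)
    return int(rng.choice(winners)) + 1


@dataclass
class RoundSnapshot:
    """The communication network and outcomes of one round.

    ``edges`` holds (adviser, receiver) pairs, 0-based, one per used
    information transfer.
    """

    round: int
    state: int
    edges: np.ndarray
    responses: np.ndarray
    correct: np.ndarray

    @property
    def n(self) -> int:
        return len(self.responses)

    @property
    def m(self) -> int:
        return len(self.edges)


class Simulation:
    """Mutable state of one run; :meth:`run_round` advances it one round."""

    def __init__(self, config: SimConfig, rng: Optional[np.random.Generator] = None):
        config.validate()
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        n = config.n
        self.abilities = sample_abilities(config.ability_spec, n, self.rng)
        self.capacities = self.rng.integers(
            config.capacity_low, config.capacity_high + 1, n
        )
        self.ask_budget = np.array(
            [nomination_count(a, config.k) for a in self.abilities], dtype=np.int64
        )
        self.mean_ability = float(self.abilities.mean())
        self.counts_n = np.zeros((n, n), dtype=np.float64)
        self.counts_s = np.zeros((n, n), dtype=np.float64)
        self.scores = self.abilities.copy()
        self.beta = ema_decay(config.half_life)
        self.env = Environment(state=int(self.rng.integers(1, config.l + 1)))
        self.prev_response: Optional[np.ndarray] = None
        # prev_used[j, i] is True when j advised i in the previous round
        self.prev_used = np.zeros((n, n), dtype=bool)
        self.round = 0

    # -- trust ------------------------------------------------------------

    def trust_matrix(self) -> np.ndarray:
        """Perceived-fitness matrix t_ij; the diagonal is the true ability."""
        t = (self.counts_s + 1.0) / (self.counts_n + self.config.l)
        np.fill_diagonal(t, self.abilities)
        return t

    # -- one round ---------------------------------------------------------

    def run_round(self) -> RoundSnapshot:
        cfg, rng = self.config, self.rng
        n, l = cfg.n, cfg.l
        self.round += 1
        t = self.round
        if t > 1:
            step_environment(self.env, cfg.p, l, rng)
        state = self.env.state
        trust = self.trust_matrix()

        # Phase 1: nomination (vectorized over agents).  Each agent ranks
        # the others by (noisy) perceived fitness; the first ask_budget
        # candidates are its primary list, the next ask_budget its backups.
        xi = relative_noise_at(cfg.noise_schedule, t)
        scores = trust.copy()
        if xi > 0:
            scores += rng.normal(0.0, xi * self.mean_ability, (n, n))
        scores += rng.random((n, n)) * _TIE_EPS  # uniform random tie-break
        np.fill_diagonal(scores, -np.inf)
        budget = np.minimum(self.ask_budget, n - 1) if n > 1 else \
            np.zeros(n, dtype=np.int64)
        listed = np.minimum(2 * self.ask_budget, n - 1) if n > 1 else \
            np.zeros(n, dtype=np.int64)
        qmax = int(listed.max()) if n > 1 else 0

        # Phase 2: acceptance in two waves.  Primary requests are resolved
        # against full link capacities; every rejected requester then
        # contacts one backup per rejection, resolved against residual
        # capacity.  Previous-round contacts are preferred in both waves.
        if qmax > 0:
            top = np.argpartition(-scores, qmax - 1, axis=1)[:, :qmax]
            sub = np.take_along_axis(scores, top, axis=1)
            top = np.take_along_axis(top, np.argsort(-sub, axis=1), axis=1)
            contact = self.prev_used | self.prev_used.T
            residual = self.capacities.copy()

            def resolve(req_i, req_j):
                """One acceptance wave: keep at most residual[j] per adviser,
                previous partners first, uniformly at random within a class."""
                if req_i.size == 0:
                    return np.zeros(0, dtype=bool)
                key = contact[req_j, req_i] + rng.random(req_i.size)
                order = np.lexsort((-key, req_j))
                jj = req_j[order]
                rank = np.arange(jj.size) - np.searchsorted(jj, jj)
                acc = np.zeros(req_i.size, dtype=bool)
                acc[order] = rank < residual[jj]
                np.subtract.at(residual, req_j[acc], 1)
                return acc

            cols = np.arange(qmax)[None, :]
            r1_i, p1 = np.nonzero(cols < budget[:, None])
            r1_j = top[r1_i, p1]
            acc1 = resolve(r1_i, r1_j)
            rejections = np.bincount(r1_i[~acc1], minlength=n)
            n_backup = np.minimum(rejections, listed - budget)
            r2_i, p2 = np.nonzero(
                (cols >= budget[:, None]) & (cols < (budget + n_backup)[:, None])
            )
            r2_j = top[r2_i, p2]
            acc2 = resolve(r2_i, r2_j)
            used_i = np.concatenate([r1_i[acc1], r2_i[acc2]])
            used_j = np.concatenate([r1_j[acc1], r2_j[acc2]])
        else:
            used_i = used_j = np.zeros(0, dtype=np.int64)

        # Phase 4: fresh own guess plus weighted plurality over messages.
        own = np.where(
            rng.random(n) < self.abilities,
            state,
            (lambda r: r + (r >= state))(rng.integers(1, l, size=n)),
        )
        votes = np.zeros((n, l))
        votes[np.arange(n), own - 1] += self.abilities
        have_messages = t > 1 and used_i.size > 0
        if have_messages:
            msg = self.prev_response[used_j]  # phase 3: previous-round responses
            np.add.at(votes, (used_i, msg - 1), trust[used_i, used_j])
        votes += rng.random((n, l)) * _TIE_EPS
        response = np.argmax(votes, axis=1) + 1

        # Phase 5: reveal, score, and update the trust counters.
        correct = response == state
        self.scores = self.beta * self.scores + (1.0 - self.beta) * correct
        if have_messages:
            self.counts_n[used_i, used_j] += 1.0
            self.counts_s[used_i, used_j] += msg == state

        used_edges = np.column_stack([used_j, used_i]) if used_i.size else \
            np.zeros((0, 2), dtype=np.int64)
        self.prev_used = np.zeros((n, n), dtype=bool)
        if used_i.size:
            self.prev_used[used_j, used_i] = True
        self.prev_response = response

        return RoundSnapshot(
            round=t,
            state=state,
            edges=used_edges,
            responses=response,
            correct=correct,
        )


@dataclass
class SimulationResult:
    """Per-round performance series, strided hierarchy metrics and final state."""

    config: SimConfig
    series: pd.DataFrame
    snapshots: dict[int, RoundSnapshot]
    trust_snapshots: dict[int, np.ndarray]
    abilities: np.ndarray
    capacities: np.ndarray
    final_trust: np.ndarray

    @property
    def final_snapshot(self) -> RoundSnapshot:
        return self.snapshots[self.config.rounds]


def run_simulation(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimulationResult:
    """Run a full simulation and collect performance and hierarchy series.

    Group performance and relative improvement are recorded every round;
    GRC, normalized forward-arc fraction and average degree are evaluated
    at multiples of ``config.hierarchy_stride`` (always including the final
    round), on the communication network of that round.  Identical configs
    and seeds give bit-identical results.
    """
    sim = Simulation(config, rng)
    cfg = config
    stride = cfg.hierarchy_stride
    hier_rounds = {cfg.rounds}
    if stride is not None:
        hier_rounds.update(range(stride, cfg.rounds + 1, stride))
    baseline = sim.mean_ability
    rows = []
    snapshots: dict[int, RoundSnapshot] = {}
    trust_snaps: dict[int, np.ndarray] = {}
    want_trust = set(cfg.trust_snapshot_rounds)
    for t in range(1, cfg.rounds + 1):
        snap = sim.run_round()
        gp = group_performance(sim.scores)
        row = {
            "round": t,
            "group_perf": gp,
            "rel_improvement": relative_improvement(gp, baseline),
            "grc": np.nan,
            "forward_frac": np.nan,
            "avg_degree": np.nan,
        }
        if t in hier_rounds:
            graph = (cfg.n, snap.edges)
            row["grc"] = global_reaching_centrality(graph) if cfg.n >= 2 else 0.0
            if cfg.compute_forward:
                row["forward_frac"] = normalized_forward_fraction(
                    graph, replicates=cfg.er_replicates
                )
            row["avg_degree"] = snap.m / cfg.n
            snapshots[t] = snap
        if t in want_trust:
            trust_snaps[t] = sim.trust_matrix()
        rows.append(row)
    series = pd.DataFrame(rows, columns=[
        "round", "grc", "forward_frac", "avg_degree", "group_perf",
        "rel_improvement",
    ])
    return SimulationResult(
        config=cfg,
        series=series,
        snapshots=snapshots,
        trust_snapshots=trust_snaps,
        abilities=sim.abilities,
        capacities=sim.capacities,
        final_trust=sim.trust_matrix(),
    )
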