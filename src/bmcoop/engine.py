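"""Synchronous round-based simulation of BM learners in social dilemmas.

Each round of the networked prisoner's dilemma proceeds in lock-step: every
player reveals an action drawn from its current (error-corrupted)
cooperation probability, payoffs are computed as the pairwise payoff
averaged over neighbors, and every learner then updates its propensity from
its own payoff alone.  The public goods game runs the continuous-action
variant in independent groups.  Ensembles are vectorized over runs and
players; every source of randomness derives from a single master seed via
``numpy.random.SeedSequence`` spawning, so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Union

import numpy as np
import pandas as pd

from .learning import (
    HARD,
    LearnerParams,
    PayoffMatrix,
    PGGParams,
    bm_update,
    draw_contribution,
    pgg_update,
    realized_prob,
    stimulus,
)
from .networks import Network, complete_group, regular_random_graph, square_lattice

__all__ = [
    "PopulationSpec",
    "SimulationResult",
    "run_pdg",
    "run_pgg",
    "run_ensemble",
    "enumerate_small_pdg",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "run_id",
    "t",
    "player_id",
    "role",
    "intended_p",
    "realized_ptilde",
    "action",
    "payoff",
    "f_C_prev",
]

SeedLike = Union[int, np.random.SeedSequence, None]


@dataclass(frozen=True)
class PopulationSpec:
    """Composition of the population: learners plus unconditional defectors.

    The number of defectors is round(defector_fraction * n_players); they
    are placed uniformly at random, independently in every run, and always
    defect (or contribute zero) with no implementation noise.
    """

    defector_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.defector_fraction <= 0.5:
            raise ValueError(
                f"defector_fraction must lie in [0, 0.5], got {self.defector_fraction}"
            )

    def n_defectors(self, n_players: int) -> int:
        return int(round(self.defector_fraction * n_players))


@dataclass
class SimulationResult:
    """Ensemble output: per player-round arrays of shape (n_runs, t_max, n).

    ``action`` is boolean (cooperate) for the PDG and the continuous
    contribution for the PGG; ``ptilde`` is the realized cooperation
    probability (PDG only).  ``f_c_prev`` holds the previous-round neighbor
    cooperation fraction (PDG) or the other members' mean contribution
    (PGG); it is NaN in round 1.
    """

    game: str
    config: dict
    master_seed: object
    intended_p: np.ndarray = field(repr=False)
    action: np.ndarray = field(repr=False)
    payoff: np.ndarray = field(repr=False)
    f_c_prev: np.ndarray = field(repr=False)
    defectors: np.ndarray = field(repr=False)
    ptilde: Optional[np.ndarray] = field(default=None, repr=False)
    network: Optional[Network] = None
    group_size: Optional[int] = None

    @property
    def n_runs(self) -> int:
        return self.action.shape[0]

    @property
    def t_max(self) -> int:
        return self.action.shape[1]

    @property
    def n_players(self) -> int:
        return self.action.shape[2]

    @property
    def n_records(self) -> int:
        return self.n_runs * self.t_max * self.n_players

    def cooperation_response(self) -> np.ndarray:
        """Per player-round cooperation measure: p-tilde (PDG) or a_t (PGG)."""
        return self.ptilde if self.game == "pdg" else self.action

    def mean_cooperation_per_round(self) -> np.ndarray:
        """Ensemble mean cooperation for rounds 1..t_max, over players and runs."""
        return self.cooperation_response().mean(axis=(0, 2))

    def grand_mean_cooperation(self) -> float:
        """Mean cooperation over all players, rounds and runs."""
        return float(self.cooperation_response().mean())

    def to_records(self) -> pd.DataFrame:
        """Long-form round records, ordered by (run_id, player_id, t)."""
        R, T, N = self.action.shape

        def flat(arr: np.ndarray) -> np.ndarray:
            # (R, T, N) -> rows ordered run, player, t
            return np.transpose(arr, (0, 2, 1)).reshape(-1)

        role = np.where(self.defectors, "defector", "learner")  # (R, N)
        if self.game == "pdg":
            action_col = np.where(flat(self.action), "C", "D")
            ptilde_col = flat(self.ptilde)
        else:
            action_col = flat(self.action)
            ptilde_col = np.full(R * T * N, np.nan)
        df = pd.DataFrame(
            {
                "run_id": np.repeat(np.arange(R), T * N),
                "t": np.tile(np.arange(1, T + 1), R * N),
                "player_id": np.repeat(np.tile(np.arange(N), R), T),
                "role": np.repeat(role.reshape(-1), T),
                "intended_p": flat(self.intended_p),
                "realized_ptilde": ptilde_col,
                "action": action_col,
                "payoff": flat(self.payoff),
                "f_C_prev": flat(self.f_c_prev),
            }
        )
        return df

    def summary(self) -> dict:
        return {
            "game": self.game,
            "master_seed": _seed_repr(self.master_seed),
            "n_runs": self.n_runs,
            "t_max": self.t_max,
            "n_players": self.n_players,
            "n_records": self.n_records,
            "grand_mean_cooperation": self.grand_mean_cooperation(),
            "config": self.config,
        }


def _seed_repr(seed: object):
    if isinstance(seed, np.random.SeedSequence):
        return list(map(int, np.atleast_1d(seed.entropy)))
    return seed


def _seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def run_pdg(
    network: Network,
    params: LearnerParams,
    pop: PopulationSpec = PopulationSpec(),
    M: PayoffMatrix = PayoffMatrix(),
    t_max: int = 25,
    seed: SeedLike = None,
    n_runs: int = 1,
    update_on: str = "implemented",
) -> SimulationResult:
    """Simulate the repeated PDG on a network for an ensemble of runs.

    Within a round all learners act simultaneously: the intended action is
    drawn from ``p_t`` and misimplemented with probability epsilon; payoffs
    are the pairwise payoff averaged over neighbors; each learner updates
    ``p`` via the BM rule from the stimulus tanh(beta * (r - A)).

    update_on : which action enters the BM update when the implementation
        error flips the decision -- "implemented" (default; the action that
        actually generated the payoff) or "intended" (for sensitivity
        checks).
    """
    if update_on not in ("implemented", "intended"):
        raise ValueError("update_on must be 'implemented' or 'intended'")
    if t_max < 1 or n_runs < 1:
        raise ValueError("t_max and n_runs must be >= 1")
    if np.any(network.degrees < 1):
        raise ValueError("every node needs at least one neighbor")
    N = network.n
    R = n_runs
    T = t_max
    eps = params.epsilon
    ss = _seed_sequence(seed)
    children = ss.spawn(R)

    n_def = pop.n_defectors(N)
    defectors = np.zeros((R, N), dtype=bool)
    u_intent = np.empty((R, T, N))
    u_flip = np.empty((R, T, N))
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        if n_def:
            defectors[r, rng.choice(N, size=n_def, replace=False)] = True
        u_intent[r] = rng.random((T, N))
        u_flip[r] = rng.random((T, N))

    adj = network.adjacency()
    deg = network.degrees.astype(float)

    learners = ~defectors
    p = np.where(learners, params.p_init, 0.0)

    intended_p = np.empty((R, T, N))
    ptilde_arr = np.empty((R, T, N))
    action_arr = np.empty((R, T, N), dtype=bool)
    payoff_arr = np.empty((R, T, N))
    fc_arr = np.full((R, T, N), np.nan)

    for t in range(T):
        ptilde = np.where(learners, realized_prob(np.where(learners, p, 0.0), eps), 0.0)
        intended = learners & (u_intent[:, t, :] < p)
        flip = learners & (u_flip[:, t, :] < eps)
        coop = intended ^ flip  # defectors: False ^ False -> D
        coop_f = coop.astype(float)
        f = (adj @ coop_f.T).T / deg  # fraction of cooperating neighbors
        r_pay = np.where(coop, M.R * f + M.S * (1.0 - f), M.T * f + M.P * (1.0 - f))

        intended_p[:, t, :] = np.where(learners, p, 0.0)
        ptilde_arr[:, t, :] = ptilde
        action_arr[:, t, :] = coop
        payoff_arr[:, t, :] = r_pay
        if t + 1 < T:
            fc_arr[:, t + 1, :] = f

        s = stimulus(r_pay, params)
        upd_action = coop if update_on == "implemented" else intended
        p = np.where(learners, bm_update(p, upd_action, s), 0.0)

    cfg = {
        "game": "pdg",
        "n_players": N,
        "beta": params.beta,
        "A": params.A,
        "epsilon": eps,
        "p_init": params.p_init,
        "payoffs": {"T": M.T, "R": M.R, "P": M.P, "S": M.S},
        "t_max": T,
        "n_runs": R,
        "defector_fraction": pop.defector_fraction,
        "update_on": update_on,
    }
    return SimulationResult(
        game="pdg",
        config=cfg,
        master_seed=ss,
        intended_p=intended_p,
        ptilde=ptilde_arr,
        action=action_arr,
        payoff=payoff_arr,
        f_c_prev=fc_arr,
        defectors=defectors,
        network=network,
    )


def run_pgg(
    params: PGGParams,
    pop: PopulationSpec = PopulationSpec(),
    t_max: int = 25,
    n_groups: int = 1,
    seed: SeedLike = None,
    n_runs: int = 1,
    p_init: Optional[float] = None,
) -> SimulationResult:
    """Simulate the repeated PGG in independent groups.

    Each learner's expected contribution starts i.i.d. uniform on [0, 1]
    (or at ``p_init`` if given), the actual contribution is a truncated
    Gaussian around it, and the BM update treats contributions above the
    threshold X as cooperation.  Unconditional defectors contribute zero.
    """
    if t_max < 1 or n_runs < 1 or n_groups < 1:
        raise ValueError("t_max, n_runs and n_groups must be >= 1")
    if p_init is not None and not 0 <= p_init <= 1:
        raise ValueError("p_init must lie in [0, 1]")
    gs = params.group_size
    N = n_groups * gs
    R, T = n_runs, t_max
    share = params.multiplier / gs
    ss = _seed_sequence(seed)
    children = ss.spawn(R)
    n_def = pop.n_defectors(N)

    intended_p = np.empty((R, T, N))
    action_arr = np.empty((R, T, N))
    payoff_arr = np.empty((R, T, N))
    fc_arr = np.full((R, T, N), np.nan)
    defectors = np.zeros((R, N), dtype=bool)

    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        if n_def:
            defectors[r, rng.choice(N, size=n_def, replace=False)] = True
        learn = ~defectors[r]
        p = np.zeros(N)
        if p_init is None:
            p[learn] = rng.uniform(0.0, 1.0, size=learn.sum())
        else:
            p[learn] = p_init
        for t in range(T):
            a = np.zeros(N)
            if learn.any():
                a[learn] = draw_contribution(p[learn], params.sigma, rng)
            groups = a.reshape(n_groups, gs)
            tot = groups.sum(axis=1, keepdims=True)
            r_pay = (params.endowment - groups + share * tot).reshape(N)
            f_c = ((tot - groups) / (gs - 1)).reshape(N)

            intended_p[r, t] = np.where(learn, p, 0.0)
            action_arr[r, t] = a
            payoff_arr[r, t] = r_pay
            if t + 1 < T:
                fc_arr[r, t + 1] = f_c

            s = stimulus(r_pay, params)
            p = np.where(learn, pgg_update(np.where(learn, p, 0.0), a, params.X, s), 0.0)

    cfg = {
        "game": "pgg",
        "n_players": N,
        "n_groups": n_groups,
        "group_size": gs,
        "beta": params.beta,
        "A": params.A,
        "X": params.X,
        "sigma": params.sigma,
        "multiplier": params.multiplier,
        "endowment": params.endowment,
        "t_max": T,
        "n_runs": R,
        "defector_fraction": pop.defector_fraction,
        "p_init": p_init,
    }
    return SimulationResult(
        game="pgg",
        config=cfg,
        master_seed=ss,
        intended_p=intended_p,
        action=action_arr,
        payoff=payoff_arr,
        f_c_prev=fc_arr,
        defectors=defectors,
        group_size=gs,
    )


def run_noisy_grim(
    network: Network,
    epsilon: float = 0.2,
    M: PayoffMatrix = PayoffMatrix(),
    t_max: int = 25,
    seed: SeedLike = None,
    n_runs: int = 1,
) -> SimulationResult:
    """Noisy GRIM comparator: a trigger strategy with no learning component.

    Every player starts cooperative and switches to permanent defection the
    first time any neighbor defects; the chosen action is misimplemented
    with probability epsilon.  No propensity is updated, so any CC/MCC-like
    pattern in BM ensembles that this comparator fails to produce can be
    attributed to reinforcement learning rather than the conditional rule.
    Output uses the standard record schema with ``intended_p`` in {0, 1}.
    """
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5), got {epsilon}")
    if t_max < 1 or n_runs < 1:
        raise ValueError("t_max and n_runs must be >= 1")
    N, R, T = network.n, n_runs, t_max
    ss = _seed_sequence(seed)
    u_flip = np.empty((R, T, N))
    for r, child in enumerate(ss.spawn(R)):
        u_flip[r] = np.random.default_rng(child).random((T, N))
    adj = network.adjacency()
    deg = network.degrees.astype(float)

    triggered = np.zeros((R, N), dtype=bool)
    intended_p = np.empty((R, T, N))
    ptilde_arr = np.empty((R, T, N))
    action_arr = np.empty((R, T, N), dtype=bool)
    payoff_arr = np.empty((R, T, N))
    fc_arr = np.full((R, T, N), np.nan)

    for t in range(T):
        intend_c = ~triggered
        coop = intend_c ^ (u_flip[:, t, :] < epsilon)
        f = (adj @ coop.astype(float).T).T / deg
        r_pay = np.where(coop, M.R * f + M.S * (1.0 - f), M.T * f + M.P * (1.0 - f))
        intended_p[:, t, :] = intend_c.astype(float)
        ptilde_arr[:, t, :] = np.where(intend_c, 1.0 - epsilon, epsilon)
        action_arr[:, t, :] = coop
        payoff_arr[:, t, :] = r_pay
        if t + 1 < T:
            fc_arr[:, t + 1, :] = f
        triggered |= f < 1.0  # any defecting neighbor trips the switch

    cfg = {
        "game": "pdg",
        "strategy": "noisy_grim",
        "n_players": N,
        "epsilon": epsilon,
        "payoffs": {"T": M.T, "R": M.R, "P": M.P, "S": M.S},
        "t_max": T,
        "n_runs": R,
    }
    return SimulationResult(
        game="pdg",
        config=cfg,
        master_seed=ss,
        intended_p=intended_p,
        ptilde=ptilde_arr,
        action=action_arr,
        payoff=payoff_arr,
        f_c_prev=fc_arr,
        defectors=np.zeros((R, N), dtype=bool),
        network=network,
    )


def build_network(config, seed: SeedLike = None) -> Optional[Network]:
    """Construct the population structure named by a RunConfig-like object."""
    kind = config.network
    if kind == "lattice":
        return square_lattice(config.L)
    if kind == "regular_random":
        rng = np.random.default_rng(_seed_sequence(seed).spawn(1)[0])
        return regular_random_graph(config.n, config.k, rng)
    if kind == "complete":
        return complete_group(config.n)
    raise ValueError(f"unknown network kind {kind!r}")


def run_ensemble(config, n_runs: Optional[int] = None, master_seed: SeedLike = None) -> SimulationResult:
    """Run the ensemble described by a RunConfig (PDG or PGG).

    ``n_runs`` and ``master_seed`` override the config's values when given.
    Per-run seeds are spawned deterministically from the master seed, so the
    same (config, master_seed) pair yields byte-identical records.
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    seed = config.seed if master_seed is None else master_seed
    ss = _seed_sequence(seed)
    if config.game == "pdg":
        net_ss, run_ss = ss.spawn(2)
        network = build_network(config, net_ss)
        return run_pdg(
            network,
            config.learner_params(),
            pop=config.population(),
            M=config.payoff_matrix(),
            t_max=config.t_max,
            seed=run_ss,
            n_runs=n_runs,
            update_on=getattr(config, "update_on", "implemented"),
        )
    if config.game == "pgg":
        return run_pgg(
            config.pgg_params(),
            pop=config.population(),
            t_max=config.t_max,
            n_groups=config.n_groups,
            seed=ss,
            n_runs=n_runs,
            p_init=config.pgg_p_init(),
        )
    raise ValueError(f"unknown game {config.game!r}")


def enumerate_small_pdg(
    params: LearnerParams,
    M: PayoffMatrix = PayoffMatrix(),
    n_players: int = 2,
    t_max: int = 4,
) -> np.ndarray:
    """Exact expected realized cooperation probability per round.

    Brute-force oracle for tiny all-learner complete-graph systems: sums
    over every joint realized-action history, weighting each branch by its
    probability under the model.  Complexity is 2^(n_players * t_max), so
    inputs are limited to n_players <= 3 and t_max <= 6.

    Returns an array of length t_max with E[mean_i p-tilde_{i,t}].
    """
    if n_players > 3 or n_players < 2:
        raise ValueError("n_players must be 2 or 3")
    if not 1 <= t_max <= 6:
        raise ValueError("t_max must be between 1 and 6")
    n = n_players
    eps = params.epsilon
    out = np.zeros(t_max)
    profiles = [np.array(c, dtype=bool) for c in product([True, False], repeat=n)]

    def recurse(p: np.ndarray, t: int, prob: float) -> None:
        pt = p * (1.0 - eps) + (1.0 - p) * eps
        out[t] += prob * pt.mean()
        if t == t_max - 1:
            return
        for coop in profiles:
            branch = float(np.prod(np.where(coop, pt, 1.0 - pt)))
            if branch == 0.0:
                continue
            f = (coop.sum() - coop) / (n - 1)
            r_pay = np.where(coop, M.R * f + M.S * (1 - f), M.T * f + M.P * (1 - f))
            s = stimulus(r_pay, params)
            recurse(np.asarray(bm_update(p, coop, s)), t + 1, prob * branch)

    recurse(np.full(n, params.p_init), 0, 1.0)
    return out
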