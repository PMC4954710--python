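"""Per-player learning mathematics for aspiration-based Bush-Mosteller agents.

A Bush-Mosteller (BM) learner carries an unconditional propensity of
cooperation ``p`` (for the prisoner's dilemma) or an expected contribution
``p`` (for the public goods game).  After every round the obtained payoff
``r`` is compared with a fixed aspiration level ``A`` and converted into a
bounded stimulus ``s = tanh(beta * (r - A))``.  Satisfying outcomes
(``s > 0``) reinforce the action just taken; dissatisfying outcomes
anti-reinforce it.  The functions here are pure and accept scalars or numpy
arrays so the simulation engine can vectorize over whole populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "HARD",
    "PayoffMatrix",
    "LearnerParams",
    "PGGParams",
    "stimulus",
    "bm_update",
    "realized_prob",
    "draw_contribution",
    "pgg_update",
]

#: Sentinel for the infinite-sensitivity (deterministic-strategy) limit,
#: where the stimulus degenerates to the sign of ``r - A``.
HARD = "hard"

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class PayoffMatrix:
    """Pairwise prisoner's dilemma payoffs for the focal (row) player.

    T: temptation (defect against a cooperator), R: reward (mutual
    cooperation), P: punishment (mutual defection), S: sucker (cooperate
    against a defector).  A valid dilemma requires T > R > P > S.
    """

    T: float = 5.0
    R: float = 3.0
    P: float = 1.0
    S: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P > S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )


def _validate_beta(beta: Union[float, str]) -> None:
    if beta == HARD:
        return
    if not np.isfinite(beta) or beta <= 0:
        raise ValueError(f"beta must be positive and finite or 'hard', got {beta!r}")


@dataclass(frozen=True)
class LearnerParams:
    """Parameters of a binary-action (PDG) Bush-Mosteller learner.

    beta : sensitivity of the stimulus to the payoff-aspiration gap;
        the string ``"hard"`` selects the beta -> infinity limit.
    A : aspiration level, in payoff units.
    epsilon : probability of misimplementing the intended action.
    p_init : initial cooperation probability.
    """

    beta: Union[float, str] = 0.2
    A: float = 0.5
    epsilon: float = 0.2
    p_init: float = 0.5

    def __post_init__(self) -> None:
        _validate_beta(self.beta)
        if not 0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must lie in [0, 0.5), got {self.epsilon}")
        if not 0 <= self.p_init <= 1:
            raise ValueError(f"p_init must lie in [0, 1], got {self.p_init}")
        if not np.isfinite(self.A):
            raise ValueError("aspiration level A must be finite")

    @property
    def hard(self) -> bool:
        return self.beta == HARD


@dataclass(frozen=True)
class PGGParams:
    """Parameters of a continuous-contribution public goods game learner.

    X : contribution threshold above which an action counts as cooperative
        (this binarization decides which behavior gets reinforced).
    sigma : standard deviation of the truncated-Gaussian contribution draw.
    multiplier : factor applied to the common pool before redistribution.
    group_size : number of players sharing the pool.
    endowment : per-round endowment, in monetary units.
    """

    beta: Union[float, str] = 0.4
    A: float = 0.9
    X: float = 0.3
    sigma: float = 0.2
    multiplier: float = 1.6
    group_size: int = 4
    endowment: float = 1.0

    def __post_init__(self) -> None:
        _validate_beta(self.beta)
        if not 0 < self.X < 1:
            raise ValueError(f"threshold X must lie in (0, 1), got {self.X}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.multiplier <= 1:
            raise ValueError(f"multiplier must exceed 1, got {self.multiplier}")
        if self.group_size < 2:
            raise ValueError(f"group_size must be >= 2, got {self.group_size}")
        if not np.isfinite(self.A):
            raise ValueError("aspiration level A must be finite")

    @property
    def hard(self) -> bool:
        return self.beta == HARD


def stimulus(r: ArrayLike, params: Union[LearnerParams, PGGParams]) -> ArrayLike:
    """Stimulus s = tanh(beta * (r - A)) driving the probability update.

    In hard mode (``beta == "hard"``) returns sign(r - A), i.e. +1 for a
    satisfying payoff, -1 for a dissatisfying one and 0 exactly at r = A
    (the pointwise limit of tanh; a tie triggers no update).
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("payoff r must be finite")
    if params.hard:
        s = np.sign(r - params.A)
    else:
        s = np.tanh(params.beta * (r - params.A))
    return s if s.ndim else float(s)


def _as_coop(action: ArrayLike) -> np.ndarray:
    """Normalize an action spec ('C'/'D', bools, or arrays thereof) to bool."""
    a = np.asarray(action)
    if a.dtype.kind in "US":
        flat = np.char.upper(a.astype(str))
        if not np.all((flat == "C") | (flat == "D")):
            raise ValueError("actions must be 'C' or 'D'")
        return flat == "C"
    return a.astype(bool)


def bm_update(p: ArrayLike, action: ArrayLike, s: ArrayLike) -> ArrayLike:
    """Bush-Mosteller update of the cooperation probability.

    The four branches move ``p`` toward the taken action when the stimulus
    is satisfying and away from it when dissatisfying, with multiplicative
    factors that keep ``p`` inside [0, 1]:

    ==========  ========  ============================
    action      stimulus  update
    ==========  ========  ============================
    C           s >= 0    p + (1 - p) * s
    C           s <  0    p + p * s
    D           s >= 0    p - p * s
    D           s <  0    p - (1 - p) * s
    ==========  ========  ============================

    Accepts scalars or broadcastable arrays.  ``p`` may sit at 0 or 1 (the
    deterministic-strategy limit); values outside [0, 1] are rejected.
    """
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if np.any((s < -1) | (s > 1)):
        raise ValueError("stimulus s must lie in [-1, 1]")
    coop = _as_coop(action)
    toward = np.where(s >= 0, p + (1.0 - p) * s, p * (1.0 + s))
    away = np.where(s >= 0, p * (1.0 - s), p - (1.0 - p) * s)
    out = np.where(coop, toward, away)
    return out if out.ndim else float(out)


def realized_prob(p: ArrayLike, epsilon: float) -> ArrayLike:
    """Actual cooperation probability after implementation error.

    p-tilde = p * (1 - eps) + (1 - p) * eps, an affine map of p whose image
    is exactly [eps, 1 - eps].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5), got {epsilon}")
    out = p * (1.0 - epsilon) + (1.0 - p) * epsilon
    return out if out.ndim else float(out)


def draw_contribution(
    p: ArrayLike,
    sigma: float,
    rng: np.random.Generator,
    max_iter: int = 10_000,
) -> ArrayLike:
    """Draw a contribution from a Gaussian(p, sigma^2) truncated to [0, 1].

    Realized by rejection: draws falling outside [0, 1] are discarded and
    redrawn, so the result follows the Gaussian conditioned on the unit
    interval.  Vectorized over ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("expected contribution p must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    a = rng.normal(p, sigma)
    a = np.asarray(a, dtype=float)
    bad = (a < 0) | (a > 1)
    it = 0
    while np.any(bad):
        it += 1
        if it > max_iter:  # pragma: no cover - acceptance prob >= ~0.5 here
            raise RuntimeError("truncated-Gaussian rejection sampling did not converge")
        a[bad] = rng.normal(np.broadcast_to(p, a.shape)[bad], sigma)
        bad = (a < 0) | (a > 1)
    return a if a.ndim else float(a)


def pgg_update(p: ArrayLike, a: ArrayLike, X: float, s: ArrayLike) -> ArrayLike:
    """BM update for continuous contributions.

    A contribution ``a >= X`` plays the role of cooperation and ``a < X``
    the role of defection in the four-branch update; otherwise identical to
    :func:`bm_update` acting on the expected contribution.
    """
    a_arr = np.asarray(a, dtype=float)
    if np.any((a_arr < 0) | (a_arr > 1)):
        raise ValueError("contribution a must lie in [0, 1]")
    if not 0 < X < 1:
        raise ValueError(f"threshold X must lie in (0, 1), got {X}")
    return bm_update(p, a_arr >= X, s)
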