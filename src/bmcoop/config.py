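"""Run configuration: a flat, validated record of every simulation knob.

Defaults reproduce the canonical study conditions: T,R,P,S = 5,3,1,0,
epsilon = 0.2, p_1 = 0.5, t_max = 25 rounds on a 10x10 periodic lattice for
the PDG; sigma = 0.2, multiplier = 1.6 and four-player groups with uniform
initial expected contributions for the PGG.  Configs serialize to/from
JSON; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .learning import LearnerParams, PayoffMatrix, PGGParams
from .engine import PopulationSpec

__all__ = ["RunConfig"]

_GAMES = ("pdg", "pgg")
_NETWORKS = ("lattice", "regular_random", "complete")

#: Fixed default master seed (not wall-clock) so default runs reproduce.
DEFAULT_SEED = 20160720


@dataclass(frozen=True)
class RunConfig:
    game: str = "pdg"
    network: str = "lattice"
    L: int = 10
    n: int = 100
    k: int = 4
    beta: Union[float, str] = 0.2
    A: float = 0.5
    epsilon: float = 0.2
    X: float = 0.3
    sigma: float = 0.2
    multiplier: float = 1.6
    group_size: int = 4
    n_groups: int = 1
    t_max: int = 25
    n_runs: int = 1
    defector_fraction: float = 0.0
    p_init: Optional[float] = 0.5
    T: float = 5.0
    R: float = 3.0
    P: float = 1.0
    S: float = 0.0
    seed: int = DEFAULT_SEED
    update_on: str = "implemented"

    def __post_init__(self) -> None:
        if self.game not in _GAMES:
            raise ValueError(f"game must be one of {_GAMES}, got {self.game!r}")
        if self.network not in _NETWORKS:
            raise ValueError(f"network must be one of {_NETWORKS}, got {self.network!r}")
        if self.t_max < 1 or self.n_runs < 1 or self.n_groups < 1:
            raise ValueError("t_max, n_runs and n_groups must be >= 1")
        if self.update_on not in ("implemented", "intended"):
            raise ValueError("update_on must be 'implemented' or 'intended'")
        # delegate the rest to the parameter objects
        self.payoff_matrix()
        self.population()
        if self.game == "pdg":
            self.learner_params()
        else:
            self.pgg_params()
            if self.p_init is not None and not 0 <= self.p_init <= 1:
                raise ValueError("p_init must lie in [0, 1] or be null")

    # ---- component builders -------------------------------------------------
    def payoff_matrix(self) -> PayoffMatrix:
        return PayoffMatrix(T=self.T, R=self.R, P=self.P, S=self.S)

    def learner_params(self) -> LearnerParams:
        p_init = 0.5 if self.p_init is None else self.p_init
        return LearnerParams(
            beta=self.beta, A=self.A, epsilon=self.epsilon, p_init=p_init
        )

    def pgg_params(self) -> PGGParams:
        return PGGParams(
            beta=self.beta,
            A=self.A,
            X=self.X,
            sigma=self.sigma,
            multiplier=self.multiplier,
            group_size=self.group_size,
        )

    def population(self) -> PopulationSpec:
        return PopulationSpec(defector_fraction=self.defector_fraction)

    def pgg_p_init(self) -> Optional[float]:
        """PGG initial expected contribution; None selects uniform draws."""
        return self.p_init

    # ---- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config JSON must be an object")
        return cls.from_dict(data)
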