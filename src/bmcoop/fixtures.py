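"""Small seed-pinned record sets for tests and quick demos."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .config import RunConfig
from .engine import SimulationResult, run_ensemble
from .networks import Network

__all__ = ["FIXTURES", "make_fixture", "fixture_result"]

FIXTURES = {
    # 3x3 periodic lattice, 5 rounds, 2 runs -> 9 * 5 * 2 = 90 rows
    "lattice-mini": RunConfig(
        game="pdg", network="lattice", L=3, beta=0.2, A=0.5,
        t_max=5, n_runs=2, seed=7,
    ),
    # two 4-player groups, 5 rounds, 1 run -> 8 * 5 = 40 rows
    "pgg-mini": RunConfig(
        game="pgg", beta=0.4, A=0.9, X=0.3, n_groups=2,
        t_max=5, n_runs=1, p_init=None, seed=11,
    ),
    # K5 well-mixed group with one defector, 6 rounds, 2 runs -> 60 rows
    "complete-mini": RunConfig(
        game="pdg", network="complete", n=5, beta=0.4, A=0.5,
        defector_fraction=0.2, t_max=6, n_runs=2, seed=13,
    ),
}


def fixture_result(name: str) -> SimulationResult:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return run_ensemble(FIXTURES[name])


def make_fixture(name: str) -> pd.DataFrame:
    """Deterministic tiny round-record table for a known fixture name."""
    return fixture_result(name).to_records()


def fixture_network(name: str) -> Optional[Network]:
    return fixture_result(name).network
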