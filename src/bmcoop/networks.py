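"""Population structures and single-round payoff rules.

Three structures are provided, all 4-regular in their default configurations:
the periodic square lattice, the random regular graph, and the well-mixed
(complete) group.  Payoffs are the focal player's pairwise prisoner's
dilemma payoff averaged over neighbors, or the standard linear public goods
payoff (keep your endowment minus your contribution, plus an equal share of
the multiplied pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .learning import PayoffMatrix, PGGParams, _as_coop

__all__ = [
    "Network",
    "square_lattice",
    "regular_random_graph",
    "complete_group",
    "pdg_round_payoff",
    "pgg_round_payoff",
]


@dataclass
class Network:
    """Undirected simple graph stored as per-node neighbor index lists."""

    n: int
    neighbors: list = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.neighbors) != self.n:
            raise ValueError("neighbor list length must equal node count")
        seen = set()
        for i, nbrs in enumerate(self.neighbors):
            arr = np.asarray(nbrs, dtype=np.int64)
            if arr.size and (arr.min() < 0 or arr.max() >= self.n):
                raise ValueError("neighbor index out of range")
            if np.any(arr == i):
                raise ValueError("self-loops are not allowed")
            if len(set(arr.tolist())) != arr.size:
                raise ValueError("duplicate edges are not allowed")
            self.neighbors[i] = np.sort(arr)
            for j in arr:
                seen.add((min(i, int(j)), max(i, int(j))))
        # symmetry check
        for i, j in seen:
            if i not in self.neighbors[j] or j not in self.neighbors[i]:
                raise ValueError("adjacency must be symmetric")
        self._edges = sorted(seen)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nbrs) for nbrs in self.neighbors])

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> list:
        return list(self._edges)

    def adjacency(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix."""
        rows = np.concatenate(
            [np.full(len(nbrs), i) for i, nbrs in enumerate(self.neighbors)]
        )
        cols = np.concatenate(self.neighbors)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "Network":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        nbrs = [np.array(sorted(index[u] for u in g.neighbors(v)), dtype=np.int64)
                for v in nodes]
        return cls(n=g.number_of_nodes(), neighbors=nbrs)

    def write_edgelist(self, path) -> None:
        """Two-column whitespace edge list, 0-based, one undirected edge per line."""
        with open(path, "w") as fh:
            for i, j in self._edges:
                fh.write(f"{i} {j}\n")

    @classmethod
    def read_edgelist(cls, path) -> "Network":
        g = nx.read_edgelist(path, nodetype=int)
        return cls.from_graph(g)


def square_lattice(L: int) -> Network:
    """L x L square lattice with periodic boundaries (von Neumann degree 4).

    Nodes are indexed row-major: node ``i*L + j`` sits at row i, column j.
    Requires L >= 3; the L = 2 wrap would duplicate edges.
    """
    if L < 3:
        raise ValueError(f"lattice side must be >= 3, got {L}")
    g = nx.grid_2d_graph(L, L, periodic=True)
    g = nx.relabel_nodes(g, {(i, j): i * L + j for i, j in g.nodes()})
    return Network.from_graph(g)


def regular_random_graph(
    n: int, k: int, rng: Union[int, np.random.Generator, None] = None
) -> Network:
    """Simple random graph in which every node has degree exactly k."""
    if n * k % 2 != 0:
        raise ValueError(f"n*k must be even for a {k}-regular graph on {n} nodes")
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n, got k={k}, n={n}")
    if rng is None:
        rng = np.random.default_rng()
    g = nx.random_regular_graph(k, n, seed=rng)
    return Network.from_graph(g)


def complete_group(n: int) -> Network:
    """Well-mixed group: the complete graph on n players."""
    if n < 2:
        raise ValueError(f"a group needs at least 2 players, got {n}")
    return Network.from_graph(nx.complete_graph(n))


def pdg_round_payoff(
    action: str,
    neighbor_actions: Sequence,
    M: PayoffMatrix = PayoffMatrix(),
) -> float:
    """Focal player's PDG payoff averaged over its neighbors.

    A cooperator earns R against each cooperating neighbor and S against
    each defecting one; a defector earns T and P respectively.
    """
    nbrs = list(neighbor_actions)
    if not nbrs:
        raise ValueError("at least one neighbor is required")
    focal_c = bool(_as_coop(action))
    nbr_c = _as_coop(nbrs)
    f = float(np.mean(nbr_c))
    if focal_c:
        return M.R * f + M.S * (1.0 - f)
    return M.T * f + M.P * (1.0 - f)


def pgg_round_payoff(
    a: float,
    others: Iterable[float],
    params: PGGParams = PGGParams(),
) -> float:
    """Public goods payoff: endowment - a + (multiplier/group_size) * pool.

    The pool is the focal contribution plus the other members' contributions;
    ``others`` must contain exactly group_size - 1 entries in [0, 1].
    """
    others = np.asarray(list(others), dtype=float)
    if len(others) != params.group_size - 1:
        raise ValueError(
            f"expected {params.group_size - 1} other contributions, got {len(others)}"
        )
    contribs = np.append(others, a)
    if np.any((contribs < 0) | (contribs > 1)):
        raise ValueError("contributions must lie in [0, 1]")
    share = params.multiplier / params.group_size
    return float(params.endowment - a + share * contribs.sum())
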