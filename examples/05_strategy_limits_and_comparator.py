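"""Deterministic strategy limits and the non-learning GRIM comparator.

With an infinitely sharp stimulus (beta = "hard") the BM rule degenerates
to classic conditional strategies: P < A < R gives Pavlov (win-stay
lose-shift), S < A < P makes defection absorbing (GRIM-like).  A noisy
GRIM *automaton* -- trigger strategy, no learning -- collapses to the
noise floor and fails the MCC pattern, showing that the moody signature
needs the learning dynamics, not just a GRIM-shaped rule.
"""

import numpy as np

from bmcoop import (
    HARD, LearnerParams, complete_group, enumerate_small_pdg, linear_fit,
    mcc_signature, run_noisy_grim, run_pdg, square_lattice,
)
from bmcoop.analysis import CONDITIONS

# Pavlov limit: mutual cooperation is self-sustaining
pav = run_pdg(complete_group(2), LearnerParams(beta=HARD, A=2.0, epsilon=0.0, p_init=1.0),
              t_max=10, n_runs=1, seed=1)
print("Pavlov pair, 10 rounds, all actions C:", bool(pav.action.all()))

# exact enumeration vs Monte Carlo on a 2-player system
params = LearnerParams(beta=0.2, A=0.5, epsilon=0.2)
exact = enumerate_small_pdg(params, n_players=2, t_max=4)
mc = run_pdg(complete_group(2), params, t_max=4, n_runs=20000, seed=2).ptilde.mean(axis=(0, 2))
print("exact E[p-tilde] per round:", np.round(exact, 4))
print("Monte-Carlo estimate:      ", np.round(mc, 4))

# noisy GRIM automaton: no MCC without learning
grim = run_noisy_grim(square_lattice(10), epsilon=0.2, t_max=25, n_runs=300, seed=3)
sig = mcc_signature({c: linear_fit(grim, c) for c in CONDITIONS})
print("\nnoisy GRIM automaton verdict:",
      f"cc={sig['cc']} mcc={sig['mcc']} ordering={sig['intercept_ordering_ok']}")
print("alpha1 by stratum:", {k: round(v, 3) for k, v in sig["alpha1"].items()})
print("(mcc=False: the automaton's response after own defection still rises "
      "with f_C, unlike the learners')")
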