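# Methods

## Model

`bmcoop` simulates populations of aspiration-based Bush–Mosteller (BM)
reinforcement learners in two repeated social dilemmas.

**Networked prisoner's dilemma (PDG).** Each player occupies a node of an
undirected graph and holds an intended cooperation probability
`p_t ∈ [0, 1]`.  Every round, synchronously:

1. Each learner forms an intended action (C with probability `p_t`) and
   misimplements it with probability `ε` (one action per round, used
   against all neighbors).  The realized cooperation probability is
   therefore `p̃_t = p_t(1 − ε) + (1 − p_t)ε`, confined to `[ε, 1 − ε]`.
2. The payoff `r_t` is the pairwise PDG payoff (T = 5, R = 3, P = 1, S = 0
   by default) averaged over the player's neighbors.
3. The payoff is converted into a bounded stimulus
   `s_t = tanh(β (r_t − A))`, where `A` is the fixed aspiration level and
   `β > 0` the sensitivity.  `s_t > 0` means the outcome satisfied the
   player.
4. The propensity is updated by the four-branch BM rule: a satisfying
   outcome moves `p` toward the action just taken, a dissatisfying one
   moves it away, with multiplicative factors `(1 − p)` or `p` that keep
   `p` inside the unit interval.  The action entering the update is the
   **implemented** one (the one that generated the payoff); the intended
   action can be selected instead (`update_on="intended"`) for sensitivity
   checks.

Players know only their own action and payoff.  They never observe the
neighborhood cooperation fraction `f_C`; any conditional-cooperation
pattern in the output is an emergent description, not a rule the agents
follow.

**Group public goods game (PGG).** Independent groups of `group_size = 4`
players each receive a unit endowment per round and contribute
`a_t ∈ [0, 1]` to a pool that is multiplied by 1.6 and redistributed
equally, so the payoff is `1 − a_t + 0.4 Σ_group a`.  Here `p_t` is the
*expected contribution*: the realized `a_t` is drawn from a Gaussian with
mean `p_t` and standard deviation `σ = 0.2`, truncated to `[0, 1]` by
rejection (out-of-range draws are discarded and redrawn, so the result is
the conditional distribution).  Because the reinforced "behavior" must be
binary, a threshold `X` classifies `a_t ≥ X` as cooperation; the BM update
is otherwise unchanged.  PGG learners have no separate `ε`; all action
noise comes from the contribution draw.

**Deterministic limits.** `beta="hard"` replaces `tanh` by the sign of
`r − A` (with `s = 0` exactly at `r = A`: satisfaction is a strict
inequality, and the tie produces no update — the pointwise limit of
`tanh`).  With `P < A < R` and `ε = 0` this is Pavlov (win-stay
lose-shift); with `S < A < P` every defection payoff satisfies, so
defection is absorbing (GRIM-like).  In hard mode `p` may legitimately sit
at exactly 0 or 1; the update branches remain well defined there, so
endpoints are allowed rather than clamped.  With a soft stimulus and
`p ∈ (0, 1)` every branch is a strict convex move, so trajectories stay
strictly inside the unit interval.

**Noisy-GRIM comparator.** `run_noisy_grim` implements the matching
*non-learning* control: a trigger automaton that starts cooperative,
defects permanently once any neighbor has defected, and misimplements its
choice with probability `ε`.  It shares the record schema, so the same
analysis applies.  This automaton — not the `β = ∞` BM learner — is the
correct "conditional rule without learning" baseline: the hard-β BM still
updates `p` and recovers to full cooperation after a satisfying
noise-induced cooperation, and consequently *does* produce MCC-shaped
patterns, whereas the automaton does not (its post-defection response
still rises with `f_C` and its intercept ordering is reversed).

## Populations, defaults, and the study conditions

The default configuration mirrors the study conditions throughout:
`β = 0.2` (PDG baseline) or as given, `A` as given, `ε = 0.2`,
`p_1 = 0.5` for all PDG learners, `t_max = 25` rounds, a 10×10 square
lattice with periodic boundaries and von Neumann (degree-4) neighborhoods.
PGG defaults: `β = 0.4`, `A = 0.9`, `X = 0.3`, `σ = 0.2`, multiplier 1.6,
four-player groups, initial expected contributions i.i.d. uniform on
`[0, 1]`.  Two further structures are available, both degree-4 in their
canonical form: the random 4-regular graph on 100 nodes (generated by
networkx's regular-graph sampler; one graph per ensemble, drawn from the
master seed) and the well-mixed group of five (complete graph).  Mixed
populations place `round(fraction × n)` unconditional defectors uniformly
at random, independently per run; defectors always defect / contribute
zero with no implementation noise (they are a strategy type, not noisy
learners) and are excluded from all analyses, which concern the learners.

## Analysis

For every learner round `t ≥ 2` the analysis pools the sample
`(f_C, response, own previous action)`, where `f_C` is the fraction of
neighbors whose realized action at `t − 1` was C (PDG; on degree-4
structures it takes only the values {0, 0.25, 0.5, 0.75, 1}) or the other
group members' mean contribution at `t − 1` (PGG), and the response is
`p̃_t` (PDG) or `a_t` (PGG).  Using `p̃_t` rather than the binary action
has the same expectation and lower variance.  Round-1 records carry no
`f_C` and are excluded; the conditional strata are defined by the focal
player's *implemented* previous action (C/D, or `a_{t−1} ≥ X` / `< X`).

* **Curves** report mean ± sd of the response per `f_C` level; continuous
  PGG `f_C` is binned at width 0.1 for display only.
* **Fits** are ordinary least squares `response ≈ α₁ f_C + α₂` over all
  pooled samples (default) or over per-level means (`per_level_means=True`;
  the two coincide on balanced designs).  A stratum with fewer than two
  distinct `f_C` values yields an explicitly undefined fit.
* **Verdicts** use a tolerance `τ = 0.02` (≈ the Monte-Carlo standard
  error of α₁ at ~2.5 × 10⁶ pooled samples; configurable): CC ⇔
  α₁(unconditioned) > τ; MCC ⇔ α₁(after C) > τ and α₁(after D) < τ;
  intercept ordering ⇔ α₂(C) − α₂(D) ≥ −τ.
* **Significance** for slope-onset questions uses a 95% percentile
  cluster bootstrap (1000 resamples) computed from per-cluster sufficient
  statistics.  The resampling unit is the run for the PDG (the lattice
  couples all players in a run) and the group for the PGG (groups are
  independent).
* **Sweeps** run an independent seeded ensemble per grid cell and record
  mean cooperation, the three fits, and the verdict; per-cell failures are
  captured in an `error` column rather than aborting.

## Reproducibility and numerics

Every ensemble consumes a single master seed through
`numpy.random.SeedSequence`; per-run generators are spawned
deterministically, so identical configurations reproduce byte-identical
records, and runs are independent replicates.  Within a round the update
is fully synchronous and vectorized — all actions are revealed, then all
payoffs, then all propensities update — so no ordering effects exist by
construction.  Per-player uniforms are pre-drawn as `(t_max, n)` matrices
per run.  The realized PDG action is drawn as intended-then-flip (two
uniforms), which makes the implemented/intended distinction available to
both update modes.  The CLI's default master seed is a fixed constant, not
wall-clock time.

`enumerate_small_pdg` provides an exact oracle for all-learner complete
graphs with ≤ 3 players and ≤ 6 rounds: it sums `E[p̃_t]` over every joint
realized-action history weighted by its probability (cost `2^(n·t)`), and
is used to validate the engine against brute-force expectation.

## What the generator emulates — and what it does not

Simulated ensembles reproduce the *structure* of round-based laboratory
social-dilemma data: synchronous rounds, binary or graded actions,
implementation error, fixed small neighborhoods, free-riding subpopulations.
They do not emulate participant heterogeneity in (β, A), learning across
supergames, payoff framing, or drop-out — so tests passing here show that
the mechanism produces CC/MCC-shaped statistics under idealized
conditions, not that human data were fit.  External round records in the
same CSV schema can be analyzed unchanged.

## Problem sizes

Bundled tests and the reproduction script use ensembles of 150–1000 runs
(PDG) and 2000–5000 groups (PGG) per condition — enough that the
Monte-Carlo error of every asserted quantity is an order of magnitude
below the asserted tolerance; the qualitative verdicts are already stable
at a tenth of these sizes.  The heaviest single computation (1000 runs ×
100 rounds × 100 players) takes a few seconds on one CPU.

## Known limitations and open choices

* The onset-in-β of conditional cooperation depends on how "appreciably
  positive slope" is operationalized: the true α₁ is already positive
  (≈ 0.04 PDG, ≈ 0.16 PGG) at β = 0.05, so a significance test at large
  sample sizes flags the smallest grid value, while visual-magnitude
  readings of heatmaps place the onset near β ≈ 0.2–0.25.  The package
  reports the significance-based onset and exposes the per-β slope table
  so any magnitude criterion can be applied downstream.
* The plateau round of the β = 0.2, A = 0.5 trajectory is sharply
  sensitive to the convergence band: the approach is roughly exponential,
  reaching within 0.02 of the late-time mean by round ~19 but within 0.01
  only by round ~25.
* Whether the BM update should consume the intended or the implemented
  action when `ε` flips the decision is not identifiable from aggregate
  patterns explored here; both are implemented, implemented-action is the
  default.
* The GRIM correspondence of the hard-stimulus limit holds for
  `S < A < P`; between `P` and `R` the same limit is Pavlov.  `A` is always
  a free parameter.
* Aspiration levels are fixed; adaptive aspirations and alternative
  reinforcement schemes (e.g. Macy–Flache-style updates, directional
  learning) are out of scope.
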