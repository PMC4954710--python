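"""Conditional-cooperation (CC) and moody-conditional-cooperation (MCC) analysis.

Given long-form round records, these routines stratify a player's
cooperation response by the previous-round cooperation of its neighbors
(``f_C``) and by the player's own previous action, fit the linear relation
``response ~ alpha1 * f_C + alpha2`` by ordinary least squares, and apply
the CC/MCC decision rules:

* CC: the unconditioned slope alpha1 is positive.
* MCC: alpha1 is positive after own cooperation and negative or close to
  zero after own defection; additionally the intercept alpha2 is larger
  after cooperation than after defection.

For the PDG the response is the realized cooperation probability p-tilde;
for the PGG it is the contribution a_t, and "own cooperation" means a
previous contribution at or above the threshold X.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimulationResult, run_ensemble
from .networks import Network

__all__ = [
    "CCCurve",
    "LinearFit",
    "SweepResult",
    "CONDITIONS",
    "prepare_samples",
    "fraction_cooperating_neighbors",
    "cc_curve",
    "linear_fit",
    "slope_bootstrap_ci",
    "mcc_signature",
    "cc_onset_beta",
    "sweep",
]

CONDITIONS = ("all", "prev_C", "prev_D")

#: Slope magnitude regarded as "close to zero" in the MCC decision rule;
#: roughly the Monte-Carlo standard error of alpha1 at ~2.5e6 pooled samples.
DEFAULT_TAU = 0.02

RecordsLike = Union[pd.DataFrame, SimulationResult]


@dataclass
class CCCurve:
    """Stratified cooperation curve: mean +/- sd of the response per f_C level."""

    condition: str
    levels: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "f_C": self.levels,
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n,
            }
        )


@dataclass
class LinearFit:
    """OLS fit response ~ alpha1 * f_C + alpha2 over pooled samples."""

    condition: str
    alpha1: float
    alpha2: float
    n_samples: int
    stderr: float = float("nan")
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "n_samples": self.n_samples,
            "stderr": self.stderr,
            "defined": self.defined,
        }


def _as_records(records: RecordsLike) -> tuple[pd.DataFrame, Optional[str]]:
    if isinstance(records, SimulationResult):
        return records.to_records(), records.game
    return records, None


def _infer_game(df: pd.DataFrame) -> str:
    ptilde = pd.to_numeric(df["realized_ptilde"], errors="coerce")
    return "pdg" if ptilde.notna().any() else "pgg"


def prepare_samples(
    records: RecordsLike,
    game: Optional[str] = None,
    x_threshold: Optional[float] = None,
    group_size: int = 4,
) -> pd.DataFrame:
    """Pool learner transition samples (t >= 2) for the CC/MCC analysis.

    Returns a frame with columns ``f_C`` (previous-round neighbor
    cooperation), ``response`` (p-tilde for the PDG, a_t for the PGG),
    ``prev_C`` (whether the focal player's own previous implemented action
    counted as cooperation), and ``cluster`` (the independent resampling
    unit: the run for the PDG, the group for the PGG).

    Round-1 records (no f_C) and defector players are excluded by
    construction.
    """
    df, inferred = _as_records(records)
    game = game or inferred or _infer_game(df)
    df = df[df["role"] == "learner"]
    df = df.sort_values(["run_id", "player_id", "t"], kind="stable")

    if game == "pdg":
        response = pd.to_numeric(df["realized_ptilde"], errors="coerce").to_numpy()
        act = df["action"].to_numpy()
        coop = np.asarray(act == "C") | np.asarray(act == True)  # noqa: E712
        cluster = df["run_id"].to_numpy()
    elif game == "pgg":
        contrib = pd.to_numeric(df["action"], errors="coerce").to_numpy()
        response = contrib
        if x_threshold is None:
            raise ValueError("x_threshold is required for PGG records")
        coop = contrib >= x_threshold
        cluster = (
            df["run_id"].to_numpy() * (df["player_id"].max() // group_size + 1)
            + df["player_id"].to_numpy() // group_size
        )
    else:
        raise ValueError(f"unknown game {game!r}")

    t = df["t"].to_numpy()
    prev_coop = np.roll(coop, 1)
    prev_response = np.roll(response, 1)
    fc = pd.to_numeric(df["f_C_prev"], errors="coerce").to_numpy()
    keep = t >= 2
    # guard against non-contiguous histories: the previous row must be t-1
    prev_t = np.roll(t, 1)
    keep &= prev_t == t - 1
    out = pd.DataFrame(
        {
            "f_C": fc[keep],
            "response": response[keep],
            "prev_C": prev_coop[keep],
            "prev_response": prev_response[keep],
            "cluster": cluster[keep],
        }
    )
    if out["f_C"].isna().any():
        raise ValueError("records with t >= 2 must carry f_C_prev")
    return out


def _stratum(samples: pd.DataFrame, condition: str) -> pd.DataFrame:
    if condition == "all":
        return samples
    if condition == "prev_C":
        return samples[samples["prev_C"]]
    if condition == "prev_D":
        return samples[~samples["prev_C"]]
    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def fraction_cooperating_neighbors(
    records: RecordsLike,
    network: Optional[Network] = None,
    group_size: int = 4,
) -> pd.Series:
    """Recompute f_C for every player-round from the raw action records.

    For the PDG (``network`` given) this is the fraction of the focal
    player's neighbors whose realized action in the previous round was C;
    for the PGG it is the mean contribution of the other group members in
    the previous round.  Round-1 entries are NaN.  The records must contain
    every player of every run; missing neighbor records are an error.
    """
    df, inferred = _as_records(records)
    game = inferred or _infer_game(df)
    out = pd.Series(np.nan, index=df.index, name="f_C")
    if game == "pdg":
        if network is None:
            raise ValueError("a network is required for PDG records")
        coop = df.assign(coop=(df["action"] == "C").astype(float)).pivot_table(
            index=["run_id", "t"], columns="player_id", values="coop", aggfunc="mean"
        )
        if coop.isna().any().any() or coop.shape[1] != network.n:
            raise ValueError("records must cover every player of every run/round")
        adj = network.adjacency()
        deg = network.degrees.astype(float)
        f = (adj @ coop.to_numpy().T).T / deg  # rows: (run, t)
        fdf = pd.DataFrame(f, index=coop.index, columns=coop.columns)
        key = pd.MultiIndex.from_arrays([df["run_id"], df["t"] - 1, df["player_id"]])
        stacked = fdf.stack()
        out[:] = stacked.reindex(key).to_numpy()
    else:
        contrib = pd.to_numeric(df["action"], errors="coerce")
        group = df["player_id"] // group_size
        tot = df.assign(a=contrib, group=group).groupby(["run_id", "t", "group"])["a"]
        gsum = tot.transform("sum")
        gcount = tot.transform("count")
        if (gcount != group_size).any():
            raise ValueError("each group must have exactly group_size records per round")
        others_mean = (gsum - contrib) / (group_size - 1)
        key = pd.MultiIndex.from_arrays([df["run_id"], df["t"] - 1, df["player_id"]])
        prev = pd.Series(
            others_mean.to_numpy(),
            index=pd.MultiIndex.from_arrays([df["run_id"], df["t"], df["player_id"]]),
        )
        out[:] = prev.reindex(key).to_numpy()
    return out


def cc_curve(
    records: RecordsLike,
    condition: str = "all",
    bins: Optional[Sequence[float]] = None,
    game: Optional[str] = None,
    x_threshold: Optional[float] = None,
    group_size: int = 4,
) -> CCCurve:
    """Mean +/- sd cooperation response stratified by f_C level.

    On degree-4 PDG structures f_C takes the five exact levels
    {0, 0.25, 0.5, 0.75, 1} and no binning is applied; for the continuous
    PGG f_C, bins of width 0.1 (by default) are used and levels are bin
    midpoints.  An empty stratum yields an empty curve, not an error.
    """
    df, inferred = _as_records(records)
    game = game or inferred or _infer_game(df)
    samples = _stratum(
        prepare_samples(df, game=game, x_threshold=x_threshold, group_size=group_size),
        condition,
    )
    if len(samples) == 0:
        empty = np.array([])
        return CCCurve(condition, empty, empty, empty, empty.astype(int))
    fc = samples["f_C"].to_numpy()
    resp = samples["response"].to_numpy()
    if game == "pdg" and bins is None:
        levels = np.unique(fc)
        codes = np.searchsorted(levels, fc)
    else:
        edges = np.asarray(bins if bins is not None else np.arange(0.0, 1.0001, 0.1))
        codes = np.clip(np.digitize(fc, edges[1:-1]), 0, len(edges) - 2)
        levels = 0.5 * (edges[:-1] + edges[1:])
    k = len(levels)
    n = np.bincount(codes, minlength=k)
    mean = np.full(k, np.nan)
    sd = np.full(k, np.nan)
    nz = n > 0
    sums = np.bincount(codes, weights=resp, minlength=k)
    sq = np.bincount(codes, weights=resp**2, minlength=k)
    mean[nz] = sums[nz] / n[nz]
    var = np.maximum(sq[nz] / n[nz] - mean[nz] ** 2, 0.0)
    sd[nz] = np.sqrt(var)
    return CCCurve(condition, levels, mean, sd, n)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.stderr)


def linear_fit(
    records: RecordsLike,
    condition: str = "all",
    game: Optional[str] = None,
    x_threshold: Optional[float] = None,
    group_size: int = 4,
    per_level_means: bool = False,
) -> LinearFit:
    """OLS fit of the cooperation response on f_C within a stratum.

    By default every pooled player-round sample enters the regression;
    ``per_level_means=True`` instead regresses the per-f_C-level means
    (equal level weights), matching the alternative reading of fitting the
    displayed curve.  A stratum with fewer than two distinct f_C values
    yields an undefined fit (``defined=False``) rather than an error.
    """
    df, inferred = _as_records(records)
    game = game or inferred or _infer_game(df)
    samples = _stratum(
        prepare_samples(df, game=game, x_threshold=x_threshold, group_size=group_size),
        condition,
    )
    n_samples = len(samples)
    if per_level_means:
        curve = cc_curve(df, condition, game=game, x_threshold=x_threshold,
                         group_size=group_size)
        ok = curve.n > 0
        x, y = curve.levels[ok], curve.mean[ok]
    else:
        x = samples["f_C"].to_numpy()
        y = samples["response"].to_numpy()
    if len(x) < 2 or np.unique(x).size < 2:
        return LinearFit(condition, float("nan"), float("nan"), n_samples, defined=False)
    slope, intercept, stderr = _ols(x, y)
    return LinearFit(condition, slope, intercept, n_samples, stderr=stderr)


def slope_bootstrap_ci(
    records: RecordsLike,
    condition: str = "all",
    game: Optional[str] = None,
    x_threshold: Optional[float] = None,
    group_size: int = 4,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: Union[int, np.random.Generator, None] = None,
) -> dict:
    """Cluster bootstrap percentile CI for the OLS slope alpha1.

    Resamples whole independent units (runs for the PDG, groups for the
    PGG) with replacement, recomputing the pooled slope from per-cluster
    sufficient statistics; returns the point estimate and the percentile
    interval.
    """
    df, inferred = _as_records(records)
    game = game or inferred or _infer_game(df)
    samples = _stratum(
        prepare_samples(df, game=game, x_threshold=x_threshold, group_size=group_size),
        condition,
    )
    if len(samples) == 0:
        return {"alpha1": float("nan"), "lo": float("nan"), "hi": float("nan")}
    x = samples["f_C"].to_numpy()
    y = samples["response"].to_numpy()
    _, cl = np.unique(samples["cluster"].to_numpy(), return_inverse=True)
    n_cl = cl.max() + 1
    suff = np.column_stack(
        [
            np.bincount(cl, minlength=n_cl),
            np.bincount(cl, weights=x, minlength=n_cl),
            np.bincount(cl, weights=y, minlength=n_cl),
            np.bincount(cl, weights=x * x, minlength=n_cl),
            np.bincount(cl, weights=x * y, minlength=n_cl),
        ]
    )

    def slope_of(tot: np.ndarray) -> np.ndarray:
        n, sx, sy, sxx, sxy = tot.T if tot.ndim == 2 else tot
        denom = sxx - sx * sx / n
        with np.errstate(divide="ignore", invalid="ignore"):
            return (sxy - sx * sy / n) / denom

    point = float(slope_of(suff.sum(axis=0)))
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = gen.integers(0, n_cl, size=(n_boot, n_cl))
    boots = slope_of(suff[idx].sum(axis=1))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(boots, [alpha, 1.0 - alpha])
    return {"alpha1": point, "lo": float(lo), "hi": float(hi), "n_boot": n_boot}


def mcc_signature(
    fits: Union[dict, Sequence[LinearFit]],
    tau: float = DEFAULT_TAU,
) -> dict:
    """Apply the CC/MCC decision rules to the three stratified fits.

    ``cc``: unconditioned slope > tau.  ``mcc``: slope after own
    cooperation > tau and slope after own defection < tau (negative or
    close to zero).  ``intercept_ordering_ok``: intercept after cooperation
    at least that after defection, up to tau.  Undefined fits propagate as
    None (undetermined).
    """
    if not isinstance(fits, dict):
        fits = {f.condition: f for f in fits}
    missing = [c for c in CONDITIONS if c not in fits]
    if missing:
        raise ValueError(f"missing fits for conditions: {missing}")
    f_all, f_c, f_d = fits["all"], fits["prev_C"], fits["prev_D"]
    cc = (f_all.alpha1 > tau) if f_all.defined else None
    mcc = (
        (f_c.alpha1 > tau) and (f_d.alpha1 < tau)
        if (f_c.defined and f_d.defined)
        else None
    )
    ordering = (
        (f_c.alpha2 - f_d.alpha2 >= -tau) if (f_c.defined and f_d.defined) else None
    )
    return {
        "cc": cc,
        "mcc": mcc,
        "intercept_ordering_ok": ordering,
        "tau": tau,
        "alpha1": {c: fits[c].alpha1 for c in CONDITIONS},
        "alpha2": {c: fits[c].alpha2 for c in CONDITIONS},
    }


def cc_onset_beta(
    betas: Sequence[float],
    result_for_beta: Callable[[float, np.random.SeedSequence], RecordsLike],
    master_seed: Union[int, np.random.SeedSequence, None] = None,
    game: Optional[str] = None,
    x_threshold: Optional[float] = None,
    group_size: int = 4,
    n_boot: int = 1000,
) -> dict:
    """Smallest beta whose unconditioned slope is significantly positive.

    For each beta on the grid, ``result_for_beta`` produces an ensemble;
    the unconditioned alpha1 and its 95% cluster-bootstrap CI are computed,
    and the onset is the smallest beta whose lower CI bound exceeds zero.
    Returns the onset (NaN if none) plus the per-beta table.
    """
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    children = ss.spawn(2 * len(betas))
    rows = []
    onset = float("nan")
    for i, beta in enumerate(betas):
        res = result_for_beta(beta, children[2 * i])
        ci = slope_bootstrap_ci(
            res,
            condition="all",
            game=game,
            x_threshold=x_threshold,
            group_size=group_size,
            n_boot=n_boot,
            rng=np.random.default_rng(children[2 * i + 1]),
        )
        significant = ci["lo"] > 0
        rows.append({"beta": beta, **{k: ci[k] for k in ("alpha1", "lo", "hi")},
                     "significant": significant})
        if significant and np.isnan(onset):
            onset = beta
    return {"onset_beta": onset, "table": pd.DataFrame(rows)}


@dataclass
class SweepResult:
    """Per-cell summaries of a 2-D parameter sweep."""

    axis1: str
    axis2: str
    grid1: np.ndarray
    grid2: np.ndarray
    table: pd.DataFrame


def sweep(
    config,
    axis1: str,
    grid1: Iterable[float],
    axis2: str,
    grid2: Iterable[float],
    n_runs: Optional[int] = None,
    master_seed: Union[int, np.random.SeedSequence, None] = None,
    tau: float = DEFAULT_TAU,
) -> SweepResult:
    """Sweep two parameters (any of beta, A, X, ...) over a grid.

    Each cell runs an independent seeded ensemble of the configured game,
    then computes the mean cooperation, the three stratified fits, and the
    MCC signature.  Per-cell failures are recorded in the ``error`` column
    rather than aborting the sweep.
    """
    grid1 = np.asarray(list(grid1), dtype=float)
    grid2 = np.asarray(list(grid2), dtype=float)
    seed = config.seed if master_seed is None else master_seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(grid1) * len(grid2))
    rows = []
    for idx, (v1, v2) in enumerate(
        (a, b) for a in grid1 for b in grid2
    ):
        cell = replace_config(config, {axis1: v1, axis2: v2})
        row = {axis1: v1, axis2: v2, "error": ""}
        try:
            res = run_ensemble(cell, n_runs=n_runs, master_seed=children[idx])
            xthr = cell.X if cell.game == "pgg" else None
            gs = getattr(cell, "group_size", 4)
            fits = {
                c: linear_fit(res, c, x_threshold=xthr, group_size=gs)
                for c in CONDITIONS
            }
            sig = mcc_signature(fits, tau=tau)
            row.update(
                mean_cooperation=res.grand_mean_cooperation(),
                alpha1_all=fits["all"].alpha1,
                alpha1_C=fits["prev_C"].alpha1,
                alpha1_D=fits["prev_D"].alpha1,
                alpha2_C=fits["prev_C"].alpha2,
                alpha2_D=fits["prev_D"].alpha2,
                alpha2_C_minus_D=fits["prev_C"].alpha2 - fits["prev_D"].alpha2,
                cc=sig["cc"],
                mcc=sig["mcc"],
                intercept_ordering_ok=sig["intercept_ordering_ok"],
                n_samples=fits["all"].n_samples,
            )
        except Exception as exc:  # pragma: no cover - defensive per spec
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return SweepResult(axis1, axis2, grid1, grid2, pd.DataFrame(rows))


def replace_config(config, updates: dict):
    """Return a copy of a RunConfig-like dataclass with fields replaced."""
    return replace(config, **updates)
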