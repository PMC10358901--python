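"""Dominance indices from interaction event logs.

Hierarchies are inferred from decided, directional interactions (typically
feeding supplants). Two indices are provided:

* **normalised David's Scores** — chance-corrected dyadic win proportions
  summed with opponent-weighted terms, normalised to ``[0, N-1]``;
* **Elo ratings** with maximum-likelihood optimisation of the update constant
  ``k`` (grid search) jointly with the start values (continuous optimisation),
  following the optimised-Elo approach. In a temporally static hierarchy the
  optimised ``k`` is 0 and the fitted start values carry all the information.

Raw index values can be standardised to ordinal ranks (1 = highest) or
proportional ranks (equidistant in [0, 1], 1 = highest), and z-scored before
entering downstream models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "WinsMatrix",
    "EloState",
    "build_wins_matrix",
    "davids_scores",
    "elo_trajectory",
    "elo_loglik",
    "optimize_elo",
    "standardise",
    "rank_table",
    "z_standardise",
    "against_hierarchy_rate",
]


@dataclass
class WinsMatrix:
    """Square matrix of decided-interaction counts, ``w[i, j]`` = wins of i over j."""

    ids: list
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.ids)
        if self.w.shape != (n, n):
            raise ValueError("wins matrix must be square and match ids")
        if np.any(self.w < 0) or np.any(self.w != np.round(self.w)):
            raise ValueError("wins must be non-negative integers")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("diagonal of wins matrix must be zero")


@dataclass
class EloState:
    """Elo configuration: update constant, start values, win-probability scale."""

    ids: list
    k: float = 0.0
    start_values: np.ndarray | None = None
    prob_scale: float = 1.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.prob_scale <= 0:
            raise ValueError("prob_scale must be positive")
        if self.start_values is None:
            self.start_values = np.zeros(len(self.ids))
        self.start_values = np.asarray(self.start_values, dtype=float)
        if self.start_values.shape != (len(self.ids),):
            raise ValueError("start_values must match ids")


def build_wins_matrix(events: pd.DataFrame, roster) -> WinsMatrix:
    """Tally a time-ordered event log into a wins matrix.

    ``events`` needs ``winner`` and ``loser`` columns; ``roster`` is the list
    of individual ids. Events referencing unknown ids are rejected.
    """
    ids = list(roster)
    index = {a: i for i, a in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for winner, loser in zip(events["winner"], events["loser"]):
        if winner not in index:
            raise KeyError(f"unknown individual id {winner!r} in event log")
        if loser not in index:
            raise KeyError(f"unknown individual id {loser!r} in event log")
        w[index[winner], index[loser]] += 1
    return WinsMatrix(ids=ids, w=w)


def davids_scores(wins: WinsMatrix) -> pd.Series:
    """Normalised David's Scores.

    Dyadic win proportions are corrected for chance,
    ``Dij = Pij - (Pij - 0.5)/(nij + 1)`` with ``Dij = 0.5`` for unobserved
    dyads; ``DS = w + w2 - l - l2`` where ``w2``/``l2`` weight by the
    opponents' totals; normalised as ``(DS + N(N-1)/2)/N`` so scores lie in
    ``[0, N-1]`` and sum to ``N(N-1)/2``.
    """
    n = len(wins.ids)
    if n < 2:
        raise ValueError("David's Scores need at least 2 individuals")
    w = wins.w
    nij = w + w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pij = np.where(nij > 0, w / np.where(nij > 0, nij, 1.0), 0.5)
    dij = pij - (pij - 0.5) / (nij + 1.0)
    np.fill_diagonal(dij, 0.0)
    w1 = dij.sum(axis=1)
    l1 = dij.sum(axis=0)
    w2 = dij @ w1
    l2 = dij.T @ l1
    ds = w1 + w2 - l1 - l2
    norm = (ds + n * (n - 1) / 2.0) / n
    return pd.Series(norm, index=wins.ids, name="davids")


def _as_pair_indices(events: pd.DataFrame, ids: list) -> tuple[np.ndarray, np.ndarray]:
    index = {a: i for i, a in enumerate(ids)}
    try:
        wi = np.array([index[a] for a in events["winner"]])
        li = np.array([index[a] for a in events["loser"]])
    except KeyError as err:
        raise KeyError(f"unknown individual id {err.args[0]!r} in event log") from None
    return wi, li


def elo_trajectory(events: pd.DataFrame, state: EloState) -> pd.DataFrame:
    """Sequential Elo ratings after each event.

    Win probability for the observed winner is
    ``p = logistic((R_w - R_l)/prob_scale)``; the winner gains ``k (1 - p)``
    and the loser loses the same amount (zero-sum update). Returns one row per
    event with the post-event ratings of every individual; query a date by
    taking the last row at or before it.
    """
    if "date" in events.columns:
        dates = pd.to_datetime(events["date"])
        if not dates.is_monotonic_increasing:
            raise ValueError("event dates must be non-decreasing (time-ordered)")
    wi, li = _as_pair_indices(events, state.ids)
    r = state.start_values.copy()
    out = np.empty((len(events), len(state.ids)))
    for t, (iw, il) in enumerate(zip(wi, li)):
        p = expit((r[iw] - r[il]) / state.prob_scale)
        delta = state.k * (1.0 - p)
        r[iw] += delta
        r[il] -= delta
        out[t] = r
    traj = pd.DataFrame(out, columns=state.ids)
    if "date" in events.columns:
        traj.insert(0, "date", pd.to_datetime(events["date"]).to_numpy())
    return traj


def elo_ratings_at(events: pd.DataFrame, state: EloState, date) -> pd.Series:
    """Ratings in force on ``date`` (start values if no earlier event)."""
    traj = elo_trajectory(events, state)
    if "date" not in traj.columns:
        raise ValueError("event log has no dates to query")
    date = pd.Timestamp(date)
    before = traj[traj["date"] <= date]
    if before.empty:
        return pd.Series(state.start_values, index=state.ids)
    return before.drop(columns="date").iloc[-1]


def _elo_core(wi, li, n, k, s, c, grad=False):
    """Sequential-Elo log-likelihood (and start-value gradient) from index arrays.

    The gradient is exact, accumulated forward through the rating updates
    (each event's ratings depend on the start values through all earlier
    updates). ``k = 0`` has a closed vectorised form: ratings never move.
    """
    if k == 0.0:
        d = (s[wi] - s[li]) / c
        ll = float(np.sum(log_expit(d)))
        if not grad:
            return ll
        g = np.zeros(n)
        coef = (1.0 - expit(d)) / c
        np.add.at(g, wi, coef)
        np.add.at(g, li, -coef)
        return ll, g
    r = s.copy()
    ll = 0.0
    if not grad:
        for iw, il in zip(wi, li):
            d = (r[iw] - r[il]) / c
            ll += log_expit(d)
            delta = k * (1.0 - expit(d))
            r[iw] += delta
            r[il] -= delta
        return float(ll)
    jac = np.eye(n)  # d r / d start_values
    g = np.zeros(n)
    for iw, il in zip(wi, li):
        d = (r[iw] - r[il]) / c
        p = expit(d)
        row = (jac[iw] - jac[il]) / c
        ll += log_expit(d)
        g += (1.0 - p) * row
        delta = k * (1.0 - p)
        dp_row = (k * p * (1.0 - p)) * row
        r[iw] += delta
        r[il] -= delta
        jac[iw] -= dp_row
        jac[il] += dp_row
    return float(ll), g


def elo_loglik(events, state: EloState, grad: bool = False):
    """Log-likelihood of the observed winners under sequential Elo updating."""
    wi, li = _as_pair_indices(events, state.ids)
    return _elo_core(wi, li, len(state.ids), state.k, state.start_values,
                     state.prob_scale, grad=grad)


def optimize_elo(
    events: pd.DataFrame,
    ids=None,
    k_grid=None,
    prob_scale: float = 1.0,
    ridge: float = 1e-3,
) -> dict:
    """Grid search over the Elo update constant ``k`` with per-``k`` start values.

    For each ``k`` on the grid the start values are optimised by maximum
    likelihood (L-BFGS with exact forward-accumulated gradients). A weak ridge
    penalty and a mean-zero anchor make the start values identifiable (adding
    a constant to all of them leaves every win probability unchanged). Ties on
    the grid are broken toward smaller ``k``.

    Returns a dict with ``k``, ``start_values`` (Series), ``loglik`` and the
    per-``k`` profile.
    """
    if ids is None:
        ids = sorted(set(events["winner"]) | set(events["loser"]))
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals to optimise Elo")
    if len(events) < 1:
        raise ValueError("need at least one event")
    if k_grid is None:
        k_grid = np.arange(0.0, 200.0 + 1e-9, 5.0)
    k_grid = np.asarray(sorted(k_grid), dtype=float)

    n = len(ids)
    wi, li = _as_pair_indices(events, ids)
    best = None
    profile = []
    s0 = np.zeros(n)
    for k in k_grid:
        def nll(s, k=k):
            ll, g = _elo_core(wi, li, n, k, s, prob_scale, grad=True)
            return -ll + 0.5 * ridge * np.dot(s, s), -g + ridge * s

        res = minimize(nll, s0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7})
        s_hat = res.x - res.x.mean()  # mean-zero anchor
        ll = _elo_core(wi, li, n, k, s_hat, prob_scale)
        profile.append((k, ll))
        if best is None or ll > best[1] + 1e-9:
            best = (k, ll, s_hat)
        s0 = s_hat  # warm start next grid point
    k_star, ll_star, s_star = best
    return {
        "k": float(k_star),
        "start_values": pd.Series(s_star, index=ids, name="elo_start"),
        "loglik": float(ll_star),
        "profile": pd.DataFrame(profile, columns=["k", "loglik"]),
    }


def standardise(values: pd.Series, method: str) -> pd.Series:
    """Standardise raw index values.

    ``raw`` returns the values unchanged; ``ordinal`` maps them to ranks
    1..N with 1 for the highest value; ``proportional`` maps to equidistant
    values in [0, 1] with 1 for the highest: ``(N - ordinal)/(N - 1)``.
    Ties in the raw values are broken by stable id order, with a warning.
    """
    values = pd.Series(values)
    n = len(values)
    if method == "raw":
        return values.astype(float)
    if n < 2:
        raise ValueError("ordinal/proportional standardisation needs N >= 2")
    if values.duplicated().any() and values.nunique() < n:
        warnings.warn("tied raw scores; ordinal ties broken by id order", stacklevel=2)
    order = np.argsort(-values.to_numpy(), kind="stable")
    ordinal = np.empty(n, dtype=int)
    ordinal[order] = np.arange(1, n + 1)
    if method == "ordinal":
        return pd.Series(ordinal, index=values.index, name="ordinal")
    if method == "proportional":
        prop = (n - ordinal) / (n - 1)
        return pd.Series(prop, index=values.index, name="proportional")
    raise ValueError(f"unknown standardisation {method!r}")


def rank_table(values: pd.Series, year=None) -> pd.DataFrame:
    """All three standardisations of one index for one year-block."""
    out = pd.DataFrame(
        {
            "raw": standardise(values, "raw"),
            "ordinal": standardise(values, "ordinal"),
            "proportional": standardise(values, "proportional"),
        }
    )
    out.index.name = "id"
    if year is not None:
        out.insert(0, "year", year)
    return out


def z_standardise(column) -> np.ndarray:
    """Z-score a variable over all rows entering a model (mean 0, sd 1)."""
    x = np.asarray(column, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-standardise a zero-variance column")
    return (x - x.mean()) / sd


def against_hierarchy_rate(events: pd.DataFrame, ordinal: pd.Series) -> float:
    """Proportion of events won by the ordinally lower-ranking individual.

    ``ordinal`` maps id -> ordinal rank (1 = highest). An event goes against
    the established hierarchy when the winner's ordinal rank number is larger
    than the loser's.
    """
    ranks = pd.Series(ordinal)
    missing = (set(events["winner"]) | set(events["loser"])) - set(ranks.index)
    if missing:
        raise KeyError(f"unranked participants in event log: {sorted(missing)!r}")
    wr = ranks.loc[events["winner"]].to_numpy()
    lr = ranks.loc[events["loser"]].to_numpy()
    return float(np.mean(wr > lr))
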