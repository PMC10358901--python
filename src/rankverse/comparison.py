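"""Model comparison: PSIS-LOO, delta-LOO tables, and the multiverse grid.

Out-of-sample predictive accuracy is estimated with Pareto-smoothed
importance-sampling leave-one-out cross-validation (PSIS-LOO): per
observation, importance ratios proportional to ``1/p(y_i | draw)`` are
stabilised by fitting a generalised Pareto distribution to their upper tail
and replacing the tail by expected order statistics, capped at the observed
maximum. The LOO information criterion is ``-2 * elpd``; within one
behaviour, models are reported as distances to the best model (delta-LOO, the
best model at 0).

The multiverse grid per behaviour is one higher-/lower-ranking factor model
plus all combinations of the five remaining specifications, two dominance
indices (optimised Elo, David's Scores) and three standardisations, 31 models
in total, all fitted to identical response rows. Models are never compared
across behaviours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .design import (
    INDICES,
    SPECS,
    STANDARDISATIONS,
    ModelSpec,
    build_design,
)
from .dominance import (
    build_wins_matrix,
    davids_scores,
    optimize_elo,
    rank_table,
)
from .inference import FamilySpec, FitResult, bayes_r2, fit_model
from .interpret import classify_effect, classify_pattern

__all__ = [
    "LooResult",
    "psis_loo",
    "delta_loo",
    "MultiverseConfig",
    "MultiverseResult",
    "compute_rank_tables",
    "run_multiverse",
]


@dataclass
class LooResult:
    """PSIS-LOO estimate for one model."""

    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Empirical-Bayes generalised-Pareto fit (profile-likelihood average).

    Zhang & Stephens (2009)-style estimator of the tail shape ``k`` and scale
    ``sigma`` from sorted exceedances ``x > 0``, with a weak prior on the
    shape that stabilises short tails. Shape convention: ``k > 0`` means a
    heavy (polynomial) tail.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b = b / (prior_bs * x[int(n / 4 + 0.5) - 1]) + 1.0 / x[-1]
    # profile log-likelihood of each candidate inverse-scale b
    k_prof = np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = n * (np.log(-b / k_prof) - k_prof - 1.0)
    log_lik[~np.isfinite(log_lik)] = -np.inf
    w = np.exp(log_lik - logsumexp(log_lik))
    b_post = np.sum(b * w)
    k = np.mean(np.log1p(-b_post * x))
    sigma = -k / b_post  # scale from the unregularised shape
    k = (n * k + prior_k * 0.5) / (n + prior_k)
    return float(k), float(sigma)


def _psis_smooth_tail(log_ratios: np.ndarray, tail_frac: float = 0.2):
    """Smooth one observation's log importance ratios; returns (lw, k_hat)."""
    s = len(log_ratios)
    lw = log_ratios - np.max(log_ratios)
    m = max(5, int(np.ceil(tail_frac * s)))
    if m >= s:
        m = s - 1
    order = np.argsort(lw)
    tail_idx = order[s - m:]
    cutoff = lw[order[s - m - 1]]
    tail = lw[tail_idx]
    if np.ptp(tail) < 1e-12:
        return lw, np.nan
    exc = np.exp(tail) - np.exp(cutoff)
    if np.any(exc <= 0) or np.all(exc < 1e-300):
        return lw, np.nan
    k, sigma = _gpd_fit(exc)
    if not (np.isfinite(k) and np.isfinite(sigma) and sigma > 0):
        return lw, np.nan
    # expected order statistics of the fitted Pareto, capped at the max ratio
    probs = (np.arange(1, m + 1) - 0.5) / m
    if abs(k) < 1e-12:
        q = -sigma * np.log1p(-probs)
    else:
        q = sigma / k * np.expm1(-k * np.log1p(-probs))
    smoothed = np.minimum(np.log(q + np.exp(cutoff)), 0.0)  # cap at max raw
    if not np.all(np.isfinite(smoothed)):
        return lw, np.nan
    out = lw.copy()
    out[tail_idx[np.argsort(tail)]] = smoothed
    return out, k


def psis_loo(pointwise_loglik: np.ndarray, tail_frac: float = 0.2) -> LooResult:
    """PSIS-LOO from a draws-by-observations log-likelihood matrix.

    For each observation the importance ratios ``exp(-loglik)`` are tail
    smoothed; the pointwise contribution is
    ``elpd_i = log( sum(w * exp(loglik)) / sum(w) )``. The tail-shape
    diagnostic ``k_hat`` is reported per observation, with a warning when any
    exceeds 0.7. Degenerate (constant-draw) observations fall back to the
    unsmoothed estimate.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise_loglik must be draws x observations")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise_loglik must be finite")
    S, n = ll.shape
    pointwise = np.empty(n)
    k_hat = np.empty(n)
    n_degenerate = 0
    for i in range(n):
        lr = -ll[:, i]
        if np.ptp(lr) < 1e-12:
            pointwise[i] = ll[0, i]
            k_hat[i] = np.nan
            n_degenerate += 1
            continue
        lw, k = _psis_smooth_tail(lr, tail_frac)
        if not np.isfinite(k):
            n_degenerate += 1
        k_hat[i] = k
        pointwise[i] = logsumexp(lw + ll[:, i]) - logsumexp(lw)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} observations with degenerate importance weights; "
            "tail shape undefined, unsmoothed estimate used", stacklevel=2)
    if np.any(k_hat[np.isfinite(k_hat)] > 0.7):
        warnings.warn(
            f"{int(np.sum(k_hat > 0.7))} observations with Pareto k > 0.7; "
            "LOO estimate may be unreliable", stacklevel=2)
    elpd = float(np.sum(pointwise))
    se = float(np.sqrt(n * np.var(pointwise)))
    return LooResult(elpd=elpd, se=se, pointwise=pointwise, pareto_k=k_hat)


def delta_loo(results: dict | Sequence[LooResult]) -> pd.DataFrame:
    """Delta-LOO table: distance of each model's LOO-IC to the best model.

    All results must cover identical observations. Returns a frame sorted by
    key order with columns ``looic``, ``delta_loo``, ``rank``; the best model
    (smallest LOO-IC, ties to the earliest key) has delta 0.
    """
    if not isinstance(results, dict):
        results = {i: r for i, r in enumerate(results)}
    if len(results) < 2:
        raise ValueError("need at least 2 models to compare")
    ns = {len(r.pointwise) for r in results.values()}
    if len(ns) != 1:
        raise ValueError("models were fitted to different observation counts; "
                         "LOO-ICs are not comparable")
    looic = np.array([r.looic for r in results.values()])
    best = looic.min()
    delta = looic - best
    order = np.argsort(looic, kind="stable")
    ranks = np.empty(len(looic), dtype=int)
    ranks[order] = np.arange(1, len(looic) + 1)
    return pd.DataFrame(
        {"looic": looic, "delta_loo": delta, "rank": ranks},
        index=list(results.keys()),
    )


@dataclass
class MultiverseConfig:
    """Settings for a multiverse run."""

    indices: Sequence[str] = INDICES
    standardisations: Sequence[str] = STANDARDISATIONS
    specs: Sequence[str] = tuple(s for s in SPECS if s != "factor_higher")
    include_factor_higher: bool = True
    elo_k_grid: Sequence[float] = (0.0, 20.0, 50.0, 100.0)
    method: str = "map"
    n_draws: int = 400
    k_marginal: int = 5
    seed: int = 0
    interpret: bool = True
    mcmc: Optional[dict] = None


@dataclass
class MultiverseResult:
    """Grid of fits for one or more behaviours."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)
    ranks: Optional[pd.DataFrame] = None

    def best(self, behaviour: str) -> pd.Series:
        sub = self.table[(self.table["behaviour"] == behaviour)
                         & self.table["ok"]]
        return sub.loc[sub["delta_loo"].idxmin()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {
            "n_models": int(len(self.table)),
            "behaviours": sorted(self.table["behaviour"].unique().tolist()),
            "rows": self.table.drop(columns=["fit_key"], errors="ignore")
                        .to_dict(orient="records"),
        }


def compute_rank_tables(events: pd.DataFrame, config: MultiverseConfig) -> pd.DataFrame:
    """Per-year rank tables for both indices from the supplant event log.

    Elo ratings use maximum-likelihood optimisation of ``k`` and start values
    per year-block (the rating in force on the first day of the year is the
    optimised start value when ``k* = 0``); David's Scores come from the
    year's wins matrix. Returns a long frame with columns ``year``, ``id``,
    and ``{index}_{standardisation}`` rank columns.
    """
    if "year" not in events.columns:
        events = events.assign(year=pd.to_datetime(events["date"]).dt.year)
    frames = []
    for year, sub in events.groupby("year"):
        ids = sorted(set(sub["winner"]) | set(sub["loser"]))
        elo = optimize_elo(sub, ids=ids, k_grid=config.elo_k_grid)
        wins = build_wins_matrix(sub, ids)
        davids = davids_scores(wins)
        tab_e = rank_table(elo["start_values"], year=year).add_prefix("elo_")
        tab_d = rank_table(davids, year=year).add_prefix("davids_")
        merged = pd.concat([tab_e, tab_d.drop(columns="davids_year")], axis=1)
        merged = merged.rename(columns={"elo_year": "year"})
        merged.index.name = "id"
        frames.append(merged.reset_index())
    return pd.concat(frames, ignore_index=True)


def _grid_specs(behaviour: str, config: MultiverseConfig):
    specs = []
    if config.include_factor_higher:
        specs.append(ModelSpec("factor_higher", index="elo",
                               standardisation="raw", behaviour=behaviour))
    for spec in config.specs:
        if spec == "factor_higher":
            continue
        for index in config.indices:
            for std in config.standardisations:
                specs.append(ModelSpec(spec, index=index, standardisation=std,
                                       behaviour=behaviour))
    return specs


def fit_cell(
    table: pd.DataFrame,
    ranks: pd.DataFrame,
    spec: ModelSpec,
    config: MultiverseConfig,
) -> tuple[FitResult, LooResult]:
    """Fit one multiverse cell and compute its PSIS-LOO."""
    design = build_design(table, ranks, spec, k_marginal=config.k_marginal)
    fam = FamilySpec(family=spec.family)
    fit = fit_model(
        design,
        table["count"].to_numpy(),
        fam,
        method=config.method,
        n_draws=config.n_draws,
        seed=config.seed,
        mcmc=config.mcmc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = psis_loo(fit.pointwise_loglik)
    return fit, loo


def run_multiverse(
    counts: pd.DataFrame,
    events: pd.DataFrame,
    config: MultiverseConfig | None = None,
    behaviours: Optional[Sequence[str]] = None,
    ranks: Optional[pd.DataFrame] = None,
) -> MultiverseResult:
    """Fit the full specification grid per behaviour.

    ``counts`` is a long dyad-year table with a ``behaviour`` column;
    ``events`` the supplant log used to build hierarchies. Individual fit
    failures are recorded (``ok = False``) and the grid continues. Within
    each behaviour exactly one model has delta-LOO 0 (ties broken by earlier
    grid order).
    """
    config = config or MultiverseConfig()
    if ranks is None:
        ranks = compute_rank_tables(events, config)
    if behaviours is None:
        behaviours = sorted(counts["behaviour"].unique().tolist())

    rows = []
    fits = {}
    for behaviour in behaviours:
        table = counts[counts["behaviour"] == behaviour].reset_index(drop=True)
        if table.empty:
            raise ValueError(f"no rows for behaviour {behaviour!r}")
        loos = {}
        for spec in _grid_specs(behaviour, config):
            key = spec.label
            try:
                fit, loo = fit_cell(table, ranks, spec, config)
                fits[key] = fit
                loos[key] = loo
                row = {
                    "behaviour": behaviour,
                    "spec": spec.spec,
                    "index": spec.index,
                    "standardisation": ("-" if spec.spec == "factor_higher"
                                        else spec.standardisation),
                    "ok": True,
                    "elpd": loo.elpd,
                    "looic": loo.looic,
                    "fit_key": key,
                }
                if config.interpret:
                    row.update(_interpret_row(fit, spec))
                rows.append(row)
            except Exception as err:  # continue-and-flag policy
                rows.append({
                    "behaviour": behaviour, "spec": spec.spec,
                    "index": spec.index,
                    "standardisation": ("-" if spec.spec == "factor_higher"
                                        else spec.standardisation),
                    "ok": False, "elpd": np.nan, "looic": np.nan,
                    "fit_key": key, "error": str(err),
                })
        ok_keys = [r["fit_key"] for r in rows
                   if r["behaviour"] == behaviour and r["ok"]]
        if len(ok_keys) >= 2:
            dl = delta_loo({k: loos[k] for k in ok_keys})
            for r in rows:
                if r["behaviour"] == behaviour and r["ok"]:
                    r["delta_loo"] = float(dl.loc[r["fit_key"], "delta_loo"])
                    r["loo_rank"] = int(dl.loc[r["fit_key"], "rank"])
        elif ok_keys:
            for r in rows:
                if r["behaviour"] == behaviour and r["ok"]:
                    r["delta_loo"], r["loo_rank"] = 0.0, 1
        # Bayesian R2 of the behaviour's best model
        best_key = None
        best = np.inf
        for r in rows:
            if r["behaviour"] == behaviour and r["ok"] and r["looic"] < best:
                best, best_key = r["looic"], r["fit_key"]
        if best_key is not None:
            r2 = bayes_r2(fits[best_key])
            for r in rows:
                if r["behaviour"] == behaviour:
                    r["best_model_r2"] = r2["median"] if r.get("fit_key") == best_key else np.nan
    result = pd.DataFrame(rows)
    return MultiverseResult(table=result, fits=fits, ranks=ranks)


def _interpret_row(fit: FitResult, spec: ModelSpec) -> dict:
    out = {}
    try:
        if "rank_sender" in fit.colnames:
            out["sender_arrow"] = classify_effect(
                fit.coef_draws("rank_sender"), spec.standardisation)
        else:
            out["sender_arrow"] = "-"
        if "rank_receiver" in fit.colnames:
            out["receiver_arrow"] = classify_effect(
                fit.coef_draws("rank_receiver"), spec.standardisation)
        else:
            out["receiver_arrow"] = "-"
        if spec.spec != "main_effects":
            pattern = classify_pattern(fit)
            out["pattern_high"] = "+".join(sorted(pattern["high"])) or "-"
            out["pattern_low"] = "+".join(sorted(pattern["low"])) or "-"
        else:
            out["pattern_high"] = out["pattern_low"] = "-"
    except Exception as err:
        out["interpret_error"] = str(err)
    return out
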