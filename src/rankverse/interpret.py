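"""Qualitative interpretation of fitted rank models.

Fixed-effect arrows and directional interaction patterns summarise what a
researcher would conclude from each model:

* **arrows** — a coefficient is deemed meaningful if the central 95% credible
  interval of its posterior excludes 0; the direction is reported on a common
  orientation where "up" always means *higher-ranking individuals show higher
  rates*. Because ordinal ranks run 1 = highest, the sign is inverted for the
  ordinal standardisation.
* **patterns** — the posterior-mean predicted rate surface over a grid of
  (sender rank, receiver rank) is contrasted within sender strata (top/bottom
  half of the hierarchy): Down The Hierarchy (DTH, targeting lower-ranking
  receivers), Closely Ranked Receiver (CRR, targeting receivers of similar
  rank) and Up The Hierarchy (UTH). A code is assigned when the stratum's
  rate contrast exceeds a ratio threshold (default 1.5) with at least 95%
  posterior probability. By construction the higher/lower factor and the rank
  difference can only express DTH/UTH, and the absolute rank difference only
  CRR.
"""

from __future__ import annotations

import numpy as np

__all__ = ["classify_effect", "classify_pattern", "plot_prediction_surface"]

_DIRECTIONAL_ONLY = {"factor_higher", "rank_difference"}
_DISTANCE_ONLY = {"abs_rank_difference"}


def classify_effect(coef_draws: np.ndarray, standardisation: str) -> str:
    """Arrow for one coefficient: ``"up"``, ``"down"`` or ``"none"``.

    ``standardisation`` fixes the orientation: raw index values and
    proportional ranks increase with dominance, ordinal ranks decrease.
    """
    draws = np.asarray(coef_draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 posterior draws to classify")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    if lo <= 0.0 <= hi:
        return "none"
    sign = 1.0 if lo > 0 else -1.0
    if standardisation == "ordinal":
        sign = -sign
    return "up" if sign > 0 else "down"


def _surface_draws(fit, grid_resolution: int, max_draws: int):
    """Posterior draws of the log-rate surface on a (zs, zr) grid."""
    design = fit.design
    zs_obs = design.X[:, design.colnames.index("rank_sender")] \
        if "rank_sender" in design.colnames else None
    # grid over the observed z-rank range; for the nonlinear spec the smooth
    # carries the range in its knots
    lo, hi = -1.6, 1.6
    if zs_obs is not None:
        lo, hi = float(np.min(zs_obs)), float(np.max(zs_obs))
    elif design.smooth is not None:
        lo, hi = design.smooth.meta_x[2], design.smooth.meta_x[3]
    g = np.linspace(lo, hi, grid_resolution)
    zs, zr = np.meshgrid(g, g, indexing="ij")
    rows = design.fixed_rows_at(zs.ravel(), zr.ravel())
    n_coef = rows.shape[1]
    # fixed block + smooth block of the coefficient vector
    p_fixed = len(design.colnames)
    if design.smooth is not None:
        coefs = np.column_stack([fit.u[:, :p_fixed], fit.u[:, -design.smooth.basis.shape[1]:]])
    else:
        coefs = fit.u[:, :p_fixed]
    if coefs.shape[1] != n_coef:
        raise ValueError("coefficient layout does not match prediction rows")
    S = min(max_draws, fit.n_draws)
    eta = coefs[:S] @ rows.T  # S x grid^2
    return g, eta.reshape(S, grid_resolution, grid_resolution)


def classify_pattern(
    fit,
    grid_resolution: int = 21,
    ratio_threshold: float = 1.5,
    prob: float = 0.95,
    max_draws: int = 400,
) -> dict:
    """Directional pattern codes per sender stratum from the fitted surface.

    Returns ``{"high": set, "low": set}`` with subsets of
    ``{"DTH", "CRR", "UTH"}``. Requires a two-rank specification (not
    ``main_effects``).
    """
    spec = fit.design.spec.spec
    if spec == "main_effects":
        raise ValueError("main-effects models carry no dyadic pattern")
    std = fit.design.spec.standardisation
    orient = -1.0 if std == "ordinal" else 1.0

    g, eta = _surface_draws(fit, grid_resolution, max_draws)
    rate = np.exp(eta - eta.max())  # scale-free: only ratios are used
    S = rate.shape[0]
    dom_s = orient * g  # dominance orientation of the sender axis
    zs, zr = np.meshgrid(g, g, indexing="ij")
    dom_diff = orient * (zs - zr)  # > 0 where sender outranks receiver
    absdist = np.abs(zs - zr)
    close_cut = np.quantile(absdist[absdist > 0], 0.25)

    out = {}
    median_dom = np.median(dom_s)
    for stratum, mask_s in (("high", dom_s > median_dom),
                            ("low", dom_s <= median_dom)):
        below = mask_s[:, None] & (dom_diff > 1e-9)
        above = mask_s[:, None] & (dom_diff < -1e-9)
        close = mask_s[:, None] & (absdist <= close_cut) & (absdist > 0)
        far = mask_s[:, None] & (absdist > close_cut)
        codes = set()

        def ratio_prob(num_mask, den_mask):
            if not num_mask.any() or not den_mask.any():
                return 0.0
            num = rate[:, num_mask].mean(axis=1)
            den = rate[:, den_mask].mean(axis=1)
            return float(np.mean(num > ratio_threshold * den))

        if spec not in _DISTANCE_ONLY:
            if ratio_prob(below, above) >= prob:
                codes.add("DTH")
            if ratio_prob(above, below) >= prob:
                codes.add("UTH")
        if spec not in _DIRECTIONAL_ONLY:
            if ratio_prob(close, far) >= prob:
                codes.add("CRR")
        out[stratum] = codes
    return out


def plot_prediction_surface(fit, grid_resolution: int = 41, ax=None):
    """Posterior-mean predicted log-rate surface (offset and REs excluded)."""
    import matplotlib.pyplot as plt

    g, eta = _surface_draws(fit, grid_resolution, max_draws=200)
    mean = eta.mean(axis=0)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(mean.T, origin="lower", aspect="auto",
                   extent=[g[0], g[-1], g[0], g[-1]], cmap="viridis")
    ax.set_xlabel("sender rank (z)")
    ax.set_ylabel("receiver rank (z)")
    ax.figure.colorbar(im, ax=ax, label="posterior mean log-rate")
    return ax
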