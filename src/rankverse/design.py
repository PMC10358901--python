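"""Fixed-effect design construction for the six rank specifications.

Each specification encodes a different hypothesis about how the dominance
ranks of sender and receiver shape dyadic interaction rates:

================== ==========================================================
main_effects        rank_sender + rank_receiver
factor_higher       rank_sender + indicator(sender outranks receiver)
rank_difference     rank_sender + (rank_sender - rank_receiver)
abs_rank_difference rank_sender * |rank_sender - rank_receiver| (full
                    interaction expansion: two mains + product)
interaction         rank_sender * rank_receiver
nonlinear           tensor-product smooth of (rank_sender, rank_receiver)
================== ==========================================================

Rank columns are z-scored over the modelled rows before any product terms are
formed. The higher-/lower-ranking indicator is computed from the raw Elo
index. The tensor smooth uses marginal B-spline bases with quantile knots and
exact integrated-squared-second-derivative penalties, so any bilinear surface
``a + b x + c y + d xy`` lies in the combined penalty null space; a
sum-to-zero constraint over the observed rows absorbs the intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .dominance import z_standardise

SPECS = (
    "main_effects",
    "factor_higher",
    "rank_difference",
    "abs_rank_difference",
    "interaction",
    "nonlinear_interaction",
)
INDICES = ("elo", "davids")
STANDARDISATIONS = ("raw", "ordinal", "proportional")

FAMILY_BY_BEHAVIOUR = {
    "aggression": "zip",
    "supplant": "zip",
    "grooming": "zinb",
    "proximity": "poisson",
}

__all__ = [
    "SPECS",
    "INDICES",
    "STANDARDISATIONS",
    "FAMILY_BY_BEHAVIOUR",
    "ModelSpec",
    "TensorSmooth",
    "tensor_basis",
    "DesignMatrix",
    "build_design",
]


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the multiverse grid."""

    spec: str
    index: str = "elo"
    standardisation: str = "proportional"
    behaviour: str = "aggression"

    def __post_init__(self):
        if self.spec not in SPECS:
            raise ValueError(f"unknown spec {self.spec!r}")
        if self.index not in INDICES:
            raise ValueError(f"unknown index {self.index!r}")
        if self.standardisation not in STANDARDISATIONS:
            raise ValueError(f"unknown standardisation {self.standardisation!r}")
        if self.behaviour not in FAMILY_BY_BEHAVIOUR:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")

    @property
    def family(self) -> str:
        return FAMILY_BY_BEHAVIOUR[self.behaviour]

    @property
    def label(self) -> str:
        if self.spec == "factor_higher":
            return f"{self.behaviour}/factor_higher"
        return f"{self.behaviour}/{self.spec}/{self.index}/{self.standardisation}"


def _marginal_bspline(x: np.ndarray, k: int):
    """Quantile-knot B-spline basis of dimension ``k`` plus curvature penalty.

    Returns ``(basis, penalty, (knots, degree))``. The penalty is the Gram
    matrix of second derivatives integrated over the data range, computed
    exactly by Simpson's rule per knot span (the integrand is piecewise
    quadratic for cubic splines), so coefficient vectors representing linear
    functions are annihilated exactly.
    """
    if k < 3:
        raise ValueError("marginal basis dimension must be >= 3")
    degree = 3 if k >= 4 else 2
    order = degree + 1
    n_interior = k - order
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("degenerate covariate: no spread for spline basis")
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # nudge coincident interior knots apart
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    else:
        interior = np.array([])
    t = np.r_[[lo] * order, interior, [hi] * order]

    def design(v):
        v = np.clip(np.asarray(v, dtype=float), lo, hi)
        return BSpline.design_matrix(v, t, degree, extrapolate=False).toarray()

    basis = design(x)
    # second-derivative Gram by exact Simpson per knot span
    spans = np.unique(t)
    funcs = [BSpline(t, np.eye(k)[j], degree).derivative(2) for j in range(k)]
    S = np.zeros((k, k))
    for a, b in zip(spans[:-1], spans[1:]):
        if b <= a:
            continue
        pts = np.array([a + 1e-12, (a + b) / 2.0, b - 1e-12])
        wts = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        vals = np.array([f(pts) for f in funcs])  # k x 3
        S += (vals * wts) @ vals.T
    S = (S + S.T) / 2.0
    return basis, S, (t, degree, lo, hi)


@dataclass
class TensorSmooth:
    """Constrained tensor-product smooth of two covariates.

    ``basis`` holds the sum-to-zero-constrained design columns at the training
    rows; ``penalties`` the two marginal roughness penalties in the
    constrained parameterisation; :meth:`evaluate` rebuilds rows at new
    covariate values (clamped to the training range).
    """

    basis: np.ndarray
    penalties: list
    raw_penalties: list
    constraint: np.ndarray  # (k^2) -> (k^2 - 1) transform Z
    meta_x: tuple
    meta_y: tuple
    k_marginal: int

    def _raw_rows(self, x, y):
        tx, dx, lox, hix = self.meta_x
        ty, dy, loy, hiy = self.meta_y
        bx = BSpline.design_matrix(
            np.clip(np.asarray(x, float), lox, hix), tx, dx, extrapolate=False
        ).toarray()
        by = BSpline.design_matrix(
            np.clip(np.asarray(y, float), loy, hiy), ty, dy, extrapolate=False
        ).toarray()
        return (bx[:, :, None] * by[:, None, :]).reshape(len(bx), -1)

    def evaluate(self, x, y) -> np.ndarray:
        """Constrained basis rows at new (x, y) pairs."""
        return self._raw_rows(x, y) @ self.constraint


def tensor_basis(x, y, k_marginal: int = 5) -> TensorSmooth:
    """Tensor-product smooth basis with marginal roughness penalties.

    Marginal cubic B-spline bases of dimension ``k_marginal`` each (quantile
    knots); the tensor expansion has ``k_marginal**2`` columns, reduced by one
    by the sum-to-zero constraint over the observed rows so the model
    intercept stays estimable. Penalties are ``S_x (x) I`` and ``I (x) S_y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("covariates must be finite")
    k = int(k_marginal)
    n = len(x)
    if k * k >= n:
        raise ValueError(
            f"tensor basis with {k * k} coefficients is unidentifiable on {n} rows"
        )
    bx, sx, meta_x = _marginal_bspline(x, k)
    by, sy, meta_y = _marginal_bspline(y, k)
    raw = (bx[:, :, None] * by[:, None, :]).reshape(n, k * k)
    s1 = np.kron(sx, np.eye(k))
    s2 = np.kron(np.eye(k), sy)
    # sum-to-zero over observed rows: null space of the column-sum vector
    c = raw.sum(axis=0)
    q, _ = np.linalg.qr(c[:, None], mode="complete")
    z = q[:, 1:]
    return TensorSmooth(
        basis=raw @ z,
        penalties=[z.T @ s1 @ z, z.T @ s2 @ z],
        raw_penalties=[s1, s2],
        constraint=z,
        meta_x=meta_x,
        meta_y=meta_y,
        k_marginal=k,
    )


@dataclass
class DesignMatrix:
    """Model-ready design: fixed effects, smooth block, offset, grouping codes."""

    X: np.ndarray
    colnames: list
    offset: np.ndarray
    groups: dict  # name -> (codes array, levels list)
    spec: ModelSpec
    smooth: Optional[TensorSmooth] = None
    z_info: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.offset)

    def fixed_rows_at(self, zs, zr) -> np.ndarray:
        """Fixed-effect + smooth design rows at arbitrary z-rank pairs.

        Used for posterior prediction surfaces; random effects and offset are
        excluded. ``zs``/``zr`` are on the z-scored rank scale of this design.
        """
        zs = np.asarray(zs, dtype=float)
        zr = np.asarray(zr, dtype=float)
        spec = self.spec.spec
        one = np.ones_like(zs)
        if spec == "main_effects":
            cols = [one, zs, zr]
        elif spec == "factor_higher":
            cols = [one, zs, (zs > zr).astype(float)]
        elif spec == "rank_difference":
            cols = [one, zs, zs - zr]
        elif spec == "abs_rank_difference":
            d = np.abs(zs - zr)
            cols = [one, zs, d, zs * d]
        elif spec == "interaction":
            cols = [one, zs, zr, zs * zr]
        elif spec == "nonlinear_interaction":
            return np.column_stack([one, self.smooth.evaluate(zs, zr)])
        else:  # pragma: no cover
            raise ValueError(spec)
        return np.column_stack(cols)

    def to_files(self, stem: str) -> None:
        """Audit dump: columnar CSV plus JSON metadata."""
        df = pd.DataFrame(self.X, columns=self.colnames)
        df["offset_log_hours"] = self.offset
        for name, (codes, levels) in self.groups.items():
            df[name] = [levels[c] for c in codes]
        if self.smooth is not None:
            for j in range(self.smooth.basis.shape[1]):
                df[f"smooth_{j}"] = self.smooth.basis[:, j]
        df.to_csv(f"{stem}.csv", index=False)
        meta = {
            "spec": self.spec.__dict__,
            "colnames": self.colnames,
            "n_rows": self.n_rows,
            "smooth": None
            if self.smooth is None
            else {
                "k_marginal": self.smooth.k_marginal,
                "n_columns": int(self.smooth.basis.shape[1]),
                "penalties": [p.tolist() for p in self.smooth.penalties],
            },
        }
        with open(f"{stem}.json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _rank_lookup(ranks: pd.DataFrame, index: str, column: str) -> dict:
    """(year, id) -> rank value for one (index, standardisation) choice."""
    col = f"{index}_{column}" if f"{index}_{column}" in ranks.columns else column
    return {
        (row["year"], row["id"]): row[col] for _, row in ranks.iterrows()
    }


def build_design(
    table: pd.DataFrame,
    ranks: pd.DataFrame,
    spec: ModelSpec,
    k_marginal: int = 5,
    abs_full_interaction: bool = True,
) -> DesignMatrix:
    """Assemble the design matrix for one specification.

    ``table`` is a dyad-year count table (sender, receiver, year, count,
    effort_hours); ``ranks`` a long table with columns ``year``, ``id`` and
    per-index rank columns ``{index}_raw``, ``{index}_ordinal``,
    ``{index}_proportional``. Every sender/receiver/year in ``table`` must be
    ranked. Rank covariates are z-scored over the table rows before products.
    """
    std = spec.standardisation
    lut = _rank_lookup(ranks, spec.index, std)
    raw_elo = _rank_lookup(ranks, "elo", "raw") if spec.spec == "factor_higher" else None

    def look(tbl, who, table_lut):
        vals = []
        for _, row in tbl.iterrows():
            key = (row["year"], row[who])
            if key not in table_lut:
                raise KeyError(
                    f"no rank for {who} {row[who]!r} in year {row['year']!r}"
                )
            vals.append(table_lut[key])
        return np.array(vals, dtype=float)

    rs = look(table, "sender", lut)
    rr = look(table, "receiver", lut)
    zs = z_standardise(rs)
    zr = z_standardise(rr)

    one = np.ones(len(table))
    smooth = None
    if spec.spec == "main_effects":
        X = np.column_stack([one, zs, zr])
        names = ["intercept", "rank_sender", "rank_receiver"]
    elif spec.spec == "factor_higher":
        es = look(table, "sender", raw_elo)
        er = look(table, "receiver", raw_elo)
        X = np.column_stack([one, zs, (es > er).astype(float)])
        names = ["intercept", "rank_sender", "sender_higher"]
    elif spec.spec == "rank_difference":
        X = np.column_stack([one, zs, zs - zr])
        names = ["intercept", "rank_sender", "rank_difference"]
    elif spec.spec == "abs_rank_difference":
        d = np.abs(zs - zr)
        if abs_full_interaction:
            X = np.column_stack([one, zs, d, zs * d])
            names = ["intercept", "rank_sender", "abs_rank_difference",
                     "rank_sender:abs_rank_difference"]
        else:
            X = np.column_stack([one, zs, d])
            names = ["intercept", "rank_sender", "abs_rank_difference"]
    elif spec.spec == "interaction":
        X = np.column_stack([one, zs, zr, zs * zr])
        names = ["intercept", "rank_sender", "rank_receiver",
                 "rank_sender:rank_receiver"]
    elif spec.spec == "nonlinear_interaction":
        smooth = tensor_basis(zs, zr, k_marginal=k_marginal)
        X = one[:, None]
        names = ["intercept"]
    else:  # pragma: no cover
        raise ValueError(spec.spec)

    effort = table["effort_hours"].to_numpy(dtype=float)
    if np.any(~np.isfinite(np.log(effort))):
        raise ValueError("effort_hours must be positive and finite")

    groups = {}
    for name, key in (("year", "year"), ("sender", "sender"), ("receiver", "receiver")):
        levels = sorted(table[key].unique().tolist())
        idx = {v: i for i, v in enumerate(levels)}
        groups[name] = (np.array([idx[v] for v in table[key]]), levels)
    # dyad identity: unordered pair (same id for A->B and B->A)
    pairs = [tuple(sorted((s, r))) for s, r in zip(table["sender"], table["receiver"])]
    levels = sorted(set(pairs))
    idx = {v: i for i, v in enumerate(levels)}
    groups["dyad"] = (np.array([idx[v] for v in pairs]), levels)

    return DesignMatrix(
        X=X,
        colnames=names,
        offset=np.log(effort),
        groups=groups,
        spec=spec,
        smooth=smooth,
        z_info={"rs_mean": rs.mean(), "rs_sd": rs.std(),
                "rr_mean": rr.mean(), "rr_sd": rr.std()},
    )
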