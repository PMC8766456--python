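"""Multi-site generalized dissimilarity modelling of zeta diversity.

Regresses a Sorensen-equivalent zeta response (shared-species count of an
i-site combination divided by the combination's mean single-site richness,
hence bounded in [0, 1]) on monotone I-spline transforms of the mean
pairwise environmental differences and the mean pairwise geographic
distance among the combination's sites.  Coefficients are constrained so
each predictor's contribution to dissimilarity is non-decreasing; the
fitted per-variable curves and their amplitudes (curve value at the full
rescaled range) rank the environmental drivers of compositional turnover.
Variance is partitioned into environment-only, distance-only, shared and
unexplained fractions by comparing the full, environment-only and
distance-only fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear

from .zeta import SchemeConfig, _nn_combinations

DEFAULT_VARIABLES = (
    "altitude", "canopy_openness", "deadwood_volume", "basal_area",
    "tree_diversity", "very_large_tree_density", "trem_diversity",
    "trem_density",
)


@dataclass
class IsplineBasis:
    """Monotone I-spline basis on [0, 1].

    I-splines are integrated M-splines: each basis function is
    non-decreasing, 0 at 0 and 1 at 1, so a non-negative combination is a
    monotone curve anchored at the origin.  With ``order`` k and
    ``n_knots`` evenly spaced interior knots there are k + n_knots basis
    functions (3 by default).
    """

    order: int = 2
    n_knots: int = 1
    knots: tuple[float, ...] | None = None

    def interior(self) -> np.ndarray:
        if self.knots is not None:
            return np.asarray(self.knots, dtype=float)
        return np.linspace(0.0, 1.0, self.n_knots + 2)[1:-1]

    @property
    def n_basis(self) -> int:
        return self.order + len(self.interior())


def ispline_transform(x, basis: IsplineBasis | None = None) -> np.ndarray:
    """I-spline basis values at x in [0, 1]; shape (len(x), n_basis).

    Built from the identity I_j(x) = sum_{m > j} B_m(x) over normalized
    B-splines of degree ``order`` on the clamped knot vector: reverse
    cumulative sums of the B-spline design matrix, dropping the constant
    (the full sum is identically 1).
    """
    basis = basis or IsplineBasis()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if (x < 0).any() or (x > 1).any():
        raise ValueError("I-spline argument outside [0, 1]")
    k = basis.order
    t = np.concatenate([np.zeros(k + 1), basis.interior(), np.ones(k + 1)])
    dm = BSpline.design_matrix(np.clip(x, 0.0, 1.0 - 1e-12), t, k).toarray()
    # at x exactly 1 the clipped evaluation is fine: the last B-spline is 1
    rev = np.cumsum(dm[:, ::-1], axis=1)[:, ::-1]
    return rev[:, 1:]  # drop the all-ones column


@dataclass
class MsgdmDesign:
    """One row per sampled i-combination: response + rescaled predictors."""

    frame: pd.DataFrame          # columns: response, distance, <variables>
    variables: tuple[str, ...]
    order: int
    n_dropped: int = 0           # all-empty combinations discarded


@dataclass
class MsgdmModel:
    variables: tuple[str, ...]
    basis: IsplineBasis
    intercept: float
    coefs: dict                  # variable -> ndarray of n_basis coefficients
    r2: float

    @property
    def amplitudes(self) -> pd.Series:
        """Total dissimilarity contribution of each variable (curve at 1)."""
        return pd.Series({v: float(self.coefs[v].sum())
                          for v in self.variables})

    def curve(self, variable: str, grid: np.ndarray | None = None) -> pd.DataFrame:
        g = np.linspace(0.0, 1.0, 101) if grid is None else np.asarray(grid)
        vals = ispline_transform(g, self.basis) @ self.coefs[variable]
        return pd.DataFrame({"x": g, "contribution": vals})


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


def combination_design(incidence: pd.DataFrame, metadata: pd.DataFrame,
                       order: int, cfg: SchemeConfig,
                       variables=DEFAULT_VARIABLES) -> MsgdmDesign:
    """Build the regression design for one zeta order.

    Response: shared-species count of each sampled combination divided by
    the mean single-plot richness of its plots (Sorensen-equivalent zeta,
    in [0, 1]); combinations whose plots are all empty are dropped and
    counted.  Predictors: per variable, the mean pairwise absolute
    difference of the min-max rescaled values among the combination's
    plots; plus the mean pairwise Euclidean distance, rescaled to [0, 1]
    over the sampled combinations.
    """
    if order < 2:
        raise ValueError("msgdm needs order >= 2")
    meta = metadata.set_index("plot_id").loc[incidence.index]
    missing = [v for v in variables if v not in meta.columns]
    if missing:
        raise KeyError(f"metadata lacks variables: {missing}")
    mat = (incidence.to_numpy() > 0).astype(np.int8)
    N = mat.shape[0]
    rng = np.random.default_rng(cfg.seed)
    if cfg.scheme == "NN":
        coords = meta[["x", "y"]].to_numpy(float)
        combos = _nn_combinations(coords, order)
        if len(combos) > cfg.sam:
            combos = combos[rng.choice(len(combos), cfg.sam, replace=False)]
    else:
        total = comb(N, order)
        if total <= cfg.sam:
            combos = np.array(list(combinations(range(N), order)), dtype=int)
        else:
            combos = np.empty((cfg.sam, order), dtype=int)
            for k in range(cfg.sam):
                combos[k] = rng.choice(N, size=order, replace=False)
    rich = mat.sum(axis=1).astype(float)
    shared = (mat[combos].sum(axis=1) == order).sum(axis=1).astype(float)
    mean_rich = rich[combos].mean(axis=1)
    keep = mean_rich > 0
    n_dropped = int((~keep).sum())
    combos, shared, mean_rich = combos[keep], shared[keep], mean_rich[keep]
    response = shared / mean_rich

    iu = np.triu_indices(order, k=1)
    cols = {"response": response}
    coords = meta[["x", "y"]].to_numpy(float)
    pts = coords[combos]                       # (n, i, 2)
    dd = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=-1)
    dist = dd[:, iu[0], iu[1]].mean(axis=1)
    cols["distance"] = _minmax(dist)
    for v in variables:
        z = _minmax(meta[v].to_numpy(float))
        zz = z[combos]
        diffs = np.abs(zz[:, iu[0]] - zz[:, iu[1]]).mean(axis=1)
        cols[v] = diffs
    frame = pd.DataFrame(cols)
    return MsgdmDesign(frame=frame, variables=tuple(variables), order=order,
                       n_dropped=n_dropped)


def fit_msgdm(design: MsgdmDesign, basis: IsplineBasis | None = None,
              predictors: tuple[str, ...] | None = None) -> MsgdmModel:
    """Constrained least squares of the zeta response on I-spline terms.

    Model: response = intercept - sum_v curve_v(x_v) with every I-spline
    coefficient >= 0, so each variable's fitted effect on dissimilarity is
    monotone non-decreasing.  Solved with bounded least squares; r2 is the
    fraction of response variance explained.
    """
    basis = basis or IsplineBasis()
    preds = predictors if predictors is not None \
        else ("distance",) + design.variables
    y = design.frame["response"].to_numpy(float)
    blocks = [ispline_transform(design.frame[v].to_numpy(float), basis)
              for v in preds]
    nb = basis.n_basis
    if len(y) < 10 * (len(preds) * nb + 1):
        import warnings
        warnings.warn("fewer than 10 rows per parameter in msgdm design",
                      stacklevel=2)
    A = np.column_stack([np.ones_like(y)] + [-b for b in blocks])
    lb = np.concatenate([[-np.inf], np.zeros(len(preds) * nb)])
    res = lsq_linear(A, y, bounds=(lb, np.full(len(lb), np.inf)))
    beta = res.x
    fitted = A @ beta
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    coefs = {v: beta[1 + j * nb:1 + (j + 1) * nb] for j, v in enumerate(preds)}
    return MsgdmModel(variables=tuple(preds), basis=basis,
                      intercept=float(beta[0]), coefs=coefs, r2=r2)


@dataclass
class AveragedMsgdm:
    """Round-averaged I-spline model (mean and spread over refits)."""

    variables: tuple[str, ...]
    basis: IsplineBasis
    amplitude_mean: pd.Series
    amplitude_sd: pd.Series
    curve_mean: pd.DataFrame     # long: variable, x, contribution
    r2_mean: float
    n_rounds: int


def average_rounds(incidence: pd.DataFrame, metadata: pd.DataFrame,
                   order: int, cfg: SchemeConfig, n_rounds: int = 30,
                   basis: IsplineBasis | None = None,
                   variables=DEFAULT_VARIABLES) -> AveragedMsgdm:
    """Refit the model on independent combination samples and average.

    Each round draws a fresh combination sample (seeded from ``cfg.seed``)
    and refits; I-spline curves, amplitudes and r2 are averaged so the
    response curves are stable against Monte-Carlo sampling noise.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    basis = basis or IsplineBasis()
    grid = np.linspace(0.0, 1.0, 101)
    amps, r2s, curves = [], [], []
    preds = None
    for r in range(n_rounds):
        sub = SchemeConfig(scheme=cfg.scheme, sam=cfg.sam,
                           seed=cfg.seed + 7919 * r, coords=cfg.coords)
        design = combination_design(incidence, metadata, order, sub,
                                    variables=variables)
        model = fit_msgdm(design, basis)
        preds = model.variables
        amps.append(model.amplitudes)
        r2s.append(model.r2)
        curves.append(np.stack([
            ispline_transform(grid, basis) @ model.coefs[v] for v in preds]))
    amp = pd.concat(amps, axis=1)
    mean_curves = np.mean(curves, axis=0)
    long = pd.DataFrame({
        "variable": np.repeat(preds, len(grid)),
        "x": np.tile(grid, len(preds)),
        "contribution": mean_curves.ravel(),
    })
    return AveragedMsgdm(
        variables=preds, basis=basis,
        amplitude_mean=amp.mean(axis=1), amplitude_sd=amp.std(axis=1),
        curve_mean=long, r2_mean=float(np.mean(r2s)), n_rounds=n_rounds)


@dataclass
class VariancePartition:
    environment: float
    distance: float
    shared: float
    unexplained: float
    clipped: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series({"environment": self.environment,
                          "distance": self.distance,
                          "shared": self.shared,
                          "unexplained": self.unexplained})


def variance_partition(design: MsgdmDesign,
                       basis: IsplineBasis | None = None) -> VariancePartition:
    """Partition explained variance between environment and distance.

    Fits the full, environment-only and distance-only models;
    environment-only fraction = r2_full - r2_dist, distance-only =
    r2_full - r2_env, shared = r2_env + r2_dist - r2_full (clipped at 0
    with a flag when slightly negative), unexplained = 1 - r2_full.  The
    four fractions sum to 1 by construction.
    """
    basis = basis or IsplineBasis()
    full = fit_msgdm(design, basis)
    env = fit_msgdm(design, basis, predictors=design.variables)
    dist = fit_msgdm(design, basis, predictors=("distance",))
    e_only = full.r2 - dist.r2
    d_only = full.r2 - env.r2
    shared = env.r2 + dist.r2 - full.r2
    clipped = False
    if shared < 0:
        # nested bounded fits can leak tiny negative shared fractions;
        # clip to 0 and absorb the excess into the larger unique part so
        # the four fractions still sum to 1
        excess = -shared
        shared, clipped = 0.0, True
        if e_only >= d_only:
            e_only -= excess
        else:
            d_only -= excess
    return VariancePartition(environment=e_only, distance=d_only,
                             shared=shared, unexplained=1.0 - full.r2,
                             clipped=clipped)
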