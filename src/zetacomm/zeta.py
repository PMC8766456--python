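"""Zeta diversity: multi-site shared-species decline and model selection.

Zeta diversity of order i is the expected number of species shared by i
sampling units.  The decline of zeta with order, and the retention rate
(zeta ratio) between consecutive orders, separate communities assembled by
niche processes (power-law decline: rare species turn over fast, common
ones persist) from stochastically assembled ones (exponential decline:
every species is equally likely to drop out).  Site combinations are drawn
either over all subsets (ALL) or as each site plus its nearest geographic
neighbours (NN).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class SchemeConfig:
    """Combination-sampling scheme for Monte-Carlo zeta estimates.

    ``scheme`` "ALL" draws uniform i-subsets of the units (exact
    enumeration whenever C(N, i) <= sam); "NN" builds one combination per
    focal unit — the unit plus its i-1 nearest neighbours by Euclidean
    distance (ties broken by unit order) — subsampled to ``sam`` focal
    units when there are more.
    """

    scheme: str = "ALL"
    sam: int = 5000
    seed: int = 0
    coords: np.ndarray | None = None  # (N, 2), required for NN

    def __post_init__(self) -> None:
        if self.scheme not in {"ALL", "NN"}:
            raise ValueError("scheme must be 'ALL' or 'NN'")
        if self.sam < 1:
            raise ValueError("sam must be >= 1")


@dataclass
class ZetaDecline:
    orders: np.ndarray
    zeta: np.ndarray
    sd: np.ndarray
    n_combinations: np.ndarray

    @property
    def ratios(self) -> np.ndarray:
        """Retention rates zeta_{i+1}/zeta_i, NaN where zeta_i = 0."""
        z = self.zeta
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(z[:-1] > 0, z[1:] / z[:-1], np.nan)
        return r

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"order": self.orders, "zeta": self.zeta,
                           "sd": self.sd, "n": self.n_combinations})
        df["ratio"] = np.append(self.ratios, np.nan)
        return df


@dataclass
class ZetaFit:
    form: str                   # "exponential" or "power-law"
    intercept: float            # on the log-zeta scale
    slope: float                # decay rate (positive for declining zeta)
    rss: float
    aic: float
    n_points: int
    perfect_fit: bool = False


# ---------------------------------------------------------------------------
# zeta values
# ---------------------------------------------------------------------------

def zeta_exact_all(incidence: pd.DataFrame, i: int) -> float:
    """Exact expected zeta_i over all i-unit combinations (closed form).

    zeta_i = sum_s C(n_s, i) / C(N, i) with n_s the occupancy of species s:
    the hypergeometric probability that all i drawn units contain s, summed
    over species.
    """
    N = incidence.shape[0]
    if not 1 <= i <= N:
        raise ValueError(f"order {i} outside 1..{N}")
    occ = incidence.to_numpy().sum(axis=0).astype(float)
    occ = occ[occ >= i]
    if len(occ) == 0:
        return 0.0
    log_ratio = (gammaln(occ + 1) - gammaln(occ - i + 1)
                 - gammaln(N + 1) + gammaln(N - i + 1))
    return float(np.exp(log_ratio).sum())


def zeta_brute_force(incidence: pd.DataFrame, i: int) -> float:
    """Oracle: average shared-species count over every i-combination."""
    mat = incidence.to_numpy() > 0
    N = mat.shape[0]
    vals = [int((mat[list(c)].all(axis=0)).sum())
            for c in combinations(range(N), i)]
    return float(np.mean(vals))


def _shared_counts(mat: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """Shared-species count for each row of ``combos`` (indices into mat)."""
    i = combos.shape[1]
    out = np.empty(len(combos))
    step = max(1, 2_000_000 // (i * mat.shape[1] + 1))
    for lo in range(0, len(combos), step):
        chunk = combos[lo:lo + step]
        out[lo:lo + step] = (mat[chunk].sum(axis=1) == i).sum(axis=1)
    return out


def _nn_combinations(coords: np.ndarray, i: int) -> np.ndarray:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    # stable argsort breaks distance ties by unit index; focal unit is at
    # distance 0 so it is always included
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :i]


def zeta_mc(incidence: pd.DataFrame, i: int, cfg: SchemeConfig):
    """(zeta_i estimate, sd over combinations) under the configured scheme."""
    mat = (incidence.to_numpy() > 0).astype(np.int8)
    N = mat.shape[0]
    if not 1 <= i <= N:
        raise ValueError(f"order {i} outside 1..{N}")
    rng = np.random.default_rng(cfg.seed)
    if cfg.scheme == "NN":
        if cfg.coords is None:
            raise ValueError("NN scheme needs coordinates")
        combos = _nn_combinations(np.asarray(cfg.coords, float), i)
        if len(combos) > cfg.sam:
            combos = combos[rng.choice(len(combos), cfg.sam, replace=False)]
    else:
        total = comb(N, i)
        if total <= cfg.sam:
            combos = np.array(list(combinations(range(N), i)), dtype=int)
            if combos.size == 0:
                combos = combos.reshape(0, i)
        else:
            # uniform i-subsets: without replacement inside a draw,
            # with replacement across draws
            combos = np.empty((cfg.sam, i), dtype=int)
            for k in range(cfg.sam):
                combos[k] = rng.choice(N, size=i, replace=False)
    vals = _shared_counts(mat, combos)
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def zeta_decline(incidence: pd.DataFrame, i_max: int,
                 cfg: SchemeConfig | None = None) -> ZetaDecline:
    """Zeta means (and sds) for orders 1..i_max.

    Without a scheme config the exact closed form is used (sd = 0);
    otherwise each order is estimated under the scheme.
    """
    N = incidence.shape[0]
    if i_max > N:
        raise ValueError("i_max exceeds number of units")
    orders = np.arange(1, i_max + 1)
    zeta = np.empty(i_max)
    sd = np.zeros(i_max)
    n_comb = np.zeros(i_max, dtype=int)
    for k, i in enumerate(orders):
        if cfg is None:
            zeta[k] = zeta_exact_all(incidence, int(i))
            n_comb[k] = comb(N, int(i))
        else:
            sub = SchemeConfig(scheme=cfg.scheme, sam=cfg.sam,
                               seed=cfg.seed + int(i), coords=cfg.coords)
            zeta[k], sd[k] = zeta_mc(incidence, int(i), sub)
            n_comb[k] = min(cfg.sam, comb(N, int(i))) if cfg.scheme == "ALL" \
                else min(cfg.sam, N)
    return ZetaDecline(orders=orders, zeta=zeta, sd=sd, n_combinations=n_comb)


# ---------------------------------------------------------------------------
# decline regressions
# ---------------------------------------------------------------------------

def _aic_ols(rss: float, n: int, p: int = 2) -> float:
    # Gaussian log-likelihood AIC of an OLS fit on the log scale,
    # p regression parameters plus the error variance; numerically exact
    # fits (RSS at float rounding level) get the -inf perfect-fit sentinel
    if rss <= 1e-12:
        return -np.inf
    return n * np.log(2 * np.pi) + n * np.log(rss / n) + n + 2 * (p + 1)


def fit_decline(decline: ZetaDecline, form: str,
                min_order: int = 2) -> ZetaFit:
    """OLS fit of log zeta_i on i (exponential) or log i (power-law).

    Orders below ``min_order`` are excluded (declines are conventionally
    fitted from zeta_2 up) and the fit range stops at the first zero zeta.
    """
    if form not in {"exponential", "power-law"}:
        raise ValueError("form must be 'exponential' or 'power-law'")
    keep = decline.orders >= min_order
    orders = decline.orders[keep].astype(float)
    z = decline.zeta[keep]
    nz = np.flatnonzero(z <= 0)
    if len(nz):
        orders, z = orders[:nz[0]], z[:nz[0]]
    if len(z) < 3:
        raise ValueError("need at least 3 positive zeta values to fit")
    x = orders if form == "exponential" else np.log(orders)
    y = np.log(z)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    aic = _aic_ols(rss, len(y))
    return ZetaFit(form=form, intercept=float(beta[0]), slope=float(-beta[1]),
                   rss=rss, aic=aic, n_points=len(y),
                   perfect_fit=not np.isfinite(aic))


def compare_fits(decline: ZetaDecline, min_order: int = 2):
    """Fit both decline forms; return (preferred form, delta AIC, fits).

    delta AIC = AIC(exponential) - AIC(power-law); ties are reported as
    "tie" rather than silently broken.
    """
    fe = fit_decline(decline, "exponential", min_order)
    fp = fit_decline(decline, "power-law", min_order)
    if fe.aic == fp.aic:
        return "tie", 0.0, (fe, fp)
    best = "exponential" if fe.aic < fp.aic else "power-law"
    return best, fe.aic - fp.aic, (fe, fp)


# ---------------------------------------------------------------------------
# per-group retention curves
# ---------------------------------------------------------------------------

def group_retention_curves(incidence: pd.DataFrame, motu_groups: dict,
                           plot_categories: dict, cfg: SchemeConfig,
                           i_max: int | None = None,
                           coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """Retention-rate (zeta ratio) curves per MOTU group x plot category.

    For each category (a set of plot labels) every listed MOTU group is
    restricted to the category's plots — keeping plots where the group is
    absent, so zero-richness plots still count — and a zeta decline is
    computed on the restricted matrix, alongside the whole-community mean
    curve for the category (group label "__all__").  Returns a long
    DataFrame (category, group, order, zeta, ratio, defined).
    """
    rows = []
    for cat, plots in plot_categories.items():
        plots = [p for p in plots if p in incidence.index]
        if len(plots) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 plots")
        sub_cfg = SchemeConfig(
            scheme=cfg.scheme, sam=cfg.sam, seed=cfg.seed,
            coords=None if cfg.scheme == "ALL" else
            coords.loc[plots].to_numpy(float))
        top = i_max or len(plots)
        top = min(top, len(plots))
        groups = dict(motu_groups)
        groups["__all__"] = list(incidence.columns)
        for gname, cols in groups.items():
            cols = [c for c in cols if c in incidence.columns]
            sub = incidence.loc[plots, cols]
            dec = zeta_decline(sub, top, sub_cfg)
            ratios = np.append(dec.ratios, np.nan)
            for k, order in enumerate(dec.orders):
                rows.append((cat, gname, int(order), dec.zeta[k], ratios[k],
                             bool(dec.zeta[k] > 0)))
    return pd.DataFrame(rows, columns=["category", "group", "order", "zeta",
                                       "ratio", "defined"])
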