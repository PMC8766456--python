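"""Richness GLMs, indicator-species analysis and bootstrapped rarity scores.

Plot-level species richness is modelled with an additive quasi-Poisson GLM
(log link, Pearson-dispersion scaling) across dieback level, stand type and
district, with type-II deviance tests per factor.  Indicator species are
scored with the group-size-equalized IndVal statistic sqrt(A * B)
(specificity x fidelity), permutation p-values, Holm correction across
species, and the p-value range over 10 independently seeded runs.  Rarity
heatmap scores come from 100 plot bootstraps, rescaled so that each
dieback category represents one third of the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


@dataclass
class RichnessGlmResult:
    params: pd.Series
    dispersion: float
    tests: pd.DataFrame  # index factor; columns df, scaled_dev, F, p
    model: object


def fit_richness_glm(richness: pd.Series, factors: pd.DataFrame) -> RichnessGlmResult:
    """Additive quasi-Poisson GLM of plot richness on categorical factors.

    Fits a log-link Poisson GLM by IRLS, estimates the dispersion as
    Pearson chi-square / residual df, and runs a type-II test per factor:
    the deviance increase from dropping that factor from the full additive
    model, scaled by the dispersion, as an F statistic on (df_factor,
    df_resid).  ``factors`` columns are treated as categorical.
    """
    df = factors.copy()
    for c in df.columns:
        df[c] = df[c].astype(str)
        if df[c].nunique() < 2:
            raise ValueError(f"factor {c!r} has fewer than 2 observed levels")
    df["richness"] = pd.Series(richness).loc[df.index].to_numpy()
    terms = list(factors.columns)
    rhs = " + ".join(f"C({t})" for t in terms)
    full = smf.glm(f"richness ~ {rhs}", data=df,
                   family=sm.families.Poisson()).fit()
    dispersion = float(full.pearson_chi2 / full.df_resid)
    if not np.isfinite(dispersion) or dispersion < 0:
        raise ValueError("degenerate dispersion estimate")
    rows = []
    for t in terms:
        others = [x for x in terms if x != t]
        rhs_red = " + ".join(f"C({x})" for x in others) if others else "1"
        red = smf.glm(f"richness ~ {rhs_red}", data=df,
                      family=sm.families.Poisson()).fit()
        ddev = float(red.deviance - full.deviance)
        ddf = int(red.df_resid - full.df_resid)
        if ddev < 1e-10:
            # factor explains nothing (incl. the perfect-fit degenerate case)
            scaled, F, p = 0.0, 0.0, 1.0
        else:
            scaled = ddev / dispersion
            F = scaled / ddf
            p = float(sps.f.sf(F, ddf, full.df_resid))
        rows.append((t, ddf, scaled, F, p))
    tests = pd.DataFrame(rows, columns=["factor", "df", "scaled_dev", "F",
                                        "p"]).set_index("factor")
    return RichnessGlmResult(params=full.params, dispersion=dispersion,
                             tests=tests, model=full)


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------

def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment: monotone, never below the raw p."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


def _indval_stats(mat: np.ndarray, group_idx: np.ndarray, n_groups: int,
                  equalize: bool) -> np.ndarray:
    """Per-species, per-group IndVal components; returns stat (S, G)."""
    sizes = np.bincount(group_idx, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, mat.shape[1]))
    np.add.at(sums, group_idx, mat)
    mean_inc = sums / sizes[:, None]            # fidelity numerator per group
    if equalize:
        denom = mean_inc.sum(axis=0)
    else:
        denom = mat.mean(axis=0) * n_groups     # plain IndVal weighting
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, mean_inc / denom, 0.0)
    B = mean_inc                                 # incidence data: B = freq
    return np.sqrt(A * B).T                      # (S, G)


@dataclass
class IndValResult:
    table: pd.DataFrame          # per species: category, A, B, stat, p range
    per_run_p: pd.DataFrame      # species x run raw p-values
    categories: tuple


def indval(incidence: pd.DataFrame, categories: pd.Series, n_perm: int = 999,
           seed: int = 0, n_runs: int = 10, equalize: bool = True) -> IndValResult:
    """Indicator value analysis with permutation tests and Holm correction.

    A (specificity) is the group-size-equalized concentration of a
    species' occurrence in its best category; B (fidelity) the fraction of
    that category's plots it occupies; the statistic is sqrt(A * B).
    p = (1 + #{permutations with stat >= observed}) / (1 + n_perm),
    permuting plot-category labels; Holm correction is applied across
    species within each run, and ``n_runs`` independently seeded runs are
    summarized as a p-value range.  Species absent everywhere are excluded
    (flagged in the table's ``excluded`` companion attribute).
    """
    cats = categories.loc[incidence.index]
    names = sorted(cats.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 categories")
    for c in names:
        if (cats == c).sum() < 2:
            raise ValueError(f"category {c!r} has fewer than 2 plots")
    mat = (incidence.to_numpy() > 0).astype(float)
    present = mat.sum(axis=0) > 0
    species = incidence.columns[present]
    mat = mat[:, present]
    gidx = pd.Categorical(cats, categories=names).codes.astype(int)
    obs = _indval_stats(mat, gidx, len(names), equalize)
    best = obs.argmax(axis=1)
    obs_stat = obs.max(axis=1)

    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=n_runs)
    per_run = np.empty((len(species), n_runs))
    for r, s in enumerate(run_seeds):
        rng = np.random.default_rng(s)
        exceed = np.zeros(len(species))
        for _ in range(n_perm):
            perm = rng.permutation(gidx)
            stat = _indval_stats(mat, perm, len(names), equalize).max(axis=1)
            exceed += stat >= obs_stat - 1e-12
        per_run[:, r] = (1.0 + exceed) / (1.0 + n_perm)
    adj = np.column_stack([holm_adjust(per_run[:, r]) for r in range(n_runs)])
    sizes = np.bincount(gidx, minlength=len(names)).astype(float)
    sums = np.zeros((len(names), mat.shape[1]))
    np.add.at(sums, gidx, mat)
    B_all = (sums / sizes[:, None]).T
    table = pd.DataFrame({
        "category": [names[b] for b in best],
        "stat": obs_stat,
        "A": (obs_stat ** 2) / np.maximum(B_all[np.arange(len(best)), best], 1e-300),
        "B": B_all[np.arange(len(best)), best],
        "p_min": per_run.min(axis=1), "p_max": per_run.max(axis=1),
        "p_holm_min": adj.min(axis=1), "p_holm_max": adj.max(axis=1),
    }, index=pd.Index(species, name="motu_id"))
    per_run_df = pd.DataFrame(per_run, index=table.index,
                              columns=[f"run{r + 1}" for r in range(n_runs)])
    return IndValResult(table=table, per_run_p=per_run_df,
                        categories=tuple(names))


# ---------------------------------------------------------------------------
# rarity scores
# ---------------------------------------------------------------------------

def rarity_bootstrap(incidence: pd.DataFrame, categories: pd.Series,
                     n_boot: int = 100, seed: int = 0, rescale: bool = True,
                     stratified: bool = False) -> pd.DataFrame:
    """Bootstrapped per-category occurrence scores (rarity heatmap input).

    Plots are resampled with replacement ``n_boot`` times (whole plot set
    by default, per category when ``stratified``); each MOTU's score in a
    category is its occurrence frequency among the drawn plots of that
    category, expressed as a percentage.  With ``rescale`` (the
    three-level dieback mode) each category is scaled to one third of the
    dataset, so a MOTU in every plot of a category scores 100/3 there and
    100 in total when present everywhere; without rescaling (district
    mode) a ubiquitous MOTU scores 100 in its district.
    """
    cats = categories.loc[incidence.index]
    names = sorted(cats.unique())
    if rescale and len(names) != 3:
        raise ValueError("rescaled mode expects exactly 3 categories")
    for c in names:
        if (cats == c).sum() == 0:
            raise ValueError(f"empty category {c!r}")
    rng = np.random.default_rng(seed)
    mat = (incidence.to_numpy() > 0).astype(np.int64)
    n = mat.shape[0]
    gidx = pd.Categorical(cats, categories=names).codes.astype(int)
    hit = np.zeros((len(names), mat.shape[1]), dtype=np.int64)
    drawn = np.zeros(len(names), dtype=np.int64)
    for _ in range(n_boot):
        if stratified:
            idx = np.concatenate([
                rng.choice(np.flatnonzero(gidx == g),
                           size=(gidx == g).sum(), replace=True)
                for g in range(len(names))])
        else:
            idx = rng.integers(0, n, size=n)
        g = gidx[idx]
        np.add.at(hit, g, mat[idx])
        drawn += np.bincount(g, minlength=len(names))
    freq = hit / np.maximum(drawn, 1)[:, None]
    scale = (100.0 / len(names)) if rescale else 100.0
    out = pd.DataFrame((freq * scale).T, index=incidence.columns,
                       columns=names)
    out.index.name = "motu_id"
    return out
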