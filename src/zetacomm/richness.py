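"""Incidence-based richness estimation and turnover partitions.

Implements the incidence-frequency machinery used for Malaise-trap
metabarcoding inventories: Chao2 and first-order jackknife asymptotic
estimators, hypergeometric rarefaction with Chao-style extrapolation at
Hill order q = 0, sample-coverage estimation, the four-month Venn
partition of temporal turnover, and the two-district shared/unique split.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class IncidenceFrequencyCounts:
    """Incidence frequencies: Q[k] species found in exactly k of R units."""

    S_obs: int
    R: int
    Q: np.ndarray  # length R, Q[k-1] = number of species in exactly k units

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=int)
        if len(self.Q) != self.R:
            raise ValueError("Q must have one entry per sampling unit count")
        if self.Q.sum() != self.S_obs:
            raise ValueError("sum of Q_k must equal S_obs")

    @property
    def Q1(self) -> int:
        return int(self.Q[0])

    @property
    def Q2(self) -> int:
        return int(self.Q[1]) if self.R >= 2 else 0

    @property
    def U(self) -> int:
        """Total incidences, sum_k k * Q_k."""
        return int((np.arange(1, self.R + 1) * self.Q).sum())


def incidence_frequencies(incidence: pd.DataFrame) -> IncidenceFrequencyCounts:
    """Tally incidence frequencies from a unit x species 0/1 matrix."""
    if incidence.size == 0:
        raise ValueError("empty incidence matrix")
    mat = incidence.to_numpy()
    R = mat.shape[0]
    occ = mat.sum(axis=0)
    occ = occ[occ > 0]
    Q = np.bincount(occ, minlength=R + 1)[1:R + 1]
    return IncidenceFrequencyCounts(S_obs=int(len(occ)), R=R, Q=Q)


def chao2(counts: IncidenceFrequencyCounts) -> float:
    """Chao2 asymptotic richness (bias-corrected form when Q2 = 0)."""
    if counts.R < 2:
        raise ValueError("Chao2 needs at least 2 sampling units")
    R, Q1, Q2 = counts.R, counts.Q1, counts.Q2
    k = (R - 1) / R
    if Q2 > 0:
        return counts.S_obs + k * Q1 * Q1 / (2.0 * Q2)
    return counts.S_obs + k * Q1 * (Q1 - 1) / 2.0


def jackknife1(counts: IncidenceFrequencyCounts) -> float:
    """First-order jackknife richness, S_obs + Q1 * (R-1)/R."""
    if counts.R < 2:
        raise ValueError("jackknife needs at least 2 sampling units")
    return counts.S_obs + counts.Q1 * (counts.R - 1) / counts.R


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def _interpolated_S(occ: np.ndarray, R: int, t: int) -> float:
    # E[S(t)] = S_obs - sum_s C(R - Y_s, t) / C(R, t)
    log_ratio = _log_comb(R - occ, t) - _log_comb(R, t)
    return float(len(occ) - np.exp(log_ratio).sum())


def coverage_estimate(counts: IncidenceFrequencyCounts) -> float:
    """Estimated sample coverage of the full set of R units."""
    R, Q1, Q2, U = counts.R, counts.Q1, counts.Q2, counts.U
    if U == 0:
        raise ValueError("no incidences")
    denom = (R - 1) * Q1 + 2.0 * Q2
    a = (R - 1) * Q1 / denom if denom > 0 else 0.0
    return 1.0 - (Q1 / U) * a


@dataclass
class RarefactionCurve:
    table: pd.DataFrame  # columns t, S, coverage, extrapolated
    counts: IncidenceFrequencyCounts

    @property
    def S_asymptote(self) -> float:
        return chao2(self.counts)


def rarefy_extrapolate(counts: IncidenceFrequencyCounts, t_max: int,
                       occupancies: np.ndarray | None = None) -> RarefactionCurve:
    """Expected richness and coverage for 1..t_max sampling units.

    Interpolation (t <= R) uses the exact hypergeometric expectation over
    t-unit subsets; extrapolation (t > R) follows the Chao2-based form
    S_obs + Q0_hat * (1 - (1 - Q1/(Q1 + R*Q0_hat))^(t-R)).  Coverage for
    t < R uses the analogous hypergeometric estimator, the coverage
    estimate at t = R, and its geometric extension beyond R.

    ``occupancies`` (per-species unit counts) is reconstructed from Q when
    not given.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    R, Q1, Q2, U = counts.R, counts.Q1, counts.Q2, counts.U
    if occupancies is None:
        occupancies = np.repeat(np.arange(1, R + 1), counts.Q)
    occ = np.asarray(occupancies)
    q0 = max(chao2(counts) - counts.S_obs, 0.0)
    denom = (R - 1) * Q1 + 2.0 * Q2
    a = (R - 1) * Q1 / denom if denom > 0 else 0.0
    rows = []
    for t in range(1, t_max + 1):
        if t <= R:
            S = _interpolated_S(occ, R, t)
            if t < R:
                # coverage analogue of the interpolation formula
                log_ratio = _log_comb(R - occ, t) - _log_comb(R - 1, t)
                cov = 1.0 - float((occ / U * np.exp(log_ratio)).sum())
            else:
                cov = 1.0 - (Q1 / U) * a if U > 0 else 1.0
            extrap = False
        else:
            if q0 > 0:
                S = counts.S_obs + q0 * (
                    1.0 - (1.0 - Q1 / (Q1 + R * q0)) ** (t - R))
            else:
                S = float(counts.S_obs)
            cov = 1.0 - (Q1 / U) * a ** (t - R + 1) if U > 0 else 1.0
            extrap = True
        rows.append((t, S, cov, extrap))
    table = pd.DataFrame(rows, columns=["t", "S", "coverage", "extrapolated"])
    return RarefactionCurve(table=table, counts=counts)


def rarefaction_band(incidence: pd.DataFrame, t_max: int, n_boot: int = 200,
                     seed: int = 0, level: float = 0.95) -> pd.DataFrame:
    """Approximate confidence band by bootstrapping sampling units.

    Units are resampled with replacement ``n_boot`` times; the band is the
    symmetric normal interval from the bootstrap standard deviation of
    S(t).  Returns the point curve with lower/upper columns.
    """
    rng = np.random.default_rng(seed)
    base = rarefy_extrapolate(incidence_frequencies(incidence), t_max,
                              occupancies=_occ(incidence))
    boots = np.empty((n_boot, t_max))
    R = incidence.shape[0]
    for b in range(n_boot):
        idx = rng.integers(0, R, size=R)
        sub = incidence.iloc[idx]
        try:
            c = incidence_frequencies(sub)
        except ValueError:
            boots[b] = np.nan
            continue
        boots[b] = rarefy_extrapolate(c, t_max, occupancies=_occ(sub)).table["S"].to_numpy()
    from scipy.stats import norm
    zcrit = norm.ppf(0.5 + level / 2.0)
    sd = np.nanstd(boots, axis=0)
    out = base.table.copy()
    out["lower"] = out["S"] - zcrit * sd
    out["upper"] = out["S"] + zcrit * sd
    return out


def _occ(incidence: pd.DataFrame) -> np.ndarray:
    occ = incidence.to_numpy().sum(axis=0)
    return occ[occ > 0]


def exhaustive_rarefaction(incidence: pd.DataFrame, t: int) -> float:
    """Brute-force E[S(t)]: average richness over all t-unit subsets.

    Exponential in the number of units; intended as an independent oracle
    on toy matrices.
    """
    mat = incidence.to_numpy()
    R = mat.shape[0]
    vals = [
        int((mat[list(sub)].sum(axis=0) > 0).sum())
        for sub in combinations(range(R), t)
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# turnover partitions
# ---------------------------------------------------------------------------

def temporal_turnover(month_incidence: pd.DataFrame) -> dict:
    """Venn partition of species over the monthly sampling windows.

    Returns subset counts (one entry per non-empty month subset, keyed by
    the tuple of month labels), the number and rounded percentage of core
    species present in every month, and the total species count.
    """
    months = list(month_incidence.index)
    mat = month_incidence.to_numpy() > 0
    present = mat.any(axis=0)
    mat = mat[:, present]
    total = int(mat.shape[1])
    patterns: dict[tuple, int] = {}
    for r in range(1, len(months) + 1):
        for sub in combinations(range(len(months)), r):
            mask = np.zeros(len(months), dtype=bool)
            mask[list(sub)] = True
            count = int((mat == mask[:, None]).all(axis=0).sum())
            patterns[tuple(months[i] for i in sub)] = count
    core = patterns.get(tuple(months), 0)
    core_pct = _round_half_up(100.0 * core / total) if total else 0.0
    return {"subset_counts": patterns, "core_count": core,
            "core_percent": core_pct, "total": total}


def district_partition(plot_incidence: pd.DataFrame,
                       metadata: pd.DataFrame) -> dict:
    """Shared and district-unique species percentages for 2 districts."""
    dist = metadata.set_index("plot_id")["district"]
    labels = dist.loc[plot_incidence.index]
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError("district partition requires exactly 2 districts")
    a = plot_incidence[labels == names[0]].to_numpy().any(axis=0)
    b = plot_incidence[labels == names[1]].to_numpy().any(axis=0)
    total = int((a | b).sum())
    if total == 0:
        raise ValueError("no species present")
    shared = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((b & ~a).sum())
    return {
        "districts": tuple(names),
        "shared_percent": _round_half_up(100.0 * shared / total),
        "unique_percent": (
            _round_half_up(100.0 * only_a / total),
            _round_half_up(100.0 * only_b / total)),
        "counts": {"shared": shared, names[0]: only_a, names[1]: only_b,
                   "total": total},
    }
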