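"""Synthetic Malaise-trap metabarcoding datasets with planted structure.

The generator emulates the shape of a two-district, 56-plot, four-month
Malaise-trap survey: triplicate PCR read counts per MOTU and sample,
negative/extraction controls, a long-tailed occupancy distribution (many
rare species, few ubiquitous ones), district-specific species pools, plot
covariates correlated with a drought-dieback gradient, and optional niche
structuring of species presence along a designated covariate.  Every draw
is driven by a single integer seed, and the planted structure (true
occupancies, niche optima, indicator identities) is returned alongside the
tables so downstream statistics can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

OCCUPANCY_MODELS = ("log-series", "geometric", "uniform")
MONTHS = ("May", "June", "July", "August")

ENV_COVARIATES = (
    "altitude", "canopy_openness", "deadwood_volume", "basal_area",
    "tree_diversity", "very_large_tree_density", "trem_diversity",
    "trem_density",
)

# order -> (weight among MOTUs, families); Diptera + Hymenoptera dominate,
# as is typical of Malaise-trap catches.
_TAXA: dict[str, tuple[float, tuple[str, ...]]] = {
    "Diptera": (0.45, ("Cecidomyiidae", "Syrphidae", "Tachinidae",
                       "Tipulidae", "Muscidae", "Phoridae")),
    "Hymenoptera": (0.28, ("Ichneumonidae", "Braconidae", "Apidae",
                           "Tenthredinidae", "Diapriidae")),
    "Lepidoptera": (0.10, ("Noctuidae", "Geometridae", "Tortricidae")),
    "Coleoptera": (0.08, ("Staphylinidae", "Curculionidae", "Elateridae")),
    "Hemiptera": (0.05, ("Miridae", "Aphididae", "Cicadellidae")),
    "Neuroptera": (0.02, ("Chrysopidae",)),
    "Trichoptera": (0.01, ("Limnephilidae",)),
    "Psocodea": (0.01, ("Psocidae",)),
}

#: family -> (floricolous, parasitoid) functional flags.
DEFAULT_FUNCTION_LOOKUP = pd.DataFrame(
    [("Cecidomyiidae", False, False), ("Syrphidae", True, False),
     ("Tachinidae", True, True), ("Tipulidae", False, False),
     ("Muscidae", True, False), ("Phoridae", False, True),
     ("Ichneumonidae", False, True), ("Braconidae", False, True),
     ("Apidae", True, False), ("Tenthredinidae", True, False),
     ("Diapriidae", False, True), ("Noctuidae", True, False),
     ("Geometridae", True, False), ("Tortricidae", False, False),
     ("Staphylinidae", False, False), ("Curculionidae", False, False),
     ("Elateridae", True, False), ("Miridae", False, False),
     ("Aphididae", False, False), ("Cicadellidae", False, False),
     ("Chrysopidae", True, False), ("Limnephilidae", False, False),
     ("Psocidae", False, False)],
    columns=["family", "floricolous", "parasitoid"],
)


@dataclass
class SimulationConfig:
    """Study-design knobs for :func:`generate_dataset`.

    Defaults mirror the sampled design: 56 one-ha plots split evenly over
    2 districts, 4 monthly samples per plot with 2 samples lost (222 field
    samples in total), triplicate PCRs, and a dieback class mix of
    18 low / 15 medium / 23 high.  ``n_species`` is a desk-scale community
    (the field study recovered ~3000 MOTUs).  ``niche_strength`` > 0 makes
    presence probability a Gaussian function of ``niche_covariate``;
    0 gives spatially unstructured occupancy.
    """

    n_plots: int = 56
    n_districts: int = 2
    n_months: int = 4
    n_species: int = 300
    occupancy_model: str = "log-series"
    district_overlap: float = 0.45
    niche_strength: float = 0.0
    niche_covariate: str = "canopy_openness"
    mean_reads: float = 60.0
    dropout_rate: float = 0.10
    contamination_rate: float = 0.0
    n_lost_samples: int = 2
    n_controls: int = 4
    dieback_mix: tuple[int, int, int] = (18, 15, 23)  # low/medium/high, scaled
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.occupancy_model not in OCCUPANCY_MODELS:
            raise ValueError(
                f"occupancy_model must be one of {OCCUPANCY_MODELS}")
        for name in ("district_overlap", "dropout_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.niche_strength < 0:
            raise ValueError("niche_strength must be non-negative")
        if self.mean_reads <= 0:
            raise ValueError("mean_reads must be positive")
        if self.n_plots % self.n_districts:
            raise ValueError("n_plots must divide evenly over districts")


@dataclass
class SyntheticDataset:
    """Generated tables plus the planted truth."""

    reads: "object"               # pipeline.ReadCountTable
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    traits: pd.DataFrame
    function_lookup: pd.DataFrame
    truth: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _occupancy_fractions(cfg: SimulationConfig, n_avail: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-species expected occupancy fraction of its available plots."""
    n = cfg.n_species
    if cfg.occupancy_model == "log-series":
        occ = sps.logser.rvs(0.95, size=n, random_state=rng)
        return np.minimum(occ, n_avail) / n_avail
    if cfg.occupancy_model == "geometric":
        ranks = np.arange(n)
        f = 0.8 * 0.97 ** ranks
        return np.maximum(f, 1.0 / n_avail)
    return np.full(n, 0.3)  # uniform


def _metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_plots
    per = n // cfg.n_districts
    plot_ids = [f"P{i + 1:02d}" for i in range(n)]
    districts = [f"D{d + 1}" for d in range(cfg.n_districts) for _ in range(per)]
    # district centres ~100 km apart on a planar grid (km units)
    centres = np.stack([np.array([100.0 * d, 40.0 * (d % 2)])
                        for d in range(cfg.n_districts)])
    xy = np.concatenate([
        centres[d] + rng.normal(0.0, 4.0, size=(per, 2))
        for d in range(cfg.n_districts)
    ])
    # dieback classes in the surveyed 18/15/23 mix, scaled to n_plots
    mix = np.array(cfg.dieback_mix, dtype=float)
    counts = np.floor(mix / mix.sum() * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(mix / mix.sum() * n - counts))] += 1
    levels = np.repeat(["low", "medium", "high"], counts)
    rng.shuffle(levels)
    dying = np.zeros(n, dtype=int)
    affected = np.zeros(n, dtype=int)
    healthy = np.zeros(n, dtype=int)
    for i, lv in enumerate(levels):
        if lv == "high":
            dying[i] = rng.integers(1, 4)
            affected[i] = rng.integers(13, 21)
        elif lv == "medium":
            affected[i] = rng.integers(13, 21)
        else:
            affected[i] = rng.integers(0, 12)
        healthy[i] = 20 - affected[i]
    stand = np.where(
        levels == "low", "healthy",
        np.where(rng.random(n) < 0.4, "salvaged", "disturbed"))
    # covariates loaded on the dieback gradient with independent noise so
    # every pairwise correlation stays well below the 0.7 collinearity bar
    s = (levels == "medium").astype(float) + 2.0 * (levels == "high")
    s = (s - s.mean()) / (s.std() or 1.0)
    e = rng.normal(size=(n, 8))
    meta = pd.DataFrame({
        "plot_id": plot_ids,
        "district": districts,
        "x": xy[:, 0], "y": xy[:, 1],
        "altitude": np.round(
            1100.0 + 250.0 * (pd.factorize(pd.Index(districts))[0] % 2)
            + 120.0 * e[:, 0]),
        "dieback_level": levels,
        "stand_type": stand,
        "dying_trees": dying,
        "affected_trees": affected,
        "healthy_or_resilient_trees": healthy,
        "canopy_openness": 1.0 / (1.0 + np.exp(-(-1.1 + 0.8 * s + 0.9 * e[:, 1]))),
        "deadwood_volume": np.exp(2.4 + 0.35 * s + 0.5 * e[:, 2]),
        "basal_area": np.clip(34.0 - 3.0 * s + 5.0 * e[:, 3], 5.0, None),
        "tree_diversity": np.clip(np.round(4.0 + 0.5 * s + 1.5 * e[:, 4]), 1, None),
        "very_large_tree_density": np.exp(1.4 - 0.25 * s + 0.5 * e[:, 5]),
        "trem_diversity": np.clip(np.round(9.0 + 1.6 * s + 2.5 * e[:, 6]), 0, 47),
        "trem_density": np.exp(2.8 + 0.3 * s + 0.4 * e[:, 7]),
    })
    return meta


def _taxonomy(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    orders = list(_TAXA)
    w = np.array([_TAXA[o][0] for o in orders])
    w = w / w.sum()
    rows = []
    for i in range(cfg.n_species):
        mid = f"MOTU_{i + 1:04d}"
        order = orders[rng.choice(len(orders), p=w)]
        fams = _TAXA[order][1]
        family = fams[rng.integers(len(fams))]
        # mixture so ~60% of MOTUs clear the 97% species threshold
        if rng.random() < 0.6:
            sim = rng.uniform(0.97, 1.0)
        else:
            sim = rng.uniform(0.90, 0.97)
        genus = f"{family[:-4]}us{rng.integers(1, 40)}"
        species = ""
        if sim >= 0.97 and rng.random() < 0.874:
            species = f"{genus} sp{rng.integers(1, 200)}"
        elif rng.random() < 0.4:
            genus = ""  # genus unresolved for part of the unnamed tail
        rows.append((mid, order, family, genus, species, round(sim, 4)))
    return pd.DataFrame(
        rows, columns=["motu_id", "order", "family", "genus", "species",
                       "similarity"])


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset (reads, metadata, taxonomy, traits).

    Species are split into district pools sharing ``district_overlap`` of
    the community; per-plot presence follows the occupancy model, optionally
    bent toward each species' optimum on the niche covariate; monthly
    activity windows are contiguous; read counts per present MOTU and PCR
    replicate follow a gamma-mixed Poisson with independent per-replicate
    dropout.  ``n_lost_samples`` field samples are removed to mirror sample
    loss, and ``n_controls`` control samples are appended (empty unless
    ``contamination_rate`` > 0).
    """
    from .pipeline import ReadCountTable  # local import avoids a cycle

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    meta = _metadata(cfg, rng)
    tax = _taxonomy(cfg, rng)
    n, S = cfg.n_plots, cfg.n_species

    # district pools
    dists = meta["district"].unique()
    n_shared = int(round(cfg.district_overlap * S))
    pool = np.empty(S, dtype=object)
    pool[:n_shared] = "shared"
    rest = np.arange(n_shared, S)
    for j, sp in enumerate(rest):
        pool[sp] = dists[j % len(dists)]
    rng.shuffle(pool)

    avail = np.zeros((n, S), dtype=bool)
    for d in dists:
        in_d = (meta["district"] == d).to_numpy()
        avail[np.ix_(in_d, (pool == "shared") | (pool == d))] = True
    n_avail = avail.sum(axis=0)

    f = _occupancy_fractions(cfg, max(int(n_avail.max()), 1), rng)

    # presence probability per plot, optionally niche-structured
    z = meta[cfg.niche_covariate].to_numpy(dtype=float)
    z = (z - z.mean()) / (z.std() or 1.0)
    optima = rng.uniform(z.min(), z.max(), size=S)
    if cfg.niche_strength > 0:
        w = np.exp(-cfg.niche_strength * (z[:, None] - optima[None, :]) ** 2)
    else:
        w = np.ones((n, S))
    w = w * avail
    colsum = w.sum(axis=0)
    colsum[colsum == 0] = 1.0
    p = np.minimum(f[None, :] * n_avail[None, :] * w / colsum, 1.0)
    presence_plot = rng.random((n, S)) < p
    # guarantee each species exists somewhere in its pool
    empty = ~presence_plot.any(axis=0)
    for sp in np.where(empty)[0]:
        cand = np.where(w[:, sp] > 0)[0]
        if len(cand):
            presence_plot[rng.choice(cand), sp] = True

    # contiguous monthly activity windows (phenology)
    m = cfg.n_months
    win_len = rng.choice(np.arange(1, m + 1), size=S,
                         p=_window_probs(m))
    win_start = rng.integers(0, m - win_len + 1)
    active = np.zeros((m, S), dtype=bool)
    for sp in range(S):
        active[win_start[sp]:win_start[sp] + win_len[sp], sp] = True

    months = list(MONTHS[:m]) if m <= len(MONTHS) else [f"M{i+1}" for i in range(m)]
    samples = [(pid, mo) for pid in meta["plot_id"] for mo in months]
    if cfg.n_lost_samples:
        lost = rng.choice(len(samples), size=cfg.n_lost_samples, replace=False)
        samples = [s for k, s in enumerate(samples) if k not in set(lost)]

    roster_rows = [
        {"sample_id": f"{pid}_{mo}", "plot_id": pid, "month": mo,
         "is_control": False, "control_type": ""}
        for pid, mo in samples
    ]
    for k in range(cfg.n_controls):
        ctype = "NC" if k % 2 == 0 else "EC"
        roster_rows.append({"sample_id": f"{ctype}{k // 2 + 1}", "plot_id": "",
                            "month": "", "is_control": True,
                            "control_type": ctype})
    roster = pd.DataFrame(roster_rows)

    plot_index = {pid: i for i, pid in enumerate(meta["plot_id"])}
    month_index = {mo: i for i, mo in enumerate(months)}
    shape = 1.5  # gamma shape of the per-replicate read factor
    recs: list[tuple[str, str, int, int]] = []
    for pid, mo in samples:
        sp_here = np.where(presence_plot[plot_index[pid]]
                           & active[month_index[mo]])[0]
        if not len(sp_here):
            continue
        lam = rng.gamma(shape, cfg.mean_reads / shape, size=(len(sp_here), 3))
        reads = rng.poisson(lam)
        reads[rng.random(reads.shape) < cfg.dropout_rate] = 0
        sid = f"{pid}_{mo}"
        for j, sp in enumerate(sp_here):
            for rep in range(3):
                if reads[j, rep] > 0:
                    recs.append((tax["motu_id"].iat[sp], sid, rep + 1,
                                 int(reads[j, rep])))
    contaminants: list[str] = []
    for row in roster_rows:
        if not row["is_control"]:
            continue
        hits = np.where(rng.random(S) < cfg.contamination_rate)[0]
        for sp in hits:
            contaminants.append(tax["motu_id"].iat[sp])
            rep = int(rng.integers(1, 4))
            recs.append((tax["motu_id"].iat[sp], row["sample_id"], rep,
                         int(rng.poisson(4) + 1)))
    counts = pd.DataFrame(recs, columns=["motu_id", "sample_id", "replicate",
                                         "reads"])

    from .pipeline import assign_functions
    traits = assign_functions(tax, DEFAULT_FUNCTION_LOOKUP)

    truth = {
        "occupancy": pd.Series(presence_plot.sum(axis=0),
                               index=tax["motu_id"], name="occupancy"),
        "presence_plot": pd.DataFrame(presence_plot.astype(int),
                                      index=meta["plot_id"],
                                      columns=tax["motu_id"]),
        "district_pool": pd.Series(pool, index=tax["motu_id"], name="pool"),
        "niche_covariate": cfg.niche_covariate if cfg.niche_strength > 0 else None,
        "niche_optima": pd.Series(optima, index=tax["motu_id"], name="optimum"),
        "active_months": pd.DataFrame(active.T.astype(int),
                                      index=tax["motu_id"], columns=months),
        "contaminants": sorted(set(contaminants)),
    }
    return SyntheticDataset(
        reads=ReadCountTable(counts=counts, roster=roster),
        metadata=meta, taxonomy=tax, traits=traits,
        function_lookup=DEFAULT_FUNCTION_LOOKUP.copy(), truth=truth,
        config=cfg)


def _window_probs(n_months: int) -> np.ndarray:
    # many single-month species, few season-long ones (strong phenology)
    base = np.array([0.35, 0.30, 0.23, 0.12][:n_months], dtype=float)
    return base / base.sum()


# ---------------------------------------------------------------------------
# incidence-only fixtures
# ---------------------------------------------------------------------------

def generate_niche_incidence(n_plots: int, n_species: int,
                             niche_breadth: float, seed: int) -> pd.DataFrame:
    """Plot x species incidence from Gaussian niches on a 1-D gradient.

    Plots sit evenly on [0, 1]; species s has a uniform random optimum
    mu_s, a maximum presence probability h_s ~ U(0, 1), and a Gaussian
    response of width w_s, where the widths are lognormally dispersed
    around ``niche_breadth`` (their median) so the community mixes narrow
    specialists with broad generalists.  The resulting occupancy
    distribution is long-tailed — many species in a handful of plots, a
    few spanning the gradient — which is the species-pool structure under
    which shared-species decline follows a power law rather than the
    exponential decay of spatially unstructured communities.
    """
    if n_plots < 4:
        raise ValueError("need at least 4 plots")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_plots)
    mu = rng.uniform(0.0, 1.0, size=n_species)
    h = rng.uniform(0.0, 1.0, size=n_species)
    w = niche_breadth * np.exp(2.0 * rng.normal(size=n_species))
    p = h[None, :] * np.exp(-(x[:, None] - mu[None, :]) ** 2
                            / (2.0 * w[None, :] ** 2))
    mat = (rng.random((n_plots, n_species)) < p).astype(int)
    return pd.DataFrame(
        mat, index=[f"P{i + 1:02d}" for i in range(n_plots)],
        columns=[f"sp{j + 1:03d}" for j in range(n_species)])


def generate_random_incidence(n_plots: int, n_species: int, p: float,
                              seed: int) -> pd.DataFrame:
    """i.i.d. Bernoulli(p) incidence — the stochastic-turnover null."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mat = (rng.random((n_plots, n_species)) < p).astype(int)
    return pd.DataFrame(
        mat, index=[f"P{i + 1:02d}" for i in range(n_plots)],
        columns=[f"sp{j + 1:03d}" for j in range(n_species)])


def plant_indicators(incidence: pd.DataFrame, categories: pd.Series,
                     k_indicators: int, fidelity: float, seed: int):
    """Rewrite k species per category into clean indicator species.

    Each planted species is made to occur in ``round(fidelity * n_cat)`` of
    its category's plots (at least 1) and nowhere else; all other species
    are untouched.  Returns (new incidence, DataFrame of planted species
    with their categories).
    """
    rng = np.random.default_rng(seed)
    categories = categories.loc[incidence.index]
    cats = categories.unique()
    for c in cats:
        if (categories == c).sum() < 2:
            raise ValueError(f"category {c!r} has fewer than 2 plots")
    if k_indicators * len(cats) > incidence.shape[1]:
        raise ValueError("k_indicators exceeds available species")
    out = incidence.copy()
    chosen = rng.choice(incidence.shape[1], size=k_indicators * len(cats),
                        replace=False)
    planted = []
    for ci, cat in enumerate(cats):
        plots = incidence.index[categories == cat]
        n_occ = max(1, int(round(fidelity * len(plots))))
        for j in chosen[ci * k_indicators:(ci + 1) * k_indicators]:
            col = incidence.columns[j]
            out[col] = 0
            occ = rng.choice(len(plots), size=n_occ, replace=False)
            out.loc[plots[occ], col] = 1
            planted.append((col, cat, n_occ))
    return out, pd.DataFrame(planted, columns=["motu_id", "category",
                                               "n_occupied"])
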