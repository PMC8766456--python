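"""From raw MOTU x replicate read tables to clean plot-level incidence.

Metabarcoding of bulk insect samples yields a table of read counts per
molecular OTU (MOTU), per field sample, per PCR replicate, together with
negative and extraction controls.  The functions here apply the
replicate-consistency retention rule (by default a MOTU must reach at least
3 reads in each of the 3 PCR replicates of a sample), remove MOTUs detected
in any control, resolve ambiguous taxonomy to a consensus path, merge MOTUs
that share a species name, and collapse sample-level presences to plots,
months or districts.  Field-survey helpers derive the plot covariates used
downstream (dieback class, canopy openness, stand structure metrics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("order", "family", "genus", "species")

#: BOLD-style similarity threshold below which a species-rank name is not kept.
SPECIES_SIMILARITY_THRESHOLD = 0.97


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReadCountTable:
    """Long-format read counts plus a sample roster.

    ``counts`` columns: motu_id, sample_id, replicate (1..3), reads.
    ``roster`` columns: sample_id, plot_id, month, is_control, control_type
    (control rows carry empty plot/month).
    """

    counts: pd.DataFrame
    roster: pd.DataFrame

    def __post_init__(self) -> None:
        bad = ~self.counts["replicate"].isin((1, 2, 3))
        if bad.any():
            raise ValueError("replicate index outside {1,2,3}")
        if (self.counts["reads"] < 0).any():
            raise ValueError("negative read counts")

    @property
    def field_samples(self) -> pd.Index:
        r = self.roster
        return pd.Index(r.loc[~r["is_control"], "sample_id"])

    @property
    def control_samples(self) -> pd.Index:
        r = self.roster
        return pd.Index(r.loc[r["is_control"], "sample_id"])


@dataclass
class FilterConfig:
    """Replicate-consistency retention rule.

    The defaults encode the restrictive rule used for Malaise-trap
    metabarcoding: a MOTU is retained in a sample only when it reaches
    ``min_reads`` reads in at least ``min_replicates`` of the 3 PCR
    replicates (3 reads in all 3 replicates by default).
    """

    min_reads: int = 3
    min_replicates: int = 3
    drop_control_motus: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_replicates <= 3:
            raise ValueError("min_replicates must be in 1..3")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass
class TaxonomyRecord:
    motu_id: str
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    similarity: float = float("nan")

    def path(self) -> tuple[str, str, str, str]:
        return (self.order, self.family, self.genus, self.species)


@dataclass
class PlotSurvey:
    """Raw field-survey records for one plot.

    trees: DataFrame(status in {living,snag,log}, species, dbh_cm)
    deadwood: DataFrame(length_m, diameter_m) for lying items
    trems: DataFrame(trem_type, tree_id) microhabitat observations
    densiometer: five counts of intersected points (each 0..68)
    dying / affected / healthy_or_resilient: counts among the 20 assessed firs
    """

    trees: pd.DataFrame
    deadwood: pd.DataFrame
    trems: pd.DataFrame
    densiometer: tuple[int, ...]
    dying: int = 0
    affected: int = 0
    healthy_or_resilient: int = 0


# ---------------------------------------------------------------------------
# read-table filtering
# ---------------------------------------------------------------------------

def replicate_filter(reads: ReadCountTable, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Sample x MOTU incidence from the PCR replicate-consistency rule.

    presence(sample, motu) = 1 iff at least ``cfg.min_replicates`` of the
    sample's replicates carry >= ``cfg.min_reads`` reads of the MOTU.
    Control samples are kept as rows so that downstream control subtraction
    can inspect them.
    """
    cfg = cfg or FilterConfig()
    c = reads.counts
    ok = c[c["reads"] >= cfg.min_reads]
    n_rep = (
        ok.groupby(["sample_id", "motu_id"])["replicate"].nunique().rename("n")
    )
    hits = n_rep[n_rep >= cfg.min_replicates].reset_index()
    samples = reads.roster["sample_id"].tolist()
    motus = sorted(c["motu_id"].unique())
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                       columns=pd.Index(motus, name="motu_id"), dtype=int)
    if len(hits):
        mat.values[
            mat.index.get_indexer(hits["sample_id"]),
            mat.columns.get_indexer(hits["motu_id"]),
        ] = 1
    return mat


def subtract_controls(presence: pd.DataFrame, reads: ReadCountTable) -> pd.DataFrame:
    """Drop every MOTU seen (>= 1 read) in any negative/extraction control.

    Removal is global — one read in one control discards the MOTU from the
    whole dataset — and control rows are dropped from the output.
    """
    controls = reads.control_samples
    c = reads.counts
    contaminated = set(
        c.loc[c["sample_id"].isin(controls) & (c["reads"] > 0), "motu_id"]
    )
    keep_cols = [m for m in presence.columns if m not in contaminated]
    keep_rows = [s for s in presence.index if s not in set(controls)]
    return presence.loc[keep_rows, keep_cols]


def renkonen_similarity(reads_a, reads_b) -> float:
    """Renkonen similarity of two replicate read-count vectors.

    Counts are renormalized to proportions; the index is
    sum_m min(p_a[m], p_b[m]) in [0, 1].  Vectors must be aligned (same
    MOTU order) or be pandas Series (aligned on index).
    """
    if isinstance(reads_a, pd.Series) or isinstance(reads_b, pd.Series):
        a = pd.Series(reads_a).astype(float)
        b = pd.Series(reads_b).astype(float)
        a, b = a.align(b, fill_value=0.0)
        a, b = a.to_numpy(), b.to_numpy()
    else:
        a = np.asarray(reads_a, dtype=float)
        b = np.asarray(reads_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("unaligned replicate vectors of different length")
    sa, sb = a.sum(), b.sum()
    if sa == 0 and sb == 0:
        raise ValueError("both replicates empty: Renkonen similarity undefined")
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.minimum(a / sa, b / sb).sum())


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def consensus_taxonomy(motu_id: str, candidates, similarity: float | None = None) -> TaxonomyRecord:
    """Consensus of several candidate rank paths for one MOTU.

    Walking order -> family -> genus -> species, a rank name is kept only
    when every candidate agrees on a single non-empty name; the path is
    truncated at the first disagreement (all lower ranks empty).  A species
    name is additionally dropped when the best-match similarity is below the
    97% threshold.

    ``candidates`` is an iterable of (order, family, genus, species) tuples
    (missing ranks empty strings).
    """
    cands = [tuple(c) + ("",) * (4 - len(c)) for c in candidates]
    if not cands:
        raise ValueError(f"no candidate paths for {motu_id}")
    kept = {}
    for i, rank in enumerate(RANKS):
        names = {c[i] for c in cands}
        if len(names) == 1 and "" not in names:
            kept[rank] = names.pop()
        else:
            break
    sim = float("nan") if similarity is None else float(similarity)
    if "species" in kept and not (sim >= SPECIES_SIMILARITY_THRESHOLD):
        del kept["species"]
    return TaxonomyRecord(motu_id=motu_id, similarity=sim, **kept)


def taxonomy_summary(taxonomy: pd.DataFrame, ndigits: int = 1) -> pd.Series:
    """Percentage of MOTUs carrying a name at each rank (half-up rounding)."""
    from decimal import Decimal, ROUND_HALF_UP
    total = len(taxonomy)
    if total == 0:
        raise ValueError("empty taxonomy table")
    out = {}
    for rank in RANKS:
        n = int((taxonomy[rank].fillna("") != "").sum())
        pct = 100.0 * n / total
        q = Decimal(1).scaleb(-ndigits)
        out[rank] = float(Decimal(repr(pct)).quantize(q, rounding=ROUND_HALF_UP))
    return pd.Series(out, name="percent_assigned")


def merge_synonymous_motus(presence: pd.DataFrame, taxonomy: pd.DataFrame):
    """Merge MOTUs that share an identical non-empty species name.

    The merged MOTU keeps the first member's id; its presence vector is the
    element-wise union of the members'.  Returns (presence, taxonomy) with
    merged columns/rows.  Idempotent.
    """
    tax = taxonomy.set_index("motu_id") if "motu_id" in taxonomy.columns else taxonomy
    named = tax.loc[tax["species"].fillna("") != "", "species"]
    drop: list[str] = []
    merged = presence.copy()
    for _, members in named.groupby(named):
        ids = [m for m in members.index if m in merged.columns]
        if len(ids) < 2:
            continue
        keep = ids[0]
        merged[keep] = merged[ids].max(axis=1)
        drop.extend(ids[1:])
    merged = merged.drop(columns=drop)
    out_tax = tax.drop(index=[d for d in drop if d in tax.index]).reset_index()
    return merged, out_tax


def assign_functions(taxonomy: pd.DataFrame, lookup: pd.DataFrame) -> pd.DataFrame:
    """Family-level functional annotation (floricolous / parasitoid flags).

    ``lookup`` has columns family, floricolous, parasitoid.  MOTUs whose
    family is empty or absent from the lookup get pandas NA flags (an
    explicit "unassigned" state) rather than False.
    """
    lk = lookup.set_index("family")
    rows = []
    for _, r in taxonomy.iterrows():
        fam = r.get("family", "") or ""
        if fam and fam in lk.index:
            flor = bool(lk.at[fam, "floricolous"])
            para = bool(lk.at[fam, "parasitoid"])
        else:
            flor = para = pd.NA
        rows.append((r["motu_id"], r.get("order", ""), fam, flor, para))
    out = pd.DataFrame(rows, columns=["motu_id", "order", "family",
                                      "floricolous", "parasitoid"])
    return out.astype({"floricolous": "boolean", "parasitoid": "boolean"})


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def collapse_to_units(presence: pd.DataFrame, roster: pd.DataFrame, unit: str,
                      metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Collapse a sample x MOTU matrix to plot, month or district units (OR).

    ``roster`` maps sample_id to plot_id and month; collapsing to district
    additionally needs ``metadata`` (plot_id -> district).
    """
    if unit not in {"plot", "month", "district"}:
        raise ValueError(f"unknown unit {unit!r}")
    r = roster.loc[~roster["is_control"]].set_index("sample_id")
    missing = [s for s in presence.index if s not in r.index]
    if missing:
        raise KeyError(f"samples not in roster: {missing[:5]}")
    if unit == "plot":
        labels = r.loc[presence.index, "plot_id"]
    elif unit == "month":
        labels = r.loc[presence.index, "month"]
    else:
        if metadata is None:
            raise ValueError("district collapse needs plot metadata")
        dist = metadata.set_index("plot_id")["district"]
        labels = r.loc[presence.index, "plot_id"].map(dist)
    out = presence.groupby(labels.values).max()
    out.index.name = unit
    return out.astype(int)


# ---------------------------------------------------------------------------
# field-survey derivations
# ---------------------------------------------------------------------------

def classify_dieback(dying: int, affected: int, healthy_or_resilient: int,
                     n_assessed: int = 20) -> str:
    """Dieback class of a plot from the 20-tree crown-condition survey.

    high:   >= 1 dying tree and > 60% affected trees
    medium: no dying tree and > 60% affected trees
    low:    no dying tree and >= 40% healthy-or-resilient trees
    Anything falling through returns "unclassified".  Rules are applied
    with precedence high > medium > low.
    """
    for v in (dying, affected, healthy_or_resilient):
        if v < 0:
            raise ValueError("negative survey count")
    if max(affected, healthy_or_resilient) > n_assessed:
        raise ValueError("survey count exceeds number of assessed trees")
    if dying >= 1 and affected / n_assessed > 0.6:
        return "high"
    if dying == 0 and affected / n_assessed > 0.6:
        return "medium"
    if dying == 0 and healthy_or_resilient / n_assessed >= 0.4:
        return "low"
    return "unclassified"


def canopy_openness(densiometer_counts) -> tuple[float, float]:
    """(cover, openness) from five spherical-densiometer counts of 68 points.

    Cover at each location is count/68; the plot value is the mean of the
    five locations and openness is its complement.
    """
    counts = np.asarray(densiometer_counts, dtype=float)
    if counts.shape != (5,):
        raise ValueError("expected exactly 5 densiometer counts")
    if (counts < 0).any() or (counts > 68).any():
        raise ValueError("densiometer count outside 0..68")
    cover = float(np.mean(counts / 68.0))
    return cover, 1.0 - cover


VERY_LARGE_DBH_CM = 67.5  # strict threshold: a tree at exactly 67.5 is not "very large"


def derive_stand_metrics(survey: PlotSurvey, plot_area_ha: float) -> dict:
    """Per-hectare stand-structure metrics from one plot survey.

    deadwood_volume: sum of cylinder volumes pi*(d/2)^2*length over lying
    items longer than 1 m, per ha; basal_area: sum of pi*(dbh/2)^2 over
    living trees per ha (dbh in cm converted to m); very_large_tree_density:
    living trees with dbh strictly above 67.5 cm per ha; tree_diversity:
    distinct living tree species on the plot; trem_diversity / trem_density:
    distinct microhabitat types and total microhabitat count on the plot
    (microhabitats and species tallies are per-plot counts, as surveyed).
    """
    if plot_area_ha <= 0:
        raise ValueError("plot area must be positive")
    dw = survey.deadwood
    dw = dw[dw["length_m"] > 1.0] if len(dw) else dw
    vol = float((math.pi * (dw["diameter_m"] / 2.0) ** 2 * dw["length_m"]).sum()) if len(dw) else 0.0
    living = survey.trees[survey.trees["status"] == "living"] if len(survey.trees) else survey.trees
    dbh_m = living["dbh_cm"] / 100.0 if len(living) else pd.Series(dtype=float)
    basal = float((math.pi * (dbh_m / 2.0) ** 2).sum())
    n_vlt = int((living["dbh_cm"] > VERY_LARGE_DBH_CM).sum()) if len(living) else 0
    n_tree_sp = int(living["species"].nunique()) if len(living) else 0
    n_trem_types = int(survey.trems["trem_type"].nunique()) if len(survey.trems) else 0
    n_trems = int(len(survey.trems))
    cover, openness = canopy_openness(survey.densiometer)
    return {
        "deadwood_volume": vol / plot_area_ha,
        "basal_area": basal / plot_area_ha,
        "very_large_tree_density": n_vlt / plot_area_ha,
        "tree_diversity": n_tree_sp,
        "trem_diversity": n_trem_types,
        "trem_density": n_trems,
        "canopy_cover": cover,
        "canopy_openness": openness,
    }
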