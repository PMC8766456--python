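"""Tab-separated readers/writers for the package's tables.

All on-disk formats are plain TSV with header rows: long read tables
(motu_id, sample_id, replicate, reads), sample rosters, plot metadata,
taxonomy and trait tables, and wide 0/1 incidence matrices (rows = units,
columns = MOTUs).  A YAML manifest records generating parameters.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml


def write_incidence(incidence: pd.DataFrame, path) -> None:
    incidence.to_csv(path, sep="\t")


def read_incidence(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_reads(counts_path, roster_path):
    from .pipeline import ReadCountTable
    counts = pd.read_csv(counts_path, sep="\t")
    roster = pd.read_csv(roster_path, sep="\t",
                         dtype={"plot_id": str, "month": str},
                         keep_default_na=False)
    roster["is_control"] = roster["is_control"].astype(str).str.lower().isin(
        {"true", "1"})
    return ReadCountTable(counts=counts, roster=roster)


def write_dataset(dataset, outdir) -> None:
    """Write a synthetic dataset's tables plus a YAML manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(dataset.reads.counts, out / "reads.tsv")
    write_table(dataset.reads.roster, out / "roster.tsv")
    write_table(dataset.metadata, out / "metadata.tsv")
    write_table(dataset.taxonomy, out / "taxonomy.tsv")
    write_table(dataset.traits, out / "traits.tsv")
    write_table(dataset.function_lookup, out / "function_lookup.tsv")
    cfg = asdict(dataset.config)
    cfg["dieback_mix"] = list(cfg["dieback_mix"])
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"generator": "zetacomm.simulate.generate_dataset",
                        "config": cfg}, fh, sort_keys=True)
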