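"""Microbial composition metrics from a taxonomic classification table.

Classification itself is consumed as a table (sample, semicolon-delimited
lineage, read count); reads the classifier re-aligned to the human host
("second human-aligned" reads) are carried separately and excluded from all
taxon-level math.  Alpha diversity uses the ecological convention
(Shannon index with natural log), distinct from the end-motif entropy's
bits — each follows its field's convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Lineage rank order, superkingdom → species.
RANKS = ["superkingdom", "phylum", "class", "order", "family", "genus", "species"]

SECOND_HUMAN_LABEL = "second_human"


@dataclass
class TaxaTable:
    """Long-form taxa counts: one row per (sample, lineage)."""

    rows: pd.DataFrame  # columns: sample_id, lineage (list[str]), count
    second_human: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.rows["count"] < 0).any():
            raise ValueError("negative taxa counts")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.rows["sample_id"]))

    def total(self, sample_id: str) -> int:
        return int(self.rows.loc[self.rows["sample_id"] == sample_id, "count"].sum())

    def totals(self) -> pd.Series:
        return self.rows.groupby("sample_id", sort=False)["count"].sum()


def load_taxa(path: str | os.PathLike) -> TaxaTable:
    """Parse a taxa TSV with header columns sample, lineage, count.

    Lineages are semicolon-delimited from superkingdom down; gaps (unranked
    levels) may be left empty.  Rows whose lineage is the host marker
    ``second_human`` are diverted to the per-sample second-human tally.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty taxa table") from exc
    cols = {c.lower(): c for c in df.columns}
    for need in ("sample", "lineage", "count"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r} (have {list(df.columns)})")
    if df.empty:
        raise ValueError(f"{path}: empty taxa table")
    second_human: dict[str, int] = {}
    rows = []
    for i, rec in df.iterrows():
        sample = str(rec[cols["sample"]])
        lineage_raw = rec[cols["lineage"]]
        try:
            count = int(rec[cols["count"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i + 2}: bad count {rec[cols['count']]!r}") from exc
        if count < 0:
            raise ValueError(f"{path}: line {i + 2}: negative count {count}")
        if not isinstance(lineage_raw, str) or not lineage_raw.strip():
            raise ValueError(f"{path}: line {i + 2}: malformed lineage {lineage_raw!r}")
        if lineage_raw.strip() == SECOND_HUMAN_LABEL:
            second_human[sample] = second_human.get(sample, 0) + count
            continue
        lineage = [t.strip() for t in lineage_raw.split(";")]
        if len(lineage) > len(RANKS):
            raise ValueError(
                f"{path}: line {i + 2}: lineage deeper than {len(RANKS)} ranks"
            )
        lineage += [""] * (len(RANKS) - len(lineage))
        rows.append((sample, lineage, count))
    out = pd.DataFrame(rows, columns=["sample_id", "lineage", "count"])
    return TaxaTable(rows=out, second_human=second_human)


def microbial_fraction(
    human_reads: int, microbial_reads: int, unclassified: int = 0
) -> dict[str, float]:
    """Percent of reads of microbial origin.

    Returns both denominators — of classified (human+microbial) reads and,
    when an unclassified remainder is supplied, of all reads.
    """
    classified = human_reads + microbial_reads
    if classified <= 0:
        raise ValueError("need at least one classified read")
    out = {"pct_of_classified": 100.0 * microbial_reads / classified}
    total = classified + unclassified
    out["pct_of_total"] = 100.0 * microbial_reads / total
    return out


def rank_abundance(table: TaxaTable, rank: str) -> pd.DataFrame:
    """Per-sample relative abundance at a taxonomic rank (rows sum to 1).

    Counts of lineages unranked at that level are dropped from the
    aggregation; taxa absent from a sample get 0.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    idx = RANKS.index(rank)
    df = table.rows.copy()
    df["taxon"] = [lin[idx] for lin in df["lineage"]]
    df = df[df["taxon"] != ""]
    if df.empty:
        raise ValueError(f"rank {rank!r} not present in any lineage")
    wide = (
        df.pivot_table(index="sample_id", columns="taxon", values="count",
                       aggfunc="sum", fill_value=0)
        .astype(float)
    )
    wide = wide.div(wide.sum(axis=1), axis=0)
    wide = wide.loc[[s for s in table.samples if s in wide.index]]
    return wide


def shannon_alpha(abundance: np.ndarray | pd.Series) -> float:
    """Shannon alpha diversity, −Σ p·ln p (natural log)."""
    p = np.asarray(abundance, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"abundances must sum to 1, got {p.sum()}")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
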