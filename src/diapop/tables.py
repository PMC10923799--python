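"""Sample design, count tables and splice-event tables (TSV I/O).

All tables are written tab-separated, UTF-8, single header row, floats at
six significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRAJECTORIES",
    "TISSUES",
    "validate_design",
    "make_design",
    "CountTable",
    "EventRecord",
    "read_design",
    "write_design",
    "read_count_table",
    "write_count_table",
    "read_events",
    "write_events",
    "write_table",
]

TRAJECTORIES = ("diapause", "direct")
TISSUES = ("head", "abdomen")

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    """Write a result table per the package conventions (TSV, %.6g floats)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample design table (sample_id, trajectory, day, tissue)."""
    required = {"sample_id", "trajectory", "day", "tissue"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    bad = set(design["trajectory"]) - set(TRAJECTORIES)
    if bad:
        raise ValueError(f"unknown trajectories: {sorted(bad)}")
    bad = set(design["tissue"]) - set(TISSUES)
    if bad:
        raise ValueError(f"unknown tissues: {sorted(bad)}")
    if (design["day"].astype(int) < 0).any():
        raise ValueError("days must be non-negative")
    design = design.copy()
    design["day"] = design["day"].astype(int)
    return design


def make_design(
    diapause_days=(0, 3, 6, 24, 114, 144, 155),
    direct_days=(0, 3, 6),
    replicates: int = 5,
    tissue: str = "head",
) -> pd.DataFrame:
    """Build the study-style design: diapause pupae sampled at days
    0/3/6/24/114/144/155 and direct-developing pupae at days 0/3/6, a fixed
    number of replicate individuals per trajectory x day cell, one tissue."""
    rows = []
    for traj, days in (("diapause", diapause_days), ("direct", direct_days)):
        for day in days:
            for r in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue[:2]}_{traj[:3]}_{day:03d}_r{r}",
                        "trajectory": traj,
                        "day": int(day),
                        "tissue": tissue,
                    }
                )
    return validate_design(pd.DataFrame(rows))


@dataclass
class CountTable:
    """features x samples non-negative integer counts.

    ``gene_of_feature`` maps every feature to exactly one gene; gene-level
    tables map each gene to itself.
    """

    counts: pd.DataFrame  # features x samples, int
    gene_of_feature: pd.Series  # index = feature ids
    level: str  # "exon" | "gene"

    def __post_init__(self) -> None:
        if self.level not in ("exon", "gene"):
            raise ValueError(f"level must be 'exon' or 'gene', got {self.level!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative entries")
        missing = self.counts.index.difference(self.gene_of_feature.index)
        if len(missing):
            raise ValueError(f"features without a gene mapping: {list(missing[:5])}")
        if self.level == "gene" and not (self.gene_of_feature.loc[self.counts.index] == self.counts.index).all():
            raise ValueError("gene-level table must have feature_id == gene_id")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class EventRecord:
    """One splice event with per-sample inclusion/skip junction counts."""

    event_id: str
    gene_id: str
    event_type: str  # SE, MXE, A5SS, A3SS, RI
    inc_len: int
    skip_len: int
    inclusion: pd.Series  # per-sample counts
    skip: pd.Series

    def __post_init__(self) -> None:
        if self.inc_len <= 0 or self.skip_len <= 0:
            raise ValueError("effective lengths must be positive")
        if (self.inclusion < 0).any() or (self.skip < 0).any():
            raise ValueError("junction counts must be non-negative")


# ---------------------------------------------------------------------------
# TSV I/O


def write_design(design: pd.DataFrame, path: str) -> None:
    write_table(validate_design(design), path)


def read_design(path: str) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t"))


def write_count_table(table: CountTable, path: str) -> None:
    df = table.counts.copy()
    df.insert(0, "gene_id", table.gene_of_feature.loc[df.index].to_numpy())
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_count_table(path: str, level: str) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    gene = df.pop("gene_id")
    return CountTable(df.astype(np.int64), gene, level)


def write_events(events: list[EventRecord], path: str) -> None:
    if not events:
        raise ValueError("no events to write")
    samples = list(events[0].inclusion.index)
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "inc_len": ev.inc_len,
            "skip_len": ev.skip_len,
        }
        for s in samples:
            row[f"inc:{s}"] = int(ev.inclusion[s])
            row[f"skip:{s}"] = int(ev.skip[s])
        rows.append(row)
    write_table(pd.DataFrame(rows), path)


def read_events(path: str) -> list[EventRecord]:
    df = pd.read_csv(path, sep="\t")
    inc_cols = [c for c in df.columns if c.startswith("inc:")]
    skip_cols = [c for c in df.columns if c.startswith("skip:")]
    samples = [c.split(":", 1)[1] for c in inc_cols]
    events = []
    for _, row in df.iterrows():
        events.append(
            EventRecord(
                event_id=row["event_id"],
                gene_id=row["gene_id"],
                event_type=row["event_type"],
                inc_len=int(row["inc_len"]),
                skip_len=int(row["skip_len"]),
                inclusion=pd.Series([int(row[c]) for c in inc_cols], index=samples),
                skip=pd.Series([int(row[c]) for c in skip_cols], index=samples),
            )
        )
    return events
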