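"""Tabular readers and writers.

One dialect everywhere: tab-separated UTF-8, "NA" for missing, provenance
lines starting with ``#`` at the top of every file the pipeline writes.
Event coordinates are 0-based half-open intervals encoded as
``start-end,start-end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("sexsplice")

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")
TISSUES = ("gonad", "spleen")
SEXES = ("male", "female")
MORPHS = ("dominant", "subordinate", "none")

NA = "NA"


@dataclass
class JunctionCounts:
    """Per-event, per-sample inclusion/exclusion junction read counts.

    Both frames are indexed by event_id with one column per sample_id;
    entries are non-negative integers.
    """

    ijc: pd.DataFrame
    sjc: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ijc.index.equals(self.sjc.index) or not self.ijc.columns.equals(
            self.sjc.columns
        ):
            raise ValueError("ijc and sjc tables must share index and columns")

    @property
    def samples(self) -> list[str]:
        return list(self.ijc.columns)

    @property
    def events(self) -> list[str]:
        return list(self.ijc.index)

    def subset_samples(self, sample_ids: Iterable[str]) -> "JunctionCounts":
        ids = list(sample_ids)
        return JunctionCounts(self.ijc[ids], self.sjc[ids])

    def subset_events(self, event_ids: Iterable[str]) -> "JunctionCounts":
        ids = list(event_ids)
        return JunctionCounts(self.ijc.loc[ids], self.sjc.loc[ids])


def _provenance_lines(meta: Mapping[str, object] | None) -> list[str]:
    if not meta:
        return []
    return [f"# {k}={v}" for k, v in meta.items()]


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: Mapping[str, object] | None = None,
              index: bool = False) -> None:
    """Write a result table with an optional ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA], **kwargs)


def parse_coords(text: str) -> list[tuple[int, int]]:
    """Parse ``start-end,start-end`` into sorted, non-overlapping intervals."""
    out: list[tuple[int, int]] = []
    for chunk in str(text).split(","):
        start_s, end_s = chunk.split("-")
        start, end = int(start_s), int(end_s)
        if end <= start:
            raise ValueError(f"empty or inverted interval {chunk!r}")
        out.append((start, end))
    for (s1, e1), (s2, e2) in zip(out, out[1:]):
        if s2 < e1:
            raise ValueError(f"intervals overlap or are unsorted near {s2}-{e2}")
    return out


def format_coords(intervals: Iterable[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in intervals)


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

_EVENT_COLS = ["event_id", "gene_id", "event_type", "chrom", "strand", "coords"]


def read_junction_counts(path: str | Path) -> tuple[pd.DataFrame, JunctionCounts]:
    """Read the event table plus the per-sample IJC/SJC column pairs.

    Returns ``(events, counts)`` where *events* is indexed by event_id and
    *counts* holds the two event × sample integer matrices.
    """
    raw = read_tsv(path, dtype={"event_id": str, "gene_id": str})
    missing = [c for c in _EVENT_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = raw["event_id"][raw["event_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate event_id {sorted(set(dup))}")
    bad_type = raw.loc[~raw["event_type"].isin(EVENT_TYPES), "event_type"]
    if len(bad_type):
        raise ValueError(
            f"{path}: unknown event_type {sorted(set(bad_type))}; "
            f"allowed types are {list(EVENT_TYPES)}"
        )
    bad_strand = raw.loc[~raw["strand"].isin(["+", "-"]), "strand"]
    if len(bad_strand):
        raise ValueError(f"{path}: strand must be + or -")
    raw["coords"].map(parse_coords)  # validates

    count_cols = [c for c in raw.columns if c not in _EVENT_COLS]
    sample_ids: list[str] = []
    for col in count_cols:
        if col.endswith("_IJC"):
            sid = col[: -len("_IJC")]
            if f"{sid}_SJC" not in count_cols:
                raise ValueError(f"{path}: column {sid}_SJC missing")
            sample_ids.append(sid)
        elif not col.endswith("_SJC"):
            raise ValueError(f"{path}: unexpected column {col!r}")
    if not sample_ids:
        raise ValueError(f"{path}: no per-sample IJC/SJC column pairs found")

    events = raw[_EVENT_COLS].set_index("event_id")
    ijc = {}
    sjc = {}
    for sid in sample_ids:
        for kind, store in (("IJC", ijc), ("SJC", sjc)):
            col = raw[f"{sid}_{kind}"]
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"{path}: invalid count {col.iloc[row]!r} in column "
                    f"{sid}_{kind}, row {row + 2} (event {raw['event_id'].iloc[row]})"
                )
            store[sid] = vals.to_numpy(dtype=np.int64)
    counts = JunctionCounts(
        pd.DataFrame(ijc, index=events.index), pd.DataFrame(sjc, index=events.index)
    )
    return events, counts


def write_junction_counts(events: pd.DataFrame, counts: JunctionCounts,
                          path: str | Path,
                          provenance: Mapping[str, object] | None = None) -> None:
    df = events.reset_index()[_EVENT_COLS].copy()
    for sid in counts.samples:
        df[f"{sid}_IJC"] = counts.ijc[sid].to_numpy()
        df[f"{sid}_SJC"] = counts.sjc[sid].to_numpy()
    write_tsv(df, path, provenance)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "species", "tissue", "sex", "morph"]


def read_sample_metadata(path: str | Path,
                         count_samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Read and validate the sample sheet; optionally cross-check against
    the sample ids present in a count table."""
    meta = read_tsv(path, dtype=str)
    missing = [c for c in _META_COLS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return validate_sample_metadata(meta, count_samples, source=str(path))


def validate_sample_metadata(meta: pd.DataFrame,
                             count_samples: Iterable[str] | None = None,
                             source: str = "metadata") -> pd.DataFrame:
    meta = meta.copy()
    meta["morph"] = meta["morph"].fillna("none")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{source}: duplicate sample_id {sorted(set(dup))}")
    for col, allowed in (("tissue", TISSUES), ("sex", SEXES), ("morph", MORPHS)):
        bad = meta.loc[~meta[col].isin(allowed), col]
        if len(bad):
            raise ValueError(f"{source}: invalid {col} value {sorted(set(bad))}")
    bad_morph = meta[(meta["sex"] == "female") & (meta["morph"] != "none")]
    if len(bad_morph):
        raise ValueError(
            f"{source}: morph labels only apply to males; offending samples "
            f"{bad_morph['sample_id'].tolist()}"
        )
    if count_samples is not None:
        counts = set(count_samples)
        sheet = set(meta["sample_id"])
        orphans = sorted(counts - sheet)
        if orphans:
            raise ValueError(f"{source}: samples in counts but not in sheet: {orphans}")
        extra = sorted(sheet - counts)
        if extra:
            log.warning("%s: %d sheet samples absent from counts: %s",
                        source, len(extra), extra)
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path,
                          provenance: Mapping[str, object] | None = None) -> None:
    write_tsv(meta[_META_COLS], path, provenance)


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> pd.DataFrame:
    genes = read_tsv(path, dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "autosomal", "n_exons", "cds_length"):
        if col not in genes.columns:
            raise ValueError(f"{path}: missing column {col}")
    if genes["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id")
    if (genes["n_exons"] < 1).any():
        raise ValueError(f"{path}: n_exons must be >= 1")
    genes["autosomal"] = genes["autosomal"].astype(bool)
    return genes


def write_gene_table(genes: pd.DataFrame, path: str | Path,
                     provenance: Mapping[str, object] | None = None) -> None:
    write_tsv(genes, path, provenance)


def filter_autosomal(genes: pd.DataFrame, table: pd.DataFrame,
                     gene_col: str = "gene_id",
                     missing: str = "drop") -> pd.DataFrame:
    """Keep only rows whose gene is flagged autosomal in the gene table.

    ``missing`` controls genes absent from the gene table: "drop" removes
    them (logged), "error" raises.
    """
    flags = genes.set_index("gene_id")["autosomal"]
    known = table[gene_col].isin(flags.index)
    if not known.all():
        absent = sorted(set(table.loc[~known, gene_col]))
        if missing == "error":
            raise ValueError(f"genes absent from gene table: {absent}")
        log.warning("dropping %d rows with genes absent from gene table", (~known).sum())
    table = table[known]
    keep = flags.reindex(table[gene_col]).to_numpy(dtype=bool)
    removed = int((~keep).sum())
    if removed:
        log.info("filter_autosomal: removed %d non-autosomal rows", removed)
    return table[keep]


# ---------------------------------------------------------------------------
# allele counts and dN/dS component tables
# ---------------------------------------------------------------------------

def read_allele_counts(path: str | Path) -> pd.DataFrame:
    tab = read_tsv(path, dtype={"gene_id": str})
    req = ["gene_id", "site", "male_ref", "male_alt", "female_ref", "female_alt"]
    missing = [c for c in req if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in req[2:]:
        if (tab[col] < 0).any():
            raise ValueError(f"{path}: negative counts in {col}")
    return tab


def read_dnds_table(path: str | Path) -> pd.DataFrame:
    tab = read_tsv(path, dtype={"gene_id": str})
    req = ["gene_id", "N", "S", "NdN", "SdS", "dS", "class"]
    missing = [c for c in req if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if ((tab["N"] <= 0) | (tab["S"] <= 0)).any():
        raise ValueError(f"{path}: N and S must be positive")
    return tab
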