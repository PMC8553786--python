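"""Reading, writing and summarising per-CpG bisulfite count data.

The atomic observation of a whole-genome bisulfite experiment is, per CpG
dinucleotide, the number of methylated reads ``mC`` and the total read count
``total`` (``umC = total - mC``).  Count tables are carried as pandas
DataFrames with columns ``chrom, pos, mC, total`` where ``pos`` is the
1-based position of the C of the CpG on the + strand; internally all region
arithmetic is 0-based half-open, and the conversion happens only at this
I/O boundary.

Missing data are absent rows, never imputed zeros: a site dropped by the
coverage filter simply does not appear.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["chrom", "pos", "mC", "total"]

#: region classes recognised in BED score fields, in index order
REGION_CLASSES = [
    "gene",
    "promoter",
    "imprinted_maternal",
    "imprinted_paternal",
    "LTR",
    "LINE",
    "SINE",
    "satellite",
    "pseudogene",
    "DNA_transposon",
    "VM_IAP",
    "DMR",
]

GROUPS = ("control", "stress")
GENERATIONS = ("F0", "F1", "F2")
STAGES = ("sperm", "oocyte", "ICM", "PS", "PGC")


class MethylationParseError(ValueError):
    """Raised when a count table line cannot be parsed; names the line."""


class MethylationValidationError(ValueError):
    """Raised when counts violate mC <= total or position constraints."""


@dataclass(frozen=True)
class CpGRecord:
    chrom: str
    pos: int  # 1-based position of the + strand C
    mC: int
    total: int

    def __post_init__(self):
        if self.mC > self.total:
            raise MethylationValidationError(
                f"mC > total at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise MethylationValidationError(f"pos < 1 ({self.pos})")


def compute_beta(mC: int, total: int) -> float:
    """Methylation level mC/(mC+umC) of a site or pooled region.

    Raises if ``total`` is zero — the caller must have applied the coverage
    filter; an uncovered site has no level, not level zero.
    """
    if total <= 0:
        raise MethylationValidationError(
            "methylation level undefined for total = 0"
        )
    if mC > total or mC < 0:
        raise MethylationValidationError(f"invalid counts ({mC}, {total})")
    return mC / total


def _finalize(df: pd.DataFrame, min_coverage: int) -> pd.DataFrame:
    # pool duplicate (chrom, pos) units (strand collapsing) BEFORE the
    # coverage filter, so the filter sees CpG-dinucleotide totals
    df = (
        df.groupby(["chrom", "pos"], as_index=False, sort=False)
        .agg(mC=("mC", "sum"), total=("total", "sum"))
    )
    df = (
        df[df["total"] >= min_coverage]
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return df[COUNT_COLUMNS]


def read_cytosine_report(
    path,
    min_coverage: int = 5,
    collapse_strands: bool = True,
) -> pd.DataFrame:
    """Read a Bismark-style cytosine report or coverage file.

    Two dialects are auto-detected by column count:

    * CX report (7 columns): ``chrom pos strand count_meth count_unmeth
      context trinucleotide``; only CpG-context rows are kept.  When
      ``collapse_strands`` is set, counts of the − strand C (at pos+1 of
      the + strand C) are folded into the + strand unit *before* the
      coverage filter, matching analysis of reference CpG dinucleotides.
    * coverage format (6 columns): ``chrom start end pct count_meth
      count_unmeth`` with 1-based start (Bismark convention).

    Sites with collapsed ``total < min_coverage`` are dropped, not
    zero-filled.  Returns a sorted, deduplicated count DataFrame.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 7:
                    chrom, pos, strand, meth, unmeth, context, _tri = fields
                    if context != "CG":
                        continue
                    pos = int(pos)
                    mC, umC = int(meth), int(unmeth)
                    if strand == "-":
                        if collapse_strands:
                            pos -= 1  # fold onto the + strand C of the CpG
                        if pos < 1:
                            continue
                elif len(fields) == 6:
                    chrom, start, _end, _pct, meth, unmeth = fields
                    pos = int(start)
                    mC, umC = int(meth), int(unmeth)
                else:
                    raise ValueError(f"{len(fields)} fields")
            except ValueError as exc:
                raise MethylationParseError(
                    f"{path}: malformed line {lineno}: {exc}"
                ) from None
            if mC < 0 or umC < 0:
                raise MethylationValidationError(
                    f"{path}: negative count at line {lineno}"
                )
            rows.append((chrom, pos, mC, mC + umC))
    if not rows:
        return pd.DataFrame(columns=COUNT_COLUMNS).astype(
            {"chrom": str, "pos": int, "mC": int, "total": int}
        )
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return _finalize(df, min_coverage)


def write_counts(df: pd.DataFrame, path) -> None:
    """Write counts in the 6-column coverage dialect (read back losslessly)."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"],
            "pct": [
                f"{100.0 * m / t:.6g}" if t else "0"
                for m, t in zip(df["mC"], df["total"])
            ],
            "mC": df["mC"],
            "umC": df["total"] - df["mC"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def validate_counts(df: pd.DataFrame) -> None:
    if (df["mC"] > df["total"]).any():
        bad = df[df["mC"] > df["total"]].iloc[0]
        raise MethylationValidationError(
            f"mC > total at {bad['chrom']}:{bad['pos']}"
        )
    if (df["pos"] < 1).any():
        raise MethylationValidationError("positions must be >= 1")
    if df.duplicated(["chrom", "pos"]).any():
        raise MethylationValidationError("duplicate (chrom, pos) records")


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet: sample_id group generation stage replicate path.

    ``generation`` may be empty/"none" for samples (e.g. the oocyte) that do
    not belong to a paternal generation.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype={"sample_id": str, "group": str, "generation": str,
               "stage": str, "path": str},
    )
    required = ["sample_id", "group", "generation", "stage", "replicate", "path"]
    missing = set(required) - set(df.columns)
    if missing:
        raise MethylationParseError(f"sample sheet missing columns: {missing}")
    df["generation"] = df["generation"].fillna("none")
    for col, allowed in [("group", GROUPS), ("stage", STAGES),
                         ("generation", GENERATIONS + ("none",))]:
        bad = set(df[col]) - set(allowed)
        if bad:
            raise MethylationValidationError(f"invalid {col} values: {bad}")
    key = df[["group", "generation", "stage", "replicate"]]
    if key.duplicated().any():
        raise MethylationValidationError(
            "(group, generation, stage, replicate) not unique"
        )
    sperm = df["stage"] == "sperm"
    if (df.loc[sperm, "generation"] == "none").any():
        raise MethylationValidationError("sperm samples must carry a generation")
    return df


# ---------------------------------------------------------------------------
# region sets


def read_regions(path, name: str | None = None) -> pd.DataFrame:
    """Read a BED6 region set.

    The BED name field carries the region label and the score field the
    region-class index into :data:`REGION_CLASSES`.  Returns a DataFrame
    with columns ``chrom, start, end, label, cls, strand`` (0-based
    half-open intervals).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "label": str},
    )
    if (df["start"] >= df["end"]).any():
        raise MethylationValidationError(f"{path}: start >= end in region set")
    idx = df["score"].astype(int)
    if (idx < 0).any() or (idx >= len(REGION_CLASSES)).any():
        raise MethylationValidationError(f"{path}: region class index out of range")
    df["cls"] = [REGION_CLASSES[i] for i in idx]
    df = df.drop(columns="score")
    df.insert(0, "name", name if name is not None else str(path))
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_regions(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "label": df["label"],
            "score": [REGION_CLASSES.index(c) for c in df["cls"]],
            "strand": df.get("strand", pd.Series(["."] * len(df))),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_same_class(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge intersecting regions of the same class into one long region."""
    merged = []
    for (chrom, cls), grp in regions.groupby(["chrom", "cls"], sort=True):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples():
            if cur is None or row.start > cur[1]:
                if cur is not None:
                    merged.append((chrom, cur[0], cur[1], cur[2], cls))
                cur = [row.start, row.end, row.label]
            else:
                cur[1] = max(cur[1], row.end)
        if cur is not None:
            merged.append((chrom, cur[0], cur[1], cur[2], cls))
    out = pd.DataFrame(merged, columns=["chrom", "start", "end", "label", "cls"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# region summaries


def summarize_region(records: pd.DataFrame, chrom: str, start: int, end: int):
    """Summarise one sample's methylation over a 0-based half-open region.

    Returns a dict with the unweighted mean of per-site levels, the
    pooled-count level sum(mC)/sum(total), and the number of covered sites.
    Both levels are NaN when no site in the region has data.
    """
    sub = records[
        (records["chrom"] == chrom)
        & (records["pos"] - 1 >= start)
        & (records["pos"] - 1 < end)
    ]
    n = len(sub)
    if n == 0:
        return {"mean_level": np.nan, "pooled_level": np.nan, "n_covered": 0}
    levels = sub["mC"].to_numpy() / sub["total"].to_numpy()
    return {
        "mean_level": float(levels.mean()),
        "pooled_level": float(sub["mC"].sum() / sub["total"].sum()),
        "n_covered": int(n),
    }


def region_levels(
    records: pd.DataFrame,
    regions: pd.DataFrame,
    kind: str = "pooled",
) -> np.ndarray:
    """Vectorised per-region levels of one sample over many regions.

    ``kind`` is "pooled" (sum mC / sum total) or "mean" (unweighted mean of
    site levels).  Regions without covered sites get NaN.  Uses cumulative
    sums over the position-sorted record table, O((n+m) log n).
    """
    out = np.full(len(regions), np.nan)
    ncov = np.zeros(len(regions), dtype=int)
    for chrom, sub in records.groupby("chrom", sort=False):
        sel = regions["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = sub["pos"].to_numpy() - 1  # 0-based site coords
        order = np.argsort(pos0)
        pos0 = pos0[order]
        mC = sub["mC"].to_numpy()[order].astype(float)
        tot = sub["total"].to_numpy()[order].astype(float)
        cm = np.concatenate([[0.0], np.cumsum(mC)])
        ct = np.concatenate([[0.0], np.cumsum(tot)])
        cl = np.concatenate([[0.0], np.cumsum(mC / tot)])
        lo = np.searchsorted(pos0, regions.loc[sel, "start"].to_numpy(), "left")
        hi = np.searchsorted(pos0, regions.loc[sel, "end"].to_numpy(), "left")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            if kind == "pooled":
                vals = (cm[hi] - cm[lo]) / (ct[hi] - ct[lo])
            elif kind == "mean":
                vals = (cl[hi] - cl[lo]) / n
            else:
                raise ValueError(f"unknown kind {kind!r}")
        vals[n == 0] = np.nan
        out[np.flatnonzero(sel)] = vals
        ncov[np.flatnonzero(sel)] = n
    return out, ncov


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path) -> dict[str, str]:
    """FASTA reader via Biopython; returns id -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def align_samples(tables: Sequence[pd.DataFrame]):
    """Align several samples' count tables onto the union of sites.

    Returns ``(index, mC, total)`` where ``index`` is a DataFrame with
    ``chrom, pos`` sorted, and ``mC``/``total`` are (n_samples, n_sites)
    integer arrays with total 0 at sites a sample does not cover.
    """
    keys = pd.concat(
        [t[["chrom", "pos"]] for t in tables], ignore_index=True
    ).drop_duplicates()
    keys = keys.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    lookup = pd.MultiIndex.from_frame(keys)
    n = len(keys)
    mC = np.zeros((len(tables), n), dtype=np.int64)
    total = np.zeros((len(tables), n), dtype=np.int64)
    for i, t in enumerate(tables):
        idx = lookup.get_indexer(pd.MultiIndex.from_frame(t[["chrom", "pos"]]))
        mC[i, idx] = t["mC"].to_numpy()
        total[i, idx] = t["total"].to_numpy()
    return keys, mC, total
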