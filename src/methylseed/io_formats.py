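"""Readers and writers for the external table formats used throughout the package.

Per-cytosine methylation counts travel in "allc"-style tab-separated tables
(chromosome, 1-based position, strand, trinucleotide context, methylated read
count, total read count, and an optional per-site call column, which is read
and ignored).  Annotations arrive as BED (0-based half-open) or GFF3 (1-based
closed); everything is normalized to 0-based half-open coordinates internally.

In memory an allc table is a :class:`pandas.DataFrame` with columns
``chrom, pos, strand, tri, context, mc, cov, low_cov`` where ``pos`` is the
0-based position and ``context`` is one of CG/CHG/CHH.  Feature annotations
are DataFrames with columns ``chrom, start, end, id, strand, feature_class``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLC_COLUMNS = ["chrom", "pos", "strand", "tri", "context", "mc", "cov", "low_cov"]
FEATURE_COLUMNS = ["chrom", "start", "end", "id", "strand", "feature_class"]

CONTEXTS = ("CG", "CHG", "CHH")
_H = frozenset("ACT")


class AllcParseError(ValueError):
    """Raised when an allc-style file contains a malformed or invalid line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


def classify_context(tri: str) -> str | None:
    """Classify a trinucleotide (5'->3' on the cytosine's strand) as CG/CHG/CHH.

    Returns ``None`` for unclassifiable contexts (N or other non-ACGT symbols
    in positions 2-3).  The first base must be C.
    """
    if len(tri) != 3 or tri[0] != "C":
        raise ValueError(f"trinucleotide context must be 3 bases starting with C, got {tri!r}")
    b2, b3 = tri[1], tri[2]
    if b2 == "G":
        return "CG"
    if b2 in _H:
        if b3 == "G":
            return "CHG"
        if b3 in _H:
            return "CHH"
    return None


def read_allc(
    path: str | Path,
    min_total: int = 0,
    chrom_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read an allc-style per-cytosine count table.

    Parameters
    ----------
    path
        Tab-separated file: chrom, 1-based position, strand, trinucleotide
        context, methylated count, total count, optionally a call column.
    min_total
        Records with ``cov < min_total`` are *retained* but flagged
        ``low_cov=True``; filtering is the caller's decision.
    chrom_map
        Optional chromosome-name normalization (e.g. ``{"1": "Chr1"}``)
        applied on ingestion.  Matching elsewhere is exact string equality.

    Returns
    -------
    DataFrame with :data:`ALLC_COLUMNS`; positions converted to 0-based and
    strictly increasing within each chromosome.  Records whose context
    contains N (unclassifiable) are dropped with a logged count.
    """
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AllcParseError(f"{path}:{lineno}: expected >=6 tab-separated fields")
            chrom, pos_s, strand, tri, mc_s, cov_s = fields[:6]
            try:
                pos = int(pos_s)
                mc = int(mc_s)
                cov = int(cov_s)
            except ValueError as exc:
                raise AllcParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            if strand not in ("+", "-"):
                raise AllcParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if pos < 1:
                raise AllcParseError(f"{path}:{lineno}: position must be >= 1 (1-based)")
            if mc < 0 or cov < 0 or mc > cov:
                raise AllcParseError(
                    f"{path}:{lineno}: invalid counts mc={mc} cov={cov} (need 0 <= mc <= cov)"
                )
            rows.append((chrom, pos - 1, strand, tri, mc, cov))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "tri", "mc", "cov"])
    if chrom_map:
        df["chrom"] = df["chrom"].map(lambda c: chrom_map.get(c, c))

    # positions must be strictly increasing within each chromosome
    for chrom, grp in df.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if len(p) > 1 and not (np.diff(p) > 0).all():
            raise AllcParseError(f"{path}: positions not strictly increasing on {chrom}")

    ctx = df["tri"].map(lambda t: classify_context(t) if len(t) == 3 and t[:1] == "C" else _bad(t, path))
    n_drop = int(ctx.isna().sum())
    if n_drop:
        logger.info("read_allc: dropped %d record(s) with unclassifiable (N) context", n_drop)
    df["context"] = ctx
    df = df[ctx.notna()].reset_index(drop=True)
    df["low_cov"] = df["cov"] < min_total
    return df[ALLC_COLUMNS]


def _bad(tri: str, path) -> None:
    raise AllcParseError(f"{path}: bad trinucleotide context {tri!r}")


def write_allc(df: pd.DataFrame, path: str | Path) -> None:
    """Write an allc DataFrame back to the tab-separated external form (1-based)."""
    out = df[["chrom", "pos", "strand", "tri", "mc", "cov"]].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_features(
    path: str | Path,
    fmt: str,
    feature_class: str,
    chrom_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read gene/TE annotations from BED (0-based half-open) or GFF3 (1-based closed).

    All intervals are normalized to 0-based half-open.  ``feature_class`` is
    attached to every record ("gene" or "TE").
    """
    fmt = fmt.upper()
    if fmt == "BED":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "id", "score", "strand"],
            usecols=range(6), dtype={"chrom": str},
        ) if _ncols(path) >= 6 else pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "id"][: max(_ncols(path), 3)], dtype={"chrom": str},
        )
        if df.empty:
            logger.warning("read_features: %s is empty", path)
            return pd.DataFrame(columns=FEATURE_COLUMNS)
        if "id" not in df.columns:
            df["id"] = [f"{feature_class}_{i}" for i in range(len(df))]
        if "strand" not in df.columns:
            df["strand"] = "."
        df = df[["chrom", "start", "end", "id", "strand"]]
    elif fmt == "GFF3":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
            dtype={"chrom": str},
        )
        if df.empty:
            logger.warning("read_features: %s is empty", path)
            return pd.DataFrame(columns=FEATURE_COLUMNS)
        df["id"] = [_gff_id(a, i) for i, a in enumerate(df["attrs"])]
        df["start"] = df["start"] - 1  # 1-based closed -> 0-based half-open
        df = df[["chrom", "start", "end", "id", "strand"]]
    else:
        raise ValueError(f"unknown annotation format {fmt!r} (expected BED or GFF3)")

    if chrom_map:
        df["chrom"] = df["chrom"].map(lambda c: chrom_map.get(c, c))
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"invalid interval after normalization: {bad['chrom']}:{bad['start']}-{bad['end']}")
    df = df.copy()
    df["feature_class"] = feature_class
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df[FEATURE_COLUMNS].reset_index(drop=True)


def _ncols(path: str | Path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 0


def _gff_id(attrs: str, i: int) -> str:
    for kv in str(attrs).split(";"):
        if kv.startswith("ID="):
            return kv[3:]
    return f"feature_{i}"


# ---------------------------------------------------------------------------
# DMR tables

DMR_FIXED_COLUMNS = ["chrom", "start", "end", "context", "n_dms", "dms_positions"]


def dmrs_to_frame(dmrs: Sequence, sample_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Convert a sequence of :class:`~methylseed.dmr_calling.Dmr` to a table.

    Per-sample weighted methylation levels become ``mlevel_<sample>`` columns.
    """
    if sample_names is None:
        sample_names = list(dmrs[0].levels) if dmrs else []
    rows = []
    for d in dmrs:
        row = {
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "context": d.context, "n_dms": d.n_dms,
            "dms_positions": ",".join(str(p) for p in d.dms_positions),
        }
        for s in sample_names:
            lv = d.levels.get(s, float("nan"))
            row[f"mlevel_{s}"] = lv
        rows.append(row)
    cols = DMR_FIXED_COLUMNS + [f"mlevel_{s}" for s in sample_names]
    return pd.DataFrame(rows, columns=cols)


def write_dmr_table(dmrs: Sequence, path: str | Path, sample_names: Sequence[str] | None = None) -> None:
    """Write DMRs as a BED-compatible TSV (first three columns chrom/start/end)."""
    dmrs_to_frame(dmrs, sample_names).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dmr_table(path: str | Path) -> list:
    """Read a DMR table written by :func:`write_dmr_table` back into Dmr objects."""
    from .dmr_calling import Dmr  # deferred: avoids an import cycle

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_names = [c[len("mlevel_"):] for c in df.columns if c.startswith("mlevel_")]
    out = []
    for _, row in df.iterrows():
        positions = tuple(int(p) for p in str(row["dms_positions"]).split(",") if p != "" and p != "nan")
        levels = {s: float(row[f"mlevel_{s}"]) for s in sample_names}
        out.append(
            Dmr(
                chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
                context=str(row["context"]), dms_positions=positions,
                n_dms=int(row["n_dms"]), levels=levels,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Expression tables


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample FPKM table (first column gene id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression table contains negative FPKM values")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def features_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    """Feature table rows as GenomicInterval objects."""
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand if r.strand in "+-" else ".")
        for r in df.itertuples()
    ]
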