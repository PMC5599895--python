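"""Weighted methylation levels, bisulfite non-conversion, and chromosome bins.

The weighted methylation level of a region is the total methylated read count
divided by the total read count over the region's cytosines of a given
context — a coverage-weighted quantity, deliberately *not* the mean of
per-site ratios.  Regions with no covered cytosines have an undefined level
(NaN), never 0: imputing 0 would manufacture demethylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval


@dataclass(frozen=True)
class WeightedMethylation:
    """Summed counts and level over one region; ``level`` is NaN when ``cov_sum == 0``."""

    region: GenomicInterval | None
    context: str | None
    mc_sum: int
    cov_sum: int

    @property
    def level(self) -> float:
        if self.cov_sum == 0:
            return float("nan")
        return self.mc_sum / self.cov_sum

    @property
    def defined(self) -> bool:
        return self.cov_sum > 0


def weighted_methylation(
    records: pd.DataFrame,
    region: GenomicInterval,
    context: str | None = None,
) -> WeightedMethylation:
    """Weighted methylation over ``region`` for one context (both strands).

    ``context=None`` pools all contexts (used for all-context "C-DMR" levels).
    """
    sel = records["chrom"] == region.chrom
    sel &= (records["pos"] >= region.start) & (records["pos"] < region.end)
    if context is not None:
        sel &= records["context"] == context
    sub = records.loc[sel]
    return WeightedMethylation(
        region=region, context=context,
        mc_sum=int(sub["mc"].sum()), cov_sum=int(sub["cov"].sum()),
    )


def nonconversion_rate(records: pd.DataFrame, control_chrom: str) -> float:
    """Apparent methylation on an unmethylated control chromosome (e.g. chloroplast).

    All contexts pooled: total methylated calls / total coverage at cytosine
    positions on ``control_chrom``.  Estimates the bisulfite non-conversion
    rate.
    """
    sub = records.loc[records["chrom"] == control_chrom]
    if sub.empty:
        raise ValueError(f"control chromosome {control_chrom!r} not present in records")
    cov = int(sub["cov"].sum())
    if cov == 0:
        raise ValueError(f"control chromosome {control_chrom!r} has zero coverage")
    return int(sub["mc"].sum()) / cov


def correct_nonconversion(records: pd.DataFrame, rate: float) -> pd.DataFrame:
    """Opt-in non-conversion correction of methylated counts.

    Returns a copy with mc' = max(0, round((mc - rate*cov) / (1 - rate))) —
    the default analysis applies no correction.
    """
    if not 0 <= rate < 1:
        raise ValueError("non-conversion rate must be in [0, 1)")
    out = records.copy()
    adj = (out["mc"] - rate * out["cov"]) / (1.0 - rate)
    out["mc"] = np.maximum(0, np.rint(adj)).astype(int)
    out["mc"] = np.minimum(out["mc"], out["cov"])
    return out


def chromosome_bins(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
    context: str | None = None,
) -> pd.DataFrame:
    """Per-bin weighted methylation along each chromosome.

    Bins are ``[k*bin_size, (k+1)*bin_size)`` in 0-based coordinates; the last
    bin of each chromosome may be short.  Bins with zero coverage get level
    NaN (reported, not dropped).

    Returns a DataFrame with columns chrom, start, end, mc, cov, level.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        sel = records["chrom"] == chrom
        if context is not None:
            sel &= records["context"] == context
        sub = records.loc[sel]
        idx = (sub["pos"].to_numpy() // bin_size).astype(int)
        mc = np.bincount(idx, weights=sub["mc"].to_numpy(), minlength=n_bins) if len(sub) else np.zeros(n_bins)
        cov = np.bincount(idx, weights=sub["cov"].to_numpy(), minlength=n_bins) if len(sub) else np.zeros(n_bins)
        for k in range(n_bins):
            rows.append((
                chrom, k * bin_size, min((k + 1) * bin_size, length),
                int(mc[k]), int(cov[k]),
                (mc[k] / cov[k]) if cov[k] > 0 else float("nan"),
            ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mc", "cov", "level"])


def bins_to_bedgraph(bins: pd.DataFrame, path) -> None:
    """Export a bin profile as bedGraph; undefined bins are omitted."""
    defined = bins.dropna(subset=["level"])
    defined[["chrom", "start", "end", "level"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def merge_symmetric_cg(records: pd.DataFrame) -> pd.DataFrame:
    """Merge symmetric CG dyads: counts of a (+) CG at p and (−) CG at p+1 are
    summed into one record at the plus-strand position.

    Optional convenience; the analysis default leaves strands unmerged.
    Unpaired CG sites pass through unchanged.  Raises on non-CG input.
    """
    if (records["context"] != "CG").any():
        raise ValueError("merge_symmetric_cg expects CG-context records only")
    out_rows = []
    for chrom, grp in records.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        strand = grp["strand"].to_numpy()
        mc = grp["mc"].to_numpy()
        cov = grp["cov"].to_numpy()
        tri = grp["tri"].to_numpy()
        low = grp["low_cov"].to_numpy()
        used = np.zeros(len(grp), dtype=bool)
        for i in range(len(grp)):
            if used[i]:
                continue
            if (
                strand[i] == "+"
                and i + 1 < len(grp)
                and strand[i + 1] == "-"
                and pos[i + 1] == pos[i] + 1
            ):
                out_rows.append((chrom, pos[i], "+", tri[i], "CG",
                                 int(mc[i] + mc[i + 1]), int(cov[i] + cov[i + 1]),
                                 bool(low[i] and low[i + 1])))
                used[i] = used[i + 1] = True
            else:
                out_rows.append((chrom, pos[i], strand[i], tri[i], "CG",
                                 int(mc[i]), int(cov[i]), bool(low[i])))
                used[i] = True
    return pd.DataFrame(
        out_rows, columns=["chrom", "pos", "strand", "tri", "context", "mc", "cov", "low_cov"]
    )
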