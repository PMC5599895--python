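"""Average methylation profiles across feature bodies and flanks.

Each feature's body is split into 40 equal-width bins and each 2-kb flank
into 40 fixed 50-bp bins; per-feature per-bin weighted methylation is
computed from raw counts and the profile value of a bin is the unweighted
mean over features with a defined value there.  Minus-strand features are
orientation-flipped before averaging, so bin 0 is always the distal end of
the upstream flank in the feature's own 5'->3' sense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MetaplotProfile:
    """120 ordered bins (upstream 40, body 40, downstream 40) of mean weighted levels."""

    feature_set_id: str
    context: str
    values: np.ndarray  # length 3*n_bins; NaN where no feature contributes
    n_contributing: np.ndarray  # per-bin count of features with a defined level
    n_features: int
    n_bins: int = 40
    flank: int = 2000

    @property
    def upstream(self) -> np.ndarray:
        return self.values[: self.n_bins]

    @property
    def body(self) -> np.ndarray:
        return self.values[self.n_bins : 2 * self.n_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.values[2 * self.n_bins :]

    def to_frame(self) -> pd.DataFrame:
        region = (["upstream"] * self.n_bins + ["body"] * self.n_bins
                  + ["downstream"] * self.n_bins)
        return pd.DataFrame({
            "bin": np.arange(3 * self.n_bins), "region": region,
            "mean_level": self.values, "n_features": self.n_contributing,
        })


def body_bin_edges(start: int, end: int, n_bins: int) -> np.ndarray:
    """Bin boundaries b_j = start + round(j * L / n_bins); non-decreasing, tile the body."""
    L = end - start
    j = np.arange(n_bins + 1)
    return start + np.rint(j * L / n_bins).astype(np.int64)


def _feature_bins(start: int, end: int, flank: int, n_bins: int) -> np.ndarray:
    """All 3*n_bins+1 bin edges in genomic coordinates, upstream->downstream."""
    up = start - flank + np.arange(n_bins) * (flank // n_bins)
    body = body_bin_edges(start, end, n_bins)
    down = end + np.arange(1, n_bins + 1) * (flank // n_bins)
    return np.concatenate([up, body, down])


def metaplot(
    records: pd.DataFrame,
    features: pd.DataFrame,
    context: str,
    flank: int = 2000,
    n_bins: int = 40,
    feature_set_id: str = "features",
    pooled_counts: bool = False,
) -> MetaplotProfile:
    """Metaplot of weighted methylation across a feature set.

    ``pooled_counts=True`` pools mc/cov counts over all features per bin
    instead of averaging per-feature levels (coverage-weighted alternative).
    Features shorter than ``n_bins`` bp may yield empty body bins; these are
    missing, not errors, and contribute nothing to the mean.
    """
    if flank % n_bins != 0:
        raise ValueError("flank must be divisible by n_bins (fixed-width flank bins)")
    if len(features) == 0:
        raise ValueError("metaplot requires a non-empty feature set")
    nb3 = 3 * n_bins
    sum_levels = np.zeros(nb3)
    n_contrib = np.zeros(nb3, dtype=int)
    mc_pool = np.zeros(nb3)
    cov_pool = np.zeros(nb3)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    sub_ctx = records.loc[records["context"] == context]
    for chrom, grp in sub_ctx.groupby("chrom", sort=False):
        g = grp.sort_values("pos")
        by_chrom[chrom] = (
            g["pos"].to_numpy(np.int64), g["mc"].to_numpy(np.int64), g["cov"].to_numpy(np.int64)
        )

    for f in features.itertuples():
        data = by_chrom.get(f.chrom)
        mc_b = np.zeros(nb3)
        cov_b = np.zeros(nb3)
        if data is not None:
            pos, mc, cov = data
            edges = _feature_bins(int(f.start), int(f.end), flank, n_bins)
            idx = np.searchsorted(edges, pos, side="right") - 1
            inside = (idx >= 0) & (idx < nb3)
            idx = idx[inside]
            mc_b = np.bincount(idx, weights=mc[inside], minlength=nb3)[:nb3]
            cov_b = np.bincount(idx, weights=cov[inside], minlength=nb3)[:nb3]
        if getattr(f, "strand", "+") == "-":
            mc_b = mc_b[::-1]
            cov_b = cov_b[::-1]
        mc_pool += mc_b
        cov_pool += cov_b
        defined = cov_b > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = np.where(defined, mc_b / np.where(defined, cov_b, 1), np.nan)
        sum_levels[defined] += lev[defined]
        n_contrib[defined] += 1

    if pooled_counts:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(cov_pool > 0, mc_pool / np.where(cov_pool > 0, cov_pool, 1), np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(n_contrib > 0, sum_levels / np.where(n_contrib > 0, n_contrib, 1), np.nan)
    return MetaplotProfile(
        feature_set_id=feature_set_id, context=context, values=values,
        n_contributing=n_contrib, n_features=len(features),
        n_bins=n_bins, flank=flank,
    )


def write_profile(profile: MetaplotProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_profile(profile: MetaplotProfile, path) -> None:
    """Render the 120-bin profile to an image file (optional convenience)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    nb = profile.n_bins
    ax.plot(np.arange(3 * nb), profile.values, lw=1.5)
    ax.axvline(nb - 0.5, color="grey", ls="--", lw=0.8)
    ax.axvline(2 * nb - 0.5, color="grey", ls="--", lw=0.8)
    ax.set_xticks([nb / 2, 1.5 * nb, 2.5 * nb])
    ax.set_xticklabels([f"-{profile.flank/1000:g} kb", "body", f"+{profile.flank/1000:g} kb"])
    ax.set_ylabel(f"m{profile.context} level")
    ax.set_title(profile.feature_set_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
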