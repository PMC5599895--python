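"""Differential methylation: RMS site tests, permutation FDR, DMR collapse.

A differentially methylated site (DMS) is a cytosine whose per-sample
(methylated, total) read counts are heterogeneous across S >= 2 samples.
Heterogeneity is measured by a root-mean-square statistic on the 2 x S
observed-vs-expected frequency table and judged against a read-label
permutation null: the N pooled read calls (sum(m) ones, N - sum(m) zeros) are
randomly re-partitioned into groups of the observed per-sample coverages.
For S = 2 this null is exactly hypergeometric.

Significance is controlled by an empirical false discovery rate: each
permutation, applied across all sites, yields one fully permuted dataset;
FDR at threshold t is the mean number of null discoveries per permuted
dataset divided by the number of observed discoveries.  DMSs within a fixed
genomic distance are then collapsed into differentially methylated regions
(DMRs), which must pass context-specific minima on DMS count (CG 8, CHG 4,
CHH 4) and on the max-min spread of per-sample weighted methylation levels
(CG 0.4, CHG 0.2, CHH 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GenomicInterval
from .methylation_core import weighted_methylation

_TIE_EPS = 1e-12  # float tolerance when comparing permuted to observed statistics


@dataclass
class DmrCallConfig:
    """All tunable constants of the DMS/DMR caller (defaults are the analysis defaults)."""

    min_coverage: int = 5
    n_permutations: int = 1000
    fdr: float = 0.01
    collapse_distance: int = 100
    min_dms: dict = field(default_factory=lambda: {"CG": 8, "CHG": 4, "CHH": 4})
    min_diff: dict = field(default_factory=lambda: {"CG": 0.4, "CHG": 0.2, "CHH": 0.1})
    rng_seed: int = 1
    fdr_method: str = "empirical"  # or "bh"

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.n_permutations < 1 or self.collapse_distance < 0:
            raise ValueError("DmrCallConfig fields must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.fdr_method not in ("empirical", "bh"):
            raise ValueError("fdr_method must be 'empirical' or 'bh'")


@dataclass
class SiteMatrix:
    """Cytosine positions shared by all samples, with per-sample count matrices.

    ``mc`` and ``cov`` are (n_sites, n_samples) integer arrays aligned with
    ``chrom``/``pos``; every retained site has cov >= min_coverage in every
    sample.
    """

    chrom: np.ndarray
    pos: np.ndarray
    context: str
    mc: np.ndarray
    cov: np.ndarray
    samples: list[str]

    def __len__(self) -> int:
        return len(self.pos)


@dataclass(frozen=True)
class Dmr:
    """A differentially methylated region: clustered DMSs plus per-sample levels."""

    chrom: str
    start: int  # 0-based half-open, spanning first to last DMS inclusive
    end: int
    context: str
    dms_positions: tuple
    n_dms: int
    levels: dict

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def max_min_diff(self) -> float:
        vals = [v for v in self.levels.values() if np.isfinite(v)]
        if not vals:
            return float("nan")
        return max(vals) - min(vals)


def build_site_matrix(
    allc_by_sample: dict[str, pd.DataFrame],
    context: str,
    min_coverage: int = 5,
) -> SiteMatrix:
    """Join per-sample allc tables on (chrom, pos) for one context and apply the
    coverage rule: a site is testable only if *every* sample has >= min_coverage reads."""
    samples = list(allc_by_sample)
    if len(samples) < 2:
        raise ValueError("differential testing needs at least two samples")
    merged: pd.DataFrame | None = None
    for s in samples:
        df = allc_by_sample[s]
        sub = df.loc[df["context"] == context, ["chrom", "pos", "mc", "cov"]]
        sub = sub.rename(columns={"mc": f"mc_{s}", "cov": f"cov_{s}"})
        merged = sub if merged is None else merged.merge(sub, on=["chrom", "pos"], how="inner")
    keep = np.ones(len(merged), dtype=bool)
    for s in samples:
        keep &= merged[f"cov_{s}"].to_numpy() >= min_coverage
    merged = merged.loc[keep].sort_values(["chrom", "pos"]).reset_index(drop=True)
    mc = merged[[f"mc_{s}" for s in samples]].to_numpy(dtype=np.int64)
    cov = merged[[f"cov_{s}" for s in samples]].to_numpy(dtype=np.int64)
    return SiteMatrix(
        chrom=merged["chrom"].to_numpy(), pos=merged["pos"].to_numpy(dtype=np.int64),
        context=context, mc=mc, cov=cov, samples=samples,
    )


# ---------------------------------------------------------------------------
# RMS statistic


def rms_statistic(mc, cov) -> np.ndarray | float:
    """Root-mean-square divergence of a 2 x S count table from homogeneity.

    With N = sum(n_i), pooled rate p = sum(m_i)/N, observed table O (entries
    count/N) and expected E (E_1i = p n_i / N, E_2i = (1-p) n_i / N),

        stat = sqrt( (1/(2S)) * sum_{cells} (O - E)^2 )
             = sqrt( mean_i ((m_i - p n_i) / N)^2 )

    (the two rows contribute equal squares).  Zero iff every sample's
    methylation fraction equals the pooled rate.  Accepts 1-D (one site) or
    2-D (sites x samples) arrays; vectorized over sites.
    """
    m = np.asarray(mc, dtype=np.float64)
    n = np.asarray(cov, dtype=np.float64)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[None, :]
        n = n[None, :]
    if (n < 1).any():
        raise ValueError("rms_statistic requires every sample coverage >= 1")
    N = n.sum(axis=1, keepdims=True)
    phat = m.sum(axis=1, keepdims=True) / N
    d = (m - phat * n) / N
    out = np.sqrt(np.mean(d * d, axis=1))
    return float(out[0]) if squeeze else out


def _permuted_stats(mc: np.ndarray, cov: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null RMS statistics under read-label permutation, shape (n_perm, n_sites).

    Permuting pooled read labels into groups of sizes n_1..n_S is a sequence
    of (multivariate) hypergeometric draws, vectorized over sites and
    permutations.
    """
    n_sites, S = mc.shape
    N = cov.sum(axis=1)
    M = mc.sum(axis=1)
    phat = M / N
    remaining_good = np.broadcast_to(M, (n_perm, n_sites)).copy()
    remaining_tot = np.broadcast_to(N, (n_perm, n_sites)).copy()
    ssq = np.zeros((n_perm, n_sites))
    for i in range(S):
        n_i = cov[:, i]
        if i == S - 1:
            x = remaining_good
        else:
            nbad = remaining_tot - remaining_good
            x = rng.hypergeometric(remaining_good, nbad, np.broadcast_to(n_i, (n_perm, n_sites)))
            remaining_good = remaining_good - x
            remaining_tot = remaining_tot - n_i
        d = (x - phat * n_i) / N
        ssq += d * d
    return np.sqrt(ssq / S)


def permutation_p(mc, cov, n_permutations: int = 1000, rng_seed: int = 1) -> float:
    """Monte-Carlo permutation p-value for one site.

    p = (1 + #{perm: stat_perm >= stat_obs}) / (1 + P); the add-one keeps
    p > 0 and makes p_min = 1/(P+1).  Deterministic under a fixed seed.
    """
    m = np.asarray(mc, dtype=np.int64)[None, :]
    n = np.asarray(cov, dtype=np.int64)[None, :]
    obs = rms_statistic(m, n)[0]
    rng = np.random.default_rng(rng_seed)
    null = _permuted_stats(m, n, n_permutations, rng)[:, 0]
    exceed = int(np.sum(null >= obs - _TIE_EPS))
    return (1 + exceed) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# DMS calling with empirical FDR


def call_dms(sites: SiteMatrix, config: DmrCallConfig | None = None) -> pd.DataFrame:
    """Test every site and flag DMSs at the configured FDR.

    Returns a DataFrame (chrom, pos, stat, p, is_dms) aligned with ``sites``.

    Empirical FDR (default): permutation j applied to all sites forms one
    fully permuted dataset.  Candidate cutoffs c run over the grid of
    observed statistics and

        FDR(c) = (#{(site, perm): stat_perm >= c} / P) / #{site: stat_obs >= c},

    i.e. the mean number of discoveries per fully permuted dataset divided
    by the observed discoveries at the same cutoff.  Sites with
    stat >= c*, the smallest cutoff with FDR(c*) <= fdr, are DMSs.
    Thresholding the statistic rather than the per-site Monte-Carlo p-value
    matters: the permutation p is floored at 1/(P+1), so on a mostly-null
    genome the null discovery count at *any* p cutoff is at least
    n_sites/(P+1) and an FDR of 0.01 would be unreachable, whereas null
    exceedances of a statistic cutoff can be arbitrarily rare.
    ``fdr_method="bh"`` switches to Benjamini-Hochberg on the Monte-Carlo
    p-values.
    """
    config = config or DmrCallConfig()
    n_sites = len(sites)
    out = pd.DataFrame({"chrom": sites.chrom, "pos": sites.pos})
    if n_sites == 0:
        out["stat"] = out["p"] = out["is_dms"] = []
        return out

    P = config.n_permutations
    rng = np.random.default_rng(config.rng_seed)
    obs = rms_statistic(sites.mc, sites.cov)
    cutoffs = np.unique(obs)
    p_obs = np.empty(n_sites)
    n_null_ge = np.zeros(len(cutoffs), dtype=np.int64)

    chunk = 4096
    for lo in range(0, n_sites, chunk):
        hi = min(lo + chunk, n_sites)
        null = _permuted_stats(sites.mc[lo:hi], sites.cov[lo:hi], P, rng)  # (P, m)
        p_obs[lo:hi] = (1 + np.sum(null >= obs[lo:hi][None, :] - _TIE_EPS, axis=0)) / (1 + P)
        if config.fdr_method == "empirical":
            flat = np.sort(null.ravel())
            n_null_ge += len(flat) - np.searchsorted(flat, cutoffs - _TIE_EPS, side="left")

    out["stat"] = obs
    out["p"] = p_obs

    if config.fdr_method == "bh":
        p_adj = sps.false_discovery_control(p_obs, method="bh")
        out["is_dms"] = p_adj <= config.fdr
        return out

    obs_sorted = np.sort(obs)
    n_obs_ge = n_sites - np.searchsorted(obs_sorted, cutoffs - _TIE_EPS, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at = (n_null_ge / P) / n_obs_ge
    feasible = fdr_at <= config.fdr
    c_star = cutoffs[feasible].min() if feasible.any() else np.inf
    out["is_dms"] = obs >= c_star - _TIE_EPS
    return out


# ---------------------------------------------------------------------------
# DMR collapse


def collapse_dmrs(
    dms: pd.DataFrame,
    allc_by_sample: dict[str, pd.DataFrame],
    context: str,
    config: DmrCallConfig | None = None,
) -> list[Dmr]:
    """Collapse flagged DMSs within ``collapse_distance`` bp into DMRs and apply
    the context-specific filters.

    Greedy single pass over position-sorted DMSs per chromosome: a DMS joins
    the open cluster iff its distance to the cluster's last DMS is
    <= collapse_distance (a gap of exactly the distance still joins).  The
    cluster interval spans first to last DMS inclusive.  Clusters with fewer
    than ``min_dms[context]`` DMSs, or whose per-sample weighted methylation
    spread (max - min over samples) is below ``min_diff[context]``, are
    discarded.
    """
    config = config or DmrCallConfig()
    if "context" in dms.columns and dms["context"].nunique() > 1:
        raise ValueError("collapse_dmrs expects DMSs of a single context")
    flagged = dms.loc[dms["is_dms"]] if "is_dms" in dms.columns else dms
    flagged = flagged.sort_values(["chrom", "pos"])
    out: list[Dmr] = []
    for chrom, grp in flagged.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if len(pos) == 0:
            continue
        breaks = np.nonzero(np.diff(pos) > config.collapse_distance)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for a, b in zip(starts, ends):
            cluster = pos[a:b]
            if len(cluster) < config.min_dms[context]:
                continue
            region = GenomicInterval(str(chrom), int(cluster[0]), int(cluster[-1]) + 1)
            levels = {
                s: weighted_methylation(df, region, context).level
                for s, df in allc_by_sample.items()
            }
            dmr = Dmr(
                chrom=str(chrom), start=region.start, end=region.end, context=context,
                dms_positions=tuple(int(p) for p in cluster), n_dms=len(cluster),
                levels=levels,
            )
            if not np.isfinite(dmr.max_min_diff) or dmr.max_min_diff < config.min_diff[context]:
                continue
            out.append(dmr)
    return out


def call_dmrs(
    allc_by_sample: dict[str, pd.DataFrame],
    context: str,
    config: DmrCallConfig | None = None,
) -> tuple[list[Dmr], pd.DataFrame]:
    """End-to-end DMR calling for one context: site matrix -> DMS test -> collapse.

    Returns (DMRs, per-site DMS table)."""
    config = config or DmrCallConfig()
    sites = build_site_matrix(allc_by_sample, context, config.min_coverage)
    dms = call_dms(sites, config)
    dmrs = collapse_dmrs(dms, allc_by_sample, context, config)
    return dmrs, dms
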