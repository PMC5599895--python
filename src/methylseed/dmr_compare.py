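"""Comparisons between DMR sets and DMR classification.

Covers: merging two DMR sets into maximal non-overlapping intervals labeled
by their source sets; a coordinate-shuffle permutation test of whether two
sets overlap more than expected; endosperm-specific DMR classification and
hierarchical clustering; single-assignment genomic-feature overlap
fractions; and the replicate-consistent hypermethylation criterion used to
attribute regions to active demethylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import GenomicInterval


def _as_arrays(intervals) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(chrom, start, end) arrays from Dmr/GenomicInterval sequences or DataFrames."""
    if isinstance(intervals, pd.DataFrame):
        return (
            intervals["chrom"].to_numpy(),
            intervals["start"].to_numpy(dtype=np.int64),
            intervals["end"].to_numpy(dtype=np.int64),
        )
    chrom = np.array([iv.chrom for iv in intervals], dtype=object)
    start = np.array([iv.start for iv in intervals], dtype=np.int64)
    end = np.array([iv.end for iv in intervals], dtype=np.int64)
    return chrom, start, end


def _merge_label_counts(chrom, start, end, source) -> tuple[int, int, int, list[GenomicInterval]]:
    """Merge labeled intervals; count merged blocks containing only A, both, only B."""
    if len(start) == 0:
        return 0, 0, 0, []
    order = np.lexsort((start, chrom.astype(str)))
    chrom, start, end, source = chrom[order], start[order], end[order], source[order]
    only_a = both = only_b = 0
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = chrom[0], start[0], end[0]
    has = {0: False, 1: False}
    has[source[0]] = True
    for i in range(1, len(start)):
        if chrom[i] == cur_chrom and start[i] < cur_end:  # >= 1 bp overlap merges
            cur_end = max(cur_end, end[i])
            has[source[i]] = True
        else:
            only_a, both, only_b = _tally(has, only_a, both, only_b)
            merged.append(GenomicInterval(str(cur_chrom), int(cur_start), int(cur_end)))
            cur_chrom, cur_start, cur_end = chrom[i], start[i], end[i]
            has = {0: False, 1: False}
            has[source[i]] = True
    only_a, both, only_b = _tally(has, only_a, both, only_b)
    merged.append(GenomicInterval(str(cur_chrom), int(cur_start), int(cur_end)))
    return only_a, both, only_b, merged


def _tally(has, only_a, both, only_b):
    if has[0] and has[1]:
        return only_a, both + 1, only_b
    if has[0]:
        return only_a + 1, both, only_b
    return only_a, both, only_b + 1


@dataclass
class DmrSetComparison:
    """Counts of merged intervals by source label, plus permutation-test results."""

    only_a: int
    both: int
    only_b: int
    merged: list
    perm_p: float | None = None
    n_trials: int = 0
    degenerate: bool = False  # no shuffled configuration can exceed the observed overlap


def merge_and_classify(set_a, set_b) -> DmrSetComparison:
    """Merge two DMR sets into maximal non-overlapping intervals and label each
    merged interval by which source set(s) contribute (>= 1 bp overlap)."""
    ca, sa, ea = _as_arrays(set_a)
    cb, sb, eb = _as_arrays(set_b)
    chrom = np.concatenate([ca, cb])
    start = np.concatenate([sa, sb])
    end = np.concatenate([ea, eb])
    source = np.concatenate([np.zeros(len(sa), dtype=int), np.ones(len(sb), dtype=int)])
    only_a, both, only_b, merged = _merge_label_counts(chrom, start, end, source)
    return DmrSetComparison(only_a=only_a, both=both, only_b=only_b, merged=merged)


def _count_both(chrom_codes, start, end, source, n_chroms) -> int:
    """Number of merged intervals containing contributions from both sets (vectorized)."""
    if len(start) == 0:
        return 0
    key = chrom_codes.astype(np.int64) * (end.max() + 1)
    order = np.argsort(key + start, kind="stable")
    s, e, src, cc = start[order], end[order], source[order], chrom_codes[order]
    run_end = np.maximum.accumulate(e + cc * (end.max() + 1))
    keyed_s = s + cc * (end.max() + 1)
    new_block = np.ones(len(s), dtype=bool)
    new_block[1:] = keyed_s[1:] >= run_end[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    has_a = np.bincount(block_id, weights=(src == 0), minlength=n_blocks) > 0
    has_b = np.bincount(block_id, weights=(src == 1), minlength=n_blocks) > 0
    return int(np.sum(has_a & has_b))


def overlap_permutation_test(
    set_a,
    set_b,
    chrom_lengths: dict[str, int],
    n_trials: int = 1000,
    rng_seed: int = 1,
    pseudo_count: bool = False,
) -> DmrSetComparison:
    """Coordinate-shuffle test of overlap between two interval sets.

    Each trial independently re-places every interval of both sets uniformly
    at random on its own chromosome, preserving interval lengths and
    per-chromosome counts (shuffled intervals may overlap each other).  The
    overlap frequency is the number of merged intervals labeled "both".

        p = #{trials: shuffled frequency > observed} / n_trials   (strict >)

    ``pseudo_count=True`` reports (x + 1)/(n + 1) instead, which is bounded
    away from 0.  When set A or B is empty no shuffle can exceed the observed
    overlap and the result is flagged ``degenerate``.
    """
    ca, sa, ea = _as_arrays(set_a)
    cb, sb, eb = _as_arrays(set_b)
    chroms = sorted(chrom_lengths)
    code = {c: i for i, c in enumerate(chroms)}
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)

    def codes_of(carr):
        try:
            return np.array([code[c] for c in carr], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"interval chromosome {exc} missing from chrom_lengths") from exc

    cca, ccb = codes_of(ca), codes_of(cb)
    la, lb = ea - sa, eb - sb
    for cc, ll in ((cca, la), (ccb, lb)):
        if len(ll) and (ll > lengths[cc]).any():
            raise ValueError("interval longer than its chromosome")

    base = merge_and_classify(set_a, set_b)
    observed = base.both

    all_codes = np.concatenate([cca, ccb])
    all_len = np.concatenate([la, lb])
    source = np.concatenate([np.zeros(len(la), dtype=int), np.ones(len(lb), dtype=int)])
    max_start = lengths[all_codes] - all_len  # inclusive upper bound for shuffled starts

    rng = np.random.default_rng(rng_seed)
    exceed = 0
    degenerate = len(la) == 0 or len(lb) == 0
    for _ in range(n_trials):
        s = rng.integers(0, max_start + 1) if len(all_len) else np.empty(0, dtype=np.int64)
        e = s + all_len
        if _count_both(all_codes, s, e, source, len(chroms)) > observed:
            exceed += 1
    p = (exceed + 1) / (n_trials + 1) if pseudo_count else exceed / n_trials
    return DmrSetComparison(
        only_a=base.only_a, both=base.both, only_b=base.only_b, merged=base.merged,
        perm_p=p, n_trials=n_trials, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Endosperm-specific DMRs


@dataclass
class EndoDmr:
    """An endosperm-specific hyper-methylated region (all-context levels)."""

    interval: GenomicInterval
    levels: dict
    cluster_id: int | None = None


def classify_endo_dmrs(
    c_dmrs,
    endosperm: str = "endosperm",
    embryo: str = "embryo",
    dry_seed: str = "dry_seed",
    thresholds: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> list[EndoDmr]:
    """Select endosperm-specific hyper-DMRs from all-context (C-)DMRs.

    A DMR qualifies iff level(endosperm) - level(embryo) > t1, level(embryo)
    < t2 and level(wild-type dry seed) < t3 (defaults all 0.1).  DMRs with an
    undefined level in any of the three samples are skipped.
    """
    t_diff, t_emb, t_dry = thresholds
    out: list[EndoDmr] = []
    for d in c_dmrs:
        lv = d.levels
        trio = (lv.get(endosperm), lv.get(embryo), lv.get(dry_seed))
        if any(v is None or not np.isfinite(v) for v in trio):
            continue
        if trio[0] - trio[1] > t_diff and trio[1] < t_emb and trio[2] < t_dry:
            out.append(EndoDmr(interval=d.interval, levels=dict(lv)))
    return out


def cluster_endo_dmrs(endo: list[EndoDmr], k: int = 11, sample_order=None) -> np.ndarray:
    """Agglomerative clustering of endo-DMRs on their per-sample methylation levels.

    Euclidean distance, complete linkage, tree cut into ``k`` flat clusters.
    Assignments are attached to the EndoDmr objects (``cluster_id``) and
    returned as an integer array in 1..k.
    """
    if len(endo) < k:
        raise ValueError(f"need at least k={k} endo-DMRs, got {len(endo)}")
    if sample_order is None:
        sample_order = sorted(endo[0].levels)
    X = np.array([[e.levels[s] for s in sample_order] for e in endo], dtype=float)
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    for e, lab in zip(endo, labels):
        e.cluster_id = int(lab)
    return labels


# ---------------------------------------------------------------------------
# Feature overlap and replicate consistency


def _overlap_bp(d_start, d_end, f_start, f_end) -> int:
    return max(0, min(d_end, f_end) - max(d_start, f_start))


def feature_overlap_fractions(dmrs, features: pd.DataFrame) -> dict[str, float]:
    """Assign each DMR to exactly one genomic-feature class and return fractions.

    Class "TE" when TE-overlap bp >= gene-overlap bp > 0 or only TEs overlap;
    "gene" when gene-overlap bp exceeds TE-overlap bp; "other" when the DMR
    overlaps neither.  Fractions over {gene, TE, other} sum to 1.
    """
    counts = {"gene": 0, "TE": 0, "other": 0}
    if len(dmrs) == 0:
        return {k: float("nan") for k in counts}
    by_chrom = {c: g for c, g in features.groupby("chrom", sort=False)}
    for d in dmrs:
        sub = by_chrom.get(d.chrom)
        gene_bp = te_bp = 0
        if sub is not None:
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            ov = np.minimum(d.end, e) - np.maximum(d.start, s)
            ov = np.maximum(ov, 0)
            cls = sub["feature_class"].to_numpy()
            gene_bp = int(ov[cls == "gene"].sum())
            te_bp = int(ov[cls == "TE"].sum())
        if gene_bp == 0 and te_bp == 0:
            counts["other"] += 1
        elif te_bp >= gene_bp:
            counts["TE"] += 1
        else:
            counts["gene"] += 1
    n = len(dmrs)
    return {k: v / n for k, v in counts.items()}


def replicate_consistent_hyper(
    dmrs,
    mutant_levels: dict[str, dict[int, float]],
    wildtype_levels: dict[str, dict[int, float]],
    threshold: float = 0.2,
) -> tuple[int, int, float]:
    """Fraction of DMRs whose mutant-minus-wild-type level difference exceeds
    ``threshold`` in *every* replicate.

    ``mutant_levels`` / ``wildtype_levels`` map replicate name -> {dmr index
    -> weighted level}.  DMRs with an undefined level in any replicate are
    excluded from the denominator (the count of exclusions is implicit in the
    returned denominator).  Returns (count, denominator, fraction).
    """
    reps = sorted(mutant_levels)
    if sorted(wildtype_levels) != reps:
        raise ValueError("mutant and wild-type replicate names must match")
    count = denom = 0
    for i in range(len(dmrs)):
        diffs = []
        ok = True
        for r in reps:
            mu = mutant_levels[r].get(i)
            wt = wildtype_levels[r].get(i)
            if mu is None or wt is None or not (np.isfinite(mu) and np.isfinite(wt)):
                ok = False
                break
            diffs.append(mu - wt)
        if not ok:
            continue
        denom += 1
        if all(d > threshold for d in diffs):
            count += 1
    frac = count / denom if denom else float("nan")
    return count, denom, frac
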