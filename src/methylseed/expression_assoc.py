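"""Expression filtering/clustering, DMR-gene association, and cluster enrichment.

Genes are "expressed" when FPKM > 1 in at least one sample; expressed genes
are k-means clustered on log2(FPKM + 1) profiles.  A gene and a DMR are
associated when the DMR lies within the gene body or within 2 kb of either
gene end, keeping only mutually closest pairs (exact distance ties keep all
tied pairs).  Enrichment of DMR-associated genes within an expression
cluster is scored by fold enrichment and a one-sided (greater) Fisher's
exact test against all expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans


def expressed_genes(table: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes with FPKM strictly greater than ``threshold`` in >= 1 sample."""
    if table.empty:
        return table.index[:0]
    mask = (table > threshold).any(axis=1)
    return table.index[mask]


def cluster_expression(
    table: pd.DataFrame,
    k: int = 10,
    max_iter: int = 20,
    rng_seed: int = 1,
    n_restarts: int = 10,
) -> pd.Series:
    """k-means clustering of genes on log2(FPKM + 1) expression profiles.

    ``n_restarts`` runs keep the best within-cluster sum of squares
    (restarts=1 reproduces a single-run configuration).  Labels are arbitrary
    integers 0..k-1, stable under the seed.
    """
    if len(table) < k:
        raise ValueError(f"need >= k={k} genes to cluster, got {len(table)}")
    X = np.log2(table.to_numpy(dtype=float) + 1.0)
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter, random_state=rng_seed)
    labels = km.fit_predict(X)
    return pd.Series(labels, index=table.index, name="cluster")


@dataclass(frozen=True)
class GeneDmrAssociation:
    gene_id: str
    dmr_index: int
    chrom: str
    dmr_start: int
    dmr_end: int
    distance: int  # bp gap to the nearer gene edge; 0 when overlapping the body


def associate_dmrs_to_genes(dmrs, genes: pd.DataFrame, window: int = 2000) -> list[GeneDmrAssociation]:
    """Associate DMRs with proximal genes (gene body or within ``window`` bp).

    Candidate pairs are (gene, DMR) with the DMR overlapping
    [gene_start - window, gene_end + window); distance is 0 for body overlap,
    else the bp gap to the nearer gene edge.  Only mutually closest pairs are
    kept: each DMR retains its minimum-distance gene(s) and each gene its
    minimum-distance DMR(s); exact ties keep every tied pair.
    """
    cand: list[GeneDmrAssociation] = []
    genes_by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}
    for di, d in enumerate(dmrs):
        sub = genes_by_chrom.get(d.chrom)
        if sub is None:
            continue
        gs = sub["start"].to_numpy(np.int64)
        ge = sub["end"].to_numpy(np.int64)
        ids = sub["id"].to_numpy()
        near = (d.start < ge + window) & (d.end > gs - window)
        for j in np.nonzero(near)[0]:
            if d.start < ge[j] and d.end > gs[j]:
                dist = 0
            elif d.end <= gs[j]:
                dist = int(gs[j] - d.end)
            else:
                dist = int(d.start - ge[j])
            if dist > window:
                continue
            cand.append(GeneDmrAssociation(
                gene_id=str(ids[j]), dmr_index=di, chrom=d.chrom,
                dmr_start=d.start, dmr_end=d.end, distance=dist,
            ))
    if not cand:
        return []
    df = pd.DataFrame([(a.gene_id, a.dmr_index, a.distance) for a in cand],
                      columns=["gene_id", "dmr_index", "distance"])
    min_by_dmr = df.groupby("dmr_index")["distance"].transform("min")
    min_by_gene = df.groupby("gene_id")["distance"].transform("min")
    keep = (df["distance"] == min_by_dmr) & (df["distance"] == min_by_gene)
    return [a for a, k in zip(cand, keep) if k]


def associations_to_frame(assoc: list[GeneDmrAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.gene_id, a.chrom, a.dmr_start, a.dmr_end, a.distance) for a in assoc],
        columns=["gene_id", "chrom", "dmr_start", "dmr_end", "distance"],
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of DMR-associated genes within one expression cluster.

    fold_enrichment = (k/n) / (K/N) with k associated genes in the cluster of
    size n, against K associated among all N expressed genes; p is a
    one-sided (greater) Fisher's exact test on the 2x2 table
    [cluster vs non-cluster] x [associated vs not].
    """

    cluster_id: int | str
    k_assoc: int
    n_cluster: int
    K_assoc_all: int
    N_all: int
    fold_enrichment: float
    p_one_sided: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.fold_enrichment)


def cluster_enrichment(
    cluster_genes,
    associated_genes,
    expressed,
    cluster_id: int | str = 0,
) -> EnrichmentResult:
    """Fold enrichment and one-sided Fisher p for one cluster vs all expressed genes."""
    expressed = set(expressed)
    cluster = set(cluster_genes) & expressed
    assoc = set(associated_genes) & expressed
    n = len(cluster)
    N = len(expressed)
    k = len(cluster & assoc)
    K = len(assoc)
    if n == 0 or K == 0:
        return EnrichmentResult(cluster_id, k, n, K, N, float("nan"), float("nan"))
    fold = (k / n) / (K / N)
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    _, p = sps.fisher_exact(table, alternative="greater")
    return EnrichmentResult(cluster_id, k, n, K, N, fold, float(p))


def enrichment_from_counts(k: int, n: int, K: int, N: int, cluster_id=0) -> EnrichmentResult:
    """Enrichment computed directly from the four counts (no gene sets needed)."""
    if n == 0 or K == 0:
        return EnrichmentResult(cluster_id, k, n, K, N, float("nan"), float("nan"))
    fold = (k / n) / (K / N)
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    _, p = sps.fisher_exact(table, alternative="greater")
    return EnrichmentResult(cluster_id, k, n, K, N, fold, float(p))
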