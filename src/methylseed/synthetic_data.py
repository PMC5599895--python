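"""Synthetic bisulfite methylomes with planted ground truth.

Emulates the data structure of a seed development / germination methylome
study: multi-sample per-cytosine count tables with context-specific
background methylation, transposable elements that are either short and
edge-methylated (RdDM-like) or long and body-methylated (CMT2-like),
planted differentially methylated regions with known per-sample rates, an
unmethylated control chromosome for the bisulfite non-conversion rate, and
a gene-by-sample FPKM table with planted expression clusters and
DMR-associated genes.

Observed counts at a site are Binomial(depth, p_eff) with depth per site and
sample drawn Poisson(coverage) and p_eff = p_true + (1 - p_true) * ncr where
ncr is the non-conversion rate, so even truly unmethylated sites show a
small apparent methylation signal.  Everything is reproducible
byte-identically under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ALLC_COLUMNS

_TRI_BY_CONTEXT = {
    "CG": ["CGA", "CGT", "CGC", "CGG"],
    "CHG": ["CAG", "CTG", "CCG"],
    "CHH": ["CAA", "CAT", "CTA", "CTT", "CCA", "CTC"],
}


@dataclass(frozen=True)
class TeModel:
    """One class of transposable elements with stage-dependent CHH methylation."""

    te_class: str  # "RdDM" (short, edge-methylated) or "CMT2" (long, body-methylated)
    n: int
    length_range: tuple[int, int]
    edge_width: int
    body_mchh: dict  # sample -> true CHH rate within the body interior
    edge_mchh: dict  # sample -> true CHH rate within edge_width of either end


@dataclass(frozen=True)
class PlantedDmr:
    """Specification of one planted DMR: context, site layout, per-sample rates."""

    context: str
    n_sites: int
    width: int
    rates: dict  # sample -> true methylation rate inside the DMR


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the germination study conditions.

    Samples follow a dry seed through imbibition: a slight gain of CHH
    methylation during stratification (day 0) followed by passive dilution
    (halving per day) over four days of germination, on a background of
    stable CG/CHG methylation.  Densities are cytosines per bp (both strands
    pooled); coverage is the mean Poisson read depth per site per sample.
    """

    rng_seed: int = 1
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    densities: dict = field(default_factory=lambda: {"CG": 0.02, "CHG": 0.02, "CHH": 0.08})
    coverage: float = 10.0
    nonconversion_rate: float = 0.005
    samples: tuple = ("dry", "dai0", "dai1", "dai2", "dai3", "dai4")
    background: dict = field(default_factory=lambda: {
        "CG": {s: 0.24 for s in ("dry", "dai0", "dai1", "dai2", "dai3", "dai4")},
        "CHG": {s: 0.07 for s in ("dry", "dai0", "dai1", "dai2", "dai3", "dai4")},
        # stratification gain then passive halving per day
        "CHH": {"dry": 0.03, "dai0": 0.035, "dai1": 0.0175,
                "dai2": 0.00875, "dai3": 0.0044, "dai4": 0.0022},
    })
    te_models: tuple = ()
    planted_dmrs: tuple = ()
    control_chrom: str = "ChrC"
    control_length: int = 20_000
    cg_pairs: bool = False  # emit CG sites as symmetric dyads (two strand records)
    expression: "ExpressionModel | None" = None

    def __post_init__(self) -> None:
        if not 0 <= self.nonconversion_rate <= 1:
            raise ValueError("nonconversion_rate must lie in [0, 1]")
        for ctx, per_sample in self.background.items():
            for s, r in per_sample.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"background rate {ctx}/{s}={r} outside [0, 1]")
        for d in self.planted_dmrs:
            if d.width >= self.chrom_length:
                raise ValueError("planted DMR wider than the chromosome")


@dataclass(frozen=True)
class ExpressionModel:
    """Cluster archetypes for the synthetic FPKM table.

    ``archetypes`` is (k, n_timepoints) mean log2(FPKM+1) profiles; clusters
    listed in ``induced`` are germination-induced.  ``assoc_induced`` /
    ``assoc_background`` are the fractions of genes near a planted DMR in
    induced vs other clusters.
    """

    archetypes: tuple
    genes_per_cluster: int = 50
    noise_sd: float = 0.5
    induced: tuple = ()
    assoc_induced: float = 0.5
    assoc_background: float = 0.2


def default_expression_model(n_timepoints: int = 4) -> ExpressionModel:
    """Ten archetypes over the germination timepoints; clusters 4 and 8 induced."""
    t = np.linspace(0, 1, n_timepoints)
    arch = [
        2 + 0 * t, 5 + 0 * t, 8 + 0 * t,          # flat low / mid / high
        6 - 4 * t, 8 - 6 * t,                     # repressed
        1 + 5 * t,                                # induced (cluster 4... index order)
        4 + 2 * np.sin(np.pi * t),                # transient
        3 + 0 * t,
        0.5 + 6 * t,                              # induced
        7 - 2 * t,
    ]
    return ExpressionModel(
        archetypes=tuple(tuple(a) for a in arch),
        induced=(5, 8),
    )


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the generator's planted signal."""

    planted_dmrs: pd.DataFrame  # chrom,start,end,context + rate_<sample> columns
    tes: pd.DataFrame           # chrom,start,end,id,strand,feature_class,te_class
    genes: pd.DataFrame         # chrom,start,end,id,strand,feature_class (may be empty)
    site_rates: pd.DataFrame    # chrom,pos,context + rate_<sample> columns
    config: SyntheticConfig


def germination_preset(**overrides) -> SyntheticConfig:
    """Germination series with RdDM-like and CMT2-like TEs ("passive dilution")."""
    samples = ("dry", "dai0", "dai1", "dai2", "dai3", "dai4")
    hi = {"dry": 0.4, "dai0": 0.45, "dai1": 0.25, "dai2": 0.15, "dai3": 0.08, "dai4": 0.05}
    mid = {"dry": 0.25, "dai0": 0.28, "dai1": 0.15, "dai2": 0.09, "dai3": 0.05, "dai4": 0.03}
    lo = {s: 0.03 for s in samples}
    te_models = (
        TeModel("RdDM", n=40, length_range=(300, 800), edge_width=150,
                body_mchh=mid, edge_mchh=hi),
        TeModel("CMT2", n=15, length_range=(3000, 6000), edge_width=300,
                body_mchh=hi, edge_mchh=mid),
    )
    del lo, samples  # interiors outside TEs follow the config background rates
    cfg = SyntheticConfig(chrom_length=3_000_000, te_models=te_models,
                          expression=default_expression_model())
    return replace(cfg, **overrides) if overrides else cfg


def seed_development_preset(**overrides) -> SyntheticConfig:
    """Seed development series: progressive genome-wide CHH gain toward the dry seed."""
    samples = ("globular", "linear_cot", "mature", "post_mature", "dry")
    chh = {"globular": 0.01, "linear_cot": 0.01, "mature": 0.015,
           "post_mature": 0.022, "dry": 0.03}
    gain_hi = {"globular": 0.05, "linear_cot": 0.1, "mature": 0.2,
               "post_mature": 0.32, "dry": 0.4}
    gain_mid = {"globular": 0.03, "linear_cot": 0.06, "mature": 0.12,
                "post_mature": 0.2, "dry": 0.25}
    te_models = (
        TeModel("RdDM", n=40, length_range=(300, 800), edge_width=150,
                body_mchh=gain_mid, edge_mchh=gain_hi),
        TeModel("CMT2", n=15, length_range=(3000, 6000), edge_width=300,
                body_mchh=gain_hi, edge_mchh=gain_mid),
    )
    cfg = SyntheticConfig(
        samples=samples,
        chrom_length=3_000_000,
        background={
            "CG": {s: 0.24 for s in samples},
            "CHG": {s: 0.07 for s in samples},
            "CHH": chh,
        },
        te_models=te_models,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------


def _place_nonoverlapping(rng, chrom_length, lengths, reserved, margin=0):
    """Place intervals of the given lengths uniformly without overlapping
    ``reserved`` (list of (start, end), mutated in place).  Rejection sampling."""
    out = []
    for L in lengths:
        for _ in range(1000):
            s = int(rng.integers(margin, chrom_length - L - margin))
            e = s + L
            if all(e <= rs or s >= re for rs, re in reserved):
                reserved.append((s, e))
                out.append((s, e))
                break
        else:
            raise RuntimeError("could not place interval; chromosome too crowded")
    return out


def _random_tris(rng, context, n):
    opts = _TRI_BY_CONTEXT[context]
    return np.array(opts, dtype=object)[rng.integers(0, len(opts), n)]


def generate_methylomes(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate per-sample allc tables plus the ground truth.

    Returns (allc tables keyed by sample name, SyntheticTruth).  Output is a
    pure function of the config (including its seed).
    """
    rng = np.random.default_rng(config.rng_seed)
    samples = list(config.samples)
    chrom_names = [f"Chr{i+1}" for i in range(config.n_chroms)]

    te_rows, dmr_rows, gene_rows = [], [], []
    site_frames = []

    for chrom in chrom_names:
        reserved: list[tuple[int, int]] = []

        # --- transposable elements
        chrom_tes = []
        for model in config.te_models:
            lens = rng.integers(model.length_range[0], model.length_range[1] + 1, model.n)
            placed = _place_nonoverlapping(rng, config.chrom_length, lens, reserved, margin=2500)
            for s, e in placed:
                strand = "+" if rng.random() < 0.5 else "-"
                chrom_tes.append((s, e, model, strand))
                te_rows.append((chrom, s, e, f"TE_{chrom}_{len(te_rows)}", strand, "TE", model.te_class))

        # --- planted DMRs (forced cytosine layout: near-even spacing with jitter)
        forced_sites = {ctx: [] for ctx in _TRI_BY_CONTEXT}
        for spec in config.planted_dmrs:
            (s, e), = _place_nonoverlapping(rng, config.chrom_length, [spec.width], reserved, margin=2500)
            dmr_rows.append((chrom, s, e, spec.context,
                             tuple(spec.rates.get(sm, np.nan) for sm in samples)))
            if spec.n_sites == 1:
                pts = np.array([s + spec.width // 2])
            else:
                step = spec.width / (spec.n_sites - 1 + 1e-9)
                jitter = rng.integers(-int(step // 4) or 0, int(step // 4) + 1, spec.n_sites)
                pts = np.clip(np.rint(s + np.arange(spec.n_sites) * step).astype(int) + jitter, s, e - 1)
                pts = np.unique(pts)
            rates = np.array([spec.rates.get(sm, np.nan) for sm in samples], dtype=float)
            forced_sites[spec.context].append((pts, rates))

        # --- background cytosines; forced (planted) sites listed first so they
        # win position-collision deduplication
        parts = []
        for ctx, forced in forced_sites.items():
            for pts, rates in forced:
                parts.append((ctx, pts, np.tile(rates, (len(pts), 1)), True))
        for ctx, dens in config.densities.items():
            n_sites = rng.poisson(dens * config.chrom_length)
            pos = np.sort(rng.choice(config.chrom_length, size=min(n_sites, config.chrom_length), replace=False))
            rate = np.tile([config.background[ctx][sm] for sm in samples], (len(pos), 1)).astype(float)
            parts.append((ctx, pos, rate, False))

        # assemble and apply TE overrides to non-forced CHH sites
        ctx_arr = np.concatenate([np.repeat(ctx, len(p)) for ctx, p, _, _ in parts])
        pos_arr = np.concatenate([p for _, p, _, _ in parts])
        rate_arr = np.vstack([r for _, _, r, _ in parts])
        forced_arr = np.concatenate([np.repeat(f, len(p)) for _, p, _, f in parts])

        order = np.argsort(pos_arr, kind="stable")
        ctx_arr, pos_arr, rate_arr, forced_arr = (
            ctx_arr[order], pos_arr[order], rate_arr[order], forced_arr[order])
        uniq, first = np.unique(pos_arr, return_index=True)
        ctx_arr, pos_arr, rate_arr, forced_arr = (
            ctx_arr[first], pos_arr[first], rate_arr[first], forced_arr[first])

        # planted intervals contain exactly their forced site layout: background
        # cytosines of the same context inside the interval are removed
        drop = np.zeros(len(pos_arr), dtype=bool)
        for c, s, e, spec_ctx, _r in dmr_rows:
            if c == chrom:
                drop |= (pos_arr >= s) & (pos_arr < e) & (ctx_arr == spec_ctx) & ~forced_arr
        if drop.any():
            keepm = ~drop
            ctx_arr, pos_arr, rate_arr, forced_arr = (
                ctx_arr[keepm], pos_arr[keepm], rate_arr[keepm], forced_arr[keepm])

        for s, e, model, _strand in chrom_tes:
            inside = (pos_arr >= s) & (pos_arr < e) & (ctx_arr == "CHH") & ~forced_arr
            edge = inside & ((pos_arr < s + model.edge_width) | (pos_arr >= e - model.edge_width))
            body = inside & ~edge
            rate_arr[body] = [model.body_mchh[sm] for sm in samples]
            rate_arr[edge] = [model.edge_mchh[sm] for sm in samples]

        frame = pd.DataFrame({"chrom": chrom, "pos": pos_arr, "context": ctx_arr})
        for i, sm in enumerate(samples):
            frame[f"rate_{sm}"] = rate_arr[:, i]
        site_frames.append(frame)

        # --- genes fill remaining space (used by expression/association tests)
        if config.expression is not None:
            n_genes = len(config.expression.archetypes) * config.expression.genes_per_cluster
            lens = rng.integers(800, 3000, n_genes)
            placed = _place_nonoverlapping(rng, config.chrom_length, lens, reserved, margin=2500)
            for s, e in placed:
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((chrom, s, e, f"gene_{len(gene_rows)}", strand, "gene"))

    # --- control chromosome: truly unmethylated
    n_ctrl = rng.poisson(sum(config.densities.values()) * config.control_length)
    ctrl_pos = np.sort(rng.choice(config.control_length, size=min(n_ctrl, config.control_length), replace=False))
    ctrl_ctx = np.array(["CHH"] * len(ctrl_pos), dtype=object)
    ctrl_frame = pd.DataFrame({"chrom": config.control_chrom, "pos": ctrl_pos, "context": ctrl_ctx})
    for sm in samples:
        ctrl_frame[f"rate_{sm}"] = 0.0
    site_frames.append(ctrl_frame)

    sites = pd.concat(site_frames, ignore_index=True)

    # --- read sampling
    allc_by_sample: dict[str, pd.DataFrame] = {}
    strand_choice = np.where(rng.random(len(sites)) < 0.5, "+", "-")
    tris = np.empty(len(sites), dtype=object)
    for ctx in _TRI_BY_CONTEXT:
        m = (sites["context"] == ctx).to_numpy()
        tris[m] = _random_tris(rng, ctx, int(m.sum()))
    ncr = config.nonconversion_rate
    for sm in samples:
        p_true = sites[f"rate_{sm}"].to_numpy(dtype=float)
        p_eff = p_true + (1.0 - p_true) * ncr
        depth = rng.poisson(config.coverage, len(sites))
        mc = rng.binomial(depth, p_eff)
        df = pd.DataFrame({
            "chrom": sites["chrom"], "pos": sites["pos"].astype(np.int64),
            "strand": strand_choice, "tri": tris, "context": sites["context"],
            "mc": mc, "cov": depth, "low_cov": depth < 1,
        })
        df = df[df["cov"] > 0].reset_index(drop=True)
        allc_by_sample[sm] = df[ALLC_COLUMNS]

    dmr_df = pd.DataFrame(
        [(c, s, e, ctx, *r) for c, s, e, ctx, r in dmr_rows],
        columns=["chrom", "start", "end", "context"] + [f"rate_{sm}" for sm in samples],
    )
    te_df = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "id", "strand", "feature_class", "te_class"])
    gene_df = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "id", "strand", "feature_class"])
    truth = SyntheticTruth(planted_dmrs=dmr_df, tes=te_df, genes=gene_df,
                           site_rates=sites, config=config)
    return allc_by_sample, truth


def generate_expression(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Synthetic FPKM table from the config's cluster archetypes.

    Returns (table, true cluster labels per gene, DMR-association flags per
    gene, planted DMR intervals used for the associations).  FPKM is
    2**(archetype + Gaussian noise) - 1 floored at 0; a configured fraction
    of genes in induced clusters (vs a background fraction elsewhere)
    receives a planted DMR within 2 kb of the gene.
    """
    model = config.expression
    if model is None:
        raise ValueError("config.expression is not set")
    rng = np.random.default_rng(config.rng_seed + 104729)  # independent stream
    genes = truth.genes
    arch = np.asarray(model.archetypes, dtype=float)
    k, n_t = arch.shape
    n_genes = len(genes)
    if n_genes == 0:
        empty = pd.DataFrame(columns=[f"t{j}" for j in range(n_t)])
        return empty, pd.Series(dtype=int), pd.Series(dtype=bool), pd.DataFrame()
    labels = np.repeat(np.arange(k), model.genes_per_cluster)[:n_genes]
    if len(labels) < n_genes:
        labels = np.concatenate([labels, rng.integers(0, k, n_genes - len(labels))])
    noise = rng.normal(0.0, model.noise_sd, (n_genes, n_t))
    log2v = arch[labels] + noise
    fpkm = np.maximum(np.exp2(log2v) - 1.0, 0.0)
    table = pd.DataFrame(fpkm, index=genes["id"].to_numpy(), columns=[f"t{j}" for j in range(n_t)])

    induced = set(model.induced)
    frac = np.where(np.isin(labels, list(induced)), model.assoc_induced, model.assoc_background)
    flagged = rng.random(n_genes) < frac
    dmr_rows = []
    for gi in np.nonzero(flagged)[0]:
        g = genes.iloc[gi]
        width = int(rng.integers(100, 400))
        gap = int(rng.integers(0, 1500))
        start = max(0, int(g.start) - gap - width)
        dmr_rows.append((g.chrom, start, start + width))
    dmr_df = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end"])
    return (
        table,
        pd.Series(labels, index=table.index, name="true_cluster"),
        pd.Series(flagged, index=table.index, name="dmr_associated"),
        dmr_df,
    )
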