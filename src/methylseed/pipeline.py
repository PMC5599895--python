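"""End-to-end orchestration of the methylome analyses.

A pipeline run is a pure function of (input files, config, seed): QC
(per-sample non-conversion rate) -> DMS/DMR calling per context ->
comparisons -> chromosome bins and TE metaplots -> gene association and
cluster enrichment.  Every output directory carries a metadata file with the
config hash and seed; a stage whose config hash matches an existing
completed run is skipped (light content-hash caching, since the permutation
stages dominate runtime).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io_formats
from .metaplot import metaplot as compute_metaplot, write_profile
from .dmr_calling import DmrCallConfig, call_dmrs
from .dmr_compare import overlap_permutation_test
from .expression_assoc import (
    associate_dmrs_to_genes,
    associations_to_frame,
    cluster_enrichment,
    cluster_expression,
    expressed_genes,
)
from .methylation_core import chromosome_bins, nonconversion_rate

logger = logging.getLogger(__name__)

ANALYSES = ("sdev", "germin", "endo", "custom")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: dict) -> None:
    if config.get("analysis", "custom") not in ANALYSES:
        raise PipelineError("validate", f"unknown analysis {config.get('analysis')!r}")
    samples = config.get("samples")
    if not samples:
        raise PipelineError("validate", "config must list samples")
    for s in samples:
        if "name" not in s or "allc" not in s:
            raise PipelineError("validate", f"sample entry missing name/allc: {s}")
        if not Path(s["allc"]).exists():
            raise PipelineError("validate", f"allc path does not exist: {s['allc']}")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured analysis; returns a result-bundle summary dict.

    Output files: per-context DMR tables, a DMS summary, non-conversion QC,
    100-kb bin profiles, TE metaplots (when annotations are given), gene
    associations and per-cluster enrichment (when expression is given), and
    run metadata with the config hash and seed.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    meta_path = out / "run_metadata.json"
    if meta_path.exists():
        old = json.loads(meta_path.read_text())
        if old.get("config_hash") == chash and old.get("complete"):
            logger.info("config hash %s already complete in %s; skipping", chash, out)
            return old

    seed = int(config.get("seed", 1))
    meta = {"config_hash": chash, "seed": seed, "complete": False,
            "analysis": config.get("analysis", "custom")}
    meta_path.write_text(json.dumps(meta, indent=2))

    call_cfg = DmrCallConfig(
        min_coverage=int(config.get("min_coverage", 5)),
        n_permutations=int(config.get("n_permutations", 1000)),
        fdr=float(config.get("fdr", 0.01)),
        collapse_distance=int(config.get("collapse_distance", 100)),
        rng_seed=seed,
    )

    # --- load
    stage = "load"
    try:
        allc = {s["name"]: io_formats.read_allc(s["allc"], min_total=call_cfg.min_coverage)
                for s in config["samples"]}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    summary: dict = dict(meta)

    # --- QC: non-conversion rate per sample
    control = config.get("control_chrom")
    if control:
        qc = {}
        for name, df in allc.items():
            try:
                qc[name] = nonconversion_rate(df, control)
            except ValueError:
                qc[name] = None
            logger.info("QC non-conversion %s: %s", name, qc[name])
        pd.Series(qc, name="nonconversion_rate").to_csv(out / "qc_nonconversion.tsv", sep="\t")
        summary["nonconversion"] = qc
        # the control chromosome takes no part in differential testing
        allc = {k: v[v["chrom"] != control].reset_index(drop=True) for k, v in allc.items()}

    # --- DMR calling per context
    contexts = config.get("contexts", ["CG", "CHG", "CHH"])
    dmrs_by_context = {}
    for ctx in contexts:
        stage = f"call-dmr:{ctx}"
        try:
            dmrs, dms = call_dmrs(allc, ctx, call_cfg)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        logger.info("%s: %d sites tested, %d DMSs, %d DMRs",
                    ctx, len(dms), int(dms["is_dms"].sum()) if len(dms) else 0, len(dmrs))
        io_formats.write_dmr_table(dmrs, out / f"dmrs_{ctx}.tsv", sample_names=list(allc))
        dms.to_csv(out / f"dms_{ctx}.tsv", sep="\t", index=False)
        dmrs_by_context[ctx] = dmrs
        summary[f"n_dmrs_{ctx}"] = len(dmrs)
        summary[f"n_dms_{ctx}"] = int(dms["is_dms"].sum()) if len(dms) else 0

    # --- comparison of two called contexts against each other is not meaningful;
    # compare against a second DMR table when configured
    cmp_cfg = config.get("compare")
    if cmp_cfg:
        stage = "compare"
        try:
            other = io_formats.read_dmr_table(cmp_cfg["dmr_table"])
            ctx = cmp_cfg.get("context", "CHH")
            chrom_lengths = {k: int(v) for k, v in config["chrom_lengths"].items()}
            res = overlap_permutation_test(
                dmrs_by_context[ctx], other, chrom_lengths,
                n_trials=int(cmp_cfg.get("n_trials", 1000)), rng_seed=seed,
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        summary["compare"] = {"only_a": res.only_a, "both": res.both,
                              "only_b": res.only_b, "perm_p": res.perm_p}
        (out / "comparison.json").write_text(json.dumps(summary["compare"], indent=2))

    # --- bins and metaplots
    if config.get("chrom_lengths"):
        stage = "bins"
        chrom_lengths = {k: int(v) for k, v in config["chrom_lengths"].items()}
        first = next(iter(allc))
        for ctx in contexts:
            bins = chromosome_bins(allc[first], chrom_lengths, context=ctx)
            bins.to_csv(out / f"bins100kb_{first}_{ctx}.tsv", sep="\t", index=False)
    if config.get("te_bed"):
        stage = "metaplot"
        try:
            tes = io_formats.read_features(config["te_bed"], "BED", "TE")
            if len(tes):
                first = next(iter(allc))
                prof = compute_metaplot(allc[first], tes, "CHH", feature_set_id="TEs")
                write_profile(prof, out / f"metaplot_TE_CHH_{first}.tsv")
            else:
                logger.warning("metaplot: no TE features in %s; skipped", config["te_bed"])
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # --- expression association / enrichment
    if config.get("expression_tsv") and config.get("gene_bed"):
        stage = "associate"
        try:
            genes = io_formats.read_features(config["gene_bed"], "BED", "gene")
            expr = io_formats.read_expression(config["expression_tsv"])
            ctx = config.get("assoc_context", "CHH")
            assoc = associate_dmrs_to_genes(dmrs_by_context[ctx], genes)
            associations_to_frame(assoc).to_csv(out / "gene_dmr_associations.tsv", sep="\t", index=False)
            expr_genes = expressed_genes(expr)
            k = int(config.get("expression_clusters", 10))
            if len(expr_genes) >= k:
                labels = cluster_expression(expr.loc[expr_genes], k=k, rng_seed=seed)
                labels.to_csv(out / "expression_clusters.tsv", sep="\t")
                assoc_ids = {a.gene_id for a in assoc}
                rows = []
                for cid in range(k):
                    res = cluster_enrichment(labels.index[labels == cid], assoc_ids,
                                             expr_genes, cluster_id=cid)
                    rows.append((cid, res.k_assoc, res.n_cluster, res.K_assoc_all,
                                 res.N_all, res.fold_enrichment, res.p_one_sided))
                pd.DataFrame(rows, columns=["cluster", "k", "n", "K", "N", "fold", "p"]).to_csv(
                    out / "cluster_enrichment.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    meta["complete"] = True
    summary["complete"] = True
    meta_path.write_text(json.dumps(meta, indent=2))
    return summary
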