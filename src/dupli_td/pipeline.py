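"""End-to-end orchestration: simulate -> DE -> TD analysis -> growth -> ORA.

A single :class:`PipelineConfig` (loadable from YAML) drives every stage with
explicit seeds; :func:`run_pipeline` writes all stage outputs plus a summary
report into an output directory and returns the in-memory results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .dge import CountMatrix, NBExpressionModel
from .errors import ConfigurationError
from .growth import fit_od_table, generations_from_bottleneck
from .ora import hypergeometric_ora
from .simulate import (
    SimConfig,
    default_design,
    simulate_annotation_map,
    simulate_catalog,
    simulate_counts,
    simulate_growth_curves,
)
from .td import (
    binomial_td_enrichment,
    category_count_null,
    classify_pair_category,
    fisher_enrichment,
    overlap_summary,
    pair_expression,
    plasticity_td_correlation,
    resampling_null_mean,
    td_table,
    td_threshold_sweep,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "analyze_timepoint"]


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the pipeline in one place.

    Thresholds default to the analysis' standard values: TD threshold
    tau = 1.25, DE fold change 1.25, BY FDR 0.005, ORA BH cutoff 0.01.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    tau: float = 1.25
    fc_threshold: float = 1.25
    fdr_threshold: float = 0.005
    fdr_method: str = "BY"
    ora_cutoff: float = 0.01
    n_iter: int = 10_000
    resample_seed: int = 2024
    timepoints: tuple[str, ...] = ("t0", "t100", "t110")
    background_medium: str = "YPD"
    growth: dict = field(
        default_factory=lambda: {"K": 1.2, "r": 0.3, "N0": 0.05, "noise_sd": 0.01, "n_wells": 3}
    )

    def validate(self) -> None:
        self.sim.validate()
        for name in ("tau", "fc_threshold", "fdr_threshold", "ora_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["timepoints"] = list(self.timepoints)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def analyze_timepoint(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pairs: pd.DataFrame,
    de_result,
    timepoint: str,
    cfg: PipelineConfig,
) -> dict:
    """TD analysis for one timepoint: TD table, categories, enrichments, nulls."""
    calls = de_result.table["call"]
    expr = pair_expression(counts, design, pairs, background=(timepoint, cfg.background_medium))
    tdt = td_table(expr, tau=cfg.tau)
    defined = tdt[np.isfinite(tdt["td_ratio"])]

    tdt = tdt.copy()
    tdt["call_a"] = calls.reindex(tdt["gene_a"]).fillna("unchanged").to_numpy()
    tdt["call_b"] = calls.reindex(tdt["gene_b"]).fillna("unchanged").to_numpy()
    tdt["category"] = [
        classify_pair_category(a, b) for a, b in zip(tdt["call_a"], tdt["call_b"])
    ]

    n_pairs = len(defined)
    n_td = int(defined["is_td"].sum())
    results = {"td_table": tdt, "n_pairs_defined": n_pairs, "n_td_pairs": n_td}

    # gene-level TD membership for the binomial enrichment
    gene_td = {}
    for _, row in defined.iterrows():
        gene_td[row["gene_a"]] = gene_td[row["gene_b"]] = bool(row["is_td"])
    enrich = {}
    for direction in ("up", "down"):
        responders = [g for g in gene_td if calls.get(g) == direction]
        n = len(responders)
        k = sum(gene_td[g] for g in responders)
        p0 = n_td / n_pairs if n_pairs else float("nan")
        if n > 0 and 0 < p0 < 1:
            enrich[direction] = binomial_td_enrichment(k, n, p0, alternative="greater")
        else:
            enrich[direction] = None
    results["binomial_enrichment"] = enrich

    # resampling null of the mean |lfc| of TD up-responders against TD pool
    lfc = de_result.table["lfc"]
    td_genes = [g for g, flag in gene_td.items() if flag]
    up_td = [g for g in td_genes if calls.get(g) == "up"]
    if len(up_td) >= 2 and len(td_genes) > len(up_td):
        pool = lfc.reindex(td_genes).to_numpy()
        observed = float(lfc.reindex(up_td).mean())
        results["resampling_null"] = resampling_null_mean(
            pool, len(up_td), observed, n_iter=cfg.n_iter, seed=cfg.resample_seed
        )
    else:
        results["resampling_null"] = None

    results["category_null"] = category_count_null(
        tdt["call_a"], tdt["call_b"], n_iter=min(cfg.n_iter, 2000), seed=cfg.resample_seed
    )

    # plasticity vs TD among defined pairs (pair plasticity = mean copy FC)
    sub = tdt[np.isfinite(tdt["td_ratio"]) & (tdt["td_ratio"] > 1.0)]
    if len(sub) >= 3:
        plast = np.power(
            2.0, 0.5 * (lfc.reindex(sub["gene_a"]).to_numpy() + lfc.reindex(sub["gene_b"]).to_numpy())
        )
        try:
            r, p = plasticity_td_correlation(sub["td_ratio"].to_numpy(), plast)
            results["plasticity_correlation"] = {"r": r, "p": p, "n": len(sub)}
        except Exception:
            results["plasticity_correlation"] = None
    else:
        results["plasticity_correlation"] = None

    results["sweep"] = td_threshold_sweep(expr, calls.to_dict())
    return results


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage from one config; write all outputs under ``outdir``."""
    cfg.validate()
    out = dio.ensure_dir(outdir)

    # --- simulate ---------------------------------------------------------
    catalog, truth = simulate_catalog(cfg.sim)
    design = default_design(cfg.sim.n_replicates, timepoints=cfg.timepoints)
    counts = simulate_counts(catalog, truth, cfg.sim, design)
    dio.write_counts(counts, out / "counts.tsv")
    dio.write_design(design, out / "design.tsv")
    catalog.to_csv(out / "catalog.tsv", sep="\t", index=False)
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)

    gp = cfg.growth
    times = np.arange(0.0, 78.0, 0.25)
    od = simulate_growth_curves(
        gp["K"], gp["r"], gp["N0"], times, noise_sd=gp.get("noise_sd", 0.01),
        seed=cfg.sim.seed + 7, n_wells=gp.get("n_wells", 3),
    )
    od["group"] = "sim"
    dio.write_od_long(od, out / "od600.tsv")

    cm = CountMatrix(counts, design)
    model = NBExpressionModel(cm)

    # --- per-timepoint DE + TD analysis ----------------------------------
    de_by_tp = {}
    analyses = {}
    pairs = truth.pairs
    for tp in cfg.timepoints:
        de = model.fit(tp, cfg.fc_threshold, cfg.fdr_threshold, cfg.fdr_method)
        de.to_tsv(out / f"de_{tp}.tsv")
        de_by_tp[tp] = de
        ana = analyze_timepoint(counts, design, pairs, de, tp, cfg)
        ana["td_table"].to_csv(out / f"td_{tp}.tsv", sep="\t", index=False, float_format="%.6g")
        ana["sweep"].to_csv(out / f"sweep_{tp}.tsv", sep="\t", index=False, float_format="%.6g")
        ana["category_null"].to_csv(out / f"category_null_{tp}.tsv", sep="\t",
                                    float_format="%.6g")
        analyses[tp] = ana

    # --- overlaps across timepoints --------------------------------------
    overlaps = {
        "up": overlap_summary({tp: de_by_tp[tp].up for tp in cfg.timepoints}),
        "down": overlap_summary({tp: de_by_tp[tp].down for tp in cfg.timepoints}),
    }
    for direction, ov in overlaps.items():
        ov.pairwise.to_csv(out / f"overlap_{direction}.tsv", sep="\t", index=False)

    # --- duplicate vs singleton Fisher enrichment at the first timepoint --
    tp0 = cfg.timepoints[0]
    calls0 = de_by_tp[tp0].table["call"]
    dup_genes = set(catalog.loc[catalog["class"] != "singleton", "gene"])
    sng_genes = set(catalog.loc[catalog["class"] == "singleton", "gene"])
    up0 = de_by_tp[tp0].up
    table = [
        [len(up0 & dup_genes), len(dup_genes - up0)],
        [len(up0 & sng_genes), len(sng_genes - up0)],
    ]
    fisher = fisher_enrichment(table)

    # --- growth fits -------------------------------------------------------
    fits = fit_od_table(od)
    fits.to_csv(out / "growth_fits.tsv", sep="\t", index=False, float_format="%.6g")

    # --- ORA on the first timepoint's up-set -------------------------------
    ann = simulate_annotation_map(
        catalog, n_terms=50, genes_per_term=min(40, len(catalog)),
        planted_term=sorted(up0)[:50] if up0 else None, seed=cfg.sim.seed + 11,
    )
    ann.to_csv(out / "term_map.tsv", sep="\t", index=False, header=False)
    ora = hypergeometric_ora(up0, ann, catalog["gene"], p_cutoff=cfg.ora_cutoff)
    ora.to_csv(out / "ora_up.tsv", sep="\t", index=False, float_format="%.6g")

    # --- summary report -----------------------------------------------------
    gens_diversify = generations_from_bottleneck(100, 0.01)
    gens_adapt = generations_from_bottleneck(10, 0.10)
    summary = {
        "n_genes": int(len(catalog)),
        "n_pairs": int(len(pairs)),
        "de_counts": {
            tp: {"up": len(de_by_tp[tp].up), "down": len(de_by_tp[tp].down)}
            for tp in cfg.timepoints
        },
        "up_overlap_pct": {
            f"{r['of']}->{r['with']}": r["pct_of"]
            for _, r in overlaps["up"].pairwise.iterrows()
        },
        "core_up": overlaps["up"].core_size,
        "core_down": overlaps["down"].core_size,
        "td": {
            tp: {
                "n_pairs_defined": analyses[tp]["n_pairs_defined"],
                "n_td_pairs": analyses[tp]["n_td_pairs"],
                "binomial_p_up": (
                    analyses[tp]["binomial_enrichment"]["up"].p
                    if analyses[tp]["binomial_enrichment"]["up"]
                    else None
                ),
                "resampling_p": (
                    analyses[tp]["resampling_null"].p
                    if analyses[tp]["resampling_null"]
                    else None
                ),
                "plasticity_r": (
                    analyses[tp]["plasticity_correlation"]["r"]
                    if analyses[tp]["plasticity_correlation"]
                    else None
                ),
            }
            for tp in cfg.timepoints
        },
        "fisher_dup_vs_singleton_up": {"odds_ratio": fisher.odds_ratio, "p": fisher.p},
        "growth": {
            "n_converged": int(fits["converged"].sum()),
            "median_mu_max": float(fits.loc[fits["converged"], "mu_max"].median()),
            "median_K": float(fits.loc[fits["converged"], "K"].median()),
        },
        "ora_enriched_terms": int(ora["enriched"].sum()) if not ora.empty else 0,
        "generations": {"diversification": gens_diversify[1], "adaptation": gens_adapt[1]},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return {
        "summary": summary,
        "de": de_by_tp,
        "analyses": analyses,
        "overlaps": overlaps,
        "fisher": fisher,
        "growth_fits": fits,
        "ora": ora,
        "catalog": catalog,
        "truth": truth,
    }
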