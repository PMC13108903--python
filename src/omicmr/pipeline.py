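"""End-to-end orchestration: sumstats -> instruments -> MR -> coloc -> meta -> ranking.

A run is described by a :class:`RunConfig` (parsed from YAML for the CLI):
a list of outcomes (each a case-control GWAS, optionally with a replication
GWAS) and a list of omic layers, each holding exposures with their own
summary statistics, gene annotation and LD panel.  ``run_all`` executes the
instrument-selection cascade and MR sensitivity cascade per
(exposure, outcome), adjusts p-values within each (layer, outcome) family
(Benjamini-Hochberg), colocalizes each exposure's cis region with the GWAS,
meta-analyzes discovery and replication estimates where a replication cohort
exists, scores the evidence, and writes per-stage TSV/JSON artifacts plus a
manifest.  Reruns with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import ColocError, ColocPriors, colocalize
from .instruments import (
    SelectionConfig, read_confounder_table, select_instruments,
)
from .meta import select_and_pool
from .mr import AnalysisConfig, analyze_exposure, bh_fdr
from .prioritize import ScoreThresholds, build_evidence, rank_targets
from .sumstats import (
    GeneAnnotation, read_ld_matrix, read_sumstats,
)

logger = logging.getLogger("omicmr.pipeline")


class DataError(ValueError):
    """Bad or inconsistent input data or configuration."""


@dataclass
class ExposureSpec:
    symbol: str
    sumstats: str
    gene: GeneAnnotation
    ld_matrix: str
    ld_snps: str
    n: float


@dataclass
class LayerSpec:
    name: str
    trait_type: str                  # quantitative | case_control
    exposures: list[ExposureSpec]


@dataclass
class OutcomeSpec:
    name: str
    gwas: str
    n: float
    case_fraction: float
    replication_gwas: str | None = None
    replication_n: float | None = None
    replication_case_fraction: float | None = None


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    outcomes: list[OutcomeSpec]
    layers: list[LayerSpec]
    confounders: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    priors: ColocPriors = field(default_factory=ColocPriors)
    thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)
    presso_n_sim: int = 1000
    cis_coloc_bp: int = 1_000_000


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        layers = []
        for lay in raw["layers"]:
            exposures = []
            for e in lay["exposures"]:
                g = e["gene"]
                exposures.append(ExposureSpec(
                    symbol=e["symbol"], sumstats=e["sumstats"],
                    gene=GeneAnnotation(g["gene_id"], g.get("symbol", e["symbol"]),
                                        str(g["chr"]), int(g["tss"]),
                                        g.get("strand", "+")),
                    ld_matrix=e["ld_matrix"], ld_snps=e["ld_snps"],
                    n=float(e["n"])))
            layers.append(LayerSpec(lay["name"], lay.get("trait_type", "quantitative"),
                                    exposures))
        outcomes = [OutcomeSpec(
            name=o["name"], gwas=o["gwas"], n=float(o["n"]),
            case_fraction=float(o.get("case_fraction", 0.5)),
            replication_gwas=o.get("replication_gwas"),
            replication_n=float(o["replication_n"]) if "replication_n" in o else None,
            replication_case_fraction=float(o["replication_case_fraction"])
            if "replication_case_fraction" in o else None,
        ) for o in raw["outcomes"]]
        return RunConfig(
            out_dir=raw["out_dir"], seed=int(raw.get("seed", 0)),
            outcomes=outcomes, layers=layers,
            confounders=raw.get("confounders"),
            selection=SelectionConfig(**raw.get("selection", {})),
            priors=ColocPriors(**raw.get("priors", {})),
            thresholds=ScoreThresholds(**raw.get("thresholds", {})),
            presso_n_sim=int(raw.get("presso_n_sim", 1000)),
        )
    except (KeyError, TypeError) as exc:
        raise DataError(f"invalid run configuration: {exc}") from exc


def _mr_row(layer: str, outcome: str, exposure: str, analysis, audit) -> dict:
    est = analysis.estimate
    row = {
        "target": exposure, "layer": layer, "outcome": outcome,
        "k": est.k if est else 0,
        "method": est.method if est else "none",
        "theta": est.theta if est else np.nan,
        "se": est.se if est else np.nan,
        "or": est.or_ if est else np.nan,
        "ci_low": est.ci_low if est else np.nan,
        "ci_high": est.ci_high if est else np.nan,
        "p": est.pvalue if est else np.nan,
        "q": analysis.heterogeneity.q if analysis.heterogeneity else np.nan,
        "q_p": analysis.heterogeneity.pvalue if analysis.heterogeneity else np.nan,
        "egger_intercept_p": analysis.egger.intercept_p if analysis.egger else np.nan,
        "presso_global_p": analysis.presso.global_p if analysis.presso else np.nan,
        "n_removed_steiger": analysis.n_removed_steiger,
        "n_removed_presso": analysis.n_removed_presso,
        "qc_verdict": analysis.qc_verdict,
        "mean_f": audit.mean_f_retained if audit else np.nan,
    }
    return row


def _cis_region(table: pd.DataFrame, gene: GeneAnnotation, window: int) -> pd.DataFrame:
    keep = (table["CHR"] == gene.chrom) & ((table["POS"] - gene.tss).abs() <= window)
    return table[keep].reset_index(drop=True)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    confounders = read_confounder_table(config.confounders) \
        if config.confounders else None

    mr_rows: list[dict] = []
    coloc_rows: list[dict] = []
    meta_rows: list[dict] = []
    stage_counts: dict[str, dict] = {}

    for outcome in config.outcomes:
        gwas = read_sumstats(outcome.gwas)
        replication = read_sumstats(outcome.replication_gwas) \
            if outcome.replication_gwas else None
        for layer in config.layers:
            for exp in layer.exposures:
                tag = f"{layer.name}.{outcome.name}.{exp.symbol}"
                exposure = read_sumstats(exp.sumstats)
                ld = read_ld_matrix(exp.ld_matrix, exp.ld_snps)
                instr, audit = select_instruments(
                    exposure, gwas, exp.gene, ld, confounders, config.selection)
                audit.to_json(out / f"audit_{tag}.json")
                stage_counts[tag] = {s.stage: [s.n_in, s.n_out] for s in audit.stages}

                acfg = AnalysisConfig(
                    n_exposure=exp.n, n_outcome=outcome.n,
                    case_fraction=outcome.case_fraction,
                    presso_n_sim=config.presso_n_sim,
                    presso_seed=config.seed)
                analysis = analyze_exposure(instr, acfg)
                mr_rows.append(_mr_row(layer.name, outcome.name, exp.symbol,
                                       analysis, audit))

                try:
                    res = colocalize(
                        _cis_region(exposure, exp.gene, config.cis_coloc_bp),
                        _cis_region(gwas, exp.gene, config.cis_coloc_bp),
                        config.priors,
                        trait_type1=layer.trait_type,
                        trait_type2="case_control")
                    coloc_rows.append({"target": exp.symbol, "layer": layer.name,
                                       "outcome": outcome.name, **res.as_dict()})
                except ColocError:
                    logger.info("coloc skipped for %s: no shared SNPs", tag)

                if replication is not None and analysis.estimate is not None:
                    rep_instr, _ = select_instruments(
                        exposure, replication, exp.gene, ld, confounders,
                        config.selection)
                    rep_cfg = AnalysisConfig(
                        n_exposure=exp.n,
                        n_outcome=outcome.replication_n or outcome.n,
                        case_fraction=outcome.replication_case_fraction
                        or outcome.case_fraction,
                        presso_n_sim=config.presso_n_sim,
                        presso_seed=config.seed)
                    rep = analyze_exposure(rep_instr, rep_cfg)
                    if rep.estimate is not None:
                        pooled = select_and_pool([
                            (analysis.estimate.theta, analysis.estimate.se),
                            (rep.estimate.theta, rep.estimate.se)])
                        meta_rows.append({
                            "target": exp.symbol, "outcome": outcome.name,
                            "model": pooled.model, "theta": pooled.theta,
                            "se": pooled.se, "or": pooled.or_,
                            "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                            "p": pooled.pvalue, "q": pooled.q, "q_p": pooled.q_p,
                            "i2": pooled.i2, "tau2": pooled.tau2,
                            "n_studies": pooled.n_studies})

    mr_results = pd.DataFrame(mr_rows)
    if len(mr_results):
        mr_results["p_adj"] = np.nan
        usable = mr_results["p"].notna() & (mr_results["qc_verdict"] == "pass")
        for (_, _), grp in mr_results[usable].groupby(["layer", "outcome"]):
            mr_results.loc[grp.index, "p_adj"] = bh_fdr(grp["p"])
    coloc_results = pd.DataFrame(
        coloc_rows, columns=["target", "layer", "outcome", "pph0", "pph1",
                             "pph2", "pph3", "pph4", "n_snps", "class"])
    meta_results = pd.DataFrame(
        meta_rows, columns=["target", "outcome", "model", "theta", "se", "or",
                            "ci_low", "ci_high", "p", "q", "q_p", "i2", "tau2",
                            "n_studies"])

    replicable = {o.name for o in config.outcomes if o.replication_gwas}
    scored = mr_results[mr_results["p_adj"].notna()] if len(mr_results) else mr_results
    if len(scored):
        evidence = build_evidence(scored, coloc_results, meta_results,
                                  replicable_outcomes=replicable,
                                  thresholds=config.thresholds)
        ranking = rank_targets(evidence)
    else:
        ranking = pd.DataFrame()
        logger.info("nothing to do: no scoreable MR results")

    float_fmt = "%.10g"
    mr_results.to_csv(out / "mr_results.tsv", sep="\t", index=False,
                      float_format=float_fmt, na_rep="NA")
    coloc_results.to_csv(out / "coloc_results.tsv", sep="\t", index=False,
                         float_format=float_fmt, na_rep="NA")
    meta_results.to_csv(out / "meta_results.tsv", sep="\t", index=False,
                        float_format=float_fmt, na_rep="NA")
    ranking.to_csv(out / "ranking.tsv", sep="\t", index=False,
                   float_format=float_fmt, na_rep="NA")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_mr_results": len(mr_results),
        "n_coloc_results": len(coloc_results),
        "n_meta_results": len(meta_results),
        "n_ranked": len(ranking),
        "stage_counts": stage_counts,
        "complete": True,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
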