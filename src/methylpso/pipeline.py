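"""Configuration-driven orchestration of the full analysis.

A YAML config names the input files (β matrix, manifest, sample sheet,
optional detection mask and GMT collections), the preprocessing options, the
contrasts to test and the thresholds. `run_pipeline` executes: probe QC →
β→M → quantile normalization → covariate screen → batch adjustment → per
contrast DMP/DMR calling, promoter partition and enrichment → gene-set
scores → PCA/PLS-DA, and writes every table plus a run manifest (config
snapshot, output checksums) to the output directory. Logging goes to
standard error; the same seed and config reproduce the bundle byte for
byte.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .datatypes import ConfigError, align_samples
from .differential import call_dmps, call_dmrs, dmp_statistics, promoter_subset, summarize_dmps
from .enrichment import ora, report_top
from .multivariate import correlation_circle, pca, plsda
from .preprocess import beta_to_m, combat_adjust, filter_probes, m_to_beta, \
    quantile_normalize, screen_covariates
from .scores import correlation_filter_score, fit_score_model, score_samples

logger = logging.getLogger("methylpso.pipeline")

DEFAULT_THRESHOLDS = {"q": 0.05, "delta_beta": 0.1, "min_cpg": 5,
                      "max_gap_bp": 1000, "corr_circle_r": 0.9,
                      "score_r": 0.7}

ALL_STAGES = ("dmp", "dmr", "enrich", "scores", "mvar")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Check paths exist and contrasts are well-formed before any compute."""
    paths = cfg.get("paths")
    if not paths:
        raise ConfigError("config needs a 'paths' block")
    for key in ("beta", "manifest", "sample_sheet"):
        if key not in paths:
            raise ConfigError(f"paths.{key} is required")
        if not Path(paths[key]).exists():
            raise ConfigError(f"paths.{key} does not exist: {paths[key]}")
    for opt in ("detection", "gene_sets"):
        if paths.get(opt) and not Path(paths[opt]).exists():
            raise ConfigError(f"paths.{opt} does not exist: {paths[opt]}")
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key, val in thresholds.items():
        if not (isinstance(val, (int, float)) and val > 0):
            raise ConfigError(f"threshold {key!r} must be positive")
    cfg = dict(cfg)
    cfg["thresholds"] = thresholds
    if not cfg.get("contrasts"):
        raise ConfigError("config needs at least one contrast")
    for con in cfg["contrasts"]:
        for key in ("name", "reference", "comparison"):
            if key not in con:
                raise ConfigError(f"contrast missing {key!r}: {con}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, out_dir=None, stages=ALL_STAGES) -> dict:
    """Execute the configured analysis; returns the in-memory result bundle.

    `config` is a dict or a YAML path. `stages` selects which downstream
    stages run (preprocessing always runs).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = validate_config(config)
    paths = cfg["paths"]
    thresholds = cfg["thresholds"]
    out = Path(out_dir or paths.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)

    logger.info("loading inputs")
    beta = mio.read_beta_matrix(paths["beta"], paths.get("detection"))
    manifest = mio.read_manifest(paths["manifest"])
    sheet = mio.read_sample_sheet(paths["sample_sheet"])
    beta, sheet = align_samples(beta, sheet)
    for con in cfg["contrasts"]:
        sheet.resolve_groups(con["reference"])
        sheet.resolve_groups(con["comparison"])
    gene_sets = mio.read_gmt(paths["gene_sets"]) if paths.get("gene_sets") else None

    pre = cfg.get("preprocessing", {})
    logger.info("filtering probes")
    beta_f, report = filter_probes(beta, manifest,
                                   max_fail_fraction=pre.get("max_fail_fraction", 0.0))
    mio.write_json(report.to_dict(), out / "filter_report.json")

    m = beta_to_m(beta_f, epsilon=pre.get("epsilon", 0.001))
    if pre.get("quantile", True):
        logger.info("quantile normalization")
        m = quantile_normalize(m)
    screen = screen_covariates(m, sheet)
    logger.info("covariate screen (min p per covariate): %s", screen)
    batch_model = None
    if pre.get("combat", True):
        batch_var = pre.get("batch_var", "slide")
        if batch_var in sheet.df.columns and sheet.df[batch_var].nunique() > 1:
            logger.info("batch adjustment on %r", batch_var)
            m, batch_model = combat_adjust(
                m, sheet, batch_var=batch_var,
                covariates=pre.get("covariates", ("age", "sex", "group")))
    beta_norm = m_to_beta(m)

    bundle: dict = {"filter_report": report, "covariate_screen": screen,
                    "batch_model": batch_model, "m": m,
                    "beta_norm": beta_norm, "contrasts": {}}
    universe = sorted({g for genes in manifest.df.loc[m.probe_ids, "genes"]
                       for g in genes})

    for con in cfg["contrasts"]:
        name = con["name"]
        contrast = (con["reference"], con["comparison"])
        covs = con.get("covariates", ["age", "sex"])
        logger.info("contrast %s: %s vs %s", name, *contrast)
        res: dict = {"contrast": contrast}
        stats_df, _ = dmp_statistics(m, beta_norm, sheet, contrast, covs)
        res["stats"] = stats_df
        if "dmp" in stages:
            dmps = call_dmps(m, beta_norm, sheet, contrast, covs,
                             q_threshold=thresholds["q"],
                             delta_beta_threshold=thresholds["delta_beta"],
                             manifest=manifest)
            res["dmps"] = dmps
            res["summary"] = summarize_dmps(dmps)
            mio.write_dmp_table(dmps, out / f"dmps_{name}.csv")
            hypo, hyper = promoter_subset(dmps, manifest)
            res["promoter_hypo"], res["promoter_hyper"] = hypo, hyper
            mio.write_json({"n_hypo": res["summary"][0],
                            "n_hyper": res["summary"][1],
                            "n_total": res["summary"][2],
                            "n_unique_genes": res["summary"][3]},
                           out / f"summary_{name}.json")
            if "enrich" in stages and gene_sets is not None:
                for direction, part in (("hypo", hypo), ("hyper", hyper)):
                    genes = sorted({g for gl in part.get("genes", pd.Series(dtype=object))
                                    for g in gl})
                    if genes:
                        rows = ora(genes, gene_sets, universe)
                        rep = report_top(rows)
                        rep.to_csv(out / f"enrichment_{name}_{direction}.csv",
                                   index=False)
                        res[f"enrichment_{direction}"] = rep
        if "dmr" in stages:
            dmrs = call_dmrs(stats_df, manifest,
                             min_cpg=thresholds["min_cpg"],
                             max_gap_bp=thresholds["max_gap_bp"],
                             q_threshold=thresholds["q"],
                             delta_beta_threshold=thresholds["delta_beta"])
            res["dmrs"] = dmrs
            mio.write_dmr_tables(dmrs, out / f"dmrs_{name}.bed",
                                 out / f"dmrs_{name}.csv")
        bundle["contrasts"][name] = res

    if "scores" in stages and gene_sets is not None:
        first = cfg["contrasts"][0]["name"]
        dmps = bundle["contrasts"][first].get("dmps")
        if dmps is None:
            raise ConfigError("score stage needs the dmp stage")
        bundle["scores"] = {}
        for sc in cfg.get("scores", []):
            sname, set_name = sc["name"], sc["gene_set"]
            if set_name not in gene_sets.names:
                raise ConfigError(f"gene set {set_name!r} not in collection")
            try:
                if sc.get("pasi_filter"):
                    fs = correlation_filter_score(
                        beta_norm, sheet, dmps, gene_sets[set_name],
                        pathway_name=sname,
                        r_threshold=thresholds["score_r"])
                    bundle["scores"][sname] = fs
                    table = pd.DataFrame({"total": fs.result.total,
                                          "group": sheet.group})
                else:
                    model = fit_score_model(beta_norm, sheet, dmps,
                                            gene_sets[set_name], sname)
                    result = score_samples(model, beta_norm, sheet)
                    bundle["scores"][sname] = result
                    table = pd.DataFrame({"total": result.total,
                                          "group": sheet.group})
                table.to_csv(out / f"score_{sname}.csv", index_label="sample_id")
            except ConfigError as exc:
                logger.warning("score %s skipped: %s", sname, exc)

    if "mvar" in stages:
        mv = cfg.get("multivariate", {})
        base = mv.get("contrast", cfg["contrasts"][0]["name"])
        dmps = bundle["contrasts"][base].get("dmps")
        if dmps is not None and len(dmps) >= 2:
            sub = beta_norm.subset_probes(dmps.index)
            ncomp = mv.get("n_components", 2)
            try:
                proj_pca = pca(sub, ncomp)
                proj_pls = plsda(sub, sheet.group, ncomp)
                circle = correlation_circle(proj_pls, sub, component=1,
                                            r_cutoff=thresholds["corr_circle_r"])
                bundle["pca"], bundle["plsda"], bundle["circle"] = \
                    proj_pca, proj_pls, circle
                proj_pca.scores.to_csv(out / "pca_scores.csv",
                                       index_label="sample_id")
                proj_pls.scores.to_csv(out / "plsda_scores.csv",
                                       index_label="sample_id")
                circle.to_csv(out / "correlation_circle.csv")
            except ConfigError as exc:
                logger.warning("multivariate stage skipped: %s", exc)
        else:
            logger.warning("multivariate stage skipped: too few DMPs")

    snapshot = out / "run_config.yaml"
    snapshot.write_text(yaml.safe_dump(cfg, sort_keys=True))
    # the config snapshot carries absolute paths; checksums cover results only
    outputs = {p.name: _sha256(p) for p in sorted(out.iterdir())
               if p.is_file() and p.name not in ("run_manifest.json",
                                                 "run_config.yaml")}
    mio.write_json({"outputs": outputs, "seed": cfg.get("seed"),
                    "n_probes_analyzed": int(len(m.probe_ids))},
                   out / "run_manifest.json")
    bundle["out_dir"] = out
    return bundle


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")
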