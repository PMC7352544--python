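"""End-to-end orchestration of the analysis stages.

A single YAML config drives the run.  Top-level keys:

``seed``        — global random seed (simulation and resampling substreams).
``output_dir``  — where stage outputs and the run manifest are written.
``stages``      — any of: simulate, de, survival, pairs, correlate,
                  geometry, nulls.  Stage dependencies are validated before
                  any computation: de needs expression data (simulate or
                  inputs), survival/pairs need clinical data and de calls,
                  correlate needs de calls.
``simulate``    — a synthetic-cohort block (see hoxpress.simulate); mutually
                  exclusive with ``inputs``.
``inputs``      — paths: expression, phenotype, clinical (optional),
                  category_map (optional).
``de`` / ``survival`` / ``pairs`` / ``correlate`` / ``nulls`` — per-stage
                  parameter overrides (cutoffs, alpha, Bonferroni n, B).

Every output is TSV; the manifest (manifest.yaml) records the config
snapshot, seed, package version, input checksums and per-stage wall times.
Result files are byte-reproducible for a fixed config and seed; the manifest
is not (it carries timings).
"""

from __future__ import annotations

import hashlib
import time as _time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import build_catalog, enumerate_pairs
from .coexpression import classify_pairs
from .diffexpr import HighlightFilter, classify_de, highlight
from .geometry import average_linkage, separation
from .io import (
    CohortPair,
    IntegrityError,
    build_cohorts,
    read_category_map,
    read_clinical,
    read_expression,
    read_phenotype,
)
from .nulls import posterior_low_expression_test
from .simulate import SimulationConfig, generate
from .survival import pair_km, tiered_km

__all__ = ["ConfigError", "run_pipeline", "load_pipeline_config"]

_FLOAT_FMT = "%.6g"

STAGES = ("simulate", "de", "survival", "pairs", "correlate", "geometry", "nulls")


class ConfigError(ValueError):
    """The run configuration is invalid (unknown stage, missing dependency)."""


def load_pipeline_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_sim_config(block: Mapping[str, Any], seed: int) -> SimulationConfig:
    from .simulate import CorrelationBlock, SurvivalConfig

    block = dict(block)
    blocks = tuple(
        CorrelationBlock(tuple(b["genes"]), float(b["rho"]))
        for b in block.pop("correlation_blocks", [])
    )
    surv_raw = block.pop("survival", {})
    survival = SurvivalConfig(
        lambda0=float(surv_raw.get("lambda0", 1.0 / 1000.0)),
        beta={str(k): float(v) for k, v in (surv_raw.get("beta") or {}).items()},
        censoring_rate=float(surv_raw.get("censoring_rate", 0.2)),
    )
    genes = tuple(block.pop("genes", ()) or ())
    block.setdefault("seed", seed)
    return SimulationConfig(
        genes=genes, correlation_blocks=blocks, survival=survival, **block
    )


def run_pipeline(config: Mapping[str, Any] | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the configured stages; returns {stage: output paths / tables}.

    Raises :class:`ConfigError` before any computation when the stage list
    has unmet dependencies or required inputs are missing.
    """
    if not isinstance(config, Mapping):
        config = load_pipeline_config(config)
    cfg = dict(config)
    stages = list(cfg.get("stages", ["simulate", "de", "survival", "pairs", "correlate", "geometry"]))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    out_dir = Path(output_dir or cfg.get("output_dir", "hoxpress_out"))
    seed = int(cfg.get("seed", 0))

    has_data = "simulate" in stages or "inputs" in cfg
    for stage, needs in {
        "de": has_data,
        "geometry": has_data,
        "nulls": has_data,
        "correlate": "de" in stages,
        "survival": "de" in stages,
        "pairs": "de" in stages,
    }.items():
        if stage in stages and not needs:
            dep = "simulate/inputs" if stage in ("de", "geometry", "nulls") else "de"
            raise ConfigError(f"stage '{stage}' requires '{dep}' to run or be configured")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        if "expression" not in inputs or "phenotype" not in inputs:
            raise ConfigError("inputs must name 'expression' and 'phenotype' files")
        for key, path in inputs.items():
            if key in ("expression", "phenotype", "clinical", "category_map") and not Path(path).exists():
                raise ConfigError(f"input file missing: {key} = {path}")
        if ("survival" in stages or "pairs" in stages) and "clinical" not in inputs:
            raise ConfigError("stages survival/pairs require a clinical input")

    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = build_catalog()
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "output_dir"},
        "inputs": {},
        "timings": {},
    }
    results: dict[str, Any] = {}
    cohorts: dict[str, CohortPair] = {}
    clinical: pd.DataFrame | None = None

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = _time.perf_counter()

            def __exit__(self, *exc):
                manifest["timings"][name] = round(_time.perf_counter() - self.t0, 4)

        return _T()

    # --- data -------------------------------------------------------------
    with timed("data"):
        if "simulate" in stages:
            sim_cfg = _build_sim_config(cfg.get("simulate", {}), seed)
            synthetic = generate(sim_cfg)
            cohorts[synthetic.cohort.category] = synthetic.cohort
            clinical = synthetic.survival.assign(her2="missing", pr="missing", er="missing")
            results["simulate"] = synthetic
        elif "inputs" in cfg:
            inputs = cfg["inputs"]
            expr = read_expression(inputs["expression"])
            pheno = read_phenotype(inputs["phenotype"])
            category_map = (
                read_category_map(inputs["category_map"]) if "category_map" in inputs else None
            )
            cohorts = build_cohorts(
                expr, pheno, category_map, min_samples=int(cfg.get("min_samples", 100))
            )
            if "clinical" in inputs:
                clinical = read_clinical(inputs["clinical"])
            for key in ("expression", "phenotype", "clinical", "category_map"):
                if key in inputs:
                    manifest["inputs"][key] = _checksum(Path(inputs[key]))
    included = {c: p for c, p in cohorts.items() if p.included}

    # --- differential expression -----------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    if "de" in stages:
        with timed("de"):
            de_cfg = cfg.get("de", {})
            frames = []
            for category, pair in included.items():
                genes = [g for g in catalog.symbols if g in pair.tumor.data.index]
                if not genes:
                    genes = pair.tumor.genes
                table = classify_de(
                    pair,
                    genes,
                    fold_cutoff=float(de_cfg.get("fold_cutoff", 2.0)),
                    alpha=float(de_cfg.get("alpha", 0.05)),
                    n_tests=int(de_cfg.get("n_tests", len(genes))),
                )
                de_tables[category] = table
                frames.append(table.assign(cancer_type=category))
            de_all = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            de_all.to_csv(out_dir / "de.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            filt = HighlightFilter(
                min_fold=float(de_cfg.get("highlight_min_fold", 3.0)),
                floor_side=de_cfg.get("highlight_floor_side", "healthy"),
                floor_value=float(de_cfg.get("highlight_floor_value", 1.0)),
            )
            if len(de_all):
                hi = (
                    de_all.groupby("cancer_type", group_keys=False)[de_all.columns]
                    .apply(lambda df: highlight(df, filt))
                    .reset_index(drop=True)
                )
            else:
                hi = de_all
            hi.to_csv(out_dir / "highlights.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            results["de"] = de_all
            results["highlights"] = hi

    def de_genes_of(category: str) -> list[str]:
        table = de_tables.get(category)
        if table is None:
            return []
        return table.loc[table["call"] != "none", "gene"].tolist()

    # --- single-gene survival screen -------------------------------------
    if "survival" in stages:
        with timed("survival"):
            if clinical is None:
                raise ConfigError("stage 'survival' requires clinical data")
            s_cfg = cfg.get("survival", {})
            rows = []
            for category, pair in included.items():
                common = [s for s in pair.tumor.samples if s in clinical.index]
                clin = clinical.loc[common]
                for gene in de_genes_of(category):
                    expr_vec = pair.tumor.data.loc[gene, common]
                    res = tiered_km(
                        expr_vec.to_numpy(dtype=float),
                        clin["time"].to_numpy(),
                        clin["event"].to_numpy(),
                        gene=gene,
                        alpha=float(s_cfg.get("alpha", 0.05)),
                        n_tests=int(s_cfg.get("n_tests", 39)),
                    )
                    row = asdict(res)
                    row.pop("tier_pvalues")
                    rows.append({"cancer_type": category, **row})
            surv_df = pd.DataFrame(rows)
            surv_df.to_csv(out_dir / "tiered_km.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            results["survival"] = surv_df

    # --- pair survival screen --------------------------------------------
    if "pairs" in stages:
        with timed("pairs"):
            if clinical is None:
                raise ConfigError("stage 'pairs' requires clinical data")
            p_cfg = cfg.get("pairs", {})
            rows = []
            for category, pair in included.items():
                common = [s for s in pair.tumor.samples if s in clinical.index]
                clin = clinical.loc[common]
                de_genes = de_genes_of(category)
                for ga, gb in enumerate_pairs(de_genes):
                    res = pair_km(
                        pair.tumor.data.loc[ga, common].to_numpy(dtype=float),
                        pair.tumor.data.loc[gb, common].to_numpy(dtype=float),
                        clin["time"].to_numpy(),
                        clin["event"].to_numpy(),
                        gene_a=ga,
                        gene_b=gb,
                        alpha=float(p_cfg.get("alpha", 0.05)),
                        n_tests=int(p_cfg.get("n_tests", 741)),
                    )
                    rows.append({"cancer_type": category, **asdict(res)})
            pairs_df = pd.DataFrame(rows)
            pairs_df.to_csv(out_dir / "pair_km.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            results["pairs"] = pairs_df

    # --- coexpression ------------------------------------------------------
    if "correlate" in stages:
        with timed("correlate"):
            frames = []
            for category, pair in included.items():
                table = classify_pairs(pair, de_tables[category], catalog)
                frames.append(table.assign(cancer_type=category))
            corr_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            corr_df.to_csv(out_dir / "coexpression.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            results["correlate"] = corr_df

    # --- geometry ----------------------------------------------------------
    if "geometry" in stages:
        with timed("geometry"):
            rows = []
            newicks = []
            for category, pair in included.items():
                sep = separation(pair)
                rows.append(
                    {
                        "cancer_type": category,
                        "mean_intra_healthy": float(np.mean(sep.intra_healthy)),
                        "mean_inter": float(np.mean(sep.inter)),
                        "p": sep.p,
                    }
                )
                joint = pd.concat([pair.healthy.data, pair.tumor.data], axis=1)
                dend = average_linkage(joint, axis="columns")
                newicks.append((category, dend.to_newick()))
            geo_df = pd.DataFrame(rows)
            geo_df.to_csv(out_dir / "separation.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            with open(out_dir / "sample_dendrograms.nwk", "w") as fh:
                for category, nwk in newicks:
                    fh.write(f"# {category}\n{nwk}\n")
            results["geometry"] = geo_df

    # --- empirical nulls ---------------------------------------------------
    if "nulls" in stages:
        with timed("nulls"):
            n_cfg = cfg.get("nulls", {})
            healthy_means = pd.DataFrame(
                {
                    category: pair.healthy.data.reindex(catalog.symbols).mean(axis=1)
                    for category, pair in included.items()
                }
            ).dropna()
            null = posterior_low_expression_test(
                healthy_means,
                catalog,
                B=int(n_cfg.get("B", 1000)),
                universe=n_cfg.get("universe", "hox"),
                seed=seed,
            )
            summary = pd.DataFrame(
                [
                    {
                        "test": "posterior_low_expression",
                        "observed": null.observed,
                        "p_empirical": null.p_empirical,
                        "tail": null.tail,
                        "B": len(null.draws),
                    }
                ]
            )
            summary.to_csv(out_dir / "nulls.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
            null.to_frame().to_csv(
                out_dir / "nulls_posterior_draws.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
            results["nulls"] = null

    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    results["manifest"] = manifest
    results["output_dir"] = out_dir
    return results
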