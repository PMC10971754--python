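"""End-to-end pipeline: preprocess -> per-rank ensembles -> ordinal
regression -> zeta assembly, under one master seed, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import TOPOLOGY_MEASURES
from .ensemble import compare_all_metrics, run_ensemble
from .io import RunConfig, read_abundance, write_json, write_results
from .ordinal import regression_report
from .preprocess import assign_quantiles, conglomerate, run_preprocessing, to_presence_absence
from .zeta import assembly_report

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and return the output directory.

    Every stage failure aborts with the stage name; outputs written before
    the failure are retained for inspection.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
    }
    stage = "load"
    try:
        table = read_abundance(config.abundance, config.taxonomy, config.metadata)
        manifest["stages"]["load"] = {
            "n_taxa": table.n_taxa,
            "n_samples": table.n_samples,
        }

        stage = "preprocess"
        base, provenance = run_preprocessing(table)
        manifest["stages"]["preprocess"] = {
            "provenance": [
                {k: v for k, v in step.items() if k not in ("dropped_taxa", "scale_factors")}
                for step in provenance
            ],
            "n_taxa_after": base.n_taxa,
            "n_samples_after": base.n_samples,
        }

        stage = "quantiles"
        quant = assign_quantiles(base.metadata, k=config.n_quantiles)
        usable = quant.labels.dropna().index
        manifest["stages"]["quantiles"] = {
            "cut_points": quant.cut_points.tolist(),
            "group_sizes": quant.group_sizes().to_dict(),
        }

        results: dict = {}
        presence_by_cell: dict = {}
        for rank in config.ranks:
            stage = f"ensemble[{rank}]"
            rank_table = conglomerate(base, rank).subset_samples(usable)
            ens = run_ensemble(
                rank_table,
                quant.labels.loc[usable],
                n_per=config.ensemble_n_per,
                n_reps=config.ensemble_n_reps,
                seed=config.seed,
                inference_options={
                    "pseudocount": config.pseudocount,
                    "n_lambda": config.n_lambda,
                    "min_ratio": config.min_ratio,
                    "n_reps": config.stability_reps,
                    "instability_threshold": config.instability_threshold,
                },
            )
            metrics = ens.to_frame()
            results[f"metrics_{rank}"] = metrics
            summary = ens.summary()
            summary.columns = ["_".join(c) for c in summary.columns]
            results[f"metrics_summary_{rank}"] = summary.reset_index()
            results[f"comparisons_{rank}"] = compare_all_metrics(ens)

            stage = f"regress[{rank}]"
            features = metrics[list(TOPOLOGY_MEASURES)].astype(float)
            y = metrics["group"]
            report = regression_report(
                features, y, r_max=config.r_max, p_threshold=config.p_threshold
            )
            results[f"odds_ratios_{rank}"] = report["odds_table"]
            fit = report["fit"]
            write_json(
                {
                    "rank": rank,
                    "screened_features": report["screened_features"],
                    "best_subset": report["best_subset"],
                    "stepwise": report["stepwise"],
                    "selected": report["selected"],
                    "beta": fit.beta.tolist(),
                    "theta": fit.theta.tolist(),
                    "se_beta": fit.se_beta.tolist(),
                    "p_values": fit.p_values.tolist(),
                    "odds_ratios": fit.odds_ratios.tolist(),
                    "log_likelihood": fit.log_likelihood,
                    "aic": fit.aic,
                    "n_obs": fit.n_obs,
                },
                out_dir / f"model_{rank}.json",
            )

            stage = f"zeta-prep[{rank}]"
            for group in sorted(quant.labels.dropna().unique()):
                members = usable[quant.labels.loc[usable] == group]
                presence_by_cell[(group, rank)] = to_presence_absence(
                    rank_table.subset_samples(members)
                )

        stage = "zeta"
        zeta_table = assembly_report(
            presence_by_cell,
            orders=config.zeta_orders,
            n_combos=config.zeta_sample_size,
            seed=config.seed,
        )
        results["zeta_assembly"] = zeta_table

        write_results(results, out_dir)
        manifest["stages"]["outputs"] = sorted(results)
        write_json(manifest, out_dir / "manifest.json")
        return out_dir
    except Exception as exc:
        manifest["stages"]["failed_stage"] = stage
        manifest["stages"]["error"] = str(exc)
        write_json(manifest, out_dir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
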