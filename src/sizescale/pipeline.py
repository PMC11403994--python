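"""End-to-end orchestration: simulate -> filter -> fit -> cycle -> plsr.

A single YAML/JSON config with per-stage blocks drives a reproducible
run; all thresholds (NF 0.7, 3-SD size window, early-S quartile,
VIP > 1) surface in the config with their conventional values as
defaults. Numeric CSV output is serialized at 9 significant digits so
reruns with identical config and seeds are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_cycle import (
    classify_cell_cycle,
    stage_size_comparison,
    train_stage_classifiers,
    verify_s_g2_by_dna,
)
from .config import make_default_config, PRESETS
from .errors import ConfigurationError, InputError
from .plsr import compute_vip, correct_phospho, fit_plsr, select_components, select_hits
from .qc import FilterConfig, qc_pipeline
from .scaling import scaling_report
from .synthetic import generate_cell_population, generate_phospho_panel, write_cell_table

__all__ = ["RunManifest", "PipelineConfigError", "MissingInputError", "run_pipeline", "write_report"]

STAGE_NAMES = ("simulate", "qc", "scaling", "cycle", "plsr")

_FLOAT_FMT = "%.9g"


class PipelineConfigError(ConfigurationError):
    """Pipeline config violates the schema (CLI exit code 2)."""


class MissingInputError(InputError):
    """A required input file is absent (CLI exit code 3)."""


DEFAULT_CONFIG: dict = {
    "stages": list(STAGE_NAMES),
    "simulate": {"preset": "breast_default", "n_cells": 4000, "seed": 17, "line_id": "synthline_0"},
    "qc": {"nf_max": 0.7, "sd_window_k": 3.0, "drop_border": True},
    "scaling": {"min_cells": 10},
    "cycle": {"n_size_bins": 4, "value_column": "yap_whole_cell_mean"},
    "plsr": {
        "n_lines": 8,
        "n_peptides": 200,
        "n_informative": 10,
        "seed": 17,
        "folds": 10,
        "vip_threshold": 1.0,
    },
    "report": {"plots": False},
}


def _validate_config(cfg: dict) -> dict:
    merged = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for key, value in cfg.items():
        if key not in DEFAULT_CONFIG:
            raise PipelineConfigError(f"unknown config section {key!r}")
        if isinstance(DEFAULT_CONFIG[key], dict):
            if not isinstance(value, dict):
                raise PipelineConfigError(f"section {key!r} must be a mapping")
            unknown = set(value) - set(DEFAULT_CONFIG[key])
            if unknown:
                raise PipelineConfigError(f"section {key!r}: unknown keys {sorted(unknown)}")
            merged[key].update(value)
        else:
            merged[key] = value
    stages = merged["stages"]
    unknown = [s for s in stages if s not in STAGE_NAMES]
    if unknown:
        raise PipelineConfigError(f"unknown stages {unknown}; valid: {list(STAGE_NAMES)}")
    if merged["simulate"]["preset"] not in PRESETS:
        raise PipelineConfigError(
            f"simulate.preset must be one of {list(PRESETS)}"
        )
    for field_name in ("n_cells", "seed"):
        if not isinstance(merged["simulate"][field_name], int):
            raise PipelineConfigError(f"simulate.{field_name} must be an integer")
    return merged


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config_hash: str
    seeds: dict
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sidecar(path: Path, config_hash: str) -> None:
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"config_hash": config_hash})
    )


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)
    _sidecar(path, config_hash)


def load_config(config_path: str | Path | None) -> dict:
    """Load and validate a pipeline config (YAML or JSON); ``None`` = defaults."""
    if config_path is None:
        return _validate_config({})
    path = Path(config_path)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise PipelineConfigError("config must be a mapping of sections")
    return _validate_config(raw)


def run_pipeline(config_path: str | Path | dict | None, out_dir: str | Path) -> RunManifest:
    """Execute the enabled stages in order and write a results bundle.

    Returns the :class:`RunManifest`; also writes it to
    ``<out_dir>/manifest.json`` together with the per-stage outputs and
    a ``summary.json`` report. Reruns with identical config reproduce
    identical numeric outputs.
    """
    cfg = config_path if isinstance(config_path, dict) else load_config(config_path)
    cfg = _validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _hash_config(cfg)
    manifest = RunManifest(
        config_hash=chash,
        seeds={"simulate": cfg["simulate"]["seed"], "plsr": cfg["plsr"]["seed"]},
    )
    stages = cfg["stages"]

    table = None
    labels = None
    summary: dict = {}

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            sim = cfg["simulate"]
            gen_cfg = make_default_config(
                sim["preset"], n_cells=sim["n_cells"], seed=sim["seed"], line_id=sim["line_id"]
            )
            table = generate_cell_population(gen_cfg)
            path = out / "cells.csv"
            write_cell_table(table, path, gen_cfg)
            _sidecar(path, chash)
            manifest.outputs["simulate"] = str(path)
        elif stage == "qc":
            if table is None:
                raise MissingInputError("qc stage needs a simulated table (enable 'simulate')")
            fcfg = FilterConfig(
                nf_max=cfg["qc"]["nf_max"],
                sd_window_k=cfg["qc"]["sd_window_k"],
                drop_border=cfg["qc"]["drop_border"],
            )
            table, qc_report = qc_pipeline(table, fcfg)
            path = out / "cells.qc.csv"
            _write_csv(table, path, chash)
            (out / "filter_report.json").write_text(json.dumps(qc_report, indent=2))
            manifest.outputs["qc"] = str(path)
            summary["qc"] = qc_report
        elif stage == "scaling":
            if table is None:
                raise MissingInputError("scaling stage needs a cell table")
            fits = scaling_report(table, min_cells=cfg["scaling"]["min_cells"])
            path = out / "fits.csv"
            _write_csv(fits, path, chash)
            manifest.outputs["scaling"] = str(path)
            fitted = fits[fits["fitted"]]
            summary["scaling"] = {
                "n_groups_fitted": int(fitted.shape[0]),
                "b": {
                    f"{r.channel}/{r.compartment}/{r.quantity}/{r.dna_bin}": float(r.b)
                    for r in fitted.itertuples()
                    if r.line_id == fitted["line_id"].iloc[0]
                },
                "fold_vs_low": {
                    f"{r.channel}/{r.compartment}/{r.quantity}": float(r.fold_vs_low)
                    for r in fitted.itertuples()
                    if np.isfinite(r.fold_vs_low)
                },
            }
        elif stage == "cycle":
            if table is None:
                raise MissingInputError("cycle stage needs a cell table")
            cyc_cfg = train_stage_classifiers(table)
            labels = classify_cell_cycle(table, cyc_cfg)
            labelled = table.assign(stage=labels)
            path = out / "cells.labeled.csv"
            _write_csv(labelled, path, chash)
            verification = verify_s_g2_by_dna(table, labels)
            comparison = stage_size_comparison(
                table,
                labels,
                n_size_bins=cfg["cycle"]["n_size_bins"],
                value_column=cfg["cycle"]["value_column"],
            )
            _write_csv(comparison.summary, out / "cycle_summary.csv", chash)
            _write_csv(comparison.contrasts, out / "cycle_contrasts.csv", chash)
            manifest.outputs["cycle"] = str(path)
            summary["cycle"] = {
                "stage_counts": {k: int(v) for k, v in labels.value_counts().items()},
                "dna_verification": {
                    "passed": verification.passed,
                    "mean_dna": verification.mean_dna,
                },
            }
        elif stage == "plsr":
            pcfg = cfg["plsr"]
            panel = generate_phospho_panel(
                n_lines=pcfg["n_lines"],
                n_peptides=pcfg["n_peptides"],
                n_informative=pcfg["n_informative"],
                seed=pcfg["seed"],
            )
            panel.write(out / "panel")
            corrected = correct_phospho(panel)
            _write_csv(corrected.residuals, out / "corrected.csv", chash, index=True)
            selection = select_components(
                corrected.residuals, panel.response, folds=pcfg["folds"], seed=pcfg["seed"]
            )
            model = fit_plsr(corrected.residuals, panel.response, selection.n_components)
            vip = compute_vip(model, panel.peptide_info)
            _write_csv(vip, out / "vip.csv", chash, index=True)
            hits = select_hits(vip, threshold=pcfg["vip_threshold"])
            ranked = vip.sort_values("vip", ascending=False)[["vip"]]
            ranked.to_csv(out / "ranked.tsv", sep="\t", float_format=_FLOAT_FMT)
            model_info = {
                "n_components": model.n_components,
                "cv_mse": [float(v) for v in selection.cv_mse],
                "cv_mse_baseline": selection.mse_baseline,
                "folds_used": selection.folds_used,
                "low_signal": selection.low_signal,
                "ssy": [float(v) for v in model.ssy],
                "ssy_total": model.ssy_total,
            }
            (out / "plsr_model.json").write_text(json.dumps(model_info, indent=2))
            manifest.outputs["plsr"] = str(out / "vip.csv")
            summary["plsr"] = {
                "n_components": model.n_components,
                "n_hits": int(len(hits)),
                "hits": list(hits.index[:25]),
                "folds_used": selection.folds_used,
            }
        manifest.stages.append(stage)
        manifest.timings[stage] = round(time.perf_counter() - t0, 4)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    manifest.outputs["summary"] = str(out / "summary.json")
    manifest.write(out / "manifest.json")
    write_report(manifest, cfg, out, table)
    return manifest


def write_report(manifest: RunManifest, cfg: dict, out_dir: Path, table=None) -> list[Path]:
    """Emit optional plots for a completed run; returns the files written.

    Plots (log-log scatter with fit line, VIP bar chart) are produced
    only when ``report.plots`` is enabled in the config.
    """
    out = Path(out_dir)
    written: list[Path] = []
    if not cfg.get("report", {}).get("plots", False):
        return written
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fits_path = out / "fits.csv"
    if table is not None and fits_path.exists():
        fits = pd.read_csv(fits_path)
        sel = fits[
            (fits["quantity"] == "concentration") & (fits["dna_bin"] == "all") & fits["fitted"]
        ]
        if len(sel):
            r = sel.iloc[0]
            col = f"{r.channel}_{r.compartment}_mean"
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.loglog(table["area"], table[col], ".", ms=2, alpha=0.3, base=2)
            grid = np.linspace(table["area"].min(), table["area"].max(), 50)
            ax.loglog(grid, 2.0**r.log2_a * grid**r.b, "r-", base=2, label=f"b = {r.b:.2f}")
            ax.set_xlabel("cell area")
            ax.set_ylabel(col)
            ax.legend()
            fig.tight_layout()
            p = out / "scaling_fit.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written.append(p)
    vip_path = out / "vip.csv"
    if vip_path.exists():
        vip = pd.read_csv(vip_path, index_col=0).sort_values("vip", ascending=False).head(25)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(range(len(vip)), vip["vip"])
        ax.axhline(1.0, color="r", ls="--")
        ax.set_xticks(range(len(vip)))
        ax.set_xticklabels(vip.index, rotation=90, fontsize=6)
        ax.set_ylabel("VIP")
        fig.tight_layout()
        p = out / "vip.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
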