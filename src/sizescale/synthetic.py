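"""Seeded synthetic single-cell feature tables and phospho/total peptide panels.

Two generators live here:

* :func:`generate_cell_population` emulates a high-content-screening
  per-cell feature export (areas, DNA content, crowding, power-law
  intensity channels, cell-cycle marker features), and

* :func:`generate_phospho_panel` emulates a cell-line x peptide
  phosphoproteome with matched total-peptide abundances, a low-rank
  covariance structure, and a planted "excess phosphorylation" signal in
  a known subset of peptides.

Everything is driven by :class:`numpy.random.Generator` under a fixed
seed, so identical configs reproduce identical outputs.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    COMPARTMENTS,
    STAGES,
    GeneratorConfig,
    config_hash,
    config_to_dict,
)
from .errors import InputError

__all__ = [
    "COMPARTMENT_AREA_COLUMNS",
    "PhosphoPanel",
    "generate_cell_population",
    "generate_phospho_panel",
    "read_cell_table",
    "write_cell_table",
]

#: Maps channel compartments to the table column holding that compartment's area.
COMPARTMENT_AREA_COLUMNS = {
    "whole_cell": "area",
    "nucleus": "nuclear_area",
    "cytoplasm": "cyto_area",
}

# Position of each stage's DNA mode between the low (2N) and high (4N)
# mixture modes, on a geometric scale: G0/G1 unreplicated, early S just
# past onset, S mid-replication, G2/M fully replicated.
_STAGE_DNA_POSITION = {"G0": 0.0, "G1": 0.0, "earlyS": 0.15, "S": 0.6, "G2": 1.0, "M": 1.0}


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with median 1 and the given CV.

    Median 1 (not mean 1) keeps the noise unbiased in log space, where
    all scaling fits are performed. With ``cv == 0`` the factor is
    exactly 1 so noiseless configs reproduce the power law bit-exactly.
    """
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(size))


def generate_cell_population(
    config: GeneratorConfig,
    n_cells: int | None = None,
    seed: int | None = None,
    line_id: str | None = None,
) -> pd.DataFrame:
    """Generate one synthetic cell line as a per-cell feature table.

    Parameters may be overridden per call without rebuilding the config.
    Returns a DataFrame with one row per cell and columns: identifiers
    and flags (``cell_id``, ``line_id``, ``true_stage``, ``mitotic_flag``,
    ``border_flag``), geometry (``area``, ``nuclear_area``, ``cyto_area``),
    crowding (``neighbour_fraction``), DNA stain (``dna_integrated``,
    ``hoechst_mean``, ``hoechst_max``), cycle markers (``pcna_mean``,
    ``ccna2_mean``, ``pcna_spottiness``) and, per channel,
    ``<name>_<compartment>_mean`` / ``..._integrated``.

    For every channel, mean intensity = ``a * area**b``, multiplied by
    ``dna_bin_factor`` for cells above the population median DNA content
    and by lognormal noise; integrated intensity = mean x compartment
    area, exactly.
    """
    n = config.n_cells if n_cells is None else int(n_cells)
    if n < 1:
        raise InputError("n_cells must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    line = config.line_id if line_id is None else line_id

    area = np.exp2(rng.normal(config.area_log_mean, config.area_log_sd, n))

    mitotic = rng.random(n) < config.mitotic_fraction
    stage_names = list(STAGES)
    probs = np.array([config.stage_mix.get(s, 0.0) for s in stage_names])
    stage_idx = rng.choice(len(stage_names), size=n, p=probs)
    stage = np.array(stage_names, dtype=object)[stage_idx]
    stage[mitotic] = "M"

    dna_cfg = config.dna_bimodal
    if config.stage_features is not None:
        pos = np.array([_STAGE_DNA_POSITION[s] for s in stage])
    else:
        pos = (rng.random(n) < dna_cfg.mixing_fraction).astype(float)
    mode = dna_cfg.low_mode * (dna_cfg.high_mode / dna_cfg.low_mode) ** pos
    dna = mode * _lognormal_factor(rng, dna_cfg.cv, n)

    nc = config.nuclear_coupling
    nuclear_area = nc.kappa * area**nc.gamma * _lognormal_factor(rng, nc.noise_cv, n)
    nuclear_area = np.minimum(nuclear_area, 0.9 * area)
    cyto_area = area - nuclear_area

    nf = rng.beta(*config.neighbour_beta, size=n)
    border = rng.random(n) < config.border_fraction

    # Condensed mitotic chromatin: bright, peaked Hoechst signal.
    hoechst_mean = dna / nuclear_area * _lognormal_factor(rng, 0.05, n)
    hoechst_mean[mitotic] *= 2.5
    hoechst_max = hoechst_mean * (1.6 + 0.2 * rng.random(n))
    hoechst_max[mitotic] *= 2.0

    table = pd.DataFrame(
        {
            "cell_id": [f"{line}-{i:06d}" for i in range(n)],
            "line_id": line,
            "true_stage": stage,
            "mitotic_flag": mitotic,
            "border_flag": border,
            "area": area,
            "nuclear_area": nuclear_area,
            "cyto_area": cyto_area,
            "neighbour_fraction": nf,
            "dna_integrated": dna,
            "hoechst_mean": hoechst_mean,
            "hoechst_max": hoechst_max,
        }
    )

    if config.stage_features is not None:
        for feat, col in (
            ("pcna", "pcna_mean"),
            ("ccna2", "ccna2_mean"),
            ("spottiness", "pcna_spottiness"),
        ):
            values = np.empty(n)
            for s in (*STAGES, "M"):  # fixed order keeps draws reproducible
                mask = stage == s
                if not mask.any():
                    continue
                mean, sd = getattr(config.stage_features[s], feat)
                values[mask] = rng.normal(mean, sd, mask.sum())
            table[col] = np.maximum(values, 0.0)

    # The DNA-bin amplitude factor is planted on the observable bin the
    # downstream analysis uses: cells above the population median DNA.
    high_dna = dna > np.median(dna)
    for ch in config.channels:
        mean = ch.a * area**ch.b
        if ch.dna_bin_factor != 1.0:
            mean = mean * np.where(high_dna, ch.dna_bin_factor, 1.0)
        mean = mean * _lognormal_factor(rng, ch.noise_cv, n)
        comp_area = table[COMPARTMENT_AREA_COLUMNS[ch.compartment]].to_numpy()
        table[f"{ch.column}_mean"] = mean
        table[f"{ch.column}_integrated"] = mean * comp_area

    return table


def write_cell_table(table: pd.DataFrame, path: str | Path, config: GeneratorConfig | None = None) -> None:
    """Write a cell table as CSV (9 significant digits) plus a JSON sidecar."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.9g")
    if config is not None:
        sidecar = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "n_cells": int(len(table)),
            "config": config_to_dict(config),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=2, default=str)
        )


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table CSV written by :func:`write_cell_table` (or Columbus-style exports)."""
    return pd.read_csv(path)


@dataclass
class PhosphoPanel:
    """Matched phospho- and total-peptide abundance matrices across cell lines.

    Attributes
    ----------
    phospho, total : DataFrame
        Cell lines (rows) x peptides (columns), strictly positive, with
        identical index and columns.
    response : Series
        Per-line scalar readout (e.g. mean nuclear YAP concentration).
    peptide_info : DataFrame
        Gene/site annotation per peptide.
    planted_truth : Series or None
        True per-peptide association weight with the response (non-zero
        exactly at the informative peptides); ``None`` for real data.
    seed : int or None
    """

    phospho: pd.DataFrame
    total: pd.DataFrame
    response: pd.Series
    peptide_info: pd.DataFrame
    planted_truth: pd.Series | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phospho.shape != self.total.shape:
            raise InputError("phospho and total matrices must share shape")
        if not (
            self.phospho.index.equals(self.total.index)
            and self.phospho.columns.equals(self.total.columns)
        ):
            raise InputError("phospho and total matrices must share index and columns")
        if not np.isfinite(self.response.to_numpy()).all():
            raise InputError("response must be finite")
        if (self.phospho.to_numpy() <= 0).any() or (self.total.to_numpy() <= 0).any():
            raise InputError("abundances must be strictly positive")

    @property
    def lines(self) -> list[str]:
        return list(self.phospho.index)

    @property
    def peptides(self) -> list[str]:
        return list(self.phospho.columns)

    def write(self, out_dir: str | Path) -> None:
        """Write the panel as two CSV matrices plus a JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.phospho.to_csv(out / "phospho.csv", float_format="%.9g")
        self.total.to_csv(out / "total.csv", float_format="%.9g")
        sidecar = {
            "response": {k: float(v) for k, v in self.response.items()},
            "planted_truth": (
                None
                if self.planted_truth is None
                else {k: float(v) for k, v in self.planted_truth.items() if v != 0}
            ),
            "seed": self.seed,
        }
        (out / "panel.json").write_text(json.dumps(sidecar, indent=2))


def generate_phospho_panel(
    n_lines: int = 8,
    n_peptides: int = 200,
    n_informative: int = 10,
    seed: int = 0,
    *,
    effect_size: float = 3.0,
    n_factors: int = 4,
    factor_sd: float = 1.0,
    noise_sd: float = 0.1,
    total_cv: float = 0.3,
    excess_scale: float = 0.1,
    config: GeneratorConfig | None = None,
) -> PhosphoPanel:
    """Generate a synthetic phospho/total peptide panel with planted signal.

    Total-peptide abundances are lognormal with a shared low-rank
    covariance across lines (``n_factors`` latent programs, constructed
    orthogonal to the response in sample: bulk protein abundance does not
    track the readout). Phospho abundance is an affine function of the
    matched total plus an "excess phosphorylation" term:
    ``phospho = alpha + beta * total + scale * excess``. The excess
    shares the same response-orthogonal latent factors (with independent
    loadings) plus idiosyncratic noise; for the ``n_informative`` planted
    peptides it additionally contains ``effect_size`` times the
    standardized response, with a random sign per peptide.

    Parameters
    ----------
    n_lines, n_peptides, n_informative : int
        Panel dimensions; defaults mirror an 8-line screen with 200
        quantified phosphopeptides of which 10 carry true signal.
    effect_size : float
        Planted association strength in excess-SD units.
    config : GeneratorConfig, optional
        Unused by the panel itself; accepted so pipeline configs can pass
        their generator config through for bookkeeping.

    Returns
    -------
    PhosphoPanel
    """
    if n_lines < 3:
        raise InputError("n_lines must be >= 3")
    if not (0 <= n_informative <= n_peptides):
        raise InputError("require 0 <= n_informative <= n_peptides")
    rng = np.random.default_rng(seed)

    y_raw = rng.standard_normal(n_lines)
    y_z = (y_raw - y_raw.mean()) / y_raw.std()
    response_values = 100.0 + 15.0 * y_z  # nuclear-YAP-like intensity scale

    log_base = rng.uniform(6.0, 10.0, n_peptides)
    base = np.exp(log_base)

    # Latent programs orthogonal (in sample) to the intercept and response.
    raw_factors = rng.standard_normal((n_lines, n_factors))
    basis = np.column_stack([np.ones(n_lines), y_z, raw_factors])
    q, _ = np.linalg.qr(basis)
    factors = q[:, 2 : 2 + n_factors] * math.sqrt(n_lines)

    # Totals: lognormal, low-rank in log space, orthogonal to the response.
    sigma_t = math.sqrt(math.log1p(total_cv**2))
    t_load = rng.normal(0.0, factor_sd, (n_factors, n_peptides))
    t_log = factors @ t_load + 0.3 * rng.standard_normal((n_lines, n_peptides))
    t_log = t_log - np.outer(y_z, y_z @ t_log) / n_lines
    t_log = t_log - t_log.mean(axis=0)
    t_sd = t_log.std(axis=0, ddof=0)
    t_log = t_log / np.where(t_sd > 0, t_sd, 1.0)
    total = base * np.exp(sigma_t * t_log)

    beta = rng.uniform(0.2, 1.0, n_peptides)
    alpha = rng.uniform(0.05, 0.3, n_peptides) * beta * base

    loadings = rng.normal(0.0, factor_sd, (n_factors, n_peptides))
    eps = rng.standard_normal((n_lines, n_peptides))
    excess = factors @ loadings + noise_sd * eps

    informative = np.sort(rng.choice(n_peptides, size=n_informative, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_informative)
    excess[:, informative] += effect_size * np.outer(y_z, signs)

    # Standardize excess per peptide so excess_scale sets its share of the
    # phospho abundance; zero-variance columns (no planted signal, no
    # noise) pass through as exact zeros.
    sd = excess.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    excess_std = excess / sd_safe

    phospho = alpha + beta * total + excess_scale * beta * base * excess_std
    floor = 1e-9 * base
    clipped = phospho < floor
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} phospho abundances clipped at the positivity floor",
            stacklevel=2,
        )
        phospho = np.maximum(phospho, floor)

    lines = [f"line_{i:02d}" for i in range(n_lines)]
    peptides = [f"pep{j:04d}" for j in range(n_peptides)]
    peptide_info = pd.DataFrame(
        {
            "gene": [f"GENE{j:04d}" for j in range(n_peptides)],
            "site": [f"S{5 * (j % 50) + 1}" for j in range(n_peptides)],
        },
        index=peptides,
    )
    truth = pd.Series(0.0, index=peptides, name="true_weight")
    truth.iloc[informative] = effect_size * signs

    return PhosphoPanel(
        phospho=pd.DataFrame(phospho, index=lines, columns=peptides),
        total=pd.DataFrame(total, index=lines, columns=peptides),
        response=pd.Series(response_values, index=lines, name="response"),
        peptide_info=peptide_info,
        planted_truth=truth,
        seed=seed,
    )
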