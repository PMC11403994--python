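"""Single-cell exclusion rules applied before any scaling fit.

Three rules, applied in the order a screening analysis would: drop
border/mitotic objects, drop crowded cells (neighbour fraction above a
cutoff), and restrict to a size window of +/- k standard deviations
about the mean area. Boundary semantics are "strictly greater is
excluded" for the neighbour fraction and a closed interval for the size
window, so cells sitting exactly on a threshold are kept.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "FilterConfig",
    "filter_border_and_mitotic",
    "filter_neighbour_fraction",
    "size_window",
    "qc_pipeline",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the QC rules.

    ``nf_max`` — neighbour-fraction cutoff (cells with NF strictly greater
    are excluded). ``sd_window_k`` — half-width of the size window in
    standard deviations (``math.inf`` disables it). ``hoechst_mean_max`` /
    ``hoechst_max_max`` — mitotic rule: a cell is called mitotic when it
    exceeds *both* Hoechst thresholds; used only when no ``mitotic_flag``
    column is present. ``window_on_log`` — compute the size window on
    log2 area instead of raw area.
    """

    nf_max: float = 0.7
    sd_window_k: float = 3.0
    hoechst_mean_max: float | None = None
    hoechst_max_max: float | None = None
    drop_border: bool = True
    window_on_log: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.nf_max <= 1.0):
            raise ValidationError("nf_max must be in [0, 1]")
        if not self.sd_window_k > 0:
            raise ValidationError("sd_window_k must be > 0")


def filter_border_and_mitotic(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Remove border objects and mitotic cells.

    Mitotic cells are identified by the ``mitotic_flag`` column when
    present, else by jointly exceeding both Hoechst thresholds (condensed
    chromatin is both brighter on average and more peaked). Row order is
    preserved; no rows are ever added.
    """
    keep = pd.Series(True, index=table.index)
    if cfg.drop_border:
        if "border_flag" not in table.columns:
            raise SchemaError(["border_flag"], "border filter")
        keep &= ~table["border_flag"].astype(bool)
    if "mitotic_flag" in table.columns:
        keep &= ~table["mitotic_flag"].astype(bool)
    elif cfg.hoechst_mean_max is not None and cfg.hoechst_max_max is not None:
        missing = [c for c in ("hoechst_mean", "hoechst_max") if c not in table.columns]
        if missing:
            raise SchemaError(missing, "mitotic filter")
        mitotic = (table["hoechst_mean"] > cfg.hoechst_mean_max) & (
            table["hoechst_max"] > cfg.hoechst_max_max
        )
        keep &= ~mitotic
    return table.loc[keep]


def filter_neighbour_fraction(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep cells whose neighbour fraction is <= ``nf_max``.

    Raises :class:`ValidationError` if any NF value lies outside [0, 1].
    """
    if "neighbour_fraction" not in table.columns:
        raise SchemaError(["neighbour_fraction"], "neighbour-fraction filter")
    nf = table["neighbour_fraction"].to_numpy()
    if len(nf) and ((nf < 0) | (nf > 1)).any():
        raise ValidationError("neighbour_fraction values must lie in [0, 1]")
    out = table.loc[nf <= cfg.nf_max] if len(nf) else table
    if len(table) and not len(out):
        warnings.warn("neighbour-fraction filter removed every cell", stacklevel=2)
    return out


def _window_bounds(areas: np.ndarray, k: float, on_log: bool) -> tuple[float, float]:
    if on_log:
        la = np.log2(areas)
        mu, sigma = la.mean(), la.std(ddof=0)
        return 2.0 ** (mu - k * sigma), 2.0 ** (mu + k * sigma)
    mu, sigma = areas.mean(), areas.std(ddof=0)
    return max(0.0, mu - k * sigma), mu + k * sigma


def size_window(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep cells within ``mean +/- k*SD`` of area, per group.

    Moments are computed within each ``line_id`` x ``dna_bin`` group when
    those columns are present (falling back to the whole table), and the
    clip is iterated to a fixed point (sigma-clipping) so that the
    retained set is self-consistent: the surviving cells all lie within
    k SD of the moments of the surviving cells, making the filter
    idempotent. The interval is closed, clipped below at zero.
    Single-row groups pass through unfiltered with a warning;
    ``sd_window_k == inf`` is the identity.
    """
    if "area" not in table.columns:
        raise SchemaError(["area"], "size window")
    if math.isinf(cfg.sd_window_k) or not len(table):
        return table
    group_cols = [c for c in ("line_id", "dna_bin") if c in table.columns]
    keep = pd.Series(True, index=table.index)
    groups = table.groupby(group_cols, sort=False) if group_cols else [(None, table)]
    for _, sub in groups:
        if len(sub) < 2:
            warnings.warn("size window skipped for single-row group", stacklevel=2)
            continue
        areas = sub["area"].to_numpy(dtype=float)
        mask = np.ones(len(areas), dtype=bool)
        while True:  # monotone shrink: terminates, and the result is a fixed point
            if mask.sum() < 2 or np.ptp(areas[mask]) == 0:
                break
            lo, hi = _window_bounds(areas[mask], cfg.sd_window_k, cfg.window_on_log)
            new_mask = mask & (areas >= lo) & (areas <= hi)
            if (new_mask == mask).all():
                break
            mask = new_mask
        keep.loc[sub.index] = mask
    return table.loc[keep]


def qc_pipeline(
    table: pd.DataFrame, cfg: FilterConfig, apply_nf: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Apply all filters in order and return the table plus a per-rule report."""
    report: dict = {"rows_in": int(len(table))}
    out = filter_border_and_mitotic(table, cfg)
    report["after_border_mitotic"] = int(len(out))
    if apply_nf:
        out = filter_neighbour_fraction(out, cfg)
        report["after_neighbour_fraction"] = int(len(out))
    out = size_window(out, cfg)
    report["after_size_window"] = int(len(out))
    report["rows_out"] = int(len(out))
    return out, report
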