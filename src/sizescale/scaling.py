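"""Power-law scaling of protein concentration/abundance with cell area.

The model is ``[Y] = a * A**b``: the mean compartment intensity of a
stained protein (a 2-D concentration proxy) as a power law in cell area
``A``. Taking logs, ``log2[Y] = log2(a) + b * log2(A)``, so ``b`` (the
scaling factor) is the slope of an ordinary least-squares fit in log-log
space and ``log2(a)`` the intercept. ``b < 0`` means the protein dilutes
as the cell grows (sub-scaling), ``b = 0`` size-invariant concentration,
``b > 0`` super-scaling. Abundance (integrated intensity = mean x
compartment area) obeys the same model with slope ``b + 1`` when the
regressor is the compartment area.

Cells are stratified into DNA-content bins either side of the per-line
median integrated DNA-stain intensity; the concentration offset between
bins at fixed size is ``2**(log2(a_high) - log2(a_low))``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InputError, SchemaError
from .qc import FilterConfig, size_window
from .synthetic import COMPARTMENT_AREA_COLUMNS

__all__ = [
    "BinnedProfile",
    "DnaBinning",
    "ScalingFit",
    "bin_by_dna",
    "binned_profile",
    "fit_power_law",
    "fold_factor",
    "scaling_report",
    "to_abundance",
]


@dataclass(frozen=True)
class ScalingFit:
    """Result of one log-log OLS fit.

    ``b`` is the scaling exponent, ``log2_a`` the intercept in log2
    intensity units, ``r2`` the coefficient of determination and
    ``r_log`` the Pearson correlation in log-log space. ``window`` is
    the (min, max) area range of the cells used.
    """

    channel: str
    compartment: str
    quantity: str
    b: float
    log2_a: float
    r2: float
    r_log: float
    n: int
    window: tuple[float, float]


def fit_power_law(
    areas,
    values,
    *,
    channel: str = "",
    compartment: str = "",
    quantity: str = "concentration",
) -> ScalingFit:
    """OLS fit of ``log2(values)`` on ``log2(areas)``.

    Parameters
    ----------
    areas, values : array-like of positive floats
        Equal-length, strictly positive. ``areas`` is the regressor (cell
        or compartment area), ``values`` the concentration or abundance.

    Returns
    -------
    ScalingFit
        With ``b`` = slope and ``log2_a`` = intercept. A zero-variance
        response returns ``b = 0``, ``log2_a`` = the constant and
        ``r2 = 1`` by convention, so constant channels flow through
        reports rather than erroring.

    Raises
    ------
    InputError
        On length mismatch or fewer than 2 points.
    DomainError
        On non-positive inputs or zero-variance areas.
    """
    a = np.asarray(areas, dtype=float)
    v = np.asarray(values, dtype=float)
    if a.shape != v.shape or a.ndim != 1:
        raise InputError("areas and values must be equal-length 1-D arrays")
    if a.size < 2:
        raise InputError("need at least 2 points to fit")
    if (a <= 0).any() or (v <= 0).any():
        raise DomainError("areas and values must be strictly positive")
    la = np.log2(a)
    lv = np.log2(v)
    window = (float(a.min()), float(a.max()))
    n = int(a.size)
    if np.ptp(lv) == 0:
        return ScalingFit(channel, compartment, quantity, 0.0, float(lv[0]), 1.0, 0.0, n, window)
    if np.ptp(la) == 0:
        raise DomainError("areas have zero variance; slope is undefined")
    la_c = la - la.mean()
    lv_c = lv - lv.mean()
    sxx = float(la_c @ la_c)
    sxy = float(la_c @ lv_c)
    syy = float(lv_c @ lv_c)
    b = sxy / sxx
    log2_a = float(lv.mean() - b * la.mean())
    r_log = sxy / np.sqrt(sxx * syy)
    return ScalingFit(
        channel,
        compartment,
        quantity,
        float(b),
        log2_a,
        float(r_log**2),
        float(r_log),
        n,
        window,
    )


@dataclass(frozen=True)
class DnaBinning:
    """Median split of integrated DNA content, computed per cell line.

    ``labels`` holds ``"low"`` (DNA <= per-line median) or ``"high"``
    per cell; the partition is exhaustive and disjoint, with ties at the
    median assigned to the low bin.
    """

    thresholds: dict
    labels: pd.Series


def bin_by_dna(table: pd.DataFrame, column: str = "dna_integrated") -> DnaBinning:
    """Split cells either side of the per-line median integrated DNA intensity."""
    if column not in table.columns:
        raise SchemaError([column], "DNA binning")
    if len(table) < 2:
        raise InputError("DNA binning needs at least 2 cells")
    line = table["line_id"] if "line_id" in table.columns else pd.Series("", index=table.index)
    thresholds: dict = {}
    labels = pd.Series("low", index=table.index, name="dna_bin")
    for line_id, sub in table.groupby(line, sort=False):
        med = float(sub[column].median())
        thresholds[line_id] = med
        if sub[column].nunique() == 1:
            warnings.warn(
                f"all DNA values identical in line {line_id!r}; every cell labelled low",
                stacklevel=2,
            )
            continue
        labels.loc[sub.index[sub[column] > med]] = "high"
    return DnaBinning(thresholds=thresholds, labels=labels)


def fold_factor(
    fit_low: ScalingFit, fit_high: ScalingFit, at_area: float | None = None
) -> float:
    """Concentration ratio between DNA bins at a fixed cell size.

    When the two fits share a slope this is exactly
    ``2**(log2a_high - log2a_low)``. With independently fitted (noisy)
    slopes the ratio is evaluated at ``at_area`` — by default the
    geometric mid-size of the two fit windows — because comparing raw
    intercepts extrapolates to unit area, far outside the measured
    range, and amplifies slope noise by that lever arm.
    """
    if (fit_low.channel, fit_low.compartment, fit_low.quantity) != (
        fit_high.channel,
        fit_high.compartment,
        fit_high.quantity,
    ):
        raise InputError("fold_factor requires fits of the same channel/compartment/quantity")
    if at_area is None:
        mids = [np.sqrt(f.window[0] * f.window[1]) for f in (fit_low, fit_high)]
        at_area = float(np.sqrt(mids[0] * mids[1]))
    la = np.log2(at_area)
    delta = (fit_high.log2_a + fit_high.b * la) - (fit_low.log2_a + fit_low.b * la)
    return float(2.0**delta)


def to_abundance(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Add/overwrite integrated-intensity columns for ``channel``.

    For every compartment with a ``<channel>_<compartment>_mean`` column,
    sets ``<channel>_<compartment>_integrated`` = mean x compartment area.
    """
    out = table.copy()
    found = False
    for comp, area_col in COMPARTMENT_AREA_COLUMNS.items():
        mean_col = f"{channel}_{comp}_mean"
        if mean_col not in table.columns:
            continue
        if area_col not in table.columns:
            raise SchemaError([area_col], f"abundance for {mean_col}")
        out[f"{channel}_{comp}_integrated"] = table[mean_col] * table[area_col]
        found = True
    if not found:
        raise SchemaError([f"{channel}_<compartment>_mean"], "to_abundance")
    return out


@dataclass(frozen=True)
class BinnedProfile:
    """Per-size-bin summary of a quantity, for display alongside the fits.

    ``edges`` are bin edges in log2 area (strictly increasing); per-bin
    mean/SD are NaN where ``counts`` is 0. ``n`` counts cells inside the
    window, ``n_total`` all cells offered.
    """

    column: str
    edges: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray
    n: int
    n_total: int


def binned_profile(
    table: pd.DataFrame,
    column: str,
    n_bins: int = 20,
    window: tuple[float, float] | str | None = None,
) -> BinnedProfile:
    """Mean/SD of ``column`` in equal-width log2-area bins.

    ``window`` restricts the area range: ``None`` spans the data,
    ``"display"`` uses 0.5x to 2x the mean area (the conventional
    display range), or pass explicit ``(area_min, area_max)``.
    """
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    for col in ("area", column):
        if col not in table.columns:
            raise SchemaError([col], "binned profile")
    if not len(table):
        raise InputError("binned_profile needs a non-empty table")
    areas = table["area"].to_numpy(dtype=float)
    values = table[column].to_numpy(dtype=float)
    if window == "display":
        mean_area = areas.mean()
        window = (0.5 * mean_area, 2.0 * mean_area)
    if window is None:
        lo, hi = areas.min(), areas.max()
        if hi == lo:  # all cells the same size: widen to a 4-fold display range
            lo, hi = lo / 2.0, hi * 2.0
    else:
        lo, hi = window
    if not (hi > lo > 0):
        raise InputError("window must satisfy 0 < area_min < area_max")
    edges = np.linspace(np.log2(lo), np.log2(hi), n_bins + 1)
    la = np.log2(areas)
    in_window = (la >= edges[0]) & (la <= edges[-1])
    idx = np.clip(np.searchsorted(edges, la[in_window], side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    vw = values[in_window]
    for k in range(n_bins):
        sel = vw[idx == k]
        if len(sel):
            means[k] = sel.mean()
            sds[k] = sel.std(ddof=0)
    return BinnedProfile(
        column=column,
        edges=edges,
        means=means,
        sds=sds,
        counts=counts,
        n=int(counts.sum()),
        n_total=int(len(table)),
    )


def _detect_channels(table: pd.DataFrame) -> list[tuple[str, str]]:
    """Infer (channel, compartment) pairs from ``*_<compartment>_mean`` columns."""
    pairs = []
    for col in table.columns:
        for comp in COMPARTMENT_AREA_COLUMNS:
            suffix = f"_{comp}_mean"
            if col.endswith(suffix):
                pairs.append((col[: -len(suffix)], comp))
    return pairs


def scaling_report(
    table: pd.DataFrame,
    cfg: FilterConfig | None = None,
    channels: list[tuple[str, str]] | None = None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Fit every line x channel x compartment x quantity x DNA bin group.

    For each cell line the cells are median-split by integrated DNA
    content; within each bin (plus the pooled ``"all"`` bin) the size
    window from ``cfg`` is applied and both the concentration (mean
    intensity) and abundance (integrated intensity) power laws are
    fitted against cell area. Groups smaller than ``min_cells`` are
    reported unfitted (``fitted = False``). High-bin rows carry
    ``fold_vs_low``, the intercept ratio ``2**(log2a_high - log2a_low)``
    against the matching low-bin fit.

    Returns a tidy DataFrame, one row per group.
    """
    if channels is None:
        channels = _detect_channels(table)
    if not channels:
        raise SchemaError(["<channel>_<compartment>_mean"], "scaling report")
    if "line_id" not in table.columns:
        table = table.assign(line_id="all")
    binning = bin_by_dna(table)
    work = table.assign(dna_bin=binning.labels)
    rows = []
    for line_id, line_tab in work.groupby("line_id", sort=False):
        for dna_bin in ("low", "high", "all"):
            sub = line_tab if dna_bin == "all" else line_tab[line_tab["dna_bin"] == dna_bin]
            if cfg is not None and len(sub) >= 2:
                sub = size_window(sub.drop(columns="dna_bin"), cfg)
            for name, comp in channels:
                for quantity, suffix in (("concentration", "mean"), ("abundance", "integrated")):
                    col = f"{name}_{comp}_{suffix}"
                    if col not in work.columns:
                        continue
                    row = {
                        "line_id": line_id,
                        "channel": name,
                        "compartment": comp,
                        "quantity": quantity,
                        "dna_bin": dna_bin,
                        "n": int(len(sub)),
                    }
                    if len(sub) < min_cells:
                        row.update(
                            b=np.nan, log2_a=np.nan, r2=np.nan, r_log=np.nan,
                            area_min=np.nan, area_max=np.nan, fitted=False,
                        )
                    else:
                        fit = fit_power_law(
                            sub["area"], sub[col],
                            channel=name, compartment=comp, quantity=quantity,
                        )
                        row.update(
                            b=fit.b, log2_a=fit.log2_a, r2=fit.r2, r_log=fit.r_log,
                            area_min=fit.window[0], area_max=fit.window[1], fitted=True,
                        )
                    rows.append(row)
    report = pd.DataFrame(rows)
    report["fold_vs_low"] = np.nan
    key_cols = ["line_id", "channel", "compartment", "quantity"]
    for _, grp in report.groupby(key_cols, sort=False):
        low = grp[(grp["dna_bin"] == "low") & grp["fitted"]]
        high = grp[(grp["dna_bin"] == "high") & grp["fitted"]]
        if len(low) == 1 and len(high) == 1:
            lo, hi = low.iloc[0], high.iloc[0]
            mid_lo = np.sqrt(lo["area_min"] * lo["area_max"])
            mid_hi = np.sqrt(hi["area_min"] * hi["area_max"])
            la = np.log2(np.sqrt(mid_lo * mid_hi))
            delta = (hi["log2_a"] + hi["b"] * la) - (lo["log2_a"] + lo["b"] * la)
            report.loc[high.index, "fold_vs_low"] = 2.0**delta
    return report
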