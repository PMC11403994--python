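"""Sequential cell-cycle stage calling from PCNA/CCNA2 features.

The procedure mirrors how replication-marker stains are read out in
high-content screens: PCNA expression rises from G1 through S/G2 and
its nuclear texture turns punctate ("spotty") during replication, while
CCNA2 accumulates toward G2. Calling is sequential:

1. mitotic cells (flag or classifier) are set aside as ``M``;
2. PCNA-negative nuclei are ``G0``;
3. PCNA+/CCNA2- nuclei are ``G1``;
4. PCNA+/CCNA2+ nuclei in the lowest quartile of CCNA2 are ``earlyS``;
5. the rest are split ``S`` (spotty PCNA) vs ``G2`` (smooth) by a
   linear classifier on texture features.

YAP intensity features are never inputs to any step, so stage labels
are independent of the quantity whose scaling they stratify. Integrated
DNA content is likewise excluded from classification and used only
post hoc to verify the S/G2 split.

Positivity thresholds default to Otsu splits of the per-line marker
distributions (absolute intensities are instrument-specific); the
spotty/smooth rule is a Fisher linear discriminant trained from
labelled examples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import InputError, SchemaError

__all__ = [
    "STAGE_ORDER",
    "ComparisonTable",
    "CycleConfig",
    "LinearClassifier",
    "VerificationReport",
    "classify_cell_cycle",
    "stage_size_comparison",
    "train_linear_classifier",
    "train_stage_classifiers",
    "verify_s_g2_by_dna",
]

#: Canonical ordering of stage labels through the cycle.
STAGE_ORDER = ("M", "G0", "G1", "earlyS", "S", "G2")


@dataclass(frozen=True)
class LinearClassifier:
    """Linear decision rule: predict ``classes[1]`` iff ``w . x + bias > 0``."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    classes: tuple
    training_accuracy: float | None = None

    def decision(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in table.columns]
            if missing:
                raise SchemaError(missing, "linear classifier")
            x = table[list(self.feature_names)].to_numpy(dtype=float)
        else:
            x = np.asarray(table, dtype=float)
        return x @ self.weights + self.bias

    def predict(self, table) -> np.ndarray:
        d = self.decision(table)
        neg, pos = self.classes
        return np.where(d > 0, pos, neg)


def train_linear_classifier(features, labels, feature_names=None) -> LinearClassifier:
    """Fit a Fisher linear discriminant to a two-class problem.

    The weight vector is the closed-form Fisher direction
    ``Sw^{-1} (mu_pos - mu_neg)`` with the pooled within-class scatter
    ``Sw``; the bias places the boundary at the midpoint of the
    projected class means (equal priors). Deterministic, no
    hyper-parameters — a stand-in for interactively trained screen
    classifiers, which are linear rules over the same feature families.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = tuple(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if feature_names is None:
            feature_names = tuple(f"f{i}" for i in range(x.shape[1]))
        feature_names = tuple(feature_names)
    y = np.asarray(labels)
    if np.isnan(x).any():
        raise InputError("features contain missing values")
    classes = sorted(pd.unique(y).tolist(), key=str)
    if len(classes) != 2:
        raise InputError(f"need exactly 2 classes, got {len(classes)}")
    neg, pos = classes
    x0, x1 = x[y == neg], x[y == pos]
    if len(x0) < 2 or len(x1) < 2:
        raise InputError("need at least 2 examples per class")
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    sw = np.cov(x0, rowvar=False, ddof=1) * (len(x0) - 1) + np.cov(
        x1, rowvar=False, ddof=1
    ) * (len(x1) - 1)
    sw = np.atleast_2d(sw) / (len(x0) + len(x1) - 2)
    d = sw.shape[0]
    # tiny ridge keeps the direction well-defined when classes have zero
    # within-class spread (perfectly separated toy inputs)
    eps = 1e-9 * (np.trace(sw) / d if np.trace(sw) > 0 else 1.0)
    w = np.linalg.pinv(sw + eps * np.eye(d)) @ (mu1 - mu0)
    bias = -0.5 * float(w @ (mu0 + mu1))
    clf = LinearClassifier(feature_names, w, bias, (neg, pos))
    acc = float((clf.predict(x) == y).mean())
    return LinearClassifier(feature_names, w, bias, (neg, pos), acc)


@dataclass(frozen=True)
class CycleConfig:
    """Thresholds and classifiers for the sequential calling procedure.

    ``None`` thresholds are replaced by per-line Otsu splits of the
    marker distribution. ``early_s_quantile`` is the CCNA2 quantile
    (within the PCNA+/CCNA2+ subpopulation, per line) below which cells
    are called early S. ``spotty_classifier`` separates S (positive
    side) from G2; when absent an Otsu split on ``pcna_spottiness`` is
    used as a fallback. ``mitotic_classifier`` is optional; the
    ``mitotic_flag`` column takes precedence when present.
    """

    pcna_pos_threshold: float | None = None
    ccna2_pos_threshold: float | None = None
    early_s_quantile: float = 0.25
    spotty_classifier: LinearClassifier | None = None
    mitotic_classifier: LinearClassifier | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.early_s_quantile < 1.0):
            raise InputError("early_s_quantile must be in (0, 1)")


def _otsu(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return float(values[0])
    return float(threshold_otsu(values))


def classify_cell_cycle(table: pd.DataFrame, cfg: CycleConfig | None = None) -> pd.Series:
    """Assign one stage label per cell by the sequential procedure.

    Returns a Series aligned with ``table`` holding labels from
    :data:`STAGE_ORDER`. Thresholds and the early-S quantile are
    computed per ``line_id`` when that column is present.
    """
    cfg = cfg or CycleConfig()
    required = ["pcna_mean", "ccna2_mean", "pcna_spottiness"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(missing, "cell-cycle classification")

    labels = pd.Series("", index=table.index, name="stage", dtype=object)

    # Step 1: mitosis, by flag or classifier; excluded from all later steps.
    if "mitotic_flag" in table.columns:
        mitotic = table["mitotic_flag"].astype(bool)
    elif cfg.mitotic_classifier is not None:
        mitotic = pd.Series(
            cfg.mitotic_classifier.decision(table) > 0, index=table.index
        )
    else:
        mitotic = pd.Series(False, index=table.index)
    labels[mitotic] = "M"

    inter = table.loc[~mitotic]
    line = (
        inter["line_id"] if "line_id" in inter.columns
        else pd.Series("", index=inter.index)
    )
    for _, sub in inter.groupby(line, sort=False):
        pcna = sub["pcna_mean"].to_numpy(dtype=float)
        ccna2 = sub["ccna2_mean"].to_numpy(dtype=float)

        pcna_thr = (
            cfg.pcna_pos_threshold if cfg.pcna_pos_threshold is not None else _otsu(pcna)
        )
        ccna2_thr = (
            cfg.ccna2_pos_threshold
            if cfg.ccna2_pos_threshold is not None
            else _otsu(ccna2)
        )

        g0 = pcna < pcna_thr
        g1 = ~g0 & (ccna2 < ccna2_thr)
        labels.loc[sub.index[g0]] = "G0"
        labels.loc[sub.index[g1]] = "G1"

        double_pos = ~g0 & ~g1
        if not double_pos.any():
            warnings.warn(
                "no PCNA+/CCNA2+ cells; early-S and S/G2 steps skipped",
                stacklevel=2,
            )
            continue
        dp = sub.loc[sub.index[double_pos]]
        q = float(np.quantile(dp["ccna2_mean"].to_numpy(dtype=float), cfg.early_s_quantile))
        early = dp["ccna2_mean"].to_numpy(dtype=float) < q
        labels.loc[dp.index[early]] = "earlyS"

        rest = dp.loc[dp.index[~early]]
        if not len(rest):
            continue
        if cfg.spotty_classifier is not None:
            labels.loc[rest.index] = cfg.spotty_classifier.predict(rest)
        else:
            spot = rest["pcna_spottiness"].to_numpy(dtype=float)
            labels.loc[rest.index] = np.where(spot > _otsu(spot), "S", "G2")
    return labels


def train_stage_classifiers(table: pd.DataFrame) -> CycleConfig:
    """Build a :class:`CycleConfig` whose spotty/smooth rule is trained on labels.

    Uses the ``true_stage`` column (standing in for the manual
    annotation a screening analyst would provide) to train the Fisher
    discriminant separating S from G2 on PCNA texture and CCNA2
    intensity. YAP and DNA-content features are deliberately excluded
    from the feature list.
    """
    if "true_stage" not in table.columns:
        raise SchemaError(["true_stage"], "stage classifier training")
    sg2 = table[table["true_stage"].isin(["S", "G2"])]
    clf = train_linear_classifier(
        sg2[["pcna_spottiness", "ccna2_mean"]], sg2["true_stage"].to_numpy()
    )
    # Fisher classes are sorted ("G2", "S"): positive side is S (spotty).
    return CycleConfig(spotty_classifier=clf)


@dataclass(frozen=True)
class VerificationReport:
    """Post-hoc DNA check of the S/G2 split: mean DNA should rise G1 < S < G2."""

    mean_dna: dict
    passed: bool | None
    applicable: bool
    message: str = ""


def verify_s_g2_by_dna(table: pd.DataFrame, labels: pd.Series) -> VerificationReport:
    """Verify classification against integrated DNA content, post hoc."""
    if "dna_integrated" not in table.columns:
        raise SchemaError(["dna_integrated"], "S/G2 verification")
    mean_dna = {
        stage: float(table.loc[labels == stage, "dna_integrated"].mean())
        for stage in STAGE_ORDER
        if (labels == stage).any()
    }
    needed = ("G1", "S", "G2")
    absent = [s for s in needed if s not in mean_dna]
    if absent:
        return VerificationReport(
            mean_dna, None, False, f"not applicable: no cells labelled {', '.join(absent)}"
        )
    passed = mean_dna["G1"] < mean_dna["S"] < mean_dna["G2"]
    return VerificationReport(mean_dna, bool(passed), True)


@dataclass(frozen=True)
class ComparisonTable:
    """Size-binned per-stage comparison of a quantity.

    ``summary`` has one row per stage x size bin (n, mean, sd);
    ``contrasts`` holds two-sided rank-sum p-values for adjacent stages
    within a bin and adjacent bins within a stage.
    """

    summary: pd.DataFrame
    contrasts: pd.DataFrame
    n_size_bins: int


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    # Degenerate case: identical constant samples carry no evidence.
    both = np.concatenate([x, y])
    if np.ptp(both) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def stage_size_comparison(
    table: pd.DataFrame,
    labels: pd.Series,
    n_size_bins: int = 4,
    value_column: str = "yap_whole_cell_mean",
    min_cells: int = 3,
) -> ComparisonTable:
    """Compare a quantity across cycle stages within cell-size bins.

    Interphase cells are split into ``n_size_bins`` area quantile bins;
    per stage x bin the mean of ``value_column`` is reported, and
    two-sided Wilcoxon rank-sum tests (exact for small untied samples)
    are run for adjacent stages within each bin and adjacent bins within
    each stage. Contrasts with fewer than ``min_cells`` cells on either
    side are skipped.
    """
    for col in ("area", value_column):
        if col not in table.columns:
            raise SchemaError([col], "stage-size comparison")
    work = table.assign(stage=labels.to_numpy())
    work = work[work["stage"] != "M"]
    stages = [s for s in STAGE_ORDER if s != "M" and (work["stage"] == s).any()]
    if len(stages) < 2:
        raise InputError("need at least 2 interphase stages present")
    work = work.assign(
        size_bin=pd.qcut(work["area"], n_size_bins, labels=False, duplicates="drop")
    )
    bins = sorted(work["size_bin"].unique())

    summary_rows = []
    groups: dict[tuple, np.ndarray] = {}
    for stage in stages:
        for b in bins:
            sel = work[(work["stage"] == stage) & (work["size_bin"] == b)]
            vals = sel[value_column].to_numpy(dtype=float)
            groups[(stage, b)] = vals
            summary_rows.append(
                {
                    "stage": stage,
                    "size_bin": int(b),
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=0) if len(vals) else np.nan,
                }
            )

    contrast_rows = []

    def add_contrast(kind, stage_a, bin_a, stage_b, bin_b):
        x, y = groups[(stage_a, bin_a)], groups[(stage_b, bin_b)]
        row = {
            "kind": kind,
            "stage_a": stage_a,
            "bin_a": int(bin_a),
            "stage_b": stage_b,
            "bin_b": int(bin_b),
            "n_a": len(x),
            "n_b": len(y),
        }
        if len(x) < min_cells or len(y) < min_cells:
            row.update(p_value=np.nan, skipped=True)
        else:
            row.update(p_value=_ranksum_p(x, y), skipped=False)
        contrast_rows.append(row)

    for b in bins:
        for s_a, s_b in zip(stages[:-1], stages[1:]):
            add_contrast("stage_within_bin", s_a, b, s_b, b)
    for stage in stages:
        for b_a, b_b in zip(bins[:-1], bins[1:]):
            add_contrast("bin_within_stage", stage, b_a, stage, b_b)

    return ComparisonTable(
        summary=pd.DataFrame(summary_rows),
        contrasts=pd.DataFrame(contrast_rows),
        n_size_bins=len(bins),
    )
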