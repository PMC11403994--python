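"""Excess-phosphorylation correction, PLSR, VIP scoring and hit calling.

Phosphopeptide abundance trivially tracks the abundance of its parent
peptide, so across a panel of cell lines the informative quantity is the
*excess* phosphorylation: the residual of phospho abundance after
regressing out the matched total-peptide abundance line-by-line. The
corrected matrix is then related to a per-line response (e.g. mean
nuclear YAP concentration) by partial least squares regression (PLS1,
NIPALS deflation), which tolerates the strong collinearity of
phosphoproteomes. Peptide influence is summarized by the variable
importance in projection,

    VIP_j = sqrt( J * sum_f SSY_f * w_jf^2 / SSY_total ),

with per-component unit-norm weight vectors ``w_f``, per-component
explained response sum of squares ``SSY_f``, ``J`` predictors and
``SSY_total = sum_f SSY_f``. Under this normalization
``sum_j VIP_j^2 = J`` identically, so VIP > 1 ("more important than
average") is the conventional hit threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InputError
from .synthetic import PhosphoPanel

__all__ = [
    "ComponentSelection",
    "CorrectedPhospho",
    "PLSRModel",
    "compute_vip",
    "correct_phospho",
    "fit_plsr",
    "select_components",
    "select_hits",
]


@dataclass
class CorrectedPhospho:
    """Excess-phosphorylation residual matrix plus per-peptide fit parameters.

    By the OLS normal equations, each peptide's residuals sum to zero
    across lines and are uncorrelated with that peptide's totals.
    """

    residuals: pd.DataFrame
    slopes: pd.Series
    intercepts: pd.Series
    flagged: list
    scale: str


def correct_phospho(panel: PhosphoPanel, scale: str = "zscore") -> CorrectedPhospho:
    """Regress each phosphopeptide on its matched total peptide; keep residuals.

    Parameters
    ----------
    panel : PhosphoPanel
        Matched phospho and total matrices (lines x peptides).
    scale : {"zscore", "none"}
        ``"zscore"`` standardizes each peptide's phospho and total
        vectors across lines before the per-peptide OLS (removing
        depth/loading differences between lines); ``"none"`` fits on raw
        abundances.

    Returns
    -------
    CorrectedPhospho
        Residual matrix with per-peptide slope/intercept. Peptides whose
        totals have zero variance are flagged and get centred phospho
        values as residuals.
    """
    if scale not in ("zscore", "none"):
        raise InputError("scale must be 'zscore' or 'none'")
    if len(panel.phospho) < 3:
        raise InputError("need at least 3 cell lines for the correction")
    p = panel.phospho.to_numpy(dtype=float)
    t = panel.total.to_numpy(dtype=float)

    if scale == "zscore":
        def zscore(m):
            sd = m.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            return (m - m.mean(axis=0)) / sd

        p = zscore(p)
        t = zscore(t)

    t_c = t - t.mean(axis=0)
    p_c = p - p.mean(axis=0)
    sxx = (t_c**2).sum(axis=0)
    sxy = (t_c * p_c).sum(axis=0)
    zero_var = sxx == 0
    slopes = np.where(zero_var, 0.0, sxy / np.where(zero_var, 1.0, sxx))
    intercepts = p.mean(axis=0) - slopes * t.mean(axis=0)
    residuals = p - (intercepts + slopes * t)

    flagged = [panel.peptides[j] for j in np.flatnonzero(zero_var)]
    if flagged:
        warnings.warn(
            f"{len(flagged)} peptides with zero-variance totals; residuals are centred phospho",
            stacklevel=2,
        )
    peptides = panel.phospho.columns
    return CorrectedPhospho(
        residuals=pd.DataFrame(residuals, index=panel.phospho.index, columns=peptides),
        slopes=pd.Series(slopes, index=peptides, name="slope"),
        intercepts=pd.Series(intercepts, index=peptides, name="intercept"),
        flagged=flagged,
        scale=scale,
    )


@dataclass
class PLSRModel:
    """Fitted PLS1 model.

    ``weights`` (J x F) holds the unit-norm weight vector of each
    component; ``ssy`` the explained response sum of squares per
    component (on the internally standardized response), with
    ``ssy_total = ssy.sum()``. ``coef`` is the regression coefficient
    vector on standardized predictors.
    """

    n_components: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    ssy: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    feature_names: list
    cv_curve: np.ndarray | None = None

    @property
    def ssy_total(self) -> float:
        return float(self.ssy.sum())

    @property
    def coef(self) -> np.ndarray:
        w, p, q = self.weights, self.x_loadings, self.y_loadings
        return w @ np.linalg.solve(p.T @ w, q)

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        xs = (x - self.x_mean) / self.x_std
        return self.y_mean + self.y_std * (xs @ self.coef)

    def training_mse(self, X, y) -> float:
        return float(np.mean((self.predict(X) - np.asarray(y, dtype=float)) ** 2))


def _standardize_xy(X, y):
    x = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    x_mean = x.mean(axis=0)
    x_std = x.std(axis=0, ddof=1)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_mean = float(yv.mean())
    y_std = float(yv.std(ddof=1)) or 1.0
    return (x - x_mean) / x_std, (yv - y_mean) / y_std, x_mean, x_std, y_mean, y_std


def fit_plsr(X, y, n_components: int, standardize: bool = True, feature_names=None) -> PLSRModel:
    """Fit PLS1 by NIPALS-style sequential deflation.

    Per component: ``w = X'y / ||X'y||`` (unit norm), scores ``t = Xw``,
    loadings ``p = X't / t't``, ``q = y't / t't``, then X and y are
    deflated. ``SSY_f = q_f^2 * t_f't_f`` is the response sum of squares
    captured by component ``f``. Components beyond the effective rank
    are truncated with a warning. Predictors are z-scored per column and
    the response centred/scaled internally when ``standardize`` is set
    (pass ``False`` for pre-processed inputs).
    """
    if n_components < 1:
        raise InputError("n_components must be >= 1")
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    x = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(x.shape[1])]
    if standardize:
        xs, ys, x_mean, x_std, y_mean, y_std = _standardize_xy(x, y)
    else:
        xs = x.copy()
        ys = np.asarray(y, dtype=float).ravel().copy()
        x_mean, x_std = np.zeros(x.shape[1]), np.ones(x.shape[1])
        y_mean, y_std = 0.0, 1.0

    n, j = xs.shape
    max_rank = min(n - 1, j) if n > 1 else 1
    weights, loadings, qs, scores, ssy = [], [], [], [], []
    xd, yd = xs.copy(), ys.copy()
    tol = 1e-12 * max(1.0, float(np.abs(xs).max()) ** 2)
    for _ in range(n_components):
        if len(weights) >= max_rank:
            break
        w = xd.T @ yd
        nw = float(np.linalg.norm(w))
        if nw <= tol:
            break
        w = w / nw
        t = xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p = xd.T @ t / tt
        q = float(yd @ t / tt)
        xd = xd - np.outer(t, p)
        yd = yd - q * t
        weights.append(w)
        loadings.append(p)
        qs.append(q)
        scores.append(t)
        ssy.append(q * q * tt)
    if not weights:
        raise DomainError("response is orthogonal to all predictors; no component can be fit")
    if len(weights) < n_components:
        warnings.warn(
            f"requested {n_components} components, rank supports {len(weights)}; truncated",
            stacklevel=2,
        )
    return PLSRModel(
        n_components=len(weights),
        weights=np.column_stack(weights),
        x_loadings=np.column_stack(loadings),
        y_loadings=np.array(qs),
        scores=np.column_stack(scores),
        ssy=np.array(ssy),
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        feature_names=list(feature_names),
    )


@dataclass
class ComponentSelection:
    """Cross-validated component count plus the full CV error curve."""

    n_components: int
    cv_mse: np.ndarray  # indexed by F - 1
    mse_baseline: float  # mean-only model
    folds_used: int
    low_signal: bool


def select_components(
    X,
    y,
    max_components: int | None = None,
    folds: int = 10,
    seed: int = 0,
    improvement: float = 0.05,
) -> ComponentSelection:
    """Pick the PLSR component count by cross-validated elbow.

    ``folds`` is capped at the sample count (leave-one-out below the
    requested fold number, the typical situation for small cell-line
    panels). The per-F CV mean squared error is computed under a fixed
    fold assignment from ``seed``; the elbow keeps adding components
    while each one improves the CV MSE by at least ``improvement``
    (relative), stopping at the first that does not.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    x = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if n < 3:
        raise InputError("need at least 3 samples for cross-validation")
    if max_components is None:
        max_components = min(n - 1, x.shape[1])
    max_components = min(max_components, n - 1, x.shape[1])
    if max_components < 1:
        raise InputError("max_components must be >= 1")

    folds_used = min(folds, n)
    if folds_used == n:
        assignment = np.arange(n)  # leave-one-out: deterministic
    else:
        rng = np.random.default_rng(seed)
        assignment = np.repeat(np.arange(folds_used), -(-n // folds_used))[:n]
        rng.shuffle(assignment)

    sq_err = np.zeros((max_components, n))
    base_err = np.zeros(n)
    for k in range(folds_used):
        test = assignment == k
        train = ~test
        base_err[test] = (yv[test] - yv[train].mean()) ** 2
        fold_max = min(max_components, int(train.sum()) - 1)
        try:
            model = fit_plsr(x[train], yv[train], fold_max)
        except DomainError:
            for f in range(max_components):
                sq_err[f, test] = base_err[test]
            continue
        for f in range(1, max_components + 1):
            if f <= model.n_components:
                sub = PLSRModel(
                    n_components=f,
                    weights=model.weights[:, :f],
                    x_loadings=model.x_loadings[:, :f],
                    y_loadings=model.y_loadings[:f],
                    scores=model.scores[:, :f],
                    ssy=model.ssy[:f],
                    x_mean=model.x_mean,
                    x_std=model.x_std,
                    y_mean=model.y_mean,
                    y_std=model.y_std,
                    feature_names=model.feature_names,
                )
                pred = sub.predict(x[test])
            else:
                pred = model.predict(x[test])
            sq_err[f - 1, test] = (yv[test] - pred) ** 2

    cv_mse = sq_err.mean(axis=1)
    mse_baseline = float(base_err.mean())
    best = 1
    for f in range(2, max_components + 1):
        prev, cur = cv_mse[f - 2], cv_mse[f - 1]
        if prev > 0 and (prev - cur) / prev >= improvement:
            best = f
        else:
            break
    low_signal = bool(cv_mse[best - 1] >= 0.9 * mse_baseline)
    return ComponentSelection(best, cv_mse, mse_baseline, folds_used, low_signal)


def compute_vip(model: PLSRModel, peptide_info: pd.DataFrame | None = None) -> pd.DataFrame:
    """Variable importance in projection for every predictor.

    Returns a DataFrame indexed by predictor with columns ``vip``,
    ``hit`` (VIP strictly > 1) and ``sign`` (sign of the PLSR
    regression coefficient); gene/site annotation columns are joined in
    when ``peptide_info`` is given.
    """
    if model.ssy_total <= 0:
        raise DomainError("SSY_total is zero; VIP is undefined")
    j = model.weights.shape[0]
    vip = np.sqrt(j * (model.weights**2 @ model.ssy) / model.ssy_total)
    table = pd.DataFrame(
        {
            "vip": vip,
            "hit": vip > 1.0,
            "sign": np.sign(model.coef).astype(int),
        },
        index=pd.Index(model.feature_names, name="peptide"),
    )
    if peptide_info is not None:
        table = peptide_info.join(table, how="right")
    return table


def select_hits(vip_table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Peptides with VIP strictly above ``threshold``, ranked descending.

    The returned frame carries a ``rank`` column (1 = most important),
    suitable as a pre-ranked list for downstream enrichment tools.
    """
    hits = vip_table[vip_table["vip"] > threshold].sort_values("vip", ascending=False)
    hits = hits.copy()
    hits["rank"] = np.arange(1, len(hits) + 1)
    return hits
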