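"""Downstream statistics: quantile normalization, PCA, divergent-group
selection on loadings, trend smoothing, ANOVA/Tukey/t-test group calls,
signed fifth-power correlation heatmaps, and the seed power-law model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

LOG_OFFSET = 1.0
LOWESS_SPAN = 0.6


# --- normalization ------------------------------------------------------


@dataclass
class NormalizedMatrix:
    """features x samples matrix after quantile norm, log, center-scale."""

    values: np.ndarray
    feature_ids: list
    sample_ids: list
    constant_features: list = field(default_factory=list)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile normalization across columns; ties get the mean of the
    tied-rank reference values."""
    matrix = np.asarray(matrix, dtype=float)
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    n = matrix.shape[0]
    for j in range(matrix.shape[1]):
        ranks = sps.rankdata(matrix[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return out


def normalize(table: pd.DataFrame) -> NormalizedMatrix:
    """Quantile-normalize, log-transform (ln, +1 offset), center & scale rows.

    ``table``: features x samples frame of raw intensities (zeros allowed;
    offset by +1 before the log). Constant rows are centered but not
    scaled, and flagged.
    """
    values = table.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("raw intensities must be non-negative")
    qn = quantile_normalize(values)
    logged = np.log(qn + LOG_OFFSET)
    means = logged.mean(axis=1, keepdims=True)
    sds = logged.std(axis=1, ddof=0, keepdims=True)
    constant = np.where(sds.ravel() == 0)[0]
    safe_sds = np.where(sds == 0, 1.0, sds)
    scaled = (logged - means) / safe_sds
    if constant.size:
        logger.warning("normalize: %d constant feature rows left unscaled", constant.size)
    return NormalizedMatrix(
        values=scaled,
        feature_ids=list(table.index),
        sample_ids=list(table.columns),
        constant_features=[table.index[i] for i in constant],
    )


# --- PCA ----------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    variance_fractions: np.ndarray


def run_pca(matrix: NormalizedMatrix, n_components: int | None = None) -> PCAResult:
    """SVD-based PCA with samples as observations (features as variables)."""
    x = matrix.values.T  # samples x features
    if x.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = n_components or s.size
    var = s**2
    return PCAResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        variance_fractions=var[:k] / var.sum(),
    )


# --- divergent group selection ------------------------------------------


@dataclass
class SelectionResult:
    trend_up: list
    trend_down: list
    threshold_quantile: float


def select_divergent_groups(
    pca: PCAResult,
    feature_ids: list,
    component: int = 0,
    loading_quantile: float = 0.95,
) -> SelectionResult:
    """Split high-|loading| features of one component into up/down sets.

    The threshold is the per-sign ``loading_quantile`` of the loading
    magnitudes; if a quantile leaves both sets empty it is stepped down
    until something is selected (or gives up at 0.5).
    """
    if component >= pca.loadings.shape[1]:
        raise ValueError(f"component {component} not available")
    load = pca.loadings[:, component]
    q = loading_quantile
    while True:
        pos = load[load > 0]
        neg = -load[load < 0]
        thr_pos = np.quantile(pos, q) if pos.size else np.inf
        thr_neg = np.quantile(neg, q) if neg.size else np.inf
        up = [feature_ids[i] for i in np.where(load > 0)[0] if load[i] >= thr_pos]
        down = [feature_ids[i] for i in np.where(load < 0)[0] if -load[i] >= thr_neg]
        if up or down or q <= 0.5:
            if not (up or down):
                logger.warning("select_divergent_groups: nothing selectable")
            return SelectionResult(trend_up=up, trend_down=down, threshold_quantile=q)
        q = max(0.5, q - 0.05)
        logger.info("selection threshold stepped down to %.2f", q)


# --- trends -------------------------------------------------------------


@dataclass
class TrendResult:
    per_feature: dict
    group_summary: dict  # group name -> (grid, mean curve)


def trend_curves(
    matrix: NormalizedMatrix,
    groups: dict[str, list],
    covariate: np.ndarray,
    method: str = "lowess",
    span: float = LOWESS_SPAN,
) -> TrendResult:
    """Smoothed per-feature series and per-group mean curves.

    ``covariate``: one value per sample (stage index or dry weight).
    With fewer than 4 samples, or method "mean-by-stage", values are
    averaged per distinct covariate level.
    """
    covariate = np.asarray(covariate, dtype=float)
    if covariate.size != len(matrix.sample_ids):
        raise ValueError("covariate length must match sample count")
    order = np.argsort(covariate)
    idx = {fid: i for i, fid in enumerate(matrix.feature_ids)}
    use_lowess = method == "lowess" and covariate.size >= 4
    if method == "lowess" and not use_lowess:
        logger.warning("too few samples for lowess; falling back to mean-by-stage")

    per_feature = {}
    group_summary = {}
    for name, members in groups.items():
        curves = []
        for fid in members:
            y = matrix.values[idx[fid]]
            if use_lowess:
                from statsmodels.nonparametric.smoothers_lowess import lowess

                smoothed = lowess(
                    y[order], covariate[order], frac=span, return_sorted=False
                )
                grid = covariate[order]
            else:
                grid, inverse = np.unique(covariate[order], return_inverse=True)
                smoothed = np.array(
                    [y[order][inverse == k].mean() for k in range(grid.size)]
                )
            per_feature[fid] = (grid, smoothed)
            curves.append(smoothed)
        if curves:
            group_summary[name] = (per_feature[members[0]][0], np.mean(curves, axis=0))
    return TrendResult(per_feature=per_feature, group_summary=group_summary)


# --- group tests --------------------------------------------------------


@dataclass
class GroupTestResult:
    anova_p: float
    letters: dict[str, str]
    ttest_p: float | None = None


def tukey_letters(reject: dict[tuple[str, str], bool], means: dict[str, float]) -> dict[str, str]:
    """Compact letter display from pairwise rejection calls.

    Insert-and-absorb: groups sorted by descending mean; each letter marks
    a maximal set of mutually non-different groups.
    """
    names = sorted(means, key=lambda g: -means[g])

    def differ(a, b):
        return reject.get((a, b), reject.get((b, a), False))

    letter_sets: list[list[str]] = []
    for g in names:
        placed = False
        for s in letter_sets:
            if not any(differ(g, member) for member in s):
                s.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(set(s) < set(t) for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def group_tests(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> GroupTestResult:
    """One-way ANOVA, Tukey HSD letters, and (for 2 groups) a Welch t-test."""
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >=2 groups with >=2 replicates each")
    arrays = list(groups.values())
    if all(np.ptp(v) == 0 for v in arrays) and len({v[0] for v in arrays}) == 1:
        logger.warning("group_tests: zero variance everywhere; p undefined")
        return GroupTestResult(anova_p=float("nan"), letters={g: "a" for g in groups})

    anova_p = float(sps.f_oneway(*arrays).pvalue)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    data = np.concatenate(arrays)
    labels = np.concatenate([[g] * groups[g].size for g in names])
    hsd = pairwise_tukeyhsd(data, labels, alpha=alpha)
    reject = {}
    for (a, b), rej in zip(
        [(str(x[0]), str(x[1])) for x in hsd.summary().data[1:]], hsd.reject
    ):
        reject[(a, b)] = bool(rej)
    means = {g: float(groups[g].mean()) for g in names}
    letters = tukey_letters(reject, means)

    ttest_p = None
    if len(groups) == 2:
        ttest_p = float(sps.ttest_ind(*arrays, equal_var=False).pvalue)
    return GroupTestResult(anova_p=anova_p, letters=letters, ttest_p=ttest_p)


# --- correlation heatmap ------------------------------------------------


@dataclass
class HeatmapResult:
    matrix: np.ndarray  # signed r^5 entries, rows A x cols B
    row_order: np.ndarray
    col_order: np.ndarray
    masked_rows: list
    masked_cols: list


def correlation_heatmap(rows_a: pd.DataFrame, rows_b: pd.DataFrame) -> HeatmapResult:
    """Signed fifth-power Pearson correlations between two feature sets.

    Entries are r^5 (the odd power preserves sign while shrinking weak
    correlations); rows and columns are ordered by average-linkage
    hierarchical clustering on within-set correlation distance. Constant
    rows yield undefined correlations and are masked (NaN).
    """
    common = [s for s in rows_a.columns if s in set(rows_b.columns)]
    if len(common) < 3:
        raise ValueError("need >=3 common samples")
    a = rows_a[common].to_numpy(dtype=float)
    b = rows_b[common].to_numpy(dtype=float)
    masked_rows = [rows_a.index[i] for i in np.where(a.std(axis=1) == 0)[0]]
    masked_cols = [rows_b.index[i] for i in np.where(b.std(axis=1) == 0)[0]]

    def safe_corr(x, y):
        full = np.corrcoef(np.vstack([x, y]))
        return full[: x.shape[0], x.shape[0]:]

    with np.errstate(invalid="ignore", divide="ignore"):
        r = safe_corr(a, b)
        signed = np.sign(r) * np.abs(r) ** 5

    def cluster_order(x):
        if x.shape[0] < 3:
            return np.arange(x.shape[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x)
        c = np.nan_to_num(c, nan=0.0)
        d = np.clip(1.0 - c, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        return leaves_list(average(squareform(d, checks=False)))

    return HeatmapResult(
        matrix=signed,
        row_order=cluster_order(a),
        col_order=cluster_order(b),
        masked_rows=masked_rows,
        masked_cols=masked_cols,
    )


# --- power law and PC prediction ----------------------------------------


@dataclass
class PowerLawFit:
    a: float
    b: float
    r_squared: float
    converged: bool = True


def fit_power_law(dw: np.ndarray, tac: np.ndarray, log_space: bool = False) -> PowerLawFit:
    """Fit TAC = a * DW^b.

    Default: nonlinear least squares on the original scale, initialized
    from the log-log linear fit; R^2 on the original scale. ``log_space``
    reports the log-log fit directly (spreadsheet-trendline equivalent).
    """
    dw = np.asarray(dw, dtype=float)
    tac = np.asarray(tac, dtype=float)
    if np.any(dw <= 0) or np.any(tac <= 0):
        raise ValueError("power-law fit requires positive DW and TAC")
    slope, intercept = np.polyfit(np.log(dw), np.log(tac), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)

    def r2(a, b):
        pred = a * dw**b
        ss_res = float(np.sum((tac - pred) ** 2))
        ss_tot = float(np.sum((tac - tac.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if log_space:
        return PowerLawFit(a=a0, b=b0, r_squared=r2(a0, b0))
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * x**b, dw, tac, p0=[a0, b0], maxfev=10000
        )
        return PowerLawFit(a=float(popt[0]), b=float(popt[1]), r_squared=r2(*popt))
    except RuntimeError:
        logger.warning("power-law fit did not converge; reporting log-log fallback")
        return PowerLawFit(a=a0, b=b0, r_squared=r2(a0, b0), converged=False)


def predict_tac_from_pc(scores: np.ndarray, tac: np.ndarray) -> float:
    """R^2 of the OLS regression of TAC on one principal-component score."""
    scores = np.asarray(scores, dtype=float)
    tac = np.asarray(tac, dtype=float)
    x = np.column_stack([np.ones_like(scores), scores])
    beta, *_ = np.linalg.lstsq(x, tac, rcond=None)
    pred = x @ beta
    ss_res = float(np.sum((tac - pred) ** 2))
    ss_tot = float(np.sum((tac - tac.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
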