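"""PCA on expressed log-expression with bootstrap confidence intervals.

Samples are the observations and transcripts the features. The data are
transcript-centered but not variance-scaled before decomposition.
Component signs are canonicalized (largest-magnitude loading positive)
so repeated runs agree. Sampling variability is estimated by a
stratified bootstrap that resamples replicate samples within each
tissue, preserving the design; percentile confidence intervals are
reported after sign-aligning every bootstrap component to the point
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DataModelError


@dataclass
class PCAxisResult:
    scores: pd.DataFrame               # samples × components
    variance_explained: np.ndarray     # fractions, non-increasing
    loadings: pd.DataFrame             # transcripts × components
    transcript_correlations: pd.DataFrame | None = None  # r, r2 vs chosen PC
    ci99: pd.DataFrame | None = None   # per-transcript (lo, hi) for r2
    variance_ci: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    excluded_tissues: list[str] = field(default_factory=list)


def expressed_mask(
    fpkm_log: pd.DataFrame, metadata: pd.DataFrame, threshold: float = 1.0
) -> pd.Series:
    """Expressed for PCA: mean log2(FPKM+1) > threshold in ≥1 tissue."""
    tissues = list(dict.fromkeys(metadata["tissue"]))
    mask = pd.Series(False, index=fpkm_log.index)
    for t in tissues:
        cols = metadata.index[metadata["tissue"] == t]
        mask |= fpkm_log[cols].mean(axis=1) > threshold
    return mask


def run_pca(
    log_expr: pd.DataFrame,
    expressed_filter: pd.Series | None = None,
    n_components: int | None = None,
) -> PCAxisResult:
    """PCA of samples in transcript space (centering only)."""
    X = log_expr if expressed_filter is None else log_expr.loc[expressed_filter]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise DataModelError("need at least 2 transcripts and 2 samples after filtering")
    M = X.to_numpy(dtype=float).T            # samples × transcripts
    M = M - M.mean(axis=0, keepdims=True)    # center each transcript
    if not np.any(M):
        raise DataModelError("matrix is constant after centering; PCA undefined")

    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # canonical sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    var = S**2
    frac = var / var.sum()
    k = n_components or len(S)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U[:, :k] * S[:k]), index=X.columns, columns=comp_names)
    loadings = pd.DataFrame(Vt[:k].T, index=X.index, columns=comp_names)
    return PCAxisResult(scores=scores, variance_explained=frac[:k], loadings=loadings)


def correlate_with_pc(
    log_expr: pd.DataFrame, scores: pd.DataFrame, component: int = 1
) -> pd.DataFrame:
    """Pearson r (and R² = r²) of each transcript with a PC score vector.

    Constant transcripts have undefined correlation and come back NaN.
    """
    col = f"PC{component}"
    if col not in scores.columns:
        raise DataModelError(f"component {component} not present in scores")
    if list(scores.index) != list(log_expr.columns):
        raise DataModelError("scores index does not match expression samples")

    X = log_expr.to_numpy(dtype=float)
    y = scores[col].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return pd.DataFrame({"r": r, "r2": r**2}, index=log_expr.index)


def rank_by_pc_correlation(correlations: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top transcripts by R², ties broken by transcript id; keeps sign of r."""
    ranked = correlations.dropna().copy()
    ranked["_id"] = ranked.index
    ranked = ranked.sort_values(["r2", "_id"], ascending=[False, True]).drop(columns="_id")
    ranked["sign"] = np.sign(ranked["r"]).astype(int)
    return ranked.head(top_n)


def bootstrap_pca(
    log_expr: pd.DataFrame,
    metadata: pd.DataFrame,
    n_boot: int = 10000,
    ci: float = 0.99,
    seed: int | None = None,
    component: int = 1,
    transcripts: list[str] | None = None,
) -> PCAxisResult:
    """Stratified bootstrap of the PCA over replicates within tissue.

    Returns the point-estimate PCA augmented with a percentile CI for
    the chosen component's variance fraction and, if ``transcripts`` is
    given, per-transcript percentile CIs for their R² with that
    component. Tissues with a single replicate cannot be resampled and
    are excluded with a warning.
    """
    if seed is None:
        raise DataModelError("seed is mandatory for bootstrap_pca")
    if not 0 < ci < 1:
        raise DataModelError("ci must be in (0, 1)")

    sizes = metadata.groupby("tissue").size()
    singles = list(sizes[sizes < 2].index)
    if singles:
        import logging

        logging.getLogger(__name__).warning(
            "excluding single-replicate tissues from bootstrap: %s", singles
        )
    meta = metadata[~metadata["tissue"].isin(singles)]
    expr = log_expr[list(meta.index)]

    point = run_pca(expr)
    point.seed = seed
    point.n_boot = n_boot
    point.excluded_tissues = singles
    ref_scores = point.scores[f"PC{component}"]
    if transcripts:
        point.transcript_correlations = correlate_with_pc(
            expr, point.scores, component
        ).loc[transcripts]

    rng = np.random.default_rng(seed)
    tissue_groups = [np.flatnonzero((meta["tissue"] == t).to_numpy())
                     for t in dict.fromkeys(meta["tissue"])]
    X = expr.to_numpy(dtype=float)
    ref = ref_scores.to_numpy()

    var_frac = np.empty(n_boot)
    r2_boot = np.empty((n_boot, len(transcripts))) if transcripts else None
    t_rows = [expr.index.get_loc(t) for t in transcripts] if transcripts else []

    kc = component - 1
    for b in range(n_boot):
        idx = np.concatenate([g[rng.integers(0, len(g), size=len(g))] for g in tissue_groups])
        M = X[:, idx].T
        M = M - M.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(M, full_matrices=False)
        var = S**2
        var_frac[b] = var[kc] / var.sum()
        if transcripts:
            sc = U[:, kc] * S[kc]
            # sign-align to the point estimate restricted to resampled samples
            if np.dot(sc, ref[idx]) < 0:
                sc = -sc
            sub = X[np.ix_(t_rows, idx)]
            sub_c = sub - sub.mean(axis=1, keepdims=True)
            sc_c = sc - sc.mean()
            denom = np.sqrt((sub_c**2).sum(axis=1)) * np.sqrt((sc_c**2).sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (sub_c @ sc_c) / denom
            r2_boot[b] = r**2

    alpha = (1.0 - ci) / 2.0
    point.variance_ci = (
        float(np.quantile(var_frac, alpha)),
        float(np.quantile(var_frac, 1 - alpha)),
    )
    if transcripts:
        point.ci99 = pd.DataFrame(
            {
                "lo": np.quantile(r2_boot, alpha, axis=0),
                "hi": np.quantile(r2_boot, 1 - alpha, axis=0),
            },
            index=transcripts,
        )
    return point


def fisher_z_ci(r: float, n: int, ci: float = 0.99) -> tuple[float, float]:
    """Analytic Fisher-z CI for a Pearson correlation (optional alternative)."""
    from scipy import stats

    if not -1 < r < 1:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(1 - (1 - ci) / 2)
    return (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
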