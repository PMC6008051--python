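"""Expressed-transcript calling, one-way ANOVA + BH differential expression.

The testing convention throughout: a transcript is *expressed* at mean
FPKM > 1 in at least one tissue of the analysed subset; differential
expression among a tissue subset is a fixed-effects one-way ANOVA on
log2(FPKM+1) values, corrected per analysis with Benjamini–Hochberg
q-values; a call is significant when q < 0.01 and the fold change of
raw-FPKM tissue means (max/min, with a 0.1 pseudocount) exceeds 2.

Degenerate inputs follow deterministic tie rules: all groups identical
gives F = 0, p = 1; nonzero between-group signal with zero within-group
variance gives p floored at 1e-300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataModelError

FC_EPSILON = 0.1          # pseudocount inside fold-change ratios
P_FLOOR = 1e-300          # reported p for zero within-group variance with signal
DEFAULT_Q = 0.01
DEFAULT_FC = 2.0


@dataclass
class ExpressionCallSet:
    """Per-tissue boolean expression calls (mean FPKM > threshold)."""

    per_tissue: pd.DataFrame   # transcripts × tissues, boolean
    threshold: float

    @property
    def any_tissue(self) -> pd.Series:
        return self.per_tissue.any(axis=1)

    @property
    def all_tissue(self) -> pd.Series:
        return self.per_tissue.all(axis=1)


def call_expressed(
    fpkm: pd.DataFrame, metadata: pd.DataFrame, threshold: float = 1.0
) -> ExpressionCallSet:
    """expressed(tissue) iff mean FPKM over that tissue's replicates > threshold."""
    tissues = list(dict.fromkeys(metadata["tissue"]))
    calls = {}
    for t in tissues:
        cols = metadata.index[metadata["tissue"] == t]
        calls[t] = fpkm[cols].mean(axis=1) > threshold
    return ExpressionCallSet(per_tissue=pd.DataFrame(calls)[tissues], threshold=threshold)


def venn_core_sets(calls: ExpressionCallSet, class_map: dict[str, str]) -> dict[str, int]:
    """Sizes of all 7 regions of the 3-class Venn of "expressed in EVERY
    tissue of the class" sets, plus the triple intersection under key "core".
    """
    classes = ("skeletal", "cardiac", "smooth")
    per_class = {}
    for cls in classes:
        tissues = [t for t, c in class_map.items() if c == cls]
        if not tissues:
            raise DataModelError(f"no tissues assigned to class {cls!r}")
        cols = [t for t in tissues if t in calls.per_tissue.columns]
        if not cols:
            raise DataModelError(f"class {cls!r} tissues absent from calls")
        mask = calls.per_tissue[cols].all(axis=1)
        per_class[cls] = set(calls.per_tissue.index[mask])

    s, c, m = (per_class[k] for k in classes)
    regions = {
        "skeletal_only": len(s - c - m),
        "cardiac_only": len(c - s - m),
        "smooth_only": len(m - s - c),
        "skeletal_cardiac": len((s & c) - m),
        "skeletal_smooth": len((s & m) - c),
        "cardiac_smooth": len((c & m) - s),
        "all_three": len(s & c & m),
    }
    regions["core"] = regions["all_three"]
    return regions


def bh_qvalues(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped
    at 1, mapped back to the input order.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise DataModelError("p must be a 1-D vector")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise DataModelError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _anova_arrays(values: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA across rows of ``values``.

    ``groups`` lists column-index arrays, one per tissue. Returns (F, p)
    with the deterministic degenerate rules applied rowwise.
    """
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = values.mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in groups:
        sub = values[:, g]
        gm = sub.mean(axis=1)
        ssb += len(g) * (gm - grand) ** 2
        ssw += ((sub - gm[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n_total - k
    if dfw <= 0:
        raise DataModelError("need at least 2 replicates in some tissue (within df = 0)")

    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = np.empty(values.shape[0])

    ok = ssw > 0
    p[ok] = stats.f.sf(F[ok], dfb, dfw)
    # zero within-group variance: all-identical -> (F=0, p=1); signal -> p floor
    degen = ~ok
    signal = degen & (ssb > 0)
    null = degen & (ssb <= 0)
    F[null] = 0.0
    p[null] = 1.0
    F[signal] = np.inf
    p[signal] = P_FLOOR
    return F, p


def _fold_change(tissue_means_fpkm: pd.DataFrame, eps: float = FC_EPSILON) -> pd.Series:
    """max/min-over-tissues fold change of raw-FPKM tissue means."""
    mx = tissue_means_fpkm.max(axis=1)
    mn = tissue_means_fpkm.min(axis=1)
    return (mx + eps) / (mn + eps)


def anova_de(
    log_expr: pd.DataFrame,
    fpkm: pd.DataFrame,
    metadata: pd.DataFrame,
    tissue_subset: list[str] | None = None,
    q_thresh: float = DEFAULT_Q,
    fc_thresh: float = DEFAULT_FC,
    expressed_threshold: float = 1.0,
) -> pd.DataFrame:
    """One-way ANOVA DE across a tissue subset.

    Transcripts are pre-filtered to those expressed (mean FPKM >
    ``expressed_threshold``) in at least one subset tissue; BH is
    applied over exactly the tested set. Returns a DataFrame indexed by
    transcript with columns F, p, q, fold_change, significant plus
    per-tissue mean log columns ``mean_<tissue>``.
    """
    tissues = tissue_subset or list(dict.fromkeys(metadata["tissue"]))
    if len(tissues) < 2:
        raise DataModelError("need at least 2 tissues for ANOVA")
    meta = metadata[metadata["tissue"].isin(tissues)]
    sizes = meta.groupby("tissue").size()
    if (sizes < 2).any():
        raise DataModelError(f"tissues with <2 replicates: {dict(sizes[sizes < 2])}")

    # expression filter within the subset
    mean_fpkm = pd.DataFrame(
        {t: fpkm[meta.index[meta["tissue"] == t]].mean(axis=1) for t in tissues}
    )
    tested = mean_fpkm.index[(mean_fpkm > expressed_threshold).any(axis=1)]
    if len(tested) == 0:
        raise DataModelError("no transcripts pass the expression filter")

    cols = list(meta.index)
    values = log_expr.loc[tested, cols].to_numpy(dtype=float)
    col_pos = {s: i for i, s in enumerate(cols)}
    groups = [np.array([col_pos[s] for s in meta.index[meta["tissue"] == t]]) for t in tissues]

    F, p = _anova_arrays(values, groups)
    q = bh_qvalues(p)
    fc = _fold_change(mean_fpkm.loc[tested])

    out = pd.DataFrame(index=tested)
    for t in tissues:
        out[f"mean_{t}"] = log_expr.loc[tested, meta.index[meta["tissue"] == t]].mean(axis=1)
    out["F"] = F
    out["p"] = p
    out["q"] = q
    out["fold_change"] = fc
    out["significant"] = (q < q_thresh) & (fc > fc_thresh)
    return out


def pairwise_de(
    log_expr: pd.DataFrame,
    fpkm: pd.DataFrame,
    metadata: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    q_thresh: float = DEFAULT_Q,
    fc_thresh: float = DEFAULT_FC,
    expressed_threshold: float = 1.0,
) -> pd.DataFrame:
    """Two-group DE (the k=2 ANOVA, i.e. pooled-variance t with F = t²).

    Adds a signed ``log2_fc`` column (A over B, computed on raw-FPKM
    tissue means with the 0.1 pseudocount) and a ``direction`` column
    (+1 up in A, −1 up in B, 0 tied).
    """
    out = anova_de(
        log_expr, fpkm, metadata, [tissue_a, tissue_b],
        q_thresh=q_thresh, fc_thresh=fc_thresh, expressed_threshold=expressed_threshold,
    )
    meta = metadata[metadata["tissue"].isin([tissue_a, tissue_b])]
    mean_a = fpkm.loc[out.index, meta.index[meta["tissue"] == tissue_a]].mean(axis=1)
    mean_b = fpkm.loc[out.index, meta.index[meta["tissue"] == tissue_b]].mean(axis=1)
    log2_fc = np.log2((mean_a + FC_EPSILON) / (mean_b + FC_EPSILON))
    out["log2_fc"] = log2_fc
    out["direction"] = np.sign(log2_fc).astype(int)
    return out


def de_fraction_matrix(
    log_expr: pd.DataFrame,
    fpkm: pd.DataFrame,
    metadata: pd.DataFrame,
    tissues: list[str] | None = None,
    q_thresh: float = DEFAULT_Q,
    fc_thresh: float = DEFAULT_FC,
) -> pd.DataFrame:
    """Symmetric matrix of % transcripts DE per tissue pair; diagonal 0."""
    tissues = tissues or list(dict.fromkeys(metadata["tissue"]))
    if len(tissues) < 2:
        raise DataModelError("need at least 2 tissues")
    mat = pd.DataFrame(0.0, index=tissues, columns=tissues)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1:]:
            de = pairwise_de(log_expr, fpkm, metadata, a, b,
                             q_thresh=q_thresh, fc_thresh=fc_thresh)
            pct = 100.0 * de["significant"].sum() / len(de)
            mat.loc[a, b] = mat.loc[b, a] = pct
    return mat


def de_threshold_sweep(
    log_expr: pd.DataFrame,
    fpkm: pd.DataFrame,
    metadata: pd.DataFrame,
    subsets: dict[str, list[str]],
    q_grid: list[float],
    fc_thresh: float = DEFAULT_FC,
) -> pd.DataFrame:
    """%DE at each q threshold for each named tissue subset.

    Rows are q values (ascending), columns the subset names; entries are
    monotone non-decreasing in q by construction.
    """
    if any(not (0 < q <= 1) for q in q_grid):
        raise DataModelError("q_grid values must lie in (0, 1]")
    q_grid = sorted(q_grid)
    out = {}
    for name, tissues in subsets.items():
        de = anova_de(log_expr, fpkm, metadata, tissues, q_thresh=1.0, fc_thresh=fc_thresh)
        passing_fc = de["fold_change"] > fc_thresh
        out[name] = [
            100.0 * ((de["q"] < q) & passing_fc).sum() / len(de) for q in q_grid
        ]
    return pd.DataFrame(out, index=pd.Index(q_grid, name="q"))
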