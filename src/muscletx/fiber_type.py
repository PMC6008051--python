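"""Fiber-type composition from Myh transcripts and marker correlations.

Skeletal muscles are mosaics of slow (Type I, Myh7) and fast (Type IIa/
IIx/IIb — Myh2/Myh1/Myh4) fibers. The composition of a tissue is
proxied by the share of myosin-heavy-chain-aligned reads falling on
each Myh transcript; marker analyses then ask how well genes reported
as fiber-type-specific track Myh4 (fast) or Myh7 (slow) across tissues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import DataModelError, ExpressionDataset
from .normalization import compute_fpkm


def _gene_rows(dataset_or_ann: pd.DataFrame, genes: list[str]) -> dict[str, list[str]]:
    symbols = dataset_or_ann["gene_symbol"].astype(str).str.upper()
    out = {}
    for g in genes:
        hits = list(dataset_or_ann.index[symbols == g.upper()])
        if hits:
            out[g] = hits
    return out


def myh_composition(
    dataset: ExpressionDataset,
    myh_gene_list: list[str],
    basis: str = "reads",
) -> pd.DataFrame:
    """Percent of Myh-aligned signal per Myh gene, per tissue.

    ``basis='reads'`` sums unique read counts over a tissue's
    replicates (read-level proportions are length-biased, which is why
    an ``fpkm`` basis is also offered; the basis used is recorded in
    ``result.attrs['basis']``). Tissues with zero Myh signal come back
    as all-NaN rows.
    """
    if not myh_gene_list:
        raise DataModelError("empty Myh gene list")
    if basis not in ("reads", "fpkm"):
        raise DataModelError(f"unknown basis {basis!r}")
    rows = _gene_rows(dataset.transcripts, myh_gene_list)
    if not rows:
        raise DataModelError(f"no Myh genes from {myh_gene_list} present in annotation")

    if basis == "reads":
        mat = dataset.counts
    else:
        mat = compute_fpkm(dataset).values

    tissues = dataset.tissues
    out = pd.DataFrame(index=tissues, columns=list(rows), dtype=float)
    for t in tissues:
        cols = dataset.samples_of_tissue(t)
        totals = {g: float(mat.loc[tids, cols].to_numpy().sum()) for g, tids in rows.items()}
        grand = sum(totals.values())
        if grand <= 0:
            out.loc[t] = np.nan
        else:
            for g, v in totals.items():
                out.loc[t, g] = 100.0 * v / grand
    out.attrs["basis"] = basis
    return out


def marker_correlation(
    tissue_means_log: pd.DataFrame,
    annotation: pd.DataFrame,
    marker_gene: str,
    reference_gene: str,
) -> tuple[float, float]:
    """Pearson r and R² between two genes across tissue means.

    One point per tissue, on the log2(FPKM+1) scale. Transcript-level
    rows are averaged per gene symbol first.
    """
    if tissue_means_log.shape[1] < 3:
        raise DataModelError("need at least 3 tissues for a meaningful correlation")
    rows = _gene_rows(annotation, [marker_gene, reference_gene])
    for g in (marker_gene, reference_gene):
        if g not in rows:
            raise DataModelError(f"gene {g!r} not present in annotation")
    x = tissue_means_log.loc[rows[marker_gene]].mean(axis=0).to_numpy(dtype=float)
    y = tissue_means_log.loc[rows[reference_gene]].mean(axis=0).to_numpy(dtype=float)
    if np.std(y) == 0:
        raise DataModelError(f"reference gene {reference_gene!r} is constant across tissues")
    if np.std(x) == 0:
        return (np.nan, np.nan)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def marker_panel_summary(
    tissue_means_log: pd.DataFrame,
    annotation: pd.DataFrame,
    marker_genes: list[str],
    reference_gene: str,
) -> tuple[pd.DataFrame, float, int]:
    """Per-marker R² vs a reference gene, plus median R² and count(R² > 0.5).

    Returns (table sorted descending by R², median_r2, n_above_half).
    Markers absent from the annotation or constant across tissues are
    reported with NaN and excluded from the summary statistics.
    """
    if not marker_genes:
        raise DataModelError("empty marker panel")
    rows = []
    for g in marker_genes:
        try:
            r, r2 = marker_correlation(tissue_means_log, annotation, g, reference_gene)
        except DataModelError as err:
            if "not present" in str(err):
                r, r2 = np.nan, np.nan
            else:
                raise
        rows.append(dict(gene=g, r=r, r2=r2))
    table = pd.DataFrame(rows).set_index("gene").sort_values("r2", ascending=False)
    valid = table["r2"].dropna()
    median_r2 = float(valid.median()) if len(valid) else np.nan
    n_above = int((valid > 0.5).sum())
    return table, median_r2, n_above
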