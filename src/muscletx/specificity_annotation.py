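"""Tissue-specificity scoring and curated gene-list overlays.

Specificity uses the tau index over per-tissue mean FPKM:

    tau = sum_i (1 − x_i / x_max) / (n − 1)

tau = 0 for perfectly uniform expression, 1 for expression confined to
a single tissue; it is invariant to rescaling all tissue means. The
fraction of total expression carried by the top tissue (max_fraction)
is reported alongside as a second, simpler statistic. Overlays
intersect DE gene sets with user-supplied disease, drug-target and
secreted-protein lists (symbols case-folded to upper case).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import DataModelError, GeneList


def specificity_scores(
    tissue_means_fpkm: pd.DataFrame,
    tissue_subset: list[str] | None = None,
) -> pd.DataFrame:
    """tau, max_tissue, max_fraction and mean log expression per transcript.

    Transcripts with all-zero means across the subset have undefined
    specificity and come back NaN.
    """
    sub = tissue_means_fpkm[tissue_subset] if tissue_subset else tissue_means_fpkm
    if sub.shape[1] < 2:
        raise DataModelError("need at least 2 tissues")
    x = sub.to_numpy(dtype=float)
    if (x < 0).any():
        raise DataModelError("tissue means must be non-negative")

    n = x.shape[1]
    xmax = x.max(axis=1)
    total = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (n - 1)
        max_fraction = xmax / total
    dead = xmax == 0
    tau[dead] = np.nan
    max_fraction[dead] = np.nan

    out = pd.DataFrame(
        {
            "tau": tau,
            "max_tissue": sub.columns.to_numpy()[x.argmax(axis=1)],
            "max_fraction": max_fraction,
            "mean_expression": np.log2(x.mean(axis=1) + 1.0),
        },
        index=sub.index,
    )
    out.loc[dead, "max_tissue"] = None
    return out


def top_specific_genes(
    scores: pd.DataFrame,
    tissue: str,
    n: int = 50,
    min_expression: float = 0.0,
) -> pd.DataFrame:
    """Transcripts most specific to one tissue.

    Candidates are transcripts whose max_tissue is the requested tissue
    and whose mean FPKM (back-transformed from mean_expression) is at
    least ``min_expression``; ranked by tau then max_fraction,
    descending. Returns at most n rows.
    """
    cand = scores[(scores["max_tissue"] == tissue)].dropna(subset=["tau"])
    mean_fpkm = 2.0 ** cand["mean_expression"] - 1.0
    cand = cand[mean_fpkm >= min_expression]
    return cand.sort_values(["tau", "max_fraction"], ascending=False).head(n)


def gene_set_venn(
    de_genes: GeneList, disease: GeneList, drug_targets: GeneList
) -> dict[str, int]:
    """Region sizes of the 3-set Venn of DE, disease and drug-target genes.

    Also reports the drug∩DE∖disease "sliver" explicitly as
    ``drug_de_not_disease``.
    """
    d, dis, drg = de_genes.members, disease.members, drug_targets.members
    regions = {
        "de_only": len(d - dis - drg),
        "disease_only": len(dis - d - drg),
        "drug_only": len(drg - d - dis),
        "de_disease": len((d & dis) - drg),
        "de_drug": len((d & drg) - dis),
        "disease_drug": len((dis & drg) - d),
        "all_three": len(d & dis & drg),
    }
    regions["union"] = len(d | dis | drg)
    regions["drug_de_not_disease"] = len((drg & d) - dis)
    return regions


def myokine_candidates(
    de_results: pd.DataFrame,
    tissue_means_fpkm: pd.DataFrame,
    annotation: pd.DataFrame,
    secreted: GeneList,
    min_fpkm: float = 10.0,
    fc_epsilon: float = 0.1,
) -> pd.DataFrame:
    """Candidate muscle-secreted signaling genes.

    A candidate is a secreted-annotated gene that is significantly DE
    among the analysed skeletal tissues and whose maximum tissue-mean
    FPKM exceeds ``min_fpkm``. Reports, per candidate, the max/min
    tissue means and their pseudocount-stabilised ratio, one row per
    unique gene symbol (best transcript by fold change kept).
    """
    if len(secreted) == 0:
        raise DataModelError("empty secreted gene list")
    sig = de_results[de_results["significant"]]
    symbols = annotation.loc[sig.index, "gene_symbol"].astype(str).str.upper()
    keep = sig.index[[s in secreted.members for s in symbols]]

    means = tissue_means_fpkm.loc[[t for t in keep if t in tissue_means_fpkm.index]]
    rows = []
    for tid in means.index:
        mx, mn = float(means.loc[tid].max()), float(means.loc[tid].min())
        if mx <= min_fpkm:
            continue
        rows.append(
            dict(
                transcript_id=tid,
                gene_symbol=annotation.loc[tid, "gene_symbol"],
                max_tissue=means.columns[means.loc[tid].argmax()],
                max_fpkm=mx,
                min_fpkm=mn,
                ratio=(mx + fc_epsilon) / (mn + fc_epsilon),
                q=float(de_results.loc[tid, "q"]),
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["transcript_id", "gene_symbol", "max_tissue", "max_fpkm",
                     "min_fpkm", "ratio", "q"]
        ).set_index("transcript_id")
    out = pd.DataFrame(rows).set_index("transcript_id")
    out = out.sort_values("ratio", ascending=False)
    out = out.loc[~out["gene_symbol"].astype(str).str.upper().duplicated()]
    return out
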