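"""Cross-species expression concordance over ortholog pairs.

Mouse and rat hindlimb muscles (EDL vs soleus) are compared on
ortholog-paired log2(FPKM+1) tissue means, with no cross-species
renormalization: overall transcriptome correlation per tissue,
shared-DE overlap, direction concordance of log fold changes, and
rank-ordered fold-change profiles. Sex differences within a tissue use
the same two-group test between male and female replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DataModelError, ExpressionDataset, OrthologTable
from .differential_expression import pairwise_de
from .normalization import compute_fpkm, log_transform, tissue_means


@dataclass
class ConcordanceResult:
    n_shared_de: int
    n_same_direction: int
    per_gene: pd.DataFrame   # log2_fc_a, log2_fc_b, same (indexed by species-A id)

    @property
    def percent_same(self) -> float:
        if self.n_shared_de == 0:
            raise DataModelError("percent_same undefined with zero shared DE genes")
        return 100.0 * self.n_same_direction / self.n_shared_de


def pair_orthologs(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    table: OrthologTable,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Restrict two matrices to ortholog pairs present in both.

    Returns (paired_a, paired_b, n_dropped); paired_b rows are reindexed
    in species-A order (one row per pair).
    """
    mapping = table.as_mapping()
    kept = [(a, b) for a, b in mapping.items() if a in expr_a.index and b in expr_b.index]
    if not kept:
        raise DataModelError("no ortholog pairs present in both datasets")
    n_dropped = len(mapping) - len(kept)
    ids_a = [a for a, _ in kept]
    ids_b = [b for _, b in kept]
    return expr_a.loc[ids_a], expr_b.loc[ids_b], n_dropped


def species_correlation(
    paired_a: pd.DataFrame,
    paired_b: pd.DataFrame,
    tissue: str,
) -> float:
    """R² between ortholog log-mean expression of one tissue in two species."""
    for df in (paired_a, paired_b):
        if tissue not in df.columns:
            raise DataModelError(f"tissue {tissue!r} absent from paired means")
    if len(paired_a) < 3:
        raise DataModelError("need at least 3 shared genes")
    x = paired_a[tissue].to_numpy(dtype=float)
    y = paired_b[tissue].to_numpy(dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def de_overlap_concordance(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    table: OrthologTable,
) -> ConcordanceResult:
    """Direction concordance of genes significantly DE in both species.

    Both DE tables must come from the same two-tissue contrast (signed
    ``log2_fc``, A-tissue over B-tissue). Same direction means equal
    sign of log2 fold change; a zero fold change counts as discordant
    unless both are zero.
    """
    for df, name in ((de_a, "A"), (de_b, "B")):
        if "log2_fc" not in df.columns:
            raise DataModelError(f"species {name} DE table lacks signed log2_fc")
    mapping = table.as_mapping()
    sig_a = set(de_a.index[de_a["significant"]])
    sig_b = set(de_b.index[de_b["significant"]])
    shared = [(a, mapping[a]) for a in sorted(sig_a) if a in mapping and mapping[a] in sig_b]

    rows = []
    n_same = 0
    for a, b in shared:
        fa = float(de_a.loc[a, "log2_fc"])
        fb = float(de_b.loc[b, "log2_fc"])
        same = bool(
            (fa == 0 and fb == 0)
            or (fa != 0 and fb != 0 and np.sign(fa) == np.sign(fb))
        )
        n_same += same
        rows.append(dict(gene=a, ortholog=b, log2_fc_a=fa, log2_fc_b=fb, same=same))
    per_gene = (
        pd.DataFrame(rows).set_index("gene")
        if rows
        else pd.DataFrame(columns=["ortholog", "log2_fc_a", "log2_fc_b", "same"])
    )
    return ConcordanceResult(n_shared_de=len(shared), n_same_direction=n_same, per_gene=per_gene)


def rank_ordered_fc_profiles(concordance: ConcordanceResult) -> pd.DataFrame:
    """Shared-DE fold changes sorted by species A, B emitted in A's order.

    The companion summary (fraction of B sharing A's sign) is stored in
    ``result.attrs['shared_sign_fraction']``.
    """
    df = concordance.per_gene.sort_values("log2_fc_a", ascending=False).copy()
    if len(df):
        frac = float(
            (np.sign(df["log2_fc_a"]) == np.sign(df["log2_fc_b"])).mean()
        )
    else:
        frac = np.nan
    df.attrs["shared_sign_fraction"] = frac
    return df


def sex_de_fraction(
    dataset: ExpressionDataset,
    tissue: str,
    q_thresh: float = 0.01,
    fc_thresh: float = 2.0,
) -> dict[str, float]:
    """% transcripts DE between sexes within a tissue, plus direction split.

    Builds a two-group contrast (male vs female replicates of the
    tissue) through the standard pairwise test. Returns percent_de,
    percent_up_in_male and percent_up_in_female (of the DE genes).
    """
    meta = dataset.samples[dataset.samples["tissue"] == tissue]
    if meta.empty:
        raise DataModelError(f"unknown tissue {tissue!r}")
    sexes = meta.groupby("sex").size()
    for s in ("male", "female"):
        if sexes.get(s, 0) < 2:
            raise DataModelError(f"tissue {tissue!r} needs >=2 {s} replicates")

    # recast sexes as pseudo-tissues so the standard two-group machinery applies
    sub_counts = dataset.counts[list(meta.index)]
    pseudo = meta.copy()
    pseudo["tissue"] = [f"{tissue}_{s}" for s in meta["sex"]]
    sub = ExpressionDataset(
        counts=sub_counts, samples=pseudo, transcripts=dataset.transcripts
    )
    fpkm = compute_fpkm(sub)
    log_expr = log_transform(fpkm)
    de = pairwise_de(
        log_expr, fpkm.values, pseudo, f"{tissue}_male", f"{tissue}_female",
        q_thresh=q_thresh, fc_thresh=fc_thresh,
    )
    sig = de[de["significant"]]
    n_sig = len(sig)
    up_male = int((sig["direction"] > 0).sum())
    return {
        "percent_de": 100.0 * n_sig / len(de),
        "n_de": float(n_sig),
        "n_tested": float(len(de)),
        "percent_up_in_male": (100.0 * up_male / n_sig) if n_sig else np.nan,
        "percent_up_in_female": (100.0 * (n_sig - up_male) / n_sig) if n_sig else np.nan,
    }


def paired_tissue_means(
    ds_a: ExpressionDataset, ds_b: ExpressionDataset, table: OrthologTable
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Convenience: log2(FPKM+1) tissue means of both datasets, ortholog-paired."""
    mean_a, _ = tissue_means(log_transform(compute_fpkm(ds_a)), ds_a.samples, scale="log")
    mean_b, _ = tissue_means(log_transform(compute_fpkm(ds_b)), ds_b.samples, scale="log")
    return pair_orthologs(mean_a, mean_b, table)
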