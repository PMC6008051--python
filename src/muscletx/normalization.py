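"""FPKM with mitochondrial depth exclusion, log transform, tissue summaries.

FPKM_ij = 10^9 * c_ij / (l_i * N_j), where c_ij is the unique-read
count for transcript i in sample j, l_i the transcript length in bp and
N_j the sample depth. Muscles differ hugely in mitochondrial content,
which would otherwise deflate every nuclear transcript's FPKM in
mitochondria-rich tissues, so N_j sums counts over *nuclear* transcripts
only. Mitochondrial transcripts still receive FPKM values (their
numerator is untouched); they simply never contribute to any
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DataModelError, ExpressionDataset


@dataclass
class FpkmMatrix:
    """FPKM values plus the per-sample nuclear depth used to compute them."""

    values: pd.DataFrame                 # transcripts × samples
    denominator_per_sample: pd.Series    # nuclear unique aligned reads N_j
    pseudocount_used: float = 0.0


def compute_fpkm(dataset: ExpressionDataset) -> FpkmMatrix:
    """FPKM_ij = 1e9 * c_ij / (l_i * N_j) with N_j over nuclear rows only."""
    counts = dataset.counts.to_numpy(dtype=float)
    lengths = dataset.transcripts["length_bp"].to_numpy(dtype=float)
    mito = dataset.transcripts["is_mitochondrial"].to_numpy(dtype=bool)

    N = counts[~mito, :].sum(axis=0)
    zero = np.flatnonzero(N <= 0)
    if len(zero):
        bad = [dataset.counts.columns[j] for j in zero]
        raise DataModelError(f"samples with zero nuclear-aligned reads: {bad}")

    fpkm = 1e9 * counts / (lengths[:, None] * N[None, :])
    values = pd.DataFrame(fpkm, index=dataset.counts.index, columns=dataset.counts.columns)
    denom = pd.Series(N, index=dataset.counts.columns, name="nuclear_reads")
    return FpkmMatrix(values=values, denominator_per_sample=denom)


def log_transform(fpkm: FpkmMatrix | pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(FPKM + pseudocount)."""
    if pseudocount <= 0:
        raise DataModelError(f"pseudocount must be positive, got {pseudocount}")
    values = fpkm.values if isinstance(fpkm, FpkmMatrix) else fpkm
    if (values.to_numpy() < 0).any():
        raise DataModelError("FPKM values must be non-negative")
    return np.log2(values + pseudocount)


def tissue_means(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    scale: str = "fpkm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue arithmetic mean and SEM of each transcript.

    ``matrix`` is transcripts × samples on the requested scale ("fpkm"
    or "log" — the scale is the caller's statement of what it passes;
    no transform is applied here). SEM uses the sample SD (ddof=1) over
    a tissue's replicates; tissues with a single replicate get NaN SEM.
    """
    if scale not in ("fpkm", "log"):
        raise DataModelError(f"unknown scale {scale!r}")
    unknown = set(metadata.index) - set(matrix.columns)
    if unknown:
        raise DataModelError(f"metadata samples absent from matrix: {sorted(unknown)}")

    tissues = list(dict.fromkeys(metadata["tissue"]))
    means = {}
    sems = {}
    for t in tissues:
        cols = metadata.index[metadata["tissue"] == t]
        sub = matrix[cols]
        means[t] = sub.mean(axis=1)
        n = sub.shape[1]
        sems[t] = sub.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(
            np.nan, index=matrix.index
        )
    return pd.DataFrame(means)[tissues], pd.DataFrame(sems)[tissues]
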