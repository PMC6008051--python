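import numpy as np
import pandas as pd
import pytest

from muscletx import SimConfig, simulate_dataset
from muscletx.data_model import ExpressionDataset


def make_tiny_dataset() -> ExpressionDataset:
    """3 transcripts (one mitochondrial) × 2 tissues × 2 replicates."""
    counts = pd.DataFrame(
        {
            "EDL_r1": [10, 100, 40],
            "EDL_r2": [12, 110, 38],
            "SOL_r1": [60, 20, 400],
            "SOL_r2": [55, 25, 420],
        },
        index=["T1", "T2", "MT1"],
        dtype=np.int64,
    )
    samples = pd.DataFrame(
        {
            "tissue": ["EDL", "EDL", "SOL", "SOL"],
            "muscle_class": ["skeletal"] * 4,
            "species": ["mouse"] * 4,
            "sex": ["male", "female", "male", "female"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["EDL_r1", "EDL_r2", "SOL_r1", "SOL_r2"], name="sample_id"),
    )
    transcripts = pd.DataFrame(
        {
            "gene_symbol": ["MYH4", "MSTN", "MT-CO1"],
            "chrom": ["chr1", "chr2", "chrM"],
            "is_mitochondrial": [False, False, True],
            "length_bp": [1000, 500, 300],
            "strand": ["+", "-", "+"],
            "exons": [((0, 400), (600, 1200)), ((0, 500),), ((0, 300),)],
        },
        index=pd.Index(["T1", "T2", "MT1"], name="transcript_id"),
    )
    return ExpressionDataset(counts=counts, samples=samples, transcripts=transcripts)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    return make_tiny_dataset()


def de_only_config(seed: int, **overrides) -> SimConfig:
    """11 skeletal tissues × 6 replicates where the ONLY between-tissue
    variation is the planted DE: no class shifts, no tissue shifts, no
    fast/slow axis, uniform fiber composition, fixed mitochondrial load.
    """
    base = dict(
        seed=seed,
        n_transcripts=2000,
        tissues_per_class={"skeletal": 11, "cardiac": 0, "smooth": 0},
        class_shift_sd=0.0,
        tissue_shift_sd=0.0,
        n_axis_drivers=0,
        de_fraction=0.1,
        de_fold_change=4.0,
        nb_dispersion=0.05,
        fast_fractions={t: 0.5 for t in
                        ["SOL", "DIA", "TON", "MAS", "FDB", "EYE", "GAS", "PLA", "QUAD", "TA", "EDL"]},
        mito_fraction_range=(0.2, 0.2),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_sim():
    """One full default simulation shared across tests (seed 1)."""
    return simulate_dataset(SimConfig(seed=1))
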