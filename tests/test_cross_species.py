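"""Ortholog pairing, species correlation, direction concordance, sex DE."""

import numpy as np
import pandas as pd
import pytest

from muscletx import (
    OrthologTable,
    SimConfig,
    de_overlap_concordance,
    pair_orthologs,
    paired_tissue_means,
    rank_ordered_fc_profiles,
    sex_de_fraction,
    simulate_dataset,
    simulate_species_pair,
    species_correlation,
)
from muscletx.cross_species import ConcordanceResult
from muscletx.data_model import DataModelError


def _de_table(fcs: dict, sig=None):
    idx = list(fcs)
    return pd.DataFrame(
        {
            "log2_fc": [fcs[k] for k in idx],
            "significant": [True if sig is None else k in sig for k in idx],
            "q": 0.001,
        },
        index=idx,
    )


class TestPairing:
    def test_identity_pairing_is_full(self):
        a = pd.DataFrame(np.ones((3, 2)), index=["x", "y", "z"], columns=["t1", "t2"])
        table = OrthologTable.from_pairs([("x", "x"), ("y", "y"), ("z", "z")])
        pa, pb, dropped = pair_orthologs(a, a, table)
        assert len(pa) == 3 and dropped == 0

    def test_unmatched_pair_dropped_and_counted(self):
        a = pd.DataFrame(np.ones((2, 1)), index=["x", "y"], columns=["t"])
        b = pd.DataFrame(np.ones((2, 1)), index=["X", "Q"], columns=["t"])
        table = OrthologTable.from_pairs([("x", "X"), ("y", "MISSING")])
        pa, pb, dropped = pair_orthologs(a, b, table)
        assert list(pa.index) == ["x"] and dropped == 1

    def test_pairing_idempotent(self):
        a = pd.DataFrame(np.arange(6.0).reshape(3, 2), index=["x", "y", "z"],
                         columns=["t1", "t2"])
        b = a.copy()
        b.index = ["X", "Y", "Z"]
        table = OrthologTable.from_pairs(zip(a.index, b.index))
        pa, pb, _ = pair_orthologs(a, b, table)
        pa2, pb2, d2 = pair_orthologs(pa, pb, table)
        assert pa2.equals(pa) and pb2.equals(pb) and d2 == 0


class TestSpeciesCorrelation:
    def test_identical_values_r2_one(self):
        a = pd.DataFrame({"EDL": [1.0, 2, 3, 4]}, index=list("wxyz"))
        assert species_correlation(a, a, "EDL") == pytest.approx(1.0)

    def test_affine_r2_one(self):
        a = pd.DataFrame({"EDL": [1.0, 2, 3, 4]}, index=list("wxyz"))
        b = 2 * a + 1
        assert species_correlation(a, b, "EDL") == pytest.approx(1.0)

    def test_calibrated_pair_near_design_value(self):
        # between-species log-normal divergence SD 1.45 against baseline
        # spread sigma0 = 2 targets R^2 ~= 4/(4+1.45^2) = 0.656 before the
        # mild compression of the +1 pseudocount
        ds_a, ds_b, table, _ = simulate_species_pair(
            SimConfig(seed=5), concordance=0.9, seed=5
        )
        pa, pb, _ = paired_tissue_means(ds_a, ds_b, table)
        r2 = species_correlation(pa, pb, "EDL")
        assert r2 == pytest.approx(0.65, abs=0.1)

    def test_too_few_genes_rejected(self):
        a = pd.DataFrame({"EDL": [1.0, 2]}, index=["x", "y"])
        with pytest.raises(DataModelError):
            species_correlation(a, a, "EDL")


class TestConcordance:
    def test_hand_count_two_of_three(self):
        de_a = _de_table({"g1": 1.0, "g2": 1.0, "g3": -1.0})
        de_b = _de_table({"G1": 1.0, "G2": -1.0, "G3": -1.0})
        table = OrthologTable.from_pairs([("g1", "G1"), ("g2", "G2"), ("g3", "G3")])
        res = de_overlap_concordance(de_a, de_b, table)
        assert res.n_shared_de == 3 and res.n_same_direction == 2
        assert res.percent_same == pytest.approx(100 * 2 / 3)

    def test_self_concordance_full(self):
        de_a = _de_table({"g1": 1.0, "g2": -2.0})
        table = OrthologTable.from_pairs([("g1", "g1"), ("g2", "g2")])
        assert de_overlap_concordance(de_a, de_a, table).percent_same == 100.0

    def test_zero_fc_discordant_unless_both_zero(self):
        de_a = _de_table({"g1": 0.0, "g2": 0.0})
        de_b = _de_table({"G1": 1.0, "G2": 0.0})
        table = OrthologTable.from_pairs([("g1", "G1"), ("g2", "G2")])
        res = de_overlap_concordance(de_a, de_b, table)
        assert list(res.per_gene["same"]) == [False, True]

    def test_symmetric_in_species_order(self):
        rng = np.random.default_rng(0)
        fa = {f"g{i}": float(rng.normal()) for i in range(20)}
        fb = {f"G{i}": float(rng.normal()) for i in range(20)}
        de_a, de_b = _de_table(fa), _de_table(fb)
        fwd = OrthologTable.from_pairs([(f"g{i}", f"G{i}") for i in range(20)])
        rev = OrthologTable.from_pairs([(f"G{i}", f"g{i}") for i in range(20)])
        assert (
            de_overlap_concordance(de_a, de_b, fwd).percent_same
            == de_overlap_concordance(de_b, de_a, rev).percent_same
        )

    def test_percent_undefined_with_no_shared(self):
        de_a = _de_table({"g1": 1.0}, sig=set())
        table = OrthologTable.from_pairs([("g1", "g1")])
        res = de_overlap_concordance(de_a, de_a, table)
        with pytest.raises(DataModelError):
            _ = res.percent_same


class TestRankOrderedProfiles:
    def test_self_comparison_sorted_descending(self):
        de_a = _de_table({"g1": 3.0, "g2": -1.0, "g3": 0.5})
        table = OrthologTable.from_pairs([(g, g) for g in de_a.index])
        res = de_overlap_concordance(de_a, de_a, table)
        prof = rank_ordered_fc_profiles(res)
        assert list(prof["log2_fc_a"]) == sorted(prof["log2_fc_a"], reverse=True)
        assert list(prof["log2_fc_b"]) == list(prof["log2_fc_a"])
        assert prof.attrs["shared_sign_fraction"] == 1.0

    def test_anticorrelated_shared_sign_zero(self):
        de_a = _de_table({"g1": 2.0, "g2": -2.0})
        de_b = _de_table({"G1": -2.0, "G2": 2.0})
        table = OrthologTable.from_pairs([("g1", "G1"), ("g2", "G2")])
        prof = rank_ordered_fc_profiles(de_overlap_concordance(de_a, de_b, table))
        assert prof.attrs["shared_sign_fraction"] == 0.0


class TestSexDE:
    def test_no_planted_sex_effect_near_zero(self):
        ds, _ = simulate_dataset(SimConfig(
            seed=17, n_transcripts=600,
            tissues_per_class={"skeletal": 2, "cardiac": 0, "smooth": 0},
            class_shift_sd=0.0, tissue_shift_sd=0.0, n_axis_drivers=0,
            de_fraction=0.0, fast_fractions={"SOL": 0.5, "DIA": 0.5},
            mito_fraction_range=(0.2, 0.2),
        ))
        res = sex_de_fraction(ds, "SOL")
        assert res["percent_de"] <= 1.0

    def test_planted_male_biased_fraction_recovered(self):
        ds, truth = simulate_dataset(SimConfig(
            seed=19, n_transcripts=1000,
            tissues_per_class={"skeletal": 2, "cardiac": 0, "smooth": 0},
            class_shift_sd=0.0, tissue_shift_sd=0.0, n_axis_drivers=0,
            n_replicates=8,  # 4 male + 4 female for a well-powered contrast
            de_fraction=0.0, sex_de_fraction=0.02, sex_de_fold_change=8.0,
            fast_fractions={"SOL": 0.5, "DIA": 0.5}, mito_fraction_range=(0.2, 0.2),
        ))
        res = sex_de_fraction(ds, "SOL", q_thresh=0.05)
        assert res["percent_de"] == pytest.approx(2.0, abs=1.0)
        assert res["percent_up_in_male"] > 50.0
        assert res["percent_up_in_male"] + res["percent_up_in_female"] == pytest.approx(100.0)

    def test_single_sex_tissue_rejected(self, tiny_dataset):
        # tiny fixture has 1 male + 1 female per tissue -> below the 2+2 floor
        with pytest.raises(DataModelError):
            sex_de_fraction(tiny_dataset, "EDL")
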