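"""Association battery: correlations, group contrasts, external tables."""

import numpy as np
import pandas as pd
import pytest

from bcrlik import (
    DataError,
    GermlineAnchoredProvider,
    InputSource,
    affinity_association,
    build_forest,
    correlate,
    cross_model_correlation,
    frequency_association,
    group_compare,
    score_repertoire,
    sp_feature_table,
)
from conftest import make_cell


def test_perfect_linear_relation_gives_pearson_one():
    x = np.arange(10.0)
    res = correlate(x, 2 * x + 1, "pearson")
    assert res.estimate == pytest.approx(1.0)
    assert res.statistic == "pearson_r"


def test_strictly_decreasing_gives_spearman_minus_one():
    x = np.arange(8.0)
    res = correlate(x, np.exp(-x), "spearman")
    assert res.estimate == pytest.approx(-1.0)


def test_spearman_rank_formula_example():
    # rank-formula oracle: rho = 1 - 6 * sum(d^2) / (n(n^2-1)) with sum(d^2) = 4
    res = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], "spearman")
    assert res.estimate == pytest.approx(1 - 6 * 4 / (5 * 24))


def test_zero_variance_flagged_not_raised():
    res = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "pearson")
    assert np.isnan(res.estimate) and res.note == "zero variance"


def test_correlation_preconditions():
    with pytest.raises(DataError):
        correlate([1.0, 2.0], [1.0, 2.0], "pearson")
    with pytest.raises(DataError):
        correlate([1.0, 2.0, np.inf], [1.0, 2.0, 3.0], "pearson")


class TestGroupCompare:
    def test_identical_groups_give_t_zero_p_one(self):
        vec = np.arange(20.0)
        table = pd.DataFrame(
            {"sp": np.concatenate([vec, vec]), "iso": ["a"] * 20 + ["b"] * 20}
        )
        (res,) = group_compare(table, "sp", "iso", [("a", "b")])
        assert abs(res.estimate) < 1e-12 and res.p_value == pytest.approx(1.0)

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(3, 1, 100)  # three pooled SDs apart
        table = pd.DataFrame(
            {"sp": np.concatenate([a, b]), "iso": ["a"] * 100 + ["b"] * 100}
        )
        (res,) = group_compare(table, "sp", "iso", [("a", "b")])
        assert res.adjusted_p < 1e-3

    def test_adjusted_p_never_below_raw_p(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {"sp": rng.normal(size=90), "iso": ["a", "b", "c"] * 30}
        )
        results = group_compare(table, "sp", "iso", [("a", "b"), ("a", "c"), ("b", "c")])
        assert len(results) == 3
        for res in results:
            assert res.adjusted_p >= res.p_value - 1e-15

    def test_tiny_groups_skipped(self):
        table = pd.DataFrame({"sp": [1.0, 2.0, 3.0], "iso": ["a", "a", "b"]})
        assert group_compare(table, "sp", "iso", [("a", "b")]) == []


class TestFeatureTable:
    def test_row_cardinality_and_join_losslessness(self, small_rep, germline_provider):
        scores = score_repertoire(
            small_rep, germline_provider, [InputSource.FULL_VDJ, InputSource.PAIRED]
        )
        table = sp_feature_table(scores, small_rep)
        assert len(table) == len(scores.records)  # 2 loci + paired per cell
        assert set(table.columns) >= {
            "sp", "isotype", "v_family", "hamming_shm",
            "normalized_expansion", "clone_id",
        }

    def test_indel_cell_gets_null_shm_but_keeps_isotype(self, germline_provider):
        from bcrlik.records import Repertoire

        cell = make_cell("indel1")
        cell.heavy.germline_aa = cell.heavy.germline_aa[:-1]  # length mismatch
        rep = Repertoire(cells=[cell], clone_assignment={"indel1": "clone_x"})
        scored = pd.DataFrame(
            [{"cell_id": "indel1", "locus": "heavy", "provider": "p",
              "source": "full_vdj", "sp": -0.5, "sample_id": "s1"}]
        )
        table = sp_feature_table(scored, rep)
        assert table["hamming_shm"].isna().all()
        assert (table["isotype"] == "IgM").all()

    def test_root_path_length_joined_from_forest(self, small_rep, germline_provider):
        scores = score_repertoire(small_rep, germline_provider, [InputSource.FULL_VDJ])
        forest = build_forest(small_rep)
        table = sp_feature_table(scores, small_rep, trees=forest)
        heavy = table[table["locus"] == "heavy"].dropna(subset=["root_path_length"])
        assert len(heavy) > 0
        assert (heavy["root_path_length"] >= 0).all()


class TestFrequencyAssociation:
    def test_proportional_frequencies_give_r_one(self):
        mean_sp = {"IGHV1": -0.2, "IGHV2": -0.4, "IGHV3": -0.6}
        freq = {"IGHV1": 50.0, "IGHV2": 30.0, "IGHV3": 10.0}
        res = frequency_association(mean_sp, freq)
        assert res.estimate == pytest.approx(1.0)

    def test_two_shared_groups_is_an_error(self):
        with pytest.raises(DataError, match="3 shared"):
            frequency_association({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0, "c": 3.0})

    def test_unmatched_groups_dropped(self):
        mean_sp = {"a": -1.0, "b": -2.0, "c": -3.0, "zzz": -9.0}
        freq = {"a": 10.0, "b": 20.0, "c": 30.0}
        res = frequency_association(mean_sp, freq)
        assert res.n == 3


class TestCrossModelCorrelation:
    def test_monotone_providers_correlate_perfectly(self, small_rep):
        frames = []
        for q in (0.6, 0.8):
            provider = GermlineAnchoredProvider.from_cells(
                small_rep.cells, q=q, name=f"anchored_q{q}"
            )
            frames.append(
                score_repertoire(small_rep, provider, [InputSource.FULL_VDJ]).to_frame()
            )
        out = cross_model_correlation(pd.concat(frames, ignore_index=True))
        off_diag = out[out["provider_a"] != out["provider_b"]]
        # both SPs are strictly monotone linear functions of mismatch count
        assert (off_diag["pearson_r"] > 0.999999).all()
        diag = out[out["provider_a"] == out["provider_b"]]
        assert (diag["pearson_r"] == 1.0).all()


class TestAffinityAssociation:
    def _table(self, small_rep, germline_provider):
        scores = score_repertoire(small_rep, germline_provider, [InputSource.FULL_VDJ])
        return sp_feature_table(scores, small_rep)

    def test_kd_monotone_in_sp_gives_rho_one(self, small_rep, germline_provider):
        from scipy.stats import rankdata

        table = self._table(small_rep, germline_provider)
        heavy = table[table["locus"] == "heavy"]
        # strictly monotone, tie-preserving map of SP onto a Kd scale
        aff = pd.DataFrame(
            {"sequence_id": heavy["cell_id"],
             "kd": 1e-9 * rankdata(heavy["sp"], method="average")}
        )
        res = affinity_association(heavy, aff)
        assert res.estimate == pytest.approx(1.0)

    def test_positive_kd_required(self, small_rep, germline_provider):
        heavy = self._table(small_rep, germline_provider)
        aff = pd.DataFrame({"sequence_id": ["cell000000"], "kd": [-1.0]})
        with pytest.raises(DataError):
            affinity_association(heavy, aff)

    def test_empty_intersection_is_an_error(self, small_rep, germline_provider):
        heavy = self._table(small_rep, germline_provider)
        aff = pd.DataFrame({"sequence_id": ["nope"], "kd": [1e-9]})
        with pytest.raises(DataError, match="overlap"):
            affinity_association(heavy, aff)
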