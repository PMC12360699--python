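"""Edge-substitution ranks, conserved-vs-mutating likelihoods, evenness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from bcrlik import (
    DataError,
    GermlineAnchoredProvider,
    UniformProvider,
    build_tree,
    conserved_vs_mutating,
    edge_substitutions,
    mean_substitution_rank,
    shannon_evenness,
)
from bcrlik.alphabet import AA_INDEX, N_AA
from bcrlik.likelihood import LikelihoodProvider, ProbabilityMatrix
from bcrlik.shm import EdgeSubstitutionRecord, SubstitutionDetail, competition_rank


class FixedColumnProvider(LikelihoodProvider):
    """Every position gets the same hand-specified 20-vector."""

    name = "fixed"

    def __init__(self, column):
        self.column = np.asarray(column, dtype=float)

    def residue_probabilities(self, sequence_aa):
        return ProbabilityMatrix(
            sequence_aa, np.tile(self.column, (len(sequence_aa), 1))
        )


def test_child_rank_from_sorted_column():
    # parent residue A most likely (rank 1); child residue C second (rank 2)
    col = np.zeros(N_AA)
    col[AA_INDEX["A"]], col[AA_INDEX["C"]], col[AA_INDEX["D"]] = 0.5, 0.3, 0.2
    provider = FixedColumnProvider(col)
    tree = build_tree({"CAAA": 1}, "AAAA")
    (record,) = edge_substitutions(tree, provider)
    (sub,) = record.substitutions
    assert (sub.position, sub.from_aa, sub.to_aa) == (0, "A", "C")
    assert sub.rank_child == 2
    assert sub.rank_parent == 1
    assert sub.rl_parent_residue == pytest.approx(0.5)


def test_one_hot_on_child_gives_rank_one():
    col = np.zeros(N_AA)
    col[AA_INDEX["C"]] = 1.0
    tree = build_tree({"CCAA": 1}, "AAAA")
    records = edge_substitutions(tree, FixedColumnProvider(col))
    assert all(s.rank_child == 1 for r in records for s in r.substitutions)


def test_edge_rank_is_mean_of_position_ranks():
    record = EdgeSubstitutionRecord(
        clone_id="c", parent_id="p", child_id="n",
        substitutions=[
            SubstitutionDetail(0, "A", "C", rank_child=1, rank_parent=1,
                               rl_parent_residue=0.5),
            SubstitutionDetail(3, "A", "D", rank_child=3, rank_parent=1,
                               rl_parent_residue=0.5),
        ],
    )
    assert record.edge_rank == 2.0


def test_competition_rank_matches_rankdata_oracle():
    rng = np.random.default_rng(4)
    for _ in range(300):
        col = rng.dirichlet(np.full(N_AA, 0.4))
        oracle = rankdata(-col, method="min")
        for idx in range(N_AA):
            assert competition_rank(col, idx) == oracle[idx]
    # argmax is always rank 1, even with ties
    tied = np.full(N_AA, 1 / N_AA)
    assert competition_rank(tied, int(np.argmax(tied))) == 1


def test_unequal_length_edges_skipped():
    provider = UniformProvider()
    tree = build_tree({"AAAAA": 1, "CAAA": 1}, "AAAA")  # one indel variant
    records = edge_substitutions(tree, provider)
    assert all(
        len(tree.sequence(r.parent_id)) == len(tree.sequence(r.child_id))
        for r in records
    )


def test_germline_edges_can_be_excluded():
    provider = UniformProvider()
    tree = build_tree({"CAAA": 1, "CCAA": 1}, "AAAA")
    with_root = edge_substitutions(tree, provider, include_germline_edges=True)
    without = edge_substitutions(tree, provider, include_germline_edges=False)
    assert len(with_root) == 2 and len(without) == 1
    assert all(r.parent_id != tree.root for r in without)


def test_conserved_vs_mutating_uniform_is_flat():
    tree = build_tree({"CAAA": 1}, "AAAA")
    out = conserved_vs_mutating(tree, UniformProvider())
    assert out.mean_rl_mutating == pytest.approx(0.05)
    assert out.mean_rl_conserved == pytest.approx(0.05)


def test_conserved_vs_mutating_germline_parent_closed_form():
    provider = GermlineAnchoredProvider(q=0.7)
    provider.register("AAAA", "AAAA")
    tree = build_tree({"CAAA": 1}, "AAAA")
    out = conserved_vs_mutating(tree, provider)
    # parent is the germline: its own residue has likelihood q everywhere
    assert out.mean_rl_mutating == pytest.approx(0.7)
    assert out.mean_rl_conserved == pytest.approx(0.7)


def test_mutating_rl_lower_when_mutations_target_low_likelihood_sites():
    # parent one mutation away from germline: the mutated site carries the
    # low alternative likelihood, conserved sites carry q
    provider = GermlineAnchoredProvider(q=0.7)
    provider.register("CAAA", "AAAA")
    # GAAA ties at distance 1 to both root and CAAA; the expanded candidate
    # parent (CAAA) wins, giving the edge CAAA -> GAAA whose mutated site is
    # exactly the position where CAAA already left the germline (low RL)
    tree = build_tree({"CAAA": 1, "GAAA": 1}, "AAAA")
    out = conserved_vs_mutating(tree, provider, include_germline_edges=False)
    assert out.mean_rl_mutating == pytest.approx(0.3 / 19)
    assert out.mean_rl_conserved == pytest.approx(0.7)


@pytest.mark.parametrize(
    "col,expected",
    [
        (np.full(N_AA, 1 / N_AA), 1.0),
        (np.eye(N_AA)[0], 0.0),
        (np.array([0.5, 0.5] + [0.0] * 18), math.log(2) / math.log(20)),
    ],
)
def test_shannon_evenness_closed_forms(col, expected):
    assert shannon_evenness(col) == pytest.approx(expected, abs=1e-12)


def test_shannon_evenness_rejects_bad_columns():
    with pytest.raises(DataError):
        shannon_evenness(np.array([-0.1, 1.1] + [0.0] * 18))
    with pytest.raises(DataError):
        shannon_evenness(np.full(N_AA, 0.1))


@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_shannon_evenness_bounds_and_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    col = rng.dirichlet(np.full(N_AA, 0.3))
    ev = shannon_evenness(col)
    assert 0.0 <= ev <= 1.0
    assert shannon_evenness(rng.permutation(col)) == pytest.approx(ev, abs=1e-12)


def test_mean_substitution_rank_grouping():
    def rec(sample, ranks):
        return EdgeSubstitutionRecord(
            clone_id="c", parent_id="p", child_id="n", sample_id=sample,
            substitutions=[
                SubstitutionDetail(i, "A", "C", rank_child=r, rank_parent=1,
                                   rl_parent_residue=0.5)
                for i, r in enumerate(ranks)
            ],
        )

    per_sample, grand = mean_substitution_rank(
        [rec("s1", [1]), rec("s1", [3]), rec("s2", [4])]
    )
    means = dict(zip(per_sample["sample_id"], per_sample["mean_edge_rank"]))
    assert means == {"s1": 2.0, "s2": 4.0}
    assert grand == 3.0  # unweighted mean of sample means, not edge-pooled
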