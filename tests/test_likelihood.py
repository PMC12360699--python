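"""SP computation, provider contract, and the three input sources."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrlik import (
    ConfigError,
    DataError,
    DirichletColumnProvider,
    GermlineAnchoredProvider,
    InputSource,
    ProbabilityMatrix,
    UniformProvider,
    compute_sp,
    score_repertoire,
)
from bcrlik.alphabet import AA_INDEX, AMINO_ACIDS, N_AA


def one_hot_matrix(sequence):
    probs = np.zeros((len(sequence), N_AA))
    probs[np.arange(len(sequence)), [AA_INDEX[c] for c in sequence]] = 1.0
    return ProbabilityMatrix(sequence, probs)


def test_uniform_matrix_sp_is_log_one_twentieth():
    m = UniformProvider().residue_probabilities("ACDEFGHIKL")
    assert compute_sp(m) == pytest.approx(math.log(1 / 20), abs=1e-12)


def test_one_hot_matrix_sp_is_zero():
    assert compute_sp(one_hot_matrix("ACDEFG")) == pytest.approx(0.0, abs=1e-15)


def test_two_position_arithmetic_example():
    # p(A@0)=0.5, p(C@1)=0.25, remaining mass spread over other residues
    probs = np.full((2, N_AA), 0.5 / 19)
    probs[0, AA_INDEX["A"]] = 0.5
    probs[1] = 0.75 / 19
    probs[1, AA_INDEX["C"]] = 0.25
    m = ProbabilityMatrix("AC", probs)
    assert compute_sp(m) == pytest.approx((math.log(0.5) + math.log(0.25)) / 2, abs=1e-12)


def test_zero_probability_is_floored():
    probs = np.zeros((1, N_AA))
    probs[0, AA_INDEX["C"]] = 1.0  # observed residue A gets exactly 0
    m = ProbabilityMatrix("A", probs)
    assert compute_sp(m) == pytest.approx(math.log(1e-10))


def test_log2_base_flag():
    m = UniformProvider().residue_probabilities("ACD")
    assert compute_sp(m, log_base="2") == pytest.approx(math.log2(1 / 20))


def test_positions_subset_and_bounds():
    m = one_hot_matrix("ACDEFG")
    assert compute_sp(m, positions=[0, 2]) == 0.0
    with pytest.raises(DataError):
        compute_sp(m, positions=[])
    with pytest.raises(DataError):
        compute_sp(m, positions=[99])


def test_probability_matrix_validation():
    with pytest.raises(DataError):
        ProbabilityMatrix("AC", np.ones((2, N_AA)))  # rows sum to 20
    with pytest.raises(DataError):
        ProbabilityMatrix("AC", np.full((3, N_AA), 1 / N_AA))  # wrong length


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_sp_matches_per_position_log_mean_oracle(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(2, 30))
    probs = rng.dirichlet(np.ones(N_AA), size=L)
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, L))
    m = ProbabilityMatrix(seq, probs)
    oracle = sum(math.log(probs[i][AA_INDEX[c]]) for i, c in enumerate(seq)) / L
    assert compute_sp(m) == pytest.approx(oracle, abs=1e-12)


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_sp_invariant_under_matched_position_permutation(seed):
    rng = np.random.default_rng(seed)
    L = 12
    probs = rng.dirichlet(np.ones(N_AA), size=L)
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, N_AA, L))
    perm = rng.permutation(L)
    m1 = ProbabilityMatrix(seq, probs)
    m2 = ProbabilityMatrix("".join(seq[i] for i in perm), probs[perm])
    assert compute_sp(m1) == pytest.approx(compute_sp(m2), abs=1e-12)


def test_sp_bounded_by_per_position_extremes(germline_provider, small_rep):
    cell = small_rep.cells[0]
    m = germline_provider.residue_probabilities(cell.heavy.sequence_aa)
    logs = np.log(m.observed_probabilities())
    sp = compute_sp(m)
    assert logs.min() - 1e-12 <= sp <= logs.max() + 1e-12


class TestGermlineAnchoredProvider:
    def test_q_boundaries_rejected(self):
        for q in (1 / 20, 1.0, 0.0):
            with pytest.raises(ConfigError):
                GermlineAnchoredProvider(q=q)

    def test_sequence_equal_to_germline_scores_ln_q(self):
        provider = GermlineAnchoredProvider(q=0.7)
        provider.register("ACDEF", "ACDEF")
        assert compute_sp(provider.residue_probabilities("ACDEF")) == pytest.approx(
            math.log(0.7), abs=1e-12
        )

    def test_mismatch_closed_form(self):
        provider = GermlineAnchoredProvider(q=0.7)
        germ = "A" * 100
        seq = "C" * 10 + "A" * 90
        provider.register(seq, germ)
        expected = (90 * math.log(0.7) + 10 * math.log(0.3 / 19)) / 100
        assert compute_sp(provider.residue_probabilities(seq)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_or_mismatched_germline_rejected(self):
        provider = GermlineAnchoredProvider(q=0.7)
        with pytest.raises(DataError):
            provider.residue_probabilities("ACDEF")
        with pytest.raises(DataError):
            provider.register("ACDEF", "ACDE")

    def test_sp_strictly_decreasing_in_mismatches(self):
        provider = GermlineAnchoredProvider(q=0.7)
        germ = "A" * 50
        sps = []
        for k in range(5):
            seq = "C" * k + "A" * (50 - k)
            provider.register(seq, germ)
            sps.append(compute_sp(provider.residue_probabilities(seq)))
        assert all(a > b for a, b in zip(sps, sps[1:]))


class TestScoreRepertoire:
    def test_record_cardinality(self, small_rep, germline_provider):
        rep_three = type(small_rep)(
            cells=small_rep.cells[:3],
            clone_assignment=small_rep.clone_assignment,
        )
        result = score_repertoire(rep_three, germline_provider, [InputSource.FULL_VDJ])
        assert len(result.records) == 6  # heavy + light per cell

    def test_paired_germline_cells_score_ln_q(self, small_sim, germline_provider):
        rep = small_sim.to_repertoire()
        result = score_repertoire(rep, germline_provider, [InputSource.PAIRED])
        unmutated = [c.cell_id for c in rep.cells
                     if c.heavy.sequence_aa == c.heavy.germline_aa
                     and c.light.sequence_aa == c.light.germline_aa]
        assert unmutated, "fixture should contain unmutated cells"
        for rec in result.records:
            if rec.cell_id in unmutated[:5]:
                assert rec.sp == pytest.approx(math.log(0.7), abs=1e-12)

    def test_cdr3_sources_agree_for_position_independent_provider(
        self, small_rep, germline_provider
    ):
        result = score_repertoire(
            small_rep, germline_provider,
            [InputSource.CDR3_FROM_VDJ, InputSource.CDR3_ONLY],
        )
        by_key = {}
        for rec in result.records:
            by_key.setdefault((rec.cell_id, rec.locus), {})[rec.source] = rec.sp
        for sps_ in by_key.values():
            assert sps_[InputSource.CDR3_FROM_VDJ] == pytest.approx(
                sps_[InputSource.CDR3_ONLY], abs=1e-12
            )

    def test_cdr3_sources_differ_for_context_sensitive_provider(self, small_rep):
        provider = DirichletColumnProvider(seed=3)
        result = score_repertoire(
            small_rep, provider,
            [InputSource.CDR3_FROM_VDJ, InputSource.CDR3_ONLY],
        )
        by_key = {}
        for rec in result.records:
            by_key.setdefault((rec.cell_id, rec.locus), {})[rec.source] = rec.sp
        diffs = [
            abs(v[InputSource.CDR3_FROM_VDJ] - v[InputSource.CDR3_ONLY])
            for v in by_key.values()
        ]
        assert max(diffs) > 1e-6

    def test_paired_requires_capability(self, small_rep):
        with pytest.raises(ConfigError):
            score_repertoire(small_rep, DirichletColumnProvider(), [InputSource.PAIRED])

    def test_provider_determinism(self):
        provider = DirichletColumnProvider(seed=9)
        a = provider.residue_probabilities("ACDEFGHIKL")
        b = provider.residue_probabilities("ACDEFGHIKL")
        assert np.array_equal(a.probs, b.probs)
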