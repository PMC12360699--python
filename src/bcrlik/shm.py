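"""Edge-substitution rank statistics and per-position evenness of RL columns.

For every lineage-tree edge whose endpoint sequences have equal length, the
parent sequence (seq1) is scored by the likelihood provider and, at each
position where parent and child differ, the child's residue is ranked within
the parent's probability column (descending; rank 1 = most likely residue).
Competition ranking — 1 + the number of strictly greater probabilities — is
used so exact ties (common with synthetic providers) keep "most likely =>
rank 1" exact. Edges with several differing positions report the mean child
rank as their substitution rank. Unequal-length edges (indels) are skipped
and counted.

The same per-edge matrices yield the conserved-vs-mutating contrast: the mean
parent-residue likelihood at differing (mutating) versus identical
(conserved) positions, compared with a paired t-test across edges.

Shannon evenness of a probability column is H / ln 20 with
H = -sum p ln p (0 ln 0 = 0): 1 for a uniform column, 0 for a one-hot one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alphabet import AA_INDEX, N_AA
from .errors import DataError
from .likelihood import LikelihoodProvider, ProbabilityMatrix
from .lineage import LineageTree


def competition_rank(column: np.ndarray, index: int) -> int:
    """Descending competition rank of entry ``index`` in a 20-vector."""
    return 1 + int(np.sum(column > column[index]))


@dataclass
class SubstitutionDetail:
    position: int
    from_aa: str
    to_aa: str
    rank_child: int
    rank_parent: int
    rl_parent_residue: float


@dataclass
class EdgeSubstitutionRecord:
    """Differential positions of one equal-length lineage edge."""

    clone_id: str
    parent_id: str
    child_id: str
    substitutions: list[SubstitutionDetail]
    sample_id: str = ""

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.substitutions]

    @property
    def edge_rank(self) -> float:
        return float(np.mean([s.rank_child for s in self.substitutions]))


@dataclass
class ConservedVsMutating:
    """Pooled parent-residue likelihoods at mutating vs conserved positions."""

    mean_rl_mutating: float
    mean_rl_conserved: float
    per_edge: list[tuple[float, float]]  # (mutating mean, conserved mean) per edge
    t_statistic: float
    p_value: float


def edge_substitutions(
    tree: LineageTree,
    provider: LikelihoodProvider,
    include_germline_edges: bool = True,
    matrix_cache: dict | None = None,
    sample_id: str = "",
) -> list[EdgeSubstitutionRecord]:
    """Rank the child residue of every substitution in the parent's RL column.

    The probability matrix is always computed for the parent (pre-edge)
    sequence with full-sequence context. ``include_germline_edges`` controls
    whether edges leaving the root participate (the germline is a valid
    parent sequence; set False to restrict to sampled-sequence parents).
    """
    cache = matrix_cache if matrix_cache is not None else {}

    def matrix_for(seq: str) -> ProbabilityMatrix:
        if seq not in cache:
            cache[seq] = provider.residue_probabilities(seq)
        return cache[seq]

    records: list[EdgeSubstitutionRecord] = []
    for parent, child, _w in tree.edges():
        if not include_germline_edges and parent == tree.root:
            continue
        p_seq = tree.sequence(parent)
        c_seq = tree.sequence(child)
        if len(p_seq) != len(c_seq):
            continue
        diff = [i for i, (a, b) in enumerate(zip(p_seq, c_seq)) if a != b]
        if not diff:
            continue
        m = matrix_for(p_seq)
        details = []
        for i in diff:
            col = m.probs[i]
            details.append(
                SubstitutionDetail(
                    position=i,
                    from_aa=p_seq[i],
                    to_aa=c_seq[i],
                    rank_child=competition_rank(col, AA_INDEX[c_seq[i]]),
                    rank_parent=competition_rank(col, AA_INDEX[p_seq[i]]),
                    rl_parent_residue=float(col[AA_INDEX[p_seq[i]]]),
                )
            )
        records.append(
            EdgeSubstitutionRecord(
                clone_id=tree.clone_id,
                parent_id=parent,
                child_id=child,
                substitutions=details,
                sample_id=sample_id,
            )
        )
    return records


def forest_edge_substitutions(
    forest: Mapping[str, LineageTree],
    provider: LikelihoodProvider,
    include_germline_edges: bool = True,
    sample_id: str = "",
) -> list[EdgeSubstitutionRecord]:
    """Edge substitutions over all trees, sharing one matrix cache."""
    cache: dict = {}
    out: list[EdgeSubstitutionRecord] = []
    for clone_id in sorted(forest):
        out.extend(
            edge_substitutions(
                forest[clone_id], provider,
                include_germline_edges=include_germline_edges,
                matrix_cache=cache, sample_id=sample_id,
            )
        )
    return out


def conserved_vs_mutating(
    tree_or_forest,
    provider: LikelihoodProvider,
    include_germline_edges: bool = True,
) -> ConservedVsMutating:
    """Parent-residue likelihood at mutating vs conserved positions, per edge.

    Edges with zero conserved positions contribute only to the mutating side;
    the paired t-test runs over edges where both means exist.
    """
    forest = (
        tree_or_forest
        if isinstance(tree_or_forest, Mapping)
        else {tree_or_forest.clone_id: tree_or_forest}
    )
    cache: dict = {}
    mutating_all: list[float] = []
    conserved_all: list[float] = []
    pairs: list[tuple[float, float]] = []
    for clone_id in sorted(forest):
        tree = forest[clone_id]
        for parent, child, _w in tree.edges():
            if not include_germline_edges and parent == tree.root:
                continue
            p_seq, c_seq = tree.sequence(parent), tree.sequence(child)
            if len(p_seq) != len(c_seq):
                continue
            diff = [i for i, (a, b) in enumerate(zip(p_seq, c_seq)) if a != b]
            if not diff:
                continue
            if p_seq not in cache:
                cache[p_seq] = provider.residue_probabilities(p_seq)
            m = cache[p_seq]
            own = m.observed_probabilities()
            same = [i for i in range(len(p_seq)) if i not in set(diff)]
            mut_mean = float(own[diff].mean())
            mutating_all.extend(own[diff])
            if same:
                cons_mean = float(own[same].mean())
                conserved_all.extend(own[same])
                pairs.append((mut_mean, cons_mean))
    if not mutating_all:
        raise DataError("no qualifying edges")
    if len(pairs) >= 2:
        mut, cons = np.array(pairs).T
        if np.allclose(mut, cons):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(mut, cons)
    else:
        t, p = float("nan"), float("nan")
    return ConservedVsMutating(
        mean_rl_mutating=float(np.mean(mutating_all)),
        mean_rl_conserved=float(np.mean(conserved_all)) if conserved_all else float("nan"),
        per_edge=pairs,
        t_statistic=float(t),
        p_value=float(p),
    )


def shannon_evenness(column: Sequence[float]) -> float:
    """Normalized Shannon entropy H / ln(20) of one probability column."""
    col = np.asarray(column, dtype=float)
    if col.shape != (N_AA,):
        raise DataError(f"expected a {N_AA}-vector, got shape {col.shape}")
    if (col < 0).any():
        raise DataError("negative probabilities")
    if not np.isclose(col.sum(), 1.0, atol=1e-6):
        raise DataError("column must sum to 1")
    nz = col[col > 0]
    h = -float(np.sum(nz * np.log(nz)))
    return h / np.log(N_AA)


def matrix_evenness(matrix: ProbabilityMatrix) -> np.ndarray:
    """Shannon evenness of every position's RL column."""
    return np.array([shannon_evenness(row) for row in matrix.probs])


def mean_substitution_rank(
    records: Iterable[EdgeSubstitutionRecord],
) -> tuple[pd.DataFrame, float]:
    """Per-sample mean edge rank and the unweighted grand mean across samples.

    The grand mean averages sample means (every sample counts equally), not
    pooled edges.
    """
    records = list(records)
    if not records:
        raise DataError("no edge substitution records")
    df = pd.DataFrame(
        {"sample_id": r.sample_id, "edge_rank": r.edge_rank} for r in records
    )
    per_sample = (
        df.groupby("sample_id", as_index=False)["edge_rank"].mean()
        .rename(columns={"edge_rank": "mean_edge_rank"})
    )
    return per_sample, float(per_sample["mean_edge_rank"].mean())


def edge_records_to_frame(records: Iterable[EdgeSubstitutionRecord]) -> pd.DataFrame:
    """Long table: one row per substitution."""
    rows = []
    for r in records:
        for s in r.substitutions:
            rows.append(
                {
                    "clone_id": r.clone_id,
                    "sample_id": r.sample_id,
                    "parent_id": r.parent_id,
                    "child_id": r.child_id,
                    "position": s.position,
                    "from_aa": s.from_aa,
                    "to_aa": s.to_aa,
                    "rank_child": s.rank_child,
                    "rank_parent": s.rank_parent,
                    "rl_parent_residue": s.rl_parent_residue,
                    "edge_rank": r.edge_rank,
                }
            )
    return pd.DataFrame(rows)
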