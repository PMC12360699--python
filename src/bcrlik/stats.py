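"""Repertoire-level association analyses.

Joins SP scores to repertoire features (isotype, V family, SHM, clonal
expansion, lineage root distance) and runs the standard battery: Pearson /
Spearman correlations, Welch two-sample contrasts with multiplicity
adjustment, group-frequency associations against an external (OAS-style)
table, cross-provider correlation matrices, and affinity associations.

Signed correlations are reported as r / rho (a squared quantity cannot be
negative). Sample-level averages are unweighted means of per-sample
statistics, never pooled-cell means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .io import hamming_shm, normalized_expansion
from .likelihood import ScoredSequence, ScoreResult
from .records import Repertoire, v_family


@dataclass
class AssociationResult:
    analysis: str
    grouping: str
    statistic: str  # "pearson_r" | "spearman_rho" | "welch_t"
    estimate: float
    p_value: float
    n: int
    adjusted_p: float = float("nan")
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "grouping": self.grouping,
            "statistic": self.statistic,
            "estimate": self.estimate,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
            "n": self.n,
            "note": self.note,
        }


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    analysis: str = "",
    grouping: str = "",
) -> AssociationResult:
    """Pearson or Spearman correlation with a two-sided p-value (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise DataError("correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in correlation input")
    stat_name = {"pearson": "pearson_r", "spearman": "spearman_rho"}.get(method)
    if stat_name is None:
        raise DataError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(
            analysis, grouping, stat_name, float("nan"), float("nan"), len(x),
            note="zero variance",
        )
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        r, p = sps.spearmanr(x, y)
    return AssociationResult(analysis, grouping, stat_name, float(r), float(p), len(x))


def sp_feature_table(
    scored: ScoreResult | Iterable[ScoredSequence] | pd.DataFrame,
    rep: Repertoire,
    trees: Mapping | None = None,
) -> pd.DataFrame:
    """One row per scored record, joined to per-cell repertoire features.

    Columns: cell_id, locus, provider, source, sp, sample_id, isotype,
    v_family, hamming_shm (null for indel cells), clone_id,
    normalized_expansion, and root_path_length when a lineage forest is
    supplied (heavy-chain node of the cell's clone tree). Features that do
    not resolve are null and excluded per-analysis, not at join time.
    """
    if isinstance(scored, ScoreResult):
        df = scored.to_frame()
    elif isinstance(scored, pd.DataFrame):
        df = scored.copy()
    else:
        df = ScoreResult(list(scored), {}).to_frame()

    expansion = normalized_expansion(rep) if rep.cells else {}
    features = {}
    for cell in rep.cells:
        clone = rep.clone_assignment.get(cell.cell_id)
        root_dist = None
        if trees is not None and clone in trees:
            node = trees[clone].node_of(cell.heavy.sequence_aa)
            if node is not None:
                root_dist = trees[clone].root_path_length(node)
        features[cell.cell_id] = {
            "isotype": cell.isotype,
            "v_family": v_family(cell.heavy.v_call),
            "hamming_shm": hamming_shm(cell.heavy.sequence_aa, cell.heavy.germline_aa),
            "clone_id": clone,
            "normalized_expansion": expansion.get(clone),
            "root_path_length": root_dist,
        }
    feat = pd.DataFrame.from_dict(features, orient="index")
    feat.index.name = "cell_id"
    return df.join(feat, on="cell_id")


def group_compare(
    table: pd.DataFrame,
    value: str,
    group: str,
    pairs: Sequence[tuple[str, str]],
    adjust: str = "holm",
) -> list[AssociationResult]:
    """Welch two-sample t-test per pair, multiplicity-adjusted over the family.

    ``adjust`` is "holm" (default), "bonferroni" or "bh". Pairs with a group
    below n = 2 are skipped. Degenerate identical groups report t = 0, p = 1.
    """
    results: list[AssociationResult] = []
    for a, b in pairs:
        xa = table.loc[table[group] == a, value].dropna().to_numpy(dtype=float)
        xb = table.loc[table[group] == b, value].dropna().to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            continue
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (float("inf"), 0.0)
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
        results.append(
            AssociationResult(
                analysis=f"{value}~{group}",
                grouping=f"{a} vs {b}",
                statistic="welch_t",
                estimate=float(t),
                p_value=float(p),
                n=len(xa) + len(xb),
            )
        )
    if results:
        method = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}.get(adjust)
        if method is None:
            raise DataError(f"unknown adjustment {adjust!r}")
        _, adj, _, _ = multipletests([r.p_value for r in results], method=method)
        for r, ap in zip(results, adj):
            r.adjusted_p = float(ap)
    return results


def frequency_association(
    mean_sp_by_group: Mapping[str, float] | pd.DataFrame,
    frequency_table: Mapping[str, float] | pd.DataFrame,
    analysis: str = "frequency_association",
) -> AssociationResult:
    """Pearson correlation between group mean SP and group frequency percent.

    Requires at least three shared groups; unmatched groups are dropped.
    """

    def as_map(obj, value_col):
        if isinstance(obj, pd.DataFrame):
            return dict(zip(obj["group"], obj[value_col]))
        return dict(obj)

    sp_map = as_map(mean_sp_by_group, "mean_sp")
    freq_map = as_map(frequency_table, "percent")
    shared = sorted(set(sp_map) & set(freq_map))
    if len(shared) < 3:
        raise DataError(f"need >= 3 shared groups, found {len(shared)}")
    return correlate(
        [sp_map[g] for g in shared],
        [freq_map[g] for g in shared],
        method="pearson",
        analysis=analysis,
        grouping=",".join(shared),
    )


def cross_model_correlation(
    scored_tables: pd.DataFrame, by: str = "source"
) -> pd.DataFrame:
    """Pairwise Pearson r of SP between providers, per input source.

    ``scored_tables`` is a long frame (columns provider, source, cell_id,
    locus, sp), typically a concatenation over providers. Pairs sharing fewer
    than 3 cells are flagged with a null estimate.
    """
    rows = []
    for (source, locus), sub in scored_tables.groupby([by, "locus"]):
        wide = sub.pivot_table(index="cell_id", columns="provider", values="sp")
        providers = list(wide.columns)
        for i, a in enumerate(providers):
            for b in providers[i:]:
                paired = wide[[a, b]].dropna() if a != b else wide[[a]].dropna()
                n = len(paired)
                if a == b:
                    r = 1.0 if n else float("nan")
                elif n < 3:
                    r = float("nan")
                else:
                    r = correlate(paired[a], paired[b]).estimate
                rows.append(
                    {by: source, "locus": locus, "provider_a": a, "provider_b": b,
                     "pearson_r": r, "n": n}
                )
    return pd.DataFrame(rows)


def affinity_association(
    feature_table: pd.DataFrame,
    affinity_table: pd.DataFrame,
    scope: str = "polyclonal",
    clone_id: str | None = None,
) -> AssociationResult:
    """Spearman correlation between SP and Kd over matched sequence ids.

    ``scope`` "polyclonal" uses all matched cells; "intraclonal" restricts to
    one clone (requires ``clone_id``). Unmatched ids are dropped with a count
    in the result note; an empty intersection is an error.
    """
    if (affinity_table["kd"] <= 0).any():
        raise DataError("Kd values must be strictly positive")
    df = feature_table.merge(
        affinity_table[["sequence_id", "kd"]],
        left_on="cell_id", right_on="sequence_id", how="inner",
    )
    dropped = len(feature_table) - len(df)
    if scope == "intraclonal":
        if clone_id is None:
            raise DataError("intraclonal scope requires a clone_id")
        df = df[df["clone_id"] == clone_id]
    elif scope != "polyclonal":
        raise DataError(f"unknown scope {scope!r}")
    if df.empty:
        raise DataError("no overlap between scored cells and affinity table")
    res = correlate(
        df["sp"], df["kd"], method="spearman",
        analysis=f"affinity_{scope}", grouping=clone_id or "all",
    )
    res.note = (res.note + f" dropped={dropped}").strip()
    return res


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
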