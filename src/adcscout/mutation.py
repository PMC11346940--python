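"""Mutation-conditioned differential expression screen.

For each (target, query gene, tumor cohort) triple, cohort samples are split
into carriers of a somatic mutation in the query gene versus wild type, and
the target's expression is compared with a two-sided Wilcoxon rank-sum test.
The effect size is ``log2((mean_mut + 1) / (mean_wt + 1))`` on the TPM scale;
a triple is retained when p < alpha, |log2FC| >= 1 and the mutated fraction
of the cohort is >= 5% (all thresholds configurable).  No multiple-testing
correction is applied by default; a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "AssociationRecord",
    "rank_sum_p",
    "association_test",
    "screen_associations",
    "summarize_by_query",
    "radar_table",
]

#: Largest combined group size for which the exact permutation null is used.
EXACT_MAX_N = 20


def rank_sum_p(x, y, *, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For combined sizes up to ``exact_max_n`` the permutation null is
    enumerated exactly (mid-ranks, so ties are handled); larger samples use
    the tie- and continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= exact_max_n:
        return _exact_rank_sum_p(x, y)
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, n1 = pooled.size, x.size
    w_obs = ranks[:n1].sum()
    center = n1 * (n + 1) / 2.0
    d_obs = abs(w_obs - center)
    hits = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - center) >= d_obs - 1e-12:
            hits += 1
    return hits / comb(n, n1)


class AssociationRecord(NamedTuple):
    target: str
    query_gene: str
    cohort: str
    log2_fc: float
    p_value: float
    prevalence: float
    direction: str | None  # "up", "down", or None when the effect is exactly 0
    n_mut: int
    n_wt: int
    testable: bool


def _mutated_samples(muts: pd.DataFrame, query_gene: str) -> set[str]:
    return set(muts.loc[muts["gene"] == query_gene, "sample"])


def association_test(
    expr: ExpressionMatrix,
    muts: pd.DataFrame,
    cohort: str,
    target: str,
    query_gene: str,
    *,
    min_group: int = 3,
    covered_samples: Iterable[str] | None = None,
) -> AssociationRecord:
    """Test one (target, query, cohort) triple; small groups are flagged untestable.

    When ``covered_samples`` is given, cohort samples outside it are excluded
    from both groups (samples without mutation data are not assumed wild
    type); otherwise every cohort sample without a call counts as wild type.
    """
    if target not in expr.values.index:
        raise KeyError(f"gene {target!r} absent from expression matrix")
    samples = expr.cohort_samples(cohort)
    if covered_samples is not None:
        covered = set(covered_samples)
        samples = [s for s in samples if s in covered]
    carriers = _mutated_samples(muts, query_gene)
    mut_samples = [s for s in samples if s in carriers]
    wt_samples = [s for s in samples if s not in carriers]
    n_mut, n_wt = len(mut_samples), len(wt_samples)
    prevalence = n_mut / (n_mut + n_wt) if (n_mut + n_wt) else 0.0
    if n_mut < min_group or n_wt < min_group:
        return AssociationRecord(
            target, query_gene, cohort, np.nan, np.nan, prevalence, None, n_mut, n_wt, False
        )
    xm = expr.values.loc[target, mut_samples].to_numpy(float)
    xw = expr.values.loc[target, wt_samples].to_numpy(float)
    log2_fc = float(np.log2((xm.mean() + 1.0) / (xw.mean() + 1.0)))
    if np.all(xm == xm[0]) and np.all(xw == xm[0]):
        # degenerate null: identical constant values in both groups
        return AssociationRecord(
            target, query_gene, cohort, 0.0, 1.0, prevalence, None, n_mut, n_wt, True
        )
    p = rank_sum_p(xm, xw)
    direction = "up" if log2_fc > 0 else ("down" if log2_fc < 0 else None)
    return AssociationRecord(
        target, query_gene, cohort, log2_fc, p, prevalence, direction, n_mut, n_wt, True
    )


def screen_associations(
    expr: ExpressionMatrix,
    muts: pd.DataFrame,
    targets: Iterable[str],
    queries: Iterable[str],
    *,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_prevalence: float = 0.05,
    min_group: int = 3,
    covered_samples: Iterable[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen all (target, query, cohort) triples and apply the joint gate.

    Retains records with p < alpha AND |log2FC| >= min_abs_log2fc AND
    prevalence >= min_prevalence; both up- and down-regulation are kept.
    With ``fdr=True`` the p gate uses Benjamini-Hochberg adjusted values.
    """
    targets = [t for t in targets if t in expr.values.index]
    queries = list(dict.fromkeys(queries))
    records: list[AssociationRecord] = []
    for cohort in expr.cohorts():
        for query in queries:
            for target in targets:
                rec = association_test(
                    expr,
                    muts,
                    cohort,
                    target,
                    query,
                    min_group=min_group,
                    covered_samples=covered_samples,
                )
                if rec.testable:
                    records.append(rec)
    df = pd.DataFrame(records, columns=AssociationRecord._fields)
    if df.empty:
        return df.drop(columns=["testable"], errors="ignore")
    p_gate = df["p_value"].to_numpy(float)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_gate = multipletests(p_gate, method="fdr_bh")[1]
    keep = (
        (p_gate < alpha)
        & (df["log2_fc"].abs() >= min_abs_log2fc)
        & (df["prevalence"] >= min_prevalence)
    )
    return df.loc[keep].drop(columns=["testable"]).reset_index(drop=True)


def summarize_by_query(records: pd.DataFrame) -> pd.DataFrame:
    """Per query gene: distinct targets/cohorts affected and direction breakdown."""
    cols = ["query_gene", "n_targets_affected", "n_cohorts", "n_up", "n_down"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    grouped = records.groupby("query_gene")
    out = pd.DataFrame(
        {
            "n_targets_affected": grouped["target"].nunique(),
            "n_cohorts": grouped["cohort"].nunique(),
            "n_up": grouped.apply(
                lambda g: int((g["direction"] == "up").sum()), include_groups=False
            ),
            "n_down": grouped.apply(
                lambda g: int((g["direction"] == "down").sum()), include_groups=False
            ),
        }
    ).reset_index()
    return out[cols]


def radar_table(records: pd.DataFrame, target: str) -> pd.DataFrame:
    """(cohort x query) -> log2FC table for one target (radar-plot layout)."""
    sub = records[records["target"] == target]
    if sub.empty:
        return pd.DataFrame()
    return sub.pivot_table(
        index="cohort", columns="query_gene", values="log2_fc", aggfunc="mean"
    ).rename_axis(index=None, columns=None)
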