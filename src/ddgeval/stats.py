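"""Mann-Whitney U comparison of AUC distributions: group versus complement.

The U statistic is computed with midranks. P-values use exact permutation
enumeration for small tie-free samples (combined n <= 16) and the normal
approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data import GroupPredicate
from .errors import ConfigError
from .evaluate import AUCSummary

__all__ = [
    "MannWhitneyResult",
    "GroupComparison",
    "mann_whitney_u",
    "compare_group_vs_complement",
]

_ALTERNATIVES = ("two_sided", "greater", "less")
_EXACT_MAX_N = 16


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class GroupComparison:
    """Result of comparing a gene group's AUCs against its complement's."""

    predictor: str
    group_name: str
    unit: str  # per_gene_mean_auc | per_rep_auc
    n_group: int
    n_complement: int
    u_statistic: float | None
    p_value: float | None
    computable: bool = True
    reason: str = ""


def _u_from_ranks(a: np.ndarray, b: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def _exact_p(u_obs: float, n_a: int, n_b: int, alternative: str) -> float:
    """Permutation p-value by full enumeration over rank assignments."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    count = 0
    total = 0
    rank_sum_offset = n_a * (n_a + 1) / 2.0
    for combo in itertools.combinations(range(1, n + 1), n_a):
        u = sum(combo) - rank_sum_offset
        total += 1
        if alternative == "greater":
            count += u >= u_obs - 1e-12
        elif alternative == "less":
            count += u <= u_obs + 1e-12
        else:
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return count / total


def _normal_p(u_obs: float, a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return 1.0
    sigma = np.sqrt(sigma2)
    if alternative == "greater":
        z = (u_obs - mu - 0.5) / sigma
        return float(norm.sf(z))
    if alternative == "less":
        z = (u_obs - mu + 0.5) / sigma
        return float(norm.cdf(z))
    z = (abs(u_obs - mu) - 0.5) / sigma
    return float(2.0 * norm.sf(z))


def mann_whitney_u(
    sample_a: np.ndarray, sample_b: np.ndarray, alternative: str = "two_sided"
) -> MannWhitneyResult:
    """Mann-Whitney U of ``sample_a`` relative to ``sample_b``.

    U counts the (a, b) pairs where a outranks b, ties credited half
    (midranks). ``alternative='greater'`` tests whether a tends to exceed b.
    """
    if alternative not in _ALTERNATIVES:
        raise ConfigError(f"alternative must be one of {_ALTERNATIVES}")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("mann_whitney_u requires two non-empty samples")
    u = _u_from_ranks(a, b)
    n = a.size + b.size
    has_ties = np.unique(np.concatenate([a, b])).size < n
    if n <= _EXACT_MAX_N and not has_ties:
        p = _exact_p(u, a.size, b.size, alternative)
        method = "exact"
    else:
        p = _normal_p(u, a, b, alternative)
        method = "normal"
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return MannWhitneyResult(u_statistic=u, p_value=p, method=method)


def compare_group_vs_complement(
    per_gene_table: dict[str, AUCSummary],
    predicate: GroupPredicate,
    flags: pd.DataFrame,
    unit: str = "per_gene_mean_auc",
    alternative: str = "two_sided",
    stratified: tuple[AUCSummary | None, AUCSummary | None] | None = None,
    predictor: str | None = None,
) -> GroupComparison:
    """Compare a gene group's AUC distribution against its complement's.

    The default unit compares per-gene mean balanced AUCs (genes are the
    exchangeable units). ``unit='per_rep_auc'`` instead compares the
    per-replicate AUCs of the pooled group/complement strata passed via
    ``stratified``; replicates of a pooled stratum overlap heavily, so this
    mode is anticonservative and flagged as such in reports.
    """
    if unit == "per_gene_mean_auc":
        if not per_gene_table:
            raise ConfigError("per_gene_table is empty")
        membership = predicate.mask(flags)
        pred_name = predictor or next(iter(per_gene_table.values())).predictor
        group_vals, comp_vals = [], []
        for gene, summary in per_gene_table.items():
            if gene not in membership.index:
                raise ConfigError(f"flags table lacks gene {gene!r}")
            (group_vals if membership[gene] else comp_vals).append(summary.mean_auc)
        n_g, n_c = len(group_vals), len(comp_vals)
        if n_g < 2 or n_c < 2:
            return GroupComparison(
                predictor=pred_name,
                group_name=predicate.group_name,
                unit=unit,
                n_group=n_g,
                n_complement=n_c,
                u_statistic=None,
                p_value=None,
                computable=False,
                reason=f"need >= 2 genes on each side, got {n_g}/{n_c}",
            )
        res = mann_whitney_u(np.array(group_vals), np.array(comp_vals), alternative)
        return GroupComparison(
            predictor=pred_name,
            group_name=predicate.group_name,
            unit=unit,
            n_group=n_g,
            n_complement=n_c,
            u_statistic=res.u_statistic,
            p_value=res.p_value,
        )

    if unit == "per_rep_auc":
        if stratified is None:
            raise ConfigError("per_rep_auc unit needs the stratified (group, complement) summaries")
        group_summary, comp_summary = stratified
        pred_name = predictor or (group_summary or comp_summary).predictor
        if group_summary is None or comp_summary is None:
            return GroupComparison(
                predictor=pred_name,
                group_name=predicate.group_name,
                unit=unit,
                n_group=0 if group_summary is None else group_summary.n_reps,
                n_complement=0 if comp_summary is None else comp_summary.n_reps,
                u_statistic=None,
                p_value=None,
                computable=False,
                reason="one side of the stratified pair is undefined",
            )
        res = mann_whitney_u(group_summary.per_rep, comp_summary.per_rep, alternative)
        return GroupComparison(
            predictor=pred_name,
            group_name=predicate.group_name,
            unit=unit,
            n_group=group_summary.n_reps,
            n_complement=comp_summary.n_reps,
            u_statistic=res.u_statistic,
            p_value=res.p_value,
        )

    raise ConfigError(f"unknown comparison unit {unit!r}")
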