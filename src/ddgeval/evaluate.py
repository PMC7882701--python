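"""Balanced-resampling AUC and precision-vs-threshold evaluation.

The core estimator repeatedly draws class-balanced subsets (all records of
the minority class plus an equal-sized uniform sample of the majority class,
without replacement), computes the ROC AUC — equivalently the normalized
Mann-Whitney U, with ties credited half — on the |ddG| scores of each
subset, and summarizes over replicates. The same balanced replicates drive
the precision-vs-threshold curves.

Missing scores are removed before building the resample plan so every
replicate is exactly balanced among scored records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._seeds import derive_rng
from .data import GroupPredicate, VariantDataset, abs_scores
from .errors import ConfigError, UndefinedStratumError

logger = logging.getLogger(__name__)

__all__ = [
    "ResamplePlan",
    "AUCSummary",
    "PrecisionCurve",
    "ThresholdResult",
    "roc_auc",
    "balanced_resample",
    "balanced_auc",
    "stratified_auc",
    "per_gene_auc",
    "precision_curve",
    "threshold_for_precision",
    "default_threshold_grid",
]

DEFAULT_N_REPS = 100
DEFAULT_GRID_STEP = 0.1


def roc_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC of ``pos`` versus ``neg`` scores; ties credited 0.5.

    Equals the Mann-Whitney U statistic of the positive sample divided by
    ``n_pos * n_neg``: the probability that a random positive outscores a
    random negative, counting ties half.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedStratumError("roc_auc needs at least one score in each class")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise ConfigError("roc_auc scores must be finite")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class ResamplePlan:
    """Per-replicate index sets producing class-balanced subsets."""

    n_reps: int
    seed: int
    rep_indices: list[np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_reps != len(self.rep_indices):
            raise ConfigError("n_reps does not match the number of index sets")


def balanced_resample(
    pathogenic: np.ndarray, n_reps: int = DEFAULT_N_REPS, seed: int = 0
) -> ResamplePlan:
    """Build a balanced resample plan over a boolean pathogenic-label vector.

    Each replicate keeps every minority-class record and draws an equal-size
    uniform subset of the majority class without replacement. When the
    classes are already balanced each replicate is the full set of records.
    """
    pathogenic = np.asarray(pathogenic, dtype=bool)
    pos_idx = np.flatnonzero(pathogenic)
    neg_idx = np.flatnonzero(~pathogenic)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise UndefinedStratumError("balanced_resample needs records in both classes")
    minority, majority = (pos_idx, neg_idx) if pos_idx.size <= neg_idx.size else (neg_idx, pos_idx)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        sampled = (
            majority
            if majority.size == minority.size
            else rng.choice(majority, size=minority.size, replace=False)
        )
        reps.append(np.concatenate([minority, sampled]))
    return ResamplePlan(n_reps=n_reps, seed=seed, rep_indices=reps)


@dataclass
class AUCSummary:
    """Resampled AUC distribution for one predictor on one stratum."""

    predictor: str
    stratum: str
    mean_auc: float
    sd_auc: float
    per_rep: np.ndarray = field(repr=False)
    n_pos: int
    n_neg: int

    @property
    def n_reps(self) -> int:
        return self.per_rep.size


def _summarize(predictor: str, stratum: str, per_rep: np.ndarray, n_pos: int, n_neg: int) -> AUCSummary:
    # identical replicates (no sampling freedom) must summarize exactly
    if np.ptp(per_rep) == 0:
        mean, sd = float(per_rep[0]), 0.0
    else:
        mean, sd = float(per_rep.mean()), float(per_rep.std(ddof=0))
    return AUCSummary(
        predictor=predictor,
        stratum=stratum,
        mean_auc=mean,
        sd_auc=sd,
        per_rep=per_rep,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _scored_arrays(dataset: VariantDataset, predictor: str) -> tuple[np.ndarray, np.ndarray]:
    """(|score|, pathogenic) over records with a value for ``predictor``."""
    dataset.convention(predictor)
    values = dataset.frame[predictor].to_numpy(dtype=float)
    present = np.isfinite(values)
    return np.abs(values[present]), dataset.labels_pathogenic()[present]


def balanced_auc(
    dataset: VariantDataset,
    predictor: str,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    stratum: str = "all",
    plan: ResamplePlan | None = None,
) -> AUCSummary:
    """Balanced-resampling AUC of one predictor's |ddG| scores.

    The AUC itself depends only on |ddG|, so harmonization state does not
    affect the result. Records missing the predictor are removed before the
    plan is built (each replicate stays exactly balanced among scored
    records).
    """
    scores, pathogenic = _scored_arrays(dataset, predictor)
    if not pathogenic.any() or pathogenic.all():
        raise UndefinedStratumError(
            f"stratum {stratum!r}, predictor {predictor!r}: a class has no scored records"
        )
    if plan is None:
        plan = balanced_resample(pathogenic, n_reps=n_reps, seed=seed)
    per_rep = np.empty(plan.n_reps)
    for r, idx in enumerate(plan.rep_indices):
        rep_scores, rep_path = scores[idx], pathogenic[idx]
        per_rep[r] = roc_auc(rep_scores[rep_path], rep_scores[~rep_path])
    return _summarize(predictor, stratum, per_rep, int(pathogenic.sum()), int((~pathogenic).sum()))


def _gene_mask(dataset: VariantDataset, predicate: GroupPredicate, flags: pd.DataFrame) -> np.ndarray:
    genes = dataset.frame["gene"]
    missing = set(genes.unique()) - set(flags.index)
    if missing:
        raise ConfigError(f"flags table lacks genes: {sorted(missing)[:10]}")
    membership = predicate.mask(flags)
    return genes.map(membership).to_numpy(dtype=bool)


def stratified_auc(
    dataset: VariantDataset,
    predictor: str,
    predicate: GroupPredicate,
    flags: pd.DataFrame,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> tuple[AUCSummary | None, AUCSummary | None]:
    """Balanced AUC on a gene group and on its complement.

    Records are routed by their gene's predicate value; each side gets an
    independent resample plan from a derived sub-seed. A side with no
    records in one class is reported as ``None`` (undefined), the other is
    still computed.
    """
    in_group = _gene_mask(dataset, predicate, flags)
    results: list[AUCSummary | None] = []
    for label, mask in ((predicate.group_name, in_group), (f"not_{predicate.group_name}", ~in_group)):
        sub_seed = derive_rng(seed, "stratum", label, predictor).integers(2**32)
        try:
            results.append(
                balanced_auc(dataset.subset(mask), predictor, n_reps=n_reps, seed=int(sub_seed), stratum=label)
            )
        except UndefinedStratumError as exc:
            logger.warning("stratum %s undefined for %s: %s", label, predictor, exc)
            results.append(None)
    return results[0], results[1]


def per_gene_auc(
    dataset: VariantDataset,
    predictor: str,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    min_per_class: int = 1,
) -> tuple[dict[str, AUCSummary], dict[str, str]]:
    """Balanced AUC per gene, plus a skip report.

    Genes with fewer than ``min_per_class`` scored records in either class
    are skipped and listed in the report with the reason.
    """
    if min_per_class < 1:
        raise ConfigError("min_per_class must be >= 1")
    results: dict[str, AUCSummary] = {}
    skipped: dict[str, str] = {}
    for gene, gene_frame in dataset.frame.groupby("gene", sort=True):
        sub = VariantDataset(
            frame=gene_frame.reset_index(drop=True), panel=list(dataset.panel), harmonized=dataset.harmonized
        )
        scores, pathogenic = _scored_arrays(sub, predictor)
        n_pos, n_neg = int(pathogenic.sum()), int((~pathogenic).sum())
        if n_pos < min_per_class or n_neg < min_per_class:
            skipped[str(gene)] = f"scored records pathogenic={n_pos}, benign={n_neg} below min_per_class={min_per_class}"
            continue
        sub_seed = int(derive_rng(seed, "gene", gene, predictor).integers(2**32))
        results[str(gene)] = balanced_auc(sub, predictor, n_reps=n_reps, seed=sub_seed, stratum=str(gene))
    return results, skipped


# ---------------------------------------------------------------------------
# precision vs threshold
# ---------------------------------------------------------------------------

@dataclass
class PrecisionCurve:
    """Precision and support at a grid of |ddG| thresholds.

    ``precision[i]`` is the mean over contributing replicates of the
    fraction of pathogenic records among records with |ddG| >= threshold
    (closed lower bound). Grid points with zero support in every replicate
    are absent.
    """

    predictor: str
    stratum: str
    thresholds: np.ndarray
    precision: np.ndarray
    n_above: np.ndarray  # mean records above threshold per contributing rep
    n_reps_contributing: np.ndarray


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    precision: float
    support: float


def default_threshold_grid(max_score: float, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """0 .. max_score (inclusive) in fixed kcal/mol steps."""
    if max_score < 0:
        raise ConfigError("max_score must be >= 0")
    n_steps = int(np.floor(max_score / step + 1e-9))
    return np.round(np.arange(n_steps + 1) * step, 10)


def precision_curve(
    dataset: VariantDataset,
    predictor: str,
    thresholds: np.ndarray | None = None,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    stratum: str = "all",
    balanced: bool = True,
    plan: ResamplePlan | None = None,
) -> PrecisionCurve:
    """Precision of "|ddG| >= t ⇒ pathogenic" over a threshold grid.

    With ``balanced=True`` (default) precision is averaged over the balanced
    replicates, so precision at threshold 0 is the balanced prevalence 0.5;
    with ``balanced=False`` a single pass over the full (imbalanced) stratum
    is used.
    """
    scores, pathogenic = _scored_arrays(dataset, predictor)
    if not pathogenic.any() or pathogenic.all():
        raise UndefinedStratumError(
            f"stratum {stratum!r}, predictor {predictor!r}: a class has no scored records"
        )
    if thresholds is None:
        thresholds = default_threshold_grid(float(scores.max()))
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or np.any(np.diff(thresholds) <= 0) or thresholds[0] < 0:
        raise ConfigError("thresholds must be a non-empty strictly increasing non-negative grid")

    if balanced:
        if plan is None:
            plan = balanced_resample(pathogenic, n_reps=n_reps, seed=seed)
        rep_indices = plan.rep_indices
    else:
        rep_indices = [np.arange(scores.size)]

    n_t = thresholds.size
    prec_sum = np.zeros(n_t)
    above_sum = np.zeros(n_t)
    contributing = np.zeros(n_t, dtype=int)
    for idx in rep_indices:
        rep_scores, rep_path = scores[idx], pathogenic[idx]
        order = np.argsort(rep_scores, kind="stable")
        sorted_scores = rep_scores[order]
        sorted_path = np.concatenate([[0], np.cumsum(rep_path[order])])
        first_above = np.searchsorted(sorted_scores, thresholds, side="left")
        n_above = rep_scores.size - first_above
        pos_above = sorted_path[-1] - sorted_path[first_above]
        supported = n_above > 0
        prec_sum[supported] += pos_above[supported] / n_above[supported]
        above_sum[supported] += n_above[supported]
        contributing += supported

    keep = contributing > 0
    if not keep.any():
        warnings.warn(
            f"precision curve for {predictor!r} on stratum {stratum!r} has no supported points",
            stacklevel=2,
        )
    return PrecisionCurve(
        predictor=predictor,
        stratum=stratum,
        thresholds=thresholds[keep],
        precision=prec_sum[keep] / np.maximum(contributing[keep], 1),
        n_above=above_sum[keep] / np.maximum(contributing[keep], 1),
        n_reps_contributing=contributing[keep],
    )


def threshold_for_precision(
    curve: PrecisionCurve, target: float, min_support: float = 1
) -> ThresholdResult | None:
    """Smallest grid threshold reaching the target precision with support.

    Returns ``None`` (not an error) when no grid point has precision >=
    ``target`` and mean support >= ``min_support``.
    """
    if not 0 < target < 1:
        raise ConfigError(f"target precision must be in (0, 1), got {target}")
    if curve.thresholds.size == 0:
        raise UndefinedStratumError("precision curve is empty")
    ok = (curve.precision >= target) & (curve.n_above >= min_support)
    if not ok.any():
        return None
    i = int(np.flatnonzero(ok)[0])
    return ThresholdResult(
        threshold=float(curve.thresholds[i]),
        precision=float(curve.precision[i]),
        support=float(curve.n_above[i]),
    )
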