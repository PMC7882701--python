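"""End-to-end orchestration: configuration, the full analysis, figures.

``run_pipeline`` produces the report bundle:

1. predictor-ranking table (balanced AUC per predictor, consensus included),
2. group-vs-complement table (AUC per inheritance group and complement,
   Mann-Whitney comparison),
3. precision-vs-threshold curves and threshold-for-target table for the
   haploinsufficient / non-haploinsufficient split and the whole dataset,
4. destabilizing-only variants of the above,
5. a run manifest (config echo, seeds, versions, skip reports).

Re-running with the same config reproduces every numeric output
bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_rng
from .data import (
    CANONICAL_GROUPS,
    PATHOGENIC,
    VariantDataset,
    annotate_inheritance,
    default_convention_map,
    harmonize_signs,
    read_convention_map,
    read_gene_list,
    read_variant_table,
)
from .errors import ConfigError, UndefinedStratumError
from .evaluate import (
    balanced_auc,
    default_threshold_grid,
    per_gene_auc,
    precision_curve,
    stratified_auc,
    threshold_for_precision,
)
from .scoring import ConsensusSpec, add_consensus, destabilizing_subset
from .stats import compare_group_vs_complement
from .synth import (
    ClassLaw,
    GroundTruth,
    PredictorModel,
    SyntheticConfig,
    emulate_paper_shape,
    generate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_figures", "load_run_config"]

_TABLE_FILES = {
    "ranking": "ranking.tsv",
    "groups": "groups.tsv",
    "precision_points": "precision_curves.tsv",
    "thresholds": "precision_thresholds.tsv",
    "ranking_destabilizing": "destabilizing_ranking.tsv",
    "groups_destabilizing": "destabilizing_groups.tsv",
    "precision_points_destabilizing": "destabilizing_precision_curves.tsv",
    "thresholds_destabilizing": "destabilizing_precision_thresholds.tsv",
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    # exactly one input source: real paths or a synthetic config / fixture
    variant_table: str | None = None
    column_map: dict[str, Any] | None = None
    gene_lists: dict[str, str] | None = None  # keys: hi, ad, ar
    conventions_path: str | None = None
    synthetic: SyntheticConfig | None = None
    paper_shape: bool = False

    predictors: list[str] | None = None  # None = full panel
    consensus: list[ConsensusSpec] = field(default_factory=list)

    n_reps: int = 100
    seed: int = 0
    threshold_step: float = 0.1
    precision_targets: list[float] = field(default_factory=lambda: [0.9, 0.96])
    min_support: float = 10.0
    min_per_class: int = 1
    comparison_unit: str = "per_gene_mean_auc"
    balanced_precision: bool = True
    destabilizing_analysis: bool = True
    outdir: str = "ddgeval_out"

    def __post_init__(self) -> None:
        real = self.variant_table is not None
        synthetic = self.synthetic is not None or self.paper_shape
        if real and synthetic:
            raise ConfigError("set either real input paths or a synthetic source, not both")
        if not real and not synthetic:
            raise ConfigError("no input source: set variant_table or a synthetic source")
        if self.synthetic is not None and self.paper_shape:
            raise ConfigError("synthetic config and paper_shape fixture are mutually exclusive")
        if real:
            if not self.column_map:
                raise ConfigError("real input requires a column_map")
            if not self.gene_lists or set(self.gene_lists) != {"hi", "ad", "ar"}:
                raise ConfigError("real input requires gene_lists with keys hi, ad, ar")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.seed is None:
            raise ConfigError("a seed is required (no silent nondeterminism)")
        if self.threshold_step <= 0:
            raise ConfigError("threshold_step must be > 0")
        for t in self.precision_targets:
            if not 0 < t < 1:
                raise ConfigError(f"precision target {t} outside (0, 1)")


def _synthetic_config_from_payload(payload: dict[str, Any]) -> SyntheticConfig:
    payload = dict(payload)
    kwargs: dict[str, Any] = {}
    if "n_genes_by_mode" in payload:
        kwargs["n_genes_by_mode"] = {k: int(v) for k, v in payload["n_genes_by_mode"].items()}
    if "variants_per_gene" in payload:
        v = payload["variants_per_gene"]
        kwargs["variants_per_gene"] = tuple(int(x) for x in v) if isinstance(v, (list, tuple)) else int(v)
    if "pathogenic_fraction" in payload:
        kwargs["pathogenic_fraction"] = float(payload["pathogenic_fraction"])
    if "benign_law" in payload:
        kwargs["benign_law"] = ClassLaw(**payload["benign_law"])
    if "delta_by_mode" in payload:
        kwargs["delta_by_mode"] = {k: float(v) for k, v in payload["delta_by_mode"].items()}
    if "shift_by_mode" in payload:
        kwargs["shift_by_mode"] = {k: float(v) for k, v in payload["shift_by_mode"].items()}
    if "predictors" in payload:
        sign_aliases = {"pos": "positive_destabilizing", "neg": "negative_destabilizing"}
        models = []
        for entry in payload["predictors"]:
            entry = dict(entry)
            if "sign" in entry:
                entry["sign_convention"] = sign_aliases.get(entry.pop("sign"), entry.get("sign_convention"))
            models.append(PredictorModel(**entry))
        kwargs["predictor_models"] = tuple(models)
    if "stabilizing_prob" in payload:
        kwargs["stabilizing_prob"] = float(payload["stabilizing_prob"])
    if "seed" in payload:
        kwargs["seed"] = int(payload["seed"])
    return SyntheticConfig(**kwargs)


def load_run_config(path: str, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a YAML run config; ``overrides`` replace top-level fields."""
    with open(path) as handle:
        payload = yaml.safe_load(handle) or {}
    kwargs: dict[str, Any] = {}
    inp = payload.get("input") or {}
    if inp:
        kwargs["variant_table"] = inp.get("variant_table")
        kwargs["column_map"] = inp.get("column_map")
        kwargs["gene_lists"] = inp.get("gene_lists")
        kwargs["conventions_path"] = inp.get("conventions")
    if payload.get("synthetic") is not None:
        kwargs["synthetic"] = _synthetic_config_from_payload(payload["synthetic"])
    kwargs["paper_shape"] = bool(payload.get("paper_shape", False))
    if payload.get("consensus"):
        kwargs["consensus"] = [
            ConsensusSpec(
                members=tuple(entry["members"]),
                output_name=entry.get("output_name") or "mean(" + "+".join(entry["members"]) + ")",
                signed=bool(entry.get("signed", False)),
            )
            for entry in payload["consensus"]
        ]
    if payload.get("predictors"):
        kwargs["predictors"] = list(payload["predictors"])
    ev = payload.get("evaluation") or {}
    for key in (
        "n_reps",
        "seed",
        "threshold_step",
        "precision_targets",
        "min_support",
        "min_per_class",
        "comparison_unit",
        "balanced_precision",
        "destabilizing_analysis",
    ):
        if key in ev:
            kwargs[key] = ev[key]
    if "outdir" in payload:
        kwargs["outdir"] = payload["outdir"]
    if overrides:
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs)


@dataclass
class ReportBundle:
    """All result tables of one run plus the manifest."""

    ranking: pd.DataFrame
    groups: pd.DataFrame
    precision_points: pd.DataFrame
    thresholds: pd.DataFrame
    ranking_destabilizing: pd.DataFrame
    groups_destabilizing: pd.DataFrame
    precision_points_destabilizing: pd.DataFrame
    thresholds_destabilizing: pd.DataFrame
    manifest: dict[str, Any]

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in _TABLE_FILES}

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, filename in _TABLE_FILES.items():
            getattr(self, name).to_csv(
                os.path.join(outdir, filename), sep="\t", index=False, float_format="%.10g"
            )
        with open(os.path.join(outdir, "manifest.yaml"), "w") as handle:
            yaml.safe_dump(self.manifest, handle, sort_keys=True)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig) -> tuple[VariantDataset, dict[str, set[str]], GroundTruth | None]:
    if config.variant_table is not None:
        conventions = (
            read_convention_map(config.conventions_path)
            if config.conventions_path
            else default_convention_map()
        )
        dataset = read_variant_table(config.variant_table, config.column_map, conventions=conventions)
        gene_lists = {key: read_gene_list(path) for key, path in config.gene_lists.items()}
        return dataset, gene_lists, None
    if config.paper_shape:
        dataset, truth = emulate_paper_shape(seed=config.seed)
    else:
        synth_config = dataclasses.replace(config.synthetic, seed=config.seed)
        dataset, truth = generate_dataset(synth_config)
    return dataset, truth.gene_lists, truth


def _evaluation_tables(
    dataset: VariantDataset,
    flags: pd.DataFrame,
    predictors: list[str],
    config: RunConfig,
    tag: str,
    per_predictor_subset: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, Any]]:
    """Ranking, group, precision and threshold tables for one dataset view.

    With ``per_predictor_subset`` each predictor is evaluated on its own
    destabilizing subset (records it calls harmonized ddG > 0).
    """
    ranking_rows = []
    group_rows = []
    point_rows = []
    threshold_rows = []
    skip_report: dict[str, Any] = {}

    hi_predicate = CANONICAL_GROUPS["haploinsufficient"]

    for predictor in predictors:
        view = dataset
        if per_predictor_subset:
            try:
                view = destabilizing_subset(dataset, predictor)
            except UndefinedStratumError as exc:
                skip_report[predictor] = str(exc)
                continue

        rank_seed = int(derive_rng(config.seed, tag, "ranking", predictor).integers(2**32))
        try:
            summary = balanced_auc(view, predictor, n_reps=config.n_reps, seed=rank_seed)
        except UndefinedStratumError as exc:
            skip_report[predictor] = str(exc)
            continue
        ranking_rows.append(
            {
                "predictor": predictor,
                "mean_auc": summary.mean_auc,
                "sd_auc": summary.sd_auc,
                "n_pos": summary.n_pos,
                "n_neg": summary.n_neg,
                "n_reps": summary.n_reps,
            }
        )

        per_gene, skipped_genes = per_gene_auc(
            view, predictor, n_reps=config.n_reps,
            seed=int(derive_rng(config.seed, tag, "per_gene", predictor).integers(2**32)),
            min_per_class=config.min_per_class,
        )
        if skipped_genes:
            skip_report.setdefault("per_gene_skips", {})[predictor] = skipped_genes

        for group_name, predicate in CANONICAL_GROUPS.items():
            strat_seed = int(derive_rng(config.seed, tag, "stratified", group_name, predictor).integers(2**32))
            group_summary, comp_summary = stratified_auc(
                view, predictor, predicate, flags, n_reps=config.n_reps, seed=strat_seed
            )
            comparison = compare_group_vs_complement(
                per_gene,
                predicate,
                flags,
                unit=config.comparison_unit,
                stratified=(group_summary, comp_summary),
                predictor=predictor,
            )
            group_rows.append(
                {
                    "predictor": predictor,
                    "group": group_name,
                    "group_mean_auc": np.nan if group_summary is None else group_summary.mean_auc,
                    "group_sd_auc": np.nan if group_summary is None else group_summary.sd_auc,
                    "group_n_pos": 0 if group_summary is None else group_summary.n_pos,
                    "group_n_neg": 0 if group_summary is None else group_summary.n_neg,
                    "complement_mean_auc": np.nan if comp_summary is None else comp_summary.mean_auc,
                    "complement_sd_auc": np.nan if comp_summary is None else comp_summary.sd_auc,
                    "complement_n_pos": 0 if comp_summary is None else comp_summary.n_pos,
                    "complement_n_neg": 0 if comp_summary is None else comp_summary.n_neg,
                    "unit": comparison.unit,
                    "n_group_units": comparison.n_group,
                    "n_complement_units": comparison.n_complement,
                    "u_statistic": np.nan if comparison.u_statistic is None else comparison.u_statistic,
                    "p_value": np.nan if comparison.p_value is None else comparison.p_value,
                    "computable": comparison.computable,
                    "reason": comparison.reason,
                }
            )

        # precision: whole view plus the HI / non-HI split (Fig 3 analogue)
        hi_mask = view.frame["gene"].map(hi_predicate.mask(flags)).to_numpy(dtype=bool)
        strata = [
            ("all", np.ones(len(view.frame), dtype=bool)),
            ("haploinsufficient", hi_mask),
            ("not_haploinsufficient", ~hi_mask),
        ]
        for stratum_name, mask in strata:
            sub = view.subset(mask)
            prec_seed = int(derive_rng(config.seed, tag, "precision", stratum_name, predictor).integers(2**32))
            try:
                values = sub.frame[predictor].to_numpy(dtype=float)
                finite = values[np.isfinite(values)]
                if finite.size == 0:
                    raise UndefinedStratumError(f"no scores for {predictor!r} in {stratum_name!r}")
                grid = default_threshold_grid(float(np.abs(finite).max()), step=config.threshold_step)
                curve = precision_curve(
                    sub,
                    predictor,
                    thresholds=grid,
                    n_reps=config.n_reps,
                    seed=prec_seed,
                    stratum=stratum_name,
                    balanced=config.balanced_precision,
                )
            except UndefinedStratumError as exc:
                skip_report.setdefault("precision_skips", {})[f"{predictor}/{stratum_name}"] = str(exc)
                continue
            for i in range(curve.thresholds.size):
                point_rows.append(
                    {
                        "predictor": predictor,
                        "stratum": stratum_name,
                        "threshold": curve.thresholds[i],
                        "precision": curve.precision[i],
                        "n_above": curve.n_above[i],
                        "n_reps_contributing": curve.n_reps_contributing[i],
                    }
                )
            for target in config.precision_targets:
                hit = threshold_for_precision(curve, target, min_support=config.min_support)
                threshold_rows.append(
                    {
                        "predictor": predictor,
                        "stratum": stratum_name,
                        "target_precision": target,
                        "threshold": np.nan if hit is None else hit.threshold,
                        "achieved_precision": np.nan if hit is None else hit.precision,
                        "support": np.nan if hit is None else hit.support,
                        "reachable": hit is not None,
                    }
                )

    return (
        pd.DataFrame(ranking_rows),
        pd.DataFrame(group_rows),
        pd.DataFrame(point_rows),
        pd.DataFrame(threshold_rows),
        skip_report,
    )


def run_pipeline(config: RunConfig, write: bool = True) -> ReportBundle:
    """Run the full analysis described by ``config``.

    Returns the report bundle; unless ``write=False`` the tables, manifest
    and figures are also written under ``config.outdir``.
    """
    dataset, gene_lists, _truth = _load_inputs(config)
    dataset = harmonize_signs(dataset)
    flags = annotate_inheritance(dataset, gene_lists["hi"], gene_lists["ad"], gene_lists["ar"])

    for spec in config.consensus:
        dataset = add_consensus(dataset, spec)

    predictors = config.predictors or dataset.predictor_names
    unknown = [p for p in predictors if p not in dataset.predictor_names]
    if unknown:
        raise ConfigError(f"requested predictors not in panel: {unknown}")

    logger.info("evaluating %d predictors on %d records", len(predictors), dataset.n_records)
    ranking, groups, points, thresholds, skips = _evaluation_tables(
        dataset, flags, predictors, config, tag="full"
    )
    if config.destabilizing_analysis:
        d_ranking, d_groups, d_points, d_thresholds, d_skips = _evaluation_tables(
            dataset, flags, predictors, config, tag="destabilizing", per_predictor_subset=True
        )
    else:
        d_ranking = d_groups = d_points = d_thresholds = pd.DataFrame()
        d_skips = {}

    labels = dataset.frame["label"]
    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": int(config.seed),
        "n_reps": int(config.n_reps),
        "counts": {
            "records": int(dataset.n_records),
            "pathogenic": int((labels == PATHOGENIC).sum()),
            "benign": int((labels != PATHOGENIC).sum()),
            "genes": int(dataset.frame["gene"].nunique()),
        },
        "predictors": list(predictors),
        "consensus": [
            {"members": list(s.members), "output_name": s.output_name, "signed": s.signed}
            for s in config.consensus
        ],
        "comparison_unit": config.comparison_unit,
        "balanced_precision": bool(config.balanced_precision),
        "threshold_step": float(config.threshold_step),
        "precision_targets": [float(t) for t in config.precision_targets],
        "min_support": float(config.min_support),
        "min_per_class": int(config.min_per_class),
        "input_source": (
            "variant_table" if config.variant_table else ("paper_shape" if config.paper_shape else "synthetic")
        ),
        "skip_reports": {"full": skips, "destabilizing": d_skips},
        "n_group_tests": int(len(groups)) + int(len(d_groups)),
    }

    bundle = ReportBundle(
        ranking=ranking,
        groups=groups,
        precision_points=points,
        thresholds=thresholds,
        ranking_destabilizing=d_ranking,
        groups_destabilizing=d_groups,
        precision_points_destabilizing=d_points,
        thresholds_destabilizing=d_thresholds,
        manifest=manifest,
    )
    if write:
        bundle.write(config.outdir)
    return bundle


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def render_figures(bundle: ReportBundle, outdir: str, fmt: str = "svg") -> list[str]:
    """Render the three report figures; returns the written paths.

    A missing/empty table skips its figure with a logged warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    if len(bundle.ranking):
        ranking = bundle.ranking.sort_values("mean_auc", ascending=False)
        fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(ranking)), 4))
        ax.bar(ranking["predictor"], ranking["mean_auc"], yerr=ranking["sd_auc"], color="#4878a8")
        ax.set_ylabel("mean balanced AUC")
        ax.set_ylim(0.4, 1.0)
        ax.tick_params(axis="x", rotation=75)
        fig.tight_layout()
        path = os.path.join(outdir, f"ranking.{fmt}")
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("ranking table empty; skipping ranking figure")

    if len(bundle.groups):
        groups = bundle.groups
        group_names = list(dict.fromkeys(groups["group"]))
        fig, axes = plt.subplots(len(group_names), 1, figsize=(8, 3 * len(group_names)), squeeze=False)
        for ax, group_name in zip(axes.ravel(), group_names):
            sub = groups[groups["group"] == group_name]
            x = np.arange(len(sub))
            ax.bar(x - 0.2, sub["group_mean_auc"], width=0.4, label=group_name, color="#a84848")
            ax.bar(x + 0.2, sub["complement_mean_auc"], width=0.4, label="complement", color="#888888")
            for xi, p in zip(x, sub["p_value"]):
                if np.isfinite(p):
                    ax.text(xi, 0.42, f"p={p:.2g}", ha="center", fontsize=7)
            ax.set_xticks(x, sub["predictor"], rotation=30, fontsize=7)
            ax.set_ylim(0.4, 1.0)
            ax.set_ylabel("mean AUC")
            ax.legend(fontsize=7)
        fig.tight_layout()
        path = os.path.join(outdir, f"groups.{fmt}")
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("groups table empty; skipping groups figure")

    if len(bundle.precision_points):
        points = bundle.precision_points
        fig, ax = plt.subplots(figsize=(7, 5))
        styles = {"haploinsufficient": "-", "not_haploinsufficient": "--"}
        cmap = plt.get_cmap("tab10")
        for i, predictor in enumerate(dict.fromkeys(points["predictor"])):
            for stratum, style in styles.items():
                sub = points[(points["predictor"] == predictor) & (points["stratum"] == stratum)]
                if not len(sub):
                    logger.warning("no precision curve for %s / %s", predictor, stratum)
                    continue
                ax.plot(sub["threshold"], sub["precision"], style, color=cmap(i % 10), label=f"{predictor} ({stratum})")
        ax.set_xlabel("|ddG| threshold (kcal/mol)")
        ax.set_ylabel("precision")
        ax.legend(fontsize=6)
        fig.tight_layout()
        path = os.path.join(outdir, f"precision.{fmt}")
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("precision table empty; skipping precision figure")

    return written
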