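"""Synthetic variant datasets with the structure the pipeline assumes.

Variants carry a latent true |ddG| drawn from a class- and inheritance-mode-
specific non-negative law (gamma; shape 1 gives the analytically convenient
exponential case). Each predictor observes the shared latent signal through
its own weight and additive Gaussian noise, applies its sign convention,
truncates at its output cap and masks a fraction of values as missing —
mirroring a panel of correlated but imperfect stability tools.

Seed discipline: one master seed; per-gene and per-predictor substreams are
derived deterministically (see :mod:`ddgeval._seeds`), so adding a predictor
leaves existing columns bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .data import (
    BENIGN,
    NEGATIVE_DESTABILIZING,
    PATHOGENIC,
    POSITIVE_DESTABILIZING,
    PredictorConvention,
    VariantDataset,
)
from .errors import ConfigError

__all__ = [
    "MODES",
    "ClassLaw",
    "PredictorModel",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "emulate_paper_shape",
    "write_ground_truth",
    "PAPER_SHAPE_COUNTS",
]

MODES = ("hi", "ad_only", "ar", "unlisted")

_MODE_GENE_PREFIX = {"hi": "HIG", "ad_only": "ADG", "ar": "ARG", "unlisted": "UNG"}


@dataclass(frozen=True)
class ClassLaw:
    """Non-negative generative law for benign latent |ddG| values.

    ``family`` is ``gamma`` or ``exponential``; for the exponential family
    ``scale`` is the mean (1/rate) and ``shape`` is ignored.
    """

    family: str = "gamma"
    shape: float = 1.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "exponential"):
            raise ConfigError(f"unknown class-law family {self.family!r}")
        if self.scale <= 0 or self.shape <= 0:
            raise ConfigError("class-law shape and scale must be > 0")

    def sample(self, rng: np.random.Generator, n: int, scale_multiplier: float = 1.0) -> np.ndarray:
        scale = self.scale * scale_multiplier
        if self.family == "exponential":
            return rng.exponential(scale, size=n)
        return rng.gamma(self.shape, scale, size=n)


@dataclass(frozen=True)
class PredictorModel:
    """Observation model of one synthetic predictor."""

    name: str
    noise_sd: float = 0.0  # kcal/mol, additive Gaussian
    signal_weight: float = 1.0  # multiplier on the shared latent |ddG|
    sign_convention: str = POSITIVE_DESTABILIZING
    cap: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"predictor {self.name!r}: noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"predictor {self.name!r}: missing_rate must be in [0, 1)")
        if self.cap is not None and self.cap <= 0:
            raise ConfigError(f"predictor {self.name!r}: cap must be > 0")

    def convention(self) -> PredictorConvention:
        return PredictorConvention(self.name, self.sign_convention, self.cap)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic dataset draw."""

    n_genes_by_mode: Mapping[str, int] = field(
        default_factory=lambda: {"hi": 10, "ad_only": 10, "ar": 10, "unlisted": 10}
    )
    variants_per_gene: int | tuple[int, int] = 30
    pathogenic_fraction: float = 0.3
    benign_law: ClassLaw = field(default_factory=ClassLaw)
    #: pathogenic scale multiplier is (1 + delta) relative to the benign law
    delta_by_mode: Mapping[str, float] = field(
        default_factory=lambda: {"hi": 2.0, "ad_only": 0.5, "ar": 0.5, "unlisted": 0.5}
    )
    #: additive location shift of pathogenic latent |ddG| (kcal/mol); a large
    #: shift makes the class supports disjoint
    shift_by_mode: Mapping[str, float] = field(default_factory=dict)
    predictor_models: tuple[PredictorModel, ...] = (PredictorModel(name="oracle"),)
    stabilizing_prob: float = 0.0  # chance a variant's harmonized ddG is negative
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_genes_by_mode) - set(MODES)
        if unknown:
            raise ConfigError(f"unknown inheritance modes: {sorted(unknown)}")
        if not 0 <= self.pathogenic_fraction <= 1:
            raise ConfigError("pathogenic_fraction must be in [0, 1]")
        if not 0 <= self.stabilizing_prob <= 1:
            raise ConfigError("stabilizing_prob must be in [0, 1]")
        if not self.predictor_models:
            raise ConfigError("at least one predictor model is required")
        if isinstance(self.variants_per_gene, int):
            if self.variants_per_gene < 1:
                raise ConfigError("variants_per_gene must be >= 1")
        else:
            lo, hi = self.variants_per_gene
            if not (1 <= lo <= hi):
                raise ConfigError("variants_per_gene range must satisfy 1 <= lo <= hi")
        total_genes = sum(self.n_genes_by_mode.get(m, 0) for m in MODES)
        if total_genes < 1:
            raise ConfigError("config generates zero genes")

    def delta(self, mode: str) -> float:
        return float(self.delta_by_mode.get(mode, 0.0))

    def shift(self, mode: str) -> float:
        return float(self.shift_by_mode.get(mode, 0.0))


@dataclass
class GroundTruth:
    """Sidecar emitted next to each synthetic dataset."""

    table: pd.DataFrame  # variant_id, gene, mode, label, true_abs_ddg, sign
    gene_lists: dict[str, set[str]]  # keys: hi, ad, ar
    config: SyntheticConfig


def _draw_gene_variants(
    config: SyntheticConfig, gene: str, mode: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels, latent |ddG| and signs for one gene, from its own substream."""
    rng = derive_rng(config.seed, "gene", gene)
    if isinstance(config.variants_per_gene, int):
        n = config.variants_per_gene
    else:
        lo, hi = config.variants_per_gene
        n = int(rng.integers(lo, hi + 1))
    pathogenic = rng.random(n) < config.pathogenic_fraction
    latent = np.empty(n)
    latent[~pathogenic] = config.benign_law.sample(rng, int((~pathogenic).sum()))
    latent[pathogenic] = config.shift(mode) + config.benign_law.sample(
        rng, int(pathogenic.sum()), scale_multiplier=1.0 + config.delta(mode)
    )
    signs = np.where(rng.random(n) < config.stabilizing_prob, -1.0, 1.0)
    return pathogenic, latent, signs


def _observe_predictor(
    model: PredictorModel, latent_abs: np.ndarray, signs: np.ndarray, master_seed: int
) -> np.ndarray:
    """Reported ddG column for one predictor (NaN = masked missing)."""
    rng = derive_rng(master_seed, "predictor", model.name)
    n = latent_abs.size
    magnitude = model.signal_weight * latent_abs
    if model.noise_sd > 0:
        magnitude = magnitude + rng.normal(0.0, model.noise_sd, size=n)
    else:
        rng.normal(0.0, 1.0, size=n)  # keep the stream aligned across configs
    magnitude = np.maximum(magnitude, 0.0)
    if model.cap is not None:
        magnitude = np.minimum(magnitude, model.cap)
    values = signs * magnitude
    if model.sign_convention == NEGATIVE_DESTABILIZING:
        values = -values
    missing = rng.random(n) < model.missing_rate
    values = values.astype(float)
    values[missing] = np.nan
    return values


def generate_dataset(config: SyntheticConfig) -> tuple[VariantDataset, GroundTruth]:
    """Draw a synthetic dataset plus its ground-truth sidecar.

    Deterministic given ``config`` (including its seed): identical configs
    yield byte-identical tables.
    """
    genes: list[tuple[str, str]] = []  # (gene, mode)
    for mode in MODES:
        count = int(config.n_genes_by_mode.get(mode, 0))
        genes.extend((f"{_MODE_GENE_PREFIX[mode]}{i:04d}", mode) for i in range(count))
    if not genes:
        raise ConfigError("config generates zero genes")

    rows: list[dict[str, object]] = []
    for gene, mode in genes:
        pathogenic, latent, signs = _draw_gene_variants(config, gene, mode)
        for i in range(latent.size):
            rows.append(
                {
                    "variant_id": f"{gene}_{i:04d}",
                    "gene": gene,
                    "mode": mode,
                    "label": PATHOGENIC if pathogenic[i] else BENIGN,
                    "true_abs_ddg": float(latent[i]),
                    "sign": float(signs[i]),
                }
            )
    truth_table = pd.DataFrame(rows)
    if truth_table.empty:
        raise ConfigError("config generates zero variants")

    frame = truth_table[["variant_id", "gene", "label"]].copy()
    latent_abs = truth_table["true_abs_ddg"].to_numpy()
    signs = truth_table["sign"].to_numpy()
    panel = []
    for model in config.predictor_models:
        frame[model.name] = _observe_predictor(model, latent_abs, signs, config.seed)
        panel.append(model.convention())

    dataset = VariantDataset(frame=frame, panel=panel, harmonized=False)
    gene_lists = {
        "hi": {g for g, m in genes if m == "hi"},
        "ad": {g for g, m in genes if m == "ad_only"},
        "ar": {g for g, m in genes if m == "ar"},
    }
    return dataset, GroundTruth(table=truth_table, gene_lists=gene_lists, config=config)


# ---------------------------------------------------------------------------
# fixed-shape fixture
# ---------------------------------------------------------------------------

#: Per-mode (pathogenic, benign) record counts of the upstream evaluation
#: dataset: 13,508 variants over 100 genes; 3,338 pathogenic / 10,170 benign.
PAPER_SHAPE_COUNTS: dict[str, tuple[int, int]] = {
    "hi": (1217, 1252),
    "ad_only": (753, 1819),
    "ar": (635, 4253),
    "unlisted": (733, 2846),  # remainder: totals minus the three listed modes
}

_PAPER_SHAPE_GENES = {"hi": 25, "ad_only": 25, "ar": 25, "unlisted": 25}


def _split_evenly(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def emulate_paper_shape(seed: int = 0) -> tuple[VariantDataset, GroundTruth]:
    """Fixture with the upstream dataset's exact marginal counts.

    Total 13,508 records over 100 genes, 3,338 pathogenic / 10,170 benign,
    with per-mode pathogenic/benign splits 1,217/1,252 (haploinsufficient),
    753/1,819 (dominant-only), 635/4,253 (recessive) and the remainder on
    unlisted genes. Scores are synthetic (stronger pathogenic shift on
    haploinsufficient genes); only the counts are meaningful.
    """
    config = SyntheticConfig(
        n_genes_by_mode=_PAPER_SHAPE_GENES,
        variants_per_gene=1,  # placeholder; counts are imposed exactly below
        pathogenic_fraction=0.5,
        delta_by_mode={"hi": 2.0, "ad_only": 0.5, "ar": 0.5, "unlisted": 0.5},
        predictor_models=(
            PredictorModel(name="foldx5", noise_sd=0.8),
            PredictorModel(name="inps3d", noise_sd=1.0, sign_convention=NEGATIVE_DESTABILIZING, cap=5.0),
            PredictorModel(name="rosetta", noise_sd=1.2),
        ),
        stabilizing_prob=0.05,
        seed=seed,
    )

    rows: list[dict[str, object]] = []
    for mode in MODES:
        n_path, n_benign = PAPER_SHAPE_COUNTS[mode]
        n_genes = _PAPER_SHAPE_GENES[mode]
        path_per_gene = _split_evenly(n_path, n_genes)
        benign_per_gene = _split_evenly(n_benign, n_genes)
        for g in range(n_genes):
            gene = f"{_MODE_GENE_PREFIX[mode]}{g:04d}"
            rng = derive_rng(seed, "gene", gene)
            n_p, n_b = path_per_gene[g], benign_per_gene[g]
            latent = np.concatenate(
                [
                    config.benign_law.sample(rng, n_p, scale_multiplier=1.0 + config.delta(mode)),
                    config.benign_law.sample(rng, n_b),
                ]
            )
            signs = np.where(rng.random(n_p + n_b) < config.stabilizing_prob, -1.0, 1.0)
            labels = [PATHOGENIC] * n_p + [BENIGN] * n_b
            for i in range(n_p + n_b):
                rows.append(
                    {
                        "variant_id": f"{gene}_{i:04d}",
                        "gene": gene,
                        "mode": mode,
                        "label": labels[i],
                        "true_abs_ddg": float(latent[i]),
                        "sign": float(signs[i]),
                    }
                )

    truth_table = pd.DataFrame(rows)
    frame = truth_table[["variant_id", "gene", "label"]].copy()
    latent_abs = truth_table["true_abs_ddg"].to_numpy()
    signs = truth_table["sign"].to_numpy()
    panel = []
    for model in config.predictor_models:
        frame[model.name] = _observe_predictor(model, latent_abs, signs, seed)
        panel.append(model.convention())

    dataset = VariantDataset(frame=frame, panel=panel, harmonized=False)
    gene_lists = {
        "hi": set(truth_table.loc[truth_table["mode"] == "hi", "gene"]),
        "ad": set(truth_table.loc[truth_table["mode"] == "ad_only", "gene"]),
        "ar": set(truth_table.loc[truth_table["mode"] == "ar", "gene"]),
    }
    return dataset, GroundTruth(table=truth_table, gene_lists=gene_lists, config=config)


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    """Write the ground-truth sidecar as TSV."""
    truth.table.to_csv(path, sep="\t", index=False, float_format="%.17g")
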