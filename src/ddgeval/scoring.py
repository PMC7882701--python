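"""Derived predictors: consensus pseudo-predictors and the destabilizing filter."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data import POSITIVE_DESTABILIZING, PredictorConvention, VariantDataset
from .errors import ConfigError, DataError, UndefinedStratumError

__all__ = [
    "ConsensusSpec",
    "add_consensus",
    "predictor_combinations",
    "destabilizing_subset",
]


@dataclass(frozen=True)
class ConsensusSpec:
    """Mean-of-|ddG| pseudo-predictor over a subset of the panel.

    By default member values enter as absolute values, so the consensus is
    insensitive to each member's sign convention. ``signed=True`` averages
    harmonized signed values instead (sensitivity-analysis variant).
    """

    members: tuple[str, ...]
    output_name: str
    signed: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ConfigError("consensus needs at least one member predictor")
        if len(set(self.members)) != len(self.members):
            raise ConfigError(f"duplicate members in consensus {self.output_name!r}")


def add_consensus(dataset: VariantDataset, spec: ConsensusSpec) -> VariantDataset:
    """Return a copy of ``dataset`` with the consensus column appended.

    The consensus value of a record is the arithmetic mean of its members'
    |ddG| values and is missing whenever ANY member is missing (so the
    effective predictor has a fixed composition across records). The new
    column is positive-destabilizing with no cap.
    """
    if not dataset.harmonized:
        raise DataError("harmonize the dataset before building consensus scores")
    if spec.output_name in dataset.predictor_names:
        raise ConfigError(f"panel already contains a predictor named {spec.output_name!r}")
    unknown = [m for m in spec.members if m not in dataset.predictor_names]
    if unknown:
        raise ConfigError(f"unknown consensus members: {unknown}")

    member_values = dataset.frame[list(spec.members)].to_numpy(dtype=float)
    values = member_values if spec.signed else np.abs(member_values)
    consensus = values.mean(axis=1)
    consensus[np.isnan(member_values).any(axis=1)] = np.nan

    out = dataset.copy()
    out.frame[spec.output_name] = consensus
    out.panel.append(PredictorConvention(spec.output_name, POSITIVE_DESTABILIZING, cap=None))
    return out


def predictor_combinations(names: list[str], sizes: set[int]) -> list[ConsensusSpec]:
    """All member subsets of the given sizes, in lexicographic order."""
    if not names:
        return []
    bad = [k for k in sizes if not 1 <= k <= len(names)]
    if bad:
        raise ConfigError(f"combination sizes {bad} outside 1..{len(names)}")
    specs = []
    for k in sorted(sizes):
        for combo in itertools.combinations(sorted(names), k):
            specs.append(ConsensusSpec(members=combo, output_name="mean(" + "+".join(combo) + ")"))
    return specs


def destabilizing_subset(dataset: VariantDataset, predictor: str) -> VariantDataset:
    """Restrict to records this predictor calls destabilizing (ddG > 0).

    Strict inequality: harmonized ddG of exactly 0 counts as
    non-destabilizing. Records missing the predictor are dropped.
    """
    if not dataset.harmonized:
        raise DataError("harmonize the dataset before filtering on sign")
    dataset.convention(predictor)  # validates membership
    values = dataset.frame[predictor].to_numpy(dtype=float)
    mask = np.isfinite(values) & (values > 0)
    if not mask.any():
        raise UndefinedStratumError(
            f"no destabilizing records for predictor {predictor!r}"
        )
    return dataset.subset(mask)
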