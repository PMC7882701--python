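"""Variant data model, table / gene-list parsing and annotation.

A :class:`VariantDataset` is a thin wrapper around a pandas DataFrame with
one row per missense variant (``variant_id``, ``gene``, ``label`` plus one
float column per stability predictor, NaN meaning "no prediction") and a
panel of :class:`PredictorConvention` entries describing each predictor's
sign convention and optional output cap.

Sign conventions differ between stability predictors (some report
destabilizing variants as positive ddG, some as negative), so datasets are
harmonized once — after :func:`harmonize_signs` every predictor stores
positive-destabilizing values and downstream code can interpret the sign of
a value directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, UndefinedStratumError

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_DESTABILIZING",
    "NEGATIVE_DESTABILIZING",
    "PATHOGENIC",
    "BENIGN",
    "DEFAULT_LABEL_VOCABULARY",
    "PredictorConvention",
    "VariantRecord",
    "VariantDataset",
    "InheritanceFlags",
    "GroupPredicate",
    "CANONICAL_GROUPS",
    "normalize_gene",
    "read_variant_table",
    "write_variant_table",
    "read_gene_list",
    "read_convention_map",
    "default_convention_map",
    "harmonize_signs",
    "annotate_inheritance",
    "abs_scores",
]

POSITIVE_DESTABILIZING = "positive_destabilizing"
NEGATIVE_DESTABILIZING = "negative_destabilizing"

PATHOGENIC = "pathogenic"
BENIGN = "benign"

#: Default mapping from raw label strings (lower-cased, stripped) to classes.
DEFAULT_LABEL_VOCABULARY: dict[str, str] = {
    "pathogenic": PATHOGENIC,
    "likely pathogenic": PATHOGENIC,
    "likely_pathogenic": PATHOGENIC,
    "p": PATHOGENIC,
    "benign": BENIGN,
    "putatively benign": BENIGN,
    "putatively_benign": BENIGN,
    "likely benign": BENIGN,
    "likely_benign": BENIGN,
    "gnomad": BENIGN,
    "b": BENIGN,
}

_META_COLUMNS = ["variant_id", "gene", "label"]


def normalize_gene(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class PredictorConvention:
    """Sign convention and optional output cap of one stability predictor."""

    name: str
    sign_convention: str = POSITIVE_DESTABILIZING
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.sign_convention not in (POSITIVE_DESTABILIZING, NEGATIVE_DESTABILIZING):
            raise ConfigError(
                f"predictor {self.name!r}: unknown sign convention "
                f"{self.sign_convention!r}"
            )
        if self.cap is not None and not self.cap > 0:
            raise ConfigError(f"predictor {self.name!r}: cap must be > 0, got {self.cap}")


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant: opaque id, gene symbol, class label, ddG values."""

    variant_id: str
    gene: str
    label: str
    ddg: Mapping[str, float]  # predictor name -> ddG (kcal/mol); absent = missing


@dataclass
class VariantDataset:
    """A variant table plus its predictor panel and harmonization state."""

    frame: pd.DataFrame
    panel: list[PredictorConvention]
    harmonized: bool = False

    def __post_init__(self) -> None:
        names = [c.name for c in self.panel]
        if len(set(names)) != len(names):
            raise DataError(f"duplicate predictor names in panel: {names}")
        missing_cols = [c for c in _META_COLUMNS + names if c not in self.frame.columns]
        if missing_cols:
            raise DataError(f"dataset frame lacks columns: {missing_cols}")
        ids = self.frame["variant_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise DataError(f"duplicate variant_id values: {dupes[:10]}")

    # -- conveniences -------------------------------------------------
    @property
    def predictor_names(self) -> list[str]:
        return [c.name for c in self.panel]

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def convention(self, predictor: str) -> PredictorConvention:
        for conv in self.panel:
            if conv.name == predictor:
                return conv
        raise ConfigError(f"predictor {predictor!r} not in panel {self.predictor_names}")

    def records(self) -> Iterator[VariantRecord]:
        names = self.predictor_names
        for _, row in self.frame.iterrows():
            ddg = {n: float(row[n]) for n in names if pd.notna(row[n])}
            yield VariantRecord(
                variant_id=str(row["variant_id"]),
                gene=str(row["gene"]),
                label=str(row["label"]),
                ddg=ddg,
            )

    def copy(self) -> "VariantDataset":
        return VariantDataset(
            frame=self.frame.copy(), panel=list(self.panel), harmonized=self.harmonized
        )

    def subset(self, mask: np.ndarray | pd.Series) -> "VariantDataset":
        """New dataset restricted to rows where ``mask`` is True."""
        frame = self.frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return VariantDataset(frame=frame, panel=list(self.panel), harmonized=self.harmonized)

    def labels_pathogenic(self) -> np.ndarray:
        return (self.frame["label"] == PATHOGENIC).to_numpy()


@dataclass(frozen=True)
class InheritanceFlags:
    """Per-gene inheritance-mode flags derived from the three gene lists."""

    gene: str
    is_hi: bool = False
    is_ad: bool = False
    is_ar: bool = False


@dataclass(frozen=True)
class GroupPredicate:
    """A binary gene-level split: a named group versus its complement."""

    group_name: str
    member_test: Callable[[InheritanceFlags], bool]

    def __call__(self, flags: InheritanceFlags) -> bool:
        return bool(self.member_test(flags))

    def mask(self, flags_table: pd.DataFrame) -> pd.Series:
        """Boolean membership Series indexed like ``flags_table``."""
        values = [
            self(InheritanceFlags(gene=row.Index, is_hi=row.is_hi, is_ad=row.is_ad, is_ar=row.is_ar))
            for row in flags_table.itertuples()
        ]
        return pd.Series(values, index=flags_table.index, name=self.group_name)


#: Canonical gene groups. Haploinsufficiency takes precedence over dominance:
#: a gene that is both HI and dominant belongs to "haploinsufficient" and is
#: excluded from "dominant_not_hi" by construction.
CANONICAL_GROUPS: dict[str, GroupPredicate] = {
    "haploinsufficient": GroupPredicate("haploinsufficient", lambda f: f.is_hi),
    "dominant_not_hi": GroupPredicate("dominant_not_hi", lambda f: f.is_ad and not f.is_hi),
    "recessive": GroupPredicate("recessive", lambda f: f.is_ar),
}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _sniff_sep(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_variant_table(
    path: str,
    column_map: Mapping[str, object],
    label_vocabulary: Mapping[str, str] | None = None,
    conventions: Mapping[str, PredictorConvention] | None = None,
    sep: str | None = None,
) -> VariantDataset:
    """Parse a TSV/CSV variant table into an (unharmonized) dataset.

    Parameters
    ----------
    path:
        Tabular file with a header row. Tab-separated unless the file ends
        with ``.csv`` or ``sep`` is given.
    column_map:
        Must bind the roles ``variant_id``, ``gene`` and ``label`` to column
        names, and carry a ``predictors`` mapping of predictor name ->
        column name (at least one entry).
    label_vocabulary:
        Raw label (lower-cased, stripped) -> ``pathogenic``/``benign``.
        Defaults to :data:`DEFAULT_LABEL_VOCABULARY`. Unmappable labels are
        a hard error.
    conventions:
        Optional predictor-name -> :class:`PredictorConvention`; predictors
        absent from the mapping default to positive-destabilizing, no cap.
    """
    column_map = dict(column_map)
    for role in _META_COLUMNS:
        if role not in column_map:
            raise ConfigError(f"column_map must bind the {role!r} role")
    predictors = dict(column_map.get("predictors") or {})
    if not predictors:
        raise ConfigError("column_map must name at least one predictor column")

    vocab = {k.lower().strip(): v for k, v in (label_vocabulary or DEFAULT_LABEL_VOCABULARY).items()}

    raw = pd.read_csv(path, sep=sep or _sniff_sep(path), dtype=str, keep_default_na=False)
    for role in _META_COLUMNS:
        if column_map[role] not in raw.columns:
            raise DataError(f"column {column_map[role]!r} (role {role!r}) absent from {path}")
    for name, col in predictors.items():
        if col not in raw.columns:
            raise DataError(f"predictor column {col!r} (predictor {name!r}) absent from {path}")

    frame = pd.DataFrame(
        {
            "variant_id": raw[column_map["variant_id"]].astype(str).str.strip(),
            "gene": raw[column_map["gene"]].map(normalize_gene),
        }
    )

    raw_labels = raw[column_map["label"]].astype(str).str.strip().str.lower()
    mapped = raw_labels.map(vocab)
    bad = mapped.isna()
    if bad.any():
        rows = [f"row {i}: {raw_labels.iloc[i]!r}" for i in np.flatnonzero(bad.to_numpy())[:10]]
        raise DataError("unmappable label values: " + "; ".join(rows))
    frame["label"] = mapped

    panel: list[PredictorConvention] = []
    for name, col in predictors.items():
        cell = raw[col].astype(str).str.strip().replace({"": None, "NA": None, "NaN": None, "nan": None})
        frame[name] = pd.to_numeric(cell, errors="raise").astype(float)
        if conventions and name in conventions:
            panel.append(conventions[name])
        else:
            panel.append(PredictorConvention(name=name))

    dataset = VariantDataset(frame=frame, panel=panel, harmonized=False)
    logger.info("read %d variant records, %d predictors from %s", len(frame), len(panel), path)
    return dataset


def write_variant_table(dataset: VariantDataset, path: str, sep: str | None = None) -> None:
    """Write the variant table back out (same layout read_variant_table reads)."""
    frame = dataset.frame[_META_COLUMNS + dataset.predictor_names]
    frame.to_csv(path, sep=sep or _sniff_sep(path), index=False, float_format="%.17g")


def read_gene_list(path: str) -> set[str]:
    """Read a plain-text gene list: one symbol per line, ``#`` comments."""
    symbols: set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.add(normalize_gene(line))
    if not symbols:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    return symbols


def read_convention_map(path: str) -> dict[str, PredictorConvention]:
    """Load a YAML convention map: ``name: {sign: pos|neg, cap: number|null}``."""
    with open(path) as handle:
        payload = yaml.safe_load(handle) or {}
    return _parse_convention_payload(payload)


def _parse_convention_payload(payload: Mapping[str, object]) -> dict[str, PredictorConvention]:
    sign_aliases = {
        "pos": POSITIVE_DESTABILIZING,
        "neg": NEGATIVE_DESTABILIZING,
        POSITIVE_DESTABILIZING: POSITIVE_DESTABILIZING,
        NEGATIVE_DESTABILIZING: NEGATIVE_DESTABILIZING,
    }
    conventions: dict[str, PredictorConvention] = {}
    for name, entry in payload.items():
        entry = entry or {}
        sign = sign_aliases.get(str(entry.get("sign", "pos")))
        if sign is None:
            raise ConfigError(f"predictor {name!r}: sign must be pos or neg")
        cap = entry.get("cap")
        conventions[str(name)] = PredictorConvention(
            name=str(name), sign_convention=sign, cap=None if cap is None else float(cap)
        )
    return conventions


def default_convention_map() -> dict[str, PredictorConvention]:
    """Packaged default sign/cap map for the 13 common stability predictors.

    The published analyses do not state per-tool conventions or cap values;
    these defaults reflect tool documentation and are meant to be edited.
    """
    text = resources.files("ddgeval").joinpath("conventions.yaml").read_text()
    return _parse_convention_payload(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def harmonize_signs(dataset: VariantDataset) -> VariantDataset:
    """Return a copy where every predictor is positive-destabilizing.

    Values of negative-destabilizing predictors are negated; |value| is
    preserved for every record/predictor and missing stays missing.
    Calling this on an already-harmonized dataset is a hard error: a second
    negation would silently corrupt the table.
    """
    if dataset.harmonized:
        raise DataError("dataset is already harmonized; refusing to flip signs twice")
    frame = dataset.frame.copy()
    panel = []
    for conv in dataset.panel:
        if conv.sign_convention == NEGATIVE_DESTABILIZING:
            frame[conv.name] = -frame[conv.name]
        panel.append(replace(conv, sign_convention=POSITIVE_DESTABILIZING))
    return VariantDataset(frame=frame, panel=panel, harmonized=True)


def annotate_inheritance(
    dataset: VariantDataset,
    hi: Iterable[str],
    ad: Iterable[str],
    ar: Iterable[str],
) -> pd.DataFrame:
    """Per-gene flags table (index: gene; columns: is_hi, is_ad, is_ar).

    Every gene present in the dataset gets a row; genes in none of the three
    lists get all-false flags and thus belong only to complements.
    """
    hi_set = {normalize_gene(g) for g in hi}
    ad_set = {normalize_gene(g) for g in ad}
    ar_set = {normalize_gene(g) for g in ar}
    genes = sorted(dataset.frame["gene"].unique())
    table = pd.DataFrame(
        {
            "is_hi": [g in hi_set for g in genes],
            "is_ad": [g in ad_set for g in genes],
            "is_ar": [g in ar_set for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return table


def abs_scores(dataset: VariantDataset, predictor: str) -> tuple[np.ndarray, np.ndarray]:
    """|ddG| score vectors ``(pathogenic, benign)`` for one predictor.

    Records with no value for this predictor are dropped from both vectors
    (pairwise deletion). Raises :class:`UndefinedStratumError` when either
    class ends up empty.
    """
    dataset.convention(predictor)  # validates membership
    values = dataset.frame[predictor].to_numpy(dtype=float)
    present = np.isfinite(values)
    pathogenic = dataset.labels_pathogenic()
    pos = np.abs(values[present & pathogenic])
    neg = np.abs(values[present & ~pathogenic])
    if pos.size == 0 or neg.size == 0:
        raise UndefinedStratumError(
            f"predictor {predictor!r}: no usable records in one class "
            f"(pathogenic={pos.size}, benign={neg.size})"
        )
    return pos, neg
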