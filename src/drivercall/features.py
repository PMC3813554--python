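"""Mutation x feature matrices with missingness tracking and kNN imputation.

Per-mutation feature values (conservation scores, domain annotations,
functional-impact predictions, ...) are consumed from precomputed tables;
this package never computes raw features itself.  Missing cells are filled
from the nearest mutations in the same gene, on the rationale that nearby
sites in the same protein share structural and evolutionary context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import MutationCatalog

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Numeric mutation x feature matrix; NaN marks a missing cell.

    ``kinds`` maps each feature to "continuous" or "binary"; binary
    features take values in {0, 1} where observed.
    """

    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        for f in self.values.columns:
            self.kinds.setdefault(f, "continuous")
        unknown = set(self.kinds) - set(self.values.columns)
        if unknown:
            raise ValueError(f"kinds declared for unknown features: {sorted(unknown)}")
        for f, kind in self.kinds.items():
            if kind not in ("continuous", "binary"):
                raise ValueError(f"bad kind {kind!r} for feature {f!r}")
            if kind == "binary":
                col = self.values[f].dropna()
                if not col.isin([0.0, 1.0]).all():
                    raise ValueError(f"binary feature {f!r} has non-0/1 values")

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), dict(self.kinds))


@dataclass(frozen=True)
class ImputationConfig:
    """k-nearest-neighbor imputation settings.

    Neighbors are same-gene mutations ranked by genomic distance in bp;
    continuous features aggregate by median, binary by mode (ties -> 0).
    When a gene has no donor for a feature the gene-wide then table-wide
    central value is used.
    """

    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def missing_fraction(table: FeatureTable) -> tuple[pd.Series, float]:
    """Per-feature and overall fractions of missing cells."""
    mask = table.missing_mask
    per_feature = mask.mean(axis=0)
    overall = float(mask.to_numpy().mean()) if mask.size else 0.0
    return per_feature, overall


def _central_value(values: pd.Series, kind: str) -> float:
    obs = values.dropna()
    if obs.empty:
        raise ValueError("no observed values")
    if kind == "binary":
        ones = int((obs == 1.0).sum())
        zeros = len(obs) - ones
        return 1.0 if ones > zeros else 0.0  # tie -> 0
    return float(obs.median())


def impute(
    table: FeatureTable,
    catalog: MutationCatalog,
    config: ImputationConfig | None = None,
) -> FeatureTable:
    """Fill every missing cell by within-gene k-nearest-neighbor transfer.

    For a missing (mutation, feature) cell, donors are same-gene mutations
    with that feature observed, ranked by |pos difference| with ties broken
    by lower position then lexicographic mutation_id; the up-to-``k``
    nearest donors aggregate by median (continuous) or mode (binary,
    tie -> 0).  Mutations without same-gene donors fall back to the
    gene-wide, then table-wide central value.  Observed cells are never
    changed.

    Raises ``ValueError`` naming any feature that is missing for every
    mutation (no fallback possible).
    """
    config = config or ImputationConfig()
    out = table.copy()
    values = out.values

    fully_missing = [f for f in values.columns if values[f].isna().all()]
    if fully_missing:
        raise ValueError(
            f"feature(s) missing for all mutations: {', '.join(fully_missing)}"
        )

    # resolve gene/pos; unknown mutations fall back to the table-wide value
    gene_of: dict[str, str] = {}
    pos_of: dict[str, int] = {}
    unresolved: list[str] = []
    for mid in values.index:
        if mid in catalog:
            gene_of[mid], pos_of[mid] = catalog.gene_pos(mid)
        else:
            unresolved.append(mid)
    if unresolved:
        logger.warning(
            "%d mutation(s) not in catalog; using table-wide central values: %s",
            len(unresolved),
            ", ".join(unresolved[:5]),
        )

    by_gene: dict[str, list[str]] = {}
    for mid, g in gene_of.items():
        by_gene.setdefault(g, []).append(mid)

    table_central = {f: _central_value(values[f], out.kinds[f]) for f in values.columns}

    for feat in values.columns:
        col = values[feat]
        missing_ids = col.index[col.isna()]
        if missing_ids.empty:
            continue
        kind = out.kinds[feat]
        for mid in missing_ids:
            if mid not in gene_of:
                values.at[mid, feat] = table_central[feat]
                continue
            gene, pos = gene_of[mid], pos_of[mid]
            donors = [
                d
                for d in by_gene.get(gene, [])
                if d != mid and not np.isnan(col.at[d])
            ]
            if not donors:
                values.at[mid, feat] = table_central[feat]
                continue
            donors.sort(key=lambda d: (abs(pos_of[d] - pos), pos_of[d], d))
            nearest = donors[: config.k]
            donor_vals = pd.Series([col.at[d] for d in nearest])
            if kind == "binary":
                ones = int((donor_vals == 1.0).sum())
                zeros = len(donor_vals) - ones
                values.at[mid, feat] = 1.0 if ones > zeros else 0.0
            else:
                values.at[mid, feat] = float(donor_vals.median())
    return out


# ---------------------------------------------------------------------------
# I/O: feature TSV + sidecar YAML declaring feature kinds


def read_feature_table(
    path: str | Path, kinds_path: str | Path | None = None
) -> FeatureTable:
    """Read a feature TSV (first column mutation_id; '' or 'NA' = missing).

    ``kinds_path`` points to a YAML mapping feature -> "continuous"/"binary";
    undeclared features default to continuous.  When omitted, a sidecar
    ``<path>.kinds.yaml`` is used if present.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["", "NA"], keep_default_na=False
    )
    df.index = df.index.astype(str)
    kinds: dict[str, str] = {}
    if kinds_path is None:
        sidecar = path.with_suffix(path.suffix + ".kinds.yaml")
        kinds_path = sidecar if sidecar.exists() else None
    if kinds_path is not None:
        with open(kinds_path) as fh:
            declared = yaml.safe_load(fh) or {}
        kinds = {str(k): str(v) for k, v in declared.items() if k in df.columns}
    return FeatureTable(df, kinds)


def write_feature_table(
    table: FeatureTable, path: str | Path, kinds_path: str | Path | None = None
) -> None:
    """Write the feature TSV and its sidecar kinds YAML."""
    path = Path(path)
    table.values.to_csv(path, sep="\t", index_label="mutation_id", na_rep="NA")
    if kinds_path is None:
        kinds_path = path.with_suffix(path.suffix + ".kinds.yaml")
    with open(kinds_path, "w") as fh:
        yaml.safe_dump(table.kinds, fh, sort_keys=True)
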