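"""Synthetic mutation catalogs and feature tables with known ground truth.

The generator emulates the statistical structure of curated somatic
training sets: driver-like mutations recur across samples or cluster in
hotspots, passenger-like mutations are isolated singletons, and features
separate the two classes by a controllable Gaussian mean shift
(continuous) or Bernoulli rate shift (binary) with optional missingness.
Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import GeneList, MutationCatalog, MutationRecord
from .features import FeatureTable


@dataclass(frozen=True)
class HotspotSpec:
    """One injected hotspot: n_records spread across a centered window."""

    gene: str
    center_pos: int
    n_records: int = 5
    window_bp: int = 25


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study.

    ``effect_size`` is the driver-vs-passenger mean shift of informative
    continuous features in SD units; a single such feature has expected
    ROC AUC Phi(effect_size / sqrt(2)).  ``binary_fraction`` of features
    are binary; informative binary features use Bernoulli(0.5 +
    ``binary_effect``) for drivers vs Bernoulli(0.5).  ``missing_rate``
    masks cells uniformly at random (or in feature blocks when
    ``block_missing`` is set, emulating portal-wise dropout).
    """

    n_drivers: int = 100
    n_passengers: int = 400
    n_features: int = 30
    n_informative: int = 3
    effect_size: float = 1.5
    binary_fraction: float = 0.0
    binary_effect: float = 0.2
    missing_rate: float = 0.0
    block_missing: bool = False
    hotspot_spec: tuple[HotspotSpec, ...] = ()
    cancer_type: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.binary_fraction <= 1):
            raise ValueError("binary_fraction must be in [0, 1]")
        if not (0 <= self.binary_effect <= 0.5):
            raise ValueError("binary_effect must be in [0, 0.5]")


def _feature_kinds(spec: FixtureSpec) -> tuple[list[str], dict[str, str], list[str]]:
    names = [f"F{i:03d}" for i in range(1, spec.n_features + 1)]
    n_binary = int(round(spec.binary_fraction * spec.n_features))
    kinds = {
        f: ("binary" if i >= spec.n_features - n_binary else "continuous")
        for i, f in enumerate(names)
    }
    informative = names[: spec.n_informative]
    return names, kinds, informative


def _draw_features(
    rng: np.random.Generator,
    n: int,
    names: Sequence[str],
    kinds: dict[str, str],
    informative: Sequence[str],
    is_driver: bool,
    spec: FixtureSpec,
) -> np.ndarray:
    cols = []
    for f in names:
        inf = f in informative and is_driver
        if kinds[f] == "binary":
            p = 0.5 + (spec.binary_effect if inf else 0.0)
            cols.append(rng.binomial(1, p, size=n).astype(float))
        else:
            mu = spec.effect_size if inf else 0.0
            cols.append(rng.normal(mu, 1.0, size=n))
    return np.column_stack(cols)


def _apply_missingness(
    rng: np.random.Generator, values: pd.DataFrame, spec: FixtureSpec
) -> None:
    if spec.missing_rate == 0:
        return
    n_rows, n_cols = values.shape
    total = n_rows * n_cols
    target = int(round(spec.missing_rate * total))
    if spec.block_missing:
        # portal-style dropout: whole row-blocks of randomly chosen features
        cols = rng.permutation(n_cols)
        masked = 0
        for c in cols:
            if masked >= target:
                break
            block = min(n_rows // 2, target - masked)
            start = int(rng.integers(0, n_rows - block + 1)) if block < n_rows else 0
            values.iloc[start : start + block, c] = np.nan
            masked += block
    else:
        flat = rng.choice(total, size=target, replace=False)
        rows, cols = np.unravel_index(flat, (n_rows, n_cols))
        vals = values.to_numpy()
        vals[rows, cols] = np.nan
        values.iloc[:, :] = vals


def make_feature_table(spec: FixtureSpec) -> tuple[FeatureTable, pd.Series]:
    """Generate a labeled feature table without a catalog.

    Rows ``drv_*`` are drivers (label 1), ``pas_*`` passengers (label 0).
    """
    rng = np.random.default_rng(spec.seed)
    names, kinds, informative = _feature_kinds(spec)
    drv = _draw_features(rng, spec.n_drivers, names, kinds, informative, True, spec)
    pas = _draw_features(rng, spec.n_passengers, names, kinds, informative, False, spec)
    ids = [f"drv_{i:05d}" for i in range(spec.n_drivers)] + [
        f"pas_{i:05d}" for i in range(spec.n_passengers)
    ]
    values = pd.DataFrame(np.vstack([drv, pas]), index=ids, columns=names)
    _apply_missingness(rng, values, spec)
    labels = pd.Series(
        [1] * spec.n_drivers + [0] * spec.n_passengers, index=ids, name="label"
    )
    return FeatureTable(values, kinds), labels


@dataclass(frozen=True)
class CatalogTruth:
    """Ground truth planted in a generated catalog."""

    expanded_drivers: tuple[str, ...]
    expanded_passengers: tuple[str, ...]
    driver_variant_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)


_GENE_SPACING = 1_000_000  # bp between simulated genes on a chromosome
_SINGLETON_SPACING = 200  # bp between isolated singletons (>> 31-bp window)


class _GenePlacer:
    """Deterministic gene -> (chrom, base position) layout."""

    def __init__(self) -> None:
        self._n = 0
        self.assigned: dict[str, tuple[str, int]] = {}

    def place(self, gene: str) -> tuple[str, int]:
        if gene not in self.assigned:
            chrom = f"chr{self._n % 22 + 1}"
            base = 1_000_000 + (self._n // 22 + 1) * _GENE_SPACING
            self.assigned[gene] = (chrom, base)
            self._n += 1
        return self.assigned[gene]


def make_catalog(spec: FixtureSpec) -> tuple[MutationCatalog, CatalogTruth, GeneList]:
    """Generate a catalog whose curated expanded sets are known by design.

    Drivers alternate between two planting mechanisms: recurrent variants
    observed in 3 primary-tumor samples (recurrence rule) and centers of
    5-record hotspots within a 25-bp window (hotspot rule).  Passengers
    are isolated singletons in non-cancer genes spaced far beyond the
    isolation window.  ``hotspot_spec`` entries add extra hotspots
    verbatim.  Returns (catalog, truth, cancer_genes) where cancer_genes
    lists the driver-hosting genes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    placer = _GenePlacer()
    records: list[MutationRecord] = []
    driver_ids: list[str] = []
    variant_ids: dict[str, tuple[str, ...]] = {}
    bases = "ACGT"

    def alleles(i: int) -> tuple[str, str]:
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        return ref, alt

    for i in range(spec.n_drivers):
        gene = f"DRVG{i:04d}"
        chrom, base = placer.place(gene)
        ref, alt = alleles(i)
        if i % 2 == 0:
            # recurrence rule: same variant in 3 primary-tumor samples
            pos = base + 500
            ids = tuple(f"drv_{i:05d}_r{j}" for j in range(3))
            for j, mid in enumerate(ids):
                records.append(
                    MutationRecord(
                        mutation_id=mid,
                        gene=gene,
                        chrom=chrom,
                        pos=pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        sample_id=f"S_{gene}_{j}",
                        mutation_class="missense",
                        sample_type="primary_tumor",
                        cancer_type=spec.cancer_type,
                    )
                )
            rep = min(ids)
        else:
            # hotspot rule: 5 records at center, +/-6, +/-12; only the
            # center's 25-bp window holds all 5
            center = base + 500
            ids_list = []
            for j, off in enumerate((-12, -6, 0, 6, 12)):
                r2, a2 = alleles(i + j)
                mid = f"drv_{i:05d}_h{j}"
                ids_list.append(mid)
                records.append(
                    MutationRecord(
                        mutation_id=mid,
                        gene=gene,
                        chrom=chrom,
                        pos=center + off,
                        ref_allele=r2,
                        alt_allele=a2,
                        sample_id=f"S_{gene}_{j}",
                        mutation_class="missense",
                        sample_type="primary_tumor",
                        cancer_type=spec.cancer_type,
                    )
                )
            ids = tuple(ids_list)
            rep = f"drv_{i:05d}_h2"  # the center record
        driver_ids.append(rep)
        variant_ids[rep] = ids

    passenger_ids: list[str] = []
    n_pass_genes = max(1, spec.n_passengers // 50 + 1)
    for i in range(spec.n_passengers):
        gene = f"PASG{i % n_pass_genes:04d}"
        chrom, base = placer.place(gene)
        pos = base + 10_000 + (i // n_pass_genes) * _SINGLETON_SPACING
        ref, alt = alleles(i)
        mid = f"pas_{i:05d}"
        passenger_ids.append(mid)
        records.append(
            MutationRecord(
                mutation_id=mid,
                gene=gene,
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                sample_id=f"S_P{i:05d}",
                mutation_class="missense",
                sample_type="primary_tumor",
                cancer_type=spec.cancer_type,
            )
        )

    for h_idx, hs in enumerate(spec.hotspot_spec):
        chrom, _ = placer.place(hs.gene)
        half = hs.window_bp // 2
        if hs.n_records > hs.window_bp:
            raise ValueError(
                f"hotspot in {hs.gene}: cannot place {hs.n_records} records "
                f"within {hs.window_bp} bp"
            )
        offsets = np.linspace(-half, half, hs.n_records).round().astype(int)
        for j, off in enumerate(offsets):
            ref, alt = alleles(j)
            records.append(
                MutationRecord(
                    mutation_id=f"hs_{h_idx}_{j}",
                    gene=hs.gene,
                    chrom=chrom,
                    pos=hs.center_pos + int(off),
                    ref_allele=ref,
                    alt_allele=alt,
                    sample_id=f"S_HS{h_idx}_{j}",
                    mutation_class="missense",
                    sample_type="primary_tumor",
                    cancer_type=spec.cancer_type,
                )
            )

    rng.shuffle(records)  # catalog order must not matter downstream
    catalog = MutationCatalog(records)
    cancer_genes = GeneList.from_symbols(
        (f"DRVG{i:04d}" for i in range(spec.n_drivers)), label="simulated_census"
    )
    truth = CatalogTruth(
        expanded_drivers=tuple(sorted(driver_ids)),
        expanded_passengers=tuple(sorted(passenger_ids)),
        driver_variant_ids=variant_ids,
    )
    return catalog, truth, cancer_genes


@dataclass(frozen=True)
class SimulatedDataset:
    catalog: MutationCatalog
    table: FeatureTable
    labels: pd.Series
    truth: CatalogTruth
    cancer_genes: GeneList


def make_dataset(spec: FixtureSpec) -> SimulatedDataset:
    """Catalog + aligned feature table for end-to-end pipeline runs.

    Every missense record gets a feature row; records of the same variant
    share one feature draw (a variant has one set of annotations).
    Truth-driver variants draw from the driver distribution, everything
    else from the passenger distribution.  ``labels`` covers only the
    truth-labeled representative ids.
    """
    catalog, truth, cancer_genes = make_catalog(spec)
    rng = np.random.default_rng(spec.seed + 2)
    names, kinds, informative = _feature_kinds(spec)

    driver_reps = set(truth.expanded_drivers)
    # one feature draw per variant, copied to each of its records
    variant_of: dict[str, tuple] = {r.mutation_id: r.variant_key for r in catalog}
    variant_rows: dict[tuple, np.ndarray] = {}
    driver_variants = {
        variant_of[rep] for rep in driver_reps
    }
    all_ids = sorted(variant_of)
    rows = []
    for mid in all_ids:
        key = variant_of[mid]
        if key not in variant_rows:
            is_driver = key in driver_variants
            variant_rows[key] = _draw_features(
                rng, 1, names, kinds, informative, is_driver, spec
            )[0]
        rows.append(variant_rows[key])
    values = pd.DataFrame(np.vstack(rows), index=all_ids, columns=names)
    _apply_missingness(rng, values, spec)
    table = FeatureTable(values, kinds)
    labels = pd.Series(
        {mid: 1 for mid in truth.expanded_drivers}
        | {mid: 0 for mid in truth.expanded_passengers},
        name="label",
    ).sort_index()
    return SimulatedDataset(catalog, table, labels, truth, cancer_genes)
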