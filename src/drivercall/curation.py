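"""Curate driver/passenger training examples from somatic mutation catalogs.

Two labeled sets are built per cancer type:

* the **stringent set (S)** — high-confidence recurrent missense drivers and
  passengers drawn from hypermutated samples; used for independent testing;
* the **expanded set (E)** — a larger, cross-cancer-informed set built from
  recurrence and hotspot-proximity rules; used for training.

All rules operate on variant identity (chrom, pos, ref, alt); each
qualifying variant is reported once, by the lexicographically smallest
mutation_id among its records.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .catalog import (
    FUNCTIONAL_CONFOUNDER_CLASSES,
    GeneList,
    MutationCatalog,
    MutationRecord,
    SiteBlacklist,
)


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds for the curation rules.

    Window widths are in base pairs and must be odd: a window of 25 bp
    centered on a site spans site ± 12.
    """

    stringent_min_samples: int = 2
    expanded_driver_min_samples: int = 3
    site_intersect_min: int = 4
    hotspot_window_bp: int = 25
    hotspot_min_mutations: int = 5
    passenger_isolation_window_bp: int = 31
    hypermutated_min_missense: int = 55

    def __post_init__(self) -> None:
        for name in (
            "stringent_min_samples",
            "expanded_driver_min_samples",
            "site_intersect_min",
            "hotspot_window_bp",
            "hotspot_min_mutations",
            "passenger_isolation_window_bp",
            "hypermutated_min_missense",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("hotspot_window_bp", "passenger_isolation_window_bp"):
            if getattr(self, name) % 2 == 0:
                raise ValueError(f"{name} must be odd (centered window)")

    @property
    def hotspot_halfwidth(self) -> int:
        return self.hotspot_window_bp // 2

    @property
    def isolation_halfwidth(self) -> int:
        return self.passenger_isolation_window_bp // 2


@dataclass(frozen=True)
class LabeledSet:
    """Driver/passenger mutation ids for one cancer type and provenance."""

    drivers: tuple[str, ...]
    passengers: tuple[str, ...]
    provenance: str  # "stringent" | "expanded"
    cancer_type: str = ""
    driver_variants: frozenset[tuple[str, int, str, str]] = field(default_factory=frozenset)
    passenger_variants: frozenset[tuple[str, int, str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if set(self.drivers) & set(self.passengers):
            raise ValueError("drivers and passengers must be disjoint")
        if self.provenance not in ("stringent", "expanded"):
            raise ValueError(f"bad provenance {self.provenance!r}")


def _group_by_variant(records) -> dict[tuple, list[MutationRecord]]:
    groups: dict[tuple, list[MutationRecord]] = defaultdict(list)
    for r in records:
        groups[r.variant_key].append(r)
    return groups


def _representative_id(records: list[MutationRecord]) -> str:
    return min(r.mutation_id for r in records)


class _PositionIndex:
    """Sorted per-chromosome positions for O(log n) window counts."""

    def __init__(self, records):
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for r in records:
            by_chrom[r.chrom].append(r.pos)
        self._pos = {c: sorted(ps) for c, ps in by_chrom.items()}

    def count_in_window(self, chrom: str, lo: int, hi: int) -> int:
        """Number of records with lo <= pos <= hi on chrom."""
        ps = self._pos.get(chrom)
        if not ps:
            return 0
        return bisect_right(ps, hi) - bisect_left(ps, lo)


# ---------------------------------------------------------------------------
# stringent set


def stringent_drivers(
    catalog: MutationCatalog,
    blacklist: SiteBlacklist,
    config: CurationConfig | None = None,
) -> list[str]:
    """Recurrent missense variants with no functional confounder in cis.

    A missense variant qualifies when it is observed in at least
    ``stringent_min_samples`` distinct samples, no carrying sample also has
    an indel/nonsense/nonstop/splice-site/translation-start mutation in the
    same gene, and its site is not blacklisted.
    """
    config = config or CurationConfig()
    # (sample, gene) pairs carrying a putative functional confounder
    confounded: set[tuple[str, str]] = {
        (r.sample_id, r.gene)
        for r in catalog
        if r.mutation_class in FUNCTIONAL_CONFOUNDER_CLASSES
    }
    out = []
    missense = [r for r in catalog if r.mutation_class == "missense"]
    for key, recs in _group_by_variant(missense).items():
        chrom, pos, _, _ = key
        if (chrom, pos) in blacklist:
            continue
        samples = {r.sample_id for r in recs}
        if len(samples) < config.stringent_min_samples:
            continue
        if any((r.sample_id, r.gene) in confounded for r in recs):
            continue
        out.append(_representative_id(recs))
    return sorted(out)


def hypermutated_samples(catalog: MutationCatalog, config: CurationConfig) -> set[str]:
    """Samples with strictly more missense mutations than the configured cutoff."""
    counts = Counter(r.sample_id for r in catalog if r.mutation_class == "missense")
    return {s for s, n in counts.items() if n > config.hypermutated_min_missense}


def stringent_passengers(
    catalog: MutationCatalog,
    blacklist: SiteBlacklist,
    cancer_genes: GeneList,
    config: CurationConfig | None = None,
) -> list[str]:
    """Missense mutations from hypermutated samples, outside cancer genes.

    Hypermutated (DNA-repair-deficient) samples carry mostly passengers, so
    their missense mutations — excluding cancer-gene and blacklisted sites —
    serve as real passenger examples.
    """
    config = config or CurationConfig()
    hyper = hypermutated_samples(catalog, config)
    candidates = [
        r
        for r in catalog
        if r.mutation_class == "missense"
        and r.sample_id in hyper
        and r.gene not in cancer_genes
        and (r.chrom, r.pos) not in blacklist
    ]
    return sorted(
        _representative_id(recs) for recs in _group_by_variant(candidates).values()
    )


def curate_stringent(
    catalog: MutationCatalog,
    blacklist: SiteBlacklist,
    cancer_genes: GeneList,
    config: CurationConfig | None = None,
    cancer_type: str = "",
) -> LabeledSet:
    config = config or CurationConfig()
    drivers = stringent_drivers(catalog, blacklist, config)
    passengers = stringent_passengers(catalog, blacklist, cancer_genes, config)
    driver_set = set(drivers)
    passengers = [p for p in passengers if p not in driver_set]
    return LabeledSet(
        drivers=tuple(drivers),
        passengers=tuple(passengers),
        provenance="stringent",
        cancer_type=cancer_type,
        driver_variants=frozenset(catalog[m].variant_key for m in drivers),
        passenger_variants=frozenset(catalog[m].variant_key for m in passengers),
    )


# ---------------------------------------------------------------------------
# expanded set


def _target_records(catalog: MutationCatalog, cancer_type: str):
    if cancer_type:
        return [r for r in catalog if r.cancer_type == cancer_type]
    return list(catalog.records)


def expanded_drivers(
    catalog: MutationCatalog,
    cancer_type: str,
    config: CurationConfig | None = None,
    stringent: LabeledSet | None = None,
) -> list[str]:
    """Cross-cancer recurrence / hotspot rules for putative drivers.

    A missense variant in a gene mutated in the target cancer type
    qualifies when any of three rules holds:

    1. it is observed in >= ``expanded_driver_min_samples`` distinct
       primary-tumor samples, regardless of cancer type;
    2. its exact genomic site intersects >= ``site_intersect_min`` catalog
       records of any class (indels, di-/trinucleotide changes included);
    3. it is centered in a ``hotspot_window_bp`` window containing
       >= ``hotspot_min_mutations`` catalog records.

    Variants already in the stringent driver set are subtracted so the two
    sets stay independent.
    """
    config = config or CurationConfig()
    target_genes = {r.gene for r in _target_records(catalog, cancer_type)}
    site_counts = Counter((r.chrom, r.pos) for r in catalog)
    index = _PositionIndex(catalog.records)
    half = config.hotspot_halfwidth
    exclude = stringent.driver_variants if stringent is not None else frozenset()

    out = []
    missense = [r for r in catalog if r.mutation_class == "missense"]
    for key, recs in _group_by_variant(missense).items():
        chrom, pos, _, _ = key
        if recs[0].gene not in target_genes:
            continue
        if key in exclude:
            continue
        primary_samples = {
            r.sample_id for r in recs if r.sample_type == "primary_tumor"
        }
        rule1 = len(primary_samples) >= config.expanded_driver_min_samples
        rule2 = site_counts[(chrom, pos)] >= config.site_intersect_min
        rule3 = (
            index.count_in_window(chrom, pos - half, pos + half)
            >= config.hotspot_min_mutations
        )
        if rule1 or rule2 or rule3:
            out.append(_representative_id(recs))
    return sorted(out)


def expanded_passengers(
    catalog: MutationCatalog,
    cancer_type: str,
    cancer_genes: GeneList,
    config: CurationConfig | None = None,
    stringent: LabeledSet | None = None,
) -> list[str]:
    """Isolated singleton missense mutations as putative passengers.

    A variant qualifies when it has exactly one primary-tumor observation in
    the target cancer type, its gene is not a known cancer gene, and no
    other catalog record of any class lies within the isolation window
    (site ± ``passenger_isolation_window_bp``//2).  Stringent passengers are
    subtracted.
    """
    config = config or CurationConfig()
    index = _PositionIndex(catalog.records)
    half = config.isolation_halfwidth
    exclude = stringent.passenger_variants if stringent is not None else frozenset()

    target_primary = [
        r
        for r in _target_records(catalog, cancer_type)
        if r.sample_type == "primary_tumor"
    ]
    missense_target = [r for r in target_primary if r.mutation_class == "missense"]

    out = []
    for key, recs in _group_by_variant(missense_target).items():
        chrom, pos, _, _ = key
        if len(recs) != 1:
            continue
        if key in exclude:
            continue
        if recs[0].gene in cancer_genes:
            continue
        # the whole-catalog window count includes the candidate's own record;
        # any additional record — same variant in a cell line, or a different
        # mutation nearby — counts as a coinciding mutation and disqualifies
        if index.count_in_window(chrom, pos - half, pos + half) > 1:
            continue
        out.append(recs[0].mutation_id)
    return sorted(out)


def curate_expanded(
    catalog: MutationCatalog,
    cancer_type: str,
    cancer_genes: GeneList,
    config: CurationConfig | None = None,
    stringent: LabeledSet | None = None,
) -> LabeledSet:
    config = config or CurationConfig()
    drivers = expanded_drivers(catalog, cancer_type, config, stringent)
    driver_set = set(drivers)
    passengers = [
        p
        for p in expanded_passengers(catalog, cancer_type, cancer_genes, config, stringent)
        if p not in driver_set
    ]
    return LabeledSet(
        drivers=tuple(drivers),
        passengers=tuple(passengers),
        provenance="expanded",
        cancer_type=cancer_type,
        driver_variants=frozenset(catalog[m].variant_key for m in drivers),
        passenger_variants=frozenset(catalog[m].variant_key for m in passengers),
    )
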