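"""Mutation catalogs, site blacklists, gene lists, and driver-call tables.

Somatic mutation catalogs arrive as MAF-like tab-separated tables (one row
per observed mutation in one sample).  Internally every coordinate is
1-based inclusive, matching MAF/COSMIC convention; BED blacklist input is
converted at the boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

MUTATION_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "nonstop",
        "splice_site",
        "translation_start",
        "indel",
        "dinucleotide",
        "trinucleotide",
        "other",
    }
)

#: mutation classes treated as "putative functional" confounders alongside
#: missense candidates during stringent driver curation
FUNCTIONAL_CONFOUNDER_CLASSES = frozenset(
    {"indel", "nonsense", "nonstop", "splice_site", "translation_start"}
)

SAMPLE_TYPES = frozenset({"primary_tumor", "cell_line", "other"})


class CatalogFormatError(ValueError):
    """Raised for malformed catalog / blacklist / call files."""


@dataclass(frozen=True)
class MutationRecord:
    """One observed somatic mutation in one sample.

    ``pos`` is the 1-based genomic coordinate of the variant site.
    ``mutation_id`` is an opaque key unique within a catalog; recurrent
    variants (same ``variant_key``) observed in several samples appear as
    several records with distinct ids.
    """

    mutation_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_id: str
    mutation_class: str = "missense"
    sample_type: str = "primary_tumor"
    protein_change: str | None = None
    source: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} for {self.mutation_id}")
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation_class {self.mutation_class!r}")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        """Genomic identity of the variant: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


class MutationCatalog:
    """An ordered collection of :class:`MutationRecord` with unique ids."""

    def __init__(self, records: Iterable[MutationRecord] = ()):
        self.records: list[MutationRecord] = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.mutation_id in seen:
                raise ValueError(f"duplicate mutation_id {r.mutation_id!r}")
            seen.add(r.mutation_id)
        self._by_id = {r.mutation_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, mutation_id: str) -> MutationRecord:
        return self._by_id[mutation_id]

    def __contains__(self, mutation_id: str) -> bool:
        return mutation_id in self._by_id

    def subset(self, predicate) -> "MutationCatalog":
        return MutationCatalog(r for r in self.records if predicate(r))

    def gene_pos(self, mutation_id: str) -> tuple[str, int]:
        r = self._by_id[mutation_id]
        return (r.gene, r.pos)


@dataclass(frozen=True)
class SiteBlacklist:
    """A set of (chrom, 1-based position) sites to exclude, e.g. known SNPs."""

    sites: frozenset[tuple[str, int]] = field(default_factory=frozenset)
    label: str = "blacklist"

    def __contains__(self, site: tuple[str, int]) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class GeneList:
    """A case-normalized set of gene symbols (e.g. a cancer gene census)."""

    genes: frozenset[str] = field(default_factory=frozenset)
    label: str = "gene_list"

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], label: str = "gene_list") -> "GeneList":
        return cls(frozenset(s.strip().upper() for s in symbols if s.strip()), label)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class DriverCall:
    """Score, three-way category, and empirical confidence for one mutation."""

    mutation_id: str
    score: float
    category: str  # "driver" | "no-call" | "passenger"
    confidence: float | None

    def __post_init__(self) -> None:
        if self.category not in ("driver", "no-call", "passenger"):
            raise ValueError(f"bad category {self.category!r}")
        if (self.confidence is None) != (self.category == "no-call"):
            raise ValueError("confidence must be null exactly for no-call")


# ---------------------------------------------------------------------------
# dialects: map file headers onto MutationRecord fields

#: default column mapping for the native TSV layout
DEFAULT_DIALECT: dict[str, str] = {
    "mutation_id": "mutation_id",
    "gene": "gene",
    "chrom": "chrom",
    "pos": "pos",
    "ref_allele": "ref_allele",
    "alt_allele": "alt_allele",
    "sample_id": "sample_id",
    "mutation_class": "mutation_class",
    "sample_type": "sample_type",
    "protein_change": "protein_change",
    "source": "source",
    "cancer_type": "cancer_type",
}

#: MAF-style headers (TCGA Mutation Annotation Format)
MAF_DIALECT: dict[str, str] = {
    "mutation_id": "Mutation_ID",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "sample_id": "Tumor_Sample_Barcode",
    "mutation_class": "Variant_Classification",
    "sample_type": "Sample_Type",
    "protein_change": "Protein_Change",
    "source": "Center",
    "cancer_type": "Cancer_Type",
}

REQUIRED_FIELDS = (
    "mutation_id",
    "gene",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "sample_id",
)

#: common external spellings of mutation classes, normalized on load
_CLASS_ALIASES: dict[str, str] = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "nonstop_mutation": "nonstop",
    "nonstop": "nonstop",
    "splice_site": "splice_site",
    "splice_site_mutation": "splice_site",
    "translation_start_site": "translation_start",
    "translation_start": "translation_start",
    "frame_shift_del": "indel",
    "frame_shift_ins": "indel",
    "in_frame_del": "indel",
    "in_frame_ins": "indel",
    "indel": "indel",
    "dnp": "dinucleotide",
    "dinucleotide": "dinucleotide",
    "tnp": "trinucleotide",
    "trinucleotide": "trinucleotide",
}

_SAMPLE_TYPE_ALIASES: dict[str, str] = {
    "primary_tumor": "primary_tumor",
    "primary": "primary_tumor",
    "tumor": "primary_tumor",
    "cell_line": "cell_line",
    "cellline": "cell_line",
}


def load_dialect(path: str | Path) -> dict[str, str]:
    """Load a column-mapping dialect from YAML ({field: column-name})."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise CatalogFormatError(f"dialect file {path} must be a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_catalog(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> MutationCatalog:
    """Read a MAF-like TSV into a :class:`MutationCatalog`.

    ``dialect`` maps MutationRecord field names to column headers; defaults
    to the native layout.  Rows whose mutation class has no known mapping
    become class ``"other"``; row count is preserved.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for fld in REQUIRED_FIELDS:
            col = dialect.get(fld, fld)
            if col not in header:
                raise CatalogFormatError(
                    f"{path}: missing required column {col!r} (field {fld!r})"
                )
        records = []
        for lineno, row in enumerate(reader, start=2):
            records.append(_row_to_record(row, dialect, path, lineno))
    return MutationCatalog(records)


def _row_to_record(
    row: Mapping[str, str], dialect: Mapping[str, str], path: Path, lineno: int
) -> MutationRecord:
    def get(fld: str, default: str = "") -> str:
        col = dialect.get(fld, fld)
        val = row.get(col)
        return default if val is None else val.strip()

    pos_raw = get("pos")
    try:
        pos = int(pos_raw)
    except ValueError:
        raise CatalogFormatError(
            f"{path}:{lineno}: non-integer position {pos_raw!r}"
        ) from None
    mut_class = _CLASS_ALIASES.get(get("mutation_class").lower(), "other")
    sample_type = _SAMPLE_TYPE_ALIASES.get(get("sample_type").lower(), "other")
    protein_change = get("protein_change") or None
    try:
        return MutationRecord(
            mutation_id=get("mutation_id"),
            gene=get("gene").upper(),
            chrom=get("chrom"),
            pos=pos,
            ref_allele=get("ref_allele"),
            alt_allele=get("alt_allele"),
            sample_id=get("sample_id"),
            mutation_class=mut_class,
            sample_type=sample_type,
            protein_change=protein_change,
            source=get("source"),
            cancer_type=get("cancer_type"),
        )
    except ValueError as exc:
        raise CatalogFormatError(f"{path}:{lineno}: {exc}") from None


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalog back to the native TSV layout (round-trips read_catalog)."""
    cols = list(DEFAULT_DIALECT)
    rows = [
        {
            "mutation_id": r.mutation_id,
            "gene": r.gene,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref_allele": r.ref_allele,
            "alt_allele": r.alt_allele,
            "sample_id": r.sample_id,
            "mutation_class": r.mutation_class,
            "sample_type": r.sample_type,
            "protein_change": r.protein_change or "",
            "source": r.source,
            "cancer_type": r.cancer_type,
        }
        for r in catalog
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_blacklist(path: str | Path) -> SiteBlacklist:
    """Read a site blacklist from BED (0-based half-open) or 2-column TSV (1-based).

    Files ending in ``.bed`` are treated as BED; anything else as a
    chrom<TAB>pos site list.  A BED line ``chr1 99 100`` yields site
    (chr1, 100); a TSV line ``chr1 100`` yields the same site.
    """
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if is_bed:
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    if start < 0 or end < start:
                        raise ValueError("negative or inverted interval")
                    sites.update((chrom, p) for p in range(start + 1, end + 1))
                else:
                    chrom, pos = parts[0], int(parts[1])
                    if pos < 1:
                        raise ValueError("position must be >= 1")
                    sites.add((chrom, pos))
            except (IndexError, ValueError) as exc:
                raise CatalogFormatError(f"{path}:{lineno}: {exc}") from None
    return SiteBlacklist(frozenset(sites), label=path.stem)


def read_gene_list(path: str | Path, label: str | None = None) -> GeneList:
    """Read a one-gene-per-line list; symbols are upper-cased, duplicates collapse."""
    path = Path(path)
    with open(path) as fh:
        symbols = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return GeneList.from_symbols(symbols, label=label or path.stem)


CALL_COLUMNS = ("mutation_id", "score", "category", "confidence")


def write_calls(calls: Sequence[DriverCall], path: str | Path) -> None:
    """Write driver calls as TSV; confidence is empty for no-call rows."""
    rows = [
        {
            "mutation_id": c.mutation_id,
            "score": f"{c.score:.6f}",
            "category": c.category,
            "confidence": "" if c.confidence is None else f"{c.confidence:.6f}",
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=list(CALL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[DriverCall]:
    """Read a calls TSV written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str})
    for col in CALL_COLUMNS:
        if col not in df.columns:
            raise CatalogFormatError(f"{path}: missing column {col!r}")
    calls = []
    for _, row in df.iterrows():
        conf = row["confidence"]
        conf = None if pd.isna(conf) else float(conf)
        calls.append(
            DriverCall(
                mutation_id=str(row["mutation_id"]),
                score=float(row["score"]),
                category=str(row["category"]),
                confidence=conf,
            )
        )
    return calls
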