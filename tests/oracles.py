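"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by exhaustive O(n^2) loops or direct
pair counting, sharing no code with the library implementations.
"""

from drivercall import MutationCatalog, MutationRecord


def oracle_expanded_drivers(catalog, cancer_type, cfg):
    """Pairwise-loop re-derivation of the expanded driver rules."""
    records = list(catalog)
    target_genes = {
        r.gene for r in records if not cancer_type or r.cancer_type == cancer_type
    }
    groups = {}
    for r in records:
        if r.mutation_class == "missense":
            groups.setdefault(r.variant_key, []).append(r)
    half = cfg.hotspot_window_bp // 2
    out = []
    for (chrom, pos, ref, alt), recs in groups.items():
        if recs[0].gene not in target_genes:
            continue
        primary = {r.sample_id for r in recs if r.sample_type == "primary_tumor"}
        rule1 = len(primary) >= cfg.expanded_driver_min_samples
        rule2 = (
            sum(1 for r in records if r.chrom == chrom and r.pos == pos)
            >= cfg.site_intersect_min
        )
        rule3 = (
            sum(
                1
                for r in records
                if r.chrom == chrom and abs(r.pos - pos) <= half
            )
            >= cfg.hotspot_min_mutations
        )
        if rule1 or rule2 or rule3:
            out.append(min(r.mutation_id for r in recs))
    return sorted(out)


def oracle_expanded_passengers(catalog, cancer_type, cancer_genes, cfg):
    """Pairwise-loop re-derivation of the isolated-singleton passenger rule."""
    records = list(catalog)
    half = cfg.passenger_isolation_window_bp // 2
    groups = {}
    for r in records:
        if (
            r.mutation_class == "missense"
            and r.sample_type == "primary_tumor"
            and (not cancer_type or r.cancer_type == cancer_type)
        ):
            groups.setdefault(r.variant_key, []).append(r)
    out = []
    for (chrom, pos, ref, alt), recs in groups.items():
        if len(recs) != 1:
            continue
        if recs[0].gene in cancer_genes:
            continue
        n_window = sum(
            1 for r in records if r.chrom == chrom and abs(r.pos - pos) <= half
        )
        if n_window > 1:
            continue
        out.append(recs[0].mutation_id)
    return sorted(out)


def random_catalog(rng, n_records, n_genes=6, span=2000, cancer_types=("GBM", "OVC")):
    """A dense random catalog that frequently triggers the window rules."""
    classes = [
        "missense",
        "missense",
        "missense",
        "indel",
        "nonsense",
        "dinucleotide",
    ]
    # genes occupy disjoint blocks so gene and position stay consistent
    gene_of_block = [f"G{j}" for j in range(n_genes)]
    records = []
    for i in range(n_records):
        block = int(rng.integers(n_genes))
        pos = int(block * span + 1 + rng.integers(span))
        records.append(
            MutationRecord(
                mutation_id=f"r{i:04d}",
                gene=gene_of_block[block],
                chrom=f"chr{int(rng.integers(2)) + 1}",
                pos=pos,
                ref_allele="ACGT"[int(rng.integers(4))],
                alt_allele="TGCA"[int(rng.integers(4))],
                sample_id=f"S{int(rng.integers(max(3, n_records // 4)))}",
                mutation_class=classes[int(rng.integers(len(classes)))],
                sample_type="primary_tumor"
                if rng.random() < 0.8
                else "cell_line",
                cancer_type=cancer_types[int(rng.integers(len(cancer_types)))],
            )
        )
    return MutationCatalog(records)


def oracle_hypergeom_tail(N, K, n, k):
    """Exact upper-tail hypergeometric by direct enumeration (small N)."""
    from math import comb

    denom = comb(N, K)
    return sum(
        comb(n, j) * comb(N - n, K - j)
        for j in range(k, min(n, K) + 1)
        if K - j <= N - n
    ) / denom
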