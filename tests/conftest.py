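import pandas as pd
import pytest

from drivercall import FeatureTable, MutationRecord


def make_record(
    mutation_id,
    gene="GENE1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    sample_id="S1",
    mutation_class="missense",
    sample_type="primary_tumor",
    cancer_type="GBM",
    **kw,
):
    return MutationRecord(
        mutation_id=mutation_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        sample_id=sample_id,
        mutation_class=mutation_class,
        sample_type=sample_type,
        cancer_type=cancer_type,
        **kw,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_table():
    """6 mutations x 3 features, no missing values."""
    values = pd.DataFrame(
        {
            "condel": [0.9, 0.8, 0.7, 0.2, 0.1, 0.3],
            "entropy": [2.0, 1.5, 1.8, 0.5, 0.2, 0.4],
            "domain_flag": [1.0, 1.0, 0.0, 0.0, 0.0, 1.0],
        },
        index=[f"m{i}" for i in range(6)],
    )
    return FeatureTable(values, {"domain_flag": "binary"})


@pytest.fixture
def small_labels():
    return pd.Series([1, 1, 1, 0, 0, 0], index=[f"m{i}" for i in range(6)])


def brute_force_auc(pos, neg):
    """Independent pair-counting oracle for the rank-sum AUC."""
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture
def auc_oracle():
    return brute_force_auc
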