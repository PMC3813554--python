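"""Evaluation statistics: ROC/recall, score-prevalence correlation,
hypergeometric enrichment of predicted drivers, and matched-vs-mismatched
model score comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, pearsonr

from .catalog import DriverCall, MutationCatalog
from .selection import feature_auc, mann_whitney_p


@dataclass(frozen=True)
class EvalResult:
    auc: float | None
    n_driver_calls_in_truth: int
    n_true_drivers: int

    @property
    def recall(self) -> float:
        return self.n_driver_calls_in_truth / self.n_true_drivers


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for the upper-tail hypergeometric enrichment test.

    N rare mutations overall, K of them predicted drivers; n rare
    mutations fall in the gene panel, k of those predicted drivers.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"inconsistent counts N={self.N} K={self.K} n={self.n} k={self.k}"
            )


def roc_auc_and_recall(
    calls: Sequence[DriverCall], truth_labels: Mapping[str, int]
) -> EvalResult:
    """AUC of scores against binary truth, and driver-call recall.

    Recall counts mutations categorized "driver" among the true drivers.
    With single-class truth the AUC is undefined (None) but recall still
    computes when drivers are present.
    """
    truth = dict(truth_labels)
    scored = [(c, truth[c.mutation_id]) for c in calls if c.mutation_id in truth]
    if not scored:
        raise ValueError("no overlap between calls and truth labels")
    pos = [c.score for c, y in scored if y == 1]
    neg = [c.score for c, y in scored if y == 0]
    auc = feature_auc(pos, neg) if pos and neg else None
    n_true = len(pos)
    if n_true == 0:
        raise ValueError("truth contains no drivers; recall undefined")
    n_called = sum(1 for c, y in scored if y == 1 and c.category == "driver")
    return EvalResult(auc=auc, n_driver_calls_in_truth=n_called, n_true_drivers=n_true)


def prevalence_correlation(
    prevalence: Sequence[float], scores: Sequence[float]
) -> float:
    """Pearson r between observed mutation prevalence and mutation scores.

    Prevalence — how often a mutation recurs in a cancer type — is a
    strong empirical indicator of driver function, so a better scorer
    should correlate more strongly with it.
    """
    x = np.asarray(prevalence, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant axis")
    return float(pearsonr(x, y).statistic)


def enrichment_pvalue(e: EnrichmentInput) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for panel driver count.

    X ~ Hypergeom(population N, panel size n, draws K); equivalently
    p = sum_{j>=k} C(n,j) C(N-n,K-j) / C(N,K).
    """
    return float(hypergeom.sf(e.k - 1, e.N, e.n, e.K))


def compare_score_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney p for two score groups (shared U engine)."""
    return mann_whitney_p(scores_a, scores_b)


def rare_mutations(
    catalog: MutationCatalog,
    cancer_type: str = "",
    vicinity_bp: int = 3,
    used_ids: Sequence[str] = (),
) -> list[str]:
    """Low-prevalence, non-hotspot missense mutations.

    Returns ids of missense mutations of the target cancer type reported
    exactly once, with no other catalog record within ``vicinity_bp`` of
    their site, excluding ``used_ids`` (e.g. training/test examples).
    """
    used = set(used_ids)
    records = [
        r
        for r in catalog
        if r.mutation_class == "missense"
        and (not cancer_type or r.cancer_type == cancer_type)
    ]
    from collections import Counter, defaultdict

    variant_counts = Counter(r.variant_key for r in records)
    by_chrom: defaultdict[str, list[int]] = defaultdict(list)
    for r in catalog:
        by_chrom[r.chrom].append(r.pos)
    for ps in by_chrom.values():
        ps.sort()
    from bisect import bisect_left, bisect_right

    out = []
    for r in records:
        if r.mutation_id in used:
            continue
        if variant_counts[r.variant_key] != 1:
            continue
        ps = by_chrom[r.chrom]
        n_near = bisect_right(ps, r.pos + vicinity_bp) - bisect_left(
            ps, r.pos - vicinity_bp
        )
        if n_near > 1:  # anything besides the record itself
            continue
        out.append(r.mutation_id)
    return sorted(out)
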