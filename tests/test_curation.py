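import numpy as np
import pytest

from drivercall import (
    CurationConfig,
    GeneList,
    MutationCatalog,
    SiteBlacklist,
    curate_expanded,
    curate_stringent,
    expanded_drivers,
    expanded_passengers,
    stringent_drivers,
    stringent_passengers,
)
from oracles import (
    oracle_expanded_drivers,
    oracle_expanded_passengers,
    random_catalog,
)

EMPTY_BL = SiteBlacklist()
NO_GENES = GeneList()
CFG = CurationConfig()


class TestStringentDrivers:
    def test_recurrent_in_two_samples_included(self, record_factory):
        cat = MutationCatalog(
            [
                record_factory("m1", sample_id="A"),
                record_factory("m2", sample_id="B"),
            ]
        )
        assert stringent_drivers(cat, EMPTY_BL, CFG) == ["m1"]

    def test_confounding_nonsense_in_same_gene_same_sample_excludes(
        self, record_factory
    ):
        cat = MutationCatalog(
            [
                record_factory("m1", sample_id="A"),
                record_factory("m2", sample_id="B"),
                record_factory(
                    "m3", sample_id="A", pos=500, mutation_class="nonsense"
                ),
            ]
        )
        assert stringent_drivers(cat, EMPTY_BL, CFG) == []

    def test_confounder_in_other_gene_does_not_exclude(self, record_factory):
        cat = MutationCatalog(
            [
                record_factory("m1", sample_id="A"),
                record_factory("m2", sample_id="B"),
                record_factory(
                    "m3", gene="OTHER", sample_id="A", pos=99999, mutation_class="indel"
                ),
            ]
        )
        assert stringent_drivers(cat, EMPTY_BL, CFG) == ["m1"]

    def test_singleton_excluded(self, record_factory):
        cat = MutationCatalog([record_factory("m1")])
        assert stringent_drivers(cat, EMPTY_BL, CFG) == []

    def test_blacklisted_site_excluded(self, record_factory):
        cat = MutationCatalog(
            [
                record_factory("m1", sample_id="A"),
                record_factory("m2", sample_id="B"),
            ]
        )
        bl = SiteBlacklist(frozenset({("chr1", 100)}))
        assert stringent_drivers(cat, bl, CFG) == []


class TestStringentPassengers:
    def _hyper_sample(self, record_factory, n_missense, sample="H1", gene="GENE1"):
        return [
            record_factory(
                f"h{i}", gene=gene, pos=1000 + 50 * i, sample_id=sample
            )
            for i in range(n_missense)
        ]

    def test_sample_above_threshold_contributes(self, record_factory):
        cfg = CurationConfig(hypermutated_min_missense=55)
        cat = MutationCatalog(self._hyper_sample(record_factory, 56))
        assert len(stringent_passengers(cat, EMPTY_BL, NO_GENES, cfg)) == 56

    def test_sample_at_threshold_contributes_nothing(self, record_factory):
        cfg = CurationConfig(hypermutated_min_missense=55)
        cat = MutationCatalog(self._hyper_sample(record_factory, 55))
        assert stringent_passengers(cat, EMPTY_BL, NO_GENES, cfg) == []

    def test_census_gene_mutations_excluded(self, record_factory):
        cfg = CurationConfig(hypermutated_min_missense=5)
        recs = self._hyper_sample(record_factory, 6, gene="TP53")
        cat = MutationCatalog(recs)
        census = GeneList.from_symbols(["TP53"])
        assert stringent_passengers(cat, EMPTY_BL, census, cfg) == []

    def test_low_mutation_sample_contributes_nothing(self, record_factory):
        cfg = CurationConfig(hypermutated_min_missense=55)
        cat = MutationCatalog(self._hyper_sample(record_factory, 10))
        assert stringent_passengers(cat, EMPTY_BL, NO_GENES, cfg) == []


class TestExpandedDrivers:
    def test_rule1_cross_cancer_recurrence(self, record_factory):
        # variant recurrent in 3 primary samples of ANOTHER cancer type,
        # but its gene is mutated in the target type
        cat = MutationCatalog(
            [
                record_factory("m1", sample_id="A", cancer_type="OVC"),
                record_factory("m2", sample_id="B", cancer_type="OVC"),
                record_factory("m3", sample_id="C", cancer_type="OVC"),
                record_factory("m4", pos=900, sample_id="D", cancer_type="GBM"),
            ]
        )
        assert "m1" in expanded_drivers(cat, "GBM", CFG)

    def test_rule1_requires_primary_tumor_samples(self, record_factory):
        cat = MutationCatalog(
            [
                record_factory("m1", sample_id="A", sample_type="cell_line"),
                record_factory("m2", sample_id="B", sample_type="cell_line"),
                record_factory("m3", sample_id="C", sample_type="cell_line"),
            ]
        )
        assert expanded_drivers(cat, "GBM", CFG) == []

    def test_rule2_site_shared_with_indels(self, record_factory):
        recs = [record_factory("m1", sample_id="A")]
        recs += [
            record_factory(
                f"i{j}", sample_id=f"S{j}", mutation_class="indel", ref="AT", alt="A"
            )
            for j in range(3)
        ]
        cat = MutationCatalog(recs)
        assert expanded_drivers(cat, "GBM", CFG) == ["m1"]

    def test_rule3_hotspot_window(self, record_factory):
        # five records inside pos +/- 12 of the center
        offsets = (-12, -6, 0, 6, 12)
        recs = [
            record_factory(
                f"m{j}", pos=1000 + off, sample_id=f"S{j}", ref="ACGTA"[j]
            )
            for j, off in enumerate(offsets)
        ]
        cat = MutationCatalog(recs)
        out = expanded_drivers(cat, "GBM", CFG)
        assert "m2" in out  # the centered mutation qualifies
        assert "m0" not in out and "m4" not in out  # edges see only 3 records

    def test_isolated_singleton_fails_all_rules(self, record_factory):
        cat = MutationCatalog([record_factory("m1")])
        assert expanded_drivers(cat, "GBM", CFG) == []

    def test_monotone_adding_records_never_removes(self, record_factory):
        rng = np.random.default_rng(5)
        cat = random_catalog(rng, 120)
        before = set(expanded_drivers(cat, "GBM", CFG))
        extra = random_catalog(rng, 30)
        grown = MutationCatalog(
            list(cat)
            + [
                type(r)(**{**r.__dict__, "mutation_id": f"x{r.mutation_id}"})
                for r in extra
            ]
        )
        after = set(expanded_drivers(grown, "GBM", CFG))
        assert before <= after


class TestExpandedPassengers:
    def test_isolated_singleton_included(self, record_factory):
        cat = MutationCatalog(
            [
                record_factory("m1", pos=1000),
                record_factory("m2", pos=1020, sample_id="S2", ref="C"),
            ]
        )
        # 20 bp apart: each is outside the other's +/-15 window? no: 20 > 15
        out = expanded_passengers(cat, "GBM", NO_GENES, CFG)
        assert out == ["m1", "m2"]

    def test_neighbor_within_window_excludes(self, record_factory):
        cat = MutationCatalog(
            [
                record_factory("m1", pos=1000),
                record_factory("m2", pos=1010, sample_id="S2", ref="C"),
            ]
        )
        assert expanded_passengers(cat, "GBM", NO_GENES, CFG) == []

    def test_non_singleton_excluded(self, record_factory):
        cat = MutationCatalog(
            [
                record_factory("m1", sample_id="A"),
                record_factory("m2", sample_id="B"),
            ]
        )
        assert expanded_passengers(cat, "GBM", NO_GENES, CFG) == []

    def test_census_gene_excluded(self, record_factory):
        cat = MutationCatalog([record_factory("m1", gene="TP53")])
        census = GeneList.from_symbols(["TP53"])
        assert expanded_passengers(cat, "GBM", census, CFG) == []

    def test_adding_records_only_shrinks(self, record_factory):
        rng = np.random.default_rng(6)
        cat = random_catalog(rng, 120)
        before = set(expanded_passengers(cat, "GBM", NO_GENES, CFG))
        extra = random_catalog(rng, 30)
        grown = MutationCatalog(
            list(cat)
            + [
                type(r)(**{**r.__dict__, "mutation_id": f"x{r.mutation_id}"})
                for r in extra
            ]
        )
        after = set(expanded_passengers(grown, "GBM", NO_GENES, CFG))
        # restricted to the original records: new isolated singletons may
        # join, but no existing passenger is ever created by adding records
        assert {m for m in after if not m.startswith("x")} <= before


class TestWindowOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_catalogs(self, seed):
        rng = np.random.default_rng(seed)
        cat = random_catalog(rng, int(rng.integers(50, 300)))
        census = GeneList.from_symbols(["G0"])
        assert expanded_drivers(cat, "GBM", CFG) == oracle_expanded_drivers(
            cat, "GBM", CFG
        )
        assert expanded_passengers(
            cat, "GBM", census, CFG
        ) == oracle_expanded_passengers(cat, "GBM", census, CFG)


class TestLabeledSets:
    def test_sets_mutually_disjoint(self, record_factory):
        rng = np.random.default_rng(11)
        cat = random_catalog(rng, 250)
        census = GeneList.from_symbols(["G1"])
        cfg = CurationConfig(hypermutated_min_missense=5)
        s = curate_stringent(cat, EMPTY_BL, census, cfg, cancer_type="GBM")
        e = curate_expanded(cat, "GBM", census, cfg, stringent=s)
        groups = [s.drivers, s.passengers, e.drivers, e.passengers]
        all_ids = [m for g in groups for m in g]
        assert len(all_ids) == len(set(all_ids))
        # subtraction is by variant, not just id
        assert not (s.driver_variants & e.driver_variants)
        assert not (s.passenger_variants & e.passenger_variants)

    def test_window_config_validation(self):
        with pytest.raises(ValueError):
            CurationConfig(hotspot_window_bp=24)
        with pytest.raises(ValueError):
            CurationConfig(stringent_min_samples=0)
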