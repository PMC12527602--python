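import pytest

from cohortmatch.models import (
    Cohort,
    GeneModel,
    GeneModelSet,
    Participant,
    Sex,
    UnknownGeneError,
    ValidationError,
    Variant,
    VariantOccurrence,
    VOStore,
    Zygosity,
)
from cohortmatch.query import (
    GeneQuery,
    check_gene_size,
    cohort_allele_frequency,
    consolidate,
    merge_results,
    query_gene,
)


def make_cohort(n=10, sexes=None):
    ps = []
    for i in range(n):
        sex = sexes[i] if sexes else Sex.FEMALE
        ps.append(Participant(f"P{i}", f"F{i}", sex=sex))
    return Cohort(ps)


GENE = GeneModel("G1", "1", "+", 1000, 2000, ((1100, 1200),))
MODELS = GeneModelSet([GENE, GeneModel("G2", "2", "+", 1, 500, ())])


class TestGeneQueryConfig:
    def test_af_cap_hard_maximum(self):
        GeneQuery("G1", max_cohort_af=0.05)  # boundary allowed
        with pytest.raises(ValidationError, match="0.05"):
            GeneQuery("G1", max_cohort_af=0.1)
        with pytest.raises(ValidationError):
            GeneQuery("G1", max_cohort_af=0.0)


class TestGeneSizeGuard:
    @pytest.mark.parametrize(
        "span,ok",
        [(150_000, True), (200_000, False), (10, True)],
    )
    def test_warn_at_limit(self, span, ok):
        m = GeneModel("G", "1", "+", 1, span)
        if ok:
            assert check_gene_size(m) is True
        else:
            with pytest.warns(UserWarning, match="bp"):
                assert check_gene_size(m) is False


class TestCohortAlleleFrequency:
    def test_autosomal_het_one_of_ten(self):
        v = Variant("1", 1500, "A", "G")
        store = VOStore([VariantOccurrence(v, "P0", Zygosity.HET)])
        assert cohort_allele_frequency(v, store, make_cohort(10)) == pytest.approx(0.05)

    def test_absent_variant_is_zero(self):
        v = Variant("1", 1500, "A", "G")
        assert cohort_allele_frequency(v, VOStore(), make_cohort(10)) == 0.0

    def test_hom_counts_twice(self):
        v = Variant("1", 1500, "A", "G")
        store = VOStore([VariantOccurrence(v, "P0", Zygosity.HOM)])
        assert cohort_allele_frequency(v, store, make_cohort(10)) == pytest.approx(0.1)

    def test_x_hemi_denominator(self):
        sexes = [Sex.MALE] * 5 + [Sex.FEMALE] * 5
        cohort = make_cohort(10, sexes)
        v = Variant("X", 100, "C", "T")
        store = VOStore([VariantOccurrence(v, "P0", Zygosity.HEMI)])
        assert cohort_allele_frequency(v, store, cohort) == pytest.approx(1 / 15)


class TestQueryGene:
    def test_unknown_gene_suggests_symbols(self):
        with pytest.raises(UnknownGeneError, match="nearest"):
            query_gene(GeneQuery("G9"), VOStore(), make_cohort(3), MODELS)

    def test_empty_store_empty_result(self):
        res = query_gene(GeneQuery("G1"), VOStore(), make_cohort(3), MODELS)
        assert res.rows == [] and res.burden == {}

    def test_af_cap_excludes_common_variant(self):
        v = Variant("1", 1500, "A", "G")
        store = VOStore(
            [VariantOccurrence(v, f"P{i}", Zygosity.HET) for i in range(3)]
        )
        cohort = make_cohort(10)  # AF = 3/20 = 0.15 > 0.05
        res = query_gene(GeneQuery("G1", max_cohort_af=0.05), store, cohort, MODELS)
        assert res.rows == []

    def test_burden_counts_vos_per_participant(self):
        store = VOStore(
            [
                VariantOccurrence(Variant("1", 1500, "A", "G"), "P0", Zygosity.HET),
                VariantOccurrence(Variant("1", 1600, "C", "T"), "P0", Zygosity.HET),
                VariantOccurrence(Variant("1", 1600, "C", "T"), "P1", Zygosity.HET),
            ]
        )
        res = query_gene(GeneQuery("G1", max_cohort_af=0.05), store, make_cohort(30), MODELS)
        assert res.burden == {"P0": 2, "P1": 1}
        assert all(r.burden == res.burden[r.participant_id] for r in res.rows)

    def test_out_of_span_variants_excluded(self):
        store = VOStore(
            [VariantOccurrence(Variant("1", 999, "A", "G"), "P0", Zygosity.HET)]
        )
        res = query_gene(GeneQuery("G1"), store, make_cohort(30), MODELS)
        assert res.rows == []

    def test_count_consistency_per_variant(self, standard_bundle):
        b = standard_bundle
        for gene in sorted(b.hypotheses)[:5]:
            res = query_gene(GeneQuery(gene), b.store, b.cohort, b.models)
            by_variant = {}
            for r in res.rows:
                by_variant[r.variant] = by_variant.get(r.variant, 0) + 1
            for v, (n_het, n_hom, n_hemi) in res.per_variant_counts.items():
                assert n_het + n_hom + n_hemi == by_variant[v]

    def test_af_cap_monotonicity(self, standard_bundle):
        b = standard_bundle
        for gene in sorted(b.hypotheses)[:5]:
            keys = {}
            for cap in (0.005, 0.01, 0.05):
                res = query_gene(GeneQuery(gene, max_cohort_af=cap), b.store, b.cohort, b.models)
                keys[cap] = {(r.variant.key(), r.participant_id) for r in res.rows}
            assert keys[0.005] <= keys[0.01] <= keys[0.05]


class TestConsolidate:
    def test_conservation(self):
        store = VOStore(
            [
                VariantOccurrence(Variant("1", 1500, "A", "G"), f"P{i}", Zygosity.HET)
                for i in range(3)
            ]
            + [
                VariantOccurrence(Variant("1", 1600, "C", "T"), f"P{i}", Zygosity.HOM)
                for i in range(2)
            ]
        )
        res = query_gene(GeneQuery("G1", max_cohort_af=0.05), store, make_cohort(50), MODELS)
        view = consolidate(res)
        assert len(view) == 2
        assert sum(r.n_occurrences for r in view) == len(res.rows) == 5
        assert {r.variant.pos: (r.n_het, r.n_hom) for r in view} == {
            1500: (3, 0),
            1600: (0, 2),
        }

    def test_consolidation_conserves_on_synthetic_genes(self, standard_bundle):
        b = standard_bundle
        for gene in sorted(b.hypotheses):
            res = query_gene(GeneQuery(gene), b.store, b.cohort, b.models)
            view = consolidate(res)
            assert sum(r.n_occurrences for r in view) == len(res.rows)
            assert len(view) == len({r.variant for r in res.rows})


class TestMergeResults:
    def _single_result(self, pid):
        v = Variant("1", 1500, "A", "G")
        store = VOStore([VariantOccurrence(v, pid, Zygosity.HET)])
        cohort = Cohort([Participant(pid, "F1")] + [Participant(f"Q{i}", "F2") for i in range(9)])
        return query_gene(GeneQuery("G1", max_cohort_af=0.05), store, cohort, MODELS)

    def test_counts_sum_across_stores(self):
        merged = merge_results(
            [self._single_result("P1"), self._single_result("P1")], labels=["a", "b"]
        )
        v = Variant("1", 1500, "A", "G")
        assert merged.per_variant_counts[v] == (2, 0, 0)
        assert {r.participant_id for r in merged.rows} == {"a:P1", "b:P1"}

    def test_merge_single_is_identity(self):
        res = self._single_result("P1")
        merged = merge_results([res])
        assert [(r.vo.sort_key()) for r in merged.rows] == [
            (r.vo.sort_key()) for r in res.rows
        ]

    def test_collision_without_labels_rejected(self):
        from cohortmatch.models import CohortmatchError

        with pytest.raises(CohortmatchError, match="namespace"):
            merge_results([self._single_result("P1"), self._single_result("P1")])

    def test_merge_order_irrelevant(self):
        a, b = self._single_result("P1"), self._single_result("P2")
        m1 = merge_results([a, b], labels=["x", "y"])
        m2 = merge_results([b, a], labels=["y", "x"])
        assert {r.vo.sort_key() for r in m1.rows} == {r.vo.sort_key() for r in m2.rows}
        assert m1.per_variant_counts == m2.per_variant_counts
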