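import pytest

from cohortmatch.models import (
    AffectedStatus,
    AnnotatedVO,
    Cohort,
    CohortmatchError,
    ConsequenceClass,
    Inheritance,
    Participant,
    Sex,
    ValidationError,
    Variant,
    VariantOccurrence,
    Zygosity,
)
from cohortmatch.workflow import (
    AdUnaffectedTrigger,
    MissingSplicePolicy,
    WorkflowConfig,
    filter_affected_status,
    filter_consequence,
    filter_gnomad_het,
    filter_gnomad_hom,
    filter_phenotype,
    filter_zygosity,
    run_workflow,
)

E = ConsequenceClass.EXONIC
L = ConsequenceClass.LOW_IMPACT
I = ConsequenceClass.INCONCLUSIVE


def row(
    pos=100,
    pid="P1",
    zyg=Zygosity.HET,
    consequence=E,
    splice=None,
    n_hom=None,
    n_het=None,
    control_af=None,
    sex=Sex.FEMALE,
    affected=AffectedStatus.AFFECTED,
    hpo=frozenset(),
    chrom="1",
):
    return AnnotatedVO(
        vo=VariantOccurrence(Variant(chrom, pos, "A", "G"), pid, zyg),
        consequence=consequence,
        splice_score=splice,
        control_n_hom=n_hom,
        control_n_het=n_het,
        control_af=control_af,
        sex=sex,
        affected=affected,
        hpo_terms=hpo,
    )


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence,splice,policy,kept",
        [
            (L, 0.6, MissingSplicePolicy.TREAT_AS_ZERO, True),   # splice rescue
            (L, 0.4, MissingSplicePolicy.TREAT_AS_ZERO, False),
            (L, None, MissingSplicePolicy.TREAT_AS_ZERO, False),  # no prediction, no rescue
            (L, None, MissingSplicePolicy.BYPASS, True),
            (I, None, MissingSplicePolicy.TREAT_AS_ZERO, True),   # inconclusive bypasses
            (E, 0.0, MissingSplicePolicy.TREAT_AS_ZERO, True),    # only low-impact filtered
        ],
    )
    def test_low_impact_removed_unless_splice_rescued(self, consequence, splice, policy, kept):
        r = row(consequence=consequence, splice=splice)
        kept_rows, removed_rows = filter_consequence([r], 0.5, policy)
        assert (r in kept_rows) is kept
        assert len(kept_rows) + len(removed_rows) == 1

    def test_threshold_boundary_is_inclusive_keep(self):
        kept, _ = filter_consequence([row(consequence=L, splice=0.5)], 0.5)
        assert len(kept) == 1


class TestGnomadHomFilter:
    @pytest.mark.parametrize(
        "n_hom,control_af,kept",
        [(1, None, False), (0, 0.04, True), (None, None, True)],
    )
    def test_hom_in_controls_removed(self, n_hom, control_af, kept):
        r = row(n_hom=n_hom, control_af=control_af)
        kept_rows, _ = filter_gnomad_hom([r])
        assert (r in kept_rows) is kept


class TestZygosityFilter:
    def test_ad_keeps_het_only(self):
        het, hom = row(zyg=Zygosity.HET), row(pos=200, zyg=Zygosity.HOM)
        kept, removed = filter_zygosity([het, hom], Inheritance.AD)
        assert kept == [het] and removed == [hom]

    def test_ar_single_het_removed_pair_kept(self):
        single = row(pos=100, pid="P1")
        pair = [row(pos=200, pid="P2"), row(pos=300, pid="P2")]
        kept, removed = filter_zygosity([single] + pair, Inheritance.AR)
        assert removed == [single] and kept == pair

    def test_ar_keeps_hom(self):
        hom = row(zyg=Zygosity.HOM)
        kept, _ = filter_zygosity([hom], Inheritance.AR)
        assert kept == [hom]

    def test_xlr_rules(self):
        hemi_m = row(pos=1, pid="M1", zyg=Zygosity.HEMI, sex=Sex.MALE, chrom="X")
        hom_f = row(pos=2, pid="W1", zyg=Zygosity.HOM, sex=Sex.FEMALE, chrom="X")
        het_f_pair = [
            row(pos=3, pid="W2", sex=Sex.FEMALE, chrom="X"),
            row(pos=4, pid="W2", sex=Sex.FEMALE, chrom="X"),
        ]
        het_f_single = row(pos=5, pid="W3", sex=Sex.FEMALE, chrom="X")
        hom_m = row(pos=6, pid="M2", zyg=Zygosity.HOM, sex=Sex.MALE, chrom="X")
        kept, removed = filter_zygosity(
            [hemi_m, hom_f, *het_f_pair, het_f_single, hom_m], Inheritance.XLR
        )
        assert set(map(id, kept)) == set(map(id, [hemi_m, hom_f, *het_f_pair]))
        assert set(map(id, removed)) == set(map(id, [het_f_single, hom_m]))

    def test_comphet_recomputed_after_upstream_removal(self):
        """If one partner of a het pair was removed upstream, the survivor no
        longer qualifies as a potential compound het."""
        survivor = row(pos=200, pid="P2")
        kept, removed = filter_zygosity([survivor], Inheritance.AR)
        assert removed == [survivor]


class TestGnomadHetFilter:
    def _config(self, inheritance=Inheritance.AD, severe=True, relax=None):
        return WorkflowConfig(
            inheritance=inheritance,
            severe_pediatric=severe,
            disease_hpo_terms=frozenset(["HP:0000002"]),
            gnomad_het_relax_af=relax,
        )

    def test_severe_ad_removes_any_control_presence(self):
        r = row(n_het=1, n_hom=0, control_af=3e-5)
        kept, removed = filter_gnomad_het([r], self._config())
        assert removed == [r]

    def test_non_severe_stream_is_identity(self):
        r = row(n_het=5, n_hom=0)
        kept, removed = filter_gnomad_het([r], self._config(Inheritance.AR, severe=False))
        assert kept == [r] and removed == []

    def test_relaxation_keeps_very_rare_control_variants(self):
        r = row(n_het=1, n_hom=0, control_af=5e-5)
        kept, _ = filter_gnomad_het([r], self._config(relax=1e-4))
        assert kept == [r]
        kept2, removed2 = filter_gnomad_het(
            [row(n_het=1, n_hom=0, control_af=5e-4)], self._config(relax=1e-4)
        )
        assert kept2 == []


def cohort_of(rows, statuses):
    seen = {}
    for r in rows:
        seen.setdefault(
            r.participant_id,
            (r.sex, statuses.get(r.participant_id), r.hpo_terms or frozenset(["HP:0000001"])),
        )
    return Cohort(
        [
            Participant(pid, "F1", sex=sex,
                        affected=status or AffectedStatus.UNKNOWN,
                        hpo_terms=terms)
            for pid, (sex, status, terms) in seen.items()
        ]
    )


AFF = AffectedStatus.AFFECTED
UNAFF = AffectedStatus.UNAFFECTED


class TestAffectedStatusFilter:
    def test_ar_hom_in_unaffected_removes_all_hom_rows(self):
        aff = row(pos=100, pid="A1", zyg=Zygosity.HOM)
        unaff = row(pos=100, pid="U1", zyg=Zygosity.HOM, affected=UNAFF)
        cohort = cohort_of([aff, unaff], {"A1": AFF, "U1": UNAFF})
        kept, removed = filter_affected_status(
            [aff, unaff], cohort, Inheritance.AR, reference_rows=[aff, unaff]
        )
        assert kept == [] and len(removed) == 2

    def test_ar_het_carrier_in_unaffected_keeps_hom_rows(self):
        aff = row(pos=100, pid="A1", zyg=Zygosity.HOM)
        unaff = row(pos=100, pid="U1", zyg=Zygosity.HET, affected=UNAFF)
        cohort = cohort_of([aff, unaff], {"A1": AFF, "U1": UNAFF})
        kept, _ = filter_affected_status(
            [aff], cohort, Inheritance.AR, reference_rows=[aff, unaff]
        )
        assert kept == [aff]

    def test_ad_het_in_unaffected_removes_everywhere(self):
        a1 = row(pos=100, pid="A1")
        a2 = row(pos=100, pid="A2")
        u = row(pos=100, pid="U1", affected=UNAFF)
        cohort = cohort_of([a1, a2, u], {"A1": AFF, "A2": AFF, "U1": UNAFF})
        kept, removed = filter_affected_status(
            [a1, a2], cohort, Inheritance.AD, reference_rows=[a1, a2, u]
        )
        assert kept == [] and removed == [a1, a2]

    def test_ad_hom_unaffected_triggers_only_in_any_mode(self):
        a1 = row(pos=100, pid="A1")
        u = row(pos=100, pid="U1", zyg=Zygosity.HOM, affected=UNAFF)
        cohort = cohort_of([a1, u], {"A1": AFF, "U1": UNAFF})
        kept_any, _ = filter_affected_status(
            [a1], cohort, Inheritance.AD, reference_rows=[a1, u],
            ad_trigger=AdUnaffectedTrigger.ANY,
        )
        kept_het, _ = filter_affected_status(
            [a1], cohort, Inheritance.AD, reference_rows=[a1, u],
            ad_trigger=AdUnaffectedTrigger.HET_ONLY,
        )
        assert kept_any == [] and kept_het == [a1]

    def test_no_unaffected_participants_is_identity(self):
        rows = [row(pos=100, pid="A1"), row(pos=200, pid="A2", zyg=Zygosity.HOM)]
        cohort = cohort_of(rows, {"A1": AFF, "A2": AFF})
        kept, removed = filter_affected_status(rows, cohort, Inheritance.AD)
        assert kept == rows and removed == []

    def test_unknown_status_never_triggers(self):
        a1 = row(pos=100, pid="A1")
        u = row(pos=100, pid="U1")  # UNKNOWN status in cohort
        cohort = cohort_of([a1, u], {"A1": AFF})
        kept, _ = filter_affected_status(
            [a1], cohort, Inheritance.AD, reference_rows=[a1, u]
        )
        assert kept == [a1]

    def test_ar_comphet_pair_in_unaffected_removes_set(self):
        pair_a = [row(pos=100, pid="A1"), row(pos=200, pid="A1")]
        pair_u = [
            row(pos=100, pid="U1", affected=UNAFF),
            row(pos=200, pid="U1", affected=UNAFF),
        ]
        cohort = cohort_of(pair_a + pair_u, {"A1": AFF, "U1": UNAFF})
        kept, removed = filter_affected_status(
            pair_a, cohort, Inheritance.AR, reference_rows=pair_a + pair_u
        )
        assert kept == [] and removed == pair_a

    def test_ar_single_shared_het_does_not_disqualify_pair(self):
        pair_a = [row(pos=100, pid="A1"), row(pos=200, pid="A1")]
        shared = row(pos=100, pid="U1", affected=UNAFF)
        cohort = cohort_of(pair_a + [shared], {"A1": AFF, "U1": UNAFF})
        kept, _ = filter_affected_status(
            pair_a, cohort, Inheritance.AR, reference_rows=pair_a + [shared]
        )
        assert kept == pair_a

    def test_xlr_hemi_in_unaffected_male_removes_hemi_rows(self):
        a = row(pos=100, pid="A1", zyg=Zygosity.HEMI, sex=Sex.MALE, chrom="X")
        u = row(pos=100, pid="U1", zyg=Zygosity.HEMI, sex=Sex.MALE,
                affected=UNAFF, chrom="X")
        hom_f = row(pos=200, pid="A2", zyg=Zygosity.HOM, sex=Sex.FEMALE, chrom="X")
        cohort = cohort_of([a, u, hom_f], {"A1": AFF, "U1": UNAFF, "A2": AFF})
        kept, removed = filter_affected_status(
            [a, hom_f], cohort, Inheritance.XLR, reference_rows=[a, u, hom_f]
        )
        assert kept == [hom_f] and removed == [a]


class TestPhenotypeFilter:
    def _setup(self, chain_ontology):
        # disease profile: {B}: closure {A, B}
        config = WorkflowConfig(
            inheritance=Inheritance.AD,
            disease_hpo_terms=frozenset(["HP:0000003"]),
        )
        return config, chain_ontology

    def test_overlapping_participant_kept(self, chain_ontology):
        config, ont = self._setup(chain_ontology)
        r = row(pid="P1", hpo=frozenset(["HP:0000004"]))  # C: closure covers A,B
        cohort = Cohort([Participant("P1", "F1", affected=AFF,
                                     hpo_terms=r.hpo_terms)])
        kept, removed, scores = filter_phenotype([r], cohort, ont, config)
        assert kept == [r] and scores["P1"] == 1.0

    def test_disjoint_participant_removed(self, chain_ontology):
        config, ont = self._setup(chain_ontology)
        r = row(pid="P1", hpo=frozenset(["HP:0000005"]))  # D: closure {A, D}
        cohort = Cohort([Participant("P1", "F1", affected=AFF, hpo_terms=r.hpo_terms)])
        kept, removed, scores = filter_phenotype([r], cohort, ont, config)
        # closure recall = |{A}| / |{A,B}| = 0.5 >= 0.2 -> kept
        assert scores["P1"] == 0.5 and kept == [r]
        strict = WorkflowConfig(
            inheritance=Inheritance.AD,
            disease_hpo_terms=frozenset(["HP:0000003"]),
            phenotype_threshold=0.6,
        )
        kept2, removed2, _ = filter_phenotype([r], cohort, ont, strict)
        assert removed2 == [r]

    def test_participant_without_terms_removed_and_flagged(self, chain_ontology):
        config, ont = self._setup(chain_ontology)
        r = row(pid="P1")
        cohort = Cohort([Participant("P1", "F1", affected=AffectedStatus.UNKNOWN)])
        kept, removed, scores = filter_phenotype([r], cohort, ont, config)
        assert removed == [r] and scores["P1"] is None

    def test_empty_disease_profile_rejected(self, chain_ontology):
        config = WorkflowConfig(inheritance=Inheritance.AD)
        with pytest.raises(ValidationError, match="disease profile"):
            filter_phenotype([], Cohort([Participant("P", "F")]), chain_ontology, config)


class TestRunWorkflow:
    def test_severe_pediatric_requires_ad(self):
        with pytest.raises(ValidationError, match="AD stream"):
            WorkflowConfig(inheritance=Inheritance.AR, severe_pediatric=True)

    def test_xlr_rejects_autosomal_rows(self, chain_ontology):
        config = WorkflowConfig(
            inheritance=Inheritance.XLR,
            disease_hpo_terms=frozenset(["HP:0000002"]),
        )
        rows = [row(chrom="1")]
        with pytest.raises(CohortmatchError, match="X-chromosome"):
            run_workflow(rows, config, cohort_of(rows, {"P1": AFF}), chain_ontology)

    def test_empty_input_all_steps_zero(self, chain_ontology):
        config = WorkflowConfig(
            inheritance=Inheritance.AD, disease_hpo_terms=frozenset(["HP:0000002"])
        )
        out = run_workflow([], config, Cohort([Participant("P", "F")]), chain_ontology)
        assert out.prioritized == []
        assert all(s.n_in == 0 and s.n_removed == 0 for s in out.report.steps)

    def test_planted_ar_comphet_survives_clean_background(self, chain_ontology):
        """Hand-traced cascade: a compound het in an affected participant with
        matching phenotype passes all six filters; a deep-intronic row and a
        single het in another participant are removed at their steps."""
        pair = [
            row(pos=100, pid="A1", hpo=frozenset(["HP:0000004"])),
            row(pos=200, pid="A1", hpo=frozenset(["HP:0000004"])),
        ]
        intronic = row(pos=300, pid="A2", consequence=L,
                       hpo=frozenset(["HP:0000004"]))
        single = row(pos=400, pid="A3", hpo=frozenset(["HP:0000004"]))
        rows = pair + [intronic, single]
        cohort = cohort_of(rows, {"A1": AFF, "A2": AFF, "A3": AFF})
        config = WorkflowConfig(
            inheritance=Inheritance.AR, disease_hpo_terms=frozenset(["HP:0000003"])
        )
        out = run_workflow(rows, config, cohort, chain_ontology)
        assert out.prioritized == pair
        assert out.removal_steps[(intronic.variant.key(), "A2")] == "consequence"
        assert out.removal_steps[(single.variant.key(), "A3")] == "zygosity"
        assert out.report.n_prioritized == 2
        assert out.report.n_participants == 1

    def test_report_counts_conserve_and_chain(self, standard_bundle):
        from cohortmatch.pipeline import run_gene

        b = standard_bundle
        for gene in sorted(b.hypotheses):
            _, out = run_gene(b, gene)
            prev = None
            for s in out.report.steps:
                assert s.n_in == s.n_removed + s.n_out
                if prev is not None:
                    assert s.n_in == prev
                prev = s.n_out
            assert out.report.steps[-1].n_out == len(out.prioritized)

    def test_cascade_idempotent_on_own_output(self, standard_bundle):
        from cohortmatch.pipeline import run_gene
        from cohortmatch.workflow import run_workflow as rw

        b = standard_bundle
        for gene in sorted(b.hypotheses):
            res, out = run_gene(b, gene)
            hyp = b.hypotheses[gene]
            config = WorkflowConfig(
                inheritance=hyp.inheritance,
                severe_pediatric=hyp.severe_pediatric,
                disease_hpo_terms=hyp.disease_hpo_terms,
            )
            again = rw(out.prioritized, config, b.cohort, b.ontology)
            assert [r.vo for r in again.prioritized] == [r.vo for r in out.prioritized]

    def test_stream_exclusivity_of_prioritized_rows(self, standard_bundle):
        from cohortmatch.pipeline import run_gene

        b = standard_bundle
        for gene in sorted(b.hypotheses):
            hyp = b.hypotheses[gene]
            _, out = run_gene(b, gene)
            het_counts = {}
            for r in out.prioritized:
                if r.zygosity is Zygosity.HET:
                    het_counts[r.participant_id] = het_counts.get(r.participant_id, 0) + 1
            for r in out.prioritized:
                if hyp.inheritance is Inheritance.AD:
                    assert r.zygosity is Zygosity.HET
                elif hyp.inheritance is Inheritance.AR:
                    assert r.zygosity is Zygosity.HOM or het_counts[r.participant_id] >= 2
                else:
                    rules = [
                        r.zygosity is Zygosity.HEMI and r.sex is Sex.MALE,
                        r.zygosity is Zygosity.HOM and r.sex is Sex.FEMALE,
                        r.zygosity is Zygosity.HET and r.sex is Sex.FEMALE
                        and het_counts[r.participant_id] >= 2,
                    ]
                    assert sum(rules) == 1
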