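"""Prioritization cascade, consensus, genotype selection, cosegregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from irdx.core import (
    Affection,
    Consequence,
    Cosegregation,
    GeneAssociation,
    GenePanel,
    InheritanceModel,
    PanelGene,
    Pedigree,
    PedigreeMember,
    PredictionProfile,
    Sex,
    Zygosity,
)
from irdx.prioritize import (
    PrioritizationConfig,
    candidate_genotypes,
    check_cosegregation,
    consensus_pathogenicity,
    filter_by_consequence,
    filter_by_frequency,
    filter_by_prediction,
    models_for_pedigree,
)

from conftest import make_variant

CFG = PrioritizationConfig()

AR_PANEL = GenePanel.from_genes([
    PanelGene("USH2A", GeneAssociation.ESTABLISHED_IRD,
              frozenset({"AR"}), True, "chr1"),
])


class TestFrequencyFilter:
    def test_published_rare_allele_kept(self):
        v = make_variant(exac=(95, 121178))  # ~7.8e-4
        assert filter_by_frequency([v], CFG) == [v]

    def test_absent_always_kept(self):
        v = make_variant()
        assert filter_by_frequency([v], CFG) == [v]

    def test_boundary_is_inclusive(self):
        an = 1_000_000
        sweep = [make_variant(pos=i + 1, exac=(ac, an))
                 for i, ac in enumerate((9900, 10000, 10100))]
        kept = filter_by_frequency(sweep, CFG)
        assert [v.exac_ac for v in kept] == [9900, 10000]

    def test_fine_grid_threshold_semantics(self):
        an = 10_000_000
        grid = [make_variant(pos=i + 1, exac=(ac, an))
                for i, ac in enumerate(range(90_000, 110_001, 500))]
        kept = filter_by_frequency(grid, CFG)
        assert all(v.frequency <= 0.01 for v in kept)
        assert all(v.frequency > 0.01 for v in set(grid) - set(kept))


class TestConsequenceFilter:
    @pytest.mark.parametrize("csq,kept", [
        (Consequence.SYNONYMOUS, False),
        (Consequence.FRAMESHIFT, True),
        (Consequence.NONSENSE, True),
        (Consequence.MISSENSE, True),
        (Consequence.CANONICAL_SPLICE, True),
        (Consequence.NONCANONICAL_SPLICE_REGION, True),
        (Consequence.EXONIC_DELETION, True),
        (Consequence.DEEP_INTRONIC, False),
        (Consequence.OTHER, False),
    ])
    def test_retained_set(self, csq, kept):
        v = make_variant(consequence=csq)
        assert (filter_by_consequence([v], CFG) == [v]) is kept

    def test_reported_deep_intronic_rescued_by_whitelist(self):
        v = make_variant(consequence=Consequence.DEEP_INTRONIC, reported=True)
        assert filter_by_consequence([v], CFG) == [v]
        no_wl = PrioritizationConfig(reported_pathogenic_whitelist=False)
        assert filter_by_consequence([v], no_wl) == []


def _profile(pp2, sift, mt, cadd):
    """Four-tool profile with the given positivity."""
    return PredictionProfile(
        polyphen2_call="Probably D." if pp2 else "Benign",
        sift_call="Damaging" if sift else "Tolerated",
        mutationtaster_call="Disease C." if mt else "Polymorphism",
        cadd_phred=30.0 if cadd else 5.0,
    )


class TestConsensus:
    def test_four_positive_tools(self):
        # ABCA4 R1129L-like: call/score pairs, all four positive
        profile = PredictionProfile(
            polyphen2_call="Probably D.", polyphen2_score=0.961,
            sift_call="Damaging", sift_score=0.0,
            mutationtaster_call="Disease C.", mutationtaster_score=1.0,
            cadd_phred=28.01)
        assert consensus_pathogenicity(profile, CFG) == (True, 4)

    def test_three_positive_with_tolerated_sift(self):
        # PHYH P223R-like: SIFT "Tolerated 0.06" is negative (call wins)
        profile = PredictionProfile(
            polyphen2_call="Probably D.", polyphen2_score=1.0,
            sift_call="Tolerated", sift_score=0.06,
            mutationtaster_call="Disease C.", mutationtaster_score=1.0,
            cadd_phred=22.7)
        assert consensus_pathogenicity(profile, CFG) == (True, 3)

    def test_all_negative(self):
        assert consensus_pathogenicity(_profile(0, 0, 0, 0), CFG) == (False, 0)

    def test_all_missing_warns_and_fails(self):
        with pytest.warns(UserWarning):
            ok, n = consensus_pathogenicity(PredictionProfile(), CFG)
        assert (ok, n) == (False, 0)

    def test_all_sixteen_combinations(self):
        for combo in itertools.product((0, 1), repeat=4):
            ok, n = consensus_pathogenicity(_profile(*combo), CFG)
            assert n == sum(combo)
            assert ok is (sum(combo) >= 2)

    def test_call_beats_score(self):
        # damaging-range score but benign call -> negative
        p = PredictionProfile(sift_call="Tolerated", sift_score=0.0)
        ok, n = consensus_pathogenicity(p, CFG)
        assert n == 0

    def test_nonmissense_bypass_in_filter(self):
        null = make_variant(consequence=Consequence.FRAMESHIFT,
                            preds=PredictionProfile())
        weak_missense = make_variant(pos=2, preds=_profile(1, 0, 0, 0))
        kept = filter_by_prediction([null, weak_missense], CFG)
        assert kept == [null]


@st.composite
def record_sets(draw):
    n = draw(st.integers(0, 12))
    out = []
    for i in range(n):
        csq = draw(st.sampled_from(list(Consequence)))
        observed = draw(st.booleans())
        if observed:
            an = 100_000
            ac = draw(st.integers(0, 3000))
            exac = (ac, an)
        else:
            exac = None
        out.append(make_variant(pos=i + 1, consequence=csq, exac=exac,
                                reported=draw(st.booleans())))
    return out


class TestFilterProperties:
    @given(record_sets())
    def test_frequency_and_consequence_filters_commute(self, records):
        a = filter_by_consequence(filter_by_frequency(records, CFG), CFG)
        b = filter_by_frequency(filter_by_consequence(records, CFG), CFG)
        assert a == b

    @given(record_sets())
    def test_filters_never_invent_records(self, records):
        kept = filter_by_consequence(filter_by_frequency(records, CFG), CFG)
        assert set(kept) <= set(records)


def _calls(**zygs):
    return dict(zygs)


class TestCandidateGenotypes:
    def test_two_het_alleles_give_one_comphet(self, trio):
        v1 = make_variant(pos=100, hgvs="USH2A C575Y")
        v2 = make_variant(pos=200, hgvs="USH2A C759F")
        calls = [
            (v1, _calls(DAD=Zygosity.HET, MOM=Zygosity.HOM_REF,
                        KID=Zygosity.HET)),
            (v2, _calls(DAD=Zygosity.HOM_REF, MOM=Zygosity.HET,
                        KID=Zygosity.HET)),
        ]
        out = candidate_genotypes(calls, trio, AR_PANEL,
                                  InheritanceModel.AR_COMPHET, CFG)
        assert len(out) == 1
        assert not out[0].phase_unknown
        assert {v.pos for v in out[0].variants} == {100, 200}

    def test_cis_pair_rejected(self, trio):
        v1 = make_variant(pos=100)
        v2 = make_variant(pos=200)
        calls = [
            (v1, _calls(DAD=Zygosity.HET, MOM=Zygosity.HOM_REF,
                        KID=Zygosity.HET)),
            (v2, _calls(DAD=Zygosity.HET, MOM=Zygosity.HOM_REF,
                        KID=Zygosity.HET)),
        ]
        assert candidate_genotypes(calls, trio, AR_PANEL,
                                   InheritanceModel.AR_COMPHET, CFG) == []

    def test_single_het_no_recessive_candidate(self, trio):
        calls = [(make_variant(), _calls(DAD=Zygosity.HET,
                                         MOM=Zygosity.HOM_REF,
                                         KID=Zygosity.HET))]
        assert candidate_genotypes(calls, trio, AR_PANEL,
                                   InheritanceModel.AR_HOM, CFG) == []
        assert candidate_genotypes(calls, trio, AR_PANEL,
                                   InheritanceModel.AR_COMPHET, CFG) == []

    def test_hemizygous_male_xl_candidate(self):
        panel = GenePanel.from_genes([
            PanelGene("RPGR", GeneAssociation.ESTABLISHED_IRD,
                      frozenset({"XL"}), True, "chrX")])
        ped = Pedigree("F76", [PedigreeMember(
            "P1", Sex.MALE, Affection.AFFECTED)])
        v = make_variant(gene="RPGR", chrom="chrX",
                         consequence=Consequence.FRAMESHIFT)
        out = candidate_genotypes([(v, _calls(P1=Zygosity.HEMIZYGOUS))],
                                  ped, panel, InheritanceModel.XL, CFG)
        assert len(out) == 1

    def test_simplex_family_tried_under_all_four_models(self):
        ped = Pedigree("F", [PedigreeMember("P1", Sex.MALE,
                                            Affection.AFFECTED)])
        assert set(models_for_pedigree(ped)) == set(InheritanceModel)

    def test_stray_sample_rejected(self, trio):
        calls = [(make_variant(), _calls(GHOST=Zygosity.HET))]
        with pytest.raises(ValueError, match="GHOST"):
            candidate_genotypes(calls, trio, AR_PANEL,
                                InheritanceModel.AD, CFG)


def brute_force_comphet(calls, pedigree, rule_trans):
    """Independent comphet oracle: enumerate all het pairs, apply the
    affected/unaffected/trans constraints literally."""
    affected = [m for m in pedigree.members
                if m.affection is Affection.AFFECTED]
    unaffected = [m for m in pedigree.members
                  if m.affection is Affection.UNAFFECTED]
    carriers = (Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMIZYGOUS)
    hets = [
        (v, z) for v, z in calls
        if all(z.get(m.member_id, Zygosity.MISSING) in
               (Zygosity.HET, Zygosity.MISSING) for m in affected)
        and any(z.get(m.member_id) is Zygosity.HET for m in affected)
    ]
    pairs = set()
    for (v1, z1), (v2, z2) in itertools.combinations(hets, 2):
        if any(z1.get(m.member_id) in carriers
               and z2.get(m.member_id) in carriers for m in unaffected):
            continue
        if not rule_trans(z1, z2):
            continue
        pairs.add(frozenset((v1.key(), v2.key())))
    return pairs


class TestComphetOracle:
    def test_matches_brute_force_on_random_genes(self, rng):
        """Candidate comphet pairs equal exhaustive pair enumeration."""
        ped = Pedigree("F", [
            PedigreeMember("DAD", Sex.MALE, Affection.UNAFFECTED),
            PedigreeMember("MOM", Sex.FEMALE, Affection.UNAFFECTED),
            PedigreeMember("KID", Sex.FEMALE, Affection.AFFECTED,
                           father_id="DAD", mother_id="MOM"),
            PedigreeMember("SIB", Sex.MALE, Affection.UNAFFECTED,
                           father_id="DAD", mother_id="MOM"),
        ])
        states = [Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT,
                  Zygosity.MISSING]

        def rule_trans(z1, z2):
            # keep unless the parents certainly phase the pair in cis
            f1, f2 = z1.get("DAD"), z2.get("DAD")
            m1, m2 = z1.get("MOM"), z2.get("MOM")
            if Zygosity.MISSING in (f1, f2, m1, m2):
                return True  # phase unknown: kept
            carr = (Zygosity.HET, Zygosity.HOM_ALT)
            if (f1 in carr and m2 in carr) or (f2 in carr and m1 in carr):
                return True  # trans transmission possible
            cis = ((f1 in carr and f2 in carr
                    and m1 not in carr and m2 not in carr)
                   or (m1 in carr and m2 in carr
                       and f1 not in carr and f2 not in carr))
            return not cis

        for _ in range(300):
            n = int(rng.integers(2, 10))
            calls = []
            for i in range(n):
                z = {mid: states[int(rng.integers(0, 4))]
                     for mid in ("DAD", "MOM", "KID", "SIB")}
                calls.append((make_variant(pos=i + 1), z))
            got = candidate_genotypes(calls, ped, AR_PANEL,
                                      InheritanceModel.AR_COMPHET, CFG)
            got_pairs = {frozenset(v.key() for v in c.variants) for c in got}
            expected = brute_force_comphet(calls, ped, rule_trans)
            assert got_pairs == expected


class TestCosegregation:
    def _sixer(self):
        return Pedigree("F", [
            PedigreeMember("DAD", Sex.MALE, Affection.UNAFFECTED),
            PedigreeMember("MOM", Sex.FEMALE, Affection.UNAFFECTED),
            PedigreeMember("A1", Sex.MALE, Affection.AFFECTED,
                           father_id="DAD", mother_id="MOM"),
            PedigreeMember("A2", Sex.FEMALE, Affection.AFFECTED,
                           father_id="DAD", mother_id="MOM"),
            PedigreeMember("U1", Sex.MALE, Affection.UNAFFECTED,
                           father_id="DAD", mother_id="MOM"),
            PedigreeMember("U2", Sex.FEMALE, Affection.UNAFFECTED,
                           father_id="DAD", mother_id="MOM"),
        ])

    def test_unaffected_het_carriers_make_ad_inconsistent(self):
        """Dominant allele with unaffected carriers: incomplete penetrance."""
        ped = self._sixer()
        panel = GenePanel.from_genes([
            PanelGene("CNGB3", GeneAssociation.ESTABLISHED_IRD,
                      frozenset({"AD", "AR"}), True, "chr8")])
        z = dict(DAD=Zygosity.HET, MOM=Zygosity.HOM_REF, A1=Zygosity.HET,
                 A2=Zygosity.HET, U1=Zygosity.HET, U2=Zygosity.HOM_REF)
        cfg = PrioritizationConfig(penetrance_mode="incomplete")
        v = make_variant(gene="CNGB3", chrom="chr8")
        out = candidate_genotypes([(v, z)], ped, panel,
                                  InheritanceModel.AD, cfg)
        assert len(out) == 1
        assert out[0].cosegregation is Cosegregation.INCONSISTENT
        # under complete penetrance the candidate is rejected outright
        assert candidate_genotypes([(v, z)], ped, panel,
                                   InheritanceModel.AD, CFG) == []

    def test_proband_only_family_unavailable(self):
        ped = Pedigree("F", [PedigreeMember("P", Sex.MALE,
                                            Affection.AFFECTED)])
        out = candidate_genotypes(
            [(make_variant(), {"P": Zygosity.HOM_ALT})], ped, AR_PANEL,
            InheritanceModel.AR_HOM, CFG)
        assert out[0].cosegregation is Cosegregation.UNAVAILABLE

    def test_recessive_hom_affecteds_het_unaffecteds_consistent(self):
        ped = self._sixer()
        z = dict(DAD=Zygosity.HET, MOM=Zygosity.HET, A1=Zygosity.HOM_ALT,
                 A2=Zygosity.HOM_ALT, U1=Zygosity.HET, U2=Zygosity.HET)
        out = candidate_genotypes([(make_variant(), z)], ped, AR_PANEL,
                                  InheritanceModel.AR_HOM, CFG)
        assert out[0].cosegregation is Cosegregation.CONSISTENT

    def test_exhaustive_unaffected_assignments_match_rule(self):
        """Over all genotype assignments to the two unaffected sibs,
        the verdict equals the carries-full-genotype rule."""
        ped = self._sixer()
        states = [Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT]
        for u1 in states:
            for u2 in states:
                z = dict(DAD=Zygosity.HET, MOM=Zygosity.HET,
                         A1=Zygosity.HOM_ALT, A2=Zygosity.HOM_ALT,
                         U1=u1, U2=u2)
                out = candidate_genotypes([(make_variant(), z)], ped,
                                          AR_PANEL, InheritanceModel.AR_HOM,
                                          CFG)
                hom_unaffected = Zygosity.HOM_ALT in (u1, u2)
                if hom_unaffected:
                    assert out == []  # rejected by the model screen
                else:
                    assert out[0].cosegregation is Cosegregation.CONSISTENT
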