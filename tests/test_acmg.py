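"""Evidence derivation, class combination and family diagnosis."""

import itertools

import pytest

from irdx.acmg import (
    AcmgConfig,
    TransAllele,
    classify_genotype,
    combine_evidence,
    derive_evidence,
    diagnose_family,
)
from irdx.core import (
    AcmgClass,
    AcmgEvidence,
    CandidateGenotype,
    Consequence,
    Cosegregation,
    DiagnosticStatus,
    GeneAssociation,
    GenePanel,
    InheritanceModel,
    PanelGene,
    PredictionProfile,
    Zygosity,
)

from conftest import make_variant

CFG = AcmgConfig()

PANEL = GenePanel.from_genes([
    PanelGene("GUCY2D", GeneAssociation.ESTABLISHED_IRD,
              frozenset({"AD", "AR"}), True, "chr17"),
    PanelGene("CEP250", GeneAssociation.CANDIDATE_GENE,
              frozenset({"AR"}), True, "chr20"),
    PanelGene("SEMA6B", GeneAssociation.CANDIDATE_GENE,
              frozenset({"AR"}), True, "chr19"),
])

DAMAGING = PredictionProfile(
    polyphen2_call="Probably D.", sift_call="Damaging",
    mutationtaster_call="Disease C.", cadd_phred=28.0)


class TestDeriveEvidence:
    def test_homozygous_null_absent_cosegregating(self):
        """GUCY2D-type allele: null + absent + cosegregation."""
        v = make_variant(gene="GUCY2D", consequence=Consequence.FRAMESHIFT)
        ev = derive_evidence(v, PANEL["GUCY2D"],
                             model=InheritanceModel.AR_HOM,
                             cosegregation=Cosegregation.CONSISTENT,
                             config=CFG)
        assert set(ev.codes) == {"PVS1", "PM2", "PP1"}

    def test_functionally_supported_missense(self):
        """CEP250-type allele: PS3 + moderate rarity + consensus + coseg."""
        preds = PredictionProfile(polyphen2_call="Probably D.",
                                  sift_call="Damaging",
                                  mutationtaster_call="Neutral",
                                  cadd_phred=20.6)
        v = make_variant(gene="CEP250", exac=(33, 121314), preds=preds)
        ev = derive_evidence(v, PANEL["CEP250"],
                             model=InheritanceModel.AR_HOM,
                             cosegregation=Cosegregation.CONSISTENT,
                             functional_support=True, config=CFG)
        assert set(ev.codes) == {"PS3", "PM2", "PP3", "PP1"}

    def test_common_variant_is_stand_alone_benign(self):
        v = make_variant(exac=(24000, 120000))  # AF 0.2
        ev = derive_evidence(v, PANEL["GUCY2D"], config=CFG)
        assert set(ev.codes) == {"BA1"}

    def test_pm2_ceiling_is_model_dependent(self):
        v = make_variant(gene="GUCY2D", exac=(30, 121388))  # ~2.5e-4
        ar = derive_evidence(v, PANEL["GUCY2D"],
                             model=InheritanceModel.AR_COMPHET, config=CFG)
        ad = derive_evidence(v, PANEL["GUCY2D"],
                             model=InheritanceModel.AD, config=CFG)
        assert "PM2" in ar and "PM2" not in ad

    def test_unknown_frequency_gives_no_pm2(self):
        v = make_variant(exac="unknown")
        ev = derive_evidence(v, PANEL["GUCY2D"], config=CFG)
        assert "PM2" not in ev

    def test_pm3_upgrade_requires_reported_plp_partner(self):
        v = make_variant(gene="GUCY2D", preds=DAMAGING)
        base = dict(model=InheritanceModel.AR_COMPHET, config=CFG)
        novel_p = derive_evidence(
            v, PANEL["GUCY2D"],
            trans=TransAllele(False, AcmgClass.PATHOGENIC), **base)
        rep_p = derive_evidence(
            v, PANEL["GUCY2D"],
            trans=TransAllele(True, AcmgClass.PATHOGENIC), **base)
        rep_vus = derive_evidence(
            v, PANEL["GUCY2D"],
            trans=TransAllele(True, AcmgClass.VUS), **base)
        no_info = derive_evidence(
            v, PANEL["GUCY2D"], trans=TransAllele(False, AcmgClass.VUS),
            **base)
        assert "PM3" in novel_p and "PM3_upgraded_strong" not in novel_p
        assert "PM3_upgraded_strong" in rep_p
        assert "PM3" in rep_vus
        assert "PM3" not in no_info and "PM3_upgraded_strong" not in no_info

    def test_pm3_not_granted_outside_retained_consequences(self):
        v = make_variant(consequence=Consequence.DEEP_INTRONIC, reported=True)
        ev = derive_evidence(v, PANEL["GUCY2D"],
                             model=InheritanceModel.AR_COMPHET,
                             trans=TransAllele(True, AcmgClass.PATHOGENIC),
                             config=CFG)
        assert "PM3" not in ev and "PM3_upgraded_strong" not in ev


def oracle_combine(codes: frozenset) -> AcmgClass:
    """Independent transcription of the 2015 combining table: each
    qualifying pattern listed explicitly as (n_vs, n_s, n_m, n_p)
    minimum requirements."""
    strength = {"PVS1": "vs", "PS3": "s", "PM3_upgraded_strong": "s",
                "PM2": "m", "PM3": "m", "PP1": "p", "PP3": "p",
                "PP5_reported": "p"}
    n = {"vs": 0, "s": 0, "m": 0, "p": 0}
    for c in codes:
        if c != "BA1":
            n[strength[c]] += 1
    if "BA1" in codes:
        return AcmgClass.VUS if sum(n.values()) else AcmgClass.BENIGN
    pathogenic_patterns = [
        # (vs, s, m, p) minima; None = any
        (1, 1, None, None), (1, None, 2, None), (1, None, 1, 1),
        (1, None, None, 2), (2, None, None, None), (None, 2, None, None),
        (None, 1, 3, None), (None, 1, 2, 2), (None, 1, 1, 4),
    ]
    likely_patterns = [
        (1, None, 1, None), (None, 1, 1, None), (None, 1, None, 2),
        (None, None, 3, None), (None, None, 2, 2), (None, None, 1, 4),
    ]

    def matches(p):
        req = dict(zip(("vs", "s", "m", "p"), p))
        return all(v is None or n[k] >= v for k, v in req.items())

    if any(matches(p) for p in pathogenic_patterns):
        return AcmgClass.PATHOGENIC
    if any(matches(p) for p in likely_patterns):
        return AcmgClass.LIKELY_PATHOGENIC
    return AcmgClass.VUS


ALL_CODES = ["PVS1", "PS3", "PM2", "PM3", "PP1", "PP3", "PP5_reported",
             "BA1"]


class TestCombineEvidence:
    def test_null_plus_rarity_plus_coseg_is_pathogenic(self):
        cls, conflict = combine_evidence(
            AcmgEvidence(frozenset({"PVS1", "PM2", "PP1"})),
            GeneAssociation.ESTABLISHED_IRD, disruptive=True)
        assert cls is AcmgClass.PATHOGENIC and not conflict

    def test_candidate_gene_missense_hom_becomes_vgus(self):
        """SEMA6B G165R-type: {PM2, PP1, PP3}, candidate gene, homozygous."""
        cls, _ = combine_evidence(
            AcmgEvidence(frozenset({"PM2", "PP1", "PP3"})),
            GeneAssociation.CANDIDATE_GENE, disruptive=False,
            model=InheritanceModel.AR_HOM)
        assert cls is AcmgClass.VGUS

    def test_established_gene_same_evidence_stays_vus(self):
        """BBS2 F112L-type: identical codes in an established gene."""
        cls, _ = combine_evidence(
            AcmgEvidence(frozenset({"PM2", "PP1", "PP3"})),
            GeneAssociation.ESTABLISHED_SYNDROMIC, disruptive=False,
            model=InheritanceModel.AR_HOM)
        assert cls is AcmgClass.VUS

    def test_candidate_gene_null_becomes_vgus(self):
        cls, _ = combine_evidence(
            AcmgEvidence(frozenset({"PVS1", "PM2", "PP1"})),
            GeneAssociation.CANDIDATE_GENE, disruptive=True)
        assert cls is AcmgClass.VGUS

    def test_ps3_lifts_candidate_gene_cap(self):
        cls, _ = combine_evidence(
            AcmgEvidence(frozenset({"PS3", "PM2", "PP3", "PP1"})),
            GeneAssociation.CANDIDATE_GENE, disruptive=False,
            model=InheritanceModel.AR_HOM)
        assert cls is AcmgClass.LIKELY_PATHOGENIC

    def test_ba1_with_pvs1_is_conflicted_vus(self):
        cls, conflict = combine_evidence(
            AcmgEvidence(frozenset({"BA1", "PVS1"})),
            GeneAssociation.ESTABLISHED_IRD, disruptive=True)
        assert cls is AcmgClass.VUS and conflict

    def test_ba1_alone_is_benign(self):
        cls, _ = combine_evidence(AcmgEvidence(frozenset({"BA1"})),
                                  GeneAssociation.ESTABLISHED_IRD)
        assert cls is AcmgClass.BENIGN

    def test_all_subsets_match_independent_oracle(self):
        """Exhaustive enumeration over every evidence subset."""
        for r in range(len(ALL_CODES) + 1):
            for combo in itertools.combinations(ALL_CODES, r):
                ev = AcmgEvidence(frozenset(combo))
                got, _ = combine_evidence(
                    ev, GeneAssociation.ESTABLISHED_IRD, disruptive=False)
                assert got is oracle_combine(frozenset(combo)), combo

    def test_monotone_in_pathogenic_evidence(self):
        """Adding pathogenic-direction evidence never moves the class
        toward benign."""
        rank = {AcmgClass.BENIGN: 0, AcmgClass.VUS: 1,
                AcmgClass.LIKELY_PATHOGENIC: 2, AcmgClass.PATHOGENIC: 3}
        path_codes = [c for c in ALL_CODES if c != "BA1"]
        for r in range(len(path_codes) + 1):
            for combo in itertools.combinations(path_codes, r):
                base, _ = combine_evidence(
                    AcmgEvidence(frozenset(combo)),
                    GeneAssociation.ESTABLISHED_IRD)
                for extra in set(path_codes) - set(combo):
                    more, _ = combine_evidence(
                        AcmgEvidence(frozenset(combo) | {extra}),
                        GeneAssociation.ESTABLISHED_IRD)
                    assert rank[more] >= rank[base]


def _genotype(alleles, model, coseg=Cosegregation.CONSISTENT, gene="GUCY2D",
              functional=False):
    zyg = (Zygosity.HOM_ALT if model is InheritanceModel.AR_HOM
           else Zygosity.HET)
    return CandidateGenotype(
        family_id="F", gene=gene, model=model,
        alleles=[(v, {"P": zyg}) for v in alleles],
        cosegregation=coseg, functional_support=functional)


class TestClassifyGenotype:
    def test_comphet_pm3_chains_to_fixed_point(self):
        """A reported LP partner upgrades PM3 on both comphet alleles."""
        a = make_variant(pos=1, gene="GUCY2D", exac=(1, 121370),
                         reported=True, preds=DAMAGING)
        b = make_variant(pos=2, gene="GUCY2D", exac=(95, 121178),
                         reported=True, preds=DAMAGING)
        cg = classify_genotype(
            _genotype([a, b], InheritanceModel.AR_COMPHET), PANEL, CFG)
        assert [x.acmg_class for x in cg.alleles] == \
            [AcmgClass.LIKELY_PATHOGENIC, AcmgClass.LIKELY_PATHOGENIC]
        assert "PM3_upgraded_strong" in cg.alleles[1].evidence

    def test_hom_genotype_gets_no_pm3(self):
        v = make_variant(gene="GUCY2D", exac=(1, 121022), preds=DAMAGING)
        cg = classify_genotype(
            _genotype([v], InheritanceModel.AR_HOM), PANEL, CFG)
        assert cg.alleles[0].acmg_class is AcmgClass.VUS
        assert "PM3" not in cg.alleles[0].evidence


class TestDiagnoseFamily:
    def test_solved_requires_all_alleles_plp(self):
        solved = make_variant(gene="GUCY2D",
                              consequence=Consequence.FRAMESHIFT)
        cg = classify_genotype(
            _genotype([solved], InheritanceModel.AR_HOM), PANEL, CFG)
        rep = diagnose_family([cg], "F", PANEL)
        assert rep.status is DiagnosticStatus.SOLVED

    def test_vus_allele_downgrades_to_candidate(self):
        lp = make_variant(pos=1, gene="GUCY2D",
                          consequence=Consequence.NONSENSE)
        vus = make_variant(pos=2, gene="GUCY2D", exac="unknown",
                           preds=PredictionProfile(cadd_phred=20))
        cg = classify_genotype(
            _genotype([lp, vus], InheritanceModel.AR_COMPHET), PANEL, CFG)
        rep = diagnose_family([cg], "F", PANEL)
        assert rep.status is DiagnosticStatus.CANDIDATE

    def test_no_candidates_is_unsolved(self):
        rep = diagnose_family([], "F", PANEL)
        assert rep.status is DiagnosticStatus.UNSOLVED

    def test_inconsistent_cosegregation_blocks_solved(self):
        """Pathogenic dominant allele with non-penetrant carriers."""
        v = make_variant(gene="GUCY2D", consequence=Consequence.FRAMESHIFT,
                         reported=True)
        cg = classify_genotype(
            _genotype([v], InheritanceModel.AD,
                      coseg=Cosegregation.INCONSISTENT), PANEL, CFG)
        assert cg.alleles[0].acmg_class is AcmgClass.PATHOGENIC
        rep = diagnose_family([cg], "F", PANEL)
        assert rep.status is DiagnosticStatus.CANDIDATE

    def test_unavailable_cosegregation_not_blocking(self):
        v = make_variant(gene="GUCY2D", consequence=Consequence.FRAMESHIFT)
        cg = classify_genotype(
            _genotype([v], InheritanceModel.AR_HOM,
                      coseg=Cosegregation.UNAVAILABLE), PANEL, CFG)
        rep = diagnose_family([cg], "F", PANEL)
        assert rep.status is DiagnosticStatus.SOLVED

    def test_candidate_gene_without_ps3_not_solved(self):
        v = make_variant(gene="SEMA6B", consequence=Consequence.FRAMESHIFT)
        cg = classify_genotype(
            _genotype([v], InheritanceModel.AR_HOM, gene="SEMA6B"), PANEL,
            CFG)
        assert cg.alleles[0].acmg_class is AcmgClass.VGUS
        rep = diagnose_family([cg], "F", PANEL)
        assert rep.status is DiagnosticStatus.CANDIDATE
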