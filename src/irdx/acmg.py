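"""ACMG/AMP-style evidence derivation, class combination and diagnosis.

The engine uses the subset of evidence codes that the cohort's published
decisions can be reconstructed from: PVS1, PS3, PM2, PM3 (moderate or
upgraded to strong), PP1, PP3, PP5 and BA1, combined by the standard
2015 combining rules, plus a cohort-specific ``VGUS`` output class for
clearly disruptive alleles in genes whose disease role is not yet
established.

PM3 (in trans with a pathogenic allele) is resolved iteratively: alleles
are first classified without PM3, then PM3 is granted and optionally
upgraded from the partner allele's current class until a fixed point is
reached.  Evidence is only ever added across iterations, so the
procedure converges in a handful of rounds.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    AcmgClass,
    AcmgEvidence,
    CandidateGenotype,
    ClassifiedAllele,
    ClassifiedGenotype,
    Consequence,
    Cosegregation,
    DEFAULT_RETAINED_CONSEQUENCES,
    DiagnosticStatus,
    EvidenceStrength,
    FamilyReport,
    FrequencyStatus,
    GeneAssociation,
    GenePanel,
    InheritanceModel,
    PanelGene,
    Reported,
    VariantRecord,
)
from .prioritize import PrioritizationConfig, count_positive_predictors


@dataclass(frozen=True)
class AcmgConfig:
    """Frequency ceilings and consensus settings for evidence derivation.

    ``pm2_max_recessive`` is deliberately looser than ``pm2_max``:
    recessive alleles persist at higher carrier frequencies, and the
    cohort's published moderate-rarity judgements include recessive
    alleles observed up to ~2.7e-4.
    """

    pm2_max: float = 1e-4
    pm2_max_recessive: float = 3e-4
    ba1_min: float = 0.05
    prioritization: PrioritizationConfig = PrioritizationConfig()


@dataclass(frozen=True)
class TransAllele:
    """What the engine knows about the in-trans partner allele."""

    reported: bool
    acmg_class: AcmgClass | None


_RECESSIVE_MODELS = {InheritanceModel.AR_HOM, InheritanceModel.AR_COMPHET}
_PLP = {AcmgClass.PATHOGENIC, AcmgClass.LIKELY_PATHOGENIC}


def derive_evidence(variant: VariantRecord,
                    gene: PanelGene | None,
                    model: InheritanceModel | None = None,
                    cosegregation: Cosegregation = Cosegregation.UNAVAILABLE,
                    functional_support: bool = False,
                    trans: TransAllele | None = None,
                    config: AcmgConfig | None = None) -> AcmgEvidence:
    """Derive the applicable evidence codes for one allele.

    * PVS1 — null allele (nonsense, frameshift, canonical splice, exonic
      deletion/duplication) in a gene where loss of function is an
      established disease mechanism.
    * PS3 — functional assay supports a damaging effect.
    * PM2 — absent from the frequency reference, or observed below the
      (model-dependent) rarity ceiling; sites not covered by the
      reference yield no PM2.
    * PM3 — compound-het allele in trans with a pathogenic/likely
      pathogenic or previously reported pathogenic allele; upgraded to
      strong when the trans allele is both reported and classified P/LP.
      Not granted for homozygous genotypes or for alleles outside the
      retained consequence classes.
    * PP1 — cosegregation with disease in the family.
    * PP3 — at least two in-silico predictors positive.
    * PP5 — allele previously reported as pathogenic.
    * BA1 — frequency above 5%: stand-alone benign.
    """
    config = config or AcmgConfig()
    codes: set[str] = set()
    freq = variant.frequency

    if freq is not None and freq > config.ba1_min:
        codes.add("BA1")

    if variant.is_disruptive and gene is not None and gene.lof_mechanism:
        codes.add("PVS1")

    if functional_support:
        codes.add("PS3")

    ceiling = (config.pm2_max_recessive if model in _RECESSIVE_MODELS
               else config.pm2_max)
    if variant.exac_status is FrequencyStatus.ABSENT:
        codes.add("PM2")
    elif variant.exac_status is FrequencyStatus.OBSERVED and freq < ceiling:
        codes.add("PM2")

    if (model is InheritanceModel.AR_COMPHET
            and trans is not None
            and variant.consequence in DEFAULT_RETAINED_CONSEQUENCES):
        trans_plp = trans.acmg_class in _PLP
        if trans.reported or trans_plp:
            if trans.reported and trans_plp:
                codes.add("PM3_upgraded_strong")
            else:
                codes.add("PM3")

    if cosegregation is Cosegregation.CONSISTENT:
        codes.add("PP1")

    if count_positive_predictors(variant.predictions,
                                 config.prioritization) >= \
            config.prioritization.min_positive_predictors:
        codes.add("PP3")

    if variant.reported is Reported.REPORTED_PATHOGENIC:
        codes.add("PP5_reported")

    return AcmgEvidence(frozenset(codes))


def _combine_pathogenic_strengths(vs: int, s: int, m: int, p: int) -> AcmgClass:
    """The 2015 combining table over strength counts (benign codes aside)."""
    if vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2):
        return AcmgClass.PATHOGENIC
    if vs >= 2 or s >= 2:
        return AcmgClass.PATHOGENIC
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return AcmgClass.PATHOGENIC
    if vs >= 1 and m == 1:
        return AcmgClass.LIKELY_PATHOGENIC
    if s == 1 and 1 <= m <= 2:
        return AcmgClass.LIKELY_PATHOGENIC
    if s == 1 and p >= 2:
        return AcmgClass.LIKELY_PATHOGENIC
    if m >= 3:
        return AcmgClass.LIKELY_PATHOGENIC
    if m == 2 and p >= 2:
        return AcmgClass.LIKELY_PATHOGENIC
    if m == 1 and p >= 4:
        return AcmgClass.LIKELY_PATHOGENIC
    return AcmgClass.VUS


def combine_evidence(evidence: AcmgEvidence,
                     association: GeneAssociation | None = None,
                     *,
                     disruptive: bool = False,
                     model: InheritanceModel | None = None
                     ) -> tuple[AcmgClass, bool]:
    """Combine evidence codes into an output class.

    Returns ``(class, conflict_flag)``.  BA1 alone yields Benign;
    BA1 together with pathogenic evidence yields VUS with the conflict
    flag set.  For candidate genes without functional support (no PS3),
    the class is remapped: disruptive alleles become VGUS, missense
    alleles that would be pathogenic/likely pathogenic are capped at
    VUS, and a homozygous, rare, consensus-damaging, cosegregating
    missense allele becomes VGUS.
    """
    counts = evidence.strength_counts()
    vs = counts[EvidenceStrength.VERY_STRONG]
    s = counts[EvidenceStrength.STRONG]
    m = counts[EvidenceStrength.MODERATE]
    p = counts[EvidenceStrength.SUPPORTING]
    ba1 = "BA1" in evidence

    if ba1 and (vs + s + m + p) > 0:
        return AcmgClass.VUS, True
    if ba1:
        return AcmgClass.BENIGN, False

    cls = _combine_pathogenic_strengths(vs, s, m, p)

    if (association is GeneAssociation.CANDIDATE_GENE
            and "PS3" not in evidence):
        if disruptive and cls is not AcmgClass.BENIGN:
            return AcmgClass.VGUS, False
        if (model is InheritanceModel.AR_HOM
                and {"PM2", "PP3", "PP1"} <= set(evidence.codes)):
            return AcmgClass.VGUS, False
        if cls in _PLP:
            return AcmgClass.VUS, False
    return cls, False


def classify_genotype(candidate: CandidateGenotype,
                      panel: GenePanel,
                      config: AcmgConfig | None = None) -> ClassifiedGenotype:
    """Classify every allele of a candidate genotype.

    PM3 couples the comphet alleles, so classification iterates to a
    fixed point (evidence only accumulates across rounds).
    """
    config = config or AcmgConfig()
    gene = panel.get(candidate.gene)
    variants = candidate.variants
    n = len(variants)
    classes: list[AcmgClass | None] = [None] * n
    evidences: list[AcmgEvidence] = [AcmgEvidence()] * n
    conflicts = [False] * n

    for _ in range(5):
        changed = False
        for i, v in enumerate(variants):
            trans = None
            if candidate.model is InheritanceModel.AR_COMPHET:
                j = 1 - i
                trans = TransAllele(
                    reported=(variants[j].reported
                              is Reported.REPORTED_PATHOGENIC),
                    acmg_class=classes[j],
                )
            ev = derive_evidence(
                v, gene, model=candidate.model,
                cosegregation=candidate.cosegregation,
                functional_support=candidate.functional_support,
                trans=trans, config=config,
            )
            cls, conflict = combine_evidence(
                ev, gene.association if gene else None,
                disruptive=v.is_disruptive, model=candidate.model,
            )
            if cls is not classes[i] or ev.codes != evidences[i].codes:
                changed = True
            classes[i], evidences[i], conflicts[i] = cls, ev, conflict
        if not changed:
            break

    return ClassifiedGenotype(
        candidate=candidate,
        alleles=[ClassifiedAllele(v, evidences[i], classes[i], conflicts[i])
                 for i, v in enumerate(variants)],
    )


def _is_diagnostic(cg: ClassifiedGenotype, panel: GenePanel) -> bool:
    gene = panel.get(cg.candidate.gene)
    if gene is None:
        return False
    if gene.association is GeneAssociation.CANDIDATE_GENE:
        if not any("PS3" in a.evidence for a in cg.alleles):
            return False
    if cg.candidate.cosegregation is Cosegregation.INCONSISTENT:
        return False
    return all(a.acmg_class in _PLP for a in cg.alleles)


def diagnose_family(classified: list[ClassifiedGenotype],
                    family_id: str,
                    panel: GenePanel,
                    modifiers: list[VariantRecord] | None = None
                    ) -> FamilyReport:
    """Per-family diagnostic verdict.

    ``solved``: some genotype in an established gene (or a candidate
    gene with functional support) is complete for its model, does not
    contradict cosegregation, and all its alleles are pathogenic or
    likely pathogenic.  ``candidate``: a plausible genotype exists but
    carries VUS/VGUS alleles, lacks functional support in a novel gene,
    or cosegregation is inconsistent (incomplete penetrance).
    ``unsolved`` otherwise.
    """
    modifiers = modifiers or []
    diagnostic = [cg for cg in classified if _is_diagnostic(cg, panel)]
    if diagnostic:
        causative = max(diagnostic, key=_genotype_rank)
        return FamilyReport(family_id=family_id,
                            status=DiagnosticStatus.SOLVED,
                            causative=causative, modifiers=modifiers)
    if classified:
        best = max(classified, key=_genotype_rank)
        return FamilyReport(family_id=family_id,
                            status=DiagnosticStatus.CANDIDATE,
                            causative=best, modifiers=modifiers)
    return FamilyReport(family_id=family_id,
                        status=DiagnosticStatus.UNSOLVED,
                        modifiers=modifiers)


_CLASS_RANK = {
    AcmgClass.PATHOGENIC: 4,
    AcmgClass.LIKELY_PATHOGENIC: 3,
    AcmgClass.VGUS: 2,
    AcmgClass.VUS: 1,
    AcmgClass.BENIGN: 0,
}


def _genotype_rank(cg: ClassifiedGenotype) -> tuple:
    ranks = sorted(_CLASS_RANK[a.acmg_class] for a in cg.alleles)
    coseg_ok = cg.candidate.cosegregation is not Cosegregation.INCONSISTENT
    return (min(ranks), sum(ranks), coseg_ok)


def find_modifiers(variant_calls, causative_keys: set,
                   panel: GenePanel, proband: str,
                   config: AcmgConfig | None = None) -> list[VariantRecord]:
    """Heterozygous modifier alleles outside the causative genotype.

    A modifier is a het allele in a panel gene that is either a known
    pathogenic recessive allele or an unreported allele predicted
    damaging by at least two algorithms.
    """
    from .core import Zygosity
    from .prioritize import _as_zygosity

    config = config or AcmgConfig()
    out = []
    for rec, calls in variant_calls:
        if rec.key() in causative_keys or rec.gene not in panel:
            continue
        zyg = _as_zygosity(calls.get(proband)) if proband in calls else None
        if zyg is not Zygosity.HET:
            continue
        reported = rec.reported is Reported.REPORTED_PATHOGENIC
        predicted = count_positive_predictors(
            rec.predictions, config.prioritization) >= 2
        if reported or predicted:
            out.append(rec)
    return out
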