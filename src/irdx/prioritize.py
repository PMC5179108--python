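"""Variant prioritization cascade and inheritance-model genotype selection.

Three filters, applied to annotated records:

1. population frequency: keep alleles at ExAC frequency <= 1% (inclusive);
   alleles absent from ExAC always pass;
2. consequence: keep null (nonsense / frameshift / canonical splice),
   missense, splice-region and exonic CNV alleles; alleles already
   reported as pathogenic are whitelisted through regardless (this covers
   reported deep-intronic alleles);
3. in-silico consensus: a missense allele must be called pathogenic by at
   least two of PolyPhen2, SIFT, MutationTaster and CADD.

The surviving alleles are then assembled into per-gene genotype
configurations compatible with a Mendelian model (dominant, recessive
homozygous, compound heterozygous, X-linked) and screened against the
family genotypes, including a cosegregation verdict.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from .core import (
    Affection,
    CandidateGenotype,
    Consequence,
    Cosegregation,
    DEFAULT_RETAINED_CONSEQUENCES,
    FrequencyStatus,
    GenePanel,
    GenotypeCall,
    InheritanceModel,
    Pedigree,
    PredictionProfile,
    Reported,
    Sex,
    VariantRecord,
    Zygosity,
    warn,
)

logger = logging.getLogger(__name__)

CARRIER_STATES = {Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMIZYGOUS}

#: PolyPhen2 categorical calls counted as positive.
POLYPHEN2_POSITIVE_CALLS = {"Probably D.", "Possibly D.",
                            "probably damaging", "possibly damaging"}
#: SIFT categorical calls counted as positive.
SIFT_POSITIVE_CALLS = {"Damaging", "damaging", "Deleterious", "deleterious"}
#: MutationTaster categorical calls counted as positive.
MT_POSITIVE_CALLS = {"Disease C.", "disease causing", "Disease causing"}


@dataclass(frozen=True)
class PrioritizationConfig:
    """Thresholds of the prioritization cascade.

    Defaults implement the published filter settings: 1% frequency
    ceiling (inclusive), null/missense/splice/CNV consequences, and a
    two-of-four in-silico consensus.  The CADD positivity cutoff
    (phred >= 15) and per-tool score cutoffs are stated explicitly here
    because the tools' categorical calls are not always available.
    """

    af_max: float = 0.01
    retained_consequences: frozenset = DEFAULT_RETAINED_CONSEQUENCES
    min_positive_predictors: int = 2
    reported_pathogenic_whitelist: bool = True
    penetrance_mode: str = "complete"  # or "incomplete"
    polyphen2_score_min: float = 0.85
    sift_score_max: float = 0.05
    mutationtaster_score_min: float = 0.5
    cadd_phred_min: float = 15.0

    def __post_init__(self):
        if not (0.0 < self.af_max <= 1.0):
            raise ValueError("af_max must be in (0, 1]")
        if self.min_positive_predictors not in (1, 2, 3, 4):
            raise ValueError("min_positive_predictors must be in 1..4")
        if self.penetrance_mode not in ("complete", "incomplete"):
            raise ValueError("penetrance_mode must be 'complete' or 'incomplete'")


# ---------------------------------------------------------------------------
# Filters 1-3

def _passes_frequency(record: VariantRecord, config: PrioritizationConfig) -> bool:
    freq = record.frequency
    if freq is None:  # not covered by the reference: cannot exclude
        return True
    return freq <= config.af_max


def filter_by_frequency(records, config: PrioritizationConfig | None = None):
    """Keep alleles with ExAC frequency <= ``af_max`` (absent always kept)."""
    config = config or PrioritizationConfig()
    return [r for r in records if _passes_frequency(r, config)]


def _passes_consequence(record: VariantRecord, config: PrioritizationConfig) -> bool:
    if record.consequence in config.retained_consequences:
        return True
    if (config.reported_pathogenic_whitelist
            and record.reported is Reported.REPORTED_PATHOGENIC):
        return True
    return False


def filter_by_consequence(records, config: PrioritizationConfig | None = None):
    """Keep null/missense/splice/CNV alleles plus reported-pathogenic ones."""
    config = config or PrioritizationConfig()
    kept = []
    for r in records:
        if _passes_consequence(r, config):
            kept.append(r)
        else:
            logger.debug("consequence filter removed %s:%s %s>%s (%s)",
                         r.chrom, r.pos, r.ref, r.alt, r.consequence.value)
    return kept


def tool_positivity(profile: PredictionProfile,
                    config: PrioritizationConfig | None = None) -> dict[str, bool | None]:
    """Per-tool positivity; ``None`` marks a tool with no output.

    Where both a categorical call and a score are present the call
    decides (published tables pair calls like "Tolerated" with scores on
    either side of the cutoff).
    """
    config = config or PrioritizationConfig()
    out: dict[str, bool | None] = {}

    if profile.polyphen2_call is not None:
        out["polyphen2"] = profile.polyphen2_call in POLYPHEN2_POSITIVE_CALLS
    elif profile.polyphen2_score is not None:
        out["polyphen2"] = profile.polyphen2_score >= config.polyphen2_score_min
    else:
        out["polyphen2"] = None

    if profile.sift_call is not None:
        out["sift"] = profile.sift_call in SIFT_POSITIVE_CALLS
    elif profile.sift_score is not None:
        out["sift"] = profile.sift_score <= config.sift_score_max
    else:
        out["sift"] = None

    if profile.mutationtaster_call is not None:
        out["mutationtaster"] = profile.mutationtaster_call in MT_POSITIVE_CALLS
    elif profile.mutationtaster_score is not None:
        out["mutationtaster"] = (profile.mutationtaster_score
                                 >= config.mutationtaster_score_min)
    else:
        out["mutationtaster"] = None

    if profile.cadd_phred is not None:
        out["cadd"] = profile.cadd_phred >= config.cadd_phred_min
    else:
        out["cadd"] = None
    return out


def count_positive_predictors(profile: PredictionProfile,
                              config: PrioritizationConfig | None = None) -> int:
    return sum(bool(v) for v in tool_positivity(profile, config).values())


def consensus_pathogenicity(profile: PredictionProfile,
                            config: PrioritizationConfig | None = None
                            ) -> tuple[bool, int]:
    """Two-of-four predictor consensus for missense alleles.

    Returns ``(is_consensus_pathogenic, n_positive_tools)``.
    """
    config = config or PrioritizationConfig()
    positivity = tool_positivity(profile, config)
    if all(v is None for v in positivity.values()):
        warn("all predictors missing; consensus defaults to negative")
        return False, 0
    n = sum(bool(v) for v in positivity.values())
    return n >= config.min_positive_predictors, n


def filter_by_prediction(records, config: PrioritizationConfig | None = None):
    """Drop missense alleles failing the predictor consensus.

    Null, splice, CNV and whitelist-rescued alleles bypass the test.
    """
    config = config or PrioritizationConfig()
    kept = []
    for r in records:
        if r.consequence is not Consequence.MISSENSE:
            kept.append(r)
        elif consensus_pathogenicity(r.predictions, config)[0]:
            kept.append(r)
        else:
            logger.debug("consensus filter removed %s (%s)", r.hgvs or r.key(),
                         r.gene)
    return kept


def prioritize_records(records, config: PrioritizationConfig | None = None):
    """Apply the full three-filter cascade."""
    config = config or PrioritizationConfig()
    records = filter_by_frequency(records, config)
    records = filter_by_consequence(records, config)
    records = filter_by_prediction(records, config)
    return records


# ---------------------------------------------------------------------------
# Inheritance-model genotype selection

def _as_zygosity(call) -> Zygosity:
    return call.zygosity if isinstance(call, GenotypeCall) else call


def _normalise_calls(variant_calls):
    out = []
    for rec, calls in variant_calls:
        out.append((rec, {s: _as_zygosity(c) for s, c in calls.items()}))
    return out


def _model_compatible_with_gene(model: InheritanceModel, gene) -> bool:
    if gene is None:
        return False
    needed = {InheritanceModel.AD: "AD", InheritanceModel.AR_HOM: "AR",
              InheritanceModel.AR_COMPHET: "AR", InheritanceModel.XL: "XL"}[model]
    return needed in gene.inheritance_modes


def _carries(zyg: Zygosity) -> bool:
    return zyg in CARRIER_STATES


def models_for_pedigree(pedigree: Pedigree) -> list[InheritanceModel]:
    """Plausible models given the pedigree structure.

    Simplex cases are evaluated under all four models (a fifth of
    apparently sporadic patients carry dominant or X-linked alleles).
    """
    affecteds = pedigree.affecteds()
    if len(affecteds) <= 1:
        return [InheritanceModel.AD, InheritanceModel.AR_HOM,
                InheritanceModel.AR_COMPHET, InheritanceModel.XL]
    affected_ids = {m.member_id for m in affecteds}
    parent_child = any(
        (m.father_id in affected_ids or m.mother_id in affected_ids)
        for m in affecteds
    )
    if parent_child:
        models = [InheritanceModel.AD]
        if all(m.sex is Sex.MALE for m in affecteds):
            models.append(InheritanceModel.XL)
        return models
    models = [InheritanceModel.AR_HOM, InheritanceModel.AR_COMPHET]
    if all(m.sex is Sex.MALE for m in affecteds):
        models.append(InheritanceModel.XL)
    return models


def _ad_candidates(variants, pedigree, panel, config):
    out = []
    affecteds = pedigree.affecteds()
    unaffecteds = pedigree.unaffecteds()
    for rec, zygs in variants:
        gene = panel.get(rec.gene)
        if not _model_compatible_with_gene(InheritanceModel.AD, gene):
            continue
        aff_typed = [zygs.get(m.member_id, Zygosity.MISSING) for m in affecteds]
        known = [z for z in aff_typed if z is not Zygosity.MISSING]
        if not known or not all(z in (Zygosity.HET, Zygosity.HEMIZYGOUS)
                                for z in known):
            continue
        unaff_carrier = any(
            _carries(zygs.get(m.member_id, Zygosity.MISSING)) for m in unaffecteds)
        if unaff_carrier and config.penetrance_mode == "complete":
            continue
        out.append(CandidateGenotype(
            family_id=pedigree.family_id, gene=rec.gene,
            model=InheritanceModel.AD, alleles=[(rec, zygs)],
        ))
    return out


def _ar_hom_candidates(variants, pedigree, panel, config):
    out = []
    affecteds = pedigree.affecteds()
    unaffecteds = pedigree.unaffecteds()
    by_id = {m.member_id: m for m in pedigree.members}
    for rec, zygs in variants:
        gene = panel.get(rec.gene)
        if not _model_compatible_with_gene(InheritanceModel.AR_HOM, gene):
            continue
        aff_typed = [zygs.get(m.member_id, Zygosity.MISSING) for m in affecteds]
        known = [z for z in aff_typed if z is not Zygosity.MISSING]
        if not known or not all(z is Zygosity.HOM_ALT for z in known):
            continue
        if any(zygs.get(m.member_id) is Zygosity.HOM_ALT for m in unaffecteds):
            continue
        # genotyped parents of affecteds must be het carriers
        parents_ok = True
        for m in affecteds:
            for pid in (m.father_id, m.mother_id):
                if pid is None or pid not in by_id:
                    continue
                pz = zygs.get(pid, Zygosity.MISSING)
                if pz not in (Zygosity.HET, Zygosity.MISSING):
                    parents_ok = False
        if not parents_ok:
            continue
        out.append(CandidateGenotype(
            family_id=pedigree.family_id, gene=rec.gene,
            model=InheritanceModel.AR_HOM, alleles=[(rec, zygs)],
        ))
    return out


def _trans_status(v1_zygs, v2_zygs, member, by_id):
    """Phase two het alleles through the parents of one affected.

    Returns "trans", "cis" or "unknown".
    """
    father, mother = member.father_id, member.mother_id
    if father is None or mother is None or father not in by_id or mother not in by_id:
        return "unknown"
    f1 = v1_zygs.get(father, Zygosity.MISSING)
    f2 = v2_zygs.get(father, Zygosity.MISSING)
    m1 = v1_zygs.get(mother, Zygosity.MISSING)
    m2 = v2_zygs.get(mother, Zygosity.MISSING)
    if Zygosity.MISSING in (f1, f2, m1, m2):
        return "unknown"
    trans_possible = ((_carries(f1) and _carries(m2))
                      or (_carries(f2) and _carries(m1)))
    if trans_possible:
        return "trans"
    cis_certain = ((_carries(f1) and _carries(f2) and not _carries(m1)
                    and not _carries(m2))
                   or (_carries(m1) and _carries(m2) and not _carries(f1)
                       and not _carries(f2)))
    return "cis" if cis_certain else "unknown"


def _comphet_candidates(variants, pedigree, panel, config):
    out = []
    affecteds = pedigree.affecteds()
    unaffecteds = pedigree.unaffecteds()
    by_id = {m.member_id: m for m in pedigree.members}
    by_gene: dict[str, list] = {}
    for rec, zygs in variants:
        gene = panel.get(rec.gene)
        if not _model_compatible_with_gene(InheritanceModel.AR_COMPHET, gene):
            continue
        aff_typed = [zygs.get(m.member_id, Zygosity.MISSING) for m in affecteds]
        known = [z for z in aff_typed if z is not Zygosity.MISSING]
        if known and all(z is Zygosity.HET for z in known):
            by_gene.setdefault(rec.gene, []).append((rec, zygs))
    for gene, pool in by_gene.items():
        for (r1, z1), (r2, z2) in itertools.combinations(pool, 2):
            if r1.key() == r2.key():
                continue
            # phase through parents of each affected where possible
            phase = "unknown"
            cis = False
            for m in affecteds:
                st = _trans_status(z1, z2, m, by_id)
                if st == "cis":
                    cis = True
                elif st == "trans":
                    phase = "trans"
            if cis:
                continue
            # no unaffected member may carry both alleles
            if any(_carries(z1.get(m.member_id, Zygosity.MISSING))
                   and _carries(z2.get(m.member_id, Zygosity.MISSING))
                   for m in unaffecteds):
                continue
            merged = {s: z1.get(s, Zygosity.MISSING)
                      for s in set(z1) | set(z2)}
            out.append(CandidateGenotype(
                family_id=pedigree.family_id, gene=gene,
                model=InheritanceModel.AR_COMPHET,
                alleles=[(r1, z1), (r2, z2)],
                phase_unknown=(phase != "trans"),
            ))
    return out


def _xl_candidates(variants, pedigree, panel, config):
    out = []
    affecteds = pedigree.affecteds()
    unaffecteds = pedigree.unaffecteds()
    for rec, zygs in variants:
        gene = panel.get(rec.gene)
        if not _model_compatible_with_gene(InheritanceModel.XL, gene):
            continue
        if rec.chrom.lstrip("chr") != "X":
            continue
        ok = True
        n_known = 0
        for m in affecteds:
            z = zygs.get(m.member_id, Zygosity.MISSING)
            if z is Zygosity.MISSING:
                continue
            n_known += 1
            if m.sex is Sex.MALE:
                if z not in (Zygosity.HEMIZYGOUS, Zygosity.HOM_ALT):
                    ok = False
            else:  # affected female: homozygous alternate accepted
                if z is not Zygosity.HOM_ALT:
                    ok = False
        if not ok or n_known == 0:
            continue
        for m in unaffecteds:
            z = zygs.get(m.member_id, Zygosity.MISSING)
            if m.sex is Sex.MALE and z in (Zygosity.HEMIZYGOUS, Zygosity.HOM_ALT):
                ok = False
        if not ok:
            continue
        out.append(CandidateGenotype(
            family_id=pedigree.family_id, gene=rec.gene,
            model=InheritanceModel.XL, alleles=[(rec, zygs)],
        ))
    return out


_MODEL_BUILDERS = {
    InheritanceModel.AD: _ad_candidates,
    InheritanceModel.AR_HOM: _ar_hom_candidates,
    InheritanceModel.AR_COMPHET: _comphet_candidates,
    InheritanceModel.XL: _xl_candidates,
}


def candidate_genotypes(variant_calls, pedigree: Pedigree, panel: GenePanel,
                        model: InheritanceModel,
                        config: PrioritizationConfig | None = None
                        ) -> list[CandidateGenotype]:
    """Genotype configurations compatible with ``model`` in this family.

    ``variant_calls`` is a list of ``(VariantRecord, {member_id:
    Zygosity | GenotypeCall})`` as returned by :func:`irdx.io.read_vcf`,
    already frequency/consequence filtered.  Every returned candidate
    carries a cosegregation verdict.
    """
    config = config or PrioritizationConfig()
    variants = _normalise_calls(variant_calls)
    ped_ids = set(pedigree.member_ids)
    for rec, zygs in variants:
        stray = set(zygs) - ped_ids
        if stray:
            raise ValueError(f"genotyped sample(s) {sorted(stray)} not in "
                             f"pedigree {pedigree.family_id}")
    candidates = _MODEL_BUILDERS[model](variants, pedigree, panel, config)
    for cand in candidates:
        cand.cosegregation = check_cosegregation(cand, pedigree)
    return candidates


def check_cosegregation(candidate: CandidateGenotype,
                        pedigree: Pedigree) -> Cosegregation:
    """Cosegregation verdict for a built candidate genotype.

    ``unavailable`` when no relative beyond the index case is genotyped;
    ``inconsistent`` when an unaffected relative carries the complete
    causal genotype (the incomplete-penetrance configuration);
    ``consistent`` otherwise.
    """
    affecteds = pedigree.affecteds()
    index_id = affecteds[0].member_id if affecteds else None

    def typed(member_id):
        return all(
            zygs.get(member_id, Zygosity.MISSING) is not Zygosity.MISSING
            for _, zygs in candidate.alleles
        )

    informative = [m for m in pedigree.members
                   if m.member_id != index_id and typed(m.member_id)]
    if not informative:
        return Cosegregation.UNAVAILABLE

    for m in pedigree.unaffecteds():
        if not typed(m.member_id):
            continue
        if _carries_full_genotype(candidate, m):
            return Cosegregation.INCONSISTENT
    return Cosegregation.CONSISTENT


def _carries_full_genotype(candidate: CandidateGenotype,
                           member) -> bool:
    model = candidate.model
    zyg_of = [zygs.get(member.member_id, Zygosity.MISSING)
              for _, zygs in candidate.alleles]
    if model is InheritanceModel.AD:
        return _carries(zyg_of[0])
    if model is InheritanceModel.AR_HOM:
        return zyg_of[0] is Zygosity.HOM_ALT
    if model is InheritanceModel.AR_COMPHET:
        return all(_carries(z) for z in zyg_of)
    if model is InheritanceModel.XL:
        z = zyg_of[0]
        if member.sex is Sex.MALE:
            return z in (Zygosity.HEMIZYGOUS, Zygosity.HOM_ALT)
        return z is Zygosity.HOM_ALT
    raise AssertionError(model)


def find_candidates(variant_calls, pedigree: Pedigree, panel: GenePanel,
                    config: PrioritizationConfig | None = None,
                    models: list[InheritanceModel] | None = None
                    ) -> list[CandidateGenotype]:
    """Prioritize records and build candidates under every plausible model."""
    config = config or PrioritizationConfig()
    records = prioritize_records([r for r, _ in variant_calls], config)
    keep = {r.key() for r in records}
    filtered_calls = [(r, c) for r, c in variant_calls if r.key() in keep]
    out = []
    for model in (models or models_for_pedigree(pedigree)):
        out.extend(candidate_genotypes(filtered_calls, pedigree, panel,
                                       model, config))
    return out
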