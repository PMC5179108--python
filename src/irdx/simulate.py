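"""Synthetic IRD cohorts with known ground truth.

The generator emulates the statistical structure the diagnostic
pipeline assumes: families with dominant, recessive (homozygous or
compound-heterozygous), X-linked and simplex structures; planted causal
SNVs/indels and exon-level CNVs; background rare variants drawn from a
long-tailed frequency spectrum; per-tool predictor outputs drawn from a
truth-conditioned error model; modifier alleles at the cohort's
published per-patient rates; and noisy exon coverage and MLPA ratios
for CNV families.  Everything is deterministic given the seed, and a
truth table records each family's planted genotype and expected
diagnostic status.

A miniature synthetic genome is used: panel genes are laid out on
contigs chr1..chr22/chrX with 1-30 exons each; no real reference is
required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import (
    Affection,
    Consequence,
    DiagnosticStatus,
    ExonCoverageMatrix,
    GeneAssociation,
    GenePanel,
    InheritanceModel,
    PanelGene,
    Pedigree,
    PedigreeMember,
    PredictionProfile,
    Reported,
    Sex,
    VariantRecord,
    Zygosity,
    FrequencyStatus,
)
from .io import (
    write_coverage_matrix,
    write_panel,
    write_ped,
    write_vcf,
)

EXAC_AN_DEFAULT = 121000
CONTROL_SAMPLES = ("CTRL1", "CTRL2", "CTRL3")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated cohort.

    The default family mix mirrors the modelled cohort: 14 simplex,
    4 dominant, 14 recessive and 1 X-linked family, and the default
    diagnostic-outcome mix mirrors its yield (18 solved, 10 candidate,
    5 unsolved of 33).  Modifier alleles are planted at the published
    per-patient means (0.3 known recessive, 5.25 rare predicted
    pathogenic).  Causal alleles are drawn from the frequency range the
    cohort's causal alleles actually span (absent .. ~2e-3), background
    alleles from a broader long-tail spectrum that deliberately crosses
    the 1% filter boundary.
    """

    n_families: int = 33
    model_mix: tuple = (("simplex", 14), ("AD", 4), ("AR", 14), ("XL", 1))
    status_mix: tuple = (("solved", 18), ("candidate", 10), ("unsolved", 5))
    panel_size: int = 300
    background_rate: float = 40.0       # mean background variants per family
    causal_absent_frac: float = 0.7
    causal_af_range_novel: tuple = (1e-6, 9e-5)     # unreported causal alleles
    causal_af_range_reported: tuple = (1e-5, 2e-3)  # previously reported ones
    causal_reported_frac: float = 0.3
    causal_common_frac: float = 0.0     # fraction of causal alleles forced >1%
    background_absent_frac: float = 0.6
    background_af_range: tuple = (1e-6, 5e-2)
    predictor_sensitivity: float = 0.9
    predictor_specificity: float = 0.8
    cnv_family_fraction: float = 0.15
    coverage_cv: float = 0.10
    mlpa_noise_sd: float = 0.05
    modifier_known_rate: float = 0.3
    modifier_predicted_rate: float = 5.25
    penetrance: float = 1.0
    seed: int = 0

    def noiseless(self) -> "SimConfig":
        """The same cohort with perfect predictors and no measurement noise."""
        return replace(self, predictor_sensitivity=1.0,
                       predictor_specificity=1.0, coverage_cv=0.0,
                       mlpa_noise_sd=0.0, penetrance=1.0)


@dataclass
class FamilyTruth:
    family_id: str
    scenario: str
    model: InheritanceModel | None
    gene: str | None
    allele_keys: tuple
    has_cnv: bool
    expected_status: DiagnosticStatus


@dataclass
class FamilyData:
    family_id: str
    pedigree: Pedigree
    variant_calls: list            # [(VariantRecord, {member: Zygosity})]
    coverage: dict = field(default_factory=dict)   # gene -> ExonCoverageMatrix
    mlpa: list = field(default_factory=list)       # [(probe, ratio)]
    truth: FamilyTruth | None = None

    @property
    def proband(self) -> str:
        return self.pedigree.affecteds()[0].member_id


@dataclass
class Cohort:
    config: SimConfig
    panel: GenePanel
    gene_layout: dict              # gene -> (chrom, base_pos, n_exons)
    families: list[FamilyData]

    @property
    def truth(self) -> list[FamilyTruth]:
        return [f.truth for f in self.families]


# ---------------------------------------------------------------------------
# Panel / genome construction

def build_panel(rng: np.random.Generator, panel_size: int) -> tuple[GenePanel, dict]:
    """The shipped panel genes plus synthetic filler genes, with a layout."""
    from .fixture import _data_path
    from .io import load_panel

    genes = dict(load_panel(_data_path("panel.tsv")).genes)
    i = 0
    while len(genes) < panel_size:
        i += 1
        symbol = f"SIMG{i:03d}"
        r = rng.random()
        if r < 0.60:
            modes, assoc = frozenset({"AR"}), GeneAssociation.ESTABLISHED_IRD
        elif r < 0.75:
            modes, assoc = frozenset({"AD"}), GeneAssociation.ESTABLISHED_IRD
        elif r < 0.85:
            modes, assoc = frozenset({"AD", "AR"}), GeneAssociation.ESTABLISHED_IRD
        elif r < 0.90:
            modes, assoc = frozenset({"XL"}), GeneAssociation.ESTABLISHED_IRD
        elif r < 0.95:
            modes, assoc = frozenset({"AR"}), GeneAssociation.ESTABLISHED_SYNDROMIC
        else:
            modes, assoc = frozenset({"AR"}), GeneAssociation.CANDIDATE_GENE
        chrom = "chrX" if "XL" in modes else f"chr{int(rng.integers(1, 23))}"
        genes[symbol] = PanelGene(symbol=symbol, association=assoc,
                                  inheritance_modes=modes,
                                  lof_mechanism=bool(rng.random() < 0.8),
                                  chrom=chrom)
    layout = {}
    per_chrom: dict[str, int] = {}
    for symbol, g in genes.items():
        idx = per_chrom.get(g.chrom, 0) + 1
        per_chrom[g.chrom] = idx
        layout[symbol] = (g.chrom, idx * 1_000_000,
                          int(rng.integers(1, 31)))
    return GenePanel(genes), layout


# ---------------------------------------------------------------------------
# Pedigrees

def _make_pedigree(fid: str, structure: str, rng: np.random.Generator,
                   carrier_sib: bool) -> Pedigree:
    P = PedigreeMember
    if structure == "simplex":
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        return Pedigree(fid, [P(f"{fid}_II1", sex, Affection.AFFECTED)])
    if structure == "AD":
        return Pedigree(fid, [
            P(f"{fid}_I1", Sex.MALE, Affection.AFFECTED),
            P(f"{fid}_I2", Sex.FEMALE, Affection.UNAFFECTED),
            P(f"{fid}_II1", Sex.FEMALE, Affection.AFFECTED,
              father_id=f"{fid}_I1", mother_id=f"{fid}_I2"),
            P(f"{fid}_II2", Sex.MALE, Affection.UNAFFECTED,
              father_id=f"{fid}_I1", mother_id=f"{fid}_I2"),
        ])
    if structure == "AR":
        return Pedigree(fid, [
            P(f"{fid}_I1", Sex.MALE, Affection.UNAFFECTED),
            P(f"{fid}_I2", Sex.FEMALE, Affection.UNAFFECTED),
            P(f"{fid}_II1", Sex.FEMALE, Affection.AFFECTED,
              father_id=f"{fid}_I1", mother_id=f"{fid}_I2"),
            P(f"{fid}_II2", Sex.MALE, Affection.AFFECTED,
              father_id=f"{fid}_I1", mother_id=f"{fid}_I2"),
            P(f"{fid}_II3", Sex.MALE, Affection.UNAFFECTED,
              father_id=f"{fid}_I1", mother_id=f"{fid}_I2"),
        ])
    if structure == "XL":
        return Pedigree(fid, [
            P(f"{fid}_I1", Sex.MALE, Affection.UNAFFECTED),
            P(f"{fid}_I2", Sex.FEMALE, Affection.UNAFFECTED),
            P(f"{fid}_II1", Sex.MALE, Affection.AFFECTED,
              father_id=f"{fid}_I1", mother_id=f"{fid}_I2"),
            P(f"{fid}_II2", Sex.MALE, Affection.AFFECTED,
              father_id=f"{fid}_I1", mother_id=f"{fid}_I2"),
        ])
    raise ValueError(structure)


# ---------------------------------------------------------------------------
# Variant fabrication

_BASES = ("A", "C", "G", "T")


def _draw_predictions(rng, pathogenic: bool, cfg: SimConfig,
                      null_like: bool) -> PredictionProfile:
    p_pos = cfg.predictor_sensitivity if pathogenic else 1 - cfg.predictor_specificity

    def pos() -> bool:
        return bool(rng.random() < p_pos)

    mt = "Disease C." if pos() else "Polymorphism"
    cadd = float(np.round(rng.uniform(20, 40) if pos() else rng.uniform(0, 10), 2))
    if null_like:
        # truncating alleles typically lack PolyPhen2/SIFT output
        return PredictionProfile(mutationtaster_call=mt, cadd_phred=cadd)
    pp2 = "Probably D." if pos() else "Benign"
    sift = "Damaging" if pos() else "Tolerated"
    return PredictionProfile(polyphen2_call=pp2, sift_call=sift,
                             mutationtaster_call=mt, cadd_phred=cadd)


def _draw_af(rng, absent_frac: float, af_range: tuple) -> tuple:
    if rng.random() < absent_frac:
        return FrequencyStatus.ABSENT, 0, 0
    lo, hi = af_range
    f = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    ac = max(1, round(f * EXAC_AN_DEFAULT))
    return FrequencyStatus.OBSERVED, ac, EXAC_AN_DEFAULT


def _common_af(rng) -> tuple:
    f = float(rng.uniform(0.02, 0.10))
    return FrequencyStatus.OBSERVED, round(f * EXAC_AN_DEFAULT), EXAC_AN_DEFAULT


class _VariantFactory:
    """Fabricates annotated variants at unique positions within genes."""

    def __init__(self, rng, cfg: SimConfig, layout: dict):
        self.rng = rng
        self.cfg = cfg
        self.layout = layout
        self._offsets: dict[str, int] = {}

    def _site(self, gene: str) -> tuple[str, int, str, str]:
        chrom, base, _ = self.layout[gene]
        off = self._offsets.get(gene, 0) + int(self.rng.integers(1, 50))
        self._offsets[gene] = off
        ref, alt = self.rng.choice(_BASES, size=2, replace=False)
        return chrom, base + off, str(ref), str(alt)

    def snv(self, gene: str, consequence: Consequence, pathogenic: bool,
            reported: bool = False, common: bool = False,
            cap_rare: bool = False) -> VariantRecord:
        """``cap_rare`` keeps a reported causal allele below the moderate
        rarity ceiling (used where neither cosegregation nor a trans
        partner could otherwise support it)."""
        chrom, pos, ref, alt = self._site(gene)
        if common:
            status, ac, an = _common_af(self.rng)
        elif pathogenic or reported:
            if reported and not cap_rare:
                af_range = self.cfg.causal_af_range_reported
            else:
                af_range = self.cfg.causal_af_range_novel
            status, ac, an = _draw_af(self.rng, self.cfg.causal_absent_frac,
                                      af_range)
        else:
            status, ac, an = _draw_af(self.rng, self.cfg.background_absent_frac,
                                      self.cfg.background_af_range)
        null_like = consequence is not Consequence.MISSENSE
        preds = (PredictionProfile() if consequence in
                 (Consequence.SYNONYMOUS, Consequence.DEEP_INTRONIC,
                  Consequence.OTHER)
                 else _draw_predictions(self.rng, pathogenic, self.cfg,
                                        null_like))
        return VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            consequence=consequence,
            hgvs=f"{gene} g.{pos}{ref}>{alt}",
            exac_status=status, exac_ac=ac, exac_an=an,
            reported=(Reported.REPORTED_PATHOGENIC if reported
                      else Reported.NOVEL),
            predictions=preds,
        )

    def cnv_record(self, gene: str) -> VariantRecord:
        chrom, base, _ = self.layout[gene]
        return VariantRecord(
            chrom=chrom, pos=base, ref="N", alt="<DEL>", gene=gene,
            consequence=Consequence.EXONIC_DELETION,
            hgvs=f"{gene} exon deletion",
            exac_status=FrequencyStatus.ABSENT,
        )


def cnv_record_from_call(call, layout_or_pos) -> VariantRecord:
    """Canonical variant record for a depth-based CNV call.

    ``layout_or_pos`` is either a gene-layout dict or the base position.
    The record key depends only on the gene, so noisy exon boundaries do
    not change candidate identity.
    """
    from .core import CnvState

    if isinstance(layout_or_pos, dict):
        pos = layout_or_pos[call.gene][1]
        chrom = layout_or_pos[call.gene][0]
    else:
        chrom, pos = "chr0", layout_or_pos
    alt = "<DEL>" if call.state is CnvState.HET_DELETION else "<DUP>"
    csq = (Consequence.EXONIC_DELETION if call.state is CnvState.HET_DELETION
           else Consequence.EXONIC_DUPLICATION)
    return VariantRecord(
        chrom=chrom, pos=pos, ref="N", alt=alt, gene=call.gene,
        consequence=csq,
        hgvs=f"{call.gene} exons {call.exon_start}-{call.exon_end} "
             f"{'deletion' if alt == '<DEL>' else 'duplication'}",
        exac_status=FrequencyStatus.ABSENT,
    )


# ---------------------------------------------------------------------------
# Cohort assembly

def _null_consequence(rng) -> Consequence:
    return [Consequence.FRAMESHIFT, Consequence.NONSENSE,
            Consequence.CANONICAL_SPLICE][int(rng.integers(0, 3))]


def _pick_gene(rng, panel: GenePanel, mode: str,
               association=None, lof: bool | None = None,
               exclude: set | None = None,
               established_only: bool = False) -> str:
    exclude = exclude or set()
    pool = [
        s for s, g in panel.genes.items()
        if mode in g.inheritance_modes and s not in exclude
        and (association is None or g.association is association)
        and (not established_only
             or g.association is not GeneAssociation.CANDIDATE_GENE)
        and (lof is None or g.lof_mechanism is lof)
    ]
    if not pool:
        raise ValueError(f"no panel gene available for mode={mode}")
    return pool[int(rng.integers(0, len(pool)))]


def _assign_genotypes(ped: Pedigree, model: InheritanceModel,
                      alleles: list[VariantRecord], rng,
                      penetrance: float) -> list:
    """Mendel-consistent member genotypes for the planted genotype."""
    Z = Zygosity
    members = ped.members
    affect = {m.member_id: m.affection for m in members}
    sex = {m.member_id: m.sex for m in members}
    parents = {m.member_id: (m.father_id, m.mother_id) for m in members}
    founders = [m.member_id for m in members
                if m.father_id is None and m.mother_id is None]
    out = []

    def base_calls(default=Z.HOM_REF):
        return {m.member_id: default for m in members}

    if model is InheritanceModel.AD:
        calls = base_calls()
        for mid in affect:
            if affect[mid] is Affection.AFFECTED:
                calls[mid] = Z.HET
        if penetrance < 1.0:
            carriers = [mid for mid in affect
                        if affect[mid] is Affection.UNAFFECTED
                        and rng.random() > penetrance]
            for mid in carriers[:1]:
                calls[mid] = Z.HET
        out.append((alleles[0], calls))
    elif model is InheritanceModel.AR_HOM:
        calls = base_calls()
        for mid in affect:
            if affect[mid] is Affection.AFFECTED:
                calls[mid] = Z.HOM_ALT
            elif mid in founders or parents[mid][0] is not None:
                calls[mid] = Z.HET  # obligate/typical carriers
        out.append((alleles[0], calls))
    elif model is InheritanceModel.AR_COMPHET:
        c1, c2 = base_calls(), base_calls()
        fathers = {parents[mid][0] for mid in affect
                   if affect[mid] is Affection.AFFECTED} - {None}
        mothers = {parents[mid][1] for mid in affect
                   if affect[mid] is Affection.AFFECTED} - {None}
        for mid in affect:
            if affect[mid] is Affection.AFFECTED:
                c1[mid] = Z.HET
                c2[mid] = Z.HET
        for f in fathers:
            c1[f] = Z.HET
        for m in mothers:
            c2[m] = Z.HET
        out.append((alleles[0], c1))
        out.append((alleles[1], c2))
    elif model is InheritanceModel.XL:
        calls = base_calls()
        for mid in affect:
            if affect[mid] is Affection.AFFECTED:
                calls[mid] = Z.HEMIZYGOUS if sex[mid] is Sex.MALE else Z.HOM_ALT
            elif sex[mid] is Sex.FEMALE and parents[mid][0] is None:
                calls[mid] = Z.HET  # carrier mother
        out.append((alleles[0], calls))
    else:
        raise AssertionError(model)
    return out


_SIMPLEX_MODEL_WEIGHTS = (
    (InheritanceModel.AR_HOM, 0.40),
    (InheritanceModel.AR_COMPHET, 0.40),
    (InheritanceModel.AD, 0.15),
    (InheritanceModel.XL, 0.05),
)


def _counts_for_mix(mix: tuple, n: int, rng) -> list[str]:
    """Expand a (label, count) mix to exactly n labels, scaled and shuffled."""
    total = sum(c for _, c in mix)
    out = []
    for label, c in mix:
        out.extend([label] * round(n * c / total))
    while len(out) < n:
        out.append(mix[int(rng.integers(0, len(mix)))][0])
    out = out[:n]
    rng.shuffle(out)
    return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort with ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    panel, layout = build_panel(rng, config.panel_size)
    factory = _VariantFactory(rng, config, layout)

    structures = _counts_for_mix(config.model_mix, config.n_families, rng)
    statuses = _counts_for_mix(config.status_mix, config.n_families, rng)

    families = []
    for k in range(config.n_families):
        fid = f"F{k + 1:04d}"
        structure = structures[k]
        intent = statuses[k]

        if structure == "simplex":
            r = rng.random()
            acc = 0.0
            model = InheritanceModel.AR_HOM
            for m, w in _SIMPLEX_MODEL_WEIGHTS:
                acc += w
                if r < acc:
                    model = m
                    break
        else:
            model = {"AD": InheritanceModel.AD,
                     "AR": (InheritanceModel.AR_HOM if rng.random() < 0.5
                            else InheritanceModel.AR_COMPHET),
                     "XL": InheritanceModel.XL}[structure]

        ped = _make_pedigree(fid, structure, rng,
                             carrier_sib=config.penetrance < 1.0)
        if model is InheritanceModel.XL:
            # ensure the affected members are male
            ped = _make_pedigree(fid, "simplex" if structure == "simplex"
                                 else "XL", rng, False)
            if structure == "simplex":
                ped = Pedigree(fid, [PedigreeMember(
                    f"{fid}_II1", Sex.MALE, Affection.AFFECTED)])

        calls = []
        coverage: dict = {}
        mlpa: list = []
        truth_gene = None
        truth_keys: tuple = ()
        has_cnv = False
        scenario = "none"
        expected = DiagnosticStatus.UNSOLVED
        causal_gene_excl: set = set()

        if intent != "unsolved":
            mode = {InheritanceModel.AD: "AD", InheritanceModel.AR_HOM: "AR",
                    InheritanceModel.AR_COMPHET: "AR",
                    InheritanceModel.XL: "XL"}[model]
            if intent == "solved":
                gene = _pick_gene(rng, panel, mode, lof=True,
                                  established_only=True)
                n_alleles = 2 if model is InheritanceModel.AR_COMPHET else 1
                use_cnv = (rng.random() < config.cnv_family_fraction
                           and model in (InheritanceModel.AD,
                                         InheritanceModel.AR_COMPHET)
                           and layout[gene][2] >= 4)
                # a reported allele above the rarity ceiling is only
                # classifiable with segregation or trans support
                cap = (structure == "simplex"
                       and model is not InheritanceModel.AR_COMPHET)
                alleles = []
                for ai in range(n_alleles):
                    if use_cnv and ai == n_alleles - 1:
                        alleles.append(factory.cnv_record(gene))
                        has_cnv = True
                    else:
                        alleles.append(factory.snv(
                            gene, _null_consequence(rng), pathogenic=True,
                            reported=rng.random() < config.causal_reported_frac,
                            cap_rare=cap,
                            common=rng.random() < config.causal_common_frac))
                scenario = ("null_" + model.value
                            + ("_cnv" if has_cnv else ""))
            else:  # candidate intent
                if (model in (InheritanceModel.AR_HOM,)
                        and rng.random() < 0.4):
                    gene = _pick_gene(rng, panel, "AR", lof=True,
                                      association=GeneAssociation.CANDIDATE_GENE)
                    alleles = [factory.snv(
                        gene, _null_consequence(rng), pathogenic=True,
                        common=rng.random() < config.causal_common_frac)]
                    scenario = "candidate_gene_null"
                else:
                    if model is InheritanceModel.AR_COMPHET:
                        model = InheritanceModel.AR_HOM  # missense hom template
                    if model is InheritanceModel.XL:
                        gene = _pick_gene(rng, panel, "XL")
                    elif model is InheritanceModel.AD:
                        gene = _pick_gene(rng, panel, "AD")
                    else:
                        gene = _pick_gene(rng, panel, "AR")
                    alleles = [factory.snv(
                        gene, Consequence.MISSENSE, pathogenic=True,
                        reported=rng.random() < config.causal_reported_frac,
                        common=rng.random() < config.causal_common_frac)]
                    scenario = "missense_" + model.value
            truth_gene = gene
            causal_gene_excl.add(gene)
            geno = _assign_genotypes(ped, model, alleles, rng,
                                     config.penetrance)
            truth_keys = tuple(sorted(v.key() for v, _ in geno))
            # CNV alleles are delivered through the coverage matrix,
            # not the VCF
            for v, zygs in geno:
                if v.consequence is Consequence.EXONIC_DELETION:
                    coverage.update(_make_coverage(
                        rng, config, layout, gene, ped, zygs))
                    mlpa = _make_mlpa(rng, config, layout, gene, zygs,
                                      ped.affecteds()[0].member_id)
                else:
                    calls.append((v, zygs))
            common = any(
                (v.frequency or 0.0) > 0.01 for v, _ in geno)
            unaffected_carrier = any(
                zygs.get(m.member_id) is Zygosity.HET
                for m in ped.unaffecteds() for _, zygs in geno
            ) if model is InheritanceModel.AD else False
            if common:
                expected = DiagnosticStatus.UNSOLVED
            elif intent == "solved":
                # an AD genotype with a non-penetrant carrier can at best
                # be a candidate (cosegregation is inconsistent)
                expected = (DiagnosticStatus.CANDIDATE if unaffected_carrier
                            else DiagnosticStatus.SOLVED)
            else:
                expected = DiagnosticStatus.CANDIDATE

        proband = ped.affecteds()[0].member_id
        member_ids = ped.member_ids

        def het_in_proband(v):
            zygs = {mid: Zygosity.HOM_REF for mid in member_ids}
            zygs[proband] = Zygosity.HET
            return (v, zygs)

        # modifier alleles: known pathogenic recessive + rare predicted,
        # each in a distinct AR-only established gene
        n_known = rng.poisson(config.modifier_known_rate)
        n_pred = rng.poisson(config.modifier_predicted_rate)
        used = set(causal_gene_excl)
        for i in range(n_known + n_pred):
            try:
                g = _pick_gene(rng, panel, "AR",
                               association=GeneAssociation.ESTABLISHED_IRD,
                               exclude=used | {s for s, pg in panel.genes.items()
                                               if "AD" in pg.inheritance_modes
                                               or "XL" in pg.inheritance_modes})
            except ValueError:
                break
            used.add(g)
            if i < n_known:
                v = factory.snv(g, Consequence.MISSENSE, pathogenic=True,
                                reported=True)
            else:
                v = factory.snv(g, Consequence.MISSENSE, pathogenic=True)
            calls.append(het_in_proband(v))

        # background variants: benign, drawn over the whole panel
        genes_list = list(panel.genes)
        for _ in range(rng.poisson(config.background_rate)):
            g = genes_list[int(rng.integers(0, len(genes_list)))]
            r = rng.random()
            if r < 0.30:
                csq = Consequence.SYNONYMOUS
            elif r < 0.80:
                csq = Consequence.MISSENSE
            elif r < 0.90:
                csq = Consequence.DEEP_INTRONIC
            else:
                csq = Consequence.OTHER
            v = factory.snv(g, csq, pathogenic=False)
            zygs = {mid: Zygosity.HOM_REF for mid in member_ids}
            if (panel[g].chrom == "chrX"
                    and ped.member(proband).sex is Sex.MALE):
                zygs[proband] = Zygosity.HEMIZYGOUS
            else:
                zygs[proband] = Zygosity.HET
            calls.append((v, zygs))

        families.append(FamilyData(
            family_id=fid, pedigree=ped, variant_calls=calls,
            coverage=coverage, mlpa=mlpa,
            truth=FamilyTruth(
                family_id=fid, scenario=scenario,
                model=model if intent != "unsolved" else None,
                gene=truth_gene, allele_keys=truth_keys,
                has_cnv=has_cnv, expected_status=expected,
            ),
        ))
    return Cohort(config=config, panel=panel, gene_layout=layout,
                  families=families)


def _make_coverage(rng, config: SimConfig, layout, gene: str,
                   ped: Pedigree, zygs: dict) -> dict:
    """Coverage matrices for the CNV gene and a copy-neutral control gene."""
    chrom, base, n_exons = layout[gene]
    n_exons = max(n_exons, 4)
    del_lo = int(rng.integers(0, n_exons - 1))
    del_hi = min(n_exons - 1, del_lo + int(rng.integers(1, 4)))
    samples = list(ped.member_ids) + list(CONTROL_SAMPLES)
    mean_depth = 60.0

    def noisy(shape):
        if config.coverage_cv <= 0:
            return np.ones(shape)
        return np.clip(rng.normal(1.0, config.coverage_cv, size=shape), 0.0,
                       None)

    exon_factor = rng.uniform(0.6, 1.4, size=n_exons)
    depths = np.empty((n_exons, len(samples)))
    for j, s in enumerate(samples):
        carrier = zygs.get(s) in (Zygosity.HET, Zygosity.HOM_ALT,
                                  Zygosity.HEMIZYGOUS)
        copy = np.ones(n_exons)
        if carrier:
            copy[del_lo:del_hi + 1] = 0.5
        depths[:, j] = mean_depth * exon_factor * copy * noisy(n_exons)
    intervals = [(base + 1000 * e, base + 1000 * e + 150)
                 for e in range(n_exons)]
    target = ExonCoverageMatrix(gene=gene, exon_intervals=intervals,
                                sample_ids=samples, depths=depths)

    # copy-neutral control-gene region for normalization (several genes'
    # worth of exons keeps the per-sample scale estimate tight)
    ctrl_exons = 24
    ctrl_depths = np.empty((ctrl_exons, len(samples)))
    ctrl_factor = rng.uniform(0.6, 1.4, size=ctrl_exons)
    for j in range(len(samples)):
        ctrl_depths[:, j] = mean_depth * ctrl_factor * noisy(ctrl_exons)
    ctrl = ExonCoverageMatrix(
        gene=f"{gene}_CTRLGENE",
        exon_intervals=[(e * 1000 + 1, e * 1000 + 150)
                        for e in range(ctrl_exons)],
        sample_ids=samples, depths=ctrl_depths)
    return {gene: target, ctrl.gene: ctrl}


def _make_mlpa(rng, config: SimConfig, layout, gene: str, zygs: dict,
               proband: str) -> list:
    _, _, n_exons = layout[gene]
    n_exons = max(n_exons, 4)
    carrier = zygs.get(proband) in (Zygosity.HET, Zygosity.HOM_ALT,
                                    Zygosity.HEMIZYGOUS)
    out = []
    for e in range(n_exons):
        expected = 0.5 if (carrier and e < 2) else 1.0
        noise = rng.normal(0, config.mlpa_noise_sd) if config.mlpa_noise_sd else 0.0
        out.append((f"{gene}_ex{e + 1}", max(0.0, expected + noise)))
    return out


def simulate_cnv_gene(rng, n_exons: int = 10, cv: float = 0.10,
                      planted_range: tuple | None = None,
                      n_controls: int = 3, mean_depth: float = 60.0,
                      duplication: bool = False,
                      n_control_exons: int = 40):
    """Coverage matrices for one target gene plus a copy-neutral
    normalization gene (case sample ``CASE`` + control samples).

    ``planted_range`` (0-based inclusive exon indices) plants a
    half-depth deletion (or 1.5x duplication) in the case.  Returns
    ``(target_matrix, control_matrix)``; the control gene anchors the
    per-sample normalization so the CNV cannot bias its own baseline.
    """
    samples = ["CASE"] + [f"CTRL{i + 1}" for i in range(n_controls)]

    def _gene(name, n, copy_profiles):
        exon_factor = rng.uniform(0.6, 1.4, size=n)
        depths = np.empty((n, len(samples)))
        for j, s in enumerate(samples):
            noise = (np.clip(rng.normal(1.0, cv, size=n), 0.0, None)
                     if cv > 0 else np.ones(n))
            depths[:, j] = (mean_depth * exon_factor
                            * copy_profiles.get(s, np.ones(n)) * noise)
        intervals = [(1000 * e + 1, 1000 * e + 150) for e in range(n)]
        return ExonCoverageMatrix(gene=name, exon_intervals=intervals,
                                  sample_ids=samples, depths=depths)

    case_copy = np.ones(n_exons)
    if planted_range is not None:
        lo, hi = planted_range
        case_copy[lo:hi + 1] = 1.5 if duplication else 0.5
    target = _gene("SIMCNV", n_exons, {"CASE": case_copy})
    control = _gene("SIMCNV_CTRLGENE", n_control_exons, {})
    return target, control


# ---------------------------------------------------------------------------
# File emission

def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write the cohort as VCF/PED/TSV files (plus panel and truth table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel(out / "panel.tsv", cohort.panel)
    with open(out / "truth.tsv", "w") as fh:
        fh.write("family\tscenario\tmodel\tgene\thas_cnv\texpected_status\t"
                 "allele_keys\n")
        for t in cohort.truth:
            keys = ";".join(f"{c}:{p}:{r}:{a}" for c, p, r, a in t.allele_keys)
            fh.write(f"{t.family_id}\t{t.scenario}\t"
                     f"{t.model.value if t.model else '.'}\t"
                     f"{t.gene or '.'}\t{int(t.has_cnv)}\t"
                     f"{t.expected_status.value}\t{keys}\n")
    for fam in cohort.families:
        write_ped(out / f"{fam.family_id}.ped", fam.pedigree)
        write_vcf(out / f"{fam.family_id}.vcf", fam.variant_calls,
                  fam.pedigree.member_ids)
        if fam.coverage:
            write_coverage_matrix(out / f"{fam.family_id}_coverage.tsv",
                                  fam.coverage)
        if fam.mlpa:
            with open(out / f"{fam.family_id}_mlpa.tsv", "w") as fh:
                fh.write("probe\tratio\n")
                for probe, ratio in fam.mlpa:
                    fh.write(f"{probe}\t{ratio:.4f}\n")
    return out
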