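"""Domain types shared by every stage of the diagnostic pipeline.

The pipeline reasons about small variants (:class:`VariantRecord`),
structural evidence (:class:`CnvCall`, :class:`DeletionEvidence`),
per-family genotype configurations under one Mendelian model
(:class:`CandidateGenotype`) and the ACMG/AMP evidence attached to each
allele.  Coordinates are 1-based inclusive throughout (VCF convention);
BED input is converted on read.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace


class Consequence(enum.Enum):
    """Molecular consequence class of a variant on its gene."""

    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    NONCANONICAL_SPLICE_REGION = "noncanonical_splice_region"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    DEEP_INTRONIC = "deep_intronic"
    EXONIC_DELETION = "exonic_deletion"
    EXONIC_DUPLICATION = "exonic_duplication"
    OTHER = "other"


#: Consequences treated as protein-disrupting ("null") for PVS1 purposes.
DISRUPTIVE_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.EXONIC_DELETION,
        Consequence.EXONIC_DUPLICATION,
    }
)

#: Consequence classes retained by the default prioritization cascade.
DEFAULT_RETAINED_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.NONCANONICAL_SPLICE_REGION,
        Consequence.MISSENSE,
        Consequence.EXONIC_DELETION,
        Consequence.EXONIC_DUPLICATION,
    }
)


class Reported(enum.Enum):
    NOVEL = "novel"
    REPORTED_PATHOGENIC = "reported_pathogenic"


class Zygosity(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMIZYGOUS = "hemizygous"
    MISSING = "missing"


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class InheritanceModel(enum.Enum):
    AD = "AD"
    AR_HOM = "AR_hom"
    AR_COMPHET = "AR_comphet"
    XL = "XL"


class Cosegregation(enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    UNAVAILABLE = "unavailable"


class GeneAssociation(enum.Enum):
    ESTABLISHED_IRD = "established_IRD"
    ESTABLISHED_SYNDROMIC = "established_syndromic"
    CANDIDATE_GENE = "candidate_gene"


class AcmgClass(enum.Enum):
    """Output classes of the classifier.

    ``VGUS`` (clearly disruptive variant in a gene of uncertain
    significance) is a cohort-specific extension of the standard
    ACMG/AMP five-tier scheme used for candidate genes lacking
    functional support.
    """

    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    VUS = "VUS"
    VGUS = "VGUS"
    BENIGN = "Benign"


class EvidenceStrength(enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE_BENIGN = "stand_alone_benign"


#: Default strength of each ACMG evidence code used by this pipeline.
DEFAULT_CODE_STRENGTH = {
    "PVS1": EvidenceStrength.VERY_STRONG,
    "PS3": EvidenceStrength.STRONG,
    "PM2": EvidenceStrength.MODERATE,
    "PM3": EvidenceStrength.MODERATE,
    "PM3_upgraded_strong": EvidenceStrength.STRONG,
    "PP1": EvidenceStrength.SUPPORTING,
    "PP3": EvidenceStrength.SUPPORTING,
    "PP5_reported": EvidenceStrength.SUPPORTING,
    "BA1": EvidenceStrength.STAND_ALONE_BENIGN,
}


@dataclass(frozen=True)
class AcmgEvidence:
    """A set of ACMG/AMP evidence codes with their strengths."""

    codes: frozenset[str] = frozenset()

    def __post_init__(self):
        unknown = set(self.codes) - set(DEFAULT_CODE_STRENGTH)
        if unknown:
            raise ValueError(f"unknown evidence codes: {sorted(unknown)}")
        object.__setattr__(self, "codes", frozenset(self.codes))

    def strength_counts(self) -> dict[EvidenceStrength, int]:
        counts: dict[EvidenceStrength, int] = {s: 0 for s in EvidenceStrength}
        for code in self.codes:
            counts[DEFAULT_CODE_STRENGTH[code]] += 1
        return counts

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __or__(self, other: "AcmgEvidence") -> "AcmgEvidence":
        return AcmgEvidence(self.codes | other.codes)


class FrequencyStatus(enum.Enum):
    """How a variant relates to the population-frequency reference."""

    ABSENT = "absent"       # screened, not observed -> frequency treated as 0
    OBSERVED = "observed"   # allele count / allele number available
    UNKNOWN = "unknown"     # site not covered by the reference


@dataclass(frozen=True)
class PredictionProfile:
    """In-silico pathogenicity predictor outputs for one variant.

    Each tool may provide a numeric score, a categorical call, both or
    neither; a tool with neither contributes nothing to the consensus.
    Categorical calls are carried verbatim (e.g. ``"Probably D."``,
    ``"Tolerated"``, ``"Disease C."``); when both a call and a score are
    present the call decides positivity.
    """

    polyphen2_call: str | None = None
    polyphen2_score: float | None = None
    sift_call: str | None = None
    sift_score: float | None = None
    mutationtaster_call: str | None = None
    mutationtaster_score: float | None = None
    cadd_phred: float | None = None

    def __post_init__(self):
        for name in ("polyphen2_score", "sift_score", "mutationtaster_score"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be >= 0")

    def is_empty(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in (
                "polyphen2_call", "polyphen2_score", "sift_call",
                "sift_score", "mutationtaster_call",
                "mutationtaster_score", "cadd_phred",
            )
        )


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele at one site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    hgvs: str = ""
    exac_status: FrequencyStatus = FrequencyStatus.ABSENT
    exac_ac: int = 0
    exac_an: int = 0
    reported: Reported = Reported.NOVEL
    predictions: PredictionProfile = field(default_factory=PredictionProfile)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.exac_status is FrequencyStatus.OBSERVED:
            if self.exac_an <= 0:
                raise ValueError("observed frequency requires exac_an > 0")
            if not (0 <= self.exac_ac <= self.exac_an):
                raise ValueError("require 0 <= exac_ac <= exac_an")

    @property
    def frequency(self) -> float | None:
        """ExAC allele frequency; 0.0 when absent, None when unknown."""
        if self.exac_status is FrequencyStatus.ABSENT:
            return 0.0
        if self.exac_status is FrequencyStatus.UNKNOWN:
            return None
        return self.exac_ac / self.exac_an

    @property
    def is_disruptive(self) -> bool:
        return self.consequence in DISRUPTIVE_CONSEQUENCES

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    zygosity: Zygosity


@dataclass(frozen=True)
class PedigreeMember:
    member_id: str
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    father_id: str | None = None
    mother_id: str | None = None


@dataclass
class Pedigree:
    family_id: str
    members: list[PedigreeMember] = field(default_factory=list)
    consanguineous: bool = False

    def __post_init__(self):
        self._validate()

    def _validate(self):
        ids = [m.member_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate member ids in family {self.family_id}")
        known = set(ids)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in known:
                    raise ValueError(
                        f"parent {parent} of {m.member_id} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self):
        by_id = {m.member_id: m for m in self.members}
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in by_id}

        def visit(mid: str):
            color[mid] = GREY
            m = by_id[mid]
            for parent in (m.father_id, m.mother_id):
                if parent is None:
                    continue
                if color[parent] == GREY:
                    raise ValueError(
                        f"cyclic parentage at {parent} in family {self.family_id}"
                    )
                if color[parent] == WHITE:
                    visit(parent)
            color[mid] = BLACK

        for mid in by_id:
            if color[mid] == WHITE:
                visit(mid)

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    def affecteds(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    def unaffecteds(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affection is Affection.UNAFFECTED]

    def is_simplex(self) -> bool:
        return len(self.affecteds()) == 1


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    association: GeneAssociation
    inheritance_modes: frozenset[str]  # subset of {"AD", "AR", "XL"}
    lof_mechanism: bool = False
    chrom: str = ""

    def __post_init__(self):
        bad = set(self.inheritance_modes) - {"AD", "AR", "XL"}
        if bad:
            raise ValueError(f"unknown inheritance modes: {sorted(bad)}")


@dataclass
class GenePanel:
    genes: dict[str, PanelGene] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, genes) -> "GenePanel":
        return cls({g.symbol: g for g in genes})

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, symbol: str) -> PanelGene | None:
        return self.genes.get(symbol)

    def __getitem__(self, symbol: str) -> PanelGene:
        return self.genes[symbol]


@dataclass
class ExonCoverageMatrix:
    """Mean read depth per exon (rows, in genomic order) per sample (columns)."""

    gene: str
    exon_intervals: list[tuple[int, int]]  # 1-based inclusive
    sample_ids: list[str]
    depths: "object"  # numpy array, shape (n_exons, n_samples)

    def __post_init__(self):
        import numpy as np

        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.shape != (len(self.exon_intervals), len(self.sample_ids)):
            raise ValueError("depth matrix shape does not match exons x samples")
        if (self.depths < 0).any():
            raise ValueError("depths must be >= 0")
        for (s1, e1), (s2, e2) in zip(self.exon_intervals, self.exon_intervals[1:]):
            if s2 <= s1:
                raise ValueError("exon intervals must follow genomic order")


class CnvState(enum.Enum):
    HET_DELETION = "het_deletion"
    DUPLICATION = "duplication"
    NORMAL = "normal"


@dataclass(frozen=True)
class CnvCall:
    gene: str
    state: CnvState
    exon_start: int | None = None  # 1-based exon index, inclusive
    exon_end: int | None = None
    ratios: tuple[float, ...] = ()
    supporting_exons: int = 0
    low_confidence: bool = False

    def __post_init__(self):
        if self.state is not CnvState.NORMAL:
            if self.exon_start is None or self.exon_end is None:
                raise ValueError("non-normal CNV call requires an exon range")
            if self.exon_end < self.exon_start:
                raise ValueError("exon range must be contiguous and ordered")


class MlpaState(enum.Enum):
    DELETION = "deletion"
    NORMAL = "normal"
    DUPLICATION = "duplication"


@dataclass(frozen=True)
class MLPAProbeResult:
    probe: str
    ratio: float
    call: MlpaState

    def __post_init__(self):
        if self.ratio < 0 or math.isnan(self.ratio):
            raise ValueError(f"probe ratio must be >= 0, got {self.ratio}")


class SnpDeletionFlag(enum.Enum):
    DELETION_SUPPORTING = "deletion_supporting"
    NON_DELETED = "non_deleted"
    UNINFORMATIVE = "uninformative"


@dataclass
class DeletionEvidence:
    """Trio-SNP evidence for a hemizygosity-revealing deletion."""

    loci: list[int]  # ordered positions
    flags: list[SnpDeletionFlag]
    breakpoint_interval: tuple[int, int] | None  # positions of flanking non-deleted loci

    @property
    def n_supporting(self) -> int:
        return sum(f is SnpDeletionFlag.DELETION_SUPPORTING for f in self.flags)


@dataclass
class CandidateGenotype:
    """A per-family, per-gene genotype configuration under one model.

    ``alleles`` holds one entry per causal allele: the variant and the
    genotype of every typed member.  This is the unit that gets ACMG
    evidence, a class per allele, and finally a diagnostic verdict.
    """

    family_id: str
    gene: str
    model: InheritanceModel
    alleles: list[tuple[VariantRecord, dict[str, Zygosity]]]
    cosegregation: Cosegregation = Cosegregation.UNAVAILABLE
    phase_unknown: bool = False
    functional_support: bool = False

    def __post_init__(self):
        n = len(self.alleles)
        if self.model is InheritanceModel.AR_COMPHET:
            if n != 2:
                raise ValueError("compound het requires exactly 2 alleles")
            if self.alleles[0][0].key() == self.alleles[1][0].key():
                raise ValueError("compound het alleles must be distinct")
        elif n != 1:
            raise ValueError(f"{self.model.value} genotype requires exactly 1 allele")

    @property
    def variants(self) -> list[VariantRecord]:
        return [v for v, _ in self.alleles]


@dataclass
class ClassifiedAllele:
    variant: VariantRecord
    evidence: AcmgEvidence
    acmg_class: AcmgClass
    conflict: bool = False


@dataclass
class ClassifiedGenotype:
    candidate: CandidateGenotype
    alleles: list[ClassifiedAllele]


class DiagnosticStatus(enum.Enum):
    SOLVED = "solved"
    CANDIDATE = "candidate"
    UNSOLVED = "unsolved"


@dataclass
class FamilyReport:
    family_id: str
    status: DiagnosticStatus
    causative: ClassifiedGenotype | None = None
    modifiers: list[VariantRecord] = field(default_factory=list)
    notes: str = ""


@dataclass
class CohortSummary:
    n_solved: int
    n_candidate: int
    n_unsolved: int

    @property
    def n_families(self) -> int:
        return self.n_solved + self.n_candidate + self.n_unsolved

    @property
    def frac_solved(self) -> float:
        return self.n_solved / self.n_families if self.n_families else 0.0

    @property
    def frac_candidate(self) -> float:
        return self.n_candidate / self.n_families if self.n_families else 0.0

    @property
    def pct_solved(self) -> int:
        return round(100 * self.frac_solved)

    @property
    def pct_candidate(self) -> int:
        return round(100 * self.frac_candidate)


def warn(msg: str):
    warnings.warn(msg, stacklevel=2)


__all__ = [name for name in dir() if not name.startswith("_")]
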