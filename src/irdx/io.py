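"""Readers and writers for the standard formats the pipeline touches.

Variant input is VCF 4.2 read through :mod:`cyvcf2`, with the annotation
fields this pipeline needs (gene, consequence class, ExAC counts,
predictor outputs) carried in INFO.  Pedigrees use the PLINK 6-column
PED dialect.  Gene panels, exon-coverage matrices and MLPA probe ratios
are TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .core import (
    Affection,
    Consequence,
    ExonCoverageMatrix,
    FrequencyStatus,
    GenePanel,
    GenotypeCall,
    PanelGene,
    Pedigree,
    PedigreeMember,
    PredictionProfile,
    Reported,
    Sex,
    VariantRecord,
    Zygosity,
    GeneAssociation,
    warn,
)

# ---------------------------------------------------------------------------
# VCF

#: INFO keys used for annotation (Number=A; one entry per alt allele).
_INFO_KEYS = (
    "GENE", "CSQ", "EXAC_AC", "EXAC_AN", "REPORTED",
    "PP2_CALL", "PP2_SCORE", "SIFT_CALL", "SIFT_SCORE",
    "MT_CALL", "MT_SCORE", "CADD",
)

_CONTIG_LINES = "\n".join(
    f"##contig=<ID=chr{c}>" for c in [*range(1, 23), "X", "Y", "0"])

_VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
""" + _CONTIG_LINES + """
##INFO=<ID=GENE,Number=A,Type=String,Description="Panel gene symbol">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence class">
##INFO=<ID=EXAC_AC,Number=A,Type=String,Description="ExAC allele count, 'absent' or 'unknown'">
##INFO=<ID=EXAC_AN,Number=A,Type=String,Description="ExAC allele number">
##INFO=<ID=REPORTED,Number=A,Type=String,Description="novel or reported_pathogenic">
##INFO=<ID=PP2_CALL,Number=A,Type=String,Description="PolyPhen2 categorical call">
##INFO=<ID=PP2_SCORE,Number=A,Type=String,Description="PolyPhen2 score">
##INFO=<ID=SIFT_CALL,Number=A,Type=String,Description="SIFT categorical call">
##INFO=<ID=SIFT_SCORE,Number=A,Type=String,Description="SIFT score">
##INFO=<ID=MT_CALL,Number=A,Type=String,Description="MutationTaster categorical call">
##INFO=<ID=MT_SCORE,Number=A,Type=String,Description="MutationTaster score">
##INFO=<ID=CADD,Number=A,Type=String,Description="CADD phred score">
##INFO=<ID=HGVS,Number=A,Type=String,Description="Display name">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""

# Spaces are not legal inside INFO values; categorical predictor calls
# such as "Probably D." are transported with '_' in place of ' '.


def _encode_info_token(value: str) -> str:
    return value.replace(" ", "_") if value else "."


def _decode_info_token(value: str | None) -> str | None:
    if value in (None, ".", ""):
        return None
    return value.replace("_", " ")


def _split_per_alt(raw, n_alt: int) -> list[str | None]:
    """Split a Number=A INFO value into one token per alt allele."""
    if raw is None:
        return [None] * n_alt
    if isinstance(raw, (tuple, list)):
        parts = [str(x) for x in raw]
    else:
        parts = str(raw).split(",")
    if len(parts) != n_alt:
        parts = (parts + [None] * n_alt)[:n_alt]
    return [None if p in (".", "", None) else p for p in parts]


def _zygosity_from_indices(indices: list[int], alt_index: int, chrom: str,
                           sex: Sex) -> Zygosity:
    if any(i < 0 for i in indices) or not indices:
        return Zygosity.MISSING
    n_alt = sum(i == alt_index for i in indices)
    if len(indices) == 1:
        if n_alt == 1:
            return Zygosity.HEMIZYGOUS
        return Zygosity.HOM_REF
    if n_alt == 2:
        if chrom.lstrip("chr") in ("X", "Y") and sex is Sex.MALE:
            return Zygosity.HEMIZYGOUS
        return Zygosity.HOM_ALT
    if n_alt == 1:
        return Zygosity.HET
    return Zygosity.HOM_REF


def read_vcf(path, pedigree: Pedigree):
    """Read an annotated multi-sample VCF into variant records.

    Returns a list of ``(VariantRecord, {member_id: GenotypeCall})``, one
    entry per alternate allele (multi-allelic sites are decomposed).

    Raises ``ValueError`` when a pedigree member is missing from the VCF
    header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [m for m in pedigree.member_ids if m not in samples]
    if missing:
        raise ValueError(
            f"pedigree member(s) {missing} of family {pedigree.family_id} "
            f"missing from VCF {path}"
        )
    sample_idx = {s: i for i, s in enumerate(samples)}
    sexes = {m.member_id: m.sex for m in pedigree.members}

    out = []
    for v in vcf:
        alts = list(v.ALT)
        n_alt = len(alts)
        info = {k: _split_per_alt(v.INFO.get(k), n_alt) for k in _INFO_KEYS}
        hgvs = _split_per_alt(v.INFO.get("HGVS"), n_alt)
        genotypes = v.genotypes  # [[a1, a2, phased], ...] or [[a, phased], ...]
        for ai, alt in enumerate(alts):
            rec = _record_from_info(v.CHROM, v.POS, v.REF, alt,
                                    {k: info[k][ai] for k in _INFO_KEYS},
                                    hgvs[ai])
            calls = {}
            for member in pedigree.members:
                g = genotypes[sample_idx[member.member_id]]
                indices = [int(x) for x in g[:-1]]
                zyg = _zygosity_from_indices(indices, ai + 1, v.CHROM,
                                             sexes[member.member_id])
                calls[member.member_id] = GenotypeCall(member.member_id, zyg)
            out.append((rec, calls))
    return out


def _record_from_info(chrom, pos, ref, alt, info: dict, hgvs) -> VariantRecord:
    gene = info["GENE"] or ""
    try:
        csq = Consequence(info["CSQ"]) if info["CSQ"] else Consequence.OTHER
    except ValueError:
        csq = Consequence.OTHER
    ac_raw = info["EXAC_AC"]
    if ac_raw in (None, "absent"):
        status, ac, an = FrequencyStatus.ABSENT, 0, 0
    elif ac_raw == "unknown":
        status, ac, an = FrequencyStatus.UNKNOWN, 0, 0
    else:
        status = FrequencyStatus.OBSERVED
        ac = int(ac_raw)
        an = int(info["EXAC_AN"]) if info["EXAC_AN"] else 0
        if an <= 0:
            warn(f"{chrom}:{pos} {ref}>{alt}: EXAC_AN=0, treating as absent")
            status, ac, an = FrequencyStatus.ABSENT, 0, 0
    reported = (Reported.REPORTED_PATHOGENIC
                if info["REPORTED"] == "reported_pathogenic" else Reported.NOVEL)

    def fnum(key):
        tok = info[key]
        return None if tok is None else float(tok)

    profile = PredictionProfile(
        polyphen2_call=_decode_info_token(info["PP2_CALL"]),
        polyphen2_score=fnum("PP2_SCORE"),
        sift_call=_decode_info_token(info["SIFT_CALL"]),
        sift_score=fnum("SIFT_SCORE"),
        mutationtaster_call=_decode_info_token(info["MT_CALL"]),
        mutationtaster_score=fnum("MT_SCORE"),
        cadd_phred=fnum("CADD"),
    )
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, consequence=csq,
        hgvs=_decode_info_token(hgvs) or "", exac_status=status,
        exac_ac=ac, exac_an=an, reported=reported, predictions=profile,
    )


def write_vcf(path, records, sample_order: list[str]):
    """Write ``(VariantRecord, {member_id: GenotypeCall})`` pairs as VCF 4.2.

    Male X/Y hemizygous calls are written as haploid genotypes.
    """
    lines = [_VCF_HEADER_TEMPLATE.format(samples="\t".join(sample_order))]
    gt_map = {
        Zygosity.HOM_REF: "0/0",
        Zygosity.HET: "0/1",
        Zygosity.HOM_ALT: "1/1",
        Zygosity.HEMIZYGOUS: "1",
        Zygosity.MISSING: "./.",
    }
    for rec, calls in sorted(records, key=lambda rc: (rc[0].chrom, rc[0].pos)):
        if rec.exac_status is FrequencyStatus.ABSENT:
            ac, an = "absent", "."
        elif rec.exac_status is FrequencyStatus.UNKNOWN:
            ac, an = "unknown", "."
        else:
            ac, an = str(rec.exac_ac), str(rec.exac_an)
        p = rec.predictions

        def num(x):
            return "." if x is None else repr(float(x))

        info = ";".join([
            f"GENE={_encode_info_token(rec.gene)}",
            f"CSQ={rec.consequence.value}",
            f"EXAC_AC={ac}",
            f"EXAC_AN={an}",
            f"REPORTED={rec.reported.value}",
            f"PP2_CALL={_encode_info_token(p.polyphen2_call or '')}",
            f"PP2_SCORE={num(p.polyphen2_score)}",
            f"SIFT_CALL={_encode_info_token(p.sift_call or '')}",
            f"SIFT_SCORE={num(p.sift_score)}",
            f"MT_CALL={_encode_info_token(p.mutationtaster_call or '')}",
            f"MT_SCORE={num(p.mutationtaster_score)}",
            f"CADD={num(p.cadd_phred)}",
            f"HGVS={_encode_info_token(rec.hgvs)}",
        ])
        def zyg_of(s):
            c = calls.get(s, Zygosity.MISSING)
            return c.zygosity if isinstance(c, GenotypeCall) else c

        gts = "\t".join(gt_map[zyg_of(s)] for s in sample_order)
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# PED

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED,
                "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}


def read_ped(path) -> Pedigree:
    """Read a PLINK 6-column PED file describing one family."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line has fewer than 6 columns: {line!r}")
        rows.append(fields[:6])
    if not rows:
        raise ValueError(f"empty PED file: {path}")
    family_ids = {r[0] for r in rows}
    if len(family_ids) != 1:
        raise ValueError(f"PED file must describe one family, found {sorted(family_ids)}")
    family_id = rows[0][0]

    listed = {r[1] for r in rows}
    members = []
    implicit: dict[str, Sex] = {}
    for _, mid, father, mother, sex, pheno in rows:
        father_id = None if father == "0" else father
        mother_id = None if mother == "0" else mother
        for pid, psex in ((father_id, Sex.MALE), (mother_id, Sex.FEMALE)):
            if pid is not None and pid not in listed:
                warn(f"PED parent {pid} not listed; creating implicit founder")
                implicit[pid] = psex
        if pheno not in _PHENO_CODES:
            warn(f"unknown phenotype code {pheno!r} for {mid}; treating as unknown")
        members.append(PedigreeMember(
            member_id=mid,
            sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
            affection=_PHENO_CODES.get(pheno, Affection.UNKNOWN),
            father_id=father_id,
            mother_id=mother_id,
        ))
    for pid, psex in implicit.items():
        members.append(PedigreeMember(member_id=pid, sex=psex,
                                      affection=Affection.UNKNOWN))
    return Pedigree(family_id=family_id, members=members)


def write_ped(path, pedigree: Pedigree):
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    pheno_out = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1",
                 Affection.UNKNOWN: "0"}
    lines = []
    for m in pedigree.members:
        lines.append("\t".join([
            pedigree.family_id, m.member_id,
            m.father_id or "0", m.mother_id or "0",
            sex_out[m.sex], pheno_out[m.affection],
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Panel / coverage / MLPA TSVs

def load_panel(path) -> GenePanel:
    """Load a gene panel TSV: symbol, association, modes, lof_mechanism[, chrom]."""
    genes = []
    with open(path) as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t")
        for row in reader:
            modes = frozenset(
                m for m in row["modes"].replace("+", ",").split(",") if m)
            genes.append(PanelGene(
                symbol=row["symbol"],
                association=GeneAssociation(row["association"]),
                inheritance_modes=modes,
                lof_mechanism=row.get("lof_mechanism", "0").lower()
                in ("1", "true", "yes"),
                chrom=row.get("chrom", "") or "",
            ))
    return GenePanel.from_genes(genes)


def write_panel(path, panel: GenePanel):
    with open(path, "w") as fh:
        fh.write("symbol\tassociation\tmodes\tlof_mechanism\tchrom\n")
        for g in panel.genes.values():
            fh.write("\t".join([
                g.symbol, g.association.value,
                ",".join(sorted(g.inheritance_modes)),
                "1" if g.lof_mechanism else "0", g.chrom,
            ]) + "\n")


def read_coverage_matrix(path) -> dict[str, ExonCoverageMatrix]:
    """Read an exon coverage TSV (gene, exon_start, exon_end, <sample>...)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    sample_cols = [c for c in df.columns
                   if c not in ("gene", "exon_start", "exon_end")]
    out = {}
    for gene, sub in df.groupby("gene", sort=False):
        sub = sub.sort_values("exon_start")
        out[gene] = ExonCoverageMatrix(
            gene=gene,
            exon_intervals=list(zip(sub["exon_start"].astype(int),
                                    sub["exon_end"].astype(int))),
            sample_ids=sample_cols,
            depths=sub[sample_cols].to_numpy(dtype=float),
        )
    return out


def write_coverage_matrix(path, matrices: dict[str, ExonCoverageMatrix]):
    with open(path, "w") as fh:
        first = next(iter(matrices.values()))
        fh.write("gene\texon_start\texon_end\t" + "\t".join(first.sample_ids) + "\n")
        for m in matrices.values():
            for (s, e), row in zip(m.exon_intervals, m.depths):
                fh.write(f"{m.gene}\t{s}\t{e}\t"
                         + "\t".join(f"{d:.3f}" for d in row) + "\n")


def read_mlpa_ratios(path) -> list[tuple[str, float]]:
    """Read an MLPA probe-ratio TSV: probe, ratio."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append((row["probe"], float(row["ratio"])))
    return out


def bed_to_intervals(path) -> list[tuple[str, int, int, str]]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else ""
        out.append((f[0], int(f[1]) + 1, int(f[2]), name))
    return out
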