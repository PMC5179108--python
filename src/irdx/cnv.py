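"""Structural-variant evidence from read depth, MLPA ratios and trio SNPs.

Exon-level CNVs leave three footprints that whole-exome data and
follow-up assays can capture without genome-wide SV calling:

* a run of exons whose normalized read depth in the case drops to ~0.5x
  (heterozygous deletion) or rises to ~1.5x (duplication) of the control
  level;
* MLPA probe ratios under 0.7 (deletion) or over 1.3 (duplication);
* Mendelian impossibilities across a deleted region: a mother and child
  homozygous for *different* alleles at a biallelic SNP cannot both be
  diploid there, so such loci support hemizygosity, while any
  heterozygous call rules a deletion out at that locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CnvCall,
    CnvState,
    DeletionEvidence,
    ExonCoverageMatrix,
    MlpaState,
    MLPAProbeResult,
    SnpDeletionFlag,
    warn,
)


@dataclass(frozen=True)
class CnvConfig:
    """Depth-ratio thresholds for exon CNV calling.

    0.65 / 1.35 sit midway between the diploid expectation (1.0) and the
    single-copy (0.5) / three-copy (1.5) expectations; two consecutive
    supporting exons are required because single-exon depth dips are the
    dominant noise mode of capture data.
    """

    del_ratio_max: float = 0.65
    dup_ratio_min: float = 1.35
    min_exons: int = 2


def normalize_depths(matrix: ExonCoverageMatrix,
                     control_matrices: list[ExonCoverageMatrix] | None = None
                     ) -> np.ndarray:
    """Normalize each sample's exon depths by its median over control genes.

    ``control_matrices`` are coverage matrices of genes assumed
    copy-neutral in every sample (a nearby gene is used in practice);
    when omitted, the gene's own per-sample median is used.
    """
    if control_matrices:
        stacked = np.vstack([m.depths for m in control_matrices])
    else:
        stacked = matrix.depths
    med = np.median(stacked, axis=0)
    med = np.where(med <= 0, np.nan, med)
    return matrix.depths / med


def exon_ratio_cnv(matrix: ExonCoverageMatrix, case: str,
                   controls: list[str] | None = None,
                   control_matrices: list[ExonCoverageMatrix] | None = None,
                   config: CnvConfig | None = None) -> CnvCall:
    """Call an exon-range CNV in ``case`` from an exon coverage matrix.

    Per-exon ratio = normalized case depth / mean normalized control
    depth.  A heterozygous deletion (duplication) is called when at
    least ``min_exons`` consecutive exons fall at or below
    ``del_ratio_max`` (at or above ``dup_ratio_min``); a single
    supporting exon is reported as a low-confidence normal call.
    """
    config = config or CnvConfig()
    if case not in matrix.sample_ids:
        raise ValueError(f"case sample {case!r} not in coverage matrix")
    controls = controls or [s for s in matrix.sample_ids if s != case]
    if not controls:
        raise ValueError("at least one control sample is required")

    norm = normalize_depths(matrix, control_matrices)
    ci = matrix.sample_ids.index(case)
    ctrl_idx = [matrix.sample_ids.index(s) for s in controls]
    ctrl_mean = np.nanmean(norm[:, ctrl_idx], axis=1)

    masked = ~np.isfinite(ctrl_mean) | (ctrl_mean <= 0) | ~np.isfinite(norm[:, ci])
    if masked.any():
        warn(f"{matrix.gene}: {int(masked.sum())} exon(s) masked "
             "(zero/undefined control depth)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(masked, np.nan, norm[:, ci] / ctrl_mean)

    best = _best_run(ratios <= config.del_ratio_max)
    state, run = CnvState.NORMAL, None
    if best is not None and best[1] - best[0] + 1 >= config.min_exons:
        state, run = CnvState.HET_DELETION, best
    else:
        best_dup = _best_run(ratios >= config.dup_ratio_min)
        if best_dup is not None and best_dup[1] - best_dup[0] + 1 >= config.min_exons:
            state, run = CnvState.DUPLICATION, best_dup

    if state is CnvState.NORMAL:
        single = best if best is not None else _best_run(ratios >= config.dup_ratio_min)
        return CnvCall(gene=matrix.gene, state=CnvState.NORMAL,
                       ratios=tuple(ratios),
                       low_confidence=single is not None)
    start, end = run
    return CnvCall(
        gene=matrix.gene, state=state,
        exon_start=start + 1, exon_end=end + 1,  # 1-based exon indices
        ratios=tuple(ratios), supporting_exons=end - start + 1,
    )


def _best_run(mask: np.ndarray):
    """Longest run of True (NaNs break runs); None when empty."""
    best = None
    start = None
    clean = np.where(np.isnan(mask.astype(float)), False, mask)
    for i, flag in enumerate(list(clean) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    return best


def mlpa_call(ratio: float) -> MlpaState:
    """MLPA interpretation: deletion under 0.7, duplication over 1.3.

    Both boundaries are strict; a probe exactly at 0.7 or 1.3 is normal.
    """
    if not (ratio >= 0):
        raise ValueError(f"probe ratio must be >= 0, got {ratio}")
    if ratio < 0.7:
        return MlpaState.DELETION
    if ratio > 1.3:
        return MlpaState.DUPLICATION
    return MlpaState.NORMAL


def mlpa_profile(ratios: list[tuple[str, float]]) -> list[MLPAProbeResult]:
    return [MLPAProbeResult(probe=p, ratio=r, call=mlpa_call(r))
            for p, r in ratios]


def snp_deletion_flag(mother: tuple[str, str] | None,
                      child: tuple[str, str] | None) -> SnpDeletionFlag:
    """Flag one biallelic SNP from mother and child diploid calls.

    Heterozygosity in either individual proves two copies there
    (non-deleted); apparent homozygosity for *different* alleles in the
    two is impossible under diploid transmission and supports a shared
    deletion (each is hemizygous for a distinct retained haplotype).
    Anything else, including missing calls, is uninformative.
    """
    if mother is None or child is None:
        return SnpDeletionFlag.UNINFORMATIVE
    m_het = mother[0] != mother[1]
    c_het = child[0] != child[1]
    if m_het or c_het:
        return SnpDeletionFlag.NON_DELETED
    if mother[0] != child[0]:
        return SnpDeletionFlag.DELETION_SUPPORTING
    return SnpDeletionFlag.UNINFORMATIVE


def trio_deletion_scan(loci: list[int],
                       mother_calls: list[tuple[str, str] | None],
                       child_calls: list[tuple[str, str] | None]
                       ) -> DeletionEvidence:
    """Scan ordered SNPs for a deletion shared by mother and child.

    The breakpoint interval spans from the non-deleted locus just left
    of the maximal run containing all deletion-supporting loci to the
    non-deleted locus just right of it (chromosome ends when no
    flanking non-deleted locus exists).
    """
    if not (len(loci) == len(mother_calls) == len(child_calls)):
        raise ValueError("loci and genotype lists must have equal length")
    if any(b < a for a, b in zip(loci, loci[1:])):
        raise ValueError("loci must be ordered")

    flags = [snp_deletion_flag(m, c)
             for m, c in zip(mother_calls, child_calls)]

    support = [i for i, f in enumerate(flags)
               if f is SnpDeletionFlag.DELETION_SUPPORTING]
    if not support:
        return DeletionEvidence(loci=list(loci), flags=flags,
                                breakpoint_interval=None)
    first, last = support[0], support[-1]
    left = next((i for i in range(first - 1, -1, -1)
                 if flags[i] is SnpDeletionFlag.NON_DELETED), None)
    right = next((i for i in range(last + 1, len(flags))
                  if flags[i] is SnpDeletionFlag.NON_DELETED), None)
    interval = (loci[left] if left is not None else loci[0],
                loci[right] if right is not None else loci[-1])
    return DeletionEvidence(loci=list(loci), flags=flags,
                            breakpoint_interval=interval)
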