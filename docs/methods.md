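# Methods

This note records the models, parameter choices and known limitations
of `irdx`, in the order the pipeline applies them.

## Prioritization cascade

Three filters reduce an annotated exome to diagnostic candidates.

* **Frequency** — keep alleles with ExAC frequency ≤ `af_max`
  (default 0.01, boundary inclusive: "≤ 1 %").  Frequency is allele
  count / allele number; alleles absent from the reference are treated
  as frequency 0 and always kept.  Sites not covered by the reference
  ("not covered") are a distinct state: they cannot be excluded on
  frequency, and later they earn no rarity evidence either.  A record
  with an allele number of 0 is treated as absent, with a warning.
* **Consequence** — retained classes: nonsense, frameshift, canonical
  splice, non-canonical splice region, missense, exonic deletion /
  duplication.  Alleles already reported as pathogenic bypass the
  filter (`reported_pathogenic_whitelist`, default on): this is what
  admits known deep-intronic splice-creating alleles that a coding
  consequence filter would discard.
* **In-silico consensus** — a missense allele needs ≥ 2 positive
  calls out of PolyPhen2, SIFT, MutationTaster and CADD
  (`min_positive_predictors`, default 2).  Per-tool positivity: when a
  categorical call is present it decides (published annotation tables
  pair calls like "Tolerated" with scores on either side of any
  cutoff); otherwise PolyPhen2 ≥ 0.85, SIFT ≤ 0.05, MutationTaster
  ≥ 0.5, CADD phred ≥ 15.  The CADD cutoff is not standardised
  anywhere authoritative; 15 is the common rare-disease screening
  value and is exposed in `PrioritizationConfig`.  Null, splice and
  CNV alleles bypass the consensus (their damage is structural, and
  most predictors do not score them).

The frequency and consequence filters commute (property-tested); the
consensus filter only ever removes missense records.

## Genotype selection and cosegregation

Candidates are built per gene under four models, restricted to the
gene's catalogued inheritance modes:

* **AD** — one allele het (or hemizygous-equivalent) in every
  genotyped affected; under complete penetrance (default) any
  unaffected carrier vetoes the candidate.  In
  `penetrance_mode="incomplete"` such candidates are retained and
  their cosegregation verdict is forced to `inconsistent`, which keeps
  the family at best a *candidate* — this reproduces the handling of
  dominant alleles found in unaffected relatives, where a second,
  independently segregating variant may explain the non-penetrance.
* **AR hom** — homozygous in all genotyped affecteds, no homozygous
  unaffected, genotyped parents must be het carriers.
* **AR comphet** — exactly two distinct alleles, het in all genotyped
  affecteds, no unaffected carrying both.  Where both parents are
  genotyped the pair is phased: a pair certainly in cis (both alleles
  from one parent, none from the other) is rejected; a pair that could
  be in trans is kept; with ungenotyped parents the pair is kept and
  flagged phase-unknown (such genotypes are routinely diagnosed when
  both alleles are independently pathogenic).
* **XL** — chromosome-X allele, hemizygous in affected males;
  homozygous affected females are accepted; carrier mothers are
  expected het.  Simplex families are evaluated under all four models:
  a substantial minority of apparently sporadic patients carry
  dominant or X-linked alleles, so assuming recessiveness would lose
  them.

Cosegregation is `unavailable` when nobody beyond the index case is
genotyped (never blocking — many secure diagnoses rest on allele-level
evidence alone), `inconsistent` when a genotyped unaffected relative
carries the complete causal genotype, `consistent` otherwise.

## ACMG-style classification

Evidence codes actually derivable from this pipeline's inputs:

| code | strength | trigger |
|------|----------|---------|
| PVS1 | very strong | null allele (incl. exonic CNV) in a gene with a loss-of-function disease mechanism |
| PS3  | strong | functional assay support (per-genotype flag) |
| PM2  | moderate | absent from reference, or frequency < 1e-4 (3e-4 for recessive genotypes) |
| PM3  | moderate | comphet allele in trans with a reported-pathogenic or P/LP-classified partner |
| PM3 → strong | strong | trans partner both reported and classified P/LP |
| PP1  | supporting | cosegregation consistent |
| PP3  | supporting | ≥ 2 predictors positive |
| PP5  | supporting | previously reported pathogenic |
| BA1  | stand-alone | frequency > 5 % |

The recessive PM2 ceiling is looser because recessive alleles persist
at appreciable carrier frequencies; 3e-4 covers the upper range of
rarity judgements observed for recessive IRD alleles.  PM3 is resolved
iteratively (classify without PM3, then re-derive with partner classes
until a fixed point; evidence only accumulates, so convergence is
immediate).  Three deliberate restrictions keep PM3 honest: it is not
granted to homozygous genotypes (a variant cannot vouch for itself),
nor to alleles outside the retained consequence classes (a
whitelist-rescued deep-intronic allele should not be lifted by its
partner), and the strong upgrade needs the partner to be *both*
reported and P/LP.

Combining follows the standard 2015 table (verified in the tests
against an independent transcription of every qualifying pattern, over
all evidence subsets).  BA1 alone → Benign; BA1 plus pathogenic
evidence → VUS with a conflict flag.

**VGUS** — the output scheme adds a class for candidate genes: in a
gene of uncertain disease significance and without functional support,
a clearly disruptive allele is labelled VGUS whatever its would-be
class; a missense allele that would be P/LP is capped at VUS; and a
homozygous, rare, consensus-damaging, cosegregating missense allele is
also VGUS (it carries the same *gene-level* uncertainty as a
disruptive allele while fully explaining the recessive phenotype).
PS3 functional support lifts the gene out of this remapping.

**Diagnosis** — solved requires: established gene (or candidate gene
with PS3), model-complete genotype, cosegregation not inconsistent,
and every causal allele P/LP.  Any surviving candidate genotype
otherwise gives status *candidate*; no genotype, *unsolved*.
Remaining het alleles in panel genes that are reported-pathogenic or
consensus-damaging are listed as potential phenotype modifiers.

## Copy-number evidence

* **Exon depth ratios** — per-sample depths are normalized by the
  sample's median exon depth over designated copy-neutral control
  genes (a whole-gene deletion is invisible to self-normalization, so
  the control anchor matters; the normalization set should span a few
  dozen exons to keep the per-sample scale estimate tight).  The
  per-exon statistic is normalized case depth over the mean of
  normalized controls.  Calls: het deletion when ≥ `min_exons` (2)
  consecutive exons sit at ratio ≤ 0.65, duplication at ≥ 1.35 —
  thresholds midway between the single-copy (0.5) / three-copy (1.5)
  expectations and the diploid 1.0, biased toward sensitivity.  A
  single supporting exon is reported as a low-confidence normal call,
  not a CNV: single-exon dips are the dominant noise mode of capture
  data.  Exons with zero control depth are masked with a warning.
  At per-exon depth noise of CV 10 % (the simulator default) this
  yields ≥ 95 % exact-range recovery of planted 2-exon half-depth
  deletions and a false-positive gene rate well under 1 %; at CV 15 %
  the 0.65/1.35 thresholds produce a several-percent false-positive
  rate, so noisier data needs stricter thresholds or more controls.
* **MLPA** — deletion iff ratio < 0.7, duplication iff ratio > 1.3,
  both strict ("under" / "over"); the call is a monotone step function
  of the ratio.  Normalized ratios are inputs; raw peak-area
  normalization is out of scope.
* **Trio-SNP deletion inference** — at a biallelic SNP, a het call in
  mother or child proves two copies (non-deleted); mother and child
  apparently homozygous for *different* alleles is impossible under
  diploid transmission and supports a deletion carried by both (each
  hemizygous for a distinct retained haplotype); everything else,
  including missing calls, is uninformative.  The breakpoint interval
  runs from the nearest non-deleted locus left of the supporting run
  to the nearest on the right (chromosome of the scanned region ends
  otherwise).  Fine-mapping via breakpoint-flank homology is out of
  scope.

## Cohort summaries

`coverage_summary` gives median depth and C10/C30 (percent of targeted
bases at ≥ 10× / ≥ 30×).  `carrier_burden` counts, per patient and
excluding the family's causative alleles, (a) het reported-pathogenic
recessive alleles in panel genes and (b) unreported het alleles called
damaging by ≥ 2 predictors, with cohort means of both.  `cohort_yield`
partitions families into solved / candidate / unsolved; percentages
are reported rounded to integers for display alongside exact
fractions.

## Synthetic cohorts

The generator emulates the cohort structure the pipeline is designed
for, on a miniature synthetic genome (~300 panel genes of 1–30 exons
laid out on chr1–22/X; no reference sequence involved):

* family mix 14 simplex / 4 dominant / 14 recessive / 1 X-linked per
  33 families; outcome mix 18 solved / 10 candidate / 5 unsolved;
* planted causal genotypes by scenario: null-allele genotypes in
  established genes (solved), homozygous missense in established genes
  (candidate: VUS), null alleles in candidate genes (candidate: VGUS);
  ~15 % of eligible solved families carry an exon deletion delivered
  through the coverage matrix instead of the VCF;
* causal allele frequencies: 70 % absent from the reference, the rest
  log-uniform — unreported alleles on [1e-6, 9e-5] and reported ones
  on [1e-5, 2e-3], matching the observed pattern that only previously
  reported pathogenic alleles reach appreciable population
  frequencies.  `causal_common_frac` deliberately pushes a fraction of
  causal alleles above the 1 % filter to exercise failure modes;
* background variants (Poisson mean 40/family) with a 60 % absent /
  40 % log-uniform [1e-6, 5e-2] spectrum that straddles the frequency
  boundary; background nulls are not planted in dominant-capable
  genes, so spurious single-allele candidates arise only through
  predictor noise;
* predictor outputs drawn per tool from a truth-conditioned error
  model (sensitivity 0.9, specificity 0.8, independent across tools —
  enough noise to make the 2-of-4 consensus meaningful);
* modifier alleles at Poisson means 0.3 (known het recessive) and 5.25
  (rare predicted damaging) per patient, each in a distinct
  recessive-only gene; coverage noise CV 0.10; MLPA ratio noise
  SD 0.05.

Everything is deterministic given the seed (byte-identical re-runs),
and a truth table records each family's planted genotype and expected
status.  `SimConfig.noiseless()` gives the same cohort with perfect
predictors and no measurement noise; under it the pipeline recovers
100 % of planted genotypes with statuses matching truth, which is the
end-to-end correctness check.  Under default noise, genotype recovery
stays above 90 % (the residual losses are consensus-filter misses on
missense alleles and marginal CNV calls).

What the simulation does *not* model: linkage disequilibrium and
haplotype structure, read-level artefacts, population stratification
of frequencies, mosaicism, de novo events, digenic inheritance, and
locus heterogeneity within a family.  Passing on simulated cohorts
therefore validates the decision logic and its thresholds, not
performance on real exomes.

## The cohort fixture

`src/irdx/data/` ships a transcription of the modelled 33-family
cohort: 41 classified alleles in 28 families plus 5 families without
findings (their ids are synthetic placeholders, as noted in the file).
Decimal commas in the source were normalized at transcription; fields
left blank are preserved as missing.  Genomic positions are synthetic
ordinals — the table records HGVS names, not coordinates — so
position-dependent logic (X-linkage aside) is exercised by the
simulator, not the fixture.  The loader hard-fails on any
family/entry/secure-count mismatch.  Running the pipeline on the
fixture yields 18 solved / 10 candidate / 5 unsolved and reproduces
39/41 recorded ACMG classes; the two divergent alleles (a homozygous
frameshift classified LP here vs Pathogenic, and a candidate-gene
splice allele classified VGUS here vs Pathogenic) are printed with
their evidence codes by `irdx fixture` and the concordance test, and
neither changes its family's diagnostic status.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive everywhere; BED input is converted
on read.  Multi-allelic VCF sites are decomposed per alt allele with
per-allele genotype mapping; male X/Y genotypes are written haploid
and read back as hemizygous.  Ties in run detection (equal-length
depth-ratio runs) resolve to the leftmost longest run.  Empty coverage
targets, negative ratios/depths, duplicate family ids, cyclic
pedigrees and pedigree/VCF sample mismatches raise errors; unknown
phenotype codes and implicit PED founders are warnings.  The
classification fixed-point loop is capped at five rounds (two alleles
can exchange class information at most twice before stabilising).
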