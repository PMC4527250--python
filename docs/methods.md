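# Methods

This note documents the models behind `compimpute`, the parameters that
matter, the numerical conventions, and what the synthetic data can and
cannot say about real composite-breed cohorts.

## Genotype representation

Genotypes are allele-B (ALT) counts: 0 = AA, 1 = AB, 2 = BB, −1 = missing.
This makes the genotype matrix directly the pre-centring incidence matrix of
the VanRaden relationship (below). Phase, where known, is an ordered allele
pair summing to the genotype. Only bi-allelic autosomal SNPs are supported;
multi-allelic or non-SNP records are hard errors so a dataset cannot drift
silently. VCF is read through cyvcf2/htslib; written VCF 4.2 carries the cM
position in an `INFO/CM` field (1 cM/Mb is assumed when absent) and imputed
dosages in `FORMAT/DS`.

## Synthetic composite-breed populations

The simulator emulates the structure of a Canchim/MA breeding programme.

**Ancestral divergence.** Two populations (taurine-like, indicine-like)
diverge from a common base under the Balding–Nichols model: base frequency
p ~ U(0.05, 0.95) per marker, each population frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F), so E = p and Var = F·p(1−p). One knob, F,
defaults to 0.15 — a taurine–indicine-scale divergence.

**Pedigree.** Founders are Charolais sires and Zebu dams. The grading-up
path is F1 = CH × ZE (1/2 CH), 3/4 = CH × F1, base Canchim = 3/4 × F1
(5/8), cohort Canchim = Canchim × Canchim; MA = CH sire × (Canchim × Zebu)
dam (21/32 ≈ 0.656 CH). Expected ancestry is propagated as the parental
mean and is exact by construction; realized ancestry is measured by
tracking founder-haplotype origins through the gene drop. The default
cohort reproduces the study-design strata — 283 Canchim, 112 MA and one
genotyped Charolais sire, both sexes, birth years 1999–2005 — laid out so
that all seven scenario splits reproduce the emulated design's reference/target
counts exactly. Scaffolding-generation sizes (60 F1 dams, 20 three-quarter
sires, 20 Canchim sires, 100 Canchim dams, …) are chosen large enough that
breeding-pool drift keeps the realized cohort ancestry within a few percent
of the 5/8 expectation; with very small pools the mean realized ancestry
itself drifts, which is a property of tiny closed nuclei rather than of the
programmes being emulated.

**Relatedness gradient.** 2005-born animals (the typical imputation
targets) are split between sires that also produced earlier offspring —
paternal half-sibs of the reference — and sires/dams used for 2005 only
(`fresh_target_fraction`, default 0.5). This gives targets a spread of
maximum genomic relationships to the reference set, which the
relatedness-accuracy regression needs.

**Gene drop.** Founder haplotypes are drawn marker-independently from their
population's frequencies; gametes recombine under Haldane's no-interference
model (crossovers ~ Poisson(L/100) per chromosome, positions uniform on the
cM scale, 100 cM per chromosome at 1 cM/Mb by default). Output is fully
phased and Mendelian-consistent. The default desk scale is 5 chromosomes ×
4,000 markers (~20k SNPs), the problem size used throughout the test suite
and the acceptance script.

**Noise.** Each entry is dropped with `missing_rate` (default 0.002) and
each surviving call perturbed to a different code with `error_rate`
(default 0.001); perturbed/dropped entries lose phase. Defaults reflect
post-array-QC data quality.

What the simulator does **not** emulate: mutation, selection, realistic
bovine recombination maps, LD beyond what the pedigree and drift induce,
genotyping batch effects, and sex chromosomes. Passing tests therefore
demonstrate algorithmic correctness and qualitative behaviour (density and
relatedness effects), not quantitative accuracy on any real cohort.

## Quality control

Fixed, reported stage order: (1) non-autosomal/unplaced markers, (2) SNP
call rate < 0.90, (3) exact Hardy–Weinberg p < 1e-6, (4) heterozygosity
> 0.85, (5) MAF < 0.0025, (6) sample call rate < 0.90 on surviving
markers. Each marker is charged to the first stage that rejects it.
Whether sample QC precedes marker QC is a convention; marker-first is
declared here and asserted idempotent on its own output in the tests.

The HWE test is the exact conditional test: given the observed allele
counts, every compatible heterozygote count k has probability
∝ 2^k / (n_AA! k! n_BB!), and the p-value sums the probabilities of
configurations no more probable than the observed one (computed in log
space via `gammaln`; ties included with 1e-12 relative slack). A
"heterozygosity > 0.85" filter can only refer to *observed* heterozygosity
— expected heterozygosity 2p(1−p) is bounded by 0.5 — so observed is the
default (`het_filter_mode="observed"`), with the literal expected-het
variant available. Note that at cohort-scale sample sizes any marker with
observed het > 0.85 also fails the exact HWE test at p < 1e-6, so stage 3
usually claims such markers first; the het stage exists as the standard
paralog screen and operates when HWE is relaxed or disabled.

Allele frequencies for MAF and HWE are computed on all samples jointly; no
stratification is applied.

## Panels and scenarios

The density ladder uses the post-QC intersection sizes of seven commercial
chips with a ~617k HD panel (2,341 / 6,280 / 7,548 / 14,305 / 38,802 /
50,038 / 67,143), rescaled proportionally to the working marker count.
Synthetic panels default to `uniform_spacing` — per-chromosome proportional
allocation and centred equal-interval selection — which approximates
commercial chip design better than uniform random (also available).

Masking hides all non-panel markers in target animals (phase removed —
targets are treated as unphased field genotypes) while reference rows stay
untouched at HD and the truth of every hidden entry is retained for
scoring.

Scenario rules S1–S7 partition the cohort by birth year, genetic group and
sex (see `build_scenario`). In the two group+year scenarios the group that
supplies the target enters the reference only with its pre-split-year
animals while the other composite group enters in full; Charolais sires
join only the year/sex-based references. These conventions reproduce the
emulated design counts exactly and keep reference and target disjoint by
construction (asserted).

## The window imputer

The imputer realises the long-IBD window principle in its simplest exact
form. Per chromosome and target, passes run from the longest window to the
shortest (default 500/200/100/50/20 typed markers, overlap 0.5). Within a
window, every reference haplotype *pair* (i ≤ j, the same haplotype twice
allowed) whose allele sums match the target's typed genotypes at
≥ (1 − `mismatch_tol`) of typed sites (default tol 0.01 — absorbs
genotyping error) and whose longest exact-match run reaches `min_match`
(default 20 typed markers) votes for its alleles at every untyped marker in
the window span. The vote weight is the length of the exact-match run
flanking the marker, so longer shared segments dominate; terminal windows
extend to the chromosome ends. After all passes the dosage is the weighted
mean pair allele count (∈ [0, 2]); markers with no accepted pair fall back
to 2p_B from reference frequencies. Best-guess genotypes are the binomial
argmax at p = dosage/2 — thresholds 2/3 and 4/3 — with ties broken toward
the smaller code.

Matching in genotype space (pairs vs genotypes) avoids committing to a
target phase and keeps the algorithm exactly checkable: for small instances
the vectorised implementation is verified against full pair enumeration to
1e-12. Two caps (`max_candidate_haplotypes` 400, `max_candidate_pairs` 50,
best-scoring kept) bound work per window; they are inactive on the oracle
instances. The per-haplotype pre-filter is exact, not approximate: a
haplotype's mismatches at the target's homozygous sites lower-bound any
pair's mismatch count.

Degenerate inputs: windows longer than a chromosome's typed-marker count
are skipped (logged), a chromosome with no typed markers falls back
entirely, and typed genotypes are never modified. A reference carrying no
phase at all is an error; individually unphased or missing reference
entries are repaired deterministically (homozygotes trivially,
heterozygotes as (0, 1), missing as the frequency-modal allele) and
counted, since a window scheme needs a complete haplotype library and these
entries are rare post-QC.

Consequence of the typed-count window ladder at desk scale: a panel with
fewer typed markers per chromosome than the smallest window imputes purely
by frequency fallback (the 3K-scaled panel at 20k synthetic markers is in
this regime), and its accuracy is then the modal-genotype frequency — the
relatedness regression is meaningful only for panels where matching
operates.

## Accuracy metrics

Concordance rate is the pooled exact-match fraction over masked,
truth-called entries (group breakdowns always pool back to the overall
value; empty cells are flagged, not zeroed). Allelic R² is the squared
Pearson correlation between true and best-guess allele dosages, computed
per marker across target animals and averaged over markers with defined
values (pooled-entries variant available; fractional-dosage variant
available via the dosage array). Zero-variance markers are excluded with a
logged count. Adjacent-marker LD uses the composite (genotype-correlation)
r² on pairwise-complete samples, since target data are unphased.

## Relationships and the relatedness regression

G = MM′ / Σ 2pᵢ(1−pᵢ) with M centred at the allele-B frequencies pᵢ.
The frequency source defaults to all genotyped samples; reference-only or
supplied frequencies are options for sensitivity analysis. Missing
genotypes are mean-imputed at 2pᵢ before centring (standard treatment;
counted). An all-monomorphic matrix (zero denominator) is an error.

Per-target maximum relationship is the largest G entry against the
reference set. The curvilinear accuracy model is quadratic OLS of
per-animal CR on that maximum. x is mean-centred before squaring because
raw x and x² are near-collinear over the narrow observed relatedness range;
the reported linear coefficient is then the slope at the mean relatedness,
and fitted values are identical to the uncentred parameterisation (tested).
Degree is configurable; coefficient p-values are standard t-tests.

## Pipeline determinism

One top-level seed feeds `numpy.random.SeedSequence`-derived sub-seeds for
every stochastic stage; the imputer itself is deterministic. The results
grid is written with fixed float formatting and contains no wall-clock
fields (timings go to the log), so identical config + seed yields a
byte-identical grid. All intermediate artifacts — masked/truth/imputed
VCFs, per-animal CR tables, QC report — are persisted so any grid cell can
be re-derived by calling the evaluation functions directly on them
(asserted in the tests).

## Known limitations

* The imputer is a principled stand-in, not a production competitor to
  HMM-based or pedigree-aware tools; no target phasing is produced and no
  Li–Stephens model is used.
* Accuracy numbers from the synthetic desk-scale populations are
  qualitative: marker density, LD structure and cohort size are far below
  real HD data, so only orderings and trends (density gain, relatedness
  effect, R² ≤ CR) transfer.
* Allele frequencies, window parameters and QC thresholds are all surfaced
  in config, but no automatic tuning is attempted.
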