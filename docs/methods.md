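# Methods

`panelval` recomputes the analytical- and clinical-validation statistics
of a 1021-gene hybrid-capture oncology panel run on FFPE tissue and plasma
cell-free DNA.  This note records the models, the parameters that matter,
what the synthetic-data layer does and does not emulate, and the design
choices made where the design was genuinely open.

## Detection model and limit of detection

Read-level variant calling is out of scope; detection is modeled
statistically.  For a variant with design allele fraction *f* sequenced to
target depth *d*:

* per-run depth `D ~ Poisson(d)` — this captures run-to-run mean-depth
  variation (two tiers of the same standard were sequenced at materially
  different mean depths) without modeling flow cells;
* alternate reads `A ~ Binomial(D, f)`;
* a call is emitted iff `A ≥ k` (default `k = 3` minimum alternate reads)
  and the observed VAF `A/D` clears the caller's reporting floor
  (default 0, so `k` governs detection; compartment positivity thresholds
  are a separate downstream filter).

The analytic detection probability at fixed depth,
`1 − F_Binom(k−1; d, f)`, is the oracle against which Monte-Carlo rates
are checked (within three standard errors at 10,000 simulations per
tier).  Poisson depth mixing perturbs this by far less than one standard
error at the depths used (≥ 250×), since the tail probability is locally
near-linear in depth over a ±√d window — the analytic formula remains the
reference.  `k = 3` is the smallest support requirement that reproduces
the depth-dependent ordering of the published per-tier sensitivities
(≈ 100% at 2%/1000×, ≈ 97% at 1.3%/993×, ≈ 85% at 0.6%/794×); the
observed extra drop at 560× relative to the binomial model reflects
real-assay effects (library complexity, error suppression) the model
deliberately omits.

CNV observations are `design copies + N(0, σ)` with σ = 0.15 copies in
tissue and 0.30 in plasma — arbitrary but fixed, and small relative to
the 3.0/2.2 positivity cutoffs.  Fusions use the same binomial support
model as SNVs.

## Positivity thresholds

SNV/indel/fusion: VAF ≥ 1% in tissue.  The plasma default is 0.5% — the
lowest tier the assay validates, and the level at which published paired
plasma findings are reported — while `PositivityPolicy.per_label()`
provides the literal 1%-both-compartments rule.  CNV: copies ≥ 3.0
(tissue) / ≥ 2.2 (plasma), inclusive.  All thresholds are inclusive (≥).

## Identity matching

SNVs/indels match on (chromosome, position, ref, alt) after minimal
left-alignment normalization (shared suffix then prefix trimmed, one
anchor base kept), so VCF dialect differences do not create false
mismatches.  CNVs match on gene symbol; fusions on the unordered gene
pair — breakpoints are carried but not required, since reported fusions
name exon-level breakpoints inconsistently across assays.  True-negative
counts exist only against a declared wild-type position list; without one
NPA is reported as undefined, never zero.

## TMB

`TMB = (# eligible calls) / coding footprint (Mb)`, eligible meaning:
SNV or indel; VAF strictly > 5%; in the coding footprint or within ±2 bp
of a splice junction; synonymous included (configurable); minus driver
mutations listed in an explicit catalog (tumor-suppressor inactivating,
driver-sensitive, driver high-frequency) — never inferred.  The footprint
must exceed 1 Mb.  No sample-quality-conditional VAF adjustment is
applied; the floor is global.  TMB-high is strictly > 10 muts/Mb.

## MSI

The score is the fraction of unstable microsatellite sites (site
instability arrives precomputed; calling instability from read-length
distributions is out of scope).  MSI-H at score ≥ 19.5% (FFPE) / ≥ 18%
(plasma).

## Allele-specific copy number and %LOH

Model (standard allele-specific copy-number closed forms, purity ρ,
sample ploidy ψ, per-segment allele counts n_A ≥ n_B ≥ 0):

```
BAF  = (1 − ρ + ρ n_B) / (2(1 − ρ) + ρ(n_A + n_B))
logR = log2[(2(1 − ρ) + ρ(n_A + n_B)) / (2(1 − ρ) + ρ ψ)]
```

Allele phase is unknown, so BAF is folded to the major-allele side
[0.5, 1] before fitting.

**Segmentation.**  Joint penalized least-squares change-point detection
on (folded BAF, logR) per chromosome, each channel variance-normalized by
a robust noise estimate (median absolute successive difference / 0.6745√2),
solved exactly by an O(n²) dynamic program.  The default penalty,
10·log n per breakpoint on the normalized scale, was calibrated on
simulations at the noise levels of the synthetic profiles (BAF sd 0.02,
logR sd 0.05): it recovers a three-state chromosome in ≥ 95% of seeded
runs while keeping homogeneous chromosomes as single segments.  Segment
boundaries are placed midway between flanking SNPs and tile each
chromosome.

**Purity/ploidy.**  Grid search (ρ: 0.10–1.00 step 0.01; ψ: 1.5–5.0 step
0.05).  Each grid point inverts the model to continuous (n_A, n_B) per
segment; the objective is the length-weighted squared distance to the
nearest non-negative integers **plus a weak regularization `10⁻³·ψ`**.
The regularization matters: the distance alone has an exact ridge — adding
one copy to every allele of every segment, at ρ′ = ρ/(1−ρ) and the
correspondingly shifted ψ, reproduces BAF and logR identically — so an
unregularized fit cannot distinguish a near-diploid genome from its
shifted-up twin, and for ρ ≤ 0.5 a purity-preferring tie-break would pick
the wrong member.  Preferring the lower-ploidy solution is how
allele-specific callers conventionally break this ridge.  Residual exact
ties go to higher purity, then lower ploidy; an all-balanced profile
(no allelic imbalance, flat logR) is flagged non-identifiable and
resolves to (1.0, 2.0).

**LOH.**  A segment is LOH iff n_B = 0 and n_A ≥ 1 (homozygous deletion
is not LOH).  Sample %LOH = 100 × (LOH bp)/(eligible bp) over autosomes;
LOH segments spanning ≥ 90% of their chromosome are excluded from both
numerator and denominator by default (whole-chromosome loss reflects
aneuploidy, not the focal instability genome-LOH measures) —
configurable off.  Sex chromosomes are excluded because the two-germline-
allele assumption fails in males.  Genes are flagged on ≥ 1 bp overlap
with an LOH segment (configurable minimum overlap fraction).  The
high-gLOH flag defaults to %LOH ≥ 16%, a conventional PARP-eligibility
cutoff for this class of score; the assay's own cutoff is not public, so
the value is explicitly configurable rather than presented as ground
truth.

## Validation statistics

PPA/NPA are sensitivity/specificity with an orthogonal method as truth.
Confidence intervals are exact Clopper–Pearson from beta quantiles
(`x = n` → [(α/2)^{1/n}, 1]; `x = 0` → [0, 1−(α/2)^{1/n}]).  Pearson
concordance uses the product-moment estimator with a two-sided t test on
n−2 degrees of freedom; p-values below 10⁻⁵ are reported as a bound.
Percentages are rounded half-up to two decimals (MSI specificity to
integer precision, matching how such reports print it).  QC gating is
inclusive at: DNA ≥ 50 ng, library ≥ 600 ng, mean depth ≥ 500× (2%-VAF
mode) or ≥ 1000× (0.5% mode), ≥ 99% of target at ≥ 50×, ≥ 80% of bases
≥ Q30.

## Synthetic-data layer

The generator reproduces the statistical structure the validation
analyses assume — binomial read support at design VAFs, Poisson depth,
Bernoulli per-gene alteration draws, log-normal TMB, a ctDNA-fraction
dilution model for paired tissue/plasma samples (plasma VAF = tissue VAF
× ctDNA fraction; a non-shedding tumor yields an empty plasma signal),
and SNP profiles under the closed forms above with Gaussian noise and
random allele phase.  All randomness descends from one integer seed
through `numpy.random.SeedSequence`, so outputs are byte-identical under
a fixed spec.

It does **not** emulate: sequencing error and UMI consensus artifacts,
mappability and GC effects, FFPE deamination damage, subclonal structure,
germline contamination or clonal hematopoiesis.  Passing tests therefore
demonstrate that the scoring, filtering and inference arithmetic is
correct under the stated statistical model — not that the model captures
every failure mode of real libraries (the 560× tier's extra sensitivity
loss is one visible example).

## Problem sizes and numerical choices

The end-to-end %LOH recovery study uses 100 seeded genomes (ten 100-Mb
chromosomes, 20% of the genome in copy-neutral LOH split across four
chromosomes, one 30-Mb single-copy gain, purities cycling 0.4/0.6/0.8,
1 SNP/Mb, BAF sd 0.02, logR sd 0.05), succeeding when purity is within
±0.05, ploidy within ±0.1 and %LOH within ±3 points of truth.
Monte-Carlo LOD uses 10,000 draws per tier.  The cross-assay concordance
harness models both platforms as truth + independent Gaussian noise with
noise sd expressed as a fraction of the biological sd, calibrated so the
expected correlation `r = 1/(1 + ratio²)` matches the concordance the two
orthogonal platforms report (TMB across 61 samples, %LOH across 35); the
reported value is the mean r over 200 repetitions, i.e. the expected
concordance under those conditions rather than one noisy draw.

Degenerate inputs are errors, not silent defaults: empty truth sets,
zero eligible genome, score outside [0, 1], fewer than 10 SNPs per
chromosome, fewer than 3 segments for the purity fit, zero-variance
vectors for correlation.

## Known limitations

* Detection ignores error suppression and strand artifacts; sensitivity
  at marginal depth is optimistic relative to real libraries.
* The purity/ploidy ridge is broken toward lower ploidy; genuinely
  polyploid genomes whose every segment shares a common allele offset
  (e.g. a clean whole-genome doubling) will be reported at the halved
  solution.
* %LOH boundary placement is limited by SNP spacing; at 1 SNP/Mb the
  per-breakpoint uncertainty is ~0.5 Mb.
* Actionability tiers are consumed as annotations; no knowledge-base
  lookup is performed.
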