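# Methods

## The design and its statistical problem

The package targets a case-control resequencing design in which DNA from
many individuals is combined into case-only or control-only pools before
library preparation. The default study conditions emulated throughout are 44
pools — 24 case pools totalling 474 individuals (eight pools of 12, one of
18, fifteen of 24) and 20 control pools of 24 totalling 480 — sequenced in
four batches at a mean depth of 1000× per pool. Individual genotypes are
unobservable; the analysable signal is, per variant site and pool, the
stranded base-call counts of each allele.

Two features dominate the statistics. First, an allele's count in a pool
estimates the number of carrier chromosomes among the pool's 2N: the
*expected chromosome count* ECC = (allele calls / total calls) × 2N. Second,
because pools are phenotype-homogeneous, any batch effect in sequencing is
partially confounded with case/control status, inflating association
statistics; this is treated with genomic control rather than covariate
adjustment (PC axes separate cases from controls and therefore cannot be
used as covariates).

## Synthetic data generator

For each site, a control minor-allele frequency p₀ is drawn from a
configurable distribution (point mass, uniform, or log-uniform over
[0.005, 0.5] by default, reflecting rare-variant-enriched target panels).
Causal sites get a case frequency under a multiplicative allelic model,

  p₁ = p₀·OR / (1 + p₀·(OR − 1)).

Per site and pool: carrier chromosomes k ~ Binomial(2N, p_group); total
depth D ~ NegativeBinomial(mean = `mean_depth`, size = `depth_dispersion`);
reads sample chromosomes uniformly, so alternate reads ~ Binomial(D, f) with
f = k/2N; each base call miscalls with probability `error_rate` (default
10⁻³, a typical post-Phred-20 residual error) to a uniformly chosen other
base; each call is assigned to the forward strand with probability
`strand_imbalance` (default 0.5). When `bias_sd` > 0, f is logit-shifted by
a per-site batch effect plus a per-site case-only effect, both
N(0, bias_sd²): the shared-within-batch component produces batch structure
on PC axes, the status-correlated component produces genomic inflation.
`bias_sd = 0.05` under the default design yields raw λ ≈ 1.3, the inflation
regime the method is designed to correct. All randomness flows from a single
seed through `numpy.random.SeedSequence.spawn`, so outputs are bit-identical
given the configuration.

Deliberately not modelled: read-level artefacts (mapping error, indels,
local realignment), capture-efficiency variation along the target, and
unequal DNA contribution of individuals within a pool. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling model, not robustness to alignment-level artefacts.

The depth model's dispersion default (8) is a free parameter — only the mean
depth is externally constrained — and was fixed once to give visible
coverage variability (CV ≈ 0.35) without extreme dropout.

## Filtering

An allele in a pool passes when (i) counts are post-Phred-20 (enforced
upstream at ingestion: the call matrix is defined as quality-filtered),
(ii) it has ≥2 calls on each strand, (iii) ECC ≥ 1 with ≥0.3 ECC per strand.
A variant is retained experiment-wide when some allele passes in ≥3 distinct
pools spanning ≥2 batches; all thresholds are exposed in `FilterThresholds`.
The per-pool criteria are applied conjunctively before the pool/batch count
(the natural reading of "criteria met in ≥3 pools"). Filtering is monotone
in the allele's calls with the site total held fixed, and invariant to pool
order and bijective batch relabelling — both property-tested. Multi-allelic
sites are filtered per alternate allele; association later designates the
two most common alleles at the site.

## Allele frequencies

Per pool, a retained allele's frequency is its call count divided by the
summed calls of the designated alleles at the site (reference plus retained
alternates); ECC = frequency × 2N. Pools with zero passing coverage are
flagged missing and drop out downstream. Cohort MAFs are **depth-weighted**
means of pool frequencies: pools differ in size (12/18/24) and coverage, and
depth weighting makes the estimate invariant to splitting a pool's calls
into pseudo-pools (property-tested); equal-pool weighting has no such
invariance and the original aggregation rule is not documented anywhere
authoritative.

## PCA diagnostics and genomic inflation

Each variant row of the variants × pools frequency matrix is standardized to
mean 0, variance 1 (population-SD convention; the choice is immaterial
downstream since PCA directions are scale-free per row) with missing entries
mean-imputed to 0; zero-variance rows are dropped. Pools are the
observations of a full-SVD PCA. Outlier pools are flagged when their robust
z-score — |score − median| / (1.4826·MAD) — on PC1 or PC2 exceeds 4 (the
threshold is a package choice; visual inspection is the field's habit and
gives no numeric rule). A zero MAD falls back to flagging any deviation from
the shared score, which flags nothing when all scores are equal.

The genomic inflation factor is λ = median(χ²)/0.4549, the standard
definition (0.4549 is the χ²₁ median). A literal median-ratio without the
0.4549 normalisation is not used: it would report ≈0.45 on perfectly null
data, while the standard definition reproduces the λ ≈ 1.3 regime the
method's own bias scenario generates.

## SNV association

Per SNV, the regression is binomial with the pool as the unit: successes =
rounded minor-allele ECC, trials = rounded minor+major ECC (floored at 1
where the pool has coverage), predictor = case/control status. With one
binary covariate the GLM is available in closed form — the fitted group
probabilities are the group-pooled frequencies — so the 1-df
likelihood-ratio χ² equals the aggregated 2×2 allele-count G statistic and
the residual deviance (n_pools − 2 df) measures extra-binomial scatter of
pools around their group frequency. The closed form is exact, matches a
statsmodels GLM fit to machine precision (tested), and makes permutation
re-analysis with λ re-estimation cheap. The LR statistic was chosen over
Wald for stability at low counts. Rounding ECCs to integer trials keeps the
deviance a genuine count-model quantity; the bias introduced is negligible
at 2N ≥ 24.

Exclusions before λ estimation: SNVs whose minor allele has zero chromosome
count in cases or in controls (these cannot be fit and carry no two-sided
information), and SNVs whose support lies entirely in outlier pools. λ is
estimated from the post-exclusion set, clamped at 1 from below (genomic
control never deflates), and divides every χ²; p-values come from the χ²₁
survival function. Overdispersion QC then removes SNVs whose residual
deviance exceeds the χ²(dof) critical value at p < 1.5×10⁻⁵; SNVs with
dof ≤ 0 are skipped with a log message. The order — exclusions, λ, then
overdispersion QC — fixes an ambiguity in the method's description; λ is
deliberately estimated before the QC step so that the QC cannot shift the
correction it is meant to complement.

### Calibration note

At 1000× depth with 2N = 48, read sampling adds variance on top of
chromosome sampling: Var(f̂) ≈ p(1−p)(1/2N + 1/D), so the binomial-in-2N
model is overdispersed by a factor ≈ 1 + 2N·E[1/D] ≈ 1.05 and the raw λ on
bias-free data sits around 1.05–1.1 rather than exactly 1. This is a real
property of the design, and genomic control absorbs it: corrected p-values
reject at 3.5–6.5% at α = 0.05 in the null calibration test. The λ → 1
property itself is tested in the deep-coverage limit (5000×, error 0) where
the binomial model is exact.

## Gene burden and permutation

A gene's burden statistic is the sum of its SNVs' GC-corrected z² values,
referred to χ² with n degrees of freedom. The reference distribution assumes
independent SNVs; linkage disequilibrium concentrates one signal in many
SNVs and makes the analytic p anticonservative. The permutation test
therefore shuffles case/control labels among pools, re-runs the closed-form
regression for the whole analysis SNV set, re-estimates λ (default; can be
switched off), and compares permuted corrected gene sums with the observed
one. The add-one estimate p = (1 + #{permuted ≥ observed})/(B + 1) is used
with B ≥ 999: it is never zero and matches the reported granularity of
permutation results in this literature. When fewer than B distinct
labelings exist, B is truncated with a warning.

## Follow-up statistics

* **Allelic OR** from MAFs: OR = [m₁/(1−m₁)]/[m₀/(1−m₀)]; from 2×2 allele
  counts, the Woolf interval exp(ln OR ± z·√(Σ1/cell)) with
  Haldane–Anscombe 0.5 correction for zero cells.
* **Cochran–Armitage trend test** with additive scores (0,1,2), 1 df; equals
  the allelic 2×2 χ² under HWE (tested against both the textbook formula and
  that equivalence).
* **Exact HWE test**: enumeration of the conditional heterozygote
  distribution given the allele counts; two-sided p sums all configurations
  no more probable than observed. Verified against exact integer-arithmetic
  enumeration.
* **Binomial enrichment**: exact upper tail P(X ≥ k), X ~ Bin(n, p₀).
* **Allelic power**: with p₁ implied by the OR under the multiplicative
  model, the two-sided two-proportion z-test on allele counts using the
  pooled-variance null standard error:
  power = Φ(Δ/SE₀ − z_{α/2}) + Φ(−Δ/SE₀ − z_{α/2}),
  Δ = p₁ − p₀, SE₀ = √(p̄(1−p̄)(1/2n₁ + 1/2n₀)). The pooled form was chosen
  because it reproduces the reference design calculations for this class of
  study to within ~2 percentage points across the rare-variant range
  (MAF 1–5%, OR 1.3–2.5, α 10⁻⁴–10⁻²); the unpooled (alternative-variance)
  form deviates by up to ~6 points at the rare, liberal-α corner. At OR = 1
  the expression returns exactly α. Power for unusual designs (very small
  counts, extreme α) should be checked by simulation; the normal
  approximation is the only method provided.

## Numerical conventions and degenerate inputs

0·log 0 = 0 throughout the deviance algebra; χ² values are floored at 0
against float cancellation. Ties in allele ranking break lexicographically
by base. Positions are 1-based internally and in all TSVs; BED input is
0-based half-open at the file boundary. Pools with zero trials drop out of
fits; a SNV needs ≥2 informative pools and both statuses, else it is
excluded with a reason string. λ estimation requires ≥1 finite χ². The
outlier flagging of constant score vectors returns the empty set.

## Known limitations

* The regression treats rounded ECCs as binomial counts; at low depth the
  extra read-sampling variance is absorbed globally by λ rather than
  modelled per pool. A beta-binomial pool model would be the refinement.
* The permutation test permutes pool labels, so its resolution is limited by
  the number of distinct case/control labelings of the pools.
* Functional variant classes for burden scans are taken from a user-supplied
  gene map (annotation is out of scope).
* Indels are not simulated or tested; the machinery is SNV-only.
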