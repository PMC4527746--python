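# Methods

## Data model

The pipeline starts downstream of array processing: genotype calls
(AA/AB/BB/NC) and normalized copy-number (CN) signal per probe, for paired
blood and tumor DNA of each patient, plus probe annotation (chromosome,
arm, position, cytoband, gene) and a clinical table (sex, age, smoking,
alcohol, stage, site, nodal status, follow-up months, vital status with
cause of death).  Only autosomes are modeled; the blood reference level is
fixed at CN = 2.

## LOH inference

LOH status is a deterministic function of the paired calls: blood AB with
tumor homozygous → LOH; blood AB with tumor AB → retained; anything else
(germline-homozygous probe, or a no-call in either tissue) →
non-informative.  A no-call carries no evidence either way, hence
non-informative.  Probes non-informative in every sample cannot evidence
LOH anywhere and are removed; the filter is idempotent.  LOH frequencies
divide by informative samples by default — a germline-homozygous patient
cannot lose heterozygosity — with an all-samples denominator available,
since either convention is defensible for consensus plots.

## Segmentation

Parent/allele-specific CN estimation is deliberately out of scope: the
downstream calling rule consumes only segmented per-probe values, so the
package uses recursive binary segmentation on difference series
(tumor − blood for tumor; blood − 2 for blood).  At each step the split
maximizing the pooled two-sample *t* statistic between the flanks is
accepted iff |t| > `t_threshold` (default 4.0) and both children have at
least `min_seg_len` probes (default 10).  The defaults are conservative
enough that pure-noise chromosomes usually stay a single segment (|t| of
the best spurious split on a few hundred Gaussian probes rarely exceeds
4), while implanted steps of ≥ 0.5 CN are found reliably.  Zero-variance
flanks (noise-free steps) are handled by scale-relative tolerances: equal
means score t = 0, different means t = ∞.  Each probe is assigned its
segment mean; segments within a chromosome are contiguous and exhaustive.

## Blood-null empirical FDR and final calls

Blood is assumed free of true somatic CN change, so blood probes surviving
a magnitude cutoff estimate the false calls among tumor probes surviving
the same cutoff.  Per subject, FDR(c) = (blood count)/(tumor count), with
0/0 and k/0 defined as 0 (no discoveries, nothing false).  Subject ratios
can exceed 1 and are stored raw; they are capped at 1 when averaged across
subjects.  The default selection takes one global cutoff — the smallest on
a grid of 0.05–2.0 by 0.05 (CN scale) whose cross-subject mean FDR is ≤
the 10% target — so per-subject realized FDRs vary around the mean, which
matches how an average-targeted procedure behaves; a per-subject-cutoff
mode is provided but not default.  Calls: difference ≥ c → gain, ≤ −c →
loss, else neutral; difference ≥ 5 → high-level amplification.  Joint
LOH × CNA classes follow the copy-number typology of LOH (loss ≤ 1,
neutral = 2, gain ≥ 3), with non-informative LOH mapping to UNINFORMATIVE
regardless of CN.

Because segmentation averages noise over segments, the blood track is
usually flat and near zero, so the smallest grid cutoff is typically
selected and the realized false-call proportion (measured against
implanted truth) is dominated by ±1-probe boundary error of true segments
plus occasional spurious segments — a few percent, comfortably inside the
10% average target.

## Landscape statistics

All tier thresholds are strict: frequent means fraction > 0.20, extreme
> 0.80, large-region means > 0.50 of an arm's probes in one sample.  Arm
membership comes from the annotation file only (no internal centromere
table).  Per-sample burden uses all probes as denominator so that
%CNA = %gain + %loss holds exactly.  Top-k tables break ties by genomic
order.

## Survival screen

Cause-specific analysis: the event is cancer-specific death; deaths from
other causes are censored at the death time.  Per probe the design is CNA
∈ {−1, 0, +1} (loss/neutral/gain; a continuous segmented-difference coding
is optional), LOH ∈ {0, 1} with non-informative coded 0 (excluding those
patients probe-by-probe would change the risk set per probe), their
product, and the fixed adjusters sex, continuous age, and smoking as
never/former/current one-hot.  Fits maximize the Efron partial likelihood
(lifelines); the no-covariate log partial likelihood is computed in closed
form for nested tests against the null model.  `p_all` is the 3-df LRT of
the genomic block, `p_interaction` the 1-df LRT of the product term.

Monotone-likelihood and non-converged fits are kept as flagged rows with
"undetermined" stratum signs rather than dropped: their coefficient signs
are meaningless, and their LRT statistic has no chi-square reference, so
calibration claims in the test suite are made over regular (converged)
fits only.  Exactly collinear designs (e.g. a probe where every LOH
carrier also carries the loss, noise-free) are skipped and logged.

Probes with LOH in fewer than 5 samples are excluded before testing
(strict: exactly 5 is retained).  Bonferroni uses 0.05 divided by the
number of probes actually tested.  Storey q-values estimate π₀ at
λ = 0.5, clipped into [1/m, 1] (the floor avoids degenerate all-zero
q-values when every p is small), then q(p₍ᵢ₎) = min over j ≥ i of
π₀·m·p₍ⱼ₎/j; q-value families for `p_all` and `p_interaction` are kept
separate.

## Clustering and association

Binary LOH profiles are compared by Jaccard distance (absence-absence
pairs carry no signal), CN difference profiles by Euclidean distance;
complete linkage, dendrogram cut into exactly two groups, with a flagged
degenerate result when all samples are identical.  Distance and linkage
are exposed as configuration.  Fisher exact p-values for 2 × k tables
(k ≤ 6) come from full enumeration of tables with the observed margins,
summing probabilities ≤ that of the observed table; tables beyond ~2×10⁶
states use a seeded permutation Monte-Carlo mode.  Mortality comparison
uses the two-group log-rank statistic (O − E)²/V from the per-event-time
hypergeometric moments, and cumulative incidence is reported as
1 − Kaplan–Meier with competing deaths censored; a true competing-risks
(Aalen–Johansen) estimator is out of scope, so the curves mildly
overestimate absolute incidence when competing mortality is heavy, while
the log-rank test of the cause-specific hazard is unaffected.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: default 75
samples and 5,000 probes over 4 chromosomes with p/q arms; germline
heterozygosity 0.3 per probe i.i.d. (no linkage disequilibrium — nothing
downstream uses it); implanted segment templates covering all three LOH
classes, plain gain/loss, and one focal high-level amplification (tumor
CN 7–8), at carrier fractions 0.15–0.45 including one whole-arm event;
Gaussian CN noise with sd 0.3 — the simplest family that exercises
segmentation and the FDR machinery; tumor genotype het↔hom flip errors at
rate 0.01 applied after implantation (blood calls are taken as the
germline truth, so the spurious-LOH rate at informative probes equals the
flip rate); an optional purity parameter shrinks the tumor signal toward
2 (default 1: the design emulates microdissected tumor).  Carriers for
each template are drawn among samples without a contradictory overlapping
assignment, and generation fails with an explicit conflict message when a
carrier fraction cannot be satisfied; overlaying gain-LOH, gain-only and
copy-neutral-LOH templates on one region with disjoint carriers is how
the validation scenarios populate all four (CNA, LOH) cells at a probe.

Survival times are exponential with rate baseline·exp(lp), where lp sums
the genomic effects at designated probes (ternary true-CN code, true LOH,
product), covariate effects (sex 0.2, age 0.02/yr centered at 60, former
smoking 0.3, current 0.6), and an optional planted-cluster effect.
Baseline 0.0023/month and competing-death rate 0.0025/month with
administrative censoring at 120 months are calibrated so a null 75-patient
cohort averages ≈ 24 cancer deaths and ≈ 16 other deaths — the event mix
of the cohort the design emulates (the baseline absorbs the ≈ 1.68×
average relative risk contributed by the covariate effects).

What the generator does not emulate: linkage disequilibrium, allele-level
intensities (B-allele frequencies), wavy CN artifacts, batch effects,
subclonal mosaicism, or germline CNVs in blood.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to platform artifacts.

## Validation study sizes

The replicated studies in the test suite and `scripts/acceptance.py` use:
20 cohorts × 75 samples × 5,000 probes for FDR control; 16 global-null
cohorts of 150 samples × 150 identifiable probes (≈ 2,000+ regular tests
pooled) for interaction-test calibration; 50 replicates at n = 300 for
opposite-sign recovery; 23-vs-52 noise-free blocks for planted-partition
recovery.  These sizes give Monte-Carlo standard errors small enough for
3-SE acceptance bands while keeping a full run at desk scale.

## Known limitations

* The segmenter is a generic change-point procedure, not an allele-specific
  CN model; it does not use genotypes, so balanced events are invisible to
  the CN track (they are still caught by the LOH track).
* Cumulative incidence by 1 − KM, not Aalen–Johansen (above).
* The q-value π₀ estimator uses a single λ rather than a smoothed spline
  over a λ grid; with few p-values it is noisy, which the [1/m, 1] clip
  bounds.
* Fisher enumeration is exponential in k; beyond the enumeration bound the
  Monte-Carlo mode trades exactness for a seeded estimate.
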