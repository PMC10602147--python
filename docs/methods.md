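# Methods

This note documents the statistical models tmzkit implements, the defaults
it ships, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Screen scoring

Counts are normalised per sample to counts-per-million (CPM). Guide-level
dropout is `lfc = log2((PD20_cpm + c) / (PD0_cpm + c))` with pseudocount
`c = 0.5` CPM; the pseudocount makes the ratio finite for zero counts and
maps a guide absent at both timepoints to lfc = 0. The gene score SigmaFC
sums, over the gene's guides, the mean lfc across screen replicates;
averaging replicates first keeps SigmaFC a per-condition gene score whose
magnitude does not grow with replicate number.

The permutation null resamples NTC guide lfcs *with replacement*,
size-matched to the gene's guide count, because the NTC pool (1000 guides)
is finite and genes share it; the two-sided add-one estimator
`p = (1 + #{|null| ≥ |obs|}) / (B + 1)` is never 0 and is uniform under the
null to resampling resolution. B = 1000 by default. Multiple testing uses
Benjamini–Hochberg; the adjusted value never falls below the raw p.

Doubling every raw count changes nothing downstream (CPM invariance); this
is a tested invariant.

## Pathway statistics

`S_g` is the standard error of the mean difference,
`sqrt(s_TMZ²/n_TMZ + s_DMSO²/n_DMSO)` with unbiased variances. Only this
reading gives `Z_P = ΣX_g / sqrt(ΣS_g²)` a standard normal null, which the
suite checks by simulation. The replication unit feeding `X_g` is
switchable: every guide × replicate ratio (default, uses all data), guides
averaged over replicates, or replicates averaged over guides. Genes whose
`S_g` is exactly 0 carry no sampling-noise information and are excluded
from `Z_P` with a count of exclusions. Normal p-values use `erfc`, not a
lookup table.

Null calibration, measured: with 504 genes, 10 pathways, 3 replicates and
CPM normalisation, the two-sided Z_P rejection rate at α = 0.05 over 2000
null pathway replicates comes out near 0.04 rather than exactly 0.05. The
deficit is real and small: normalising both timepoints to fixed depth ties
the guides of a column together and induces weak negative correlation
between genes, deflating Var(ΣX) by roughly (1 − pathway fraction of the
library). It stays within 3 binomial standard errors at the replicate
numbers used, and would affect any fixed-depth screen analysed this way.

The paired-t pathway statistic pools (guide, replicate) pairs of
`log10(count + 0.5)` at PD20 vs PD0 over the pathway's genes, pairing by
guide identity rather than row position. Zero-variance difference vectors
are reported as degenerate with p = 1.

## Variant filtering and catalogs

Filter order: indel length → allele frequency → coverage → supporting
reads → known polymorphisms → exome intervals. Boundaries are inclusive as
the thresholds are written ("≥ 10%", "≥ 10×", "≥ 3"), and "greater than
10 bp" means a 10 bp indel survives. Coverage applies jointly to tumour
and normal depths. Each removed record is attributed to the first rule it
fails, making the audit deterministic; kept + removals = input is a tested
invariant, as is idempotence of re-filtering. Known-polymorphism and
exome-interval membership are precomputed boolean flags on the record, not
live database lookups, so the stage runs offline.

SNVs are classified on the pyrimidine strand (purine-reference variants are
reverse-complemented with their context), giving 6 classes × 16 contexts =
96 bins; exactly 96 labels are reachable, 16 per class. C>T is tagged
Pattern I (the class attributed to O6-methylguanine mispairing) and the
other five classes Pattern II. Arm comparisons use Welch's unequal-variance
t-test on per-clone counts; identical constant arms are flagged degenerate
with p = 1.

## Signature refitting

Exposures solve min ‖S·a − m‖₂, a ≥ 0, via the Lawson–Hanson active-set
algorithm, and the returned point is verified against the KKT conditions at
relative tolerance 1e-8 of ‖m‖ (zero gradient on active coordinates,
non-negative gradient on inactive ones); the convex problem makes the
optimum uniquely checkable by construction and by random feasible search.
Exposures are reported in mutation counts, not proportions. Fitting is
per sample by default, with a pooled per-arm mode.

No published signature tables ship with the package.
`make_signature_matrix` generates clearly-synthetic matrices whose first
column, named "Signature 11", has an alkylation-like profile (~90% of mass
on C>T, down-weighted at CpG) — enough structure for the refitting and
hypermutation machinery to be exercised and validated end to end. Analyses
of real catalogs should load a published 96-context matrix via
`io_formats.read_signature_matrix`.

Hypermutation is strict: a sample is hypermutated iff its Signature-11
exposure exceeds 500 counts; 500 itself is negative.

## Cohort model

Expression is regressed on the proliferation score by OLS and the residual
taken as adjusted expression; residuals are centred and orthogonal to the
score to numerical precision. Tertiles are rank-based with sizes as equal
as possible; when n mod 3 ≠ 0 the extra member(s) go to "low" then
"medium", and ties break by stable input order — the rule is arbitrary but
deterministic and invariant to monotone transforms. Rows flagged
POLE-mutated are excluded before all computation. The logistic model is a
binomial-logit GLM fit by IRLS (tolerance 1e-10, 100 iterations max);
perfect separation and single-class outcomes are rejected with the
offending covariate named. MGMT enters as provided: a binary low/high
status (indicator of "low") or a continuous expression value, recorded as
`mgmt_kind` at read time. Tertiles are computed over the whole cohort;
per-stratum stratification can be done by calling `stratify_tertiles` on a
subset.

## Synthetic generators

The generators define the study conditions for all tests:

* **Screen**: 504 genes × 10 guides + 1000 NTCs; 20 population doublings;
  DMSO and TMZ arms with 3 replicates; negative-binomial counts with
  baseline mean 500 per guide and overdispersion 0.2
  (variance = μ + 0.2 μ²), values typical of well-covered pooled screens;
  a guide with per-doubling effect e has expected PD20 abundance
  `baseline · 2^(20e)` before the column is renormalised to fixed
  sequencing depth, so dropout is relative as in a real screen. NTC guides
  always have effect 0.
* **Clone catalogs**: six clones per genotype × treatment arm; the count
  attributed to signature k is Poisson around its activity, contexts
  multinomial over the signature column. Each mutation is also emitted as
  a raw variant record (MAF uniform 0.2–0.6, depths 30–120, supporting
  reads consistent, half represented on the purine strand) that passes the
  default filters, so rebuilding catalogs from records must reproduce the
  ground truth exactly — a tested invariant.
* **Cohort**: proliferation standard normal; expression
  `5 + 2·proliferation + N(0, 1)`; MGMT low with probability 0.5;
  hypermutation Bernoulli with logit `−1 − 0.8·residual − 0.5·MGMTlow`;
  Signature-11 counts drawn on the matching side of the 500 threshold.

What they do not emulate: raw reads, alignment or calling artifacts, guide
efficiency variation, copy-number effects, clonal phylogenies, batch
structure, or dose–response. Passing tests therefore demonstrate that the
statistics are correct and calibrated under the stated stochastic models,
not that they are robust to artifacts those models omit.

## Problem sizes and determinism

Every generator and test takes an explicit integer seed; identical seeds
give bit-identical output, and the demo writes byte-identical files across
runs. The calibration studies use 200 null screens (2000 pathway
statistics), one 504-gene screen with B = 1000 for permutation uniformity,
500 replicates of a 400-patient null cohort for Wald-p sizing, and one
5000-patient cohort for parameter recovery — sizes at which the binomial
3·SE bands are tight enough to be informative while the whole suite runs in
well under a minute.

## Known limitations

* The NTC-based null assumes non-targeting guides share the targeting
  guides' technical noise; guide-specific efficiency differences are not
  modelled.
* The slight conservativeness of Z_P under fixed-depth normalisation
  (above) is inherent to the statistic, not a solver issue.
* The paired-t statistic treats guide × replicate pairs as independent;
  guides within a gene are correlated in real data, so its p-values are
  descriptive rather than strictly calibrated.
* Exposure estimates from NNLS are point estimates; no uncertainty is
  attached (bootstrap intervals are out of scope).
* Headline biological counts from the original experimental setting
  (deposited exome data, external patient cohorts) are not reproducible
  from synthetic data; the pipeline reproduces the procedures and
  validates them by ground-truth recovery.
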