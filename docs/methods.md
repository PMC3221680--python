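# Methods

## Measurement model

Bisulfite pyrosequencing reports, per (sample, locus), a **methylation
density**: the percent of methylated cytosines averaged over the CpG sites
assayed at the locus (CpG sites within one promoter are highly concordant, so
the arithmetic mean is the locus summary; the per-CpG values may be kept
alongside, in which case the stored density must equal their mean to 1e-9).
Densities live in [0, 100]; missing measurements are `NA`. Matrices are
written with the shortest positional decimal that round-trips the float, so
write → read is bit-exact.

## Calling rules and their boundaries

All thresholds are collected in `ThresholdConfig`; every comparison against a
cutoff is **strict**:

| parameter | default | meaning |
|---|---|---|
| `density_cutoff` | 15 (%) | methylated iff density > 15 |
| `fold_cutoff` | 2 | meaningful drift iff fold > 2 |
| `cimp_min_markers` / `cimp_panel` | 2 / six markers | CIMP-positive iff ≥ 2 of MINT1, MINT2, MINT31, p16, p14, MLH1 methylated |
| `mcam_log2_cutoff` | 1.0 | array gene hypermethylated iff mean normalized log₂ ratio > 1 |
| `metachronous_min_months` | 12 | metachronous iff interval ≥ 12 months (closed bound) |
| `ci_level` | 0.95 | confidence level for normal-approximation CIs |

A density of exactly 15% is unmethylated; a fold of exactly 2 is not drift;
the 12-month timing bound is the one *closed* boundary (an interval of
exactly 12 months is metachronous).

**Paired drift.** Each measurement pair (both members observed) receives two
independent labels. Concordance binarizes the two densities separately.
Drift requires fold = max/min > 2 AND max > 15%, with direction from the
larger side. Degenerate folds: both densities 0 → fold 1 (no change); one
density 0 → fold ∞, so the 15% clause alone decides. The labels can
disagree (20 → 45 is concordant-methylated yet an increase); this is
intentional — concordance asks whether the methylated *state* changed,
drift whether the *level* changed meaningfully.

**CIMP with missing panel markers.** Positive when measured methylated
markers ≥ 2; negative when methylated + missing < 2 (no assignment of the
missing markers could reach the threshold); indeterminate otherwise. This is
the only three-way rule that never contradicts the complete-data rule.

**Z-scores.** z = (x − mean)/SD per gene with the sample SD (n − 1); the
sample universe the moments were computed over is recorded in the result,
since z-scores are only comparable within a stated universe. Constant genes
raise an error naming the gene. Panel scores are means over non-missing
z-values.

## Group statistics

Tests are two-sided throughout. **No multiple-testing correction is applied
across loci**: per-gene P values are reported as-is, in keeping with
candidate-gene reporting practice; users comparing many loci should adjust
downstream.

*Mann-Whitney U*: midranks for ties; exact enumeration (scipy) when both
groups have n ≤ 8 and the pooled data are tie-free, otherwise a
tie-corrected normal approximation with a **signed** continuity correction
(the correction is σ(U − μ)·½, as in R's `wilcox.test`, so identical samples
give p = 1; an unsigned correction would give ≈ 0.8). Enumerating the exact
null distribution shows the approximation's worst-case two-sided error is
below 0.02 only once both groups have ≥ 5 values (0.031 at 4 vs 4, 0.088 at
2 vs 2) — which is why the exact path serves all n ≤ 8. Simulated null
calibration at the study's group sizes (36 vs 43, beta-mixture data) gives a
type-I error within 5% ± 1.5%.

*Confidence intervals*: mean ± z(level)·s/√n with the z (not t) multiplier;
the lower bound is deliberately **not truncated at zero** (group means of
near-zero percentages legitimately carry negative lower bounds). The
difference from a t multiplier at n ≈ 36–43 is cosmetic.

*Contingency tests*: Pearson χ² without continuity correction; Fisher's
exact test whenever a 2×2 table has any expected cell < 5 (the standard
operationalization of "small numbers"). Fisher p-values equal two-sided
hypergeometric tail sums (verified by full enumeration over all tables with
total ≤ 30).

## Two-channel array analysis

Metastasis amplicons are Cy5-labeled and cohybridized against Cy3-labeled
primary amplicons. Per probe, A = ½(log₂Cy5 + log₂Cy3) and
M = log₂(Cy5/Cy3). Within-array lowess of M on A (span 0.4 of probes per
local fit, one robustness iteration; both adjustable — the exact settings of
the original normalization are not recoverable, so these are documented
defaults, not a claimed match) yields M_norm = M − trend(A). The gene
statistic is the **mean of its probes' M_norm** (least-assumption
aggregation; "any probe > cutoff" is available as an option), and a gene is
hypermethylated when that mean strictly exceeds 1.0. Percentages are taken
against the declared gene universe; universe genes without probes are
excluded from the denominator and reported. Dye-swap antisymmetry (swapping
channels negates M_raw exactly, M_norm to refit tolerance) is tested.

Note that lowess removes *smooth intensity-dependent dye bias*, not true
differential methylation: when many genes genuinely gain methylation, the
gained genes concentrate at high intensity with positive M, and a residual
correlation between A and M_norm of ~0.06 is real signal. The bias-removal
property (|corr(A, M_norm)| < 0.05) is therefore assessed on arrays
simulated *without* drift.

## Synthetic cohort generator

The generator separates the two quantities the analysis is designed to
distinguish:

* **Frequency** f_g — each locus is latently methylated in a patient's
  primary tumor with probability f_g. Defaults for the 13-locus candidate
  panel span 0.10–0.60, mirroring the spread from rarely methylated tumor
  suppressors (MLH1) to frequently methylated age-related loci; other
  universes default to 0.3.
* **Density** — methylated loci draw Beta(2, 2)·100 (broad, mean 50%);
  unmethylated loci Beta(1, 30)·100 (mass near 0). The Beta(2, 2) default
  overlaps the 15% cutoff slightly, as real tumor data do; recovery tests
  that require separation across the cutoff use Beta(5, 5).

The matched metastasis is a clone of the primary plus drift over the
resection interval t (months): frequency gains at per-locus hazard
r_gain·t (default r_gain = 0.002/month — no empirical rate is published;
chosen so a 46-month interval yields roughly a 9% gained-gene fraction,
the scale seen on metachronous arrays), frequency losses at
r_loss·t (0.0005/month), and density inflation ×2.5 on 25% of loci
methylated in both tumors. Inflation is only drawn among loci whose inflated
density stays ≤ 100 (a multiplicative increase is modeled in the
non-saturated regime; saturated inflations would realize a fold below the
nominal factor). Observed density = purity·tumor + (1 − purity)·baseline +
Gaussian noise, clipped to [0, 100] (clipped mass is logged). Defaults:
purity 0.9 (specimens contain ≥ 80% tumor cells), normal baseline 2%, noise
SD 2 percentage points. Cohort shape defaults: 79 patients, 43 with liver
metastasis, 16 matched pairs; metachronous fraction 7/43 with intervals
12–46 months, synchronous 0–11. All randomness flows from one seeded
generator; identical config ⇒ identical output.

Array signals: probe count per gene ~ 1 + Poisson(1.8) (≈ 2.8 probes/gene,
matching an 18 340-probe/6 528-gene design), channel intensity ∝ density +
background with log-normal probe noise, and a smooth monotone
intensity-dependent dye bias (tanh of standardized A, amplitude 0.8 log₂
units) applied to Cy5 to exercise the normalization.

**What the generator does not model** — and hence what passing recovery
tests do not establish about real data: correlation between panel markers
(CIMP tumors methylate markers jointly, so at matched marginal frequencies
the simulated CIMP-positive rate runs higher than real cohorts'), bisulfite
conversion failure, allele-specific (mono- vs biallelic) methylation,
locus-specific normal-cell baselines, pyrosequencing chemistry, and probe
cross-hybridization.

## Reporting

Human-readable numbers round half away from zero at the displayed precision
(integers for count percentages, one decimal for mean densities and
gene-fraction percentages); internal values are full precision. Every number
in a report is a formatted view of a machine-readable field; pipeline
outputs carry the resolved run configuration in their headers. Published
gene-fraction percentages are not always consistent with their own counts
(a 716/6528 call set prints as both 10.8% and 10.9% in different places,
while the ratio is 11.0%); the package computes percentages from counts and
documents, rather than reconciles, such inconsistencies.

## Problem sizes in the test suite

The suite exercises full-size problems where the check is cheap
(the 101×101 integer grid for the pair rules, all 2×2 tables with total
≤ 30 for Fisher, ~18 000 probes for normalization) and scaled
simulations elsewhere (2 000 null replicates for test calibration;
200 patients × 500 loci for frequency/drift recovery; 2 000-gene arrays for
the interval-trend property), sizes at which the binomial/empirical error
bands quoted in the tests are already tight.

## Known limitations

* The drift rules are locus-level; no per-CpG-site paired comparison.
* CIMP is the binary two-of-six rule only (no high/low/0 refinements).
* The Mann-Whitney exact path requires tie-free data; with ties the
  tie-corrected approximation is used regardless of n.
* Lowess normalization assumes the majority of genes are non-differential;
  arrays dominated by genuine gains violate that assumption, as on any
  two-channel platform.
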