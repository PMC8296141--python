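# Methods

This note documents the statistical model behind each stage, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was open.

## Trial design and the ANOVA model

The screening trial evaluates 64 sorghum genotypes in a resolvable square
lattice: three complete replicates, each partitioned into eight incomplete
blocks of eight plots, in two environments (a *Striga*-infested field and
inoculated pots). The analysis fits a fixed-effects ordinary-least-squares
decomposition with sequential (type-I) sums of squares in the order

    replicate -> block within replicate (lattice only) -> genotype -> residual.

Degrees of freedom are obtained as rank increments of the growing design
matrix, so confounded or unbalanced layouts (missing plots) are handled
exactly; a term that adds no rank simply contributes a zero-df row, and a
genotype term fully confounded with the blocking structure is an error.
F statistics test each source against the residual mean square.

This is the classical intra-block analysis. Recovery of inter-block
information by REML is deliberately out of scope: the downstream
variance-component formulas consume the genotype and error mean squares,
which the intra-block analysis provides reproducibly from first principles.
One consequence worth knowing: because the incomplete blocks absorb part of
the genotype signal, the genotype mean square is mildly deflated relative
to a complete-block design, so heritability estimated from a lattice fit
runs a few points below the generative truth (about 56–57% observed at a
true 60% in the recovery simulations).

The genotype sum of squares is further partitioned — sequentially, in the
order 1-df parents-vs-progenies contrast, among-parents, among-progenies —
and the three components sum to the genotype SS by construction. The
parents-vs-progenies mean square is defined here as that group contrast;
this is an explicit modeling decision, since several equally plausible
definitions exist. The pooled two-environment table fits environment as a
fixed 1-df source followed by each trial's own decomposition nested within
environment; the pooled residual is the sum of the per-trial residuals.

## Variance components, GCV/PCV, heritability, LSD

With r replications, MS_g and MS_e give

    sigma2_g = (MS_g - MS_e)/r,  sigma2_e = MS_e,  sigma2_p = sigma2_g + sigma2_e.

Negative sigma2_g estimates (MS_g < MS_e) are clamped to zero and flagged,
which keeps H2 = 100 sigma2_g / sigma2_p inside [0, 100]. The clamping has a
known cost: under a true sigma2_g of 0 the estimator's mean is not 0 but the
positive-part floor, about 3 percentage points at this design size (the
median is exactly 0). GCV and PCV are 100·sqrt(variance)/grand-mean — the
square-root form of the coefficient of variation, as in the standard
plant-breeding references. Heritability classes: low 0–30%, moderate
30–60%, high >60%.

Fisher's LSD, t(1-alpha/2, df_e)·sqrt(2 MS_e/r), is protected: compact
letter groupings are produced only when the overall genotype F test is
significant at alpha (default 0.05); otherwise the LSD value is reported
with groupings suppressed. Letter assignment uses maximal runs of sorted
means whose range does not exceed the LSD.

## Striga progress statistics

ASNPC is the trapezoidal area under the emerged-count curve over exactly
the recorded assessment dates. No zero count is prepended at sowing or at
the first-emergence date — alternative conventions change the values, and
the literal-sum convention is used throughout. A single-observation series
has zero area. NSFC (capsule-forming plants at 105 days after sowing) is a
directly recorded trait, never derived from the count series.

## Correlations

All correlations are Pearson's r on genotype means with pairwise-complete
deletion, significance from t = r·sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom, starred at 0.05/0.01/0.001 with no multiple-testing correction
(matching standard practice for these trial reports). Whether within-trial
correlations should use plot-level or genotype-mean data is a genuine
choice; genotype means are used consistently for both within- and
across-trial correlations.

## Residual heterosis

Residual heterosis at F4 is 100·(F4 − MP)/MP with MP the arithmetic
mid-parent of the two parental genotype means from the *same environment*
as the F4 mean. Crosses are directional (A × B ≠ B × A). Crosses with a
parent absent from the trial (e.g. failed germination) or a zero mid-parent
are excluded with a logged reason. Rankings sort descending for
higher-is-better traits (HGW) and ascending for lower-is-better traits
(NS_max), ties broken by cross id.

## SNP analyses

Marker filtering keeps SNPs with call rate ≥ 0.80 and minor-allele
frequency ≥ 0.05 by default; the thresholds are configuration, and the
filter is idempotent. Informative markers for a cross are those where both
parents are non-missing, homozygous, and opposite — a heterozygous or
missing parent call makes A/B assignment ambiguous, so such markers are
excluded, mirroring standard ABH-encoding practice. Progeny heterozygosity
percentages are computed over non-missing codes only.

The diversity distance is allele-sharing identity-by-state,
d = 1 − shared alleles/(2·overlapping markers); with dosage coding this is
mean |g_i − g_j|/2 over the pairwise-complete overlap. Neighbor joining is
the standard Saitou–Nei agglomeration with two pinned numerical choices:
Q-criterion ties break on the lowest (i, j) index pair, and negative
branch-length estimates are clamped to zero with the excess transferred to
the sister branch (preserving the pair's summed length). On additive
matrices the method is exact — the generating topology and all path lengths
are recovered — which the test suite verifies on random additive trees. No
bootstrap support is computed.

## The synthetic-data generator

The generator emulates the study conditions so that downstream estimates
can be checked against known truth:

- **Panel composition**: 64 genotypes — 17 wild, 8 landraces, 13 improved,
  26 F4 crosses whose parents are drawn from the improved + landrace pool.
- **Layout**: the 3-replicate lattice with blocks of 8, blocks re-randomized
  per replicate.
- **Traits**: additive Gaussian model, value = mean + genotype effect
  (variance sigma2_g, drawn once per genotype within a trial) + replicate
  effect + block effect + plot error (variance sigma2_e). Replicate and
  block effects default to variance 0.1·sigma2_e each — the design is given
  by the study, the nuisance scale is a modeling choice. Default trait
  means and variances are set to field-realistic scales (e.g. HGW ~2.6 g
  with moderate heritability). Scores are clipped to the 1–9 scale and
  weights floored at zero, which slightly truncates the tails.
- **Striga counts**: negative-binomial counts with mean
  baseline-curve(day) × genotype susceptibility and dispersion k = 2 by
  default (field counts are overdispersed; k → ∞ gives the Poisson limit).
  The baseline rises over the biweekly assessments (days 49–91) toward a
  plateau — the emergence-curve shape is a modeling choice, as no canonical
  curve exists. Susceptibilities are lognormal with median 1; the pot
  environment uses 0.3× the field baseline, mirroring the lower pot
  infestation pressure.
- **SNPs**: parents are fully homozygous inbreds with per-marker alternate
  allele frequencies uniform on the MAF range and 2% missingness; F_g
  progeny are heterozygous at informative loci with probability 0.5^(g−1)
  (F1 = 1, F4 = 0.125), otherwise fixed for either parental allele with
  equal probability. Loci are independent — linkage is ignored, which is
  irrelevant to the per-locus hybridity expectations checked downstream.

What the generator does **not** emulate, hence what passing tests do not
show about real data: genotype effects are drawn independently per
environment (no genotype × environment model), so across-trial correlations
of agronomic traits are near zero in simulation even though real trials can
show them; *Striga* susceptibility, by contrast, is shared across
environments, so the Striga traits do correlate across trials. NSFC is
simulated as an independent trait rather than being driven by the same
susceptibility as the count series, so the strong real-world
ASNPC–NSFC correlation is absent. There is no spatial trend, no
genotype-specific emergence timing, and no linkage.

## Problem sizes and determinism

Every simulator is a pure function of (parameters, seed); pipelines and the
acceptance script derive all randomness from one seed, and reruns are
byte-identical. The recovery simulations use the study-scale design (64
genotypes × 3 replicates) with 200–500 independent trials, 500 progeny ×
1,000 loci for the F4 heterozygosity check, 100 random 8-taxon trees for
the neighbor-joining check and 2,000 replicates for test-calibration
checks — sizes chosen to put Monte-Carlo error well inside the tolerances
being asserted.

## Known limitations

- Intra-block fixed-effects analysis only; no REML/inter-block recovery, no
  spatial adjustment, no narrow-sense heritability.
- The clamped variance-component estimator is biased upward at the null
  (positive-part bias, ~3 points at this design size) and the lattice
  genotype mean square is mildly deflated (H2 underestimated by ~3–4 points
  at a true 60%).
- The parents-vs-progenies mean square is the 1-df group contrast by
  definition here; other definitions would give different values.
- No imputation, population-structure modeling or bootstrap support in the
  SNP stage.
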