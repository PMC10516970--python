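# Methods

## Model and assumptions

vapor-qSIP estimates how much ¹⁸O a taxon incorporated into its DNA during an
incubation with isotopically enriched soil water, and converts that into a
relative growth rate. Three model layers are involved.

**Isotope delivery.** The dosing volume solves a two-component mass balance:
mixing `V` µl of tracer water (atom% `added`) into `V_sw` µl of soil water at
natural abundance (0.2 atom%) yields the target enrichment, so
`V = V_sw·(NA − target)/(target − added)`. The soil water does not reach the
target instantaneously; a calibration time series is fitted with a saturating
exponential `e(t) = a·(1 − e^(−kt))` and the growth-rate denominator uses its
time average over the incubation window `[0, T]`,
`ē = a·(1 − (1 − e^(−kT))/(kT))`. The curve is purely empirical: no vapor
transport physics, no headspace geometry. We fit excess enrichment above zero
rather than adding a natural-abundance offset term; at plateau values of
~60–70 atom% the 0.2 atom% baseline is negligible relative to measurement
scatter, and a two-parameter fit is better determined by 4–5 calibration
points.

**Density shift → enrichment.** DNA buoyant density is linear in GC fraction
(`W = 0.083506·GC + 1.646057` g/mL) and DNA molecular weight is linear in GC
(`M_light = 0.496·GC + 307.691` g/mol); full ¹⁸O substitution of DNA oxygen
adds 12.07747 g/mol. GC is inferred from the taxon's unlabeled weighted
average density, so no sequence information is needed. The relative WAD shift
between labeled and unlabeled tubes maps to a molecular-weight shift and, after
scaling by the maximal shift and subtracting natural ¹⁸O abundance
(0.002000429), to the excess atom fraction. All constants live in
`QsipConstants` and can be overridden. The forward model
(`wad_shift_from_eaf`) and the estimator (`excess_atom_fraction`) are exact
inverses (machine precision), which the test suite exploits heavily.

**Enrichment → growth.** Assuming linear growth, a taxon whose DNA is as
enriched as the water pool replicated once per `days`; in general
`RGR = AFE_taxon/(AFE_water·days)` per day. This is a *relative* rate: no
biomass conversion, no CO₂ flux estimation is attempted.

## Estimator conventions

- Fractions are kept inside an inclusive 1.614–1.753 g/mL window with strictly
  more than 2000 read pairs. Taxa are kept per treatment when present (reads
  > 0) in ≥ 4 fractions in each of ≥ 2 **labeled** replicate tubes; "two
  replicates" could in principle count either isotope, and labeled tubes are
  the ones whose enrichment is estimated (`labeled_only` is exposed).
- Per-fraction taxon copies weight reads-proportions by the fraction's ddPCR
  total (`reads-only` weighting would make WADs independent of ddPCR; the
  ddPCR-scaled form is the package's default because it reflects the absolute
  quantification design; EAF is invariant to uniform scaling of either input).
- The unlabeled reference WAD of a taxon is the mean over the treatment's
  natural-abundance tubes, falling back to the global unlabeled mean when a
  taxon is missing there, and excluding (with a log entry) taxa absent from
  every unlabeled tube.
- Negative EAF (labeled WAD lighter than reference) is retained in the
  enrichment table — it is informative about noise — but clamped to zero in the
  whole-community mean-RGR summary and never counted as active.
- GC inferred outside [0, 1] is clamped and logged, not an error: density
  noise routinely pushes the linear inverse slightly out of range.
- Tube-level density offset correction (for tubes that lost fractions during
  fractionation) applies only to explicitly flagged tubes, never by
  auto-detection, mirroring how such accidents are diagnosed in practice.
- Mean per-sample RGR is the unweighted mean over taxa (growing-only, or all
  taxa with negative EAF clamped); proportional ¹⁸O assimilation renormalises
  growing-subset abundances to 1, weights by RGR and renormalises again, so it
  always sums to 1 per sample. Top-assimilator selection ranks at taxon level
  and only afterwards agglomerates labels genus → family → phylum.
- The growing share of the community is computed per sample and then averaged
  across replicates (matching replicate-level error bars), not from pooled
  copies per treatment.

## Synthetic data generator

The generator emulates the study conditions: a 2 × 2 factorial
(drought × climate) with four replicates, one labeled and one
natural-abundance tube each, 24 fractions of 250 µl on a 1.60–1.78 g/mL grid,
five-day incubation, soil-water enrichment drawn uniformly in 55–64 atom% per
treatment. A shared taxon pool (lognormal base abundances, σ = 1.3 on the log
scale; GC ~ U(0.3, 0.7); lineages drawn from a small weighted table that
includes predatory orders and unassigned genera) is given per-treatment growth
structure: scenario presets fix the abundance-weighted share of 16S copies in
growing taxa at 35 % (ambient), 4 % (drought), 45 % (future climate) and 9 %
(future climate + drought). Growing taxa draw EAF from Beta(2, 4) scaled to
(0.06, soil-water AFE) — safely above the 5 % APE threshold and capped by the
water-pool enrichment; 30 % of non-growing taxa are active below threshold
(EAF ~ U(0, 0.04)).

Within a tube, each taxon's DNA spreads over the density grid as a Gaussian
centered on its tube WAD with σ_d = 0.006 g/mL — a modelling choice (no
empirical within-tube spread is available) that lets DNA span ~4–6 fractions,
matching the ≥ 4-fraction prevalence filter; it is exposed in the design.
Unlabeled WADs sit on the density–GC line plus taxon-level noise
(sd 0.002 g/mL), so GC inference is imperfect as in real gradients; labeled
centers are computed from the *density-implied* GC so the forward–inverse
identity is exact and the w_light noise acts purely as GC misassignment.
Reads are multinomial over the tube's copy proportions (50 000 per tube by
default), ddPCR totals get lognormal noise (σ = 0.1) and densities Gaussian
jitter (sd 0.0005 g/mL). Seeding is hierarchical: one master seed, per-tube
and per-stage sub-seeds derived by CRC32 hashing of stable labels, so partial
re-simulation is reproducible.

Two deposition schemes distribute a taxon's Gaussian mass over fractions.
The default (`cdf`) integrates the Gaussian between bin edges — mass-exact,
but the binned first moment carries O(h²) discretization error. The `moment`
scheme deposits mass linearly onto neighbouring bin centers (hat functions),
which preserves the first moment exactly for mass inside the grid; the
noiseless configuration (`ExperimentDesign.noiseless`) uses it, together with
exact expected reads, so that estimated RGR equals truth to ~1e-14 — an
estimator identity check, not a realism claim.

**What passing tests do and do not show.** The generator has taxon-labeled
reads only: no PCR or primer bias, no chimeras, no sequencing error, no
compositional competition between treatments, and a single within-tube spread
for all taxa. Recovery results therefore demonstrate correctness of the
estimator chain under the stated noise model, not performance on real
gradients, where fraction loss, variable spreads and amplification bias add
structured error.

## Numerical choices

- Enrichment-curve fitting: `scipy.optimize.curve_fit`, start values
  `a₀ = max(values)`, `k₀ = 1/median(times)`, bounds `a ∈ [0, 100]`,
  `k ∈ [0, ∞)`. Flat nonzero series return `k = ∞` (instantaneous
  equilibration); all-zero series return the zero curve.
- The incubation mean uses `expm1` and switches to the second-order series
  `a·(kT/2 − (kT)²/6)` below `kT < 1e-6`: the naive closed form loses ~3 %
  relative accuracy already at `kT ≈ 1e-8` through cancellation.
- PERMANOVA partitions the Gower-centered inner-product matrix with
  sequential (Type-I) sums of squares in the order drought, climate,
  interaction — the order is configurable and matters only for unbalanced
  designs. `p = (1 + #{F* ≥ F})/(1 + n_perm)` with a seeded generator
  (default n_perm = 9999; a seed is always required). Degenerate geometry
  (zero residual mean square) defines F = 0 for terms explaining nothing, so
  identical points give p = 1 rather than NaN.
- Two-way ANOVA delegates to an OLS fit with Type-I SS (identical to any
  standard formulation on balanced designs and verified against a hand-coded
  SS oracle). Welch t-tests use the Welch–Satterthwaite df; two zero-variance
  groups with equal means return t = 0, p = 1 by convention.
- The gate runs Shapiro–Wilk on group-mean residuals and median-centered
  Levene at α = 0.05; groups smaller than 3, or constant data, make it
  abstain and route to the rank-based family. The rank fallback is the
  Mann–Whitney rank-sum with the exact null for n ≤ 8 per group.
- Benjamini–Hochberg is the standard step-up; note that BH is *not*
  idempotent (re-adjusting adjusted values inflates tied groups), so only
  monotonicity and `p_adj ≥ p` are guaranteed.
- CLR uses a pseudocount of 1 gene copy on the absolute-abundance scale
  before the log; exact scale invariance holds when the pseudocount is scaled
  with the data.
- EAF validation accepts the conventional domain [0, 0.998], marginally above
  the physical saturation 1 − 0.002000429; the linear forward model
  extrapolates harmlessly over the 4 × 10⁻⁷ gap.

## Problem sizes

Default analyses and tests run at 40–200 taxa, 2–4 replicates per treatment
and 20–50 k reads per tube; the PERMANOVA calibration check uses 200 null
datasets at n = 16 with 999 permutations. These sizes give stable estimates
of every reported quantity (shares to within a few percentage points, type-I
error to ±0.02) while keeping a full run in seconds on a single core.

## Known limitations

- No bootstrap confidence intervals on EAF; enrichment is replicate-level.
- The hierarchical mixed model (genus-level growth with sample random
  effects) used in companion analyses is out of scope here.
- The Venn worked-example region counts are reconstructed from reported
  pairwise sums; singleton regions are synthetic placeholders (marked as such)
  and do not affect the computed sums.
- Raw-read processing (ASV inference, taxonomic classification, contaminant
  removal) is upstream of this package; inputs are feature tables.
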