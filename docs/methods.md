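# Methods

## The exposure model

The package treats each sampled home as a single well-mixed zone observed
through one time-integrated canister sample. Three steady-state
assumptions carry all the physics:

1. **Occupant CO₂ balance.** Occupants are the only indoor CO₂ source, and
   ventilation the only sink. At steady state the air change rate is
   `ACR = G_total / (V_adj · ΔC·10⁻⁶)`, where `G_total` is the summed
   per-occupant metabolic generation rate (adults 0.312, children
   0.174 L min⁻¹, converted to m³ h⁻¹ by ×0.06) scaled by the fraction of
   the sampling period spent in the room; `V_adj` is the measured room
   volume reduced 7 % for furnishings; and `ΔC = C_in − C_ex` is the excess
   of indoor over outdoor CO₂ (outdoor assumed 450 ppm). The conversions
   (L min⁻¹ → m³ h⁻¹, ppm → volume fraction) are forced by dimensional
   analysis. A sample with `C_in ≤ C_ex` is rejected, not clamped: a
   non-positive excess means the model's premise fails for that home and
   silently flooring it would manufacture an infinite or arbitrary ACR.
   The same occupancy fraction is applied to adults and children; time-use
   data fine enough to separate them is rarely available.

2. **VOC emission balance.** If a VOC's indoor concentration is also at
   steady state and ventilation is its only removal path, the whole-room
   time-averaged source strength is `q = ACR · V_adj · (C_in − C_out)` in
   µg h⁻¹. Oxidation and surface uptake are deliberately excluded — their
   rates are unknown for most species and homes — so `q` is an effective
   emission rate, biased low for reactive species such as monoterpenes.
   Negative `q` (outdoor exceeding indoor) is physically meaningful net
   ingress and is retained with a flag rather than clamped; a replication
   study can floor it explicitly.

3. **Exposure benchmarks.** Measured concentration stands in for lifetime
   exposure concentration after the standard inhalation adjustment
   `EC = C·(ET/24)·(EF/365)·(ED/AT)`. Lifetime cancer risk is `IUR·EC`
   (threshold 10⁻⁶) and the hazard quotient is `EC/RfC` with the averaging
   time set to the exposure duration (threshold 1, strict inequality in
   both cases). These are screening indicators, not predictions for any
   occupant.

## Outlier treatment

Aromatic VOCs (BTEX and trimethylbenzenes) show rare, very large episodic
spikes — typically from painting — that would dominate medians and rank
statistics. Each VOC's concentrations are log-transformed and scored with
the MAD-based modified Z-score `mz = 0.6745·(log x − median)/MAD`; values
with `mz > 3.5` are removed in a single pass and the retained values are
returned bit-for-bit (log and exponential cancel exactly). Choices worth
recording:

- **Natural log internally.** Provably inconsequential: a base change
  rescales the numerator and the MAD identically, and a property test
  asserts score equality to 1e-12 against a log₁₀ recomputation.
- **One-sided filter.** Episodic sources only inflate concentrations; a
  `two_sided` flag exists but is off by default.
- **MAD = 0 raises.** When half the group is identical the score is
  undefined; substituting a mean-deviation fallback would silently change
  the meaning of "outlier", so degenerate groups are an error.
- **Positivity is required.** Below-LOD zeros must be handled upstream by
  the pipeline's LOD policy (`keep`, `drop`, or `half-lod`; default
  `keep`, which forces `drop` or `half-lod` before any log-domain step when
  zeros are present).
- **Scope.** Only the aromatic panel is treated by default; TVOC and the
  emission tables use untreated concentrations, with the treated table
  feeding the urban/rural comparison. Both scope and threshold are config.

## Nonparametric statistics

All group comparisons are rank-based because indoor concentration data are
strongly right-skewed with group-dependent spread. The Brunner–Munzel test
targets the relative effect `p = P(X<Y) + ½P(X=Y)` without assuming equal
variances or a location shift; the studentized statistic uses
placement-based variance estimates and a t reference with
Satterthwaite-type degrees of freedom. For small samples an exact
permutation reference for the same statistic is available
(`method="permutation"`, exhaustive up to ~200k splits); degenerate
permutations with zero rank variance are scored as statistic 0. Seasonal
(4-level) comparisons use the ties-corrected Kruskal–Wallis H followed by
Dunn's pairwise z tests on the pooled midranks, Holm-adjusted. All tests
are two-sided at α = 0.05; midranks resolve every tie; with all
observations equal, H is defined as 0 ("no evidence") rather than 0/0.
Bootstrap CIs use the seeded percentile method with 1000 resamples
(percentile rather than BCa: the reported statistics are medians and means
of moderate samples where the difference is immaterial, and percentile
intervals are reproducible from the seed alone). Boxplot-style summaries
report the 5/25/50/75/95 percentiles under linear interpolation between
order statistics (numpy's default rule), with values outside the 5–95 band
listed as outliers.

## The synthetic cohort generator

The generator exists so every downstream stage can be tested against known
truth. It emulates the statistical structure of a yearlong residential
campaign:

- **Concentrations** are log-normal per VOC (positive, right-skewed), with
  a default 17-species panel whose indoor/outdoor medians are anchored to
  reported UK residential values (e.g. benzene 0.70, xylene 1.22, carbon
  tetrachloride 15.5, ethanol 320 µg m⁻³) and geometric SDs set by
  compound class (solvents/propellants ≈ 3, aromatics ≈ 2, halocarbons
  tighter). The panel is a deliberate subset of a full >120-species
  speciation, so synthetic TVOC sits below a full campaign's.
- **Seasonal ACR** is log-normal per season with medians 1.2 (summer),
  1.0 (spring), 0.8 (autumn), 0.70 (winter) h⁻¹ — a summer-high,
  winter-low annual cycle with the spring rise ahead of the autumn decline.
- **Urban aromatic shift**: urban homes (default 70 %) have BTEX/TMB
  medians multiplied by a configurable factor (default 2) both outdoors
  and indoors, reflecting traffic aromatics carried indoors by ingress.
- **Painting spikes**: with probability 0.05 a home's *indoor* aromatics
  are multiplied by 50 — the episodic-burst signature the outlier filter
  is designed to remove — without modelling paint chemistry.
- **CO₂ by inversion**: each home's indoor CO₂ is computed from its drawn
  true ACR by algebraically inverting the mass balance, so ACR inference
  is an exact round trip (≤ 1e-9 relative error, in practice machine
  epsilon). A multiplicative noise knob (`co2_noise_gsd`, default off)
  degrades this for robustness studies while keeping CO₂ above outdoor.
- **Occupancy**: 1–2 adults and 0–3 children uniform, occupancy fraction
  uniform on [0.3, 0.8] — a stated stand-in for survey-derived time-use
  statistics, not a reconstruction of any population.

Everything is drawn from one seeded generator; identical specs reproduce
identical cohorts bit-for-bit. What passing tests on synthetic data do
*not* show: robustness to real-data pathologies the generator omits —
correlated VOCs, non-log-normal tails, measurement error in CO₂ and
volumes, unaccounted CO₂ sources (pets, combustion), and seasonal
confounding between occupancy and ventilation.

## Numerical and design choices

- Working unit for emission rates is µg h⁻¹ (matching the magnitude of
  reported residential totals); display conversion to g h⁻¹ is trivial.
- Min–max normalization requires at least two distinct values per VOC and
  raises (naming the VOC) on constant series; ties at the extremes are
  allowed and map to 0/1.
- Missing outdoor concentrations skip the record with a warning instead of
  assuming zero outdoor (which would overstate indoor sources).
- Holm adjustment enforces monotonicity with a running maximum and caps at
  1; it is permutation-invariant by construction.
- Group tests are only run when at least two groups have ≥ 2 observations;
  a single-home cohort produces degenerate summaries, no tests, and a
  successful exit with warnings.
- Exceedance flags use strict inequality at both thresholds.
- The pipeline's exclusion log records every dropped observation (below
  LOD, no CO₂ excess, outlier) with a reason code; no record disappears
  silently.

## Problem sizes

The bundled analyses default to 124-home cohorts. Calibration-style checks
use sizes chosen for their Monte-Carlo error, stated where used: 600 homes
for recovering the urban/rural aromatic ratio (±20 % band), 1000 homes for
seasonal ACR medians (≈3 % error on a per-season median), 2000 replicates
for type-I-error and bootstrap-coverage rates, and exhaustive permutation
enumeration for Brunner–Munzel at ≤ 8 observations per group.

## Known limitations

The ACR method assumes occupants are the only CO₂ source and that reported
occupancy is accurate; both fail in homes with gas cooking or pets. The
emission model cannot separate indoor generation from sorbed-mass
re-release, and time-averaging smooths short emission events. Toxicity
values carry their own uncertainty and the bundled exposure factors
(16 h day⁻¹ at home, 365 d yr⁻¹, 70-year exposure and averaging) are
documented stand-ins to be replaced with population-specific values. None
of the risk outputs are individual health predictions.
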