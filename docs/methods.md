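# Methods

## Scope and model

`quechemo` treats method development for a multi-residue LC–MS/MS assay as
three statistical stages over small tabular experiments, followed by
validation arithmetic over printed reference tables.

### Screening (Plackett–Burman)

The 12-run design is the standard cyclic construction: first row
`+ + − + + + − − − + −`, ten cyclic shifts, and a final all-minus row; the
first k ≤ 11 columns are kept. Every kept column has exactly six highs and
six lows and any two columns are orthogonal, so main effects are estimated
independently as the difference of the two six-run means. Center points
(default 3) estimate pure error; with three centers the error df is 2 and
the 95 % two-sided critical t is 4.303. The standard error of an effect is
s_pe·√(1/6 + 1/6). We deliberately use **pure error only** as the error
term (not the idle-column or residual variance): center replicates are the
only model-free replication in the design. The idle columns are retained
internally and can serve as an alternative error estimate behind a flag,
off by default. No multiplicity correction is applied across factors — the
test is per-factor at α = 0.05, which is also why, with two truly null
factors, an occasional false positive is expected (≈ 1 − 0.95² per seed
before correlation).

### Optimization (CCD + quadratic response surface)

The CCD uses the rotatable α = (2^f)^{1/4} and 6 center points by default
(20 runs for f = 3), a textbook rotatable layout; both are configurable.
Star points of a rotatable design extrapolate a factor whose natural low is
a physical zero (e.g. sorbent mass) below zero; natural-unit exports clamp
such cells at 0 with a warning and record the clamp, while the coded design
is left exact so the model basis keeps its geometry.

Fitting is **always in coded units** (conditioning, comparability of
coefficients); the full 1 + 2f + f(f−1)/2 term basis is retained without
backward elimination. Ordinary least squares (statsmodels) supplies
coefficient inference; R² is SS_model/(SS_model + SS_residual). A
zero-variance response is defined to have R² = 0 (with a warning) rather
than NaN. The residual is partitioned over exactly-replicated design points
into pure error and lack of fit; F_lof = MS_lof/MS_pe with p from the F
distribution. Rank deficiency raises an error naming the collinear terms.

### Desirability

Only the larger-is-better branch is implemented (recoveries are to be
maximized); the two-sided and smaller-is-better branches are out of scope.
The default scaling is `auto_range`: L and T are the minimum and maximum of
the fitted model's predictions over the optimization region (evaluated on a
41-per-axis grid), so the region's best point attains dᵢ = 1 — the
software-style convention under which an optimum can report desirability
exactly 1.0 at recoveries well below 100 %. The exponent s defaults to 1
(linear ramp). The optimizer is a dense 21-per-axis grid over the coded
cube [−1, 1]^f (ties broken toward the smallest coded norm, then
lexicographically) followed by L-BFGS-B refinement; the refined point is
never allowed to fall below the best grid point. The region can be extended
to the star sphere, but the cube is the default since the boundary optimum
of interest (0 mg GCB) lies on it either way. Against an exhaustive
101³ grid the two-stage optimizer agrees within 1e-3 in D on random
quadratic ensembles (tested).

### Validation arithmetic

- Calibration lines are unweighted OLS over ≥ 5 levels (1/x weighting is
  available behind a flag but is not the default since the reference
  curves were fit unweighted).
- ME boundaries follow a literal reading of the classification rules:
  exactly ±20 % is "none", exactly ±50 % is "medium", strictly beyond ±50 %
  is "strong". ME values are kept at full precision internally and rounded
  half-away-from-zero to integers for display.
- Two candidate metrics are implemented for the "improvement after 10-fold
  dilution" figure: the share of analytes whose |ME| strictly decreased
  (default) and the share of ND-strong analytes resolved to non-strong.
  Neither is asserted against per-matrix reference percentages, because the
  published metric is not defined precisely enough to discriminate.
- Recovery: intra-day RSD is the CV of day 1's five replicates; inter-day
  is the CV of all 3 × 5 = 15. The 3-day × 5-replicate structure is
  validated and configurable.
- The LOQ is validation-based — the lowest spike level with mean recovery
  in [70, 120] % (inclusive) and every RSD < 20 % (strict) — not
  signal-to-noise based.
- Survey records below the detection limit are censored and count as
  non-positive; a sample is positive when at least one analyte is
  quantified at or above its LOQ. Ratios are reported as integer percent.

### Uncertainty budget

All components are dimensionless relative fractions; percent appears only
at reporting (U_exp (%) = 100·k·u_c, k = 2). Stated tolerances in the
standards-preparation component are converted rectangularly (÷√3) by
default, with triangular and normal conversions selectable. Display
rounding is u_c to 4 decimals and U_exp to 1 decimal, half away from zero,
matching the reference budget's precision. Recombining the reference
components reproduces the reported combined values except for two
last-digit cells (2,4-D and carbendazim u_c, and carbendazim U_exp), where
the original computation evidently carried unrounded components; those
cells are not asserted. The closed-form calibration component is
cross-checked against a parametric bootstrap of the estimated
concentration (within 10 % at 2 000 resamples).

## Synthetic truth: what it emulates, and its defaults

The generator plants the qualitative structure the analysis is designed to
detect; defaults were chosen once as realistic study conditions:

- **Recovery surfaces** (coded units, recovery %): common toluene terms
  +4.5·x − 6·x², HCl terms +6·x − 5·x² (both positive screening effects
  with interior maxima at coded 0.375 and 0.6), and GCB linear terms −8,
  −8.5, −7.5 for carbendazim, iprodione, prochloraz and +0.75 for 2,4-D and
  thiabendazole — three-of-five negative GCB effects with a boundary
  optimum at 0 mg, mirroring the screening sign exception for those two
  analytes. Intercepts 84–90 %. Responses are clipped to [0, 110] % to keep
  desirability anchors physically meaningful.
- **Response noise** is Gaussian with SD 1.5 % — consistent with the low
  end of the observed intra-day RSDs and chosen so the smallest planted
  screening effect (toluene, effect 9 %) has effect-to-noise ≥ 6, the
  regime in which the screening stage should essentially always find the
  planted factors.
- **Matrix effects** are per-matrix slope multipliers (citrus 1.50 …
  lychee 0.55), spanning strong enhancement to strong suppression;
  10-fold dilution shrinks the deviation from 1 by 60 % (factor → 1 +
  0.4·(f − 1)), so |ME| always decreases on dilution when it is non-zero.
- **Calibration noise** is proportional with CV 2 % (R² ≈ 0.999 at 7
  levels, matching the reference curves' range).
- **Recovery replicates**: mean 85 %, between-day SD 2 %, within-day SD
  3 % — mid-range of the observed intra/inter-day RSDs.
- **Survey**: per-commodity prevalences (citrus 0.30, apple 0.20, lychee
  0.05, tomato 0.20, rest 0) whose expected overall positive rate is
  10/85 ≈ 12 %; concentrations are log-normal (μ = ln 4, σ = 0.8 in
  log µg/kg — non-negative, right-skewed residues in the low-µg/kg range),
  censored below the LOQ; carbendazim is drawn most often.
- **Seeds**: one global seed expands to per-stage child generators via a
  `SeedSequence` keyed on CRC32 hashes of stage labels, so stages are
  independently reproducible and changing the seed changes noise only,
  never the truth.

What the generator does **not** emulate: chromatographic drift, carryover,
heteroscedastic calibration noise beyond the proportional model,
analyte-by-matrix interaction in the matrix effect (the factor is
per-matrix), day-to-day calibration drift, and correlated residues across
analytes in survey samples. Passing tests therefore demonstrate the
statistical machinery under its stated assumptions, not robustness of the
laboratory method to these real-world effects.

## Problem sizes

The Monte-Carlo checks run at sizes chosen to make their targets
statistically sharp while keeping the suite quick: 10 000 null simulations
for the screening type-I rate (binomial SE ≈ 0.002), 300–500 replicates
for coefficient-bias and lack-of-fit calibration, 100 seeds for the
end-to-end boundary-optimum property, 2 000 resamples for the calibration
bootstrap, and a 21-per-axis optimizer grid checked once against a
101-per-axis exhaustive search.

## Known limitations

- Screening supports only the 12-run Plackett–Burman family (no fold-over,
  fractional factorial, or Lenth's method); designs with > 11 factors are
  rejected.
- The lack-of-fit partition pools only exact replicates; near-replicates
  are treated as distinct points.
- `check_loq` requires validation results at every candidate level and
  does not interpolate between levels.
- The desirability optimizer is a grid-plus-local scheme: for surfaces
  with many near-tied optima it returns the tie closest to the design
  center, which is a convention, not a claim of uniqueness.
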