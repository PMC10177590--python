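# Methods

This note documents the models, defaults, and numerical choices behind the
`transwell` package, and what its synthetic-data tests do and do not
demonstrate about real experiments.

## The permeability model

The assay is a dual-chamber (Transwell) diffusion cell: a drug solution at
concentration *C*₀ in the donor chamber, blank buffer in the receiver,
separated by a cell monolayer of area *A* = 0.33 cm². With paper-standard
geometry the apical chamber holds 0.2 mL and the basolateral 0.7 mL; the
donor/receiver roles swap with direction (AP→BL vs BL→AP), and all
direction-dependent volumes are resolved accordingly.

Passive transport is modeled as linear exchange: flux = Papp · *A* ·
(*C_D* − *C_R*). Apparent permeability is estimated, per well, as

1. **Cumulative correction.** At each scheduled time (default 15, 30, 45,
   60, 90, 120 min) a 100 µL receiver aliquot is withdrawn and replaced
   with blank buffer. The measured concentration is corrected by
   `corrected(t_k) = measured(t_k) + (V_s/V_R)·Σ_{j<k} measured(t_j)`,
   which makes `corrected·V_R` exactly the cumulative transported mass
   (removal takes mass proportional to concentration; replacement restores
   volume). Below-LOQ points contribute 0 to the running sum and stay
   masked. The correction assumes aliquot replacement; the non-replacement
   protocol is rejected rather than silently mis-corrected.
2. **Transfer slope.** Ordinary least squares of the corrected series
   against time. Two conventions are exposed because both circulate in
   practice: `full_range` (default) fits one line from the first
   quantifiable point to the end; `max_window` returns the maximal OLS
   slope over contiguous windows of at least `min_points` points (ties go
   to the earliest window). `min_points` defaults to 3 — fitting a
   transfer rate through two points is allowed only by explicit opt-in.
3. **Uncorrected Papp** = `(V_R/(A·C_0))·slope/60` in cm/s, with slope in
   concentration/min sharing the concentration unit of *C*₀.
4. **Recovery** = `(C_D,end·V_D + corrected_end·V_R)/(C_0·V_D)`. Donor
   concentration is measured only at 0 and 120 min, so recovery is an
   endpoint quantity by construction. The corrected final receiver
   concentration already counts withdrawn aliquots; an independent
   explicit aliquot-ledger computation is provided and asserted equal in
   the tests. If the endpoint donor measurement is missing, the well is
   reported with `papp_corrected = papp_uncorrected` and an explicit
   warning rather than failing.
5. **Corrected Papp** = uncorrected / recovery, with recovery as a
   *fraction* — dividing by a percent-scale number would shrink estimates
   a hundredfold and is dimensionally indefensible. Recovery above a
   configurable bound (default 1.2) attaches a QC warning; recovery ≤ 0 is
   an error.

Wells with fewer than `min_points` quantifiable receiver points are
reported **BLQ** with no permeability fields — a result, not an error.
The efflux ratio Papp(BL→AP)/Papp(AP→BL) with the conventional >2 flag is
computed only when both directions are quantifiable.

Condition-level summaries use the arithmetic mean, sample SD (n−1), SEM,
and CV%; single-well groups report the mean only. Report tables round
half-up to two decimals on the 10⁻⁶ cm/s display scale; internal math is
full precision.

### Donor-depletion bias

The linear-slope estimator assumes near-sink conditions. When a
substantial fraction of the donor mass crosses during the assay, the
cumulative receiver curve is concave and the OLS slope underestimates the
initial transfer rate by roughly half the total depletion — and recovery
cannot compensate, because a lossless well has recovery exactly 1.
With the default geometry (donor 0.2 mL, 120 min), measured noiseless
relative errors of the full-range estimator are −0.8% at Papp = 10⁻⁶ cm/s,
−4.0% at 5×10⁻⁶, −7.8% at 10⁻⁵ (11% depletion), and −14.9% at 2×10⁻⁵
(21% depletion); the max-window estimator roughly halves these. This is a
property of the estimator itself, faithfully reproduced, not an
implementation artifact: parameter-recovery guarantees in the test suite
are therefore stated for the sink regime (≤5×10⁻⁶ cm/s under this
geometry), and the high-permeability points are characterized (negative
bias bounded by the depletion) rather than asserted unbiased.

## The synthetic-data generator

`simulate_well` propagates the donor/receiver mass vector with the matrix
exponential of the 2×2 rate matrix between sampling events — the *exact*
solution of the linear system — so integrator error never contaminates
parameter-recovery comparisons (verified against the closed-form
two-compartment solution to 10⁻⁶ relative on a grid of permeabilities and
volume pairs). At each sampling event the measurement reflects the
concentration immediately before aliquot removal; removal and blank
replacement are instantaneous.

Generator defaults emulate the bench protocol: 0.33 cm² insert, 0.2/0.7 mL
chambers, 100 µL aliquots at 15/30/45/60/90/120 min with replacement,
donor measured at 0 and 120 min only. Measurement noise is mean-one
multiplicative lognormal with CV 5% — LC-MS error scales with
concentration, the lognormal keeps concentrations positive, and 5% is
consistent with an assay holding QC bias within ±10%. Optional
first-order loss (`loss_rate_per_min`) drains both chambers, producing
recoveries below 1 that the pipeline's Eq.-style correction then repairs.
Values below the LOQ are censored to BLQ; per-analyte LOQs default to the
low end of the validated linear ranges (0.5 atenolol, 0.2 metoprolol,
1 µg/mL propranolol).

What the simulator does **not** model: pH-dependent ionization, unstirred
water layers or mucus, active (saturable) transport, volume evaporation,
or inter-well biological variability beyond measurement noise.
Consequently, passing parameter-recovery tests shows the *arithmetic* of
the pipeline is right under its own assumptions; it does not validate the
passive-diffusion assumption for any particular compound or monolayer.

TEER trajectories follow a logistic rise to a plateau,
`plateau/(1+exp(−k(day−midpoint)))` plus Gaussian noise, emitted as raw
ohm readings (`normalized/area + blank`) so the normalization path is
exercised. Defaults: colonoid plateau 4200 Ω·cm² (rate 1/day, midpoint
day 6 — plateaus around days 10–12), Caco-2 plateau 500 Ω·cm² (rate
0.6/day, midpoint day 12 — plateaus around days 18–21), blank 120 Ω,
noise SD 50 / 10 Ω·cm² respectively. qPCR tables draw a housekeeping Ct
per replicate (default N(20.67, 1.52)) and add gene-specific true dCt plus
N(0, 0.3) technical noise, so replicate-matched normalization recovers the
configured dCt exactly at zero noise.

## Integrity QC

- **Normalization**: `(R_sample − R_blank)·A`. Negative values (sample
  below blank) are flagged, not fatal.
- **Plateau**: "steady state" is not defined by the source protocols;
  it is operationalized as every successive relative change ≤ 5% across a
  3-day window (both configurable), the earliest such window winning. The
  definition is translation-invariant in day labels.
- **Gates**: ≥ 500 Ω·cm² (Caco-2) and ≥ 4000 Ω·cm² (colonoid),
  *inclusive*, because reported passing Caco-2 means sit barely above the
  threshold. Pipeline runs exclude gate-failing wells from Papp
  estimation and list each exclusion with its reason.
- **FITC-dextran leakage**: receiver %RFU = 100·RFU/donor-initial; the
  criterion is applied to the rise above the time-zero baseline (receiver
  channels read ~0.02% background before any transport occurs, so an
  absolute reading would fail intact monolayers); transport < 0.02%
  passes. This baseline-subtracted reading is a documented design choice.

## Bioanalytical QC

Calibration fits area ratio on nominal concentration by unweighted OLS
(1/x weighting available but not default — no weighting scheme is implied
by the source QC tables); at least five distinct levels are required, and
curves with R² < 0.99 are flagged failing (the conventional bioanalytical
acceptance floor). Quantification inverts the line and flags
back-calculated values below the linear range as BLQ and above it as
over-range (dilute and re-measure). QC bias = 100·(measured −
nominal)/nominal with the inclusive ±10% acceptance rule.

## Expression statistics

dCt = Ct(gene) − Ct(housekeeping, default GAPDH), replicate-matched when
replicate counts agree, otherwise against the group-mean housekeeping Ct
(the convention that reproduces published group-mean arithmetic);
ddCt = mean dCt difference between groups, fold change = 2^(−ddCt).
The two-sample t-test defaults to the pooled-variance Student form (Welch
available); one-way ANOVA is computed from the between/within sums of
squares; Šídák adjustment is `1−(1−p)^m` with the family size *m* an
explicit parameter, because which comparisons form the family is a
modeling decision, not something the arithmetic can infer. All three are
implemented from their closed forms with scipy supplying only reference
distributions, and the test suite cross-checks them against
`scipy.stats.ttest_ind` / `f_oneway` as an independent route. Degenerate
inputs carry no evidence and return t = 0, p = 1 (identical zero-variance
groups) or F = 0, p = 1 (identical constant groups). The 0.05
significance threshold is reported as annotation, never used to gate
computation.

## Numerical and interface choices

- A perfectly flat fitted series has zero residual and is reported with
  r² = 1 (rather than NaN from a 0/0).
- Coincident time points cannot support a slope and raise a validation
  error; fewer than `min_points` quantifiable points is a BLQ signal, not
  an exception.
- The BLQ token in CSVs is the literal string `BLQ`; a numeric 0 is a
  valid measurement, distinct from censored.
- CSV numerics are written with shortest round-trip float representation
  and read back with round-trip parsing, so write→read reproduces every
  numeric field exactly and reruns are byte-identical.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical parameters + seed give
  bit-identical outputs, including across the plate generator's
  per-well seed spawning.
- Drug molar conversions divide by `MW_freebase · salt_factor`; the salt
  factor defaults to 1.0 and is deliberately user-supplied for salt-dosed
  compounds, since published tables often print free-base MWs while doses
  refer to salts. The bundled benchmark asserts conversions only for
  atenolol, the one free-base-dosed compound.

## Problem sizes

Test-suite and acceptance-script simulations are sized for seconds-scale
runs: 200 wells for the noisy parameter-recovery median, 1000 random
series for the aliquot-ledger cross-check, 500 seeds for the dCt
unbiasedness check, 20 seeds for TEER plateau statistics, and 10,000 null
replicates (n = 3 per group, vectorized) for the t-test type-I-error
calibration. These sizes give Monte-Carlo standard errors comfortably
below the asserted tolerances.

## Known limitations

- The slope estimator inherits the field's sink-condition assumption;
  see "Donor-depletion bias" above for the quantified consequences.
- Recovery is an endpoint quantity (donor measured only at 0 and
  120 min); time-resolved loss cannot be distinguished from late loss.
- No amplification-efficiency correction in ddCt (plain 2^(−ddCt)).
- The CLI covers desk-scale workflows; it is not a LIMS and parses no
  instrument raw files — only post-quantification concentration tables.
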