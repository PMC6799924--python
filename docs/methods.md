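# Methods

## The retrieval chain

Relative humidity is retrieved pixelwise from co-registered grids of
five NIR apparent reflectances ρ\* (bands at 0.865, 1.24, 0.905, 0.936
and 0.940 µm), surface air temperature Ta (°C) and elevation H (m).
Water vapour absorbs in the 0.905/0.936/0.940 µm bands and is nearly
transparent in the 0.865/1.24 µm window bands, so the ratio

- T<sub>obs,17</sub> = ρ\*(0.905)/ρ\*(0.865)
- T<sub>obs,18</sub> = ρ\*(0.936)/ρ\*(0.865)
- T<sub>obs,19</sub> = ρ\*(0.940)/(C₁ρ\*(0.865) + C₂ρ\*(1.24)), C₁ = 0.8, C₂ = 0.2

approximates the two-way vapour transmittance. Each band maps to
precipitable water PW (cm) with region-calibrated coefficients
(α, β) = (0.025, 0.30), (0.056, 0.60), (0.120, 0.651); the three
estimates are fused with weights f = (0.36, 0.24, 0.40). Specific
humidity follows the empirical quadratic
Q = 0.001(−0.0762 PW² + 1.753 PW + 12.405), air pressure the linear
lapse Pa = 1013.3 − 0.1038 H (hPa), vapour pressure e = Q·Pa/0.622, and
saturation vapour pressure the Magnus-type form
e<sub>s</sub> = 611·exp(17.27 Ta/(237.3 + Ta)) in pascals. RH = 100·e/e<sub>s</sub>.

**Unit harmonisation.** The e<sub>s</sub> formula yields pascals while
Pa — and therefore e — is in hectopascals. We divide e<sub>s</sub> by 100
before the final ratio; without this the "percentage" would be off by a
factor of 100 and could never land in the plausible tropical range of
roughly 47–71%.

**The PW–transmittance relation is ambiguous as printed**, and the
channel-ratio literature it descends from uses a logarithmic form. Three
switchable variants are implemented — `as_printed_grouped`
(PW = ((α − T)/β)², the default), `as_printed_literal`
(PW = (α − T/β)²) and `log_form` (PW = ((α − ln T)/β)²) — and every RH
raster records the variant used in its metadata. The synthetic round
trip is exact under all three, so the choice does not affect the
pipeline's internal consistency; it would matter for absolute
calibration against real radiances, which is out of scope.

**Validity domain.** Q(PW) is a downward parabola with vertex near
PW ≈ 11.5 cm; beyond it more vapour would *lower* Q. PW outside
[0, 11.5] becomes NaN rather than silently extrapolated. A side effect
worth knowing: Q(0) = 0.0124 kg/kg > 0, so the chain has a *floor* on
derivable humidity — at 30 °C sea-level air the minimum reachable RH is
about 47%. The scene simulator clips its target humidity into the
reachable band (`pw_for_target_rh(..., clip=True)`).

RH is clamped to [0, 100] by default; raw values are kept in the
intermediates. NaNs propagate through every stage. No reprojection is
performed: all grids and polygons are assumed to share one projected
CRS (metres, default UTM 47N).

## Zonal extraction and lag assembly

RH rasters are resampled by nearest neighbour (default 1 km → 250 m;
value-preserving by construction) and reduced per block by
Σ(pixel∩block area × value)/Σ(pixel∩block area), with exact polygon
intersection rather than centre-in-polygon tests — edge pixels
contribute proportionally, which matters because the 26 blocks
(~77 ha each) are narrower than a 1-km pixel. NaN pixels are excluded
from numerator and denominator; a block mean is reported only when at
least 50% (configurable) of the block area is valid.

The lagged predictor rh_Tk is the mean RH over a window of
`window_days` (default 8, matching the 8-day averaging of the source
composites) ending *exactly* 7·k days before the census date, k = 1…6.
The anchoring choice — window ends at, rather than is centred on, the
lag date — is ours; the source material says only "prior to the census
date". Rows with any empty lag window are dropped and logged. Cleaning
removes missing values always, plus count outliers by |z| > 3 (default)
or a 1.5·IQR rule; the one-pass rule is recomputed from the data it is
applied to.

## Regression and stepwise selection

Counts are regressed on lag terms by OLS; degree-2 models carry each
selected lag at powers 1 and 2 (no cross terms, mirroring the published
model forms). Stepwise selection is classical forward/backward on
partial-F p-values with entry/stay thresholds of 0.15 (a common
statistical-package default; the source analysis does not state its
thresholds), lags entering and leaving as units (both powers in degree
2) and ties broken toward the smaller lag. Pearson screening pools
blocks within each census cycle and reports two-sided t-distribution
p-values with the conventional star labels at 0.05/0.01/0.001/0.0001,
uncorrected for multiplicity.

## The quickprop MLP

A single hidden layer (k–x–1), logistic activation on hidden and output
units. Inputs and target are min–max scaled to [−1, 1]; because the
logistic output lives in (0, 1), the scaled target is mapped internally
to [0.1, 0.9] to keep it away from the asymptotes, and the inverse map
(with clipping) bounds back-transformed predictions by the training
target range. Training is full-batch quickprop: per weight,
Δw(t) = S(t)/(S(t−1) − S(t))·Δw(t−1) with |Δw| capped at μ·|Δw(t−1)|
and a plain gradient-descent fallback when no previous step exists or
the secant denominator vanishes — so the first epoch is exactly a
gradient-descent epoch. Hyperparameters (all configurable):
learning rate 0.1, μ = 1.75, max 500 epochs, early stopping after 25
epochs without validation improvement, returning the
minimum-validation-error weights. These are conventional quickprop
settings; the source analysis used a commercial tool whose settings are
not published, and bit-for-bit replication of it is a non-goal.

Data are split 60/20/20 into training/testing/validation by seeded
shuffle, test and validation sizes taken as floor(0.2·n) and the
remainder to training — the rule reproduces 170/56/56 from 282 rows.
Architecture search scores hidden sizes 1–10 by fitness
= 1/(1 + validation absolute error) — the "fitness" of the source
analysis is not defined there; this inverse-error definition is our
choice and is recorded in model metadata — with ties toward the smaller
network. Feature selection is greedy forward addition on the same
fitness, stopping when no candidate improves it.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the study system: a 2000-ha
estate as a 2 × 13 grid of rectangular blocks (10 division-A, 16
division-B); daily block-level RH as an estate-wide AR(1) weather signal
(sd 5%, lag-1 correlation 0.6) plus a weak annual harmonic (amplitude
4%), persistent block offsets (sd 2%) and daily block noise (sd 1.5%),
clipped to 47–71%; Ta around 29 ± 3 °C; biweekly censuses on a fixed
14-day calendar (the real census dates are not published; any biweekly
alignment is consistent); counts in [0, 32] per frond. Scenes are built
by inverting the retrieval chain — window-band reflectances are set to
base values 0.30/0.25 with ±10% seeded spatial jitter, and each
absorption-band reflectance is solved from the transmittance the
forward chain must observe — so the forward derivation recovers the
planted PW field to machine precision; this round trip is the oracle
for the whole retrieval module.

The census response maps the lag-weighted RH exposure
z = Σ w<sub>k</sub>·rh_Tk to an expected count; the default is a peaked
quadratic with optimum 59% RH, peak 12 larvae/palm and half-width 8
percentage points (an ecological optimum: desiccation below, fungal
mortality above), lag weights (0.5, 0.3, 0.2, 0, 0, 0) concentrating
the effect on the three most recent weeks, plus Gaussian noise
(sd 1 larva/palm) and clamping to [0, 32]. Linear and saturating shapes
are available. Per-palm counts, when requested, are Poisson with the
block mean as intensity (25 palms per block; palm-level dispersion is
not characterised in the field data, so equidispersion is the neutral
choice).

Not emulated: instar-stage development dynamics, pesticide
interventions, spatial contagion between blocks, cloud masking, real
radiometric calibration, and the actual (undeposited) plantation census.
Passing tests therefore demonstrate that the pipeline *recovers known
structure from data generated under its own assumptions* — including
the qualitative headline that a nonlinear, recent-lag-driven response
yields ANN ≥ regression and {T1,T2,T3} ≥ {T4,T5,T6} — not that the
fitted coefficients transfer to any particular estate.

## Evaluation metrics

Absolute error is mean |predicted − actual|. Min–max accuracy is
implemented in two modes, because the defining formula (elementwise mean
of min/max ratios, the default) and its prose description (ratio of the
pooled means) disagree in the source material; the mode is recorded in
each report. Rows where both values are zero count as perfect agreement;
rows where exactly one is zero are excluded with a warning (the ratio
would be identically 0 regardless of magnitude, which over-penalises
near-zero counts). Negative inputs are rejected with guidance to clamp
first; when scoring models whose raw predictions may be negative, the
report clamps at zero for this metric only. Adjusted R² is computed from
the OLS regression of actual on predicted; with p_terms = 1 (the ANN
convention here) it equals the squared correlation, adjusted, and is
symmetric in its arguments — asymmetry enters only through a model's
design size, which is used as p_terms when scoring regression models.

## Problem sizes and determinism

Default runs simulate two census years (48 cycles × 26 blocks = 1248
records) over daily scenes on a 5 × 6 grid of 1-km pixels — small enough
that a full end-to-end run with architecture search completes in well
under a minute, while exercising partial-pixel zonal statistics
(blocks are sub-pixel in one dimension). All randomness flows from one
root seed expanded per stage with a stable hash, so a rerun with the
same configuration reproduces every model file byte for byte; the run
manifest records the configuration, its hash and the seed.

## Known limitations

- The three PW variants cannot be discriminated with synthetic data
  (all are self-consistent); calibration against real granules would be
  needed.
- The quickprop fallback is pure gradient descent; the classical
  variant that adds a gradient term while slopes keep sign converges
  slightly faster on some problems but makes the first epoch deviate
  from plain gradient descent.
- Stepwise selection inherits the usual caveats (greedy, inflated
  in-sample fit); the paper-style configurations are fitted alongside it
  so results never depend on selection alone.
- Area-weighted extraction loops pixels in Python; fine for estate-scale
  grids, not tuned for continental rasters.
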