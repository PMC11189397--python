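# Methods

## The proxy chain

`epco2` estimates atmospheric pCO₂ from the photosynthetic carbon-isotope
fractionation εp recorded by general phytoplankton biomarkers. The chain
assumes passive CO₂ diffusion into the cell (carbon-concentrating
mechanisms violate it and are an acknowledged limitation of all εp-based
proxies), air–sea CO₂ equilibrium, and that the foraminiferal δ¹³C
compilation tracks surface-ocean HCO₃⁻.

Per sample:

1. **δp (biomass)** = lipid δ¹³C + lipid–biomass offset. Offsets are
   culture-derived: phytane 3.5 ± 1.3 ‰ (via its precursor phytol),
   steranes 4.5 ± 3.0 ‰ (via sterols), alkenones 3.9 ± 0.4 ‰, all normal.
   The sterane δ¹³C entering the chain is the abundance-weighted mean of
   the C₂₇/C₂₈/C₂₉ compounds.
2. **δd (dissolved CO₂)** = foram δ¹³C combined multiplicatively with the
   temperature-dependent CO₂(aq)/HCO₃⁻ fractionation ε = 24.12 − 9866/T(K)
   (a Mook-type expression; at 25 °C, ε ≈ −8.97 ‰). The exact
   (δ + 1000)-scale combination is used rather than the additive
   approximation; they differ by < 0.05 ‰. No calcite–HCO₃⁻ offset is
   applied: the compilation value is taken as the HCO₃⁻ composition.
3. **εp** = 1000·[(δd + 1000)/(δp + 1000) − 1].
4. **CO₂(aq)** = b/(εf − εp), b = 168 ± 43 ‰ kg µM⁻¹ (normal), εf =
   26.5 ± 1.5 ‰ (uniform, reflecting the spread of Rubisco fractionation
   in algal cultures).
5. **pCO₂** = CO₂(aq)/K₀ with the Weiss ln-polynomial solubility
   K₀(T, S) in mol kg⁻¹ atm⁻¹; µmol kg⁻¹ over mol kg⁻¹ atm⁻¹ gives µatm,
   treated as ppmv. Salinity defaults to a modern open-ocean 35 PSU (no
   reconstruction-specific value is available) and is configurable.

SSTs come from TEX₈₆-H: TEX₈₆ = (GDGT-2 + GDGT-3 + cren′)/(GDGT-1 +
GDGT-2 + GDGT-3 + cren′), SST = 68.4·log₁₀TEX₈₆ + 38.6 °C. The
calibration constants are configurable. Samples without measurable
isoGDGTs are gap-filled by linear age interpolation from auxiliary-site
SST series (several series are averaged age-wise first); outside aux
coverage the nearest knot is used and the record flagged, because
unbounded extrapolation of an SST trend is unsafe. A measured TEX₈₆-H SST
is never overwritten.

## Monte Carlo uncertainty

Each (sample, biomarker) estimate redraws b, εf, the offset, and SST
(normal, ±4 °C) `n_draws` times (default 10 000) and re-runs the whole
chain, including K₀ and the δd correction, per draw. All parameters are
drawn independently: no covariance information exists for them. SST draws
are clipped to the solubility formulation's validity range (−2 to 45 °C);
with the default ±4 °C SD this is a < 10⁻⁴ tail event at any realistic
SST. Draws with εf − εp ≤ 0.5 ‰ (configurable floor) are **rejected**
rather than truncated — near saturation the proxy simply carries no
information — and the rejected fraction is reported; an estimate with
more than 50 % rejection is flagged unreliable. Perturbation of the
interpolated foram δ¹³C is off by default and switchable.

The summary is the arithmetic mean ± 1 SD of retained draws, with median
and 16/84 % quantiles alongside. The draw distribution is right-skewed:
1/(εf − εp) is convex, so compounding symmetric parameter uncertainty
inflates the mean above the central-chain value (strongly for steranes,
whose offset SD is 3 ‰ — at a 650-ppmv truth the mean can sit ~20 % high
while the median stays within a few percent). Users comparing central
values across biomarkers should prefer the median or the deterministic
chain; the mean ± SD is retained as the primary summary because it is the
conventional way such compounded uncertainties are reported.

RNG: each (sample, biomarker) pair gets its own `numpy` generator seeded
by `SeedSequence(master_seed, spawn_key=(crc32(sample_id|biomarker),))`,
so estimates are bit-stable and independent of processing order.

## Forcing and sensitivity

ΔR_CO₂ = [a₁(C−C₀)² + b₁|C−C₀| + c₁N₀ + 5.36]·ln(C/C₀), a₁ = 2.4×10⁻⁷,
b₁ = 7.2×10⁻⁴, c₁ = 2.1×10⁻⁴, C₀ = 280 ppm. N₀ (background N₂O) defaults
to a near-preindustrial 270 ppb and is configurable; its effect on the
forcing is < 2 %. Land-ice forcing is sea level × 0.0308 W m⁻³ with sea
level linearly interpolated between the tie points (0 Ma, 0 m), (3.2, 24),
(10.0, 67), (14.9, 66), (19.5, 105).

Regional sensitivity fits regress the binned ΔSST compilation
(interpolated to the pCO₂ sample ages; ages outside compilation coverage
are dropped) on ΔR_CO₂ (ESS) or ΔR_CO₂ + ΔR_LI (ECS). Only the
phytane-based pCO₂ record feeds these fits — it is the most complete
biomarker record. Tropical pairs older than 8 Ma are excluded because the
alkenone-unsaturation SST proxy saturates (ratio → 1.00) at warm tropical
sites.

The fit is a York errors-in-both-variables regression (iteratively
reweighted, zero x–y error correlation, convergence when the slope moves
< 10⁻¹⁰, max 200 iterations), with x-errors from the Monte Carlo pCO₂ SD
mapped through the local derivative of the forcing curve (delta method)
and y-errors from the ΔSST uncertainty (default 1.5 °C SD where the
compilation provides none). r² is reported as the squared Pearson
correlation of the raw (x, y) — a descriptive statistic, not a weighted
fit diagnostic. The intercept is left free. Slopes convert to °C per CO₂
doubling by the forcing of one doubling, f2x; the default is the full
polynomial at 560 ppm (≈ 3.907 W m⁻²), with a `simple` option 5.36·ln 2
(≈ 3.715) since sensitivity tables in this literature use either
convention. Global values are 0.500·tropics + 0.366·(mean of NH/SH mid) +
0.134·(high latitudes).

**A caution on error specification.** The Monte Carlo pCO₂ SD is
dominated by *systematic* parameter uncertainty (one global b, one εf),
yet the York fit necessarily treats it as independent per-sample x-error.
When the claimed x-errors exceed the actual independent scatter, an
errors-in-variables fit over-corrects regression attenuation and biases
the slope high — on synthetic data generated with known slopes the
recovered ECS slopes run 10–50 % above truth (worst in the tropics, where
the saturation filter leaves few points over a short forcing range),
while with correctly specified independent errors the same fit recovers
slopes to within a few percent (verified in tests). This mirrors the
published procedure; interpreting the regional slopes should keep the
systematic/independent distinction in mind.

## Synthetic data generator

The generator emulates a single organic-rich drill site: 35 samples
evenly spaced over 0.3–15 Ma (≈ every 30 m of a ~1 km section), true pCO₂
declining linearly 650 → 280 ppmv toward the present, site SST 25 → 12 °C,
foram δ¹³C 2.4 → 1.0 ‰. At each age the chain is inverted exactly and the
implied lipid δ¹³C values are emitted with 0.3 ‰ noise (a typical
compound-specific IRMS replicate precision); GDGT abundances are
back-solved from SST (+1 °C SST-equivalent noise); the foram compilation
grid carries 0.1 ‰ noise; alkenones appear only at ages ≤ 4 Ma; the three
oldest samples lack GDGTs and rely on the auxiliary-site series. The
sterane noise is centred so the abundance-weighted mean stays exactly on
target. Regional ΔSST series are slope·(ΔR_CO₂ + ΔR_LI) + 1.5 °C noise in
0.125-Ma bins, with default slopes (3.1, 2.3, 2.2, 1.3) K/W m⁻² for
NH-high/NH-mid/SH-mid/tropics.

With all noise at zero the full pipeline reproduces true pCO₂, εp and SST
to 10⁻⁶ relative (limited only by 10-significant-digit CSV
serialisation) and an ECS fit returns the written slopes to the 0.125-Ma
binning error (< 10⁻³ relative). What passing these tests shows is that
the inference chain is the exact inverse of the forward model and that
the uncertainty machinery is calibrated when errors are correctly
specified; it does not validate the proxy's geochemical assumptions
(constant b, passive uptake, equilibrium), nor does the generator emulate
diagenesis, age-model error, or depth-dependent preservation.

## Numerical choices and degenerate inputs

- Age convention: Ma before present, larger = older; all interpolations
  assume strictly increasing age knots and flag (never silently
  extrapolate) out-of-range targets. Compilation edges exclude samples
  rather than invent trend.
- Zero-spread distributions collapse to their center exactly, so a
  deterministic chain is a special case of the Monte Carlo path.
- York fit: zero error bars are floored at 10⁻¹² of the data scale so the
  OLS/weighted-OLS limits emerge numerically (matched to closed-form OLS
  at 10⁻⁸ relative); degenerate x-spread raises.
- Proxy saturation (εp ≥ εf) raises in point computations and rejects
  draws in Monte Carlo; the generator refuses scenarios that saturate.
- Sample-table rows violating invariants (sterane fractions off unity by
  > 10⁻⁶, δ¹³C outside −60…+10 ‰) are rejected row-wise with a logged
  line number; the run continues.

## Test and script problem sizes

The default test suite runs the full pipeline at 12–35 samples with
200–2000 Monte Carlo draws, 100-seed replication for regression-recovery
calibration, and 10⁵ draws for the convergence check; the acceptance
script uses 35 samples × 5000 draws. These sizes give Monte Carlo
standard errors well below the tolerances asserted.
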