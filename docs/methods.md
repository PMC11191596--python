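# Methods

This note documents the models implemented in `coastalch4`, their
assumptions, the defaults that matter, what the synthetic-site generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Benthic diffusive flux (porewater module)

Fluxes across the sediment–water interface (SWI) follow Fick's first law
for sediments, `J = −φ·Ds·dC/dz`. All depths in the package are positive
downward (porewater from the SWI, water column from the surface), so the
implementation returns `J = +φ·Ds·dC/d(depth)` with positive J meaning
efflux to the water column; the stored `BenthicFlux` fields satisfy this
identity exactly and tests re-multiply them against a one-line oracle.

`D0(T, S)` uses the Boudreau (1997) compilation: for dissolved methane
the quadratic fit `(9.798 + 0.3975 t + 0.00437 t²)·10⁻⁶ cm² s⁻¹` (Wise &
Houghton data), for the sulfate and bisulfide ions the Li & Gregory
linear fits `(4.88 + 0.232 t)` and `(10.4 + 0.273 t)·10⁻⁶ cm² s⁻¹`, all
at S = 0. Salinity enters through a Stokes–Einstein viscosity ratio
`D(S) = D(0)·μ(0,T)/μ(S,T)` with the standard polynomial viscosity fit;
at the brackish salinities this package targets (S ≈ 4.5) the correction
is well under 1 %. Tortuosity uses `θ² = 1 − 2 ln φ`, the standard
porosity–tortuosity relation for fine-grained sediments; `Ds = D0/θ²`.
The relation is isolated in `tortuosity_theta2` and trivially swappable.

Two open choices are resolved as follows and logged per run:

* **Gradient method.** Default is `two_point` across the SWI — the
  shallowest porewater sample against the bottom-water concentration —
  because interfacial fluxes are conventionally computed from the
  porewater *or bottom-water* pair. A `linear_fit` option (least squares
  over the uppermost 0–5 cm, bottom-water point included) is provided for
  profiles with dense near-surface sampling.
* **Porosity.** The surface-interval porosity is used for the interfacial
  calculation; depth-resolved porosity columns are carried but not
  depth-matched.

Porewater methane can degas during core retrieval, so measured gradients
are potential underestimates: when the maximum porewater methane exceeds
a configurable saturation threshold (default 2000 mmol m⁻³), the flux is
flagged `lower_bound` rather than corrected.

**SMTZ depth** is the shallowest depth where the linearly interpolated
methane and sulfate profiles are equimolar. Both series are resampled
onto the union of their depth grids within the overlapping range; a sign
change between grid nodes is located by linear interpolation, an exact
zero at a node is taken as the crossing. Multiple crossings (possible in
noisy data) warn and report the shallowest, matching the convention of a
single SMTZ per site.

## Sea–air exchange (watercolumn module)

`F_atm = k·(C_W − C_O)`, positive toward the atmosphere. Because the
exact parameterization behind the study-style calculation is a
site-survey choice, the package defaults to the two community standards
and records their names in every output:

* `k = 0.251·u₁₀²·(Sc/660)^−1/2` cm h⁻¹ (Wanninkhof 2014 quadratic;
  coefficient configurable). Converted internally to m d⁻¹ (×0.24).
* CH₄ Schmidt number from the published fourth-order polynomials at S = 0
  and S = 35, linearly interpolated in salinity — appropriate for
  brackish water; outside 0–30 °C the polynomial extrapolates with a
  warning.
* `C_O` from the Wiesenburg & Guinasso (1979) solubility of methane from
  moist air, linear in the dry-air mixing ratio (default 1900 ppb,
  present-day order) and in total pressure.

`C_W` is the dissolved methane at 1 m depth; when no 1 m sample exists
the nearest sample within 0–2 m is used with a warning.

**Redox classification**: hypoxic below 63 mmol m⁻³ O₂; euxinic at O₂ at
or below a sensor zero-tolerance (default 1 mmol m⁻³, since "zero" is
never exact in sensor data) with free sulfide present; anoxic water
without sulfide is labelled `anoxic_non_euxinic` with a warning. The
mapping is total. The **oxycline** is the shallowest interpolated
crossing of the 63 mmol m⁻³ threshold.

**Floating chamber**: flux = (slope of headspace mixing ratio) ×
(pV/RT)/A, converted to mmol m⁻² d⁻¹; triplicates are averaged with a
standard deviation. Default geometry is a 0.39 m diameter drum with
0.27 m headspace (A = 0.1195 m², V = 0.0323 m³). Series with R² < 0.9
are flagged non-linear but still return a value; deployments outside the
3–10 min protocol window warn.

## Isotope systematics (isotopes module)

**Rayleigh fractionation.** The closed-system model
`δ + 1000 = (δ₀ + 1000)·f^(1/α−1)` is fitted by ordinary least squares of
`ln(δ + 1000)` on `ln C`, using concentration as the proxy for the
remaining fraction f; the slope s gives `α = 1/(1+s)` and
`ε = (α−1)·1000 ‰`. An open-system alternative (`δ = δ₀ + ε(1−f)`) is
available. The fit window is a per-site analyst choice — the depth zone
where residual-pool enrichment is observed, typically between the surface
mixed layer and the oxycline — and is never auto-detected. Fits implying
α < 1 are returned with an inverse-fractionation warning; values are
compared against the 1.002–1.035 window typical of aerobic and anaerobic
methane oxidation.

**Bubble/diffusion partition.** Two endmembers: the sediment source
signature carried by dissolving bubbles (default δ¹³C = −58.7 ‰), and a
residual endmember representing the maximally oxidized diffusive pool,
defaulting to the most ¹³C-enriched δ observed below the
bubble-influenced surface band and at/above the oxycline (overridable per
site, since this choice is not uniquely determined by theory). The
mixing fraction is clipped to [0, 1], warning when the raw value falls
outside by more than 0.02. δD is carried through all types and an
optional dual-isotope consistency check compares δD- and δ¹³C-predicted
fractions, but the partition itself is carbon-based. Report-level
percentages are rounded to integers; unrounded values are retained in
machine-readable output, and the implementation never forces rounded
concentration cells to reproduce a rounded percentage.

## Budgets (budget module)

Removal efficiency treats the diffusive benthic flux as the sole source
(`assuming diffusive supply only` is the stated scope of this statistic):
`efficiency = 100·(F_sed − F_atm)/F_sed`, `escape = 100·F_atm/F_sed`;
the two sum to exactly 100 unrounded. `F_atm > F_sed` produces a negative
efficiency with a warning — bubble dissolution or lateral inputs are then
implied — rather than clipping. Cross-site structure is summarized by the
Spearman rank correlation of SMTZ depth against the benthic or calculated
sea–air flux; degenerate ranks return None with a warning.

## Synthetic sites (synthetic_data module)

The generator plants a known truth for every estimated quantity:

* **Porewater**: methane rises linearly from the bottom-water value with
  the gradient that makes Fick's law return the planted flux (given the
  spec's φ, T, S), saturating below the SMTZ with a continuous slope;
  sulfate decays exponentially so the noise-free curves cross exactly at
  the planted SMTZ depth. Default grid 2.5 cm with a z = 0 bottom-water
  row. The functional form is a convenience, not a diagenetic model; only
  the crossing depth and interfacial gradient are contractually
  meaningful.
* **Water column** (1 m grid, 20 m deep by default): stratified sites get
  an O₂ profile crossing 63 mmol m⁻³ exactly at the planted oxycline,
  sulfide and methane accumulating linearly below it (bottom methane of
  order 80 mmol m⁻³ under euxinia), and a closed-system Rayleigh
  enrichment zone between the oxycline (remaining fraction 1) and the
  surface mixed layer (fraction `f_top = 0.25`), with concentration
  proportional to the remaining fraction so the ln–ln fit is exact in the
  noise-free limit. A surface band (≤ 5.5 m) mixes in a bubble-derived
  fraction carrying the source signature. The 1 m concentration is scaled
  so the calculated sea–air flux equals the planted escape fraction times
  the planted benthic flux — which also makes chamber and gas-exchange
  estimates mutually consistent. Fully mixed oxic sites get uniform O₂
  and a uniform oxidized methane pool plus the same bubble band.
* **Chamber**: triplicate linear ppb series whose slope encodes the
  planted flux through the ideal-gas chamber equation, with independent
  Gaussian noise per replicate (default 2 ppb, analyzer-class).
* **Archipelago**: the default 11-site mix is 4 oxic / 3 hypoxic /
  4 euxinic. Euxinic sites draw the shallowest SMTZ depths (1–6 cm),
  hypoxic intermediate, oxic the deepest (12–40 cm); the planted benthic
  flux is a monotone-decreasing function of SMTZ depth spanning
  ~0.4–8.4 mmol m⁻² d⁻¹ (so the planted rank correlation is exactly −1);
  the planted escape fraction decreases with SMTZ depth and is scaled up
  ×1.6 for euxinic sites, encoding the finding that long-stratified
  euxinic sites with shallow oxyclines have the weakest water-column
  filter.

Noise: multiplicative, mean-preserving lognormal on concentrations
(default CV 2.4 %, a typical replicate analytical uncertainty) and
additive Gaussian 0.5 ‰ on δ values. All draws are seeded; replicates use
documented seed offsets.

**What passing recovery tests shows — and does not.** The generator's
profiles are smooth parametric curves with independent noise; real
profiles carry correlated structure (bioturbation, lateral advection,
bubble stochasticity, sensor drift) that the generator does not emulate.
Parameter-recovery results therefore validate the estimators'
correctness and their robustness to analytical-scale noise, not their
field accuracy; field-derived flux ranges cannot be reproduced without
the original profile data and enter the tests only as worked-example
inputs.

## Numerical choices and edge cases

* Equimolar/oxycline crossings: linear interpolation; exact node hits are
  taken as-is; shallowest crossing wins on ties, with a warning.
* Rayleigh fits require ≥ 3 pairs and strictly positive concentrations;
  δ ≤ −1000 ‰ is rejected as unphysical.
* Unit grammar: `<measurand>_<unit>` CSV headers with a whitelist;
  `umol_L` is accepted and exposed as `mmol_m3` (numerically identical),
  flagged so a second conversion is refused.
* Problem sizes in the test suite and acceptance script (100-site SMTZ
  ensembles, 100-seed Rayleigh recoveries, 11-site archipelagos) were
  chosen so each statistic is stable to well within its tolerance while
  the whole suite completes in seconds.

## Known limitations

* No reaction–transport modelling of the SMTZ and no ebullitive benthic
  flux: bubble release enters only through its dissolved isotope imprint.
* No mechanistic bubble-plume or turbulence modelling; stratification
  effects are encoded empirically in the generator.
* The open-system Rayleigh variant is a first-order alternative, not a
  reactive-transport isotope model.
* Efficiency budgets assume diffusive benthic supply only; sites with
  strong ebullition will show `F_atm > F_sed` and a flagged negative
  efficiency.
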