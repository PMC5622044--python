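# Methods

This note documents the models implemented in `tradeair`, the assumptions
behind the synthetic world, the numerical choices, and the limits of what
the tests demonstrate.

## Linked MRIO accounting

The economy is a single square table over R regions × S sectors
(region-major, sector-minor flattening): intermediate flows Z, final demand
Y (one column per consuming region), gross output x = Z·1 + Y·1. The first
`n_domestic` regions are provinces; the rest are foreign partners.
Technical coefficients are A = Z x̂⁻¹; the economy must be productive
(spectral radius of A below 1). The Leontief inverse is obtained by a dense
linear solve of (I − A)L = I rather than an explicit inverse, and all
balance checks use a relative tolerance of 1e-8. Zero-output sectors get
all-zero coefficient columns and zero emission intensity (with a logged
warning) so the algebra stays total.

Embodied emissions are E = F̂ L Y expanded to a (pollutant, producer
region, producer sector, consumer region) tensor, from which the
production account E_p (local + interprovincial exports + international
exports) and the consumption account E_c (local + interprovincial imports +
international imports) are read off as partial sums. Because both accounts
are partial sums of one tensor, global conservation ΣE_p = ΣE_c and the
exact partition of E_p hold by construction and are asserted at run time.

**Table linking.** Coupling a stand-alone provincial MRIO to a foreign IO
table requires splitting each bilateral export flow into intermediate
deliveries (into the destination's industries) and final demand. The full
estimation of those two matrices from trade statistics is a data exercise
outside this package's scope; `link_tables` implements the simplest rule
consistent with the binding constraint — the splits must re-sum to the
given export/import matrices exactly: each flow is divided proportionally
to the destination region's own intermediate-vs-final absorption shares for
that product and spread over purchasing industries in proportion to the
destination's internal use pattern. Gross output is then recomputed from
the row balance. This proportional rule is a declared stand-in, not an
estimate of any real country's trade structure.

Inventory-to-MRIO sector mapping (`sector_map`) is a mass-conserving
reallocation driven by a configuration dictionary of per-category weights.

## Counterfactual scenarios

Scenario vectors are built from the embodied tensor on regional totals
(per pollutant), not per sector: the dispersion surrogate takes provincial
totals, so a sectoral spatial allocation would add no information.

1. baseline = production-based totals;
2. international exports removed: E_p − Σ_foreign E^{r→f};
3. interprovincial relocation: E_p − Σ_{s≠r} E^{r→s} + Σ_{s≠r} E^{s→r}
   over domestic partners only — the international-export component stays
   with the producer, so the national total of every pollutant is conserved
   (checked to 1e-9 relative);
4.–6. partner-group variants of scenario 2; when the groups partition the
   foreign set, their removals sum exactly to scenario 2's removal.

## Exposure attribution

The chemistry-transport step is a linear source–receptor surrogate: per
pollutant and province, an isotropic exponential-decay kernel from the
province centroid, normalized to unit sum over the grid, scaled by a
transfer coefficient β (μg/m³ per Mt per unit kernel weight) and added to a
natural background. Linearity is what makes exact ground truth computable;
it ignores chemistry, meteorology and nonlinear aerosol formation, which is
acceptable here because modelled fields are used *only* through the change
ratio A = 1 − C_m,scen/C_m,base (cells with baseline below 1e-6 μg/m³ get
A = 0; the background makes this unreachable in practice, but the operation
must be total). The satellite-calibrated split C_TRE = C_sat·A,
C_noTRE = C_sat − C_TRE is exact by construction; C_TRE is negative
wherever a scenario raises the modelled concentration (relocation
scenarios). When the model grid is coarser than the satellite grid, ratios
are upsampled by nearest-cell replication before calibration — the simplest
scheme that cannot create new extrema. Population regridding is a
conservative block sum.

## IER mortality

Relative risk follows the integrated exposure–response form
RR(C) = 1 + α(1 − exp(−γ(C − C₀)^δ)) above the counterfactual
concentration C₀ and 1 at or below it; all four parameters are strictly
positive, so every curve is nondecreasing with plateau 1 + α.

The increment average RR(C_TRE) = (1/N)Σ_{i=0}^{N−1} RR(i·h + C_TRE)/RR(i·h)
uses h = C_noTRE/(N−1) and N = 1000, so the sampled positions include both
0 and C_noTRE exactly; a zero C_noTRE degenerates to RR(C_TRE) itself.
Negative increments (relocation scenarios) evaluate through the same
formula — ratio arguments below C₀ clamp to RR = 1 — giving RR ≤ 1,
AF ≤ 0 and negative deaths, reported as avoided deaths. Attributable
fractions are computed per grid cell (each cell its own aggregation unit)
and deaths summed to provinces; population-share weighting over a larger
unit is available as an alternative through the `pop` argument of
`attributable_fraction`.

**Ensemble propagation.** The 1000-draw parameter ensemble is pushed
through the full rr_of_trade → AF → M chain per endpoint; the central
estimate is draw 0 and CI95 the (2.5, 97.5) percentiles. For speed the
ensemble evaluator tabulates each drawn curve on a 4096-node uniform
concentration grid and interpolates linearly, with the interpolation
abscissae precomputed once per exposure field (they do not depend on the
draw). Numerator and denominator interpolate the same table, so a zero
increment cancels to exactly 1 and scenarios identical to baseline yield
exactly zero deaths. The interpolation error is below 2e-5 in RR (tested
against the direct sum); the direct N-term evaluation remains the
reference implementation of `rr_of_trade` and is itself validated against
an adaptive-quadrature oracle to better than 1e-3 relative.

## Synthetic world

Defaults define the standard study conditions: 6 provinces (3 coastal,
3 interior), 3 foreign regions, 3 sectors, a 60×60 grid of 10 km cells,
1000 IER draws.

- **Economy.** Coefficient columns are Dirichlet compositions scaled to
  column sums drawn in [0.35, 0.65], bounding the spectral radius below 1
  by construction (a defensive rescale guards the bound). Weights bias
  interior provinces toward supplying intermediates and coastal/foreign
  regions toward consumption, reproducing the qualitative asymmetry the
  pipeline is designed to resolve. Final demand totals (coastal 140–200,
  interior 40–70, foreign 80–140 billion US$) give provincial outputs of
  order 10²–10³ billion US$.
- **Intensities.** Coastal SO₂ base 3.5 g/US$, heavy industry 3× services
  0.3×, interior provinces dirtier by `intensity_gradient` (default 3),
  foreign regions 0.4× coastal. Sector jitter is shared across regions so a
  unit gradient yields identical provinces.
- **Grid.** Provinces partition the lattice by nearest centroid (coastal
  east, interior west); population is a 10⁴-per-cell base plus Gaussian
  agglomerations (coastal 4×10⁷, interior 1.5×10⁷ people), total ≈ 2×10⁸.
- **Dispersion.** Decay lengths 60 km (primary PM₂.₅), 150 km (SO₂),
  120 km (NOx) — secondary precursors travel farther; transfer
  coefficients 4500/2200/1500 μg·m⁻³ per Mt per unit weight and an 8 μg/m³
  background put population-weighted means in the realistic tens of μg/m³.
- **Satellite.** Multiplicative lognormal noise with mean 1 and CV 0.2 on
  the baseline modelled field: nonnegative by construction, zero CV
  reproduces the model exactly.
- **IER ensemble.** Central parameters per endpoint (C₀ ≈ 7 μg/m³,
  plateau excess risks 0.55–1.40, γ 0.012–0.035, δ 0.70–0.85) emulate
  published integrated exposure–response shapes; draws scatter
  lognormally (CVs 0.10–0.30) around the central values, draw 0 being the
  central set. National baseline incidences: IHD 1.10, stroke 1.60, COPD
  0.90, LC 0.45 per 1000 person-years.

What the generator does **not** emulate: real geography and wind fields,
sectoral spatial allocation of emissions within provinces, correlated
satellite retrieval error, age structure and province-level incidence.
Passing tests therefore demonstrate the correctness of the accounting,
calibration and burden algebra under a linear atmosphere — not the
realism of any particular published estimate.

## Oracle and verification

`tradeair.oracle` shares no code with the pipeline paths it validates:
embodied emissions by truncated Neumann summation Σ A^k Y (tolerance
1e-10, failure if unconverged by order 500), concentration fields rebuilt
cell-by-cell from kernel metadata with explicit loops, and the increment
average by adaptive quadrature of the continuous mean ratio with the
curve's kinks passed as breakpoints. End-to-end, pipeline scenario deaths
match the oracle within 0.1% on the default world (the acceptance bound is
1%, dominated by the O(1/N) discretization of the increment average).

## Problem sizes and runtime

The default world (3600 cells × 1000 draws × 4 endpoints × N = 1000) is
the package's chosen standard condition; a full-ensemble scenario CI takes
~40 s on one CPU and the whole acceptance script about two minutes. Unit
tests run on a 4-province, 20×20-cell, 50-draw world in seconds.

## Known limitations

- The dispersion surrogate is linear and isotropic; secondary-PM chemistry
  enters only as longer decay lengths and smaller transfer coefficients.
- The IDM/FDM proportional linking rule is a stand-in for a data-driven
  estimation.
- Confidence intervals reflect only IER parameter uncertainty, not
  emission, dispersion or satellite error.
- Baseline incidence is national; provincial heterogeneity in health
  status is not represented.
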