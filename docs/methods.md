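# Methods

## Model structure and assumptions

The model is a five-pool, annual-step representation of moist acidic tundra
biogeochemistry: vegetation C and N, detritus + soil organic C and N
(a single lumped pool), and inorganic N. There is no seasonality, no
vertical soil structure, no phosphorus, and a single implicit vegetation
type. Temperature responses use simple Q10 multipliers, Q10^(T/10), which
is adequate because warming scenarios stay within 5 °C of the baseline;
T is on a summer-calibrated scale (10 °C at calibration), since annual
plant and microbial activity is dominated by the growing season. Vole
metabolism instead uses annual temperature, obtained from the summer scale
with the offset T0 = 10 °C; per-capita offtake and respiration *decline*
linearly with warming (slope εV) because thermoregulation costs fall, and
both are floored at zero.

Voles are prescribed drivers (voles/ha), reflecting top-down control of
small-mammal cycles; the model deliberately contains no vole demography.
The `run_with_npp_feedback` mode relaxes this by scaling each year's
density by the previous year's NPP relative to the calibration NPP — a
minimal bottom-up coupling used for sensitivity analysis, not a population
model.

### Stoichiometric regulation

Ψ = (B_C/B_N)/q_B and Φ = (D_C/D_N)/q_D equal 1 at calibration. Their
placement in the process equations encodes C:N acclimation:

- P_s = (g_C/Ψ)·S·C_a/(k_C + C_a)·Q10^(T/10) — rising plant C:N
  down-regulates C acquisition;
- U_N ∝ Ψ, L_itN ∝ 1/Ψ, R_a ∝ Ψ;
- U_Nm ∝ Φ, R_h ∝ Φ, N_min ∝ 1/Φ — rising soil C:N favors immobilization
  over mineralization.

Where the source material was typographically ambiguous about these
placements, we selected among the sign-consistent alternatives the
combination that reproduces the documented causal structure (↑Ψ → ↓P_s,
↑Ψ → ↓L_itN, ↑Φ → ↓(N_min − U_Nm)) *and* the reported long-run responses:
with Ψ dividing P_s and multiplying R_a, vole removal in the explicit
40-vole calibration shifts plant C by +116 gC/m² and soil C by +731 gC/m²,
and the CO₂-only scenario raises plant C by 11% and soil C by 4.0% —
matching the reported 13%/4% and 11–12%/4% responses. The rejected
variants miss those anchors by factors of ~2. All variants agree exactly
at the calibration point (Ψ = Φ = 1), which is why calibration cannot
discriminate among them.

## Calibration

All rate parameters come from closed-form inversion of the flux targets at
the reference state, never from rounded printed values: e.g.
g_C = P_s(k_C + C_a)/(S·C_a·Q10_Ps), m_CB = (L_itC,total − G_C*)/B_C.
The optimum C:N ratios are set from the stock ratios themselves
(q_B = 878/20.6, q_D = 19 452/831) so Ψ = Φ = 1 holds exactly; otherwise
4-digit rounding would leave O(10⁻³) derivative residuals where exact
steady state is required. Explicit calibrations subtract the vole fluxes,
evaluated at T = T0 so εV drops out, from the four parallel processes
(litter C and N, heterotrophic respiration, gross mineralization) before
fitting m_CB, m_NB, r_D, m_Nm. Vole + parallel totals are invariant across
calibrations by construction. A requested density is infeasible once any
parallel residual would go non-positive (first litter N, near 292
voles/ha).

## Synthetic drivers

The vole-cycle generator emulates only the documented summary statistics
of Arctic small-mammal cycles: peaks every 3 or 4 years (uniform choice),
peak heights U(90, 110), troughs U(8, 12) voles/ha, long-run mean 40. The
within-cycle shape is our choice: [peak, trough, trough] for 3-yr cycles
and [peak, trough, trough, shoulder] with shoulder ~ U(35, 45) for 4-yr
cycles, giving both an expected mean of 40. If a realized series drifts
outside mean 40 ± 1, non-peak years are rescaled by at most ±5% (troughs
clamped back to [8, 12]). The generator does not emulate dampened or
interrupted cycles, snow-driven irregularity, or spatial structure — so
passing tests say nothing about model behavior under non-cyclic vole
dynamics. Climate drivers are linear ramps (CO₂ 400→800 μmol/mol,
T 10→15 °C over 100 yr) held constant afterward. Drivers are annual
constants; year t's fluxes use year t's drivers.

## Numerics

Integration is explicit Euler with 48 substeps per year (`DEFAULT_SUBSTEPS`).
The inorganic-N pool (0.27 gN/m²) turns over ~70×/yr and its linearized
relaxation rate is ≈58 yr⁻¹, so explicit Euler needs dt < 2/58 ≈ 1/29 yr;
coarser stepping (e.g. 12 substeps) is numerically unstable on cycling-vole
runs. At 48 substeps, doubling to 96 moves 200-yr stock trajectories by
< 10⁻⁴ relative. Reported annual fluxes are substep averages; the final
row of a trajectory holds the instantaneous evaluation at the end state.
If inorganic N undershoots zero within a substep (deep N depletion at a
late-warming vole peak; it never happens at calibration conditions), it is
floored at zero, the event logged, and the injected mass tracked so the
whole-run conservation audit — stock change equals time-integrated net
flux, to < 10⁻⁶ — still closes. B_C, B_N, D_N reaching zero raises a
degenerate-state error rather than returning infinities.

The steady-state solver integrates under constant drivers until
max|dX/dt|/X < 10⁻¹⁰ yr⁻¹ (2000-yr cap, non-convergence flagged). Note
that *total* ecosystem N equilibrates only on the refractory-loss
timescale 1/β_NR ≈ 6000 yr, so vole-addition/removal experiments quote
stocks from fixed 500-yr integrations — long enough for the fast
redistribution (decades) to complete, matching how the reference responses
were measured — rather than from the strict fixed point, where soil-N
deltas would drift by another ~1 gN/m² over millennia. Plant and soil C
shifts differ by < 3% between the two conventions.

## Scenario suite and metrics

Thirteen scenarios: Set 1 (200 yr, constant climate, calibration II) —
constant 40 voles/ha (stability control), cycling voles, cycling 10 yr
then held at 100 or 0 voles/ha; Set 2 (100 yr) — calibrations I/II/III
crossed with CO₂ ramp, warming ramp, and both.

- Total ecosystem C is B_C + D_C; vole standing biomass is not a pool.
- Set-2 comparisons are evaluated at year 100, the end of the ramps.
- The underestimation index is 100·(ΔC_explicit − ΔC_aggregated)/ΔC_explicit;
  it exceeds 100% when the aggregated run *loses* C while the explicit run
  gains.
- Cycle metrics (amplitude, vole-peak→plant-C-minimum lag) use end-of-year
  stocks, since the grazing of a peak year draws biomass down within that
  year; with this convention the plant-C minimum falls in the peak year
  itself (lag 0).
- The recovery partition uses annual-mean stocks (average of start and end
  of year): the reference thresholds (875 gC/m², 20.2 gN/m²) sit between
  the start-of-year and end-of-year levels at vole peaks and only bisect
  the annual-mean distribution. Recovery segments cover one cycle each
  (peak year up to the next peak), classified by the stock at the
  *previous* peak.

## Known limitations

- The stoichiometric placements of Ψ in R_a and Φ in R_h have no
  independent sign anchor; the adopted forms are validated only against
  aggregate responses, and at Ψ ≈ Φ ≈ 1 the alternatives are
  second-order-indistinguishable.
- The 20.2 gN/m² plant-N recovery threshold does not bisect our generated
  cycles as cleanly as the 875 gC/m² plant-C threshold; group sizes for
  plant N are unbalanced under the default generator.
- Annual time stepping with piecewise-constant drivers cannot represent
  within-year grazing pulses; the substep machinery is numerical, not
  phenological.
- Euler integration conserves mass exactly by construction but is
  first-order; all quoted responses are converged to < 0.1% in dt.
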