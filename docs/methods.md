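# Methods

This note documents the models implemented in `plantdeb`, the assumptions
and parameter choices behind the shipped defaults, and the numerical
decisions that matter for interpreting results.

## Synthesizing-unit kinetics

All transformations are described by synthesizing units (SUs): stylized
biochemical machines converting substrate fluxes into a product flux. For
complementary substrates with scaled arrival rates ρᵢ (raw arrivals divided
by their stoichiometric yields):

* **Minimum rule** — `j = min(ρ₁, ρ₂)`. A Liebig idealization: the SU is
  perfectly efficient with respect to the limiting substrate and rejects
  only the non-limiting one.
* **Parallel complementary SU (PCSU)** — `j = (1/ρ₁ + 1/ρ₂ − 1/(ρ₁+ρ₂))⁻¹`.
  Substrates bind independently at parallel sites and a production cycle
  completes when both are bound. The mean cycle time is the expectation of
  the maximum of two exponentials, which is where the closed form comes
  from; the k-substrate generalization uses the inclusion–exclusion
  expansion of E[max] and is provided as an optional code path. At ρ₁ = ρ₂
  the PCSU runs at exactly 2/3 of the minimum rule.

Both rules return 0 if any required substrate is absent (the reciprocal
form is never evaluated at zero). Rejection is always
`arrivalᵢ − yieldᵢ·j ≥ 0`, so substrate is conserved identically at every
SU. A discrete-event binding-site simulation (exponential waiting times,
seeded generator) serves as an independent stochastic oracle for the PCSU
rate in the tests and the acceptance script; it is never used in the
deterministic models.

Acquisition SUs saturate hyperbolically with environmental concentration
(`j = j_max·c/(c+K)`); internal SUs are demand-unconstrained and process
whatever arrives.

## Root–shoot DEB model

State (13 components): structural masses `M_V_S`, `M_V_R` (C-mol); reserve
densities `m_EC_S`, `m_EN_S`, `m_EC_R`, `m_EN_R` (C-mol reserve per C-mol
structure); cumulative pools for products, litter C and N, metabolic CO₂,
excreted N, and assimilated C and N. The cumulative pools are audit
bookkeeping, not metabolic state. Time is in days; carbon in C-mol,
nitrogen in N-mol. Both organs are V1-morphs: surface scales with volume,
so specific rates are size-independent and growth in a constant
environment is exponential and indeterminate.

Per right-hand-side evaluation the cascade is:

1. **Acquisition.** `J_A_C = M_V_S · j_CAm · f(CO₂) · f(light) · A(T)` and
   `J_A_N = M_V_R · j_NAm · f(N) · A(T)` with saturating `f` and the
   Arrhenius factor `A(T) = exp(T_A/T_ref − T_A/T)` applied to every rate
   in the model (one shared `T_A`). Light enters multiplicatively by
   default; a config switch (`light_mode="pcsu"`) treats CO₂ and light as
   complementary PCSU substrates instead.
2. **Mobilization.** First-order reserve turnover `ν·m·M_V` per reserve,
   with one ν per reserve class shared across organs.
3. **Maintenance and growth.** The maintenance demand `p_M·M_V` is paid
   from the mobilized C-reserve flux first, then from the carbon of the
   mobilized N-reserve flux (its nitrogen is excreted); any unpaid
   remainder is a reported deficit. Post-maintenance fluxes feed the
   growth PCSU with yields `(y_EC_V, y_EN_V)`; a fraction `κ_P` of
   synthesis becomes products (wood: no maintenance, no turnover, no
   physiological feedback), the rest becomes structure of N:C ratio
   `n_NV`. The growth SU's rejected fluxes are the organ's surplus.
4. **Translocation.** Organs share only their surplus. The shoot's surplus
   carbon is delivered to the root assimilation SU (its rejection lands in
   the root C reserve); the other three surpluses arrive directly in the
   partner's corresponding reserve. This asymmetry reflects the wiring of
   N assimilation: building the nitrogen-rich (organic) reserve in the
   root consumes carbon skeletons that only the shoot can supply. A
   fraction `1 − η_T` of every transfer dissipates (carbon to CO₂,
   nitrogen to litter).
5. **Reserve assembly.** N-rich reserve formation takes priority over the
   C reserve. Root assembly first: a PCSU over (shoot-derived CH₂O, the
   local share `(1−λ_N)` of uptake N) with yields `(y_C_EN, n_NE)`;
   rejected CH₂O feeds the root C reserve, rejected N is forwarded
   upward. Shoot assembly second: photosynthate plus `λ_N` of uptake and
   the root-rejected N; shoot-rejected N is excreted to a tracked pool
   (`N_excess`) rather than recirculated, which avoids an algebraic loop
   while conserving nitrogen exactly. The carbon overhead `y_C_EN − 1` of
   each synthesis respires.
6. **Senescence and resorption.** Structure turns over at `h_V`; a
   fraction σ of the lost carbon and nitrogen is resorbed into the organ's
   own C and N reserves (nitrogen as N-reserve C-equivalents via `n_NE`),
   the rest is litter. Reserves carried by the senescing tissue go to
   litter without resorption; this choice keeps the reserve-density
   derivative in the standard V1-morph form (dilution by structural growth
   only) while closing the element balances identically.

Reserve densities follow `dm/dt = (inflow − mobilized)/M_V − m·G/M_V` with
`G` the structural growth rate.

**Starvation death.** The plant is flagged dead — a terminal event located
by sign-change root finding — when an organ has a positive maintenance
deficit while both of its reserve densities are below `eps_death`. There
is no shrinkage rescue by default (`allow_shrinkage` pays deficits from
structure when enabled, with its own ledger entries so closure still
holds). Because resorption from senescing structure sustains reserve
densities at a floor of roughly `h_V·σ/ν` (0.025 at the defaults) even
with zero assimilation, `eps_death` must exceed that floor to be reachable;
the default is 0.03 — a reserve below 3% of structural mass is treated as
functionally exhausted.

**Mass-balance audit.** Two independent checks: (i) the change in total
tracked carbon (structures + reserves + products + CO₂ + litter) must
equal cumulative assimilation, with the cumulative pools integrated by the
same solver so the comparison is exact up to integration error, and the
nitrogen analogue including the excreted pool; (ii) the signed C and N
sums of every recorded flux ledger must vanish. The audit reports the
worst relative error of either check and detects injected ledger faults.

### Default parameters

Values are normalized fixture defaults (half-saturation constants of 1,
order-one yields), chosen once so that the default scenarios support
viable balanced growth; they are not calibrated to any species.

| parameter | default | units | meaning |
|---|---|---|---|
| `j_CAm` | 1.0 | C-mol (C-mol shoot)⁻¹ d⁻¹ | max specific assimilation |
| `j_NAm` | 0.06 | N-mol (C-mol root)⁻¹ d⁻¹ | max specific N uptake; ≈ the N:C demand ratio of growth, so neither element is grossly surplus |
| `K_C, K_L, K_N` | 1.0 | env units | half-saturations (normalized) |
| `ν_EC, ν_EN` | 0.2 | d⁻¹ | reserve turnover |
| `p_M_S, p_M_R` | 0.05 | C-mol (C-mol V)⁻¹ d⁻¹ | maintenance |
| `y_EC_V, y_EN_V` | 1.2, 0.3 | C-mol/C-mol | growth yields |
| `n_NV, n_NE` | 0.05, 0.25 | N-mol/C-mol | N:C of structure / N-reserve |
| `y_C_EN` | 1.25 | C-mol/C-mol | CH₂O cost of N-reserve synthesis |
| `λ_N` | 0.5 | – | xylem share of uptake N sent straight to the shoot |
| `κ_P_S, κ_P_R` | 0.2, 0.1 | – | product fraction of growth |
| `h_V` | 0.01 | d⁻¹ | senescence |
| `σ` | 0.5 | – | resorption fraction |
| `η_T` | 0.95 | – | translocation efficiency |
| `T_ref, T_A` | 293.15, 8000 | K | Arrhenius reference / temperature |
| `eps_death` | 0.03 | – | starvation threshold (above the resorption floor) |

Stoichiometric closure `y_EN_V·n_NE ≥ n_NV` and `n_NV ≤ n_NE` are enforced
at load: without them new structure could not be supplied with nitrogen,
and resorbed nitrogen could not be stored.

## Root–stem–leaf model

Three organ masses in series; the leaf acquires carbon (`A_C = a_C·m_L`),
the root nitrogen (`A_N = a_N·m_R`), and both streams must pass the stem's
own growth SU, which retains what it uses and shares both surpluses
onward. Each organ grows at its SU rate and turns over at μ;
`dm_i/dt = jᵢ − μᵢ·mᵢ`. α = `a_C/a_N` is varied by scaling `a_C`.

**Resolving the flux loop.** The within-instant fluxes are mutually
dependent: the stem needs the end organs' surpluses, and the end organs
need the stem's pass-through. Two resolutions are implemented:

* *Quasi-static*: damped fixed-point iteration on the two stem outflows
  (damping 0.5, tolerance 1e-10, max 500 iterations, warm-startable).
  For the smooth PCSU map this converges and is verified against a
  brute-force nested-grid search to 1e-8. For the minimum rule the map is
  piecewise linear with only degenerate corner fixed points (all growth
  concentrated in one end organ) and the iteration's drift rate vanishes
  as the carbon and nitrogen streams approach balance, so no fixed point
  is reachable there; the resolver reports failure with diagnostics
  rather than returning an unconverged answer.
* *Dynamic transport* (used by the simulator): the two pass-through
  streams are state variables relaxing at rate `k_u` (default 10 d⁻¹)
  toward the one-sweep chain update — a short but finite residence time in
  the transport path. For the PCSU this tracks the quasi-static fixed
  point to a lag bias of order `growth rate / k_u`; for the minimum rule
  it gives the model well-defined dynamics near stream balance. That
  regime is exactly the interesting one: the stem consumes essentially
  both streams, leaves and roots receive only the small imbalance leak,
  and the plant collapses toward all-stem. The asymptotic leaf and root
  shares equal `μ/(2a)` each, so the stem fraction approaches `1 − μ/a`;
  this is a property of the collapse regime, not of the relaxation rate
  (it is unchanged from `k_u = 50` to `k_u = 1000`).

**Defaults.** Yields of 1, `a_C = a_N = 1 d⁻¹`, μ = 0.005 d⁻¹ for every
organ (turnover slow relative to daily-scale acquisition — organ lifetimes
of months; the model is invariant under a joint rescaling of time, `a`, μ
and `k_u`, so only the ratio μ/a is meaningful), leaf-deficient start
`(m_L, m_S, m_R) = (0.1, 1, 1)`. Under the minimum rule: leaves grow first
(the root's nitrogen surplus passes the carbon-starved stem), the stem
takes over as the streams balance, and leaf and root masses peak and decay
while the stem fraction passes 0.99 within the 700-day fixture horizon.
Under the PCSU the same start settles into balanced exponential growth
with all three fractions above 0.24.

**α sweep.** 41 points, log₁₀α ∈ [−2, 2]. Each α is integrated from the
leaf-deficient start in doubling time chunks (initial horizon 300 d, total
mass renormalized between chunks, which scale invariance permits) until
the fraction drift over the final tenth of a chunk falls below 1e-6;
non-convergent rows are flagged, never dropped. Roots gain share where
carbon is plentiful (high α), leaves where nitrogen is easy to collect,
and the stem holds a positive share everywhere because it is the
bottleneck both streams must pass.

## Environment

Forcing is prescribed, never depleted by the plant: resource supply and
temperature are boundary conditions. Four scenario kinds: constant, step,
seasonal (sinusoidal), and noisy (multiplicative lognormal factors,
piecewise constant on a configurable grid, re-seeded per bin so channel
evaluation is a pure function of time and reproducible from the seed;
temperature is left noise-free). Channels are normalized to
half-saturation units by default. The generator emulates idealized
resource regimes — it makes no attempt at weather autocorrelation,
co-varying channels, diurnal cycles or soil feedback, so passing tests
demonstrate the internal consistency and qualitative behaviour of the
allocation rules, not predictive skill against field data.

## Numerics

* Integrator: implicit Radau (reserve turnover is fast relative to
  growth), `rel_tol 1e-8`, `abs_tol 1e-10`; explicit RK45 for the
  non-stiff root–stem–leaf runs whose minimum-rule right-hand side is
  non-smooth.
* Nonnegativity: recorded states are clipped at zero only within 1e-9
  (relative); anything worse is a hard error, because silent projection
  would corrupt the mass audit.
* Events: starvation is located by the solver's sign-change root finding
  on a continuous indicator (the smaller of the maintenance deficit and
  the two threshold gaps, maximized over organs); integration terminates
  at death since a dead plant has identically zero derivatives.
* Temperature consistency: with one shared `T_A` the entire right-hand
  side scales by a common factor, so a run at T₂ equals the run at T₁
  with time rescaled; the check integrates both on matching rescaled
  record grids and reports the worst relative state discrepancy (~1e-9 at
  the default tolerances).
* Problem sizes: the balanced-growth analysis uses a 1000-day horizon
  (growth settles within ~100 days; the long tail demonstrates drift-free
  densities), the starvation fixture 200 days, the collapse fixture 700
  days, and the sweep 41 α values; these sizes make every analysis exact
  to well beyond the tolerances quoted while keeping a full run of the
  suite inexpensive.

## Known limitations

* Water is not a resource here (no transpiration trade-off, no hydraulic
  failure); temperature has a single shared Arrhenius sensitivity and
  there is no relative-humidity dependence.
* The environment is non-depleting: no plant–soil or plant–light feedback,
  hence no self-limitation of growth.
* Death is a flag, not a mechanistic module; reproduction and maturity are
  out of scope.
* Stems appear only in the three-organ comparison model; the root–shoot
  model books wood as products and the two models are deliberately not
  merged — interposing a stem SU into the reserve-based model would
  require additional allocation constraints that the surplus rule alone
  does not supply.
* The minimum-rule collapse endpoint (`stem fraction → 1 − μ/a`) depends
  on the transport-relaxation closure of the flux loop; the quasi-static
  limit of that closure does not exist for the minimum rule, which is the
  mathematically honest reading of why the perfectly efficient rule fails
  in a three-organ chain.
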