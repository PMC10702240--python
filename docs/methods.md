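# Methods

## The estimation model

The package targets subsystems in which the MIDs of (essentially) every
participating metabolite are measured over a short labeling time course.
Under metabolic steady state (pool sizes constant, `N v = 0`) the labeling
kinetics of the tracked isotopologue concentrations are linear in the
fluxes, `P dx/dt = S(x) v`, because every entry of `S` can be evaluated
from *measured* MIDs — the defining feature of the approach is that nothing
is simulated.  Forward Euler over each measurement interval turns the ODEs
into per-interval linear balances with local error O(Δt²) and an O(Δt)
effect on the estimate, and weighted least squares over all intervals,
measured boundary fluxes and (optionally) pool sizes becomes a single
convex QP.

Assumptions inherited from the formulation:

* **Metabolic steady state.**  Checked, not enforced, by a one-way ANOVA of
  replicate pool measurements across time points (`sfcr.gof.steady_state_anova`);
  verdicts are advisory.  Masking a late time point (`mask_times`) is the
  intended remedy when steady state fails there.
* **One net flux per reversible reaction.**  A reversible reaction enters as
  a single column with bounds ±10⁶ whose S-entries use the forward-direction
  source MIDs.  Bidirectional label exchange can be expressed by authoring
  the reaction as two irreversible columns with direction-specific sources;
  the solver is unchanged.
* **Replicate means enter the fit.**  `Y(tᵢ)` and `S(tᵢ)` are built from
  replicate-mean MIDs; replicate scatter enters only through the error
  model.  One QP is solved per condition, not per replicate.
* **Diagonal error model.**  Covariance between isotopologues of one
  metabolite is ignored.

## Error model and χ²

The MID measurement SD σ per isotopologue is the maximum across-replicate
SD over the time course (time-independent by assumption); an isotopologue
with zero SD everywhere inherits σ of the next-lighter isotopologue,
recursively toward M+0.  Residuals are formed on concentration *changes*
`Y = P x(t+Δt) − P x(t)`; treating the two terms as independent with equal
variance gives `Var(Y) = 2 (μ_P σ)²`.  The weight matrices are inverse
variances, so the optimal objective equals the χ² statistic; acceptance
uses the two-sided interval `[χ²_{α/2}(df), χ²_{1−α/2}(df)]` with
`df = #measurements − rank(N)`, counting every tracked isotopologue at
every interval plus each fitted boundary flux (plus each fitted pool in
variable-pool mode).  Whether the M+0 rows should count as independent
measurements is a convention; `MIDBalanceSpec(drop_m0=True)` drops them and
changes df accordingly.

In variable-pool mode `P` and `x` are independent random variables and
`Var(P x) = σ_P² σ_x² + σ_P² μ_x² + σ_x² μ_P²` with `μ_x` estimated as the
time-mean measured fraction; the difference of two time points doubles this
variance.  (The doubling is applied for consistency with the fixed-pool
case; the variance formula itself does not make it explicit.)

Two practical consequences, visible in any fit of replicated data:
fitting replicate means while σ is a per-replicate SD understates χ² by
roughly the replicate count, and clip-and-renormalize reporting of MIDs
projects noise onto the simplex, shrinking its variance further.  Both push
χ² *below* the acceptance range ("over-fitting" verdicts).  The χ²
calibration test therefore uses single-replicate datasets with known σ and
raw (non-renormalized) Gaussian noise — the only configuration in which the
noise is exactly as specified — and recovers mean χ² ≈ df.

## The QP and its solver

ε bounds (±10⁶) never bind in practice, so the residuals are eliminated by
substitution and the program is solved over `v` (and `P` in variable-pool
mode) with equality `N v = 0` and box bounds (defaults `v_max = 10⁶`,
`v_min = −10⁶` reversible / 0 otherwise, `P ≥ 0`).  The dense solver first
tries the equality-only KKT system, then an active-set iteration on the
box, then a `trust-constr` fall-back polished by re-solving the KKT system
on the free variables; all routes are deterministic and the route taken is
reported.  A ridge of 10⁻¹² (scaled by the mean curvature) tie-breaks flat
directions toward the minimum-norm optimizer, since a rank-deficient
stacked design would otherwise leave the reported optimum arbitrary.
Every solution is checked against `max |N v| ≤ 10⁻⁶ max(1, |v|∞)`, and the
reported χ² is recomputed from the residual fields rather than read off
the solver objective.  Fluxes below 10⁻⁶ nmol gDW⁻¹ s⁻¹ are reported as
zero (`zero_small_fluxes`), the resolution at which flux rank orders are
also compared.

## Compartmentation

Compartment-specific MIDs are generally unmeasurable, so for a metabolite
present in plastid and cytosol the cytosolic MID is approximated as
`c · (measured MID)` with one scalar per compartmented species (a
per-species `c` is the default; a shared draw is available).  `c` cannot
be a QP variable without making the constraints bilinear; instead `c` is
sampled uniformly from [0.1, 0.9] (labeling dynamics assumed
plastid-dominated), 50 draws by default, and the minimum-χ² sample is
reported — explicitly *not* a global optimum over `c`.  During bootstrap,
`c` is redrawn uniformly within ±2.5 % (relative) of the best fit, clipped
to (0, 1).

Note that a `c`-scaled consumption term makes the total-pool balance
non-conservative: the tracked MID sum drifts at rate `(1−c)·v/P` per
second.  This is a property of the approximation, not of the
implementation; the synthetic fixture keeps the drift over 40 s below the
loader's 2 % normalization tolerance.

## Bootstrap

Non-parametric residual resampling: MID residuals are pooled across
isotopologues and intervals (a stratified-by-row option exists), boundary
(and pool) residuals are resampled within their own pools, the resampled
residuals are added to the *fitted* values, and the QP is re-solved; 1000
replicates by default, CIs from the 2.5th/97.5th percentiles.  The
perturbation is applied in concentration-change (Y) space: residuals carry
concentration units, so adding them to dimensionless fractions would be
inconsistent — this is the one place where the procedure is sharpened
relative to its loose prose description.  The acceptance fraction (share
of bootstrap χ² inside the acceptance interval at the base df) is reported
alongside the χ² CI.

## Synthetic data

The generator inverts the model.  `simulate_labeling` integrates
`P dx/dt = S(x) v*` with LSODA at rtol 10⁻¹⁰ and renormalizes outputs;
`euler_propagate` applies the exact Forward Euler recursion, producing data
for which the QP's equality constraints hold exactly — the strongest
possible oracle for the estimator (recovery to ~10⁻¹¹ relative).
`add_noise` adds homoscedastic Gaussian noise on fractions per replicate
(matching the time-independent σ assumption; no multinomial counting
noise), by default clipped and renormalized as measured MIDs would be, with
a raw-Gaussian option for calibration studies.

Fixture choices (made once, for realism and generator validity):

* Grid 0/5/10/20/40 s; pools nmol gDW⁻¹; fluxes a few nmol gDW⁻¹ s⁻¹
  (the magnitude of measured algal carboxylation rates); MID noise SD 0.01,
  3 replicates, 5 % pool SDs.
* Pool sizes are set so every pool/consumption turnover time exceeds the
  widest sampling interval (20 s) — below that the Euler recursion leaves
  the simplex (the generator raises an error), and a 2× margin keeps the
  decay monotone.
* All fixture fluxes exceed the 10⁻⁶ reporting threshold by ≥ 5 orders of
  magnitude.
* `mini_cbc` keeps the compartmentation drift (above) under the 2 %
  tolerance: sucrose-like flux 0.2 against a 300 nmol gDW⁻¹ hexose pool.

What the fixtures do *not* emulate: natural-abundance contamination and
mass-spectrometric fragment effects, correlated isotopologue errors,
pool-size drift during labeling, and model misspecification (every fit sees
the structurally correct balance spec).  Passing tests therefore validate
the estimator and its statistics under the stated error model, not
robustness to structural error in real data.

## Validation experiments (what the acceptance script computes)

* **χ² ranges** at df 149/166/118 straight from the inverse CDF.
* **Exact recovery** on Euler-consistent data for both fixtures.
* **Euler convergence**: fitting exact-ODE data at Δt = 4, 2, 1 s.  The
  experiment weakens the boundary-flux priors (SD 10³): with informative
  boundary measurements the boundary rows contribute Δt-independent
  information while the MID blocks' information scales with Δt, so the
  estimate error decays ~O(Δt²) and hides the first-order discretization
  signature that the experiment is meant to measure.  With weak priors the
  per-halving error ratios are ≈ 2.0.
* **χ² calibration** (50 single-replicate fits, raw Gaussian noise, known
  σ): mean χ² vs df.
* **Bootstrap coverage**: 20 datasets × 200 replicates, share of 95 % CIs
  covering the generating fluxes.
* **Compartmentation recovery**: 50 uniform draws against noise-free data
  generated with c* = 0.4; the best fit is the draw nearest c*.
* **Interpolation stability**: Spearman correlation between fluxes fit on
  the coarse grid and on a 1 s B-spline-densified grid (ranks taken at the
  10⁻⁶ flux resolution so stoichiometrically tied fluxes tie consistently).

Problem sizes (5–6 reactions, 9–11 tracked isotopologue rows, 4 intervals)
are desk-scale on purpose: every quantity recomputes from scratch in
seconds while exercising every code path, and the properties tested
(convexity, calibration, coverage, first-order convergence) are
size-independent.

## Known limitations

* Forward evaluation at the left endpoint only; no midpoint/trapezoid
  variant yet (densification via `interpolate_mids` is the provided
  mitigation).
* No covariances in the error model; no flux-variability analysis at fixed
  χ²; no global-optimality claim for the sampled compartmentation
  coefficients.
* Boundary fluxes are always soft-fitted; the `exchange_scale` option can
  rescale the measured values (default 1) but no attempt is made to
  reconcile order-of-magnitude tension between labeling-driven and
  measured boundary fluxes.
* SBML import and atom-mapping inference are out of scope: balance specs
  are authored explicitly, mirroring how such ODE systems are written by
  hand.
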