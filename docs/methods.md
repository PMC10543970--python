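# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `fermsense`, and what the synthetic campaign does and
does not establish about real fermentation data.

## The synthetic bioreactor

The simulator emulates a 3.6 L stirred-tank cultivation of *L. rhamnosus*
at 37 °C, pH 6 held with 3 M NaOH, 200 rpm, 12 L/h air sparging, sampled
on a uniform 5-minute grid with hourly offline cell-dry-weight draws
(10 ml each) through the growth phase plus an end point.

**Batch growth truth.** Batch biomass follows the logistic curve
x(t) = X_m / (1 + exp(2 + (4V_x/X_m)(λ_x − t))). Its parameters are
derived from the medium rather than set per run: X_m = X₀ + 0.95·Y_xs·S₀,
where S₀ is the fermentable-lactose equivalent of the carbohydrate
components (lactose 100%, whey permeate 80%, demineralised whey 70%,
skim-milk powder 52% lactose by mass), V_x = μ_max·X_m/4, and λ_x is the
unique lag for which x(0) equals the inoculum. Using the same logistic
form the downstream `fit_logistic` estimator assumes makes batch
parameter recovery exact by construction — deliberately, so that estimator
defects cannot hide behind model mismatch.

**Fed-batch growth truth.** The study's logistic model is batch-only, so
during feeding the simulator switches to the minimal mechanistic model
consistent with the exponential-feed design equations: Monod kinetics
μ = μ_max·S/(K_s + S) on the limiting substrate with maintenance-inclusive
yield Y_xs, and mass balances dm_x/dt = μ·m_x,
dm_s/dt = F·S_i/1000 − μ·m_x/Y_xs, integrated with LSODA
(rtol 1e-9) between offline draws; draws scale the state by the removed
volume fraction. The feed F(t) = F₀·e^{μ_set·(t−t_start)} starts at 14 h
from the simulated batch-phase state, with the feed window capped so
feed + stoichiometric base cannot overflow the vessel; exceeding the
configured maximum volume terminates the run with an overflow flag.
The four setpoints are spread over the four fed-batch runs with the
held-out run at 0.19 h⁻¹, matching the reported test cultivation; the
held-out condition is then an interpolation of the training envelope, as
in the study design.

**Base addition.** Lactate formation is tied to growth by Y_ps/Y_xs
(homofermentative assumption) and neutralised 1:1 by 3 M NaOH. In the
batch phase this gives the closed-form volume
V(t) = V_ref·(1 − c·X_ref)/(1 − c·X(t)) with
c = (Y_ps/Y_xs)/(M_lac·molarity), so no ODE is needed there and the
mass-balance identity base_mol = (Y_ps/Y_xs)·Δ(X·V)/M_lac holds to
floating-point precision.

**Off-gas and DO.** O₂ consumption and CO₂ evolution are proportional to
growth (0.08 g O₂ and 0.115 g CO₂ per g biomass — lactic acid bacteria
are weak respirers; the implied molar RQ is ≈1.05). Outlet gas fractions
are obtained by inverting the inert-gas balance, which makes
`compute_our`/`compute_cer` exact inverses of the generator — a strong
round-trip test. Dissolved oxygen is quasi-steady,
DO% = 100·(1 − OUR/(k_La·C*)), clipped to [0, 100]; at 5-minute
resolution the DO time constant (~1/k_La ≈ 1 min) is not resolvable, so a
DO ODE would add stiffness without information.

**Measurement model.** The TCD probe responds as
AU = g·X/(1 + X/X_sat) + offset with X_sat = 30 g/L — the mild
Beer–Lambert saturation every optical density probe shows — plus Gaussian
noise and occasional spike outliers (which give the median filter real
work); the per-run gain is perturbed by a few percent to emulate
media-dependent calibrations. Remaining channels carry independent
Gaussian noise (DO 0.5%, O₂ 0.02%, CO₂ 0.01% absolute); the base channel
is metered, not noisy. Offline CDW carries 0.05 g/L error. All
randomness flows from a single integer seed; re-simulation is
bit-identical, and per-run seeds derive deterministically from the
campaign seed.

**What the generator does not emulate:** pH dynamics, temperature
excursions, foam, milk-gel rheology, diauxie, analyser delay and drift,
or cell viability. Passing tests therefore demonstrate that the
estimation pipeline is correct and well-conditioned under realistic noise
and nonlinearity — not that it is robust to every failure mode of plant
data.

## Reconciliation

Filtering is median-then-moving-average (median first removes spikes
before smoothing — the standard robust order; the study lists both stages
without an order). A 20-minute window at 5-minute sampling is 4 samples,
rounded up to 5 for a centred window. Edge windows shrink symmetrically,
so the output exists at every grid point and never leaves the local
min–max envelope of its input window.

## Growth-rate estimation

μ_est(t) = ln(X_t·V_t / X_{t−w}·V_{t−w})/Δt over a 20-minute window. The
estimate is reported at the window midpoint by default: a trailing label
carries a first-order bias of (w/2)·dμ/dt (~0.015 h⁻¹ mid-exponential on
logistic runs), while centring leaves only the ~2·10⁻⁴ second-order term,
which is what allows the 10⁻³ truth-recovery bound the tests enforce.
Trailing labelling is available (`center=False`). Samples with
non-positive X·V at either window end, and the half-window at each series
edge, are NaN rather than extrapolated.

## Logistic fitting

Multi-start trust-region least squares (`scipy.optimize.least_squares`,
bounds X_m > 0, λ_x ≥ 0, V_x > 0, tolerances 1e-14): one data-driven
start (X_m from the largest sample, V_x from the steepest slope, λ_x from
the crossing of X_m/(1+e²)) plus seeded ±50% jitters. A Nelder–Mead-style
search would satisfy the same contract; the least-squares solver is
simply better conditioned for a 3-parameter smooth residual. If no start
converges the error carries the best parameters found.

## Off-gas computation

The printed rate equations omit the broth volume; the implementation
divides by V to give volumetric rates (g L⁻¹ h⁻¹), which is the form the
soft sensors consume. ρ is absolute pressure, so ρ·M/(R·T) is the
pure-gas mass density — the only dimensionally coherent reading. F_out is
closed by the nitrogen balance
F_out = F_in·(100 − C_O₂,in − C_CO₂,in)/(100 − C_O₂,out − C_CO₂,out).
RQ is molar: the mass-rate ratio rescaled by M_O₂/M_CO₂, flagged NaN
(not an error) where OUR is below threshold. The feed-design equation is
used in its unit-consistent form F₀ = μ·X₀·V₀/(S_i·Y_xs).

## Neural networks

One hidden layer, tansig (≡ tanh) hidden activation, logsig output on
min-max-normalized targets; normalization constants come from the
training subset only, and values outside the fitted range pass through
unclipped. The split is random uniform 75/12.5/12.5 (rounded sizes,
remainder to training), seed-recorded. Weights start Nguyen–Widrow-style:
uniform, hidden rows rescaled to 0.7·H^(1/I).

Engines (all full-batch, analytic derivatives verified against central
finite differences at 1e-6):

* **SCG** — Møller's scaled conjugate gradient (σ₀ = 5·10⁻⁵,
  λ init 5·10⁻⁷), default 1000 epochs.
* **LM** — Levenberg–Marquardt on the residual vector with a per-sample
  backpropagated Jacobian and Marquardt-scaled damping λ·diag(JᵀJ)
  (decade decrease on accepted steps, decade increase on rejections, so
  accepted steps never raise the training error); default 300 epochs.
* **BR** — the same inner loop on β·E_D + α·E_W with MacKay evidence
  re-estimation γ = P − α·tr(H⁻¹), α = γ/2E_W, β = (N − γ)/2E_D; the
  validation subset is not used for stopping (regularization replaces
  early stopping). With α = 0 and updates off it reduces exactly to LM.

SCG and LM stop early at the validation minimum (patience 6 epochs) and
return that epoch's weights. The "training goal" of 0.001 is interpreted
as a normalized-space error (RMSE) target — engines stop at MSE ≤ goal² —
because the reported per-subset training errors at the stopping epochs
(down to 0.001) are only attainable under that reading; an MSE target of
10⁻³ would cap training at normalized RMSE ≈ 0.032. Five seeded restarts
are kept per configuration and the best by validation MSE (training MSE
for BR) is returned — the reading of "trained using 5 iterations"
consistent with stopping epochs in the tens to hundreds.

Training targets in the pipeline are the simulator's truth channels
(biomass, instantaneous μ). The original workflow, lacking ground truth,
trained on logistic-modelled or probe-calibrated biomass; with a
simulator the truth is available, holdout evaluation is against truth,
and the logistic and calibrated-probe reconstructions are still computed
as the classical comparators. Note that exact min-max target
normalization maps the extreme training samples to 0 and 1, which a
logsig output can only approach asymptotically — a structural property of
this architecture worth knowing when interpreting very small training
errors.

Model selection: grid over {SCG, LM, BR} × 1–15 hidden nodes, metrics on
the full dataset, argmin RMSE with ties broken by fewer nodes then engine
order. R² is reported as the standard 1 − SS_res/SS_tot (the printed
formula omits the "1 −"; values near 1 for good fits are only consistent
with the standard form). The growth-rate network receives the fed-batch
biomass network's prediction as an additional input (chained soft
sensor).

## Sensitivity

Garson's connection-weight decomposition with absolute values throughout
(per hidden node, each input's share of Σ|w₁|, weighted by |w₂|,
normalized across inputs) — without absolute input weights, effects could
be negative, contradicting their interpretation as non-negative shares
summing to one. Reported effects average 3 retrainings from different
seeds, renormalized, with the standard error per input.

## Baseline

Ordinary least squares via statsmodels with one-pass pruning: every term
with p > α (default 0.05) is removed simultaneously and the reduced model
refit once — matching a single reported reduced equation rather than
stepwise selection. Rank-deficient designs are rejected naming the most
collinear terms. The fed-batch comparison fits the baseline on exactly
the rows and features the network sees.

## Problem sizes

The default campaign is 6 batch + 4 fed-batch 24 h runs (289 samples per
run). The end-to-end test and the acceptance script use the scaled-down
study: 4 fed-batch runs, grid restricted to nodes {4, 6, 8} with 3
restarts (~10 s on one CPU); the full 45-cell sweep per task is available
through `PipelineConfig` defaults. Oracle and recovery checks run at the
sizes stated in their tests (20 random networks, 50 logistic replicates,
100 filter signals, 20 sensitivity experiments).

## Known limitations

* The fed-batch μ_true at feed start is discontinuous (logistic-to-Monod
  handoff with residual substrate) — visible as a growth burst, as real
  fed starts show, but the size of the burst is model-determined.
* Garson effects are weight-based, not function-based; they agree in rank
  with permutation importance on dominant-input problems (tested) but are
  not attributions in the Shapley sense.
* The MLR-vs-ANN holdout contrast depends on the generator's nonlinear
  measurement map (probe saturation, volume dependence); on a perfectly
  linear plant the two would tie.
* Tables of reference selection grids exercise `select_best` only; they
  are transcription fixtures, not outputs of this package's training.
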