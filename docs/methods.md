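# Methods

## The model

`pipnet` models EGF-stimulated turnover of the class I PI3K lipid products in a
single well-mixed compartment. State variables are EGF, inactive/active EGFR,
inactive/active PI3K, and the phosphoinositides PI(4,5)P2, PI(3,4,5)P3,
PI(3,4)P2, PI4P and PI3P, plus a constant EGF-insensitive background PI(3,4)P2
pool. Time is in seconds; concentrations are arbitrary units (a.u.) normalised
so that basal PI(4,5)P2 is 100 a.u. Measured species map onto model
observables through per-species scale factors that are global across genotypes
(identity by default, since the synthetic data are generated in model units).

Reactions (all single-substrate conversions):

| step | rate law | notes |
|---|---|---|
| EGF clearance | first order | receptor-mediated ligand depletion; the transience driver |
| EGFR activation | mass action x [EGF] | |
| EGFR desensitization | first order | |
| PI3K activation | mass action x [EGFR_active] | scaled by the inhibitor factor |
| PI3K basal activation | first order | small, gives nonzero starved PIP3 |
| PI3K deactivation | first order | |
| PI3K catalysis PI(4,5)P2 -> PIP3 | mass action x [PI3K_active] | scaled by the inhibitor factor |
| PTEN: PIP3 -> PI(4,5)P2 | mass action | 3-phosphatase recycling route |
| SHIP2, X: PIP3 -> PI(3,4)P2 | mass action | X lumps all other 5-phosphatases |
| INPP4B: PI(3,4)P2 -> PI3P | mass action | |
| PTEN: PI(3,4)P2 -> PI4P | mass action | direct PI(3,4)P2 3-phosphatase route |
| Y: PI(3,4)P2 -> PI4P | Michaelis-Menten (reference) | low-Km residual phosphatase; see below |
| PI4P synthesis | zeroth order | PI is treated as an infinite reservoir |
| PIP5K: PI4P -> PI(4,5)P2 and PI(4,5)P2 -> PI4P | first order | constitutive futile cycle buffering PI(4,5)P2 |
| PI3P and PI4P sinks | first order | close the basal source/sink balance |

Genotypes are enzyme-activity multipliers (knockout exactly 0, knockdown 0.1
residual by default). PI3K inhibition is a timed event that scales the
*effective* active-PI3K concentration: both the activation drive and the
catalytic step are multiplied by the residual fraction from the event time on.
With residual 0 this stops synthesis instantly, so the post-inhibition
PI(3,4,5)P3 trace is an exact single exponential with rate equal to the summed
first-order dephosphorylation constants — the analytic oracle the tests use.

### Why ligand depletion drives the transient

A two-state receptor that recycles (active -> inactive -> active) under a
constant ligand approaches a sustained steady state monotonically, so
first-order desensitization and PI3K deactivation alone cannot produce the
observed rise-and-fall. First-order EGF clearance is the minimal additional
mechanism: the drive rises with receptor/PI3K activation (tens of seconds) and
decays with the ligand (hundreds of seconds), placing the PIP3 peak near 1 min
and returning it toward basal by 15 min. Both first-order deactivation steps
are retained; they set the rise time.

### Why the PI(4,5)P2 futile cycle

During the strongest responses up to ~20 a.u. of PIP2 are redistributed into
PI(3,4)P2. Without a standing resynthesis flux the PI(4,5)P2 pool would sag by
that full amount for the rest of the time course, which the measured panel
does not show. A constitutive PI4P/PI(4,5)P2 interconversion cycle (standing
flux 0.5 a.u./s) buffers the pool so it dips by ~10-20% and recovers.

### Why the residual phosphatase Y saturates

The study's route quantities constrain the PI(3,4)P2-phosphatase split twice:
in wild type PTEN : INPP4B : Y carry about 57 : 37 : 6 percent of the maximal
dephosphorylation flux, and in the INPP4A/B knockdown the PTEN : Y flux ratio
is about 16 : 1. If every route were strictly first order in the shared
substrate, the two routes' flux ratio would be substrate-independent and both
statements cannot hold (57/6 = 9.5, not 16). They become jointly consistent
if Y's flux *saturates*: in the knockdown, PI(3,4)P2 rises ~1.6-fold, PTEN's
linear flux rises with it, and Y's flux plateaus at its Vmax. A quasi-steady
analysis over the attainable designs gives a joint optimum at a wild-type Y
share of ~5.6% with a knockdown ratio of ~15.5-16; the reference calibration
adopts it (Km_Y = 0.05 a.u., well below the stimulated PI(3,4)P2 excursion).
All named phosphatases remain mass-action — the linear-range form that fits
the panel best — and the fully linear and fully saturable variants of the
whole network remain available for the model comparison.

## Reference calibration

The deposited parameterization of this network is not bundled, so
`reference_parameterization()` returns the package's own calibration
(provenance `"fallback-calibration"`), constructed as follows and then frozen
in `model.DEFAULT_PARAMS`:

- **PI(3,4,5)P3 routes.** Total first-order removal lambda = 0.35 /s (half-life
  2.0 s, comfortably below the observed 5 s bound), split so that
  (SHIP2+X):PTEN = 1.4 and SHIP2:X = 2.65.
- **PI(3,4)P2 routes.** Total removal ~0.48 /s at the wild-type peak, split
  57% PTEN, 37.4% INPP4B, 5.6% Y with Y saturable as above.
- **Cascade timing.** EGF clearance 0.0052 /s, receptor activation fast
  (~10 s), PI3K layer slower (~20-30 s): the PIP3 peak lands at ~75 s (the
  1-min design sample is its sampled argmax) and the double-mutant PI(3,4)P2
  observable peaks at the 5-min sample.
- **Amplitude.** PI3K catalysis set so the wild-type PIP3 peak is ~1.1% of
  the PI(4,5)P2 pool; the PTEN-KO/SHIP2-KD double mutant then peaks ~4-fold
  higher and the INPP4A/B-KD,PTEN-KO double mutant accumulates PI(3,4)P2 to
  ~10x its own PIP3 peak and ~20% of the total PIP2 pool.
- **Basal PI3K activity.** 0.5% of the stimulated drive — small but nonzero
  starved PIP3/PI(3,4)P2, below the 5% bound adopted for it.
- **Background pool.** 5 a.u. added to the PI(3,4)P2 observable only; it
  dominates the basal PI(3,4)P2 signal, as required to reproduce basal levels
  without EGF-sensitive synthesis.

## Numerics

- **Integration.** LSODA via `scipy.integrate.solve_ivp`, rtol 1e-8 /
  atol 1e-10 a.u. for analysis (1e-6 / 1e-9 inside the fitting objective,
  where only sampled observables matter). Fast PIP3 turnover (~3 s) coexists
  with the 900 s horizon, hence the stiff-capable method. The right-hand side
  is JIT-compiled with numba when available, with an identical numpy path
  otherwise. Substrate concentrations are clamped at zero inside the kernel;
  trajectories stay above -1e-9 a.u.
- **Events.** The EGF dose and the inhibitor are applied by stopping and
  restarting the integrator at the event time; nothing is smoothed across the
  discontinuity. Splitting a run at the event time reproduces the one-shot
  trajectory to integrator tolerance.
- **Steady states.** The starved state is found by a Newton solve of the
  right-hand side in which one equation per conserved pair (receptor, PI3K)
  is replaced by the conservation constraint — the raw Jacobian is singular
  along conserved directions and an unconstrained solve can silently drift to
  a root with the wrong totals. A relaxation integration (2e5 s) is the
  fallback for poor starting guesses. Convergence requires max |d[S]/dt|
  < 1e-8 a.u./s.
- **Read-offs.** Maximal flux is the per-route maximum of instantaneous flux
  over the stimulated window [0, 900] s on the 1 s dense grid, refined by a
  local quadratic; routes sharing an enzyme are reported per substrate. The
  post-inhibition half-life is the time to fall halfway from the event value
  to the post-event plateau, taken as the post-event minimum because the
  background/basal signal persists; the crossing is interpolated linearly.
  Peak metrics use the same grid and refinement, with fold change relative to
  the t=0 observable (background-inclusive for PI(3,4)P2).

## Fitting

The objective is weighted least squares over every experiment, species, time
and replicate: w = 1/max(SD, floor)^2 with a floor of 5% of the species'
panel-wide mean, preventing near-zero-SD points from dominating. Rate
constants are global across the panel; genotypes enter only as activity
multipliers. A candidate that cannot be simulated scores a large finite
penalty (1e12) so the search continues.

Search is a genetic algorithm in log10 parameter space (bounds [-4, +2]
decades around the template magnitudes): tournament selection (size 3),
uniform crossover (rate 0.7), per-gene Gaussian mutation (rate 0.1, sigma
0.25 decades), elitism 2, log-uniform initialization; deterministic given the
seed (PCG64). Defaults are population 50 x 300 generations; the package's
standard runs use a reduced budget (population 20 x 15 generations) because
the heavy lifting is done by the refinement stage: bounded trust-region least
squares (`scipy.optimize.least_squares`, trf) started from the best few
mutually distinct GA individuals. Multi-start matters — the noisy objective
has local minima that trap a single start. The finite-difference step is set
to 1e-3 decades, well above the ODE-solver noise floor, which is essential:
steps near machine precision differentiate solver jitter instead of the
model. On noiseless panels this pipeline recovers every headline flux
quantity to <0.1%; at the replicate noise level (CV 0.15) individual seeds
recover them within ~25% and three-seed averages within ~12% — the flux
*ratios* are the identifiable quantities, individual rate constants are not
all separately determined by four time points.

Rate-law model comparison fits the fully linear and fully saturable variants
with matched budgets and compares small-sample AICc
(n ln(wRSS/n) + 2k + 2k(k+1)/(n-k-1)); the saturable variant carries one
extra parameter (a shared Km), so ties fall to the smaller model.
Uncertainty on the headline ratios comes from a residual-resampling
bootstrap: residuals are resampled within species, added back to the fitted
predictions, and each synthetic panel is refit at reduced budget; percentile
intervals are reported.

## Synthetic data

`generate_panel` mirrors the measurement design exactly: six genotypes (WT,
PTEN-KO, SHIP2-KD, INPP4A/B-KD and the two PTEN-KO doubles), EGF at t=0,
vehicle or full PI3K inhibition at 60 s, samples at 0/1/5/15 min, three
replicates, for PI(3,4,5)P3, PI(3,4)P2 and PI(4,5)P2. Replicate noise is
multiplicative lognormal, mean-preserving, CV 0.15 (replicate scatter of this
kind of response-ratio measurement is roughly constant-CV), with an additive
SD floor of 1% of the species basal; CV 0 disables noise entirely. The
generator is deterministic given the seed.

What it does **not** emulate: chromatography and peak integration, internal
standard drift, correlated biological vs technical replicate structure
(a single multiplicative term stands in for both), acyl-species composition
effects, or any mismatch between model structure and cellular reality.
Passing recovery tests therefore demonstrate identifiability of the flux
ratios *under the study design and the model's own assumptions* — not that
the model is correct for real cells.

## Problem sizes

Standard runs use the 1 s dense grid over 900 s per simulation and the
reduced fitting budget described above; a full-budget GA (50 x 300) is a
configuration change (`FitConfig(population=50, generations=300)`). The
recovery harness fits 7 free parameters to 432 data points.

## Known limitations

- Single compartment; no membrane/cytosol partitioning, no spatial gradients.
- Arbitrary units: absolute fluxes are meaningful only relative to the
  normalised pools; only ratios and shares are compared across genotypes.
- The identity and mechanism of phosphatase Y are unknown; its saturable rate
  law is the minimal kinetic form consistent with the two route-split
  constraints, not a mechanistic claim.
- Knockdown residual activity is fixed at 10% unless overridden; measured
  residuals would sharpen the knockdown predictions.
- The deposited parameterization of the original network is not vendored;
  the calibration here reproduces its reported derived quantities, not its
  individual rate constants.
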