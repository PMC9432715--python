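# Methods

## The crypt-level process

Each crypt niche is a continuous-time Markov chain over the number
*i* = 0…*N*−1 of benign cells, plus two absorbing states (ADENOMA at
*i* = *N*, CARCINOMA on the first malignant daughter).  Replacement events
occur at total rate *N*λ — each stem cell is replaced at rate λ per year,
the standard Moran convention and the one matching the reported units of λ
(y⁻¹ per stem cell).  At an event a dividing cell is chosen uniformly; the
daughter inherits the parent's type unless it mutates (wild-type → benign
with probability *u*, benign → malignant with probability *v*; at most one
mutation per division), and replaces a competitor chosen uniformly from the
other *N*−1 cells (well-mixed) or from the parent's two ring neighbours
(linear ring).  Self-replacement is excluded.  Modelling choices:

- **Tunneling is instantaneous.**  The first malignant daughter absorbs the
  niche into CARCINOMA.  Malignant-vs-rest competition is not modelled; for
  the small *N* of a colonic crypt the effective λ absorbs the omitted
  delay.
- **ADENOMA is absorbing.**  Post-fixation mutation and growth kinetics are
  outside the model; progression to adenocarcinoma enters only through the
  tissue-level probability γ.
- **Strict two-step sequence.**  No direct wild-type → malignant mutation.
- **Ring topology** uses a periodic ring (no boundary special cases) and a
  single-contiguous-clone reduction in the master equation: while a benign
  clone exists, new wild-type → benign mutations are suppressed.  At
  physiological mutation probabilities (~10⁻⁶ per division) the expected
  number of clone arrivals per crypt lifetime is ≪ 1, so the reduction is
  exact for practical purposes; the cell-level simulator makes no such
  assumption and validates it (agreement within Monte-Carlo error even at
  exaggerated u = v = 10⁻³).

Transition rates from transient state *i* (per year):

- well-mixed: *i*→*i*+1 at λ[(1−*v*)*i*(*N*−*i*) + *u*(*N*−*i*)(*N*−*i*−1)]/(*N*−1);
  *i*→*i*−1 at λ(1−*u*)(*N*−*i*)*i*/(*N*−1); *i*→CARCINOMA at λ*iv*.
- ring: 0→1 at *N*λ*u*; *i*→*i*±1 at λ(1−*v*) / λ(1−*u*) for 1 ≤ *i* ≤ *N*−1;
  *i*→CARCINOMA at λ*iv*.

## Solving the master equation

The transient block is tridiagonal with positive off-diagonals whenever
0 < *u* < 1 and *v* < 1.  A diagonal similarity transform makes it
symmetric, so `scipy.linalg.eigh_tridiagonal` yields an exact spectral
representation (all eigenvalues real and strictly negative): absorption
probabilities are sums of `expm1(w·λt)/w` terms and their fluxes are the
matching exponential sums, evaluable at arbitrary ages in one vectorised
pass.  This was chosen over ODE integration because it is exact to machine
precision, trivially satisfies probability conservation, and — since the
generator is proportional to λ — one decomposition of the unit-rate chain
serves every trial λ during calibration (the time-rescaling identity
P(λ, t) = P(1, λt) holds exactly).  Degenerate parameters (*u* ∈ {0, 1} or
*v* = 1) fall back to stepwise matrix exponentials of the full generator,
likewise exact for a time-homogeneous chain.  Fluxes are always computed
analytically (occupancy × absorption rate), never by finite differencing.

Default grid: 0–90 years in 0.25-year steps (361 points); absorption
quantities are smooth, and all fitting evaluates the solution directly at
the requested ages, so the grid only matters for exported curves.

## The Monte-Carlo referee

`simulate_niche` is an exact event-driven simulation of the full cell-level
process (every cell typed individually; multiple clones allowed in either
topology).  Because the total event rate *N*λ is independent of the niche
state, the number of events in a horizon is Poisson(*N*λ*T*) per replicate
and the embedded discrete chain is advanced synchronously across
replicates as a vectorised loop.  Identical seeds give identical output.
The master-equation solver and the simulator share no code path beyond the
parameter container, making their agreement a genuine cross-validation.

## Tissue level

S(t) is evaluated as exp(*K*·log1p(−(*P*c + γ*P*a))) to stay accurate with
per-crypt probabilities ~10⁻⁸ raised to the ~10⁷-th power, and
R = *K*(d*P*c + γd*P*a)/(1 − *P*c − γ*P*a) from the analytic fluxes.  Rates
are reported per 100,000 person-years (scale 10⁵) to match registry
convention.  The pathway decomposition uses R_tunnel = *K*·d*P*c/(1 − *P*c)
and R_seq = *K*γ·d*P*a/(1 − γ*P*a); note (1−*P*c)(1−γ*P*a) ≥ 1−*P*c−γ*P*a,
so R_tunnel + R_seq ≤ R with equality to first order in the (small)
per-crypt probabilities.  The crossover age is located by linear
interpolation at the sign change of R_tunnel − R_seq; grid points where
both hazards are below 10⁻⁹ of their maximum are ignored so that the exact
zeros at t = 0 cannot fake a crossing.  Lifetime fractions default to
*T* = 85 y.  γ*P*a is an upper limit for sequential progression (adenomas
may regress or turn malignant during growth), so the reported crossover age
is a lower bound; this caveat is documented, not modelled.

## Incidence preprocessing

Registry-style tables carry eighteen 5-year age groups; rates attach to
group midpoints (age_lo + 2.5), and the open 85+ group is dropped before
fitting.  95% intervals use exact Poisson quantiles of the expected count
under the US Standard population 2000 (embedded as a packaged TSV; 19
census strata collapsed to 18 groups), rescaled to rates;
σ = (CI width)/(2·1.96) feeds the χ² weights.  Zero-count groups get a
one-sided σ from the exact 97.5% Poisson upper bound (−ln 0.025 counts) so
weights stay finite.  The screening adjustment multiplies rates (and
counts, for internal consistency) of groups with age_lo ≥ 55 by 4/3 —
compensating the ~25% incidence reduction attributed to colonoscopy
screening at older ages — and both the factor and the age threshold are
arguments, so alternative adjustments (including none) are one-line
changes.  "Above 55" is interpreted as groups starting at 55 (55–59 and
older).

## Calibration

χ² = Σ((model − rate)/σ)² over the 17 prepared groups, all of which enter
the fit (including the youngest, whose observed registry value is known to
sit below model predictions).  The σ definition is configurable —
`poisson_ci` (default), `sqrt_mu`, or `log_rates` — because the objective
is not uniquely pinned down by registry practice; alternative weightings
shift the fitted λ only by O(1) factors.  λ is fitted by a bounded Brent
search on log λ in [10⁻⁴, 10] y⁻¹ (wide enough to contain both the
effective 0.01–0.06 range and the physiological 0.3–2.0 range), tolerance
10⁻⁴ on the log scale; results at a bound are flagged.  The ensemble scan
takes {low, expected, high} for each of K, u, v, γ and every integer
N in [5, 15] (3⁴ × 11 = 891 fits), filters at χ² ≤ 100 × min χ² (the
threshold is an argument), and reports mean ± sd of λ, N and the lifetime
fractions evaluated at T = 85 per kept member.  One unit-rate spectral
decomposition per (N, u, v) is cached across the scan, so the full 891-fit
ensemble completes in seconds.  Organ presets: colon
(K = 1–2 × 10⁷), gastric (K = 4–16 × 10⁶, exemplar N = 7), rectum
(K = 1–2 × 10⁶); mutation, γ and N ranges are shared across organs.

## Synthetic data

`generate_incidence` emulates the statistical structure the analysis
assumes: counts per age group Poisson-distributed around
R(midpoint) × person-years.  The default person-years schedule follows the
US-2000 standard-population shape scaled to 10⁸ person-years total — a
registry-scale at-risk population chosen so that group counts range from
~10 (youngest) to ~10⁴ (oldest), reproducing the registry's relative
precision per group.  It does not emulate secular trends, birth cohorts,
screening dynamics, or true US person-years; passing recovery tests
therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to real-world trend artefacts.  Seeds: a master
seed spawns per-replicate streams via `numpy` SeedSequence; identical seeds
give identical tables.  Noise-free tables set counts to their expectations
(non-integer) and still carry Poisson-CI σ so χ² stays defined.

## Problem sizes in the shipped checks

Monte-Carlo cross-validation uses 10⁵ replicates per parameter/topology
combination (N ∈ {5, 8, 15} × both arrangements, u = v = 10⁻³, λ = 1/y,
horizon 10 y) against a 3-standard-error band; recovery experiments use 50
Poisson replicates at the default 10⁸ person-years schedule; the ensemble
check runs the full 891-fit scan twice.  These sizes keep each check's
Monte-Carlo error well below the tolerance it asserts.

## Known limitations

- No fitness differences between wild-type and benign cells (neutral
  competition), no more than two mutational steps, no crypt fission or
  post-fixation growth kinetics — all by design; λ is an *effective* rate
  that absorbs the omitted time scales, which is why fitted values
  (~0.01–0.06 y⁻¹) sit far below physiological replacement rates
  (0.3–2 y⁻¹).
- The two spatial arrangements are limiting cases.  At a *fixed* λ their
  per-crypt probabilities differ substantially in the short-time regime
  (λt ≲ 1.5) because the well-mixed chain's interior transition rates
  exceed the ring's; after each arrangement receives its own calibrated λ,
  their predicted incidence curves agree closely at the ages carrying the
  fit weight (within ~10% above age 40, within a factor ~2 at the sparse
  youngest ages).
- Fitted-λ benchmarks for real registry extracts require the user to supply
  their own table; the package validates the calibration machinery through
  synthetic-data recovery instead.
- Ensemble "±" values are standard deviations over the kept ensemble.
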