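# Methods

## Model

The Balloon model couples neuronal input u(t) to the BOLD signal through
four dimensionless states x = [f, s, q, v] (flow, flow-inducing signal,
deoxyhemoglobin, venous volume), written as first-order ODEs with s = ḟ.
The resting point (1, 0, 1, 1) is an exact fixed point of the
implementation: the oxygen-extraction ratio is evaluated as
(1 − m^{1/f})/(1 − m) with m = 1 − E₀, which is exactly 1 at f = 1 in
floating point, so resting derivatives and the resting BOLD signal are
bit-exact zeros rather than ~1e−16 residues.

The observation y = V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v)) uses the 1.5 T
coefficient calibration k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2.  No other field
strength is supported.  k₁ and k₃ are recomputed from the *current* E₀ on
every evaluation, so a filter that revises its oxygen-extraction estimate
immediately sees consistent observation weights.

Seven parameters with independent normal priors:

| parameter | meaning                    | prior          | filtered? |
|-----------|----------------------------|----------------|-----------|
| ε         | neuronal efficacy          | N(0.54, 0.1²)  | yes       |
| τ_s       | signal decay [s]           | N(1.54, 0.25²) | yes       |
| τ_f       | autoregulation [s]         | N(2.46, 0.25²) | yes       |
| τ_0       | venous transit time [s]    | N(0.98, 0.25²) | yes       |
| α         | stiffness exponent         | N(0.33, 0.045²)| fixed     |
| E₀        | resting O₂ extraction      | N(0.34, 0.1²)  | yes       |
| V₀        | resting volume fraction    | N(0.02, 0.005²)| fixed     |

V₀ multiplies the whole observation, so it cannot be estimated jointly
with the bracket's contents; α only modulates the degree of BOLD
nonlinearity.  Both are held at their prior means (configurable).

## Numerics

* **Integration.** Classical fixed-step RK4 with dt_sub = 0.1 s (20
  substeps per TR = 2 s), zero-order hold on u within each acquisition
  interval.  The dynamics are smooth and nonstiff; the suite verifies the
  empirical convergence order ≈ 4 on the stimulated trajectory.
* **Positivity.** f, q, v are floored at 1e−6 after every substep and
  after every sigma-point propagation, keeping v^{1/α} and (1−E₀)^{1/f}
  defined even for adventurous sigma points.  Floor hits are counted in the
  run diagnostics.  On plausible parameter draws (within 2 prior SDs) the
  floor is never touched.
* **Sigma points.** Scaled unscented transform with α_ut = 1, β_ut = 2,
  κ_ut = 3 − L.  This makes the composite spread L + λ equal 3 for every
  dimension, which has a convenient corollary: for additive noise the
  noise-augmented formulation (sigma points over [x, v, n] with
  block-diagonal covariance) and the plain formulation produce identical
  moments, and the suite checks they agree over a whole filtering run.
  The matrix square root is a lower Cholesky factor; if factorization
  fails, diagonal jitter 1e−9·tr(P)/L is added and escalated tenfold up to
  three times before a conditioning error is raised.  Covariances are
  re-symmetrized after every update, and the innovation covariance is
  inverted through a Cholesky solve, never explicitly.
* **Parameter projection.** The free parameters are filtered in natural
  units and clipped to a validity box (ε ∈ [1e−3, 5], time constants ∈
  [0.05, 20] s, E₀ ∈ [0.01, 0.99]) wherever a sigma point or posterior
  mean would leave it; clips are idempotent and counted.  A log-space
  option exists behind a flag and performs comparably on the synthetic
  protocol.

## The dual filter

Per acquisition, state filter first (the reverse order is available and
gives near-identical results):

1. **State filter** — predict by integrating each state sigma point one TR
   under the current parameter mean; update against y_k with the BOLD
   observation at the current parameter mean.
2. **Parameter filter** — random-walk time update (covariance + R_r), then
   a measurement update through G(x̂_{k−1}, w): integrate the previous
   state estimate one TR under each parameter sigma point and observe.

No state–parameter cross-covariance exists anywhere in this scheme — the
result type carries a 4×4 and a 5×5 covariance and nothing else.

**Noise treatment.** Because each filter conditions on the other's point
estimate, each one's innovation contains variability the measurement-noise
variance R alone does not explain.  Two devices address this:

* *Cross-inflation:* the state filter adds to R the observation variance
  induced by the current parameter spread (read off the parameter filter's
  last sigma set), and the parameter filter adds the state-induced
  variance (read off the state filter's innovation covariance).  These
  terms are exact in the linear case — the suite's bridge test shows that
  with them, a joint filter whose cross block is forcibly zeroed reduces
  exactly to the dual pair on a linear toy model.
* *Tempering:* the parameter filter's measurement noise is additionally
  scaled by `param_r_scale` (default 30).  The scalar BOLD signal
  identifies the response *amplitude* much faster than it separates the
  parameters that produce it (ε, E₀ and τ_0 trade off within one block);
  an untempered parameter filter absorbs the first block's amplitude
  mismatch into whichever parameter has the steepest local gradient —
  E₀ — overshoots it, and collapses its variance before the shape
  information of later blocks arrives.  Tempering by ~30 spreads one
  block's evidence over several blocks, after which all five parameters
  move coherently toward the generating values.  Setting it to 1 restores
  the untempered update.

Defaults elsewhere: initial state belief at rest with covariance 1e−2·I;
initial parameter belief at the prior means and *prior variances* (the
stated parameter uncertainty, not a token value); Q = 1e−6·I per TR on the
states; R_r = 1e−4 × the prior variances per scan (optional exponential
annealing behind a flag).  The observation-noise variance R should match
the data; the simulator's sidecar records the injected value.

## The joint filter

One UKF over [x; w] ∈ ℝ⁹ with block covariance [P_xx P_xw; P_wx P_ww].
The transition integrates the state block under each sigma point's *own*
parameter block (identity on the parameter block) with process noise
blockdiag(Q, R_r); the update evaluates the observation with each sigma
point's own E₀.  The cross block P_xw starts at zero, acquires mass as
soon as stimulation couples the blocks, and is what lets single-scan noise
move the parameter estimates — the origin of the joint filter's larger
post-convergence parameter fluctuations, which the suite quantifies as
post-first-block total variation on shared seeds.

## Synthetic data

The generator emulates an auditory block paradigm: 136 scans at TR = 2 s,
an 8-scan rest lead-in, then 16 alternating 8-scan blocks starting with
rest (the lead-in closes the gap between 136 acquisitions and 16×8 = 128
block scans; it is an assumption, configurable).  Truth parameters default
to the prior means.  Process noise (off by default) enters the states
after each RK4 substep as sd·√h·N(0,1); observation noise is per-scan
Gaussian, with an option to set its SD as a fraction of the clean peak
(the recovery study uses 10 %).  A seed fully determines the output, to
the byte.

What the generator does **not** emulate: scanner drift, motion,
physiological aliasing, event-related designs, multi-voxel structure, or
any mismatch between the generating model and the filter's model.  Passing
recovery tests therefore demonstrate correct and stable estimation under a
well-specified model at realistic noise, not robustness to the confounds
of real fMRI.

## Cost accounting

Sigma-point generation requires a Cholesky factorization of the L×L
covariance each cycle — the only cubic operation in the UKF — charged at
L³/6 flops.  Dual filtering pays two factorizations per scan (4×4 and 5×5
plain; 9×9 and 11×11 augmented, where the augmented dimension is
L + L_v + L_n), joint filtering one (9×9 plain, 19×19 augmented; its
single cycle per scan, versus dual's two, is exactly this one-vs-two
charging).  Joint exceeds dual by 285.7 % (plain) and 233.0 % (augmented),
so comfortably above 56 % in both modes; the advantage is structural,
since (a+b)³ > a³ + b³ for any positive split.

## Study sizes

The recovery study runs 20 seeded datasets of 136 scans each and fits the
dual (and, for the stability comparison, joint) filter with the parameter
belief initialized one prior SD above the truth; the acceptance script
reports the across-seed mean final ε and τ_0.  These sizes match the
paradigm the generator emulates and keep the full suite fast.  Smaller
CLI round-trip tests use a 4-block design.

## Known limitations

* τ_0 and τ_s are weakly identified by one-step innovations at TR = 2 s:
  their posteriors move in the right direction but remain prior-dominated
  after 136 scans.  Longer runs or richer designs would sharpen them.
* The tempering constant is a heuristic; a fully adaptive (innovation-
  based) parameter-noise estimate is out of scope.
* The 1.5 T observation coefficients are the only calibration provided.
* Filtering assumes the input train u is known; deconvolving u is not
  attempted.
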