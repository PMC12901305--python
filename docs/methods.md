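# Methods

## Model and assumptions

The occupant is a linear lumped-parameter system: rigid segment masses
with one vertical coordinate each, connected by massless linear
spring–damper couplings, excited by a harmonic seat displacement. The
bundled seated-female topology has 10 segments — a trunk chain
head(1)–thorax(2)–abdomen(3)–pelvis(4) grounded to the seat through the
pelvis coupling (k₄, c₄), plus two arm branches
thorax–upper-arm–forearm–hand. Only vertical motion is modelled; posture
is fixed; all elements are linear, so responses are independent of the
excitation amplitude and the frequency domain fully characterizes the
system.

System matrices are assembled from the coupling list with the standard
two-sided stencil (+k on both diagonals, −k off-diagonal, likewise for
c); the seat coupling contributes only to the diagonal of the pelvis row,
with the seat motion entering through the forcing vector
(k₄ + jωc₄)Z₀e₄. By construction K and C are exactly symmetric and every
row sums to zero except the pelvis row, which sums to the seat
stiffness/damping — properties the test suite checks on randomly
generated chain/branch topologies.

## Biodynamic responses and conventions

STHT = Z₁/Z₀. The transmitted seat force is
F = (k₄ + jωc₄)(Z₀ − Z₄). Apparent mass is force per driving-point
acceleration, AM = F/(−ω²D), and impedance DPMI = jω·AM, which makes the
identity |DPMI| = 2πf·|AM| exact at every grid point and gives the
textbook limits AM(f→0) = Σm (Newton's second law for the quasi-static
body) and STHT(f→0) = 1.

The denominator motion D is the seat displacement Z₀ by default. The
alternative reading — pelvis motion Z₄ — is exposed as
`driving_point="pelvis"`; the two coincide quasi-statically (Z₄ → Z₀ as
f → 0) but differ substantially around resonance, where the pelvis
moves out of phase with the seat. The seat convention is the default
because the driving point physically is the seat–body interface and the
convention matches the apparent-mass literature.

Frequencies are external in Hz, internal in rad/s. The default grid is
0.5–20 Hz in 0.1 Hz steps (196 points): the band where seated humans are
most vibration-sensitive. ω = 0 is never evaluated; the lowest grid
point is strictly positive, so the system matrix is never singular for a
grounded model.

## Constraints and projection

The constrained female parameter set satisfies: Σm = 54 kg;
m₅=m₈, m₆=m₉, m₇=m₁₀ and the same pairings for k and c (sagittal
symmetry of the arms); 100 < k < 300000 N/m; 500 < c < 4000 N·s/m.
Single masses are additionally clipped to [0.1, 54] kg — a floor the
source constraints leave unstated but which prevents non-physical
near-zero segments. Projection order is symmetry-averaging → bound
clipping → multiplicative mass rescale; the clip/rescale pair iterates
to a fixed point so projection is idempotent, and the rescale runs last
so the mass sum holds exactly (to float precision) on output.

## Calibration

The objective is the weighted sum over grid points of squared magnitude
errors in STHT, DPMI and AM, equal weights by default. Phases are not
fitted: magnitude curves are what measurement campaigns report.
`N` in the goodness-of-fit formula is the number of grid points.

Because DPMI magnitudes are O(10³) N·s/m while STHT is O(1), the literal
objective is dominated by DPMI. `ObjectiveSpec(normalize=True)` divides
each response's residuals by the mean of its target curve, making the
three responses commensurate; this is the recommended (and the package's
own) setting for recovery experiments, while the literal unnormalized
form remains the default for comparability.

The optimizer is the canonical firefly algorithm: positions live in the
unit hypercube spanned by the bound box; dimmer fireflies move toward
every brighter one by β₀e^{−γr²}(x_j − x_i) plus a random step
α·U(−0.5, 0.5) per coordinate; the current best performs the random walk
alone. Defaults: swarm 100, 50 iterations, β₀ = 1, γ = 0.8, α = 0.2
(fixed — no decay schedule), seeded `numpy` Generator throughout, so
identical seeds give bit-identical runs. Every candidate is projected
through the constraint set *before* evaluation, so all iterates are
feasible and the final mass sum is exact. The best-so-far objective is
recorded per iteration, hence the history is non-increasing.

Stopping: the iteration budget, or earlier once the per-iteration
improvement of the best objective stays below the tolerance (default
10⁻⁴) for 5 consecutive iterations. A single sub-tolerance iteration is
not treated as convergence because a stochastic best-so-far search
routinely produces isolated zero-improvement sweeps long before it has
converged; with the patience window, typical runs on noiseless targets
stop after 8–20 iterations.

### Convergence limits

With fixed α = 0.2 the random walk injects a per-coordinate perturbation
of ≈6% of each bound range at every move. This keeps the swarm
exploring, but it also sets a stochastic floor on the achievable
objective: near the optimum, attraction steps vanish while the jitter
does not, so the best curve mismatch plateaus around ~1% RMS per
response (normalized objective ~0.03–0.3 depending on seed). Recovery is
therefore judged on the response curves — weighted goodness of fit ε̄,
reliably ≥ 0.95 on noiseless targets — not on driving the objective to
zero or on matching individual parameters, which are only weakly
identifiable from magnitude curves (near-degenerate directions in
parameter space leave the curves essentially unchanged).

## Goodness of fit

ε = 1 − √(Σ(τe−τp)²/(N−2)) / (Στe/N): one minus an RMS residual (with an
N−2 denominator, hence the ≥3-point grid requirement) over the mean
target level. ε is scale-covariant, equals 1 only for identical curves,
and is deliberately not clipped below. The combined ε̄ is the convex
weighting of the three per-response values; with equal weights it is
their arithmetic mean. The report's `variance` field is the sample
variance (N−1 denominator) of the three ε values — the population
variant differs only by the 2/3 factor and the choice is recorded here
because published tables round too aggressively to distinguish them.
Values are stored on the 0–1 scale and multiplied by 100 only for
display.

## Synthetic targets

The generator produces target curves from a known constrained parameter
set via the forward model, optionally multiplied pointwise by
independent lognormal factors with unit median and chosen coefficient of
variation (σ² = ln(1+CV²)). Multiplicative lognormal noise is used
because magnitude curves are positive and measurement error scales with
level. The bundled ground truth combines the published iteration-1
segment masses (the row whose sum matches the 54 kg constraint) with
mid-bound stiffness (150050 N/m) and damping (2250 N·s/m); it is a
synthetic, illustrative parameter set — its STHT peak of 2.42 at 5.4 Hz
falls in the 3–6 Hz band reported for seated humans, but it is not a
calibrated model of any measured subject. What passing recovery tests
show is that the *pipeline* (forward model → objective → constrained FA
→ GOF) closes the loop on data of the right shape and scale; they do not
validate the model against real female subjects, whose curves include
multi-axis coupling, posture effects and inter-subject variability that
the generator does not emulate.

## Sensitivity

The announced sensitivity analysis is operationalized as one-at-a-time
perturbation: each of the 30 parameters is scaled by 1+fraction, the
constraint set is re-applied (default; disable for a pure
ceteris-paribus derivative), and the relative change of each peak
magnitude plus the shift of each peak frequency is tabulated. With
re-projection on, symmetric arm parameters necessarily produce identical
rows and a mass perturbation redistributes through the sum constraint —
the feasible-model reading of sensitivity. Results are deterministic.

## Modal analysis

Natural frequencies come from the real symmetric generalized
eigenproblem Kφ = ω²Mφ (`scipy.linalg.eigh`), reported in Hz, ascending.
Damping is ignored — "natural frequency" here means the undamped value,
and complex damped modes are out of scope. Mode shapes are normalized to
unit maximum absolute entry with positive sign at the dominant
component, since eigenvector scale is otherwise arbitrary; comparisons
should be made up to scale. An ungrounded system (seat stiffness
removed) reports its rigid-body mode as exactly 0 Hz via a relative
eigenvalue snap tolerance of 10⁻⁹.

## Numerical choices and degenerate inputs

- Frequency sweeps batch all grid points into one stacked complex solve.
- Peak finding takes the first (lowest-frequency) grid argmax on ties.
- Grids need ≥3 points (the GOF denominator), strictly increasing, all
  positive.
- Non-finite parameter vectors, non-positive masses, duplicate seat
  couplings, disconnected segments and mismatched grids are rejected
  with specific messages.
- Test and example problem sizes (196-point grids, swarm 100, ≤50
  iterations, ~2100 objective evaluations per calibration) keep a full
  pipeline run in seconds while using the full default configuration.

## Known limitations

Single-axis vertical motion only; linear elements only; no seat-cushion
or backrest submodel; no time-domain or random-vibration (PSD) input; no
damped complex modes; parameter identifiability from magnitude curves is
limited, so calibrated parameter values should be interpreted as one
member of a near-equivalent family reproducing the curves.
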