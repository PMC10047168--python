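# Methods

## Model class

A model is M states with a rate function π(x): entry (i, j) is the rate of a
particle hop j → i, a function of the density vector x = n/N only (never of N
itself). N particles move one at a time (one-step process: after every hop
the rates are updated before the next hop), so the network state
n = (n₁,…,n_M), |n| = N, performs a continuous-time Markov jump process on
the simplex lattice. Time is rescaled by 1/N throughout: the hop n → n − e_j + e_i
has propensity π_ij(n/N)·n_j. This rescaling leaves stationary distributions
untouched and makes deterministic time scales O(1); all relaxation rates are
reported in rescaled time.

The deterministic (N → ∞) dynamics is dx/dt = −L(x)x with the graph
Laplacian L(x) = diag(d(x)) − π(x), d_k = Σ_i π_ik. Its fixed points are the
self-consistent densities p(x\*) = x\*, where p(x) is the null
right-eigenvector of L(x) normalized to sum 1.

## The Random Walk Approximation

ρ_RWA(n) = C(N)·N!·∏_k p_k(n/N)^{n_k}/n_k!, with p evaluated at each lattice
state's own density (boundary states included — boundary densities are valid
simplex points) and C(N) fixed by exact summation over the lattice. All
products are computed in log space via log-gamma: N! overflows double
precision near N = 171 while N = 205 must work. Conventions: 0·log 0 = 0;
p_k = 0 with n_k > 0 gives that state probability zero (log-weight −∞), not
an error.

Exact summation for C(N) (rather than a perturbative estimate) removes one
approximation layer at negligible cost for the lattice sizes of interest;
empirically log C(N) stays O(1) and moves weakly with N (toy model, α ≤ 0.6,
N = 50…400: within a band of width < 1).

Error model: the ℓ1 residual of the RWA under the master-equation generator
is of order ‖∂p/∂x‖ at the stable critical point and independent of N. Both
facts are checked empirically (residual/‖∂p/∂x‖ within a factor 10 across
the toy model's parameter range; residual flat in N to within ~10%).

### Modes, spurious modes, bifurcation

A critical point is stable while every eigenvalue of ∂p/∂x has real part
below 1 (strict, with a 1e-9 guard band; values within the band are flagged
"marginal"). An eigenvalue crossing 1 is simultaneously the deterministic
bifurcation (δ_ik − ∂p_i/∂x_k becomes singular) and the point beyond which
the RWA may acquire stationary points that the true dynamics does not have.
`mode_check` therefore enumerates all local maxima of the RWA over the
process's own one-step moves and flags as **spurious** every mode whose
density is farther than 2/N (∞-norm) from any self-consistent critical
point. No repair is attempted — the RWA past the bifurcation is reported as
it is. Concretely, for the bistable PdPC at v2 = 3.04, N = 205 the dominant
RWA modes are a mirror pair genuinely displaced from the deterministic
critical points (the probability at the lattice state nearest x₂\* is ~12%
below the peak), with additional small ridge maxima near the unstable
symmetric point; the detector reports all of them.

### Jacobian of p

p is only defined on the simplex, so derivatives are central finite
differences along simplex tangents: coordinate i is incremented and a
reference coordinate decremented (h = 1e-6), keeping Σx = 1. The reference
coordinate is the middle (B) state for 3-state models, the last state
otherwise; its row of the matrix is identically zero, which adds a harmless
zero eigenvalue (the stability threshold is at 1). The returned matrix has
entry (i, k) = ∂p_k/∂x_i; all stability tests use eigenvalues, which are
transpose-invariant, so the convention cannot affect results. Steps that
would leave the simplex (critical points on the boundary) raise a dedicated
error and such points are classified as not-stable with NaN eigenvalues.

### Critical-point search and bifurcation scans

Fixed points of x ↦ p(x) are found by multi-start root finding (scipy hybr)
in reduced coordinates (the reference coordinate eliminated via Σx = 1),
from a fixed interior grid plus seeded Dirichlet draws; roots are accepted at
ℓ1 self-consistency residual < 1e-9 and deduplicated at ‖Δx‖∞ < 1e-6.
`bifurcation_scan` follows one branch by continuation (each grid point's
search starts from the previous solution), records the largest real
eigenvalue of ∂p/∂x, and refines the first crossing of 1 by bisection to
1e-6 in the parameter. Following the branch (rather than re-searching
globally) keeps the indicator attached to the symmetric point that actually
loses stability.

For 3-state chain topologies (no direct A↔C hops) p has the closed form
p ∝ (π_AB·π_BC, π_BA·π_BC, π_CB·π_BA), used both scalar and vectorized over
the whole lattice; the generic path solves the dense eigenproblem for the
smallest-magnitude eigenvalue, sign-fixes, clips negatives below 1e-12 and
renormalizes (Perron–Frobenius guarantees a nonnegative null vector for
strongly connected graphs). A degenerate null space raises a
disconnected-graph error. Closed form and eigensolve agree to 1e-10 on
random simplex points (tested).

## Exact solvers

**Generator.** Sparse CSC matrix W over the lexicographically ordered
lattice (lex on (n₁,…,n_{M−1}), n_M implied): for every ordered pair (i, j)
and state with n_j ≥ 1, rate π_ij(n/N)·n_j into column n, row n − e_j + e_i;
diagonals balance columns to zero at machine precision.

**Null-space solve.** One row of Wρ = 0 is replaced by the normalization
constraint and solved by sparse LU, then polished by inverse iteration with
a tiny diagonal shift until the ℓ1 residual stops improving. Residuals reach
~1e-13 even on the 21321-state N = 205 lattice.

**Time integration.** Adaptive RK5(4) (Dormand–Prince, scipy `RK45`) on
dρ/dt = Wρ in chunks, stopping at ‖Wρ‖₁ < 1e-9. The stop threshold sits just
above the double-precision residual floor of explicit integration at these
sizes (empirically 2–8e-10); the induced distribution error,
≈ residual/spectral gap, is far below the 1e-6 solver-equivalence tolerances
used in validation. Probability drift is monitored (stays < 1e-9 per chunk)
and renormalized. Default initial condition in the CLI is uniform (symmetric,
biases no basin). The integrator also records an (time, ℓ1-distance-to-final)
trace for relaxation analysis.

**Gillespie.** Standard continuous-time algorithm with propensities
recomputed after every event (the one-step assumption), exponential waiting
times from a seeded PCG64 generator, and *time-weighted* occupancy collected
after a burn-in; runs are bitwise reproducible per seed.

**Relaxation rates.** Fitted as −slope of log ℓ1-distance vs time on the
final decade of decay, discarding samples at the integrator noise floor
(1e-7) and falling back to the last half of the series when less than a
decade of decay is available (the case past the bifurcation, where the slow
inter-basin mode dominates). Relaxation studies start from a corner point
mass: a symmetric initial condition would not excite the slow antisymmetric
mode at all.

## System Size Expansion and linearized multinomial

The conservation constraint makes the full M×M Fokker–Planck problem
singular, so drift and diffusion are reduced to independent coordinates
((x_A, x_C) for 3-state models). The drift A̅ is assembled from the Laplacian
and its finite-difference derivatives, A̅_ij = L\*_ij + Σ_k (∂L_ik/∂x_j)x\*_k,
reduced by the chain rule for the eliminated coordinate
(A_red[i,j] = A[i,j] − A[i,ref]); a loud programmatic check verifies that
−A̅_red equals the numerical Jacobian of the reduced deterministic flow
before any Lyapunov solve. The diffusion matrix
D_ij = (1/N)[δ_ij Σ_k(π_ik x_k + π_ki x_i) − (π_ij x_j + π_ji x_i)], reduced
as a plain submatrix, is diagonal for chain topologies (A↔B hops move only
n_A, C↔B only n_C). Σ solves A̅Σ + ΣA̅ᵀ = D\* (scipy Lyapunov solver,
residual < 1e-10, D carries the 1/N); a drift eigenvalue at 0 (at the
bifurcation) raises a singular-Lyapunov error rather than returning a
meaningless covariance.

The lattice distribution evaluates the Gaussian kernel at every lattice
density and renormalizes over the lattice, which makes the continuous
normalization prefactor irrelevant and automatically accounts for boundary
truncation. In a bistable regime one component is placed per stable critical
point with equal weights — justified here by the exact A↔C symmetry of both
built-in models; models without that symmetry would need asymmetric weights,
which is out of scope and flagged. The linearized multinomial mirrors the
same mixture convention with p frozen at p(x\*).

Boundary caveat: the linear-noise 1/N variance scaling holds on the lattice
only while the Gaussian is well inside the simplex. For the PdPC at
v2 = 1.82 the A/C marginals sit ~1.7 standard deviations from the boundary
at N = 50 and the lattice variance is visibly truncated (it approaches NΣ
from below as N grows); the toy model, whose critical point is deep in the
interior, shows the clean scaling at N = 50…200.

## Metrics

ℓ1 distance Σ|p − q| ∈ [0, 2]; Jensen–Shannon divergence with base-2 logs
∈ [0, 1] (0·log 0 = 0); and its square root, the JS **distance**, which is
the scale on which headline percentage errors between stationary
distributions are quoted; covariance error ‖C_p − C_q‖_F / N (scale-free
across N since multinomial covariances grow ∝ N). Mode agreement compares
the sets of lattice local maxima (same count, pairwise within 2 occupation
steps).

## Built-in models

**Toy threshold model**: π_AB = π_CB = 1, π_BA = θ(x_A), π_BC = θ(x_C),
θ(x) = 1 − α + α(1 − x)², α ∈ [0, 1]. α = 0 is linear; the symmetric fixed
point solves x(2 + θ(x)) = 1 and destabilizes at α_c ≈ 0.8778. The generic
spectral criterion (bisection-refined) is used as the authoritative
bifurcation test for this model rather than a model-specific closed-form
condition, and the located α_c is checked against the known (0.8, 0.9)
bracket.

**Dual PdPC (sQSSA)**: x_A/x_B/x_C are the un-/mono-/double-phosphorylated
substrate fractions; the four Michaelis–Menten reactions give
π_AB = k₄v₂/(k₄k₂ + k₄x_B + k₂x_C) and companions. Defaults k₁ = k₄ = 0.1,
k₂ = k₃ = 1, v₁ = v₄ = 1, v₃ = v₂ (dimensionless concentrations and
velocities), with v₂ the control parameter. The symmetric critical point
x₁\* = (k₁v₂, k₂v₁, k₁v₂)/(k₂v₁ + 2k₁v₂) always exists; when
[v₂ − v₁(1+k₂)]² ≥ [2k₁v₂]², v₂ ≥ v₁ and v₂ ≥ v₁(1+k₂) all hold, a mirror
pair (x₊, b, x₋)/(x₋, b, x₊) appears with b = k₂v₁/(v₂ − v₁) and x₊, x₋ the
roots of s² − Ss + P = 0, S = (v₂ − v₁(1+k₂))/(v₂ − v₁),
P = (k₁v₂/(v₂ − v₁))². This quadratic is derived directly from the
stationarity conditions of the reduced flow; its discriminant S² − 4P
reproduces exactly the first bistability inequality, which cross-confirms
the derivation, and a discriminant within 1e-12 of zero is treated as the
bifurcation point itself. The closed-form
threshold v₂ = v₁(1+k₂)/(1 − 2k₁) = 2.5 at defaults agrees with the
spectral scan to 1e-3.

## Problem sizes and determinism

The reference comparisons use the sizes at which the reference values are
quoted: N = 205 for lattice maxima (21321 states) and N = 200 for JS errors;
validation and property tests run at N ≤ 200 with most at N ≤ 100. Sweeps
and the acceptance script are deterministic given the seed, which feeds the
multi-start searches and the Gillespie sampler (derived seeds stay below
2³¹). Monte Carlo validation uses 10⁶ events (ℓ1 sampling error ≈ 0.04 on
the 5151-state toy lattice at N = 100).

## What the built-in models do and do not probe

Both fixtures are 3-state chain topologies with an exact A↔C exchange
symmetry and smooth, strictly positive rates on the simplex interior.
Passing tests therefore demonstrate the machinery on symmetric pitchfork
bifurcations with at most two stable states; they do not exercise asymmetric
mixtures, M > 3 graphs (supported by the generic code paths but only
unit-tested), graphs with direct A↔C links (generic eigensolve path),
time-dependent rates or unbounded state spaces (out of scope).

## Known limitations

* The RWA past a bifurcation may have displaced or spurious modes; the
  package detects and reports them but cannot repair the ansatz.
* The SSE is undefined exactly at the bifurcation (singular Lyapunov) and
  degrades when Gaussians overlap or hit the simplex boundary.
* The null-space solver requires an irreducible chain; absorbing or
  disconnected lattices raise errors rather than returning partial answers.
* Gillespie is a pure-Python loop: fine at 10⁶ events, not intended for
  10⁸-event production sampling.
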