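# Methods

`kinmap` estimates state-to-state kinetics of a metastable system from a
discretized collective-variable (CV) trajectory, and embeds the same
trajectory with diffusion maps. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic fixtures
do and do not establish.

## State discretization

Metastable states are *cores*: disks of radius r around printed centers in
CV space (the bundled three-state definition places them at (−3, 0),
(3, −5), (2, 2) with r = 1.4, the folded / misfolded / intermediate layout
of a chignolin-like 2-D landscape). Frames outside every core carry the
reserved label −1 ("unfolded"). Conventions:

* **Boundary inclusive** (distance ≤ r is inside): makes the measure-zero
  boundary deterministic.
* **Disjointness enforced at construction** (center separation strictly
  greater than the radius sum) rather than first-match tie-breaking:
  silent tie-breaking hides configuration errors.
* Plain Euclidean metric in CV units, the same metric the diffusion-map
  kernel uses.

## Markov state model

With lag τ (in frames), the counting matrix N_ij accumulates every sliding
pair (t, t+τ); T_ij = N_ij / Σ_j N_ij. Sliding (rather than strided)
counting maximizes counts; both conventions are statistically consistent,
and strided counting can be recovered by pre-striding the label sequence.
Unassigned frames enter as an explicit extra state by default (they are
real dynamics, and dropping them silently biases passage counts through the
unfolded region); they can be excluded via `include_unassigned=False`.

Counts are used raw: no detailed-balance symmetrization (non-reversibility
in finite data is informative) and no pseudocounts (they bias MFPTs);
states without outgoing counts are dropped with a warning instead.

Mean first passage times solve F_if = 1 + Σ_{j≠f} T_ij F_jf over non-target
states; times are converted to physical units via τ × frame interval, and
F(target→target) is 0 by convention. First-passage distributions use the
absorbing-chain recursion f_ij(1) = T_ij, f_ij(n) = Σ_{k≠j} T_ik f_kj(n−1),
implemented as repeated application of T with the target column zeroed.

**Tail correction.** The stored distribution covers n ≤ n_max; the mean adds
the exact conditional remainder Σ_k ρ_k (n_max + F_k), where ρ is the
probability of occupying transient state k at step n_max without having hit
the target and F the linear-solve MFPT vector. The reported mean therefore
equals the linear-solve value to rounding, whatever n_max, and the
remaining probability is reported separately as `tail_mass`.

## History-augmented ("non-Markov") analysis

For an ordered core pair (A, B) every frame is annotated with the
last-visited element of {A, B}; frames before the first visit to either are
undefined and excluded (any default history would inject spurious
transitions). Transitions are then counted only from frames with history A,
and the target B row is set to the exact absorbing row (0, …, 0, 1).
Because an intermediate frame "remembers" which core it came from, lumping
distinct intermediate pathways no longer contaminates the A→B kinetics —
the bias that a plain MSM suffers whenever lumped states have different
outgoing dynamics.

Defaults: all non-A, non-B labels (including unfolded) are lumped into one
intermediate block, matching the three-block conditional-matrix layout;
`intermediate_mode="keep"` retains each label for multi-core analyses. The
reverse direction is an independent second pass with the pair swapped, so
forward and backward MFPTs are free to differ. The same lag (default 1
frame) is used for conditional and plain analyses so their estimates are
comparable.

## Naive estimator

The model-free baseline scans the trajectory: from every frame in A
(default) or every entry into A, the first subsequent frame in B gives an
FPT of (j − i) × frame interval. Starts with no later arrival are counted
as censored and excluded from the mean — imputing them would require a
model, defeating the estimator's purpose. Every-frame starts are serially
correlated, so the per-event standard error is optimistic; tests and the
acceptance checks use contiguous-block resampling instead. The convergence
study truncates prefixes (first f × n frames), emulating "a shorter
simulation" rather than a random subsample.

On Markov data all three estimators (MSM solve, history-augmented solve,
naive mean) are consistent for the same quantity; their pairwise agreement
within combined sampling error is the suite's central cross-validation, and
the lumped-chain fixture (below) is where the first and second genuinely
part ways.

## Diffusion maps

Gaussian kernel k(x_i, x_j) = exp(−‖x_i − x_j‖²/2ε); row normalization
M = D⁻¹K (D = row sums) by default, with the density-corrected variant
(K_ij/(p_i p_j), then row-normalized) available — on smooth fixtures the
two give eigenvalues within ~10% and strongly correlated eigenvectors.
Numerics:

* Eigenpairs come from the symmetric conjugate D^{−1/2} K D^{−1/2}
  (identical spectrum; real, stable eigenvectors), back-transformed and
  scaled to unit norm, with the sign convention that each eigenvector's
  largest-magnitude entry is positive.
* λ₁ = 1 with constant right eigenvector u₁; the stationary density over
  samples is the *left* λ₁-eigenvector, D/ΣD. Both are reported — "the
  leading eigenvector represents the equilibrium distribution" is true of
  the left eigenvector only, and the package does not conflate them.
* DM coordinates are λ_α^t u_α with t = 1.
* A repeated unit eigenvalue (1 − λ₂ < 1e−12) means the kernel graph is
  numerically disconnected; the error advises increasing ε.
* Default ε = median nonzero pairwise squared distance of the embedded
  sample. No single criterion is canonical; the kernel-sum diagnostic
  (Σ_ij k vs. ε on a log-log grid with its maximum-slope region marked) is
  emitted so users can override deliberately.

**Short-time maps.** The trajectory is chopped into consecutive,
non-overlapping windows and each window embedded independently with a
single fixed ε (the full-trajectory median by default) so fluctuation
amplitudes are comparable across windows. Eigenvector sign is arbitrary and
eigenvector *order* can interchange between windows when eigenvalues cross,
so each window's nontrivial eigenvectors are aligned to a reference by the
sign-and-permutation maximizing total |Pearson r| (linear assignment) over
frames shared with the reference (the full-trajectory map is usually
computed with a stride, so windows share a subset of frames with it).
Aligning to the *previous window* instead is supported even though
consecutive windows share no frames: the previous window's eigenvectors are
evaluated at the current window's points by nearest-neighbour lookup in CV
space before correlating. This is a function-space comparison, not a
Nyström extension of the kernel (which is out of scope).

The per-window standard deviation of each aligned DM coordinate is the
fluctuation series. Within a single well the kernel at the trajectory-wide
ε is nearly uniform and λ₂ is small, so λ₂u₂ barely varies; a window
straddling a core-to-core transition contains two well-separated clusters,
λ₂ approaches 1, and the coordinate's spread grows by an order of
magnitude. That contrast is what flags rare events.

## Synthetic fixtures

The generators produce data with exactly the statistical structure the
analysis assumes, in place of an MD trajectory that no public archive
provides:

* **Markov chains** with known T: the generative counterpart of the MSM.
  The bundled 3-state reference chain (diagonal 0.90, mild asymmetry) has
  MFPTs of 15–26 frames, so 10⁵–10⁶-frame samples hold 10³–10⁵ passage
  events.
* **Lumped hidden chains**: 4 hidden states {A, I₁, I₂, B}, I₁ entered
  only from A and returning mostly to A, I₂ entered only from B. Lumping
  I = {I₁, I₂} makes the observed chain strongly non-Markov:
  P(next = B | in I, last core A) = 0.10 exactly, while the unconditional
  I row mixes in I₂'s 0.80 — which is why the plain MSM underestimates the
  A→B MFPT several-fold and the history-augmented estimate is unbiased.
* **Brownian dynamics** on U(x) = −kT·log(Σ_k e^{depth_k} G_k(x) + 10⁻⁸):
  Gaussian bumps G_k at the three core centers guarantee each printed
  center is a genuine smooth minimum; the 10⁻⁸ floor keeps the force
  finite everywhere. Overdamped Euler–Maruyama with per-step displacement
  std √(2D·dt) checked against the narrowest well width at construction —
  adequate for generating metastable test data, not for physics claims.
  Defaults kT = 1, D = 1, dt = 0.01, save every 10 steps, well width 1.0:
  barriers of ≈3–7 kT between the three wells, giving trajectories that
  stay in a core's basin for hundreds of frames with occasional switches —
  the metastable-with-rare-transitions regime the analyses target. With
  equal depths the depth parameter cancels from barrier heights; it sets
  the well depth relative to the flat far-field floor (≈18 kT for the
  default floor), which prevents escape to infinity.
* **Noisy circles** for the embedding: the Laplacian eigenfunctions on a
  circle are sine/cosine pairs, so atan2(u₃, u₂) must recover the
  generating angle up to an orthogonal transformation. Recovery is scored
  by the Fisher–Lee circular correlation, which is rotation-invariant and
  well defined for uniform angles; reflections flip its sign, so the
  absolute value is the meaningful score.

All generators take explicit integer seeds (no global state) and are
bit-reproducible; the Brownian integrator draws its noise in chunks from a
single seeded stream so chunking cannot change results.

**What passing tests show — and don't.** The fixtures are exactly Markov
(chains), exactly lumped-Markov (hidden chains), or genuinely diffusive on
a smooth 2-D landscape. Real MD discretizations violate all three in ways
these fixtures cannot expose: projection onto CVs induces memory at *all*
states (not just a designed intermediate block), landscapes are rugged and
high-dimensional, and saved frames are far from the overdamped limit at
short lags. Passing here certifies the estimators against their own
assumptions and against exact oracles; it does not certify any particular
lag or state definition for a given molecular system.

## Problem sizes

Default test and verification sizes are chosen so every stochastic check
holds with wide margin at desk scale: 10⁵–10⁶ frames for chain-based
estimator comparisons (sampling SEs of ~0.5% of the MFPT), 20 replicates
of 10⁶ frames for the lumped-chain bias comparison, 30 000 frames / 40
windows of 750 frames for the windowed-map rare-event test, and 75 000
frames for the prefix-convergence study (matching the sample count of a
typical long CV trajectory saved every 10 ps).

## Known limitations

* Dense kernels only: diffusion maps cost O(N²) memory, so long
  trajectories should be strided (the `stride` argument) — no sparse or
  landmark approximation is provided.
* No committor/flux analysis, no lag-time variational scoring, no
  reversible MSM estimation, no survival-analysis treatment of censored
  first-passage starts.
* The windowed-map transition flag is a diagnostic, not a detector with
  calibrated error rates; the rank-test property holds for well-separated
  metastable states at the trajectory-wide bandwidth.
* Angle observables correlate linearly by default (`angle_mode="raw"`);
  the sin/cos embedding must be requested explicitly and is flagged in the
  output rather than silently applied.
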