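# Methods

This note documents the models and procedures implemented in flockscale,
the defaults and why they were chosen, and the known limits of each
approximation.

## Trajectory processing

Raw tracks are smoothed with a fixed 9-point Gaussian kernel,
x̄_i(t) = Σ_{k=-4..4} φ_k x_i(t−kΔt) with φ_k = C·e^{−k²/4} and Σφ_k = 1,
applied exactly as written: frames without a full stencil are dropped
rather than smoothed with a renormalized truncated kernel, so no edge
weights are invented. Missing frames split a track into independent runs;
a smoothing window never spans a gap. Velocities are centered differences
of the smoothed positions (exact for locally quadratic paths), with run
endpoints dropped. Cells with exactly zero velocity at a frame have no
defined heading; they are excluded from that snapshot and tallied, rather
than assigned an arbitrary angle. The frame interval defaults to 10 min.
Angles are measured counterclockwise from +x in [0, 2π).

## Order metrics and classification

Polarization S = |⟨s⟩| and the nematic order parameter
2⟨cos²(θ−θ̄)⟩ − 1 are computed per snapshot; θ̄ is the mean-spin
orientation, falling back to the leading eigenvector of the 2D nematic
tensor when the mean spin vanishes (antiparallel populations), which keeps
the statistic defined and rotation-invariant in the degenerate case.

The flock/stream/swarm classification fits three circular densities to
the pooled angles by maximum likelihood: a von Mises (circular normal)
density for flocks, an equal-weight antipodal von Mises mixture with
shared concentration for streams, and the uniform density for swarms.
Angles are pooled over all time points by default (a per-snapshot option
exists via the snapshot API). Because the flock and stream families nest
the uniform density, the raw maximized likelihoods can never favor the
uniform model on a finite sample — any sample has a nonzero resultant, so
the fitted concentration is positive and the richer model wins by an
O(1) overfitting margin. Model selection therefore compares BIC-penalized
log-likelihoods (L − (k/2)·ln N, with k = 2 free parameters for flock and
stream, 0 for swarm). The penalty only matters for near-uniform data: any
genuinely unimodal or antipodal structure at realistic N overwhelms it.
Raw log-likelihoods and fitted parameters are reported alongside the
label. Fits on fewer than 10 angles are flagged unreliable.

Angle-histogram comparison between rotation-symmetric model output and
data first rotates one angle set to minimize the summed squared
difference of the two frequency histograms (36 bins, 720 candidate
rotations of π/360). The uniform-vs-uniform control residual is the noise
floor against which "agreement" must be judged; alignment alone cannot
manufacture agreement between genuinely different shapes.

## Correlation functions and scaling

C(r) = ⟨δs_i·δs_j⟩_r with δs_i = s_i − ⟨s⟩ subtracted per snapshot (the
co-moving frame). All unordered pairs from all snapshots are pooled into
one (distance, dot product) list — each pair weighted equally — and C(r)
is a moving average over a centered window of ±100 µm on a 5 µm grid
(the window dominates the grid step, so the grid choice is immaterial).
The SEM within each window is reported; windows holding fewer than two
pairs are undefined (NaN), never zero.

Within every snapshot Σ_{i≠j} δs_i·δs_j = −Σ_i|δs_i|² exactly, so C(r)
must go negative whenever fluctuations are nonzero; the correlation
length r₀ is the first zero crossing, linearly interpolated between grid
points. Its uncertainty is half the width of the interval around the
crossing where |C| ≤ its local SEM, floored at half a grid step. An
all-positive C(r) raises an explicit no-crossing error instead of
extrapolating.

System size L is the time average of the per-snapshot maximum pairwise
separation; √(convex-hull area) is available as an alternative (degenerate
hulls raise). Scaling fits are ordinary least squares of r₀ on L and on
log L with Pearson correlations; "prefers log" means the logarithmic
model explains more variance than the linear one.

Box scaling subsamples each snapshot with randomly positioned W×W boxes
(default 30 per snapshot) fully inside the field of view, selecting cells
strictly inside. Fluctuations are taken about each box's own mean — the
box is the subsystem whose correlation structure is being probed — with a
global-mean option for sensitivity analysis. Pairs from all boxes of one
width are pooled into C_W(r) (±50 µm window) and r₀(W) extracted as
above. Boxes of widths small enough to average fewer than 2 cells, or
whose C_W never crosses zero, are excluded with a warning. The box-width
range should span at least a factor of two (200–800 µm is the intended
regime at typical explant densities of a few hundred cells per
800×800 µm field).

## The maximum-entropy model

The minimal distribution over unit velocity vectors matching the observed
neighborhood correlation C_int (Eq. above) is the nonlocally coupled XY
model P ∝ exp[(J/2N) Σ_i Σ_{j∈nc(i)} s_i·s_j], with topological
neighborhoods: each cell couples to its n_c nearest cells by Euclidean
distance, ties broken by lower index. One-way neighbor relations get
weight 1/2, mutual ones 1, in the symmetric weight matrix whose Laplacian
A = diag(row sums) − n enters the spin-wave partition function
log Z = −Σ_{k>1} log(Jλ_k/N) + Jn_c/2 (zero mode excluded; more than one
zero mode means a disconnected interaction graph, which is an error, not
a warning). Matching C_int ties J to the data, 1/J = n_c(1−C_int)/2N, and
the per-n_c profile log L(n_c) = Jn_cC_int/2 − log Z is maximized over a
log-spaced integer grid (≈25 values in [2, N−1]) to select n_c*. Profiles
from multiple snapshots are averaged over time before the argmax. In the
all-to-all limit the constraint reduces to J = 2/(1−C_int), with the
mean-field critical point at J_c = 2.

**Validity and bias.** The spin-wave expansion assumes strong
polarization. It is nevertheless applied at any polarization (with a
logged warning below S = 0.5) because the selected n_c* remains
informative well outside the formally valid regime. Two systematic
behaviors of the J estimator must be kept in mind when reading results:

- *Disordered data always maps to the critical point.* C_int ≈ 0 gives
  J ≈ 2 under the closed form, exactly where the mean-field transition
  sits, so J ≈ J_c alone is never evidence of criticality — genuinely
  disordered populations produce the same estimate. The acceptance suite
  measures this directly (median Ĵ ≈ 2 for populations simulated at and
  below J_c).
- *Ordered data overstates J.* For strongly ordered configurations the
  Gaussian fluctuation theory gives C_int ≈ 1 − (N−1)/(Jn_c), so
  inverting the constraint returns roughly 2J; near the critical surface
  the factor is closer to 1.4–1.5. The estimator is accurate only
  slightly above the critical point. The n_c selection is unaffected —
  recovery tests at 1.2× the critical coupling return the generating n_c
  exactly in the median — but inferred J values on the ordered side
  should be read as upper bounds. The direct least-squares histogram
  check (`least_squares_fit_check`) provides a model-independent
  cross-validation of any fitted parameter pair.

## Monte Carlo sampling

Single-site Metropolis with Gaussian angle proposals (SD 0.5 rad,
tunable), sequential site scan; a dedicated O(1)-per-update kernel serves
the all-to-all graph via a running resultant. Defaults: 1000 burn-in
sweeps, thinning 10 when drawing multiple samples from one chain. The
sampler is validated against direct quadrature of the 3-cell density
(total variation < 0.02) and against closed-form null moments at J = 0.

Phase-diagram sweeps use one independent, freshly seeded chain per
realization so that susceptibility (variance of S across realizations)
and heat capacity (variance of energy) are variances over independent
samples. These chains start from an ordered configuration with a random
common direction: a cold start relaxes quickly at every coupling, whereas
random starts deep in the ordered phase freeze into long-lived vortex
states whose across-chain spread masquerades as a second susceptibility
peak at strong coupling. The critical surface is the per-n_c χ-peak
locus, refined by a quadratic fit through the three grid points around
the maximum; rows whose maximum sits on a grid edge are flagged
"unbracketed" and excluded. The default J grid is log-spaced around
2N/n_c, the natural ordering scale set by the minimum of the spin-wave
log Z (at J = 2(N−1)/n_c). Population placement interpolates J*(n_c)
linearly in log n_c and refuses to extrapolate outside the scanned range.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical* conditions of explant imaging:
a few hundred cells in an 800×800 µm field (uniform or clustered
positions), equilibrium directional configurations from the XY model,
~1 µm/min speeds at 10-min frames, isotropic Gaussian positional jitter,
and 25 size-matched uniform-angle null datasets as the disorder baseline.
Trajectories are a kinematic dressing of equilibrium configurations —
there is no self-propelled dynamics with interaction-driven turning, no
cell division or death, no density change, and free boundaries
throughout. Passing tests therefore demonstrate that the *analysis chain*
is correct and that the *model phenomenology* (critical point, scale-free
box scaling at criticality) is reproduced; they do not demonstrate that
real cell populations satisfy the model's equilibrium or topological
assumptions.

## Numerical choices

- kNN neighbor lists: stable argsort of the full distance matrix up to
  N = 2000 (deterministic lower-index tie-break), k-d tree beyond.
- Eigenvalues below 10⁻⁸ × λ_max are treated as zero modes.
- C_int = 1 (perfect order) raises a divergence error: J is
  unidentifiable there.
- Likelihood profiles whose finite range is below 2 log-units are flagged
  low-confidence (disordered data gives essentially flat profiles).
- All stochastic stages take explicit seeds; the pipeline manifest
  records the master seed and a config hash, and rerunning with both
  reproduces every number exactly.

## Problem sizes used in the validation suite

Simulation-based checks run at the scale of the data they emulate while
staying cheap: N = 200 for the all-to-all critical-point scan (21 J
values × 50 independent chains), N = 300 with n_c = 20 for parameter
recovery (20 replicates at 1.2× the measured χ-peak), N = 400 for box
scaling (25 snapshots, widths 200–600 µm, 20 boxes per snapshot), and
N = 500 × 100 replicates per class for the classification suite.
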