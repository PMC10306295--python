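# flockscale

Quantitative analysis of weakly ordered collective cell motion in 2D —
from raw track tables to correlation-length scaling, box scaling,
maximum-entropy inference of effective cell–cell coupling, and a Monte
Carlo phase diagram.

The package is built for time-lapse tracking data of migrating cell
populations (e.g. glioma explant imaging tracked with TrackMate), where
the question is not *whether* cells align — global polarization is weak —
but *how far* directional fluctuations are correlated, and whether that
correlation length is set by an intrinsic scale or by the size of the
population itself (scale-free correlations, the hallmark of systems near a
critical point).

## What it computes

Starting from per-cell positions `x_i(t)` at a fixed frame interval
(Δt = 10 min by default):

- **Trajectories** — 9-point Gaussian smoothing
  `x̄_i(t) = Σ_{k=-4..4} φ_k x_i(t-kΔt)`, `φ_k = C e^{-k²/4}`, then
  centered-difference velocities
  `v̄_i(t) = (x̄_i(t+Δt) - x̄_i(t-Δt)) / 2Δt`, unit vectors `s_i` and
  heading angles `θ_i ∈ [0, 2π)`.
- **Order metrics** — polarization `S = |⟨s⟩|`, nematic order
  `2⟨cos²(θ-θ̄)⟩ - 1`, and a flock / stream / swarm classification of the
  pooled angle distribution (unimodal circular normal vs antipodal mixture
  vs uniform).
- **Correlations** — fluctuation correlation
  `C(r) = ⟨δs_i·δs_j⟩_r` with `δs_i = s_i - ⟨s⟩` per snapshot, pooled over
  time and smoothed with a ±100 µm moving window; the correlation length
  `r₀` is the first zero crossing of `C(r)`; system size `L` is the
  time-averaged maximum pairwise separation (or √convex-hull-area); linear
  vs logarithmic fits of `r₀` against `L`, and **box scaling**: `r₀(W)`
  from randomly placed W×W subsampling boxes (±50 µm window, 30
  boxes/snapshot).
- **Maximum-entropy inference** — the minimal model matching the observed
  neighborhood correlation
  `C_int = (1/N) Σ_i (1/n_c) Σ_{j∈nc(i)} s_i·s_j`
  is a nonlocally coupled XY model,
  `P({s}) ∝ exp[(J/2N) Σ_i Σ_{j∈nc(i)} s_i·s_j]`,
  with topological (k-nearest-neighbor) interactions. The constraint pins
  `1/J = n_c(1-C_int)/2N`; the remaining parameter `n_c` is selected by
  maximizing the spin-wave log-likelihood, using
  `log Z = -Σ_{k>1} log(Jλ_k/N) + Jn_c/2` over the eigenvalues `λ_k` of
  the neighborhood Laplacian. The all-to-all limit gives the closed form
  `J = 2/(1-C_int)` with mean-field critical point `J_c = 2`.
- **Phase diagram** — Metropolis Monte Carlo over a (J, n_c) grid on a
  representative position set; mean polarization, susceptibility χ
  (variance of S across independent realizations) and generalized heat
  capacity (variance of energy); the critical surface is the χ-peak locus,
  and inferred populations are placed by their signed J-distance from it.
- **Synthetic data** — position sets, equilibrium XY configurations,
  noisy tracks dressed around them, and size-matched uniform-angle null
  datasets, so the entire pipeline is testable without imaging data.

## Worked example

Simulate a moderately ordered population (120 cells, 60 frames, coupling
J = 45 to the n_c = 10 nearest neighbors, 1 µm positional jitter) and
analyze it end to end:

```sh
flockscale simulate --n-cells 120 --n-frames 60 --j 45 --nc 10 \
    --jitter-sd 1.0 --seed 11 --out-dir demo
flockscale analyze demo/tracks.csv --seed 7 --out-dir demo_out
```

`demo_out/manifest.json` then reports, for this population:

```
classification: flock
r0_um:  358.1      # correlation length: first zero of C(r)
L_um:  1029.2      # time-averaged maximum pairwise separation
maxent: {"nc_star": 8, "J_star": 171.2}
mean polarization S = 0.579, mean nematic OP = 0.134
```

Reading: the smoothed velocities are unimodally aligned (flock), with
directional fluctuations correlated out to ~360 µm — about a third of the
population extent. The inferred interaction neighborhood n_c* = 8 sits
next to the generating value 10; the inferred coupling is on the ordered
side of the critical surface (the spin-wave inversion systematically
overstates J for strongly ordered data; see `docs/methods.md`). Per-stage
CSV/JSON artifacts (order series, C(r), fit profiles) are written under
`demo_out/tracks/`.

The other subcommands — `flockscale boxscale`, `flockscale fit`,
`flockscale phase-diagram` — expose the box-scaling curve, the
maximum-entropy fit, and the Monte Carlo phase diagram individually.

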