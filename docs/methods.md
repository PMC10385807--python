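# Methods

## Model

The sensing region of a magnetometer array is source free, so the magnetic
scalar potential obeys Laplace's equation and expands in solid harmonics
about an origin inside the array:

* internal terms `Y_lm(θ,φ) / r^(l+1)`, singular at the origin — fields of
  sources inside the array;
* external terms `r^l Y_lm(θ,φ)`, divergent at infinity — fields of distant
  sources.

Degrees start at `l = 1` (no magnetic monopole). Harmonics are real valued
and fully normalised: the Condon–Shortley phase is carried inside the
associated Legendre functions (as `scipy.special.lpmv` returns them), and
for `m ≠ 0` the `√2·cos(mφ)` / `√2·sin(|m|φ)` combinations of the complex
pair are used. Measured data are real, so a real basis keeps all weight
estimation in real arithmetic; consistency of phase convention between the
Legendre functions and the real combinations is what guarantees no sign
flips between ±m partners. Orthonormality is verified by quadrature in the
test suite rather than assumed from transcription.

Term *fields* are `−∇` of the potential terms, evaluated analytically:
`dP_l^m(cosθ)/dθ` via the recurrence
`sinθ · dP/dθ = l·cosθ·P_l^m − (l+m)·P_{l−1}^m`, and the azimuthal factor
`m·P_l^m/sinθ`, regular for `m ≥ 1` because `P_l^m ∼ sinθ^m`. Points on
the ±z axis (degenerate spherical coordinates, not a physical singularity)
are nudged off-axis by a relative 1e−7, introducing error far below any
tolerance used. Physical constants (μ₀, the overall sign of
`B = −μ₀∇V`) are dropped: basis columns are normalised, so only the
pattern matters. Finite differences appear only in tests, as oracles.

The basis `S = [S_in S_out]` projects each term field onto every channel's
orientation at its position and column-normalises. Columns are ordered
l-major with m ascending from −l to +l, giving deterministic index maps for
the degree-block slicing below; pre-normalisation norms are stored so
reconstructions come out in the physical units of the input data.
Over-complete bases (more columns than channels) may be *built* — only the
standard solver rejects them, since the iterative one never inverts the
full matrix.

## Solvers

**Standard SSS** solves `x̂ = S⁺φ` per time sample and reconstructs
`Φ̂_in = S_in x̂_in`. Pseudo-inverses use SVD with a relative cutoff of
1e−12·σ_max. The cutoff is deliberately tiny: the point of the comparison
is to *exhibit* the noise amplification of a near-singular basis, not to
mask it with aggressive truncation (which would be a different,
regularised method).

**Iterative partial-basis SSS** starts from zero weights and cycles over
internal degrees `l = 1..L_in` in ascending order. For each degree it
forms the residual of the measurement with the current degree's internal
weights *and all external weights* zeroed, solves the least-squares problem
on the partial basis `S_l = [S_in,l  S_out]` (width `2l+1 + N_out`, always
≪ N, hence well-conditioned), and overwrites that internal block and the
external block. The final external weights are those of the last partial
solve of the last sweep. An algebraically equivalent formulation subtracts
the current external prediction and accumulates corrections; both were
implemented during development and agree to machine precision, so the
replace-per-solve form is used.

Properties that follow (and are tested):

* At a fixed point the residual is orthogonal to every partial basis and
  hence to `span(S)`: on well-conditioned problems the iteration converges
  to the joint least-squares solution. The contraction is geometric with a
  rate set by the principal angles between degree blocks — about
  0.96/sweep at `(L_in, L_out) = (4, 3)` on the default helmet, faster at
  lower orders.
* With `L_in = 1` the first sweep *is* the standard solve.
* The method is linear per time sample; samples are independent and share
  one set of partial-basis factorisations (factor once, reuse across
  samples and sweeps).
* Runs are resumable: the internal running prediction is recomputed from
  the weights at each sweep start, so warm-starting from stored weights is
  bit-identical to an uninterrupted run.

The per-sweep convergence monitor is `dx`, the mean over time samples of
the Euclidean norm of the weight change, computed in the column-normalised
frame with data in femtotesla (the studies convert tesla → fT at a single
point). An optional `dx` threshold stops early; by default the fixed sweep
count is honoured and non-convergence is not an error.

## Synthetic study conditions

The generator reproduces the study conditions used throughout:

* **Helmet**: 64 triaxial point magnetometers (192 channels) on a Fibonacci
  lattice over a spherical cap; each sensor contributes a radial and two
  tangential channels (orthonormal triads). The array is translated so the
  centre of mass of the positions — also the expansion origin — is
  (0, 0, 0.02) m, the common centre of both source shells. Two calibration
  anchors pin the free parameters: the cap radius is set so the closest
  sensor lies 21.5 mm outside the internal source shell surface, and the
  cap half-angle (100°) is set so the mean principal angle between the
  internal and external subspaces at `(L_in, L_out) = (8, 3)` is ~60°, the
  published figure of merit for whole-head triaxial arrays. With these
  anchors the condition number of the `(11, 5)` basis is ~1e5 and standard
  SSS amplifies white noise ~16×, i.e. the array is squarely in the regime
  the iterative method exists for. The lattice seed only rotates the
  pattern azimuthally.
* **Sources**: point magnetic dipoles, uniform in shell volume with
  isotropic random moments of fixed magnitude — 10 nA·m² in the internal
  shell (5–50 mm), 10 mA·m² in the external shell (2–3 m). Each dipole is
  driven sinusoidally at a distinct random integer frequency in 1–100 Hz
  (distinct across the whole draw); recordings last 1 s at 1200 Hz with
  i.i.d. Gaussian sensor noise of 30 fT per sample. Internal and external
  ground truths are accumulated separately, so every metric has an exact
  reference. A free-space current-dipole forward model was evaluated as an
  alternative during development; with the magnitudes above its external
  fields bury the internal signal three orders of magnitude deep, which no
  truncation can separate, so the point-magnetic-dipole model (the natural
  reading of the quoted moments as A·m²) is used. The forward operator is
  isolated behind `dipole_field`, so an alternative source model is a
  drop-in.
* **Experiments**: (1) *reconstruction noise* — 100 standard-normal signal
  vectors shared across the grid `L_in = 3..11 × L_out = 3..5`; the
  noise-amplification ratio `nr = ‖Φ̂_in‖/‖φ‖` per vector, averaged, per
  iteration for the iterative solver (10 iterations). (2) *source
  separation* — replicate runs of 5+5 dipoles over `L_in = 7..11 ×
  L_out = 3..5` with 20 sweeps, recording after every complete sweep the
  pooled explained variance `EV = 100·(1 − var(truth − est)/var(truth))`
  of the internal reconstruction, its pooled RMSE (tesla), and `dx`.
  Pooling over channels × samples gives one scalar per run; means over
  runs (no trimming) are the aggregates. Replicates use 25 runs by default
  in the acceptance script — run-to-run standard errors of mean EV are
  ~0.2–1 percentage points at that size, and the run count is a config
  field (`StudyConfig.n_runs = 100` reproduces the full-size study).
  Randomness flows from a single master seed through per-run
  `SeedSequence` substreams, so run-level parallelism or reordering cannot
  change results.

## What the synthetic geometry does and does not show

The helmet is a calibrated idealisation, not a digitisation of any
commercial helmet. The two anchors above fix conditioning-type diagnostics
well, and the package reproduces the qualitative results robustly:
iterative noise amplification < 2 everywhere on the grid versus ≫ 10 for
standard SSS at high orders; monotone growth of the condition number with
`L_in`; EV rising and RMSE falling to a plateau over sweeps with `dx`
collapsing by orders of magnitude after the first sweeps.

Quantitatively, however, the per-sweep contraction rate of the block
iteration is geometry-sensitive: on the calibrated cap it is ~0.75 per
sweep at high orders, so iteration-5 mean EV reaches ~96–97 % at
`(11, 3)`/`(11, 4)` and ~90 % at `(11, 5)`, converging towards the ~99.8 %
that the one-shot least-squares limit attains at `(11, 3)` only over tens
of sweeps. Synthetic cap and ellipsoid families trade conditioning against
contraction rate along a single frontier — members tuned to converge to
~99.8 % EV within 5 sweeps are too well-conditioned to exhibit the
standard-SSS instability at all. Real helmet geometries evidently sit off
this frontier, so iteration-5 EV figures from any synthetic array should
be read as lower bounds on achievable separation quality, not as
array-independent constants. Likewise `dx` is reported on the fT scale
where its absolute value after 5 sweeps is O(10³) here; its *shape*
(monotone collapse and plateau) is the robust, transferable property, and
is what a stopping rule should use.

Other limitations: sensors are ideal point magnetometers (no pickup-loop
integration, no calibration error, no 1/f noise); sources sit in free
space (no volume conductor); the array is static; and temporal/
spatiotemporal SSS extensions are out of scope.
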