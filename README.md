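# opmsss

Signal space separation (SSS) for multichannel magnetic field recordings,
with an **iterative partial-basis solver** that remains numerically stable
when the dimension of the multipole basis approaches the number of
channels — the regime of current optically-pumped-magnetometer (OPM) MEG
helmets.

## The problem

A magnetometer array inside a shielded room measures a superposition of the
fields of interest (sources inside the helmet, tens of femtotesla) and
environmental interference (distant sources, often orders of magnitude
larger). In a source-free sensing region the magnetic scalar potential
solves Laplace's equation and splits into two solid-harmonic series,

```
V(r) = Σ_{l,m} α_lm Y_lm(θ,φ) / r^(l+1)  +  Σ_{l,m} β_lm r^l Y_lm(θ,φ),
```

whose first series describes sources *inside* the array and the second
sources *outside* it. Projecting each term's field pattern onto the N
channels gives basis matrices `S_in` (N × N_in) and `S_out` (N × N_out),
truncated at degrees `L_in`, `L_out`, so any signal vector is modelled as
`φ = S_in x_in + S_out x_out = S x`. Classic SSS estimates the weights in
one shot, `x̂ = S⁺φ`, and keeps `Φ̂_in = S_in x̂_in` — this needs
`N_dims = (L_in+1)² + (L_out+1)² − 2 ≤ N` and becomes unstable as the two
approach parity: on a 192-channel triaxial helmet at the orders proposed
for on-scalp arrays (`L_in=11, L_out=5`, `N_dims=178`) the pseudo-inverse
amplifies white noise more than tenfold.

The iterative solver exploits the hierarchy of the expansion instead.  Per
sweep it solves, for each internal degree `l = 1..L_in` in turn, a small
well-conditioned least-squares problem on the *partial basis*
`S_l = [S_in,l  S_out]` (the 2l+1 degree-l internal columns plus all
external columns) against the residual of everything estimated so far,
overwriting that degree's internal weights and the external weights.  No
wide matrix is ever inverted, so the noise amplification stays near unity
at any truncation order; on well-conditioned problems the fixed point is
the joint least-squares solution.

## Worked example

Everything is synthetic and seeded: a 64-slot triaxial helmet (192
channels, spherical cap calibrated so the closest sensor sits 21.5 mm from
the internal source shell), 5 internal dipoles (10 nA·m², 5–50 mm from the
expansion origin) and 5 external dipoles (10 mA·m², 2–3 m away), driven at
distinct integer frequencies for 1 s at 1200 Hz with 30 fT sensor noise.

```python
import numpy as np
from opmsss import (build_basis, condition_number, iterative_sss,
                    make_helmet_array, ndims, sample_shell_dipoles,
                    simulate_recording, standard_sss, explained_variance)
from opmsss.sss_basis import mean_subspace_angle
from opmsss.simulate import (INTERNAL_SHELL, EXTERNAL_SHELL,
                             INTERNAL_MOMENT, EXTERNAL_MOMENT)

helmet = make_helmet_array()                   # 64 triaxial sensors, 192 channels
basis = build_basis(helmet, l_in=11, l_out=5)  # 178 basis vectors

print(f"N_dims = {ndims(11, 5)} on {helmet.n_channels} channels")
print(f"condition number  = {condition_number(basis):.3g}")
print(f"mean subspace angle = {mean_subspace_angle(basis):.1f} deg")

rng = np.random.SeedSequence(7).spawn(4)
freqs = np.random.default_rng(rng[0]).choice(np.arange(1, 101), 10, replace=False)
sources = sample_shell_dipoles(5, *INTERNAL_SHELL, kind="internal",
                               moment_magnitude=INTERNAL_MOMENT, seed=rng[1],
                               frequencies=freqs[:5]) \
        + sample_shell_dipoles(5, *EXTERNAL_SHELL, kind="external",
                               moment_magnitude=EXTERNAL_MOMENT, seed=rng[2],
                               frequencies=freqs[5:])
rec = simulate_recording(helmet, sources, duration=1.0, fs=1200, seed=rng[3])

std = standard_sss(basis, rec.data_fT)
it = iterative_sss(basis, rec.data_fT, n_iterations=5)
for name, res in [("standard", std), ("iterative", it)]:
    ev = explained_variance(rec.ground_truth_in * 1e15, res.phi_in_hat)
    print(f"{name:9s} SSS: internal-signal explained variance = {ev:.1f} %")
```

prints

```
N_dims = 178 on 192 channels
condition number  = 1.22e+05
mean subspace angle = 31.8 deg
standard  SSS: internal-signal explained variance = 84.5 %
iterative SSS: internal-signal explained variance = 89.7 %
```

The condition number of the full basis is ~10⁵, so the one-shot
pseudo-inverse smears sensor noise and interference into the internal
reconstruction; five sweeps of the partial-basis iteration recover the
internal signal more faithfully at identical truncation orders (and keep
improving with further sweeps — see `docs/methods.md` for convergence
behaviour). `SeparationResult.history` carries the per-sweep weight-change
norm `dx`, the convergence monitor that remains available on real data.

A command-line interface mirrors the library:
`opmsss geometry`, `opmsss simulate`, `opmsss basis`, `opmsss separate`
and `opmsss study` (the full metric studies; see `opmsss study --help`).

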