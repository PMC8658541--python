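# rftomo

Receptive-field mapping from flashed-bar responses by non-negative matrix
factorization and iterative reconstruction tomography.

## The problem

Neurons in the early visual system (retina, LGN) respond to light within a
restricted region of visual space — the receptive field (RF), classically a
centre mechanism with an antagonistic surround.  Linear cells are routinely
characterized with drifting gratings and a difference-of-Gaussians (DoG)
model, but nonlinear cells (on/off-rectifying, direction-selective) need
discrete stimuli, and grating protocols are slow.  Flashing a long bar at a
handful of orientations and many perpendicular offsets probes every RF in
the field in a few minutes: each bar response is a strip integral of the
underlying sensitivity map, so the per-bar response weights form a sinogram
and the RF can be recovered tomographically.

`rftomo` implements the full analysis chain, plus the synthetic neurons
needed to validate it end to end:

1. **PSTH factorization.** Spike responses are binned into per-stimulus
   peristimulus time histograms `R[i, t]` and factorized,

   `R[i,t] ≅ P[t,k] W[k,i]`,

   with non-negative temporal profiles `P` and spatial weights `W`
   (multiplicative-update NNMF, restarts, components ordered by explained
   variance).
2. **Gaussian rotation.** Non-negativity captures only excitatory
   components.  Inhibition is exposed by a rotation `F` (unit diagonal,
   non-negative off-diagonals): `R ≅ (P F⁻¹)(F W)`, with `F` chosen so each
   rotated weight row is a compact radial Gaussian of the bar-to-centre
   distance `d_i`,

   `(F W)_k = g_k exp(−(d_i / 4 r_k)²) + b_k`.

   For two components this model has exactly 10 free parameters; the
   rotated profiles `P F⁻¹` may go negative, revealing inhibitory
   contributions.
3. **Tomographic reconstruction.** Each (rotated) weight row is
   reconstructed into a 2-D map by SART — `x ← x + λ D_r Aᵀ D_c (y − A x)`
   with the exact strip-coverage operator `A` — stopped at the iteration
   whose residual is most white-noise-like (normalized cumulative
   periodogram rule), with ramp-×-Butterworth filtered back-projection as a
   comparator.  Maps are signed: negative regions are inhibitory.
4. **RF statistics.** DoG fits to grating first-harmonic curves,

   `K(ω) = π k_c r_c² e^{−(π r_c ω)²} − π k_s r_s² e^{−(π r_s ω)²}`,

   surround/centre gain ratios `k_s/k_c`, bar-width-corrected radii, and
   correlation of maps with dendritic-density rasters.

The synthetic module (`rftomo.simulate`) provides linear centre-surround
cells, frequency-doubled on/off rectifiers and latency-staggered
direction-selective cells with inhomogeneous-Poisson spiking, fully
reproducible from a seed.

## Worked example

```python
import rftomo as rt

# 6 orientations x 21 positions of 0.08-deg bars flashed at 5 Hz
stim = rt.build_stimulus_set(n_orientations=6, n_positions=21,
                             bar_width=0.08, extent=0.84)

# ground-truth magnocellular-like centre-surround cell at (0.1, -0.05) deg
neuron = rt.m_like_neuron(center=(0.1, -0.05))
spikes = rt.simulate_flash_responses(neuron, stim, n_replicates=3, seed=42)

R = rt.build_psth(spikes, bin_width=0.01)
comps = rt.nnmf_decompose(R, k=2, seed=1)
fit = rt.rotate_to_gaussian(comps, stim)

r_corr = rt.correct_bar_width(float(fit.radii[0]), stim.bar_width)
print(f"centre: ({fit.center[0]:.3f}, {fit.center[1]:.3f}) deg")
print(f"centre radius: {fit.radii[0]:.4f} deg "
      f"-> {r_corr:.4f} deg after bar-width correction")
print(f"surround/centre gain ratio: {fit.gains[1] / fit.gains[0]:.3f}")

A = rt.render_projection_matrix(stim)
maps = rt.reconstruct_all(fit, stim, A=A, method="sart")
print(f"map 0: {maps[0].image.shape} pixels, "
      f"SART stopped at iteration {maps[0].iterations}")
```

prints

```
centre: (0.095, -0.050) deg
centre radius: 0.0544 deg -> 0.0538 deg after bar-width correction
surround/centre gain ratio: 0.168
map 0: (63, 63) pixels, SART stopped at iteration 64
```

The fitted centre lands within 0.005° of the planted (0.1, −0.05); the
corrected radius, 0.0538° in the `exp(−(d/4r)²)` convention (Gaussian
σ = 2√2·r ≈ 0.152°), recovers the planted DoG centre (σ = r_c/√2 ≈ 0.17°)
to about 10% from three Poisson replicates.  The gain ratio is the fitted
surround/centre Gaussian amplitude ratio; it is larger for M-like than
P-like cells.  `maps[0]` is the centre-component RF image in degrees;
its negative annulus marks the surround's inhibitory contribution.

The same chain is scriptable from the shell:

```bash
rftomo simulate  --neuron neuron.json --seed 42 --out run/
rftomo pipeline  --spikes run/spikes.csv --stimulus run/stimulus.json \
                 --k 2 --seed 1 --out run/out/
```

which writes the PSTH matrix, component profiles/weights, the rotation fit
(centre, radii, gains, `F`), per-component map CSVs with JSON sidecars, and
a run log.  `rftomo fit-dog` fits the DoG model to a grating f1 curve;
`rftomo reconstruct` maps stored weights.

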