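# Methods

This note documents the models, conventions, numerical choices and known
limitations of `rftomo`.  Empirical figures quoted here are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## Stimulus geometry and the forward model

A mapping run presents long bars at `n_orientations` evenly spaced angles
on [0°, 180°) and `n_positions` perpendicular offsets per angle (default
6 × 21 = 126 bars).  Angles are measured counterclockwise from horizontal;
offsets are signed distances along the +90° normal; all lengths are in
degrees of visual angle.  Adjacent offsets abut by default (spacing = bar
width) — whether real protocols overlap bars is rarely reported, and
abutting tiles the field without redundancy; the spacing is overridable.

The reconstruction grid is square and centred; its resolution defaults to
a pixel size of about one third of the bar width, clamped to 32–128 pixels
per side — fine enough to resolve sub-bar structure without making the
inverse problem needlessly underdetermined.

The forward operator `A` (stimuli × pixels) holds the fraction of each
pixel's area covered by each bar.  Because a strip boundary is a level set
of a linear function, the covered fraction of a square pixel is an
interval probability under the trapezoid distribution of the pixel's
projection onto the bar normal, and is evaluated in closed form.  This is
exact: strip areas are conserved across grid resolutions to machine
precision, and the forward projection of an isotropic Gaussian matches the
erf closed form to ≲0.2% RMS at every orientation (sampled-coverage
schemes leave percent-level aliasing on axis-aligned bars).

## Response decomposition

PSTHs use 10 ms bins by default (≥10 bins per cycle at flash rates up to
10 Hz) over a window that includes 0.2 s of pre-stimulus baseline.  Rates
are `count / (n_replicates × bin_width)`; the pre-stimulus baseline is
*not* subtracted before factorization — baseline handling enters only
through the per-component offsets `b_k` of the rotation model.

NNMF minimizes the Frobenius reconstruction error with multiplicative
updates (scikit-learn's solver) from 10 random non-negative
initializations; sub-seeds derive deterministically from the master seed,
the lowest-error restart wins, and ties break toward the earliest
sub-seed.  Components are ordered by descending explained variance, and
each temporal profile is max-normalized with the compensating scale folded
into its weight row.  NNMF is identifiable only up to a non-negative
mixing cone; planted factorizations are recovered essentially exactly when
weight rows reach zero somewhere (spatially localized components — the
realistic case), and only up to mixtures when they do not.

### Choosing the number of components

Following the incremental-usefulness idea, the count grows from the floor
of two while each added component (identified as the component of the
k+1 decomposition least explainable by the k-component profiles, since
successive decompositions are not nested) passes two tests: a modulation
index (stimulus-window variance over pre-stimulus variance of its profile,
threshold 2) and an orientation-separation index (largest fraction of its
weight mass in one orientation block, threshold 0.6).  The default search
range is capped at 4 components, the most that practice finds
interpretable.  A caveat this package makes explicit: strongly rectified,
high-rate cells generate genuinely stimulus-locked harmonic structure at
every k, so the modulation criterion alone does not terminate on them —
the cap, not the criteria, binds.  On sustained, linear-regime cells the
criteria behave as intended (centre-only cells select 2; centre-surround
cells 2–3).

### The Gaussian rotation

With `W` fixed, the fit solves for the rotation `F` (unit diagonal,
off-diagonal entries ≥ 0, initialized at 0), a shared RF centre, and per-
component gain, radius and baseline minimizing the squared difference
between `(F W)_k,i` and `g_k exp(−(d_i/4r_k)²) + b_k`, where `d_i` is the
perpendicular distance from bar i's midline to the centre.  For k = 2 this
is a 10-parameter problem (2 + 2 + 6); k = 3 adds one (g, r, b) triple and
four more off-diagonals sharing the same centre.  Bounded trust-region
least squares (`scipy.optimize.least_squares`, trf) is run from three
radius-scale starts (0.5×, 1×, 2×); the centre initializes at a weighted
least-squares back-projection of the first component's weights
(soft-thresholded at their median so baseline mass does not drag the
centre to the origin), radii at the weight-profile second moment, gains
and baselines at the row range and minimum.  Gains, radii and baselines
are bounded below at 0 (radius at 10⁻⁴ deg); the returned objective is
never worse than its initialization.  The identity
`(P F⁻¹)(F W) = P W` holds to machine precision by construction.

The radius convention is taken literally from the fitted form
`exp(−(d/4r)²)`: the reported `r` relates to the Gaussian σ by
σ = 2√2·r.  `bar_radius_to_sigma` / `dog_radius_to_sigma` convert both
pipelines to σ before any cross-method comparison (the DoG spatial profile
`exp(−(x/r_c)²)` has σ = r_c/√2).

### First harmonics

`component_f1` projects each profile onto `e^{−2πift}` over the stimulus-on
window truncated to whole cycles, with the amplitude convention that
`A(1 + sin 2πft)` yields f1 = A.  Raw NNMF profiles are the default
(rotated, signed profiles on request): the raw profiles are the directly
estimated quantities and keep f1 independent of rotation-fit quality.

## Tomographic reconstruction

SART iterates `x ← x + λ D_r Aᵀ D_c (y − A x)` from zero with
inverse-row/column-sum scaling; λ defaults to 0.25 and max_iter to 100,
stable semi-convergent settings for noisy 126-bar sinograms at these grid
sizes (on noiseless data λ = 1 with a few thousand iterations converges to
the least-squares solution within 0.5%).  No positivity constraint is
applied — negative map values carry the inhibitory structure the rotation
exposes.  The full iterate and residual history is retained; the
normalized cumulative periodogram (NCP) rule stops at the iteration whose
residual periodogram (zero frequency excluded, cumulated, normalized) is
closest to the white-noise diagonal, by maximum absolute deviation
(Kolmogorov–Smirnov style; an L2 variant is available).  On noisy
phantoms, the NCP-selected iterate is within 1.25× of the oracle-best
iteration in 20/20 noise draws.

Filtered back-projection filters each orientation's offset profile with
ramp × first-order low-pass Butterworth at a normalized corner of 0.8 —
interpreted as 0.8 of the offset-sampling Nyquist frequency, the
convention of the filtered back-projection literature this follows, and
configurable.  Sinograms in strip-coverage units are converted to line
integrals with the factor `pixel_area / bar_width`, so a unit-integral
phantom reconstructs to unit integral within discretization error (0.5%
on a 32×32 grid) and FBP and SART maps are directly comparable (Pearson
r ≈ 0.997 on a noiseless phantom).  Both solvers are linear in the
sinogram (FBP exactly; SART at a fixed iteration count).

Streak ("star") artifacts shrink with orientation count: the phantom RMS
error falls monotonically across 3 → 6 → 12 orientations (0.094 → 0.058 →
0.017 in the acceptance run).

## RF statistics

The DoG first-harmonic model is fit by bounded multi-start least squares,
parameterized as (k_c, k_s, r_c, r_s − r_c) so the surround is always
broader than the centre; centre-radius starts span 0.01°–1° in decade
steps with surround-free and moderate-surround gain starts.  Noiseless
curves are recovered to 10⁻⁴ relative; with noise at 5% of peak the median
r_c error over 50 draws is ≈2%.

**Bar-width correction.**  The weight profile measured with bars of width
w is the underlying radial Gaussian convolved with the bar's boxcar
cross-section.  No published closed form exists for removing this, so the
package uses variance matching: σ² = 8r² for the fitted Gaussian and
w²/12 for the boxcar give `r_corr = sqrt(r_fit² − w²/96)`, clamped at
w/20 (with a warning) when the fit is narrower than the bar allows.  The
correction has the right limits (identity at w = 0, factor → 1 for
r ≫ w), is monotone in both arguments, and reconciles 3:1 bar-width
remappings of the same simulated cell to within 2% where the uncorrected
radii differ by ~15%.  It is deliberately isolated in one function.

**Anatomy correlation.**  Dendritic-density rasters are Gaussian-blurred
with a fitted half-height radius h (σ = h/√(2 ln 2)) — modelling the
lateral spread introduced by presynaptic circuitry — then regressed
affinely onto the RF map, one point per overlapping pixel; h minimizes the
squared error (bounded scalar search) and the coefficient of
determination r² is reported at the optimum.  Registration is taken from
metadata; no automatic image alignment is attempted.  On synthetic
blur-and-noise constructions a planted h = 50 μm is recovered to a few
percent.

## The synthetic neurons

Three archetypes, with frozen factory parameter sets used as the study
conditions throughout the tests (`p_like_neuron`, `m_like_neuron`,
`onoff_like_neuron`, `direction_selective_neuron`):

* **Linear centre-surround** — drive is the exact strip integral of a DoG
  over the bar footprint, modulated by the square-wave flash convolved
  with a biphasic difference-of-gammas kernel (τ 12/24 ms, undershoot 0.7;
  the data this emulates do not constrain the kernel — any phase-locking
  kernel serves), then rectified about a 15 imp/s baseline.  P-like:
  r_c = 0.08°, integrated surround/centre ≈ 0.3; M-like: r_c = 0.24°,
  ≈ 0.55 — typical parafoveal primate values, with gains giving 50–250
  imp/s peak evoked rates.
* **On/off rectifier** — two half-wave-rectified subunit pools: a
  transient ON pathway whose gain decays with τ = 0.5 s (the adapting
  term; the decay rate is a free choice, flagged in the factory) and a
  sustained OFF pathway, with concentric Gaussian pools at 0.75×/1.25× of
  a 0.3° nominal radius, fast kinetics (τ 6/12 ms, fully biphasic) and a
  2 imp/s maintained rate.  The summed response is frequency-doubled.  The
  polarity split is a deliberate identifiability choice: with identical
  full-wave drives the adapting/sustained factorization admits a continuum
  of equivalent non-negative solutions, so no factorization method could
  recover the planted structure.
* **Direction-selective** — two (or more) spatially offset Gaussian
  subfields with staggered response latencies (default 0.25° separation,
  60 ms step), each driving a rectified response.

Spikes are an inhomogeneous Poisson process generated by time rescaling on
a 1 ms rate grid (exact at these rates); replicate counts have Fano
factors within [0.8, 1.25] as expected, and identical seeds give
bit-identical spike data.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real recordings: spike-sorting contamination, slow
nonstationarities (adaptation across the session, eye movements),
correlated (non-Poisson) spiking, optics, and surround mechanisms beyond
the DoG (extra-classical suppression).  The end-to-end recovery figures
(centre within a bar width; corrected radius within ~10–15% at three
replicates) therefore bound the method's statistical, not systematic,
error.  One systematic effect is visible even in simulation: rectified
centre-phase weights are narrowed by surround subtraction, biasing
recovered centre σ low by roughly 10% at realistic surround strengths —
consistent with bar- and grating-derived radii correlating near-perfectly
(r ≈ 0.99 across a 20-cell synthetic population) while individual radii
sit slightly below truth.

## Chromatic runs

Responses to per-channel (e.g. S- and ML-cone-isolating) stimulus blocks
are concatenated along the stimulus axis and factorized jointly: one set
of temporal profiles, one weight block per channel
(`nnmf_decompose_joint`), each block reconstructed independently on the
shared geometry.  Block order is channel-major and preserved everywhere.

## File conventions

Stimulus and replicate indices are 1-based on disk and 0-based in memory,
converted only at the I/O boundary; spike times are seconds relative to
stimulus onset (negative in the pre-stimulus window).  Every matrix CSV
carries a JSON sidecar (grid extent, pixel size, units, method, iteration
count) sufficient to re-derive its geometry without the run
configuration.

## Problem sizes

The test suite and acceptance script run the full protocol (126 bars, 2 s
at 5 Hz, 3–10 Poisson replicates) with 32–63-pixel grids, 5–20 seed
repetitions per statistical claim, 50 draws for noisy DoG refits and a
20-cell population for the cross-method comparison — sizes at which every
quantity is stable to well within its stated tolerance while the whole
suite completes in a few minutes.

## Known limitations

* The rotation model describes each rotated weight row as a single radial
  Gaussian; annular surround-phase rows are only approximately Gaussian
  after rotation, so surround radii are markedly noisier than centre
  radii at low replicate counts.
* The NCP rule assumes residual whiteness is a good proxy for optimal
  stopping; sinograms with strongly correlated noise would need the L2
  variant or manual iteration caps.
* Excitatory and suppressive contributions to the surround are not
  separated — the rotation exposes signed structure but remains a
  model-based (Gaussian-compactness) decomposition.
* `select_k` on strongly rectified cells is cap-limited (see above);
  treat component counts above 3 as exploratory.
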