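"""Ground-truth model neurons and inhomogeneous-Poisson spike generation.

Three response archetypes, spanning the receptive-field classes the
flashed-bar tomography pipeline is designed to resolve:

``linear_dog``
    A linear centre-surround cell.  The spatial sensitivity is a
    difference of Gaussians (DoG); the drive to a bar is the integral of
    the DoG over the bar footprint, modulated in time by the square-wave
    flash convolved with a biphasic (difference-of-gammas) kernel.
``onoff_rectifier``
    A nonlinear cell responding to both contrast polarities.  The linear
    drive is full-wave rectified, producing frequency-doubled responses,
    and is split into an exponentially adapting and a sustained gain term
    with coextensive (slightly different-radius) Gaussian spatial pools.
``direction_selective``
    Two or more spatially offset Gaussian subfields with staggered
    response latencies, the minimal model of a direction-selective cell.

Spikes are drawn as an inhomogeneous Poisson process by time rescaling on
a 1 ms grid, so every simulation is exactly reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, gammaln

from .geometry import StimulusSet, bar_center_distance

__all__ = [
    "DoGParams",
    "GaussianSubfield",
    "NeuronSpec",
    "SpikeData",
    "dog_f1",
    "simulate_grating_f1",
    "simulate_flash_responses",
    "gaussian_strip_integral",
    "dog_strip_integral",
    "biphasic_kernel",
    "p_like_neuron",
    "m_like_neuron",
    "onoff_like_neuron",
    "direction_selective_neuron",
]

SPIKE_DT = 1e-3  # s; rate-function resolution for time rescaling


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians receptive field.

    Spatial sensitivity ``kc exp(-(r/rc)^2) - ks exp(-(r/rs)^2)`` with
    centre/surround gains ``kc, ks`` (impulses/s per unit contrast per
    square degree) and radii ``rc < rs`` (degrees).  Its first-harmonic
    response to a drifting grating of spatial frequency ``w`` (cycles per
    degree) is

        K(w) = pi kc rc^2 exp(-(pi rc w)^2) - pi ks rs^2 exp(-(pi rs w)^2).
    """

    kc: float
    ks: float
    rc: float
    rs: float

    def __post_init__(self) -> None:
        if self.rc <= 0:
            raise ValueError(f"rc must be positive, got {self.rc}")
        if self.rs <= self.rc:
            raise ValueError(f"rs must exceed rc, got rs={self.rs}, rc={self.rc}")
        if self.kc <= 0:
            raise ValueError(f"kc must be positive, got {self.kc}")
        if self.ks < 0:
            raise ValueError(f"ks must be non-negative, got {self.ks}")

    @property
    def gain_ratio(self) -> float:
        """Surround-to-centre gain ratio ks/kc."""
        return self.ks / self.kc


@dataclass(frozen=True)
class GaussianSubfield:
    """One Gaussian input pool: ``gain * exp(-(r/radius)^2)`` about ``center``,
    driving the cell with an extra response ``latency`` (seconds)."""

    center: tuple[float, float]
    radius: float
    gain: float
    latency: float = 0.0


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth parameters for one simulated neuron.

    Shared fields: ``center`` (receptive-field centre, degrees),
    ``latency`` (response latency, s), biphasic-kernel time constants
    ``tau_fast``/``tau_slow`` and negative-lobe weight ``kernel_balance``,
    and ``baseline_rate`` (impulses/s; output is half-wave rectified at
    zero).  Kind-specific fields:

    * ``linear_dog`` — ``dog`` holds the DoG spatial model.
    * ``onoff_rectifier`` — ``onoff_gain_adapt``/``onoff_gain_sustained``
      scale the adapting (ON half-wave) and sustained (OFF half-wave)
      subunit pathways, ``onoff_radius`` their nominal Gaussian pool
      radius (adapting pool 0.75x, sustained 1.25x; transient and
      sustained circuits sample different-sized pools),
      ``adaptation_tau`` the adapting term's decay constant (s).
    * ``direction_selective`` — ``subfields`` lists spatially offset
      Gaussian pools with staggered latencies.
    """

    kind: str
    dog: DoGParams | None = None
    center: tuple[float, float] = (0.0, 0.0)
    subfields: tuple[GaussianSubfield, ...] | None = None
    latency: float = 0.03
    tau_fast: float = 0.012
    tau_slow: float = 0.024
    kernel_balance: float = 0.7
    baseline_rate: float = 10.0
    adaptation_tau: float = 0.5
    onoff_gain_adapt: float = 1.0
    onoff_gain_sustained: float = 0.6
    onoff_radius: float = 0.3

    _KINDS = ("linear_dog", "onoff_rectifier", "direction_selective")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown neuron kind {self.kind!r}; one of {self._KINDS}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        for name in ("tau_fast", "tau_slow", "adaptation_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kind == "linear_dog" and self.dog is None:
            raise ValueError("linear_dog neuron requires dog parameters")
        if self.kind == "direction_selective":
            if not self.subfields or len(self.subfields) < 2:
                raise ValueError("direction_selective requires >= 2 subfields")
            object.__setattr__(self, "subfields", tuple(self.subfields))


@dataclass(frozen=True)
class SpikeData:
    """Spike events from a flashed-bar run.

    ``stimulus_index`` and ``replicate`` are 0-based internally (file I/O
    converts to the 1-based on-disk convention); ``times`` are seconds
    relative to stimulus onset, negative in the pre-stimulus window.
    """

    stimulus_index: np.ndarray
    replicate: np.ndarray
    times: np.ndarray
    n_replicates: int
    stimulus_set: StimulusSet = field(repr=False)
    window: tuple[float, float] = (-0.2, 2.2)
    seed: int | None = None

    def __post_init__(self) -> None:
        si = np.asarray(self.stimulus_index, dtype=int)
        rep = np.asarray(self.replicate, dtype=int)
        t = np.asarray(self.times, dtype=float)
        if not (si.shape == rep.shape == t.shape):
            raise ValueError("stimulus_index, replicate and times must align")
        if si.size and (si.min() < 0 or si.max() >= self.stimulus_set.s):
            raise ValueError("stimulus_index out of range for the stimulus set")
        order = np.lexsort((t, rep, si))
        object.__setattr__(self, "stimulus_index", si[order])
        object.__setattr__(self, "replicate", rep[order])
        object.__setattr__(self, "times", t[order])

    @property
    def n_spikes(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# closed forms


def dog_f1(dog: DoGParams, spatial_frequency) -> np.ndarray:
    """First-harmonic grating response ``K(w)`` of a DoG receptive field."""
    w = np.asarray(spatial_frequency, dtype=float)
    if np.any(w < 0):
        raise ValueError("spatial frequency must be non-negative")
    kc_term = np.pi * dog.kc * dog.rc**2 * np.exp(-((np.pi * dog.rc * w) ** 2))
    ks_term = np.pi * dog.ks * dog.rs**2 * np.exp(-((np.pi * dog.rs * w) ** 2))
    return kc_term - ks_term


def gaussian_strip_integral(d, width: float, radius: float, gain: float = 1.0):
    """Integral of ``gain * exp(-(r/radius)^2)`` over an infinite strip.

    ``d`` is the perpendicular distance from the strip midline to the
    Gaussian centre, ``width`` the strip width.  Along-bar integration is
    analytic (``sqrt(pi) * radius``), across-bar uses erf::

        (pi gain radius^2 / 2) * [erf((d + w/2)/radius) - erf((d - w/2)/radius)]
    """
    d = np.asarray(d, dtype=float)
    return (
        0.5
        * np.pi
        * gain
        * radius**2
        * (erf((d + width / 2) / radius) - erf((d - width / 2) / radius))
    )


def dog_strip_integral(d, width: float, dog: DoGParams):
    """Signed DoG drive to a bar at perpendicular centre distance ``d``."""
    return gaussian_strip_integral(d, width, dog.rc, dog.kc) - gaussian_strip_integral(
        d, width, dog.rs, dog.ks
    )


def biphasic_kernel(
    t: np.ndarray,
    tau_fast: float,
    tau_slow: float,
    balance: float,
    n_stages: int = 5,
) -> np.ndarray:
    """Difference-of-gammas temporal impulse response, peak-normalized.

    ``g(t; n, tau) proportional to t^(n-1) exp(-t/tau)`` — a fast positive
    lobe minus ``balance`` times a slower copy, the standard biphasic
    shape of early-visual impulse responses.
    """
    t = np.asarray(t, dtype=float)

    def gamma_pdf(tau: float) -> np.ndarray:
        out = np.zeros_like(t)
        pos = t > 0
        logp = (
            (n_stages - 1) * np.log(t[pos] / tau)
            - t[pos] / tau
            - np.log(tau)
            - gammaln(n_stages)
        )
        out[pos] = np.exp(logp)
        return out

    k = gamma_pdf(tau_fast) - balance * gamma_pdf(tau_slow)
    peak = np.max(np.abs(k))
    return k / peak if peak > 0 else k


# ---------------------------------------------------------------------------
# rate construction


def _square_contrast(t: np.ndarray, frequency: float, duration: float) -> np.ndarray:
    """Square-wave flash contrast: 1 while the bar is shown, 0 otherwise."""
    phase = np.mod(t * frequency, 1.0)
    on = (t >= 0) & (t < duration) & (phase < 0.5)
    return on.astype(float)


def _linear_drive(
    t: np.ndarray,
    frequency: float,
    duration: float,
    latency: float,
    tau_fast: float,
    tau_slow: float,
    balance: float,
) -> np.ndarray:
    """Flash contrast convolved with the biphasic kernel, latency applied."""
    dt = t[1] - t[0]
    c = _square_contrast(t - latency, frequency, duration)
    k_t = np.arange(0, 8 * tau_slow, dt)
    kernel = biphasic_kernel(k_t, tau_fast, tau_slow, balance)
    drive = np.convolve(c, kernel)[: t.size] * dt
    # normalize so a sustained step drives a unit peak response
    peak = np.max(np.cumsum(kernel) * dt)
    return drive / peak if peak > 0 else drive


def rate_functions(
    neuron: NeuronSpec,
    stimulus_set: StimulusSet,
    window: tuple[float, float],
    dt: float = SPIKE_DT,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous firing rate (impulses/s) per stimulus on a time grid.

    Returns ``(t, rates)`` with ``rates`` of shape ``(s, len(t))``.  This
    is the simulator's ground truth; tests compare empirical PSTHs
    against it directly.
    """
    t0, t1 = window
    t = np.arange(t0, t1, dt)
    bar = stimulus_set.bars[0]
    freq, dur, width = bar.temporal_frequency, bar.duration, bar.width

    kin = (neuron.latency, neuron.tau_fast, neuron.tau_slow, neuron.kernel_balance)
    if neuron.kind == "linear_dog":
        d = bar_center_distance(stimulus_set, neuron.center)
        spatial = dog_strip_integral(d, width, neuron.dog)  # (s,)
        drive = _linear_drive(t, freq, dur, *kin)  # (T,)
        rates = neuron.baseline_rate + spatial[:, None] * drive[None, :]
    elif neuron.kind == "onoff_rectifier":
        # two half-wave-rectified subunit pools: a transient (adapting) ON
        # pathway and a sustained OFF pathway.  The cell responds to both
        # contrast polarities, so the summed PSTH is frequency doubled; the
        # polarity split keeps the two terms separable by factorization.
        d = bar_center_distance(stimulus_set, neuron.center)
        s_adapt = gaussian_strip_integral(
            d, width, 0.75 * neuron.onoff_radius, neuron.onoff_gain_adapt
        )
        s_sust = gaussian_strip_integral(
            d, width, 1.25 * neuron.onoff_radius, neuron.onoff_gain_sustained
        )
        lin = _linear_drive(t, freq, dur, *kin)
        on = np.maximum(lin, 0.0)
        off = np.maximum(-lin, 0.0)
        envelope = np.where(t >= 0, np.exp(-np.maximum(t, 0) / neuron.adaptation_tau), 1.0)
        rates = (
            neuron.baseline_rate
            + s_adapt[:, None] * (on * envelope)[None, :]
            + s_sust[:, None] * off[None, :]
        )
    elif neuron.kind == "direction_selective":
        rates = np.full((stimulus_set.s, t.size), float(neuron.baseline_rate))
        for sf in neuron.subfields:
            d = bar_center_distance(stimulus_set, sf.center)
            spatial = gaussian_strip_integral(d, width, sf.radius, sf.gain)
            drive = _linear_drive(
                t,
                freq,
                dur,
                neuron.latency + sf.latency,
                neuron.tau_fast,
                neuron.tau_slow,
                neuron.kernel_balance,
            )
            rates = rates + spatial[:, None] * np.maximum(drive, 0.0)[None, :]
    else:  # pragma: no cover - guarded in NeuronSpec
        raise ValueError(f"unknown neuron kind {neuron.kind!r}")

    return t, np.maximum(rates, 0.0)


# ---------------------------------------------------------------------------
# spike generation


def _poisson_times(rate: np.ndarray, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw an inhomogeneous Poisson spike train by time rescaling."""
    dt = t[1] - t[0]
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    total = cum[-1]
    if total <= 0:
        return np.empty(0)
    n = rng.poisson(total)
    if n == 0:
        return np.empty(0)
    u = np.sort(rng.uniform(0.0, total, n))
    edges = np.concatenate([t, [t[-1] + dt]])
    return np.interp(u, cum, edges)


def simulate_flash_responses(
    neuron: NeuronSpec,
    stimulus_set: StimulusSet,
    n_replicates: int,
    seed: int,
    window: tuple[float, float] | None = None,
) -> SpikeData:
    """Simulate spike responses of ``neuron`` to every bar in the set.

    The analysis window defaults to 0.2 s of pre-stimulus baseline through
    0.2 s past stimulus offset.  Spike generation is an inhomogeneous
    Poisson process (time rescaling, 1 ms rate resolution); the same seed
    gives bit-identical output.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if window is None:
        window = (-0.2, stimulus_set.duration + 0.2)
    t, rates = rate_functions(neuron, stimulus_set, window)
    rng_streams = np.random.SeedSequence(seed).spawn(stimulus_set.s * n_replicates)

    idx: list[np.ndarray] = []
    reps: list[np.ndarray] = []
    times: list[np.ndarray] = []
    for i in range(stimulus_set.s):
        for r in range(n_replicates):
            rng = np.random.default_rng(rng_streams[i * n_replicates + r])
            spk = _poisson_times(rates[i], t, rng)
            idx.append(np.full(spk.size, i))
            reps.append(np.full(spk.size, r))
            times.append(spk)
    return SpikeData(
        stimulus_index=np.concatenate(idx) if idx else np.empty(0, int),
        replicate=np.concatenate(reps) if reps else np.empty(0, int),
        times=np.concatenate(times) if times else np.empty(0),
        n_replicates=n_replicates,
        stimulus_set=stimulus_set,
        window=window,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# canonical model cells
#
# One parameter set per archetype, used by the tests and the acceptance
# pipeline as the fixed study conditions.  Gains give bar-evoked peak rates
# in the 50-250 impulses/s range typical of well-driven early-visual
# neurons; P/M radii and surround strengths follow typical parafoveal
# primate values (P centre small with weak integrated surround, M centre
# about 3x larger with a stronger surround); the K-like rectifier has a low
# maintained rate and fast subunit kinetics.


def p_like_neuron(center: tuple[float, float] = (0.0, 0.0)) -> NeuronSpec:
    """Parvocellular-like linear cell: small centre, weak surround."""
    return NeuronSpec(
        kind="linear_dog",
        dog=DoGParams(kc=20000.0, ks=380.0, rc=0.08, rs=0.32),
        center=center,
        baseline_rate=15.0,
    )


def m_like_neuron(center: tuple[float, float] = (0.0, 0.0)) -> NeuronSpec:
    """Magnocellular-like linear cell: larger centre, stronger surround."""
    return NeuronSpec(
        kind="linear_dog",
        dog=DoGParams(kc=4000.0, ks=244.0, rc=0.24, rs=0.72),
        center=center,
        baseline_rate=15.0,
    )


def onoff_like_neuron(center: tuple[float, float] = (0.0, 0.0)) -> NeuronSpec:
    """K-on/off-like rectifying cell: frequency-doubled, adapting + sustained."""
    return NeuronSpec(
        kind="onoff_rectifier",
        center=center,
        baseline_rate=2.0,
        tau_fast=0.006,
        tau_slow=0.012,
        kernel_balance=1.0,
        onoff_radius=0.3,
        onoff_gain_adapt=3600.0,
        onoff_gain_sustained=1800.0,
        adaptation_tau=0.5,
    )


def direction_selective_neuron(
    center: tuple[float, float] = (0.0, 0.0),
    subfield_offset: float = 0.25,
    latency_step: float = 0.06,
) -> NeuronSpec:
    """Two latency-staggered subfields displaced along the y axis."""
    x0, y0 = center
    return NeuronSpec(
        kind="direction_selective",
        center=center,
        baseline_rate=5.0,
        subfields=(
            GaussianSubfield(center=(x0, y0 + subfield_offset / 2), radius=0.2, gain=2500.0),
            GaussianSubfield(
                center=(x0, y0 - subfield_offset / 2),
                radius=0.2,
                gain=2500.0,
                latency=latency_step,
            ),
        ),
    )


def simulate_grating_f1(
    dog: DoGParams,
    spatial_frequencies,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """First-harmonic grating responses with additive Gaussian noise.

    ``noise_sd = 0`` returns the exact DoG curve ``K(w)``.
    """
    k = dog_f1(dog, spatial_frequencies)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        k = k + rng.normal(0.0, noise_sd, size=np.shape(k))
    return k
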