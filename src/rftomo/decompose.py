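"""PSTH construction, non-negative factorization and the Gaussian rotation.

The response to the flashed-bar protocol is summarised as a matrix
``R[i, t]`` of per-stimulus peristimulus time histograms (PSTHs).  It is
factorized as ``R ~ P W`` with non-negative temporal profiles ``P[t, k]``
and spatial weights ``W[k, i]``; because of the non-negativity constraint
these components capture only excitatory contributions.  Signed
(excitatory/inhibitory) mechanisms are exposed by relaxing the constraint
through a rotation matrix ``F`` (unit diagonal, non-negative elsewhere)::

    R ~ P W = (P F^-1)(F W),

where ``F`` is chosen so each rotated weight row ``(F W)_k`` is a compact
radial Gaussian of the bar-to-centre distance ``d_i``::

    (F W)_k = g_k exp(-(d_i / (4 r_k))^2) + b_k.

For the two-component centre-surround case this model has exactly 10 free
parameters: two off-diagonal entries of ``F``, the receptive-field centre
``(x0, y0)``, and a gain, radius and baseline per component.  The rotated
profiles ``P F^-1`` may then go negative, revealing inhibition, while the
rotated weights stay non-negative and tomographically reconstructable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.decomposition import NMF

from .geometry import StimulusSet, bar_center_distance
from .simulate import SpikeData

__all__ = [
    "ResponseMatrix",
    "ComponentSet",
    "RotationFit",
    "build_psth",
    "nnmf_decompose",
    "nnmf_decompose_joint",
    "select_k",
    "rotate_to_gaussian",
    "component_f1",
    "PSTHNMF",
    "GaussianRotation",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Per-stimulus PSTHs ``R[i, t]`` in impulses/s.

    ``window`` is (start, end) in seconds relative to stimulus onset and
    normally includes a pre-stimulus baseline segment (negative start).
    """

    rates: np.ndarray
    bin_width: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 2:
            raise ValueError("rates must be a 2-D (stimuli x time) array")
        if np.any(r < 0):
            raise ValueError("PSTH rates must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "rates", r)

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Bin-centre times, seconds relative to stimulus onset."""
        return self.window[0] + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class ComponentSet:
    """Non-negative factorization ``R ~ P W``.

    ``profiles`` is ``(T, k)`` in impulses/s (each column max-normalized to
    1, with the compensating scale folded into its weight row);
    ``weights`` is ``(k, s)``, dimensionless.  Components are ordered by
    descending explained variance.
    """

    profiles: np.ndarray
    weights: np.ndarray
    bin_width: float
    window: tuple[float, float]
    reconstruction_error: float = np.nan

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if p.shape[1] != w.shape[0]:
            raise ValueError("profiles and weights disagree on component count")
        object.__setattr__(self, "profiles", p)
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return self.profiles.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + (np.arange(self.profiles.shape[0]) + 0.5) * self.bin_width

    def reconstruct(self) -> np.ndarray:
        """``(P W)^T``: the rank-k approximation of ``R[i, t]``."""
        return (self.profiles @ self.weights).T


@dataclass(frozen=True)
class RotationFit:
    """Result of the radial-Gaussian rotation refit.

    ``F`` has unit diagonal and non-negative off-diagonal entries;
    ``rotated_profiles = P F^-1`` (signed), ``rotated_weights = F W``
    (non-negative).  ``gains``, ``radii`` (degrees, in the
    ``exp(-(d/4r)^2)`` convention) and ``baselines`` parameterize each
    rotated weight row as a Gaussian of centre distance.
    """

    F: np.ndarray
    center: tuple[float, float]
    gains: np.ndarray
    radii: np.ndarray
    baselines: np.ndarray
    rotated_profiles: np.ndarray
    rotated_weights: np.ndarray
    components: ComponentSet = field(repr=False)
    objective: float = np.nan
    objective_init: float = np.nan
    converged: bool = True

    @property
    def k(self) -> int:
        return self.F.shape[0]

    @property
    def n_free_parameters(self) -> int:
        """Off-diagonal F entries + centre coordinates + (g, r, b) per component."""
        k = self.k
        return k * (k - 1) + 2 + 3 * k

    def model_weights(self, stimulus_set: StimulusSet) -> np.ndarray:
        """Gaussian model prediction of ``F W`` for each stimulus."""
        d = bar_center_distance(stimulus_set, self.center)
        return radial_gaussian(d, self.gains[:, None], self.radii[:, None], self.baselines[:, None])


def radial_gaussian(d, gain, radius, baseline):
    """``gain * exp(-(d / (4 radius))^2) + baseline``.

    The printed-radius convention: the Gaussian's sigma is ``2 sqrt(2) r``.
    """
    d = np.asarray(d, dtype=float)
    return gain * np.exp(-((d / (4.0 * radius)) ** 2)) + baseline


# ---------------------------------------------------------------------------
# PSTH


def build_psth(
    spikes: SpikeData,
    bin_width: float = 0.01,
    window: tuple[float, float] | None = None,
) -> ResponseMatrix:
    """Bin spikes into per-stimulus, replicate-averaged PSTHs.

    Rate in a bin is ``count / (n_replicates * bin_width)`` in impulses/s.
    The default 10 ms bin gives at least 10 bins per cycle at flash rates
    up to 10 Hz.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if window is None:
        window = spikes.window
    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_width))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    s = spikes.stimulus_set.s
    rates = np.zeros((s, n_bins))
    if spikes.n_spikes == 0:
        warnings.warn("no spikes: PSTH is all zero", stacklevel=2)
    else:
        for i in range(s):
            mask = spikes.stimulus_index == i
            counts, _ = np.histogram(spikes.times[mask], bins=edges)
            rates[i] = counts / (spikes.n_replicates * bin_width)
    return ResponseMatrix(rates=rates, bin_width=bin_width, window=(t0, t0 + n_bins * bin_width))


# ---------------------------------------------------------------------------
# NNMF


class PSTHNMF(BaseEstimator):
    """Non-negative factorization of a PSTH matrix with restarts.

    Thin estimator around :class:`sklearn.decomposition.NMF`
    (multiplicative-update, Frobenius loss): ``n_restarts`` random
    non-negative initializations with sub-seeds derived from
    ``random_state``, keeping the factorization with the lowest
    reconstruction error (ties broken by the earliest sub-seed).
    Components are then ordered by descending explained variance and each
    profile column is max-normalized, scaling its weight row to
    compensate.

    Attributes (after ``fit``): ``profiles_`` (T, k), ``weights_`` (k, s),
    ``reconstruction_err_``, ``explained_variance_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 10,
        max_iter: int = 1000,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, R, y=None) -> "PSTHNMF":
        X = R.rates if isinstance(R, ResponseMatrix) else np.asarray(R, dtype=float)
        if np.any(X < 0):
            raise ValueError("response matrix must be non-negative")
        s, T = X.shape
        k = self.n_components
        if not 2 <= k <= min(s, T):
            raise ValueError(f"n_components must be in [2, min(s, T)] = [2, {min(s, T)}]")

        # R[i, t] ~ P[t, k] W[k, i]  <=>  X.T ~ P @ W
        seeds = np.random.SeedSequence(self.random_state).generate_state(self.n_restarts)
        best: tuple[float, int, np.ndarray, np.ndarray] | None = None
        for j, sub in enumerate(seeds):
            model = NMF(
                n_components=k,
                init="random",
                solver="mu",
                beta_loss="frobenius",
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=int(sub) % (2**32 - 1),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence warnings per restart
                P = model.fit_transform(X.T)
            W = model.components_
            err = model.reconstruction_err_
            if best is None or err < best[0] - 1e-12:
                best = (err, j, P, W)
        assert best is not None
        err, _, P, W = best

        # order by descending explained variance (energy of each rank-1 term)
        energy = np.linalg.norm(P, axis=0) ** 2 * np.linalg.norm(W, axis=1) ** 2
        order = np.argsort(energy)[::-1]
        P, W = P[:, order], W[order]
        # max-normalize profiles, fold scale into weights
        scale = P.max(axis=0)
        scale[scale == 0] = 1.0
        P = P / scale
        W = W * scale[:, None]

        self.profiles_ = P
        self.weights_ = W
        self.reconstruction_err_ = float(err)
        total = np.linalg.norm(X) ** 2
        self.explained_variance_ = 1.0 - err**2 / total if total > 0 else 0.0
        return self

    def to_components(self, R: ResponseMatrix) -> ComponentSet:
        return ComponentSet(
            profiles=self.profiles_,
            weights=self.weights_,
            bin_width=R.bin_width,
            window=R.window,
            reconstruction_error=self.reconstruction_err_,
        )


def nnmf_decompose(
    R: ResponseMatrix,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 10,
) -> ComponentSet:
    """Factorize ``R ~ P W`` with ``k`` non-negative components.

    Wrapper over :class:`PSTHNMF`; see its docstring for the restart and
    normalization policy.
    """
    est = PSTHNMF(
        n_components=k, n_restarts=n_restarts, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(R)
    return est.to_components(R)


def nnmf_decompose_joint(
    responses: dict[str, ResponseMatrix],
    k: int,
    seed: int = 0,
    **kwargs,
) -> tuple[ComponentSet, dict[str, np.ndarray]]:
    """Jointly factorize per-channel response matrices with shared profiles.

    For chromatic runs the same bar geometry is presented through several
    chromatic channels (e.g. S-cone- and ML-cone-isolating stimuli).  The
    channel blocks are concatenated along the stimulus axis (channel-major,
    insertion order of ``responses``) and factorized together, yielding
    common temporal profiles but distinct spatial weights per channel.
    Returns the concatenated :class:`ComponentSet` and a mapping from
    channel label to its ``(k, s)`` weight block.
    """
    labels = list(responses)
    mats = [responses[c] for c in labels]
    first = mats[0]
    if any(m.rates.shape[1] != first.rates.shape[1] for m in mats):
        raise ValueError("channel response matrices disagree on time bins")
    stacked = ResponseMatrix(
        rates=np.concatenate([m.rates for m in mats], axis=0),
        bin_width=first.bin_width,
        window=first.window,
    )
    comps = nnmf_decompose(stacked, k, seed=seed, **kwargs)
    blocks: dict[str, np.ndarray] = {}
    start = 0
    for label, m in zip(labels, mats):
        blocks[label] = comps.weights[:, start : start + m.n_stimuli]
        start += m.n_stimuli
    return comps, blocks


# ---------------------------------------------------------------------------
# component-count selection


def modulation_index(profile: np.ndarray, times: np.ndarray) -> float:
    """Stimulus-window variance over pre-stimulus variance of a profile.

    A component whose profile does not change from pre-stimulus to
    stimulus carries no stimulus-driven signal; its index stays near 1.
    """
    pre = profile[times < 0]
    stim = profile[times >= 0]
    if pre.size < 2 or stim.size < 2:
        return np.inf
    v_pre = max(pre.var(), 1e-12 * max(stim.var(), 1.0))
    return float(stim.var() / v_pre)


def orientation_separation_index(weights_row: np.ndarray, stimulus_set: StimulusSet) -> float:
    """Largest fraction of a weight row's mass in one orientation block.

    Near ``1 / n_orientations`` for orientation-balanced components; near
    1 when a component merely splits off one orientation's responses.
    """
    w = np.abs(np.asarray(weights_row, dtype=float))
    total = w.sum()
    if total == 0:
        return 1.0
    blocks = stimulus_set.orientation_blocks()
    return float(max(w[idx].sum() for idx in blocks.values()) / total)


def select_k(
    R: ResponseMatrix,
    stimulus_set: StimulusSet,
    k_range: tuple[int, int] = (2, 4),
    tau_mod: float = 2.0,
    tau_orient: float = 0.6,
    seed: int = 0,
    n_restarts: int = 10,
) -> int:
    """Choose the number of components by the incremental-usefulness rule.

    Starting from the floor of two components, the count is increased
    while each added component both (1) is stimulus-modulated (modulation
    index >= ``tau_mod``) and (2) does not merely separate orientations
    (orientation-separation index <= ``tau_orient``).  The first added
    component failing either test stops the search and the previous count
    is returned.
    """
    k_lo, k_hi = k_range
    k_lo = max(2, k_lo)
    k_hi = min(k_hi, min(R.n_stimuli, R.n_bins))
    k = k_lo
    comps_k = nnmf_decompose(R, k, seed=seed, n_restarts=n_restarts)
    while k < k_hi:
        comps_next = nnmf_decompose(R, k + 1, seed=seed, n_restarts=n_restarts)
        # decompositions at k and k+1 are not nested; the "added" component
        # is the one least explainable by the k-component temporal profiles
        Q, _ = np.linalg.qr(comps_k.profiles)
        P1 = comps_next.profiles
        resid = P1 - Q @ (Q.T @ P1)
        norms = np.linalg.norm(P1, axis=0)
        novelty = np.linalg.norm(resid, axis=0) / np.where(norms > 0, norms, 1.0)
        j = int(np.argmax(novelty))
        prof = comps_next.profiles[:, j]
        wrow = comps_next.weights[j]
        if modulation_index(prof, comps_next.times) < tau_mod:
            return k
        if orientation_separation_index(wrow, stimulus_set) > tau_orient:
            return k
        k += 1
        comps_k = comps_next
    return k


# ---------------------------------------------------------------------------
# Gaussian rotation


def _center_from_sinogram(weights_row: np.ndarray, stimulus_set: StimulusSet) -> np.ndarray:
    """Back-project a weight row to an initial centre estimate.

    Each bar constrains the centre to lie near its midline in proportion
    to its weight: minimize ``sum_i w_i (n_i . c - q_i)^2`` over ``c``,
    with weights soft-thresholded at their median so the baseline does
    not drag the centre to the origin.
    """
    w = np.clip(weights_row - np.median(weights_row), 0.0, None)
    if w.sum() == 0:
        w = np.abs(weights_row)
    if w.sum() == 0:
        return np.zeros(2)
    th = np.deg2rad(stimulus_set.orientations)
    n = np.stack([-np.sin(th), np.cos(th)], axis=1)
    q = stimulus_set.offsets
    M = (n * w[:, None]).T @ n
    rhs = (n * w[:, None]).T @ q
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        return np.zeros(2)


class GaussianRotation(BaseEstimator):
    """Constrained refit of NNMF weights under the radial-Gaussian model.

    Solves, by bounded trust-region nonlinear least squares, for the
    rotation ``F`` (unit diagonal, off-diagonals >= 0 initialized at 0),
    the shared receptive-field centre, and per-component gain, radius and
    baseline, minimizing::

        sum_{k,i} [ (F W)_{k,i} - (g_k exp(-(d_i/(4 r_k))^2) + b_k) ]^2.

    The centre is initialized at the back-projected centroid of the first
    component's weights; several radius-scale starts guard against the
    radius local minima of the Gaussian model.

    Attributes (after ``fit``): ``F_``, ``center_``, ``gains_``,
    ``radii_``, ``baselines_``, ``rotated_profiles_``,
    ``rotated_weights_``, ``objective_``.
    """

    def __init__(
        self,
        stimulus_set: StimulusSet = None,
        radius_starts: tuple[float, ...] = (0.5, 1.0, 2.0),
        max_nfev: int = 2000,
    ):
        self.stimulus_set = stimulus_set
        self.radius_starts = radius_starts
        self.max_nfev = max_nfev

    def fit(self, components: ComponentSet, y=None) -> "GaussianRotation":
        if self.stimulus_set is None:
            raise ValueError("stimulus_set is required")
        ss = self.stimulus_set
        W = components.weights
        P = components.profiles
        k, s = W.shape
        if k not in (2, 3):
            raise ValueError("rotation refit supports k = 2 or 3 components")
        if s != ss.s:
            raise ValueError("weights and stimulus set disagree on stimulus count")
        n_off = k * (k - 1)
        off_idx = [(a, b) for a in range(k) for b in range(k) if a != b]

        def unpack(theta):
            F = np.eye(k)
            for (a, b), v in zip(off_idx, theta[:n_off]):
                F[a, b] = v
            x0, y0 = theta[n_off], theta[n_off + 1]
            g = theta[n_off + 2 : n_off + 2 + k]
            r = theta[n_off + 2 + k : n_off + 2 + 2 * k]
            b = theta[n_off + 2 + 2 * k :]
            return F, (x0, y0), g, r, b

        def residuals(theta):
            F, center, g, r, b = unpack(theta)
            d = bar_center_distance(ss, center)
            model = radial_gaussian(d[None, :], g[:, None], r[:, None], b[:, None])
            return (F @ W - model).ravel()

        # --- initialization
        c0 = _center_from_sinogram(W[0], ss)
        d0 = bar_center_distance(ss, tuple(c0))
        g_init = np.maximum(W.max(axis=1) - W.min(axis=1), 1e-6)
        b_init = np.clip(W.min(axis=1), 0.0, None)
        r_init = np.empty(k)
        for j in range(k):
            wpos = np.clip(W[j] - W[j].min(), 0.0, None)
            if wpos.sum() > 0:
                sigma = np.sqrt(np.sum(wpos * d0**2) / wpos.sum())
            else:
                sigma = ss.bar_width
            r_init[j] = max(sigma / (2.0 * np.sqrt(2.0)), ss.bar_width / 20.0)

        extent = ss.grid.extent
        lo = np.concatenate(
            [np.zeros(n_off), [-2 * extent, -2 * extent], np.zeros(k), np.full(k, 1e-4), np.zeros(k)]
        )
        hi = np.full(lo.size, np.inf)
        hi[n_off : n_off + 2] = 2 * extent

        best = None
        theta_init0 = None
        for scale in self.radius_starts:
            theta0 = np.concatenate([np.zeros(n_off), c0, g_init, r_init * scale, b_init])
            theta0 = np.clip(theta0, lo, hi)
            if scale == 1.0:
                theta_init0 = theta0
            sol = least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf", max_nfev=self.max_nfev
            )
            if best is None or sol.cost < best.cost:
                best = sol
        assert best is not None and theta_init0 is not None

        F, center, g, r, b = unpack(best.x)
        self.F_ = F
        self.center_ = (float(center[0]), float(center[1]))
        self.gains_ = g
        self.radii_ = r
        self.baselines_ = b
        self.rotated_profiles_ = P @ np.linalg.inv(F)
        self.rotated_weights_ = F @ W
        self.objective_ = float(2 * best.cost)  # cost is 0.5 * sum of squares
        self.objective_init_ = float(np.sum(residuals(theta_init0) ** 2))
        self.converged_ = bool(best.status > 0)
        self.n_iter_ = int(best.nfev)
        self._components = components
        return self

    def to_fit(self) -> RotationFit:
        return RotationFit(
            F=self.F_,
            center=self.center_,
            gains=self.gains_,
            radii=self.radii_,
            baselines=self.baselines_,
            rotated_profiles=self.rotated_profiles_,
            rotated_weights=self.rotated_weights_,
            components=self._components,
            objective=self.objective_,
            objective_init=self.objective_init_,
            converged=self.converged_,
        )


def rotate_to_gaussian(
    components: ComponentSet,
    stimulus_set: StimulusSet,
    radius_starts: tuple[float, ...] = (0.5, 1.0, 2.0),
    max_nfev: int = 2000,
) -> RotationFit:
    """Fit the rotation matrix and radial-Gaussian weight model.

    Wrapper over :class:`GaussianRotation`.  Raises if the optimizer made
    no progress; the returned fit carries the best solution found.
    """
    est = GaussianRotation(
        stimulus_set=stimulus_set, radius_starts=radius_starts, max_nfev=max_nfev
    ).fit(components)
    fit = est.to_fit()
    if np.min(fit.rotated_weights) < -1e-8:
        warnings.warn("rotated weights contain negative values beyond tolerance", stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# first harmonic


def component_f1(
    components_or_fit: ComponentSet | RotationFit,
    stimulus_frequency: float,
    bin_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First-harmonic amplitude and phase of each temporal profile.

    The discrete Fourier amplitude at the flash frequency is computed over
    the stimulus-on window, truncated to a whole number of cycles
    (amplitude convention: a profile ``A (1 + sin(2 pi f t))`` yields f1
    amplitude ``A``).  Returns ``(amplitudes, phases_deg)``.  Raw NNMF
    profiles are used for a :class:`ComponentSet`; rotated (signed)
    profiles for a :class:`RotationFit`.
    """
    if isinstance(components_or_fit, RotationFit):
        comps = components_or_fit.components
        profiles = components_or_fit.rotated_profiles
    else:
        comps = components_or_fit
        profiles = comps.profiles
    bw = comps.bin_width if bin_width is None else bin_width
    times = comps.times
    t_on = times[times >= 0]
    span = t_on[-1] + bw / 2 if t_on.size else 0.0
    n_cycles = int(np.floor(span * stimulus_frequency + 1e-9))
    if n_cycles < 1:
        raise ValueError("stimulus window must span at least one full cycle")
    t_end = n_cycles / stimulus_frequency
    sel = (times >= 0) & (times < t_end)
    t = times[sel]
    X = profiles[sel]
    phasor = np.exp(-2j * np.pi * stimulus_frequency * t)
    coef = 2.0 / t.size * (phasor @ X)
    return np.abs(coef), np.rad2deg(np.angle(coef))
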