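import warnings

import numpy as np
import pytest

import rftomo as rt

# sklearn NMF emits convergence warnings on loose-tolerance restarts; they
# are expected and handled by the restart policy
warnings.filterwarnings("ignore", message="Maximum number of iterations")


@pytest.fixture(scope="session")
def bar_set():
    """Standard mapping protocol: 6 orientations x 21 positions, 0.1 deg bars."""
    return rt.build_stimulus_set(6, 21, bar_width=0.1, extent=1.05)


@pytest.fixture(scope="session")
def pm_protocol():
    """Finer protocol used for the P/M-cell simulations (0.08 deg bars)."""
    return rt.build_stimulus_set(6, 21, bar_width=0.08, extent=0.84)


@pytest.fixture(scope="session")
def pm_projection(pm_protocol):
    return rt.render_projection_matrix(pm_protocol)


@pytest.fixture(scope="session")
def m_cell_run(pm_protocol):
    """Simulate + decompose + rotate an M-like cell once for the session."""
    neuron = rt.m_like_neuron(center=(0.1, -0.05))
    spikes = rt.simulate_flash_responses(neuron, pm_protocol, n_replicates=3, seed=42)
    R = rt.build_psth(spikes)
    comps = rt.nnmf_decompose(R, 2, seed=1)
    fit = rt.rotate_to_gaussian(comps, pm_protocol)
    return {
        "neuron": neuron,
        "spikes": spikes,
        "psth": R,
        "components": comps,
        "fit": fit,
        "stimulus_set": pm_protocol,
    }


@pytest.fixture(scope="session")
def gaussian_phantom_32():
    """Isotropic Gaussian phantom on a 32x32 grid with its exact sinogram."""
    ss = rt.build_stimulus_set(
        6, 21, bar_width=0.1, extent=1.05, grid=rt.PixelGrid(1.05, 32)
    )
    A = rt.render_projection_matrix(ss)
    X, Y = ss.grid.pixel_centers()
    sigma = 0.25
    img = np.exp(-(X**2 + Y**2) / (2 * sigma**2))
    img /= img.sum() * ss.grid.pixel_size**2
    y = A.entries @ img
    return {"stimulus_set": ss, "A": A, "image": img, "sinogram": y, "sigma": sigma}
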