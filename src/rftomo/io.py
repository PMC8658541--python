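"""File formats: spike-event CSV, stimulus JSON, matrix CSV + sidecars.

On-disk conventions: stimulus and replicate indices are 1-based (matching
the ``i = 1...s`` labelling used throughout the analysis); internal
arrays are 0-based, converted only here.  Spike times are seconds
relative to stimulus onset (negative in the pre-stimulus window).  Every
matrix CSV gets a JSON sidecar sufficient to re-derive its grid and units
without the run configuration.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import ComponentSet, ResponseMatrix, RotationFit
from .geometry import PixelGrid, StimulusSet, build_stimulus_set
from .reconstruct import RFMap
from .simulate import SpikeData

__all__ = [
    "read_spike_events",
    "write_spike_events",
    "read_stimulus_json",
    "write_stimulus_json",
    "write_response_matrix",
    "read_response_matrix",
    "write_components",
    "write_rotation_fit",
    "write_rfmap",
    "read_rfmap",
    "write_rfmap_image",
]

SPIKE_COLUMNS = ("stimulus_id", "replicate", "spike_time_s")


def write_spike_events(spikes: SpikeData, path) -> None:
    """Write spike events as CSV (1-based stimulus and replicate ids)."""
    df = pd.DataFrame(
        {
            "stimulus_id": spikes.stimulus_index + 1,
            "replicate": spikes.replicate + 1,
            "spike_time_s": spikes.times,
        }
    )
    df.to_csv(path, index=False)


def read_spike_events(
    path,
    stimulus_set: StimulusSet,
    n_replicates: int | None = None,
    window: tuple[float, float] | None = None,
) -> SpikeData:
    """Read a spike-event CSV into :class:`~rftomo.simulate.SpikeData`.

    Validates the header and every row; errors name the offending line
    (1-based, counting the header as line 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file without header") from None
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: no spike events", stacklevel=2)
    for col in ("stimulus_id", "replicate"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() | (vals != vals.round()))
        if bad.size:
            raise ValueError(f"{path}: line {bad[0] + 2}: non-integer {col}")
        df[col] = vals.astype(int)
    t = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = np.flatnonzero(t.isna())
    if bad.size:
        raise ValueError(f"{path}: line {bad[0] + 2}: malformed spike_time_s")
    sid = df["stimulus_id"].to_numpy()
    out_of_range = np.flatnonzero((sid < 1) | (sid > stimulus_set.s))
    if out_of_range.size:
        raise ValueError(
            f"{path}: line {out_of_range[0] + 2}: stimulus_id {sid[out_of_range[0]]} "
            f"outside [1, {stimulus_set.s}]"
        )
    rep = df["replicate"].to_numpy()
    if len(df) and rep.min() < 1:
        raise ValueError(f"{path}: replicate indices must be >= 1")
    if n_replicates is None:
        n_replicates = int(rep.max()) if len(df) else 1
    times = t.to_numpy()
    if window is None:
        lo = float(min(times.min(), -0.2)) if len(df) else -0.2
        hi = float(max(times.max(), stimulus_set.duration)) if len(df) else stimulus_set.duration
        window = (lo, hi)
    return SpikeData(
        stimulus_index=sid - 1,
        replicate=rep - 1,
        times=times,
        n_replicates=n_replicates,
        stimulus_set=stimulus_set,
        window=window,
    )


# ---------------------------------------------------------------------------
# stimulus description


def write_stimulus_json(stimulus_set: StimulusSet, path) -> None:
    blocks = stimulus_set.orientation_blocks()
    first = next(iter(blocks.values()))
    payload = {
        "orientations_deg": [float(o) for o in stimulus_set.unique_orientations],
        "n_positions": int(first.size),
        "bar_width_deg": stimulus_set.bar_width,
        "extent_deg": stimulus_set.grid.extent,
        "temporal_frequency_hz": stimulus_set.temporal_frequency,
        "duration_s": stimulus_set.duration,
        "offsets_deg": [float(q) for q in stimulus_set.offsets[first]],
        "n_pixels_per_side": stimulus_set.grid.n_pixels_per_side,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_stimulus_json(path) -> StimulusSet:
    """Read a stimulus description JSON (see the module docstring format)."""
    spec = json.loads(Path(path).read_text())
    orientations = spec["orientations_deg"]
    grid = None
    if "n_pixels_per_side" in spec:
        grid = PixelGrid(extent=spec["extent_deg"], n_pixels_per_side=spec["n_pixels_per_side"])
    ss = build_stimulus_set(
        n_orientations=len(orientations),
        n_positions=spec["n_positions"],
        bar_width=spec["bar_width_deg"],
        extent=spec["extent_deg"],
        temporal_frequency=spec.get("temporal_frequency_hz", 5.0),
        duration=spec.get("duration_s", 2.0),
        grid=grid,
    )
    if "offsets_deg" in spec:
        from .geometry import BarStimulus

        bars = [
            BarStimulus(
                orientation=float(o),
                offset=float(q),
                width=spec["bar_width_deg"],
                temporal_frequency=spec.get("temporal_frequency_hz", 5.0),
                duration=spec.get("duration_s", 2.0),
            )
            for o in orientations
            for q in spec["offsets_deg"]
        ]
        ss = StimulusSet(bars=tuple(bars), grid=ss.grid)
    return ss


# ---------------------------------------------------------------------------
# response matrix and components


def write_response_matrix(R: ResponseMatrix, path) -> None:
    """CSV (rows = stimuli, columns = time bins) + JSON sidecar."""
    path = Path(path)
    pd.DataFrame(R.rates).to_csv(path, index=False, header=False)
    sidecar = {
        "bin_width_s": R.bin_width,
        "window_s": list(R.window),
        "units": "impulses/s",
        "rows": "stimuli (canonical order)",
        "columns": "time bins",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_response_matrix(path) -> ResponseMatrix:
    path = Path(path)
    rates = pd.read_csv(path, header=None).to_numpy(dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ResponseMatrix(
        rates=rates, bin_width=sidecar["bin_width_s"], window=tuple(sidecar["window_s"])
    )


def write_components(components: ComponentSet, out_dir, prefix: str = "components") -> None:
    out = Path(out_dir)
    pd.DataFrame(components.profiles).to_csv(out / f"{prefix}_profiles.csv", index=False, header=False)
    pd.DataFrame(components.weights).to_csv(out / f"{prefix}_weights.csv", index=False, header=False)
    sidecar = {
        "k": components.k,
        "bin_width_s": components.bin_width,
        "window_s": list(components.window),
        "profiles": "rows = time bins, columns = components (max-normalized)",
        "weights": "rows = components, columns = stimuli",
        "reconstruction_error": components.reconstruction_error,
    }
    (out / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def write_rotation_fit(fit: RotationFit, path) -> None:
    payload = {
        "F": fit.F.tolist(),
        "center_deg": list(fit.center),
        "gains": fit.gains.tolist(),
        "radii_deg": fit.radii.tolist(),
        "baselines": fit.baselines.tolist(),
        "objective": fit.objective,
        "n_free_parameters": fit.n_free_parameters,
        "converged": fit.converged,
        "radius_convention": "exp(-(d/(4 r))^2); sigma = 2*sqrt(2)*r",
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# receptive-field maps


def write_rfmap(rf_map: RFMap, path, units: str = "arbitrary") -> None:
    """CSV matrix + JSON sidecar carrying grid, units and provenance."""
    path = Path(path)
    pd.DataFrame(rf_map.image).to_csv(path, index=False, header=False)
    sidecar = {
        "extent_deg": rf_map.grid.extent,
        "pixel_size_deg": rf_map.grid.pixel_size,
        "units": units,
        "method": rf_map.method,
        "component": rf_map.component,
        "iterations": rf_map.iterations,
        "orientation": "row 0 is the top of the field of view (largest y)",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_rfmap(path) -> RFMap:
    path = Path(path)
    image = pd.read_csv(path, header=None).to_numpy(dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    grid = PixelGrid(extent=sidecar["extent_deg"], n_pixels_per_side=image.shape[0])
    return RFMap(
        image=image,
        grid=grid,
        method=sidecar.get("method", "unknown"),
        component=sidecar.get("component"),
        iterations=sidecar.get("iterations"),
    )


def write_rfmap_image(rf_map: RFMap, path) -> None:
    """Optional 16-bit grayscale export (full map range scaled to 0-65535)."""
    import imageio.v3 as iio  # optional dependency, imported on demand

    img = rf_map.image
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    iio.imwrite(path, (scaled * 65535).astype(np.uint16))
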