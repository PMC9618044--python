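"""Experiment presets, orchestration and serialization.

A preset names a complete protocol: pre-equilibrate the ring under normal
turnover, switch to a perturbation mode at t = 0, simulate, and record
kymographs plus observable traces at the imaging cadence.  Every run is
fully determined by its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constrained_dynamics import step
from .length_theory import calibrated_mean_length
from .observables import (
    correlation_length,
    detect_aggregates,
    detect_gaps,
    kymograph,
    mean_separation,
    mechanical_connectivity,
    relative_fluctuation,
    render_fluorescence,
    ring_tension,
    total_intensity,
)
from .params import ModelParams
from .ring_model import make_initial_ring, pre_equilibrate
from .turnover_kinetics import TurnoverMode

MINUTE = 60.0


@dataclass
class ExperimentPreset:
    """A named protocol: mode, duration, replicates and per-condition values."""

    name: str
    mode: str
    duration_s: float
    replicates: int
    equilibrate_s: float = 11.0 * MINUTE
    #: list of (label, TurnoverMode overrides) conditions; one entry for
    #: single-condition presets
    conditions: list = field(default_factory=list)

    def resolved_conditions(self) -> list[tuple[str, TurnoverMode]]:
        if not self.conditions:
            return [(self.mode, TurnoverMode(self.mode))]
        return [
            (label, TurnoverMode(self.mode, **kw)) for label, kw in self.conditions
        ]


PRESETS: dict[str, ExperimentPreset] = {
    "ghost_aggregation": ExperimentPreset(
        "ghost_aggregation", "ghost", 60 * MINUTE, replicates=10
    ),
    "rescue_both": ExperimentPreset("rescue_both", "normal", 60 * MINUTE, replicates=10),
    "rescue_myosin": ExperimentPreset(
        "rescue_myosin", "ghost_plus_myosin_turnover", 60 * MINUTE, replicates=5
    ),
    "rescue_actin": ExperimentPreset(
        "rescue_actin", "ghost_plus_actin_turnover", 60 * MINUTE, replicates=5
    ),
    "blebbistatin_scan": ExperimentPreset(
        "blebbistatin_scan",
        "blebbistatin",
        9 * MINUTE,
        replicates=5,
        conditions=[
            (f"bleb_{int(100 * f)}", {"bleb_fraction": f})
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ],
    ),
    "diffusion_scan": ExperimentPreset(
        "diffusion_scan",
        "diffusion",
        30 * MINUTE,
        replicates=5,
        conditions=[(f"D_{D:g}", {"D_myo": D}) for D in (1e-5, 1e-4, 1e-3, 1e-2)],
    ),
    "turnover_scan": ExperimentPreset(
        "turnover_scan", "normal", 30 * MINUTE, replicates=5
    ),
}


def scale_geometry(params: ModelParams, ring_radius: float) -> ModelParams:
    """Smaller-ring parameter set with identical densities and rates.

    Intended for fast property tests; the aggregation mechanism is local
    (range ≈ the mean filament length), so the circumference must remain
    several filament lengths for the scaled ring to show the same physics.
    """
    mean_len = calibrated_mean_length(params, method="closed_form")
    if 2.0 * np.pi * ring_radius <= 4.0 * mean_len:
        raise ValueError(
            f"ring radius {ring_radius} μm too small: circumference "
            f"{2 * np.pi * ring_radius:.2f} μm must exceed 4× the mean filament "
            f"length ({mean_len:.2f} μm) so the aggregation range stays local"
        )
    return params.replace(R=ring_radius)


# ---------------------------------------------------------------------------
# core simulation loop with sampling
# ---------------------------------------------------------------------------

def simulate_with_sampling(
    state,
    params: ModelParams,
    mode: str | TurnoverMode,
    duration_s: float,
    sample_every: float = MINUTE,
):
    """Run the dynamics, sampling observables at the imaging cadence.

    Returns ``(state, samples, records)`` where samples are (time, profile)
    pairs and records a list of per-sample observable dicts.
    """
    tm = mode if isinstance(mode, TurnoverMode) else TurnoverMode(mode)
    n_steps = int(round(duration_s / params.dt))
    stride = max(1, int(round(sample_every / params.dt)))
    samples = []
    records = []

    def sample(k):
        t = state.time
        profile = render_fluorescence(state, params)
        samples.append((t, profile))
        rec = {"time_s": t, "total_intensity": total_intensity(profile)}
        rec["n_myosin"] = len(state.myosins)
        rec["n_filaments"] = len(state.filaments)
        rec["n_crosslinks"] = len(state.crosslinks)
        try:
            rec["relative_fluctuation"] = relative_fluctuation(profile)
            rec["correlation_length_um"] = correlation_length(profile)
        except ValueError:
            rec["relative_fluctuation"] = np.nan
            rec["correlation_length_um"] = np.nan
        peaks = detect_aggregates(
            profile, params.peak_prominence_frac, params.peak_min_separation
        )
        rec["n_aggregates"] = len(peaks)
        sep = mean_separation(peaks, params.circumference)
        rec["mean_separation_um"] = np.nan if sep is None else sep
        rec["n_gaps"] = len(detect_gaps(profile, params))
        rec["tension_pN"] = ring_tension(state, params)
        connected, comps = mechanical_connectivity(state, params)
        rec["connected"] = bool(connected)
        rec["n_components"] = len(comps)
        records.append(rec)

    sample(0)
    for k in range(n_steps):
        state = step(state, params, mode=tm)
        if (k + 1) % stride == 0:
            sample(k + 1)
    return state, samples, records


def run_experiment(
    preset: str | ExperimentPreset,
    params: ModelParams,
    seeds,
    out_dir: str | Path,
    duration_s: float | None = None,
    equilibrate_s: float | None = None,
    sample_every: float = MINUTE,
) -> Path:
    """Execute a preset for each seed (and condition) and write its outputs.

    Per run directory: ``kymograph.csv`` (long format time_s, arc_um,
    intensity), ``traces.csv`` (one row per sample with tension,
    fluctuation, correlation length, aggregates, gaps, connectivity) and
    ``manifest.json`` (full configuration + seed + code version).
    """
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    duration = preset.duration_s if duration_s is None else duration_s
    equil = preset.equilibrate_s if equilibrate_s is None else equilibrate_s

    for label, tmode in preset.resolved_conditions():
        for seed in seeds:
            run_dir = out_dir / f"{label}_seed{seed}"
            run_dir.mkdir(parents=True, exist_ok=True)
            rng = np.random.default_rng(int(seed))
            state = make_initial_ring(params, rng)
            if equil > 0:
                state = pre_equilibrate(state, params, equil)
            state.time = 0.0  # perturbation switched on at t = 0
            state, samples, records = simulate_with_sampling(
                state, params, tmode, duration, sample_every
            )
            _write_run(run_dir, params, preset, label, seed, samples, records)
    return out_dir


def _write_run(run_dir: Path, params, preset, label, seed, samples, records) -> None:
    ky = kymograph(samples) if len(samples) >= 2 else None
    if ky is not None:
        long = pd.DataFrame(
            {
                "time_s": np.repeat(ky.times, len(ky.bin_centers)),
                "arc_um": np.tile(ky.bin_centers, len(ky.times)),
                "intensity": ky.data.ravel(),
            }
        )
        long.to_csv(run_dir / "kymograph.csv", index=False)
    pd.DataFrame(records).to_csv(run_dir / "traces.csv", index=False)
    manifest = {
        "package": "ringsim",
        "version": __version__,
        "preset": preset.name,
        "condition": label,
        "mode": preset.mode,
        "seed": int(seed),
        "duration_s": preset.duration_s,
        "params": params.to_dict(),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def analyze_kymograph_csv(path: str | Path, params: ModelParams) -> pd.DataFrame:
    """Recompute profile statistics from a long-format kymograph CSV.

    Accepts any 1D ring-intensity trace table with columns
    (time_s, arc_um, intensity), e.g. digitized experimental kymographs.
    """
    from .observables import IntensityProfile

    df = pd.read_csv(path)
    out = []
    for t, grp in df.groupby("time_s"):
        grp = grp.sort_values("arc_um")
        arc = grp["arc_um"].to_numpy()
        bw = float(np.diff(arc).mean())
        profile = IntensityProfile(arc, np.clip(grp["intensity"].to_numpy(), 0, None), bw)
        rec = {"time_s": t}
        try:
            rec["relative_fluctuation"] = relative_fluctuation(profile)
            rec["correlation_length_um"] = correlation_length(profile)
        except ValueError:
            rec["relative_fluctuation"] = np.nan
            rec["correlation_length_um"] = np.nan
        peaks = detect_aggregates(
            profile, params.peak_prominence_frac, params.peak_min_separation
        )
        sep = mean_separation(peaks, profile.circumference)
        rec["n_aggregates"] = len(peaks)
        rec["mean_separation_um"] = np.nan if sep is None else sep
        rec["n_gaps"] = len(detect_gaps(profile, params))
        out.append(rec)
    return pd.DataFrame(out)
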