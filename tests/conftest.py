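"""Session-scoped toy-simulation fixtures shared across the statistical tests.

Every long run lives here so each is integrated exactly once per session.
Problem sizes (particle counts, step counts) are the package's study
conditions: large enough for the statistical checks, small enough that the
whole suite runs on one CPU in well under half an hour.
"""

import dataclasses

import numpy as np
import pytest

from isopress import profiles, tensor, toysim, trajio
from isopress.isotherm import analyze_run, sweep

STUDY_SEED = 12345

#: steps for the single-state runs (clean slab, dilute monolayer, k-doubled)
SINGLE_RUN_STEPS = 40_000
#: per-area steps inside sweeps, plus extra first-point equilibration
SWEEP_POINT_STEPS = 22_000
SWEEP_EQUILIBRATION = 6_000
#: compression grid (areas per surfactant, σ²), descending; the densest
#: point stays in the reversible monolayer regime
SWEEP_AREAS = (16.0, 10.0, 6.0, 4.0)
#: replicate sweeps combined for the ξ-behaviour and reversibility checks
N_REPLICATES = 3
N_EXPANSION_REPLICATES = 1
SAMPLE_EVERY = 20
BURN_IN = 0.2
ANALYSIS_BIN = 0.2


def burned(traj, frac=BURN_IN):
    start = int(frac * len(traj))
    return trajio.Trajectory(traj.frames[start:])


def burned_series(press, frac=BURN_IN):
    start = int(frac * len(press))
    return trajio.PressureTensorSeries(
        press.times[start:],
        press.pxx[start:],
        press.pyy[start:],
        press.pzz[start:],
        box_lz=press.box_lz,
        units=press.units,
    )


@pytest.fixture(scope="session")
def clean_slab_run():
    spec = toysim.clean_slab_spec(seed=STUDY_SEED)
    initial = toysim.build_system(spec)
    out = toysim.run(
        spec, initial, n_steps=SINGLE_RUN_STEPS, sample_every=SAMPLE_EVERY
    )
    return spec, out


@pytest.fixture(scope="session")
def clean_traj(clean_slab_run):
    _, out = clean_slab_run
    return burned(out.trajectory)


@pytest.fixture(scope="session")
def gamma_w(clean_slab_run):
    _, out = clean_slab_run
    return tensor.kirkwood_irving(
        burned_series(out.pressure_log), kind="air-water"
    )


@pytest.fixture(scope="session")
def dilute_run():
    spec = toysim.dilute_monolayer_spec(seed=STUDY_SEED)
    out = toysim.run(
        spec,
        toysim.build_system(spec),
        n_steps=SINGLE_RUN_STEPS,
        sample_every=SAMPLE_EVERY,
    )
    return spec, out


@pytest.fixture(scope="session")
def dilute_point(dilute_run, clean_traj, gamma_w):
    spec, out = dilute_run
    return analyze_run(
        out,
        spec,
        lz_ref=clean_traj,
        gamma_w=gamma_w,
        burn_in_frac=BURN_IN,
        bin_width=ANALYSIS_BIN,
    )


@pytest.fixture(scope="session")
def dilute_point_double_k(clean_traj):
    spec = toysim.dilute_monolayer_spec(seed=STUDY_SEED)
    spec = dataclasses.replace(
        spec, wall=dataclasses.replace(spec.wall, k=2 * spec.wall.k)
    )
    out = toysim.run(
        spec,
        toysim.build_system(spec),
        n_steps=SINGLE_RUN_STEPS,
        sample_every=SAMPLE_EVERY,
    )
    return analyze_run(
        out, spec, lz_ref=clean_traj, burn_in_frac=BURN_IN, bin_width=ANALYSIS_BIN
    )


def run_sweep(seed, areas, direction, clean_traj):
    spec = toysim.dilute_monolayer_spec(seed=seed)
    return sweep(
        spec,
        areas,
        direction=direction,
        per_area_steps=SWEEP_POINT_STEPS,
        sample_every=SAMPLE_EVERY,
        lz_ref=clean_traj,
        burn_in_frac=BURN_IN,
        bin_width=ANALYSIS_BIN,
        equilibration_steps=SWEEP_EQUILIBRATION,
    )


@pytest.fixture(scope="session")
def compression_sweeps(clean_traj):
    return [
        run_sweep(STUDY_SEED + 101 * k, SWEEP_AREAS, "compression", clean_traj)
        for k in range(N_REPLICATES)
    ]


@pytest.fixture(scope="session")
def expansion_sweeps(clean_traj):
    areas = tuple(reversed(SWEEP_AREAS))
    return [
        run_sweep(STUDY_SEED + 101 * k, areas, "expansion", clean_traj)
        for k in range(N_EXPANSION_REPLICATES)
    ]


@pytest.fixture(scope="session")
def ideal_gas_run():
    spec = toysim.ideal_gas_spec(seed=STUDY_SEED, n=512)
    out = toysim.run(
        spec,
        toysim.build_system(spec),
        n_steps=SINGLE_RUN_STEPS,
        sample_every=50,
    )
    return spec, out
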