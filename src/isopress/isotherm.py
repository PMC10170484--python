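"""Π–A isotherm assembly: area sweeps, per-area analysis, plateau detection.

A sweep holds the surfactant count fixed and moves the walls, exactly as a
Langmuir trough moves its barriers: area per surfactant is
A = 2·x_wall·L_y / n_per_leaflet.  At each area the walls are repositioned
instantaneously, a burn-in fraction of the run is discarded, and the
retained samples yield Π_ideal (wall-force mean), ξ (interfacial-thickness
ratio against a clean-slab reference), Π_real = Π_ideal·ξ and, when a
clean-slab tension γ_w is supplied, the tensor-route Π = γ_w − γ_m from the
same run.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import osmotic, profiles, tensor
from .trajio import PressureTensorSeries, Trajectory
from .toysim import ToyModelSpec, ToyRunOutput, build_system, run

__all__ = [
    "IsothermPoint",
    "Isotherm",
    "area_per_lipid",
    "x_wall_for_area",
    "analyze_run",
    "sweep",
    "plateau_detect",
    "combine_isotherms",
]


@dataclass
class IsothermPoint:
    """One (area, surface pressure) point with method metadata."""

    area_per_lipid: float
    pi_ideal: float
    pi_ideal_err: float
    pi_real: float
    pi_real_err: float
    xi: float
    lz_int: float
    pi_tensor: float | None = None
    pi_tensor_err: float | None = None
    equilibrated: bool = True

    def __post_init__(self) -> None:
        if self.area_per_lipid <= 0:
            raise ValueError("area per lipid must be positive")
        if not math.isclose(
            self.pi_real, self.pi_ideal * self.xi, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValueError("pi_real must equal pi_ideal * xi")


@dataclass
class Isotherm:
    """Ordered Π–A points from one sweep (or independent runs)."""

    points: list[IsothermPoint]
    units: str = "reduced"
    temperature: float | None = None
    direction: str = "independent"  # compression | expansion | independent

    def __post_init__(self) -> None:
        areas = [p.area_per_lipid for p in self.points]
        if len(areas) > 1:
            diffs = np.diff(areas)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError("areas must be strictly monotone within a sweep")

    def areas(self) -> np.ndarray:
        return np.array([p.area_per_lipid for p in self.points])

    def pi_real(self) -> np.ndarray:
        return np.array([p.pi_real for p in self.points])


def area_per_lipid(x_wall: float, l_y: float, n_per_leaflet: int) -> float:
    """A = 2·x_wall·L_y / n_per_leaflet (Å² in real units, σ² reduced)."""
    if n_per_leaflet <= 0:
        raise ValueError("need at least one surfactant per leaflet")
    if x_wall <= 0 or l_y <= 0:
        raise ValueError("x_wall and l_y must be positive")
    return 2.0 * x_wall * l_y / n_per_leaflet


def x_wall_for_area(area: float, l_y: float, n_per_leaflet: int) -> float:
    """Wall half-separation that realizes a given area per surfactant."""
    if area <= 0:
        raise ValueError("area must be positive")
    return area * n_per_leaflet / (2.0 * l_y)


def analyze_run(
    output: ToyRunOutput,
    spec: ToyModelSpec,
    lz_ref: float | Trajectory,
    gamma_w: tensor.SurfaceTension | None = None,
    burn_in_frac: float = 0.2,
    n_blocks: int = 5,
    bin_width: float = 0.1,
    solvent_species: str = "W",
    observation_width: float | None = None,
) -> IsothermPoint:
    """Single-area analysis of a toy run's logs.

    Pure function of the run logs: re-running it on saved logs reproduces
    the point exactly.  The burn-in fraction is discarded from every log;
    the drift test (first vs second half of the retained wall-force series
    differing by more than 3× their combined block SE) flags the point as
    unequilibrated rather than dropping it.

    ``lz_ref`` is the infinite-dilution interfacial thickness — either a
    precomputed number or a clean-slab trajectory, in which case the
    reference is measured over x-strips of the same width as this run's
    analysis windows (capillary broadening depends on the sampled lateral
    area, so matched widths give an unbiased ξ).  ``observation_width``
    fixes that lateral window; inside a sweep it is held constant across
    all areas (the narrowest film region) so thickness differences between
    areas reflect the film, not the window.  When omitted, the window is
    the full between-the-walls strip.

    When ``gamma_w`` is given, the tensor-route Π is also computed from the
    run's own pressure log.  The walled strip covers only a fraction
    c = 2·x_wall/L_x of the interface (the rest is the clean margin), so
    the box-average tension is γ_box = c·γ_strip + (1−c)·γ_w and the film
    pressure is recovered as Π = (γ_w − γ_box)/c.  For a wall-free
    full-coverage system c = 1 and this reduces to Π = γ_w − γ_m.
    """
    if not 0.0 <= burn_in_frac < 1.0:
        raise ValueError("burn_in_frac must be in [0, 1)")
    n_samples = len(output.wall_force_log)
    start = int(burn_in_frac * n_samples)
    wall_f = output.wall_force_log["f_total"].to_numpy()[start:]
    frames = output.trajectory.frames[start:]
    traj = Trajectory(frames)
    ly = spec.box[1]

    record = osmotic.WallForceRecord(
        per_frame_force=wall_f,
        mean_force=float(np.sum(wall_f) / len(wall_f)),
        n_frames=len(wall_f),
        per_species_force={},
    )
    pi_id = osmotic.pi_ideal(record, ly, units="reduced")
    pi_id_err = osmotic.block_uncertainty(wall_f, n_blocks) / (4.0 * ly)

    region = (-spec.wall.x_wall, spec.wall.x_wall)
    window = observation_width or 2.0 * spec.wall.x_wall
    lz_value = profiles.tiled_thickness(
        traj,
        region,
        strip_width=window,
        solvent_species=solvent_species,
        bin_width=bin_width,
    )
    if isinstance(lz_ref, Trajectory):
        lz_ref = profiles.strip_averaged_reference(
            lz_ref,
            strip_width=window,
            solvent_species=solvent_species,
            bin_width=bin_width,
        )
    xi = profiles.xi_coefficient(lz_value, lz_ref)
    pi_re = osmotic.pi_real(pi_id, xi)
    pi_re_err = pi_id_err * xi.xi

    pi_t = pi_t_err = None
    if gamma_w is not None:
        press = output.pressure_log
        sub = PressureTensorSeries(
            press.times[start:],
            press.pxx[start:],
            press.pyy[start:],
            press.pzz[start:],
            box_lz=press.box_lz,
            units=press.units,
        )
        gamma_m = tensor.kirkwood_irving(sub, n_blocks=n_blocks)
        pi_tension = tensor.surface_pressure(gamma_w, gamma_m)
        coverage = min(1.0, 2.0 * spec.wall.x_wall / spec.box[0])
        pi_t = pi_tension.value / coverage
        pi_t_err = pi_tension.uncertainty / coverage

    # burn-in drift check on the retained series
    half = len(wall_f) // 2
    first, second = wall_f[:half], wall_f[half:]
    se = math.hypot(
        osmotic.block_uncertainty(first, max(2, n_blocks // 2)),
        osmotic.block_uncertainty(second, max(2, n_blocks // 2)),
    )
    equilibrated = abs(first.mean() - second.mean()) <= 3.0 * se if se > 0 else True

    return IsothermPoint(
        area_per_lipid=spec.area_per_surfactant(),
        pi_ideal=pi_id,
        pi_ideal_err=pi_id_err,
        pi_real=pi_re,
        pi_real_err=pi_re_err,
        xi=xi.xi,
        lz_int=lz_value,
        pi_tensor=pi_t,
        pi_tensor_err=pi_t_err,
        equilibrated=equilibrated,
    )


def sweep(
    spec: ToyModelSpec,
    areas: Sequence[float],
    direction: str,
    per_area_steps: int,
    lz_ref: float | Trajectory,
    sample_every: int = 20,
    gamma_w: tensor.SurfaceTension | None = None,
    burn_in_frac: float = 0.2,
    n_blocks: int = 5,
    bin_width: float = 0.1,
    equilibration_steps: int = 0,
    between_equilibration_steps: int = 4000,
    relax_steps: int = 2000,
    relax_max_speed: float = 5.0,
    observation_width: float | None = None,
) -> Isotherm:
    """Run a wall-position sweep and assemble the Π–A isotherm.

    ``areas`` must be ordered to match ``direction``: strictly decreasing
    for compression, strictly increasing for expansion.  The final state of
    each per-area run seeds the next one (walls repositioned
    instantaneously, burn-in re-discarded), mirroring a quasi-static trough
    sweep.  ``equilibration_steps`` adds extra discarded steps before the
    first area only.

    After an inward wall jump, surfactant beads can sit far beyond the new
    walls, where the quadratic restraint is violent; each repositioning is
    therefore followed by a short discarded displacement-limited relaxation
    segment (``relax_steps`` at capped speed) and a discarded thermal
    re-equilibration segment (``between_equilibration_steps``) before
    sampling resumes.
    """
    areas = list(areas)
    if not areas:
        raise ValueError("areas must be non-empty")
    diffs = np.diff(areas)
    if direction == "compression":
        if len(areas) > 1 and not np.all(diffs < 0):
            raise ValueError("compression sweep needs strictly decreasing areas")
    elif direction == "expansion":
        if len(areas) > 1 and not np.all(diffs > 0):
            raise ValueError("expansion sweep needs strictly increasing areas")
    else:
        raise ValueError("direction must be 'compression' or 'expansion'")

    ly = spec.box[1]
    n_leaf = spec.n_per_leaflet
    if observation_width is None:
        # fixed lateral analysis window: the narrowest film region of the
        # sweep, so the capillary contribution to L_z;int is constant
        observation_width = 2.0 * x_wall_for_area(min(areas), ly, n_leaf)
    points = []
    state = None
    velocities = None
    for k, area in enumerate(areas):
        xw = x_wall_for_area(area, ly, n_leaf)
        wall = dataclasses.replace(spec.wall, x_wall=xw)
        spec_k = dataclasses.replace(spec, wall=wall)
        if state is None:
            state = build_system(spec_k)
            if equilibration_steps:
                eq = run(
                    spec_k,
                    state,
                    n_steps=equilibration_steps,
                    sample_every=equilibration_steps,
                )
                state = eq.trajectory.frames[-1]
                velocities = eq.final_velocities
        elif relax_steps:
            # walls just jumped: relax overstretched restraints gently,
            # then re-equilibrate thermally before sampling
            relax = run(
                spec_k,
                state,
                n_steps=relax_steps,
                sample_every=relax_steps,
                velocities=velocities,
                probe=False,
                max_speed=relax_max_speed,
            )
            state = relax.trajectory.frames[-1]
            velocities = relax.final_velocities
            if between_equilibration_steps:
                eq = run(
                    spec_k,
                    state,
                    n_steps=between_equilibration_steps,
                    sample_every=between_equilibration_steps,
                    velocities=velocities,
                    probe=False,
                )
                state = eq.trajectory.frames[-1]
                velocities = eq.final_velocities
        output = run(
            spec_k,
            state,
            n_steps=per_area_steps,
            sample_every=sample_every,
            velocities=velocities,
        )
        points.append(
            analyze_run(
                output,
                spec_k,
                lz_ref=lz_ref,
                gamma_w=gamma_w,
                burn_in_frac=burn_in_frac,
                n_blocks=n_blocks,
                bin_width=bin_width,
                observation_width=observation_width,
            )
        )
        state = output.trajectory.frames[-1]
        velocities = output.final_velocities
    return Isotherm(
        points=points,
        units="reduced",
        temperature=spec.temperature,
        direction=direction,
    )


def plateau_detect(
    isotherm: Isotherm, slope_threshold: float
) -> tuple[float, float] | None:
    """Longest contiguous area interval with |dΠ/dA| below the threshold.

    Centered finite differences on interior points; a qualifying interior
    point spans its two adjacent segments.  Returns (area_lo, area_hi) or
    None.  Intended as a phase-coexistence diagnostic: LE–LC coexistence
    shows up as a near-flat stretch of the isotherm.
    """
    if len(isotherm.points) < 4:
        raise ValueError("plateau detection needs at least 4 points")
    areas = isotherm.areas()
    pi = isotherm.pi_real()
    slopes = (pi[2:] - pi[:-2]) / (areas[2:] - areas[:-2])
    qualifying = np.abs(slopes) < slope_threshold
    best: tuple[int, int] | None = None
    i = 0
    while i < len(qualifying):
        if qualifying[i]:
            j = i
            while j + 1 < len(qualifying) and qualifying[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    lo_ix, hi_ix = best[0], best[1] + 2  # interior index k spans points k..k+2
    a0, a1 = areas[lo_ix], areas[hi_ix]
    return (min(a0, a1), max(a0, a1))


def combine_isotherms(isotherms: Sequence[Isotherm]) -> Isotherm:
    """Combine replicate sweeps by inverse-variance weighting per area.

    All replicates must share the same area grid (to rounding).
    """
    if not isotherms:
        raise ValueError("need at least one isotherm")
    base = isotherms[0]
    grids = [iso.areas() for iso in isotherms]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
            raise ValueError("replicate isotherms must share the area grid")
    points = []
    for k in range(len(base.points)):
        reps = [iso.points[k] for iso in isotherms]
        w = np.array(
            [1.0 / p.pi_real_err**2 if p.pi_real_err > 0 else 1.0 for p in reps]
        )
        w /= w.sum()
        pi_re = float(np.sum(w * [p.pi_real for p in reps]))
        pi_re_err = float(np.sqrt(np.sum(w**2 * [p.pi_real_err**2 for p in reps])))
        xi = float(np.sum(w * [p.xi for p in reps]))
        pi_id = pi_re / xi if xi > 0 else float(np.mean([p.pi_ideal for p in reps]))
        points.append(
            IsothermPoint(
                area_per_lipid=base.points[k].area_per_lipid,
                pi_ideal=pi_id,
                pi_ideal_err=float(np.mean([p.pi_ideal_err for p in reps])),
                pi_real=pi_re,
                pi_real_err=pi_re_err,
                xi=xi,
                lz_int=float(np.mean([p.lz_int for p in reps])),
                equilibrated=all(p.equilibrated for p in reps),
            )
        )
    return Isotherm(
        points=points,
        units=base.units,
        temperature=base.temperature,
        direction=base.direction,
    )
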