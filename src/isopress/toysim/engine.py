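"""BAOAB Langevin engine with linked-cell force-shifted pair interactions.

The whole integration loop runs inside a single numba-compiled kernel:
forces, virials, wall restraints and the thermostat noise (legacy numpy
RNG seeded once inside the kernel) are all evaluated there, which makes a
run bitwise reproducible for a given seed.

Periodic boundaries apply in all three directions; the vacuum region along
z makes z-periodicity inert.  The pressure tensor is the instantaneous
kinetic + virial estimator, with pair, bond and wall (external) terms; pair
forces are force-shifted at the cutoff so the logged tensor is
self-consistent with the truncated potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ..trajio import Frame, PressureTensorSeries, Trajectory

__all__ = ["ToyRunOutput", "IntegrationError", "run"]

SPECIES = ("W", "H", "T")


class IntegrationError(RuntimeError):
    """Trajectory diverged (coordinate blow-up); carries the step number."""

    def __init__(self, step: int):
        super().__init__(f"integration diverged at step {step}")
        self.step = step


@dataclass
class ToyRunOutput:
    """Logs of one toy run, time-aligned with the sampled frames."""

    trajectory: Trajectory
    wall_force_log: pd.DataFrame
    pressure_log: PressureTensorSeries
    energy_log: pd.DataFrame
    final_positions: np.ndarray
    final_velocities: np.ndarray


@njit(cache=True)
def _forces(
    pos,
    frc,
    codes,
    eps,
    sig2,
    rc2,
    frc_rc,
    u_rc,
    lx,
    ly,
    lz,
    restrained,
    x_wall,
    k_wall,
    quadratic,
    bonds,
    bond_k,
    bond_r0,
    cell_head,
    cell_next,
    ncx,
    ncy,
    ncz,
    offsets,
    wall_sp,
):
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    pot = 0.0
    wall_total = 0.0
    for s in range(wall_sp.shape[0]):
        wall_sp[s] = 0.0

    # ---- linked cells
    ncells = ncx * ncy * ncz
    for c in range(ncells):
        cell_head[c] = -1
    cwx = lx / ncx
    cwy = ly / ncy
    cwz = lz / ncz
    for i in range(n):
        cx = int((pos[i, 0] + 0.5 * lx) / cwx)
        cy = int((pos[i, 1] + 0.5 * ly) / cwy)
        cz = int((pos[i, 2] + 0.5 * lz) / cwz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        cell_next[i] = cell_head[c]
        cell_head[c] = i

    # ---- pair interactions over half neighbour stencil
    # cells are at least one cutoff wide, so the minimum image between
    # particles of adjacent cells is the per-cell shift applied below
    rc2_max = rc2.max()
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                i = cell_head[c]
                while i >= 0:
                    xi = pos[i, 0]
                    yi = pos[i, 1]
                    zi = pos[i, 2]
                    a = codes[i]
                    # same cell, j after i in the list: no image shift
                    j = cell_next[i]
                    while j >= 0:
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2_max:
                            b = codes[j]
                            if 1e-12 < r2 < rc2[a, b] and eps[a, b] > 0.0:
                                s2 = sig2[a, b] / r2
                                s6 = s2 * s2 * s2
                                r = math.sqrt(r2)
                                fmag = (
                                    24.0 * eps[a, b] * (2.0 * s6 * s6 - s6) / r
                                    - frc_rc[a, b]
                                )
                                rcut = math.sqrt(rc2[a, b])
                                pot += (
                                    4.0 * eps[a, b] * (s6 * s6 - s6)
                                    - u_rc[a, b]
                                    + (r - rcut) * frc_rc[a, b]
                                )
                                fx = fmag * dx / r
                                fy = fmag * dy / r
                                fz = fmag * dz / r
                                frc[i, 0] += fx
                                frc[i, 1] += fy
                                frc[i, 2] += fz
                                frc[j, 0] -= fx
                                frc[j, 1] -= fy
                                frc[j, 2] -= fz
                                wxx += fx * dx
                                wyy += fy * dy
                                wzz += fz * dz
                        j = cell_next[j]
                    # neighbour cells (13 forward offsets) with image shifts
                    for o in range(13):
                        nx = cx + offsets[o, 0]
                        ny = cy + offsets[o, 1]
                        nz = cz + offsets[o, 2]
                        sx = 0.0
                        sy = 0.0
                        sz = 0.0
                        if nx < 0:
                            nx += ncx
                            sx = -lx
                        elif nx >= ncx:
                            nx -= ncx
                            sx = lx
                        if ny < 0:
                            ny += ncy
                            sy = -ly
                        elif ny >= ncy:
                            ny -= ncy
                            sy = ly
                        if nz < 0:
                            nz += ncz
                            sz = -lz
                        elif nz >= ncz:
                            nz -= ncz
                            sz = lz
                        xis = xi - sx
                        yis = yi - sy
                        zis = zi - sz
                        c2 = (nx * ncy + ny) * ncz + nz
                        j = cell_head[c2]
                        while j >= 0:
                            dx = xis - pos[j, 0]
                            dy = yis - pos[j, 1]
                            dz = zis - pos[j, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < rc2_max:
                                b = codes[j]
                                if 1e-12 < r2 < rc2[a, b] and eps[a, b] > 0.0:
                                    s2 = sig2[a, b] / r2
                                    s6 = s2 * s2 * s2
                                    r = math.sqrt(r2)
                                    fmag = (
                                        24.0 * eps[a, b] * (2.0 * s6 * s6 - s6) / r
                                        - frc_rc[a, b]
                                    )
                                    rcut = math.sqrt(rc2[a, b])
                                    pot += (
                                        4.0 * eps[a, b] * (s6 * s6 - s6)
                                        - u_rc[a, b]
                                        + (r - rcut) * frc_rc[a, b]
                                    )
                                    fx = fmag * dx / r
                                    fy = fmag * dy / r
                                    fz = fmag * dz / r
                                    frc[i, 0] += fx
                                    frc[i, 1] += fy
                                    frc[i, 2] += fz
                                    frc[j, 0] -= fx
                                    frc[j, 1] -= fy
                                    frc[j, 2] -= fz
                                    wxx += fx * dx
                                    wyy += fy * dy
                                    wzz += fz * dz
                            j = cell_next[j]
                    i = cell_next[i]

    # ---- harmonic bonds
    for b_ix in range(bonds.shape[0]):
        i = bonds[b_ix, 0]
        j = bonds[b_ix, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * math.floor(dx / lx + 0.5)
        dy -= ly * math.floor(dy / ly + 0.5)
        dz -= lz * math.floor(dz / lz + 0.5)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 1e-12:
            fmag = -bond_k * (r - bond_r0)  # >0 means repulsive (pushes apart)
            pot += 0.5 * bond_k * (r - bond_r0) ** 2
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            frc[i, 0] += fx
            frc[i, 1] += fy
            frc[i, 2] += fz
            frc[j, 0] -= fx
            frc[j, 1] -= fy
            frc[j, 2] -= fz
            wxx += fx * dx
            wyy += fy * dy
            wzz += fz * dz

    # ---- flat-bottom walls at x = ±x_wall (restrained species only)
    if k_wall > 0.0:
        for i in range(n):
            if restrained[codes[i]]:
                ax = abs(pos[i, 0])
                pen = ax - x_wall
                if pen > 0.0:
                    if quadratic:
                        fmag = k_wall * pen * pen
                        pot += k_wall * pen * pen * pen / 3.0
                    else:
                        fmag = k_wall * pen
                        pot += 0.5 * k_wall * pen * pen
                    fx = -fmag if pos[i, 0] > 0.0 else fmag
                    frc[i, 0] += fx
                    wxx += pos[i, 0] * fx
                    wall_total += fmag
                    wall_sp[codes[i]] += fmag
    return wxx, wyy, wzz, pot, wall_total


@njit(cache=True)
def _run_kernel(
    pos,
    vel,
    codes,
    eps,
    sig2,
    rc2,
    frc_rc,
    u_rc,
    lx,
    ly,
    lz,
    restrained,
    x_wall,
    k_wall,
    quadratic,
    bonds,
    bond_k,
    bond_r0,
    dt,
    friction,
    temperature,
    vmax,
    n_steps,
    sample_every,
    seed,
    ncx,
    ncy,
    ncz,
    frames_out,
    times_out,
    wallf_out,
    wallf_sp_out,
    press_out,
    energy_out,
):
    np.random.seed(seed)
    n = pos.shape[0]
    nsp = eps.shape[0]
    frc = np.zeros((n, 3))
    cell_head = np.empty(ncx * ncy * ncz, dtype=np.int64)
    cell_next = np.empty(n, dtype=np.int64)
    wall_sp = np.zeros(nsp)
    offsets = np.empty((13, 3), dtype=np.int64)  # forward half-stencil
    o = 0
    for dxo in range(-1, 2):
        for dyo in range(-1, 2):
            for dzo in range(-1, 2):
                key = dxo * 9 + dyo * 3 + dzo
                if key > 0:
                    offsets[o, 0] = dxo
                    offsets[o, 1] = dyo
                    offsets[o, 2] = dzo
                    o += 1

    c1 = math.exp(-friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * temperature)
    volume = lx * ly * lz
    half_dt = 0.5 * dt

    wxx, wyy, wzz, pot, wall_total = _forces(
        pos, frc, codes, eps, sig2, rc2, frc_rc, u_rc, lx, ly, lz,
        restrained, x_wall, k_wall, quadratic, bonds, bond_k, bond_r0,
        cell_head, cell_next, ncx, ncy, ncz, offsets, wall_sp,
    )

    sample_ix = 0
    limit = 10.0 * max(lx, max(ly, lz))
    for step in range(1, n_steps + 1):
        # B
        for i in range(n):
            vel[i, 0] += half_dt * frc[i, 0]
            vel[i, 1] += half_dt * frc[i, 1]
            vel[i, 2] += half_dt * frc[i, 2]
        if vmax > 0.0:
            for i in range(n):
                for d in range(3):
                    if vel[i, d] > vmax:
                        vel[i, d] = vmax
                    elif vel[i, d] < -vmax:
                        vel[i, d] = -vmax
        # A
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # O
        if friction > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.standard_normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.standard_normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.standard_normal()
        # A
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
            pos[i, 0] -= lx * math.floor(pos[i, 0] / lx + 0.5)
            pos[i, 1] -= ly * math.floor(pos[i, 1] / ly + 0.5)
            pos[i, 2] -= lz * math.floor(pos[i, 2] / lz + 0.5)
        # B with fresh forces
        wxx, wyy, wzz, pot, wall_total = _forces(
            pos, frc, codes, eps, sig2, rc2, frc_rc, u_rc, lx, ly, lz,
            restrained, x_wall, k_wall, quadratic, bonds, bond_k, bond_r0,
            cell_head, cell_next, ncx, ncy, ncz, offsets, wall_sp,
        )
        for i in range(n):
            vel[i, 0] += half_dt * frc[i, 0]
            vel[i, 1] += half_dt * frc[i, 1]
            vel[i, 2] += half_dt * frc[i, 2]
        if vmax > 0.0:
            for i in range(n):
                for d in range(3):
                    if vel[i, d] > vmax:
                        vel[i, d] = vmax
                    elif vel[i, d] < -vmax:
                        vel[i, d] = -vmax

        if step % sample_every == 0:
            kx = 0.0
            ky = 0.0
            kz = 0.0
            for i in range(n):
                if not math.isfinite(pos[i, 0]) or abs(pos[i, 0]) > limit:
                    return step
                if not math.isfinite(pos[i, 2]) or abs(pos[i, 2]) > limit:
                    return step
                kx += vel[i, 0] * vel[i, 0]
                ky += vel[i, 1] * vel[i, 1]
                kz += vel[i, 2] * vel[i, 2]
            times_out[sample_ix] = step * dt
            press_out[sample_ix, 0] = (kx + wxx) / volume
            press_out[sample_ix, 1] = (ky + wyy) / volume
            press_out[sample_ix, 2] = (kz + wzz) / volume
            wallf_out[sample_ix] = wall_total
            for s in range(nsp):
                wallf_sp_out[sample_ix, s] = wall_sp[s]
            kinetic = 0.5 * (kx + ky + kz)
            energy_out[sample_ix, 0] = kinetic
            energy_out[sample_ix, 1] = pot
            energy_out[sample_ix, 2] = kinetic / (1.5 * n)
            for i in range(n):
                frames_out[sample_ix, i, 0] = pos[i, 0]
                frames_out[sample_ix, i, 1] = pos[i, 1]
                frames_out[sample_ix, i, 2] = pos[i, 2]
            sample_ix += 1
    return 0


def _pair_arrays(spec):
    nsp = len(SPECIES)
    eps = np.zeros((nsp, nsp))
    sig2 = np.ones((nsp, nsp))
    rc2 = np.ones((nsp, nsp))
    frc_rc = np.zeros((nsp, nsp))
    u_rc = np.zeros((nsp, nsp))
    for a, sa in enumerate(SPECIES):
        for b, sb in enumerate(SPECIES):
            e, sigma, rc = spec.pair_param(sa, sb)
            eps[a, b] = e
            sig2[a, b] = sigma * sigma
            rc2[a, b] = rc * rc
            if e > 0:
                s6 = (sigma / rc) ** 6
                frc_rc[a, b] = 24.0 * e * (2.0 * s6 * s6 - s6) / rc
                u_rc[a, b] = 4.0 * e * (s6 * s6 - s6)
    return eps, sig2, rc2, frc_rc, u_rc


def _wrap(coords: np.ndarray, box) -> np.ndarray:
    lengths = np.asarray(box)
    return coords - lengths * np.floor(coords / lengths + 0.5)


def initial_velocities(spec, n: int) -> np.ndarray:
    """Maxwell–Boltzmann draw at the target temperature, zero net momentum."""
    rng = np.random.default_rng((spec.seed + 1) % 2**31)
    vel = rng.normal(scale=math.sqrt(spec.temperature), size=(n, 3))
    vel -= vel.mean(axis=0)
    return vel


def run(
    spec,
    initial: Frame,
    n_steps: int,
    sample_every: int = 20,
    velocities: np.ndarray | None = None,
    probe: bool = True,
    max_speed: float = 0.0,
) -> ToyRunOutput:
    """Integrate a toy system and log frames, wall forces and pressures.

    Parameters
    ----------
    spec : ToyModelSpec
        Model parameters (interactions, thermostat, walls, box).
    initial
        Starting frame, e.g. from :func:`~isopress.toysim.build_system` or
        the final state of a previous run.
    n_steps, sample_every
        Total integration steps and the logging stride.
    velocities
        Optional starting velocities; drawn from the Maxwell distribution
        at the target temperature when omitted.
    probe
        Run a short stability probe first and fail fast on a divergent
        timestep.
    max_speed
        When positive, clamp each velocity component to ±max_speed after
        every kick (displacement-limited dynamics).  Used to relax
        configurations with overstretched restraints — e.g. right after an
        instantaneous wall repositioning — without integrator blow-up;
        production runs leave it at 0 (off).
    """
    if n_steps < sample_every:
        raise ValueError("n_steps must be at least sample_every")
    codes = np.array(
        [SPECIES.index(s) for s in initial.species], dtype=np.int64
    )
    n = len(codes)
    eps, sig2, rc2, frc_rc, u_rc = _pair_arrays(spec)
    lx, ly, lz = spec.box
    rc_max = math.sqrt(rc2.max())
    ncx, ncy, ncz = (max(1, int(d / rc_max)) for d in (lx, ly, lz))
    if min(ncx, ncy, ncz) < 3:
        raise ValueError("box must span at least three cutoffs per direction")
    restrained = np.array(
        [s in spec.wall.restrained_species for s in SPECIES], dtype=np.bool_
    )
    has_restrained = bool(np.any(restrained[codes]))
    k_wall = spec.wall.k if has_restrained else 0.0
    quadratic = spec.wall.force_law == "quadratic-penetration"
    bonds = _bond_array(spec, n)

    pos = _wrap(np.array(initial.coords, dtype=np.float64), spec.box)
    vel = (
        np.array(velocities, dtype=np.float64)
        if velocities is not None
        else initial_velocities(spec, n)
    )
    seed = spec.seed % 2**31

    def _launch(p, v, steps, stride, rng_seed):
        n_samples = steps // stride
        frames = np.empty((n_samples, n, 3))
        times = np.empty(n_samples)
        wallf = np.empty(n_samples)
        wallf_sp = np.empty((n_samples, len(SPECIES)))
        press = np.empty((n_samples, 3))
        energy = np.empty((n_samples, 3))
        err = _run_kernel(
            p, v, codes, eps, sig2, rc2, frc_rc, u_rc, lx, ly, lz,
            restrained, spec.wall.x_wall, k_wall, quadratic,
            bonds, spec.bond_k, spec.bond_r0,
            spec.dt, spec.friction, spec.temperature, max_speed,
            steps, stride, rng_seed, ncx, ncy, ncz,
            frames, times, wallf, wallf_sp, press, energy,
        )
        if err != 0:
            raise IntegrationError(err)
        return frames, times, wallf, wallf_sp, press, energy

    if probe and n_steps > 100:
        pf, *_rest, penergy = _launch(pos.copy(), vel.copy(), 100, 10, seed)
        if not np.all(np.isfinite(penergy)):
            raise IntegrationError(100)

    frames, times, wallf, wallf_sp, press, energy = _launch(
        pos, vel, n_steps, sample_every, seed
    )

    species = np.asarray(initial.species, dtype=str)
    traj = Trajectory(
        [
            Frame(frames[k], species, spec.box, float(times[k]))
            for k in range(len(times))
        ]
    )
    wall_df = pd.DataFrame({"time": times, "f_total": wallf})
    for s, name in enumerate(SPECIES):
        if restrained[s]:
            wall_df[f"f_{name}"] = wallf_sp[:, s]
    pressure = PressureTensorSeries(
        times, press[:, 0], press[:, 1], press[:, 2], box_lz=lz, units="reduced"
    )
    energy_df = pd.DataFrame(
        {
            "time": times,
            "kinetic": energy[:, 0],
            "potential": energy[:, 1],
            "temperature": energy[:, 2],
        }
    )
    return ToyRunOutput(
        trajectory=traj,
        wall_force_log=wall_df,
        pressure_log=pressure,
        energy_log=energy_df,
        final_positions=pos,
        final_velocities=vel,
    )


def _bond_array(spec, n_total: int) -> np.ndarray:
    from .model import bond_list  # deferred: model imports nothing from here

    bonds = bond_list(spec)
    if len(bonds) and bonds.max() >= n_total:
        raise ValueError("bond index beyond particle count")
    return bonds
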