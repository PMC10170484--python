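"""Osmotic route to the surface pressure of a confined monolayer.

Two semipermeable virtual walls at x = ±x_wall confine the surfactants
(solvent passes freely), playing the role of the mobile barriers of a
Langmuir trough.  The walls apply a flat-bottom planar restraint to every
surfactant bead beyond them; the time-averaged total restoring force
⟨F_wall⟩ is the osmotic force.  The ideal 2D surface pressure follows as

    Π_ideal = ⟨F_wall⟩ / (4 L_y)

— the factor 4 counts the four intersections of the two walls with the two
air–monolayer–water interfaces of the slab.  The semi-empirical correction
Π_real = Π_ideal·ξ rescales by the interfacial-thickness ratio ξ computed
in :mod:`isopress.profiles`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .trajio import Trajectory
from .units import check_units, force_per_length_to_output
from .profiles import XiCoefficient

__all__ = [
    "WallSpec",
    "WallForceRecord",
    "wall_force",
    "pi_ideal",
    "pi_real",
    "block_uncertainty",
    "FORCE_LAWS",
]

FORCE_LAWS = ("quadratic-penetration", "linear-penetration")


@dataclass(frozen=True)
class WallSpec:
    """Semipermeable flat-bottom walls at x = ±x_wall.

    ``k`` is in kcal mol⁻¹ Å⁻³ for the quadratic law (force k·d² at
    penetration depth d, the units print of the reference setup) or
    kcal mol⁻¹ Å⁻² for the linear law — or the reduced equivalents.
    """

    x_wall: float
    k: float = 20.0
    force_law: str = "quadratic-penetration"
    restrained_species: frozenset[str] = frozenset({"H", "T"})

    def __post_init__(self) -> None:
        if self.x_wall <= 0:
            raise ValueError("x_wall must be positive")
        if self.k <= 0:
            raise ValueError("force constant k must be positive")
        if self.force_law not in FORCE_LAWS:
            raise ValueError(f"force_law must be one of {FORCE_LAWS}")
        if not self.restrained_species:
            raise ValueError("restrained_species must be non-empty")
        object.__setattr__(
            self, "restrained_species", frozenset(self.restrained_species)
        )

    def force_magnitude(self, penetration: float) -> float:
        """Restoring-force magnitude at a given penetration depth (> 0)."""
        if self.force_law == "quadratic-penetration":
            return self.k * penetration**2
        return self.k * penetration


@dataclass
class WallForceRecord:
    """Per-frame and mean wall restoring forces."""

    per_frame_force: np.ndarray
    mean_force: float
    n_frames: int
    per_species_force: dict[str, float]

    def __post_init__(self) -> None:
        self.per_frame_force = np.asarray(self.per_frame_force, dtype=np.float64)
        if np.any(self.per_frame_force < 0):
            raise ValueError("wall forces must be non-negative")


def wall_force(
    traj: Trajectory,
    wall: WallSpec,
    sanity_distance: float = 5.0,
) -> WallForceRecord:
    """Accumulate wall restoring forces over a trajectory.

    For each frame, beads of the restrained species with |x| > x_wall
    contribute the force-law magnitude at penetration depth |x| − x_wall;
    both walls contribute to a single total.  Accumulation is sequential in
    bead-index order so the result is reproducible against a naive
    double-loop reference bit for bit.

    A bead beyond a wall by more than ``sanity_distance`` triggers a
    warning (escaped surfactant).
    """
    if len(traj) == 0:
        raise ValueError("trajectory has no frames")
    restrained = sorted(wall.restrained_species)
    present = traj.species_set()
    if not any(sp in present for sp in restrained):
        raise ValueError(
            f"none of the restrained species {restrained} present in trajectory"
        )
    per_frame = np.zeros(len(traj))
    species_totals = {sp: 0.0 for sp in restrained}
    max_pen = 0.0
    for t, fr in enumerate(traj):
        frame_total = 0.0
        frame_species = {sp: 0.0 for sp in restrained}
        for i in range(fr.n_particles):
            sp = str(fr.species[i])
            if sp not in wall.restrained_species:
                continue
            pen = abs(fr.coords[i, 0]) - wall.x_wall
            if pen > 0.0:
                f = wall.force_magnitude(pen)
                frame_total += f
                frame_species[sp] += f
                if pen > max_pen:
                    max_pen = pen
        per_frame[t] = frame_total
        for sp in restrained:
            species_totals[sp] += frame_species[sp]
    if max_pen > sanity_distance:
        warnings.warn(
            f"bead found {max_pen:.2f} length units beyond a wall "
            f"(> sanity distance {sanity_distance}); escaped surfactant?",
            stacklevel=2,
        )
    n = len(traj)
    # sequential frame sum, mirroring the per-frame accumulation order
    return WallForceRecord(
        per_frame_force=per_frame,
        mean_force=sum(per_frame.tolist()) / n,
        n_frames=n,
        per_species_force={sp: v / n for sp, v in species_totals.items()},
    )


def pi_ideal(
    record: WallForceRecord,
    l_y: float,
    per_species_depths: Mapping[str, float] | None = None,
    units: str = "reduced",
) -> float:
    """Ideal 2D surface pressure Π_ideal = ⟨F_wall⟩ / (4 L_y).

    When ``per_species_depths`` (species → interfacial depth τ_zα) is given,
    the per-species decomposition is evaluated instead: each species'
    3D osmotic-pressure contribution ⟨F_α⟩/(τ_zα·L_y) is multiplied back by
    its depth and summed.  The depths cancel algebraically, so this path
    must agree with the direct one to rounding — it exists as a consistency
    check on the species decomposition.

    Output in mN/m for real units (input forces kcal mol⁻¹ Å⁻¹, lengths Å),
    ε/σ² for reduced.
    """
    check_units(units)
    if l_y <= 0:
        raise ValueError("l_y must be positive")
    if per_species_depths is not None:
        missing = set(record.per_species_force) - set(per_species_depths)
        if missing:
            raise ValueError(f"missing depths for species: {sorted(missing)}")
        total = 0.0
        for sp in sorted(record.per_species_force):
            tau = per_species_depths[sp]
            if tau <= 0:
                raise ValueError(f"depth for species {sp!r} must be positive")
            pi_os_alpha = record.per_species_force[sp] / (tau * l_y)
            total += pi_os_alpha * tau
        value = total / 4.0
    else:
        value = record.mean_force / (4.0 * l_y)
    return force_per_length_to_output(value, units)


def pi_real(pi_ideal_value: float, xi: XiCoefficient | float) -> float:
    """Corrected surface pressure Π_real = Π_ideal·ξ."""
    if not math.isfinite(pi_ideal_value):
        raise ValueError("pi_ideal must be finite")
    xi_value = xi.xi if isinstance(xi, XiCoefficient) else float(xi)
    if not math.isfinite(xi_value) or xi_value < 0:
        raise ValueError("xi must be finite and non-negative")
    return pi_ideal_value * xi_value


def block_uncertainty(per_frame_values: Sequence[float], n_blocks: int) -> float:
    """Standard error of the mean by block averaging.

    The series is split into ``n_blocks`` contiguous equal blocks (any
    remainder frames at the end are dropped); the SE of the block means is
    returned.  Blocks longer than the correlation time make this a fair
    error estimate for correlated MD time series.
    """
    values = np.asarray(per_frame_values, dtype=np.float64)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(values) < n_blocks:
        raise ValueError(
            f"series of length {len(values)} shorter than {n_blocks} blocks"
        )
    block_len = len(values) // n_blocks
    trimmed = values[: block_len * n_blocks].reshape(n_blocks, block_len)
    means = trimmed.mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))
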