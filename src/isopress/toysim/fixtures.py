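"""Deterministic fixtures: hand-built penetration frames and short runs."""

from __future__ import annotations

import numpy as np

from ..osmotic import WallSpec
from ..trajio import Frame, Trajectory
from . import model
from .engine import ToyRunOutput, run

__all__ = [
    "generate_fixture",
    "penetration_frames",
    "PENETRATION_WALL",
    "FIXTURE_KINDS",
]

#: Wall used by the ``penetration-frames`` fixture: quadratic law, k = 20
#: (the force-constant value of the reference monolayer setup, in
#: kcal mol⁻¹ Å⁻³ when read in real units).
PENETRATION_WALL = WallSpec(
    x_wall=12.0,
    k=20.0,
    force_law="quadratic-penetration",
    restrained_species=frozenset({"H", "T"}),
)


def penetration_frames() -> Trajectory:
    """One hand-built frame with a single bead 1 length unit beyond a wall.

    With the quadratic force law and k = 20 the exact mean wall force is
    k·d² = 20 (force units): one surfactant head at x = x_wall + 1, every
    other bead safely inside.  Useful as a pencil-and-paper oracle.
    """
    box = (33.0, 8.0, 28.0)
    coords = np.array(
        [
            [13.0, 4.0, 3.0],  # H, 1.0 beyond the +x wall
            [5.0, 2.0, 3.5],  # T, inside
            [-11.0, 1.0, -3.0],  # H, inside
            [0.0, 0.0, 0.0],  # W, solvent (never restrained)
        ]
    )
    species = np.array(["H", "T", "H", "W"])
    return Trajectory([Frame(coords, species, box, time=0.0)])


FIXTURE_KINDS = (
    "penetration-frames",
    "clean-slab",
    "dilute-monolayer",
    "compressed-monolayer",
)


def generate_fixture(
    kind: str,
    seed: int = 12345,
    n_steps: int = 4000,
    sample_every: int = 20,
) -> Trajectory | ToyRunOutput:
    """Deterministic test fixtures.

    ``penetration-frames`` returns the hand-built :func:`penetration_frames`
    trajectory (its wall is :data:`PENETRATION_WALL`); the other kinds are
    short seeded runs of the corresponding preset.
    """
    if kind == "penetration-frames":
        return penetration_frames()
    if kind not in model.PRESETS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    spec = model.PRESETS[kind](seed=seed)
    initial = model.build_system(spec)
    return run(spec, initial, n_steps=n_steps, sample_every=sample_every)
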