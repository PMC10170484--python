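"""Toy monolayer model: species, pair table, system builder and presets.

The model is a deliberately generic coarse-grained amphiphile system in
reduced Lennard-Jones units (ε = σ = m = k_B = 1), not a fit to any real
lipid force field — the surface-pressure estimators under test are
force-field-agnostic.  Three species:

``W``  solvent bead.  Cohesive (attractive LJ) so it forms a liquid slab
       with two free interfaces normal to z at the chosen temperature.
``H``  surfactant head bead, hydrophilic (solvent-attractive), anchored at
       each interface.
``T``  surfactant tail bead(s), solvent-repulsive (WCA), bonded in a short
       chain pointing into the vacuum.

Surfactants live only between the two semipermeable walls at x = ±x_wall;
the solvent slab spans the whole (periodic) x length, leaving a
surfactant-free clean-interface margin beyond the walls so solvent can
exchange freely across the wall planes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..osmotic import WallSpec
from ..trajio import Frame

__all__ = [
    "ToyModelSpec",
    "ConstructionError",
    "DEFAULT_PAIR_TABLE",
    "IDEAL_GAS_PAIR_TABLE",
    "build_system",
    "clean_slab_spec",
    "dilute_monolayer_spec",
    "compressed_monolayer_spec",
    "ideal_gas_spec",
    "PRESETS",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

#: (ε, σ, r_cut) per species pair, reduced units.  The head bead is small
#: (σ 0.8) and moderately hydrated (ε_WH > ε_WW): when the film is dilute a
#: lone head floats in the existing interfacial zone and barely perturbs
#: the water decay, but under compression the crowded heads are pushed into
#: the near-surface water, where their excluded volume dilutes it and the
#: 90–10% interfacial zone thickens — the hydrated-headgroup-band behaviour
#: of a packed monolayer.  Tails are dry (WCA against water, pointing into
#: the vacuum) and the film itself is only weakly cohesive, so it stays a
#: monolayer instead of collapsing into a 3D aggregate.
DEFAULT_PAIR_TABLE: dict[tuple[str, str], tuple[float, float, float]] = {
    ("W", "W"): (1.0, 1.0, 2.5),
    ("W", "H"): (1.2, 0.9, 2.5),
    ("W", "T"): (0.25, 1.0, WCA_CUTOFF),
    ("H", "H"): (0.15, 0.8, 2.5),
    ("H", "T"): (0.15, 0.9, 2.5),
    ("T", "T"): (0.15, 1.0, 2.5),
}

#: All interactions off — free particles (ideal-gas reference).
IDEAL_GAS_PAIR_TABLE: dict[tuple[str, str], tuple[float, float, float]] = {
    pair: (0.0, 1.0, WCA_CUTOFF) for pair in DEFAULT_PAIR_TABLE
}


class ConstructionError(RuntimeError):
    """Initial configuration could not be packed without overlaps."""


@dataclass
class ToyModelSpec:
    """Parameters of one toy monolayer system.

    Defaults define the standard study conditions used by the test suite
    and the acceptance script: a ~1500-bead solvent slab at T = 0.5 with 15
    three-bead surfactants per leaflet at a dilute area per surfactant of
    2·x_wall·L_y/n_per_leaflet = 16 σ².
    """

    n_solvent: int = 1480
    n_surfactant: int = 30  # total over both leaflets; must be even
    tail_beads_per_surfactant: int = 2
    pair_table: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_TABLE)
    )
    bond_k: float = 100.0
    bond_r0: float = 1.0
    temperature: float = 0.5
    friction: float = 1.0
    dt: float = 0.005
    box: tuple[float, float, float] = (33.0, 10.0, 28.0)
    slab_density: float = 0.8
    wall: WallSpec = field(
        default_factory=lambda: WallSpec(
            x_wall=12.0,
            k=50.0,
            force_law="quadratic-penetration",
            restrained_species=frozenset({"H", "T"}),
        )
    )
    seed: int = 12345

    def __post_init__(self) -> None:
        if self.n_solvent <= 0:
            raise ValueError("n_solvent must be positive")
        if self.n_surfactant < 0 or self.n_surfactant % 2:
            raise ValueError("n_surfactant must be a non-negative even count")
        if self.n_surfactant and self.tail_beads_per_surfactant < 1:
            raise ValueError("surfactants need at least one tail bead")
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        interacting = False
        for (a, b), (eps, sigma, rc) in self.pair_table.items():
            if rc < sigma and eps > 0:
                raise ValueError(f"cutoff < sigma for pair ({a},{b})")
            interacting = interacting or eps > 0
        if interacting and self.vacuum_extent() <= 0:
            raise ValueError(
                "no vacuum region along z: enlarge the box or shrink the slab"
            )
        if self.n_surfactant and self.wall.x_wall >= self.box[0] / 2:
            raise ValueError("walls must lie inside the box")

    # -- derived geometry -------------------------------------------------

    def slab_height(self) -> float:
        lx, ly, _ = self.box
        return self.n_solvent / (self.slab_density * lx * ly)

    def vacuum_extent(self) -> float:
        """Total z extent not occupied by slab or surfactant tails."""
        tails = self.tail_beads_per_surfactant * self.bond_r0 if self.n_surfactant else 0.0
        return self.box[2] - self.slab_height() - 2.0 * (tails + 1.0)

    def margin(self) -> float:
        """Clean-interface margin between each wall and the box edge."""
        return self.box[0] / 2.0 - self.wall.x_wall

    @property
    def n_per_leaflet(self) -> int:
        return self.n_surfactant // 2

    def area_per_surfactant(self) -> float:
        if self.n_surfactant == 0:
            return math.inf
        return 2.0 * self.wall.x_wall * self.box[1] / self.n_per_leaflet

    def beads_per_surfactant(self) -> int:
        return 1 + self.tail_beads_per_surfactant

    def pair_param(self, a: str, b: str) -> tuple[float, float, float]:
        return self.pair_table.get((a, b)) or self.pair_table[(b, a)]


def _solvent_lattice(spec: ToyModelSpec, rng: np.random.Generator) -> np.ndarray:
    lx, ly, _ = spec.box
    s = (1.0 / spec.slab_density) ** (1.0 / 3.0)
    nx = max(1, int(lx / s))
    ny = max(1, int(ly / s))
    per_plane = nx * ny
    nz = int(math.ceil(spec.n_solvent / per_plane))
    sx = lx / nx
    sy = ly / ny
    xs = (np.arange(nx) + 0.5) * sx - lx / 2
    ys = (np.arange(ny) + 0.5) * sy - ly / 2
    zs = (np.arange(nz) - (nz - 1) / 2.0) * s
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    sites = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    # fill planes bottom-up so the slab stays centred
    order = np.argsort(sites[:, 2], kind="stable")
    sites = sites[order][: spec.n_solvent]
    sites += rng.uniform(-0.02, 0.02, size=sites.shape)
    return sites


def _surfactant_positions(
    spec: ToyModelSpec, z_surface: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Lay one leaflet per interface: heads near the surface, tails outward."""
    lx, ly, _ = spec.box
    n_leaf = spec.n_per_leaflet
    xw = spec.wall.x_wall
    pad = min(0.6, 0.25 * xw)
    width = 2 * (xw - pad)
    gx = max(1, int(round(math.sqrt(n_leaf * width / ly))))
    gy = int(math.ceil(n_leaf / gx))
    while ly / gy < 0.9 and gx < n_leaf:  # avoid sub-σ y spacing
        gx += 1
        gy = int(math.ceil(n_leaf / gx))
    coords = []
    species: list[str] = []
    for sign in (1.0, -1.0):
        placed = 0
        for ix in range(gx):
            for iy in range(gy):
                if placed >= n_leaf:
                    break
                x = -(xw - pad) + (ix + 0.5) * width / gx
                y = (iy + 0.5) * ly / gy - ly / 2
                zh = sign * (z_surface + 0.85)
                head = np.array([x, y, zh])
                head[:2] += rng.uniform(-0.05, 0.05, size=2)
                coords.append(head)
                species.append("H")
                for t in range(1, spec.tail_beads_per_surfactant + 1):
                    tail = head + np.array([0.0, 0.0, sign * t * spec.bond_r0])
                    coords.append(tail)
                    species.append("T")
                placed += 1
    return np.array(coords), species


def bond_list(spec: ToyModelSpec) -> np.ndarray:
    """Bonds (i, j) along each surfactant chain; solvent beads come first."""
    bonds = []
    bps = spec.beads_per_surfactant()
    for m in range(spec.n_surfactant):
        base = spec.n_solvent + m * bps
        for t in range(bps - 1):
            bonds.append((base + t, base + t + 1))
    return np.array(bonds, dtype=np.int64).reshape(-1, 2)


def build_system(spec: ToyModelSpec, max_retries: int = 20) -> Frame:
    """Deterministic initial configuration for a toy run.

    Solvent slab centred at z = 0; surfactant heads half a lattice spacing
    outside each solvent surface (well inside the interfacial zone), tails
    pointing into the vacuum; surfactants only between the walls.  Raises
    :class:`ConstructionError` if no overlap-free packing (non-bonded
    separation ≥ 0.8 σ) is found within ``max_retries`` jitter attempts.
    """
    half_h = spec.slab_height() / 2.0
    bps = spec.beads_per_surfactant()
    for attempt in range(max_retries):
        rng = np.random.default_rng((spec.seed + 7919 * attempt) % 2**31)
        solvent = _solvent_lattice(spec, rng)
        z_top = float(np.max(solvent[:, 2]))
        if spec.n_surfactant:
            surf, surf_species = _surfactant_positions(spec, z_top, rng)
            coords = np.vstack([solvent, surf])
            species = ["W"] * spec.n_solvent + surf_species
        else:
            coords = solvent
            species = ["W"] * spec.n_solvent
        if _min_nonbonded_ok(spec, coords):
            return Frame(
                coords=coords,
                species=np.array(species),
                box=spec.box,
                time=0.0,
            )
    raise ConstructionError(
        f"could not pack {len(coords)} beads without overlap "
        f"after {max_retries} attempts"
    )


def _min_nonbonded_ok(spec: ToyModelSpec, coords: np.ndarray, tol: float = 0.8) -> bool:
    lx, ly, lz = spec.box
    lengths = np.array([lx, ly, lz])
    shifted = np.mod(coords + lengths / 2, lengths)
    shifted = np.minimum(shifted, np.nextafter(lengths, 0.0))
    tree = cKDTree(shifted, boxsize=(lx, ly, lz))
    pairs = tree.query_pairs(r=tol)
    if not pairs:
        return True
    bonded = {tuple(sorted(b)) for b in bond_list(spec).tolist()}
    return all(tuple(sorted(p)) in bonded for p in pairs)


# -- presets ---------------------------------------------------------------


def clean_slab_spec(seed: int = 12345, **overrides) -> ToyModelSpec:
    """Surfactant-free solvent slab: γ_w and the dilute ξ reference."""
    return dataclasses.replace(
        ToyModelSpec(seed=seed), n_surfactant=0, **overrides
    )


def dilute_monolayer_spec(seed: int = 12345, **overrides) -> ToyModelSpec:
    """Default dilute monolayer (area per surfactant 16 σ²)."""
    return dataclasses.replace(ToyModelSpec(seed=seed), **overrides)


def compressed_monolayer_spec(seed: int = 12345, **overrides) -> ToyModelSpec:
    """Compressed monolayer: walls at ±3 σ (area per surfactant 4 σ²)."""
    spec = ToyModelSpec(seed=seed)
    wall = dataclasses.replace(spec.wall, x_wall=3.0)
    return dataclasses.replace(spec, wall=wall, **overrides)


def ideal_gas_spec(seed: int = 12345, n: int = 512, **overrides) -> ToyModelSpec:
    """Non-interacting solvent gas filling the box (pressure oracle NkT/V)."""
    spec = ToyModelSpec(
        n_solvent=n,
        n_surfactant=0,
        pair_table=dict(IDEAL_GAS_PAIR_TABLE),
        box=(16.0, 16.0, 16.0),
        slab_density=n / 16.0**3,  # lattice spans the whole box
        seed=seed,
    )
    return dataclasses.replace(spec, **overrides) if overrides else spec


PRESETS = {
    "clean-slab": clean_slab_spec,
    "dilute-monolayer": dilute_monolayer_spec,
    "compressed-monolayer": compressed_monolayer_spec,
    "ideal-gas": ideal_gas_spec,
}
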