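"""Wall-force accumulation, Π_ideal/Π_real and block uncertainties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopress import osmotic
from isopress.osmotic import (
    WallForceRecord,
    WallSpec,
    block_uncertainty,
    pi_ideal,
    pi_real,
    wall_force,
)
from isopress.profiles import xi_coefficient
from isopress.trajio import Frame, Trajectory

BOX = (30.0, 8.0, 24.0)


def naive_wall_force(traj, wall):
    """Independent double-loop reference: frames × beads, sequential sums."""
    totals = []
    for fr in traj:
        total = 0.0
        for i in range(fr.n_particles):
            if str(fr.species[i]) not in wall.restrained_species:
                continue
            pen = abs(fr.coords[i, 0]) - wall.x_wall
            if pen > 0.0:
                if wall.force_law == "quadratic-penetration":
                    total += wall.k * pen**2
                else:
                    total += wall.k * pen
        totals.append(total)
    acc = 0.0
    for t in totals:
        acc += t
    return acc / len(totals), totals


def random_penetration_traj(rng, n_frames=4, n_beads=30):
    species = rng.choice(["W", "H", "T"], size=n_beads)
    frames = []
    for t in range(n_frames):
        coords = np.column_stack(
            [
                rng.uniform(-14.5, 14.5, n_beads),  # some beads beyond ±12
                rng.uniform(-4, 4, n_beads),
                rng.uniform(-10, 10, n_beads),
            ]
        )
        frames.append(Frame(coords, species, BOX, time=float(t)))
    return Trajectory(frames)


class TestWallForce:
    def test_single_bead_hand_value(self):
        """One bead 1 Å beyond the wall, k = 20, quadratic → force exactly 20."""
        coords = np.array([[13.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        traj = Trajectory([Frame(coords, ["H", "W"], BOX)])
        wall = WallSpec(x_wall=12.0, k=20.0)
        assert wall_force(traj, wall).mean_force == 20.0

    def test_linear_law_hand_value(self):
        coords = np.array([[-14.0, 0.0, 0.0]])  # 2 beyond the -x wall
        traj = Trajectory([Frame(coords, ["H"], BOX)])
        wall = WallSpec(x_wall=12.0, k=5.0, force_law="linear-penetration")
        assert wall_force(traj, wall, sanity_distance=5.0).mean_force == 10.0

    def test_no_penetration_gives_zero(self):
        rng = np.random.default_rng(0)
        coords = np.column_stack(
            [rng.uniform(-11, 11, 20), rng.uniform(-4, 4, 20), rng.uniform(-10, 10, 20)]
        )
        traj = Trajectory([Frame(coords, ["H"] * 20, BOX)])
        assert wall_force(traj, WallSpec(x_wall=12.0, k=20.0)).mean_force == 0.0

    def test_half_occupancy_mean(self):
        f0 = Frame(np.array([[13.0, 0.0, 0.0]]), ["H"], BOX, time=0.0)
        f1 = Frame(np.array([[11.0, 0.0, 0.0]]), ["H"], BOX, time=1.0)
        rec = wall_force(Trajectory([f0, f1]), WallSpec(x_wall=12.0, k=20.0))
        assert rec.mean_force == 10.0

    @pytest.mark.parametrize("law", ["quadratic-penetration", "linear-penetration"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_double_loop_exactly(self, seed, law):
        rng = np.random.default_rng(seed)
        traj = random_penetration_traj(rng)
        wall = WallSpec(
            x_wall=12.0, k=rng.uniform(5, 40), force_law=law
        )
        rec = wall_force(traj, wall, sanity_distance=10.0)
        ref_mean, ref_frames = naive_wall_force(traj, wall)
        assert rec.mean_force == ref_mean  # bitwise, same accumulation order
        assert list(rec.per_frame_force) == ref_frames

    def test_per_species_forces_sum_to_total(self):
        rng = np.random.default_rng(11)
        traj = random_penetration_traj(rng)
        rec = wall_force(traj, WallSpec(x_wall=12.0), sanity_distance=10.0)
        assert sum(rec.per_species_force.values()) == pytest.approx(
            rec.mean_force, rel=1e-12
        )

    def test_reflection_invariance(self):
        rng = np.random.default_rng(12)
        traj = random_penetration_traj(rng)
        mirrored = Trajectory(
            [
                Frame(f.coords * np.array([-1.0, 1.0, 1.0]), f.species, f.box, f.time)
                for f in traj
            ]
        )
        wall = WallSpec(x_wall=12.0, k=20.0)
        a = wall_force(traj, wall, sanity_distance=10.0)
        b = wall_force(mirrored, wall, sanity_distance=10.0)
        assert a.mean_force == b.mean_force

    def test_escaped_bead_warns(self):
        coords = np.array([[15.0, 0.0, 0.0]])  # > 1 beyond with tight sanity
        traj = Trajectory([Frame(coords, ["H"], BOX)])
        with pytest.warns(UserWarning, match="escaped"):
            wall_force(traj, WallSpec(x_wall=12.0), sanity_distance=1.0)

    def test_absent_species_rejected(self):
        traj = Trajectory([Frame(np.zeros((1, 3)), ["W"], BOX)])
        with pytest.raises(ValueError):
            wall_force(traj, WallSpec(x_wall=12.0))


class TestWallSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"x_wall": -1.0},
            {"x_wall": 1.0, "k": 0.0},
            {"x_wall": 1.0, "force_law": "cubic"},
            {"x_wall": 1.0, "restrained_species": frozenset()},
        ],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            WallSpec(**kwargs)


def record(mean, per_species=None, n=1):
    values = np.full(n, mean)
    return WallForceRecord(
        per_frame_force=values,
        mean_force=mean,
        n_frames=n,
        per_species_force=per_species or {},
    )


class TestPiIdeal:
    def test_zero_force(self):
        assert pi_ideal(record(0.0), l_y=8.0) == 0.0

    def test_real_units_conversion(self):
        """⟨F⟩ = 4 kcal mol⁻¹ Å⁻¹ over L_y = 1 Å is 1 kcal mol⁻¹ Å⁻², which
        must convert to 694.77 mN/m (independent SI chain in the assert)."""
        value = pi_ideal(record(4.0), l_y=1.0, units="real")
        expected = (4.0 / (4 * 1.0)) * 4184.0 / 6.02214076e23 / 1e-20 * 1e3
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(694.77, abs=0.005)

    def test_doubling_ly_halves(self):
        assert pi_ideal(record(4.0), l_y=2.0) == pi_ideal(record(4.0), l_y=1.0) / 2

    @pytest.mark.parametrize("seed", range(8))
    def test_species_decomposition_equals_total(self, seed):
        """The per-species route (3D osmotic pressures times depths) must
        collapse to ⟨F⟩/(4·L_y): the depths cancel algebraically."""
        rng = np.random.default_rng(seed)
        forces = {sp: rng.uniform(0, 10) for sp in ("H", "T")}
        depths = {sp: rng.uniform(0.5, 5.0) for sp in ("H", "T")}
        total = sum(forces.values())
        rec = record(total, per_species=forces)
        a = pi_ideal(rec, l_y=8.0, per_species_depths=depths)
        b = pi_ideal(rec, l_y=8.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_depth_rejected(self):
        rec = record(1.0, per_species={"H": 1.0})
        with pytest.raises(ValueError):
            pi_ideal(rec, l_y=1.0, per_species_depths={})

    def test_nonpositive_ly_rejected(self):
        with pytest.raises(ValueError):
            pi_ideal(record(1.0), l_y=0.0)


class TestPiReal:
    def test_dilute_identity(self):
        assert pi_real(40.0, xi_coefficient(2.0, 2.0)) == 40.0

    def test_half(self):
        assert pi_real(40.0, 0.5) == 20.0

    def test_degenerate_zero(self):
        assert pi_real(40.0, 0.0) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pi_real(math.nan, 1.0)


class TestBlockUncertainty:
    def test_constant_series(self):
        assert block_uncertainty(np.ones(100), 5) == 0.0

    def test_alternating_series(self):
        series = np.tile([1.0, -1.0], 20)
        assert block_uncertainty(series, 4) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            block_uncertainty([1.0, 2.0], 5)

    @settings(derandomize=True, max_examples=30)
    @given(
        scale=st.floats(1e-3, 1e3),
        seed=st.integers(0, 2**16),
        n_blocks=st.integers(2, 8),
    )
    def test_linear_in_scale(self, scale, seed, n_blocks):
        """SE is homogeneous of degree 1 in the series scale."""
        rng = np.random.default_rng(seed)
        series = rng.standard_normal(64)
        a = block_uncertainty(series, n_blocks)
        b = block_uncertainty(scale * series, n_blocks)
        assert b == pytest.approx(scale * a, rel=1e-9)

    def test_iid_normal_monte_carlo(self):
        """For iid noise the block SE estimates σ/√N; across 100 seeded
        repeats every estimate stays within 3× either way."""
        n, blocks = 1000, 10
        expected = 1.0 / math.sqrt(n)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            se = block_uncertainty(rng.standard_normal(n), blocks)
            assert expected / 3 < se < expected * 3
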