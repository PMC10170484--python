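"""Density profiles, 90–10% interfacial thickness and the ξ coefficient.

The thickness oracles are closed forms: a tanh interface of width w has its
90% and 10% crossings at tanh(u) = ∓0.8, i.e. 2·atanh(0.8)·w apart; a
linear ramp of length L spans 0.8·L between the same fractions.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopress import profiles
from isopress.profiles import (
    DegenerateProfileError,
    DensityProfile,
    density_profile,
    interfacial_thickness,
    reference_thickness,
    xi_coefficient,
)
from isopress.trajio import Frame, Trajectory

TANH_THICKNESS = 2.0 * math.atanh(0.8)  # ≈ 2.1972, per unit width


def tanh_profile(w=1.0, rho0=0.8, z0=6.0, bin_width=0.05, z_max=20.0):
    z = np.arange(-z_max, z_max, bin_width) + bin_width / 2
    rho = rho0 / 2 * (1 - np.tanh((z - z0) / w))
    return DensityProfile(z, {"W": rho}, bin_width)


class TestInterfacialThickness:
    @pytest.mark.parametrize("w", [0.5, 1.0, 2.0])
    def test_tanh_closed_form(self, w):
        thick = interfacial_thickness(tanh_profile(w=w), "W")
        assert thick.lz_int == pytest.approx(TANH_THICKNESS * w, rel=0.01)

    def test_linear_ramp(self):
        bw = 0.02
        L = 4.0
        z = np.arange(-10, 10, bw) + bw / 2
        rho = np.clip(1.0 - z / L, 0.0, 1.0)
        rho[z < 0] = 1.0
        prof = DensityProfile(z, {"W": rho}, bw)
        thick = interfacial_thickness(prof, "W")
        assert abs(thick.lz_int - 0.8 * L) <= bw

    def test_step_profile_within_one_bin(self):
        bw = 0.1
        z = np.arange(-5, 5, bw) + bw / 2
        rho = np.where(z < 0, 1.0, 0.0)
        prof = DensityProfile(z, {"W": rho}, bw)
        thick = interfacial_thickness(prof, "W")
        assert thick.lz_int <= bw

    def test_two_sided_slab_reports_both_interfaces(self):
        bw = 0.05
        z = np.arange(-15, 15, bw) + bw / 2
        rho = 0.4 * (np.tanh((z + 6) / 1.0) - np.tanh((z - 6) / 1.0))
        prof = DensityProfile(z, {"W": rho}, bw)
        thick = interfacial_thickness(prof, "W")
        assert len(thick.per_interface) == 2
        assert thick.lz_int == pytest.approx(TANH_THICKNESS, rel=0.02)

    def test_density_rescaling_invariance(self):
        a = interfacial_thickness(tanh_profile(rho0=0.8), "W").lz_int
        b = interfacial_thickness(tanh_profile(rho0=123.0), "W").lz_int
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("c", [2.0, 3.5])
    def test_spatial_stretch_scales_thickness(self, c):
        base = tanh_profile(w=1.0)
        stretched = DensityProfile(
            base.bin_centers * c,
            {"W": base.density_per_species["W"].copy()},
            base.bin_width * c,
        )
        a = interfacial_thickness(base, "W").lz_int
        b = interfacial_thickness(stretched, "W").lz_int
        assert b == pytest.approx(c * a, rel=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(
        scale=st.floats(1e-6, 1e6),
        w=st.floats(0.5, 3.0),
    )
    def test_density_units_cancel(self, scale, w):
        """The 90–10 criterion is a ratio: rescaling ρ leaves L_z;int."""
        a = interfacial_thickness(tanh_profile(w=w), "W").lz_int
        b = interfacial_thickness(tanh_profile(w=w, rho0=0.8 * scale), "W").lz_int
        assert b == pytest.approx(a, rel=1e-9)

    def test_halving_bin_width_is_consistent(self):
        coarse = tanh_profile(bin_width=0.2)
        fine = tanh_profile(bin_width=0.1)
        a = interfacial_thickness(coarse, "W").lz_int
        b = interfacial_thickness(fine, "W").lz_int
        assert abs(a - b) < 0.2

    def test_flat_profile_is_degenerate(self):
        z = np.arange(-5, 5, 0.1) + 0.05
        prof = DensityProfile(z, {"W": np.full_like(z, 0.7)}, 0.1)
        with pytest.raises(DegenerateProfileError):
            interfacial_thickness(prof, "W")

    def test_multiple_crossings_use_outermost_with_warning(self):
        bw = 0.05
        z = np.arange(0, 20, bw) + bw / 2
        rho = 0.5 * (1 - np.tanh((z - 8) / 0.5))
        bump = 0.12 * np.exp(-((z - 11.0) ** 2) / 0.1)  # vapor-side droplet
        prof = DensityProfile(z, {"W": rho + bump}, bw)
        plain = interfacial_thickness(
            DensityProfile(z, {"W": rho}, bw), "W"
        ).lz_int
        with pytest.warns(UserWarning, match="outermost"):
            thick = interfacial_thickness(prof, "W")
        assert thick.lz_int > plain

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            interfacial_thickness(tanh_profile(), "W", lo_frac=0.9, hi_frac=0.1)


class TestDensityProfile:
    def test_uniform_lattice_is_flat(self):
        # 10 particles in each of 20 z-slabs -> exactly n/V in every bin
        box = (10.0, 10.0, 20.0)
        bw = 1.0
        coords = []
        for k in range(20):
            zc = -10 + (k + 0.5) * bw
            for j in range(10):
                coords.append([-4.5 + j, 0.0, zc])
        fr = Frame(np.array(coords), ["W"] * 200, box)
        prof = density_profile(Trajectory([fr]), ["W"], bin_width=bw)
        np.testing.assert_allclose(
            prof.density_per_species["W"], 200 / (10 * 10 * 20.0)
        )

    def test_single_plane_occupies_one_bin(self):
        box = (5.0, 5.0, 10.0)
        coords = np.column_stack(
            [np.linspace(-2, 2, 30), np.zeros(30), np.full(30, 3.14)]
        )
        prof = density_profile(
            Trajectory([Frame(coords, ["W"] * 30, box)]), ["W"], bin_width=0.5
        )
        assert np.count_nonzero(prof.density_per_species["W"]) == 1

    def test_multi_frame_average_matches_per_frame_oracle(self):
        rng = np.random.default_rng(7)
        box = (6.0, 6.0, 12.0)
        frames = [
            Frame(
                np.column_stack(
                    [
                        rng.uniform(-3, 3, 50),
                        rng.uniform(-3, 3, 50),
                        rng.uniform(-6, 6, 50),
                    ]
                ),
                ["W"] * 50,
                box,
                time=float(t),
            )
            for t in range(4)
        ]
        prof = density_profile(Trajectory(frames), ["W"], bin_width=0.5)
        # brute-force reference: average of single-frame histograms
        singles = [
            density_profile(Trajectory([f]), ["W"], bin_width=0.5).density_per_species[
                "W"
            ]
            for f in frames
        ]
        np.testing.assert_allclose(
            prof.density_per_species["W"], np.mean(singles, axis=0)
        )

    def test_region_restriction_excludes_margin(self):
        box = (10.0, 5.0, 10.0)
        coords = np.array([[0.0, 0.0, 1.0], [4.0, 0.0, 1.0]])  # one in margin
        fr = Frame(coords, ["W", "W"], box)
        full = density_profile(Trajectory([fr]), ["W"], bin_width=1.0)
        strip = density_profile(
            Trajectory([fr]), ["W"], bin_width=1.0, region=(-2.0, 2.0)
        )
        assert full.density_per_species["W"].sum() > 0
        # strip density counts only the inside particle over the strip volume
        assert strip.density_per_species["W"].sum() == pytest.approx(
            1.0 / (4.0 * 5.0 * 1.0)
        )

    def test_empty_selection_rejected(self, ):
        fr = Frame(np.zeros((1, 3)), ["W"], (5.0, 5.0, 5.0))
        with pytest.raises(ValueError):
            density_profile(Trajectory([fr]), [])

    def test_oversized_bin_rejected(self):
        fr = Frame(np.zeros((1, 3)), ["W"], (5.0, 5.0, 5.0))
        with pytest.raises(ValueError):
            density_profile(Trajectory([fr]), ["W"], bin_width=50.0)


class TestXi:
    def test_identity_at_reference(self):
        assert xi_coefficient(2.0, 2.0).xi == 1.0

    def test_half_for_doubled_thickness(self):
        assert xi_coefficient(4.0, 2.0).xi == 0.5

    def test_thinner_than_reference_warns(self):
        with pytest.warns(UserWarning):
            xi = xi_coefficient(1.0, 2.0)
        assert xi.xi == 2.0

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            xi_coefficient(*bad)


class TestReferenceThickness:
    @staticmethod
    def _slab_traj(rng, n=60000, w=1.0, half=5.0, species="W"):
        """Sample particles from a two-sided tanh slab density."""
        z = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.uniform(-12, 12, size=2 * n)
            acc = 0.5 * (np.tanh((cand + half) / w) - np.tanh((cand - half) / w))
            keep = cand[rng.uniform(0, 1, size=cand.size) < acc / acc.max()]
            take = min(n - filled, keep.size)
            z[filled : filled + take] = keep[:take]
            filled += take
        coords = np.column_stack(
            [rng.uniform(-5, 5, n), rng.uniform(-5, 5, n), z]
        )
        return Trajectory([Frame(coords, [species] * n, (10.0, 10.0, 24.0))])

    def test_matches_tanh_closed_form(self):
        traj = self._slab_traj(np.random.default_rng(3))
        lz = reference_thickness(traj, "W", bin_width=0.1)
        assert lz == pytest.approx(TANH_THICKNESS, rel=0.05)

    def test_monolayer_trajectory_rejected(self):
        rng = np.random.default_rng(4)
        traj = self._slab_traj(rng, n=1000)
        coords = np.vstack([traj[0].coords, rng.uniform(-2, 2, size=(200, 3))])
        species = np.array(["W"] * 1000 + ["H"] * 200)
        bad = Trajectory([Frame(coords, species, traj.box)])
        with pytest.raises(ValueError, match="clean"):
            reference_thickness(bad, "W")

    def test_deterministic(self):
        a = reference_thickness(self._slab_traj(np.random.default_rng(5)), "W")
        b = reference_thickness(self._slab_traj(np.random.default_rng(5)), "W")
        assert a == b
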