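"""Density profiles along the interface normal and the ξ correction.

The osmotic-route correction rests on the interfacial thickness L_z;int:
the depth over which the solvent density falls from 90% to 10% of its bulk
value along z.  The bulk reference is the mean solvent density over the
central 50% of the slab (a plateau average, not the noisy maximum bin).
The correction coefficient is ξ = L_z;int(dilute reference) / L_z;int(A):
close to 1 for a widely spread film and below 1 as packing thickens the
inhomogeneous surface zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .trajio import Trajectory

__all__ = [
    "DensityProfile",
    "InterfacialThickness",
    "XiCoefficient",
    "density_profile",
    "interfacial_thickness",
    "xi_coefficient",
    "reference_thickness",
    "strip_averaged_reference",
    "tiled_thickness",
    "DegenerateProfileError",
]


class DegenerateProfileError(ValueError):
    """Profile has no resolvable 90–10% interfacial zone."""


@dataclass
class DensityProfile:
    """Time-averaged per-species number density vs z."""

    bin_centers: np.ndarray
    density_per_species: dict[str, np.ndarray]
    bin_width: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        for sp, rho in self.density_per_species.items():
            rho = np.asarray(rho, dtype=np.float64)
            if rho.shape != self.bin_centers.shape:
                raise ValueError(f"density for {sp!r} does not match bin count")
            if np.any(rho < 0):
                raise ValueError("densities must be non-negative")
            self.density_per_species[sp] = rho

    def total(self) -> np.ndarray:
        return np.sum(list(self.density_per_species.values()), axis=0)


@dataclass
class InterfacialThickness:
    """90–10% interfacial depth, per interface and combined."""

    lz_int: float  # mean over resolved interfaces; used downstream
    per_interface: tuple[float, ...]
    lo_frac: float = 0.10
    hi_frac: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 < self.lo_frac < self.hi_frac < 1.0):
            raise ValueError("need 0 < lo_frac < hi_frac < 1")
        if self.lz_int <= 0:
            raise ValueError("interfacial thickness must be positive")


@dataclass
class XiCoefficient:
    """Semi-empirical correction ξ = L_z;int(reference) / L_z;int(area)."""

    xi: float
    lz_ref: float
    lz_at_area: float


def density_profile(
    traj: Trajectory,
    species_selection: Iterable[str],
    axis: str = "z",
    bin_width: float = 0.1,
    region: tuple[float, float] | None = None,
    center_on: str | None = None,
) -> DensityProfile:
    """Time-averaged number-density histogram along ``axis`` (z only).

    Parameters
    ----------
    traj
        Trajectory with a constant box.
    species_selection
        Species tags to histogram (one profile per tag).
    bin_width
        Nominal bin width; actual width divides the box length exactly.
    region
        Optional ``(x_lo, x_hi)`` restriction, e.g. the between-the-walls
        region, excluding the clean-interface margin.
    center_on
        Optional species whose per-frame mean z is subtracted before
        histogramming.  A Langevin-thermostatted slab performs a slow
        random walk along z; recentring on the solvent removes that drift
        from the time-averaged profile, which would otherwise smear the
        interfaces.  Requires a slab that does not wrap the z boundary.
    """
    if axis != "z":
        raise ValueError("only the z axis (interface normal) is supported")
    species = [str(s) for s in species_selection]
    if not species:
        raise ValueError("species selection is empty")
    lx, ly, lz = traj.box
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if bin_width > lz:
        raise ValueError("bin width exceeds the box length along z")
    if region is not None:
        x_lo, x_hi = region
        if not (-lx / 2 <= x_lo < x_hi <= lx / 2):
            raise ValueError("region must lie inside the box along x")
        width_x = x_hi - x_lo
    else:
        width_x = lx

    n_bins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(-lz / 2, lz / 2, n_bins + 1)
    actual_width = edges[1] - edges[0]
    bin_volume = width_x * ly * actual_width

    counts = {sp: np.zeros(n_bins) for sp in species}
    for fr in traj:
        z_shift = 0.0
        if center_on is not None:
            ref_mask = fr.species == center_on
            if region is not None:
                # restrict the centring reference to the same strip: this
                # also cancels the vertical wander of capillary modes longer
                # than the strip, not just whole-slab drift
                ref_mask &= (fr.coords[:, 0] >= x_lo) & (fr.coords[:, 0] < x_hi)
            ref_z = fr.coords[ref_mask, 2]
            if len(ref_z) == 0:
                raise ValueError(f"no particles of species {center_on!r} to center on")
            z_shift = float(np.mean(ref_z))
        for sp in species:
            mask = fr.species == sp
            if region is not None:
                mask &= (fr.coords[:, 0] >= x_lo) & (fr.coords[:, 0] < x_hi)
            z = fr.coords[mask, 2] - z_shift
            counts[sp] += np.histogram(z, bins=edges)[0]

    n_frames = len(traj)
    density = {sp: c / (n_frames * bin_volume) for sp, c in counts.items()}
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, density, actual_width)


def _bulk_reference(z: np.ndarray, rho: np.ndarray) -> float:
    """Mean density over the central 50% (by index) of the slab region.

    The slab region is the contiguous run of bins around the densest bin
    where the density stays above half its maximum.
    """
    imax = int(np.argmax(rho))
    if rho[imax] <= 0:
        raise DegenerateProfileError("profile is identically zero")
    half = 0.5 * rho[imax]
    lo = imax
    while lo > 0 and rho[lo - 1] >= half:
        lo -= 1
    hi = imax
    while hi < len(rho) - 1 and rho[hi + 1] >= half:
        hi += 1
    span = hi - lo + 1
    trim = span // 4
    return float(np.mean(rho[lo + trim : hi + 1 - trim])) if span > 2 else float(
        np.mean(rho[lo : hi + 1])
    )


def _outermost_crossing(
    z: np.ndarray, rho: np.ndarray, level: float, side: str
) -> float | None:
    """Outermost z where ``rho`` crosses ``level``, by linear interpolation.

    ``z``/``rho`` cover one half of the profile (slab centre at one end).
    ``side="left"`` scans from the low-z end inward; ``side="right"`` from
    the high-z end inward.  Returns None when the edge bin already sits at
    or above ``level`` (no decay on that side) or no crossing exists.
    """
    edge = rho[0] if side == "left" else rho[-1]
    if edge >= level:
        return None
    above = rho >= level
    idx = range(len(rho) - 1) if side == "left" else range(len(rho) - 2, -1, -1)
    crossings = []
    for i in idx:
        if above[i] != above[i + 1]:
            z0, z1 = z[i], z[i + 1]
            r0, r1 = rho[i], rho[i + 1]
            crossings.append(z0 + (level - r0) * (z1 - z0) / (r1 - r0))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(
            "multiple density crossings found; using the outermost",
            stacklevel=3,
        )
    return crossings[0]


def interfacial_thickness(
    profile: DensityProfile,
    solvent_species: str,
    lo_frac: float = 0.10,
    hi_frac: float = 0.90,
) -> InterfacialThickness:
    """90–10% interfacial depth of the solvent density profile.

    For each z side of the slab the distance between the ``hi_frac`` and
    ``lo_frac`` crossings (relative to the bulk plateau density) is measured,
    crossings located by linear interpolation between adjacent bins.  Sides
    where the density never decays (e.g. a half-infinite plateau fixture)
    are skipped; at least one side must resolve.
    """
    if not (0.0 < lo_frac < hi_frac < 1.0):
        raise ValueError("need 0 < lo_frac < hi_frac < 1")
    if solvent_species not in profile.density_per_species:
        raise ValueError(f"no profile for species {solvent_species!r}")
    rho = profile.density_per_species[solvent_species]
    z = profile.bin_centers
    rho_ref = _bulk_reference(z, rho)
    hi_level = hi_frac * rho_ref
    lo_level = lo_frac * rho_ref
    if np.max(rho) < hi_level:
        raise DegenerateProfileError(
            f"profile never reaches {hi_frac:.0%} of the bulk reference density"
        )
    centre = int(np.argmax(rho))
    halves = {
        "left": (z[: centre + 1], rho[: centre + 1]),
        "right": (z[centre:], rho[centre:]),
    }
    per_interface = []
    for side, (z_half, rho_half) in halves.items():
        if len(z_half) < 2:
            continue
        z_hi = _outermost_crossing(z_half, rho_half, hi_level, side)
        z_lo = _outermost_crossing(z_half, rho_half, lo_level, side)
        if z_hi is None or z_lo is None:
            continue
        thickness = abs(z_hi - z_lo)
        if thickness > 0:
            per_interface.append(thickness)
    if not per_interface:
        raise DegenerateProfileError(
            "no interface with a resolvable 90-10% decay found"
        )
    return InterfacialThickness(
        lz_int=float(np.mean(per_interface)),
        per_interface=tuple(per_interface),
        lo_frac=lo_frac,
        hi_frac=hi_frac,
    )


def tiled_thickness(
    traj: Trajectory,
    region: tuple[float, float],
    strip_width: float,
    solvent_species: str = "W",
    bin_width: float = 0.1,
    lo_frac: float = 0.10,
    hi_frac: float = 0.90,
) -> float:
    """Mean L_z;int over fixed-width sub-strips tiling an x-region.

    The apparent interfacial thickness contains a capillary-wave term that
    grows with the lateral width of the averaging window.  Measuring every
    state of an area sweep over sub-strips of one fixed width — the film
    region of the narrowest state — makes that term constant across the
    sweep, so differences in the tiled thickness reflect the film's own
    perturbation of the interface.  The region is tiled with
    ``floor(width/strip_width)`` centred sub-strips (at least one).
    """
    x_lo, x_hi = region
    if strip_width <= 0:
        raise ValueError("strip_width must be positive")
    width = x_hi - x_lo
    n_sub = max(1, int(width / strip_width))
    span = n_sub * strip_width
    start = (x_lo + x_hi) / 2 - span / 2
    values = []
    for k in range(n_sub):
        sub = (start + k * strip_width, start + (k + 1) * strip_width)
        profile = density_profile(
            traj,
            [solvent_species],
            bin_width=bin_width,
            region=sub,
            center_on=solvent_species,
        )
        thick = interfacial_thickness(
            profile, solvent_species, lo_frac=lo_frac, hi_frac=hi_frac
        )
        values.append(thick.lz_int)
    return float(np.mean(values))


def xi_coefficient(lz_at_area: float, lz_ref: float) -> XiCoefficient:
    """ξ = L_z;int(infinite-dilution reference) / L_z;int(current area)."""
    if lz_at_area <= 0 or lz_ref <= 0:
        raise ValueError("interfacial thicknesses must be positive")
    if lz_at_area < lz_ref:
        warnings.warn(
            "interface thinner than the dilute reference (xi > 1); "
            "physically unexpected for a compressed monolayer",
            stacklevel=2,
        )
    return XiCoefficient(xi=lz_ref / lz_at_area, lz_ref=lz_ref, lz_at_area=lz_at_area)


def reference_thickness(
    clean_slab_traj: Trajectory,
    solvent_species: str = "W",
    bin_width: float = 0.1,
    surfactant_species: Iterable[str] = ("H", "T"),
    negligible_fraction: float = 0.01,
    lo_frac: float = 0.10,
    hi_frac: float = 0.90,
    region: tuple[float, float] | None = None,
) -> float:
    """Infinite-dilution L_z;int from a surfactant-free solvent slab.

    Raises ValueError if the trajectory contains a non-negligible surfactant
    population (more than ``negligible_fraction`` of the solvent count):
    the reference must come from a clean slab simulated under the same
    conditions and analysed with identical bins and thresholds.

    ``region`` restricts the lateral x-range.  Because the apparent
    time-averaged interface width includes a capillary-wave contribution
    that grows with the sampled lateral area, the reference should be
    measured over the same x-strip width as the monolayer profile it will
    be compared with.
    """
    present = clean_slab_traj.species_set()
    surf = [s for s in surfactant_species if s in present]
    if surf:
        n_surf = sum(
            int(np.sum(clean_slab_traj[0].species == s)) for s in surf
        )
        n_solv = int(np.sum(clean_slab_traj[0].species == solvent_species))
        if n_solv == 0 or n_surf > negligible_fraction * n_solv:
            raise ValueError(
                f"trajectory contains {n_surf} surfactant beads; the dilute "
                "reference requires a clean solvent slab"
            )
    profile = density_profile(
        clean_slab_traj,
        [solvent_species],
        bin_width=bin_width,
        region=region,
        center_on=solvent_species,
    )
    thick = interfacial_thickness(
        profile, solvent_species, lo_frac=lo_frac, hi_frac=hi_frac
    )
    return thick.lz_int


def strip_averaged_reference(
    clean_slab_traj: Trajectory,
    strip_width: float,
    solvent_species: str = "W",
    bin_width: float = 0.1,
    lo_frac: float = 0.10,
    hi_frac: float = 0.90,
) -> float:
    """Dilute-reference L_z;int averaged over disjoint x-strips.

    The clean slab is statistically homogeneous along x, so every strip of
    the given width is an equivalent realization of the strip-restricted
    interface; averaging their thicknesses reduces the reference variance
    without changing its expectation.  The box is tiled with
    ``floor(L_x / strip_width)`` centred strips (at least one).
    """
    lx = clean_slab_traj.box[0]
    if strip_width <= 0:
        raise ValueError("strip_width must be positive")
    n_strips = max(1, int(lx / strip_width))
    span = n_strips * strip_width
    values = []
    for k in range(n_strips):
        x0 = -span / 2 + k * strip_width
        region = (x0, min(x0 + strip_width, lx / 2))
        profile = density_profile(
            clean_slab_traj,
            [solvent_species],
            bin_width=bin_width,
            region=region,
            center_on=solvent_species,
        )
        thick = interfacial_thickness(
            profile, solvent_species, lo_frac=lo_frac, hi_frac=hi_frac
        )
        values.append(thick.lz_int)
    return float(np.mean(values))
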