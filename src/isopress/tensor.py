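"""Kirkwood–Irving surface tension and the classical surface pressure route.

For a slab with two interfaces normal to z, the surface tension follows
from the time-averaged anisotropy of the diagonal pressure tensor:

    γ = (L_z / 2) · ⟨P_zz − (P_xx + P_yy)/2⟩

(the 1/2 shares the integrated anisotropy between the two interfaces).
The monolayer surface pressure is the tension deficit relative to the bare
solvent interface, Π = γ_w − γ_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajio import PressureTensorSeries
from .units import bar_length_to_output, surface_pressure_label
from .osmotic import block_uncertainty

__all__ = ["SurfaceTension", "SurfacePressure", "kirkwood_irving", "surface_pressure"]


@dataclass
class SurfaceTension:
    """Surface tension with block-average uncertainty."""

    gamma: float
    uncertainty: float
    units: str
    kind: str = "air-monolayer-water"  # or "air-water"

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


@dataclass
class SurfacePressure:
    """Surface pressure Π = γ_w − γ_m with combined uncertainty."""

    value: float
    uncertainty: float
    units: str
    metastable: bool = False  # negative Π: metastable bare-interface regime


def kirkwood_irving(
    series: PressureTensorSeries,
    n_blocks: int = 5,
    kind: str = "air-monolayer-water",
) -> SurfaceTension:
    """Surface tension of a two-interface slab from the pressure tensor.

    Output units: mN/m when the series is in real units (bar, Å), reduced
    ε/σ² otherwise.  Uncertainty by block averaging over ``n_blocks``
    contiguous blocks of the instantaneous tension estimator.
    """
    if len(series) == 0:
        raise ValueError("pressure series is empty")
    anisotropy = series.pzz - 0.5 * (series.pxx + series.pyy)
    inst_gamma = 0.5 * series.box_lz * anisotropy
    gamma = float(np.mean(inst_gamma))
    unc = block_uncertainty(inst_gamma, n_blocks) if len(series) >= n_blocks else 0.0
    return SurfaceTension(
        gamma=bar_length_to_output(gamma, series.units),
        uncertainty=bar_length_to_output(unc, series.units),
        units=surface_pressure_label(series.units),
        kind=kind,
    )


def surface_pressure(
    gamma_w: SurfaceTension, gamma_m: SurfaceTension
) -> SurfacePressure:
    """Π = γ_w − γ_m; uncertainties combined in quadrature.

    Slightly negative values are permitted and flagged: they indicate a
    metastable interface rather than an analysis failure.
    """
    if gamma_w.units != gamma_m.units:
        raise ValueError(
            f"unit mismatch: {gamma_w.units!r} vs {gamma_m.units!r}"
        )
    value = gamma_w.gamma - gamma_m.gamma
    unc = math.hypot(gamma_w.uncertainty, gamma_m.uncertainty)
    return SurfacePressure(
        value=value,
        uncertainty=unc,
        units=gamma_w.units,
        metastable=value < 0,
    )
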