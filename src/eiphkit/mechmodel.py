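"""Biophysical model of pulmonary capillary stress failure.

Exercise-induced pulmonary haemorrhage (EIPH) is modelled as a fracture
problem in the capillary wall: a pre-existing flaw in the endothelial
cell layer propagates, and bleeding is sustained once the fracture
exceeds a critical length.  Dimensional analysis of an adhesion energy
per unit area (gamma, J/m^2) against an elastic modulus (E, Pa) yields
the elasto-capillary length

    l_c = alpha * gamma / E

so that weaker cell-cell adhesion (smaller gamma) or stiffer cells
(larger E) shorten the critical length and make sustained bleeding more
likely.  Two haemodynamic modulators complete the picture: the
transmural pressure across the capillary wall (intraluminal minus
alveolar), and the rise in upstream pressure drop when venous
remodelling narrows the lumen (Poiseuille, radius^-4).

All pressures are in Pa internally; :func:`mmhg_to_pa` /
:func:`pa_to_mmhg` are the only unit boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Conversion factor, Pa per mmHg.
PA_PER_MMHG = 133.322


def mmhg_to_pa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    """Convert a pressure from Pa to mmHg."""
    return p_pa / PA_PER_MMHG


@dataclass(frozen=True)
class CapillaryParams:
    """Mechanical parameters of the capillary wall cell layer.

    Parameters
    ----------
    gamma : float
        Cell-cell adhesion energy per unit area, J/m^2. Must be > 0.
    stiffness_E : float
        Effective elastic modulus of the cell layer, Pa. Must be > 0.
    alpha : float
        Dimensionless prefactor of the fracture-length law (default 1).
    defect_length : float
        Pre-existing flaw length, m (default 0).
    """

    gamma: float
    stiffness_E: float
    alpha: float = 1.0
    defect_length: float = 0.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.stiffness_E > 0:
            raise ValueError(f"stiffness_E must be > 0, got {self.stiffness_E}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.defect_length < 0:
            raise ValueError(f"defect_length must be >= 0, got {self.defect_length}")


@dataclass(frozen=True)
class VesselParams:
    """Geometry and flow state of a small vessel segment (SI units)."""

    radius: float
    length: float
    viscosity: float
    flow: float
    lumen_reduction: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")
        if self.flow < 0:
            raise ValueError(f"flow must be >= 0, got {self.flow}")
        if not 0.0 <= self.lumen_reduction < 1.0:
            raise ValueError(
                f"lumen_reduction must be in [0, 1), got {self.lumen_reduction}"
            )


@dataclass(frozen=True)
class PressureState:
    """Intraluminal and alveolar pressures, Pa (alveolar may be negative)."""

    intraluminal: float
    alveolar: float


def critical_fracture_length(params: CapillaryParams) -> float:
    """Critical fracture length l_c = alpha * gamma / E, in metres.

    Strictly increasing in the adhesion energy gamma and strictly
    decreasing in the stiffness E: sustained bleeding needs a shorter
    crack when adhesion is weak or cells are stiff.
    """
    return params.alpha * params.gamma / params.stiffness_E


def rupture_indicator(params: CapillaryParams) -> float:
    """Ratio of the pre-existing defect length to the critical length.

    Values >= 1 flag predicted sustained bleeding.  The ratio is
    scale-free: multiplying gamma and E by the same constant leaves it
    unchanged.
    """
    return params.defect_length / critical_fracture_length(params)


def transmural_pressure(state: PressureState) -> float:
    """Transmural pressure = intraluminal - alveolar, Pa."""
    return state.intraluminal - state.alveolar


def poiseuille_pressure_drop(vessel: VesselParams) -> float:
    """Laminar pressure drop 8*mu*L*Q / (pi*r^4) over the segment, Pa.

    The reduced radius (1 - lumen_reduction) * radius is NOT applied
    here; compose with :func:`pressure_amplification` or build a
    ``VesselParams`` at the reduced radius.
    """
    return (
        8.0 * vessel.viscosity * vessel.length * vessel.flow
        / (math.pi * vessel.radius ** 4)
    )


def pressure_amplification(lumen_reduction: float) -> float:
    """Factor by which the segment pressure drop rises at fixed flow.

    A fractional radius reduction f in [0, 1) scales the Poiseuille drop
    by (1 - f)^-4.
    """
    if not 0.0 <= lumen_reduction < 1.0:
        raise ValueError(f"lumen_reduction must be in [0, 1), got {lumen_reduction}")
    return (1.0 - lumen_reduction) ** -4


def parameter_sweep(
    gammas,
    stiffnesses,
    lumen_reductions,
    alpha: float = 1.0,
    defect_length: float = 0.0,
) -> pd.DataFrame:
    """Grid sweep over (gamma, E, lumen_reduction).

    Returns a tidy frame with columns gamma, stiffness_E,
    lumen_reduction, critical_length, rupture_indicator, amplification —
    the table behind risk-surface plots.
    """
    rows = []
    for g in np.atleast_1d(gammas):
        for e in np.atleast_1d(stiffnesses):
            p = CapillaryParams(gamma=float(g), stiffness_E=float(e),
                                alpha=alpha, defect_length=defect_length)
            lc = critical_fracture_length(p)
            ri = rupture_indicator(p)
            for f in np.atleast_1d(lumen_reductions):
                rows.append({
                    "gamma": float(g),
                    "stiffness_E": float(e),
                    "lumen_reduction": float(f),
                    "critical_length": lc,
                    "rupture_indicator": ri,
                    "amplification": pressure_amplification(float(f)),
                })
    return pd.DataFrame(rows)
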