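"""Cubic-particle model of the aragonite seed and its epitaxial growth.

The seed powder is idealised as N identical cubes.  For a cube of edge a
and density ρ the specific surface area is  SSA = 6a²/(ρa³) = 6/(ρa),
so a BET surface area fixes the starting edge length.  Epitaxial growth
deposits the precipitated CaCO3 as a conformal layer, distributed equally
over the cubes, which therefore stay cubic while edge, area and mass grow
self-similarly; particle count is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ARAGONITE_DENSITY",
    "CACO3_MOLAR_MASS",
    "SeedPopulation",
    "ApparatusGeometry",
    "edge_from_ssa",
    "ssa_from_edge",
    "surface_area",
    "grow_epitaxial",
    "apparatus_wetted_area",
]

#: Aragonite density, g cm⁻³.
ARAGONITE_DENSITY = 2.94
#: Molar mass of CaCO3, g mol⁻¹.
CACO3_MOLAR_MASS = 100.09


def edge_from_ssa(ssa: float, density: float = ARAGONITE_DENSITY) -> float:
    """Cube edge (μm) with specific surface area ``ssa`` (m² g⁻¹) at ``density`` (g cm⁻³).

    With these units the relation reduces to  a[μm] = 6/(ρ·SSA).
    """
    if ssa <= 0.0 or density <= 0.0:
        raise ValueError("ssa and density must be positive")
    return 6.0 / (density * ssa)


def ssa_from_edge(edge: float, density: float = ARAGONITE_DENSITY) -> float:
    """Specific surface area (m² g⁻¹) of cubes with edge ``edge`` (μm)."""
    if edge <= 0.0 or density <= 0.0:
        raise ValueError("edge and density must be positive")
    return 6.0 / (density * edge)


def surface_area(mass: float, ssa: float) -> float:
    """Total surface area (m²) of ``mass`` grams of powder at ``ssa`` m² g⁻¹."""
    if mass < 0.0:
        raise ValueError("mass must be non-negative")
    return mass * ssa


@dataclass(frozen=True)
class SeedPopulation:
    """Monodisperse cubic seed population.

    Attributes
    ----------
    mass : float
        g.
    density : float
        g cm⁻³.
    edge : float
        Cube edge, μm.
    n_particles : float
        Particle count (a large real number; not rounded).
    """

    mass: float
    density: float
    edge: float
    n_particles: float

    def __post_init__(self) -> None:
        if min(self.mass, self.density, self.edge, self.n_particles) <= 0.0:
            raise ValueError("all SeedPopulation fields must be positive")

    @classmethod
    def from_mass_ssa(
        cls, mass: float, ssa: float = 4.2, density: float = ARAGONITE_DENSITY
    ) -> "SeedPopulation":
        """Build a population from mass (g) and BET surface area (m² g⁻¹)."""
        edge = edge_from_ssa(ssa, density)
        v_particle_cm3 = (edge * 1e-4) ** 3
        n = mass / (density * v_particle_cm3)
        return cls(mass=mass, density=density, edge=edge, n_particles=n)

    @property
    def ssa(self) -> float:
        """Specific surface area, m² g⁻¹ (= 6/(ρ·a) for cubes)."""
        return ssa_from_edge(self.edge, self.density)

    @property
    def total_area(self) -> float:
        """Total surface area, m² (6a²N)."""
        return 6.0 * (self.edge * 1e-6) ** 2 * self.n_particles

    @property
    def particle_volume(self) -> float:
        """Single-particle volume, cm³."""
        return (self.edge * 1e-4) ** 3

    @property
    def moles(self) -> float:
        """CaCO3 content, μmol."""
        return self.mass / CACO3_MOLAR_MASS * 1e6


def grow_epitaxial(pop: SeedPopulation, added_moles: float) -> SeedPopulation:
    """Grow the population by ``added_moles`` (μmol CaCO3) of epitaxial deposit.

    The added volume is distributed equally over the N cubes, which remain
    cubes:  a' = (a³ + ΔV/N)^(1/3).  Mass increases by the molar mass of
    CaCO3 per mole; particle count is unchanged.
    """
    if added_moles < 0.0:
        raise ValueError("added_moles must be non-negative")
    if added_moles == 0.0:
        return pop
    added_mass = added_moles * 1e-6 * CACO3_MOLAR_MASS           # g
    dv_particle_cm3 = added_mass / pop.density / pop.n_particles  # cm³
    edge_cm = pop.edge * 1e-4
    new_edge_cm = (edge_cm ** 3 + dv_particle_cm3) ** (1.0 / 3.0)
    return replace(pop, mass=pop.mass + added_mass, edge=new_edge_cm * 1e4)


@dataclass(frozen=True)
class ApparatusGeometry:
    """Immersed apparatus dimensions (diameters in mm, depths in cm).

    ``cylinders`` lists the immersed probes/tubes as
    (diameter_mm, depth_cm, count) — lateral areas only.  The beaker
    contributes its immersed wall plus the bottom disc; meniscus and lid
    ports are ignored.
    """

    beaker_diameter_mm: float = 73.0
    fill_depth_cm: float = 8.2
    cylinders: tuple[tuple[float, float, int], ...] = (
        (12.0, 6.0, 1),   # pH sensor
        (15.0, 7.5, 1),   # stirrer (widest point)
        (2.0, 7.5, 2),    # titrant dosing tubes
    )

    def __post_init__(self) -> None:
        if self.beaker_diameter_mm <= 0.0 or self.fill_depth_cm < 0.0:
            raise ValueError("beaker dimensions must be positive")
        for d, h, n in self.cylinders:
            if d <= 0.0 or h < 0.0 or n < 1:
                raise ValueError("cylinder dimensions must be positive")


def apparatus_wetted_area(geometry: ApparatusGeometry | None = None) -> float:
    """Seawater-wetted apparatus area (m²): beaker wall + bottom + immersed cylinders."""
    g = geometry if geometry is not None else ApparatusGeometry()
    r_beaker = g.beaker_diameter_mm * 1e-3 / 2.0
    area = 2.0 * math.pi * r_beaker * (g.fill_depth_cm * 1e-2)  # wall
    area += math.pi * r_beaker ** 2                              # bottom disc
    for d_mm, h_cm, n in g.cylinders:
        area += n * math.pi * (d_mm * 1e-3) * (h_cm * 1e-2)
    return area
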