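"""Equilibrium partitioning of PAHs between water, biota and DOC.

Dissolved-phase concentrations in a bottle incubation can drop without
any biodegradation simply because hydrophobic compounds sorb to growing
organic-matter pools.  This module closes a three-pool equilibrium mass
balance (dissolved water phase, microbial biota, dissolved organic
carbon) so that the repartitioning artifact can be bounded per compound.

The bioconcentration factor of a compound in microbial organic matter is
modelled as linear in its octanol-water partition constant,

    BCF = C_M / C_W = f_OM * Kow / delta,

with ``f_OM`` the organic-matter fraction of the biomass and ``delta``
the density of octanol (the organic phase Kow is referenced to).  The
DOC-water partition coefficient is taken as ``K_DOC = 0.1 * Kow``, a
standard rule of thumb for natural dissolved organic matter.

At equilibrium in a fixed volume with biota pool ``B`` (kg OM / L) and
DOC pool ``D`` (kg C / L), the mass fraction remaining dissolved is

    f_dissolved = 1 / (1 + BCF * B + K_DOC * D),

and the sorbed fractions follow by closure.  If the organic-matter pools
grow between two timepoints, at most ``1 - f_dissolved(t1)/f_dissolved(t0)``
of the dissolved-phase decrease can be explained by repartitioning; any
larger observed decrease requires an actual removal process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .compounds import PAHCompound
from .errors import InputError

__all__ = [
    "PartitionContext",
    "PartitionState",
    "bcf",
    "kdoc",
    "biomass_from_cells",
    "doc_mass_concentration",
    "equilibrium_fractions",
    "compound_fractions",
    "sorption_artifact_bound",
]

#: Molar mass of carbon, g/mol.
CARBON_MOLAR_MASS = 12.011

#: Density of octanol, kg/L (default organic-phase density for BCF).
OCTANOL_DENSITY = 0.82

#: Default per-cell carbon content for marine bacterioplankton, fg C.
DEFAULT_FG_C_PER_CELL = 20.0

#: Default organic matter : organic carbon mass ratio.
DEFAULT_OM_TO_OC = 2.0


def bcf(log_kow: float, f_om: float = 1.0, delta_octanol: float = OCTANOL_DENSITY) -> float:
    """Bioconcentration factor (L/kg organic matter): ``f_OM * 10**log_kow / delta``."""
    if delta_octanol <= 0:
        raise InputError(f"octanol density must be > 0, got {delta_octanol}")
    if not 0.0 <= f_om <= 1.0:
        raise InputError(f"f_om must be within [0, 1], got {f_om}")
    return f_om * 10.0**log_kow / delta_octanol


def kdoc(log_kow: float) -> float:
    """DOC-water partition coefficient (L/kg C): ``0.1 * 10**log_kow``."""
    return 0.1 * 10.0**log_kow


def biomass_from_cells(
    cells_per_L: float,
    fg_c_per_cell: float = DEFAULT_FG_C_PER_CELL,
    om_to_oc_ratio: float = DEFAULT_OM_TO_OC,
) -> float:
    """Microbial organic matter concentration (kg OM / L) from cell counts.

    ``cells_per_L * fg_c_per_cell`` femtograms of carbon per litre,
    converted to kg (1 fg = 1e-18 kg) and scaled by the OM:OC mass ratio.
    """
    if cells_per_L < 0 or fg_c_per_cell < 0 or om_to_oc_ratio < 0:
        raise InputError("cell count, carbon content and OM:OC ratio must be >= 0")
    return cells_per_L * fg_c_per_cell * 1e-18 * om_to_oc_ratio


def doc_mass_concentration(doc_molar_uM: float) -> float:
    """Convert a molar DOC level (micromol C / L) to kg C / L."""
    if doc_molar_uM < 0:
        raise InputError(f"DOC concentration must be >= 0, got {doc_molar_uM}")
    return doc_molar_uM * 1e-6 * CARBON_MOLAR_MASS * 1e-3


@dataclass(frozen=True)
class PartitionContext:
    """Organic-matter pools and constants entering the mass balance.

    Attributes
    ----------
    biomass_kg_om_per_L
        Microbial (bacteria + phytoplankton) organic matter, kg OM / L.
    doc_kg_per_L
        Dissolved organic carbon, kg C / L.
    f_om
        Organic-matter fraction applied to the biomass basis (0-1).
    delta_octanol
        Density of octanol, kg/L.
    om_to_oc_ratio
        Mass conversion organic matter : organic carbon (>= 1).
    """

    biomass_kg_om_per_L: float = 0.0
    doc_kg_per_L: float = 0.0
    f_om: float = 1.0
    delta_octanol: float = OCTANOL_DENSITY
    om_to_oc_ratio: float = DEFAULT_OM_TO_OC

    def __post_init__(self) -> None:
        if self.biomass_kg_om_per_L < 0 or self.doc_kg_per_L < 0:
            raise InputError("organic-matter pools must be >= 0")
        if not 0.0 <= self.f_om <= 1.0:
            raise InputError(f"f_om must be within [0, 1], got {self.f_om}")
        if self.delta_octanol <= 0:
            raise InputError("octanol density must be > 0")
        if self.om_to_oc_ratio < 1:
            raise InputError("OM:OC ratio must be >= 1")

    @classmethod
    def from_field(
        cls,
        cells_per_L: float,
        fg_c_per_cell: float = DEFAULT_FG_C_PER_CELL,
        doc_uM: float = 60.0,
        phyto_kg_om_per_L: float = 0.0,
        f_om: float = 1.0,
        delta_octanol: float = OCTANOL_DENSITY,
        om_to_oc_ratio: float = DEFAULT_OM_TO_OC,
    ) -> "PartitionContext":
        """Build a context from field observables.

        Bacterial biomass comes from flow-cytometry cell counts at the
        default 20 fg C per cell; phytoplankton biomass (e.g. from net
        tows) is added directly as kg OM / L; DOC defaults to 60 uM, the
        average for Antarctic surface seawater.
        """
        biomass = biomass_from_cells(cells_per_L, fg_c_per_cell, om_to_oc_ratio)
        return cls(
            biomass_kg_om_per_L=biomass + phyto_kg_om_per_L,
            doc_kg_per_L=doc_mass_concentration(doc_uM),
            f_om=f_om,
            delta_octanol=delta_octanol,
            om_to_oc_ratio=om_to_oc_ratio,
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PartitionContext":
        """Build from a YAML/JSON mapping of field observables.

        Recognized keys: ``cells_per_L, fg_c_per_cell, doc_uM,
        phyto_kgOM_per_L, f_om, delta_octanol, om_to_oc_ratio``.
        """
        known = {
            "cells_per_L", "fg_c_per_cell", "doc_uM", "phyto_kgOM_per_L",
            "f_om", "delta_octanol", "om_to_oc_ratio",
        }
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown partition context key(s): {sorted(unknown)}")
        return cls.from_field(
            cells_per_L=float(d.get("cells_per_L", 0.0)),
            fg_c_per_cell=float(d.get("fg_c_per_cell", DEFAULT_FG_C_PER_CELL)),
            doc_uM=float(d.get("doc_uM", 60.0)),
            phyto_kg_om_per_L=float(d.get("phyto_kgOM_per_L", 0.0)),
            f_om=float(d.get("f_om", 1.0)),
            delta_octanol=float(d.get("delta_octanol", OCTANOL_DENSITY)),
            om_to_oc_ratio=float(d.get("om_to_oc_ratio", DEFAULT_OM_TO_OC)),
        )

    def scale_biomass(self, factor: float) -> "PartitionContext":
        """A copy with the biota pool multiplied by ``factor`` (e.g. growth)."""
        return replace(self, biomass_kg_om_per_L=self.biomass_kg_om_per_L * factor)


@dataclass(frozen=True)
class PartitionState:
    """Equilibrium mass fractions of one compound over the three pools."""

    f_dissolved: float
    f_biota: float
    f_doc: float

    def __post_init__(self) -> None:
        for name, value in (
            ("f_dissolved", self.f_dissolved),
            ("f_biota", self.f_biota),
            ("f_doc", self.f_doc),
        ):
            if not 0.0 <= value <= 1.0:
                raise InputError(f"{name} outside [0, 1]: {value}")
        if abs(self.f_dissolved + self.f_biota + self.f_doc - 1.0) > 1e-12:
            raise InputError("partition fractions must sum to 1")


def equilibrium_fractions(
    bcf_L_per_kg: float,
    biomass_kg_om_per_L: float,
    kdoc_L_per_kg: float,
    doc_kg_per_L: float,
) -> PartitionState:
    """Close the three-pool mass balance at equilibrium.

    ``f_dissolved = 1 / (1 + BCF*B + K_DOC*D)``; the biota and DOC
    fractions follow as ``BCF*B*f_dissolved`` and ``K_DOC*D*f_dissolved``.
    """
    if min(bcf_L_per_kg, biomass_kg_om_per_L, kdoc_L_per_kg, doc_kg_per_L) < 0:
        raise InputError("all partitioning inputs must be >= 0")
    b = bcf_L_per_kg * biomass_kg_om_per_L
    d = kdoc_L_per_kg * doc_kg_per_L
    f_diss = 1.0 / (1.0 + b + d)
    return PartitionState(f_dissolved=f_diss, f_biota=b * f_diss, f_doc=d * f_diss)


def compound_fractions(compound: PAHCompound, ctx: PartitionContext) -> PartitionState:
    """Equilibrium fractions of ``compound`` in context ``ctx``."""
    return equilibrium_fractions(
        bcf(compound.log_kow, ctx.f_om, ctx.delta_octanol),
        ctx.biomass_kg_om_per_L,
        kdoc(compound.log_kow),
        ctx.doc_kg_per_L,
    )


def sorption_artifact_bound(
    compound: PAHCompound,
    ctx_t0: PartitionContext,
    ctx_t1: PartitionContext,
) -> float:
    """Fraction of a dissolved-phase decrease attributable to repartitioning.

    Computes ``max(0, 1 - f_dissolved(t1) / f_dissolved(t0))`` at the
    compound's BCF and K_DOC.  Zero when the organic-matter pools do not
    change (or shrink: a declining pool cannot explain a dissolved-phase
    decrease, hence the floor at 0).
    """
    f0 = compound_fractions(compound, ctx_t0).f_dissolved
    f1 = compound_fractions(compound, ctx_t1).f_dissolved
    return max(0.0, 1.0 - f1 / f0)
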