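"""Theoretical lumen hydraulics and percentage loss of conductivity.

Unit chain
----------
Per-conduit laminar (Hagen-Poiseuille) conductance of a cylinder of
diameter ``d`` (metres) per unit length and unit pressure gradient is
``pi*rho/(128*mu) * d**4`` with units::

    [kg m-3] / [Pa s] * [m4]  =  kg m / (Pa s)

Conductivities are reported MPa-normalised (multiply by 1e6) to match the
conventional ``kg m MPa-1 s-1``; dividing by the xylem cross-sectional
area (m2) gives specific conductivity ``kg m-1 MPa-1 s-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import ConduitMap

__all__ = [
    "FluidProperties",
    "HydraulicSample",
    "ScanPair",
    "ClampedPLC",
    "theoretical_conductance",
    "specific_conductivity",
    "plc_hydraulic",
    "plc_theoretical",
    "water_viscosity_pa_s",
    "viscosity_correct",
]


@dataclass(frozen=True)
class FluidProperties:
    """Perfusion fluid; defaults are water at 20 degC."""

    density_kg_m3: float = 998.2
    viscosity_pa_s: float = 1.002e-3
    temperature_c: float = 20.0

    def __post_init__(self):
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise ValidationError("fluid density and viscosity must be positive")


WATER_20C = FluidProperties()


@dataclass(frozen=True)
class HydraulicSample:
    """One flow-meter measurement: initial and maximum conductivity at a Psi.

    ``ki``/``ks`` are length- and area-normalised conductivities
    (kg m-1 MPa-1 s-1).
    """

    psi_mpa: float
    ki: float
    ks: float
    temperature_c: float = 20.0
    sample_id: str = ""

    def __post_init__(self):
        if self.ki < 0:
            raise ValidationError(f"{self.sample_id or 'sample'}: ki must be >= 0")
        if self.ks <= 0:
            raise ValidationError(f"{self.sample_id or 'sample'}: ks must be > 0")


@dataclass
class ScanPair:
    """Matched initial/final scans of one organ sample at a measured Psi.

    ``embolised_ids`` indexes the final conduit set. Conductance fields are
    populated by :func:`plc_theoretical`.
    """

    psi_mpa: float
    initial: "ConduitMap"
    final: "ConduitMap"
    embolised_ids: frozenset[int]
    unmatched_initial_ids: frozenset[int] = field(default_factory=frozenset)
    kt_final: float | None = None
    kt_initial: float | None = None
    plc_t_pct: float | None = None


@dataclass(frozen=True)
class ClampedPLC:
    """PLC clamped to [0, 100] with the raw (unclamped) value retained."""

    plc_pct: float
    raw_pct: float

    def __float__(self) -> float:
        return self.plc_pct


def theoretical_conductance(diameters_um, fluid: FluidProperties = WATER_20C,
                            pressure_unit: str = "MPa") -> float:
    """Cumulative lumen conductance ``pi*rho/(128*mu) * sum(d_i**4)``.

    Diameters in micrometres are converted to metres; the result is per
    unit length and unit pressure gradient, in ``kg m MPa-1 s-1`` by
    default (``pressure_unit="Pa"`` leaves it in ``kg m Pa-1 s-1``).
    An empty list yields 0 (no conduits, no flow) rather than an error.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size and np.any(d <= 0):
        raise ValidationError("diameters must be positive")
    if pressure_unit not in ("Pa", "MPa"):
        raise ValidationError("pressure_unit must be 'Pa' or 'MPa'")
    kt = (np.pi * fluid.density_kg_m3 / (128.0 * fluid.viscosity_pa_s)
          * float(np.sum((d * 1e-6) ** 4)))
    return kt * 1e6 if pressure_unit == "MPa" else kt


def specific_conductivity(kt: float, xylem_area_mm2: float) -> float:
    """Conductance divided by xylem cross-sectional area.

    With ``kt`` in kg m MPa-1 s-1 and the area in mm2 the result is in
    kg m-1 MPa-1 s-1.
    """
    if xylem_area_mm2 <= 0:
        raise ValidationError("xylem_area_mm2 must be > 0")
    return kt / (xylem_area_mm2 * 1e-6)


def plc_hydraulic(sample: HydraulicSample) -> ClampedPLC:
    """Percentage loss of conductivity ``(1 - ki/ks) * 100``.

    Noise can push the raw value below 0 (ki > ks); the clamped value is
    reported and the raw one retained on the result.
    """
    raw = (1.0 - sample.ki / sample.ks) * 100.0
    return ClampedPLC(plc_pct=float(np.clip(raw, 0.0, 100.0)), raw_pct=raw)


def plc_theoretical(pair: ScanPair, fluid: FluidProperties = WATER_20C) -> float:
    """Theoretical PLC of a scan pair: ``(1 - kt_initial/kt_final) * 100``.

    ``kt_final`` sums over every conduit visible in the final (fully
    embolised) scan; ``kt_initial`` is ``kt_final`` minus the conductance
    of the conduits already embolised in the initial scan, so the PLC
    equals the embolised share of total theoretical conductance. Results
    are stored on the pair and returned.
    """
    if not pair.final.conduits:
        raise ValidationError("final scan contains no conduits")
    d_all = pair.final.diameters_um()
    d_emb = np.array(
        [c.equivalent_diameter_um for c in pair.final.conduits
         if c.id in pair.embolised_ids],
        dtype=float,
    )
    kt_final = theoretical_conductance(d_all, fluid)
    kt_emb = theoretical_conductance(d_emb, fluid)
    pair.kt_final = kt_final
    pair.kt_initial = kt_final - kt_emb
    pair.plc_t_pct = float(np.clip(100.0 * kt_emb / kt_final, 0.0, 100.0))
    return pair.plc_t_pct


# Kestin, Sokolov & Wakeham (1978) correlation for the viscosity of liquid
# water relative to 20 degC; stated validity ~0-40 degC, used here to 50.
_KESTIN_COEFFS = (1.2364, -1.37e-3, 5.7e-6)


def water_viscosity_pa_s(temperature_c: float) -> float:
    """Dynamic viscosity of water (Pa s) from the Kestin 1978 correlation."""
    if not (0.0 < temperature_c < 50.0):
        raise ValidationError("temperature must lie in (0, 50) degC")
    dt = 20.0 - temperature_c
    a0, a1, a2 = _KESTIN_COEFFS
    log10_ratio = dt / (temperature_c + 96.0) * (a0 + a1 * dt + a2 * dt * dt)
    return 1.002e-3 * 10.0**log10_ratio


def viscosity_correct(k_raw: float, temperature_c: float) -> float:
    """Normalise a conductivity measured at ``temperature_c`` to 20 degC.

    Multiplies by ``mu(T)/mu(20)``: water is less viscous when warm, so a
    warm measurement overstates the 20-degC conductivity and the factor is
    < 1 above 20 degC.
    """
    return k_raw * water_viscosity_pa_s(temperature_c) / water_viscosity_pa_s(20.0)
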