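"""Data model for bony-labyrinth morphometrics.

The unit of observation is a single labyrinth endocast per taxon (left ear
unless noted).  Measurements are grouped anatomically: the cochlea (the
spiral hearing canal), the three semicircular canals (anterior, lateral,
posterior), and the vestibule with its accessory channels.  All linear
dimensions are millimetres, volumes mm^3, angles degrees, body mass grams.

Missing values are represented as ``None`` throughout; they are never
silently coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Optional


class Canal(str, Enum):
    """The three semicircular canals."""

    ANTERIOR = "anterior"
    LATERAL = "lateral"
    POSTERIOR = "posterior"


CANALS = (Canal.ANTERIOR, Canal.LATERAL, Canal.POSTERIOR)

MAJOR_CLADES = (
    "Marsupialia",
    "Eutheria(stem)",
    "Afrotheria",
    "Xenarthra",
    "Laurasiatheria",
    "Euarchontoglires",
)

HABITATS = ("terrestrial", "aquatic", "volant", "unknown")

#: How the posterior limb of the lateral semicircular canal reaches the
#: vestibule: fused with the posterior canal (secondary common crus),
#: through the posterior ampulla, or directly into the vestibule.
LSC_ENTRY_STATES = ("secondary_common_crus", "posterior_ampulla", "vestibule")


@dataclass
class TaxonRecord:
    taxon_id: str
    display_name: str
    major_clade: str
    status: str  # "extant" | "fossil"
    habitat: str
    body_mass_g: Optional[float] = None
    skull_length_mm: Optional[float] = None
    is_average: bool = False
    lsc_entry: Optional[str] = None

    def __post_init__(self) -> None:
        if self.major_clade not in MAJOR_CLADES:
            raise ValueError(f"unknown major clade {self.major_clade!r}")
        if self.status not in ("extant", "fossil"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.body_mass_g is not None and not self.body_mass_g > 0:
            raise ValueError("body_mass_g must be positive when present")
        if self.lsc_entry is not None and self.lsc_entry not in LSC_ENTRY_STATES:
            raise ValueError(f"unknown lateral-canal entry {self.lsc_entry!r}")


@dataclass
class CochleaMeasurements:
    volume_mm3: Optional[float] = None
    coil_degrees: Optional[float] = None
    lamina_degrees: Optional[float] = None
    canal_length_mm: Optional[float] = None
    aqueduct_length_mm: Optional[float] = None
    aspect_ratio: Optional[float] = None
    basal_angle_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.coil_degrees is not None and self.coil_degrees < 0:
            raise ValueError("coil_degrees must be >= 0")
        if self.aspect_ratio is not None and not self.aspect_ratio > 0:
            raise ValueError("aspect_ratio must be positive when present")


@dataclass
class CanalMeasurements:
    canal: Canal
    arc_radius_mm: Optional[float] = None
    arc_height_mm: Optional[float] = None
    arc_width_mm: Optional[float] = None
    slender_length_mm: Optional[float] = None
    lumen_diameter_mm: Optional[float] = None
    linear_deviation_mm: Optional[float] = None
    angular_deviation_deg: Optional[float] = None
    arc_aspect_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        self.canal = Canal(self.canal)
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_mm") and v is not None and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        ad = self.angular_deviation_deg
        if ad is not None and not (0 <= ad <= 180):
            raise ValueError("angular_deviation_deg must lie in [0, 180]")


@dataclass
class VestibuleMeasurements:
    aqueduct_length_mm: Optional[float] = None
    stapedial_ratio: Optional[float] = None
    sagittal_index_pct: Optional[float] = None
    angle_AL_deg: Optional[float] = None
    angle_AP_deg: Optional[float] = None
    angle_LP_deg: Optional[float] = None

    def __post_init__(self) -> None:
        si = self.sagittal_index_pct
        if si is not None and not (0 <= si <= 100):
            raise ValueError("sagittal_index_pct must lie in [0, 100]")
        for name in ("angle_AL_deg", "angle_AP_deg", "angle_LP_deg"):
            v = getattr(self, name)
            if v is not None and not (0 < v < 180):
                raise ValueError(f"{name} must lie in (0, 180)")


@dataclass
class LabyrinthRecord:
    """All per-specimen endocast measurements for one taxon."""

    taxon_id: str
    labyrinth_volume_mm3: Optional[float] = None
    labyrinth_length_mm: Optional[float] = None
    cochlea: CochleaMeasurements = field(default_factory=CochleaMeasurements)
    canals: dict = field(default_factory=dict)  # Canal -> CanalMeasurements
    vestibule: VestibuleMeasurements = field(default_factory=VestibuleMeasurements)

    def __post_init__(self) -> None:
        if self.canals and set(self.canals) != set(CANALS):
            raise ValueError("exactly three canal entries required")
        cv, lv = self.cochlea.volume_mm3, self.labyrinth_volume_mm3
        if cv is not None and lv is not None and cv > lv:
            raise ValueError("cochlear volume cannot exceed labyrinth volume")

    def canal(self, canal: Canal) -> CanalMeasurements:
        return self.canals[Canal(canal)]


@dataclass
class SpecimenDeviationRecord:
    """Per-specimen canal planarity data (intraspecific variation sample)."""

    specimen_id: str
    linear_deviation_mm: dict  # Canal -> float
    lumen_diameter_mm: dict  # Canal -> float

    def __post_init__(self) -> None:
        for d in self.lumen_diameter_mm.values():
            if not d > 0:
                raise ValueError("lumen diameters must be positive")
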