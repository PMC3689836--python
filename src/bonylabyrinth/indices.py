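"""Scalar morphometric indices and discrete character scoring.

These are the derived quantities used throughout the comparative analysis:

* arc radius of curvature ``R = (arc height + arc width) / 4`` — the mean
  semi-extent of a semicircular canal arc, the standard size measure for
  vestibular sensitivity comparisons;
* angular deviation of a canal from its best-fit plane, obtained from the
  total linear deviation ``ld`` as the angle subtended at the arc centre by
  a chord of length ``ld``: ``theta = 2 asin(ld / 2R)``;
* the substantiality ratio ``ld / lumen diameter`` (>= 1 flags a canal whose
  departure from planarity exceeds its own cross-section);
* slender-length/radius ratio, cochlear turn count (degrees / 360),
  volumetric contributions of cochlea vs vestibule, and the agility
  normalisation ``100 * mean arc radius / body mass``;
* the six discrete characters traced on the cladogram (lateral-canal entry,
  lateral-canal position, largest canal, cochlear spire shape, coiling bin,
  cochlear-contribution bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .records import CANALS, Canal, LabyrinthRecord, TaxonRecord

#: A cochlear spire is called "high" when height/basal-width exceeds this.
HIGH_ASPECT_THRESHOLD = 0.55

#: Planarity deviation is "substantial" when linear deviation / lumen
#: diameter reaches this value.
SUBSTANTIAL_RATIO = 1.0

COIL_BINS = ("1-2 turns", "2-3 turns", ">3 turns")
CONTRIBUTION_BINS = ("<=50%", "51-75%", ">75%")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching the convention of printed tables
    (banker's rounding would turn 0.375 into 0.38 too, but not 0.445)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def arc_radius(arc_height_mm: float, arc_width_mm: float) -> float:
    """Radius of curvature of a canal arc: half the mean of height and width.

    Symmetric in its arguments; for a circle of diameter d both extents are
    d and the radius is d/2.
    """
    if arc_height_mm < 0 or arc_width_mm < 0:
        raise ValueError("arc extents must be non-negative")
    return (arc_height_mm + arc_width_mm) / 4.0


def angular_deviation(linear_deviation_mm: float, arc_radius_mm: float) -> float:
    """Total angular deviation (degrees) of a canal from its plane.

    The linear deviation is read as a chord of the canal's arc circle; the
    returned angle is the central angle subtending that chord,
    ``2 asin(ld / 2R)``.  Undefined (rejected) when ld exceeds the diameter.
    """
    if arc_radius_mm <= 0:
        raise ValueError("arc radius must be positive")
    if linear_deviation_mm < 0:
        raise ValueError("linear deviation must be non-negative")
    x = linear_deviation_mm / (2.0 * arc_radius_mm)
    if x > 1.0:
        raise ValueError("linear deviation exceeds the arc diameter")
    return math.degrees(2.0 * math.asin(x))


def deviation_ratio(
    linear_deviation_mm: float, lumen_diameter_mm: float
) -> tuple[float, bool]:
    """Linear deviation over lumen diameter, with the substantiality flag."""
    if lumen_diameter_mm <= 0:
        raise ValueError("lumen diameter must be positive")
    if linear_deviation_mm < 0:
        raise ValueError("linear deviation must be non-negative")
    ratio = linear_deviation_mm / lumen_diameter_mm
    return ratio, ratio >= SUBSTANTIAL_RATIO


def slender_ratio(slender_length_mm: float, arc_radius_mm: float) -> float:
    """Length of the unampullated (slender) canal portion over arc radius."""
    if arc_radius_mm <= 0:
        raise ValueError("arc radius must be positive")
    return slender_length_mm / arc_radius_mm


def cochlear_turns(coil_degrees: float) -> float:
    """Number of completed cochlear turns: total degrees / 360."""
    if coil_degrees < 0:
        raise ValueError("coil degrees must be non-negative")
    return coil_degrees / 360.0


def volumetric_contributions(
    cochlea_volume_mm3: float, labyrinth_volume_mm3: float
) -> tuple[float, float]:
    """Percent contributions (cochlear, vestibular) to total labyrinth volume.

    The vestibular share is defined as the complement, so the two always sum
    to exactly 100.
    """
    if labyrinth_volume_mm3 <= 0:
        raise ValueError("labyrinth volume must be positive")
    if not 0 <= cochlea_volume_mm3 <= labyrinth_volume_mm3:
        raise ValueError("cochlear volume must lie within [0, labyrinth volume]")
    cochlear = 100.0 * cochlea_volume_mm3 / labyrinth_volume_mm3
    return cochlear, 100.0 - cochlear


def mean_arc_radius(record: LabyrinthRecord) -> Optional[float]:
    radii = [record.canal(c).arc_radius_mm for c in CANALS]
    if any(r is None for r in radii):
        return None
    return sum(radii) / 3.0


def normalized_radius(
    mean_arc_radius_mm: float, body_mass_g: Optional[float]
) -> Optional[float]:
    """Mean canal arc radius over body mass, x100 (agility normalisation).

    Missing mass propagates to a missing result — never 0.
    """
    if body_mass_g is None:
        return None
    if body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    return 100.0 * mean_arc_radius_mm / body_mass_g


@dataclass
class DiscreteCharacterVector:
    """States of the six labyrinth characters traced on the cladogram.

    Multi-valued slots (frozensets of state strings) mark polymorphic
    scorings, e.g. a tie for the largest canal arc.  ``None`` marks missing.
    """

    lsc_entry: Optional[str] = None           # c1
    lsc_position: Optional[str] = None        # c2: low | high
    largest_canal: Optional[frozenset] = None  # c3: set of canal names
    cochlea_shape: Optional[str] = None       # c4: low | high
    coil_bin: Optional[str] = None            # c5
    contribution_bin: Optional[str] = None    # c6

    def as_dict(self) -> dict:
        return {
            "lsc_entry": self.lsc_entry,
            "lsc_position": self.lsc_position,
            "largest_canal": self.largest_canal,
            "cochlea_shape": self.cochlea_shape,
            "coil_bin": self.coil_bin,
            "contribution_bin": self.contribution_bin,
        }


def bin_coiling(coil_degrees: float) -> str:
    """Bin cochlear coiling: 360-720 deg, (720, 1080], over 1080."""
    if coil_degrees <= 720:
        return COIL_BINS[0]
    if coil_degrees <= 1080:
        return COIL_BINS[1]
    return COIL_BINS[2]


def bin_contribution(cochlear_pct: float) -> str:
    """Bin the cochlear volume percentage: <=50, (50, 75], >75."""
    if cochlear_pct <= 50:
        return CONTRIBUTION_BINS[0]
    if cochlear_pct <= 75:
        return CONTRIBUTION_BINS[1]
    return CONTRIBUTION_BINS[2]


def largest_canal(record: LabyrinthRecord) -> Optional[frozenset]:
    """Canal(s) with the greatest arc radius; ties reported as a set, never
    silently broken."""
    radii = {c: record.canal(c).arc_radius_mm for c in CANALS}
    if any(v is None for v in radii.values()):
        return None
    best = max(radii.values())
    return frozenset(c.value for c, v in radii.items() if v == best)


def classify_characters(
    record: LabyrinthRecord, taxon: TaxonRecord
) -> DiscreteCharacterVector:
    """Score the six discrete characters for one taxon.

    The lateral-canal entry (c1) is an anatomical observation carried as a
    fixture annotation; position (c2), largest canal (c3), spire shape (c4),
    coiling bin (c5) and contribution bin (c6) derive from measurements.
    """
    v = DiscreteCharacterVector(lsc_entry=taxon.lsc_entry)
    si = record.vestibule.sagittal_index_pct
    if si is not None:
        v.lsc_position = "high" if si > 0 else "low"
    v.largest_canal = largest_canal(record)
    ar = record.cochlea.aspect_ratio
    if ar is not None:
        v.cochlea_shape = "high" if ar > HIGH_ASPECT_THRESHOLD else "low"
    coil = record.cochlea.coil_degrees
    if coil is not None:
        v.coil_bin = bin_coiling(coil)
    cv, lv = record.cochlea.volume_mm3, record.labyrinth_volume_mm3
    if cv is not None and lv is not None:
        v.contribution_bin = bin_contribution(
            volumetric_contributions(cv, lv)[0]
        )
    return v
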