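"""Readers and writers for the packaged measurement tables and the phylogeny.

The measurement fixture is a single flat CSV (one row per taxon, column
groups for the cochlea, the three canals, and the vestibule) so it can be
audited cell-by-cell against the printed comparative tables it transcribes.
Empty fields are missing values; they are preserved on round-trip and never
read as zero.

One printed cell is corrected in the fixture: the body mass of *Homo
sapiens* appears in the source table as 8000 g, a physically impossible
value for an adult human (a dropped digit); the same publication's
radius/body-mass ratios for *Homo* (0.004 after x100 scaling) require a
mass of ~80 kg, so the fixture stores 80000 g.

Trees are Newick; internal node labels (the clade letters A..e) are kept as
plain node labels, absent branch lengths default to 1.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import dendropy

from .records import (
    CANALS,
    Canal,
    CanalMeasurements,
    CochleaMeasurements,
    LabyrinthRecord,
    SpecimenDeviationRecord,
    TaxonRecord,
    VestibuleMeasurements,
)

Source = Union[str, Path, TextIO]

_TAXON_COLS = [
    "taxon_id",
    "display_name",
    "major_clade",
    "status",
    "habitat",
    "is_average",
    "lsc_entry",
    "body_mass_g",
    "skull_length_mm",
]
_LAB_COLS = ["labyrinth_volume_mm3", "labyrinth_length_mm"]
_COCHLEA_COLS = {
    "cochlea_volume_mm3": "volume_mm3",
    "cochlea_coil_deg": "coil_degrees",
    "cochlea_lamina_deg": "lamina_degrees",
    "cochlea_length_mm": "canal_length_mm",
    "cochlea_aqueduct_mm": "aqueduct_length_mm",
    "cochlea_aspect": "aspect_ratio",
    "cochlea_basal_angle_deg": "basal_angle_deg",
}
_VEST_COLS = {
    "vest_aqueduct_mm": "aqueduct_length_mm",
    "stapedial_ratio": "stapedial_ratio",
    "sagittal_index_pct": "sagittal_index_pct",
    "angle_AL_deg": "angle_AL_deg",
    "angle_AP_deg": "angle_AP_deg",
    "angle_LP_deg": "angle_LP_deg",
}
_CANAL_COLS = {
    "radius": "arc_radius_mm",
    "slender": "slender_length_mm",
    "lumen": "lumen_diameter_mm",
    "lindev": "linear_deviation_mm",
    "angdev": "angular_deviation_deg",
    "arc_aspect": "arc_aspect_ratio",
}
_CANAL_SUFFIX = {Canal.ANTERIOR: "ant", Canal.LATERAL: "lat", Canal.POSTERIOR: "post"}


class TableFormatError(ValueError):
    """Raised when a measurement table cannot be parsed."""


def _open(source: Source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", newline="", encoding="utf-8"), True


def _parse_float(value: str, row: str, col: str) -> Optional[float]:
    value = value.strip()
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise TableFormatError(
            f"non-numeric value {value!r} in row {row!r}, column {col!r}"
        ) from None


def _canal_col(kind: str, canal: Canal) -> str:
    suffix = _CANAL_SUFFIX[canal]
    unit = {"radius": "_mm", "slender": "_mm", "lumen": "_mm",
            "lindev": "_mm", "angdev": "_deg", "arc_aspect": ""}[kind]
    return f"{kind}_{suffix}{unit}"


def load_measurements(source: Source) -> list[tuple[TaxonRecord, LabyrinthRecord]]:
    """Read the per-taxon measurement table.

    Returns one ``(TaxonRecord, LabyrinthRecord)`` pair per row.  Duplicate
    taxon ids and non-numeric measurement cells are rejected.
    """
    handle, close = _open(source)
    try:
        reader = csv.DictReader(handle)
        out: list[tuple[TaxonRecord, LabyrinthRecord]] = []
        seen: set[str] = set()
        for rowdict in reader:
            tid = rowdict["taxon_id"].strip()
            if tid in seen:
                raise TableFormatError(f"duplicate taxon_id {tid!r}")
            seen.add(tid)
            num = {
                col: _parse_float(rowdict[col], tid, col)
                for col in rowdict
                if col not in ("taxon_id", "display_name", "major_clade",
                               "status", "habitat", "is_average", "lsc_entry")
            }
            taxon = TaxonRecord(
                taxon_id=tid,
                display_name=rowdict["display_name"].strip(),
                major_clade=rowdict["major_clade"].strip(),
                status=rowdict["status"].strip(),
                habitat=rowdict["habitat"].strip(),
                is_average=rowdict["is_average"].strip().lower() == "true",
                lsc_entry=rowdict["lsc_entry"].strip() or None,
                body_mass_g=num["body_mass_g"],
                skull_length_mm=num["skull_length_mm"],
            )
            canals = {
                canal: CanalMeasurements(
                    canal=canal,
                    **{field: num[_canal_col(kind, canal)]
                       for kind, field in _CANAL_COLS.items()},
                )
                for canal in CANALS
            }
            record = LabyrinthRecord(
                taxon_id=tid,
                labyrinth_volume_mm3=num["labyrinth_volume_mm3"],
                labyrinth_length_mm=num["labyrinth_length_mm"],
                cochlea=CochleaMeasurements(
                    **{f: num[c] for c, f in _COCHLEA_COLS.items()}
                ),
                canals=canals,
                vestibule=VestibuleMeasurements(
                    **{f: num[c] for c, f in _VEST_COLS.items()}
                ),
            )
            out.append((taxon, record))
        return out
    finally:
        if close:
            handle.close()


def write_measurements(
    records: Iterable[tuple[TaxonRecord, LabyrinthRecord]], target: Source
) -> None:
    """Write records back to the flat CSV layout (round-trip inverse of
    :func:`load_measurements`)."""
    header = (
        _TAXON_COLS
        + _LAB_COLS
        + list(_COCHLEA_COLS)
        + list(_VEST_COLS)
        + [_canal_col(kind, canal) for kind in _CANAL_COLS for canal in CANALS]
    )

    def fmt(v) -> str:
        if v is None:
            return ""
        return repr(v) if isinstance(v, float) else str(v)

    handle, close = _open_write(target)
    try:
        writer = csv.writer(handle)
        writer.writerow(header)
        for taxon, rec in records:
            row = [
                taxon.taxon_id,
                taxon.display_name,
                taxon.major_clade,
                taxon.status,
                taxon.habitat,
                "true" if taxon.is_average else "false",
                taxon.lsc_entry or "",
                fmt(taxon.body_mass_g),
                fmt(taxon.skull_length_mm),
                fmt(rec.labyrinth_volume_mm3),
                fmt(rec.labyrinth_length_mm),
            ]
            row += [fmt(getattr(rec.cochlea, f)) for f in _COCHLEA_COLS.values()]
            row += [fmt(getattr(rec.vestibule, f)) for f in _VEST_COLS.values()]
            for kind, field in _CANAL_COLS.items():
                row += [fmt(getattr(rec.canal(c), field)) for c in CANALS]
            writer.writerow(row)
    finally:
        if close:
            handle.close()


def _open_write(target: Source):
    if hasattr(target, "write"):
        return target, False
    return open(target, "w", newline="", encoding="utf-8"), True


def load_specimen_deviations(source: Source) -> list[SpecimenDeviationRecord]:
    """Read the per-specimen canal deviation/diameter table."""
    handle, close = _open(source)
    try:
        reader = csv.DictReader(handle)
        out = []
        seen: set[str] = set()
        for row in reader:
            sid = row["specimen_id"].strip()
            if sid in seen:
                raise TableFormatError(f"duplicate specimen_id {sid!r}")
            seen.add(sid)
            ld = {
                canal: _parse_float(row[_canal_col("lindev", canal)], sid, "lindev")
                for canal in CANALS
            }
            dia = {
                canal: _parse_float(row[_canal_col("lumen", canal)], sid, "lumen")
                for canal in CANALS
            }
            out.append(SpecimenDeviationRecord(sid, ld, dia))
        return out
    finally:
        if close:
            handle.close()


def load_tree(source: Source, tip_ids: Optional[set] = None) -> dendropy.Tree:
    """Parse a Newick tree.

    Topology (including polytomies) is preserved exactly; internal labels are
    node labels; absent branch lengths default to 1.  When ``tip_ids`` is
    given, tips absent from it raise a warning (not an error).
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        data = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0
    if tip_ids is not None:
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label not in tip_ids:
                warnings.warn(
                    f"tree tip {leaf.taxon.label!r} has no measurement record",
                    stacklevel=2,
                )
    return tree


def write_tree(tree: dendropy.Tree, target: Source) -> None:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=True,
        unquoted_underscores=True,
    )
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


# -- packaged fixtures -------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("bonylabyrinth.data").joinpath(name).read_text()


def load_packaged_measurements() -> list[tuple[TaxonRecord, LabyrinthRecord]]:
    """The 36-taxon comparative dataset transcribed from the printed tables."""
    return load_measurements(_io.StringIO(_data_text("measurements.csv")))


def load_packaged_specimens() -> list[SpecimenDeviationRecord]:
    """The 12-specimen *Monodelphis domestica* planarity sample."""
    return load_specimen_deviations(_io.StringIO(_data_text("monodelphis_deviations.csv")))


def load_packaged_tree() -> dendropy.Tree:
    """The 36-tip composite therian cladogram (node labels A..e)."""
    return load_tree(_io.StringIO(_data_text("theria_tree.nwk")))
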