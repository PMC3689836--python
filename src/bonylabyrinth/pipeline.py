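"""End-to-end pipeline: derived indices, scaling statistics, habitat
contrast, ancestral states, and verification against transcribed printed
values.

Everything is deterministic for a fixed configuration and seed; every taxon
excluded from any statistic is logged together with the rule that excluded
it.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import allometry, ancestral, geometry, indices, io, synthetic
from .records import CANALS, Canal


@dataclass
class PipelineConfig:
    output_dir: Path
    measurements_path: Optional[Path] = None  # None -> packaged fixture
    tree_path: Optional[Path] = None
    specimens_path: Optional[Path] = None
    alpha: float = 0.05
    include_fossil_terrestrial: bool = True
    include_marsupial: bool = True
    include_stem_eutherians: bool = False
    seed: int = 0
    round_ratios: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.output_dir = Path(self.output_dir)


def _load(config: PipelineConfig):
    records = (
        io.load_measurements(config.measurements_path)
        if config.measurements_path
        else io.load_packaged_measurements()
    )
    tree = (
        io.load_tree(config.tree_path)
        if config.tree_path
        else io.load_packaged_tree()
    )
    specimens = (
        io.load_specimen_deviations(config.specimens_path)
        if config.specimens_path
        else io.load_packaged_specimens()
    )
    return records, tree, specimens


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def derived_indices_table(records) -> pd.DataFrame:
    """Per-taxon derived quantities: turns, volume contributions, slender
    ratios, deviation ratios and substantiality, recomputed angular
    deviations, normalized radius."""
    rows = []
    for taxon, rec in records:
        row: dict = {"taxon_id": taxon.taxon_id}
        coil = rec.cochlea.coil_degrees
        row["cochlear_turns"] = (
            None if coil is None else indices.cochlear_turns(coil)
        )
        cv, lv = rec.cochlea.volume_mm3, rec.labyrinth_volume_mm3
        if cv is not None and lv is not None:
            c, v = indices.volumetric_contributions(cv, lv)
            row["cochlear_pct"], row["vestibular_pct"] = c, v
        mr = indices.mean_arc_radius(rec)
        row["mean_arc_radius_mm"] = mr
        row["normalized_radius_x100"] = (
            None if mr is None else indices.normalized_radius(mr, taxon.body_mass_g)
        )
        for canal in CANALS:
            cm = rec.canal(canal)
            tag = canal.value
            if cm.slender_length_mm is not None and cm.arc_radius_mm:
                row[f"{tag}_slender_ratio"] = indices.slender_ratio(
                    cm.slender_length_mm, cm.arc_radius_mm
                )
            if cm.linear_deviation_mm is not None and cm.lumen_diameter_mm:
                ratio, flag = indices.deviation_ratio(
                    cm.linear_deviation_mm, cm.lumen_diameter_mm
                )
                row[f"{tag}_deviation_ratio"] = ratio
                row[f"{tag}_substantial"] = flag
            if cm.linear_deviation_mm is not None and cm.arc_radius_mm:
                row[f"{tag}_angular_deviation_deg"] = indices.angular_deviation(
                    cm.linear_deviation_mm, cm.arc_radius_mm
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon_id")


def specimen_ratio_table(specimens, ndigits: int = 2) -> pd.DataFrame:
    """Deviation/diameter ratios for the intraspecific specimen sample,
    rounded at report precision."""
    rows = []
    for spec in specimens:
        row = {"specimen_id": spec.specimen_id}
        for canal in CANALS:
            ratio, flag = indices.deviation_ratio(
                spec.linear_deviation_mm[canal], spec.lumen_diameter_mm[canal]
            )
            row[f"{canal.value}_ratio"] = indices.round_half_up(ratio, ndigits)
            row[f"{canal.value}_substantial"] = flag
        rows.append(row)
    return pd.DataFrame(rows).set_index("specimen_id")


def correlation_frame(tables: dict) -> pd.DataFrame:
    rows = []
    for name, res in tables["mass"].items():
        rows.append(("mass", name, res.n, res.r, res.r_squared, res.p, res.significant))
    for (a, b), res in tables["cochlea"].items():
        rows.append(("cochlea", f"{a}~{b}", res.n, res.r, res.r_squared, res.p, res.significant))
    for (canal, a, b), res in tables["canals"].items():
        rows.append((f"canal_{canal}", f"{a}~{b}", res.n, res.r, res.r_squared, res.p, res.significant))
    return pd.DataFrame(
        rows, columns=["table", "pair", "n", "r", "r_squared", "p", "significant"]
    )


def build_character_matrices(records) -> tuple[dict, dict]:
    """(discrete, continuous) character matrices keyed by character name."""
    discrete: dict[str, dict] = {c: {} for c in ancestral.DISCRETE_CHARACTERS}
    continuous: dict[str, dict] = {"coil_degrees": {}, "cochlear_contribution_pct": {}}
    for taxon, rec in records:
        vec = indices.classify_characters(rec, taxon)
        for name, value in vec.as_dict().items():
            discrete[name][taxon.taxon_id] = value
        continuous["coil_degrees"][taxon.taxon_id] = rec.cochlea.coil_degrees
        cv, lv = rec.cochlea.volume_mm3, rec.labyrinth_volume_mm3
        continuous["cochlear_contribution_pct"][taxon.taxon_id] = (
            None if cv is None or lv is None
            else indices.volumetric_contributions(cv, lv)[0]
        )
    return discrete, continuous


def mass_prediction_table(records, fit: allometry.RegressionFit) -> pd.DataFrame:
    """Body-mass point estimates for taxa lacking a published mass."""
    rows = []
    for taxon, rec in records:
        if taxon.body_mass_g is not None or rec.labyrinth_length_mm is None:
            continue
        if taxon.major_clade == "Eutheria(stem)":
            continue  # stem eutherian averages are outside the fit's domain
        mass = allometry.predict_mass(rec.labyrinth_length_mm, fit)
        rows.append(
            {
                "taxon_id": taxon.taxon_id,
                "labyrinth_length_mm": rec.labyrinth_length_mm,
                "predicted_mass_g": mass,
                "predicted_mass_kg": mass / 1000.0,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


# ---------------------------------------------------------------------------
# synthetic measurement closure
# ---------------------------------------------------------------------------

def measure_bundle(parts: dict, reference_point=None, cochlea_axis=None) -> dict:
    """Run the geometry operators over a generated labyrinth bundle.

    Returns per-canal plane fits, radii (from in-plane extents), linear
    deviations, pairwise inter-plane angles, and cochlear coiling/profile
    (about the axis recovered from the cochlea's own basal-plane normal
    when no truth axis is given).
    """
    canal_names = ("anterior", "lateral", "posterior")
    fits = {name: geometry.fit_plane(parts[name]) for name in canal_names}
    if reference_point is None:
        all_pts = np.vstack([parts[n].points for n in parts])
        reference_point = all_pts.mean(axis=0)
    out: dict = {"planes": fits, "reference_point": reference_point}
    for name in canal_names:
        h, w = geometry.arc_extents(parts[name], fits[name])
        out[f"{name}_height_mm"] = h
        out[f"{name}_width_mm"] = w
        out[f"{name}_radius_mm"] = indices.arc_radius(h, w)
        out[f"{name}_aspect"] = h / w
        out[f"{name}_linear_deviation_mm"] = geometry.linear_deviation(
            parts[name], fits[name]
        )
    for a, b in (("anterior", "lateral"), ("anterior", "posterior"),
                 ("lateral", "posterior")):
        out[f"angle_{a}_{b}_deg"] = geometry.interplane_angle(
            fits[a], fits[b], reference_point
        )
    if "cochlea" in parts:
        spiral = parts["cochlea"]
        if cochlea_axis is not None:
            axis_point, axis_dir = map(np.asarray, cochlea_axis)
            basal_fit = None
        else:
            axis_point, axis_dir, basal_fit = estimate_spiral_axis(spiral)
        out["cochlea_coil_deg"] = geometry.cochlear_coiling(
            spiral, axis_point, axis_dir
        )
        h, w, aspect, full = geometry.cochlear_profile(
            spiral, axis_point, axis_dir
        )
        out["cochlea_height_mm"] = h
        out["cochlea_basal_width_mm"] = w
        out["cochlea_aspect"] = aspect
        out["cochlea_full_basal_turn"] = full
        if basal_fit is None:
            basal_fit = geometry.PlaneFit(
                normal=axis_dir / np.linalg.norm(axis_dir),
                centroid=axis_point, rms_residual_mm=0.0,
            )
        # basal-turn plane vs lateral canal plane, folded to the acute angle
        raw = geometry.interplane_angle(basal_fit, fits["lateral"], reference_point)
        out["angle_cochlea_lateral_deg"] = min(raw, 180.0 - raw)
    return out


def estimate_spiral_axis(spiral: geometry.Centerline, iterations: int = 6):
    """Estimate the rotation axis of a cochlear spiral from its points.

    Seeds the axis with the accumulated oriented-area vector of the point
    path (each loop contributes its area along the axis, so the seed is
    robust to spire height), then iterates: unwrap azimuths about the
    current axis, subtract the fitted linear rise of the helix, re-fit the
    flattened spiral's plane for the direction, and take the least-squares
    circle centre of the (flattened) basal turn as the axis point.
    Converges to well under a degree of the true axis for conical helices.

    Returns ``(axis_point, axis_direction, basal_plane)``.
    """
    pts = spiral.points
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    area = np.cross(rel[:-1], rel[1:]).sum(axis=0)
    norm = np.linalg.norm(area)
    if norm < 1e-12:
        raise ValueError("cannot estimate a rotation axis (zero winding)")
    axis_dir, axis_point = area / norm, centroid
    basal_fit = None
    for _ in range(iterations):
        az = geometry._azimuths(spiral, axis_point, axis_dir)
        theta = az - az[0]
        z = pts @ axis_dir
        rise = np.polyfit(theta, z, 1)
        flat = pts - np.outer(np.polyval(rise, theta) - z.mean(), axis_dir)
        fit = geometry.fit_plane(geometry.Centerline(flat))
        n = fit.normal if np.dot(fit.normal, axis_dir) >= 0 else -fit.normal
        axis_dir = n
        swept = np.abs(theta)
        mask = swept <= 2 * np.pi
        first = flat[mask] if mask.sum() >= 8 else flat
        c1 = first.mean(axis=0)
        u = first - c1
        u = u - np.outer(u @ axis_dir, axis_dir)
        b1 = u[0] / np.linalg.norm(u[0])
        b2 = np.cross(axis_dir, b1)
        xy = np.column_stack([u @ b1, u @ b2])
        lhs = np.column_stack([2 * xy, np.ones(len(xy))])
        sol, *_ = np.linalg.lstsq(lhs, (xy**2).sum(axis=1), rcond=None)
        axis_point = c1 + sol[0] * b1 + sol[1] * b2
        basal_fit = geometry.PlaneFit(
            normal=axis_dir, centroid=axis_point, rms_residual_mm=fit.rms_residual_mm
        )
    return axis_point, axis_dir, basal_fit


# ---------------------------------------------------------------------------
# verification against transcribed printed values
# ---------------------------------------------------------------------------

@dataclass
class Verdict:
    target_id: str
    expected: float
    computed: Optional[float]
    mode: str
    tolerance: float
    gating: str
    passed: bool


def load_reference(source=None) -> list[dict]:
    if source is None:
        text = resources.files("bonylabyrinth.data").joinpath(
            "reference_values.csv"
        ).read_text()
        handle = _io.StringIO(text)
    else:
        handle = open(source, newline="", encoding="utf-8")
    with handle:
        return list(csv.DictReader(handle))


def compare_to_reference(
    computed: dict, reference: list[dict]
) -> tuple[list[Verdict], bool]:
    """Check computed quantities against the transcribed reference.

    Modes: ``abs`` (|computed - expected| <= tolerance), ``ge``/``le``
    (bound checks).  Returns verdicts and the exit flag: True iff every
    ``exact``-gated target passes.  Unknown target ids are rejected.
    """
    verdicts = []
    for row in reference:
        tid = row["target_id"]
        if tid not in computed:
            raise KeyError(f"unknown verification target {tid!r}")
        value = computed[tid]
        expected = float(row["expected"])
        tol = float(row["tolerance"]) if row["tolerance"] else 0.0
        mode = row["mode"]
        if value is None:
            ok = False
        elif mode == "abs":
            ok = abs(value - expected) <= tol
        elif mode == "ge":
            ok = value >= expected
        elif mode == "le":
            ok = value <= expected
        else:
            raise ValueError(f"unknown comparison mode {mode!r}")
        verdicts.append(
            Verdict(tid, expected, value, mode, tol, row["gating"], ok)
        )
    exact_ok = all(v.passed for v in verdicts if v.gating == "exact")
    return verdicts, exact_ok


def reference_computations(records, specimens, fit=None) -> dict:
    """Recompute every quantity the packaged reference table checks."""
    by_id = {t.taxon_id: (t, r) for t, r in records}
    out: dict = {}
    # per-specimen deviation ratios, at report precision
    ratio_table = specimen_ratio_table(specimens)
    for spec in specimens:
        short = spec.specimen_id.split("-")[-1]
        for canal in CANALS:
            out[f"ratio_{short}_{canal.value[:3]}"] = ratio_table.loc[
                spec.specimen_id, f"{canal.value}_ratio"
            ]
    # regression and mass predictions (from the printed-coefficient line)
    fit = fit or allometry.fit_allometry(records)
    printed = allometry.RegressionFit(slope=0.151, intercept=0.8212, n=28, r_squared=float("nan"))
    out["regression_slope"] = fit.slope
    out["regression_intercept"] = fit.intercept
    for taxon_id, key in (("Canis", "mass_canis_kg"),
                          ("Bathygenys", "mass_bathygenys_kg"),
                          ("Balaenopteridae", "mass_balaenopterid_kg")):
        length = by_id[taxon_id][1].labyrinth_length_mm
        out[key] = allometry.predict_mass(length, printed) / 1000.0
    # headline correlations on the extant-mass sample
    extant = [(t, r) for t, r in records if t.body_mass_g is not None]
    masses = [t.body_mass_g for t, _ in extant]
    out["r_length_mass"] = allometry.log_correlation(
        masses, [r.labyrinth_length_mm for _, r in extant]
    ).r
    out["r_volume_mass"] = allometry.log_correlation(
        masses, [r.labyrinth_volume_mm3 for _, r in extant]
    ).r
    out["r_coiling_mass"] = allometry.log_correlation(
        masses, [r.cochlea.coil_degrees for _, r in extant]
    ).r
    # volumetric contributions
    for taxon_id, key in (("Didelphis", "cochlear_pct_didelphis"),
                          ("Hemicentetes", "cochlear_pct_hemicentetes"),
                          ("Chrysochloris", "cochlear_pct_chrysochloris")):
        t, r = by_id[taxon_id]
        out[key] = indices.round_half_up(
            indices.volumetric_contributions(
                r.cochlea.volume_mm3, r.labyrinth_volume_mm3
            )[0], 0,
        )
    dlat = by_id["Didelphis"][1].canal(Canal.LATERAL)
    out["didelphis_lateral_deviation_ratio"] = indices.round_half_up(
        indices.deviation_ratio(dlat.linear_deviation_mm, dlat.lumen_diameter_mm)[0]
    )
    # angular-deviation formula adequacy on non-averaged taxa
    hits = total = 0
    for taxon, rec in records:
        if taxon.is_average:
            continue
        for canal in CANALS:
            cm = rec.canal(canal)
            if cm.arc_radius_mm and cm.linear_deviation_mm is not None \
                    and cm.angular_deviation_deg is not None:
                theta = indices.angular_deviation(
                    cm.linear_deviation_mm, cm.arc_radius_mm
                )
                total += 1
                hits += abs(theta - cm.angular_deviation_deg) <= 0.6
    out["angular_deviation_within_0p6_share"] = hits / total if total else None
    # habitat contrast (default grouping)
    comparison, _ = allometry.habitat_contrast(records)
    out["contrast_welch_p"] = comparison.welch_p
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write report tables under the output
    directory; return paths and headline results."""
    records, tree, specimens = _load(config)
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    exclusion_log: dict[str, str] = {}

    idx_table = derived_indices_table(records)
    idx_table.to_csv(outdir / "derived_indices.csv")

    ratio_table = specimen_ratio_table(specimens, config.round_ratios)
    ratio_table.to_csv(outdir / "specimen_deviation_ratios.csv")

    tables = allometry.correlation_tables(records, config.alpha)
    corr = correlation_frame(tables)
    corr.to_csv(outdir / "correlations.csv", index=False)
    for taxon, _ in records:
        if taxon.body_mass_g is None:
            exclusion_log[taxon.taxon_id] = "no body mass: excluded from mass correlations/regression"

    fit = allometry.fit_allometry(records)
    predictions = mass_prediction_table(records, fit)
    with open(outdir / "allometry.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["slope", "intercept", "n", "r_squared"])
        w.writerow([fit.slope, fit.intercept, fit.n, fit.r_squared])
    predictions.to_csv(outdir / "mass_predictions.csv")

    comparison, contrast_exclusions = allometry.habitat_contrast(
        records,
        include_fossil_terrestrial=config.include_fossil_terrestrial,
        include_marsupial=config.include_marsupial,
        include_stem_eutherians=config.include_stem_eutherians,
    )
    exclusion_log.update(
        {k: f"habitat contrast: {v}" for k, v in contrast_exclusions.items()}
    )
    with open(outdir / "habitat_contrast.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["statistic", "value"])
        for name in ("n1", "n2", "mean1", "mean2", "var1", "var2",
                     "f_statistic", "f_p", "welch_t", "welch_df", "welch_p",
                     "pooled_t", "pooled_p"):
            w.writerow([name, getattr(comparison, name)])

    discrete, continuous = build_character_matrices(records)
    result = ancestral.reconstruct_all(tree, discrete, continuous)
    node_frame = pd.DataFrame.from_dict(result["nodes"], orient="index")
    node_frame.index.name = "node"
    node_frame.to_csv(outdir / "ancestral_states.csv")

    computed = reference_computations(records, specimens, fit)
    verdicts, exact_ok = compare_to_reference(computed, load_reference())

    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write("bony-labyrinth comparative pipeline\n")
        fh.write(f"taxa: {len(records)}; specimens: {len(specimens)}\n")
        fh.write(
            f"allometry: ln(length) = {fit.slope:.4f} ln(mass) + "
            f"{fit.intercept:.4f} (n={fit.n}, r^2={fit.r_squared:.3f})\n"
        )
        fh.write(
            f"habitat contrast: Welch t={comparison.welch_t:.3f}, "
            f"df={comparison.welch_df:.2f}, p={comparison.welch_p:.4f} "
            f"(aquatic n={comparison.n1}, terrestrial n={comparison.n2})\n"
        )
        fh.write(f"verification: exact-class pass = {exact_ok}\n")
        for v in verdicts:
            fh.write(
                f"  [{'PASS' if v.passed else 'FAIL'}] {v.target_id} "
                f"({v.gating}): computed={v.computed} expected={v.expected} "
                f"mode={v.mode} tol={v.tolerance}\n"
            )
        fh.write("exclusions:\n")
        for taxon_id in sorted(exclusion_log):
            fh.write(f"  {taxon_id}: {exclusion_log[taxon_id]}\n")

    with open(outdir / "exclusions.json", "w", encoding="utf-8") as fh:
        json.dump(exclusion_log, fh, indent=1, sort_keys=True)

    return {
        "fit": fit,
        "comparison": comparison,
        "verdicts": verdicts,
        "exact_ok": exact_ok,
        "outputs": sorted(p.name for p in outdir.iterdir()),
        "ancestral": result,
    }
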