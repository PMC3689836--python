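"""Allometric scaling, correlation screens, and the habitat contrast.

All bivariate analyses run on natural-log transformed values, pairing only
taxa with both members present (pairwise deletion).  Significance of a
Pearson correlation uses the exact t transform ``t = r sqrt((n-2)/(1-r^2))``
with n-2 degrees of freedom, two-tailed.

The body-mass regression is ordinary least squares of ln(labyrinth length,
mm) on ln(body mass, g) over the extant species with a usable published
mass (the domestic dog is excluded — breed masses span an order of
magnitude — as are fossil and Mesozoic taxa, which have none).  Inverting
the fit yields body-mass point estimates for fossil specimens from their
labyrinth length alone.

The habitat contrast compares vestibular volume contributions between
aquatic and terrestrial (non-volant) taxa with an F-test for variance
equality followed by a Welch two-tailed t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .indices import volumetric_contributions
from .records import LabyrinthRecord, TaxonRecord


@dataclass
class CorrelationResult:
    n: int
    r: float
    r_squared: float
    p: float
    alpha: float
    significant: bool


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    n: int
    r_squared: float
    response: str = "ln(labyrinth length, mm)"
    predictor: str = "ln(body mass, g)"


@dataclass
class GroupComparison:
    n1: int
    n2: int
    mean1: float
    mean2: float
    var1: float
    var2: float
    f_statistic: float
    f_p: float
    welch_t: float
    welch_df: float
    welch_p: float
    pooled_t: float
    pooled_p: float


def _paired_logs(x_values: Sequence, y_values: Sequence) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for x, y in zip(x_values, y_values, strict=True):
        if x is None or y is None:
            continue
        if not (x > 0 and y > 0):
            raise ValueError("log transform requires positive values")
        xs.append(math.log(x))
        ys.append(math.log(y))
    return np.array(xs), np.array(ys)


def log_correlation(
    x_values: Sequence, y_values: Sequence, alpha: float = 0.05
) -> CorrelationResult:
    """Pearson correlation of ln-transformed pairs with a two-tailed t test.

    Pairs with a missing member are dropped; fewer than 3 usable pairs is an
    error.
    """
    x, y = _paired_logs(x_values, y_values)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        n=n, r=float(r), r_squared=float(r) ** 2, p=float(p),
        alpha=alpha, significant=bool(p < alpha),
    )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at two-tailed ``alpha`` with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_star / math.sqrt(n - 2 + t_star**2))


def allometry_dataset(
    records: Iterable[tuple[TaxonRecord, LabyrinthRecord]],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(taxon ids, ln mass, ln length) for the extant regression sample."""
    ids, lx, ly = [], [], []
    for taxon, rec in records:
        if taxon.status != "extant":
            continue
        if taxon.body_mass_g is None or rec.labyrinth_length_mm is None:
            continue
        ids.append(taxon.taxon_id)
        lx.append(math.log(taxon.body_mass_g))
        ly.append(math.log(rec.labyrinth_length_mm))
    return ids, np.array(lx), np.array(ly)


def fit_allometry(
    records: Iterable[tuple[TaxonRecord, LabyrinthRecord]],
) -> RegressionFit:
    """OLS of ln(labyrinth length) on ln(body mass) over extant taxa with
    both values (fossils and the massless dog drop out automatically)."""
    _, x, y = allometry_dataset(records)
    if len(x) < 3:
        raise ValueError("need at least 3 taxa with mass and length")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope), intercept=float(res.intercept),
        n=len(x), r_squared=float(res.rvalue) ** 2,
    )


def predict_mass(labyrinth_length_mm: float, fit: RegressionFit) -> float:
    """Invert the ln-ln fit: mass (g) whose predicted length matches."""
    if labyrinth_length_mm <= 0:
        raise ValueError("length must be positive")
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope fit")
    return math.exp((math.log(labyrinth_length_mm) - fit.intercept) / fit.slope)


def vestibular_contribution(record: LabyrinthRecord) -> Optional[float]:
    cv, lv = record.cochlea.volume_mm3, record.labyrinth_volume_mm3
    if cv is None or lv is None:
        return None
    return volumetric_contributions(cv, lv)[1]


def two_sample_comparison(group1: Sequence[float], group2: Sequence[float]) -> GroupComparison:
    """F-test for variance equality plus Welch and pooled two-tailed t-tests."""
    a, b = np.asarray(group1, float), np.asarray(group2, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v2 > 0:
        f = v1 / v2
        fp = 2.0 * min(
            stats.f.cdf(f, len(a) - 1, len(b) - 1),
            stats.f.sf(f, len(a) - 1, len(b) - 1),
        )
        fp = min(fp, 1.0)
    else:
        f, fp = math.inf, 0.0
    welch = stats.ttest_ind(a, b, equal_var=False)
    pooled = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        n1=len(a), n2=len(b),
        mean1=float(a.mean()), mean2=float(b.mean()),
        var1=float(v1), var2=float(v2),
        f_statistic=float(f), f_p=float(fp),
        welch_t=float(welch.statistic), welch_df=float(welch.df),
        welch_p=float(welch.pvalue),
        pooled_t=float(pooled.statistic), pooled_p=float(pooled.pvalue),
    )


def habitat_contrast(
    records: Iterable[tuple[TaxonRecord, LabyrinthRecord]],
    include_fossil_terrestrial: bool = True,
    include_marsupial: bool = True,
    include_stem_eutherians: bool = False,
) -> tuple[GroupComparison, dict]:
    """Aquatic-vs-terrestrial contrast of vestibular volume contributions.

    Volant taxa (bats; ears specialised for aerial locomotion) are always
    excluded.  The default terrestrial set keeps fossil terrestrial taxa and
    the marsupial outgroup but drops Mesozoic stem eutherians; switches
    expose the alternatives.  Returns the comparison (group 1 = aquatic)
    and a log of exclusions {taxon_id: rule}.
    """
    aquatic, terrestrial, excluded = [], [], {}
    for taxon, rec in records:
        v = vestibular_contribution(rec)
        if v is None:
            excluded[taxon.taxon_id] = "missing volume"
            continue
        if taxon.habitat == "volant":
            excluded[taxon.taxon_id] = "volant taxa excluded"
            continue
        if taxon.habitat == "aquatic":
            aquatic.append(v)
            continue
        if taxon.major_clade == "Eutheria(stem)" and not include_stem_eutherians:
            excluded[taxon.taxon_id] = "Mesozoic stem eutherian"
            continue
        if taxon.major_clade == "Marsupialia" and not include_marsupial:
            excluded[taxon.taxon_id] = "marsupial excluded by configuration"
            continue
        if taxon.status == "fossil" and not include_fossil_terrestrial:
            excluded[taxon.taxon_id] = "fossil excluded by configuration"
            continue
        terrestrial.append(v)
    return two_sample_comparison(aquatic, terrestrial), excluded


# -- correlation screens over the comparative tables ------------------------

_MASS_VARIABLES = {
    "labyrinth_volume": lambda t, r: r.labyrinth_volume_mm3,
    "labyrinth_length": lambda t, r: r.labyrinth_length_mm,
    "cochlea_volume": lambda t, r: r.cochlea.volume_mm3,
    "cochlea_length": lambda t, r: r.cochlea.canal_length_mm,
    "cochlea_aqueduct_length": lambda t, r: r.cochlea.aqueduct_length_mm,
    "cochlea_coiling": lambda t, r: r.cochlea.coil_degrees,
    "cochlea_aspect_ratio": lambda t, r: r.cochlea.aspect_ratio,
    "vestibular_aqueduct_length": lambda t, r: r.vestibule.aqueduct_length_mm,
    "stapedial_ratio": lambda t, r: r.vestibule.stapedial_ratio,
    "anterior_radius": lambda t, r: r.canal("anterior").arc_radius_mm,
    "lateral_radius": lambda t, r: r.canal("lateral").arc_radius_mm,
    "posterior_radius": lambda t, r: r.canal("posterior").arc_radius_mm,
    "anterior_slender_length": lambda t, r: r.canal("anterior").slender_length_mm,
    "lateral_slender_length": lambda t, r: r.canal("lateral").slender_length_mm,
    "posterior_slender_length": lambda t, r: r.canal("posterior").slender_length_mm,
}

_COCHLEA_VARIABLES = {
    "coiling": lambda r: r.cochlea.coil_degrees,
    "volume": lambda r: r.cochlea.volume_mm3,
    "length": lambda r: r.cochlea.canal_length_mm,
    "aspect_ratio": lambda r: r.cochlea.aspect_ratio,
}

_CANAL_VARIABLES = {
    "radius": lambda c: c.arc_radius_mm,
    "slender_length": lambda c: c.slender_length_mm,
    "arc_aspect_ratio": lambda c: c.arc_aspect_ratio,
}


def correlation_tables(
    records: Sequence[tuple[TaxonRecord, LabyrinthRecord]],
    alpha: float = 0.05,
) -> dict:
    """Recompute the three correlation screens.

    ``mass``: each dimension against body mass over extant taxa with mass;
    ``cochlea``: pairwise among cochlear dimensions (all taxa with both);
    ``canals``: per-canal pairwise among radius, slender length, arc aspect.
    """
    mass_rows = {}
    extant = [(t, r) for t, r in records if t.body_mass_g is not None]
    masses = [t.body_mass_g for t, r in extant]
    for name, getter in _MASS_VARIABLES.items():
        mass_rows[name] = log_correlation(
            masses, [getter(t, r) for t, r in extant], alpha
        )
    cochlea_rows = {}
    for na, ga in _COCHLEA_VARIABLES.items():
        for nb, gb in _COCHLEA_VARIABLES.items():
            if na < nb:
                cochlea_rows[(na, nb)] = log_correlation(
                    [ga(r) for _, r in records], [gb(r) for _, r in records], alpha
                )
    canal_rows = {}
    for canal in ("anterior", "lateral", "posterior"):
        for na, ga in _CANAL_VARIABLES.items():
            for nb, gb in _CANAL_VARIABLES.items():
                if na < nb:
                    canal_rows[(canal, na, nb)] = log_correlation(
                        [ga(r.canal(canal)) for _, r in records],
                        [gb(r.canal(canal)) for _, r in records],
                        alpha,
                    )
    return {"mass": mass_rows, "cochlea": cochlea_rows, "canals": canal_rows}
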