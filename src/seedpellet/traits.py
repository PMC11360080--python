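"""Morphological seed trait variables and trait-by-performance tests.

Per-seed measurements (length, width, height, seed area, endosperm area,
coat thickness, perimeter; mm and mm²) are reduced to per-species means, and
three derived variables are computed:

* endosperm:seed area ratio (E:Sarea) — endosperm area / seed area, in
  [0, 1]; a proxy for the relative nutrient reserve;
* circularity — 4·pi·area / perimeter², 1 for a perfect circle (clamped to
  [0, 1] against numeric overshoot);
* shape variance — variance of the three axis lengths after dividing each
  by length, i.e. of (1, w/l, h/l); 0 for a sphere, larger for elongated or
  flattened seeds. Height is often unavailable from plan-view X-ray images;
  the default fallback sets h = w and flags it.

Per-species trait means are then related to a categorical performance
ranking (amenability or emergence speed) with a one-way linear model per
trait: an overall F-test plus Tukey-adjusted pairwise category contrasts in
trait units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import TrialDataError

__all__ = [
    "es_area_ratio",
    "shape_variance",
    "circularity",
    "species_trait_means",
    "TraitCategoryTest",
    "trait_by_category_test",
]

SEED_COLUMNS = [
    "species",
    "seed_id",
    "length_mm",
    "width_mm",
    "height_mm",
    "seed_area_mm2",
    "endosperm_area_mm2",
    "coat_thickness_mm",
    "perimeter_mm",
]


def es_area_ratio(endosperm_area: float, seed_area: float) -> float:
    """Endosperm area as a fraction of total seed area."""
    if endosperm_area <= 0 or seed_area <= 0:
        raise TrialDataError("areas must be positive")
    if endosperm_area > seed_area:
        raise TrialDataError("endosperm area exceeds seed area")
    return endosperm_area / seed_area


def shape_variance(length: float, width: float, height: float | None = None) -> float:
    """Seed shape variance: population variance of (1, w/l, h/l).

    Dimensionless, unit-invariant, and zero exactly for a sphere. With
    ``height`` missing the width is substituted (plan-view images carry no
    depth); callers wanting the flag should check ``height is None``.
    """
    if length <= 0 or width <= 0 or (height is not None and height <= 0):
        raise TrialDataError("dimensions must be positive")
    if height is None:
        height = width
    dims = np.array([1.0, width / length, height / length])
    return float(np.mean((dims - dims.mean()) ** 2))


def circularity(seed_area: float, perimeter: float) -> float:
    """Isoperimetric circularity 4·pi·A/P², clamped to [0, 1]."""
    if seed_area <= 0 or perimeter <= 0:
        raise TrialDataError("area and perimeter must be positive")
    return min(1.0, 4.0 * math.pi * seed_area / perimeter**2)


def species_trait_means(seeds: pd.DataFrame) -> pd.DataFrame:
    """Per-species trait means from per-seed measurements.

    Expects the ``SEED_COLUMNS`` schema (``height_mm`` and ``perimeter_mm``
    may be empty). Adds the derived per-seed variables before averaging and
    flags species where the h = w fallback was used.
    """
    missing = [c for c in SEED_COLUMNS if c not in seeds.columns and c not in ("height_mm", "perimeter_mm")]
    if missing:
        raise TrialDataError(f"seed measurement table missing columns: {missing}")
    df = seeds.copy()
    if "height_mm" not in df.columns:
        df["height_mm"] = np.nan
    if "perimeter_mm" not in df.columns:
        df["perimeter_mm"] = np.nan
    bad = df.index[(df["width_mm"] > df["length_mm"])]
    if len(bad):
        raise TrialDataError(f"width exceeds length for seed rows {list(bad[:5])} (axis ordering)")
    df["es_area_ratio"] = [
        es_area_ratio(e, s) for e, s in zip(df["endosperm_area_mm2"], df["seed_area_mm2"])
    ]
    df["shape_variance"] = [
        shape_variance(l, w, None if (h is None or (isinstance(h, float) and math.isnan(h))) else h)
        for l, w, h in zip(df["length_mm"], df["width_mm"], df["height_mm"])
    ]
    df["circularity"] = [
        (np.nan if (isinstance(p, float) and math.isnan(p)) else circularity(a, p))
        for a, p in zip(df["seed_area_mm2"], df["perimeter_mm"])
    ]
    traits = [
        "length_mm",
        "width_mm",
        "seed_area_mm2",
        "endosperm_area_mm2",
        "coat_thickness_mm",
        "es_area_ratio",
        "shape_variance",
        "circularity",
    ]
    out = df.groupby("species")[traits].mean().reset_index()
    out["n_seeds"] = df.groupby("species").size().values
    out["height_imputed"] = df.groupby("species")["height_mm"].apply(lambda s: bool(s.isna().any())).values
    return out


@dataclass(frozen=True)
class TraitCategoryTest:
    """One trait's one-way model against a performance ranking."""

    trait: str
    n_species: int
    categories: tuple[str, ...]
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # Tukey-adjusted category contrasts, trait units
    dropped_categories: tuple[str, ...] = ()


def trait_by_category_test(
    species_traits: pd.DataFrame,
    labels: pd.Series | dict,
    trait: str,
    min_per_category: int = 2,
) -> TraitCategoryTest:
    """One-way linear model of a species-mean trait on a categorical ranking.

    Categories with fewer than ``min_per_category`` species are dropped with
    a warning. Returns the overall F-test and Tukey-adjusted pairwise
    differences (trait units).
    """
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if trait not in species_traits.columns:
        raise TrialDataError(f"unknown trait {trait!r}")
    lab = pd.Series(labels)
    df = species_traits[["species", trait]].copy()
    df["category"] = df["species"].map(lab)
    df = df.dropna(subset=["category", trait])
    sizes = df.groupby("category").size()
    small = tuple(sorted(sizes.index[sizes < min_per_category]))
    if small:
        warnings.warn(f"dropping categories with < {min_per_category} species: {small}")
        df = df[~df["category"].isin(small)]
    if df["category"].nunique() < 2:
        raise TrialDataError("need >= 2 categories with >= 2 species each")
    fit = smf.ols(f"Q('{trait}') ~ C(category)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    f = float(anova.loc["C(category)", "F"])
    p = float(anova.loc["C(category)", "PR(>F)"])
    tukey = pairwise_tukeyhsd(df[trait].to_numpy(), df["category"].to_numpy())
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    return TraitCategoryTest(
        trait=trait,
        n_species=len(df),
        categories=tuple(sorted(df["category"].unique())),
        f_statistic=f,
        p_value=p,
        pairwise=pairwise,
        dropped_categories=small,
    )
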