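"""Per-species treatment comparisons.

Total emergence and post-emergence survival are compared between treatment
arms with Pearson's chi-squared test of independence on the 2x2 table of
(outcome, no outcome) x (bare, pellet). The Yates continuity correction is
applied by default — matching the default behaviour of R's ``chisq.test`` on
2x2 tables, which is the convention the published classification counts
follow — and can be disabled with ``correction=False``.

Time to emergence is compared with a linear mixed model on the emerged
replicates' emergence days (species, treatment and their interaction as
fixed effects; a lot-level random intercept), yielding a global treatment
test and per-species pairwise treatment contrasts. Lot-level speed metrics
(ERI, TSE) get a global mixed-model treatment test with species as a random
intercept.

No multiple-testing adjustment is applied to the per-species tests; every
species is tested at the same alpha (0.05 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import TrialDataError

__all__ = [
    "Direction",
    "ComparisonResult",
    "SpeciesDropped",
    "DegenerateTableWarning",
    "pearson_chi2_2x2",
    "compare_emergence",
    "compare_survival",
    "TimeModelResult",
    "time_to_emergence_model",
    "lot_level_treatment_test",
]

ALPHA_DEFAULT = 0.05


class Direction(str, Enum):
    """Direction of the pellet arm relative to the bare arm."""

    PELLET_HIGHER = "pellet_higher"
    PELLET_LOWER = "pellet_lower"
    NO_DIFFERENCE = "no_difference"


class SpeciesDropped(TrialDataError):
    """The species cannot be tested for this response (e.g. no emergence)."""


class DegenerateTableWarning(UserWarning):
    """A 2x2 table with a zero margin: the chi-squared test is undefined."""


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one per-species treatment comparison."""

    species: str
    response: str
    direction: Direction
    statistic: float
    p_value: float
    n_bare: int
    n_pellet: int
    method: str
    note: str = ""


def pearson_chi2_2x2(
    a: int, b: int, c: int, d: int, correction: bool = True
) -> tuple[float, float]:
    """Pearson chi-squared statistic and p-value for the 2x2 table
    ``[[a, b], [c, d]]`` (rows = treatment arms, columns = outcome yes/no).

    Closed form ``X2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with
    ``N = a+b+c+d``; with ``correction`` (default), ``|ad - bc|`` is shrunk
    by ``N/2`` (floored at zero) — the Yates continuity correction. A table
    with a zero margin is degenerate: the test carries no information, and
    ``(0.0, 1.0)`` is returned with a :class:`DegenerateTableWarning`.
    """
    if min(a, b, c, d) < 0:
        raise TrialDataError("cell counts must be non-negative")
    if a + b < 1 or c + d < 1:
        raise TrialDataError("both row sums must be >= 1")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        warnings.warn("degenerate 2x2 table (zero margin); returning p = 1", DegenerateTableWarning)
        return 0.0, 1.0
    num = abs(a * d - b * c)
    if correction:
        num = max(0.0, num - n / 2)
    x2 = n * num * num / denom
    return x2, float(sps.chi2.sf(x2, df=1))


def _direction(bare_rate: float, pellet_rate: float, p: float, alpha: float) -> Direction:
    if p >= alpha or pellet_rate == bare_rate:
        return Direction.NO_DIFFERENCE
    return Direction.PELLET_HIGHER if pellet_rate > bare_rate else Direction.PELLET_LOWER


def compare_emergence(
    species: str,
    bare_emerged: int,
    bare_sown: int,
    pellet_emerged: int,
    pellet_sown: int,
    alpha: float = ALPHA_DEFAULT,
    correction: bool = True,
) -> ComparisonResult:
    """Chi-squared comparison of total emergence between arms.

    A species with zero emergence in both arms is dropped from the analysis
    (raises :class:`SpeciesDropped`), mirroring the removal of
    zero-emergence species from the published table.
    """
    if bare_emerged == 0 and pellet_emerged == 0:
        raise SpeciesDropped(f"{species}: no emergence recorded in either arm")
    x2, p = pearson_chi2_2x2(
        bare_emerged,
        bare_sown - bare_emerged,
        pellet_emerged,
        pellet_sown - pellet_emerged,
        correction=correction,
    )
    return ComparisonResult(
        species=species,
        response="emergence",
        direction=_direction(bare_emerged / bare_sown, pellet_emerged / pellet_sown, p, alpha),
        statistic=x2,
        p_value=p,
        n_bare=bare_sown,
        n_pellet=pellet_sown,
        method="chi2_yates" if correction else "chi2",
    )


def compare_survival(
    species: str,
    bare_survived: int,
    bare_emerged: int,
    pellet_survived: int,
    pellet_emerged: int,
    alpha: float = ALPHA_DEFAULT,
    correction: bool = True,
) -> ComparisonResult:
    """Chi-squared comparison of survival between arms.

    Denominators are the *emerged* replicate counts. A species with zero
    emergence in either arm has no defined survival contrast and is excluded
    (raises :class:`SpeciesDropped`).
    """
    if bare_emerged == 0 or pellet_emerged == 0:
        raise SpeciesDropped(f"{species}: survival undefined (an arm has no emergence)")
    x2, p = pearson_chi2_2x2(
        bare_survived,
        bare_emerged - bare_survived,
        pellet_survived,
        pellet_emerged - pellet_survived,
        correction=correction,
    )
    return ComparisonResult(
        species=species,
        response="survival",
        direction=_direction(
            bare_survived / bare_emerged, pellet_survived / pellet_emerged, p, alpha
        ),
        statistic=x2,
        p_value=p,
        n_bare=bare_emerged,
        n_pellet=pellet_emerged,
        method="chi2_yates" if correction else "chi2",
    )


@dataclass(frozen=True)
class TimeModelResult:
    """Global treatment test and per-species contrasts for time to emergence."""

    global_p: float
    global_statistic: float
    contrasts: list[ComparisonResult]
    method: str
    dropped_species: tuple[str, ...] = ()


def _emerged_frame(records) -> pd.DataFrame:
    rows = [
        {
            "species": r.species,
            "provenance": -1 if r.provenance is None else r.provenance,
            "treatment": r.treatment,
            "day": float(r.emergence_day),
        }
        for r in records
        if r.emerged
    ]
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["lot"] = frame["species"] + ":" + frame["provenance"].astype(str)
    return frame


def _welch_contrasts(frame: pd.DataFrame, alpha: float, note: str) -> list[ComparisonResult]:
    out = []
    for sp, sub in frame.groupby("species", sort=True):
        bare = sub.loc[sub.treatment == "bare", "day"].to_numpy()
        pellet = sub.loc[sub.treatment == "pellet", "day"].to_numpy()
        t, p = sps.ttest_ind(pellet, bare, equal_var=False)
        if np.isnan(p):  # zero variance in both arms
            t, p = 0.0, 1.0
        est = pellet.mean() - bare.mean()
        if p < alpha and est != 0:
            direction = Direction.PELLET_HIGHER if est > 0 else Direction.PELLET_LOWER
        else:
            direction = Direction.NO_DIFFERENCE
        out.append(
            ComparisonResult(
                species=sp,
                response="mean_time",
                direction=direction,
                statistic=float(t),
                p_value=float(p),
                n_bare=len(bare),
                n_pellet=len(pellet),
                method="welch",
                note=note,
            )
        )
    return out


def time_to_emergence_model(
    records,
    alpha: float = ALPHA_DEFAULT,
    min_emerged: int = 4,
) -> TimeModelResult:
    """Mixed-model analysis of emergence day over emerged replicates.

    Species with fewer than ``min_emerged`` emerged replicates in either arm
    are dropped. The global treatment p-value comes from an additive model
    (day ~ species + treatment, lot random intercept); per-species pellet
    minus bare contrasts come from the interaction model and are mapped to a
    direction at ``alpha`` (PELLET_HIGHER = later emergence from pellets).
    If the mixed-model fit fails, per-species Welch t-tests are used and the
    fallback is recorded in the result's ``method``/``note`` fields.
    """
    import statsmodels.formula.api as smf

    frame = _emerged_frame(records)
    if frame.empty:
        raise TrialDataError("no emerged replicates to model")
    counts = frame.groupby(["species", "treatment"]).size().unstack(fill_value=0)
    for arm in ("bare", "pellet"):
        if arm not in counts.columns:
            counts[arm] = 0
    keep = counts.index[(counts["bare"] >= min_emerged) & (counts["pellet"] >= min_emerged)]
    dropped = tuple(sorted(set(counts.index) - set(keep)))
    frame = frame[frame.species.isin(keep)]
    if frame.empty or frame.species.nunique() < 1:
        raise TrialDataError("no species with enough emerged replicates in both arms")

    single_species = frame.species.nunique() == 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if single_species:
                additive = smf.mixedlm("day ~ C(treatment)", frame, groups=frame["lot"]).fit(reml=False)
                inter = additive
            else:
                additive = smf.mixedlm(
                    "day ~ C(species) + C(treatment)", frame, groups=frame["lot"]
                ).fit(reml=False)
                inter = smf.mixedlm(
                    "day ~ C(species) * C(treatment)", frame, groups=frame["lot"]
                ).fit(reml=False)
        treat_name = "C(treatment)[T.pellet]"
        global_z = additive.params[treat_name] / additive.bse[treat_name]
        global_p = 2 * float(sps.norm.sf(abs(global_z)))
        if not np.isfinite(global_p):
            raise ValueError("non-finite global test")

        params = inter.params
        cov = inter.cov_params()
        contrasts: list[ComparisonResult] = []
        species_sorted = sorted(frame.species.unique())
        n_by = frame.groupby(["species", "treatment"]).size()
        for sp in species_sorted:
            vec = pd.Series(0.0, index=params.index)
            vec[treat_name] = 1.0
            inter_name = f"C(species)[T.{sp}]:C(treatment)[T.pellet]"
            if inter_name in vec.index:
                vec[inter_name] = 1.0
            est = float(vec @ params)
            se = float(np.sqrt(vec @ cov @ vec))
            if not np.isfinite(se) or se == 0:
                raise ValueError("singular contrast covariance")
            z = est / se
            p = 2 * float(sps.norm.sf(abs(z)))
            if p < alpha and est != 0:
                direction = Direction.PELLET_HIGHER if est > 0 else Direction.PELLET_LOWER
            else:
                direction = Direction.NO_DIFFERENCE
            contrasts.append(
                ComparisonResult(
                    species=sp,
                    response="mean_time",
                    direction=direction,
                    statistic=z,
                    p_value=p,
                    n_bare=int(n_by.get((sp, "bare"), 0)),
                    n_pellet=int(n_by.get((sp, "pellet"), 0)),
                    method="lmm",
                )
            )
        return TimeModelResult(
            global_p=global_p,
            global_statistic=float(global_z),
            contrasts=contrasts,
            method="lmm",
            dropped_species=dropped,
        )
    except (ValueError, np.linalg.LinAlgError, KeyError) as exc:
        note = f"mixed-model fit failed ({exc}); Welch fallback"
        contrasts = _welch_contrasts(frame, alpha, note)
        worst = min(contrasts, key=lambda c: c.p_value)
        return TimeModelResult(
            global_p=worst.p_value if single_species else float("nan"),
            global_statistic=worst.statistic if single_species else float("nan"),
            contrasts=contrasts,
            method="welch_fallback",
            dropped_species=dropped,
        )


def lot_level_treatment_test(summaries, metric: str) -> tuple[float, float]:
    """Global treatment test for a lot-level speed metric (``eri`` or ``tse``).

    Fits a mixed model metric ~ treatment with a species random intercept on
    the per-arm summaries (arms with no emergence contribute nothing, the
    metric being undefined there). Returns (treatment effect estimate,
    p-value).
    """
    import statsmodels.formula.api as smf

    if metric not in {"eri", "tse"}:
        raise TrialDataError(f"metric must be 'eri' or 'tse', got {metric!r}")
    attr = "eri" if metric == "eri" else "tse_days"
    rows = [
        {"species": s.species, "treatment": s.treatment, "value": float(getattr(s, attr))}
        for s in summaries
        if getattr(s, attr) is not None
    ]
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise TrialDataError("no defined metric values")
    complete = frame.groupby("species")["treatment"].nunique()
    if (complete == 2).sum() < 2:
        raise TrialDataError("need >= 2 species with the metric defined in both arms")
    if float(frame.groupby("treatment")["value"].mean().diff().dropna().abs().iloc[-1]) == 0 and (
        frame["value"].var() == 0
    ):
        return 0.0, 1.0  # all values identical; nothing to estimate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("value ~ C(treatment)", frame, groups=frame["species"]).fit(reml=False)
    name = "C(treatment)[T.pellet]"
    est = float(fit.params[name])
    se = float(fit.bse[name])
    if not np.isfinite(se) or se == 0:
        return est, 1.0
    p = 2 * float(sps.norm.sf(abs(est / se)))
    return est, p
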