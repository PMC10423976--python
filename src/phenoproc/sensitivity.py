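"""Temperature and CO2 sensitivity of transition dates.

Two complementary analyses of a warming-enclosure experiment:

* A linear mixed-effects model per plant functional type and season,
  ``DOY ~ warming x CO2`` with a random intercept per year, with backward
  elimination of the interaction and then the CO2 main effect when
  non-significant.  The temperature coefficient is the sensitivity in days
  per degree of measured warming differential.
* Per-year ordinary regressions of DOY on the warming differential, giving
  one sensitivity per year.

Season-length extension per degree is the autumn sensitivity minus the
spring sensitivity (a spring advance counts positively toward extension).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datatypes import EnclosureMetadata, TransitionObservation

__all__ = [
    "SensitivityRecord",
    "fit_lme",
    "fit_sensitivity_lme",
    "per_year_sensitivity",
    "season_extension",
    "observations_frame",
]

#: Wald significance level used during backward elimination.
ELIMINATION_ALPHA = 0.05


@dataclass
class SensitivityRecord:
    """Fixed-effect estimates from the final mixed model."""

    pft: str
    season: str
    intercept: float
    slope: float  # days per °C
    intercept_se: float
    slope_se: float
    co2_effect: Optional[float] = None  # days (elevated vs ambient)
    co2_se: Optional[float] = None
    interaction: Optional[float] = None  # days per °C
    interaction_se: Optional[float] = None
    p_values: dict = field(default_factory=dict)
    year_variance: float = np.nan
    n_obs: int = 0
    formula: str = ""

    def to_dict(self) -> dict:
        return {
            "pft": self.pft,
            "season": self.season,
            "intercept": self.intercept,
            "slope": self.slope,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "co2_effect": self.co2_effect,
            "co2_se": self.co2_se,
            "interaction": self.interaction,
            "interaction_se": self.interaction_se,
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "year_variance": float(self.year_variance),
            "n_obs": self.n_obs,
            "formula": self.formula,
        }


def observations_frame(
    observations: Sequence[TransitionObservation],
    metadata: Sequence[EnclosureMetadata],
    season: Optional[str] = None,
    pft: Optional[str] = None,
) -> pd.DataFrame:
    """Tidy frame joining transitions with enclosure warming/CO2 treatment."""
    meta = {m.enclosure_id: m for m in metadata}
    rows = []
    for o in observations:
        if season and o.season != season:
            continue
        if pft and o.pft != pft:
            continue
        m = meta.get(o.enclosure_id)
        if m is None:
            raise ValueError(f"no metadata for enclosure {o.enclosure_id}")
        rows.append(
            {
                "enclosure": o.enclosure_id,
                "year": o.year,
                "pft": o.pft,
                "season": o.season,
                "doy": o.doy,
                "dt": m.measured_warming,
                "co2": 1.0 if m.elevated_co2 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _formula(include_co2: bool, include_interaction: bool) -> str:
    terms = ["dt"]
    if include_co2:
        terms.append("co2")
    if include_interaction:
        terms.append("dt:co2")
    return "doy ~ " + " + ".join(terms)


def _fit_mixed(df: pd.DataFrame, formula: str, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits (zero year variance) are fine
        model = smf.mixedlm(formula, df, groups=df["year"])
        # bfgs first; fall back to powell on degenerate (boundary) fits
        try:
            return model.fit(reml=reml, method="bfgs")
        except np.linalg.LinAlgError:
            return model.fit(reml=reml, method="powell")


def fit_lme(
    observations: Sequence[TransitionObservation],
    metadata: Sequence[EnclosureMetadata],
    season: str,
    pft: str,
    include_co2: bool = True,
    include_interaction: bool = True,
    reml: bool = True,
) -> SensitivityRecord:
    """Fit one mixed model of a fixed structure (no elimination)."""
    df = observations_frame(observations, metadata, season, pft)
    _validate_design(df)
    formula = _formula(include_co2, include_interaction)
    res = _fit_mixed(df, formula, reml)
    return _record_from(res, df, formula, season, pft)


def fit_sensitivity_lme(
    observations: Sequence[TransitionObservation],
    metadata: Sequence[EnclosureMetadata],
    season: str,
    pft: str,
    alpha: float = ELIMINATION_ALPHA,
) -> SensitivityRecord:
    """Mixed model with backward elimination of the CO2 terms.

    The full model ``doy ~ dt * co2`` (random intercept per year) is fitted
    by maximum likelihood; the interaction and then the CO2 main effect are
    dropped when their Wald p-value is >= ``alpha``.  The final structure is
    refitted by REML.
    """
    df = observations_frame(observations, metadata, season, pft)
    _validate_design(df)

    include_co2, include_interaction = True, True
    if df["co2"].nunique() < 2:
        include_co2 = include_interaction = False
    if include_interaction:
        res = _fit_mixed(df, _formula(True, True), reml=False)
        if res.pvalues.get("dt:co2", 1.0) >= alpha:
            include_interaction = False
    if include_co2 and not include_interaction:
        res = _fit_mixed(df, _formula(True, False), reml=False)
        if res.pvalues.get("co2", 1.0) >= alpha:
            include_co2 = False

    formula = _formula(include_co2, include_interaction)
    final = _fit_mixed(df, formula, reml=True)
    return _record_from(final, df, formula, season, pft)


def _validate_design(df: pd.DataFrame) -> None:
    if df.empty:
        raise ValueError("no observations for the requested season/pft")
    if df["year"].nunique() < 2:
        raise ValueError("need at least two years for a year random effect")
    if df["dt"].nunique() < 2:
        raise ValueError("need at least two distinct warming levels (rank-deficient design)")


def _record_from(res, df, formula, season, pft) -> SensitivityRecord:
    params = res.params
    bse = res.bse
    pvals = {k: float(v) for k, v in res.pvalues.items() if k != "Group Var"}
    return SensitivityRecord(
        pft=pft,
        season=season,
        intercept=float(params["Intercept"]),
        slope=float(params["dt"]),
        intercept_se=float(bse["Intercept"]),
        slope_se=float(bse["dt"]),
        co2_effect=float(params["co2"]) if "co2" in params else None,
        co2_se=float(bse["co2"]) if "co2" in bse else None,
        interaction=float(params["dt:co2"]) if "dt:co2" in params else None,
        interaction_se=float(bse["dt:co2"]) if "dt:co2" in bse else None,
        p_values=pvals,
        year_variance=float(res.cov_re.iloc[0, 0]) if res.cov_re.size else np.nan,
        n_obs=len(df),
        formula=formula,
    )


def per_year_sensitivity(
    observations: Sequence[TransitionObservation],
    metadata: Sequence[EnclosureMetadata],
    season: str,
    pft: str,
    min_points: int = 3,
) -> dict[int, float]:
    """Ordinary regression slope of DOY on warming, separately per year.

    Years with fewer than ``min_points`` enclosures are omitted (flagged by
    absence from the result).
    """
    df = observations_frame(observations, metadata, season, pft)
    slopes: dict[int, float] = {}
    for year, grp in df.groupby("year"):
        if len(grp) < min_points:
            continue
        slope = np.polyfit(grp["dt"], grp["doy"], 1)[0]
        slopes[int(year)] = float(slope)
    return slopes


def season_extension(spring: SensitivityRecord, autumn: SensitivityRecord) -> float:
    """Growing-season extension in days per °C: autumn slope minus spring
    slope (spring advance counts positively)."""
    if spring.pft != autumn.pft:
        raise ValueError(
            f"records are for different functional types: {spring.pft} vs {autumn.pft}"
        )
    if spring.season != "spring" or autumn.season != "autumn":
        raise ValueError("expected one spring and one autumn record")
    return float(autumn.slope - spring.slope)
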