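"""Country-level education quality (EQ) from PISA-style cycle scores.

PISA reports country mean scores on a scale with mean 500 and SD 100 across
assessment cycles (2003-2022, one every ~3 years).  The EQ score used
throughout this package is the across-cycle average of a country's scores,
standardised to a z-score and shifted by +2 so that values are positive
(a standard normal puts 95.4% of its mass inside +/-2 SD, so the shift
removes essentially all negative values)::

    EQ = (mean_pisa - 500) / 100 + 2

Within a cycle the three subject domains (reading, mathematics, science) are
averaged unweighted before cycles are averaged; countries missing cycles
contribute only the cycles they have.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PISA_MEAN = 500.0
PISA_SD = 100.0
EQ_SHIFT = 2.0

__all__ = [
    "PISA_MEAN",
    "PISA_SD",
    "EQ_SHIFT",
    "aggregate_country_scores",
    "standardize_to_eq",
    "eq_to_mean_pisa",
    "build_eq_table",
    "test_temporal_stability",
    "StabilityReport",
]


def _validate_cycle_scores(cycle_scores: pd.DataFrame) -> pd.DataFrame:
    required = {"country", "year", "score"}
    missing = required - set(cycle_scores.columns)
    if missing:
        raise ValueError(f"cycle score table missing columns: {sorted(missing)}")
    if len(cycle_scores) == 0:
        raise ValueError("cycle score table is empty")
    if cycle_scores["score"].isna().any() or not np.isfinite(
        cycle_scores["score"].to_numpy(float)
    ).all():
        raise ValueError("non-finite PISA scores in cycle table")
    return cycle_scores


def aggregate_country_scores(cycle_scores: pd.DataFrame) -> pd.Series:
    """Average cycle scores to one mean PISA score per country.

    Parameters
    ----------
    cycle_scores
        Long table with columns ``country``, ``year``, ``score`` and
        optionally ``domain``.  If ``domain`` is present, domain scores are
        first averaged (unweighted) within each (country, year) cell.

    Returns
    -------
    pandas.Series
        ``mean_pisa`` indexed by country: the unweighted mean over that
        country's available cycles.
    """
    cycle_scores = _validate_cycle_scores(cycle_scores)
    per_cycle = cycle_scores.groupby(["country", "year"], sort=True)["score"].mean()
    out = per_cycle.groupby("country").mean()
    out.name = "mean_pisa"
    return out


def standardize_to_eq(mean_pisa):
    """Map a mean PISA score to EQ: ``(score - 500)/100 + 2``.

    Accepts scalars or arrays; rejects non-finite input.
    """
    arr = np.asarray(mean_pisa, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite PISA score")
    eq = (arr - PISA_MEAN) / PISA_SD + EQ_SHIFT
    if np.isscalar(mean_pisa) or arr.ndim == 0:
        return float(eq)
    return eq


def eq_to_mean_pisa(eq):
    """Inverse of :func:`standardize_to_eq` (exact round trip)."""
    arr = np.asarray(eq, dtype=float)
    out = (arr - EQ_SHIFT) * PISA_SD + PISA_MEAN
    if np.isscalar(eq) or arr.ndim == 0:
        return float(out)
    return out


def build_eq_table(cycle_scores: pd.DataFrame) -> pd.DataFrame:
    """Construct the per-country EQ table from a long cycle-score table.

    Returns a DataFrame with columns ``country``, ``cycles_used`` (sorted
    list of years), ``mean_pisa`` and ``eq``.
    """
    mean_pisa = aggregate_country_scores(cycle_scores)
    cycles = (
        cycle_scores.groupby("country")["year"]
        .apply(lambda y: sorted(set(int(v) for v in y)))
        .rename("cycles_used")
    )
    table = pd.DataFrame(
        {
            "country": mean_pisa.index,
            "cycles_used": cycles.loc[mean_pisa.index].to_numpy(),
            "mean_pisa": mean_pisa.to_numpy(),
        }
    )
    table["eq"] = standardize_to_eq(table["mean_pisa"].to_numpy())
    return table.reset_index(drop=True)


@dataclass(frozen=True)
class StabilityReport:
    """Temporal stability of country PISA scores.

    The year x country interaction from a mixed linear model
    (``score ~ year * country`` with a random intercept per country) tests
    whether countries' scores drift at different rates over cycles.  The
    scalar ``interaction_coefficient`` is the largest-magnitude country
    deviation slope (score points per year); ``interaction_p`` is the joint
    Wald p-value over all interaction terms.  Verdict is "stable" when the
    interaction is not significant at alpha = 0.05.
    """

    interaction_coefficient: float
    interaction_p: float
    random_effect_variance: float
    verdict: str


def test_temporal_stability(cycle_scores: pd.DataFrame, alpha: float = 0.05) -> StabilityReport:
    """Fit the mixed model and report whether EQ is temporally stable.

    Requires at least two countries with at least two cycles each; a single
    country makes the interaction design singular.
    """
    cycle_scores = _validate_cycle_scores(cycle_scores)
    per_cycle = (
        cycle_scores.groupby(["country", "year"], sort=True)["score"].mean().reset_index()
    )
    countries = per_cycle["country"].unique()
    if len(countries) < 2:
        raise ValueError("temporal stability needs >= 2 countries (singular design)")
    n_cycles = per_cycle.groupby("country")["year"].nunique()
    if (n_cycles < 2).any():
        bad = n_cycles[n_cycles < 2].index.tolist()
        raise ValueError(f"countries with < 2 cycles: {bad}")

    # Degenerate zero-variance input: every score identical within rounding.
    if float(per_cycle["score"].std(ddof=0)) < 1e-12:
        return StabilityReport(0.0, 1.0, 0.0, "stable")

    import statsmodels.formula.api as smf

    df = per_cycle.copy()
    df["year_c"] = df["year"] - df["year"].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "score ~ year_c * C(country)", data=df, groups=df["country"]
        )
        fit = model.fit(reml=True, method="lbfgs")
    names = list(fit.fe_params.index)
    inter_names = [nm for nm in names if nm.startswith("year_c:")]
    if not inter_names:
        raise RuntimeError("interaction terms missing from design")
    coefs = fit.fe_params.loc[inter_names].to_numpy()
    # Joint Wald test over all year x country deviation slopes.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wald = fit.wald_test(
            ", ".join(f"{nm} = 0" for nm in inter_names), scalar=True
        )
    p = float(np.asarray(wald.pvalue))
    coef = float(coefs[np.argmax(np.abs(coefs))]) if len(coefs) else 0.0
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    verdict = "stable" if p >= alpha else "unstable"
    return StabilityReport(coef, p, re_var, verdict)
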