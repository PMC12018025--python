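"""Robustness analyses for the whole-brain EQ vs YoE comparison.

Four checks mirror the sensitivity battery of the main analysis:

1. interaction contrast — EQ against the product EQ x YoE;
2. covariate augmentation — rerun with country-level (Gini, GDP) or
   individual (SES) socioeconomic covariates added to both models;
3. leave-one-country-out — drop each country's subjects and re-estimate the
   contrast, summarising how often sign and significance survive;
4. image-quality screening and correction — correlate SNR/tSNR with the
   exposures (|r| < 0.1 is negligible), residualise the whole-brain measure
   on the quality metrics with a linear model, and rerun.

A contrast is judged "robust" when the adjusted analysis keeps the baseline
delta-mean sign and significance status, "attenuated" when a significant
baseline loses significance (same sign), and "reversed" when the sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regional import RegressionSpec
from .wholebrain import (
    ComparisonResult,
    GM_COVARIATES,
    FC_COVARIATES,
    ITERATIONS_DEFAULT,
    K_DEFAULT,
    REPS_DEFAULT,
    _wholebrain_outcomes,
    compare_predictors,
    cv_ridge_r2,
)

__all__ = [
    "QualityMetrics",
    "SensitivityReport",
    "interaction_contrast",
    "covariate_augmented_rerun",
    "leave_one_country_out",
    "quality_screen_and_correct",
    "residualize",
    "NEGLIGIBLE_BAND",
]

NEGLIGIBLE_BAND = (-0.1, 0.1)
ALPHA = 0.05


@dataclass
class QualityMetrics:
    """Per-subject no-reference image quality metrics."""

    snr_t1: np.ndarray | None = None
    snr_fmri: np.ndarray | None = None
    tsnr: np.ndarray | None = None


@dataclass
class SensitivityReport:
    """Baseline vs adjusted contrast and the deterministic verdict."""

    contrast: str
    baseline: ComparisonResult
    adjusted: ComparisonResult
    screening: dict = field(default_factory=dict)
    verdict: str = ""

    def __post_init__(self):
        if not self.verdict:
            self.verdict = _verdict(self.baseline, self.adjusted)


def _verdict(base: ComparisonResult, adj: ComparisonResult, alpha: float = ALPHA) -> str:
    if np.sign(adj.delta_mean) != np.sign(base.delta_mean) and adj.delta_mean != 0:
        return "reversed"
    if base.p < alpha and adj.p >= alpha:
        return "attenuated"
    return "robust"


def _group_outcome(cohort, group: str, modality: str):
    parts = cohort.participants
    sel = (parts["group"] == group).to_numpy()
    if not sel.any():
        raise ValueError(f"group absent from cohort: {group}")
    sub = parts.loc[sel].reset_index(drop=True)
    gm_mean, eff = _wholebrain_outcomes(cohort)
    y = gm_mean[sel] if modality == "gm" else eff[sel]
    covs = GM_COVARIATES if modality == "gm" else FC_COVARIATES
    return y, sub, covs


def _contrast(
    y, participants, pred_a, pred_b, covariates,
    k=K_DEFAULT, reps=REPS_DEFAULT, iterations=ITERATIONS_DEFAULT, seed=0,
) -> ComparisonResult:
    cva = cv_ridge_r2(
        y, participants, RegressionSpec(predictor=pred_a, covariates=tuple(covariates)),
        k=k, reps=reps, seed=seed,
    )
    cvb = cv_ridge_r2(
        y, participants, RegressionSpec(predictor=pred_b, covariates=tuple(covariates)),
        k=k, reps=reps, seed=seed,
    )
    return compare_predictors(cva, cvb, iterations=iterations, seed=seed)


def interaction_contrast(
    cohort, group: str = "HC", modality: str = "gm",
    k=K_DEFAULT, reps=REPS_DEFAULT, iterations=ITERATIONS_DEFAULT, seed: int = 0,
) -> ComparisonResult:
    """EQ vs the EQ x YoE product at the whole-brain level."""
    y, sub, covs = _group_outcome(cohort, group, modality)
    return _contrast(y, sub, "eq", "eqxyoe", covs, k, reps, iterations, seed)


def covariate_augmented_rerun(
    cohort, extra_covariates: tuple[str, ...],
    group: str = "HC", modality: str = "gm",
    k=K_DEFAULT, reps=REPS_DEFAULT, iterations=ITERATIONS_DEFAULT, seed: int = 0,
) -> SensitivityReport:
    """Rerun EQ vs YoE with socioeconomic covariates added to both models."""
    y, sub, covs = _group_outcome(cohort, group, modality)
    missing = [c for c in extra_covariates if c not in sub.columns or sub[c].isna().all()]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    base = _contrast(y, sub, "eq", "yoe", covs, k, reps, iterations, seed)
    adj = _contrast(
        y, sub, "eq", "yoe", tuple(covs) + tuple(extra_covariates),
        k, reps, iterations, seed,
    )
    return SensitivityReport(
        contrast=f"eq_vs_yoe+{'+'.join(extra_covariates)}", baseline=base, adjusted=adj
    )


def leave_one_country_out(
    cohort, group: str = "HC", modality: str = "gm",
    k=K_DEFAULT, reps=REPS_DEFAULT, iterations=ITERATIONS_DEFAULT, seed: int = 0,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Drop each country in turn and re-estimate the whole-brain contrast.

    Countries whose removal leaves fewer than 3k subjects in the group are
    skipped with a ``skipped`` flag.  The returned frame has one row per
    country with delta_mean, p, and sign/significance preservation columns.
    """
    y, sub, covs = _group_outcome(cohort, group, modality)
    countries = sorted(sub["country"].unique())
    if len(countries) < 3:
        raise ValueError("leave-one-country-out needs >= 3 countries")
    base = _contrast(y, sub, "eq", "yoe", covs, k, reps, iterations, seed)
    rows = []
    for drop in countries:
        keep = (sub["country"] != drop).to_numpy()
        if keep.sum() < 3 * k:
            rows.append(
                {"dropped": drop, "n": int(keep.sum()), "skipped": True,
                 "delta_mean": np.nan, "p": np.nan,
                 "sign_preserved": False, "significance_preserved": False}
            )
            continue
        res = _contrast(
            y[keep], sub.loc[keep].reset_index(drop=True), "eq", "yoe", covs,
            k, reps, iterations, seed,
        )
        rows.append(
            {
                "dropped": drop,
                "n": int(keep.sum()),
                "skipped": False,
                "delta_mean": res.delta_mean,
                "p": res.p,
                "sign_preserved": np.sign(res.delta_mean) == np.sign(base.delta_mean),
                "significance_preserved": (res.p < alpha) == (base.p < alpha),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["baseline_delta_mean"] = base.delta_mean
    out.attrs["baseline_p"] = base.p
    return out


def residualize(y: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1 | nuisance] — a projection, hence idempotent."""
    y = np.asarray(y, dtype=float)
    Z = np.asarray(nuisance, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if np.any(Z.std(axis=0, ddof=0) == 0):
        raise ValueError("constant quality metric cannot be used for correction")
    X = np.column_stack([np.ones(len(y)), Z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def quality_screen_and_correct(
    cohort, group: str = "HC", modality: str = "gm",
    k=K_DEFAULT, reps=REPS_DEFAULT, iterations=ITERATIONS_DEFAULT, seed: int = 0,
    band: tuple[float, float] = NEGLIGIBLE_BAND,
) -> SensitivityReport:
    """Screen SNR/tSNR against the exposures, correct the outcome, rerun.

    Pearson r inside the open interval ``band`` is flagged negligible; the
    whole-brain measure is residualised on the modality's quality metrics
    regardless, and the EQ vs YoE contrast rerun on the residuals.
    """
    y, sub, covs = _group_outcome(cohort, group, modality)
    metric_cols = ["snr_t1"] if modality == "gm" else ["snr_fmri", "tsnr"]
    for c in metric_cols:
        if c not in sub.columns or sub[c].isna().any():
            raise ValueError(f"quality metric column missing or incomplete: {c}")
    screening = {}
    for c in metric_cols:
        for exposure in ("eq", "yoe"):
            r = float(np.corrcoef(sub[c], sub[exposure])[0, 1])
            screening[f"r_{c}_{exposure}"] = r
            screening[f"negligible_{c}_{exposure}"] = bool(band[0] < r < band[1])
    base = _contrast(y, sub, "eq", "yoe", covs, k, reps, iterations, seed)
    y_corr = residualize(y, sub[metric_cols].to_numpy())
    adj = _contrast(y_corr, sub, "eq", "yoe", covs, k, reps, iterations, seed)
    return SensitivityReport(
        contrast=f"eq_vs_yoe|quality_{modality}",
        baseline=base,
        adjusted=adj,
        screening=screening,
    )
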