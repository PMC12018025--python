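"""Regional (voxel- / edge-wise) mass-univariate regression and comparison.

Each brain unit (a GM voxel or an FC edge) is regressed on a single
education predictor (EQ, YoE, or their product EQ x YoE) plus covariates
(age, sex, MMSE, and TIV for grey matter or eyes-open/closed for functional
connectivity).  The per-unit p-values for the predictor coefficient are
corrected with Benjamini-Hochberg FDR at q = 0.05 within each map, and only
units whose model R^2 exceeds 0.05 enter downstream effect-size comparison.
The EQ and YoE adjusted-R^2 maps are then compared with a paired Wilcoxon
signed-rank test and a paired Cohen's d.

Because the design matrix is shared by every unit in a map, the whole map is
fit with a single pseudoinverse solve; a per-unit normal-equations reference
is used as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests
from sklearn.base import BaseEstimator

__all__ = [
    "RegressionSpec",
    "EffectMap",
    "PairedMapComparison",
    "MassUnivariateOLS",
    "fit_mass_univariate",
    "build_design",
    "adjusted_r2",
    "fdr_bh",
    "check_assumptions",
    "compare_effect_maps",
]

ALPHA_FDR_DEFAULT = 0.05
R2_FLOOR_DEFAULT = 0.05
PREDICTORS = ("eq", "yoe", "eqxyoe")


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress: one predictor, a covariate list, FDR and floor levels."""

    predictor: str = "eq"
    covariates: tuple[str, ...] = ("age", "sex", "mmse")
    alpha_fdr: float = ALPHA_FDR_DEFAULT
    r2_floor: float = R2_FLOOR_DEFAULT

    def __post_init__(self):
        if self.predictor not in PREDICTORS:
            raise ValueError(f"predictor must be one of {PREDICTORS}")
        if self.predictor in self.covariates:
            raise ValueError("predictor cannot also be a covariate")


@dataclass
class EffectMap:
    """Per-unit regression results for one predictor over one modality."""

    predictor: str
    r2: np.ndarray
    r2_adj: np.ndarray
    beta: np.ndarray
    p: np.ndarray
    q_significant: np.ndarray
    floor_pass: np.ndarray
    n_subjects: int
    n_predictors: int
    unit_ids: np.ndarray = field(default=None)

    @property
    def n_units(self) -> int:
        return len(self.r2)


def adjusted_r2(r2, n_subjects: int, n_predictors: int):
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n_subjects <= n_predictors + 1:
        raise ValueError("need n > p + 1 for adjusted R^2")
    r2 = np.asarray(r2, dtype=float)
    out = 1.0 - (1.0 - r2) * (n_subjects - 1) / (n_subjects - n_predictors - 1)
    return float(out) if out.ndim == 0 else out


def fdr_bh(p_values, q: float = ALPHA_FDR_DEFAULT) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def build_design(
    participants: pd.DataFrame, spec: RegressionSpec
) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept | predictor | covariates] from the participant table.

    ``eqxyoe`` is the elementwise product of the eq and yoe columns.  Raises
    on missing values and on rank-deficient designs, naming the collinear
    columns.
    """
    cols = {}
    if spec.predictor == "eqxyoe":
        if "eq" not in participants or "yoe" not in participants:
            raise ValueError("eq and yoe columns required for the eqxyoe product")
        cols["eqxyoe"] = participants["eq"].to_numpy(float) * participants[
            "yoe"
        ].to_numpy(float)
    else:
        cols[spec.predictor] = participants[spec.predictor].to_numpy(float)
    for c in spec.covariates:
        if c not in participants:
            raise ValueError(f"covariate column missing: {c}")
        cols[c] = participants[c].to_numpy(float)
    names = list(cols)
    X = np.column_stack([np.ones(len(participants))] + [cols[c] for c in names])
    names = ["intercept"] + names
    if np.isnan(X).any():
        bad = [names[j] for j in range(X.shape[1]) if np.isnan(X[:, j]).any()]
        raise ValueError(f"missing values in design columns: {bad}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify collinear columns from the small diagonal entries of R.
        r_diag = np.abs(np.diag(np.linalg.qr(X)[1]))
        tol = r_diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(X.shape[1]) if r_diag[j] <= tol]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, names


class MassUnivariateOLS(BaseEstimator):
    """Vectorised per-unit OLS with a shared design matrix.

    fit(Y, participants) regresses every column of ``Y`` (subjects x units)
    on the design from ``spec``; fitted attributes carry the per-unit
    statistics (``r2_``, ``r2_adj_``, ``beta_``, ``p_``,
    ``q_significant_``, ``floor_pass_``).
    """

    def __init__(self, spec: RegressionSpec = RegressionSpec()):
        self.spec = spec

    def fit(self, Y: np.ndarray, participants: pd.DataFrame):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = Y.shape[0]
        if len(participants) != n:
            raise ValueError("Y rows must match participant rows")
        X, names = build_design(participants, self.spec)
        p_model = X.shape[1] - 1  # predictors excluding intercept
        if n < p_model + 2:
            raise ValueError("too few subjects for the design")
        pinv = np.linalg.pinv(X)
        beta_all = pinv @ Y  # (k, units)
        resid = Y - X @ beta_all
        dof = n - X.shape[1]
        rss = (resid**2).sum(axis=0)
        tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        sigma2 = rss / dof
        xtx_inv = pinv @ pinv.T
        j = names.index(self.spec.predictor)
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        beta = beta_all[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        self.design_columns_ = names
        self.residuals_ = resid
        self.design_ = X
        self.r2_ = r2
        self.r2_adj_ = adjusted_r2(r2, n, p_model)
        self.beta_ = beta
        self.p_ = pvals
        self.q_significant_ = fdr_bh(pvals, self.spec.alpha_fdr)
        self.floor_pass_ = r2 > self.spec.r2_floor
        self.n_subjects_ = n
        self.n_predictors_ = p_model
        return self

    def effect_map(self, unit_ids=None) -> EffectMap:
        return EffectMap(
            predictor=self.spec.predictor,
            r2=self.r2_,
            r2_adj=self.r2_adj_,
            beta=self.beta_,
            p=self.p_,
            q_significant=self.q_significant_,
            floor_pass=self.floor_pass_,
            n_subjects=self.n_subjects_,
            n_predictors=self.n_predictors_,
            unit_ids=unit_ids if unit_ids is not None else np.arange(len(self.r2_)),
        )


def fit_mass_univariate(
    brain_units: np.ndarray,
    participants: pd.DataFrame,
    spec: RegressionSpec,
    unit_ids=None,
) -> EffectMap:
    """OLS of every brain unit on the predictor + covariates; FDR per map."""
    est = MassUnivariateOLS(spec=spec).fit(brain_units, participants)
    return est.effect_map(unit_ids=unit_ids)


def check_assumptions(
    residuals: np.ndarray,
    exog: np.ndarray,
    max_units: int | None = 200,
    random_state: int = 0,
) -> pd.DataFrame:
    """Shapiro-Wilk and Breusch-Pagan p-values per fitted unit.

    ``residuals`` is subjects x units; ``exog`` the shared design matrix.
    With many units a deterministic subsample of ``max_units`` columns is
    summarised.  Returns a tidy frame with one row per checked unit.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 1:
        residuals = residuals[:, None]
    if residuals.shape[0] < 3:
        raise ValueError("need >= 3 residuals per unit")
    n_units = residuals.shape[1]
    idx = np.arange(n_units)
    if max_units is not None and n_units > max_units:
        idx = np.random.default_rng(random_state).choice(
            n_units, size=max_units, replace=False
        )
        idx.sort()
    rows = []
    for u in idx:
        r = residuals[:, u]
        sw_p = float(stats.shapiro(r).pvalue)
        bp_p = float(het_breuschpagan(r, exog)[1])
        rows.append({"unit": int(u), "shapiro_p": sw_p, "breusch_pagan_p": bp_p})
    return pd.DataFrame(rows)


@dataclass
class PairedMapComparison:
    """Wilcoxon + Cohen's d contrast of two adjusted-R^2 maps."""

    W: float
    p: float
    cohen_d: float
    diff_map: np.ndarray
    unit_ids: np.ndarray
    n_units: int
    note: str = ""


def compare_effect_maps(
    map_eq: EffectMap,
    map_yoe: EffectMap,
    unit_set: str = "union",
) -> PairedMapComparison:
    """Paired Wilcoxon signed-rank of adjusted R^2 between two predictors.

    ``unit_set`` selects which units enter the comparison: "union" (floor
    passed for either predictor, the default), "intersection", or "all".
    Cohen's d for paired data is mean(diff)/SD(diff); if every difference is
    zero the test is undefined and the result is flagged "no discrimination".
    """
    if map_eq.n_units != map_yoe.n_units:
        raise ValueError("maps must share unit indexing")
    if unit_set == "union":
        sel = map_eq.floor_pass | map_yoe.floor_pass
    elif unit_set == "intersection":
        sel = map_eq.floor_pass & map_yoe.floor_pass
    elif unit_set == "all":
        sel = np.ones(map_eq.n_units, dtype=bool)
    else:
        raise ValueError("unit_set must be union|intersection|all")
    if not sel.any():
        raise ValueError("comparison unit set is empty")
    a = map_eq.r2_adj[sel]
    b = map_yoe.r2_adj[sel]
    diff = a - b
    ids = np.asarray(map_eq.unit_ids)[sel]
    if np.allclose(diff, 0.0):
        return PairedMapComparison(
            W=np.nan, p=np.nan, cohen_d=0.0, diff_map=diff, unit_ids=ids,
            n_units=int(sel.sum()), note="no discrimination",
        )
    sd = diff.std(ddof=1)
    if sd <= 1e-8 * max(abs(diff.mean()), np.abs(diff).max()):
        d = np.inf * np.sign(diff.mean())  # constant shift: SD ~ 0
    else:
        d = diff.mean() / sd
    nz = diff[diff != 0]
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method, correction=True)
    return PairedMapComparison(
        W=float(res.statistic),
        p=float(res.pvalue),
        cohen_d=float(d),
        diff_map=diff,
        unit_ids=ids,
        n_units=int(sel.sum()),
    )
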