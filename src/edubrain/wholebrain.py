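"""Whole-brain ridge comparison of education quality vs years of education.

For each diagnostic group and modality, the whole-brain measure (mean GM
volume or network global efficiency) is predicted with ridge regression from
one education predictor plus covariates.  Out-of-sample fit is measured by
R^2 under 3-fold cross-validation repeated 20 times, with the penalty alpha
grid-searched over 1000 log-spaced values in [1e-10, 1e10] by nested 3-fold
CV inside each training partition.  The two predictors' repetition-level R^2
distributions are then contrasted:

* Delta-mean: mean R^2_EQ - mean R^2_YoE (the paired point estimate),
* a permutation p-value from sign-flips of the paired repetition differences
  (full enumeration when feasible, otherwise Monte-Carlo up to the iteration
  cap, with the add-one correction),
* a 95% percentile bootstrap CI over repetition pairs,
* the effect ratio mean R^2_EQ / mean R^2_YoE.

The ridge path is solved by SVD of the (train-standardised) design so that
the full alpha grid is evaluated in one vectorised pass per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from .harmonization import GMImageSet, whole_brain_mean_volume
from .network import DENSITY_DEFAULT, fc_matrix, global_efficiency, proportional_threshold
from .regional import RegressionSpec

__all__ = [
    "CVResult",
    "ComparisonResult",
    "RepeatedRidgeCV",
    "default_alpha_grid",
    "cv_ridge_r2",
    "compare_predictors",
    "run_group_modality_grid",
]

N_ALPHAS_DEFAULT = 1000
ALPHA_LO, ALPHA_HI = 1e-10, 1e10
REPS_DEFAULT = 20
K_DEFAULT = 3
ITERATIONS_DEFAULT = 100_000
RATIO_GUARD = 1e-6


def default_alpha_grid(n: int = N_ALPHAS_DEFAULT) -> np.ndarray:
    """1000 log-spaced ridge penalties from 1e-10 to 1e10."""
    return np.logspace(np.log10(ALPHA_LO), np.log10(ALPHA_HI), n)


@dataclass
class CVResult:
    """Repetition-level cross-validated R^2 for one predictor.

    ``subject_losses`` holds the per-subject out-of-fold squared prediction
    errors, one row per repetition; they feed the subject-level permutation
    test (see :func:`compare_predictors`).
    """

    predictor: str
    rep_scores: np.ndarray  # mean across folds, one per repetition
    chosen_alphas: np.ndarray  # (reps, k) selected penalty per outer fold
    seed: int
    subject_losses: np.ndarray | None = None  # (reps, n)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.rep_scores))


@dataclass
class ComparisonResult:
    """Delta-mean contrast between two predictors' CV R^2 distributions."""

    delta_mean: float
    ci95: tuple[float, float]
    p: float
    ratio: float
    n_iterations: int
    predictor_a: str = "eq"
    predictor_b: str = "yoe"
    mean_a: float = np.nan
    mean_b: float = np.nan
    extras: dict = field(default_factory=dict)


def _derive_seed(master: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master)] + [int(s) for s in streams]))


def _standardize_train(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _ridge_path_predict(Xtr, ytr, Xte, alphas):
    """Predictions on Xte for every alpha at once, intercept via centring.

    Returns an array (n_test, n_alphas).
    """
    ym = ytr.mean()
    yc = ytr - ym
    U, s, Vt = np.linalg.svd(Xtr, full_matrices=False)
    uty = U.T @ yc  # (r,)
    # shrinkage factors per (singular value, alpha)
    d = s[:, None] / (s[:, None] ** 2 + alphas[None, :])  # (r, A)
    xv = Xte @ Vt.T  # (n_test, r)
    return xv @ (d * uty[:, None]) + ym


def _ridge_fit_predict(Xtr, ytr, Xte, alpha):
    return _ridge_path_predict(Xtr, ytr, Xte, np.asarray([alpha]))[:, 0]


class RepeatedRidgeCV(BaseEstimator):
    """Repeated k-fold ridge CV with nested alpha grid search.

    fit(X, y) runs ``reps`` repetitions of ``k``-fold CV.  Within each outer
    training partition the penalty is chosen by an inner ``k``-fold grid
    search over ``alphas`` (minimum mean validation MSE, ties to the smaller
    alpha); regressors are z-scored with training-fold statistics only.
    Fitted attributes: ``rep_scores_`` (mean out-of-fold R^2 per repetition)
    and ``chosen_alphas_``.
    """

    def __init__(
        self,
        k: int = K_DEFAULT,
        reps: int = REPS_DEFAULT,
        alphas: np.ndarray | None = None,
        seed: int = 0,
    ):
        self.k = k
        self.reps = reps
        self.alphas = alphas
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if X.ndim != 2 or X.shape[0] != n:
            raise ValueError("X must be n x p matching y")
        if n < 3 * self.k:
            raise ValueError(f"need n >= {3 * self.k} for {self.k}-fold CV")
        if y.std(ddof=0) == 0:
            raise ValueError("zero-variance outcome")
        alphas = (
            default_alpha_grid() if self.alphas is None else np.asarray(self.alphas, float)
        )
        rep_scores = np.empty(self.reps)
        chosen = np.empty((self.reps, self.k))
        losses = np.empty((self.reps, n))
        for rep in range(self.reps):
            rng = _derive_seed(self.seed, rep)
            kf = KFold(
                n_splits=self.k,
                shuffle=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            fold_r2 = []
            for f, (tr, te) in enumerate(kf.split(X)):
                Xtr, Xte = _standardize_train(X[tr], X[te])
                ytr, yte = y[tr], y[te]
                alpha = self._inner_select(Xtr, ytr, alphas, rng)
                pred = _ridge_fit_predict(Xtr, ytr, Xte, alpha)
                sst = ((yte - yte.mean()) ** 2).sum()
                ssr = ((yte - pred) ** 2).sum()
                fold_r2.append(1.0 - ssr / sst if sst > 0 else 0.0)
                chosen[rep, f] = alpha
                losses[rep, te] = (yte - pred) ** 2
            rep_scores[rep] = float(np.mean(fold_r2))
        self.rep_scores_ = rep_scores
        self.chosen_alphas_ = chosen
        self.subject_losses_ = losses
        self.alphas_ = alphas
        return self

    def _inner_select(self, Xtr, ytr, alphas, rng) -> float:
        inner = KFold(
            n_splits=self.k,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        mse = np.zeros(len(alphas))
        for tr, va in inner.split(Xtr):
            Xi, Xv = _standardize_train(Xtr[tr], Xtr[va])
            preds = _ridge_path_predict(Xi, ytr[tr], Xv, alphas)
            mse += ((preds - ytr[va][:, None]) ** 2).mean(axis=0)
        return float(alphas[int(np.argmin(mse))])


def cv_ridge_r2(
    y: np.ndarray,
    participants: pd.DataFrame,
    spec: RegressionSpec,
    k: int = K_DEFAULT,
    reps: int = REPS_DEFAULT,
    alphas: np.ndarray | None = None,
    seed: int = 0,
) -> CVResult:
    """Repeated-CV ridge R^2 for one predictor + covariates."""
    from .regional import build_design

    X, _ = build_design(participants, spec)
    X = X[:, 1:]  # RepeatedRidgeCV centres internally; drop explicit intercept
    est = RepeatedRidgeCV(k=k, reps=reps, alphas=alphas, seed=seed).fit(X, np.asarray(y))
    return CVResult(
        predictor=spec.predictor,
        rep_scores=est.rep_scores_,
        chosen_alphas=est.chosen_alphas_,
        seed=seed,
        subject_losses=est.subject_losses_,
    )


def _signflip_p(diff: np.ndarray, iterations: int, rng: np.random.Generator):
    """Two-sided sign-flip p-value for mean(diff) = 0.

    Full enumeration when 2^len(diff) fits in the iteration cap, otherwise
    Monte-Carlo with the add-one correction.
    """
    m = len(diff)
    obs = abs(diff.mean())
    if 2**m <= iterations:
        signs = np.array(
            [[1 if (msk >> i) & 1 else -1 for i in range(m)] for msk in range(2**m)]
        )
        null = (signs * diff[None, :]).mean(axis=1)
        return float(np.mean(np.abs(null) >= obs - 1e-15)), 2**m
    signs = rng.choice([-1.0, 1.0], size=(iterations, m))
    null = (signs * diff[None, :]).mean(axis=1)
    extreme = int(np.sum(np.abs(null) >= obs - 1e-15))
    return (1.0 + extreme) / (1.0 + iterations), iterations


def compare_predictors(
    cv_a: CVResult,
    cv_b: CVResult,
    iterations: int = ITERATIONS_DEFAULT,
    seed: int = 0,
    bootstrap_iterations: int | None = None,
    scheme: str = "auto",
    ci_method: str = "bootstrap_t",
) -> ComparisonResult:
    """Permutation + bootstrap contrast of two CV results.

    Delta-mean is mean(R^2_a) - mean(R^2_b) over the repetition pairs, and
    the 95% CI is bootstrapped over those pairs: a studentized bootstrap-t
    interval by default (the plain percentile interval, available as
    ``ci_method="percentile"``, undercovers at small repetition counts
    because it uses z-like rather than t-like quantiles).  The permutation
    p-value swaps the two predictors' labels:

    * ``scheme="subject"`` (default whenever both results carry per-subject
      out-of-fold losses): sign-flips of the per-subject mean loss
      differences.  Repetitions reuse the same subjects, so subjects -- not
      repetitions -- are the approximately independent exchangeable units;
      this scheme is calibrated under data-level nulls.
    * ``scheme="reps"``: sign-flips of the paired repetition differences,
      exactly valid when the repetition pairs themselves are exchangeable
      draws (e.g. independent replicates).
    """
    a = np.asarray(cv_a.rep_scores, dtype=float)
    b = np.asarray(cv_b.rep_scores, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched repetition counts")
    reps = len(a)
    diff = a - b
    delta = float(diff.mean())
    rng = _derive_seed(seed, 7)
    n_boot = iterations if bootstrap_iterations is None else bootstrap_iterations

    if scheme == "auto":
        scheme = (
            "subject"
            if cv_a.subject_losses is not None and cv_b.subject_losses is not None
            else "reps"
        )
    if scheme == "subject":
        if cv_a.subject_losses is None or cv_b.subject_losses is None:
            raise ValueError("subject scheme needs per-subject losses")
        # loss_b - loss_a > 0 where predictor a fits better
        ldiff = np.asarray(cv_b.subject_losses).mean(axis=0) - np.asarray(
            cv_a.subject_losses
        ).mean(axis=0)
        p, n_iter = _signflip_p(ldiff, iterations, rng)
    elif scheme == "reps":
        p, n_iter = _signflip_p(diff, iterations, rng)
    else:
        raise ValueError("scheme must be auto|subject|reps")

    # bootstrap CI of the mean repetition difference
    idx = rng.integers(0, reps, size=(n_boot, reps))
    samples = diff[idx]
    boot = samples.mean(axis=1)
    if ci_method == "percentile":
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    elif ci_method == "bootstrap_t":
        se = diff.std(ddof=1) / np.sqrt(reps)
        se_star = samples.std(axis=1, ddof=1) / np.sqrt(reps)
        if se <= 0:
            ci = (delta, delta)
        else:
            ok = se_star > 0
            tstar = (boot[ok] - delta) / se_star[ok]
            ci = (
                float(delta - np.percentile(tstar, 97.5) * se),
                float(delta - np.percentile(tstar, 2.5) * se),
            )
    else:
        raise ValueError("ci_method must be bootstrap_t|percentile")

    mean_b = float(b.mean())
    ratio = float(a.mean() / mean_b) if abs(mean_b) >= RATIO_GUARD else float("nan")
    return ComparisonResult(
        delta_mean=delta,
        ci95=ci,
        p=float(min(p, 1.0)),
        ratio=ratio,
        n_iterations=n_iter,
        predictor_a=cv_a.predictor,
        predictor_b=cv_b.predictor,
        mean_a=float(a.mean()),
        mean_b=mean_b,
        extras={"scheme": scheme},
    )


GM_COVARIATES = ("age", "sex", "mmse", "tiv")
FC_COVARIATES = ("age", "sex", "mmse", "eyes_condition")


def _wholebrain_outcomes(cohort, density: float = DENSITY_DEFAULT):
    """Whole-brain GM mean and FC global efficiency per subject."""
    gm_mean = whole_brain_mean_volume(cohort.gm)
    eff = np.array(
        [
            global_efficiency(proportional_threshold(fc_matrix(ts), density=density))
            for ts in cohort.timeseries_normalized
        ]
    )
    return gm_mean, eff


def run_group_modality_grid(
    cohort,
    groups: tuple[str, ...] = ("HC", "AD", "FTLD"),
    contrasts: tuple[tuple[str, str], ...] = (("eq", "yoe"), ("eq", "eqxyoe")),
    k: int = K_DEFAULT,
    reps: int = REPS_DEFAULT,
    iterations: int = ITERATIONS_DEFAULT,
    alphas: np.ndarray | None = None,
    seed: int = 0,
    density: float = DENSITY_DEFAULT,
) -> pd.DataFrame:
    """All group x modality x contrast whole-brain comparisons.

    Returns a tidy frame with one row per (group, modality, contrast)
    carrying delta_mean, the 95% CI, p, the ratio and the seed used.
    """
    parts = cohort.participants
    missing = [g for g in groups if g not in set(parts["group"])]
    if missing:
        raise ValueError(f"groups absent from cohort: {missing}")
    gm_mean, eff = _wholebrain_outcomes(cohort, density=density)
    rows = []
    for gi, group in enumerate(groups):
        sel = (parts["group"] == group).to_numpy()
        sub = parts.loc[sel].reset_index(drop=True)
        for mi, (modality, y, covs) in enumerate(
            (("gm", gm_mean[sel], GM_COVARIATES), ("fc", eff[sel], FC_COVARIATES))
        ):
            for ci_, (pa, pb) in enumerate(contrasts):
                sub_seed = int(
                    np.random.SeedSequence([seed, gi, mi, ci_]).generate_state(1)[0]
                    % 2**31
                )
                cva = cv_ridge_r2(
                    y, sub, RegressionSpec(predictor=pa, covariates=covs),
                    k=k, reps=reps, alphas=alphas, seed=sub_seed,
                )
                cvb = cv_ridge_r2(
                    y, sub, RegressionSpec(predictor=pb, covariates=covs),
                    k=k, reps=reps, alphas=alphas, seed=sub_seed,
                )
                res = compare_predictors(cva, cvb, iterations=iterations, seed=sub_seed)
                rows.append(
                    {
                        "group": group,
                        "modality": modality,
                        "contrast": f"{pa}_vs_{pb}",
                        "delta_mean": res.delta_mean,
                        "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1],
                        "p": res.p,
                        "ratio": res.ratio,
                        "mean_r2_a": res.mean_a,
                        "mean_r2_b": res.mean_b,
                        "seed": sub_seed,
                    }
                )
    return pd.DataFrame(rows)
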