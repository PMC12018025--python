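"""Synthetic multi-country cohort with planted education effects.

Generates all four inputs the analysis pipeline consumes — a country x cycle
PISA-like score table, a participant table, per-subject grey-matter maps on
a small voxel grid, and per-subject ROI time series — with known ground
truth, so every downstream stage (harmonization, network metrics, regional
and whole-brain comparisons, sensitivity analyses) is testable end to end
without external data.

Planted structure
-----------------
* Country mean PISA scores span a configurable range (default 393-561, which
  standardises to EQ values from 0.93 to 2.61); each country contributes 4-7
  assessment cycles with cycle- and domain-level noise.
* Years of education are coupled to country EQ through a latent-Gaussian
  construction with configurable correlation (default r = 0.3), emulating
  exposure confounding; scanner SNR is coupled to EQ the same way (default
  r = -0.15, the nuisance pattern used by the quality sensitivity analysis).
* Grey-matter voxels carry linear EQ and YoE effects on disjoint random
  voxel subsets (a configurable fraction of the mask each), on top of a
  fixed baseline, group-specific atrophy topographies, covariate effects
  (age, sex, MMSE, TIV) on random voxel subsets, and i.i.d. Gaussian noise.
  Effect sizes are expressed in residual-SD units: a voxel in the EQ set
  gets ``beta_eq * noise_sd`` per SD of EQ.
* ROI time series come from a latent-factor AR(1) model (module structure
  via a block loading matrix); EQ and YoE modulate the amplitude of shared
  pair signals on disjoint random edge subsets, so connectivity on those
  edges — and through them network integration — tracks the exposures.

Identical config (including seed) reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .education import build_eq_table
from .harmonization import (
    GMImageSet,
    TimeSeriesPreprocessor,
    minmax_scale_subject,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "CohortTruth",
    "generate_country_table",
    "generate_participants",
    "generate_brain_data",
    "simulate_cohort",
]

PISA_YEARS = (2003, 2006, 2009, 2012, 2015, 2018, 2022)
DOMAINS = ("reading", "mathematics", "science")

# Per-group demographics: age (mean, sd), fraction female, MMSE (mean, sd),
# YoE (mean, sd).  Mirrors typical aging/dementia cohort tables.
GROUP_DEMOGRAPHICS = {
    "HC": {"age": (58.1, 17.6), "female": 0.566, "mmse": (29.1, 1.7), "yoe": (13.7, 4.6)},
    "AD": {"age": (72.2, 7.9), "female": 0.590, "mmse": (23.2, 5.3), "yoe": (11.5, 4.6)},
    "FTLD": {"age": (65.7, 8.2), "female": 0.464, "mmse": (22.6, 5.8), "yoe": (13.8, 4.6)},
}
GROUPS = ("HC", "AD", "FTLD")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic cohort; identical config => identical data."""

    n_countries: int = 20
    pisa_mean_range: tuple[float, float] = (393.0, 561.0)
    country_mean_spacing: str = "linspace"  # or "uniform"
    cycle_score_sd: float = 8.0
    domain_score_sd: float = 5.0
    n_subjects_per_group: tuple[int, int, int] = (200, 120, 80)
    country_size_imbalance: float = 0.5
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_rois: int = 90
    n_volumes: int = 140
    sampling_interval: float = 2.0
    beta_eq: float = 0.5
    beta_yoe: float = 0.25
    beta_eq_fc: float | None = None  # edge-modulation effects; default betas above
    beta_yoe_fc: float | None = None
    effect_topography: float = 0.2
    covariate_effects: dict = field(
        default_factory=lambda: {"age": -0.3, "sex": 0.1, "mmse": 0.2, "tiv": 0.15}
    )
    eq_yoe_corr: float = 0.3
    snr_eq_corr: float = -0.15
    snr_fmri_eq_corr: float = 0.07
    tsnr_eq_corr: float = -0.02
    noise_sd: float = 0.1
    n_latent_factors: int = 6
    ar_coef: float = 0.6
    fc_gain: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_countries < 2:
            raise ValueError("need n_countries >= 2")
        if not 0 <= self.effect_topography <= 1:
            raise ValueError("effect_topography must be in [0, 1]")
        if min(self.grid_shape) < 2 or self.n_rois < 2:
            raise ValueError("grid dims and ROI count must be >= 2")
        if all(n == 0 for n in self.n_subjects_per_group):
            raise ValueError("all group sizes are zero")
        if any(n < 0 for n in self.n_subjects_per_group):
            raise ValueError("group sizes must be non-negative")


@dataclass
class CohortTruth:
    """Planted coefficients and the affected voxel / edge index sets."""

    beta_eq: float
    beta_yoe: float
    eq_voxels: np.ndarray
    yoe_voxels: np.ndarray
    eq_edges: np.ndarray
    yoe_edges: np.ndarray
    covariate_effects: dict
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("eq_voxels", "yoe_voxels", "eq_edges", "yoe_edges"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class SyntheticCohort:
    """Everything one run of the generator produces."""

    config: SyntheticConfig
    eq_table: pd.DataFrame
    participants: pd.DataFrame
    gm: GMImageSet
    timeseries: np.ndarray  # (n_subjects, n_rois, n_volumes), raw
    truth: CohortTruth
    _ts_norm: list | None = None

    @property
    def timeseries_normalized(self) -> list[np.ndarray]:
        """Band-passed, truncated, z-scored series (lazily cached)."""
        if self._ts_norm is None:
            pre = TimeSeriesPreprocessor(
                sampling_interval=self.config.sampling_interval
            )
            self._ts_norm = [pre.fit_transform(ts) for ts in self.timeseries]
        return self._ts_norm


def _rng_for(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_country_table(config: SyntheticConfig) -> pd.DataFrame:
    """Country x cycle x domain PISA-like scores.

    Country means are spread over ``pisa_mean_range`` (evenly by default).
    Each country has 4-7 cycles: when there are at least four countries,
    three randomly chosen ones keep only 4, 6 and 5 cycles respectively,
    mirroring real gaps in PISA participation.
    """
    rng = _rng_for(config, 0)
    lo, hi = config.pisa_mean_range
    if config.country_mean_spacing == "linspace":
        means = np.linspace(lo, hi, config.n_countries)
    elif config.country_mean_spacing == "uniform":
        means = rng.uniform(lo, hi, config.n_countries)
    else:
        raise ValueError("country_mean_spacing must be linspace|uniform")
    countries = [f"C{i:02d}" for i in range(config.n_countries)]
    cycle_counts = np.full(config.n_countries, len(PISA_YEARS))
    if config.n_countries >= 4:
        short = rng.choice(config.n_countries, size=3, replace=False)
        cycle_counts[short] = [4, 6, 5]
    rows = []
    for ci, country in enumerate(countries):
        years = sorted(
            rng.choice(len(PISA_YEARS), size=cycle_counts[ci], replace=False)
        )
        for yi in years:
            cycle_shift = rng.normal(0.0, config.cycle_score_sd)
            for domain in DOMAINS:
                rows.append(
                    {
                        "country": country,
                        "year": PISA_YEARS[yi],
                        "domain": domain,
                        "score": means[ci]
                        + cycle_shift
                        + rng.normal(0.0, config.domain_score_sd),
                    }
                )
    return pd.DataFrame(rows)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _coupled_latent(z_ref: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Latent standard-normal variable with target correlation r to z_ref."""
    eps = rng.normal(size=len(z_ref))
    return r * z_ref + np.sqrt(max(0.0, 1.0 - r**2)) * eps


def generate_participants(
    config: SyntheticConfig, eq_table: pd.DataFrame
) -> pd.DataFrame:
    """Participant table with demographics, exposures and nuisance metrics."""
    if len(eq_table) == 0:
        raise ValueError("eq_table is empty")
    rng = _rng_for(config, 1)
    n_total = sum(config.n_subjects_per_group)
    groups = np.repeat(GROUPS, config.n_subjects_per_group)

    # country assignment with log-normal size imbalance
    raw_w = np.exp(config.country_size_imbalance * rng.normal(size=len(eq_table)))
    weights = raw_w / raw_w.sum()
    country_ix = rng.choice(len(eq_table), size=n_total, p=weights)
    countries = eq_table["country"].to_numpy()[country_ix]
    eq = eq_table["eq"].to_numpy()[country_ix]
    z_eq = _standardize(eq)

    age = np.empty(n_total)
    sex = np.empty(n_total, dtype=int)
    mmse = np.empty(n_total)
    yoe_mu = np.empty(n_total)
    yoe_sd = np.empty(n_total)
    for g in GROUPS:
        m = groups == g
        demo = GROUP_DEMOGRAPHICS[g]
        age[m] = np.clip(rng.normal(*demo["age"], size=m.sum()), 20, 100)
        sex[m] = (rng.random(m.sum()) < demo["female"]).astype(int)
        mmse[m] = np.clip(rng.normal(*demo["mmse"], size=m.sum()), 0, 30)
        yoe_mu[m], yoe_sd[m] = demo["yoe"]

    z_yoe_latent = _coupled_latent(z_eq, config.eq_yoe_corr, rng)
    yoe = np.clip(yoe_mu + yoe_sd * z_yoe_latent, 0.0, 20.0)
    tiv = rng.normal(1.45e6, 1.3e5, size=n_total)

    snr_t1 = 12.0 + 2.0 * _coupled_latent(z_eq, config.snr_eq_corr, rng)
    snr_fmri = 8.0 + 1.5 * _coupled_latent(z_eq, config.snr_fmri_eq_corr, rng)
    tsnr = 50.0 + 8.0 * _coupled_latent(z_eq, config.tsnr_eq_corr, rng)

    # individual SES tracks YoE; Gini and GDP are country-level functions of EQ
    ses = 0.5 * _standardize(yoe) + np.sqrt(0.75) * rng.normal(size=n_total)
    z_eq_country = _standardize(eq_table["eq"].to_numpy())
    gini_c = 38.0 - 6.0 * z_eq_country + rng.normal(0, 2.0, size=len(eq_table))
    gdp_c = 20_000.0 * np.exp(0.4 * z_eq_country + rng.normal(0, 0.2, size=len(eq_table)))

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n_total)],
            "country": countries,
            "group": groups,
            "age": age,
            "sex": sex,
            "yoe": yoe,
            "mmse": mmse,
            "tiv": tiv,
            "eyes_condition": rng.integers(0, 2, size=n_total),
            "eq": eq,
            "ses": ses,
            "gini": gini_c[country_ix],
            "gdp": gdp_c[country_ix],
            "snr_t1": snr_t1,
            "snr_fmri": snr_fmri,
            "tsnr": tsnr,
        }
    )


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    val = sum(((g - (s - 1) / 2) / (0.52 * s)) ** 2 for g, s in zip(grids, shape))
    return val <= 1.0


def _ar1(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    white = rng.normal(size=shape)
    out = sp_signal.lfilter([1.0], [1.0, -phi], white, axis=-1)
    return out * np.sqrt(1.0 - phi**2)  # unit marginal variance


def generate_brain_data(
    config: SyntheticConfig, participants: pd.DataFrame
) -> tuple[GMImageSet, np.ndarray, CohortTruth]:
    """Grey-matter maps and ROI time series with planted linear effects."""
    if len(participants) == 0:
        raise ValueError("participants table is empty")
    rng = _rng_for(config, 2)
    n = len(participants)
    mask = _ellipsoid_mask(config.grid_shape)
    n_vox = int(mask.sum())

    z_eq = _standardize(participants["eq"].to_numpy())
    z_yoe = _standardize(participants["yoe"].to_numpy())
    z_cov = {
        "age": _standardize(participants["age"].to_numpy()),
        "sex": _standardize(participants["sex"].to_numpy()),
        "mmse": _standardize(participants["mmse"].to_numpy()),
        "tiv": _standardize(participants["tiv"].to_numpy()),
    }

    # Voxel topographies mirror the observed regional pattern: the country
    # exposure's influence covers the individual exposure's regions and
    # extends beyond them, so the YoE set is a random half of the EQ set.
    k_eff = int(round(config.effect_topography * n_vox))
    perm = rng.permutation(n_vox)
    eq_vox = np.sort(perm[:k_eff])
    yoe_vox = np.sort(rng.choice(eq_vox, size=k_eff // 2, replace=False)) if k_eff else eq_vox
    baseline = rng.uniform(0.02, 0.98, size=n_vox)
    # tissue-probability profile: GM segmentations have near-zero variance at
    # the intensity extremes (background / peak tissue), so between-subject
    # variability -- noise, atrophy and planted effects alike -- is scaled by
    # (4 b(1-b))^2.  This keeps the per-subject min/max (hence the min-max
    # harmonization) stable, as it is for real segmentations.
    profile = (4.0 * baseline * (1.0 - baseline)) ** 2
    atrophy = {g: np.zeros(n_vox) for g in GROUPS}
    for g in ("AD", "FTLD"):
        sel = rng.random(n_vox) < 0.3
        atrophy[g][sel] = -0.15 * profile[sel]

    signal_v = np.zeros((n, n_vox))
    signal_v[:, eq_vox] += config.beta_eq * z_eq[:, None]
    signal_v[:, yoe_vox] += config.beta_yoe * z_yoe[:, None]
    for name, coef in config.covariate_effects.items():
        if coef == 0 or name not in z_cov:
            continue
        sel = rng.random(n_vox) < 0.5
        signal_v[:, sel] += coef * z_cov[name][:, None]

    group_arr = participants["group"].to_numpy()
    atrophy_mat = np.stack([atrophy[g] for g in group_arr])
    gm_data = (
        baseline[None, :]
        + atrophy_mat
        + config.noise_sd * profile[None, :] * (signal_v + rng.normal(size=(n, n_vox)))
    )
    gm = GMImageSet(data=gm_data, mask=mask, tiv=participants["tiv"].to_numpy())

    # ---- ROI time series: latent-factor AR(1) + exposure-modulated pair signals
    n_rois, t = config.n_rois, config.n_volumes
    iu, ju = np.triu_indices(n_rois, k=1)
    n_edges = len(iu)
    k_edges = int(round(config.effect_topography * n_edges))
    eperm = rng.permutation(n_edges)
    eq_edges = np.sort(eperm[:k_edges])
    yoe_edges = (
        np.sort(rng.choice(eq_edges, size=k_edges // 2, replace=False))
        if k_edges
        else eq_edges
    )

    modules = rng.integers(0, config.n_latent_factors, size=n_rois)
    loadings = 0.1 * rng.normal(size=(n_rois, config.n_latent_factors))
    loadings[np.arange(n_rois), modules] += 0.8

    b_eq_fc = config.beta_eq if config.beta_eq_fc is None else config.beta_eq_fc
    b_yoe_fc = config.beta_yoe if config.beta_yoe_fc is None else config.beta_yoe_fc
    amp_eq = np.clip(config.fc_gain * (1.0 + b_eq_fc * z_eq), 0.0, None)
    amp_yoe = np.clip(config.fc_gain * (1.0 + b_yoe_fc * z_yoe), 0.0, None)

    # incidence matrices mapping edge signals onto their two endpoint ROIs
    def _incidence(edge_ix):
        inc = np.zeros((n_rois, len(edge_ix)))
        inc[iu[edge_ix], np.arange(len(edge_ix))] = 1.0
        inc[ju[edge_ix], np.arange(len(edge_ix))] = 1.0
        return inc

    inc_eq = _incidence(eq_edges)
    inc_yoe = _incidence(yoe_edges)

    ts = np.empty((n, n_rois, t))
    for i in range(n):
        factors = _ar1(rng, (config.n_latent_factors, t), config.ar_coef)
        noise = rng.normal(size=(n_rois, t))
        x = loadings @ factors + noise
        if k_edges:
            e_eq = _ar1(rng, (len(eq_edges), t), config.ar_coef)
            e_yoe = _ar1(rng, (len(yoe_edges), t), config.ar_coef)
            x = x + amp_eq[i] * (inc_eq @ e_eq) + amp_yoe[i] * (inc_yoe @ e_yoe)
        ts[i] = x

    truth = CohortTruth(
        beta_eq=config.beta_eq,
        beta_yoe=config.beta_yoe,
        eq_voxels=eq_vox,
        yoe_voxels=yoe_vox,
        eq_edges=eq_edges,
        yoe_edges=yoe_edges,
        covariate_effects=dict(config.covariate_effects),
        seed=config.seed,
    )
    return gm, ts, truth


def simulate_cohort(config: SyntheticConfig, harmonize: bool = True) -> SyntheticCohort:
    """Run the full generator: country table -> participants -> brain data.

    With ``harmonize=True`` (default) the GM maps are min-max scaled per
    subject, i.e. delivered in the state the statistical stages expect.
    """
    country_table = generate_country_table(config)
    eq_table = build_eq_table(country_table)
    participants = generate_participants(config, eq_table)
    gm, ts, truth = generate_brain_data(config, participants)
    if harmonize:
        gm = GMImageSet(
            data=minmax_scale_subject(gm.data),
            mask=gm.mask,
            tiv=gm.tiv,
            affine=gm.affine,
        )
    return SyntheticCohort(
        config=config,
        eq_table=eq_table,
        participants=participants,
        gm=gm,
        timeseries=ts,
        truth=truth,
    )
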