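"""Formats, validation, configuration and the end-to-end pipeline runner.

Participant tables are TSV/CSV with one row per subject; rows violating the
schema (duplicate ids, unknown group labels, years of education outside
0-20, MMSE outside 0-30) are rejected with per-row diagnostics.  GM maps and
masks round-trip through NIfTI; time series and edge tables through CSV/TSV;
reports, manifests and truth records through JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GROUP_VOCAB = ("HC", "AD", "FTLD")
REQUIRED_COLUMNS = ("subject_id", "country", "group", "age", "sex", "yoe", "mmse")
OPTIONAL_COLUMNS = (
    "tiv", "eyes_condition", "eq", "ses", "gini", "gdp", "snr_t1", "snr_fmri", "tsnr",
)

__all__ = [
    "read_participants",
    "write_participants",
    "ParticipantValidationError",
    "save_gm_nifti",
    "load_gm_nifti",
    "RunConfig",
    "run_full_pipeline",
]


class ParticipantValidationError(ValueError):
    """Raised when participant rows violate the schema; carries diagnostics."""

    def __init__(self, diagnostics: list[dict]):
        self.diagnostics = diagnostics
        lines = "; ".join(
            f"row {d['row']} ({d['subject_id']}): {d['rule']}" for d in diagnostics[:10]
        )
        super().__init__(f"{len(diagnostics)} invalid participant rows: {lines}")


def validate_participants(df: pd.DataFrame) -> list[dict]:
    """Return one diagnostic dict per invalid row (empty list = valid)."""
    problems: list[dict] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participant table missing required columns: {missing}")

    dup = df["subject_id"].duplicated(keep=False)
    for i in df.index[dup]:
        problems.append(
            {"row": int(i), "subject_id": str(df.at[i, "subject_id"]),
             "rule": "duplicate subject_id"}
        )
    for i in df.index:
        sid = str(df.at[i, "subject_id"])
        if df.at[i, "group"] not in GROUP_VOCAB:
            problems.append(
                {"row": int(i), "subject_id": sid,
                 "rule": f"unknown group label {df.at[i, 'group']!r}"}
            )
        yoe = df.at[i, "yoe"]
        if not np.isfinite(yoe) or not 0 <= yoe <= 20:
            problems.append(
                {"row": int(i), "subject_id": sid, "rule": "YoE range 0-20"}
            )
        mmse = df.at[i, "mmse"]
        if not np.isfinite(mmse) or not 0 <= mmse <= 30:
            problems.append(
                {"row": int(i), "subject_id": sid, "rule": "MMSE range 0-30"}
            )
    return problems


def read_participants(path, strict: bool = False) -> pd.DataFrame:
    """Read and validate a participant TSV/CSV.

    Invalid rows are dropped (with diagnostics stored in
    ``df.attrs["rejected"]``); ``strict=True`` raises instead.  Fully-empty
    optional columns are dropped so downstream stages can detect and disable
    the analyses that need them.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    problems = validate_participants(df)
    if problems and strict:
        raise ParticipantValidationError(problems)
    bad_rows = sorted({d["row"] for d in problems})
    df = df.drop(index=bad_rows).reset_index(drop=True)
    for col in OPTIONAL_COLUMNS:
        if col in df.columns and df[col].isna().all():
            df = df.drop(columns=[col])
    df.attrs["rejected"] = problems
    return df


def write_participants(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)
    return path


def save_gm_nifti(gm, path) -> Path:
    """Write a GMImageSet as a 4-D NIfTI (subjects along the 4th axis)."""
    import nibabel as nib

    path = Path(path)
    vol = np.zeros(gm.mask.shape + (gm.n_subjects,), dtype=np.float32)
    for i in range(gm.n_subjects):
        v = np.zeros(gm.mask.shape, dtype=np.float32)
        v[gm.mask] = gm.data[i]
        vol[..., i] = v
    nib.save(nib.Nifti1Image(vol, gm.affine), str(path))
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    nib.save(nib.Nifti1Image(gm.mask.astype(np.uint8), gm.affine), str(mask_path))
    return path


def load_gm_nifti(path, tiv=None):
    """Read a 4-D NIfTI written by :func:`save_gm_nifti` back to a GMImageSet."""
    import nibabel as nib

    from .harmonization import GMImageSet

    path = Path(path)
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    data = np.stack([vol[..., i][mask] for i in range(vol.shape[-1])])
    if tiv is None:
        tiv = np.full(data.shape[0], np.nan)
    return GMImageSet(data=data, mask=mask, tiv=np.asarray(tiv, float), affine=img.affine)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    modalities: tuple[str, ...] = ("gm", "fc")
    groups: tuple[str, ...] = ("HC", "AD", "FTLD")
    cv_folds: int = 3
    cv_reps: int = 20
    iterations: int = 100_000
    density: float = 0.3
    run_regional: bool = True
    run_wholebrain: bool = True
    run_sensitivity: tuple[str, ...] = ()
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        errors = []
        if not self.modalities:
            errors.append("modalities: at least one of gm|fc must be enabled")
        for m in self.modalities:
            if m not in ("gm", "fc"):
                errors.append(f"modalities: unknown modality {m!r}")
        for g in self.groups:
            if g not in GROUP_VOCAB:
                errors.append(f"groups: unknown group {g!r}")
        if not 0 < self.density <= 1:
            errors.append("density: must be in (0, 1]")
        if self.cv_folds < 2 or self.cv_reps < 1 or self.iterations < 1:
            errors.append("cv_folds/cv_reps/iterations: must be positive")
        for s in self.run_sensitivity:
            if s not in ("interaction", "ses", "gini_gdp", "loco", "quality"):
                errors.append(f"run_sensitivity: unknown analysis {s!r}")
        if errors:
            raise ValueError("invalid run config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"invalid run config: unknown fields {sorted(unknown)}")
        for key in ("modalities", "groups", "run_sensitivity"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Simulate (or load), harmonize, and run all enabled analysis stages.

    Writes the participant table, EQ table, whole-brain comparison grid,
    regional comparison summaries and a manifest (seeds, config, file
    hashes) under ``config.out_dir``; returns the result bundle in memory.
    """
    from . import __version__
    from .regional import RegressionSpec, compare_effect_maps, fit_mass_univariate
    from .synthetic import SyntheticConfig, simulate_cohort
    from .wholebrain import GM_COVARIATES, run_group_modality_grid
    from . import sensitivity as sens

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        syn = SyntheticConfig(**{**config.synthetic, "seed": config.seed})
        cohort = simulate_cohort(syn)
        write_participants(cohort.participants, out / "participants.tsv")
        cohort.eq_table.to_csv(out / "eq_table.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(cohort.truth.to_dict(), fh, indent=1)

        bundle: dict = {"cohort": cohort}
        if config.run_regional and "gm" in config.modalities:
            stage = "regional"
            regional_rows = []
            for group in config.groups:
                sel = (cohort.participants["group"] == group).to_numpy()
                sub = cohort.participants.loc[sel].reset_index(drop=True)
                maps = {
                    pred: fit_mass_univariate(
                        cohort.gm.data[sel], sub,
                        RegressionSpec(predictor=pred, covariates=GM_COVARIATES),
                    )
                    for pred in ("eq", "yoe")
                }
                cmp_ = compare_effect_maps(maps["eq"], maps["yoe"], unit_set="all")
                regional_rows.append(
                    {
                        "group": group,
                        "modality": "gm",
                        "n_sig_eq": int(maps["eq"].q_significant.sum()),
                        "n_sig_yoe": int(maps["yoe"].q_significant.sum()),
                        "wilcoxon_W": cmp_.W,
                        "p": cmp_.p,
                        "cohen_d": cmp_.cohen_d,
                    }
                )
            regional_df = pd.DataFrame(regional_rows)
            regional_df.to_csv(out / "regional_summary.tsv", sep="\t", index=False)
            bundle["regional"] = regional_df

        if config.run_wholebrain:
            stage = "wholebrain"
            grid = run_group_modality_grid(
                cohort,
                groups=config.groups,
                k=config.cv_folds,
                reps=config.cv_reps,
                iterations=config.iterations,
                seed=config.seed,
                density=config.density,
            )
            grid.to_csv(out / "wholebrain_grid.tsv", sep="\t", index=False)
            bundle["wholebrain"] = grid

        sens_results = {}
        for which in config.run_sensitivity:
            stage = f"sensitivity:{which}"
            common = dict(
                reps=config.cv_reps, iterations=config.iterations, seed=config.seed
            )
            if which == "interaction":
                sens_results[which] = sens.interaction_contrast(cohort, **common)
            elif which == "ses":
                sens_results[which] = sens.covariate_augmented_rerun(
                    cohort, ("ses",), **common
                )
            elif which == "gini_gdp":
                sens_results[which] = sens.covariate_augmented_rerun(
                    cohort, ("gini", "gdp"), **common
                )
            elif which == "loco":
                sens_results[which] = sens.leave_one_country_out(cohort, **common)
            elif which == "quality":
                sens_results[which] = sens.quality_screen_and_correct(cohort, **common)
        if sens_results:
            bundle["sensitivity"] = sens_results

        stage = "manifest"
        files = sorted(
            p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()
            },
            "files": {p.name: _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
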