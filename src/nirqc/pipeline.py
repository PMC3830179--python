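"""End-to-end study orchestration: design → simulate → preprocess → calibrate
→ specificity → validate → accuracy profile.

One run builds, per API, a PLS1 content model (with cross-validated factor
selection and external validation) and an intermediate-precision validation
study summarized as an accuracy profile; a single shared PCA identification
model screens specificity challenges.  All randomness flows from the one
config seed through deterministic substreams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .design import (
    hgc_formulation,
    make_blend_design,
    specificity_proof_set,
)
from .pls import (
    CVResult,
    PLSModel,
    cross_validate,
    error_interval,
    fit_pls1,
    predict,
    rmsep,
)
from .preprocess import PreprocessPlan, paper_plan
from .profile import AccuracyProfile, accuracy_profile
from .simulate import (
    SpectraSet,
    default_library,
    simulate_set,
    simulate_specificity_set,
    simulate_validation_study,
)
from .specificity import PCAModel, classify, fit_pca

__all__ = [
    "CalibrationResult",
    "calibrate_api",
    "run_validation_study",
    "run_specificity_screen",
    "run_full_study",
    "stage_seeds",
]

log = logging.getLogger("nirqc")


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    """Deterministic per-stage seed substreams from the single run seed."""
    ss = np.random.SeedSequence(seed)
    names = (
        "cal_AZ",
        "val_AZ",
        "study_AZ",
        "cal_AS",
        "val_AS",
        "study_AS",
        "challenge",
    )
    return dict(zip(names, ss.spawn(len(names))))


@dataclass
class CalibrationResult:
    api: str
    plan: PreprocessPlan
    model: PLSModel
    cv: CVResult
    calibration: SpectraSet
    validation: SpectraSet
    merit: dict


def _library(config: RunConfig):
    return default_library(
        seed=config.library_seed,
        dha_shift=config.dha_shift_cm1,
        dha_height_scale=config.dha_height_scale,
    )


def calibrate_api(
    api: str,
    config: RunConfig,
    cal_seed: np.random.SeedSequence | int,
    val_seed: np.random.SeedSequence | int,
) -> CalibrationResult:
    """Build and externally validate the PLS1 content model for one API."""
    form = hgc_formulation()
    library = _library(config)
    cal_design = make_blend_design(
        form,
        api,
        levels=config.calibration_levels,
        total_mass=config.calibration_total_mg,
        replicates=config.calibration_replicates,
        role="calibration",
    )
    val_design = make_blend_design(
        form,
        api,
        levels=config.validation_levels,
        total_mass=config.validation_total_mg,
        replicates=config.validation_replicates,
        role="validation",
    )
    cal = simulate_set(
        cal_design, library, config.grid, config.noise, config.repacks, cal_seed
    )
    val = simulate_set(
        val_design, library, config.grid, config.noise, config.repacks, val_seed
    )
    plan = paper_plan()
    F_cal = plan.fit_transform(cal)
    y_cal = cal.meta[f"percent_{api}"].to_numpy()
    cv = cross_validate(
        F_cal,
        y_cal,
        max_factors=config.max_factors,
        n_splits=config.cv_splits,
        strata=cal.meta["level_percent"].to_numpy(),
    )
    model = fit_pls1(F_cal, y_cal, cv.n_factors)
    F_val = plan.transform(val)
    y_val = val.meta[f"percent_{api}"].to_numpy()
    yhat_val = predict(model, F_val)
    lo, hi = error_interval(y_val, yhat_val)
    merit = {
        "api": api,
        "n_factors": model.n_factors,
        "r": model.r,
        "rmsec": model.rmsec,
        "rmsep": rmsep(model, F_val, y_val),
        "error_low": lo,
        "error_high": hi,
    }
    log.info(
        "calibrated %s: %d factors, r=%.4f, RMSEC=%.3f, RMSEP=%.3f",
        api, model.n_factors, model.r, merit["rmsec"], merit["rmsep"],
    )
    return CalibrationResult(api, plan, model, cv, cal, val, merit)


def run_validation_study(
    result: CalibrationResult,
    config: RunConfig,
    seed: np.random.SeedSequence | int,
) -> tuple[AccuracyProfile, pd.DataFrame]:
    """Simulate the intermediate-precision study (series × replicates per
    level), predict recovered contents and build the accuracy profile."""
    form = hgc_formulation()
    library = _library(config)
    design = make_blend_design(
        form,
        result.api,
        levels=config.profile_levels,
        total_mass=config.validation_total_mg,
        replicates=config.series_replicates,
        role="validation",
    )
    study = simulate_validation_study(
        design,
        library,
        config.grid,
        config.noise,
        n_series=config.n_series,
        repacks=config.repacks,
        series_gain_sd=config.series_gain_sd,
        seed=seed,
    )
    F = result.plan.transform(study)
    recovered = predict(result.model, F)
    data = study.meta[["level_percent", "series_id", "replicate_id"]].copy()
    data["recovered_percent"] = recovered
    prof = accuracy_profile(data, config.beta, config.acceptance_limit)
    log.info(
        "%s accuracy profile: %s",
        result.api,
        "PASS" if prof.passed else "FAIL",
    )
    return prof, data


def run_specificity_screen(
    results: list[CalibrationResult],
    config: RunConfig,
    seed: np.random.SeedSequence | int,
) -> dict:
    """Fit the shared PCA identification model on all calibration spectra and
    screen the challenge proof-set plus the genuine validation spectra."""
    library = _library(config)
    plan = paper_plan()
    combined = SpectraSet(
        results[0].calibration.grid,
        np.vstack([r.calibration.absorbance for r in results]),
        pd.concat([r.calibration.meta for r in results], ignore_index=True),
    )
    F_train = plan.fit_transform(combined)
    pca = fit_pca(
        F_train,
        n_components=config.pca_components,
        score_quantile=config.score_quantile,
        residual_sds=config.residual_sds,
    )
    challenges = simulate_specificity_set(
        specificity_proof_set(),
        library,
        config.grid,
        config.noise,
        repacks=config.repacks,
        seed=seed,
    )
    verdict_challenge = classify(
        pca, plan.transform(challenges), challenges.meta["label"].tolist()
    )
    genuine = SpectraSet(
        combined.grid,
        np.vstack([r.validation.absorbance for r in results]),
        pd.concat([r.validation.meta for r in results], ignore_index=True),
    )
    verdict_genuine = classify(
        pca, plan.transform(genuine), genuine.meta["sample"].tolist()
    )
    reject_rate = float(np.mean(verdict_challenge["verdict"] == "reject"))
    accept_rate = float(np.mean(verdict_genuine["verdict"] == "accept"))
    log.info(
        "specificity: challenge rejection %.0f%%, genuine acceptance %.1f%%",
        100 * reject_rate, 100 * accept_rate,
    )
    return {
        "pca": pca,
        "plan": plan,
        "explained_pc12": float(np.sum(pca.explained_variance[:2])),
        "challenge_verdicts": verdict_challenge,
        "genuine_verdicts": verdict_genuine,
        "challenge_reject_rate": reject_rate,
        "genuine_accept_rate": accept_rate,
    }


def run_full_study(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole quality-control study and return a JSON-serializable
    report (merit table per API, specificity summary, accuracy profiles)."""
    seeds = stage_seeds(config.seed)
    results: list[CalibrationResult] = []
    profiles: dict[str, AccuracyProfile] = {}
    profile_data: dict[str, pd.DataFrame] = {}
    for api in config.apis:
        res = calibrate_api(api, config, seeds[f"cal_{api}"], seeds[f"val_{api}"])
        prof, data = run_validation_study(res, config, seeds[f"study_{api}"])
        results.append(res)
        profiles[api] = prof
        profile_data[api] = data
    spec = run_specificity_screen(results, config, seeds["challenge"])
    report = {
        "nirqc_version": __version__,
        "config": config.to_dict(),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "merit_table": [r.merit for r in results],
        "specificity": {
            "explained_variance_pc12_percent": spec["explained_pc12"],
            "challenge_reject_rate": spec["challenge_reject_rate"],
            "genuine_accept_rate": spec["genuine_accept_rate"],
            "challenge_verdicts": spec["challenge_verdicts"].to_dict("records"),
        },
        "accuracy_profiles": {
            api: {
                "passed": prof.passed,
                "beta": prof.beta,
                "acceptance_limit": prof.acceptance_limit,
                "levels": prof.to_frame().to_dict("records"),
            }
            for api, prof in profiles.items()
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame([r.merit for r in results]).to_csv(
            outdir / "merit_table.csv", index=False
        )
        for api, prof in profiles.items():
            prof.to_frame().to_csv(outdir / f"profile_{api}.csv", index=False)
            profile_data[api].to_csv(outdir / f"validation_{api}.csv", index=False)
            from .profile import plot_profile

            ax = plot_profile(prof, title=f"{api} accuracy profile")
            ax.figure.savefig(outdir / f"profile_{api}.png", dpi=150)
        spec["challenge_verdicts"].to_csv(outdir / "specificity.csv", index=False)
    report["_objects"] = {
        "calibrations": results,
        "profiles": profiles,
        "specificity": spec,
    }
    return report
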