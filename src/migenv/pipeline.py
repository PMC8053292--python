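"""End-to-end study orchestration.

Stages: score the event streams, ascertain cases, frequency-match
controls, link exposures, apply the exclusion cascade, then fit the
configured model grid:

* case-control — 4 continuous-exposure logistic GLMMs, 2 binary-exposure
  secondary GLMMs, and a penalized-spline nonlinearity check per
  continuous exposure;
* case-case — 4 exposures x 5 severity outcomes (negative-binomial for the
  three count outcomes with log person-year offsets, logistic for the two
  dichotomous ones) plus 2 binary exposures x 5 outcomes;
* sensitivity — emitter-category split, additional BMI/marital adjustment,
  and distance-to-nearest-ED adjustment for the ED outcome.

Every fitted model appears in the output table, converged or not; nothing
is dropped silently. Exclusions follow the printed order (outside study
counties, missing block-group poverty, missing PM2.5) and a record failing
several filters is counted at the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from migenv import ascertain, diagnostics, exposure as expo, glmm, matching, spline
from migenv.geo import cross_distance_km

log = logging.getLogger("migenv.pipeline")

CONTINUOUS_EXPOSURES = (
    "pm25_per5",
    "no2_per5",
    "methane_idw_per1e5",
    "well_idw_per1e3",
)
BINARY_EXPOSURES = ("any_emitter_10km", "any_well_10km")
SPLIT_EXPOSURES = (
    "methane_idw_dairy_landfill_per1e5",
    "methane_idw_other_industrial_per1e5",
)

#: (outcome column, family) for the case-case grid
CASE_CASE_OUTCOMES = (
    ("neurology_count", "negbin"),
    ("urgent_care_count", "negbin"),
    ("triptan_count", "negbin"),
    ("any_migraine_ed", "logistic"),
    ("mpa_gt_100", "logistic"),
)

DEFAULT_COVARIATES = (
    "age_cat",
    "sex",
    "race",
    "medicaid",
    "pc_visits_py",
    "pop_density",
    "poverty_pct",
)


@dataclass
class StudyConfig:
    paths: dict[str, str] = field(default_factory=dict)
    radius_km: float = 10.0
    min_distance_km: float = 0.05
    metric: str = "geodesic"
    mpa: ascertain.MPAConfig = field(default_factory=ascertain.MPAConfig)
    ratio: int = 3
    seed: int = 0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    county_filter: tuple[str, ...] | None = None
    n_quad: int = 15
    rescale: expo.RescaleConstants = field(default_factory=expo.RescaleConstants)
    sensitivity: dict[str, bool] = field(
        default_factory=lambda: {"split": True, "bmi_marital": True, "distance_ed": True}
    )
    spline_checks: bool = True
    moran_n_perm: int = 199
    moran_max_n: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mpa" in raw:
            mpa = raw.pop("mpa")
            raw["mpa"] = (
                ascertain.MPAConfig.from_yaml(mpa)
                if isinstance(mpa, str)
                else ascertain.MPAConfig(**mpa)
            )
        if "rescale" in raw:
            raw["rescale"] = expo.RescaleConstants(**raw["rescale"])
        for key in ("covariates", "county_filter"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# exclusion cascade


EXCLUSION_STEPS = ("outside_county", "missing_poverty", "missing_pm25")


@dataclass
class ExclusionReport:
    initial: dict[str, int]
    removed: dict[str, dict[str, int]]  # step -> {"case": n, "control": n}
    final: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": "initial", "cases": self.initial["case"], "controls": self.initial["control"]}
        ]
        for step in EXCLUSION_STEPS:
            rows.append(
                {
                    "step": step,
                    "cases": -self.removed[step]["case"],
                    "controls": -self.removed[step]["control"],
                }
            )
        rows.append(
            {"step": "final", "cases": self.final["case"], "controls": self.final["control"]}
        )
        return pd.DataFrame(rows)

    def check_arithmetic(self) -> bool:
        for arm in ("case", "control"):
            total_removed = sum(self.removed[s][arm] for s in EXCLUSION_STEPS)
            if self.final[arm] != self.initial[arm] - total_removed:
                return False
        return True


def apply_exclusions(
    cohort: pd.DataFrame,
    county_filter,
    arm_col: str = "arm",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the three exclusion filters in their fixed order.

    ``cohort`` needs columns ``arm`` ("case"/"control"), ``county``,
    ``poverty_pct`` and ``pm25``. A record failing several filters counts
    at the first; the report arithmetic is exact per arm.
    """
    county_filter = set(county_filter)
    arms = cohort[arm_col].to_numpy()
    masks = {
        "outside_county": ~cohort["county"].isin(county_filter).to_numpy(),
        "missing_poverty": cohort["poverty_pct"].isna().to_numpy(),
        "missing_pm25": cohort["pm25"].isna().to_numpy(),
    }
    removed_so_far = np.zeros(len(cohort), dtype=bool)
    removed: dict[str, dict[str, int]] = {}
    initial = {
        "case": int((arms == "case").sum()),
        "control": int((arms == "control").sum()),
    }
    for step in EXCLUSION_STEPS:
        hit = masks[step] & ~removed_so_far
        removed[step] = {
            "case": int((hit & (arms == "case")).sum()),
            "control": int((hit & (arms == "control")).sum()),
        }
        removed_so_far |= hit
        log.info("exclusion %s removed %s", step, removed[step])
    kept = cohort[~removed_so_far].copy()
    karms = kept[arm_col].to_numpy()
    final = {
        "case": int((karms == "case").sum()),
        "control": int((karms == "control").sum()),
    }
    return kept, ExclusionReport(initial=initial, removed=removed, final=final)


# ---------------------------------------------------------------------------
# descriptive reporting


def category_percentages(frame: pd.DataFrame, column: str) -> pd.DataFrame:
    """Counts and one-decimal percentages of a categorical column."""
    counts = frame[column].value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "level": counts.index,
            "n": counts.to_numpy(),
            "pct": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    )


# ---------------------------------------------------------------------------
# data assembly


def load_tables(config: StudyConfig) -> dict[str, pd.DataFrame]:
    tables = {}
    for name in ("patients", "events", "block_groups", "emitters", "wells"):
        tables[name] = pd.read_csv(config.paths[name])
    if "ed_sites" in config.paths:
        tables["ed_sites"] = pd.read_csv(config.paths["ed_sites"])
    return tables


def prepare_analysis(
    config: StudyConfig, tables: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, ExclusionReport, matching.MatchedCohort]:
    """Score, match, link exposures and apply exclusions.

    Returns the analysis frame (one row per retained subject, ``arm`` plus
    the outcome, exposure and covariate columns), the exclusion report and
    the matched-cohort object.
    """
    patients = tables["patients"]
    events = tables["events"]
    scored = ascertain.score_cohort(events, patients["patient_id"], config.mpa)
    log.info("scored %d patients, %d cases", len(scored), int(scored["is_case"].sum()))

    flags = scored[["patient_id", "is_case"]]
    pats = patients.merge(flags, on="patient_id")
    cases = pats[pats["is_case"]]
    pool = pats[~pats["is_case"]]
    cohort = matching.frequency_match(cases, pool, ratio=config.ratio, seed=config.seed)
    frame = matching.matched_table(cohort, patients)

    exp_table = expo.compute_exposure_table(
        frame,
        tables["emitters"],
        tables["wells"],
        tables["block_groups"],
        radius_km=config.radius_km,
        min_distance_km=config.min_distance_km,
        metric=config.metric,
        constants=config.rescale,
    )
    frame = frame.merge(exp_table, on="patient_id")

    counties = config.county_filter
    if counties is None:
        counties = tuple(sorted(tables["block_groups"]["county"].unique()))
    frame, report = apply_exclusions(frame, counties)
    frame = frame.copy()
    frame["case"] = (frame["arm"] == "case").astype(int)

    severity = ascertain.severity_table(scored, patients)
    frame = frame.merge(severity.drop(columns=["person_years"]), on="patient_id", how="left")

    if "ed_sites" in tables and len(tables["ed_sites"]):
        d = cross_distance_km(
            frame[["lat", "lon"]].to_numpy(dtype=float),
            tables["ed_sites"][["lat", "lon"]].to_numpy(dtype=float),
            config.metric,
        )
        frame["dist_ed_km"] = d.min(axis=1)
    return frame, report, cohort


# ---------------------------------------------------------------------------
# model grids


def _fit(spec: glmm.ModelSpec, data: pd.DataFrame, analysis: str, fits, rows):
    fit = glmm.fit_glmm(spec, data)
    fits.append((analysis, fit))
    tab = glmm.effect_table([fit])
    tab.insert(0, "analysis", analysis)
    rows.append(tab)
    return fit


def run_case_control(
    config: StudyConfig, frame: pd.DataFrame
) -> tuple[pd.DataFrame, list, list[spline.SplineFit]]:
    """4 continuous + 2 binary logistic GLMMs and per-exposure spline checks."""
    fits: list = []
    rows: list[pd.DataFrame] = []
    sigma_by_exposure: dict[str, float] = {}
    for exp_col in CONTINUOUS_EXPOSURES + BINARY_EXPOSURES:
        spec = glmm.ModelSpec(
            family="logistic",
            outcome="case",
            exposure=exp_col,
            covariates=config.covariates,
            group="county",
            n_quad=config.n_quad,
        )
        fit = _fit(spec, frame, "case_control", fits, rows)
        sigma_by_exposure[exp_col] = fit.sigma_u
        log.info("case-control %s: %s", exp_col, fit.effects.to_dict("records"))
    splines: list[spline.SplineFit] = []
    if config.spline_checks:
        for exp_col in CONTINUOUS_EXPOSURES:
            ridge = 1.0 / max(sigma_by_exposure[exp_col], 0.05) ** 2
            splines.append(
                spline.spline_exposure_fit(
                    frame,
                    outcome="case",
                    exposure=exp_col,
                    covariates=config.covariates,
                    group="county",
                    group_ridge=ridge,
                )
            )
    return pd.concat(rows, ignore_index=True), fits, splines


def run_case_case(config: StudyConfig, frame: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """(4 continuous + 2 binary exposures) x 5 severity outcomes, cases only."""
    cases = frame[frame["case"] == 1]
    fits: list = []
    rows: list[pd.DataFrame] = []
    for outcome, family in CASE_CASE_OUTCOMES:
        for exp_col in CONTINUOUS_EXPOSURES + BINARY_EXPOSURES:
            spec = glmm.ModelSpec(
                family=family,
                outcome=outcome,
                exposure=exp_col,
                covariates=config.covariates,
                group="county",
                offset="person_years" if family == "negbin" else None,
                n_quad=config.n_quad,
            )
            _fit(spec, cases, "case_case", fits, rows)
    return pd.concat(rows, ignore_index=True), fits


def run_sensitivity(config: StudyConfig, frame: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """The three labelled sensitivity re-runs, per the configured toggles."""
    cases = frame[frame["case"] == 1]
    fits: list = []
    rows: list[pd.DataFrame] = []

    if config.sensitivity.get("split", False):
        spec = glmm.ModelSpec(
            family="logistic",
            outcome="case",
            exposure=SPLIT_EXPOSURES,
            covariates=config.covariates,
            group="county",
            n_quad=config.n_quad,
        )
        _fit(spec, frame, "sensitivity_split", fits, rows)
        for outcome, family in CASE_CASE_OUTCOMES:
            spec = glmm.ModelSpec(
                family=family,
                outcome=outcome,
                exposure=SPLIT_EXPOSURES,
                covariates=config.covariates,
                group="county",
                offset="person_years" if family == "negbin" else None,
                n_quad=config.n_quad,
            )
            _fit(spec, cases, "sensitivity_split", fits, rows)

    if config.sensitivity.get("bmi_marital", False):
        covs = config.covariates + ("bmi_cat", "marital")
        for exp_col in CONTINUOUS_EXPOSURES:
            spec = glmm.ModelSpec(
                family="logistic",
                outcome="case",
                exposure=exp_col,
                covariates=covs,
                group="county",
                n_quad=config.n_quad,
            )
            _fit(spec, frame, "sensitivity_bmi_marital", fits, rows)

    if config.sensitivity.get("distance_ed", False):
        if "dist_ed_km" not in frame.columns:
            raise ValueError("distance_ed sensitivity needs an ed_sites table")
        covs = config.covariates + ("dist_ed_km",)
        for exp_col in CONTINUOUS_EXPOSURES:
            spec = glmm.ModelSpec(
                family="logistic",
                outcome="any_migraine_ed",
                exposure=exp_col,
                covariates=covs,
                group="county",
                n_quad=config.n_quad,
            )
            _fit(spec, cases, "sensitivity_distance_ed", fits, rows)

    if not rows:
        return glmm.effect_table([]).assign(analysis=[]), fits
    return pd.concat(rows, ignore_index=True), fits


def expected_grid_size(config: StudyConfig) -> int:
    """Number of fitted models implied by the configuration."""
    n = 6 + 30  # case-control + case-case
    if config.sensitivity.get("split", False):
        n += 1 + 5
    if config.sensitivity.get("bmi_marital", False):
        n += 4
    if config.sensitivity.get("distance_ed", False):
        n += 4
    return n


def run_moran(
    config: StudyConfig, frame: pd.DataFrame, fits: list
) -> pd.DataFrame:
    """Moran's I of deviance residuals per fitted model (reporting only)."""
    rows = []
    for analysis, fit in fits:
        data = frame if fit.spec.outcome == "case" else frame[frame["case"] == 1]
        resid = glmm.deviance_residuals(fit, data)
        coords = data[["lat", "lon"]].to_numpy(dtype=float)
        if len(resid) > config.moran_max_n:
            rng = np.random.default_rng(config.seed)
            idx = rng.choice(len(resid), size=config.moran_max_n, replace=False)
            resid, coords = resid[idx], coords[idx]
        res = diagnostics.morans_i(
            resid, coords, n_perm=config.moran_n_perm, seed=config.seed
        )
        rows.append(
            {
                "analysis": analysis,
                "outcome": fit.spec.outcome,
                "exposure": ",".join(fit.spec.exposure_terms),
                "moran_i": res.I,
                "expected_i": res.expected_I,
                "p_perm": res.p_perm,
                "n_perm": res.n_perm,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: StudyConfig, outdir) -> dict[str, pd.DataFrame]:
    """Full study: assembly, all model grids, spline checks, diagnostics.

    Writes delimited results under ``outdir`` (6-significant-digit floats,
    deterministic for a fixed config and seed) and returns the tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = load_tables(config)
    frame, report, cohort = prepare_analysis(config, tables)

    cc_tab, cc_fits, splines = run_case_control(config, frame)
    ccase_tab, ccase_fits = run_case_case(config, frame)
    sens_tab, sens_fits = run_sensitivity(config, frame)
    results = pd.concat([cc_tab, ccase_tab, sens_tab], ignore_index=True)
    n_fit = len(cc_fits) + len(ccase_fits) + len(sens_fits)
    if n_fit != expected_grid_size(config):
        raise RuntimeError(
            f"model grid mismatch: fitted {n_fit}, expected {expected_grid_size(config)}"
        )
    moran_tab = run_moran(config, frame, cc_fits + ccase_fits + sens_fits)
    spline_tab = pd.DataFrame(
        [
            {
                "exposure": s.exposure,
                "edf": s.edf,
                "lambda_opt": s.lambda_opt,
                "deviance_drop": s.deviance_drop,
                "nonmonotone": s.nonmonotone,
            }
            for s in splines
        ]
    )

    out = {
        "exclusions": report.to_frame(),
        "matching_strata": cohort.strata,
        "results": results,
        "splines": spline_tab,
        "moran": moran_tab,
    }
    for name, tab in out.items():
        tab.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
    return out
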