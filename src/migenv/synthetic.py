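"""Synthetic geography, point sources, cohorts and EHR event streams.

Everything downstream (scoring, matching, exposure assessment, models) is
exercised on data from this module, whose generating parameters are known
exactly:

* a region of counties and block groups with smooth pollutant surfaces
  clipped to plausible observed ranges;
* sparse point sources (emitters with kg/hour rates, wells with an active
  flag);
* patients at jittered block-group centroids with configurable demographic
  marginals, whose latent case status follows a logistic model with county
  random intercepts and configurable exposure effects, and whose severity
  counts are negative-binomial with log person-year offsets;
* EHR event streams constructed so that, under the package's default
  scoring configuration, latent cases always score above the case
  threshold and latent controls score zero.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from migenv import exposure as expo
from migenv.geo import jitter_coords

# Northern-California-like bounding box (lat, lon)
DEFAULT_BBOX = (36.5, 40.5, -123.0, -119.5)

PM25_RANGE = (3.7, 13.3)
NO2_RANGE = (1.1, 15.2)

AGE_CATS = ("18-29", "30-44", "45-54", "55-64", "65+")
FOLLOWUP_CATS = ("0-6", "7-24", ">24")
ENTRY_YEARS = (2014, 2015, 2016, 2017, 2018)

#: demographic marginals; proportions loosely follow the published cohort
DEFAULT_MARGINALS: dict[str, dict] = {
    "age_cat": dict(zip(AGE_CATS, (0.189, 0.369, 0.215, 0.141, 0.086))),
    "sex": {"female": 0.825, "male": 0.175},
    "race": {
        "asian": 0.195,
        "black": 0.038,
        "white": 0.483,
        "other": 0.156,
        "hispanic": 0.128,
    },
    "marital": {
        "div_sep_wid": 0.070,
        "married": 0.575,
        "single": 0.236,
        "other_unknown": 0.119,
    },
    "bmi_cat": {
        "underweight": 0.020,
        "normal": 0.414,
        "overweight": 0.293,
        "obese1": 0.146,
        "obese2": 0.064,
        "obese3": 0.043,
        "missing": 0.020,
    },
    "medicaid": {"yes": 0.056, "no": 0.944},
}

SEVERITY_OUTCOMES = ("neurology", "urgent_care", "triptans", "ed", "severe")


@dataclass
class Region:
    counties: list[str]
    block_groups: pd.DataFrame  # block_group, county, lat, lon, poverty_pct,
    # pop_density, pm25, no2

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        bg = self.block_groups
        return (
            float(bg["lat"].min()),
            float(bg["lat"].max()),
            float(bg["lon"].min()),
            float(bg["lon"].max()),
        )


@dataclass
class SourceSet:
    emitters: pd.DataFrame  # source_id, lat, lon, category, emission_kg_hr
    wells: pd.DataFrame  # well_id, lat, lon, active


@dataclass
class SeverityParams:
    """Ground truth for the case-case outcomes.

    ``effects`` maps outcome -> {rescaled exposure column -> log effect};
    count outcomes share one NB2 dispersion.
    """

    dispersion: float = 0.8
    intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "neurology": -0.3,
            "urgent_care": -2.0,
            "triptans": -0.7,
            "ed": -2.8,
            "severe": -0.7,
        }
    )
    effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("NB dispersion must be positive")


@dataclass
class TrueModel:
    """Ground-truth parameters of the case-status and severity models."""

    intercept: float = -1.2
    exposure_betas: dict[str, float] = field(default_factory=dict)
    covariate_betas: dict[str, float | dict[str, float]] = field(default_factory=dict)
    county_sigma: float = 0.3
    severity: SeverityParams = field(default_factory=SeverityParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.county_sigma < 0:
            raise ValueError("county_sigma must be nonnegative")
        vals = [self.intercept, self.county_sigma, *self.exposure_betas.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("TrueModel parameters must be finite")


# ---------------------------------------------------------------------------
# geography


def _smooth_surface(lat, lon, rng, lo, hi):
    """Low-order trend plus low-frequency sinusoids, min-max mapped to
    [lo, hi]; smooth in space by construction."""
    latn = (lat - lat.min()) / max(np.ptp(lat), 1e-9)
    lonn = (lon - lon.min()) / max(np.ptp(lon), 1e-9)
    a = rng.normal(0.0, 1.0, size=2)
    f = a[0] * latn + a[1] * lonn
    for _ in range(4):
        u, v = rng.uniform(-1.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.2, 0.6)
        f = f + amp * np.sin(2 * np.pi * (u * latn + v * lonn) + phase)
    f = (f - f.min()) / max(np.ptp(f), 1e-9)
    return lo + f * (hi - lo)


def generate_region(
    n_counties: int,
    n_block_groups: int,
    seed: int,
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX,
    pm25_range: tuple[float, float] = PM25_RANGE,
    no2_range: tuple[float, float] = NO2_RANGE,
) -> Region:
    """Counties with spatially clustered block groups and smooth surfaces.

    Every county receives at least one block group; pollutant values are
    clipped to the configured plausible ranges.
    """
    if n_counties < 1 or n_block_groups < n_counties:
        raise ValueError("need n_counties >= 1 and n_block_groups >= n_counties")
    rng = np.random.default_rng(seed)
    lat0, lat1, lon0, lon1 = bbox
    centers = np.column_stack(
        [rng.uniform(lat0, lat1, n_counties), rng.uniform(lon0, lon1, n_counties)]
    )
    # first one block group per county, then the rest proportional to a
    # random county size profile
    county_idx = np.arange(n_counties)
    extra = rng.choice(
        n_counties,
        size=n_block_groups - n_counties,
        p=rng.dirichlet(np.ones(n_counties) * 2.0),
    )
    county_of_bg = np.concatenate([county_idx, extra])
    spread = 0.12 * min(lat1 - lat0, lon1 - lon0)
    lat = np.clip(
        centers[county_of_bg, 0] + rng.normal(0, spread, n_block_groups), lat0, lat1
    )
    lon = np.clip(
        centers[county_of_bg, 1] + rng.normal(0, spread, n_block_groups), lon0, lon1
    )
    counties = [f"C{i:02d}" for i in range(n_counties)]
    bg = pd.DataFrame(
        {
            "block_group": [f"BG{i:05d}" for i in range(n_block_groups)],
            "county": [counties[c] for c in county_of_bg],
            "lat": lat,
            "lon": lon,
            "poverty_pct": np.clip(
                _smooth_surface(lat, lon, rng, 0.0, 40.0)
                + rng.normal(0, 2.0, n_block_groups),
                0.0,
                100.0,
            ),
            "pop_density": np.clip(
                _smooth_surface(lat, lon, rng, 100.0, 4500.0)
                + rng.normal(0, 150.0, n_block_groups),
                1.0,
                None,
            ),
            "pm25": _smooth_surface(lat, lon, rng, *pm25_range),
            "no2": _smooth_surface(lat, lon, rng, *no2_range),
        }
    )
    return Region(counties=counties, block_groups=bg)


def _scatter_near_population(
    region: Region, n: int, rng: np.random.Generator, frac_near: float, sd_km: float
) -> tuple[np.ndarray, np.ndarray]:
    """Source locations: a mixture of near-population and uniform points.

    Point sources sit disproportionately near settled areas, which keeps a
    realistic share of patients inside the 10 km buffer.
    """
    lat0, lat1, lon0, lon1 = region.bbox
    bg = region.block_groups
    near = rng.random(n) < frac_near
    pick = rng.integers(0, len(bg), n)
    lat = np.where(near, bg["lat"].to_numpy()[pick], rng.uniform(lat0, lat1, n))
    lon = np.where(near, bg["lon"].to_numpy()[pick], rng.uniform(lon0, lon1, n))
    lat, lon = jitter_coords(lat, lon, sd_km, rng)
    return np.clip(lat, lat0, lat1), np.clip(lon, lon0, lon1)


def generate_sources(
    region: Region,
    n_emitters: int = 25,
    n_wells: int = 300,
    seed: int = 0,
    active_fraction: float = 0.7,
    rate_log_mean: float = 9.5,
    rate_log_sd: float = 1.5,
    frac_near: float = 0.6,
    scatter_sd_km: float = 4.0,
) -> SourceSet:
    """Sparse emitters (heavy-tailed lognormal kg/hour rates) and wells.

    All coordinates lie inside the region bounding box; a configurable
    fraction of sources clusters near block groups.
    """
    rng = np.random.default_rng(seed)
    elat, elon = _scatter_near_population(region, n_emitters, rng, frac_near, scatter_sd_km)
    emitters = pd.DataFrame(
        {
            "source_id": [f"S{i:04d}" for i in range(n_emitters)],
            "lat": elat,
            "lon": elon,
            "category": rng.choice(expo.EMITTER_CATEGORIES, size=n_emitters, p=[0.55, 0.45]),
            "emission_kg_hr": np.exp(rng.normal(rate_log_mean, rate_log_sd, n_emitters)),
        }
    )
    # wells concentrate in a handful of tight fields, so well proximity
    # varies across the cohort instead of covering (almost) everyone
    lat0, lat1, lon0, lon1 = region.bbox
    bg = region.block_groups
    n_fields = max(2, n_wells // 60)
    centers = rng.integers(0, len(bg), n_fields)
    which = rng.integers(0, n_fields, n_wells)
    wlat = bg["lat"].to_numpy()[centers][which]
    wlon = bg["lon"].to_numpy()[centers][which]
    wlat, wlon = jitter_coords(wlat, wlon, 3.0, rng)
    wells = pd.DataFrame(
        {
            "well_id": [f"W{i:05d}" for i in range(n_wells)],
            "lat": np.clip(wlat, lat0, lat1),
            "lon": np.clip(wlon, lon0, lon1),
            "active": (rng.random(n_wells) < active_fraction).astype(int),
        }
    )
    return SourceSet(emitters=emitters, wells=wells)


# ---------------------------------------------------------------------------
# cohort


def _draw_categorical(rng, marg: dict[str, float], n: int) -> np.ndarray:
    labels = list(marg.keys())
    p = np.array([marg[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def _covariate_contribution(patients: pd.DataFrame, betas) -> np.ndarray:
    out = np.zeros(len(patients))
    for col, spec in betas.items():
        if isinstance(spec, dict):
            vals = patients[col].astype(str)
            out += vals.map(lambda v: spec.get(v, 0.0)).to_numpy(dtype=float)
        else:
            out += float(spec) * patients[col].to_numpy(dtype=float)
    return out


def generate_cohort(
    region: Region,
    sources: SourceSet | None,
    n_patients: int,
    truth: TrueModel,
    with_events: bool = True,
    jitter_sd_km: float = 0.5,
    marginals: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Patients plus (optionally) their EHR event streams.

    The returned patients table carries the latent ground truth columns
    (``latent_case``, ``latent_severe``, severity counts) alongside the
    observable fields and computed exposure columns; ``write_dataset``
    separates the two when persisting. With ``with_events=False`` only the
    tabular outcomes are produced (fast path for simulation studies).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if len(region.block_groups) == 0:
        raise ValueError("region has no block groups")
    marginals = marginals or DEFAULT_MARGINALS
    rng = np.random.default_rng(truth.seed)
    bg = region.block_groups

    dens = bg["pop_density"].to_numpy(dtype=float)
    p_bg = dens / dens.sum()
    bg_idx = rng.choice(len(bg), size=n_patients, p=p_bg)
    lat, lon = jitter_coords(
        bg["lat"].to_numpy()[bg_idx], bg["lon"].to_numpy()[bg_idx], jitter_sd_km, rng
    )

    followup = _draw_categorical(rng, {"0-6": 0.15, "7-24": 0.25, ">24": 0.60}, n_patients)
    months = np.empty(n_patients)
    for cat, (lo, hi) in {"0-6": (1.0, 6.0), "7-24": (7.0, 24.0), ">24": (25.0, 60.0)}.items():
        m = followup == cat
        months[m] = rng.uniform(lo, hi, m.sum())

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n_patients)],
            "lat": lat,
            "lon": lon,
            "block_group": bg["block_group"].to_numpy()[bg_idx],
            "county": bg["county"].to_numpy()[bg_idx],
            "age_cat": _draw_categorical(rng, marginals["age_cat"], n_patients),
            "sex": _draw_categorical(rng, marginals["sex"], n_patients),
            "race": _draw_categorical(rng, marginals["race"], n_patients),
            "marital": _draw_categorical(rng, marginals["marital"], n_patients),
            "bmi_cat": _draw_categorical(rng, marginals["bmi_cat"], n_patients),
            "medicaid": _draw_categorical(rng, marginals["medicaid"], n_patients),
            "entry_year": rng.choice(ENTRY_YEARS, size=n_patients),
            "followup_cat": followup,
            "person_years": months / 12.0,
            "pc_visits_py": rng.gamma(2.0, 1.2, n_patients),
        }
    )

    if sources is None:
        sources = SourceSet(
            emitters=pd.DataFrame(columns=["source_id", "lat", "lon", "category", "emission_kg_hr"]),
            wells=pd.DataFrame(columns=["well_id", "lat", "lon", "active"]),
        )
    exp_table = expo.compute_exposure_table(
        patients, sources.emitters, sources.wells, region
    )
    patients = patients.merge(exp_table, on="patient_id")

    # latent case status: logistic with county random intercepts
    u = rng.normal(0.0, truth.county_sigma, size=len(region.counties))
    county_code = pd.Categorical(
        patients["county"], categories=region.counties
    ).codes
    eta = truth.intercept + u[county_code]
    for col, beta in truth.exposure_betas.items():
        eta = eta + beta * patients[col].to_numpy(dtype=float)
    eta = eta + _covariate_contribution(patients, truth.covariate_betas)
    case = rng.random(n_patients) < expit(eta)
    patients["latent_case"] = case.astype(int)

    # severity, cases only
    sev = truth.severity
    py = patients["person_years"].to_numpy()
    sev_eta = {}
    for oc in SEVERITY_OUTCOMES:
        e = np.full(n_patients, sev.intercepts[oc])
        for col, b in sev.effects.get(oc, {}).items():
            e = e + b * patients[col].to_numpy(dtype=float)
        sev_eta[oc] = e
    counts = {}
    for oc in ("neurology", "urgent_care", "triptans"):
        mu = py * np.exp(sev_eta[oc])
        lam = rng.gamma(1.0 / sev.dispersion, sev.dispersion * mu)
        counts[oc] = np.where(case, rng.poisson(lam), 0)
    ed = np.where(case, rng.random(n_patients) < expit(sev_eta["ed"]), False)
    severe = np.where(case, rng.random(n_patients) < expit(sev_eta["severe"]), False)

    patients["latent_severe"] = severe.astype(int)
    patients["neurology_count"] = counts["neurology"]
    patients["urgent_care_count"] = counts["urgent_care"]
    patients["triptan_count"] = counts["triptans"]
    patients["any_ed_visit"] = ed.astype(int)

    events = _build_events(patients, rng) if with_events else None
    return patients, events


def _build_events(patients: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Event rows consistent with the latent statuses under default scoring.

    Non-severe cases get 1 outpatient migraine encounter, a coin-flip
    problem-list entry and their triptan fills: score in [20, 96]. Severe
    cases get 5 outpatient encounters plus the problem-list entry, which
    caps the score at 101 (> 100) whatever else accrues. Controls get no
    events at all (score 0). Neurology and urgent-care visits never touch
    the score under the default configuration.
    """
    case = patients["latent_case"].to_numpy(dtype=bool)
    severe = patients["latent_severe"].to_numpy(dtype=bool)
    n = len(patients)
    shp = np.where(severe, True, rng.random(n) < 0.5) & case

    rows: list[pd.DataFrame] = []

    def emit(mask_or_counts, event_type, code, setting, med_class=None):
        if mask_or_counts.dtype == bool:
            counts = mask_or_counts.astype(int)
        else:
            counts = mask_or_counts
        total = int(counts.sum())
        if total == 0:
            return
        pid = np.repeat(patients["patient_id"].to_numpy(), counts)
        yrs = np.repeat(patients["entry_year"].to_numpy(), counts)
        day = rng.integers(0, 364, size=total)
        dates = pd.to_datetime(yrs.astype(str)) + pd.to_timedelta(day, unit="D")
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "date": dates.strftime("%Y-%m-%d"),
                    "event_type": event_type,
                    "code": code,
                    "care_setting": setting,
                    "med_class": med_class if med_class else "",
                }
            )
        )

    base_enc = np.where(case, np.where(severe, 5, 1), 0)
    # mix ICD-9 and ICD-10 coding for the scored encounters
    icd10 = rng.random(n) < 0.7
    emit(np.where(icd10, base_enc, 0), "encounter", "G43.909", "outpatient")
    emit(np.where(icd10, 0, base_enc), "encounter", "346.90", "outpatient")
    emit(shp, "problem_list", "G43.909", "outpatient")
    trip = patients["triptan_count"].to_numpy() * case
    emit(trip, "prescription", "", "outpatient", med_class="triptan")
    emit(patients["neurology_count"].to_numpy() * case, "encounter", "R51", "neurology")
    emit(
        patients["urgent_care_count"].to_numpy() * case,
        "encounter",
        "G43.909",
        "urgent_care",
    )
    emit(patients["any_ed_visit"].to_numpy(dtype=bool) & case, "encounter", "G43.909", "emergency")

    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "date", "event_type", "code", "care_setting", "med_class"]
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# persistence

PATIENT_COLUMNS = [
    "patient_id", "lat", "lon", "block_group", "county", "age_cat", "sex",
    "race", "marital", "bmi_cat", "medicaid", "entry_year", "followup_cat",
    "person_years", "pc_visits_py",
]

LATENT_COLUMNS = [
    "patient_id", "latent_case", "latent_severe", "neurology_count",
    "urgent_care_count", "triptan_count", "any_ed_visit",
]


def write_dataset(
    outdir,
    region: Region,
    sources: SourceSet,
    patients: pd.DataFrame,
    events: pd.DataFrame | None,
    truth: TrueModel,
) -> dict[str, Path]:
    """Write the five delimited inputs plus the ground-truth sidecar files.

    CSV, header row, UTF-8; floats at 10 significant digits so a re-read
    round-trips the analysis deterministically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def put(name, frame, cols=None):
        p = outdir / f"{name}.csv"
        (frame[cols] if cols else frame).to_csv(p, index=False, float_format="%.10g")
        paths[name] = p

    put("patients", patients, PATIENT_COLUMNS)
    if events is not None:
        put("events", events)
    put("block_groups", region.block_groups)
    put("emitters", sources.emitters)
    put("wells", sources.wells)
    put("latent", patients, LATENT_COLUMNS)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(dataclasses.asdict(truth), indent=2))
    paths["truth"] = truth_path
    return paths
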