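"""Per-patient exposure assessment.

Four exposure measures per patient:

* block-group pollutant linkage (PM2.5 ug/m3, NO2 ppb) plus block-group
  percent poverty and population density;
* inverse-distance-squared sum of point-source emissions within a buffer:
  ``sum_i E_i / d_ij**2`` over emitters i within ``radius_km`` of patient j;
* the same with E_i == 1 over active wells;
* binary presence indicators for any emitter / any active well in the buffer.

The buffer is closed (d <= radius included) and distances are floored at a
configurable minimum before squaring so a co-located source cannot dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from migenv.geo import cross_distance_km

DEFAULT_RADIUS_KM = 10.0
DEFAULT_MIN_DISTANCE_KM = 0.05

EMITTER_CATEGORIES = ("dairy_landfill", "other_industrial")


@dataclass(frozen=True)
class RescaleConstants:
    """Divisors mapping raw exposures to the model's coefficient scale."""

    pm25: float = 5.0  # per 5 ug/m3
    no2: float = 5.0  # per 5 ppb
    methane_idw: float = 100_000.0  # per 100,000 kg/hour IDW units
    well_idw: float = 1_000.0  # per 1000 IDW units


@dataclass
class ExposureProfile:
    """The seven exposure fields for one patient."""

    pm25: float
    no2: float
    methane_idw: float
    well_idw: float
    any_emitter_10km: bool
    any_well_10km: bool
    methane_idw_by_category: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pm25 <= 0 or self.no2 <= 0:
            raise ValueError("pm25 and no2 must be positive")
        if self.methane_idw < 0 or self.well_idw < 0:
            raise ValueError("IDW sums must be nonnegative")


def _idw_weights(
    d: np.ndarray, radius_km: float, min_distance_km: float
) -> np.ndarray:
    """1/d^2 with the closed-buffer mask and the distance floor applied."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    d = np.asarray(d, dtype=float)
    inside = d <= radius_km
    d_floored = np.maximum(d, min_distance_km)
    w = np.zeros_like(d_floored)
    w[inside] = 1.0 / d_floored[inside] ** 2
    return w


def idw_emission_sum(
    patient_loc,
    emitters: pd.DataFrame,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_distance_km: float = DEFAULT_MIN_DISTANCE_KM,
    metric: str = "geodesic",
) -> float:
    """Sum of E_i / d_ij^2 over emitters within the (closed) buffer.

    ``emitters`` needs columns lat, lon, emission_kg_hr. Returns 0.0 for an
    empty table or when no source lies within the buffer.
    """
    if len(emitters) == 0:
        return 0.0
    rates = emitters["emission_kg_hr"].to_numpy(dtype=float)
    if np.any(rates <= 0):
        raise ValueError("emission rates must be positive")
    pts = emitters[["lat", "lon"]].to_numpy(dtype=float)
    d = cross_distance_km(np.asarray(patient_loc, dtype=float), pts, metric)[0]
    return float(np.sum(rates * _idw_weights(d, radius_km, min_distance_km)))


def idw_well_sum(
    patient_loc,
    wells: pd.DataFrame,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_distance_km: float = DEFAULT_MIN_DISTANCE_KM,
    metric: str = "geodesic",
) -> float:
    """Sum of 1 / d_ij^2 over *active* wells within the (closed) buffer."""
    if len(wells) == 0:
        return 0.0
    active = wells["active"].astype(bool).to_numpy()
    if not active.any():
        return 0.0
    pts = wells.loc[active, ["lat", "lon"]].to_numpy(dtype=float)
    d = cross_distance_km(np.asarray(patient_loc, dtype=float), pts, metric)[0]
    return float(np.sum(_idw_weights(d, radius_km, min_distance_km)))


def link_block_group(patient, region) -> tuple[float, float, float, float]:
    """Return (pm25, no2, poverty, density) for the patient's block group.

    ``patient`` is anything with a ``block_group`` key; ``region`` a Region
    or a block-group DataFrame indexed by or containing ``block_group``.
    Raises KeyError for an unknown block-group id (the pipeline excludes
    such records).
    """
    bg_id = patient["block_group"]
    table = getattr(region, "block_groups", region)
    if "block_group" in table.columns:
        table = table.set_index("block_group")
    try:
        row = table.loc[bg_id]
    except KeyError:
        raise KeyError(f"unknown block group id {bg_id!r}") from None
    return (
        float(row["pm25"]),
        float(row["no2"]),
        float(row["poverty_pct"]),
        float(row["pop_density"]),
    )


def rescale_exposures(
    profile: ExposureProfile | pd.DataFrame,
    constants: RescaleConstants = RescaleConstants(),
):
    """Divide continuous exposures by the reporting-scale constants.

    Accepts a single :class:`ExposureProfile` (returns a rescaled copy) or
    an exposure table (returns the table with ``*_per*`` columns added).
    Binary indicators are unchanged.
    """
    if isinstance(profile, ExposureProfile):
        return replace(
            profile,
            pm25=profile.pm25 / constants.pm25,
            no2=profile.no2 / constants.no2,
            methane_idw=profile.methane_idw / constants.methane_idw,
            well_idw=profile.well_idw / constants.well_idw,
            methane_idw_by_category={
                k: v / constants.methane_idw
                for k, v in profile.methane_idw_by_category.items()
            },
        )
    out = profile.copy()
    out["pm25_per5"] = out["pm25"] / constants.pm25
    out["no2_per5"] = out["no2"] / constants.no2
    out["methane_idw_per1e5"] = out["methane_idw"] / constants.methane_idw
    out["well_idw_per1e3"] = out["well_idw"] / constants.well_idw
    for cat in EMITTER_CATEGORIES:
        col = f"methane_idw_{cat}"
        if col in out.columns:
            out[f"{col}_per1e5"] = out[col] / constants.methane_idw
    return out


def sources_within_radius_of_any(
    patient_points: np.ndarray,
    source_points: np.ndarray,
    radius_km: float = DEFAULT_RADIUS_KM,
    metric: str = "geodesic",
) -> np.ndarray:
    """Boolean mask over sources: within ``radius_km`` of >=1 patient.

    Distance matrices are built in patient chunks to bound memory.
    """
    pts_p = np.atleast_2d(np.asarray(patient_points, dtype=float))
    pts_s = np.atleast_2d(np.asarray(source_points, dtype=float))
    covered = np.zeros(len(pts_s), dtype=bool)
    chunk = 2000
    for start in range(0, len(pts_p), chunk):
        d = cross_distance_km(pts_p[start : start + chunk], pts_s, metric)
        covered |= (d <= radius_km).any(axis=0)
    return covered


def compute_exposure_table(
    patients: pd.DataFrame,
    emitters: pd.DataFrame,
    wells: pd.DataFrame,
    region,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_distance_km: float = DEFAULT_MIN_DISTANCE_KM,
    metric: str = "geodesic",
    constants: RescaleConstants = RescaleConstants(),
) -> pd.DataFrame:
    """Build the per-patient exposure table, keyed by ``patient_id``.

    Columns: the raw ExposureProfile fields, per-category methane IDW sums,
    linked block-group covariates (poverty_pct, pop_density) and the
    rescaled ``*_per*`` forms. Patients with an unknown block-group id get
    NaN pollutant/covariate values (excluded downstream, never dropped
    silently here).
    """
    bg = getattr(region, "block_groups", region)
    if "block_group" in bg.columns:
        bg = bg.set_index("block_group")
    ppts = patients[["lat", "lon"]].to_numpy(dtype=float)
    n = len(patients)

    methane = np.zeros(n)
    by_cat = {c: np.zeros(n) for c in EMITTER_CATEGORIES}
    any_emitter = np.zeros(n, dtype=bool)
    if len(emitters) > 0:
        spts = emitters[["lat", "lon"]].to_numpy(dtype=float)
        rates = emitters["emission_kg_hr"].to_numpy(dtype=float)
        if np.any(rates <= 0):
            raise ValueError("emission rates must be positive")
        cats = emitters["category"].to_numpy()
        chunk = 2000
        for start in range(0, n, chunk):
            d = cross_distance_km(ppts[start : start + chunk], spts, metric)
            w = np.maximum(d, min_distance_km) ** -2.0
            w[d > radius_km] = 0.0
            sl = slice(start, start + d.shape[0])
            any_emitter[sl] = (d <= radius_km).any(axis=1)
            methane[sl] = w @ rates
            for cat in EMITTER_CATEGORIES:
                mask = cats == cat
                if mask.any():
                    by_cat[cat][sl] = w[:, mask] @ rates[mask]

    well = np.zeros(n)
    any_well = np.zeros(n, dtype=bool)
    if len(wells) > 0:
        active = wells["active"].astype(bool).to_numpy()
        if active.any():
            wpts = wells.loc[active, ["lat", "lon"]].to_numpy(dtype=float)
            chunk = 2000
            for start in range(0, n, chunk):
                d = cross_distance_km(ppts[start : start + chunk], wpts, metric)
                w = np.maximum(d, min_distance_km) ** -2.0
                w[d > radius_km] = 0.0
                sl = slice(start, start + d.shape[0])
                any_well[sl] = (d <= radius_km).any(axis=1)
                well[sl] = w.sum(axis=1)

    linked = bg.reindex(patients["block_group"].to_numpy())
    out = pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "pm25": linked["pm25"].to_numpy(dtype=float),
            "no2": linked["no2"].to_numpy(dtype=float),
            "poverty_pct": linked["poverty_pct"].to_numpy(dtype=float),
            "pop_density": linked["pop_density"].to_numpy(dtype=float),
            "methane_idw": methane,
            "well_idw": well,
            "any_emitter_10km": any_emitter.astype(int),
            "any_well_10km": any_well.astype(int),
        }
    )
    for cat in EMITTER_CATEGORIES:
        out[f"methane_idw_{cat}"] = by_cat[cat]
    return rescale_exposures(out, constants)
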