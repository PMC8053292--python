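"""EHR scoring and outcome construction.

A patient's score in [0, 101] is assembled from three component classes:
migraine-coded encounters, a problem-list migraine entry, and fills of
migraine-specific abortive medication. A score above 10 defines a case and
a score above 100 the more-severe stratum. The published weight table is
proprietary, so the default weights here are a documented surrogate with
the same structure (three components, 0-101 range, thresholds 10 and 100)
and are fully configurable, including from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MIGRAINE_CODE_PREFIXES = ("346", "G43")

#: single-label event classes, in classification precedence order
EVENT_CLASSES = (
    "migraine_ed",
    "migraine_urgent_care",
    "migraine_encounter",
    "problem_list_migraine",
    "abortive_fill",
    "neurology_visit",
    "other",
)

ABORTIVE_CLASSES = ("triptan", "ergotamine")


@dataclass(frozen=True)
class MPAConfig:
    """Surrogate scoring weights; structure fixed, numbers replaceable."""

    w_encounter: float = 20.0
    cap_encounter: int = 5
    w_problem_list: float = 11.0
    w_fill: float = 15.0
    cap_fill: int = 3
    case_threshold: float = 10.0
    severe_threshold: float = 100.0
    max_score: float = 101.0
    # which event classes count as scored encounters; urgent-care visits are
    # excluded by default (the published criteria list inpatient, emergency
    # and outpatient encounters)
    encounter_classes: tuple[str, ...] = ("migraine_encounter", "migraine_ed")

    @classmethod
    def from_yaml(cls, path) -> "MPAConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "encounter_classes" in raw:
            raw["encounter_classes"] = tuple(raw["encounter_classes"])
        return cls(**raw)


@dataclass
class MPAResult:
    score: float
    is_case: bool
    severe: bool
    component_counts: tuple[int, int, int]  # (encounters, problem list, fills)


@dataclass
class SeverityOutcomes:
    neurology_visits_per_py: float
    migraine_urgent_care_per_py: float
    triptans_per_py: float
    any_migraine_ed: bool
    mpa_gt_100: bool
    person_years: float
    counts: dict[str, int] = field(default_factory=dict)


def _is_migraine_code(code) -> bool:
    if not isinstance(code, str):
        return False
    c = code.strip().upper()
    return any(c.startswith(p) for p in MIGRAINE_CODE_PREFIXES)


def classify_event(event) -> str:
    """Map one EHR event to a single class label.

    ``event`` is a mapping with keys event_type, code, care_setting,
    med_class (missing keys tolerated). Malformed input classifies as
    ``other``; this never raises.

    A migraine-coded encounter is labelled by its care setting (emergency,
    urgent care, else plain encounter); code matching takes precedence over
    the neurology setting, so a migraine-coded neurology visit counts as a
    migraine encounter, not a neurology visit.
    """
    etype = event.get("event_type")
    if etype == "prescription":
        if event.get("med_class") in ABORTIVE_CLASSES:
            return "abortive_fill"
        return "other"
    migraine = _is_migraine_code(event.get("code"))
    if etype == "problem_list":
        return "problem_list_migraine" if migraine else "other"
    if etype == "encounter":
        setting = event.get("care_setting")
        if migraine:
            if setting == "emergency":
                return "migraine_ed"
            if setting == "urgent_care":
                return "migraine_urgent_care"
            return "migraine_encounter"
        if setting == "neurology":
            return "neurology_visit"
    return "other"


def classify_events(events: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_event` over an events table."""
    n = len(events)
    etype = events["event_type"].astype(str).to_numpy()
    code = events["code"]
    codes = code.where(code.notna(), "").astype(str).str.strip().str.upper()
    migraine = np.zeros(n, dtype=bool)
    for p in MIGRAINE_CODE_PREFIXES:
        migraine |= codes.str.startswith(p).to_numpy()
    setting = events["care_setting"].astype(str).to_numpy()
    med = events["med_class"].astype(str).to_numpy() if "med_class" in events else np.full(n, "")

    out = np.full(n, "other", dtype=object)
    enc = etype == "encounter"
    out[enc & (setting == "neurology") & ~migraine] = "neurology_visit"
    out[enc & migraine] = "migraine_encounter"
    out[enc & migraine & (setting == "urgent_care")] = "migraine_urgent_care"
    out[enc & migraine & (setting == "emergency")] = "migraine_ed"
    out[(etype == "problem_list") & migraine] = "problem_list_migraine"
    out[(etype == "prescription") & np.isin(med, ABORTIVE_CLASSES)] = "abortive_fill"
    return pd.Series(out, index=events.index, name="event_class")


def _score_from_counts(
    n_enc: int, has_shp: bool, n_fills: int, cfg: MPAConfig
) -> float:
    raw = (
        cfg.w_encounter * min(n_enc, cfg.cap_encounter)
        + cfg.w_problem_list * (1 if has_shp else 0)
        + cfg.w_fill * min(n_fills, cfg.cap_fill)
    )
    return float(min(cfg.max_score, raw))


def mpa_score(events, cfg: MPAConfig = MPAConfig()) -> MPAResult:
    """Score one patient's event stream.

    ``events`` is a list of event mappings or a DataFrame of that patient's
    events. Returns the bounded score with case/severe flags and the three
    component counts.
    """
    if isinstance(events, pd.DataFrame):
        classes = classify_events(events) if len(events) else pd.Series(dtype=object)
        labels = classes.to_numpy()
    else:
        labels = np.array([classify_event(e) for e in events], dtype=object)
    n_enc = int(np.isin(labels, cfg.encounter_classes).sum())
    has_shp = bool((labels == "problem_list_migraine").any()) if len(labels) else False
    n_fills = int((labels == "abortive_fill").sum())
    score = _score_from_counts(n_enc, has_shp, n_fills, cfg)
    return MPAResult(
        score=score,
        is_case=score > cfg.case_threshold,
        severe=score > cfg.severe_threshold,
        component_counts=(n_enc, int(has_shp), n_fills),
    )


def score_cohort(events: pd.DataFrame, patient_ids, cfg: MPAConfig = MPAConfig()) -> pd.DataFrame:
    """Score every patient; patients with no events score 0.

    Returns a table keyed by patient_id with score, is_case, severe and the
    per-class event counts (reused by :func:`severity_table`).
    """
    patient_ids = pd.Index(patient_ids, name="patient_id")
    if len(events):
        cls = classify_events(events)
        counts = (
            pd.crosstab(events["patient_id"], cls)
            .reindex(patient_ids, fill_value=0)
            .reindex(columns=list(EVENT_CLASSES), fill_value=0)
        )
    else:
        counts = pd.DataFrame(0, index=patient_ids, columns=list(EVENT_CLASSES))
    n_enc = counts[list(cfg.encounter_classes)].sum(axis=1).to_numpy()
    has_shp = counts["problem_list_migraine"].to_numpy() > 0
    n_fills = counts["abortive_fill"].to_numpy()
    raw = (
        cfg.w_encounter * np.minimum(n_enc, cfg.cap_encounter)
        + cfg.w_problem_list * has_shp
        + cfg.w_fill * np.minimum(n_fills, cfg.cap_fill)
    )
    score = np.minimum(cfg.max_score, raw).astype(float)
    out = counts.copy()
    out.insert(0, "mpa_score", score)
    out.insert(1, "is_case", score > cfg.case_threshold)
    out.insert(2, "severe", score > cfg.severe_threshold)
    return out.reset_index()


def severity_outcomes(events, mpa: MPAResult, person_years: float) -> SeverityOutcomes:
    """The five severity outcomes for one case.

    Count outcomes are rates per person-year; the ED outcome is any-vs-none
    over the whole window regardless of follow-up length.
    """
    if not mpa.is_case:
        raise ValueError("severity outcomes are defined for cases only (score > 10)")
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if isinstance(events, pd.DataFrame):
        labels = classify_events(events).to_numpy() if len(events) else np.array([], dtype=object)
    else:
        labels = np.array([classify_event(e) for e in events], dtype=object)
    counts = {
        "neurology_visit": int((labels == "neurology_visit").sum()),
        "migraine_urgent_care": int((labels == "migraine_urgent_care").sum()),
        "abortive_fill": int((labels == "abortive_fill").sum()),
        "migraine_ed": int((labels == "migraine_ed").sum()),
    }
    return SeverityOutcomes(
        neurology_visits_per_py=counts["neurology_visit"] / person_years,
        migraine_urgent_care_per_py=counts["migraine_urgent_care"] / person_years,
        triptans_per_py=counts["abortive_fill"] / person_years,
        any_migraine_ed=counts["migraine_ed"] >= 1,
        mpa_gt_100=mpa.severe,
        person_years=float(person_years),
        counts=counts,
    )


def severity_table(scored: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Per-case severity outcomes from a scored cohort table.

    ``scored`` is the output of :func:`score_cohort`; ``patients`` supplies
    person_years. Controls are dropped.
    """
    merged = scored.merge(patients[["patient_id", "person_years"]], on="patient_id")
    cases = merged[merged["is_case"]].copy()
    py = cases["person_years"].to_numpy(dtype=float)
    if np.any(py <= 0):
        raise ValueError("person_years must be positive")
    out = pd.DataFrame(
        {
            "patient_id": cases["patient_id"].to_numpy(),
            "neurology_count": cases["neurology_visit"].to_numpy(),
            "urgent_care_count": cases["migraine_urgent_care"].to_numpy(),
            "triptan_count": cases["abortive_fill"].to_numpy(),
            "neurology_visits_per_py": cases["neurology_visit"] / py,
            "migraine_urgent_care_per_py": cases["migraine_urgent_care"] / py,
            "triptans_per_py": cases["abortive_fill"] / py,
            "any_migraine_ed": (cases["migraine_ed"] >= 1).astype(int),
            "mpa_gt_100": cases["severe"].astype(int),
            "person_years": py,
        }
    )
    return out
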