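"""Frequency matching of controls to cases.

Controls are sampled without replacement within joint strata of the four
matching variables (age category, sex, entry year, follow-up category) at a
target ratio. Strata with too few candidates keep everything available and
are reported as shortfalls rather than relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MATCH_VARS = ("age_cat", "sex", "entry_year", "followup_cat")


@dataclass
class MatchedCohort:
    cases: list
    controls: list
    strata: pd.DataFrame  # one row per stratum: counts, target, achieved ratio
    ratio: int

    @property
    def shortfall(self) -> pd.DataFrame:
        return self.strata[self.strata["n_controls"] < self.strata["target"]]


def frequency_match(
    cases: pd.DataFrame,
    candidate_pool: pd.DataFrame,
    ratio: int = 3,
    seed: int = 0,
    match_vars: tuple[str, ...] = MATCH_VARS,
) -> MatchedCohort:
    """Sample ``ratio`` controls per case within each matching stratum.

    Sampling is uniform without replacement, deterministic for a fixed
    seed (strata are visited in sorted order under one generator). The
    candidate pool must be disjoint from the cases.
    """
    if len(cases) == 0:
        raise ValueError("case set is empty")
    overlap = set(cases["patient_id"]) & set(candidate_pool["patient_id"])
    if overlap:
        raise ValueError(f"candidate pool overlaps cases: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(seed)

    key_cols = list(match_vars)
    case_counts = cases.groupby(key_cols, observed=True).size()
    pool_groups = {
        key: grp["patient_id"].to_numpy()
        for key, grp in candidate_pool.groupby(key_cols, observed=True)
    }

    chosen: list = []
    rows = []
    for key in sorted(case_counts.index.tolist(), key=str):
        n_cases = int(case_counts.loc[key])
        avail = pool_groups.get(key, np.array([], dtype=object))
        avail = np.sort(avail)
        target = ratio * n_cases
        take = min(target, len(avail))
        picked = rng.choice(avail, size=take, replace=False) if take else np.array([])
        chosen.extend(picked.tolist())
        rows.append(
            dict(
                zip(key_cols, key if isinstance(key, tuple) else (key,)),
                n_cases=n_cases,
                n_controls=take,
                target=target,
                achieved_ratio=take / n_cases,
            )
        )
    strata = pd.DataFrame(rows)
    return MatchedCohort(
        cases=cases["patient_id"].tolist(),
        controls=chosen,
        strata=strata,
        ratio=ratio,
    )


def matched_table(cohort: MatchedCohort, patients: pd.DataFrame) -> pd.DataFrame:
    """Long-format matched cohort with an arm indicator column."""
    ids = cohort.cases + cohort.controls
    arm = ["case"] * len(cohort.cases) + ["control"] * len(cohort.controls)
    frame = pd.DataFrame({"patient_id": ids, "arm": arm})
    return frame.merge(patients, on="patient_id", how="left")
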