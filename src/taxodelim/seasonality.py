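"""Monthly reproductive-activity profiles and their comparison.

Field records note the reproductive state of an individual in a given
month. Pregnancy and lactation are back-dated to the approximate month
of oestrus (about 2 months, and 2-3.5 months, earlier, respectively) so
profiles of different candidates line up on the same event. Comparison
stays descriptive: peak months, high-activity months, and Schoener's D
between month-normalized profiles; no delimitation verdict is derived
automatically because sampling effort varies too much across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEMALE_STATES = {"oestrus", "pregnant", "lactating", "inactive"}
MALE_STATES = {"enlarged_testes", "inactive"}
ACTIVE_STATES = {"oestrus", "pregnant", "lactating", "enlarged_testes"}

PREGNANCY_OFFSET = 2  # months from oestrus to diagnosable pregnancy
LACTATION_OFFSET = 3  # midpoint of the 2-3.5 month range, rounded


def backdate_oestrus(
    month: int, state: str, sex: str, lactation_offset: int = LACTATION_OFFSET
) -> int:
    """Shift a pregnancy/lactation record back to the oestrus month.

    Months are 1-12 and wrap around the year boundary; states other
    than pregnant/lactating are returned unchanged.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month {month} out of range 1-12")
    if state in {"pregnant", "lactating"} and sex != "F":
        raise ValueError(f"state {state!r} is only valid for females")
    if state == "pregnant":
        shift = PREGNANCY_OFFSET
    elif state == "lactating":
        shift = lactation_offset
    else:
        shift = 0
    return (month - 1 - shift) % 12 + 1


@dataclass
class ActivityProfile:
    species: str
    sex: str
    n_active: np.ndarray  # (12,)
    n_total: np.ndarray  # (12,)

    @property
    def proportion(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_active / np.maximum(self.n_total, 1), np.nan)

    @property
    def is_empty(self) -> bool:
        return int(self.n_total.sum()) == 0


def activity_profile(records: pd.DataFrame, species: str, sex: str) -> ActivityProfile:
    """Monthly counts of reproductively active vs surveyed individuals
    after oestrus back-dating.

    `records` columns: species, sex, month, state.
    """
    sub = records[(records["species"] == species) & (records["sex"] == sex)]
    n_active = np.zeros(12, dtype=int)
    n_total = np.zeros(12, dtype=int)
    for r in sub.itertuples():
        valid = FEMALE_STATES if r.sex == "F" else MALE_STATES
        if r.state not in valid:
            raise ValueError(f"state {r.state!r} invalid for sex {r.sex!r}")
        m = backdate_oestrus(int(r.month), r.state, r.sex)
        n_total[m - 1] += 1
        if r.state in ACTIVE_STATES:
            n_active[m - 1] += 1
    return ActivityProfile(species, sex, n_active, n_total)


@dataclass
class SeasonalReport:
    species: tuple[str, str]
    peaks: dict[str, list[int]]
    high_activity_months: dict[str, list[int]]
    schoener_d: float
    masked_months: dict[str, list[int]] = field(default_factory=dict)
    note: str = ""


def seasonal_comparison(
    profile_a: ActivityProfile,
    profile_b: ActivityProfile,
    min_total: int = 1,
) -> SeasonalReport:
    """Descriptive comparison of two monthly activity profiles.

    Months surveyed below `min_total` individuals are masked. The
    Schoener's D index treats each profile's active counts as a
    month-normalized distribution; it is descriptive only.
    """
    if profile_a.is_empty or profile_b.is_empty:
        return SeasonalReport(
            species=(profile_a.species, profile_b.species),
            peaks={},
            high_activity_months={},
            schoener_d=float("nan"),
            note="insufficient data: at least one profile is empty",
        )
    out_peaks, out_high, masked = {}, {}, {}
    dists = []
    for p in (profile_a, profile_b):
        prop = p.proportion.copy()
        mask = p.n_total < min_total
        prop[mask] = np.nan
        masked[p.species] = (np.flatnonzero(mask) + 1).tolist()
        peak = np.nanmax(prop) if np.isfinite(prop).any() else np.nan
        out_peaks[p.species] = (
            (np.flatnonzero(prop == peak) + 1).tolist() if np.isfinite(peak) else []
        )
        out_high[p.species] = (np.flatnonzero(prop > 0.5) + 1).tolist()
        w = np.where(np.isfinite(prop), prop, 0.0)
        dists.append(w / w.sum() if w.sum() > 0 else np.full(12, 1 / 12))
    d = float(1.0 - 0.5 * np.abs(dists[0] - dists[1]).sum())
    return SeasonalReport(
        species=(profile_a.species, profile_b.species),
        peaks=out_peaks,
        high_activity_months=out_high,
        schoener_d=d,
        masked_months=masked,
    )
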