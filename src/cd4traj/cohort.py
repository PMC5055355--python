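"""Long-format visit records: container, CSV round-trip, eligibility filters.

A cohort is a long table with one row per clinic visit:

    patient_id, sex, age_group, age_at_init, visit_time_years, cd4_count

``visit_time_years`` is relative to ART initiation (negative = pre-ART, up
to 2 months allowed); ``cd4_count`` in cells/mm^3.  Eligibility mirrors the
source study's inclusion rules: adults (>= 19 years at initiation), a
baseline CD4 measurement within [-2, +3] months of initiation, and at least
five CD4-measured visits after dropping visits more than 2 months pre-ART.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structures import AGE_GROUPS, SEXES

__all__ = [
    "Cohort",
    "ExclusionLog",
    "apply_eligibility_filters",
    "descriptive_table",
    "read_cohort",
    "VISIT_COLUMNS",
]

VISIT_COLUMNS = ["patient_id", "sex", "age_group", "age_at_init", "visit_time_years", "cd4_count"]

# eligibility windows, in years; months are 1/12 year throughout
PRE_ART_CUTOFF = -2.0 / 12.0
BASELINE_WINDOW = (-2.0 / 12.0, 3.0 / 12.0)
MIN_VISITS = 5
MIN_AGE = 19.0

#: Table-1-style baseline CD4 bands, closed on the upper bound
CD4_BANDS = ((0, 50), (51, 200), (201, 350), (351, 500), (501, np.inf))
CD4_BAND_LABELS = ("0-50", "51-200", "201-350", "351-500", "500+")


@dataclass
class Cohort:
    """Visit-level records plus optional latent truth from the simulator.

    ``latent`` (per-patient true trajectory parameters) exists only for
    synthetic cohorts and is oracle-only: the fitting code never reads it.
    """

    visits: pd.DataFrame
    latent: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in VISIT_COLUMNS if c not in self.visits.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.visits = self.visits.reset_index(drop=True)

    @property
    def n_patients(self) -> int:
        return self.visits["patient_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def patients(self) -> pd.DataFrame:
        """One row per patient: demographics, visit count, follow-up span."""
        g = self.visits.groupby("patient_id", sort=True)
        out = g.agg(
            sex=("sex", "first"),
            age_group=("age_group", "first"),
            age_at_init=("age_at_init", "first"),
            n_visits=("cd4_count", "size"),
            first_visit=("visit_time_years", "min"),
            last_visit=("visit_time_years", "max"),
        )
        out["followup_years"] = out["last_visit"] - out["first_visit"]
        return out

    def baseline_cd4(self) -> pd.Series:
        """Earliest in-window CD4 measurement per patient (cells/mm^3)."""
        w = self.visits[
            (self.visits["visit_time_years"] >= BASELINE_WINDOW[0])
            & (self.visits["visit_time_years"] <= BASELINE_WINDOW[1])
        ]
        w = w.sort_values(["patient_id", "visit_time_years"], kind="mergesort")
        return w.groupby("patient_id", sort=True)["cd4_count"].first()

    # ---- round-trip ----------------------------------------------------
    def to_csv(self, path, write_sidecar: bool = True) -> None:
        path = Path(path)
        self.visits.to_csv(path, index=False)
        if self.latent is not None:
            self.latent.to_csv(path.with_suffix(".latent.csv"), index=False)
        if write_sidecar and self.meta:
            with open(path.with_suffix(".meta.yaml"), "w") as fh:
                yaml.safe_dump(self.meta, fh, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        path = Path(path)
        visits = pd.read_csv(path)
        latent = None
        lp = path.with_suffix(".latent.csv")
        if lp.exists():
            latent = pd.read_csv(lp)
        meta = {}
        mp = path.with_suffix(".meta.yaml")
        if mp.exists():
            with open(mp) as fh:
                meta = yaml.safe_load(fh) or {}
        return cls(visits=visits, latent=latent, meta=meta)


def read_cohort(path) -> Cohort:
    return Cohort.from_csv(path)


@dataclass
class ExclusionLog:
    """Per-criterion accounting of dropped rows and patients, in order applied.

    The conservation identity ``n_patients_in == n_patients_out + sum of
    patient exclusions`` holds on every input.
    """

    n_patients_in: int = 0
    n_patients_out: int = 0
    n_visits_in: int = 0
    n_visits_out: int = 0
    bad_rows: int = 0
    visits_missing_cd4: int = 0
    visits_pre_window: int = 0
    patients_excluded: dict = field(default_factory=dict)  # criterion -> count

    def check_conservation(self) -> bool:
        return self.n_patients_in == self.n_patients_out + sum(self.patients_excluded.values())


def _coerce_raw(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Type-coerce a permissive raw table; count unparseable rows."""
    df = raw.copy()
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw visit table missing columns: {missing}")
    df["cd4_count"] = pd.to_numeric(df["cd4_count"], errors="coerce")
    df["visit_time_years"] = pd.to_numeric(df["visit_time_years"], errors="coerce")
    df["age_at_init"] = pd.to_numeric(df["age_at_init"], errors="coerce")
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    df["age_group"] = df["age_group"].astype(str).str.strip()
    # rows whose structural fields cannot be parsed at all (time, sex, age)
    bad = (
        df["visit_time_years"].isna()
        | df["age_at_init"].isna()
        | ~df["sex"].isin(SEXES)
        | ~df["age_group"].isin(AGE_GROUPS)
    )
    return df[~bad].copy(), int(bad.sum())


def apply_eligibility_filters(raw: pd.DataFrame) -> tuple[Cohort, ExclusionLog]:
    """Apply the study inclusion rules to a raw long-format visit table.

    Order (logged, because it affects per-criterion counts):
    parse -> drop missing-CD4 visits -> drop visits before -2 months ->
    age >= 19 -> baseline CD4 in [-2, +3] months -> >= 5 remaining visits.
    """
    log = ExclusionLog(n_patients_in=raw["patient_id"].nunique() if len(raw) else 0, n_visits_in=len(raw))
    df, log.bad_rows = _coerce_raw(raw)

    m = df["cd4_count"].isna() | (df["cd4_count"] <= 0)
    log.visits_missing_cd4 = int(m.sum())
    df = df[~m]

    m = df["visit_time_years"] < PRE_ART_CUTOFF
    log.visits_pre_window = int(m.sum())
    df = df[~m]

    patients = df.groupby("patient_id", sort=True)
    age = patients["age_at_init"].first()
    current = set(age.index)
    # patients whose every visit was dropped above never reach the criteria
    lost = log.n_patients_in - len(current)
    if lost:
        log.patients_excluded["no_parseable_cd4_visits"] = lost

    ok_age = set(age[age >= MIN_AGE].index)
    log.patients_excluded["age_under_19"] = len(current) - len(ok_age & current)
    current &= ok_age

    inwin = df[
        (df["visit_time_years"] >= BASELINE_WINDOW[0]) & (df["visit_time_years"] <= BASELINE_WINDOW[1])
    ]
    has_baseline = set(inwin["patient_id"].unique())
    log.patients_excluded["no_baseline_cd4"] = len(current) - len(current & has_baseline)
    current &= has_baseline

    nvis = patients.size()
    enough = set(nvis[nvis >= MIN_VISITS].index)
    log.patients_excluded["fewer_than_5_visits"] = len(current) - len(current & enough)
    current &= enough

    out = df[df["patient_id"].isin(current)].sort_values(
        ["patient_id", "visit_time_years"], kind="mergesort"
    )
    log.n_patients_out = len(current)
    log.n_visits_out = len(out)
    return Cohort(visits=out.reset_index(drop=True)), log


def _band_label(cd4: float) -> str:
    for (lo, hi), lab in zip(CD4_BANDS, CD4_BAND_LABELS):
        if cd4 <= hi:
            return lab
    return CD4_BAND_LABELS[-1]


def descriptive_table(cohort: Cohort) -> pd.DataFrame:
    """Table-1-style descriptives, per age stratum and overall.

    Rows: n_patients, n_visits, visits_per_patient, median follow-up,
    percent female, and baseline-CD4 band counts (bands closed above, so a
    baseline of exactly 200 falls in "51-200").
    """
    if cohort.n_visits == 0:
        raise ValueError("empty cohort")
    pat = cohort.patients()
    base = cohort.baseline_cd4()
    pat = pat.join(base.rename("baseline_cd4"))
    pat["band"] = pat["baseline_cd4"].map(_band_label, na_action="ignore")

    cols = {}
    groups = [(a, pat[pat["age_group"] == a]) for a in AGE_GROUPS] + [("all", pat)]
    for label, sub in groups:
        n = len(sub)
        col = {
            "n_patients": n,
            "n_visits": int(sub["n_visits"].sum()),
            "visits_per_patient": sub["n_visits"].mean() if n else np.nan,
            "median_followup_years": sub["followup_years"].median() if n else np.nan,
            "pct_female": 100.0 * (sub["sex"] == "female").mean() if n else np.nan,
        }
        for lab in CD4_BAND_LABELS:
            col[f"baseline_{lab}"] = int((sub["band"] == lab).sum())
        cols[label] = col
    return pd.DataFrame(cols)
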