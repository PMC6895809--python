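"""Tracheal-wash cytology records and the EIPH phenotype.

Each weekly tracheal-wash sample is scored 0-3 ("none", "occasional",
"moderate", "high") for twelve cytological categories plus an overall
cell density.  The haemosiderophage (HF) column is the bleeding marker:
haemosiderophages are macrophages that have phagocytosed red-cell
breakdown products, so elevated HF scores a week or more after exercise
indicate prior pulmonary haemorrhage.

The per-horse EIPH phenotype is the HF frequency score computed over
the horse's series of samples, in one of two modes:

- ``count`` (default): (number of samples with HF score > threshold) / n
- ``sum``: (sum of HF scores over samples with HF score > threshold) / n

with threshold 1 ("occasional" does not count) in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = [
    "epithelial_cells", "macrophages", "lymphocytes", "eosinophils",
    "haemosiderophages", "erythrocytes", "squames", "mucus",
    "fungi", "bacteria", "plant_material", "debris",
]
SCORE_COLUMNS = CATEGORIES + ["cell_density"]

DAYS_PER_YEAR = 365.25


@dataclass
class ValidationReport:
    n_input: int
    n_retained: int
    rejects: pd.DataFrame  # columns: row, horse_id, reason


def validate_cytology(records: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate raw cytology rows; retained rows satisfy every invariant.

    Rejections (with a reason each): unparseable date, any score outside
    {0,1,2,3}, missing haemosiderophage value.
    """
    records = records.copy()
    reject_rows, reasons = [], []

    dates = pd.to_datetime(records["date"], format="%Y-%m-%d", errors="coerce")
    bad_date = dates.isna()

    present = [c for c in SCORE_COLUMNS if c in records.columns]
    scores = records[present].apply(pd.to_numeric, errors="coerce")
    if "haemosiderophages" not in records.columns:
        hf_missing = pd.Series(True, index=records.index)
    else:
        hf_missing = scores["haemosiderophages"].isna()
    out_of_range = ((scores < 0) | (scores > 3) | (scores != scores.round())).any(axis=1)

    for idx in records.index:
        if bad_date.loc[idx]:
            reject_rows.append(idx); reasons.append("malformed date")
        elif hf_missing.loc[idx]:
            reject_rows.append(idx); reasons.append("missing haemosiderophage score")
        elif out_of_range.loc[idx]:
            reject_rows.append(idx); reasons.append("score outside 0-3")

    rejects = pd.DataFrame({
        "row": reject_rows,
        "horse_id": records.loc[reject_rows, "horse_id"].to_numpy() if reject_rows else [],
        "reason": reasons,
    })
    keep = records.index.difference(reject_rows)
    retained = records.loc[keep].copy()
    retained["date"] = dates.loc[keep]
    for c in present:
        retained[c] = scores.loc[keep, c].astype(int)
    report = ValidationReport(n_input=len(records), n_retained=len(retained), rejects=rejects)
    return retained.reset_index(drop=True), report


def filter_min_samples(records: pd.DataFrame, min_n: int = 4):
    """Ids of horses with at least ``min_n`` validated samples.

    Returns (eligible ids, excluded ids); the study kept horses sampled
    on four or more occasions.
    """
    counts = records.groupby("horse_id").size()
    eligible = counts.index[counts >= min_n]
    excluded = counts.index[counts < min_n]
    return list(eligible), list(excluded)


def hf_frequency_score(hf_scores, threshold: int = 1, mode: str = "count") -> float:
    """HF frequency score for one horse's series of HF scores (0-3).

    count mode: fraction of samples whose HF score strictly exceeds
    ``threshold``; sum mode: sum of those exceeding scores divided by
    the number of samples.  Order-invariant; raises on an empty series.
    """
    hf = np.asarray(list(hf_scores), dtype=float)
    if hf.size == 0:
        raise ValueError("HF frequency undefined for a horse with zero samples")
    over = hf > threshold
    if mode == "count":
        return float(over.sum() / hf.size)
    if mode == "sum":
        return float(hf[over].sum() / hf.size)
    raise ValueError(f"unknown mode {mode!r}")


def derive_covariates(race_records: pd.DataFrame, cytology: pd.DataFrame) -> pd.DataFrame:
    """Regression covariates per horse.

    Emits gender code (male=0, female=1), age at first race start within
    the sampling window (fractional years), period factor
    (first/second/both) from the sampling dates, and the mean over
    samples of days since the most recent prior race start.  Horses with
    cytology but no race record get NaN covariates and are dropped from
    downstream regressions.
    """
    race = race_records.copy()
    for col in ("dob", "first_start", "last_start"):
        race[col] = pd.to_datetime(race[col], errors="coerce")
    cyt = cytology.copy()
    cyt["date"] = pd.to_datetime(cyt["date"])

    rows = []
    race_by_horse = dict(tuple(race.groupby("horse_id")))
    for horse, samples in cyt.groupby("horse_id"):
        rec = race_by_horse.get(horse)
        if rec is None or rec.empty:
            rows.append({"horse_id": horse, "gender": np.nan, "age_first_start": np.nan,
                         "period": "", "mean_days_since_race": np.nan, "missing": True})
            continue
        gender = rec["gender"].iloc[0]
        dob = rec["dob"].iloc[0]
        first_start = rec["first_start"].min()
        age = (first_start - dob).days / DAYS_PER_YEAR if pd.notna(dob) and pd.notna(first_start) else np.nan
        years = sorted(samples["date"].dt.year.unique())
        if len(years) > 1:
            period = "both"
        else:
            period = "first" if years[0] == cyt["date"].dt.year.min() else "second"
        # days since most recent prior race start, averaged over samples
        starts = pd.concat([rec["first_start"], rec["last_start"]]).dropna().sort_values()
        days = []
        for d in samples["date"]:
            prior = starts[starts <= d]
            if len(prior):
                days.append((d - prior.iloc[-1]).days)
        mean_days = float(np.mean(days)) if days else np.nan
        rows.append({
            "horse_id": horse,
            "gender": 0.0 if str(gender).lower().startswith("m") else 1.0,
            "age_first_start": age,
            "period": period,
            "mean_days_since_race": mean_days,
            "missing": False,
        })
    return pd.DataFrame(rows).set_index("horse_id")


def phenotype_table(
    cytology: pd.DataFrame,
    race_records: pd.DataFrame,
    min_n: int = 4,
    threshold: int = 1,
    mode: str = "count",
) -> pd.DataFrame:
    """Per-horse EIPH phenotype plus covariates, eligibility-filtered.

    One row per eligible horse (>= min_n samples) with columns
    hf_frequency, n_samples, gender, age_first_start, period_second,
    period_both, mean_days_since_race; horses lacking race records carry
    NaN covariates.
    """
    eligible, _ = filter_min_samples(cytology, min_n=min_n)
    cyt = cytology[cytology["horse_id"].isin(eligible)]
    pheno = cyt.groupby("horse_id")["haemosiderophages"].agg(
        lambda s: hf_frequency_score(s, threshold=threshold, mode=mode)
    ).rename("hf_frequency")
    n_samples = cyt.groupby("horse_id").size().rename("n_samples")
    cov = derive_covariates(race_records, cyt)
    out = pd.concat([pheno, n_samples], axis=1).join(cov)
    out["period_second"] = (out["period"] == "second").astype(float)
    out["period_both"] = (out["period"] == "both").astype(float)
    return out


def age_correlation(race_records: pd.DataFrame, cytology: pd.DataFrame) -> float:
    """Pearson r between age at first race start and age at first sampling.

    A cohort-description statistic (the study population showed these
    two ages to be strongly correlated).
    """
    race = race_records.copy()
    race["dob"] = pd.to_datetime(race["dob"])
    race["first_start"] = pd.to_datetime(race["first_start"])
    cyt = cytology.copy()
    cyt["date"] = pd.to_datetime(cyt["date"])
    first_sample = cyt.groupby("horse_id")["date"].min()
    merged = race.groupby("horse_id").agg(
        dob=("dob", "first"), first_start=("first_start", "min")
    ).join(first_sample.rename("first_sample"), how="inner").dropna()
    age_start = (merged["first_start"] - merged["dob"]).dt.days / DAYS_PER_YEAR
    age_sample = (merged["first_sample"] - merged["dob"]).dt.days / DAYS_PER_YEAR
    return float(np.corrcoef(age_start, age_sample)[0, 1])
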