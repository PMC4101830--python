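"""Cohort assembly: from raw subject records to the analysis-ready survival table.

This module encodes the endpoint and eligibility rules of a post-prostatectomy
biochemical-failure (BF) study:

* **BF endpoint** — failure at the date of the first serum PSA value
  >= 0.2 ng/mL drawn at least 6 weeks (42 days, inclusive) after surgery that
  is confirmed by *any* later PSA value > 0.2 ng/mL; otherwise the subject is
  censored at the last date of contact. Time runs from the prostatectomy
  date, in years (days / 365.25).
* **Eligibility** — Gleason patterns 3+3, 3+4, 4+3, 4+4 and 4+5 are analyzed;
  tumors predominantly of pattern 5 (5+4, 5+5) are excluded, as are subjects
  with fewer than two post-operative PSA values (a single value cannot
  confirm a failure).
* **Derived indicators** — primary Gleason pattern group (3: 3+3 and 3+4;
  4: 4+3, 4+4 and 4+5) and the composite non-localized tumor indicator
  (extraprostatic extension pT3, nodal involvement pN1, and/or positive
  surgical margin pR1).
* **Spot averaging** — tissue-microarray staining metrics are averaged over
  non-missing spots per subject and biomarker.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "SurvivalDataset",
    "ExclusionReason",
    "eligibility_filter",
    "derive_bf_endpoint",
    "derive_indicators",
    "average_spots",
    "assemble_dataset",
    "summarize_cohort",
    "run_concordance",
    "read_cohort_csv",
    "write_cohort_csv",
]

DAYS_PER_YEAR = 365.25
BF_INDEX_THRESHOLD = 0.2    # ng/mL, first qualifying value (>=)
BF_CONFIRM_THRESHOLD = 0.2  # ng/mL, confirming value (strictly >)
BF_MIN_DAYS = 42            # "at least 6 weeks" post-surgery, inclusive

ELIGIBLE_GLEASON = {(3, 3), (3, 4), (4, 3), (4, 4), (4, 5)}


@dataclass
class SubjectRecord:
    """One patient's clinicopathologic features, PSA series and follow-up."""

    subject_id: str
    age: float
    preop_psa: float | None
    gleason_primary: int
    gleason_secondary: int
    pT3: bool
    pN1: bool
    pR1: bool
    surgery_date: _dt.date
    psa_series: list[tuple[_dt.date, float]] = field(default_factory=list)
    last_contact: _dt.date | None = None

    def validate(self) -> None:
        if not (3 <= self.gleason_primary <= 5 and 3 <= self.gleason_secondary <= 5):
            raise ValueError(
                f"{self.subject_id}: malformed Gleason pattern "
                f"{self.gleason_primary}+{self.gleason_secondary}"
            )
        for d, v in self.psa_series:
            if d <= self.surgery_date:
                raise ValueError(
                    f"{self.subject_id}: PSA dated {d} not after surgery "
                    f"{self.surgery_date}"
                )
            if v < 0:
                raise ValueError(f"{self.subject_id}: negative PSA {v}")
        if self.last_contact is not None and self.last_contact < self.surgery_date:
            raise ValueError(f"{self.subject_id}: last contact precedes surgery")


@dataclass
class SurvivalDataset:
    """Analysis-ready time/event/covariate table.

    ``frame`` holds one row per subject with reserved columns ``time``
    (years) and ``event`` (0/1); remaining columns are covariates with
    missing entries as NaN.
    """

    frame: pd.DataFrame
    biomarkers: list[str] = field(default_factory=list)

    def __post_init__(self):
        for col in ("time", "event"):
            if col not in self.frame.columns:
                raise ValueError(f"missing required column {col!r}")
        if (self.frame["time"] <= 0).any():
            raise ValueError("non-positive survival time")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate covariate names")


class ExclusionReason:
    GLEASON_PATTERN5 = "gleason_pattern5"
    SINGLE_PSA = "single_psa"
    INVALID = "invalid_record"


def eligibility_filter(
    records: list[SubjectRecord],
) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, str]]]:
    """Apply the cohort eligibility rules.

    Keeps Gleason 3+3, 3+4, 4+3, 4+4 and 4+5 tumors with at least two
    post-operative PSA values. Returns ``(kept, excluded)`` where each
    exclusion carries a machine-readable reason code.
    """
    kept, excluded = [], []
    for rec in records:
        rec.validate()
        if (rec.gleason_primary, rec.gleason_secondary) not in ELIGIBLE_GLEASON:
            if rec.gleason_primary == 5:
                excluded.append((rec, ExclusionReason.GLEASON_PATTERN5))
            else:
                raise ValueError(
                    f"{rec.subject_id}: unsupported Gleason pattern "
                    f"{rec.gleason_primary}+{rec.gleason_secondary}"
                )
            continue
        if len(rec.psa_series) < 2:
            excluded.append((rec, ExclusionReason.SINGLE_PSA))
            continue
        kept.append(rec)
    return kept, excluded


def derive_bf_endpoint(record: SubjectRecord) -> tuple[float, bool]:
    """Time (years) and event indicator under the BF rule.

    Event time is the date of the first PSA >= 0.2 ng/mL taken at least 42
    days after surgery that is followed by any later PSA > 0.2 ng/mL; a
    subject with no such confirmed rise is censored at last contact.
    """
    series = sorted(record.psa_series)
    for i, (d, v) in enumerate(series):
        days_post = (d - record.surgery_date).days
        if days_post < BF_MIN_DAYS or v < BF_INDEX_THRESHOLD:
            continue
        if any(v2 > BF_CONFIRM_THRESHOLD for _, v2 in series[i + 1:]):
            t = days_post / DAYS_PER_YEAR
            if t <= 0:
                raise ValueError(f"{record.subject_id}: non-positive event time")
            return t, True
    if record.last_contact is None:
        raise ValueError(f"{record.subject_id}: censored subject lacks last_contact")
    t = (record.last_contact - record.surgery_date).days / DAYS_PER_YEAR
    if t <= 0:
        raise ValueError(f"{record.subject_id}: non-positive censoring time")
    return t, False


def derive_indicators(record: SubjectRecord) -> dict:
    """Primary Gleason pattern group and non-localized tumor indicator."""
    pattern = (record.gleason_primary, record.gleason_secondary)
    if pattern in {(3, 3), (3, 4)}:
        group = 3
    elif pattern in {(4, 3), (4, 4), (4, 5)}:
        group = 4
    else:
        raise ValueError(f"{record.subject_id}: pattern {pattern} not in grouping")
    return {
        "primary_pattern": group,
        "non_localized": bool(record.pT3 or record.pN1 or record.pR1),
    }


def average_spots(spot_table: pd.DataFrame) -> pd.DataFrame:
    """Mean staining metric over non-missing spots, per subject x biomarker.

    ``spot_table`` columns: ``subject_id``, ``biomarker``, ``spot_index``,
    ``value``. A subject whose spots are all missing for a biomarker gets
    NaN (the row may simply be absent). Duplicate spot keys raise.
    """
    key = ["subject_id", "biomarker", "spot_index"]
    if spot_table.duplicated(subset=key).any():
        dup = spot_table[spot_table.duplicated(subset=key, keep=False)]
        raise ValueError(f"duplicate spot keys:\n{dup[key].head()}")
    wide = (
        spot_table.groupby(["subject_id", "biomarker"])["value"]
        .mean()
        .unstack("biomarker")
    )
    wide.columns.name = None
    return wide


def assemble_dataset(
    records: list[SubjectRecord],
    spot_table: pd.DataFrame | None = None,
) -> SurvivalDataset:
    """Eligibility-filtered records + averaged spots -> survival dataset."""
    kept, _ = eligibility_filter(records)
    rows = []
    for rec in kept:
        t, e = derive_bf_endpoint(rec)
        row = {
            "subject_id": rec.subject_id,
            "time": t,
            "event": int(e),
            "age": rec.age,
            "preop_psa": rec.preop_psa if rec.preop_psa is not None else np.nan,
            "gleason_primary": rec.gleason_primary,
            "gleason_secondary": rec.gleason_secondary,
            "pT3": int(rec.pT3),
            "pN1": int(rec.pN1),
            "pR1": int(rec.pR1),
        }
        row.update(derive_indicators(rec))
        row["non_localized"] = int(row["non_localized"])
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("subject_id")
    biomarkers: list[str] = []
    if spot_table is not None and len(spot_table):
        means = average_spots(spot_table)
        biomarkers = list(means.columns)
        frame = frame.join(means)
    return SurvivalDataset(frame=frame.reset_index(), biomarkers=biomarkers)


def summarize_cohort(dataset: SurvivalDataset) -> pd.DataFrame:
    """Cohort summary table: category counts with percentages of total N
    (one decimal), and means (SD) for continuous variables."""
    df = dataset.frame
    n_total = len(df)
    rows = [{"variable": "Total population", "category": "", "n": n_total,
             "pct": "", "mean_sd": ""}]

    def round_half_up(x):  # printed tables round .xx5 upward, not to even
        return float(np.floor(x * 10.0 + 0.5) / 10.0)

    def add_categorical(name, series, labels):
        for lab in labels:
            cnt = int((series == lab).sum())
            rows.append(
                {
                    "variable": name,
                    "category": str(lab),
                    "n": cnt,
                    "pct": round_half_up(100.0 * cnt / n_total),
                    "mean_sd": "",
                }
            )

    gleason = df["gleason_primary"].astype(int).astype(str) + "+" + df[
        "gleason_secondary"
    ].astype(int).astype(str)
    add_categorical(
        "Combined Gleason score", gleason, ["3+3", "3+4", "4+3", "4+4", "4+5"]
    )
    add_categorical("Primary Gleason pattern", df["primary_pattern"], [3, 4])
    add_categorical("Pathologic stage pT3", df["pT3"], [1, 0])
    add_categorical("Lymph node involvement pN1", df["pN1"], [1, 0])
    add_categorical("Surgical margin pR1", df["pR1"], [1, 0])
    add_categorical("Non-localized tumor indicator", df["non_localized"], [1, 0])

    for name, col in (("Age (years)", "age"), ("Pre-operative PSA (ng/mL)", "preop_psa")):
        vals = df[col].dropna()
        rows.append(
            {
                "variable": name,
                "category": "",
                "n": int(len(vals)),
                "pct": "",
                "mean_sd": f"{vals.mean():.1f} ({vals.std(ddof=1):.1f})",
            }
        )
    return pd.DataFrame(rows)


def run_concordance(
    run1: pd.Series | np.ndarray,
    run2: pd.Series | np.ndarray,
    method: str = "pearson",
) -> dict:
    """Reproducibility of two independent staining runs of one biomarker.

    Returns the 2x2 observed/missing percentage cross-tabulation and the
    correlation over doubly-observed subjects (missing-flagged when fewer
    than 3 such subjects). ``method`` is ``pearson`` (default) or
    ``spearman``.
    """
    a = np.asarray(run1, dtype=float)
    b = np.asarray(run2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"run length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    oa, ob = ~np.isnan(a), ~np.isnan(b)
    tab = pd.DataFrame(
        {
            "run2_observed": [100.0 * np.mean(oa & ob), 100.0 * np.mean(~oa & ob)],
            "run2_missing": [100.0 * np.mean(oa & ~ob), 100.0 * np.mean(~oa & ~ob)],
        },
        index=["run1_observed", "run1_missing"],
    )
    both = oa & ob
    if both.sum() < 3:
        corr = np.nan
    else:
        x, y = a[both], b[both]
        if method == "pearson":
            corr = float(np.corrcoef(x, y)[0, 1])
        elif method == "spearman":
            from scipy import stats

            corr = float(stats.spearmanr(x, y).statistic)
        else:
            raise ValueError(f"unknown method {method!r}")
    return {"crosstab_pct": tab, "correlation": corr, "n_both": int(both.sum())}


# ---------------------------------------------------------------------------
# CSV I/O. PSA series are serialized as a semicolon-delimited list of
# ISO-date:value pairs, e.g. "2001-03-04:0.05;2001-06-02:0.25".

def _fmt_psa(series: list[tuple[_dt.date, float]]) -> str:
    return ";".join(f"{d.isoformat()}:{v:g}" for d, v in series)


def _parse_psa(s: str) -> list[tuple[_dt.date, float]]:
    if not s or (isinstance(s, float) and np.isnan(s)):
        return []
    out = []
    for item in str(s).split(";"):
        d, v = item.rsplit(":", 1)
        out.append((_dt.date.fromisoformat(d), float(v)))
    return out


def write_cohort_csv(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "age": r.age,
                "preop_psa": r.preop_psa if r.preop_psa is not None else "",
                "gleason_primary": r.gleason_primary,
                "gleason_secondary": r.gleason_secondary,
                "pT3": int(r.pT3),
                "pN1": int(r.pN1),
                "pR1": int(r.pR1),
                "surgery_date": r.surgery_date.isoformat(),
                "psa_series": _fmt_psa(r.psa_series),
                "last_contact": r.last_contact.isoformat() if r.last_contact else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    records = []
    for _, row in df.iterrows():
        psa = row.get("preop_psa")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                preop_psa=None if pd.isna(psa) or psa == "" else float(psa),
                gleason_primary=int(row["gleason_primary"]),
                gleason_secondary=int(row["gleason_secondary"]),
                pT3=bool(int(row["pT3"])),
                pN1=bool(int(row["pN1"])),
                pR1=bool(int(row["pR1"])),
                surgery_date=_dt.date.fromisoformat(row["surgery_date"]),
                psa_series=_parse_psa(row["psa_series"]),
                last_contact=(
                    _dt.date.fromisoformat(row["last_contact"])
                    if isinstance(row["last_contact"], str) and row["last_contact"]
                    else None
                ),
            )
        )
    return records
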