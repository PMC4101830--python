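"""Synthetic cohorts, expression studies and stained spots with known truth.

The generators emulate the three data streams the analysis consumes, each
with ground truth recorded for recovery tests:

* **Cohort** — a prostatectomy cohort (default 160 subjects) with 33
  correlated staining biomarkers, a Weibull proportional-hazards
  biochemical-failure outcome driven by configurable per-SD log hazard
  ratios, administrative censoring calibrated to a target event fraction
  (default 13.75%, i.e. 22 of 160), quadruplicate spot-level staining
  values, per-biomarker missing-completely-at-random core loss in a 6-30%
  range, and a post-operative PSA series constructed so that the
  biochemical-failure rule recovers the simulated event time to within the
  90-day PSA sampling interval.
* **Expression studies** — two-class gene x sample matrices with a planted
  differential-expression signature of consistent sign across studies.
* **Spot images** — RGB TMA spots synthesized by inverting the optical
  density transform from known per-pixel stain concentrations, so that the
  quantification round trip has an exact oracle.

Default effect sizes for the cohort plant three prognostic markers with
per-SD hazard ratios 2.01, 1.76 and 1.46 — the magnitudes typical of the
strongest immunohistochemistry markers in studies of this design.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .ihc import RegionMasks, StainVectors, TISSUE_LABELS, od_to_intensity

__all__ = [
    "CohortSimConfig",
    "ExpressionSimConfig",
    "SpotSimConfig",
    "CohortTruth",
    "ExpressionStudy",
    "simulate_cohort",
    "simulate_survival_frame",
    "simulate_expression_studies",
    "simulate_spot_image",
    "write_spot_csv",
    "write_expression_tsv",
]

PSA_VISIT_DAYS = 90  # scheduled post-operative PSA interval


def _default_log_hr() -> dict[str, float]:
    return {
        "B01": float(np.log(2.01)),
        "B02": float(np.log(1.76)),
        "B03": float(np.log(1.46)),
    }


@dataclass
class CohortSimConfig:
    n_subjects: int = 160
    n_biomarkers: int = 33
    true_log_hr: dict[str, float] = field(default_factory=_default_log_hr)
    biomarker_correlation: float = 0.2
    baseline_shape: float = 1.3
    baseline_scale: float = 30.0  # years
    censor_window: float = 30.0   # upper bound for calibrated admin window
    censor_min: float = 0.55      # years; guarantees >= 2 scheduled PSA visits
    target_event_fraction: float = 0.1375  # 22 / 160
    missing_fraction_range: tuple[float, float] = (0.06, 0.30)
    n_spots: int = 4
    spot_noise_sd: float = 0.25
    seed: int = 0

    @property
    def biomarker_names(self) -> list[str]:
        return [f"B{i + 1:02d}" for i in range(self.n_biomarkers)]

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.missing_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("missing_fraction_range must satisfy 0 <= lo <= hi <= 1")
        if not (0 <= self.biomarker_correlation < 1):
            raise ValueError("biomarker_correlation must be in [0, 1)")
        if not (0 < self.target_event_fraction < 1):
            raise ValueError("target_event_fraction must be in (0, 1)")
        unknown = set(self.true_log_hr) - set(self.biomarker_names)
        if unknown:
            raise ValueError(f"true_log_hr names not among biomarkers: {sorted(unknown)}")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline parameters must be positive")
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")


@dataclass
class CohortTruth:
    """Generating parameters and latent states of one simulated cohort."""

    config: CohortSimConfig
    biomarker_names: list[str]
    log_hr: np.ndarray           # per biomarker, per SD
    latent: np.ndarray           # n x p standardized biomarker values
    event_time: np.ndarray       # latent failure times (years)
    censor_time: np.ndarray      # administrative censoring times (years)
    time: np.ndarray             # observed min(T, C)
    event: np.ndarray            # bool
    censor_window_used: float
    missing_rates: np.ndarray    # per-biomarker configured MCAR rate
    frame: pd.DataFrame          # analysis-ready table (exact times)


def _calibrate_censor_window(event_time, target, lo, hi, tol=1e-6):
    """Bisection on the admin-censoring window so that the expected event
    fraction E[P(C > T_i)], C ~ U(lo, W), matches the target."""

    def frac(W):
        T = event_time
        p = np.where(T <= lo, 1.0, np.where(T < W, (W - T) / (W - lo), 0.0))
        return float(p.mean())

    f_hi = frac(hi)
    f_lo = frac(lo + 1e-9)
    if target > f_hi:
        raise ValueError(
            f"event-fraction calibration infeasible: target {target:.3f} exceeds "
            f"maximum attainable {f_hi:.3f} at censor_window={hi} years; "
            "increase censor_window or the baseline hazard"
        )
    if target < f_lo:
        raise ValueError(
            f"event-fraction calibration infeasible: target {target:.3f} below "
            f"minimum attainable {f_lo:.3f} at the minimum follow-up window"
        )
    a, b = lo + 1e-9, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        if frac(mid) < target:
            a = mid
        else:
            b = mid
        if b - a < tol:
            break
    return 0.5 * (a + b)


def _draw_biomarkers(rng, n, p, rho):
    """Exchangeable-correlation standard-normal biomarkers via a shared
    latent factor: X = sqrt(rho) u + sqrt(1-rho) eps."""
    u = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, p))
    return np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps


def simulate_survival_frame(config: CohortSimConfig):
    """Fast numeric path: simulate the analysis-ready survival table.

    Returns ``(frame, truth)`` without materializing subject records or PSA
    series; biomarker columns are spot means with MCAR missingness, exactly
    as :func:`simulate_cohort` would deliver after assembly (but with exact
    event times rather than visit-rounded ones).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_biomarkers
    names = config.biomarker_names
    Z = _draw_biomarkers(rng, n, p, config.biomarker_correlation)
    beta = np.array([config.true_log_hr.get(b, 0.0) for b in names])
    eta = Z @ beta
    # Weibull PH: S(t|x) = exp(-(t/scale)^shape * e^eta)
    U = rng.uniform(size=n)
    T = config.baseline_scale * (-np.log(U) * np.exp(-eta)) ** (
        1.0 / config.baseline_shape
    )
    W = _calibrate_censor_window(
        T, config.target_event_fraction, config.censor_min, config.censor_window
    )
    C = rng.uniform(config.censor_min, W, size=n)
    time = np.minimum(T, C)
    event = T <= C

    # quadruplicate spot values: subject latent value + spot noise
    spots = (
        Z[:, :, None]
        + rng.normal(0.0, config.spot_noise_sd, size=(n, p, config.n_spots))
    )
    lo, hi = config.missing_fraction_range
    miss_rates = rng.uniform(lo, hi, size=p)
    miss = rng.uniform(size=(n, p)) < miss_rates[None, :]  # whole-core loss
    biomarker_values = spots.mean(axis=2)
    biomarker_values[miss] = np.nan

    # clinicopathologic features, independent of outcome by construction
    age = rng.normal(60.8, 6.8, size=n)
    psa_sigma2 = np.log(1.0 + (5.3 / 7.2) ** 2)
    preop_psa = rng.lognormal(
        np.log(7.2) - psa_sigma2 / 2.0, np.sqrt(psa_sigma2), size=n
    )
    preop_psa[rng.uniform(size=n) < 12.0 / 160.0] = np.nan
    gleason_probs = np.array([50, 63, 34, 8, 5], dtype=float) / 160.0
    gleason_cats = [(3, 3), (3, 4), (4, 3), (4, 4), (4, 5)]
    gidx = rng.choice(5, size=n, p=gleason_probs)
    gp = np.array([gleason_cats[i][0] for i in gidx])
    gs = np.array([gleason_cats[i][1] for i in gidx])
    pT3 = rng.uniform(size=n) < 29.0 / 160.0
    pN1 = rng.uniform(size=n) < 5.0 / 160.0
    pR1 = rng.uniform(size=n) < 53.0 / 160.0

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "time": time,
            "event": event.astype(int),
            "age": age,
            "preop_psa": preop_psa,
            "gleason_primary": gp,
            "gleason_secondary": gs,
            "pT3": pT3.astype(int),
            "pN1": pN1.astype(int),
            "pR1": pR1.astype(int),
            "primary_pattern": np.where(gp == 3, 3, 4),
            "non_localized": (pT3 | pN1 | pR1).astype(int),
        }
    )
    for j, b in enumerate(names):
        frame[b] = biomarker_values[:, j]

    truth = CohortTruth(
        config=config,
        biomarker_names=names,
        log_hr=beta,
        latent=Z,
        event_time=T,
        censor_time=C,
        time=time,
        event=event,
        censor_window_used=W,
        missing_rates=miss_rates,
        frame=frame,
    )
    truth._spots = spots       # kept for spot-table materialization
    truth._spot_missing = miss
    return frame, truth


def _psa_series(surgery, t_event_days, t_censor_days, is_event):
    """Scheduled 90-day PSA series exercising every branch of the BF rule.

    Failure-free subjects stay below 0.2 ng/mL until last contact. Failing
    subjects show 0.25 at the first scheduled visit on/after the (latent)
    failure time — never before 6 weeks post-surgery — and 0.30 at the
    next visit, which confirms the failure.
    """
    series = []
    if is_event:
        first_qual = max(t_event_days, 42)
        qual_visit = int(np.ceil(first_qual / PSA_VISIT_DAYS)) * PSA_VISIT_DAYS
        day = PSA_VISIT_DAYS
        while day < qual_visit:
            series.append((surgery + _dt.timedelta(days=day), 0.05))
            day += PSA_VISIT_DAYS
        series.append((surgery + _dt.timedelta(days=qual_visit), 0.25))
        series.append(
            (surgery + _dt.timedelta(days=qual_visit + PSA_VISIT_DAYS), 0.30)
        )
        last = surgery + _dt.timedelta(days=qual_visit + PSA_VISIT_DAYS)
    else:
        day = PSA_VISIT_DAYS
        end = int(np.floor(t_censor_days))
        while day <= end:
            series.append((surgery + _dt.timedelta(days=day), 0.05))
            day += PSA_VISIT_DAYS
        last = surgery + _dt.timedelta(days=end)
    return series, last


def simulate_cohort(config: CohortSimConfig):
    """Simulate subject records, spot-level staining table and ground truth.

    Returns ``(records, spot_table, truth)``. Records carry full PSA series
    and follow-up dates so that cohort assembly (eligibility filter, BF
    endpoint, spot averaging) can be exercised end to end; ``truth.frame``
    holds the exact-time analysis table.
    """
    frame, truth = simulate_survival_frame(config)
    surgery0 = _dt.date(2000, 1, 1)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    records = []
    n = config.n_subjects
    surgery_offsets = rng.integers(0, 365 * 8, size=n)
    for i in range(n):
        row = frame.iloc[i]
        surgery = surgery0 + _dt.timedelta(days=int(surgery_offsets[i]))
        t_event_days = truth.event_time[i] * 365.25
        t_censor_days = max(truth.censor_time[i] * 365.25, 2 * PSA_VISIT_DAYS)
        series, last = _psa_series(
            surgery, t_event_days, t_censor_days, bool(truth.event[i])
        )
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                age=float(row["age"]),
                preop_psa=None if np.isnan(row["preop_psa"]) else float(row["preop_psa"]),
                gleason_primary=int(row["gleason_primary"]),
                gleason_secondary=int(row["gleason_secondary"]),
                pT3=bool(row["pT3"]),
                pN1=bool(row["pN1"]),
                pR1=bool(row["pR1"]),
                surgery_date=surgery,
                psa_series=series,
                last_contact=last,
            )
        )

    spots, miss = truth._spots, truth._spot_missing
    rows = []
    for i in range(n):
        sid = frame.iloc[i]["subject_id"]
        for j, b in enumerate(config.biomarker_names):
            if miss[i, j]:
                continue  # whole core lost: all spots missing
            for k in range(config.n_spots):
                rows.append((sid, b, k + 1, spots[i, j, k]))
    spot_table = pd.DataFrame(
        rows, columns=["subject_id", "biomarker", "spot_index", "value"]
    )
    return records, spot_table, truth


# ---------------------------------------------------------------------------
# expression studies


@dataclass
class ExpressionStudy:
    """One gene x sample expression study with binary aggressiveness labels."""

    name: str
    matrix: pd.DataFrame       # genes x samples
    labels: pd.Series          # per sample: "aggressive" / "non_aggressive"
    role: str = "training"     # or "validation"

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def validate(self) -> None:
        counts = self.labels.value_counts()
        for cls in ("aggressive", "non_aggressive"):
            if counts.get(cls, 0) < 2:
                raise ValueError(f"{self.name}: fewer than 2 {cls} samples")
        if self.matrix.index.duplicated().any():
            raise ValueError(f"{self.name}: duplicate gene identifiers")


@dataclass
class ExpressionSimConfig:
    n_genes: int = 1000
    train_sizes: tuple[int, ...] = (21, 58)
    validation_size: int | None = 28
    n_signal_genes: int = 11
    effect_size: float = 2.0   # standardized mean difference between classes
    seed: int = 0

    def validate(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must not exceed n_genes")
        for s in (*self.train_sizes, *( [self.validation_size] if self.validation_size else [] )):
            if s < 4:
                raise ValueError("each study needs >= 2 samples per class")


@dataclass
class ExpressionTruth:
    signal_genes: list[str]
    signs: dict[str, int]      # +1: higher in non-aggressive; -1: higher in aggressive


def _one_study(rng, name, n_samples, genes, signal, signs, effect, role):
    n_agg = n_samples // 2
    labels = ["aggressive"] * n_agg + ["non_aggressive"] * (n_samples - n_agg)
    X = rng.standard_normal((len(genes), n_samples))
    is_na = np.array([l == "non_aggressive" for l in labels])
    for g in signal:
        i = genes.index(g)
        shift = signs[g] * effect / 2.0
        X[i, is_na] += shift
        X[i, ~is_na] -= shift
    cols = [f"{name}_s{j + 1:03d}" for j in range(n_samples)]
    return ExpressionStudy(
        name=name,
        matrix=pd.DataFrame(X, index=genes, columns=cols),
        labels=pd.Series(labels, index=cols),
        role=role,
    )


def simulate_expression_studies(config: ExpressionSimConfig):
    """Simulate training (and optionally validation) expression studies.

    Signal genes are shifted between classes by ``effect_size`` with a
    consistent random sign per gene across all studies. Returns
    ``(studies, truth)``; the validation study (if any) is last, with
    ``role == "validation"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    signal_idx = rng.choice(config.n_genes, size=config.n_signal_genes, replace=False)
    signal = [genes[i] for i in sorted(signal_idx)]
    signs = {g: int(s) for g, s in zip(signal, rng.choice([-1, 1], size=len(signal)))}
    studies = [
        _one_study(rng, f"train{k + 1}", sz, genes, signal, signs,
                   config.effect_size, "training")
        for k, sz in enumerate(config.train_sizes)
    ]
    if config.validation_size:
        studies.append(
            _one_study(rng, "validation", config.validation_size, genes, signal,
                       signs, config.effect_size, "validation")
        )
    for s in studies:
        s.validate()
    return studies, ExpressionTruth(signal_genes=signal, signs=signs)


# ---------------------------------------------------------------------------
# stained spot images


@dataclass
class SpotSimConfig:
    width: int = 64
    height: int = 64
    dab_fraction: float = 0.5
    dab_od_level: float = 0.8          # DAB concentration (OD units along stain vector)
    hematoxylin_od_level: float = 0.3
    tissue_layout: str = "epithelium_only"
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.dab_fraction <= 1):
            raise ValueError("dab_fraction must be in [0, 1]")
        if self.dab_od_level < 0 or self.hematoxylin_od_level < 0:
            raise ValueError("OD levels must be non-negative")
        if self.tissue_layout not in (
            "epithelium_only", "epithelium_stroma", "nuclei", "vessels"
        ):
            raise ValueError(f"unknown tissue_layout {self.tissue_layout!r}")


def _positive_subset(rng, flat_indices, fraction):
    k = int(round(fraction * flat_indices.size))
    if k == 0:
        return np.empty(0, dtype=int)
    return rng.permutation(flat_indices)[:k]


def simulate_spot_image(
    config: SpotSimConfig,
    threshold: float = 0.15,
    vectors: StainVectors | None = None,
):
    """Synthesize an RGB TMA spot with known stain concentrations.

    The image is built by inverting the OD transform
    (``I = round(256 * 10**(-OD) - 1)``) from known per-pixel hematoxylin
    and DAB concentrations along fixed stain vectors. Returns
    ``(rgb, masks, truth)`` where ``truth`` holds the exact region metrics
    computed from the generator's own concentration maps (AvgOD over all
    region pixels, %Pos at ``threshold``, and their product; per-nucleus or
    per-vessel variants for those layouts).
    """
    config.validate()
    vectors = vectors or StainVectors()
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    c_dab = np.zeros((H, W))
    c_hem = np.full((H, W), config.hematoxylin_od_level)
    tissue = np.full((H, W), TISSUE_LABELS["tumor_epithelium"], dtype=int)
    nuclei = None
    vessels = None
    lumen = None
    truth: dict = {"threshold": threshold}

    def region_truth(conc_vals):
        avg = float(conc_vals.mean())
        pct = float(100.0 * np.mean(conc_vals >= threshold))
        return {"avg_od": avg, "pct_pos": pct, "score": avg * pct}

    if config.tissue_layout in ("epithelium_only", "epithelium_stroma"):
        if config.tissue_layout == "epithelium_stroma":
            tissue[:, W // 2:] = TISSUE_LABELS["stroma"]
        for region_name, level_scale in (
            ("tumor_epithelium", 1.0),
            ("stroma", 0.5),
        ):
            sel = np.flatnonzero(tissue.ravel() == TISSUE_LABELS[region_name])
            if sel.size == 0:
                continue
            pos = _positive_subset(rng, sel, config.dab_fraction)
            c_dab.ravel()[pos] = config.dab_od_level * level_scale
            truth[region_name] = region_truth(c_dab.ravel()[sel])
    elif config.tissue_layout == "nuclei":
        nuclei = np.zeros((H, W), dtype=int)
        side, gap = 5, 4
        nid = 0
        for r0 in range(gap, H - side, side + gap):
            for c0 in range(gap, W - side, side + gap):
                nid += 1
                nuclei[r0:r0 + side, c0:c0 + side] = nid
        ids = np.arange(1, nid + 1)
        pos_ids = _positive_subset(rng, ids, config.dab_fraction)
        for vid in pos_ids:
            c_dab[nuclei == vid] = config.dab_od_level
        means = np.array(
            [float(c_dab[nuclei == vid].mean()) for vid in ids]
        )
        truth["nuclear"] = {
            "avg_nuclear_od": float(means.mean()),
            "pct_pos_nuclei": float(100.0 * np.mean(means >= threshold)),
            "n_nuclei": int(nid),
        }
        truth["nuclear"]["score"] = (
            truth["nuclear"]["avg_nuclear_od"] * truth["nuclear"]["pct_pos_nuclei"]
        )
        truth["tumor_epithelium"] = region_truth(c_dab.ravel())
    elif config.tissue_layout == "vessels":
        vessels = np.zeros((H, W), dtype=int)
        lumen = np.zeros((H, W), dtype=int)
        specs = [  # (row, col, outer_h, outer_w, lumen_h, lumen_w)
            (6, 6, 8, 10, 4, 6),
            (6, 30, 6, 6, 2, 2),
            (30, 10, 10, 8, 6, 4),
        ]
        areas, perims, lumens = [], [], []
        for vid, (r, c, oh, ow, lh, lw) in enumerate(specs, start=1):
            vessels[r:r + oh, c:c + ow] = vid
            lr, lc = r + (oh - lh) // 2, c + (ow - lw) // 2
            lumen[lr:lr + lh, lc:lc + lw] = vid
            wall = (vessels == vid) & (lumen != vid)
            c_dab[wall] = config.dab_od_level
            areas.append(oh * ow)
            perims.append(2 * (oh + ow))
            lumens.append(lh * lw)
        areas = np.array(areas, float)
        lumens = np.array(lumens, float)
        truth["microvessel"] = {
            "avg_vessel_area": float(areas.mean()),
            "avg_vessel_perimeter": float(np.mean(perims)),
            "avg_lumen_area": float(lumens.mean()),
            "avg_vascular_area": float((areas - lumens).mean()),
            "n_vessels": len(specs),
            "microvessel_density": len(specs) / float(H * W),
        }

    od = (
        c_hem[:, :, None] * vectors.hematoxylin[None, None, :]
        + c_dab[:, :, None] * vectors.dab[None, None, :]
    )
    rgb = od_to_intensity(od)
    masks = RegionMasks(tissue_class=tissue, nuclei=nuclei, vessels=vessels, lumen=lumen)
    return rgb, masks, truth


# ---------------------------------------------------------------------------
# writers


def write_spot_csv(spot_table: pd.DataFrame, path) -> None:
    spot_table.to_csv(path, index=False)


def write_expression_tsv(study: ExpressionStudy, matrix_path, labels_path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    study.labels.rename("label").to_frame().to_csv(
        labels_path, sep="\t", index_label="sample"
    )
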