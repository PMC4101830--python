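"""Cross-study weighted-voting gene signature of tumor aggressiveness.

A signal-to-noise statistic is computed per gene within each training
expression study,

    sx = (mu_non_aggressive - mu_aggressive) / (sd_non_aggressive + sd_aggressive),

so positive values mark genes higher in non-aggressive tumors. Per study the
top ``n_each`` most-positive and ``n_each`` most-negative genes form the
informative set; genes informative in *every* training study are ranked by
the absolute sample-size-weighted mean of their per-study sx. An n-gene
voting model classifies a specimen by the sign of the vote sum

    V = sum_x sx_w * (g_x - b_x),

with ``sx_w`` the weighted sx, ``g_x`` the specimen's (normalized)
expression and ``b_x`` a per-gene decision boundary (0 on per-gene
standardized data by default, or the class-mean midpoint). Positive V votes
non-aggressive, negative aggressive, exactly zero is indeterminate.

Expression matrices are genes x samples. "Fully normalized" is
operationalized as a per-gene z-score within each study (optionally after
log2), which makes the zero boundary meaningful across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .synthetic import ExpressionStudy

__all__ = [
    "VotingModel",
    "collapse_probes",
    "normalize_study",
    "compute_sx",
    "select_top_informative",
    "weighted_average_sx",
    "build_model",
    "classify",
    "evaluate_models",
    "train_voting_model",
]

AGG, NON_AGG = "aggressive", "non_aggressive"


@dataclass
class VotingModel:
    """Ranked voting genes with weighted sx scores and decision boundaries."""

    genes: list[str]
    weighted_sx: pd.Series
    boundaries: pd.Series
    boundary_mode: str = "zero"

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Average expression over probes mapping to the same gene, per sample."""
    missing = [p for p in matrix.index if p not in probe_to_gene]
    if missing:
        raise ValueError(f"probes without gene mapping: {missing[:5]}")
    genes = pd.Series({p: probe_to_gene[p] for p in matrix.index})
    out = matrix.groupby(genes).mean()
    out.index.name = matrix.index.name
    return out


def normalize_study(study: ExpressionStudy, log2: bool = False) -> ExpressionStudy:
    """Per-gene z-score within the study (after log2 when values are raw
    intensities). Constant genes are left at 0."""
    X = study.matrix.astype(float)
    if log2:
        X = np.log2(X.clip(lower=1e-12))
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1).replace(0.0, 1.0)
    Z = X.sub(mu, axis=0).div(sd, axis=0)
    return ExpressionStudy(name=study.name, matrix=Z, labels=study.labels, role=study.role)


def compute_sx(study: ExpressionStudy) -> pd.Series:
    """Per-gene signal-to-noise statistic; positive = higher in
    non-aggressive tumors. Genes with zero pooled spread get sx = 0 with a
    warning (uninformative)."""
    study.validate()
    is_na = (study.labels == NON_AGG).to_numpy()
    X = study.matrix.to_numpy(float)
    mu_na = X[:, is_na].mean(axis=1)
    mu_ag = X[:, ~is_na].mean(axis=1)
    sd_na = X[:, is_na].std(axis=1, ddof=1)
    sd_ag = X[:, ~is_na].std(axis=1, ddof=1)
    denom = sd_na + sd_ag
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"{study.name}: {int(zero.sum())} gene(s) with zero pooled SD; sx set to 0"
        )
        denom = np.where(zero, 1.0, denom)
    sx = np.where(zero, 0.0, (mu_na - mu_ag) / denom)
    return pd.Series(sx, index=study.matrix.index, name=f"sx_{study.name}")


def select_top_informative(sx: pd.Series, n_each: int = 500) -> set[str]:
    """Union of the ``n_each`` most-positive and ``n_each`` most-negative
    sx genes; boundary ties broken by gene identifier."""
    if len(sx) < 2 * n_each:
        raise ValueError(f"need >= {2 * n_each} genes, have {len(sx)}")
    ranked = sx.to_frame("sx").reset_index()
    ranked.columns = ["gene", "sx"]
    top = ranked.sort_values(["sx", "gene"], ascending=[False, True]).head(n_each)
    bottom = ranked.sort_values(["sx", "gene"], ascending=[True, True]).head(n_each)
    return set(top["gene"]) | set(bottom["gene"])


def weighted_average_sx(
    sx_per_study: dict[str, pd.Series], n_per_study: dict[str, int]
) -> pd.Series:
    """Sample-size-weighted mean sx over training studies, computed on the
    genes present in every study's series."""
    if set(sx_per_study) != set(n_per_study):
        raise ValueError("study name mismatch between sx and sample sizes")
    for name, n in n_per_study.items():
        if n <= 0:
            raise ValueError(f"study {name!r} has non-positive sample size")
    common = None
    for s in sx_per_study.values():
        common = set(s.index) if common is None else common & set(s.index)
    common = sorted(common)
    total = sum(n_per_study.values())
    acc = pd.Series(0.0, index=common)
    for name, s in sx_per_study.items():
        acc += s.loc[common] * (n_per_study[name] / total)
    return acc.rename("weighted_sx")


def rank_genes(weighted_sx: pd.Series) -> pd.DataFrame:
    """Genes ranked by decreasing |weighted sx| (ties by name)."""
    df = weighted_sx.to_frame("weighted_sx")
    df.index.name = "gene"
    df["abs_sx"] = df["weighted_sx"].abs()
    df = df.sort_values(
        ["abs_sx", "gene"], ascending=[False, True], kind="stable"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="abs_sx")


def build_model(
    ranked: pd.DataFrame,
    n_genes: int,
    boundary_mode: str = "zero",
    training_studies: list[ExpressionStudy] | None = None,
) -> VotingModel:
    """Voting model from the top ``n_genes`` ranked genes.

    ``boundary_mode="zero"`` sets every decision boundary to 0 (appropriate
    on per-gene standardized data); ``"midpoint"`` uses the class-mean
    midpoint (mu_non_aggressive + mu_aggressive)/2 pooled over the provided
    training studies.
    """
    if n_genes > len(ranked):
        raise ValueError(f"n_genes={n_genes} exceeds ranked list ({len(ranked)})")
    genes = list(ranked.index[:n_genes])
    wsx = ranked["weighted_sx"].loc[genes]
    if boundary_mode == "zero":
        b = pd.Series(0.0, index=genes)
    elif boundary_mode == "midpoint":
        if not training_studies:
            raise ValueError("midpoint boundaries require training studies")
        mids = []
        for st in training_studies:
            is_na = (st.labels == NON_AGG).to_numpy()
            sub = st.matrix.loc[genes]
            mids.append(
                (sub.loc[:, is_na].mean(axis=1) + sub.loc[:, ~is_na].mean(axis=1)) / 2.0
            )
        b = pd.concat(mids, axis=1).mean(axis=1)
    else:
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    return VotingModel(genes=genes, weighted_sx=wsx, boundaries=b, boundary_mode=boundary_mode)


def classify(model: VotingModel, sample: pd.Series) -> dict:
    """Vote a single specimen.

    Per model gene ``v = weighted_sx * (g - b)``; genes missing from the
    sample are skipped (logged in the result); V > 0 labels non-aggressive,
    V < 0 aggressive, V == 0 indeterminate.
    """
    votes = {}
    skipped = []
    for g in model.genes:
        if g not in sample.index or pd.isna(sample[g]):
            skipped.append(g)
            continue
        votes[g] = float(
            model.weighted_sx[g] * (float(sample[g]) - model.boundaries[g])
        )
    if not votes:
        raise ValueError("sample provides no model genes")
    V = float(sum(votes.values()))
    label = NON_AGG if V > 0 else (AGG if V < 0 else "indeterminate")
    return {"votes": votes, "V": V, "label": label, "skipped_genes": skipped}


def evaluate_models(
    studies: list[ExpressionStudy],
    ranked: pd.DataFrame,
    n_range=None,
    boundary_mode: str = "zero",
    training_studies: list[ExpressionStudy] | None = None,
) -> pd.DataFrame:
    """Accuracy/sensitivity/specificity of n-gene models per study.

    Genes are added consecutively in rank order; for each ``n`` every
    specimen of every study is classified and tabulated against its label.
    Indeterminate calls count as errors. Sensitivity is the detection rate
    of aggressive tumors (the clinically costly class), specificity that of
    non-aggressive ones.
    """
    if n_range is None:
        n_range = range(1, len(ranked) + 1)
    n_range = [n for n in n_range if n >= 1]
    if max(n_range) > len(ranked):
        warnings.warn(
            f"n_range truncated to ranked-list length {len(ranked)}"
        )
        n_range = [n for n in n_range if n <= len(ranked)]
    rows = []
    for n in n_range:
        model = build_model(ranked, n, boundary_mode, training_studies)
        for st in studies:
            preds = [
                classify(model, st.matrix[c])["label"] for c in st.matrix.columns
            ]
            truth = st.labels.to_numpy()
            preds = np.asarray(preds)
            correct = preds == truth
            agg = truth == AGG
            rows.append(
                {
                    "n_genes": n,
                    "study": st.name,
                    "role": st.role,
                    "accuracy": float(correct.mean()),
                    "sensitivity": float(correct[agg].mean()) if agg.any() else np.nan,
                    "specificity": float(correct[~agg].mean()) if (~agg).any() else np.nan,
                    "n_indeterminate": int((preds == "indeterminate").sum()),
                }
            )
    return pd.DataFrame(rows)


def train_voting_model(
    training: list[ExpressionStudy],
    n_each: int = 500,
    n_genes: int = 11,
    normalize: bool = True,
    boundary_mode: str = "zero",
):
    """End-to-end training: normalize, sx per study, per-study informative
    sets, intersection, weighted ranking, model of ``n_genes``.

    Returns ``(model, ranked)``.
    """
    studies = [normalize_study(s) if normalize else s for s in training]
    sx = {s.name: compute_sx(s) for s in studies}
    informative = None
    for name, s in sx.items():
        sel = select_top_informative(s, n_each=n_each)
        informative = sel if informative is None else informative & sel
    sx_sub = {name: s.loc[sorted(informative)] for name, s in sx.items()}
    wsx = weighted_average_sx(sx_sub, {s.name: s.n_samples for s in studies})
    ranked = rank_genes(wsx)
    model = build_model(ranked, min(n_genes, len(ranked)), boundary_mode, studies)
    return model, ranked
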