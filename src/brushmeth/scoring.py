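"""The CpG discriminant score: ROC-based CpG ranking, two-class linear
discriminant fitting, positivity-threshold selection and classification.

A sample's score is ``S = sum_i c_i * m_i + b`` over the model's selected
CpGs; a sample is positive iff ``S`` strictly exceeds the model threshold.
The published positivity threshold is shipped as ``PUBLISHED_THRESHOLD``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .methcall import MethylationMatrix

#: Fixed positivity cut-off used in "fixed" threshold mode.
PUBLISHED_THRESHOLD = 1.0615547


class UnevaluableSampleError(ValueError):
    """Too many of the model's CpGs are missing to score the sample."""


@dataclass(frozen=True)
class SampleScore:
    sample_id: str
    score: float
    positive: bool


@dataclass
class ScoreModel:
    """Selected CpGs, their coefficients, the constant and the threshold."""

    cpg_ids: list[str]
    coefficients: list[float]
    constant: float
    threshold: float = PUBLISHED_THRESHOLD
    impute_means: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.cpg_ids) != len(self.coefficients):
            raise ValueError("cpg_ids and coefficients must have equal length")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        for cid, m in self.impute_means.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"impute mean for {cid} outside [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cpg_ids": self.cpg_ids,
            "coefficients": self.coefficients,
            "constant": self.constant,
            "threshold": self.threshold,
            "impute_means": self.impute_means,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        payload = json.loads(Path(path).read_text())
        model = cls(
            cpg_ids=list(payload["cpg_ids"]),
            coefficients=[float(c) for c in payload["coefficients"]],
            constant=float(payload["constant"]),
            threshold=float(payload.get("threshold", PUBLISHED_THRESHOLD)),
            impute_means={k: float(v) for k, v in payload.get("impute_means", {}).items()},
            provenance=str(payload.get("provenance", "")),
        )
        if model.threshold != PUBLISHED_THRESHOLD:
            warnings.warn(
                f"model file supplies its own threshold {model.threshold} "
                f"(published default {PUBLISHED_THRESHOLD})"
            )
        return model


# ---------------------------------------------------------------------------
# CpG ranking by AUC
# ---------------------------------------------------------------------------

def rank_cpgs_by_auc(matrix: MethylationMatrix, labels) -> pd.DataFrame:
    """Per-CpG AUC (rank statistic, ties share average rank), descending.

    ``labels`` is a 0/1 vector in the matrix's sample order (1 = tumor).
    CpGs with any missing training value are dropped with a warning.
    """
    y = np.asarray(labels, dtype=int)
    if y.size != len(matrix.sample_ids):
        raise ValueError("labels must match the number of samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be represented")
    n1 = int(y.sum())
    n0 = y.size - n1
    rows = []
    dropped = []
    for cid in matrix.cpg_ids:
        x = matrix.ratios[cid].to_numpy(dtype=float)
        if np.isnan(x).any():
            dropped.append(cid)
            continue
        ranks = rankdata(x)
        auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        rows.append((cid, float(auc)))
    if dropped:
        warnings.warn(f"{len(dropped)} CpGs dropped for missing training values")
    out = pd.DataFrame(rows, columns=["cpg_id", "auc"])
    return out.sort_values("auc", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# linear discriminant fit
# ---------------------------------------------------------------------------

def fit_lda(
    matrix: MethylationMatrix,
    labels,
    cpg_ids: list[str] | None = None,
    ridge: float = 1e-6,
) -> ScoreModel:
    """Two-class linear discriminant on the selected CpGs.

    Coefficients solve ``S_pooled w = mu1 - mu0``; the constant centres the
    score at the class-mean midpoint (``b = -w . (mu0+mu1)/2``). A ridge
    term ``ridge * I`` is added when the pooled covariance is
    ill-conditioned. The returned model has the published default
    threshold; callers re-estimate it with :func:`choose_threshold`.
    """
    y = np.asarray(labels, dtype=int)
    ids = list(cpg_ids) if cpg_ids is not None else list(matrix.cpg_ids)
    X = matrix.ratios[ids].to_numpy(dtype=float)
    if np.isnan(X).any():
        means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), means, X)
        warnings.warn("missing training values imputed with column means")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be represented")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if min(n0, n1) < 2:
        raise ValueError("need >= 2 samples per class")
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    pooled = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1)
              + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
    pooled = np.atleast_2d(pooled)
    diff = mu1 - mu0
    if np.allclose(diff, 0):
        warnings.warn("identical class means: degenerate zero-coefficient model")
        w = np.zeros_like(diff)
    else:
        cond = np.linalg.cond(pooled)
        if not np.isfinite(cond) or cond > 1e8:
            pooled = pooled + ridge * np.eye(pooled.shape[0])
        try:
            w = np.linalg.solve(pooled, diff)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; increase ridge or reduce CpGs"
            )
    b = float(-w @ ((mu0 + mu1) / 2))
    impute = {cid: float(m) for cid, m in zip(ids, X.mean(axis=0))}
    return ScoreModel(
        cpg_ids=ids,
        coefficients=[float(c) for c in w],
        constant=b,
        impute_means=impute,
        provenance=f"LDA fit on {len(y)} samples ({n1} positive-class)",
    )


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def choose_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J over midpoints of adjacent scores.

    Positivity is ``score > t`` (strict). Ties on J are broken toward
    higher sensitivity, then toward the lower threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical; threshold undefined")
    cuts = (uniq[:-1] + uniq[1:]) / 2
    n1 = int(y.sum())
    n0 = y.size - n1
    best = None
    for t in cuts:
        pos = s > t
        sens = (pos & (y == 1)).sum() / n1
        spec = (~pos & (y == 0)).sum() / n0
        j = sens + spec - 1
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, float(t))
    return best[1]


def train_score_model(
    matrix: MethylationMatrix,
    labels,
    k: int = 20,
    threshold_mode: str = "refit",
) -> tuple[ScoreModel, pd.DataFrame]:
    """Rank CpGs, fit the discriminant on the top ``k``, set the threshold.

    ``threshold_mode`` is ``"refit"`` (Youden on training scores) or
    ``"fixed"`` (the published constant). Returns (model, AUC table).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    auc_table = rank_cpgs_by_auc(matrix, labels)
    top = auc_table["cpg_id"].head(k).tolist()
    model = fit_lda(matrix, labels, cpg_ids=top)
    if threshold_mode == "refit":
        scores = [apply_score(model, matrix.ratios.loc[sid], sid).score
                  for sid in matrix.sample_ids]
        model.threshold = choose_threshold(scores, labels)
    elif threshold_mode == "fixed":
        model.threshold = PUBLISHED_THRESHOLD
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return model, auc_table


# ---------------------------------------------------------------------------
# scoring and classification
# ---------------------------------------------------------------------------

def apply_score(
    model: ScoreModel,
    row,
    sample_id: str = "sample",
    max_missing_fraction: float = 0.5,
) -> SampleScore:
    """Score one sample: ``S = sum c_i * m_i + b``, positive iff ``S > tau``.

    Missing CpGs are imputed from the model's training means; a sample
    missing more than ``max_missing_fraction`` of the model's CpGs is
    rejected as unevaluable instead of being silently scored.
    """
    if isinstance(row, pd.Series):
        values = {cid: row.get(cid, np.nan) for cid in model.cpg_ids}
    else:
        values = {cid: row.get(cid, np.nan) for cid in model.cpg_ids}
    missing = [cid for cid, v in values.items() if v is None or not np.isfinite(v)]
    if model.cpg_ids and len(missing) / len(model.cpg_ids) > max_missing_fraction:
        raise UnevaluableSampleError(
            f"{sample_id}: {len(missing)}/{len(model.cpg_ids)} model CpGs missing"
        )
    s = model.constant
    for cid, coef in zip(model.cpg_ids, model.coefficients):
        v = values[cid]
        if v is None or not np.isfinite(v):
            if cid not in model.impute_means:
                raise UnevaluableSampleError(
                    f"{sample_id}: CpG {cid} missing and no impute mean recorded"
                )
            v = model.impute_means[cid]
        s += coef * v
    return SampleScore(sample_id=sample_id, score=float(s), positive=bool(s > model.threshold))


def classify_scores(scores, threshold: float, sample_ids=None) -> list[SampleScore]:
    """Turn precomputed scores into positive/negative calls at a threshold."""
    s = np.asarray(scores, dtype=float)
    ids = sample_ids if sample_ids is not None else [f"sample_{i + 1}" for i in range(s.size)]
    return [
        SampleScore(sample_id=str(sid), score=float(v), positive=bool(v > threshold))
        for sid, v in zip(ids, s)
    ]


def percent_one_decimal(count: int, total: int) -> float:
    """100*count/total truncated (floored) to one decimal, exact in integers."""
    if total <= 0:
        raise ValueError("total must be positive")
    return (count * 1000 // total) / 10


def summarize_positivity(n_positive: int, n_total: int) -> dict:
    """Cohort positivity summary with one-decimal percentages."""
    if n_total == 0:
        return {"n": 0, "n_positive": 0, "n_negative": 0,
                "pct_positive": None, "pct_negative": None}
    return {
        "n": n_total,
        "n_positive": n_positive,
        "n_negative": n_total - n_positive,
        "pct_positive": percent_one_decimal(n_positive, n_total),
        "pct_negative": percent_one_decimal(n_total - n_positive, n_total),
    }


def classify_cohort(
    model: ScoreModel,
    matrix: MethylationMatrix,
    max_missing_fraction: float = 0.5,
) -> tuple[list[SampleScore], dict]:
    """Score every sample of a matrix and summarize positive/negative counts."""
    scores: list[SampleScore] = []
    for sid in matrix.sample_ids:
        scores.append(
            apply_score(model, matrix.ratios.loc[sid], sid, max_missing_fraction)
        )
    summary = summarize_positivity(sum(s.positive for s in scores), len(scores))
    return scores, summary
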