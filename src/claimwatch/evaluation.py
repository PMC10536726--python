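"""Claim-level scoring, threshold sweep, classification metrics, McNemar.

The autoencoder produces one reconstruction probability per procedure code on
a claim; these are aggregated to a single claim score in [0, 1] oriented so
that a score near one means "at least one procedure on this claim is an
outlier".  The default aggregator is ``1 - min(per-code probability)``: a
claim is as suspicious as its least-reconstructable procedure.

Claim scores are binarized at every threshold on the 21-point grid
0.00, 0.05, ..., 1.00 (score >= threshold -> predicted outlier); precision,
recall and F1 (outliers = positive class) are computed at each threshold, and
the reported operating point is the threshold maximizing F1, ties broken
toward the lower threshold (the higher-recall side, which is the preference
for post-payment review where a false negative is a missed overutilization).

Two models are compared with McNemar's paired test on the discordance table
of their best-threshold predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

logger = logging.getLogger(__name__)

#: 0.00 .. 1.00 in 0.05 increments (21 points).
THRESHOLD_GRID: tuple[float, ...] = tuple(float(t) for t in np.round(np.linspace(0.0, 1.0, 21), 2))

AGGREGATORS = ("min", "mean", "product")


class EvaluationError(ValueError):
    pass


def aggregate_claim_score(per_cpt: dict[str, float], method: str = "min") -> float:
    """Reduce per-procedure probabilities to one claim score in [0, 1].

    ``min``: 1 - min(p) — the claim scores as its most anomalous procedure
    (the natural "at least one code is an outlier" reduction, and the
    default).  ``mean``: 1 - mean(p).  ``product``: 1 - prod(p).
    """
    if not per_cpt:
        raise EvaluationError("cannot aggregate an empty per-CPT score map")
    probs = np.array(list(per_cpt.values()), dtype=np.float64)
    if method == "min":
        score = 1.0 - probs.min()
    elif method == "mean":
        score = 1.0 - probs.mean()
    elif method == "product":
        score = 1.0 - probs.prod()
    else:
        raise EvaluationError(f"unknown aggregator {method!r}; choose from {AGGREGATORS}")
    return float(np.clip(score, 0.0, 1.0))


@dataclass(frozen=True)
class ScoredClaim:
    claim_id: str
    claim_score: float
    truth: int
    per_cpt: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.claim_score <= 1.0:
            raise EvaluationError(f"claim_score {self.claim_score} outside [0, 1]")
        if self.truth not in (0, 1):
            raise EvaluationError(f"truth must be 0 or 1, got {self.truth}")


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    zero_division: bool = False


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    """Precision, recall and F1 with outliers as the positive class.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 = 2PR/(P+R).  A zero
    denominator yields 0 for that metric and sets the ``zero_division`` flag.
    """
    if min(tp, fp, fn, tn) < 0:
        raise EvaluationError("confusion counts must be non-negative")
    flag = False
    if tp + fp == 0:
        precision, flag = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, flag = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0.0:
        f1, flag = 0.0, True
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return Metrics(precision=precision, recall=recall, f1=f1, zero_division=flag)


@dataclass(frozen=True)
class ThresholdRow:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float


@dataclass
class ThresholdSweepResult:
    rows: list[ThresholdRow]
    best_threshold: float
    best_f1: float

    @property
    def best_row(self) -> ThresholdRow:
        return next(r for r in self.rows if r.threshold == self.best_threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


def sweep_thresholds(scored: Sequence[ScoredClaim]) -> ThresholdSweepResult:
    """Binarize claim scores at each grid threshold and score the confusion.

    Prediction rule: score >= threshold -> outlier (so threshold 0.0 predicts
    everything positive).  The best threshold maximizes F1; ties break toward
    the lower threshold.
    """
    if not scored:
        raise EvaluationError("no scored claims to sweep")
    scores = np.array([s.claim_score for s in scored])
    truth = np.array([s.truth for s in scored])
    rows = []
    for thr in THRESHOLD_GRID:
        pred = (scores >= thr).astype(int)
        tp = int(((pred == 1) & (truth == 1)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        fn = int(((pred == 0) & (truth == 1)).sum())
        tn = int(((pred == 0) & (truth == 0)).sum())
        m = compute_metrics(tp, fp, fn, tn)
        rows.append(
            ThresholdRow(
                threshold=thr, tp=tp, fp=fp, fn=fn, tn=tn,
                precision=m.precision, recall=m.recall, f1=m.f1,
            )
        )
    best = max(rows, key=lambda r: r.f1)  # max() keeps the first (lowest) tie
    return ThresholdSweepResult(rows=rows, best_threshold=best.threshold, best_f1=best.f1)


def predictions_at(scored: Sequence[ScoredClaim], threshold: float) -> np.ndarray:
    scores = np.array([s.claim_score for s in scored])
    return (scores >= threshold).astype(int)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # model A correct, model B wrong
    c: int  # model A wrong, model B correct
    method: str


def mcnemar_compare(
    truth: np.ndarray, pred_a: np.ndarray, pred_b: np.ndarray
) -> McNemarResult:
    """McNemar's paired test on the discordant predictions of two models.

    ``b`` counts items model A classifies correctly and model B does not;
    ``c`` the reverse.  The reported statistic is the continuity-corrected
    chi-square (|b - c| - 1)^2 / (b + c); the p-value comes from the exact
    binomial distribution when b + c < 25 and from the chi-square reference
    otherwise.  With no discordant pairs the models are indistinguishable and
    p = 1.
    """
    truth = np.asarray(truth).astype(int)
    pred_a = np.asarray(pred_a).astype(int)
    pred_b = np.asarray(pred_b).astype(int)
    if not (truth.shape == pred_a.shape == pred_b.shape):
        raise EvaluationError("truth and prediction vectors must share one length")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    if b + c == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, b=0, c=0, method="degenerate")
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    both_ok = int((a_ok & b_ok).sum())
    neither = int((~a_ok & ~b_ok).sum())
    table = [[both_ok, b], [c, neither]]
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    method = "exact-binomial" if exact else "chi-square-corrected"
    return McNemarResult(
        statistic=float(statistic), p_value=float(res.pvalue), b=b, c=c, method=method
    )


@dataclass
class EvaluationReport:
    model_name: str
    sweep: ThresholdSweepResult
    n_claims: int
    comparison_name: str | None = None
    comparison_sweep: ThresholdSweepResult | None = None
    mcnemar: McNemarResult | None = None

    def to_dict(self) -> dict:
        def sweep_dict(s: ThresholdSweepResult) -> dict:
            return {
                "best_threshold": s.best_threshold,
                "best_f1": s.best_f1,
                "best_confusion": {
                    k: getattr(s.best_row, k) for k in ("tp", "fp", "fn", "tn")
                },
                "best_metrics": {
                    "precision": s.best_row.precision,
                    "recall": s.best_row.recall,
                    "f1": s.best_row.f1,
                },
                "rows": [asdict(r) for r in s.rows],
            }

        doc = {
            "model": self.model_name,
            "n_claims": self.n_claims,
            "sweep": sweep_dict(self.sweep),
        }
        if self.comparison_sweep is not None:
            doc["comparison"] = {
                "model": self.comparison_name,
                "sweep": sweep_dict(self.comparison_sweep),
            }
        if self.mcnemar is not None:
            doc["mcnemar"] = asdict(self.mcnemar)
        return doc

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_model(
    scored: Sequence[ScoredClaim],
    comparison: Sequence[ScoredClaim] | None = None,
    model_name: str = "autoencoder",
    comparison_name: str = "dbscan",
) -> EvaluationReport:
    """Full report: sweep, best-threshold confusion, optional paired McNemar.

    When a comparison model is given, its claims must cover the same claim_id
    set; both models are binarized at their own best thresholds before the
    McNemar discordance table is built.
    """
    sweep = sweep_thresholds(scored)
    report = EvaluationReport(model_name=model_name, sweep=sweep, n_claims=len(scored))
    if comparison is not None:
        ids_a = {s.claim_id for s in scored}
        ids_b = {s.claim_id for s in comparison}
        if ids_a != ids_b:
            raise EvaluationError(
                f"claim_id sets differ between models "
                f"({len(ids_a ^ ids_b)} claims not shared)"
            )
        by_id = {s.claim_id: s for s in comparison}
        comparison = [by_id[s.claim_id] for s in scored]  # align order
        comp_sweep = sweep_thresholds(comparison)
        truth = np.array([s.truth for s in scored])
        pred_a = predictions_at(scored, sweep.best_threshold)
        pred_b = predictions_at(comparison, comp_sweep.best_threshold)
        report.comparison_name = comparison_name
        report.comparison_sweep = comp_sweep
        report.mcnemar = mcnemar_compare(truth, pred_a, pred_b)
    return report


def write_scored_claims(
    scored: Sequence[ScoredClaim], best_threshold: float, path: str | Path
) -> None:
    """Export the scored-claims table: claim_id, score, truth, prediction."""
    pd.DataFrame(
        {
            "claim_id": [s.claim_id for s in scored],
            "claim_score": [s.claim_score for s in scored],
            "truth": [s.truth for s in scored],
            "prediction_at_best_threshold": predictions_at(scored, best_threshold),
        }
    ).to_csv(path, index=False)


def read_scored_claims(path: str | Path) -> list[ScoredClaim]:
    df = pd.read_csv(path, dtype={"claim_id": str})
    return [
        ScoredClaim(claim_id=r.claim_id, claim_score=float(r.claim_score), truth=int(r.truth))
        for r in df.itertuples(index=False)
    ]


def plot_confusion_matrix(row: ThresholdRow, path: str | Path, title: str = "") -> None:
    """Render the 2x2 confusion matrix at one threshold as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.array([[row.tn, row.fp], [row.fn, row.tp]])
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, f"{v}", ha="center", va="center",
                color="white" if v > mat.max() / 2 else "black")
    ax.set_xticks([0, 1], ["normal", "outlier"])
    ax.set_yticks([0, 1], ["normal", "outlier"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    ax.set_title(title or f"threshold {row.threshold:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
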