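"""Density-based clustering baseline: noise points are predicted outliers.

DBSCAN clusters claims that are dense in the binary feature space and leaves
sparse, unreachable claims unclustered ("noise").  Noise claims become the
baseline's outlier predictions; clustered claims are normal.  Per-procedure
attribution is not defined for this baseline — it scores whole claims only.

On binary vectors the Euclidean metric reduces to the square root of the
Hamming distance, so ``eps`` is interpretable as "sqrt of how many feature
bits may differ inside a neighborhood"; Jaccard over the active bits is
selectable as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN

logger = logging.getLogger(__name__)


class DbscanConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DbscanConfig:
    eps: float = 2.0
    min_samples: int = 5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise DbscanConfigError(f"eps must be positive, got {self.eps}")
        if self.min_samples < 1:
            raise DbscanConfigError("min_samples must be >= 1")
        if self.metric not in ("euclidean", "jaccard"):
            raise DbscanConfigError(f"unsupported metric {self.metric!r}")


def fit_dbscan(X: np.ndarray, cfg: DbscanConfig) -> np.ndarray:
    """Cluster the encoded claims; returns sklearn-style labels (-1 = noise).

    Border points reachable from several clusters go to the cluster reached
    first in input order (the scan order rule of the underlying
    implementation), so labels are deterministic for a fixed input order.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise DbscanConfigError(f"expected a non-empty 2-D matrix, got shape {X.shape}")
    Xf = X.astype(bool) if cfg.metric == "jaccard" else X
    model = DBSCAN(eps=cfg.eps, min_samples=cfg.min_samples, metric=cfg.metric)
    return model.fit_predict(Xf)


def dbscan_claim_scores(labels: np.ndarray) -> np.ndarray:
    """Map cluster labels to claim-level outlier scores: noise -> 1.0."""
    labels = np.asarray(labels)
    return (labels == -1).astype(np.float64)


def tune_dbscan(
    X: np.ndarray,
    truth: np.ndarray,
    eps_grid: Sequence[float] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5),
    min_samples_grid: Sequence[int] = (3, 5, 10),
    metric: str = "euclidean",
) -> tuple[DbscanConfig, float]:
    """Grid-search (eps, min_samples) maximizing outlier F1 on labeled data.

    Stands in for hyper-parameter tuning on a labeled validation split; ties
    break toward the first grid point (smaller eps, then smaller min_samples).
    """
    from .evaluation import compute_metrics  # local import to avoid a cycle

    truth = np.asarray(truth).astype(int)
    best_cfg, best_f1 = None, -1.0
    for eps, ms in product(eps_grid, min_samples_grid):
        cfg = DbscanConfig(eps=eps, min_samples=ms, metric=metric)
        pred = dbscan_claim_scores(fit_dbscan(X, cfg)).astype(int)
        tp = int(((pred == 1) & (truth == 1)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        fn = int(((pred == 0) & (truth == 1)).sum())
        tn = int(((pred == 0) & (truth == 0)).sum())
        f1 = compute_metrics(tp, fp, fn, tn).f1
        logger.info("dbscan grid eps=%.2f min_samples=%d -> F1 %.4f", eps, ms, f1)
        if f1 > best_f1:
            best_cfg, best_f1 = cfg, f1
    assert best_cfg is not None
    return best_cfg, best_f1
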