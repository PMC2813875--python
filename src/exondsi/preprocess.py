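"""Sample normalization, DABG expression filtering, gene-level summary.

The fixed processing order is scale -> filter -> summarize:

1. percentile scaling conserves a chosen per-sample percentile (default the
   75th) as an additive shift on the log2 scale — multiplicative on the raw
   scale, matching scanner-software scaling semantics;
2. the detection-above-background (DABG) filter discards a probeset when
   fewer than ``min_detected`` samples (over ALL samples pooled) have a
   detection p-value at or below ``alpha``;
3. gene-level summarization collapses each transcript cluster's retained
   probesets to one value per sample (median by default).

Filtering is a boolean mask over probesets, not a deletion, until a caller
materializes it with :meth:`~exondsi.io.ProbesetMatrix.subset`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ProbesetAnnotation, ProbesetMatrix

__all__ = ["scale_percentile", "dabg_filter", "summarize_gene_level"]

logger = logging.getLogger(__name__)


def scale_percentile(
    matrix: ProbesetMatrix, q: float = 75.0, target: float | str = "median-of-samples"
) -> ProbesetMatrix:
    """Shift each sample so its q-th signal percentile equals a common target.

    Parameters
    ----------
    q : float
        Percentile in (0, 100), default 75.
    target : float or "median-of-samples"
        The common value the percentile is shifted to; the default uses the
        median of the per-sample percentiles, leaving the data centred.

    The shift is additive on the log2 scale, so within-sample rank order is
    preserved exactly.
    """
    if not 0 < q < 100:
        raise ValueError(f"percentile q must lie in (0, 100), got {q}")
    sig = matrix.signals
    const = sig.nunique(axis=0) <= 1
    if const.any():
        bad = list(sig.columns[const])
        raise ValueError(f"constant-signal sample(s), scaling undefined: {bad}")
    percs = sig.quantile(q / 100.0, axis=0)
    tgt = float(percs.median()) if target == "median-of-samples" else float(target)
    shifted = sig + (tgt - percs)
    return ProbesetMatrix(shifted, matrix.detection_p)


def dabg_filter(
    matrix: ProbesetMatrix, alpha: float = 0.05, min_detected: int = 3
) -> pd.Series:
    """Boolean retained-probeset mask from detection p-values.

    A probeset is retained iff at least ``min_detected`` samples — counted
    over all samples jointly, not per group — have p <= ``alpha``
    (boundary inclusive).
    """
    if matrix.detection_p is None:
        raise ValueError("dabg_filter requires detection p-values")
    detected = (matrix.detection_p <= alpha).sum(axis=1)
    mask = detected >= min_detected
    mask.name = "retained"
    return mask


def summarize_gene_level(
    matrix: ProbesetMatrix,
    annotation: ProbesetAnnotation,
    mask: pd.Series | None = None,
    method: str = "median",
) -> pd.DataFrame:
    """Collapse retained probesets to one row per transcript cluster.

    ``method`` is "median" (default, robust) or "mean", applied per sample
    over each cluster's retained probesets.  Clusters left with zero
    retained probesets are dropped and logged.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown summarization method {method!r}")
    sig = matrix.signals
    if mask is not None:
        sig = sig.loc[mask[mask].index.intersection(sig.index)]
    ann = annotation.table
    unannotated = sig.index.difference(ann.index)
    if len(unannotated):
        raise ValueError(
            f"{len(unannotated)} retained probeset(s) lack annotation, "
            f"e.g. {list(unannotated[:3])}"
        )
    clusters = ann.loc[sig.index, "transcript_cluster_id"]
    grouped = sig.groupby(clusters, sort=True)
    summary = grouped.median() if method == "median" else grouped.mean()
    all_clusters = set(ann["transcript_cluster_id"].unique())
    dropped = all_clusters - set(summary.index)
    if dropped:
        logger.info(
            "%d transcript cluster(s) dropped: no retained probesets", len(dropped)
        )
    summary.index.name = "transcript_cluster_id"
    return summary
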