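"""Windowed differential splicing indexes (dsi) and the dsiT score.

Alternative splicing on an exon array shows up as a *localized* difference
in probeset signal between two sample groups, on top of whatever whole-gene
expression difference exists.  The detector therefore works on the per-gene
vector of group differences

    delta_i = A_i - B_i

where ``A_i`` and ``B_i`` are the mean log2 signals of probeset ``i`` in
sample groups A and B, ordered along the transcript.  Over every window of
four contiguous probesets (n, n+1, n+2, n+3) three zero-sum linear
contrasts are evaluated:

    dsi_1 (step)  = (d_n + d_{n+1})/2 - (d_{n+2} + d_{n+3})/2
    dsi_2 (bump)  = (d_{n+1} + d_{n+2})/2 - (d_n + d_{n+3})/2
    dsi_3 (spike) = d_{n+1} - (d_n + d_{n+2} + d_{n+3})/3

Each contrast is zero on any constant window, so a uniform whole-gene shift
(differential expression, or a change of dynamic range between tissues)
contributes nothing — only local deviations score.  The total index

    dsiT(n) = |dsi_1| + |dsi_2| + |dsi_3|

is assigned to the window's anchor (first) probeset; the last three
probesets of a gene carry no score.  Per comparison, the K probesets with
the highest dsiT are retained (K = 100 by default), and selections across
the whole comparison plan are aggregated to a deduplicated transcript list.

The default comparison plan mirrors the study design: each hematopoietic
group (whole blood, CD34+ HSPC) versus each of 10 solid tissues (spleen
excluded for its mixed cellular content), plus blood versus CD34+ — 21
comparisons in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ProbesetAnnotation, ProbesetMatrix, SampleGroups

__all__ = [
    "DSI_COEFFICIENTS",
    "GroupDelta",
    "ComparisonPlan",
    "SplicingModel",
    "SplicingResults",
    "dsi_window",
    "dsiT_per_probeset",
    "group_delta",
    "select_top_k",
    "aggregate_as_list",
    "overlap_with_de",
    "default_plan",
]

logger = logging.getLogger(__name__)

#: Contrast coefficients (rows: step, bump, spike; columns: window positions
#: n..n+3).  Rows sum to zero, so every index is invariant to constant
#: shifts of the window.  Configurable via the ``coefficients`` argument of
#: the scoring functions.
DSI_COEFFICIENTS = np.array(
    [
        [0.5, 0.5, -0.5, -0.5],
        [-0.5, 0.5, 0.5, -0.5],
        [-1.0 / 3.0, 1.0, -1.0 / 3.0, -1.0 / 3.0],
    ]
)

WINDOW = 4


@dataclass(frozen=True)
class GroupDelta:
    """Per-gene vector of probeset group differences, in ordinal order."""

    cluster: str
    probeset_ids: tuple[str, ...]
    delta: np.ndarray  # same length as probeset_ids

    def __len__(self) -> int:
        return len(self.delta)


def dsi_window(
    window: np.ndarray, coefficients: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Evaluate the three dsi contrasts on one 4-probeset delta window."""
    w = np.asarray(window, dtype=float)
    if w.shape != (WINDOW,):
        raise ValueError(f"window must have exactly {WINDOW} values, got {w.shape}")
    if not np.isfinite(w).all():
        raise ValueError("non-finite value in dsi window")
    coeffs = DSI_COEFFICIENTS if coefficients is None else np.asarray(coefficients)
    d1, d2, d3 = coeffs @ w
    return float(d1), float(d2), float(d3)


def dsiT_per_probeset(
    delta: GroupDelta | np.ndarray, coefficients: np.ndarray | None = None
) -> pd.DataFrame:
    """Score every anchored window of one gene.

    Returns a frame with one row per anchor position (0..L-4) and columns
    dsi1, dsi2, dsi3, dsiT where dsiT = |dsi1| + |dsi2| + |dsi3|.  Genes
    shorter than four probesets are unscoreable.
    """
    if isinstance(delta, GroupDelta):
        vec = delta.delta
    else:
        vec = np.asarray(delta, dtype=float)
    if len(vec) < WINDOW:
        raise ValueError(
            f"dsi scoring needs >= {WINDOW} probesets, got {len(vec)}"
        )
    if not np.isfinite(vec).all():
        raise ValueError("non-finite value in delta vector")
    coeffs = DSI_COEFFICIENTS if coefficients is None else np.asarray(coefficients)
    windows = np.lib.stride_tricks.sliding_window_view(vec, WINDOW)
    contrasts = windows @ coeffs.T  # anchors x 3
    out = pd.DataFrame(contrasts, columns=["dsi1", "dsi2", "dsi3"])
    out["dsiT"] = np.abs(contrasts).sum(axis=1)
    out.index.name = "anchor"
    return out


def group_delta(
    matrix: ProbesetMatrix,
    annotation: ProbesetAnnotation,
    groups: SampleGroups,
    group_a: str,
    group_b: str,
    mask: pd.Series | None = None,
) -> dict[str, GroupDelta]:
    """Per-cluster delta vectors A - B over retained probesets.

    Probesets failing ``mask`` (typically the DABG filter) are removed
    before windows are formed, so windows are contiguous in the *retained*
    series.  Clusters with fewer than four retained probesets are excluded
    and logged.
    """
    samples_a = groups.samples_in(group_a)
    samples_b = groups.samples_in(group_b)
    sig = matrix.signals
    delta_all = sig[samples_a].mean(axis=1) - sig[samples_b].mean(axis=1)
    if mask is not None:
        retained = set(mask[mask].index)
    else:
        retained = set(sig.index)

    out: dict[str, GroupDelta] = {}
    n_excluded = 0
    for cluster, ps_ids in annotation.clusters().items():
        kept = [p for p in ps_ids if p in retained and p in delta_all.index]
        if len(kept) < WINDOW:
            n_excluded += 1
            continue
        out[cluster] = GroupDelta(
            cluster, tuple(kept), delta_all.loc[kept].to_numpy()
        )
    if n_excluded:
        logger.info(
            "%s vs %s: %d cluster(s) excluded (<%d retained probesets)",
            group_a, group_b, n_excluded, WINDOW,
        )
    return out


# ---------------------------------------------------------------------------
# comparison plans and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonPlan:
    """Ordered list of (group A, group B) pairs to score."""

    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    @staticmethod
    def labels(pair: tuple[str, str]) -> str:
        return f"{pair[0]}_vs_{pair[1]}"


def default_plan(
    group_names,
    hematopoietic: tuple[str, str] = ("blood", "cd34"),
    exclude: tuple[str, ...] = ("spleen",),
) -> ComparisonPlan:
    """The 21-comparison study plan.

    Each hematopoietic group versus each solid tissue (excluded groups —
    spleen by default, for its mixed hematopoietic content — are dropped),
    plus the hematopoietic pair against each other.
    """
    solids = [
        g for g in group_names if g not in hematopoietic and g not in exclude
    ]
    pairs = [(h, t) for h in hematopoietic for t in solids]
    pairs.append((hematopoietic[0], hematopoietic[1]))
    return ComparisonPlan(tuple(pairs))


def select_top_k(table: pd.DataFrame, comparison: str, k: int = 100) -> pd.DataFrame:
    """Flag the k highest-dsiT probesets of one comparison.

    Ties are broken by ascending probeset id, so selection is deterministic.
    If fewer than k probesets are scoreable all are selected and a warning
    is logged.
    """
    sub = table[table["comparison"] == comparison].copy()
    sub = sub.sort_values(
        ["dsiT", "probeset_id"], ascending=[False, True], kind="stable"
    )
    sub["rank"] = np.arange(1, len(sub) + 1)
    n_sel = min(k, len(sub))
    if n_sel < k:
        logger.warning(
            "%s: only %d scoreable probesets for top-%d selection",
            comparison, len(sub), k,
        )
    if n_sel and float(sub["dsiT"].iloc[0]) == 0.0:
        logger.warning("%s: all dsiT are zero; selection is degenerate", comparison)
    sub["selected"] = sub["rank"] <= n_sel
    return sub


def aggregate_as_list(table: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate selected probesets to a transcript list.

    Returns one row per transcript cluster with the number of selections,
    the supporting comparisons, and the best (maximum) dsiT, ordered by
    that score descending.
    """
    sel = table[table["selected"]]
    if sel.empty:
        return pd.DataFrame(
            columns=["transcript_cluster_id", "n_selections", "comparisons",
                     "max_dsiT"]
        ).set_index("transcript_cluster_id")
    grouped = sel.groupby("transcript_cluster_id")
    out = pd.DataFrame(
        {
            "n_selections": grouped.size(),
            "comparisons": grouped["comparison"].agg(
                lambda c: ",".join(sorted(set(c)))
            ),
            "max_dsiT": grouped["dsiT"].max(),
        }
    )
    return out.sort_values(
        ["max_dsiT", "transcript_cluster_id"], ascending=[False, True]
    )


def overlap_with_de(
    as_transcripts: set,
    up_union: set,
    down_union: set,
) -> dict[str, int]:
    """Counts of alternative-splicing transcripts among DE gene unions."""
    as_set = set(as_transcripts)
    return {
        "n_as": len(as_set),
        "n_up_union": len(up_union),
        "n_down_union": len(down_union),
        "as_in_up": len(as_set & set(up_union)),
        "as_in_down": len(as_set & set(down_union)),
    }


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class SplicingModel:
    """Differential-splicing detector over a probeset matrix.

    Parameters
    ----------
    matrix : ProbesetMatrix
        Normalized probeset signals (log2).
    annotation : ProbesetAnnotation
        Probeset -> transcript cluster / ordinal mapping.
    groups : SampleGroups
        Sample grouping; every matrix sample must be assigned.
    plan : ComparisonPlan, optional
        Defaults to the 21-comparison study plan built from the group names.
    mask : pandas.Series, optional
        Retained-probeset mask, typically from the DABG filter; scoring
        uses retained probesets only.
    """

    def __init__(
        self,
        matrix: ProbesetMatrix,
        annotation: ProbesetAnnotation,
        groups: SampleGroups,
        plan: ComparisonPlan | None = None,
        mask: pd.Series | None = None,
    ):
        groups.validate_against(matrix)
        self.matrix = matrix
        self.annotation = annotation
        self.groups = groups
        self.plan = plan if plan is not None else default_plan(groups.group_names)
        self.mask = mask

    def fit(self, k: int = 100,
            coefficients: np.ndarray | None = None) -> "SplicingResults":
        """Score every comparison of the plan and select the top-k probesets."""
        cluster_of = self.annotation.table["transcript_cluster_id"]
        pieces = []
        for pair in self.plan.pairs:
            comp = ComparisonPlan.labels(pair)
            deltas = group_delta(
                self.matrix, self.annotation, self.groups, *pair, mask=self.mask
            )
            rows = []
            for cluster, gd in deltas.items():
                scores = dsiT_per_probeset(gd, coefficients)
                scores = scores.assign(
                    probeset_id=[gd.probeset_ids[a] for a in scores.index],
                    transcript_cluster_id=cluster,
                    comparison=comp,
                )
                rows.append(scores)
            if not rows:
                logger.warning("%s: no scoreable clusters", comp)
                continue
            comp_table = pd.concat(rows, ignore_index=True)
            pieces.append(select_top_k(comp_table, comp, k=k))
        columns = [
            "probeset_id", "transcript_cluster_id", "comparison",
            "dsi1", "dsi2", "dsi3", "dsiT", "rank", "selected",
        ]
        if pieces:
            table = pd.concat(pieces, ignore_index=True)[columns]
        else:
            table = pd.DataFrame(columns=columns)
        _ = cluster_of  # annotation consistency is enforced in group_delta
        return SplicingResults(self, table, k=k)


@dataclass
class SplicingResults:
    """Scored dsi table plus the aggregated alternative-splicing list."""

    model: SplicingModel
    table: pd.DataFrame
    k: int
    _as_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    @property
    def as_table(self) -> pd.DataFrame:
        if self._as_table is None:
            self._as_table = aggregate_as_list(self.table)
        return self._as_table

    @property
    def as_transcripts(self) -> set[str]:
        return set(self.as_table.index)

    def summary(self) -> str:
        comps = self.table["comparison"].nunique()
        lines = [
            "Differential splicing (dsiT) scan",
            f"  comparisons:        {comps} of {len(self.model.plan)} planned",
            f"  top-K per compare:  {self.k}",
            f"  selections:         {self.n_selected} probesets "
            f"(with multiplicity across comparisons)",
            f"  AS transcripts:     {len(self.as_transcripts)} after "
            f"deduplication",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
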