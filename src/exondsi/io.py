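"""Readers and writers for the probeset-level formats shared by the pipeline.

The atomic measurement unit of an exon array is the probeset (PS): a small
group of oligonucleotide probes interrogating one exon-level target.  The
pipeline works on three plain-text artefacts:

* a signal matrix (probesets x samples, log2 scale, tab-delimited) with an
  optional parallel matrix of detection-above-background (DABG) p-values;
* a probeset annotation mapping each probeset to its transcript cluster
  (the array's gene-level grouping), an ordinal position along the
  transcription direction, and an evidence class (``core`` probesets target
  RefSeq transcripts, ``full`` adds EST/prediction-supported ones);
* a two-column sample-to-group table.

All readers validate and reject malformed input rather than coercing it;
writers produce files their paired readers accept bit-exactly for finite
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbesetMatrix",
    "ProbesetAnnotation",
    "SampleGroups",
    "FormatError",
    "read_signal_matrix",
    "write_signal_matrix",
    "read_annotation",
    "write_annotation",
    "read_groups",
    "write_groups",
]

EVIDENCE_CLASSES = frozenset({"core", "full"})


class FormatError(ValueError):
    """A file violated the expected dialect or internal consistency rules."""


@dataclass
class ProbesetMatrix:
    """Probesets x samples log2 signals with optional detection p-values.

    Parameters
    ----------
    signals : pandas.DataFrame
        Log2 signal values, index = probeset ids, columns = sample ids.
    detection_p : pandas.DataFrame, optional
        DABG p-values in (0, 1], same index/columns as ``signals``.
    """

    signals: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sig = self.signals
        if sig.index.has_duplicates:
            dup = sig.index[sig.index.duplicated()][0]
            raise FormatError(f"duplicate probeset id: {dup!r}")
        if sig.columns.has_duplicates:
            dup = sig.columns[sig.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(sig.to_numpy()).all():
            raise FormatError("signal matrix contains non-finite values")
        if self.detection_p is not None:
            p = self.detection_p
            if not (p.index.equals(sig.index) and p.columns.equals(sig.columns)):
                raise FormatError("detection_p index/columns do not match signals")
            vals = p.to_numpy()
            if not ((vals > 0) & (vals <= 1)).all():
                raise FormatError("detection p-values must lie in (0, 1]")

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.signals.shape

    def subset(self, probesets=None, samples=None) -> "ProbesetMatrix":
        """Return a new matrix restricted to the given probesets/samples."""
        sig = self.signals
        p = self.detection_p
        if probesets is not None:
            sig = sig.loc[probesets]
            p = p.loc[probesets] if p is not None else None
        if samples is not None:
            sig = sig[samples]
            p = p[samples] if p is not None else None
        return ProbesetMatrix(sig, p)


@dataclass
class ProbesetAnnotation:
    """Maps probesets to transcript clusters with ordinal positions.

    ``table`` has index = probeset_id and columns ``transcript_cluster_id``,
    ``ordinal`` (0-based, dense within each cluster, ordered 5'->3' along the
    transcription direction) and ``evidence`` (``core`` or ``full``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"transcript_cluster_id", "ordinal", "evidence"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"annotation missing column(s): {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"probeset {dup!r} assigned to more than one cluster")
        bad = set(t["evidence"].unique()) - EVIDENCE_CLASSES
        if bad:
            raise FormatError(f"unknown evidence class(es): {sorted(bad)}")
        self.table = _densify_ordinals(t)

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.table.index)

    def clusters(self) -> dict[str, list[str]]:
        """Transcript cluster id -> probeset ids in ordinal order."""
        ordered = self.table.sort_values(["transcript_cluster_id", "ordinal"])
        return {
            tc: list(sub.index)
            for tc, sub in ordered.groupby("transcript_cluster_id", sort=True)
        }

    def cluster_of(self, probeset_id: str) -> str:
        return self.table.at[probeset_id, "transcript_cluster_id"]


def _densify_ordinals(table: pd.DataFrame) -> pd.DataFrame:
    """Re-rank ordinals to 0..k-1 within each cluster, preserving order."""
    table = table.copy()
    table["ordinal"] = (
        table.groupby("transcript_cluster_id")["ordinal"]
        .rank(method="first")
        .astype(int)
        - 1
    )
    return table


@dataclass
class SampleGroups:
    """Assignment of each sample to exactly one group."""

    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        out = [s for s, g in self.assignment.items() if g == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    def validate_against(self, matrix: ProbesetMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignment]
        if missing:
            raise FormatError(f"samples without group assignment: {missing}")


# ---------------------------------------------------------------------------
# matrix TSV dialect: UTF-8, tab separator, '.' decimal, no quoting
# ---------------------------------------------------------------------------

def read_signal_matrix(path, detection_p_path=None) -> ProbesetMatrix:
    """Read a tab-delimited probeset signal matrix.

    Header row carries sample ids; first column carries probeset ids.
    Raises :class:`FormatError` on duplicate ids and a parse error naming
    the offending cell on non-numeric input.
    """
    signals = _read_matrix_tsv(path)
    detection_p = _read_matrix_tsv(detection_p_path) if detection_p_path else None
    return ProbesetMatrix(signals, detection_p)


def _read_matrix_tsv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    try:
        out = raw.astype(float)
    except ValueError:
        for col in raw.columns:
            for ps, cell in raw[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at row {ps!r}, "
                        f"column {col!r}"
                    ) from None
        raise
    out.index.name = None
    out.columns.name = None
    return out


def write_signal_matrix(matrix: ProbesetMatrix, path, detection_p_path=None) -> None:
    """Write the signal matrix (and optionally the p-value matrix) as TSV."""
    matrix.signals.to_csv(path, sep="\t", index_label="probeset_id")
    if detection_p_path is not None:
        if matrix.detection_p is None:
            raise ValueError("matrix carries no detection p-values")
        matrix.detection_p.to_csv(detection_p_path, sep="\t", index_label="probeset_id")


def read_annotation(path) -> ProbesetAnnotation:
    """Read probeset annotation CSV.

    Required columns: probeset_id, transcript_cluster_id, ordinal, evidence.
    Ordinals are re-densified to 0..k-1 per cluster after sorting.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["probeset_id", "transcript_cluster_id", "ordinal", "evidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing column(s): {missing}")
    df["ordinal"] = df["ordinal"].astype(int)
    df = df.set_index("probeset_id")
    return ProbesetAnnotation(df)


def write_annotation(annotation: ProbesetAnnotation, path) -> None:
    annotation.table.to_csv(path, index_label="probeset_id")


def read_groups(path) -> SampleGroups:
    """Read a two-column TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "group"]:
        raise FormatError(f"{path}: expected columns sample_id, group; got {cols}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: sample {dup!r} assigned to more than one group")
    return SampleGroups(dict(zip(df["sample_id"], df["group"])))


def write_groups(groups: SampleGroups, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.assignment), "group": list(groups.assignment.values())}
    ).to_csv(path, sep="\t", index=False)
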