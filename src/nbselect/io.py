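"""Count-matrix readers/writers and the real-data preprocessing step.

Count tables are plain TSV/CSV: first column feature ids, header row of
sample ids, integer cells.  Group labels (1 = case, 0 = control) arrive
either as a row of the matrix itself or as a sidecar file of
``sample_id<TAB>label`` lines.  The only preprocessing applied to real
cohorts is the low-expression filter: features whose total count across all
samples falls below a threshold (default 10) are dropped, with the removals
logged in the table's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import LabeledCountMatrix

__all__ = [
    "CohortTable",
    "read_count_matrix",
    "write_count_matrix",
    "filter_low_expression",
    "write_truth_mask",
    "read_truth_mask",
]


@dataclass
class CohortTable:
    """A loaded cohort: counts + labels plus provenance of any filtering."""

    data: LabeledCountMatrix
    source: str = ""
    filter_log: list[str] = field(default_factory=list)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_matrix(
    path: str | Path,
    label_row_or_file: str | Path = "label",
) -> CohortTable:
    """Read a features-x-samples count table with binary labels.

    ``label_row_or_file`` names either a row of the table holding the 0/1
    labels (default ``"label"``) or a sidecar file of ``sample_id  label``
    pairs.  Duplicate feature ids, non-numeric cells and non-integer counts
    raise errors that name the offending coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    frame.index = frame.index.astype(str)

    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature id {dup[0]!r} in {path}")

    label_key = str(label_row_or_file)
    labels = None
    if label_key in frame.index:
        labels = frame.loc[label_key]
        frame = frame.drop(index=label_key)
    elif Path(label_row_or_file).exists():
        side = pd.read_csv(Path(label_row_or_file), sep=None, engine="python",
                           header=None, index_col=0)
        labels = side.iloc[:, 0].reindex(frame.columns)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])[:3]
            raise ValueError(f"label sidecar misses samples {missing}")
    else:
        raise ValueError(
            f"labels not found: no row {label_key!r} in {path} and no such file")

    for col in frame.columns:
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric cell at feature {bad[0]!r}, sample {col!r} in {path}")
    values = frame.to_numpy(dtype=float)
    if not np.allclose(values, np.rint(values)):
        g, s = np.argwhere(~np.isclose(values, np.rint(values)))[0]
        raise ValueError(
            f"non-integer count at feature {frame.index[g]!r}, "
            f"sample {frame.columns[s]!r}")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at feature {frame.index[g]!r}, sample {frame.columns[s]!r}")

    data = LabeledCountMatrix(
        counts=values.astype(np.int64),
        labels=labels.astype(int).to_numpy(),
        feature_ids=list(frame.index),
        sample_ids=list(frame.columns),
    )
    return CohortTable(data=data, source=str(path))


def write_count_matrix(table: CohortTable | LabeledCountMatrix,
                       path: str | Path, with_labels: bool = True) -> None:
    """Write a count table (TSV/CSV by extension), labels as a ``label`` row."""
    data = table.data if isinstance(table, CohortTable) else table
    path = Path(path)
    frame = pd.DataFrame(data.counts, index=data.feature_ids, columns=data.sample_ids)
    if with_labels:
        frame = pd.concat([
            pd.DataFrame([data.labels], index=["label"], columns=data.sample_ids),
            frame,
        ])
    frame.to_csv(path, sep=_sep_for(path), index_label="feature_id")


def write_truth_mask(data: LabeledCountMatrix, path: str | Path) -> None:
    if data.truth is None:
        raise ValueError("dataset carries no truth mask")
    frame = pd.DataFrame({"feature_id": data.feature_ids,
                          "is_significant": data.truth.astype(int)})
    frame.to_csv(path, sep="\t", index=False)


def read_truth_mask(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t")
    return frame["is_significant"].to_numpy().astype(bool)


def filter_low_expression(table: CohortTable, min_total: int = 10) -> CohortTable:
    """Drop features whose summed count over all samples is below
    ``min_total`` (a feature summing to exactly ``min_total`` is kept).

    Idempotent; raises if nothing survives.
    """
    data = table.data
    totals = data.counts.sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError(f"low-expression filter (total < {min_total}) removed "
                         "every feature")
    removed = [f"{fid} (total {tot})"
               for fid, tot in zip(data.feature_ids, totals) if tot < min_total]
    filtered = LabeledCountMatrix(
        counts=data.counts[keep],
        labels=data.labels,
        truth=data.truth[keep] if data.truth is not None else None,
        feature_ids=[f for f, k in zip(data.feature_ids, keep) if k],
        sample_ids=list(data.sample_ids),
    )
    log = table.filter_log + [
        f"low-expression filter: removed {len(removed)} of {data.n_features} "
        f"features with total < {min_total}: {', '.join(removed) or 'none'}"
    ]
    return CohortTable(data=filtered, source=table.source, filter_log=log)
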