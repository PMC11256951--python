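"""Reading, validation, alignment and output of taxa-abundance tables.

Tables are plain tab-separated text in the FEAST/SourceTracker style:
one row per taxon (or per sample, see ``orientation``), one column per
sample, non-negative counts or relative abundances, with taxon and sample
identifiers in the first column and first row.  Lines starting with ``#``
are treated as comments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "ProportionRecord",
    "read_abundance_table",
    "read_metadata",
    "align_taxa",
    "normalize_columns",
    "write_proportions",
    "read_proportions",
]


@dataclass(frozen=True)
class AbundanceTable:
    """A taxa x samples non-negative abundance matrix with identifiers.

    Parameters
    ----------
    taxon_ids
        Ordered, unique taxon identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    values
        Non-negative float matrix of shape ``(len(taxon_ids), len(sample_ids))``.
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError("abundance values must be a 2-D matrix")
        if values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite abundance at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance {values[i, j]} at taxon "
                f"{self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    def column(self, sample_id: str) -> np.ndarray:
        """Abundance vector of one sample."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None
        return self.values[:, j].copy()

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(self.taxon_ids, tuple(sample_ids), self.values[:, idx])


@dataclass(frozen=True)
class ProportionRecord:
    """Estimated source proportions for one sink sample.

    ``source_ids`` ends with ``"Unknown"``; ``proportions`` is a simplex
    vector of length K+1 whose last entry is the aggregate unknown-source
    proportion.
    """

    sink_id: str
    source_ids: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "source_ids", tuple(str(s) for s in self.source_ids))
        if len(self.source_ids) != props.size:
            raise ValueError("source_ids and proportions differ in length")
        if self.source_ids[-1] != "Unknown":
            raise ValueError('final source id must be "Unknown"')
        if np.any(props < -1e-9) or np.any(props > 1 + 1e-9):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {props.sum()}, expected 1")


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id {x!r}")
        seen.add(x)


def read_abundance_table(
    path: str | Path,
    orientation: Literal["taxa-in-rows", "taxa-in-columns"] = "taxa-in-rows",
) -> AbundanceTable:
    """Read a tab-separated abundance table.

    The first row and first column carry sample/taxon identifiers (the
    top-left header cell is ignored).  ``orientation`` states what the file
    rows are; the returned table is always taxa x samples.
    """
    path = Path(path)
    if orientation not in ("taxa-in-rows", "taxa-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if orientation == "taxa-in-columns":
        df = df.T
    body = np.empty(df.shape, dtype=float)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            try:
                body[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {cell!r} at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r} in {path}"
                ) from None
    return AbundanceTable(tuple(df.index), tuple(df.columns), body)


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read a (SampleID, SourceSink) metadata table.

    Returns a mapping from sample id to its role (``"source"``/``"sink"``,
    case-normalized).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        sid = cols["sampleid"]
        role = cols["sourcesink"]
    except KeyError:
        raise ValueError(
            f"metadata {path} must have SampleID and SourceSink columns"
        ) from None
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        value = str(row[role]).strip().lower()
        if value not in ("source", "sink"):
            raise ValueError(f"SourceSink value {row[role]!r} is not source/sink")
        out[str(row[sid])] = value
    return out


def align_taxa(
    sources: AbundanceTable, sinks: AbundanceTable
) -> tuple[AbundanceTable, AbundanceTable]:
    """Place two tables on the sorted union of their taxon sets.

    Taxa absent from one table are zero-filled there: sink taxa unseen in
    every reference source are informative (they drive the unknown-source
    estimate) and must not be dropped.
    """
    union = sorted(set(sources.taxon_ids) | set(sinks.taxon_ids))
    if not union:
        raise ValueError("taxon union is empty")

    def reindex(table: AbundanceTable) -> AbundanceTable:
        pos = {t: i for i, t in enumerate(table.taxon_ids)}
        values = np.zeros((len(union), table.n_samples))
        for row, taxon in enumerate(union):
            if taxon in pos:
                values[row] = table.values[pos[taxon]]
        return AbundanceTable(tuple(union), table.sample_ids, values)

    return reindex(sources), reindex(sinks)


def normalize_columns(table: AbundanceTable) -> AbundanceTable:
    """Scale every sample column to sum to one (relative abundances)."""
    sums = table.values.sum(axis=0)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total abundance"
        )
    return AbundanceTable(table.taxon_ids, table.sample_ids, table.values / sums)


def write_proportions(
    records: Sequence[ProportionRecord],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write sink-by-source proportion records as TSV.

    One row per sink; columns are the source ids (last one ``Unknown``).
    All records must share one source ordering.  ``header_comment`` lines,
    if given, are emitted first prefixed with ``#``.
    """
    path = Path(path)
    records = list(records)
    if records:
        source_ids = records[0].source_ids
        for rec in records[1:]:
            if rec.source_ids != source_ids:
                raise ValueError("records disagree on source ids/order")
    else:
        source_ids = ("Unknown",)
    lines: list[str] = []
    if header_comment:
        lines.extend(f"# {line}" for line in header_comment.splitlines())
    lines.append("\t".join(["SinkID", *source_ids]))
    for rec in records:
        lines.append(
            "\t".join([rec.sink_id, *(format(p, ".12g") for p in rec.proportions)])
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write proportions to {path}: {exc}") from exc


def read_proportions(path: str | Path) -> list[ProportionRecord]:
    """Inverse of :func:`write_proportions` (up to float formatting)."""
    path = Path(path)
    rows = [
        line.rstrip("\n")
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if not rows:
        raise ValueError(f"{path} has no header row")
    header = rows[0].split("\t")
    source_ids = tuple(header[1:])
    out = []
    for line in rows[1:]:
        fields = line.split("\t")
        props = np.array([float(x) for x in fields[1:]])
        # renormalize away formatting round-off before validation
        props = props / props.sum()
        out.append(ProportionRecord(fields[0], source_ids, props))
    return out
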