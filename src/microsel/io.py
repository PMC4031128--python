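"""Readers and writers for the tab-delimited table formats used by the pipeline.

Two dialects are supported:

* the "classic" OTU table: first header field ``#OTU ID``, one row per OTU,
  one column per sample, optional trailing ``taxonomy`` column;
* the mapping (sample metadata) file: first header field ``#SampleID``,
  one row per sample.

Both are parsed into validated, typed containers. Missing metadata cells are
stored as the explicit token ``"NA"`` rather than the empty string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

__all__ = [
    "CountTable",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_mapping",
    "write_mapping",
    "align_samples",
    "MISSING_TOKEN",
]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise InputError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """A samples x OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers (rows of ``counts``).
    otu_ids
        Ordered unique OTU identifiers (columns of ``counts``).
    counts
        Integer array of shape ``(n_samples, n_otus)``; no negative entries,
        every row total strictly positive.
    taxonomy
        Optional map from OTU id to a lineage string.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.otu_ids = list(self.otu_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.otu_ids),
        ):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                raise InputError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise InputError(
                f"negative count for sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            i = int(np.argmax(totals == 0))
            raise InputError(f"sample {self.sample_ids[i]!r} has zero total count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
            and (self.taxonomy or {}) == (other.taxonomy or {})
        )


@dataclass
class SampleMetadata:
    """Per-sample categorical metadata, keyed by sample id, in file order."""

    sample_ids: list[str]
    columns: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        for name, vals in self.columns.items():
            if len(vals) != len(self.sample_ids):
                raise InputError(
                    f"metadata column {name!r} has {len(vals)} values for "
                    f"{len(self.sample_ids)} samples"
                )

    def column(self, name: str) -> list[str]:
        if name not in self.columns:
            raise InputError(
                f"metadata column {name!r} not found; available: "
                f"{sorted(self.columns)}"
            )
        return self.columns[name]

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise InputError(f"sample ids not in metadata: {missing}")
        rows = [idx[s] for s in sample_ids]
        return SampleMetadata(
            sample_ids=list(sample_ids),
            columns={k: [v[i] for i in rows] for k, v in self.columns.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.sample_ids == other.sample_ids and self.columns == other.columns


def _parse_count(cell: str, otu_id: str, sample_id: str) -> int:
    try:
        value = int(cell)
    except ValueError:
        try:
            f = float(cell)
        except ValueError:
            raise InputError(
                f"non-numeric count {cell!r} for OTU {otu_id!r}, "
                f"sample {sample_id!r}"
            ) from None
        if f != int(f):
            raise InputError(
                f"non-integer count {cell!r} for OTU {otu_id!r}, "
                f"sample {sample_id!r}"
            ) from None
        value = int(f)
    if value < 0:
        raise InputError(
            f"negative count {cell!r} for OTU {otu_id!r}, sample {sample_id!r}"
        )
    return value


def read_otu_table(path: str, dialect: str = "qiime_classic_tsv") -> CountTable:
    """Read a classic tab-delimited OTU table (OTUs as rows, samples as columns).

    Leading comment lines are skipped; the header line must begin with
    ``#OTU ID``. A trailing column named ``taxonomy`` (case-insensitive) is
    captured as lineage strings.
    """
    if dialect != "qiime_classic_tsv":
        raise InputError(f"unsupported OTU table dialect: {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header_idx = None
    for i, ln in enumerate(lines):
        if ln.startswith("#OTU ID"):
            header_idx = i
            break
        if not ln.startswith("#"):
            break
    if header_idx is None:
        raise InputError(f"{path}: malformed header (expected a '#OTU ID' line)")
    header = lines[header_idx].split("\t")
    has_taxonomy = len(header) > 1 and header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_taxonomy else len(header)]
    if not sample_ids:
        raise InputError(f"{path}: no sample columns in header")
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    taxonomy: dict[str, str] = {}
    expected = len(header)
    for lineno, ln in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        fields = ln.split("\t")
        if len(fields) != expected:
            raise InputError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {expected})"
            )
        otu_id = fields[0]
        if otu_id in set(otu_ids):
            raise InputError(f"{path}:{lineno}: duplicate OTU id {otu_id!r}")
        cells = fields[1 : -1 if has_taxonomy else expected]
        rows.append(
            [_parse_count(c, otu_id, s) for c, s in zip(cells, sample_ids)]
        )
        if has_taxonomy:
            taxonomy[otu_id] = fields[-1]
        otu_ids.append(otu_id)
    if not otu_ids:
        raise InputError(f"{path}: no OTU rows")
    counts = np.asarray(rows, dtype=np.int64).T  # file is OTUs x samples
    return CountTable(
        sample_ids=sample_ids,
        otu_ids=otu_ids,
        counts=counts,
        taxonomy=taxonomy if has_taxonomy else None,
    )


def write_otu_table(table: CountTable, path: str) -> None:
    """Write ``table`` in the classic dialect (round-trips with the reader)."""
    with open(path, "wt", encoding="utf-8") as fh:
        header = ["#OTU ID"] + table.sample_ids
        if table.taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for j, otu in enumerate(table.otu_ids):
            row = [otu] + [str(int(c)) for c in table.counts[:, j]]
            if table.taxonomy is not None:
                row.append(table.taxonomy.get(otu, ""))
            fh.write("\t".join(row) + "\n")


def read_mapping(path: str) -> SampleMetadata:
    """Read a tab-delimited mapping file whose header starts with ``#SampleID``."""
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("#SampleID"):
        raise InputError(f"{path}: malformed header (expected '#SampleID' first)")
    header = lines[0].split("\t")
    col_names = header[1:]
    sample_ids: list[str] = []
    columns: dict[str, list[str]] = {name: [] for name in col_names}
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise InputError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {len(header)})"
            )
        sid = fields[0]
        if sid in set(sample_ids):
            raise InputError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        sample_ids.append(sid)
        for name, cell in zip(col_names, fields[1:]):
            columns[name].append(cell.strip() or MISSING_TOKEN)
    return SampleMetadata(sample_ids=sample_ids, columns=columns)


def write_mapping(meta: SampleMetadata, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        names = list(meta.columns)
        fh.write("\t".join(["#SampleID"] + names) + "\n")
        for i, sid in enumerate(meta.sample_ids):
            fh.write("\t".join([sid] + [meta.columns[n][i] for n in names]) + "\n")


def align_samples(
    table: CountTable, meta: SampleMetadata
) -> tuple[CountTable, SampleMetadata]:
    """Restrict both objects to their shared sample ids, in the table's order.

    The OTU table is the ordering authority. The number of dropped ids on each
    side is logged.
    """
    meta_ids = set(meta.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise InputError("no sample ids shared between OTU table and mapping")
    dropped_table = table.n_samples - len(shared)
    dropped_meta = len(meta.sample_ids) - len(shared)
    if dropped_table or dropped_meta:
        logger.info(
            "align_samples: dropped %d table sample(s), %d mapping sample(s)",
            dropped_table,
            dropped_meta,
        )
    rows = [table.sample_ids.index(s) for s in shared]
    aligned_table = CountTable(
        sample_ids=shared,
        otu_ids=list(table.otu_ids),
        counts=table.counts[rows, :],
        taxonomy=dict(table.taxonomy) if table.taxonomy is not None else None,
    )
    return aligned_table, meta.subset(shared)
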