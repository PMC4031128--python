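"""Count closure, the centered log-ratio transform, and variance filtering.

Counts are turned into strictly positive compositions (rows summing to 1)
with an additive pseudocount; each row of the centered log-ratio (clr) matrix
is the log of the composition divided by its geometric mean, so full-feature
clr rows sum to zero and the transform is invariant to per-sample scaling of
the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .io import CountTable

__all__ = [
    "CompositionMatrix",
    "ClrMatrix",
    "close_composition",
    "clr_transform",
    "filter_variable_features",
    "write_clr_tsv",
]


@dataclass
class CompositionMatrix:
    """Strictly positive relative abundances; every row sums to 1."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise InputError("composition shape does not match ids")
        if (self.values <= 0).any():
            raise InputError("composition entries must be strictly positive")
        row_sums = self.values.sum(axis=1)
        if np.max(np.abs(row_sums - 1.0)) > 1e-12:
            raise InputError("composition rows must sum to 1")


@dataclass
class ClrMatrix:
    """clr-transformed abundances.

    Row sums are zero only for the full feature set; after variance filtering
    the rows no longer sum to zero, so that invariant is not enforced here.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise InputError("clr matrix shape does not match ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.otu_ids)

    def subset_samples(self, rows: np.ndarray) -> "ClrMatrix":
        rows = np.asarray(rows)
        return ClrMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            otu_ids=list(self.otu_ids),
            values=self.values[rows, :],
        )


def close_composition(
    table: CountTable, pseudocount: float = 0.5
) -> CompositionMatrix:
    """Close counts to proportions after adding ``pseudocount`` to every cell.

    ``pseudocount`` must be positive unless the table is zero-free: the clr
    transform is undefined on zeros.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    if pseudocount == 0 and (table.counts == 0).any():
        raise InputError(
            "zero counts present with pseudocount 0; clr is undefined on zeros "
            "(use a positive pseudocount)"
        )
    adjusted = table.counts.astype(float) + pseudocount
    values = adjusted / adjusted.sum(axis=1, keepdims=True)
    return CompositionMatrix(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        values=values,
    )


def clr_transform(comp: CompositionMatrix) -> ClrMatrix:
    """Apply the centered log-ratio transform row-wise.

    ``clr[i, j] = ln(x[i, j]) - mean_j(ln x[i, j])`` — equivalently, the log
    of each component divided by the geometric mean of its row.
    """
    if (comp.values <= 0).any():
        raise InputError("clr requires strictly positive entries")
    logs = np.log(comp.values)
    values = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(
        sample_ids=list(comp.sample_ids),
        otu_ids=list(comp.otu_ids),
        values=values,
    )


def filter_variable_features(clr: ClrMatrix, top_n: int) -> ClrMatrix:
    """Keep the ``top_n`` most variable features (clr sample variance, ddof=1).

    Ties are broken in favour of the lexicographically smaller OTU id.
    Retained columns keep their original order. ``top_n >= n_features`` is the
    identity.
    """
    if top_n < 1:
        raise InputError("top_n must be >= 1")
    p = clr.n_features
    if top_n >= p:
        return ClrMatrix(
            sample_ids=list(clr.sample_ids),
            otu_ids=list(clr.otu_ids),
            values=clr.values.copy(),
        )
    ddof = 1 if clr.n_samples > 1 else 0
    variances = clr.values.var(axis=0, ddof=ddof)
    ranked = sorted(range(p), key=lambda j: (-variances[j], clr.otu_ids[j]))
    keep = sorted(ranked[:top_n])  # original column order
    return ClrMatrix(
        sample_ids=list(clr.sample_ids),
        otu_ids=[clr.otu_ids[j] for j in keep],
        values=clr.values[:, keep],
    )


def write_clr_tsv(clr: ClrMatrix, path: str) -> None:
    """Dump a clr matrix as TSV with samples as rows."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(["#SampleID"] + clr.otu_ids) + "\n")
        for i, sid in enumerate(clr.sample_ids):
            cells = [f"{v:.10g}" for v in clr.values[i]]
            fh.write("\t".join([sid] + cells) + "\n")
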