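"""Alpha diversity with rarefaction, group comparison, ANOSIM and prevalence.

Shannon entropy defaults to base 2; rarefaction subsamples without
replacement (multivariate hypergeometric). The two-sample t-test uses the
classical pooled-variance form by default, with Welch behind a flag. ANOSIM
is rank-based with mid-ranks and the add-one permutation p-value rule.
Prevalence confidence intervals use the Wald normal approximation on the
percent scale, clipped to [0, 100] and rounded to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .exceptions import InputError
from .io import CountTable

__all__ = [
    "RarefactionCurve",
    "DistanceMatrix",
    "PrevalenceEstimate",
    "alpha_metrics",
    "rarefy",
    "rarefaction_curve",
    "group_ttest",
    "bray_curtis",
    "anosim",
    "prevalence_ci",
    "read_distance_tsv",
    "write_distance_tsv",
]

_METRICS = ("shannon", "observed_otus")


@dataclass
class RarefactionCurve:
    metric: str
    sample_ids: list[str]
    depths: list[int]
    iterations: int
    seed: int
    means: np.ndarray  # n_samples x n_depths
    sds: np.ndarray

    def write_tsv(self, path: str) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("sample_id\tdepth\tmean\tsd\n")
            for i, sid in enumerate(self.sample_ids):
                for d, depth in enumerate(self.depths):
                    fh.write(
                        f"{sid}\t{depth}\t{self.means[i, d]:.6g}\t"
                        f"{self.sds[i, d]:.6g}\n"
                    )


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")
        if (self.values < 0).any():
            raise InputError("distances must be non-negative")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise InputError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InputError("distance matrix diagonal must be zero")


@dataclass
class PrevalenceEstimate:
    """Binomial point estimate and 95% Wald CI, on the percent scale.

    ``percent``, ``ci_low`` and ``ci_high`` are rounded to one decimal.
    """

    x: int
    n: int
    percent: float
    ci_low: float
    ci_high: float


def alpha_metrics(counts: np.ndarray, metric: str, base: float = 2.0) -> float:
    """Within-sample diversity of one count vector.

    ``shannon`` is the entropy of the count proportions (log base 2 by
    default); ``observed_otus`` is the number of nonzero entries.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise InputError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise InputError("all-zero count vector")
    if metric == "observed_otus":
        return float(np.count_nonzero(counts))
    if metric == "shannon":
        p = counts[counts > 0] / total
        return float(-(p * (np.log(p) / np.log(base))).sum())
    raise InputError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def rarefy(
    counts: np.ndarray, depth: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth``."""
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise InputError("counts must be non-negative")
    total = int(counts.sum())
    if depth < 0:
        raise InputError("depth must be >= 0")
    if depth > total:
        raise InputError(f"depth {depth} exceeds sample total {total}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def rarefaction_curve(
    table: CountTable,
    depths: list[int],
    iterations: int = 10,
    metric: str = "shannon",
    seed: int = 0,
) -> RarefactionCurve:
    """Mean/SD of an alpha metric over repeated rarefactions, per sample."""
    if not depths:
        raise InputError("depths must be non-empty")
    if iterations < 1:
        raise InputError("iterations must be >= 1")
    totals = table.counts.sum(axis=1)
    for i, sid in enumerate(table.sample_ids):
        if max(depths) > totals[i]:
            raise InputError(
                f"depth {max(depths)} exceeds total count {totals[i]} "
                f"of sample {sid!r}"
            )
    rng = np.random.default_rng(seed)
    n = table.n_samples
    means = np.zeros((n, len(depths)))
    sds = np.zeros((n, len(depths)))
    for i in range(n):
        for d, depth in enumerate(depths):
            vals = [
                alpha_metrics(rarefy(table.counts[i], depth, rng), metric)
                for _ in range(iterations)
            ]
            means[i, d] = float(np.mean(vals))
            sds[i, d] = float(np.std(vals, ddof=1)) if iterations > 1 else 0.0
    return RarefactionCurve(
        metric=metric,
        sample_ids=list(table.sample_ids),
        depths=list(depths),
        iterations=iterations,
        seed=seed,
        means=means,
        sds=sds,
    )


def group_ttest(
    values_a: np.ndarray, values_b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t-test (pooled variance by default; Welch via flag)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 values")
    if not welch:
        pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        if pooled == 0 and a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on raw counts."""
    values = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(sample_ids=list(table.sample_ids), values=values)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n_pairs = len(ranks)
    r_between = ranks[~within].mean()
    r_within = ranks[within].mean()
    return float((r_between - r_within) / (n_pairs / 2.0))


def anosim(
    D: DistanceMatrix,
    labels: list[str],
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """ANOSIM R statistic with a permutation p-value (add-one rule).

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M/2), with mid-ranks for ties, M = n(n-1)/2 pairs.
    """
    labels_arr = np.asarray([str(x) for x in labels])
    if len(labels_arr) != len(D.sample_ids):
        raise InputError("labels length does not match distance matrix")
    levels = sorted(set(labels_arr.tolist()))
    if len(levels) < 2 or any(np.sum(labels_arr == lv) < 2 for lv in levels):
        raise InputError("need >= 2 groups with >= 2 samples each")
    if permutations < 1:
        raise InputError("permutations must be >= 1")
    condensed = squareform(D.values, checks=False)
    ranks = stats.rankdata(condensed)  # mid-ranks
    n = len(labels_arr)
    iu = np.triu_indices(n, k=1)
    within = labels_arr[iu[0]] == labels_arr[iu[1]]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        perm_labels = labels_arr[perm]
        w = perm_labels[iu[0]] == perm_labels[iu[1]]
        if _anosim_r(ranks, w) >= r_obs:
            hits += 1
    p = (1 + hits) / (permutations + 1)
    return r_obs, float(p)


def prevalence_ci(x: int, n: int, z: float = 1.96) -> PrevalenceEstimate:
    """Binomial prevalence percent with a 95% Wald CI, one-decimal rounding."""
    if n < 1:
        raise InputError("n must be >= 1")
    if not 0 <= x <= n:
        raise InputError("x must satisfy 0 <= x <= n")
    p = x / n
    half = float(z * 100.0 * np.sqrt(p * (1 - p) / n))
    percent = 100.0 * p
    lo = max(0.0, percent - half)
    hi = min(100.0, percent + half)
    return PrevalenceEstimate(
        x=int(x),
        n=int(n),
        percent=round(percent, 1),
        ci_low=round(lo, 1),
        ci_high=round(hi, 1),
    )


def read_distance_tsv(path: str) -> DistanceMatrix:
    """Read a square distance matrix TSV with matching header and row ids."""
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise InputError(f"{path}: empty distance matrix")
    header = lines[0].split("\t")
    ids = header[1:]
    rows = []
    row_ids = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        row_ids.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    if row_ids != ids:
        raise InputError(f"{path}: row ids do not match header ids")
    return DistanceMatrix(sample_ids=ids, values=np.asarray(rows))


def write_distance_tsv(D: DistanceMatrix, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join([""] + D.sample_ids) + "\n")
        for i, sid in enumerate(D.sample_ids):
            fh.write(
                "\t".join([sid] + [f"{v:.10g}" for v in D.values[i]]) + "\n"
            )
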