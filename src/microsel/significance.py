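"""Resampling-based significance for sparse PLS-DA coefficients.

Two coefficient distributions are built around a tuned (eta, K) fit: a
class-stratified bootstrap, and a null obtained by refitting with uniformly
permuted labels. Per feature, the null's two-sided tail thresholds at level
alpha are compared with the bootstrap draws: the significance strength ``s``
is the fraction of bootstrap draws at or beyond the thresholds and the pseudo
p-value is ``1 - s``; a feature is selected when ``pseudo_p <= alpha``.

When a feature's null distribution is a point mass (e.g. the sparsity
penalty zeroes it in every permutation), the tail comparison degenerates to
"every draw equals both thresholds"; such features use strict inequalities so
that an identically-zero feature is never declared significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositional import ClrMatrix
from .exceptions import FitError, InputError
from .splsda import SplsdaModel, encode_response, fit_splsda

__all__ = [
    "ResamplingDistribution",
    "SignificanceReport",
    "BiplotData",
    "bootstrap_coefficients",
    "permutation_null",
    "pseudo_pvalues",
    "biplot_coordinates",
    "write_significance_tsv",
    "write_biplot_tsv",
]


@dataclass
class ResamplingDistribution:
    """R x p matrix of coefficient draws for one resampling scheme."""

    kind: str  # "bootstrap" | "permutation_null"
    otu_ids: list[str]
    draws: np.ndarray
    seed: int
    eta: float
    n_components: int
    positive_class: str
    n_redraws: int = 0

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.otu_ids):
            raise InputError("draws shape does not match feature ids")
        if self.draws.shape[0] < 1:
            raise InputError("need at least one resample")


@dataclass
class SignificanceReport:
    """Per-feature bootstrap summary, null tails, pseudo p-values, selection."""

    otu_ids: list[str]
    boot_median: np.ndarray
    boot_lo: np.ndarray
    boot_hi: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    tail_fraction: np.ndarray
    pseudo_p: np.ndarray
    selected: np.ndarray
    alpha: float

    @property
    def selected_ids(self) -> list[str]:
        return [o for o, s in zip(self.otu_ids, self.selected) if s]


@dataclass
class BiplotData:
    """Sample coordinates and selected-feature arrows on two latent axes."""

    sample_ids: list[str]
    coordinates: np.ndarray  # n x 2
    arrow_ids: list[str]
    arrows: np.ndarray  # len(arrow_ids) x 2
    class_labels: list[str]
    second_axis_degenerate: bool = False


def _positive_column(
    model: SplsdaModel, positive_class: str
) -> np.ndarray:
    if positive_class not in model.class_levels:
        raise InputError(
            f"positive class {positive_class!r} not among levels "
            f"{model.class_levels}"
        )
    g = model.class_levels.index(positive_class)
    return model.coefficients[:, g]


def _resolve_positive(labels: np.ndarray, positive_class: str | None) -> str:
    levels = sorted(set(labels.tolist()))
    if positive_class is None:
        return levels[-1]
    if positive_class not in levels:
        raise InputError(
            f"positive class {positive_class!r} not among labels {levels}"
        )
    return positive_class


def bootstrap_coefficients(
    X: ClrMatrix,
    labels: list[str],
    eta: float,
    n_components: int,
    n_boot: int = 1000,
    seed: int = 0,
    positive_class: str | None = None,
) -> ResamplingDistribution:
    """Class-stratified bootstrap of the positive-class coefficient column.

    Each resample draws, within every class, that class's sample count with
    replacement, refits at the fixed (eta, K), and records the coefficients.
    Degenerate resamples (a vanished class or a failed fit) are redrawn, up to
    ``10 * n_boot`` total attempts.
    """
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    labels_arr = np.asarray([str(x) for x in labels])
    pos = _resolve_positive(labels_arr, positive_class)
    rng = np.random.default_rng(seed)
    class_idx = {
        lv: np.flatnonzero(labels_arr == lv)
        for lv in sorted(set(labels_arr.tolist()))
    }
    draws = np.empty((n_boot, X.n_features))
    attempts = 0
    b = 0
    while b < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise FitError(
                "bootstrap redraw cap exceeded (degenerate class sizes?)"
            )
        idx = np.concatenate(
            [
                rng.choice(members, size=len(members), replace=True)
                for members in class_idx.values()
            ]
        )
        sub_labels = labels_arr[idx]
        if len(set(sub_labels.tolist())) < 2:
            continue
        try:
            Y = encode_response(sub_labels.tolist())
            model = fit_splsda(X.subset_samples(idx), Y, eta, n_components)
        except (FitError, InputError):
            continue
        draws[b] = _positive_column(model, pos)
        b += 1
    return ResamplingDistribution(
        kind="bootstrap",
        otu_ids=list(X.otu_ids),
        draws=draws,
        seed=seed,
        eta=eta,
        n_components=n_components,
        positive_class=pos,
        n_redraws=attempts - n_boot,
    )


def permutation_null(
    X: ClrMatrix,
    labels: list[str],
    eta: float,
    n_components: int,
    n_perm: int = 1000,
    seed: int = 0,
    positive_class: str | None = None,
) -> ResamplingDistribution:
    """Null coefficient draws from refits with uniformly permuted labels."""
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    labels_arr = np.asarray([str(x) for x in labels])
    pos = _resolve_positive(labels_arr, positive_class)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_perm, X.n_features))
    attempts = 0
    b = 0
    while b < n_perm:
        attempts += 1
        if attempts > 10 * n_perm:
            raise FitError("permutation redraw cap exceeded")
        perm_labels = labels_arr[rng.permutation(len(labels_arr))]
        try:
            Y = encode_response(perm_labels.tolist())
            model = fit_splsda(X, Y, eta, n_components)
        except (FitError, InputError):
            continue
        draws[b] = _positive_column(model, pos)
        b += 1
    return ResamplingDistribution(
        kind="permutation_null",
        otu_ids=list(X.otu_ids),
        draws=draws,
        seed=seed,
        eta=eta,
        n_components=n_components,
        positive_class=pos,
        n_redraws=attempts - n_perm,
    )


def pseudo_pvalues(
    boot: ResamplingDistribution,
    null: ResamplingDistribution,
    alpha: float = 0.05,
    fraction_is_p: bool = False,
) -> SignificanceReport:
    """Score features by the position of bootstrap draws vs. null tails.

    Per feature: the null's empirical ``alpha/2`` and ``1 - alpha/2``
    quantiles bound the tails; ``s`` is the fraction of bootstrap draws at or
    beyond them; ``pseudo_p = 1 - s`` and selection is ``pseudo_p <= alpha``.
    ``fraction_is_p=True`` switches to the complementary convention where the
    reported p IS the tail fraction (small fraction significant).
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if boot.otu_ids != null.otu_ids:
        raise InputError("bootstrap and null feature sets differ")
    p = len(boot.otu_ids)
    null_lo = np.quantile(null.draws, alpha / 2, axis=0)
    null_hi = np.quantile(null.draws, 1 - alpha / 2, axis=0)
    tail = np.empty(p)
    for j in range(p):
        bj = boot.draws[:, j]
        beyond = (bj <= null_lo[j]) | (bj >= null_hi[j])
        if null_lo[j] <= 0 <= null_hi[j]:
            # a zeroed coefficient is the null's modal value under the
            # sparsity penalty; it never counts as evidence
            beyond &= bj != 0
        tail[j] = float(np.mean(beyond))
    pseudo_p = tail if fraction_is_p else 1.0 - tail
    selected = pseudo_p <= alpha
    return SignificanceReport(
        otu_ids=list(boot.otu_ids),
        boot_median=np.median(boot.draws, axis=0),
        boot_lo=np.quantile(boot.draws, 0.025, axis=0),
        boot_hi=np.quantile(boot.draws, 0.975, axis=0),
        null_lo=null_lo,
        null_hi=null_hi,
        tail_fraction=tail,
        pseudo_p=pseudo_p,
        selected=selected,
        alpha=alpha,
    )


def biplot_coordinates(
    model: SplsdaModel,
    report: SignificanceReport,
    class_labels: list[str] | None = None,
) -> BiplotData:
    """Sample scores on the first two components plus selected-feature arrows.

    With a single-component model the second axis is all-zero and flagged.
    """
    n = model.scores.shape[0]
    coords = np.zeros((n, 2))
    degenerate = model.n_components < 2
    coords[:, 0] = model.scores[:, 0]
    if not degenerate:
        coords[:, 1] = model.scores[:, 1]
    sel = set(report.selected_ids)
    arrow_ids = [o for o in model.otu_ids if o in sel]
    arrows = np.zeros((len(arrow_ids), 2))
    for i, o in enumerate(arrow_ids):
        j = model.otu_ids.index(o)
        arrows[i, 0] = model.weights[j, 0]
        if not degenerate:
            arrows[i, 1] = model.weights[j, 1]
    if class_labels is None:
        class_labels = [""] * n
    if len(class_labels) != n:
        raise InputError("class_labels length does not match sample count")
    return BiplotData(
        sample_ids=[f"s{i}" for i in range(n)],
        coordinates=coords,
        arrow_ids=arrow_ids,
        arrows=arrows,
        class_labels=list(class_labels),
        second_axis_degenerate=degenerate,
    )


def write_significance_tsv(
    report: SignificanceReport,
    path: str,
    taxonomy: dict[str, str] | None = None,
) -> None:
    cols = [
        "otu_id",
        "taxonomy",
        "boot_median",
        "boot_lo",
        "boot_hi",
        "null_lo",
        "null_hi",
        "tail_fraction",
        "pseudo_p",
        "selected",
    ]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for j, otu in enumerate(report.otu_ids):
            row = [
                otu,
                (taxonomy or {}).get(otu, ""),
                f"{report.boot_median[j]:.6g}",
                f"{report.boot_lo[j]:.6g}",
                f"{report.boot_hi[j]:.6g}",
                f"{report.null_lo[j]:.6g}",
                f"{report.null_hi[j]:.6g}",
                f"{report.tail_fraction[j]:.6g}",
                f"{report.pseudo_p[j]:.6g}",
                str(bool(report.selected[j])),
            ]
            fh.write("\t".join(row) + "\n")


def write_biplot_tsv(
    biplot: BiplotData, samples_path: str, arrows_path: str,
    sample_ids: list[str] | None = None,
) -> None:
    ids = sample_ids if sample_ids is not None else biplot.sample_ids
    with open(samples_path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tcomp1\tcomp2\tclass\n")
        for i, sid in enumerate(ids):
            fh.write(
                f"{sid}\t{biplot.coordinates[i, 0]:.6g}\t"
                f"{biplot.coordinates[i, 1]:.6g}\t{biplot.class_labels[i]}\n"
            )
    with open(arrows_path, "wt", encoding="utf-8") as fh:
        fh.write("otu_id\tcomp1\tcomp2\n")
        for i, otu in enumerate(biplot.arrow_ids):
            fh.write(
                f"{otu}\t{biplot.arrows[i, 0]:.6g}\t{biplot.arrows[i, 1]:.6g}\n"
            )
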