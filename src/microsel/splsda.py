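"""Sparse partial least squares discriminant analysis (sparse PLS-DA).

The fit extracts latent components one at a time. For component ``k`` the
direction vector is the leading left singular vector of ``X_k' Y_k`` (for a
binary response this is proportional to ``X_k' y``), soft-thresholded at
``eta * max_i |z_i|`` and renormalised; scores, loadings and deflation follow
standard PLS2 regression mode, with the response deflated alongside the
predictors so the coefficient matrix ``B = W (P'W)^{-1} Q'`` is well defined.
``eta = 0`` reduces exactly to dense PLS2.

Sign convention: each direction vector is flipped, if necessary, so that its
largest-magnitude entry is positive. This makes fits deterministic and
independent of the response level ordering.

Features are centered internally with training means only; an optional
unit-variance scaling flag is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .compositional import ClrMatrix
from .exceptions import FitError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMatrix",
    "SplsdaModel",
    "TuningResult",
    "encode_response",
    "fit_splsda",
    "predict_classes",
    "cross_validate",
    "write_model",
    "read_model",
]


@dataclass
class ResponseMatrix:
    """Column-centered one-hot class indicator matrix (n x G)."""

    sample_ids: list[str]
    class_levels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.class_levels)):
            raise InputError("response shape does not match ids/levels")


@dataclass
class SplsdaModel:
    """A fitted sparse PLS-DA model.

    ``weights`` (W), ``x_loadings`` (P) are p x K; ``y_loadings`` (Q) is
    G x K; ``scores`` (T) is n x K; ``coefficients`` (B) is p x G on centered
    features. ``support`` lists OTU ids with any nonzero weight.
    """

    eta: float
    n_components: int
    otu_ids: list[str]
    class_levels: list[str]
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coefficients: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    support: list[str] = field(default_factory=list)


@dataclass
class TuningResult:
    """Cross-validation grid with the chosen (eta, K) pair."""

    grid: list[tuple[float, int, float, float]]  # (eta, K, mean_error, se)
    eta: float
    n_components: int
    folds: int
    seed: int


def encode_response(labels: list[str]) -> ResponseMatrix:
    """Dummy-code class labels into a column-centered indicator matrix.

    Class levels are sorted lexicographically; each class must have at least
    two members.
    """
    labels = [str(x) for x in labels]
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise InputError("need at least 2 classes to encode a response")
    for lv in levels:
        if labels.count(lv) < 2:
            raise InputError(f"class {lv!r} has fewer than 2 samples")
    n = len(labels)
    values = np.zeros((n, len(levels)))
    for i, lab in enumerate(labels):
        values[i, levels.index(lab)] = 1.0
    values -= values.mean(axis=0, keepdims=True)
    return ResponseMatrix(
        sample_ids=[f"s{i}" for i in range(n)], class_levels=levels, values=values
    )


def _leading_direction(M: np.ndarray) -> np.ndarray:
    """Leading left singular vector of M with the sign convention applied."""
    if M.shape[1] == 1:
        z = M[:, 0].copy()
    else:
        u, s, _ = np.linalg.svd(M, full_matrices=False)
        z = u[:, 0] * s[0]
    if not np.any(np.abs(z) > 1e-12):
        raise FitError(
            "degenerate direction vector (X'Y is zero); cannot extract a component"
        )
    jmax = int(np.argmax(np.abs(z)))
    if z[jmax] < 0:
        z = -z
    return z


def _soft_threshold(z: np.ndarray, eta: float) -> np.ndarray:
    thr = eta * np.max(np.abs(z))
    w = np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise FitError(
            "soft thresholding zeroed the whole direction vector; "
            "use a smaller eta"
        )
    return w / nrm


def fit_splsda(
    X: ClrMatrix,
    Y: ResponseMatrix,
    eta: float,
    n_components: int,
    scale: bool = False,
) -> SplsdaModel:
    """Fit a sparse PLS-DA model with sparsity ``eta`` and ``n_components``.

    Parameters
    ----------
    X
        Predictor matrix (clr-transformed features). Centered internally.
    Y
        Column-centered class indicator matrix.
    eta
        Sparsity in [0, 1): per component, entries of the direction vector
        with magnitude below ``eta * max|z|`` are zeroed (soft threshold).
    n_components
        Number of latent components K; requires ``n_samples >= K + 2``.
    scale
        If True, features are also scaled to unit variance (training data).
    """
    if not 0 <= eta < 1:
        raise InputError("eta must be in [0, 1)")
    if n_components < 1:
        raise InputError("n_components must be >= 1")
    Xv = np.asarray(X.values, dtype=float)
    Yv = np.asarray(Y.values, dtype=float)
    n, p = Xv.shape
    if Yv.shape[0] != n:
        raise InputError("X and Y have different numbers of samples")
    if n < n_components + 2:
        raise InputError(
            f"need at least n_components + 2 = {n_components + 2} samples, got {n}"
        )
    means = Xv.mean(axis=0)
    scales = np.ones(p)
    if scale:
        sd = Xv.std(axis=0, ddof=1)
        scales = np.where(sd > 0, sd, 1.0)
    Xk = (Xv - means) / scales
    Yk = Yv.copy()
    G = Yv.shape[1]
    K = n_components
    W = np.zeros((p, K))
    P = np.zeros((p, K))
    Q = np.zeros((G, K))
    T = np.zeros((n, K))
    for k in range(K):
        z = _leading_direction(Xk.T @ Yk)
        w = _soft_threshold(z, eta)
        t = Xk @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            raise FitError(f"component {k + 1} has zero score variance")
        p_load = Xk.T @ t / tt
        q_load = Yk.T @ t / tt
        W[:, k] = w
        P[:, k] = p_load
        Q[:, k] = q_load
        T[:, k] = t
        Xk = Xk - np.outer(t, p_load)
        Yk = Yk - np.outer(t, q_load)
    PtW = P.T @ W
    try:
        inv = np.linalg.inv(PtW)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular P'W; cannot form regression coefficients") from exc
    if np.linalg.cond(PtW) > 1e12:
        raise FitError("ill-conditioned P'W; cannot form regression coefficients")
    B = W @ inv @ Q.T
    B = B / scales[:, None]  # back to the original feature scale
    nonzero = np.any(W != 0, axis=1)
    support = [X.otu_ids[j] for j in range(p) if nonzero[j]]
    # zero coefficient rows off-support exactly (they are already ~0)
    B[~nonzero, :] = 0.0
    return SplsdaModel(
        eta=eta,
        n_components=K,
        otu_ids=list(X.otu_ids),
        class_levels=list(Y.class_levels),
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coefficients=B,
        feature_means=means,
        feature_scales=scales,
        support=support,
    )


def predict_classes(model: SplsdaModel, Xnew: ClrMatrix) -> list[str]:
    """Predict class labels for new samples.

    ``Xnew`` must contain every feature of the model (extra columns are
    dropped); the predicted class is the argmax over response columns, with
    ties resolved to the lexicographically smallest class level.
    """
    col = {o: j for j, o in enumerate(Xnew.otu_ids)}
    missing = [o for o in model.otu_ids if o not in col]
    if missing:
        raise InputError(f"new data is missing model features: {missing}")
    idx = [col[o] for o in model.otu_ids]
    Xv = np.asarray(Xnew.values, dtype=float)[:, idx]
    yhat = (Xv - model.feature_means) @ model.coefficients
    out: list[str] = []
    for row in yhat:
        best = np.max(row)
        ties = [
            model.class_levels[g]
            for g in range(len(model.class_levels))
            if row[g] >= best - 1e-12
        ]
        out.append(min(ties))
    return out


def _stratified_folds(
    labels: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Deterministic stratified fold assignment (round-robin per class)."""
    assignment = np.empty(len(labels), dtype=int)
    for lv in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lv)
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            assignment[i] = pos % folds
    return assignment


def cross_validate(
    X: ClrMatrix,
    labels: list[str],
    eta_grid: list[float] | None = None,
    K_grid: list[int] | None = None,
    folds: int = 5,
    seed: int = 0,
    scale: bool = False,
) -> TuningResult:
    """Tune (eta, K) by stratified K-fold cross-validated misclassification.

    Folds are assigned deterministically from ``seed``. If some class has
    fewer members than ``folds``, the fold count is reduced (floor 2) with a
    warning. The chosen pair minimises mean CV error; ties prefer smaller K,
    then larger eta. Grid points whose fit fails on any fold are excluded.
    """
    if eta_grid is None:
        eta_grid = [round(0.1 * i, 1) for i in range(10)]
    if K_grid is None:
        K_grid = [1, 2, 3]
    if not eta_grid or not K_grid:
        raise InputError("empty tuning grid")
    if folds < 2:
        raise InputError("folds must be >= 2")
    labels_arr = np.asarray([str(x) for x in labels])
    min_class = min(
        int(np.sum(labels_arr == lv)) for lv in sorted(set(labels_arr.tolist()))
    )
    if min_class < 2:
        raise InputError("every class needs at least 2 samples")
    if min_class < folds:
        new_folds = max(2, min_class)
        logger.warning(
            "reducing folds from %d to %d (smallest class has %d samples)",
            folds,
            new_folds,
            min_class,
        )
        folds = new_folds
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(labels_arr, folds, rng)
    grid: list[tuple[float, int, float, float]] = []
    for eta in eta_grid:
        for K in K_grid:
            errors = []
            failed = False
            for f in range(folds):
                train = np.flatnonzero(assignment != f)
                test = np.flatnonzero(assignment == f)
                try:
                    Yt = encode_response(labels_arr[train].tolist())
                    model = fit_splsda(
                        X.subset_samples(train), Yt, eta, K, scale=scale
                    )
                    pred = predict_classes(model, X.subset_samples(test))
                except (FitError, InputError):
                    failed = True
                    break
                errors.append(float(np.mean(pred != labels_arr[test])))
            if failed:
                grid.append((float(eta), int(K), float("nan"), float("nan")))
                continue
            err = np.asarray(errors)
            se = float(err.std(ddof=1) / np.sqrt(folds)) if folds > 1 else 0.0
            grid.append((float(eta), int(K), float(err.mean()), se))
    valid = [g for g in grid if np.isfinite(g[2])]
    if not valid:
        raise FitError("every grid point failed to fit during cross-validation")
    # minimise error; ties -> smaller K, then larger eta
    best = min(valid, key=lambda g: (g[2], g[1], -g[0]))
    return TuningResult(
        grid=grid, eta=best[0], n_components=best[1], folds=folds, seed=seed
    )


def write_model(model: SplsdaModel, path: str) -> None:
    """Persist a model as a plain-text key-value + matrix dump."""

    def fmt_matrix(M: np.ndarray) -> str:
        return "\n".join(
            "\t".join(f"{v:.17g}" for v in row) for row in np.atleast_2d(M)
        )

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"eta\t{model.eta:.17g}\n")
        fh.write(f"n_components\t{model.n_components}\n")
        fh.write("otu_ids\t" + "\t".join(model.otu_ids) + "\n")
        fh.write("class_levels\t" + "\t".join(model.class_levels) + "\n")
        fh.write("support\t" + "\t".join(model.support) + "\n")
        for name in (
            "feature_means",
            "feature_scales",
            "weights",
            "x_loadings",
            "y_loadings",
            "scores",
            "coefficients",
        ):
            M = np.atleast_2d(getattr(model, name))
            fh.write(f"[{name}]\t{M.shape[0]}\t{M.shape[1]}\n")
            fh.write(fmt_matrix(M) + "\n")


def read_model(path: str) -> SplsdaModel:
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    kv: dict[str, list[str]] = {}
    matrices: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        fields = lines[i].split("\t")
        key = fields[0]
        if key.startswith("["):
            name = key.strip("[]")
            nrow, ncol = int(fields[1]), int(fields[2])
            block = lines[i + 1 : i + 1 + nrow]
            matrices[name] = np.array(
                [[float(v) for v in row.split("\t")] for row in block]
            ).reshape(nrow, ncol)
            i += 1 + nrow
        else:
            kv[key] = fields[1:]
            i += 1
    return SplsdaModel(
        eta=float(kv["eta"][0]),
        n_components=int(kv["n_components"][0]),
        otu_ids=kv["otu_ids"],
        class_levels=kv["class_levels"],
        weights=matrices["weights"],
        x_loadings=matrices["x_loadings"],
        y_loadings=matrices["y_loadings"],
        scores=matrices["scores"],
        coefficients=matrices["coefficients"],
        feature_means=matrices["feature_means"].ravel(),
        feature_scales=matrices["feature_scales"].ravel(),
        support=[s for s in kv.get("support", []) if s],
    )
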