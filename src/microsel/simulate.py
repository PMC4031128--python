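"""Synthetic two-class microbiome cohorts with known discriminative taxa.

Per sample the log-abundance of feature j is ``mu_j + delta_j * c + eps``
with ``eps ~ Normal(0, sigma^2)`` and a long-tailed baseline ``mu_j ~
Normal(0, 2)``; ``delta_j = +/- effect`` on the discriminative features
(balanced signs) and 0 elsewhere, so planted effects live directly on the
clr scale the selection method operates on. Counts are multinomial with
log-normal library sizes. Class-1 samples can additionally receive a few
rare features at a small fixed count, emulating a class-linked richness
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .io import CountTable, SampleMetadata

__all__ = ["SyntheticTruth", "generate_cohort", "truth_recovery_metrics",
           "write_truth_tsv"]

CLASS_COLUMN = "Helminth"
POS_LEVEL = "Pos"
NEG_LEVEL = "Neg"
RARE_COUNT = 2  # fixed count given to each bonus rare feature
RARE_POOL_FACTOR = 4  # rare-pool size per unit of richness_bonus


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort."""

    effects: dict[str, float]  # discriminative OTU id -> signed clr effect
    classes: dict[str, str]  # sample id -> class level
    params: dict[str, float | int] = field(default_factory=dict)

    @property
    def discriminative_ids(self) -> list[str]:
        return [o for o, e in self.effects.items() if e != 0]


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(
    n_pos: int = 36,
    n_neg: int = 15,
    p: int = 200,
    n_disc: int = 10,
    effect: float = 1.5,
    sigma: float = 0.15,
    depth_mean: float = 19000.0,
    depth_cv: float = 0.34,
    richness_bonus: int = 0,
    seed: int = 0,
) -> tuple[CountTable, SampleMetadata, SyntheticTruth]:
    """Generate a two-class cohort of OTU count vectors.

    Defaults mirror a 51-subject cohort with 36 positives and log-normal
    library sizes averaging 19000 reads. ``richness_bonus`` rare features per
    positive sample (drawn from a dedicated rare pool appended after the
    ``p`` baseline features) produce a class-linked richness difference.
    All draws derive from ``seed``; identical parameters give identical
    cohorts.
    """
    if n_pos < 1 or n_neg < 1:
        raise InputError("need at least one sample per class")
    if p < 2:
        raise InputError("p must be >= 2")
    if not 0 <= n_disc <= p:
        raise InputError("n_disc must be in [0, p]")
    if sigma <= 0:
        raise InputError("sigma must be > 0")
    if depth_mean <= 0 or depth_cv < 0:
        raise InputError("invalid depth distribution parameters")
    if richness_bonus < 0:
        raise InputError("richness_bonus must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    n_rare = RARE_POOL_FACTOR * richness_bonus
    otu_ids = [f"OTU_{j:04d}" for j in range(p)]
    rare_ids = [f"OTU_R{j:04d}" for j in range(n_rare)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    classes = np.array([1] * n_pos + [0] * n_neg)

    mu = rng.normal(0.0, 2.0, size=p)
    # plant effects on the abundant half of the baseline: a spike on a
    # feature expecting ~0 reads at the target depth is not observable
    eligible = np.flatnonzero(mu >= np.median(mu))
    if n_disc > len(eligible):
        eligible = np.arange(p)
    disc = np.sort(rng.choice(eligible, size=n_disc, replace=False))
    delta = np.zeros(p)
    signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(n_disc)])
    delta[disc] = signs * effect

    lmu, lsd = _lognormal_params(depth_mean, depth_cv) if depth_cv > 0 else (
        np.log(depth_mean),
        0.0,
    )
    counts = np.zeros((n, p + n_rare), dtype=np.int64)
    for i in range(n):
        lam = mu + delta * classes[i] + rng.normal(0.0, sigma, size=p)
        prob = np.exp(lam - lam.max())
        prob /= prob.sum()
        depth = max(1, int(round(rng.lognormal(lmu, lsd))))
        counts[i, :p] = rng.multinomial(depth, prob)
        if classes[i] == 1 and richness_bonus > 0:
            bonus = rng.choice(n_rare, size=richness_bonus, replace=False)
            counts[i, p + bonus] = RARE_COUNT
    table = CountTable(
        sample_ids=sample_ids, otu_ids=otu_ids + rare_ids, counts=counts
    )
    meta = SampleMetadata(
        sample_ids=sample_ids,
        columns={
            CLASS_COLUMN: [
                POS_LEVEL if c == 1 else NEG_LEVEL for c in classes
            ]
        },
    )
    truth = SyntheticTruth(
        effects={otu_ids[j]: float(delta[j]) for j in disc},
        classes={
            s: (POS_LEVEL if c == 1 else NEG_LEVEL)
            for s, c in zip(sample_ids, classes)
        },
        params={
            "n_pos": n_pos,
            "n_neg": n_neg,
            "p": p,
            "n_disc": n_disc,
            "effect": effect,
            "sigma": sigma,
            "depth_mean": depth_mean,
            "depth_cv": depth_cv,
            "richness_bonus": richness_bonus,
            "seed": seed,
        },
    )
    return table, meta, truth


def truth_recovery_metrics(report, truth: SyntheticTruth) -> tuple[float, float]:
    """Sensitivity and false-discovery proportion of a selection vs. truth.

    ``report`` is anything with a ``selected_ids`` list (or a plain list of
    selected ids). With an empty selection the FDP is 0 by convention.
    """
    selected = set(
        report if isinstance(report, (list, set, tuple)) else report.selected_ids
    )
    true_set = set(truth.discriminative_ids)
    if not true_set:
        sensitivity = 0.0
    else:
        sensitivity = len(selected & true_set) / len(true_set)
    fdp = len(selected - true_set) / max(1, len(selected))
    return float(sensitivity), float(fdp)


def write_truth_tsv(truth: SyntheticTruth, path: str) -> None:
    """Write ground-truth effects plus a parameter echo as TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#param\tvalue\n")
        for k, v in truth.params.items():
            fh.write(f"#{k}\t{v}\n")
        fh.write("otu_id\teffect\n")
        for otu, eff in truth.effects.items():
            fh.write(f"{otu}\t{eff:.10g}\n")
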