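"""Evaluation protocols: rank-based ROC/AUC, leave-one-out cross-validation,
random-split stability experiments and label corruption.

AUC is computed as the Mann-Whitney U statistic (ties count 0.5), which
equals the trapezoidal integral of the rank-based ROC curve; a pooled
(micro-averaged) ROC across diseases is the default for LOOCV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import RunConfig, ValidationError
from .model import AssociationModel

logger = logging.getLogger("lncdis")


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class LoocvResult:
    """Per-evaluation records and the pooled ROC."""

    records: list[dict] = field(default_factory=list)  # disease, lncRNA, rank, score, n_candidates
    roc: RocCurve | None = None

    @property
    def auc(self) -> float:
        return self.roc.auc


@dataclass
class SplitExperiment:
    n_splits: int
    train_fraction: float
    aucs: list[float]
    summary: dict[str, float]


def roc_auc(scores, labels) -> RocCurve:
    """Rank-based ROC curve and AUC.

    The curve steps through score thresholds from high to low (tied scores
    grouped), so its trapezoidal integral equals the Mann-Whitney AUC with
    ties counted 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length vectors")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], (labels[order] == 1).astype(float)
    # group tied scores into single thresholds
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(1 - y)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def pair_auc(pos_scores, neg_scores) -> float:
    """AUC from two score pools via the U statistic."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return roc_auc(scores, labels).auc


def loocv(
    network,
    config: RunConfig | None = None,
    seed: int = 0,
    mode: str = "warm",
    warm_iterations: int = 200,
    audit: list | None = None,
) -> LoocvResult:
    """Leave-one-out over the known associations.

    For every disease and every known related lncRNA, that single pair is
    removed from A, the model is retrained (``mode='warm'`` restarts from
    the parameters converged on the full data and re-runs a bounded number
    of iterations; ``mode='full'`` retrains from scratch), and the held-out
    lncRNA is ranked against the disease's candidate lncRNAs (those with no
    known association). Records are pooled into one ROC.

    ``audit``, if given, collects per-evaluation evidence that the held-out
    entry was absent from every training input (its value in the training A
    and its membership in the loss mask).
    """
    if mode not in ("warm", "full"):
        raise ValidationError("loocv mode must be 'warm' or 'full'")
    config = config or RunConfig()
    A = network.A.values
    positives = np.argwhere(A == 1)
    if len(positives) < 2:
        raise ValidationError("LOOCV needs at least 2 known associations")

    base_params = None
    if mode == "warm":
        base = AssociationModel(network, config).fit(seed=seed)
        base_params = base.params

    result = LoocvResult()
    pooled_scores, pooled_labels = [], []
    for i, j in positives:
        held_net = network.copy()
        held_net.A.values[i, j] = 0.0
        assert held_net.A.values[i, j] == 0.0 and network.A.values[i, j] == 1.0
        model = AssociationModel(held_net, config)
        forbidden = np.zeros(A.shape, dtype=bool)
        forbidden[i, j] = True  # never sampled as a training negative
        res = model.fit(
            seed=seed,
            start_params=base_params,
            max_iterations=warm_iterations if mode == "warm" else None,
            forbidden=forbidden,
        )
        if audit is not None:
            audit.append(
                {
                    "pair": (int(i), int(j)),
                    "train_A_value": float(held_net.A.values[i, j]),
                    "in_training_mask": bool(res.mask[i, j]),
                }
            )
        col = res.scores()[:, j]
        candidates = np.nonzero(held_net.A.values[:, j] == 0)[0]
        cand_scores = col[candidates]
        cand_labels = (candidates == i).astype(int)
        rank = int(1 + (cand_scores > col[i]).sum())
        result.records.append(
            {
                "disease": network.dis_index.names[j],
                "lncRNA": network.lnc_index.names[i],
                "rank": rank,
                "score": float(col[i]),
                "n_candidates": len(candidates),
            }
        )
        pooled_scores.extend(cand_scores.tolist())
        pooled_labels.extend(cand_labels.tolist())
    result.roc = roc_auc(np.array(pooled_scores), np.array(pooled_labels))
    return result


def holdout_auc(
    network,
    held_pos: list[tuple[int, int]],
    held_neg: list[tuple[int, int]],
    config: RunConfig | None = None,
    seed: int = 0,
) -> float:
    """Train with the held-out pairs excluded and score them.

    ``network`` must already have the held-out positives zeroed in A.
    """
    config = config or RunConfig()
    forbidden = np.zeros(network.A.shape, dtype=bool)
    for i, j in list(held_pos) + list(held_neg):
        forbidden[i, j] = True
    res = AssociationModel(network, config).fit(seed=seed, forbidden=forbidden)
    S = res.scores()
    pos = [S[i, j] for i, j in held_pos]
    neg = [S[i, j] for i, j in held_neg]
    return pair_auc(pos, neg)


def five_number_summary(values) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def random_split_experiment(
    bundle,
    n_splits: int,
    train_fraction: float = 2 / 3,
    config: RunConfig | None = None,
    seed: int = 0,
) -> SplitExperiment:
    """Stability experiment: repeatedly split the known associations into a
    training share and a test share, train on the first, report AUC on the
    second; split ``s`` uses seed ``seed + s`` so the whole experiment is
    reproducible from one seed.
    """
    from .model import AssociationModel  # local to avoid cycle confusion
    from .pipeline import build_network
    from .synthetic import holdout_mask

    if n_splits < 1:
        raise ValidationError("need at least one split")
    if not (0 < train_fraction < 1):
        raise ValidationError("train fraction must lie in (0, 1)")
    config = config or RunConfig()
    aucs = []
    for s in range(n_splits):
        split_seed = seed + s
        train_bundle, held_pos, held_neg = holdout_mask(
            bundle, 1 - train_fraction, seed=split_seed
        )
        network = build_network(train_bundle, config)
        aucs.append(
            holdout_auc(network, held_pos, held_neg, config=config, seed=split_seed)
        )
    return SplitExperiment(
        n_splits=n_splits,
        train_fraction=train_fraction,
        aucs=aucs,
        summary=five_number_summary(aucs),
    )


def corrupt_labels(network_or_bundle, fraction: float, seed: int = 0):
    """Copy with ``round(fraction * A.size)`` entries of A flipped (1 <-> 0),
    chosen uniformly over all cells. Flipping twice with the same seed is the
    identity."""
    if not (0 <= fraction < 1):
        raise ValidationError("corruption fraction must lie in [0, 1)")
    out = network_or_bundle.copy()
    A = out.A.values
    n_flip = int(round(fraction * A.size))
    if n_flip:
        rng = np.random.default_rng(seed)
        flat = rng.choice(A.size, size=n_flip, replace=False)
        A.ravel()[flat] = 1.0 - A.ravel()[flat]
    return out
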