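"""Metric-learning and classification losses, with pair/triplet mining.

Hard samples — subjects whose regional profiles sit near the inter-class
boundary — dominate the error of a plain cross-entropy classifier.  The
deep-metric-learning remedy shapes the embedding space directly: the
contrastive loss pulls same-class pairs together and pushes different-class
pairs apart up to a margin m, and the triplet loss enforces
d(anchor, positive) + m <= d(anchor, negative) per triple.  Either metric
loss L_M is combined with binary cross-entropy L_C as

    L_total = lambda * L_M + L_C,

with lambda = 0.05 by default and margin m = 1.0.

All losses also expose analytic gradients with respect to the embeddings so
the trainer can backpropagate them through the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "PairBatch",
    "TripletBatch",
    "MiningError",
    "contrastive_loss",
    "contrastive_loss_grad",
    "triplet_loss",
    "triplet_loss_grad",
    "cross_entropy_loss",
    "joint_loss",
    "mine_pairs",
    "mine_triplets",
]

METRIC_KINDS = ("none", "contrastive", "triplet")
MINING_STRATEGIES = ("random", "semi_hard")


class MiningError(ValueError):
    """Pair/triplet construction impossible for this batch composition."""


@dataclass(frozen=True)
class LossConfig:
    """Loss hyper-parameters: margin m > 0, coefficient lambda >= 0."""

    margin: float = 1.0
    lam: float = 0.05
    metric_kind: str = "none"
    mining: str = "random"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError(f"margin must be positive, got {self.margin}")
        if self.lam < 0:
            raise ValueError(f"lambda must be non-negative, got {self.lam}")
        if self.metric_kind not in METRIC_KINDS:
            raise ValueError(f"metric_kind must be one of {METRIC_KINDS}")
        if self.mining not in MINING_STRATEGIES:
            raise ValueError(f"mining must be one of {MINING_STRATEGIES}")


@dataclass
class PairBatch:
    """Embedding pairs with a same-class indicator per pair.

    ``i1``/``i2`` index into the source batch so gradients can be scattered
    back to per-sample embedding gradients.
    """

    f1: np.ndarray  # (n_pairs, e)
    f2: np.ndarray  # (n_pairs, e)
    same: np.ndarray  # (n_pairs,) bool, True for same-class pairs
    i1: np.ndarray | None = None
    i2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.f1.shape != self.f2.shape:
            raise ValueError(f"pair shape mismatch: {self.f1.shape} vs {self.f2.shape}")
        if len(self.same) != len(self.f1):
            raise ValueError("same-class indicator length mismatch")


@dataclass
class TripletBatch:
    """(anchor, positive, negative) embedding triples; anchor/positive share a class."""

    fa: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    ia: np.ndarray | None = None
    ip: np.ndarray | None = None
    in_: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.fa.shape == self.fp.shape == self.fn.shape):
            raise ValueError("triplet shape mismatch")


# ---------------------------------------------------------------------------
# Contrastive loss
# ---------------------------------------------------------------------------


def contrastive_loss(batch: PairBatch, margin: float = 1.0, *,
                     literal: bool = False) -> float:
    """Mean contrastive loss over the batch.

    Default (standard) form, with d the Euclidean distance and s the
    same-class indicator:

        L = mean_i [ s_i * d_i^2 + (1 - s_i) * max(0, m - d_i)^2 ]

    ``literal=True`` evaluates the alternative printed convention in which
    d is the *squared* Euclidean norm and the indicator y is 0 for positive
    (same-class) pairs; it is provided for comparison only and carries no
    gradient support.
    """
    if len(batch.f1) == 0:
        raise MiningError("empty pair batch")
    if margin <= 0:
        raise ValueError("margin must be positive")
    diff = batch.f1 - batch.f2
    if literal:
        d = np.sum(diff * diff, axis=1)  # squared norm, per the printed symbols
        y = (~batch.same).astype(float)  # y = 0 for positive pairs
        per = y * d ** 2 + (1 - y) * np.maximum(0.0, margin - d) ** 2
    else:
        d = np.sqrt(np.sum(diff * diff, axis=1))
        s = batch.same.astype(float)
        per = s * d ** 2 + (1 - s) * np.maximum(0.0, margin - d) ** 2
    return float(per.mean())


def contrastive_loss_grad(batch: PairBatch, margin: float = 1.0
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Standard contrastive loss and its gradients w.r.t. f1 and f2."""
    if len(batch.f1) == 0:
        raise MiningError("empty pair batch")
    diff = batch.f1 - batch.f2
    d = np.sqrt(np.sum(diff * diff, axis=1))
    s = batch.same.astype(float)
    hinge = np.maximum(0.0, margin - d)
    per = s * d ** 2 + (1 - s) * hinge ** 2
    n = len(per)
    # d(d^2)/df1 = 2*diff ; d(hinge^2)/df1 = -2*hinge*diff/d (0 where d=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(d[:, None] > 0, diff / np.where(d == 0, 1.0, d)[:, None], 0.0)
    g = (2.0 * s[:, None] * diff - 2.0 * ((1 - s) * hinge)[:, None] * unit) / n
    return float(per.mean()), g, -g


# ---------------------------------------------------------------------------
# Triplet loss (squared Euclidean distances)
# ---------------------------------------------------------------------------


def _sq_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a - b
    return np.sum(diff * diff, axis=1)


def triplet_loss(batch: TripletBatch, margin: float = 1.0) -> float:
    """Mean of max(0, m + d_ap - d_an) with squared Euclidean distances."""
    if len(batch.fa) == 0:
        raise MiningError("empty triplet batch")
    if margin <= 0:
        raise ValueError("margin must be positive")
    per = np.maximum(0.0, margin + _sq_dist(batch.fa, batch.fp) - _sq_dist(batch.fa, batch.fn))
    return float(per.mean())


def triplet_loss_grad(batch: TripletBatch, margin: float = 1.0
                      ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Triplet loss and gradients w.r.t. (anchor, positive, negative)."""
    if len(batch.fa) == 0:
        raise MiningError("empty triplet batch")
    dap = _sq_dist(batch.fa, batch.fp)
    dan = _sq_dist(batch.fa, batch.fn)
    per = margin + dap - dan
    active = (per > 0).astype(float)[:, None]
    n = len(dap)
    ga = active * 2.0 * (batch.fn - batch.fp) / n
    gp = active * (-2.0) * (batch.fa - batch.fp) / n
    gn = active * 2.0 * (batch.fa - batch.fn) / n
    return float(np.maximum(0.0, per).mean()), ga, gp, gn


# ---------------------------------------------------------------------------
# Cross-entropy and the joint loss
# ---------------------------------------------------------------------------


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray,
                       eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; probabilities clamped to [eps, 1-eps]."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"labels must be binary 0/1, got {np.unique(y)}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def joint_loss(metric_loss: float, ce_loss: float, lam: float = 0.05) -> float:
    """L_total = lambda * L_M + L_C."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    total = lam * metric_loss + ce_loss
    if not np.isfinite(total):
        raise FloatingPointError("non-finite joint loss")
    return float(total)


# ---------------------------------------------------------------------------
# Pair / triplet mining
# ---------------------------------------------------------------------------


def _check_batch(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if y.size == 0:
        raise MiningError("empty batch")
    if np.unique(y).size < 2:
        raise MiningError(
            "batch contains a single class; use stratified batch sampling so "
            "every batch holds both classes")
    return y


def mine_pairs(embeddings: np.ndarray, labels: np.ndarray,
               strategy: str = "random", seed: int | np.random.Generator = 0,
               margin: float = 1.0) -> PairBatch:
    """Build one pair per sample (each sample anchors one pair).

    ``random``: the partner is drawn uniformly from the rest of the batch.
    ``semi_hard``: different-class partners still inside the margin
    (d < m) are preferred — those are the pairs the hinge actually
    penalizes — falling back to uniform choice when none exist.
    """
    y = _check_batch(labels)
    emb = np.asarray(embeddings, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(y)
    i1 = np.arange(n)
    i2 = np.empty(n, dtype=int)
    for i in range(n):
        candidates = np.delete(np.arange(n), i)
        if strategy == "semi_hard":
            other = candidates[y[candidates] != y[i]]
            if other.size:
                d = np.linalg.norm(emb[other] - emb[i], axis=1)
                violating = other[d < margin]
                if violating.size:
                    i2[i] = rng.choice(violating)
                    continue
        i2[i] = rng.choice(candidates)
    same = y[i1] == y[i2]
    return PairBatch(emb[i1], emb[i2], same, i1, i2)


def mine_triplets(embeddings: np.ndarray, labels: np.ndarray,
                  strategy: str = "random", seed: int | np.random.Generator = 0,
                  margin: float = 1.0) -> TripletBatch:
    """One triplet per eligible anchor (anchors need a same-class partner).

    ``semi_hard`` prefers negatives with d_ap < d_an < d_ap + m (inside the
    margin but farther than the positive), falling back to uniform sampling
    when no such negative exists for an anchor.
    """
    y = _check_batch(labels)
    emb = np.asarray(embeddings, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(y)
    ia, ip, in_ = [], [], []
    for i in range(n):
        positives = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        negatives = np.flatnonzero(y != y[i])
        if positives.size == 0 or negatives.size == 0:
            continue
        p = int(rng.choice(positives))
        dap = float(np.sum((emb[i] - emb[p]) ** 2))
        neg = None
        if strategy == "semi_hard":
            dan = np.sum((emb[negatives] - emb[i]) ** 2, axis=1)
            semi = negatives[(dan > dap) & (dan < dap + margin)]
            if semi.size:
                neg = int(rng.choice(semi))
        if neg is None:
            neg = int(rng.choice(negatives))
        ia.append(i)
        ip.append(p)
        in_.append(neg)
    if not ia:
        raise MiningError("no valid triplet in batch (need >=2 of one class and >=1 of the other)")
    ia, ip, in_ = np.array(ia), np.array(ip), np.array(in_)
    return TripletBatch(emb[ia], emb[ip], emb[in_], ia, ip, in_)
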