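"""Training loop, validation protocols, metrics and statistical tests.

The optimizer is plain SGD with momentum 0.9 and weight decay 0.001,
minimizing the joint loss L_total = lambda * L_M + L_C.  Evaluation follows
the standard protocol for imbalanced clinical cohorts: stratified fivefold
cross-validation (each fold preserves the class proportions) or a
stratified 80/10/10 train/validation/test holdout, with seven metrics per
fold (ACC, PPV, NPV, SEN, SPE, AUC, F1) summarized as mean ± sd.  Paired
comparisons between model variants use the fold-wise paired t-test and the
DeLong test on pooled out-of-fold scores.

Everything is deterministic given (config, seed): all randomness flows
through explicit NumPy generators and the network is pure NumPy, so a rerun
reproduces reports bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import LabeledCohort
from .losses import (LossConfig, contrastive_loss_grad, cross_entropy_loss,
                     joint_loss, mine_pairs, mine_triplets, triplet_loss_grad)
from .model import BMNet, BMNetConfig

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "SplitError",
    "TrainingError",
    "EvaluationReport",
    "AblationResult",
    "ABLATION_VARIANTS",
    "LAMBDA_GRID",
    "METRIC_NAMES",
    "stratified_kfold_split",
    "holdout_split",
    "confusion_metrics",
    "roc_auc",
    "delong_test",
    "delong_auc_variance",
    "paired_fold_ttest",
    "train_model",
    "evaluate_scores",
    "run_cv_experiment",
    "run_ablation",
    "lambda_sweep",
]

METRIC_NAMES = ("acc", "ppv", "npv", "sen", "spe", "auc", "f1")
LAMBDA_GRID = (0.0, 0.03, 0.05, 0.08, 0.1)

# The six rows of the ablation grid: (name, use_bp, metric_kind).
ABLATION_VARIANTS = (
    ("Baseline", False, "none"),
    ("Baseline+BP", True, "none"),
    ("Tri-loss", False, "triplet"),
    ("Tri-loss+BP", True, "triplet"),
    ("Con-loss", False, "contrastive"),
    ("Con-loss+BP", True, "contrastive"),
)


class SplitError(ValueError):
    """Invalid split request (k too large, bad fractions, ...)."""


class TrainingError(RuntimeError):
    """Optimization failure (non-finite loss)."""


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyper-parameters; momentum and weight decay follow the published defaults."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    grad_clip: float | None = 5.0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.grad_clip is not None and self.grad_clip <= 0:
            raise ValueError("grad_clip must be positive or None")


@dataclass
class FoldSplit:
    """Fold assignment per subject: ``kind='kfold'`` stores fold indices
    0..k-1, ``kind='holdout'`` stores 0/1/2 for train/validation/test."""

    kind: str
    assignment: np.ndarray
    k: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one CV fold."""
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def stratified_kfold_split(labels: np.ndarray, k: int, seed: int) -> FoldSplit:
    """Stratified k-fold partition; per-fold class counts differ by < 1
    from exact proportionality (e.g., a 290/147 cohort at k=5 yields class-0
    folds of 58 and class-1 folds of 30,30,29,29,29)."""
    y = np.asarray(labels)
    if k < 2:
        raise SplitError(f"k must be >= 2, got {k}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise SplitError(f"smallest class has {counts.min()} members < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return FoldSplit("kfold", assignment, k)


def holdout_split(labels: np.ndarray, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> FoldSplit:
    """Stratified train/validation/test split at the given fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SplitError(f"fractions must sum to 1, got {fractions}")
    y = np.asarray(labels)
    idx = np.arange(len(y))
    train_idx, rest_idx = train_test_split(
        idx, test_size=fractions[1] + fractions[2], stratify=y, random_state=seed)
    val_share = fractions[1] / (fractions[1] + fractions[2])
    val_idx, test_idx = train_test_split(
        rest_idx, test_size=1.0 - val_share, stratify=y[rest_idx], random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    assignment[train_idx] = 0
    assignment[val_idx] = 1
    assignment[test_idx] = 2
    return FoldSplit("holdout", assignment, 3)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray,
                      threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at a probability threshold.

    Returns a dict with keys acc/ppv/npv/sen/spe/f1; a metric whose
    denominator is zero is reported as None and listed under
    ``undefined`` rather than silently set to 0.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must be probabilities in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def ratio(num, den):
        return num / den if den > 0 else None

    out = {
        "acc": ratio(tp + tn, tp + tn + fp + fn),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "sen": ratio(tp, tp + fn),
        "spe": ratio(tn, tn + fp),
    }
    if out["ppv"] is None or out["sen"] is None or (out["ppv"] + out["sen"]) == 0:
        out["f1"] = None
    else:
        out["f1"] = 2 * out["ppv"] * out["sen"] / (out["ppv"] + out["sen"])
    out["undefined"] = tuple(k for k, v in out.items() if v is None)
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC; tied scores contribute 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# DeLong test for paired AUCs
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-positive and per-negative placement values (V10, V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong estimate of Var(AUC) for a single score vector."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    v10, v01 = _placements(s, y)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    p_value: float
    z: float


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> DeLongResult:
    """DeLong test for the difference of two correlated (paired) AUCs.

    Identical score vectors (zero variance of the difference) yield the
    defined result p = 1.0 rather than a division error.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired scores and labels must have equal length")
    v10a, v01a = _placements(sa, y)
    v10b, v01b = _placements(sb, y)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var)
        p = float(np.clip(2 * stats.norm.sf(abs(z)), 0.0, 1.0))
    return DeLongResult(auc_a, auc_b, p, float(z))


@dataclass
class TTestResult:
    p_value: float
    t: float
    degenerate: bool = False


def paired_fold_ttest(metric_a: np.ndarray, metric_b: np.ndarray) -> TTestResult:
    """Two-sided paired t-test on per-fold metric differences."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need equal-length fold vectors with >= 2 folds")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        if abs(diff.mean()) < 1e-15:
            return TTestResult(1.0, 0.0, degenerate=True)
        return TTestResult(0.0, np.inf if diff.mean() > 0 else -np.inf, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(p), float(t))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


class _SGD:
    """SGD with momentum, (coupled) L2 weight decay and global-norm clipping.

    Clipping tames the occasional gradient spikes of the quadratic bilinear
    path without changing the function class being optimized.
    """

    def __init__(self, model: BMNet, lr: float, momentum: float,
                 weight_decay: float, grad_clip: float | None = None):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.velocity = {name: np.zeros_like(v) for name, v, _ in model.named_parameters()}

    def step(self) -> None:
        scale = 1.0
        if self.grad_clip is not None:
            total = np.sqrt(sum(float(np.sum(g * g))
                                for _, _, g in self.model.named_parameters()))
            if total > self.grad_clip:
                scale = self.grad_clip / total
        for name, value, grad in self.model.named_parameters():
            g = scale * grad + self.weight_decay * value
            v = self.velocity[name]
            v *= self.momentum
            v += g
            value -= self.lr * v


def _l2_normalize_with_grad(emb: np.ndarray) -> tuple[np.ndarray, callable]:
    """Row-wise L2 normalization and a closure mapping d(normed) -> d(emb).

    Metric losses operate on the unit hypersphere (standard practice: it
    makes the margin m a scale-free quantity and prevents the same-class
    d^2 term from collapsing an unbounded embedding).
    """
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    safe = np.maximum(norms, 1e-12)
    unit = emb / safe

    def backward(g: np.ndarray) -> np.ndarray:
        return (g - (g * unit).sum(axis=1, keepdims=True) * unit) / safe

    return unit, backward


def _stratified_batches(y: np.ndarray, batch_size: int, rng: np.random.Generator,
                        require_both: bool) -> list[np.ndarray]:
    """Shuffled batches; with ``require_both`` every batch holds both classes."""
    n = len(y)
    if not require_both:
        perm = rng.permutation(n)
        return [perm[i:i + batch_size] for i in range(0, n, batch_size)]
    idx0 = rng.permutation(np.flatnonzero(y == 0))
    idx1 = rng.permutation(np.flatnonzero(y == 1))
    n_batches = max(1, min(int(np.ceil(n / batch_size)), len(idx0), len(idx1)))
    chunks0 = np.array_split(idx0, n_batches)
    chunks1 = np.array_split(idx1, n_batches)
    return [rng.permutation(np.concatenate([c0, c1]))
            for c0, c1 in zip(chunks0, chunks1)]


def train_model(features: np.ndarray, labels: np.ndarray,
                model_config: BMNetConfig, loss_config: LossConfig,
                train_config: TrainConfig) -> tuple[BMNet, list[dict]]:
    """Train one model by SGD on the joint loss; returns (model, epoch log).

    Deterministic given the configs: model initialization, batch order and
    pair/triplet mining all derive from ``train_config.seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise TrainingError("training data must contain both classes")
    model = BMNet(model_config, seed=train_config.seed)
    opt = _SGD(model, train_config.learning_rate, train_config.momentum,
               train_config.weight_decay, train_config.grad_clip)
    rng = np.random.default_rng(train_config.seed)
    use_metric = loss_config.metric_kind != "none"
    log: list[dict] = []
    for epoch in range(train_config.epochs):
        batches = _stratified_batches(y, train_config.batch_size, rng, use_metric)
        ce_sum = m_sum = 0.0
        n_seen = 0
        for batch_idx in batches:
            xb, yb = X[batch_idx], y[batch_idx]
            out = model.forward(xb, train=True)
            ce = cross_entropy_loss(out.probability, yb)
            dlogit = (out.probability - yb) / len(yb)
            demb = None
            m_loss = 0.0
            if use_metric:
                unit, unnormalize = _l2_normalize_with_grad(out.embedding)
                dunit = np.zeros_like(unit)
                if loss_config.metric_kind == "contrastive":
                    pairs = mine_pairs(unit, yb, loss_config.mining, rng,
                                       margin=loss_config.margin)
                    m_loss, g1, g2 = contrastive_loss_grad(pairs, loss_config.margin)
                    np.add.at(dunit, pairs.i1, loss_config.lam * g1)
                    np.add.at(dunit, pairs.i2, loss_config.lam * g2)
                else:
                    trips = mine_triplets(unit, yb, loss_config.mining, rng,
                                          margin=loss_config.margin)
                    m_loss, ga, gp, gn = triplet_loss_grad(trips, loss_config.margin)
                    np.add.at(dunit, trips.ia, loss_config.lam * ga)
                    np.add.at(dunit, trips.ip, loss_config.lam * gp)
                    np.add.at(dunit, trips.in_, loss_config.lam * gn)
                demb = unnormalize(dunit)
            total = joint_loss(m_loss, ce, loss_config.lam)
            if not np.isfinite(total):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.zero_grad()
            model.backward(dlogit, demb)
            opt.step()
            ce_sum += ce * len(yb)
            m_sum += m_loss * len(yb)
            n_seen += len(yb)
        entry = {"epoch": epoch, "ce_loss": ce_sum / n_seen,
                 "metric_loss": m_sum / n_seen,
                 "total_loss": loss_config.lam * m_sum / n_seen + ce_sum / n_seen}
        if not np.isfinite(entry["total_loss"]):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        log.append(entry)
    return model, log


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def evaluate_scores(probabilities: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """All seven metrics for one evaluation set."""
    out = confusion_metrics(probabilities, labels, threshold)
    out["auc"] = roc_auc(probabilities, labels)
    return out


@dataclass
class EvaluationReport:
    """Per-fold metrics, mean ± sd summary, and pooled out-of-fold scores."""

    per_fold: list[dict]
    summary: dict
    oof_scores: np.ndarray
    labels: np.ndarray
    config: dict = field(default_factory=dict)

    def fold_values(self, metric: str) -> np.ndarray:
        return np.array([f[metric] for f in self.per_fold
                         if f.get(metric) is not None], dtype=float)

    def to_dict(self) -> dict:
        return {
            "per_fold": [{k: v for k, v in f.items()} for f in self.per_fold],
            "summary": self.summary,
            "oof_scores": np.asarray(self.oof_scores).tolist(),
            "labels": np.asarray(self.labels).tolist(),
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def to_text(self) -> str:
        lines = [f"{'metric':<6} {'mean ± sd':>20}"]
        for m in METRIC_NAMES:
            s = self.summary.get(m)
            if s is None or s["mean"] is None:
                lines.append(f"{m.upper():<6} {'undefined':>20}")
            else:
                lines.append(f"{m.upper():<6} {s['mean']:>12.4f} ± {s['sd']:.4f}")
        return "\n".join(lines)


def _summarize(per_fold: list[dict]) -> dict:
    summary = {}
    for m in METRIC_NAMES:
        vals = np.array([f[m] for f in per_fold if f.get(m) is not None], dtype=float)
        if vals.size == 0:
            summary[m] = {"mean": None, "sd": None, "n_folds": 0}
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            summary[m] = {"mean": float(vals.mean()), "sd": sd, "n_folds": int(vals.size)}
    return summary


def _fold_seed(base_seed: int, fold: int) -> int:
    return int((base_seed * 100003 + 7919 * fold + 1) % (2 ** 31))


def run_cv_experiment(cohort: LabeledCohort, model_config: BMNetConfig,
                      loss_config: LossConfig, train_config: TrainConfig,
                      k: int = 5, folds: FoldSplit | None = None) -> EvaluationReport:
    """Stratified k-fold cross-validation of one model variant.

    Trains k models (one per fold, each seeded deterministically from the
    base seed) and evaluates each on its held-out fold; out-of-fold scores
    are pooled for paired AUC comparisons across variants.
    """
    if folds is None:
        folds = stratified_kfold_split(cohort.labels, k, train_config.seed)
    per_fold = []
    oof = np.full(cohort.n_subjects, np.nan)
    for fold in range(folds.k):
        train_idx, test_idx = folds.fold_indices(fold)
        cfg = TrainConfig(**{**train_config.__dict__,
                             "seed": _fold_seed(train_config.seed, fold)})
        model, _ = train_model(cohort.features[train_idx], cohort.labels[train_idx],
                               model_config, loss_config, cfg)
        probs = model.forward(cohort.features[test_idx]).probability
        oof[test_idx] = probs
        row = evaluate_scores(probs, cohort.labels[test_idx])
        row["fold"] = fold
        per_fold.append(row)
    return EvaluationReport(
        per_fold=per_fold, summary=_summarize(per_fold), oof_scores=oof,
        labels=cohort.labels.copy(),
        config={"model": model_config.to_dict(),
                "loss": loss_config.__dict__.copy(),
                "train": train_config.__dict__.copy(), "k": folds.k})


@dataclass
class AblationResult:
    """Six-variant ablation grid with pairwise statistics against Baseline."""

    reports: dict
    stats_vs_baseline: dict
    folds: FoldSplit

    def to_dict(self) -> dict:
        return {
            "reports": {name: r.to_dict() for name, r in self.reports.items()},
            "stats_vs_baseline": self.stats_vs_baseline,
        }


def run_ablation(cohort: LabeledCohort, model_config: BMNetConfig,
                 train_config: TrainConfig, loss_config: LossConfig | None = None,
                 k: int = 5) -> AblationResult:
    """Run the 2 (BP on/off) x 3 (none/triplet/contrastive) grid on shared folds.

    Every variant sees identical fold assignments and per-fold seeds, so
    differences are attributable to the architecture/loss alone.  Each
    non-Baseline row gets a fold-wise paired t-test on AUC and a DeLong
    test on pooled out-of-fold scores against Baseline.
    """
    base_loss = loss_config or LossConfig()
    folds = stratified_kfold_split(cohort.labels, k, train_config.seed)
    reports = {}
    for name, use_bp, metric_kind in ABLATION_VARIANTS:
        mcfg = BMNetConfig.from_dict({**model_config.to_dict(), "use_bp": use_bp})
        lcfg = LossConfig(margin=base_loss.margin, lam=base_loss.lam,
                          metric_kind=metric_kind, mining=base_loss.mining)
        reports[name] = run_cv_experiment(cohort, mcfg, lcfg, train_config,
                                          folds=folds)
    base = reports["Baseline"]
    stats_out = {}
    for name in reports:
        if name == "Baseline":
            continue
        t_res = paired_fold_ttest(reports[name].fold_values("auc"),
                                  base.fold_values("auc"))
        d_res = delong_test(reports[name].oof_scores, base.oof_scores, cohort.labels)
        stats_out[name] = {
            "ttest_auc_p": t_res.p_value,
            "ttest_degenerate": t_res.degenerate,
            "delong_p": d_res.p_value,
            "delong_auc": d_res.auc_a,
            "delong_auc_baseline": d_res.auc_b,
        }
    return AblationResult(reports, stats_out, folds)


def lambda_sweep(cohort: LabeledCohort, model_config: BMNetConfig,
                 train_config: TrainConfig, metric_kind: str = "triplet",
                 lambdas: tuple[float, ...] = LAMBDA_GRID, k: int = 5,
                 margin: float = 1.0) -> list[dict]:
    """Cross-validated AUC for each joint-loss coefficient on shared folds."""
    folds = stratified_kfold_split(cohort.labels, k, train_config.seed)
    rows = []
    for lam in lambdas:
        if lam == 0:
            lcfg = LossConfig(margin=margin, lam=0.0, metric_kind="none")
        else:
            lcfg = LossConfig(margin=margin, lam=lam, metric_kind=metric_kind)
        rep = run_cv_experiment(cohort, model_config, lcfg, train_config, folds=folds)
        rows.append({"lambda": lam,
                     "auc_mean": rep.summary["auc"]["mean"],
                     "auc_sd": rep.summary["auc"]["sd"]})
    return rows
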