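"""Linear SVM stage classification with leave-one-participant-out CV.

The classifier is a binary soft-margin SVM with a linear kernel applied
to standardized component scores; its two hyperparameters are the
misclassification cost (box constraint C) and the kernel scale (a
positive divisor applied to feature vectors before the inner product).
Cross-validation is leave-one-*participant*-out: both scans (pre and
post) of the held-out participant are predicted by a model trained on
the remaining participants, so a subject's correlated pair of scans can
never straddle the train/test split ("twinning").

Two protocols are supported:

* ``pooled`` — the feature chain (outlier screen, selection,
  PCA, standardization) is fitted once on the full cohort and only the
  SVM is refit per fold.  This mirrors the common published protocol
  but leaks test information into feature selection.
* ``nested`` — the entire feature chain is refit inside each training
  fold; the held-out participant influences nothing.  This is the
  honest estimate; on null cohorts it centers on chance while the
  pooled protocol is optimistically biased.

Hyperparameters can be tuned by Bayesian optimization (GP surrogate +
expected improvement over log10 cost × log10 kernel scale) minimizing
the cross-validation error, with a fixed evaluation budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .features import FeatureChain

__all__ = [
    "SvmHyperparams",
    "SvmModel",
    "CvReport",
    "PRE", "POST",
    "train_svm",
    "loocv_by_participant",
    "compute_metrics",
    "bayes_optimize",
]

PRE, POST = "pre", "post"
_LABEL_NUM = {PRE: 1.0, POST: -1.0}  # "pre" is the positive class


@dataclass(frozen=True)
class SvmHyperparams:
    cost: float = 1.0
    kernel_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.kernel_scale <= 0:
            raise ValueError("cost and kernel_scale must be positive")


@dataclass
class SvmModel:
    """Fitted linear SVM: decision = weights·(x / kernel_scale) + bias."""

    weights: np.ndarray
    bias: float
    hyperparams: SvmHyperparams
    n_support: int = 0
    fold_id: int | None = None

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x / self.hyperparams.kernel_scale @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> list[str]:
        # tie at exactly 0 predicts "post"
        return [PRE if d > 0 else POST for d in self.decision_values(x)]


def train_svm(
    scores: np.ndarray, labels: Sequence[str], hp: SvmHyperparams = SvmHyperparams()
) -> SvmModel:
    """Fit the soft-margin linear SVM on (scores / kernel_scale)."""
    from sklearn.svm import SVC

    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    y = np.array([_LABEL_NUM[l] for l in labels])
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(kernel="linear", C=hp.cost, tol=1e-6)
    svc.fit(scores / hp.kernel_scale, y)
    # sklearn orders classes [-1, +1]; positive decision → +1 → "pre"
    return SvmModel(
        weights=svc.coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        hyperparams=hp,
        n_support=int(svc.n_support_.sum()),
    )


@dataclass
class CvReport:
    """Pooled leave-one-participant-out results."""

    fold_assignments: dict[str, int]
    participants: list[str]  # one entry per observation
    stages: list[str]  # actual stage per observation
    predictions: list[str]
    decision_values: np.ndarray
    confusion: np.ndarray  # rows actual (pre, post) × cols predicted (pre, post)
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    hyperparams: SvmHyperparams = field(default_factory=SvmHyperparams)
    mode: str = "pooled"

    @property
    def error(self) -> float:
        return 1.0 - self.accuracy

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "hyperparams": {
                "cost": self.hyperparams.cost,
                "kernel_scale": self.hyperparams.kernel_scale,
            },
            "fold_assignments": self.fold_assignments,
            "observations": [
                {
                    "participant": p,
                    "stage": s,
                    "predicted": pr,
                    "decision_value": float(d),
                }
                for p, s, pr, d in zip(
                    self.participants, self.stages, self.predictions, self.decision_values
                )
            ],
            "confusion_matrix": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def compute_metrics(
    confusion: np.ndarray,
    decision_values: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
) -> dict:
    """Accuracy / sensitivity / specificity from a 2×2 confusion matrix.

    Rows are actual (pre, post), columns predicted (pre, post);
    sensitivity is the pre-stage recall, specificity the post-stage
    recall.  AUC (trapezoidal, over ranked decision values with "pre"
    positive) and the ROC points are added when pooled decision values
    and their true labels are supplied.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("confusion matrix must be 2×2 nonnegative")
    n = c.sum()
    if c[0].sum() == 0 or c[1].sum() == 0:
        raise ValueError("empty actual class in confusion matrix")
    out = {
        "accuracy": float(np.trace(c) / n),
        "sensitivity": float(c[0, 0] / c[0].sum()),
        "specificity": float(c[1, 1] / c[1].sum()),
    }
    if decision_values is not None:
        from sklearn.metrics import roc_auc_score, roc_curve

        y = np.array([1 if l == PRE else 0 for l in labels])
        d = np.asarray(decision_values, dtype=float)
        if np.ptp(d) == 0:
            out["auc"] = 0.5  # uninformative scores rank nothing
            out["roc_points"] = np.array([[0.0, 0.0], [1.0, 1.0]])
        else:
            out["auc"] = float(roc_auc_score(y, d))
            fpr, tpr, _ = roc_curve(y, d)
            out["roc_points"] = np.column_stack([fpr, tpr])
    return out


def _pair_matrices(
    x_pre: np.ndarray, x_post: np.ndarray, participants: Sequence[str]
) -> None:
    if x_pre.shape != x_post.shape:
        raise ValueError("stage matrices must have identical shapes")
    if x_pre.shape[0] != len(participants):
        raise ValueError("one row per participant required in each stage matrix")
    if len(set(participants)) != len(participants):
        raise ValueError("duplicate participant ids (each needs exactly one pre and one post)")


def loocv_by_participant(
    x_pre: np.ndarray,
    x_post: np.ndarray,
    participants: Sequence[str],
    hp: SvmHyperparams = SvmHyperparams(),
    mode: str = "pooled",
    chain: FeatureChain | None = None,
    chain_factory: Callable[[], FeatureChain] | None = None,
) -> CvReport:
    """Leave-one-participant-out CV over raw FC matrices.

    ``x_pre`` / ``x_post`` are n × p FC matrices with rows aligned to
    ``participants``.  In ``pooled`` mode a single feature
    chain (``chain``, or a fresh default) is fitted on the full cohort;
    in ``nested`` mode a fresh chain from ``chain_factory`` is fitted
    per fold on the training participants only.
    """
    if mode not in ("pooled", "nested"):
        raise ValueError(f"unknown mode {mode!r}")
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    _pair_matrices(x_pre, x_post, participants)
    n = len(participants)
    factory = chain_factory if chain_factory is not None else FeatureChain

    shared_chain = None
    if mode == "pooled":
        shared_chain = chain if chain is not None and chain.is_fitted else factory().fit(
            x_pre, x_post
        )

    fold_assignments: dict[str, int] = {}
    obs_participants: list[str] = []
    obs_stages: list[str] = []
    predictions: list[str] = []
    decisions: list[float] = []

    for fold, held_out in enumerate(participants):
        fold_assignments[held_out] = fold
        train = np.array([p != held_out for p in participants])
        if mode == "nested":
            fold_chain = factory().fit(x_pre[train], x_post[train])
        else:
            fold_chain = shared_chain
        tr_scores = np.vstack(
            [fold_chain.transform(x_pre[train]), fold_chain.transform(x_post[train])]
        )
        tr_labels = [PRE] * int(train.sum()) + [POST] * int(train.sum())
        model = train_svm(tr_scores, tr_labels, hp)
        model.fold_id = fold
        te_scores = np.vstack(
            [fold_chain.transform(x_pre[~train]), fold_chain.transform(x_post[~train])]
        )
        d = model.decision_values(te_scores)
        for stage, dv in zip((PRE, POST), d):
            obs_participants.append(held_out)
            obs_stages.append(stage)
            predictions.append(PRE if dv > 0 else POST)
            decisions.append(float(dv))

    confusion = np.zeros((2, 2), dtype=int)
    for actual, predicted in zip(obs_stages, predictions):
        confusion[0 if actual == PRE else 1, 0 if predicted == PRE else 1] += 1
    decisions_arr = np.array(decisions)
    metrics = compute_metrics(confusion, decisions_arr, obs_stages)
    return CvReport(
        fold_assignments=fold_assignments,
        participants=obs_participants,
        stages=obs_stages,
        predictions=predictions,
        decision_values=decisions_arr,
        confusion=confusion,
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        auc=metrics["auc"],
        hyperparams=hp,
        mode=mode,
    )


# -- Bayesian hyperparameter optimization ------------------------------


def _expected_improvement(
    mu: np.ndarray, sigma: np.ndarray, best: float, xi: float = 0.01
) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu - xi) / sigma
    return (best - mu - xi) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def bayes_optimize(
    x_pre: np.ndarray,
    x_post: np.ndarray,
    participants: Sequence[str],
    n_iter: int = 30,
    cost_range: tuple[float, float] = (1e-3, 1e3),
    scale_range: tuple[float, float] = (1e-3, 1e3),
    rng_seed: int = 0,
    mode: str = "pooled",
    chain_factory: Callable[[], FeatureChain] | None = None,
    n_warmup: int = 5,
) -> tuple[SvmHyperparams, list[tuple[SvmHyperparams, float]]]:
    """Minimize the LOOCV error over (cost, kernel scale).

    Gaussian-process surrogate with expected-improvement proposals over
    the log10 box ``cost_range`` × ``scale_range``; the first
    ``n_warmup`` of the ``n_iter`` evaluations are space-filling random
    draws.  Returns the best-observed point and the full evaluation
    trace.  Fully deterministic under ``rng_seed``.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    for lo, hi in (cost_range, scale_range):
        if not 0 < lo < hi:
            raise ValueError("ranges must satisfy 0 < lo < hi")
    rng = np.random.default_rng(rng_seed)
    lo = np.log10([cost_range[0], scale_range[0]])
    hi = np.log10([cost_range[1], scale_range[1]])

    factory = chain_factory if chain_factory is not None else FeatureChain
    shared_chain = None
    if mode == "pooled":
        # the chain does not depend on hyperparameters; fit it once
        shared_chain = factory().fit(np.asarray(x_pre, float), np.asarray(x_post, float))

    def objective(u: np.ndarray) -> float:
        hp = SvmHyperparams(cost=10 ** u[0], kernel_scale=10 ** u[1])
        report = loocv_by_participant(
            x_pre, x_post, participants, hp=hp, mode=mode,
            chain=shared_chain, chain_factory=factory,
        )
        return report.error

    observed_u: list[np.ndarray] = []
    observed_y: list[float] = []
    trace: list[tuple[SvmHyperparams, float]] = []

    n_warm = min(n_warmup, n_iter)
    for _ in range(n_warm):
        u = rng.uniform(lo, hi)
        y = objective(u)
        observed_u.append(u)
        observed_y.append(y)
        trace.append((SvmHyperparams(10 ** u[0], 10 ** u[1]), y))

    for it in range(n_iter - n_warm):
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * Matern(length_scale=[1.0, 1.0], nu=2.5),
            alpha=1e-6,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gp.fit(np.vstack(observed_u), np.array(observed_y))
        candidates = rng.uniform(lo, hi, size=(256, 2))
        mu, sigma = gp.predict(candidates, return_std=True)
        ei = _expected_improvement(mu, sigma, min(observed_y))
        u = candidates[int(np.argmax(ei))]
        y = objective(u)
        observed_u.append(u)
        observed_y.append(y)
        trace.append((SvmHyperparams(10 ** u[0], 10 ** u[1]), y))

    best = int(np.argmin(observed_y))
    return trace[best][0], trace
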