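"""Fitted feature chain for group-level FC analysis.

Order of operations, each stage persisting its mask so any surviving
feature maps back to its seed pair:

1. robust outlier screen — a feature (FC coefficient) is dropped if any
   participant's value lies more than ``mad_multiplier`` scaled MADs
   from the feature median, in either stage;
2. Kolmogorov–Smirnov normality filter on the standardized paired
   differences (post − pre), keeping features not rejected against a
   standard normal;
3. univariate paired t-test, keeping features with p below ``alpha``;
4. PCA on the mean-centered stacked (pre over post) selected features —
   variance is deliberately *not* standardized before PCA;
5. component count chosen as the smallest k whose cumulative explained
   variance exceeds ``variance_threshold`` (default 85%);
6. per-component score standardization (train mean 0, sd 1) so no
   component dominates the SVM through sheer scale.

The scaled MAD uses the normal-consistency constant 1.4826, so "three
scaled MADs" corresponds to roughly three standard deviations for
Gaussian data while staying robust to the very outliers being screened.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "OutlierScreenResult",
    "SelectionResult",
    "PcaBasis",
    "ScoreStandardizer",
    "FeatureChain",
    "mad_outlier_flags",
    "screen_outlier_features",
    "ks_normality_pvalues",
    "ks_normality_filter",
    "paired_t_select",
    "fit_pca",
    "choose_components",
    "transform_scores",
    "fit_standardizer",
]

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass
class OutlierScreenResult:
    retained_indices: np.ndarray
    removed_pre: np.ndarray
    removed_post: np.ndarray
    mad_multiplier: float = 3.0
    mad_scale: float = MAD_SCALE


@dataclass
class SelectionResult:
    """Normality + paired-t selection masks, in original feature indexing."""

    normal_indices: np.ndarray
    p_values: np.ndarray  # aligned with normal_indices
    selected_indices: np.ndarray
    alpha: float


@dataclass
class PcaBasis:
    mean_vector: np.ndarray
    loadings: np.ndarray  # p × m, orthonormal columns
    variance_fractions: np.ndarray  # length m, non-increasing
    n_components_kept: int
    variance_threshold: float = 0.85


@dataclass
class ScoreStandardizer:
    score_means: np.ndarray
    score_sds: np.ndarray

    def apply(self, scores: np.ndarray) -> np.ndarray:
        return (scores - self.score_means) / self.score_sds

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.score_sds + self.score_means


def mad_outlier_flags(
    values: np.ndarray, multiplier: float = 3.0, scale: float = MAD_SCALE
) -> np.ndarray:
    """Flag values more than ``multiplier`` scaled MADs from the median.

    Degenerate MAD = 0 (at least half the values tied at the median):
    any value different from the median is flagged, keeping the screen
    strict rather than silently passing everything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to screen for outliers")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    return np.abs(x - med) > multiplier * scale * mad


def _stage_outlier_mask(
    x: np.ndarray, multiplier: float, scale: float
) -> np.ndarray:
    """Per-feature 'any participant flagged' mask, vectorized over columns."""
    med = np.median(x, axis=0)
    absdev = np.abs(x - med)
    mad = np.median(absdev, axis=0)
    degenerate = mad == 0
    flags = absdev > multiplier * scale * np.where(degenerate, np.inf, mad)
    flags[:, degenerate] = x[:, degenerate] != med[degenerate]
    return flags.any(axis=0)


def screen_outlier_features(
    x_pre: np.ndarray,
    x_post: np.ndarray,
    multiplier: float = 3.0,
    scale: float = MAD_SCALE,
) -> OutlierScreenResult:
    """Drop features containing an outlier in either stage.

    Only features clean in *both* stages are retained (the screen is
    symmetric in stage order).
    """
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape:
        raise ValueError(f"stage shapes differ: {x_pre.shape} vs {x_post.shape}")
    if x_pre.shape[0] < 3:
        raise ValueError("need at least 3 participants to screen for outliers")
    bad_pre = _stage_outlier_mask(x_pre, multiplier, scale)
    bad_post = _stage_outlier_mask(x_post, multiplier, scale)
    retained = np.flatnonzero(~(bad_pre | bad_post))
    return OutlierScreenResult(
        retained_indices=retained,
        removed_pre=np.flatnonzero(bad_pre),
        removed_post=np.flatnonzero(bad_post),
        mad_multiplier=multiplier,
        mad_scale=scale,
    )


def ks_normality_pvalues(x: np.ndarray) -> np.ndarray:
    """Column-wise KS p-values of standardized data against N(0, 1).

    Matches ``scipy.stats.kstest(z, "norm")`` with the exact two-sided
    null distribution, computed vectorized across columns.  Zero-variance
    columns get p = 0 (they cannot be standardized and are excluded).
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 4:
        raise ValueError("need at least 4 observations per feature for the KS test")
    sd = x.std(axis=0, ddof=1)
    degenerate = np.ptp(x, axis=0) == 0
    sd = np.where(degenerate, 0.0, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - x.mean(axis=0)) / sd
    z = np.sort(z, axis=0)
    cdf = stats.norm.cdf(z)
    steps = np.arange(1, n + 1)[:, None] / n
    d_plus = (steps - cdf).max(axis=0)
    d_minus = (cdf - (steps - 1.0 / n)).max(axis=0)
    d = np.maximum(d_plus, d_minus)
    pvals = stats.kstwo.sf(np.clip(d, 0, 1), n)
    pvals = np.clip(pvals, 0.0, 1.0)
    pvals[degenerate] = 0.0
    return pvals


def ks_normality_filter(x: np.ndarray, alpha_ks: float = 0.05) -> np.ndarray:
    """Indices (into columns of ``x``) not rejected by the KS test."""
    x = np.asarray(x, dtype=float)
    degenerate = np.ptp(x, axis=0) == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s) excluded from the "
            "normality filter (cannot be standardized)",
            stacklevel=2,
        )
    pvals = ks_normality_pvalues(x)
    return np.flatnonzero((pvals > alpha_ks) & ~degenerate)


def paired_t_select(
    x_pre: np.ndarray,
    x_post: np.ndarray,
    alpha: float = 0.05,
    fdr: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t-test per feature on d = post − pre.

    Returns ``(p_values, selected)`` where ``selected`` indexes columns
    with p < alpha (after Benjamini–Hochberg adjustment when ``fdr``).
    Zero-variance differences get p = 1 with a warning.
    """
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape:
        raise ValueError("stage shapes differ")
    n = x_pre.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants for the paired t-test")
    d = x_post - x_pre
    zero_var = d.std(axis=0, ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} feature(s) with zero-variance paired difference "
            "assigned p = 1 and excluded",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_rel(x_post, x_pre, axis=0)
    pvals = np.where(zero_var, 1.0, res.pvalue)
    crit = stats.false_discovery_control(pvals) if fdr else pvals
    selected = np.flatnonzero(crit < alpha)
    return pvals, selected


def fit_pca(x: np.ndarray, variance_threshold: float = 0.85) -> PcaBasis:
    """Mean-centered PCA (no variance standardization).

    At most ``min(n − 1, p)`` positive-variance components exist for n
    samples of p features; only those are kept in the basis.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to PCA")
    n, p = x.shape
    m = min(n - 1, p)
    if m < 1:
        raise ValueError("need at least 2 samples and 1 feature")
    pca = PCA(n_components=m, svd_solver="full")
    pca.fit(x)
    fractions = pca.explained_variance_ratio_.copy()
    k = choose_components(fractions, variance_threshold)
    return PcaBasis(
        mean_vector=pca.mean_.copy(),
        loadings=pca.components_.T.copy(),
        variance_fractions=fractions,
        n_components_kept=k,
        variance_threshold=variance_threshold,
    )


def choose_components(variance_fractions: np.ndarray, threshold: float = 0.85) -> int:
    """Smallest k with cumulative variance fraction strictly > threshold."""
    fr = np.asarray(variance_fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("no components")
    if np.any(fr < -1e-12) or np.any(np.diff(fr) > 1e-12):
        raise ValueError("variance fractions must be non-increasing and nonnegative")
    cum = np.cumsum(fr)
    above = np.flatnonzero(cum > threshold)
    if above.size == 0:
        warnings.warn(
            f"total explained variance {cum[-1]:.3f} never exceeds threshold "
            f"{threshold}; keeping all {fr.size} components",
            stacklevel=2,
        )
        return int(fr.size)
    return int(above[0] + 1)


def transform_scores(x: np.ndarray, basis: PcaBasis) -> np.ndarray:
    """Project onto the kept components: (X − mean) · loadings[:, :k]."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != basis.mean_vector.size:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match basis ({basis.mean_vector.size})"
        )
    return (x - basis.mean_vector) @ basis.loadings[:, : basis.n_components_kept]


def fit_standardizer(scores: np.ndarray) -> ScoreStandardizer:
    scores = np.asarray(scores, dtype=float)
    sds = scores.std(axis=0, ddof=0)
    if np.any(sds == 0):
        raise ValueError("zero-variance component score; cannot standardize")
    return ScoreStandardizer(score_means=scores.mean(axis=0), score_sds=sds)


@dataclass
class FeatureChain:
    """The full fitted chain, from raw FC features to standardized scores.

    ``fit`` consumes the two n × p stage matrices (rows aligned by
    participant); ``transform`` maps any full-width FC matrix into the
    standardized component-score space of the training fit.  All masks
    are kept in original feature indexing, so ``selected_indices`` maps
    straight back to seed pairs via the connectivity index convention.
    """

    alpha: float = 0.05
    alpha_ks: float = 0.05
    mad_multiplier: float = 3.0
    mad_scale: float = MAD_SCALE
    variance_threshold: float = 0.85
    use_ks_filter: bool = True
    fdr: bool = False

    screen: OutlierScreenResult | None = field(default=None, repr=False)
    selection: SelectionResult | None = field(default=None, repr=False)
    basis: PcaBasis | None = field(default=None, repr=False)
    standardizer: ScoreStandardizer | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self.standardizer is not None

    def fit(self, x_pre: np.ndarray, x_post: np.ndarray) -> "FeatureChain":
        x_pre = np.asarray(x_pre, dtype=float)
        x_post = np.asarray(x_post, dtype=float)
        self.screen = screen_outlier_features(
            x_pre, x_post, self.mad_multiplier, self.mad_scale
        )
        kept = self.screen.retained_indices
        if kept.size == 0:
            raise ValueError("outlier screen removed every feature")
        d = x_post[:, kept] - x_pre[:, kept]
        if self.use_ks_filter:
            normal_local = ks_normality_filter(d, self.alpha_ks)
        else:
            normal_local = np.arange(kept.size)
        if normal_local.size == 0:
            warnings.warn("no feature passed the normality filter; skipping it", stacklevel=2)
            normal_local = np.arange(kept.size)
        normal = kept[normal_local]
        pvals, sel_local = paired_t_select(
            x_pre[:, normal], x_post[:, normal], self.alpha, self.fdr
        )
        if sel_local.size == 0:
            # degenerate on null-like folds: keep the single best feature so
            # the chain (and any CV fold using it) still produces scores
            warnings.warn(
                "no feature passed the paired-t threshold; retaining the "
                "smallest-p feature",
                stacklevel=2,
            )
            sel_local = np.array([int(np.argmin(pvals))])
        selected = normal[sel_local]
        self.selection = SelectionResult(
            normal_indices=normal,
            p_values=pvals,
            selected_indices=selected,
            alpha=self.alpha,
        )
        stacked = np.vstack([x_pre[:, selected], x_post[:, selected]])
        self.basis = fit_pca(stacked, self.variance_threshold)
        train_scores = transform_scores(stacked, self.basis)
        self.standardizer = fit_standardizer(train_scores)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Full-width FC matrix → standardized kept-component scores."""
        if not self.is_fitted:
            raise RuntimeError("FeatureChain is not fitted")
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        sub = x[:, self.selection.selected_indices]
        return self.standardizer.apply(transform_scores(sub, self.basis))

    # -- serialization --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        if not self.is_fitted:
            raise RuntimeError("cannot serialize an unfitted chain")
        payload = {
            "params": {
                "alpha": self.alpha,
                "alpha_ks": self.alpha_ks,
                "mad_multiplier": self.mad_multiplier,
                "mad_scale": self.mad_scale,
                "variance_threshold": self.variance_threshold,
                "use_ks_filter": self.use_ks_filter,
                "fdr": self.fdr,
            },
            "screen": {
                "retained_indices": self.screen.retained_indices.tolist(),
                "removed_pre": self.screen.removed_pre.tolist(),
                "removed_post": self.screen.removed_post.tolist(),
            },
            "selection": {
                "normal_indices": self.selection.normal_indices.tolist(),
                "p_values": self.selection.p_values.tolist(),
                "selected_indices": self.selection.selected_indices.tolist(),
                "alpha": self.selection.alpha,
            },
            "basis": {
                "mean_vector": self.basis.mean_vector.tolist(),
                "loadings": self.basis.loadings.tolist(),
                "variance_fractions": self.basis.variance_fractions.tolist(),
                "n_components_kept": self.basis.n_components_kept,
                "variance_threshold": self.basis.variance_threshold,
            },
            "standardizer": {
                "score_means": self.standardizer.score_means.tolist(),
                "score_sds": self.standardizer.score_sds.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureChain":
        payload = json.loads(Path(path).read_text())
        chain = cls(**payload["params"])
        sc = payload["screen"]
        chain.screen = OutlierScreenResult(
            retained_indices=np.array(sc["retained_indices"], dtype=int),
            removed_pre=np.array(sc["removed_pre"], dtype=int),
            removed_post=np.array(sc["removed_post"], dtype=int),
            mad_multiplier=chain.mad_multiplier,
            mad_scale=chain.mad_scale,
        )
        se = payload["selection"]
        chain.selection = SelectionResult(
            normal_indices=np.array(se["normal_indices"], dtype=int),
            p_values=np.array(se["p_values"], dtype=float),
            selected_indices=np.array(se["selected_indices"], dtype=int),
            alpha=se["alpha"],
        )
        ba = payload["basis"]
        chain.basis = PcaBasis(
            mean_vector=np.array(ba["mean_vector"], dtype=float),
            loadings=np.array(ba["loadings"], dtype=float),
            variance_fractions=np.array(ba["variance_fractions"], dtype=float),
            n_components_kept=int(ba["n_components_kept"]),
            variance_threshold=float(ba["variance_threshold"]),
        )
        st = payload["standardizer"]
        chain.standardizer = ScoreStandardizer(
            score_means=np.array(st["score_means"], dtype=float),
            score_sds=np.array(st["score_sds"], dtype=float),
        )
        return chain
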