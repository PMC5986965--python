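"""Synthetic two-stage cohorts with known connectivity ground truth.

Real scan data behind the study design (a 20-participant pre/post
intervention cohort, 231 time points at TR = 2.6 s, BOLD fluctuations
band-limited to 0.01–0.1 Hz) are emulated by a controllable generator:

* a latent *stage correlation matrix* per stage with network-block
  structure — within-network coupling above between-network coupling —
  identical across stages except on a planted subset of seed pairs whose
  latent correlation shifts by ``effect_size`` from pre to post;
* per participant and stage, independent band-limited Gaussian series
  (white noise → Butterworth band-pass → mixed by the correlation
  Cholesky factor) whose sample FC converges to the latent matrix as T
  grows;
* optional corruption of a fraction of FC entries by extreme values, to
  exercise the robust outlier screen.

Every draw is reproducible from ``rng_seed``, and the returned
:class:`SyntheticTruth` records exactly what was planted, so downstream
selection / classification / attribution stages can be scored against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .atlas import DEFAULT_NETWORKS, Seed, SeedAtlas
from .connectivity import correlation_matrix, n_unique_pairs, pair_to_index, vectorize_unique

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "toy_atlas",
    "build_stage_covariances",
    "generate_cohort",
    "cohort_fc",
    "write_cohort",
]


def toy_atlas(n_seeds: int, n_networks: int = 4) -> SeedAtlas:
    """Small block-structured atlas for synthetic cohorts.

    Seeds are split into ``n_networks`` contiguous blocks named after
    the first networks of the default template (so the first block is a
    motor network and motor/non-motor partitioning works out of the
    box).  Coordinates are a deterministic grid — placeholders for
    visualization only.
    """
    if not 1 <= n_networks <= len(DEFAULT_NETWORKS):
        raise ValueError(f"n_networks must be in 1..{len(DEFAULT_NETWORKS)}")
    if n_seeds < n_networks:
        raise ValueError("need at least one seed per network")
    palette = [DEFAULT_NETWORKS[i] for i in range(n_networks)]
    block = [n_seeds // n_networks + (1 if i < n_seeds % n_networks else 0)
             for i in range(n_networks)]
    seeds, sid = [], 0
    for (name, _color, _), size in zip(palette, block):
        for i in range(size):
            seeds.append(
                Seed(
                    seed_id=sid,
                    label=f"net{palette.index((name, _color, _))}_s{i:02d}",
                    mni_xyz=(float(10 * (sid % 12) - 60), float(8 * (sid // 12) - 60), 0.0),
                    network=name,
                )
            )
            sid += 1
    networks = [(name, color, size) for (name, color, _), size in zip(palette, block)]
    return SeedAtlas(seeds=seeds, networks=networks)

_FILTER_PAD = 128  # burn-in samples trimmed from each end after filtering


@dataclass
class CohortConfig:
    """Generator knobs; defaults mirror the study conditions."""

    n_participants: int = 20
    n_seeds: int = 30
    n_timepoints: int = 231
    tr_seconds: float = 2.6
    band_hz: tuple[float, float] = (0.01, 0.1)
    n_planted: int = 12
    effect_size: float = 0.4
    base_within: float = 0.3
    base_between: float = 0.1
    noise_sd: float = 0.0
    outlier_rate: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.n_planted > n_unique_pairs(self.n_seeds):
            raise ValueError("n_planted exceeds C(n_seeds, 2)")
        lo, hi = self.band_hz
        nyquist = 0.5 / self.tr_seconds
        if not 0 < lo < hi < nyquist:
            raise ValueError(f"band must satisfy 0 < low < high < Nyquist ({nyquist:.3f} Hz)")
        for base in (self.base_within, self.base_between):
            if not abs(base + self.effect_size) < 1 or not abs(base) < 1:
                raise ValueError("base correlation ± effect_size must stay inside (-1, 1)")


@dataclass
class SyntheticTruth:
    """What the generator planted (for scoring downstream stages)."""

    planted_pairs: list[tuple[int, int, float]]
    cov_pre: np.ndarray
    cov_post: np.ndarray
    injected_outliers: list[tuple[str, str, int]] = field(default_factory=list)

    def planted_indices(self, s: int) -> np.ndarray:
        """FC-vector indices of the planted pairs."""
        if not self.planted_pairs:
            return np.array([], dtype=int)
        i = np.array([p[0] for p in self.planted_pairs])
        j = np.array([p[1] for p in self.planted_pairs])
        return np.asarray(pair_to_index(i, j, s))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pairs": [[int(i), int(j), float(e)] for i, j, e in self.planted_pairs],
            "injected_outliers": [
                [pid, stage, int(k)] for pid, stage, k in self.injected_outliers
            ],
            "cov_pre": self.cov_pre.tolist(),
            "cov_post": self.cov_post.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _check_spd(m: np.ndarray, name: str) -> None:
    eigmin = float(np.linalg.eigvalsh(m)[0])
    if eigmin <= 1e-10:
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {eigmin:.3e}); "
            "reduce base correlations or the planted effect"
        )


def build_stage_covariances(
    config: CohortConfig,
    atlas: SeedAtlas,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, float]]]:
    """Latent pre/post correlation matrices with planted stage effects.

    Both matrices share a network-block baseline (``base_within`` inside
    a network, ``base_between`` across networks, unit diagonal) and
    differ by ``effect_size`` on ``n_planted`` randomly chosen pairs.
    Planted pairs are drawn from between-network pairs when enough
    exist, since those carry the weaker baseline and leave headroom for
    positive effects.
    """
    config.validate()
    if atlas.n_seeds != config.n_seeds:
        raise ValueError(f"atlas has {atlas.n_seeds} seeds, config expects {config.n_seeds}")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    s = config.n_seeds
    labels = np.array([seed.network for seed in atlas.seeds])
    same = labels[:, None] == labels[None, :]
    base = np.where(same, config.base_within, config.base_between)
    np.fill_diagonal(base, 1.0)

    iu, ju = np.triu_indices(s, k=1)
    between = ~same[iu, ju]
    pool = np.flatnonzero(between)
    if pool.size < config.n_planted:
        pool = np.arange(iu.size)
    # prefer seed-disjoint pairs: the planted perturbation then has
    # eigenvalues exactly ±effect_size, keeping both matrices SPD as
    # long as the block baseline is comfortably positive definite
    shuffled = rng.permutation(pool)
    chosen_list: list[int] = []
    used: set[int] = set()
    for k in shuffled:
        if iu[k] not in used and ju[k] not in used:
            chosen_list.append(int(k))
            used.update((int(iu[k]), int(ju[k])))
        if len(chosen_list) == config.n_planted:
            break
    if len(chosen_list) < config.n_planted:  # too many pairs to stay disjoint
        remaining = [int(k) for k in shuffled if int(k) not in chosen_list]
        chosen_list.extend(remaining[: config.n_planted - len(chosen_list)])
    chosen = np.sort(np.array(chosen_list, dtype=int))

    cov_pre = base.copy()
    cov_post = base.copy()
    planted: list[tuple[int, int, float]] = []
    for k in chosen:
        i, j = int(iu[k]), int(ju[k])
        new = cov_pre[i, j] + config.effect_size
        if not abs(new) < 1:
            raise ValueError(f"planted effect pushes correlation ({i},{j}) to {new}, outside (-1,1)")
        cov_post[i, j] = cov_post[j, i] = new
        planted.append((i, j, config.effect_size))

    _check_spd(cov_pre, "pre-stage covariance")
    _check_spd(cov_post, "post-stage covariance")
    return cov_pre, cov_post, planted


def _band_limited_noise(
    rng: np.random.Generator, t: int, s: int, config: CohortConfig
) -> np.ndarray:
    """T×S matrix of independent band-limited unit-variance series."""
    fs = 1.0 / config.tr_seconds
    sos = signal.butter(4, config.band_hz, btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal((t + 2 * _FILTER_PAD, s))
    colored = signal.sosfiltfilt(sos, white, axis=0)[_FILTER_PAD:-_FILTER_PAD]
    sd = colored.std(axis=0)
    return colored / sd


def generate_cohort(
    config: CohortConfig,
    atlas: SeedAtlas,
) -> tuple[dict[tuple[str, str], np.ndarray], SyntheticTruth]:
    """Per-participant, per-stage T×S series plus ground truth.

    Outlier injection (``outlier_rate`` > 0) operates on FC values, not
    on the series, and is therefore applied by :func:`cohort_fc`; the
    truth object returned here has an empty outlier log until then.
    """
    rng = np.random.default_rng(config.rng_seed)
    cov_pre, cov_post, planted = build_stage_covariances(config, atlas, rng)
    chol = {"pre": np.linalg.cholesky(cov_pre), "post": np.linalg.cholesky(cov_post)}

    series: dict[tuple[str, str], np.ndarray] = {}
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        for stage in ("pre", "post"):
            z = _band_limited_noise(rng, config.n_timepoints, config.n_seeds, config)
            x = z @ chol[stage].T
            if config.noise_sd > 0:
                x = x + config.noise_sd * rng.standard_normal(x.shape)
            series[(pid, stage)] = x
    truth = SyntheticTruth(planted_pairs=planted, cov_pre=cov_pre, cov_post=cov_post)
    return series, truth


def cohort_fc(
    config: CohortConfig,
    atlas: SeedAtlas,
) -> tuple[np.ndarray, np.ndarray, list[str], SyntheticTruth]:
    """Generate a cohort and return group FC matrices.

    Returns ``(X_pre, X_post, participants, truth)`` where each X is an
    n_participants × C(n_seeds, 2) matrix of FC vectors (participants in
    row order).  When ``outlier_rate`` > 0, that fraction of entries in
    each stage matrix is replaced by extreme values (±0.999, a
    correlation far outside the sampling spread of any smooth feature)
    and logged in ``truth.injected_outliers``.
    """
    series, truth = generate_cohort(config, atlas)
    participants = sorted({pid for pid, _ in series})
    stacks = {}
    for stage in ("pre", "post"):
        stacks[stage] = np.vstack(
            [vectorize_unique(correlation_matrix(series[(pid, stage)])) for pid in participants]
        )
    if config.outlier_rate > 0:
        # separate stream so the series draw is unaffected by the rate
        rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 7)))
        for stage in ("pre", "post"):
            x = stacks[stage]
            mask = rng.random(x.shape) < config.outlier_rate
            rows, cols = np.nonzero(mask)
            x[rows, cols] = 0.999 * np.where(rng.random(rows.size) < 0.5, -1.0, 1.0)
            truth.injected_outliers.extend(
                (participants[r], stage, int(c)) for r, c in zip(rows, cols)
            )
    return stacks["pre"], stacks["post"], participants, truth


def write_cohort(
    series: dict[tuple[str, str], np.ndarray],
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> Path:
    """Write series TSVs, a cohort manifest, and the ground-truth JSON.

    Returns the manifest path.  Manifest columns: participant_id, stage,
    path (relative to the manifest's directory).
    """
    from .connectivity import write_series_tsv  # local import to avoid cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (pid, stage), x in sorted(series.items()):
        rel = f"{pid}_{stage}.tsv"
        write_series_tsv(x, out / rel)
        rows.append(f"{pid}\t{stage}\t{rel}")
    manifest = out / "manifest.tsv"
    manifest.write_text("participant_id\tstage\tpath\n" + "\n".join(rows) + "\n")
    truth.to_json(out / "truth.json")
    return manifest
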