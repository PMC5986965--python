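"""End-to-end orchestration: cohort → FC → selection → SVM → attribution.

A :class:`RunConfig` fully determines a run (together with the input
data); :func:`run_pipeline` executes the declared chain, writes every
artifact under the output directory, and returns a :class:`RunReport`
whose JSON form is byte-identical across reruns with the same config
and seed (modulo the recorded wall time).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import SeedAtlas, default_atlas, load_atlas
from .attribution import (
    connection_weights,
    direction_partition,
    network_involvement,
    seed_weights,
    write_edge_file,
)
from .classify import SvmHyperparams, bayes_optimize, loocv_by_participant, train_svm, PRE, POST
from .connectivity import correlation_matrix, n_unique_pairs, read_series_tsv, vectorize_unique
from .features import FeatureChain
from .synthetic import CohortConfig, cohort_fc

log = logging.getLogger("fcstage")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "feature_count_table", "load_manifest"]


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the study-anchored values."""

    manifest: str | None = None  # cohort manifest TSV; None → synthetic cohort
    atlas_path: str | None = None  # None → packaged default (real data) / synthetic atlas
    out_dir: str = "results/run"
    mode: str = "pooled"  # or "nested"
    alpha: float = 0.05
    alpha_ks: float = 0.05
    mad_multiplier: float = 3.0
    mad_scale: float = 1.4826
    variance_threshold: float = 0.85
    use_ks_filter: bool = True
    fdr: bool = False
    fisher_z: bool = False
    optimize: bool = False
    bo_iters: int = 30
    cost: float = 1.0
    kernel_scale: float = 1.0
    cost_range: tuple[float, float] = (1e-3, 1e3)
    scale_range: tuple[float, float] = (1e-3, 1e3)
    weighting_mode: str = "loading_magnitude"
    magnitude_direction: bool = False
    rng_seed: int = 0
    synthetic: CohortConfig | None = None

    def validate(self) -> None:
        if self.mode not in ("pooled", "nested"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("alpha", "alpha_ks"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.mad_multiplier <= 0 or self.mad_scale <= 0:
            raise ValueError("MAD multiplier and scale must be positive")
        if self.manifest is None and self.synthetic is None:
            raise ValueError("either a cohort manifest or a synthetic config is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "band_hz" in syn:
                syn["band_hz"] = tuple(syn["band_hz"])
            cfg.synthetic = CohortConfig(**syn)
        for name in ("cost_range", "scale_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
        return d


@dataclass
class RunReport:
    config: dict
    feature_counts: dict[str, int]
    cv: dict
    attribution_summary: dict
    version: str = __version__
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "feature_counts": self.feature_counts,
            "cv": self.cv,
            "attribution_summary": self.attribution_summary,
            "wall_time_s": self.wall_time_s,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def load_manifest(manifest: str | Path) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Read a cohort manifest and build the group FC matrices.

    Returns (X_pre, X_post, participants, n_seeds).  Errors if any
    participant is missing a stage.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest, sep="\t")
    records: dict[tuple[str, str], np.ndarray] = {}
    for _, row in df.iterrows():
        series = read_series_tsv(manifest.parent / row["path"])
        records[(str(row["participant_id"]), str(row["stage"]))] = vectorize_unique(
            correlation_matrix(series)
        )
    participants = sorted({pid for pid, _ in records})
    for pid in participants:
        for stage in (PRE, POST):
            if (pid, stage) not in records:
                raise ValueError(f"participant {pid} is missing the {stage} stage")
    x_pre = np.vstack([records[(pid, PRE)] for pid in participants])
    x_post = np.vstack([records[(pid, POST)] for pid in participants])
    p = x_pre.shape[1]
    s = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    return x_pre, x_post, participants, s


def _resolve_inputs(config: RunConfig):
    if config.manifest is not None:
        x_pre, x_post, participants, s = load_manifest(config.manifest)
        atlas = (
            load_atlas(config.atlas_path) if config.atlas_path else default_atlas()
        )
        if atlas.n_seeds != s:
            raise ValueError(f"atlas has {atlas.n_seeds} seeds but data implies {s}")
        return x_pre, x_post, participants, atlas
    syn = config.synthetic
    if config.atlas_path:
        atlas = load_atlas(config.atlas_path)
    else:
        from .synthetic import toy_atlas

        atlas = toy_atlas(syn.n_seeds)
    x_pre, x_post, participants, truth = cohort_fc(syn, atlas)
    return x_pre, x_post, participants, atlas


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain and write all artifacts under out_dir."""
    config.validate()
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    x_pre, x_post, participants, atlas = _resolve_inputs(config)
    if config.fisher_z:
        from .connectivity import fisher_z

        x_pre = fisher_z(x_pre, clamp=True)
        x_post = fisher_z(x_post, clamp=True)
    s = atlas.n_seeds
    p_original = n_unique_pairs(s)
    log.info("cohort: %d participants, %d seeds, %d FC features",
             len(participants), s, p_original)

    def chain_factory() -> FeatureChain:
        return FeatureChain(
            alpha=config.alpha,
            alpha_ks=config.alpha_ks,
            mad_multiplier=config.mad_multiplier,
            mad_scale=config.mad_scale,
            variance_threshold=config.variance_threshold,
            use_ks_filter=config.use_ks_filter,
            fdr=config.fdr,
        )

    # reporting chain (fit on the full cohort) — this is also the CV chain
    # in pooled mode; nested CV refits its own per fold
    chain = chain_factory().fit(x_pre, x_post)
    chain.to_json(out / "feature_chain.json")

    hp = SvmHyperparams(cost=config.cost, kernel_scale=config.kernel_scale)
    bo_trace = None
    if config.optimize:
        hp, bo_trace = bayes_optimize(
            x_pre, x_post, participants,
            n_iter=config.bo_iters,
            cost_range=config.cost_range,
            scale_range=config.scale_range,
            rng_seed=config.rng_seed,
            mode=config.mode,
            chain_factory=chain_factory,
        )
        log.info("optimized hyperparameters: cost=%.4g kernel_scale=%.4g", hp.cost, hp.kernel_scale)

    cv = loocv_by_participant(
        x_pre, x_post, participants, hp=hp, mode=config.mode,
        chain=chain if config.mode == "pooled" else None,
        chain_factory=chain_factory,
    )
    log.info("%s LOOCV accuracy %.3f (AUC %.3f)", config.mode, cv.accuracy, cv.auc)
    (out / "cv_report.json").write_text(json.dumps(cv.to_dict(), indent=1))
    if bo_trace is not None:
        (out / "bo_trace.json").write_text(json.dumps(
            [{"cost": t[0].cost, "kernel_scale": t[0].kernel_scale, "cv_error": t[1]}
             for t in bo_trace], indent=1))

    # attribution on the full-cohort fit
    selected = chain.selection.selected_indices
    final_scores = np.vstack([chain.transform(x_pre), chain.transform(x_post)])
    final_labels = [PRE] * len(participants) + [POST] * len(participants)
    final_model = train_svm(final_scores, final_labels, hp)
    conn = connection_weights(
        chain.basis, selected, s,
        model=final_model, mode=config.weighting_mode,
    )
    seeds_tab = seed_weights(conn, atlas)
    part = direction_partition(
        x_pre, x_post, selected, atlas, magnitude=config.magnitude_direction
    )
    involvement_raw = network_involvement(selected, atlas, normalize=False)
    involvement_norm = network_involvement(selected, atlas, normalize=True)

    conn_frame = conn.as_frame(atlas)
    conn_frame["direction"] = part.direction
    conn_frame["class"] = np.where(part.motor, "motor", "non-motor")
    conn_frame.to_csv(out / "connection_weights.tsv", sep="\t", index=False)
    seeds_tab.as_frame(atlas).to_csv(out / "seed_weights.tsv", sep="\t", index=False)
    part.summary().to_csv(out / "direction_partition.tsv", sep="\t")
    pd.DataFrame(
        {"network": list(involvement_raw), "raw": list(involvement_raw.values()),
         "normalized": [involvement_norm[n] for n in involvement_raw]}
    ).to_csv(out / "network_involvement.tsv", sep="\t", index=False)

    from .atlas import write_node_file

    sizes = seeds_tab.cumulative_weight
    write_node_file(atlas, out / "seeds.node",
                    sizes=sizes if sizes.max() > 0 else None)
    write_edge_file(conn, part.direction, s, out / "connections.edge")

    feature_counts = {
        "original": int(p_original),
        "after_outlier_removal": int(chain.screen.retained_indices.size),
        "after_univariate_filtering": int(selected.size),
        "after_pca": int(chain.basis.variance_fractions.size),
        "chosen_components": int(chain.basis.n_components_kept),
    }
    report = RunReport(
        config=config.echo(),
        feature_counts=feature_counts,
        cv=cv.to_dict(),
        attribution_summary={
            "direction_partition": part.counts.tolist(),
            "n_selected": int(selected.size),
            "network_involvement_raw": involvement_raw,
            "network_involvement_normalized": involvement_norm,
            "top_seeds": seeds_tab.as_frame(atlas).head(10).to_dict(orient="records"),
        },
        wall_time_s=round(time.perf_counter() - t0, 3),
    )
    report.to_json(out / "run_report.json")
    return report


def feature_count_table(report: RunReport) -> pd.DataFrame:
    """Staged feature-count table (original → chosen components)."""
    fc = report.feature_counts
    return pd.DataFrame(
        {
            "analysis_step": [
                "Original features",
                "After outlier removal",
                "After univariate filtering",
                "After principal component analysis",
                "Chosen principal components for classification",
            ],
            "n_features": [
                fc["original"],
                fc["after_outlier_removal"],
                fc["after_univariate_filtering"],
                fc["after_pca"],
                fc["chosen_components"],
            ],
            "feature_space": ["rs-FC", "rs-FC", "rs-FC", "reduced", "reduced"],
        }
    )
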