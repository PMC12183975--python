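"""Single configuration schema and the seeded end-to-end pipeline driver.

One YAML file describes a whole run — synthetic cohort, backbone, training,
screening, scoring and statistics — and every source of randomness flows from
``master_seed`` through named per-stage sub-seeds, so any stage can be rerun
in isolation and two full runs with the same config are byte-identical.

Stage order: simulate -> screen -> train -> score -> metrics -> stats.
Each stage reads only the declared artifacts of earlier stages from the run
directory, and writes its own artifacts plus a line in the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn, pi, screening, stats, synthetic, volumes
from ._seeds import derive_seed

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "screen", "train", "score", "metrics", "stats")


class ConfigError(ValueError):
    """Invalid pipeline configuration (field-level message)."""


@dataclass
class PipelineConfig:
    out_dir: Path
    master_seed: int = 0
    # data sources; simulate fills atlas/manifest when absent
    atlas: Path | None = None
    manifest: Path | None = None
    covariates: Path | None = None
    # backbone / patches
    channels: tuple[int, ...] = (16, 32, 64, 64, 64)
    patch_size: int = 32
    standardize: bool = True
    # training
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 10
    validation_fraction: float = 0.2
    # screening
    candidate_labels: list[int] | None = None
    k: int = 10
    screen_contrast: str = "composite"
    # synthetic cohort
    shape: tuple[int, int, int] = (48, 48, 48)
    n_rois: int = 30
    roi_radius: int = 4
    informative_labels: tuple[int, ...] = (1, 2, 3)
    intensity_shift: float = 0.5
    erosion_fraction: float = 0.1
    noise_sd: float = 0.2
    n_per_group: dict = field(default_factory=lambda: {"pNC": 20, "sNC": 20})
    # statistics
    pi_scale: float = 100.0
    n_boot: int = 2000
    models: dict = field(default_factory=dict)  # name -> list of covariate cols

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("config field 'out_dir' is required")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("atlas", "manifest", "covariates"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        self.channels = tuple(int(c) for c in self.channels)
        self.shape = tuple(int(s) for s in self.shape)
        self.informative_labels = tuple(int(i) for i in self.informative_labels)

    def validate(self) -> None:
        def bad(msg):
            raise ConfigError(msg)
        if self.k < 1:
            bad(f"screen.k must be >= 1, got {self.k}")
        if self.candidate_labels is not None:
            if self.k > len(self.candidate_labels):
                bad(f"k={self.k} exceeds the {len(self.candidate_labels)} "
                    f"candidate ROIs")
        elif self.manifest is None and self.k > self.n_rois:
            bad(f"k={self.k} exceeds the {self.n_rois} synthetic ROIs")
        if self.patch_size < 2 ** (len(self.channels) - 1):
            bad(f"patch_size {self.patch_size} cannot survive "
                f"{len(self.channels) - 1} stride-2 pools")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            bad("epochs, batch_size and learning_rate must be positive")
        if not 0 < self.validation_fraction < 1:
            bad("validation_fraction must be in (0, 1)")
        if self.screen_contrast not in ("composite", "ad_vs_nc"):
            bad("screen_contrast must be 'composite' or 'ad_vs_nc'")
        if self.noise_sd < 0 or not 0 <= self.erosion_fraction < 1:
            bad("noise_sd must be >= 0 and erosion_fraction in [0, 1)")
        bad_tags = [t for t in self.n_per_group
                    if t != "AD" and t[:1] not in ("p", "s", "r")]
        if bad_tags:
            bad(f"unrecognized group tag(s): {bad_tags}")

    def config_hash(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:16]

    # -- derived pieces ---------------------------------------------------

    def backbone_spec(self) -> nn.BackboneSpec:
        return nn.BackboneSpec(channels=self.channels)

    def train_config(self, stage: str) -> nn.TrainConfig:
        return nn.TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, validation_fraction=self.validation_fraction,
            seed=derive_seed(self.master_seed, stage))

    def effect_spec(self) -> synthetic.EffectSpec:
        return synthetic.EffectSpec(
            informative_labels=frozenset(self.informative_labels),
            intensity_shift=self.intensity_shift,
            erosion_fraction=self.erosion_fraction,
            noise_sd=self.noise_sd)

    # -- artifact paths ---------------------------------------------------

    @property
    def cohort_dir(self) -> Path:
        return self.out_dir / "cohort"

    def artifact(self, name: str) -> Path:
        return self.out_dir / name

    def atlas_path(self) -> Path:
        if self.atlas is not None:
            return self.atlas
        return self.cohort_dir / "atlas.nii"

    def manifest_path(self) -> Path:
        if self.manifest is not None:
            return self.manifest
        return self.cohort_dir / "manifest.csv"


class _RunLog:
    def __init__(self, cfg: PipelineConfig):
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        self.path = cfg.out_dir / "run.log"
        self.write(f"config_hash={cfg.config_hash()} "
                   f"master_seed={cfg.master_seed}")

    def write(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp} {msg}\n")


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{produced_by}' stage first")
    return path


def _stage_simulate(cfg: PipelineConfig, log: _RunLog) -> None:
    man = synthetic.simulate_cohort(
        out_dir=cfg.cohort_dir, shape=cfg.shape, n_rois=cfg.n_rois,
        effect=cfg.effect_spec(), n_per_group=cfg.n_per_group,
        roi_radius=cfg.roi_radius,
        seed=derive_seed(cfg.master_seed, "simulate"))
    log.write(f"simulate: {len(man.records)} subjects -> {cfg.cohort_dir}")


def _stage_screen(cfg: PipelineConfig, log: _RunLog) -> None:
    atlas = volumes.load_label_volume(_require(cfg.atlas_path(), "simulate"))
    manifest = volumes.read_manifest(_require(cfg.manifest_path(), "simulate"))
    table = screening.screen_rois(
        manifest, atlas, candidate_labels=cfg.candidate_labels,
        spec=cfg.backbone_spec(), cfg=cfg.train_config("screen"),
        patch_size=cfg.patch_size, standardize=cfg.standardize,
        screen_contrast=cfg.screen_contrast)
    ranking = screening.rank_rois(table, k=cfg.k)
    # AAL names only make sense for a user-supplied atlas, not phantoms
    lookup = volumes.load_aal116_lookup() if cfg.atlas is not None else None
    table.save_csv(cfg.artifact("auc_table.csv"), lookup=lookup)
    ranking.save_json(cfg.artifact("ranking.json"))
    log.write(f"screen: {len(table.entries)} ROIs, selected {ranking.selected}")


def _stage_train(cfg: PipelineConfig, log: _RunLog) -> None:
    atlas = volumes.load_label_volume(_require(cfg.atlas_path(), "simulate"))
    manifest = volumes.read_manifest(_require(cfg.manifest_path(), "simulate"))
    ranking = screening.ROIRanking.load_json(
        _require(cfg.artifact("ranking.json"), "screen"))
    tc = cfg.train_config("train")
    model, report = pi.train_mrnet(
        manifest, atlas, ranking, spec=cfg.backbone_spec(), cfg=tc,
        patch_size=cfg.patch_size, standardize=cfg.standardize)
    nn.save_model(model, cfg.artifact("mrnet.npz"), train_config=tc)
    with open(cfg.artifact("train_report.json"), "w") as fh:
        json.dump({"train_loss": report.train_loss,
                   "val_loss": report.val_loss, "val_auc": report.val_auc,
                   "n_train": report.n_train, "n_val": report.n_val}, fh,
                  indent=2)
    log.write(f"train: val_auc={report.val_auc:.4f}")


def _stage_score(cfg: PipelineConfig, log: _RunLog) -> None:
    atlas = volumes.load_label_volume(_require(cfg.atlas_path(), "simulate"))
    manifest = volumes.read_manifest(_require(cfg.manifest_path(), "simulate"))
    model = nn.load_model(_require(cfg.artifact("mrnet.npz"), "train"))
    table = pi.score_cohort(model, manifest, atlas, patch_size=cfg.patch_size,
                            standardize=cfg.standardize)
    table.to_csv(cfg.artifact("pi_table.csv"), index=False)
    pi.stage_sorted_table(table).to_csv(cfg.artifact("stage_plot.csv"),
                                        index=False)
    log.write(f"score: {len(table)} subjects")


def _read_pi_table(cfg: PipelineConfig) -> pd.DataFrame:
    df = pd.read_csv(_require(cfg.artifact("pi_table.csv"), "score"))
    df["label"] = pd.array(
        [pd.NA if pd.isna(v) else int(v) for v in df["label"]], dtype="Int64")
    return df


def _stage_metrics(cfg: PipelineConfig, log: _RunLog) -> None:
    table = _read_pi_table(cfg)
    m = pi.threshold_metrics(table, threshold_mode="overall_mean")
    pi.save_metrics_json(m, cfg.artifact("metrics.json"))
    log.write(f"metrics: auc={m.auc:.4f} sen={m.sensitivity:.4f} "
              f"spe={m.specificity:.4f} thr={m.threshold:.4f}")


def _stage_stats(cfg: PipelineConfig, log: _RunLog) -> None:
    table = _read_pi_table(cfg)
    cov = None
    if cfg.covariates is not None:
        cov = pd.read_csv(_require(cfg.covariates, "user-supplied covariates"))
    out: dict = {"pi_scale": cfg.pi_scale}
    gs = stats.group_pi_summary(table)
    out["group_summary"] = {
        "per_group": gs.per_group.to_dict(orient="records"),
        "contrast_coef": gs.contrast_coef, "statistic": gs.statistic,
        "pvalue": gs.pvalue}
    known = table[table["label"].notna() & table["pi"].notna()].copy()
    known["outcome"] = known["label"].astype(int)
    pi_term = f"pi_x{cfg.pi_scale:g}"
    known[pi_term] = known["pi"] * cfg.pi_scale
    seed = derive_seed(cfg.master_seed, "stats")
    out["unadjusted"] = stats.fit_logistic(known, "outcome", [pi_term]).to_dict()
    roc = stats.roc_with_ci(known["pi"].to_numpy(),
                            known["outcome"].to_numpy(),
                            n_boot=cfg.n_boot, seed=seed)
    roc.curve_frame().to_csv(cfg.artifact("roc_pi.csv"), index=False)
    out["roc_pi"] = roc.to_dict()
    if cov is not None:
        for name, terms in (cfg.models or {}).items():
            fit, roc_m = stats.combined_model_eval(
                table, cov, list(terms), n_boot=cfg.n_boot,
                seed=derive_seed(seed, name), pi_scale=cfg.pi_scale)
            out[name] = {"logistic": fit.to_dict(), "roc": roc_m.to_dict()}
            roc_m.curve_frame().to_csv(cfg.artifact(f"roc_{name}.csv"),
                                       index=False)
    with open(cfg.artifact("stats.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    log.write("stats: written stats.json")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "train": _stage_train,
    "score": _stage_score,
    "metrics": _stage_metrics,
    "stats": _stage_stats,
}


def run_pipeline(config: PipelineConfig | str | Path,
                 stage: str = "all") -> Path:
    """Execute one stage or the whole pipeline; returns the run directory."""
    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig.from_yaml(config))
    cfg.validate()
    if stage != "all" and stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from "
                          f"{('all',) + STAGES}")
    log = _RunLog(cfg)
    todo = STAGES if stage == "all" else (stage,)
    if stage == "all" and cfg.manifest is not None:
        todo = tuple(s for s in todo if s != "simulate")
    for s in todo:
        _STAGE_FNS[s](cfg, log)
    return cfg.out_dir
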