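"""The package's standard synthetic benchmark: study conditions and runners.

A fixed phantom-cohort configuration exercises the whole two-step pipeline at
desk scale: 48^3 volumes carrying 30 spherical ROIs (radius 4) of which the
first three are informative, an atrophy effect of intensity shift 0.5 with
10% boundary erosion, Gaussian noise SD 0.2, and 100 subjects per class. The
screening/scoring networks use the reduced backbone (channels 4-8-16-16-16)
on 16^3 centroid patches, which preserves the architecture's structure (five
3^3 conv layers, four stride-2 pools, global average pool) at a fraction of
the full 32^3 compute.

Patch windows (16^3) are wider than the spheres (radius 4), so a patch
centred on a non-informative ROI that happens to neighbour an informative
one can see part of the planted signal — the same spillover a real atlas
patch has over adjacent parcels. Recovery is therefore judged by whether the
planted ROIs reach the top of the ranking, not by uninformative regions
staying exactly at chance in a signal cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .nn import BackboneSpec, TrainConfig
from .screening import AUCTable, ROIRanking, rank_rois, screen_rois
from .synthetic import EffectSpec, PatchCohort, simulate_patch_cohort

__all__ = [
    "SHAPE", "N_ROIS", "ROI_RADIUS", "INFORMATIVE", "PATCH_SIZE",
    "N_PER_CLASS", "benchmark_effect", "null_effect", "benchmark_spec",
    "screening_train_config", "mrnet_train_config", "benchmark_cohort",
    "run_screen",
]

SHAPE = (48, 48, 48)
N_ROIS = 30
ROI_RADIUS = 4
INFORMATIVE = (1, 2, 3)
PATCH_SIZE = 16
N_PER_CLASS = 100
INTENSITY_SHIFT = 0.5
EROSION_FRACTION = 0.1
NOISE_SD = 0.2


def benchmark_effect(intensity_shift: float = INTENSITY_SHIFT,
                     erosion_fraction: float = EROSION_FRACTION,
                     noise_sd: float = NOISE_SD) -> EffectSpec:
    return EffectSpec(informative_labels=frozenset(INFORMATIVE),
                      intensity_shift=intensity_shift,
                      erosion_fraction=erosion_fraction, noise_sd=noise_sd)


def null_effect(noise_sd: float = NOISE_SD) -> EffectSpec:
    """No planted signal anywhere: the two classes are exchangeable."""
    return EffectSpec(informative_labels=frozenset(), intensity_shift=0.0,
                      erosion_fraction=0.0, noise_sd=noise_sd)


def benchmark_spec() -> BackboneSpec:
    return BackboneSpec.reduced()


def screening_train_config(seed: int,
                           validation_fraction: float = 0.2) -> TrainConfig:
    """Per-ROI screening nets: 2 epochs of Adam at lr 2e-3, batch 16.

    The per-ROI contrast in the benchmark is strong, so short training
    suffices to rank regions; the settings are deliberately the same for
    signal and null cohorts.
    """
    return TrainConfig(learning_rate=2e-3, batch_size=16, epochs=2,
                       seed=seed, validation_fraction=validation_fraction)


def mrnet_train_config(seed: int) -> TrainConfig:
    """Multi-ROI stage: 6 epochs at lr 1e-3, batch 16."""
    return TrainConfig(learning_rate=1e-3, batch_size=16, epochs=6,
                       seed=seed, validation_fraction=0.2)


def benchmark_cohort(seed: int, intensity_shift: float = INTENSITY_SHIFT,
                     n_per_class: int = N_PER_CLASS,
                     noise_sd: float = NOISE_SD,
                     erosion_fraction: float = EROSION_FRACTION,
                     null: bool = False) -> PatchCohort:
    """One seeded replicate of the benchmark cohort, as in-memory patches."""
    eff = null_effect(noise_sd) if null else \
        benchmark_effect(intensity_shift, erosion_fraction, noise_sd)
    return simulate_patch_cohort(SHAPE, N_ROIS, eff, n_per_class, PATCH_SIZE,
                                 seed=seed, roi_radius=ROI_RADIUS)


def run_screen(cohort: PatchCohort, seed: int, k: int = 10,
               validation_fraction: float = 0.2
               ) -> tuple[AUCTable, ROIRanking]:
    """Screen every benchmark ROI and rank the top ``k``."""
    cfg = screening_train_config(derive_seed(seed, "screen"),
                                 validation_fraction=validation_fraction)
    table = screen_rois(cohort.manifest, cohort.atlas, cohort.roi_labels,
                        spec=benchmark_spec(), cfg=cfg,
                        patch_size=PATCH_SIZE, patches=cohort.patches)
    return table, rank_rois(table, k=k)
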