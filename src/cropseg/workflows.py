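"""End-to-end pipelines shared by the CLI, the tests and the acceptance
script: synthetic scene -> features -> tiles -> training -> stitched
prediction -> metrics, plus the controlled year-shift transfer sweep."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate, features, synthgen, tiling
from .attnseg import AttentionSegNet, NetworkConfig
from .train import TrainConfig, train


@dataclass
class ExperimentResult:
    net: AttentionSegNet
    stats: features.NormStats
    report: evaluate.MetricsReport
    history: object
    scene: synthgen.MultispectralScene
    labels: np.ndarray
    test_region: tiling.Region
    spec: tiling.TileSpec
    prediction: np.ndarray


def make_scene(height=768, width=768, seed=0, noise_sd=0.05,
               plot_size_range=(40, 80), mix_width=1):
    """Labeled synthetic scene with the default spectral library."""
    cfg = synthgen.MosaicConfig(height=height, width=width, seed=seed,
                                plot_size_range=plot_size_range,
                                mix_width=mix_width)
    labels = synthgen.generate_field_mosaic(cfg)
    lib = synthgen.default_library(noise_sd=noise_sd)
    scene = synthgen.render_reflectance(labels, lib, seed=seed + 1,
                                        mix_width=cfg.mix_width)
    return scene, labels


def run_end_to_end(seed=0, attention=True, height=768, width=768,
                   noise_sd=0.05, tile_size=64, margin=8, n_crops=80,
                   n_train=60, width_scale=0.125, epochs=12, lr=1e-3,
                   scene=None, labels=None) -> ExperimentResult:
    """Train a (reduced-width) network on a synthetic scene's training half
    and score the stitched prediction on the held-out test region."""
    if scene is None:
        scene, labels = make_scene(height, width, seed=seed, noise_sd=noise_sd)
    stack = features.build_feature_stack(scene)
    train_region, test_region = tiling.split_train_test(stack.shape, ratio=0.6, axis=0)
    # normalization statistics come from the training region only
    train_view = features.FeatureStack(
        stack.values[train_region.r0:train_region.r1,
                     train_region.c0:train_region.c1])
    stats = features.normalize_stack(train_view).stats
    stack = features.normalize_stack(stack, stats)
    spec = tiling.TileSpec(size=tile_size, margin=margin, count=n_crops,
                           train_count=n_train, val_count=n_crops - n_train,
                           seed=seed)
    tiles = tiling.sample_training_tiles(stack.values, labels, train_region, spec)
    # attention=False is the plain-SegNet analogue: no attention blocks and
    # no skip concatenations (the attention-refined skips are part of the
    # attention variant's contribution)
    net = AttentionSegNet(NetworkConfig.scaled(
        width_scale, in_channels=8, input_size=tile_size,
        attention=attention, skip_connections=attention, seed=seed))
    tcfg = TrainConfig(lr=lr, max_epochs=epochs, patience=max(2, epochs - 1),
                       seed=seed)
    net, history = train(net, tiles.arrays("train"), tiles.arrays("val"), tcfg)
    pred = evaluate.predict_region(net, stack, test_region, spec)
    truth = labels[test_region.r0:test_region.r1, test_region.c0:test_region.c1]
    report = evaluate.metrics_report(pred, truth, k=3)
    return ExperimentResult(net=net, stats=stack.stats, report=report,
                            history=history, scene=scene, labels=labels,
                            test_region=test_region, spec=spec, prediction=pred)


def transfer_sweep(result: ExperimentResult, offsets=(0.0, 0.05, 0.10)):
    """Apply growing uniform additive band offsets to the scene and re-score
    the trained model on the shifted test region (same normalization stats)."""
    reports = []
    for off in offsets:
        shift = synthgen.YearShift(gains=np.ones(6), offsets=np.full(6, off))
        shifted = synthgen.simulate_year_shift(result.scene, shift)
        rep = evaluate.cross_domain_eval(result.net, result.stats, shifted,
                                         result.labels, result.test_region,
                                         result.spec)
        reports.append(rep)
    return reports
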