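"""Herd-scale weight-estimation experiment: simulate, process, train, score.

Reproduces the evaluation protocol of the field study at simulation scale:
a herd of synthetic sows (198 by default), the full segmentation pipeline
run per scene, a 140/58 train/test split, the CNN regressor trained on the
training pigs and scored on the held-out ones, with the RBF network as the
features-only baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import SceneParams, iter_herd
from .weightnet import (
    CNNConfig, EvalMetrics, RBFWeightRegressor, CNNWeightRegressor,
    evaluate, rasterize_back,
)


@dataclass
class ExperimentResult:
    cnn_metrics: EvalMetrics
    rbf_metrics: EvalMetrics
    cnn_model: CNNWeightRegressor
    rbf_model: RBFWeightRegressor
    true_weights: np.ndarray     # test-set actual weights, kg
    cnn_predictions: np.ndarray  # kg
    rbf_predictions: np.ndarray  # kg
    features: np.ndarray         # (n_pigs, 6) extracted back features
    n_train: int


def run_weight_experiment(n_pigs: int = 198, n_train: int = 140, seed: int = 1,
                          scene_params: SceneParams | None = None,
                          pipeline_config: PipelineConfig | None = None,
                          rbf_centers: int = 40) -> ExperimentResult:
    """Full protocol: herd → pipeline per scene → train CNN + RBF → metrics.

    The train/test split takes the first ``n_train`` pigs of a seeded
    shuffle; pigs are exchangeable so this is a random split.
    """
    if not 1 <= n_train < n_pigs:
        raise ParameterError("need 1 <= n_train < n_pigs")
    scene_params = scene_params or SceneParams()
    config = pipeline_config or PipelineConfig()

    rasters, feats, weights = [], [], []
    for cloud, truth in iter_herd(n_pigs, seed=seed, params_base=scene_params):
        result = run_pipeline(cloud, config)
        raster = rasterize_back(result.cloud, config.raster_h, config.raster_w)
        rasters.append(raster.heights)
        feats.append(result.features.as_array())
        weights.append(truth.true_weight)
    rasters = np.stack(rasters)
    feats = np.stack(feats)
    weights = np.array(weights)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pigs)
    tr, te = order[:n_train], order[n_train:]

    cnn_cfg = replace(config.cnn, seed=seed,
                      raster_hw=(config.raster_h, config.raster_w))
    cnn = CNNWeightRegressor(cnn_cfg).fit(rasters[tr], feats[tr], weights[tr])
    cnn_pred = cnn.predict(rasters[te], feats[te])

    rbf = RBFWeightRegressor(min(rbf_centers, n_train), seed=seed)
    rbf.fit(feats[tr], weights[tr])
    rbf_pred = rbf.predict(feats[te])

    return ExperimentResult(
        cnn_metrics=evaluate(cnn_pred, weights[te]),
        rbf_metrics=evaluate(rbf_pred, weights[te]),
        cnn_model=cnn, rbf_model=rbf,
        true_weights=weights[te],
        cnn_predictions=cnn_pred, rbf_predictions=rbf_pred,
        features=feats, n_train=n_train,
    )
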