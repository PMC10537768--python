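"""End-to-end orchestration of the segmentation + measurement pipeline.

Stage order: statistical outlier filter → DBSCAN → pig-cluster selection →
horizontal alignment → head/tail trim at the contour notches → voxel
downsampling → back-feature extraction → (optional) rasterization and
weight prediction. Down-sampling runs after the trim so the reduced cloud
already is the back of interest. Every stage's input/output point counts
and parameters are recorded in a stage report; a failure aborts with the
stage name attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .cloud import PointCloud
from .dbscan import DBSCANParams, dbscan, select_pig_cluster
from .errors import PigbackError
from .features import BackFeatures, extract_back_features
from .segmentation import align_horizontal, split_head_tail
from .statfilter import FilterParams, statistical_filter
from .voxel import voxel_downsample
from .weightnet import CNNConfig, rasterize_back


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    sf_k: int = 30
    sf_sigma: float = 2.0
    eps: float = 0.02
    min_pts: int = 10
    cluster_min_size: int = 200
    floor_margin: float = 0.1
    voxel_size: float = 0.005
    alpha: float | None = None     # None: 3x median NN spacing
    sag_min: float = 0.03
    head_direction: str = "+x"
    raster_h: int = 64
    raster_w: int = 64
    cnn: CNNConfig = field(default_factory=CNNConfig)

    def validate(self) -> None:
        FilterParams(self.sf_k, self.sf_sigma).validate()
        DBSCANParams(self.eps, self.min_pts).validate()
        if self.voxel_size <= 0:
            raise StageError("config", "voxel_size must be positive")
        if self.sag_min <= 0:
            raise StageError("config", "sag_min must be positive")
        if self.head_direction not in ("+x", "-x"):
            raise StageError("config", "head_direction must be '+x' or '-x'")
        self.cnn.validate()

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(PigbackError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    features: BackFeatures
    weight: float | None
    report: list  # [(stage, n_in, n_out, params_dict), ...]
    cloud: PointCloud  # trimmed, aligned, downsampled back cloud


def run_pipeline(cloud: PointCloud, config: PipelineConfig | None = None,
                 model=None) -> PipelineResult:
    """Run all stages on one scene; returns features, prediction and report."""
    config = config or PipelineConfig()
    config.validate()
    report = []

    def stage(name, fn, current, **params):
        try:
            out = fn()
        except PigbackError as exc:
            raise StageError(name, exc) from exc
        n_out = len(out if isinstance(out, PointCloud) else out[0]) \
            if isinstance(out, (PointCloud, tuple)) else len(current)
        report.append((name, len(current), n_out, params))
        return out

    kept, _, _ = stage(
        "statistical_filter",
        lambda: statistical_filter(cloud, FilterParams(config.sf_k, config.sf_sigma)),
        cloud, k=config.sf_k, sigma=config.sf_sigma,
    )
    labeling = dbscan(kept, DBSCANParams(config.eps, config.min_pts))
    pig = stage(
        "select_pig_cluster",
        lambda: select_pig_cluster(kept, labeling, config.cluster_min_size,
                                   config.floor_margin),
        kept, eps=config.eps, min_pts=config.min_pts,
        min_size=config.cluster_min_size,
    )
    aligned, angle = stage(
        "align_horizontal", lambda: align_horizontal(pig), pig,
    )
    report[-1][3]["angle_deg"] = angle
    split = stage(
        "split_head_tail",
        lambda: split_head_tail(aligned, config.sag_min, config.head_direction,
                                config.alpha),
        aligned, sag_min=config.sag_min,
    )
    report[-1] = ("split_head_tail", len(aligned), len(split.cloud),
                  report[-1][3])
    down, _grid = stage(
        "voxel_downsample",
        lambda: voxel_downsample(split.cloud, config.voxel_size),
        split.cloud, r=config.voxel_size,
    )
    try:
        feats = extract_back_features(down, config.alpha, config.head_direction)
    except PigbackError as exc:
        raise StageError("extract_back_features", exc) from exc
    report.append(("extract_back_features", len(down), len(down), {}))

    weight = None
    if model is not None:
        raster = rasterize_back(down, config.raster_h, config.raster_w)
        weight = float(model.predict(raster.heights[None],
                                     feats.as_array()[None])[0])
        report.append(("predict", len(down), len(down), {}))
    return PipelineResult(feats, weight, report, down)
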