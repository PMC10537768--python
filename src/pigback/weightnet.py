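"""Weight estimation: back-height raster encoding, CNN regressor, RBF baseline.

The regressor consumes two views of the trimmed, aligned back cloud: a
height raster (mean height above the cloud's base per grid cell over the
x-y bounding rectangle) fed to a small convolutional stack, and the six
scalar back features concatenated at the first fully connected layer. The
network is written directly in numpy:

* convolution layers: valid convolution, per-filter bias, ReLU;
* down-sampling layers: mean-pooling with a learnable per-channel scale β
  and bias B applied to the pooled map, then the activation — i.e. the
  pooled response is β·down(χ) + B rather than a plain max-pool;
* fully connected layers on the flattened maps ⊕ feature vector.

Training is plain full-batch gradient descent on a mean-squared-error loss,
with raster cells, features and target all standardized (z-scored) during
fitting and restored at prediction. Everything is deterministic for a given
seed. A features-only mode (no conv stack) is available for ablation.

The Gaussian radial-basis-function network baseline uses seeded random
training points as centers, a shared width set to the median pairwise center
distance, and output weights solved by linear least squares.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist

from .cloud import PointCloud
from .errors import ConfigError, DivergenceError, ParameterError


# ---------------------------------------------------------------------------
# Raster encoding
# ---------------------------------------------------------------------------

@dataclass
class BackRaster:
    """H×W grid of mean heights (m, relative to the cloud's lowest point)."""

    heights: np.ndarray  # (H, W), empty cells 0
    counts: np.ndarray   # (H, W) points per cell


def rasterize_back(cloud: PointCloud, H: int = 64, W: int = 64) -> BackRaster:
    """Bin the cloud onto an H×W grid spanning its x-y bounding rectangle.

    Rows index y, columns index x; each occupied cell holds the mean height
    of its points relative to the cloud minimum z.
    """
    if H < 4 or W < 4:
        raise ParameterError("raster dimensions must be at least 4x4")
    if len(cloud) == 0:
        raise ParameterError("cannot rasterize an empty cloud")
    pts = cloud.points
    z = pts[:, 2] - pts[:, 2].min()

    def bin_idx(coord, n):
        span = np.ptp(coord)
        if span == 0:
            return np.zeros(len(coord), dtype=np.int64)
        i = np.floor((coord - coord.min()) / span * n).astype(np.int64)
        return np.minimum(i, n - 1)

    iy = bin_idx(pts[:, 1], H)
    ix = bin_idx(pts[:, 0], W)
    flat = iy * W + ix
    counts = np.bincount(flat, minlength=H * W)
    sums = np.bincount(flat, weights=z, minlength=H * W)
    heights = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return BackRaster(heights.reshape(H, W), counts.reshape(H, W))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    mae: float   # kg
    mape: float  # %
    rmse: float  # kg

    def to_json(self, path) -> None:
        payload = {"mae_kg": self.mae, "mape_pct": self.mape, "rmse_kg": self.rmse}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def evaluate(estimates, actuals) -> EvalMetrics:
    """MAE (kg), MAPE (%), RMSE (kg) between estimated and actual weights."""
    p = np.asarray(estimates, dtype=float)
    r = np.asarray(actuals, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or len(p) == 0:
        raise ParameterError("estimates and actuals must be equal-length 1D")
    if np.any(r == 0):
        raise ParameterError("MAPE undefined: an actual weight is zero")
    err = p - r
    return EvalMetrics(
        mae=float(np.mean(np.abs(err))),
        mape=float(np.mean(np.abs(err) / np.abs(r)) * 100.0),
        rmse=float(np.sqrt(np.mean(err ** 2))),
    )


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

@dataclass
class CNNConfig:
    conv_filters: tuple = (8, 16)  # filters per conv layer
    kernel_size: int = 3
    pool_size: int = 2
    fc_widths: tuple = (64,)       # hidden fully connected widths
    activation: str = "relu"       # relu | linear
    learning_rate: float = 0.01
    epochs: int = 250
    seed: int = 0
    features_only: bool = False    # ablation: drop the conv stack
    raster_hw: tuple = (64, 64)

    def validate(self) -> None:
        if not self.features_only and len(self.conv_filters) < 1:
            raise ConfigError("need at least one conv layer (or features_only)")
        if len(self.fc_widths) < 1:
            raise ConfigError("need at least one fully connected layer")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.activation not in ("relu", "linear"):
            raise ConfigError(f"unsupported activation {self.activation!r}")
        if self.kernel_size < 1 or self.pool_size < 1:
            raise ConfigError("kernel and pool sizes must be >= 1")


def _act(u, kind):
    return np.maximum(u, 0.0) if kind == "relu" else u


def _act_grad(u, kind):
    return (u > 0).astype(u.dtype) if kind == "relu" else np.ones_like(u)


def _im2col(x, k):
    # x (N,C,H,W) -> (N, H', W', C*k*k) with H' = H-k+1
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,H',W',k,k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    n, hh, ww = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, hh, ww, -1)


class CNNWeightRegressor:
    """Convolutional weight regressor trained by full-batch gradient descent.

    Call :meth:`fit` with rasters of shape (N, H, W), features (N, 6) and
    weights (N,); then :meth:`predict`. ``loss_history_`` holds the
    standardized-scale MSE per epoch.
    """

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        self.config.validate()
        self.params: dict[str, np.ndarray] = {}
        self.norms_: dict[str, float] | None = None
        self.loss_history_: list[float] = []

    # -- architecture ------------------------------------------------------

    def _init_params(self, n_features: int):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        P = {}
        if not cfg.features_only:
            c_in = 1
            h, w = cfg.raster_hw
            for li, f in enumerate(cfg.conv_filters):
                k = cfg.kernel_size
                fan_in = c_in * k * k
                P[f"W{li}"] = rng.normal(0, np.sqrt(2 / fan_in),
                                         (f, c_in, k, k)).astype(np.float32)
                P[f"b{li}"] = np.zeros(f, dtype=np.float32)
                P[f"beta{li}"] = np.ones(f, dtype=np.float32)
                P[f"B{li}"] = np.zeros(f, dtype=np.float32)
                h = (h - k + 1) // cfg.pool_size
                w = (w - k + 1) // cfg.pool_size
                if h < 1 or w < 1:
                    raise ConfigError("raster too small for the conv stack")
                c_in = f
            flat = c_in * h * w
        else:
            flat = 0
        dim = flat + n_features
        for fi, width in enumerate(cfg.fc_widths):
            P[f"FW{fi}"] = rng.normal(0, np.sqrt(2 / dim),
                                      (dim, width)).astype(np.float32)
            P[f"Fb{fi}"] = np.zeros(width, dtype=np.float32)
            dim = width
        P["OW"] = rng.normal(0, np.sqrt(1 / dim), (dim, 1)).astype(np.float32)
        P["Ob"] = np.zeros(1, dtype=np.float32)
        self.params = P

    # -- forward / backward ------------------------------------------------

    def _forward(self, rasters, feats, cache=None):
        cfg, P = self.config, self.params
        act = cfg.activation
        x = feats
        if not cfg.features_only:
            a = rasters[:, None, :, :]  # (N,1,H,W)
            for li in range(len(cfg.conv_filters)):
                k, p = cfg.kernel_size, cfg.pool_size
                cols = _im2col(a, k)
                wmat = P[f"W{li}"].reshape(len(P[f"W{li}"]), -1)
                u = cols @ wmat.T + P[f"b{li}"]     # (N,H',W',F)
                conv = _act(u, act)
                n, hh, ww, f = conv.shape
                hc, wc = (hh // p) * p, (ww // p) * p
                blocks = conv[:, :hc, :wc].reshape(n, hc // p, p, wc // p, p, f)
                pooled = blocks.mean(axis=(2, 4))    # (N,Hp,Wp,F)
                up = P[f"beta{li}"] * pooled + P[f"B{li}"]
                a2 = _act(up, act)
                if cache is not None:
                    cache.append((a, cols, u, conv, pooled, up, (hh, ww)))
                a = a2.transpose(0, 3, 1, 2)        # back to (N,F,Hp,Wp)
            flat = a.reshape(len(a), -1)
            x = np.concatenate([flat, feats], axis=1)
            if cache is not None:
                cache.append(("concat", a.shape, flat.shape[1]))
        fcs = []
        for fi in range(len(cfg.fc_widths)):
            u = x @ P[f"FW{fi}"] + P[f"Fb{fi}"]
            x_new = _act(u, act)
            fcs.append((x, u))
            x = x_new
        out = x @ P["OW"] + P["Ob"]
        if cache is not None:
            cache.append(("fc", fcs, x))
        return out[:, 0]

    def _backward(self, rasters, feats, dout, cache):
        cfg, P = self.config, self.params
        act = cfg.activation
        grads = {}
        tag, fcs, x_last = cache.pop()
        assert tag == "fc"
        grads["OW"] = x_last.T @ dout[:, None]
        grads["Ob"] = dout.sum(keepdims=True)
        dx = dout[:, None] @ P["OW"].T
        for fi in reversed(range(len(cfg.fc_widths))):
            x_in, u = fcs[fi]
            du = dx * _act_grad(u, act)
            grads[f"FW{fi}"] = x_in.T @ du
            grads[f"Fb{fi}"] = du.sum(axis=0)
            dx = du @ P[f"FW{fi}"].T
        if cfg.features_only:
            return grads
        tag, a_shape, flat_dim = cache.pop()
        assert tag == "concat"
        dflat = dx[:, :flat_dim]
        da = dflat.reshape(a_shape)            # (N,F,Hp,Wp)
        for li in reversed(range(len(cfg.conv_filters))):
            a_in, cols, u, conv, pooled, up, (hh, ww) = cache.pop()
            k, p = cfg.kernel_size, cfg.pool_size
            dup = da.transpose(0, 2, 3, 1) * _act_grad(up, act)  # (N,Hp,Wp,F)
            grads[f"beta{li}"] = (dup * pooled).sum(axis=(0, 1, 2))
            grads[f"B{li}"] = dup.sum(axis=(0, 1, 2))
            dpool = dup * P[f"beta{li}"]
            n, hp, wp, f = dpool.shape
            dconv = np.zeros_like(conv)
            spread = np.repeat(np.repeat(dpool / (p * p), p, axis=1), p, axis=2)
            dconv[:, :hp * p, :wp * p] = spread
            du_conv = dconv * _act_grad(u, act)  # (N,H',W',F)
            wmat = P[f"W{li}"].reshape(f, -1)
            du_flat = du_conv.reshape(-1, f)
            grads[f"W{li}"] = (du_flat.T @ cols.reshape(-1, cols.shape[-1])
                               ).reshape(P[f"W{li}"].shape)
            grads[f"b{li}"] = du_flat.sum(axis=0)
            dcols = du_flat @ wmat                # (N*H'*W', C*k*k)
            c_in = a_in.shape[1]
            dcols = dcols.reshape(n, hh, ww, c_in, k, k)
            da_in = np.zeros_like(a_in)
            for ki in range(k):
                for kj in range(k):
                    da_in[:, :, ki:ki + hh, kj:kj + ww] += \
                        dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            da = da_in
        return grads

    # -- training ----------------------------------------------------------

    def fit(self, rasters, features, weights):
        cfg = self.config
        rasters = np.asarray(rasters, dtype=np.float32)
        feats = np.asarray(features, dtype=np.float32)
        y = np.asarray(weights, dtype=np.float64)
        if len(y) < 2:
            raise ParameterError("need at least 2 training records")
        if not cfg.features_only and rasters.shape[1:] != tuple(cfg.raster_hw):
            raise ConfigError(
                f"raster shape {rasters.shape[1:]} does not match config "
                f"{tuple(cfg.raster_hw)}"
            )

        r_mean, r_std = float(rasters.mean()), float(rasters.std()) or 1.0
        f_mean = feats.mean(axis=0)
        f_std = feats.std(axis=0)
        f_std[f_std == 0] = 1.0
        y_mean, y_std = float(y.mean()), float(y.std()) or 1.0
        self.norms_ = {
            "r_mean": r_mean, "r_std": r_std,
            "f_mean": f_mean, "f_std": f_std,
            "y_mean": y_mean, "y_std": y_std,
        }
        xr = (rasters - r_mean) / r_std
        xf = ((feats - f_mean) / f_std).astype(np.float32)
        yt = ((y - y_mean) / y_std).astype(np.float32)

        self._init_params(xf.shape[1])
        n = len(y)
        self.loss_history_ = []
        for _ in range(cfg.epochs):
            cache = []
            pred = self._forward(xr, xf, cache)
            resid = pred - yt
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"training diverged (non-finite loss) at learning rate "
                    f"{cfg.learning_rate}"
                )
            self.loss_history_.append(loss)
            grads = self._backward(xr, xf, (2.0 / n) * resid, cache)
            for key, g in grads.items():
                self.params[key] -= (cfg.learning_rate * g).astype(np.float32)
        return self

    def predict(self, rasters, features):
        if self.norms_ is None:
            raise ConfigError("model is not fitted")
        nm = self.norms_
        xr = (np.asarray(rasters, dtype=np.float32) - nm["r_mean"]) / nm["r_std"]
        xf = ((np.asarray(features, dtype=np.float32) - nm["f_mean"])
              / nm["f_std"]).astype(np.float32)
        pred = self._forward(xr, xf)
        return pred * nm["y_std"] + nm["y_mean"]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        if self.norms_ is None:
            raise ConfigError("cannot save an unfitted model")
        cfg = asdict(self.config)
        np.savez(
            path, __config__=json.dumps(cfg), __kind__="cnn",
            norm_f_mean=self.norms_["f_mean"], norm_f_std=self.norms_["f_std"],
            norm_scalars=np.array([self.norms_["r_mean"], self.norms_["r_std"],
                                   self.norms_["y_mean"], self.norms_["y_std"]]),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "CNNWeightRegressor":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["__config__"]))
        for key in ("conv_filters", "fc_widths", "raster_hw"):
            cfg[key] = tuple(cfg[key])
        model = cls(CNNConfig(**cfg))
        model.params = {k: data[k] for k in data.files
                        if not k.startswith(("__", "norm_"))}
        sc = data["norm_scalars"]
        model.norms_ = {
            "r_mean": float(sc[0]), "r_std": float(sc[1]),
            "y_mean": float(sc[2]), "y_std": float(sc[3]),
            "f_mean": data["norm_f_mean"], "f_std": data["norm_f_std"],
        }
        return model


def cnn_forward(raster, features, config: CNNConfig, params: dict) -> float:
    """Single-sample forward pass with explicit parameter arrays (no norms)."""
    model = CNNWeightRegressor(config)
    model.params = params
    r = np.asarray(raster, dtype=np.float32)[None]
    f = np.asarray(features, dtype=np.float32).reshape(1, -1)
    return float(model._forward(r, f)[0])


def train_cnn(dataset, config: CNNConfig | None = None):
    """Train on (raster, features, weight) triples; returns (model, history).

    ``raster`` entries may be :class:`BackRaster` or plain arrays.
    """
    if len(dataset) < 2:
        raise ParameterError("need at least 2 training records")
    rasters = np.stack([
        r.heights if isinstance(r, BackRaster) else np.asarray(r)
        for r, _, _ in dataset
    ])
    feats = np.stack([np.asarray(f.as_array() if hasattr(f, "as_array") else f)
                      for _, f, _ in dataset])
    ys = np.array([w for _, _, w in dataset], dtype=float)
    model = CNNWeightRegressor(config).fit(rasters, feats, ys)
    return model, model.loss_history_


# ---------------------------------------------------------------------------
# RBF baseline
# ---------------------------------------------------------------------------

class RBFWeightRegressor:
    """Gaussian RBF network: random training centers + least-squares output."""

    def __init__(self, n_centers: int = 20, seed: int = 0):
        if n_centers < 1:
            raise ParameterError("n_centers must be >= 1")
        self.n_centers = n_centers
        self.seed = seed
        self.centers_ = None
        self.width_ = None
        self.coef_ = None
        self.norms_ = None

    def fit(self, features, targets):
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[0] == 1 and np.asarray(features).ndim == 1:
            X = X.T
        y = np.asarray(targets, dtype=float)
        if len(X) < self.n_centers:
            raise ParameterError(
                f"need at least n_centers={self.n_centers} records, got {len(X)}"
            )
        f_mean = X.mean(axis=0)
        f_std = X.std(axis=0)
        f_std[f_std == 0] = 1.0
        self.norms_ = (f_mean, f_std)
        Xs = (X - f_mean) / f_std
        rng = np.random.default_rng(self.seed)
        idx = rng.choice(len(Xs), size=self.n_centers, replace=False)
        self.centers_ = Xs[idx]
        if self.n_centers > 1:
            self.width_ = float(np.median(pdist(self.centers_))) or 1.0
        else:
            self.width_ = 1.0
        Phi = self._design(Xs)
        try:
            coef, _, _, _ = np.linalg.lstsq(Phi, y, rcond=-1)
            if not np.all(np.isfinite(coef)):
                raise np.linalg.LinAlgError("non-finite solution")
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular RBF least-squares system; falling back to ridge",
                stacklevel=2,
            )
            lam = 1e-8
            coef = np.linalg.solve(Phi.T @ Phi + lam * np.eye(Phi.shape[1]),
                                   Phi.T @ y)
        self.coef_ = coef
        return self

    def _design(self, Xs):
        d2 = ((Xs[:, None, :] - self.centers_[None]) ** 2).sum(axis=2)
        Phi = np.exp(-d2 / (2 * self.width_ ** 2))
        return np.column_stack([Phi, np.ones(len(Xs))])

    def predict(self, features):
        if self.coef_ is None:
            raise ConfigError("model is not fitted")
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[0] == 1 and np.asarray(features).ndim == 1:
            X = X.T
        f_mean, f_std = self.norms_
        return self._design((X - f_mean) / f_std) @ self.coef_


def train_rbf(dataset, n_centers: int = 20, seed: int = 0) -> RBFWeightRegressor:
    """Train the RBF baseline on (BackFeatures, weight) pairs."""
    feats = np.stack([np.asarray(f.as_array() if hasattr(f, "as_array") else f)
                      for f, _ in dataset])
    ys = np.array([w for _, w in dataset], dtype=float)
    return RBFWeightRegressor(n_centers, seed).fit(feats, ys)
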