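"""Stage 1: femoral head center detection by volume-wise heatmap regression.

A fully convolutional encoder-decoder maps the whole (downsampled)
volume to a heatmap whose peak marks the femoral head center (FHC); the
argmax, refined by the intensity-weighted centroid of its 3x3x3
neighbourhood, is mapped back to world coordinates.  The detected FHC
is then used to crop the joint region for the segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io_formats import LabelMap, VolumeImage
from .nn import UNet3D, mse_heatmap_loss


def _pooled_grid(vol: VolumeImage, f: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, spacing, origin) of the f-times average-pooled volume."""
    shape = np.asarray(vol.shape)
    if np.any(shape % f):
        raise ValueError(f"volume shape {tuple(shape)} not divisible by factor {f}")
    v = vol.values.astype(np.float32)
    d, h, w = shape // f
    v = v.reshape(d, f, h, f, w, f).mean(axis=(1, 3, 5))
    spacing = vol.spacing_mm * f
    origin = vol.origin_mm + (f - 1) / 2.0 * vol.spacing_mm  # pooled voxel centers
    return v, spacing, origin


def make_heatmap_target(fhc_mm: np.ndarray, shape, spacing_mm, origin_mm,
                        sigma_mm: float) -> np.ndarray:
    """Gaussian heatmap H(v) = exp(-||x(v) - fhc||^2 / (2 sigma^2)).

    Defined in world coordinates, so the half-width in mm is independent
    of the grid spacing.  Raises if the FHC lies outside the grid.
    """
    fhc = np.asarray(fhc_mm, dtype=float).reshape(3)
    shape = tuple(shape)
    spacing = np.asarray(spacing_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    idx = (fhc - origin) / spacing
    if np.any(idx < -0.5) or np.any(idx > np.asarray(shape) - 0.5):
        raise ValueError(f"fhc {fhc} outside grid of shape {shape}")
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    d2 = ((axes[0] - fhc[0])[:, None, None] ** 2
          + (axes[1] - fhc[1])[None, :, None] ** 2
          + (axes[2] - fhc[2])[None, None, :] ** 2)
    return np.exp(-d2 / (2.0 * sigma_mm**2)).astype(np.float32)


class LandmarkLocator(BaseEstimator):
    """Sklearn-style heatmap-regression landmark detector.

    Parameters
    ----------
    depth, base_channels : U-Net size (pooling levels / first-level width).
    sigma_mm : width of the Gaussian target; must be at least one
        working-resolution voxel.
    downsample_factor : average-pooling factor applied to the input
        volume; detection is mapped back to full resolution.
    heatmap_amplitude : scale applied to the unit-peak Gaussian target
        during training; conditions the MSE loss against the trivial
        all-zero solution of a very sparse target.  Detection is
        scale-invariant.
    epochs, lr, seed : training schedule (Adam, MSE loss).
    max_restarts : a sparse heatmap target has a near-constant local
        optimum that some initializations fall into; training whose
        final loss stays above half the best-constant-predictor MSE is
        deemed collapsed and restarted from a fresh initialization (up
        to this many times, deterministically derived from ``seed``).
    """

    def __init__(self, depth: int = 3, base_channels: int = 8, sigma_mm: float = 6.0,
                 downsample_factor: int = 2, heatmap_amplitude: float = 20.0,
                 epochs: int = 8, lr: float = 1e-3, seed: int = 0,
                 max_restarts: int = 3):
        self.depth = depth
        self.base_channels = base_channels
        self.sigma_mm = sigma_mm
        self.downsample_factor = downsample_factor
        self.heatmap_amplitude = heatmap_amplitude
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.max_restarts = max_restarts

    def _validate(self, volumes):
        if len(volumes) == 0:
            raise ValueError("empty training set")
        for p in ("depth", "base_channels", "sigma_mm", "downsample_factor",
                  "epochs", "lr"):
            if getattr(self, p) <= 0:
                raise ValueError(f"{p} must be positive")

    @staticmethod
    def _normalize(values: np.ndarray) -> np.ndarray:
        scale = np.percentile(values, 99)
        return (values / max(scale, 1e-6)).astype(np.float32)

    def fit(self, X: list[VolumeImage], y) -> "LandmarkLocator":
        """Train on volumes ``X`` with true FHC world coordinates ``y``."""
        self._validate(X)
        if len(X) < 2:
            raise ValueError("need at least 2 training samples")
        f = self.downsample_factor
        data = []
        for vol, fhc in zip(X, y):
            v, spacing, origin = _pooled_grid(vol, f)
            if self.sigma_mm < spacing.min():
                raise ValueError("sigma_mm below one working-resolution voxel")
            target = self.heatmap_amplitude * make_heatmap_target(
                fhc, v.shape, spacing, origin, self.sigma_mm)
            data.append((self._normalize(v)[None], target[None]))
        # MSE of the best constant predictor: the collapse plateau level
        collapse_level = float(np.mean([np.var(t) for _, t in data]))
        self.n_restarts_ = 0
        for attempt in range(self.max_restarts + 1):
            rng = np.random.default_rng(self.seed + 9973 * attempt)
            self.model_ = UNet3D(1, 1, depth=self.depth,
                                 base_channels=self.base_channels,
                                 rng=np.random.default_rng(self.seed + 1 + 9973 * attempt))
            opt = self.model_.make_optimizer(self.lr)
            self.loss_history_ = []
            for _ in range(self.epochs):
                order = rng.permutation(len(data))
                losses = []
                for i in order:
                    x, t = data[i]
                    pred = self.model_.forward(x)
                    loss, grad = mse_heatmap_loss(pred, t)
                    opt.zero_grad()
                    self.model_.backward(grad.astype(np.float32))
                    opt.step()
                    losses.append(loss)
                self.loss_history_.append(float(np.mean(losses)))
            if self.loss_history_[-1] <= 0.5 * collapse_level:
                break
            self.n_restarts_ = attempt + 1
        return self

    def predict_heatmap(self, vol: VolumeImage):
        v, spacing, origin = _pooled_grid(vol, self.downsample_factor)
        hm = self.model_.forward(self._normalize(v)[None])[0]
        return hm, spacing, origin

    def detect(self, vol: VolumeImage) -> tuple[np.ndarray, float]:
        """(fhc_mm, confidence): refined heatmap peak in world coordinates."""
        hm, spacing, origin = self.predict_heatmap(vol)
        return refine_peak(hm, spacing, origin)

    def predict(self, X: list[VolumeImage]) -> np.ndarray:
        return np.asarray([self.detect(v)[0] for v in X])


def refine_peak(heatmap: np.ndarray, spacing_mm, origin_mm) -> tuple[np.ndarray, float]:
    """Argmax of a heatmap refined by the 3x3x3 intensity-weighted centroid."""
    heatmap = np.asarray(heatmap)
    peak = float(heatmap.max())
    if peak <= 0 or np.allclose(heatmap, heatmap.ravel()[0]):
        raise ValueError("no landmark response: flat or non-positive heatmap")
    pk = np.unravel_index(int(np.argmax(heatmap)), heatmap.shape)
    lo = [max(p - 1, 0) for p in pk]
    hi = [min(p + 2, s) for p, s in zip(pk, heatmap.shape)]
    nb = np.clip(heatmap[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], 0.0, None)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    wsum = nb.sum()
    idx = np.array([float((g * nb).sum() / wsum) for g in grids])
    return np.asarray(origin_mm) + idx * np.asarray(spacing_mm), peak


def detect_fhc(model: LandmarkLocator, vol: VolumeImage) -> tuple[np.ndarray, float]:
    """Functional wrapper over :meth:`LandmarkLocator.detect`."""
    return model.detect(vol)


def train_landmark_net(samples, **params) -> LandmarkLocator:
    """Train a :class:`LandmarkLocator` on phantom samples."""
    est = LandmarkLocator(**params)
    return est.fit([s.volume for s in samples], [s.fhc_mm for s in samples])


# ---------------------------------------------------------------------------
# ROI cropping

@dataclass
class CropOffset:
    """Bookkeeping to place ROI results back into the original frame."""

    start_index: np.ndarray        # ROI start in original voxel indices (may be <0)
    roi_shape: tuple[int, int, int]
    original_shape: tuple[int, int, int]


def crop_around_fhc(grid: VolumeImage, fhc_mm: np.ndarray, roi_size_mm=None,
                    roi_shape=None, pad_value: float = 0.0):
    """Crop an ROI centered on the FHC; out-of-bounds regions are padded.

    Give either a physical ``roi_size_mm`` (scalar or 3-vector) or an
    explicit ``roi_shape`` in voxels.  Returns (cropped grid, CropOffset);
    :func:`uncrop` restores original-frame placement losslessly.
    """
    if (roi_size_mm is None) == (roi_shape is None):
        raise ValueError("give exactly one of roi_size_mm or roi_shape")
    if roi_shape is None:
        size = np.broadcast_to(np.asarray(roi_size_mm, dtype=float), 3)
        if np.any(size <= 0):
            raise ValueError("roi_size_mm must be positive")
        roi_shape = np.maximum(np.rint(size / grid.spacing_mm).astype(int), 1)
    roi_shape = tuple(int(s) for s in roi_shape)
    center = np.rint(grid.world_to_index(fhc_mm)).astype(int)
    start = center - np.asarray(roi_shape) // 2
    out = np.full(roi_shape, pad_value, dtype=grid.values.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + roi_shape, grid.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            grid.values[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    cls = LabelMap if isinstance(grid, LabelMap) else VolumeImage
    cropped = cls(values=out, spacing_mm=grid.spacing_mm,
                  origin_mm=grid.index_to_world(start))
    return cropped, CropOffset(start_index=start, roi_shape=roi_shape,
                               original_shape=grid.shape)


def uncrop(values: np.ndarray, offset: CropOffset, fill=0):
    """Place ROI values back into an original-frame array (fill outside)."""
    out = np.full(offset.original_shape, fill, dtype=values.dtype)
    start = offset.start_index
    src_lo = np.maximum(-start, 0)
    dst_lo = np.maximum(start, 0)
    dst_hi = np.minimum(start + offset.roi_shape, offset.original_shape)
    n = dst_hi - dst_lo
    if np.all(n > 0):
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
            values[src_lo[0]:src_lo[0] + n[0], src_lo[1]:src_lo[1] + n[1],
                   src_lo[2]:src_lo[2] + n[2]]
    return out
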