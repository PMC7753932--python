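"""Stage 2: LP-U-Net segmentation of the cropped hip joint.

The segmenter crops a fixed-size region of interest around the femoral
head center, runs an LP-U-Net (a 3D U-Net whose input is rearranged by
a space-to-depth "holistic decomposition" stage and whose output is
reassembled by a depth-to-space "dense upsampling" stage), and places
the per-voxel argmax labels back into the original frame.  Model
selection follows a patient-grouped k-fold design: hips of the same
patient never appear in both the training and the test side of a fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluation import compare_models
from .io_formats import LabelMap, VolumeImage
from .landmark import LandmarkLocator, crop_around_fhc, uncrop
from .nn import LPUNet, seg_loss
from .nn import depth_to_space, space_to_depth  # re-exported architecture ops

__all__ = [
    "space_to_depth", "depth_to_space", "build_lp_unet", "HipSegmenter",
    "FoldPlan", "make_group_kfold", "train_segmentation", "segment",
    "run_cross_validation",
]


def build_lp_unet(hdc_factor: int = 2, duc_factor: int | None = None, depth: int = 3,
                  base_channels: int = 8, n_classes: int = 3, seed: int = 0) -> LPUNet:
    """Construct the LP-U-Net (see :class:`hip3d.nn.LPUNet`)."""
    return LPUNet(1, n_classes, hdc_factor=hdc_factor, duc_factor=duc_factor,
                  depth=depth, base_channels=base_channels, seed=seed)


class HipSegmenter(BaseEstimator):
    """Sklearn-style LP-U-Net hip-joint segmenter.

    fit(X, y, fhc) trains on ROI crops around the (true) femoral head
    centers; predict(X, fhc) segments full volumes, using detected or
    injected FHCs, and returns label maps in the original frame with
    background outside the ROI.  Loss is soft-Dice + cross-entropy with
    configurable weights.
    """

    def __init__(self, hdc_factor: int = 2, duc_factor: int | None = None,
                 depth: int = 3, base_channels: int = 8, n_classes: int = 3,
                 dice_weight: float = 1.0, ce_weight: float = 1.0,
                 roi_shape: tuple[int, int, int] = (48, 48, 48),
                 epochs: int = 40, lr: float = 1e-3, seed: int = 0):
        self.hdc_factor = hdc_factor
        self.duc_factor = duc_factor
        self.depth = depth
        self.base_channels = base_channels
        self.n_classes = n_classes
        self.dice_weight = dice_weight
        self.ce_weight = ce_weight
        self.roi_shape = roi_shape
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def _check_config(self):
        k = self.hdc_factor
        div = k * 2**self.depth
        if any(s % div for s in self.roi_shape):
            raise ValueError(
                f"roi_shape {self.roi_shape} must be divisible by k * 2**depth = {div}"
            )

    @staticmethod
    def _normalize(values: np.ndarray) -> np.ndarray:
        scale = np.percentile(values, 99)
        return (values / max(scale, 1e-6)).astype(np.float32)

    def _crop(self, vol: VolumeImage, fhc_mm):
        return crop_around_fhc(vol, fhc_mm, roi_shape=self.roi_shape)

    def fit(self, X: list[VolumeImage], y: list[LabelMap], fhc: list) -> "HipSegmenter":
        """Train on (volume, label map, FHC) triples."""
        self._check_config()
        if len(X) < 2:
            raise ValueError("need at least 2 training samples")
        data = []
        seen = np.zeros(self.n_classes, dtype=bool)
        for vol, lab, c in zip(X, y, fhc):
            v, _ = self._crop(vol, c)
            l, _ = self._crop(lab, c)
            seen |= np.isin(np.arange(self.n_classes), np.unique(l.values))
            data.append((self._normalize(v.values)[None], l.values.astype(np.int64)))
        self.missing_classes_ = [int(c) for c in np.nonzero(~seen)[0]]
        if self.missing_classes_:
            warnings.warn(f"classes {self.missing_classes_} absent from all training labels")
        # restart guard: a real training run (>= 10 epochs) that fails to
        # cut the first-epoch loss markedly has hit a bad initialization
        max_restarts = 2 if self.epochs >= 10 else 0
        self.n_restarts_ = 0
        for attempt in range(max_restarts + 1):
            self.model_ = build_lp_unet(self.hdc_factor, self.duc_factor, self.depth,
                                        self.base_channels, self.n_classes,
                                        seed=self.seed + 1 + 9973 * attempt)
            opt = self.model_.make_optimizer(self.lr)
            rng = np.random.default_rng(self.seed + 9973 * attempt)
            self.loss_history_ = []
            for _ in range(self.epochs):
                order = rng.permutation(len(data))
                losses = []
                for i in order:
                    x, lab = data[i]
                    logits = self.model_.forward(x)
                    loss, grad = seg_loss(logits, lab, ce_weight=self.ce_weight,
                                          dice_weight=self.dice_weight)
                    opt.zero_grad()
                    self.model_.backward(grad)
                    opt.step()
                    losses.append(loss)
                self.loss_history_.append(float(np.mean(losses)))
            if max_restarts == 0 or self.loss_history_[-1] <= 0.6 * self.loss_history_[0]:
                break
            self.n_restarts_ = attempt + 1
        return self

    def predict_one(self, vol: VolumeImage, fhc_mm) -> LabelMap:
        v, offset = self._crop(vol, fhc_mm)
        logits = self.model_.forward(self._normalize(v.values)[None])
        # argmax with lowest-class-index tie-break (np.argmax takes the first max)
        pred = np.argmax(logits, axis=0).astype(np.uint8)
        full = uncrop(pred, offset, fill=0)
        return LabelMap(values=full, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)

    def predict(self, X: list[VolumeImage], fhc: list) -> list[LabelMap]:
        return [self.predict_one(v, c) for v, c in zip(X, fhc)]


def train_segmentation(samples, **params) -> HipSegmenter:
    """Train a :class:`HipSegmenter` on phantom samples (true FHCs)."""
    est = HipSegmenter(**params)
    return est.fit([s.volume for s in samples], [s.labels for s in samples],
                   [s.fhc_mm for s in samples])


def segment(model: HipSegmenter, vol: VolumeImage, fhc_mm) -> LabelMap:
    """Functional wrapper over :meth:`HipSegmenter.predict_one`."""
    return model.predict_one(vol, fhc_mm)


# ---------------------------------------------------------------------------
# patient-grouped cross-validation

@dataclass
class FoldPlan:
    """k-fold partition that never splits a patient across train/test."""

    folds: list  # list of (train_indices, test_indices) arrays
    patient_ids: list = field(default_factory=list)

    def validate(self) -> None:
        all_test = np.concatenate([t for _, t in self.folds])
        n = len(self.patient_ids)
        if sorted(all_test.tolist()) != list(range(n)):
            raise ValueError("test sets must partition the dataset")
        for train, test in self.folds:
            p_train = {self.patient_ids[i] for i in train}
            p_test = {self.patient_ids[i] for i in test}
            if p_train & p_test:
                raise ValueError(f"patient leak across train/test: {p_train & p_test}")


def make_group_kfold(samples, k: int = 3, seed: int = 0) -> FoldPlan:
    """Randomly assign whole patients to k folds (greedy size balancing)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    patient_ids = [s.patient_id for s in samples]
    patients = sorted(set(patient_ids))
    if len(patients) < k:
        raise ValueError(f"{len(patients)} patients < {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of = {}
    sizes = np.zeros(k, dtype=int)
    counts = {p: patient_ids.count(p) for p in patients}
    for i in order:
        p = patients[i]
        f = int(np.argmin(sizes))
        fold_of[p] = f
        sizes[f] += counts[p]
    folds = []
    idx = np.arange(len(samples))
    for f in range(k):
        test = idx[[fold_of[p] == f for p in patient_ids]]
        train = idx[[fold_of[p] != f for p in patient_ids]]
        folds.append((train, test))
    plan = FoldPlan(folds=folds, patient_ids=patient_ids)
    plan.validate()
    return plan


def run_cross_validation(samples, fold_plan: FoldPlan,
                         landmark_params: dict | None = None,
                         seg_params: dict | None = None,
                         use_true_fhc: bool = False,
                         smooth_sigma_vox: float = 0.6):
    """Train and evaluate the two-stage pipeline per fold.

    For every test hip: detect the FHC (or inject the true one), crop,
    segment, and evaluate against the ground-truth labels (Dice,
    precision, recall, ASD, Hausdorff per structure, plus the FHC
    detection error).  Per-sample failures are recorded and the run
    continues.  Returns (metric table, details dict).
    """
    landmark_params = landmark_params or {}
    seg_params = seg_params or {}
    rows = []
    errors = []
    fhc_rows = []
    predictions = {}
    for fold_id, (train, test) in enumerate(fold_plan.folds):
        train_samples = [samples[i] for i in train]
        locator = None
        if not use_true_fhc:
            locator = LandmarkLocator(**landmark_params).fit(
                [s.volume for s in train_samples], [s.fhc_mm for s in train_samples])
        seg = HipSegmenter(**seg_params).fit(
            [s.volume for s in train_samples], [s.labels for s in train_samples],
            [s.fhc_mm for s in train_samples])
        for i in test:
            s = samples[i]
            try:
                if locator is not None:
                    fhc, conf = locator.detect(s.volume)
                    err_mm = float(np.linalg.norm(fhc - s.fhc_mm))
                    wvox = float(s.volume.spacing_mm.max() * locator.downsample_factor)
                    fhc_rows.append({"fold": fold_id, "sample": s.sample_id,
                                     "fhc_error_mm": err_mm,
                                     "fhc_error_wvox": err_mm / wvox,
                                     "confidence": conf})
                else:
                    fhc = s.fhc_mm
                pred = seg.predict_one(s.volume, fhc)
                predictions[s.sample_id] = pred
                reports = compare_models(pred, s.labels, smooth_sigma_vox=smooth_sigma_vox)
                for name, rep in reports.items():
                    rows.append({"fold": fold_id, "sample": s.sample_id,
                                 "patient": s.patient_id, "structure": name,
                                 "doc_pct": rep.doc_pct, "precision_pct": rep.precision_pct,
                                 "recall_pct": rep.recall_pct, "asd_mm": rep.asd_mm,
                                 "hd_mm": rep.hd_mm})
            except Exception as exc:  # isolate per-sample failures
                errors.append({"fold": fold_id, "sample": s.sample_id, "error": str(exc)})
    table = pd.DataFrame(rows)
    details = {"fhc": pd.DataFrame(fhc_rows), "errors": errors, "predictions": predictions}
    return table, details
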