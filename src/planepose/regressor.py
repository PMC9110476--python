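"""Plane-pose regression estimator.

:class:`PlanePoseRegressor` is a scikit-learn-style estimator mapping 2D
grayscale slice images to 6D plane poses.  The network emits nine
parameters per image — a normalised translation triple and six rotation
parameters — and the forward pass reconstructs a proper rotation matrix
from the six by Gram-Schmidt orthonormalisation, so every prediction is a
valid pose regardless of the raw head values.

Targets ``y`` are 9-vectors ``(t1, t2, t3, r1..r6)`` as produced by
:meth:`planepose.rotations.Pose.as_target`.  Training minimises

    L_total = L_rotation + lambda * L_translation

where the rotation term is the batch mean of Frobenius norms
``||R' - R||_F`` and the translation term the batch mean of Euclidean
norms ``||t' - t||_2`` (squared variants behind ``squared_norm``).  Model
selection keeps the epoch with the lowest validation total loss.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .dataset import DatasetManifest, read_manifest
from .nn.layers import get_model_state, set_model_state
from .rotations import Pose
from .volume import load_slice_png

__all__ = [
    "PlanePoseRegressor",
    "desk_scale_params",
    "mean_pose_baseline",
    "preprocess_image",
    "save_checkpoint",
    "load_checkpoint",
    "train_from_manifest",
    "load_manifest_arrays",
]

try:  # BaseEstimator gives get_params/set_params; optional at runtime
    from sklearn.base import BaseEstimator, RegressorMixin
except ImportError:  # pragma: no cover - sklearn is expected to be present
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

    class RegressorMixin:  # type: ignore[no-redef]
        pass


def desk_scale_params() -> dict:
    """Training parameters of the package's desk-scale (CPU) recipe.

    A from-scratch small CNN wants the 1e-3-scale Adam step with cosine
    decay and small batches (many updates per epoch); everything else
    follows the estimator defaults.
    """
    return dict(backbone="smallconv", image_size=64, epochs=10,
                batch_size=15, learning_rate=3e-3, lr_schedule="cosine",
                lambda_weight=0.01)


def preprocess_image(image: np.ndarray, image_size: int) -> np.ndarray:
    """Resize preserving aspect ratio (short side to ``image_size``) and
    centre-crop to a square; intensities stay in [0, 1]."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got {image.ndim}-D")
    h, w = image.shape
    if (h, w) == (image_size, image_size):
        return image
    scale = image_size / min(h, w)
    nh, nw = max(image_size, int(round(h * scale))), max(image_size, int(round(w * scale)))
    pil = Image.fromarray(image)
    pil = pil.resize((nw, nh), Image.BILINEAR)
    arr = np.asarray(pil, dtype=np.float32)
    top = (nh - image_size) // 2
    left = (nw - image_size) // 2
    return arr[top:top + image_size, left:left + image_size]


class PlanePoseRegressor(BaseEstimator, RegressorMixin):
    """CNN regressor from slice images to 6D plane poses.

    Parameters
    ----------
    backbone
        ``"resnet18"`` (18-layer residual network, the full-scale choice)
        or ``"smallconv"`` (compact CPU-friendly variant).
    image_size
        Square input side in pixels; images are resized/cropped to it.
    epochs, batch_size, learning_rate, beta1, beta2
        Adam training schedule.
    lambda_weight
        Weight of the translation term in the total loss.
    val_fraction
        Seeded fraction of the training set held out for model selection.
    squared_norm
        Use squared norms in both loss terms instead of plain norms.
    lr_schedule
        ``"constant"`` or ``"cosine"`` (half-cosine decay of the learning
        rate over the epochs; helps the mean-of-norms loss settle, whose
        gradients do not shrink near the optimum).
    restore_best
        Keep the weights of the best-validation epoch (default); when
        False the final epoch's weights are kept instead, which is what a
        deliberate memorisation/capacity check wants.
    pretrained
        Reserved toggle for externally supplied backbone weights; no
        weights ship with the package, so enabling it raises.
    seed
        Seeds the split, shuffling and weight initialisation.

    Attributes
    ----------
    model_ : fitted network
    history_ : per-epoch train/validation losses (DataFrame)
    best_epoch_ : epoch whose weights were kept (lowest validation total)
    """

    def __init__(self, backbone: str = "resnet18", image_size: int = 128,
                 epochs: int = 50, batch_size: int = 100,
                 learning_rate: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, lambda_weight: float = 0.01,
                 val_fraction: float = 0.2, squared_norm: bool = False,
                 lr_schedule: str = "constant", restore_best: bool = True,
                 pretrained: bool = False, seed: int = 0, verbose: int = 0):
        self.backbone = backbone
        self.image_size = image_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.lambda_weight = lambda_weight
        self.val_fraction = val_fraction
        self.squared_norm = squared_norm
        self.lr_schedule = lr_schedule
        self.restore_best = restore_best
        self.pretrained = pretrained
        self.seed = seed
        self.verbose = verbose

    # -- helpers ---------------------------------------------------------

    def _validate_inputs(self, X: np.ndarray, y: np.ndarray | None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"X must be (n_samples, H, W), got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite pixels")
        if X.shape[1:] != (self.image_size, self.image_size):
            X = np.stack([preprocess_image(img, self.image_size) for img in X])
        if y is not None:
            y = np.asarray(y, dtype=np.float64)
            if y.ndim != 2 or y.shape[1] != 9:
                raise ValueError(f"y must be (n_samples, 9), got shape {y.shape}")
            if y.shape[0] != X.shape[0]:
                raise ValueError("X and y sample counts differ")
            if not np.all(np.isfinite(y)):
                raise ValueError("y contains non-finite values")
        return X, y

    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        return self.model_.forward((X - 0.5)[:, None, :, :], train=train)

    def _batch_losses(self, out: np.ndarray, y: np.ndarray):
        t_pred = out[:, :3].astype(np.float64)
        R_pred, cache = nn.gram_schmidt_forward(out[:, 3:].astype(np.float64))
        R_gt, _ = nn.gram_schmidt_forward(y[:, 3:])
        l_rot, g_R = nn.rotation_loss_grad(R_pred, R_gt, squared=self.squared_norm)
        l_tr, g_t = nn.translation_loss_grad(t_pred, y[:, :3], squared=self.squared_norm)
        dout = np.concatenate(
            [self.lambda_weight * g_t, nn.gram_schmidt_backward(g_R, cache)], axis=1
        ).astype(np.float32)
        return l_rot, l_tr, dout

    def _eval_losses(self, X: np.ndarray, y: np.ndarray, chunk: int = 256):
        tot_r = tot_t = 0.0
        n = len(X)
        for lo in range(0, n, chunk):
            xb, yb = X[lo:lo + chunk], y[lo:lo + chunk]
            out = self._forward(xb, train=False)
            l_rot, l_tr, _ = self._batch_losses(out, yb)
            tot_r += l_rot * len(xb)
            tot_t += l_tr * len(xb)
        return tot_r / n, tot_t / n

    # -- sklearn API -----------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PlanePoseRegressor":
        """Train on images ``X`` (n, H, W) and pose targets ``y`` (n, 9)."""
        if self.pretrained:
            raise ValueError(
                "no pretrained backbone weights are bundled with this package; "
                "set pretrained=False or load a checkpoint instead"
            )
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.lambda_weight <= 0:
            raise ValueError("lambda_weight must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        X, y = self._validate_inputs(X, y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")

        seedseq = np.random.SeedSequence(self.seed)
        init_rng, split_rng, shuffle_rng = (
            np.random.default_rng(s) for s in seedseq.spawn(3))
        self.model_ = nn.build_network(self.backbone, self.image_size, rng=init_rng)

        n_val = int(round(self.val_fraction * len(X)))
        perm = split_rng.permutation(len(X))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("validation split leaves no training samples")
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        opt = nn.Adam(self.model_.parameters(), lr=self.learning_rate,
                      beta1=self.beta1, beta2=self.beta2)
        history: list[dict] = []
        best = (np.inf, get_model_state(self.model_), -1)
        lam = self.lambda_weight

        for epoch in range(self.epochs):
            if self.lr_schedule == "cosine":
                opt.lr = self.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / max(1, self.epochs)))
            elif self.lr_schedule != "constant":
                raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
            order = shuffle_rng.permutation(len(Xtr))
            run_r = run_t = 0.0
            for lo in range(0, len(order), self.batch_size):
                sel = order[lo:lo + self.batch_size]
                out = self._forward(Xtr[sel], train=True)
                l_rot, l_tr, dout = self._batch_losses(out, ytr[sel])
                opt.zero_grad()
                self.model_.backward(dout)
                opt.step()
                run_r += l_rot * len(sel)
                run_t += l_tr * len(sel)
            tr_rot, tr_tr = run_r / len(Xtr), run_t / len(Xtr)
            if len(Xval):
                va_rot, va_tr = self._eval_losses(Xval, yval)
            else:
                va_rot, va_tr = tr_rot, tr_tr
            rec = {
                "epoch": epoch,
                "train_rotation": tr_rot, "train_translation": tr_tr,
                "train_total": tr_rot + lam * tr_tr,
                "val_rotation": va_rot, "val_translation": va_tr,
                "val_total": va_rot + lam * va_tr,
            }
            history.append(rec)
            if self.verbose:
                print(
                    f"epoch={epoch} train_total={rec['train_total']:.5f} "
                    f"val_total={rec['val_total']:.5f}", file=sys.stderr)
            if rec["val_total"] < best[0]:
                best = (rec["val_total"], get_model_state(self.model_), epoch)

        if self.epochs > 0 and self.restore_best:
            set_model_state(self.model_, best[1])
        self.best_epoch_ = best[2]
        self.history_ = pd.DataFrame(
            history, columns=["epoch", "train_rotation", "train_translation",
                              "train_total", "val_rotation", "val_translation",
                              "val_total"])
        self.n_features_in_ = self.image_size * self.image_size
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted 9-vectors; the rotation part is the Gram-Schmidt
        projection of the raw head output (so it always encodes a valid
        rotation)."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit or load a checkpoint")
        X, _ = self._validate_inputs(X, None)
        outs = []
        for lo in range(0, len(X), 256):
            out = self._forward(X[lo:lo + 256], train=False).astype(np.float64)
            R, _ = nn.gram_schmidt_forward(out[:, 3:])
            outs.append(np.concatenate(
                [out[:, :3], R[:, :, 0], R[:, :, 1]], axis=1))
        return np.concatenate(outs, axis=0)

    def predict_pose(self, image: np.ndarray) -> Pose:
        """Pose of a single image (resized/cropped to the model's input)."""
        theta = self.predict(np.asarray(image)[None])[0]
        return Pose.from_target(theta)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Negative total loss (higher is better), for model selection."""
        X, y = self._validate_inputs(X, y)
        l_rot, l_tr = self._eval_losses(X, y)
        return -(l_rot + self.lambda_weight * l_tr)


# ---------------------------------------------------------------------------
# Constant baseline
# ---------------------------------------------------------------------------

def mean_pose_baseline(y: np.ndarray) -> Pose:
    """Constant predictor: mean translation and chordal-mean rotation.

    The rotation mean is the SO(3) projection (via SVD) of the elementwise
    mean of the training rotation matrices.
    """
    y = np.asarray(y, dtype=float)
    t = y[:, :3].mean(axis=0)
    R_all, _ = nn.gram_schmidt_forward(y[:, 3:])
    M = R_all.mean(axis=0)
    U, _, Vt = np.linalg.svd(M)
    D = np.diag([1.0, 1.0, np.linalg.det(U @ Vt)])
    return Pose(U @ D @ Vt, t)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(est: PlanePoseRegressor, path: str | Path,
                    fingerprint: str = "") -> None:
    """Single-archive checkpoint: weights + params + history."""
    if not hasattr(est, "model_"):
        raise ValueError("cannot checkpoint an unfitted estimator")
    state = get_model_state(est.model_)
    meta = {
        "params": est.get_params(),
        "history": est.history_.to_dict(orient="records"),
        "best_epoch": int(est.best_epoch_),
        "fingerprint": fingerprint,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(state)}
    np.savez(Path(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> PlanePoseRegressor:
    """Rebuild a fitted estimator from :func:`save_checkpoint` output."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        n = len([k for k in data.files if k.startswith("arr_")])
        state = [data[f"arr_{i}"] for i in range(n)]
    est = PlanePoseRegressor(**meta["params"])
    est.model_ = nn.build_network(est.backbone, est.image_size,
                                  rng=np.random.default_rng(est.seed))
    set_model_state(est.model_, state)
    est.history_ = pd.DataFrame(meta["history"])
    est.best_epoch_ = meta["best_epoch"]
    est.n_features_in_ = est.image_size * est.image_size
    return est


# ---------------------------------------------------------------------------
# Manifest plumbing
# ---------------------------------------------------------------------------

def load_manifest_arrays(manifest: DatasetManifest | str | Path,
                         root_dir: str | Path | None = None):
    """Images, targets and subset tags for every manifest row.

    Returns ``(X, y, subsets)`` with ``X`` of shape (n, res, res) in [0, 1]
    and ``y`` the (n, 9) pose targets.
    """
    if not isinstance(manifest, DatasetManifest):
        path = Path(manifest)
        root_dir = root_dir if root_dir is not None else path.parent
        manifest = read_manifest(path)
    if root_dir is None:
        raise ValueError("root_dir is required when passing a DatasetManifest")
    root = Path(root_dir)
    if len(manifest.rows) == 0:
        raise ValueError("manifest is empty")
    images, targets = [], []
    for i, row in enumerate(manifest.rows.itertuples(index=False)):
        img_path = root / row.image_path
        if not img_path.exists():
            raise FileNotFoundError(f"manifest image missing: {img_path}")
        images.append(load_slice_png(img_path))
        targets.append(manifest.pose(i).as_target())
    X = np.stack(images).astype(np.float32)
    y = np.stack(targets)
    return X, y, manifest.rows["subset"].to_numpy()


def train_from_manifest(manifest_path: str | Path,
                        out_path: str | Path | None = None,
                        **params) -> PlanePoseRegressor:
    """Fit a :class:`PlanePoseRegressor` on a dataset manifest and
    optionally save a checkpoint."""
    manifest = read_manifest(manifest_path)
    X, y, _ = load_manifest_arrays(manifest, Path(manifest_path).parent)
    est = PlanePoseRegressor(**params)
    est.fit(X, y)
    if out_path is not None:
        save_checkpoint(est, out_path, fingerprint=manifest.fingerprint())
    return est
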