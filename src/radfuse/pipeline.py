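"""End-to-end assembly: splitting, augmentation, joint training, evaluation.

The central object is :class:`FusionImageClassifier`, an sklearn-style
estimator that owns the whole two-branch pipeline:

1. radiomic features are extracted once from the *unaugmented* images,
   standardized on the training data and reduced by L1-penalized selection;
2. the image branch (small CNN encoder + linear projection) and the fusion
   block (anti-cross-attention or plain concatenation) are trained jointly
   with the spline or fully-connected head, minimising
   ``L_ce + alpha * L_dec`` where ``alpha`` ramps linearly to ``alpha_max``;
3. early stopping monitors a small internal validation split (held out of the
   training data; the test split never touches model selection).

Augmentation (flip / rotation +-15 deg / scale 0.8-1.2 / brightness-contrast
jitter) is applied to the encoder branch only -- recomputing co-occurrence
statistics per augmented view would dominate the training loop and the
radiomics branch is meant to see the native lesion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from ._tensor import Tensor, cross_entropy, softmax
from .aca import AntiCrossAttention, ConcatFusion
from .decorrelation import alpha_schedule, decorrelation_loss_t
from .encoder import DeepBranch, EncoderConfig
from .kan import FCHead, KANHead
from .metrics import MetricsReport, evaluate_predictions
from .nn import Adam, Module, clone_state
from .radiomics import FeatureConfig, RadiomicsExtractor
from .selection import LassoFeatureSelector

__all__ = [
    "ABLATION_MODES",
    "AugmentPolicy",
    "TrainConfig",
    "FusionNetwork",
    "FusionImageClassifier",
    "stratified_split",
    "augment",
    "train",
    "evaluate",
    "run_ablation",
]

ABLATION_MODES = ("baseline_fc", "aca_fc", "aca_deco_fc", "aca_deco_kan")


@dataclass
class TrainConfig:
    """Training protocol defaults (overridable per experiment)."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    split_ratio: float = 0.8
    patience: int = 20
    val_fraction: float = 0.1
    alpha_max: float = 0.2
    unified_dim: int = 512
    native_dim: int = 128
    seed: int = 0
    ablation_mode: str = "aca_deco_kan"
    augment: bool = True

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie strictly between 0 and 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch statistics)")
        if self.ablation_mode not in ABLATION_MODES:
            raise ValueError(f"ablation_mode must be one of {ABLATION_MODES}")


@dataclass
class AugmentPolicy:
    enabled: bool = True
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    flip_prob: float = 0.5
    jitter: float = 0.10  # brightness/contrast fraction


def stratified_split(labels: np.ndarray, ratio: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split preserving class balance."""
    labels = np.asarray(labels)
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=labels, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def _affine_image(image: np.ndarray, angle_deg: float, scale: float,
                  flip: bool, order: int) -> np.ndarray:
    h, w = image.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    mat = rot / scale  # output -> input mapping
    if flip:
        mat = mat @ np.array([[1.0, 0.0], [0.0, -1.0]])
    offset = centre - mat @ centre
    return ndimage.affine_transform(
        image, mat, offset=offset, order=order, mode="nearest"
    )


def augment(image: np.ndarray, rng: np.random.Generator,
            policy: AugmentPolicy | None = None,
            mask: np.ndarray | None = None):
    """One random augmented view; geometric ops applied identically to a mask.

    Returns the image, or ``(image, mask)`` when a mask is given.  Disabled
    policy is the identity.
    """
    policy = policy or AugmentPolicy()
    if not policy.enabled:
        return image if mask is None else (image, mask)
    flip = rng.random() < policy.flip_prob
    angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
    scale = rng.uniform(*policy.scale_range)
    out = _affine_image(np.asarray(image, float), angle, scale, flip, order=1)
    out = out + rng.uniform(-policy.jitter, policy.jitter)  # brightness
    out = out * (1.0 + rng.uniform(-policy.jitter, policy.jitter))  # contrast
    out = np.clip(out, 0.0, 1.0)
    if mask is None:
        return out
    mask_out = _affine_image(np.asarray(mask, float), angle, scale, flip, order=0)
    return out, mask_out > 0.5


class FusionNetwork(Module):
    """Deep branch + fusion block + decorrelation projectors + head."""

    def __init__(self, k: int, n_classes: int, rng: np.random.Generator,
                 d: int = 512, native_dim: int = 128, use_aca: bool = True,
                 head: str = "kan", gate_mode: str = "scalar",
                 use_residual_gate: bool = True, kan_grid_size: int = 5,
                 kan_order: int = 3, kan_depth: int = 1,
                 deco_hidden_dim: int | None = None, dtype=np.float64):
        super().__init__()
        from .decorrelation import ViewProjectors  # local to avoid cycle at import

        self.deep = DeepBranch(EncoderConfig("small_cnn", native_dim, d), rng, dtype)
        if use_aca:
            self.fusion = AntiCrossAttention(
                k, d, rng, gate_mode=gate_mode,
                use_residual_gate=use_residual_gate, dtype=dtype,
            )
        else:
            self.fusion = ConcatFusion(k, d, rng, dtype=dtype)
        self.projectors = ViewProjectors(d, rng, hidden_dim=deco_hidden_dim, dtype=dtype)
        if head == "kan":
            self.head = KANHead(2 * d, n_classes, rng, grid_size=kan_grid_size,
                                order=kan_order, depth=kan_depth, dtype=dtype)
        elif head == "fc":
            self.head = FCHead(2 * d, n_classes, rng, dtype=dtype)
        else:
            raise ValueError("head must be 'kan' or 'fc'")

    def forward(self, images: Tensor, R: Tensor) -> dict[str, Tensor]:
        F = self.deep(images)
        out = self.fusion(R, F)
        H1, H2 = self.projectors(out["Rp"], out["Fn"])
        out.update(F_raw=F, H1=H1, H2=H2, logits=self.head(out["Ffus"]))
        return out


class FusionImageClassifier(ClassifierMixin, BaseEstimator):
    """Radiomics-guided two-branch image classifier (sklearn interface).

    Parameters mirror the training protocol: Adam with the given learning
    rate and weight decay, batch size >= 2, ``alpha_max`` weighting of the
    decorrelation loss on a linear epoch ramp, unified fusion dimension
    ``unified_dim`` and a choice of 'kan' or 'fc' head.  ``n_selected``
    defaults to min(100, number of extracted features).

    Fitted attributes (trailing underscore) include ``classes_``,
    ``network_``, ``history_`` (per-epoch losses and validation metrics),
    ``selected_idx_`` and ``selection_report_``.
    """

    def __init__(self, epochs: int = 30, batch_size: int = 32,
                 learning_rate: float = 1e-3, weight_decay: float = 1e-5,
                 alpha_max: float = 0.2, use_aca: bool = True,
                 head: str = "kan", unified_dim: int = 64,
                 native_dim: int = 128, n_selected: int | None = None,
                 n_levels: int = 32, glcm_distances: tuple[int, ...] = (1, 2, 3),
                 gate_mode: str = "scalar", use_residual_gate: bool = True,
                 kan_grid_size: int = 5, kan_order: int = 3, kan_depth: int = 1,
                 deco_hidden_dim: int | None = None, val_fraction: float = 0.1,
                 patience: int = 20, augment: bool = True,
                 dtype: str = "float32", random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.alpha_max = alpha_max
        self.use_aca = use_aca
        self.head = head
        self.unified_dim = unified_dim
        self.native_dim = native_dim
        self.n_selected = n_selected
        self.n_levels = n_levels
        self.glcm_distances = glcm_distances
        self.gate_mode = gate_mode
        self.use_residual_gate = use_residual_gate
        self.kan_grid_size = kan_grid_size
        self.kan_order = kan_order
        self.kan_depth = kan_depth
        self.deco_hidden_dim = deco_hidden_dim
        self.val_fraction = val_fraction
        self.patience = patience
        self.augment = augment
        self.dtype = dtype
        self.random_state = random_state

    # -- internals ------------------------------------------------------------

    def _np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64

    def _extract(self, X, masks):
        extractor = RadiomicsExtractor(
            FeatureConfig(n_levels=self.n_levels,
                          distances=tuple(self.glcm_distances))
        )
        return extractor.extract_table(np.asarray(X, float), masks)

    def _prepare_radiomics(self, values):
        Z = self.scaler_.transform(values)[:, self.selected_idx_]
        return Z.astype(self._np_dtype())

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y, masks=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be a (n_samples, height, width) image stack")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch statistics)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least two classes")

        ss = np.random.SeedSequence(self.random_state)
        init_rng, shuffle_rng, aug_rng, misc_rng = (
            np.random.default_rng(c) for c in ss.spawn(4)
        )
        split_seed = int(misc_rng.integers(2**31))

        # radiomics branch: extract once, standardize + select on training data
        table = self._extract(X, masks)
        self.feature_names_ = list(table.feature_names)
        n = len(X)
        if self.val_fraction > 0 and np.bincount(y_idx).min() >= 2:
            tr_idx, val_idx = train_test_split(
                np.arange(n), test_size=self.val_fraction,
                stratify=y_idx, random_state=split_seed,
            )
        else:
            tr_idx, val_idx = np.arange(n), np.array([], dtype=int)

        self.scaler_ = StandardScaler().fit(table.values[tr_idx])
        k = self.n_selected or min(100, table.values.shape[1])
        k = min(k, table.values.shape[1])
        selector = LassoFeatureSelector(k=k, random_state=int(misc_rng.integers(2**31)))
        selector.fit(self.scaler_.transform(table.values[tr_idx]), y_idx[tr_idx])
        self.selected_idx_ = np.asarray(selector.selected_idx_)
        self.selection_report_ = selector.report_
        self.selected_names_ = [self.feature_names_[i] for i in self.selected_idx_]

        R_all = self._prepare_radiomics(table.values)
        dtype = self._np_dtype()
        images = X.astype(dtype)

        self.network_ = FusionNetwork(
            k=len(self.selected_idx_), n_classes=n_classes, rng=init_rng,
            d=self.unified_dim, native_dim=self.native_dim,
            use_aca=self.use_aca, head=self.head, gate_mode=self.gate_mode,
            use_residual_gate=self.use_residual_gate,
            kan_grid_size=self.kan_grid_size, kan_order=self.kan_order,
            kan_depth=self.kan_depth, deco_hidden_dim=self.deco_hidden_dim,
            dtype=dtype,
        )
        params = self.network_.parameters()
        opt = Adam(params, lr=self.learning_rate, weight_decay=self.weight_decay)
        policy = AugmentPolicy(enabled=self.augment)

        history = []
        best_metric, best_state, best_epoch, stall = -np.inf, None, 0, 0
        for epoch in range(1, self.epochs + 1):
            alpha = alpha_schedule(epoch, self.epochs, self.alpha_max)
            self.network_.train()
            order = shuffle_rng.permutation(tr_idx)
            ce_sum = dec_sum = 0.0
            n_batches = 0
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                if len(batch) < 2:
                    continue  # batch statistics need >= 2 samples
                imgs = images[batch]
                if self.augment:
                    imgs = np.stack(
                        [augment(im, aug_rng, policy) for im in imgs]
                    ).astype(dtype)
                out = self.network_(Tensor(imgs), Tensor(R_all[batch]))
                l_ce = cross_entropy(out["logits"], y_idx[batch])
                l_dec = decorrelation_loss_t(out["H1"], out["H2"])
                loss = l_ce + alpha * l_dec if alpha > 0 else l_ce
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch} (non-finite loss)"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                ce_sum += l_ce.item()
                dec_sum += l_dec.item()
                n_batches += 1

            row = {
                "epoch": epoch,
                "L_ce": ce_sum / max(n_batches, 1),
                "L_dec": dec_sum / max(n_batches, 1),
                "alpha": alpha,
            }
            row["L_tot"] = row["L_ce"] + alpha * row["L_dec"]
            if len(val_idx):
                prob = self._forward_proba(images[val_idx], R_all[val_idx])
                report = evaluate_predictions(y_idx[val_idx], prob)
                row["val_acc"], row["val_auc"] = report.acc, report.auc
                metric = report.auc if np.isfinite(report.auc) else report.acc
                if metric > best_metric:
                    best_metric, best_epoch, stall = metric, epoch, 0
                    best_state = clone_state(self.network_)
                elif metric == best_metric:
                    # the validation metric is coarse on a small holdout and
                    # plateaus often; on exact ties keep the later (more
                    # trained) checkpoint, but still count toward patience
                    best_epoch = epoch
                    best_state = clone_state(self.network_)
                    stall += 1
                else:
                    stall += 1
            history.append(row)
            if len(val_idx) and stall >= self.patience:
                break

        if best_state is not None:
            self.network_.load_state_dict(best_state)
        self.best_epoch_ = best_epoch if best_state is not None else self.epochs
        self.history_ = pd.DataFrame(history)
        self.n_classes_ = n_classes
        return self

    def _forward_proba(self, images, R, batch_size: int = 64):
        self.network_.eval()
        probs = []
        for start in range(0, len(images), batch_size):
            out = self.network_(
                Tensor(images[start : start + batch_size]),
                Tensor(R[start : start + batch_size]),
            )
            probs.append(softmax(out["logits"], axis=1).data)
        self.network_.train()
        return np.vstack(probs)

    def predict_proba(self, X, masks=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=float)
        table = self._extract(X, masks)
        R = self._prepare_radiomics(table.values)
        return self._forward_proba(X.astype(self._np_dtype()), R)

    def predict(self, X, masks=None):
        prob = self.predict_proba(X, masks)
        return self.classes_[prob.argmax(axis=1)]

    def score(self, X, y, masks=None):
        return float(np.mean(self.predict(X, masks) == np.asarray(y)))

    def latent_views(self, X, masks=None):
        """Eval-mode decorrelation views (H1, H2) for the given samples."""
        X = np.asarray(X, dtype=float)
        table = self._extract(X, masks)
        R = self._prepare_radiomics(table.values)
        self.network_.eval()
        out = self.network_(
            Tensor(X.astype(self._np_dtype())), Tensor(R)
        )
        self.network_.train()
        return out["H1"].data, out["H2"].data

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint the fitted pipeline (network state + preprocessing)."""
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "classes": np.asarray(self.classes_).tolist(),
            "feature_names": self.feature_names_,
            "selected_idx": self.selected_idx_.tolist(),
            "n_classes": int(self.n_classes_),
        }
        arrays = {f"state/{k}": v for k, v in self.network_.state_dict().items()}
        arrays["scaler_mean"] = self.scaler_.mean_
        arrays["scaler_scale"] = self.scaler_.scale_
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "FusionImageClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"]).decode())
        params = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in meta["params"].items()
        }
        clf = cls(**params)
        clf.classes_ = np.asarray(meta["classes"])
        clf.feature_names_ = meta["feature_names"]
        clf.selected_idx_ = np.asarray(meta["selected_idx"])
        clf.n_classes_ = meta["n_classes"]
        clf.scaler_ = StandardScaler()
        clf.scaler_.mean_ = data["scaler_mean"]
        clf.scaler_.scale_ = data["scaler_scale"]
        clf.scaler_.var_ = data["scaler_scale"] ** 2
        clf.scaler_.n_features_in_ = len(data["scaler_mean"])
        rng = np.random.default_rng(0)
        clf.network_ = FusionNetwork(
            k=len(clf.selected_idx_), n_classes=clf.n_classes_, rng=rng,
            d=clf.unified_dim, native_dim=clf.native_dim, use_aca=clf.use_aca,
            head=clf.head, gate_mode=clf.gate_mode,
            use_residual_gate=clf.use_residual_gate,
            kan_grid_size=clf.kan_grid_size, kan_order=clf.kan_order,
            kan_depth=clf.kan_depth, deco_hidden_dim=clf.deco_hidden_dim,
            dtype=clf._np_dtype(),
        )
        clf.network_.load_state_dict(
            {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
        )
        clf.history_ = pd.DataFrame()
        return clf


def _mode_params(mode: str) -> dict:
    if mode == "baseline_fc":
        return {"use_aca": False, "alpha_max": 0.0, "head": "fc"}
    if mode == "aca_fc":
        return {"use_aca": True, "alpha_max": 0.0, "head": "fc"}
    if mode == "aca_deco_fc":
        return {"use_aca": True, "head": "fc"}
    if mode == "aca_deco_kan":
        return {"use_aca": True, "head": "kan"}
    raise ValueError(f"unknown ablation mode '{mode}'")


def train(X, y, masks=None, cfg: TrainConfig | None = None,
          **overrides) -> FusionImageClassifier:
    """Fit a classifier configured from a :class:`TrainConfig`."""
    cfg = cfg or TrainConfig()
    params = dict(
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, weight_decay=cfg.weight_decay,
        alpha_max=cfg.alpha_max, unified_dim=cfg.unified_dim,
        native_dim=cfg.native_dim, val_fraction=cfg.val_fraction,
        patience=cfg.patience, augment=cfg.augment, random_state=cfg.seed,
    )
    params.update(_mode_params(cfg.ablation_mode))
    params.update(overrides)
    return FusionImageClassifier(**params).fit(X, y, masks=masks)


def evaluate(clf: FusionImageClassifier, X, y, masks=None) -> MetricsReport:
    """Deterministic eval-mode metrics report on a held-out set."""
    if len(np.asarray(y)) == 0:
        raise ValueError("empty test set")
    prob = clf.predict_proba(X, masks)
    y_idx = np.searchsorted(clf.classes_, np.asarray(y))
    return evaluate_predictions(y_idx, prob)


def run_ablation(X, y, masks=None, modes=ABLATION_MODES,
                 split_ratio: float = 0.8, seed: int = 0,
                 **clf_params) -> tuple[pd.DataFrame, dict[str, MetricsReport]]:
    """Fit every ablation configuration on one shared split and compare.

    All modes share the identical train/test partition and the same seed, so
    differences in the table reflect the architecture, not the data.
    """
    y = np.asarray(y)
    train_idx, test_idx = stratified_split(y, ratio=split_ratio, seed=seed)
    X = np.asarray(X, float)
    masks_arr = None if masks is None else np.asarray(masks)
    rows, reports = [], {}
    for mode in modes:
        params = dict(clf_params)
        params.update(_mode_params(mode))
        params.setdefault("random_state", seed)
        clf = FusionImageClassifier(**params)
        clf.fit(X[train_idx], y[train_idx],
                masks=None if masks_arr is None else masks_arr[train_idx])
        report = evaluate(
            clf, X[test_idx], y[test_idx],
            masks=None if masks_arr is None else masks_arr[test_idx],
        )
        reports[mode] = report
        rows.append({"mode": mode, "acc": report.acc, "auc": report.auc,
                     "sen": report.sen, "spe": report.spe,
                     "n_test": len(test_idx)})
    table = pd.DataFrame(rows)
    table.attrs["test_idx"] = test_idx
    return table, reports
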