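"""Parameterized CNN family for two-level collateral classification.

Each architecture is determined by a point of the hyperparameter grid:
kernel size K, first-layer filter count F, number of convolutional
blocks N_conv (filters double per block), fully connected width, and
batch size.  Inputs are the two binarized vessel-morphology images of a
patient (ganglionic and supraganglionic levels), resized to 128x128 and
stacked as a 2-channel tensor.  Training uses tenfold augmentation
(small-angle rotations and horizontal flips) on the training images
only, and early stopping monitored on validation AUC with best-weight
restoration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize
from sklearn.metrics import roc_auc_score

from ._nn import Adam, EarlyStopping, SmallCNN
from .phantom import PatientRecord

__all__ = [
    "KERNEL_OPTIONS",
    "FILTER_OPTIONS",
    "DEPTH_OPTIONS",
    "FC_OPTIONS",
    "BATCH_OPTIONS",
    "INPUT_SIZE",
    "HyperParams",
    "ArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "build_architecture",
    "prepare_input",
    "augment_tenfold",
    "train_model",
    "predict",
]

# default option sets; full Cartesian grid has 3*2*4*2*4 = 192 points
KERNEL_OPTIONS = (3, 5, 7)
FILTER_OPTIONS = (8, 16)
DEPTH_OPTIONS = (2, 3, 4, 5)
FC_OPTIONS = (64, 128)
BATCH_OPTIONS = (8, 16, 32, 64)

INPUT_SIZE = 128
N_CHANNELS = 2
AUGMENT_FACTOR = 10

# fixed augmentation family: small-angle rotations and horizontal flips
_AUGMENT_POOL = tuple(
    [("rot", a) for a in (2, -2, 4, -4, 6, -6)]
    + [("flip", 0)]
    + [("fliprot", a) for a in (2, -2, 4, -4, 6, -6)]
)


@dataclass(frozen=True)
class HyperParams:
    """One point of the (K, F, N_conv, fc, batch) hyperparameter grid."""

    kernel_size: int
    first_filters: int
    n_conv: int
    fc_nodes: int
    batch_size: int

    def validate(self, grid=None) -> None:
        from .sweep import GridConfig

        grid = grid if grid is not None else GridConfig()
        checks = [
            ("kernel_size", self.kernel_size, grid.kernel_options),
            ("first_filters", self.first_filters, grid.filter_options),
            ("n_conv", self.n_conv, grid.depth_options),
            ("fc_nodes", self.fc_nodes, grid.fc_options),
            ("batch_size", self.batch_size, grid.batch_options),
        ]
        for name, value, options in checks:
            if value not in options:
                raise ValueError(f"{name}={value} not in configured grid {options}")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Concrete layer plan derived from a grid point.

    ``conv_layers`` lists (kernel, filters) per block; every block is
    convolution ('same'), rectified-linear activation, then 2x2
    downsampling, so the l-th block has F * 2**(l-1) filters.
    """

    hyperparams: HyperParams
    input_shape: tuple[int, int, int]
    conv_layers: tuple[tuple[int, int], ...]
    fc_nodes: int

    def n_parameters(self) -> int:
        """Trainable parameter count (weights + biases), closed form."""
        h, w, c_in = self.input_shape
        total = 0
        for k, f in self.conv_layers:
            total += k * k * c_in * f + f
            c_in = f
            h //= 2
            w //= 2
        flat = h * w * c_in
        total += flat * self.fc_nodes + self.fc_nodes  # hidden dense
        total += self.fc_nodes * 1 + 1  # sigmoid head
        return total


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop settings; the early-stopping monitor is validation AUC."""

    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def build_architecture(hp: HyperParams, grid=None) -> ArchitectureSpec:
    """Deterministically expand a grid point into a layer plan."""
    hp.validate(grid)
    conv_layers = tuple(
        (hp.kernel_size, hp.first_filters * 2**l) for l in range(hp.n_conv)
    )
    return ArchitectureSpec(
        hyperparams=hp,
        input_shape=(INPUT_SIZE, INPUT_SIZE, N_CHANNELS),
        conv_layers=conv_layers,
        fc_nodes=hp.fc_nodes,
    )


def _binarize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == bool:
        return arr
    return arr >= (128 if arr.max(initial=0) > 1 else 0.5)


def prepare_input(rec: PatientRecord) -> np.ndarray:
    """Stack the two levels as a 128x128x2 binary tensor.

    Resizing is nearest-neighbour so masks stay strictly binary; output
    values are {0.0, 1.0} float32.
    """
    planes = []
    for img in (rec.ganglionic, rec.supraganglionic):
        if img is None:
            raise ValueError(f"patient {rec.patient_id}: missing level image")
        mask = _binarize(img).astype(np.float32)
        if mask.shape != (INPUT_SIZE, INPUT_SIZE):
            mask = resize(
                mask,
                (INPUT_SIZE, INPUT_SIZE),
                order=0,
                preserve_range=True,
                anti_aliasing=False,
            )
        planes.append((mask >= 0.5).astype(np.float32))
    return np.stack(planes, axis=-1)


def _apply_variant(img: np.ndarray, kind: str, angle: float) -> np.ndarray:
    out = np.asarray(img, dtype=np.float32)
    if kind in ("flip", "fliprot"):
        out = out[:, ::-1]
    if kind in ("rot", "fliprot") and angle != 0:
        out = ndimage.rotate(
            out, angle, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
        )
    return (out >= 0.5).astype(np.float32)


def augment_tenfold(images: list[np.ndarray], seed: int = 0) -> list[np.ndarray]:
    """Original plus nine seeded variants per image (10x the input length).

    Variants are drawn without replacement from the fixed family of
    small-angle rotations (+-2, +-4, +-6 degrees), horizontal flip, and
    flip-plus-rotation; rotated masks are re-binarized at 0.5.
    """
    if len(images) == 0:
        raise ValueError("empty image list")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(_AUGMENT_POOL), size=AUGMENT_FACTOR - 1, replace=False)
    variants = [_AUGMENT_POOL[i] for i in idx]
    out: list[np.ndarray] = []
    for img in images:
        img = (np.asarray(img, dtype=np.float32) >= 0.5).astype(np.float32)
        out.append(img)
        out.extend(_apply_variant(img, kind, ang) for kind, ang in variants)
    return out


@dataclass
class TrainedModel:
    """Fitted CNN plus its architecture and per-epoch training log."""

    arch: ArchitectureSpec
    net: SmallCNN
    history: list[dict] = field(default_factory=list)

    @property
    def best_val_auc(self) -> float:
        return max(h["val_auc"] for h in self.history) if self.history else float("nan")


def _stack_inputs(records: list[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([prepare_input(r) for r in records])
    y = np.array([r.label for r in records], dtype=np.float32)
    return x, y


def train_model(
    arch: ArchitectureSpec,
    train_records: list[PatientRecord],
    val_records: list[PatientRecord],
    cfg: TrainConfig,
) -> TrainedModel:
    """Fit one architecture with AUC-monitored early stopping.

    Training inputs are augmented tenfold (when ``cfg.augment``);
    validation stays un-augmented.  The epoch with the best validation
    AUC supplies the final weights.
    """
    train_ids = {r.patient_id for r in train_records}
    if train_ids & {r.patient_id for r in val_records}:
        raise ValueError("train and validation sets overlap at patient level")
    x_tr, y_tr = _stack_inputs(train_records)
    x_val, y_val = _stack_inputs(val_records)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class")
    if cfg.augment:
        aug = augment_tenfold(list(x_tr), seed=cfg.seed)
        x_tr = np.stack(aug)
        y_tr = np.repeat(y_tr, AUGMENT_FACTOR)

    rng = np.random.default_rng(cfg.seed)
    net = SmallCNN(arch.input_shape, arch.conv_layers, arch.fc_nodes, rng)
    opt = Adam(net.params, lr=cfg.learning_rate)
    stopper = EarlyStopping(patience=cfg.patience)
    model = TrainedModel(arch=arch, net=net)
    best_weights = net.get_weights()
    batch = arch.hyperparams.batch_size
    n = len(x_tr)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            sel = order[start : start + batch]
            losses.append(net.train_batch(x_tr[sel], y_tr[sel], opt))
        val_probs = net.predict_proba(x_val)
        val_auc = float(roc_auc_score(y_val, val_probs)) if len(np.unique(y_val)) > 1 else float("nan")
        model.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": val_auc}
        )
        monitored = val_auc if np.isfinite(val_auc) else -1.0
        stop = stopper.update(epoch, monitored)
        # snapshot the latest epoch tied for the best AUC: among
        # AUC-equivalent epochs the later one is further converged, which
        # keeps probability scales comparable when folds are pooled
        if monitored >= stopper.best:
            best_weights = net.get_weights()
        if stop:
            break
    net.set_weights(best_weights)
    return model


def predict(model: TrainedModel, records: list[PatientRecord]) -> np.ndarray:
    """Per-patient probability of good (positive) collateral.

    Evaluation always runs on the original, un-augmented images.
    """
    if not records:
        return np.zeros(0)
    x, _ = _stack_inputs(records)
    return model.net.predict_proba(x)


def save_model(model: TrainedModel, path) -> None:
    """Serialize weights and layer plan to an .npz checkpoint."""
    meta = dict(
        input_shape=np.array(model.arch.input_shape),
        conv_layers=np.array(model.arch.conv_layers),
        fc_nodes=np.array(model.arch.fc_nodes),
        hp=np.array(
            [
                model.arch.hyperparams.kernel_size,
                model.arch.hyperparams.first_filters,
                model.arch.hyperparams.n_conv,
                model.arch.hyperparams.fc_nodes,
                model.arch.hyperparams.batch_size,
            ]
        ),
    )
    np.savez(path, **meta, **{f"param_{k}": v for k, v in model.net.params.items()})


def load_model(path) -> TrainedModel:
    data = np.load(path)
    hp = HyperParams(*(int(v) for v in data["hp"]))
    arch = build_architecture(hp)
    net = SmallCNN(
        arch.input_shape, arch.conv_layers, arch.fc_nodes, np.random.default_rng(0)
    )
    net.set_weights(
        {k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")}
    )
    return TrainedModel(arch=arch, net=net)
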