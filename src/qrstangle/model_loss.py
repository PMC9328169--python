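"""CNN1D regressor and composite direction/angle loss.

The model maps the signal-averaged beats of ``j`` input leads (550 samples
each at 250 Hz) plus scaled sex/age metadata to the six coordinates of the
estimated dominant vectors ``u_QRS`` and ``u_T``; the spatial QRS-T angle is
then the angle between the two estimated vectors.  Predicting the vectors
rather than the angle lets the network exploit whatever spatial information
the lead subset carries: two patients with the same angle can have their
vector pairs in entirely different octants.

Architecture (feature extraction): ``D`` sequential blocks.  Block 1 applies
a depthwise convolution (``k/j`` private kernels per lead, size 3, stride 1)
so each lead learns its own features, followed by layer normalization and
LeakyReLU(0.1).  Blocks 2..D-1 hold two conv/LN/LeakyReLU layer structures
with a residual connection (1x1 convolution equalizes channel counts) and
end in max pooling; the channel count doubles in each successive residual
block.  Block D repeats the double layer structure and finishes with global
average pooling and dropout (p = 0.25).  The regression head is three dense
layers -- metadata is concatenated to the first -- the first two with layer
normalization and LeakyReLU, the last linear with six outputs.

The training loss is the weighted composite

    L = w1 * (Ld(u_QRS, u_QRS_hat) + Ld(u_T, u_T_hat)) + w2 * L_alpha,

where Ld is the Euclidean distance between unit-normalized vectors (range
[0, 2], with 2 at exactly antiparallel directions) and L_alpha is the mean
absolute angle error in radians, putting both terms on comparable scales.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .core_geometry import DegenerateVectorError

__all__ = [
    "ArrayDataset",
    "CnnRegressor",
    "DEFAULT_CONFIGS",
    "LEAD_SUBSETS",
    "ModelConfig",
    "PredictionPair",
    "TrainConfig",
    "angle_loss",
    "angles_between",
    "build_model",
    "composite_loss",
    "composite_loss_and_grad",
    "euclid_loss",
    "load_model",
    "predict_angle",
    "save_model",
    "train",
]

#: Lead subsets supported out of the box (arbitrary subsets also work).
LEAD_SUBSETS = {
    "xyz": ("X", "Y", "Z"),
    "two_precordial": ("I", "aVF", "V2", "V6"),
    "one_precordial": ("I", "II", "aVF", "V2"),
    "frontal": ("I", "II", "aVL", "aVR"),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of blocks D (2-5 explored), ``initial_kernels``
    the first-block kernel budget k (8 or 16), split across the input leads.
    ``w1``/``w2`` weigh the direction and angle loss terms; (0.8, 0.2) is the
    best-performing weighting and the default.
    """

    depth: int = 3
    initial_kernels: int = 16
    leads: tuple[str, ...] = LEAD_SUBSETS["one_precordial"]
    w1: float = 0.8
    w2: float = 0.2
    dropout_rate: float = 0.25
    leaky_slope: float = 0.1
    dense_widths: tuple[int, int] = (64, 32)
    input_length: int = 550

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.initial_kernels < len(self.leads):
            raise ValueError(
                f"initial_kernels={self.initial_kernels} < {len(self.leads)} leads: "
                "the depthwise split needs at least one kernel per lead"
            )
        if not (self.w1 + self.w2) > 0:
            raise ValueError("w1 + w2 must be positive")


#: Best configurations per lead subset: XYZ needs fewer kernels but more
#: depth; reduced-lead subsets do best shallower with more kernels.
DEFAULT_CONFIGS = {
    "xyz": ModelConfig(depth=4, initial_kernels=8, leads=LEAD_SUBSETS["xyz"]),
    "two_precordial": ModelConfig(depth=3, initial_kernels=16, leads=LEAD_SUBSETS["two_precordial"]),
    "one_precordial": ModelConfig(depth=3, initial_kernels=16, leads=LEAD_SUBSETS["one_precordial"]),
    "frontal": ModelConfig(depth=3, initial_kernels=16, leads=LEAD_SUBSETS["frontal"]),
}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: batches of 8 at an initial learning rate of
    0.001 for 100 epochs, halving the rate every 20 epochs."""

    batch_size: int = 8
    initial_lr: float = 1e-3
    epochs: int = 100
    lr_halving_period: int = 20
    seed: int = 0

    def learning_rate(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch number."""
        return self.initial_lr * 0.5 ** ((epoch - 1) // self.lr_halving_period)


@dataclass(frozen=True)
class PredictionPair:
    """Predicted dominant vectors and the angle between them (degrees)."""

    u_qrs_hat: np.ndarray
    u_t_hat: np.ndarray
    alpha_hat: float
    degenerate: bool = False  # a predicted vector was near zero magnitude


@dataclass
class ArrayDataset:
    """Batched training arrays: inputs, metadata, and vector/angle targets."""

    x: np.ndarray  # (n, 550, j)
    meta: np.ndarray  # (n, 2): sex_code, age_scaled
    u_qrs: np.ndarray  # (n, 3), mV
    u_t: np.ndarray  # (n, 3), mV
    alpha_deg: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = self.x.shape[0]
        if not all(a.shape[0] == n for a in (self.meta, self.u_qrs, self.u_t, self.alpha_deg)):
            raise ValueError("dataset arrays must share the leading dimension")

    def __len__(self) -> int:
        return self.x.shape[0]

    @classmethod
    def from_pairs(cls, inputs, labels) -> "ArrayDataset":
        """Assemble from parallel ModelInput / AngleLabel sequences."""
        return cls(
            x=np.stack([mi.matrix for mi in inputs]),
            meta=np.array([[mi.sex_code, mi.age_scaled] for mi in inputs]),
            u_qrs=np.stack([lb.u_qrs for lb in labels]),
            u_t=np.stack([lb.u_t for lb in labels]),
            alpha_deg=np.array([lb.alpha for lb in labels]),
        )


# ---------------------------------------------------------------------------
# Loss terms
# ---------------------------------------------------------------------------

def _normalize_rows(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.atleast_2d(np.asarray(u, dtype=float))
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms == 0.0):
        raise DegenerateVectorError("zero-magnitude vector in loss input")
    return u / norms[:, None], norms


def euclid_loss(u: np.ndarray, u_hat: np.ndarray) -> float:
    """Batch-mean Euclidean distance between unit-normalized vectors, in [0, 2].

    Magnitudes are ignored: only the directions enter.  Accepts single
    vectors or ``(n, 3)`` batches.
    """
    un, _ = _normalize_rows(u)
    vn, _ = _normalize_rows(u_hat)
    return float(np.linalg.norm(un - vn, axis=1).mean())


def angles_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise angles between two (n, 3) batches, in radians."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    cross = np.cross(a, b)
    return np.arctan2(np.linalg.norm(cross, axis=1), np.einsum("ij,ij->i", a, b))


def angle_loss(alpha: np.ndarray, alpha_hat: np.ndarray) -> float:
    """Mean absolute angle error over the batch, both arguments in radians."""
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    alpha_hat = np.atleast_1d(np.asarray(alpha_hat, dtype=float))
    if alpha.shape != alpha_hat.shape:
        raise ValueError("angle batches must have equal shape")
    return float(np.abs(alpha - alpha_hat).mean())


def composite_loss(
    u_qrs: np.ndarray,
    u_t: np.ndarray,
    alpha_deg: np.ndarray,
    u_qrs_hat: np.ndarray,
    u_t_hat: np.ndarray,
    w1: float,
    w2: float,
) -> float:
    """Composite loss ``w1 * (Ld_QRS + Ld_T) + w2 * L_alpha`` (L_alpha in radians).

    The estimated angle is recomputed from the predicted vectors, so the loss
    is zero exactly when both predicted directions match the targets.
    """
    loss, _, _ = composite_loss_and_grad(u_qrs, u_t, alpha_deg, u_qrs_hat, u_t_hat, w1, w2)
    return loss


def _euclid_grad(u_target_unit: np.ndarray, u_hat: np.ndarray) -> np.ndarray:
    """Row-wise gradient of ||unit(u_hat) - t_unit|| w.r.t. u_hat."""
    vn, norms = _normalize_rows(u_hat)
    e = vn - u_target_unit
    d = np.linalg.norm(e, axis=1)
    grad = np.zeros_like(vn)
    ok = d > 1e-12
    proj = e[ok] - vn[ok] * np.einsum("ij,ij->i", vn[ok], e[ok])[:, None]
    grad[ok] = proj / (d[ok] * norms[ok])[:, None]
    return grad


def _angle_grads(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angle between rows of a and b (radians) and its gradients w.r.t. both."""
    an, na = _normalize_rows(a)
    bn, nb = _normalize_rows(b)
    cos = np.clip(np.einsum("ij,ij->i", an, bn), -1.0, 1.0)
    ang = np.arccos(cos)
    sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-16))
    # d(ang)/da = (an * cos - bn) / (|a| * sin); symmetric for b
    da = (an * cos[:, None] - bn) / (na * sin)[:, None]
    db = (bn * cos[:, None] - an) / (nb * sin)[:, None]
    return ang, da, db


def composite_loss_and_grad(
    u_qrs: np.ndarray,
    u_t: np.ndarray,
    alpha_deg: np.ndarray,
    u_qrs_hat: np.ndarray,
    u_t_hat: np.ndarray,
    w1: float,
    w2: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Composite loss plus analytic gradients w.r.t. the predicted vectors.

    Returns ``(loss, d/du_qrs_hat, d/du_t_hat)`` with gradients shaped
    ``(n, 3)``; used directly by backpropagation and checked against finite
    differences in the test suite.
    """
    uq, _ = _normalize_rows(u_qrs)
    ut, _ = _normalize_rows(u_t)
    uq_hat = np.atleast_2d(np.asarray(u_qrs_hat, dtype=float))
    ut_hat = np.atleast_2d(np.asarray(u_t_hat, dtype=float))
    alpha_rad = np.radians(np.atleast_1d(np.asarray(alpha_deg, dtype=float)))
    n = uq.shape[0]

    vq, _ = _normalize_rows(uq_hat)
    vt, _ = _normalize_rows(ut_hat)
    ld_q = np.linalg.norm(vq - uq, axis=1)
    ld_t = np.linalg.norm(vt - ut, axis=1)
    gq = _euclid_grad(uq, uq_hat)
    gt = _euclid_grad(ut, ut_hat)

    ang_hat, d_ang_q, d_ang_t = _angle_grads(uq_hat, ut_hat)
    diff = ang_hat - alpha_rad
    sign = np.sign(diff)

    loss = w1 * (ld_q.mean() + ld_t.mean()) + w2 * np.abs(diff).mean()
    grad_q = (w1 * gq + w2 * sign[:, None] * d_ang_q) / n
    grad_t = (w1 * gt + w2 * sign[:, None] * d_ang_t) / n
    return float(loss), grad_q, grad_t


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CnnRegressor:
    """Depthwise/residual CNN1D with a metadata-aware regression head.

    Construction is deterministic given ``config`` and ``seed``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        j = len(config.leads)
        per_lead = config.initial_kernels // j
        k = config.initial_kernels

        self.block1: list[_nn.Layer] = [
            _nn.DepthwiseConv1d(j, per_lead, 3, rng),
            _nn.LayerNorm(j * per_lead),
            _nn.LeakyReLU(config.leaky_slope),
        ]
        c_prev = j * per_lead

        def layer_structure(c_in: int, c_out: int) -> list[_nn.Layer]:
            return [
                _nn.Conv1d(c_in, c_out, 3, rng),
                _nn.LayerNorm(c_out),
                _nn.LeakyReLU(config.leaky_slope),
            ]

        # Residual blocks d = 2 .. D-1, channel count doubling each block.
        self.res_blocks: list[dict] = []
        for d in range(2, config.depth):
            c_out = k * 2 ** (d - 2)
            block = {
                "main": layer_structure(c_prev, c_out) + layer_structure(c_out, c_out),
                "proj": _nn.Conv1d(c_prev, c_out, 1, rng),
                "pool": _nn.MaxPool1d(2),
            }
            self.res_blocks.append(block)
            c_prev = c_out

        # Last block: double layer structure then global average pooling.
        c_last = k * 2 ** (config.depth - 2)
        self.last_block = layer_structure(c_prev, c_last) + layer_structure(c_last, c_last)
        self.gap = _nn.GlobalAvgPool1d()
        self.dropout = _nn.Dropout(config.dropout_rate, self._dropout_rng)

        d1, d2 = config.dense_widths
        self.head: list[_nn.Layer] = [
            _nn.Dense(c_last + 2, d1, rng),  # metadata concatenated here
            _nn.LayerNorm(d1),
            _nn.LeakyReLU(config.leaky_slope),
            _nn.Dense(d1, d2, rng),
            _nn.LayerNorm(d2),
            _nn.LeakyReLU(config.leaky_slope),
            _nn.Dense(d2, 6, rng),
        ]

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self) -> list[_nn.Layer]:
        layers = list(self.block1)
        for block in self.res_blocks:
            layers.extend(block["main"])
            layers.append(block["proj"])
        layers.extend(self.last_block)
        layers.extend(self.head)
        return layers

    def parameters(self) -> list[_nn.Parameter]:
        return [p for layer in self._all_layers() for p in layer.parameters()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, meta: np.ndarray, train: bool = False) -> np.ndarray:
        """Map ``(n, 550, j)`` inputs and ``(n, 2)`` metadata to ``(n, 6)`` outputs."""
        h = np.asarray(x, dtype=float)
        for layer in self.block1:
            h = layer.forward(h, train)
        for block in self.res_blocks:
            shortcut = block["proj"].forward(h, train)
            for layer in block["main"]:
                h = layer.forward(h, train)
            h = h + shortcut
            h = block["pool"].forward(h, train)
        for layer in self.last_block:
            h = layer.forward(h, train)
        h = self.gap.forward(h, train)
        h = self.dropout.forward(h, train)
        h = np.concatenate([h, np.asarray(meta, dtype=float)], axis=1)
        self._n_features = h.shape[1] - 2
        for layer in self.head:
            h = layer.forward(h, train)
        return h

    def backward(self, dout: np.ndarray) -> None:
        g = dout
        for layer in reversed(self.head):
            g = layer.backward(g)
        g = g[:, : self._n_features]  # metadata columns carry no gradient
        g = self.dropout.backward(g)
        g = self.gap.backward(g)
        for layer in reversed(self.last_block):
            g = layer.backward(g)
        for block in reversed(self.res_blocks):
            g = block["pool"].backward(g)
            g_short = g
            for layer in reversed(block["main"]):
                g = layer.backward(g)
            g = g + block["proj"].backward(g_short)
        for layer in reversed(self.block1):
            g = layer.backward(g)


def build_model(config: ModelConfig, seed: int = 0) -> CnnRegressor:
    """Construct the regressor; raises if ``k`` cannot be split across leads."""
    return CnnRegressor(config, seed=seed)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def predict_angle(
    model: CnnRegressor,
    x: np.ndarray,
    meta: np.ndarray,
    degenerate_tol: float = 1e-6,
) -> list[PredictionPair]:
    """Predict dominant-vector pairs and angles (degrees) for a batch.

    Near-zero predicted vectors are flagged rather than raising, since an
    untrained model may legitimately emit them.
    """
    out = model.forward(np.atleast_3d(x), np.atleast_2d(meta), train=False)
    pairs = []
    for row in out:
        uq, ut = row[:3], row[3:]
        nq, nt = np.linalg.norm(uq), np.linalg.norm(ut)
        degenerate = bool(nq < degenerate_tol or nt < degenerate_tol)
        if degenerate:
            alpha = float("nan")
        else:
            alpha = float(np.degrees(angles_between(uq, ut)[0]))
        pairs.append(PredictionPair(uq.copy(), ut.copy(), alpha, degenerate))
    return pairs


def _epoch_loss(model: CnnRegressor, ds: ArrayDataset, config: ModelConfig) -> float:
    out = model.forward(ds.x, ds.meta, train=False)
    loss, _, _ = composite_loss_and_grad(
        ds.u_qrs, ds.u_t, ds.alpha_deg, out[:, :3], out[:, 3:], config.w1, config.w2
    )
    return loss


def train(
    model: CnnRegressor,
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    tc: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Train with Adam under the composite loss and the stated schedule.

    The learning rate starts at ``tc.initial_lr`` and halves every
    ``tc.lr_halving_period`` epochs.  Returns the per-epoch history (train
    and validation loss, validation median absolute angle error in degrees).

    Raises
    ------
    RuntimeError
        If the loss turns non-finite (with the offending epoch/batch).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    config = model.config
    rng = np.random.default_rng(tc.seed)
    optimizer = _nn.Adam(model.parameters(), lr=tc.initial_lr)
    history = []
    for epoch in range(1, tc.epochs + 1):
        optimizer.lr = tc.learning_rate(epoch)
        order = rng.permutation(len(train_set))
        running = 0.0
        n_batches = 0
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            out = model.forward(train_set.x[idx], train_set.meta[idx], train=True)
            loss, gq, gt = composite_loss_and_grad(
                train_set.u_qrs[idx],
                train_set.u_t[idx],
                train_set.alpha_deg[idx],
                out[:, :3],
                out[:, 3:],
                config.w1,
                config.w2,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {loss}"
                )
            optimizer.zero_grad()
            model.backward(np.concatenate([gq, gt], axis=1))
            optimizer.step()
            running += loss
            n_batches += 1

        val_loss = _epoch_loss(model, val_set, config)
        preds = model.forward(val_set.x, val_set.meta, train=False)
        alpha_hat = np.degrees(angles_between(preds[:, :3], preds[:, 3:]))
        med_err = float(np.median(np.abs(alpha_hat - val_set.alpha_deg)))
        history.append(
            {
                "epoch": epoch,
                "lr": optimizer.lr,
                "train_loss": running / max(n_batches, 1),
                "val_loss": val_loss,
                "val_median_abs_err_deg": med_err,
            }
        )
    return pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: CnnRegressor, path: str | Path) -> None:
    """Save weights as .npz with a sidecar JSON of the configuration."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    cfg = asdict(model.config)
    cfg["leads"] = list(cfg["leads"])
    cfg["dense_widths"] = list(cfg["dense_widths"])
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_model(path: str | Path) -> CnnRegressor:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["leads"] = tuple(cfg["leads"])
    cfg["dense_widths"] = tuple(cfg["dense_widths"])
    model = CnnRegressor(ModelConfig(**cfg))
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
    return model
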