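"""Training loop: Adam on MSE loss with validation tracking."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from smv.velocity_net.model import ConvLSTMUNet, NetworkConfig

__all__ = ["TrainingConfig", "mse_loss", "Adam", "train", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainingConfig:
    lr: float = 0.001
    batch: int = 4
    epochs: int = 100
    rng_seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self):
        if self.lr < 0 or self.batch < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean over all elements of squared differences; returns (loss, grad)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


class Adam:
    def __init__(self, model: ConvLSTMUNet, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for name, layer, key in model.named_params():
            self.m[name] = np.zeros_like(layer.params[key])
            self.v[name] = np.zeros_like(layer.params[key])

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for name, layer, key in self.model.named_params():
            g = layer.grads[key]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    model: ConvLSTMUNet
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_state: dict | None = None
    best_val: float = float("inf")


def train(
    inputs: np.ndarray,
    targets: np.ndarray,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainingConfig | None = None,
    split: int | None = None,
    model: ConvLSTMUNet | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Train a ConvLSTM-UNet on (inputs [n,T,H,W], targets [n,2,H,W]).

    ``split`` is the boundary index between training and validation samples;
    when omitted it is derived from ``validation_fraction``. The best
    validation-state parameters are checkpointed in the result. Deterministic
    for a fixed seed. Raises on NaN loss.
    """
    if len(inputs) == 0:
        raise ValueError("empty dataset")
    train_cfg = train_cfg or TrainingConfig()
    net_cfg = net_cfg or NetworkConfig()
    rng = np.random.default_rng(train_cfg.rng_seed)
    model = model or ConvLSTMUNet(net_cfg, rng_seed=train_cfg.rng_seed)
    if split is None:
        n_val = int(round(len(inputs) * train_cfg.validation_fraction))
        split = len(inputs) - n_val
    x_tr, y_tr = inputs[:split], targets[:split]
    x_va, y_va = inputs[split:], targets[split:]
    if len(x_tr) == 0:
        raise ValueError("no training samples after split")
    opt = Adam(model, lr=train_cfg.lr)
    result = TrainResult(model=model)

    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(x_tr))
        model.train(True)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(x_tr), train_cfg.batch):
            idx = order[start : start + train_cfg.batch]
            xb = x_tr[idx][:, :, None]  # (B, T, 1, H, W)
            yb = y_tr[idx]
            model.zero_grad()
            pred = model.forward(xb)
            loss, grad = mse_loss(pred, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: {loss}")
            model.backward(grad)
            opt.step()
            ep_loss += loss
            n_batches += 1
        result.train_loss.append(ep_loss / n_batches)
        if len(x_va):
            vl = evaluate_loss(model, x_va, y_va, batch=train_cfg.batch)
            result.val_loss.append(vl)
            if vl < result.best_val:
                result.best_val = vl
                result.best_state = model.state_dict()
        if verbose:
            msg = f"epoch {epoch + 1}/{train_cfg.epochs} train {result.train_loss[-1]:.5f}"
            if result.val_loss:
                msg += f" val {result.val_loss[-1]:.5f}"
            print(msg, flush=True)
    if result.best_state is None:
        result.best_state = model.state_dict()
    return result


def evaluate_loss(model: ConvLSTMUNet, x, y, batch: int = 4) -> float:
    model.train(False)
    total, n = 0.0, 0
    for start in range(0, len(x), batch):
        xb = x[start : start + batch][:, :, None]
        pred = model.forward(xb)
        loss, _ = mse_loss(pred, y[start : start + batch])
        total += loss * len(xb)
        n += len(xb)
    model.train(True)
    return total / n


def save_checkpoint(model: ConvLSTMUNet, path: str, meta: dict | None = None) -> None:
    """Parameters to .npz with a JSON metadata sidecar (<path>.json)."""
    sd = model.state_dict()
    np.savez(path, **sd)
    cfg = model.cfg
    sidecar = {
        "depth": cfg.depth,
        "base_width": cfg.base_width,
        "lstm_hidden": cfg.lstm_hidden,
        "skip_mode": cfg.skip_mode,
    }
    sidecar.update(meta or {})
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str) -> ConvLSTMUNet:
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    cfg = NetworkConfig(
        depth=meta["depth"],
        base_width=meta["base_width"],
        lstm_hidden=meta["lstm_hidden"],
        skip_mode=meta["skip_mode"],
    )
    model = ConvLSTMUNet(cfg)
    data = np.load(str(path) + (".npz" if not str(path).endswith(".npz") else ""))
    model.load_state_dict({k: data[k] for k in data.files})
    model.train(False)
    return model
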