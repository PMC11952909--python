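"""Physics-informed multilayer perceptron for material-property regression.

The network maps the 16 mechanical-response features to the 10 material
properties. Its training loss augments the data misfit with soft penalties
on the isotropic-elasticity identities, evaluated per tissue compartment on
de-normalized (physical-unit) predictions:

    L = (1/N) sum_i ||N(x_i) - y_i||^2
        + lambda1 * mean|k - E/(3(1-2nu))| + lambda2 * mean|mu - E/(2(1+nu))|

The data term is computed on z-scored targets; each constraint residual is
formed in physical units and divided by the std of its modulus column so the
penalties live on the same scale as the data term (bone spans GPa, disc MPa).
The bone and disc constraint groups are averaged. Everything — forward pass,
backpropagation (including the chain through de-normalization and the
clamped Poisson ratio), and the Adam optimizer — is implemented in numpy and
is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import TrainingDataset
from .fea import FEATURE_NAMES
from .materials import TARGET_NAMES

__all__ = [
    "NetConfig",
    "TrainedNet",
    "PAPER_ARCHITECTURES",
    "pinn_loss",
    "pinn_loss_terms",
    "constraint_residuals",
    "accuracy",
    "train",
    "architecture_sweep",
    "fine_tune",
    "TrainingDivergedError",
]

#: The 11 hidden-layer layouts of the architecture sweep.
PAPER_ARCHITECTURES: Tuple[Tuple[int, ...], ...] = (
    (16,),
    (32,),
    (64,),
    (16, 8),
    (16, 16),
    (32, 16),
    (32, 32),
    (64, 32),
    (64, 64),
    (64, 32, 16),
    (128, 64, 32),
)

# column indices in the 10-target vector
_I_E = {"bone": 0, "disc": 1}
_I_NU = {"bone": 2, "disc": 3}
_I_K = {"bone": 4, "disc": 5}
_I_MU = {"bone": 6, "disc": 7}

_NU_EPS = 1e-6
#: width (in scaled-residual units) of the smoothed |.| gradient near zero
_PENALTY_SMOOTHING = 0.01


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimization settings.

    hidden_layers : widths of the hidden layers (output layer is linear, 10 wide)
    lambda1, lambda2 : weights of the bulk- and shear-consistency penalties
        (normalized-loss units)
    batch_size : None for full-batch gradient steps
    patience : early-stopping patience on validation loss, in epochs
    lambda_warmup : fraction f of the epoch budget before the constraint
        penalties switch on; their weight then ramps linearly to full over the
        next f of the budget. Letting the data fit take shape first prevents
        the constraint force from steering early training into poor basins;
        model selection always scores validation loss at the full weights.
    """

    hidden_layers: Tuple[int, ...] = (64, 32, 16)
    activation: str = "relu"
    lambda1: float = 0.1
    lambda2: float = 0.1
    learning_rate: float = 1e-3
    lr_decay: str = "cosine"
    epochs: int = 2000
    batch_size: Optional[int] = None
    patience: int = 300
    lambda_warmup: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be positive")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.lr_decay not in ("cosine", "none"):
            raise ValueError(f"unknown lr_decay {self.lr_decay!r}")
        if not 0.0 <= self.lambda_warmup < 0.5:
            raise ValueError("lambda_warmup must lie in [0, 0.5)")

    @property
    def architecture_label(self) -> str:
        return "[" + "-".join(str(w) for w in self.hidden_layers) + "]"


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _clamped_nu(nu: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Clamp Poisson predictions into the admissible open interval.

    Returns (clamped values, mask of clamped entries). Clamping keeps the
    penalty finite near the incompressible limit; the event count is logged
    by the training loop rather than raised.
    """
    lo, hi = -1.0 + _NU_EPS, 0.5 - _NU_EPS
    mask = (nu < lo) | (nu > hi)
    return np.clip(nu, lo, hi), mask


def constraint_residuals(pred: np.ndarray, relative: bool = True) -> Dict[str, np.ndarray]:
    """Isotropic-identity residuals of a (N, 10) physical-unit prediction batch.

    Returns per-sample |k - E/(3(1-2nu))| and |mu - E/(2(1+nu))| for each
    tissue; with ``relative`` they are divided by |k| (resp. |mu|).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    out = {}
    for tissue in ("bone", "disc"):
        E = pred[:, _I_E[tissue]]
        nu, _ = _clamped_nu(pred[:, _I_NU[tissue]])
        k, mu = pred[:, _I_K[tissue]], pred[:, _I_MU[tissue]]
        rk = np.abs(k - E / (3.0 * (1.0 - 2.0 * nu)))
        rmu = np.abs(mu - E / (2.0 * (1.0 + nu)))
        if relative:
            rk = rk / np.maximum(np.abs(k), 1e-300)
            rmu = rmu / np.maximum(np.abs(mu), 1e-300)
        out[f"k_{tissue}"] = rk
        out[f"mu_{tissue}"] = rmu
    return out


def pinn_loss_terms(
    pred: np.ndarray,
    target: np.ndarray,
    lambda1: float,
    lambda2: float,
    data_scale: Optional[np.ndarray] = None,
    penalty_scale: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Decomposed physics-informed loss on a (N, 10) batch in physical units.

    data term: mean over the batch of the squared 2-norm of the (optionally
    column-scaled) prediction error. penalty terms: mean absolute residual of
    each isotropic identity, per tissue, divided by the corresponding entry
    of ``penalty_scale`` (the k/mu column scales; default 1) and averaged
    over the bone and disc groups.

    Returns {"total", "mse", "pen_k", "pen_mu", "n_nu_clamped"} with
    total = mse + lambda1 * pen_k + lambda2 * pen_mu exactly.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if pred.shape != target.shape or pred.shape[1] != 10:
        raise ValueError("pred and target must both be (N, 10)")
    ds = np.ones(10) if data_scale is None else np.asarray(data_scale, dtype=float)
    ps = np.ones(10) if penalty_scale is None else np.asarray(penalty_scale, dtype=float)

    err = (pred - target) / ds
    mse = float(np.mean(np.sum(err**2, axis=1)))

    pen_k = pen_mu = 0.0
    n_clamped = 0
    for tissue in ("bone", "disc"):
        E = pred[:, _I_E[tissue]]
        nu, mask = _clamped_nu(pred[:, _I_NU[tissue]])
        n_clamped += int(mask.sum())
        k, mu = pred[:, _I_K[tissue]], pred[:, _I_MU[tissue]]
        rk = np.abs(k - E / (3.0 * (1.0 - 2.0 * nu))) / ps[_I_K[tissue]]
        rmu = np.abs(mu - E / (2.0 * (1.0 + nu))) / ps[_I_MU[tissue]]
        pen_k += float(rk.mean()) / 2.0
        pen_mu += float(rmu.mean()) / 2.0

    total = mse + lambda1 * pen_k + lambda2 * pen_mu
    return {
        "total": total,
        "mse": mse,
        "pen_k": pen_k,
        "pen_mu": pen_mu,
        "n_nu_clamped": n_clamped,
    }


def pinn_loss(
    pred: np.ndarray,
    target: np.ndarray,
    lambda1: float,
    lambda2: float,
    data_scale: Optional[np.ndarray] = None,
    penalty_scale: Optional[np.ndarray] = None,
) -> float:
    """Scalar physics-informed loss (see :func:`pinn_loss_terms`)."""
    return pinn_loss_terms(pred, target, lambda1, lambda2, data_scale, penalty_scale)[
        "total"
    ]


def accuracy(pred: np.ndarray, target: np.ndarray) -> float:
    """Regression accuracy: 100 x mean over samples and outputs of
    max(0, 1 - |yhat - y| / |y|), in physical units."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    rel = np.abs(pred - target) / np.abs(target)
    return float(100.0 * np.mean(np.maximum(0.0, 1.0 - rel)))


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _init_params(layers: Sequence[int], rng: np.random.Generator):
    params = []
    for fan_in, fan_out in zip(layers[:-1], layers[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params.append([W, np.zeros(fan_out)])
    return params


def _forward(params, X, activation):
    """Forward pass; returns output and per-layer activations for backprop."""
    acts = [X]
    h = X
    for i, (W, b) in enumerate(params):
        z = h @ W + b
        if i < len(params) - 1:
            h = np.maximum(z, 0.0) if activation == "relu" else np.tanh(z)
        else:
            h = z
        acts.append(h)
    return h, acts


def _backward(params, acts, dL_dout, activation):
    grads = []
    delta = dL_dout
    for i in range(len(params) - 1, -1, -1):
        W, _ = params[i]
        h_in = acts[i]
        gW = h_in.T @ delta
        gb = delta.sum(axis=0)
        grads.append([gW, gb])
        if i > 0:
            delta = delta @ W.T
            h_prev = acts[i]
            if activation == "relu":
                delta = delta * (h_prev > 0.0)
            else:
                delta = delta * (1.0 - h_prev**2)
    grads.reverse()
    return grads


def _loss_grad_out(
    Yn_pred, Yn_true, y_mean, y_std, lambda1, lambda2
) -> Tuple[Dict[str, float], np.ndarray, int]:
    """Loss terms and gradient w.r.t. the normalized network output."""
    N = len(Yn_pred)
    Yp = Yn_pred * y_std + y_mean  # physical units

    terms = pinn_loss_terms(Yp, Yn_true * y_std + y_mean, lambda1, lambda2,
                            data_scale=y_std, penalty_scale=y_std)

    # data term gradient: mean over batch of squared norms on normalized values
    g = 2.0 * (Yn_pred - Yn_true) / N

    for tissue in ("bone", "disc"):
        iE, iNu, iK, iMu = (
            _I_E[tissue], _I_NU[tissue], _I_K[tissue], _I_MU[tissue],
        )
        E = Yp[:, iE]
        nu, clamp_mask = _clamped_nu(Yp[:, iNu])
        k, mu = Yp[:, iK], Yp[:, iMu]

        one_m2nu = 1.0 - 2.0 * nu
        one_pnu = 1.0 + nu
        sk = y_std[iK]
        smu = y_std[iMu]

        # d|r|/dr is taken as r/sqrt(r^2 + delta^2) (pseudo-Huber smoothing of
        # the kink at r = 0, delta in scaled-residual units): the reported
        # penalty stays the exact |r|, but the gradient vanishes smoothly at
        # consistency instead of oscillating under Adam
        delta = _PENALTY_SMOOTHING
        if lambda1 > 0.0:
            rk = (k - E / (3.0 * one_m2nu)) / sk
            s = rk / np.sqrt(rk**2 + delta**2) * (lambda1 / (2.0 * N * sk))
            g[:, iK] += s * y_std[iK]
            g[:, iE] += s * (-1.0 / (3.0 * one_m2nu)) * y_std[iE]
            dnu = s * (-2.0 * E / (3.0 * one_m2nu**2)) * y_std[iNu]
            g[:, iNu] += np.where(clamp_mask, 0.0, dnu)
        if lambda2 > 0.0:
            rmu = (mu - E / (2.0 * one_pnu)) / smu
            s = rmu / np.sqrt(rmu**2 + delta**2) * (lambda2 / (2.0 * N * smu))
            g[:, iMu] += s * y_std[iMu]
            g[:, iE] += s * (-1.0 / (2.0 * one_pnu)) * y_std[iE]
            dnu = s * (E / (2.0 * one_pnu**2)) * y_std[iNu]
            g[:, iNu] += np.where(clamp_mask, 0.0, dnu)

    return terms, g, terms["n_nu_clamped"]


@dataclass
class TrainedNet:
    """A trained network: parameters, attached normalization, provenance.

    Prediction is a pure function of (input, parameters); serialization via
    :meth:`save`/:meth:`load` round-trips bit-exactly (weights stored as
    repr-precision JSON floats).
    """

    params: List
    config: NetConfig
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    target_names: Tuple[str, ...] = TARGET_NAMES
    history: Dict[str, List[float]] = field(default_factory=dict)
    accuracies: Dict[str, float] = field(default_factory=dict)
    n_nu_clamped: int = 0
    meta: Dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Physical-unit predictions for physical-unit features (N, 16)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xn = (X - self.x_mean) / self.x_std
        Yn, _ = _forward(self.params, Xn, self.config.activation)
        return Yn * self.y_std + self.y_mean

    def save(self, path) -> None:
        blob = {
            "format": "spinepinn-net-v1",
            "config": {
                **self.config.__dict__,
                "hidden_layers": list(self.config.hidden_layers),
            },
            "weights": [[W.tolist(), b.tolist()] for W, b in self.params],
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "feature_names": list(self.feature_names),
            "target_names": list(self.target_names),
            "history": self.history,
            "accuracies": self.accuracies,
            "n_nu_clamped": self.n_nu_clamped,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path) -> "TrainedNet":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "spinepinn-net-v1":
            raise ValueError(f"unrecognized checkpoint format in {path}")
        cfg_d = dict(blob["config"])
        cfg_d["hidden_layers"] = tuple(cfg_d["hidden_layers"])
        return cls(
            params=[[np.array(W), np.array(b)] for W, b in blob["weights"]],
            config=NetConfig(**cfg_d),
            x_mean=np.array(blob["x_mean"]),
            x_std=np.array(blob["x_std"]),
            y_mean=np.array(blob["y_mean"]),
            y_std=np.array(blob["y_std"]),
            feature_names=tuple(blob["feature_names"]),
            target_names=tuple(blob["target_names"]),
            history=blob.get("history", {}),
            accuracies=blob.get("accuracies", {}),
            n_nu_clamped=blob.get("n_nu_clamped", 0),
            meta=blob.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_normalized(ds: TrainingDataset) -> None:
    if not ds.is_normalized or "train" not in ds.splits:
        raise ValueError(
            "dataset must be split and normalized first (see split_and_normalize)"
        )


def _fit(
    params,
    cfg: NetConfig,
    Xn_tr,
    Yn_tr,
    Xn_val,
    Yn_val,
    y_mean,
    y_std,
    rng: np.random.Generator,
):
    """Adam loop with early stopping on validation loss; returns best params."""
    m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
    v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, [[W.copy(), b.copy()] for W, b in params], 0)
    n_clamped = 0
    n = len(Xn_tr)
    bs = cfg.batch_size or n

    for epoch in range(cfg.epochs):
        # cosine decay shrinks the late-epoch step size so the non-smooth
        # |residual| penalties settle instead of oscillating under Adam
        if cfg.lr_decay == "cosine":
            lr_e = cfg.learning_rate * max(
                0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs)), 1e-2
            )
        else:
            lr_e = cfg.learning_rate
        # constraint warm-up: zero until f*epochs, linear to full at 2f*epochs
        f = cfg.lambda_warmup
        if f > 0.0:
            ramp = min(max((epoch / cfg.epochs - f) / f, 0.0), 1.0)
        else:
            ramp = 1.0
        lam1, lam2 = cfg.lambda1 * ramp, cfg.lambda2 * ramp
        order = rng.permutation(n) if bs < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            Yn_pred, acts = _forward(params, Xn_tr[idx], cfg.activation)
            terms, dL, clamped = _loss_grad_out(
                Yn_pred, Yn_tr[idx], y_mean, y_std, lam1, lam2
            )
            n_clamped += clamped
            if not np.isfinite(terms["total"]):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (terms: {terms})"
                )
            epoch_loss += terms["total"] * len(idx)
            grads = _backward(params, acts, dL, cfg.activation)
            t += 1
            lr_t = lr_e * np.sqrt(1 - b2**t) / (1 - b1**t)
            for p, g_, m_, v_ in zip(params, grads, m, v):
                for j in range(2):
                    m_[j] = b1 * m_[j] + (1 - b1) * g_[j]
                    v_[j] = b2 * v_[j] + (1 - b2) * g_[j] ** 2
                    p[j] -= lr_t * m_[j] / (np.sqrt(v_[j]) + eps)
        history["train_loss"].append(epoch_loss / n)

        Yn_vp, _ = _forward(params, Xn_val, cfg.activation)
        vterms, _, _ = _loss_grad_out(
            Yn_vp, Yn_val, y_mean, y_std, cfg.lambda1, cfg.lambda2
        )
        history["val_loss"].append(vterms["total"])
        if vterms["total"] < best[0]:
            best = (vterms["total"], [[W.copy(), b.copy()] for W, b in params], epoch)
        elif epoch - best[2] > cfg.patience:
            break
    return best[1], history, n_clamped


def train(ds: TrainingDataset, cfg: NetConfig) -> TrainedNet:
    """Train a physics-informed network on a split, normalized dataset.

    Deterministic for fixed (dataset, config): the parameter initialisation
    and any minibatch shuffling derive from ``cfg.seed``. Records train/val/
    test accuracies (physical units) and the per-epoch loss curves.
    """
    _check_normalized(ds)
    rng = np.random.default_rng(cfg.seed)
    layers = [len(ds.feature_names), *cfg.hidden_layers, len(ds.target_names)]
    params = _init_params(layers, rng)

    Xn = {k: ds.normalize_X(ds.X[idx]) for k, idx in ds.splits.items()}
    Yn = {k: ds.normalize_Y(ds.Y[idx]) for k, idx in ds.splits.items()}
    val_key = "val" if "val" in Xn else "train"
    params, history, n_clamped = _fit(
        params, cfg, Xn["train"], Yn["train"], Xn[val_key], Yn[val_key],
        ds.y_mean, ds.y_std, rng,
    )

    net = TrainedNet(
        params=params,
        config=cfg,
        x_mean=ds.x_mean.copy(),
        x_std=ds.x_std.copy(),
        y_mean=ds.y_mean.copy(),
        y_std=ds.y_std.copy(),
        feature_names=ds.feature_names,
        target_names=ds.target_names,
        history=history,
        n_nu_clamped=n_clamped,
        meta={
            "aggregation": ds.metadata.get("aggregation", "split"),
            "u_mode": ds.metadata.get("u_mode", "centroid_node"),
        },
    )
    for split in ds.splits:
        Xs, Ys = ds.split_arrays(split)
        net.accuracies[split] = accuracy(net.predict(Xs), Ys)
    return net


def architecture_sweep(
    ds: TrainingDataset,
    cases: Optional[Sequence[NetConfig]] = None,
    base: Optional[NetConfig] = None,
) -> pd.DataFrame:
    """Train each architecture case and tabulate train/val/test accuracies.

    Rows are independent (each case trains from its own seeded init), so the
    table is invariant to sweep order. Per-case failures are recorded in the
    ``error`` column and the sweep continues.
    """
    if cases is None:
        base = base or NetConfig()
        cases = [replace(base, hidden_layers=h) for h in PAPER_ARCHITECTURES]
    if len(cases) == 0:
        raise ValueError("architecture sweep needs at least one case")
    rows = []
    for i, cfg in enumerate(cases, start=1):
        row = {
            "case": i,
            "n_analyses": ds.n_samples,
            "n_input_features": len(ds.feature_names),
            "architecture": cfg.architecture_label,
            "n_output_features": len(ds.target_names),
        }
        try:
            net = train(ds, cfg)
            row.update(
                train_accuracy=net.accuracies.get("train"),
                val_accuracy=net.accuracies.get("val"),
                test_accuracy=net.accuracies.get("test"),
                error=None,
            )
        except Exception as exc:
            row.update(
                train_accuracy=None, val_accuracy=None, test_accuracy=None,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def fine_tune(net: TrainedNet, calib_ds: TrainingDataset, **overrides) -> TrainedNet:
    """Continue optimisation from an existing network on a calibration dataset.

    The network's stored normalization is kept (it is part of the model);
    the calibration dataset only needs compatible feature/target schemas.
    Returns a new TrainedNet whose ``meta`` records before/after accuracies.
    """
    if tuple(calib_ds.feature_names) != tuple(net.feature_names) or tuple(
        calib_ds.target_names
    ) != tuple(net.target_names):
        raise ValueError("calibration dataset schema does not match the network")
    if "train" not in calib_ds.splits:
        raise ValueError("calibration dataset must carry splits")

    cfg = replace(net.config, **overrides) if overrides else net.config
    rng = np.random.default_rng(cfg.seed)
    params = [[W.copy(), b.copy()] for W, b in net.params]

    norm_x = lambda X: (X - net.x_mean) / net.x_std
    norm_y = lambda Y: (Y - net.y_mean) / net.y_std
    Xn = {k: norm_x(calib_ds.X[idx]) for k, idx in calib_ds.splits.items()}
    Yn = {k: norm_y(calib_ds.Y[idx]) for k, idx in calib_ds.splits.items()}
    val_key = "val" if "val" in Xn else "train"

    before = {
        s: accuracy(net.predict(calib_ds.X[idx]), calib_ds.Y[idx])
        for s, idx in calib_ds.splits.items()
    }
    params, history, n_clamped = _fit(
        params, cfg, Xn["train"], Yn["train"], Xn[val_key], Yn[val_key],
        net.y_mean, net.y_std, rng,
    )
    tuned = TrainedNet(
        params=params,
        config=cfg,
        x_mean=net.x_mean.copy(),
        x_std=net.x_std.copy(),
        y_mean=net.y_mean.copy(),
        y_std=net.y_std.copy(),
        feature_names=net.feature_names,
        target_names=net.target_names,
        history=history,
        n_nu_clamped=n_clamped,
        meta={**net.meta, "fine_tuned": True, "accuracy_before": before},
    )
    for split in calib_ds.splits:
        Xs, Ys = calib_ds.split_arrays(split)
        tuned.accuracies[split] = accuracy(tuned.predict(Xs), Ys)
    return tuned
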