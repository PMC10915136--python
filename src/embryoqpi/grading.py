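"""Feature-based embryo health grading.

A small feedforward network grades individual nuclei as healthy/
intermediate (HI) or sick (S) from five features — the embryo's
scattering-spectrum bandwidth ``bw3dB`` and nucleus count, and the
nucleus's dry-mass density, surface area and sphericity — and a
max-voting step aggregates the per-nucleus votes into an embryo-level
grade with a confidence probability (mean prediction score over the
majority-class subset).  A sparse-subset protocol grades an embryo from
a reduced set of z-slices subject to a minimum-slice / maximum-spacing
policy.

The network is a fully connected 5→10→2→2 architecture with ReLU hidden
activations and softmax output, trained with full-batch L-BFGS on
cross-entropy + L2 (λ = 1e−6), Glorot-initialized weights, zero biases,
and early stopping on validation patience (20) / gradient (1e−9) / loss
change (1e−9); the returned model is the one at minimum validation loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

#: frozen classifier input order
FEATURE_ORDER = ("bw3dB", "nuc_count", "dmd", "surface_area", "sphericity")
CLASS_NAMES = ("HI", "S")
HIDDEN_SIZES = (10, 2)


class PolicyError(RuntimeError):
    """A sparse-vote selection violates the acquisition policy."""


@dataclass
class FBMConfig:
    l2_lambda: float = 1e-6
    validation_fraction: float = 0.15
    validation_patience: int = 20
    gradient_tolerance: float = 1e-9
    loss_tolerance: float = 1e-9
    max_iterations: int = 2000
    seed: int = 0


@dataclass
class FBMModel:
    """Trained feature-based grading network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    config: FBMConfig = field(default_factory=FBMConfig)
    training_meta: dict = field(default_factory=dict)

    # -- forward pass -----------------------------------------------------
    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_mean) / self.feature_sd

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        a = self._standardize(np.atleast_2d(np.asarray(x, dtype=float)))
        return _forward(self.weights, self.biases, a)[-1]

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            dict(
                feature_order=list(FEATURE_ORDER),
                weights=[w.tolist() for w in self.weights],
                biases=[b.tolist() for b in self.biases],
                feature_mean=self.feature_mean.tolist(),
                feature_sd=self.feature_sd.tolist(),
                l2_lambda=self.config.l2_lambda,
                seed=self.config.seed,
                training_meta=self.training_meta,
            )
        )

    @classmethod
    def from_json(cls, text: str) -> "FBMModel":
        d = json.loads(text)
        cfg = FBMConfig(l2_lambda=d["l2_lambda"], seed=d["seed"])
        return cls(
            weights=[np.array(w) for w in d["weights"]],
            biases=[np.array(b) for b in d["biases"]],
            feature_mean=np.array(d["feature_mean"]),
            feature_sd=np.array(d["feature_sd"]),
            config=cfg,
            training_meta=d.get("training_meta", {}),
        )


@dataclass
class GradeResult:
    """Embryo-level grade from max-voting per-item predictions."""

    embryo_id: str | int
    predicted_class: str  # "HI" or "S"
    cp: float  # mean score over the majority-class items
    majority_fraction: float
    votes: list[str]
    tie: bool = False


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _layer_sizes(n_features: int = len(FEATURE_ORDER)) -> list[tuple[int, int]]:
    dims = [n_features, *HIDDEN_SIZES, len(CLASS_NAMES)]
    return list(zip(dims[:-1], dims[1:]))


def _glorot_init(rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in _layer_sizes():
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(weights, biases, x):
    activations = [x]
    a = x
    for i, (w, b) in enumerate(zip(weights, biases)):
        z = a @ w + b
        if i < len(weights) - 1:
            a = np.maximum(z, 0.0)  # ReLU
        else:
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            a = e / e.sum(axis=1, keepdims=True)  # softmax
        activations.append(a)
    return activations


def _pack(weights, biases):
    return np.concatenate([w.ravel() for w in weights] + [b.ravel() for b in biases])


def _unpack(theta):
    weights, biases = [], []
    pos = 0
    sizes = _layer_sizes()
    for fan_in, fan_out in sizes:
        weights.append(theta[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
    for _, fan_out in sizes:
        biases.append(theta[pos : pos + fan_out])
        pos += fan_out
    return weights, biases


def _loss_and_grad(theta, x, y_onehot, l2):
    weights, biases = _unpack(theta)
    acts = _forward(weights, biases, x)
    probs = acts[-1]
    n = x.shape[0]
    ce = -np.log(np.clip(probs[np.arange(n), y_onehot.argmax(axis=1)], 1e-300, None)).mean()
    loss = ce + l2 * sum(float((w * w).sum()) for w in weights)

    grad_w = [np.zeros_like(w) for w in weights]
    grad_b = [np.zeros_like(b) for b in biases]
    delta = (probs - y_onehot) / n  # softmax + CE gradient
    for i in range(len(weights) - 1, -1, -1):
        grad_w[i] = acts[i].T @ delta + 2.0 * l2 * weights[i]
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ weights[i].T) * (acts[i] > 0)
    return loss, _pack(grad_w, grad_b)


def _validation_loss(theta, x, y_onehot, l2):
    weights, biases = _unpack(theta)
    probs = _forward(weights, biases, x)[-1]
    n = x.shape[0]
    ce = -np.log(np.clip(probs[np.arange(n), y_onehot.argmax(axis=1)], 1e-300, None)).mean()
    return ce + l2 * sum(float((w * w).sum()) for w in weights)


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def _as_feature_matrix(rows) -> np.ndarray:
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in FEATURE_ORDER if c not in rows.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        x = rows.loc[:, list(FEATURE_ORDER)].to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(rows, dtype=float))
        if x.shape[1] != len(FEATURE_ORDER):
            raise ValueError(f"expected {len(FEATURE_ORDER)} feature columns")
    return x


def train_fbm(
    rows,
    labels,
    config: FBMConfig = FBMConfig(),
    validation: tuple | None = None,
) -> FBMModel:
    """Train the grading network on per-nucleus feature rows.

    ``rows`` is a DataFrame with the :data:`FEATURE_ORDER` columns (or an
    (n, 5) array); ``labels`` are 0 (HI) / 1 (S).  ``validation`` may give
    an explicit ``(rows, labels)`` split, otherwise a stratified random
    fraction (``config.validation_fraction``, seeded) is held out.
    Features are z-scored with the training-split statistics.  Identical
    data, config and seed reproduce identical weights.
    """
    x = _as_feature_matrix(rows)
    y = np.asarray(labels, dtype=int).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("rows and labels disagree in length")
    if np.isnan(x).any():
        raise ValueError("NaNs in features")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(config.seed)
    if validation is not None:
        x_val = _as_feature_matrix(validation[0])
        y_val = np.asarray(validation[1], dtype=int).ravel()
        x_tr, y_tr = x, y
    else:
        idx = np.arange(len(y))
        val_idx = []
        for cls in np.unique(y):
            cls_idx = idx[y == cls]
            n_val = max(1, int(round(config.validation_fraction * len(cls_idx))))
            val_idx.extend(rng.choice(cls_idx, size=n_val, replace=False))
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        x_tr, y_tr = x[~val_mask], y[~val_mask]
        x_val, y_val = x[val_mask], y[val_mask]

    mean = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd[sd == 0] = 1.0
    xs_tr = (x_tr - mean) / sd
    xs_val = (x_val - mean) / sd
    y1h_tr = np.eye(2)[y_tr]
    y1h_val = np.eye(2)[y_val]

    weights, biases = _glorot_init(rng)
    theta0 = _pack(weights, biases)

    best = dict(theta=theta0.copy(), val=np.inf, it=0)
    state = dict(since_best=0, iters=0)

    def callback(theta):
        state["iters"] += 1
        val = _validation_loss(theta, xs_val, y1h_val, config.l2_lambda)
        if val < best["val"]:
            best.update(theta=theta.copy(), val=val, it=state["iters"])
            state["since_best"] = 0
        else:
            state["since_best"] += 1
        if state["since_best"] >= config.validation_patience:
            raise StopIteration

    stop_reason = "converged"
    try:
        res = minimize(
            _loss_and_grad,
            theta0,
            args=(xs_tr, y1h_tr, config.l2_lambda),
            method="L-BFGS-B",
            jac=True,
            callback=callback,
            options=dict(
                maxiter=config.max_iterations,
                gtol=config.gradient_tolerance,
                ftol=config.loss_tolerance,
            ),
        )
        if state["since_best"] < config.validation_patience:
            # the optimizer stopped on its own gradient/loss tolerances
            callback(res.x)
    except StopIteration:
        stop_reason = "validation_patience"

    weights, biases = _unpack(best["theta"])
    model = FBMModel(
        weights=weights,
        biases=biases,
        feature_mean=mean,
        feature_sd=sd,
        config=config,
        training_meta=dict(
            iterations=state["iters"],
            best_iteration=best["it"],
            best_validation_loss=float(best["val"]),
            stopping_reason=stop_reason,
            n_train=int(len(y_tr)),
            n_validation=int(len(y_val)),
        ),
    )
    return model


def predict_items(model: FBMModel, rows) -> pd.DataFrame:
    """Per-item class and winning-probability score.

    Class is the argmax of the softmax output; an exact (0.5, 0.5) tie
    resolves to HI (index 0).  Row order is preserved.
    """
    x = _as_feature_matrix(rows)
    probs = model.predict_proba(x)
    cls_idx = probs.argmax(axis=1)  # first max -> HI on ties
    return pd.DataFrame(
        dict(
            predicted_class=[CLASS_NAMES[i] for i in cls_idx],
            score=probs[np.arange(len(cls_idx)), cls_idx],
            p_hi=probs[:, 0],
            p_s=probs[:, 1],
        )
    )


def max_vote(predictions: pd.DataFrame, embryo_id: str | int = 0) -> GradeResult:
    """Aggregate per-item predictions into an embryo-level grade.

    The most frequent class wins; the confidence probability ``cp`` is the
    mean prediction score over the majority-class items.  An exact tie is
    resolved conservatively to S (down-grading) and flagged.  Item order
    never affects the result.
    """
    if predictions.empty:
        raise ValueError("empty prediction list")
    votes = predictions["predicted_class"].tolist()
    n_hi = votes.count("HI")
    n_s = votes.count("S")
    tie = n_hi == n_s
    winner = "S" if n_s >= n_hi else "HI"
    majority = predictions[predictions["predicted_class"] == winner]
    return GradeResult(
        embryo_id=embryo_id,
        predicted_class=winner,
        cp=float(majority["score"].mean()),
        majority_fraction=max(n_hi, n_s) / len(votes),
        votes=votes,
        tie=tie,
    )


def sparse_vote(
    predictions: pd.DataFrame,
    step_um: float,
    min_slices: int = 7,
    max_step_um: float = 10.0,
    force: bool = False,
    embryo_id: str | int = 0,
) -> tuple[GradeResult, pd.DataFrame]:
    """Grade an embryo from a sparse subset of per-slice predictions.

    ``predictions`` must carry a ``z_um`` column.  Slices are subselected
    by dropping intermediate entries: starting from the lowest z, the next
    kept slice is the first one at least ``step_um`` above the previous.
    Configurations with spacing above ``max_step_um`` (10 µm: the largest
    inter-slice distance at which grades remain reliable) or fewer than
    ``min_slices`` selected slices (7; 6 is avoided since an even split
    can tie) raise :class:`PolicyError` unless ``force``.  Returns the
    grade and the selected subset.
    """
    if "z_um" not in predictions.columns:
        raise ValueError("per-slice predictions need a z_um column")
    if step_um > max_step_um and not force:
        raise PolicyError(
            f"requested spacing {step_um} µm exceeds the {max_step_um} µm policy bound"
        )
    ordered = predictions.sort_values("z_um", kind="stable")
    keep = []
    last = -np.inf
    for i, z in zip(ordered.index, ordered["z_um"]):
        if z - last >= step_um - 1e-9:
            keep.append(i)
            last = z
    selected = ordered.loc[keep]
    if len(selected) < min_slices and not force:
        raise PolicyError(
            f"only {len(selected)} slices selected; policy requires >= {min_slices}"
        )
    return max_vote(selected, embryo_id), selected


def nucleus_feature_rows(
    records: pd.DataFrame,
    nuc_count: int,
    bw3db: float,
    embryo_id: str | int = 0,
    label: str | None = None,
) -> pd.DataFrame:
    """Per-nucleus classifier rows in the frozen feature order."""
    rows = pd.DataFrame(
        dict(
            bw3dB=bw3db,
            nuc_count=nuc_count,
            dmd=records["dmd_pg_um3"].to_numpy(),
            surface_area=records["surface_um2"].to_numpy(),
            sphericity=records["sphericity"].to_numpy(),
        )
    )
    rows.insert(0, "embryo_id", embryo_id)
    if label is not None:
        rows["label"] = label
    return rows
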