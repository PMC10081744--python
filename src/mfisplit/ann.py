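"""Feed-forward backpropagation classifier with greedy architecture search.

A deliberately classic multilayer perceptron: sigmoid hidden and output
units, squared-error loss against one-hot targets, full-batch gradient
descent with momentum.  Training halts at epoch checkpoints once the
training-set RMSE falls below a target, plateaus, or the epoch budget is
exhausted.  Architecture search grows depth 1 -> 2 -> 3, sweeping each new
hidden layer's node count from ceil(n/3) to 4n (n = nodes in the preceding
layer) and stopping a sweep after two successive increments that are each
worse than the best seen.

Everything is deterministic given the configured seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Architecture",
    "TrainConfig",
    "SearchConfig",
    "TrainedModel",
    "DivergenceError",
    "train_mlp",
    "predict",
    "predict_proba",
    "compute_rmse",
    "search_architecture",
    "save_model",
    "load_model",
]


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Architecture:
    input_dim: int
    hidden_layers: tuple[int, ...]
    output_dim: int

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be >= 1")
        if not 1 <= len(self.hidden_layers) <= 3:
            raise ValueError("between 1 and 3 hidden layers required")
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be >= 1")

    @property
    def total_hidden(self) -> int:
        return sum(self.hidden_layers)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol constants.

    Defaults follow the full-scale protocol (checkpoints every 10000 epochs
    between 50000 and 150000, RMSE target 0.05); use :func:`desk_config`
    for a scaled-down profile suitable for interactive work and tests.
    """

    min_epochs: int = 50_000
    max_epochs: int = 150_000
    epoch_step: int = 10_000
    rmse_target: float = 0.05
    plateau_window: int = 10_000
    plateau_tol: float = 1e-4
    learning_rate: float = 0.1
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must be <= max_epochs")
        if self.epoch_step <= 0 or self.plateau_window <= 0:
            raise ValueError("epoch_step and plateau_window must be positive")
        if self.rmse_target <= 0:
            raise ValueError("rmse_target must be positive")


def desk_config(seed: int = 0, **overrides) -> TrainConfig:
    """Scaled-down training profile (2000-6000 epochs, 500-epoch checkpoints)."""
    kw = dict(
        min_epochs=2_000, max_epochs=6_000, epoch_step=500,
        plateau_window=500, seed=seed,
    )
    kw.update(overrides)
    return TrainConfig(**kw)


@dataclass
class TrainedModel:
    architecture: Architecture
    weights: list[np.ndarray]      # W[i]: (fan_in, fan_out)
    biases: list[np.ndarray]
    log: list[tuple[int, float]]   # (epoch, training RMSE) at checkpoints
    seed: int
    stop_reason: str = ""
    scaling_bounds: dict | None = None


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(X: np.ndarray, weights, biases) -> list[np.ndarray]:
    activations = [X]
    for W, b in zip(weights, biases):
        activations.append(_sigmoid(activations[-1] @ W + b))
    return activations


def compute_rmse(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Root mean square error over all rows and output units."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError(f"shape mismatch: {outputs.shape} vs {targets.shape}")
    if outputs.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((outputs - targets) ** 2)))


def _gradients(X, Y, weights, biases):
    """Analytic backprop gradients of 0.5 * mean squared error."""
    acts = _forward(X, weights, biases)
    n = X.shape[0]
    grads_W, grads_b = [], []
    delta = (acts[-1] - Y) * acts[-1] * (1.0 - acts[-1]) / n
    for layer in range(len(weights) - 1, -1, -1):
        grads_W.append(acts[layer].T @ delta)
        grads_b.append(delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ weights[layer].T) * acts[layer] * (1.0 - acts[layer])
    return grads_W[::-1], grads_b[::-1]


def _init_params(arch: Architecture, rng: np.random.Generator):
    dims = [arch.input_dim, *arch.hidden_layers, arch.output_dim]
    weights = [rng.uniform(-0.5, 0.5, size=(a, b)) for a, b in zip(dims, dims[1:])]
    biases = [rng.uniform(-0.5, 0.5, size=b) for b in dims[1:]]
    return weights, biases


def train_mlp(
    X: np.ndarray,
    Y: np.ndarray,
    arch: Architecture,
    cfg: TrainConfig,
) -> TrainedModel:
    """Full-batch backpropagation training with the checkpointed stopping rule.

    Stopping is evaluated only at checkpoints (multiples of ``epoch_step`` at
    or after ``min_epochs``): training RMSE below ``rmse_target``; RMSE change
    below ``plateau_tol`` across ``plateau_window`` epochs; or ``max_epochs``.
    If the loss turns non-finite the learning rate is halved once and training
    restarts; a second divergence raises :class:`DivergenceError`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if X.shape[1] != arch.input_dim or Y.shape[1] != arch.output_dim:
        raise ValueError(
            f"feature/label dims {X.shape[1]}/{Y.shape[1]} do not match "
            f"architecture {arch.input_dim}/{arch.output_dim}"
        )

    lr = cfg.learning_rate
    for attempt in range(2):
        rng = np.random.default_rng(cfg.seed)
        weights, biases = _init_params(arch, rng)
        vel_W = [np.zeros_like(W) for W in weights]
        vel_b = [np.zeros_like(b) for b in biases]
        log: list[tuple[int, float]] = []
        # checkpoint RMSE history for the plateau rule
        history: dict[int, float] = {}
        diverged = False
        stop_reason = "max_epochs"
        epoch = 0
        for epoch in range(1, cfg.max_epochs + 1):
            gW, gb = _gradients(X, Y, weights, biases)
            for i in range(len(weights)):
                vel_W[i] = cfg.momentum * vel_W[i] - lr * gW[i]
                vel_b[i] = cfg.momentum * vel_b[i] - lr * gb[i]
                weights[i] += vel_W[i]
                biases[i] += vel_b[i]
            if epoch % cfg.epoch_step == 0 or epoch == cfg.max_epochs:
                out = _forward(X, weights, biases)[-1]
                rmse = compute_rmse(out, Y)
                if not math.isfinite(rmse):
                    diverged = True
                    break
                log.append((epoch, rmse))
                history[epoch] = rmse
                if epoch >= cfg.min_epochs:
                    if rmse < cfg.rmse_target:
                        stop_reason = "rmse_target"
                        break
                    prior = [e for e in history if e <= epoch - cfg.plateau_window]
                    if prior and abs(history[max(prior)] - rmse) < cfg.plateau_tol:
                        stop_reason = "plateau"
                        break
        if not diverged:
            return TrainedModel(
                architecture=arch, weights=weights, biases=biases,
                log=log, seed=cfg.seed, stop_reason=stop_reason,
            )
        lr /= 2.0
    raise DivergenceError(
        f"training diverged (non-finite RMSE) at epoch {epoch} even after "
        f"halving the learning rate to {lr}"
    )


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.architecture.input_dim:
        raise ValueError(
            f"feature matrix has {X.shape[-1]} columns, model expects "
            f"{model.architecture.input_dim}"
        )
    return _forward(X, model.weights, model.biases)[-1]


def predict(
    model: TrainedModel, X: np.ndarray, classes: Sequence[str] | None = None
) -> np.ndarray:
    """Argmax over output activations; ties go to the earliest class index
    (i.e. the lowest destination in the fixed taxonomy order)."""
    out = predict_proba(model, X)
    idx = np.argmax(out, axis=1)
    if classes is None:
        return idx
    if len(classes) != model.architecture.output_dim:
        raise ValueError("classes length must equal output_dim")
    return np.asarray(classes, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Greedy architecture search

@dataclass(frozen=True)
class SearchConfig:
    max_depth: int = 3
    increment: int = 1
    min_factor: float = 1.0 / 3.0
    max_factor: float = 4.0

    def sweep_sizes(self, preceding: int) -> list[int]:
        lo = max(1, math.ceil(preceding * self.min_factor))
        hi = max(lo, int(math.floor(preceding * self.max_factor)))
        return list(range(lo, hi + 1, self.increment))


def _sweep(
    score_fn: Callable[[int], float | None],
    sizes: Sequence[int],
) -> tuple[int | None, float, list[tuple[int, float | None]]]:
    """Evaluate sizes in order, stopping after two successive candidates
    strictly worse than the best seen.  Returns (best size, best score, trace).
    ``score_fn`` may return None for an untrainable candidate."""
    best_size, best_score = None, -np.inf
    worse_streak = 0
    trace: list[tuple[int, float | None]] = []
    for size in sizes:
        score = score_fn(size)
        trace.append((size, score))
        if score is None:
            continue
        if score > best_score:
            best_size, best_score = size, score
            worse_streak = 0
        elif score == best_score:
            worse_streak = 0  # a tie is not a reduction
        else:
            worse_streak += 1
            if worse_streak >= 2:
                break
    return best_size, best_score, trace


def search_architecture(
    train_X: np.ndarray,
    train_Y: np.ndarray,
    test_X: np.ndarray,
    test_Y: np.ndarray,
    cfg: TrainConfig,
    search: SearchConfig = SearchConfig(),
) -> tuple[Architecture, TrainedModel, float]:
    """Greedy depth-then-width search maximizing test-set accuracy.

    For each depth the preceding layers are frozen at their selected widths
    and the new layer is swept; the globally best (accuracy, with ties to
    the smaller total hidden-node count) architecture is returned.
    """
    input_dim = train_X.shape[1]
    output_dim = train_Y.shape[1]
    test_labels = np.argmax(test_Y, axis=1)
    cache: dict[tuple[int, ...], tuple[TrainedModel, float]] = {}

    def evaluate(hidden: tuple[int, ...]):
        if hidden in cache:
            return cache[hidden]
        arch = Architecture(input_dim, hidden, output_dim)
        try:
            model = train_mlp(train_X, train_Y, arch, cfg)
        except DivergenceError:
            cache[hidden] = (None, None)
            return cache[hidden]
        acc = float(np.mean(predict(model, test_X) == test_labels))
        cache[hidden] = (model, acc)
        return cache[hidden]

    best: tuple[float, int, tuple[int, ...]] | None = None  # (acc, total, hidden)
    prefix: tuple[int, ...] = ()
    for depth in range(1, search.max_depth + 1):
        preceding = prefix[-1] if prefix else input_dim
        sizes = search.sweep_sizes(preceding)

        def score(size: int) -> float | None:
            model, acc = evaluate(prefix + (size,))
            return acc

        best_size, _, _ = _sweep(score, sizes)
        if best_size is None:
            break
        prefix = prefix + (best_size,)
        for hidden, (model, acc) in cache.items():
            if model is None:
                continue
            cand = (acc, -sum(hidden), hidden)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    if best is None:
        raise DivergenceError("no trainable architecture found in the search range")
    acc, _, hidden = best
    model, _ = cache[hidden]
    return model.architecture, model, acc


# ---------------------------------------------------------------------------
# Serialization

def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "architecture": {
            "input_dim": model.architecture.input_dim,
            "hidden_layers": list(model.architecture.hidden_layers),
            "output_dim": model.architecture.output_dim,
        },
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "log": [[e, r] for e, r in model.log],
        "seed": model.seed,
        "stop_reason": model.stop_reason,
        "scaling_bounds": model.scaling_bounds,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    a = payload["architecture"]
    return TrainedModel(
        architecture=Architecture(a["input_dim"], tuple(a["hidden_layers"]), a["output_dim"]),
        weights=[np.asarray(W, dtype=float) for W in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        log=[(int(e), float(r)) for e, r in payload["log"]],
        seed=int(payload["seed"]),
        stop_reason=payload.get("stop_reason", ""),
        scaling_bounds=payload.get("scaling_bounds"),
    )
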