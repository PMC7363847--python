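"""Feed-forward classifier over cytometry events: assembly, training, ensemble.

The classifier is a single-hidden-layer network mapping the seven
log10-scale cytometer parameters to a probability vector over K
standard classes: inputs are min-max scaled to [-1, 1] (the range is
pinned by anchor events to the log filter bounds), passed through a
20-node logistic-sigmoid hidden layer, then an affine output layer with
softmax normalization.  Training minimizes the mean categorical
cross-entropy on the training block by full-batch scaled conjugate
gradient, with three stopping rules: a cycle limit, a gradient-norm
floor, and early stopping when the validation cross-entropy fails to
improve for a fixed number of consecutive cycles (the weights from the
best validation point are returned).  Five independently subsampled,
split and initialized replicates form the classifier ensemble whose
spread quantifies training variability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fcm import (
    LOG10,
    PARAMETERS,
    ConfigError,
    EventTable,
    FilterSpec,
    StandardDataset,
    add_anchors,
    subsample_events,
)

__all__ = [
    "TrainingConfig",
    "TrainingAssembly",
    "ClassifierModel",
    "ClassifierEnsemble",
    "ClassificationResult",
    "assemble_training_set",
    "train_classifier",
    "train_ensemble",
    "forward_pass",
    "classify_events",
    "summarize_counts",
]


@dataclass
class TrainingConfig:
    """Training hyperparameters; defaults follow the reference protocol."""

    max_cycles: int = 1000
    min_gradient: float = 1e-6
    max_validation_failures: int = 6
    hidden_nodes: int = 20
    performance_goal: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_cycles < 1 or self.hidden_nodes < 1:
            raise ValueError("max_cycles and hidden_nodes must be positive")
        if self.min_gradient <= 0 or self.max_validation_failures < 1:
            raise ValueError("min_gradient and max_validation_failures must be positive")


@dataclass
class TrainingAssembly:
    """Scaled, labelled, split training matrix assembled from standards.

    ``X`` is in [-1, 1] with every column attaining both -1 and +1
    (guaranteed by the anchor events).  ``splits`` partitions the row
    indices into train/validation/test blocks with 50/25/25 proportions.
    ``scaling`` holds the per-parameter (min, max) pairs, which equal
    the log10 filter bounds.
    """

    X: np.ndarray
    y: np.ndarray
    class_labels: list[str]
    splits: dict[str, np.ndarray]
    scaling: tuple[np.ndarray, np.ndarray]
    anchor_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.X)
        all_idx = np.sort(np.concatenate(list(self.splits.values())))
        if not np.array_equal(all_idx, np.arange(n)):
            raise ValueError("splits must partition all rows")


def _scale(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return 2.0 * (X - lo) / (hi - lo) - 1.0


def assemble_training_set(
    standards: Sequence[StandardDataset],
    n_per_standard: int,
    spec: FilterSpec,
    seed: int,
) -> TrainingAssembly:
    """Subsample, anchor, concatenate, scale and split standards.

    Each standard is subsampled to ``n_per_standard`` events; the two
    anchor events are appended to the first standard; everything is
    concatenated, min-max scaled to [-1, 1] per parameter, and randomly
    partitioned into 50% train / 25% validation / 25% test.
    """
    if len(standards) < 2:
        raise ConfigError("at least two standards are required")
    names = [s.standard_name for s in standards]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate standard names in {names}")
    for s in standards:
        if s.n_events == 0:
            raise ConfigError(f"standard {s.standard_name!r} has no events")
        if s.events.scale != LOG10:
            raise ConfigError(f"standard {s.standard_name!r} not on log10 scale")

    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(standards))
    parts, labels, anchor_flags = [], [], []
    for i, (s, s_seed) in enumerate(zip(standards, sub_seeds)):
        sub = subsample_events(s, n_per_standard, int(s_seed))
        if i == 0:
            sub = add_anchors(sub, spec)
        parts.append(sub.events.values)
        labels.append(np.full(sub.n_events, i, dtype=int))
        anchor_flags.append(sub.anchor_mask)

    X_log = np.vstack(parts)
    y = np.concatenate(labels)
    anchor_mask = np.concatenate(anchor_flags)

    lo = X_log.min(axis=0)
    hi = X_log.max(axis=0)
    X = _scale(X_log, lo, hi)

    n = len(X)
    perm = rng.permutation(n)
    n_train = round(0.5 * n)
    n_val = round(0.25 * n)
    splits = {
        "train": perm[:n_train],
        "validation": perm[n_train : n_train + n_val],
        "test": perm[n_train + n_val :],
    }
    return TrainingAssembly(
        X=X, y=y, class_labels=names, splits=splits,
        scaling=(lo, hi), anchor_mask=anchor_mask,
    )


# ---------------------------------------------------------------------------
# Network forward/backward


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _unpack(w: np.ndarray, n_in: int, n_hidden: int, n_out: int):
    i = 0
    W1 = w[i : i + n_in * n_hidden].reshape(n_in, n_hidden); i += n_in * n_hidden
    b1 = w[i : i + n_hidden]; i += n_hidden
    W2 = w[i : i + n_hidden * n_out].reshape(n_hidden, n_out); i += n_hidden * n_out
    b2 = w[i : i + n_out]
    return W1, b1, W2, b2


def _cross_entropy(w, X, y, n_in, n_hidden, n_out) -> float:
    W1, b1, W2, b2 = _unpack(w, n_in, n_hidden, n_out)
    A1 = _sigmoid(X @ W1 + b1)
    Z2 = A1 @ W2 + b2
    lse = np.log(np.exp(Z2 - Z2.max(axis=1, keepdims=True)).sum(axis=1)) \
        + Z2.max(axis=1)
    return float(np.mean(lse - Z2[np.arange(len(y)), y]))


def _loss_and_grad(w, X, y, n_in, n_hidden, n_out):
    W1, b1, W2, b2 = _unpack(w, n_in, n_hidden, n_out)
    N = len(X)
    A1 = _sigmoid(X @ W1 + b1)
    Z2 = A1 @ W2 + b2
    zmax = Z2.max(axis=1, keepdims=True)
    expz = np.exp(Z2 - zmax)
    P = expz / expz.sum(axis=1, keepdims=True)
    loss = float(np.mean(np.log(expz.sum(axis=1)) + zmax[:, 0]
                         - Z2[np.arange(N), y]))
    D2 = P.copy()
    D2[np.arange(N), y] -= 1.0
    D2 /= N
    gW2 = A1.T @ D2
    gb2 = D2.sum(axis=0)
    D1 = (D2 @ W2.T) * A1 * (1.0 - A1)
    gW1 = X.T @ D1
    gb1 = D1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return loss, grad


@dataclass
class ClassifierModel:
    """Trained 7 -> hidden -> K network with its scaling and labels."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    class_labels: list[str]
    scaling: tuple[np.ndarray, np.ndarray]
    training_log: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def predict_proba(self, events: EventTable) -> np.ndarray:
        """Class probabilities for log10-scale events, shape (N, K)."""
        if events.scale != LOG10:
            raise ValueError("predict_proba expects log10-scale events")
        lo, hi = self.scaling
        Xs = _scale(events.values, lo, hi)
        n_out = int((np.abs(Xs) > 1).any(axis=1).sum())
        if n_out:
            warnings.warn(
                f"{n_out} event(s) outside the scaling bounds were clipped to [-1, 1]"
            )
            Xs = np.clip(Xs, -1.0, 1.0)
        if len(Xs) == 0:
            return np.empty((0, self.n_classes))
        A1 = _sigmoid(Xs @ self.W1 + self.b1)
        return _softmax(A1 @ self.W2 + self.b2)

    def to_dict(self) -> dict:
        lo, hi = self.scaling
        return {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "class_labels": self.class_labels,
            "scaling": {"min": lo.tolist(), "max": hi.tolist()},
            "training_log": self.training_log,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            W2=np.array(d["W2"]), b2=np.array(d["b2"]),
            class_labels=list(d["class_labels"]),
            scaling=(np.array(d["scaling"]["min"]), np.array(d["scaling"]["max"])),
            training_log=d.get("training_log", {}),
        )


@dataclass
class ClassificationResult:
    """Per-event class probabilities and argmax assignments for one model."""

    probabilities: np.ndarray
    class_labels: list[str]
    assigned_idx: np.ndarray
    source_sample: str = "sample"

    @property
    def n_events(self) -> int:
        return len(self.probabilities)

    @property
    def assigned_class(self) -> np.ndarray:
        return np.array(self.class_labels, dtype=object)[self.assigned_idx]

    @property
    def winning_probability(self) -> np.ndarray:
        if self.n_events == 0:
            return np.empty(0)
        return self.probabilities[np.arange(self.n_events), self.assigned_idx]

    @property
    def class_counts(self) -> pd.Series:
        counts = np.bincount(self.assigned_idx, minlength=len(self.class_labels))
        return pd.Series(counts, index=self.class_labels, name=self.source_sample)


def forward_pass(model: ClassifierModel, events: EventTable) -> ClassificationResult:
    """Apply the trained network event-wise; ties go to the lowest class index."""
    P = model.predict_proba(events)
    assigned = P.argmax(axis=1) if len(P) else np.empty(0, dtype=int)
    return ClassificationResult(
        probabilities=P,
        class_labels=list(model.class_labels),
        assigned_idx=assigned.astype(int),
        source_sample=events.sample_id,
    )


def _init_weights(rng: np.random.Generator, n_in: int, n_hidden: int, n_out: int):
    """Small uniform symmetric initialization, scaled by layer fan."""
    s1 = np.sqrt(6.0 / (n_in + n_hidden))
    s2 = np.sqrt(6.0 / (n_hidden + n_out))
    return np.concatenate([
        rng.uniform(-s1, s1, n_in * n_hidden),
        np.zeros(n_hidden),
        rng.uniform(-s2, s2, n_hidden * n_out),
        np.zeros(n_out),
    ])


def train_classifier(
    assembly: TrainingAssembly, config: TrainingConfig | None = None
) -> ClassifierModel:
    """Train one classifier on an assembly with scaled conjugate gradient.

    Stops on whichever comes first: ``max_cycles`` training cycles, a
    gradient infinity-norm below ``min_gradient``, or
    ``max_validation_failures`` consecutive cycles without improvement
    of the validation cross-entropy.  The returned weights are those of
    the best validation point; the training log records the optimizer,
    stop reason, cycles run, and the cross-entropy on all three blocks.
    """
    config = config or TrainingConfig()
    K = len(assembly.class_labels)
    if K < 2:
        raise ConfigError("training requires at least two classes")
    n_in, n_hidden = assembly.X.shape[1], config.hidden_nodes

    tr, va = assembly.splits["train"], assembly.splits["validation"]
    Xtr, ytr = assembly.X[tr], assembly.y[tr]
    Xva, yva = assembly.X[va], assembly.y[va]

    rng = np.random.default_rng(config.seed)
    w = _init_weights(rng, n_in, n_hidden, K)

    def f(wv):
        return _loss_and_grad(wv, Xtr, ytr, n_in, n_hidden, K)

    # Scaled conjugate gradient (Moller 1993), full batch.
    sigma0, lamb, lamb_bar = 1e-4, 1e-6, 0.0
    fw, grad = f(w)
    if not np.isfinite(fw):
        raise FloatingPointError("non-finite initial loss")
    r = -grad
    p = r.copy()
    success = True
    nparam = w.size

    best_w = w.copy()
    best_val = _cross_entropy(w, Xva, yva, n_in, n_hidden, K)
    val_fails = 0
    stop_reason = "max_cycles"
    cycles = 0
    delta = 1.0

    for k in range(1, config.max_cycles + 1):
        cycles = k
        p_norm2 = float(p @ p)
        if p_norm2 == 0.0:
            stop_reason = "min_gradient"
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g2 = f(w + sigma * p)
            s = (g2 - (-r)) / sigma
            delta = float(p @ s)
        delta_k = delta + (lamb - lamb_bar) * p_norm2
        if delta_k <= 0:
            lamb_bar = 2.0 * (lamb - delta_k / p_norm2)
            delta_k = -delta_k + lamb * p_norm2
            lamb = lamb_bar
        mu = float(p @ r)
        alpha = mu / delta_k
        fw_new, g_new = f(w + alpha * p)
        if not np.isfinite(fw_new):
            raise FloatingPointError("non-finite loss during training")
        comp = 2.0 * delta_k * (fw - fw_new) / mu**2
        if comp >= 0:
            w = w + alpha * p
            fw = fw_new
            r_new = -g_new
            lamb_bar = 0.0
            success = True
            if k % nparam == 0:
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comp >= 0.75:
                lamb = max(lamb * 0.25, 1e-20)
        else:
            lamb_bar = lamb
            success = False
        if comp < 0.25:
            lamb = min(lamb + delta_k * (1.0 - comp) / p_norm2, 1e20)

        # stopping rules, evaluated once per cycle
        if np.max(np.abs(r)) < config.min_gradient:
            stop_reason = "min_gradient"
            break
        if fw <= config.performance_goal:
            stop_reason = "performance_goal"
            break
        val_ce = _cross_entropy(w, Xva, yva, n_in, n_hidden, K)
        if val_ce < best_val:
            best_val = val_ce
            best_w = w.copy()
            val_fails = 0
        else:
            val_fails += 1
            if val_fails >= config.max_validation_failures:
                stop_reason = "validation"
                break

    # keep the best-validation weights
    final_val = _cross_entropy(w, Xva, yva, n_in, n_hidden, K)
    if final_val <= best_val:
        best_w, best_val = w, final_val
    te = assembly.splits["test"]
    test_ce = _cross_entropy(
        best_w, assembly.X[te], assembly.y[te], n_in, n_hidden, K
    )
    W1, b1, W2, b2 = _unpack(best_w.copy(), n_in, n_hidden, K)
    lo, hi = assembly.scaling
    return ClassifierModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        class_labels=list(assembly.class_labels),
        scaling=(lo.copy(), hi.copy()),
        training_log={
            "optimizer": "scaled conjugate gradient",
            "cycles": cycles,
            "stop_reason": stop_reason,
            "train_cross_entropy": _cross_entropy(best_w, Xtr, ytr, n_in, n_hidden, K),
            "validation_cross_entropy": best_val,
            "test_cross_entropy": test_ce,
            "seed": config.seed,
        },
    )


@dataclass
class ClassifierEnsemble:
    """Replicate classifiers trained from independent subsamples and splits."""

    models: list[ClassifierModel]

    def __post_init__(self) -> None:
        labels = self.models[0].class_labels
        lo0, hi0 = self.models[0].scaling
        for m in self.models[1:]:
            if m.class_labels != labels:
                raise ValueError("ensemble members must share class labels")
            lo, hi = m.scaling
            if not (np.allclose(lo, lo0) and np.allclose(hi, hi0)):
                raise ValueError("ensemble members must share scaling bounds")

    @property
    def class_labels(self) -> list[str]:
        return self.models[0].class_labels

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.models):
            with open(directory / f"classifier_{i}.json", "w") as fh:
                json.dump(m.to_dict(), fh)

    @classmethod
    def load(cls, directory: str | Path) -> "ClassifierEnsemble":
        directory = Path(directory)
        paths = sorted(directory.glob("classifier_*.json"))
        if not paths:
            raise FileNotFoundError(f"no classifier_*.json under {directory}")
        models = []
        for p in paths:
            with open(p) as fh:
                models.append(ClassifierModel.from_dict(json.load(fh)))
        return cls(models=models)


def train_ensemble(
    standards: Sequence[StandardDataset],
    n_per_standard: int,
    spec: FilterSpec,
    config: TrainingConfig | None = None,
    n_replicates: int = 5,
) -> ClassifierEnsemble:
    """Train ``n_replicates`` classifiers, each from independent seeds.

    Subsampling, anchoring, concatenation, splitting and weight
    initialization are all re-drawn per replicate; downstream metrics
    are reported as mean +/- SD over the replicates.
    """
    config = config or TrainingConfig()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_replicates)
    models = []
    for child in children:
        s1, s2 = (int(v % (2**31 - 1)) for v in child.generate_state(2))
        assembly = assemble_training_set(standards, n_per_standard, spec, seed=s1)
        rep_config = TrainingConfig(
            max_cycles=config.max_cycles,
            min_gradient=config.min_gradient,
            max_validation_failures=config.max_validation_failures,
            hidden_nodes=config.hidden_nodes,
            performance_goal=config.performance_goal,
            seed=s2,
        )
        models.append(train_classifier(assembly, rep_config))
    return ClassifierEnsemble(models=models)


def classify_events(
    ensemble: ClassifierEnsemble, events: EventTable
) -> list[ClassificationResult]:
    """One classification result per ensemble member."""
    return [forward_pass(m, events) for m in ensemble.models]


def summarize_counts(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Per-class mean +/- SD of assigned counts across ensemble members."""
    counts = pd.concat([r.class_counts for r in results], axis=1)
    return pd.DataFrame({
        "mean_count": counts.mean(axis=1),
        "sd_count": counts.std(axis=1, ddof=1) if counts.shape[1] > 1
        else np.zeros(len(counts)),
    })
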