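"""Synthetic seven-parameter cytometry standards and communities.

Standards are modelled as (mixtures of) multivariate Gaussians in log10
intensity space, matching the ellipsoidal clusters that log-transformed
cytometry populations form; events falling outside the log filter
bounds are replaced by rejection sampling so generated data pass
preprocessing without loss.  Cluster separation is parameterised in
units of the pooled per-axis standard deviation, which makes classifier
difficulty controllable: well-separated standards should be recovered
almost perfectly, identically distributed ones only at chance.

The canned five-standard fixture mimics a three-strain proof-of-concept
community in which two strains show two cytometric subpopulations each:
five classes with pairwise separations of about 9 pooled SD, two of
them bimodal along an extra axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
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
)
from .ann import (
    TrainingConfig,
    assemble_training_set,
    forward_pass,
    train_classifier,
)
from .evaluation import confusion_and_metrics

__all__ = [
    "SyntheticStandardSpec",
    "CommunitySpec",
    "generate_standard",
    "generate_community",
    "paperlike_standards",
    "background_spec",
    "separability_sweep",
]

_NDIM = len(PARAMETERS)

#: Default per-axis standard deviation of a synthetic cluster, log10 units.
DEFAULT_SD = 0.15


@dataclass
class SyntheticStandardSpec:
    """Generative description of one synthetic standard.

    ``center`` is a 7-vector in log10 space; ``covariance`` may be a
    scalar SD (isotropic), a 7-vector of per-axis SDs, or a full 7x7
    covariance matrix.  Optional ``subpopulations`` is a list of
    (weight, center, covariance) triples describing a mixture; weights
    must sum to 1 and override the top-level center/covariance.
    """

    name: str
    center: np.ndarray
    covariance: float | np.ndarray = DEFAULT_SD
    n_events: int = 10_000
    subpopulations: list[tuple[float, np.ndarray, float | np.ndarray]] | None = None

    def components(self) -> list[tuple[float, np.ndarray, np.ndarray]]:
        if self.subpopulations:
            comps = [
                (w, np.asarray(c, dtype=float), _as_cov(cov))
                for w, c, cov in self.subpopulations
            ]
            total = sum(w for w, _, _ in comps)
            if not np.isclose(total, 1.0):
                raise ConfigError(f"{self.name}: subpopulation weights sum to {total}")
            return comps
        return [(1.0, np.asarray(self.center, dtype=float), _as_cov(self.covariance))]


def _as_cov(cov: float | np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        return np.eye(_NDIM) * float(cov) ** 2
    if cov.ndim == 1:
        return np.diag(cov**2)
    if cov.shape != (_NDIM, _NDIM):
        raise ConfigError(f"covariance must be {_NDIM}x{_NDIM}")
    if not np.allclose(cov, cov.T):
        raise ConfigError("covariance must be symmetric")
    return cov


@dataclass
class CommunitySpec:
    """Mixture of standards (and optionally a background) forming a community."""

    components: list[tuple[SyntheticStandardSpec, float]]
    total_events: int
    seed: int = 0
    background_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.components)
        if self.components and not np.isclose(total, 1.0):
            raise ConfigError(f"community mixing weights sum to {total}")


def _sample_truncated(
    rng: np.random.Generator,
    mean: np.ndarray,
    cov: np.ndarray,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Multivariate normal samples restricted to the box [lo, hi] by rejection."""
    if np.any(mean < lo) or np.any(mean > hi):
        raise ConfigError("cluster center lies outside the filter bounds")
    out = np.empty((0, _NDIM))
    attempts = 0
    while len(out) < n:
        draw = rng.multivariate_normal(mean, cov, size=max(n - len(out), 64),
                                       method="cholesky")
        inside = np.all((draw >= lo) & (draw <= hi), axis=1)
        out = np.vstack([out, draw[inside]])
        attempts += 1
        if attempts > 1000:
            raise ConfigError("truncation rejects nearly all samples; widen bounds")
    return out[:n]


def generate_standard(
    spec: SyntheticStandardSpec,
    seed: int,
    filter_spec: FilterSpec | None = None,
) -> StandardDataset:
    """Draw a synthetic standard dataset in log10 space, inside the filter bounds."""
    filter_spec = filter_spec or FilterSpec()
    lo, hi = filter_spec.log_lower, filter_spec.log_upper
    rng = np.random.default_rng(seed)
    comps = spec.components()
    weights = np.array([w for w, _, _ in comps])
    assignment = rng.choice(len(comps), size=spec.n_events, p=weights)
    X = np.empty((spec.n_events, _NDIM))
    for i, (_, mean, cov) in enumerate(comps):
        mask = assignment == i
        if mask.any():
            X[mask] = _sample_truncated(rng, mean, cov, int(mask.sum()), lo, hi)
    table = EventTable(
        data=pd.DataFrame(X, columns=list(PARAMETERS)),
        scale=LOG10,
        sample_id=spec.name,
    )
    return StandardDataset(standard_name=spec.name, events=table)


def generate_community(
    spec: CommunitySpec, filter_spec: FilterSpec | None = None
) -> tuple[EventTable, np.ndarray]:
    """Pool standards per mixing weight into one shuffled community table.

    Returns the events plus per-event truth labels; components listed in
    ``background_names`` are labelled "unknown".
    """
    rng = np.random.default_rng(spec.seed)
    if spec.total_events == 0 or not spec.components:
        empty = EventTable(
            data=pd.DataFrame(np.empty((0, _NDIM)), columns=list(PARAMETERS)),
            scale=LOG10, sample_id="community",
        )
        return empty, np.empty(0, dtype=object)
    weights = np.array([w for _, w in spec.components])
    counts = rng.multinomial(spec.total_events, weights)
    frames, labels = [], []
    for (std_spec, _), n in zip(spec.components, counts):
        if n == 0:
            continue
        sized = SyntheticStandardSpec(
            name=std_spec.name, center=std_spec.center,
            covariance=std_spec.covariance, n_events=int(n),
            subpopulations=std_spec.subpopulations,
        )
        ds = generate_standard(sized, seed=int(rng.integers(2**31 - 1)),
                               filter_spec=filter_spec)
        frames.append(ds.events.data)
        label = "unknown" if std_spec.name in spec.background_names else std_spec.name
        labels.append(np.full(n, label, dtype=object))
    data = pd.concat(frames, ignore_index=True)
    truth = np.concatenate(labels)
    order = rng.permutation(len(data))
    table = EventTable(
        data=data.iloc[order].reset_index(drop=True),
        scale=LOG10, sample_id="community",
    )
    return table, truth[order]


def paperlike_standards(
    n_events: int = 10_000,
    sd: float = DEFAULT_SD,
    offset: float = 1.0,
    base: float = 4.0,
) -> list[SyntheticStandardSpec]:
    """The canned five-standard fixture (three-strain proof of concept).

    Five classes with centers ``base + offset * e_i`` on axes 0-4 of
    log10 space, per-axis SD ``sd``; pairwise center distance is
    ``sqrt(2) * offset`` (about 9.4 pooled SD at the defaults, well
    above the ~6 SD where recovery saturates).  Classes 1 and 3 are
    bimodal along axis 5 (two cytometric subpopulations of the same
    strain, weights 0.6/0.4), emulating the within-standard
    heterogeneity seen in real strain standards.
    """
    specs = []
    for i in range(5):
        center = np.full(_NDIM, base)
        center[i] += offset
        if i in (1, 3):
            delta = np.zeros(_NDIM)
            delta[5] = 2.0 * sd
            subpops = [
                (0.6, center + delta, sd),
                (0.4, center - delta, sd),
            ]
            specs.append(SyntheticStandardSpec(
                name=f"STD{i + 1}", center=center, covariance=sd,
                n_events=n_events, subpopulations=subpops,
            ))
        else:
            specs.append(SyntheticStandardSpec(
                name=f"STD{i + 1}", center=center, covariance=sd,
                n_events=n_events,
            ))
    return specs


def background_spec(
    standards: Sequence[SyntheticStandardSpec],
    exclude: Sequence[str],
    n_events: int = 5_000,
    seed: int = 0,
) -> CommunitySpec:
    """Background community resembling every standard except the excluded ones.

    Used for spike-in experiments: the background occupies the regions
    of the non-target standards, so it is disjoint from the target
    standard's cluster and rarely attributed to the target class.
    """
    keep = [s for s in standards if s.name not in set(exclude)]
    if not keep:
        raise ConfigError("background must retain at least one component")
    w = 1.0 / len(keep)
    return CommunitySpec(
        components=[(s, w) for s in keep],
        total_events=n_events,
        seed=seed,
        background_names={s.name for s in keep},
    )


def separability_sweep(
    separations: Sequence[float],
    config: TrainingConfig | None = None,
    n_events: int = 2_000,
    sd: float = DEFAULT_SD,
    seeds: Sequence[int] = (0, 1, 2),
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Recall of a two-standard classifier as cluster separation varies.

    For each separation d (in pooled-SD units) two standards are
    generated with centers d*sd apart along one axis, a classifier is
    trained, and held-out (test block, anchors excluded) per-class
    recall is recorded.  Returns a tidy frame with columns
    ``separation``, ``seed``, ``standard``, ``recall_pct``.
    """
    config = config or TrainingConfig()
    filter_spec = filter_spec or FilterSpec()
    rows = []
    for sep in separations:
        if sep < 0:
            raise ValueError("separations must be non-negative")
        for seed in seeds:
            c1 = np.full(_NDIM, 4.0)
            c2 = c1.copy()
            c2[0] += sep * sd
            spec_a = SyntheticStandardSpec("A", c1, sd, n_events)
            spec_b = SyntheticStandardSpec("B", c2, sd, n_events)
            ds_a = generate_standard(spec_a, seed=seed * 1000 + 1,
                                     filter_spec=filter_spec)
            ds_b = generate_standard(spec_b, seed=seed * 1000 + 2,
                                     filter_spec=filter_spec)
            assembly = assemble_training_set(
                [ds_a, ds_b], n_events, filter_spec, seed=seed
            )
            run_cfg = TrainingConfig(
                max_cycles=config.max_cycles,
                min_gradient=config.min_gradient,
                max_validation_failures=config.max_validation_failures,
                hidden_nodes=config.hidden_nodes,
                performance_goal=config.performance_goal,
                seed=seed,
            )
            model = train_classifier(assembly, run_cfg)
            te = assembly.splits["test"]
            X_log = _unscale(assembly.X[te], *assembly.scaling)
            events = EventTable(
                data=pd.DataFrame(X_log, columns=list(PARAMETERS)),
                scale=LOG10, sample_id="sweep_test",
            )
            result = forward_pass(model, events)
            truth = np.array(assembly.class_labels, dtype=object)[assembly.y[te]]
            _, mx = confusion_and_metrics(
                truth, result, exclude=assembly.anchor_mask[te]
            )
            for name in assembly.class_labels:
                rows.append({
                    "separation": sep, "seed": seed, "standard": name,
                    "recall_pct": mx.recall[name],
                })
    return pd.DataFrame(rows)


def _unscale(Xs: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return (Xs + 1.0) / 2.0 * (hi - lo) + lo
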