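"""Same-class k-nearest-neighbour oversampling.

Class imbalance is endemic in clinical movement data (few low-score
performances, many high-score ones). The remedy implemented here raises
*every* class — minority and majority alike — to a common target count N by
interpolating between an existing sample x and one of its k nearest
same-class neighbours x_k (Euclidean distance over the flattened
time x channel matrix):

    literal mode:  x_new = x + rand(0,1) * |x - x_k|   (element-wise abs)
    smote mode:    x_new = x + rand(0,1) * (x_k - x)

The literal rule is the package default; it biases generated points upward
from x element-wise, unlike standard SMOTE whose signed form is offered as
``mode="smote"``. Both modes are kept because they are genuinely different
generators, not variants of one another. The blend coefficient can be one
scalar per generated sample (default) or drawn per element.

Every generated sample's parentage (parent index, neighbour index, blend
value) is logged in the dataset's provenance table, so leakage checks and
the element-wise parent bounds can be audited after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import N_SCORES, TaskDataset

__all__ = [
    "AugmentationConfig",
    "knn_same_class",
    "synthesize_sample",
    "balance_classes",
    "sweep_augmentation",
]


@dataclass(frozen=True)
class AugmentationConfig:
    k: int = 2
    target_per_class_N: int = 60
    mode: str = "literal"  # "literal" | "smote"
    blend: str = "per_sample_scalar"  # "per_sample_scalar" | "per_element"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target_per_class_N < 1:
            raise ValueError("target_per_class_N must be >= 1")
        if self.mode not in ("literal", "smote"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.blend not in ("per_sample_scalar", "per_element"):
            raise ValueError(f"unknown blend {self.blend!r}")


def knn_same_class(
    x: np.ndarray,
    class_pool: np.ndarray,
    k: int,
    exclude_index: int | None = None,
) -> np.ndarray:
    """Indices of the k pool members nearest to ``x`` (excluding x itself).

    ``class_pool`` is ``(m, d)``. If ``exclude_index`` is None, the first
    pool row exactly equal to ``x`` is excluded. Ties break toward the
    lower index.
    """
    pool = np.asarray(class_pool, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if pool.ndim != 2 or pool.shape[1] != x.size:
        raise ValueError("class_pool must be (m, d) matching x")
    if exclude_index is None:
        matches = np.nonzero((pool == x).all(axis=1))[0]
        exclude_index = int(matches[0]) if matches.size else -1
    candidates = pool.shape[0] - (1 if 0 <= exclude_index < pool.shape[0] else 0)
    if candidates < k:
        raise ValueError(
            f"class pool has only {candidates} candidate neighbours, need k={k}"
        )
    d = np.linalg.norm(pool - x, axis=1)
    if 0 <= exclude_index < pool.shape[0]:
        d[exclude_index] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def synthesize_sample(
    x: np.ndarray,
    x_k: np.ndarray,
    rand_value: float | np.ndarray,
    mode: str = "literal",
) -> np.ndarray:
    """Interpolate a new sample from parent ``x`` and neighbour ``x_k``."""
    x = np.asarray(x, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    if x.shape != x_k.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_k.shape}")
    r = np.asarray(rand_value, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("rand_value must lie in [0, 1]")
    if mode == "literal":
        return x + r * np.abs(x - x_k)
    if mode == "smote":
        return x + r * (x_k - x)
    raise ValueError(f"unknown mode {mode!r}")


def balance_classes(dataset: TaskDataset, config: AugmentationConfig) -> TaskDataset:
    """Raise every present class to exactly N samples.

    Originals are retained verbatim; new samples are appended, each built
    from a uniformly drawn original x of the class and a uniformly chosen
    one of its k nearest same-class original neighbours. Shrinking a class
    is refused: under-sampling is out of scope.
    """
    N = config.target_per_class_N
    counts = dataset.class_counts()
    present = [s for s in range(N_SCORES) if counts[s] > 0]
    for s in present:
        if counts[s] > N:
            raise ValueError(
                f"class {s} has {counts[s]} samples, above target N={N}; "
                "under-sampling is not supported"
            )
        if counts[s] < N and counts[s] < config.k + 1:
            raise ValueError(
                f"class {s} has only {counts[s]} samples; need at least "
                f"k+1={config.k + 1} to draw {config.k} neighbours"
            )

    rng = np.random.default_rng([config.seed, dataset.task_id])
    n, t, ch = dataset.samples.shape
    flat = dataset.samples.reshape(n, t * ch)
    new_samples: list[np.ndarray] = []
    new_labels: list[int] = []
    provenance = list(dataset.provenance)

    for s in present:
        members = np.nonzero(dataset.labels == s)[0]
        pool = flat[members]
        # neighbour lists are static (originals only), so precompute
        neighbours = {
            int(members[j]): members[
                knn_same_class(pool[j], pool, config.k, exclude_index=j)
            ]
            for j in range(len(members))
        }
        for _ in range(N - counts[s]):
            parent = int(rng.choice(members))
            nbr = int(rng.choice(neighbours[parent]))
            if config.blend == "per_sample_scalar":
                r: float | np.ndarray = float(rng.random())
                r_logged: float | str = float(r)
            else:
                r = rng.random(t * ch)
                r_logged = "per_element"
            xn = synthesize_sample(flat[parent], flat[nbr], r, config.mode)
            provenance.append(
                {
                    "index": n + len(new_samples),
                    "parent_index": parent,
                    "neighbour_index": nbr,
                    "rand": r_logged,
                    "mode": config.mode,
                }
            )
            new_samples.append(xn.reshape(t, ch))
            new_labels.append(s)

    if not new_samples:
        return replace(dataset, provenance=provenance)
    samples = np.concatenate([dataset.samples, np.stack(new_samples)])
    labels = np.concatenate([dataset.labels, np.array(new_labels, dtype=int)])
    return TaskDataset(
        samples=samples,
        labels=labels,
        task_id=dataset.task_id,
        sampling_rate_hz=dataset.sampling_rate_hz,
        provenance=provenance,
    )


def sweep_augmentation(
    dataset: TaskDataset,
    N_values: list[int],
    model_variant: str,
    cv_config=None,
    augmentation_config: AugmentationConfig | None = None,
    n_folds: int = 10,
    leakage_mode: str = "pre_split",
):
    """Accuracy as a function of the per-class target N.

    For each N (strictly ascending, no duplicates), balances the dataset to
    N per class and cross-validates ``model_variant``. Returns
    ``(curve, best_N)`` where ``curve`` is a list of ``(N, mean_accuracy)``.
    """
    from .evaluation import TrainConfig, cross_validate  # deferred: cycle

    if list(N_values) != sorted(set(N_values)):
        raise ValueError("N_values must be strictly ascending without duplicates")
    base_aug = augmentation_config or AugmentationConfig()
    cv_config = cv_config or TrainConfig()
    curve = []
    for N in N_values:
        aug = replace(base_aug, target_per_class_N=N)
        report = cross_validate(
            model_variant,
            dataset,
            K=n_folds,
            train_config=cv_config,
            augmentation_config=aug,
            leakage_mode=leakage_mode,
        )
        curve.append((N, report.mean_accuracy))
    best_N = max(curve, key=lambda p: p[1])[0]
    return curve, best_N
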