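"""Self-organizing-map (SOM) weather typing of daily MSLP fields.

Daily mean-sea-level-pressure fields are standardized per grid cell and
fed to a rectangular SOM; each trained node is a recurring pressure
pattern ("weather type", WT), and every day is coded by the index of its
nearest node in Euclidean distance.  Grid size is selected by the
Bauer-Pawelzik topographic product, a scalar diagnostic of how well the
map's neighborhood structure preserves the data-space topology (values
near zero are best; the sign indicates whether the map dimension is too
low or too high).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Preprocessing:
    mean: np.ndarray  # per-cell temporal mean
    sd: np.ndarray  # per-cell temporal sd
    field_shape: tuple[int, int]

    def transform(self, fields: np.ndarray) -> np.ndarray:
        """(n_days, nlat, nlon) -> standardized (n_days, n_cells), row-major."""
        flat = np.asarray(fields, dtype=float).reshape(fields.shape[0], -1)
        return (flat - self.mean) / self.sd


@dataclass
class SOMModel:
    shape: tuple[int, int]  # (rows, cols)
    weights: np.ndarray  # (rows*cols, n_cells), nodes row-major
    sigma: float
    learning_rate: float
    iterations: int
    seed: int
    preprocessing: Preprocessing | None = None
    topographic_product: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    def node_positions(self) -> np.ndarray:
        rows, cols = self.shape
        return np.array([(r, c) for r in range(rows) for c in range(cols)], float)


def preprocess_mslp(fields: np.ndarray) -> tuple[np.ndarray, Preprocessing]:
    """Standardize each grid cell over time; returns vectors and parameters.

    ``fields`` is (n_days, nlat, nlon); flattening is row-major.  A cell
    that is constant in time cannot be standardized and raises.
    """
    fields = np.asarray(fields, dtype=float)
    flat = fields.reshape(fields.shape[0], -1)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=0)
    if np.any(np.isclose(sd, 0.0)):
        raise ValueError("zero-variance grid cell; cannot standardize MSLP")
    prep = Preprocessing(mean, sd, fields.shape[1:])
    return prep.transform(fields), prep


def train_som(
    vectors: np.ndarray,
    shape: tuple[int, int],
    *,
    sigma: float = 1.0,
    learning_rate: float = 0.5,
    iterations: int = 5000,
    seed: int = 0,
    min_samples_per_node: int = 10,
    preprocessing: Preprocessing | None = None,
) -> SOMModel:
    """Train a rectangular SOM with a Gaussian neighborhood.

    Online Kohonen updates with asymptotically decaying sigma and learning
    rate (halved at the midpoint of training); weights are initialized from
    randomly drawn training vectors.  Fully deterministic given the seed.
    """
    X = np.asarray(vectors, dtype=float)
    rows, cols = shape
    n_nodes = rows * cols
    if len(X) < min_samples_per_node * n_nodes:
        raise ValueError(
            f"need >= {min_samples_per_node * n_nodes} samples to train a "
            f"{rows}x{cols} SOM, got {len(X)}"
        )
    rng = np.random.default_rng(seed)
    W = X[rng.choice(len(X), size=n_nodes, replace=False)].copy()
    pos = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
    # pairwise squared map distances between nodes
    map_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)

    order = rng.integers(0, len(X), size=iterations)
    for t in range(iterations):
        decay = 1.0 + t / (iterations / 2.0)
        sig = max(sigma / decay, 1e-3)
        lr = learning_rate / decay
        x = X[order[t]]
        bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
        h = np.exp(-map_d2[bmu] / (2.0 * sig * sig))
        W += lr * h[:, None] * (x - W)

    return SOMModel(
        shape=shape,
        weights=W,
        sigma=sigma,
        learning_rate=learning_rate,
        iterations=iterations,
        seed=seed,
        preprocessing=preprocessing,
    )


def quantization_error(model: SOMModel, vectors: np.ndarray) -> float:
    """Mean Euclidean distance of each vector to its best-matching node."""
    X = np.asarray(vectors, dtype=float)
    d = np.sqrt(((X[:, None, :] - model.weights[None, :, :]) ** 2).sum(-1))
    return float(d.min(axis=1).mean())


def topographic_product(model: SOMModel) -> float:
    """Bauer-Pawelzik topographic product of a trained map.

    For every node j and neighborhood order k the ratios of the distances
    to the k-th nearest neighbor in weight space versus map space are
    combined into P3(j,k) = (prod_{l<=k} Q1(j,l) Q2(j,l))^(1/2k) and
    log-averaged over all j, k.  Zero indicates perfect topology
    preservation; the value is invariant to a global rescaling of the
    weights.
    """
    N = model.n_nodes
    if N < 3:
        raise ValueError("topographic product needs at least 3 nodes")
    W = model.weights
    pos = model.node_positions()
    dV = np.sqrt(((W[:, None, :] - W[None, :, :]) ** 2).sum(-1))
    dA = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))

    total = 0.0
    for j in range(N):
        others = np.array([i for i in range(N) if i != j])
        # stable neighbor orders; ties broken by node index
        nA = others[np.lexsort((others, dA[j, others]))]
        nV = others[np.lexsort((others, dV[j, others]))]
        q1 = dV[j, nA] / dV[j, nV]
        q2 = dA[j, nA] / dA[j, nV]
        log_q = np.log(q1) + np.log(q2)
        csum = np.cumsum(log_q)
        k = np.arange(1, N)
        total += float(np.sum(csum / (2.0 * k)))
    return total / (N * (N - 1))


def select_grid(
    vectors: np.ndarray,
    shapes: list[tuple[int, int]],
    *,
    tuning_grid: dict | None = None,
    seed: int = 0,
    preprocessing: Preprocessing | None = None,
) -> tuple[SOMModel, pd.DataFrame]:
    """Train candidate grid sizes and return the model of minimal |TP|.

    ``tuning_grid`` maps hyperparameter names (``sigma``,
    ``learning_rate``, ``iterations``) to candidate value lists; every
    combination is trained for every shape.  Returns the winning model and
    the full leaderboard (one row per shape x hyperparameter combination).
    """
    if not shapes:
        raise ValueError("no candidate shapes")
    for rows, cols in shapes:
        if not 4 <= rows * cols <= 20:
            raise ValueError(f"shape {rows}x{cols} outside the 4..20-node range")
    if tuning_grid is None:
        tuning_grid = {}
    keys = sorted(tuning_grid)
    combos = list(itertools.product(*(tuning_grid[k] for k in keys))) or [()]

    records = []
    best = None
    for shape in shapes:
        for combo in combos:
            params = dict(zip(keys, combo))
            try:
                model = train_som(
                    vectors, shape, seed=seed, preprocessing=preprocessing, **params
                )
                tp = topographic_product(model)
            except ValueError as exc:
                records.append(
                    {"rows": shape[0], "cols": shape[1], **params,
                     "topographic_product": np.nan, "error": str(exc)}
                )
                continue
            model.topographic_product = tp
            records.append(
                {"rows": shape[0], "cols": shape[1], **params,
                 "topographic_product": tp, "error": ""}
            )
            if best is None or abs(tp) < abs(best.topographic_product):
                best = model
    if best is None:
        raise RuntimeError("all candidate SOM trainings failed")
    return best, pd.DataFrame(records)


def save_model(model: SOMModel, path) -> None:
    """Persist a trained SOM (weights, hyperparameters, preprocessing) as JSON."""
    import json

    payload = {
        "shape": list(model.shape),
        "weights": model.weights.tolist(),
        "sigma": model.sigma,
        "learning_rate": model.learning_rate,
        "iterations": model.iterations,
        "seed": model.seed,
        "topographic_product": model.topographic_product,
        "preprocessing": None
        if model.preprocessing is None
        else {
            "mean": model.preprocessing.mean.tolist(),
            "sd": model.preprocessing.sd.tolist(),
            "field_shape": list(model.preprocessing.field_shape),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> SOMModel:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    prep = payload["preprocessing"]
    preprocessing = None
    if prep is not None:
        preprocessing = Preprocessing(
            np.asarray(prep["mean"]), np.asarray(prep["sd"]),
            tuple(prep["field_shape"]),
        )
    return SOMModel(
        shape=tuple(payload["shape"]),
        weights=np.asarray(payload["weights"], dtype=float),
        sigma=payload["sigma"],
        learning_rate=payload["learning_rate"],
        iterations=payload["iterations"],
        seed=payload["seed"],
        preprocessing=preprocessing,
        topographic_product=payload["topographic_product"],
    )


def assign_wt(vectors: np.ndarray, model: SOMModel) -> np.ndarray:
    """Code each day by its nearest node (row-major, 1-based; ties -> lowest).

    ``vectors`` must be preprocessed with the same per-cell standardization
    as the training data (see :class:`Preprocessing`).
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[1] != model.weights.shape[1]:
        raise ValueError("vector dimension does not match SOM weights")
    d2 = ((X[:, None, :] - model.weights[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1) + 1
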